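"""Seed decisions and metrics: the vote rule against brute-force
enumeration, the closed-form voting gain, and score() against a naive
per-class oracle."""

import itertools

import numpy as np
import pytest

from libsid import evaluate as ev


def _brute_force_vote(labels, probas):
    """Independent restatement of the decision rule."""
    counts = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    if best >= 2:
        return [lab for lab, c in counts.items() if c == best][0]
    total = np.sum(probas, axis=0)
    return int(np.flatnonzero(total == total.max())[0])


class TestMajorityVote:
    def test_majority_and_unanimity(self):
        p = np.full(10, 0.1)
        assert ev.majority_vote([3, 3, 7], [p, p, p]) == 3
        assert ev.majority_vote([5, 5, 5], [p, p, p]) == 5

    def test_all_distinct_uses_probabilities(self):
        pa = np.zeros(10); pa[0] = 1.0
        pb = np.zeros(10); pb[4] = 0.6; pb[1] = 0.4
        pc = np.zeros(10); pc[7] = 0.55; pc[4] = 0.45
        # summed: class 4 gets 1.05, the maximum
        assert ev.majority_vote([0, 4, 7], [pa, pb, pc]) == 4

    def test_exact_tie_falls_to_lowest_index(self):
        onehots = [np.eye(10)[i] for i in (8, 2, 5)]
        assert ev.majority_vote([8, 2, 5], onehots) == 2

    def test_wrong_arity_rejected(self):
        p = np.full(10, 0.1)
        with pytest.raises(ValueError):
            ev.majority_vote([1, 2], [p, p])

    def test_enumeration_of_all_label_triples(self):
        """All 1000 triples for K=10 agree with the brute-force rule,
        including the tie-break path."""
        K = 10
        rng = np.random.default_rng(0)
        probas = rng.dirichlet(np.ones(K), size=3)
        mismatches = 0
        for triple in itertools.product(range(K), repeat=3):
            ps = [probas[i] for i in range(3)]
            if ev.majority_vote(list(triple), ps) != \
                    _brute_force_vote(list(triple), ps):
                mismatches += 1
        assert mismatches == 0


def _decisions_from_confusion(conf):
    ds = []
    for t, row in enumerate(conf):
        for p, count in enumerate(row):
            for i in range(count):
                ds.append(ev.SeedDecision(f"s{t}_{p}_{i}", t, p, "matrix"))
    return ds


class TestScore:
    def test_perfect_decisions(self):
        ds = [ev.SeedDecision(f"s{i}", i % 3, i % 3, "matrix")
              for i in range(12)]
        r = ev.score(ds, n_classes=3)
        assert r.accuracy == 1.0
        assert r.macro_precision == r.macro_recall == r.macro_f1 == 1.0
        assert r.macro_mcc == 1.0
        assert np.array_equal(np.diag(np.diag(r.confusion)), r.confusion)

    def test_hand_computed_binary_example(self):
        """Confusion [[8,2],[3,7]]: accuracy 15/20, per-class MCC equals
        the binary MCC (8*7-2*3)/sqrt(10*10*11*9)."""
        r = ev.score(_decisions_from_confusion([[8, 2], [3, 7]]),
                     n_classes=2)
        assert r.accuracy == pytest.approx(0.75)
        want_mcc = (8 * 7 - 2 * 3) / np.sqrt(10 * 10 * 11 * 9)
        assert r.macro_mcc == pytest.approx(want_mcc)
        assert np.array_equal(r.confusion, [[8, 2], [3, 7]])

    def test_trace_over_total_equals_accuracy(self):
        rng = np.random.default_rng(1)
        conf = rng.integers(0, 10, size=(4, 4))
        conf[0, 0] += 1   # nonempty
        r = ev.score(_decisions_from_confusion(conf), n_classes=4)
        assert r.accuracy == pytest.approx(r.confusion.trace()
                                           / r.confusion.sum())

    def test_single_class_present(self):
        ds = [ev.SeedDecision(f"s{i}", 0, 0, "matrix") for i in range(5)]
        r = ev.score(ds, n_classes=3)
        assert r.macro_recall == pytest.approx(1.0 / 3)

    def test_matches_naive_per_class_oracle(self):
        """100 random decision lists against an independent loop."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            K = int(rng.integers(2, 6))
            n = int(rng.integers(5, 40))
            yt = rng.integers(0, K, n)
            yp = rng.integers(0, K, n)
            ds = [ev.SeedDecision(f"s{i}", int(t), int(p), "matrix")
                  for i, (t, p) in enumerate(zip(yt, yp))]
            r = ev.score(ds, n_classes=K)
            # naive oracle
            precis, recall, f1s, mccs = [], [], [], []
            for k in range(K):
                tp = int(np.sum((yt == k) & (yp == k)))
                fp = int(np.sum((yt != k) & (yp == k)))
                fn = int(np.sum((yt == k) & (yp != k)))
                tn = n - tp - fp - fn
                p = tp / (tp + fp) if tp + fp else 0.0
                rc = tp / (tp + fn) if tp + fn else 0.0
                precis.append(p)
                recall.append(rc)
                f1s.append(2 * p * rc / (p + rc) if p + rc else 0.0)
                den = np.sqrt(float(tp + fp) * (tp + fn)
                              * (tn + fp) * (tn + fn))
                mccs.append((tp * tn - fp * fn) / den if den else 0.0)
            assert r.accuracy == pytest.approx(np.mean(yt == yp))
            assert r.macro_precision == pytest.approx(np.mean(precis))
            assert r.macro_recall == pytest.approx(np.mean(recall))
            assert r.macro_f1 == pytest.approx(np.mean(f1s))
            assert r.macro_mcc == pytest.approx(np.mean(mccs))


class TestVoteGain:
    def test_published_svm_row(self):
        assert ev.compare_vote_gain(0.8467, 0.90) == pytest.approx(0.0533)

    def test_equal_inputs_zero(self):
        assert ev.compare_vote_gain(0.5, 0.5) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ev.compare_vote_gain(1.2, 0.5)

    def test_voting_closed_form_at_p08(self):
        """Independent per-spectrum correctness at p = 0.8 on 2000 seeds:
        voted accuracy matches p^3 + 3 p^2 (1-p) within 2 binomial SE.

        Wrong predictions carry higher confidence than correct ones, so
        every all-distinct tie resolves to a wrong label and the
        pure-majority closed form applies exactly.
        """
        K, n_seeds, p = 10, 2000, 0.8
        rng = np.random.default_rng(3)
        correct = 0
        for s in range(n_seeds):
            true = int(rng.integers(K))
            labels, probas = [], []
            n_right = 0
            for _ in range(3):
                if rng.random() < p:
                    lab = true
                    conf = 0.5
                    n_right += 1
                else:
                    lab = int((true + 1 + rng.integers(K - 1)) % K)
                    conf = 0.9
                vec = np.full(K, (1 - conf) / (K - 1))
                vec[lab] = conf
                labels.append(lab)
                probas.append(vec)
            won = ev.majority_vote(labels, probas) == true
            assert won == (n_right >= 2)     # exactly the majority rule
            correct += won
        voted = correct / n_seeds
        expected = p ** 3 + 3 * p ** 2 * (1 - p)
        se = np.sqrt(expected * (1 - expected) / n_seeds)
        assert abs(voted - expected) <= 2 * se

    def test_voting_never_hurts_with_independent_errors(self):
        """For per-spectrum accuracy > 1/2 and independent errors,
        majority voting improves accuracy (within 2 SE)."""
        K, n_seeds, p = 5, 1500, 0.7
        rng = np.random.default_rng(7)
        correct = 0
        for _ in range(n_seeds):
            true = 0
            labels = []
            for _ in range(3):
                if rng.random() < p:
                    labels.append(true)
                else:
                    labels.append(int(rng.integers(1, K)))
            onehots = [np.eye(K)[l] for l in labels]
            if ev.majority_vote(labels, onehots) == true:
                correct += 1
        voted = correct / n_seeds
        se = np.sqrt(p * (1 - p) / n_seeds)
        assert voted >= p - 2 * se
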