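"""Seed-level decisions and classification metrics.

A seed is classified either from its three spectra through a majority
vote (the 1D route) or from its spectral matrix directly (the 2D
route).  The vote returns any label predicted at least twice; a
three-way tie falls back to the argmax of the element-wise sum of the
three probability vectors, and a further exact tie to the lowest
class index.

Metrics are computed from the K×K confusion matrix (rows = true,
columns = predicted): accuracy plus macro-averaged one-vs-rest
precision, recall, F-measure and Matthews correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SeedDecision",
    "MetricReport",
    "majority_vote",
    "decide_by_vote",
    "decide_direct",
    "score",
    "compare_vote_gain",
]


@dataclass
class SeedDecision:
    seed_id: str
    true_class: int
    predicted_class: int
    rule: str                   # "vote" or "matrix"
    spectrum_labels: tuple = ()  # per-spectrum labels (vote rule only)
    spectrum_probas: tuple = ()  # per-spectrum probability vectors

    def __post_init__(self):
        if self.rule not in ("vote", "matrix"):
            raise ValueError("rule must be 'vote' or 'matrix'")
        if self.rule == "vote" and len(self.spectrum_labels) != 3:
            raise ValueError("vote rule carries exactly 3 predictions")


@dataclass
class MetricReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_mcc: float
    confusion: np.ndarray       # K×K, rows = true, columns = predicted

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy,
                "macro_precision": self.macro_precision,
                "macro_recall": self.macro_recall,
                "macro_f1": self.macro_f1,
                "macro_mcc": self.macro_mcc,
                "confusion": self.confusion.tolist()}


def majority_vote(labels, probas) -> int:
    """Seed decision from three per-spectrum predictions.

    Any label occurring at least twice wins.  If all three labels
    differ, the argmax of the summed probability vectors decides; an
    exact tie there falls to the lowest class index.
    """
    labels = list(labels)
    probas = [np.asarray(p, dtype=float) for p in probas]
    if len(labels) != 3 or len(probas) != 3:
        raise ValueError("exactly three labels and probability vectors")
    K = len(probas[0])
    if any(len(p) != K for p in probas):
        raise ValueError("probability vectors differ in length")
    for lab in labels:
        if labels.count(lab) >= 2:
            return int(lab)
    total = probas[0] + probas[1] + probas[2]
    return int(np.argmax(total))    # argmax takes the lowest index on ties


def decide_by_vote(seed_ids, labels, probas, true_labels) -> list:
    """Group per-spectrum predictions by seed and vote.

    All inputs are parallel per-spectrum sequences; each seed must
    appear exactly three times.
    """
    by_seed: dict = {}
    for sid, lab, p, t in zip(seed_ids, labels, probas, true_labels):
        by_seed.setdefault(sid, []).append((int(lab), np.asarray(p), int(t)))
    decisions = []
    for sid in sorted(by_seed):
        entries = by_seed[sid]
        if len(entries) != 3:
            raise ValueError(f"seed {sid} has {len(entries)} spectra, not 3")
        labs = [e[0] for e in entries]
        ps = [e[1] for e in entries]
        decisions.append(SeedDecision(
            seed_id=sid, true_class=entries[0][2],
            predicted_class=majority_vote(labs, ps), rule="vote",
            spectrum_labels=tuple(labs),
            spectrum_probas=tuple(tuple(p) for p in ps)))
    return decisions


def decide_direct(seed_ids, predicted, true_labels) -> list:
    """One decision per seed from its spectral-matrix prediction."""
    return [SeedDecision(seed_id=s, true_class=int(t),
                         predicted_class=int(p), rule="matrix")
            for s, p, t in zip(seed_ids, predicted, true_labels)]


def _safe_div(num, den):
    return num / den if den != 0 else 0.0


def score(decisions, n_classes: int | None = None) -> MetricReport:
    """Confusion matrix, accuracy and macro one-vs-rest metrics.

    Classes absent from the predictions contribute 0 to their
    undefined ratios (per-class precision/recall/F/MCC default to 0
    when their denominators vanish).
    """
    decisions = list(decisions)
    if not decisions:
        raise ValueError("no decisions to score")
    y_true = np.array([d.true_class for d in decisions])
    y_pred = np.array([d.predicted_class for d in decisions])
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    K = n_classes
    conf = np.zeros((K, K), dtype=int)
    np.add.at(conf, (y_true, y_pred), 1)
    total = conf.sum()
    accuracy = conf.trace() / total
    precis, recall, f1, mcc = [], [], [], []
    for k in range(K):
        tp = conf[k, k]
        fp = conf[:, k].sum() - tp
        fn = conf[k, :].sum() - tp
        tn = total - tp - fp - fn
        p = _safe_div(tp, tp + fp)
        r = _safe_div(tp, tp + fn)
        precis.append(p)
        recall.append(r)
        f1.append(_safe_div(2 * p * r, p + r))
        den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc.append(_safe_div(tp * tn - fp * fn, den))
    return MetricReport(accuracy=float(accuracy),
                        macro_precision=float(np.mean(precis)),
                        macro_recall=float(np.mean(recall)),
                        macro_f1=float(np.mean(f1)),
                        macro_mcc=float(np.mean(mcc)),
                        confusion=conf)


def compare_vote_gain(single_accuracy: float, voted_accuracy: float) -> float:
    """Signed improvement of the voted over the single-spectrum rule."""
    for a in (single_accuracy, voted_accuracy):
        if not 0.0 <= a <= 1.0:
            raise ValueError("accuracies must lie in [0, 1]")
    return voted_accuracy - single_accuracy
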