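"""Preprocessing: crop, area normalization, dead-variable removal,
seed-level partitioning and spectral-matrix assembly.

The fixed pipeline order is crop → area-normalize → variable mask →
split → matrix assembly.  The partition is drawn at seed level (all
three spectra of a seed land in the same partition — the leakage
guard every split asserts) and the variable mask is fitted on the
calibration partition only, then applied unchanged everywhere, so all
partitions share the same kept-wavelength grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sim import SpectraDataset

__all__ = [
    "Spectrum",
    "NormalizedSpectrum",
    "VariableMask",
    "DatasetSplit",
    "SpectralMatrix",
    "PreprocessedData",
    "crop",
    "area_normalize",
    "fit_variable_mask",
    "split_by_seed",
    "assemble_matrix",
    "preprocess_dataset",
]

PARTITIONS = ("calibration", "validation", "prediction")


@dataclass
class Spectrum:
    wavelengths: np.ndarray
    intensities: np.ndarray
    seed_id: str = ""
    variety_id: int = 0
    point_index: int = 1

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelength/intensity length mismatch")
        if len(self.wavelengths) > 1 and np.any(
                np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")


class NormalizedSpectrum(Spectrum):
    """A spectrum whose intensities sum to one (area normalized)."""


@dataclass
class VariableMask:
    keep: np.ndarray            # boolean flag per wavelength index
    std_threshold: float        # absolute threshold that was applied

    def __post_init__(self):
        self.keep = np.asarray(self.keep, dtype=bool)
        if not self.keep.any():
            raise ValueError("mask keeps no variables")

    def apply(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x)[..., self.keep]


@dataclass(frozen=True)
class DatasetSplit:
    calibration: frozenset
    validation: frozenset
    prediction: frozenset
    ratio: tuple

    def __post_init__(self):
        parts = [self.calibration, self.validation, self.prediction]
        for i in range(3):
            for j in range(i + 1, 3):
                if parts[i] & parts[j]:
                    raise ValueError("partitions overlap")

    def partition_of(self, seed_id) -> str:
        for name in PARTITIONS:
            if seed_id in getattr(self, name):
                return name
        raise KeyError(seed_id)


@dataclass
class SpectralMatrix:
    """3×P stack of one seed's area-normalized spectra (2D-CNN input)."""
    values: np.ndarray
    seed_id: str
    variety_id: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 3:
            raise ValueError("spectral matrix must have exactly 3 rows")


# ----------------------------------------------------------------------
def crop(spectrum: Spectrum, lo_nm: float, hi_nm: float) -> Spectrum:
    """Keep wavelengths with lo <= λ <= hi (inclusive both ends)."""
    if lo_nm >= hi_nm:
        raise ValueError("crop bounds must satisfy lo < hi")
    sel = (spectrum.wavelengths >= lo_nm) & (spectrum.wavelengths <= hi_nm)
    if not sel.any():
        raise ValueError("empty crop window")
    return type(spectrum)(spectrum.wavelengths[sel],
                          spectrum.intensities[sel],
                          spectrum.seed_id, spectrum.variety_id,
                          spectrum.point_index)


def area_normalize(spectrum: Spectrum) -> NormalizedSpectrum:
    """X_i = x_i / Σ x_i, so the spectrum sums to one."""
    total = spectrum.intensities.sum()
    if total == 0:
        raise ValueError("degenerate spectrum: zero total intensity")
    return NormalizedSpectrum(spectrum.wavelengths,
                              spectrum.intensities / total,
                              spectrum.seed_id, spectrum.variety_id,
                              spectrum.point_index)


def fit_variable_mask(calibration: np.ndarray,
                      rel_threshold: float = 1e-6) -> VariableMask:
    """Drop near-zero-variance wavelengths, judged on calibration only.

    Index j is dropped iff std_j < rel_threshold × max_k std_k (and
    exactly-constant columns, std 0, are always dropped).
    """
    X = np.asarray(calibration, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two calibration spectra")
    if rel_threshold < 0:
        raise ValueError("rel_threshold must be nonnegative")
    std = X.std(axis=0)
    thr = rel_threshold * std.max()
    keep = ~((std < thr) | (std == 0.0))
    if not keep.any():
        raise ValueError("mask would drop every variable")
    return VariableMask(keep=keep, std_threshold=float(thr))


def split_by_seed(dataset: SpectraDataset, ratio=(3, 1, 1),
                  rng_seed: int = 0) -> DatasetSplit:
    """Random seed-level partition, stratified per variety.

    Within each variety, seed counts follow ``ratio`` with
    largest-remainder rounding (fractional ties resolved in favour of
    calibration, then validation).  All spectra of a seed share its
    partition by construction.
    """
    ratio = tuple(int(r) for r in ratio)
    if len(ratio) != 3 or any(r < 0 for r in ratio) or sum(ratio) == 0:
        raise ValueError("ratio must be three nonnegative integers")
    by_variety: dict[int, list] = {}
    seen = set()
    for r in dataset.records:
        if r.seed_id not in seen:
            seen.add(r.seed_id)
            by_variety.setdefault(r.variety_id, []).append(r.seed_id)
    rng = np.random.default_rng(rng_seed)
    parts: list[set] = [set(), set(), set()]
    R = sum(ratio)
    for variety in sorted(by_variety):
        seeds = sorted(by_variety[variety])
        n = len(seeds)
        if n < 5:
            raise ValueError(
                f"variety {variety} has {n} seeds; at least 5 required")
        quota = [n * r / R for r in ratio]
        counts = [int(np.floor(q)) for q in quota]
        remainder = n - sum(counts)
        frac_order = sorted(range(3), key=lambda i: (-(quota[i] - counts[i]),
                                                     i))
        for i in range(remainder):
            counts[frac_order[i % 3]] += 1
        order = rng.permutation(n)
        shuffled = [seeds[i] for i in order]
        start = 0
        for p in range(3):
            parts[p].update(shuffled[start:start + counts[p]])
            start += counts[p]
    return DatasetSplit(frozenset(parts[0]), frozenset(parts[1]),
                        frozenset(parts[2]), ratio)


def assemble_matrix(spectra) -> SpectralMatrix:
    """Stack one seed's three normalized spectra, ordered by point index."""
    spectra = list(spectra)
    if len(spectra) != 3:
        raise ValueError("exactly three spectra required")
    seed_ids = {s.seed_id for s in spectra}
    if len(seed_ids) != 1:
        raise ValueError("spectra come from different seeds")
    points = sorted(s.point_index for s in spectra)
    if points != [1, 2, 3]:
        raise ValueError(f"point indices must be {{1,2,3}}, got {points}")
    grids = [s.wavelengths for s in spectra]
    if not all(np.array_equal(grids[0], g) for g in grids[1:]):
        raise ValueError("wavelength grids differ between spectra")
    ordered = sorted(spectra, key=lambda s: s.point_index)
    return SpectralMatrix(np.stack([s.intensities for s in ordered]),
                          seed_id=spectra[0].seed_id,
                          variety_id=spectra[0].variety_id)


# ----------------------------------------------------------------------
@dataclass
class Partition:
    """Model-ready arrays for one partition."""
    X: np.ndarray               # (n_spectra, P) normalized masked spectra
    y: np.ndarray               # (n_spectra,) 0-based class labels
    seed_ids: list
    point_index: np.ndarray
    matrices: np.ndarray        # (n_seeds, 3, P)
    matrix_y: np.ndarray        # (n_seeds,)
    matrix_seed_ids: list


@dataclass
class PreprocessedData:
    wavelengths: np.ndarray     # kept wavelengths (nm)
    mask: VariableMask
    split: DatasetSplit
    classes: np.ndarray         # variety ids, index = 0-based label
    partitions: dict

    def partition(self, name: str) -> Partition:
        return self.partitions[name]


def preprocess_dataset(dataset: SpectraDataset, lo_nm: float = 242.0,
                       hi_nm: float = 882.0, rel_threshold: float = 1e-6,
                       ratio=(3, 1, 1), rng_seed: int = 0
                       ) -> PreprocessedData:
    """Run the full pipeline on a dataset.

    Crop to [lo, hi] nm, area-normalize each spectrum, draw the
    seed-level split, fit the variance mask on calibration spectra,
    apply it to every partition, and assemble the per-seed 3×P
    spectral matrices.
    """
    wl = dataset.wavelengths
    sel = (wl >= lo_nm) & (wl <= hi_nm)
    if not sel.any():
        raise ValueError("empty crop window")
    X = dataset.intensity_matrix()[:, sel]
    sums = X.sum(axis=1)
    if np.any(sums == 0):
        bad = int(np.argmax(sums == 0))
        raise ValueError(f"degenerate spectrum: zero total intensity "
                         f"(record {bad})")
    X = X / sums[:, None]
    y_variety = dataset.labels()
    seed_ids = dataset.seed_ids()
    points = np.array([r.point_index for r in dataset.records])

    split = split_by_seed(dataset, ratio=ratio, rng_seed=rng_seed)
    part_of = np.array([split.partition_of(s) for s in seed_ids])
    # leakage guard: every seed's spectra sit in exactly one partition
    seed_part: dict = {}
    for s, p in zip(seed_ids, part_of):
        assert seed_part.setdefault(s, p) == p, "seed straddles partitions"

    mask = fit_variable_mask(X[part_of == "calibration"],
                             rel_threshold=rel_threshold)
    classes = np.unique(y_variety)
    label_of = {v: i for i, v in enumerate(classes)}

    partitions = {}
    for name in PARTITIONS:
        rows = np.where(part_of == name)[0]
        Xp = mask.apply(X[rows])
        yp = np.array([label_of[y_variety[i]] for i in rows], dtype=int)
        sids = [seed_ids[i] for i in rows]
        pts = points[rows]
        # group into per-seed matrices, rows ordered by point index
        mats, mat_y, mat_sids = [], [], []
        by_seed: dict = {}
        for j, sid in enumerate(sids):
            by_seed.setdefault(sid, []).append(j)
        for sid in sorted(by_seed):
            idx = by_seed[sid]
            if len(idx) == 3 and sorted(pts[idx]) == [1, 2, 3]:
                order = np.argsort(pts[idx])
                mats.append(Xp[np.array(idx)[order]])
                mat_y.append(yp[idx[0]])
                mat_sids.append(sid)
        partitions[name] = Partition(
            X=Xp, y=yp, seed_ids=sids, point_index=pts,
            matrices=(np.stack(mats) if mats
                      else np.empty((0, 3, Xp.shape[1]))),
            matrix_y=np.array(mat_y, dtype=int),
            matrix_seed_ids=mat_sids)
    return PreprocessedData(wavelengths=wl[sel][mask.keep], mask=mask,
                            split=split, classes=classes,
                            partitions=partitions)
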