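"""Synthetic LIBS emission-spectrum simulator.

Emulates the statistical structure of a seed-variety LIBS study: K
varieties, a fixed number of seeds per variety, and three ablation
points per seed, each yielding one spectrum on a shared wavelength
grid.  A spectrum is a sum of Lorentzian emission lines at the
characteristic wavelengths of the elements found in seed tissue
(C, Si, Mg, Ca, Na, H, K, O, N, Fe and the CN molecular band), on top
of a smooth continuum baseline, with a seed-level multiplicative
shot-to-shot fluctuation and additive detector noise.

Variety identity enters only through per-line intensity multipliers
(``VarietyProfile``): varieties differ in the content and proportion
of these elements, which is exactly the signal the downstream
classifiers must recover.  The simulator does no plasma physics — no
Saha-Boltzmann equilibrium, no self-absorption — because the pipeline
only needs localized, positive, variety-dependent peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmissionLine",
    "VarietyProfile",
    "SimConfig",
    "SpectrumRecord",
    "SpectraDataset",
    "default_line_table",
    "default_profiles",
    "simulate_spectrum",
    "simulate_dataset",
]


@dataclass(frozen=True)
class EmissionLine:
    wavelength_nm: float
    element: str
    base_intensity: float
    width_nm: float = 0.3       # Lorentzian half-width

    def __post_init__(self):
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.width_nm <= 0:
            raise ValueError("width must be positive")
        if self.base_intensity < 0:
            raise ValueError("base intensity must be nonnegative")


@dataclass(frozen=True)
class VarietyProfile:
    """Per-variety line-intensity multipliers (one per emission line)."""
    variety_id: int
    line_multipliers: tuple

    def __post_init__(self):
        if any(m < 0 for m in self.line_multipliers):
            raise ValueError("multipliers must be nonnegative")


@dataclass(frozen=True)
class SimConfig:
    n_varieties: int = 10
    seeds_per_variety: int = 200
    spectra_per_seed: int = 3
    grid_start_nm: float = 230.0
    grid_end_nm: float = 904.0
    grid_step_nm: float = 0.05
    noise_sd: float = 0.01
    shot_fluctuation_sd: float = 0.10
    baseline_amplitude: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if self.grid_start_nm >= self.grid_end_nm:
            raise ValueError("grid_start_nm must be below grid_end_nm")
        if min(self.n_varieties, self.seeds_per_variety,
               self.spectra_per_seed) < 1:
            raise ValueError("all counts must be >= 1")
        if min(self.noise_sd, self.shot_fluctuation_sd,
               self.baseline_amplitude) < 0:
            raise ValueError("noise parameters must be nonnegative")

    def wavelengths(self) -> np.ndarray:
        n = int(round((self.grid_end_nm - self.grid_start_nm)
                      / self.grid_step_nm)) + 1
        return self.grid_start_nm + self.grid_step_nm * np.arange(n)


@dataclass(frozen=True)
class SpectrumRecord:
    seed_id: str
    variety_id: int
    point_index: int            # ablation point, 1..3 (2 = middle)
    intensities: np.ndarray


@dataclass
class SpectraDataset:
    wavelengths: np.ndarray
    records: list

    def __post_init__(self):
        P = len(self.wavelengths)
        for r in self.records:
            if len(r.intensities) != P:
                raise ValueError("intensity length does not match grid")

    def __len__(self):
        return len(self.records)

    def intensity_matrix(self) -> np.ndarray:
        return np.stack([r.intensities for r in self.records])

    def labels(self) -> np.ndarray:
        return np.array([r.variety_id for r in self.records])

    def seed_ids(self) -> list:
        return [r.seed_id for r in self.records]


# Characteristic emission lines of seed tissue with NIST wavelengths.
# Base intensities are relative plausible values: resonance Ca II / Na I /
# K I / H-alpha lines strong, minor-element lines weaker.  The CN
# violet band is one broad feature centred at 388 nm.
_LINE_TABLE = [
    ("C",  247.86, 0.60), ("Si", 251.61, 0.35),
    ("Mg", 279.55, 0.80), ("Mg", 280.27, 0.65),
    ("Ca", 317.93, 0.50), ("CN", 388.00, 0.70),
    ("Ca", 393.37, 1.00), ("Ca", 396.80, 0.90),
    ("Ca", 422.67, 0.85), ("Ca", 430.25, 0.40),
    ("Ca", 445.48, 0.35), ("Na", 589.59, 0.75),
    ("H",  656.28, 0.90), ("K",  766.49, 1.00),
    ("K",  769.90, 0.85), ("N",  746.83, 0.45),
    ("O",  777.54, 0.70), ("N",  821.63, 0.40),
    ("Fe", 844.80, 0.25), ("Ca", 854.21, 0.55),
    ("N",  868.03, 0.35),
]


def default_line_table() -> list[EmissionLine]:
    """Emission lines of the elements observed in soybean seed plasma."""
    return [EmissionLine(wl, el, base,
                         width_nm=(1.5 if el == "CN" else 0.3))
            for el, wl, base in _LINE_TABLE]


def default_profiles(n_varieties: int, n_lines: int | None = None,
                     separation: float = 0.25,
                     rng_seed: int = 12345) -> list[VarietyProfile]:
    """Variety profiles with log-normal line multipliers around 1.

    ``separation`` is the log-scale standard deviation of the
    multipliers: 0 makes all varieties identical, larger values spread
    the elemental compositions apart and make classification easier.
    """
    if n_lines is None:
        n_lines = len(_LINE_TABLE)
    rng = np.random.default_rng(rng_seed)
    profiles = []
    for v in range(1, n_varieties + 1):
        mult = np.exp(rng.normal(0.0, separation, size=n_lines))
        profiles.append(VarietyProfile(v, tuple(mult)))
    return profiles


def _line_shapes(lines, wavelengths) -> np.ndarray:
    """(n_lines, P) matrix of unit-height Lorentzian profiles × base."""
    wl = np.asarray(wavelengths)
    shapes = np.empty((len(lines), len(wl)))
    for i, ln in enumerate(lines):
        w2 = ln.width_nm ** 2
        shapes[i] = ln.base_intensity * w2 / ((wl - ln.wavelength_nm) ** 2
                                              + w2)
    return shapes


def _baseline(wavelengths, amplitude, rng) -> np.ndarray:
    """Smooth continuum: a random cubic in [0, amplitude]."""
    t = ((wavelengths - wavelengths[0])
         / max(wavelengths[-1] - wavelengths[0], 1e-12))
    coeffs = rng.uniform(0.0, 1.0, size=4)
    poly = coeffs[0] + coeffs[1] * t + coeffs[2] * t ** 2 + coeffs[3] * t ** 3
    return amplitude * poly / 4.0


def simulate_spectrum(profile: VarietyProfile, lines: list[EmissionLine],
                      cfg: SimConfig, rng: np.random.Generator,
                      shot_factor: float | None = None) -> np.ndarray:
    """One spectrum: shot_factor * (baseline + lines) + noise, clipped at 0.

    ``shot_factor`` is the seed-level multiplicative fluctuation; when
    None it is drawn here as LogNormal(0, shot_fluctuation_sd).
    """
    if len(profile.line_multipliers) != len(lines):
        raise ValueError("profile length does not match line table")
    wl = cfg.wavelengths()
    shapes = _line_shapes(lines, wl)
    signal = np.asarray(profile.line_multipliers) @ shapes
    base = _baseline(wl, cfg.baseline_amplitude, rng)
    if shot_factor is None:
        shot_factor = float(np.exp(rng.normal(0.0, cfg.shot_fluctuation_sd))) \
            if cfg.shot_fluctuation_sd > 0 else 1.0
    spec = shot_factor * (signal + base)
    if cfg.noise_sd > 0:
        spec = spec + rng.normal(0.0, cfg.noise_sd, size=spec.shape)
    return np.clip(spec, 0.0, None)


def simulate_dataset(cfg: SimConfig,
                     profiles: list[VarietyProfile] | None = None,
                     lines: list[EmissionLine] | None = None
                     ) -> SpectraDataset:
    """Full study: n_varieties × seeds_per_variety × spectra_per_seed.

    The spectra of one seed share a single shot-fluctuation draw (they
    come from one physical seed) but have independent baselines and
    additive noise (separate ablation points and acquisitions).
    """
    if lines is None:
        lines = default_line_table()
    if profiles is None:
        profiles = default_profiles(cfg.n_varieties, len(lines))
    if len(profiles) != cfg.n_varieties:
        raise ValueError("need one profile per variety")
    rng = np.random.default_rng(cfg.rng_seed)
    wl = cfg.wavelengths()
    shapes = _line_shapes(lines, wl)
    records = []
    for profile in profiles:
        signal = np.asarray(profile.line_multipliers) @ shapes
        for s in range(cfg.seeds_per_variety):
            seed_id = f"v{profile.variety_id:02d}s{s + 1:04d}"
            shot = float(np.exp(rng.normal(0.0, cfg.shot_fluctuation_sd))) \
                if cfg.shot_fluctuation_sd > 0 else 1.0
            for p in range(1, cfg.spectra_per_seed + 1):
                base = _baseline(wl, cfg.baseline_amplitude, rng)
                spec = shot * (signal + base)
                if cfg.noise_sd > 0:
                    spec = spec + rng.normal(0.0, cfg.noise_sd,
                                             size=spec.shape)
                records.append(SpectrumRecord(
                    seed_id, profile.variety_id, p,
                    np.clip(spec, 0.0, None)))
    return SpectraDataset(wavelengths=wl, records=records)
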