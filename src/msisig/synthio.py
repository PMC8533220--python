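"""Synthetic cohorts, MSI datasets and LC-MS/MS reference lists with ground truth.

The generator emulates a tissue-microarray MALDI-MSI study of resected
pancreatic tumors: a cohort of patients carrying binary prognostic
histopathology flags (lymphatic vessel invasion pL, nodal metastasis pN,
angioinvasion pV) at the published prevalences, 1-7 tissue cores per patient,
and one profile spectrum per pixel over the tryptic-peptide detection range
m/z 800-3200.

Each spectrum is a sum of Gaussian peptide peaks whose per-pixel amplitudes
are log-normal (MSI peptide intensities are heavy-tailed and strictly
positive), on top of a slowly varying baseline (low-frequency sinusoid plus a
linear ramp) and additive Gaussian noise, clipped at zero.  A configurable
subset of peaks is *planted*: grouped into synthetic proteins (two peptides
per protein by default, matching the two-peptide identification rule), their
amplitudes are multiplied (direction "up") or divided (direction "down") by
``effect_size`` in pixels of feature-positive patients.  The returned
:class:`GroundTruth` records exactly which m/z were planted for which feature
and protein, so downstream recovery can be scored.

The matching LC-MS/MS reference list carries one peptide mass per planted m/z
with a small Gaussian mass jitter (emulating the sub-0.2 Da deviations between
MSI centroids and LC-MS/MS monoisotopic masses), plus uniquely named decoy
peptides placed farther than 0.2 Da from any planted m/z.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotate import ReferencePeptide
from .msio import AcquisitionMetadata, MSIDataset, Spectrum

__all__ = [
    "FEATURES",
    "DEFAULT_FEATURE_PREVALENCE",
    "CohortRecord",
    "SimConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_msi_dataset",
    "generate_reference_list",
    "write_cohort",
    "read_cohort",
    "write_ground_truth",
]

FEATURES = ("pL", "pN", "pV")

#: Published cohort marginals: pN+ 12/18, pL+ 8/18, pV+ 5/18.
DEFAULT_FEATURE_PREVALENCE = {"pN": 0.67, "pL": 0.44, "pV": 0.27}
#: Tumor-stage and grade marginals of the same 18-patient cohort.
DEFAULT_PT_PROPORTIONS = {1: 1 / 18, 2: 1 / 18, 3: 16 / 18, 4: 0.0}
DEFAULT_GRADE_PROPORTIONS = {1: 1 / 18, 2: 11 / 18, 3: 5 / 18, 4: 1 / 18}

DETECTOR_RANGE = (800.0, 3200.0)  # Da, reflector-mode tryptic peptide window


@dataclass
class CohortRecord:
    """One patient: prognostic flags, stage, grade and number of tissue cores."""

    patient_id: str
    pT: int
    pN: bool
    pL: bool
    pV: bool
    grade: int
    n_cores: int

    def __post_init__(self) -> None:
        if self.n_cores < 1:
            raise ValueError("n_cores must be >= 1")
        if self.pT not in (1, 2, 3, 4) or self.grade not in (1, 2, 3, 4):
            raise ValueError("pT and grade must be in 1..4")

    def feature(self, name: str) -> bool:
        return bool(getattr(self, name))


@dataclass
class SimConfig:
    """Synthetic-acquisition settings.

    Defaults mirror the emulated study: m/z 800-3200 detection range, 557
    peptide peaks, 16 x 16 pixel cores at 50 um raster.  ``peak_width`` is the
    Gaussian sigma of a peptide peak in Da; ``intensity_sigma`` the log-normal
    sigma of per-pixel amplitudes; ``ref_mass_jitter_sd`` the Gaussian
    deviation (Da) between reference peptide masses and planted centroids,
    kept small enough that |jitter| < 0.2 Da with high probability.
    """

    grid_shape: tuple[int, int] = (16, 16)  # (rows, cols) pixels per core
    n_peaks: int = 557
    mz_range: tuple[float, float] = DETECTOR_RANGE
    axis_step: float = 0.05  # Da between profile points
    peak_width: float = 0.1  # Gaussian sigma, Da
    intensity_sigma: float = 0.5  # log-normal sigma of amplitudes
    base_intensity_range: tuple[float, float] = (50.0, 500.0)
    noise_sd: float = 2.0
    baseline_amplitude: float = 30.0
    core_intercept_sd: float = 0.0  # per-core log-intensity random intercept
    effect_size: float = 2.0  # multiplicative shift on planted peaks
    planted_proteins: dict[str, int] = field(
        default_factory=lambda: {"pL": 8, "pN": 1, "pV": 2}
    )
    peptides_per_protein: int = 2
    effect_direction: dict[str, str] = field(
        default_factory=lambda: {"pL": "up", "pN": "down", "pV": "up"}
    )
    n_decoys: int = 20
    ref_mass_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mz_range
        if not (DETECTOR_RANGE[0] <= lo < hi <= DETECTOR_RANGE[1]):
            raise ValueError(f"mz_range must lie within the detector range {DETECTOR_RANGE}")
        if self.grid_shape[0] * self.grid_shape[1] <= 0:
            raise ValueError("grid_shape must contain at least one pixel")
        if 3 * self.ref_mass_jitter_sd >= 0.2:
            raise ValueError("ref_mass_jitter_sd too large for <0.2 Da matching")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")

    def to_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
        return path


@dataclass
class GroundTruth:
    """Which m/z were planted, for which feature/direction/protein."""

    planted_mzs: list[float]
    effect_feature: dict[float, str]
    effect_direction: dict[float, str]
    effect_size: float
    protein_map: dict[float, str]

    def proteins_for(self, feature: str) -> set[str]:
        return {
            self.protein_map[mz]
            for mz in self.planted_mzs
            if self.effect_feature[mz] == feature
        }

    def mzs_for(self, feature: str) -> list[float]:
        return [mz for mz in self.planted_mzs if self.effect_feature[mz] == feature]


def _largest_remainder(n: int, proportions: dict) -> dict:
    """Integer counts per category summing to n, by the largest-remainder rule."""
    keys = list(proportions)
    quotas = np.array([n * proportions[k] for k in keys], dtype=float)
    counts = np.floor(quotas).astype(int)
    leftover = n - counts.sum()
    remainders = quotas - counts
    # distribute leftover to the largest remainders; ties -> earlier category
    order = np.argsort(-remainders, kind="stable")
    for i in range(leftover):
        counts[order[i % len(keys)]] += 1
    return dict(zip(keys, counts.tolist()))


def generate_cohort(
    n_patients: int,
    proportions: dict[str, float] | None = None,
    seed: int = 0,
    cores_range: tuple[int, int] = (1, 7),
    joint: dict[tuple[bool, bool, bool], float] | None = None,
) -> list[CohortRecord]:
    """Generate a synthetic patient cohort with fixed feature prevalences.

    Per binary feature, exactly ``round(n * p)`` patients (largest-remainder
    rule) are positive; the assignment is then randomly permuted across
    patients, independently per feature.  Passing ``joint`` (a probability
    table over (pL, pN, pV) combinations) models feature correlations instead.
    Cores per patient are uniform over ``cores_range``.
    """
    if n_patients < 0:
        raise ValueError("n_patients must be >= 0")
    if n_patients == 0:
        return []
    props = dict(DEFAULT_FEATURE_PREVALENCE if proportions is None else proportions)
    for name, p in props.items():
        if not 0 <= p <= 1:
            raise ValueError(f"proportion for {name} must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)

    flags: dict[str, np.ndarray] = {}
    if joint is not None:
        combos = sorted(joint)
        counts = _largest_remainder(n_patients, {c: joint[c] for c in combos})
        assigned = np.concatenate(
            [np.repeat(np.arange(len(combos)), [counts[c] for c in combos])]
        )
        assigned = assigned[rng.permutation(n_patients)]
        for fi, name in enumerate(FEATURES):
            flags[name] = np.array([combos[a][fi] for a in assigned], dtype=bool)
    else:
        for name in FEATURES:
            p = props.get(name, 0.0)
            n_pos = _largest_remainder(n_patients, {True: p, False: 1 - p})[True]
            vec = np.zeros(n_patients, dtype=bool)
            vec[rng.permutation(n_patients)[:n_pos]] = True
            flags[name] = vec

    def categorical(proportions: dict) -> np.ndarray:
        counts = _largest_remainder(n_patients, proportions)
        values = np.concatenate(
            [np.full(counts[k], k, dtype=int) for k in proportions]
        )
        return values[rng.permutation(n_patients)]

    pts = categorical(DEFAULT_PT_PROPORTIONS)
    grades = categorical(DEFAULT_GRADE_PROPORTIONS)
    lo, hi = cores_range
    cores = rng.integers(lo, hi + 1, size=n_patients)
    return [
        CohortRecord(
            patient_id=f"P{i + 1:02d}",
            pT=int(pts[i]),
            pN=bool(flags["pN"][i]),
            pL=bool(flags["pL"][i]),
            pV=bool(flags["pV"][i]),
            grade=int(grades[i]),
            n_cores=int(cores[i]),
        )
        for i in range(n_patients)
    ]


def _peak_profiles(centroids: np.ndarray, axis: np.ndarray, sigma: float) -> sp.csr_matrix:
    """Sparse (n_peaks x n_axis) matrix of unit-height Gaussian peak profiles."""
    rows, cols, vals = [], [], []
    step = axis[1] - axis[0] if len(axis) > 1 else 1.0
    half = int(np.ceil(5 * sigma / step))
    for k, c in enumerate(centroids):
        j0 = int(np.searchsorted(axis, c))
        lo, hi = max(0, j0 - half), min(len(axis), j0 + half + 1)
        window = axis[lo:hi]
        prof = np.exp(-0.5 * ((window - c) / sigma) ** 2)
        rows.extend([k] * (hi - lo))
        cols.extend(range(lo, hi))
        vals.extend(prof.tolist())
    return sp.csr_matrix((vals, (rows, cols)), shape=(len(centroids), len(axis)))


def _baseline_curve(axis: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Deterministic slowly varying background: sinusoid + descending ramp."""
    lo, hi = cfg.mz_range
    t = (axis - lo) / max(hi - lo, 1e-9)
    period = max((hi - lo) / 1.5, 1e-9)
    return cfg.baseline_amplitude * (
        0.5 * (1 + np.sin(2 * np.pi * (axis - lo) / period)) * 0.5 + 0.5 * (1 - t)
    )


def generate_msi_dataset(
    cohort: list[CohortRecord], cfg: SimConfig
) -> tuple[MSIDataset, GroundTruth]:
    """Simulate one profile spectrum per pixel for every core of every patient.

    Cores are laid side by side along x (two-pixel gutters); coordinates are
    1-based.  Each core becomes one ROI named ``<patient>-core<i>`` labeled
    with the patient's prognostic flags.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.mz_range
    axis = np.arange(lo, hi + cfg.axis_step / 2, cfg.axis_step)

    # peak centroids on a 1-Da slot lattice (plus jitter): guarantees >= 0.5 Da
    # spacing, so 0.156 Da intervals never overlap and planted peaks stay
    # resolvable from their neighbours
    margin = 2.0
    slots = np.arange(lo + margin, hi - margin, 1.0)
    if cfg.n_peaks > len(slots):
        raise ValueError(f"n_peaks={cfg.n_peaks} exceeds available slots ({len(slots)})")
    chosen = rng.choice(len(slots), size=cfg.n_peaks, replace=False)
    centroids = np.sort(slots[chosen] + rng.uniform(-0.25, 0.25, cfg.n_peaks))
    base_log = np.log(rng.uniform(*cfg.base_intensity_range, size=cfg.n_peaks))

    # planted peaks, grouped into synthetic proteins per prognostic feature
    total_planted = sum(
        cfg.planted_proteins.get(f, 0) * cfg.peptides_per_protein for f in FEATURES
    )
    if total_planted > cfg.n_peaks:
        raise ValueError("more planted peptides than peaks")
    planted_idx = rng.choice(cfg.n_peaks, size=total_planted, replace=False)
    effect_feature: dict[float, str] = {}
    effect_direction: dict[float, str] = {}
    protein_map: dict[float, str] = {}
    planted_by_feature: dict[str, np.ndarray] = {}
    pos = 0
    for f in FEATURES:
        n_prot = cfg.planted_proteins.get(f, 0)
        idxs = planted_idx[pos : pos + n_prot * cfg.peptides_per_protein]
        pos += len(idxs)
        planted_by_feature[f] = idxs
        for i, idx in enumerate(idxs):
            mz = float(centroids[idx])
            effect_feature[mz] = f
            effect_direction[mz] = cfg.effect_direction.get(f, "up")
            protein_map[mz] = f"SYN-{f}-{i // cfg.peptides_per_protein + 1:02d}"
    log_shift = {
        f: (1 if cfg.effect_direction.get(f, "up") == "up" else -1)
        * np.log(cfg.effect_size)
        for f in FEATURES
    }

    profiles = _peak_profiles(centroids, axis, cfg.peak_width)
    baseline = _baseline_curve(axis, cfg)

    rows_px, cols_px = cfg.grid_shape
    n_px = rows_px * cols_px
    yy, xx = np.divmod(np.arange(n_px), cols_px)

    spectra: list[Spectrum] = []
    rois: dict[str, set[tuple[int, int]]] = {}
    labels: dict[str, dict[str, bool]] = {}
    x_offset = 1
    for rec in cohort:
        for core in range(1, rec.n_cores + 1):
            gamma = cfg.core_intercept_sd * rng.standard_normal()
            log_amp = (
                base_log[None, :]
                + cfg.intensity_sigma * rng.standard_normal((n_px, cfg.n_peaks))
                + gamma
            )
            for f in FEATURES:
                if rec.feature(f) and len(planted_by_feature[f]):
                    log_amp[:, planted_by_feature[f]] += log_shift[f]
            signal = (profiles.T @ np.exp(log_amp).T).T  # (n_px, n_axis)
            noise = cfg.noise_sd * rng.standard_normal(signal.shape)
            intens = np.clip(signal + baseline[None, :] + noise, 0.0, None)
            coords = [(int(x_offset + xx[p]), int(1 + yy[p])) for p in range(n_px)]
            for p in range(n_px):
                spectra.append(Spectrum(axis, intens[p], coords[p]))
            roi = f"{rec.patient_id}-core{core}"
            rois[roi] = set(coords)
            labels[roi] = {f: rec.feature(f) for f in FEATURES}
            x_offset += cols_px + 2

    meta = AcquisitionMetadata(mz_min=lo, mz_max=hi)
    ds = MSIDataset(
        spectra=spectra, pixel_size=50.0, rois=rois, labels=labels, acquisition=meta
    )
    truth = GroundTruth(
        planted_mzs=sorted(effect_feature),
        effect_feature=effect_feature,
        effect_direction=effect_direction,
        effect_size=cfg.effect_size,
        protein_map=protein_map,
    )
    return ds, truth


def generate_reference_list(
    truth: GroundTruth, cfg: SimConfig, n_decoys: int | None = None
) -> list[ReferencePeptide]:
    """LC-MS/MS reference list matching the planted peaks, plus decoys.

    One reference mass per planted m/z at ``planted + N(0, ref_mass_jitter_sd)``
    carrying the planted protein name; decoys get uniquely named proteins and
    masses farther than 0.2 Da from every planted m/z.  Uses a seed derived
    from ``cfg.seed`` so the list is reproducible independently of dataset
    generation order.
    """
    if not truth.planted_mzs:
        raise ValueError("ground truth has no planted m/z")
    rng = np.random.default_rng(cfg.seed + 1)
    refs = [
        ReferencePeptide(
            mass=float(mz + rng.normal(0.0, cfg.ref_mass_jitter_sd)),
            protein=truth.protein_map[mz],
        )
        for mz in truth.planted_mzs
    ]
    nd = cfg.n_decoys if n_decoys is None else n_decoys
    planted = np.array(truth.planted_mzs)
    lo, hi = cfg.mz_range
    made = 0
    while made < nd:
        mass = float(rng.uniform(lo, hi))
        if np.abs(planted - mass).min() > 0.2:
            made += 1
            refs.append(ReferencePeptide(mass=mass, protein=f"DECOY-{made:03d}"))
    return refs


# ---------------------------------------------------------------------------
# manifests


def write_cohort(cohort: list[CohortRecord], path: str) -> str:
    pd.DataFrame([asdict(r) for r in cohort]).to_csv(path, sep="\t", index=False)
    return path


def read_cohort(path: str) -> list[CohortRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        CohortRecord(
            patient_id=str(r["patient_id"]),
            pT=int(r["pT"]),
            pN=bool(r["pN"]),
            pL=bool(r["pL"]),
            pV=bool(r["pV"]),
            grade=int(r["grade"]),
            n_cores=int(r["n_cores"]),
        )
        for _, r in df.iterrows()
    ]


def write_ground_truth(truth: GroundTruth, path: str) -> str:
    df = pd.DataFrame(
        {
            "planted_mz": truth.planted_mzs,
            "feature": [truth.effect_feature[m] for m in truth.planted_mzs],
            "direction": [truth.effect_direction[m] for m in truth.planted_mzs],
            "effect_size": truth.effect_size,
            "protein": [truth.protein_map[m] for m in truth.planted_mzs],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return path


def scaled_config(**overrides) -> SimConfig:
    """A small-problem configuration for quick runs: one 12x12 core per
    patient over m/z 800-1000 with 40 peaks.  Noise, peak and effect settings
    keep their defaults; pass overrides for anything else."""
    base = SimConfig(
        grid_shape=(12, 12),
        n_peaks=40,
        mz_range=(800.0, 1000.0),
        planted_proteins={"pL": 2, "pN": 1, "pV": 1},
        n_decoys=10,
    )
    return replace(base, **overrides)
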