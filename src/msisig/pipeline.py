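"""End-to-end orchestration: simulate/load -> preprocess -> align -> screen -> annotate.

One peak-alignment pass produces the shared datacube on which the three
prognostic-feature screens (pL, pN, pV) run; their discriminative m/z sets are
annotated against the LC-MS/MS reference list, proteins inferred under the
two-peptide concordance rule, and the per-feature signatures partitioned into
the seven Venn regions (uniques, pairwise and three-way overlaps).

Every stage logs its in/out counts; a failing stage aborts with the stage
name attached.  Reports written to disk carry a manifest (settings, seed,
package version) and use fixed numeric formatting, so a rerun with the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .annotate import ProteinAssignment, ReferencePeptide, infer_proteins, match_to_reference
from .discrim import DiscriminativeFeature, ScreenConfig, screen_feature
from .msio import (
    MSIDataset,
    read_imzml,
    read_labels,
    read_reference_list,
    read_roi_masks,
    write_results_table,
)
from .multivariate import PCAResult, bisect_kmeans, level_scale, run_pca, SegmentationResult
from .peakalign import Datacube, PeakList, align_to_intervals, pick_peaks_omp
from .preprocess import remove_baseline, tic_normalize
from .synthio import FEATURES, GroundTruth, SimConfig, generate_cohort, generate_msi_dataset, generate_reference_list

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PipelineReport",
    "SignaturePartition",
    "run_pipeline",
    "partition_signatures",
]

log = logging.getLogger(__name__)

#: Per-feature offsets added to the screening seed, so each feature's
#: balancing subsample is independent of which other features are screened.
_FEATURE_SEED_OFFSET = {"pL": 0, "pN": 1, "pV": 2}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for context."""


@dataclass
class PipelineConfig:
    """All pipeline settings in one place; the seed is recorded in every output."""

    sim: SimConfig | None = None  # synthetic mode
    n_patients: int = 18
    proportions: dict[str, float] | None = None
    cores_range: tuple[int, int] = (1, 7)
    # real-data mode: paths to an imzML pair + sidecars
    imzml_path: str | None = None
    roi_path: str | None = None
    labels_path: str | None = None
    reference_path: str | None = None
    # stages
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    baseline_width: int = 20
    max_peaks: int = 600
    min_rel_height: float = 0.02
    peak_sigma: float = 0.1
    half_width: float = 0.156
    interval_mode: str = "mean"
    pca_half_width: float = 0.3
    pca_interval_mode: str = "max"
    n_components: int = 5
    run_multivariate: bool = False
    segmentation_k: int = 0
    tolerance: float = 0.2
    min_peptides: int = 2
    require_concordance: bool = True
    features: tuple[str, ...] = FEATURES
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("half_width", self.half_width),
            ("pca_half_width", self.pca_half_width),
            ("tolerance", self.tolerance),
            ("min_peptides", self.min_peptides),
            ("baseline_width", self.baseline_width),
        ):
            if not value > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SignaturePartition:
    """The seven Venn regions of the three per-feature discriminative m/z sets."""

    regions: dict[str, set[float]]

    REGION_NAMES = (
        "pL_only",
        "pN_only",
        "pV_only",
        "pL_pN",
        "pL_pV",
        "pN_pV",
        "pL_pN_pV",
    )

    @property
    def counts(self) -> dict[str, int]:
        return {name: len(self.regions.get(name, set())) for name in self.REGION_NAMES}

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def partition_signatures(per_feature: dict[str, set[float]]) -> SignaturePartition:
    """Partition three discriminative m/z sets into their 7 disjoint Venn regions."""
    sl = set(per_feature.get("pL", set()))
    sn = set(per_feature.get("pN", set()))
    sv = set(per_feature.get("pV", set()))
    regions = {
        "pL_only": sl - sn - sv,
        "pN_only": sn - sl - sv,
        "pV_only": sv - sl - sn,
        "pL_pN": (sl & sn) - sv,
        "pL_pV": (sl & sv) - sn,
        "pN_pV": (sn & sv) - sl,
        "pL_pN_pV": sl & sn & sv,
    }
    return SignaturePartition(regions=regions)


@dataclass
class PipelineReport:
    """Everything one run produces, for inspection or export."""

    config: PipelineConfig
    peaks: PeakList
    cube: Datacube
    screens: dict[str, list[DiscriminativeFeature]]
    screen_tables: dict[str, "object"]
    matches: dict[str, list]
    assignments: dict[str, list[ProteinAssignment]]
    partition: SignaturePartition
    truth: GroundTruth | None = None
    reference: list[ReferencePeptide] | None = None
    pca: dict[str, PCAResult] | None = None
    segmentation: SegmentationResult | None = None
    manifest: dict | None = None


def _feature_masks(ds: MSIDataset, cube: Datacube, feature: str) -> tuple[np.ndarray, np.ndarray]:
    """(positive, labeled) boolean masks over cube rows for one prognostic feature."""
    rois = cube.pixel_index["roi"].to_numpy()
    labeled = np.zeros(len(rois), dtype=bool)
    positive = np.zeros(len(rois), dtype=bool)
    for i, roi in enumerate(rois):
        status = ds.labels.get(roi, {}).get(feature)
        if status is not None:
            labeled[i] = True
            positive[i] = bool(status)
    return positive, labeled


def run_pipeline(cfg: PipelineConfig, outdir: str | None = None) -> PipelineReport:
    """Execute the full pipeline and return (optionally also write) the report."""

    def stage(name):
        class _Stage:
            def __enter__(self):
                log.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage {name}: {exc}") from exc
                return False

        return _Stage()

    truth: GroundTruth | None = None
    reference: list[ReferencePeptide] | None = None

    with stage("input"):
        if cfg.sim is not None:
            cohort = generate_cohort(
                cfg.n_patients,
                proportions=cfg.proportions,
                seed=cfg.sim.seed,
                cores_range=cfg.cores_range,
            )
            ds, truth = generate_msi_dataset(cohort, cfg.sim)
            reference = (
                generate_reference_list(truth, cfg.sim) if truth.planted_mzs else []
            )
        elif cfg.imzml_path is not None:
            ds = read_imzml(cfg.imzml_path)
            if cfg.roi_path:
                ds.rois = read_roi_masks(cfg.roi_path)
            if cfg.labels_path:
                ds.labels = read_labels(cfg.labels_path)
            ds.__post_init__()  # re-validate ROI/coord consistency
            if cfg.reference_path:
                reference = read_reference_list(cfg.reference_path)
        else:
            raise ValueError("config must supply either sim or imzml_path")
        log.info("input: %d spectra, %d ROIs", len(ds.spectra), len(ds.rois))

    with stage("preprocess"):
        processed = [
            tic_normalize(remove_baseline(s, cfg.baseline_width)) for s in ds.spectra
        ]
        ds = MSIDataset(
            spectra=processed,
            pixel_size=ds.pixel_size,
            rois=ds.rois,
            labels=ds.labels,
            acquisition=ds.acquisition,
        )

    with stage("peak_selection"):
        mean = ds.mean_spectrum()
        peaks = pick_peaks_omp(
            mean, max_peaks=cfg.max_peaks, min_rel_height=cfg.min_rel_height,
            sigma=cfg.peak_sigma,
        )
        log.info("peak_selection: %d centroids", len(peaks))
        if len(peaks) == 0:
            raise ValueError("no peaks selected from mean spectrum")

    with stage("alignment"):
        cube = align_to_intervals(ds, peaks, cfg.half_width, cfg.interval_mode)
        log.info("alignment: %d pixels x %d aligned m/z", cube.n_pixels, cube.n_features)

    pca_results: dict[str, PCAResult] | None = None
    segmentation = None
    if cfg.run_multivariate:
        with stage("multivariate"):
            pca_cube = align_to_intervals(
                ds, peaks, cfg.pca_half_width, cfg.pca_interval_mode, allow_overlap=True
            )
            keep = pca_cube.matrix.mean(axis=0) > 0
            pca_cube = Datacube(
                matrix=pca_cube.matrix[:, keep],
                feature_mzs=pca_cube.feature_mzs[keep],
                pixel_index=pca_cube.pixel_index,
                interval_half_width=pca_cube.interval_half_width,
                interval_mode=pca_cube.interval_mode,
            )
            scaled = level_scale(pca_cube)
            pca_results = {}
            for f in cfg.features:
                positive, labeled = _feature_masks(ds, scaled, f)
                groups = np.where(labeled, np.where(positive, f + "+", f + "-"), None)
                pca_results[f] = run_pca(scaled, cfg.n_components, group_labels=groups)
            if cfg.segmentation_k >= 2:
                segmentation = bisect_kmeans(
                    cube, cfg.segmentation_k, spatial_smoothing="medium", seed=cfg.seed
                )

    screens: dict[str, list[DiscriminativeFeature]] = {}
    tables: dict[str, object] = {}
    with stage("screen"):
        for f in cfg.features:
            positive, labeled = _feature_masks(ds, cube, f)
            fcfg = dataclasses.replace(
                cfg.screen, seed=cfg.screen.seed + _FEATURE_SEED_OFFSET.get(f, 0)
            )
            selected, table = screen_feature(cube, positive, labeled, fcfg, feature=f)
            screens[f] = selected
            tables[f] = table
            log.info(
                "screen %s: %d of %d m/z discriminative", f, len(selected), cube.n_features
            )

    matches: dict[str, list] = {}
    assignments: dict[str, list[ProteinAssignment]] = {}
    with stage("annotate"):
        for f in cfg.features:
            if reference is None:
                matches[f], assignments[f] = [], []
                continue
            m = match_to_reference(screens[f], reference, tolerance=cfg.tolerance)
            matches[f] = m
            assignments[f] = infer_proteins(
                m, min_peptides=cfg.min_peptides,
                require_concordance=cfg.require_concordance,
            )
            log.info(
                "annotate %s: %d matches -> %d proteins", f, len(m), len(assignments[f])
            )

    partition = partition_signatures({f: {d.mz for d in screens[f]} for f in cfg.features})

    manifest = {
        "package": "msisig",
        "version": __version__,
        "seed": cfg.seed,
        "screen_seed": cfg.screen.seed,
        "sim": dataclasses.asdict(cfg.sim) if cfg.sim else None,
        "settings": {
            "baseline_width": cfg.baseline_width,
            "half_width": cfg.half_width,
            "interval_mode": cfg.interval_mode,
            "tolerance": cfg.tolerance,
            "min_peptides": cfg.min_peptides,
            "auc_gates": [cfg.screen.auc_low, cfg.screen.auc_high],
            "alpha": cfg.screen.alpha,
            "max_spectra_per_group": cfg.screen.max_spectra_per_group,
        },
        "counts": {
            "spectra": cube.n_pixels,
            "aligned_mz": cube.n_features,
            "discriminative": {f: len(screens[f]) for f in cfg.features},
            "proteins": {f: len(assignments[f]) for f in cfg.features},
        },
    }

    report = PipelineReport(
        config=cfg,
        peaks=peaks,
        cube=cube,
        screens=screens,
        screen_tables=tables,
        matches=matches,
        assignments=assignments,
        partition=partition,
        truth=truth,
        reference=reference,
        pca=pca_results,
        segmentation=segmentation,
        manifest=manifest,
    )
    if outdir is not None:
        _write_report(report, outdir)
    return report


def _write_report(report: PipelineReport, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    report.peaks.to_tsv(os.path.join(outdir, "peaks.tsv"))
    for f, table in report.screen_tables.items():
        table.to_csv(
            os.path.join(outdir, f"screen_{f}.tsv"), sep="\t", index=False,
            float_format="%.6g",
        )
    all_assignments = [a for f in report.config.features for a in report.assignments[f]]
    write_results_table(all_assignments, os.path.join(outdir, "protein_assignments.tsv"))
    with open(os.path.join(outdir, "partition.json"), "w") as fh:
        json.dump(
            {
                "counts": report.partition.counts,
                "regions": {
                    k: sorted(v) for k, v in report.partition.regions.items()
                },
                "total": report.partition.total,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(report.manifest, fh, indent=1, sort_keys=True, default=str)
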