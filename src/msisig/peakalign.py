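"""Dataset-wide peak selection (orthogonal matching pursuit) and interval binning.

Peak centroids are selected on the dataset mean spectrum by greedy orthogonal
matching pursuit over a dictionary of Gaussian peak atoms centered on the
m/z-axis points: at each step the atom most correlated with the residual is
selected, the amplitudes of *all* selected atoms are refit jointly by least
squares (the orthogonal step), and the refit model is subtracted.  Selection
stops at ``max_peaks`` or when the best remaining atom's estimated height
falls below ``min_rel_height`` times the global maximum.  Because each step
projects onto a growing subspace, the residual norm is non-increasing.

Every spectrum is then binned into aligned intervals ``[c - h, c + h]`` around
the selected centroids (default half-width 0.156 Da, mean interval mode),
yielding the pixels x features :class:`Datacube` that all downstream
statistics operate on.  Interval boundaries are closed on both sides; with
overlap explicitly allowed, a datapoint exactly on a boundary shared by two
intervals is counted in the lower one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msio import MSIDataset, Spectrum

__all__ = ["PeakList", "Datacube", "pick_peaks_omp", "align_to_intervals"]

DEFAULT_HALF_WIDTH = 0.156  # Da


@dataclass
class PeakList:
    """Selected peak centroids plus the OMP selection provenance.

    ``provenance`` has one row per selection step: selection order, centroid,
    fitted height at selection, and residual norm after the orthogonal refit.
    """

    centroids: np.ndarray
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["order", "centroid", "height", "residual_norm"]
        )
    )

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if len(self.centroids) > 1 and not np.all(np.diff(self.centroids) > 0):
            raise ValueError("centroids must be strictly increasing")

    def __len__(self) -> int:
        return len(self.centroids)

    def to_tsv(self, path: str) -> str:
        df = pd.DataFrame({"centroid_mz": self.centroids})
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")
        return path


@dataclass
class Datacube:
    """Pixels x aligned-features matrix of non-negative interval intensities."""

    matrix: np.ndarray  # (n_pixels, n_features)
    feature_mzs: np.ndarray
    pixel_index: pd.DataFrame  # columns: x, y, roi
    interval_half_width: float = DEFAULT_HALF_WIDTH
    interval_mode: str = "mean"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.feature_mzs = np.asarray(self.feature_mzs, dtype=np.float64)
        if self.matrix.shape[1] != len(self.feature_mzs):
            raise ValueError("matrix column count must equal number of feature m/z values")
        if self.matrix.shape[0] != len(self.pixel_index):
            raise ValueError("matrix row count must equal pixel index length")

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def replace(self, matrix: np.ndarray) -> "Datacube":
        return Datacube(
            matrix=matrix,
            feature_mzs=self.feature_mzs.copy(),
            pixel_index=self.pixel_index.copy(),
            interval_half_width=self.interval_half_width,
            interval_mode=self.interval_mode,
        )

    def to_tsv(self, path: str) -> str:
        df = pd.DataFrame(self.matrix, columns=[f"{m:.4f}" for m in self.feature_mzs])
        pd.concat([self.pixel_index.reset_index(drop=True), df], axis=1).to_csv(
            path, sep="\t", index=False
        )
        return path


def _gaussian_kernel(sigma_points: float) -> np.ndarray:
    half = max(1, int(np.ceil(5 * sigma_points)))
    x = np.arange(-half, half + 1, dtype=np.float64)
    return np.exp(-0.5 * (x / sigma_points) ** 2)


def pick_peaks_omp(
    mean_spectrum: Spectrum,
    max_peaks: int = 600,
    min_rel_height: float = 0.01,
    sigma: float = 0.1,
    min_separation: float | None = None,
) -> PeakList:
    """Select peak centroids from a dense mean spectrum by OMP.

    Parameters
    ----------
    sigma
        Width (Da) of the Gaussian atoms; should match the instrument peak
        width of the profile spectra.
    min_separation
        Minimum centroid spacing (Da); defaults to twice the default interval
        half-width so that downstream binning intervals do not overlap.
    """
    y = mean_spectrum.intensity
    axis = mean_spectrum.mz
    if len(y) == 0:
        raise ValueError("empty mean spectrum")
    global_max = float(y.max())
    if global_max <= 0:
        return PeakList(np.empty(0))
    if min_separation is None:
        min_separation = 2 * DEFAULT_HALF_WIDTH + 1e-9

    step = float(np.median(np.diff(axis)))
    kernel = _gaussian_kernel(sigma / step)
    atom_norm = float(np.sqrt((kernel**2).sum()))
    unit_kernel = kernel / atom_norm  # correlate -> <residual, atom_i>
    atom_peak = kernel.max() / atom_norm  # apex value of a unit-norm atom

    residual = y.astype(np.float64).copy()
    selected: list[int] = []
    excluded = np.zeros(len(y), dtype=bool)
    columns: list[np.ndarray] = []
    records = []

    n = len(y)
    half = (len(kernel) - 1) // 2
    for order in range(max_peaks):
        corr = np.convolve(residual, unit_kernel, mode="same")
        corr[excluded] = -np.inf
        j = int(np.argmax(corr))
        est_height = corr[j] * atom_peak
        if not np.isfinite(est_height) or est_height < min_rel_height * global_max:
            break
        # build the (truncated-at-edges) unit-norm atom column for axis point j
        col = np.zeros(n)
        lo, hi = max(0, j - half), min(n, j + half + 1)
        col[lo:hi] = kernel[half - (j - lo) : half + (hi - j)] / atom_norm
        columns.append(col)
        selected.append(j)
        excluded |= np.abs(axis - axis[j]) < min_separation
        A = np.column_stack(columns)
        amps, *_ = np.linalg.lstsq(A, y, rcond=None)
        residual = y - A @ amps
        records.append(
            {
                "order": order,
                "centroid": float(axis[j]),
                "height": float(est_height),
                "residual_norm": float(np.linalg.norm(residual)),
            }
        )

    prov = pd.DataFrame(records, columns=["order", "centroid", "height", "residual_norm"])
    centroids = np.sort(axis[selected]) if selected else np.empty(0)
    return PeakList(centroids=centroids, provenance=prov)


def align_to_intervals(
    ds: MSIDataset,
    peaks: PeakList,
    half_width: float = DEFAULT_HALF_WIDTH,
    mode: str = "mean",
    allow_overlap: bool = False,
) -> Datacube:
    """Bin every spectrum into aligned intervals around the peak centroids.

    The feature value of pixel ``p`` at centroid ``c`` is the mean (or max,
    per ``mode``) of ``p``'s intensities with m/z in ``[c - h, c + h]``; an
    empty interval contributes 0.  Centroids closer than ``2 * half_width``
    raise unless ``allow_overlap`` is set.
    """
    if mode not in ("mean", "max"):
        raise ValueError(f"unknown interval mode {mode!r}")
    centroids = peaks.centroids
    if len(centroids) > 1:
        gaps = np.diff(centroids)
        if not allow_overlap and np.any(gaps < 2 * half_width):
            worst = int(np.argmin(gaps))
            raise ValueError(
                f"centroids {centroids[worst]:.4f} and {centroids[worst + 1]:.4f} are "
                f"closer than 2*half_width={2 * half_width:.4f}; pass allow_overlap=True"
            )
    lows = centroids - half_width
    highs = centroids + half_width
    # boundary exactly shared by two overlapping intervals -> lower centroid
    left_open = np.zeros(len(centroids), dtype=bool)
    if len(centroids) > 1:
        left_open[1:] = highs[:-1] == lows[1:]

    n_px, n_feat = len(ds.spectra), len(centroids)
    matrix = np.zeros((n_px, n_feat))
    for i, s in enumerate(ds.spectra):
        lo_idx = np.searchsorted(s.mz, lows, side="left")
        lo_open = np.searchsorted(s.mz, lows, side="right")
        lo_idx = np.where(left_open, lo_open, lo_idx)
        hi_idx = np.searchsorted(s.mz, highs, side="right")
        if mode == "mean":
            cs = np.concatenate([[0.0], np.cumsum(s.intensity)])
            counts = hi_idx - lo_idx
            sums = cs[hi_idx] - cs[lo_idx]
            with np.errstate(invalid="ignore"):
                vals = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
            matrix[i] = vals
        else:
            for j in range(n_feat):
                if hi_idx[j] > lo_idx[j]:
                    matrix[i, j] = s.intensity[lo_idx[j] : hi_idx[j]].max()

    roi_map = ds.roi_of()
    pixel_index = pd.DataFrame(
        {
            "x": [s.coord[0] for s in ds.spectra],
            "y": [s.coord[1] for s in ds.spectra],
            "roi": [roi_map.get(s.coord, "") for s in ds.spectra],
        }
    )
    return Datacube(
        matrix=matrix,
        feature_mzs=centroids.copy(),
        pixel_index=pixel_index,
        interval_half_width=half_width,
        interval_mode=mode,
    )
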