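"""Per-spectrum preprocessing: baseline removal and TIC normalization.

Applied to profile-mode spectra before peak picking and alignment.  The
baseline estimator is the standard minimum-filter + Gaussian-convolution
construction: a running minimum of half-width ``width`` data points tracks the
slowly varying background underneath the peaks, and convolving it with a
Gaussian kernel (sigma = width/2 points) smooths the staircase the minimum
filter leaves.  Both filters use reflect padding; the corrected intensity is
clipped at zero, so non-negativity is preserved.

Total-ion-count normalization divides a spectrum by its summed intensity,
making pixels comparable regardless of ablation efficiency.  The target is
unit sum; downstream ROC/rank statistics are invariant to the common scale
choice anyway.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d, minimum_filter1d

from .msio import Spectrum

__all__ = ["remove_baseline", "tic_normalize", "estimate_baseline"]


def estimate_baseline(intensity: np.ndarray, width: int = 20) -> np.ndarray:
    """Minimum-filter (half-width ``width`` points) + Gaussian (sigma=width/2) baseline."""
    if width < 1:
        raise ValueError("width must be >= 1")
    floor = minimum_filter1d(intensity, size=2 * width + 1, mode="reflect")
    return gaussian_filter1d(floor, sigma=width / 2.0, mode="reflect")


def remove_baseline(s: Spectrum, width: int = 20) -> Spectrum:
    """Subtract the estimated baseline, clipping at zero; m/z axis unchanged."""
    if len(s) == 0:
        raise ValueError(f"pixel {s.coord}: empty spectrum")
    corrected = np.maximum(s.intensity - estimate_baseline(s.intensity, width), 0.0)
    return Spectrum(s.mz, corrected, s.coord)


def tic_normalize(s: Spectrum) -> Spectrum:
    """Divide intensities by their sum so the spectrum sums to one."""
    if len(s) == 0:
        raise ValueError(f"pixel {s.coord}: empty spectrum")
    total = float(s.intensity.sum())
    if not total > 0:
        raise ValueError(f"pixel {s.coord}: zero total ion count, cannot normalize")
    return Spectrum(s.mz, s.intensity / total, s.coord)
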