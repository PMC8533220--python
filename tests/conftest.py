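import numpy as np
import pytest

from msisig.msio import MSIDataset, Spectrum
from msisig.pipeline import PipelineConfig
from msisig.synthio import scaled_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectrum(axis, intensity, coord=(1, 1)):
    return Spectrum(np.asarray(axis, float), np.asarray(intensity, float), coord)


@pytest.fixture
def gaussian_peaks_spectrum():
    """Dense profile spectrum: three Gaussian peaks on a linear ramp baseline."""
    axis = np.arange(800.0, 820.0, 0.01)
    centers = [803.0, 809.5, 816.0]
    heights = [100.0, 60.0, 140.0]
    sigma = 0.05
    y = np.zeros_like(axis)
    for c, h in zip(centers, heights):
        y += h * np.exp(-0.5 * ((axis - c) / sigma) ** 2)
    ramp = 5.0 + 0.5 * (axis - axis[0])  # baseline
    return make_spectrum(axis, y + ramp), centers, heights, ramp


@pytest.fixture
def tiny_dataset():
    """2x2-pixel dataset with pixel-specific axes (processed mode)."""
    spectra = [
        make_spectrum([800.0, 900.0, 1000.0], [1.0, 2.0, 3.0], (1, 1)),
        make_spectrum([810.0, 910.0], [4.0, 5.0], (2, 1)),
        make_spectrum([805.5, 905.5, 1005.5, 1100.0], [0.5, 1.5, 2.5, 3.5], (1, 2)),
        make_spectrum([820.0], [7.0], (2, 2)),
    ]
    return MSIDataset(spectra=spectra)


def null_pipeline_config(seed: int) -> PipelineConfig:
    """Balanced 8-patient null run: no planted effects, 576 pixels per group."""
    sim = scaled_config(seed=seed, effect_size=1.0, planted_proteins={})
    return PipelineConfig(
        sim=sim,
        n_patients=8,
        proportions={"pL": 0.5, "pN": 0.5, "pV": 0.5},
        cores_range=(1, 1),
        seed=seed,
    )


def recovery_pipeline_config(seed: int) -> PipelineConfig:
    """Planted-signal run: 3 pL proteins x 2 peptides at effect size 2.5."""
    sim = scaled_config(
        seed=seed,
        effect_size=2.5,
        planted_proteins={"pL": 3, "pN": 0, "pV": 0},
        grid_shape=(10, 10),
        ref_mass_jitter_sd=0.05,
    )
    return PipelineConfig(
        sim=sim,
        n_patients=8,
        proportions={"pL": 0.5, "pN": 0.5, "pV": 0.5},
        cores_range=(1, 1),
        seed=seed,
        features=("pL",),
    )
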