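import numpy as np
import pytest

from msisig.discrim import ScreenConfig, auc_per_feature
from msisig.peakalign import PeakList, align_to_intervals
from msisig.synthio import (
    DEFAULT_FEATURE_PREVALENCE,
    SimConfig,
    generate_cohort,
    generate_msi_dataset,
    generate_reference_list,
    read_cohort,
    scaled_config,
    write_cohort,
)


class TestGenerateCohort:
    def test_published_cohort_margins(self):
        cohort = generate_cohort(18, DEFAULT_FEATURE_PREVALENCE, seed=0)
        assert sum(r.pN for r in cohort) == 12
        assert sum(r.pL for r in cohort) == 8
        assert sum(r.pV for r in cohort) == 5

    def test_empty_cohort(self):
        assert generate_cohort(0) == []

    def test_negative_n_errors(self):
        with pytest.raises(ValueError):
            generate_cohort(-1)

    def test_largest_remainder_exact_at_half(self):
        cohort = generate_cohort(10000, {"pL": 0.5, "pN": 0.5, "pV": 0.5}, seed=99)
        assert sum(r.pL for r in cohort) == 5000

    def test_deterministic_given_seed(self):
        a = generate_cohort(18, seed=7)
        b = generate_cohort(18, seed=7)
        assert a == b

    def test_cores_within_range(self):
        cohort = generate_cohort(50, seed=3, cores_range=(1, 7))
        assert all(1 <= r.n_cores <= 7 for r in cohort)
        assert {r.n_cores for r in cohort} > {1}

    def test_joint_probability_table(self):
        joint = {
            (True, True, False): 0.5,
            (False, False, False): 0.5,
        }
        joint.update({c: 0.0 for c in
                      [(a, b, v) for a in (True, False) for b in (True, False)
                       for v in (True, False)] if c not in joint})
        cohort = generate_cohort(10, seed=1, joint=joint)
        assert sum(r.pL and r.pN for r in cohort) == 5
        assert not any(r.pV for r in cohort)

    def test_tsv_round_trip(self, tmp_path):
        cohort = generate_cohort(6, seed=2)
        path = write_cohort(cohort, str(tmp_path / "cohort.tsv"))
        assert read_cohort(path) == cohort


class TestGenerateDataset:
    def test_deterministic_given_seed(self):
        cfg = scaled_config(seed=4, grid_shape=(4, 4))
        cohort = generate_cohort(2, seed=4, cores_range=(1, 2))
        ds_a, truth_a = generate_msi_dataset(cohort, cfg)
        ds_b, truth_b = generate_msi_dataset(cohort, cfg)
        assert truth_a == truth_b
        for sa, sb in zip(ds_a.spectra, ds_b.spectra):
            np.testing.assert_array_equal(sa.intensity, sb.intensity)

    def test_null_effect_gives_identical_group_means(self):
        # with the stochastic terms off, every pixel is deterministic, so
        # feature-positive and -negative mean spectra coincide exactly
        cfg = scaled_config(
            seed=5, grid_shape=(3, 3), effect_size=1.0,
            noise_sd=0.0, intensity_sigma=0.0,
        )
        cohort = generate_cohort(4, {"pL": 0.5, "pN": 0.5, "pV": 0.5},
                                 seed=5, cores_range=(1, 1))
        ds, _ = generate_msi_dataset(cohort, cfg)
        roi_map = ds.roi_of()
        pos = [s for s in ds.spectra if ds.labels[roi_map[s.coord]]["pL"]]
        neg = [s for s in ds.spectra if not ds.labels[roi_map[s.coord]]["pL"]]
        mean_pos = np.mean([s.intensity for s in pos], axis=0)
        mean_neg = np.mean([s.intensity for s in neg], axis=0)
        np.testing.assert_array_equal(mean_pos, mean_neg)

    def test_planted_effect_auc_above_gate(self):
        """A 2x multiplicative shift on a planted m/z yields an empirical
        per-pixel AUC in (0.6, 1.0] for the planted feature."""
        cfg = scaled_config(seed=6, effect_size=2.0,
                            planted_proteins={"pL": 1, "pN": 0, "pV": 0})
        cohort = generate_cohort(6, {"pL": 0.5, "pN": 0.5, "pV": 0.5},
                                 seed=6, cores_range=(1, 1))
        ds, truth = generate_msi_dataset(cohort, cfg)
        cube = align_to_intervals(ds, PeakList(np.array(truth.mzs_for("pL"))))
        roi_map = ds.roi_of()
        labels = [ds.labels[roi_map[s.coord]]["pL"] for s in ds.spectra]
        for _, auc in auc_per_feature(cube, labels):
            assert 0.6 < auc <= 1.0

    def test_planted_mzs_are_centroid_subset_with_proteins(self):
        cfg = scaled_config(seed=7)
        cohort = generate_cohort(2, seed=7, cores_range=(1, 1))
        _, truth = generate_msi_dataset(cohort, cfg)
        assert len(truth.planted_mzs) == (2 + 1 + 1) * 2
        for mz in truth.planted_mzs:
            assert truth.protein_map[mz].startswith("SYN-")
        for feature, n_prot in (("pL", 2), ("pN", 1), ("pV", 1)):
            assert len(truth.proteins_for(feature)) == n_prot

    def test_all_intensities_non_negative(self):
        cfg = scaled_config(seed=8, grid_shape=(4, 4), noise_sd=50.0)
        cohort = generate_cohort(1, seed=8, cores_range=(1, 1))
        ds, _ = generate_msi_dataset(cohort, cfg)
        assert all(s.intensity.min() >= 0 for s in ds.spectra)

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            generate_msi_dataset([], scaled_config())

    def test_zero_pixel_grid_errors(self):
        with pytest.raises(ValueError, match="pixel"):
            scaled_config(grid_shape=(0, 5))


class TestGenerateReferenceList:
    def _truth(self, seed=9, jitter=0.05):
        cfg = scaled_config(seed=seed, ref_mass_jitter_sd=jitter,
                            planted_proteins={"pL": 3, "pN": 1, "pV": 1})
        cohort = generate_cohort(2, seed=seed, cores_range=(1, 1))
        _, truth = generate_msi_dataset(cohort, cfg)
        return truth, cfg

    def test_zero_jitter_identity(self):
        truth, cfg = self._truth(jitter=0.0)
        refs = generate_reference_list(truth, cfg, n_decoys=0)
        assert [r.mass for r in refs] == truth.planted_mzs

    def test_jitter_tail_below_tolerance(self):
        """With sigma = 0.05 Da, at least 99% of reference deviations fall
        below the 0.2 Da matching tolerance (4-sigma tail)."""
        cfg = SimConfig(
            grid_shape=(2, 2), n_peaks=500, ref_mass_jitter_sd=0.05,
            planted_proteins={"pL": 250}, peptides_per_protein=2, seed=10,
        )
        cohort = generate_cohort(1, seed=10, cores_range=(1, 1))
        # dataset generation is not needed to test the jitter distribution,
        # but ground truth comes from it
        _, truth = generate_msi_dataset(cohort, cfg)
        refs = generate_reference_list(truth, cfg, n_decoys=0)
        deltas = np.array([r.mass for r in refs]) - np.array(truth.planted_mzs)
        assert np.mean(np.abs(deltas) < 0.2) >= 0.99

    def test_decoy_count_and_placement(self):
        truth, cfg = self._truth()
        refs = generate_reference_list(truth, cfg, n_decoys=15)
        decoys = [r for r in refs if r.protein.startswith("DECOY")]
        assert len(decoys) == 15
        assert len(refs) == len(truth.planted_mzs) + 15
        planted = np.array(truth.planted_mzs)
        for d in decoys:
            assert np.abs(planted - d.mass).min() > 0.2

    def test_no_decoys_conserves_count(self):
        truth, cfg = self._truth()
        refs = generate_reference_list(truth, cfg, n_decoys=0)
        assert len(refs) == len(truth.planted_mzs)
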