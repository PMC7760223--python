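"""Spectral binning, PCA, discriminant LOOCV and ion-yield comparison."""

import dataclasses

import numpy as np
import pytest

from alidose.simulate import SimulationConfig, simulate_tofsims_spectra
from alidose.tofsims import (
    BinnedSpectrum,
    SpectrumBinner,
    Spectrum,
    compare_ion_yields,
    fisher_lda_loocv,
    pca_scores,
    preprocess_spectrum,
    spectra_to_matrix,
)


def spectrum(pairs, group="g", rid="r"):
    mz = np.array([p[0] for p in pairs], float)
    it = np.array([p[1] for p in pairs], float)
    return Spectrum(mz=mz, intensity=it, group=group, replicate_id=rid)


class TestPreprocess:
    def test_single_peak_owns_the_whole_sum(self):
        b = preprocess_spectrum(spectrum([(500.0, 7.0)]))
        assert list(b.masses) == [500]
        assert b.intensities[0] == pytest.approx(100.0)

    def test_low_mass_contamination_region_excluded(self):
        # the metal-oxide ion at m/z 156.12 lies below the 200 u floor
        b = preprocess_spectrum(spectrum([(156.12, 50.0), (500.0, 5.0)]))
        assert list(b.masses) == [500]
        assert b.intensities.sum() == pytest.approx(100.0)

    def test_two_equal_peaks_split_evenly(self):
        b = preprocess_spectrum(spectrum([(400.0, 3.0), (600.0, 3.0)]))
        np.testing.assert_allclose(b.intensities, [50.0, 50.0])

    def test_channels_merge_into_unit_mass_bins_with_half_up_ties(self):
        b = preprocess_spectrum(spectrum([(499.6, 1.0), (500.2, 1.0), (500.5, 2.0)]))
        # 499.6 and 500.2 round to 500; the .5 tie rounds up to 501
        assert list(b.masses) == [500, 501]
        np.testing.assert_allclose(b.intensities, [50.0, 50.0])

    def test_idempotent_on_binned_normalized_input(self):
        b = preprocess_spectrum(spectrum([(400.3, 2.0), (617.8, 6.0)]))
        again = preprocess_spectrum(
            Spectrum(mz=b.masses.astype(float), intensity=b.intensities, group="g")
        )
        np.testing.assert_allclose(again.intensities, b.intensities)
        np.testing.assert_array_equal(again.masses, b.masses)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            preprocess_spectrum(spectrum([(50.0, 1.0)]))

    def test_normalization_sums_to_100_on_generated_spectra(self):
        spectra = simulate_tofsims_spectra(SimulationConfig(seed=3))
        for b in SpectrumBinner().transform(spectra):
            assert b.intensities.sum() == pytest.approx(100.0, abs=1e-9)


class TestPca:
    def test_duplicated_spectra_have_identical_scores_zero_variance(self):
        b = preprocess_spectrum(spectrum([(400.0, 1.0), (600.0, 2.0)]))
        scores, evr, _, _ = pca_scores([b, b, b])
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)
        np.testing.assert_allclose(evr, 0.0, atol=1e-12)

    def test_one_bin_difference_drives_pc1(self):
        a = [BinnedSpectrum(np.array([400, 600]), np.array([30.0, 70.0]), (200, 1200), "a", str(i))
             for i in range(3)]
        b = [BinnedSpectrum(np.array([400, 600]), np.array([70.0, 30.0]), (200, 1200), "b", str(i))
             for i in range(3)]
        scores, evr, loadings, masses = pca_scores(a + b)
        assert evr[0] == pytest.approx(1.0)
        # groups separate on PC1 and the loading lives on the differing bins
        assert np.sign(scores[:3, 0]).tolist() != np.sign(scores[3:, 0]).tolist()
        assert abs(loadings[0]).max() == pytest.approx(abs(loadings[0]).min(), rel=1e-6)

    def test_explained_variance_non_increasing(self):
        spectra = simulate_tofsims_spectra(SimulationConfig(seed=4))
        _, evr, _, _ = pca_scores(SpectrumBinner().transform(spectra))
        assert np.all(np.diff(evr) <= 1e-12)


class TestLdaLoocv:
    def test_disjoint_dominant_peaks_classify_perfectly(self):
        cfg = SimulationConfig(
            seed=5,
            spectra_groups={
                "a": [(300.2, 10.0, 0.5)],
                "b": [(420.2, 10.0, 0.5)],
            },
            common_peaks=[(700.3, 2.0, 0.2)],
        )
        binned = SpectrumBinner().transform(simulate_tofsims_spectra(cfg))
        _, accuracy, _ = fisher_lda_loocv(binned)
        assert accuracy == 1.0

    def test_accuracy_bounded(self):
        binned = SpectrumBinner().transform(
            simulate_tofsims_spectra(SimulationConfig(seed=6))
        )
        _, accuracy, _ = fisher_lda_loocv(binned)
        assert 0.0 <= accuracy <= 1.0

    def test_identical_groups_score_near_chance(self):
        """Same generating parameters for both groups: LOOCV accuracy over
        repeated seeds must straddle the 50% chance level."""
        peaks = [(500.3, 5.0, 0.5), (700.3, 3.0, 0.3)]
        accs = []
        for seed in range(12):
            cfg = SimulationConfig(
                seed=seed, spectra_groups={"a": peaks, "b": peaks}, common_peaks=[]
            )
            binned = SpectrumBinner().transform(simulate_tofsims_spectra(cfg))
            accs.append(fisher_lda_loocv(binned)[1])
        assert 0.2 <= np.mean(accs) <= 0.8

    def test_single_group_rejected(self):
        binned = [preprocess_spectrum(spectrum([(400.0, 1.0)], group="a", rid=str(i)))
                  for i in range(3)]
        with pytest.raises(ValueError):
            fisher_lda_loocv(binned)


class TestIonYields:
    def _binned(self, control_level, exposed_level, n=4, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for g, level in (("control", control_level), ("exposed", exposed_level)):
            for i in range(n):
                it = np.array([level + sd * rng.normal(), 10.0])
                out.append(
                    preprocess_spectrum(
                        spectrum([(500.0, max(it[0], 1e-9)), (900.0, it[1])], group=g, rid=f"{g}{i}")
                    )
                )
        return out

    def test_equal_groups_read_100pct_not_significant(self):
        table = compare_ion_yields(self._binned(5.0, 5.0), [500], "control")
        assert table.loc[0, "relative_pct"] == pytest.approx(100.0)
        assert not table.loc[0, "significant"]

    def test_halved_intensity_detected(self):
        table = compare_ion_yields(self._binned(5.0, 2.5, sd=0.01, seed=1), [500], "control")
        # relative on the normalized scale: exposed bin share drops
        assert table.loc[0, "relative_pct"] < 100.0
        assert table.loc[0, "significant"]

    def test_absent_control_signal_reported_missing(self):
        table = compare_ion_yields(self._binned(5.0, 5.0), [777], "control")
        assert bool(table.loc[0, "missing"])

    def test_default_lipid_bins_downregulated_on_emulated_groups(self):
        binned = SpectrumBinner().transform(
            simulate_tofsims_spectra(SimulationConfig(seed=8))
        )
        table = compare_ion_yields(binned, [625, 777, 791, 813], "control")
        assert (table["relative_pct"] < 100.0).all()

    def test_label_permutation_keeps_matrix_shape(self):
        binned = SpectrumBinner().transform(
            simulate_tofsims_spectra(SimulationConfig(seed=9))
        )
        rng = np.random.default_rng(0)
        labels = [b.group for b in binned]
        perm = rng.permutation(labels)
        shuffled = [dataclasses.replace(b, group=g) for b, g in zip(binned, perm)]
        X1, _, _ = spectra_to_matrix(binned)
        X2, _, _ = spectra_to_matrix(shuffled)
        np.testing.assert_array_equal(X1, X2)
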