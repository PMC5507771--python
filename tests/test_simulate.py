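"""Synthetic cohort generator: spectra, phenotypes, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from metabopredict import CohortConfig, simulate_cohort, derive_phenotypes
from metabopredict.library import MetaboliteSpec, default_library, dump_library, load_library
from metabopredict.simulate import mixture_spectrum, synthesize_spectrum
from metabopredict.spectra import SpectralDataset

AXIS = np.linspace(0.5, 9.5, 2000)


def singlet(name="X", center=3.0, rel=2.0, hw=0.01, **kw):
    return MetaboliteSpec(name, [(center, rel, hw)], **kw)


class TestSynthesizeSpectrum:
    def test_empty_mixture_is_zero(self):
        lib = [singlet()]
        out = synthesize_spectrum({"X": 0.0}, lib, AXIS, noise_sd=0, baseline_amplitude=0)
        assert np.all(out == 0)

    def test_lorentzian_apex_and_half_width(self):
        lib = [singlet(center=3.0, rel=2.0, hw=0.05)]
        out = synthesize_spectrum({"X": 1.5}, lib, AXIS, noise_sd=0, baseline_amplitude=0)
        apex_idx = np.argmax(out)
        assert abs(AXIS[apex_idx] - 3.0) <= (AXIS[1] - AXIS[0])
        apex = out[apex_idx]
        half_idx = np.argmin(np.abs(AXIS - 3.05))
        assert out[half_idx] == pytest.approx(apex / 2, rel=0.05)

    def test_concentration_linearity(self):
        lib = [singlet("A", 2.0), singlet("B", 6.0)]
        base = synthesize_spectrum({"A": 0.0, "B": 1.0}, lib, AXIS, 0, 0)
        one = synthesize_spectrum({"A": 1.0, "B": 1.0}, lib, AXIS, 0, 0)
        two = synthesize_spectrum({"A": 2.0, "B": 1.0}, lib, AXIS, 0, 0)
        np.testing.assert_allclose(two - base, 2 * (one - base), rtol=1e-9, atol=1e-12)

    def test_unknown_metabolite_named_in_error(self):
        with pytest.raises(KeyError, match="nonexistent"):
            mixture_spectrum({"nonexistent": 1.0}, [singlet()], AXIS)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            mixture_spectrum({"X": -1.0}, [singlet()], AXIS)

    def test_deterministic_given_seed(self):
        lib = [singlet()]
        a = synthesize_spectrum({"X": 1.0}, lib, AXIS, 0.1, 0.3, seed=5)
        b = synthesize_spectrum({"X": 1.0}, lib, AXIS, 0.1, 0.3, seed=5)
        np.testing.assert_array_equal(a, b)


class TestDerivePhenotypes:
    def test_constant_curve(self):
        times = [0.0, 30.0, 60.0, 120.0]
        gly = pd.DataFrame([[5.0] * 4], index=["a1"])
        out = derive_phenotypes(times, gly)
        assert out.loc["a1", "CG"] == pytest.approx(600.0)
        assert out.loc["a1", "dG"] == pytest.approx(0.0)

    def test_hand_trapezoid(self):
        times = [0.0, 15.0, 30.0]
        gly = pd.DataFrame([[5.0, 10.0, 5.0]], index=["a1"])
        out = derive_phenotypes(times, gly)
        assert out.loc["a1", "CG"] == pytest.approx(225.0)

    def test_zero_organ_weight_gives_zero_ratio(self):
        times = [0.0, 15.0]
        gly = pd.DataFrame([[5.0, 6.0]], index=["a1"])
        weights = pd.DataFrame({"BW": [30.0], "EPD": [0.0]}, index=["a1"])
        out = derive_phenotypes(times, gly, weights=weights)
        assert out.loc["a1", "EPD_ratio"] == 0.0

    def test_missing_time_zero_rejected(self):
        with pytest.raises(ValueError, match="time 0"):
            derive_phenotypes([15.0, 30.0], pd.DataFrame([[5.0, 6.0]]))

    def test_negative_glycemia_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            derive_phenotypes([0.0, 15.0], pd.DataFrame([[5.0, -1.0]]))


class TestSimulateCohort:
    def test_bit_identical_for_same_seed(self):
        cfg = CohortConfig(n_animals=16, timepoints=(0,), n_ppm_points=500, seed=3,
                           group_fractions={"ob_igt": 0.1, "l_igt": 0.1, "lng": 0.1})
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        for tp in a.spectra:
            np.testing.assert_array_equal(a.spectra[tp].intensities,
                                          b.spectra[tp].intensities)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_series_equal(a.ground_truth.z, b.ground_truth.z)

    def test_degenerate_noise_gives_exact_mixtures(self):
        cfg = CohortConfig(n_animals=14, timepoints=(0,), n_ppm_points=600,
                           noise_sd=0.0, dilution_log_sd=0.0, jitter_max=0,
                           baseline_amplitude=0.0, seed=4,
                           group_fractions={"ob_igt": 0.08, "l_igt": 0.08, "lng": 0.08})
        c = simulate_cohort(cfg)
        ds = c.spectra[0]
        for i, aid in enumerate(c.animal_ids):
            clean = mixture_spectrum(
                c.ground_truth.concentrations[0].loc[aid].to_dict(),
                c.library, ds.ppm,
            )
            np.testing.assert_allclose(ds.intensities[i], clean, rtol=1e-12)

    def test_shared_ids_across_components(self, small_cohort):
        ids = small_cohort.animal_ids
        for tp, ds in small_cohort.spectra.items():
            assert ds.sample_ids == ids
        assert list(small_cohort.ground_truth.z.index) == ids
        assert list(small_cohort.phenotypes.index) == ids

    def test_planted_extremes_exceed_two_sd(self, default_cohort):
        gt = default_cohort.ground_truth
        pheno = gt.noiseless_phenotypes
        cg, bw = pheno["CG"], pheno["BW"]
        t_cg = cg.mean() + 2 * cg.std()
        t_bw = bw.mean() + 2 * bw.std()
        igt = gt.planted_group.isin(["ob_igt", "l_igt"])
        assert (cg[igt] > t_cg).all()
        assert (bw[gt.planted_group == "ob_igt"] > t_bw).all()

    def test_effect_size_zero_decouples_metabolome(self):
        # under the null the baseline-metabolite -> outcome correlation sits
        # below the n-dependent 95% bound in nearly all replicates
        null_bound = 1.96 / np.sqrt(50 - 1)
        hits = 0
        for rep in range(100):
            cfg = CohortConfig(seed=50_000 + rep, effect_size=0.0,
                               timepoints=(0,), n_ppm_points=50,
                               ppm_range=(3.0, 3.5))
            lib = [MetaboliteSpec("TMAO", [(3.27, 9.0, 0.006)], 6.0)]
            c = simulate_cohort(cfg, lib)
            rho = spearmanr(c.ground_truth.concentrations[0]["TMAO"],
                            c.phenotypes["CG"]).statistic
            hits += abs(rho) < null_bound
        assert hits >= 94

    def test_infeasible_group_fraction_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            CohortConfig(n_animals=20,
                         group_fractions={"ob_igt": 0.01, "l_igt": 0.05, "lng": 0.05})

    def test_cohort_too_small_rejected(self):
        with pytest.raises(ValueError, match="14"):
            CohortConfig(n_animals=10)

    def test_tmao_outcome_rho_matches_calibration(self):
        # generator self-check: planted TMAO -> CG Spearman rho ~ 0.6
        rhos = []
        for seed in range(50):
            c = simulate_cohort(CohortConfig(seed=seed, timepoints=(0,),
                                             n_ppm_points=60))
            rhos.append(spearmanr(c.ground_truth.concentrations[0]["TMAO"],
                                  c.phenotypes["CG"]).statistic)
        assert abs(np.mean(rhos) - 0.6) <= 0.15


class TestLibraryAndSpectraIO:
    def test_library_yaml_round_trip(self, tmp_path, library):
        path = tmp_path / "lib.yaml"
        dump_library(library, path)
        back = load_library(path)
        assert [m.name for m in back] == [m.name for m in library]
        assert back[0].peaks == library[0].peaks
        assert back[0].marker_loading == library[0].marker_loading

    def test_required_markers_present(self, library):
        names = {m.name for m in library}
        assert {"TMAO", "TMA", "DMA", "MMA", "choline", "hippurate", "PAG",
                "citrate", "2-oxoglutarate"} <= names

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="at least one peak"):
            MetaboliteSpec("empty", [])
        with pytest.raises(ValueError, match="half_width"):
            MetaboliteSpec("bad", [(3.0, 1.0, 0.0)])
        with pytest.raises(ValueError, match="marker_loading"):
            MetaboliteSpec("bad", [(3.0, 1.0, 0.01)], marker_loading=1.5)

    def test_spectral_dataset_round_trip(self, tmp_path, small_cohort):
        ds = small_cohort.spectra[0]
        path = tmp_path / "spec.tsv"
        ds.write(path)
        back = SpectralDataset.read(path)
        np.testing.assert_array_equal(back.ppm, ds.ppm)
        np.testing.assert_array_equal(back.intensities, ds.intensities)
        assert back.sample_ids == ds.sample_ids

    def test_dataset_invariants(self):
        with pytest.raises(ValueError, match="monotone"):
            SpectralDataset(np.array([1.0, 3.0, 2.0]), np.zeros((1, 3)), ["a"])
        with pytest.raises(ValueError, match="duplicate"):
            SpectralDataset(np.array([1.0, 2.0]), np.zeros((2, 2)), ["a", "a"])
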