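import numpy as np
import pytest

from polyqvoc.assays import (
    CDSpectrum,
    LandmarkSet,
    MREParams,
    cd_features,
    cochlear_ratios,
    condensate_relative_area,
    frap_normalize,
    frap_normalize_fit,
    luciferase_normalize,
    mean_residue_ellipticity,
    melt_curve,
    ratio_222_208,
    subtraction_spectrum,
)
from polyqvoc.errors import DegenerateDataError
from polyqvoc.synth import cd_basis_coil, cd_basis_helix, gen_cd_spectra, gen_frap_trace


class TestMRE:
    def test_direct_substitution(self):
        params = MREParams(mw=1000, n_residues=11, conc_mg_ml=1, pathlength_cm=0.1)
        assert mean_residue_ellipticity(20, params) == pytest.approx(2000)

    @pytest.mark.parametrize("seed", range(5))
    def test_linearity_in_theta_and_inverse_in_c_pl(self, seed):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(-50, 50)
        params = MREParams(
            mw=rng.uniform(500, 5000),
            n_residues=int(rng.integers(2, 60)),
            conc_mg_ml=rng.uniform(0.05, 2),
            pathlength_cm=rng.uniform(0.01, 1),
        )
        base = mean_residue_ellipticity(theta, params)
        assert mean_residue_ellipticity(2 * theta, params) == pytest.approx(2 * base)
        doubled_c = MREParams(params.mw, params.n_residues, 2 * params.conc_mg_ml,
                              params.pathlength_cm)
        assert mean_residue_ellipticity(theta, doubled_c) == pytest.approx(base / 2)
        doubled_pl = MREParams(params.mw, params.n_residues, params.conc_mg_ml,
                               2 * params.pathlength_cm)
        assert mean_residue_ellipticity(theta, doubled_pl) == pytest.approx(base / 2)

    def test_single_residue_rejected(self):
        with pytest.raises(ValueError):
            MREParams(mw=1000, n_residues=1, conc_mg_ml=1, pathlength_cm=0.1)


class TestCDFeatures:
    def _spec(self, values, temp):
        wl = np.arange(190.0, 261.0)
        return CDSpectrum(wl, values, temp, mre=values)

    def test_identical_spectra_zero_subtraction(self):
        wl = np.arange(190.0, 261.0)
        values = np.sin(wl / 10.0)
        low, high = self._spec(values, 5), self._spec(values, 75)
        assert np.allclose(subtraction_spectrum(low, high), 0.0)

    def test_ratio_222_208_arithmetic(self):
        wl = np.arange(190.0, 261.0)
        values = np.zeros_like(wl)
        values[wl == 222] = -30000
        values[wl == 208] = -25000
        assert ratio_222_208(self._spec(values, 5)) == pytest.approx(1.2)

    def test_melt_first_point_exactly_one(self):
        wl = np.arange(190.0, 261.0)
        spectra = [
            self._spec(np.full_like(wl, v), t)
            for v, t in [(-30000, 5), (-20000, 25), (-10000, 75)]
        ]
        temps, melt = melt_curve(spectra)
        assert melt[0] == 1.0
        assert list(temps) == [5, 25, 75]
        assert melt[-1] == pytest.approx(1 / 3)

    def test_mismatched_grids_error(self):
        a = CDSpectrum(np.arange(190.0, 261.0), np.zeros(71), 5)
        b = CDSpectrum(np.arange(190.0, 260.0), np.zeros(70), 75)
        with pytest.raises(ValueError):
            subtraction_spectrum(a, b)

    def test_nearest_grid_point_within_1nm(self):
        wl = np.arange(190.0, 261.0, 0.5)
        spec = CDSpectrum(wl, np.ones_like(wl), 5, mre=np.ones_like(wl))
        assert spec.value_at(222.3) == 1.0
        sparse = CDSpectrum(np.array([190.0, 240.0]), np.ones(2), 5)
        with pytest.raises(ValueError, match="1 nm"):
            sparse.value_at(208.0)

    def test_synthetic_bases_share_isodichroic_point(self):
        wl = np.arange(190.0, 261.0)
        idx = int(np.nonzero(wl == 203.0)[0][0])
        helix, coil = cd_basis_helix(wl), cd_basis_coil(wl)
        assert helix[idx] == pytest.approx(coil[idx])
        spectra, _ = gen_cd_spectra(temperatures_c=(5, 25, 50, 75), seed=0)
        at_203 = [s.mre[idx] for s in spectra]
        assert np.ptp(at_203) < 1e-9

    def test_cd_features_bundle(self):
        spectra, truth = gen_cd_spectra(temperatures_c=(5, 75), weights=(1.0, 0.0))
        features = cd_features(spectra)
        assert np.allclose(features.subtraction, truth["basis_difference"])
        assert features.melt_normalized[0] == 1.0


class TestFRAP:
    def test_noiseless_recovery_matches_programmed_parameters(self):
        trace, truth = gen_frap_trace(tau_s=24.28, f0=0.1, plateau=0.802, noise_sd=0.0)
        fit, _ = frap_normalize_fit(trace)
        assert fit.t_half_s == pytest.approx(truth["t_half_s"], rel=0.01)
        assert fit.t_half_s == pytest.approx(16.83, rel=0.01)
        assert fit.mobile_fraction == pytest.approx(0.78, rel=0.01)

    def test_prebleach_mean_of_normalized_curve_is_one(self):
        trace, _ = gen_frap_trace(noise_sd=0.0, seed=5)
        norm = frap_normalize(trace)
        assert norm[: trace.n_prebleach].mean() == pytest.approx(1.0)

    def test_shared_decay_cancels(self):
        plain, _ = gen_frap_trace(noise_sd=0.0, seed=2)
        drifting, _ = gen_frap_trace(noise_sd=0.0, seed=2, shared_decay_rate=0.004)
        fit_plain, _ = frap_normalize_fit(plain)
        fit_drift, _ = frap_normalize_fit(drifting)
        assert fit_drift.plateau == pytest.approx(fit_plain.plateau, rel=1e-6)
        assert fit_drift.t_half_s == pytest.approx(fit_plain.t_half_s, rel=1e-4)

    def test_no_recovery_flagged(self):
        trace, _ = gen_frap_trace(tau_s=20, f0=0.6, plateau=0.4, noise_sd=0.0)
        fit, _ = frap_normalize_fit(trace)
        assert "no_recovery" in fit.flags

    def test_invalid_prebleach_count_rejected(self):
        from polyqvoc.assays import FRAPTrace

        with pytest.raises(ValueError):
            FRAPTrace(np.arange(5.0), np.ones(5), np.ones((1, 5)), n_prebleach=5)


class TestLuciferase:
    def test_programmed_effect_recovered_exactly_without_noise(self):
        from polyqvoc.synth import gen_luciferase_plate

        plate, _ = gen_luciferase_plate(
            group_effects={"control": 1.0, "treated": 0.79}, noise_sd=0.0, seed=1
        )
        out = luciferase_normalize(
            plate["firefly"], plate["renilla"], plate["group"].to_numpy(), "control"
        )
        treated = out[plate["group"] == "treated"]
        assert np.allclose(treated, 0.79)

    def test_control_mean_exactly_one(self, rng):
        firefly = rng.uniform(1e4, 1e6, 24)
        renilla = rng.uniform(1e4, 1e6, 24)
        labels = np.array(["control"] * 12 + ["treated"] * 12)
        out = luciferase_normalize(firefly, renilla, labels, "control")
        assert out[labels == "control"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        firefly = rng.uniform(1e4, 1e6, 10)
        renilla = rng.uniform(1e4, 1e6, 10)
        labels = np.array(["control"] * 5 + ["t"] * 5)
        base = luciferase_normalize(firefly, renilla, labels, "control")
        scaled = luciferase_normalize(2 * firefly, 2 * renilla, labels, "control")
        assert np.allclose(base, scaled)

    def test_zero_renilla_names_well(self):
        with pytest.raises(ValueError, match="well 1"):
            luciferase_normalize([1, 1], [1, 0], np.array(["control", "t"]), "control")


class TestCondensateArea:
    def test_relative_area(self):
        relative, normalized = condensate_relative_area(10, 100)
        assert relative == pytest.approx(0.10)
        assert normalized is None

    def test_control_normalization(self):
        relative, normalized = condensate_relative_area(5, 100, control_mean=0.20)
        assert relative == pytest.approx(0.05)
        assert normalized == pytest.approx(0.25)

    def test_treated_vs_control_pair(self):
        # control fields averaging 0.5 relative area; treated at 0.12
        control_mean = 0.5
        _, treated = condensate_relative_area(12, 100, control_mean)
        _, control = condensate_relative_area(50, 100, control_mean)
        assert treated == pytest.approx(0.24)
        assert control == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            condensate_relative_area(1, 0)


class TestCochlearRatios:
    def test_unit_distances(self):
        lm = LandmarkSet(
            cochlear_width=((0, 0, 0), (1, 0, 0)),
            cochlear_height=((0, 0, 0), (0, 1, 0)),
            basicranial_width=((0, 0, 0), (4, 0, 0)),
        )
        cw_bw, h_w = cochlear_ratios(lm)
        assert cw_bw == pytest.approx(0.25)
        assert h_w == pytest.approx(1.0)

    def test_3d_distances(self):
        lm = LandmarkSet(
            cochlear_width=((1, 1, 1), (2, 2, 2)),
            cochlear_height=((0, 0, 0), (0, 0, np.sqrt(3))),
            basicranial_width=((0, 0, 0), (2 * np.sqrt(3), 0, 0)),
        )
        cw_bw, h_w = cochlear_ratios(lm)
        assert cw_bw == pytest.approx(0.5)
        assert h_w == pytest.approx(1.0)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            LandmarkSet(
                cochlear_width=((0, 0, 0), (np.nan, 0, 0)),
                cochlear_height=((0, 0, 0), (0, 1, 0)),
                basicranial_width=((0, 0, 0), (1, 0, 0)),
            )

    def test_zero_denominator_rejected(self):
        lm = LandmarkSet(
            cochlear_width=((0, 0, 0), (1, 0, 0)),
            cochlear_height=((0, 0, 0), (0, 1, 0)),
            basicranial_width=((0, 0, 0), (0, 0, 0)),
        )
        with pytest.raises(ValueError):
            cochlear_ratios(lm)

    def test_zero_208_errors(self):
        wl = np.arange(190.0, 261.0)
        values = np.zeros_like(wl)
        values[wl == 222] = -1.0
        spec = CDSpectrum(wl, values, 5, mre=values)
        with pytest.raises(DegenerateDataError):
            ratio_222_208(spec)
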