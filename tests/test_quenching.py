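import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from ionquench.beam_model import DepthDoseCurve, DepthGrid, SpeciesDepthProfile
from ionquench.constants import RHO_WATER_UG_CM3
from ionquench.datasets import load_fluence_let_tables, published_birks_params
from ionquench.errors import (
    CalibrationError,
    ConfigurationError,
    IonquenchError,
)
from ionquench.quenching import (
    PROBE_PRESETS,
    BirksParams,
    NormalizedRL,
    birks_rl,
    correct_curve,
    eta_combined,
    eta_profile,
    eta_single,
    fit_birks,
    model_normalized_rl,
    normalized_rl_curve,
    volume_average,
)
from ionquench.workflow import (
    DEFAULT_GROUND_TRUTH,
    DEFAULT_LET_RANGES,
    ExperimentConfig,
    synth_experiment,
)


class TestBirksModel:
    def test_kb_zero_is_unquenched(self):
        p = BirksParams("H-1", 0.0, 1.2)
        assert birks_rl(50.0, 2.0, p) == pytest.approx(1.2 * 50.0 * 2.0)

    def test_saturation_asymptote(self):
        p = BirksParams("C-12", 5000.0, 0.9)
        asymptote = p.rl0 / p.kb_cm_per_mev
        assert birks_rl(1e9, 1.0, p) == pytest.approx(asymptote, rel=1e-3)

    def test_table6_hand_arithmetic(self):
        # published 4um proton row: kB = 300 ug/MeV/cm^2, RL0 = 1.13, at
        # LET = 45 MeV/cm and unit fluence; direct substitution oracle
        p = published_birks_params("grain_4um")["H-1"]
        kb_dimless = 300.0 / RHO_WATER_UG_CM3 * 45.0
        oracle = 1.13 * 45.0 / (1.0 + kb_dimless) * 1.0
        assert birks_rl(45.0, 1.0, p) == pytest.approx(oracle, rel=1e-12)

    def test_eta_single_kb_zero(self):
        p = BirksParams("H-1", 0.0, 1.25)
        assert eta_single(10.0, p) == pytest.approx(1.0 / 1.25)

    def test_energy_recovery_identity(self):
        # eta * RL == fluence * LET per species, to 1e-12 relative
        rng = np.random.default_rng(8)
        for _ in range(200):
            p = BirksParams(
                "H-1", float(rng.uniform(0, 5000)), float(rng.uniform(0.1, 2.0))
            )
            let = float(rng.uniform(0.1, 2000.0))
            phi = float(rng.uniform(0.01, 10.0))
            assert eta_single(let, p) * birks_rl(let, phi, p) == pytest.approx(
                phi * let, rel=1e-12
            )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BirksParams("H-1", -1.0, 1.0)
        with pytest.raises(ValueError):
            BirksParams("H-1", 1.0, 0.0)


def _eq8(f, let, p):
    return f * (1.0 + p.kb_cm_per_mev * let) / p.rl0


class TestEtaCombined:
    def test_single_species_kb_zero(self):
        p = {"H-1": BirksParams("H-1", 0.0, 1.3)}
        eta = eta_combined(["H-1"], [1.0], [10.0], p)
        assert eta == pytest.approx(1.0 / 1.3)

    def test_reduces_to_single_species_form_bitwise(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = BirksParams("H-1", float(rng.uniform(0, 4000)),
                            float(rng.uniform(0.1, 2)))
            let = float(rng.uniform(1, 500))
            assert eta_combined(["H-1"], [1.0], [let], {"H-1": p}) == _eq8(
                1.0, let, p
            )

    def test_reduces_to_two_and_three_species_forms_bitwise(self):
        rng = np.random.default_rng(2)
        params = {
            "H-1": BirksParams("H-1", 3000.0, 1.0),
            "He-4": BirksParams("He-4", 800.0, 1.05),
            "C-12": BirksParams("C-12", 4000.0, 0.95),
        }
        for species in (["He-4", "H-1"], ["C-12", "He-4", "H-1"]):
            for _ in range(200):
                f = rng.dirichlet(np.ones(len(species)))
                let = rng.uniform(1, 1000, len(species))
                oracle = 0.0
                for j, sp in enumerate(species):
                    oracle += _eq8(f[j], let[j], params[sp])
                assert eta_combined(species, f, let, params) == oracle

    def test_three_species_peak_row_oracle(self):
        # published C400 Bragg-peak row with published parameters,
        # term-by-term summation oracle
        tables = load_fluence_let_tables()
        row = tables[(tables.beam == "C400") & (tables.row_kind == "peak")]
        species = list(row.species)
        f = row.fluence_pct.to_numpy() / 100.0
        f = f / f.sum()
        let = 10.0 * row.let_kev_um.to_numpy()
        params = published_birks_params("grain_4um")
        oracle = sum(
            _eq8(f[j], let[j], params[sp]) for j, sp in enumerate(species)
        )
        got = eta_combined(species, f, let, params)
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_missing_species_error_lists_names(self):
        p = {"H-1": BirksParams("H-1", 100.0, 1.0)}
        with pytest.raises(ConfigurationError, match="He-4"):
            eta_combined(
                ["H-1", "He-4"], [0.6, 0.4], [10.0, 20.0], p, default=None
            )

    def test_unnormalized_fractions_rejected(self):
        p = {"H-1": BirksParams("H-1", 100.0, 1.0)}
        with pytest.raises(ConfigurationError):
            eta_combined(["H-1"], [0.7], [10.0], p)

    @settings(max_examples=40, deadline=None)
    @given(
        kb=st.floats(1.0, 5000.0),
        rl0=st.floats(0.1, 2.0),
        let1=st.floats(1.0, 1000.0),
        dlet=st.floats(0.1, 1000.0),
    )
    def test_eta_nondecreasing_in_let(self, kb, rl0, let1, dlet):
        p = BirksParams("H-1", kb, rl0)
        assert eta_single(let1 + dlet, p) >= eta_single(let1, p)

    @settings(max_examples=40, deadline=None)
    @given(data=st.data())
    def test_eta_floor_is_min_inverse_rl0(self, data):
        n = data.draw(st.integers(1, 4))
        rl0s = [data.draw(st.floats(0.1, 2.0)) for _ in range(n)]
        kbs = [data.draw(st.floats(0.0, 5000.0)) for _ in range(n)]
        lets = [data.draw(st.floats(1.0, 1000.0)) for _ in range(n)]
        f = np.random.default_rng(0).dirichlet(np.ones(n))
        species = [f"S{i}" for i in range(n)]
        params = {
            sp: BirksParams(sp, kb, rl0)
            for sp, kb, rl0 in zip(species, kbs, rl0s)
        }
        eta = eta_combined(species, f, lets, params)
        assert eta >= min(1.0 / r for r in rl0s) - 1e-12


class TestNormalizedRL:
    def test_entrance_value_is_mu_entrance(self, proton_bundle):
        b = proton_bundle.beams["H160"]
        measured = list(zip(b.depths, b.expected_delta_rl))
        nrl = normalized_rl_curve(0.93, measured, b.reference)
        assert nrl.values[0] == pytest.approx(0.93, rel=1e-12)

    def test_unquenched_detector_reproduces_reference(self, proton_bundle):
        b = proton_bundle.beams["H160"]
        measured = [(d, 1000.0 * b.reference.at(d)) for d in b.depths]
        nrl = normalized_rl_curve(1.0, measured, b.reference)
        np.testing.assert_allclose(nrl.values, nrl.ref_norm, rtol=1e-9)

    def test_quenched_deficit_matches_eta_prediction(self, proton_bundle):
        b = proton_bundle.beams["H160"]
        measured = list(zip(b.depths, b.expected_delta_rl))
        nrl = normalized_rl_curve(b.mu_entrance_true, measured, b.reference)
        predicted = model_normalized_rl(
            b.depths, b.profile, proton_bundle.ground_truth, b.reference
        )
        np.testing.assert_allclose(nrl.values, predicted, rtol=5e-3)

    def test_missing_entrance_point_raises(self, proton_bundle):
        b = proton_bundle.beams["H160"]
        with pytest.raises(CalibrationError):
            normalized_rl_curve(1.0, [(50.0, 10.0), (60.0, 9.0)], b.reference)


class TestFitBirks:
    def _nrl(self, bundle, label):
        b = bundle.beams[label]
        eta = eta_profile(b.profile, bundle.ground_truth)
        idx = [b.profile.grid.locate(d) for d in b.depths]
        refn = b.reference.dose / b.reference.dose[0]
        return NormalizedRL(b.depths, refn[idx] / eta[idx], refn[idx]), b

    def test_zero_noise_recovery(self, proton_bundle):
        nrl, b = self._nrl(proton_bundle, "H160")
        fit = fit_birks(
            nrl, b.profile, DEFAULT_LET_RANGES["H-1"], frozen={},
            fit_species="H-1",
        )
        kb_t, rl0_t = DEFAULT_GROUND_TRUTH["H-1"]
        assert fit.fitted.kb_ug_per_mev_cm2 == pytest.approx(kb_t, rel=1e-3)
        assert fit.fitted.rl0 == pytest.approx(rl0_t, rel=1e-3)
        assert fit.r_squared > 0.999

    def test_frozen_params_pass_through_untouched(self, tri_bundle):
        nrl, b = self._nrl(tri_bundle, "He150")
        frozen = {"H-1": tri_bundle.ground_truth["H-1"]}
        fit = fit_birks(
            nrl, b.profile, DEFAULT_LET_RANGES["He-4"], frozen=frozen,
            fit_species="He-4",
        )
        assert fit.params["H-1"] is frozen["H-1"]

    def test_bias_vanishes_with_noise(self, proton_bundle):
        nrl, b = self._nrl(proton_bundle, "H160")
        kb_t = DEFAULT_GROUND_TRUTH["H-1"][0]
        medians = []
        for noise in (0.01, 0.001, 0.0001):
            errs = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                noisy = NormalizedRL(
                    nrl.depths,
                    nrl.values * (1 + noise * rng.standard_normal(len(nrl.values))),
                    nrl.ref_norm,
                )
                fit = fit_birks(
                    noisy, b.profile, DEFAULT_LET_RANGES["H-1"], frozen={},
                    fit_species="H-1",
                )
                errs.append(abs(fit.fitted.kb_ug_per_mev_cm2 / kb_t - 1))
            medians.append(float(np.median(errs)))
        assert medians[0] < 0.10
        assert medians[2] < medians[0]
        assert medians[2] < 1e-3

    def test_too_few_points_in_let_range(self, proton_bundle):
        nrl, b = self._nrl(proton_bundle, "H160")
        with pytest.raises(ConfigurationError):
            fit_birks(nrl, b.profile, (4000.0, 5000.0), frozen={},
                      fit_species="H-1")

    def test_cannot_fit_frozen_species(self, proton_bundle):
        nrl, b = self._nrl(proton_bundle, "H160")
        frozen = {"H-1": proton_bundle.ground_truth["H-1"]}
        with pytest.raises(ConfigurationError):
            fit_birks(nrl, b.profile, DEFAULT_LET_RANGES["H-1"],
                      frozen=frozen, fit_species="H-1")


class TestVolumeAverage:
    def _gaussian_curve(self, sigma_mm=0.5, bin_width=0.05):
        grid = DepthGrid(bin_width=bin_width, n_bins=801)
        x = grid.depths
        mu = x[len(x) // 2]
        dose = np.exp(-0.5 * ((x - mu) / sigma_mm) ** 2)
        return DepthDoseCurve(grid, dose), mu, sigma_mm

    def test_single_bin_window_is_identity_with_warning(self):
        curve, _, _ = self._gaussian_curve(bin_width=0.5)
        probe = PROBE_PRESETS["grain_38um"]  # 0.2 mm < 0.5 mm bin
        with pytest.raises(ConfigurationError):
            volume_average(curve, probe)

    def test_constant_profile_unchanged(self):
        grid = DepthGrid(bin_width=0.1, n_bins=200)
        curve = DepthDoseCurve(grid, np.full(200, 3.3))
        out = volume_average(curve, PROBE_PRESETS["single_crystal"])
        np.testing.assert_allclose(out.dose, 3.3, rtol=1e-12)

    def test_gaussian_peak_reduction_matches_closed_form(self):
        # boxcar * gaussian has the closed form
        #   (Phi((x - mu + w/2)/s) - Phi((x - mu - w/2)/s)) * s*sqrt(2pi)/w
        curve, mu, sigma = self._gaussian_curve()
        probe = PROBE_PRESETS["single_crystal"]  # 1.0 mm window
        out = volume_average(curve, probe)
        w = probe.active_length_mm
        expected_peak = (
            (norm.cdf(w / 2 / sigma) - norm.cdf(-w / 2 / sigma))
            * sigma
            * np.sqrt(2 * np.pi)
            / w
        )
        i_peak = curve.grid.locate(mu)
        assert out.dose[i_peak] == pytest.approx(expected_peak, rel=1e-3)

    def test_integral_conserved(self):
        curve, _, _ = self._gaussian_curve()
        out = volume_average(curve, PROBE_PRESETS["single_crystal"])
        assert out.dose.sum() == pytest.approx(curve.dose.sum(), rel=1e-3)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_integral_conserved_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        grid = DepthGrid(bin_width=0.1, n_bins=300)
        dose = rng.uniform(0.1, 5.0, 300)
        dose[:10] = dose[-10:] = 0.0  # edge renormalization aside
        out = volume_average(
            DepthDoseCurve(grid, dose), PROBE_PRESETS["single_crystal"]
        )
        assert out.dose.sum() == pytest.approx(dose.sum(), rel=1e-3)

    def test_profile_averaging_keeps_invariants(self, carbon_bundle):
        profile = carbon_bundle.beams["C290"].profile
        out = volume_average(profile, PROBE_PRESETS["single_crystal"])
        out.validate()


class TestCorrectCurve:
    def test_single_species_quench_then_correct_is_exact(
        self, pure_proton_profile
    ):
        profile, reference = pure_proton_profile
        truth = {"H-1": BirksParams("H-1", 3000.0, 1.1)}
        eta = eta_profile(profile, truth)
        refn = reference.dose / reference.dose[0]
        sel = refn > 0.01
        depths = profile.grid.depths[sel]
        nrl = NormalizedRL(depths, (refn / eta)[sel], refn[sel])
        result = correct_curve(nrl, profile, truth, reference)
        finite = np.isfinite(result.diff_pct_corrected)
        assert np.all(np.abs(result.diff_pct_corrected[finite]) < 0.1)

    def test_mixed_carbon_correction_beats_uncorrected(self, carbon_bundle):
        b = carbon_bundle.beams["C290"]
        eta = eta_profile(b.profile, carbon_bundle.ground_truth)
        idx = [b.profile.grid.locate(d) for d in b.depths]
        refn = b.reference.dose / b.reference.dose[0]
        nrl = NormalizedRL(b.depths, refn[idx] / eta[idx], refn[idx])
        result = correct_curve(nrl, b.profile, carbon_bundle.ground_truth,
                               b.reference)
        m = result.metrics
        assert abs(m["diff_at_peak_pct_corrected"]) <= 5.0
        assert abs(m["diff_at_peak_pct_uncorrected"]) > 25.0

    def test_helium_improvement_pattern(self, tri_bundle):
        # uncorrected tens of percent at the peak, corrected to a few
        b = tri_bundle.beams["He150"]
        eta = eta_profile(b.profile, tri_bundle.ground_truth)
        idx = [b.profile.grid.locate(d) for d in b.depths]
        refn = b.reference.dose / b.reference.dose[0]
        nrl = NormalizedRL(b.depths, refn[idx] / eta[idx], refn[idx])
        result = correct_curve(nrl, b.profile, tri_bundle.ground_truth,
                               b.reference)
        m = result.metrics
        assert abs(m["diff_at_peak_pct_uncorrected"]) > 20.0
        assert abs(m["diff_at_peak_pct_corrected"]) <= 5.0

    def test_non_finite_eta_raises_with_depth(self):
        grid = DepthGrid(bin_width=0.1, n_bins=3)
        profile = SpeciesDepthProfile(
            grid,
            ["H-1"],
            np.ones((3, 1)),
            np.array([[10.0], [np.inf], [10.0]]),
        )
        reference = DepthDoseCurve(grid, np.array([1.0, 2.0, 1.5]))
        nrl = NormalizedRL(grid.depths, np.array([1.0, 0.5, 0.4]),
                           np.array([1.0, 2.0, 1.5]))
        with pytest.raises(IonquenchError, match="0.15"):
            correct_curve(nrl, profile, {"H-1": BirksParams("H-1", 100.0, 1.0)},
                          reference)

    def test_result_csv_schema(self, carbon_bundle, tmp_path):
        b = carbon_bundle.beams["C290"]
        eta = eta_profile(b.profile, carbon_bundle.ground_truth)
        idx = [b.profile.grid.locate(d) for d in b.depths]
        refn = b.reference.dose / b.reference.dose[0]
        nrl = NormalizedRL(b.depths, refn[idx] / eta[idx], refn[idx])
        result = correct_curve(nrl, b.profile, carbon_bundle.ground_truth,
                               b.reference)
        path = tmp_path / "corr.csv"
        result.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == [
            "depth_mm", "eta", "dose_corrected", "dose_uncorrected",
            "ref_dose", "diff_pct_corrected", "diff_pct_uncorrected",
            "falloff",
        ]
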