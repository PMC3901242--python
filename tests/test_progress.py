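"""Splines, rate extraction, equilibrium inference, normalization."""

import numpy as np
import pytest

from nmrkin.progress import (AssayRun, EquilibrationError, ProgressCurve,
                             SplineFitError, conservation_defect,
                             estimate_noise_sd, exclude_pre_equilibration,
                             fit_smoothing_spline, frame_to_samples,
                             infer_equilibrium_species, normalize_to_reference,
                             rates_from_splines, read_tidy_csv,
                             reference_maximal_rate, samples_to_frame,
                             write_tidy_csv, RateSample)
from nmrkin.ratelaws import ReactionScheme, ReversibleHillUni
from nmrkin.synthetic import (NOISELESS, pgi_scenario,
                              simulate_noisy_timecourses)


def curve(t, c, assay="a1", species="G6P"):
    return ProgressCurve(assay, species, np.asarray(t, float),
                         np.asarray(c, float))


class TestSplineFitting:
    def test_linear_data_derivative_is_slope(self):
        t = np.linspace(0, 10, 12)
        spl = fit_smoothing_spline(curve(t, 3.0 + 0.7 * t), smoothing=5.0)
        np.testing.assert_allclose(spl.derivative(np.linspace(0, 10, 50)),
                                   0.7, rtol=1e-8)

    def test_quadratic_interpolation_derivative(self):
        # c(t) = 4 + 2t - 0.05 t^2 -> c'(10) = 1 exactly within cubic degree
        t = np.linspace(0, 20, 15)
        spl = fit_smoothing_spline(curve(t, 4 + 2 * t - 0.05 * t ** 2),
                                   smoothing=0.0)
        assert spl.derivative(10.0) == pytest.approx(1.0, rel=1e-9)

    def test_noisy_derivative_beats_finite_differences(self, rng):
        """Smoothing-spline derivative RMSE < central differences on the
        same noisy monotone curve."""
        t = np.linspace(0, 40, 60)
        true = 8.0 * np.exp(-t / 15.0)
        dtrue = -8.0 / 15.0 * np.exp(-t / 15.0)
        noisy = true + rng.normal(0, 0.05, t.size)
        spl = fit_smoothing_spline(curve(t, np.maximum(noisy, 0)), "auto")
        interior = slice(1, -1)
        rmse_spl = np.sqrt(np.mean(
            (spl.derivative(t[interior]) - dtrue[interior]) ** 2))
        fd = np.gradient(noisy, t)
        rmse_fd = np.sqrt(np.mean((fd[interior] - dtrue[interior]) ** 2))
        assert rmse_spl < rmse_fd

    def test_too_few_points_named_error(self):
        with pytest.raises(SplineFitError, match="a1/G6P"):
            fit_smoothing_spline(curve([0, 1, 2], [1, 2, 3]))

    def test_noise_estimator_scale(self, rng):
        y = 5.0 + rng.normal(0, 0.2, 500)
        assert estimate_noise_sd(y) == pytest.approx(0.2, rel=0.15)


class TestRatesFromSplines:
    @pytest.fixture
    def pgi_assay(self):
        spec = pgi_scenario(noise=NOISELESS)
        curves, truth = simulate_noisy_timecourses(spec)
        d = {c.species: c for c in curves if c.assay_id == "pgi1"}
        splines = {sp: fit_smoothing_spline(c, 0.0) for sp, c in d.items()}
        return spec, d, splines

    def test_signed_average_matches_single_species(self, pgi_assay):
        """With exactly consistent stoichiometry the averaged rate equals
        either single-species derivative."""
        spec, d, splines = pgi_assay
        scheme = ReactionScheme(("G6P",), ("F6P",), reversible=True)
        t = d["G6P"].time[5:-5]
        samples = rates_from_splines(AssayRun("pgi1"), splines, scheme, t)
        v_from_product = splines["F6P"].derivative(t)
        np.testing.assert_allclose([s.rate for s in samples], v_from_product,
                                   rtol=0.02, atol=1e-4)

    def test_opposite_derivatives_average(self):
        t = np.linspace(0, 10, 20)
        splines = {"S": fit_smoothing_spline(curve(t, 10 - 0.5 * t, species="S"), 0.0),
                   "P": fit_smoothing_spline(curve(t, 0.5 * t, species="P"), 0.0)}
        scheme = ReactionScheme(("S",), ("P",), reversible=True)
        samples = rates_from_splines(AssayRun("a1"), splines, scheme, t[2:-2])
        np.testing.assert_allclose([s.rate for s in samples], 0.5, rtol=1e-8)

    def test_rates_match_generating_law(self, pgi_assay):
        """Spline rates track the generating reversible MM law within 2%
        away from the endpoints."""
        from nmrkin.ratelaws import reversible_hill_uni_rate
        spec, d, splines = pgi_assay
        scheme = ReactionScheme(("G6P",), ("F6P",), reversible=True)
        t = d["G6P"].time[4:-4]
        samples = rates_from_splines(AssayRun("pgi1"), splines, scheme, t)
        v_model = np.array([
            reversible_hill_uni_rate(s.conc["G6P"], s.conc["F6P"],
                                     vf=spec.params.vf_volumetric(),
                                     ks=0.550, kp=0.152, keq=0.286)
            for s in samples])
        v_obs = np.array([s.rate for s in samples])
        scale = np.abs(v_model).max()
        np.testing.assert_allclose(v_obs, v_model, atol=0.02 * scale)

    def test_excluded_species_not_averaged(self):
        t = np.linspace(0, 10, 20)
        splines = {"S": fit_smoothing_spline(curve(t, 10 - 0.5 * t, species="S"), 0.0),
                   "P": fit_smoothing_spline(curve(t, 0.9 * t, species="P"), 0.0)}
        scheme = ReactionScheme(("S",), ("P",), reversible=True)
        samples = rates_from_splines(AssayRun("a1"), splines, scheme, t[2:-2],
                                     exclude=("P",))
        np.testing.assert_allclose([s.rate for s in samples], 0.5, rtol=1e-8)

    def test_out_of_support_times_skipped(self):
        t = np.linspace(0, 10, 20)
        splines = {"S": fit_smoothing_spline(curve(t, 10 - t, species="S"), 0.0)}
        scheme = ReactionScheme(("S",))
        samples = rates_from_splines(AssayRun("a1"), splines, scheme,
                                     [5.0, 50.0])
        assert len(samples) == 1

    def test_endpoint_downweighting(self):
        t = np.linspace(0, 10, 20)
        splines = {"S": fit_smoothing_spline(curve(t, 10 - t, species="S"), 0.0)}
        scheme = ReactionScheme(("S",))
        samples = rates_from_splines(AssayRun("a1"), splines, scheme, t)
        assert samples[0].weight == 0.5 and samples[-1].weight == 0.5
        assert all(s.weight == 1.0 for s in samples[1:-1])


class TestEquilibriumInference:
    def test_linear_exact(self):
        assert infer_equilibrium_species(5.0, 0.286) == pytest.approx(1.43)
        assert infer_equilibrium_species(0.0, 0.286) == 0.0

    def test_ratio_roundtrip(self):
        g6p = 3.7
        f6p = infer_equilibrium_species(g6p, 0.286)
        assert f6p / g6p == pytest.approx(0.286, rel=1e-12)


class TestPreEquilibrationExclusion:
    def make_pair(self, ratio, t=None):
        t = np.linspace(0, 30, 31) if t is None else t
        g = np.full_like(t, 5.0)
        return {"G6P": curve(t, g), "F6P": curve(t, ratio * g, species="F6P")}

    def test_already_equilibrated_nothing_removed(self):
        split = exclude_pre_equilibration(self.make_pair(0.286), keq=0.286)
        assert split.boundary_time == 0.0
        assert split.withheld["G6P"].time.size == 0

    def test_infinite_tolerance_is_identity(self):
        t = np.linspace(0, 30, 31)
        pair = self.make_pair(0.286 * (1 + 2 * np.exp(-t / 5)), t)
        split = exclude_pre_equilibration(pair, keq=0.286, rel_tol=np.inf)
        assert split.retained["G6P"].time.size == t.size

    def test_exponential_relaxation_crossing_time(self):
        """ratio = keq(1 + A e^{-t/tau}): boundary is the first grid time
        past the analytic crossing t* = tau ln(A/rel_tol)."""
        keq, A, tau, tol = 0.286, 2.0, 5.0, 0.05
        t = np.linspace(0, 40, 401)
        pair = self.make_pair(keq * (1 + A * np.exp(-t / tau)), t)
        split = exclude_pre_equilibration(pair, keq=keq, rel_tol=tol)
        t_star = tau * np.log(A / tol)
        assert split.boundary_time == pytest.approx(
            t[np.searchsorted(t, t_star)], abs=1e-9)

    def test_never_met_flags_whole_assay(self):
        with pytest.raises(EquilibrationError):
            exclude_pre_equilibration(self.make_pair(1.5), keq=0.286)

    def test_boundary_monotone_in_tolerance(self):
        keq = 0.286
        t = np.linspace(0, 40, 201)
        pair = self.make_pair(keq * (1 + 2 * np.exp(-t / 5.0)), t)
        bounds = [exclude_pre_equilibration(pair, keq, rel_tol=tol).boundary_time
                  for tol in (0.02, 0.05, 0.2, 1.0)]
        assert all(b1 >= b2 for b1, b2 in zip(bounds, bounds[1:]))


class TestNormalization:
    def make_samples(self, rates, t=None):
        t = np.arange(len(rates), dtype=float) if t is None else t
        return [RateSample(float(tt), {"S": 1.0}, float(r), "S", assay_id="a")
                for tt, r in zip(t, rates)]

    def test_reference_normalizes_itself_to_one(self):
        samples = self.make_samples([2.0] * 10 + [1.0] * 30)
        ref = reference_maximal_rate(samples)
        out = normalize_to_reference(samples, ref)
        assert out[0].rate == pytest.approx(1.0)

    def test_scale_invariance_across_sessions(self):
        base = self.make_samples(np.linspace(2, 0.5, 20))
        doubled = self.make_samples(2 * np.linspace(2, 0.5, 20))
        n1 = normalize_to_reference(base, reference_maximal_rate(base))
        n2 = normalize_to_reference(doubled, reference_maximal_rate(doubled))
        np.testing.assert_allclose([s.rate for s in n1],
                                   [s.rate for s in n2], rtol=1e-12)

    def test_vmax_rescaling(self):
        samples = self.make_samples([1.0, 0.5])
        out = normalize_to_reference(samples, 1.0, vmax_scale=3.551)
        assert out[1].rate == pytest.approx(0.5 * 3.551)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_reference(self.make_samples([1.0]), 0.0)

    def test_session_jitter_removed_by_normalization(self):
        """Two sessions with x2 different Vf but identical kinetics give
        identical normalized datasets (exact, by construction)."""
        rates = np.linspace(2, 0.2, 15)
        s1 = self.make_samples(rates)
        s2 = self.make_samples(rates * 2.0)
        n1 = normalize_to_reference(s1, reference_maximal_rate(s1))
        n2 = normalize_to_reference(s2, reference_maximal_rate(s2))
        np.testing.assert_allclose([a.rate for a in n1],
                                   [a.rate for a in n2], rtol=1e-12)


class TestDiagnosticsAndIO:
    def test_conservation_defect_reported_not_enforced(self):
        t = np.linspace(0, 10, 11)
        curves = {"S": curve(t, 10 - t), "P": curve(t, 0.9 * t, species="P")}
        defect = conservation_defect(curves, ["S", "P"])
        assert defect == pytest.approx(1.0 / 9.5, rel=1e-6)

    def test_tidy_csv_roundtrip(self, tmp_path):
        t = np.linspace(0, 5, 6)
        cs = [curve(t, 1 + t, "a1", "G6P"), curve(t, 2 * t, "a1", "F6P")]
        path = tmp_path / "curves.csv"
        write_tidy_csv(cs, path)
        back = read_tidy_csv(path)
        assert {(c.assay_id, c.species) for c in back} == {("a1", "G6P"),
                                                           ("a1", "F6P")}
        np.testing.assert_allclose(back[0].conc, cs[0].conc)

    def test_rate_sample_frame_roundtrip(self):
        samples = [RateSample(1.0, {"G6P": 2.0, "F6P": 0.5}, 0.3, "F6P",
                              weight=0.5, assay_id="x")]
        back = frame_to_samples(samples_to_frame(samples))
        assert back[0].conc == samples[0].conc
        assert back[0].rate == samples[0].rate
        assert back[0].weight == 0.5

    def test_curve_invariants(self):
        with pytest.raises(ValueError):
            curve([0, 0, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            curve([0, 1, 2], [1, -2, 3])
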