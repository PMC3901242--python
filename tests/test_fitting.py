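"""Global fitting: objective, GA+LM pipeline, errors, truncation scan."""

import numpy as np
import pytest

from nmrkin.fitting import (FreeParameter, GAConfig, GlobalRateFit,
                            goodness_of_fit, load_problem_yaml,
                            truncation_scan)
from nmrkin.pipeline import default_free_parameters, exact_rate_samples
from nmrkin.progress import RateSample, samples_to_frame
from nmrkin.ratelaws import (IrreversibleMM, RateLaw, ReactionScheme,
                             ReversibleHillUni, register_rate_law)
from nmrkin.synthetic import pgi_scenario

PGI_LAW = ReversibleHillUni("G6P", "F6P")
PGI_P = {"vf": 0.3551, "ks": 0.550, "kp": 0.152, "keq": 0.286, "h": 1.0}


class LinearLaw(RateLaw):
    """v = vf * s — registry-pluggable test law with a closed-form fit."""

    name = "linear"
    param_names = ("vf",)

    def __init__(self, substrate="S"):
        super().__init__(ReactionScheme((substrate,)))
        self.substrate = substrate

    def rate(self, concs, params):
        return params["vf"] * np.asarray(concs[self.substrate], dtype=float)

    def params_from(self, p):
        return {"vf": p.vf}


register_rate_law("linear", LinearLaw)


def linear_samples(x, y):
    return [RateSample(float(i), {"S": float(xi)}, float(yi), "S",
                       assay_id="a") for i, (xi, yi) in enumerate(zip(x, y))]


def pgi_samples(noise=0.0, seed=0):
    return exact_rate_samples(pgi_scenario(), PGI_LAW, rate_noise_sd=noise,
                              seed=seed)


class TestResiduals:
    def test_zero_at_generating_parameters(self):
        samples = pgi_samples()
        prob = GlobalRateFit(samples, PGI_LAW, {"vf": 0.3, "ks": 1.0,
                                                "kp": 1.0, "keq": 1.0},
                             {"h": 1.0})
        r = prob.residuals(PGI_P)
        assert np.linalg.norm(r) / np.linalg.norm(prob.v_obs) < 1e-8

    def test_vanishing_vf_leaves_negated_rates(self):
        samples = pgi_samples()
        prob = GlobalRateFit(samples, PGI_LAW, {"vf": 1.0, "ks": 1.0,
                                                "kp": 1.0, "keq": 1.0},
                             {"h": 1.0})
        r = prob.residuals(dict(PGI_P, vf=1e-15))
        np.testing.assert_allclose(r, -prob.v_obs * prob.sqrt_w, atol=1e-10)

    def test_hand_computed_residuals(self):
        """Three samples against the long-hand reversible MM arithmetic."""
        from nmrkin.ratelaws import reversible_hill_uni_rate
        concs = [(1.0, 0.5), (2.0, 0.1), (0.5, 0.143)]
        v_obs = [0.1, 0.2, 0.05]
        samples = [RateSample(float(i), {"G6P": s, "F6P": p}, v, "F6P",
                              assay_id="a")
                   for i, ((s, p), v) in enumerate(zip(concs, v_obs))]
        prob = GlobalRateFit(samples, PGI_LAW, {"vf": 1.0, "ks": 1.0,
                                                "kp": 1.0, "keq": 1.0},
                             {"h": 1.0})
        r = prob.residuals(PGI_P)
        expect = [reversible_hill_uni_rate(s, p, vf=0.3551, ks=0.550,
                                           kp=0.152, keq=0.286) - v
                  for (s, p), v in zip(concs, v_obs)]
        np.testing.assert_allclose(r, expect, rtol=1e-12)

    def test_missing_species_rejected(self):
        s = [RateSample(0.0, {"G6P": 1.0}, 0.1, "G6P", assay_id="a")]
        with pytest.raises(ValueError, match="F6P"):
            GlobalRateFit(s, PGI_LAW, {"vf": 1.0, "ks": 1.0, "kp": 1.0,
                                       "keq": 1.0}, {"h": 1.0})

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            GlobalRateFit([], PGI_LAW, {"vf": 1.0}, {})


class TestFitGlobal:
    def test_single_parameter_closed_form(self):
        """Weighted least squares for v = vf*s has the closed form
        vf = sum(s*v)/sum(s^2)."""
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.1, 3.9, 6.3])
        prob = GlobalRateFit(linear_samples(x, y), LinearLaw("S"),
                             {"vf": 1.0}, {})
        res = prob.fit(seed=0, ga=GAConfig(generations=40))
        assert res.params["vf"] == pytest.approx(np.sum(x * y) / np.sum(x * x),
                                                 rel=1e-8)

    def test_seeded_determinism_bitwise(self):
        samples = pgi_samples(noise=0.03, seed=9)
        free = default_free_parameters(PGI_LAW, samples, {"h": 1.0})
        r1 = GlobalRateFit(samples, PGI_LAW, free, {"h": 1.0}).fit(seed=11)
        r2 = GlobalRateFit(samples, PGI_LAW, free, {"h": 1.0}).fit(seed=11)
        assert r1.params == r2.params  # exact equality

    def test_rss_not_worse_than_ga(self):
        samples = pgi_samples(noise=0.05, seed=2)
        free = default_free_parameters(PGI_LAW, samples, {"h": 1.0})
        prob = GlobalRateFit(samples, PGI_LAW, free, {"h": 1.0})
        res = prob.fit(seed=3)
        assert res.rss <= res.ga_rss + 1e-12

    def test_grid_search_oracle_two_parameters(self):
        """GA+LM agrees with a dense log-grid search + local polish on a
        2-parameter Michaelis-Menten problem."""
        from scipy.optimize import minimize
        law = IrreversibleMM("S")
        rng = np.random.default_rng(4)
        s = rng.uniform(0.05, 8.0, 60)
        v = 1.7 * s / (0.6 + s) * (1 + rng.normal(0, 0.04, s.size))
        samples = [RateSample(float(i), {"S": float(si)}, float(vi), "S",
                              assay_id="a") for i, (si, vi) in enumerate(zip(s, v))]
        prob = GlobalRateFit(samples, law,
                             [FreeParameter("vf", 1.0, 0.01, 100.0),
                              FreeParameter("ks", 1.0, 0.01, 100.0)], {})
        res = prob.fit(seed=0)
        # independent oracle: brute force over a 200x200 log lattice
        g = np.logspace(-2, 2, 200)
        VF, KS = np.meshgrid(g, g, indexing="ij")
        rss = ((VF[..., None] * s / (KS[..., None] + s) - v) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)

        def f(z):
            vf, ks = np.exp(z)
            return np.sum((vf * s / (ks + s) - v) ** 2)

        polished = minimize(f, np.log([g[i], g[j]]), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14}).x
        vf_o, ks_o = np.exp(polished)
        assert res.params["vf"] == pytest.approx(vf_o, rel=1e-4)
        assert res.params["ks"] == pytest.approx(ks_o, rel=1e-4)

    def test_normalization_equivariance(self):
        """Rates x c -> fitted vf x c, other parameters unchanged."""
        base = pgi_samples(noise=0.02, seed=6)
        c = 3.7
        scaled = [RateSample(s.time, s.conc, s.rate * c, s.source_species,
                             s.weight, s.assay_id) for s in base]
        f1 = default_free_parameters(PGI_LAW, base, {"h": 1.0})
        f2 = default_free_parameters(PGI_LAW, scaled, {"h": 1.0})
        r1 = GlobalRateFit(base, PGI_LAW, f1, {"h": 1.0}).fit(seed=1)
        r2 = GlobalRateFit(scaled, PGI_LAW, f2, {"h": 1.0}).fit(seed=1)
        assert r2.params["vf"] == pytest.approx(c * r1.params["vf"], rel=1e-6)
        for name in ("ks", "kp", "keq"):
            assert r2.params[name] == pytest.approx(r1.params[name], rel=1e-6)

    def test_summary_and_json(self, tmp_path):
        samples = pgi_samples()
        free = default_free_parameters(PGI_LAW, samples, {"h": 1.0})
        res = GlobalRateFit(samples, PGI_LAW, free, {"h": 1.0}).fit(seed=0)
        txt = res.summary()
        assert "keq" in txt and "R^2" in txt and "(fixed)" in txt
        out = tmp_path / "fit.json"
        res.to_json(out)
        import json
        payload = json.loads(out.read_text())
        assert payload["params"]["keq"] == pytest.approx(res.params["keq"])


class TestParameterErrors:
    def test_linear_regression_closed_form_sem(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0.5, 5, 40)
        y = 2.0 * x + rng.normal(0, 0.3, x.size)
        prob = GlobalRateFit(linear_samples(x, y), LinearLaw("S"),
                             {"vf": 1.0}, {})
        res = prob.fit(seed=0, ga=GAConfig(generations=40))
        sigma2 = res.rss / (x.size - 1)
        assert res.bse["vf"] == pytest.approx(
            np.sqrt(sigma2 / np.sum(x ** 2)), rel=1e-4)

    def test_zero_residuals_zero_sem(self):
        x = np.array([1.0, 2.0, 4.0])
        prob = GlobalRateFit(linear_samples(x, 3.0 * x), LinearLaw("S"),
                             {"vf": 1.0}, {})
        res = prob.fit(seed=0, ga=GAConfig(generations=40))
        assert res.bse["vf"] == pytest.approx(0.0, abs=1e-8)

    def test_duplication_shrinks_sem_by_dof_formula(self):
        """Doubling every sample at identical per-point RSS rescales the
        SEM by sqrt((n-p)/(2n-p)), per cov = (JtJ)^-1 RSS/(n-p)."""
        rng = np.random.default_rng(8)
        x = np.linspace(0.5, 5, 25)
        y = 2.0 * x + rng.normal(0, 0.2, x.size)
        p1 = GlobalRateFit(linear_samples(x, y), LinearLaw("S"),
                           {"vf": 1.0}, {})
        r1 = p1.fit(seed=0, ga=GAConfig(generations=40))
        x2, y2 = np.tile(x, 2), np.tile(y, 2)
        p2 = GlobalRateFit(linear_samples(x2, y2), LinearLaw("S"),
                           {"vf": 1.0}, {})
        r2 = p2.fit(seed=0, ga=GAConfig(generations=40))
        n, p = x.size, 1
        assert r2.bse["vf"] == pytest.approx(
            r1.bse["vf"] * np.sqrt((n - p) / (2 * n - p)), rel=1e-3)

    def test_invariance_under_reordering(self):
        samples = pgi_samples(noise=0.03, seed=3)
        free = default_free_parameters(PGI_LAW, samples, {"h": 1.0})
        r1 = GlobalRateFit(samples, PGI_LAW, free, {"h": 1.0}).fit(seed=2)
        r2 = GlobalRateFit(samples[::-1], PGI_LAW, free, {"h": 1.0}).fit(seed=2)
        for k in r1.params:
            assert r1.bse[k] == pytest.approx(r2.bse[k], rel=1e-5)

    def test_rank_deficient_flagged_infinite(self):
        """Two perfectly collinear parameters get infinite SEM, not
        silent numbers."""

        class TwoVf(RateLaw):
            name = "twovf"
            param_names = ("a", "b")

            def __init__(self):
                super().__init__(ReactionScheme(("S",)))

            def rate(self, concs, params):
                return (params["a"] * params["b"]) * np.asarray(concs["S"])

            def params_from(self, p):  # pragma: no cover
                return {}

        x = np.array([1.0, 2.0, 3.0, 4.0])
        prob = GlobalRateFit(linear_samples(x, 2 * x), TwoVf(),
                             {"a": 1.0, "b": 1.0}, {})
        res = prob.fit(seed=0, ga=GAConfig(generations=30))
        assert np.isinf(res.bse["a"]) or np.isinf(res.bse["b"])


class TestGoodnessOfFit:
    def test_perfect_fit_is_one(self):
        assert goodness_of_fit(0.0, np.array([1.0, 2.0, 3.0])) == 1.0

    def test_constant_model_at_mean_is_zero(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        tss = float(np.sum((y - y.mean()) ** 2))
        assert goodness_of_fit(tss, y) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            goodness_of_fit(0.1, np.ones(5))

    def test_pfk_long_course_noise_floor(self):
        """Run-to-completion PFK rates with 5% multiplicative noise fit
        at R^2 >= 0.96, the scale of real progress-curve fits."""
        from nmrkin.ratelaws import IrreversibleHillBi
        from nmrkin.synthetic import pfk_scenario
        law = IrreversibleHillBi("F6P", "ATP", "PEP")
        samples = exact_rate_samples(pfk_scenario(t_max=150.0), law,
                                     rate_noise_sd=0.05, seed=13)
        free = default_free_parameters(law, samples)
        res = GlobalRateFit(samples, law, free, {}).fit(seed=13)
        assert res.rsquared >= 0.96


@pytest.fixture(scope="module")
def pgi_problem():
    samples = pgi_samples(noise=0.02, seed=5)
    free = default_free_parameters(PGI_LAW, samples, {"h": 1.0})
    return GlobalRateFit(samples, PGI_LAW, free, {"h": 1.0})


class TestTruncationScan:
    def test_step_zero_equals_baseline(self, pgi_problem):
        scan = truncation_scan(pgi_problem, 2, seed=5)
        base = pgi_problem.fit(seed=5)
        assert scan.steps[0].result.params == base.params

    def test_removed_counts_strictly_increase(self, pgi_problem):
        scan = truncation_scan(pgi_problem, 4, seed=5)
        removed = [s.removed_total for s in scan.steps]
        assert removed == sorted(set(removed))
        n_assays = len(np.unique(pgi_problem.assay_ids))
        assert removed[1] - removed[0] == n_assays

    def test_both_dof_conventions_reported(self, pgi_problem):
        scan = truncation_scan(pgi_problem, 3, seed=5)
        for st in scan.steps[1:]:
            for name in st.result.params:
                # original-dof errors are the rescaled ones shrunk by
                # sqrt((n_k - p)/(n_0 - p)) < 1
                assert st.bse_original_dof[name] <= st.bse_rescaled_dof[name]

    def test_max_remove_bounded_by_shortest_assay(self, pgi_problem):
        with pytest.raises(ValueError):
            truncation_scan(pgi_problem, 10**6, seed=0)


class TestYAMLProblem:
    def test_load_and_fit(self, tmp_path):
        samples = pgi_samples()
        df = samples_to_frame(samples)
        data_path = tmp_path / "rates.csv"
        df.to_csv(data_path, index=False)
        yaml_path = tmp_path / "problem.yaml"
        yaml_path.write_text(f"""
law: {{law: reversible_hill_uni, substrate: G6P, product: F6P}}
data: {data_path}
free:
  vf: {{init: 1.0, lo: 0.001, hi: 10}}
  ks: {{init: 1.0}}
  kp: {{init: 1.0}}
  keq: {{init: 1.0}}
fixed:
  h: 1.0
""")
        prob = load_problem_yaml(yaml_path)
        res = prob.fit(seed=0)
        assert res.params["keq"] == pytest.approx(0.286, rel=0.01)
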