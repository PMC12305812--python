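import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ifcea.sensitivity import (
    CEACCurve,
    ParamDistribution,
    PSAResult,
    ceac,
    fit_beta_from_ci,
    fit_gamma_from_ci,
    one_way,
    run_psa,
)


class TestGammaFit:
    def test_mean_recovered_exactly(self):
        shape, scale = fit_gamma_from_ci(0.17, 0.13, 0.21)
        assert shape * scale == pytest.approx(0.17, abs=1e-9)

    def test_degenerate_ci_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_from_ci(0.17, 0.17, 0.17)

    def test_sample_mean_within_3se(self):
        shape, scale = fit_gamma_from_ci(0.17, 0.13, 0.21)
        rng = np.random.default_rng(0)
        draws = rng.gamma(shape, scale, size=100_000)
        se = np.sqrt(shape) * scale / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.17) <= 3 * se


class TestBetaFit:
    def test_symmetric_case(self):
        a, b = fit_beta_from_ci(0.5, 0.4, 0.6)
        assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("mean,lo,hi", [(0.052, 0.034, 0.076), (0.149, 0.101, 0.21)])
    def test_mean_identity(self, mean, lo, hi):
        a, b = fit_beta_from_ci(mean, lo, hi)
        assert a / (a + b) == pytest.approx(mean, abs=1e-9)

    def test_infeasible_variance_rejected(self):
        with pytest.raises(ValueError, match="no beta"):
            fit_beta_from_ci(0.01, 0.001, 0.999)

    def test_sample_mean_within_3se(self):
        a, b = fit_beta_from_ci(0.052, 0.034, 0.076)
        rng = np.random.default_rng(1)
        draws = rng.beta(a, b, size=100_000)
        sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        assert abs(draws.mean() - 0.052) <= 3 * sd / np.sqrt(len(draws))


def toy_pipeline(params):
    """Analytic stand-in pipeline: cost scales with x, effect with y."""
    d_cost = params["x"] * 540.0
    d_eff = 20.0 * params["y"]
    return d_cost, d_eff, d_cost / -d_eff


def toy_icer(params):
    return toy_pipeline(params)[2]


BASE = {"x": 0.17, "y": 1.0}


class TestOneWay:
    def test_zero_width_bounds_zero_swing(self):
        res = one_way(toy_icer, BASE, {"x": (0.17, 0.17), "y": (0.5, 1.5)})
        row = res.table.set_index("parameter")
        assert row.loc["x", "swing"] == 0.0

    def test_swing_matches_direct_recomputation(self):
        bounds = {"x": (0.136, 0.204), "y": (0.8, 1.2)}
        res = one_way(toy_icer, BASE, bounds)
        for name, (lo, hi) in bounds.items():
            expected = abs(toy_icer({**BASE, name: hi}) - toy_icer({**BASE, name: lo}))
            got = res.table.set_index("parameter").loc[name, "swing"]
            assert got == pytest.approx(expected, rel=1e-12)

    def test_sorted_by_swing_and_complete(self):
        bounds = {"x": (0.136, 0.204), "y": (0.99, 1.01)}
        res = one_way(toy_icer, BASE, bounds)
        assert list(res.table["swing"]) == sorted(res.table["swing"], reverse=True)
        assert sorted(res.parameters()) == sorted(bounds)

    def test_non_bracketing_bounds_rejected(self):
        with pytest.raises(ValueError, match="bracket"):
            one_way(toy_icer, BASE, {"x": (0.2, 0.3)})


class TestPSA:
    def fixed_dists(self):
        return [
            ParamDistribution("x", "fixed", 0.17),
            ParamDistribution("y", "fixed", 1.0),
        ]

    def test_all_fixed_equals_deterministic(self):
        res = run_psa(toy_pipeline, BASE, self.fixed_dists(), n_runs=10, seed=0)
        det = toy_icer(BASE)
        assert np.allclose(res.samples["icer"], det)
        assert res.median_icer == pytest.approx(det)

    def test_seed_determinism(self):
        dists = [
            ParamDistribution("x", "gamma", 0.17, 0.13, 0.21),
            ParamDistribution("y", "beta", 0.5, 0.4, 0.6),
        ]
        a = run_psa(toy_pipeline, BASE, dists, n_runs=40, seed=5)
        b = run_psa(toy_pipeline, BASE, dists, n_runs=40, seed=5)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_vanishing_spread_recovers_deterministic(self):
        """As cost CIs shrink, the PSA median converges on the base ICER."""
        dists = [
            ParamDistribution("x", "gamma", 0.17, 0.17 - 1e-7, 0.17 + 1e-7),
            ParamDistribution("y", "fixed", 1.0),
        ]
        res = run_psa(toy_pipeline, BASE, dists, n_runs=50, seed=2)
        assert res.median_icer == pytest.approx(toy_icer(BASE), rel=1e-5)

    def test_failed_runs_recorded_and_excluded(self):
        def flaky(params):
            if params["y"] < 0.5:
                raise ValueError("infeasible draw")
            return toy_pipeline(params)

        dists = [
            ParamDistribution("x", "fixed", 0.17),
            ParamDistribution("y", "beta", 0.5, 0.3, 0.7),
        ]
        res = run_psa(flaky, BASE, dists, n_runs=60, seed=3)
        assert len(res.failures) > 0
        assert len(res.samples) + len(res.failures) == 60
        assert "infeasible" in res.failures[0]["reason"]


def psa_from_samples(d_cost, d_eff):
    n = len(d_cost)
    samples = pd.DataFrame(
        {"run": range(n), "delta_cost": d_cost, "delta_effect": d_eff, "icer": 0.0}
    )
    med = float(samples["icer"].median())
    return PSAResult(samples, med, (med, med), n, 100, 0)


class TestCEAC:
    def test_zero_wtp_all_costly(self):
        psa = psa_from_samples([10.0, 20.0, 5.0], [1.0, 2.0, 3.0])
        curve = ceac(psa, [0.0])
        assert curve.p_cost_effective[0] == 0.0

    def test_large_wtp_all_effective(self):
        psa = psa_from_samples([10.0, 20.0, 5.0], [1.0, 2.0, 3.0])
        curve = ceac(psa, [1e9])
        assert curve.p_cost_effective[0] == 1.0

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(7)
        psa = psa_from_samples(rng.normal(90, 10, 200), rng.gamma(5, 2, 200))
        grid = np.linspace(0, 30, 21)
        curve = ceac(psa, grid)
        for lam, p in zip(grid, curve.p_cost_effective):
            count = sum(
                1
                for c, e in zip(psa.samples["delta_cost"], psa.samples["delta_effect"])
                if lam * e - c >= 0
            )
            assert p == count / 200

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-100, max_value=200),
                st.floats(min_value=0, max_value=50),
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_monotone_for_nonnegative_gains(self, pairs):
        d_cost = [c for c, _ in pairs]
        d_eff = [e for _, e in pairs]
        curve = ceac(psa_from_samples(d_cost, d_eff), np.linspace(0, 50, 26))
        assert np.all(np.diff(curve.p_cost_effective) >= -1e-12)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            CEACCurve(np.array([0.0, 1.0]), np.array([0.5, 1.5]))
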