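"""Tornado analysis, distribution fitting, Monte Carlo PSA and CEACs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from chwcea import (
    InputError,
    ParameterRole,
    ParameterSpec,
    ceac,
    fit_distribution,
    one_way_sa,
    run_psa,
)
from conftest import make_model


class RatioModel:
    """Toy two-parameter model: cost and LYG are the parameters themselves."""

    def __init__(self, cost: float, lyg: float):
        self.means = {"cost": cost, "lyg": lyg}

    def evaluate(self, values):
        cost = np.asarray(values.get("cost", self.means["cost"]), dtype=float)
        lyg = np.asarray(values.get("lyg", self.means["lyg"]), dtype=float)
        return np.broadcast_arrays(cost, lyg)

    def specs(self, **kwargs):
        return [
            ParameterSpec("cost", ParameterRole.COST_INPUT, self.means["cost"], **kwargs),
            ParameterSpec("lyg", ParameterRole.LYG, self.means["lyg"], **kwargs),
        ]


class TestOneWaySA:
    def test_lyg_bounds_are_reciprocal(self):
        """ICER is inversely proportional to the LYG parameter."""
        model = RatioModel(cost=999.9 * 471, lyg=471.0)
        entries = one_way_sa(model, model.specs())
        lyg_entry = next(e for e in entries if e.parameter == "lyg")
        assert lyg_entry.icer_low == pytest.approx(999.9 / 0.7, rel=1e-9)
        assert lyg_entry.icer_high == pytest.approx(999.9 / 1.3, rel=1e-9)
        assert lyg_entry.range == pytest.approx(999.9 / 0.7 - 999.9 / 1.3, rel=1e-9)

    def test_ignored_parameter_has_zero_range(self):
        model = RatioModel(cost=1000.0, lyg=10.0)
        specs = model.specs() + [
            ParameterSpec("unused", ParameterRole.USEFUL_LIFE, 10.0)
        ]
        entries = one_way_sa(model, specs)
        unused = next(e for e in entries if e.parameter == "unused")
        assert unused.range == 0.0

    def test_zero_fraction_collapses_all_ranges(self):
        model = RatioModel(cost=1000.0, lyg=10.0)
        entries = one_way_sa(model, model.specs(dsa_fraction=0.0))
        assert all(e.range == 0.0 for e in entries)

    def test_sorted_by_descending_range_then_name(self):
        model = RatioModel(cost=1000.0, lyg=10.0)
        entries = one_way_sa(model, model.specs())
        ranges = [e.range for e in entries]
        assert ranges == sorted(ranges, reverse=True)

    def test_undefined_bound_flagged_and_warned(self):
        model = RatioModel(cost=1000.0, lyg=10.0)
        specs = [ParameterSpec("lyg", ParameterRole.LYG, 10.0, dsa_fraction=1.0)]
        with pytest.warns(UserWarning, match="lyg"):
            entries = one_way_sa(model, specs)
        assert entries[0].undefined is True
        assert np.isnan(entries[0].range)

    def test_widest_bar_is_lyg_for_every_district(self, district):
        """Cost-effectiveness is most sensitive to the LYG estimate."""
        model = make_model(district)
        entries = one_way_sa(model, model.parameter_specs(dsa_fraction=0.30))
        assert entries[0].parameter == "lyg"


class TestFitDistribution:
    def test_gamma_moment_matching(self):
        spec = ParameterSpec("c", ParameterRole.COST_INPUT, 100.0, psa_fraction=0.10)
        fit = fit_distribution(spec)
        assert fit.family == "gamma"
        assert fit.sd == pytest.approx(5.1020, abs=5e-5)
        assert fit.params["shape"] == pytest.approx(384.16, abs=0.005)
        assert fit.params["scale"] == pytest.approx(0.26031, abs=5e-6)

    def test_beta_moment_matching(self):
        spec = ParameterSpec("p", ParameterRole.OVERHEAD_PCT, 0.15, psa_fraction=0.10)
        fit = fit_distribution(spec)
        assert fit.family == "beta"
        assert fit.sd == pytest.approx(0.0076531, abs=5e-8)
        assert fit.params["alpha"] == pytest.approx(326.4, abs=0.1)
        assert fit.params["beta"] == pytest.approx(1849.5, abs=0.1)

    def test_normal_fit(self):
        spec = ParameterSpec("lyg", ParameterRole.LYG, 471.0, psa_fraction=0.10)
        fit = fit_distribution(spec)
        assert fit.family == "normal"
        assert fit.sd == pytest.approx(24.03, abs=0.005)

    @given(
        mean=st.floats(1e-3, 1e7),
        fraction=st.floats(0.01, 0.5),
        role=st.sampled_from([ParameterRole.COST_INPUT, ParameterRole.LYG]),
    )
    def test_fitted_moments_match_targets(self, mean, fraction, role):
        """Moment matching reproduces mean and sd to near machine precision."""
        fit = fit_distribution(
            ParameterSpec("x", role, mean, psa_fraction=fraction)
        )
        if fit.family == "gamma":
            dist = stats.gamma(a=fit.params["shape"], scale=fit.params["scale"])
        else:
            dist = stats.norm(loc=fit.mean, scale=fit.sd)
        assert dist.mean() == pytest.approx(mean, rel=1e-10)
        assert dist.std() == pytest.approx(fraction * mean / 1.96, rel=1e-10)

    @given(mean=st.floats(0.005, 0.995), fraction=st.floats(0.01, 0.3))
    def test_beta_moments_match_targets(self, mean, fraction):
        fit = fit_distribution(
            ParameterSpec(
                "p", ParameterRole.OVERHEAD_PCT, mean, psa_fraction=fraction
            )
        )
        dist = stats.beta(a=fit.params["alpha"], b=fit.params["beta"])
        assert dist.mean() == pytest.approx(mean, rel=1e-10)
        assert dist.std() == pytest.approx(fraction * mean / 1.96, rel=1e-10)

    def test_beta_infeasible_sd_rejected(self):
        spec = ParameterSpec(
            "p", ParameterRole.OVERHEAD_PCT, 0.999, psa_fraction=0.5
        )
        with pytest.raises(InputError, match="infeasible"):
            fit_distribution(spec)

    def test_zero_fraction_is_degenerate(self):
        fit = fit_distribution(
            ParameterSpec("c", ParameterRole.COST_INPUT, 50.0, psa_fraction=0.0)
        )
        assert fit.family == "degenerate"
        draws = fit.rvs(5, np.random.default_rng(0))
        assert np.all(draws == 50.0)

    def test_structural_parameter_has_no_family(self):
        spec = ParameterSpec("r", ParameterRole.DISCOUNT_RATE, 0.03)
        assert spec.family is None
        with pytest.raises(InputError):
            fit_distribution(spec)


class TestRunPSA:
    def test_identical_seeds_give_identical_draws(self):
        model = RatioModel(cost=1e6, lyg=500.0)
        a = run_psa(model, model.specs(), n=200, seed=42)
        b = run_psa(model, model.specs(), n=200, seed=42)
        assert np.array_equal(a.cost, b.cost)
        assert np.array_equal(a.lyg, b.lyg)

    def test_different_seeds_differ(self):
        model = RatioModel(cost=1e6, lyg=500.0)
        a = run_psa(model, model.specs(), n=200, seed=1)
        b = run_psa(model, model.specs(), n=200, seed=2)
        assert not np.array_equal(a.cost, b.cost)

    def test_zero_variance_collapses_to_baseline(self, district):
        model = make_model(district)
        baseline_cost, baseline_lyg = model.baseline()
        psa = run_psa(
            model, model.parameter_specs(psa_fraction=0.0), n=50, seed=0
        )
        assert np.allclose(psa.cost, baseline_cost, rtol=1e-12)
        assert np.allclose(psa.lyg, baseline_lyg, rtol=1e-12)

    def test_draw_means_near_spec_means(self):
        """Monte Carlo consistency: sample means within 3 standard errors."""
        model = RatioModel(cost=1e6, lyg=500.0)
        specs = model.specs(psa_fraction=0.10)
        n = 5000
        psa = run_psa(model, specs, n=n, seed=7)
        for mean, draws in ((1e6, psa.cost), (500.0, psa.lyg)):
            se = (0.10 * mean / 1.96) / np.sqrt(n)
            assert abs(draws.mean() - mean) < 3 * se

    def test_mean_icer_matches_quadrature_oracle(self):
        """MC mean ICER agrees with numerical integration on the toy model.

        Cost ~ gamma and LYG ~ normal are independent, so
        E[C/E] = E[C] * E[1/E]; E[1/E] is computed by quadrature against
        the normal density.
        """
        cost_mean, lyg_mean, f = 1e6, 500.0, 0.10
        model = RatioModel(cost=cost_mean, lyg=lyg_mean)
        sd = f * lyg_mean / 1.96
        expected = cost_mean * integrate.quad(
            lambda e: stats.norm.pdf(e, lyg_mean, sd) / e,
            lyg_mean - 8 * sd,
            lyg_mean + 8 * sd,
        )[0]
        n = 40_000
        psa = run_psa(model, model.specs(psa_fraction=f), n=n, seed=11)
        mc_mean = np.nanmean(psa.icer)
        mc_se = np.nanstd(psa.icer) / np.sqrt(n)
        assert abs(mc_mean - expected) < 4 * mc_se

    def test_nonpositive_lyg_draws_counted_not_dropped(self):
        model = RatioModel(cost=100.0, lyg=0.05)
        # huge relative uncertainty pushes some normal draws below zero
        specs = [
            ParameterSpec("cost", ParameterRole.COST_INPUT, 100.0),
            ParameterSpec("lyg", ParameterRole.LYG, 0.05, psa_fraction=3.0),
        ]
        psa = run_psa(model, specs, n=2000, seed=3)
        assert psa.n_nonpositive_lyg > 0
        assert len(psa.cost) == 2000
        assert np.isnan(psa.icer[psa.lyg <= 0]).all()


class TestCEAC:
    def test_step_function_for_degenerate_draws(self):
        model = RatioModel(cost=1000.0, lyg=10.0)  # ICER 100
        psa = run_psa(model, model.specs(psa_fraction=0.0), n=20, seed=0)
        points = ceac(psa, [50.0, 100.0, 150.0])
        assert [p.probability for p in points] == [0.0, 1.0, 1.0]

    def test_zero_wtp_with_positive_costs(self):
        model = RatioModel(cost=1000.0, lyg=10.0)
        psa = run_psa(model, model.specs(), n=100, seed=0)
        assert ceac(psa, [0.0])[0].probability == 0.0

    def test_monotone_and_bounded(self, district):
        model = make_model(district)
        psa = run_psa(model, model.parameter_specs(), n=1000, seed=5)
        grid = np.linspace(0.0, 4 * district.gdp_per_capita, 41)
        probs = [p.probability for p in ceac(psa, grid)]
        assert all(0.0 <= p <= 1.0 for p in probs)
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_empty_grid_rejected(self):
        model = RatioModel(cost=1000.0, lyg=10.0)
        psa = run_psa(model, model.specs(), n=10, seed=0)
        with pytest.raises(InputError):
            ceac(psa, [])

    def test_nonincreasing_grid_rejected(self):
        model = RatioModel(cost=1000.0, lyg=10.0)
        psa = run_psa(model, model.specs(), n=10, seed=0)
        with pytest.raises(InputError):
            ceac(psa, [10.0, 5.0])
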