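"""One-way sweeps, probabilistic draws, reproducibility and CEAC."""

import numpy as np
import pytest

from strokecea import fixtures
from strokecea.config_io import ConfigError, DistributionSpec, StateDistribution
from strokecea.economics import compare_arms, inmb
from strokecea.sensitivity import (
    PSAResult,
    beta_from_moments,
    ceac,
    gamma_from_moments,
    one_way_tornado,
    perturb_parameter,
    run_psa,
    sample_parameter_set,
)


class TestPerturb:
    def test_factor_one_changes_nothing(self, base_spec):
        assert perturb_parameter(base_spec, "utilities.mRS4", 1.0) == base_spec

    def test_probability_component_renormalises_the_rest(self, base_spec):
        spec = perturb_parameter(base_spec, "arms.alteplase.dist90.mRS01", 0.8)
        probs = spec.arm_by_name("alteplase").dist90_no_evt.probs
        base = base_spec.arm_by_name("alteplase").dist90_no_evt.probs
        assert probs[0] == pytest.approx(0.348 * 0.8, abs=1e-12)
        scale = (1 - 0.2784) / (1 - 0.348)
        for i in range(1, 5):
            assert probs[i] == pytest.approx(base[i] * scale, abs=1e-12)
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)

    def test_cost_scales_exactly(self, base_spec):
        spec = perturb_parameter(base_spec, "annual_costs.mRS4", 1.2)
        assert spec.annual_costs.values[2] == pytest.approx(40_000.0 * 1.2, abs=0)

    def test_utility_capped_at_one(self, base_spec):
        spec = perturb_parameter(base_spec, "utilities.mRS01", 1.2)
        assert spec.utilities.values[0] == 1.0

    def test_unknown_parameter_is_an_error(self, base_spec):
        with pytest.raises(ConfigError, match="unknown"):
            perturb_parameter(base_spec, "arms.alteplase.no_such_knob", 1.2)

    def test_cannot_renormalise_around_certainty(self):
        spec, _ = fixtures.closed_form_model(p=0.1, u=0.8, c=100.0)
        with pytest.raises(ConfigError, match="renormalise"):
            perturb_parameter(spec, "arms.comparator.dist90.mRS01", 0.8)

    def test_base_spec_never_mutated(self, base_spec):
        snapshot = base_spec.model_copy(deep=True)
        perturb_parameter(base_spec, "arms.tenecteplase.dist90.dead", 1.2)
        assert base_spec == snapshot


class TestTornado:
    def test_rows_sorted_by_width_and_anchored_at_base(self, base_spec):
        rows = one_way_tornado(base_spec, 50_000.0)
        widths = [r.width for r in rows]
        assert widths == sorted(widths, reverse=True)
        base = compare_arms(base_spec)
        expected = inmb(base.delta_cost, base.delta_qalys, 50_000.0)
        assert all(r.base_inmb == pytest.approx(expected, abs=1e-9) for r in rows)

    def test_uninfluential_parameter_gives_zero_width(self, base_spec):
        # EVT cost is irrelevant when nobody is EVT-eligible
        from strokecea.config_io import OWSAConfig

        spec = base_spec.model_copy(deep=True)
        spec.owsa = OWSAConfig.model_validate(
            {"parameters": [{"id": "evt_cost",
                             "targets": ["arms.tenecteplase.evt_cost",
                                         "arms.alteplase.evt_cost"]}]}
        )
        (row,) = one_way_tornado(spec, 50_000.0)
        assert row.width == pytest.approx(0.0, abs=1e-9)

    def test_shared_parameter_cancels_between_identical_arms(self):
        from strokecea.config_io import OWSAConfig

        spec, _ = fixtures.closed_form_model(p=0.1, u=0.8, c=2_000.0)
        spec.owsa = OWSAConfig.model_validate(
            {"parameters": ["utilities.mRS01", "annual_costs.mRS01"]}
        )
        for row in one_way_tornado(spec, 50_000.0):
            assert row.width == pytest.approx(0.0, abs=1e-9)

    def test_grouped_both_arm_sweep_moves_both_components(self, base_spec):
        from strokecea.config_io import OWSAConfig

        spec = base_spec.model_copy(deep=True)
        spec.owsa = OWSAConfig.model_validate(
            {"parameters": [{
                "id": "mrs01_both",
                "targets": [
                    "arms.alteplase.dist90.mRS01",
                    "arms.tenecteplase.dist90.mRS01",
                ],
            }]}
        )
        (grouped,) = one_way_tornado(spec, 50_000.0)
        singles = one_way_tornado(base_spec, 50_000.0)
        single = next(r for r in singles if r.param_id == "mrs01_90d_tenecteplase")
        # correlated variation of near-identical proportions partly cancels
        assert grouped.width < single.width


class TestMomentMatching:
    def test_beta_reproduces_mean_and_symmetry(self):
        a, b = beta_from_moments(0.5, 0.1)
        assert a == pytest.approx(b)
        assert a / (a + b) == pytest.approx(0.5, abs=1e-12)
        a, b = beta_from_moments(0.369, 0.03)
        assert a / (a + b) == pytest.approx(0.369, abs=1e-12)

    def test_beta_infeasible_se_rejected(self):
        with pytest.raises(ConfigError, match="infeasible"):
            beta_from_moments(0.5, 0.6)

    def test_gamma_reproduces_moments(self):
        shape, scale = gamma_from_moments(12_000.0, 1_224.5)
        assert shape * scale == pytest.approx(12_000.0, abs=1e-9)
        assert np.sqrt(shape) * scale == pytest.approx(1_224.5, abs=1e-9)


class TestSampling:
    def test_all_fixed_returns_identical_spec(self, base_spec):
        spec = base_spec.model_copy(deep=True)
        spec.psa.distributions = [
            DistributionSpec(target=d.target, kind="fixed")
            for d in spec.psa.distributions
        ]
        drawn = sample_parameter_set(spec, np.random.default_rng(0))
        assert drawn == spec

    def test_dirichlet_draw_stays_on_simplex(self, base_spec):
        drawn = sample_parameter_set(base_spec, np.random.default_rng(42))
        for arm in drawn.arms:
            assert sum(arm.dist90_no_evt.probs) == pytest.approx(1.0, abs=1e-12)
            assert min(arm.dist90_no_evt.probs) >= 0.0

    def test_sampled_spec_validates(self, base_spec):
        from strokecea.config_io import validate_model

        for seed in range(20):
            drawn = sample_parameter_set(base_spec, np.random.default_rng(seed))
            assert validate_model(drawn) == []

    def test_infeasible_se_names_the_parameter(self, base_spec):
        spec = base_spec.model_copy(deep=True)
        spec.psa.distributions = [
            DistributionSpec(target="utilities.mRS01", kind="beta", se=0.9)
        ]
        with pytest.raises(ConfigError, match="infeasible"):
            sample_parameter_set(spec, np.random.default_rng(0))


class TestRunPSA:
    def test_single_all_fixed_draw_equals_base_case(self, base_spec, base_result):
        spec = base_spec.model_copy(deep=True)
        spec.psa.distributions = [
            DistributionSpec(target=d.target, kind="fixed")
            for d in spec.psa.distributions
        ]
        psa = run_psa(spec, n=1, seed=99)
        assert psa.delta_costs[0] == pytest.approx(base_result.delta_cost, abs=1e-9)
        assert psa.delta_effects[0] == pytest.approx(base_result.delta_qalys, abs=1e-9)

    def test_same_seed_reproduces_bit_identically(self, base_spec):
        a = run_psa(base_spec, n=60, seed=7)
        b = run_psa(base_spec, n=60, seed=7)
        assert np.array_equal(a.delta_costs, b.delta_costs)
        assert np.array_equal(a.delta_effects, b.delta_effects)

    def test_growing_n_preserves_earlier_draws(self, base_spec):
        short = run_psa(base_spec, n=20, seed=5)
        long = run_psa(base_spec, n=40, seed=5)
        assert np.array_equal(short.delta_costs, long.delta_costs[:20])

    def test_mean_increment_matches_analytic_expectation(self):
        # two-state closed-form model: intervention utility ~ beta(mean 0.8),
        # comparator fixed at 0.7 -> E[dE] = (0.8 - 0.7) x geometric series
        spec, _ = fixtures.closed_form_model(p=0.1, u=0.8, c=0.0, horizon=10)
        spec.utilities.values = [0.8, 0.7, 0.0, 0.0, 0.0]
        rows = [list(r) for r in spec.t_annual.rows]
        rows[1] = [0.0, 0.9, 0.0, 0.0, 0.1]
        spec.t_annual.rows = rows
        spec.arms[0].dist90_no_evt = StateDistribution.model_validate([0, 1, 0, 0, 0])
        spec.psa.distributions = [
            DistributionSpec(target="utilities.mRS01", kind="beta", mean=0.8, se=0.05)
        ]
        n = 2_000
        psa = run_psa(spec, n=n, seed=11)
        series = (1 - 0.9**10) / 0.1
        analytic = 0.1 * series
        mc_se = psa.delta_effects.std(ddof=1) / np.sqrt(n)
        assert abs(psa.delta_effects.mean() - analytic) < 3 * mc_se


class TestCEAC:
    def test_dominant_draws_are_always_cost_effective(self):
        psa = PSAResult(
            seed=0, n=3,
            delta_costs=np.array([-10.0, -5.0, -1.0]),
            delta_effects=np.array([0.1, 0.2, 0.3]),
            distributions=[],
        )
        curve = ceac(psa, [1_000.0, 50_000.0, 100_000.0])
        assert np.all(curve.probabilities == 1.0)

    def test_single_draw_switches_at_its_own_icer(self):
        psa = PSAResult(
            seed=0, n=1,
            delta_costs=np.array([1_000.0]),
            delta_effects=np.array([0.1]),
            distributions=[],
        )
        curve = ceac(psa, [5_000.0, 9_999.0, 10_001.0, 50_000.0])
        assert list(curve.probabilities) == [0.0, 0.0, 1.0, 1.0]

    def test_symmetric_cloud_sits_near_one_half(self):
        rng = np.random.default_rng(3)
        dc = rng.normal(0, 1_000, 4_000)
        de = rng.normal(0, 0.1, 4_000)
        psa = PSAResult(seed=3, n=4_000, delta_costs=dc, delta_effects=de,
                        distributions=[])
        curve = ceac(psa, [50_000.0])
        assert curve.probabilities[0] == pytest.approx(0.5, abs=0.03)

    def test_equals_mean_positive_inmb_indicator(self, base_spec):
        psa = run_psa(base_spec, n=80, seed=13)
        curve = ceac(psa, base_spec.economics.ceac_grid)
        for lam, prob in zip(curve.thresholds, curve.probabilities):
            if lam <= 0:
                continue
            indicator = [
                inmb(dc, de, lam) > 0
                for dc, de in zip(psa.delta_costs, psa.delta_effects)
            ]
            assert prob == pytest.approx(np.mean(indicator), abs=0)

    def test_empty_grid_rejected(self):
        psa = PSAResult(seed=0, n=1, delta_costs=np.zeros(1),
                        delta_effects=np.zeros(1), distributions=[])
        with pytest.raises(ConfigError, match="empty"):
            ceac(psa, [])
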