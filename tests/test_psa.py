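"""PSA sampling, CEAC, and value-of-information estimators."""

import numpy as np
import pandas as pd
import pytest

from briskwalk.healthecon import HEParameters, run_deterministic
from briskwalk import psa as P


BASE = HEParameters(delta_met=3.0)


def make_results(delta_cost, delta_qaly, samples=None) -> P.PSAResults:
    dc = np.asarray(delta_cost, dtype=float)
    dq = np.asarray(delta_qaly, dtype=float)
    if samples is None:
        samples = pd.DataFrame(index=range(len(dc)))
    return P.PSAResults(dc, dq, samples)


class TestSampling:
    def test_seed_reproducible(self):
        dists = {"delta_met": P.normal(3, 1), "intervention_cost": P.gamma_dist(60, 10)}
        a = P.sample_parameters(dists, 100, seed=5)
        b = P.sample_parameters(dists, 100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_moments_converge(self):
        dists = {
            "delta_met": P.normal(3.0, 2.0),
            "hr_cancer_per_methr": P.lognormal(0.97, 0.05),
            "utility_baseline": P.beta_dist(32, 8),
            "intervention_cost": P.gamma_dist(62.52, 10.0),
        }
        k = 100_000
        s = P.sample_parameters(dists, k, seed=11)
        targets = {
            "delta_met": (3.0, 2.0),
            "hr_cancer_per_methr": (0.97, 0.05),
            "utility_baseline": (0.8, np.sqrt(0.8 * 0.2 / 41)),
            "intervention_cost": (62.52, 10.0),
        }
        for name, (mean, sd) in targets.items():
            assert abs(s[name].mean() - mean) < 3 * sd / np.sqrt(k)

    def test_degenerate_distributions_constant(self):
        s = P.sample_parameters({"delta_met": P.fixed(3.0)}, 50, seed=0)
        assert (s["delta_met"] == 3.0).all()


class TestRunPsa:
    def test_degenerate_draws_equal_deterministic(self):
        det = run_deterministic(BASE)
        samples = P.sample_parameters(
            {"delta_met": P.fixed(BASE.delta_met)}, 5, seed=0
        )
        res = P.run_psa(BASE, samples)
        assert np.allclose(res.delta_cost, det.delta_cost)
        assert np.allclose(res.delta_qaly, det.delta_qaly)

    def test_linear_in_intervention_cost(self):
        # delta cost passes the sampled intervention cost straight through,
        # so the PSA mean must equal the sampled mean exactly
        samples = P.sample_parameters(
            {"intervention_cost": P.gamma_dist(62.52, 15.0)}, 200, seed=3
        )
        res = P.run_psa(BASE, samples)
        assert np.allclose(res.delta_cost, samples["intervention_cost"])

    def test_invalid_draws_rejected_with_count(self):
        samples = pd.DataFrame({"utility_baseline": [0.8, 1.4, 0.7, -0.1]})
        res = P.run_psa(BASE, samples)
        assert res.n_rejected == 2
        assert len(res) == 2

    def test_unknown_column_rejected(self):
        with pytest.raises(ValueError, match="not in HEParameters"):
            P.run_psa(BASE, pd.DataFrame({"not_a_field": [1.0]}))


class TestSummarise:
    def test_constant_draws_zero_width(self):
        res = make_results([5.0] * 50, [0.1] * 50)
        out = P.summarise_psa(res).set_index("quantity")
        assert out.loc["delta_cost", "ci_lower"] == out.loc["delta_cost", "ci_upper"] == 5.0

    def test_normal_quantiles_recovered(self, rng):
        draws = rng.standard_normal(100_000)
        res = make_results(draws, np.zeros_like(draws))
        out = P.summarise_psa(res).set_index("quantity")
        assert out.loc["delta_cost", "ci_lower"] == pytest.approx(-1.96, abs=0.03)
        assert out.loc["delta_cost", "ci_upper"] == pytest.approx(1.96, abs=0.03)
        assert out.loc["delta_cost", "mean"] == pytest.approx(draws.mean())


class TestCeac:
    def test_all_dominant(self):
        res = make_results([-1.0] * 10, [0.01] * 10)
        out = P.ceac(res, np.array([0.0, 20_000.0]))
        assert (out["prob_cost_effective"] == 1.0).all()

    def test_two_draw_hand_count(self):
        # INB at wtp=1000: {+10, -10}
        res = make_results([-10.0, 10.0], [0.0, 0.0])
        out = P.ceac(res, np.array([1000.0]))
        assert out["prob_cost_effective"].iloc[0] == 0.5

    def test_calibrated_37_percent_fixture(self):
        # 37 of 100 draws have positive net benefit at 20,000/QALY
        dc = np.where(np.arange(100) < 37, -1.0, 1.0)
        res = make_results(dc, np.zeros(100))
        out = P.ceac(res, np.array([20_000.0]))
        assert out["prob_cost_effective"].iloc[0] == pytest.approx(0.37)

    def test_at_zero_wtp_equals_cost_saving_fraction(self, rng):
        dc = rng.normal(size=500)
        res = make_results(dc, rng.normal(size=500))
        out = P.ceac(res, np.array([0.0]))
        assert out["prob_cost_effective"].iloc[0] == np.mean(dc < 0)


class TestEvpi:
    def test_two_point_hand_calculation(self):
        res = make_results([-10.0] * 50 + [10.0] * 50, [0.0] * 100)
        assert P.evpi(res, wtp=1000.0) == pytest.approx(5.0)

    def test_no_decision_uncertainty(self):
        res = make_results([-1.0] * 100, [0.01] * 100)
        assert P.evpi(res, 20_000.0) == 0.0

    def test_always_non_negative(self, rng):
        for _ in range(1000):
            k = int(rng.integers(100, 300))
            res = make_results(
                rng.normal(50, 100, k), rng.normal(0.001, 0.05, k)
            )
            assert P.evpi(res, 20_000.0) >= 0.0


class TestEvppi:
    @staticmethod
    def _fixture(rng, k=2000, informative=True):
        x = rng.normal(0.0, 1.0, k)
        noise = rng.normal(0.0, 1.0, k)
        dq = x if informative else noise
        samples = pd.DataFrame({"delta_met": x})
        return make_results(np.zeros(k), dq, samples)

    def test_irrelevant_parameter_near_zero(self, rng):
        res = self._fixture(rng, informative=False)
        total = P.evpi(res, wtp=1.0)
        assert P.evppi(res, "delta_met", wtp=1.0) <= 0.1 * total + 0.02

    def test_deterministic_monotone_recovers_evpi(self, rng):
        res = self._fixture(rng, informative=True)
        total = P.evpi(res, wtp=1.0)
        partial = P.evppi(res, "delta_met", wtp=1.0)
        assert partial == pytest.approx(total, rel=0.05)

    def test_bounded_by_evpi(self, rng):
        for _ in range(25):
            k = 1200
            x = rng.normal(size=k)
            dq = 0.5 * x + rng.normal(scale=0.8, size=k)
            res = make_results(np.zeros(k), dq, pd.DataFrame({"delta_met": x}))
            total = P.evpi(res, wtp=1.0)
            partial = P.evppi(res, "delta_met", wtp=1.0)
            mc_se = np.std(np.maximum(res.inb(1.0), 0)) / np.sqrt(k)
            assert 0.0 <= partial <= total + 2 * mc_se


class TestPopulationValue:
    def test_backsolved_uk_scaling(self):
        # annual patient count chosen to echo a 2.8m-scale national value
        assert P.population_value(18.83, 148_700) == pytest.approx(2.8e6, rel=0.01)

    @pytest.mark.parametrize("pp,n", [(5.0, 0), (0.0, 1000)])
    def test_zero_edge(self, pp, n):
        assert P.population_value(pp, n) == 0.0

    def test_multi_year_discounted_exceeds_single(self):
        assert P.population_value(10.0, 100, years=5) > P.population_value(10.0, 100)


class TestScenarios:
    DISTS = {
        "delta_met": P.normal(3.0, 1.0),
        "intervention_cost": P.gamma_dist(62.52, 10.0),
    }

    def test_base_scenario_reproduces_base(self):
        scenarios = [P.Scenario("base"), P.Scenario("base_again")]
        out = P.scenario_run(BASE, scenarios, self.DISTS, k=100, seed=9)
        a, b = out.iloc[0], out.iloc[1]
        assert a["delta_cost"] == b["delta_cost"]
        assert a["delta_qaly"] == b["delta_qaly"]

    def test_free_intervention_dominates(self):
        out = P.scenario_run(
            BASE,
            [P.Scenario("free", cost_scaling=0.0)],
            {"delta_met": P.normal(3.0, 0.5)},
            k=100,
            seed=9,
        )
        assert out["ceac_at_wtp"].iloc[0] == 1.0

    def test_longer_effect_duration_helps(self):
        scenarios = [
            P.Scenario(f"d{d}", effect_duration=float(d)) for d in (1, 5, 20)
        ]
        out = P.scenario_run(BASE, scenarios, self.DISTS, k=100, seed=9)
        nmbs = out["nmb"].tolist()
        assert nmbs[0] <= nmbs[1] <= nmbs[2]

    def test_higher_baseline_mortality_helps(self):
        scenarios = [
            P.Scenario(f"m{m}", mortality_multiplier=float(m)) for m in (1.0, 2.0)
        ]
        out = P.scenario_run(BASE, scenarios, self.DISTS, k=100, seed=9)
        assert out["delta_qaly"].iloc[1] >= out["delta_qaly"].iloc[0]


def test_nmb_linearity_per_draw(rng):
    res = make_results(rng.normal(size=200), rng.normal(size=200))
    l1, l2 = 10_000.0, 30_000.0
    assert np.allclose(res.inb(l2) - res.inb(l1), (l2 - l1) * res.delta_qaly)
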