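import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aerisk import (
    TrialDataset,
    ValidationError,
    aalen_johansen,
    aj_components,
    estimate,
    incidence_density,
    incidence_proportion,
    max_eval_time,
    one_minus_km,
    prob_transform_id,
    prob_transform_id_ce,
    simulate_trial,
)
from aerisk.simulate import ScenarioConfig, true_cif_ae

from oracles import brute_force_curves

ARM = "experimental"

# strategy for small single-arm datasets with ties likely (integer times)
subject_lists = st.lists(
    st.tuples(st.sampled_from([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]), st.sampled_from([0, 1, 2])),
    min_size=1,
    max_size=10,
)


def dataset_from(pairs):
    times, events = zip(*pairs)
    return TrialDataset.from_arrays({ARM: (times, events)})


class TestWorkedExample:
    """Hand-computed values on the 4-subject fixture, exact to 1e-10."""

    def test_incidence_proportion(self, toy4):
        assert incidence_proportion(toy4, ARM, 4.0).point == pytest.approx(0.5, abs=1e-10)

    def test_incidence_densities(self, toy4):
        assert incidence_density(toy4, ARM, 4.0, "AE") == pytest.approx(0.2, abs=1e-10)
        assert incidence_density(toy4, ARM, 4.0, "CE") == pytest.approx(0.1, abs=1e-10)

    def test_probability_transforms(self, toy4):
        assert prob_transform_id(toy4, ARM, 4.0).point == pytest.approx(
            1 - np.exp(-0.8), abs=1e-10
        )
        assert prob_transform_id_ce(toy4, ARM, 4.0).point == pytest.approx(
            (0.2 / 0.3) * (1 - np.exp(-1.2)), abs=1e-10
        )

    def test_one_minus_km_reaches_one(self, toy4):
        est, _ = one_minus_km(toy4, ARM, 4.0)
        assert est.point == pytest.approx(1.0, abs=1e-10)

    def test_aalen_johansen_both_types(self, toy4):
        ae, _ = aalen_johansen(toy4, ARM, 4.0, "AE")
        ce, _ = aalen_johansen(toy4, ARM, 4.0, "CE")
        assert ae.point == pytest.approx(0.75, abs=1e-10)
        assert ce.point == pytest.approx(0.25, abs=1e-10)

    def test_counts_and_person_time(self, toy4):
        est = incidence_proportion(toy4, ARM, 4.0)
        assert (est.d_ae, est.d_ce, est.n_cens, est.person_time) == (2, 1, 1, 10.0)


class TestEdgeCases:
    def test_all_censored_gives_zero(self):
        ds = TrialDataset.from_arrays({ARM: ([1.0, 2.0, 3.0], [0, 0, 0])})
        assert incidence_proportion(ds, ARM, 3.0).point == 0.0
        assert incidence_density(ds, ARM, 3.0, "AE") == 0.0
        assert prob_transform_id(ds, ARM, 3.0).point == 0.0
        assert prob_transform_id_ce(ds, ARM, 3.0).point == 0.0
        est, _ = one_minus_km(ds, ARM, 3.0)
        assert est.point == 0.0

    def test_transform_monotone_in_tau(self, toy4):
        taus = [1.0, 2.0, 5.0, 20.0, 100.0]
        vals = [prob_transform_id(toy4, ARM, t).point for t in taus]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 0.999  # tends to 1 as tau grows

    def test_empty_arm_errors(self, toy4):
        for fn in (incidence_proportion, prob_transform_id):
            with pytest.raises(ValidationError):
                fn(toy4, "control", 4.0)

    def test_nonpositive_tau_rejected(self, toy4):
        with pytest.raises(ValueError):
            incidence_proportion(toy4, ARM, 0.0)

    def test_extrapolation_flagged(self, toy4):
        est, _ = aalen_johansen(toy4, ARM, 10.0, "AE")
        assert est.extrapolated
        assert est.point == pytest.approx(0.75)  # last value carried forward
        assert not aalen_johansen(toy4, ARM, 4.0, "AE")[0].extrapolated


class TestCollapseIdentities:
    def test_aje_equals_km_without_competing_events(self):
        cfg = ScenarioConfig(n_per_arm=150, alpha_E=0.3, beta_E=0.0, gamma=0.2, seed=11)
        ds = simulate_trial(cfg)
        tau = max_eval_time(ds)
        _, km_curve = one_minus_km(ds, ARM, tau)
        _, aj_curve = aalen_johansen(ds, ARM, tau, "AE")
        grid = np.linspace(0, tau, 211)
        # product-form (KM) and sum-form (AJE) accumulations agree to the ulp
        np.testing.assert_allclose(km_curve.at(grid), aj_curve.at(grid), atol=1e-12)

    def test_ip_equals_aje_without_censoring_at_max_time(self):
        cfg = ScenarioConfig(n_per_arm=120, alpha_E=0.2, beta_E=0.4, seed=3)
        ds = simulate_trial(cfg)
        tau = max_eval_time(ds)
        ip = incidence_proportion(ds, ARM, tau).point
        aje = aalen_johansen(ds, ARM, tau, "AE")[0].point
        assert ip == pytest.approx(aje, abs=1e-12)

    def test_id_ce_transform_collapses_without_ces(self, toy4):
        ds = TrialDataset.from_arrays({ARM: ([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 1])})
        a = prob_transform_id(ds, ARM, 4.0)
        b = prob_transform_id_ce(ds, ARM, 4.0)
        assert b.point == a.point
        assert b.variance == pytest.approx(a.variance, rel=1e-12)


class TestInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(subject_lists)
    def test_conservation_at_every_jump(self, pairs):
        ds = dataset_from(pairs)
        _, cif_ae, cif_ce, surv = aj_components(ds, ARM)
        np.testing.assert_allclose(cif_ae + cif_ce + surv, 1.0, atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(subject_lists)
    def test_km_dominates_aje_and_aje_dominates_ip(self, pairs):
        ds = dataset_from(pairs)
        tau = max_eval_time(ds)
        grid = np.linspace(0.0, tau, 50)
        _, km_curve = one_minus_km(ds, ARM, tau)
        _, aj_curve = aalen_johansen(ds, ARM, tau, "AE")
        assert np.all(km_curve.at(grid) >= aj_curve.at(grid) - 1e-12)
        assert aj_curve.at(tau) >= incidence_proportion(ds, ARM, tau).point - 1e-12

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(subject_lists)
    def test_matches_brute_force_oracle(self, pairs):
        """Step curves agree with a plain-loop product-limit/CIF recursion."""
        ds = dataset_from(pairs)
        times, events = ds.arm_arrays(ARM)
        expected = brute_force_curves(times, events)
        tau = max_eval_time(ds)
        _, km_curve = one_minus_km(ds, ARM, tau)
        _, ae_curve = aalen_johansen(ds, ARM, tau, "AE")
        _, ce_curve = aalen_johansen(ds, ARM, tau, "CE")
        for t, (omk, cif_ae, cif_ce, _surv) in expected.items():
            assert km_curve.at(t) == pytest.approx(omk, abs=1e-12)
            assert ae_curve.at(t) == pytest.approx(cif_ae, abs=1e-12)
            assert ce_curve.at(t) == pytest.approx(cif_ce, abs=1e-12)

    def test_curves_monotone_and_bounded(self):
        cfg = ScenarioConfig(n_per_arm=200, alpha_E=0.2, beta_E=0.2, gamma=0.15, seed=5)
        ds = simulate_trial(cfg)
        tau = max_eval_time(ds)
        for ev in ("AE", "CE"):
            _, curve = aalen_johansen(ds, ARM, tau, ev)
            assert np.all(np.diff(curve.values) >= 0)
            assert np.all((curve.values >= 0) & (curve.values <= 1))


class TestAgainstLifelines:
    """Cross-checks against an independent survival library (tie-free data)."""

    @pytest.fixture
    def sim(self):
        cfg = ScenarioConfig(n_per_arm=200, alpha_E=0.15, beta_E=0.25, gamma=0.1, seed=21)
        return simulate_trial(cfg)

    def test_km_curve(self, sim):
        from lifelines import KaplanMeierFitter

        times, events = sim.arm_arrays(ARM)
        tau = max_eval_time(sim)
        _, curve = one_minus_km(sim, ARM, tau)
        kmf = KaplanMeierFitter().fit(times, events == 1)
        grid = kmf.survival_function_.index.to_numpy()[1:]
        theirs = 1.0 - kmf.survival_function_.iloc[1:, 0].to_numpy()
        np.testing.assert_allclose(curve.at(grid), theirs, atol=1e-12)

    def test_aje_curve(self, sim):
        from lifelines import AalenJohansenFitter

        times, events = sim.arm_arrays(ARM)
        tau = max_eval_time(sim)
        _, curve = aalen_johansen(sim, ARM, tau, "AE")
        ajf = AalenJohansenFitter(calculate_variance=False).fit(
            times, events, event_of_interest=1
        )
        grid = ajf.cumulative_density_.index.to_numpy()
        theirs = ajf.cumulative_density_.iloc[:, 0].to_numpy()
        np.testing.assert_allclose(curve.at(grid), theirs, atol=1e-12)


class TestVarianceAndConsistency:
    def test_aje_variance_matches_bootstrap(self):
        """Aalen-type closed form vs subject-level bootstrap SD."""
        cfg = ScenarioConfig(n_per_arm=300, alpha_E=0.2, beta_E=0.3, gamma=0.1, seed=17)
        ds = simulate_trial(cfg)
        tau = np.median(ds.table["time"])
        est, _ = aalen_johansen(ds, ARM, tau, "AE")
        rng = np.random.default_rng(99)
        times, events = ds.arm_arrays(ARM)
        points = []
        for _ in range(300):
            idx = rng.integers(0, len(times), len(times))
            boot = TrialDataset.from_arrays({ARM: (times[idx], events[idx])})
            points.append(aalen_johansen(boot, ARM, tau, "AE")[0].point)
        assert np.sqrt(est.variance) == pytest.approx(np.std(points, ddof=1), rel=0.25)

    def test_km_variance_matches_greenwood_formula_shape(self, toy4):
        est, curve = one_minus_km(toy4, ARM, 2.5)
        # single AE among 4 at t=1: KM = 3/4, Greenwood var = (3/4)^2 * 1/(4*3)
        assert est.point == pytest.approx(0.25)
        assert est.variance == pytest.approx((0.75**2) / 12)

    @pytest.mark.parametrize("n,tol", [(200, 0.08), (2000, 0.03)])
    def test_consistency_under_constant_hazards(self, n, tol):
        """AJE and the CE-aware transform approach the closed-form truth."""
        cfg = ScenarioConfig(n_per_arm=n, alpha_E=0.2, beta_E=0.3, gamma=0.3)
        errs_aje, errs_id = [], []
        for seed in range(8):
            ds = simulate_trial(cfg, seed=1000 + seed)
            tau = float(np.quantile(ds.table["time"], 0.8))
            truth = true_cif_ae(0.2, 0.3, tau)
            errs_aje.append(abs(aalen_johansen(ds, ARM, tau, "AE")[0].point - truth))
            errs_id.append(abs(prob_transform_id_ce(ds, ARM, tau).point - truth))
        assert np.mean(errs_aje) < tol
        assert np.mean(errs_id) < tol


class TestProbabilityCI:
    def test_cloglog_interval_contains_point_and_respects_range(self, toy4):
        est, _ = aalen_johansen(toy4, ARM, 4.0, "AE")
        lo, hi = est.ci()
        assert 0.0 <= lo < est.point < hi <= 1.0

    def test_degenerate_at_bounds(self, toy4):
        est, _ = one_minus_km(toy4, ARM, 4.0)  # point is exactly 1
        assert est.ci() == (1.0, 1.0)

    def test_near_nominal_coverage_against_binomial_case(self):
        # uncensored, CE-free data: AJE is the empirical CDF; the cloglog CI
        # should behave like a standard binomial interval
        cfg = ScenarioConfig(n_per_arm=400, alpha_E=0.3, beta_E=0.0)
        hits = 0
        truth = true_cif_ae(0.3, 0.0, 2.0)
        for seed in range(40):
            ds = simulate_trial(cfg, seed=300 + seed)
            est, _ = aalen_johansen(ds, ARM, 2.0, "AE")
            lo, hi = est.ci()
            hits += lo <= truth <= hi
        assert hits >= 33  # ~95% nominal with binomial noise at 40 draws


def test_dispatcher_rejects_unknown_name(toy4):
    with pytest.raises(ValueError, match="unknown estimator"):
        estimate(toy4, ARM, 4.0, "nope")
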