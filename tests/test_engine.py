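"""Hazard model, calibration, exact year evolution, Monte-Carlo cohort
and the deterministic forward recursion."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import dynapop as dp
from dynapop.engine import DiseaseCluster, clusters_of, evolve_cluster_year


def _flat_scenario(
    a_max=3, w=(0.5, 0.5), rr=(1.0, 3.0), inc=0.05, am=0.1, oc=0.01,
    prev=0.02, prev_lo=None,
):
    """Single chronic disease, two risk states, age-constant rates."""
    states = ("lo", "hi")
    if prev_lo is None:
        prev_tabs = {
            "lo": dp.RateTable.constant("w0", w[0], a_max),
            "hi": dp.RateTable.constant("w1", w[1], a_max),
        }
    else:
        prev_tabs = {
            "lo": dp.RateTable("w0", np.tile(np.asarray(prev_lo, float), (2, 1))),
            "hi": dp.RateTable("w1", 1.0 - np.tile(np.asarray(prev_lo, float), (2, 1))),
        }
    rf = dp.RiskFactor("x", states, prev_tabs)
    d = dp.Disease(
        name="d", kind="chronic-constant",
        prevalence=dp.RateTable.constant("p", prev, a_max),
        incidence=dp.RateTable.constant("i", inc, a_max),
        attributable_mortality=dp.RateTable.constant("am", am, a_max),
        rr_from_risk={s: dp.RateTable.constant("rr", v, a_max)
                      for s, v in zip(states, rr)},
    )
    return dp.Scenario("flat", rf, (d,), dp.RateTable.constant("oc", oc, a_max),
                       a_max, a_max)


def _fit(sc):
    joint = dp.build_joint_distribution(sc)
    cp = dp.calibrate_baseline_incidence(sc, joint)
    sched = dp.estimate_net_transitions(sc.risk_factor)
    return joint, cp, sched


# ---------------------------------------------------------------------------
# per-state rates
# ---------------------------------------------------------------------------

class TestRates:
    def test_incidence_rate_product_form(self, causal_pipeline):
        sc, joint, cp, _ = causal_pipeline
        i0 = cp.baseline_incidence["disease_b"][0, 60]
        # empty causal vector: baseline times risk RR (here 1)
        assert dp.incidence_rate(cp, "disease_b", "low", set(), "male", 60) == \
            pytest.approx(i0)
        # causal disease present: multiplied by its RR (4)
        assert dp.incidence_rate(cp, "disease_b", "low", {"disease_a"}, "male", 60) == \
            pytest.approx(4.0 * i0)

    def test_incidence_rate_risk_times_cause(self):
        sc = _flat_scenario()
        _, cp, _ = _fit(sc)
        cp.baseline_incidence["d"][:, :] = 0.001
        # RR_r = 3, no causal diseases
        assert dp.incidence_rate(cp, "d", "hi", set(), "male", 1) == pytest.approx(0.003)

    def test_mortality_rate_additive(self):
        sc = _flat_scenario(am=0.05, oc=0.02)
        _, cp, _ = _fit(sc)
        assert dp.mortality_rate(cp, "lo", {}, "male", 1) == pytest.approx(0.02)
        assert dp.mortality_rate(cp, "lo", {"d": 1}, "male", 1) == pytest.approx(0.07)

    def test_cured_state_contributes_no_excess_mortality(self, smoking_scenario):
        joint = dp.build_joint_distribution(smoking_scenario)
        cp = dp.calibrate_baseline_incidence(smoking_scenario, joint)
        base = dp.mortality_rate(cp, "never", {}, "female", 70)
        cured = dp.mortality_rate(cp, "never", {"lung_cancer": 2}, "female", 70)
        not_cured = dp.mortality_rate(cp, "never", {"lung_cancer": 1}, "female", 70)
        assert cured == pytest.approx(base)
        am = smoking_scenario.disease("lung_cancer").attributable_mortality.values[1, 70]
        assert not_cured == pytest.approx(base + am)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

class TestCalibration:
    def test_all_rr_one_passes_population_incidence_through(self, indep_pipeline):
        sc, joint, cp, _ = indep_pipeline
        for d in sc.diseases:
            np.testing.assert_allclose(
                cp.baseline_incidence[d.name], d.incidence.values, atol=1e-14
            )

    def test_two_equal_strata_closed_form(self):
        # disease-free everywhere, strata weights 1/2 with RR {1, 2}
        sc = _flat_scenario(rr=(1.0, 2.0), prev=0.0, inc=0.03)
        _, cp, _ = _fit(sc)
        np.testing.assert_allclose(cp.baseline_incidence["d"], 0.03 / 1.5, atol=1e-14)

    def test_first_year_incidence_matches_input(self, causal_pipeline):
        """Self-consistency: applying the calibrated baseline to the
        initial joint distribution reproduces the input population
        incidence among the disease-free."""
        sc, joint, cp, _ = causal_pipeline
        d = sc.disease("disease_b")
        i = joint.disease_names.index("disease_b")
        free = joint.combos[:, i] == 0
        for si in (0, 1):
            for age in (30, 55, 80):
                num = den = 0.0
                for r, state in enumerate(joint.risk_states):
                    for c in np.nonzero(free)[0]:
                        m = joint.mass[si, age, r, c]
                        present = {
                            joint.disease_names[k]
                            for k in range(len(joint.disease_names))
                            if joint.combos[c, k] >= 1
                        }
                        num += m * dp.incidence_rate(
                            cp, "disease_b", state, present, dp.SEXES[si], age
                        )
                        den += m
                assert num / den == pytest.approx(
                    d.incidence.values[si, age], abs=1e-10
                )

    def test_unattainable_incidence_raises(self):
        # everyone sits in a zero-RR stratum, yet positive incidence is asked
        sc = _flat_scenario(w=(0.0, 1.0), rr=(1.0, 0.0), prev=0.0, inc=0.01)
        joint = dp.build_joint_distribution(sc)
        with pytest.raises(ValueError, match="incidence unattainable"):
            dp.calibrate_baseline_incidence(sc, joint)


# ---------------------------------------------------------------------------
# year evolution
# ---------------------------------------------------------------------------

class TestEvolveClusterYear:
    def test_zero_rates_leave_state_unchanged(self):
        sc = _flat_scenario(inc=0.0, am=0.0, oc=0.0, prev=0.0)
        _, cp, _ = _fit(sc)
        cluster = clusters_of(sc)[0]
        state = np.array([0.7, 0.2, 0.1])
        out = evolve_cluster_year(state, cluster, cp, "lo", "male", 1)
        np.testing.assert_allclose(out, state, atol=1e-14)

    def test_single_transition_closed_form(self):
        # I=0.1, Am=0, OC=0: P(disease after 1y) = 1 - exp(-0.1)
        sc = _flat_scenario(rr=(1.0, 1.0), inc=0.1, am=0.0, oc=0.0, prev=0.0)
        _, cp, _ = _fit(sc)
        cluster = clusters_of(sc)[0]
        out = evolve_cluster_year(np.array([1.0, 0.0, 0.0]), cluster, cp, "lo", "male", 0)
        assert out[1] == pytest.approx(1.0 - np.exp(-0.1), abs=1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_causal_cluster_matches_dense_generator_oracle(self, causal_pipeline):
        """Three years of the diabetes->CHD-style cluster against an
        independently assembled dense generator exponential."""
        sc, joint, cp, _ = causal_pipeline
        cluster = clusters_of(sc)[0]
        assert cluster.disease_names == ("disease_a", "disease_b")
        si, r, state_name = 0, 1, "high"
        oc = 0.0
        v = np.zeros(5)
        v[0] = 1.0
        v_oracle = v.copy()
        d_a, d_b = sc.disease("disease_a"), sc.disease("disease_b")
        for age in (40, 41, 42):
            v = evolve_cluster_year(v, cluster, cp, state_name, "male", age, oc_rate=oc)
            # oracle: states ordered (a,b) = 00,01,10,11, dead
            i0a = cp.baseline_incidence["disease_a"][si, age]
            i0b = cp.baseline_incidence["disease_b"][si, age]
            rr_ab = d_b.rr_from_causes["disease_a"].values[si, age]
            am_a = d_a.attributable_mortality.values[si, age]
            am_b = d_b.attributable_mortality.values[si, age]
            Q = np.zeros((5, 5))
            Q[0, 2] = i0a            # 00 -> a
            Q[0, 1] = i0b            # 00 -> b
            Q[1, 3] = i0a            # b -> ab
            Q[1, 4] = am_b
            Q[2, 3] = i0b * rr_ab    # a -> ab (causal RR applies)
            Q[2, 4] = am_a
            Q[3, 4] = am_a + am_b
            np.fill_diagonal(Q, -Q.sum(axis=1))
            v_oracle = v_oracle @ expm(Q)
            np.testing.assert_allclose(v, v_oracle, atol=1e-10)


# ---------------------------------------------------------------------------
# risk paths
# ---------------------------------------------------------------------------

class TestRiskPaths:
    def test_identity_schedule_gives_constant_paths(self):
        sched = dp.TransitionSchedule(("a", "b"), np.tile(np.eye(2), (2, 6, 1, 1)))
        rng = np.random.default_rng(0)
        paths = dp.simulate_risk_path(sched, "male", rng, np.array([0.5, 0.5]), 200)
        assert np.all(paths == paths[:, [0]])

    def test_antidiagonal_schedule_alternates(self):
        T = np.array([[0.0, 1.0], [1.0, 0.0]])
        sched = dp.TransitionSchedule(("a", "b"), np.tile(T, (2, 4, 1, 1)))
        rng = np.random.default_rng(0)
        paths = dp.simulate_risk_path(sched, "female", rng, np.array([1.0, 0.0]), 5)
        np.testing.assert_array_equal(paths, np.tile([0, 1, 0, 1], (5, 1)))


# ---------------------------------------------------------------------------
# newborn cohort and forward recursion
# ---------------------------------------------------------------------------

class TestNewbornCohort:
    def test_survival_closed_form_without_diseases(self):
        a_max = 10
        rf = dp.RiskFactor(
            "x", ("only",), {"only": dp.RateTable.constant("w", 1.0, a_max)}
        )
        oc = dp.RateTable.from_function("oc", lambda s, a: 0.01 + 0.002 * a, a_max)
        sc = dp.Scenario("nodisease", rf, (), oc, a_max, a_max)
        joint = dp.build_joint_distribution(sc)
        cp = dp.calibrate_baseline_incidence(sc, joint)
        sched = dp.estimate_net_transitions(rf)
        res = dp.simulate_newborn_cohort(sc, cp, sched, 5, seed=0)
        ages = np.arange(a_max + 1)
        haz = 0.01 + 0.002 * ages
        expected = np.exp(-np.concatenate([[0.0], np.cumsum(haz[:-1])]))
        np.testing.assert_allclose(res.alive[0], expected, atol=1e-12)

    def test_cohort_deterministic_given_seed(self, mini_pipeline):
        sc, joint, cp, sched = mini_pipeline
        a = dp.simulate_newborn_cohort(sc, cp, sched, 50, seed=4)
        b = dp.simulate_newborn_cohort(sc, cp, sched, 50, seed=4)
        c = dp.simulate_newborn_cohort(sc, cp, sched, 50, seed=5)
        np.testing.assert_array_equal(a.disease_prev, b.disease_prev)
        np.testing.assert_array_equal(a.risk_marginal, b.risk_marginal)
        assert not np.array_equal(a.risk_marginal, c.risk_marginal)

    def test_monte_carlo_matches_forward_recursion(self, mini_pipeline, mini_forward):
        """2000 individuals per sex land within 3.5 Monte-Carlo SEs of
        the deterministic expectation for every disease at every age."""
        sc, joint, cp, sched = mini_pipeline
        mc = dp.simulate_newborn_cohort(sc, cp, sched, 2000, seed=20)
        diff = np.abs(mc.disease_prev - mini_forward.disease_prev)
        bound = 3.5 * mc.disease_prev_se + 1e-9
        assert np.all(diff <= bound)

    def test_survival_non_increasing(self, mini_pipeline):
        sc, joint, cp, sched = mini_pipeline
        mc = dp.simulate_newborn_cohort(sc, cp, sched, 100, seed=1)
        assert np.all(np.diff(mc.alive, axis=1) <= 1e-12)
        assert np.allclose(mc.alive[:, 0], 1.0)

    def test_error_scales_roughly_as_inverse_sqrt_n(self, mini_pipeline, mini_forward):
        sc, joint, cp, sched = mini_pipeline
        def sup_err(n, seed):
            mc = dp.simulate_newborn_cohort(sc, cp, sched, n, seed=seed)
            return np.abs(mc.disease_prev - mini_forward.disease_prev).max()
        e_small = np.mean([sup_err(500, s) for s in (1, 2, 3)])
        e_big = np.mean([sup_err(8000, s) for s in (1, 2, 3)])
        ratio = (e_small * np.sqrt(500)) / (e_big * np.sqrt(8000))
        assert 0.25 <= ratio <= 4.0


class TestForwardExpectation:
    def test_single_disease_no_mortality_closed_form(self):
        sc = _flat_scenario(a_max=20, w=(1.0, 0.0), rr=(1.0, 1.0),
                            inc=0.02, am=0.0, oc=0.0, prev=0.0)
        joint, cp, sched = _fit(sc)
        det = dp.forward_expectation(sc, cp, sched)
        ages = np.arange(21)
        expected = 1.0 - np.exp(-0.02 * ages)
        np.testing.assert_allclose(det.disease_prev[0, :, 0], expected, atol=1e-12)

    def test_mass_conserved_and_survival_monotone(self, causal_forward):
        det = causal_forward
        assert np.all(np.diff(det.alive, axis=1) <= 1e-12)
        assert np.allclose(det.alive[:, 0], 1.0)

    def test_state_space_limit_advises_factorization(self, smoking_scenario):
        joint = dp.build_joint_distribution(smoking_scenario)
        cp = dp.calibrate_baseline_incidence(smoking_scenario, joint)
        sched = dp.estimate_net_transitions(smoking_scenario.risk_factor)
        with pytest.raises(ValueError, match="cluster"):
            dp.forward_expectation(smoking_scenario, cp, sched)

    def test_matches_exhaustive_path_enumeration(self):
        """3-age toy with 2 risk states: the forward recursion equals the
        expectation over all 8 explicit risk paths."""
        sc = _flat_scenario(a_max=3, rr=(1.0, 3.0), inc=0.05, am=0.1, oc=0.02,
                            prev=0.02, prev_lo=[0.6, 0.55, 0.5, 0.5])
        joint, cp, sched = _fit(sc)
        det = dp.forward_expectation(sc, cp, sched)
        cluster = clusters_of(sc)[0]
        si = 0
        w0 = sc.risk_factor.prevalence_array()[:, si, 0]
        agg_alive = np.zeros(4)
        agg_dis = np.zeros(4)
        for path in itertools.product(range(2), repeat=4):
            prob = w0[path[0]]
            for a in range(3):
                prob *= sched.matrices[si, a][path[a], path[a + 1]]
            if prob == 0.0:
                continue
            v = np.zeros(cluster.n_states + 1)
            v[0] = 1.0
            for a in range(4):
                alive = 1.0 - v[-1]
                agg_alive[a] += prob * alive
                agg_dis[a] += prob * v[1]  # disease present & alive
                if a < 3:
                    v = evolve_cluster_year(
                        v, cluster, cp, sc.risk_factor.states[path[a]],
                        "male", a, oc_rate=0.02,
                    )
            np.testing.assert_allclose(v.sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(det.alive[si], agg_alive, atol=1e-10)
        np.testing.assert_allclose(
            det.disease_prev[si, :, 0], agg_dis / agg_alive, atol=1e-10
        )


class TestClusterFactorization:
    """Product-of-clusters survival equals the dense full-joint generator
    on toys: with RR 1 (or a single path) the Monte-Carlo engine is
    deterministic and must agree with the dense recursion to 1e-10."""

    def test_independent_pair_two_singleton_clusters(self, indep_pipeline, indep_forward):
        sc, joint, cp, sched = indep_pipeline
        assert len(sc.clusters()) == 2
        mc = dp.simulate_newborn_cohort(sc, cp, sched, 16, seed=0)
        np.testing.assert_allclose(mc.alive, indep_forward.alive, atol=1e-10)
        np.testing.assert_allclose(
            mc.disease_prev, indep_forward.disease_prev, atol=1e-10
        )
        np.testing.assert_allclose(
            mc.pair_prev, indep_forward.pair_prev, atol=1e-10
        )

    def test_causal_pair_one_joint_cluster(self, causal_pipeline, causal_forward):
        sc, joint, cp, sched = causal_pipeline
        assert sc.clusters() == [("disease_a", "disease_b")]
        mc = dp.simulate_newborn_cohort(sc, cp, sched, 16, seed=0)
        np.testing.assert_allclose(mc.alive, causal_forward.alive, atol=1e-10)
        np.testing.assert_allclose(
            mc.disease_prev, causal_forward.disease_prev, atol=1e-10
        )
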