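"""The aABC planner: fitness semantics, selection probabilities, neighborhood
moves, convergence and recovery behaviour, grid oracle, target adjustment."""

import numpy as np
import pytest

from orthoplan.cephalometry import compute_profile
from orthoplan.cohort import make_template
from orthoplan.kinematics import SurgicalPlan, apply_plan
from orthoplan.planner import (
    ColonyConfig,
    FitnessSpec,
    PlanBounds,
    PlannerError,
    SurgicalPlanner,
    adjust_targets,
    grid_oracle,
    neighbor_candidate,
    optimize,
    plan_fitness,
    selection_probabilities,
)

FAST = ColonyConfig(np_bees=20, t_max=60, limit=30)


@pytest.fixture(scope="module")
def template_spec(template):
    """Targets set to the template's own profile: the zero plan scores 0."""
    return FitnessSpec(targets=compute_profile(template).as_dict())


class TestFitness:
    def test_zero_at_target(self, template, template_spec, intervals):
        f = plan_fitness(SurgicalPlan.zero(), template, template_spec, intervals)
        assert f == pytest.approx(0.0, abs=1e-24)

    def test_matches_hand_formula(self, template, intervals):
        spec = FitnessSpec()  # midpoint targets
        plan = SurgicalPlan(maxilla_translation=[0.0, 2.0, 0.0])
        profile = compute_profile(apply_plan(template, plan))
        expected = sum(
            ((profile[m] - intervals.midpoint(m, "female"))
             / intervals.half_width(m, "female")) ** 2
            for m in spec.measurements
        )
        got = plan_fitness(plan, template, spec, intervals)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_weight_doubling_doubles_term(self, template, intervals):
        plan = SurgicalPlan(maxilla_translation=[0.0, 2.0, 0.0])
        spec1 = FitnessSpec(measurements=("SNA",))
        spec2 = FitnessSpec(measurements=("SNA",), weights={"SNA": 2.0})
        f1 = plan_fitness(plan, template, spec1, intervals)
        f2 = plan_fitness(plan, template, spec2, intervals)
        assert f2 == pytest.approx(2.0 * f1, rel=1e-12)
        assert f1 > 0

    def test_boundary_value_scores_one(self, template, intervals):
        # a measurement sitting exactly at an interval endpoint contributes
        # ((high - midpoint)/half_width)^2 = 1 by construction
        profile = compute_profile(template)
        low, high = intervals.bounds("SNA", "female")
        shifted = dict(profile.as_dict())
        shifted["SNA"] = high

        spec = FitnessSpec(measurements=("SNA",))
        t, w, u = spec.resolve(intervals, "female")
        term = float(u[0] * ((shifted["SNA"] - t[0]) / w[0]) ** 2)
        assert term == pytest.approx(1.0, rel=1e-12)

    def test_target_outside_interval_rejected(self, template, intervals):
        spec = FitnessSpec(targets={"SNA": 95.0})
        with pytest.raises(PlannerError, match="SNA"):
            plan_fitness(SurgicalPlan.zero(), template, spec, intervals)

    def test_unknown_measurement_rejected(self, template, intervals):
        spec = FitnessSpec(measurements=("SNA", "nonexistent"))
        with pytest.raises(PlannerError, match="nonexistent"):
            plan_fitness(SurgicalPlan.zero(), template, spec, intervals)


class TestSelectionProbabilities:
    def test_equal_objectives_uniform(self):
        p = selection_probabilities([3.0, 3.0, 3.0])
        np.testing.assert_allclose(p, 1 / 3)

    def test_reference_values(self):
        np.testing.assert_allclose(
            selection_probabilities([0.0, 1.0]), [2 / 3, 1 / 3], atol=1e-12
        )

    def test_normalization_and_monotonicity(self, rng):
        f = rng.uniform(0, 50, size=20)
        p = selection_probabilities(f)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        order = np.argsort(f)
        assert np.all(np.diff(p[order]) <= 1e-15)

    def test_empty_rejected(self):
        with pytest.raises(PlannerError):
            selection_probabilities([])


class TestNeighborCandidate:
    bounds = PlanBounds.default()

    def test_candidate_clamped_to_bounds(self, rng):
        src = np.full(15, 7.9)
        partner = np.full(15, -7.9)
        gbest = np.full(15, 7.9)
        for _ in range(50):
            v = neighbor_candidate(src, partner, gbest, 1, FAST, rng, self.bounds)
            assert self.bounds.contains(v)

    def test_final_cycle_moves_toward_gbest_componentwise(self, rng):
        cfg = ColonyConfig(np_bees=20, t_max=100, limit=30, a_start=0.0, a_end=0.0)
        src = np.zeros(15)
        gbest = np.ones(15)
        partner = np.full(15, 0.5)
        v = neighbor_candidate(src, partner, gbest, 100, cfg, rng, self.bounds)
        # with a == 0 the move is a per-dimension convex step toward gbest
        assert np.all(v >= -1e-12) and np.all(v <= 1.0 + 1e-12)

    def test_degenerate_population_is_fixed_point(self, rng):
        # source == partner == gbest leaves nothing to move along
        src = np.full(15, 1.5)
        v = neighbor_candidate(src, src.copy(), src.copy(), 10, FAST, rng, self.bounds)
        np.testing.assert_allclose(v, src, atol=1e-12)

    def test_adaptive_coefficient_schedule(self):
        cfg = ColonyConfig(np_bees=20, t_max=101, limit=30, a_start=1.0, a_end=0.5)
        assert cfg.adaptive_coefficient(1) == pytest.approx(1.0)
        assert cfg.adaptive_coefficient(101) == pytest.approx(0.5)
        assert cfg.adaptive_coefficient(51) == pytest.approx(0.75)


class TestOptimize:
    def test_trace_nonincreasing_and_bounds(self, template, template_spec, intervals):
        patient = apply_plan(template, SurgicalPlan(maxilla_translation=[0, -4, 0]))
        res = optimize(patient, template_spec, PlanBounds.default(), intervals, FAST, seed=5)
        assert np.all(np.diff(res.trace) <= 0)
        assert PlanBounds.default().contains(res.plan.to_vector())
        np.testing.assert_allclose(res.plan.to_vector()[6:9] * 0, 0)  # shape sanity

    def test_determinism(self, template, template_spec, intervals):
        patient = apply_plan(template, SurgicalPlan(maxilla_translation=[0, -4, 0]))
        r1 = optimize(patient, template_spec, PlanBounds.default(), intervals, FAST, seed=11)
        r2 = optimize(patient, template_spec, PlanBounds.default(), intervals, FAST, seed=11)
        np.testing.assert_array_equal(r1.plan.to_vector(), r2.plan.to_vector())
        np.testing.assert_array_equal(r1.trace, r2.trace)

    def test_recovers_inverse_displacement(self, template, template_spec, intervals):
        # 5 mm maxillary setback patient: the planner should advance ~+5 mm
        patient = apply_plan(template, SurgicalPlan(maxilla_translation=[0, -5, 0]))
        cfg = ColonyConfig(np_bees=40, t_max=200, limit=50)
        res = optimize(patient, template_spec, PlanBounds.default(), intervals, cfg, seed=0)
        assert res.plan.maxilla_translation[1] == pytest.approx(5.0, abs=0.5)

    def test_infeasible_target_fails_before_search(self, template, intervals):
        spec = FitnessSpec(targets={"SNB": 90.0})
        with pytest.raises(PlannerError, match="SNB"):
            optimize(template, spec, PlanBounds.default(), intervals, FAST, seed=0)


class TestGridOracle:
    def test_matches_independent_enumeration(self, template, template_spec, intervals):
        import itertools

        patient = apply_plan(template, SurgicalPlan(maxilla_translation=[0, -3, 0]))
        bounds = PlanBounds.default()
        steps, dims = 7, [4, 10]
        _, best = grid_oracle(patient, template_spec, bounds, intervals, steps, dims)

        axes = [np.linspace(bounds.low[d], bounds.high[d], steps) for d in dims]
        brute = np.inf
        for combo in itertools.product(*axes):
            v = np.zeros(15)
            v[dims] = combo
            f = plan_fitness(SurgicalPlan.from_vector(v), patient, template_spec, intervals)
            brute = min(brute, f)
        assert best == pytest.approx(brute, rel=1e-12)

    def test_exact_grid_member_found(self, template, template_spec, intervals):
        patient = apply_plan(template, SurgicalPlan(maxilla_translation=[0, -4, 0]))
        bounds = PlanBounds.default()
        # 9 steps over [-8, 8] include exactly +4 on the maxilla ty axis
        plan, best = grid_oracle(patient, template_spec, bounds, intervals, 9, [4])
        assert plan.maxilla_translation[1] == pytest.approx(4.0)

    def test_cap_refusal(self, template, template_spec, intervals):
        with pytest.raises(PlannerError, match="cap"):
            grid_oracle(template, template_spec, PlanBounds.default(), intervals,
                        steps=50, active_dims=[0, 1, 2, 3], cap=1000)


class TestAdjustTargets:
    def test_override_changes_single_target(self, intervals):
        spec = FitnessSpec(targets={"SNA": 82.5})
        new = adjust_targets(spec, {"SNA": 84.0}, intervals, "female")
        assert new.targets["SNA"] == 84.0
        assert spec.targets["SNA"] == 82.5
        assert new.measurements == spec.measurements

    def test_out_of_interval_override_rejected(self, intervals):
        with pytest.raises(PlannerError, match="SNA"):
            adjust_targets(FitnessSpec(), {"SNA": 95.0}, intervals, "female")

    def test_reoptimization_moves_toward_new_target(self, template, intervals):
        patient = apply_plan(template, SurgicalPlan(maxilla_translation=[0, -5, 0]))
        base = FitnessSpec(targets=compute_profile(template).as_dict())
        planner = SurgicalPlanner(
            patient, intervals, base, config=ColonyConfig(np_bees=40, t_max=120, limit=50)
        )
        first = planner.fit(seed=2)
        sna_before = first.profile_after()["SNA"]
        revised = first.interact({"SNA": 84.5}, seed=2)
        sna_after = revised.profile_after()["SNA"]
        assert abs(sna_after - 84.5) < abs(sna_before - 84.5)
        assert revised.plan.provenance == "ai"
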