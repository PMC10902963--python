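"""Adaptive artificial-bee-colony (aABC) surgical planner.

The planner searches the 15-dimensional surgical-plan space (maxilla 6-DOF,
mandible 6-DOF, chin translation) inside a box of clinically feasible moves
for the plan whose post-move cephalometric profile is closest to target
values — by default the midpoints of the per-sex reference intervals, on the
principle that measurement values nearer the middle of their normal range
are better.

Fitness
-------
For targeted measurements k with target t_k, interval half-width w_k and
weight u_k, a candidate plan x scores

    F(x) = sum_k u_k * ((c_k(x) - t_k) / w_k)^2  [+ lambda * occlusal misfit^2]

where c_k(x) is the measurement after applying the plan.  F >= 0 with
equality iff every target is met exactly.  Half-width normalization makes
degrees, millimetres and percent commensurate.

Search
------
Classic ABC phases (employed -> onlooker -> scout, greedy one-to-one
replacement, abandonment after ``limit`` failed trials) with an adaptive
neighborhood equation blending a differential exploration term with a
global-best-guided exploitation term, applied componentwise over the whole
parameter vector:

    v_j = x_j + a(c) * phi_j * (x_j - partner_j) + (1 - a(c)) * psi_j * (g_j - x_j)

with independent phi_j ~ U(-1, 1) and psi_j ~ U(0, 1) per dimension, and the
adaptive coefficient a(c) decaying linearly from ``a_start`` to ``a_end``
over the cycles: early cycles explore, late cycles exploit the region around
the global best.  Full-vector moves keep the population-difference term
aligned with the correlated valleys of the cephalometric objective (the
measurements share parameters, so the objective is far from separable);
one-dimension-at-a-time updates degenerate into coordinate descent there and
converge an order of magnitude slower.  ``a_end`` defaults to 0.5 so the
differential term never vanishes — the exploitation weight still rises
monotonically, but the population retains the difference-vector steps that
ill-conditioned objectives need.  Expert preferences enter by overriding
targets (:func:`adjust_targets`) and re-optimizing, optionally warm-started
from the previous best plan.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from collections.abc import Mapping, Sequence

import numpy as np

from .cephalometry import (
    LandmarkSet,
    PatientFrame,
    ReferenceIntervalTable,
    build_patient_frame,
    compute_profile,
    default_reference_intervals,
)
from .kinematics import (
    PLAN_PARAM_NAMES,
    OcclusalRegistration,
    SegmentDefinition,
    SurgicalPlan,
    apply_plan,
    plan_motions,
)
from .registry import MEASUREMENTS

__all__ = [
    "PlannerError",
    "PlanBounds",
    "FitnessSpec",
    "ColonyConfig",
    "FoodSource",
    "OptimResult",
    "plan_fitness",
    "selection_probabilities",
    "neighbor_candidate",
    "optimize",
    "grid_oracle",
    "adjust_targets",
    "SurgicalPlanner",
    "PlanningResults",
]


class PlannerError(ValueError):
    """Invalid planner configuration."""


@dataclass(frozen=True)
class PlanBounds:
    """Box bounds for the 15 plan parameters, in :data:`PLAN_PARAM_NAMES`
    order (degrees for rotations, mm for translations)."""

    low: np.ndarray
    high: np.ndarray

    def __post_init__(self):
        low = np.asarray(self.low, dtype=float)
        high = np.asarray(self.high, dtype=float)
        if low.shape != (15,) or high.shape != (15,):
            raise PlannerError("bounds must be 15-vectors")
        if not np.all(np.isfinite(low)) or not np.all(np.isfinite(high)):
            raise PlannerError("bounds must be finite")
        if not np.all(low < high):
            bad = [PLAN_PARAM_NAMES[i] for i in np.nonzero(~(low < high))[0]]
            raise PlannerError(f"low >= high for parameter(s): {', '.join(bad)}")
        object.__setattr__(self, "low", low)
        object.__setattr__(self, "high", high)

    @classmethod
    def default(cls, rotation_deg: float = 10.0, translation_mm: float = 8.0) -> "PlanBounds":
        """Symmetric bounds: +-``rotation_deg`` on rotations, +-``translation_mm``
        on translations (typical clinical feasibility)."""
        rot = np.array([rotation_deg] * 3)
        trans = np.array([translation_mm] * 3)
        high = np.concatenate([rot, trans, rot, trans, trans])
        return cls(low=-high, high=high)

    def clip(self, v: np.ndarray) -> np.ndarray:
        return np.clip(v, self.low, self.high)

    def contains(self, v: np.ndarray, atol: float = 1e-9) -> bool:
        return bool(np.all(v >= self.low - atol) and np.all(v <= self.high + atol))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.low, self.high)


@dataclass(frozen=True)
class FitnessSpec:
    """Objective specification: targeted measurements, targets, weights and
    the optional occlusal coupling penalty.

    ``targets`` may override a subset of measurements; missing entries default
    to the reference-interval midpoint for the patient's sex.  Every explicit
    target must lie inside its interval.
    """

    measurements: tuple[str, ...] = MEASUREMENTS
    targets: Mapping[str, float] = field(default_factory=dict)
    weights: Mapping[str, float] = field(default_factory=dict)
    occlusal_weight: float = 0.0
    occlusal: OcclusalRegistration | None = None

    def __post_init__(self):
        if not self.measurements:
            raise PlannerError("at least one targeted measurement is required")
        for m, w in self.weights.items():
            if w < 0:
                raise PlannerError(f"negative weight for {m!r}")
        if self.occlusal_weight < 0:
            raise PlannerError("occlusal_weight must be nonnegative")
        if self.occlusal_weight > 0 and self.occlusal is None:
            raise PlannerError("occlusal_weight > 0 requires an OcclusalRegistration")

    def resolve(
        self, intervals: ReferenceIntervalTable, sex: str
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(targets, half_widths, weights) arrays over ``measurements``.

        Raises :class:`PlannerError` for a missing interval or a target
        outside its interval."""
        t = np.empty(len(self.measurements))
        w = np.empty(len(self.measurements))
        u = np.empty(len(self.measurements))
        for i, m in enumerate(self.measurements):
            try:
                low, high = intervals.bounds(m, sex)
            except Exception as exc:
                raise PlannerError(f"no reference interval for measurement {m!r}") from exc
            t[i] = self.targets.get(m, 0.5 * (low + high))
            if not low <= t[i] <= high:
                raise PlannerError(
                    f"target {t[i]} for {m!r} outside reference interval [{low}, {high}]"
                )
            w[i] = 0.5 * (high - low)
            u[i] = self.weights.get(m, 1.0)
        return t, w, u


def adjust_targets(
    spec: FitnessSpec,
    overrides: Mapping[str, float],
    intervals: ReferenceIntervalTable,
    sex: str,
) -> FitnessSpec:
    """Expert target override (human-computer interaction step).

    Each override must name a targeted measurement and lie inside its
    reference interval; untouched targets are preserved.  Re-run the
    optimizer (optionally warm-started) with the returned spec.
    """
    new_targets = dict(spec.targets)
    for m, value in overrides.items():
        if m not in spec.measurements:
            raise PlannerError(f"{m!r} is not a targeted measurement")
        low, high = intervals.bounds(m, sex)
        if not low <= value <= high:
            raise PlannerError(
                f"override {value} for {m!r} outside reference interval [{low}, {high}]"
            )
        new_targets[m] = float(value)
    return replace(spec, targets=new_targets)


class _PlanProblem:
    """Cached evaluation context: patient frame, resolved targets, segment
    tables.  The cranial base never moves, so the frame is computed once."""

    def __init__(
        self,
        landmarks: LandmarkSet,
        spec: FitnessSpec,
        intervals: ReferenceIntervalTable,
        segments: Mapping[str, SegmentDefinition] | None = None,
        frame: PatientFrame | None = None,
    ):
        self.landmarks = landmarks
        self.spec = spec
        self.intervals = intervals
        self.segments = segments
        self.frame = frame if frame is not None else build_patient_frame(landmarks)
        self.targets, self.half_widths, self.weights = spec.resolve(
            intervals, landmarks.sex
        )

    def profile_after(self, plan: SurgicalPlan):
        moved = apply_plan(self.landmarks, plan, self.segments)
        return compute_profile(moved, self.frame)

    def evaluate_plan(self, plan: SurgicalPlan) -> float:
        profile = self.profile_after(plan)
        c = np.array([profile[m] for m in self.spec.measurements])
        f = float(np.sum(self.weights * ((c - self.targets) / self.half_widths) ** 2))
        if self.spec.occlusal_weight > 0:
            motions = plan_motions(self.landmarks, plan, self.segments)
            reg = self.spec.occlusal
            moved_max = motions["maxilla"].apply(reg.maxilla_markers)
            moved_mand = motions["mandible"].apply(reg.mandible_markers)
            misfit = reg.motion.apply(moved_mand) - moved_max
            rms = float(np.sqrt(np.mean(np.sum(misfit**2, axis=1))))
            f += self.spec.occlusal_weight * rms**2
        return f

    def evaluate(self, params: np.ndarray) -> float:
        return self.evaluate_plan(SurgicalPlan.from_vector(params))


def plan_fitness(
    plan: SurgicalPlan,
    landmarks: LandmarkSet,
    spec: FitnessSpec,
    intervals: ReferenceIntervalTable,
    *,
    segments: Mapping[str, SegmentDefinition] | None = None,
    frame: PatientFrame | None = None,
) -> float:
    """Objective value of a plan (0 iff every targeted measurement is on
    target and, when enabled, the occlusal misfit is zero)."""
    return _PlanProblem(landmarks, spec, intervals, segments, frame).evaluate_plan(plan)


def selection_probabilities(objectives: Sequence[float]) -> np.ndarray:
    """Onlooker-selection probabilities p_i = fit_i / sum(fit), with
    fit_i = 1 / (1 + F_i): strictly decreasing in the objective."""
    f = np.asarray(objectives, dtype=float)
    if f.size == 0:
        raise PlannerError("no objectives to select among")
    if np.any(f < 0):
        raise PlannerError("objectives must be nonnegative")
    fit = 1.0 / (1.0 + f)
    return fit / fit.sum()


@dataclass(frozen=True)
class ColonyConfig:
    """Colony settings.

    ``np_bees`` is the total colony; employed and onlooker bees each make up
    half, so there are ``np_bees // 2`` food sources.  A source not improved
    within ``limit`` trials is abandoned (scout re-initialization).  The
    adaptive coefficient decays linearly from ``a_start`` to ``a_end`` over
    ``t_max`` cycles.
    """

    np_bees: int = 40
    limit: int = 50
    t_max: int = 500
    a_start: float = 1.0
    a_end: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.np_bees < 4 or self.np_bees % 2:
            raise PlannerError("np_bees must be even and >= 4")
        if self.limit < 1:
            raise PlannerError("limit must be >= 1")
        if self.t_max < 1:
            raise PlannerError("t_max must be >= 1")
        if not (self.a_start >= self.a_end >= 0):
            raise PlannerError("need a_start >= a_end >= 0")

    def adaptive_coefficient(self, cycle: int) -> float:
        """a(cycle), linear from a_start (cycle 1) to a_end (cycle t_max)."""
        if self.t_max == 1:
            return self.a_start
        frac = (cycle - 1) / (self.t_max - 1)
        return self.a_start + (self.a_end - self.a_start) * frac


@dataclass
class FoodSource:
    """One candidate solution with its objective and failed-trial counter."""

    params: np.ndarray
    objective: float
    trials: int = 0


def neighbor_candidate(
    source: np.ndarray,
    partner: np.ndarray,
    gbest: np.ndarray,
    cycle: int,
    config: ColonyConfig,
    rng: np.random.Generator,
    bounds: PlanBounds,
) -> np.ndarray:
    """Adaptive full-vector neighborhood move, clamped to bounds.

    Each dimension gets independent coefficients: an exploration term
    ``a * phi_j * (x_j - partner_j)`` and an exploitation term
    ``(1 - a) * psi_j * (gbest_j - x_j)``.
    """
    a = config.adaptive_coefficient(cycle)
    phi = rng.uniform(-1.0, 1.0, size=source.size)
    psi = rng.uniform(0.0, 1.0, size=source.size)
    v = source + a * phi * (source - partner) + (1.0 - a) * psi * (gbest - source)
    return bounds.clip(v)


@dataclass
class OptimResult:
    """Outcome of an aABC run: the best plan, its objective, the per-cycle
    best-objective trace (nonincreasing) and the seed used."""

    plan: SurgicalPlan
    objective: float
    trace: np.ndarray
    cycles: int
    seed: int | None


def optimize(
    landmarks: LandmarkSet,
    spec: FitnessSpec,
    bounds: PlanBounds,
    intervals: ReferenceIntervalTable,
    config: ColonyConfig,
    *,
    seed: int | None = None,
    segments: Mapping[str, SegmentDefinition] | None = None,
    initial: SurgicalPlan | None = None,
) -> OptimResult:
    """Run the aABC search and return the best plan found.

    Fully reproducible given (seed, config, inputs).  ``initial`` warm-starts
    the colony by injecting a plan as one food source (used after expert
    target adjustment).
    """
    problem = _PlanProblem(landmarks, spec, intervals, segments)
    used_seed = seed if seed is not None else config.seed
    rng = np.random.default_rng(used_seed)
    n_sources = config.np_bees // 2

    sources = []
    for i in range(n_sources):
        params = bounds.sample(rng)
        if i == 0 and initial is not None:
            params = bounds.clip(initial.to_vector())
        sources.append(FoodSource(params, problem.evaluate(params)))

    best = min(sources, key=lambda s: s.objective)
    gbest_params = best.params.copy()
    gbest_obj = best.objective

    def attempt(i: int, cycle: int) -> None:
        nonlocal gbest_params, gbest_obj
        src = sources[i]
        partner_idx = int(rng.integers(n_sources - 1))
        if partner_idx >= i:
            partner_idx += 1
        cand = neighbor_candidate(
            src.params, sources[partner_idx].params, gbest_params, cycle, config, rng, bounds
        )
        obj = problem.evaluate(cand)
        if obj < src.objective:
            sources[i] = FoodSource(cand, obj, 0)
            if obj < gbest_obj:
                gbest_obj = obj
                gbest_params = cand.copy()
        else:
            src.trials += 1

    trace = np.empty(config.t_max)
    for cycle in range(1, config.t_max + 1):
        for i in range(n_sources):  # employed phase
            attempt(i, cycle)
        probs = selection_probabilities([s.objective for s in sources])
        for _ in range(n_sources):  # onlooker phase
            attempt(int(rng.choice(n_sources, p=probs)), cycle)
        for i, src in enumerate(sources):  # scout phase
            if src.trials > config.limit:
                params = bounds.sample(rng)
                obj = problem.evaluate(params)
                sources[i] = FoodSource(params, obj, 0)
                if obj < gbest_obj:
                    gbest_obj = obj
                    gbest_params = params.copy()
        trace[cycle - 1] = gbest_obj

    return OptimResult(
        plan=SurgicalPlan.from_vector(gbest_params, provenance="ai"),
        objective=gbest_obj,
        trace=trace,
        cycles=config.t_max,
        seed=used_seed,
    )


def grid_oracle(
    landmarks: LandmarkSet,
    spec: FitnessSpec,
    bounds: PlanBounds,
    intervals: ReferenceIntervalTable,
    steps: int,
    active_dims: Sequence[int],
    *,
    segments: Mapping[str, SegmentDefinition] | None = None,
    cap: int = 200_000,
) -> tuple[SurgicalPlan, float]:
    """Exhaustive grid argmin over up to 4 active plan dimensions.

    Inactive dimensions are fixed at 0.  Brute-force reference for validating
    the stochastic search; refuses grids above ``cap`` points.
    """
    active = list(dict.fromkeys(int(d) for d in active_dims))
    if not 1 <= len(active) <= 4:
        raise PlannerError("active_dims must name 1-4 distinct dimensions")
    if any(d < 0 or d >= 15 for d in active):
        raise PlannerError("active dimension index out of range")
    if steps < 2:
        raise PlannerError("steps must be >= 2")
    if steps ** len(active) > cap:
        raise PlannerError(f"grid of {steps ** len(active)} points exceeds cap {cap}")

    problem = _PlanProblem(landmarks, spec, intervals, segments)
    axes = [np.linspace(bounds.low[d], bounds.high[d], steps) for d in active]
    best_params, best_obj = None, np.inf
    base = np.zeros(15)
    for combo in itertools.product(*axes):
        params = base.copy()
        params[active] = combo
        obj = problem.evaluate(params)
        if obj < best_obj:
            best_obj, best_params = obj, params
    return SurgicalPlan.from_vector(best_params, provenance="ai"), float(best_obj)


class SurgicalPlanner:
    """Model-style front end: a patient's landmarks plus planning settings.

    ``fit`` runs the aABC search and returns :class:`PlanningResults`.
    """

    def __init__(
        self,
        landmarks: LandmarkSet,
        intervals: ReferenceIntervalTable | None = None,
        spec: FitnessSpec | None = None,
        bounds: PlanBounds | None = None,
        config: ColonyConfig | None = None,
        segments: Mapping[str, SegmentDefinition] | None = None,
    ):
        self.landmarks = landmarks
        self.intervals = intervals if intervals is not None else default_reference_intervals()
        self.spec = spec if spec is not None else FitnessSpec()
        self.bounds = bounds if bounds is not None else PlanBounds.default()
        self.config = config if config is not None else ColonyConfig()
        self.segments = segments
        # fail fast on an infeasible spec
        self.spec.resolve(self.intervals, landmarks.sex)

    def fit(self, seed: int | None = None, initial: SurgicalPlan | None = None) -> "PlanningResults":
        result = optimize(
            self.landmarks,
            self.spec,
            self.bounds,
            self.intervals,
            self.config,
            seed=seed,
            segments=self.segments,
            initial=initial,
        )
        return PlanningResults(self, result)


class PlanningResults:
    """Fitted planning outcome: best plan, objective, trace, diagnostics."""

    def __init__(self, model: SurgicalPlanner, result: OptimResult):
        self.model = model
        self.result = result

    @property
    def plan(self) -> SurgicalPlan:
        return self.result.plan

    @property
    def objective(self) -> float:
        return self.result.objective

    @property
    def trace(self) -> np.ndarray:
        return self.result.trace

    @property
    def seed(self) -> int | None:
        return self.result.seed

    def profile_before(self):
        return compute_profile(self.model.landmarks)

    def profile_after(self):
        moved = apply_plan(self.model.landmarks, self.plan, self.model.segments)
        return compute_profile(moved)

    def interact(self, overrides: Mapping[str, float], seed: int | None = None) -> "PlanningResults":
        """Adjust targets per expert preference and re-optimize, warm-started
        from the current best plan."""
        new_spec = adjust_targets(
            self.model.spec, overrides, self.model.intervals, self.model.landmarks.sex
        )
        refitted = SurgicalPlanner(
            self.model.landmarks,
            self.model.intervals,
            new_spec,
            self.model.bounds,
            self.model.config,
            self.model.segments,
        )
        return refitted.fit(seed=seed, initial=self.plan)

    def summary(self) -> str:
        """Plain-text report: plan parameters and pre/post measurements."""
        import pandas as pd

        sex = self.model.landmarks.sex
        before = self.profile_before()
        after = self.profile_after()
        targets, _, _ = self.model.spec.resolve(self.model.intervals, sex)
        rows = []
        for m, t in zip(self.model.spec.measurements, targets):
            low, high = self.model.intervals.bounds(m, sex)
            rows.append(
                {
                    "measurement": m,
                    "before": round(before[m], 2),
                    "after": round(after[m], 2),
                    "target": round(t, 2),
                    "interval": f"[{low}, {high}]",
                }
            )
        table = pd.DataFrame(rows).to_string(index=False)
        params = pd.DataFrame(
            {"parameter": PLAN_PARAM_NAMES, "value": np.round(self.plan.to_vector(), 3)}
        ).to_string(index=False)
        return (
            "Surgical plan (aABC)\n"
            f"objective: {self.objective:.6g}  cycles: {self.result.cycles}  "
            f"seed: {self.seed}\n\n" + params + "\n\n" + table + "\n"
        )
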