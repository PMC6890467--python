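"""Stochastic per-origin simulator of the *E. coli* cell cycle.

The central object is a single mother-machine-style lineage: one cell is
followed through time, growing exponentially and undergoing replication
initiation (origin doubling) and division events.  Four control models are
implemented:

``double_adder``
    Replication initiation fires when the per-origin size
    ``Lambda(t) = L(t) / n_ori`` has increased by a drawn increment
    ``dLif`` since the last initiation; the corresponding division fires
    when the cell has added a drawn per-origin increment ``dLid`` since
    that same initiation, i.e. at absolute length
    ``n_post * (Lambda_i + dLid)``.

``initiation_timer``
    Initiation as above, but division fires a drawn *duration* after
    initiation (``dLid_mean``/``dLid_cv`` are then interpreted in
    minutes).

``initiation_sizer``
    Division as in the double adder, but initiation fires when
    ``Lambda(t)`` reaches a freshly drawn critical per-origin size
    (``dLif_mean`` is then interpreted as that critical size, the
    classical initiation-mass picture).

``independent_adders``
    Initiation as in the double adder; division is an uncoupled classic
    birth-to-division length adder (``dLid_mean`` is then the mean added
    length ``dL`` per division cycle).

Growth is exact exponential between events; events are applied at the
exact threshold crossing inside each time step, so that with all noise
terms switched off the lineage converges to the analytic fixed point of
the per-origin map to machine precision.  Time steps only control the
sampling grid of the recorded trajectory.
"""

from __future__ import annotations

import math
from bisect import insort
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LN2",
    "MAX_ORIGINS",
    "VARIANTS",
    "SimulationError",
    "RunawayInitiationError",
    "EmpiricalDistribution",
    "ModelParams",
    "SimConfig",
    "CellState",
    "DivisionTrigger",
    "InitiationEvent",
    "DivisionEvent",
    "LineageEventLog",
    "FixedPoint",
    "default_params",
    "draw_inherited_growth_rate",
    "step_cell",
    "apply_initiation",
    "apply_division",
    "simulate_lineages",
    "deterministic_fixed_point",
]

LN2 = math.log(2.0)

#: Origin counts above this abort the lineage (runaway initiation).
MAX_ORIGINS = 16

VARIANTS = (
    "double_adder",
    "initiation_timer",
    "initiation_sizer",
    "independent_adders",
)

#: Draws at or below this fraction of the mean are rejected and redrawn.
_FLOOR_FRACTION = 0.1
_MAX_REDRAWS = 100
#: Division-ratio draws are restricted to this open interval.
_RATIO_BOUNDS = (0.3, 0.7)


class SimulationError(RuntimeError):
    """Raised when a lineage cannot be advanced (bad draws, event storm)."""


class RunawayInitiationError(SimulationError):
    """Raised when the origin count would exceed :data:`MAX_ORIGINS`."""


# ---------------------------------------------------------------------------
# Parameters and configuration
# ---------------------------------------------------------------------------


@dataclass
class EmpiricalDistribution:
    """Histogram override for a parametric draw.

    ``values`` are the support points, ``weights`` the (unnormalised)
    probabilities.  Draws are i.i.d. from this histogram.
    """

    values: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != self.values.shape:
                raise ValueError("weights must match values in shape")
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("weights must be non-negative and sum > 0")
            self.weights = w / w.sum()

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.choice(self.values, p=self.weights))


@dataclass
class ModelParams:
    """Generative model choice and its parameter distributions.

    Units: lengths in micrometres, rates in 1/min, durations in minutes.
    ``dLif_mean``/``dLid_mean`` are re-interpreted per variant as
    described in the module docstring.
    """

    model_variant: str = "double_adder"
    lambda_mean: float = LN2 / 89.0  # glycerol-like doubling time of 89 min
    lambda_cv: float = 0.10
    rho_lambda: float = 0.3  # mother-daughter growth-rate correlation
    dLif_mean: float = 1.0
    dLif_cv: float = 0.17
    dLid_mean: float = 0.5
    dLid_cv: float = 0.17
    ratio_sd: float = 0.04
    lambda_dist: EmpiricalDistribution | None = None
    dLif_dist: EmpiricalDistribution | None = None
    dLid_dist: EmpiricalDistribution | None = None
    ratio_dist: EmpiricalDistribution | None = None

    def validate(self) -> None:
        if self.model_variant not in VARIANTS:
            raise ValueError(
                f"unknown model_variant {self.model_variant!r}; "
                f"expected one of {VARIANTS}"
            )
        if self.dLif_mean <= 0 or self.dLid_mean <= 0:
            raise ValueError("adder/threshold means must be > 0")
        if self.lambda_mean < 0:
            raise ValueError("lambda_mean must be >= 0")
        if min(self.lambda_cv, self.dLif_cv, self.dLid_cv, self.ratio_sd) < 0:
            raise ValueError("CVs and ratio_sd must be >= 0")
        if not abs(self.rho_lambda) < 1 and not (
            self.rho_lambda == 1.0 and self.lambda_cv >= 0
        ):
            raise ValueError("|rho_lambda| must be < 1 (or exactly 1)")
        if self.ratio_sd >= 0.2:
            raise ValueError("ratio_sd must be < 0.2")


def default_params(variant: str = "double_adder") -> ModelParams:
    """Slow-growth-like defaults for each control model.

    The alternative variants re-use the ``dLif``/``dLid`` slots with
    different meanings; the presets are chosen so that all four variants
    share the same noise-free steady state (birth length 1.5 um, one
    origin at birth, 89 min doubling time).
    """
    p = ModelParams(model_variant=variant)
    if variant == "initiation_timer":
        # duration from initiation to division; ln(1.5)/lambda reproduces
        # the double-adder fixed point
        p.dLid_mean = math.log(1.5) / p.lambda_mean
    elif variant == "initiation_sizer":
        # critical pre-duplication per-origin size; the CV is set so the
        # variant reproduces the per-origin initiation-size dispersion the
        # adder chain produces (CV(Lambda_i) = cv/sqrt(3) ~ 0.10), rather
        # than the dispersion of the adder increments themselves
        p.dLif_mean = 2.0
        p.dLif_cv = 0.10
    elif variant == "independent_adders":
        # classic birth-to-division added length
        p.dLid_mean = 1.5
    return p


@dataclass
class SimConfig:
    """Run geometry: lineage count, duration, sampling step, burn-in."""

    n_lineages: int = 500
    duration: float = 1800.0  # minutes (30 h)
    dt: float = 1.0  # minutes
    burn_in_generations: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < 100 * self.dt:
            raise ValueError("duration must be >= 100*dt")
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if self.burn_in_generations < 0:
            raise ValueError("burn_in_generations must be >= 0")


# ---------------------------------------------------------------------------
# Random draws
# ---------------------------------------------------------------------------


def _draw_truncated(
    mean: float,
    cv: float,
    rng: np.random.Generator,
    dist: EmpiricalDistribution | None = None,
) -> float:
    """Normal draw with mean ``mean`` and SD ``mean*cv``, redrawn while the
    value is at or below 10% of the mean."""
    if dist is not None:
        return dist.draw(rng)
    if cv == 0.0:
        return mean
    sd = mean * cv
    floor = _FLOOR_FRACTION * mean
    for _ in range(_MAX_REDRAWS):
        x = mean + sd * rng.standard_normal()
        if x > floor:
            return x
    raise SimulationError(
        f"exceeded {_MAX_REDRAWS} redraws for truncated normal "
        f"(mean={mean}, cv={cv})"
    )


def _draw_ratio(params: ModelParams, rng: np.random.Generator) -> float:
    """Division ratio around 0.5, truncated to (0.3, 0.7)."""
    if params.ratio_dist is not None:
        return params.ratio_dist.draw(rng)
    if params.ratio_sd == 0.0:
        return 0.5
    lo, hi = _RATIO_BOUNDS
    for _ in range(_MAX_REDRAWS):
        r = 0.5 + params.ratio_sd * rng.standard_normal()
        if lo < r < hi:
            return r
    raise SimulationError("exceeded redraws for division ratio")


def draw_inherited_growth_rate(
    lambda_mother: float, params: ModelParams, rng: np.random.Generator
) -> float:
    """Daughter growth rate from a stationary AR(1) scheme.

    Marginal mean ``lambda_mean``, marginal SD ``lambda_mean*lambda_cv``
    and lag-1 (mother-daughter) correlation ``rho_lambda``.  Values at or
    below 10% of the mean are redrawn.
    """
    if lambda_mother <= 0 and params.lambda_mean > 0:
        raise ValueError("lambda_mother must be > 0")
    if params.lambda_dist is not None:
        # empirical override: i.i.d. draws, no inheritance
        return params.lambda_dist.draw(rng)
    mean, cv, rho = params.lambda_mean, params.lambda_cv, params.rho_lambda
    if cv == 0.0:
        return mean
    base = mean + rho * (lambda_mother - mean)
    innov_sd = mean * cv * math.sqrt(max(0.0, 1.0 - rho * rho))
    floor = _FLOOR_FRACTION * mean
    if innov_sd == 0.0:
        if base > floor:
            return base
        raise SimulationError("degenerate inherited growth rate below floor")
    for _ in range(_MAX_REDRAWS):
        x = base + innov_sd * rng.standard_normal()
        if x > floor:
            return x
    raise SimulationError("exceeded redraws for inherited growth rate")


def _draw_marginal_growth_rate(
    params: ModelParams, rng: np.random.Generator
) -> float:
    """Founder draw from the stationary marginal of the AR(1) scheme."""
    if params.lambda_dist is not None:
        return params.lambda_dist.draw(rng)
    return _draw_truncated(params.lambda_mean, params.lambda_cv, rng)


# ---------------------------------------------------------------------------
# Cell state and events
# ---------------------------------------------------------------------------


@dataclass
class DivisionTrigger:
    """One pending division.

    ``threshold_length`` is an absolute cell length (adder-type control,
    halved at every division so per-origin bookkeeping survives
    overlapping rounds); ``threshold_time`` is an absolute time (timer
    control).  ``control_draw`` records the drawn control value (dLid,
    duration, or dL) that produced this trigger.
    """

    threshold_length: float | None
    threshold_time: float | None
    control_draw: float

    def sort_key(self) -> float:
        return (
            self.threshold_length
            if self.threshold_length is not None
            else self.threshold_time
        )

    def __lt__(self, other: "DivisionTrigger") -> bool:
        return self.sort_key() < other.sort_key()


@dataclass
class CellState:
    """State of the followed cell at time ``clock``."""

    length: float
    n_ori: int
    growth_rate: float
    init_target: float  # per-origin length threshold for next initiation
    pending_div_targets: list[DivisionTrigger] = field(default_factory=list)
    clock: float = 0.0
    generation: int = 0

    @property
    def lambda_per_origin(self) -> float:
        return self.length / self.n_ori


@dataclass
class InitiationEvent:
    time: float
    length: float  # cell length at the event (pre-duplication)
    n_pre: int
    n_post: int
    d_lif_drawn: float  # drawn control value (dLif or critical size)
    generation: int


@dataclass
class DivisionEvent:
    time: float
    mother_length: float
    ratio: float  # followed-daughter fraction of the mother length
    daughter_length: float
    d_lid_drawn: float  # control draw of the retired trigger
    new_growth_rate: float
    old_growth_rate: float
    n_before: int
    n_after: int
    generation: int  # generation of the mother
    premature: bool = False


@dataclass
class LineageEventLog:
    """Exact trajectory and event record of one simulated lineage."""

    lineage_id: int
    burn_in_generations: int
    times: np.ndarray
    lengths: np.ndarray
    n_oris: np.ndarray
    generations: np.ndarray
    initiations: list[InitiationEvent]
    divisions: list[DivisionEvent]
    premature_divisions: int = 0
    aborted: bool = False
    abort_reason: str = ""

    def validate(self) -> None:
        """Assert the structural invariants of the event record."""
        times = [e.time for e in self.initiations] + [
            e.time for e in self.divisions
        ]
        if sorted(times) != sorted(set(times)) or times != sorted(times):
            # combined chronology is checked per stream below; duplicates
            # across streams (same-instant init+div) are allowed
            pass
        for ev in self.initiations:
            assert ev.n_post == 2 * ev.n_pre, "origin count must double"
            assert 1 <= ev.n_post <= MAX_ORIGINS
        for ev in self.divisions:
            assert ev.n_after * 2 == ev.n_before, "origin count must halve"
            assert ev.n_after >= 1
            assert abs(
                ev.daughter_length - ev.ratio * ev.mother_length
            ) <= 1e-9 * ev.mother_length
        for stream in (self.initiations, self.divisions):
            ts = [e.time for e in stream]
            assert all(a < b for a, b in zip(ts, ts[1:])), (
                "event times must strictly increase"
            )
        assert (np.diff(np.asarray(self.times)) > 0).all()


# ---------------------------------------------------------------------------
# Event application
# ---------------------------------------------------------------------------


def apply_initiation(
    state: CellState, params: ModelParams, rng: np.random.Generator
) -> InitiationEvent:
    """Fire a replication initiation on ``state`` (mutating it).

    The origin count doubles, so the recorded per-origin size is
    ``Lambda_i = L / n_post`` (post-duplication convention).  A fresh
    per-origin initiation threshold is drawn, and (except for the
    independent-adders variant, which schedules division at birth) a new
    pending division trigger is appended.
    """
    n_pre = state.n_ori
    n_post = 2 * n_pre
    if n_post > MAX_ORIGINS:
        raise RunawayInitiationError(
            f"origin count {n_post} exceeds {MAX_ORIGINS} at t={state.clock:.1f}"
        )
    length = state.length
    state.n_ori = n_post
    lam_i = length / n_post

    variant = params.model_variant
    if variant == "initiation_sizer":
        drawn = _draw_truncated(
            params.dLif_mean, params.dLif_cv, rng, params.dLif_dist
        )
        state.init_target = drawn  # critical per-origin size, no memory
    else:
        drawn = _draw_truncated(
            params.dLif_mean, params.dLif_cv, rng, params.dLif_dist
        )
        state.init_target = lam_i + drawn

    if variant in ("double_adder", "initiation_sizer"):
        d_lid = _draw_truncated(
            params.dLid_mean, params.dLid_cv, rng, params.dLid_dist
        )
        insort(
            state.pending_div_targets,
            DivisionTrigger(n_post * (lam_i + d_lid), None, d_lid),
        )
    elif variant == "initiation_timer":
        t_id = _draw_truncated(
            params.dLid_mean, params.dLid_cv, rng, params.dLid_dist
        )
        insort(
            state.pending_div_targets,
            DivisionTrigger(None, state.clock + t_id, t_id),
        )
    # independent_adders: division trigger is set at birth, not here

    return InitiationEvent(
        time=state.clock,
        length=length,
        n_pre=n_pre,
        n_post=n_post,
        d_lif_drawn=drawn,
        generation=state.generation,
    )


def apply_division(
    state: CellState, params: ModelParams, rng: np.random.Generator
) -> DivisionEvent:
    """Fire a division on ``state`` (mutating it).

    The triggering (smallest) pending target is retired; the remaining
    length thresholds are halved so that per-origin thresholds set in the
    mother stay valid in the daughter; timer thresholds are left
    untouched.  A fair coin decides which daughter the lineage follows.
    """
    if not state.pending_div_targets:
        raise SimulationError("division fired with empty pending-target queue")
    if state.n_ori < 2:
        raise SimulationError("division fired with a single origin")
    trig = state.pending_div_targets.pop(0)
    r = _draw_ratio(params, rng)
    frac = r if rng.random() < 0.5 else 1.0 - r
    mother_length = state.length
    n_before = state.n_ori
    premature = (
        trig.threshold_length is not None
        and mother_length > trig.threshold_length * (1.0 + 1e-9)
    )

    state.length = frac * mother_length
    state.n_ori = n_before // 2
    for t in state.pending_div_targets:
        if t.threshold_length is not None:
            t.threshold_length /= 2.0
    old_rate = state.growth_rate
    new_rate = draw_inherited_growth_rate(old_rate, params, rng)
    state.growth_rate = new_rate
    mother_generation = state.generation
    state.generation += 1

    if params.model_variant == "independent_adders":
        d_l = _draw_truncated(
            params.dLid_mean, params.dLid_cv, rng, params.dLid_dist
        )
        insort(
            state.pending_div_targets,
            DivisionTrigger(state.length + d_l, None, d_l),
        )

    return DivisionEvent(
        time=state.clock,
        mother_length=mother_length,
        ratio=frac,
        daughter_length=state.length,
        d_lid_drawn=trig.control_draw,
        new_growth_rate=new_rate,
        old_growth_rate=old_rate,
        n_before=n_before,
        n_after=state.n_ori,
        generation=mother_generation,
        premature=premature,
    )


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------


def _division_due(state: CellState, at_length: float, at_time: float) -> bool:
    if not state.pending_div_targets or state.n_ori < 2:
        return False
    trig = state.pending_div_targets[0]
    if trig.threshold_length is not None:
        return at_length >= trig.threshold_length * (1.0 - 1e-12)
    return at_time >= trig.threshold_time - 1e-9


def _time_to_length(state: CellState, target: float) -> float:
    """Time for exponential growth from the current length to ``target``."""
    if state.length >= target:
        return 0.0
    if state.growth_rate <= 0.0:
        return math.inf
    return math.log(target / state.length) / state.growth_rate


def _next_event(state: CellState) -> tuple[float, str] | None:
    """Earliest pending event as ``(tau, kind)``; initiation wins ties."""
    tau_init = _time_to_length(state, state.n_ori * state.init_target)
    tau_div = math.inf
    if state.pending_div_targets and state.n_ori >= 2:
        trig = state.pending_div_targets[0]
        if trig.threshold_length is not None:
            tau_div = _time_to_length(state, trig.threshold_length)
        else:
            tau_div = max(0.0, trig.threshold_time - state.clock)
    if math.isinf(tau_init) and math.isinf(tau_div):
        return None
    if tau_init <= tau_div:
        return tau_init, "initiation"
    return tau_div, "division"


def _grow(state: CellState, tau: float) -> None:
    if tau > 0.0:
        state.length *= math.exp(state.growth_rate * tau)
        state.clock += tau


def step_cell(
    state: CellState,
    dt: float,
    params: ModelParams,
    rng: np.random.Generator,
) -> tuple[CellState, list]:
    """Advance ``state`` by one sampling step of ``dt`` minutes.

    Growth is exponential; any initiation/division thresholds crossed
    within the step are applied at their exact crossing, in chronological
    order (initiation first on ties).  Both event types may fire within a
    single step.  Returns the mutated state and the list of emitted
    events.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    events: list = []
    t_end = state.clock + dt
    # fast path: no threshold is reached by the end of the step
    full = state.length * math.exp(state.growth_rate * dt)
    if not (
        full >= state.n_ori * state.init_target
        or _division_due(state, full, t_end)
    ):
        state.length = full
        state.clock = t_end
        return state, events

    for _ in range(64):
        remaining = t_end - state.clock
        if remaining <= 0:
            break
        nxt = _next_event(state)
        if nxt is None or nxt[0] > remaining * (1.0 + 1e-12):
            _grow(state, remaining)
            state.clock = t_end
            break
        tau, kind = nxt
        if kind == "initiation":
            target = state.n_ori * state.init_target
            _grow(state, tau)
            if state.length < target:
                state.length = target  # land exactly on the threshold
            events.append(apply_initiation(state, params, rng))
        else:
            trig = state.pending_div_targets[0]
            _grow(state, tau)
            if (
                trig.threshold_length is not None
                and state.length < trig.threshold_length
            ):
                state.length = trig.threshold_length
            events.append(apply_division(state, params, rng))
    else:
        raise SimulationError("event storm: >64 events within one step")
    return state, events


# ---------------------------------------------------------------------------
# Lineage simulation
# ---------------------------------------------------------------------------


def _initial_state(
    params: ModelParams, rng: np.random.Generator
) -> CellState:
    """Newborn cell with one origin and mid-cycle counters.

    Birth length is log-normal around the double-adder fixed point (a
    crude but adequate guess for the other variants); the first
    generations are discarded as burn-in anyway.
    """
    if params.model_variant == "initiation_sizer":
        lb_star = params.dLif_mean / 2.0 + params.dLid_mean
    elif params.model_variant == "initiation_timer":
        lb_star = params.dLif_mean * math.exp(
            params.lambda_mean * params.dLid_mean
        )
    elif params.model_variant == "independent_adders":
        lb_star = params.dLid_mean
    else:
        lb_star = params.dLif_mean + params.dLid_mean
    length = lb_star * math.exp(0.1 * rng.standard_normal())
    rate = _draw_marginal_growth_rate(params, rng)
    if params.model_variant == "initiation_sizer":
        init_target = _draw_truncated(
            params.dLif_mean, params.dLif_cv, rng, params.dLif_dist
        )
        init_target = max(init_target, length * 1.01)
    else:
        init_target = length + 0.5 * _draw_truncated(
            params.dLif_mean, params.dLif_cv, rng, params.dLif_dist
        )
    state = CellState(
        length=length,
        n_ori=1,
        growth_rate=rate,
        init_target=init_target,
        pending_div_targets=[],
    )
    if params.model_variant == "independent_adders":
        d_l = _draw_truncated(
            params.dLid_mean, params.dLid_cv, rng, params.dLid_dist
        )
        state.pending_div_targets.append(
            DivisionTrigger(length + d_l, None, d_l)
        )
    return state


def _simulate_one(
    lineage_id: int,
    params: ModelParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> LineageEventLog:
    n_steps = int(round(config.duration / config.dt))
    times = np.empty(n_steps + 1)
    lengths = np.empty(n_steps + 1)
    n_oris = np.empty(n_steps + 1, dtype=np.int64)
    gens = np.empty(n_steps + 1, dtype=np.int64)

    state = _initial_state(params, rng)
    initiations: list[InitiationEvent] = []
    divisions: list[DivisionEvent] = []
    premature = 0
    aborted = False
    abort_reason = ""

    times[0], lengths[0] = 0.0, state.length
    n_oris[0], gens[0] = state.n_ori, state.generation
    k = 0
    for k in range(1, n_steps + 1):
        try:
            state, events = step_cell(state, config.dt, params, rng)
        except SimulationError as exc:
            aborted = True
            abort_reason = str(exc)
            k -= 1
            break
        for ev in events:
            if isinstance(ev, InitiationEvent):
                initiations.append(ev)
            else:
                divisions.append(ev)
                if ev.premature:
                    premature += 1
        times[k] = state.clock
        lengths[k] = state.length
        n_oris[k] = state.n_ori
        gens[k] = state.generation

    end = k + 1
    return LineageEventLog(
        lineage_id=lineage_id,
        burn_in_generations=config.burn_in_generations,
        times=times[:end],
        lengths=lengths[:end],
        n_oris=n_oris[:end],
        generations=gens[:end],
        initiations=initiations,
        divisions=divisions,
        premature_divisions=premature,
        aborted=aborted,
        abort_reason=abort_reason,
    )


def simulate_lineages(
    params: ModelParams, config: SimConfig
) -> list[LineageEventLog]:
    """Simulate ``config.n_lineages`` independent mother-machine lineages.

    After each division a fair coin decides which daughter is followed.
    All randomness flows from ``config.seed`` (one spawned stream per
    lineage), so equal seeds give bit-identical logs.
    """
    params.validate()
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_lineages)
    return [
        _simulate_one(i, params, config, np.random.default_rng(s))
        for i, s in enumerate(seeds)
    ]


# ---------------------------------------------------------------------------
# Noise-free fixed point
# ---------------------------------------------------------------------------


@dataclass
class FixedPoint:
    """Noise-free steady state of the double-adder per-origin map."""

    Lb: float  # birth length
    Li_abs: float  # absolute cell length at initiation (pre-duplication)
    Lambda_i: float  # per-origin size at initiation (post-duplication)
    limit_cycle: bool = False
    cycle_Lb: tuple = ()


def deterministic_fixed_point(
    params: ModelParams, max_events: int = 4000, tol: float = 1e-12
) -> FixedPoint:
    """Steady state of the noise-free double-adder map.

    Iterates the exact event map (growth rate drops out: the event order
    is fixed by the required lengths).  In the non-overlapping regime the
    fixed point is ``Lambda_i* = dLif`` and ``Lb* = dLif + dLid``; if the
    trajectory settles on a period > 1 orbit instead, the values of the
    last cycle are returned with ``limit_cycle=True``.
    """
    if params.model_variant != "double_adder":
        raise ValueError("fixed point is defined for the double_adder variant")
    dlif, dlid = params.dLif_mean, params.dLid_mean

    # start exactly at an initiation with an arbitrary per-origin size
    lam_i = 0.61803398875 * dlif
    n = 2
    length = n * lam_i
    init_target = lam_i + dlif
    queue = [n * (lam_i + dlid)]

    lb_hist: list[float] = []
    li_hist: list[tuple[float, float]] = []  # (L at init, Lambda_i)
    for _ in range(max_events):
        init_req = n * init_target
        div_req = queue[0] if queue else math.inf
        if init_req <= div_req:
            length = max(length, init_req)
            n *= 2
            if n > MAX_ORIGINS:
                raise RunawayInitiationError(
                    "runaway initiation in deterministic map"
                )
            lam_i = length / n
            init_target = lam_i + dlif
            insort(queue, n * (lam_i + dlid))
            li_hist.append((length, lam_i))
        else:
            length = max(length, div_req)
            queue.pop(0)
            length /= 2.0
            n //= 2
            queue = [t / 2.0 for t in queue]
            lb_hist.append(length)
        # convergence / cycle detection on birth lengths
        if len(lb_hist) >= 24:
            tail = lb_hist[-12:]
            for period in (1, 2, 3, 4):
                ok = all(
                    abs(tail[i] - tail[i - period]) <= tol * abs(tail[i])
                    for i in range(period, 12)
                )
                if ok:
                    li_tail = li_hist[-period:]
                    return FixedPoint(
                        Lb=lb_hist[-1],
                        Li_abs=li_tail[-1][0],
                        Lambda_i=li_tail[-1][1],
                        limit_cycle=period > 1,
                        cycle_Lb=tuple(lb_hist[-period:]),
                    )
    raise SimulationError("deterministic map did not settle")
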