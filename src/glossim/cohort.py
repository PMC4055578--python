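"""The hunger-cycle cohort: movement, recruitment to baits, death, starvation.

A cohort of flies that has just fed moves about the habitat for up to
six days.  Daily flight-step allocations rise as hunger sharpens
(150, 300, 600, 1200, 2400 steps on days 1-5, 1350 on day 6; 6000 per
cycle) and each day alternates 25 *host-searching* steps, in which
flies respond to stationary baits, with 25 *general* steps in which
they do not.

Every step applies, in order (the per-step stages of the calculation):

1. start-of-step numbers;
2. natural losses: background mortality (3%/day spread geometrically
   over the day's steps) and feeding on unmapped wild hosts
   (probability ``p_wild * f(day)`` per step);
3. recruitment of flies already inside a bait's stimulus footprint
   (host-searching steps only), in proportion to the per-cell
   stimulation fraction;
4. orthogonal dispersal of the remaining flies;
5. recruitment of flies that have just stepped into stimulus cells;
6. partition of recruited flies: a fraction ``f`` responds effectively
   (fed/caught/killed -- removed and tallied per bait), the rest joins
   the bait's *inactive pool* of flies recovering near it;
7. clock advance; at the end of each 25-step host-searching block the
   inactive pools are released evenly over the good-habitat cells of
   each bait's visual footprint.

``f`` is 0.6 for capture devices (electric pen, per capture-efficiency
estimates) and rises 0.1 -> 0.6 over days 1-6 for probing responses
(feeding, targets).  Flies still unfed at the end of day 6 starve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baits import BaitSpec, StimulusFootprint, stimulus_footprint
from .kinematics import DiffusionOperator, DispersalParams, FlyField, stabilize
from .landscape import VegetationGrid

DEFAULT_DAILY_STEPS = (150, 300, 600, 1200, 2400, 1350)
FEEDING_F = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
CAPTURE_F = 0.6


@dataclass(frozen=True)
class StepSchedule:
    """Day-by-day step counts with the 25/25 host-searching alternation."""

    daily_steps: tuple[int, ...] = DEFAULT_DAILY_STEPS
    block_size: int = 25
    mobility_multiplier: float = 1.0

    def steps_on_day(self, day: int) -> int:
        """Steps allotted on cycle day ``day`` (1-based), scaled by the
        mobility multiplier and rounded to whole 25/25 block pairs."""
        base = self.daily_steps[day - 1] * self.mobility_multiplier
        pair = 2 * self.block_size
        return max(pair, int(round(base / pair)) * pair)

    def is_host_searching(self, step_in_day: int) -> bool:
        """Blocks alternate through the day, beginning with host-searching."""
        return (step_in_day // self.block_size) % 2 == 0

    def is_block_end(self, step_in_day: int) -> bool:
        """True on the last host-searching step of a 25-step block."""
        return (self.is_host_searching(step_in_day)
                and step_in_day % self.block_size == self.block_size - 1)

    @property
    def n_days(self) -> int:
        return len(self.daily_steps)

    @property
    def steps_per_cycle(self) -> int:
        return sum(self.steps_on_day(d) for d in range(1, self.n_days + 1))


@dataclass(frozen=True)
class ResponseSchedule:
    """Probability ``f`` of an effective close-range response to a bait."""

    mode: str = "day_schedule"          # "day_schedule" or "fixed_f"
    f_by_day: tuple[float, ...] = FEEDING_F
    f_fixed: float = CAPTURE_F

    def f(self, day: int) -> float:
        if self.mode == "fixed_f":
            return self.f_fixed
        return self.f_by_day[min(day, len(self.f_by_day)) - 1]


FEEDING_RESPONSE = ResponseSchedule("day_schedule")
CAPTURE_RESPONSE = ResponseSchedule("fixed_f")


@dataclass(frozen=True)
class CohortParams:
    """Background rates of the cohort model."""

    wild_host_step_prob: float = 0.00125   # encounter probability per step
    daily_mortality: float = 0.03          # other-cause mortality per day
    wild_f_by_day: tuple[float, ...] = FEEDING_F
    starvation_day: int = 6                # starvation at the end of this day

    def __post_init__(self) -> None:
        for p in (self.wild_host_step_prob, self.daily_mortality):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class DeployedBait:
    """A bait together with its (possibly day-dependent) footprint."""

    spec: BaitSpec
    footprints: list[StimulusFootprint]   # one per day, or a single entry
    response: ResponseSchedule = FEEDING_RESPONSE

    def footprint_for_day(self, day: int) -> StimulusFootprint:
        if len(self.footprints) == 1:
            return self.footprints[0]
        return self.footprints[day - 1]


def deploy(spec: BaitSpec, grid: VegetationGrid,
           response: ResponseSchedule = FEEDING_RESPONSE) -> DeployedBait:
    return DeployedBait(spec, [stimulus_footprint(spec, grid)], response)


@dataclass
class CohortState:
    """Active field, per-bait inactive pools and cumulative tallies."""

    active: np.ndarray
    pools: np.ndarray
    fed_wild: float = 0.0
    dead_other: float = 0.0
    starved: float = 0.0
    caught: np.ndarray = field(default_factory=lambda: np.zeros(0))
    day: int = 1
    step_in_day: int = 0
    initial_total: float = 0.0

    @property
    def active_total(self) -> float:
        return float(self.active.sum())

    @property
    def accounted_total(self) -> float:
        return (self.active_total + float(self.pools.sum()) + self.fed_wild
                + self.dead_other + self.starved + float(self.caught.sum()))


class BookkeepingError(RuntimeError):
    pass


@dataclass
class CycleResult:
    daily: pd.DataFrame
    state: CohortState

    @property
    def caught_total(self) -> float:
        return float(self.state.caught.sum())

    @property
    def starved_fraction(self) -> float:
        return self.state.starved / self.state.initial_total


class CohortSimulation:
    """Deterministic engine stepping a cohort through its hunger cycle.

    ``presence`` controls when located baits operate: ``"always"``
    (targets, natural hosts) or ``"second_half"`` (field-experiment
    baits present only for the second half of each day's step periods,
    the afternoon of the field analogy).
    """

    def __init__(self, grid: VegetationGrid, baits: list[DeployedBait] = (),
                 schedule: StepSchedule | None = None,
                 params: CohortParams | None = None,
                 dispersal: DispersalParams | None = None,
                 presence: str = "always",
                 standing_recruitment: str = "arrivals",
                 check_tolerance: float = 1e-9):
        grid.validate(strict=False)
        if presence not in ("always", "second_half"):
            raise ValueError("presence must be 'always' or 'second_half'")
        self.grid = grid
        self.baits = list(baits)
        self.schedule = schedule or StepSchedule()
        self.params = params or CohortParams()
        self.op = DiffusionOperator(grid, dispersal)
        self._stay_flat = self.op._stay.reshape(-1)
        if standing_recruitment not in ("arrivals", "every_step", "block_start"):
            raise ValueError("standing_recruitment must be 'arrivals', "
                             "'every_step' or 'block_start'")
        self.presence = presence
        self.standing_recruitment = standing_recruitment
        self.check_tolerance = check_tolerance
        self._day_cache: int | None = None

    # -- per-day precomputation -------------------------------------------
    def _prepare_day(self, day: int) -> None:
        if self._day_cache == day:
            return
        idx_parts, frac_parts, bid_parts = [], [], []
        rel_idx_parts, rel_bid_parts = [], []
        ncols = self.grid.n_cols
        seen: set[int] = set()
        for b, bait in enumerate(self.baits):
            fp = bait.footprint_for_day(day)
            flat = fp.rows * ncols + fp.cols
            overlap = seen.intersection(flat.tolist())
            if overlap:
                raise ValueError("stimulus footprints of deployed baits "
                                 "overlap; separate the baits")
            seen.update(flat.tolist())
            idx_parts.append(flat)
            frac_parts.append(fp.fraction)
            bid_parts.append(np.full(flat.size, b))
            rr, rc = fp.release_cells(self.grid)
            if rr.size == 0:  # fall back to habitable footprint cells
                hab = self.grid.entry[fp.rows, fp.cols] > 0
                rr, rc = fp.rows[hab], fp.cols[hab]
            if rr.size == 0:
                raise ValueError(f"bait {bait.spec.kind} at "
                                 f"{bait.spec.position} has no habitable "
                                 "release cell")
            rel_idx_parts.append(rr * ncols + rc)
            rel_bid_parts.append(np.full(rr.size, b))
        if self.baits:
            self._stim_idx = np.concatenate(idx_parts)
            self._stim_frac = np.concatenate(frac_parts)
            self._stim_bid = np.concatenate(bid_parts)
            self._rel_idx = np.concatenate(rel_idx_parts)
            self._rel_bid = np.concatenate(rel_bid_parts)
            self._rel_counts = np.bincount(self._rel_bid, minlength=len(self.baits))
            self._f_today = np.array([b.response.f(day) for b in self.baits])
        self._day_cache = day

    def _bait_active(self, day: int, step_in_day: int) -> bool:
        if not self.baits:
            return False
        if self.presence == "always":
            return True
        return step_in_day >= self.schedule.steps_on_day(day) // 2

    # -- state ------------------------------------------------------------
    def initial_state(self, initial: FlyField | np.ndarray | None = None) -> CohortState:
        if initial is None:
            initial = stabilize(self.grid)
        density = (initial.density if isinstance(initial, FlyField)
                   else np.asarray(initial, dtype=float)).copy()
        if density.shape != self.grid.shape:
            raise ValueError("initial field shape does not match grid")
        return CohortState(active=density, pools=np.zeros(len(self.baits)),
                           caught=np.zeros(len(self.baits)),
                           initial_total=float(density.sum()))

    # -- the seven-stage step ---------------------------------------------
    def step(self, state: CohortState) -> CohortState:
        """Advance one step period (stages 1-7) in place."""
        day = state.day
        sched = self.schedule
        n_day = sched.steps_on_day(day)
        self._prepare_day(day)
        A = state.active

        # stage 2: natural losses at the start of the step period
        surv = (1.0 - self.params.daily_mortality) ** (1.0 / n_day)
        total = A.sum()
        state.dead_other += total * (1.0 - surv)
        wild = (self.params.wild_host_step_prob
                * self.params.wild_f_by_day[min(day, len(self.params.wild_f_by_day)) - 1])
        state.fed_wild += total * surv * wild
        A *= surv * (1.0 - wild)

        searching = sched.is_host_searching(state.step_in_day)
        active_baits = searching and self._bait_active(day, state.step_in_day)

        # stage 3: recruit flies already inside stimulus footprints.
        # A sub-cell stimulus (lizard, tiny target) covers a fixed part
        # of its cell, so a fly perched in the uncovered part is not
        # re-stimulated just by the clock ticking.  The default
        # "arrivals" semantics offers the stimulus to the standing
        # occupants when a host-searching block opens, and thereafter
        # to every fly arriving at the cell center -- whether stepping
        # in from a neighbor or bounced back from a failed crossing.
        # "every_step" re-offers standing refusers at every step;
        # "block_start" offers entrants only (bounce-backs excluded).
        # All three coincide exactly for whole-cell (fraction 1.0)
        # stimuli, which empty their cells every step.
        if active_baits:
            flat = A.reshape(-1)
            offer_standing = (self.standing_recruitment == "every_step"
                              or state.step_in_day % sched.block_size == 0)
            if offer_standing:
                take = flat[self._stim_idx] * self._stim_frac
                flat[self._stim_idx] -= take
                recruited = np.bincount(self._stim_bid, weights=take,
                                        minlength=len(self.baits))
            else:
                recruited = np.zeros(len(self.baits))
            if self.standing_recruitment == "arrivals":
                # only non-movers (probability 1-h) keep their perch
                stayed = flat[self._stim_idx] * (1.0 - self.op.params.h)
            else:
                stayed = flat[self._stim_idx] * self._stay_flat[self._stim_idx]
        # stage 4: orthogonal dispersal
        state.active = A = self.op.step(A)
        # stage 5: recruit flies that have just arrived in stimulus cells
        if active_baits:
            flat = A.reshape(-1)
            entered = flat[self._stim_idx] - stayed
            take = entered * self._stim_frac
            flat[self._stim_idx] -= take
            recruited += np.bincount(self._stim_bid, weights=take,
                                     minlength=len(self.baits))
            # stage 6: effective responders vs temporarily inactive flies
            state.caught += self._f_today * recruited
            state.pools += (1.0 - self._f_today) * recruited

        # stage 7: advance clock; release inactive pools at block end
        if self.baits and sched.is_block_end(state.step_in_day) and state.pools.any():
            share = state.pools[self._rel_bid] / self._rel_counts[self._rel_bid]
            np.add.at(A.reshape(-1), self._rel_idx, share)
            state.pools[:] = 0.0
        state.step_in_day += 1
        if state.step_in_day >= n_day:
            state.step_in_day = 0
            state.day += 1
            self._day_cache = None

        drift = abs(state.accounted_total - state.initial_total)
        if drift > self.check_tolerance * max(1.0, state.initial_total):
            raise BookkeepingError(f"bookkeeping identity violated by {drift:.3e}")
        return state

    # -- whole days / cycles ----------------------------------------------
    def run(self, state: CohortState | None = None,
            initial: FlyField | np.ndarray | None = None,
            end_day: int | None = None) -> CycleResult:
        """Run from the state's current day to the end of ``end_day``.

        If the run reaches the end of the starvation day (day 6), all
        remaining active flies are tallied as starved.
        """
        if state is None:
            state = self.initial_state(initial)
        end_day = end_day if end_day is not None else self.schedule.n_days
        records = []
        while state.day <= end_day:
            day = state.day
            n_day = self.schedule.steps_on_day(day)
            while state.day == day:
                self.step(state)
            records.append({
                "day": day, "steps": n_day,
                "fed_wild": state.fed_wild,
                "caught": float(state.caught.sum()),
                "dead_other": state.dead_other,
                "active_remaining": state.active_total,
            })
        if end_day >= self.params.starvation_day:
            state.starved += state.active_total + float(state.pools.sum())
            state.active[:] = 0.0
            state.pools[:] = 0.0
            if records:
                records[-1]["active_remaining"] = 0.0
        daily = pd.DataFrame.from_records(records)
        if not daily.empty:
            daily["starved"] = [0.0] * (len(daily) - 1) + [state.starved]
        return CycleResult(daily, state)


def run_cycle(grid: VegetationGrid, baits: list[DeployedBait] = (),
              schedule: StepSchedule | None = None,
              params: CohortParams | None = None,
              initial: FlyField | np.ndarray | None = None,
              presence: str = "always",
              dispersal: DispersalParams | None = None,
              end_day: int | None = None,
              standing_recruitment: str = "arrivals") -> CycleResult:
    """Run one cohort through (part of) its 6-day hunger cycle."""
    sim = CohortSimulation(grid, baits, schedule, params, dispersal, presence,
                           standing_recruitment)
    return sim.run(initial=initial, end_day=end_day)


def starvation_probability(grid: VegetationGrid, baits: list[DeployedBait],
                           day_completed: int,
                           schedule: StepSchedule | None = None,
                           params: CohortParams | None = None,
                           presence: str = "always",
                           standing_recruitment: str = "arrivals") -> float:
    """Probability that flies unfed after ``day_completed`` days starve.

    The cohort is run (with its hosts) to the end of that day; the
    still-active, unfed field is renormalized and continued to the end
    of day 6.  The returned probability is starved / (starved + fed):
    death from causes other than starvation is treated as
    non-informative censoring of a fly's feed-or-starve fate.
    """
    if not 1 <= day_completed <= 5:
        raise ValueError("day_completed must be between 1 and 5")
    schedule = schedule or StepSchedule()
    params = params or CohortParams()
    sim = CohortSimulation(grid, baits, schedule, params, presence=presence,
                           standing_recruitment=standing_recruitment)
    head = sim.run(end_day=day_completed)
    unfed = head.state.active
    if unfed.sum() <= 0:
        raise ValueError("no flies remain unfed at the requested day")
    tail_state = sim.initial_state(unfed / unfed.sum())
    tail_state.day = day_completed + 1
    tail = sim.run(state=tail_state)
    starved = tail.state.starved
    fed = float(tail.state.caught.sum()) + tail.state.fed_wild
    return starved / (starved + fed)


def goal_seek_wild_prob(target_starved_fraction: float = 0.027,
                        bracket: tuple[float, float] = (1e-5, 1e-2),
                        schedule: StepSchedule | None = None,
                        daily_mortality: float = 0.03,
                        tol: float = 1e-6) -> float:
    """Wild-host encounter probability yielding a given starvation rate.

    Inverts the non-spatial cohort run (wild hosts only) by bisection;
    reproduces the calibration that fixed the encounter probability at
    0.00125 for a 2.7% per-cycle starvation rate.
    """
    from scipy.optimize import brentq

    grid = VegetationGrid(np.ones((1, 1)))

    def starved(p: float) -> float:
        params = CohortParams(wild_host_step_prob=p,
                              daily_mortality=daily_mortality)
        return run_cycle(grid, schedule=schedule, params=params).starved_fraction

    lo, hi = bracket
    f_lo = starved(lo) - target_starved_fraction
    f_hi = starved(hi) - target_starved_fraction
    if f_lo * f_hi > 0:
        raise ValueError("target starvation fraction not bracketed")
    return float(brentq(lambda p: starved(p) - target_starved_fraction,
                        lo, hi, rtol=tol))
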