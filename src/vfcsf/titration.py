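"""Adaptive contrast titration: best PEST and a weighted 3-down-1-up staircase.

Both procedures target 75% correct.  Best PEST places every trial at the
current maximum-likelihood estimate of the log10-contrast threshold under
the fixed-slope logistic CRF, maximized over a discrete candidate grid.
The weighted staircase lowers contrast after three consecutive correct
responses and raises it after any error, with the up/down step ratio
p*^3 / (1 - p*^3) at p* = 0.75 so that the expected drift vanishes at the
75%-correct contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .crf import CRFSpec, crf_probability, sample_response

__all__ = [
    "DEFAULT_GRID",
    "DEFAULT_START",
    "weighted_up_step",
    "PestState",
    "StaircaseState",
    "best_pest_next",
    "pest_update",
    "pest_estimate",
    "staircase_update",
    "run_titration",
    "TitrationResult",
]

DEFAULT_GRID = np.linspace(-3.0, 0.0, 61)
DEFAULT_START = -0.3  # ~0.5 linear contrast

_TARGET = 0.75
DOWN_STEP = 0.05


def weighted_up_step(down_step: float = DOWN_STEP, target: float = _TARGET) -> float:
    """Up step making a 3-down-1-up rule drift-free at ``target`` accuracy.

    Zero expected movement per response run requires
    ``up/down = target**3 / (1 - target**3)``.
    """
    q = target**3
    return down_step * q / (1.0 - q)


@dataclass
class PestState:
    """Running state of a best-PEST track.

    ``loglik`` accumulates, for every candidate threshold on ``grid``, the
    log-likelihood of the response history; it is updated incrementally per
    trial.
    """

    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    constants: CRFSpec = field(default_factory=CRFSpec)
    start_level: float = DEFAULT_START
    history: list[tuple[float, int]] = field(default_factory=list)
    loglik: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise ValueError("candidate grid must be nonempty")
        self.grid = np.sort(np.asarray(self.grid, dtype=float))
        self.loglik = np.zeros_like(self.grid)
        pending = list(self.history)
        self.history = []
        for c, y in pending:
            pest_update(self, c, y)


def best_pest_next(state: PestState) -> float:
    """Next placement: the ML threshold estimate (ties -> lower contrast).

    With no history, returns the configured start level snapped to the grid.
    """
    if not state.history:
        return float(state.grid[np.argmin(np.abs(state.grid - state.start_level))])
    return pest_estimate(state)


def pest_update(state: PestState, c: float, response: int) -> PestState:
    """Record one (contrast, response) observation; updates in place."""
    p = np.clip(
        crf_probability(c, state.constants, ct=state.grid), 1e-12, 1.0 - 1e-12
    )
    state.loglik += np.log(p) if response else np.log1p(-p)
    state.history.append((float(c), int(response)))
    return state


def pest_estimate(state: PestState) -> float:
    """Current ML threshold over the grid; ties break toward lower contrast."""
    return float(state.grid[int(np.argmax(state.loglik))])


@dataclass(frozen=True)
class StaircaseState:
    """Weighted 3-down-1-up staircase state (immutable; update returns a copy)."""

    level: float = DEFAULT_START
    down_step: float = DOWN_STEP
    up_step: float = weighted_up_step()
    counter: int = 0
    bounds: tuple[float, float] = (-3.0, 0.0)
    reversals: tuple[float, ...] = ()
    last_direction: int = 0  # +1 up, -1 down, 0 none yet

    def __post_init__(self) -> None:
        if not (0 <= self.counter <= 2):
            raise ValueError("counter must be in {0, 1, 2}")


def _move(state: StaircaseState, delta: float, direction: int) -> StaircaseState:
    lo, hi = state.bounds
    new_level = float(np.clip(state.level + delta, lo, hi))
    reversals = state.reversals
    if state.last_direction != 0 and direction != state.last_direction:
        reversals = reversals + (state.level,)
    return replace(
        state, level=new_level, counter=0, reversals=reversals, last_direction=direction
    )


def staircase_update(state: StaircaseState, response: int) -> StaircaseState:
    """Apply one response: error -> step up; 3rd consecutive correct -> step down."""
    if response:
        if state.counter == 2:
            return _move(state, -state.down_step, -1)
        return replace(state, counter=state.counter + 1)
    return _move(state, +state.up_step, +1)


@dataclass(frozen=True)
class TitrationResult:
    """Trial sequence and threshold estimates from one titration track."""

    contrasts: np.ndarray
    responses: np.ndarray
    estimate: float  # procedure-conventional estimate
    ml_estimate: float  # ML over the whole run (always recorded)
    reversal_estimate: float | None  # staircase only
    procedure: str


def run_titration(
    true_ct: float,
    procedure: str,
    n_trials: int,
    seed,
    constants: CRFSpec | None = None,
    grid: np.ndarray | None = None,
    start_level: float = DEFAULT_START,
) -> TitrationResult:
    """Run one adaptive track against a simulated observer.

    The observer's true log10 threshold at this (cell, SF) is ``true_ct``;
    responses are Bernoulli draws from the logistic CRF.  ``seed`` may be an
    int or a ``numpy`` SeedSequence/Generator.  Deterministic given the seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if procedure not in ("best_pest", "staircase"):
        raise ValueError("procedure must be 'best_pest' or 'staircase'")
    constants = constants or CRFSpec()
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pest = PestState(grid=grid.copy(), constants=constants, start_level=start_level)
    stair = StaircaseState(
        level=float(np.clip(start_level, grid.min(), grid.max())),
        bounds=(float(grid.min()), float(grid.max())),
    )

    contrasts = np.empty(n_trials)
    responses = np.empty(n_trials, dtype=np.int8)
    for i in range(n_trials):
        c = best_pest_next(pest) if procedure == "best_pest" else stair.level
        p = crf_probability(c, constants, ct=true_ct)
        y = sample_response(p, rng)
        contrasts[i] = c
        responses[i] = y
        pest_update(pest, c, y)  # ML track is maintained for both procedures
        if procedure == "staircase":
            stair = staircase_update(stair, y)

    ml = pest_estimate(pest)
    rev_est = None
    if procedure == "staircase":
        tail = stair.reversals[-6:]
        rev_est = float(np.mean(tail)) if tail else ml
        estimate = rev_est
    else:
        estimate = ml
    return TitrationResult(
        contrasts=contrasts,
        responses=responses,
        estimate=float(estimate),
        ml_estimate=float(ml),
        reversal_estimate=rev_est,
        procedure=procedure,
    )
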