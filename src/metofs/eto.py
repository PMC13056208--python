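"""Exponential-Trigonometric Optimization (ETO), implemented as printed.

ETO is a purely mathematical metaheuristic: exponential terms scale the
step sizes and trigonometric terms perturb candidate positions.  One run
consists of a dual-phase exploration stage (iterations ``t <= T``) and a
dual-phase exploitation stage (``t > T``), with a per-iteration changeover
value ``CM`` selecting the phase-1 or phase-2 update rule, and a
constrained-exploration (CE) schedule that occasionally shrinks the
sampling bounds around the two best solutions.

A note on the d1/d2 ratio: the printed definitions give ``d2 = -d1``
exactly, so the ratio is the constant -1 wherever defined (0/0 at cosine
zeros).  It is implemented as the guarded constant -1 everywhere, which
makes ``tan(d1/d2) = tan(-1)`` and ``c = exp(tan(-1))`` constants.  This
follows the formulas as printed rather than any upstream variant.

Draw conventions (the source leaves them open): branch choices
(q1, q2, q3, q4) are drawn once per solution; step magnitudes are drawn
per dimension, matching the element-wise subscripting of the update rules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .optim_core import (
    Objective,
    OptimizerResult,
    Population,
    RngStream,
    SearchSpace,
    clip_to_bounds,
    evaluate_and_update_best,
    init_population,
    register_optimizer,
)

logger = logging.getLogger("metofs")

#: guarded value of d1/d2 (the printed d1, d2 are exact negatives)
D_RATIO = -1.0
TAN_D_RATIO = math.tan(D_RATIO)

__all__ = [
    "EtoParams",
    "EtoState",
    "EtoCoefficients",
    "D_RATIO",
    "TAN_D_RATIO",
    "compute_d_pair",
    "compute_cm",
    "transition_iteration",
    "ce_first",
    "ce_next_value",
    "ce_update_bounds",
    "compute_alphas",
    "explore_phase1",
    "explore_phase2",
    "exploit_phase1",
    "exploit_phase2",
    "phase_coefficients",
    "eto_step",
    "eto_run",
]


@dataclass
class EtoParams:
    """ETO control parameters.

    ``a`` and ``b`` are the CE adjustment coefficients (4.6 and 1.55);
    ``ce_enabled`` allows switching the bound-adaptation events off.
    """

    tmax: int = 100
    a: float = 4.6
    b: float = 1.55
    ce_enabled: bool = True

    def __post_init__(self) -> None:
        if self.tmax < 1:
            raise ValueError("tmax must be >= 1")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("adjustment coefficients a, b must be positive")


@dataclass
class EtoState:
    """Per-iteration control state (d1, d2, CM, T, CE, adaptive bounds)."""

    t: int
    T: int
    ce_next: int
    d1: float = 0.0
    d2: float = 0.0
    cm: float = 0.0
    adaptive_lb: np.ndarray | None = None
    adaptive_ub: np.ndarray | None = None

    @classmethod
    def initial(cls, params: EtoParams, space: SearchSpace) -> "EtoState":
        return cls(
            t=1,
            T=transition_iteration(params.tmax),
            ce_next=ce_first(params.tmax, params.b),
            adaptive_lb=space.lb.copy(),
            adaptive_ub=space.ub.copy(),
        )


@dataclass
class EtoCoefficients:
    alpha1: float
    alpha2: float
    alpha3: float
    c: float


# ---------------------------------------------------------------------------
# Control quantities


def compute_d_pair(t: int, tmax: int) -> tuple[float, float]:
    """d1 = 0.1 cos(0.5 tmax (1 - t/tmax)) exp(-0.01 t);  d2 = -d1."""
    d1 = 0.1 * math.cos(0.5 * tmax * (1.0 - t / tmax)) * math.exp(-0.01 * t)
    return d1, -d1


def compute_cm(t: int, tmax: int, rng: RngStream) -> float:
    """Changeover value CM = 0.01 u (t/tmax)^tan(d1/d2), one draw.

    With the ratio guard the exponent is the constant tan(-1); CM > 1
    selects the phase-1 (broad) update, CM < 1 the phase-2 update.
    Undefined at t = 0 (zero base, negative exponent): callers start at 1.
    """
    if t < 1:
        raise ValueError("CM is undefined for t < 1")
    u = rng.uniform()
    return 0.01 * u * (t / tmax) ** TAN_D_RATIO


def transition_iteration(tmax: int) -> int:
    """Exploration/exploitation switch T = floor(1.2 + tmax / 2.25)."""
    return math.floor(1.2 + tmax / 2.25)


def ce_first(tmax: int, b: float = 1.55) -> int:
    """First CE event: CE_1 = floor(1 + tmax / b)."""
    return math.floor(1.0 + tmax / b)


def ce_next_value(ce_i: int, t: int, tmax: int, a: float = 4.6) -> int:
    """CE_{i+1} = floor(2 - 2 t (tmax - CE_i a)) + CE_i, as printed.

    The printed recurrence grows explosively, so in practice at most one
    adaptation event fires; values beyond tmax mean no further events.
    """
    return math.floor(2.0 - 2.0 * t * (tmax - ce_i * a)) + ce_i


def ce_update_bounds(
    state: EtoState, pop: Population, space: SearchSpace, rng: RngStream, tmax: int
) -> bool:
    """Shrink the adaptive sampling bounds around Xb / Xs (CE event).

    Per dimension j:  UB_j = r1 (1 - t/tmax) [r2 |Xb_j - Xs_j| + Xb_j]
    and LB_j = -(the same expression with fresh draws).  Draw order:
    r1 for UB (D), r2 for UB (D), r1 for LB (D), r2 for LB (D).

    The adapted bounds replace the *sampling* bounds used by donor
    operators; final feasibility clipping always uses the original box.
    Returns False (event skipped, bounds untouched) if the draw produces
    LB_j > UB_j in any dimension.
    """
    t = state.t
    gap = np.abs(pop.xb - pop.xs)
    shrink = 1.0 - t / tmax
    r1u = rng.uniform(space.d)
    r2u = rng.uniform(space.d)
    ub = r1u * shrink * (r2u * gap + pop.xb)
    r1l = rng.uniform(space.d)
    r2l = rng.uniform(space.d)
    lb = -(r1l * shrink * (r2l * gap + pop.xb))
    if np.any(lb > ub):
        logger.debug("CE event at t=%d skipped: degenerate bounds (LB > UB)", t)
        return False
    state.adaptive_lb = lb
    state.adaptive_ub = ub
    return True


def compute_alphas(t: int, tmax: int, rng: RngStream) -> EtoCoefficients:
    """All four weighting coefficients with independent draws.

    alpha1 = 3 u (t/tmax - 0.85) exp(d1/d2 - 1)
    alpha2 = u exp(tanh(1.5 (-t/tmax - 0.75) - u'))    (two fresh draws)
    alpha3 = 3 u (t/tmax - 0.85) exp(|d1/d2| - 1.3)
    c      = exp(tan(d1/d2))                            (constant, no draw)

    Draw order: alpha1 u, alpha2 u, alpha2 u', alpha3 u.
    """
    a1 = alpha1_value(t, tmax, rng.uniform())
    a2 = alpha2_value(t, tmax, rng.uniform(), rng.uniform())
    a3 = alpha3_value(t, tmax, rng.uniform())
    return EtoCoefficients(alpha1=a1, alpha2=a2, alpha3=a3, c=math.exp(TAN_D_RATIO))


def alpha1_value(t: int, tmax: int, u: float) -> float:
    return 3.0 * u * (t / tmax - 0.85) * math.exp(D_RATIO - 1.0)


def alpha2_value(t: int, tmax: int, u: float, u2: float) -> float:
    return u * math.exp(math.tanh(1.5 * (-t / tmax - 0.75) - u2))


def alpha3_value(t: int, tmax: int, u: float) -> float:
    return 3.0 * u * (t / tmax - 0.85) * math.exp(abs(D_RATIO) - 1.3)


# ---------------------------------------------------------------------------
# Position update rules (one row each; branch draw then per-dimension draws)


def explore_phase1(xi: np.ndarray, xb: np.ndarray, alpha1: float, rng: RngStream) -> np.ndarray:
    """First exploration rule: Xb +/- u alpha1 |Xb - Xi| (branch by q1)."""
    q1 = rng.uniform()
    u = rng.uniform(xi.size)
    step = u * alpha1 * np.abs(xb - xi)
    return xb + step if q1 <= 0.5 else xb - step


def explore_phase2(xi: np.ndarray, xb: np.ndarray, alpha2: float, rng: RngStream) -> np.ndarray:
    """Second exploration rule: Xi +/- 3 u alpha2 |Xb - Xi| (branch by q2)."""
    q2 = rng.uniform()
    u = rng.uniform(xi.size)
    step = 3.0 * u * alpha2 * np.abs(xb - xi)
    return xi + step if q2 <= 0.5 else xi - step


def exploit_phase1(xi: np.ndarray, xb: np.ndarray, alpha3: float, rng: RngStream) -> np.ndarray:
    """First exploitation rule: Xb +/- q4 alpha3 u |Xb - Xi| (branch by q3)."""
    q3 = rng.uniform()
    q4 = rng.uniform()
    u = rng.uniform(xi.size)
    step = q4 * alpha3 * u * np.abs(xb - xi)
    return xb + step if q3 <= 0.5 else xb - step


def exploit_phase2(
    xi: np.ndarray, xb: np.ndarray, alpha2: float, c: float, rng: RngStream
) -> np.ndarray:
    """Second exploitation rule: Xi + c u alpha2 |Xb - Xi| (no branch)."""
    u = rng.uniform(xi.size)
    return xi + c * u * alpha2 * np.abs(xb - xi)


def phase_coefficients(
    phase: str, cm: float, t: int, tmax: int, rng: RngStream
) -> EtoCoefficients:
    """Coefficients actually needed for this iteration's branch.

    Only the coefficient consumed by the selected update rule draws from
    the stream (alpha1 one draw, alpha2 two draws, alpha3 one draw, c
    none), keeping the draw sequence identical between a pure ETO step
    and the degenerate all-ETO hybrid step.
    """
    a1 = a2 = a3 = 0.0
    if phase == "explore":
        if cm > 1.0:
            a1 = alpha1_value(t, tmax, rng.uniform())
        else:
            a2 = alpha2_value(t, tmax, rng.uniform(), rng.uniform())
    else:
        if cm > 1.0:
            a3 = alpha3_value(t, tmax, rng.uniform())
        else:
            a2 = alpha2_value(t, tmax, rng.uniform(), rng.uniform())
    return EtoCoefficients(alpha1=a1, alpha2=a2, alpha3=a3, c=math.exp(TAN_D_RATIO))


def eto_update_row(
    xi: np.ndarray,
    xb: np.ndarray,
    phase: str,
    cm: float,
    coef: EtoCoefficients,
    rng: RngStream,
) -> np.ndarray:
    """Dispatch one row to the phase-1 / phase-2 rule selected by CM."""
    if phase == "explore":
        if cm > 1.0:
            return explore_phase1(xi, xb, coef.alpha1, rng)
        return explore_phase2(xi, xb, coef.alpha2, rng)
    if cm > 1.0:
        return exploit_phase1(xi, xb, coef.alpha3, rng)
    return exploit_phase2(xi, xb, coef.alpha2, coef.c, rng)


# ---------------------------------------------------------------------------
# Full step and run


def eto_step(
    pop: Population,
    state: EtoState,
    params: EtoParams,
    space: SearchSpace,
    f: Objective,
    rng: RngStream,
) -> tuple[Population, EtoState]:
    """One ETO iteration: bookkeeping, per-row update, clip, evaluate."""
    t, tmax = state.t, params.tmax
    state.d1, state.d2 = compute_d_pair(t, tmax)
    state.cm = compute_cm(t, tmax, rng)
    if params.ce_enabled and t == state.ce_next:
        ce_update_bounds(state, pop, space, rng, tmax)
        state.ce_next = ce_next_value(state.ce_next, t, tmax, params.a)
    phase = "explore" if t <= state.T else "exploit"
    coef = phase_coefficients(phase, state.cm, t, tmax, rng)
    new_x = np.empty_like(pop.x)
    for i in range(pop.n):
        new_x[i] = eto_update_row(pop.x[i], pop.xb, phase, state.cm, coef, rng)
    pop.x = clip_to_bounds(new_x, space)
    evaluate_and_update_best(pop, f)
    state.t += 1
    return pop, state


def eto_run(
    space: SearchSpace,
    objective: Objective,
    n: int = 20,
    tmax: int = 100,
    rng: RngStream | int | None = None,
    params: EtoParams | None = None,
) -> OptimizerResult:
    """Run ETO: init, evaluate, then ``tmax`` iterations of :func:`eto_step`."""
    if not isinstance(rng, (RngStream,)) and not hasattr(rng, "uniform"):
        rng = RngStream(rng)
    params = params or EtoParams(tmax=tmax)
    params.tmax = tmax
    pop = init_population(space, n, rng)
    evaluate_and_update_best(pop, objective)
    state = EtoState.initial(params, space)
    trace = np.empty(tmax)
    for t in range(1, tmax + 1):
        pop, state = eto_step(pop, state, params, space, objective, rng)
        trace[t - 1] = pop.fitb
    return OptimizerResult(xb=pop.xb, fitb=pop.fitb, trace=trace)


register_optimizer("eto", eto_run)
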