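"""METO: ETO control flow with fitness-proportional AOA injection and periodic GLS.

Each iteration keeps ETO's bookkeeping (d1/d2, CM, the CE bound
adaptation, the exploration/exploitation switch T) and then updates every
solution by one of two donors: solutions whose normalized fitness share
``P_i = Fit_i / sum(Fit)`` falls below a random threshold
``rp = Lp + r3 (Up - Lp)`` take the AOA operator of the current phase
(Division/Multiplication when exploring, Subtraction/Addition when
exploiting, using the CE-adapted sampling bounds); the remaining
solutions take the ETO operator of the phase, with ETO's own CM > 1 test
choosing the phase-1 or phase-2 variant.  Because the fitness here is a
minimization cost, better solutions carry *smaller* shares and are the
likelier AOA takers — implemented as printed, not "corrected".

Every iteration records the population into the GLS experience buffer;
whenever ``t`` is a multiple of the guidance period (10, per the
``rem(t, 10) == 0`` gate) a guidance event is attempted, itself gated on
the buffer's ``C > Cmax`` rule.

With the AOA branch forced off the draw sequence is identical to pure
ETO, so a METO run degenerates bitwise to an ETO run on the same seed
(the GLS gate permitting); forced on, every update is an AOA operator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .aoa import AoaParams, aoa_exploit, aoa_explore, compute_moa, compute_mop
from .eto import (
    EtoParams,
    EtoState,
    ce_next_value,
    ce_update_bounds,
    compute_cm,
    compute_d_pair,
    eto_update_row,
    phase_coefficients,
)
from .gls import ExperienceBuffer, GlsParams, gls_apply, record_experience
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

__all__ = [
    "MetoParams",
    "SelectionState",
    "selection_probabilities",
    "selection_threshold",
    "hybrid_update",
    "meto_step",
    "meto_run",
]


@dataclass
class MetoParams:
    """Hybrid parameters: the three constituents plus the guidance period."""

    eto: EtoParams = field(default_factory=EtoParams)
    aoa: AoaParams = field(default_factory=AoaParams)
    gls: GlsParams = field(default_factory=GlsParams)
    gls_period: int = 10
    #: "fitness" = Eq-style share-vs-threshold branch; "eto-only" /
    #: "aoa-only" force the degenerate modes (no threshold draw).
    injection: str = "fitness"

    def __post_init__(self) -> None:
        if self.gls_period < 1:
            raise ValueError("gls_period must be >= 1")
        if self.injection not in ("fitness", "eto-only", "aoa-only"):
            raise ValueError("injection must be 'fitness', 'eto-only' or 'aoa-only'")


@dataclass
class SelectionState:
    """Normalized fitness shares and the iteration's AOA-injection threshold."""

    p: np.ndarray
    lp: float
    up: float
    rp: float


def selection_probabilities(fit: np.ndarray) -> np.ndarray:
    """P_i = Fit_i / sum(Fit); an all-zero fitness vector falls back to 1/N."""
    fit = np.asarray(fit, dtype=float)
    if not np.all(np.isfinite(fit)):
        raise ValueError("fitness vector must be finite")
    total = fit.sum()
    if total == 0.0:
        logger.debug("degenerate zero-sum fitness; uniform selection shares")
        return np.full(fit.size, 1.0 / fit.size)
    return fit / total


def selection_threshold(p: np.ndarray, rng: RngStream) -> float:
    """rp = Lp + u (Up - Lp) with Lp/Up the min/max share (one draw)."""
    lp = float(np.min(p))
    up = float(np.max(p))
    return lp + rng.uniform() * (up - lp)


def hybrid_update(
    pop: Population,
    state: EtoState,
    sel: SelectionState | None,
    params: MetoParams,
    phase: str,
    mop: float,
    rng: RngStream,
) -> tuple[np.ndarray, dict]:
    """Row-wise donor dispatch for one iteration.

    Returns the unclipped new position matrix and the branch counts.
    ``sel`` is None in the forced degenerate modes.
    """
    coef = phase_coefficients(phase, state.cm, state.t, params.eto.tmax, rng)
    new_x = np.empty_like(pop.x)
    counts = {"aoa": 0, "eto": 0}
    for i in range(pop.n):
        if params.injection == "aoa-only":
            take_aoa = True
        elif params.injection == "eto-only":
            take_aoa = False
        else:
            take_aoa = sel.p[i] < sel.rp
        if take_aoa:
            if phase == "explore":
                new_x[i] = aoa_explore(
                    pop.xb, mop, state.adaptive_lb, state.adaptive_ub, params.aoa, rng
                )
            else:
                new_x[i] = aoa_exploit(
                    pop.xb, mop, state.adaptive_lb, state.adaptive_ub, params.aoa, rng
                )
            counts["aoa"] += 1
        else:
            new_x[i] = eto_update_row(pop.x[i], pop.xb, phase, state.cm, coef, rng)
            counts["eto"] += 1
    return new_x, counts


def meto_step(
    pop: Population,
    state: EtoState,
    buffer: ExperienceBuffer,
    params: MetoParams,
    space: SearchSpace,
    f: Objective,
    rng: RngStream,
) -> tuple[Population, EtoState, ExperienceBuffer, dict]:
    """One METO iteration (bookkeeping, hybrid update, experience, GLS gate)."""
    t, tmax = state.t, params.eto.tmax
    state.d1, state.d2 = compute_d_pair(t, tmax)
    state.cm = compute_cm(t, tmax, rng)
    if params.eto.ce_enabled and t == state.ce_next:
        ce_update_bounds(state, pop, space, rng, tmax)
        state.ce_next = ce_next_value(state.ce_next, t, tmax, params.eto.a)
    sel = None
    if params.injection == "fitness":
        p = selection_probabilities(pop.fit)
        rp = selection_threshold(p, rng)
        sel = SelectionState(p=p, lp=float(p.min()), up=float(p.max()), rp=rp)
    phase = "explore" if t <= state.T else "exploit"
    mop = compute_mop(t, tmax, params.aoa)
    new_x, counts = hybrid_update(pop, state, sel, params, phase, mop, rng)
    pop.x = clip_to_bounds(new_x, space)
    evaluate_and_update_best(pop, f)
    record_experience(buffer, pop)
    counts["gls_event"] = False
    if t % params.gls_period == 0:
        c_before = buffer.c
        pop, buffer = gls_apply(pop, buffer, space, params.gls, f, rng)
        counts["gls_event"] = buffer.c < c_before
    state.t += 1
    return pop, state, buffer, counts


def meto_run(
    space: SearchSpace,
    objective: Objective,
    n: int = 20,
    tmax: int = 100,
    rng: RngStream | int | None = None,
    params: MetoParams | None = None,
) -> OptimizerResult:
    """Run the METO hybrid under the shared optimizer contract.

    ``history`` carries per-iteration branch counts and GLS event flags
    for diagnostics (counts sum to N each iteration).
    """
    if not hasattr(rng, "uniform"):
        rng = RngStream(rng)
    params = params or MetoParams()
    params.eto.tmax = tmax
    pop = init_population(space, n, rng)
    evaluate_and_update_best(pop, objective)
    state = EtoState.initial(params.eto, space)
    buffer = ExperienceBuffer()
    trace = np.empty(tmax)
    history = {"aoa": [], "eto": [], "gls_event": []}
    for t in range(1, tmax + 1):
        pop, state, buffer, counts = meto_step(pop, state, buffer, params, space, objective, rng)
        trace[t - 1] = pop.fitb
        history["aoa"].append(counts["aoa"])
        history["eto"].append(counts["eto"])
        history["gls_event"].append(counts["gls_event"])
    return OptimizerResult(xb=pop.xb, fitb=pop.fitb, trace=trace, history=history)


register_optimizer("meto", meto_run)
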