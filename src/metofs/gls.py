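"""Guided Learning Strategy (GLS): dispersion feedback over an experience buffer.

GLS accumulates the visited population positions in a learning-experience
store.  Once the experience counter exceeds its cap, the dispersion of
the stored positions (a per-dimension population standard deviation,
normalized to the box width by B = 200/(UB - LB) and averaged over
dimensions) decides the guidance move: high dispersion (V0 above the
threshold) triggers a heavy-tailed exploitation jump around the best
solution, low dispersion a uniform exploration restart.  New candidates
replace current rows only when strictly not worse (greedy selection),
after which the buffer is cleared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .optim_core import (
    Objective,
    Population,
    RngStream,
    SearchSpace,
    clip_to_bounds,
)

logger = logging.getLogger("metofs")

__all__ = [
    "GlsParams",
    "ExperienceBuffer",
    "record_experience",
    "compute_v0",
    "gls_guidance",
    "gls_apply",
]

#: exclusion half-width around R = 0.5 (tan singularity), resampled
_TAN_GUARD = 1e-9


@dataclass
class GlsParams:
    """GLS parameters.

    The source states neither the experience cap nor the dispersion
    threshold; the defaults (cap = 10 N via ``cmax_factor`` when ``cmax``
    is None, threshold alpha = 1.0) are this package's documented choices
    and are fully configurable.
    """

    cmax: int | None = None
    cmax_factor: int = 10
    alpha: float = 1.0

    def resolved_cmax(self, n: int) -> int:
        c = self.cmax if self.cmax is not None else self.cmax_factor * n
        if c < n:
            raise ValueError("experience cap must be >= population size")
        return c


@dataclass
class ExperienceBuffer:
    """Ordered store of past position matrices with experience counter C."""

    records: list = field(default_factory=list)
    c: int = 0

    def clear(self) -> None:
        self.records.clear()
        self.c = 0


def record_experience(buffer: ExperienceBuffer, pop: Population) -> ExperienceBuffer:
    """Append the current positions; C increases by the population size."""
    buffer.records.append(pop.x.copy())
    buffer.c += pop.n
    return buffer


def compute_v0(buffer: ExperienceBuffer, space: SearchSpace, params: GlsParams) -> float:
    """Dispersion V0 = mean_j [ std_j(stored positions) * B_j ], B_j = 200/(UB_j - LB_j).

    The standard deviation uses the population (1/n) convention.  V0 is
    zero iff every stored record is identical per dimension.
    """
    if not buffer.records:
        raise ValueError("experience buffer is empty")
    stacked = np.vstack(buffer.records)  # (C, D)
    std = stacked.std(axis=0, ddof=0)
    b = 200.0 / (space.ub - space.lb)
    return float(np.mean(std * b))


def gls_guidance(
    xb: np.ndarray,
    v0: float,
    space: SearchSpace,
    params: GlsParams,
    n: int,
    rng: RngStream,
) -> np.ndarray:
    """Generate N guidance candidates.

    V0 > alpha (dispersed -> exploit):  Xn_ij = Xb_j + tan(R pi) (UB_j - LB_j) / V0
    else (collapsed -> explore):        Xn_ij = LB_j + R (UB_j - LB_j)

    R is drawn per element and resampled while |R - 0.5| < 1e-9 (tan
    singularity guard).  The printed exploration branch has no LB offset;
    the offset is added here so non-zero lower bounds stay inside the box
    (identical on [0, 1], the feature-selection case).
    """
    r = rng.uniform((n, space.d))
    while True:
        bad = np.abs(r - 0.5) < _TAN_GUARD
        if not bad.any():
            break
        r[bad] = rng.uniform(int(bad.sum()))
    width = space.ub - space.lb
    if v0 > params.alpha:
        return xb + np.tan(r * np.pi) * width / v0
    return space.lb + r * width


def gls_apply(
    pop: Population,
    buffer: ExperienceBuffer,
    space: SearchSpace,
    params: GlsParams,
    f: Objective,
    rng: RngStream,
) -> tuple[Population, ExperienceBuffer]:
    """Guidance event, gated on C > Cmax; no-op otherwise.

    On trigger: compute V0, generate Xn, clip, evaluate, keep per-row the
    better of X and Xn (greedy), update the elitist best, clear the buffer.
    """
    if buffer.c <= params.resolved_cmax(pop.n):
        return pop, buffer
    v0 = compute_v0(buffer, space, params)
    xn = clip_to_bounds(gls_guidance(pop.xb, v0, space, params, pop.n, rng), space)
    for i in range(pop.n):
        fn = f(xn[i])
        if not np.isfinite(fn):
            raise ValueError(f"objective returned non-finite fitness for guidance row {i}")
        if fn < pop.fit[i]:
            pop.x[i] = xn[i]
            pop.fit[i] = fn
        if fn < pop.fitb:
            pop.fitb = fn
            pop.xb = xn[i].copy()
    order = np.argsort(pop.fit, kind="stable")
    pop.xs = pop.x[int(order[1])].copy()
    buffer.clear()
    return pop, buffer
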