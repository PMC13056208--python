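"""Shared search-space, population, RNG and objective contracts.

Every population-based optimizer in this package (ETO, AOA, the METO
hybrid) works on the same primitives: a box-bounded real search space,
an ``N x D`` population with an elitist best-so-far record, a uniform
random stream that can be stubbed for oracle tests, and a minimization
objective.  Keeping these in one place guarantees that the optimizers
are interchangeable behind a single run contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np

logger = logging.getLogger("metofs")

__all__ = [
    "SearchSpace",
    "RngStream",
    "StubRng",
    "Objective",
    "Population",
    "OptimizerResult",
    "init_population",
    "clip_to_bounds",
    "evaluate_and_update_best",
    "child_seeds",
    "OPTIMIZER_REGISTRY",
    "register_optimizer",
    "get_optimizer",
]


# ---------------------------------------------------------------------------
# Search space


@dataclass(frozen=True)
class SearchSpace:
    """Box-bounded D-dimensional real search domain.

    Parameters
    ----------
    lb, ub
        Per-dimension lower/upper bounds.  ``lb[j] < ub[j]`` for all j.
    """

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        lb = np.asarray(self.lb, dtype=float)
        ub = np.asarray(self.ub, dtype=float)
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)
        if lb.ndim != 1 or ub.shape != lb.shape:
            raise ValueError("lb and ub must be 1-D vectors of equal length")
        if lb.size < 1:
            raise ValueError("dimension count must be >= 1")
        if not np.all(lb < ub):
            raise ValueError("every lower bound must be strictly below its upper bound")

    @property
    def d(self) -> int:
        return self.lb.size

    @classmethod
    def unit(cls, d: int) -> "SearchSpace":
        """The unit hypercube [0, 1]^d (feature-selection domain)."""
        return cls(np.zeros(d), np.ones(d))

    @classmethod
    def cube(cls, d: int, lo: float, hi: float) -> "SearchSpace":
        return cls(np.full(d, float(lo)), np.full(d, float(hi)))


# ---------------------------------------------------------------------------
# Random streams


class RngStream:
    """Uniform random stream with seed-reproducible draws.

    A thin wrapper around :class:`numpy.random.Generator` exposing only
    uniform draws (the algorithms consume nothing else).  Identical seeds
    produce identical draw sequences; child streams derived per run index
    are independent by :class:`numpy.random.SeedSequence` construction.
    """

    def __init__(self, seed: int | np.random.SeedSequence | None = None) -> None:
        self._gen = np.random.Generator(np.random.PCG64(seed))
        self.draw_count = 0

    def uniform(self, size: int | tuple | None = None) -> float | np.ndarray:
        """Uniform draw(s) on [0, 1)."""
        out = self._gen.random(size)
        self.draw_count += 1 if size is None else int(np.prod(np.atleast_1d(size)))
        return out


class StubRng:
    """Deterministic stand-in for :class:`RngStream` fed a fixed sequence.

    Used by the straight-line oracle tests: the same injected sequence is
    consumed by the implementation and by an independent hand computation.
    """

    def __init__(self, values) -> None:
        self._values = [float(v) for v in values]
        self._pos = 0

    def uniform(self, size: int | tuple | None = None):
        if size is None:
            return self._take(1)[0]
        shape = tuple(np.atleast_1d(size).astype(int))
        n = int(np.prod(shape))
        return np.array(self._take(n)).reshape(shape)

    def _take(self, n: int):
        if self._pos + n > len(self._values):
            raise RuntimeError("stub draw sequence exhausted")
        out = self._values[self._pos : self._pos + n]
        self._pos += n
        return out

    @property
    def remaining(self) -> int:
        return len(self._values) - self._pos


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# Objective


@dataclass
class Objective:
    """Minimization objective: real vector of length D -> finite real."""

    fn: Callable[[np.ndarray], float]
    name: str = "objective"
    known_optimum: Optional[float] = None

    def __call__(self, x: np.ndarray) -> float:
        return float(self.fn(np.asarray(x, dtype=float)))


def sphere_objective() -> Objective:
    """Sum-of-squares benchmark (known optimum 0)."""
    return Objective(lambda x: float(np.dot(x, x)), name="sphere", known_optimum=0.0)


# ---------------------------------------------------------------------------
# Population


@dataclass
class Population:
    """``N x D`` candidate positions with elitist best bookkeeping.

    ``xb``/``fitb`` are the best position/fitness over *all* evaluations so
    far (never replaced by a worse one); ``xs`` is the second-best position
    of the current population (ties broken by lowest row index).
    """

    x: np.ndarray
    fit: Optional[np.ndarray] = None
    xb: Optional[np.ndarray] = None
    fitb: float = np.inf
    xs: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def d(self) -> int:
        return self.x.shape[1]


def init_population(space: SearchSpace, n: int, rng: RngStream) -> Population:
    """Uniform random initialization ``X = (UB - LB) * u + LB``.

    Requires ``n >= 2`` so that a second-best solution exists.
    """
    if n < 2:
        raise ValueError("population size must be >= 2 (second-best undefined otherwise)")
    u = rng.uniform((n, space.d))
    x = (space.ub - space.lb) * u + space.lb
    return Population(x=x)


def clip_to_bounds(position: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Project a position (or row-stack of positions) onto the box."""
    position = np.asarray(position, dtype=float)
    if position.shape[-1] != space.d:
        raise ValueError("position length does not match search-space dimension")
    return np.clip(position, space.lb, space.ub)


def evaluate_and_update_best(pop: Population, f: Objective) -> Population:
    """Evaluate all rows and update the elitist best / current second-best.

    The global best is replaced only on strict improvement; ties among
    current rows resolve to the lowest row index.
    """
    fit = np.empty(pop.n)
    for i in range(pop.n):
        v = f(pop.x[i])
        if not np.isfinite(v):
            raise ValueError(f"objective returned non-finite fitness for solution {i}")
        fit[i] = v
    pop.fit = fit
    order = np.argsort(fit, kind="stable")
    best_i = int(order[0])
    if fit[best_i] < pop.fitb:
        pop.fitb = float(fit[best_i])
        pop.xb = pop.x[best_i].copy()
    if pop.xb is None:  # first evaluation with equal-to-inf guard
        pop.fitb = float(fit[best_i])
        pop.xb = pop.x[best_i].copy()
    second_i = int(order[1]) if pop.n > 1 else best_i
    pop.xs = pop.x[second_i].copy()
    return pop


# ---------------------------------------------------------------------------
# Optimizer run contract and plugin registry


@dataclass
class OptimizerResult:
    """Uniform output of every registered optimizer run."""

    xb: np.ndarray
    fitb: float
    trace: np.ndarray  # per-iteration best fitness (non-increasing)
    history: dict = field(default_factory=dict)


#: name -> runner(space, objective, n, tmax, rng, params=None) -> OptimizerResult
OPTIMIZER_REGISTRY: Dict[str, Callable] = {}


def register_optimizer(name: str, runner: Callable) -> None:
    """Register an optimizer under ``name`` (plugin slot for comparisons)."""
    OPTIMIZER_REGISTRY[name] = runner


def get_optimizer(name: str) -> Callable:
    try:
        return OPTIMIZER_REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(OPTIMIZER_REGISTRY))
        raise KeyError(f"unknown optimizer '{name}' (registered: {known})") from None
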