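"""Synthetic data generators for the full detection workflow.

Two generators emulate the two stages' inputs without any download:

* :func:`gen_feature_dataset` — a two-class Gaussian feature table
  standing in for the learned 100-dimensional representation: class 0 is
  standard normal; class 1 shifts a known subset of informative
  dimensions by ``delta`` within-class standard deviations.  Ground
  truth (the informative indices) is always returned.
* :func:`gen_roi_timeseries` — multi-subject ROI time series whose
  between-class difference lives purely in the correlation structure of
  one designated ROI pair, for exercising the connectivity stack.

Splits follow the study's 623/308/104-of-1,035 proportions
(0.602/0.298/0.100), stratified by label with largest-remainder
rounding.  All generators are seed-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import RoiTimeSeries
from .fs_wrapper import Dataset

__all__ = [
    "SynthSpec",
    "gen_feature_dataset",
    "gen_roi_timeseries",
    "make_splits",
    "DEFAULT_FRACTIONS",
]

#: training/validation/test proportions (623, 308, 104 of 1,035)
DEFAULT_FRACTIONS = (0.602, 0.298, 0.100)

_SPLIT_NAMES = ("train", "validation", "test")


@dataclass
class SynthSpec:
    """Study conditions for the synthetic feature table."""

    n: int = 600
    d: int = 100
    d_inf: int = 10
    delta: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.d_inf <= self.d):
            raise ValueError("informative count must lie in [0, D]")
        if self.delta < 0:
            raise ValueError("effect size delta must be non-negative")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class balance must lie in (0, 1)")


def _largest_remainder(total: int, fractions) -> list[int]:
    raw = np.asarray(fractions, dtype=float) * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    for k in range(short):
        base[order[k]] += 1
    return base.tolist()


def make_splits(
    n: int,
    fractions=DEFAULT_FRACTIONS,
    labels=None,
    seed: int = 0,
) -> np.ndarray:
    """Random train/validation/test assignment with largest-remainder sizes.

    With ``labels`` given the partition is stratified per class (each
    class is split by largest remainder, so e.g. 505 + 530 subjects under
    the default fractions yield the 623/308/104 totals); every split must
    then contain both classes.
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=object)
    if labels is None:
        groups = [np.arange(n)]
    else:
        labels = np.asarray(labels).astype(int)
        groups = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    for idx in groups:
        counts = _largest_remainder(idx.size, fractions)
        shuffled = rng.permutation(idx)
        pos = 0
        for name, c in zip(_SPLIT_NAMES, counts):
            assignment[shuffled[pos : pos + c]] = name
            pos += c
    if labels is not None:
        for name in _SPLIT_NAMES:
            sub = labels[assignment == name]
            if sub.size == 0 or len(np.unique(sub)) < 2:
                raise ValueError(f"split '{name}' lacks both classes; increase n")
    return assignment


def gen_feature_dataset(spec: SynthSpec) -> tuple[Dataset, dict]:
    """Two-class Gaussian feature table with planted informative dimensions.

    Returns the dataset (with stratified splits) and a ground-truth dict
    holding the informative feature indices and the generating spec.
    """
    rng = np.random.default_rng(spec.seed)
    n1 = int(round(spec.n * spec.class_balance))
    n0 = spec.n - n1
    labels = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    x = rng.standard_normal((spec.n, spec.d))
    informative = np.arange(spec.d_inf)  # leading block; order is immaterial
    x[n0:, informative] += spec.delta
    perm = rng.permutation(spec.n)
    x, labels = x[perm], labels[perm]
    split = make_splits(spec.n, labels=labels, seed=spec.seed)
    data = Dataset(features=x, labels=labels, split=split)
    truth = {"informative": informative.tolist(), "spec": spec}
    return data, truth


def gen_roi_timeseries(
    n_subjects: int = 40,
    r: int = 20,
    t: int = 200,
    coupling_delta: float = 0.5,
    base_coupling: float = 0.1,
    seed: int = 0,
) -> tuple[list[RoiTimeSeries], dict]:
    """Cohort of Gaussian ROI time series with a class-coupled ROI pair.

    All ROIs are independent standard normal except ROIs 0 and 1, whose
    correlation is ``base_coupling`` for class 0 and ``base_coupling +
    coupling_delta`` for class 1 (class 1 higher).  Half the subjects are
    class 1.  Returns the series plus ground truth (the coupled pair and
    the two correlations).
    """
    if r < 2 or t < 3:
        raise ValueError("need at least 2 ROIs and 3 time points")
    rho1 = base_coupling + coupling_delta
    if not (-1.0 < rho1 < 1.0) or not (-1.0 < base_coupling < 1.0):
        raise ValueError("couplings must stay inside (-1, 1)")
    rng = np.random.default_rng(seed)
    n1 = n_subjects // 2
    out = []
    for i in range(n_subjects):
        label = int(i >= n_subjects - n1)
        rho = rho1 if label else base_coupling
        z = rng.standard_normal((t, r))
        z[:, 1] = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
        out.append(RoiTimeSeries(z, subject_id=f"sub-{i:04d}", label=label))
    truth = {"pair": (0, 1), "rho0": base_coupling, "rho1": rho1}
    return out, truth
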