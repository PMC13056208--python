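"""Binary wrapper feature selection over METO (or any registered optimizer).

A continuous position in the unit hypercube is binarized into a feature
mask, the mask is scored by the misclassification rate of a K=5
nearest-neighbor classifier fit on the training split and evaluated on
the validation split, and the fitness blends that error with the
selected-feature ratio:

    Fit = rho * gamma + (1 - rho) * |BX| / D        (minimized)

The test split is touched exactly once, by :func:`evaluate_on_test` on
the final best mask.  The default binarization thresholds the position
at 0.5 (the standard transfer rule; the only reading under which the
fitness feeds back into the search); the literal coin-flip rule from the
source is available as ``binarization="literal-random"`` for fidelity
experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier

from .evaluation import MetricsReport, aggregate_runs, auc_rank, compute_metrics, confusion
from .meto import MetoParams
from .optim_core import Objective, RngStream, SearchSpace, get_optimizer

logger = logging.getLogger("metofs")

__all__ = [
    "Dataset",
    "FeatureMask",
    "FsConfig",
    "binarize",
    "knn_error",
    "fitness_value",
    "make_objective",
    "evaluate_on_test",
    "run_experiment",
    "ExperimentResult",
]

SPLITS = ("train", "validation", "test")


@dataclass
class Dataset:
    """Feature matrix with binary labels (ASD = 1) and a three-way split."""

    features: np.ndarray
    labels: np.ndarray
    split: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels).astype(int)
        self.split = np.asarray(self.split, dtype=object)
        n, d = self.features.shape
        if d < 1:
            raise ValueError("dataset needs at least one feature")
        if self.labels.shape != (n,) or self.split.shape != (n,):
            raise ValueError("labels/split length must match the feature rows")
        if np.isnan(self.features).any():
            raise ValueError("dataset contains missing values")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        for s in SPLITS:
            ys = self.labels[self.split == s]
            if ys.size == 0 or len(np.unique(ys)) < 2:
                raise ValueError(f"split '{s}' must contain both classes")

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def rows(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == split
        return self.features[m], self.labels[m]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label_col: str = "label",
                   split_col: str = "split") -> "Dataset":
        cols = [c for c in frame.columns if c not in (label_col, split_col)]
        return cls(frame[cols].to_numpy(float), frame[label_col].to_numpy(),
                   frame[split_col].to_numpy())

    @classmethod
    def from_csv(cls, path, **kw) -> "Dataset":
        return cls.from_frame(pd.read_csv(path), **kw)

    def to_frame(self) -> pd.DataFrame:
        d = self.d
        frame = pd.DataFrame(self.features, columns=[f"f{j}" for j in range(d)])
        frame["label"] = self.labels
        frame["split"] = self.split
        return frame


@dataclass
class FeatureMask:
    """Binary selection vector with at least one active feature."""

    bx: np.ndarray

    def __post_init__(self) -> None:
        self.bx = np.asarray(self.bx).astype(bool)
        if self.count < 1:
            raise ValueError("a feature mask must select at least one feature")

    @property
    def count(self) -> int:
        return int(self.bx.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bx)


@dataclass
class FsConfig:
    """Wrapper-FS configuration.

    ``rho`` balances classification error against the selected-feature
    ratio (error-dominant 0.99 default, standard wrapper practice);
    ``k`` is the KNN neighbor count (5, odd so binary votes never tie).
    """

    rho: float = 0.99
    k: int = 5
    binarization: str = "threshold"
    threshold: float = 0.5
    runs: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if self.k % 2 == 0 or self.k < 1:
            raise ValueError("K must be a positive odd integer")
        if self.binarization not in ("threshold", "literal-random"):
            raise ValueError("binarization must be 'threshold' or 'literal-random'")


def binarize(position: np.ndarray, cfg: FsConfig, rng: RngStream | None = None) -> FeatureMask:
    """Continuous position in [0, 1]^D -> binary mask.

    Threshold mode: BX_j = 1 iff position_j > threshold.  Literal-random
    mode: BX_j = 1 iff a fresh uniform draw < 0.5 (the printed rule,
    independent of the position).  An all-zero mask is repaired by
    forcing the coordinate with the largest position value.
    """
    position = np.asarray(position, dtype=float)
    if cfg.binarization == "literal-random":
        if rng is None:
            raise ValueError("literal-random binarization needs an RngStream")
        bx = rng.uniform(position.size) < 0.5
    else:
        bx = position > cfg.threshold
    if not bx.any():
        bx = bx.copy()
        bx[int(np.argmax(position))] = True
    return FeatureMask(bx)


def _knn(cfg: FsConfig) -> KNeighborsClassifier:
    return KNeighborsClassifier(n_neighbors=cfg.k, metric="euclidean")


def knn_error(data: Dataset, mask: FeatureMask, cfg: FsConfig) -> float:
    """Validation-split misclassification rate of KNN on the masked features."""
    xtr, ytr = data.rows("train")
    xva, yva = data.rows("validation")
    clf = _knn(cfg).fit(xtr[:, mask.bx], ytr)
    return float(np.mean(clf.predict(xva[:, mask.bx]) != yva))


def fitness_value(
    data: Dataset, position: np.ndarray, cfg: FsConfig, rng: RngStream | None = None
) -> float:
    """Fit = rho * gamma + (1 - rho) * count / D (a cost in [0, 1])."""
    mask = binarize(position, cfg, rng)
    gamma = knn_error(data, mask, cfg)
    return cfg.rho * gamma + (1.0 - cfg.rho) * (mask.count / data.d)


def make_objective(data: Dataset, cfg: FsConfig, rng: RngStream | None = None) -> Objective:
    """Wrap the wrapper-FS fitness as a minimization objective on [0, 1]^D."""
    return Objective(lambda pos: fitness_value(data, pos, cfg, rng), name="knn-wrapper-fs")


def evaluate_on_test(data: Dataset, mask: FeatureMask, cfg: FsConfig) -> MetricsReport:
    """Final, single evaluation of a mask on the held-out test split.

    KNN (K=5) is fit on the selected training features; AUC uses the
    positive-neighbor vote fraction as the score.
    """
    xtr, ytr = data.rows("train")
    xte, yte = data.rows("test")
    clf = _knn(cfg).fit(xtr[:, mask.bx], ytr)
    pred = clf.predict(xte[:, mask.bx])
    scores = clf.predict_proba(xte[:, mask.bx])[:, list(clf.classes_).index(1)]
    report = compute_metrics(confusion(yte, pred))
    report.auc = auc_rank(scores, yte)
    report.n_features = mask.count
    return report


@dataclass
class ExperimentResult:
    """Per-seed runs plus the Mean/StD/Best/Worst aggregate table."""

    runs: list = field(default_factory=list)
    summary: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([r["metrics"][name] for r in self.runs])


_METRICS = ("accuracy", "sensitivity", "precision", "fscore", "auc")


def run_experiment(
    data: Dataset,
    algorithm: str = "meto",
    params: MetoParams | object | None = None,
    cfg: FsConfig | None = None,
    seeds=(0,),
    n: int = 20,
    tmax: int = 100,
) -> ExperimentResult:
    """Multi-seed FS experiment driver.

    For each seed: run the named optimizer over [0, 1]^D with the wrapper
    fitness, binarize its final best position, evaluate once on the test
    split.  Metrics and the selected-feature count are aggregated into
    Mean/StD/Best/Worst rows (StD with the 1/n convention; best = min for
    the feature count).
    """
    cfg = cfg or FsConfig()
    if isinstance(seeds, int):
        seeds = list(range(seeds))
    runner = get_optimizer(algorithm)
    space = SearchSpace.unit(data.d)
    result = ExperimentResult(metadata={
        "algorithm": algorithm, "seeds": list(map(int, seeds)), "n": n, "tmax": tmax,
        "rho": cfg.rho, "k": cfg.k, "binarization": cfg.binarization,
    })
    for seed in seeds:
        rng = RngStream(int(seed))
        objective = make_objective(data, cfg, rng if cfg.binarization == "literal-random" else None)
        opt = runner(space, objective, n=n, tmax=tmax, rng=rng, params=params)
        mask = binarize(opt.xb, cfg, rng if cfg.binarization == "literal-random" else None)
        report = evaluate_on_test(data, mask, cfg)
        result.runs.append({
            "seed": int(seed),
            "fitb": float(opt.fitb),
            "trace": opt.trace.tolist(),
            "selected": mask.indices.tolist(),
            "metrics": report.as_dict(),
        })
        logger.info("run seed=%s fitb=%.4f n_features=%d accuracy=%.4f",
                    seed, opt.fitb, mask.count, report.accuracy)
    rows = {}
    for m in _METRICS:
        rows[m] = aggregate_runs(result.metric_values(m))
    rows["features"] = aggregate_runs(result.metric_values("n_features"),
                                      higher_is_better=False)
    result.summary = pd.DataFrame(rows).T[["mean", "std", "best", "worst"]]
    result.summary.columns = ["Mean", "StD", "Best", "Worst"]
    result.summary.index.name = "metric"
    return result
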