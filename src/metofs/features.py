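"""rs-fMRI connectivity feature stack.

Pipeline: per-subject ROI time series -> Pearson functional-connectivity
matrix -> strict-upper-triangle flattening (R(R-1)/2 entries) -> Fisher
criterion filter keeping the top 15% of features -> stacked sparse
denoising autoencoder (SSDAE) pre-training -> supervised MLP fine-tuning
whose first two layers start from the SSDAE encoder weights -> the final
100-unit hidden layer exported as the learned feature table.

The networks are compact numpy feed-forward models: sigmoid encoders with
a linear reconstruction decoder, mean-squared reconstruction loss plus a
KL-divergence sparsity penalty on the mean hidden activation, masking
noise on the autoencoder inputs, inverted dropout on hidden layers, and
plain minibatch gradient descent (SSDAE) / stochastic gradient descent
(MLP).  Layer sizes are configuration-driven so tests exercise scaled
versions of the documented 1000/600/100 defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("metofs")

__all__ = [
    "RoiTimeSeries",
    "SsdaeConfig",
    "MlpConfig",
    "pearson_fc",
    "flatten_upper",
    "fisher_score",
    "filter_top_fraction",
    "pretrain_ssdae",
    "finetune_mlp",
    "extract_learned_features",
    "connectivity_features",
    "MlpModel",
]


@dataclass
class RoiTimeSeries:
    """T x R matrix of per-ROI mean BOLD time series for one subject."""

    values: np.ndarray
    subject_id: str = ""
    label: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 3:
            raise ValueError("time series must be T x R with T >= 3")


# ---------------------------------------------------------------------------
# Connectivity


def pearson_fc(ts: RoiTimeSeries) -> np.ndarray:
    """Pearson correlation matrix between ROI time series.

    Symmetric with unit diagonal; zero-variance ROIs yield 0 correlations
    (logged) rather than NaN.
    """
    values = ts.values
    if values.shape[0] < 3:
        raise ValueError("need at least 3 time points for a correlation")
    # constant ROIs leave rounding residue in the covariance; flag explicitly
    std = values.std(axis=0)
    constant = std <= 1e-12 * (1.0 + np.abs(values.mean(axis=0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(values, rowvar=False)
    if constant.any() or np.isnan(fc).any():
        if constant.any():
            logger.warning("zero-variance ROI in subject %s; correlations set to 0",
                           ts.subject_id or "<unnamed>")
        fc = np.nan_to_num(fc, nan=0.0)
        fc[constant, :] = 0.0
        fc[:, constant] = 0.0
        np.fill_diagonal(fc, 1.0)
    return fc


def flatten_upper(fc: np.ndarray) -> np.ndarray:
    """Row-major strict upper triangle of a symmetric matrix: R(R-1)/2 entries."""
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError("connectivity matrix must be square")
    r = fc.shape[0]
    iu = np.triu_indices(r, k=1)
    return fc[iu]


def connectivity_features(series: list[RoiTimeSeries]) -> tuple[np.ndarray, np.ndarray]:
    """Stack flattened FC vectors for a cohort; returns (features, labels)."""
    feats = np.vstack([flatten_upper(pearson_fc(ts)) for ts in series])
    labels = np.array([ts.label for ts in series], dtype=int)
    return feats, labels


# ---------------------------------------------------------------------------
# Fisher-criterion filter


def fisher_score(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Two-class Fisher criterion per feature.

    score_j = [(m+_j - m_j)^2 + (m-_j - m_j)^2] / [var+_j + var-_j]
    with sample variances; a zero denominator scores 0.  (This is the
    feature-ranking "F-score" filter, distinct from the harmonic-mean
    F-score classification metric.)
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("Fisher score needs both classes present")
    pos, neg = features[labels == 1], features[labels == 0]
    m = features.mean(axis=0)
    mp, mn = pos.mean(axis=0), neg.mean(axis=0)
    vp = pos.var(axis=0, ddof=1) if pos.shape[0] > 1 else np.zeros(features.shape[1])
    vn = neg.var(axis=0, ddof=1) if neg.shape[0] > 1 else np.zeros(features.shape[1])
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = vp + vn
    out = np.zeros_like(num)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def filter_top_fraction(scores: np.ndarray, fraction: float = 0.15) -> np.ndarray:
    """Indices of the floor(fraction * d) highest-scoring features.

    Ties break toward the lower index; the returned indices are sorted
    ascending.  The floor convention reproduces the documented 1,000
    retained features for a 6,670-dimensional (116-ROI) vector.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    keep = int(np.floor(fraction * scores.size))
    keep = max(keep, 1)
    order = np.argsort(-scores, kind="stable")  # stable: ties -> lower index first
    return np.sort(order[:keep])


# ---------------------------------------------------------------------------
# SSDAE + MLP (numpy)


@dataclass
class SsdaeConfig:
    """Stacked sparse denoising autoencoder configuration.

    Defaults mirror the documented architecture (input -> 1000 -> 600,
    masking-noise fraction 0.2, sparsity target 0.05 with weight 1e-3,
    learning rate 0.001, batch 100, dropout 0.5, 700/1000 epochs for the
    two autoencoders).  Epoch counts are read as passes over the training
    split.
    """

    hidden_sizes: tuple[int, int] = (1000, 600)
    sparsity_target: float = 0.05
    sparsity_weight: float = 1e-3
    noise_fraction: float = 0.2
    lr: float = 0.001
    batch_size: int = 100
    epochs: tuple[int, int] = (700, 1000)
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.hidden_sizes[1] >= self.hidden_sizes[0]:
            raise ValueError("encoder sizes must decrease across the stack")
        if not (0.0 < self.sparsity_target < 1.0):
            raise ValueError("sparsity target must lie in (0, 1)")


@dataclass
class MlpConfig:
    """Fine-tuning MLP: hidden sizes (first two = SSDAE encoders) + 100-unit
    feature layer; SGD lr 0.0005, batch 10, dropout 0.3."""

    hidden_sizes: tuple[int, int, int] = (1000, 600, 100)
    lr: float = 0.0005
    batch_size: int = 10
    epochs: int = 100
    dropout: float = 0.3


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -40.0, 40.0)))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _train_dae(
    x: np.ndarray, hidden: int, cfg: SsdaeConfig, epochs: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """One denoising autoencoder: masking noise, sigmoid encoder, linear
    decoder, MSE + KL sparsity, minibatch gradient descent.  Returns the
    encoder weights/bias and the per-epoch loss trace."""
    n, d = x.shape
    w1 = _glorot(rng, d, hidden)
    b1 = np.zeros(hidden)
    w2 = _glorot(rng, hidden, d)
    b2 = np.zeros(d)
    rho_t = cfg.sparsity_target
    losses = []
    for _ in range(epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb = x[idx]
            m = xb.shape[0]
            noisy = xb * (rng.random(xb.shape) >= cfg.noise_fraction)
            h = _sigmoid(noisy @ w1 + b1)
            rho_hat = np.clip(h.mean(axis=0), 1e-6, 1.0 - 1e-6)
            if cfg.dropout > 0:
                keep = rng.random(h.shape) >= cfg.dropout
                h_fwd = h * keep / (1.0 - cfg.dropout)
            else:
                keep = None
                h_fwd = h
            recon = h_fwd @ w2 + b2
            err = recon - xb
            mse = float(np.mean(err**2))
            kl = float(np.sum(rho_t * np.log(rho_t / rho_hat)
                              + (1 - rho_t) * np.log((1 - rho_t) / (1 - rho_hat))))
            epoch_loss += (mse + cfg.sparsity_weight * kl) * m
            # backprop (loss normalized per batch element and feature)
            g_recon = 2.0 * err / (m * d)
            gw2 = h_fwd.T @ g_recon
            gb2 = g_recon.sum(axis=0)
            g_h = g_recon @ w2.T
            if keep is not None:
                g_h = g_h * keep / (1.0 - cfg.dropout)
            g_h += cfg.sparsity_weight * (-(rho_t / rho_hat)
                                          + (1 - rho_t) / (1 - rho_hat)) / m
            g_pre = g_h * h * (1.0 - h)
            gw1 = noisy.T @ g_pre
            gb1 = g_pre.sum(axis=0)
            w1 -= cfg.lr * gw1
            b1 -= cfg.lr * gb1
            w2 -= cfg.lr * gw2
            b2 -= cfg.lr * gb2
        losses.append(epoch_loss / n)
        if not np.isfinite(losses[-1]):
            raise FloatingPointError(f"non-finite autoencoder loss at epoch {len(losses)}")
    return w1, b1, losses


def pretrain_ssdae(
    features: np.ndarray, cfg: SsdaeConfig, rng: np.random.Generator | int | None = None
) -> dict:
    """Greedy layer-wise pre-training of the two denoising autoencoders.

    Returns encoder weights/biases for both layers plus loss traces.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.asarray(features, dtype=float)
    h1, h2 = cfg.hidden_sizes
    w1, b1, loss1 = _train_dae(x, h1, cfg, cfg.epochs[0], rng)
    enc1 = _sigmoid(x @ w1 + b1)
    w2, b2, loss2 = _train_dae(enc1, h2, cfg, cfg.epochs[1], rng)
    return {"w1": w1, "b1": b1, "w2": w2, "b2": b2, "loss1": loss1, "loss2": loss2}


@dataclass
class MlpModel:
    """Trained fine-tuning network (three sigmoid hidden layers + logistic head)."""

    weights: list
    biases: list
    config: MlpConfig
    loss_trace: list = field(default_factory=list)

    def hidden_activations(self, x: np.ndarray) -> np.ndarray:
        """Activations of the last hidden (feature) layer, one row per sample."""
        a = np.asarray(x, dtype=float)
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = _sigmoid(a @ w + b)
        return a

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        h = self.hidden_activations(x)
        return _sigmoid(h @ self.weights[-1] + self.biases[-1]).ravel()


def finetune_mlp(
    features: np.ndarray,
    labels: np.ndarray,
    ssdae: dict,
    cfg: MlpConfig,
    rng: np.random.Generator | int | None = None,
) -> MlpModel:
    """Supervised fine-tuning with SGD and cross-entropy.

    The first two hidden layers start from the SSDAE encoder weights
    (shape-checked); the third hidden layer and the logistic output head
    are freshly initialized.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(float)
    h1, h2, h3 = cfg.hidden_sizes
    if ssdae["w1"].shape != (x.shape[1], h1) or ssdae["w2"].shape != (h1, h2):
        raise ValueError("SSDAE encoder shapes do not match the MLP configuration")
    weights = [ssdae["w1"].copy(), ssdae["w2"].copy(), _glorot(rng, h2, h3),
               _glorot(rng, h3, 1)]
    biases = [ssdae["b1"].copy(), ssdae["b2"].copy(), np.zeros(h3), np.zeros(1)]
    n = x.shape[0]
    losses = []
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            m = xb.shape[0]
            acts = [xb]
            drops = []
            a = xb
            for li, (w, b) in enumerate(zip(weights[:-1], biases[:-1])):
                a = _sigmoid(a @ w + b)
                if cfg.dropout > 0:
                    keep = rng.random(a.shape) >= cfg.dropout
                    a = a * keep / (1.0 - cfg.dropout)
                    drops.append(keep)
                else:
                    drops.append(None)
                acts.append(a)
            logits = acts[-1] @ weights[-1] + biases[-1]
            p = _sigmoid(logits).ravel()
            p = np.clip(p, 1e-12, 1.0 - 1e-12)
            epoch_loss += float(-np.sum(yb * np.log(p) + (1 - yb) * np.log(1 - p)))
            g_logit = ((p - yb) / m)[:, None]
            g_w = [None] * len(weights)
            g_b = [None] * len(weights)
            g_w[-1] = acts[-1].T @ g_logit
            g_b[-1] = g_logit.sum(axis=0)
            g_a = g_logit @ weights[-1].T
            for li in range(len(weights) - 2, -1, -1):
                if drops[li] is not None:
                    g_a = g_a * drops[li] / (1.0 - cfg.dropout)
                    # pre-dropout sigmoid value on kept units (zero elsewhere)
                    a_sig = np.where(drops[li], acts[li + 1] * (1.0 - cfg.dropout), 0.0)
                else:
                    a_sig = acts[li + 1]
                g_pre = g_a * a_sig * (1.0 - a_sig)
                g_w[li] = acts[li].T @ g_pre
                g_b[li] = g_pre.sum(axis=0)
                if li > 0:
                    g_a = g_pre @ weights[li].T
            for li in range(len(weights)):
                weights[li] -= cfg.lr * g_w[li]
                biases[li] -= cfg.lr * g_b[li]
        losses.append(epoch_loss / n)
        if not np.isfinite(losses[-1]):
            raise FloatingPointError(f"non-finite fine-tuning loss at epoch {len(losses)}")
    return MlpModel(weights=weights, biases=biases, config=cfg, loss_trace=losses)


def extract_learned_features(model: MlpModel, features: np.ndarray) -> np.ndarray:
    """Rows of last-hidden-layer activations (the learned representation)."""
    return model.hidden_activations(features)


# ---------------------------------------------------------------------------
# Cohort I/O


def load_manifest(manifest_path, base_dir=None) -> list[RoiTimeSeries]:
    """Read a cohort manifest CSV (subject_id, file, label) of time-series CSVs."""
    import pathlib

    manifest = pd.read_csv(manifest_path)
    base = pathlib.Path(base_dir) if base_dir else pathlib.Path(manifest_path).parent
    out = []
    for _, row in manifest.iterrows():
        values = pd.read_csv(base / row["file"]).to_numpy(float)
        out.append(RoiTimeSeries(values, subject_id=str(row["subject_id"]),
                                 label=int(row["label"])))
    return out
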