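"""Dual-head drug-response classifier on a frozen Res-VAE stem.

Supervision comes only from labeled bulk samples, through a categorical
cross-entropy over two output neurons (sensitivity and resistance heads).
Training is two-phase: for the first 130 epochs only the classification
head is updated while the pretrained stem stays frozen; in the final 20
epochs the stem is fine-tuned jointly.  With ``transfer='mmd'`` the
Gaussian-kernel MMD between bulk and target latent batches (paired sizes)
is added to every batch loss, aligning the two domains while the labels
remain bulk-only.

Also here: SMOTE(k)/Tomek-link rebalancing, VAE-based augmentation, and
the evaluation-metric suite (AUROC, AUPRC, F1, MCC, accuracy, precision,
recall, per-class silhouette).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neighbors import NearestNeighbors

from . import nn
from .io import FeatureMatrix
from .resvae import ResVAE
from .transfer import FeatureStats, adain_transform, compute_stats, mmd2_with_grads

__all__ = ["TrainSchedule", "DualHeadClassifier", "smote_oversample",
           "tomek_remove", "vae_augment", "evaluate", "per_class_silhouette"]

SENSITIVE, RESISTANT = 0, 1


@dataclass
class TrainSchedule:
    """Two-phase schedule: head-only epochs then joint fine-tuning."""

    total_epochs: int = 150
    head_only_epochs: int = 130
    lr: float = 1e-3
    batch_size: int = 64
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0 <= self.head_only_epochs <= self.total_epochs):
            raise ValueError("head_only_epochs must be within total_epochs")

    @property
    def joint_epochs(self) -> int:
        return self.total_epochs - self.head_only_epochs


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DualHeadClassifier(ClassifierMixin, BaseEstimator):
    """Two-logit drug-response classifier over a pretrained Res-VAE stem.

    Parameters
    ----------
    stem : a fitted :class:`~scadapt.resvae.ResVAE` whose deterministic
        latent (posterior mean) feeds the head.
    hidden_dim : width of the single hidden layer of the MLP head.
    schedule : :class:`TrainSchedule` (150 = 130 head-only + 20 joint by
        default).
    transfer : 'adain' | 'mmd' | 'none'.  'adain' expects the training
        matrix to already be re-styled by the bidirectional protocol and
        persists the bulk statistics for inference-time AdaIN; 'mmd' adds
        the latent MMD loss against ``target_X`` batches.
    mmd_gamma : Gaussian kernel scale; if None it is set once by the
        median heuristic on the initial latents.
    """

    def __init__(self, stem: ResVAE | None = None, hidden_dim: int = 128,
                 schedule: TrainSchedule | None = None,
                 transfer: str = "none", mmd_gamma: float | None = None,
                 mmd_weight: float = 1.0):
        self.stem = stem
        self.hidden_dim = hidden_dim
        self.schedule = schedule
        self.transfer = transfer
        self.mmd_gamma = mmd_gamma
        self.mmd_weight = mmd_weight

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _as_array(X) -> np.ndarray:
        return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)

    def _head_forward(self, mu: np.ndarray) -> np.ndarray:
        return self.head_.forward(mu, training=False)

    def _stem_forward(self, x: np.ndarray) -> np.ndarray:
        """Deterministic stem pass (eps = 0, BN running stats) that leaves
        caches in place for an immediate backward."""
        h = self.stem.encoder_.forward(x, training=False)
        return self.stem.mu_head_.forward(h, training=False)

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, target_X=None, bulk_stats: FeatureStats | None = None
            ) -> "DualHeadClassifier":
        """Train on labeled bulk data (y: 0=sensitive, 1=resistant).

        ``target_X`` (unlabeled) is required for ``transfer='mmd'``.
        ``bulk_stats`` are the raw-bulk feature statistics to persist for
        inference-time AdaIN; if omitted under ``transfer='adain'`` they
        are computed from ``X`` itself.
        """
        if self.stem is None:
            raise ValueError("a fitted ResVAE stem is required")
        x = self._as_array(X)
        yarr = np.asarray(y, dtype=int)
        if not np.isin(yarr, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if self.transfer == "mmd" and target_X is None:
            raise ValueError("transfer='mmd' requires target_X")
        sched = self.schedule or TrainSchedule()
        self.schedule_ = sched
        rng = np.random.default_rng(sched.seed)

        d = self.stem.latent_dim
        self.head_ = nn.Sequential([
            nn.Linear(d, self.hidden_dim, rng),
            nn.Swish(1.0),
            nn.Linear(self.hidden_dim, 2, rng),
        ])
        self.classes_ = np.array([SENSITIVE, RESISTANT])

        if self.transfer == "adain":
            self.bulk_stats_ = bulk_stats if bulk_stats is not None else compute_stats(x)
        else:
            self.bulk_stats_ = bulk_stats

        tgt = self._as_array(target_X) if target_X is not None else None
        if self.transfer == "mmd":
            gamma = self.mmd_gamma
            if gamma is None:
                mu0 = np.vstack([self._stem_forward(x[: min(len(x), 256)]),
                                 self._stem_forward(tgt[: min(len(tgt), 256)])])
                dist = ((mu0[:, None] - mu0[None, :]) ** 2).sum(-1)
                med = np.median(dist[dist > 0])
                gamma = 1.0 / max(med, 1e-12)
            self.mmd_gamma_ = float(gamma)

        onehot = np.eye(2)[yarr]
        n = x.shape[0]
        opt = nn.Adam(self.head_.params(), lr=sched.lr)
        self.history_ = []
        for epoch in range(sched.total_epochs):
            joint = epoch >= sched.head_only_epochs
            if epoch == sched.head_only_epochs and sched.joint_epochs > 0:
                opt = nn.Adam(self.head_.params() + self.stem.stem_params(),
                              lr=sched.lr)
            order = rng.permutation(n)
            if tgt is not None:
                tgt_order = rng.permutation(tgt.shape[0])
            ep_loss, nb = 0.0, 0
            for start in range(0, n, sched.batch_size):
                idx = order[start:start + sched.batch_size]
                xb, ohb = x[idx], onehot[idx]
                b = xb.shape[0]
                use_mmd = self.transfer == "mmd"
                if use_mmd:
                    tpos = (start // sched.batch_size * b) % tgt.shape[0]
                    tidx = np.take(tgt_order, range(tpos, tpos + b),
                                   mode="wrap")
                    # paired batch sizes: n_s == n_t
                    xin = np.vstack([xb, tgt[tidx]])
                else:
                    xin = xb
                opt.zero_grad()
                mu = self._stem_forward(xin)
                mu_s = mu[:b]
                logits = self.head_.forward(mu_s, training=True)
                p = _softmax(logits)
                ce = float(-np.mean(np.sum(ohb * np.log(p + 1e-12), axis=1)))
                glogits = (p - ohb) / b
                gmu_s = self.head_.backward(glogits)
                loss = ce
                if use_mmd:
                    val, gs, gt = mmd2_with_grads(mu_s, mu[b:], self.mmd_gamma_)
                    loss += self.mmd_weight * val
                    gcat = np.vstack([gmu_s + self.mmd_weight * gs,
                                      self.mmd_weight * gt])
                else:
                    gcat = gmu_s
                if joint:
                    gh = self.stem.mu_head_.backward(gcat)
                    self.stem.encoder_.backward(gh)
                opt.step()
                if not np.isfinite(loss):
                    raise FloatingPointError("classifier loss diverged")
                ep_loss += loss
                nb += 1
            self.history_.append(ep_loss / max(nb, 1))
        return self

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X, apply_adain: bool = False) -> np.ndarray:
        """Columns: [p_sensitive, p_resistant]; rows sum to 1."""
        x = self._as_array(X)
        if apply_adain:
            if self.bulk_stats_ is None:
                raise ValueError("no persisted bulk statistics for AdaIN")
            x = adain_transform(x, self.bulk_stats_)
        mu = self.stem.encode(x, deterministic=True).mu
        return _softmax(self._head_forward(mu))

    def decision_logits(self, X, apply_adain: bool = False) -> np.ndarray:
        """Pre-softmax logits of both heads (attribution target)."""
        x = self._as_array(X)
        if apply_adain:
            x = adain_transform(x, self.bulk_stats_)
        mu = self.stem.encode(x, deterministic=True).mu
        return self._head_forward(mu)

    def predict(self, X, apply_adain: bool = False) -> np.ndarray:
        return self.predict_proba(X, apply_adain).argmax(axis=1)

    def predict_table(self, X, apply_adain: bool = False
                      ) -> list[tuple[str, float, float, str]]:
        proba = self.predict_proba(X, apply_adain)
        ids = (list(X.row_ids) if isinstance(X, FeatureMatrix)
               else [f"s{i}" for i in range(proba.shape[0])])
        names = {SENSITIVE: "sensitive", RESISTANT: "resistant"}
        return [(sid, float(p[0]), float(p[1]), names[int(p.argmax())])
                for sid, p in zip(ids, proba)]


# -- augmentation ----------------------------------------------------------

def smote_oversample(minority: np.ndarray, majority: np.ndarray, k: int = 5,
                     seed: int = 42) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: grow the minority class to the majority size by interpolating
    x_new = x_i + u (x_nn - x_i), u ~ U(0,1), x_nn one of the k nearest
    minority neighbors of x_i."""
    minority = np.atleast_2d(np.asarray(minority, float))
    majority = np.atleast_2d(np.asarray(majority, float))
    n = minority.shape[0]
    if n < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    if k >= n:
        raise ValueError("k must be smaller than the minority count")
    n_new = majority.shape[0] - n
    if n_new <= 0:
        return minority, majority
    rng = np.random.default_rng(seed)
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    _, nbr_idx = nbrs.kneighbors(minority)  # col 0 is the point itself
    parents = rng.integers(n, size=n_new)
    picks = nbr_idx[parents, rng.integers(1, k + 1, size=n_new)]
    u = rng.random((n_new, 1))
    synthetic = minority[parents] + u * (minority[picks] - minority[parents])
    return np.vstack([minority, synthetic]), majority


def tomek_remove(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop the majority-class member of every Tomek link (mutual nearest
    neighbors of opposite class).  Minority samples are never removed."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    majority_label = classes[np.argmax(counts)]
    nbrs = NearestNeighbors(n_neighbors=2).fit(X)
    _, nbr_idx = nbrs.kneighbors(X)
    nn1 = nbr_idx[:, 1]
    drop = np.zeros(len(y), dtype=bool)
    for i in range(len(y)):
        j = nn1[i]
        if nn1[j] == i and y[i] != y[j]:
            if y[i] == majority_label:
                drop[i] = True
            else:
                drop[j] = True
    keep = ~drop
    return X[keep], y[keep]


def vae_augment(model: ResVAE, X_minority, n_new: int, seed: int = 42
                ) -> np.ndarray:
    """Sample synthetic minority points from the VAE posterior: pick a
    minority sample, draw z* ~ N(mu_i, exp(log_var_i)), decode."""
    if not hasattr(model, "decoder_"):
        raise ValueError("the VAE model must be fitted before augmentation")
    if n_new <= 0:
        x = DualHeadClassifier._as_array(X_minority)
        return np.empty((0, x.shape[1]))
    rng = np.random.default_rng(seed)
    code = model.encode(X_minority, deterministic=True)
    idx = rng.integers(code.mu.shape[0], size=n_new)
    eps = rng.standard_normal((n_new, code.mu.shape[1]))
    z = code.mu[idx] + eps * np.exp(0.5 * code.log_var[idx])
    return model.decode(z)


# -- evaluation ------------------------------------------------------------

def evaluate(y_true, scores, calls) -> dict[str, float]:
    """Standard binary metrics; ``scores`` are resistance probabilities,
    ``calls`` hard 0/1 predictions.  With a single-class truth vector the
    rank metrics are NaN and the rest are still returned."""
    y_true = np.asarray(y_true, int)
    calls = np.asarray(calls, int)
    out: dict[str, float] = {}
    if np.unique(y_true).size < 2:
        out["auroc"] = float("nan")
        out["auprc"] = float("nan")
    else:
        out["auroc"] = float(skm.roc_auc_score(y_true, scores))
        out["auprc"] = float(skm.average_precision_score(y_true, scores))
    out["f1"] = float(skm.f1_score(y_true, calls, zero_division=0))
    out["mcc"] = float(skm.matthews_corrcoef(y_true, calls))
    out["accuracy"] = float(skm.accuracy_score(y_true, calls))
    out["precision"] = float(skm.precision_score(y_true, calls, zero_division=0))
    out["recall"] = float(skm.recall_score(y_true, calls, zero_division=0))
    return out


def per_class_silhouette(embedding: np.ndarray, labels) -> dict[str, float]:
    """Mean Euclidean silhouette within each response class."""
    emb = np.atleast_2d(np.asarray(embedding, float))
    labels = np.asarray(labels, int)
    if np.unique(labels).size < 2 or emb.shape[0] < 4:
        raise ValueError("need both classes and at least 4 samples")
    s = skm.silhouette_samples(emb, labels)
    return {"sensitive": float(s[labels == SENSITIVE].mean()),
            "resistant": float(s[labels == RESISTANT].mean())}
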