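"""Domain transfer: bidirectional AdaIN, Gaussian-kernel MMD, and a
per-dimension Gaussian KL alignment diagnostic.

AdaIN re-scales every feature of a source matrix to the per-feature mean
and standard deviation of a target domain:

    AdaIN(x, y)_j = sigma_y[j] * (x_j - mu_x[j]) / sigma_x[j] + mu_y[j]

It is parameter-free, inverts any per-feature affine batch effect exactly
in the population limit, and is applied in two phases: bulk -> reference
style at training time, patient cells -> bulk style at inference time
(the bulk statistics are frozen into the model bundle for that purpose).

MMD^2 is the biased Gaussian-kernel V-statistic between two latent
samples; its analytic gradient is provided so it can be minimized as a
training loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import FeatureMatrix

EPS_STD = 1e-8

__all__ = ["FeatureStats", "compute_stats", "adain_transform", "AdaIN",
           "bidirectional_protocol", "mmd2", "mmd2_with_grads",
           "per_dimension_kl"]


@dataclass
class FeatureStats:
    """Per-feature population mean and (floored) standard deviation."""

    mean: np.ndarray
    std: np.ndarray
    n: int
    domain: str = ""

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist(),
                "n": self.n, "domain": self.domain}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureStats":
        return cls(mean=np.asarray(d["mean"], float),
                   std=np.asarray(d["std"], float),
                   n=int(d["n"]), domain=d.get("domain", ""))


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, FeatureMatrix) else np.asarray(m, float)


def compute_stats(m) -> FeatureStats:
    """Population (biased) per-feature mean/std with an eps floor on std."""
    x = _values(m)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows to compute feature statistics")
    domain = m.domain if isinstance(m, FeatureMatrix) else ""
    return FeatureStats(
        mean=x.mean(axis=0),
        std=np.maximum(x.std(axis=0), EPS_STD),
        n=x.shape[0],
        domain=domain,
    )


def adain_transform(x, target: FeatureStats):
    """Re-style ``x`` to the target statistics; source statistics are
    computed from ``x`` itself."""
    vals = _values(x)
    if vals.shape[1] != target.mean.shape[0]:
        raise ValueError(
            f"feature dim mismatch: {vals.shape[1]} vs {target.mean.shape[0]}")
    own = compute_stats(vals)
    out = target.std * (vals - own.mean) / own.std + target.mean
    if isinstance(x, FeatureMatrix):
        return FeatureMatrix(values=out, row_ids=list(x.row_ids),
                             col_ids=list(x.col_ids), domain=x.domain,
                             kind=x.kind)
    return out


class AdaIN(TransformerMixin, BaseEstimator):
    """Adaptive instance normalization as a transformer: ``fit`` captures
    the target-domain statistics, ``transform`` re-styles new data to them."""

    def fit(self, X, y=None) -> "AdaIN":
        self.target_stats_ = compute_stats(X)
        return self

    def transform(self, X):
        return adain_transform(X, self.target_stats_)


def bidirectional_protocol(bulk, reference, patient_sc=None,
                           bulk_stats: FeatureStats | None = None):
    """The two-phase transfer protocol.

    Training phase: bulk is re-styled to the reference corpus.  Inference
    phase: patient single cells are re-styled to the bulk statistics
    (persisted from the training phase).  Returns
    ``(train_input, inference_input, bulk_stats)``; ``inference_input`` is
    None when no patient data is given.
    """
    if bulk is not None:
        bulk_stats = compute_stats(bulk)
        train_input = adain_transform(bulk, compute_stats(reference))
    else:
        if bulk_stats is None:
            raise ValueError("inference-only call requires persisted bulk stats")
        train_input = None
    inference_input = None
    if patient_sc is not None:
        if bulk_stats is None:
            raise ValueError("no persisted bulk statistics for inference")
        inference_input = adain_transform(patient_sc, bulk_stats)
    return train_input, inference_input, bulk_stats


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)


def mmd2(s: np.ndarray, t: np.ndarray, gamma: float = 1.0) -> float:
    """Biased Gaussian-kernel MMD^2 V-statistic between two samples.

    MMD^2 = mean K(s,s) + mean K(t,t) - 2 mean K(s,t),
    K(x,y) = exp(-gamma ||x - y||^2).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    s = np.atleast_2d(np.asarray(s, float))
    t = np.atleast_2d(np.asarray(t, float))
    kss = np.exp(-gamma * _sq_dists(s, s)).mean()
    ktt = np.exp(-gamma * _sq_dists(t, t)).mean()
    kst = np.exp(-gamma * _sq_dists(s, t)).mean()
    return float(kss + ktt - 2.0 * kst)


def mmd2_with_grads(s: np.ndarray, t: np.ndarray, gamma: float = 1.0
                    ) -> tuple[float, np.ndarray, np.ndarray]:
    """MMD^2 and its analytic gradients with respect to both sample sets.

    d K(x,y) / dx = -2 gamma (x - y) K(x,y); the double sums are symmetric
    in their arguments, which doubles the within-set terms.
    """
    s = np.atleast_2d(np.asarray(s, float))
    t = np.atleast_2d(np.asarray(t, float))
    ns, nt = s.shape[0], t.shape[0]
    dss = s[:, None, :] - s[None, :, :]
    dtt = t[:, None, :] - t[None, :, :]
    dst = s[:, None, :] - t[None, :, :]
    kss = np.exp(-gamma * (dss**2).sum(axis=2))
    ktt = np.exp(-gamma * (dtt**2).sum(axis=2))
    kst = np.exp(-gamma * (dst**2).sum(axis=2))
    val = float(kss.mean() + ktt.mean() - 2.0 * kst.mean())
    gs = (-2.0 * gamma) * (
        2.0 * (kss[:, :, None] * dss).sum(axis=1) / ns**2
        - 2.0 * (kst[:, :, None] * dst).sum(axis=1) / (ns * nt)
    )
    gt = (-2.0 * gamma) * (
        2.0 * (ktt[:, :, None] * dtt).sum(axis=1) / nt**2
        - 2.0 * (-(kst[:, :, None] * dst)).sum(axis=0) / (ns * nt)
    )
    return val, gs, gt


def per_dimension_kl(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """KL(N(mu_a, sd_a^2) || N(mu_b, sd_b^2)) fitted per dimension.

    Used as an alignment diagnostic on latent codes before/after transfer.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 rows per sample")
    mu_a, sd_a = a.mean(axis=0), np.maximum(a.std(axis=0), EPS_STD)
    mu_b, sd_b = b.mean(axis=0), np.maximum(b.std(axis=0), EPS_STD)
    return (np.log(sd_b / sd_a)
            + (sd_a**2 + (mu_a - mu_b) ** 2) / (2.0 * sd_b**2) - 0.5)
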