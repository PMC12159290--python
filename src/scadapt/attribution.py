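"""Dual-head feature attribution by expectation-based integrated gradients.

For a scalar head F and baseline x', the attribution of feature i at
input x is

    (x_i - x'_i) * E_{x'}[ integral_0^1 dF(x' + a (x - x')) / dx_i da ],

with the path integral approximated by an n_steps midpoint Riemann sum and
the expectation over baselines by explicit draws (a single term for the
mean and zero baselines).  Heads are attributed on their pre-softmax
logits, since softmax gradients saturate and the sensitivity/resistance
heads are analyzed separately.

The baseline library mirrors the robustness protocol: cohort mean, zero
vector, k random cohort samples (multi-baseline expectation), and the mean
of k random samples as a single baseline.  ``baseline_audit`` compares the
feature-importance rankings these produce via pairwise Spearman rank
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .classify import DualHeadClassifier
from .io import FeatureMatrix

__all__ = ["BaselineSpec", "AttributionResult", "integrated_gradients",
           "dual_head_attribution", "baseline_audit", "dependence_summary",
           "resistance_probability", "top_k_features", "logit_grad_fn"]

GradFn = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class BaselineSpec:
    """kind: 'mean' | 'zero' | 'random_k' | 'random_mean'; k is the number
    of cohort samples drawn for the random kinds."""

    kind: str = "mean"
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("mean", "zero", "random_k", "random_mean"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        if self.kind in ("random_k", "random_mean") and self.k < 1:
            raise ValueError("k must be >= 1 for random baselines")

    def label(self) -> str:
        if self.kind == "random_k":
            return f"random{self.k}"
        return self.kind


@dataclass
class AttributionResult:
    values: np.ndarray            # N x F per-sample attributions
    baseline: BaselineSpec
    n_steps: int
    n_baseline_samples: int
    feature_ids: list[str] | None = None

    @property
    def overall_importance(self) -> np.ndarray:
        """Mean absolute attribution per feature."""
        return np.abs(self.values).mean(axis=0)


def _as_array(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)


def _baseline_vectors(x: np.ndarray, spec: BaselineSpec) -> np.ndarray:
    """The explicit baseline draws as a (n_draws, F) array."""
    if spec.kind == "mean":
        return x.mean(axis=0, keepdims=True)
    if spec.kind == "zero":
        return np.zeros((1, x.shape[1]))
    rng = np.random.default_rng(spec.seed)
    rows = x[rng.integers(x.shape[0], size=spec.k)]
    if spec.kind == "random_mean":
        return rows.mean(axis=0, keepdims=True)
    return rows


def logit_grad_fn(model: DualHeadClassifier, head: int) -> GradFn:
    """Value-and-input-gradient of one pre-softmax logit of the classifier.

    Parameter gradients accumulated during the backward pass are cleared
    afterwards so attribution never perturbs subsequent training."""
    def fn(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = model._stem_forward(x)
        logits = model.head_.forward(mu, training=False)
        g = np.zeros_like(logits)
        g[:, head] = 1.0
        gmu = model.head_.backward(g)
        gh = model.stem.mu_head_.backward(gmu)
        gx = model.stem.encoder_.backward(gh)
        for p in model.head_.params() + model.stem.stem_params():
            p.zero_grad()
        return logits[:, head].copy(), gx
    return fn


def integrated_gradients(grad_fn: GradFn, X, baseline: BaselineSpec,
                         n_steps: int = 64, feature_ids=None
                         ) -> AttributionResult:
    """Expectation-based integrated gradients for one scalar head.

    ``grad_fn(x)`` must return ``(values, dvalues/dx)`` for a batch.
    """
    import warnings
    if n_steps < 8:
        warnings.warn("n_steps < 8 gives a coarse path integral")
    x = _as_array(X)
    baselines = _baseline_vectors(x, baseline)
    total = np.zeros_like(x)
    for b in baselines:
        diff = x - b  # broadcast baseline row
        grad_sum = np.zeros_like(x)
        for step in range(n_steps):
            alpha = (step + 0.5) / n_steps
            _, g = grad_fn(b + alpha * diff)
            grad_sum += g
        total += diff * grad_sum / n_steps
    values = total / baselines.shape[0]
    return AttributionResult(values=values, baseline=baseline,
                             n_steps=n_steps,
                             n_baseline_samples=baselines.shape[0],
                             feature_ids=list(feature_ids) if feature_ids is not None
                             else (list(X.col_ids) if isinstance(X, FeatureMatrix) else None))


def dual_head_attribution(model: DualHeadClassifier, X,
                          baseline: BaselineSpec = BaselineSpec("mean"),
                          n_steps: int = 64
                          ) -> tuple[AttributionResult, AttributionResult]:
    """IG against the sensitivity (head 0) and resistance (head 1) logits."""
    if not hasattr(model, "head_"):
        raise ValueError("classifier must be fitted before attribution")
    fids = list(X.col_ids) if isinstance(X, FeatureMatrix) else None
    sens = integrated_gradients(logit_grad_fn(model, 0), X, baseline,
                                n_steps, feature_ids=fids)
    resi = integrated_gradients(logit_grad_fn(model, 1), X, baseline,
                                n_steps, feature_ids=fids)
    return sens, resi


def baseline_audit(grad_fn: GradFn, X, baselines: list[BaselineSpec],
                   n_steps: int = 32
                   ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Rank-robustness audit: overall importance under each baseline and
    the pairwise Spearman correlation matrix of the importance rankings."""
    if len(baselines) < 2:
        raise ValueError("need at least two baselines to audit")
    importances: dict[str, np.ndarray] = {}
    for spec in baselines:
        res = integrated_gradients(grad_fn, X, spec, n_steps)
        label = spec.label()
        while label in importances:  # disambiguate repeated baselines
            label += "'"
        importances[label] = res.overall_importance
    labels = list(importances)
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                ia, ib = importances[a], importances[b]
                if np.ptp(ia) == 0 or np.ptp(ib) == 0:
                    rho = np.nan  # constant importance: correlation undefined
                else:
                    rho = spearmanr(ia, ib).statistic
                mat.iloc[i, j] = mat.iloc[j, i] = rho
    return mat, importances


def dependence_summary(attr: AttributionResult, X, target_feature: int,
                       rho_threshold: float = 0.3) -> pd.DataFrame:
    """Dependence table for one feature: its values, its attributions, and
    the values of the strongest interacting feature.

    The interaction candidate is the feature whose values correlate most
    (|Spearman|) with the target's attribution residual after removing the
    marginal trend (a running mean along the target's sorted values).
    """
    x = _as_array(X)
    t = int(target_feature)
    xt = x[:, t]
    if np.ptp(xt) == 0:
        raise ValueError("target feature is constant")
    at = attr.values[:, t]
    order = np.argsort(xt, kind="stable")
    # marginal trend: running mean over a ~10% window in sorted order
    window = max(3, len(xt) // 10)
    kernel = np.ones(window) / window
    trend_sorted = np.convolve(np.pad(at[order], (window // 2, window - 1 - window // 2),
                                      mode="edge"), kernel, mode="valid")
    residual = np.empty_like(at)
    residual[order] = at[order] - trend_sorted
    best_j, best_rho = None, 0.0
    # a product interaction flips the residual's sign with the target, so
    # also test each candidate conditioned on the target's side of its median
    side = np.sign(xt - np.median(xt))
    for j in range(x.shape[1]):
        if j == t or np.ptp(x[:, j]) == 0:
            continue
        plain = spearmanr(x[:, j], residual).statistic
        signed = spearmanr(side * x[:, j], residual).statistic
        rho = max((r for r in (plain, signed) if np.isfinite(r)),
                  key=abs, default=np.nan)
        if np.isfinite(rho) and abs(rho) > abs(best_rho):
            best_j, best_rho = j, rho
    if best_j is None or abs(best_rho) < rho_threshold:
        interaction, interaction_vals = "none", np.full(len(xt), np.nan)
    else:
        fid = (attr.feature_ids[best_j] if attr.feature_ids is not None
               else str(best_j))
        interaction, interaction_vals = fid, x[:, best_j]
    df = pd.DataFrame({
        "x": xt[order],
        "attribution": at[order],
        "interaction_value": interaction_vals[order],
    })
    df.attrs["interaction_feature"] = interaction
    df.attrs["interaction_rho"] = float(best_rho)
    return df


def resistance_probability(attr_resistance: AttributionResult) -> np.ndarray:
    """Per-sample resistance score: min-max normalized sum of all feature
    attributions from the resistance head; all-equal sums map to 0.5."""
    sums = attr_resistance.values.sum(axis=1)
    if sums.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    span = sums.max() - sums.min()
    if span == 0:
        return np.full(sums.shape, 0.5)
    return (sums - sums.min()) / span


def top_k_features(attr: AttributionResult, k: int = 30) -> list[int]:
    """Feature indices ranked by overall importance, descending; ties
    break toward the lower index (stable)."""
    imp = attr.overall_importance
    if k > imp.shape[0]:
        raise ValueError("k exceeds the feature count")
    order = np.argsort(-imp, kind="stable")
    return order[:k].tolist()
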