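"""Two-domain synthetic data with the structure the transfer method assumes.

The generator emulates the situation the framework is built for: a labeled
"bulk" source domain and an unlabeled "single-cell" target domain that share
the same biology (latent factors driving both features and drug response)
but differ by a per-feature affine style shift — exactly the family of
batch/platform effects that adaptive instance normalization can invert.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureMatrix, LabelTable

DEFAULT_SEED = 42

__all__ = ["SyntheticSpec", "TwoDomainData", "generate_two_domain",
           "generate_survival", "generate_expression_pair"]


@dataclass
class SyntheticSpec:
    """Parameters of the two-domain generator.

    Defaults give 2000 samples per domain of 64 features driven by 8
    latent factors.  Loadings are block-sparse (each feature belongs to a
    single latent program, emulating modular gene-expression programs).
    The target-domain style shift uses heavy-tailed per-feature scale
    factors a ~ LogNormal(0, 3) and offsets c ~ U(-6, 6): platform
    efficiency factors spanning orders of magnitude, severe enough that a
    bulk-trained model cannot rank the shifted cells without transfer,
    yet exactly invertible by moment matching.  Label logits have sd 5
    (class membership informative but stochastic); the resistant class is
    a 30% minority.

    ``shift_scale`` / ``shift_offset`` override the drawn shift with
    explicit per-feature (or scalar) values.
    """

    n_source: int = 2000
    n_target: int = 2000
    n_features: int = 64
    d_true: int = 8
    shift_scale_log_sd: float = 3.0
    shift_offset_range: tuple[float, float] = (-6.0, 6.0)
    shift_scale: float | np.ndarray | None = None
    shift_offset: float | np.ndarray | None = None
    noise_sd: float = 0.3
    label_logit_sd: float = 5.0
    imbalance: float = 0.3
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_source < 2 or self.n_target < 2:
            raise ValueError("need at least 2 samples per domain")
        if self.n_features < self.d_true:
            raise ValueError("n_features must be >= d_true")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 < self.imbalance < 1.0):
            raise ValueError("imbalance must be in (0, 1)")


@dataclass
class TwoDomainData:
    source: FeatureMatrix
    source_labels: LabelTable
    target: FeatureMatrix
    target_labels: LabelTable
    shift_scale: np.ndarray
    shift_offset: np.ndarray
    loadings: np.ndarray          # W, shared across domains
    label_weights: np.ndarray     # v, shared across domains
    source_latents: np.ndarray
    target_latents: np.ndarray


def _draw_domain(
    rng: np.random.Generator,
    n: int,
    W: np.ndarray,
    v: np.ndarray,
    spec: SyntheticSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw n samples with the requested class imbalance.

    Labels are Bernoulli(sigmoid(v.h)); the pool is oversampled and then
    thinned so the resistant (label 1) fraction equals the requested
    imbalance exactly.
    """
    n_pos = int(round(n * spec.imbalance))
    n_neg = n - n_pos
    h_pos, h_neg = [], []
    # rejection-style fill; logit sd ~3 gives both classes ample mass
    while len(h_pos) < n_pos or len(h_neg) < n_neg:
        h = rng.standard_normal((max(4 * n, 64), spec.d_true))
        p = 1.0 / (1.0 + np.exp(-h @ v))
        y = rng.random(h.shape[0]) < p
        for hi, yi in zip(h, y):
            if yi and len(h_pos) < n_pos:
                h_pos.append(hi)
            elif not yi and len(h_neg) < n_neg:
                h_neg.append(hi)
            if len(h_pos) >= n_pos and len(h_neg) >= n_neg:
                break
    h_all = np.vstack([np.array(h_pos).reshape(n_pos, spec.d_true),
                       np.array(h_neg).reshape(n_neg, spec.d_true)])
    y_all = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    perm = rng.permutation(n)
    h_all, y_all = h_all[perm], y_all[perm]
    x = h_all @ W.T + spec.noise_sd * rng.standard_normal((n, spec.n_features))
    return x, y_all, h_all


def _model_params(spec: SyntheticSpec, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Shared generative parameters (W, v, a, c), drawn once per spec seed.

    W is block-sparse: feature j loads on factor j mod-assigned so every
    factor drives n_features/d_true features, with Normal loadings scaled
    to keep per-feature variance comparable to a dense draw.
    """
    F, d = spec.n_features, spec.d_true
    assign = np.arange(F) % d
    W = np.zeros((F, d))
    W[np.arange(F), assign] = rng.standard_normal(F) * np.sqrt(d)
    v = rng.standard_normal(d)
    v *= spec.label_logit_sd / np.linalg.norm(v)
    if spec.shift_scale is not None:
        a = np.broadcast_to(np.asarray(spec.shift_scale, float), (F,)).copy()
    else:
        a = np.exp(rng.normal(0.0, spec.shift_scale_log_sd, F))
    if np.any(a <= 0):
        raise ValueError("shift scales must be positive")
    if spec.shift_offset is not None:
        c = np.broadcast_to(np.asarray(spec.shift_offset, float), (F,)).copy()
    else:
        c = rng.uniform(*spec.shift_offset_range, size=F)
    return W, v, a, c


def generate_two_domain(spec: SyntheticSpec) -> TwoDomainData:
    """Generate a labeled source (bulk) and style-shifted target
    (single-cell) domain sharing latent factors and label mechanism.

    target = a * x + c per feature, on independently drawn samples.
    """
    rng = np.random.default_rng(spec.seed)
    W, v, a, c = _model_params(spec, rng)

    xs, ys, hs = _draw_domain(rng, spec.n_source, W, v, spec)
    xt_base, yt, ht = _draw_domain(rng, spec.n_target, W, v, spec)
    xt = a * xt_base + c

    def _fm(x: np.ndarray, prefix: str, domain: str) -> FeatureMatrix:
        return FeatureMatrix(
            values=x,
            row_ids=[f"{prefix}{i}" for i in range(x.shape[0])],
            col_ids=[f"f{j}" for j in range(spec.n_features)],
            domain=domain, kind="embedding",
        )

    src = _fm(xs, "bulk_", "bulk")
    tgt = _fm(xt, "cell_", "single_cell")
    return TwoDomainData(
        source=src,
        source_labels=LabelTable(sample_ids=list(src.row_ids), response=ys),
        target=tgt,
        target_labels=LabelTable(sample_ids=list(tgt.row_ids), response=yt),
        shift_scale=a, shift_offset=c, loadings=W, label_weights=v,
        source_latents=hs, target_latents=ht,
    )


def generate_reference(spec: SyntheticSpec, n: int, seed: int) -> FeatureMatrix:
    """An unlabeled reference corpus drawn from the same base (unshifted)
    distribution — the role a large public atlas plays for pretraining."""
    rng = np.random.default_rng(seed)
    W, _, _, _ = _model_params(spec, np.random.default_rng(spec.seed))
    h = rng.standard_normal((n, spec.d_true))
    x = h @ W.T + spec.noise_sd * rng.standard_normal((n, spec.n_features))
    return FeatureMatrix(
        values=x,
        row_ids=[f"ref_{i}" for i in range(n)],
        col_ids=[f"f{j}" for j in range(spec.n_features)],
        domain="reference", kind="embedding",
    )


def generate_survival(
    n: int,
    coefs: np.ndarray,
    baseline_hazard: float = 0.1,
    censor_rate: float = 0.2,
    seed: int = DEFAULT_SEED,
) -> tuple[pd.DataFrame, FeatureMatrix]:
    """Exponential survival times under a known proportional-hazards model.

    time_i ~ Exponential(rate = baseline_hazard * exp(coefs . g_i)) with
    per-gene covariates g ~ N(0,1); independent uniform censoring tuned to
    the requested censor fraction.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    if not (0.0 <= censor_rate < 1.0):
        raise ValueError("censor_rate must be in [0, 1)")
    coefs = np.atleast_1d(np.asarray(coefs, dtype=float))
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n, coefs.shape[0]))
    rate = baseline_hazard * np.exp(g @ coefs)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        # censor a random fraction at a time drawn uniformly before the event
        censored = rng.random(n) < censor_rate
        t_cens = t_event * rng.random(n)
        time = np.where(censored, t_cens, t_event)
        event = (~censored).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    genes = [f"g{j}" for j in range(coefs.shape[0])]
    table = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "time": time,
        "event": event,
        **{gj: g[:, j] for j, gj in enumerate(genes)},
    })
    fm = FeatureMatrix(values=g, row_ids=list(table["patient_id"]), col_ids=genes,
                       domain="bulk", kind="embedding")
    return table, fm


def generate_expression_pair(
    teacher_embeddings: FeatureMatrix, G: int, seed: int = DEFAULT_SEED,
    latents: np.ndarray | None = None, noise_seed: int | None = None,
    style_scale_log_sd: float = 0.0, style_offset_sd: float = 0.0,
) -> FeatureMatrix:
    """A nonnegative expression matrix sharing the geometry of a given
    embedding matrix, for training a raw-expression student.

    The gene loading matrix is drawn from ``seed`` alone, so calls with
    the same seed share the latent-to-gene map (paired bulk/single-cell
    expression).  When the true latent draw is known it can be passed via
    ``latents``; otherwise the embedding rows are projected onto their
    leading principal axes.  An optional mild per-gene affine style shift
    (pre-softplus) emulates platform differences on the expression side;
    softplus keeps values nonnegative while preserving neighborhoods.
    """
    if G < 2:
        raise ValueError("need G >= 2 genes")
    rng = np.random.default_rng(seed)
    X = teacher_embeddings.values
    if latents is not None:
        h = np.asarray(latents, float).copy()
        if h.shape[0] != X.shape[0]:
            raise ValueError("latents must be row-aligned with the embeddings")
    else:
        Xc = X - X.mean(axis=0)
        d = min(8, Xc.shape[1], max(2, Xc.shape[0] - 1))
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        h = Xc @ vt[:d].T
    h = h / (h.std(axis=0, keepdims=True) + 1e-12)
    B = rng.standard_normal((h.shape[1], G))
    nrng = np.random.default_rng(seed + 1 if noise_seed is None else noise_seed)
    # unit-scale pre-activations keep the expression O(1) per gene
    pre = h @ B / np.sqrt(h.shape[1]) + 0.1 * nrng.standard_normal((X.shape[0], G))
    if style_scale_log_sd > 0 or style_offset_sd > 0:
        a = np.exp(nrng.normal(0.0, style_scale_log_sd, G))
        c = nrng.normal(0.0, style_offset_sd, G)
        pre = a * pre + c
    expr = np.log1p(np.exp(np.clip(pre, -30, 30)))  # softplus, overflow-safe
    return FeatureMatrix(
        values=expr,
        row_ids=list(teacher_embeddings.row_ids),
        col_ids=[f"g{j}" for j in range(G)],
        domain=teacher_embeddings.domain, kind="expression",
    )
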