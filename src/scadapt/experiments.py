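"""Canned desk-scale experiments: transfer recovery, distillation
fidelity, and survival-signature power at the package's default synthetic
study conditions.

These functions are what the acceptance script and the integration tests
run; they build everything from the synthetic generators at call time.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

from .classify import DualHeadClassifier, TrainSchedule
from .distill import DistillConfig, DistilledResVAE
from .resvae import ResVAE
from .simulate import (SyntheticSpec, generate_expression_pair,
                       generate_reference, generate_survival,
                       generate_two_domain)
from .survival import cox_risk, km_logrank
from .transfer import bidirectional_protocol, mmd2, per_dimension_kl

__all__ = ["transfer_recovery", "distilled_transfer", "survival_power",
           "three_seed_median"]

# desk-scale model settings used across the canned experiments
VAE_KW = dict(latent_dim=8, encoder_block_dims=(32,), epochs=40)
N_REFERENCE = 500
N_GENES = 100


def transfer_recovery(seed: int = 42) -> dict[str, float]:
    """AdaIN-protocol pipeline vs its no-transfer ablation on the default
    two-domain synthetic conditions (2000 samples/domain, 64 features,
    8 latent programs).  Returns target AUROCs and the mean per-dimension
    latent KL before/after the inference-time AdaIN."""
    spec = SyntheticSpec(seed=seed)
    two = generate_two_domain(spec)
    reference = generate_reference(spec, N_REFERENCE, seed=spec.seed + 7)
    vae = ResVAE(**VAE_KW, seed=seed)
    vae.fit(reference.values)
    train_in, infer_in, bulk_stats = bidirectional_protocol(
        two.source, reference, two.target)
    clf = DualHeadClassifier(stem=vae, schedule=TrainSchedule(seed=seed + 1),
                             transfer="adain")
    clf.fit(train_in, two.source_labels.response, bulk_stats=bulk_stats)
    y = two.target_labels.response
    auroc_adain = roc_auc_score(
        y, clf.predict_proba(two.target, apply_adain=True)[:, 1])
    auroc_raw = roc_auc_score(
        y, clf.predict_proba(two.target, apply_adain=False)[:, 1])
    z_bulk = vae.transform(two.source.values)
    kl_before = float(np.mean(per_dimension_kl(
        vae.transform(two.target.values), z_bulk)))
    kl_after = float(np.mean(per_dimension_kl(
        vae.transform(infer_in.values), z_bulk)))
    return {"auroc_adain": float(auroc_adain),
            "auroc_no_transfer": float(auroc_raw),
            "latent_kl_before": kl_before, "latent_kl_after": kl_after}


def distilled_transfer(seed: int = 42, theta: float = 1000.0
                       ) -> dict[str, float]:
    """Raw-expression student distilled from the embedding teacher, then
    MMD-transfer classification of the target domain."""
    spec = SyntheticSpec(seed=seed)
    two = generate_two_domain(spec)
    reference = generate_reference(spec, N_REFERENCE, seed=spec.seed + 7)
    expr_ref = generate_expression_pair(reference, N_GENES,
                                        seed=spec.seed + 11,
                                        noise_seed=spec.seed + 21)
    expr_bulk = generate_expression_pair(two.source, N_GENES,
                                         seed=spec.seed + 11,
                                         latents=two.source_latents,
                                         noise_seed=spec.seed + 22)
    expr_tgt = generate_expression_pair(two.target, N_GENES,
                                        seed=spec.seed + 11,
                                        latents=two.target_latents,
                                        noise_seed=spec.seed + 23,
                                        style_scale_log_sd=0.3,
                                        style_offset_sd=0.3)
    teacher = ResVAE(**VAE_KW, seed=seed)
    teacher.fit(reference.values)
    cfg = DistillConfig(theta=theta, latent_dim=teacher.latent_dim,
                        seed=seed + 1)
    est = DistilledResVAE(teacher=teacher, config=cfg)
    est.fit(expr_ref, teacher_X=reference)
    student = est.student_
    cos = _mean_cosine(est.teacher_latents_, student.transform(expr_ref.values))
    clf = DualHeadClassifier(stem=student,
                             schedule=TrainSchedule(seed=seed + 2),
                             transfer="mmd")
    clf.fit(expr_bulk, two.source_labels.response, target_X=expr_tgt)
    auroc = roc_auc_score(two.target_labels.response,
                          clf.predict_proba(expr_tgt)[:, 1])
    mmd_final = mmd2(student.transform(expr_bulk.values),
                     student.transform(expr_tgt.values), clf.mmd_gamma_)
    return {"auroc_distilled_mmd": float(auroc),
            "teacher_student_cosine": cos,
            "mmd_bulk_target": float(mmd_final)}


def _mean_cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    return float(np.mean((a * b).sum(axis=1) / np.maximum(na * nb, 1e-12)))


def survival_power(seed: int = 42, n: int = 200, hazard_ratio: float = 3.0,
                   censor_rate: float = 0.2) -> dict[str, float]:
    """Single-gene Cox recovery and two-group log-rank power at a known
    hazard model (one gene with log-hazard 1, i.e. covariate sd maps to
    the requested hazard ratio via a median split)."""
    beta_true = 1.0
    table, _ = generate_survival(300, np.array([beta_true]),
                                 baseline_hazard=0.1, censor_rate=censor_rate,
                                 seed=seed)
    _, coefs, _ = cox_risk(table, ["g0"])
    # two-group comparison at exactly the requested hazard ratio
    low, _ = generate_survival(n // 2, np.zeros(1), baseline_hazard=0.1,
                               censor_rate=censor_rate, seed=seed + 1)
    high, _ = generate_survival(n - n // 2, np.zeros(1),
                                baseline_hazard=0.1 * hazard_ratio,
                                censor_rate=censor_rate, seed=seed + 2)
    import pandas as pd
    table2 = pd.concat([low, high], ignore_index=True)
    groups = np.array(["low"] * len(low) + ["high"] * len(high))
    _, stat, p = km_logrank(table2, groups)
    return {"cox_beta_hat": float(coefs["g0"]),
            "logrank_statistic": float(stat), "logrank_p": float(p)}


def three_seed_median(fn, base_seed: int = 42, key: str | None = None,
                      **kwargs):
    """Run ``fn`` at seeds base, base+1, base+2 and return the per-key
    medians (or the median of one key)."""
    runs = [fn(seed=base_seed + i, **kwargs) for i in range(3)]
    keys = runs[0].keys()
    med = {k: float(np.median([r[k] for r in runs])) for k in keys}
    return med[key] if key is not None else med
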