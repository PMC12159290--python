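"""Run orchestration: configuration validation, the three pipeline
flavors, model bundles, and deterministic run manifests.

Pipelines
---------
``adain_embedding``          : embedding input, AdaIN bidirectional transfer
                               (scFoundation-flavored; no spectral norm).
``adain_embedding_gf_flavor``: same with spectral normalization on every
                               learnable linear map (Geneformer-flavored).
``distilled_mmd``            : raw-expression student distilled from the
                               embedding teacher, MMD latent transfer.

A run writes models, predictions, metrics, attributions, survival results
(when configured) and a manifest recording seeds and artifact hashes into
one directory; nothing mutates its inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import (BaselineSpec, dual_head_attribution,
                          resistance_probability, top_k_features)
from .classify import DualHeadClassifier, TrainSchedule, evaluate
from .distill import DistillConfig, DistilledResVAE
from .io import (FeatureMatrix, read_feature_matrix, read_label_table,
                 write_predictions)
from .resvae import ResVAE
from .simulate import (SyntheticSpec, generate_expression_pair,
                       generate_reference, generate_survival,
                       generate_two_domain)
from .survival import cox_risk, km_logrank, median_stratify
from .transfer import FeatureStats, bidirectional_protocol, compute_stats

PIPELINES = ("adain_embedding", "adain_embedding_gf_flavor", "distilled_mmd")

_SCHEMA: dict[str, dict] = {
    "pipeline": {},
    "seed": {},
    "data": {
        "synthetic": {"n_source", "n_target", "n_features", "d_true",
                      "noise_sd", "imbalance", "seed", "n_reference",
                      "n_genes"},
        "bulk_path": None, "bulk_labels_path": None, "reference_path": None,
        "target_path": None, "target_labels_path": None,
    },
    "vae": {"latent_dim", "encoder_block_dims", "beta", "lr", "epochs",
            "batch_size", "folds"},
    "distill": {"theta", "latent_dim", "encoder_block_dims", "lr",
                "epochs", "batch_size"},
    "classifier": {"hidden_dim", "total_epochs", "head_only_epochs", "lr",
                   "batch_size"},
    "attribution": {"baseline", "n_steps", "top_k"},
    "survival": {"path", "synthetic_n", "baseline_hazard", "censor_rate",
                 "effect_size"},
}


def validate_config(cfg: dict | str | Path) -> list[str]:
    """Schema-check a run configuration; returns a list of violations
    (empty when the config is valid).  Unknown keys are rejected."""
    if not isinstance(cfg, dict):
        with open(cfg) as fh:
            try:
                cfg = json.load(fh)
            except json.JSONDecodeError as exc:
                return [f"config does not parse as JSON: {exc}"]
    issues: list[str] = []
    for key in cfg:
        if key not in _SCHEMA:
            issues.append(f"unknown key {key!r}")
    for key, sub in _SCHEMA.items():
        if key in cfg and isinstance(sub, dict) and isinstance(cfg[key], dict):
            for k2 in cfg[key]:
                if k2 not in sub:
                    issues.append(f"unknown key {key}.{k2!r}")
                elif isinstance(sub[k2], set) and isinstance(cfg[key][k2], dict):
                    for k3 in cfg[key][k2]:
                        if k3 not in sub[k2]:
                            issues.append(f"unknown key {key}.{k2}.{k3!r}")
    if "pipeline" not in cfg:
        issues.append("missing required key 'pipeline'")
    elif cfg["pipeline"] not in PIPELINES:
        issues.append(f"pipeline must be one of {PIPELINES}")
    data = cfg.get("data", {})
    if not data:
        issues.append("missing required key 'data'")
    elif "synthetic" not in data:
        if cfg.get("pipeline", "").startswith("adain") and "reference_path" not in data:
            issues.append("adain pipelines require data.reference_path")
        for k in ("bulk_path", "bulk_labels_path", "target_path"):
            if k not in data:
                issues.append(f"missing data.{k}")
        for k, v in data.items():
            if k.endswith("_path") and not Path(v).exists():
                issues.append(f"data.{k} does not exist: {v}")
    return issues


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_model_bundle(path: str | Path, vae: ResVAE,
                      clf: DualHeadClassifier | None = None,
                      bulk_stats: FeatureStats | None = None) -> Path:
    """Persist a model as a directory: JSON config, weight arrays, and the
    frozen bulk feature statistics used for inference-time AdaIN."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = {"vae": vae.get_params(), "n_features": vae.n_features_in_,
           "version": __version__}
    arrays = {f"vae_{i}": a for i, a in enumerate(
        vae.encoder_.state_arrays() + vae.mu_head_.state_arrays()
        + vae.logvar_head_.state_arrays() + vae.decoder_.state_arrays())}
    if clf is not None:
        cfg["classifier"] = {"hidden_dim": clf.hidden_dim,
                             "transfer": clf.transfer}
        arrays.update({f"clf_{i}": a for i, a in
                       enumerate(clf.head_.state_arrays())})
    cfg["vae"]["encoder_block_dims"] = list(cfg["vae"]["encoder_block_dims"])
    (path / "config.json").write_text(json.dumps(cfg, indent=1, default=str))
    np.savez(path / "weights.npz", **arrays)
    if bulk_stats is not None:
        (path / "bulk_stats.json").write_text(json.dumps(bulk_stats.to_dict()))
    return path


def load_model_bundle(path: str | Path
                      ) -> tuple[ResVAE, DualHeadClassifier | None,
                                 FeatureStats | None]:
    path = Path(path)
    cfg = json.loads((path / "config.json").read_text())
    blob = np.load(path / "weights.npz")
    vae_params = dict(cfg["vae"])
    vae_params["encoder_block_dims"] = tuple(
        int(d) for d in vae_params["encoder_block_dims"])
    for key in ("latent_dim", "epochs", "batch_size", "seed"):
        vae_params[key] = int(vae_params[key])
    for key in ("beta", "lr", "alpha_init"):
        vae_params[key] = float(vae_params[key])
    vae_params["spectral_norm"] = str(vae_params["spectral_norm"]) == "True"
    vae = ResVAE(**vae_params)
    vae._build(int(cfg["n_features"]), np.random.default_rng(vae.seed))
    vae_arrays = [blob[f"vae_{i}"] for i in range(
        len([k for k in blob.files if k.startswith("vae_")]))]
    off = vae.encoder_.load_state_arrays(vae_arrays, 0)
    off = vae.mu_head_.load_state_arrays(vae_arrays, off)
    off = vae.logvar_head_.load_state_arrays(vae_arrays, off)
    vae.decoder_.load_state_arrays(vae_arrays, off)
    stats = None
    if (path / "bulk_stats.json").exists():
        stats = FeatureStats.from_dict(
            json.loads((path / "bulk_stats.json").read_text()))
    clf = None
    if "classifier" in cfg:
        clf = DualHeadClassifier(stem=vae,
                                 hidden_dim=int(cfg["classifier"]["hidden_dim"]),
                                 transfer=cfg["classifier"]["transfer"])
        from . import nn
        rng = np.random.default_rng(0)
        clf.head_ = nn.Sequential([
            nn.Linear(vae.latent_dim, clf.hidden_dim, rng),
            nn.Swish(1.0),
            nn.Linear(clf.hidden_dim, 2, rng),
        ])
        clf_arrays = [blob[f"clf_{i}"] for i in range(
            len([k for k in blob.files if k.startswith("clf_")]))]
        clf.head_.load_state_arrays(clf_arrays, 0)
        clf.bulk_stats_ = stats
        clf.classes_ = np.array([0, 1])
    return vae, clf, stats


def _load_data(cfg: dict):
    """Resolve the data block into (bulk, bulk_y, reference, target,
    target_y-or-None, expression trio-or-None)."""
    data = cfg["data"]
    seed = int(cfg.get("seed", 42))
    if "synthetic" in data:
        syn = dict(data["synthetic"])
        n_ref = int(syn.pop("n_reference", 500))
        n_genes = int(syn.pop("n_genes", 100))
        spec = SyntheticSpec(**{**syn, "seed": int(syn.get("seed", seed))})
        two = generate_two_domain(spec)
        reference = generate_reference(spec, n_ref, seed=spec.seed + 7)
        expr = None
        if cfg["pipeline"] == "distilled_mmd":
            expr = {
                "reference": generate_expression_pair(
                    reference, n_genes, seed=spec.seed + 11, noise_seed=spec.seed + 21),
                "bulk": generate_expression_pair(
                    two.source, n_genes, seed=spec.seed + 11, latents=two.source_latents,
                    noise_seed=spec.seed + 22),
                "target": generate_expression_pair(
                    two.target, n_genes, seed=spec.seed + 11, latents=two.target_latents,
                    noise_seed=spec.seed + 23,
                    style_scale_log_sd=0.3, style_offset_sd=0.3),
            }
        return (two.source, two.source_labels.response, reference,
                two.target, two.target_labels.response, expr)
    bulk = read_feature_matrix(data["bulk_path"], domain="bulk")
    bulk_y = read_label_table(data["bulk_labels_path"]).response
    target = read_feature_matrix(data["target_path"], domain="single_cell")
    reference = (read_feature_matrix(data["reference_path"], domain="reference")
                 if "reference_path" in data else None)
    target_y = (read_label_table(data["target_labels_path"]).response
                if "target_labels_path" in data else None)
    return bulk, bulk_y, reference, target, target_y, None


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Execute a configured pipeline end to end; returns the manifest."""
    issues = validate_config(cfg)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 42))
    pipeline = cfg["pipeline"]
    bulk, bulk_y, reference, target, target_y, expr = _load_data(cfg)

    vae_cfg = dict(cfg.get("vae", {}))
    folds = int(vae_cfg.pop("folds", 0)) or None
    spectral = pipeline == "adain_embedding_gf_flavor"
    sched_cfg = dict(cfg.get("classifier", {}))
    hidden = int(sched_cfg.pop("hidden_dim", 128))
    schedule = TrainSchedule(**{**sched_cfg, "seed": seed + 2})

    if pipeline in ("adain_embedding", "adain_embedding_gf_flavor"):
        vae = ResVAE(**vae_cfg, spectral_norm=spectral, seed=seed)
        vae.fit(reference.values, cv_folds=folds)
        train_in, infer_in, bulk_stats = bidirectional_protocol(
            bulk, reference, target)
        clf = DualHeadClassifier(stem=vae, hidden_dim=hidden,
                                 schedule=schedule, transfer="adain")
        clf.fit(train_in, bulk_y, bulk_stats=bulk_stats)
        predict_X, apply_adain = target, True
        attribution_X = infer_in
    else:  # distilled_mmd
        teacher = ResVAE(**vae_cfg, seed=seed)
        teacher.fit(reference.values, cv_folds=folds)
        dist_cfg = DistillConfig(**{**cfg.get("distill", {}),
                                    "latent_dim": teacher.latent_dim,
                                    "seed": seed + 1})
        est = DistilledResVAE(teacher=teacher, config=dist_cfg)
        est.fit(expr["reference"], teacher_X=reference)
        student = est.student_
        clf = DualHeadClassifier(stem=student, hidden_dim=hidden,
                                 schedule=schedule, transfer="mmd")
        clf.fit(expr["bulk"], bulk_y, target_X=expr["target"])
        vae, bulk_stats = student, None
        predict_X, apply_adain = expr["target"], False
        attribution_X = expr["target"]

    # artifacts -----------------------------------------------------------
    model_dir = save_model_bundle(out / "model", vae, clf, bulk_stats)
    table = clf.predict_table(predict_X, apply_adain=apply_adain)
    pred_path = write_predictions(table, out / "predictions.csv")

    metrics = {}
    if target_y is not None:
        proba = clf.predict_proba(predict_X, apply_adain=apply_adain)
        metrics = evaluate(target_y, proba[:, 1], proba.argmax(axis=1))
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1))

    attr_cfg = cfg.get("attribution", {})
    baseline = BaselineSpec(attr_cfg.get("baseline", "mean"), seed=seed + 3)
    sens, resi = dual_head_attribution(
        clf, attribution_X, baseline, n_steps=int(attr_cfg.get("n_steps", 32)))
    fids = (attribution_X.col_ids if isinstance(attribution_X, FeatureMatrix)
            else [f"f{j}" for j in range(resi.values.shape[1])])
    imp = pd.DataFrame({
        "feature": fids,
        "importance_sensitivity": sens.overall_importance,
        "importance_resistance": resi.overall_importance,
    })
    imp.to_csv(out / "attribution_importance.csv", index=False,
               float_format="%.10g")
    pd.DataFrame(resi.values, columns=fids).to_csv(
        out / "attribution_resistance.csv", index=False, float_format="%.10g")
    score = resistance_probability(resi)
    pd.DataFrame({"sample_id": [t[0] for t in table],
                  "resistance_score": score}).to_csv(
        out / "resistance_scores.csv", index=False, float_format="%.10g")

    surv_results = {}
    surv_cfg = cfg.get("survival")
    if surv_cfg:
        k = int(cfg.get("attribution", {}).get("top_k", 30))
        top = top_k_features(resi, k=min(k, len(fids)))
        if "path" in surv_cfg:
            surv_table = pd.read_csv(surv_cfg["path"])
            genes = [fids[j] for j in top if fids[j] in surv_table.columns]
        else:
            n_pat = int(surv_cfg.get("synthetic_n", 200))
            effect = float(surv_cfg.get("effect_size", 1.0))
            coefs = np.zeros(len(top))
            coefs[: max(1, len(top) // 3)] = effect
            surv_table, _ = generate_survival(
                n_pat, coefs,
                baseline_hazard=float(surv_cfg.get("baseline_hazard", 0.1)),
                censor_rate=float(surv_cfg.get("censor_rate", 0.2)),
                seed=seed + 4)
            surv_table = surv_table.rename(
                columns={f"g{i}": fids[j] for i, j in enumerate(top)})
            genes = [fids[j] for j in top]
        risk, coefs_fit, _ = cox_risk(surv_table, genes)
        groups = median_stratify(risk)
        curves, stat, p = km_logrank(surv_table, groups)
        for name, frame in curves.items():
            frame.to_csv(out / f"km_{name}.csv", index=False,
                         float_format="%.10g")
        surv_results = {"logrank_statistic": stat, "logrank_p": p,
                        "top_genes": genes}
        (out / "survival.json").write_text(json.dumps(surv_results, indent=1))

    manifest = {
        "version": __version__,
        "pipeline": pipeline,
        "seed": seed,
        "config": cfg,
        "metrics": metrics,
        "survival": surv_results,
        "artifacts": {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return manifest
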