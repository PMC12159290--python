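"""Knowledge distillation from an embedding-space teacher VAE to a
raw-expression student VAE.

The student is a Res-VAE over gene expression (input width G) trained with

    L = beta * REC + KLD + theta * COD,

where COD is one minus the cosine similarity between the teacher's and the
student's latent vectors for the same cell.  The teacher is frozen and its
deterministic latents (posterior means) are precomputed once.  theta = 0
reduces exactly to plain Res-VAE pretraining.

The cosine term can only rotate the student's latent space once the
beta-weighted reconstruction is near its noise floor (its gradient scales
as 1/||f_S||, tiny next to early reconstruction gradients), so the
default student schedule trains longer, with smaller batches and a higher
learning rate, than embedding pretraining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .io import FeatureMatrix
from .resvae import ResVAE
from .classify import DualHeadClassifier, TrainSchedule

EPS = 1e-12

__all__ = ["DistillConfig", "cod_loss", "cod_loss_with_grad",
           "DistilledResVAE", "train_student", "distilled_pipeline"]


@dataclass
class DistillConfig:
    """theta weights the cosine distillation term; the remaining fields
    configure the student Res-VAE (its latent width must equal the
    teacher's)."""

    theta: float = 1000.0
    beta: float = 1000.0
    latent_dim: int = 16
    encoder_block_dims: tuple[int, ...] = (64, 32)
    lr: float = 3e-3
    epochs: int = 800
    batch_size: int = 32
    seed: int = 42

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")


def cod_loss(f_T: np.ndarray, f_S: np.ndarray) -> float:
    """Mean over samples of 1 - cos(f_T, f_S); range [0, 2]."""
    f_T = np.atleast_2d(np.asarray(f_T, float))
    f_S = np.atleast_2d(np.asarray(f_S, float))
    if f_T.shape != f_S.shape:
        raise ValueError("teacher/student latent shapes differ")
    nT = np.linalg.norm(f_T, axis=1)
    nS = np.linalg.norm(f_S, axis=1)
    if np.any(nT < EPS) or np.any(nS < EPS):
        warnings.warn("zero-norm latent vector in cosine distillation loss")
    cos = (f_T * f_S).sum(axis=1) / (np.maximum(nT, EPS) * np.maximum(nS, EPS))
    return float(np.mean(1.0 - cos))


def cod_loss_with_grad(f_T: np.ndarray, f_S: np.ndarray
                       ) -> tuple[float, np.ndarray]:
    """COD and its gradient with respect to the student latents."""
    f_T = np.atleast_2d(np.asarray(f_T, float))
    f_S = np.atleast_2d(np.asarray(f_S, float))
    nT = np.maximum(np.linalg.norm(f_T, axis=1, keepdims=True), EPS)
    nS = np.maximum(np.linalg.norm(f_S, axis=1, keepdims=True), EPS)
    tn, sn = f_T / nT, f_S / nS
    cos = (tn * sn).sum(axis=1, keepdims=True)
    val = float(np.mean(1.0 - cos))
    # d(1 - cos)/df_S = -(t_hat - cos * s_hat) / ||f_S||, averaged over rows
    grad = -(tn - cos * sn) / nS / f_S.shape[0]
    return val, grad


class DistilledResVAE(BaseEstimator):
    """Raw-expression student trained against a frozen teacher.

    ``fit(X_expression, teacher_X=...)`` requires row-aligned inputs (same
    cells in the same order for student and teacher).  After fitting,
    ``student_`` is a plain :class:`ResVAE` usable as a classifier stem.
    """

    def __init__(self, teacher: ResVAE | None = None,
                 config: DistillConfig | None = None, cv_folds: int | None = None):
        self.teacher = teacher
        self.config = config
        self.cv_folds = cv_folds

    def fit(self, X, y=None, teacher_X=None) -> "DistilledResVAE":
        if self.teacher is None or not hasattr(self.teacher, "decoder_"):
            raise ValueError("a fitted teacher ResVAE is required")
        if teacher_X is None:
            raise ValueError("teacher_X (the teacher's inputs) is required")
        cfg = self.config or DistillConfig(latent_dim=self.teacher.latent_dim)
        x = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
        tx = (teacher_X.values if isinstance(teacher_X, FeatureMatrix)
              else np.asarray(teacher_X, float))
        if x.shape[0] != tx.shape[0]:
            raise ValueError("student and teacher inputs must be row-aligned")
        if cfg.latent_dim != self.teacher.latent_dim:
            raise ValueError("student latent width must equal the teacher's")

        f_T = self.teacher.encode(tx, deterministic=True).mu  # frozen, cached

        def hook(idx, code):
            val, gmu = cod_loss_with_grad(f_T[idx], code.mu)
            return cfg.theta * val, cfg.theta * gmu

        self.student_ = ResVAE(
            latent_dim=cfg.latent_dim,
            encoder_block_dims=cfg.encoder_block_dims,
            beta=cfg.beta, lr=cfg.lr, epochs=cfg.epochs,
            batch_size=cfg.batch_size, seed=cfg.seed,
        )
        self.student_.fit(x, cv_folds=self.cv_folds, loss_hook=hook)
        self.teacher_latents_ = f_T
        return self

    def transform(self, X) -> np.ndarray:
        return self.student_.transform(X)


def train_student(teacher: ResVAE, teacher_X, student_X,
                  cfg: DistillConfig | None = None,
                  cv_folds: int | None = None) -> ResVAE:
    """Functional wrapper: returns the trained student Res-VAE."""
    est = DistilledResVAE(teacher=teacher, config=cfg, cv_folds=cv_folds)
    est.fit(student_X, teacher_X=teacher_X)
    return est.student_


def distilled_pipeline(student: ResVAE, bulk_expression, bulk_y,
                       target_expression, schedule: TrainSchedule | None = None
                       ) -> tuple[np.ndarray, DualHeadClassifier]:
    """Classifier on the student latent with MMD transfer; no AdaIN
    anywhere in this path.  Returns (target resistance probabilities,
    fitted classifier)."""
    clf = DualHeadClassifier(stem=student, schedule=schedule, transfer="mmd")
    clf.fit(bulk_expression, bulk_y, target_X=target_expression)
    proba = clf.predict_proba(target_expression, apply_adain=False)
    return proba[:, 1], clf
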