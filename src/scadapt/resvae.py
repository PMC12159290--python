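"""Residual variational autoencoder over precomputed feature embeddings.

The encoder and decoder are stacks of residual blocks (linear map ->
optional spectral normalization -> batch normalization -> trainable-slope
Swish, with a dimension-adaptive shortcut).  A variational layer in the
middle holds two single linear heads for the posterior mean and log
variance; z is sampled with the reparameterization trick
z = mu + eps * exp(log_var / 2).

The objective is the beta-weighted form

    L = beta * REC + KLD,      beta = 1000 by default,

where REC is the per-sample mean squared reconstruction error summed over
features and KLD the Gaussian KL to the standard-normal prior, averaged
over samples.  The large beta keeps the reconstruction term dominant and
guards against posterior collapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import FeatureMatrix
from . import nn

__all__ = ["LatentCode", "ResVAE", "loss_rec", "loss_kld", "loss_total",
           "swish", "kfold_indices", "search_hyperparameters"]

swish = nn.swish


@dataclass
class LatentCode:
    """Variational layer outputs; z = mu + eps * exp(log_var / 2)."""

    mu: np.ndarray
    log_var: np.ndarray
    z: np.ndarray
    eps: np.ndarray


def loss_rec(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean over samples of the squared L2 reconstruction error."""
    x, x_hat = np.asarray(x, float), np.asarray(x_hat, float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    return float(np.sum((x - x_hat) ** 2) / x.shape[0])


def loss_kld(code: LatentCode) -> float:
    """Gaussian KL to the standard-normal prior, mean over samples."""
    mu, lv = np.asarray(code.mu, float), np.asarray(code.log_var, float)
    n = mu.shape[0]
    return float(-0.5 / n * np.sum(1.0 + lv - mu**2 - np.exp(lv)))


def loss_total(rec: float, kld: float, beta: float) -> float:
    if beta <= 0:
        raise ValueError("beta must be positive")
    return beta * rec + kld


def kfold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded permutation partition into `folds` near-equal index sets."""
    if not (2 <= folds <= n):
        raise ValueError("need 2 <= folds <= n")
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


class ResVAE(TransformerMixin, BaseEstimator):
    """Residual VAE estimator.

    Parameters
    ----------
    latent_dim : width of z.
    encoder_block_dims : residual-block output widths between the input and
        the variational heads; the decoder mirrors them in reverse and ends
        in a plain linear map back to the input width.  An empty list gives
        a linear VAE.
    beta : weight on the reconstruction term of the total loss.
    spectral_norm : constrain every learnable linear map to unit spectral
        norm (used for the Geneformer-flavored models, where it stabilizes
        early training).
    epochs, batch_size, lr, seed : optimization settings (Adam).

    After ``fit``: ``encoder_``, ``decoder_``, ``mu_head_``, ``logvar_head_``,
    ``history_`` (per-epoch total loss) and, when ``cv_folds`` was given,
    ``cv_losses_`` (per-fold validation total loss).
    """

    def __init__(self, latent_dim: int = 16,
                 encoder_block_dims: Sequence[int] = (32,),
                 beta: float = 1000.0, lr: float = 1e-3, epochs: int = 60,
                 batch_size: int = 128, spectral_norm: bool = False,
                 alpha_init: float = 1.0, seed: int = 42):
        self.latent_dim = latent_dim
        self.encoder_block_dims = encoder_block_dims
        self.beta = beta
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.spectral_norm = spectral_norm
        self.alpha_init = alpha_init
        self.seed = seed

    # -- construction ------------------------------------------------------

    def _build(self, n_features: int, rng: np.random.Generator) -> None:
        dims = list(self.encoder_block_dims)
        enc_layers: list[nn.Layer] = []
        prev = n_features
        for d in dims:
            enc_layers.append(nn.ResidualBlock(prev, d, rng, self.spectral_norm,
                                               self.alpha_init))
            prev = d
        self.encoder_ = nn.Sequential(enc_layers)
        self.mu_head_ = nn.Linear(prev, self.latent_dim, rng,
                                  spectral_norm=self.spectral_norm)
        self.logvar_head_ = nn.Linear(prev, self.latent_dim, rng,
                                      spectral_norm=self.spectral_norm)
        dec_layers: list[nn.Layer] = []
        prev = self.latent_dim
        for d in reversed(dims):
            dec_layers.append(nn.ResidualBlock(prev, d, rng, self.spectral_norm,
                                               self.alpha_init))
            prev = d
        dec_layers.append(nn.Linear(prev, n_features, rng,
                                    spectral_norm=self.spectral_norm))
        self.decoder_ = nn.Sequential(dec_layers)
        self.n_features_in_ = n_features

    def _all_params(self) -> list[nn.Param]:
        return (self.encoder_.params() + self.mu_head_.params()
                + self.logvar_head_.params() + self.decoder_.params())

    def stem_params(self) -> list[nn.Param]:
        """Encoder + variational-head parameters (the classifier stem)."""
        return (self.encoder_.params() + self.mu_head_.params()
                + self.logvar_head_.params())

    # -- core passes -------------------------------------------------------

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            return X.values
        return np.asarray(X, dtype=float)

    def _forward_latent(self, x: np.ndarray, training: bool,
                        rng: np.random.Generator | None) -> LatentCode:
        h = self.encoder_.forward(x, training)
        mu = self.mu_head_.forward(h, training)
        lv = self.logvar_head_.forward(h, training)
        lv = np.clip(lv, -15.0, 15.0)
        if training and rng is not None:
            eps = rng.standard_normal(mu.shape)
        else:
            eps = np.zeros_like(mu)
        z = mu + eps * np.exp(0.5 * lv)
        return LatentCode(mu=mu, log_var=lv, z=z, eps=eps)

    def encode(self, X, deterministic: bool = True,
               rng: np.random.Generator | None = None) -> LatentCode:
        """Encode to the latent space.  Deterministic mode sets eps = 0 so
        z = mu (the path used whenever the encoder feeds a classifier)."""
        x = self._as_array(X)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite inputs to encode")
        code = self._forward_latent(x, training=False,
                                    rng=None if deterministic else rng)
        if not deterministic:
            if rng is None:
                raise ValueError("stochastic encode needs an rng")
            eps = rng.standard_normal(code.mu.shape)
            z = code.mu + eps * np.exp(0.5 * code.log_var)
            code = LatentCode(code.mu, code.log_var, z, eps)
        if not np.all(np.isfinite(code.z)):
            raise ValueError("non-finite activations in the variational layer")
        return code

    def decode(self, z: np.ndarray) -> np.ndarray:
        return self.decoder_.forward(np.asarray(z, float), training=False)

    def transform(self, X) -> np.ndarray:
        """Deterministic latent representation (posterior mean)."""
        return self.encode(X, deterministic=True).mu

    def reconstruct(self, X) -> np.ndarray:
        return self.decode(self.transform(X))

    # -- training ----------------------------------------------------------

    def _epoch(self, x: np.ndarray, opt: nn.Adam, rng: np.random.Generator,
               hook: Callable | None = None) -> float:
        n = x.shape[0]
        order = rng.permutation(n)
        total, nb = 0.0, 0
        for start in range(0, n, self.batch_size):
            idx = order[start:start + self.batch_size]
            xb = x[idx]
            b = xb.shape[0]
            opt.zero_grad()
            code = self._forward_latent(xb, training=True, rng=rng)
            xhat = self.decoder_.forward(code.z, training=True)
            rec = loss_rec(xb, xhat)
            kld = loss_kld(code)
            loss = loss_total(rec, kld, self.beta)
            gxhat = self.beta * 2.0 * (xhat - xb) / b
            gz = self.decoder_.backward(gxhat)
            gmu = gz + code.mu / b
            glv = (gz * code.eps * 0.5 * np.exp(0.5 * code.log_var)
                   + (np.exp(code.log_var) - 1.0) / (2.0 * b))
            if hook is not None:
                extra_loss, extra_gmu = hook(idx, code)
                loss += extra_loss
                gmu = gmu + extra_gmu
            gh = self.mu_head_.backward(gmu) + self.logvar_head_.backward(glv)
            self.encoder_.backward(gh)
            opt.step()
            if not np.isfinite(loss):
                raise FloatingPointError("training loss diverged (NaN/Inf)")
            total += loss
            nb += 1
        return total / max(nb, 1)

    def _train(self, x: np.ndarray, epochs: int, rng: np.random.Generator,
               hook: Callable | None = None) -> list[float]:
        opt = nn.Adam(self._all_params(), lr=self.lr)
        return [self._epoch(x, opt, rng, hook) for _ in range(epochs)]

    def fit(self, X, y=None, cv_folds: int | None = None,
            loss_hook: Callable | None = None) -> "ResVAE":
        """Train the VAE; with ``cv_folds`` run k-fold cross-validation
        first (recording per-fold validation losses) and then refit on the
        full data with the same budget."""
        x = self._as_array(X)
        rng = np.random.default_rng(self.seed)
        if cv_folds is not None:
            self.cv_losses_ = []
            fold_sets = kfold_indices(x.shape[0], cv_folds,
                                      np.random.default_rng(self.seed))
            for k, val_idx in enumerate(fold_sets):
                mask = np.ones(x.shape[0], dtype=bool)
                mask[val_idx] = False
                fold_model = ResVAE(**self.get_params())
                fold_model.seed = self.seed + 1 + k
                fold_model._build(x.shape[1], np.random.default_rng(fold_model.seed))
                fold_hook = None
                if loss_hook is not None:
                    global_idx = np.where(mask)[0]
                    fold_hook = (lambda idx, code, _g=global_idx:
                                 loss_hook(_g[idx], code))
                fold_model._train(x[mask], self.epochs,
                                  np.random.default_rng(fold_model.seed + 1000),
                                  hook=fold_hook)
                code = fold_model.encode(x[val_idx])
                xhat = fold_model.decode(code.z)
                self.cv_losses_.append(
                    loss_total(loss_rec(x[val_idx], xhat), loss_kld(code), self.beta))
        self._build(x.shape[1], rng)
        self.history_ = self._train(x, self.epochs,
                                    np.random.default_rng(self.seed + 1),
                                    hook=loss_hook)
        return self

    def pretrain(self, X, folds: int = 10) -> tuple["ResVAE", list[float]]:
        """k-fold cross-validated pretraining; returns (self, fold losses)."""
        self.fit(X, cv_folds=folds)
        return self, self.cv_losses_


def search_hyperparameters(
    X, space: dict[str, Sequence], trials: int = 10, folds: int = 5,
    seed: int = 42, strategy: str = "random", base_params: dict | None = None,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Reduced hyperparameter search minimizing the mean k-fold validation
    total loss.

    ``space`` maps ResVAE parameter names to candidate values, e.g.
    ``{"latent_dim": [8, 16], "lr": [1e-3, 1e-2]}``.  Strategies:
    ``random`` draws ``trials`` seeded combinations; ``exhaustive``
    evaluates the full grid (ignoring ``trials``); ``adaptive`` spends the
    second half of the budget re-sampling coordinates of the incumbent.
    """
    if not space:
        raise ValueError("empty search space")
    if trials < 1:
        raise ValueError("need trials >= 1")
    keys = sorted(space)
    rng = np.random.default_rng(seed)
    base = dict(base_params or {})

    def _candidates() -> list[dict]:
        if strategy == "exhaustive":
            from itertools import product
            return [dict(zip(keys, combo)) for combo in product(*(space[k] for k in keys))]
        return [{k: space[k][rng.integers(len(space[k]))] for k in keys}
                for _ in range(trials)]

    def _score(cfg: dict) -> float:
        params = {**base, **cfg, "seed": seed}
        model = ResVAE(**params)
        model.fit(X, cv_folds=folds)
        return float(np.mean(model.cv_losses_))

    results: list[tuple[dict, float]] = []
    cands = _candidates()
    if strategy == "adaptive":
        half = max(1, len(cands) // 2)
        for cfg in cands[:half]:
            results.append((cfg, _score(cfg)))
        best = min(results, key=lambda r: r[1])[0]
        for _ in range(len(cands) - half):
            cfg = dict(best)
            k = keys[rng.integers(len(keys))]
            cfg[k] = space[k][rng.integers(len(space[k]))]
            results.append((cfg, _score(cfg)))
    else:
        for cfg in cands:
            results.append((cfg, _score(cfg)))
    best_cfg = min(results, key=lambda r: r[1])[0]
    return dict(best_cfg), results
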