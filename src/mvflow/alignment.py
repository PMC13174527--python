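"""Projector heads and multiview latent-alignment objectives.

Alignment acts on the shared block of each view's latent, mapped by a small
per-view MLP projector into a matched D-dimensional embedding space.  Five
objectives are provided, all reduced over unordered view pairs and returned
with the "lower is better" sign convention (maximization objectives are
negated):

* ``pearson`` — negative mean pairwise correlation of batch-normalized
  embeddings; purely second-order, stable at small batches.
* ``barlow_twins`` — cross-correlation matrix of batch-normalized
  embeddings pushed to the identity (invariance on the diagonal,
  redundancy reduction off it).
* ``vicreg`` — alpha*invariance + beta*variance-hinge + gamma*covariance;
  preserves per-dimension variance to prevent collapse without negatives.
* ``infonce`` — contrastive softmax classification of the subject-matched
  pair among in-batch negatives, cosine similarity with temperature tau.
* ``hsic`` — negative (biased) Hilbert-Schmidt Independence Criterion with
  RBF kernels; captures nonlinear shared structure.

An unbiased HSIC U-statistic is also provided for screening and testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._autodiff import MLP, Module, Tensor, logsumexp

__all__ = [
    "Projector",
    "build_projectors",
    "project",
    "AlignmentConfig",
    "alignment_loss",
    "hsic_estimate",
    "median_heuristic_bandwidth",
]

VALID_METHODS = ("pearson", "barlow_twins", "vicreg", "infonce", "hsic")


class Projector(Module):
    """Per-view MLP from shared latent coordinates to the alignment space."""

    def __init__(self, view: str, input_dim: int, hidden: int = 512,
                 output_dim: int = 256, seed: int = 0):
        self.view = view
        self.input_dim = int(input_dim)
        self.hidden = int(hidden)
        self.output_dim = int(output_dim)
        self.net = MLP([input_dim, hidden, output_dim], np.random.default_rng(seed))

    def __call__(self, z: Tensor) -> Tensor:
        if z.shape[-1] != self.input_dim:
            raise ValueError(
                f"projector {self.view!r} expects dim {self.input_dim}, got {z.shape[-1]}"
            )
        return self.net(z)


def build_projectors(input_dims: dict[str, int], hidden: int = 512,
                     output_dim: int = 256, seed: int = 0) -> dict[str, Projector]:
    """One projector per view with a matched output dimensionality."""
    return {
        view: Projector(view, d, hidden=hidden, output_dim=output_dim,
                        seed=seed + i)
        for i, (view, d) in enumerate(sorted(input_dims.items()))
    }


def project(p: Projector, z_shared) -> Tensor:
    z = z_shared if isinstance(z_shared, Tensor) else Tensor(np.atleast_2d(z_shared))
    if z.shape[0] < 1:
        raise ValueError("empty batch")
    return p(z)


@dataclass
class AlignmentConfig:
    """Alignment objective and its hyperparameters.

    ``weight`` is the lambda multiplying the alignment term in the joint
    objective; weight 0 disables alignment exactly.
    """

    method: str = "vicreg"
    weight: float = 1.0
    # Barlow Twins
    barlow_lambda_off: float = 5e-3
    # VICReg (invariance / variance / covariance coefficients, hinge)
    vicreg_alpha: float = 25.0
    vicreg_beta: float = 25.0
    vicreg_gamma: float = 1.0
    vicreg_hinge: float = 1.0
    # InfoNCE
    infonce_temperature: float = 0.1
    # HSIC
    hsic_bandwidth: float | None = None  # None -> median heuristic per batch
    # shrinkage added to variances before correlation normalization
    shrinkage: float = 1e-4

    def __post_init__(self):
        if self.method not in VALID_METHODS:
            raise ValueError(f"method must be one of {VALID_METHODS}")
        if self.weight < 0:
            raise ValueError("alignment weight must be >= 0")


def _batch_normalize(z: Tensor, eps: float) -> Tensor:
    mu = z.mean(axis=0, keepdims=True)
    zc = z - mu
    var = (zc * zc).mean(axis=0, keepdims=True)
    return zc / (var + eps).sqrt()


def _pearson_pair(z1: Tensor, z2: Tensor, eps: float) -> Tensor:
    a = _batch_normalize(z1, eps)
    b = _batch_normalize(z2, eps)
    corr = (a * b).mean(axis=0)  # per-dimension correlation
    return -corr.mean()


def _barlow_pair(z1: Tensor, z2: Tensor, lam_off: float, eps: float) -> Tensor:
    n, d = z1.shape
    a = _batch_normalize(z1, eps)
    b = _batch_normalize(z2, eps)
    C = (a.T @ b) / float(n)
    eye = np.eye(d)
    on_diag = ((C - Tensor(eye)) * Tensor(eye)) ** 2
    off_diag = (C * Tensor(1.0 - eye)) ** 2
    return on_diag.sum() + lam_off * off_diag.sum()


def _vicreg_pair(z1: Tensor, z2: Tensor, cfg: AlignmentConfig) -> Tensor:
    n, d = z1.shape
    inv = ((z1 - z2) ** 2).mean()
    var_terms = []
    cov_terms = []
    for z in (z1, z2):
        zc = z - z.mean(axis=0, keepdims=True)
        std = ((zc * zc).sum(axis=0) / float(max(n - 1, 1)) + cfg.shrinkage).sqrt()
        var_terms.append((Tensor(cfg.vicreg_hinge) - std).relu().mean())
        C = (zc.T @ zc) / float(max(n - 1, 1))
        off = C * Tensor(1.0 - np.eye(d))
        cov_terms.append((off**2).sum() / float(d))
    var = 0.5 * (var_terms[0] + var_terms[1])
    cov = 0.5 * (cov_terms[0] + cov_terms[1])
    return cfg.vicreg_alpha * inv + cfg.vicreg_beta * var + cfg.vicreg_gamma * cov


def _infonce_pair(z1: Tensor, z2: Tensor, tau: float) -> Tensor:
    n = z1.shape[0]
    a = z1 / ((z1 * z1).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    b = z2 / ((z2 * z2).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    logits = (a @ b.T) / tau  # (n, n); diagonal = matched pairs
    diag_idx = (np.arange(n), np.arange(n))
    pos = logits[diag_idx]
    loss_ab = (logsumexp(logits, axis=1) - pos).mean()
    loss_ba = (logsumexp(logits.T, axis=1) - pos).mean()
    return 0.5 * (loss_ab + loss_ba)


def _rbf_gram(z: Tensor, bandwidth: float) -> Tensor:
    sq = (z * z).sum(axis=1, keepdims=True)
    d2 = sq + sq.T - 2.0 * (z @ z.T)
    return (d2 * (-0.5 / bandwidth**2)).exp()


def median_heuristic_bandwidth(x: np.ndarray) -> float:
    """Median pairwise Euclidean distance (a robust RBF bandwidth default)."""
    x = np.atleast_2d(x)
    n = x.shape[0]
    sq = (x**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * x @ x.T
    iu = np.triu_indices(n, 1)
    med = float(np.median(np.sqrt(np.maximum(d2[iu], 0.0))))
    return med if med > 0 else 1.0


def _hsic_biased_pair(z1: Tensor, z2: Tensor, bandwidth: float | None) -> Tensor:
    n = z1.shape[0]
    s1 = bandwidth or median_heuristic_bandwidth(z1.data)
    s2 = bandwidth or median_heuristic_bandwidth(z2.data)
    K = _rbf_gram(z1, s1)
    L = _rbf_gram(z2, s2)
    H = Tensor(np.eye(n) - np.ones((n, n)) / n)
    KH = K @ H
    LH = L @ H
    hsic = (KH * LH.T).sum() / float(n**2)  # trace(KHLH)/n^2
    return -hsic  # maximize dependence


def alignment_loss(cfg: AlignmentConfig, embeddings) -> Tensor:
    """Scalar alignment objective over >= 2 views (lower is better).

    ``embeddings`` is a sequence (or view->Tensor mapping) of subject-matched
    batches with identical row order; pairwise objectives are averaged over
    all unordered view pairs.
    """
    if isinstance(embeddings, dict):
        embeddings = [embeddings[k] for k in sorted(embeddings)]
    embeddings = [e if isinstance(e, Tensor) else Tensor(np.atleast_2d(e))
                  for e in embeddings]
    if len(embeddings) < 2:
        raise ValueError("alignment needs at least two views")
    n = embeddings[0].shape[0]
    if n < 2:
        raise ValueError("alignment statistics need batch size >= 2")
    d = embeddings[0].shape[1]
    for e in embeddings:
        if e.shape != (n, d):
            raise ValueError("all views must share batch size and embedding dim")

    pair_losses = []
    for i, j in combinations(range(len(embeddings)), 2):
        a, b = embeddings[i], embeddings[j]
        if cfg.method == "pearson":
            pair_losses.append(_pearson_pair(a, b, cfg.shrinkage))
        elif cfg.method == "barlow_twins":
            pair_losses.append(_barlow_pair(a, b, cfg.barlow_lambda_off, cfg.shrinkage))
        elif cfg.method == "vicreg":
            pair_losses.append(_vicreg_pair(a, b, cfg))
        elif cfg.method == "infonce":
            pair_losses.append(_infonce_pair(a, b, cfg.infonce_temperature))
        elif cfg.method == "hsic":
            pair_losses.append(_hsic_biased_pair(a, b, cfg.hsic_bandwidth))
    total = pair_losses[0]
    for pl in pair_losses[1:]:
        total = total + pl
    return total / float(len(pair_losses))


def hsic_estimate(X: np.ndarray, Y: np.ndarray, bandwidth: float | None = None,
                  variant: str = "biased") -> float:
    """HSIC between paired batches with RBF kernels.

    ``biased`` is trace(KHLH)/n^2 with the centering matrix H; ``unbiased``
    is the standard U-statistic (requires n >= 4).
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must be paired (same number of rows)")
    if variant not in ("biased", "unbiased"):
        raise ValueError("variant must be 'biased' or 'unbiased'")
    if variant == "unbiased" and n < 4:
        raise ValueError("unbiased HSIC requires n >= 4")

    def gram(Z):
        s = bandwidth or median_heuristic_bandwidth(Z)
        sq = (Z**2).sum(axis=1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * Z @ Z.T, 0.0)
        return np.exp(-0.5 * d2 / s**2)

    K, L = gram(X), gram(Y)
    if variant == "biased":
        H = np.eye(n) - np.ones((n, n)) / n
        return float(np.trace(K @ H @ L @ H) / n**2)
    # unbiased U-statistic (Song et al.): zero the diagonals
    Kt = K - np.diag(np.diag(K))
    Lt = L - np.diag(np.diag(L))
    term1 = np.sum(Kt * Lt)
    term2 = Kt.sum() * Lt.sum() / ((n - 1) * (n - 2))
    term3 = 2.0 / (n - 2) * np.sum(Kt.sum(axis=1) * Lt.sum(axis=1))
    return float((term1 + term2 - term3) / (n * (n - 3)))
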