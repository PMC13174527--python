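"""Low-rank-plus-diagonal Gaussian over concatenated multiscale latents.

Once per-view flows are trained and frozen, every subject's latents (all
levels of all views, flattened and concatenated in level-within-view order)
are modelled jointly as z ~ N(mu, Sigma) with

    Sigma = U Lambda U^T + sigma^2 I ,

where U holds the top-r eigenvectors of the sample covariance, Lambda the
top-r eigenvalues, and sigma^2 the mean residual variance.  At image scale
the dense Sigma is unrepresentable (a 64^3 volume already gives D ~ 2.6e5,
i.e. > 500 GB for a dense double-precision covariance), so all conditioning,
densities and Mahalanobis distances are evaluated through the push-through
Woodbury identity: only the r x r matrix

    K = Lambda^{1/2} U_O^T U_O Lambda^{1/2} + sigma^2 I_r

is ever factorized.  The conditional of unobserved coordinates U given
observed O is exactly

    mu_{U|O}    = mu_U + U_U Lambda^{1/2} K^{-1} Lambda^{1/2} U_O^T (z_O - mu_O)
    Sigma_{U|O} = sigma^2 ( I + U_U Lambda^{1/2} K^{-1} Lambda^{1/2} U_U^T ),

again low-rank-plus-diagonal, so sampling and log-densities stay cheap.
Cross-view imputation encodes the observed views, conditions, and decodes
the conditional mean through each target view's inverse flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, solve_triangular

from .flow_image import ImageFlowModel, MultiscaleLatent
from .flow_tabular import TabularFlowModel

logger = logging.getLogger(__name__)

__all__ = [
    "JointGaussian",
    "ConditionalResult",
    "fit_joint_gaussian",
    "condition",
    "sample_conditional",
    "lowrank_log_prob",
    "mahalanobis_full",
    "collect_latents",
    "fit_latent_model",
    "impute_views",
    "DENSE_THRESHOLD",
]

SIGMA2_FLOOR = 1e-8
DENSE_THRESHOLD = 4096  # refuse to materialize dense D x D above this


def latent_dimension(shape) -> int:
    """Total latent dimensionality of an image of the given (C, *spatial) or spatial shape."""
    return int(np.prod(shape))


def dense_covariance_memory_gb(dim: int, bytes_per_entry: int = 8) -> float:
    """Memory (GB) a dense dim x dim covariance would need — why the low-rank form exists."""
    return dim * dim * bytes_per_entry / 1e9


@dataclass
class LatentBlock:
    """Coordinate range of one (view, level) block in the concatenated latent."""

    view: str
    level: int
    start: int
    stop: int
    shape: tuple[int, ...]
    scale: float = 1.0  # per-block standardization scalar (divided out before fitting)


@dataclass
class JointGaussian:
    mean: np.ndarray                 # (D,)
    factors: np.ndarray              # U: (D, r), orthonormal columns
    eigenvalues: np.ndarray          # Lambda: (r,), non-increasing, > 0
    sigma2: float                    # isotropic residual variance
    blocks: list[LatentBlock] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.mean.size

    @property
    def rank(self) -> int:
        return self.factors.shape[1]

    def dense_covariance(self) -> np.ndarray:
        """Dense Sigma, for oracles/tests only; guarded against huge D."""
        if self.dim > DENSE_THRESHOLD:
            raise MemoryError(
                f"refusing to materialize dense {self.dim}x{self.dim} covariance"
            )
        U, lam = self.factors, self.eigenvalues
        return (U * lam) @ U.T + self.sigma2 * np.eye(self.dim)


@dataclass
class ConditionalResult:
    """Conditional Gaussian over unobserved coordinates, in factored form."""

    observed: np.ndarray             # index set O
    unobserved: np.ndarray           # index set U (complement)
    mean: np.ndarray                 # mu_{U|O}, (|U|,)
    cov_factor: np.ndarray           # F: (|U|, r); Sigma_{U|O} = F F^T + sigma2 I
    sigma2: float

    def covariance_dense(self) -> np.ndarray:
        if self.unobserved.size > DENSE_THRESHOLD:
            raise MemoryError("refusing to materialize dense conditional covariance")
        F = self.cov_factor
        return F @ F.T + self.sigma2 * np.eye(self.unobserved.size)


def _chol_with_jitter(K: np.ndarray):
    """Cholesky with small adaptive jitter (start 1e-10*trace/r, x10, 3 retries)."""
    r = K.shape[0]
    jitter = 0.0
    base = 1e-10 * np.trace(K) / max(r, 1)
    for attempt in range(4):
        try:
            return np.linalg.cholesky(K + jitter * np.eye(r))
        except np.linalg.LinAlgError:
            jitter = base * 10**attempt if base > 0 else 10.0 ** (-10 + attempt)
    raise np.linalg.LinAlgError("K matrix not positive definite after jitter retries")


def fit_joint_gaussian(latents: np.ndarray, rank: int,
                       shrinkage: float = 0.0,
                       blocks: list[LatentBlock] | None = None) -> JointGaussian:
    """Fit mean + top-r SVD covariance factors on collected latents (n x D).

    sigma^2 is the mean sample variance over the discarded directions,
    floored at 1e-8; optional shrinkage blends the eigenvalues toward their
    mean: Lambda <- (1-a) Lambda + a mean(Lambda).
    """
    z = np.atleast_2d(np.asarray(latents, dtype=np.float64))
    n, D = z.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if rank >= n:
        raise ValueError(f"rank {rank} must be < n = {n}")
    if rank >= D:
        raise ValueError(f"rank {rank} must be < D = {D}")
    mean = z.mean(axis=0)
    zc = z - mean
    _, s, vt = np.linalg.svd(zc, full_matrices=False)
    eigvals = s**2 / n
    lam = eigvals[:rank].copy()
    rest = eigvals[rank:]
    sigma2 = float(np.mean(rest)) if rest.size else 0.0
    if sigma2 < SIGMA2_FLOOR:
        logger.warning("residual variance %.3g below floor; clamping", sigma2)
        sigma2 = SIGMA2_FLOOR
    if shrinkage > 0:
        lam = (1.0 - shrinkage) * lam + shrinkage * lam.mean()
    lam = np.maximum(lam, SIGMA2_FLOOR)
    return JointGaussian(mean=mean, factors=vt[:rank].T, eigenvalues=lam,
                         sigma2=sigma2, blocks=blocks or [])


def condition(g: JointGaussian, observed_idx, z_obs: np.ndarray) -> ConditionalResult:
    """Exact Gaussian conditioning via the push-through Woodbury identity.

    Never forms Sigma_OO; only the r x r matrix K is Cholesky-factorized.
    """
    O = np.asarray(observed_idx, dtype=int)
    if O.size == 0:
        raise ValueError("observed index set is empty")
    if O.size >= g.dim:
        raise ValueError("all coordinates observed; nothing to condition")
    z_obs = np.asarray(z_obs, dtype=np.float64).ravel()
    if z_obs.size != O.size:
        raise ValueError("z_obs length must match observed index set")
    if not np.all(np.isfinite(z_obs)):
        raise ValueError("observed values must be finite")
    mask = np.ones(g.dim, dtype=bool)
    mask[O] = False
    Uidx = np.flatnonzero(mask)

    U_O = g.factors[O]                     # (|O|, r)
    U_U = g.factors[Uidx]                  # (|U|, r)
    lam_half = np.sqrt(g.eigenvalues)
    B_O = U_O * lam_half                   # U_O Lambda^{1/2}
    K = B_O.T @ B_O + g.sigma2 * np.eye(g.rank)
    L = _chol_with_jitter(K)

    d = z_obs - g.mean[O]
    w = B_O.T @ d                          # Lambda^{1/2} U_O^T d
    y = cho_solve((L, True), w)            # K^{-1} w
    mean_u = g.mean[Uidx] + (U_U * lam_half) @ y

    # Sigma_{U|O} = sigma2 * (I + U_U L^{1/2} K^{-1} L^{1/2} U_U^T) = F F^T + sigma2 I
    # with F = sqrt(sigma2) * U_U Lambda^{1/2} L^{-T}
    Linv_t = solve_triangular(L, np.eye(g.rank), lower=True).T  # L^{-T}
    F = np.sqrt(g.sigma2) * (U_U * lam_half) @ Linv_t
    return ConditionalResult(observed=O, unobserved=Uidx, mean=mean_u,
                             cov_factor=F, sigma2=g.sigma2)


def sample_conditional(c: ConditionalResult, n: int, seed: int | None = None) -> np.ndarray:
    """Draw n samples of the unobserved coordinates from the conditional."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    r = c.cov_factor.shape[1]
    eps0 = rng.standard_normal((n, c.unobserved.size))
    eps1 = rng.standard_normal((n, r))
    return c.mean + np.sqrt(c.sigma2) * eps0 + eps1 @ c.cov_factor.T


def _woodbury_quad_logdet(g: JointGaussian, d: np.ndarray) -> tuple[np.ndarray, float]:
    """(d^T Sigma^{-1} d, log|Sigma|) without any dense D x D object."""
    d2 = np.atleast_2d(d)
    if g.rank == 0:
        quad = (d2**2).sum(axis=1) / g.sigma2
        return quad, g.dim * float(np.log(g.sigma2))
    lam_half = np.sqrt(g.eigenvalues)
    B = g.factors * lam_half               # (D, r)
    K = B.T @ B + g.sigma2 * np.eye(g.rank)
    L = _chol_with_jitter(K)
    w = d2 @ B                             # (n, r)
    y = solve_triangular(L, w.T, lower=True)
    quad = ((d2**2).sum(axis=1) - (y**2).sum(axis=0)) / g.sigma2
    logdet = (g.dim - g.rank) * float(np.log(g.sigma2)) + 2.0 * float(
        np.sum(np.log(np.diag(L)))
    )
    return quad, logdet


def lowrank_log_prob(g: JointGaussian, z: np.ndarray) -> np.ndarray:
    """Gaussian log-density via matrix-determinant lemma + Woodbury solves."""
    z2 = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if z2.shape[1] != g.dim:
        raise ValueError(f"z has dim {z2.shape[1]}, model has {g.dim}")
    if not np.all(np.isfinite(z2)):
        raise ValueError("z must be finite")
    quad, logdet = _woodbury_quad_logdet(g, z2 - g.mean)
    out = -0.5 * (quad + logdet + g.dim * np.log(2.0 * np.pi))
    return out if np.asarray(z).ndim > 1 else out[0]


def mahalanobis_full(g: JointGaussian, z: np.ndarray) -> np.ndarray:
    """sqrt((z-mu)^T Sigma^{-1} (z-mu)) via Woodbury solves."""
    z2 = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if z2.shape[1] != g.dim:
        raise ValueError(f"z has dim {z2.shape[1]}, model has {g.dim}")
    if not np.all(np.isfinite(z2)):
        raise ValueError("z must be finite")
    quad, _ = _woodbury_quad_logdet(g, z2 - g.mean)
    out = np.sqrt(np.maximum(quad, 0.0))
    return out if np.asarray(z).ndim > 1 else out[0]


# ---------------------------------------------------------------------------
# end-to-end helpers over fitted flows
# ---------------------------------------------------------------------------


def _encode_view(flow, x: np.ndarray) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    if isinstance(flow, TabularFlowModel):
        z = flow.encode(x)
        return z, [(flow.dim,)]
    if isinstance(flow, ImageFlowModel):
        from .flow_image import encode as img_encode

        lat, _ = img_encode(flow, x)
        return lat.flatten(), [tuple(s) for s in flow.latent_shapes]
    raise TypeError(f"unsupported flow type {type(flow).__name__}")


def _decode_view(flow, flat: np.ndarray) -> np.ndarray:
    if isinstance(flow, TabularFlowModel):
        return flow.inverse(flat)
    if isinstance(flow, ImageFlowModel):
        lat = MultiscaleLatent.unflatten(flat, flow.latent_shapes, view=flow.view)
        return flow.decode_np(lat)
    raise TypeError(f"unsupported flow type {type(flow).__name__}")


def collect_latents(flows: dict[str, object], data: dict[str, np.ndarray],
                    standardize_blocks: bool = True
                    ) -> tuple[np.ndarray, list[LatentBlock]]:
    """Encode every view and concatenate per-subject latents (views sorted by name).

    With ``standardize_blocks`` each (view, level) block is divided by its
    scalar standard deviation so no single high-variance view dominates the
    eigen-spectrum; the scalars are recorded on the blocks and undone on
    decode.
    """
    names = sorted(flows)
    pieces, blocks, offset = [], [], 0
    n = None
    for view in names:
        z, shapes = _encode_view(flows[view], np.asarray(data[view]))
        if n is None:
            n = z.shape[0]
        elif z.shape[0] != n:
            raise ValueError("views must be subject-matched (equal row counts)")
        start_b = 0
        for lev, shp in enumerate(shapes):
            size = int(np.prod(shp))
            block = z[:, start_b: start_b + size]
            scale = float(block.std()) if standardize_blocks else 1.0
            scale = scale if scale > 1e-12 else 1.0
            pieces.append(block / scale)
            blocks.append(LatentBlock(view=view, level=lev, start=offset,
                                      stop=offset + size, shape=tuple(shp),
                                      scale=scale))
            start_b += size
            offset += size
    return np.concatenate(pieces, axis=1), blocks


def fit_latent_model(flows: dict[str, object], data: dict[str, np.ndarray],
                     rank: int | None = None, shrinkage: float = 0.0,
                     standardize_blocks: bool = True) -> JointGaussian:
    """Freeze the flows, collect latents for all subjects, fit the Gaussian."""
    Z, blocks = collect_latents(flows, data, standardize_blocks)
    n, D = Z.shape
    if rank is None:
        rank = min(n - 1, 64, D - 1)
    return fit_joint_gaussian(Z, rank, shrinkage=shrinkage, blocks=blocks)


def _view_indices(g: JointGaussian, views) -> np.ndarray:
    idx = []
    known = {b.view for b in g.blocks}
    for v in views:
        if v not in known:
            raise KeyError(f"view {v!r} not present in the fitted Gaussian")
    for b in g.blocks:
        if b.view in views:
            idx.append(np.arange(b.start, b.stop))
    return np.concatenate(idx)


def impute_views(flows: dict[str, object], g: JointGaussian,
                 observed: dict[str, np.ndarray], targets: list[str],
                 ) -> dict[str, np.ndarray]:
    """Cross-view imputation: encode observed views, condition, decode targets.

    Supports many-to-many translation: any subset of views may be observed
    and any disjoint subset requested.  Decoding pushes the conditional mean
    through each target view's inverse flow.
    """
    obs_views = sorted(observed)
    if not obs_views:
        raise ValueError("at least one observed view required")
    overlap = set(obs_views) & set(targets)
    if overlap:
        raise ValueError(f"targets must be disjoint from observed views: {sorted(overlap)}")
    for t in targets:
        if t not in flows:
            raise KeyError(f"no fitted flow for target view {t!r}")

    # encode observed views into the standardized concatenated coordinates
    obs_idx_parts, obs_val_parts = [], []
    n = None
    for v in obs_views:
        z, _ = _encode_view(flows[v], np.asarray(observed[v]))
        n = z.shape[0] if n is None else n
        if z.shape[0] != n:
            raise ValueError("observed views must be subject-matched")
        vblocks = [b for b in g.blocks if b.view == v]
        off = 0
        for b in vblocks:
            size = b.stop - b.start
            obs_idx_parts.append(np.arange(b.start, b.stop))
            obs_val_parts.append(z[:, off: off + size] / b.scale)
            off += size
    O = np.concatenate(obs_idx_parts)
    Zobs = np.concatenate(obs_val_parts, axis=1)

    target_idx = {t: _view_indices(g, [t]) for t in targets}
    out: dict[str, list[np.ndarray]] = {t: [] for t in targets}
    for i in range(n):
        cond = condition(g, O, Zobs[i])
        pos = {j: k for k, j in enumerate(cond.unobserved)}
        for t in targets:
            flat = cond.mean[[pos[j] for j in target_idx[t]]]
            # undo per-block standardization before decoding
            off = 0
            parts = []
            for b in (bb for bb in g.blocks if bb.view == t):
                size = b.stop - b.start
                parts.append(flat[off: off + size] * b.scale)
                off += size
            out[t].append(_decode_view(flows[t], np.concatenate(parts)[None, :])[0])
    return {t: np.stack(v) for t, v in out.items()}
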