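"""Shared-subspace selection by CCA or HSIC screening.

After a warm-up phase of pure likelihood training, screening inspects the
per-view projector outputs and selects the rank-r subspace (CCA) or
coordinate subset (HSIC) where cross-view dependence is strongest.  The
alignment loss is subsequently applied only to these projected or masked
coordinates; screening never touches flow parameters or invertibility.

CCA screening whitens each view (with a ridge on the covariance), takes the
SVD of the pairwise cross-covariance, and averages the per-pair projectors
per view, re-orthonormalizing so each per-view projector has orthonormal
columns.  HSIC screening prefilters coordinates by maximum absolute Pearson
correlation with any other view, ranks survivors by mean unbiased HSIC
against the other views' retained blocks, and keeps the top r (ties broken
toward lower indices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.linalg import eigh, qr

from .alignment import hsic_estimate

__all__ = ["ScreeningResult", "cca_screen", "hsic_screen"]

DEFAULT_RIDGE = 1e-3          # covariance ridge used for whitening
DEFAULT_WARMUP_ITERS = 1000   # likelihood-only iterations before screening
DEFAULT_REFRESH_ITERS = 5000  # periodic refresh interval
DEFAULT_FRAC = 0.5            # fraction of coordinates retained


@dataclass
class ScreeningResult:
    """Fitted shared-subspace selection for every view."""

    mode: str                                  # "cca" | "hsic"
    rank: int
    projectors: dict[str, np.ndarray] = field(default_factory=dict)  # cca: D x r
    masks: dict[str, np.ndarray] = field(default_factory=dict)       # hsic: index arrays
    canonical_correlations: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    refresh_iteration: int = 0

    def apply(self, view: str, embeddings: np.ndarray) -> np.ndarray:
        """Project (cca) or mask (hsic) a view's embeddings to the shared subspace."""
        if self.mode == "cca":
            return np.asarray(embeddings) @ self.projectors[view]
        return np.asarray(embeddings)[:, self.masks[view]]


def _as_dict(latents) -> dict[str, np.ndarray]:
    if isinstance(latents, dict):
        return {str(k): np.asarray(v, dtype=np.float64) for k, v in latents.items()}
    return {f"view{i}": np.asarray(v, dtype=np.float64) for i, v in enumerate(latents)}


def _whitener(x: np.ndarray, ridge: float) -> np.ndarray:
    """Symmetric inverse square root of the ridge-regularized covariance."""
    n = x.shape[0]
    cov = x.T @ x / n + ridge * np.eye(x.shape[1])
    w, v = eigh(cov)
    w = np.maximum(w, 1e-12)
    return v @ np.diag(w**-0.5) @ v.T


def cca_screen(latents, r: int, ridge: float = DEFAULT_RIDGE,
               refresh_iteration: int = 0) -> ScreeningResult:
    """Select a rank-r shared subspace per view by pairwise whitened SVD.

    For each unordered view pair, both views are centered and whitened, the
    cross-covariance is factored by SVD, and the top-r singular directions
    (mapped back through each view's whitener) contribute to that view's
    projector.  Per-view contributions are averaged over pairs and
    re-orthonormalized by QR.
    """
    views = _as_dict(latents)
    names = sorted(views)
    if len(names) < 2:
        raise ValueError("CCA screening needs at least two views")
    n = views[names[0]].shape[0]
    for v in views.values():
        if v.shape[0] != n:
            raise ValueError("all views must have the same number of rows")
    d_min = min(v.shape[1] for v in views.values())
    if r >= min(n, d_min):
        raise ValueError(f"rank r={r} must be < min(n, D) = {min(n, d_min)}")

    centered = {k: v - v.mean(axis=0) for k, v in views.items()}
    whiteners = {k: _whitener(v, ridge) for k, v in centered.items()}
    whitened = {k: centered[k] @ whiteners[k] for k in names}

    sums: dict[str, np.ndarray] = {k: np.zeros((views[k].shape[1], r)) for k in names}
    counts = {k: 0 for k in names}
    result = ScreeningResult(mode="cca", rank=r, refresh_iteration=refresh_iteration)
    for a, b in combinations(names, 2):
        cross = whitened[a].T @ whitened[b] / n
        u, s, vt = np.linalg.svd(cross, full_matrices=False)
        result.canonical_correlations[(a, b)] = s[:r]
        # deterministic sign: largest-magnitude entry of each left vector positive
        for j in range(r):
            sign = np.sign(u[np.argmax(np.abs(u[:, j])), j]) or 1.0
            u[:, j] *= sign
            vt[j] *= sign
        sums[a] += whiteners[a] @ u[:, :r]
        sums[b] += whiteners[b] @ vt[:r].T
        counts[a] += 1
        counts[b] += 1

    for k in names:
        avg = sums[k] / counts[k]
        q, rr = qr(avg, mode="economic")
        q = q * np.sign(np.diag(rr))  # fix QR sign ambiguity
        result.projectors[k] = q
    return result


def hsic_screen(latents, r: int, prefilter_frac: float = DEFAULT_FRAC,
                refresh_iteration: int = 0) -> ScreeningResult:
    """Select r shared coordinates per view by Pearson prefilter + HSIC ranking."""
    views = _as_dict(latents)
    names = sorted(views)
    if len(names) < 2:
        raise ValueError("HSIC screening needs at least two views")
    n = views[names[0]].shape[0]
    if n < 8:
        raise ValueError("HSIC screening needs n >= 8")
    if not (0.0 < prefilter_frac <= 1.0):
        raise ValueError("prefilter_frac must lie in (0, 1]")

    std = {k: (v - v.mean(axis=0)) / np.maximum(v.std(axis=0), 1e-12)
           for k, v in views.items()}
    result = ScreeningResult(mode="hsic", rank=r, refresh_iteration=refresh_iteration)

    # survivors of the Pearson prefilter, per view
    survivors: dict[str, np.ndarray] = {}
    for k in names:
        d = views[k].shape[1]
        max_abs_corr = np.zeros(d)
        for other in names:
            if other == k:
                continue
            corr = np.abs(std[k].T @ std[other] / n)  # d x d_other
            max_abs_corr = np.maximum(max_abs_corr, corr.max(axis=1))
        keep = max(int(np.ceil(prefilter_frac * d)), 1)
        # stable: sort by (-corr, index) so ties break toward lower index
        order = np.lexsort((np.arange(d), -max_abs_corr))
        survivors[k] = np.sort(order[:keep])
        if survivors[k].size < r:
            raise ValueError(
                f"view {k!r}: only {survivors[k].size} coordinates survive the "
                f"prefilter but r={r}; increase prefilter_frac"
            )

    for k in names:
        scores = np.zeros(survivors[k].size)
        for other in names:
            if other == k:
                continue
            block = views[other][:, survivors[other]]
            for i, j in enumerate(survivors[k]):
                scores[i] += hsic_estimate(views[k][:, j], block, variant="unbiased")
        scores /= len(names) - 1
        order = np.lexsort((survivors[k], -scores))
        result.masks[k] = np.sort(survivors[k][order[:r]])
    return result
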