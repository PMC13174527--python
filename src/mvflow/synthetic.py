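"""Synthetic subject-matched multiview data with known ground truth.

Two families of generators make every part of the toolkit testable without
any data download:

* :func:`make_multiview_tabular` — tabular views driven by a planted shared
  factor S plus per-view private factors P^(v), observed through linear or
  monotone-nonlinear mixing with additive Gaussian noise.  This emulates
  subject-matched imaging-derived-phenotype cohorts: the subject pairing
  carries the shared signal, so shuffling the pairing destroys cross-view
  correlation.
* :func:`make_phantoms` — multimodal image phantoms: a smooth-edged
  ellipse/ellipsoid foreground whose per-subject geometry (center, radii)
  is shared across all views of a subject, while each view applies its own
  monotone intensity transfer — emulating co-registered multimodal MRI,
  where anatomy is shared and contrast is view-specific.

:func:`augment_image` mirrors the training-time augmentation families:
shared geometric perturbations (small affine, smoothed random deformation)
applied identically to every view of a subject, and per-view intensity
perturbations (multiplicative low-frequency bias field, monotone histogram
warp, additive noise).  All generators are pure functions of spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter, map_coordinates

__all__ = [
    "SharedFactorSpec",
    "TabularViews",
    "make_multiview_tabular",
    "PhantomSpec",
    "PhantomViews",
    "make_phantoms",
    "augment_image",
]


# ---------------------------------------------------------------------------
# tabular
# ---------------------------------------------------------------------------


@dataclass
class SharedFactorSpec:
    """Planted-factor model for subject-matched tabular views."""

    n_subjects: int = 500
    shared_dim: int = 2
    private_dim: int = 2
    view_dims: tuple[int, ...] = (8, 8)
    mixing: str = "linear"            # linear | monotone_nonlinear
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.mixing not in ("linear", "monotone_nonlinear"):
            raise ValueError("mixing must be 'linear' or 'monotone_nonlinear'")
        if any(d < 1 for d in self.view_dims):
            raise ValueError("view dims must be positive")
        if self.shared_dim < 0 or self.private_dim < 0:
            raise ValueError("factor dims must be non-negative")
        if self.shared_dim == 0 and self.private_dim == 0:
            raise ValueError("at least one factor dimension required")


@dataclass
class TabularViews:
    views: dict[str, np.ndarray]
    shared_factors: np.ndarray                      # (n, k_s)
    private_factors: dict[str, np.ndarray]
    loadings: dict[str, np.ndarray]                 # mixing matrices (k_s+k_p, d_v)


def make_multiview_tabular(spec: SharedFactorSpec) -> TabularViews:
    """Generate subject-matched views from shared + private Gaussian factors.

    Observations are ``mix([S, P^(v)]) + noise`` per view; with
    ``monotone_nonlinear`` mixing an elementwise smooth monotone map
    (x + 0.5*tanh(x)) is applied after the linear mix, preserving the
    factor information while bending the marginals.
    """
    rng = np.random.default_rng(spec.seed)
    n, ks, kp = spec.n_subjects, spec.shared_dim, spec.private_dim
    S = rng.standard_normal((n, ks))
    views: dict[str, np.ndarray] = {}
    privates: dict[str, np.ndarray] = {}
    loadings: dict[str, np.ndarray] = {}
    for i, d in enumerate(spec.view_dims):
        name = f"view{i}"
        P = rng.standard_normal((n, kp))
        A = rng.standard_normal((ks + kp, d)) / np.sqrt(ks + kp)
        lin = np.concatenate([S, P], axis=1) @ A
        if spec.mixing == "monotone_nonlinear":
            x = lin + 0.5 * np.tanh(lin)
        else:
            x = lin
        x = x + spec.noise_sd * rng.standard_normal((n, d))
        views[name] = x
        privates[name] = P
        loadings[name] = A
    return TabularViews(views, S, privates, loadings)


# ---------------------------------------------------------------------------
# image phantoms
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Multimodal ellipse/ellipsoid phantoms with shared per-subject geometry."""

    n_subjects: int = 64
    size: tuple[int, ...] = (16, 16)     # 2D (H, W) or 3D (D, H, W)
    n_views: int = 2
    center_jitter: float = 1.5            # voxels, per-subject center variation
    radius_mean: float = 4.0
    radius_jitter: float = 1.0
    edge_softness: float = 1.0            # sigmoid width of the boundary, voxels
    seed: int = 0

    def __post_init__(self):
        if len(self.size) not in (2, 3):
            raise ValueError("size must be 2D or 3D")
        if self.radius_mean + self.radius_jitter >= min(self.size) / 2:
            raise ValueError("radius exceeds image extent")


@dataclass
class PhantomViews:
    views: dict[str, np.ndarray]          # each (n, 1, *size), intensities in [0,1]
    centers: np.ndarray                   # (n, ndim)
    radii: np.ndarray                     # (n, ndim)


def _contrast_transfer(view_index: int) -> callable:
    """Fixed monotone intensity transfer per view (gamma-style curves)."""
    gamma = (0.6, 1.6, 1.0, 2.2, 0.4)[view_index % 5]
    lo, hi = (0.12, 0.95) if view_index % 2 == 0 else (0.05, 0.8)
    return lambda u: lo + (hi - lo) * np.power(np.clip(u, 0.0, 1.0), gamma)


def make_phantoms(spec: PhantomSpec) -> PhantomViews:
    """Smooth-edged ellipse/ellipsoid foreground with per-view contrast."""
    rng = np.random.default_rng(spec.seed)
    nd = len(spec.size)
    n = spec.n_subjects
    size = np.array(spec.size, dtype=float)
    centers = size / 2 + rng.uniform(-spec.center_jitter, spec.center_jitter, (n, nd))
    radii = spec.radius_mean + rng.uniform(-spec.radius_jitter, spec.radius_jitter,
                                           (n, nd))
    grids = np.meshgrid(*[np.arange(s) for s in spec.size], indexing="ij")
    views = {f"view{v}": np.empty((n, 1) + tuple(spec.size)) for v in range(spec.n_views)}
    for i in range(n):
        # smooth-edged ellipsoid: sigmoid of the signed ellipsoidal distance
        q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centers[i], radii[i]))
        signed = (np.sqrt(q) - 1.0) * float(np.mean(radii[i]))
        fg = 1.0 / (1.0 + np.exp(signed / spec.edge_softness))
        for v in range(spec.n_views):
            views[f"view{v}"][i, 0] = _contrast_transfer(v)(fg)
    return PhantomViews(views, centers, radii)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _affine_displace(shape: tuple[int, ...], sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Coordinates of a small random affine (rotation/scale/shift) resample."""
    nd = len(shape)
    center = (np.array(shape, dtype=float) - 1) / 2
    A = np.eye(nd) + sd * rng.standard_normal((nd, nd))
    shift = sd * np.array(shape) * 0.25 * rng.standard_normal(nd)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    coords = np.stack([g - c for g, c in zip(grids, center)])
    flat = coords.reshape(nd, -1)
    new = (A @ flat).reshape(coords.shape)
    return np.stack([nc + c + s for nc, c, s in zip(new, center, shift)])


def _deformation_field(shape: tuple[int, ...], sd: float,
                       rng: np.random.Generator, smooth_sd: float = 4.0) -> np.ndarray:
    nd = len(shape)
    field = rng.standard_normal((nd,) + shape)
    for a in range(nd):
        field[a] = gaussian_filter(field[a], smooth_sd)
        mag = np.sqrt(np.mean(field[a] ** 2))
        if mag > 0:
            field[a] *= sd / mag
    return field


def _bias_field(shape: tuple[int, ...], sd: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-one multiplicative field: exp of a low-order smooth random polynomial."""
    nd = len(shape)
    coords = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape], indexing="ij")
    poly = np.zeros(shape)
    for c in coords:
        poly += rng.normal(0, sd) * c + rng.normal(0, sd) * c**2
    for i in range(nd):
        for j in range(i + 1, nd):
            poly += rng.normal(0, sd) * coords[i] * coords[j]
    poly -= poly.mean()
    return np.exp(poly)


def _histogram_warp(img: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Random monotone piecewise-cubic intensity transfer on [0, 1]."""
    knots = np.linspace(0.0, 1.0, 7)
    jitter = rng.normal(0.0, sd, size=knots.size)
    targets = knots + jitter - jitter[0]
    targets = np.maximum.accumulate(targets + np.linspace(0, 1e-6, knots.size))
    targets = (targets - targets[0]) / max(targets[-1] - targets[0], 1e-9)
    f = PchipInterpolator(knots, targets)
    lo, hi = float(img.min()), float(img.max())
    span = max(hi - lo, 1e-12)
    u = (img - lo) / span
    return f(u) * span + lo


def augment_image(img: np.ndarray, strengths: dict[str, float],
                  shared_geometric_seed: int, view_seed: int) -> np.ndarray:
    """Apply the training augmentation stack to one image (C, *spatial).

    Order: shared affine -> shared smooth deformation (both driven by
    ``shared_geometric_seed`` so every view of a subject receives the
    identical geometry) -> per-view bias field -> per-view monotone
    histogram warp -> per-view additive Gaussian noise (``view_seed``).
    Strength names: ``sd_affine``, ``sd_deformation``,
    ``sd_simulated_bias_field``, ``sd_histogram_warping``, ``noise_std``;
    all zero (or absent) is the identity bit-exactly.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim < 3:
        raise ValueError("expected channel-first image (C, *spatial)")
    for k, v in strengths.items():
        if v < 0:
            raise ValueError(f"strength {k!r} must be >= 0")
    spatial = img.shape[1:]
    out = img
    geo_rng = np.random.default_rng(shared_geometric_seed)
    sd_aff = strengths.get("sd_affine", 0.0)
    if sd_aff > 0:
        coords = _affine_displace(spatial, sd_aff, geo_rng)
        out = np.stack([map_coordinates(ch, coords, order=1, mode="nearest")
                        for ch in out])
    sd_def = strengths.get("sd_deformation", 0.0)
    if sd_def > 0:
        field = _deformation_field(spatial, sd_def, geo_rng)
        grids = np.meshgrid(*[np.arange(s, dtype=float) for s in spatial], indexing="ij")
        coords = np.stack(grids) + field
        out = np.stack([map_coordinates(ch, coords, order=1, mode="nearest")
                        for ch in out])
    view_rng = np.random.default_rng(view_seed)
    sd_bias = strengths.get("sd_simulated_bias_field", 0.0)
    if sd_bias > 0:
        out = out * _bias_field(spatial, sd_bias, view_rng)
    sd_hist = strengths.get("sd_histogram_warping", 0.0)
    if sd_hist > 0:
        out = np.stack([_histogram_warp(ch, sd_hist, view_rng) for ch in out])
    noise = strengths.get("noise_std", 0.0)
    if noise > 0:
        out = out + noise * view_rng.standard_normal(out.shape)
    return out
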