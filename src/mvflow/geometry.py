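"""Latent-space navigation respecting high-dimensional Gaussian geometry.

In a standard-normal latent space of dimension d, probability mass
concentrates on a thin shell of radius ~ sqrt(d) (the Gaussian annulus /
typical set), so straight-line interpolation between two typical latents
cuts through the low-probability interior and its decoded images degrade
("variance collapse").  The operations here keep trajectories and distances
on the shell: spherical linear interpolation (optionally centered on the
population mean), angular geodesic distance, standardized-Euclidean
(diagonal Mahalanobis) distance, temperature-scaled sampling, and decoding
of the latent origin as the population template — a barycentric anchor of
the learned bijection rather than a typical sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow_image import ImageFlowModel, MultiscaleLatent
from .flow_tabular import TabularFlowModel

__all__ = [
    "GeometryContext",
    "slerp",
    "slerp_mu_centered",
    "geodesic_distance",
    "standardized_euclidean",
    "sample_with_temperature",
    "decode_template",
]

COS_CLAMP = 1.0 - 1e-7


@dataclass
class GeometryContext:
    """Population statistics for mean-centered / standardized operations."""

    mean: np.ndarray
    variances: np.ndarray | None = None
    epsilon: float = 1e-8

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        if self.variances is not None:
            self.variances = np.asarray(self.variances, dtype=np.float64)
            if np.any(self.variances < self.epsilon):
                raise ValueError("per-coordinate variances must be >= epsilon")


def _raw_cosine(z1: np.ndarray, z2: np.ndarray) -> float:
    n1 = np.linalg.norm(z1)
    n2 = np.linalg.norm(z2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("zero vector has no direction")
    return float(z1 @ z2 / (n1 * n2))


def _clamped_cosine(z1: np.ndarray, z2: np.ndarray) -> float:
    return float(np.clip(_raw_cosine(z1, z2), -COS_CLAMP, COS_CLAMP))


def slerp(z1: np.ndarray, z2: np.ndarray, t: float) -> np.ndarray:
    """Spherical linear interpolation between two latent vectors.

    Constant angular velocity along the great circle spanned by z1 and z2;
    falls back to linear interpolation in the small-angle (collinear) limit
    and rejects antipodal endpoints where the great circle is ambiguous.
    """
    z1 = np.asarray(z1, dtype=np.float64).ravel()
    z2 = np.asarray(z2, dtype=np.float64).ravel()
    c = _raw_cosine(z1, z2)
    if c <= -COS_CLAMP:
        raise ValueError("antipodal endpoints: spherical interpolation is not unique")
    if c >= COS_CLAMP:
        return (1.0 - t) * z1 + t * z2  # small-angle limit: linear interpolation
    theta = float(np.arccos(c))
    s = np.sin(theta)
    return (np.sin((1.0 - t) * theta) / s) * z1 + (np.sin(t * theta) / s) * z2


def slerp_mu_centered(ctx: GeometryContext, z1: np.ndarray, z2: np.ndarray,
                      t: float) -> np.ndarray:
    """Slerp applied relative to the population mean: mu + slerp(z1-mu, z2-mu, t)."""
    z1 = np.asarray(z1, dtype=np.float64).ravel()
    z2 = np.asarray(z2, dtype=np.float64).ravel()
    mu = ctx.mean
    return mu + slerp(z1 - mu, z2 - mu, t)


def geodesic_distance(z1: np.ndarray, z2: np.ndarray) -> float:
    """Angular distance arccos(clamped cosine similarity), in [0, pi]."""
    z1 = np.asarray(z1, dtype=np.float64).ravel()
    z2 = np.asarray(z2, dtype=np.float64).ravel()
    return float(np.arccos(_clamped_cosine(z1, z2)))


def standardized_euclidean(ctx: GeometryContext, z: np.ndarray) -> float:
    """Diagonal Mahalanobis distance to mu: sqrt(sum (z_i-mu_i)^2/(sigma_i^2+eps))."""
    z = np.asarray(z, dtype=np.float64).ravel()
    if z.shape != ctx.mean.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {ctx.mean.shape}")
    var = ctx.variances if ctx.variances is not None else np.ones_like(ctx.mean)
    return float(np.sqrt(np.sum((z - ctx.mean) ** 2 / (var + ctx.epsilon))))


def sample_with_temperature(flow, temperature: float, n: int,
                            seed: int | None = None) -> np.ndarray:
    """Draw n decoded samples with the base scaled by temperature tau.

    tau < 1 contracts toward the high-density region near the template;
    tau ~ 1 samples the typical set at radius ~ tau*sqrt(d).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    rng = np.random.default_rng(seed)
    if isinstance(flow, TabularFlowModel):
        return flow.sample(n, rng, temperature=temperature)
    if isinstance(flow, ImageFlowModel):
        lat = flow.sample_latent(n, rng, temperature=temperature)
        return flow.decode_np(lat)
    raise TypeError(f"unsupported flow type {type(flow).__name__}")


def decode_template(flow) -> np.ndarray:
    """Decode the latent origin z = 0: the population template.

    The origin is where the Gaussian mean, mode and median coincide; its
    decoded image is the central anchor of the bijection, smoother than any
    typical sample because idiosyncratic high-frequency variation averages
    out.
    """
    if isinstance(flow, TabularFlowModel):
        return flow.inverse(np.zeros((1, flow.dim)))[0]
    if isinstance(flow, ImageFlowModel):
        zero = MultiscaleLatent(
            [np.zeros((1,) + tuple(s)) for s in flow.latent_shapes], view=flow.view
        )
        return flow.decode_np(zero)[0]
    raise TypeError(f"unsupported flow type {type(flow).__name__}")
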