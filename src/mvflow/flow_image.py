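"""Glow-style multiscale invertible flows for 2D and 3D image views.

Each level squeezes space into channels (factor 2 per spatial axis), applies
K flow steps in the order ActNorm -> invertible 1x1(x1) convolution ->
affine coupling, then splits off half the channels into the latent; the last
level exits fully.  The base over each latent block is a channel-wise
diagonal Gaussian with one mean and one log-scale per channel broadcast over
all spatial positions, so the parameter count is 2C regardless of
resolution:

    log p(z) = -(d/2) log(2pi) - (prod N_i) * sum_c s_c
               - 1/2 * sum_{c,x} ((z_{c,x} - mu_c) * exp(-s_c))^2 .

ActNorm layers use data-dependent initialization on a warm-up batch and keep
fixed statistics thereafter; the 1x1 convolutions carry an LU
parameterization with a fixed permutation so the log-determinant is a sum of
log|diag(U)| terms.  Coupling scales are squashed through a tanh cap and
base log-scales are clamped, which keeps deep stacks numerically stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu as scipy_lu

from ._autodiff import ConvNd, Module, Parameter, Tensor, concat

LOG_2PI = float(np.log(2.0 * np.pi))
BASE_LOGSCALE_MAX = 5.0
ACTNORM_SD_FLOOR = 1e-6

__all__ = [
    "ActNorm",
    "Invertible1x1ConvLU",
    "invertible_conv_logdet",
    "ChannelwiseBase",
    "MultiscaleLatent",
    "ImageFlowModel",
    "build_image_flow",
    "init_actnorm",
    "encode",
    "decode",
    "base_log_prob",
]


# ---------------------------------------------------------------------------
# squeeze / unsqueeze (channel-major, checkerboard-free)
# ---------------------------------------------------------------------------


def _squeeze(x: Tensor, nd: int) -> Tensor:
    """(B, C, N1..Ns) -> (B, C*2^s, N1/2..Ns/2), channel-major block order."""
    shape = x.shape
    B, C = shape[0], shape[1]
    spatial = shape[2:]
    split_shape = [B, C]
    for s in spatial:
        split_shape += [s // 2, 2]
    x = x.reshape(tuple(split_shape))
    # move the size-2 block axes right after the channel axis
    block_axes = tuple(3 + 2 * i for i in range(nd))
    space_axes = tuple(2 + 2 * i for i in range(nd))
    x = x.transpose((0, 1) + block_axes + space_axes)
    return x.reshape((B, C * 2**nd) + tuple(s // 2 for s in spatial))


def _unsqueeze(z: np.ndarray, nd: int) -> np.ndarray:
    B, C = z.shape[0], z.shape[1]
    spatial = z.shape[2:]
    c_out = C // 2**nd
    z = z.reshape((B, c_out) + (2,) * nd + tuple(spatial))
    order = [0, 1]
    for i in range(nd):
        order += [2 + nd + i, 2 + i]
    z = z.transpose(order)
    return z.reshape((B, c_out) + tuple(2 * s for s in spatial))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class ActNorm(Module):
    """Per-channel affine y = exp(s) * (x + b), data-dependent init."""

    def __init__(self, channels: int, nd: int):
        self.nd = nd
        self.bias = Parameter(np.zeros(channels))
        self.log_scale = Parameter(np.zeros(channels))
        self.initialized = False

    def _bshape(self) -> tuple[int, ...]:
        return (1, -1) + (1,) * self.nd

    def initialize(self, x: np.ndarray) -> None:
        if self.initialized:
            raise RuntimeError("ActNorm already initialized")
        if x.shape[0] < 2:
            raise ValueError("ActNorm init needs >= 2 samples (sd is degenerate)")
        axes = (0,) + tuple(range(2, x.ndim))
        mean = x.mean(axis=axes)
        sd = np.maximum(x.std(axis=axes), ACTNORM_SD_FLOOR)
        self.bias.data = -mean
        self.log_scale.data = -np.log(sd)
        self.initialized = True

    def forward(self, x: Tensor) -> tuple[Tensor, float]:
        if not self.initialized:
            raise RuntimeError("ActNorm not initialized; run init_actnorm first")
        shape = self._bshape()
        y = (x + self.bias.reshape(shape)) * self.log_scale.reshape(shape).exp()
        n_spatial = int(np.prod(x.shape[2:]))
        logdet = n_spatial * self.log_scale.sum()
        return y, logdet

    def inverse_np(self, y: np.ndarray) -> np.ndarray:
        shape = self._bshape()
        return y * np.exp(-self.log_scale.data.reshape(shape)) - self.bias.data.reshape(shape)


class Invertible1x1ConvLU(Module):
    """Channel-mixing invertible 1x1(x1) convolution, LU-parameterized.

    W = P L U with P a fixed permutation, L unit-lower-triangular and U
    upper-triangular with parameterized log|diag|; log|det W| over an image
    is (prod N_i) * sum log|diag(U)|.
    """

    def __init__(self, channels: int, nd: int, rng: np.random.Generator):
        self.nd = nd
        self.channels = channels
        w0 = np.linalg.qr(rng.standard_normal((channels, channels)))[0]  # random rotation
        p, l, u = scipy_lu(w0)
        diag = np.diag(u).copy()
        self.perm = p  # fixed
        self.sign_s = np.sign(diag)  # fixed
        self.lower = Parameter(np.tril(l, -1))
        self.upper = Parameter(np.triu(u, 1))
        self.log_s = Parameter(np.log(np.abs(diag)))
        self._mask_l = np.tril(np.ones((channels, channels)), -1)
        self._mask_u = np.triu(np.ones((channels, channels)), 1)
        self._eye = np.eye(channels)

    def _weight(self) -> Tensor:
        L = self.lower * Tensor(self._mask_l) + Tensor(self._eye)
        U = self.upper * Tensor(self._mask_u) + Tensor(self._eye) * (
            self.log_s.exp() * Tensor(self.sign_s)
        )
        return Tensor(self.perm) @ L @ U

    def weight_np(self) -> np.ndarray:
        return self._weight().data

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        B, C = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        W = self._weight()
        y = (W @ x.reshape(B, C, -1)).reshape((B, C) + tuple(spatial))
        n_spatial = int(np.prod(spatial))
        logdet = n_spatial * self.log_s.sum()
        return y, logdet

    def inverse_np(self, y: np.ndarray) -> np.ndarray:
        B, C = y.shape[0], y.shape[1]
        W = self.weight_np()
        x = np.linalg.solve(W, y.reshape(B, C, -1))
        return x.reshape(y.shape)


def invertible_conv_logdet(conv, spatial_size) -> float:
    """Log-determinant of an LU-parameterized 1x1 convolution over an image.

    ``conv`` is an :class:`Invertible1x1ConvLU` or a tuple ``(P, L, U)``;
    returns ``prod(spatial_size) * sum(log |diag(U)|)``.
    """
    n_spatial = int(np.prod(spatial_size))
    if isinstance(conv, Invertible1x1ConvLU):
        diag = np.exp(conv.log_s.data) * conv.sign_s
    else:
        _, L, U = conv
        if not np.allclose(np.diag(L), 1.0):
            raise ValueError("L must be unit-triangular")
        diag = np.diag(U)
    if np.any(diag == 0.0):
        raise ValueError("singular 1x1 convolution: zero diagonal entry in U")
    return float(n_spatial * np.sum(np.log(np.abs(diag))))


class _ConvCoupling(Module):
    """Affine coupling with a shallow convolutional conditioner.

    The first half of the channels conditions; the second half is shifted
    and scaled.  Two hidden conv layers with 3^S kernels; the last layer is
    zero-initialized so the coupling starts as the identity.
    """

    def __init__(self, channels: int, hidden: int, nd: int, scale_cap: float,
                 rng: np.random.Generator):
        self.c_cond = channels // 2
        self.c_trans = channels - self.c_cond
        self.scale_cap = float(scale_cap)
        self.conv1 = ConvNd(self.c_cond, hidden, 3, nd, rng)
        self.conv2 = ConvNd(hidden, hidden, 3, nd, rng)
        self.conv3 = ConvNd(hidden, 2 * self.c_trans, nd=nd, ksize=3, rng=rng,
                            zero_init=True)

    def _shift_logscale(self, xc: Tensor) -> tuple[Tensor, Tensor]:
        h = self.conv1(xc).relu()
        h = self.conv2(h).relu()
        h = self.conv3(h)
        shift = h[:, : self.c_trans]
        raw = h[:, self.c_trans:]
        log_s = self.scale_cap * (raw / self.scale_cap).tanh() if self.scale_cap > 0 else raw * 0.0
        return shift, log_s

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        xc = x[:, : self.c_cond]
        xt = x[:, self.c_cond:]
        shift, log_s = self._shift_logscale(xc)
        yt = xt * log_s.exp() + shift
        y = concat([xc, yt], axis=1)
        return y, log_s.reshape(log_s.shape[0], -1).sum(axis=1)

    def inverse_np(self, y: np.ndarray) -> np.ndarray:
        yc = Tensor(y[:, : self.c_cond])
        shift, log_s = self._shift_logscale(yc)
        x = y.copy()
        x[:, self.c_cond:] = (y[:, self.c_cond:] - shift.data) * np.exp(-log_s.data)
        return x


class _FlowStep(Module):
    def __init__(self, channels: int, hidden: int, nd: int, scale_cap: float,
                 rng: np.random.Generator):
        self.actnorm = ActNorm(channels, nd)
        self.invconv = Invertible1x1ConvLU(channels, nd, rng)
        self.coupling = _ConvCoupling(channels, hidden, nd, scale_cap, rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        x, ld1 = self.actnorm.forward(x)
        x, ld2 = self.invconv.forward(x)
        x, ld3 = self.coupling.forward(x)
        return x, ld1 + ld2 + ld3

    def forward_init(self, x: np.ndarray) -> np.ndarray:
        """Numpy pass that performs data-dependent ActNorm init."""
        self.actnorm.initialize(x)
        y, _ = self.actnorm.forward(Tensor(x))
        y, _ = self.invconv.forward(Tensor(y.data))
        y, _ = self.coupling.forward(Tensor(y.data))
        return y.data

    def inverse_np(self, y: np.ndarray) -> np.ndarray:
        y = self.coupling.inverse_np(y)
        y = self.invconv.inverse_np(y)
        return self.actnorm.inverse_np(y)


class ChannelwiseBase(Module):
    """Channel-wise diagonal Gaussian over one latent block."""

    def __init__(self, channels: int, spatial: tuple[int, ...]):
        self.channels = channels
        self.spatial = tuple(spatial)
        self.mu = Parameter(np.zeros(channels))
        self.s = Parameter(np.zeros(channels))

    @property
    def dim(self) -> int:
        return self.channels * int(np.prod(self.spatial))

    def clamp_(self) -> None:
        np.clip(self.s.data, -BASE_LOGSCALE_MAX, BASE_LOGSCALE_MAX, out=self.s.data)

    def log_prob(self, z: Tensor) -> Tensor:
        """Per-sample log-density; parameters broadcast over spatial indices."""
        self.clamp_()
        nd = len(self.spatial)
        shape = (1, -1) + (1,) * nd
        n_spatial = int(np.prod(self.spatial))
        u = (z - self.mu.reshape(shape)) * (-self.s).reshape(shape).exp()
        quad = (u * u).reshape(z.shape[0], -1).sum(axis=1)
        return (
            -0.5 * self.dim * LOG_2PI
            - n_spatial * self.s.sum()
            - 0.5 * quad
        )

    def sample(self, n: int, rng: np.random.Generator, temperature: float = 1.0) -> np.ndarray:
        self.clamp_()
        shape = (1, -1) + (1,) * len(self.spatial)
        eps = rng.standard_normal((n, self.channels) + self.spatial)
        return self.mu.data.reshape(shape) + temperature * np.exp(self.s.data.reshape(shape)) * eps


def base_log_prob(base: ChannelwiseBase, z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    if z.shape[1:] != (base.channels,) + base.spatial:
        raise ValueError(
            f"latent shape {z.shape[1:]} does not match base {(base.channels,) + base.spatial}"
        )
    return base.log_prob(Tensor(z)).data


@dataclass
class MultiscaleLatent:
    """Per-level latent blocks of one (batch of) image(s)."""

    blocks: list[np.ndarray]
    view: str = ""

    @property
    def batch_size(self) -> int:
        return self.blocks[0].shape[0]

    @property
    def total_dim(self) -> int:
        return sum(int(np.prod(b.shape[1:])) for b in self.blocks)

    def flatten(self) -> np.ndarray:
        """(B, total_dim) concatenation in level order (shallow -> deep)."""
        return np.concatenate([b.reshape(b.shape[0], -1) for b in self.blocks], axis=1)

    @staticmethod
    def unflatten(flat: np.ndarray, shapes: list[tuple[int, ...]], view: str = "") -> "MultiscaleLatent":
        flat = np.atleast_2d(flat)
        blocks, off = [], 0
        for shp in shapes:
            size = int(np.prod(shp))
            blocks.append(flat[:, off: off + size].reshape((flat.shape[0],) + tuple(shp)))
            off += size
        if off != flat.shape[1]:
            raise ValueError("flat latent size does not match block shapes")
        return MultiscaleLatent(blocks, view=view)


class ImageFlowModel(Module):
    """Multiscale Glow flow: per level squeeze -> K steps -> split."""

    def __init__(self, input_shape: tuple[int, ...], levels: int,
                 steps_per_level, hidden_channels: int, scale_cap: float = 3.0,
                 seed: int = 0, view: str = ""):
        C, *spatial = input_shape
        nd = len(spatial)
        if nd not in (2, 3):
            raise ValueError("input_shape must be (C, H, W) or (C, D, H, W)")
        for s in spatial:
            if s % 2**levels != 0:
                raise ValueError(
                    f"spatial size {s} must be divisible by 2^L = {2**levels}"
                )
        if isinstance(steps_per_level, int):
            steps = [steps_per_level] * levels
        else:
            steps = list(steps_per_level)  # shallow -> deep
            if len(steps) != levels:
                raise ValueError("need one step count per level")
        self.input_shape = tuple(input_shape)
        self.nd = nd
        self.levels = levels
        self.steps = steps
        self.hidden_channels = hidden_channels
        self.scale_cap = float(scale_cap)
        self.view = view
        rng = np.random.default_rng(seed)

        self.level_steps: list[list[_FlowStep]] = []
        self.bases: list[ChannelwiseBase] = []
        self.latent_shapes: list[tuple[int, ...]] = []
        c, sp = C, list(spatial)
        for lev in range(levels):
            c *= 2**nd
            sp = [s // 2 for s in sp]
            self.level_steps.append(
                [_FlowStep(c, hidden_channels, nd, scale_cap, rng) for _ in range(steps[lev])]
            )
            if lev < levels - 1:
                c_out = c // 2
                c = c - c_out
            else:
                c_out = c
            self.latent_shapes.append((c_out,) + tuple(sp))
            self.bases.append(ChannelwiseBase(c_out, tuple(sp)))

    # -- initialization -------------------------------------------------------

    @property
    def actnorm_initialized(self) -> bool:
        return all(st.actnorm.initialized for lev in self.level_steps for st in lev)

    @property
    def total_latent_dim(self) -> int:
        return sum(int(np.prod(s)) for s in self.latent_shapes)

    # -- bijection ------------------------------------------------------------

    def forward(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        if not self.actnorm_initialized:
            raise RuntimeError("ActNorm not initialized; call init_actnorm first")
        logdet = Tensor(np.zeros(x.shape[0]))
        blocks: list[Tensor] = []
        for lev in range(self.levels):
            x = _squeeze(x, self.nd)
            for step in self.level_steps[lev]:
                x, ld = step.forward(x)
                logdet = logdet + ld
            if lev < self.levels - 1:
                c_out = self.latent_shapes[lev][0]
                blocks.append(x[:, :c_out])  # first half of channels exits
                x = x[:, c_out:]
            else:
                blocks.append(x)
        return blocks, logdet

    def log_prob(self, x: Tensor) -> Tensor:
        blocks, logdet = self.forward(x)
        lp = logdet
        for base, z in zip(self.bases, blocks):
            lp = lp + base.log_prob(z)
        return lp

    def decode_np(self, latent: MultiscaleLatent) -> np.ndarray:
        for b, shp in zip(latent.blocks, self.latent_shapes):
            if tuple(b.shape[1:]) != tuple(shp):
                raise ValueError(f"latent block shape {b.shape[1:]} != expected {shp}")
        x = None
        for lev in range(self.levels - 1, -1, -1):
            z = latent.blocks[lev]
            x = z if x is None else np.concatenate([z, x], axis=1)
            for step in reversed(self.level_steps[lev]):
                x = step.inverse_np(x)
            x = _unsqueeze(x, self.nd)
        return x

    def sample_latent(self, n: int, rng: np.random.Generator,
                      temperature: float = 1.0) -> MultiscaleLatent:
        return MultiscaleLatent(
            [b.sample(n, rng, temperature) for b in self.bases], view=self.view
        )


def build_image_flow(input_shape: tuple[int, ...], levels: int, steps_per_level,
                     hidden_channels: int, scale_cap: float = 3.0,
                     seed: int = 0, view: str = "") -> ImageFlowModel:
    """Build a multiscale image flow; spatial sizes must be divisible by 2^L."""
    return ImageFlowModel(input_shape, levels, steps_per_level, hidden_channels,
                          scale_cap=scale_cap, seed=seed, view=view)


def init_actnorm(model: ImageFlowModel, warmup_batch: np.ndarray) -> ImageFlowModel:
    """Data-dependent ActNorm initialization on a warm-up batch.

    Statistics are fixed afterwards (the parameters keep training as
    ordinary parameters, but no further data-dependent resets happen);
    re-initialization is rejected.
    """
    x = np.asarray(warmup_batch, dtype=np.float64)
    if model.actnorm_initialized:
        raise RuntimeError("ActNorm already initialized")
    if x.shape[0] < 2:
        raise ValueError("ActNorm warm-up needs >= 2 samples (sd degenerate at 1)")
    if x.shape[0] < 8:
        raise ValueError("ActNorm warm-up batch must have >= 8 samples")
    for lev in range(model.levels):
        x = _squeeze(Tensor(x), model.nd).data
        for step in model.level_steps[lev]:
            x = step.forward_init(x)
        if lev < model.levels - 1:
            c_out = model.latent_shapes[lev][0]
            x = x[:, c_out:]
    return model


def encode(model: ImageFlowModel, x: np.ndarray) -> tuple[MultiscaleLatent, np.ndarray]:
    """Deterministic encode; returns multiscale latents and exact log-det."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == len(model.input_shape):
        x = x[None]
    if tuple(x.shape[1:]) != model.input_shape:
        raise ValueError(f"input shape {x.shape[1:]} != model {model.input_shape}")
    blocks, logdet = model.forward(Tensor(x))
    return MultiscaleLatent([b.data for b in blocks], view=model.view), logdet.data


def decode(model: ImageFlowModel, latent: MultiscaleLatent) -> np.ndarray:
    """Exact inverse of :func:`encode`."""
    return model.decode_np(latent)
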