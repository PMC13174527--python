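"""Joint optimization of the multiview flow objective.

The training objective over a subject-matched minibatch of size N is

    L(theta, psi) = (1/N) sum_n sum_v -log p_theta(x_n^(v))
                    + lambda * L_align({phi_psi^(v)(z_S,n^(v))}),

i.e. the sum of exact per-view negative log-likelihoods plus a weighted
alignment term on projected shared latent coordinates; lambda = 0 recovers
pure maximum likelihood exactly.  Supporting machinery: decay schedules for
jitter/augmentation amplitudes, additive dequantization noise, gradient
accumulation (microbatching) with per-microbatch alignment statistics,
global-norm clipping, Adamax with learning-rate warm-up and
reduce-on-plateau, and an exponential moving average of parameters used for
sampling and inference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import EMA, Adamax, Tensor, clip_global_norm, concat
from .alignment import AlignmentConfig, Projector, alignment_loss, build_projectors
from .flow_image import ImageFlowModel
from .flow_tabular import TabularFlowModel, build_tabular_flow
from .screening import ScreeningResult, cca_screen, hsic_screen

__all__ = [
    "AugmentationSchedule",
    "parse_schedule_entry",
    "schedule_value",
    "MultiviewBatch",
    "TrainingConfig",
    "total_loss",
    "TrainerState",
    "accumulate_and_step",
    "ema_update",
    "dequantize",
    "train_tabular",
    "train_image",
    "TrainResult",
]


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------


@dataclass
class ScheduleEntry:
    kind: str          # linear | cos | exp
    v0: float
    v1: float
    horizon: int = 0   # iterations over which t runs 0 -> 1; 0 = use total

    def __post_init__(self):
        if self.kind not in ("linear", "cos", "exp"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "exp" and (self.v0 <= 0 or self.v1 <= 0):
            raise ValueError("exponential schedule requires positive endpoints")


@dataclass
class AugmentationSchedule:
    """Named decay curves for jitter/augmentation amplitudes."""

    entries: dict[str, ScheduleEntry] = field(default_factory=dict)
    total_iterations: int = 1

    def value(self, name: str, t: float) -> float:
        return schedule_value(self, name, t)

    def value_at_iteration(self, name: str, iteration: int) -> float:
        e = self.entries[name]
        horizon = e.horizon or self.total_iterations
        return schedule_value(self, name, iteration / max(horizon, 1))


_ENTRY_RE = re.compile(
    r"^\s*(?P<name>[\w.]+)\s*:\s*(?P<kind>linear|cos|exp)\s*:\s*"
    r"(?P<v0>[-+0-9.eE]+)\s*->\s*(?P<v1>[-+0-9.eE]+)\s*$"
)


def parse_schedule_entry(text: str) -> tuple[str, ScheduleEntry]:
    """Parse the grammar ``<name>:<kind>:<v0>-><v1>``, e.g. ``noise_std: cos:0.05->0.02``."""
    m = _ENTRY_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse schedule entry {text!r}")
    return m["name"], ScheduleEntry(m["kind"], float(m["v0"]), float(m["v1"]))


def schedule_value(s: AugmentationSchedule, name: str, t: float) -> float:
    """Evaluate a named schedule at normalized training time t (clamped at 1)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if name not in s.entries:
        raise KeyError(f"schedule {name!r} not registered")
    e = s.entries[name]
    t = min(t, 1.0)
    if e.kind == "linear":
        return e.v0 + (e.v1 - e.v0) * t
    if e.kind == "cos":
        return e.v1 + (e.v0 - e.v1) * (1.0 + np.cos(np.pi * t)) / 2.0
    return e.v0 * (e.v1 / e.v0) ** t


def dequantize(x: np.ndarray, amplitude: float, seed: int | None = None,
               kind: str = "gaussian") -> np.ndarray:
    """Additive jitter noise treated as dequantization.

    ``gaussian`` (tabular): x + amplitude * eta with standard-normal eta;
    ``uniform`` (images): x + U[0, amplitude).  Amplitude 0 is the identity
    bit-exactly; a fixed seed reproduces the jitter.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    x = np.asarray(x, dtype=np.float64)
    if amplitude == 0.0:
        return x
    rng = np.random.default_rng(seed)
    if kind == "gaussian":
        return x + amplitude * rng.standard_normal(x.shape)
    if kind == "uniform":
        return x + rng.uniform(0.0, amplitude, size=x.shape)
    raise ValueError("kind must be 'gaussian' or 'uniform'")


def ema_update(ema_params: list[np.ndarray], params: list[np.ndarray],
               decay: float) -> list[np.ndarray]:
    """ema <- decay * ema + (1 - decay) * params, element-wise."""
    if not (0.0 <= decay < 1.0):
        raise ValueError("decay must lie in [0, 1)")
    if len(ema_params) != len(params):
        raise ValueError("parameter list length mismatch")
    out = []
    for e, p in zip(ema_params, params):
        e = np.asarray(e)
        p = np.asarray(p)
        if e.shape != p.shape:
            raise ValueError(f"shape mismatch {e.shape} vs {p.shape}")
        out.append(decay * e + (1.0 - decay) * p)
    return out


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


@dataclass
class MultiviewBatch:
    """Subject-matched per-view observations for one minibatch."""

    views: dict[str, np.ndarray]
    subjects: np.ndarray | None = None

    def __post_init__(self):
        sizes = {k: np.asarray(v).shape[0] for k, v in self.views.items()}
        if len(set(sizes.values())) > 1:
            raise ValueError(f"views are not subject-matched: sizes {sizes}")

    @property
    def size(self) -> int:
        return next(iter(self.views.values())).shape[0]


@dataclass
class TrainingConfig:
    """Optimization settings; effective batch is accum_factor * microbatch_size."""

    iterations: int = 2000
    microbatch_size: int = 64
    accum_factor: int = 1
    learning_rate: float = 5e-4
    warmup_steps: int = 100
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    clip_norm: float = 0.2
    ema_decay: float = 0.999
    seed: int = 0
    val_fraction: float = 0.2
    val_interval: int = 200
    # model
    coupling_depth: int = 4
    hidden_channels: int = 80
    scale_cap: float = 3.0
    base_kind: str = "diag_gaussian"
    # alignment
    alignment: AlignmentConfig = field(default_factory=lambda: AlignmentConfig(weight=0.0))
    projector_hidden: int = 512
    projector_dim: int = 256
    shared_fraction: float = 1.0   # leading fraction of latent coords treated as shared
    # screening
    screen_mode: str | None = None      # None | "cca" | "hsic"
    screen_rank: int = 8
    screen_warmup_iters: int = 1000
    screen_refresh_iters: int = 5000
    screen_prefilter_frac: float = 0.5
    screen_ridge: float = 1e-3
    # jitter
    jitter: AugmentationSchedule = field(default_factory=AugmentationSchedule)

    @property
    def effective_batch(self) -> int:
        return self.accum_factor * self.microbatch_size


def _flow_logprob_and_latent(flow, x: Tensor) -> tuple[Tensor, Tensor]:
    """Per-sample log-density and flat latent (with gradient) for either flow family."""
    if isinstance(flow, TabularFlowModel):
        z, logdet = flow.forward(x)
        return flow.base.log_prob(z) + logdet, z
    if isinstance(flow, ImageFlowModel):
        blocks, logdet = flow.forward(x)
        lp = logdet
        for base, zb in zip(flow.bases, blocks):
            lp = lp + base.log_prob(zb)
        flat = concat([b.reshape(b.shape[0], -1) for b in blocks], axis=1)
        return lp, flat
    raise TypeError(f"unsupported flow type {type(flow).__name__}")


def _shared_slice(dim: int, fraction: float) -> np.ndarray:
    k = max(int(round(fraction * dim)), 1)
    return np.arange(k)


def _embed(flow, projector: Projector, z: Tensor, shared_idx: np.ndarray,
           screening: ScreeningResult | None, view: str) -> Tensor:
    e = projector(z[:, shared_idx])
    if screening is not None:
        if screening.mode == "cca":
            e = e @ Tensor(screening.projectors[view])
        else:
            e = e[:, screening.masks[view]]
    return e


def total_loss(flows: dict[str, object], projectors: dict[str, Projector] | None,
               cfg: AlignmentConfig, batch: MultiviewBatch,
               shared_indices: dict[str, np.ndarray] | None = None,
               screening: ScreeningResult | None = None,
               ) -> tuple[Tensor, dict[str, float]]:
    """Joint objective on one subject-matched batch, with a per-term breakdown.

    Returns (scalar loss tensor, {"nll": ..., "align": ..., per-view nll}).
    With cfg.weight == 0 the result is exactly the mean summed NLL.
    """
    names = sorted(batch.views)
    missing = set(names) ^ set(flows)
    if missing:
        raise ValueError(f"batch/flows view mismatch: {sorted(missing)}")
    breakdown: dict[str, float] = {}
    total_nll: Tensor | None = None
    embeddings = []
    for v in names:
        x = Tensor(np.asarray(batch.views[v], dtype=np.float64))
        lp, z = _flow_logprob_and_latent(flows[v], x)
        nll = -(lp.mean())
        breakdown[f"nll/{v}"] = nll.item()
        total_nll = nll if total_nll is None else total_nll + nll
        if cfg.weight > 0:
            if projectors is None or v not in projectors:
                raise ValueError(f"alignment enabled but no projector for view {v!r}")
            idx = (shared_indices or {}).get(v, np.arange(z.shape[1]))
            embeddings.append(_embed(flows[v], projectors[v], z, idx, screening, v))
    breakdown["nll"] = total_nll.item()
    if cfg.weight > 0:
        if len(names) < 2:
            raise ValueError("alignment requires at least two views")
        align = alignment_loss(cfg, embeddings)
        breakdown["align"] = align.item()
        return total_nll + cfg.weight * align, breakdown
    breakdown["align"] = 0.0
    return total_nll, breakdown


# ---------------------------------------------------------------------------
# optimization state & accumulation
# ---------------------------------------------------------------------------


@dataclass
class TrainerState:
    flows: dict[str, object]
    projectors: dict[str, Projector] | None
    align_cfg: AlignmentConfig
    optimizer: Adamax
    ema: EMA
    clip_norm: float = 0.2
    shared_indices: dict[str, np.ndarray] | None = None
    screening: ScreeningResult | None = None
    iteration: int = 0
    lr_scale: float = 1.0

    def all_params(self):
        return self.optimizer.params


def accumulate_and_step(state: TrainerState, microbatches: list[MultiviewBatch]
                        ) -> dict[str, float]:
    """One effective-batch update from A microbatches.

    Likelihood gradients are summed over microbatches and normalized by the
    total sample count; alignment is computed within each microbatch and
    divided by A (its statistics are local to each microbatch).  One clip +
    optimizer step + EMA update per effective batch.
    """
    A = len(microbatches)
    if A == 0 or any(mb.size == 0 for mb in microbatches):
        raise ValueError("microbatches must be non-empty")
    total_n = sum(mb.size for mb in microbatches)
    state.optimizer.zero_grad()
    agg = {"nll": 0.0, "align": 0.0}
    for mb in microbatches:
        names = sorted(mb.views)
        embeddings = []
        micro_loss: Tensor | None = None
        for v in names:
            x = Tensor(np.asarray(mb.views[v], dtype=np.float64))
            lp, z = _flow_logprob_and_latent(state.flows[v], x)
            # sum (not mean) so normalization is by the total effective count
            term = -(lp.sum()) / float(total_n)
            micro_loss = term if micro_loss is None else micro_loss + term
            agg["nll"] += term.item()
            if state.align_cfg.weight > 0:
                idx = (state.shared_indices or {}).get(v, np.arange(z.shape[1]))
                embeddings.append(
                    _embed(state.flows[v], state.projectors[v], z, idx,
                           state.screening, v)
                )
        if state.align_cfg.weight > 0:
            align = alignment_loss(state.align_cfg, embeddings) / float(A)
            agg["align"] += align.item()
            micro_loss = micro_loss + state.align_cfg.weight * align
        micro_loss.backward()
    grad_norm = clip_global_norm(state.optimizer.params, state.clip_norm)
    state.optimizer.step()
    state.ema.update()
    state.iteration += 1
    agg["grad_norm"] = grad_norm
    agg["loss"] = agg["nll"] + state.align_cfg.weight * agg["align"]
    return agg


class _LRSchedule:
    """Linear warm-up followed by reduce-on-plateau."""

    def __init__(self, base_lr: float, warmup: int, patience: int, factor: float):
        self.base_lr = base_lr
        self.warmup = max(warmup, 1)
        self.patience = patience
        self.factor = factor
        self.scale = 1.0
        self.best = np.inf
        self.bad = 0

    def lr(self, iteration: int) -> float:
        warm = min(1.0, (iteration + 1) / self.warmup)
        return self.base_lr * warm * self.scale

    def observe(self, metric: float) -> None:
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad = 0
        else:
            self.bad += 1
            if self.bad > self.patience:
                self.scale *= self.factor
                self.bad = 0


# ---------------------------------------------------------------------------
# high-level training loops
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    flows: dict[str, object]
    projectors: dict[str, Projector] | None
    screening: ScreeningResult | None
    history: list[dict]
    ema_arrays: list[np.ndarray]
    train_idx: np.ndarray | None = None
    val_idx: np.ndarray | None = None

    def best_val_nll(self) -> float:
        vals = [h["val_nll"] for h in self.history if "val_nll" in h]
        return float(np.min(vals)) if vals else float("nan")


def _subject_split(n: int, val_fraction: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_val = max(int(round(val_fraction * n)), 1) if val_fraction > 0 else 0
    return perm[n_val:], perm[:n_val]


def train_tabular(views: dict[str, np.ndarray], cfg: TrainingConfig) -> TrainResult:
    """Jointly train one tabular flow per view with optional alignment/screening.

    ``views`` maps view name to an already-preprocessed (n_subjects x dim)
    matrix with matched row order across views.  The split into training and
    validation subjects is done here, at the subject level.
    """
    rng = np.random.default_rng(cfg.seed)
    names = sorted(views)
    data = {v: np.asarray(views[v], dtype=np.float64) for v in names}
    n = data[names[0]].shape[0]
    for v in names:
        if data[v].shape[0] != n:
            raise ValueError("views must be subject-matched")
    train_idx, val_idx = _subject_split(n, cfg.val_fraction, rng)

    flows: dict[str, object] = {
        v: build_tabular_flow(data[v].shape[1], cfg.coupling_depth,
                              cfg.hidden_channels, base_kind="diag_gaussian",
                              scale_cap=cfg.scale_cap, seed=cfg.seed + i)
        for i, v in enumerate(names)
    }
    shared_indices = {
        v: _shared_slice(data[v].shape[1], cfg.shared_fraction) for v in names
    }
    projectors = None
    params = [p for f in flows.values() for p in f.parameters()]
    if cfg.alignment.weight > 0:
        projectors = build_projectors(
            {v: shared_indices[v].size for v in names},
            hidden=cfg.projector_hidden, output_dim=cfg.projector_dim,
            seed=cfg.seed,
        )
        params += [p for pj in projectors.values() for p in pj.parameters()]

    optimizer = Adamax(params, lr=cfg.learning_rate)
    sched = _LRSchedule(cfg.learning_rate, cfg.warmup_steps,
                        cfg.plateau_patience, cfg.plateau_factor)
    flow_params = [p for f in flows.values() for p in f.parameters()]
    state = TrainerState(flows=flows, projectors=projectors,
                         align_cfg=cfg.alignment, optimizer=optimizer,
                         ema=EMA(flow_params, cfg.ema_decay),
                         clip_norm=cfg.clip_norm, shared_indices=shared_indices)

    history: list[dict] = []

    def _screen_now(iteration: int) -> ScreeningResult:
        embeds = {}
        for v in names:
            z = flows[v].encode(data[v][train_idx])
            e = projectors[v](Tensor(z[:, shared_indices[v]])).data
            embeds[v] = e
        if cfg.screen_mode == "cca":
            return cca_screen(embeds, cfg.screen_rank, ridge=cfg.screen_ridge,
                              refresh_iteration=iteration)
        return hsic_screen(embeds, cfg.screen_rank,
                           prefilter_frac=cfg.screen_prefilter_frac,
                           refresh_iteration=iteration)

    def _val_nll() -> float:
        total = 0.0
        for v in names:
            lp, _ = _flow_logprob_and_latent(flows[v], Tensor(data[v][val_idx]))
            total += float(-(lp.data.mean()))
        return total

    for it in range(cfg.iterations):
        optimizer.lr = sched.lr(it)
        micro = []
        for _ in range(cfg.accum_factor):
            sel = rng.choice(train_idx, size=min(cfg.microbatch_size, train_idx.size),
                             replace=False)
            mb_views = {}
            for v in names:
                x = data[v][sel]
                if "noise_std" in cfg.jitter.entries:
                    amp = cfg.jitter.value_at_iteration("noise_std", it)
                    x = dequantize(x, amp, seed=int(rng.integers(2**31)), kind="gaussian")
                mb_views[v] = x
            micro.append(MultiviewBatch(mb_views, subjects=sel))
        if (cfg.alignment.weight > 0 and cfg.screen_mode
                and it >= cfg.screen_warmup_iters
                and (it - cfg.screen_warmup_iters) % cfg.screen_refresh_iters == 0):
            state.screening = _screen_now(it)
        stats = accumulate_and_step(state, micro)
        rec = {"iteration": it, "lr": optimizer.lr, **stats}
        if val_idx.size and (it % cfg.val_interval == cfg.val_interval - 1 or it == 0):
            rec["val_nll"] = _val_nll()
            sched.observe(rec["val_nll"])
        history.append(rec)

    return TrainResult(flows=flows, projectors=projectors,
                       screening=state.screening, history=history,
                       ema_arrays=[a.copy() for a in state.ema.shadow],
                       train_idx=train_idx, val_idx=val_idx)


def train_image(images: np.ndarray, model: ImageFlowModel,
                cfg: TrainingConfig) -> TrainResult:
    """Maximum-likelihood training of a single image flow (lambda = 0 path).

    ``images`` is (n, C, *spatial); ActNorm is initialized on the first
    warm-up batch if needed.  Uniform dequantization jitter follows the
    ``noise_std`` schedule when present.
    """
    rng = np.random.default_rng(cfg.seed)
    x = np.asarray(images, dtype=np.float64)
    n = x.shape[0]
    train_idx, val_idx = _subject_split(n, cfg.val_fraction, rng)
    if not model.actnorm_initialized:
        warm = x[train_idx[: max(8, min(32, train_idx.size))]]
        from .flow_image import init_actnorm

        init_actnorm(model, warm)

    params = model.parameters()
    optimizer = Adamax(params, lr=cfg.learning_rate)
    sched = _LRSchedule(cfg.learning_rate, cfg.warmup_steps,
                        cfg.plateau_patience, cfg.plateau_factor)
    ema = EMA(params, cfg.ema_decay)
    history: list[dict] = []
    dim = model.total_latent_dim

    def _val_nll() -> float:
        lp = model.log_prob(Tensor(x[val_idx])).data
        return float(-lp.mean())

    for it in range(cfg.iterations):
        optimizer.lr = sched.lr(it)
        sel = rng.choice(train_idx, size=min(cfg.microbatch_size, train_idx.size),
                         replace=False)
        xb = x[sel]
        if "noise_std" in cfg.jitter.entries:
            amp = cfg.jitter.value_at_iteration("noise_std", it)
            xb = dequantize(xb, amp, seed=int(rng.integers(2**31)), kind="uniform")
        lp = model.log_prob(Tensor(xb))
        loss = -(lp.mean())
        optimizer.zero_grad()
        loss.backward()
        grad_norm = clip_global_norm(params, cfg.clip_norm)
        optimizer.step()
        ema.update()
        rec = {"iteration": it, "loss": loss.item(), "grad_norm": grad_norm,
               "bpd": loss.item() / (dim * np.log(2.0)), "lr": optimizer.lr}
        if val_idx.size and (it % cfg.val_interval == cfg.val_interval - 1 or it == 0):
            rec["val_nll"] = _val_nll()
            sched.observe(rec["val_nll"])
        history.append(rec)

    return TrainResult(flows={model.view or "image": model}, projectors=None,
                       screening=None, history=history,
                       ema_arrays=[a.copy() for a in ema.shadow],
                       train_idx=train_idx, val_idx=val_idx)
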