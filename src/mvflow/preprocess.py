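"""Dataset-owned preprocessing for tabular views.

Each tabular view (a subject-by-feature table of imaging-derived phenotypes
or other continuous measurements) owns a fitted :class:`TabularPreprocessor`
that is applied before the flow and inverted after decoding.  The pipeline
is, in order: mean imputation of missing entries, an optional per-feature
monotone marginal transform (log / log1p / asinh / rank-based
Gaussianization), then normalization (standardize to zero mean and unit
variance, or rescale to [0, 1]).  Low-variance columns are stabilized by
floor-clamping the scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

VALID_TRANSFORMS = ("none", "log", "log1p", "asinh", "rank_gauss")
VALID_MODES = ("standardize", "rescale01")


@dataclass
class TabularPreprocessor:
    """Fitted, invertible per-view preprocessing state."""

    column_names: list[str]
    impute_values: np.ndarray          # raw-scale column means used to fill NaNs
    column_means: np.ndarray           # location (mean or min) on the transformed scale
    column_scales: np.ndarray          # scale (sd or range), floor-clamped
    normalization_mode: str = "standardize"
    marginal_transform: list[str] = field(default_factory=list)
    scale_floor: float = 1e-6
    rank_gauss_reference: dict[int, np.ndarray] = field(default_factory=dict)

    # -- marginal transforms -------------------------------------------------

    def _transform_column(self, x: np.ndarray, j: int) -> np.ndarray:
        kind = self.marginal_transform[j]
        if kind == "none":
            return x
        if kind == "log":
            return np.log(x)
        if kind == "log1p":
            return np.log1p(x)
        if kind == "asinh":
            return np.arcsinh(x)
        if kind == "rank_gauss":
            ref = self.rank_gauss_reference[j]
            n = ref.size
            # Hazen plotting position (k - 0.5) / n on the training ECDF;
            # new values interpolate between training quantiles.
            pos = np.interp(x, ref, (np.arange(1, n + 1) - 0.5) / n)
            return ndtri(np.clip(pos, 0.5 / n, 1.0 - 0.5 / n))
        raise ValueError(f"unknown marginal transform {kind!r}")

    def _invert_column(self, t: np.ndarray, j: int) -> np.ndarray:
        kind = self.marginal_transform[j]
        if kind == "none":
            return t
        if kind == "log":
            return np.exp(t)
        if kind == "log1p":
            return np.expm1(t)
        if kind == "asinh":
            return np.sinh(t)
        if kind == "rank_gauss":
            ref = self.rank_gauss_reference[j]
            n = ref.size
            pos = ndtr(t)
            return np.interp(pos, (np.arange(1, n + 1) - 0.5) / n, ref)
        raise ValueError(f"unknown marginal transform {kind!r}")

    # -- public API ------------------------------------------------------------

    def apply(self, table) -> np.ndarray:
        x = _coerce(table, self.column_names)
        # 1. mean imputation
        nan_mask = ~np.isfinite(x)
        x = np.where(nan_mask, self.impute_values, x)
        # 2. marginal transforms
        t = np.empty_like(x)
        for j in range(x.shape[1]):
            t[:, j] = self._transform_column(x[:, j], j)
        # 3. normalization
        return (t - self.column_means) / self.column_scales

    def invert(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        t = y * self.column_scales + self.column_means
        x = np.empty_like(t)
        for j in range(t.shape[1]):
            x[:, j] = self._invert_column(t[:, j], j)
        return x


def _coerce(table, expected_columns: Sequence[str] | None = None) -> np.ndarray:
    """Coerce a DataFrame/array to a float matrix, validating the column set."""
    if isinstance(table, pd.DataFrame):
        if expected_columns is not None:
            got, want = set(table.columns), set(expected_columns)
            if got != want:
                diff = sorted(got.symmetric_difference(want))
                raise ValueError(f"column mismatch; symmetric difference: {diff}")
            table = table[list(expected_columns)]
        cols = []
        for name in table.columns:
            try:
                cols.append(pd.to_numeric(table[name], errors="raise").to_numpy(dtype=np.float64))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"column {name!r} cannot be coerced to numeric") from exc
        return np.column_stack(cols)
    x = np.asarray(table, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a 2-D table")
    if expected_columns is not None and x.shape[1] != len(expected_columns):
        raise ValueError(
            f"column mismatch; expected {len(expected_columns)} columns, got {x.shape[1]}"
        )
    return x


def fit_preprocessor(
    table,
    normalization_mode: str = "standardize",
    marginal_transform: str | Sequence[str] = "none",
    scale_floor: float = 1e-6,
) -> TabularPreprocessor:
    """Fit imputation, marginal-transform, and normalization state on a table.

    Parameters
    ----------
    table
        Subject-by-feature matrix (DataFrame or ndarray); NaNs allowed.
    normalization_mode
        ``"standardize"`` (zero mean / unit sd) or ``"rescale01"`` (min-max).
    marginal_transform
        Single name applied to every column, or one name per column, from
        ``none | log | log1p | asinh | rank_gauss``.
    scale_floor
        Lower clamp for per-column scales, stabilizing near-constant columns.
    """
    if normalization_mode not in VALID_MODES:
        raise ValueError(f"normalization_mode must be one of {VALID_MODES}")
    if isinstance(table, pd.DataFrame):
        names = [str(c) for c in table.columns]
    else:
        names = [f"f{j}" for j in range(np.asarray(table).shape[1])]
    x = _coerce(table)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a preprocessor")

    d = x.shape[1]
    if isinstance(marginal_transform, str):
        transforms = [marginal_transform] * d
    else:
        transforms = list(marginal_transform)
        if len(transforms) != d:
            raise ValueError("one marginal transform per column required")
    for t in transforms:
        if t not in VALID_TRANSFORMS:
            raise ValueError(f"unknown marginal transform {t!r}")

    finite = np.isfinite(x)
    n_finite = finite.sum(axis=0)
    for j, nf in enumerate(n_finite):
        if nf == 0:
            raise ValueError(f"column {names[j]!r} has no finite values")
    impute_values = np.where(finite, x, 0.0).sum(axis=0) / n_finite

    xi = np.where(finite, x, impute_values)
    pre = TabularPreprocessor(
        column_names=names,
        impute_values=impute_values,
        column_means=np.zeros(d),
        column_scales=np.ones(d),
        normalization_mode=normalization_mode,
        marginal_transform=transforms,
        scale_floor=float(scale_floor),
    )
    for j, t in enumerate(transforms):
        if t == "rank_gauss":
            pre.rank_gauss_reference[j] = np.sort(xi[:, j])

    t = np.empty_like(xi)
    for j in range(d):
        t[:, j] = pre._transform_column(xi[:, j], j)

    if normalization_mode == "standardize":
        pre.column_means = t.mean(axis=0)
        pre.column_scales = np.maximum(t.std(axis=0, ddof=0), scale_floor)
    else:
        lo, hi = t.min(axis=0), t.max(axis=0)
        pre.column_means = lo
        pre.column_scales = np.maximum(hi - lo, scale_floor)
    return pre


def apply_preprocessor(pre: TabularPreprocessor, table) -> np.ndarray:
    return pre.apply(table)
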