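"""File formats, model archives, and multiview manifests.

Tabular views are delimited text tables (CSV/TSV) with a header row and a
mandatory subject-ID column; multiview runs inner-join the views on that
column so each minibatch contains matched subjects (dropped subjects are
counted and logged).  Image views are NIfTI volumes (3D; the affine header
is preserved and re-attached on write) or lossless 2D rasters (PNG), with
intensities linearly mapped to [0, 1] per volume and the min/max recorded
for inversion.

Model archives are single-file ``.npz`` containers holding the flow
parameters, preprocessor state, base parameters and a JSON config echo,
under a versioned schema key.  A flow is reconstructed by rebuilding the
architecture from the config (construction is deterministic given its seed)
and loading the parameter arrays.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .flow_image import ImageFlowModel, build_image_flow
from .flow_tabular import TabularFlowModel, build_tabular_flow
from .joint_gaussian import JointGaussian, LatentBlock
from .preprocess import TabularPreprocessor

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = [
    "read_tabular_view",
    "join_views",
    "RunManifest",
    "save_tabular_model",
    "load_tabular_model",
    "save_image_model",
    "load_image_model",
    "save_joint_gaussian",
    "load_joint_gaussian",
    "load_image",
    "save_image",
    "IntensityMap",
]


# ---------------------------------------------------------------------------
# tabular tables & manifests
# ---------------------------------------------------------------------------


def read_tabular_view(path, id_column: str = "subject_id") -> pd.DataFrame:
    """Read one view's delimited table; the subject-ID column becomes the index."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if id_column not in df.columns:
        raise ValueError(f"{path}: missing subject-ID column {id_column!r}")
    return df.set_index(id_column)


def join_views(tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Inner-join views on subject ID; log how many subjects were dropped."""
    ids = None
    for df in tables.values():
        ids = df.index if ids is None else ids.intersection(df.index)
    if ids is None or len(ids) == 0:
        raise ValueError("no subjects shared across all views")
    dropped = {v: len(df.index.difference(ids)) for v, df in tables.items()}
    total_dropped = sum(dropped.values())
    if total_dropped:
        logger.info("inner join dropped %d rows across views: %s", total_dropped, dropped)
    ids = sorted(ids)
    return {v: df.loc[ids] for v, df in tables.items()}


@dataclass
class RunManifest:
    """Declares the per-view data sources of one training run."""

    views: dict[str, dict]      # name -> {"path": ..., "role": tabular|image2d|image3d}
    id_column: str = "subject_id"
    split_seed: int = 0
    config: dict | None = None

    @staticmethod
    def from_json(path) -> "RunManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return RunManifest(views=raw["views"], id_column=raw.get("id_column", "subject_id"),
                           split_seed=raw.get("split_seed", 0), config=raw.get("config"))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"views": self.views, "id_column": self.id_column,
                       "split_seed": self.split_seed, "config": self.config}, fh, indent=2)

    def load_tabular(self) -> dict[str, pd.DataFrame]:
        tables = {
            name: read_tabular_view(meta["path"], self.id_column)
            for name, meta in self.views.items()
            if meta.get("role", "tabular") == "tabular"
        }
        return join_views(tables)


# ---------------------------------------------------------------------------
# model archives
# ---------------------------------------------------------------------------


def _pack_params(prefix: str, arrays: list[np.ndarray]) -> dict[str, np.ndarray]:
    return {f"{prefix}{i:04d}": a for i, a in enumerate(arrays)}


def _unpack_params(data, prefix: str) -> list[np.ndarray]:
    keys = sorted(k for k in data.files if k.startswith(prefix))
    return [data[k] for k in keys]


def _preproc_to_dict(pre: TabularPreprocessor) -> dict:
    d = {
        "pre_columns": np.array(pre.column_names, dtype=object).astype(str),
        "pre_impute": pre.impute_values,
        "pre_means": pre.column_means,
        "pre_scales": pre.column_scales,
    }
    for j, ref in pre.rank_gauss_reference.items():
        d[f"pre_rg{j:04d}"] = ref
    return d


def save_tabular_model(path, flow: TabularFlowModel,
                       preprocessor: TabularPreprocessor | None = None,
                       extra_config: dict | None = None) -> None:
    cfg = {
        "schema_version": SCHEMA_VERSION,
        "kind": "tabular",
        "dim": flow.dim,
        "coupling_depth": flow.coupling_depth,
        "hidden_channels": flow.hidden_channels,
        "base_kind": flow.base_kind,
        "scale_cap": flow.scale_cap,
        "extra": extra_config or {},
    }
    payload: dict = {"config": np.array(json.dumps(cfg))}
    payload.update(_pack_params("param", flow.state_arrays()))
    if preprocessor is not None:
        cfg["preprocessor"] = {
            "normalization_mode": preprocessor.normalization_mode,
            "marginal_transform": preprocessor.marginal_transform,
            "scale_floor": preprocessor.scale_floor,
        }
        payload["config"] = np.array(json.dumps(cfg))
        payload.update(_preproc_to_dict(preprocessor))
    np.savez(path, **payload)


def load_tabular_model(path) -> tuple[TabularFlowModel, TabularPreprocessor | None]:
    data = np.load(path, allow_pickle=False)
    cfg = json.loads(str(data["config"]))
    if cfg.get("schema_version") != SCHEMA_VERSION or cfg.get("kind") != "tabular":
        raise ValueError("not a tabular model archive of a supported schema version")
    flow = build_tabular_flow(cfg["dim"], cfg["coupling_depth"], cfg["hidden_channels"],
                              base_kind=cfg["base_kind"], scale_cap=cfg["scale_cap"])
    flow.load_state_arrays(_unpack_params(data, "param"))
    pre = None
    if "pre_columns" in data.files:
        pc = cfg["preprocessor"]
        pre = TabularPreprocessor(
            column_names=[str(c) for c in data["pre_columns"]],
            impute_values=data["pre_impute"],
            column_means=data["pre_means"],
            column_scales=data["pre_scales"],
            normalization_mode=pc["normalization_mode"],
            marginal_transform=list(pc["marginal_transform"]),
            scale_floor=pc["scale_floor"],
        )
        for k in data.files:
            if k.startswith("pre_rg"):
                pre.rank_gauss_reference[int(k[6:])] = data[k]
    return flow, pre


def save_image_model(path, flow: ImageFlowModel, extra_config: dict | None = None,
                     build_seed: int = 0) -> None:
    cfg = {
        "schema_version": SCHEMA_VERSION,
        "kind": "image",
        "input_shape": list(flow.input_shape),
        "levels": flow.levels,
        "steps": list(flow.steps),
        "hidden_channels": flow.hidden_channels,
        "scale_cap": flow.scale_cap,
        "view": flow.view,
        "build_seed": build_seed,
        "actnorm_initialized": flow.actnorm_initialized,
        "extra": extra_config or {},
    }
    payload: dict = {"config": np.array(json.dumps(cfg))}
    payload.update(_pack_params("param", flow.state_arrays()))
    np.savez(path, **payload)


def load_image_model(path) -> ImageFlowModel:
    data = np.load(path, allow_pickle=False)
    cfg = json.loads(str(data["config"]))
    if cfg.get("schema_version") != SCHEMA_VERSION or cfg.get("kind") != "image":
        raise ValueError("not an image model archive of a supported schema version")
    flow = build_image_flow(tuple(cfg["input_shape"]), cfg["levels"], cfg["steps"],
                            cfg["hidden_channels"], scale_cap=cfg["scale_cap"],
                            seed=cfg["build_seed"], view=cfg.get("view", ""))
    flow.load_state_arrays(_unpack_params(data, "param"))
    if cfg["actnorm_initialized"]:
        for lev in flow.level_steps:
            for step in lev:
                step.actnorm.initialized = True
    return flow


def save_joint_gaussian(path, g: JointGaussian) -> None:
    blocks = [
        {"view": b.view, "level": b.level, "start": b.start, "stop": b.stop,
         "shape": list(b.shape), "scale": b.scale}
        for b in g.blocks
    ]
    cfg = {"schema_version": SCHEMA_VERSION, "kind": "joint_gaussian",
           "sigma2": g.sigma2, "blocks": blocks}
    np.savez(path, config=np.array(json.dumps(cfg)), mean=g.mean,
             factors=g.factors, eigenvalues=g.eigenvalues)


def load_joint_gaussian(path) -> JointGaussian:
    data = np.load(path, allow_pickle=False)
    cfg = json.loads(str(data["config"]))
    if cfg.get("kind") != "joint_gaussian":
        raise ValueError("not a joint-Gaussian archive")
    blocks = [LatentBlock(view=b["view"], level=b["level"], start=b["start"],
                          stop=b["stop"], shape=tuple(b["shape"]), scale=b["scale"])
              for b in cfg["blocks"]]
    return JointGaussian(mean=data["mean"], factors=data["factors"],
                         eigenvalues=data["eigenvalues"], sigma2=cfg["sigma2"],
                         blocks=blocks)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


@dataclass
class IntensityMap:
    """Recorded per-volume linear map raw -> [0, 1], invertible on write."""

    vmin: float
    vmax: float

    def forward(self, x: np.ndarray) -> np.ndarray:
        span = max(self.vmax - self.vmin, 1e-12)
        return (x - self.vmin) / span

    def inverse(self, u: np.ndarray) -> np.ndarray:
        return u * (self.vmax - self.vmin) + self.vmin


def load_image(path) -> tuple[np.ndarray, IntensityMap, object]:
    """Load a NIfTI volume or 2D raster as channel-first float in [0, 1].

    Returns (image (1, *spatial), intensity map, affine-or-None).  No
    resampling or reorientation is performed; inputs must be pre-aligned.
    """
    path = Path(path)
    if path.suffix in (".nii",) or str(path).endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asarray(img.get_fdata(), dtype=np.float64)
        affine = img.affine
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
        affine = None
    imap = IntensityMap(float(arr.min()), float(arr.max()))
    return imap.forward(arr)[None], imap, affine


def save_image(path, img: np.ndarray, imap: IntensityMap | None = None,
               affine=None) -> None:
    """Write a decoded channel-first image back in its input format."""
    path = Path(path)
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim >= 3 and arr.shape[0] == 1:
        arr = arr[0]
    if imap is not None:
        arr = imap.inverse(arr)
    if path.suffix in (".nii",) or str(path).endswith(".nii.gz"):
        import nibabel as nib

        nib.save(nib.Nifti1Image(arr, affine if affine is not None else np.eye(4)),
                 str(path))
    else:
        from PIL import Image

        u = np.clip(arr, 0.0, 1.0) if imap is None else np.clip(
            (arr - arr.min()) / max(arr.max() - arr.min(), 1e-12), 0, 1)
        Image.fromarray((u * 255).astype(np.uint8)).save(path)
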