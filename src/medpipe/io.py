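"""File formats: CSV tables, grayscale PNGs, JSON models/reports, YAML config.

CSV dialect: comma-separated, header row, UTF-8; an empty cell or "NA" marks
a missing value. PNGs are 8-bit (mode L) or 16-bit (mode I;16) grayscale and
round-trip pixel-exactly. Run configuration loads from YAML or JSON with
unknown keys rejected and every seed materialized.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .preprocess import TabularDataset


# ---------------------------------------------------------------- tabular --
def read_csv(path) -> TabularDataset:
    """Read a feature table; a column named ``label`` becomes the labels."""
    try:
        df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    except Exception as e:                       # surface file context
        raise ValueError(f"malformed CSV {path}: {e}") from e
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy()
    return TabularDataset(features=df.to_numpy(dtype=float),
                          labels=labels,
                          feature_names=list(df.columns))


def write_csv(ds: TabularDataset, path) -> None:
    df = pd.DataFrame(ds.features, columns=ds.feature_names)
    if ds.labels is not None:
        df["label"] = ds.labels
    df.to_csv(path, index=False, na_rep="NA")


# ----------------------------------------------------------------- images --
def read_png(path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG as a 2-D uint8/uint16 array."""
    try:
        with Image.open(path) as im:
            if im.mode == "L":
                return np.asarray(im, dtype=np.uint8)
            if im.mode in ("I;16", "I"):
                return np.asarray(im, dtype=np.int32).astype(np.uint16)
            raise ValueError(f"unsupported PNG mode {im.mode}")
    except ValueError:
        raise
    except Exception as e:
        raise ValueError(f"malformed PNG {path}: {e}") from e


def write_png(img: np.ndarray, path) -> None:
    img = np.asarray(img)
    if img.dtype == np.uint8:
        Image.fromarray(img, mode="L").save(path)
    elif img.dtype == np.uint16:
        Image.fromarray(img.astype(np.uint16)).save(path)
    else:
        raise ValueError(f"unsupported image dtype {img.dtype}")


# ------------------------------------------------------------------- json --
def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, allow_nan=True) + "\n")


def load_json(path):
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed JSON {path}:{e.lineno}: {e.msg}") from e


# ----------------------------------------------------------------- config --
@dataclass
class RunConfig:
    """Materialized per-stage parameters of a run (all seeds explicit)."""

    seed: int = 0
    verbosity: int = 1
    # tabular arm
    k_tabular: int = 2
    n_chunks: int = 1
    shift_threshold: float = 1e-6
    max_rounds: int = 100
    outlier_quantile: float = 0.99
    drop_outliers: bool = True
    augment_mode: str = "indicators"
    weight_metric: str = "accuracy"
    alpha: float = 0.1
    max_iters: int = 1000
    tol: float = 1e-8
    refine_rounds: int = 20
    # image arm
    k_image: int = 5
    image_side: int = 640
    grid_s: int = 7
    n_anchors: int = 3
    n_classes: int = 2
    obj_thresh: float = 0.5
    iou_thresh: float = 0.5
    detector_input: str = "clustered"   # clustered | stacked | raw

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load YAML or JSON run configuration; unknown keys are rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    known = set(RunConfig().to_dict())
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**data)
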