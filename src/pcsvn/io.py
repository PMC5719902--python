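"""Reading and writing masks, tracings, ground truth and tabular outputs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from PIL import Image

from .features import FEATURE_UNITS
from .skeleton import SkeletonGraph
from .synthetic import GroundTruth


def write_mask_png(mask: np.ndarray, path) -> None:
    """Single-channel PNG, foreground 255 / background 0."""
    img = Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8), mode="L")
    img.save(str(path))


def read_mask_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(str(path)).convert("L"))
    return arr > 127


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict()))


def write_graph_json(graph: SkeletonGraph, path) -> None:
    Path(path).write_text(json.dumps(graph.to_json_dict()))


def read_color_tracing(
    image_path, palette: Dict[str, dict]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decode a color-coded tracing with a palette map.

    ``palette`` maps ``"#RRGGBB"`` to ``{"kind": "artery"|"vein",
    "caliber_cm": float}`` — the convention of protocols where pencil color
    and size encode vessel class and thickness.  Returns
    ``(artery_mask, vein_mask, caliber_map)`` with caliber in cm per pixel
    (0 outside vessels).
    """
    rgb = np.asarray(Image.open(str(image_path)).convert("RGB"))
    artery = np.zeros(rgb.shape[:2], dtype=bool)
    vein = np.zeros(rgb.shape[:2], dtype=bool)
    caliber = np.zeros(rgb.shape[:2], dtype=float)
    for hexcode, info in palette.items():
        h = hexcode.lstrip("#")
        color = tuple(int(h[i : i + 2], 16) for i in (0, 2, 4))
        hit = np.all(rgb == np.array(color, dtype=np.uint8), axis=-1)
        if info.get("kind", "artery") == "artery":
            artery |= hit
        else:
            vein |= hit
        caliber[hit] = float(info.get("caliber_cm", 0.0))
    return artery, vein, caliber


def write_feature_table(df: pd.DataFrame, path, label_col: str = "cohort") -> None:
    """Feature table CSV plus a JSON sidecar with units and sentinel policy."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = {
        "units": {c: FEATURE_UNITS.get(c, "1") for c in df.columns if c != label_col},
        "label_col": label_col,
        "missing_value_sentinel": "NaN (empty CSV cell); rows with missing values are dropped from model fitting",
    }
    path.with_suffix(".units.json").write_text(json.dumps(sidecar, indent=1))


def write_manifest(rows, path) -> None:
    """Cohort manifest CSV: id, label, file paths."""
    pd.DataFrame(rows).to_csv(str(path), index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(str(path))
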