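"""Reading and writing scene components, response tables and design specs.

Scene components are stored as a directory of float TIFF layers (lossless
linear light) named ``full/diffuse1/diffuse2/specular/normals/mask`` plus a
``meta.json`` sidecar, with an 8-bit gamma-encoded ``preview.png`` of the
full rendering for quick inspection.  Response and rating tables are plain
CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .design import DesignSpec, ParameterDef
from .scene import SceneComponents

__all__ = [
    "write_components",
    "read_components",
    "write_preview_png",
    "read_responses",
    "read_ratings",
    "design_to_dict",
    "design_from_dict",
    "load_design",
    "save_design",
]

LAYER_NAMES = ("full", "diffuse1", "diffuse2", "specular", "normals", "mask")


def write_preview_png(image: np.ndarray, path, gamma: float = 1 / 2.2) -> None:
    """Write a clipped, gamma-encoded 8-bit preview of a linear-light image."""
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0) ** gamma
    iio.imwrite(Path(path), (img * 255).round().astype(np.uint8))


def write_components(scene: SceneComponents, path, preview: bool = True) -> Path:
    """Write scene components as float TIFF layers with a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in LAYER_NAMES:
        arr = getattr(scene, name)
        if name == "mask":
            arr = arr.astype(np.uint8)
        arr = np.asarray(arr)
        photometric = "rgb" if arr.ndim == 3 else "minisblack"
        tifffile.imwrite(path / f"{name}.tif", arr, photometric=photometric)
    (path / "meta.json").write_text(json.dumps(scene.meta, indent=2))
    if preview:
        write_preview_png(scene.full, path / "preview.png")
    return path


def read_components(path) -> SceneComponents:
    """Read scene components written by :func:`write_components`.

    Raises ``FileNotFoundError`` naming the first missing layer and
    ``ValueError`` (naming the layer) on shape mismatches or non-unit
    normals; those checks live in ``SceneComponents.validate``.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"component directory not found: {path}")
    layers = {}
    for name in LAYER_NAMES:
        f = path / f"{name}.tif"
        if not f.exists():
            raise FileNotFoundError(f"missing layer {name!r} in {path}")
        layers[name] = tifffile.imread(f)
    meta_file = path / "meta.json"
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    return SceneComponents(meta=meta, **layers)


def read_responses(path) -> pd.DataFrame:
    """Read a forced-choice response table.

    Expects columns ``participant, stimulus, category, confidence`` with
    confidence in {1, 2, 3}; rejects out-of-range values naming the first
    offending row (0-based data row index).
    """
    df = _read_csv(path, ["participant", "stimulus", "category", "confidence"])
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    bad = ~conf.isin([1, 2, 3])
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"confidence must be in {{1, 2, 3}}; row {row} has "
            f"{df['confidence'].iloc[row]!r}"
        )
    df["confidence"] = conf.astype(int)
    return df


def read_ratings(path) -> pd.DataFrame:
    """Read a gloss-rating table (``participant, stimulus, rating`` in [0,1])."""
    df = _read_csv(path, ["participant", "stimulus", "rating"])
    rating = pd.to_numeric(df["rating"], errors="coerce")
    bad = ~((rating >= 0) & (rating <= 1))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"rating must be in [0, 1]; row {row} has {df['rating'].iloc[row]!r}"
        )
    df["rating"] = rating.astype(float)
    return df


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no records in {path}") from None
    if len(df) == 0:
        raise ValueError(f"no records in {path}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path} lacks required columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Design spec serialization


def design_to_dict(spec: DesignSpec) -> dict:
    return {
        "name": spec.name,
        "parameters": [
            {
                "name": p.name,
                "clauses": [
                    {"when": {k: list(v) for k, v in when}, "levels": list(levels)}
                    for when, levels in p.clauses
                ],
            }
            for p in spec.parameters
        ],
        "base_rgb_table": [
            {"saturation": sat, "value": val, "rgb": list(rgb)}
            for (sat, val), rgb in spec.base_rgb_table
        ],
    }


def design_from_dict(d: dict) -> DesignSpec:
    params = tuple(
        ParameterDef.conditional(
            p["name"], [(c.get("when", {}), c["levels"]) for c in p["clauses"]]
        )
        for p in d["parameters"]
    )
    table = tuple(
        ((e["saturation"], e["value"]), tuple(e["rgb"]))
        for e in d.get("base_rgb_table", [])
    )
    return DesignSpec(name=d.get("name", "custom"), parameters=params,
                      base_rgb_table=table)


def save_design(spec: DesignSpec, path) -> None:
    path = Path(path)
    d = design_to_dict(spec)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_design(path) -> DesignSpec:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"design spec not found: {path}")
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return design_from_dict(d)
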