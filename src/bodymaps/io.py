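"""Readers and writers for map stores, configs and result tables.

Maps travel as long-format CSV (subject, emotion, row, col, value; inside
pixels only) or per-map H x W CSV matrices; PNG export splits a signed map
into an activation and a deactivation 8-bit grayscale image. Configs are
YAML/JSON; summaries are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .mask import BodyMask, build_manikin_mask
from .simulate import EMOTIONS, GeneratorConfig
from .pipeline import AnalysisConfig, StudyConfig

__all__ = [
    "write_map_store",
    "read_map_store",
    "write_map_matrix",
    "read_map_matrix",
    "export_map_png",
    "import_map_png",
    "load_config",
    "save_config",
    "write_summary",
]


def write_map_store(
    maps: np.ndarray, subject_ids: list, mask: BodyMask, path: str | Path
) -> None:
    """Write S x E x P maps as one long-format CSV over inside pixels."""
    rows_idx, cols_idx = np.nonzero(mask.inside)
    n_s, n_e, p = maps.shape
    frame = pd.DataFrame(
        {
            "subject": np.repeat(subject_ids, n_e * p),
            "emotion": np.tile(np.repeat(EMOTIONS, p), n_s),
            "row": np.tile(rows_idx, n_s * n_e),
            "col": np.tile(cols_idx, n_s * n_e),
            "value": maps.ravel(),
        }
    )
    # %.17g guarantees lossless float round trips through text
    frame.to_csv(path, index=False, float_format="%.17g")


def read_map_store(
    path: str | Path, mask: BodyMask
) -> tuple[np.ndarray, list[str]]:
    """Read a long-format map CSV back into an S x E x P array."""
    frame = pd.read_csv(path, float_precision="round_trip")
    expected = {"subject", "emotion", "row", "col", "value"}
    if not expected.issubset(frame.columns):
        raise ValueError(
            f"malformed map store {path}: columns {list(frame.columns)}, "
            f"expected {sorted(expected)}"
        )
    subjects = list(dict.fromkeys(frame["subject"]))
    p = mask.n_pixels
    n_s, n_e = len(subjects), len(EMOTIONS)
    if len(frame) != n_s * n_e * p:
        raise ValueError(
            f"map store {path} has {len(frame)} rows; expected {n_s * n_e * p} "
            f"for mask with {p} inside pixels"
        )
    values = frame["value"].to_numpy().reshape(n_s, n_e, p)
    return values, subjects


def write_map_matrix(map_vec: np.ndarray, mask: BodyMask, path: str | Path) -> None:
    """Write one subject-emotion map as an H x W CSV matrix."""
    np.savetxt(path, mask.rasterize(map_vec), delimiter=",", fmt="%.6g")


def read_map_matrix(path: str | Path, mask: BodyMask) -> np.ndarray:
    """Read one H x W CSV matrix back to a vector over inside pixels."""
    raster = np.loadtxt(path, delimiter=",", ndmin=2)
    if raster.shape != mask.inside.shape:
        raise ValueError(
            f"{path}: matrix shape {raster.shape} does not match mask "
            f"{mask.inside.shape}"
        )
    return mask.vectorize(raster)


def export_map_png(map_vec: np.ndarray, mask: BodyMask, stem: str | Path) -> None:
    """Export a signed map as <stem>_activation.png / <stem>_deactivation.png.

    Activation = positive part x 255, deactivation = -negative part x 255,
    both 8-bit grayscale.
    """
    raster = mask.rasterize(map_vec)
    act = np.clip(raster, 0, 1)
    deact = np.clip(-raster, 0, 1)
    for name, img in (("activation", act), ("deactivation", deact)):
        Image.fromarray((img * 255).round().astype(np.uint8), mode="L").save(
            f"{stem}_{name}.png"
        )


def import_map_png(stem: str | Path, mask: BodyMask) -> np.ndarray:
    """Rebuild a signed map from its activation/deactivation PNG pair."""
    act = np.asarray(Image.open(f"{stem}_activation.png"), dtype=float) / 255.0
    deact = np.asarray(Image.open(f"{stem}_deactivation.png"), dtype=float) / 255.0
    if act.shape != mask.inside.shape:
        raise ValueError(f"{stem}: PNG shape {act.shape} does not match mask")
    return mask.vectorize(act - deact)


def save_config(config: StudyConfig, path: str | Path) -> None:
    data = {
        "seed": config.seed,
        "generator": dataclasses.asdict(config.generator),
        "analysis": dataclasses.asdict(config.analysis),
    }
    data["generator"]["spearman_targets"] = {
        f"{a}|{b}": v for (a, b), v in config.generator.spearman_targets.items()
    }
    data["generator"]["scales"] = [list(s) for s in config.generator.scales]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) else json.load(fh)
    gen = data.get("generator", {})
    if "spearman_targets" in gen:
        gen["spearman_targets"] = {
            tuple(k.split("|")): float(v) for k, v in gen["spearman_targets"].items()
        }
    if "scales" in gen:
        gen["scales"] = tuple(tuple(s) for s in gen["scales"])
    return StudyConfig(
        generator=GeneratorConfig(**gen),
        analysis=AnalysisConfig(**data.get("analysis", {})),
        seed=int(data.get("seed", 0)),
    )


def write_summary(summary: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(summary, indent=2, default=_default))


def default_mask_for_config(config: StudyConfig) -> BodyMask:
    return build_manikin_mask(config.generator.mask_height, config.generator.mask_width)
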