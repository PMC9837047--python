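"""Procedural body silhouette ("manikin") masks.

The painting task collects sensation maps on a shared body silhouette; every
pixel inside the silhouette is one variable of the map data matrix. The mask
built here is a deterministic stand-in silhouette assembled from stacked
ellipses and rectangles, partitioned into named body regions that the spatial
component templates and the component-naming step refer to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["REGIONS", "BodyMask", "build_manikin_mask"]

#: Body regions partitioning the inside of the silhouette.
REGIONS = (
    "head",
    "upper_chest",
    "heart_area",
    "stomach",
    "arms",
    "hands",
    "legs",
    "feet",
    "other_torso",
)


@dataclass(frozen=True)
class BodyMask:
    """Boolean silhouette raster plus a per-pixel region partition.

    ``inside`` is a row-major boolean raster (origin top-left);
    ``region_labels`` holds an index into :data:`REGIONS` on inside pixels and
    -1 outside. ``n_pixels`` is the number of inside pixels P — the dimension
    of the vectorized map space.
    """

    inside: np.ndarray
    region_labels: np.ndarray
    _flat_index: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not self.inside.any():
            raise ValueError("mask has no inside pixels")
        object.__setattr__(self, "_flat_index", np.flatnonzero(self.inside.ravel()))

    @property
    def height(self) -> int:
        return self.inside.shape[0]

    @property
    def width(self) -> int:
        return self.inside.shape[1]

    @property
    def n_pixels(self) -> int:
        return int(self.inside.sum())

    def region(self, name: str) -> np.ndarray:
        """Boolean raster selecting one region."""
        return self.region_labels == REGIONS.index(name)

    def region_vector(self, name: str) -> np.ndarray:
        """Boolean vector over inside pixels selecting one region."""
        return self.vectorize(self.region(name).astype(float)) > 0.5

    def vectorize(self, raster: np.ndarray) -> np.ndarray:
        """Flatten a full raster to the P inside pixels (row-major order)."""
        if raster.shape[-2:] != self.inside.shape:
            raise ValueError(
                f"raster shape {raster.shape} does not match mask "
                f"{self.inside.shape}"
            )
        flat = raster.reshape(*raster.shape[:-2], -1)
        return flat[..., self._flat_index]

    def rasterize(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Expand a vector on inside pixels back to a full H x W raster."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_pixels:
            raise ValueError(
                f"expected {self.n_pixels} inside-pixel values, got {values.shape[-1]}"
            )
        out = np.full(values.shape[:-1] + (self.height * self.width,), fill, dtype=float)
        out[..., self._flat_index] = values
        return out.reshape(values.shape[:-1] + self.inside.shape)


def _ellipse(h: int, w: int, cr: float, cc: float, rr: float, rc: float) -> np.ndarray:
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    return ((rows - cr) / rr) ** 2 + ((cols - cc) / rc) ** 2 <= 1.0


def _rect(h: int, w: int, r0: float, r1: float, c0: float, c1: float) -> np.ndarray:
    out = np.zeros((h, w), dtype=bool)
    out[int(round(r0)):int(round(r1)), int(round(c0)):int(round(c1))] = True
    return out


def build_manikin_mask(height: int = 120, width: int = 44) -> BodyMask:
    """Deterministic procedural body silhouette with a region partition.

    The layout places (top to bottom) a head ellipse, neck, torso with an
    upper-chest band, a heart patch (left of the body midline as seen by the
    viewer), a stomach patch, arms with hands, and legs with feet. Identical
    inputs yield bit-identical masks.
    """
    if height < 40 or width < 16:
        raise ValueError("mask dimensions too small: need height >= 40, width >= 16")

    H, W = height, width
    labels = np.full((H, W), -1, dtype=int)

    def paint(region: str, sel: np.ndarray) -> None:
        labels[sel] = REGIONS.index(region)

    # head + neck
    head = _ellipse(H, W, 0.085 * H, 0.5 * W, 0.072 * H, 0.17 * W)
    neck = _rect(H, W, 0.150 * H, 0.195 * H, 0.44 * W, 0.56 * W)
    # torso block; specific patches painted over it below
    torso = _rect(H, W, 0.19 * H, 0.52 * H, 0.27 * W, 0.73 * W)
    upper_chest = _rect(H, W, 0.19 * H, 0.27 * H, 0.27 * W, 0.73 * W)
    heart = _ellipse(H, W, 0.315 * H, 0.40 * W, 0.042 * H, 0.11 * W)
    stomach = _ellipse(H, W, 0.445 * H, 0.50 * W, 0.062 * H, 0.17 * W)
    arms = _rect(H, W, 0.21 * H, 0.45 * H, 0.13 * W, 0.24 * W) | _rect(
        H, W, 0.21 * H, 0.45 * H, 0.76 * W, 0.87 * W
    )
    hands = _rect(H, W, 0.45 * H, 0.52 * H, 0.13 * W, 0.24 * W) | _rect(
        H, W, 0.45 * H, 0.52 * H, 0.76 * W, 0.87 * W
    )
    legs = _rect(H, W, 0.52 * H, 0.915 * H, 0.29 * W, 0.46 * W) | _rect(
        H, W, 0.52 * H, 0.915 * H, 0.54 * W, 0.71 * W
    )
    feet = _rect(H, W, 0.915 * H, 0.985 * H, 0.27 * W, 0.46 * W) | _rect(
        H, W, 0.915 * H, 0.985 * H, 0.54 * W, 0.73 * W
    )

    paint("other_torso", torso | neck)
    paint("upper_chest", upper_chest)
    paint("heart_area", heart & torso)
    paint("stomach", stomach & torso)
    paint("head", head)
    paint("arms", arms)
    paint("hands", hands)
    paint("legs", legs)
    paint("feet", feet)

    inside = labels >= 0
    mask = BodyMask(inside=inside, region_labels=labels)
    missing = [r for r in REGIONS if not mask.region(r).any()]
    if missing:
        raise ValueError(
            f"mask dimensions too small to place regions: {', '.join(missing)}"
        )
    return mask
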