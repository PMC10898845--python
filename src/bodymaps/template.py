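"""Body-outline templates.

A :class:`BodyTemplate` is the canvas every bodily-sensation map (BSM) lives
on: a ``height x width`` pixel grid, a boolean in-outline mask, and a set of
named landmark regions (head, chest, abdomen, limbs) used by the synthetic
cohort generator to place sensation blobs. The mask plays the same role as
the 50,364-pixel silhouette used with real painting data; synthetic templates
are simply smaller silhouettes built from composable ellipses and rectangles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LANDMARK_NAMES = (
    "head",
    "chest",
    "abdomen",
    "left_arm",
    "right_arm",
    "left_leg",
    "right_leg",
    "full_body",
)


@dataclass(frozen=True)
class BodyTemplate:
    """A body silhouette mask with named landmark regions.

    Parameters
    ----------
    height, width
        Grid dimensions in pixels.
    in_mask
        Boolean ``(height, width)`` array; True inside the body outline.
    landmarks
        Mapping from landmark name to a sorted array of flat (row-major)
        pixel indices, each a subset of the in-mask pixels.
    """

    height: int
    width: int
    in_mask: np.ndarray
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.in_mask.shape != (self.height, self.width):
            raise ValueError("in_mask shape does not match height/width")
        flat = self.in_mask.ravel()
        for name, idx in self.landmarks.items():
            if idx.size == 0:
                raise ValueError(f"landmark '{name}' is empty")
            if not flat[idx].all():
                raise ValueError(f"landmark '{name}' has pixels outside the mask")

    @property
    def n_in_mask(self) -> int:
        return int(self.in_mask.sum())

    @property
    def in_mask_flat_indices(self) -> np.ndarray:
        """Flat row-major indices of in-mask pixels, ascending."""
        return np.flatnonzero(self.in_mask.ravel())

    def to_vector(self, grid: np.ndarray) -> np.ndarray:
        """Extract the in-mask pixels of a full grid as a flat vector."""
        if grid.shape != (self.height, self.width):
            raise ValueError("grid shape does not match template")
        return grid.ravel()[self.in_mask_flat_indices]

    def to_grid(self, vector: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter an in-mask vector back onto a full grid."""
        if vector.shape != (self.n_in_mask,):
            raise ValueError("vector length does not match n_in_mask")
        grid = np.full(self.height * self.width, fill, dtype=float)
        grid[self.in_mask_flat_indices] = vector
        return grid.reshape(self.height, self.width)


def _ellipse(height: int, width: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    return ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0


def _rect(height: int, width: int, r0: float, r1: float, c0: float, c1: float) -> np.ndarray:
    out = np.zeros((height, width), dtype=bool)
    out[int(round(r0)) : int(round(r1)), int(round(c0)) : int(round(c1))] = True
    return out


def make_body_template(height: int, width: int) -> BodyTemplate:
    """Build a front-facing humanoid silhouette with landmark regions.

    The silhouette is assembled deterministically from ellipses and
    rectangles scaled to the requested dimensions: a head, a torso split
    into chest and abdomen, two arms held slightly away from the torso,
    and two legs. ``full_body`` covers every in-mask pixel.

    Parameters
    ----------
    height
        Grid height in pixels, at least 32.
    width
        Grid width in pixels, at least 16.

    Raises
    ------
    ValueError
        If the dimensions are too small to give every landmark at least
        one pixel; the message names the failing landmark.
    """
    if height < 32 or width < 16:
        raise ValueError("template requires height >= 32 and width >= 16")
    H, W = height, width
    cx = (W - 1) / 2.0

    head = _ellipse(H, W, cy=0.09 * H, cx=cx, ry=0.075 * H, rx=0.14 * W)
    neck = _rect(H, W, 0.15 * H, 0.20 * H, cx - 0.06 * W, cx + 0.06 * W + 1)
    chest = _rect(H, W, 0.19 * H, 0.37 * H, cx - 0.19 * W, cx + 0.19 * W + 1)
    abdomen = _rect(H, W, 0.37 * H, 0.55 * H, cx - 0.17 * W, cx + 0.17 * W + 1)
    left_arm = _rect(H, W, 0.21 * H, 0.54 * H, 0.04 * W, 0.04 * W + max(0.10 * W, 1.0))
    right_arm = _rect(H, W, 0.21 * H, 0.54 * H, W - 0.04 * W - max(0.10 * W, 1.0), W - 0.04 * W)
    left_leg = _rect(H, W, 0.55 * H, 0.97 * H, cx - 0.17 * W, cx - 0.02 * W)
    right_leg = _rect(H, W, 0.55 * H, 0.97 * H, cx + 0.02 * W + 1, cx + 0.17 * W + 1)

    parts = {
        "head": head,
        "chest": chest,
        "abdomen": abdomen,
        "left_arm": left_arm,
        "right_arm": right_arm,
        "left_leg": left_leg,
        "right_leg": right_leg,
    }
    in_mask = neck.copy()
    for part in parts.values():
        in_mask |= part

    landmarks: dict[str, np.ndarray] = {}
    for name, part in parts.items():
        idx = np.flatnonzero(part.ravel())
        if idx.size == 0:
            raise ValueError(f"dimensions too small to place landmark '{name}'")
        landmarks[name] = idx
    landmarks["full_body"] = np.flatnonzero(in_mask.ravel())

    return BodyTemplate(height=H, width=W, in_mask=in_mask, landmarks=landmarks)
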