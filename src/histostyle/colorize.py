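"""Color-coding of stylized images for bias-controlled rating.

Raters familiar with H&E could over-score a stylized image merely because it
is pink and purple. To control for that, stylized images are presented in
four groups: converted to gray (channel average), green-coded, red-coded
(gray value placed in a single channel), or left intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import Image

GROUPS = ("gray", "green", "red", "intact")

_CHANNEL_INDEX = {"red": 0, "green": 1}


@dataclass(frozen=True)
class ColorGroupAssignment:
    """A partition of image ids into the four presentation groups."""

    groups: dict[str, str]  # image_id -> group
    seed: int

    def members(self, group: str) -> list[str]:
        return [i for i, g in self.groups.items() if g == group]


def to_gray(img: Image) -> Image:
    """Replace each pixel by the unweighted mean of its R, G, B channels."""
    g = img.pixels.mean(axis=2, keepdims=True)
    return Image(pixels=np.repeat(g, 3, axis=2), source_id=img.source_id)


def color_code(img: Image, keep: str) -> Image:
    """Grayscale the image, then keep the gray value in one channel only.

    The two non-kept channels are exactly zero.
    """
    if keep not in _CHANNEL_INDEX:
        raise ValueError(f"keep must be 'red' or 'green', got {keep!r}")
    g = img.pixels.mean(axis=2)
    out = np.zeros_like(img.pixels)
    out[:, :, _CHANNEL_INDEX[keep]] = g
    return Image(pixels=out, source_id=img.source_id)


def assign_color_groups(image_ids: list[str], seed: int) -> ColorGroupAssignment:
    """Deterministic seeded shuffle, then round-robin split into four groups.

    Group sizes differ by at most one; 100 images give exactly 25 per group.
    """
    ids = list(image_ids)
    if not ids:
        raise ValueError("cannot assign color groups to an empty image list")
    if len(set(ids)) != len(ids):
        raise ValueError("image ids must be unique")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[k]: GROUPS[pos % 4] for pos, k in enumerate(order)}
    return ColorGroupAssignment(groups=assignment, seed=seed)


def apply_group(img: Image, group: str) -> Image:
    """Apply one group's presentation transform."""
    if group == "gray":
        return to_gray(img)
    if group in ("green", "red"):
        return color_code(img, keep=group)
    if group == "intact":
        return img
    raise ValueError(f"unknown color group {group!r}; expected one of {GROUPS}")
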