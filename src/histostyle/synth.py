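"""Synthetic pipeline inputs with ground-truth manifests.

No CLE frames, H&E micrograph, or rater score table is publicly deposited,
so every pipeline input has a seeded generator here:

* pseudo-CLE content images — dark noisy background, bright elliptical
  cell bodies, and occluding artifacts (bright blurred disks and motion
  streaks) mimicking red blood cells, blur, and background noise;
* a pseudo-H&E style image — pink-dominant stroma texture with purple
  elliptical nuclei;
* rating tables — five raters × 100 images by default, with a planted
  modal (added, removed) score cell per color group and planted per-image
  improvement categories.

Each generator is a pure function of (params, seed) and returns its output
together with a manifest recording the planted ground truth, so recovery
tests have an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage

from .image import Image
from .colorize import GROUPS, assign_color_groups
from .rater_stats import CATEGORIES, ScoreRecord


class GenerationError(ValueError):
    """The requested plant is infeasible."""


# ---------------------------------------------------------------------------
# image generators


@dataclass(frozen=True)
class CLESynthParams:
    """Controls for the pseudo-CLE generator.

    artifact_density is the approximate fraction of the field occluded by
    artifacts (disks + streaks).
    """

    size: int = 256
    n_cells: int = 25
    cell_radius_range: tuple[float, float] = (4.0, 12.0)
    background_noise_sd: float = 0.04
    artifact_density: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 8 or self.n_cells < 0:
            raise ValueError("size must be >= 8 and n_cells >= 0")
        lo, hi = self.cell_radius_range
        if not (0 < lo <= hi):
            raise ValueError("cell_radius_range must be positive and ordered")
        if not (0.0 <= self.artifact_density <= 1.0):
            raise ValueError("artifact_density must be in [0, 1]")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be non-negative")


def _ellipse_mask(size: int, cy, cx, ry, rx, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def make_cle_image(p: CLESynthParams) -> tuple[Image, dict]:
    """Generate one pseudo-CLE frame (grayscale, 3 equal channels).

    Returns (image, manifest); the manifest records cell centers/radii and
    the boolean artifact mask.
    """
    rng = np.random.default_rng(p.seed)
    s = p.size
    canvas = 0.10 + rng.normal(0.0, p.background_noise_sd, size=(s, s))

    cells = []
    lo, hi = p.cell_radius_range
    for _ in range(p.n_cells):
        cy, cx = rng.uniform(0, s, size=2)
        ry, rx = rng.uniform(lo, hi, size=2)
        theta = rng.uniform(0, np.pi)
        brightness = rng.uniform(0.45, 0.85)
        mask = _ellipse_mask(s, cy, cx, ry, rx, theta)
        canvas[mask] = np.maximum(canvas[mask], brightness)
        # darker nucleus-like core, as FNa pools extracellularly
        core = _ellipse_mask(s, cy, cx, ry * 0.4, rx * 0.4, theta)
        canvas[core] = np.minimum(canvas[core], brightness * 0.45)
        cells.append({"center": (float(cy), float(cx)), "radii": (float(ry), float(rx)),
                      "angle": float(theta), "brightness": float(brightness)})

    artifact_mask = np.zeros((s, s), dtype=bool)
    target_area = p.artifact_density * s * s
    guard = 0
    while artifact_mask.sum() < target_area and guard < 10_000:
        guard += 1
        if rng.uniform() < 0.5:  # bright blurred disk (e.g. erythrocyte)
            cy, cx = rng.uniform(0, s, size=2)
            r = rng.uniform(3.0, s / 10)
            m = _ellipse_mask(s, cy, cx, r, r, 0.0)
        else:  # motion streak
            cy = rng.uniform(0, s)
            h = rng.uniform(1.0, 4.0)
            m = np.zeros((s, s), dtype=bool)
            m[int(cy) : int(cy + h), :] = True
        artifact_mask |= m
    if p.artifact_density > 0 and artifact_mask.any():
        glare = scipy.ndimage.gaussian_filter(artifact_mask.astype(float), sigma=2.0)
        canvas = np.where(glare > 0.05, np.maximum(canvas, 0.55 + 0.4 * glare), canvas)

    canvas = scipy.ndimage.gaussian_filter(canvas, sigma=0.8)
    canvas = np.clip(canvas, 0.0, 1.0)
    pixels = np.repeat(canvas[:, :, None], 3, axis=2)
    manifest = {
        "cells": cells,
        "artifact_mask": artifact_mask,
        "artifact_fraction": float(artifact_mask.mean()),
        "params": p,
    }
    return Image(pixels=pixels, source_id=f"cle-synth-{p.seed}"), manifest


def make_he_style_image(
    size: int = 256, seed: int = 0, n_nuclei: int = 80
) -> tuple[Image, dict]:
    """Generate a pseudo-H&E micrograph: pink stroma, purple nuclei.

    The pink/purple gamut guarantees mean(R) > mean(G). Returns
    (image, manifest) with the planted nuclei listed in the manifest.
    """
    if size < 32:
        raise ValueError("style image size must be >= 32")
    rng = np.random.default_rng(seed)
    # eosin-pink stroma with low-frequency texture
    base = np.array([0.91, 0.72, 0.82])
    tex = scipy.ndimage.gaussian_filter(rng.normal(0, 1, (size, size)), sigma=4.0)
    tex = tex / (np.abs(tex).max() + 1e-12)
    canvas = np.empty((size, size, 3))
    for ch, (b, amp) in enumerate(zip(base, (0.06, 0.10, 0.07))):
        canvas[:, :, ch] = b + amp * tex

    nuclei = []
    purple = np.array([0.42, 0.26, 0.58])
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, size, size=2)
        ry, rx = rng.uniform(2.5, 7.0, size=2)
        theta = rng.uniform(0, np.pi)
        mask = _ellipse_mask(size, cy, cx, ry, rx, theta)
        shade = purple + rng.normal(0, 0.03, size=3)
        canvas[mask] = shade
        nuclei.append({"center": (float(cy), float(cx)), "radii": (float(ry), float(rx))})

    canvas = scipy.ndimage.gaussian_filter(canvas, sigma=(0.7, 0.7, 0))
    canvas = np.clip(canvas, 0.0, 1.0)
    img = Image(pixels=canvas, source_id=f"he-synth-{seed}")
    mean_r = float(canvas[:, :, 0].mean())
    mean_g = float(canvas[:, :, 1].mean())
    assert mean_r > mean_g, "pseudo-H&E gamut must be pink/purple dominant"
    return img, {"nuclei": nuclei, "mean_r": mean_r, "mean_g": mean_g, "seed": seed}


# ---------------------------------------------------------------------------
# rating-table generator


#: default planted categories: dominated by both-axis improvement, echoing a
#: cohort where most transformed images gain diagnostic quality. Counts are
#: chosen to partition exactly 100 images.
DEFAULT_PLANTED_CATEGORIES = {
    "improved_both": 84,
    "improved_removed_only": 6,
    "improved_added_only": 5,
    "degraded_removed_only": 2,
    "degraded_added_only": 2,
    "degraded_both": 1,
    "neutral": 0,
}

#: per-color-group modal (added, removed) anchors for improved images
DEFAULT_GROUP_MODAL_CELLS = {
    "gray": (5, 4),
    "green": (5, 5),
    "red": (5, 4),
    "intact": (5, 4),
}

_DEGRADED_ANCHOR = 1  # modal score on a degraded axis


@dataclass(frozen=True)
class RatingSynthParams:
    """Controls for the synthetic rating-table generator.

    dispersion is the standard deviation of the (rounded Gaussian) rater
    noise around each axis anchor; scores are clipped to the planted
    category's score region so per-image means respect the plant exactly.
    """

    n_raters: int = 5
    n_images: int = 100
    modal_cell: tuple[int, int] = (5, 4)
    dispersion: float = 0.7
    planted_categories: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_CATEGORIES)
    )
    group_modal_cells: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MODAL_CELLS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_raters < 1 or self.n_images < 1:
            raise ValueError("n_raters and n_images must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        unknown = set(self.planted_categories) - set(CATEGORIES)
        if unknown:
            raise GenerationError(f"unknown categories {sorted(unknown)}")
        if any(v < 0 for v in self.planted_categories.values()):
            raise GenerationError("planted category counts must be non-negative")
        if sum(self.planted_categories.values()) != self.n_images:
            raise GenerationError(
                f"planted category counts sum to "
                f"{sum(self.planted_categories.values())}, need n_images="
                f"{self.n_images}"
            )
        for g, cell in self.group_modal_cells.items():
            if g not in GROUPS:
                raise GenerationError(f"unknown color group {g!r}")
            if not all(4 <= c <= 6 for c in cell):
                raise GenerationError(
                    f"group {g!r} modal cell {cell} must lie in the improved "
                    "region (4..6) on both axes"
                )


_STATUS_BY_CATEGORY = {
    "improved_both": ("improved", "improved"),
    "improved_removed_only": ("neutral", "improved"),
    "improved_added_only": ("improved", "neutral"),
    "degraded_removed_only": ("improved", "degraded"),
    "degraded_added_only": ("degraded", "improved"),
    "degraded_both": ("degraded", "degraded"),
    "neutral": ("neutral", "neutral"),
}

_STATUS_RANGE = {"improved": (4, 6), "degraded": (0, 2), "neutral": (3, 3)}


def _draw_score(rng, status: str, anchor: int, dispersion: float) -> int:
    lo, hi = _STATUS_RANGE[status]
    if status == "neutral":
        return 3
    v = anchor + int(np.rint(rng.normal(0.0, dispersion)))
    return int(np.clip(v, lo, hi))


def make_rating_table(p: RatingSynthParams) -> tuple[list[ScoreRecord], dict]:
    """Generate n_raters × n_images ScoreRecords honoring the plant.

    Every rating on an improved axis lies in 4..6 (anchored at the image's
    color group modal cell), on a degraded axis in 0..2, and on a neutral
    axis at exactly 3 — so per-image means fall in the planted category's
    region by construction. Returns (records, manifest); the manifest holds
    the per-image category, group, and anchors.
    """
    rng = np.random.default_rng(p.seed)
    image_ids = [f"img{k:03d}" for k in range(p.n_images)]
    groups = assign_color_groups(image_ids, seed=p.seed).groups

    # deterministic category assignment: shuffle images, fill category quotas
    order = rng.permutation(p.n_images)
    slots: list[str] = []
    for cat in CATEGORIES:
        slots.extend([cat] * p.planted_categories.get(cat, 0))
    category_of = {image_ids[k]: slots[j] for j, k in enumerate(order)}

    records: list[ScoreRecord] = []
    manifest_images = {}
    for img_id in image_ids:
        cat = category_of[img_id]
        group = groups[img_id]
        a_status, r_status = _STATUS_BY_CATEGORY[cat]
        cell = p.group_modal_cells.get(group, p.modal_cell)
        a_anchor = cell[0] if a_status == "improved" else _DEGRADED_ANCHOR
        r_anchor = cell[1] if r_status == "improved" else _DEGRADED_ANCHOR
        manifest_images[img_id] = {
            "category": cat, "group": group, "anchors": (a_anchor, r_anchor),
        }
        for rater in range(p.n_raters):
            records.append(
                ScoreRecord(
                    rater_id=f"rater{rater + 1}",
                    image_id=img_id,
                    color_group=group,
                    added_score=_draw_score(rng, a_status, a_anchor, p.dispersion),
                    removed_score=_draw_score(rng, r_status, r_anchor, p.dispersion),
                )
            )
    manifest = {
        "images": manifest_images,
        "planted_categories": dict(p.planted_categories),
        "group_modal_cells": dict(p.group_modal_cells),
        "params": p,
    }
    return records, manifest


def make_paired_scores(
    gap: float = 0.8, sigma: float = 1.0, n: int = 500, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (added, removed) samples with a planted mean difference.

    d = added − removed is N(gap, sigma²); used to exercise the paired
    t-test at a known effect size.
    """
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    rng = np.random.default_rng(seed)
    removed = rng.normal(4.0, 1.0, size=n)
    added = removed + rng.normal(gap, sigma, size=n)
    return added, removed
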