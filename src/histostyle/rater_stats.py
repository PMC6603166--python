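"""Dual-axis rater-score model and evaluation statistics.

Each rating event scores a stylized image on two ordinal axes, 0-6 each
(0 = extreme negative impact, 3 = no significant impact, 6 = extreme
positive impact):

* **added** — did the transformation add structures that were absent
  (negative) or hard to notice (positive) in the original CLE image?
* **removed** — did it remove critical structures (negative) or occluding
  artifacts (positive)?

This module reproduces the analysis battery run on such tables: per-axis
score histograms, the 7×7 (added, removed) intensity map and its modal
cell, a one-way chi-square test against uniformity, a paired t-test of
added vs. removed scores, and per-image improvement categories based on
the mean score over raters (> 3 improved, < 3 degraded, = 3 neutral).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .colorize import GROUPS

VALID_SCORES = frozenset(range(7))

CATEGORIES = (
    "improved_both",
    "improved_removed_only",
    "improved_added_only",
    "degraded_removed_only",
    "degraded_added_only",
    "degraded_both",
    "neutral",
)


class ValidationError(ValueError):
    """A score table violates the record invariants."""


class DegenerateTestError(ValueError):
    """A statistical test is undefined for the given data."""


@dataclass(frozen=True)
class ScoreRecord:
    """One rating event: a rater's (added, removed) scores for one image."""

    rater_id: str
    image_id: str
    color_group: str
    added_score: int
    removed_score: int

    def __post_init__(self) -> None:
        if self.color_group not in GROUPS:
            raise ValidationError(
                f"unknown color group {self.color_group!r}; expected one of {GROUPS}"
            )
        for name in ("added_score", "removed_score"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v not in VALID_SCORES:
                raise ValidationError(f"{name} must be an integer in 0..6, got {v!r}")


@dataclass(frozen=True)
class IntensityMap:
    """7×7 co-occurrence counts of (added_score, removed_score)."""

    counts: np.ndarray  # shape (7, 7), counts[added][removed]
    n_records: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (7, 7) or (c < 0).any():
            raise ValueError("intensity map must be a 7×7 non-negative count array")
        if int(c.sum()) != self.n_records:
            raise ValueError("intensity map counts must sum to n_records")
        object.__setattr__(self, "counts", c)


class ModalCell(NamedTuple):
    added: int
    removed: int
    tie: bool


@dataclass(frozen=True)
class ImageCategorySummary:
    """Per-image mean scores and improvement-category counts."""

    mean_added: dict[str, float]
    mean_removed: dict[str, float]
    categories: dict[str, str]  # image_id -> category
    counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# input


_EXPECTED_COLUMNS = ["rater_id", "image_id", "color_group", "added_score", "removed_score"]


def read_scores(path) -> list[ScoreRecord]:
    """Read and validate a rating table CSV.

    Expects the header ``rater_id,image_id,color_group,added_score,
    removed_score``. Errors cite the 1-based file row (header is row 1).
    """
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != _EXPECTED_COLUMNS:
        raise ValidationError(
            f"{path}: expected columns {_EXPECTED_COLUMNS}, got {list(df.columns)}"
        )
    records: list[ScoreRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            added = int(row.added_score)
            removed = int(row.removed_score)
        except (TypeError, ValueError):
            raise ValidationError(f"{path} row {i}: scores must be integers") from None
        try:
            rec = ScoreRecord(
                rater_id=str(row.rater_id),
                image_id=str(row.image_id),
                color_group=str(row.color_group),
                added_score=added,
                removed_score=removed,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from None
        key = (rec.rater_id, rec.image_id)
        if key in seen:
            raise ValidationError(f"{path} row {i}: duplicate (rater, image) pair {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_scores(records: Sequence[ScoreRecord], path) -> None:
    """Write a rating table CSV in the canonical column order."""
    pd.DataFrame(
        [
            (r.rater_id, r.image_id, r.color_group, r.added_score, r.removed_score)
            for r in records
        ],
        columns=_EXPECTED_COLUMNS,
    ).to_csv(path, index=False)


def _filtered(records: Sequence[ScoreRecord], group: Optional[str]):
    if group is None:
        out = list(records)
    else:
        if group not in GROUPS:
            raise ValueError(f"unknown color group {group!r}")
        out = [r for r in records if r.color_group == group]
    if not out:
        raise ValueError(
            "no records" + (f" in color group {group!r}" if group else "")
        )
    return out


# ---------------------------------------------------------------------------
# descriptive statistics


def score_histogram(
    records: Sequence[ScoreRecord], axis: str, group: Optional[str] = None
) -> np.ndarray:
    """7-bin counts of one score axis; bins sum to the record count."""
    if axis not in ("added", "removed"):
        raise ValueError(f"axis must be 'added' or 'removed', got {axis!r}")
    recs = _filtered(records, group)
    scores = [r.added_score if axis == "added" else r.removed_score for r in recs]
    return np.bincount(scores, minlength=7).astype(np.int64)


def intensity_map(
    records: Sequence[ScoreRecord], group: Optional[str] = None
) -> IntensityMap:
    """7×7 counts of how often each (added, removed) score pair occurred."""
    recs = _filtered(records, group)
    counts = np.zeros((7, 7), dtype=np.int64)
    for r in recs:
        counts[r.added_score, r.removed_score] += 1
    return IntensityMap(counts=counts, n_records=len(recs))


def modal_combination(imap: IntensityMap) -> ModalCell:
    """Most frequent (added, removed) cell.

    Ties are broken toward the larger added score, then the larger removed
    score, and flagged in the result.
    """
    if imap.n_records < 1:
        raise ValueError("intensity map holds no records")
    best = imap.counts.max()
    winners = np.argwhere(imap.counts == best)
    # lexicographic max on (added, removed)
    order = np.lexsort((winners[:, 1], winners[:, 0]))
    added, removed = winners[order[-1]]
    return ModalCell(added=int(added), removed=int(removed), tie=len(winners) > 1)


# ---------------------------------------------------------------------------
# inferential statistics


def chi_square_uniform(counts: Sequence[int]) -> tuple[float, int, float]:
    """One-way chi-square of observed counts against a uniform expectation.

    Returns (statistic, degrees of freedom, upper-tail p).
    """
    obs = np.asarray(counts, dtype=np.float64)
    if obs.ndim != 1 or len(obs) < 2:
        raise ValueError("need a flat vector of at least 2 counts")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("all counts are zero; chi-square is undefined")
    expected = total / len(obs)
    stat = float(np.sum((obs - expected) ** 2 / expected))
    df = len(obs) - 1
    p = float(scipy.stats.chi2.sf(stat, df))
    return stat, df, p


def paired_t_test(
    added: Sequence[float], removed: Sequence[float]
) -> tuple[float, int, float, float]:
    """Paired two-sided t-test on d = added − removed.

    Returns (t, df, p, mean difference). The pairing unit is whatever the
    caller aligned (one entry per rating event by default). Raises
    DegenerateTestError when the differences have zero variance.
    """
    a = np.asarray(added, dtype=np.float64)
    r = np.asarray(removed, dtype=np.float64)
    if a.shape != r.shape or a.ndim != 1:
        raise ValueError("added and removed must be equal-length 1-D sequences")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - r
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegenerateTestError(
            "differences have zero variance; the paired t statistic is undefined"
        )
    t = mean_diff / (sd / np.sqrt(n))
    df = n - 1
    p = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return float(t), df, p, mean_diff


# ---------------------------------------------------------------------------
# per-image categories


def _status(mean: float) -> str:
    if mean > 3.0:
        return "improved"
    if mean < 3.0:
        return "degraded"
    return "neutral"


def _category(added_status: str, removed_status: str) -> str:
    """Map the (added, removed) status pair to one of seven exclusive cells.

    A degraded axis dominates a mixed pair: e.g. added degraded + removed
    improved is 'degraded_added_only'.
    """
    if added_status == "degraded":
        return "degraded_both" if removed_status == "degraded" else "degraded_added_only"
    if removed_status == "degraded":
        return "degraded_removed_only"
    if added_status == "improved":
        return "improved_both" if removed_status == "improved" else "improved_added_only"
    if removed_status == "improved":
        return "improved_removed_only"
    return "neutral"


def categorize_images(records: Sequence[ScoreRecord]) -> ImageCategorySummary:
    """Mean scores over raters per image and the seven-category partition."""
    if not records:
        raise ValueError("no records")
    added: dict[str, list[int]] = {}
    removed: dict[str, list[int]] = {}
    for r in records:
        added.setdefault(r.image_id, []).append(r.added_score)
        removed.setdefault(r.image_id, []).append(r.removed_score)

    mean_added = {i: float(np.mean(v)) for i, v in added.items()}
    mean_removed = {i: float(np.mean(v)) for i, v in removed.items()}
    categories = {
        i: _category(_status(mean_added[i]), _status(mean_removed[i]))
        for i in mean_added
    }
    counts = {c: 0 for c in CATEGORIES}
    for c in categories.values():
        counts[c] += 1
    return ImageCategorySummary(
        mean_added=mean_added,
        mean_removed=mean_removed,
        categories=categories,
        counts=counts,
    )
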