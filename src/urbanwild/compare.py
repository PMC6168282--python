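"""Cross-stratum and cross-study occupancy comparison summaries.

Marginal occupancy distributions (e.g. the four carnivores in one city and
development level, or species from a global protected-areas compilation)
are summarized as box-and-whisker five-number summaries, and differences
are called significant by the interquartile-range overlap heuristic:
two distributions differ significantly only when their [q1, q3] boxes are
disjoint.  Quartiles use the median-inclusive (Tukey hinge) convention;
interval endpoints are treated as closed, so boxes touching at a point
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class OccupancyDistribution:
    """Distribution of marginal occupancy values under one label."""

    label: str
    values: np.ndarray
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float


def _tukey_hinges(values: np.ndarray) -> tuple[float, float, float]:
    """Median and hinges: medians of the lower/upper halves, including the
    overall median in both halves when n is odd."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    med = float(np.median(v))
    half = (n + 1) // 2
    return float(np.median(v[:half])), med, float(np.median(v[n - half :]))


def summarize_distribution(values, label: str = "") -> OccupancyDistribution:
    """Five-number box summary of occupancy values.

    Hinge quartiles, whiskers at the most extreme values within 1.5 IQR of
    the box.  Requires at least two values.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to summarize a distribution")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("occupancy values must lie in [0, 1]")
    q1, med, q3 = _tukey_hinges(v)
    iqr = q3 - q1
    in_fence = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
    return OccupancyDistribution(
        label=label,
        values=v,
        q1=q1,
        median=med,
        q3=q3,
        whisker_low=float(in_fence.min()),
        whisker_high=float(in_fence.max()),
    )


def iqr_overlap_test(a: OccupancyDistribution, b: OccupancyDistribution) -> dict:
    """Interquartile-range overlap rule for a significant difference.

    The difference is significant iff the closed intervals [q1, q3] are
    disjoint; boxes touching at a single point count as overlapping.
    Symmetric in its arguments.
    """
    overlapping = (a.q1 <= b.q3) and (b.q1 <= a.q3)
    return {"overlapping": overlapping, "significant_difference": not overlapping}


def average_duplicate_studies(
    table: pd.DataFrame, exclude_omnivores: bool = False
) -> pd.DataFrame:
    """Species-level mean occupancy from a multi-study comparison table.

    ``table`` columns: species, study, occupancy[, diet_class].  Where a
    species appears in several studies the unweighted mean is taken.  With
    ``exclude_omnivores`` the diet_class column is required and rows labelled
    ``omnivore`` are dropped before averaging.
    """
    df = table.copy()
    for col in ("species", "occupancy"):
        if col not in df.columns:
            raise ValueError(f"comparison table missing column {col!r}")
    if exclude_omnivores:
        if "diet_class" not in df.columns:
            raise ValueError("omnivore exclusion requested but no diet_class column supplied")
        df = df[df["diet_class"].str.lower() != "omnivore"]
    out = df.groupby("species", as_index=False)["occupancy"].mean()
    return out
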