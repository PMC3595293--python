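"""Co-occurrence, richness and niche-overlap statistics for detection data.

Richness here is the number of probe-defined groups detected in a habitat
(row sum of the binary detection matrix).  Co-occurrence histograms,
per-pH-class richness summaries, printed-style percentages (half-up, one
decimal) and pairwise niche-overlap indices, including a complete-separation
flag for group pairs that never share a habitat, live here.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .score_data import BinaryMatrix, HabitatTable

__all__ = [
    "DEFAULT_PH_BREAKS",
    "detection_counts",
    "cooccurrence_histogram",
    "percentage",
    "richness_by_ph_class",
    "mean_richness_split",
    "OverlapMatrix",
    "pairwise_overlap",
]

# pH classes of ~1 unit spanning the surveyed gradient (3.8–9.1); the last
# interval is closed at the top so the most alkaline habitat is kept.
DEFAULT_PH_BREAKS = (3.8, 4.8, 5.8, 6.8, 7.8, 9.1)


def detection_counts(b: BinaryMatrix) -> pd.Series:
    """Number of probe-defined groups detected per habitat (row sums)."""
    return b.df.sum(axis=1).rename("k")


def cooccurrence_histogram(b: BinaryMatrix) -> pd.Series:
    """Habitat count per number of concurrently detected groups.

    Indexed 0..n_probes; counts sum to the number of habitats.
    """
    k = detection_counts(b)
    n_probes = len(b.probe_names)
    hist = k.value_counts().reindex(range(n_probes + 1), fill_value=0)
    hist.index.name = "k"
    return hist.rename("n_habitats")


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """100·count/total rounded half-up to ``decimals`` places."""
    if total <= 0:
        raise ValueError("percentage: total must be > 0")
    if not (0 <= count <= total):
        raise ValueError(f"percentage: count {count} outside [0, {total}]")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100) * Decimal(count) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))


def richness_by_ph_class(
    b: BinaryMatrix,
    habitats: HabitatTable,
    class_edges: tuple[float, ...] = DEFAULT_PH_BREAKS,
) -> pd.DataFrame:
    """Mean ± SD of per-habitat richness within explicit pH classes.

    Intervals are half-open [low, high), except the last, which is closed at
    the top.  SD uses the n−1 denominator and is reported as NaN for
    single-habitat classes.  Habitats outside every class are excluded (their
    count is returned in the ``excluded`` attribute of the frame).
    """
    edges = np.asarray(class_edges, dtype=float)
    if len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("class_edges must be >= 2 strictly increasing breakpoints")
    if b.habitat_ids != habitats.habitat_ids:
        raise ValueError("matrix and habitat table are not aligned (use score_data.align)")
    k = detection_counts(b)
    ph = habitats.ph
    rows = []
    included = 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        mask = (ph >= lo) & ((ph <= hi) if last else (ph < hi))
        sub = k[mask]
        included += len(sub)
        if len(sub) == 0:
            continue
        rows.append(
            {
                "class_low": lo,
                "class_high": hi,
                "n": len(sub),
                "mean": float(sub.mean()),
                "sd": float(sub.std(ddof=1)) if len(sub) > 1 else np.nan,
            }
        )
    out = pd.DataFrame(rows, columns=["class_low", "class_high", "n", "mean", "sd"])
    out.attrs["excluded"] = len(k) - included
    return out


def mean_richness_split(
    b: BinaryMatrix, habitats: HabitatTable, cut: float = 7.0
) -> tuple[float, float]:
    """(mean richness below ``cut``, mean richness at/above ``cut``).

    The boundary habitat (pH == cut exactly) goes to the upper class,
    following the half-open binning convention.
    """
    if b.habitat_ids != habitats.habitat_ids:
        raise ValueError("matrix and habitat table are not aligned (use score_data.align)")
    k = detection_counts(b)
    below = k[habitats.ph < cut]
    above = k[habitats.ph >= cut]
    if len(below) == 0 or len(above) == 0:
        raise ValueError("mean_richness_split: one side of the cut has no habitats")
    return float(below.mean()), float(above.mean())


@dataclass(frozen=True)
class OverlapMatrix:
    """Pairwise habitat-sharing between probe-defined groups.

    ``counts``: habitats where both groups are detected.  ``index``: a
    normalized overlap in [0,1] (Jaccard by default; 0 when both groups are
    empty).  ``separated``: True where two groups are each detected at least
    once yet never co-occur — the complete niche-separation flag.
    """

    counts: pd.DataFrame
    index: pd.DataFrame
    separated: pd.DataFrame
    method: str


def pairwise_overlap(b: BinaryMatrix, index: str = "jaccard") -> OverlapMatrix:
    """Symmetric overlap matrix between probe occurrence columns."""
    if index not in ("jaccard", "shared-count"):
        raise ValueError(f"unknown overlap index {index!r}")
    x = b.df.to_numpy()
    names = b.probe_names
    shared = x.T @ x  # |A ∩ B|
    sizes = x.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        if index == "jaccard":
            idx = np.where(union > 0, shared / np.maximum(union, 1), 0.0)
        else:
            # shared-count mode normalizes by the smaller set (overlap
            # coefficient) so the index stays in [0,1] with unit diagonal
            smaller = np.minimum(sizes[:, None], sizes[None, :])
            idx = np.where(smaller > 0, shared / np.maximum(smaller, 1), 0.0)
    both_present = (sizes[:, None] > 0) & (sizes[None, :] > 0)
    separated = (shared == 0) & both_present
    np.fill_diagonal(separated, False)
    mk = lambda a, dtype=float: pd.DataFrame(a.astype(dtype), index=names, columns=names)
    return OverlapMatrix(mk(shared, int), mk(idx), mk(separated, bool), index)
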