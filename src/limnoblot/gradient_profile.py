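"""Per-probe occurrence profiles along the pH gradient.

For one probe-defined group, ordinal scores are summed within 0.2-unit pH
classes, expressed as fractions of the group's total score across all
habitats, rescaled so the maximum class equals 1 ("normalized relative
intensity"), and finally smoothed with a centered 7-point gliding average.
A shape classifier then labels each profile (acidic / alkaline /
circumneutral-narrow / bimodal / broad / undetected) with an explicit,
parameterized peak-finding rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .score_data import HabitatTable

__all__ = [
    "GradientConfig",
    "GradientProfile",
    "DistributionLabel",
    "assign_ph_class",
    "gliding_average",
    "compute_profile",
    "compute_all_profiles",
    "classify_distribution",
    "plot_profiles",
]

# Absolute slack when locating a pH on a bin edge; 2e-10 pH units, far below
# measurement precision, so e.g. pH 7.0 lands in [7.0, 7.2) despite the
# binary representation of 0.2.
_EDGE_EPS = 1e-9


@dataclass(frozen=True)
class GradientConfig:
    """Binning and smoothing parameters for gradient profiles.

    ``class_width``: pH class width (default 0.2).  ``class_origin``: anchor
    for bin edges (default 0.0 — makes the class [7.0, 7.2) reproducible).
    ``window``: odd gliding-average width (default 7 = middle ±3).
    ``edge_policy``: 'shrink' averages only in-range positions at the series
    ends; 'reflect' mirrors the series.  ``per_class_mean`` divides each
    class sum by its habitat count (off by default: raw summed scores).
    """

    class_width: float = 0.2
    class_origin: float = 0.0
    window: int = 7
    edge_policy: str = "shrink"
    per_class_mean: bool = False

    def __post_init__(self) -> None:
        if not (self.class_width > 0):
            raise ValueError("class_width must be > 0")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 1")
        if self.edge_policy not in ("shrink", "reflect"):
            raise ValueError(f"unknown edge_policy {self.edge_policy!r}")


def assign_ph_class(ph: float, cfg: GradientConfig = GradientConfig()) -> int:
    """Index k of the half-open class [origin + k·w, origin + (k+1)·w)."""
    if not math.isfinite(ph):
        raise ValueError(f"pH must be finite, got {ph!r}")
    return int(math.floor((ph - cfg.class_origin) / cfg.class_width + _EDGE_EPS))


def class_edges(k: int, cfg: GradientConfig = GradientConfig()) -> tuple[float, float]:
    """(low, high) pH bounds of class ``k``."""
    return (cfg.class_origin + k * cfg.class_width, cfg.class_origin + (k + 1) * cfg.class_width)


def gliding_average(series, window: int, edge_policy: str = "shrink") -> np.ndarray:
    """Centered moving mean of width ``window`` (odd), same output length.

    ``shrink`` averages only the positions inside the series near the edges;
    ``reflect`` pads by mirroring before averaging.
    """
    x = np.asarray(series, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be an odd integer >= 1")
    if window > 2 * len(x) - 1:
        raise ValueError("window too large for series length")
    half = window // 2
    if window == 1:
        return x.copy()
    if edge_policy == "reflect":
        padded = np.pad(x, half, mode="reflect")
        kernel = np.ones(window) / window
        return np.convolve(padded, kernel, mode="valid")
    if edge_policy == "shrink":
        csum = np.concatenate(([0.0], np.cumsum(x)))
        n = len(x)
        idx = np.arange(n)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half, n - 1) + 1
        return (csum[hi] - csum[lo]) / (hi - lo)
    raise ValueError(f"unknown edge_policy {edge_policy!r}")


@dataclass(frozen=True)
class GradientProfile:
    """Normalized relative intensity of one group across pH classes.

    ``raw_sums`` → ``fractions`` (share of total score) → ``normalized``
    (rescaled to max 1) → ``smoothed`` (gliding average).  A group never
    detected is flagged ``detected=False`` with all-zero series.
    """

    probe_name: str
    class_index: np.ndarray  # integer class ids, contiguous
    edges: np.ndarray  # (K, 2) pH bounds per class
    raw_sums: np.ndarray
    fractions: np.ndarray
    normalized: np.ndarray
    smoothed: np.ndarray
    detected: bool
    config: GradientConfig = field(default_factory=GradientConfig)

    @property
    def midpoints(self) -> np.ndarray:
        return self.edges.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe": self.probe_name,
                "class_low": self.edges[:, 0],
                "class_high": self.edges[:, 1],
                "raw_sum": self.raw_sums,
                "fraction": self.fractions,
                "normalized": self.normalized,
                "smoothed": self.smoothed,
            }
        )


def compute_profile(
    scores: pd.Series,
    habitats: HabitatTable,
    cfg: GradientConfig = GradientConfig(),
    probe_name: str | None = None,
) -> GradientProfile:
    """Profile one probe's score column along the habitat pH gradient.

    ``scores`` must be indexed by habitat id and aligned with ``habitats``.
    Classes run contiguously from the class containing min(pH) to the class
    containing max(pH); classes without habitats or signal keep value 0 and
    participate in smoothing.  Scale-invariant: doubling all scores leaves
    fractions, normalized and smoothed series unchanged.
    """
    if list(scores.index) != habitats.habitat_ids:
        raise ValueError("scores and habitat table are not aligned (use score_data.align)")
    name = probe_name if probe_name is not None else str(scores.name)
    ph = habitats.ph.to_numpy(dtype=float)
    ks = np.array([assign_ph_class(p, cfg) for p in ph])
    k_lo, k_hi = int(ks.min()), int(ks.max())
    index = np.arange(k_lo, k_hi + 1)
    raw = np.zeros(len(index))
    vals = scores.to_numpy(dtype=float)
    np.add.at(raw, ks - k_lo, vals)
    if cfg.per_class_mean:
        counts = np.zeros(len(index))
        np.add.at(counts, ks - k_lo, 1.0)
        with np.errstate(invalid="ignore"):
            raw = np.where(counts > 0, raw / np.maximum(counts, 1), 0.0)
    edges = np.array([class_edges(int(k), cfg) for k in index])
    total = raw.sum()
    if total <= 0:
        zero = np.zeros(len(index))
        return GradientProfile(name, index, edges, raw, zero, zero.copy(), zero.copy(), False, cfg)
    fractions = raw / total
    normalized = fractions / fractions.max()
    # clamp the window for very short gradients (both operands odd, so the
    # effective window stays odd)
    window = min(cfg.window, 2 * len(normalized) - 1)
    smoothed = gliding_average(normalized, window, cfg.edge_policy)
    return GradientProfile(name, index, edges, raw, fractions, normalized, smoothed, True, cfg)


def compute_all_profiles(matrix, habitats: HabitatTable, cfg: GradientConfig = GradientConfig()):
    """Profiles for every probe column of an (aligned) score matrix."""
    return {
        probe: compute_profile(matrix.df[probe], habitats, cfg, probe_name=probe)
        for probe in matrix.df.columns
    }


@dataclass(frozen=True)
class DistributionLabel:
    """Shape class of a gradient profile plus the peak pH values used."""

    label: str  # undetected | acidic | alkaline | circumneutral-narrow | bimodal | broad
    peaks: tuple[float, ...]

    def __post_init__(self) -> None:
        allowed = {"undetected", "acidic", "alkaline", "circumneutral-narrow", "bimodal", "broad"}
        if self.label not in allowed:
            raise ValueError(f"invalid label {self.label!r}")
        if self.label == "bimodal" and len(self.peaks) != 2:
            raise ValueError("bimodal label requires exactly 2 peaks")
        if self.label == "undetected" and self.peaks:
            raise ValueError("undetected label carries no peaks")


def _find_peaks(smoothed: np.ndarray, midpoints: np.ndarray, threshold: float, min_sep: float):
    """Local maxima of the smoothed series above threshold·max, merged when
    closer than ``min_sep`` pH units (the higher peak wins; ties go to the
    lower pH).  Plateau runs report their central class."""
    s = smoothed
    if s.max() <= 0:
        return []
    cut = threshold * s.max()
    candidates = []
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        left_ok = i == 0 or s[i - 1] < s[i]
        right_ok = j == n - 1 or s[j + 1] < s[i]
        if left_ok and right_ok and s[i] >= cut and s[i] > 0:
            candidates.append(((i + j) // 2, s[i]))
        i = j + 1
    # merge near-by peaks until stable
    merged = sorted(candidates)
    changed = True
    while changed and len(merged) > 1:
        changed = False
        for a in range(len(merged) - 1):
            ia, va = merged[a]
            ib, vb = merged[a + 1]
            if abs(midpoints[ib] - midpoints[ia]) < min_sep:
                keep = (ia, va) if (va > vb or (va == vb and ia < ib)) else (ib, vb)
                merged = merged[:a] + [keep] + merged[a + 2 :]
                changed = True
                break
    return [float(midpoints[i]) for i, _ in merged]


def classify_distribution(
    profile: GradientProfile,
    peak_threshold: float = 0.5,
    min_separation: float = 1.0,
    acid_cut: float = 7.0,
) -> DistributionLabel:
    """Deterministic shape label for a gradient profile.

    Rules, in order: no signal → ``undetected``; exactly two merged peaks →
    ``bimodal``; occupancy (classes whose smoothed intensity reaches 25% of
    the maximum) above 60% of the spanned range, or more than two peaks →
    ``broad``; a single peak is ``acidic`` below ``acid_cut``−0.5,
    ``alkaline`` above ``acid_cut``+0.5, and ``circumneutral-narrow`` in
    between.
    """
    if not profile.detected:
        return DistributionLabel("undetected", ())
    peaks = _find_peaks(profile.smoothed, profile.midpoints, peak_threshold, min_separation)
    if len(peaks) == 2:
        return DistributionLabel("bimodal", tuple(peaks))
    occupancy = float((profile.smoothed >= 0.25 * profile.smoothed.max()).mean())
    if occupancy > 0.6 or len(peaks) > 2:
        return DistributionLabel("broad", tuple(peaks))
    peak = peaks[0]
    if peak < acid_cut - 0.5:
        return DistributionLabel("acidic", (peak,))
    if peak > acid_cut + 0.5:
        return DistributionLabel("alkaline", (peak,))
    return DistributionLabel("circumneutral-narrow", (peak,))


def plot_profiles(profiles, path=None, ncols: int = 4):
    """Small-multiple plot of smoothed profiles (one panel per probe)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    items = [p for p in profiles.values() if p.detected]
    nrows = max(1, -(-len(items) // ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.2 * nrows), squeeze=False)
    for ax, prof in zip(axes.flat, items):
        ax.plot(prof.midpoints, prof.smoothed, lw=1.5)
        ax.set_title(prof.probe_name, fontsize=8)
        ax.set_ylim(0, 1.05)
    for ax in axes.flat[len(items):]:
        ax.axis("off")
    fig.supxlabel("pH")
    fig.supylabel("normalized relative intensity (smoothed)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
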