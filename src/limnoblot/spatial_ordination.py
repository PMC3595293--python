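"""Distance matrices, permutation Mantel tests, PCA and probe clustering.

Community similarity between habitats is computed on the 0/1 detection
profiles (simple matching by default — the fraction of probes on which two
habitats agree — with Jaccard optional).  Geographic distance offers a
paper-reproduction 1-D "distance from the equator" transform (latitude
only) and a general great-circle (haversine) mode.  The Mantel test is a
joint row/column permutation test on the lower triangles with the
(count+1)/(N+1) p estimator; for small n it can enumerate all n!
relabelings exactly.  PCA is a centered (optionally scaled)
eigendecomposition with a deterministic sign convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .score_data import BinaryMatrix, HabitatTable

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "PCAResult",
    "community_similarity",
    "geo_distance",
    "env_delta",
    "mantel",
    "pca",
    "cluster_probes",
    "METERS_PER_DEGREE",
    "EARTH_RADIUS_M",
]

METERS_PER_DEGREE = 111_319.49  # equatorial circumference / 360
EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labeled objects."""

    ids: tuple[str, ...]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distance matrix must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries as a flat vector (scipy condensed order)."""
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def community_similarity(
    b: BinaryMatrix, method: str = "simple-matching"
) -> tuple[pd.DataFrame, DistanceMatrix]:
    """Pairwise habitat similarity on detection profiles; also returns 1−s.

    ``simple-matching``: fraction of probes on which two habitats agree
    (shared presences and shared absences both count).  ``jaccard``:
    intersection over union of detection sets, defined as 1 for two empty
    sets (identical profiles).
    """
    if len(b.habitat_ids) < 2:
        raise ValueError("community_similarity: need at least 2 habitats")
    x = b.df.to_numpy()
    n, p = x.shape
    if method == "simple-matching":
        agree = (x[:, None, :] == x[None, :, :]).sum(axis=2)
        sim = agree / p
    elif method == "jaccard":
        inter = x @ x.T
        sizes = x.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore"):
            sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    else:
        raise ValueError(f"unknown similarity method {method!r}")
    np.fill_diagonal(sim, 1.0)
    ids = tuple(b.habitat_ids)
    sim_df = pd.DataFrame(sim, index=list(ids), columns=list(ids))
    dist = DistanceMatrix(ids, 1.0 - sim, kind="community-dissimilarity")
    return sim_df, dist


def _haversine(lat1, lon1, lat2, lon2) -> float:
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


def geo_distance(habitats: HabitatTable, method: str = "great-circle") -> DistanceMatrix:
    """Pairwise geographic distance (meters) between habitats.

    ``equator-1d`` reproduces the historical transform: each habitat is
    collapsed to its distance from the equator (latitude × 111,319.49 m),
    discarding longitude; distances are absolute differences of that single
    value.  ``great-circle`` is the haversine distance on a 6,371 km sphere
    and is the default for new analyses.
    """
    df = habitats.df
    for col in ("latitude", "longitude"):
        if col not in df.columns or df[col].isna().any():
            missing = list(df.index) if col not in df.columns else list(df.index[df[col].isna()])
            raise ValueError(f"geo_distance: missing {col} for habitats {missing[:5]}")
    lat = df["latitude"].to_numpy(float)
    lon = df["longitude"].to_numpy(float)
    ids = tuple(habitats.habitat_ids)
    if method == "equator-1d":
        pos = lat * METERS_PER_DEGREE
        d = np.abs(pos[:, None] - pos[None, :])
    elif method == "great-circle":
        n = len(lat)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = _haversine(lat[i], lon[i], lat[j], lon[j])
    else:
        raise ValueError(f"unknown geo method {method!r}")
    return DistanceMatrix(ids, d, kind="geographic")


def env_delta(habitats: HabitatTable, column: str = "pH") -> DistanceMatrix:
    """|x_i − x_j| distance on one environmental covariate (e.g. ΔpH)."""
    if column not in habitats.df.columns:
        raise ValueError(f"env_delta: no column {column!r}")
    x = habitats.df[column]
    if x.isna().any():
        raise ValueError(f"env_delta: {column!r} missing for {list(habitats.df.index[x.isna()])}")
    v = x.to_numpy(float)
    return DistanceMatrix(tuple(habitats.habitat_ids), np.abs(v[:, None] - v[None, :]), kind="environmental-delta")


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    tail: str
    seed: int | None
    method: str  # "permutation" or "exact"

    def __str__(self) -> str:
        return (
            f"Mantel r = {self.r:.4f}, p = {self.p:.4g} "
            f"({self.tail}, {self.n_permutations} {self.method} relabelings)"
        )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / math.sqrt((a @ a) * (b @ b)))


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 10_000,
    tail: str = "two-sided",
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """Permutation Mantel test between two distance matrices.

    r is the Pearson correlation of the lower triangles; the null is built
    by jointly permuting rows and columns of ``d2``.  Sampled mode uses the
    p = (count + 1)/(N + 1) estimator, so p is never 0.  ``exact=True``
    enumerates all n! relabelings (identity included) and reports
    p = count/n! — feasible only for small n.  Tails: ``two-sided`` counts
    |r*| ≥ |r|, ``one-sided-positive`` r* ≥ r, ``one-sided-negative``
    r* ≤ r.
    """
    if d1.ids != d2.ids:
        raise ValueError("mantel: distance matrices must share ids and order")
    n = d1.n
    if n < 4:
        raise ValueError("mantel: need at least 4 objects")
    if tail not in ("two-sided", "one-sided-positive", "one-sided-negative"):
        raise ValueError(f"unknown tail {tail!r}")
    v1 = d1.condensed()
    v2 = d2.condensed()
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("mantel: zero variance in a distance triangle; correlation undefined")
    r_obs = _pearson(v1, v2)

    m2 = d2.values

    def crit(r_perm: np.ndarray) -> np.ndarray:
        if tail == "two-sided":
            return np.abs(r_perm) >= abs(r_obs) - 1e-12
        if tail == "one-sided-positive":
            return r_perm >= r_obs - 1e-12
        return r_perm <= r_obs + 1e-12

    c1 = v1 - v1.mean()
    denom1 = math.sqrt(c1 @ c1)
    iu = np.triu_indices(n, k=1)

    def r_of(perm: np.ndarray) -> float:
        w = m2[np.ix_(perm, perm)][iu]
        wc = w - w.mean()
        return float((c1 @ wc) / (denom1 * math.sqrt(wc @ wc)))

    if exact:
        rs = np.array([r_of(np.array(p)) for p in itertools.permutations(range(n))])
        return MantelResult(r_obs, float(crit(rs).mean()), len(rs), tail, seed, "exact")

    rng = np.random.default_rng(seed)
    rs = np.empty(n_permutations)
    for i in range(n_permutations):
        rs[i] = r_of(rng.permutation(n))
    p = (int(crit(rs).sum()) + 1) / (n_permutations + 1)
    return MantelResult(r_obs, p, n_permutations, tail, seed, "permutation")


@dataclass(frozen=True)
class PCAResult:
    """Scores per object, loadings per variable, explained variance shares.

    Explained fractions are non-negative, non-increasing and sum to 1 over
    all axes of the centered data; axis signs are fixed by making each
    axis's largest-|loading| positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_fraction: np.ndarray


def pca(b: BinaryMatrix | pd.DataFrame, scale: bool = False) -> PCAResult:
    """PCA of the (0/1 detection) matrix via SVD of the centered columns."""
    df = b.df if isinstance(b, BinaryMatrix) else pd.DataFrame(b)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("pca: need at least 2 objects and 2 variables")
    x = df.to_numpy(float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        x = x[:, keep] / sd[keep]
        cols = df.columns[keep]
    else:
        cols = df.columns
    if not np.any(x.std(axis=0) > 0):
        raise ValueError("pca: all variables are constant")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    explained = var / var.sum()
    # deterministic axis orientation: largest-|loading| positive
    for a in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[a])))
        if vt[a, j] < 0:
            vt[a] *= -1
            u[:, a] *= -1
    axes = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=df.index, columns=axes)
    loadings = pd.DataFrame(vt.T, index=cols, columns=axes)
    return PCAResult(scores, loadings, explained)


def cluster_probes(b: BinaryMatrix, k: int = 4) -> pd.Series:
    """Group probes into k 'environmentally similar' occurrence clusters.

    Average-linkage hierarchical clustering on correlation distance between
    probe occurrence columns, cut at k clusters.  Probes never detected are
    excluded (and absent from the result); columns are processed in
    lexicographic probe-name order so ties break deterministically.
    """
    detected = sorted(c for c in b.probe_names if b.df[c].sum() > 0)
    if not (1 <= k <= len(detected)):
        raise ValueError(f"cluster_probes: k={k} invalid for {len(detected)} detected probes")
    x = b.df[detected].to_numpy(float).T  # probes × habitats
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc @ xc.T) / np.outer(norms, norms)
    dist = 1.0 - corr
    # constant columns (zero variance): distance 0 to identical columns,
    # otherwise maximal correlation distance
    for i in range(len(detected)):
        for j in range(len(detected)):
            if norms[i] == 0 or norms[j] == 0:
                same = np.array_equal(x[i], x[j])
                dist[i, j] = 0.0 if same else 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    z = linkage(squareform((dist + dist.T) / 2, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=detected, name="cluster")
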