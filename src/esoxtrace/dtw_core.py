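"""Dynamic-time-warping distances, Ward clustering and choice of k.

Lifelong otolith chemistry series differ in length (fish differ in age) and
in phase (habitat shifts happen in different years), so fish are compared
with dynamic time warping under a slanted-band window: the warping path must
stay within a fixed fraction of the series length around the (possibly
non-square) alignment diagonal.  Both channels (Sr:Ca and the d18O residual)
are globally z-scored across all fish and warped jointly, so between-fish
mean differences -- the signal that separates residents of different
habitats -- survive scaling.

Fish are grouped by Ward agglomeration on the DTW distance matrix and the
number of clusters is chosen by majority vote of six internal cluster
validity indices computed from the same distance matrix (medoid-based where
a centroid is required).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .transect_io import Transect

__all__ = [
    "MultiSeries",
    "DistanceMatrix",
    "CviReport",
    "build_multiseries",
    "dtw_distance",
    "distance_matrix",
    "ward_cluster",
    "cvi_suite",
    "select_k",
    "CVI_ORIENTATION",
]

CVI_ORIENTATION: dict[str, str] = {
    "silhouette": "max",
    "dunn": "max",
    "calinski_harabasz": "max",
    "davies_bouldin": "min",
    "davies_bouldin_star": "min",
    "cop": "min",
}


@dataclass
class MultiSeries:
    """One fish's (length x channels) z-scored chemistry series."""

    fish_id: str
    values: np.ndarray  # shape (n_points, n_channels)
    scaling: tuple[np.ndarray, np.ndarray] | None = None  # global (mean, sd)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape[0] < 2:
            raise ValueError(f"fish {self.fish_id}: need >= 2 points")


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    window_frac: float

    def __post_init__(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must have zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


@dataclass
class CviReport:
    """Index values per k, per-index votes, and the winning k."""

    values: pd.DataFrame          # rows k, columns index names
    best_k: dict[str, int]        # per defined index
    votes: dict[int, int]
    k_best: int
    tie: bool = False


def build_multiseries(
    transects: Mapping[str, Transect] | Sequence[Transect],
    channels: tuple[str, str] = ("sr_ca", "d18o_res"),
) -> list[MultiSeries]:
    """Stack each fish's paired points into a series, z-scored globally.

    Scaling uses the pooled mean/sd of each channel over all points of all
    fish (not per fish), so fish that lived in different mean salinities
    stay separated after scaling.
    """
    items = list(transects.values()) if isinstance(transects, Mapping) else list(transects)
    raw = []
    for t in items:
        pts = t.points
        ok = np.ones(len(pts), dtype=bool)
        for ch in channels:
            if ch not in pts.columns:
                raise ValueError(f"fish {t.fish_id}: channel {ch!r} missing")
            ok &= pts[ch].notna().to_numpy()
        raw.append((t.fish_id, pts.loc[ok, list(channels)].to_numpy(float)))
    pooled = np.concatenate([v for _, v in raw], axis=0)
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return [MultiSeries(fid, (v - mean) / sd, scaling=(mean, sd)) for fid, v in raw]


# ---------------------------------------------------------------------------
# DTW distance
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dtw_dp(a: np.ndarray, b: np.ndarray, band: int) -> float:
    n, m = a.shape[0], b.shape[0]
    scale = max(n - 1, m - 1)
    lim = band * scale
    D = np.full((n, m), np.inf)
    for i in range(n):
        for j in range(m):
            # slanted band, symmetric in the two series
            if abs(i * (m - 1) - j * (n - 1)) > lim:
                continue
            c = 0.0
            for ch in range(a.shape[1]):
                d = a[i, ch] - b[j, ch]
                c += d * d
            c = np.sqrt(c)
            if i == 0 and j == 0:
                D[i, j] = c
            else:
                best = np.inf
                if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                    best = D[i - 1, j - 1]
                if i > 0 and D[i - 1, j] < best:
                    best = D[i - 1, j]
                if j > 0 and D[i, j - 1] < best:
                    best = D[i, j - 1]
                D[i, j] = c + best
    return D[n - 1, m - 1]


def dtw_distance(a, b, window_frac: float = 0.05) -> float:
    """Windowed DTW cost between two multichannel series.

    Local cost is the Euclidean norm across channels; steps are the three
    unit-weight moves (diagonal, up, right); there is no path-length
    normalisation.  A cell (i, j) is admissible iff it lies within
    ``ceil(window_frac * max(n, m))`` index units of the alignment diagonal,
    measured on the scale of the longer series, which makes the constraint
    symmetric in the two arguments.
    """
    if not 0 < window_frac <= 1:
        raise ValueError("window_frac must be in (0, 1]")
    av = a.values if isinstance(a, MultiSeries) else np.atleast_2d(np.asarray(a, float).T).T
    bv = b.values if isinstance(b, MultiSeries) else np.atleast_2d(np.asarray(b, float).T).T
    if av.ndim == 1:
        av = av[:, None]
    if bv.ndim == 1:
        bv = bv[:, None]
    if av.shape[1] != bv.shape[1]:
        raise ValueError("series must have the same number of channels")
    band = int(np.ceil(window_frac * max(av.shape[0], bv.shape[0])))
    d = _dtw_dp(np.ascontiguousarray(av), np.ascontiguousarray(bv), band)
    if not np.isfinite(d):
        raise ValueError(
            f"no warping path within a {window_frac:.0%} band: series lengths "
            f"{av.shape[0]} and {bv.shape[0]} are too unequal for this window"
        )
    return float(d)


def distance_matrix(series: Sequence[MultiSeries], window_frac: float = 0.05) -> DistanceMatrix:
    """All-pairs DTW distances (each unordered pair computed once)."""
    if len(series) < 2:
        raise ValueError("need >= 2 series")
    n = len(series)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                mat[i, j] = mat[j, i] = dtw_distance(series[i], series[j], window_frac)
            except ValueError as e:
                raise ValueError(
                    f"DTW failed for fish {series[i].fish_id} vs "
                    f"{series[j].fish_id}: {e}"
                ) from e
    return DistanceMatrix([s.fish_id for s in series], mat, window_frac)


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def ward_linkage(dmat: DistanceMatrix) -> np.ndarray:
    """Ward agglomeration of the DTW distance matrix.

    Uses the Lance-Williams recursion on squared distances with merge
    heights reported back on the distance scale (the standard Ward-on-
    dissimilarities convention).
    """
    return linkage(squareform(dmat.matrix, checks=False), method="ward")


def ward_cluster(dmat: DistanceMatrix, k: int) -> np.ndarray:
    """Cut the Ward dendrogram at k clusters; labels are stable ints 1..k."""
    n = len(dmat.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if k == n:
        return np.arange(1, n + 1)
    Z = ward_linkage(dmat)
    return fcluster(Z, t=k, criterion="maxclust")


# ---------------------------------------------------------------------------
# Internal cluster validity indices
# ---------------------------------------------------------------------------

def _medoid(dm: np.ndarray, idx: np.ndarray) -> int:
    sub = dm[np.ix_(idx, idx)]
    return int(idx[np.argmin(sub.sum(axis=0))])


def cvi_suite(dmat: DistanceMatrix, labels: np.ndarray) -> dict[str, float]:
    """Six internal validity indices from the distance matrix alone.

    Medoids stand in for centroids.  An index that is undefined for the
    given partition (e.g. coincident medoids) is returned as NaN and later
    excluded from its vote.
    """
    dm = dmat.matrix
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = len(uniq), len(labels)
    if k < 2:
        raise ValueError("need >= 2 non-empty clusters")
    groups = [np.flatnonzero(labels == u) for u in uniq]
    medoids = np.array([_medoid(dm, g) for g in groups])
    overall_medoid = _medoid(dm, np.arange(n))

    out: dict[str, float] = {}

    out["silhouette"] = float(silhouette_score(dm, labels, metric="precomputed"))

    # Dunn: smallest between-cluster gap over largest within-cluster diameter
    diam = max(dm[np.ix_(g, g)].max() for g in groups)
    sep = min(
        dm[np.ix_(groups[i], groups[j])].min()
        for i in range(k) for j in range(i + 1, k)
    )
    out["dunn"] = float(sep / diam) if diam > 0 else np.nan

    # Calinski-Harabasz with medoid dispersion
    W = sum(np.sum(dm[g, medoids[i]] ** 2) for i, g in enumerate(groups))
    B = sum(len(g) * dm[medoids[i], overall_medoid] ** 2 for i, g in enumerate(groups))
    out["calinski_harabasz"] = float((B / (k - 1)) / (W / (n - k))) if W > 0 else np.nan

    # Davies-Bouldin and its modified (DB*) form
    S = np.array([dm[g, medoids[i]].mean() for i, g in enumerate(groups)])
    M = dm[np.ix_(medoids, medoids)]
    with np.errstate(divide="ignore", invalid="ignore"):
        db_terms, dbs_terms = [], []
        for i in range(k):
            others = [j for j in range(k) if j != i]
            if min(M[i, j] for j in others) == 0:
                db_terms.append(np.nan)
                dbs_terms.append(np.nan)
                continue
            db_terms.append(max((S[i] + S[j]) / M[i, j] for j in others))
            dbs_terms.append(max(S[i] + S[j] for j in others)
                             / min(M[i, j] for j in others))
    out["davies_bouldin"] = float(np.mean(db_terms))
    out["davies_bouldin_star"] = float(np.mean(dbs_terms))

    # COP: cluster cohesion over worst-case outside separation
    cop = 0.0
    ok = True
    for i, g in enumerate(groups):
        outside = np.setdiff1d(np.arange(n), g)
        if len(outside) == 0:
            ok = False
            break
        intra = dm[g, medoids[i]].mean()
        sep_g = dm[np.ix_(outside, g)].max(axis=1).min()
        if sep_g == 0:
            ok = False
            break
        cop += len(g) * intra / sep_g
    out["cop"] = float(cop / n) if ok else np.nan

    return out


def select_k(
    series: Sequence[MultiSeries] | None,
    k_min: int = 2,
    k_max: int = 10,
    window_frac: float = 0.05,
    dmat: DistanceMatrix | None = None,
) -> tuple[int, CviReport]:
    """Test k in [k_min, k_max]; each index votes; modal k wins.

    Ties are broken toward the smaller k (parsimony) and flagged in the
    report.  The range is truncated (with a shrunk upper bound) when there
    are fewer than k_max + 1 fish.
    """
    if dmat is None:
        if series is None:
            raise ValueError("need series or a precomputed distance matrix")
        dmat = distance_matrix(series, window_frac)
    n = len(dmat.ids)
    k_hi = min(k_max, n - 1)
    ks = list(range(k_min, k_hi + 1))
    if not ks:
        raise ValueError("no admissible k in range")
    rows = {}
    for k in ks:
        labels = ward_cluster(dmat, k)
        rows[k] = cvi_suite(dmat, labels)
    values = pd.DataFrame(rows).T
    values.index.name = "k"

    best_k: dict[str, int] = {}
    for name, orient in CVI_ORIENTATION.items():
        col = values[name].dropna()
        if col.empty:
            continue
        best_k[name] = int(col.idxmax() if orient == "max" else col.idxmin())
    votes: dict[int, int] = {}
    for k in best_k.values():
        votes[k] = votes.get(k, 0) + 1
    top = max(votes.values())
    winners = sorted(k for k, v in votes.items() if v == top)
    report = CviReport(values, best_k, votes, winners[0], tie=len(winners) > 1)
    return report.k_best, report
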