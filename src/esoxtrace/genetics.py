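"""Genotype assignment probabilities and phenotype-genotype matching.

The admixture analysis itself happens upstream (e.g. STRUCTURE); this
module consumes its per-fish Q-matrix of assignment probabilities to K
genetic clusters, assigns discrete genotypes by a conservative probability
threshold, tests whether behavioral phenotypes differ in their genotype
assignment probabilities (PERMANOVA on Euclidean distances, pairwise
follow-up with Benjamini-Hochberg control), and delimits ecotypes: a
phenotype distinct from all others in genotype space is its own ecotype,
while phenotypes that cannot be told apart genetically merge.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .phenotyper import chisq_test

__all__ = [
    "QMatrix",
    "PermanovaResult",
    "EcotypePartition",
    "read_q_matrix",
    "threshold_assign",
    "permanova",
    "pairwise_permanova",
    "infer_ecotypes",
    "genotype_location_test",
]

UNASSIGNED = "UNASSIGNED"


@dataclass
class QMatrix:
    """Per-fish ancestry/assignment probability vectors over K clusters."""

    fish_ids: list[str]
    q: np.ndarray              # (n, K), rows sum to 1
    cluster_labels: list[str]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.fish_ids):
            raise ValueError("Q matrix shape does not match fish ids")
        if len(self.cluster_labels) != self.q.shape[1]:
            raise ValueError("cluster label count does not match K")
        if np.any(self.q < 0) or np.any(self.q > 1 + 1e-9):
            raise ValueError("Q entries must lie in [0, 1]")
        sums = self.q.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = self.fish_ids[int(np.argmax(np.abs(sums - 1.0)))]
            raise ValueError(f"Q rows must sum to 1 (fish {bad})")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.q, columns=self.cluster_labels)
        df.insert(0, "fish_id", self.fish_ids)
        return df


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_perm: int
    seed: int
    n: int
    n_groups: int
    pairwise: pd.DataFrame | None = None


@dataclass
class EcotypePartition:
    """Phenotype -> ecotype id mapping from the pairwise test graph."""

    mapping: dict[str, int]
    alpha: float
    provenance: str  # hash of the pairwise table the partition came from

    @property
    def n_ecotypes(self) -> int:
        return len(set(self.mapping.values()))

    def blocks(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for phe, eco in self.mapping.items():
            out.setdefault(eco, set()).add(phe)
        return [out[k] for k in sorted(out)]


# ---------------------------------------------------------------------------
# Input
# ---------------------------------------------------------------------------

def _validate_rows(fish_ids: list[str], q: np.ndarray, labels: list[str]) -> QMatrix:
    if len(set(fish_ids)) != len(fish_ids):
        dup = next(f for f in fish_ids if fish_ids.count(f) > 1)
        raise ValueError(f"duplicate fish id {dup!r}")
    if np.any(q < 0):
        bad = fish_ids[int(np.argmax((q < 0).any(axis=1)))]
        raise ValueError(f"negative assignment probability (fish {bad})")
    sums = q.sum(axis=1)
    off = np.abs(sums - 1.0)
    if np.any(off > 1e-3):
        bad = fish_ids[int(np.argmax(off))]
        raise ValueError(
            f"row sum {sums[int(np.argmax(off))]:.4f} outside tolerance (fish {bad})"
        )
    q = q / sums[:, None]
    return QMatrix(fish_ids, q, labels)


def read_q_matrix(path: str | Path, dialect: str = "csv") -> QMatrix:
    """Read assignment probabilities from CSV or a STRUCTURE-style outfile.

    The CSV dialect expects columns ``fish_id,q1..qK``.  The
    ``structure_outfile`` dialect parses the whitespace-aligned cluster
    membership block that follows the "Inferred ancestry of individuals"
    header.  Rows whose sum is within 1e-3 of 1 are renormalised; anything
    further off is rejected with the fish id.
    """
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path, dtype={"fish_id": str})
        qcols = [c for c in df.columns if re.fullmatch(r"q\d+", c)]
        if "fish_id" not in df.columns or not qcols:
            raise ValueError(f"{path}: need columns fish_id,q1..qK")
        qcols = sorted(qcols, key=lambda c: int(c[1:]))
        return _validate_rows(df["fish_id"].tolist(),
                              df[qcols].to_numpy(float), qcols)
    if dialect == "structure_outfile":
        lines = path.read_text().splitlines()
        try:
            start = next(i for i, l in enumerate(lines)
                         if "Inferred ancestry of individuals" in l)
        except StopIteration:
            raise ValueError(f"{path}: no 'Inferred ancestry' block") from None
        fish_ids: list[str] = []
        rows: list[list[float]] = []
        for line in lines[start + 1:]:
            if ":" not in line:
                if fish_ids and not line.strip():
                    break
                continue
            left, right = line.split(":", 1)
            toks = left.split()
            try:
                vals = [float(v) for v in right.split()]
            except ValueError:
                # column-header line ("... : Inferred clusters")
                continue
            if len(toks) < 2 or not vals:
                continue
            fish_ids.append(toks[1])
            rows.append(vals)
        if not fish_ids:
            raise ValueError(f"{path}: empty membership block")
        q = np.asarray(rows, dtype=float)
        labels = [f"q{i+1}" for i in range(q.shape[1])]
        return _validate_rows(fish_ids, q, labels)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Discrete assignment
# ---------------------------------------------------------------------------

def threshold_assign(q: QMatrix, tau: float = 0.7,
                     genotype_names: Sequence[str] | None = None) -> pd.Series:
    """Assign each fish to its argmax cluster iff that probability >= tau.

    ``tau`` must exceed 0.5 so at most one cluster can qualify; the
    comparison is inclusive at the boundary.  Fish below the threshold stay
    ``UNASSIGNED`` (related to more than one genotype).
    """
    if not 0.5 < tau <= 1.0:
        raise ValueError("tau must satisfy 0.5 < tau <= 1 to guarantee uniqueness")
    names = list(genotype_names) if genotype_names is not None else q.cluster_labels
    if len(names) != q.q.shape[1]:
        raise ValueError("genotype_names length must equal K")
    best = q.q.argmax(axis=1)
    ok = q.q[np.arange(len(best)), best] >= tau
    labels = [names[b] if o else UNASSIGNED for b, o in zip(best, ok)]
    return pd.Series(labels, index=q.fish_ids, name="genotype")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def permanova(Y: np.ndarray | pd.DataFrame, groups: Sequence[str],
              n_perm: int = 9999, seed: int = 0) -> PermanovaResult:
    """Permutational MANOVA of assignment probabilities across groups.

    Euclidean distances on the rows of ``Y``; pseudo-F and R^2 come from
    the distance-matrix decomposition of the total sum of squares, and the
    p-value from whole-row label permutations with the observed statistic
    included in the null set, so the smallest attainable p is
    1/(n_perm + 1).  Rows are brought into a canonical (lexicographic)
    order before the permutation stream is applied, making the result
    invariant to the input row order.
    """
    Y = np.asarray(Y, dtype=float)
    labels = np.asarray(groups)
    if Y.ndim == 1:
        Y = Y[:, None]
    if len(labels) != Y.shape[0]:
        raise ValueError("groups length must match rows of Y")
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y must be complete (finite)")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if counts.min() < 2:
        small = uniq[int(np.argmin(counts))]
        raise ValueError(f"group {small!r} has < 2 members")

    order = np.lexsort(np.vstack([labels.astype(str)] + [Y[:, c] for c in range(Y.shape[1])]))
    Y = Y[order]
    labels = labels[order]

    n = Y.shape[0]
    g = len(uniq)
    sq = (Y ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Y @ Y.T)
    np.clip(d2, 0.0, None, out=d2)
    ss_total = d2.sum() / (2.0 * n)

    rng = np.random.default_rng(seed)
    codes = np.searchsorted(uniq, labels)
    perm_codes = np.empty((n_perm + 1, n), dtype=np.int64)
    perm_codes[0] = codes
    for b in range(1, n_perm + 1):
        perm_codes[b] = rng.permutation(codes)

    ssw = np.zeros(n_perm + 1)
    for gi, ng in enumerate(zip(uniq, counts)):
        _, size = ng
        ind = (perm_codes == gi).astype(float)
        ssw += np.einsum("bi,ij,bj->b", ind, d2, ind) / (2.0 * size)
    ssb = ss_total - ssw
    with np.errstate(divide="ignore", invalid="ignore"):
        f_all = (ssb / (g - 1)) / (ssw / (n - g))
    f_obs = float(f_all[0])
    p = float(np.count_nonzero(f_all >= f_obs) / (n_perm + 1))
    r2 = float(ssb[0] / ss_total) if ss_total > 0 else 0.0
    return PermanovaResult(f_obs, r2, p, n_perm, seed, n, g)


def pairwise_permanova(Y: np.ndarray | pd.DataFrame, groups: Sequence[str],
                       n_perm: int = 9999, seed: int = 0,
                       fdr_alpha: float = 0.05) -> pd.DataFrame:
    """PERMANOVA on every group pair with Benjamini-Hochberg adjustment."""
    Y = np.asarray(Y, dtype=float)
    labels = np.asarray(groups)
    uniq = sorted(np.unique(labels))
    pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1:]]
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             np.random.SeedSequence(seed).spawn(len(pairs))]
    rows = []
    for (a, b), s in zip(pairs, seeds):
        sel = (labels == a) | (labels == b)
        res = permanova(Y[sel], labels[sel], n_perm=n_perm, seed=s)
        rows.append({"group_a": a, "group_b": b, "pseudo_f": res.pseudo_f,
                     "r2": res.r2, "p": res.p})
    table = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(table["p"], alpha=fdr_alpha,
                                        method="fdr_bh")
    table["p_adjusted"] = p_adj
    table["significant"] = reject
    return table


def infer_ecotypes(pairwise: pd.DataFrame, phenotypes: Sequence[str],
                   alpha: float = 0.05) -> EcotypePartition:
    """Merge phenotypes indistinguishable in genotype space into ecotypes.

    Build a graph over phenotypes with an edge wherever the adjusted
    pairwise p-value is >= alpha (the pair cannot be told apart); ecotypes
    are the connected components, so a phenotype significantly different
    from all others forms a singleton ecotype.
    """
    phenotypes = list(dict.fromkeys(phenotypes))
    have = {frozenset((r.group_a, r.group_b)) for r in pairwise.itertuples()}
    need = {frozenset((a, b)) for i, a in enumerate(phenotypes)
            for b in phenotypes[i + 1:]}
    missing = need - have
    if missing:
        pair = sorted(next(iter(missing)))
        raise ValueError(f"pairwise table missing pair {pair}")

    parent = {p: p for p in phenotypes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for r in pairwise.itertuples():
        if r.group_a in parent and r.group_b in parent and r.p_adjusted >= alpha:
            ra, rb = find(r.group_a), find(r.group_b)
            if ra != rb:
                parent[ra] = rb
    roots: dict[str, int] = {}
    mapping: dict[str, int] = {}
    for p in phenotypes:
        r = find(p)
        if r not in roots:
            roots[r] = len(roots) + 1
        mapping[p] = roots[r]
    digest = hashlib.sha256(
        pairwise.sort_values(["group_a", "group_b"]).to_csv(index=False).encode()
    ).hexdigest()[:16]
    return EcotypePartition(mapping, alpha, digest)


def genotype_location_test(labels: pd.Series, locations: pd.Series,
                           include_unassigned: bool = False):
    """Chi-squared test of genotype counts against capture location."""
    df = pd.DataFrame({"genotype": labels, "location": locations}).dropna()
    if not include_unassigned:
        df = df[df["genotype"] != UNASSIGNED]
    table = pd.crosstab(df["genotype"], df["location"])
    return chisq_test(table.to_numpy())
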