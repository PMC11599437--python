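"""Behavioral phenotype assignment and validation.

DTW clustering separates fish by the shape and level of their lifelong
chemistry, but several clusters can be ecologically equivalent (e.g. two
groups of brackish residents from lagoons of different mean salinity).
This module collapses clusters into four behavioral phenotypes through an
explicit, ordered rule framework driven by natal origin (annulus-1 Sr:Ca),
lifelong habitat use (threshold excursions in the annual Sr:Ca means) and
capture context, then validates the phenotypes with a leave-one-out linear
discriminant reclassification on life-stage features and tests phenotype
frequencies along the salinity gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeCall",
    "ConfusionMatrix",
    "Thresholds",
    "natal_origin",
    "count_excursions",
    "assign_phenotypes",
    "jackknife_lda",
    "chisq_test",
    "phenotype_frequency_report",
]

ORIGINS = ("FRESH", "BRACKISH", "INTERMEDIATE")
PHENOTYPE_LABELS = ("FW_RESIDENT", "ANADROMOUS", "BRACKISH_RESIDENT",
                    "CROSS_HABITAT")


@dataclass
class Thresholds:
    """Sr:Ca decision thresholds (mg/g).

    ``fw`` / ``brackish`` bound the natal-origin call (core chemistry at or
    below ``fw`` means a freshwater birth, at or above ``brackish`` a
    brackish one, in between is intermediate); ``excursion`` is the single
    boundary used to count lifelong habitat shifts; ``min_run`` is the
    number of consecutive annual means required before a crossing counts as
    an excursion rather than noise.
    """

    fw: float = 1.0
    brackish: float = 2.0
    excursion: float = 1.5
    min_run: int = 1

    def validate(self) -> None:
        if self.fw >= self.brackish:
            raise ValueError("thresholds inverted: fw must be < brackish")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


@dataclass
class PhenotypeCall:
    fish_id: str
    phenotype: str          # one of PHENOTYPE_LABELS or "UNCLASSIFIED"
    natal_origin: str
    excursions: int
    rule_trace: list[str]
    cluster: int | None = None


@dataclass
class ConfusionMatrix:
    labels: list[str]
    counts: np.ndarray      # rows = true, columns = predicted
    recall: dict[str, float]
    correct_rate: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# Rule primitives
# ---------------------------------------------------------------------------

def natal_origin(natal_sr: float, fw_threshold: float, brackish_threshold: float) -> str:
    """Classify the birth habitat from the annulus-1 mean Sr:Ca."""
    if fw_threshold >= brackish_threshold:
        raise ValueError("thresholds inverted: fw must be < brackish")
    if natal_sr <= fw_threshold:
        return "FRESH"
    if natal_sr >= brackish_threshold:
        return "BRACKISH"
    return "INTERMEDIATE"


def count_excursions(series: Sequence[float], threshold: float,
                     natal_side: str = "low", min_run: int = 1) -> int:
    """Count habitat excursions in a per-annulus mean series.

    An excursion is a maximal run of at least ``min_run`` consecutive annual
    means on the opposite side of ``threshold`` from the natal side; shorter
    runs are treated as noise.  ``natal_side`` is ``"low"`` for a freshwater
    birth and ``"high"`` for a brackish one.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    x = np.asarray(series, dtype=float)
    if natal_side == "low":
        opposite = x > threshold
    elif natal_side == "high":
        opposite = x < threshold
    else:
        raise ValueError("natal_side must be 'low' or 'high'")
    count = 0
    run = 0
    for flag in opposite:
        if flag:
            run += 1
        else:
            if run >= min_run:
                count += 1
            run = 0
    if run >= min_run:
        count += 1
    return count


# ---------------------------------------------------------------------------
# Decision framework
# ---------------------------------------------------------------------------

def _classify_one(natal: str, means: np.ndarray, thr: Thresholds,
                  habitat: str, season: str) -> tuple[str, int, list[str]]:
    trace: list[str] = [f"natal_origin={natal}"]
    natal_side = "high" if natal == "BRACKISH" else "low"
    exc = count_excursions(means, thr.excursion, natal_side, thr.min_run)
    trace.append(f"excursions={exc}")

    def r2_fw() -> bool:
        return natal == "FRESH" and bool(np.all(means <= thr.excursion))

    # R5: capture-context guard -- a tributary capture outside the spawning
    # season can only be a freshwater resident, so that check runs first
    if habitat == "tributary" and season == "non_spawning":
        trace.append("R5:tributary_non_spawning_guard")
        if r2_fw():
            trace.append("R2:fw_resident")
            return "FW_RESIDENT", exc, trace
        trace.append("R5:conflict(non-FW signal in non-spawning tributary capture)")

    # R1: brackish birth and never a freshwater excursion
    if natal == "BRACKISH" and exc == 0:
        trace.append("R1:brackish_resident")
        return "BRACKISH_RESIDENT", exc, trace
    # R2: freshwater birth and lifelong freshwater chemistry
    if r2_fw():
        trace.append("R2:fw_resident")
        return "FW_RESIDENT", exc, trace
    # R3: freshwater birth with at least one brackish excursion
    if natal == "FRESH" and exc >= 1:
        trace.append("R3:anadromous")
        return "ANADROMOUS", exc, trace
    # R4: intermediate origin, or oscillations whose minima stay brackish
    if natal == "INTERMEDIATE" or (len(means) and means.min() > thr.fw):
        trace.append("R4:cross_habitat")
        return "CROSS_HABITAT", exc, trace
    trace.append("UNCLASSIFIED:no_rule_fired")
    return "UNCLASSIFIED", exc, trace


def assign_phenotypes(
    annual_table: pd.DataFrame,
    fish: pd.DataFrame,
    thresholds: Thresholds | None = None,
    cluster_labels: Mapping[str, int] | None = None,
) -> list[PhenotypeCall]:
    """Run the ordered decision rules R1-R5 for every fish.

    ``annual_table`` is the per-fish-year table of annual Sr:Ca means (from
    :func:`esoxtrace.transect_io.annual_means_table`); ``fish`` supplies
    capture habitat and season.  Cluster labels, when given, are recorded on
    each call for auditing the cluster-to-phenotype collapse; the rules
    themselves are a pure function of chemistry, thresholds and capture
    context, so identical inputs always produce identical calls and traces.
    """
    thr = thresholds or Thresholds()
    thr.validate()
    meta = fish.set_index("fish_id")
    calls: list[PhenotypeCall] = []
    for fish_id, grp in annual_table.groupby("fish_id", sort=False):
        grp = grp.sort_values("annulus")
        means = grp["sr_ca_mean"].to_numpy(float)
        if grp["annulus"].iloc[0] != 1:
            raise ValueError(f"fish {fish_id}: natal annulus missing")
        natal = natal_origin(means[0], thr.fw, thr.brackish)
        try:
            habitat = str(meta.loc[fish_id, "capture_habitat"])
            season = str(meta.loc[fish_id, "capture_season"])
        except KeyError:
            raise ValueError(f"fish {fish_id}: no metadata record") from None
        phe, exc, trace = _classify_one(natal, means, thr, habitat, season)
        cl = None if cluster_labels is None else int(cluster_labels.get(fish_id, -1))
        if cl is not None:
            trace.insert(0, f"cluster={cl}")
        calls.append(PhenotypeCall(str(fish_id), phe, natal, exc, trace, cl))
    return calls


def calls_to_frame(calls: Sequence[PhenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "fish_id": c.fish_id,
            "phenotype": c.phenotype,
            "natal_origin": c.natal_origin,
            "excursions": c.excursions,
            "rule_trace": ";".join(c.rule_trace),
        }
        for c in calls
    ])


# ---------------------------------------------------------------------------
# Jackknife LDA validation
# ---------------------------------------------------------------------------

def _lda_fit_predict(X_train: np.ndarray, y_train: np.ndarray,
                     x_new: np.ndarray, ridge: float = 0.0) -> str:
    classes, counts = np.unique(y_train, return_counts=True)
    n, p = X_train.shape
    means = np.vstack([X_train[y_train == c].mean(axis=0) for c in classes])
    pooled = np.zeros((p, p))
    for c, m in zip(classes, means):
        d = X_train[y_train == c] - m
        pooled += d.T @ d
    pooled /= (n - len(classes))
    pooled += ridge * np.eye(p)
    try:
        inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError:
        inv = np.linalg.inv(pooled + 1e-6 * np.trace(pooled) / p * np.eye(p))
    priors = counts / n
    scores = [
        x_new @ inv @ m - 0.5 * m @ inv @ m + np.log(pi)
        for m, pi in zip(means, priors)
    ]
    return classes[int(np.argmax(scores))]


def jackknife_lda(
    features: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    feature_cols: Sequence[str] = ("natal_sr", "natal_d18o_res", "early_sr",
                                   "early_d18o_res", "later_sr",
                                   "later_d18o_res"),
) -> tuple[float, ConfusionMatrix]:
    """Leave-one-out linear-discriminant reclassification rate.

    For each fish a Gaussian linear discriminant (pooled covariance, class
    priors proportional to training counts) is fitted on all other fish and
    asked to reclassify the held-out fish from its six life-stage features.
    Fish with missing stages (age-1/age-2) are excluded up front; a singular
    pooled covariance is ridge-regularised with a trace-scaled epsilon.
    """
    if isinstance(labels, Mapping):
        labels = pd.Series(labels)
    df = features.set_index("fish_id")[list(feature_cols)].copy()
    df["__label"] = labels.reindex(df.index)
    df = df.dropna()
    X = df[list(feature_cols)].to_numpy(float)
    y = df["__label"].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("each class needs >= 2 members")
    n = len(y)
    pred = np.empty(n, dtype=object)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        pred[i] = _lda_fit_predict(X[keep], y[keep], X[i])
    order = list(classes)
    counts = np.zeros((len(order), len(order)), dtype=int)
    for t, p in zip(y, pred):
        counts[order.index(t), order.index(p)] += 1
    recall = {
        c: counts[i, i] / counts[i].sum() if counts[i].sum() else float("nan")
        for i, c in enumerate(order)
    }
    rate = float(np.trace(counts) / n)
    return rate, ConfusionMatrix([str(c) for c in order], counts, recall, rate)


# ---------------------------------------------------------------------------
# Frequency tests
# ---------------------------------------------------------------------------

def chisq_test(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction.

    All-zero rows/columns are dropped before testing (the drop is reflected
    in the degrees of freedom).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("need a 2-D contingency table")
    if np.any(t < 0):
        raise ValueError("counts must be >= 0")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.size == 0:
        raise ValueError("all counts zero")
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns with nonzero margins")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(dof), float(p)


def phenotype_frequency_report(
    calls: Sequence[PhenotypeCall] | pd.DataFrame,
    fish: pd.DataFrame,
    pool_by: str = "capture_habitat",
) -> dict:
    """Phenotype counts by capture pool plus the chi-squared gradient test.

    Fish captured in tributaries outside the spawning season are sampled
    from a resident-only frame and are therefore excluded from the test (but
    reported).  Returns the counts table, the exclusion list, and the test
    triple (or ``None`` with a reason when the pooled table is untestable).
    """
    df = calls if isinstance(calls, pd.DataFrame) else calls_to_frame(calls)
    merged = df.merge(fish, on="fish_id", how="left")
    excluded = merged[(merged["capture_habitat"] == "tributary")
                      & (merged["capture_season"] == "non_spawning")]
    tested = merged.drop(excluded.index)
    if tested.empty:
        raise ValueError("no fish left in testing scope")
    counts = pd.crosstab(tested[pool_by], tested["phenotype"])
    result: dict = {
        "counts": counts,
        "excluded_fish": excluded["fish_id"].tolist(),
        "test": None,
        "untestable_reason": None,
    }
    nz = counts.loc[counts.sum(axis=1) > 0, counts.sum(axis=0) > 0]
    if nz.shape[0] < 2 or nz.shape[1] < 2:
        result["untestable_reason"] = "degenerate table after dropping zero margins"
        return result
    stat, dof, p = chisq_test(counts.to_numpy())
    result["test"] = {"statistic": stat, "df": dof, "p": p}
    return result
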