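"""Reading, pairing and preprocessing of otolith core-to-edge transects.

An otolith transect carries two chemical channels measured along the same
core-to-edge track but on different spatial grids: Sr:Ca (mg/g, salinity
proxy, fine laser-ablation grid) and delta-18-O (permil VPDB, thermal proxy,
coarser ion-probe grid).  This module pairs the two channels, removes the
salinity covariation from delta-18-O by pooled linear regression (the
residual is the relative-temperature proxy used everywhere downstream), and
summarises transects per annulus and per life stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Transect",
    "LifeStageFeatures",
    "TransectFormatError",
    "read_transects",
    "write_transects",
    "read_fish_records",
    "write_fish_records",
    "pair_channels",
    "correct_temperature_proxy",
    "annual_means",
    "annual_means_table",
    "stage_features",
    "stage_features_table",
]

TRANSECT_COLUMNS = ["fish_id", "distance_um", "annulus", "sr_ca", "d18o"]
FISH_COLUMNS = [
    "fish_id",
    "sex",
    "age",
    "total_length_mm",
    "capture_location",
    "capture_habitat",
    "capture_season",
]

SEXES = {"F", "M"}
HABITATS = {"lagoon", "tributary"}
SEASONS = {"spawning", "non_spawning"}


class TransectFormatError(ValueError):
    """Raised when a transect or fish CSV violates the input contract."""


@dataclass
class Transect:
    """One fish's ordered core-to-edge transect.

    ``points`` has columns ``distance_um`` (strictly increasing), ``annulus``
    (1-based, non-decreasing), ``sr_ca`` (mg/g, >= 0), ``d18o`` (permil VPDB,
    NaN where only the elemental channel was measured) and, after
    :func:`correct_temperature_proxy`, ``d18o_res``.
    """

    fish_id: str
    points: pd.DataFrame
    paired: bool = False

    def __post_init__(self) -> None:
        self.points = self.points.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        pts = self.points
        for col in ("distance_um", "annulus", "sr_ca"):
            if col not in pts.columns:
                raise TransectFormatError(
                    f"fish {self.fish_id}: missing column {col!r}"
                )
        if len(pts) == 0:
            raise TransectFormatError(f"fish {self.fish_id}: empty transect")
        d = pts["distance_um"].to_numpy(float)
        if np.any(~np.isfinite(d)) or np.any(np.diff(d) <= 0):
            raise TransectFormatError(
                f"fish {self.fish_id}: distances must be finite and strictly increasing"
            )
        ann = pts["annulus"].to_numpy()
        if np.any(np.diff(ann) < 0):
            raise TransectFormatError(
                f"fish {self.fish_id}: annulus indices must be non-decreasing"
            )
        if ann[0] != 1 and 1 not in set(ann.tolist()):
            raise TransectFormatError(f"fish {self.fish_id}: annulus 1 absent")
        sr = pts["sr_ca"].to_numpy(float)
        if np.any(~np.isfinite(sr)) or np.any(sr < 0):
            raise TransectFormatError(
                f"fish {self.fish_id}: Sr:Ca must be finite and >= 0"
            )

    @property
    def n_annuli(self) -> int:
        return int(self.points["annulus"].max())


@dataclass
class LifeStageFeatures:
    """Stage-wise mean Sr:Ca / d18O residual for one fish.

    Stages follow the otolith chronology: natal = year 1, early = year 2,
    later = unweighted mean over the annual means of years >= 3.  Early and
    later are NaN (and flagged absent) for age-1 / age-2 fish.
    """

    fish_id: str
    natal_sr: float
    natal_d18o_res: float
    early_sr: float = float("nan")
    early_d18o_res: float = float("nan")
    later_sr: float = float("nan")
    later_d18o_res: float = float("nan")
    has_early: bool = False
    has_later: bool = False


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_transects(path: str | Path) -> dict[str, Transect]:
    """Read ``transects.csv`` into one :class:`Transect` per fish.

    Rows must be grouped by fish; within each fish, points are sorted by
    distance before validation so file order is forgiving, but duplicated or
    reversed distances are reported with the offending fish id.
    """
    df = pd.read_csv(path, dtype={"fish_id": str})
    missing = [c for c in TRANSECT_COLUMNS if c not in df.columns and c != "d18o"]
    if missing:
        raise TransectFormatError(f"{path}: missing required column(s) {missing}")
    if "d18o" not in df.columns:
        df["d18o"] = np.nan
    bad = df.index[df["sr_ca"].isna()]
    if len(bad):
        lines = (bad[:5] + 2).tolist()  # +2: header + 1-based
        raise TransectFormatError(f"{path}: missing sr_ca at line(s) {lines}")
    out: dict[str, Transect] = {}
    for fish_id, grp in df.groupby("fish_id", sort=False):
        pts = grp[["distance_um", "annulus", "sr_ca", "d18o"]].copy()
        d = pts["distance_um"].to_numpy(float)
        if np.any(np.diff(d) <= 0):
            i = int(np.argmax(np.diff(d) <= 0))
            line = int(grp.index[i + 1]) + 2
            raise TransectFormatError(
                f"{path}: non-increasing distance for fish {fish_id} at line {line}"
            )
        out[str(fish_id)] = Transect(str(fish_id), pts)
    return out


def write_transects(transects: Mapping[str, Transect] | Iterable[Transect],
                    path: str | Path) -> None:
    if isinstance(transects, Mapping):
        transects = transects.values()
    frames = []
    for t in transects:
        f = t.points[["distance_um", "annulus", "sr_ca", "d18o"]].copy()
        f.insert(0, "fish_id", t.fish_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_fish_records(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-fish metadata table (``fish.csv``)."""
    df = pd.read_csv(path, dtype={"fish_id": str})
    missing = [c for c in FISH_COLUMNS if c not in df.columns]
    if missing:
        raise TransectFormatError(f"{path}: missing required column(s) {missing}")
    if df["fish_id"].duplicated().any():
        dup = df.loc[df["fish_id"].duplicated(), "fish_id"].iloc[0]
        raise TransectFormatError(f"{path}: duplicate fish id {dup!r}")
    for col, vocab in (("sex", SEXES), ("capture_habitat", HABITATS),
                       ("capture_season", SEASONS)):
        bad = set(df[col].astype(str)) - vocab
        if bad:
            raise TransectFormatError(f"{path}: invalid {col} value(s) {sorted(bad)}")
    if (df["age"] < 1).any():
        raise TransectFormatError(f"{path}: age must be >= 1")
    return df


def write_fish_records(fish: pd.DataFrame, path: str | Path) -> None:
    fish[FISH_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Channel pairing
# ---------------------------------------------------------------------------

def pair_channels(transect: Transect) -> Transect:
    """Attach the elemental channel to the isotope grid.

    The d18O spots sit on a coarser grid than the laser-ablation Sr:Ca
    points.  Each d18O spot receives the mean Sr:Ca of elemental points
    within +/- half the median spot spacing of its position; the output
    series lives on the d18O spot positions only.  Spots with no elemental
    point in their window are kept but flagged ``paired_excluded`` so the
    pooled regression can skip them.
    """
    pts = transect.points
    iso = pts[pts["d18o"].notna()]
    if len(iso) == 0:
        raise TransectFormatError(
            f"fish {transect.fish_id}: no d18o points to pair"
        )
    iso_pos = iso["distance_um"].to_numpy(float)
    if len(iso_pos) > 1:
        half_window = float(np.median(np.diff(iso_pos))) / 2.0
    else:
        half_window = np.inf
    el_pos = pts["distance_um"].to_numpy(float)
    el_sr = pts["sr_ca"].to_numpy(float)

    sr_paired = np.empty(len(iso_pos))
    excluded = np.zeros(len(iso_pos), dtype=bool)
    for i, x in enumerate(iso_pos):
        mask = np.abs(el_pos - x) <= half_window
        if not mask.any():
            sr_paired[i] = np.nan
            excluded[i] = True
        else:
            sr_paired[i] = el_sr[mask].mean()

    out = pd.DataFrame({
        "distance_um": iso_pos,
        "annulus": iso["annulus"].to_numpy(),
        "sr_ca": sr_paired,
        "d18o": iso["d18o"].to_numpy(float),
        "paired_excluded": excluded,
    })
    # the Transect invariant requires finite sr_ca; excluded spots carry the
    # original (nearest) value but stay flagged out of the regression
    if excluded.any():
        nearest = np.abs(el_pos[None, :] - iso_pos[excluded, None]).argmin(axis=1)
        out.loc[excluded, "sr_ca"] = el_sr[nearest]
    return Transect(transect.fish_id, out, paired=True)


# ---------------------------------------------------------------------------
# Salinity correction of the thermal proxy
# ---------------------------------------------------------------------------

def correct_temperature_proxy(
    transects: Mapping[str, Transect] | Sequence[Transect],
) -> tuple[dict[str, Transect], tuple[float, float]]:
    """Pool all paired points, regress d18O on Sr:Ca, store residuals.

    Water salinity co-determines otolith d18O, so the raw isotope channel
    confounds temperature and salinity.  A single ordinary-least-squares fit
    of d18O on co-located Sr:Ca over *all* fish removes that shared
    component; the per-point residual is the relative-temperature proxy.
    Re-running replaces residuals (idempotent).  Returns the corrected
    transects and the (intercept, slope) of the pooled fit.
    """
    if isinstance(transects, Mapping):
        items = list(transects.values())
    else:
        items = list(transects)
    xs, ys = [], []
    for t in items:
        pts = t.points
        use = pts["d18o"].notna()
        if "paired_excluded" in pts.columns:
            use &= ~pts["paired_excluded"].astype(bool)
        xs.append(pts.loc[use, "sr_ca"].to_numpy(float))
        ys.append(pts.loc[use, "d18o"].to_numpy(float))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 3:
        raise ValueError("need >= 3 paired points across all fish for the regression")
    if np.ptp(x) == 0:
        raise ValueError("constant Sr:Ca: regression design is singular")
    slope, intercept = np.polyfit(x, y, 1)
    out: dict[str, Transect] = {}
    for t in items:
        pts = t.points.copy()
        pts["d18o_res"] = pts["d18o"] - (intercept + slope * pts["sr_ca"])
        if "paired_excluded" in pts.columns:
            pts.loc[pts["paired_excluded"].astype(bool), "d18o_res"] = np.nan
        out[t.fish_id] = Transect(t.fish_id, pts, paired=t.paired)
    return out, (float(intercept), float(slope))


# ---------------------------------------------------------------------------
# Annual and life-stage summaries
# ---------------------------------------------------------------------------

def annual_means(transect: Transect) -> pd.DataFrame:
    """Per-annulus arithmetic means of Sr:Ca and the d18O residual.

    Annuli with zero points are simply absent from the output (they cannot
    occur for a valid transect read from file, but may after pairing drops
    spots).
    """
    pts = transect.points
    cols = {"sr_ca": "sr_ca_mean"}
    if "d18o_res" in pts.columns:
        cols["d18o_res"] = "d18o_res_mean"
    g = pts.groupby("annulus").agg({c: "mean" for c in cols})
    g = g.rename(columns=cols).reset_index()
    g.insert(0, "fish_id", transect.fish_id)
    if "d18o_res_mean" not in g.columns:
        g["d18o_res_mean"] = np.nan
    return g


def annual_means_table(
    transects: Mapping[str, Transect] | Sequence[Transect],
) -> pd.DataFrame:
    """Annual means for all fish plus a grand z-scored Sr:Ca column.

    The z-score uses the mean and sd (ddof=1) over *all* fish-years, the
    scaling used for the salinity covariate of the growth model.
    """
    if isinstance(transects, Mapping):
        items = list(transects.values())
    else:
        items = list(transects)
    tab = pd.concat([annual_means(t) for t in items], ignore_index=True)
    mu = tab["sr_ca_mean"].mean()
    sd = tab["sr_ca_mean"].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        tab["sr_ca_z"] = 0.0
    else:
        tab["sr_ca_z"] = (tab["sr_ca_mean"] - mu) / sd
    return tab


def stage_features(annual: pd.DataFrame) -> LifeStageFeatures:
    """Collapse one fish's annual means into natal/early/later stage means.

    ``later`` is the unweighted mean of the annual means of years >= 3, so a
    long final annulus does not dominate the late-life signal.
    """
    fish_id = str(annual["fish_id"].iloc[0]) if "fish_id" in annual.columns else ""
    a = annual.set_index("annulus")
    if 1 not in a.index:
        raise ValueError(f"fish {fish_id}: natal annulus missing from annual means")
    feats = LifeStageFeatures(
        fish_id=fish_id,
        natal_sr=float(a.loc[1, "sr_ca_mean"]),
        natal_d18o_res=float(a.loc[1, "d18o_res_mean"]),
    )
    if 2 in a.index:
        feats.early_sr = float(a.loc[2, "sr_ca_mean"])
        feats.early_d18o_res = float(a.loc[2, "d18o_res_mean"])
        feats.has_early = True
    late = a[a.index >= 3]
    if len(late):
        feats.later_sr = float(late["sr_ca_mean"].mean())
        feats.later_d18o_res = float(late["d18o_res_mean"].mean())
        feats.has_later = True
    return feats


def stage_features_table(annual_table: pd.DataFrame) -> pd.DataFrame:
    """Stage features for every fish in an annual-means table."""
    rows = []
    for fish_id, grp in annual_table.groupby("fish_id", sort=False):
        f = stage_features(grp)
        rows.append({
            "fish_id": f.fish_id,
            "natal_sr": f.natal_sr,
            "natal_d18o_res": f.natal_d18o_res,
            "early_sr": f.early_sr,
            "early_d18o_res": f.early_d18o_res,
            "later_sr": f.later_sr,
            "later_d18o_res": f.later_d18o_res,
            "has_early": f.has_early,
            "has_later": f.has_later,
        })
    return pd.DataFrame(rows)
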