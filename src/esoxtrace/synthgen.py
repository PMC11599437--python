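"""Synthetic pike populations with known life-history ground truth.

Emulates a coastal pike study system along a salinity gradient: four
behavioral phenotypes leave distinct lifelong Sr:Ca / d18O signatures in
their otoliths, annual otolith increments follow an age/sex/thermosaline
linear model on the log10 scale, radius-at-age follows individual von
Bertalanffy curves drawn from gamma group distributions, and genetic
ancestry vectors are Dirichlet draws concentrated on each fish's true
genotype.  Every downstream estimator in the package can be validated
against the planted truth.

Phenotype archetypes
--------------------
FW_RESIDENT       born in freshwater, low Sr:Ca for life, strong ontogenetic
                  shift from warm to cold habitats (rising d18O residual).
ANADROMOUS        born in freshwater, post-natal years oscillate across the
                  freshwater/brackish boundary.
BRACKISH_RESIDENT born in brackish water, high Sr:Ca throughout, weak
                  thermal shift.
CROSS_HABITAT     intermediate natal salinity, lifelong oscillations whose
                  minima never return below the freshwater threshold, strong
                  thermal shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import transect_io
from .transect_io import Transect

__all__ = [
    "PHENOTYPES",
    "GENOTYPES",
    "SynthConfig",
    "SyntheticDataset",
    "simulate_population",
    "simulate_transect",
    "simulate_increments",
    "simulate_q_vector",
    "simulate_radii",
]

PHENOTYPES = ("FW_RESIDENT", "ANADROMOUS", "BRACKISH_RESIDENT", "CROSS_HABITAT")
#: genetic clusters in Q-matrix column order (q1..q4)
GENOTYPES = ("FRESHWATER", "ANADROMOUS", "BRACKISH1", "BRACKISH2")
#: truth label for fish whose ancestry is split over several clusters
ADMIXED = "ADMIXED"

LAGOONS = ("NRBC", "WRBC", "GB")
TRIBUTARIES = ("BARTHE", "SEHROWBACH", "PEENE", "ZIESE")


def _default_increment_coefs() -> dict[str, float]:
    # log10-increment model; treatment contrasts vs ANADROMOUS / female
    return {
        "intercept": 2.76,
        "age": -0.15,
        "age2": 0.01,
        "d18o_res": -0.03,
        "sr_z": -0.04,
        "sex_male": -0.03,
        "phe_BRACKISH_RESIDENT": -0.02,
        "phe_FW_RESIDENT": -0.08,
        "phe_CROSS_HABITAT": 0.04,
        "age_phe_BRACKISH_RESIDENT": 0.01,
        "age_phe_FW_RESIDENT": 0.01,
        "age_phe_CROSS_HABITAT": 0.01,
    }


def _default_vb_means() -> dict[str, tuple[float, float, float]]:
    # (R_inf [mm], k [1/yr], s0 = -t0 [yr]) group means per phenotype
    return {
        "FW_RESIDENT": (2.85, 0.12, 0.62),
        "ANADROMOUS": (2.85, 0.12, 0.63),
        "CROSS_HABITAT": (2.96, 0.12, 0.64),
        "BRACKISH_RESIDENT": (2.68, 0.11, 0.81),
    }


def _default_dirichlet() -> dict[str, tuple[float, float, float, float]]:
    # concentration over (q_fw, q_anadromous, q_brackish1, q_brackish2)
    return {
        "FRESHWATER": (8.0, 1.0, 0.3, 0.3),
        "ANADROMOUS": (1.0, 8.0, 0.3, 0.3),
        "BRACKISH1": (0.3, 0.5, 8.0, 1.0),
        "BRACKISH2": (0.3, 0.5, 1.0, 8.0),
        ADMIXED: (0.4, 3.0, 2.5, 2.5),
    }


def _default_genotype_mix() -> dict[str, dict[str, float]]:
    # phenotype -> distribution of true genotypes
    return {
        "FW_RESIDENT": {"FRESHWATER": 0.6, "ANADROMOUS": 0.4},
        "ANADROMOUS": {"ANADROMOUS": 0.6, "FRESHWATER": 0.4},
        "BRACKISH_RESIDENT": {"BRACKISH1": 0.4, "BRACKISH2": 0.6},
        "CROSS_HABITAT": {ADMIXED: 1.0},
    }


@dataclass
class SynthConfig:
    """Study conditions for one synthetic population.

    Defaults mirror the emulated field study: 1-13 year old adult pike, 14
    chemistry points per annulus, a freshwater Sr:Ca baseline well below the
    brackish one, and increment / growth-curve coefficients on the scale of
    published estimates for the system.  The same seed always yields the
    same dataset.
    """

    n_fish: tuple[int, int, int, int] = (20, 20, 20, 20)  # per phenotype
    age_min: int = 1
    age_max: int = 13
    points_per_annulus: int = 14
    d18o_every: int = 2  # isotope spot on every Nth elemental point

    # Sr:Ca habitat baselines (mg/g)
    sr_fw: float = 0.5
    sr_bw: float = 3.0
    sr_cross: float = 1.8
    cross_osc_amp: float = 0.7   # excursion amplitude of the cross-habitat wave
    an_cycles: float = 1.5       # habitat-shift cycles over an anadromous life
    cross_cycles: float = 2.0    # oscillation cycles over a cross-habitat life
    sr_noise_sd: float = 0.25       # point-level
    annulus_effect_sd: float = 0.08  # shared within an annulus

    # raw d18O model: intercept + slope*SrCa + ontogenetic thermal shift + noise
    d18o_intercept: float = -4.0
    d18o_sr_slope: float = 0.30
    d18o_noise_sd: float = 0.15
    d18o_shift_timescale: float = 2.0  # years to reach ~63% of the shift
    d18o_shift_amp: Mapping[str, float] = field(default_factory=lambda: {
        "FW_RESIDENT": 0.9, "ANADROMOUS": 0.3,
        "BRACKISH_RESIDENT": 0.25, "CROSS_HABITAT": -0.6,
    })  # permil, total ontogenetic thermal-proxy shift (sign = direction)

    # increment model (log10 um scale)
    increment_coefs: Mapping[str, float] = field(default_factory=_default_increment_coefs)
    random_intercept_sd: float = 0.0316  # sqrt(0.001)
    residual_sd: float = 0.1095          # sqrt(0.012)

    # von Bertalanffy group truth
    vb_means: Mapping[str, tuple[float, float, float]] = field(default_factory=_default_vb_means)
    vb_precisions: tuple[float, float, float] = (25.0, 4444.0, 156.0)
    radius_noise_sd: float = 0.03  # mm, on the radius-at-age table

    # genetics
    dirichlet: Mapping[str, tuple[float, float, float, float]] = field(default_factory=_default_dirichlet)
    genotype_mix: Mapping[str, Mapping[str, float]] = field(default_factory=_default_genotype_mix)

    # sampling design
    fw_nonspawning_frac: float = 0.3    # FW residents netted in July
    anadromous_lagoon_frac: float = 0.2
    cross_lagoon_frac: float = 0.6
    female_frac: float = 0.65

    seed: int = 0

    def validate(self) -> None:
        if len(self.n_fish) != 4 or any(int(n) < 1 for n in self.n_fish):
            raise ValueError("n_fish: need four counts >= 1")
        if self.age_min < 1 or self.age_max < self.age_min:
            raise ValueError("age_min/age_max: need 1 <= age_min <= age_max")
        if self.points_per_annulus < 1:
            raise ValueError("points_per_annulus: must be >= 1")
        if self.d18o_every < 1:
            raise ValueError("d18o_every: must be >= 1")
        for name in ("sr_noise_sd", "annulus_effect_sd", "d18o_noise_sd",
                     "random_intercept_sd", "residual_sd", "radius_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        if not self.sr_fw < self.sr_bw:
            raise ValueError("sr_fw: freshwater baseline must be below sr_bw")
        if self.an_cycles <= 0 or self.cross_cycles <= 0:
            raise ValueError("an_cycles/cross_cycles: must be > 0")
        for g, alpha in self.dirichlet.items():
            if any(a <= 0 for a in alpha):
                raise ValueError(f"dirichlet[{g}]: concentrations must be > 0")
        for frac in ("fw_nonspawning_frac", "anadromous_lagoon_frac",
                     "cross_lagoon_frac", "female_frac"):
            if not 0 <= getattr(self, frac) <= 1:
                raise ValueError(f"{frac}: must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """All tables of one synthetic study, keyed by a shared fish id set."""

    fish: pd.DataFrame
    transects: dict[str, Transect]
    growth: pd.DataFrame
    radii: pd.DataFrame
    qmatrix: pd.DataFrame
    truth: pd.DataFrame
    config: SynthConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        transect_io.write_transects(self.transects, outdir / "transects.csv")
        transect_io.write_fish_records(self.fish, outdir / "fish.csv")
        self.growth.to_csv(outdir / "increments.csv", index=False)
        self.radii.to_csv(outdir / "radii.csv", index=False)
        self.qmatrix.to_csv(outdir / "qmatrix.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)


# ---------------------------------------------------------------------------
# Elemental / isotope transects
# ---------------------------------------------------------------------------

def _sr_truth(phenotype: str, t: np.ndarray, n_annuli: int,
              config: SynthConfig) -> np.ndarray:
    """Noise-free Sr:Ca trajectory at ages ``t`` (years since hatch).

    Habitat shifts are planted in proportional life time (the ontogenetic
    schedule scales with lifespan), so fish of the same archetype but
    different ages trace the same shape and align under a slanted-band
    warp.
    """
    c = config
    if phenotype == "FW_RESIDENT":
        return np.full_like(t, c.sr_fw, dtype=float)
    if phenotype == "BRACKISH_RESIDENT":
        return np.full_like(t, c.sr_bw, dtype=float)
    if phenotype == "ANADROMOUS":
        # fresh natal year, then a smooth habitat wave between baselines
        u = np.clip((t - 1.0) / max(n_annuli - 1.0, 1.0), 0.0, 1.0)
        s = 0.5 * (1.0 - np.cos(2.0 * np.pi * c.an_cycles * u))
        s = np.where(t < 1.0, 0.0, s)
        return c.sr_fw + (c.sr_bw - c.sr_fw) * s
    if phenotype == "CROSS_HABITAT":
        # intermediate start, oscillation trough stays above freshwater
        u = t / max(float(n_annuli), 1.0)
        return c.sr_cross - c.cross_osc_amp * np.cos(2.0 * np.pi * c.cross_cycles * u)
    raise ValueError(f"unknown phenotype label {phenotype!r}")


def simulate_transect(
    phenotype: str,
    n_annuli: int,
    config: SynthConfig,
    rng: np.random.Generator,
    vb_params: tuple[float, float, float] | None = None,
    fish_id: str = "SIM",
) -> Transect:
    """One core-to-edge transect for a fish of the given archetype.

    Point positions follow the fish's von Bertalanffy radius schedule so
    annuli narrow with age like real otoliths; each annulus carries
    ``points_per_annulus`` Sr:Ca points with the isotope channel present on
    every ``d18o_every``-th point.
    """
    if n_annuli < 1:
        raise ValueError("n_annuli must be >= 1")
    c = config
    if vb_params is None:
        vb_params = c.vb_means[phenotype] if phenotype in c.vb_means else (2.85, 0.12, 0.6)
    rinf, k, s0 = vb_params
    radii = rinf * (1.0 - np.exp(-k * (np.arange(0, n_annuli + 1) + s0)))

    amp = c.d18o_shift_amp.get(phenotype, 0.5)
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype label {phenotype!r}")

    ppa = c.points_per_annulus
    rows = []
    for a in range(1, n_annuli + 1):
        r0, r1 = radii[a - 1], radii[a]
        # microns; offset within the annulus, never touching the boundary
        pos = 1000.0 * (r0 + (r1 - r0) * (np.arange(ppa) + 0.5) / ppa)
        t_mid = (a - 1) + (np.arange(ppa) + 0.5) / ppa  # age in years at point
        ann_eff = rng.normal(0.0, c.annulus_effect_sd)
        sr = (_sr_truth(phenotype, t_mid, n_annuli, c) + ann_eff
              + rng.normal(0.0, c.sr_noise_sd, ppa))
        sr = np.clip(sr, 0.0, None)
        # size-driven ontogenetic shift to colder habitats, saturating early
        shift = amp * (1.0 - np.exp(-t_mid / c.d18o_shift_timescale))
        d18o = (c.d18o_intercept + c.d18o_sr_slope * sr + shift
                + rng.normal(0.0, c.d18o_noise_sd, ppa))
        take_iso = (np.arange(ppa) % c.d18o_every) == 0
        d18o = np.where(take_iso, d18o, np.nan)
        rows.append(pd.DataFrame({
            "distance_um": pos,
            "annulus": a,
            "sr_ca": sr,
            "d18o": d18o,
        }))
    return Transect(fish_id, pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Increments, radii, ancestry
# ---------------------------------------------------------------------------

def simulate_increments(
    truth: pd.DataFrame,
    config: SynthConfig,
    rng: np.random.Generator,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One growth record per fish-year from the log10 linear model.

    ``truth`` needs columns fish_id, age, sex, phenotype.  ``covariates``
    (fish_id, lifeyear, annual_d18o_res, annual_srca_z) are used when given,
    e.g. the annual means of simulated transects; otherwise thermosaline
    covariates are drawn independently (standard-normal Sr z-score, 0.5-sd
    thermal residual) for stand-alone model studies.
    """
    c = config
    beta = dict(c.increment_coefs)
    rows = []
    cov_idx = None
    if covariates is not None:
        cov_idx = covariates.set_index(["fish_id", "lifeyear"])
    for rec in truth.itertuples(index=False):
        age = int(rec.age)
        if age < 1:
            raise ValueError(f"fish {rec.fish_id}: age must be >= 1")
        u = rng.normal(0.0, c.random_intercept_sd)
        for year in range(1, age + 1):
            if cov_idx is not None:
                try:
                    cov = cov_idx.loc[(rec.fish_id, year)]
                except KeyError:
                    raise ValueError(
                        f"fish {rec.fish_id}: no covariates for lifeyear {year}"
                    ) from None
                d18o_res = float(cov["annual_d18o_res"])
                sr_z = float(cov["annual_srca_z"])
            else:
                d18o_res = rng.normal(0.0, 0.5)
                sr_z = rng.normal(0.0, 1.0)
            eta = (beta["intercept"]
                   + beta["age"] * year
                   + beta["age2"] * year ** 2
                   + beta["d18o_res"] * d18o_res
                   + beta["sr_z"] * sr_z
                   + (beta["sex_male"] if rec.sex == "M" else 0.0)
                   + beta.get(f"phe_{rec.phenotype}", 0.0)
                   + beta.get(f"age_phe_{rec.phenotype}", 0.0) * year)
            log_inc = eta + u + rng.normal(0.0, c.residual_sd)
            rows.append({
                "fish_id": rec.fish_id,
                "lifeyear": year,
                "increment_um": 10.0 ** log_inc,
                "annual_d18o_res": d18o_res,
                "annual_srca_z": sr_z,
                "sex": rec.sex,
                "phenotype": rec.phenotype,
            })
    return pd.DataFrame(rows)


def simulate_radii(
    truth: pd.DataFrame, config: SynthConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Radius-at-age observations from each fish's planted growth curve."""
    rows = []
    for rec in truth.itertuples(index=False):
        ages = np.arange(1, int(rec.age) + 1)
        mu = rec.R_inf * (1.0 - np.exp(-rec.k * (ages - rec.t0)))
        obs = mu + rng.normal(0.0, config.radius_noise_sd, len(ages))
        obs = np.clip(obs, 1e-6, None)
        for t, r in zip(ages, obs):
            rows.append({"fish_id": rec.fish_id, "age": int(t), "radius": float(r)})
    return pd.DataFrame(rows)


def simulate_q_vector(
    true_genotype: str, config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet ancestry vector concentrated on the fish's true genotype."""
    try:
        alpha = np.asarray(config.dirichlet[true_genotype], dtype=float)
    except KeyError:
        raise ValueError(f"unknown genotype label {true_genotype!r}") from None
    if np.any(alpha <= 0):
        raise ValueError(f"dirichlet[{true_genotype}]: concentrations must be > 0")
    return rng.dirichlet(alpha)


# ---------------------------------------------------------------------------
# Whole-population assembly
# ---------------------------------------------------------------------------

def _draw_age(config: SynthConfig, rng: np.random.Generator) -> int:
    # adult, length-stratified sampling: mid ages common, extremes rare
    span = config.age_max - config.age_min
    return int(config.age_min + rng.binomial(span, 0.4)) if span else config.age_min


def _capture(phenotype: str, config: SynthConfig, rng: np.random.Generator):
    c = config
    if phenotype == "BRACKISH_RESIDENT":
        loc = rng.choice(LAGOONS, p=[0.4, 0.4, 0.2])
        return loc, "lagoon", "non_spawning"
    if phenotype == "FW_RESIDENT":
        loc = rng.choice(TRIBUTARIES, p=[0.35, 0.35, 0.15, 0.15])
        season = "non_spawning" if rng.random() < c.fw_nonspawning_frac else "spawning"
        return loc, "tributary", season
    lagoon_frac = (c.anadromous_lagoon_frac if phenotype == "ANADROMOUS"
                   else c.cross_lagoon_frac)
    if rng.random() < lagoon_frac:
        loc = rng.choice(LAGOONS, p=[0.3, 0.3, 0.4])
        return loc, "lagoon", "non_spawning"
    loc = rng.choice(TRIBUTARIES, p=[0.25, 0.35, 0.15, 0.25])
    return loc, "tributary", "spawning"


def simulate_population(config: SynthConfig) -> SyntheticDataset:
    """Generate a complete, mutually consistent synthetic study.

    Transects, metadata, annual growth records (with covariates taken from
    the transects' own annual means), radius-at-age observations, ancestry
    vectors and the truth table all share one fish id set and one seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    c = config

    fish_rows, truth_rows = [], []
    transects: dict[str, Transect] = {}
    q_rows = []
    idx = 0
    for phe, n in zip(PHENOTYPES, c.n_fish):
        mu = c.vb_means[phe]
        tau = c.vb_precisions
        geno_dist = dict(c.genotype_mix[phe])
        geno_labels = list(geno_dist)
        geno_p = np.array([geno_dist[g] for g in geno_labels], dtype=float)
        geno_p = geno_p / geno_p.sum()
        for _ in range(int(n)):
            idx += 1
            fid = f"F{idx:04d}"
            age = _draw_age(c, rng)
            sex = "F" if rng.random() < c.female_frac else "M"
            # individual growth-curve parameters from the gamma group model
            rinf = rng.gamma(mu[0] ** 2 * tau[0], 1.0 / (mu[0] * tau[0]))
            kk = rng.gamma(mu[1] ** 2 * tau[1], 1.0 / (mu[1] * tau[1]))
            s0 = rng.gamma(mu[2] ** 2 * tau[2], 1.0 / (mu[2] * tau[2]))
            geno = geno_labels[rng.choice(len(geno_labels), p=geno_p)]
            loc, habitat, season = _capture(phe, c, rng)
            transects[fid] = simulate_transect(
                phe, age, c, rng, vb_params=(rinf, kk, s0), fish_id=fid
            )
            length = 400.0 + 500.0 * (1.0 - np.exp(-0.25 * age)) + rng.normal(0, 30)
            fish_rows.append({
                "fish_id": fid, "sex": sex, "age": age,
                "total_length_mm": round(float(length), 1),
                "capture_location": str(loc), "capture_habitat": habitat,
                "capture_season": season,
            })
            truth_rows.append({
                "fish_id": fid, "true_phenotype": phe, "true_genotype": geno,
                "R_inf": rinf, "k": kk, "t0": -s0,
                "age": age, "sex": sex, "phenotype": phe,
            })
            q_rows.append([fid] + list(simulate_q_vector(geno, c, rng)))

    fish = pd.DataFrame(fish_rows)
    truth_full = pd.DataFrame(truth_rows)

    # thermosaline covariates from the transects themselves
    paired = {fid: transect_io.pair_channels(t) for fid, t in transects.items()}
    corrected, _ = transect_io.correct_temperature_proxy(paired)
    ann = transect_io.annual_means_table(corrected)
    covariates = ann.rename(columns={
        "annulus": "lifeyear",
        "d18o_res_mean": "annual_d18o_res",
        "sr_ca_z": "annual_srca_z",
    })[["fish_id", "lifeyear", "annual_d18o_res", "annual_srca_z"]]

    growth = simulate_increments(truth_full, c, rng, covariates=covariates)
    radii = simulate_radii(truth_full, c, rng)
    qmatrix = pd.DataFrame(q_rows, columns=["fish_id", "q1", "q2", "q3", "q4"])
    truth = truth_full[["fish_id", "true_phenotype", "true_genotype",
                        "R_inf", "k", "t0"]].copy()
    return SyntheticDataset(fish, transects, growth, radii, qmatrix, truth, c)
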