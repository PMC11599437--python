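"""End-to-end orchestration: config, stages, artifacts, manifest.

The pipeline runs the analysis in the order the data dictate: read and
preprocess transects, cluster lifelong chemistry per capture pool, collapse
clusters into behavioral phenotypes, validate them by jackknife, model
age-specific (mixed model) and lifelong (hierarchical von Bertalanffy)
growth, match phenotypes with genotype assignment probabilities, and emit
the ecotype partition.  Every stage writes plain CSV/JSON artifacts and the
run ends with a machine-readable manifest whose hash is reproducible for a
fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import dtw_core, genetics, growthmod, phenotyper, synthgen, transect_io

__all__ = ["PipelineConfig", "ConfigError", "StageError", "validate_config",
           "run_pipeline", "simulate_inputs", "STAGES"]

log = logging.getLogger("esoxtrace")

STAGES = ("read", "cluster", "phenotype", "jackknife", "growth_lmm",
          "growth_vb", "genetics")

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "stages": list(STAGES),
    "paths": {
        "transects": "transects.csv",
        "fish": "fish.csv",
        "increments": "increments.csv",
        "radii": "radii.csv",
        "qmatrix": "qmatrix.csv",
        "output_dir": "esoxtrace_out",
    },
    "thresholds": {
        "fw": 1.0,
        "brackish": 2.0,
        "excursion": 1.5,
        "min_run": 1,
        "tau": 0.7,
        "fdr_alpha": 0.05,
    },
    "dtw": {"window_frac": 0.05, "k_min": 2, "k_max": 10,
            "per_capture_pool": True},
    "mcmc": {"chains": 2, "draws": 500, "warmup": 1000, "thin": 5},
    "permutations": 9999,
    "simulate": {"n_fish": [20, 20, 20, 20]},
}


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are preserved."""


@dataclass
class PipelineConfig:
    seed: int
    stages: list[str]
    paths: dict[str, str]
    thresholds: dict[str, float]
    dtw: dict[str, Any]
    mcmc: dict[str, int]
    permutations: int
    simulate: dict[str, Any]

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed fan-out from the global seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in user:
            uval = user[key]
            if isinstance(dval, dict):
                if not isinstance(uval, dict):
                    raise ConfigError(f"{path}{key}: expected a mapping")
                out[key] = _merge(dval, uval, f"{path}{key}.")
            else:
                out[key] = uval
        else:
            out[key] = dval
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown key(s): {sorted(path + k for k in unknown)}")
    return out


def validate_config(source: str | Path | dict | None = None) -> PipelineConfig:
    """Load a TOML/YAML config file, fill defaults, reject unknown keys.

    Defaults follow the analysis conventions: a 5% DTW window, k tested
    over 2-10, a 0.7 genotype assignment threshold and 9999 permutations.
    An empty file (or ``None``) yields the pure-default config.
    """
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        p = Path(source)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        text = p.read_text()
        if p.suffix in (".toml", ".tml"):
            user = tomllib.loads(text)
        else:
            user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{p}: top level must be a mapping")
    merged = _merge(_DEFAULTS, user)

    thr = merged["thresholds"]
    if not 0.5 < thr["tau"] <= 1:
        raise ConfigError("thresholds.tau: must be in (0.5, 1]")
    if not 0 < thr["fdr_alpha"] < 1:
        raise ConfigError("thresholds.fdr_alpha: must be in (0, 1)")
    if thr["fw"] >= thr["brackish"]:
        raise ConfigError("thresholds.fw: must be below thresholds.brackish")
    if not 0 < merged["dtw"]["window_frac"] <= 1:
        raise ConfigError("dtw.window_frac: must be in (0, 1]")
    if not 2 <= merged["dtw"]["k_min"] <= merged["dtw"]["k_max"]:
        raise ConfigError("dtw.k_min/k_max: need 2 <= k_min <= k_max")
    if merged["permutations"] < 1:
        raise ConfigError("permutations: must be >= 1")
    for key in ("chains", "draws", "warmup", "thin"):
        if merged["mcmc"][key] < 1:
            raise ConfigError(f"mcmc.{key}: must be >= 1")
    bad = [s for s in merged["stages"] if s not in STAGES]
    if bad:
        raise ConfigError(f"stages: unknown stage(s) {bad}")
    return PipelineConfig(
        seed=int(merged["seed"]),
        stages=list(merged["stages"]),
        paths={k: str(v) for k, v in merged["paths"].items()},
        thresholds=dict(thr),
        dtw=dict(merged["dtw"]),
        mcmc={k: int(v) for k, v in merged["mcmc"].items()},
        permutations=int(merged["permutations"]),
        simulate=dict(merged["simulate"]),
    )


def simulate_inputs(config: PipelineConfig, indir: str | Path) -> Path:
    """Write a complete synthetic input set for the configured seed."""
    indir = Path(indir)
    sc = synthgen.SynthConfig(
        n_fish=tuple(int(n) for n in config.simulate["n_fish"]),
        seed=config.stage_seed("simulate"),
    )
    ds = synthgen.simulate_population(sc)
    ds.write(indir)
    log.info("simulate: wrote %d fish to %s", len(ds.fish), indir)
    return indir


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, indir: str | Path | None = None) -> dict:
    """Execute the enabled stages; return the run manifest.

    Input CSVs are resolved against ``indir`` (or the configured paths as
    given).  A stage failure raises :class:`StageError` naming the stage;
    artifacts written so far stay on disk.
    """
    outdir = Path(config.paths["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    def respath(key: str) -> Path:
        p = Path(config.paths[key])
        return (Path(indir) / p) if (indir is not None and not p.is_absolute()) else p

    artifacts: dict[str, str] = {}
    counts: dict[str, Any] = {}
    state: dict[str, Any] = {}

    def save_df(name: str, df: pd.DataFrame) -> None:
        p = outdir / name
        df.to_csv(p, index=False)
        artifacts[name] = _sha256(p)

    def save_json(name: str, obj: Any) -> None:
        p = outdir / name
        p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        artifacts[name] = _sha256(p)

    enabled = [s for s in STAGES if s in config.stages]
    stage = "read"
    try:
        # ---- read + preprocess (always required) -------------------------
        transects = transect_io.read_transects(respath("transects"))
        fish = transect_io.read_fish_records(respath("fish"))
        paired = {f: transect_io.pair_channels(t) for f, t in transects.items()}
        corrected, (b0, b1) = transect_io.correct_temperature_proxy(paired)
        annual = transect_io.annual_means_table(corrected)
        stages_feats = transect_io.stage_features_table(annual)
        counts["read"] = {"fish": len(fish), "transect_points":
                          int(sum(len(t.points) for t in transects.values()))}
        save_df("annual_means.csv", annual)
        save_json("salinity_correction.json", {"intercept": b0, "slope": b1})
        state.update(fish=fish, corrected=corrected, annual=annual,
                     features=stages_feats)
        log.info("read: %d fish in, %d fish-years out", len(fish), len(annual))

        # ---- clustering per capture pool ---------------------------------
        cluster_labels: dict[str, int] = {}
        if "cluster" in enabled:
            stage = "cluster"
            offset = 0
            pools = (fish.groupby("capture_habitat")["fish_id"].apply(list).to_dict()
                     if config.dtw["per_capture_pool"]
                     else {"all": fish["fish_id"].tolist()})
            k_by_pool = {}
            for pool, ids in sorted(pools.items()):
                series = dtw_core.build_multiseries(
                    [corrected[f] for f in ids if f in corrected])
                dmat = dtw_core.distance_matrix(series, config.dtw["window_frac"])
                k_best, report = dtw_core.select_k(
                    None, config.dtw["k_min"], config.dtw["k_max"],
                    dmat=dmat)
                labels = dtw_core.ward_cluster(dmat, k_best)
                for fid, lab in zip(dmat.ids, labels):
                    cluster_labels[fid] = int(lab) + offset
                offset += int(labels.max())
                k_by_pool[pool] = k_best
                dmat.to_frame().to_csv(outdir / f"distances_{pool}.csv")
                artifacts[f"distances_{pool}.csv"] = _sha256(
                    outdir / f"distances_{pool}.csv")
                save_df(f"cvi_{pool}.csv", report.values.reset_index())
                log.info("cluster[%s]: n=%d, k=%d votes=%s", pool,
                         len(ids), k_best, report.votes)
            counts["cluster"] = {"k_by_pool": k_by_pool}

        # ---- phenotypes ---------------------------------------------------
        stage = "phenotype"
        thr = phenotyper.Thresholds(
            fw=config.thresholds["fw"], brackish=config.thresholds["brackish"],
            excursion=config.thresholds["excursion"],
            min_run=int(config.thresholds["min_run"]))
        calls = phenotyper.assign_phenotypes(
            annual, fish, thr, cluster_labels or None)
        calls_df = phenotyper.calls_to_frame(calls)
        save_df("phenotypes.csv", calls_df)
        freq = phenotyper.phenotype_frequency_report(calls, fish)
        save_df("frequency_counts.csv", freq["counts"].reset_index())
        save_json("frequency_test.json", {
            "test": freq["test"], "excluded_fish": freq["excluded_fish"],
            "untestable_reason": freq["untestable_reason"]})
        counts["phenotype"] = calls_df["phenotype"].value_counts().to_dict()
        state["calls_df"] = calls_df
        log.info("phenotype: %s", counts["phenotype"])

        # ---- jackknife validation -----------------------------------------
        if "jackknife" in enabled:
            stage = "jackknife"
            labels = calls_df.set_index("fish_id")["phenotype"]
            labels = labels[labels != "UNCLASSIFIED"]
            rate, conf = phenotyper.jackknife_lda(stages_feats, labels)
            conf.to_frame().to_csv(outdir / "confusion_matrix.csv")
            artifacts["confusion_matrix.csv"] = _sha256(
                outdir / "confusion_matrix.csv")
            save_json("jackknife.json", {"correct_rate": rate,
                                         "recall": conf.recall})
            counts["jackknife"] = {"correct_rate": rate}
            log.info("jackknife: %.1f%% correct", 100 * rate)

        # ---- growth: mixed model ------------------------------------------
        if "growth_lmm" in enabled:
            stage = "growth_lmm"
            growth = pd.read_csv(respath("increments"), dtype={"fish_id": str})
            merged = growth.drop(columns=["phenotype"], errors="ignore").merge(
                calls_df[["fish_id", "phenotype"]], on="fish_id")
            merged = merged[merged["phenotype"] != "UNCLASSIFIED"]
            fit = growthmod.fit_increment_lmm(merged)
            llr = growthmod.llr_term_tests(
                merged, test_terms=["age2", "d18o", "sr", "sex", "age_phenotype"])
            save_json("lmm_summary.json", {
                "params": fit.params.to_dict(),
                "bse": fit.bse.to_dict(),
                "random_intercept_var": fit.random_intercept_var,
                "residual_var": fit.residual_var,
                "r2_marginal": fit.r2_marginal,
                "r2_conditional": fit.r2_conditional,
            })
            save_df("llr_tests.csv", llr)
            counts["growth_lmm"] = {"records": len(merged),
                                    "r2_marginal": fit.r2_marginal}
            state["lmm"] = fit
            log.info("growth_lmm: %d records, marginal R2=%.3f",
                     len(merged), fit.r2_marginal)

        # ---- genetics ------------------------------------------------------
        pairwise = None
        eco = None
        if "genetics" in enabled:
            stage = "genetics"
            qm = genetics.read_q_matrix(respath("qmatrix"))
            qdf = qm.to_frame().merge(
                calls_df[["fish_id", "phenotype"]], on="fish_id")
            qdf = qdf[qdf["phenotype"] != "UNCLASSIFIED"]
            keep = qdf["phenotype"].map(qdf["phenotype"].value_counts()) >= 2
            qdf = qdf[keep]
            Y = qdf[qm.cluster_labels].to_numpy(float)
            omni = genetics.permanova(Y, qdf["phenotype"],
                                      n_perm=config.permutations,
                                      seed=config.stage_seed("genetics"))
            pairwise = genetics.pairwise_permanova(
                Y, qdf["phenotype"], n_perm=config.permutations,
                seed=config.stage_seed("genetics_pairwise"),
                fdr_alpha=config.thresholds["fdr_alpha"])
            eco = genetics.infer_ecotypes(
                pairwise, sorted(qdf["phenotype"].unique()),
                alpha=config.thresholds["fdr_alpha"])
            assign = genetics.threshold_assign(
                qm, tau=config.thresholds["tau"],
                genotype_names=list(synthgen.GENOTYPES))
            loc = fish.set_index("fish_id")["capture_location"]
            try:
                gl_stat, gl_df, gl_p = genetics.genotype_location_test(
                    assign, loc.reindex(assign.index))
                gl = {"statistic": gl_stat, "df": gl_df, "p": gl_p}
            except ValueError as e:
                gl = {"untestable": str(e)}
            save_df("pairwise_permanova.csv", pairwise)
            save_json("genetics.json", {
                "permanova": {"pseudo_f": omni.pseudo_f, "r2": omni.r2,
                              "p": omni.p, "n_perm": omni.n_perm,
                              "n": omni.n},
                "ecotypes": {"mapping": eco.mapping,
                             "n_ecotypes": eco.n_ecotypes,
                             "alpha": eco.alpha,
                             "provenance": eco.provenance},
                "genotype_location_test": gl,
                "n_unassigned": int((assign == genetics.UNASSIGNED).sum()),
            })
            assign.rename_axis("fish_id").reset_index().to_csv(
                outdir / "genotypes.csv", index=False)
            artifacts["genotypes.csv"] = _sha256(outdir / "genotypes.csv")
            counts["genetics"] = {"pseudo_f": omni.pseudo_f, "r2": omni.r2,
                                  "p": omni.p, "n_ecotypes": eco.n_ecotypes}
            state["assign"] = assign
            log.info("genetics: F=%.2f R2=%.3f p=%.4g -> %d ecotypes",
                     omni.pseudo_f, omni.r2, omni.p, eco.n_ecotypes)

        # ---- growth: hierarchical von Bertalanffy ---------------------------
        if "growth_vb" in enabled:
            stage = "growth_vb"
            radii = pd.read_csv(respath("radii"), dtype={"fish_id": str})
            nobs = radii.groupby("fish_id").size()
            radii = radii[radii["fish_id"].map(nobs) >= 2]
            groupings: dict[str, pd.Series] = {
                "phenotype": calls_df.set_index("fish_id")["phenotype"],
            }
            if "genetics" in enabled and eco is not None:
                groupings["genotype"] = state["assign"]
                groupings["ecotype"] = (
                    calls_df.set_index("fish_id")["phenotype"]
                    .map(lambda p: f"ECO{eco.mapping.get(p, -1)}"))
            vb_summary = {}
            for name, grp in groupings.items():
                grp = grp[~grp.isin(["UNCLASSIFIED", genetics.UNASSIGNED,
                                     "ECO-1"])]
                sub = radii[radii["fish_id"].isin(grp.index)]
                sizes = grp.reindex(sub["fish_id"].unique()).value_counts()
                ok_groups = sizes[sizes >= 2].index
                sub = sub[sub["fish_id"].map(grp).isin(ok_groups)]
                if sub["fish_id"].nunique() < 4 or len(ok_groups) < 2:
                    log.warning("growth_vb[%s]: too few fish/groups, skipped",
                                name)
                    continue
                mc = growthmod.MCMCConfig(
                    chains=config.mcmc["chains"], draws=config.mcmc["draws"],
                    warmup=config.mcmc["warmup"], thin=config.mcmc["thin"],
                    seed=config.stage_seed(f"vb_{name}"))
                post = growthmod.fit_vb_hierarchical(sub, grp.to_dict(),
                                                     grouping=name, mcmc=mc)
                diff = growthmod.group_differences(post)
                save_df(f"vb_differences_{name}.csv", diff)
                draws_rows = []
                for pname, arr in post.draws.items():
                    for c in range(arr.shape[0]):
                        draws_rows.append(pd.DataFrame({
                            "chain": c, "iter": np.arange(arr.shape[1]),
                            "parameter": pname, "value": arr[c]}))
                save_df(f"vb_draws_{name}.csv",
                        pd.concat(draws_rows, ignore_index=True))
                vb_summary[name] = {
                    "groups": post.groups,
                    "converged": bool(post.converged),
                    "max_rhat": float(max(post.rhat.values())),
                    "min_ess": float(min(post.ess.values())),
                    "any_difference": bool(diff["different"].any()),
                }
                log.info("growth_vb[%s]: converged=%s groups=%s", name,
                         post.converged, post.groups)
            save_json("vb_summary.json", vb_summary)
            counts["growth_vb"] = {k: v["converged"] for k, v in vb_summary.items()}

    except (ValueError, KeyError, RuntimeError, OSError) as e:
        if isinstance(e, StageError):
            raise
        raise StageError(f"stage {stage!r} failed: {e}") from e

    # the manifest describes the computation, not where it was written, so
    # filesystem locations are excluded to keep the hash location-invariant
    config_dict = config.as_dict()
    config_dict["paths"] = {k: v for k, v in config_dict["paths"].items()
                            if k != "output_dir"}
    manifest = {
        "package": "esoxtrace",
        "config": config_dict,
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in enabled},
        "counts": counts,
        "artifacts": artifacts,
    }
    canon = json.dumps(manifest, sort_keys=True, default=str)
    manifest["manifest_hash"] = hashlib.sha256(canon.encode()).hexdigest()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
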