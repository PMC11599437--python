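"""Age-specific and lifelong growth models.

Two complementary views of pike growth are fitted to otolith material, so
no body-length back-calculation is needed:

* age-specific growth: a linear mixed model of log10 annual increment
  widths on age (linear + quadratic), sex, the annual thermal proxy (d18O
  residual), the annual salinity proxy (z-scored Sr:Ca) and an
  age x phenotype interaction, with a per-fish random intercept (REML for
  estimation, ML refits for likelihood-ratio term tests);

* lifelong growth: a hierarchical Bayesian von Bertalanffy model of radius
  at age, R(t) = R_inf * (1 - exp(-k * (t - t0))), with individual
  parameters drawn from gamma group distributions parameterised by mean and
  precision.  Because estimated t0 values are negative while the gamma has
  positive support, s0 = -t0 is the gamma-distributed quantity.  Group
  differences are read from non-overlap of 95% credible intervals.

The posterior is sampled with an adaptive Metropolis-within-Gibbs scheme:
per-fish parameter blocks are proposed jointly on the log scale and
accepted fish-wise (vectorised across fish), group-level means/precisions
and the observation noise get scalar log-scale random-walk updates, and all
proposal scales adapt toward standard acceptance targets during warmup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import optimize, stats

__all__ = [
    "MixedFit",
    "MCMCConfig",
    "VBPosterior",
    "fit_increment_lmm",
    "llr_term_tests",
    "nakagawa_r2",
    "vb_radius",
    "fit_vb_hierarchical",
    "group_differences",
]

# term name -> formula fragment of the increment model
LMM_TERMS: dict[str, str] = {
    "age": "age",
    "age2": "I(age**2)",
    "d18o": "annual_d18o_res",
    "sr": "annual_srca_z",
    "sex": "C(sex, Treatment('F'))",
    "phenotype": "C(phenotype, Treatment('ANADROMOUS'))",
    "age_phenotype": "age:C(phenotype, Treatment('ANADROMOUS'))",
}


@dataclass
class MixedFit:
    """REML mixed-model fit with the ML twin kept for LLR testing."""

    params: pd.Series
    bse: pd.Series
    random_intercept_var: float
    residual_var: float
    llf_reml: float
    llf_ml: float
    r2_marginal: float
    r2_conditional: float
    terms: list[str]
    formula: str
    result: object = field(repr=False)     # statsmodels REML results
    result_ml: object = field(repr=False)  # statsmodels ML results
    data: pd.DataFrame = field(repr=False)


def _build_formula(terms: Sequence[str]) -> str:
    rhs = " + ".join(LMM_TERMS[t] for t in terms) if terms else "1"
    return f"log10_increment ~ {rhs}"


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    if (df["increment_um"] <= 0).any():
        raise ValueError("increment widths must be > 0")
    df["log10_increment"] = np.log10(df["increment_um"])
    df["age"] = df["lifeyear"].astype(float)
    return df


def fit_increment_lmm(
    records: pd.DataFrame,
    terms: Sequence[str] | None = None,
) -> MixedFit:
    """Fit the log10-increment mixed model with a per-fish random intercept.

    ``records`` needs columns fish_id, lifeyear, increment_um,
    annual_d18o_res, annual_srca_z, sex, phenotype.  Treatment contrasts use
    the anadromous phenotype and females as references.  Raises a named
    error for non-identifiable designs (e.g. a single phenotype level while
    phenotype terms are requested).
    """
    terms = list(terms) if terms is not None else list(LMM_TERMS)
    df = _prepare(records)
    per_fish = df.groupby("fish_id").size()
    if (per_fish >= 2).sum() < 2:
        raise ValueError("need >= 2 fish with >= 2 annual records each")
    for t in terms:
        if t in ("phenotype", "age_phenotype") and df["phenotype"].nunique() < 2:
            raise ValueError(f"term {t!r} not identifiable: phenotype is constant")
        if t == "sex" and df["sex"].nunique() < 2:
            raise ValueError("term 'sex' not identifiable: sex is constant")
    formula = _build_formula(terms)
    reml = smf.mixedlm(formula, df, groups=df["fish_id"]).fit(reml=True)
    ml = smf.mixedlm(formula, df, groups=df["fish_id"]).fit(reml=False)
    var_u = float(reml.cov_re.iloc[0, 0])
    var_e = float(reml.scale)
    fe = reml.fe_params
    fit = MixedFit(
        params=fe,
        bse=reml.bse.loc[fe.index],
        random_intercept_var=var_u,
        residual_var=var_e,
        llf_reml=float(reml.llf),
        llf_ml=float(ml.llf),
        r2_marginal=float("nan"),
        r2_conditional=float("nan"),
        terms=terms,
        formula=formula,
        result=reml,
        result_ml=ml,
        data=df,
    )
    fit.r2_marginal, fit.r2_conditional = nakagawa_r2(fit)
    return fit


def llr_term_tests(
    records: pd.DataFrame,
    terms: Sequence[str] | None = None,
    test_terms: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test for each model term, ML fits, chi2 upper tail.

    Marginality is respected: dropping ``age`` or ``phenotype`` while the
    age x phenotype interaction is in the model removes the interaction as
    well, so the interaction is always dropped before its marginal terms.
    """
    terms = list(terms) if terms is not None else list(LMM_TERMS)
    test_terms = list(test_terms) if test_terms is not None else list(terms)
    df = _prepare(records)
    full = smf.mixedlm(_build_formula(terms), df, groups=df["fish_id"]).fit(reml=False)
    k_full = len(full.fe_params)
    rows = []
    for t in test_terms:
        if t not in terms:
            raise ValueError(f"term {t!r} not in the fitted model")
        drop = {t}
        if t in ("age", "phenotype") and "age_phenotype" in terms:
            drop.add("age_phenotype")
        reduced_terms = [x for x in terms if x not in drop]
        red = smf.mixedlm(_build_formula(reduced_terms), df,
                          groups=df["fish_id"]).fit(reml=False)
        llr = 2.0 * (full.llf - red.llf)
        dof = k_full - len(red.fe_params)
        p = float(stats.chi2.sf(max(llr, 0.0), dof)) if dof > 0 else 1.0
        rows.append({"term": t, "llr": float(max(llr, 0.0)), "df": dof, "p": p,
                     "dropped_with": sorted(drop - {t})})
    return pd.DataFrame(rows)


def nakagawa_r2(fit: MixedFit) -> tuple[float, float]:
    """Marginal and conditional R^2 for the random-intercept model.

    marginal = var(fixed predictor) / (var(fixed) + var(ID) + var(resid));
    conditional adds the random-intercept variance to the numerator.
    """
    X = fit.result.model.exog
    eta = X @ fit.params.to_numpy()
    var_f = float(np.var(eta, ddof=1))
    denom = var_f + fit.random_intercept_var + fit.residual_var
    if denom == 0:
        return 1.0, 1.0
    return var_f / denom, (var_f + fit.random_intercept_var) / denom


# ---------------------------------------------------------------------------
# von Bertalanffy growth
# ---------------------------------------------------------------------------

def vb_radius(t, r_inf, k, t0):
    """von Bertalanffy radius at age: R(t) = R_inf (1 - exp(-k (t - t0)))."""
    if np.any(np.asarray(r_inf) <= 0) or np.any(np.asarray(k) <= 0):
        raise ValueError("R_inf and k must be > 0")
    return r_inf * (1.0 - np.exp(-k * (np.asarray(t, dtype=float) - t0)))


@dataclass
class MCMCConfig:
    chains: int = 4
    draws: int = 2000
    warmup: int = 2000
    seed: int = 0
    thin: int = 10
    rhat_limit: float = 1.01
    ess_limit: float = 400.0


@dataclass
class VBPosterior:
    """Group-level posterior draws and diagnostics.

    ``draws`` maps names like ``mu_r_inf[GROUP]``, ``tau_k[GROUP]``,
    ``sigma_obs`` to (chains, draws) arrays; ``mu_t0`` draws are reported as
    the negative of the gamma-distributed s0 group mean.  ``individual``
    summarises per-fish posterior medians.
    """

    groups: list[str]
    grouping: str
    draws: dict[str, np.ndarray]
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    individual: pd.DataFrame
    accept_rates: dict[str, float]

    def group_interval(self, param: str, group: str, prob: float = 0.95):
        x = self.draws[f"mu_{param}[{group}]"].ravel()
        lo, hi = np.quantile(x, [(1 - prob) / 2, 1 - (1 - prob) / 2])
        return float(lo), float(hi), float(np.median(x))


_PARAMS = ("r_inf", "k", "s0")


def _gamma_logpdf(x, mu, tau):
    # gamma with mean mu, precision tau: shape = mu^2 tau, rate = mu tau
    from scipy.special import gammaln
    shape = mu * mu * tau
    rate = mu * tau
    return shape * np.log(rate) + (shape - 1.0) * np.log(x) - rate * x - gammaln(shape)


def _pooled_start(ages: np.ndarray, radii: np.ndarray) -> tuple[float, float, float]:
    """One VB curve through all points; centers hyperpriors and chains."""
    r_max = float(radii.max())

    def f(t, r_inf, k, s0):
        return r_inf * (1.0 - np.exp(-k * (t + s0)))

    try:
        popt, _ = optimize.curve_fit(
            f, ages, radii, p0=(1.2 * r_max, 0.2, 0.7),
            bounds=([1e-3, 1e-4, 1e-3], [100 * r_max, 10.0, 50.0]),
            maxfev=20000,
        )
        return float(popt[0]), float(popt[1]), float(popt[2])
    except RuntimeError:
        return 1.2 * r_max, 0.2, 0.7


def fit_vb_hierarchical(
    radii: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    grouping: str = "phenotype",
    mcmc: MCMCConfig | None = None,
) -> VBPosterior:
    """Hierarchical Bayesian fit of radius-at-age growth curves.

    ``radii`` has columns fish_id, age, radius (one row per observation,
    every fish needs >= 2); ``groups`` maps fish ids to group labels.
    Radii are nested within individuals and individuals within groups:
    individual (R_inf, k, s0 = -t0) are gamma with group-specific mean mu
    and precision tau (shape = mu^2 tau, rate = mu tau); observation error
    on radius is Gaussian with a half-normal prior on its sd; group means
    get weakly-informative gammas centered on a pooled single-curve fit and
    precisions get half-normal priors.  Non-convergence (R-hat or bulk ESS
    beyond their limits on any group-level quantity) flags the result but
    never hides it.
    """
    mcmc = mcmc or MCMCConfig()
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()

    fish_ids = list(dict.fromkeys(radii["fish_id"].astype(str)))
    n_fish = len(fish_ids)
    counts = radii.groupby("fish_id").size()
    bad = counts[counts < 2]
    if len(bad):
        raise ValueError(f"fish with < 2 radius observations: {list(bad.index)[:5]}")
    missing = [f for f in fish_ids if f not in groups]
    if missing:
        raise ValueError(f"no group for fish {missing[:5]}")
    group_names = sorted(set(groups[f] for f in fish_ids))
    g_index = {g: i for i, g in enumerate(group_names)}
    fish_group = np.array([g_index[groups[f]] for f in fish_ids])

    max_obs = int(counts.max())
    age_mat = np.zeros((n_fish, max_obs))
    rad_mat = np.zeros((n_fish, max_obs))
    mask = np.zeros((n_fish, max_obs), dtype=bool)
    for i, f in enumerate(fish_ids):
        sub = radii[radii["fish_id"].astype(str) == f]
        m = len(sub)
        age_mat[i, :m] = sub["age"].to_numpy(float)
        rad_mat[i, :m] = sub["radius"].to_numpy(float)
        mask[i, :m] = True
    n_obs_fish = mask.sum(axis=1)

    r0, k0, s00 = _pooled_start(radii["age"].to_numpy(float),
                                radii["radius"].to_numpy(float))
    centers = np.array([r0, k0, s00])
    sigma_scale = 0.1 * float(np.ptp(rad_mat[mask])) or 0.1
    # half-normal scales for the group precisions: individual CVs much
    # below ~5% are implausible, which keeps these weakly-identified
    # precisions from wandering off toward degenerate tight groups
    tau_scale = 1.0 / (0.05 * centers) ** 2
    hyper_alpha = 2.0  # shape of the weak gamma on group means

    def loglik_fish(theta, log_sigma):
        # theta: (n_fish, 3) on log scale
        r_inf = np.exp(theta[:, 0])[:, None]
        kk = np.exp(theta[:, 1])[:, None]
        s0 = np.exp(theta[:, 2])[:, None]
        mu = r_inf * (1.0 - np.exp(-kk * (age_mat + s0)))
        sig = np.exp(log_sigma)
        ll = -0.5 * ((rad_mat - mu) / sig) ** 2
        return np.where(mask, ll, 0.0).sum(axis=1) - n_obs_fish * log_sigma

    def _loglik_rows(theta_rows, log_sigma, sel):
        # likelihood restricted to one group's fish
        r_inf = np.exp(theta_rows[:, 0])[:, None]
        kk = np.exp(theta_rows[:, 1])[:, None]
        s0 = np.exp(theta_rows[:, 2])[:, None]
        mu = r_inf * (1.0 - np.exp(-kk * (age_mat[sel] + s0)))
        sig = np.exp(log_sigma)
        ll = -0.5 * ((rad_mat[sel] - mu) / sig) ** 2
        return np.where(mask[sel], ll, 0.0).sum(axis=1) - n_obs_fish[sel] * log_sigma

    def logprior_fish(theta, mu_g, tau_g):
        # gamma prior per parameter + log-jacobian of the log transform
        lp = np.zeros(n_fish)
        for p in range(3):
            x = np.exp(theta[:, p])
            lp += _gamma_logpdf(x, mu_g[fish_group, p], tau_g[fish_group, p])
            lp += theta[:, p]
        return lp

    n_groups = len(group_names)
    keep = mcmc.draws
    store: dict[str, np.ndarray] = {}
    names = []
    for p in _PARAMS:
        for g in group_names:
            names += [f"mu_{p}[{g}]", f"tau_{p}[{g}]"]
    names.append("sigma_obs")
    for nm in names:
        store[nm] = np.empty((mcmc.chains, keep))
    indiv_acc = []
    acc_report: dict[str, float] = {}
    indiv_med = np.zeros((mcmc.chains, n_fish, 3))

    ss = np.random.SeedSequence(mcmc.seed)
    chain_seeds = ss.spawn(mcmc.chains)

    for c in range(mcmc.chains):
        rng = np.random.default_rng(chain_seeds[c])
        theta = np.log(np.tile(centers, (n_fish, 1))
                       * rng.uniform(0.9, 1.1, (n_fish, 3)))
        mu_g = np.tile(centers, (n_groups, 1)) * rng.uniform(0.9, 1.1, (n_groups, 3))
        tau_g = np.tile(1.0 / (0.15 * centers) ** 2, (n_groups, 1))
        log_sigma = float(np.log(sigma_scale * rng.uniform(0.5, 1.5)))

        step_f = np.full(n_fish, 0.05)
        step_g = np.full((n_groups, 3, 2), 0.1)  # [..., 0]=mu, [..., 1]=tau
        step_sp = np.full((n_groups, 3), 0.1)    # joint spread moves
        step_lc = np.full((n_groups, 3), 0.02)   # joint location moves
        step_s = 0.1

        ll_f = loglik_fish(theta, log_sigma)
        lp_f = logprior_fish(theta, mu_g, tau_g)
        acc_f_total = 0.0
        n_total = mcmc.warmup + keep * mcmc.thin

        # pooled proposal shape for the per-fish blocks: the three growth
        # parameters sit on a strong common ridge (R_inf trades off against
        # k and s0), so isotropic proposals mix poorly; during warmup we
        # estimate one shared covariance of the per-fish deviations and
        # freeze its Cholesky factor for the sampling phase
        prop_chol = np.eye(3)
        run_mean = theta.copy()
        run_m2 = np.zeros((3, 3))
        run_n = 0
        fish_sum = np.zeros((n_fish, 3))
        for it in range(n_total):
            adapt = it < mcmc.warmup
            gamma = 1.0 / (1.0 + it) ** 0.6

            # --- per-fish blocks, vectorised accept/reject
            z = rng.standard_normal((n_fish, 3)) @ prop_chol.T
            prop = theta + step_f[:, None] * z
            ll_p = loglik_fish(prop, log_sigma)
            lp_p = logprior_fish(prop, mu_g, tau_g)
            log_alpha = (ll_p + lp_p) - (ll_f + lp_f)
            accept = np.log(rng.random(n_fish)) < log_alpha
            theta[accept] = prop[accept]
            ll_f[accept] = ll_p[accept]
            lp_f[accept] = lp_p[accept]
            if adapt:
                step_f *= np.exp(gamma * (accept.astype(float) - 0.25))
                run_n += 1
                dev = theta - run_mean
                run_mean += dev / run_n
                run_m2 += (dev.T @ (theta - run_mean)) / n_fish
                if run_n >= 50 and run_n % 50 == 0:
                    cov = run_m2 / (run_n - 1) + 1e-8 * np.eye(3)
                    # normalise so step_f keeps its scalar meaning
                    cov /= np.exp(np.log(np.diag(cov)).mean())
                    try:
                        prop_chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass
            else:
                acc_f_total += accept.mean()

            # --- group-level means and precisions
            x_ind = np.exp(theta)
            for g in range(n_groups):
                sel = fish_group == g
                for p in range(3):
                    x = x_ind[sel, p]
                    # mean
                    cur = mu_g[g, p]
                    new = cur * np.exp(step_g[g, p, 0] * rng.standard_normal())
                    lo = (np.sum(_gamma_logpdf(x, new, tau_g[g, p]))
                          + (hyper_alpha - 1) * np.log(new)
                          - hyper_alpha / centers[p] * new + np.log(new))
                    lc = (np.sum(_gamma_logpdf(x, cur, tau_g[g, p]))
                          + (hyper_alpha - 1) * np.log(cur)
                          - hyper_alpha / centers[p] * cur + np.log(cur))
                    ok = np.log(rng.random()) < lo - lc
                    if ok:
                        mu_g[g, p] = new
                    if adapt:
                        step_g[g, p, 0] *= np.exp(gamma * (float(ok) - 0.44))
                    # precision
                    cur = tau_g[g, p]
                    new = cur * np.exp(step_g[g, p, 1] * rng.standard_normal())
                    lo = (np.sum(_gamma_logpdf(x, mu_g[g, p], new))
                          - 0.5 * (new / tau_scale[p]) ** 2 + np.log(new))
                    lc = (np.sum(_gamma_logpdf(x, mu_g[g, p], cur))
                          - 0.5 * (cur / tau_scale[p]) ** 2 + np.log(cur))
                    ok = np.log(rng.random()) < lo - lc
                    if ok:
                        tau_g[g, p] = new
                    if adapt:
                        step_g[g, p, 1] *= np.exp(gamma * (float(ok) - 0.44))

            # --- joint spread moves: rescale a group's individual values
            # about the group mean while compensating the group precision.
            # A plain random walk cannot traverse the funnel between "tight
            # group, prior-dominated individuals" and "loose group"; this
            # move travels along exactly that ridge.
            for g in range(n_groups):
                sel = fish_group == g
                n_g = int(sel.sum())
                for p in range(3):
                    x = np.exp(theta[sel, p])
                    log_c = step_sp[g, p] * rng.standard_normal()
                    scale_c = np.exp(log_c)
                    x_new = mu_g[g, p] + scale_c * (x - mu_g[g, p])
                    ok = False
                    if np.all(x_new > 0):
                        tau_new = tau_g[g, p] / (scale_c * scale_c)
                        theta_new = theta[sel].copy()
                        theta_new[:, p] = np.log(x_new)
                        ll_new = _loglik_rows(theta_new, log_sigma, sel)
                        ll_cur = ll_f[sel]
                        pr_new = (np.sum(_gamma_logpdf(x_new, mu_g[g, p], tau_new))
                                  - 0.5 * (tau_new / tau_scale[p]) ** 2)
                        pr_cur = (np.sum(_gamma_logpdf(x, mu_g[g, p], tau_g[g, p]))
                                  - 0.5 * (tau_g[g, p] / tau_scale[p]) ** 2)
                        # |J| of (theta, tau) -> (theta', tau/c^2) in log space
                        log_jac = (n_g - 2.0) * log_c + np.sum(
                            theta[sel, p] - theta_new[:, p])
                        log_alpha = (ll_new.sum() + pr_new) - (ll_cur.sum() + pr_cur) \
                            + log_jac
                        ok = np.log(rng.random()) < log_alpha
                        if ok:
                            theta[sel] = theta_new
                            tau_g[g, p] = tau_new
                            ll_f[sel] = ll_new
                    if adapt:
                        step_sp[g, p] *= np.exp(gamma * (float(ok) - 0.44))

                    # joint location move: scale the whole group and its
                    # mean together (the gamma shape is preserved exactly),
                    # so the group mean can track the likelihood directly.
                    # Enabled only once the observation noise has settled,
                    # otherwise early loose-noise sweeps can hop to a
                    # degenerate mode that later becomes inescapable.
                    if it < mcmc.warmup // 2:
                        continue
                    x = np.exp(theta[sel, p])
                    log_d = step_lc[g, p] * rng.standard_normal()
                    scale_d = np.exp(log_d)
                    mu_new = scale_d * mu_g[g, p]
                    tau_new = tau_g[g, p] / (scale_d * scale_d)
                    theta_new = theta[sel].copy()
                    theta_new[:, p] = theta[sel, p] + log_d
                    ll_new = _loglik_rows(theta_new, log_sigma, sel)
                    pr_new = (np.sum(_gamma_logpdf(scale_d * x, mu_new, tau_new))
                              + (hyper_alpha - 1) * np.log(mu_new)
                              - hyper_alpha / centers[p] * mu_new
                              - 0.5 * (tau_new / tau_scale[p]) ** 2)
                    pr_cur = (np.sum(_gamma_logpdf(x, mu_g[g, p], tau_g[g, p]))
                              + (hyper_alpha - 1) * np.log(mu_g[g, p])
                              - hyper_alpha / centers[p] * mu_g[g, p]
                              - 0.5 * (tau_g[g, p] / tau_scale[p]) ** 2)
                    # |J| of (theta, mu, tau) -> (theta + log d, d mu, tau/d^2)
                    log_alpha = (ll_new.sum() + pr_new) \
                        - (ll_f[sel].sum() + pr_cur) - log_d
                    ok = np.log(rng.random()) < log_alpha
                    if ok:
                        theta[sel] = theta_new
                        mu_g[g, p] = mu_new
                        tau_g[g, p] = tau_new
                        ll_f[sel] = ll_new
                    if adapt:
                        step_lc[g, p] *= np.exp(gamma * (float(ok) - 0.44))
            lp_f = logprior_fish(theta, mu_g, tau_g)

            # --- observation noise
            new_ls = log_sigma + step_s * rng.standard_normal()
            ll_new = loglik_fish(theta, new_ls)
            post_new = ll_new.sum() - 0.5 * (np.exp(new_ls) / sigma_scale) ** 2 + new_ls
            post_cur = ll_f.sum() - 0.5 * (np.exp(log_sigma) / sigma_scale) ** 2 + log_sigma
            ok = np.log(rng.random()) < post_new - post_cur
            if ok:
                log_sigma = new_ls
                ll_f = ll_new
            if adapt:
                step_s *= np.exp(gamma * (float(ok) - 0.44))

            if not adapt and (it - mcmc.warmup) % mcmc.thin == 0:
                j = (it - mcmc.warmup) // mcmc.thin
                for p_i, p in enumerate(_PARAMS):
                    for g, gname in enumerate(group_names):
                        store[f"mu_{p}[{gname}]"][c, j] = mu_g[g, p_i]
                        store[f"tau_{p}[{gname}]"][c, j] = tau_g[g, p_i]
                store["sigma_obs"][c, j] = np.exp(log_sigma)
                fish_sum += np.exp(theta)
        indiv_acc.append(acc_f_total / (keep * mcmc.thin))
        indiv_med[c] = fish_sum / keep

    acc_report["individual_blocks"] = float(np.mean(indiv_acc))

    idata = az.from_dict({k: v for k, v in store.items()})
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata, method="bulk")
    rhat = {k: float(rhat_ds[k].values) for k in store}
    ess = {k: float(ess_ds[k].values) for k in store}
    converged = all(r < mcmc.rhat_limit for r in rhat.values()) and \
        all(e > mcmc.ess_limit for e in ess.values())

    indiv = pd.DataFrame(indiv_med.mean(axis=0), columns=["r_inf", "k", "s0"])
    indiv.insert(0, "fish_id", fish_ids)
    indiv["t0"] = -indiv["s0"]
    indiv["group"] = [groups[f] for f in fish_ids]

    return VBPosterior(
        groups=group_names,
        grouping=grouping,
        draws=store,
        rhat=rhat,
        ess=ess,
        converged=converged,
        individual=indiv,
        accept_rates=acc_report,
    )


def group_differences(post: VBPosterior, prob: float = 0.95) -> pd.DataFrame:
    """Pairwise credible-interval overlap per growth parameter.

    Two groups count as different in a parameter iff their central
    ``prob`` credible intervals for the group mean are disjoint.  t0 rows
    are reported on the t0 scale (negated s0 draws).
    """
    if len(post.groups) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for p in ("r_inf", "k", "t0"):
        key = "s0" if p == "t0" else p
        ivals = {}
        for g in post.groups:
            x = post.draws[f"mu_{key}[{g}]"].ravel()
            if p == "t0":
                x = -x
            lo, hi = np.quantile(x, [(1 - prob) / 2, 1 - (1 - prob) / 2])
            ivals[g] = (float(lo), float(hi), float(np.median(x)))
        for i, a in enumerate(post.groups):
            for b in post.groups[i + 1:]:
                la, ha, ma = ivals[a]
                lb, hb, mb = ivals[b]
                overlap = not (ha < lb or hb < la)
                rows.append({
                    "parameter": p, "group_a": a, "group_b": b,
                    "median_a": ma, "lo_a": la, "hi_a": ha,
                    "median_b": mb, "lo_b": lb, "hi_b": hb,
                    "overlap": overlap, "different": not overlap,
                })
    return pd.DataFrame(rows)
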