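"""Derived physiological traits, mixed-model LSmeans, heritability and
trait-yield correlations.

Derived traits
--------------
* membrane thermostability MT = (1 - T1/T2) * 100 from the electrolyte
  leakage conductivities before (T1, after heat treatment) and after
  autoclaving (T2);
* accumulated growing degree days (AGDD), the cumulative clamped mean daily
  temperature above a base;
* rate of senescence RS, the slope of the linear NDVI decline over AGDD;
* stay-green SG, the predicted NDVI at physiological-maturity AGDD from the
  same fitted line.

Mixed models
------------
Genotype LSmeans come from a model with genotype fixed, block (and
optionally environment) random, and an optional days-to-heading covariate;
broad-sense heritability comes from the all-random model with
H^2 = sigma^2_G / (sigma^2_G + sigma^2_e).  Variance components are
estimated by REML (profiled likelihood over variance ratios, quasi-Newton
maximization), implemented here because the two models are small and their
structure is fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

PHYSIO_TRAITS = ["SPAD", "CT", "MT", "NDVI_1", "NDVI_2", "NDVI_3", "NDVI_4", "NDVI_5", "NDVI_6", "RS", "SG"]


class PhenotypeDataError(ValueError):
    pass


class RemlError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# derived traits
# ---------------------------------------------------------------------------


def membrane_thermostability(t1, t2):
    """MT percent from conductivity readings: (1 - t1/t2) * 100.

    ``t2`` (post-autoclave, total electrolytes) must be positive.  Values
    above 100 are impossible for t1 >= 0; negative values (t1 > t2) are
    allowed but indicate a data problem and trigger a warning.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if (t2 <= 0).any():
        raise PhenotypeDataError("t2 conductivity must be > 0")
    if (t1 < 0).any():
        raise PhenotypeDataError("t1 conductivity must be >= 0")
    mt = (1.0 - t1 / t2) * 100.0
    if (mt < 0).any():
        warnings.warn("negative MT values: T1 exceeds T2 for some plots", stacklevel=2)
    return mt if mt.ndim else float(mt)


def accumulate_gdd(daily_tmin, daily_tmax, t_base: float = 0.0) -> np.ndarray:
    """Cumulative growing degree days: sum of max(0, (tmax+tmin)/2 - t_base)."""
    tmin = np.asarray(daily_tmin, dtype=float)
    tmax = np.asarray(daily_tmax, dtype=float)
    if tmin.shape != tmax.shape:
        raise PhenotypeDataError("tmin and tmax series must align day-by-day")
    if (tmax < tmin).any():
        raise PhenotypeDataError("tmax below tmin")
    return np.cumsum(np.maximum(0.0, (tmax + tmin) / 2.0 - t_base))


def fit_ndvi_decay(ndvi, agdd) -> tuple[float, float]:
    """OLS line through the available (AGDD, NDVI) points.

    Returns (slope m, intercept b); the slope is the rate of senescence RS.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    agdd = np.asarray(agdd, dtype=float)
    ok = ~(np.isnan(ndvi) | np.isnan(agdd))
    if ok.sum() < 2:
        raise PhenotypeDataError("need at least 2 non-missing NDVI points")
    x, y = agdd[ok], ndvi[ok]
    vx = x.var()
    if vx == 0:
        raise PhenotypeDataError("AGDD stamps have zero variance")
    m = ((x - x.mean()) * (y - y.mean())).mean() / vx
    b = y.mean() - m * x.mean()
    return float(m), float(b)


def stay_green(m: float, b: float, agdd_pm: float, clip: bool = False) -> float:
    """Predicted NDVI at physiological maturity: SG = m * AGDD_PM + b."""
    sg = m * agdd_pm + b
    if clip:
        return float(np.clip(sg, 0.0, 1.0))
    if not 0.0 <= sg <= 1.0:
        warnings.warn(f"stay-green value {sg:.3f} outside [0, 1]", stacklevel=2)
    return float(sg)


def derive_traits(plots: pd.DataFrame) -> pd.DataFrame:
    """Add MT, RS and SG columns computed per plot from the raw columns."""
    df = plots.copy()
    if "T1" in df.columns and "T2" in df.columns:
        ok = df["T1"].notna() & df["T2"].notna()
        mt = np.full(len(df), np.nan)
        if ok.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mt[ok.to_numpy()] = membrane_thermostability(
                    df.loc[ok, "T1"].to_numpy(), df.loc[ok, "T2"].to_numpy()
                )
        df["MT"] = mt
    ndvi_cols = [f"NDVI_{t}" for t in range(1, 7)]
    agdd_cols = [f"AGDD_{t}" for t in range(1, 7)]
    if all(c in df.columns for c in ndvi_cols + agdd_cols):
        rs = np.full(len(df), np.nan)
        sg = np.full(len(df), np.nan)
        N = df[ndvi_cols].to_numpy(float)
        A = df[agdd_cols].to_numpy(float)
        pm = df["AGDD_PM"].to_numpy(float) if "AGDD_PM" in df.columns else np.full(len(df), np.nan)
        for i in range(len(df)):
            try:
                m, b = fit_ndvi_decay(N[i], A[i])
            except PhenotypeDataError:
                continue
            rs[i] = m
            if np.isfinite(pm[i]):
                sg[i] = m * pm[i] + b
        df["RS"] = rs
        df["SG"] = sg
    return df


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------


@dataclass
class RemlResult:
    beta: np.ndarray
    cov_beta: np.ndarray
    var_components: np.ndarray  # one per random factor
    var_error: float
    loglik: float
    converged: bool


def _design(labels: pd.Series) -> tuple[np.ndarray, list]:
    levels, idx = np.unique(np.asarray(labels), return_inverse=True)
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), idx] = 1.0
    return Z, list(levels)


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: list[np.ndarray],
    max_iter: int = 200,
) -> RemlResult:
    """REML for y = X beta + sum_k Z_k u_k + e with independent random
    effects u_k ~ N(0, sigma^2_k I).

    The residual variance is profiled out and the restricted likelihood is
    maximized over log variance ratios gamma_k = sigma^2_k / sigma^2_e with
    a quasi-Newton method.  Estimated components are truncated at zero.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise RemlError("more fixed effects than observations")
    ZZt = [Z @ Z.T for Z in Z_list]

    def neg2_restricted_ll(log_gamma: np.ndarray) -> float:
        gamma = np.exp(log_gamma)
        H = np.eye(n)
        for g, M in zip(gamma, ZZt):
            H = H + g * M
        try:
            L = np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            return 1e30
        logdet_H = 2.0 * np.log(np.diag(L)).sum()
        Hi_y = np.linalg.solve(H, y)
        Hi_X = np.linalg.solve(H, X)
        XtHiX = X.T @ Hi_X
        sign, logdet_X = np.linalg.slogdet(XtHiX)
        if sign <= 0:
            return 1e30
        beta = np.linalg.solve(XtHiX, X.T @ Hi_y)
        r = y - X @ beta
        quad = float(r @ np.linalg.solve(H, r))
        if quad <= 0:
            return 1e30
        return (n - p) * np.log(quad) + logdet_H + logdet_X

    k = len(Z_list)
    if k == 1:
        res = optimize.minimize_scalar(
            lambda lg: neg2_restricted_ll(np.array([lg])),
            bounds=(-16.0, 16.0),
            method="bounded",
            options={"xatol": 1e-7},
        )
        best = optimize.OptimizeResult(x=np.array([res.x]), fun=res.fun, success=True)
    else:
        best = None
        for start in ([0.0] * k, [-2.0] * k, [2.0] * k):
            res = optimize.minimize(
                neg2_restricted_ll,
                np.asarray(start, dtype=float),
                method="Nelder-Mead",
                options={"maxiter": max_iter * max(k, 1), "xatol": 1e-6, "fatol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
    gamma = np.exp(best.x)
    # truncate negligible ratios to exactly zero
    gamma = np.where(gamma < 1e-8, 0.0, gamma)

    H = np.eye(n)
    for g, M in zip(gamma, ZZt):
        H = H + g * M
    Hi_y = np.linalg.solve(H, y)
    Hi_X = np.linalg.solve(H, X)
    XtHiX = X.T @ Hi_X
    beta = np.linalg.solve(XtHiX, X.T @ Hi_y)
    r = y - X @ beta
    sigma2_e = float(r @ np.linalg.solve(H, r)) / (n - p)
    if sigma2_e < 0:
        sigma2_e = 0.0
    return RemlResult(
        beta=beta,
        cov_beta=np.linalg.inv(XtHiX) * sigma2_e,
        var_components=gamma * sigma2_e,
        var_error=sigma2_e,
        loglik=-0.5 * float(best.fun),
        converged=bool(best.success or best.fun < 1e29),
    )


# ---------------------------------------------------------------------------
# LSmeans and heritability
# ---------------------------------------------------------------------------


def compute_lsmeans(
    plots: pd.DataFrame,
    trait: str = "GY",
    dth_covariate: bool = False,
    per_environment: bool = True,
) -> pd.DataFrame:
    """Genotype LSmeans per environment (default) or from the joint model.

    Environment-wise: genotype fixed, block random, optional centered DTH
    covariate.  Joint: genotype fixed, environment and block-within-
    environment random.  Returns a long table (genotype, environment,
    trait, lsmean, se) with the ``dth_corrected`` flag.
    """
    if trait not in plots.columns:
        raise PhenotypeDataError(f"trait {trait!r} not in plot table")
    results = []
    if per_environment:
        groups = [(env, sub) for env, sub in plots.groupby("environment", sort=True)]
    else:
        groups = [("ALL", plots)]
    for env, sub in groups:
        sub = sub[sub[trait].notna()].copy()
        if dth_covariate:
            sub = sub[sub["DTH"].notna()]
        if sub.empty:
            logger.warning("no data for trait %s in %s", trait, env)
            continue
        dropped = set(plots["genotype"]) - set(sub["genotype"])
        if dropped:
            logger.warning("%d genotypes with no plots for %s in %s", len(dropped), trait, env)
        Zg, genos = _design(sub["genotype"])
        X = Zg  # cell-means coding: one column per genotype, no intercept
        if dth_covariate:
            dth = sub["DTH"].to_numpy(float)
            X = np.column_stack([X, dth - dth.mean()])
        Z_list = []
        if per_environment:
            blk, _ = _design(sub["block"])
            if blk.shape[1] > 1:
                Z_list.append(blk)
        else:
            Ze, _ = _design(sub["environment"])
            Z_list.append(Ze)
            eb, _ = _design(
                sub["environment"].astype(str) + ":" + sub["block"].astype(str)
            )
            Z_list.append(eb)
        y = sub[trait].to_numpy(float)
        if Z_list:
            fit = reml_fit(y, X, Z_list)
        else:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            dof = max(len(y) - X.shape[1], 1)
            s2 = float(r @ r) / dof
            XtXi = np.linalg.pinv(X.T @ X)
            fit = RemlResult(beta, XtXi * s2, np.array([]), s2, 0.0, True)
        se = np.sqrt(np.maximum(np.diag(fit.cov_beta)[: len(genos)], 0.0))
        for j, geno in enumerate(genos):
            results.append(
                {
                    "genotype": geno,
                    "environment": env,
                    "trait": trait,
                    "lsmean": float(fit.beta[j]),
                    "se": float(se[j]),
                    "dth_corrected": dth_covariate,
                }
            )
    if not results:
        raise PhenotypeDataError(f"no LSmeans computable for trait {trait!r}")
    return pd.DataFrame(results)


def lsmeans_wide(lsm: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long LSmeans table to genotype x trait for one environment."""
    return lsm.pivot_table(index="genotype", columns="trait", values="lsmean")


@dataclass
class HeritabilityEstimate:
    trait: str
    environment: str
    var_G: float
    var_e: float

    @property
    def H2(self) -> float:
        tot = self.var_G + self.var_e
        return float(self.var_G / tot) if tot > 0 else 0.0


def heritability(
    plots: pd.DataFrame, trait: str = "GY", environment: str | None = None
) -> HeritabilityEstimate:
    """Broad-sense plot-basis heritability from the random-genotype,
    random-block model within one environment."""
    sub = plots if environment is None else plots[plots["environment"] == environment]
    sub = sub[sub[trait].notna()]
    if sub.empty:
        raise PhenotypeDataError(f"no data for {trait!r} in {environment!r}")
    counts = sub["genotype"].value_counts()
    blocks = sub["block"].nunique()
    if (counts.max() < 2) and blocks < 2:
        raise PhenotypeDataError(
            "no genotype replicated and a single block: residual variance "
            "is not identifiable"
        )
    Zg, _ = _design(sub["genotype"])
    Z_list = [Zg]
    if blocks > 1:
        Zb, _ = _design(sub["block"])
        Z_list.append(Zb)
    y = sub[trait].to_numpy(float)
    fit = reml_fit(y, np.ones((len(y), 1)), Z_list)
    var_G = max(float(fit.var_components[0]), 0.0)
    return HeritabilityEstimate(
        trait=trait,
        environment=environment or "ALL",
        var_G=var_G,
        var_e=max(fit.var_error, 0.0),
    )


def heritability_all(plots: pd.DataFrame, trait: str = "GY") -> dict[str, float]:
    """H^2 per environment for one trait."""
    return {
        str(env): heritability(plots, trait, str(env)).H2
        for env in sorted(plots["environment"].unique())
    }


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def trait_yield_correlations(
    lsm: pd.DataFrame, environment: str, yield_trait: str = "GY"
) -> pd.DataFrame:
    """Pearson correlation of each trait's LSmeans with grain-yield LSmeans
    within one environment, with two-sided P and significance stars."""
    sub = lsm[lsm["environment"] == environment]
    wide = sub.pivot_table(index="genotype", columns="trait", values="lsmean")
    if yield_trait not in wide.columns:
        raise PhenotypeDataError(f"{yield_trait!r} LSmeans absent for {environment!r}")
    rows = []
    gy = wide[yield_trait]
    for trait in wide.columns:
        if trait == yield_trait:
            continue
        pair = pd.concat([wide[trait], gy], axis=1).dropna()
        if len(pair) < 3 or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
            rows.append({"trait": trait, "r": np.nan, "p_value": np.nan, "stars": "", "n": len(pair)})
            continue
        r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append({"trait": trait, "r": float(r), "p_value": float(p), "stars": _stars(p), "n": len(pair)})
    return pd.DataFrame(rows)
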