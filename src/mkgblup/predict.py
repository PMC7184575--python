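"""Bayesian multi-kernel BLUP by Gibbs sampling.

Six model forms combine a genomic main-effect kernel (G), a physiological
main-effect kernel (P) and their environment-interaction kernels (GE, PE)
around fixed environment effects:

    G        y = mu + E_i + G_j            + eps
    G+GE     y = mu + E_i + G_j  + GE_ij   + eps
    G+PE     y = mu + E_i + G_j  + PE_ij   + eps
    P        y = mu + E_i + P_j            + eps
    P+PE     y = mu + E_i + P_j  + PE_ij   + eps
    P+GE     y = mu + E_i + P_j  + GE_ij   + eps

Each random vector u_k ~ N(0, sigma^2_k K_k) over trial records.  The
sampler works in the eigenbasis of each record-level kernel (K = U D U',
u = U alpha with alpha_i ~ N(0, sigma^2_k d_i)), where the full
conditionals of the alpha coordinates are independent normals; variance
components have scaled-inverse-chi-square full conditionals.  Records with
masked phenotypes are treated as latent and refreshed from their
conditional each sweep (data augmentation), which is what lets whole-line
cross-validation masking propagate information through the kernels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import ExpandedKernel, RecordDesign

logger = logging.getLogger(__name__)

MODEL_KERNELS: dict[str, list[str]] = {
    "G": ["G_main"],
    "G+GE": ["G_main", "GE"],
    "G+PE": ["G_main", "PE"],
    "P": ["P_main"],
    "P+PE": ["P_main", "PE"],
    "P+GE": ["P_main", "GE"],
}

MODEL_NAMES = list(MODEL_KERNELS)


class FitError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """One of the six kernel combinations, with fixed environment effects."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in MODEL_KERNELS:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")

    @property
    def kernel_names(self) -> list[str]:
        return MODEL_KERNELS[self.name]


@dataclass
class ChainConfig:
    """Gibbs chain settings and variance priors.

    Priors are scaled-inverse-chi-square with ``prior_df`` degrees of
    freedom; each component's prior scale is set from the phenotypic
    variance so the prior modes split it equally between the kernels and
    the residual.  ``fixed_variances`` pins named components (kernel names
    or "residual") at given values, bypassing their updates — the
    degenerate-prior limit used for oracle checks.
    """

    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0
    eig_tol: float = 1e-8
    fixed_variances: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.n_iter > self.burn_in >= 0):
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class FitResult:
    """Posterior summaries from one Gibbs run."""

    model: str
    design: RecordDesign
    env_effects: pd.Series  # posterior mean fixed effect per environment
    u_means: dict  # kernel name -> posterior mean effect vector (records)
    var_means: dict  # component -> posterior mean variance
    var_sds: dict
    fitted: np.ndarray  # fixed part + sum of random effects, per record
    gebv: np.ndarray  # sum of random effects, per record
    ess: dict  # effective sample size per variance component
    n_samples: int
    seed: int

    @property
    def mu(self) -> float:
        return float(self.env_effects.mean())

    def gebv_frame(self) -> pd.DataFrame:
        df = self.design.to_frame()
        df["gebv"] = self.gebv
        df["fitted"] = self.fitted
        return df


def _eigen(kernel: ExpandedKernel, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Reduced-rank eigendecomposition, cached on the kernel object."""
    cached = getattr(kernel, "_eig", None)
    if cached is not None:
        return cached
    w, U = np.linalg.eigh(kernel.matrix)
    keep = w > tol * max(w.max(), 1.0)
    if not keep.any():
        raise FitError(f"kernel {kernel.name} has no positive eigenvalues")
    if w.min() < -tol * max(w.max(), 1.0):
        raise FitError(f"kernel {kernel.name} is not PSD within tolerance")
    eig = (w[keep], U[:, keep])
    kernel._eig = eig  # type: ignore[attr-defined]
    return eig


def _ess(trace: np.ndarray) -> float:
    """Initial-positive-sequence effective sample size of a scalar trace."""
    n = len(trace)
    if n < 10 or trace.std() == 0:
        return float(n)
    x = trace - trace.mean()
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (x @ x)
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def fit(
    y,
    design: RecordDesign,
    spec: ModelSpec,
    kernels: dict[str, ExpandedKernel],
    chain: ChainConfig | None = None,
) -> FitResult:
    """Run the Gibbs sampler for one model.

    Parameters
    ----------
    y : array-like, length n_records
        Record-indexed grain-yield LSmeans; NaN entries are treated as
        unobserved and predicted.
    design : RecordDesign
        The (genotype, environment) record index of ``y``.
    spec : ModelSpec
        Which kernels enter the model.
    kernels : dict
        Expanded record-level kernels, keyed by name; must contain every
        kernel of ``spec``.
    chain : ChainConfig
        Sampler settings; defaults to 12,000 iterations, 2,000 burn-in,
        thinning 5.
    """
    chain = chain or ChainConfig()
    y = np.asarray(y, dtype=float)
    n = design.n_records
    if y.shape != (n,):
        raise FitError(f"y has shape {y.shape}, expected ({n},)")
    missing = ~np.isfinite(y)
    observed = ~missing
    if not observed.any():
        raise FitError("no observed phenotypes")
    for e in range(len(design.env_levels)):
        if not observed[design.env_index == e].any():
            raise FitError(f"environment {design.env_levels[e]} has no observed records")

    names = spec.kernel_names
    for nm in names:
        if nm not in kernels:
            raise FitError(f"model {spec.name} needs kernel {nm!r}")
    eigs = {nm: _eigen(kernels[nm], chain.eig_tol) for nm in names}

    rng = np.random.default_rng(chain.seed)
    env_idx = design.env_index
    n_env = len(design.env_levels)
    env_counts = np.bincount(env_idx, minlength=n_env).astype(float)

    y_obs = y[observed]
    vy = float(y_obs.var()) if y_obs.size > 1 else 1.0
    vy = max(vy, 1e-12)
    df0 = chain.prior_df
    n_comp = len(names) + 1
    share = vy / n_comp
    prior_scale = {}
    for nm in names:
        mean_diag = float(np.mean(np.diag(kernels[nm].matrix)))
        prior_scale[nm] = share * (df0 + 2.0) / df0 / max(mean_diag, 1e-12)
    prior_scale["residual"] = share * (df0 + 2.0) / df0

    # state
    y_aug = y.copy()
    y_aug[missing] = float(y_obs.mean())
    b = np.array([y_aug[env_idx == e].mean() for e in range(n_env)])
    alphas = {nm: np.zeros(eigs[nm][0].shape[0]) for nm in names}
    u = {nm: np.zeros(n) for nm in names}
    var = {nm: chain.fixed_variances.get(nm, share) for nm in names}
    var["residual"] = chain.fixed_variances.get("residual", share)

    keep_iters = range(chain.burn_in, chain.n_iter, chain.thin)
    n_keep = len(keep_iters)
    keep_set = set(keep_iters)

    b_sum = np.zeros(n_env)
    u_sum = {nm: np.zeros(n) for nm in names}
    var_trace = {c: np.empty(n_keep) for c in var}
    k_saved = 0

    for it in range(chain.n_iter):
        sve = var["residual"]
        total_u = np.sum(list(u.values()), axis=0) if names else np.zeros(n)

        # fixed environment effects (flat prior): independent per environment
        r = y_aug - total_u
        env_sums = np.bincount(env_idx, weights=r, minlength=n_env)
        b = env_sums / env_counts + rng.standard_normal(n_env) * np.sqrt(sve / env_counts)
        fixed = b[env_idx]

        # kernel effects in their eigenbases
        for nm in names:
            d, U = eigs[nm]
            total_u -= u[nm]
            resid = y_aug - fixed - total_u
            rt = U.T @ resid
            prec = 1.0 / sve + 1.0 / (var[nm] * d)
            mean = (rt / sve) / prec
            alpha = mean + rng.standard_normal(d.shape[0]) / np.sqrt(prec)
            alphas[nm] = alpha
            u[nm] = U @ alpha
            total_u += u[nm]

        # variance components
        for nm in names:
            if nm in chain.fixed_variances:
                continue
            d, _ = eigs[nm]
            ss = float(np.sum(alphas[nm] ** 2 / d))
            post_df = df0 + d.shape[0]
            var[nm] = (df0 * prior_scale[nm] + ss) / rng.chisquare(post_df)
        if "residual" not in chain.fixed_variances:
            resid = y_aug - fixed - total_u
            ss = float(resid @ resid)
            post_df = df0 + n
            var["residual"] = (df0 * prior_scale["residual"] + ss) / rng.chisquare(post_df)

        if not np.isfinite(list(var.values())).all() or not np.isfinite(total_u).all():
            raise FitError(f"divergent chain at iteration {it}")

        # refresh latent phenotypes of masked records
        if missing.any():
            fit_miss = fixed[missing] + total_u[missing]
            y_aug[missing] = fit_miss + rng.standard_normal(missing.sum()) * np.sqrt(
                var["residual"]
            )

        if it in keep_set:
            b_sum += b
            for nm in names:
                u_sum[nm] += u[nm]
            for c in var:
                var_trace[c][k_saved] = var[c]
            k_saved += 1

    b_mean = b_sum / n_keep
    u_means = {nm: u_sum[nm] / n_keep for nm in names}
    gebv = np.sum(list(u_means.values()), axis=0) if names else np.zeros(n)
    fitted = b_mean[env_idx] + gebv
    return FitResult(
        model=spec.name,
        design=design,
        env_effects=pd.Series(b_mean, index=design.env_levels),
        u_means=u_means,
        var_means={c: float(var_trace[c].mean()) for c in var_trace},
        var_sds={c: float(var_trace[c].std()) for c in var_trace},
        fitted=fitted,
        gebv=gebv,
        ess={c: _ess(var_trace[c]) for c in var_trace},
        n_samples=n_keep,
        seed=chain.seed,
    )


def predict(
    fit_result: FitResult,
    target_records=None,
    include_fixed: bool = False,
) -> np.ndarray:
    """GEBV (posterior-mean summed random effects) for records.

    ``target_records`` may be None (all records), an index array, or a list
    of (genotype, environment) pairs present in the fit's design.
    """
    if target_records is None:
        idx = np.arange(fit_result.design.n_records)
    elif isinstance(target_records, (list, tuple)) and target_records and isinstance(
        target_records[0], (list, tuple)
    ):
        lookup = {
            (g, e): i
            for i, (g, e) in enumerate(
                zip(fit_result.design.genotypes, fit_result.design.environments)
            )
        }
        try:
            idx = np.array([lookup[(g, e)] for g, e in target_records])
        except KeyError as exc:
            raise FitError(f"record {exc.args[0]} absent from the fitted design") from exc
    else:
        idx = np.asarray(target_records, dtype=int)
    out = fit_result.gebv[idx]
    if include_fixed:
        out = out + fit_result.env_effects.to_numpy()[fit_result.design.env_index[idx]]
    return out
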