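"""Population-structure-aware cross-validation and response to selection.

Lines are stratified into genetic groups by the clustering stage of DAPC
(principal components of the standardized marker matrix followed by
k-means), whole groups are assigned to cross-validation folds so that
related lines never straddle the training/validation split, and prediction
accuracy is the fold-mean predictive correlation adjusted by the square
root of heritability:

    r_GY = r_p / sqrt(H^2),      SE = sigma_{r_p} / sqrt(f * H^2)

Response to selection applies the breeder's equation R = H^2 * S with the
selection differential S = mu_selected - mu_population at a 10% selection
intensity on GEBV rank, aggregated over folds with SE = sigma_RTS / sqrt(f).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import MarkerMatrix
from .kernels import ExpandedKernel, RecordDesign
from .predict import ChainConfig, FitResult, ModelSpec, fit

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# stratification and folds
# ---------------------------------------------------------------------------


def stratify_lines(
    m: MarkerMatrix,
    k_groups: int = 10,
    n_pcs: int | None = None,
    seed: int = 0,
    var_explained: float = 0.80,
) -> pd.Series:
    """Cluster lines into genetic groups: PCA on the standardized marker
    matrix, then k-means on the retained components.

    ``n_pcs`` defaults to the smallest number of components explaining at
    least ``var_explained`` of the marker variance.  This is the clustering
    stage of DAPC; the discriminant step is not needed for fold building.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    if m.missing.any():
        raise EvaluationError("impute markers before stratification")
    if k_groups > m.n_lines:
        raise EvaluationError("more groups than lines")
    X = m.dosage - m.dosage.mean(axis=0, keepdims=True)
    sd = m.dosage.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    max_pcs = min(m.n_lines - 1, m.n_markers)
    pca = PCA(n_components=max_pcs, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    if n_pcs is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_pcs = int(np.searchsorted(cum, var_explained) + 1)
    n_pcs = min(n_pcs, scores.shape[1])
    km = KMeans(n_clusters=k_groups, n_init=10, random_state=seed)
    labels = km.fit_predict(scores[:, :n_pcs])
    groups = pd.Series(labels, index=m.line_ids, name="group")
    sizes = groups.value_counts()
    logger.info(
        "stratify_lines: %d groups from %d PCs; sizes %d-%d",
        k_groups, n_pcs, int(sizes.min()), int(sizes.max()),
    )
    return groups


@dataclass
class StratifiedFolds:
    """Line-to-fold assignment in which no genetic group is split."""

    groups: pd.Series  # line -> group label
    folds: pd.Series  # line -> fold in 1..f
    f: int
    seed: int

    def validation_lines(self, fold: int) -> list[str]:
        return list(self.folds.index[self.folds == fold])


def assign_folds(groups: pd.Series, f: int = 5, seed: int = 0) -> StratifiedFolds:
    """Assign whole groups to ``f`` folds, greedily balancing fold sizes
    (largest group first into the currently smallest fold, ties broken at
    random)."""
    sizes = groups.value_counts()
    if len(sizes) < f:
        raise EvaluationError(
            f"only {len(sizes)} groups for {f} folds; use fewer folds"
        )
    rng = np.random.default_rng(seed)
    order = sizes.sample(frac=1.0, random_state=rng).sort_values(
        ascending=False, kind="stable"
    )
    fold_sizes = np.zeros(f)
    fold_of_group: dict = {}
    for grp, size in order.items():
        candidates = np.flatnonzero(fold_sizes == fold_sizes.min())
        tgt = int(rng.choice(candidates))
        fold_of_group[grp] = tgt + 1
        fold_sizes[tgt] += size
    folds = groups.map(fold_of_group).astype(int)
    return StratifiedFolds(groups=groups, folds=folds, f=f, seed=seed)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    model: str
    environment: str
    fold_correlations: list[float]
    H2: float
    dth_corrected: bool = False

    @property
    def r_p(self) -> float:
        vals = [c for c in self.fold_correlations if np.isfinite(c)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def r_GY(self) -> float:
        if self.H2 <= 0:
            return float("nan")
        return self.r_p / math.sqrt(self.H2)

    @property
    def se(self) -> float:
        vals = [c for c in self.fold_correlations if np.isfinite(c)]
        if len(vals) < 2 or self.H2 <= 0:
            return float("nan")
        f = len(self.fold_correlations)
        return float(np.std(vals, ddof=1) / math.sqrt(f * self.H2))


def accuracy_from_folds(r_p: float, h2: float) -> float:
    """Heritability-adjusted accuracy r_GY = r_p / sqrt(H^2)."""
    if h2 <= 0:
        raise EvaluationError("H^2 must be positive to adjust accuracy")
    return r_p / math.sqrt(h2)


def accuracy_se(sigma_rp: float, f: int, h2: float) -> float:
    """SE of the adjusted accuracy: sigma_rp / sqrt(f * H^2)."""
    if h2 <= 0 or f < 1:
        raise EvaluationError("need H^2 > 0 and f >= 1")
    return sigma_rp / math.sqrt(f * h2)


def cross_validate(
    y,
    design: RecordDesign,
    specs: list[ModelSpec],
    kernels: dict[str, ExpandedKernel],
    folds: StratifiedFolds,
    h2: dict[str, float],
    chain: ChainConfig | None = None,
    dth_corrected: bool = False,
    return_gebv: bool = False,
):
    """Group-respecting f-fold cross-validation of the requested models.

    For each fold, every record of each validation line is masked across
    all environments, the model is refit, and predictions for the masked
    records are correlated (Pearson) with the observed LSmeans within each
    environment.

    Returns a list of CVResult (one per model x environment); with
    ``return_gebv`` also a DataFrame of pooled validation GEBVs per model
    with fold labels, for response-to-selection analysis.
    """
    chain = chain or ChainConfig()
    y = np.asarray(y, dtype=float)
    line_fold = folds.folds
    covered = set(design.genotypes) - set(line_fold.index)
    if covered:
        raise EvaluationError(f"lines missing from folds: {sorted(covered)[:5]}")
    record_fold = np.array([line_fold[g] for g in design.genotypes])

    results: list[CVResult] = []
    gebv_rows = []
    for spec in specs:
        fold_corr: dict[str, list[float]] = {e: [] for e in design.env_levels}
        for k in range(1, folds.f + 1):
            mask = record_fold == k
            y_train = y.copy()
            y_train[mask] = np.nan
            fold_chain = ChainConfig(
                n_iter=chain.n_iter,
                burn_in=chain.burn_in,
                thin=chain.thin,
                seed=int(np.random.SeedSequence([chain.seed, k]).generate_state(1)[0] % (2**31)),
                prior_df=chain.prior_df,
                eig_tol=chain.eig_tol,
                fixed_variances=dict(chain.fixed_variances),
            )
            res = fit(y_train, design, spec, kernels, fold_chain)
            for e, env in enumerate(design.env_levels):
                sel = mask & (design.env_index == e) & np.isfinite(y)
                if sel.sum() >= 3 and np.std(res.gebv[sel]) > 0 and np.std(y[sel]) > 0:
                    r = float(np.corrcoef(res.gebv[sel], y[sel])[0, 1])
                else:
                    r = float("nan")
                fold_corr[env].append(r)
            if return_gebv:
                for i in np.flatnonzero(mask):
                    gebv_rows.append(
                        {
                            "model": spec.name,
                            "fold": k,
                            "genotype": design.genotypes[i],
                            "environment": design.environments[i],
                            "gebv": float(res.gebv[i]),
                            "observed": float(y[i]),
                        }
                    )
        for env in design.env_levels:
            h2_env = h2.get(env, float("nan"))
            if not (h2_env > 0):
                logger.warning("H^2 <= 0 for %s; adjusted accuracy undefined", env)
            results.append(
                CVResult(
                    model=spec.name,
                    environment=env,
                    fold_correlations=fold_corr[env],
                    H2=h2_env,
                    dth_corrected=dth_corrected,
                )
            )
    if return_gebv:
        return results, pd.DataFrame(gebv_rows)
    return results


def cv_table(results: list[CVResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": r.model,
                "environment": r.environment,
                "r_p": r.r_p,
                "H2": r.H2,
                "r_GY": r.r_GY,
                "se": r.se,
                "dth_corrected": r.dth_corrected,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# response to selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    model: str
    environment: str
    mu_selected: float
    mu_population: float
    H2: float
    intensity: float
    n_selected: int

    @property
    def S(self) -> float:
        return self.mu_selected - self.mu_population

    @property
    def R(self) -> float:
        return self.H2 * self.S


def response_to_selection(
    gebv,
    observed,
    h2: float,
    intensity: float = 0.10,
    model: str = "",
    environment: str = "",
    line_ids=None,
) -> SelectionResult:
    """Breeder's-equation response from truncation selection on GEBV.

    Lines are ranked by GEBV (descending; ties broken by stable line-id
    order) and the top ceil(intensity * n) selected.  S is the difference
    between the mean *observed* yield of the selected set and of the whole
    population; R = H^2 * S.
    """
    gebv = np.asarray(gebv, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if gebv.shape != observed.shape:
        raise EvaluationError("gebv and observed must cover the same lines")
    if not (0.0 < intensity < 1.0):
        raise EvaluationError("intensity must be in (0, 1)")
    n = len(gebv)
    n_sel = math.ceil(intensity * n)
    if line_ids is not None:
        # ties at the cutoff broken by stable line-id order
        order = np.asarray(sorted(range(n), key=lambda i: (-gebv[i], str(line_ids[i]))))
    else:
        order = np.argsort(-gebv, kind="stable")  # ties by input order
    selected = order[:n_sel]
    return SelectionResult(
        model=model,
        environment=environment,
        mu_selected=float(observed[selected].mean()),
        mu_population=float(observed.mean()),
        H2=h2,
        intensity=intensity,
        n_selected=n_sel,
    )


def rts_from_cv(
    gebv_table: pd.DataFrame,
    h2: dict[str, float],
    intensity: float = 0.10,
) -> pd.DataFrame:
    """Per-fold response to selection from pooled validation GEBVs.

    Within each (model, environment, fold), validation lines are ranked by
    GEBV and the breeder's equation applied against their observed yields;
    fold values are averaged with SE = sigma_RTS / sqrt(f).
    """
    rows = []
    for (model, env), sub in gebv_table.groupby(["model", "environment"]):
        per_fold = []
        for _, fold_sub in sub.groupby("fold"):
            sr = response_to_selection(
                fold_sub["gebv"].to_numpy(),
                fold_sub["observed"].to_numpy(),
                h2.get(env, float("nan")),
                intensity,
                model=model,
                environment=env,
                line_ids=list(fold_sub["genotype"]),
            )
            per_fold.append(sr.R)
        f = len(per_fold)
        rows.append(
            {
                "model": model,
                "environment": env,
                "R": float(np.mean(per_fold)),
                "se": float(np.std(per_fold, ddof=1) / math.sqrt(f)) if f > 1 else float("nan"),
                "f": f,
                "intensity": intensity,
            }
        )
    return pd.DataFrame(rows)
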