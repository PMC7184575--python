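"""Synthetic soft-wheat panel generator with known ground truth.

Emulates a multi-environment un-replicated augmented yield trial: a diversity
panel of inbred lines genotyped at thousands of biallelic SNPs, grown once
per environment alongside replicated check varieties, with grain yield driven
by an additive polygenic value, exchangeable genotype-by-environment
deviations, block effects and plot error.  Physiological traits (SPAD
chlorophyll, canopy temperature, membrane thermostability conductivities,
six NDVI time points, days to heading) are generated as noisy linear
reflections of the same genetic signal so that trait-yield correlations of
realistic magnitude arise by construction.

Defaults mirror the structure of a 242-line soft wheat panel evaluated in
four Florida environments: ~19,353 SNPs, 12 blocks per environment with
three repeated checks, plot-basis grain-yield heritability near 1/3
(observed range 0.20-0.41), NDVI declining linearly over accumulated
growing degree days with slopes around -5e-4 per degree-day, and stay-green
values near 0.3-0.45.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotype import MarkerMatrix

logger = logging.getLogger(__name__)


class SimulationConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


#: traits simulated as noisy linear functions of the genetic signal;
#: loadings are in trait units contributed per SD of (g + ge).
DEFAULT_LOADINGS = {
    "SPAD": 1.6,
    "CT": -0.45,
    "MT": 4.0,
}

DEFAULT_NOISE_SD = {
    "SPAD": 4.0,
    "CT": 1.2,
    "MT": 9.0,
}

DEFAULT_TRAIT_MEANS = {
    "SPAD": 50.0,
    "CT": 27.0,
    "MT": 57.0,
}


@dataclass
class SimulationConfig:
    """All parameters of the synthetic trial; the defaults are the study
    conditions the generator emulates."""

    n_lines: int = 242
    n_markers: int = 19353
    n_envs: int = 4
    n_blocks_per_env: int = 12
    check_ids: list[str] = field(default_factory=lambda: ["CHK1", "CHK2", "CHK3"])
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    het_rate: float = 0.0
    var_genetic: float = 200_000.0  # kg^2 ha^-2
    var_ge: float = 100_000.0
    var_error: float = 400_000.0
    block_sd: float = 200.0
    env_means: list[float] = field(
        default_factory=lambda: [3500.0, 2257.0, 4673.0, 4776.0]
    )
    n_qtl: int | None = None  # default resolves to min(300, n_markers)
    physio_loadings: dict = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    physio_noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    t2_conductivity: float = 120.0  # post-autoclave conductivity baseline
    ndvi_intercept_mean: float = 0.85
    ndvi_intercept_sd: float = 0.02
    ndvi_slope_mean: float = -5e-4
    ndvi_slope_sd: float = 8e-5
    ndvi_slope_loading: float = 1e-4  # slope units per SD of g
    ndvi_noise_sd: float = 0.02
    agdd_points: tuple[float, ...] = (100.0, 250.0, 400.0, 550.0, 700.0, 850.0)
    agdd_pm: float = 1000.0
    dth_mean: float = 107.0
    dth_sd: float = 3.5
    dth_loading: float = 0.0  # days per SD of g; 0 = DTH orthogonal to yield
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationConfigError(
                f"maf_range must lie in (0, 0.5], got {self.maf_range}"
            )
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimulationConfigError("missing_rate must be in [0, 1)")
        for name in ("var_genetic", "var_ge", "var_error"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name} must be >= 0")
        if self.n_qtl is None:
            self.n_qtl = min(300, self.n_markers)
        if self.n_qtl > self.n_markers:
            raise SimulationConfigError("n_qtl cannot exceed n_markers")
        if len(self.env_means) < self.n_envs:
            raise SimulationConfigError("need an env_mean per environment")
        pts = np.asarray(self.agdd_points, dtype=float)
        if not (np.diff(pts) > 0).all():
            raise SimulationConfigError("agdd_points must be strictly increasing")

    @property
    def line_ids(self) -> list[str]:
        n_test = self.n_lines - len(self.check_ids)
        return [f"L{i:04d}" for i in range(1, n_test + 1)] + list(self.check_ids)

    def to_file(self, path) -> None:
        import yaml

        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["agdd_points"] = list(self.agdd_points)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["maf_range"] = tuple(d["maf_range"])
        d["agdd_points"] = tuple(d["agdd_points"])
        return cls(**d)


@dataclass
class GroundTruth:
    """True simulated quantities for parameter-recovery tests."""

    line_ids: list[str]
    env_ids: list[str]
    g: np.ndarray  # per-line additive genetic value
    ge: np.ndarray  # lines x envs deviations
    block_effects: dict  # (env, block) -> effect
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    var_genetic: float
    var_ge: float
    var_error: float

    def g_series(self) -> pd.Series:
        return pd.Series(self.g, index=self.line_ids, name="g")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.ge, index=self.line_ids, columns=self.env_ids)
        df.insert(0, "g", self.g)
        df.to_csv(path, index_label="line_id")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def simulate_markers(config: SimulationConfig) -> MarkerMatrix:
    """Draw an inbred-panel dosage matrix.

    Per-marker allele frequencies are uniform on ``maf_range``; each line is
    homozygous alt with probability p (dosage 2) and homozygous ref otherwise,
    with an optional residual heterozygote rate.  Missing calls are masked
    independently at ``missing_rate``.
    """
    rng = _rng(config.seed, 1)
    n, m = config.n_lines, config.n_markers
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    dosage = 2.0 * (rng.random((n, m)) < p[None, :])
    if config.het_rate > 0:
        het = rng.random((n, m)) < config.het_rate
        dosage = np.where(het, 1.0, dosage)
    missing = rng.random((n, m)) < config.missing_rate
    return MarkerMatrix(
        line_ids=config.line_ids,
        marker_ids=[f"S1_{j + 1}" for j in range(m)],
        dosage=dosage,
        missing=missing,
    )


def simulate_trial(
    markers: MarkerMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate plot-level grain yield under an augmented design.

    True genetic values are g = X beta over ``n_qtl`` randomly chosen
    markers, with effects rescaled so the sample variance of g equals
    ``var_genetic`` exactly.  GE deviations are i.i.d. normal per
    line-by-environment cell, rescaled to ``var_ge`` exactly.  Each
    non-check line appears once per environment (assigned to a block);
    every check appears once in every block.
    """
    if not set(config.check_ids) <= set(markers.line_ids):
        raise SimulationConfigError(
            f"check_ids {config.check_ids} not all present among line ids"
        )
    rng = _rng(config.seed, 2)
    n = markers.n_lines
    env_ids = [f"E{i + 1}" for i in range(config.n_envs)]

    qtl = rng.choice(markers.n_markers, size=config.n_qtl, replace=False)
    beta = rng.normal(size=config.n_qtl)
    X = np.where(markers.missing, np.nan, markers.dosage)[:, qtl]
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean[None, :], X) - col_mean[None, :]
    g = X @ beta
    g = g - g.mean()
    sd = g.std()
    if config.var_genetic > 0 and sd > 0:
        scale = np.sqrt(config.var_genetic) / sd
        g *= scale
        beta *= scale
    else:
        g[:] = 0.0
        beta[:] = 0.0

    ge = rng.normal(size=(n, config.n_envs))
    ge -= ge.mean()
    if config.var_ge > 0 and ge.std() > 0:
        ge *= np.sqrt(config.var_ge) / ge.std()
    else:
        ge[:] = 0.0

    checks = list(config.check_ids)
    test_lines = [l for l in markers.line_ids if l not in set(checks)]
    line_index = {l: i for i, l in enumerate(markers.line_ids)}

    block_effects: dict = {}
    rows = []
    for e, env in enumerate(env_ids):
        b_eff = rng.normal(0.0, config.block_sd, size=config.n_blocks_per_env)
        for k in range(config.n_blocks_per_env):
            block_effects[(env, k + 1)] = b_eff[k]
        # spread the un-replicated test entries over blocks
        perm = rng.permutation(len(test_lines))
        blocks = np.arange(len(test_lines)) % config.n_blocks_per_env + 1
        for idx, blk in zip(perm, blocks):
            rows.append((env, int(blk), test_lines[idx], False))
        for k in range(config.n_blocks_per_env):
            for chk in checks:
                rows.append((env, k + 1, chk, True))

    df = pd.DataFrame(rows, columns=["environment", "block", "genotype", "is_check"])
    li = df["genotype"].map(line_index).to_numpy()
    ei = df["environment"].map({e: i for i, e in enumerate(env_ids)}).to_numpy()
    eps = rng.normal(0.0, np.sqrt(config.var_error), size=len(df))
    blk = np.array([block_effects[(env, b)] for env, b in zip(df["environment"], df["block"])])
    df["GY"] = (
        np.asarray(config.env_means)[ei] + g[li] + ge[li, ei] + blk + eps
    )

    truth = GroundTruth(
        line_ids=list(markers.line_ids),
        env_ids=env_ids,
        g=g,
        ge=ge,
        block_effects=block_effects,
        qtl_indices=qtl,
        qtl_effects=beta,
        var_genetic=config.var_genetic,
        var_ge=config.var_ge,
        var_error=config.var_error,
    )
    return df, truth


def simulate_physiology(
    plots: pd.DataFrame, truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Attach physiological trait columns to the plot table.

    Scalar traits are trait = mean + loading * z + noise where z is the
    standardized (g + ge) signal of the plot's line in its environment, so a
    loading is the trait-unit SD contributed by the genetic signal.  MT is
    realized through its conductivity pair (T1, T2); NDVI time points follow
    a per-plot linear decay over thermal time whose slope is correlated with
    g; DTH is drawn with a configurable genetic loading.
    """
    if len(config.agdd_points) != 6:
        raise SimulationConfigError("exactly six agdd_points are required")
    rng = _rng(config.seed, 3)
    df = plots.copy()
    li = df["genotype"].map({l: i for i, l in enumerate(truth.line_ids)}).to_numpy()
    ei = df["environment"].map({e: i for i, e in enumerate(truth.env_ids)}).to_numpy()
    signal = truth.g[li] + truth.ge[li, ei]
    ssd = signal.std()
    z = (signal - signal.mean()) / ssd if ssd > 0 else np.zeros_like(signal)
    zg_line = (
        (truth.g - truth.g.mean()) / truth.g.std()
        if truth.g.std() > 0
        else np.zeros_like(truth.g)
    )
    zg = zg_line[li]

    for trait, loading in config.physio_loadings.items():
        noise = config.physio_noise_sd.get(trait, 1.0)
        mean = config.trait_means.get(trait, 0.0)
        values = mean + loading * z + rng.normal(0.0, noise, size=len(df))
        if trait == "MT":
            # realize MT through its conductivity pair: MT = (1 - T1/T2)*100
            t2 = np.full(len(df), config.t2_conductivity)
            t1 = t2 * (1.0 - values / 100.0)
            df["T1"] = t1
            df["T2"] = t2
        else:
            df[trait] = values

    # NDVI linear decay over AGDD; slope carries the genetic signal
    b = rng.normal(config.ndvi_intercept_mean, config.ndvi_intercept_sd, size=len(df))
    m = (
        config.ndvi_slope_mean
        + config.ndvi_slope_loading * zg
        + rng.normal(0.0, config.ndvi_slope_sd, size=len(df))
    )
    pts = np.asarray(config.agdd_points)
    for t, agdd in enumerate(pts, start=1):
        ndvi = b + m * agdd + rng.normal(0.0, config.ndvi_noise_sd, size=len(df))
        df[f"NDVI_{t}"] = np.clip(ndvi, 0.0, 1.0)
        df[f"AGDD_{t}"] = agdd
    df["AGDD_PM"] = config.agdd_pm

    df["DTH"] = (
        config.dth_mean
        + config.dth_loading * zg
        + rng.normal(0.0, config.dth_sd, size=len(df))
    )
    return df


def simulate_weather(config: SimulationConfig, n_days: int = 180) -> pd.DataFrame:
    """Daily min/max temperature per environment (a smooth seasonal ramp plus
    noise) sufficient to accumulate growing degree days."""
    rng = _rng(config.seed, 4)
    frames = []
    for e in range(config.n_envs):
        day = np.arange(1, n_days + 1)
        base = 8.0 + 12.0 * day / n_days + rng.normal(0, 1.5, size=n_days)
        spread = rng.uniform(6.0, 10.0, size=n_days)
        frames.append(
            pd.DataFrame(
                {
                    "environment": f"E{e + 1}",
                    "day": day,
                    "tmin": base - spread / 2,
                    "tmax": base + spread / 2,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: markers, plot table with physiology, weather,
    and ground truth."""
    markers = simulate_markers(config)
    plots, truth = simulate_trial(markers, config)
    plots = simulate_physiology(plots, truth, config)
    weather = simulate_weather(config)
    return markers, plots, weather, truth
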