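"""Relationship kernels over lines and their expansion to trial records.

The physiological kernel P = SS'/m mirrors the genomic G = XX'/n with S the
centered, standardized (population SD) matrix of trait LSmeans.  Line-level
kernels are mapped to the (genotype, environment) record level through 0/1
incidence matrices Z_g and Z_E: the main-effect covariance is Z_g K Z_g',
and the genotype-by-environment (reaction-norm) covariance is the Hadamard
product (Z_g K Z_g') o (Z_E Z_E'), which zeroes every cross-environment
entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class KernelError(ValueError):
    pass


def _check_psd(matrix: np.ndarray, name: str, tol: float = 1e-8) -> None:
    w = np.linalg.eigvalsh(matrix)
    if w.min() < -tol * max(w.max(), 1.0):
        raise KernelError(f"{name} kernel is not positive semi-definite (min eig {w.min():.3g})")


@dataclass
class PhysioKernel:
    """Symmetric trait-derived relationship matrix P = SS'/m."""

    line_ids: list[str]
    matrix: np.ndarray
    traits_used: list[str]

    @property
    def m(self) -> int:
        return len(self.traits_used)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.line_ids, columns=self.line_ids).to_csv(
            path, index_label="line_id"
        )


@dataclass
class RecordDesign:
    """Ordered (genotype, environment) records with incidence matrices."""

    genotypes: list[str]
    environments: list[str]

    def __post_init__(self) -> None:
        if len(self.genotypes) != len(self.environments):
            raise KernelError("genotype and environment lists differ in length")
        self.line_levels = sorted(set(self.genotypes))
        self.env_levels = sorted(set(self.environments))
        li = {g: i for i, g in enumerate(self.line_levels)}
        ei = {e: i for i, e in enumerate(self.env_levels)}
        n = len(self.genotypes)
        self.line_index = np.array([li[g] for g in self.genotypes])
        self.env_index = np.array([ei[e] for e in self.environments])
        self.Z_g = np.zeros((n, len(self.line_levels)))
        self.Z_g[np.arange(n), self.line_index] = 1.0
        self.Z_E = np.zeros((n, len(self.env_levels)))
        self.Z_E[np.arange(n), self.env_index] = 1.0

    @property
    def n_records(self) -> int:
        return len(self.genotypes)

    @classmethod
    def from_lsmeans(cls, lsm: pd.DataFrame) -> "RecordDesign":
        sub = lsm.sort_values(["environment", "genotype"])
        return cls(list(sub["genotype"]), list(sub["environment"]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"genotype": self.genotypes, "environment": self.environments})


@dataclass
class ExpandedKernel:
    """Records x records covariance kernel (G_main, P_main, GE or PE)."""

    name: str
    matrix: np.ndarray


def compute_physio_kernel(
    lsm: pd.DataFrame,
    traits: list[str] | None = None,
    line_ids: list[str] | None = None,
) -> PhysioKernel:
    """Trait relationship matrix P = SS'/m from LSmeans.

    ``lsm`` may be a long table (genotype, trait, lsmean) — pooled over
    environments by mean — or a genotype x trait wide frame.  Traits that
    are entirely missing or have zero variance are dropped with a warning;
    sporadic per-line gaps are filled with the trait mean (logged) before
    standardization with the population SD.
    """
    if {"genotype", "trait", "lsmean"} <= set(lsm.columns):
        wide = lsm.pivot_table(index="genotype", columns="trait", values="lsmean")
    else:
        wide = lsm.copy()
    if line_ids is not None:
        wide = wide.reindex(line_ids)
    if traits is None:
        traits = [t for t in wide.columns]
    cols = []
    used = []
    for t in traits:
        if t not in wide.columns or wide[t].notna().sum() < 2:
            logger.warning("trait %s dropped from P: entirely missing", t)
            continue
        col = wide[t].to_numpy(float)
        n_miss = int(np.isnan(col).sum())
        if n_miss:
            logger.info("trait %s: %d line values imputed with the trait mean", t, n_miss)
            col = np.where(np.isnan(col), np.nanmean(col), col)
        sd = col.std()
        if sd == 0:
            logger.warning("trait %s dropped from P: zero variance", t)
            continue
        cols.append((col - col.mean()) / sd)
        used.append(str(t))
    if not cols:
        raise KernelError("no usable traits for the physiological kernel")
    S = np.column_stack(cols)
    P = S @ S.T / S.shape[1]
    P = (P + P.T) / 2.0
    _check_psd(P, "P")
    return PhysioKernel(line_ids=[str(i) for i in wide.index], matrix=P, traits_used=used)


def _line_kernel_on_design(K: np.ndarray, kernel_lines: list[str], design: RecordDesign) -> np.ndarray:
    idx = {g: i for i, g in enumerate(kernel_lines)}
    missing = [g for g in design.line_levels if g not in idx]
    if missing:
        raise KernelError(f"genotypes absent from kernel: {missing[:5]}")
    rows = np.array([idx[g] for g in design.genotypes])
    return K[np.ix_(rows, rows)]


def expand_main_kernel(K, design: RecordDesign, name: str = "G_main") -> ExpandedKernel:
    """Map a line-level kernel to records: Z_g K Z_g'."""
    kernel_lines, mat = _as_line_kernel(K)
    expanded = _line_kernel_on_design(mat, kernel_lines, design)
    _check_psd(expanded, name)
    return ExpandedKernel(name=name, matrix=expanded)


def interaction_kernel(K, design: RecordDesign, name: str = "GE") -> ExpandedKernel:
    """Reaction-norm interaction covariance (Z_g K Z_g') o (Z_E Z_E')."""
    kernel_lines, mat = _as_line_kernel(K)
    main = _line_kernel_on_design(mat, kernel_lines, design)
    same_env = (design.env_index[:, None] == design.env_index[None, :]).astype(float)
    expanded = main * same_env
    _check_psd(expanded, name)
    return ExpandedKernel(name=name, matrix=expanded)


def _as_line_kernel(K) -> tuple[list[str], np.ndarray]:
    if hasattr(K, "line_ids") and hasattr(K, "matrix"):
        return list(K.line_ids), np.asarray(K.matrix, float)
    if isinstance(K, pd.DataFrame):
        return [str(i) for i in K.index], K.to_numpy(float)
    raise KernelError("kernel must carry line ids (GenomicKernel, PhysioKernel or DataFrame)")


def build_model_kernels(
    grm,
    physio: PhysioKernel | None,
    design: RecordDesign,
) -> dict[str, ExpandedKernel]:
    """All expanded kernels needed by the six prediction models."""
    kernels: dict[str, ExpandedKernel] = {}
    if grm is not None:
        kernels["G_main"] = expand_main_kernel(grm, design, "G_main")
        kernels["GE"] = interaction_kernel(grm, design, "GE")
    if physio is not None:
        kernels["P_main"] = expand_main_kernel(physio, design, "P_main")
        kernels["PE"] = interaction_kernel(physio, design, "PE")
    return kernels
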