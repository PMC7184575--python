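"""Marker quality control and genomic relationship matrix construction.

Dosage matrices are stored lines x markers with alternate-allele dosage in
{0, 1, 2} and an explicit missingness mask.  The genomic relationship matrix
(GRM) follows the VanRaden-style form G = XX'/n, where X is the
column-centered, column-standardized dosage matrix and n is the number of
markers.  Standardization uses the population (divide-by-N) standard
deviation so that trace(G)/n_lines is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class GenotypeDataError(ValueError):
    """Raised for malformed or degenerate genotype data."""


@dataclass
class MarkerMatrix:
    """Lines x markers dosage matrix with a missingness mask.

    Attributes
    ----------
    line_ids : list of str
        Ordered, unique line labels (rows).
    marker_ids : list of str
        Ordered, unique marker labels (columns).
    dosage : ndarray, shape (n_lines, n_markers), float
        Alternate-allele dosages; entries at masked positions are arbitrary.
    missing : ndarray of bool, same shape
        True where the call is missing.
    """

    line_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.dosage.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.dosage.shape != (len(self.line_ids), len(self.marker_ids)):
            raise GenotypeDataError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if self.missing.shape != self.dosage.shape:
            raise GenotypeDataError("missing mask shape mismatch")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise GenotypeDataError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise GenotypeDataError("duplicate marker ids")
        observed = self.dosage[~self.missing]
        if observed.size and not np.isin(np.round(observed, 6), [0.0, 1.0, 2.0]).all():
            # fractional dosages are permitted only after mean imputation
            if ((observed < 0) | (observed > 2)).any():
                raise GenotypeDataError("dosages must lie in [0, 2]")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return self.missing.mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency, computed on non-missing calls.

        Markers with no observed calls get MAF = nan.
        """
        dos = np.where(self.missing, np.nan, self.dosage)
        with np.errstate(invalid="ignore"):
            p = np.nanmean(dos, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, keep: np.ndarray) -> "MarkerMatrix":
        keep = np.asarray(keep)
        return MarkerMatrix(
            line_ids=list(self.line_ids),
            marker_ids=[self.marker_ids[j] for j in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.marker_ids[j] for j in keep],
            dosage=self.dosage[:, keep].copy(),
            missing=self.missing[:, keep].copy(),
        )

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path) -> None:
        """Write as lines x markers CSV; missing entries written empty."""
        dos = np.where(self.missing, np.nan, self.dosage)
        df = pd.DataFrame(dos, index=self.line_ids, columns=self.marker_ids)
        df.to_csv(path, index_label="line_id")

    @classmethod
    def from_csv(cls, path) -> "MarkerMatrix":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(dtype=float)
        missing = np.isnan(values)
        values = np.where(missing, 0.0, values)
        return cls(
            line_ids=[str(i) for i in df.index],
            marker_ids=[str(c) for c in df.columns],
            dosage=values,
            missing=missing,
        )

    def to_vcf(self, path) -> None:
        """Write as a minimal biallelic VCF (GT field only).

        Marker ids of the form ``chrom:pos`` are used for coordinates;
        otherwise markers are placed on chromosome "1" at consecutive
        1-based positions.
        """
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("##contig=<ID=1>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.line_ids)
                + "\n"
            )
            for j, mid in enumerate(self.marker_ids):
                if ":" in mid:
                    chrom, pos = mid.split(":", 1)
                else:
                    chrom, pos = "1", str(j + 1)
                calls = []
                for i in range(self.n_lines):
                    if self.missing[i, j]:
                        calls.append("./.")
                    else:
                        d = int(round(self.dosage[i, j]))
                        calls.append({0: "0/0", 1: "0/1", 2: "1/1"}[d])
                fh.write(
                    f"{chrom}\t{pos}\t{mid}\tA\tG\t.\tPASS\t.\tGT\t"
                    + "\t".join(calls)
                    + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "MarkerMatrix":
        """Read a biallelic VCF into a dosage matrix via cyvcf2.

        Multiallelic records are rejected; phased and unphased genotypes
        are both accepted.  Marker ids preserve the 1-based VCF coordinate
        as ``chrom:pos`` when the record carries no ID.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        line_ids = list(vcf.samples)
        marker_ids: list[str] = []
        rows: list[np.ndarray] = []
        miss: list[np.ndarray] = []
        for rec in vcf:
            if len(rec.ALT) != 1:
                raise GenotypeDataError(
                    f"multiallelic site at {rec.CHROM}:{rec.POS}; "
                    "only biallelic records are supported"
                )
            marker_ids.append(
                rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
            )
            gts = np.asarray(rec.genotype.array())[:, :2]
            m = (gts < 0).any(axis=1)
            d = gts.clip(min=0).sum(axis=1).astype(float)
            rows.append(d)
            miss.append(m)
        return cls(
            line_ids=line_ids,
            marker_ids=marker_ids,
            dosage=np.column_stack(rows) if rows else np.empty((len(line_ids), 0)),
            missing=np.column_stack(miss) if miss else np.empty((len(line_ids), 0), bool),
        )


@dataclass
class GenomicKernel:
    """Symmetric genomic relationship matrix over lines (G = XX'/n)."""

    line_ids: list[str]
    matrix: np.ndarray
    n_markers_used: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.line_ids)
        if self.matrix.shape != (n, n):
            raise GenotypeDataError("kernel shape does not match line ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise GenotypeDataError("kernel is not symmetric")
        w = np.linalg.eigvalsh(self.matrix)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise GenotypeDataError("kernel is not positive semi-definite")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.line_ids, columns=self.line_ids).to_csv(
            path, index_label="line_id"
        )

    @classmethod
    def from_csv(cls, path, n_markers_used: int = 0) -> "GenomicKernel":
        df = pd.read_csv(path, index_col=0)
        return cls([str(i) for i in df.index], df.to_numpy(float), n_markers_used)


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------


def filter_markers(
    m: MarkerMatrix, max_missing: float = 0.80, min_maf: float = 0.05
) -> MarkerMatrix:
    """Remove markers with too much missingness or too-rare minor alleles.

    A marker survives iff its missing fraction is <= ``max_missing`` and its
    MAF (on non-missing calls) is >= ``min_maf``; ties at the thresholds are
    retained.  Marker order is preserved.
    """
    if m.n_markers == 0:
        raise GenotypeDataError("empty marker matrix")
    miss_frac = m.missing_fraction()
    maf = m.maf()
    over_missing = miss_frac > max_missing
    below_maf = ~over_missing & (np.isnan(maf) | (maf < min_maf))
    keep = ~(over_missing | below_maf)
    logger.info(
        "filter_markers: %d removed for missingness > %.2f, %d for MAF < %.3f, %d retained",
        int(over_missing.sum()),
        max_missing,
        int(below_maf.sum()),
        min_maf,
        int(keep.sum()),
    )
    if not keep.any():
        raise GenotypeDataError("all markers removed by QC filters")
    out = m.subset_markers(keep)
    out.qc_counts = {  # type: ignore[attr-defined]
        "removed_missing": int(over_missing.sum()),
        "removed_maf": int(below_maf.sum()),
        "retained": int(keep.sum()),
    }
    return out


def impute_markers(m: MarkerMatrix, method: str = "column_mean") -> MarkerMatrix:
    """Replace missing calls; ``column_mean`` gives fractional dosages,
    ``major_allele`` the most frequent integer dosage."""
    if method not in ("column_mean", "major_allele"):
        raise ValueError(f"unknown imputation method {method!r}")
    dos = np.where(m.missing, np.nan, m.dosage)
    full_missing = np.isnan(dos).all(axis=0)
    if full_missing.any():
        bad = [m.marker_ids[j] for j in np.flatnonzero(full_missing)]
        raise GenotypeDataError(f"markers with all calls missing: {bad[:5]}")
    if method == "column_mean":
        fill = np.nanmean(dos, axis=0)
    else:
        fill = np.empty(m.n_markers)
        for j in range(m.n_markers):
            col = dos[:, j]
            vals, counts = np.unique(col[~np.isnan(col)], return_counts=True)
            fill[j] = vals[np.argmax(counts)]
    out_dos = np.where(np.isnan(dos), fill[None, :], dos)
    return MarkerMatrix(
        line_ids=list(m.line_ids),
        marker_ids=list(m.marker_ids),
        dosage=out_dos,
        missing=np.zeros_like(m.missing),
    )


def fisher_allelic_filter(m: MarkerMatrix, alpha: float = 0.001) -> MarkerMatrix:
    """Keep markers whose two alleles are *dependent* across inbred lines.

    For each marker a 2x2 table of reference/alternate allele presence per
    line is built (presence of an allele = dosage carrying at least one copy)
    and a two-sided Fisher exact test of independence is computed.  In a
    panel of inbreds a true biallelic locus shows strong negative association
    between the alleles (few heterozygotes), so the marker is retained iff
    P < ``alpha``.  Degenerate markers with an allele absent from every line
    are removed.
    """
    keep = np.zeros(m.n_markers, dtype=bool)
    n_degenerate = 0
    for j in range(m.n_markers):
        obs = ~m.missing[:, j]
        d = m.dosage[:, j]
        # presence of an allele in a line; a missing call carries neither
        ref_present = obs & (d <= 1)
        alt_present = obs & (d >= 1)
        n11 = int((ref_present & alt_present).sum())  # heterozygous lines
        n10 = int((ref_present & ~alt_present).sum())
        n01 = int((~ref_present & alt_present).sum())
        n00 = int((~ref_present & ~alt_present).sum())
        if alt_present.sum() == 0 or ref_present.sum() == 0:
            n_degenerate += 1
            continue
        _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
        keep[j] = p < alpha
    logger.info(
        "fisher_allelic_filter: retained %d / %d markers (%d degenerate)",
        int(keep.sum()),
        m.n_markers,
        n_degenerate,
    )
    if not keep.any():
        raise GenotypeDataError("Fisher allelic filter removed every marker")
    out = m.subset_markers(keep)
    out.qc_counts = {  # type: ignore[attr-defined]
        "retained": int(keep.sum()),
        "removed": int(m.n_markers - keep.sum()),
        "degenerate": n_degenerate,
    }
    return out


def compute_grm(m: MarkerMatrix, ddof: int = 0) -> GenomicKernel:
    """Genomic relationship matrix G = XX'/n from the centered, standardized
    dosage matrix.

    Parameters
    ----------
    m : MarkerMatrix
        Complete (imputed) matrix; every column must have nonzero variance.
    ddof : int
        Degrees of freedom for the standard deviation (0 = population SD,
        the default, which makes the mean diagonal exactly 1).
    """
    if m.missing.any():
        raise GenotypeDataError("compute_grm requires an imputed (complete) matrix")
    X = m.dosage - m.dosage.mean(axis=0, keepdims=True)
    sd = m.dosage.std(axis=0, ddof=ddof)
    zero = sd == 0
    if zero.any():
        bad = [m.marker_ids[j] for j in np.flatnonzero(zero)]
        raise GenotypeDataError(f"zero-variance markers (filter first): {bad[:5]}")
    X = X / sd
    G = X @ X.T / m.n_markers
    G = (G + G.T) / 2.0
    return GenomicKernel(line_ids=list(m.line_ids), matrix=G, n_markers_used=m.n_markers)


def qc_report(m: MarkerMatrix) -> dict:
    """Summary counts for a QC report."""
    return {
        "n_lines": m.n_lines,
        "n_markers": m.n_markers,
        "mean_missing_fraction": float(m.missing_fraction().mean()) if m.n_markers else 0.0,
        "qc_counts": getattr(m, "qc_counts", {}),
    }
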