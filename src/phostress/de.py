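"""RPKM normalization, negative-binomial differential expression, clustering.

The differential-expression procedure is deliberately simple and fully
specified (no dispersion shrinkage, no outlier filtering), so that every
number it produces is reproducible from the definitions below:

1. Size factors by median-of-ratios: each sample's factor is the median over
   genes of its count divided by the gene's geometric mean across samples
   (genes with any zero count are excluded from the median).
2. Per gene, normalized group means ``m1`` (replete) and ``m2`` (deplete);
   ``log2fc = log2((m2 + c) / (m1 + c))`` with pseudocount ``c = 0.5``.
3. Gene-wise method-of-moments dispersion ``phi = (s² − m) / m²`` averaged
   over the two conditions and floored at 1e-8, under the NB variance model
   ``Var = m + phi·m²``.
4. Delta-method standard error of log2fc from ``Var(m_c) = (m_c + phi·m_c²)/n_c``;
   the Wald statistic is referred to a Student-t distribution with
   ``n1 + n2 − 2`` degrees of freedom (a small-sample calibration: with
   gene-wise dispersion at n = 3 a normal reference is anticonservative).
5. Benjamini–Hochberg adjustment; significance at FDR < alpha (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError, FormatError, UnknownGeneError

CONDITIONS = ("replete", "deplete")
DEFAULT_ALPHA = 0.05
DEFAULT_MAX_GAP = 50
PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Gene-by-sample read counts with gene lengths and sample metadata.

    ``totals`` are total mapped reads per sample (host + phage), which may
    exceed the column sums of the analyzed gene subset; they feed the RPKM
    denominator.  ``conditions`` take values in ``{"replete", "deplete"}``.
    """

    genes: list[str]
    lengths: np.ndarray
    samples: list[str]
    conditions: list[str]
    totals: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.totals = np.asarray(self.totals, dtype=float)
        self.counts = np.asarray(self.counts)
        G, S = len(self.genes), len(self.samples)
        if self.counts.shape != (G, S):
            raise FormatError(f"counts shape {self.counts.shape} != ({G}, {S})")
        if len(self.lengths) != G or (self.lengths < 1).any():
            raise FormatError("need one length >= 1 nt per gene")
        if len(self.conditions) != S or len(self.totals) != S:
            raise FormatError("need one condition and one total per sample")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise FormatError(f"unknown condition labels: {sorted(unknown)}")
        if (self.counts < 0).any():
            raise FormatError("counts must be non-negative")
        if (self.totals < np.asarray(self.counts).sum(axis=0)).any():
            raise FormatError("per-sample totals smaller than column sums")

    def condition_columns(self, condition: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.conditions) if c == condition])


def rpkm(counts: np.ndarray, lengths: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Reads per kilobase per million mapped reads, element-wise.

    ``RPKM[g, j] = counts[g, j] / (lengths[g]·1e-3 · totals[j]·1e-6)``.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if (lengths < 1).any():
        raise FormatError("gene lengths must be >= 1")
    if (totals < 1).any():
        bad = int(np.flatnonzero(totals < 1)[0])
        raise ZeroDivisionError(f"sample {bad} has zero total mapped reads")
    return counts / (lengths[:, None] * 1e-3 * totals[None, :] * 1e-6)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (one per sample).

    Genes with a zero count in any sample are excluded from the median; if no
    gene survives, factors fall back to column-sum ratios.
    """
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=1)
    if positive.any():
        logc = np.log(counts[positive])
        ref = logc.mean(axis=1, keepdims=True)
        return np.exp(np.median(logc - ref, axis=0))
    sums = counts.sum(axis=0)
    return sums / sums.mean()


def nb_wald_test(matrix: CountMatrix, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-gene NB Wald test of deplete vs replete expression.

    Returns a DataFrame with columns ``gene, base_mean, log2fc, se, p, fdr,
    significant`` in the input gene order.  Requires >= 2 replicates per
    condition.  Genes with identical normalized means in both groups get
    log2fc 0 and p 1.
    """
    i1 = matrix.condition_columns("replete")
    i2 = matrix.condition_columns("deplete")
    if len(i1) < 2 or len(i2) < 2:
        raise DesignError("need >= 2 replicates per condition")
    sf = size_factors(matrix.counts)
    norm = matrix.counts / sf[None, :]
    a, b = norm[:, i1], norm[:, i2]
    n1, n2 = len(i1), len(i2)
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi1 = np.where(m1 > 0, (v1 - m1) / m1**2, 0.0)
        phi2 = np.where(m2 > 0, (v2 - m2) / m2**2, 0.0)
    phi = np.maximum((phi1 + phi2) / 2.0, DISPERSION_FLOOR)

    c = PSEUDOCOUNT
    log2fc = np.log2((m2 + c) / (m1 + c))
    var_m1 = (m1 + phi * m1**2) / n1
    var_m2 = (m2 + phi * m2**2) / n2
    se = np.sqrt(var_m1 / (m1 + c) ** 2 + var_m2 / (m2 + c) ** 2) / np.log(2)
    se = np.maximum(se, 1e-12)
    wald = log2fc / se
    p = 2.0 * stats.t.sf(np.abs(wald), df=n1 + n2 - 2)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    fdr = bh_fdr(p)
    return pd.DataFrame(
        {
            "gene": matrix.genes,
            "base_mean": (m1 + m2) / 2,
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "fdr": fdr,
            "significant": fdr < alpha,
        }
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise FormatError("p-values must be a non-empty 1-D array")
    if (p <= 0).any() or (p > 1).any():
        raise FormatError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def de_filter(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    exclude: set[str] | None = None,
) -> list[str]:
    """Genes with FDR < alpha, minus excluded ids, sorted by FDR ascending."""
    exclude = exclude or set()
    gene_col = "cds_id" if "cds_id" in results.columns else "gene"
    sig = results[(results["fdr"] < alpha) & ~results[gene_col].isin(exclude)]
    return list(sig.sort_values("fdr", kind="stable")[gene_col])


@dataclass
class GeneCluster:
    """A run of genomically adjacent genes (single-linkage, gap <= max_gap)."""

    members: list[str]
    span: tuple[int, int]
    size: int = field(init=False)

    def __post_init__(self) -> None:
        self.size = len(self.members)


def cluster_de_genes(
    gene_ids,
    coordinates: pd.DataFrame,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[GeneCluster]:
    """Single-linkage clustering of genes along the genomic line.

    ``coordinates`` needs columns identifying each gene (``cds_id`` or
    ``gene``) plus ``start``/``stop``.  Sorted by start, a gene joins the
    current cluster iff ``next.start − prev.stop − 1 <= max_gap`` (overlap
    gives a non-positive gap).  Clusters are returned largest first; strand
    is ignored.
    """
    idcol = "cds_id" if "cds_id" in coordinates.columns else "gene"
    table = coordinates.set_index(idcol)
    missing = [g for g in gene_ids if g not in table.index]
    if missing:
        raise UnknownGeneError(f"no coordinates for: {missing}")
    rows = sorted(
        ((int(table.at[g, "start"]), int(table.at[g, "stop"]), g) for g in gene_ids)
    )
    clusters: list[GeneCluster] = []
    current: list[tuple[int, int, str]] = []
    for row in rows:
        if current and row[0] - max(stop for _, stop, _ in current) - 1 > max_gap:
            clusters.append(_close(current))
            current = []
        current.append(row)
    if current:
        clusters.append(_close(current))
    clusters.sort(key=lambda c: (-c.size, c.span[0]))
    return clusters



def _close(rows: list[tuple[int, int, str]]) -> GeneCluster:
    return GeneCluster(
        members=[g for _, _, g in rows],
        span=(min(s for s, _, _ in rows), max(e for _, e, _ in rows)),
    )
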