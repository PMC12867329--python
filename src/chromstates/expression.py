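"""Association of chromatin states with transcription.

Genes are ranked by expression (TPM in a reference tissue) or by variability
(CV = sd/mean across samples), grouped into equal-sized rank bins, and the
mean proportion of each chromatin state over each gene's promoter (1 kb
upstream of the TSS by default) or gene body is profiled across bins.
Tissue-specific genes are called by the two-fold rule: TPM in one tissue at
least ``fold`` times the gene's mean across all tissues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GeneModelSet, GenomicInterval, StateSegmentation
from .core import UNASSIGNED

logger = logging.getLogger("chromstates")


def compute_cv(expr: ExpressionMatrix) -> pd.Series:
    """Coefficient of variation per gene: sample sd / mean TPM across samples.

    Genes with mean 0 get NaN (undefined; excluded downstream, logged).
    """
    if expr.tpm.shape[1] < 2:
        raise ValueError("CV needs at least two samples")
    mean = expr.tpm.mean(axis=1)
    sd = expr.tpm.std(axis=1, ddof=1)
    cv = sd / mean.replace(0.0, np.nan)
    n_undef = int(cv.isna().sum())
    if n_undef:
        logger.info("compute_cv: %d genes with mean 0 have undefined CV", n_undef)
    return cv.rename("cv")


@dataclass
class GeneBins:
    """Rank-based equal-size gene bins (bin index 1..B)."""

    assignment: pd.Series  # gene -> bin
    statistic: str  # "TPM" | "CV"
    B: int

    def members(self, b: int) -> list[str]:
        return list(self.assignment.index[self.assignment == b])


def bin_genes(values: pd.Series, B: int = 20, statistic: str = "TPM") -> GeneBins:
    """Group genes into B equal-sized bins by ascending value.

    Ties break by stable gene-id order; NaN values are dropped with a log
    line.  Bin sizes differ by at most one.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    vals = values.dropna()
    if len(vals) < B:
        raise ValueError(f"need >= {B} genes with defined values, got {len(vals)}")
    if len(vals) < len(values):
        logger.info("bin_genes: dropped %d genes with undefined values",
                    len(values) - len(vals))
    order = vals.sort_values(kind="stable").index  # stable: ties keep id order
    # spread n genes over B bins, sizes differing by <= 1 (larger bins first)
    n = len(order)
    base, extra = divmod(n, B)
    sizes = [base + (1 if i < extra else 0) for i in range(B)]
    bins = np.repeat(np.arange(1, B + 1), sizes)
    return GeneBins(
        assignment=pd.Series(bins, index=order, name="bin"),
        statistic=statistic,
        B=B,
    )


def promoter_regions(
    genes: GeneModelSet,
    length: int = 1000,
    chrom_sizes: dict[str, int] | None = None,
) -> dict[str, GenomicInterval]:
    """The ``length`` bp region immediately upstream of each TSS, strand-aware.

    Clipped at chromosome edges; fully clipped promoters are dropped with a
    warning.
    """
    out: dict[str, GenomicInterval] = {}
    clipped = 0
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - length, g.tss
        else:
            start, end = g.tss, g.tss + length
        size = chrom_sizes.get(g.chrom) if chrom_sizes else None
        s, e = max(0, start), (min(end, size) if size is not None else end)
        if (e - s) < (end - start):
            clipped += 1
        if s >= e:
            logger.warning("promoter of %s fully clipped, dropped", g.gene_id)
            continue
        out[g.gene_id] = GenomicInterval(g.chrom, s, e, g.strand)
    if clipped:
        logger.info("promoter_regions: %d promoters clipped at chromosome edges",
                    clipped)
    return out


def gene_body_regions(genes: GeneModelSet) -> dict[str, GenomicInterval]:
    """Gene intervals themselves, keyed by id (for gene-body profiles)."""
    return {g.gene_id: g.interval for g in genes}


def state_proportion_profile(
    regions: dict[str, GenomicInterval],
    bins: GeneBins,
    seg: StateSegmentation,
) -> pd.DataFrame:
    """Mean per-state bp proportion of member genes' regions, per bin.

    Rows (bins) sum to 1 over assigned states for genes whose regions carry
    assigned chromatin; genes without a region are excluded with a log line.
    """
    states = seg.states_assigned()
    codes = [seg.state_code(s) for s in states]
    prof = np.zeros((bins.B, len(states)))
    for b in range(1, bins.B + 1):
        members = bins.members(b)
        props = []
        missing = 0
        for gid in members:
            region = regions.get(gid)
            if region is None:
                missing += 1
                continue
            bp = seg.overlap_bp(region.chrom, region.start, region.end)
            bp = bp[codes].astype(float)
            total = bp.sum()
            if total > 0:
                props.append(bp / total)
        if missing:
            logger.info("bin %d: %d genes without a region excluded", b, missing)
        if props:
            prof[b - 1] = np.mean(props, axis=0)
    return pd.DataFrame(prof, index=pd.RangeIndex(1, bins.B + 1, name="bin"),
                        columns=states)


def tissue_specific_genes(
    expr: ExpressionMatrix, fold: float = 2.0
) -> pd.DataFrame:
    """Call genes tissue-specific by the fold-over-mean rule.

    A gene is specific to tissue t iff its mean TPM in t is at least ``fold``
    times its mean across all tissues.  Genes qualifying in several tissues
    are all reported (``n_tissues`` column lets callers drop them).  Genes
    with zero mean everywhere are never called.
    """
    tm = expr.tissue_means()
    mean = tm.mean(axis=1)
    rows = []
    for gene in tm.index:
        mu = mean[gene]
        if mu == 0:
            continue
        hits = tm.columns[tm.loc[gene] >= fold * mu]
        for t in hits:
            rows.append((gene, t, len(hits)))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "n_tissues"])


def group_expression_summary(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    gene_groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-group asinh(TPM) distribution summaries for two conditions."""
    rows = []
    for name, members in gene_groups.items():
        for cond, expr in (("a", expr_a), ("b", expr_b)):
            present = [g for g in members if g in expr.tpm.index]
            if not present:
                logger.warning("group %r empty in condition %s, skipped", name, cond)
                continue
            v = np.arcsinh(expr.tpm.loc[present].to_numpy().ravel())
            rows.append(
                (name, cond, len(present), float(np.mean(v)), float(np.median(v)),
                 float(np.quantile(v, 0.25)), float(np.quantile(v, 0.75)))
            )
    return pd.DataFrame(
        rows, columns=["group", "condition", "n", "mean", "median", "q25", "q75"]
    )
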