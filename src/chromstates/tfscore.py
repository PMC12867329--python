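"""TF occupancy of chromatin states and co-expression-based activity scoring.

Occupancy of a TF in state *s* is the bp-level enrichment

    (a_s / b) / (c_s / d)

with a_s the peak bp falling in s, b the total peak bp, c_s the genomic bp of
s, and d the total assigned genome.  Activity goes further: each peak is
assigned a state by its centre bin and a target gene by a promoter / gene
body / nearest-TSS cascade; targets are intersected with the TF's
co-expressed genes (ATTED-style ranks, positive score < 2000 and negative
score > max - 1000, both configurable) and the per-state overlap is tested
with a one-sided (greater) exact hypergeometric test.  The activity score is

    -log10(p) + log2(odds ratio + 1)

normalised per TF by its maximum; TFs whose maximum raw score is below 8 are
dropped as low-confidence.  Retained TFs are clustered hierarchically on the
normalised score matrix and clusters are tested for TF-family enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import UNASSIGNED, GeneModelSet, PeakSet, StateSegmentation

logger = logging.getLogger("chromstates")

_P_FLOOR = 1e-300  # keep -log10(p) finite for vanishing tail probabilities


# ---------------------------------------------------------------------------
# peak-state assignment & occupancy
# ---------------------------------------------------------------------------

def assign_peak_states(peaks: PeakSet, seg: StateSegmentation) -> list[str]:
    """State label of the bin containing each peak's centre."""
    peaks.validate_against(seg.chrom_sizes)
    labels = []
    for p in peaks.peaks:
        code = int(seg.state_at(p.chrom, p.center)[0])
        labels.append(seg.states[code])
    return labels


def occupancy_enrichment(peaks: PeakSet, seg: StateSegmentation) -> pd.DataFrame:
    """bp-level over/under-representation of a TF's peaks per state.

    Returns a frame indexed by assigned state with columns a_s, b, c_s, d and
    enrichment = (a_s/b)/(c_s/d); states with c_s = 0 get NaN enrichment.
    Peak bp on unassigned genome are excluded from b.
    """
    if len(peaks) == 0:
        raise ValueError(f"{peaks.tf_id}: empty peak set")
    peaks.validate_against(seg.chrom_sizes)
    a = np.zeros(len(seg.states), dtype=np.int64)
    for p in peaks.peaks:
        a += seg.overlap_bp(p.chrom, p.start, p.end)
    a = pd.Series(a, index=seg.states).loc[seg.states_assigned()]
    b = int(a.sum())
    if b == 0:
        raise ValueError(f"{peaks.tf_id}: peaks cover no assigned genome")
    c = seg.state_bp().loc[seg.states_assigned()]
    d = int(c.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = (a / b) / (c / d).replace(0, np.nan)
    return pd.DataFrame(
        {"a_s": a, "b": b, "c_s": c, "d": d, "enrichment": enr}
    )


# ---------------------------------------------------------------------------
# target annotation
# ---------------------------------------------------------------------------

class _TSSIndex:
    """Sorted per-chromosome TSS positions for nearest-gene lookups."""

    def __init__(self, genes: GeneModelSet) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, list]] = {}
        tmp: dict[str, list] = {}
        for g in genes:
            base = g.tss if g.strand == "+" else g.tss - 1
            tmp.setdefault(g.chrom, []).append((base, g.gene_id, g))
        for chrom, rows in tmp.items():
            rows.sort(key=lambda r: (r[0], r[1]))
            self._by_chrom[chrom] = (np.array([r[0] for r in rows]), rows)

    def nearest(self, chrom: str, pos: int):
        """(distance, gene) of the nearest TSS; ties to the smaller gene id."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        bases, rows = entry
        i = np.searchsorted(bases, pos)
        cands = []
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(rows):
                base, gid, g = rows[j]
                cands.append((abs(base - pos), gid, g))
        cands.sort()
        return (cands[0][0], cands[0][2]) if cands else None


def annotate_targets(
    peaks: PeakSet,
    peak_states: list[str],
    genes: GeneModelSet,
    promoter_window: tuple[int, int] = (1000, 100),
    max_distance: int = 10_000,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Assign each peak a target gene and collect per-state target sets.

    Rule cascade on the peak centre: (1) inside a gene's promoter window
    (``promoter_window`` = (upstream, downstream) bp around the TSS, strand
    oriented) -> that gene, nearest TSS on ties; (2) inside a gene body ->
    that gene; (3) nearest TSS within ``max_distance`` bp; else unassigned.
    """
    up, down = promoter_window
    tss_index = _TSSIndex(genes)
    promoters: dict[str, list] = {}
    bodies: dict[str, list] = {}
    for g in genes:
        base = g.tss if g.strand == "+" else g.tss - 1
        if g.strand == "+":
            win = (base - up, base + down)
        else:
            win = (base - down + 1, base + up + 1)
        promoters.setdefault(g.chrom, []).append((win[0], win[1], base, g))
        bodies.setdefault(g.chrom, []).append(
            (g.interval.start, g.interval.end, base, g)
        )

    rows = []
    targets: dict[str, set[str]] = {}
    for p, state in zip(peaks.peaks, peak_states):
        center = p.center
        gene, rule = None, "unassigned"
        hits = [
            (abs(base - center), g.gene_id, g)
            for s, e, base, g in promoters.get(p.chrom, [])
            if s <= center < e
        ]
        if hits:
            hits.sort()
            gene, rule = hits[0][2], "promoter"
        else:
            hits = [
                (abs(base - center), g.gene_id, g)
                for s, e, base, g in bodies.get(p.chrom, [])
                if s <= center < e
            ]
            if hits:
                hits.sort()
                gene, rule = hits[0][2], "gene_body"
            else:
                near = tss_index.nearest(p.chrom, center)
                if near is not None and near[0] <= max_distance:
                    gene, rule = near[1], "nearest_tss"
        gid = gene.gene_id if gene is not None else None
        rows.append((p.chrom, p.start, p.end, state, gid, rule))
        if gid is not None:
            targets.setdefault(state, set()).add(gid)
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "state", "gene_id", "rule"]
    )
    return df, targets


# ---------------------------------------------------------------------------
# co-expression filter & activity scoring
# ---------------------------------------------------------------------------

def coexpression_filter(
    scores: pd.Series,
    positive_threshold: float = 2000,
    negative_tail: float = 1000,
) -> tuple[set[str], set[str]]:
    """Positively and negatively co-expressed gene sets for one TF.

    ``scores`` is the TF's gene -> rank-like score series (lower = more
    positively co-expressed).  Positive set: score < positive_threshold
    (strict).  Negative set: score > max(score) - negative_tail (strict),
    the maximum taken over this TF's own entries.
    """
    positive = set(scores.index[scores < positive_threshold])
    negative = set(scores.index[scores > scores.max() - negative_tail])
    return positive, negative


def _contingency(k: int, m: int, q: int, N: int, literal_table: bool = False):
    if literal_table:
        # the printed layout: (targets ∩ co-expressed, targets; co-expressed, N)
        return np.array([[k, m], [q, N]], dtype=float)
    return np.array([[k, m - k], [q - k, N - m - q + k]], dtype=float)


def _odds_ratio(table: np.ndarray) -> float:
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5  # Haldane correction keeps the OR finite
    return float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))


def activity_score(
    targets_by_state: dict[str, set[str]],
    coexpressed: set[str],
    N_genes: int,
    states: list[str] | None = None,
    literal_table: bool = False,
) -> pd.DataFrame:
    """Per-state activity of one TF from target / co-expressed overlap.

    For each state: k = |targets ∩ co-expressed|, m = |targets in state|,
    q = |co-expressed|, N = gene universe.  One-sided (greater) exact
    hypergeometric p on the margins-derived 2x2 table, sample odds ratio
    (Haldane 0.5 on zero cells), and raw score -log10(p) + log2(OR + 1).
    States without targets are reported with p = 1, OR = 0, score 0.
    """
    if states is None:
        states = sorted(targets_by_state)
    q = len(coexpressed)
    rows = []
    for state in states:
        tg = targets_by_state.get(state, set())
        m = len(tg)
        k = len(tg & coexpressed)
        if m == 0:
            rows.append((state, 0, 0, q, N_genes, 1.0, 0.0, 0.0))
            continue
        if m > N_genes or q > N_genes:
            raise ValueError("target/co-expressed sets exceed the gene universe")
        p = float(hypergeom.sf(k - 1, N_genes, q, m))
        orr = _odds_ratio(_contingency(k, m, q, N_genes, literal_table))
        raw = raw_score(p, orr)
        rows.append((state, k, m, q, N_genes, p, orr, raw))
    return pd.DataFrame(
        rows,
        columns=["state", "k", "m", "q", "N", "p_value", "odds_ratio", "raw_score"],
    ).set_index("state")


def raw_score(p: float, odds_ratio: float) -> float:
    """-log10(p) + log2(OR + 1), the per-state TF activity score."""
    return float(-np.log10(max(p, _P_FLOOR)) + np.log2(odds_ratio + 1.0))


def build_score_matrix(
    results: dict[str, pd.DataFrame], min_max_score: float = 8.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalised TF x state score matrix after the low-confidence filter.

    TFs whose maximum raw score is strictly below ``min_max_score`` are
    dropped; remaining rows are divided by their own maximum (so every
    retained row has max 1).  Returns (matrix, dropped frame with reasons).
    """
    if not results:
        raise ValueError("no activity results supplied")
    raw = pd.DataFrame(
        {tf: res["raw_score"] for tf, res in results.items()}
    ).T.sort_index()
    maxes = raw.max(axis=1)
    keep = maxes >= min_max_score
    dropped = pd.DataFrame(
        {"max_raw_score": maxes[~keep],
         "reason": f"max raw score < {min_max_score}"}
    )
    if not keep.any():
        raise ValueError(
            f"all {len(raw)} TFs fall below the max-score threshold "
            f"{min_max_score}"
        )
    mat = raw[keep].div(maxes[keep], axis=0)
    return mat, dropped


# ---------------------------------------------------------------------------
# clustering & family enrichment
# ---------------------------------------------------------------------------

@dataclass
class TFClusterModel:
    """Normalised score matrix with its dendrogram and flat cluster labels."""

    matrix: pd.DataFrame  # TF x state normalised scores (retained TFs)
    merge_table: pd.DataFrame  # scipy linkage as (node1, node2, height, size)
    labels: pd.Series  # TF -> cluster id in 1..k
    k: int
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)


def cluster_tfs(
    matrix: pd.DataFrame,
    k: int,
    metric: str = "euclidean",
    method: str = "complete",
    dropped: pd.DataFrame | None = None,
) -> TFClusterModel:
    """Hierarchical clustering of TFs on their normalised activity profiles."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(matrix) < k:
        raise ValueError(f"need >= {k} TFs, got {len(matrix)}")
    Z = hierarchy.linkage(pdist(matrix.to_numpy(), metric=metric), method=method)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return TFClusterModel(
        matrix=matrix,
        merge_table=pd.DataFrame(Z, columns=["node1", "node2", "height", "size"]),
        labels=pd.Series(flat, index=matrix.index, name="cluster"),
        k=k,
        dropped=dropped if dropped is not None else pd.DataFrame(),
    )


def family_enrichment(
    labels: pd.Series, families: pd.Series
) -> pd.DataFrame:
    """Fisher-style (one-sided greater) family enrichment per cluster.

    For each (family, cluster): k = in-family TFs in the cluster, m = cluster
    size, q = family size, N = clustered TFs, with the same margins-derived
    2x2 convention as the activity score.  Benjamini-Hochberg q-values are
    reported alongside raw p.  TFs without a family label count as
    ``unknown``.
    """
    fam = families.reindex(labels.index).fillna("unknown")
    N = len(labels)
    rows = []
    for family in sorted(fam.unique()):
        in_fam = set(fam.index[fam == family])
        q = len(in_fam)
        for cluster in sorted(labels.unique()):
            members = set(labels.index[labels == cluster])
            m = len(members)
            k = len(members & in_fam)
            p = float(hypergeom.sf(k - 1, N, q, m))
            orr = _odds_ratio(_contingency(k, m, q, N))
            rows.append((family, int(cluster), k, m, q, N, p, orr))
    df = pd.DataFrame(
        rows,
        columns=["family", "cluster", "k", "m", "q", "N", "p_value", "odds_ratio"],
    )
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# TSS-relative binding histograms
# ---------------------------------------------------------------------------

def tss_binding_histogram(
    peaks_by_cluster: dict[int, list[PeakSet]],
    genes: GeneModelSet,
    window: int = 2000,
    nbins: int = 40,
) -> pd.DataFrame:
    """Per-cluster histogram of peak-centre distances to the nearest TSS.

    Distance is signed in the nearest gene's reading direction (negative =
    upstream of the TSS); peaks farther than ``window`` bp are not counted.
    Returns a long frame (cluster, bin_left, bin_right, count).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    index = _TSSIndex(genes)
    edges = np.linspace(-window, window, nbins + 1)
    rows = []
    for cluster, peak_sets in sorted(peaks_by_cluster.items()):
        dists = []
        for ps in peak_sets:
            for p in ps.peaks:
                near = index.nearest(p.chrom, p.center)
                if near is None:
                    continue
                _, g = near
                base = g.tss if g.strand == "+" else g.tss - 1
                d = p.center - base if g.strand == "+" else base - p.center
                if -window <= d <= window:
                    dists.append(d)
        counts, _ = np.histogram(dists, bins=edges)
        for i in range(nbins):
            rows.append((cluster, float(edges[i]), float(edges[i + 1]),
                         int(counts[i])))
    return pd.DataFrame(rows, columns=["cluster", "bin_left", "bin_right", "count"])
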