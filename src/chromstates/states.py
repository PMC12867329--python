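"""Per-state genome statistics and positional analyses.

The central quantity is the neighbourhood enrichment of each chromatin state
around stranded anchors (TSS/TTS):

    enrichment(s, k) = P(bin at signed offset k is state s | anchors)
                       / P(random assigned bin is state s)

computed on the segmentation's own bin grid, with offsets mirrored for minus
strand anchors.  States are then classified into the four canonical chromatin
domains (H constitutive heterochromatin, F facultative heterochromatin,
E euchromatin, I intergenic) by an explicit rule cascade over emission
probabilities and TE overlap, and numbered within each domain by their
position of maximal TSS enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import UNASSIGNED, GeneModelSet, StateSegmentation, EmissionMatrix

logger = logging.getLogger("chromstates")

#: default mark sets driving the domain rule cascade; matched against the
#: emission matrix columns actually present
HETEROCHROMATIN_MARKS = (
    "H3K9me1", "H3K9me2", "H3K27me1", "H2A.W", "H2A.M", "H2A.M.1", "H2A.M.2",
)
FACULTATIVE_MARKS = ("H3K27me3", "H2A.Z", "H2Aub")


# ---------------------------------------------------------------------------
# coverage & composition
# ---------------------------------------------------------------------------

def genome_coverage(seg: StateSegmentation) -> pd.Series:
    """Percent of the assigned genome covered by each state.

    (bp covered by state / total assigned bp) * 100; the reserved
    ``unassigned`` label is excluded from both numerator and denominator.
    """
    bp = seg.state_bp()
    bp = bp.loc[seg.states_assigned()]
    total = bp.sum()
    if total == 0:
        raise ValueError("segmentation has no assigned base pairs")
    return (bp / total * 100.0).rename("percent")


def feature_composition(
    seg: StateSegmentation, genes: GeneModelSet
) -> pd.DataFrame:
    """bp proportions of each state over genomic feature classes.

    Every base pair receives exactly one class, with overlap priority
    protein_coding > TE > other > intergenic, so each state's row sums to 1.
    """
    classes = ["protein_coding", "TE", "other", "intergenic"]
    prio = {"intergenic": 0, "other": 1, "TE": 2, "protein_coding": 3}
    n_states = len(seg.states)
    counts = np.zeros((n_states, len(classes)), dtype=np.int64)

    for chrom, size in seg.chrom_sizes.items():
        paint = np.zeros(size, dtype=np.int8)  # class priority per bp
        for g in genes:
            if g.chrom != chrom:
                continue
            p = prio[g.feature_class]
            s, e = g.interval.start, min(g.interval.end, size)
            paint[s:e] = np.maximum(paint[s:e], p)
        starts, ends, codes = seg.runs[chrom]
        for s, e, c in zip(starts, ends, codes):
            cls_counts = np.bincount(paint[s:e], minlength=4)
            # priority index -> class column
            counts[c, 3] += cls_counts[0]  # intergenic
            counts[c, 2] += cls_counts[1]  # other
            counts[c, 1] += cls_counts[2]  # TE
            counts[c, 0] += cls_counts[3]  # protein_coding
    df = pd.DataFrame(counts, index=seg.states, columns=classes)
    df = df.loc[seg.states_assigned()]
    totals = df.sum(axis=1)
    if (totals == 0).any():
        logger.warning("states with zero bp in composition: %s",
                       list(df.index[totals == 0]))
    return df.div(totals.replace(0, np.nan), axis=0)


# ---------------------------------------------------------------------------
# neighbourhood enrichment
# ---------------------------------------------------------------------------

@dataclass
class NeighbourhoodMatrix:
    """States x signed bin offsets fold-enrichment around anchors."""

    enrichment: pd.DataFrame  # states x offsets (-L..+L)
    anchor_kind: str  # TSS | TTS
    L: int
    n_anchors: pd.Series = field(default=None)  # anchors counted per offset
    genome_fraction: pd.Series = field(default=None)  # per-state bin fraction

    def argmax_offset(self, state: str) -> int:
        row = self.enrichment.loc[state]
        return int(row.idxmax())


def extract_anchors(
    genes: GeneModelSet, kind: str = "TSS"
) -> list[tuple[str, int, str]]:
    """Stranded anchor base positions for TSS or TTS.

    The anchor is the first (TSS) or last (TTS) transcribed base, so
    coordinates derived from an interval's exclusive end are shifted by -1.
    """
    if kind not in {"TSS", "TTS"}:
        raise ValueError("anchor kind must be TSS or TTS")
    out = []
    for g in genes:
        if kind == "TSS":
            pos = g.tss if g.strand == "+" else g.tss - 1
        else:
            pos = g.tts - 1 if g.strand == "+" else g.tts
        out.append((g.chrom, pos, g.strand))
    return out


def neighbourhood_enrichment(
    seg: StateSegmentation,
    anchors: GeneModelSet | list[tuple[str, int, str]],
    L: int = 10,
    anchor_kind: str = "TSS",
) -> NeighbourhoodMatrix:
    """Fold enrichment of each state at signed bin offsets -L..+L from anchors.

    Offsets are mirrored for minus-strand anchors (offset +1 is always the
    bin downstream of the anchor in the gene's reading direction).  Anchors
    whose offset bin falls outside the chromosome, or on an ``unassigned``
    bin, are excluded from that offset's denominator.  States with zero
    genome fraction get NaN rather than infinity.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if isinstance(anchors, GeneModelSet):
        anchors = extract_anchors(anchors, kind=anchor_kind)

    states = seg.states
    n_states = len(states)
    unassigned_code = states.index(UNASSIGNED) if seg.has_unassigned else -1

    # genome background: fraction of assigned bins per state
    bin_counts = np.zeros(n_states, dtype=np.int64)
    bin_codes = {c: seg.bin_codes(c) for c in seg.chrom_sizes}
    for codes in bin_codes.values():
        np.add.at(bin_counts, codes, 1)
    if unassigned_code >= 0:
        bin_counts[unassigned_code] = 0
    genome_frac = bin_counts / bin_counts.sum()

    offsets = np.arange(-L, L + 1)
    hits = np.zeros((n_states, len(offsets)), dtype=np.int64)
    denom = np.zeros(len(offsets), dtype=np.int64)
    for chrom, pos, strand in anchors:
        if chrom not in seg.chrom_sizes:
            raise ValueError(f"anchor on unknown chromosome {chrom!r}")
        codes = bin_codes[chrom]
        bin0 = pos // seg.bin_size
        sign = 1 if strand != "-" else -1
        bins = bin0 + sign * offsets
        ok = (bins >= 0) & (bins < len(codes))
        got = codes[bins[ok]]
        keep = got != unassigned_code
        cols = np.nonzero(ok)[0][keep]
        np.add.at(hits, (got[keep], cols), 1)
        np.add.at(denom, cols, 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        anchor_frac = hits / np.where(denom > 0, denom, np.nan)
        enr = anchor_frac / np.where(genome_frac > 0, genome_frac, np.nan)[:, None]
    df = pd.DataFrame(enr, index=states, columns=offsets)
    df = df.loc[seg.states_assigned()]
    return NeighbourhoodMatrix(
        enrichment=df,
        anchor_kind=anchor_kind,
        L=L,
        n_anchors=pd.Series(denom, index=offsets),
        genome_fraction=pd.Series(genome_frac, index=states).loc[
            seg.states_assigned()
        ],
    )


# ---------------------------------------------------------------------------
# domain classification & nomenclature
# ---------------------------------------------------------------------------

@dataclass
class DomainAssignment:
    """Per-state chromatin domain, final name and the rule that fired."""

    table: pd.DataFrame  # index: state; columns: domain, rule, name (optional)

    @property
    def domains(self) -> pd.Series:
        return self.table["domain"]

    @property
    def names(self) -> pd.Series:
        return self.table["name"]

    def rename_map(self) -> dict[str, str]:
        return dict(self.table["name"])


def classify_domains(
    emissions: EmissionMatrix,
    composition: pd.DataFrame,
    heterochromatin_marks: tuple[str, ...] = HETEROCHROMATIN_MARKS,
    facultative_marks: tuple[str, ...] = FACULTATIVE_MARKS,
    tau_H: float = 0.5,
    tau_TE: float = 0.3,
    tau_I: float = 0.2,
    tau_F: float = 0.5,
) -> DomainAssignment:
    """Classify each state into H / I / F / E by an explicit rule cascade.

    1. H — max emission over heterochromatin marks >= tau_H and TE bp
       proportion >= tau_TE;
    2. I — max emission over all marks < tau_I (nucleosome-free/intergenic);
    3. F — max emission over facultative marks >= tau_F;
    4. E — otherwise.
    """
    marks = emissions.marks
    het = [m for m in marks if m in heterochromatin_marks]
    fac = [m for m in marks if m in facultative_marks]
    if not het and not fac:
        raise ValueError(
            "emission matrix has none of the rule marks; need one of "
            f"{heterochromatin_marks + facultative_marks}"
        )
    rows = []
    for state in emissions.states:
        e = emissions.p.loc[state]
        te_prop = composition.loc[state, "TE"] if state in composition.index else 0.0
        if het and e[het].max() >= tau_H and te_prop >= tau_TE:
            dom, rule = "H", f"max({het}) >= {tau_H} and TE >= {tau_TE}"
        elif e.max() < tau_I:
            dom, rule = "I", f"max(all marks) < {tau_I}"
        elif fac and e[fac].max() >= tau_F:
            dom, rule = "F", f"max({fac}) >= {tau_F}"
        else:
            dom, rule = "E", "fallthrough"
        rows.append((state, dom, rule))
    df = pd.DataFrame(rows, columns=["state", "domain", "rule"]).set_index("state")
    df["name"] = df.index  # until assign_nomenclature runs
    return DomainAssignment(table=df)


def assign_nomenclature(
    domains: DomainAssignment,
    neighbourhood: NeighbourhoodMatrix,
    seg: StateSegmentation,
    centromeres: dict[str, int] | None = None,
    prefix: str = "",
) -> DomainAssignment:
    """Number states within each domain and build final names.

    E/F/I states are numbered by ascending argmax TSS offset (the order in
    which they appear going from TSS into the gene body); ties break by the
    profile's enrichment-weighted centroid, then label.  H states are
    numbered by ascending median distance to the centromere when centromere
    coordinates are supplied, else by descending genome coverage.
    """
    table = domains.table.copy()
    cov = genome_coverage(seg)

    def genic_key(state: str):
        row = neighbourhood.enrichment.loc[state]
        if row.isna().all():
            return (np.inf, np.inf, state)
        amax = int(row.idxmax())
        w = row.fillna(0.0)
        centroid = float((w.index * w).sum() / w.sum()) if w.sum() > 0 else np.inf
        return (amax, centroid, state)

    def centromere_key(state: str) -> float:
        dists = []
        for chrom, (starts, ends, codes) in seg.runs.items():
            cen = centromeres.get(chrom)
            if cen is None:
                continue
            mask = codes == seg.state_code(state)
            mids = (starts[mask] + ends[mask]) / 2.0
            dists.extend(np.abs(mids - cen))
        return float(np.median(dists)) if dists else np.inf

    names: dict[str, str] = {}
    for dom in ["H", "F", "E", "I"]:
        members = [s for s in table.index if table.loc[s, "domain"] == dom]
        if not members:
            continue
        if dom == "H":
            if centromeres:
                members.sort(key=lambda s: (centromere_key(s), s))
            else:
                members.sort(key=lambda s: (-cov.get(s, 0.0), s))
        else:
            members.sort(key=genic_key)
        for i, s in enumerate(members, start=1):
            names[s] = f"{prefix}{dom}{i}"
    table["name"] = pd.Series(names).reindex(table.index)
    return DomainAssignment(table=table)


# ---------------------------------------------------------------------------
# chromosomal distribution & signal aggregation
# ---------------------------------------------------------------------------

def chromosomal_distribution(
    seg: StateSegmentation,
    states_subset: list[str] | None = None,
    binwidth: int = 50_000,
) -> pd.DataFrame:
    """Counts of state-bin occurrences per genomic window.

    Returns a long frame (chrom, window_start, state, count); windows of
    ``binwidth`` bp tile each chromosome.
    """
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    if states_subset is None:
        states_subset = seg.states_assigned()
    rows = []
    for chrom, size in seg.chrom_sizes.items():
        codes = seg.bin_codes(chrom)
        bin_starts = np.arange(len(codes)) * seg.bin_size
        windows = bin_starts // binwidth
        n_windows = -(-size // binwidth)
        for state in states_subset:
            mask = codes == seg.state_code(state)
            counts = np.bincount(windows[mask], minlength=n_windows)
            for w in range(n_windows):
                rows.append((chrom, w * binwidth, state, int(counts[w])))
    return pd.DataFrame(rows, columns=["chrom", "window_start", "state", "count"])


def aggregate_signal_by_state(
    seg: StateSegmentation, signal: pd.DataFrame
) -> pd.DataFrame:
    """bp-weighted distribution summary of a bedGraph-style signal per state.

    ``signal`` has columns (chrom, start, end, value) with non-overlapping
    intervals per chromosome.  Genome bp without signal records contribute
    value 0.  Returns per state: n_bp, mean, and the box-plot statistic set
    (min, q25, median, q75, max), bp-weighted.
    """
    vals: dict[int, list[tuple[float, int]]] = {
        i: [] for i in range(len(seg.states))
    }
    covered = {c: 0 for c in seg.chrom_sizes}
    for rec in signal.itertuples(index=False):
        if rec.chrom not in seg.chrom_sizes:
            logger.warning("signal on unknown chromosome %r skipped", rec.chrom)
            continue
        bp_by_state = seg.overlap_bp(rec.chrom, int(rec.start), int(rec.end))
        for code in np.nonzero(bp_by_state)[0]:
            vals[code].append((float(rec.value), int(bp_by_state[code])))
        covered[rec.chrom] += min(int(rec.end), seg.chrom_sizes[rec.chrom]) - max(
            0, int(rec.start)
        )
    # implicit zeros for uncovered genome
    state_bp = seg.state_bp()
    for code, state in enumerate(seg.states):
        recorded = sum(w for _, w in vals[code])
        gap = int(state_bp[state]) - recorded
        if gap > 0:
            vals[code].append((0.0, gap))

    rows = []
    for code, state in enumerate(seg.states):
        if state == UNASSIGNED:
            continue
        pairs = vals[code]
        v = np.array([x for x, _ in pairs])
        w = np.array([n for _, n in pairs], dtype=np.int64)
        if w.sum() == 0:
            rows.append((state, 0, *([np.nan] * 6)))
            continue
        order = np.argsort(v)
        v, w = v[order], w[order]
        cum = np.cumsum(w)
        total = cum[-1]

        def wq(q: float) -> float:
            # value at the q-th weighted position (per-bp expansion semantics)
            target = q * (total - 1)
            return float(v[np.searchsorted(cum - 1, target, side="left")])

        mean = float(np.average(v, weights=w))
        rows.append(
            (state, int(total), mean, wq(0.0), wq(0.25), wq(0.5), wq(0.75), wq(1.0))
        )
    return pd.DataFrame(
        rows,
        columns=["state", "n_bp", "mean", "min", "q25", "median", "q75", "max"],
    ).set_index("state")
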