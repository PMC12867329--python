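"""Synthetic epigenome generator with planted ground truth.

The generator emits a binned multi-state segmentation with positional
structure around TSSs (promoter/NFR bins upstream, a +1-nucleosome state,
early and deep gene-body states), TE blocks filled with constitutive
heterochromatin states, TF peak sets with planted state preferences plus a
uniform background, TPM matrices with ubiquitous / tissue-specific / silent
gene classes, and rank-style co-expression that links each TF's functional
targets to it.  Expressed and repressed genes are coupled to chromatin: the
probability that a gene body is covered by the facultative state decreases
with the gene's expression rank, planting the expression/state gradient the
profile analyses recover.

One master seed is expanded into independent child streams (genome, peaks,
expression, co-expression), so regenerating one layer never perturbs the
others.  Identical config + seed gives byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CoexpressionTable,
    EmissionMatrix,
    ExpressionMatrix,
    GeneModel,
    GeneModelSet,
    GenomicInterval,
    PeakSet,
    StateSegmentation,
)

logger = logging.getLogger("chromstates")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class StateSpec:
    """One palette state: label, chromatin domain, TSS-relative profile.

    ``profile`` maps signed bin offsets (relative to the TSS bin) to sampling
    weights; ``body_extension`` states also fill gene-body bins beyond the
    deepest profiled offset.  ``emissions`` are the state's per-mark emission
    probabilities.
    """

    label: str
    domain: str  # H | F | E | I
    profile: dict[int, float] = field(default_factory=dict)
    emissions: dict[str, float] = field(default_factory=dict)
    body_extension: bool = False


@dataclass
class TEBlockSpec:
    count: int = 40
    length_bins: int = 25
    state_mixture: dict[str, float] = field(
        default_factory=lambda: {"H1": 0.6, "H2": 0.4}
    )


@dataclass
class TFSpec:
    tf_id: str
    n_peaks: int = 60
    preferred_state: str = "E1"
    preference_weight: float = 0.8
    functional_fraction: float = 0.1
    family: str = ""


@dataclass
class ExpressionSpec:
    n_tissues: int = 5
    reps_per_tissue: int = 2
    lognorm_mu: float = 1.0
    lognorm_sigma: float = 1.0
    tissue_specific_fraction: float = 0.2
    fold_effect: float = 8.0  # owning-tissue boost for specific genes
    noise_sd: float = 0.1  # sd of multiplicative log-normal sample noise
    silent_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.tissue_specific_fraction > 0 and self.fold_effect < 2:
            raise ValueError(
                "fold_effect must be >= 2 for tissue-specific genes to be "
                "callable by the two-fold rule"
            )


@dataclass
class CoexprSpec:
    functional_rank_ceiling: int = 100  # functional targets rank below this
    negative_tail: int = 50  # scores > G - tail form the negative set


@dataclass
class FacCouplingSpec:
    """Expression-coupled facultative repression of gene bodies."""

    state: str = "F1"
    p_max: float = 0.9  # repression probability of the least expressed gene
    p_min: float = 0.05  # ... of the most expressed gene


def default_palette() -> list[StateSpec]:
    low = 0.05
    marks = ["H3K4me3", "H3K36me3", "H2Bub", "H2A.Z", "H3K27me3",
             "H3K9me1", "H3K9me2", "H3K27me1", "H2A.W"]

    def em(**kw) -> dict[str, float]:
        return {m: kw.get(m.replace(".", "_"), low) for m in marks}

    return [
        StateSpec("I1", "I", {-2: 1.0, -1: 1.0, 0: 1.0}, em()),
        StateSpec("E1", "E", {1: 1.0}, em(H3K4me3=0.9, H2A_Z=0.3)),
        StateSpec("E2", "E", {2: 1.0}, em(H3K36me3=0.8, H2Bub=0.6)),
        StateSpec("E3", "E", {3: 1.0}, em(H3K36me3=0.9), body_extension=True),
        StateSpec("F1", "F", {}, em(H3K27me3=0.9, H2A_Z=0.6),
                  body_extension=True),
        StateSpec("H1", "H", {}, em(H3K9me2=0.9, H2A_W=0.8, H3K27me1=0.6)),
        StateSpec("H2", "H", {}, em(H3K9me1=0.8, H2A_W=0.5)),
    ]


def default_tf_specs(
    n_tfs: int = 30,
    preferred_states: tuple[str, ...] = ("I1", "E1", "E2", "E3", "F1"),
    preference_weight: float = 0.8,
    n_peaks: int = 60,
    functional_fraction: float = 0.1,
) -> list[TFSpec]:
    """n_tfs TFs in len(preferred_states) planted groups (round-robin)."""
    specs = []
    for i in range(n_tfs):
        state = preferred_states[i % len(preferred_states)]
        specs.append(
            TFSpec(
                tf_id=f"TF{i + 1:02d}",
                n_peaks=n_peaks,
                preferred_state=state,
                preference_weight=preference_weight,
                functional_fraction=functional_fraction,
                family=f"FAM_{state}",
            )
        )
    return specs


@dataclass
class SyntheticConfig:
    """Full description of one synthetic study; defaults are the package's
    standard study conditions (1 Mb genome, 500 genes, 30 TFs in 5 planted
    groups at preference weight 0.8)."""

    n_chroms: int = 1
    chrom_length: int = 1_000_000
    bin_size: int = 200
    gene_count: int = 500
    promoter_bins: int = 2
    body_bins_min: int = 3
    body_bins_max: int = 5
    min_spacing_bins: int = 0
    state_palette: list[StateSpec] = field(default_factory=default_palette)
    te_blocks: TEBlockSpec = field(default_factory=TEBlockSpec)
    tf_specs: list[TFSpec] = field(default_factory=default_tf_specs)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    coexpr: CoexprSpec = field(default_factory=CoexprSpec)
    fac_coupling: FacCouplingSpec | None = field(default_factory=FacCouplingSpec)
    peak_width_min: int = 200
    peak_width_max: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [s.label for s in self.state_palette]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate state labels in palette")
        for tf in self.tf_specs:
            if tf.preferred_state not in labels:
                raise ValueError(
                    f"{tf.tf_id}: preferred state {tf.preferred_state!r} "
                    "not in palette"
                )
            if not 0.0 <= tf.preference_weight <= 1.0:
                raise ValueError(f"{tf.tf_id}: preference_weight outside [0,1]")
        if self.fac_coupling and self.fac_coupling.state not in labels:
            raise ValueError("fac_coupling.state not in palette")
        for s in self.te_blocks.state_mixture:
            if s not in labels:
                raise ValueError(f"TE mixture state {s!r} not in palette")

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(5)
        names = ["genome", "peaks", "expression", "coexpr", "expr_noise"]
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Planted ground truth, serialisable to JSON for recovery tests."""

    state_table: pd.DataFrame  # state: domain, mode_offset, genome_fraction
    gene_table: pd.DataFrame  # gene_id: class, tissue, baseline, ref_tpm, repressed
    tf_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    tf_targets: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "state_table": self.state_table.reset_index().to_dict("records"),
            "gene_table": self.gene_table.reset_index().to_dict("records"),
            "tf_table": self.tf_table.reset_index().to_dict("records"),
            "tf_targets": self.tf_targets,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        st = pd.DataFrame(payload["state_table"]).set_index("state")
        gt = pd.DataFrame(payload["gene_table"]).set_index("gene_id")
        tt = pd.DataFrame(payload["tf_table"])
        if not tt.empty:
            tt = tt.set_index("tf_id")
        return cls(st, gt, tt, dict(payload["tf_targets"]))

    def tissue_specific_ids(self) -> set[str]:
        g = self.gene_table
        return set(g.index[g["gene_class"] == "tissue_specific"])


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _offset_distribution(palette: list[StateSpec], offset: int):
    """States and weights eligible at one signed TSS offset."""
    states, weights = [], []
    for s in palette:
        if offset in s.profile:
            states.append(s.label)
            weights.append(s.profile[offset])
    if not states and offset >= 1:
        for s in palette:
            if s.body_extension and s.domain != "F":
                states.append(s.label)
                weights.append(1.0)
    if not states:
        return None
    w = np.asarray(weights, dtype=float)
    return states, w / w.sum()


def generate_genome(
    config: SyntheticConfig,
) -> tuple[GeneModelSet, StateSegmentation, EmissionMatrix, SyntheticTruth]:
    """Lay out genes and TE blocks on the bin grid and label every bin.

    Gene cassettes carry ``promoter_bins`` upstream bins and a body of
    ``body_bins_min..body_bins_max`` bins, strand-mirrored for minus genes.
    Bins around each TSS are labelled by sampling the palette's per-offset
    state distribution; repressed genes (probability decreasing with the
    gene's planted expression rank, when facultative coupling is on) get the
    facultative state over the whole body.  TE blocks sample the configured
    heterochromatin mixture; everything else is the background (first
    profile-less I or the first palette) state.
    """
    rngs = config.rngs()
    rng = rngs["genome"]
    palette = config.state_palette
    labels = [s.label for s in palette]
    code_of = {s: i for i, s in enumerate(labels)}
    bin_size = config.bin_size

    background = next((s.label for s in palette if s.domain == "I"), labels[0])

    # -- per-gene expression plan (drawn here so chromatin can couple to it)
    G = config.gene_count
    ex = config.expression
    expr_rng = rngs["expression"]
    n_silent = int(round(ex.silent_fraction * G))
    n_spec = int(round(ex.tissue_specific_fraction * G))
    classes = np.array(
        ["silent"] * n_silent
        + ["tissue_specific"] * n_spec
        + ["ubiquitous"] * (G - n_silent - n_spec)
    )
    expr_rng.shuffle(classes)
    baseline = expr_rng.lognormal(ex.lognorm_mu, ex.lognorm_sigma, size=G)
    baseline[classes == "silent"] = 0.0
    tissues = [f"tissue{i + 1}" for i in range(ex.n_tissues)]
    owner = np.array([
        tissues[expr_rng.integers(ex.n_tissues)] if c == "tissue_specific" else ""
        for c in classes
    ])
    ref_tpm = baseline.copy()
    ref_tpm[(classes == "tissue_specific") & (owner == tissues[0])] *= ex.fold_effect

    # repression probability decreases with expression rank of the reference
    # tissue (rank 0 = least expressed)
    order = np.argsort(ref_tpm, kind="stable")
    rank = np.empty(G, dtype=float)
    rank[order] = np.arange(G)
    if config.fac_coupling is not None and G > 1:
        fc = config.fac_coupling
        p_rep = fc.p_max - (fc.p_max - fc.p_min) * rank / (G - 1)
        repressed = rng.random(G) < p_rep
    else:
        repressed = np.zeros(G, dtype=bool)

    # -- chromosome packing
    n_bins_total = config.chrom_length // bin_size
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genes_per_chrom = [
        G // config.n_chroms + (1 if i < G % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    te = config.te_blocks
    te_per_chrom = [
        te.count // config.n_chroms + (1 if i < te.count % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]

    body_lens = rng.integers(config.body_bins_min, config.body_bins_max + 1, size=G)
    strands = np.where(rng.random(G) < 0.5, "+", "-")

    genes: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    runs: dict[str, tuple] = {}
    gene_idx = 0
    te_counter = 0
    te_state_labels = list(te.state_mixture)
    te_state_p = np.array(list(te.state_mixture.values()), dtype=float)
    te_state_p /= te_state_p.sum()

    for ci, chrom in enumerate(chrom_names):
        chrom_sizes[chrom] = config.chrom_length
        n_genes_c = genes_per_chrom[ci]
        n_te_c = te_per_chrom[ci]
        idxs = list(range(gene_idx, gene_idx + n_genes_c))
        # cassette = promoter bins + TSS bin (offset 0) + body bins + spacing
        cassette_bins = [
            config.promoter_bins + 1 + int(body_lens[i]) + config.min_spacing_bins
            for i in idxs
        ]
        used = sum(cassette_bins) + n_te_c * te.length_bins
        free = n_bins_total - used
        if free < 0:
            raise ValueError(
                f"infeasible packing on {chrom}: need {used} bins, have "
                f"{n_bins_total}; reduce gene_count or TE blocks"
            )
        # interleave items along the chromosome with multinomial spacers
        items = [("gene", i) for i in idxs] + [("te", None)] * n_te_c
        rng.shuffle(items)
        spacers = rng.multinomial(free, np.ones(len(items) + 1) / (len(items) + 1))

        codes = np.full(n_bins_total, code_of[background], dtype=np.int64)
        cursor = 0
        for item, spacer in zip(items, spacers[:-1]):
            cursor += int(spacer)
            kind, i = item
            if kind == "te":
                block = rng.choice(len(te_state_labels), size=te.length_bins,
                                   p=te_state_p)
                codes[cursor:cursor + te.length_bins] = [
                    code_of[te_state_labels[b]] for b in block
                ]
                te_counter += 1
                genes.append(
                    GeneModel(
                        gene_id=f"te{te_counter:04d}",
                        interval=GenomicInterval(
                            chrom, cursor * bin_size,
                            (cursor + te.length_bins) * bin_size, "+",
                        ),
                        feature_class="TE",
                    )
                )
                cursor += te.length_bins
                continue
            L = int(body_lens[i])
            strand = strands[i]
            P = config.promoter_bins
            # the gene spans the TSS bin (offset 0) plus L body bins
            # (offsets +1..+L); promoter bins sit upstream in reading
            # direction, mirrored for minus genes
            if strand == "+":
                prom_bins = list(range(cursor, cursor + P))
                gene_bins = list(range(cursor + P, cursor + P + 1 + L))
            else:
                gene_bins = list(range(cursor, cursor + 1 + L))[::-1]
                prom_bins = list(range(cursor + 1 + L, cursor + 1 + L + P))[::-1]
            # promoter bins nearest the gene get offset -1, then -2, ...
            prom_ordered = prom_bins[::-1] if strand == "+" else prom_bins
            for j, b in enumerate(prom_ordered, start=1):
                dist = _offset_distribution(palette, -j)
                if dist is not None:
                    st, w = dist
                    codes[b] = code_of[st[rng.choice(len(st), p=w)]]
            for off, b in enumerate(gene_bins):  # offsets 0..L
                if off >= 1 and repressed[i] and config.fac_coupling is not None:
                    codes[b] = code_of[config.fac_coupling.state]
                    continue
                dist = _offset_distribution(palette, off)
                if dist is not None:
                    st, w = dist
                    codes[b] = code_of[st[rng.choice(len(st), p=w)]]
            lo, hi = min(gene_bins), max(gene_bins)
            genes.append(
                GeneModel(
                    gene_id=f"g{i + 1:04d}",
                    interval=GenomicInterval(
                        chrom, lo * bin_size, (hi + 1) * bin_size, strand
                    ),
                    feature_class="protein_coding",
                )
            )
            cursor += P + 1 + L + config.min_spacing_bins
        gene_idx += n_genes_c

        # run-length encode
        change = np.nonzero(np.diff(codes))[0] + 1
        starts = np.concatenate([[0], change]) * bin_size
        ends = np.concatenate([change, [n_bins_total]]) * bin_size
        ends[-1] = config.chrom_length
        rcodes = codes[np.concatenate([[0], change])]
        runs[chrom] = (starts, ends, rcodes)

    seg = StateSegmentation(chrom_sizes, labels, runs, bin_size=bin_size)
    marks = sorted({m for s in palette for m in s.emissions})
    em = EmissionMatrix(
        p=pd.DataFrame(
            [[s.emissions.get(m, 0.0) for m in marks] for s in palette],
            index=labels, columns=marks,
        )
    )

    bp = seg.state_bp()
    frac = bp / bp.sum()
    mode_offset = {}
    for s in palette:
        if s.profile:
            mode_offset[s.label] = int(max(s.profile, key=lambda k: (s.profile[k], -abs(k))))
        elif s.body_extension:
            mode_offset[s.label] = None
        else:
            mode_offset[s.label] = None
    state_table = pd.DataFrame(
        {
            "domain": {s.label: s.domain for s in palette},
            "mode_offset": mode_offset,
            "genome_fraction": frac,
        }
    )
    state_table.index.name = "state"
    gene_table = pd.DataFrame(
        {
            "gene_class": classes,
            "tissue": owner,
            "baseline": baseline,
            "ref_tpm": ref_tpm,
            "repressed": repressed,
        },
        index=pd.Index([f"g{i + 1:04d}" for i in range(G)], name="gene_id"),
    )
    truth = SyntheticTruth(state_table=state_table, gene_table=gene_table)
    return GeneModelSet(genes), seg, em, truth


# ---------------------------------------------------------------------------
# peak generation
# ---------------------------------------------------------------------------

def generate_peaks(
    genes: GeneModelSet,
    seg: StateSegmentation,
    config: SyntheticConfig,
    truth: SyntheticTruth,
) -> list[PeakSet]:
    """Per TF, planted-preference peaks near functional targets plus uniform
    background peaks.

    ceil(preference_weight * n_peaks) peak centres are drawn from bins of the
    preferred state within functional target genes' cassettes (promoter +
    body); the remainder are uniform over the genome.  Functional targets are
    sampled among genes that actually carry the preferred state, and recorded
    in the truth object.
    """
    rng = config.rngs()["peaks"]
    bin_size = seg.bin_size
    prom = config.promoter_bins

    pc_genes = genes.subset("protein_coding")
    # per gene, the bins of each state inside its cassette
    gene_state_bins: dict[str, dict[str, list[tuple[str, int]]]] = {}
    for g in pc_genes:
        first_bin = g.interval.start // bin_size
        last_bin = (g.interval.end - 1) // bin_size
        if g.strand == "+":
            lo, hi = first_bin - prom, last_bin
        else:
            lo, hi = first_bin, last_bin + prom
        lo = max(lo, 0)
        hi = min(hi, seg.n_bins(g.chrom) - 1)
        codes = seg.bin_codes(g.chrom)[lo:hi + 1]
        d: dict[str, list[tuple[str, int]]] = {}
        for b, c in zip(range(lo, hi + 1), codes):
            d.setdefault(seg.states[int(c)], []).append((g.chrom, b))
        gene_state_bins[g.gene_id] = d

    tf_rows = []
    targets: dict[str, list[str]] = {}
    out: list[PeakSet] = []
    chroms = list(seg.chrom_sizes)
    sizes = np.array([seg.chrom_sizes[c] for c in chroms], dtype=float)
    chrom_p = sizes / sizes.sum()

    for spec in config.tf_specs:
        if spec.preferred_state not in seg.states:
            raise ValueError(
                f"{spec.tf_id}: preferred state {spec.preferred_state!r} "
                "absent from segmentation"
            )
        eligible = [
            gid for gid, d in gene_state_bins.items() if spec.preferred_state in d
        ]
        n_func = min(len(eligible),
                     int(round(spec.functional_fraction * len(pc_genes))))
        func = sorted(rng.choice(eligible, size=n_func, replace=False)) if n_func else []
        n_pref = int(np.ceil(spec.preference_weight * spec.n_peaks)) if func else 0
        n_pref = min(n_pref, spec.n_peaks)

        peaks = []
        for _ in range(n_pref):
            gid = func[int(rng.integers(len(func)))]
            chrom, b = gene_state_bins[gid][spec.preferred_state][
                int(rng.integers(len(gene_state_bins[gid][spec.preferred_state])))
            ]
            center = b * bin_size + int(rng.integers(bin_size))
            peaks.append(_peak_around(chrom, center, seg, rng, config))
        for _ in range(spec.n_peaks - n_pref):
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
            center = int(rng.integers(seg.chrom_sizes[chrom]))
            peaks.append(_peak_around(chrom, center, seg, rng, config))
        out.append(PeakSet(tf_id=spec.tf_id, assay="chip", peaks=peaks))
        targets[spec.tf_id] = list(func)
        tf_rows.append(
            (spec.tf_id, spec.preferred_state, spec.preference_weight,
             spec.family or "unknown", len(func), spec.n_peaks)
        )

    truth.tf_table = pd.DataFrame(
        tf_rows,
        columns=["tf_id", "preferred_state", "preference_weight", "family",
                 "n_functional", "n_peaks"],
    ).set_index("tf_id")
    truth.tf_targets = targets
    return out


def _peak_around(chrom, center, seg, rng, config) -> GenomicInterval:
    width = int(rng.integers(config.peak_width_min, config.peak_width_max + 1))
    start = center - width // 2
    size = seg.chrom_sizes[chrom]
    start = min(max(start, 0), size - width) if size >= width else 0
    return GenomicInterval(chrom, start, min(start + width, size))


# ---------------------------------------------------------------------------
# expression & co-expression
# ---------------------------------------------------------------------------

def generate_expression(
    genes: GeneModelSet, config: SyntheticConfig, truth: SyntheticTruth
) -> ExpressionMatrix:
    """TPM matrix realising the planted gene classes.

    Tissue-specific genes get ``fold_effect`` x baseline in their owning
    tissue and baseline elsewhere; ubiquitous genes get their baseline in
    every tissue; silent genes are exactly 0.  Replicate noise is
    multiplicative log-normal with sd ``noise_sd`` (0 = noiseless).
    """
    ex = config.expression
    # class/baseline draws live in the "expression" stream (consumed during
    # genome generation and recorded in truth); replicate noise has its own
    # child stream so regenerating it never perturbs the planted classes
    rng = config.rngs()["expr_noise"]
    gt = truth.gene_table.loc[genes.subset("protein_coding").ids()]
    tissues = [f"tissue{i + 1}" for i in range(ex.n_tissues)]
    cols, tags = [], {}
    data = {}
    for t in tissues:
        level = gt["baseline"].to_numpy().copy()
        boost = (gt["gene_class"] == "tissue_specific") & (gt["tissue"] == t)
        level[boost.to_numpy()] *= ex.fold_effect
        for r in range(ex.reps_per_tissue):
            sample = f"{t}_rep{r + 1}"
            noise = (
                np.exp(rng.normal(0.0, ex.noise_sd, size=len(level)))
                if ex.noise_sd > 0 else 1.0
            )
            data[sample] = level * noise
            cols.append(sample)
            tags[sample] = t
    tpm = pd.DataFrame(data, index=gt.index)[cols]
    return ExpressionMatrix(tpm=tpm, tissues=pd.Series(tags))


def generate_coexpression(
    truth: SyntheticTruth, config: SyntheticConfig
) -> CoexpressionTable:
    """Integer ranks 1..G per TF; functional targets below the ceiling.

    Each TF's functional targets receive distinct ranks drawn uniformly from
    [1, functional_rank_ceiling]; the remaining genes share the remaining
    ranks at random.
    """
    rng = config.rngs()["coexpr"]
    gene_ids = list(truth.gene_table.index)
    G = len(gene_ids)
    # ranks are 1..G, so the effective ceiling cannot exceed the gene count
    ceiling = min(config.coexpr.functional_rank_ceiling, G)
    rows = []
    for tf_id, func in truth.tf_targets.items():
        func = [g for g in func if g in truth.gene_table.index]
        if len(func) > ceiling - 1:
            raise ValueError(
                f"{tf_id}: {len(func)} functional targets exceed the rank "
                f"ceiling {ceiling}"
            )
        # strictly below the ceiling, matching the strict < of the filter
        low = 1 + rng.permutation(ceiling - 1)[:len(func)]
        taken = set(low.tolist())
        rest_ranks = np.array([r for r in range(1, G + 1) if r not in taken])
        rng.shuffle(rest_ranks)
        rank_of = dict(zip(func, low.tolist()))
        others = [g for g in gene_ids if g not in rank_of]
        rank_of.update(zip(others, rest_ranks.tolist()))
        for g in gene_ids:
            rows.append((tf_id, g, int(rank_of[g])))
    return CoexpressionTable(
        scores=pd.DataFrame(rows, columns=["tf_id", "gene_id", "score"])
    )


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    genes: GeneModelSet
    segmentation: StateSegmentation
    emissions: EmissionMatrix
    peaks: list[PeakSet]
    expression: ExpressionMatrix
    coexpression: CoexpressionTable
    truth: SyntheticTruth
    config: SyntheticConfig


def generate_study(config: SyntheticConfig | None = None) -> SyntheticStudy:
    """Generate every layer of a synthetic study under one config."""
    if config is None:
        config = SyntheticConfig()
    genes, seg, em, truth = generate_genome(config)
    peaks = generate_peaks(genes, seg, config, truth)
    expr = generate_expression(genes, config, truth)
    coexpr = generate_coexpression(truth, config)
    return SyntheticStudy(genes, seg, em, peaks, expr, coexpr, truth, config)
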