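"""End-to-end orchestration: simulate -> states -> expression -> compare -> tf.

A single validated config drives every stage; all outputs land under the
configured directory and are listed in a JSON manifest with content hashes,
so identical config + seed yields identical manifests and a parameter change
only touches the artifacts downstream of it.  Stages are pure functions of
files: each stage reads the files the previous stages wrote.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import compare as cmp_mod
from . import expression as expr_mod
from . import io as io_mod
from . import states as states_mod
from . import tfscore as tf_mod
from .synth import (
    CoexprSpec,
    ExpressionSpec,
    FacCouplingSpec,
    SyntheticConfig,
    TEBlockSpec,
    default_tf_specs,
    generate_study,
)

logger = logging.getLogger("chromstates")


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

@dataclass
class TFBlock:
    """Planted-TF layer and scoring parameters of a run."""

    n_tfs: int = 30
    n_peaks: int = 60
    preference_weight: float = 0.8
    functional_fraction: float = 0.1
    positive_threshold: float = 100.0  # co-expression rank ceiling of the run
    negative_tail: float = 50.0
    min_max_score: float = 8.0
    k: int = 5
    linkage: str = "complete"
    metric: str = "euclidean"
    promoter_up: int = 1000
    promoter_down: int = 100
    max_distance: int = 10_000
    tss_window: int = 2000
    tss_nbins: int = 40


@dataclass
class StatesBlock:
    L: int = 10
    binwidth: int = 50_000
    tau_H: float = 0.5
    tau_TE: float = 0.3
    tau_I: float = 0.2
    tau_F: float = 0.5


@dataclass
class ExpressionBlock:
    n_bins: int = 20
    promoter_length: int = 1000
    fold: float = 2.0


@dataclass
class SynthBlock:
    n_chroms: int = 1
    chrom_length: int = 1_000_000
    bin_size: int = 200
    gene_count: int = 500
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    coexpr: CoexprSpec = field(default_factory=CoexprSpec)
    te_blocks: TEBlockSpec = field(default_factory=TEBlockSpec)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "run_out"
    synth: SynthBlock = field(default_factory=SynthBlock)
    states: StatesBlock = field(default_factory=StatesBlock)
    expression: ExpressionBlock = field(default_factory=ExpressionBlock)
    tf: TFBlock = field(default_factory=TFBlock)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            n_chroms=self.synth.n_chroms,
            chrom_length=self.synth.chrom_length,
            bin_size=self.synth.bin_size,
            gene_count=self.synth.gene_count,
            expression=self.synth.expression,
            coexpr=self.synth.coexpr,
            te_blocks=self.synth.te_blocks,
            tf_specs=default_tf_specs(
                n_tfs=self.tf.n_tfs,
                preference_weight=self.tf.preference_weight,
                n_peaks=self.tf.n_peaks,
                functional_fraction=self.tf.functional_fraction,
            ),
            seed=self.seed,
        )


def _build(cls, data: dict, path: str, errors: list[str]):
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in fields:
            errors.append(f"{path}: unknown key {key!r}")
            continue
        ftype = fields[key].type
        nested = {
            "SynthBlock": SynthBlock, "StatesBlock": StatesBlock,
            "ExpressionBlock": ExpressionBlock, "TFBlock": TFBlock,
            "ExpressionSpec": ExpressionSpec, "CoexprSpec": CoexprSpec,
            "TEBlockSpec": TEBlockSpec, "FacCouplingSpec": FacCouplingSpec,
        }
        name = ftype if isinstance(ftype, str) else getattr(ftype, "__name__", "")
        if name in nested:
            if not isinstance(value, dict):
                errors.append(f"{path}.{key}: expected a mapping")
                continue
            kwargs[key] = _build(nested[name], value, f"{path}.{key}", errors)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{path}: {exc}")
        return cls()


def validate_config(path: str | Path | dict) -> RunConfig:
    """Load and fully default a run config, rejecting unknown keys.

    All violations are collected and reported together.  The effective
    parameters are echoed to the log.
    """
    if isinstance(path, dict):
        raw = path
    else:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    errors: list[str] = []
    cfg = _build(RunConfig, raw, "config", errors)
    if cfg.synth.bin_size <= 0:
        errors.append("config.synth.bin_size: must be positive")
    if cfg.synth.chrom_length <= 0:
        errors.append("config.synth.chrom_length: must be positive")
    if cfg.tf.k < 2:
        errors.append("config.tf.k: must be >= 2")
    for name in ("tau_H", "tau_TE", "tau_I", "tau_F"):
        v = getattr(cfg.states, name)
        if not 0.0 <= v <= 1.0:
            errors.append(f"config.states.{name}: must lie in [0, 1]")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    logger.info("effective config: %s", json.dumps(cfg.to_dict(), sort_keys=True))
    return cfg


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_hash: str
    files: list[dict]  # path, stage, sha256
    failed_stage: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"config_hash": self.config_hash, "failed_stage": self.failed_stage,
                 "files": self.files},
                indent=1, sort_keys=True,
            )
        )

    def hashes(self) -> dict[str, str]:
        return {f["path"]: f["sha256"] for f in self.files}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in dependency order under ``config.outdir``.

    A stage failure halts downstream stages; the manifest written so far is
    still emitted (with ``failed_stage`` set) and the error re-raised.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(config_hash=config_hash, files=[])

    def record(stage: str, path: Path) -> None:
        manifest.files.append(
            {"path": str(path.relative_to(out)), "stage": stage,
             "sha256": _sha256(path)}
        )

    stages = [
        ("simulate", _stage_simulate),
        ("states", _stage_states),
        ("expression", _stage_expression),
        ("compare", _stage_compare),
        ("tf", _stage_tf),
    ]
    try:
        for name, fn in stages:
            logger.info("stage %s", name)
            for path in fn(config, out):
                record(name, path)
    except Exception as exc:  # noqa: BLE001 - converted to StageError below
        manifest.failed_stage = name
        manifest.to_json(out / "manifest.json")
        raise StageError(name, exc) from exc
    manifest.to_json(out / "manifest.json")
    return manifest


def _stage_simulate(config: RunConfig, out: Path) -> list[Path]:
    study = generate_study(config.synthetic_config())
    sim = out / "sim"
    peaks_dir = sim / "peaks"
    peaks_dir.mkdir(parents=True, exist_ok=True)
    io_mod.write_chrom_sizes(study.segmentation.chrom_sizes, sim / "chrom.sizes")
    io_mod.write_segmentation(study.segmentation, sim / "segmentation.bed")
    io_mod.write_gff3(study.genes, sim / "genes.gff3")
    io_mod.write_emissions(study.emissions, sim / "emissions.tsv")
    io_mod.write_expression(study.expression, sim / "expression.tsv")
    io_mod.write_coexpression(study.coexpression, sim / "coexpression.tsv")
    study.truth.to_json(sim / "truth.json")
    written = [
        sim / "chrom.sizes", sim / "segmentation.bed", sim / "genes.gff3",
        sim / "emissions.tsv", sim / "expression.tsv", sim / "coexpression.tsv",
        sim / "truth.json",
    ]
    for ps in study.peaks:
        p = peaks_dir / f"{ps.tf_id}.bed"
        io_mod.write_peaks(ps, p)
        written.append(p)
    return written


def _load_inputs(config: RunConfig, out: Path):
    sim = out / "sim"
    sizes = io_mod.read_chrom_sizes(sim / "chrom.sizes")
    seg = io_mod.read_segmentation(
        sim / "segmentation.bed", sizes, bin_size=config.synth.bin_size
    )
    genes = io_mod.read_gff3(sim / "genes.gff3")
    return seg, genes


def _stage_states(config: RunConfig, out: Path) -> list[Path]:
    seg, genes = _load_inputs(config, out)
    pc = genes.subset("protein_coding")
    em = io_mod.read_emissions(out / "sim" / "emissions.tsv")
    sb = config.states
    d = out / "states"
    d.mkdir(exist_ok=True)

    cov = states_mod.genome_coverage(seg)
    comp = states_mod.feature_composition(seg, genes)
    nb_tss = states_mod.neighbourhood_enrichment(seg, pc, L=sb.L, anchor_kind="TSS")
    nb_tts = states_mod.neighbourhood_enrichment(seg, pc, L=sb.L, anchor_kind="TTS")
    domains = states_mod.classify_domains(
        em, comp, tau_H=sb.tau_H, tau_TE=sb.tau_TE, tau_I=sb.tau_I, tau_F=sb.tau_F
    )
    named = states_mod.assign_nomenclature(domains, nb_tss, seg)
    dist = states_mod.chromosomal_distribution(seg, binwidth=sb.binwidth)

    io_mod.write_table(cov, d / "coverage.tsv")
    io_mod.write_table(comp, d / "composition.tsv")
    io_mod.write_table(nb_tss.enrichment, d / "neighbourhood_TSS.tsv")
    io_mod.write_table(nb_tts.enrichment, d / "neighbourhood_TTS.tsv")
    io_mod.write_table(named.table, d / "domains.tsv")
    io_mod.write_table(dist, d / "chromdist.tsv", index=False)
    return [d / f for f in (
        "coverage.tsv", "composition.tsv", "neighbourhood_TSS.tsv",
        "neighbourhood_TTS.tsv", "domains.tsv", "chromdist.tsv",
    )]


def _stage_expression(config: RunConfig, out: Path) -> list[Path]:
    seg, genes = _load_inputs(config, out)
    pc = genes.subset("protein_coding")
    expr = io_mod.read_expression(out / "sim" / "expression.tsv")
    eb = config.expression
    d = out / "expression"
    d.mkdir(exist_ok=True)

    cv = expr_mod.compute_cv(expr)
    ref_tissue = expr.tissues.iloc[0]
    ref_samples = [s for s in expr.samples if expr.tissues[s] == ref_tissue]
    ref_tpm = expr.tpm[ref_samples].mean(axis=1)
    bins = expr_mod.bin_genes(ref_tpm, B=eb.n_bins, statistic="TPM")
    body_profile = expr_mod.state_proportion_profile(
        expr_mod.gene_body_regions(pc), bins, seg
    )
    prom_profile = expr_mod.state_proportion_profile(
        expr_mod.promoter_regions(pc, eb.promoter_length, seg.chrom_sizes),
        bins, seg,
    )
    tspec = expr_mod.tissue_specific_genes(expr, fold=eb.fold)

    io_mod.write_table(cv.to_frame(), d / "cv.tsv")
    io_mod.write_table(bins.assignment.to_frame(), d / "tpm_bins.tsv")
    io_mod.write_table(body_profile, d / "body_profile.tsv")
    io_mod.write_table(prom_profile, d / "promoter_profile.tsv")
    io_mod.write_table(tspec, d / "tissue_specific.tsv", index=False)
    return [d / f for f in (
        "cv.tsv", "tpm_bins.tsv", "body_profile.tsv", "promoter_profile.tsv",
        "tissue_specific.tsv",
    )]


def _stage_compare(config: RunConfig, out: Path) -> list[Path]:
    seg, genes = _load_inputs(config, out)
    domains = pd.read_csv(out / "states" / "domains.tsv", sep="\t", index_col=0)
    d = out / "compare"
    d.mkdir(exist_ok=True)
    # domain-coarsened reduction of the model: states merged within H/F/E/I
    frame = seg.to_frame()
    frame["state"] = frame["state"].map(domains["domain"]).fillna("NA")
    from .core import GenomicInterval, StateSegmentation
    reduced = StateSegmentation.from_intervals(
        [
            (GenomicInterval(r.chrom, r.start, r.end), r.state)
            for r in frame.itertuples(index=False)
        ],
        seg.chrom_sizes, bin_size=seg.bin_size,
    )
    tm = cmp_mod.transition_matrix(seg, reduced)
    jac = cmp_mod.state_jaccard(seg, reduced)
    io_mod.write_table(tm, d / "transition.tsv")
    io_mod.write_table(cmp_mod.transition_long(tm), d / "transition_long.tsv",
                       index=False)
    io_mod.write_table(jac, d / "jaccard.tsv")
    return [d / f for f in ("transition.tsv", "transition_long.tsv", "jaccard.tsv")]


def _stage_tf(config: RunConfig, out: Path) -> list[Path]:
    seg, genes = _load_inputs(config, out)
    pc = genes.subset("protein_coding")
    coexpr = io_mod.read_coexpression(out / "sim" / "coexpression.tsv")
    tb = config.tf
    d = out / "tf"
    d.mkdir(exist_ok=True)
    peak_files = sorted((out / "sim" / "peaks").glob("*.bed"))
    N = len(pc)

    occ_rows, results = [], {}
    peak_sets = {}
    for pf in peak_files:
        ps = io_mod.read_peaks(pf, assay="chip")
        peak_sets[ps.tf_id] = ps
        occ = tf_mod.occupancy_enrichment(ps, seg)
        for state, row in occ.iterrows():
            occ_rows.append((ps.tf_id, state, row["a_s"], row["b"], row["c_s"],
                             row["d"], row["enrichment"]))
        labels = tf_mod.assign_peak_states(ps, seg)
        _, targets = tf_mod.annotate_targets(
            ps, labels, pc,
            promoter_window=(tb.promoter_up, tb.promoter_down),
            max_distance=tb.max_distance,
        )
        pos, neg = tf_mod.coexpression_filter(
            coexpr.for_tf(ps.tf_id),
            positive_threshold=tb.positive_threshold,
            negative_tail=tb.negative_tail,
        )
        results[ps.tf_id] = tf_mod.activity_score(
            targets, pos | neg, N, states=seg.states_assigned()
        )

    occ_df = pd.DataFrame(
        occ_rows, columns=["tf_id", "state", "a_s", "b", "c_s", "d", "enrichment"]
    )
    activity_long = pd.concat(
        {tf: res for tf, res in results.items()}, names=["tf_id", "state"]
    ).reset_index()
    matrix, dropped = tf_mod.build_score_matrix(results, tb.min_max_score)
    model = tf_mod.cluster_tfs(
        matrix, tb.k, metric=tb.metric, method=tb.linkage, dropped=dropped
    )
    # family labels come from the simulation's TF metadata
    tf_meta = pd.DataFrame(
        json.loads((out / "sim" / "truth.json").read_text())["tf_table"]
    ).set_index("tf_id")
    fam = tf_mod.family_enrichment(model.labels, tf_meta["family"])
    peaks_by_cluster = {
        int(c): [peak_sets[tf] for tf in model.labels.index[model.labels == c]]
        for c in sorted(model.labels.unique())
    }
    hist = tf_mod.tss_binding_histogram(
        peaks_by_cluster, pc, window=tb.tss_window, nbins=tb.tss_nbins
    )

    io_mod.write_table(occ_df, d / "occupancy.tsv", index=False)
    io_mod.write_table(activity_long, d / "activity.tsv", index=False)
    io_mod.write_table(matrix, d / "score_matrix.tsv")
    io_mod.write_table(model.labels.to_frame(), d / "clusters.tsv")
    io_mod.write_table(model.merge_table, d / "linkage.tsv", index=False)
    io_mod.write_table(model.dropped, d / "dropped.tsv")
    io_mod.write_table(fam, d / "families.tsv", index=False)
    io_mod.write_table(hist, d / "tsshist.tsv", index=False)
    return [d / f for f in (
        "occupancy.tsv", "activity.tsv", "score_matrix.tsv", "clusters.tsv",
        "linkage.tsv", "dropped.tsv", "families.tsv", "tsshist.tsv",
    )]
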