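"""Readers and writers for the external formats the pipeline touches.

BED-family inputs are 0-based half-open and kept as-is; GFF3 is 1-based
inclusive and converted on read.  All writers emit the canonical form their
reader accepts, so write -> read is the identity on canonical objects.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import gffutils
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


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>size`` file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    if df["chrom"].duplicated().any():
        raise ValueError(f"duplicate chromosome in {path}")
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# segmentation BED (ChromHMM dense / segments dialects both have the state
# label in column 4; extra dense columns are ignored)
# ---------------------------------------------------------------------------

def read_segmentation(
    path: str | Path,
    chrom_sizes: Mapping[str, int] | None = None,
    bin_size: int = 200,
) -> StateSegmentation:
    """Read a state segmentation from a 4+-column BED file.

    Gaps are filled with the reserved ``unassigned`` label (and logged);
    overlapping records raise, naming the first collision.  When
    ``chrom_sizes`` is omitted, each chromosome's size is taken as the end of
    its last record.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected >= 4 BED columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed coordinates") from exc
    if not rows:
        raise ValueError(f"{path}: empty segmentation")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    if chrom_sizes is None:
        chrom_sizes = df.groupby("chrom", sort=False)["end"].max().to_dict()
    else:
        unknown = set(df["chrom"]) - set(chrom_sizes)
        if unknown:
            raise ValueError(f"{path}: unknown chromosome {sorted(unknown)[0]!r}")
    # preserve first-appearance state order, as ChromHMM files are state-sorted
    # only by position
    order: list[str] = []
    for s in df["state"]:
        if s not in order:
            order.append(s)
    intervals = [
        (GenomicInterval(c, s, e), lab)
        for c, s, e, lab in df.itertuples(index=False)
    ]
    return StateSegmentation.from_intervals(
        intervals, chrom_sizes, bin_size=bin_size, states=order
    )


def write_segmentation(seg: StateSegmentation, path: str | Path) -> None:
    seg.to_frame().to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

_TE_TYPES = ("transposable_element", "transposon")
_GENE_TYPES = {"gene", "transposable_element_gene", "pseudogene"}


def read_gff3(path: str | Path) -> GeneModelSet:
    """Read gene-level records from GFF3 into 0-based half-open gene models.

    TSS/TTS are derived strand-aware; ``transposable_element*`` types (or a
    ``locus_type`` attribute saying so) map to feature class ``TE``.
    Strand-less genes are skipped with a warning.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    skipped = 0
    for feat in db.all_features():
        ftype = feat.featuretype
        if ftype not in _GENE_TYPES and not ftype.startswith(_TE_TYPES):
            continue
        if feat.strand not in {"+", "-"}:
            skipped += 1
            continue
        gid = feat.attributes.get("ID", [feat.id])[0]
        if ftype.startswith(_TE_TYPES):
            fclass = "TE"
        elif ftype == "gene":
            biotype = feat.attributes.get("locus_type", ["protein_coding"])[0]
            fclass = "protein_coding" if biotype == "protein_coding" else "other"
        else:
            fclass = "other"
        genes.append(
            GeneModel(
                gene_id=gid,
                # GFF3 is 1-based inclusive; internal is 0-based half-open
                interval=GenomicInterval(
                    feat.seqid, feat.start - 1, feat.end, feat.strand
                ),
                feature_class=fclass,
            )
        )
    if skipped:
        logger.warning("read_gff3: skipped %d strand-less gene records", skipped)
    return GeneModelSet(genes)


def write_gff3(genes: GeneModelSet, path: str | Path) -> None:
    type_of = {"protein_coding": "gene", "TE": "transposable_element_gene", "other": "gene"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.feature_class == "other":
                attrs += ";locus_type=other"
            fh.write(
                f"{g.chrom}\tchromstates\t{type_of[g.feature_class]}\t"
                f"{g.interval.start + 1}\t{g.interval.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# peaks (BED or narrowPeak)
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path, assay: str, tf_id: str | None = None) -> PeakSet:
    """Read a plain BED or 10-column narrowPeak file into a PeakSet.

    A narrowPeak summit of -1 (the format's sentinel) is treated as absent.
    """
    if tf_id is None:
        tf_id = Path(path).stem
    peaks: list[GenomicInterval] = []
    scores: list[float] = []
    have_scores = False
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed coordinates") from exc
            peaks.append(GenomicInterval(chrom, start, end))
            if len(parts) >= 7:  # narrowPeak signalValue
                scores.append(float(parts[6]))
                have_scores = True
            elif len(parts) >= 5 and parts[4] not in {".", ""}:
                scores.append(float(parts[4]))
                have_scores = True
            else:
                scores.append(float("nan"))
    return PeakSet(tf_id=tf_id, assay=assay, peaks=peaks,
                   scores=scores if have_scores else None)


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks.peaks):
            score = ""
            if peaks.scores is not None and not np.isnan(peaks.scores[i]):
                score = f"\t{peaks.tf_id}_{i}\t{peaks.scores[i]:g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}{score}\n")


# ---------------------------------------------------------------------------
# matrices and tables
# ---------------------------------------------------------------------------

def read_emissions(path: str | Path) -> EmissionMatrix:
    """Read a ChromHMM-style emissions TSV (states as rows, marks as columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return EmissionMatrix(p=df)


def write_emissions(em: EmissionMatrix, path: str | Path) -> None:
    em.p.to_csv(path, sep="\t")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TPM TSV whose header row carries ``sample:tissue`` labels
    (a bare ``sample`` name is its own tissue)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    tissues = {}
    renames = {}
    for col in df.columns:
        if ":" in col:
            sample, tissue = col.split(":", 1)
        else:
            sample, tissue = col, col
        renames[col] = sample
        tissues[sample] = tissue
    df = df.rename(columns=renames)
    return ExpressionMatrix(tpm=df, tissues=pd.Series(tissues))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.tpm.copy()
    df.columns = [f"{s}:{expr.tissues[s]}" for s in df.columns]
    df.to_csv(path, sep="\t")


def read_coexpression(path: str | Path) -> CoexpressionTable:
    df = pd.read_csv(path, sep="\t")
    return CoexpressionTable(scores=df[["tf_id", "gene_id", "score"]])


def write_coexpression(table: CoexpressionTable, path: str | Path) -> None:
    table.scores.to_csv(path, sep="\t", index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph signal track into a (chrom, start, end, value) frame."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_table(obj, path: str | Path, **kwargs) -> None:
    """Write any DataFrame/Series-like object as TSV (generic sink)."""
    if isinstance(obj, pd.Series):
        obj = obj.to_frame()
    obj.to_csv(path, sep="\t", **kwargs)
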