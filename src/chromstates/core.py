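"""Coordinate-normalised domain containers shared by every analysis module.

All coordinates are 0-based half-open throughout the package; GFF3 input is
converted on read.  A chromatin-state segmentation is stored as sorted
run-length intervals that tile each chromosome, with gaps carried explicitly
under the reserved ``unassigned`` label so that downstream denominators can
exclude them consistently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("chromstates")

#: reserved label for genome not covered by any state record
UNASSIGNED = "unassigned"

_VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, floor((start+end)/2) — the peak-centre convention."""
        return (self.start + self.end) // 2


class StateSegmentation:
    """A genome-tiling chromatin-state map on a fixed bin grid.

    Parameters
    ----------
    chrom_sizes
        Chromosome name -> length in bp.
    states
        Ordered state labels.  ``unassigned`` is appended automatically when
        any gap exists and is excluded from statistical denominators.
    runs
        Per chromosome, a ``(starts, ends, codes)`` triple of numpy arrays of
        run-length intervals that are sorted, non-overlapping and together
        cover ``[0, chrom_size)``.  ``codes`` index into ``states``.
    bin_size
        The segmentation grid in bp (default 200).  Every run boundary except
        chromosome ends must sit on the grid.
    """

    def __init__(
        self,
        chrom_sizes: Mapping[str, int],
        states: Sequence[str],
        runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        bin_size: int = 200,
    ) -> None:
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if len(set(states)) != len(states):
            raise ValueError("duplicate state labels")
        self.chrom_sizes = dict(chrom_sizes)
        self.states = list(states)
        self.bin_size = int(bin_size)
        self.runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, size in self.chrom_sizes.items():
            if chrom not in runs:
                raise ValueError(f"no runs for chromosome {chrom}")
            starts, ends, codes = (np.asarray(a) for a in runs[chrom])
            if starts.size == 0:
                raise ValueError(f"empty run list for chromosome {chrom}")
            if starts[0] != 0 or ends[-1] != size:
                raise ValueError(f"runs do not cover chromosome {chrom}")
            if not np.all(starts[1:] == ends[:-1]):
                raise ValueError(f"runs on {chrom} are not contiguous/sorted")
            interior = np.concatenate([starts[1:]])
            if np.any(interior % self.bin_size != 0):
                raise ValueError(
                    f"run boundary off the {self.bin_size} bp grid on {chrom}"
                )
            self.runs[chrom] = (
                starts.astype(np.int64),
                ends.astype(np.int64),
                codes.astype(np.int64),
            )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_intervals(
        cls,
        intervals: Sequence[tuple[GenomicInterval, str]],
        chrom_sizes: Mapping[str, int],
        bin_size: int = 200,
        states: Sequence[str] | None = None,
    ) -> "StateSegmentation":
        """Build from labelled intervals, filling gaps with ``unassigned``.

        Raises on the first overlapping pair and on intervals outside
        ``chrom_sizes``.  Gap bp counts are logged.
        """
        if states is None:
            seen: list[str] = []
            for _, lab in intervals:
                if lab not in seen:
                    seen.append(lab)
            states = seen
        states = list(states)
        by_chrom: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chrom_sizes}
        for iv, lab in intervals:
            if iv.chrom not in chrom_sizes:
                raise ValueError(f"unknown chromosome {iv.chrom!r} in segmentation")
            if iv.end > chrom_sizes[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome size {chrom_sizes[iv.chrom]}"
                )
            by_chrom[iv.chrom].append((iv.start, iv.end, lab))

        code_of = {s: i for i, s in enumerate(states)}
        unassigned_code = len(states)  # provisional; appended only if needed
        gap_bp = 0
        runs = {}
        for chrom, size in chrom_sizes.items():
            recs = sorted(by_chrom[chrom])
            starts, ends, codes = [], [], []
            cursor = 0
            for s, e, lab in recs:
                if s < cursor:
                    raise ValueError(
                        f"overlapping records at {chrom}:{s}-{e} "
                        f"(previous record ends at {cursor})"
                    )
                if s > cursor:
                    starts.append(cursor)
                    ends.append(s)
                    codes.append(unassigned_code)
                    gap_bp += s - cursor
                starts.append(s)
                ends.append(e)
                codes.append(code_of[lab])
                cursor = e
            if cursor < size:
                starts.append(cursor)
                ends.append(size)
                codes.append(unassigned_code)
                gap_bp += size - cursor
            if not starts:
                starts, ends, codes = [0], [size], [unassigned_code]
                gap_bp += size
            runs[chrom] = (np.array(starts), np.array(ends), np.array(codes))

        if gap_bp > 0:
            states = states + [UNASSIGNED]
            logger.warning(
                "segmentation has %d bp of uncovered genome, labelled %r",
                gap_bp,
                UNASSIGNED,
            )
        return cls(chrom_sizes, states, runs, bin_size=bin_size)

    # -- queries ------------------------------------------------------------

    @property
    def has_unassigned(self) -> bool:
        return UNASSIGNED in self.states

    def state_code(self, label: str) -> int:
        return self.states.index(label)

    def intervals(self) -> Iterator[tuple[GenomicInterval, str]]:
        """Yield run-length intervals with their state label, in order."""
        for chrom in self.chrom_sizes:
            starts, ends, codes = self.runs[chrom]
            for s, e, c in zip(starts, ends, codes):
                yield GenomicInterval(chrom, int(s), int(e)), self.states[int(c)]

    def state_bp(self) -> pd.Series:
        """Total bp per state label (including ``unassigned`` if present)."""
        bp = np.zeros(len(self.states), dtype=np.int64)
        for starts, ends, codes in self.runs.values():
            np.add.at(bp, codes, ends - starts)
        return pd.Series(bp, index=self.states, name="bp")

    def states_assigned(self) -> list[str]:
        """State labels excluding the reserved ``unassigned`` label."""
        return [s for s in self.states if s != UNASSIGNED]

    def n_bins(self, chrom: str) -> int:
        size = self.chrom_sizes[chrom]
        return -(-size // self.bin_size)

    def bin_codes(self, chrom: str) -> np.ndarray:
        """Per-bin state codes for one chromosome (vector of length n_bins)."""
        starts, ends, codes = self.runs[chrom]
        n = self.n_bins(chrom)
        bin_starts = np.arange(n, dtype=np.int64) * self.bin_size
        idx = np.searchsorted(ends, bin_starts, side="right")
        return codes[idx]

    def state_at(self, chrom: str, pos: int | np.ndarray) -> np.ndarray:
        """State code(s) at base-pair position(s) on one chromosome."""
        starts, ends, codes = self.runs[chrom]
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        size = self.chrom_sizes[chrom]
        if np.any((pos < 0) | (pos >= size)):
            raise ValueError(f"position outside chromosome {chrom}")
        idx = np.searchsorted(ends, pos, side="right")
        return codes[idx]

    def overlap_bp(self, chrom: str, start: int, end: int) -> np.ndarray:
        """bp of each state within ``[start, end)`` (clipped to the chromosome).

        Returns a vector over ``self.states``.
        """
        out = np.zeros(len(self.states), dtype=np.int64)
        size = self.chrom_sizes[chrom]
        start, end = max(0, start), min(size, end)
        if start >= end:
            return out
        starts, ends, codes = self.runs[chrom]
        i0 = np.searchsorted(ends, start, side="right")
        i1 = np.searchsorted(starts, end, side="left")
        ov = np.minimum(ends[i0:i1], end) - np.maximum(starts[i0:i1], start)
        np.add.at(out, codes[i0:i1], ov)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (iv.chrom, iv.start, iv.end, lab) for iv, lab in self.intervals()
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StateSegmentation):
            return NotImplemented
        return (
            self.chrom_sizes == other.chrom_sizes
            and self.states == other.states
            and self.bin_size == other.bin_size
            and all(
                all(np.array_equal(a, b) for a, b in zip(self.runs[c], other.runs[c]))
                for c in self.chrom_sizes
            )
        )


@dataclass
class EmissionMatrix:
    """Per-state emission probabilities over marks/variants."""

    p: pd.DataFrame  # states x marks

    def __post_init__(self) -> None:
        if self.p.index.duplicated().any() or self.p.columns.duplicated().any():
            raise ValueError("duplicate state or mark names in emission matrix")
        vals = self.p.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)) or np.any(~np.isfinite(vals)):
            raise ValueError("emission probabilities must lie in [0, 1]")

    @property
    def states(self) -> list[str]:
        return list(self.p.index)

    @property
    def marks(self) -> list[str]:
        return list(self.p.columns)


@dataclass(frozen=True)
class GeneModel:
    """One gene record with strand-aware TSS/TTS."""

    gene_id: str
    interval: GenomicInterval
    feature_class: str = "protein_coding"  # protein_coding | TE | other

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id} needs a +/- strand")

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end

    @property
    def tts(self) -> int:
        return self.interval.end if self.interval.strand == "+" else self.interval.start

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class GeneModelSet:
    """A collection of gene records with unique ids."""

    def __init__(self, genes: Sequence[GeneModel]) -> None:
        ids = [g.gene_id for g in genes]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).loc[lambda s: s.duplicated()].iloc[0]
            raise ValueError(f"duplicate gene id {dup!r}")
        self.genes = list(genes)
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def subset(self, feature_class: str) -> "GeneModelSet":
        return GeneModelSet([g for g in self.genes if g.feature_class == feature_class])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                g.gene_id,
                g.chrom,
                g.interval.start,
                g.interval.end,
                g.strand,
                g.tss,
                g.tts,
                g.feature_class,
            )
            for g in self.genes
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "chrom", "start", "end",
                "strand", "tss", "tts", "feature_class",
            ],
        )


@dataclass
class PeakSet:
    """One TF experiment's binding intervals."""

    tf_id: str
    assay: str  # chip | dap | pwm
    peaks: list[GenomicInterval]
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        if self.assay not in {"chip", "dap", "pwm"}:
            raise ValueError(f"unknown assay {self.assay!r}")
        key = [(p.chrom, p.start, p.end) for p in self.peaks]
        if key != sorted(key):
            order = np.lexsort(
                (
                    [p.end for p in self.peaks],
                    [p.start for p in self.peaks],
                    [p.chrom for p in self.peaks],
                )
            )
            self.peaks = [self.peaks[i] for i in order]
            if self.scores is not None:
                self.scores = [self.scores[i] for i in order]

    def __len__(self) -> int:
        return len(self.peaks)

    def validate_against(self, chrom_sizes: Mapping[str, int]) -> None:
        for p in self.peaks:
            if p.chrom not in chrom_sizes or p.end > chrom_sizes[p.chrom]:
                raise ValueError(
                    f"peak {p.chrom}:{p.start}-{p.end} of {self.tf_id} is outside "
                    "the attached genome"
                )


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix with per-sample tissue tags."""

    tpm: pd.DataFrame  # genes x samples
    tissues: pd.Series  # sample -> tissue label

    def __post_init__(self) -> None:
        if self.tpm.index.duplicated().any():
            dup = self.tpm.index[self.tpm.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in expression matrix")
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        missing = [c for c in self.tpm.columns if c not in self.tissues.index]
        if missing:
            raise ValueError(f"samples without tissue tag: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.tpm.columns)

    def tissue_means(self) -> pd.DataFrame:
        """Genes x tissues mean TPM (replicates averaged)."""
        groups = self.tissues.loc[self.tpm.columns]
        return self.tpm.T.groupby(groups.values).mean().T


@dataclass
class CoexpressionTable:
    """Per-TF rank-like co-expression scores; lower = more positively
    co-expressed (ATTED-style)."""

    scores: pd.DataFrame  # columns: tf_id, gene_id, score

    def __post_init__(self) -> None:
        req = {"tf_id", "gene_id", "score"}
        if not req.issubset(self.scores.columns):
            raise ValueError(f"co-expression table needs columns {sorted(req)}")
        if (self.scores["score"] < 0).any():
            raise ValueError("co-expression scores must be >= 0")
        if self.scores.duplicated(["tf_id", "gene_id"]).any():
            raise ValueError("duplicate (tf, gene) entry in co-expression table")

    def tfs(self) -> list[str]:
        return list(self.scores["tf_id"].unique())

    def for_tf(self, tf_id: str) -> pd.Series:
        sub = self.scores[self.scores["tf_id"] == tf_id]
        if sub.empty:
            raise KeyError(f"TF {tf_id!r} absent from co-expression table")
        return sub.set_index("gene_id")["score"]
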