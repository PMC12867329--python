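"""Comparison of chromatin-state models and of coordinate annotations.

Two segmentations over the same genome are compared through their bp-level
transition matrix (co-occurrence of labels) and per-state-pair Jaccard
similarity; reduced models (marks removed in silico) are matched to the full
model by best Jaccard.  Emission matrices of two species are merged over
shared marks and clustered hierarchically.  Gene TSS/TTS annotations can be
updated from experimentally determined anchor points, with strand-aware
per-gene shifts and a tolerance-based set Jaccard.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import UNASSIGNED, EmissionMatrix, GeneModelSet, GeneModel, GenomicInterval, StateSegmentation

logger = logging.getLogger("chromstates")


def _check_same_genome(segA: StateSegmentation, segB: StateSegmentation) -> None:
    if set(segA.chrom_sizes) != set(segB.chrom_sizes):
        raise ValueError("segmentations have different chromosome sets")
    for c in segA.chrom_sizes:
        if segA.chrom_sizes[c] != segB.chrom_sizes[c]:
            raise ValueError(f"chromosome {c} has different sizes in the two models")


def transition_matrix(
    segA: StateSegmentation, segB: StateSegmentation
) -> pd.DataFrame:
    """bp of co-occurrence of each (stateA, stateB) label pair.

    Base pairs unassigned in either model are excluded, so the total equals
    the bp assigned in both.
    """
    _check_same_genome(segA, segB)
    nA, nB = len(segA.states), len(segB.states)
    counts = np.zeros((nA, nB), dtype=np.int64)
    for chrom in segA.chrom_sizes:
        sA, eA, cA = segA.runs[chrom]
        sB, eB, cB = segB.runs[chrom]
        # sweep the union of run boundaries; each elementary segment has one
        # label in each model
        bounds = np.union1d(sA, sB)
        seg_starts = bounds
        seg_ends = np.append(bounds[1:], segA.chrom_sizes[chrom])
        codesA = cA[np.searchsorted(eA, seg_starts, side="right")]
        codesB = cB[np.searchsorted(eB, seg_starts, side="right")]
        np.add.at(counts, (codesA, codesB), seg_ends - seg_starts)
    df = pd.DataFrame(counts, index=segA.states, columns=segB.states)
    return df.loc[segA.states_assigned(), segB.states_assigned()]


def transition_long(tm: pd.DataFrame) -> pd.DataFrame:
    """Alluvial-ready long form (stateA, stateB, bp) of a transition matrix."""
    long = tm.stack().reset_index()
    long.columns = ["stateA", "stateB", "bp"]
    return long[long["bp"] > 0].reset_index(drop=True)


def state_jaccard(
    segA: StateSegmentation, segB: StateSegmentation
) -> pd.DataFrame:
    """Jaccard similarity J(a,b) = bp(a∩b) / bp(a∪b) for every state pair."""
    tm = transition_matrix(segA, segB)
    bpA = segA.state_bp().loc[tm.index].to_numpy(dtype=float)
    bpB = segB.state_bp().loc[tm.columns].to_numpy(dtype=float)
    inter = tm.to_numpy(dtype=float)
    union = bpA[:, None] + bpB[None, :] - inter
    zeroA = bpA == 0
    zeroB = bpB == 0
    if zeroA.any() or zeroB.any():
        logger.warning(
            "states with zero bp: %s / %s",
            list(tm.index[zeroA]), list(tm.columns[zeroB]),
        )
    with np.errstate(invalid="ignore"):
        J = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return pd.DataFrame(J, index=tm.index, columns=tm.columns)


def mark_removal_experiment(
    full_seg: StateSegmentation,
    reduced_segs: dict[str, StateSegmentation],
    domains: pd.Series | None = None,
) -> pd.DataFrame:
    """Best-match Jaccard of each full-model state under each mark removal.

    For every reduced segmentation (keyed by the removed mark label) and each
    full-model state, reports the reduced state maximising Jaccard and its J;
    when a state -> domain mapping is supplied, a per-domain mean is included
    so removals can be ranked by how much they perturb each chromatin domain.
    """
    rows = []
    for removal, seg in reduced_segs.items():
        J = state_jaccard(full_seg, seg)
        for state in J.index:
            best = J.loc[state].idxmax()
            rows.append(
                (removal, state,
                 domains.get(state, "NA") if domains is not None else "NA",
                 best, float(J.loc[state, best]))
            )
    df = pd.DataFrame(
        rows, columns=["removal", "full_state", "domain", "best_match", "jaccard"]
    )
    return df


def emission_clustering(
    emissA: EmissionMatrix,
    emissB: EmissionMatrix,
    mark_map: dict[str, str] | None = None,
    metric: str = "euclidean",
    method: str = "average",
    label_a: str = "",
    label_b: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge two emission matrices over shared marks and cluster the states.

    ``mark_map`` renames marks of B into A's namespace (e.g., a species'
    H2A.M.2 used interchangeably with the other's H2A.W); unmapped,
    non-shared marks are dropped with a warning.  Returns the merged
    states x marks matrix and the dendrogram as a merge table
    (node1, node2, height, size) in scipy linkage convention.
    """
    pB = emissB.p.rename(columns=mark_map or {})
    common = [m for m in emissA.marks if m in pB.columns]
    dropped = (set(emissA.marks) - set(common)) | (set(pB.columns) - set(common))
    if dropped:
        logger.warning("emission_clustering: dropping non-shared marks %s",
                       sorted(dropped))
    if len(common) < 2:
        raise ValueError(f"need >= 2 common marks, got {len(common)}")
    pA = emissA.p[common]
    pB = pB[common]
    if label_a or label_b or set(pA.index) & set(pB.index):
        la = label_a or "A"
        lb = label_b or "B"
        pA = pA.rename(index=lambda s: f"{la}:{s}")
        pB = pB.rename(index=lambda s: f"{lb}:{s}")
    merged = pd.concat([pA, pB])
    Z = hierarchy.linkage(pdist(merged.to_numpy(), metric=metric), method=method)
    merge_table = pd.DataFrame(Z, columns=["node1", "node2", "height", "size"])
    return merged, merge_table


# ---------------------------------------------------------------------------
# coordinate updates from experimental anchors
# ---------------------------------------------------------------------------

def update_coordinates(
    genes: GeneModelSet,
    anchors: list[tuple[str, int, str]],
    kind: str = "TSS",
    max_distance: int = 500,
) -> tuple[GeneModelSet, pd.DataFrame]:
    """Update gene TSS (or TTS) positions from experimental anchor points.

    Each anchor (chrom, base, strand) is assigned to the nearest gene anchor
    of the same kind on the matching strand within ``max_distance`` bp; ties
    go to the lexicographically smaller gene id.  When several anchors match
    one gene, the nearest wins.  The reported shift is new - old in the
    gene's reading direction (positive = downstream), i.e. the sign is
    flipped on the minus strand.  Unmatched anchors are counted in the log.
    """
    if kind not in {"TSS", "TTS"}:
        raise ValueError("kind must be TSS or TTS")

    def old_base(g: GeneModel) -> int:
        if kind == "TSS":
            return g.tss if g.strand == "+" else g.tss - 1
        return g.tts - 1 if g.strand == "+" else g.tts

    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_key.setdefault((g.chrom, g.strand), []).append(g)
    sorted_keys = {}
    for key, gs in by_key.items():
        gs.sort(key=lambda g: (old_base(g), g.gene_id))
        sorted_keys[key] = (np.array([old_base(g) for g in gs]), gs)

    best: dict[str, tuple[int, int]] = {}  # gene -> (distance, anchor base)
    unmatched = 0
    for chrom, pos, strand in anchors:
        entry = sorted_keys.get((chrom, strand))
        if entry is None:
            unmatched += 1
            continue
        bases, gs = entry
        i = np.searchsorted(bases, pos)
        cands = []
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(gs):
                cands.append((abs(int(bases[j]) - pos), gs[j].gene_id, gs[j]))
        cands.sort()
        if not cands or cands[0][0] > max_distance:
            unmatched += 1
            continue
        dist, gid, g = cands[0]
        if gid not in best or dist < best[gid][0]:
            best[gid] = (dist, pos)
    if unmatched:
        logger.info("update_coordinates: %d anchors unmatched within %d bp",
                    unmatched, max_distance)

    updated: list[GeneModel] = []
    shifts = []
    for g in genes:
        if g.gene_id not in best:
            updated.append(g)
            continue
        _, pos = best[g.gene_id]
        iv = g.interval
        if kind == "TSS":
            new = (GenomicInterval(iv.chrom, pos, iv.end, "+")
                   if g.strand == "+"
                   else GenomicInterval(iv.chrom, iv.start, pos + 1, "-"))
        else:
            new = (GenomicInterval(iv.chrom, iv.start, pos + 1, "+")
                   if g.strand == "+"
                   else GenomicInterval(iv.chrom, pos, iv.end, "-"))
        raw = pos - old_base(g)
        shift = raw if g.strand == "+" else -raw
        try:
            updated.append(GeneModel(g.gene_id, new, g.feature_class))
            shifts.append((g.gene_id, shift))
        except ValueError:
            logger.warning("update for %s would invert the gene, kept original",
                           g.gene_id)
            updated.append(g)
    shift_df = pd.DataFrame(shifts, columns=["gene_id", "shift"]).set_index("gene_id")
    return GeneModelSet(updated), shift_df


def coordinate_set_jaccard(
    coordsA: dict[str, int], coordsB: dict[str, int], tolerance_bp: int = 0
) -> float:
    """Similarity of two per-gene coordinate sets.

    |genes whose coordinates agree within tolerance| / |genes with a
    coordinate in either set|.
    """
    union = set(coordsA) | set(coordsB)
    if not union:
        return float("nan")
    agree = sum(
        1 for g in set(coordsA) & set(coordsB)
        if abs(coordsA[g] - coordsB[g]) <= tolerance_bp
    )
    return agree / len(union)
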