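"""Naive per-bp reference implementations used to cross-check the package.

Everything here expands genomes to one-entry-per-base-pair numpy arrays and
counts directly; deliberately independent of the run-length/searchsorted
arithmetic inside the package.  Only usable on small genomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from chromstates.core import UNASSIGNED, StateSegmentation


def perbp_codes(seg: StateSegmentation) -> dict[str, np.ndarray]:
    out = {}
    for chrom, size in seg.chrom_sizes.items():
        arr = np.empty(size, dtype=np.int64)
        for iv, lab in seg.intervals():
            if iv.chrom == chrom:
                arr[iv.start:iv.end] = seg.states.index(lab)
        out[chrom] = arr
    return out


def oracle_coverage(seg: StateSegmentation) -> pd.Series:
    arrs = perbp_codes(seg)
    counts = np.zeros(len(seg.states), dtype=np.int64)
    for arr in arrs.values():
        counts += np.bincount(arr, minlength=len(seg.states))
    s = pd.Series(counts, index=seg.states).loc[seg.states_assigned()]
    return s / s.sum() * 100.0


def oracle_composition(seg: StateSegmentation, genes) -> pd.DataFrame:
    classes = ["protein_coding", "TE", "other", "intergenic"]
    prio = {"intergenic": 0, "other": 1, "TE": 2, "protein_coding": 3}
    arrs = perbp_codes(seg)
    out = np.zeros((len(seg.states), 4), dtype=np.int64)
    for chrom, arr in arrs.items():
        cls = np.zeros(len(arr), dtype=np.int64)
        for g in genes:
            if g.chrom != chrom:
                continue
            for bp in range(g.interval.start, min(g.interval.end, len(arr))):
                cls[bp] = max(cls[bp], prio[g.feature_class])
        for bp in range(len(arr)):
            col = {0: 3, 1: 2, 2: 1, 3: 0}[cls[bp]]
            out[arr[bp], col] += 1
    df = pd.DataFrame(out, index=seg.states, columns=classes)
    df = df.loc[seg.states_assigned()]
    return df.div(df.sum(axis=1).replace(0, np.nan), axis=0)


def oracle_neighbourhood(
    seg: StateSegmentation, anchors, L: int
) -> pd.DataFrame:
    """Brute-force anchor walk on the bin grid."""
    states = seg.states
    una = states.index(UNASSIGNED) if UNASSIGNED in states else -1
    bin_codes = {}
    for chrom, size in seg.chrom_sizes.items():
        arr = perbp_codes(seg)[chrom]
        n = -(-size // seg.bin_size)
        bin_codes[chrom] = np.array(
            [arr[b * seg.bin_size] for b in range(n)]
        )
    bg = np.zeros(len(states))
    for codes in bin_codes.values():
        for c in codes:
            if c != una:
                bg[c] += 1
    bg = bg / bg.sum()
    offsets = list(range(-L, L + 1))
    hits = np.zeros((len(states), len(offsets)))
    denom = np.zeros(len(offsets))
    for chrom, pos, strand in anchors:
        codes = bin_codes[chrom]
        b0 = pos // seg.bin_size
        for j, k in enumerate(offsets):
            b = b0 + k if strand != "-" else b0 - k
            if not (0 <= b < len(codes)):
                continue
            if codes[b] == una:
                continue
            hits[codes[b], j] += 1
            denom[j] += 1
    enr = np.full_like(hits, np.nan)
    for j in range(len(offsets)):
        for s in range(len(states)):
            if bg[s] > 0 and denom[j] > 0:
                enr[s, j] = (hits[s, j] / denom[j]) / bg[s]
            elif bg[s] > 0:
                enr[s, j] = np.nan
    df = pd.DataFrame(enr, index=states, columns=offsets)
    return df.loc[seg.states_assigned()]


def oracle_transition(segA: StateSegmentation, segB: StateSegmentation):
    arrsA, arrsB = perbp_codes(segA), perbp_codes(segB)
    out = np.zeros((len(segA.states), len(segB.states)), dtype=np.int64)
    for chrom in segA.chrom_sizes:
        for a, b in zip(arrsA[chrom], arrsB[chrom]):
            out[a, b] += 1
    df = pd.DataFrame(out, index=segA.states, columns=segB.states)
    return df.loc[segA.states_assigned(), segB.states_assigned()]


def oracle_jaccard(segA: StateSegmentation, segB: StateSegmentation):
    arrsA, arrsB = perbp_codes(segA), perbp_codes(segB)
    rows = segA.states_assigned()
    cols = segB.states_assigned()
    out = pd.DataFrame(0.0, index=rows, columns=cols)
    a_all = np.concatenate([arrsA[c] for c in segA.chrom_sizes])
    b_all = np.concatenate([arrsB[c] for c in segA.chrom_sizes])
    for ra in rows:
        ia = segA.states.index(ra)
        for rb in cols:
            ib = segB.states.index(rb)
            inter = int(np.sum((a_all == ia) & (b_all == ib)))
            union = int(np.sum((a_all == ia) | (b_all == ib)))
            out.loc[ra, rb] = inter / union if union else 0.0
    return out


def oracle_signal_mean(seg: StateSegmentation, signal: pd.DataFrame) -> pd.Series:
    arrs = perbp_codes(seg)
    vals = {c: np.zeros(seg.chrom_sizes[c]) for c in seg.chrom_sizes}
    for rec in signal.itertuples(index=False):
        if rec.chrom not in vals:
            continue
        vals[rec.chrom][rec.start:rec.end] = rec.value
    sums = np.zeros(len(seg.states))
    counts = np.zeros(len(seg.states))
    for chrom in seg.chrom_sizes:
        np.add.at(sums, arrs[chrom], vals[chrom])
        np.add.at(counts, arrs[chrom], 1)
    with np.errstate(invalid="ignore"):
        mean = sums / counts
    return pd.Series(mean, index=seg.states).loc[seg.states_assigned()]
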