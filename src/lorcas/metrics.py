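"""Evaluation metrics: truth-aligned error rates, HERS windows, Nx/NGx, QV.

Error rate is defined as edit operations per alignment column (matches +
mismatches + indel columns) of the best alignment of a read against its
truth interval or a reference.  HERS windows tile the truth coordinates in
500 bp steps; a window with error above 0.5 is high-error, and a read "has
HERS" when at least one window does.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _align, candidates as cand_mod
from ._align import OP_D, OP_M, OP_X
from .correction import _chain_anchors_tolerant
from .io_core import RawRead
from .simulate import ReadTruth, SyntheticGenome


# ---------------------------------------------------------------------------
# reference alignment
# ---------------------------------------------------------------------------


def align_to_reference(
    query: np.ndarray, ref: np.ndarray, k: int = 13
) -> tuple[np.ndarray, tuple[int, int], tuple[int, int]]:
    """Best-effort alignment of a query onto a (longer) reference.

    Anchors via exact k-mers, chains them tolerantly, refines the chained
    region piecewise, and aligns the outer query tails globally against the
    facing reference slack.  Returns (ops, query interval, ref interval).
    """
    stride = max(1, len(query) // 8000)
    tpos, cpos, strand = cand_mod.match_kmer_pairs(query, ref, k, stride=stride,
                                                   max_occ=8)
    fwd = strand == "+"
    tpos, cpos = tpos[fwd], cpos[fwd]
    if len(tpos) == 0:
        band = _align.default_band(len(query), len(ref), 0.5)
        ops = _align._segment_align(query, ref, band)  # memory-guarded
        return ops, (0, len(query)), (0, len(ref))
    idx = _chain_anchors_tolerant(tpos, cpos, k)
    qt, rt = tpos[idx], cpos[idx]
    sparse = _align.sparsify_anchors(qt, rt, min_spacing=256)
    qt, rt = qt[sparse], rt[sparse]
    q_lo, q_hi = int(qt[0]), int(qt[-1]) + k
    r_lo, r_hi = int(rt[0]), int(rt[-1]) + k
    anchors = np.stack([qt - q_lo, rt - r_lo], axis=1)
    core = _align.align_with_anchors(query[q_lo:q_hi], ref[r_lo:r_hi], anchors, k,
                                     band_frac=0.55)
    # tails: bounded-memory blockwise extension that never stops on error
    from .correction import _extend_right

    l_ops, lq, lr, _ = _extend_right(
        query[:q_lo][::-1].copy(),
        ref[max(0, r_lo - q_lo - 500) : r_lo][::-1].copy(),
        0, 0, 500, 1.1, 150, 150,
    )
    t_ops, tq, tr, _ = _extend_right(
        query[q_hi:], ref[r_hi : min(len(ref), r_hi + (len(query) - q_hi) + 500)],
        0, 0, 500, 1.1, 150, 150,
    )
    ops = np.concatenate([l_ops[::-1], core, t_ops])
    # any query bases the tails could not consume count as unaligned edits
    missing = (q_lo - lq) + (len(query) - q_hi - tq)
    if missing > 0:
        ops = np.concatenate([ops, np.full(missing, _align.OP_D, np.uint8)])
    return ops, (0, len(query)), (r_lo - lr, r_hi + tr)


def truth_interval_codes(genome: SyntheticGenome, truth: ReadTruth) -> np.ndarray:
    codes = _align.encode(genome.sequence)[truth.start : truth.end]
    if truth.strand == "-":
        codes = _align.revcomp_codes(codes)
    return codes


def read_error_rate(
    read: RawRead,
    reference: np.ndarray,
    k: int = 13,
) -> float:
    """Edits per alignment column against the (truth) reference codes."""
    q = _align.encode(read.sequence)
    ops, _, _ = align_to_reference(q, reference, k)
    return _align.difference(ops)


def error_rate_vs_truth(
    read: RawRead, genome: SyntheticGenome, truth: ReadTruth, pad: int = 200
) -> float:
    ref = truth_interval_codes(genome, truth)
    return read_error_rate(read, ref)


# ---------------------------------------------------------------------------
# HERS windows
# ---------------------------------------------------------------------------


def window_errors(
    ops: np.ndarray, window: int = 500, min_last: Optional[int] = None
) -> np.ndarray:
    """Per-window error fractions over the reference span of an alignment.

    Windows tile reference (first-sequence) coordinates; a trailing partial
    window shorter than ``min_last`` (default window/2) is merged into the
    previous one.
    """
    if min_last is None:
        min_last = window // 2
    cons_r = (ops == OP_M) | (ops == OP_X) | (ops == OP_D)
    rpos = np.cumsum(cons_r) - cons_r  # reference offset per column
    span = int(rpos[-1]) + 1 if len(rpos) else 0
    if span == 0:
        return np.empty(0)
    n_win = max(1, span // window)
    if span - n_win * window >= min_last:
        n_win += 1
    widx = np.minimum(rpos // window, n_win - 1)
    edits = (ops != OP_M).astype(np.int64)
    err = np.zeros(n_win, np.int64)
    tot = np.zeros(n_win, np.int64)
    np.add.at(err, widx, edits)
    np.add.at(tot, widx, 1)
    return err / np.maximum(tot, 1)


def hers_windows(
    read: RawRead,
    reference: np.ndarray,
    window: int = 500,
    cutoff: float = 0.5,
) -> int:
    """Count of tiled windows with alignment error above ``cutoff``."""
    q = _align.encode(read.sequence)
    ops, _, _ = align_to_reference(q, reference)
    w = window_errors(ops, window)
    return int((w > cutoff).sum())


def has_hers(read: RawRead, reference: np.ndarray, window: int = 500,
             cutoff: float = 0.5) -> bool:
    return hers_windows(read, reference, window, cutoff) >= 1


# ---------------------------------------------------------------------------
# assembly statistics
# ---------------------------------------------------------------------------


def nx(lengths: Sequence[int], x: float, genome_size: Optional[int] = None) -> int:
    """Smallest length whose descending cumulative sum reaches x% of the
    total (Nx) or of the genome size (NGx)."""
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    ls = sorted((int(l) for l in lengths), reverse=True)
    if not ls:
        return 0
    base = genome_size if genome_size is not None else sum(ls)
    threshold = x / 100.0 * base
    acc = 0
    for l in ls:
        acc += l
        if acc >= threshold:
            return l
    return 0  # genome_size larger than total assembly


def qv(mismatches_per_100kbp: float, indels_per_100kbp: float) -> float:
    """10*log10(100000 / (mismatches + indels per 100 kbp))."""
    if mismatches_per_100kbp < 0 or indels_per_100kbp < 0:
        raise ValueError("rates must be non-negative")
    total = mismatches_per_100kbp + indels_per_100kbp
    if total == 0:
        return math.inf
    return 10.0 * math.log10(100000.0 / total)


def percent_below(error_rates: Sequence[float], cutoff: float = 0.05) -> float:
    rates = list(error_rates)
    if not rates:
        return 0.0
    return 100.0 * sum(1 for r in rates if r < cutoff) / len(rates)


@dataclass
class AssemblyStats:
    n_seqs: int
    total_bases: int
    max_length: int
    n50: int
    n75: int
    ng50: Optional[int] = None
    qv: Optional[float] = None

    def to_json(self) -> str:
        d = dict(self.__dict__)
        if d["qv"] == math.inf:
            d["qv"] = "inf"
        return json.dumps(d, indent=2)


def assembly_stats(
    lengths: Sequence[int], genome_size: Optional[int] = None,
    qv_value: Optional[float] = None,
) -> AssemblyStats:
    ls = sorted((int(l) for l in lengths), reverse=True)
    return AssemblyStats(
        n_seqs=len(ls),
        total_bases=sum(ls),
        max_length=ls[0] if ls else 0,
        n50=nx(ls, 50) if ls else 0,
        n75=nx(ls, 75) if ls else 0,
        ng50=nx(ls, 50, genome_size) if genome_size and ls else None,
        qv=qv_value,
    )


# ---------------------------------------------------------------------------
# contig-vs-reference evaluation (simulated data)
# ---------------------------------------------------------------------------


def contigs_vs_reference(
    contigs: Sequence[RawRead] | Sequence, genome: SyntheticGenome, k: int = 15
) -> tuple[float, float]:
    """(covered fraction of the genome, aligned identity) for an assembly.

    Each contig (either orientation) is aligned to the genome with the
    anchored aligner; covered reference intervals are unioned.
    """
    ref = _align.encode(genome.sequence)
    covered = np.zeros(len(ref) + 1, np.int32)
    match_cols = 0
    total_cols = 0
    for c in contigs:
        seq = c.sequence if hasattr(c, "sequence") else str(c)
        best = None
        for variant in (seq, _align.revcomp(seq)):
            q = _align.encode(variant)
            ops, _, r_iv = align_to_reference(q, ref, k)
            diff = _align.difference(ops)
            if best is None or diff < best[0]:
                best = (diff, ops, r_iv)
        diff, ops, (r_lo, r_hi) = best
        m, x, i, d = _align.ops_counts(ops)
        match_cols += m
        total_cols += m + x + i + d
        covered[max(0, r_lo)] += 1
        covered[min(len(ref), r_hi)] -= 1
    frac = float((np.cumsum(covered[:-1]) > 0).mean()) if len(ref) else 0.0
    identity = match_cols / total_cols if total_cols else 0.0
    return frac, identity
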