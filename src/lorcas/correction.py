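"""Two-pass progressive error correction.

Pass 1 corrects low-error subsequences: candidates are aligned blockwise
from the seed k-mer pair (500 bp blocks, banded edit distance per block,
extension stops at a >50%-error block), an adaptive per-template quality
threshold selects the supports, and a plurality consensus replaces the
covered intervals; the whole template (corrected + uncorrected parts) is
emitted.  Pass 2 re-runs the procedure on pass-1 output with a sensitive
realigner (anchor chain + piecewise global alignment) that can cross
high-error regions, and emits only the corrected intervals, so one template
may yield several fragments.

A coverage count array (CCA) gates alignment work: once every base of the
candidate's approximate interval is supported by more than C alignments,
the local alignment is skipped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from numba import njit

from . import _align, candidates as cand_mod
from ._align import OP_D, OP_I, OP_M, OP_X
from .candidates import CandidateHit, KmerIndex
from .io_core import PipelineConfig, RawRead

logger = logging.getLogger("lorcas")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ThresholdEstimate:
    """Adaptive per-template alignment-quality threshold."""

    n: int
    d_i: list[float]
    d0: float
    D: float
    d: float


@dataclass
class SupportAlignment:
    """A recorded local alignment of one candidate onto the template."""

    candidate_id: str
    strand: str
    t_interval: tuple[int, int]
    c_interval: tuple[int, int]  # forward-strand candidate coordinates
    difference: float
    ops: np.ndarray  # edit transcript, template = first sequence
    cseq: np.ndarray = field(repr=False, default=None)  # oriented aligned slice
    terminated_early: bool = False

    @property
    def columns(self) -> int:
        return len(self.ops)


class CoverageCountArray:
    """Per-base count of accepted supports, gating further alignments."""

    def __init__(self, length: int, C: int = 12):
        self.counts = np.zeros(length, np.int32)
        self.C = C

    def gate(self, interval: tuple[int, int]) -> bool:
        """True = proceed with the alignment; False = skip (all counts > C)."""
        s, e = max(0, interval[0]), min(len(self.counts), interval[1])
        if e <= s:
            return True
        return not bool((self.counts[s:e] > self.C).all())

    def update(self, interval: tuple[int, int]) -> None:
        s, e = max(0, interval[0]), min(len(self.counts), interval[1])
        if e > s:
            self.counts[s:e] += 1


@dataclass
class CorrectedRead:
    id: str
    sequence: str
    source_template_id: str
    pass_num: int
    template_interval: tuple[int, int]
    corrected_mask: Optional[np.ndarray] = field(repr=False, default=None)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def as_raw(self) -> RawRead:
        return RawRead(self.id, self.sequence)


# ---------------------------------------------------------------------------
# threshold arithmetic
# ---------------------------------------------------------------------------


def threshold_from_differences(
    d_i: Sequence[float],
    global_threshold: float = 0.5,
    sigma: float = 5.0,
    mode: str = "quality",
    normalize: bool = True,
) -> ThresholdEstimate:
    """Compute the individual threshold from recorded alignment differences.

    ``mode='quality'`` treats the rule as a bound in quality space (mean
    quality minus sigma deviations), i.e. d = d0 + sigma*D in difference
    space; ``mode='literal'`` applies d = d0 - sigma*D as printed.  Either
    way d is clamped to [0, global_threshold]; with no recorded alignments
    the global threshold is the fallback.
    """
    d_list = [float(x) for x in d_i]
    n = len(d_list)
    if n == 0:
        return ThresholdEstimate(0, [], 0.0, 0.0, global_threshold)
    arr = np.asarray(d_list)
    d0 = float(arr.mean())
    ss = float(((arr - d0) ** 2).sum())
    D = math.sqrt(ss / n) if normalize else math.sqrt(ss)
    d = d0 + sigma * D if mode == "quality" else d0 - sigma * D
    d = min(max(d, 0.0), global_threshold)
    return ThresholdEstimate(n, d_list, d0, D, d)


def filter_supports(
    aligned: list[tuple[CandidateHit, SupportAlignment]],
    estimate: ThresholdEstimate,
    global_threshold: float,
    min_coverage: int = 4,
):
    """Keep supports whose difference passes min(global, individual).

    Returns (kept, uncorrectable) where uncorrectable marks templates with
    fewer passing supports than the consensus minimum coverage.
    """
    eff = min(global_threshold, estimate.d)
    kept = [(h, a) for h, a in aligned if a.difference <= eff]
    return kept, len(kept) < min_coverage


# ---------------------------------------------------------------------------
# blockwise alignment
# ---------------------------------------------------------------------------

def _extend_right(
    t: np.ndarray,
    c: np.ndarray,
    t0: int,
    c0: int,
    block: int,
    max_block_error: float,
    band: int,
    slack: int,
):
    """Blockwise extension toward the sequence ends (template side first).

    Returns (ops, t_end, c_end, stopped_by_error).
    """
    return _align.extend_blockwise(
        t, c, t0, c0, block, max_block_error, band, slack
    )


def blockwise_align(
    template: np.ndarray,
    candidate_oriented: np.ndarray,
    seed_t: int,
    seed_c: int,
    block: int = 500,
    max_block_error: float = 0.5,
    band: Optional[int] = None,
    slack: Optional[int] = None,
):
    """Blockwise banded extension from a seed position in both directions.

    Both sequences are code arrays; the candidate must already be oriented
    to the template strand.  Returns (ops, t_interval, c_interval,
    terminated_early) or None when nothing aligns.
    """
    if band is None:
        band = block // 16 + 24
    if slack is None:
        slack = block // 16 + 24
    r_ops, t_hi, c_hi, r_stop = _extend_right(
        template, candidate_oriented, seed_t, seed_c, block, max_block_error,
        band, slack,
    )
    l_ops, lt, lc, l_stop = _extend_right(
        template[:seed_t][::-1].copy(),
        candidate_oriented[:seed_c][::-1].copy(),
        0, 0, block, max_block_error, band, slack,
    )
    t_lo, c_lo = seed_t - lt, seed_c - lc
    ops = np.concatenate([l_ops[::-1], r_ops])
    if len(ops) == 0:
        return None
    early = r_stop or l_stop
    return ops, (t_lo, t_hi), (c_lo, c_hi), early


# ---------------------------------------------------------------------------
# sensitive alignment (anchor chain + piecewise global refinement)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _chain_kernel(t, c, max_gap, drift, floor):  # pragma: no cover
    n = t.shape[0]
    score = np.ones(n, np.int64)
    parent = np.full(n, -1, np.int64)
    for i in range(n):
        ti, ci = t[i], c[i]
        best_s = 0
        best_j = -1
        for j in range(i - 1, -1, -1):
            dt = ti - t[j]
            if dt > max_gap:
                break  # t is sorted: no closer predecessor remains
            dc = ci - c[j]
            if dt <= 0 or dc <= 0 or dc > max_gap:
                continue
            lim = max(max(dt, dc) * drift, floor)
            if abs(dt - dc) > lim:
                continue
            if score[j] > best_s:
                best_s = score[j]
                best_j = j
        if best_j >= 0:
            score[i] = best_s + 1
            parent[i] = best_j
    return score, parent


def _chain_anchors_tolerant(tpos, cpos, k, max_gap=6000, drift=0.75, floor=64,
                            max_anchors=1200):
    """Best co-linear anchor chain allowing large, bounded-drift gaps (O(n^2))."""
    n = len(tpos)
    if n == 0:
        return np.empty(0, np.int64)
    if n > max_anchors:  # keep the quadratic chainer tractable
        sub = np.sort(np.argsort(tpos, kind="stable")[:: n // max_anchors + 1])
        mapped = _chain_anchors_tolerant(
            tpos[sub], cpos[sub], k, max_gap, drift, floor, max_anchors
        )
        return sub[mapped]
    order = np.lexsort((cpos, tpos))
    t, c = tpos[order], cpos[order]
    score, parent = _chain_kernel(
        t.astype(np.int64), c.astype(np.int64), max_gap, drift, floor
    )
    i = int(np.argmax(score))
    chain = []
    while i != -1:
        chain.append(i)
        i = int(parent[i])
    chain.reverse()
    return order[np.array(chain, np.int64)]


def sensitive_align(
    template: np.ndarray,
    candidate_oriented: np.ndarray,
    k: int = 11,
    min_anchors: int = 3,
    max_difference: float = 0.5,
    block: int = 500,
    stride: int = 1,
    min_spacing: int = 192,
    band_frac: float = 0.55,
    max_anchors: int = 1200,
    a_profile=None,
    b_profile=None,
):
    """Coarse anchor-chain location followed by piecewise global alignment.

    Tolerates local error up to ~0.5 (crosses high-error inserts that stop
    the blockwise aligner).  Returns (ops, t_interval, c_interval) or None.
    Low-error inputs can pass wider ``min_spacing`` and a narrower
    ``band_frac`` for speed.
    """
    tpos, cpos, strand = cand_mod.match_kmer_pairs(
        template, candidate_oriented, k, stride=stride, max_occ=20,
        a_profile=a_profile, b_profile=b_profile,
    )
    fwd = strand == "+"
    tpos, cpos = tpos[fwd], cpos[fwd]
    if len(tpos) == 0:
        return None
    idx = _chain_anchors_tolerant(tpos, cpos, k, max_anchors=max_anchors)
    if len(idx) < min_anchors:
        return None
    ct, cc = tpos[idx], cpos[idx]
    sparse = _align.sparsify_anchors(ct, cc, min_spacing=min_spacing)
    ct, cc = ct[sparse], cc[sparse]
    t_lo, t_hi = int(ct[0]), int(ct[-1]) + k
    c_lo, c_hi = int(cc[0]), int(cc[-1]) + k
    anchors = np.stack([ct - t_lo, cc - c_lo], axis=1)
    ops = _align.align_with_anchors(
        template[t_lo:t_hi], candidate_oriented[c_lo:c_hi], anchors, k,
        band_frac=band_frac,
    )
    # extend the chain-bounded core outward with tolerant blockwise steps
    r_ops, t_hi, c_hi, _ = _extend_right(
        template, candidate_oriented, t_hi, c_hi, block, max_difference,
        block // 3 + 32, block // 3,
    )
    l_ops, lt, lc, _ = _extend_right(
        template[:t_lo][::-1].copy(), candidate_oriented[:c_lo][::-1].copy(),
        0, 0, block, max_difference, block // 3 + 32, block // 3,
    )
    ops = np.concatenate([l_ops[::-1], ops, r_ops])
    t_lo, c_lo = t_lo - lt, c_lo - lc
    if len(ops) == 0 or _align.difference(ops) > max_difference:
        return None
    return ops, (t_lo, t_hi), (c_lo, c_hi)


# ---------------------------------------------------------------------------
# CCA gate
# ---------------------------------------------------------------------------


def cca_gate_and_update(
    cca: CoverageCountArray,
    interval: tuple[int, int],
    alignment: Optional[SupportAlignment] = None,
    threshold: float = 0.5,
) -> bool:
    """Gate an approximate interval; update counts for a passing alignment."""
    proceed = cca.gate(interval)
    if alignment is not None and alignment.difference <= threshold:
        cca.update(alignment.t_interval)
    return proceed


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def consensus(
    template: np.ndarray,
    supports: Sequence[SupportAlignment],
    min_cov: int = 4,
    min_concordance: float = 0.0,
) -> list[tuple[tuple[int, int], str]]:
    """Plurality-vote consensus over support transcripts.

    Per template column, match/mismatch bases and deletion events are
    tallied; insertion strings between columns are tallied against implicit
    no-insertion votes.  Maximal runs with support count >= min_cov are
    emitted as (interval, corrected sequence).  Ties break to the
    lexicographically smaller base; a deletion needs a strict majority.

    With ``min_concordance`` > 0, stretches where the winning vote falls
    below that fraction of the coverage (supports disagree -- the template
    backbone is junk there) are treated as uncorrectable and excluded from
    the emitted runs.
    """
    tlen = len(template)
    if tlen == 0 or not supports:
        return []
    base_counts = np.zeros((tlen, 4), np.int32)
    del_counts = np.zeros(tlen, np.int32)
    cov = np.zeros(tlen + 1, np.int32)
    # single-base insertions are tallied vectorized; longer runs in a dict
    ins1 = np.zeros((tlen + 1, 4), np.int32)
    inserts: dict[int, dict[tuple, int]] = {}

    for sup in supports:
        ops = sup.ops
        if len(ops) == 0:
            continue
        cons_t = (ops == OP_M) | (ops == OP_X) | (ops == OP_D)
        cons_c = (ops == OP_M) | (ops == OP_X) | (ops == OP_I)
        tcol = sup.t_interval[0] + np.cumsum(cons_t) - cons_t
        ccol = np.cumsum(cons_c) - cons_c
        mx = (ops == OP_M) | (ops == OP_X)
        np.add.at(base_counts, (tcol[mx], sup.cseq[ccol[mx]]), 1)
        np.add.at(del_counts, tcol[ops == OP_D], 1)
        cov[sup.t_interval[0]] += 1
        cov[min(sup.t_interval[1], tlen)] -= 1
        ins_mask = ops == OP_I
        if ins_mask.any():
            idx = np.flatnonzero(ins_mask)
            gaps = np.diff(idx)
            run_start = np.ones(len(idx), bool)
            run_start[1:] = gaps > 1
            run_end = np.ones(len(idx), bool)
            run_end[:-1] = gaps > 1
            single = run_start & run_end
            np.add.at(ins1, (tcol[idx[single]], sup.cseq[ccol[idx[single]]]), 1)
            multi_starts = np.flatnonzero(run_start & ~run_end)
            if len(multi_starts):
                multi_ends = np.flatnonzero(run_end & ~run_start)
                for ms, me in zip(multi_starts, multi_ends):
                    run = idx[ms : me + 1]
                    g = int(tcol[run[0]])  # insertion sits before base g
                    s = tuple(int(x) for x in sup.cseq[ccol[run]])
                    inserts.setdefault(g, {})
                    inserts[g][s] = inserts[g].get(s, 0) + 1

    coverage = np.cumsum(cov[:-1])
    eligible = coverage >= min_cov
    if min_concordance > 0.0 and tlen:
        # regions where supports cannot agree on a winner (anchorless junk
        # lets each DP drift differently) are uncorrectable
        winner = np.maximum(base_counts.max(axis=1), del_counts)
        conc = winner / np.maximum(coverage, 1)
        w = min(129, tlen)
        kern = np.ones(w)
        smooth = np.convolve(conc, kern, "same") / np.convolve(
            np.ones(tlen), kern, "same"
        )
        eligible &= smooth >= min_concordance
    # vectorized per-position vote: winning base, or template base when no
    # votes; a deletion needs a strict majority over the best base
    best_base = np.argmax(base_counts, axis=1)  # smallest base wins ties
    best_n = base_counts[np.arange(tlen), best_base]
    emit = np.where(best_n > 0, best_base, template).astype(np.uint8)
    deleted = del_counts > best_n

    # insertion winners, vectorized for the single-base common case: the
    # best vote must beat the implicit no-insertion votes of the coverage
    ins1_total = ins1.sum(axis=1)
    multi_total = np.zeros(tlen + 1, np.int64)
    for g, votes in inserts.items():
        multi_total[g] = sum(votes.values())
    best1 = ins1.max(axis=1)
    best1_base = ins1.argmax(axis=1)
    cov_at = np.empty(tlen + 1, np.int64)
    cov_at[:tlen] = coverage
    cov_at[tlen] = coverage[tlen - 1] if tlen else 0
    no_ins = cov_at - (ins1_total + multi_total)
    single_wins = best1 > no_ins
    voted_gaps = set(np.flatnonzero(single_wins).tolist()) | set(inserts)

    def winning_insert(g: int):
        votes = [(int(best1[g]), (int(best1_base[g]),))] if best1[g] else []
        votes += [(c, s) for s, c in inserts.get(g, {}).items()]
        if not votes:
            return None
        cnt, s = max(votes)
        return np.array(s, np.uint8) if cnt > no_ins[g] else None

    out: list[tuple[tuple[int, int], str]] = []
    pos = 0
    while pos < tlen:
        if not eligible[pos]:
            pos += 1
            continue
        end = pos
        while end < tlen and eligible[end]:
            end += 1
        run_gaps = sorted(g for g in voted_gaps if pos < g < end)
        parts = []
        prev = pos
        for g in run_gaps:
            ins = winning_insert(g)
            if ins is None:
                continue
            parts.append(emit[prev:g][~deleted[prev:g]])
            parts.append(ins)
            prev = g
        parts.append(emit[prev:end][~deleted[prev:end]])
        piece = parts[0] if len(parts) == 1 else np.concatenate(parts)
        out.append(((pos, end), _align.decode(piece)))
        pos = end
    return out


# ---------------------------------------------------------------------------
# per-template driver
# ---------------------------------------------------------------------------


def _orient_candidate(read: RawRead, codes: np.ndarray, hit: CandidateHit, k: int):
    """Candidate codes oriented to the template strand plus the seed position."""
    if hit.strand == "-":
        return _align.revcomp_codes(codes), read.length - (hit.seed.cpos + k)
    return codes, hit.seed.cpos


def _to_forward(interval: tuple[int, int], length: int, strand: str):
    if strand == "+":
        return interval
    return length - interval[1], length - interval[0]


def align_candidate(
    template: RawRead,
    tcodes: np.ndarray,
    candidate: RawRead,
    ccodes: np.ndarray,
    hit: CandidateHit,
    config: PipelineConfig,
    sensitive: bool = False,
) -> Optional[SupportAlignment]:
    """Blockwise alignment from the hit's seed; sensitive realignment when
    the blockwise pass terminates early (pass 2 only)."""
    cori, seed_c = _orient_candidate(candidate, ccodes, hit, config.kmer_size)
    res = blockwise_align(
        tcodes, cori, hit.seed.tpos, seed_c, block=config.block_size,
        max_block_error=config.global_error_threshold,
    )
    aln = None
    if res is not None:
        ops, t_iv, c_iv, early = res
        aln = SupportAlignment(
            candidate.id, hit.strand, t_iv,
            _to_forward(c_iv, candidate.length, hit.strand),
            _align.difference(ops), ops, cori[c_iv[0] : c_iv[1]], early,
        )
    if sensitive and (aln is None or aln.terminated_early):
        res2 = sensitive_align(tcodes, cori, max_difference=config.global_error_threshold)
        if res2 is not None:
            ops, t_iv, c_iv = res2
            if aln is None or len(ops) > aln.columns:
                aln = SupportAlignment(
                    candidate.id, hit.strand, t_iv,
                    _to_forward(c_iv, candidate.length, hit.strand),
                    _align.difference(ops), ops, cori[c_iv[0] : c_iv[1]], False,
                )
    return aln


def estimate_threshold(
    template: RawRead,
    hits: Sequence[CandidateHit],
    aligner: Callable[[CandidateHit], Optional[SupportAlignment]],
    config: PipelineConfig,
    cca: Optional[CoverageCountArray] = None,
    candidate_lengths: Optional[dict[str, int]] = None,
):
    """Align the top hits, record >60%-span alignments, derive the threshold.

    An alignment is recorded when it covers more than ``min_span_fraction``
    of the template or of the candidate read.  Returns (ThresholdEstimate,
    aligned pairs).  The CCA, when given, gates candidates and accumulates
    passing alignments (against the global threshold, since the individual
    one is not yet known at this stage).
    """
    aligned: list[tuple[CandidateHit, SupportAlignment]] = []
    d_list: list[float] = []
    for hit in hits[: config.top_candidates_for_threshold]:
        if cca is not None and not cca.gate(hit.approx_t_interval):
            continue
        aln = aligner(hit)
        if aln is None:
            continue
        aligned.append((hit, aln))
        t_frac = (aln.t_interval[1] - aln.t_interval[0]) / template.length
        c_frac = 0.0
        if candidate_lengths and hit.candidate_id in candidate_lengths:
            c_frac = (aln.c_interval[1] - aln.c_interval[0]) / candidate_lengths[
                hit.candidate_id
            ]
        if max(t_frac, c_frac) > config.min_span_fraction:
            d_list.append(aln.difference)
        if cca is not None and aln.difference <= config.global_error_threshold:
            cca.update(aln.t_interval)
    est = threshold_from_differences(
        d_list,
        config.global_error_threshold,
        config.threshold_sigma,
        config.threshold_mode,
        config.normalize_deviation,
    )
    if est.n == 0:
        logger.debug(
            "template %s: no alignment passed the span rule; global fallback",
            template.id,
        )
    return est, aligned


def correct_template(
    template: RawRead,
    index: KmerIndex,
    config: PipelineConfig,
    pass_num: int = 1,
) -> tuple[list[tuple[tuple[int, int], str]], ThresholdEstimate, int]:
    """Full per-template support collection + consensus.

    Returns (corrected pieces, threshold estimate, supports used).
    """
    tcodes = _align.encode(template.sequence)
    hits = cand_mod.find_candidates(
        template, index, config.ddf_epsilon, config.min_chain_anchors
    )
    hits = cand_mod.top_candidates(hits, config.max_aligned_candidates)
    cca = CoverageCountArray(template.length, config.cca_threshold)
    sensitive = pass_num == 2
    cand_lookup = {r.id: i for i, r in enumerate(index.reads)}
    cand_lengths = {r.id: r.length for r in index.reads}

    def aligner(hit: CandidateHit) -> Optional[SupportAlignment]:
        ci = cand_lookup[hit.candidate_id]
        return align_candidate(
            template, tcodes, index.reads[ci], index.codes[ci], hit, config,
            sensitive=sensitive,
        )

    est, aligned = estimate_threshold(
        template, hits, aligner, config, cca, cand_lengths
    )
    supports, uncorrectable = filter_supports(
        aligned, est, config.global_error_threshold, config.consensus_min_coverage
    )
    eff = min(config.global_error_threshold, est.d)
    for hit in hits[config.top_candidates_for_threshold :]:
        if not cca.gate(hit.approx_t_interval):
            continue
        aln = aligner(hit)
        if aln is None or aln.difference > eff:
            continue
        supports.append((hit, aln))
        cca.update(aln.t_interval)
    if len(supports) < config.consensus_min_coverage:
        return [], est, len(supports)
    pieces = consensus(
        tcodes, [a for _, a in supports], config.consensus_min_coverage,
        config.consensus_min_concordance if pass_num == 2 else 0.0,
    )
    return pieces, est, len(supports)


def correct_pass1(
    template: RawRead, index: KmerIndex, config: PipelineConfig
) -> CorrectedRead:
    """Correct covered intervals, emit the full-length template."""
    pieces, est, n_sup = correct_template(template, index, config, pass_num=1)
    mask = np.zeros(template.length, bool)
    if not pieces:
        return CorrectedRead(
            template.id, template.sequence, template.id, 1,
            (0, template.length), mask,
        )
    out = []
    pos = 0
    for (s, e), seq in pieces:
        out.append(template.sequence[pos:s])
        out.append(seq)
        mask[s:e] = True
        pos = e
    out.append(template.sequence[pos:])
    return CorrectedRead(
        template.id, "".join(out), template.id, 1, (0, template.length), mask
    )


def correct_pass2(
    template: RawRead,
    index: KmerIndex,
    config: PipelineConfig,
    min_fragment: Optional[int] = None,
) -> list[CorrectedRead]:
    """Correct with the sensitive aligner; emit corrected fragments only."""
    if min_fragment is None:
        min_fragment = config.min_read_length
    pieces, est, n_sup = correct_template(template, index, config, pass_num=2)
    frags = []
    for (s, e), seq in (p for p in pieces if len(p[1]) >= min_fragment):
        frags.append(
            CorrectedRead(
                f"{template.id}/2/{s}_{e}", seq, template.id, 2, (s, e),
                np.ones(len(seq), bool),
            )
        )
    return frags


def correct_read_set(
    reads: Sequence[RawRead],
    config: PipelineConfig,
    pass_num: int,
    index_reads: Optional[Sequence[RawRead]] = None,
):
    """Correct every read against an index of the set itself.

    Returns (corrected reads, per-template stat rows).
    """
    index_reads = reads if index_reads is None else index_reads
    index = cand_mod.index_kmers(
        index_reads, config.kmer_size, config.kmer_stride, config.kmer_max_occ
    )
    out: list[CorrectedRead] = []
    stats = []
    for template in reads:
        if pass_num == 1:
            cr = correct_pass1(template, index, config)
            out.append(cr)
            stats.append((template.id, 1, 1))
        else:
            frags = correct_pass2(template, index, config)
            out.extend(frags)
            stats.append((template.id, 2, len(frags)))
    return out, stats
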