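"""Coverage-based trimming of corrected reads and overlap scheduling.

The longest reads totalling ~40x the genome size are selected; pairwise
overlaps with identity above 0.90 define per-read covered intervals.  Fully
covered reads are "complete", others are trimmed to their longest covered
subsequence.  The second alignment round only pairs complete x trimmed and
trimmed x trimmed reads; complete x complete overlaps from the first round
are reused for assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from . import _align, candidates as cand_mod, correction
from .assembly import OverlapRecord
from .io_core import PipelineConfig, RawRead

logger = logging.getLogger("lorcas")


@dataclass
class CoverageInterval:
    read_id: str
    intervals: list[tuple[int, int]]  # sorted, disjoint

    def covers_fully(self, length: int) -> bool:
        return len(self.intervals) == 1 and self.intervals[0] == (0, length)


@dataclass
class TrimmedRead:
    id: str
    sequence: str
    kind: str  # "complete" | "trimmed"
    source_interval: tuple[int, int]

    @property
    def length(self) -> int:
        return len(self.sequence)

    def as_raw(self) -> RawRead:
        return RawRead(self.id, self.sequence)


def select_longest_40x(
    reads: Sequence[RawRead], genome_size: int, target: int = 40
) -> list[RawRead]:
    """Smallest length-descending prefix reaching target x genome_size bases."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    ordered = sorted(reads, key=lambda r: (-r.length, r.id))
    budget = target * genome_size
    total = 0
    selected: list[RawRead] = []
    for r in ordered:
        if total >= budget:
            break
        selected.append(r)
        total += r.length
    if total < budget:
        logger.warning(
            "select_longest_40x: only %.1fx available (target %dx)",
            total / genome_size, target,
        )
    return selected


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def coverage_from_overlaps(
    read: RawRead,
    overlaps: Sequence[OverlapRecord],
    min_identity: float = 0.90,
) -> CoverageInterval:
    """Union of this read's intervals over overlaps with identity > cutoff."""
    ivs = [
        ov.interval_of(read.id)
        for ov in overlaps
        if read.id in (ov.a_id, ov.b_id) and ov.identity > min_identity
    ]
    return CoverageInterval(read.id, _merge_intervals(ivs))


def classify_and_trim(
    read: RawRead, cov: CoverageInterval
) -> Optional[TrimmedRead]:
    """Complete when fully covered; else the longest (leftmost) covered
    interval; None when nothing is covered."""
    if not cov.intervals:
        logger.info("trim: read %s has no covered bases, dropped", read.id)
        return None
    if cov.covers_fully(read.length):
        return TrimmedRead(read.id, read.sequence, "complete", (0, read.length))
    best = max(cov.intervals, key=lambda iv: (iv[1] - iv[0], -iv[0]))
    return TrimmedRead(
        read.id, read.sequence[best[0] : best[1]], "trimmed", best
    )


def second_round_pairs(
    completes: Sequence[TrimmedRead], trimmeds: Sequence[TrimmedRead]
) -> list[tuple[str, str]]:
    """(complete x trimmed) + (trimmed x trimmed) pairs, no complete pairs."""
    pairs: list[tuple[str, str]] = []
    for t in trimmeds:
        for c in completes:
            pairs.append(tuple(sorted((c.id, t.id))))
    for i, t1 in enumerate(trimmeds):
        for t2 in trimmeds[i + 1 :]:
            pairs.append(tuple(sorted((t1.id, t2.id))))
    return pairs


# ---------------------------------------------------------------------------
# pairwise overlap alignment (candidates + sensitive aligner)
# ---------------------------------------------------------------------------


def pairwise_overlaps(
    reads: Sequence[RawRead],
    config: PipelineConfig,
    restrict_pairs: Optional[set[tuple[str, str]]] = None,
) -> list[OverlapRecord]:
    """All-vs-all (or schedule-restricted) overlaps via seed hits plus the
    sensitive aligner; identity comes from the alignment transcript."""
    index = cand_mod.index_kmers(
        reads, config.kmer_size, config.kmer_stride, config.kmer_max_occ
    )
    lengths = {r.id: r.length for r in reads}
    done: set[tuple[str, str]] = set()
    out: list[OverlapRecord] = []
    k = config.kmer_size
    b_profiles: dict[tuple[str, str], tuple] = {}
    oriented: dict[tuple[str, str], object] = {}
    for template in reads:
        tcodes = index.codes[index.read_index(template.id)]
        a_profile = cand_mod.query_profile(tcodes, k, stride=4)
        hits = cand_mod.find_candidates(
            template, index, config.ddf_epsilon, config.min_chain_anchors
        )
        # budget split between overall-best hits (containment detection) and
        # hits touching the template ends (the dovetails the graph needs)
        half = max(1, config.max_overlaps_per_read // 2)
        best = cand_mod.top_candidates(hits, half)
        end_margin = 1000
        enders = cand_mod.top_candidates(
            [
                h for h in hits
                if h.approx_t_interval[0] < end_margin
                or template.length - h.approx_t_interval[1] < end_margin
            ],
            half,
        )
        seen_ids = set()
        hits = [
            h for h in best + enders
            if not (h.candidate_id in seen_ids or seen_ids.add(h.candidate_id))
        ]
        for hit in hits:
            key = tuple(sorted((template.id, hit.candidate_id)))
            if key in done:
                continue
            if restrict_pairs is not None and key not in restrict_pairs:
                continue
            done.add(key)
            ci = index.read_index(hit.candidate_id)
            ckey = (hit.candidate_id, hit.strand)
            if ckey not in b_profiles:
                cori, _ = correction._orient_candidate(
                    index.reads[ci], index.codes[ci], hit, k
                )
                oriented[ckey] = cori
                b_profiles[ckey] = cand_mod.target_profile(cori, k)
            cori = oriented[ckey]
            # corrected reads are low-error: sparse anchors, narrow bands
            res = correction.sensitive_align(
                tcodes, cori, k=k,
                max_difference=1.0 - config.trim_identity + 0.2,
                min_spacing=512, band_frac=0.05, max_anchors=400,
                a_profile=a_profile, b_profile=b_profiles[ckey],
            )
            if res is None:
                continue
            ops, t_iv, c_iv = res
            if t_iv[1] - t_iv[0] < config.min_overlap_length:
                continue
            c_fwd = correction._to_forward(c_iv, lengths[hit.candidate_id], hit.strand)
            out.append(
                OverlapRecord(
                    a_id=template.id,
                    b_id=hit.candidate_id,
                    strand=hit.strand,
                    a_interval=t_iv,
                    b_interval=c_fwd,
                    a_len=template.length,
                    b_len=lengths[hit.candidate_id],
                    identity=_align.identity(ops),
                    length=len(ops),
                )
            )
    return out


def trim_stage(
    corrected: Sequence[RawRead], genome_size: int, config: PipelineConfig
) -> tuple[list[TrimmedRead], list[OverlapRecord]]:
    """Select, overlap, classify, re-overlap; returns (trimmed reads,
    overlaps to feed the assembler)."""
    selected = select_longest_40x(corrected, genome_size, config.trim_coverage_target)
    first_round = pairwise_overlaps(selected, config)
    results: list[TrimmedRead] = []
    for read in selected:
        cov = coverage_from_overlaps(read, first_round, config.trim_identity)
        tr = classify_and_trim(read, cov)
        if tr is not None:
            results.append(tr)
    completes = [t for t in results if t.kind == "complete"]
    trimmeds = [t for t in results if t.kind == "trimmed"]
    n_trim = len(trimmeds)
    logger.info(
        "trim: %d complete, %d trimmed (%.1f%%)",
        len(completes), n_trim, 100.0 * n_trim / max(1, len(results)),
    )
    # first-round complete x complete overlaps are reused as-is
    complete_ids = {t.id for t in completes}
    kept = [
        ov for ov in first_round
        if ov.a_id in complete_ids and ov.b_id in complete_ids
    ]
    if trimmeds:
        schedule = set(second_round_pairs(completes, trimmeds))
        second = pairwise_overlaps(
            [t.as_raw() for t in results], config, restrict_pairs=schedule
        )
        kept.extend(second)
    return results, kept
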