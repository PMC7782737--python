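"""Correction: thresholds, CCA gating, blockwise alignment, consensus."""

import numpy as np
import pytest

from lorcas import _align, candidates as cand, correction as corr, simulate as sim
from lorcas._align import OP_D, OP_I, OP_M, OP_X
from lorcas.correction import (
    CoverageCountArray,
    SupportAlignment,
    blockwise_align,
    cca_gate_and_update,
    consensus,
    filter_supports,
    sensitive_align,
    threshold_from_differences,
)
from lorcas.io_core import PipelineConfig, RawRead

from conftest import random_pair
from test_align import levenshtein


class TestThreshold:
    def test_zero_variance(self):
        est = threshold_from_differences([0.10] * 50, mode="literal")
        assert est.n == 50
        assert est.d0 == pytest.approx(0.10)
        assert est.D == pytest.approx(0.0)
        assert est.d == pytest.approx(0.10)

    def test_two_level_arithmetic_literal(self):
        # d0 = 0.15, D = sqrt(sum((d-d0)^2)/n) = 0.01, d = 0.15 - 5*0.01
        est = threshold_from_differences(
            [0.14] * 25 + [0.16] * 25, mode="literal"
        )
        assert est.d0 == pytest.approx(0.15)
        assert est.D == pytest.approx(0.01)
        assert est.d == pytest.approx(0.10)

    def test_two_level_arithmetic_quality(self):
        est = threshold_from_differences([0.14] * 25 + [0.16] * 25, mode="quality")
        assert est.d == pytest.approx(0.20)

    def test_unnormalized_deviation(self):
        est = threshold_from_differences(
            [0.14] * 25 + [0.16] * 25, mode="literal", normalize=False
        )
        assert est.D == pytest.approx(0.01 * np.sqrt(50))

    def test_empty_falls_back_to_global(self):
        est = threshold_from_differences([], global_threshold=0.5)
        assert est.n == 0 and est.d == 0.5

    def test_clamped_to_global(self):
        est = threshold_from_differences([0.4, 0.6], global_threshold=0.5,
                                         mode="quality")
        assert est.d == 0.5

    def test_literal_clamped_at_zero(self):
        est = threshold_from_differences([0.1, 0.5], mode="literal")
        assert est.d == 0.0


class TestFilterSupports:
    def _aln(self, diff, cid="c"):
        return SupportAlignment(cid, "+", (0, 100), (0, 100), diff,
                                np.empty(0, np.uint8))

    def test_threshold_rule(self):
        est = threshold_from_differences([0.12], mode="literal")  # d = 0.12
        aligned = [(None, self._aln(d)) for d in (0.08, 0.3, 0.55)]
        kept, _ = filter_supports(aligned, est, 0.5, min_coverage=1)
        assert [a.difference for _, a in kept] == [0.08]

    def test_global_binds_on_fallback(self):
        est = threshold_from_differences([], global_threshold=0.5)
        aligned = [(None, self._aln(d)) for d in (0.45, 0.52)]
        kept, _ = filter_supports(aligned, est, 0.5, min_coverage=1)
        assert [a.difference for _, a in kept] == [0.45]

    def test_matches_predicate_oracle(self):
        rng = np.random.default_rng(2)
        diffs = rng.random(100) * 0.6
        est = threshold_from_differences([0.1, 0.2, 0.3], mode="quality")
        aligned = [(None, self._aln(float(d))) for d in diffs]
        kept, _ = filter_supports(aligned, est, 0.5, min_coverage=1)
        eff = min(0.5, est.d)
        oracle = [float(d) for d in diffs if d <= eff]
        assert [a.difference for _, a in kept] == oracle

    def test_uncorrectable_flag(self):
        est = threshold_from_differences([0.1])
        kept, unc = filter_supports(
            [(None, self._aln(0.05))], est, 0.5, min_coverage=4
        )
        assert unc and len(kept) == 1


class TestCca:
    def test_gate_closed_when_all_above(self):
        cca = CoverageCountArray(100, C=12)
        cca.counts[:] = 13
        assert cca.gate((0, 100)) is False

    def test_strict_inequality(self):
        cca = CoverageCountArray(100, C=12)
        cca.counts[:] = 13
        cca.counts[50] = 12  # not > 12
        assert cca.gate((0, 100)) is True

    def test_replay_bounds_alignments(self):
        # 30 full-span passing alignments: the gate closes once counts
        # exceed C everywhere, so at most C+1 are executed
        cca = CoverageCountArray(1000, C=12)
        executed = 0
        for _ in range(30):
            aln = SupportAlignment("c", "+", (0, 1000), (0, 1000), 0.1,
                                   np.empty(0, np.uint8))
            if cca_gate_and_update(cca, (0, 1000), aln, threshold=0.5):
                executed += 1
        assert executed <= 13

    def test_update_only_on_passing(self):
        cca = CoverageCountArray(100, C=12)
        bad = SupportAlignment("c", "+", (0, 100), (0, 100), 0.9,
                               np.empty(0, np.uint8))
        cca_gate_and_update(cca, (0, 100), bad, threshold=0.5)
        assert cca.counts.max() == 0

    def test_monotone_counts(self):
        cca = CoverageCountArray(50, C=3)
        prev = cca.counts.copy()
        for s, e in ((0, 30), (10, 50), (5, 45)):
            cca.update((s, e))
            assert (cca.counts >= prev).all()
            prev = cca.counts.copy()


class TestBlockwiseAlign:
    def test_identical_full_span(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, 2000).astype(np.uint8)
        res = blockwise_align(a, a.copy(), 1000, 1000)
        ops, t_iv, c_iv, early = res
        assert _align.difference(ops) == 0.0
        assert t_iv == (0, 2000) and c_iv == (0, 2000)
        assert not early

    def test_stops_at_junk_block(self):
        # equal-length random corruption aligns to ~0.47 error -- just under
        # the 0.5 cutoff -- so the stop is exercised with length-inflated
        # junk, the same model the simulator uses for HERS
        rng = np.random.default_rng(1)
        a = rng.integers(0, 4, 3000).astype(np.uint8)
        junk = sim._hers_rewrite(a[2000:2600], 0.6, rng)
        a_bad = np.concatenate([a[:2000], junk, a[2600:]])
        res = blockwise_align(a_bad, a.copy(), 500, 500, block=500)
        ops, t_iv, c_iv, early = res
        assert early
        assert t_iv[1] <= 2500  # extension stops at the junk block
        # oracle: the stopping block pair really is >50% error
        edits, _ = _align.global_align(a_bad[2000:2500], a[2000:2500], band=250)
        assert edits / 500 > 0.5

    def test_agrees_with_global_oracle_on_5pct_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = random_pair(rng, 800, 0.05)
            res = blockwise_align(a, b, 400, 400)
            ops, t_iv, c_iv, early = res
            oracle = levenshtein(list(a), list(b))
            blockwise_rate = _align.difference(ops)
            oracle_rate = oracle / max(len(ops), 1)
            assert abs(blockwise_rate - oracle_rate) <= 0.02

    def test_seed_at_read_end(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 4, 1000).astype(np.uint8)
        res = blockwise_align(a, a.copy(), 0, 0)
        ops, t_iv, _, _ = res
        assert t_iv == (0, 1000)


class TestSensitiveAlign:
    def test_crosses_high_error_insert(self):
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 4, 6000).astype(np.uint8)
        template = truth.copy()
        # 600 bp of 60%-corrupted (length-inflated) sequence mid-template
        piece = sim._hers_rewrite(truth[2700:3300], 0.75, rng)
        template = np.concatenate([truth[:2700], piece, truth[3300:]])
        candidate = truth.copy()  # clean support
        bw = blockwise_align(template, candidate, 500, 500)
        assert bw is None or bw[3]  # blockwise terminates early
        res = sensitive_align(template, candidate)
        assert res is not None
        ops, t_iv, c_iv = res
        assert t_iv[0] < 2000 and t_iv[1] > len(template) - 2000  # spans across

    def test_clean_pair_agrees_with_blockwise(self):
        rng = np.random.default_rng(6)
        a, b = random_pair(rng, 4000, 0.05)
        bw = blockwise_align(a, b, 2000, 2000)
        sv = sensitive_align(a, b)
        assert bw is not None and sv is not None
        assert abs(sv[1][0] - bw[1][0]) <= 500
        assert abs(sv[1][1] - bw[1][1]) <= 500

    def test_unrelated_reads_none(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 4, 3000).astype(np.uint8)
        b = rng.integers(0, 4, 3000).astype(np.uint8)
        assert sensitive_align(a, b) is None


def _support_from_pair(template, cand_codes, t_start=0):
    band = _align.default_band(len(template), len(cand_codes), 0.5)
    _, ops = _align.global_align(template, cand_codes, band)
    return SupportAlignment(
        "c", "+", (t_start, t_start + len(template)), (0, len(cand_codes)),
        _align.difference(ops), ops, cand_codes,
    )


class TestConsensus:
    def test_majority_recovers_truth(self):
        rng = np.random.default_rng(8)
        truth = rng.integers(0, 4, 1500).astype(np.uint8)
        model = sim.ErrorModel()
        template, _, _ = sim._corrupt(truth, 0.15, model, rng)
        supports = [
            _support_from_pair(template, truth.copy()) for _ in range(12)
        ]
        pieces = consensus(template, supports, min_cov=4)
        assert len(pieces) == 1
        (iv, seq) = pieces[0]
        assert seq == _align.decode(truth)

    def test_below_min_cov_empty(self):
        rng = np.random.default_rng(9)
        truth = rng.integers(0, 4, 500).astype(np.uint8)
        supports = [_support_from_pair(truth, truth.copy()) for _ in range(2)]
        assert consensus(truth, supports, min_cov=4) == []

    def test_tie_breaks_to_smaller_base(self):
        # template all A; 6 supports vote C at one column, 6 vote G
        template = np.zeros(200, np.uint8)
        sup = []
        for base in (1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2):
            c = template.copy()
            c[100] = base
            sup.append(_support_from_pair(template, c))
        pieces = consensus(template, sup, min_cov=4)
        (iv, seq) = pieces[0]
        assert seq[100] == "C"  # C < G lexicographically

    def test_noisy_supports_still_converge(self):
        rng = np.random.default_rng(10)
        truth = rng.integers(0, 4, 2000).astype(np.uint8)
        model = sim.ErrorModel()
        template, _, _ = sim._corrupt(truth, 0.15, model, rng)
        supports = []
        for i in range(14):
            noisy, _, _ = sim._corrupt(truth, 0.12, model,
                                       np.random.default_rng(100 + i))
            supports.append(_support_from_pair(template, noisy))
        pieces = consensus(template, supports, min_cov=4)
        out = _align.encode(pieces[0][1])
        edits, _ = _align.global_align(out, truth,
                                       _align.default_band(len(out), len(truth)))
        assert edits / len(truth) < 0.02


@pytest.fixture(scope="module")
def corrected(noisy_readset):
    reads, truths, model = noisy_readset
    cfg = PipelineConfig()
    sub = reads[:60]
    index = cand.index_kmers(sub, cfg.kmer_size, cfg.kmer_stride,
                             cfg.kmer_max_occ)
    out = [corr.correct_pass1(r, index, cfg) for r in sub[:15]]
    return sub, truths, out


class TestCorrectionEndToEnd:
    def test_pass1_reduces_error(self, corrected, small_genome):
        from lorcas import metrics as met

        reads, truths, out = corrected
        tr = {t.read_id: t for t in truths}
        raw_rates, cor_rates = [], []
        for r, c in zip(reads[:15], out):
            ref = met.truth_interval_codes(small_genome, tr[r.id])
            raw_rates.append(met.read_error_rate(r, ref))
            cor_rates.append(met.read_error_rate(c.as_raw(), ref))
        assert np.mean(cor_rates) < 0.5 * np.mean(raw_rates)

    def test_pass1_full_length_output(self, corrected):
        reads, _, out = corrected
        for r, c in zip(reads[:15], out):
            assert abs(c.length - r.length) <= 0.1 * r.length
            assert c.template_interval == (0, r.length)
            assert len(c.corrected_mask) == r.length

    def test_zero_support_passthrough(self, config):
        rng = np.random.default_rng(11)
        lone = RawRead("lone", _align.decode(rng.integers(0, 4, 3000).astype(np.uint8)))
        other = RawRead("other", _align.decode(rng.integers(0, 4, 3000).astype(np.uint8)))
        index = cand.index_kmers([lone, other], 13, 5)
        out = corr.correct_pass1(lone, index, config)
        assert out.sequence == lone.sequence
        assert not out.corrected_mask.any()

    def test_pass2_clean_read_single_fragment(self, clean_readset, config):
        reads, _ = clean_readset
        index = cand.index_kmers(reads, 13, 5)
        frags = corr.correct_pass2(reads[0], index, config)
        assert len(frags) == 1
        assert frags[0].pass_num == 2


def test_pass2_interior_zero_coverage_splits(config):
    """A template whose interior has no support coverage yields >= 2 pieces."""
    rng = np.random.default_rng(12)
    truth = rng.integers(0, 4, 9000).astype(np.uint8)
    template = truth.copy()
    supports = []
    # supports cover [0, 4000) and [5000, 9000) only
    for i in range(6):
        supports.append(_support_from_pair(template[:4000], truth[:4000].copy(), 0))
        supports.append(
            _support_from_pair(template[5000:], truth[5000:].copy(), 5000)
        )
    pieces = consensus(template, supports, min_cov=4)
    assert len(pieces) == 2
    assert pieces[0][0] == (0, 4000)
    assert pieces[1][0] == (5000, 9000)
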