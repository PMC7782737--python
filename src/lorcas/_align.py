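"""Banded edit-distance alignment primitives.

All aligners work on 2-bit encoded sequences (uint8 arrays, A=0 C=1 G=2 T=3)
and produce edit transcripts as uint8 op arrays:

    OP_M = 0   match      (consumes one base of each sequence)
    OP_X = 1   mismatch   (consumes one base of each sequence)
    OP_I = 2   insertion  (consumes one base of the second sequence only)
    OP_D = 3   deletion   (consumes one base of the first sequence only)

"First" is the template/reference side throughout; "second" is the
candidate/query side.  Edit distance = #X + #I + #D, alignment columns =
len(ops).  The kernels are numba-compiled; pure-numpy fallbacks are not
provided because numba is a hard dependency.
"""

from __future__ import annotations

import numpy as np
from numba import njit

OP_M, OP_X, OP_I, OP_D = 0, 1, 2, 3

_BASES = "ACGT"
_ENCODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(_BASES.encode(), dtype=np.uint8)

_INF = np.int32(1 << 28)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code array (non-ACGT maps to A)."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.uint8)


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


@njit(cache=True)
def _band_dp(a, b, band):  # pragma: no cover - exercised via wrappers
    """Fill the banded DP matrix. Returns (score, traceback) arrays.

    Cell (i, j) lives at row i, column j - i + band.  Unit costs.
    """
    la = a.shape[0]
    lb = b.shape[0]
    W = 2 * band + 1
    score = np.full((la + 1, W), _INF, np.int32)
    tb = np.zeros((la + 1, W), np.uint8)
    score[0, band] = 0
    for j in range(1, min(band, lb) + 1):
        score[0, j + band] = j
        tb[0, j + band] = OP_I
    for i in range(1, la + 1):
        jlo = i - band
        if jlo < 0:
            jlo = 0
        jhi = i + band
        if jhi > lb:
            jhi = lb
        ai = a[i - 1]
        for j in range(jlo, jhi + 1):
            c = j - i + band
            best = _INF
            op = OP_D
            if c + 1 < W:
                v = score[i - 1, c + 1] + 1  # deletion: consume a only
                if v < best:
                    best = v
                    op = OP_D
            if j > 0:
                if c - 1 >= 0:
                    v = score[i, c - 1] + 1  # insertion: consume b only
                    if v < best:
                        best = v
                        op = OP_I
                sub = 0 if ai == b[j - 1] else 1
                v = score[i - 1, c] + sub
                if v < best:
                    best = v
                    op = OP_M if sub == 0 else OP_X
            score[i, c] = best
            tb[i, c] = op
    return score, tb


@njit(cache=True)
def _traceback(tb, band, i, j):  # pragma: no cover
    n = i + j  # upper bound on path length
    ops = np.empty(n, np.uint8)
    p = n
    while i > 0 or j > 0:
        op = tb[i, j - i + band]
        p -= 1
        ops[p] = op
        if op == OP_I:
            j -= 1
        elif op == OP_D:
            i -= 1
        else:
            i -= 1
            j -= 1
    return ops[p:]


def global_align(a: np.ndarray, b: np.ndarray, band: int | None = None):
    """Banded global (Needleman-Wunsch, unit cost) alignment of a vs b.

    Returns (edits, ops).  ``band`` is widened automatically so the corner
    cell is reachable.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb, np.full(lb, OP_I, np.uint8)
    if lb == 0:
        return la, np.full(la, OP_D, np.uint8)
    if band is None:
        band = default_band(la, lb)
    band = max(band, abs(la - lb) + 1)
    band = min(band, max(la, lb))
    score, tb = _band_dp(a, b, band)
    edits = int(score[la, lb - la + band])
    ops = _traceback(tb, band, la, lb)
    return edits, np.asarray(ops)


def semiglobal_align(a: np.ndarray, b: np.ndarray, band: int):
    """Align all of ``a`` against a prefix of ``b`` (free end on b).

    Returns (edits, b_consumed, ops).
    """
    la, lb = len(a), len(b)
    if la == 0:
        return 0, 0, np.empty(0, np.uint8)
    if lb == 0:
        return la, 0, np.full(la, OP_D, np.uint8)
    band = max(band, abs(la - lb) + 1) if lb < la else max(band, 1)
    band = min(band, max(la, lb))
    score, tb = _band_dp(a, b, band)
    jlo = max(0, la - band)
    jhi = min(lb, la + band)
    row = score[la, jlo - la + band : jhi - la + band + 1]
    best = int(np.argmin(row))
    j = jlo + best
    edits = int(row[best])
    ops = _traceback(tb, band, la, j)
    return edits, j, np.asarray(ops)


def default_band(la: int, lb: int, frac: float = 0.25, floor: int = 32) -> int:
    return abs(la - lb) + max(floor, int(frac * max(la, lb)))


def ops_counts(ops: np.ndarray):
    """Return (matches, mismatches, insertions, deletions)."""
    c = np.bincount(ops, minlength=4)
    return int(c[OP_M]), int(c[OP_X]), int(c[OP_I]), int(c[OP_D])


def difference(ops: np.ndarray) -> float:
    """Edit operations per alignment column."""
    if len(ops) == 0:
        return 0.0
    m, x, i, d = ops_counts(ops)
    return (x + i + d) / (m + x + i + d)


def identity(ops: np.ndarray) -> float:
    return 1.0 - difference(ops)


_SWAP_OPS = np.array([OP_M, OP_X, OP_D, OP_I], np.uint8)  # transpose a<->b


def extend_blockwise(
    a: np.ndarray,
    b: np.ndarray,
    a0: int,
    b0: int,
    block: int = 500,
    max_block_error: float = 0.5,
    band: int = 78,
    slack: int = 78,
):
    """Rightward blockwise extension from (a0, b0) with bounded memory.

    Aligns successive a-blocks semi-globally against b windows; stops at a
    block whose error exceeds ``max_block_error`` or at a sequence end.
    Returns (ops, a_end, b_end, stopped_by_error).
    """
    pieces = []
    ai, bi = a0, b0
    stopped = False
    la, lb = len(a), len(b)
    while ai < la and bi < lb:
        ab = a[ai : ai + block]
        bb = b[bi : bi + block + slack]
        if len(bb) >= len(ab):
            edits, consumed, ops = semiglobal_align(ab, bb, band)
            # error per block base: random junk measures ~0.47 per column
            # under optimal alignment, which would slip under a 0.5 cutoff
            if edits / max(len(ab), 1) > max_block_error:
                stopped = True
                break
            pieces.append(ops)
            ai += len(ab)
            bi += consumed
            if consumed == 0:
                break
        else:
            # b nearly exhausted: consume it fully, free end on a
            rem_b = b[bi:lb]
            ab = a[ai : min(la, ai + len(rem_b) + slack)]
            edits, consumed_a, ops = semiglobal_align(rem_b, ab, band)
            if edits / max(len(rem_b), 1) > max_block_error:
                stopped = True
                break
            pieces.append(_SWAP_OPS[ops])
            ai += consumed_a
            bi = lb
            break
    ops = np.concatenate(pieces) if pieces else np.empty(0, np.uint8)
    return ops, ai, bi, stopped


_MAX_SEGMENT_CELLS = 30_000_000  # DP matrix guard for piecewise segments


def _segment_align(seg_a: np.ndarray, seg_b: np.ndarray, band: int) -> np.ndarray:
    """Banded global alignment with a bounded-memory blockwise fallback."""
    la, lb = len(seg_a), len(seg_b)
    if (la + 1) * (2 * band + 1) <= _MAX_SEGMENT_CELLS:
        _, ops = global_align(seg_a, seg_b, band)
        return ops
    ops, ai, bi, _ = extend_blockwise(
        seg_a, seg_b, 0, 0, block=1000, max_block_error=1.1, band=300, slack=300
    )
    pad = []
    if ai < la:
        pad.append(np.full(la - ai, OP_D, np.uint8))
    if bi < lb:
        pad.append(np.full(lb - bi, OP_I, np.uint8))
    return np.concatenate([ops, *pad]) if pad else ops


def sparsify_anchors(a_pos: np.ndarray, b_pos: np.ndarray, min_spacing: int):
    """Thin a co-linear anchor chain to >= min_spacing in both coordinates.

    The first and last anchors are always kept; fewer, wider segments keep
    the piecewise aligner's per-segment overhead low.
    """
    n = len(a_pos)
    if n <= 2:
        return np.arange(n)
    keep = [0]
    for i in range(1, n - 1):
        j = keep[-1]
        if a_pos[i] - a_pos[j] >= min_spacing and b_pos[i] - b_pos[j] >= min_spacing:
            keep.append(i)
    keep.append(n - 1)
    return np.array(keep, np.int64)


def align_with_anchors(
    a: np.ndarray,
    b: np.ndarray,
    anchors: np.ndarray,
    k: int,
    band_frac: float = 0.4,
    band_floor: int = 32,
) -> np.ndarray:
    """Piecewise banded global alignment of a vs b guided by exact anchors.

    ``anchors`` is an (n, 2) array of (a_pos, b_pos) start positions of
    matching k-mers, strictly increasing in both coordinates.  Segments
    between consecutive anchors (and the two free ends) are aligned with a
    banded global aligner and the transcripts are concatenated.
    """
    if len(anchors) == 0:
        _, ops = global_align(a, b, default_band(len(a), len(b), 0.5))
        return ops
    pieces = []
    pa = pb = 0
    for ai, bi in anchors:
        if ai < pa or bi < pb:  # anchor overlaps the previous one
            continue
        seg_a = a[pa:ai]
        seg_b = b[pb:bi]
        if len(seg_a) or len(seg_b):
            band = abs(len(seg_a) - len(seg_b)) + max(
                band_floor, int(band_frac * max(len(seg_a), len(seg_b)))
            )
            pieces.append(_segment_align(seg_a, seg_b, band))
        pieces.append(np.full(k, OP_M, np.uint8))
        pa, pb = ai + k, bi + k
    seg_a, seg_b = a[pa:], b[pb:]
    if len(seg_a) or len(seg_b):
        band = abs(len(seg_a) - len(seg_b)) + max(
            band_floor, int(band_frac * max(len(seg_a), len(seg_b)))
        )
        pieces.append(_segment_align(seg_a, seg_b, band))
    if not pieces:
        return np.empty(0, np.uint8)
    return np.concatenate(pieces)
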