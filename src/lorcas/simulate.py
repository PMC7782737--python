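"""Synthetic genome and noisy long-read simulation with full ground truth.

Reads are sampled uniformly in position and strand.  Each read draws a
per-read error rate from a Beta distribution rescaled to a configurable
support (default [0.07, 0.50], mode in the 0.10-0.20 range) and realizes it
as substitutions/insertions/deletions.  A fraction of long reads --
increasing with read length -- additionally receives one high-error-rate
subsequence (HERS): a contiguous interval rewritten at a local error rate
above 0.5.

Every read is a pure function of (genome, truth record): the truth record
stores the child RNG entropy, so ``realize_read`` reproduces the emitted
read byte-for-byte (the conservation property used by tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import _align
from .io_core import RawRead

__all__ = [
    "SyntheticGenome",
    "ReadTruth",
    "ErrorModel",
    "make_genome",
    "sample_reads",
    "inject_hers",
    "realize_read",
    "write_truth_tsv",
    "read_truth_tsv",
]


@dataclass(frozen=True)
class SyntheticGenome:
    sequence: str
    # (source interval, inserted interval, identity) for each repeat copy
    repeat_features: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ReadTruth:
    read_id: str
    start: int
    end: int
    strand: str
    planned_error_rate: float
    realized_error_rate: float = 0.0
    # (read-coordinate start, end, local error rate)
    hers_intervals: list = field(default_factory=list)
    # entropy words recreating the per-read RNG (the stored edit plan)
    entropy: tuple = ()

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.read_id}: end <= start")
        if self.strand not in "+-":
            raise ValueError(f"{self.read_id}: bad strand {self.strand!r}")


@dataclass
class ErrorModel:
    """Per-read error-rate distribution plus HERS injection policy."""

    mean_rate: float = 0.15
    rate_lo: float = 0.07
    rate_hi: float = 0.50
    beta_a: float = 2.0
    sub_frac: float = 0.4
    ins_frac: float = 0.3
    del_frac: float = 0.3
    hers_local_rate: float = 0.6
    hers_window: int = 500
    # logistic P(HERS | read length); or a fixed probability above a length
    hers_prob_max: float = 0.25
    hers_midpoint: int = 15000
    hers_scale: float = 4000.0
    hers_fixed_prob: Optional[float] = None
    hers_min_len: int = 10000

    def __post_init__(self):
        if not self.rate_lo <= self.mean_rate <= self.rate_hi:
            raise ValueError("mean_rate outside [rate_lo, rate_hi]")
        if abs(self.sub_frac + self.ins_frac + self.del_frac - 1.0) > 1e-9:
            raise ValueError("error composition must sum to 1")

    @property
    def beta_b(self) -> float:
        if self.rate_hi == self.rate_lo:
            return 1.0
        m = (self.mean_rate - self.rate_lo) / (self.rate_hi - self.rate_lo)
        return self.beta_a * (1.0 - m) / m

    def draw_rate(self, rng: np.random.Generator) -> float:
        for _ in range(100):
            r = self.rate_lo + (self.rate_hi - self.rate_lo) * rng.beta(
                self.beta_a, self.beta_b
            )
            if r <= 0.95:  # degenerate read guard
                return float(r)
        return 0.95

    def hers_probability(self, read_len: int) -> float:
        if self.hers_fixed_prob is not None:
            return self.hers_fixed_prob if read_len > self.hers_min_len else 0.0
        z = (read_len - self.hers_midpoint) / self.hers_scale
        return self.hers_prob_max / (1.0 + math.exp(-z))

    @classmethod
    def noiseless(cls) -> "ErrorModel":
        return cls(mean_rate=0.0, rate_lo=0.0, rate_hi=0.0, hers_prob_max=0.0)


def make_genome(
    length: int,
    repeat_spec: Optional[tuple[int, int, float]] = None,
    seed: int = 0,
) -> SyntheticGenome:
    """Uniform random genome with optional near-identical repeat copies.

    ``repeat_spec`` is (copy count, unit length, identity fraction): one
    source unit is chosen from the background and ``count`` mutated copies
    replace disjoint background intervals.
    """
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, length, dtype=np.uint8)
    features = []
    if repeat_spec is not None:
        count, unit, identity = repeat_spec
        if count < 0 or not 0.0 <= identity <= 1.0:
            raise ValueError("bad repeat_spec")
        if count and length < 10 * unit:
            raise ValueError("genome must be >= 10x repeat unit length")
        if (count + 1) * unit > length:
            raise ValueError("repeat copies exceed genome length")
        src_start = int(rng.integers(0, length - unit + 1))
        src = (src_start, src_start + unit)
        taken = [src]
        for _ in range(count):
            for _attempt in range(1000):
                s = int(rng.integers(0, length - unit + 1))
                if all(s + unit <= a or s >= b for a, b in taken):
                    break
            else:
                raise ValueError("cannot place repeat copies without overlap")
            taken.append((s, s + unit))
            copy = codes[src[0] : src[1]].copy()
            # identity is between copies: each copy diverges half the budget
            n_mut = int(round((1.0 - identity) / 2.0 * unit))
            if n_mut:
                pos = rng.choice(unit, size=n_mut, replace=False)
                copy[pos] = (copy[pos] + rng.integers(1, 4, n_mut)) % 4
            codes[s : s + unit] = copy
            features.append((src, (s, s + unit), identity))
    return SyntheticGenome(_align.decode(codes), features)


def _corrupt(
    codes: np.ndarray, rate: float, model: ErrorModel, rng: np.random.Generator
):
    """Apply iid substitution/insertion/deletion noise at ``rate``.

    Returns (mutated codes, edits, alignment columns).
    """
    n = len(codes)
    if n == 0 or rate <= 0.0:
        return codes.copy(), 0, n
    r = rng.random(n)
    shift = rng.integers(1, 4, n, dtype=np.uint8)  # substituted base offset
    ins_base = rng.integers(0, 4, n, dtype=np.uint8)
    t_sub = rate * model.sub_frac
    t_del = t_sub + rate * model.del_frac
    t_ins = t_del + rate * model.ins_frac
    sub = r < t_sub
    dele = (r >= t_sub) & (r < t_del)
    ins = (r >= t_del) & (r < t_ins)
    emit = np.where(sub, (codes + shift) % 4, codes).astype(np.uint8)
    counts = np.ones(n, dtype=np.int64)
    counts[dele] = 0
    counts[ins] = 2
    total = int(counts.sum())
    out = np.empty(total, dtype=np.uint8)
    starts = np.cumsum(counts) - counts
    one = counts == 1
    out[starts[one]] = emit[one]
    out[starts[ins]] = ins_base[ins]
    out[starts[ins] + 1] = emit[ins]
    edits = int(sub.sum() + dele.sum() + ins.sum())
    columns = n + int(ins.sum())
    return out, edits, columns


def _hers_rewrite(codes: np.ndarray, rate: float, rng: np.random.Generator):
    """Garbage-duplication corruption for high-error subsequences.

    Each base is, with probability ``rate``, replaced by three random bases
    -- the length-inflated junk that stalled pores produce.  Balanced
    equal-length corruption cannot exceed the 0.5 HERS cutoff under optimal
    realignment (random sequence pairs measure ~0.49); the inserted surplus
    is what pushes windowed error decisively past it.
    """
    n = len(codes)
    garb = rng.random(n) < rate
    junk = rng.integers(0, 4, (n, 3), dtype=np.uint8)
    counts = np.where(garb, 3, 1)
    out = np.empty(int(counts.sum()), np.uint8)
    starts = np.cumsum(counts) - counts
    out[starts[~garb]] = codes[~garb]
    for j in range(3):
        out[starts[garb] + j] = junk[garb, j]
    return out


def _pick_hers_interval(read_len: int, window: int, rng: np.random.Generator):
    # long enough that at least one tiled window lies fully inside
    w = min(read_len, 2 * window + int(rng.integers(0, window // 2 + 1)))
    s = int(rng.integers(0, read_len - w + 1))
    return s, s + w


def _materialize(
    genome_codes: np.ndarray,
    start: int,
    end: int,
    strand: str,
    rate: float,
    with_hers: bool,
    model: ErrorModel,
    rng: np.random.Generator,
):
    codes = genome_codes[start:end]
    if strand == "-":
        codes = _align.revcomp_codes(codes)
    codes, edits, columns = _corrupt(codes, rate, model, rng)
    hers = []
    if with_hers and len(codes) >= 2 * model.hers_window:
        s, e = _pick_hers_interval(len(codes), model.hers_window, rng)
        piece = _hers_rewrite(codes[s:e], model.hers_local_rate, rng)
        codes = np.concatenate([codes[:s], piece, codes[e:]])
        hers.append((s, s + len(piece), model.hers_local_rate))
    realized = edits / columns if columns else 0.0
    return codes, realized, hers


def sample_reads(
    genome: SyntheticGenome,
    coverage: float,
    length_model: tuple[int, int, int],
    error_model: ErrorModel,
    seed: int = 0,
    sigma_log: float = 0.35,
):
    """Sample reads to ~coverage-fold depth. Returns (reads, truths)."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    mean_len, min_len, max_len = length_model
    if not min_len <= mean_len <= max_len:
        raise ValueError("length model must satisfy min <= mean <= max")
    glen = genome.length
    gcodes = _align.encode(genome.sequence)
    target = coverage * glen
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    mu = math.log(mean_len) - 0.5 * sigma_log**2  # E[lognormal] == mean_len
    reads: list[RawRead] = []
    truths: list[ReadTruth] = []
    total = 0
    idx = 0
    while total < target:
        length = int(rng.lognormal(mu, sigma_log))
        length = max(min_len, min(max_len, min(length, glen)))
        # allow reads to run off either end (then clip) so per-base coverage
        # stays flat at the genome boundaries instead of ramping to zero
        pos = int(rng.integers(-length // 2, glen - length + length // 2 + 1))
        start = max(0, pos)
        end = min(glen, pos + length)
        if end - start < max(1000, min_len // 3):
            continue  # too little left after clipping
        length = end - start
        strand = "+" if rng.random() < 0.5 else "-"
        rate = error_model.draw_rate(rng)
        with_hers = rng.random() < error_model.hers_probability(length)
        entropy = (seed, 7919, idx)
        child = np.random.default_rng(np.random.SeedSequence(entropy))
        codes, realized, hers = _materialize(
            gcodes, start, start + length, strand, rate, with_hers, error_model, child
        )
        rid = f"read{idx:05d}"
        reads.append(RawRead(rid, _align.decode(codes)))
        truths.append(
            ReadTruth(
                rid, start, start + length, strand, rate, realized, hers, entropy
            )
        )
        total += len(codes)
        idx += 1
    return reads, truths


def realize_read(
    genome: SyntheticGenome, truth: ReadTruth, error_model: ErrorModel
) -> RawRead:
    """Re-derive a read from its truth record (stored edit plan)."""
    gcodes = _align.encode(genome.sequence)
    child = np.random.default_rng(np.random.SeedSequence(truth.entropy))
    codes, _, _ = _materialize(
        gcodes,
        truth.start,
        truth.end,
        truth.strand,
        truth.planned_error_rate,
        bool(truth.hers_intervals),
        error_model,
        child,
    )
    return RawRead(truth.read_id, _align.decode(codes))


def inject_hers(
    read: RawRead,
    truth: ReadTruth,
    window: int = 500,
    local_rate: float = 0.6,
    seed: int = 0,
    model: Optional[ErrorModel] = None,
):
    """Rewrite one contiguous interval of ``read`` at ``local_rate``.

    Returns (mutated read, updated truth).  Reads shorter than ``window``
    are returned unchanged.
    """
    if local_rate <= 0.5:
        raise ValueError("HERS local rate must exceed 0.5")
    if read.length < window:
        import logging

        logging.getLogger("lorcas").warning(
            "inject_hers: read %s shorter than window, skipped", read.id
        )
        return read, truth
    model = model or ErrorModel()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 104729)))
    codes = _align.encode(read.sequence)
    s, e = _pick_hers_interval(len(codes), window, rng)
    piece = _hers_rewrite(codes[s:e], local_rate, rng)
    out = np.concatenate([codes[:s], piece, codes[e:]])
    new_truth = replace(
        truth,
        hers_intervals=truth.hers_intervals + [(s, s + len(piece), local_rate)],
    )
    return RawRead(read.id, _align.decode(out)), new_truth


# ---------------------------------------------------------------------------
# truth TSV
# ---------------------------------------------------------------------------


def write_truth_tsv(truths: list[ReadTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tstart\tend\tstrand\tplanned_error\trealized_error\t"
            "hers_intervals\tentropy\n"
        )
        for t in truths:
            hers = ";".join(f"{s}-{e}:{r:.3f}" for s, e, r in t.hers_intervals)
            ent = ",".join(str(x) for x in t.entropy)
            fh.write(
                f"{t.read_id}\t{t.start}\t{t.end}\t{t.strand}\t"
                f"{t.planned_error_rate:.6f}\t{t.realized_error_rate:.6f}\t"
                f"{hers}\t{ent}\n"
            )


def read_truth_tsv(path: str | Path) -> list[ReadTruth]:
    truths = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: missing truth TSV header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hers = []
            if f[6]:
                for item in f[6].split(";"):
                    span, rate = item.split(":")
                    s, e = span.split("-")
                    hers.append((int(s), int(e), float(rate)))
            entropy = tuple(int(x) for x in f[7].split(",")) if f[7] else ()
            truths.append(
                ReadTruth(
                    f[0], int(f[1]), int(f[2]), f[3],
                    float(f[4]), float(f[5]), hers, entropy,
                )
            )
    return truths
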