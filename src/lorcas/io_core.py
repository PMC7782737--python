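"""Sequence/record I/O, read preprocessing, and pipeline configuration.

Handles FASTA/FASTQ round-trips (via Biopython), PAF and GFA 1.0 emission,
and the YAML key-value config that every pipeline constant is drawn from.
Coordinates are 0-based half-open everywhere; strands are '+'/'-' with
coordinates always reported on the forward strand of the relevant sequence.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO

logger = logging.getLogger("lorcas")

_VALID_RE = re.compile(r"^[ACGT]+$")
# any IUPAC ambiguity code (incl. N) is deterministically mapped to 'A':
# keeps coordinates stable instead of dropping otherwise well-formed reads
_AMBIG_TABLE = str.maketrans({c: "A" for c in "RYSWKMBDHVNU"})


@dataclass(frozen=True)
class RawRead:
    """A sequence record over {A,C,G,T}."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, overridable via YAML/CLI."""

    # correction
    global_error_threshold: float = 0.5
    top_candidates_for_threshold: int = 50
    max_aligned_candidates: int = 200
    cca_threshold: int = 12
    block_size: int = 500
    consensus_min_coverage: int = 4
    consensus_min_concordance: float = 0.78
    min_span_fraction: float = 0.6
    threshold_sigma: float = 5.0
    # "quality": d = d0 + sigma*D (difference-space upper bound);
    # "literal": d = d0 - sigma*D as printed, degenerate in practice
    threshold_mode: str = "quality"
    normalize_deviation: bool = True
    # candidate finding
    kmer_size: int = 13
    kmer_stride: int = 5
    kmer_max_occ: int = 500
    ddf_epsilon: int = 32
    min_chain_anchors: int = 3
    # metrics / HERS
    hers_window: int = 500
    hers_error_cutoff: float = 0.5
    # trimming
    trim_identity: float = 0.90
    trim_coverage_target: int = 40
    max_overlaps_per_read: int = 60
    # assembly
    min_coverage: int = 2
    max_coverage: int = 200
    max_diff_coverage: int = 150
    overlap_global_identity: float = 0.90
    overlap_global_overhang: int = 500
    overlap_alpha: float = 2.0
    transitive_fuzz: int = 500
    tip_length: int = 3
    bubble_depth: int = 5
    spurious_fraction: float = 0.25
    min_overlap_length: int = 500
    # bridging
    bridge_cluster_window: int = 1000
    bridge_end_window: int = 2000
    bridge_min_hit_length: int = 500
    # preprocessing / misc
    min_read_length: int = 1000
    rng_seed: int = 1
    genome_size: int = 0  # 0 = estimate from read bases / trim target

    def __post_init__(self):
        for name in (
            "global_error_threshold",
            "hers_error_cutoff",
            "trim_identity",
            "min_span_fraction",
            "overlap_global_identity",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "top_candidates_for_threshold",
            "max_aligned_candidates",
            "cca_threshold",
            "block_size",
            "hers_window",
            "trim_coverage_target",
            "bridge_cluster_window",
            "min_read_length",
            "consensus_min_coverage",
            "kmer_size",
            "kmer_stride",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.threshold_mode not in ("quality", "literal"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} is not a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_sequences(path: str | Path, format: str | None = None) -> list[RawRead]:
    """Read FASTA or FASTQ into RawReads (uppercased, order preserved)."""
    path = Path(path)
    if format is None:
        format = _sniff_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    reads: list[RawRead] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), format):
            if rec.id in seen:
                raise ValueError(f"duplicate read id {rec.id!r} in {path}")
            seen.add(rec.id)
            reads.append(RawRead(rec.id, str(rec.seq).upper()))
    except ValueError:
        raise
    except Exception as exc:  # Biopython raises bare exceptions on bad records
        raise ValueError(f"malformed {format} record in {path}: {exc}") from exc
    return reads


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    return "fasta"


def write_fasta(reads: Iterable[RawRead], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


def write_fastq(reads: Iterable[RawRead], path: str | Path, qual: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual * len(r.sequence)}\n")


def preprocess(reads: Sequence[RawRead], min_len: int = 1000) -> list[RawRead]:
    """Drop short reads; map ambiguity codes to 'A' in the survivors."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept: list[RawRead] = []
    removed = 0
    for r in reads:
        if r.length < min_len:
            removed += 1
            continue
        seq = r.sequence
        if not _VALID_RE.match(seq):
            seq = seq.translate(_AMBIG_TABLE)
            if not _VALID_RE.match(seq):
                raise ValueError(f"read {r.id!r} contains non-nucleotide characters")
            kept.append(RawRead(r.id, seq))
        else:
            kept.append(r)
    logger.info("preprocess: kept %d reads, removed %d short reads", len(kept), removed)
    if not kept:
        logger.warning("preprocess: no reads survive min_len=%d", min_len)
    return kept


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------


@dataclass
class PafRecord:
    """One PAF line: 12 standard columns plus optional tags."""

    q_name: str
    q_len: int
    q_start: int
    q_end: int
    strand: str
    t_name: str
    t_len: int
    t_start: int
    t_end: int
    matches: int
    columns: int
    mapq: int = 255
    tags: dict = field(default_factory=dict)

    def to_line(self) -> str:
        cols = [
            self.q_name,
            str(self.q_len),
            str(self.q_start),
            str(self.q_end),
            self.strand,
            self.t_name,
            str(self.t_len),
            str(self.t_start),
            str(self.t_end),
            str(self.matches),
            str(self.columns),
            str(self.mapq),
        ]
        for key, val in sorted(self.tags.items()):
            if isinstance(val, float):
                cols.append(f"{key}:f:{val:.6f}")
            elif isinstance(val, int):
                cols.append(f"{key}:i:{val}")
            else:
                cols.append(f"{key}:Z:{val}")
        return "\t".join(cols)


def write_paf(records: Iterable[PafRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_paf(path: str | Path) -> list[PafRecord]:
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: PAF line has {len(f)} < 12 columns")
            tags = {}
            for t in f[12:]:
                key, typ, val = t.split(":", 2)
                tags[key] = int(val) if typ == "i" else float(val) if typ == "f" else val
            records.append(
                PafRecord(
                    f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                    f[5], int(f[6]), int(f[7]), int(f[8]),
                    int(f[9]), int(f[10]), int(f[11]), tags,
                )
            )
    return records


# ---------------------------------------------------------------------------
# GFA 1.0
# ---------------------------------------------------------------------------


def write_gfa(
    segments: dict[str, str | int],
    links: Iterable[tuple[str, str, str, str, int]],
    path: str | Path,
) -> None:
    """Write a GFA 1.0 graph.

    ``segments`` maps name -> sequence (or int length, emitted as LN tag);
    ``links`` yields (from, from_orient, to, to_orient, overlap_bases).
    """
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for name, seq in segments.items():
            if isinstance(seq, int):
                fh.write(f"S\t{name}\t*\tLN:i:{seq}\n")
            else:
                fh.write(f"S\t{name}\t{seq}\n")
        for a, ao, b, bo, ov in links:
            fh.write(f"L\t{a}\t{ao}\t{b}\t{bo}\t{ov}M\n")


def require_artifact(path: str | Path, stage: str) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stage {stage!r}: missing upstream artifact {path}")
    return path
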