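"""End-to-end pipeline: preprocess -> correct (2 passes) -> trim -> assemble
-> bridge, with every stage also runnable independently from its on-disk
inputs.  All stage outputs are plain text (FASTA/PAF/GFA/TSV/JSON)."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

from . import assembly as asm
from . import bridging as brg
from . import correction as corr
from . import metrics as met
from . import trimming as trm
from .io_core import (
    PipelineConfig,
    RawRead,
    preprocess,
    read_paf,
    read_sequences,
    require_artifact,
    write_fasta,
    write_paf,
)

logger = logging.getLogger("lorcas")


def _estimate_genome_size(reads, config: PipelineConfig) -> int:
    if config.genome_size > 0:
        return config.genome_size
    total = sum(r.length for r in reads)
    return max(1, total // config.trim_coverage_target)


def correct_stage(raw_path: Path, out_dir: Path, config: PipelineConfig):
    require_artifact(raw_path, "correct")
    reads = preprocess(read_sequences(raw_path), config.min_read_length)
    t0 = time.time()
    pass1, stats1 = corr.correct_read_set(reads, config, pass_num=1)
    logger.info("pass 1: %d reads in %.1fs", len(pass1), time.time() - t0)
    pass1_raw = [c.as_raw() for c in pass1]
    write_fasta(pass1_raw, out_dir / "corrected.pass1.fasta")
    t0 = time.time()
    pass2, stats2 = corr.correct_read_set(pass1_raw, config, pass_num=2)
    logger.info("pass 2: %d fragments in %.1fs", len(pass2), time.time() - t0)
    pass2_raw = [c.as_raw() for c in pass2]
    write_fasta(pass2_raw, out_dir / "corrected.pass2.fasta")
    with open(out_dir / "correction.stats.tsv", "w") as fh:
        fh.write("template_id\tpass\toutputs\n")
        for rows in (stats1, stats2):
            for tid, p, n in rows:
                fh.write(f"{tid}\t{p}\t{n}\n")
    return pass2_raw


def trim_stage(corrected_path: Path, out_dir: Path, config: PipelineConfig):
    require_artifact(corrected_path, "trim")
    corrected = read_sequences(corrected_path)
    genome_size = _estimate_genome_size(corrected, config)
    trimmed, overlaps = trm.trim_stage(corrected, genome_size, config)
    recs = []
    for t in trimmed:
        recs.append(RawRead(t.id, t.sequence))
    with open(out_dir / "trimmed.fasta", "w") as fh:
        for t in trimmed:
            fh.write(f">{t.id} kind={t.kind} src={t.source_interval[0]}-"
                     f"{t.source_interval[1]}\n{t.sequence}\n")
    write_paf([ov.to_paf() for ov in overlaps], out_dir / "overlaps.paf")
    return trimmed, overlaps


def assemble_stage(out_dir: Path, config: PipelineConfig,
                   trimmed=None, overlaps=None):
    if trimmed is None:
        path = require_artifact(out_dir / "trimmed.fasta", "assemble")
        trimmed_reads = read_sequences(path)
        reads = trimmed_reads
    else:
        reads = [t.as_raw() for t in trimmed]
    if overlaps is None:
        paf_path = require_artifact(out_dir / "overlaps.paf", "assemble")
        overlaps = _overlaps_from_paf(paf_path)
    contigs, graph = asm.assemble(reads, overlaps, config, gfa_dir=str(out_dir))
    write_fasta(
        [RawRead(c.id, c.sequence) for c in contigs],
        out_dir / "contigs.pre_bridge.fasta",
    )
    with open(out_dir / "contigs.layout.tsv", "w") as fh:
        fh.write("contig_id\tread_id\torientation\toffset\n")
        for c in contigs:
            for rid, o, off in c.layout:
                fh.write(f"{c.id}\t{rid}\t{o}\t{off}\n")
    return contigs


def _overlaps_from_paf(path):
    out = []
    for rec in read_paf(path):
        identity = 1.0 - rec.tags.get("df", 1.0 - rec.matches / max(1, rec.columns))
        out.append(
            asm.OverlapRecord(
                rec.q_name, rec.t_name, rec.strand,
                (rec.q_start, rec.q_end), (rec.t_start, rec.t_end),
                rec.q_len, rec.t_len, identity, rec.columns,
            )
        )
    return out


def bridge_stage(raw_path: Path, out_dir: Path, config: PipelineConfig,
                 contigs=None):
    require_artifact(raw_path, "bridge")
    raw = preprocess(read_sequences(raw_path), config.min_read_length)
    if contigs is None:
        path = require_artifact(out_dir / "contigs.pre_bridge.fasta", "bridge")
        contigs = [
            asm.Contig(r.id, r.sequence) for r in read_sequences(path)
        ]
    final, links = brg.bridge_stage(contigs, raw, config)
    write_fasta([RawRead(c.id, c.sequence) for c in final],
                out_dir / "contigs.final.fasta")
    with open(out_dir / "bridge.links.tsv", "w") as fh:
        fh.write("read_id\tcontig_a\tstrand_a\tcontig_b\tstrand_b\t"
                 "orientation\tkind\tgap_len\tscore\n")
        for l in links:
            fh.write(
                f"{l.read_id}\t{l.a_id}\t{l.strand_a}\t{l.b_id}\t{l.strand_b}"
                f"\t{l.orientation}\t{l.kind}\t{l.gap_len}\t{l.score:.1f}\n"
            )
    from .io_core import write_gfa

    write_gfa(
        {c.id: c.length for c in final},
        [],
        out_dir / "bridge_graph.gfa",
    )
    return final


def run_pipeline(config: PipelineConfig, raw_path: str | Path,
                 out_dir: str | Path) -> list:
    """Run every stage in series; returns the final contigs."""
    raw_path = Path(raw_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out_dir / "pipeline.log")
    logger.addHandler(handler)
    try:
        stages = []
        t0 = time.time()
        corrected = correct_stage(raw_path, out_dir, config)
        stages.append(("correct", time.time() - t0))
        t0 = time.time()
        trimmed, overlaps = trim_stage(
            out_dir / "corrected.pass2.fasta", out_dir, config
        )
        stages.append(("trim", time.time() - t0))
        t0 = time.time()
        contigs = assemble_stage(out_dir, config, trimmed, overlaps)
        stages.append(("assemble", time.time() - t0))
        t0 = time.time()
        final = bridge_stage(raw_path, out_dir, config, contigs)
        stages.append(("bridge", time.time() - t0))
        genome_size = config.genome_size or None
        stats = {
            "n_corrected": len(corrected),
            "n_trimmed_set": len(trimmed),
            "pre_bridge": met.assembly_stats(
                [c.length for c in contigs], genome_size
            ).__dict__,
            "final": met.assembly_stats(
                [c.length for c in final], genome_size
            ).__dict__,
            "stage_seconds": {k: round(v, 2) for k, v in stages},
        }
        (out_dir / "metrics.json").write_text(json.dumps(stats, indent=2))
        return final
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
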