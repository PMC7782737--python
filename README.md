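# lorcas

Progressive two-pass error correction and two-stage string-graph assembly
for noisy long reads, with a built-in nanopore-style read simulator.

Noisy long reads carry broadly distributed error rates (roughly 7–50% per
read) and occasional high-error-rate subsequences (HERS: >50% error within
a 500 bp window). `lorcas` handles both:

1. **Correction, pass 1** — for each template read, candidate reads are
   found by sampled k-mer matching with distance-difference (DDF) seed
   scoring and co-linear chaining; supports are aligned blockwise (500 bp
   banded blocks extended from the seed, stopping at >50%-error blocks),
   filtered by a global (0.5) plus an adaptive per-template quality
   threshold, and consumed by a plurality consensus. A coverage count array
   (CCA, threshold C=12) skips alignments over already well-supported
   template regions. The full-length template (corrected + uncorrected
   stretches) is emitted.
2. **Correction, pass 2** — the same machinery over pass-1 output with a
   sensitive realigner (tolerant anchor chaining + piecewise banded global
   alignment) that crosses high-error regions; only corrected intervals are
   emitted, so a read with an uncorrectable stretch splits into fragments.
3. **Trimming** — the longest ~40x of corrected reads are pairwise
   overlapped; reads fully covered by >90%-identity overlaps are "complete",
   others are trimmed to their longest covered interval; the second overlap
   round pairs only complete×trimmed and trimmed×trimmed.
4. **Assembly** — overlaps are filtered by per-read coverage statistics and
   adaptive identity/overhang cutoffs, a Myers-style string graph is built
   (contained reads removed, dovetails as dual extension edges), then
   transitive reduction, best-in/out edge marking, tip/bubble/spurious-link
   cleaning, and contig extraction from maximal linear paths.
5. **Bridging** — raw reads are mapped back to contig ends; gap/overlapped
   link candidates are clustered by gap length (1 kb single linkage), the
   best-scoring cluster (Σ identity×length) links each contig pair, and
   linear chains of links are spliced into final contigs (gap sequence taken
   from the representative raw read).

The `simulate` module generates a synthetic genome and reads reproducing
this error structure (Beta-distributed per-read rates on [0.07, 0.50],
length-inflated HERS injection, full ground truth with replayable per-read
edit plans), so the whole pipeline is testable offline.

## CLI

```bash
# simulate a dataset (genome.fasta, reads.fastq, truth.tsv)
lorcas --out-dir work --seed 1 simulate --genome-length 300000 --coverage 40

# full pipeline: correct -> trim -> assemble -> bridge
lorcas --out-dir work --seed 1 run work/reads.fastq

# stages individually
lorcas --out-dir work correct work/reads.fastq
lorcas --out-dir work trim work/corrected.pass2.fasta
lorcas --out-dir work assemble
lorcas --out-dir work bridge work/reads.fastq

# length/error statistics (JSON)
lorcas --out-dir work stats work/contigs.final.fasta \
    --genome work/genome.fasta --truth work/truth.tsv
```

Global flags: `--config cfg.yaml` (every constant in
`lorcas.io_core.PipelineConfig` is a YAML key), `--seed`, `--out-dir`.
Stage outputs are plain text: FASTA, PAF (12 columns + `df:f:` difference
tag), GFA 1.0 graphs, TSV link/layout tables, JSON metrics.

## Layout

```
src/lorcas/
  io_core.py     FASTA/FASTQ/PAF/GFA I/O, preprocessing, PipelineConfig
  simulate.py    synthetic genome + error-model read simulation, truth TSV
  candidates.py  k-mer index, DDF seed scoring, co-linear chaining
  correction.py  two-pass correction: thresholds, CCA, consensus
  trimming.py    40x selection, overlap coverage, complete/trimmed reads
  assembly.py    overlap filters, string graph, reduction, contigs
  bridging.py    raw-read contig links, clustering, gap splicing
  metrics.py     truth-aligned error rates, HERS windows, N50/NG50, QV
  pipeline.py    stage drivers and the end-to-end runner
  cli.py         click command-line interface
  _align.py      banded edit-distance kernels (numba) and transcripts
```
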