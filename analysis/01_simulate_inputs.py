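#!/usr/bin/env python
"""Generate the synthetic study inputs and summarise what was planted.

Writes the full input files (genomes, reads, methylation calls, peaks, SNP
counts) under scratch/analysis/inputs/ and a small planting summary under
results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SCRATCH, build_study, ensure_dirs  # noqa: E402

from sineboundary import io, synthetic  # noqa: E402

ensure_dirs()
outdir = SCRATCH / "inputs"
outdir.mkdir(parents=True, exist_ok=True)

cfg, lib, genome_a, genome_b, truth = build_study()
treated, untreated = synthetic.simulate_mel_reads(cfg, genome_a, truth)
cpg = synthetic.simulate_methylation(cfg, truth)
paa = synthetic.simulate_peaks_and_allelics(cfg, genome_a, genome_b, truth)

lib.to_fasta(outdir / "library.fa")
io.write_fasta(outdir / "genomeA.fa", {"chrS": genome_a})
io.write_fasta(outdir / "genomeB.fa", {"chrS": genome_b})
io.write_fastq(outdir / "mel_treated.fq", treated)
io.write_fastq(outdir / "mel_untreated.fq", untreated)
io.write_cpg_calls(outdir / "cpg_calls.tsv", cpg)
io.write_bed(outdir / "peaksA.bed", paa.peaks_A)
io.write_bed(outdir / "peaksB.bed", paa.peaks_B)
io.write_snp_counts(outdir / "snp_counts.tsv", paa.snp_counts)

rows = []
for strain in ("shared", "A", "B"):
    events = [e for e in truth.insertions
              if e.strain == strain and e.kind == "regular"]
    by_sub = pd.Series([e.subfamily for e in events]).value_counts()
    for sub, n in by_sub.items():
        rows.append({"strain": strain, "subfamily": sub, "n_planted": int(n)})
summary = pd.DataFrame(rows)
summary.to_csv(RESULTS / "simulation_planting_summary.tsv", sep="\t",
               index=False)

print(f"genomes: {len(genome_a):,} / {len(genome_b):,} bp")
print(f"planted insertions: {len(truth.insertions)} "
      f"({sum(e.strain != 'shared' for e in truth.insertions)} strain-specific"
      f" incl. 2 controls)")
print(f"reads: {len(treated):,} treated / {len(untreated):,} untreated")
print(f"CpG call rows: {len(cpg):,}; peaks: {len(paa.peaks_A)}; "
      f"SNPs: {len(paa.snp_counts):,}")
print(f"inputs -> {outdir}")
print(f"summary -> {RESULTS / 'simulation_planting_summary.tsv'}")
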