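#!/usr/bin/env python
"""Annotate strain-A genome against the consensus library and summarise
copy counts and divergence per subfamily (the re-annotation step)."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SCRATCH, build_study, ensure_dirs  # noqa: E402

from sineboundary import io  # noqa: E402
from sineboundary.repeat_toolkit import annotate_genome  # noqa: E402

ensure_dirs()
cfg, lib, genome_a, _, truth = build_study()
hits = annotate_genome(genome_a, lib)

io.write_bed(SCRATCH / "repeats_A.bed",
             [(h.contig, h.q_start, h.q_end, h.subfamily, int(h.score),
               h.strand, f"{h.divergence:.4f}") for h in hits])

df = pd.DataFrame([{"subfamily": h.subfamily,
                    "family": lib[h.subfamily].family,
                    "age_class": lib[h.subfamily].age_class,
                    "divergence": h.divergence,
                    "span": h.span} for h in hits])
summary = (df.groupby(["subfamily", "family", "age_class"])
           .agg(n_copies=("divergence", "size"),
                mean_divergence=("divergence", "mean"),
                mean_span=("span", "mean"))
           .reset_index())
summary.to_csv(RESULTS / "repeat_annotation_summary.tsv", sep="\t",
               index=False, float_format="%.4f")

expected = len([e for e in truth.insertions if e.strain in ("shared", "A")]) \
    + len(truth.rrna_loci)
print(summary.to_string(index=False))
print(f"\n{len(hits)} hits (expected {expected} planted loci in strain A)")
print("young copies sit near the simulated 2% divergence; the truncation "
      "of 5'-shortened copies leaves spans below the 190-bp consensus")
print(f"annotation -> {SCRATCH / 'repeats_A.bed'}")
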