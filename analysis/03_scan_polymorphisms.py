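#!/usr/bin/env python
"""Call insertional polymorphisms between the two strain genomes and score
the calls against the planted truth.

The scan aligns the genomes under the minimum-gap-penalty scheme, extracts
internal 120-300 bp gaps with well-aligned flanks, and keeps gaps whose
sequence is >80% occupied by a single repeat hit."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SCRATCH, build_study, ensure_dirs  # noqa: E402

from sineboundary import io  # noqa: E402
from sineboundary.evaluate import match_scan_calls, subfamily_accuracy  # noqa: E402
from sineboundary.polymorphism import (  # noqa: E402
    scan_genome_pair,
    summarize_polymorphisms,
)

ensure_dirs()
cfg, lib, genome_a, genome_b, truth = build_study()
calls = scan_genome_pair(genome_a, genome_b, lib)

io.write_bed(SCRATCH / "insertion_calls.bed",
             [(c.candidate.contig, c.candidate.start, c.candidate.end,
               c.subfamily, int(100 * c.occupancy), c.strand, c.carrier,
               f"{c.divergence:.4f}") for c in calls])

table = summarize_polymorphisms(calls)
table.to_csv(RESULTS / "polymorphism_counts.tsv", sep="\t")

rec = match_scan_calls(calls, truth, tol=5)
metrics = pd.DataFrame([{
    "n_planted": rec.n_truth,
    "n_calls": rec.n_calls,
    "sensitivity": rec.sensitivity,
    "precision": rec.precision,
    "subfamily_accuracy": subfamily_accuracy(calls, truth),
}])
metrics.to_csv(RESULTS / "polymorphism_recovery.tsv", sep="\t", index=False,
               float_format="%.4f")

print("carrier x subfamily counts:")
print(table.to_string())
print(f"\nrecovery vs planted truth (breakpoints within 5 bp): "
      f"sensitivity {rec.sensitivity:.3f}, precision {rec.precision:.3f}")
ctrl = [e for e in truth.insertions if e.kind.startswith("control")]
for e in ctrl:
    called = any(c.carrier == "B" and abs(c.candidate.start - e.start_B) <= 20
                 for c in calls)
    print(f"control {e.kind} ({e.length} bp): called={called} "
          f"(expected False)")
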