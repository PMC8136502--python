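#!/usr/bin/env python
"""Repeat density around ChIP-style peak boundaries, summit-in-repeat
counts, and the binding-vs-methylated-CpG stratification."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, build_study, ensure_dirs  # noqa: E402

from sineboundary import synthetic  # noqa: E402
from sineboundary.chromatin import (  # noqa: E402
    PeakSet,
    binding_vs_methylation,
    boundary_profile,
    summit_overlap,
)
from sineboundary.repeat_toolkit import annotate_genome  # noqa: E402

ensure_dirs()
cfg, lib, genome_a, genome_b, truth = build_study()
hits = [h for h in annotate_genome(genome_a, lib)
        if lib[h.subfamily].family != "rRNA"]
paa = synthetic.simulate_peaks_and_allelics(cfg, genome_a, genome_b, truth)

peaks = PeakSet(paa.peaks_A, summits=paa.summits_A, label="simK9ac")
prof = boundary_profile(peaks, hits, len(genome_a), window=2000, bin_size=100)
prof.to_frame().to_csv(RESULTS / "boundary_profile.tsv", sep="\t",
                       index=False, float_format="%.4f")

summits = summit_overlap(peaks, hits)
summits.to_csv(RESULTS / "summit_overlap.tsv", sep="\t", index=False,
               float_format="%.4f")

calls = synthetic.simulate_methylation(cfg, truth)
flags = synthetic.simulate_binding(cfg, truth, effect=0.0)
bind_table, chi2, p, direction = binding_vs_methylation(hits, calls, flags)
bind_table.to_csv(RESULTS / "binding_vs_methylation.tsv", sep="\t",
                  index=False, float_format="%.4f")

adj = prof.enrichment[int(np.argmax(prof.bin_edges[:-1] == -100))]
far = prof.enrichment[0]
print(f"genome-wide repeat density (background): {prof.background:.3f}")
print(f"enrichment in the first bin outside the boundary: {adj:.1f}x "
      f"(half of all peak edges are anchored at planted copies)")
print(f"enrichment 2 kb outside: {far:.2f}x (returns toward background)")
inside = summits[summits.subfamily != "outside"]["fraction"].sum()
print(f"peak summits inside repeat copies: {100 * inside:.1f}%")
print(f"binding vs methylated-CpG count (independence planted): "
      f"chi2 p = {p:.3f} -> no association, as simulated")
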