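#!/usr/bin/env python
"""F1-hybrid allelic analysis across polymorphic insertions: per-SNP
allelic fractions, the pooled ratio in the domain-extension region, and
boundary-shift detection on the per-allele coverage profiles."""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, build_study, ensure_dirs  # noqa: E402

from sineboundary import synthetic  # noqa: E402
from sineboundary.allelic import (  # noqa: E402
    locate_boundary_shift,
    region_allelic_ratio,
    snp_allelic_fractions,
)

ensure_dirs()
cfg, lib, genome_a, genome_b, truth = build_study()
paa = synthetic.simulate_peaks_and_allelics(cfg, genome_a, genome_b, truth)

per_snp = snp_allelic_fractions(paa.snp_counts)
per_snp.head(500).to_csv(RESULTS / "snp_allelic_fractions.tsv", sep="\t",
                          index=False, float_format="%.4f")

calls = {}
for region in ("extension", "background"):
    call = region_allelic_ratio(paa.snp_counts, region)
    calls[region] = call
    print(f"region '{region}': fraction_A {call.fraction_A:.3f} "
          f"[{call.ci_low:.3f}, {call.ci_high:.3f}], "
          f"fold (free/carrier) {call.fold:.2f} -> {call.flag} "
          f"({call.n_snps} SNPs, {call.count_A + call.count_B:,} reads)")

detected = 0
shifts = []
for prof in paa.profiles:
    s = locate_boundary_shift(prof.coverage_A, prof.coverage_B,
                              prof.bin_edges)
    detected += s.shifted
    shifts.append({"breakpoint": int(prof.breakpoint_bg),
                   "boundary_carrier": s.boundary_carrier,
                   "boundary_free": s.boundary_free,
                   "shift_bins": s.shift_bins, "detected": s.shifted})
print(f"boundary shift detected at {detected}/{len(paa.profiles)} anchored "
      f"insertions (carrier boundary at the breakpoint, free-allele domain "
      f"extended >= 3 bins beyond)")

report = {
    "extension_fold": calls["extension"].fold,
    "extension_flag": calls["extension"].flag,
    "background_fold": calls["background"].fold,
    "background_flag": calls["background"].flag,
    "planted_fold": cfg.allelic_fold,
    "n_anchored_profiles": len(paa.profiles),
    "n_shifts_detected": int(detected),
    "shifts": shifts,
}
(RESULTS / "allelic_boundary.json").write_text(json.dumps(report, indent=1))
print(f"report -> {RESULTS / 'allelic_boundary.json'}")
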