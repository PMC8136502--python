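# sineboundary

Analysis pipeline for studying young SINE (short interspersed element)
insertions as mobile boundaries of DNA methylation and histone
modification, exercised end-to-end on seeded synthetic data.

Mouse B2-type SINEs are Pol III-transcribed retrotransposons that are still
mobile: copies inserted recently are present in one laboratory strain and
absent in another. Such polymorphic insertions can terminate a
hypomethylated, hyperacetylated chromatin domain at their insertion site,
reducing expression of the neighbouring gene on the insertion-carrying
allele. Testing this computationally requires a chain of analyses —
polymorphic-insertion discovery between two genomes, repeat subfamily
phylogenetics, quantification of full-length Pol III transcripts,
methylation-stratified expression analysis, repeat-density metaprofiles at
peak boundaries, and allele-specific comparisons in F1 hybrids. This
package implements each step as a tested, reusable module and ships a
generator that produces all inputs with the statistical structure those
analyses assume, so every step can be validated against a known ground
truth.

## Methods at a glance

* **Insertion scanning** — genomes are aligned under a minimum-gap-penalty
  scheme (match +1, mismatch −1, gap open 0, gap extend −1), so an inserted
  element of length *L* aligns as one internal gap costing only *L*.
  Internal gaps of 120–300 bp with well-aligned flanks (≥50 aligned bases
  per side at ≥90% identity) are candidate insertions; a candidate is
  called when a single repeat hit occupies >80% of the gapped region
  (strict). Whole genomes are anchored on shared unique 21-mers (collinear
  chaining) with the DP run only between anchors. Breakpoints are
  normalised to the leftmost position equivalent under the target-site
  duplication.
* **Repeat classification** — local alignment (match +1, mismatch −1, gap
  open −2, gap extend −1) against a consensus library, both strands;
  divergence = (substitutions + gap events) / aligned sites.
* **Phylogenetics** — pairwise p-distances (substitutions per aligned
  site) and Saitou–Nei neighbor joining; on additive matrices the tree
  reproduces all path lengths exactly.
* **melRNA quantification** — reads retaining the 3′ adaptor are complete
  molecules (5′→3′); retained reads are classified against the library and
  mapped by exact, unique, zero-mismatch search over both strands. Counts
  are expressed as RPM = reads per million 5.8S reads, the internal
  control whose 5′ monophosphate makes it ligatable with or without
  enzymatic 5′-end conversion; the conversion contrast (treated vs
  untreated) quantifies Pol III transcript recovery.
* **Methylation × expression** — per-locus methylation pools
  methylated/total counts over CpG sites in the locus; loci are stratified
  jointly by CpG count (≤2 / 3–5 / ≥6) and methylation level (quartile
  bins), and expression summaries are compared across strata.
* **Chromatin boundaries** — repeat density versus signed distance from
  peak boundaries (positive = into the peak, end boundaries mirrored),
  with enrichment relative to the genome-wide covered fraction;
  summit-in-repeat counting on half-open intervals; binding vs
  methylated-CpG-count association (chi-square).
* **Allelic analysis** — Wilson 95% intervals on per-SNP allelic
  fractions, pooled per-region ratios with a binomial test, and a
  half-plateau boundary locator that compares where each allele's
  chromatin domain ends relative to a polymorphic insertion breakpoint.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
seeded configuration (two ~1 Mb strain genomes, 400 planted copies of four
subfamilies, 100 strain-specific insertions, 200k-read libraries). For
example, the polymorphism scan:

```bash
$ python analysis/03_scan_polymorphisms.py
carrier x subfamily counts:
subfamily  SF1_young  SF2_young
carrier
A                 22         28
B                 27         23

recovery vs planted truth (breakpoints within 5 bp): sensitivity 1.000, precision 1.000
control control_short (110 bp): called=False (expected False)
control control_lowocc (200 bp): called=False (expected False)
```

All 100 planted strain-specific insertions are recovered at their exact
breakpoints with no false calls; the planted 110-bp control falls below
the 120-bp floor and the 75%-occupancy control fails the >80% rule, as
intended. The transcript quantification step:

```bash
$ python analysis/05_quantify_melrna.py
input reads 200,000: retained 140,032 full-length, discarded 59,968 adaptorless
5.8S internal control reads: 42,131
5S-surrogate enrichment by 5' conversion: 20.0-fold (generator carryover model expects 20)
unique / multi / unmapped: 139,431 / 601 / 0
replicate concordance (log10 RPM, locus level): R = 0.990
loci with RPM < 1: 5; with RPM > 1000: 266
rank-abundance log-log slope over the top 200 loci: -1.00 (power-law exponent 1 planted)
```

The 20-fold recovery of the 5S surrogate is exactly the inverse of the
generator's 5% tri-phosphate carryover rate, locus abundances follow the
planted power law (slope −1), and the two replicates agree at R = 0.99.
Scripts 06–08 reproduce the methylation–expression coupling (median
expression falling monotonically with methylation only in CpG-rich
strata), the boundary-adjacent repeat enrichment (≈7.5× background when
half the peak edges are anchored at planted copies), and the allelic
analysis (≈6-fold bias toward the insertion-free allele in the domain
extension, with the boundary shift detected at 40/40 anchored sites).

The same functionality is exposed as a CLI
(`sineboundary simulate|annotate|scan|melquant|methexpr|boundary|allelic|tree|consensus|run-all`)
for use on files.

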