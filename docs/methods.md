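# Methods

This note records the models, parameter choices and numerical conventions
behind `sineboundary`, and what the synthetic study does and does not
establish.

## The synthetic study design

One `SimConfig` (a single seed) determines every input. Independent
per-stage random streams are derived from `(seed, stage_id, replicate)`,
so adding a stage or drawing a replicate never perturbs the others, and
identical configurations produce byte-identical outputs.

**Genomes.** The background is i.i.d. uniform over ACGT. This is a
deliberate idealisation: it guarantees that planted repeat copies are the
only repeat-like sequence, so every recovery test has an unambiguous
truth. Two strain genomes share the background and the shared insertions;
each strain additionally carries its own insertions. An insertion of
element sequence *S* at background position *p* with target-site
duplication (TSD) length *t* yields `g[:p+t] + S + g[p:]` — the *t* bases
at the target site appear on both sides of the element, exactly as
L1-machinery integration leaves them. The default TSD is 9 bp. The element
is a copy of a subfamily consensus mutated by i.i.d. substitutions at
`per_copy_divergence` (default 2%, the scale typical of recently active
subfamilies); lengths are drawn from `insertion_length_range` (default
120–300 bp, the size window used for polymorphism discovery). Copies
shorter than the 190-bp consensus are 5′-truncated (the common
retrotransposition failure mode); longer ones carry a 3′ poly-A tail.
Strand is random. Events are placed with ≥(max length + 500) bp spacing so
flanks are unique; this is the one respect in which placement is *not*
uniform.

**Consensus library.** Subfamilies share a core sequence and differ at 10
private diagnostic positions each (pairwise Hamming ≥ 20). Young
subfamilies carry 7 CpG dinucleotides at fixed slots, old subfamilies 1;
all other CpGs are scrubbed from the core so CpG content is controlled.
Two reserved rRNA surrogates of 158 and 121 bases (the 5.8S/5S length
scale) are random sequences stored under reserved names and planted once
in each genome.

**Expression.** Locus abundances follow a power law: shares proportional
to `rank^(-zipf_exponent)` (default exponent 1) over the loci present in
the analysed genome, multiplied by a methylation coupling
`exp(-c * w * m)` where `m` is the locus's planted methylation level
(uniform on [0,1]), `c = meth_coupling_strength` (default 3), and
`w = 1` for loci with ≥3 CpG sites but `w = 0.2` for CpG-poor loci. The
default `c` was chosen by a power calculation on the median statistic: a
quartile step in `m` then shifts median log₁₀ expression by
`3 × 0.25 × log₁₀e ≈ 0.33`, several times the sampling noise of a
~30-locus stratum median, so the monotone trend is recoverable seed after
seed without being so strong as to be trivial. Shares sum to
`1 − frac_5p8S − frac_5S` of the library.

**5′ chemistry.** Each molecule carries a label rather than a sequence
feature: the 5.8S surrogate is 5′-monophosphate (always ligatable); the 5S
surrogate and all SINE transcripts are 5′-triphosphate. Phosphatase
treatment is modelled as label-conditional inclusion: treated libraries
accept everything; untreated libraries accept tri-P molecules with
probability `untreated_polIII_inclusion` (default 0.05, making the
expected treated/untreated contrast for Pol III classes 20-fold). A
`frac_degraded` fraction of molecules (default 0.30 — the real fraction is
not known; this is a stress setting) is truncated at the 3′ end and loses
the adaptor, so the full-length filter removes it. Reads carry no
sequencing errors and no PCR duplicates (out of scope by design).

**Methylation calls.** Per-CpG truth levels jitter around the locus level
(Beta with concentration 10) so that the "number of methylated CpG sites"
statistic varies within loci; observed counts are Binomial(total, level)
with total ~ Poisson(`meth_depth`, default 30).

**Peaks and allelics.** Boundary-anchored peaks start exactly at the end
of a strain-A-specific copy (the copy just outside the peak); in strain B,
where the copy is absent, the corresponding domain extends
`extension_length` (default 1 kb) beyond the breakpoint. SNPs are planted
in the shared background at `snp_density` (default 1/200 bp); allelic
read counts are balanced Binomial(depth, 0.5) everywhere except inside an
extension region, where the insertion-free allele's share is
`fold/(fold+1)` with `allelic_fold` = 6 — the magnitude of the allelic
expression difference that motivates the analysis. Per-allele coverage
profiles around each anchored breakpoint are Poisson draws at
`profile_depth_high` (50/bin) inside the domain and `profile_depth_low`
(2/bin) outside.

Because the background is uniform, read errors absent, and coverage purely
Poisson, passing tests demonstrate the correctness of the *computations*
(alignment, filtering rules, normalisation, interval arithmetic,
statistics) under the stated statistical structure — not robustness to
mappability artefacts, sequence context biases, or misassembly in real
genomes.

## Numerical conventions

* **Alignment scoring.** Classification uses match +1, mismatch −1, gap
  open −2, gap extend −1 (a gap of length L costs 2+L): simple and
  exhaustively testable, adequate at ≤15% divergence. Strain comparison
  uses the minimum-gap scheme (open 0, extend −1) so long indels cost
  linearly and align as single gaps. Both run on Biopython's
  `PairwiseAligner`; an infinitesimal extra open penalty (1e-4) makes the
  traceback prefer the fewest gap runs among co-optimal alignments —
  without it a zero-open-cost gap can be scattered across coincidental
  matches. All legitimate scores are integers, so the epsilon cannot
  change which alignments are optimal (total runs × ε < 1); reported
  scores are exact (rescored or rounded).
* **Whole-genome alignment** anchors on k-mers (k = 21) unique within each
  genome and shared between them, keeps the longest collinear chain
  (LIS), merges overlapping same-diagonal anchors into exact-match runs,
  and aligns inter-run segments by the DP. Segments beyond the DP budget
  raise an explicit error rather than silently degrading.
* **Breakpoint normalisation.** Within a TSD the gap placement is
  ambiguous; gaps are shifted to the leftmost equivalent position (shift
  allowed while the base entering the gap equals the base leaving it),
  which provably recovers the planted breakpoint; the equivalence range is
  reported as the TSD length.
* **Occupancy.** The denominator is the gap length; the numerator is the
  repeat-hit span extended across flanking A (3′) / T (5′) homopolymer
  runs, the way repeat annotators absorb the retrotransposon poly-A tail
  (up to 2 interrupting bases are tolerated — a mutated base between body
  and tail would otherwise break the run). ">80%" is strict: occupancy
  exactly 0.80 is rejected.
* **Flank rule.** "Well aligned" flanks means ≥50 aligned bases within
  the 100 alignment columns on each side of the gap, at ≥90% identity.
* **Divergence** counts substitutions plus gap *events* (one per gap run)
  per aligned site; no CpG-adjusted correction is applied.
* **Ties.** Classification ties break by younger age class, then name;
  consensus-column base ties break in A<C<G<T order; a column whose gap
  count strictly exceeds the best base count is dropped.
* **Neighbor joining** clamps negative branch-length estimates to zero and
  records the clamped total on the tree.
* **Bins.** CpG-count strata default to ≤2 / 3–5 / ≥6 (the CpG-poor
  boundary at 2 reflects where the methylation effect empirically fades);
  methylation bins are quartiles, left-closed right-open with the last
  closed at 1. RPM bins use edges ≤1 / (1,10] / (10,100] / >100; RPM-bin
  threshold counts are strict inequalities. Both bin sets are
  configurable.
* **Intervals** are 0-based half-open everywhere; a summit at a repeat's
  start coordinate is inside, at its end coordinate outside. Peak-set
  overlap uses ≥1-base overlap with per-set ("pre-merge") shared counts:
  a chain a1–b1–a2 leaves both a1 and a2 shared.
* **Boundary profiles** aggregate both edges of every peak with the end
  boundary mirrored so positive offsets always point into the peak;
  density is base-coverage fraction (occupancy, not element counts); the
  background is the genome-wide covered fraction, which makes the
  uniform-null enrichment exactly 1 in expectation. Bins are clipped at
  genome edges and clipped bases leave the denominator. Peaks shorter than
  two bins still contribute both edges (their interiors overlap). Both raw
  density and enrichment are emitted.
* **Allelic statistics** use Wilson 95% intervals (valid at low counts)
  rather than Wald; the regional test is a two-sided exact binomial
  against 0.5, flagged "biased" at p < 0.01 and fold ≥ 1.5 in either
  direction. Fold is reported as free-allele / carrier-allele. The
  chromatin boundary of an allele is the outermost bin whose coverage
  falls below half the domain plateau (the median of positive-offset
  bins); a flat-zero profile has no plateau and raises an error. This
  half-plateau rule is this package's operational definition — published
  boundary positions are typically read off coverage tracks by eye, so a
  reproducible criterion had to be chosen; it is configurable.
* **RPM** divides by reads classified to the reserved 5.8S entry after
  trimming; a zero denominator is an explicit error. Log-scale
  correlations add a 0.5-RPM pseudocount. "Expressed" means ≥1 uniquely
  mapped read in either replicate.
* **Unique mapping** is exact string search (both strands) with zero
  mismatches — deliberately stricter than a general aligner, matching the
  full-length/unique-mapping reporting convention; reads mapping to ≥2
  positions are tallied as multi-mapped, never assigned.
* **A CpG site counts as methylated** at pooled level ≥ 0.5 (used by the
  binding stratification); categories above 6 methylated CpGs are pooled.

## Scale choices

Tests and the acceptance script run the full study at 1 Mb genomes ×
~400 copies × 200k reads — large enough that every statistical check has
its intended power, small enough that the suite completes in about two
minutes. Multi-seed properties (methylation coupling, null calibrations,
boundary-shift detection, CI coverage) use 3–20 seeds as stated in each
test.

## Known limitations

* The scanner assumes mostly-collinear genomes; rearrangements beyond
  insertions/deletions (inversions, translocations) are out of scope.
* Copies of the same subfamily at low divergence can be identical by
  chance; their transcripts become multi-mapped and the loci are
  undercounted — the same mappability ceiling the unique-mapping rule
  imposes on real data.
* Insertions whose gap (element + TSD) exceeds the 300-bp window ceiling
  are invisible to the scan, just as a windowed discovery screen would
  miss them; with the default 120–300 bp length range and a 9-bp TSD this
  affects copies longer than 291 bp.
* The half-plateau boundary rule and the anchored-peak geometry are
  idealisations; on real ChIP-seq data domain edges are gradual and the
  locator's ±1-bin accuracy claim holds only at the simulated
  signal-to-noise ratio.
* Fragmentary repeat hits passing the occupancy rule are kept and flagged
  (`fragment=True`); no attempt is made to join multiple fragments of one
  element.
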