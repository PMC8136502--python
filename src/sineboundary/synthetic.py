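"""Seeded generator for every input the pipeline consumes.

One :class:`~sineboundary.config.SimConfig` determines, reproducibly:

* a consensus library of SINE-like subfamilies (young subfamilies CpG-rich,
  old ones CpG-poor) plus two reserved rRNA surrogates of the 5.8S/5S length
  scale (158 and 121 bases);
* a pair of strain genomes sharing an i.i.d. uniform background, differing
  by planted strain-specific insertions (mutated consensus derivatives with
  target-site duplications);
* full-length medium-length-RNA reads whose locus abundances follow a power
  law modulated by a planted methylation-expression coupling, with 5'-end
  chemistry classes deciding library inclusion with/without phosphatase
  treatment;
* per-CpG bisulfite-style methylation calls;
* ChIP-style peaks whose edges can be anchored at planted insertion
  breakpoints, with F1-hybrid allelic SNP counts biased in the domain
  extension of the insertion-free strain.

The background genome is i.i.d. uniform over ACGT so the planted copies are
the only repeat-like sequence present -- recovery tests are unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import revcomp
from .config import SimConfig
from .repeat_toolkit import (
    RESERVED_5P8S,
    RESERVED_5S,
    ConsensusLibrary,
)

_BASES = np.array(list("ACGT"))

# stage identifiers for seed derivation: one config seed, one stream per stage
_STAGES = {
    "library": 1,
    "genome": 2,
    "expression": 3,
    "reads": 4,
    "methylation": 5,
    "peaks": 6,
    "binding": 7,
}


def _rng(cfg: SimConfig, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STAGES[stage], extra])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position independently at ``rate`` (no indels)."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# consensus library


def make_consensus_library(cfg: SimConfig) -> ConsensusLibrary:
    """Build the subfamily consensus library.

    Subfamilies share a core sequence, differ pairwise at >=10 diagnostic
    positions, and carry age-dependent CpG content: young subfamilies >=5
    CpG sites, old subfamilies <=2.
    """
    cfg.validate()
    rng = _rng(cfg, "library")
    clen = cfg.consensus_length
    n_sub = cfg.n_subfamilies
    n_young = (n_sub + 1) // 2

    core = list(_random_seq(rng, clen))
    # strip background CpGs so CpG content is fully controlled
    for i in range(clen - 1):
        if core[i] == "C" and core[i + 1] == "G":
            core[i + 1] = "A"

    n_cpg_young, n_cpg_old = 7, 1
    # CpG sites occupy a reserved block of positions, spaced 3 apart
    cpg_slots = list(range(10, 10 + 3 * n_cpg_young, 3))
    reserved = set()
    for q in cpg_slots:
        reserved.update((q, q + 1))
    # 10 private diagnostic positions per subfamily
    pool = [i for i in range(clen) if i not in reserved and i + 1 not in reserved]
    diag_positions = rng.permutation(pool)[: n_sub * 10]
    diag_by_sub = [sorted(diag_positions[i * 10 : (i + 1) * 10]) for i in range(n_sub)]

    lib = ConsensusLibrary()
    rotate = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for s in range(n_sub):
        young = s < n_young
        seq = core.copy()
        n_cpg = n_cpg_young if young else n_cpg_old
        for j, q in enumerate(cpg_slots):
            if j < n_cpg:
                seq[q], seq[q + 1] = "C", "G"
            else:
                seq[q], seq[q + 1] = "C", "A"
        for p in diag_positions:
            if p in diag_by_sub[s]:
                seq[p] = rotate[seq[p]]
        # repair accidental CpGs created by diagnostics (keep planned sites only)
        planned = {q for j, q in enumerate(cpg_slots) if j < n_cpg}
        for i in range(clen - 1):
            if seq[i] == "C" and seq[i + 1] == "G" and i not in planned:
                if i + 1 in diag_positions:
                    seq[i] = "T"
                else:
                    seq[i + 1] = "T"
        age = "young" if young else "old"
        lib.add(f"SF{s + 1}_{age}", "".join(seq), family="B2sim", age_class=age)

    lib.add(RESERVED_5P8S, _random_seq(rng, 158), family="rRNA", age_class="rRNA")
    lib.add(RESERVED_5S, _random_seq(rng, 121), family="rRNA", age_class="rRNA")
    return lib


# ---------------------------------------------------------------------------
# genomes and ground truth


@dataclass
class PlantedInsertion:
    strain: str  # 'A', 'B' or 'shared'
    contig: str
    bg_pos: int  # breakpoint in the shared-background frame
    length: int  # element length incl. any A-tail, excl. TSD
    tsd: int
    subfamily: str
    strand: str
    sequence: str  # genome-strand element sequence
    rna: str  # element in transcript orientation
    kind: str = "regular"  # regular | control_short | control_lowocc | rrna
    start_A: int = -1  # leftmost removable-block start, genome A coords
    start_B: int = -1
    elem_start_A: int = -1  # element interval start in genome A coords
    elem_start_B: int = -1

    @property
    def block_length(self) -> int:
        return self.length + self.tsd

    def locus_key(self) -> tuple:
        return (self.contig, self.elem_start_A, self.elem_start_A + self.length,
                self.strand)


@dataclass
class PeakTruth:
    bg_start: int
    bg_end: int
    anchored: bool
    anchor: PlantedInsertion | None
    interval_A: tuple[int, int]
    interval_B: tuple[int, int]


@dataclass
class SnpTruth:
    bg_pos: int
    pos_A: int
    allele_A: str
    allele_B: str
    region: str  # 'extension' | 'background'


@dataclass
class GroundTruth:
    contig: str
    insertions: list[PlantedInsertion] = field(default_factory=list)
    rrna_loci: list[PlantedInsertion] = field(default_factory=list)
    locus_expression: dict[tuple, float] = field(default_factory=dict)
    locus_methylation: dict[tuple, float] = field(default_factory=dict)
    locus_cpg_levels: dict[tuple, list[tuple[int, float]]] = field(
        default_factory=dict
    )  # locus -> [(genomic CpG pos in A, true level), ...]
    peak_truth: list[PeakTruth] = field(default_factory=list)
    snp_table: list[SnpTruth] = field(default_factory=list)

    def specific_insertions(self, kinds: tuple[str, ...] = ("regular",)):
        return [e for e in self.insertions
                if e.strain in ("A", "B") and e.kind in kinds]

    def expression_loci(self) -> list[PlantedInsertion]:
        return [e for e in self.insertions
                if e.kind == "regular" and e.strain in ("shared", "A")]


def _place_positions(
    rng: np.random.Generator, n: int, genome_length: int, sep: int, margin: int
) -> np.ndarray:
    span = genome_length - 2 * margin - n * sep
    if span <= n:
        raise ValueError("genome too short to place insertions without overlap")
    draw = np.sort(rng.choice(span, size=n, replace=False))
    return margin + draw + np.arange(n) * sep


def _assemble(bg: str, events: list[PlantedInsertion], strain: str) -> str:
    """Insert events (sorted by bg_pos) into the background with TSDs."""
    parts = []
    prev = 0
    for e in sorted(events, key=lambda x: x.bg_pos):
        p, t = e.bg_pos, e.tsd
        parts.append(bg[prev : p + t])
        parts.append(e.sequence)
        prev = p
    parts.append(bg[prev:])
    return "".join(parts)


def _coordinates(events: list[PlantedInsertion], strain: str) -> None:
    """Fill leftmost-block and element coordinates for one assembled genome."""
    offset = 0
    for e in sorted(events, key=lambda x: x.bg_pos):
        start = e.bg_pos + offset
        elem = start + e.tsd
        if strain == "A":
            e.start_A, e.elem_start_A = start, elem
        else:
            e.start_B, e.elem_start_B = start, elem
        offset += e.block_length


def map_to_genome(bg_pos: int, events: list[PlantedInsertion]) -> int:
    """Map a background coordinate to a genome built from ``events``
    (leftmost convention at breakpoints)."""
    return bg_pos + sum(e.block_length for e in events if e.bg_pos < bg_pos)


def simulate_genome_pair(
    cfg: SimConfig, lib: ConsensusLibrary
) -> tuple[str, str, GroundTruth]:
    cfg.validate()
    rng = _rng(cfg, "genome")
    contig = "chrS"
    bg = _random_seq(rng, cfg.genome_length)

    young = [e.name for e in lib.sine_entries() if e.age_class == "young"]
    all_subs = [e.name for e in lib.sine_entries()]
    lo, hi = cfg.insertion_length_range

    n_controls = int(cfg.plant_short_control) + int(cfg.plant_low_occupancy_control)
    n_events = (
        cfg.n_shared_insertions
        + 2 * cfg.n_specific_insertions_per_strain
        + n_controls
        + 2  # rRNA surrogate loci
    )
    sep = hi + 500
    margin = 3000
    positions = _place_positions(rng, n_events, cfg.genome_length, sep, margin)
    positions = rng.permutation(positions)

    def make_copy(subfamily: str, length: int) -> tuple[str, str, str]:
        cons = lib[subfamily].sequence
        if length <= len(cons):
            rna = cons[len(cons) - length :]  # 5'-truncation keeps the 3' end
        else:
            rna = cons + "A" * (length - len(cons))
        body = _mutate(rna[: min(length, len(cons))], cfg.per_copy_divergence, rng)
        rna = body + rna[min(length, len(cons)) :]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = rna if strand == "+" else revcomp(rna)
        return seq, rna, strand

    truth = GroundTruth(contig=contig)
    cursor = 0

    def next_pos() -> int:
        nonlocal cursor
        p = int(positions[cursor])
        cursor += 1
        return p

    for strain, count in (("shared", cfg.n_shared_insertions),
                          ("A", cfg.n_specific_insertions_per_strain),
                          ("B", cfg.n_specific_insertions_per_strain)):
        for _ in range(count):
            sub = str(rng.choice(all_subs if strain == "shared" else young))
            length = int(rng.integers(lo, hi + 1))
            seq, rna, strand = make_copy(sub, length)
            truth.insertions.append(PlantedInsertion(
                strain=strain, contig=contig, bg_pos=next_pos(), length=length,
                tsd=cfg.tsd_length, subfamily=sub, strand=strand,
                sequence=seq, rna=rna,
            ))

    if cfg.plant_short_control:
        sub = young[0]
        seq, rna, strand = make_copy(sub, 110)
        truth.insertions.append(PlantedInsertion(
            strain="B", contig=contig, bg_pos=next_pos(), length=110,
            tsd=cfg.tsd_length, subfamily=sub, strand=strand, sequence=seq,
            rna=rna, kind="control_short",
        ))
    if cfg.plant_low_occupancy_control:
        sub = young[-1]
        frag, _, _ = make_copy(sub, 150)
        filler = _random_seq(rng, 50)
        seq = frag + filler
        truth.insertions.append(PlantedInsertion(
            strain="B", contig=contig, bg_pos=next_pos(), length=200,
            tsd=0, subfamily=sub, strand="+", sequence=seq, rna=seq,
            kind="control_lowocc",
        ))
    for name in (RESERVED_5P8S, RESERVED_5S):
        seq = lib[name].sequence
        truth.rrna_loci.append(PlantedInsertion(
            strain="shared", contig=contig, bg_pos=next_pos(), length=len(seq),
            tsd=0, subfamily=name, strand="+", sequence=seq, rna=seq,
            kind="rrna",
        ))

    events_A = [e for e in truth.insertions if e.strain in ("shared", "A")]
    events_A += truth.rrna_loci
    events_B = [e for e in truth.insertions if e.strain in ("shared", "B")]
    events_B += truth.rrna_loci
    genome_A = _assemble(bg, events_A, "A")
    genome_B = _assemble(bg, events_B, "B")
    _coordinates(events_A, "A")
    _coordinates(events_B, "B")

    _plant_expression_and_methylation(cfg, truth)
    return genome_A, genome_B, truth


def expression_multiplier(level: float, n_cpg: int, cfg: SimConfig) -> float:
    """Planted methylation-expression coupling.

    CpG-rich loci (>=3 CpG sites) are repressed by exp(-c * level); in
    CpG-poor loci the coupling is attenuated toward 1.
    """
    weight = 1.0 if n_cpg >= 3 else cfg.meth_attenuation_cpg_poor
    return math.exp(-cfg.meth_coupling_strength * weight * level)


def _plant_expression_and_methylation(cfg: SimConfig, truth: GroundTruth) -> None:
    rng = _rng(cfg, "expression")
    loci = truth.expression_loci()
    if not loci:
        return
    sine_frac = 1.0 - cfg.frac_5p8S - cfg.frac_5S
    ranks = rng.permutation(len(loci)) + 1
    raw = np.zeros(len(loci))
    for i, e in enumerate(loci):
        key = e.locus_key()
        level = float(rng.uniform())
        cpg_offsets = [j for j in range(len(e.sequence) - 1)
                       if e.sequence[j : j + 2] == "CG"]
        # per-CpG truth levels jitter around the locus level (Beta, conc. 10)
        conc = 10.0
        a = max(level * conc, 1e-3)
        b = max((1 - level) * conc, 1e-3)
        site_levels = rng.beta(a, b, size=len(cpg_offsets))
        truth.locus_methylation[key] = level
        truth.locus_cpg_levels[key] = [
            (e.elem_start_A + off, float(lv))
            for off, lv in zip(cpg_offsets, site_levels)
        ]
        raw[i] = (ranks[i] ** -cfg.zipf_exponent) * expression_multiplier(
            level, len(cpg_offsets), cfg
        )
    shares = raw / raw.sum() * sine_frac
    for e, s in zip(loci, shares):
        truth.locus_expression[e.locus_key()] = float(s)


# ---------------------------------------------------------------------------
# melRNA-seq reads


@dataclass
class SimRead:
    id: str
    sequence: str
    cls: str  # library-entry name or locus subfamily
    chem: str  # monoP | triP
    full_length: bool


def simulate_mel_reads(
    cfg: SimConfig,
    genome: str,
    truth: GroundTruth,
    replicate: int = 0,
) -> tuple[list[SimRead], list[SimRead]]:
    """Treated (phosphatase-converted) and untreated libraries, ``n_reads``
    each. 5.8S-surrogate molecules carry a ligatable 5' mono-P and enter both
    libraries; Pol III-class molecules (5S surrogate and SINE loci) carry a
    5' tri-P and enter the untreated library only at the configured
    carryover rate. ``frac_degraded`` molecules lose the 3' adaptor."""
    cfg.validate()
    if len(cfg.adaptor3) < 8:
        raise ValueError("3' adaptor shorter than 8 bases is unanchorable")
    rng = _rng(cfg, "reads", replicate)
    loci = truth.expression_loci()
    lib_shares = np.array(
        [cfg.frac_5p8S, cfg.frac_5S]
        + [truth.locus_expression[e.locus_key()] for e in loci]
    )
    lib_shares = lib_shares / lib_shares.sum()
    rnas = [truth.rrna_loci[0].rna, truth.rrna_loci[1].rna] + [e.rna for e in loci]
    classes = [RESERVED_5P8S, RESERVED_5S] + [e.subfamily for e in loci]
    chems = ["monoP", "triP"] + ["triP"] * len(loci)

    def draw_molecules(n: int, rng: np.random.Generator) -> list[tuple[int, bool]]:
        idx = rng.choice(len(lib_shares), size=n, p=lib_shares)
        degraded = rng.random(n) < cfg.frac_degraded
        return list(zip(idx.tolist(), degraded.tolist()))

    def build(molecules, prefix: str) -> list[SimRead]:
        reads = []
        for i, (idx, degraded) in enumerate(molecules):
            rna = rnas[idx]
            if degraded:
                cut = int(rng.integers(20, len(rna) + 1))
                seq = rna[:cut]
            else:
                seq = rna + cfg.adaptor3
            reads.append(SimRead(
                id=f"{prefix}{i}",
                sequence=seq,
                cls=classes[idx],
                chem=chems[idx],
                full_length=not degraded,
            ))
        return reads

    n = cfg.n_reads
    treated = build(draw_molecules(n, rng), "t")

    untreated_mols: list[tuple[int, bool]] = []
    while len(untreated_mols) < n:
        batch = draw_molecules(max(1000, 4 * (n - len(untreated_mols))), rng)
        for idx, degraded in batch:
            if chems[idx] == "monoP" or rng.random() < cfg.untreated_polIII_inclusion:
                untreated_mols.append((idx, degraded))
                if len(untreated_mols) == n:
                    break
    untreated = build(untreated_mols, "u")
    return treated, untreated


# ---------------------------------------------------------------------------
# methylation calls


def simulate_methylation(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Per-CpG (contig, position, methylated, total) calls over genome A,
    binomially sampled at the planted per-CpG levels."""
    cfg.validate()
    rng = _rng(cfg, "methylation")
    rows = []
    for key, sites in truth.locus_cpg_levels.items():
        contig = key[0]
        for pos, level in sites:
            total = max(1, int(rng.poisson(cfg.meth_depth)))
            meth = int(rng.binomial(total, level))
            rows.append((contig, pos, meth, total))
    df = pd.DataFrame(rows, columns=["contig", "position", "methylated", "total"])
    return df.sort_values(["contig", "position"], ignore_index=True)


# ---------------------------------------------------------------------------
# peaks, summits, allelic counts, coverage profiles


@dataclass
class AllelicProfile:
    """Binned domain coverage of the two alleles around one anchored
    insertion breakpoint; offsets are signed background-frame distances
    (positive = into the peak)."""

    breakpoint_bg: int
    bin_edges: np.ndarray  # offsets, len nbins+1
    coverage_A: np.ndarray  # carrier allele
    coverage_B: np.ndarray  # insertion-free allele
    anchor: PlantedInsertion


@dataclass
class PeaksAndAllelics:
    peaks_A: list[tuple[str, int, int]]
    peaks_B: list[tuple[str, int, int]]
    summits_A: list[int]
    snp_counts: pd.DataFrame
    profiles: list[AllelicProfile]


def simulate_peaks_and_allelics(
    cfg: SimConfig,
    genome_A: str,
    genome_B: str,
    truth: GroundTruth,
    window: int = 2000,
    bin_size: int = 100,
) -> PeaksAndAllelics:
    cfg.validate()
    rng = _rng(cfg, "peaks")
    contig = truth.contig
    n_edges = 2 * cfg.peak_count
    n_anchored = int(round(cfg.frac_boundary_anchored * n_edges))
    anchors = [e for e in truth.insertions
               if e.strain == "A" and e.kind == "regular"]
    if n_anchored > len(anchors):
        raise ValueError(
            f"need {n_anchored} anchor insertions but only {len(anchors)} planted"
        )
    anchors = [anchors[i] for i in rng.permutation(len(anchors))[:n_anchored]]
    n_anchored_peaks = len(anchors)
    n_free_peaks = cfg.peak_count - n_anchored_peaks
    if n_free_peaks < 0:
        raise ValueError("frac_boundary_anchored > 0.5 with one anchored edge "
                         "per peak is not representable")

    plo, phi = cfg.peak_length_range
    occupied: list[tuple[int, int]] = []
    peak_truth: list[PeakTruth] = []

    events_A = sorted(
        [e for e in truth.insertions if e.strain in ("shared", "A")]
        + truth.rrna_loci, key=lambda e: e.bg_pos)
    events_B = sorted(
        [e for e in truth.insertions if e.strain in ("shared", "B")]
        + truth.rrna_loci, key=lambda e: e.bg_pos)

    for e in anchors:
        plen = int(rng.integers(plo, phi + 1))
        p = e.bg_pos
        bg_iv = (p, min(p + plen, len(genome_B)))
        occupied.append((p - cfg.extension_length - window, bg_iv[1]))
        a0 = e.elem_start_A + e.block_length  # peak starts at the copy edge
        b_bp = map_to_genome(p, events_B)
        peak_truth.append(PeakTruth(
            bg_start=p, bg_end=bg_iv[1], anchored=True, anchor=e,
            interval_A=(a0, a0 + (bg_iv[1] - p)),
            interval_B=(b_bp - cfg.extension_length, b_bp + (bg_iv[1] - p)),
        ))

    tries = 0
    while n_free_peaks > 0 and tries < 10_000:
        tries += 1
        plen = int(rng.integers(plo, phi + 1))
        p = int(rng.integers(window, cfg.genome_length - plen - window))
        if any(p < hi and p + plen > lo for lo, hi in occupied):
            continue
        occupied.append((p, p + plen))
        peak_truth.append(PeakTruth(
            bg_start=p, bg_end=p + plen, anchored=False, anchor=None,
            interval_A=(map_to_genome(p, events_A),
                        map_to_genome(p, events_A) + plen),
            interval_B=(map_to_genome(p, events_B),
                        map_to_genome(p, events_B) + plen),
        ))
        n_free_peaks -= 1
    if n_free_peaks > 0:
        raise ValueError("could not place non-anchored peaks without overlap")

    peak_truth.sort(key=lambda pt: pt.bg_start)
    truth.peak_truth = peak_truth
    peaks_A = [(contig, *pt.interval_A) for pt in peak_truth]
    peaks_B = [(contig, *pt.interval_B) for pt in peak_truth]
    summits_A = [(a + b) // 2 for _, a, b in peaks_A]

    # --- SNP allelic counts -------------------------------------------------
    n_snps = rng.binomial(cfg.genome_length, cfg.snp_density)
    snp_bg = np.sort(rng.choice(cfg.genome_length, size=n_snps, replace=False))
    blocks = [(e.bg_pos, e.bg_pos + 1) for e in events_A + events_B]
    ext_regions = [(pt.bg_start - cfg.extension_length, pt.bg_start)
                   for pt in peak_truth if pt.anchored]
    rows = []
    frac_free = cfg.allelic_fold / (cfg.allelic_fold + 1.0)
    for x in snp_bg.tolist():
        if any(lo <= x < hi for lo, hi in blocks):
            continue
        region = "extension" if any(lo <= x < hi for lo, hi in ext_regions) \
            else "background"
        total = max(1, int(rng.poisson(cfg.allelic_depth)))
        p_b = frac_free if region == "extension" else 0.5
        count_b = int(rng.binomial(total, p_b))
        pos_a = map_to_genome(x, events_A)
        rows.append((contig, pos_a, total - count_b, count_b, region))
        truth.snp_table.append(SnpTruth(
            bg_pos=x, pos_A=pos_a, allele_A="", allele_B="", region=region))
    snp_counts = pd.DataFrame(
        rows, columns=["contig", "position", "alleleA_count", "alleleB_count",
                       "region_label"])

    # --- per-anchor binned coverage profiles --------------------------------
    profiles = []
    edges = np.arange(-window, window + bin_size, bin_size)
    for pt in peak_truth:
        if not pt.anchored:
            continue
        p = pt.bg_start
        cov_a = np.zeros(len(edges) - 1)
        cov_b = np.zeros(len(edges) - 1)
        for i in range(len(edges) - 1):
            lo, hi = p + edges[i], p + edges[i + 1]
            # domain A: [p, bg_end); domain B: [p - ext, bg_end)
            for cov, dlo in ((cov_a, p), (cov_b, p - cfg.extension_length)):
                ov = max(0, min(hi, pt.bg_end) - max(lo, dlo))
                lam = (ov * cfg.profile_depth_high
                       + (bin_size - ov) * cfg.profile_depth_low) / bin_size
                cov[i] = rng.poisson(lam)
        profiles.append(AllelicProfile(
            breakpoint_bg=p, bin_edges=edges.copy(), coverage_A=cov_a,
            coverage_B=cov_b, anchor=pt.anchor))

    return PeaksAndAllelics(peaks_A, peaks_B, summits_A, snp_counts, profiles)


# ---------------------------------------------------------------------------
# factor binding flags (for the binding-vs-methylation stratification)


def simulate_binding(
    cfg: SimConfig,
    truth: GroundTruth,
    effect: float = 0.0,
    base_rate: float = 0.3,
    replicate: int = 0,
) -> dict[tuple, bool]:
    """Bernoulli binding flags per expression locus. ``effect`` is the
    log-odds slope on the number of methylated CpG sites (0 = binding
    independent of methylation); ``replicate`` draws an independent flag
    set for the same truth."""
    rng = _rng(cfg, "binding", replicate)
    out: dict[tuple, bool] = {}
    keys = list(truth.locus_cpg_levels)
    n_meth = np.array(
        [sum(1 for _, lv in truth.locus_cpg_levels[k] if lv >= 0.5) for k in keys],
        dtype=float,
    )
    centered = n_meth - n_meth.mean() if len(keys) else n_meth
    logit0 = math.log(base_rate / (1 - base_rate))
    for k, x in zip(keys, centered):
        p = 1.0 / (1.0 + math.exp(-(logit0 + effect * x)))
        out[k] = bool(rng.random() < p)
    return out
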