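"""Insertion-polymorphism scanning: gap extraction rules, occupancy filter,
strain symmetry and end-to-end recovery on small genome pairs."""

import numpy as np
import pytest

from sineboundary.alignment import DPBudgetError
from sineboundary.config import SimConfig
from sineboundary import synthetic
from sineboundary.polymorphism import (
    align_genomes,
    align_min_gap,
    call_insertions,
    extract_internal_gaps,
    scan_genome_pair,
    summarize_polymorphisms,
)
from sineboundary.evaluate import match_scan_calls

from conftest import random_seq


def test_identical_sequences_gapless():
    aln = align_min_gap("ACGT" * 25, "ACGT" * 25)
    assert aln.ops == [("M", 100)]
    assert aln.score == 100


def test_min_gap_budget_error():
    with pytest.raises(DPBudgetError):
        align_min_gap("A" * 8000, "C" * 8000, dp_budget=10_000)


def _pair_with_gap(rng, gap_len, flank=400, tsd=0):
    """Background plus one planted block; returns (carrier_seq, free_seq,
    insert_pos)."""
    bg = random_seq(rng, 2 * flank)
    ins = random_seq(rng, gap_len - tsd)
    p = flank
    carrier = bg[: p + tsd] + ins + bg[p:]
    return carrier, bg, p


def test_gap_length_floor_excludes_119(rng):
    carrier, free, _ = _pair_with_gap(rng, 119)
    aln = align_min_gap(carrier, free)
    assert extract_internal_gaps(aln, min_len=120) == []


def test_gap_passing_all_rules_is_extracted(rng):
    carrier, free, p = _pair_with_gap(rng, 200)
    aln = align_min_gap(carrier, free)
    cands = extract_internal_gaps(aln)
    assert len(cands) == 1
    c = cands[0]
    assert c.length == 200
    assert c.start == p
    assert c.carrier == "A"  # extra bases in the query
    assert c.left_identity >= 0.98 and c.right_identity >= 0.98


def test_gap_ceiling_excludes_long_insertions(rng):
    carrier, free, _ = _pair_with_gap(rng, 400)
    aln = align_min_gap(carrier, free)
    assert extract_internal_gaps(aln, max_len=300) == []


def test_terminal_gaps_are_not_candidates(rng):
    free = random_seq(rng, 500)
    carrier = free + random_seq(rng, 150)  # trailing gap only
    aln = align_min_gap(carrier, free)
    assert extract_internal_gaps(aln) == []


def test_leftmost_normalisation_recovers_tsd_breakpoint(rng):
    # a 9-bp target-site duplication makes the gap placement ambiguous over
    # 9 positions; the candidate must report the leftmost one
    carrier, free, p = _pair_with_gap(rng, 200 + 9, tsd=9)
    aln = align_min_gap(carrier, free)
    cands = extract_internal_gaps(aln)
    assert len(cands) == 1
    assert cands[0].start == p
    assert cands[0].tsd_len >= 9


def test_insertion_in_subject_carried_by_other_strain(rng):
    free, _, _ = _pair_with_gap(rng, 1)  # just a background
    carrier, bg, p = _pair_with_gap(rng, 180)
    aln = align_min_gap(bg, carrier)  # carrier is now the subject
    cands = extract_internal_gaps(aln)
    assert len(cands) == 1
    assert cands[0].carrier == "B"


def test_occupancy_rule_is_strict(small_library):
    rng = np.random.default_rng(55)
    cons = small_library.sine_entries()[0].sequence  # 190 bases

    def candidate_with(repeat_frac):
        gap_len = 200
        n_rep = int(gap_len * repeat_frac)
        gap_seq = cons[:n_rep] + random_seq(rng, gap_len - n_rep)
        bg = random_seq(rng, 800)
        carrier = bg[:400] + gap_seq + bg[400:]
        aln = align_min_gap(carrier, bg)
        cands = extract_internal_gaps(aln)
        assert len(cands) == 1
        return cands

    # exact 0.80 occupancy -> rejected (strictly greater than is required)
    assert call_insertions(candidate_with(0.80), small_library) == []
    # 0.75 -> rejected
    assert call_insertions(candidate_with(0.75), small_library) == []
    # 0.90 -> called
    calls = call_insertions(candidate_with(0.90), small_library)
    assert len(calls) == 1 and calls[0].occupancy > 0.80


def test_min_occupancy_monotonicity(small_cfg, small_library, small_genomes):
    genome_a, genome_b, _ = small_genomes
    aln = align_genomes(genome_a, genome_b)
    cands = extract_internal_gaps(aln)
    counts = [len(call_insertions(cands, small_library, min_occupancy=mo))
              for mo in (0.5, 0.8, 0.9, 0.97)]
    assert counts == sorted(counts, reverse=True)


def test_full_consensus_gap_has_occupancy_near_one(small_library):
    rng = np.random.default_rng(56)
    cons = small_library.sine_entries()[1].sequence
    bg = random_seq(rng, 900)
    carrier = bg[:450] + cons + bg[450:]
    calls = call_insertions(
        extract_internal_gaps(align_min_gap(carrier, bg)), small_library)
    assert len(calls) == 1
    assert calls[0].occupancy == 1.0
    assert calls[0].divergence == 0.0


def test_strain_swap_symmetry(small_cfg, small_library, small_genomes):
    """Swapping the two strains swaps carrier labels but preserves the
    call set."""
    genome_a, genome_b, _ = small_genomes
    fwd = scan_genome_pair(genome_a, genome_b, small_library)
    rev = scan_genome_pair(genome_b, genome_a, small_library,
                           strain_names=("B", "A"))
    key_fwd = sorted((c.carrier, c.candidate.length, c.subfamily) for c in fwd)
    key_rev = sorted((c.carrier, c.candidate.length, c.subfamily) for c in rev)
    assert key_fwd == key_rev
    # breakpoints agree after mapping through the carrier genome
    starts_fwd = sorted(c.candidate.start for c in fwd)
    starts_rev = sorted(c.candidate.start for c in rev)
    assert starts_fwd == starts_rev


def test_scan_recovery_on_small_pair(small_cfg, small_library, small_genomes):
    genome_a, genome_b, truth = small_genomes
    calls = scan_genome_pair(genome_a, genome_b, small_library)
    rec = match_scan_calls(calls, truth)
    assert rec.sensitivity >= 0.95
    assert rec.precision >= 0.95
    # planted controls excluded by the length floor / occupancy rule
    for e in truth.insertions:
        if e.kind.startswith("control"):
            assert not any(abs(c.candidate.start - e.start_B) <= 10
                           for c in calls)


def test_no_insertions_no_calls(small_library):
    cfg = SimConfig(seed=9, genome_length=50_000, n_shared_insertions=10,
                    n_specific_insertions_per_strain=0, peak_count=0)
    lib = synthetic.make_consensus_library(cfg)
    ga, gb, truth = synthetic.simulate_genome_pair(cfg, lib)
    assert ga == gb
    assert scan_genome_pair(ga, gb, lib) == []


def test_summary_bookkeeping(small_cfg, small_library, small_genomes):
    genome_a, genome_b, truth = small_genomes
    calls = scan_genome_pair(genome_a, genome_b, small_library)
    table = summarize_polymorphisms(calls)
    assert int(table.to_numpy().sum()) == len(calls)
    assert set(table.index) <= {"A", "B"}
    assert summarize_polymorphisms([]).empty
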