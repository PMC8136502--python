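"""Full-length filtering, classification, unique mapping and RPM
normalisation."""

import math

import numpy as np
import pytest

from sineboundary.config import SimConfig
from sineboundary.alignment import revcomp
from sineboundary.melrna import (
    LocusExpression,
    NormalizationError,
    classify_reads,
    map_unique,
    normalize_rpm,
    rank_abundance,
    replicate_concordance,
    tap_contrast,
    trim_filter,
)
from sineboundary.repeat_toolkit import RESERVED_5P8S, RESERVED_5S, ConsensusLibrary
from sineboundary import synthetic

from conftest import random_seq

ADAPTOR = "TGGAATTCTCGGGTGCCAAGG"


def test_trim_filter_known_adaptor_status(rng):
    """Constructed reads of known adaptor status are filtered without
    error: full-length retained and trimmed, adaptorless discarded."""
    reads, expected = [], []
    for i in range(300):
        t = random_seq(rng, int(rng.integers(30, 200)))
        has = bool(rng.random() < 0.5)
        reads.append((f"r{i}", t + ADAPTOR if has else t))
        expected.append((has, t))
    records, stats = trim_filter(reads, ADAPTOR)
    assert stats.conserved()
    assert stats.n_retained == sum(h for h, _ in expected)
    by_id = {r.id: r for r in records}
    for i, (has, t) in enumerate(expected):
        if has:
            assert by_id[f"r{i}"].trimmed_sequence == t
        else:
            assert f"r{i}" not in by_id


def test_trim_filter_adaptor_prefix_at_read_end(rng):
    t = random_seq(rng, 80)
    records, stats = trim_filter([("r", t + ADAPTOR[:10])], ADAPTOR,
                                 min_overlap=8)
    assert stats.n_retained == 1
    assert records[0].trimmed_sequence == t
    # below the overlap floor the suffix is not recognised
    _, stats2 = trim_filter([("r", t + ADAPTOR[:5])], ADAPTOR, min_overlap=8)
    assert stats2.n_no_adaptor == 1


def test_adaptor_only_read_dropped_by_length_rule():
    records, stats = trim_filter([("r", ADAPTOR)], ADAPTOR)
    assert records == []
    assert stats.n_too_short == 1


def test_classify_reads_pure_5p8S(small_library):
    seq = small_library[RESERVED_5P8S].sequence
    records, _ = trim_filter([(f"r{i}", seq + ADAPTOR) for i in range(100)],
                             ADAPTOR)
    cc = classify_reads(records, small_library)
    assert cc.counts == {RESERVED_5P8S: 100}
    assert cc.n_5p8S == 100
    assert cc.conserved()


def test_classify_reads_mixture_within_binomial_noise(small_library, rng):
    names = [e.name for e in small_library.sine_entries()][:2] + [RESERVED_5P8S]
    probs = [0.5, 0.3, 0.2]
    n = 600
    reads = []
    for i in range(n):
        name = names[rng.choice(3, p=probs)]
        reads.append((f"r{i}", small_library[name].sequence + ADAPTOR))
    records, _ = trim_filter(reads, ADAPTOR)
    cc = classify_reads(records, small_library)
    for name, p in zip(names, probs):
        sd = math.sqrt(n * p * (1 - p))
        assert abs(cc.counts.get(name, 0) - n * p) <= 3 * sd
    assert cc.family_counts["B2sim"] == cc.counts[names[0]] + cc.counts[names[1]]


def test_normalize_rpm_definition_and_scale_invariance():
    assert normalize_rpm({"x": 5}, 1_000_000)["x"] == pytest.approx(5.0)
    a = normalize_rpm({"x": 7, "y": 3}, 10_000)
    b = normalize_rpm({"x": 70, "y": 30}, 100_000)
    assert a == pytest.approx(b)
    with pytest.raises(NormalizationError):
        normalize_rpm({"x": 1}, 0)


def test_map_unique_counts_and_multimapping(rng):
    genome = random_seq(rng, 5_000)
    copy = random_seq(rng, 150)
    # one unique copy at 1000, one duplicated pair at 2000/3500
    dup = random_seq(rng, 150)
    genome = (genome[:1000] + copy + genome[1150:2000] + dup
              + genome[2150:3500] + dup + genome[3650:])
    loci = [("chrS", 1000, 1150, "+"), ("chrS", 2000, 2150, "+"),
            ("chrS", 3500, 3650, "+")]
    reads, _ = trim_filter(
        [("u1", copy + ADAPTOR), ("u2", revcomp(copy) + ADAPTOR),
         ("m1", dup + ADAPTOR), ("x1", random_seq(rng, 100) + ADAPTOR)],
        ADAPTOR)
    expr, stats = map_unique(reads, genome, loci)
    by_locus = {le.locus: le.unique_read_count for le in expr}
    assert by_locus[("chrS", 1000, 1150, "+")] == 2  # both strands map there
    assert by_locus[("chrS", 2000, 2150, "+")] == 0  # multi-mapped
    assert stats.n_multi == 1
    assert stats.n_unmapped == 1
    assert stats.n_unique == 2


def test_tap_contrast_identical_libraries(small_library):
    seqs = [small_library[RESERVED_5P8S].sequence,
            small_library[RESERVED_5S].sequence]
    reads = [(f"r{i}", s + ADAPTOR) for i, s in enumerate(seqs * 50)]
    records, _ = trim_filter(reads, ADAPTOR)
    cc = classify_reads(records, small_library)
    ratios = tap_contrast(cc, cc)
    assert all(r.ratio == pytest.approx(1.0) for r in ratios.values()
               if not r.undefined)
    # class absent from both -> undefined, flagged
    cc2 = classify_reads(records, small_library)
    cc2.counts["ghost"] = 0
    assert tap_contrast(cc2, cc)["ghost"].undefined


def test_replicate_concordance_limits():
    a = {"x": 10.0, "y": 1.0, "z": 100.0}
    assert replicate_concordance(a, a) == pytest.approx(1.0)
    anti = {"x": 100.0, "y": 10.0, "z": 0.1}
    assert replicate_concordance(a, anti) < 0
    flat = {"x": 1.0, "y": 1.0, "z": 1.0}
    assert replicate_concordance(flat, a) is None  # zero variance, flagged


def test_rank_abundance_bins():
    expr = [LocusExpression(("c", 0, 1, "+"), 1, rpm=5.0)]
    table, lo, hi = rank_abundance(expr)
    assert list(table["rank"]) == [1]
    assert (lo, hi) == (0, 0)
    expr = [LocusExpression(("c", i, i + 1, "+"), 1, rpm=r)
            for i, r in enumerate([0.5, 2000.0, 3.0, 0.99, 1000.0])]
    _, lo, hi = rank_abundance(expr)
    assert lo == 2  # strictly below 1
    assert hi == 1  # strictly above 1000 (1000.0 itself excluded)
    table, lo, hi = rank_abundance([])
    assert table.empty and lo == 0 and hi == 0


def test_rpm_expectation_invariant_to_depth(small_cfg, small_library,
                                            small_genomes):
    """Halving the sequencing depth leaves RPM expectations unchanged
    (within Monte-Carlo noise) because the 5.8S denominator scales too."""
    genome_a, _, truth = small_genomes
    hits = [e.locus_key() for e in truth.expression_loci()]
    loci = [(k[0], k[1], k[2], k[3]) for k in hits]

    def rpm_at_depth(n_reads, replicate):
        cfg = SimConfig(**{**small_cfg.__dict__, "n_reads": n_reads})
        tr, _ = synthetic.simulate_mel_reads(cfg, genome_a, truth,
                                             replicate=replicate)
        records, _ = trim_filter(tr, cfg.adaptor3)
        cc = classify_reads(records, small_library)
        expr, _ = map_unique(records, genome_a, loci)
        return {le.locus: le.rpm for le in
                normalize_rpm(expr, cc.n_5p8S)}

    full = rpm_at_depth(small_cfg.n_reads, 3)
    half = rpm_at_depth(small_cfg.n_reads // 2, 4)
    top = sorted(full, key=lambda k: -full[k])[:20]
    for k in top:
        # Poisson noise on counts; compare on the log scale within 3 SD
        n_full = full[k]
        n_half = half[k]
        if n_full <= 0 or n_half <= 0:
            continue
        sd = math.sqrt(1 / max(n_full, 1) + 2 / max(n_half, 1))
        assert abs(math.log(n_half / n_full)) < 3 * sd + 0.5
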