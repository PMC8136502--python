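"""Boundary metaprofiles (with a per-base brute-force oracle), summit and
peak-set overlap bookkeeping, and the binding-methylation association."""

import numpy as np
import pandas as pd
import pytest

from sineboundary.chromatin import (
    PeakSet,
    binding_vs_methylation,
    boundary_profile,
    peak_set_overlap,
    summit_overlap,
)
from sineboundary import synthetic
from sineboundary.config import SimConfig


def brute_force_profile(peaks, repeats, genome_length, window, bin_size):
    """Per-base membership count over all boundaries (the oracle)."""
    covered = np.zeros(genome_length, dtype=bool)
    for _, s, e in repeats:
        covered[s:e] = True
    edges = np.arange(-window, window + bin_size, bin_size)
    nbins = len(edges) - 1
    cov = np.zeros(nbins)
    bases = np.zeros(nbins)
    for _, start, end in peaks:
        for i in range(nbins):
            for a, b in ((start + edges[i], start + edges[i + 1]),
                         (end - edges[i + 1], end - edges[i])):
                a, b = max(0, a), min(genome_length, b)
                if b > a:
                    cov[i] += covered[a:b].sum()
                    bases[i] += b - a
    density = np.divide(cov, bases, out=np.zeros(nbins), where=bases > 0)
    return density, covered.mean()


def test_profile_matches_brute_force_oracle(rng):
    genome_length = 50_000
    repeats = []
    pos = 100
    while pos < genome_length - 400:
        repeats.append(("chrS", pos, pos + int(rng.integers(80, 300))))
        pos += int(rng.integers(400, 1500))
    peaks = [("chrS", int(p), int(p) + int(rng.integers(1000, 3000)))
             for p in rng.integers(2000, genome_length - 5000, size=8)]
    prof = boundary_profile(PeakSet(peaks), repeats, genome_length,
                            window=1000, bin_size=100)
    density, background = brute_force_profile(peaks, repeats, genome_length,
                                              1000, 100)
    np.testing.assert_allclose(prof.density, density, atol=1e-12)
    assert prof.background == pytest.approx(background)


def test_no_repeats_gives_zero_density():
    prof = boundary_profile(PeakSet([("chrS", 1000, 3000)]), [], 10_000,
                            window=500, bin_size=100)
    assert np.all(prof.density == 0)


def test_peak_end_at_repeat_edge_maximises_first_outside_bin():
    # repeat immediately outside each peak end
    peaks, repeats = [], []
    for i in range(5):
        s = 5000 + i * 6000
        peaks.append(("chrS", s, s + 2000))
        repeats.append(("chrS", s + 2000, s + 2200))  # outside the end
    prof = boundary_profile(PeakSet(peaks), repeats, 50_000,
                            window=1000, bin_size=100)
    outside = prof.density[prof.bin_edges[:-1] < 0]
    first_outside = prof.density[np.argmax(prof.bin_edges[:-1] == -100)]
    assert first_outside == outside.max()
    assert first_outside >= 0.5  # half the boundaries are flush with a repeat


def test_uniform_placement_enrichment_is_flat():
    """Uniformly placed repeats: every bin's enrichment within 3 empirical
    SD of 1 (10 seeds)."""
    genome_length = 200_000
    enrichments = []
    for seed in range(10):
        r = np.random.default_rng(900 + seed)
        repeats = [("chrS", int(p), int(p) + 150)
                   for p in r.integers(0, genome_length - 150, size=120)]
        peaks = [("chrS", int(p), int(p) + 2500)
                 for p in r.integers(3000, genome_length - 6000, size=10)]
        prof = boundary_profile(PeakSet(peaks), repeats, genome_length,
                                window=1000, bin_size=200)
        enrichments.append(prof.enrichment)
    enr = np.array(enrichments)
    mean = enr.mean(axis=0)
    sd = enr.std(axis=0, ddof=1) / np.sqrt(enr.shape[0])
    # flat at 1 within 3 SD of the empirical mean, every bin
    assert np.all(np.abs(mean - 1) <= 3 * enr.std(axis=0, ddof=1))
    assert np.abs(mean - 1).max() < 0.5


def test_window_must_be_bin_multiple():
    with pytest.raises(ValueError):
        boundary_profile(PeakSet([("c", 0, 10)]), [], 100, window=150,
                         bin_size=100)
    with pytest.raises(ValueError):
        boundary_profile(PeakSet([]), [], 100)


def test_summit_half_open_edges():
    repeats = [("chrS", 100, 200, "B2x")]
    peaks = PeakSet([("chrS", 50, 250), ("chrS", 50, 250)],
                    summits=[100, 200])  # start counted, end not
    table = summit_overlap(peaks, repeats)
    by = table.set_index("subfamily")
    assert by.loc["B2x", "count"] == 1
    assert by.loc["outside", "count"] == 1


def test_summit_fraction_bookkeeping():
    repeats = [("chrS", i * 1000, i * 1000 + 200, "B2x") for i in range(4)]
    summits = [i * 1000 + 100 for i in range(4)] + \
              [50_000 + i * 10 for i in range(6)]
    peaks = PeakSet([("chrS", s - 10, s + 10) for s in summits],
                    summits=summits)
    table = summit_overlap(peaks, repeats)
    by = table.set_index("subfamily")
    assert by.loc["B2x", "count"] == 4
    assert by.loc["B2x", "fraction"] == pytest.approx(0.4)


def test_peak_set_overlap_partitions():
    a = PeakSet([("c", 0, 10), ("c", 20, 30), ("c", 40, 50), ("c", 60, 70),
                 ("c", 80, 90)])
    b = PeakSet([("c", 5, 12), ("c", 44, 46), ("c", 100, 110)])
    ov = peak_set_overlap(a, b)
    assert len(ov.shared_a) == 2
    assert len(ov.shared_b) == 2
    assert len(ov.a_specific) == 3
    assert len(ov.b_specific) == 1
    # identical sets: all shared; disjoint: none
    same = peak_set_overlap(a, a)
    assert len(same.shared_a) == 5 and not same.a_specific
    disj = peak_set_overlap(a, PeakSet([("c", 300, 310)]))
    assert not disj.shared_a and len(disj.b_specific) == 1


def test_all_unbound_gives_zero_bound_fractions(small_cfg, small_genomes):
    _, _, truth = small_genomes
    calls = synthetic.simulate_methylation(small_cfg, truth)
    loci = [e.locus_key() for e in truth.expression_loci()]
    flags = {k: False for k in loci}
    table, chi2, p, _ = binding_vs_methylation(loci, calls, flags)
    assert (table["bound_fraction"] == 0).all()
    assert p == 1.0


def test_binding_independence_vs_dependence(small_cfg, small_genomes):
    _, _, truth = small_genomes
    calls = synthetic.simulate_methylation(small_cfg, truth)
    loci = [e.locus_key() for e in truth.expression_loci()]
    null_flags = synthetic.simulate_binding(small_cfg, truth, effect=0.0)
    _, _, p0, _ = binding_vs_methylation(loci, calls, null_flags)
    alt_flags = synthetic.simulate_binding(small_cfg, truth, effect=1.0)
    _, _, p1, d1 = binding_vs_methylation(loci, calls, alt_flags)
    assert p0 > 0.01
    assert p1 < 0.01
    assert d1 > 0  # more methylated CpGs -> higher binding, as planted
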