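"""Properties of the synthetic-data generator: determinism, bookkeeping,
CpG structure, planted coupling, and 5'-chemistry behaviour."""

import math

import numpy as np
import pytest

from sineboundary.config import SimConfig
from sineboundary.repeat_toolkit import RESERVED_5P8S, RESERVED_5S
from sineboundary import synthetic
from sineboundary.synthetic import expression_multiplier


def _tiny_cfg(**kw):
    base = dict(seed=3, genome_length=60_000, n_shared_insertions=15,
                n_specific_insertions_per_strain=5, n_reads=2_000,
                peak_count=4)
    base.update(kw)
    return SimConfig(**base)


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        SimConfig(frac_degraded=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(zipf_exponent=0).validate()
    with pytest.raises(ValueError):
        SimConfig(n_subfamilies=1).validate()
    with pytest.raises(ValueError):
        SimConfig(genome_length=1000).validate()  # < 10x max insertion


def test_library_construction_guarantees():
    cfg = _tiny_cfg()
    lib = synthetic.make_consensus_library(cfg)
    sine = lib.sine_entries()
    assert len(sine) == cfg.n_subfamilies
    # equal length, >= 10 diagnostic differences pairwise
    for i, a in enumerate(sine):
        assert len(a.sequence) == cfg.consensus_length
        for b in sine[i + 1:]:
            ham = sum(x != y for x, y in zip(a.sequence, b.sequence))
            assert ham >= 10
    # young CpG-rich, old CpG-poor
    for e in sine:
        if e.age_class == "young":
            assert e.cpg_count >= 5
        else:
            assert e.cpg_count <= 2
    # reserved rRNA surrogates at the 5.8S/5S length scale
    assert len(lib[RESERVED_5P8S].sequence) == 158
    assert len(lib[RESERVED_5S].sequence) == 121


def test_generator_is_deterministic():
    cfg = _tiny_cfg()
    out = []
    for _ in range(2):
        lib = synthetic.make_consensus_library(cfg)
        ga, gb, truth = synthetic.simulate_genome_pair(cfg, lib)
        tr, un = synthetic.simulate_mel_reads(cfg, ga, truth)
        cpg = synthetic.simulate_methylation(cfg, truth)
        out.append((ga, gb,
                    [(r.id, r.sequence) for r in tr],
                    [(r.id, r.sequence) for r in un],
                    cpg.to_csv()))
    assert out[0] == out[1]


def test_bookkeeping_of_planted_events():
    cfg = _tiny_cfg(n_specific_insertions_per_strain=8)
    lib = synthetic.make_consensus_library(cfg)
    _, _, truth = synthetic.simulate_genome_pair(cfg, lib)
    specific = truth.specific_insertions()
    assert len(specific) == 16
    assert sum(e.strain == "A" for e in specific) == 8
    assert sum(e.strain == "B" for e in specific) == 8


def test_zero_divergence_plants_exact_consensus_substrings():
    cfg = _tiny_cfg(per_copy_divergence=0.0)
    lib = synthetic.make_consensus_library(cfg)
    ga, _, truth = synthetic.simulate_genome_pair(cfg, lib)
    for e in truth.insertions:
        if e.strain not in ("shared", "A"):
            continue
        body = e.rna.rstrip("A") if e.length > cfg.consensus_length else e.rna
        assert body in lib[e.subfamily].sequence
        assert ga[e.elem_start_A : e.elem_start_A + e.length] == e.sequence


def test_planted_blocks_are_removable_at_breakpoint():
    """Removing the leftmost block of length L+tsd from the carrier genome
    restores the other genome locally (the TSD construction)."""
    cfg = _tiny_cfg()
    lib = synthetic.make_consensus_library(cfg)
    ga, gb, truth = synthetic.simulate_genome_pair(cfg, lib)
    for e in truth.specific_insertions()[:5]:
        genome = ga if e.strain == "A" else gb
        start = e.start_A if e.strain == "A" else e.start_B
        bl = e.block_length
        # the target site is duplicated: the block's first tsd bases recur
        # immediately after the block
        assert genome[start : start + e.tsd] == \
            genome[start + bl : start + bl + e.tsd]
        assert genome[start + e.tsd : start + bl] == e.sequence


def test_expression_shares_sum_to_sine_fraction():
    cfg = _tiny_cfg()
    lib = synthetic.make_consensus_library(cfg)
    _, _, truth = synthetic.simulate_genome_pair(cfg, lib)
    total = sum(truth.locus_expression.values())
    assert total == pytest.approx(1 - cfg.frac_5p8S - cfg.frac_5S)


def test_expression_multiplier_coupling_structure():
    cfg = _tiny_cfg(meth_coupling_strength=2.0)
    # CpG-rich: strictly decreasing in methylation level
    rich = [expression_multiplier(m, 7, cfg) for m in (0.0, 0.3, 0.6, 0.9)]
    assert all(a > b for a, b in zip(rich, rich[1:]))
    # planted levels 0.1 vs 0.9 favour the hypomethylated group
    assert expression_multiplier(0.1, 7, cfg) / expression_multiplier(0.9, 7, cfg) > 1
    # CpG-poor attenuated toward 1
    assert expression_multiplier(0.9, 1, cfg) > expression_multiplier(0.9, 7, cfg)
    # no coupling -> flat
    cfg0 = _tiny_cfg(meth_coupling_strength=0.0)
    assert expression_multiplier(0.9, 7, cfg0) == 1.0


def test_read_conservation_and_class_fractions():
    cfg = _tiny_cfg(n_reads=20_000)
    lib = synthetic.make_consensus_library(cfg)
    ga, _, truth = synthetic.simulate_genome_pair(cfg, lib)
    tr, un = synthetic.simulate_mel_reads(cfg, ga, truth)
    assert len(tr) == cfg.n_reads and len(un) == cfg.n_reads
    for frac, cls in ((cfg.frac_5p8S, RESERVED_5P8S), (cfg.frac_5S, RESERVED_5S)):
        n = sum(r.cls == cls for r in tr)
        sd = math.sqrt(cfg.n_reads * frac * (1 - frac))
        assert abs(n - cfg.n_reads * frac) <= 3 * sd
    n_deg = sum(not r.full_length for r in tr)
    sd = math.sqrt(cfg.n_reads * cfg.frac_degraded * (1 - cfg.frac_degraded))
    assert abs(n_deg - cfg.n_reads * cfg.frac_degraded) <= 3 * sd


def test_full_length_reads_end_with_adaptor():
    cfg = _tiny_cfg(frac_degraded=0.0, n_reads=500)
    lib = synthetic.make_consensus_library(cfg)
    ga, _, truth = synthetic.simulate_genome_pair(cfg, lib)
    tr, _ = synthetic.simulate_mel_reads(cfg, ga, truth)
    assert all(r.sequence.endswith(cfg.adaptor3) for r in tr)


def test_pol3_reads_depleted_without_treatment():
    cfg = _tiny_cfg(n_reads=20_000)
    lib = synthetic.make_consensus_library(cfg)
    ga, _, truth = synthetic.simulate_genome_pair(cfg, lib)
    tr, un = synthetic.simulate_mel_reads(cfg, ga, truth)
    frac_5s_tr = sum(r.cls == RESERVED_5S for r in tr) / len(tr)
    frac_5s_un = sum(r.cls == RESERVED_5S for r in un) / len(un)
    # Pol III class strongly enriched by treatment (qualitative direction)
    assert frac_5s_tr > 3 * frac_5s_un


def test_zero_reads_gives_empty_libraries():
    cfg = _tiny_cfg(n_reads=0)
    lib = synthetic.make_consensus_library(cfg)
    ga, _, truth = synthetic.simulate_genome_pair(cfg, lib)
    tr, un = synthetic.simulate_mel_reads(cfg, ga, truth)
    assert tr == [] and un == []


def test_short_adaptor_rejected():
    cfg = _tiny_cfg(adaptor3="ACGTA")
    lib = synthetic.make_consensus_library(cfg)
    ga, _, truth = synthetic.simulate_genome_pair(cfg, lib)
    with pytest.raises(ValueError):
        synthetic.simulate_mel_reads(cfg, ga, truth)


def test_methylation_sampling_matches_planted_levels():
    cfg = _tiny_cfg(meth_depth=25)
    lib = synthetic.make_consensus_library(cfg)
    _, _, truth = synthetic.simulate_genome_pair(cfg, lib)
    cpg = synthetic.simulate_methylation(cfg, truth)
    assert (cpg["methylated"] <= cpg["total"]).all()
    levels = dict()
    for key, sites in truth.locus_cpg_levels.items():
        for pos, lv in sites:
            levels[pos] = lv
    obs = cpg.set_index("position")
    resid = []
    for pos, lv in levels.items():
        row = obs.loc[pos]
        resid.append(row["methylated"] - lv * row["total"])
    # centred residuals: binomial sampling around the planted level
    assert abs(np.mean(resid)) < 1.0


def test_balanced_allelics_without_fold():
    cfg = _tiny_cfg(allelic_fold=1.0, peak_count=3,
                    n_specific_insertions_per_strain=6, genome_length=100_000,
                    n_shared_insertions=20)
    lib = synthetic.make_consensus_library(cfg)
    ga, gb, truth = synthetic.simulate_genome_pair(cfg, lib)
    paa = synthetic.simulate_peaks_and_allelics(cfg, ga, gb, truth)
    ext = paa.snp_counts[paa.snp_counts.region_label == "extension"]
    frac = ext.alleleB_count.sum() / (ext.alleleA_count.sum()
                                      + ext.alleleB_count.sum())
    assert abs(frac - 0.5) < 0.05


def test_no_anchoring_when_fraction_zero():
    cfg = _tiny_cfg(frac_boundary_anchored=0.0, peak_count=5)
    lib = synthetic.make_consensus_library(cfg)
    ga, gb, truth = synthetic.simulate_genome_pair(cfg, lib)
    paa = synthetic.simulate_peaks_and_allelics(cfg, ga, gb, truth)
    assert all(not pt.anchored for pt in truth.peak_truth)
    assert paa.profiles == []


def test_anchor_shortage_raises():
    cfg = _tiny_cfg(n_specific_insertions_per_strain=1, peak_count=6,
                    frac_boundary_anchored=0.5)
    lib = synthetic.make_consensus_library(cfg)
    ga, gb, truth = synthetic.simulate_genome_pair(cfg, lib)
    with pytest.raises(ValueError):
        synthetic.simulate_peaks_and_allelics(cfg, ga, gb, truth)
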