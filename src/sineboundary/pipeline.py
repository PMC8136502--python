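"""End-to-end orchestration of the synthetic run.

``run_all`` executes simulate -> annotate -> scan -> melquant -> methexpr ->
boundary -> allelic on one seeded configuration and writes a JSON report of
per-stage record counts, recovery metrics against the ground truth, and
output checksums. All intervals are 0-based half-open throughout.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np

from . import allelic as allelic_mod
from . import chromatin, evaluate, io, meth_expr, melrna, polymorphism
from . import synthetic
from .config import RunConfig
from .repeat_toolkit import annotate_genome

logger = logging.getLogger("sineboundary")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage(name: str):
    logger.info("[%s] running", name)


def run_all(cfg: RunConfig) -> dict:
    logging.basicConfig(stream=sys.stderr, level=cfg.log_level,
                        format="%(levelname)s %(message)s")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "checksums": {}}

    _stage("simulate")
    lib = synthetic.make_consensus_library(cfg.sim)
    genome_a, genome_b, truth = synthetic.simulate_genome_pair(cfg.sim, lib)
    treated, untreated = synthetic.simulate_mel_reads(cfg.sim, genome_a, truth)
    treated2, _ = synthetic.simulate_mel_reads(cfg.sim, genome_a, truth,
                                               replicate=1)
    cpg_calls = synthetic.simulate_methylation(cfg.sim, truth)
    paa = synthetic.simulate_peaks_and_allelics(
        cfg.sim, genome_a, genome_b, truth,
        window=cfg.profile_window, bin_size=cfg.profile_bin)
    lib.to_fasta(outdir / "library.fa")
    io.write_fasta(outdir / "genomeA.fa", {"chrS": genome_a})
    io.write_fasta(outdir / "genomeB.fa", {"chrS": genome_b})
    io.write_fastq(outdir / "mel_treated.fq", treated)
    io.write_fastq(outdir / "mel_untreated.fq", untreated)
    io.write_cpg_calls(outdir / "cpg_calls.tsv", cpg_calls)
    io.write_bed(outdir / "peaksA.bed", paa.peaks_A)
    io.write_snp_counts(outdir / "snp_counts.tsv", paa.snp_counts)
    report["stages"]["simulate"] = {
        "n_insertions": len(truth.insertions),
        "n_treated_reads": len(treated),
        "n_cpg_sites": int(len(cpg_calls)),
        "n_peaks": len(paa.peaks_A),
        "n_snps": int(len(paa.snp_counts)),
    }

    _stage("annotate")
    hits = annotate_genome(genome_a, lib, contig="chrS")
    sine_hits = [h for h in hits if lib[h.subfamily].family != "rRNA"]
    report["stages"]["annotate"] = {
        "n_hits": len(hits),
        "mean_divergence": float(np.mean([h.divergence for h in hits])) if hits else None,
    }

    _stage("scan")
    calls = polymorphism.scan_genome_pair(
        genome_a, genome_b, lib, min_len=cfg.min_gap_len,
        max_len=cfg.max_gap_len, min_occupancy=cfg.min_occupancy,
        min_flank=cfg.min_flank, min_flank_identity=cfg.min_flank_identity)
    recovery = evaluate.match_scan_calls(calls, truth)
    report["stages"]["scan"] = {
        "n_calls": len(calls),
        "sensitivity": recovery.sensitivity,
        "precision": recovery.precision,
    }

    _stage("melquant")
    records, trim_stats = melrna.trim_filter(treated, cfg.sim.adaptor3)
    counts = melrna.classify_reads(records, lib,
                                   n_discarded=trim_stats.n_no_adaptor
                                   + trim_stats.n_too_short)
    u_records, u_stats = melrna.trim_filter(untreated, cfg.sim.adaptor3)
    u_counts = melrna.classify_reads(u_records, lib,
                                     n_discarded=u_stats.n_no_adaptor
                                     + u_stats.n_too_short)
    contrast = melrna.tap_contrast(counts, u_counts)
    expr1, _ = melrna.map_unique(records, genome_a, sine_hits)
    expr1 = melrna.normalize_rpm(expr1, counts.n_5p8S)
    rec2, st2 = melrna.trim_filter(treated2, cfg.sim.adaptor3)
    cc2 = melrna.classify_reads(rec2, lib,
                                n_discarded=st2.n_no_adaptor + st2.n_too_short)
    expr2, _ = melrna.map_unique(rec2, genome_a, sine_hits)
    expr2 = melrna.normalize_rpm(expr2, cc2.n_5p8S)
    concord = melrna.replicate_concordance(expr1, expr2)
    _, n_below_1, n_above_1000 = melrna.rank_abundance(expr1)
    from .repeat_toolkit import RESERVED_5S
    tap_5s = contrast.get(RESERVED_5S)
    report["stages"]["melquant"] = {
        "n_retained": trim_stats.n_retained,
        "n_discarded": trim_stats.n_no_adaptor + trim_stats.n_too_short,
        "tap_5S_enrichment": tap_5s.ratio if tap_5s else None,
        "locus_concordance_R": concord,
        "n_loci_rpm_below_1": n_below_1,
        "n_loci_rpm_above_1000": n_above_1000,
    }

    _stage("methexpr")
    meths = meth_expr.locus_methylation(cpg_calls, sine_hits, genome=genome_a)
    strata = meth_expr.stratify(meths)
    stratum_table = meth_expr.expression_by_stratum(strata, expr1, expr2)
    stratum_table.to_csv(outdir / "strata.tsv", sep="\t", index=False)
    report["stages"]["methexpr"] = {
        "n_loci_with_level": sum(1 for m in meths if m.mean_level is not None),
        "n_strata": len(strata),
    }

    _stage("boundary")
    peaks = chromatin.PeakSet(paa.peaks_A, summits=paa.summits_A, label="simK9ac")
    profile = chromatin.boundary_profile(
        peaks, sine_hits, len(genome_a), window=cfg.profile_window,
        bin_size=cfg.profile_bin)
    profile.to_frame().to_csv(outdir / "boundary_profile.tsv", sep="\t",
                              index=False)
    summit_table = chromatin.summit_overlap(peaks, sine_hits)
    bound = synthetic.simulate_binding(cfg.sim, truth, effect=0.0)
    bind_table, chi2, pval, direction = chromatin.binding_vs_methylation(
        sine_hits, cpg_calls, bound)
    outside_bin = int(np.argmax(profile.bin_edges[:-1] == -cfg.profile_bin))
    report["stages"]["boundary"] = {
        "boundary_adjacent_enrichment": float(profile.enrichment[outside_bin]),
        "background_density": profile.background,
        "summit_in_repeat_fraction": float(
            1 - summit_table.loc[summit_table["subfamily"] == "outside",
                                 "fraction"].iloc[0]),
        "binding_meth_p": pval,
    }

    _stage("allelic")
    ext_call = allelic_mod.region_allelic_ratio(paa.snp_counts, "extension")
    shifts = []
    for prof in paa.profiles:
        try:
            shift = allelic_mod.locate_boundary_shift(
                prof.coverage_A, prof.coverage_B, prof.bin_edges)
            shifts.append(shift.shifted)
        except allelic_mod.PlateauError:
            shifts.append(False)
    report["stages"]["allelic"] = {
        "extension_fold": ext_call.fold,
        "extension_flag": ext_call.flag,
        "boundary_shift_detected_frac": float(np.mean(shifts)) if shifts else None,
    }

    for f in sorted(outdir.glob("*")):
        if f.is_file():
            report["checksums"][f.name] = _checksum(f)
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    logger.info("run complete: %s", outdir / "report.json")
    return report
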