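"""Per-locus CpG methylation and methylation-stratified expression.

Locus methylation pools read counts over the CpG sites inside the locus
interval (coverage-weighted); loci are then binned jointly by CpG-site
count and methylation level, and expression summaries are compared across
strata. The expected biology on synthetic data: expression decreases with
methylation for CpG-rich loci and the trend is attenuated for CpG-poor
loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .melrna import PSEUDOCOUNT_RPM, LocusExpression

DEFAULT_CPG_BINS = ((0, 2), (3, 5), (6, math.inf))
DEFAULT_METH_BINS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class LocusMethylation:
    locus: tuple  # (contig, start, end, strand)
    n_cpg: int
    covered_cpg: int
    mean_level: float | None  # pooled methylated/total; None when uncovered


@dataclass
class Stratum:
    cpg_bin: tuple
    meth_bin: tuple[float, float]
    loci: list[tuple] = field(default_factory=list)

    @property
    def label(self) -> str:
        hi = "+" if math.isinf(self.cpg_bin[1]) else str(int(self.cpg_bin[1]))
        return (f"cpg{int(self.cpg_bin[0])}-{hi}"
                f"_meth{self.meth_bin[0]:g}-{self.meth_bin[1]:g}")


def locus_methylation(
    cpg_calls: pd.DataFrame,
    loci,
    genome: str | None = None,
) -> list[LocusMethylation]:
    """Pooled methylation per locus.

    ``cpg_calls`` columns: contig, position, methylated, total. ``n_cpg``
    counts CG dinucleotides in the genome when a genome is given, else the
    call rows inside the locus. Loci with zero covered CpGs get level
    ``None`` (undefined, never 0).
    """
    if ((cpg_calls["methylated"] < 0).any()
            or (cpg_calls["methylated"] > cpg_calls["total"]).any()):
        raise ValueError("calls must satisfy 0 <= methylated <= total")
    out = []
    by_contig = {c: g.sort_values("position") for c, g in
                 cpg_calls.groupby("contig")}
    for l in loci:
        key = tuple(l) if not hasattr(l, "q_start") else (
            l.contig, l.q_start, l.q_end, l.strand)
        contig, start, end = key[0], key[1], key[2]
        g = by_contig.get(contig)
        if g is None:
            sub = cpg_calls.iloc[0:0]
        else:
            pos = g["position"].to_numpy()
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            sub = g.iloc[lo:hi]
        covered = int((sub["total"] > 0).sum())
        if genome is not None:
            n_cpg = genome[start:end].upper().count("CG")
        else:
            n_cpg = len(sub)
        total = int(sub["total"].sum())
        level = float(sub["methylated"].sum()) / total if total > 0 else None
        out.append(LocusMethylation(key, n_cpg, covered, level))
    return out


def stratify(
    meths: list[LocusMethylation],
    cpg_bins=DEFAULT_CPG_BINS,
    meth_bins=DEFAULT_METH_BINS,
) -> list[Stratum]:
    """Partition defined-level loci into (CpG-count x methylation) strata.

    Methylation bins are left-closed right-open, except the last which is
    closed at 1. Raises on overlapping CpG bins.
    """
    for i, (lo, hi) in enumerate(cpg_bins):
        for lo2, hi2 in cpg_bins[i + 1 :]:
            if lo <= hi2 and lo2 <= hi:
                raise ValueError("overlapping CpG bins")
    edges = list(meth_bins)
    if edges[0] > 0 or edges[-1] < 1:
        raise ValueError("methylation bins must cover [0, 1]")
    strata = [Stratum(cb, (edges[i], edges[i + 1]))
              for cb in cpg_bins for i in range(len(edges) - 1)]
    for m in meths:
        if m.mean_level is None:
            continue
        for s in strata:
            in_cpg = s.cpg_bin[0] <= m.n_cpg <= s.cpg_bin[1]
            last = s.meth_bin[1] == edges[-1]
            in_meth = (s.meth_bin[0] <= m.mean_level < s.meth_bin[1]) or (
                last and m.mean_level == s.meth_bin[1])
            if in_cpg and in_meth:
                s.loci.append(m.locus)
                break
    return strata


RPM_BIN_EDGES = (1.0, 10.0, 100.0)  # <=1, (1,10], (10,100], >100


def expression_by_stratum(
    strata: list[Stratum],
    rep1: list[LocusExpression],
    rep2: list[LocusExpression],
    pseudocount: float = PSEUDOCOUNT_RPM,
) -> pd.DataFrame:
    """Per-stratum expression summary over two replicate runs.

    Reports the five-number summary of log10(mean rpm + pseudocount), the
    fraction of loci expressed (>=1 uniquely mapped read in either
    replicate), and the fraction of expressed loci per RPM bin.
    """
    e1 = {le.locus: le for le in rep1}
    e2 = {le.locus: le for le in rep2}
    rows = []
    for s in strata:
        rpms, expressed = [], []
        for key in s.loci:
            a, b = e1.get(key), e2.get(key)
            if a is None and b is None:
                continue
            counts = [(x.unique_read_count if x else 0) for x in (a, b)]
            mean_rpm = float(np.mean([(x.rpm if x else 0.0) for x in (a, b)]))
            rpms.append(mean_rpm)
            expressed.append(max(counts) >= 1)
        n = len(rpms)
        n_expr = int(np.sum(expressed)) if n else 0
        log_rpm = np.log10(np.array(rpms) + pseudocount) if n else np.array([])
        expr_rpms = [r for r, e in zip(rpms, expressed) if e]
        e_lo, e_mid, e_hi = RPM_BIN_EDGES
        rpm_bins = {
            "frac_rpm_le1": np.mean([r <= e_lo for r in expr_rpms]) if expr_rpms else np.nan,
            "frac_rpm_1_10": np.mean([e_lo < r <= e_mid for r in expr_rpms]) if expr_rpms else np.nan,
            "frac_rpm_10_100": np.mean([e_mid < r <= e_hi for r in expr_rpms]) if expr_rpms else np.nan,
            "frac_rpm_gt100": np.mean([r > e_hi for r in expr_rpms]) if expr_rpms else np.nan,
        }
        rows.append({
            "stratum": s.label,
            "cpg_lo": s.cpg_bin[0], "cpg_hi": s.cpg_bin[1],
            "meth_lo": s.meth_bin[0], "meth_hi": s.meth_bin[1],
            "n_loci": n,
            "frac_expressed": n_expr / n if n else np.nan,
            "log_rpm_min": log_rpm.min() if n else np.nan,
            "log_rpm_q1": np.percentile(log_rpm, 25) if n else np.nan,
            "log_rpm_median": np.median(log_rpm) if n else np.nan,
            "log_rpm_q3": np.percentile(log_rpm, 75) if n else np.nan,
            "log_rpm_max": log_rpm.max() if n else np.nan,
            **rpm_bins,
        })
    return pd.DataFrame(rows)


def clone_table(locus, clones: list[list[int]]):
    """Bisulfite-PCR clone matrix (rows = clones, columns = CpG sites).

    Returns (matrix, per-CpG column means, locus grand mean)."""
    if not clones:
        raise ValueError("no clones")
    lengths = {len(c) for c in clones}
    if len(lengths) != 1:
        raise ValueError("ragged clone vectors")
    m = np.array(clones, dtype=float)
    if not np.isin(m, (0.0, 1.0)).all():
        raise ValueError("clone vectors must be binary")
    return m, m.mean(axis=0), float(m.mean())
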