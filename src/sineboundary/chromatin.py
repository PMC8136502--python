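"""Repeat density around ChIP-seq peak boundaries, summit/peak overlap
bookkeeping, and binding-vs-methylation stratification.

All intervals are 0-based half-open. A boundary profile aggregates both
edges of every peak on a signed axis oriented *into* the peak (negative =
outside); the end boundary is mirrored so the two edges are comparable.
Density is the base-coverage fraction of the repeat class per bin;
enrichment divides by the genome-wide covered fraction, so uniformly placed
repeats give enrichment 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2_contingency, spearmanr

from .repeat_toolkit import RepeatHit


@dataclass
class PeakSet:
    intervals: list[tuple[str, int, int]]
    summits: list[int] | None = None
    label: str = ""

    def validate(self) -> None:
        for i, (c, s, e) in enumerate(self.intervals):
            if s >= e:
                raise ValueError(f"peak {i}: start {s} >= end {e}")
            if self.summits is not None and not s <= self.summits[i] < e:
                raise ValueError(f"peak {i}: summit outside interval")


def _as_intervals(repeats) -> list[tuple[str, int, int]]:
    out = []
    for r in repeats:
        if isinstance(r, RepeatHit):
            out.append((r.contig or "chrS", r.q_start, r.q_end))
        else:
            out.append((r[0], int(r[1]), int(r[2])))
    return out


class _Coverage:
    """Merged-interval coverage with O(log n) covered-bases queries."""

    def __init__(self, intervals: list[tuple[int, int]]):
        ivs = sorted((s, e) for s, e in intervals if e > s)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        self.starts = np.array([m[0] for m in merged], dtype=np.int64)
        self.ends = np.array([m[1] for m in merged], dtype=np.int64)
        lens = self.ends - self.starts
        self.cum = np.concatenate([[0], np.cumsum(lens)])

    def total(self) -> int:
        return int(self.cum[-1])

    def covered(self, a: int, b: int) -> int:
        """Covered bases within [a, b)."""
        if b <= a:
            return 0
        i = int(np.searchsorted(self.ends, a, side="right"))
        j = int(np.searchsorted(self.starts, b, side="left"))
        if i >= j:
            return 0
        full = int(self.cum[j] - self.cum[i])
        full -= max(0, a - int(self.starts[i]))
        full -= max(0, int(self.ends[j - 1]) - b)
        return full


@dataclass
class BoundaryProfile:
    bin_edges: np.ndarray  # signed offsets, positive = inside the peak
    density: np.ndarray  # covered fraction per bin
    background: float  # genome-wide covered fraction
    enrichment: np.ndarray
    n_boundaries: int
    bin_bases: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_frame(self) -> pd.DataFrame:
        centers = (self.bin_edges[:-1] + self.bin_edges[1:]) / 2
        return pd.DataFrame({
            "bin_center": centers,
            "density": self.density,
            "background": self.background,
            "enrichment": self.enrichment,
        })


def boundary_profile(
    peaks: PeakSet,
    repeats,
    genome_length: int,
    window: int = 2000,
    bin_size: int = 100,
) -> BoundaryProfile:
    """Repeat-class density vs signed distance from peak boundaries.

    For the peak start boundary, offset bin [o, o+bin) maps to genomic
    [start+o, start+o+bin); for the end boundary the axis is mirrored
    ([end-o-bin, end-o)) so positive offsets always point into the peak.
    Bins are clipped at genome edges (clipped bases leave the denominator).
    """
    if window % bin_size:
        raise ValueError("window must be a multiple of bin_size")
    if not peaks.intervals:
        raise ValueError("empty peak set")
    cov = _Coverage([(s, e) for _, s, e in _as_intervals(repeats)])
    edges = np.arange(-window, window + bin_size, bin_size)
    nbins = len(edges) - 1
    covered = np.zeros(nbins)
    bases = np.zeros(nbins)
    for _, start, end in peaks.intervals:
        for i in range(nbins):
            for a, b in (
                (start + edges[i], start + edges[i + 1]),  # start boundary
                (end - edges[i + 1], end - edges[i]),  # end boundary, mirrored
            ):
                a2, b2 = max(0, a), min(genome_length, b)
                if b2 > a2:
                    covered[i] += cov.covered(a2, b2)
                    bases[i] += b2 - a2
    density = np.divide(covered, bases, out=np.zeros(nbins), where=bases > 0)
    background = cov.covered(0, genome_length) / genome_length
    enrichment = density / background if background > 0 else np.full(nbins, np.nan)
    return BoundaryProfile(
        bin_edges=edges, density=density, background=background,
        enrichment=enrichment, n_boundaries=2 * len(peaks.intervals),
        bin_bases=bases,
    )


def summit_overlap(peaks: PeakSet, repeats) -> pd.DataFrame:
    """Count peak summits falling inside repeat copies (half-open:
    start <= summit < end; ties resolved by highest repeat score).

    Returns one row per subfamily plus an 'outside' row, with fractions of
    total summits.
    """
    if peaks.summits is None:
        raise ValueError("peak set has no summits")
    tree = IntervalTree()
    for r in repeats:
        if isinstance(r, RepeatHit):
            tree.addi(r.q_start, r.q_end, (r.subfamily, r.family, r.score))
        else:
            c, s, e = r[0], int(r[1]), int(r[2])
            name = r[3] if len(r) > 3 else "repeat"
            tree.addi(s, e, (name, name, 0.0))
    counts: dict[str, int] = {}
    fams: dict[str, str] = {}
    outside = 0
    for summit in peaks.summits:
        hits = tree[summit]  # intervaltree is half-open: [begin, end)
        if not hits:
            outside += 1
            continue
        best = max(hits, key=lambda iv: (iv.data[2], iv.data[0]))
        sub, fam, _ = best.data
        counts[sub] = counts.get(sub, 0) + 1
        fams[sub] = fam
    total = len(peaks.summits)
    rows = [{"subfamily": s, "family": fams[s], "count": c,
             "fraction": c / total} for s, c in sorted(counts.items())]
    rows.append({"subfamily": "outside", "family": "-", "count": outside,
                 "fraction": outside / total})
    return pd.DataFrame(rows)


@dataclass
class PeakOverlap:
    shared_a: list[tuple[str, int, int]]
    shared_b: list[tuple[str, int, int]]
    a_specific: list[tuple[str, int, int]]
    b_specific: list[tuple[str, int, int]]

    @property
    def n_shared(self) -> int:
        # single-link components containing peaks from both sets would merge
        # chains; the per-set shared counts are reported separately instead
        return len(self.shared_a)


def peak_set_overlap(a: PeakSet, b: PeakSet) -> PeakOverlap:
    """Partition two peak sets by >=1-base interval overlap.

    A peak is 'shared' when it overlaps any peak of the other set; counts
    are reported per set (a chain a1-b1-a2 leaves both a1 and a2 shared),
    which is the pre-merge accounting.
    """
    trees: dict[str, IntervalTree] = {}
    for c, s, e in b.intervals:
        trees.setdefault(c, IntervalTree()).addi(s, e)
    shared_a, a_spec = [], []
    for c, s, e in a.intervals:
        (shared_a if c in trees and trees[c].overlap(s, e) else a_spec).append(
            (c, s, e))
    trees_a: dict[str, IntervalTree] = {}
    for c, s, e in a.intervals:
        trees_a.setdefault(c, IntervalTree()).addi(s, e)
    shared_b, b_spec = [], []
    for c, s, e in b.intervals:
        (shared_b if c in trees_a and trees_a[c].overlap(s, e) else b_spec
         ).append((c, s, e))
    return PeakOverlap(shared_a, shared_b, a_spec, b_spec)


METHYLATED_CPG_LEVEL = 0.5  # a CpG counts as methylated at pooled level >= 0.5


def binding_vs_methylation(
    repeats,
    cpg_calls: pd.DataFrame,
    bound_flags: dict[tuple, bool],
    max_category: int = 6,
) -> tuple[pd.DataFrame, float, float, float]:
    """Stratify repeat copies by their number of methylated CpG sites and
    test association with factor binding.

    Returns (table, chi2, p_value, direction) where direction is the
    Spearman correlation between methylated-CpG count and binding.
    """
    ivs = _as_intervals(repeats)
    pos = cpg_calls["position"].to_numpy()
    level = (cpg_calls["methylated"] / cpg_calls["total"].clip(lower=1)).to_numpy()
    order = np.argsort(pos)
    pos, level = pos[order], level[order]
    # flags may be keyed on intervals that differ slightly from the repeat
    # annotation spans (e.g. trimmed tails): match by overlap, not equality
    flag_tree = IntervalTree()
    for key, flag in bound_flags.items():
        if key[2] > key[1]:
            flag_tree.addi(key[1], key[2], bool(flag))
    xs, ys = [], []
    for r, iv in zip(repeats, ivs):
        lo = np.searchsorted(pos, iv[1], side="left")
        hi = np.searchsorted(pos, iv[2], side="left")
        n_meth = int((level[lo:hi] >= METHYLATED_CPG_LEVEL).sum())
        overlapping = flag_tree.overlap(iv[1], iv[2])
        bound = any(o.data for o in overlapping) if overlapping else False
        xs.append(n_meth)
        ys.append(bound)
    cats = [min(x, max_category) for x in xs]
    df = pd.DataFrame({"meth_cpg": cats, "bound": ys})
    table = (df.groupby("meth_cpg")["bound"]
             .agg(n_bound="sum", n_total="count").reset_index())
    table["n_unbound"] = table["n_total"] - table["n_bound"]
    table["bound_fraction"] = table["n_bound"] / table["n_total"]
    cont = table[["n_bound", "n_unbound"]].to_numpy()
    cont = cont[cont.sum(axis=1) > 0]
    if cont.shape[0] < 2 or cont.sum(axis=0).min() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = chi2_contingency(cont)
    if len(set(xs)) > 1 and len(set(ys)) > 1:
        direction = float(spearmanr(xs, ys).statistic)
    else:
        direction = 0.0
    return table, float(chi2), float(p), direction
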