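"""Allele-specific signal across a polymorphic insertion in F1 hybrids.

SNP-level allelic fractions with Wilson intervals, pooled per-region
allelic ratios (fold reported as free-allele over carrier-allele), and an
operational chromatin-boundary locator: the domain boundary of each allele
is the outermost bin where coverage drops below half the domain plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.proportion import proportion_confint


class PlateauError(ValueError):
    """No detectable coverage plateau in a profile."""


def snp_allelic_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP fraction of allele A with a Wilson 95% CI.

    Zero-coverage SNPs are flagged ``no_data`` rather than dropped.
    Expected columns: contig, position, alleleA_count, alleleB_count (and
    optionally region_label).
    """
    df = counts.copy()
    a = df["alleleA_count"].to_numpy(float)
    b = df["alleleB_count"].to_numpy(float)
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, a / np.maximum(total, 1), np.nan)
    lo, hi = proportion_confint(a, np.maximum(total, 1), alpha=0.05,
                                method="wilson")
    df["total"] = total.astype(int)
    df["fraction_A"] = frac
    df["ci_low"] = np.where(total > 0, lo, np.nan)
    df["ci_high"] = np.where(total > 0, hi, np.nan)
    df["no_data"] = total == 0
    return df


@dataclass
class AllelicCall:
    region: str
    n_snps: int
    count_A: int  # carrier allele
    count_B: int  # insertion-free allele
    fraction_A: float
    ci_low: float  # Wilson 95% CI on fraction_A
    ci_high: float
    fold: float  # count_B / count_A (free over carrier)
    p_value: float
    flag: str  # 'balanced' | 'biased'


def region_allelic_ratio(
    counts: pd.DataFrame,
    region: str,
    alpha: float = 0.01,
    min_fold: float = 1.5,
) -> AllelicCall:
    """Pool SNP counts within ``region`` and test for allelic bias
    (two-sided binomial test against 0.5; biased iff p < alpha and the
    fold change in either direction is >= min_fold)."""
    sub = counts[counts["region_label"] == region]
    if sub.empty:
        raise ValueError(f"region {region!r} has no SNPs")
    ca = int(sub["alleleA_count"].sum())
    cb = int(sub["alleleB_count"].sum())
    total = ca + cb
    if total == 0:
        raise ValueError(f"region {region!r} has no reads")
    frac = ca / total
    lo, hi = proportion_confint(ca, total, alpha=0.05, method="wilson")
    fold = cb / ca if ca > 0 else math.inf
    p = binomtest(ca, total, 0.5).pvalue
    biased = p < alpha and max(fold, 1 / fold if fold > 0 else math.inf) >= min_fold
    return AllelicCall(
        region=region, n_snps=len(sub), count_A=ca, count_B=cb,
        fraction_A=frac, ci_low=float(lo), ci_high=float(hi), fold=fold,
        p_value=float(p), flag="biased" if biased else "balanced",
    )


@dataclass
class BoundaryShift:
    boundary_carrier: int  # signed offset (bp) from the breakpoint
    boundary_free: int
    bin_size: int
    carrier_at_breakpoint: bool  # within +-1 bin of the breakpoint
    free_beyond: bool  # free-allele boundary >= k bins outside
    shift_bins: int

    @property
    def shifted(self) -> bool:
        return self.carrier_at_breakpoint and self.free_beyond


def _half_plateau_boundary(
    coverage: np.ndarray, edges: np.ndarray
) -> tuple[int, float]:
    """Boundary = outer edge of the domain: scanning outward from the peak
    interior (offset 0), the first bin below half the plateau marks it.
    The plateau is the median of the interior (positive-offset) bins."""
    inner = coverage[edges[:-1] >= 0]
    if inner.size == 0:
        raise PlateauError("profile has no interior bins")
    plateau = float(np.median(inner))
    if plateau <= 0:
        raise PlateauError("no detectable plateau (interior median is 0)")
    thr = plateau / 2
    # first interior bin index (left edge >= 0), walk outward (leftward)
    first_inner = int(np.argmax(edges[:-1] >= 0))
    boundary = int(edges[first_inner])
    for i in range(first_inner - 1, -1, -1):
        if coverage[i] < thr:
            boundary = int(edges[i + 1])
            break
        boundary = int(edges[i])
    return boundary, plateau


def locate_boundary_shift(
    profile_carrier: np.ndarray,
    profile_free: np.ndarray,
    bin_edges: np.ndarray,
    min_shift_bins: int = 3,
) -> BoundaryShift:
    """Locate each allele's domain boundary and report whether the carrier
    boundary sits at the insertion breakpoint (offset 0, +-1 bin) while the
    free allele's domain extends at least ``min_shift_bins`` bins beyond.

    Profiles share ``bin_edges``: signed offsets from the breakpoint,
    positive pointing into the chromatin domain.
    """
    edges = np.asarray(bin_edges)
    bin_size = int(edges[1] - edges[0])
    bc, _ = _half_plateau_boundary(np.asarray(profile_carrier, float), edges)
    bf, _ = _half_plateau_boundary(np.asarray(profile_free, float), edges)
    shift_bins = (bc - bf) // bin_size
    return BoundaryShift(
        boundary_carrier=bc,
        boundary_free=bf,
        bin_size=bin_size,
        carrier_at_breakpoint=abs(bc) <= bin_size,
        free_beyond=(bc - bf) >= min_shift_bins * bin_size,
        shift_bins=int(shift_bins),
    )
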