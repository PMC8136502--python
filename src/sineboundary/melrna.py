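"""Quantification of full-length medium-length RNAs (the computational half
of melRNA-seq).

Only reads that still contain the 3' adaptor represent complete molecules
(5' to 3'), so the adaptor filter doubles as a full-length filter. Counts
are normalised as RPM = reads per million 5.8S-surrogate reads: the 5.8S
rRNA carries a ligatable 5' monophosphate regardless of enzymatic 5'-end
treatment and therefore serves as the internal control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kmers import KmerIndex, kmer_codes
from .alignment import revcomp
from .repeat_toolkit import (
    RESERVED_5P8S,
    ConsensusLibrary,
    RepeatHit,
    classify_sequence,
)

MIN_TRIMMED_LEN = 20  # below this, unique exact mapping is meaningless


class NormalizationError(ValueError):
    pass


@dataclass
class ReadRecord:
    id: str
    sequence: str
    adaptor_found: bool
    trimmed_sequence: str


@dataclass
class TrimStats:
    n_input: int = 0
    n_retained: int = 0
    n_no_adaptor: int = 0
    n_too_short: int = 0

    def conserved(self) -> bool:
        return self.n_retained + self.n_no_adaptor + self.n_too_short == self.n_input


def trim_filter(
    reads,
    adaptor3: str,
    min_overlap: int = 8,
    min_len: int = MIN_TRIMMED_LEN,
) -> tuple[list[ReadRecord], TrimStats]:
    """Retain reads containing the 3' adaptor and trim at its start.

    The adaptor must occur exactly (internal match), or an adaptor *prefix*
    of >= ``min_overlap`` bases must terminate the read (the molecule ended
    inside the adaptor). Trimmed sequences shorter than ``min_len`` are
    dropped separately.
    """
    if len(adaptor3) < min_overlap:
        raise ValueError("adaptor shorter than min_overlap")
    stats = TrimStats()
    out: list[ReadRecord] = []
    for read in reads:
        rid, seq = (read.id, read.sequence) if hasattr(read, "sequence") else read
        stats.n_input += 1
        idx = seq.find(adaptor3)
        if idx == -1:
            # adaptor prefix at the read end
            max_l = min(len(adaptor3) - 1, len(seq))
            for l in range(max_l, min_overlap - 1, -1):
                if seq.endswith(adaptor3[:l]):
                    idx = len(seq) - l
                    break
        if idx == -1:
            stats.n_no_adaptor += 1
            continue
        trimmed = seq[:idx]
        if len(trimmed) < min_len:
            stats.n_too_short += 1
            continue
        stats.n_retained += 1
        out.append(ReadRecord(rid, seq, True, trimmed))
    return out, stats


@dataclass
class ClassCounts:
    counts: dict[str, int] = field(default_factory=dict)
    family_counts: dict[str, int] = field(default_factory=dict)
    n_total: int = 0
    n_adaptorless_discarded: int = 0
    n_unclassified: int = 0

    @property
    def n_5p8S(self) -> int:
        return self.counts.get(RESERVED_5P8S, 0)

    def conserved(self) -> bool:
        return (self.n_adaptorless_discarded + sum(self.counts.values())
                + self.n_unclassified == self.n_total)


def classify_reads(
    records: list[ReadRecord],
    lib: ConsensusLibrary,
    min_score: float = 20.0,
    n_discarded: int = 0,
) -> ClassCounts:
    """Assign each trimmed read to its best library entry (or
    'unclassified'). Identical sequences are classified once and the result
    broadcast -- synthetic full-length reads deduplicate heavily."""
    if not lib.entries:
        raise ValueError("empty consensus library")
    cc = ClassCounts(n_total=len(records) + n_discarded,
                     n_adaptorless_discarded=n_discarded)
    uniq: dict[str, int] = {}
    for r in records:
        uniq[r.trimmed_sequence] = uniq.get(r.trimmed_sequence, 0) + 1
    for seq, mult in uniq.items():
        hit = classify_sequence(seq, lib, min_score=min_score)
        if hit is None:
            cc.n_unclassified += mult
            continue
        cc.counts[hit.subfamily] = cc.counts.get(hit.subfamily, 0) + mult
        fam = lib[hit.subfamily].family
        cc.family_counts[fam] = cc.family_counts.get(fam, 0) + mult
    return cc


@dataclass
class LocusExpression:
    locus: tuple  # (contig, start, end, strand)
    unique_read_count: int
    rpm: float = float("nan")


@dataclass
class MapStats:
    n_unique: int = 0
    n_multi: int = 0
    n_unmapped: int = 0
    n_outside_loci: int = 0  # uniquely mapped but not in any annotated locus


def map_unique(
    records: list[ReadRecord],
    genome: str,
    loci: list[RepeatHit] | list[tuple],
    contig: str = "chrS",
    index_k: int = MIN_TRIMMED_LEN,
) -> tuple[list[LocusExpression], MapStats]:
    """Exact, unique, zero-mismatch locus mapping.

    A read contributes iff its trimmed sequence occurs at exactly one
    genomic position over both strands; counts aggregate per annotated
    repeat locus (>= 1 base overlap with the occurrence span).
    """
    genome = genome.upper()
    index = KmerIndex(genome, index_k)

    ivs = []
    for l in loci:
        if isinstance(l, RepeatHit):
            ivs.append((l.q_start, l.q_end, (l.contig or contig, l.q_start,
                                             l.q_end, l.strand)))
        else:
            start, end = l[1], l[2]
            ivs.append((start, end, tuple(l)))
    ivs.sort()
    starts = np.array([a for a, _, _ in ivs], dtype=np.int64)
    ends = np.array([b for _, b, _ in ivs], dtype=np.int64)

    def occurrences(seq: str) -> list[int]:
        out = []
        for s, sign in ((seq, 1), (revcomp(seq), -1)):
            codes, valid = kmer_codes(s[:index_k], index_k)
            if len(codes) == 0 or not valid[0]:
                continue
            for p in index.lookup(int(codes[0])):
                p = int(p)
                if genome[p : p + len(s)] == s:
                    out.append(p)
        return out

    counts: dict[tuple, int] = {}
    stats = MapStats()
    uniq: dict[str, int] = {}
    for r in records:
        uniq[r.trimmed_sequence] = uniq.get(r.trimmed_sequence, 0) + 1
    for seq, mult in uniq.items():
        occ = occurrences(seq)
        if len(occ) == 0:
            stats.n_unmapped += mult
            continue
        if len(occ) > 1:
            stats.n_multi += mult
            continue
        p = occ[0]
        stats.n_unique += mult
        j = np.searchsorted(ends, p, side="right")
        if j < len(starts) and starts[j] < p + len(seq):
            key = ivs[j][2]
            counts[key] = counts.get(key, 0) + mult
        else:
            stats.n_outside_loci += mult
    expressions = [LocusExpression(iv[2], counts.get(iv[2], 0)) for iv in ivs]
    return expressions, stats


def normalize_rpm(counts_or_loci, n_5p8S: int):
    """RPM = count / n_5.8S x 1e6; invariant under uniform depth scaling."""
    if n_5p8S <= 0:
        raise NormalizationError("no 5.8S reads: cannot normalize")
    scale = 1e6 / n_5p8S
    if isinstance(counts_or_loci, dict):
        return {k: v * scale for k, v in counts_or_loci.items()}
    out = []
    for le in counts_or_loci:
        out.append(LocusExpression(le.locus, le.unique_read_count,
                                   le.unique_read_count * scale))
    return out


@dataclass
class TapRatio:
    ratio: float  # math.inf when untreated normalized count is 0
    undefined: bool = False


def tap_contrast(treated: ClassCounts, untreated: ClassCounts) -> dict[str, TapRatio]:
    """Per-class enrichment of the treated over the untreated library,
    each normalised by its own 5.8S count."""
    if treated.n_5p8S <= 0 or untreated.n_5p8S <= 0:
        raise NormalizationError("both libraries need 5.8S reads")
    out: dict[str, TapRatio] = {}
    for name in set(treated.counts) | set(untreated.counts):
        ct = treated.counts.get(name, 0) / treated.n_5p8S
        cu = untreated.counts.get(name, 0) / untreated.n_5p8S
        if ct == 0 and cu == 0:
            out[name] = TapRatio(float("nan"), undefined=True)
        elif cu == 0:
            out[name] = TapRatio(math.inf, undefined=True)
        else:
            out[name] = TapRatio(ct / cu)
    return out


PSEUDOCOUNT_RPM = 0.5  # half-unit continuity correction for log correlations


def replicate_concordance(run_a, run_b, pseudocount: float = PSEUDOCOUNT_RPM):
    """Pearson correlation of log10(rpm + pseudocount) over the label union.

    Accepts dicts label->rpm or lists of :class:`LocusExpression`. Returns
    ``None`` on degenerate (zero-variance) input.
    """

    def as_dict(run) -> dict:
        if isinstance(run, dict):
            return run
        return {le.locus: le.rpm for le in run}

    a, b = as_dict(run_a), as_dict(run_b)
    labels = sorted(set(a) | set(b), key=str)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    xa = np.log10(np.array([a.get(l, 0.0) for l in labels]) + pseudocount)
    xb = np.log10(np.array([b.get(l, 0.0) for l in labels]) + pseudocount)
    if xa.std() == 0 or xb.std() == 0:
        return None
    return float(np.corrcoef(xa, xb)[0, 1])


def rank_abundance(expressions: list[LocusExpression]):
    """Descending rank-abundance table plus the counts of loci below 1 RPM
    and above 1000 RPM (strict thresholds)."""
    import pandas as pd

    rpms = sorted((le.rpm for le in expressions), reverse=True)
    table = pd.DataFrame({
        "rank": np.arange(1, len(rpms) + 1),
        "rpm": rpms,
    })
    n_below_1 = sum(1 for r in rpms if r < 1.0)
    n_above_1000 = sum(1 for r in rpms if r > 1000.0)
    return table, n_below_1, n_above_1000
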