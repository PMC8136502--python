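"""Repeat-library classification and annotation.

Simplified, fully testable stand-ins for the RepeatMasker-style steps of the
pipeline: local alignment of a sequence against a consensus library (both
strands), seeded whole-genome annotation, and majority-rule consensus
rebuilding. Divergence counts substitutions plus gap *events* (one per gap,
irrespective of length) per aligned site, close to the Kimura-style
treatment repeat annotators report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import (
    CLASSIFY_SCORING,
    AlignScoring,
    global_align,
    local_align,
    local_align_score,
    revcomp,
)
from ._kmers import kmer_codes

RESERVED_5P8S = "rRNA_5.8S"
RESERVED_5S = "rRNA_5S"
RESERVED_NAMES = (RESERVED_5P8S, RESERVED_5S)

#: Tie-break order for age classes (younger preferred, mirroring the
#: re-annotation preference for recently active subfamilies).
_AGE_RANK = {"young": 0, "intermediate": 1, "old": 2, "rRNA": 3, "na": 4}

#: Minimum reportable local alignment score; suppresses chance hits on a
#: uniform background (see the false-positive test).
DEFAULT_MIN_SCORE = 20.0


@dataclass(frozen=True)
class LibraryEntry:
    name: str
    sequence: str
    family: str
    age_class: str

    @property
    def cpg_count(self) -> int:
        return self.sequence.count("CG")


@dataclass
class ConsensusLibrary:
    entries: dict[str, LibraryEntry] = field(default_factory=dict)

    def add(self, name: str, sequence: str, family: str, age_class: str) -> None:
        if name in self.entries:
            raise ValueError(f"duplicate library entry {name!r}")
        sequence = sequence.upper()
        if not sequence or set(sequence) - set("ACGTN"):
            raise ValueError(f"entry {name!r}: empty or non-ACGTN sequence")
        self.entries[name] = LibraryEntry(name, sequence, family, age_class)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> LibraryEntry:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def sine_entries(self) -> list[LibraryEntry]:
        """Repeat entries, excluding the reserved rRNA surrogates."""
        return [e for n, e in self.entries.items() if n not in RESERVED_NAMES]

    def names(self) -> list[str]:
        return list(self.entries)

    # FASTA with `name|family|age_class` headers
    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries.values():
                fh.write(f">{e.name}|{e.family}|{e.age_class}\n{e.sequence}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ConsensusLibrary":
        from .io import read_fasta

        lib = cls()
        for header, seq in read_fasta(path).items():
            parts = header.split("|")
            name = parts[0]
            family = parts[1] if len(parts) > 1 else "na"
            age = parts[2] if len(parts) > 2 else "na"
            lib.add(name, seq, family, age)
        return lib


@dataclass
class RepeatHit:
    query_id: str
    subfamily: str
    q_start: int
    q_end: int
    strand: str
    divergence: float
    occupancy: float
    score: float
    family: str = ""
    contig: str = ""

    @property
    def span(self) -> int:
        return self.q_end - self.q_start


def _hit_sort_key(lib: ConsensusLibrary, name: str) -> tuple:
    entry = lib[name]
    return (_AGE_RANK.get(entry.age_class, 9), name)


def classify_sequence(
    seq: str,
    lib: ConsensusLibrary,
    min_score: float = DEFAULT_MIN_SCORE,
    scoring: AlignScoring = CLASSIFY_SCORING,
    query_id: str = "",
    candidates: list[str] | None = None,
) -> RepeatHit | None:
    """Best local-alignment hit of ``seq`` against the library, both strands.

    Ties at equal score are broken by younger age class first, then by name.
    Returns ``None`` when the best score is below ``min_score``.
    """
    if not lib.entries:
        raise ValueError("empty consensus library")
    if len(seq) < 20:
        return None
    seq = seq.upper()
    names = candidates if candidates is not None else lib.names()
    best: tuple[float, tuple, str, str] | None = None  # (-score, tiekey)
    for name in names:
        entry = lib[name]
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            score = local_align_score(s, entry.sequence, scoring)
            key = (score, _hit_sort_key(lib, name))
            if best is None or score > best[0] or (
                score == best[0] and key[1] < best[1]
            ):
                best = (score, key[1], name, strand)
    score, _, name, strand = best
    if score < min_score:
        return None
    s = seq if strand == "+" else revcomp(seq)
    hit_aln = local_align(s, lib[name].sequence, scoring)
    cols, mism, gaps = hit_aln.stats(s, lib[name].sequence)
    divergence = (mism + gaps) / cols if cols else 0.0
    if strand == "+":
        q_start, q_end = hit_aln.q_start, hit_aln.q_end
    else:
        q_start, q_end = len(seq) - hit_aln.q_end, len(seq) - hit_aln.q_start
    return RepeatHit(
        query_id=query_id,
        subfamily=name,
        q_start=q_start,
        q_end=q_end,
        strand=strand,
        divergence=divergence,
        occupancy=(q_end - q_start) / len(seq),
        score=score,
        family=lib[name].family,
    )


def annotate_genome(
    genome: str,
    lib: ConsensusLibrary,
    contig: str = "chrS",
    seed_k: int = 12,
    min_score: float = DEFAULT_MIN_SCORE,
    cluster_gap: int = 150,
    margin: int = 60,
) -> list[RepeatHit]:
    """Seeded whole-genome repeat scan.

    Genome positions sharing an exact ``seed_k``-mer with any library entry
    (either strand) are clustered into candidate windows, each window is
    classified by local alignment, and overlapping hits are resolved by
    score (higher wins).
    """
    if not genome:
        return []
    genome = genome.upper()
    lib_codes = []
    max_len = 0
    for e in lib.entries.values():
        max_len = max(max_len, len(e.sequence))
        for s in (e.sequence, revcomp(e.sequence)):
            codes, valid = kmer_codes(s, seed_k)
            lib_codes.append(codes[valid])
    lib_set = np.unique(np.concatenate(lib_codes))
    gcodes, gvalid = kmer_codes(genome, seed_k)
    hit_mask = np.isin(gcodes, lib_set) & gvalid
    positions = np.nonzero(hit_mask)[0]
    if positions.size == 0:
        return []
    # cluster seed positions into windows
    breaks = np.nonzero(np.diff(positions) > cluster_gap)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [positions.size - 1]])
    hits: list[RepeatHit] = []
    for a, b in zip(starts, ends):
        w0 = max(0, int(positions[a]) - margin)
        w1 = min(len(genome), int(positions[b]) + seed_k + margin)
        window = genome[w0:w1]
        hit = classify_sequence(window, lib, min_score=min_score)
        if hit is None:
            continue
        hit.q_start += w0
        hit.q_end += w0
        hit.contig = contig
        hit.query_id = contig
        hits.append(hit)
    # resolve overlaps, higher score wins; deterministic order
    hits.sort(key=lambda h: (-h.score, h.q_start, h.subfamily))
    kept: list[RepeatHit] = []
    for h in hits:
        if all(h.q_end <= k.q_start or h.q_start >= k.q_end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.q_start)
    return kept


def build_consensus(copies: list[str], anchor: str) -> str:
    """Majority-rule consensus over ``copies`` pairwise-aligned to ``anchor``.

    Per anchor column the majority symbol over aligned copies is emitted;
    base ties resolve in A<C<G<T order; columns where the gap symbol holds a
    strict majority are dropped. Insertions relative to the anchor are
    ignored (the anchor defines the column space).
    """
    if len(copies) < 2:
        raise ValueError("need at least 2 copies")
    if not anchor:
        raise ValueError("empty anchor")
    counts = np.zeros((len(anchor), 5), dtype=np.int64)  # A C G T gap
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for copy in copies:
        aln = global_align(copy.upper(), anchor, CLASSIFY_SCORING)
        qi = si = 0
        for op, n in aln.ops:
            if op == "M":
                for j in range(n):
                    idx = base_idx.get(copy[qi + j].upper())
                    if idx is not None:
                        counts[si + j, idx] += 1
                qi += n
                si += n
            elif op == "D":  # copy insertion relative to anchor: ignored
                qi += n
            else:  # I: anchor columns unmatched in this copy -> gap votes
                counts[si : si + n, 4] += 1
                si += n
    out = []
    for col in counts:
        best_base = int(np.argmax(col[:4]))  # argmax takes first on ties: A<C<G<T
        if col[4] > col[best_base]:
            continue  # gap majority: drop column
        out.append("ACGT"[best_base])
    return "".join(out)
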