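"""File I/O for the pipeline's interchange formats.

FASTA/FASTQ go through Biopython; interval files are plain BED (0-based
half-open) or narrowPeak (summit = start + 10th-column offset); methylation
calls and SNP allele counts are simple TSV schemas. Sequences are
uppercased on read. Malformed records raise with the offending record/line
identified.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from io import StringIO
from pathlib import Path

import pandas as pd
from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylo import Tree, TreeNode

CPG_COLUMNS = ["contig", "position", "methylated", "total"]
SNP_COLUMNS = ["contig", "position", "alleleA_count", "alleleB_count",
               "region_label"]


# --- FASTA / FASTQ ---------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.description] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            out.append((rec.id, str(rec.seq).upper()))
    except ValueError as exc:
        raise ValueError(
            f"{path}: malformed FASTQ after record {len(out)}: {exc}"
        ) from exc
    return out


def write_fastq(path: str | Path, reads, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for read in reads:
            rid, seq = (read.id, read.sequence) if hasattr(read, "sequence") \
                else read
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


# --- BED / narrowPeak ------------------------------------------------------


def read_bed(path: str | Path, min_cols: int = 3) -> list[tuple]:
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise ValueError(f"{path}:{lineno}: expected >= {min_cols} columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            rows.append((parts[0], start, end, *parts[3:]))
    return rows


def write_bed(path: str | Path, rows) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_narrowpeak(path: str | Path) -> tuple[list[tuple[str, int, int]], list[int]]:
    """Returns (intervals, summit positions); summit offset -1 maps to the
    interval midpoint."""
    intervals, summits = [], []
    for row in read_bed(path, min_cols=10):
        contig, start, end = row[0], row[1], row[2]
        offset = int(row[9])
        intervals.append((contig, start, end))
        summits.append(start + offset if offset >= 0 else (start + end) // 2)
    return intervals, summits


# --- TSV schemas -----------------------------------------------------------


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_cpg_calls(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, CPG_COLUMNS)
    if (df["methylated"] > df["total"]).any() or (df["methylated"] < 0).any():
        bad = df.index[(df["methylated"] > df["total"]) | (df["methylated"] < 0)][0]
        raise ValueError(f"{path}: methylated > total at row {bad + 2}")
    return df


def write_cpg_calls(path: str | Path, df: pd.DataFrame) -> None:
    df[CPG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_snp_counts(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, SNP_COLUMNS)


def write_snp_counts(path: str | Path, df: pd.DataFrame) -> None:
    df[SNP_COLUMNS].to_csv(path, sep="\t", index=False)


# --- Newick ----------------------------------------------------------------


def write_newick(path: str | Path, tree: Tree) -> None:
    Path(path).write_text(tree.newick() + "\n")


def read_newick(path_or_text: str | Path) -> Tree:
    text = Path(path_or_text).read_text() if str(path_or_text).strip()[-1] != ";" \
        else str(path_or_text)
    clade_tree = Phylo.read(StringIO(text), "newick")

    def convert(clade) -> tuple[TreeNode, float]:
        if not clade.clades:
            return TreeNode(name=clade.name), clade.branch_length or 0.0
        node = TreeNode(name=clade.name)
        node.children = [convert(c) for c in clade.clades]
        return node, clade.branch_length or 0.0

    root, _ = convert(clade_tree.root)
    return Tree(root=root)


# --- JSON truth / reports --------------------------------------------------


def write_json(path: str | Path, obj) -> None:
    def default(o):
        try:
            return asdict(o)
        except TypeError:
            if hasattr(o, "tolist"):
                return o.tolist()
            return str(o)

    Path(path).write_text(json.dumps(obj, indent=1, default=default))
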