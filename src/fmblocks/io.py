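"""Shared genomic file I/O and interval containers.

Coordinates are 0-based half-open everywhere in memory; BED files are read
as-is, VCF positions are converted from 1-based on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree


def read_genome(path) -> dict[str, str]:
    """Read a FASTA into a dict chrom -> uppercase sequence string."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class GenomicIntervals:
    """A set of labelled genomic intervals with fast overlap queries."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple]) -> "GenomicIntervals":
        """Build from (chrom, start, end[, label]) tuples."""
        obj = cls()
        for t in tuples:
            chrom, start, end = t[0], int(t[1]), int(t[2])
            label = t[3] if len(t) > 3 else None
            obj.add(chrom, start, end, label)
        return obj

    @classmethod
    def from_bed(cls, path) -> "GenomicIntervals":
        """Read BED3+ (4th column, when present, becomes the interval label)."""
        obj = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed BED line: {line!r}")
                label = parts[3] if len(parts) > 3 else None
                obj.add(parts[0], int(parts[1]), int(parts[2]), label)
        return obj

    def add(self, chrom: str, start: int, end: int, label=None) -> None:
        if end <= start:
            return
        self.trees.setdefault(chrom, IntervalTree()).addi(start, end, label)

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())

    def __iter__(self) -> Iterator[tuple[str, int, int, object]]:
        for chrom in sorted(self.trees):
            for iv in sorted(self.trees[chrom]):
                yield chrom, iv.begin, iv.end, iv.data

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def contains_point(self, chrom: str, pos: int) -> bool:
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.at(pos))

    def at(self, chrom: str, pos: int) -> list:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [(iv.begin, iv.end, iv.data) for iv in sorted(tree.at(pos))]

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [(iv.begin, iv.end, iv.data) for iv in sorted(tree.overlap(start, end))]

    def flanked(self, flank: int) -> "GenomicIntervals":
        """A copy with ``flank`` bp added on each side (clipped at 0)."""
        out = GenomicIntervals()
        for chrom, start, end, label in self:
            out.add(chrom, max(0, start - flank), end + flank, label)
        return out

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, label in self:
                if label is None:
                    fh.write(f"{chrom}\t{start}\t{end}\n")
                else:
                    fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def read_expression(matrix_path, groups_path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a genes-by-samples expression TSV plus a sample->group map.

    The group file is two tab-separated columns: sample id, then 'tumor' or
    'normal'.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups = pd.read_csv(
        groups_path, sep="\t", header=None, names=["sample", "group"], index_col=0
    )["group"]
    missing = [s for s in mat.columns if s not in groups.index]
    if missing:
        raise ValueError(f"samples missing from group file: {missing}")
    bad = set(groups.unique()) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return mat, groups.loc[mat.columns]


def read_annotation(path) -> pd.DataFrame:
    """Read a BED6-style gene annotation into chrom/strand/tss/tes columns.

    Columns: chrom, start, end, gene, score, strand.  TSS/TES are inferred
    from the strand: on '+' the TSS is ``start`` and the TES ``end - 1``; on
    '-' the TSS is ``end - 1`` and the TES ``start`` (0-based base positions).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene", "score", "strand"],
        dtype={"chrom": str, "gene": str, "strand": str},
    )
    plus = df["strand"] == "+"
    df["tss"] = df["end"] - 1
    df.loc[plus, "tss"] = df.loc[plus, "start"]
    df["tes"] = df["start"]
    df.loc[plus, "tes"] = df.loc[plus, "end"] - 1
    return df.set_index("gene", drop=False)
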