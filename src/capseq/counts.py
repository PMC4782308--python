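"""Strand-specific per-position counting of read 5' ends and RRS normalization.

The relative read score (RRS) of a position is its 5'-end read count Rns
normalized to the library's total mapped reads Rt:

    RRS = (Rns / Rt) * 1e6

so RRS values sum to 1e6 over each library, and an RRS is directly a
"reads per million 5' ends" strength measure for the position.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .io import AlignedRead, EmptyDataError, InputFormatError

Key = tuple[str, int, str]  # (reference, 1-based position, strand)


@dataclass
class FivePrimeCountTable:
    """Per-(reference, position, strand) 5'-end counts for one library."""

    library_id: str
    counts: dict[Key, int] = field(default_factory=dict)
    rrs: dict[Key, float] = field(default_factory=dict)
    total_mapped: int = 0

    def __len__(self) -> int:
        return len(self.counts)

    def rrs_at(self, key: Key) -> float:
        return self.rrs.get(key, 0.0)

    def items(self) -> Iterator[tuple[Key, int]]:
        return iter(self.counts.items())

    def restrict(self, reference: str) -> "FivePrimeCountTable":
        """Sub-table for one reference; Rt restricted to that reference."""
        counts = {k: c for k, c in self.counts.items() if k[0] == reference}
        t = FivePrimeCountTable(self.library_id, counts, total_mapped=sum(counts.values()))
        if self.rrs:
            compute_rrs(t)
        return t


def extract_five_prime_ends(
    reads: Iterable[AlignedRead], library_id: str = ""
) -> FivePrimeCountTable:
    """Accumulate read 5' ends into a count table.

    The 5' end of a plus-strand read is its leftmost aligned base, of a
    minus-strand read its rightmost aligned base. Rt is the number of
    contributing reads.
    """
    counts: dict[Key, int] = {}
    n = 0
    for r in reads:
        pos = r.aligned_start if r.strand == "+" else r.aligned_end
        key = (r.reference, pos, r.strand)
        counts[key] = counts.get(key, 0) + 1
        n += 1
    return FivePrimeCountTable(library_id, counts, total_mapped=n)


def compute_rrs(table: FivePrimeCountTable) -> FivePrimeCountTable:
    """Fill the table's RRS values in place; requires a non-empty library."""
    if table.total_mapped <= 0:
        raise EmptyDataError(f"empty library {table.library_id!r}: Rt = 0")
    scale = 1e6 / table.total_mapped
    table.rrs = {k: c * scale for k, c in table.counts.items()}
    return table


def merge_tables(
    a: FivePrimeCountTable, b: FivePrimeCountTable, library_id: str = ""
) -> FivePrimeCountTable:
    """Sum two count tables (counts add, Rt adds); RRS left unfilled."""
    counts = dict(a.counts)
    for k, c in b.counts.items():
        counts[k] = counts.get(k, 0) + c
    return FivePrimeCountTable(library_id, counts, total_mapped=a.total_mapped + b.total_mapped)


def write_counts_tsv(table: FivePrimeCountTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# library_id={table.library_id}\ttotal_mapped={table.total_mapped}\n")
        fh.write("reference\tposition\tstrand\tcount\trrs\n")
        for (ref, pos, strand) in sorted(table.counts):
            c = table.counts[(ref, pos, strand)]
            r = table.rrs.get((ref, pos, strand), 0.0)
            fh.write(f"{ref}\t{pos}\t{strand}\t{c}\t{r:.6f}\n")


def read_counts_tsv(path: str | os.PathLike) -> FivePrimeCountTable:
    table = FivePrimeCountTable("")
    with open(path) as fh:
        header = fh.readline()
        if header.startswith("#"):
            meta = dict(
                item.split("=", 1) for item in header[1:].strip().split("\t") if "=" in item
            )
            table.library_id = meta.get("library_id", "")
            table.total_mapped = int(meta.get("total_mapped", 0))
            fh.readline()  # column header
        for ln, line in enumerate(fh, 3):
            line = line.strip()
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 5:
                raise InputFormatError(f"{path}:{ln}: expected 5 columns")
            key = (f[0], int(f[1]), f[2])
            table.counts[key] = int(f[3])
            table.rrs[key] = float(f[4])
    if table.total_mapped == 0:
        table.total_mapped = sum(table.counts.values())
    return table
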