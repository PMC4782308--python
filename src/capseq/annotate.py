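"""Genomic-context classification of TSS and the positional statistics
derived from it: intergenic vs intragenic (sense/antisense), position within
the host gene, codon-frame preference, leaderless transcripts, internal
in-frame start codons, and the read-per-feature distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .calling import TssRecord
from .io import AlignedRead, GeneModel, GenomeSequence

INTERGENIC = "intergenic"
SENSE = "intragenic_sense"
ANTISENSE = "intragenic_antisense"


@dataclass
class ClassifiedTss:
    tss: TssRecord
    context: str
    host_gene: str | None = None
    relative_position: float | None = None
    codon_position: int | None = None
    is_leaderless: bool = False
    is_internal_inframe_start: bool = False


class GeneIndex:
    """Interval lookup over an annotation, split by feature role.

    Context classification uses gene-level intervals (any non-CDS duplicate
    of a CDS feature counts as the gene); the codon frame always comes from
    a CDS feature.
    """

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._tree: dict[str, IntervalTree] = {}
        self._cds_tree: dict[str, IntervalTree] = {}
        self._starts: dict[tuple[str, str], set[int]] = {}
        seen: set[tuple] = set()
        for g in genes:
            ident = (g.reference, g.start, g.end, g.strand)
            if g.feature_class == "CDS":
                self._cds_tree.setdefault(g.reference, IntervalTree()).addi(
                    g.start, g.end + 1, g
                )
            if ident in seen:
                continue  # gene + CDS rows over the same interval: index once
            seen.add(ident)
            self._tree.setdefault(g.reference, IntervalTree()).addi(g.start, g.end + 1, g)
            self._starts.setdefault((g.reference, g.strand), set()).add(g.five_prime)

    def overlapping(self, reference: str, position: int) -> list[GeneModel]:
        tree = self._tree.get(reference)
        return [iv.data for iv in tree[position]] if tree else []

    def overlapping_cds(self, reference: str, position: int) -> list[GeneModel]:
        tree = self._cds_tree.get(reference)
        return [iv.data for iv in tree[position]] if tree else []

    def is_gene_start(self, reference: str, position: int, strand: str) -> bool:
        return position in self._starts.get((reference, strand), ())


def relative_position(position: int, gene: GeneModel) -> float:
    """Fractional position within the gene, 0 at its 5' end, 1 at its 3' end."""
    if gene.end == gene.start:
        return 0.0
    if gene.strand == "+":
        return (position - gene.start) / (gene.end - gene.start)
    return (gene.end - position) / (gene.end - gene.start)


def codon_position(position: int, cds: GeneModel) -> int:
    """Codon phase {1,2,3} of a position, indexed on the CDS coding strand.

    The host CDS frame is used regardless of the TSS strand, so antisense
    TSS are also expressed relative to the host codon.
    """
    if not cds.start <= position <= cds.end:
        raise ValueError(f"position {position} outside CDS {cds.gene_id}")
    if cds.strand == "+":
        return (position - cds.start) % 3 + 1
    return (cds.end - position) % 3 + 1


def detect_leaderless(tss: TssRecord, index: GeneIndex, window: int = 0) -> bool:
    """A TSS is leaderless when it coincides with an annotated gene start
    on the same strand (exact coordinate by default; ``window`` relaxes)."""
    if window == 0:
        return index.is_gene_start(tss.reference, tss.position, tss.strand)
    starts = index._starts.get((tss.reference, tss.strand), ())
    return any(abs(s - tss.position) <= window for s in starts)


def detect_internal_inframe_start(
    tss: TssRecord, host_cds: GeneModel, genome: GenomeSequence
) -> bool:
    """True when a sense intragenic TSS sits on the first base of an
    internal in-frame ATG codon (a putative truncated-protein start)."""
    if codon_position(tss.position, host_cds) != 1:
        return False
    if tss.position == host_cds.five_prime:
        return False  # the annotated start codon itself
    if host_cds.strand == "+":
        codon = genome.subseq(tss.position, tss.position + 2, "+")
    else:
        codon = genome.subseq(tss.position - 2, tss.position, "-")
    return codon == "ATG"


def classify_context(
    tss: TssRecord,
    index: GeneIndex,
    genome: GenomeSequence | None = None,
) -> ClassifiedTss:
    """Classify one TSS against the annotation.

    Overlapping genes resolve to a single host: sense-strand genes are
    preferred, and among candidates the one in which the TSS lies closest
    to the gene's 5' end (smallest relative position) wins.
    """
    hits = index.overlapping(tss.reference, tss.position)
    out = ClassifiedTss(tss=tss, context=INTERGENIC)
    out.is_leaderless = detect_leaderless(tss, index)
    if not hits:
        return out
    sense = [g for g in hits if g.strand == tss.strand]
    pool = sense if sense else hits
    host = min(pool, key=lambda g: (relative_position(tss.position, g), g.gene_id))
    out.context = SENSE if sense else ANTISENSE
    out.host_gene = host.gene_id
    out.relative_position = relative_position(tss.position, host)
    if host.feature_class == "CDS":
        cds = host
    else:
        # CDS row backing the host gene: same strand, same interval preferred
        cds_hits = [c for c in index.overlapping_cds(tss.reference, tss.position)
                    if c.strand == host.strand]
        exact = [c for c in cds_hits if (c.start, c.end) == (host.start, host.end)]
        cds = (exact or cds_hits or [None])[0]
    if cds is not None:
        out.codon_position = codon_position(tss.position, cds)
        if genome is not None and out.context == SENSE:
            out.is_internal_inframe_start = detect_internal_inframe_start(tss, cds, genome)
    return out


def classify_all(
    tss_records: Iterable[TssRecord],
    index: GeneIndex,
    genome: GenomeSequence | None = None,
) -> list[ClassifiedTss]:
    return [classify_context(t, index, genome) for t in tss_records]


def positional_histograms(classified: Sequence[ClassifiedTss], bins: int = 10) -> dict:
    """Aggregate intragenic TSS by position decile, codon phase and context.

    Returns a dict of DataFrames:
      * ``position_counts`` — sense/antisense TSS counts per gene-length bin
      * ``codon_by_bin`` — codon-phase counts per bin (sense and antisense)
      * ``rrs_by_context`` — RRS summary statistics per context class
    """
    rows = []
    for c in classified:
        if c.context == INTERGENIC or c.relative_position is None:
            continue
        b = min(int(c.relative_position * bins), bins - 1) + 1
        rows.append({
            "bin": b,
            "sense": c.context == SENSE,
            "codon_position": c.codon_position,
            "rrs": c.tss.rrs_cap,
        })
    intr = pd.DataFrame(rows, columns=["bin", "sense", "codon_position", "rrs"])
    pos_counts = (
        intr.assign(orientation=intr["sense"].map({True: "sense", False: "antisense"}))
        .groupby(["bin", "orientation"]).size().unstack(fill_value=0)
        .reindex(range(1, bins + 1), fill_value=0)
    )
    codon = (
        intr.dropna(subset=["codon_position"])
        .assign(orientation=lambda d: d["sense"].map({True: "sense", False: "antisense"}))
        .groupby(["orientation", "bin", "codon_position"]).size().unstack(fill_value=0)
    )
    rrs_rows = pd.DataFrame(
        [{"context": c.context, "rrs": c.tss.rrs_cap} for c in classified]
    )
    rrs_by_context = (
        rrs_rows.groupby("context")["rrs"].describe()
        if len(rrs_rows) else pd.DataFrame()
    )
    return {"position_counts": pos_counts, "codon_by_bin": codon,
            "rrs_by_context": rrs_by_context}


def codon_position_fractions(classified: Sequence[ClassifiedTss]) -> pd.DataFrame:
    """Fraction of intragenic TSS at codon phases 1..3, by orientation."""
    rows = [
        {"orientation": "sense" if c.context == SENSE else "antisense",
         "codon_position": c.codon_position}
        for c in classified
        if c.context in (SENSE, ANTISENSE) and c.codon_position is not None
    ]
    df = pd.DataFrame(rows, columns=["orientation", "codon_position"])
    counts = df.groupby(["orientation", "codon_position"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=[1, 2, 3], fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


_PRECEDENCE = ("rRNA", "tRNA", "CDS", "intergenic")


def read_feature_distribution(
    reads: Iterable[AlignedRead], index: GeneIndex
) -> dict[str, float]:
    """Fraction of reads whose 5' end falls in rRNA / tRNA / coding genes /
    intergenic space, with that precedence for overlapping features."""
    counts = dict.fromkeys(_PRECEDENCE, 0)
    total = 0
    for r in reads:
        pos = r.aligned_start if r.strand == "+" else r.aligned_end
        classes = {g.feature_class for g in index.overlapping(r.reference, pos)}
        classes |= {g.feature_class for g in index.overlapping_cds(r.reference, pos)}
        for feat in _PRECEDENCE[:3]:
            if feat in classes:
                counts[feat] += 1
                break
        else:
            counts["intergenic"] += 1
        total += 1
    if total == 0:
        return dict.fromkeys(_PRECEDENCE, 0.0)
    return {k: v / total for k, v in counts.items()}
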