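"""Per-genome TSS profiling for mixed bacterial communities.

No control library exists in this mode: every 5' end of a uniquely mapped
read is a putative TSS. A genome is considered present in the community
when it carries at least 300 clustered putative TSS (clustering radius 50,
i.e. the strongest putative TSS within 100 bp). High-confidence TSS use an
absolute raw-count floor of 10 reads before clustering. Per-genome
summaries cover leaderless-transcript fraction, read distribution across
feature classes, and between-replicate RRS correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .annotate import GeneIndex, detect_leaderless
from .calling import TssRecord, TssSet, cluster_tss
from .counts import FivePrimeCountTable, compute_rrs
from .io import EmptyDataError


@dataclass
class SpeciesReport:
    genome_id: str
    n_putative_clustered_tss: int
    present: bool
    n_high_confidence_tss: int
    leaderless_fraction: float | None = None
    feature_distribution: dict[str, float] | None = None
    replicate_r: float | None = None
    n_replicate_union: int | None = None


def _records_from_table(table: FivePrimeCountTable, min_count: int) -> list[TssRecord]:
    if not table.rrs and table.total_mapped > 0:
        compute_rrs(table)
    records = []
    for (ref, pos, strand), c in table.items():
        if c >= min_count:
            records.append(
                TssRecord(ref, pos, strand, count=c, rrs_cap=table.rrs.get(
                    (ref, pos, strand), 0.0))
            )
    records.sort(key=lambda r: (r.reference, r.strand, r.position))
    return records


def putative_tss(counts: FivePrimeCountTable, min_count: int = 1) -> TssSet:
    """Every position holding >= min_count uniquely mapped 5' ends."""
    return TssSet(_records_from_table(counts, min_count), {"min_count": min_count})


def species_presence(
    putative: TssSet, cluster_cutoff: int = 50, min_clusters: int = 300
) -> tuple[int, bool]:
    """(number of clustered putative TSS, presence call for the genome)."""
    n = len(cluster_tss(putative, cluster_cutoff).peaks())
    return n, n >= min_clusters


def high_confidence_tss(
    counts: FivePrimeCountTable, abs_count_min: int = 10, cluster_cutoff: int = 50
) -> TssSet:
    """Positions with >= abs_count_min raw reads, clustered; peaks returned."""
    strong = TssSet(_records_from_table(counts, abs_count_min),
                    {"abs_count_min": abs_count_min})
    clustered = cluster_tss(strong, cluster_cutoff)
    return TssSet(clustered.peaks(), clustered.parameters)


def replicate_correlation(
    rep1: FivePrimeCountTable,
    rep2: FivePrimeCountTable,
    abs_count_min: int = 10,
    cluster_cutoff: int = 50,
) -> tuple[float, int]:
    """Pearson r of RRS between two replicates over the union of their
    high-confidence clustered TSS positions (RRS 0 where a position is
    absent from one replicate). Returns (r, union size)."""
    hc1 = high_confidence_tss(rep1, abs_count_min, cluster_cutoff)
    hc2 = high_confidence_tss(rep2, abs_count_min, cluster_cutoff)
    union = sorted({r.key() for r in hc1} | {r.key() for r in hc2})
    if not union:
        raise EmptyDataError("no high-confidence TSS in either replicate")
    for t in (rep1, rep2):
        if not t.rrs and t.total_mapped > 0:
            compute_rrs(t)
    v1 = np.array([rep1.rrs_at(k) for k in union])
    v2 = np.array([rep2.rrs_at(k) for k in union])
    if len(union) < 2 or v1.std() == 0 or v2.std() == 0:
        # degenerate: a single shared position, or constant vectors
        return (1.0 if np.allclose(v1, v2) else 0.0), len(union)
    r, _ = stats.pearsonr(v1, v2)
    return float(r), len(union)


def profile_species(
    genome_id: str,
    counts: FivePrimeCountTable,
    gene_index: GeneIndex | None = None,
    counts_rep2: FivePrimeCountTable | None = None,
    presence_min: int = 300,
    abs_count_min: int = 10,
    cluster_cutoff: int = 50,
) -> SpeciesReport:
    """Run the full per-genome microbiome analysis for one candidate genome."""
    putative = putative_tss(counts)
    n_clustered, present = species_presence(putative, cluster_cutoff, presence_min)
    hc = high_confidence_tss(counts, abs_count_min, cluster_cutoff)
    report = SpeciesReport(
        genome_id=genome_id,
        n_putative_clustered_tss=n_clustered,
        present=present,
        n_high_confidence_tss=len(hc),
    )
    if gene_index is not None:
        if len(hc):
            n_leaderless = sum(detect_leaderless(r, gene_index) for r in hc)
            report.leaderless_fraction = n_leaderless / len(hc)
        report.feature_distribution = _feature_distribution_from_table(counts, gene_index)
    if counts_rep2 is not None:
        r, n_union = replicate_correlation(counts, counts_rep2, abs_count_min, cluster_cutoff)
        report.replicate_r = r
        report.n_replicate_union = n_union
    return report


def _feature_distribution_from_table(
    table: FivePrimeCountTable, index: GeneIndex
) -> dict[str, float]:
    """Read-weighted feature-class distribution from 5'-end positions,
    precedence rRNA > tRNA > CDS > intergenic."""
    counts = {"rRNA": 0, "tRNA": 0, "CDS": 0, "intergenic": 0}
    total = 0
    for (ref, pos, strand), c in table.items():
        classes = {g.feature_class for g in index.overlapping(ref, pos)}
        classes |= {g.feature_class for g in index.overlapping_cds(ref, pos)}
        for feat in ("rRNA", "tRNA", "CDS"):
            if feat in classes:
                counts[feat] += c
                break
        else:
            counts["intergenic"] += c
        total += c
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: v / total for k, v in counts.items()}
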