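"""TSS calling: enrichment filtering against a control library, depleted
(processed) site detection, greedy strongest-first peak clustering, and
comparison with known-TSS catalogs.

A position is a TSS candidate when its enriched-library RRS clears a floor
(default 1.5) and its enrichment score

    enrichment = log2(RRS_enriched / RRS_control)

is at or above a threshold (default 0): primary 5'-triphosphorylated ends
are enriched by the capture step, processed 5'-monophosphate ends are
depleted. Nearby TSS from one promoter are collapsed to the single
highest-RRS position ("clustered TSS").
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

from .counts import FivePrimeCountTable
from .io import EmptyDataError

log = logging.getLogger(__name__)


@dataclass
class TssRecord:
    reference: str
    position: int
    strand: str
    count: int
    rrs_cap: float
    rrs_control: float = 0.0
    enrichment: float = math.inf
    cluster_id: int | None = None
    is_cluster_peak: bool = False

    def key(self) -> tuple[str, int, str]:
        return (self.reference, self.position, self.strand)


@dataclass
class TssSet:
    """An ordered collection of TSS records plus the calling parameters."""

    records: list[TssRecord] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TssRecord]:
        return iter(self.records)

    def sorted(self) -> list[TssRecord]:
        return sorted(self.records, key=lambda r: (r.reference, r.strand, r.position))

    def peaks(self) -> list[TssRecord]:
        """Cluster peaks if clustered, else all records."""
        if any(r.is_cluster_peak for r in self.records):
            return [r for r in self.sorted() if r.is_cluster_peak]
        return self.sorted()

    def clusters(self) -> dict[int, list[TssRecord]]:
        out: dict[int, list[TssRecord]] = {}
        for r in self.records:
            if r.cluster_id is not None:
                out.setdefault(r.cluster_id, []).append(r)
        return out


def enrichment_score(rrs_cap: float, rrs_control: float) -> float:
    """log2(RRS_enriched / RRS_control).

    Returns +inf when the position is absent from the control (maximal
    enrichment, retained downstream), -inf when absent from the enriched
    library, and NaN when absent from both — NaN fails every threshold
    comparison, so such positions can never be called.
    """
    if rrs_cap < 0 or rrs_control < 0:
        raise ValueError("RRS values must be non-negative")
    if rrs_cap == 0 and rrs_control == 0:
        return math.nan
    if rrs_control == 0:
        return math.inf
    if rrs_cap == 0:
        return -math.inf
    return math.log2(rrs_cap / rrs_control)


def call_tss(
    cap: FivePrimeCountTable,
    control: FivePrimeCountTable,
    rrs_min: float = 1.5,
    enrichment_min: float = 0.0,
) -> TssSet:
    """Call unclustered TSS from an enriched table and its control.

    Retains exactly the positions with ``rrs_cap >= rrs_min`` and
    ``enrichment >= enrichment_min``.
    """
    if len(cap) == 0:
        raise EmptyDataError("enriched count table is empty")
    if not cap.rrs:
        raise ValueError("enriched table has no RRS values; run compute_rrs first")
    if len(control) == 0:
        log.warning("control table is empty: all candidates get +inf enrichment")
    records = []
    for key, c in cap.items():
        rrs_cap = cap.rrs[key]
        if rrs_cap < rrs_min:
            continue
        rrs_ctrl = control.rrs_at(key)
        e = enrichment_score(rrs_cap, rrs_ctrl)
        if e >= enrichment_min:
            ref, pos, strand = key
            records.append(
                TssRecord(ref, pos, strand, count=c, rrs_cap=rrs_cap,
                          rrs_control=rrs_ctrl, enrichment=e)
            )
    records.sort(key=lambda r: (r.reference, r.strand, r.position))
    return TssSet(records, {"rrs_min": rrs_min, "enrichment_min": enrichment_min})


def depleted_sites(
    cap: FivePrimeCountTable,
    control: FivePrimeCountTable,
    rrs_control_min: float = 1.5,
) -> TssSet:
    """Processed-site candidates: control RRS >= floor and enrichment < 0."""
    if not control.rrs:
        raise ValueError("control table has no RRS values; run compute_rrs first")
    records = []
    for key, c_ctrl in control.items():
        rrs_ctrl = control.rrs[key]
        if rrs_ctrl < rrs_control_min:
            continue
        rrs_cap = cap.rrs_at(key)
        e = enrichment_score(rrs_cap, rrs_ctrl)
        if e < 0:
            ref, pos, strand = key
            records.append(
                TssRecord(ref, pos, strand, count=cap.counts.get(key, 0),
                          rrs_cap=rrs_cap, rrs_control=rrs_ctrl, enrichment=e)
            )
    records.sort(key=lambda r: (r.reference, r.strand, r.position))
    return TssSet(records, {"rrs_control_min": rrs_control_min})


def cluster_tss(tss: TssSet, cutoff: int = 5) -> TssSet:
    """Greedy strongest-first clustering within each (reference, strand).

    Repeatedly the highest-RRS unassigned position becomes a cluster peak
    and absorbs every unassigned position within ±cutoff bases of it.
    Ties in RRS break to the leftmost coordinate. Opposite strands never
    co-cluster; membership is distance-to-peak, not transitive chaining.
    """
    if cutoff < 0:
        raise ValueError("cluster cutoff must be non-negative")
    groups: dict[tuple[str, str], list[TssRecord]] = {}
    for r in tss.records:
        groups.setdefault((r.reference, r.strand), []).append(r)

    out: list[TssRecord] = []
    cluster_id = 0
    for gkey in sorted(groups):
        members = sorted(groups[gkey], key=lambda r: r.position)
        positions = [r.position for r in members]
        assigned = [False] * len(members)
        # peak candidates in greedy order: strongest RRS first, leftmost on ties
        order = sorted(range(len(members)),
                       key=lambda i: (-members[i].rrs_cap, members[i].position))
        for i in order:
            if assigned[i]:
                continue
            peak = members[i]
            lo = bisect_left(positions, peak.position - cutoff)
            hi = bisect_left(positions, peak.position + cutoff + 1)
            for j in range(lo, hi):
                if not assigned[j]:
                    assigned[j] = True
                    out.append(replace(members[j], cluster_id=cluster_id,
                                       is_cluster_peak=(j == i)))
            cluster_id += 1
    out.sort(key=lambda r: (r.reference, r.strand, r.position))
    return TssSet(out, {**tss.parameters, "cluster_cutoff": cutoff})


def match_known_tss(
    tss: TssSet,
    known: Sequence[tuple[int, str | None]],
    window: int = 25,
    require_strand: bool = True,
) -> tuple[TssSet, TssSet]:
    """Partition a TSS set into (common, specific) against a known catalog.

    A TSS is *common* when at least one known TSS lies within ±window bases
    (and on the same strand, when the catalog is stranded and
    ``require_strand`` is set); otherwise it is *specific*.
    """
    by_strand: dict[str | None, list[int]] = {}
    for pos, strand in known:
        s = strand if require_strand else None
        by_strand.setdefault(s, []).append(pos)
    for v in by_strand.values():
        v.sort()

    def is_common(r: TssRecord) -> bool:
        for s in (r.strand, None):
            positions = by_strand.get(s)
            if not positions:
                continue
            i = bisect_left(positions, r.position)
            for j in (i - 1, i):
                if 0 <= j < len(positions) and abs(positions[j] - r.position) <= window:
                    return True
        return False

    common, specific = [], []
    for r in tss.records:
        (common if is_common(r) else specific).append(r)
    params = {**tss.parameters, "known_window": window}
    return TssSet(common, params), TssSet(specific, params)
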