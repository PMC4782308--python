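"""Sequence-level characterization of TSS.

Promoter windows are written 5'->3' on the TSS strand with offset 0 at the
TSS base, so the sigma-70 -10 element (TATAAT) sits around offsets -12..-7
and the -35 element (TTGACA) around -36..-31. The module computes
per-position information content against the genome's base composition,
builds and scans log-odds position weight matrices with a null-calibrated
hit threshold, tabulates -1/+1 initiation dinucleotides (the YR rule), and
scores per-promoter initiation precision from cluster RRS concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import TssRecord, TssSet
from .io import EmptyDataError, GenomeSequence

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class PromoterWindow:
    """Sequence from -upstream_len to +downstream_len around one TSS,
    5'->3' on the TSS strand; the TSS base is at index ``upstream_len``."""

    tss: TssRecord
    upstream_len: int
    downstream_len: int
    sequence: str
    has_n: bool = False

    def at_offset(self, offset: int) -> str:
        """Base at a TSS-relative offset (0 = the TSS base itself)."""
        return self.sequence[self.upstream_len + offset]


def extract_windows(
    tss_set: TssSet | Sequence[TssRecord],
    genome: GenomeSequence,
    upstream: int = 45,
    downstream: int = 5,
) -> list[PromoterWindow]:
    """Extract promoter windows; TSS too close to a genome end are skipped."""
    records = tss_set.records if isinstance(tss_set, TssSet) else list(tss_set)
    windows = []
    n_skipped = 0
    for r in records:
        if r.strand == "+":
            start, end = r.position - upstream, r.position + downstream
        else:
            start, end = r.position - downstream, r.position + upstream
        if start < 1 or end > genome.length:
            n_skipped += 1
            continue
        seq = genome.subseq(start, end, r.strand)
        windows.append(PromoterWindow(r, upstream, downstream, seq, "N" in seq))
    if n_skipped:
        import logging
        logging.getLogger(__name__).info("skipped %d windows at genome ends", n_skipped)
    return windows


def genome_background(genome: GenomeSequence) -> np.ndarray:
    """Base composition of the genome over A,C,G,T (N ignored)."""
    counts = np.array([genome.sequence.count(b) for b in _BASES], dtype=float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def _column_counts(seqs: Sequence[str]) -> np.ndarray:
    """(L, 4) base counts per column; N and other ambiguity codes excluded."""
    length = len(seqs[0])
    counts = np.zeros((length, 4))
    for s in seqs:
        if len(s) != length:
            raise ValueError("sequences must all have the same length")
        for j, b in enumerate(s):
            i = _BASE_INDEX.get(b)
            if i is not None:
                counts[j, i] += 1
    return counts


def information_content(
    windows: Sequence[PromoterWindow] | Sequence[str],
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Per-position information in bits: the relative entropy
    sum_b p_b log2(p_b / q_b) of the observed column distribution p
    against the background q (genome composition; uniform by default)."""
    if len(windows) == 0:
        raise EmptyDataError("no windows supplied")
    seqs = [w.sequence if isinstance(w, PromoterWindow) else w for w in windows]
    q = np.full(4, 0.25) if background is None else np.asarray(background, float)
    counts = _column_counts(seqs)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    p = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q), 0.0)
    return terms.sum(axis=1)


@dataclass
class Pwm:
    """Log-odds position weight matrix over A,C,G,T.

    ``log_odds[j, b] = log2(p[j, b] / background[b])`` where p is the
    pseudocount-smoothed per-column base probability. Bases outside ACGT
    contribute 0 (background odds) when scoring.
    """

    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.5
    probabilities: np.ndarray | None = None

    @property
    def motif_length(self) -> int:
        return self.log_odds.shape[0]

    def score(self, seq: str, offset: int = 0) -> float:
        """Score the motif placed at ``offset`` within ``seq``."""
        total = 0.0
        for j in range(self.motif_length):
            i = _BASE_INDEX.get(seq[offset + j])
            if i is not None:
                total += self.log_odds[j, i]
        return total

    def best_score(self, seq: str, start: int = 0, end: int | None = None) -> float:
        """Best score over all placements fully inside seq[start:end]."""
        end = len(seq) if end is None else end
        last = end - self.motif_length
        if last < start:
            raise ValueError("PWM longer than the scanned interval")
        return max(self.score(seq, o) for o in range(start, last + 1))


def build_pwm(
    sites: Sequence[str],
    background: np.ndarray | None = None,
    pseudocount: float = 0.5,
) -> Pwm:
    """Build a PWM from aligned, equal-length motif instances.

    Column probabilities are (count + pseudocount) / (n + 4*pseudocount);
    log-odds are base-2 against the background.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to build a PWM")
    q = np.full(4, 0.25) if background is None else np.asarray(background, float)
    counts = _column_counts(sites)
    n = len(sites)
    p = (counts + pseudocount) / (n + 4 * pseudocount)
    with np.errstate(divide="ignore"):
        lo = np.log2(p / q)
    return Pwm(log_odds=lo, background=q, pseudocount=pseudocount, probabilities=p)


def scan_fraction_with_motif(
    windows: Sequence[PromoterWindow],
    pwm: Pwm,
    null_windows: Sequence[PromoterWindow],
    null_quantile: float = 0.95,
    scan_start: int = -15,
    scan_end: int = -4,
) -> tuple[float, float]:
    """Fraction of promoter windows with a PWM hit above a null-calibrated
    threshold.

    The threshold is the ``null_quantile`` of best-hit scores over windows
    drawn at random genome positions; a window "has the motif" when its
    best hit inside TSS-relative offsets [scan_start, scan_end] exceeds it.
    Returns (fraction, null_fraction); the null fraction is approximately
    1 - null_quantile by construction.
    """
    if not windows or not null_windows:
        raise EmptyDataError("windows and null_windows must be non-empty")

    def best(w: PromoterWindow) -> float:
        lo = w.upstream_len + scan_start
        hi = w.upstream_len + scan_end + 1  # slice end, inclusive interval
        if lo < 0 or hi > len(w.sequence):
            raise ValueError("scan interval outside window")
        return pwm.best_score(w.sequence, lo, hi)

    null_scores = np.array([best(w) for w in null_windows])
    threshold = float(np.quantile(null_scores, null_quantile))
    scores = np.array([best(w) for w in windows])
    return float(np.mean(scores > threshold)), float(np.mean(null_scores > threshold))


def sample_null_windows(
    genome: GenomeSequence,
    n: int,
    upstream: int = 45,
    downstream: int = 5,
    rng: np.random.Generator | None = None,
) -> list[PromoterWindow]:
    """Windows around uniformly random positions/strands of the same genome,
    the background set for motif-scan calibration."""
    rng = np.random.default_rng() if rng is None else rng
    lo, hi = upstream + downstream + 2, genome.length - upstream - downstream - 2
    positions = rng.integers(lo, hi, size=n)
    strands = rng.choice(["+", "-"], size=n)
    fake = [TssRecord(genome.name, int(p), s, 0, 0.0) for p, s in zip(positions, strands)]
    return extract_windows(fake, genome, upstream, downstream)


# --- -1/+1 dinucleotide classes --------------------------------------------

def dinucleotide_group(minus1: str, plus1: str) -> str | None:
    """YR/YY/RR/RY class of a (-1, +1) base pair; None for ambiguous bases."""
    if minus1 not in "ACGT" or plus1 not in "ACGT":
        return None
    a = "Y" if minus1 in PYRIMIDINES else "R"
    b = "R" if plus1 in PURINES else "Y"
    return a + b


@dataclass
class DinucleotideClassTable:
    """Counts and RRS mass for the 16 (-1, +1) initiation dinucleotides."""

    table: pd.DataFrame  # index: dinucleotide string "-1 base + +1 base"
    group_fractions: pd.Series
    group_rrs_fractions: pd.Series
    assignments: list[tuple[TssRecord, str]] = field(default_factory=list)


def dinucleotide_classes(
    tss_set: TssSet | Sequence[TssRecord], genome: GenomeSequence
) -> DinucleotideClassTable:
    """Tabulate the -1/+1 dinucleotide of every TSS (on the TSS strand;
    +1 is the TSS base itself, -1 the base immediately upstream)."""
    records = tss_set.records if isinstance(tss_set, TssSet) else list(tss_set)
    rows: dict[str, dict] = {
        m + p: {"count": 0, "rrs_sum": 0.0, "group": dinucleotide_group(m, p)}
        for m in _BASES for p in _BASES
    }
    assignments = []
    for r in records:
        m1_pos = r.position - 1 if r.strand == "+" else r.position + 1
        if not (1 <= m1_pos <= genome.length and 1 <= r.position <= genome.length):
            continue
        minus1 = genome.base(m1_pos, r.strand)
        plus1 = genome.base(r.position, r.strand)
        dinuc = minus1 + plus1
        if dinuc not in rows:
            continue
        rows[dinuc]["count"] += 1
        rows[dinuc]["rrs_sum"] += r.rrs_cap
        assignments.append((r, dinuc))
    df = pd.DataFrame.from_dict(rows, orient="index")
    total_n = df["count"].sum()
    total_rrs = df["rrs_sum"].sum()
    df["tss_fraction"] = df["count"] / total_n if total_n else 0.0
    df["rrs_fraction"] = df["rrs_sum"] / total_rrs if total_rrs else 0.0
    groups = df.groupby("group")[["tss_fraction", "rrs_fraction"]].sum()
    return DinucleotideClassTable(
        table=df,
        group_fractions=groups["tss_fraction"],
        group_rrs_fractions=groups["rrs_fraction"],
        assignments=assignments,
    )


# --- initiation precision ---------------------------------------------------

def initiation_precision(
    clustered: TssSet,
    peak_fraction_min: float = 0.75,
    genome: GenomeSequence | None = None,
) -> pd.DataFrame:
    """Classify each TSS cluster as precise or imprecise initiation.

    A cluster is *precise* when its peak concentrates at least
    ``peak_fraction_min`` of the cluster's total RRS. When a genome is
    supplied, the peak's -1/+1 dinucleotide group is attached so precision
    can be cross-tabulated against the YR rule.
    """
    rows = []
    for cid, members in sorted(clustered.clusters().items()):
        peak = max(members, key=lambda r: (r.is_cluster_peak, r.rrs_cap))
        total = sum(r.rrs_cap for r in members)
        frac = peak.rrs_cap / total if total > 0 else 1.0
        row = {
            "cluster_id": cid,
            "reference": peak.reference,
            "peak_position": peak.position,
            "strand": peak.strand,
            "n_members": len(members),
            "peak_fraction": frac,
            "precise": frac >= peak_fraction_min,
        }
        if genome is not None:
            m1 = peak.position - 1 if peak.strand == "+" else peak.position + 1
            if 1 <= m1 <= genome.length:
                row["group"] = dinucleotide_group(
                    genome.base(m1, peak.strand), genome.base(peak.position, peak.strand)
                )
        rows.append(row)
    return pd.DataFrame(rows)
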