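"""Synthetic data generator: toy genomes with planted promoters and TSS,
plus paired enriched/control alignment libraries, so the whole pipeline can
be exercised and parameter recovery measured without any download.

The generator emulates the data-generating assumptions of a 5'-end
enrichment experiment:

* planted TSS of log-uniform strength, a fraction of which initiate
  imprecisely (5' ends jittered by a rounded, clipped Gaussian);
* planted processed sites that dominate the non-enriched control library
  and leak into the enriched library at a small residual rate;
* rRNA-locus background that makes up most of the control library (and a
  small residue of the enriched one), mirroring the observed read
  composition of real libraries (~85% rRNA without enrichment, ~3% with);
* optional sigma-70 promoter elements (TATAAT at -12..-7, TTGACA at
  -36..-31) and a -1 pyrimidine / +1 purine (YR) initiation bias planted
  at each TSS.

Reads are fixed-length perfect-match alignments written as valid SAM;
minus-strand reads are placed so their rightmost aligned base is the 5' end.
"""

from __future__ import annotations

import os
from bisect import bisect_left, insort
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pysam
from Bio.Seq import reverse_complement

from .calling import TssSet
from .io import EmptyDataError, GeneModel, GenomeSequence, write_annotation, write_genome

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for one simulation.

    Depths and counts are reads; strengths are relative expected-read
    weights drawn log-uniformly; all *_fraction fields are in [0, 1].
    """

    genome_length: int = 120_000
    gc_content: float = 0.5
    n_genes: int = 40          # protein-coding genes
    n_rrna: int = 2
    n_trna: int = 4
    n_tss: int = 200
    strength_min: float = 1.0
    strength_max: float = 100.0
    precise_fraction: float = 0.4
    jitter_sd: float = 1.5     # bases; imprecise TSS only
    jitter_max: int = 4        # hard clip, keeps dispersion inside one cluster
    n_processed_sites: int = 100
    processed_in_cap_rate: float = 0.02
    rrna_fraction_cap: float = 0.03
    control_tss_fraction: float = 0.05
    control_processed_fraction: float = 0.10
    rrna_fraction_control: float = 0.85
    depth_cap: int = 100_000
    depth_control: int = 100_000
    read_length: int = 50
    motif_plant: bool = True
    yr_bias: float = 0.8
    min_site_separation: int = 80  # keeps planted promoter elements disjoint
    seed: int = 1

    def __post_init__(self):
        for name in ("gc_content", "precise_fraction", "processed_in_cap_rate",
                     "rrna_fraction_cap", "control_tss_fraction",
                     "control_processed_fraction", "rrna_fraction_control", "yr_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_cap <= 0 or self.depth_control <= 0:
            raise ValueError("library depths must be positive")
        ctl = (self.control_tss_fraction + self.control_processed_fraction
               + self.rrna_fraction_control)
        if abs(ctl - 1.0) > 1e-9:
            raise ValueError("control mixture fractions must sum to 1")
        if self.processed_in_cap_rate + self.rrna_fraction_cap > 1.0:
            raise ValueError("enriched-library background fractions exceed 1")


@dataclass(frozen=True)
class PlantedTss:
    position: int
    strand: str
    strength: float
    precise: bool
    is_yr: bool


@dataclass(frozen=True)
class ProcessedSite:
    position: int
    strand: str
    strength: float


@dataclass
class SimTruth:
    tss: list[PlantedTss] = field(default_factory=list)
    processed: list[ProcessedSite] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)


def _place_intervals(lengths, lo, hi, rng, gap=20, max_tries=200_000):
    """Randomly place non-overlapping intervals of the given lengths inside
    [lo, hi]; returns sorted-by-placement (start, end) list."""
    placed: list[tuple[int, int]] = []
    out = []
    tries = 0
    for length in lengths:
        while True:
            tries += 1
            if tries > max_tries:
                raise ValueError("infeasible packing: too many/long features for genome")
            start = int(rng.integers(lo, hi - length + 1))
            end = start + length - 1
            if all(end + gap < s or start - gap > e for s, e in placed):
                placed.append((start, end))
                out.append((start, end))
                break
    return out


def _write_on_strand(seq: bytearray, pos: int, strand: str, rel_start: int, motif: str):
    """Write `motif` so that, read 5'->3' on `strand`, it occupies TSS-relative
    offsets rel_start .. rel_start+len-1 (offset 0 = the TSS base)."""
    if strand == "+":
        start = pos + rel_start  # 1-based
        seq[start - 1 : start - 1 + len(motif)] = motif.encode()
    else:
        rc = reverse_complement(motif)
        end = pos - rel_start  # genome position of motif base 0
        start = end - len(motif) + 1
        seq[start - 1 : start - 1 + len(motif)] = rc.encode()


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeSequence, list[GeneModel], SimTruth]:
    """Generate the toy genome, its annotation and the planted truth."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.genome_length
    margin = 150
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = bytearray(_BASES[rng.choice(4, size=L, p=probs)].tobytes())

    # --- gene placement ---
    lengths = ([3000] * config.n_rrna + [80] * config.n_trna
               + [int(300 + 3 * rng.integers(0, 300)) for _ in range(config.n_genes)])
    classes = (["rRNA"] * config.n_rrna + ["tRNA"] * config.n_trna
               + ["CDS"] * config.n_genes)
    intervals = _place_intervals(lengths, margin, L - margin, rng)
    genes = []
    counters = {"rRNA": 0, "tRNA": 0, "CDS": 0}
    for (start, end), cls in zip(intervals, classes):
        counters[cls] += 1
        strand = "+" if rng.random() < 0.5 else "-"
        gid = {"rRNA": "rrna", "tRNA": "trna", "CDS": "gene"}[cls] + f"{counters[cls]:03d}"
        g = GeneModel(gid, cls, start, end, strand, reference="sim")
        genes.append(g)
        if cls == "CDS":  # start codon on the coding strand, for realism
            if strand == "+":
                seq[start - 1 : start + 2] = b"ATG"
            else:
                seq[end - 3 : end] = b"CAT"
    genes.sort(key=lambda g: g.start)

    # --- TSS / processed-site placement (outside rRNA loci) ---
    rrna_iv = [(g.start - 5, g.end + 5) for g in genes if g.feature_class == "rRNA"]
    chosen: list[int] = []  # sorted
    n_sites = config.n_tss + config.n_processed_sites
    sites = []
    tries = 0
    while len(sites) < n_sites:
        tries += 1
        if tries > 500_000:
            raise ValueError("infeasible packing: cannot place TSS with separation")
        p = int(rng.integers(margin, L - margin))
        if any(s <= p <= e for s, e in rrna_iv):
            continue
        i = bisect_left(chosen, p)
        if i > 0 and p - chosen[i - 1] < config.min_site_separation:
            continue
        if i < len(chosen) and chosen[i] - p < config.min_site_separation:
            continue
        insort(chosen, p)
        sites.append(p)

    truth = SimTruth(genes=genes)
    for p in sites[: config.n_tss]:
        strand = "+" if rng.random() < 0.5 else "-"
        strength = float(np.exp(rng.uniform(np.log(config.strength_min),
                                            np.log(config.strength_max))))
        precise = bool(rng.random() < config.precise_fraction)
        is_yr = bool(rng.random() < config.yr_bias)
        if config.motif_plant:
            _write_on_strand(seq, p, strand, -12, "TATAAT")
            _write_on_strand(seq, p, strand, -36, "TTGACA")
        if is_yr:
            minus1 = "C" if rng.random() < 0.5 else "T"
            plus1 = "A" if rng.random() < 0.5 else "G"
            _write_on_strand(seq, p, strand, -1, minus1 + plus1)
        truth.tss.append(PlantedTss(p, strand, strength, precise, is_yr))
    for p in sites[config.n_tss :]:
        strand = "+" if rng.random() < 0.5 else "-"
        strength = float(np.exp(rng.uniform(np.log(config.strength_min),
                                            np.log(config.strength_max))))
        truth.processed.append(ProcessedSite(p, strand, strength))

    genome = GenomeSequence("sim", seq.decode())
    return genome, genes, truth


def _five_prime_sources(truth: SimTruth, config: SimConfig, library: str):
    """(positions, strands, probabilities, jitter-eligible flags) for one library."""
    if library == "cap":
        f_tss = 1.0 - config.processed_in_cap_rate - config.rrna_fraction_cap
        f_proc, f_rrna = config.processed_in_cap_rate, config.rrna_fraction_cap
    else:
        f_tss = config.control_tss_fraction
        f_proc, f_rrna = config.control_processed_fraction, config.rrna_fraction_control

    positions, strands, probs, jitter = [], [], [], []
    w_tss = np.array([t.strength for t in truth.tss])
    if len(w_tss) and f_tss > 0:
        for t, w in zip(truth.tss, w_tss / w_tss.sum()):
            positions.append(t.position)
            strands.append(t.strand)
            probs.append(f_tss * w)
            jitter.append(not t.precise)
    w_proc = np.array([s.strength for s in truth.processed])
    if len(w_proc) and f_proc > 0:
        for s, w in zip(truth.processed, w_proc / w_proc.sum()):
            positions.append(s.position)
            strands.append(s.strand)
            probs.append(f_proc * w)
            jitter.append(False)
    rrna = [g for g in truth.genes if g.feature_class == "rRNA"]
    if rrna and f_rrna > 0:
        n_pos = sum(g.length for g in rrna)
        for g in rrna:
            for p in range(g.start, g.end + 1):
                positions.append(p)
                strands.append(g.strand)
                probs.append(f_rrna / n_pos)
                jitter.append(False)
    probs = np.array(probs)
    return np.array(positions), np.array(strands), probs / probs.sum(), np.array(jitter)


def simulate_libraries(
    genome: GenomeSequence,
    truth: SimTruth,
    config: SimConfig,
    cap_path: str | os.PathLike,
    control_path: str | os.PathLike,
    rng: np.random.Generator | None = None,
) -> None:
    """Sample both libraries and write them as coordinate-sorted SAM."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    for library, depth, path in (
        ("cap", config.depth_cap, cap_path),
        ("control", config.depth_control, control_path),
    ):
        if depth <= 0:
            raise ValueError("library depth must be positive")
        positions, strands, probs, jitter = _five_prime_sources(truth, config, library)
        counts = rng.multinomial(depth, probs)
        ends = []  # (five_prime_pos, strand)
        for pos, strand, c, j in zip(positions, strands, counts, jitter):
            if c == 0:
                continue
            if j and config.jitter_sd > 0:
                offsets = np.clip(
                    np.rint(rng.normal(0.0, config.jitter_sd, size=c)).astype(int),
                    -config.jitter_max, config.jitter_max,
                )
            else:
                offsets = np.zeros(c, dtype=int)
            gpos = pos + offsets if strand == "+" else pos - offsets
            ends.extend((int(p), strand) for p in gpos)
        _write_sam(genome, ends, config.read_length, path, library)


def _write_sam(genome, five_prime_ends, read_length, path, library):
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": genome.name, "LN": genome.length}],
    })
    rows = []
    for p, strand in five_prime_ends:
        start = p if strand == "+" else p - read_length + 1
        rows.append((start, strand))
    rows.sort()
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (start, strand) in enumerate(rows):
            a = pysam.AlignedSegment(header)
            a.query_name = f"sim:{library}:{i}"
            a.flag = 16 if strand == "-" else 0
            a.reference_id = 0
            a.reference_start = start - 1
            a.mapping_quality = 42
            a.cigartuples = [(0, read_length)]
            a.query_sequence = genome.sequence[start - 1 : start - 1 + read_length]
            out.write(a)


def write_truth_tsv(truth: SimTruth, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tposition\tstrand\tstrength\tprecise\tis_yr\n")
        for t in truth.tss:
            fh.write(f"tss\t{t.position}\t{t.strand}\t{t.strength:.6f}\t"
                     f"{int(t.precise)}\t{int(t.is_yr)}\n")
        for s in truth.processed:
            fh.write(f"processed\t{s.position}\t{s.strand}\t{s.strength:.6f}\t.\t.\n")


def read_truth_tsv(path: str | os.PathLike) -> SimTruth:
    truth = SimTruth()
    with open(path) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if f[0] == "tss":
                truth.tss.append(PlantedTss(int(f[1]), f[2], float(f[3]),
                                            f[4] == "1", f[5] == "1"))
            else:
                truth.processed.append(ProcessedSite(int(f[1]), f[2], float(f[3])))
    return truth


def simulate(config: SimConfig, out_dir: str | os.PathLike):
    """Run the full generator and write genome.fa, genes.gff3, truth.tsv,
    cap.sam, control.sam into ``out_dir``. Returns (genome, genes, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome, genes, truth = simulate_genome(config, rng)
    write_genome([genome], out / "genome.fa")
    write_annotation(genes, out / "genes.gff3")
    write_truth_tsv(truth, out / "truth.tsv")
    simulate_libraries(genome, truth, config, out / "cap.sam", out / "control.sam", rng)
    return genome, genes, truth


def evaluate_calls(
    called: TssSet | list,
    truth_sites: list,
    tolerance: int = 2,
) -> tuple[float, float]:
    """Precision/recall of called peaks against planted truth.

    A called position is a true positive when it lies within ±tolerance of
    an unmatched truth site on the same strand; matching is one-to-one,
    greedy by distance.
    """
    peaks = called.peaks() if isinstance(called, TssSet) else list(called)
    if not peaks or not truth_sites:
        raise EmptyDataError("called set and truth must both be non-empty")
    pairs = []
    truth_pos = [(t.position, t.strand) for t in truth_sites]
    for i, r in enumerate(peaks):
        for j, (tp, ts) in enumerate(truth_pos):
            d = abs(r.position - tp)
            if d <= tolerance and r.strand == ts:
                pairs.append((d, i, j))
    pairs.sort()
    used_called: set[int] = set()
    used_truth: set[int] = set()
    tp = 0
    for d, i, j in pairs:
        if i in used_called or j in used_truth:
            continue
        used_called.add(i)
        used_truth.add(j)
        tp += 1
    return tp / len(peaks), tp / len(truth_pos)
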