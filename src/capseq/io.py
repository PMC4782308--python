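"""Readers and writers for the on-disk formats the pipeline consumes and emits.

All internal coordinates are 1-based inclusive (GTF convention); the only
0-based half-open conversion happens at the BED boundary. Strands are the
strings ``"+"`` and ``"-"`` throughout.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class CapseqError(Exception):
    """Base error; ``exit_code`` drives the CLI exit status."""

    exit_code = 1


class InputFormatError(CapseqError):
    """Unparseable or inconsistent input file."""

    exit_code = 3


class EmptyDataError(CapseqError):
    """An operation received no usable data (e.g. empty library)."""

    exit_code = 4


@dataclass(frozen=True)
class GenomeSequence:
    """A single reference sequence, uppercase DNA over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int, strand: str = "+") -> str:
        """Base at a 1-based position; complemented on the minus strand."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        b = self.sequence[position - 1]
        return b if strand == "+" else b.translate(_COMPLEMENT)

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of the 1-based inclusive interval, 5'->3' on `strand`."""
        if start < 1 or end > self.length or start > end:
            raise IndexError(f"interval {start}..{end} outside 1..{self.length}")
        s = self.sequence[start - 1 : end]
        return s if strand == "+" else reverse_complement(s)


@dataclass(frozen=True)
class AlignedRead:
    """Minimal view of one primary alignment.

    ``aligned_start``/``aligned_end`` are the 1-based leftmost/rightmost
    *aligned* reference bases: soft-clipped bases are excluded, so the
    5' end of the original molecule is ``aligned_start`` on ``+`` and
    ``aligned_end`` on ``-``.
    """

    query_name: str
    reference: str
    strand: str
    aligned_start: int
    aligned_end: int
    is_unique: bool
    mapq: int


@dataclass(frozen=True)
class GeneModel:
    """A gene/CDS/rRNA/tRNA feature interval."""

    gene_id: str
    feature_class: str  # one of CDS, rRNA, tRNA, other
    start: int
    end: int
    strand: str
    reference: str = ""

    @property
    def five_prime(self) -> int:
        """Annotated 5' boundary: start on +, end on -."""
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_genome(path: str | os.PathLike) -> dict[str, GenomeSequence]:
    """Load a FASTA file into a name -> GenomeSequence map."""
    genomes = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genomes[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    if not genomes:
        raise InputFormatError(f"no sequences found in {path}")
    return genomes


def write_genome(genomes: Iterable[GenomeSequence], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, g.length, 70):
                fh.write(g.sequence[i : i + 70] + "\n")


def read_alignments(
    path: str | os.PathLike,
    min_mapq: int = 10,
    unique_only: bool = True,
) -> Iterator[AlignedRead]:
    """Stream mapped primary alignments from a SAM/BAM file.

    Uniqueness: a read is non-unique when the aligner reports a
    secondary-alignment score tag (``XS``, as emitted by bowtie2/bwa);
    when that tag is absent the MAPQ fallback ``mapq >= min_mapq``
    is used instead. With ``unique_only`` non-unique reads are dropped.
    """
    with pysam.AlignmentFile(str(path), require_index=False) as af:
        if af.header.nreferences == 0:
            raise InputFormatError(f"{path}: header has no reference sequences")
        for i, rec in enumerate(af):
            try:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.has_tag("XS"):
                    is_unique = False
                else:
                    is_unique = rec.mapping_quality >= min_mapq
                if unique_only and not is_unique:
                    continue
                yield AlignedRead(
                    query_name=rec.query_name,
                    reference=rec.reference_name,
                    strand="-" if rec.is_reverse else "+",
                    aligned_start=rec.reference_start + 1,
                    aligned_end=rec.reference_end,  # 0-based excl == 1-based incl
                    is_unique=is_unique,
                    mapq=rec.mapping_quality,
                )
            except (ValueError, TypeError) as exc:
                raise InputFormatError(f"{path}: unparseable record #{i}: {exc}")


_FEATURE_CLASSES = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}
_ID_KEYS = ("ID", "gene_id", "locus_tag", "Name", "gene")


def read_annotation(
    path: str | os.PathLike,
    feature_types: Sequence[str] = ("gene", "CDS", "rRNA", "tRNA"),
) -> list[GeneModel]:
    """Parse a GFF3 or GTF file (dialect auto-detected) into GeneModels.

    Features whose type is not CDS/rRNA/tRNA are kept with
    ``feature_class="other"`` (this covers plain ``gene`` rows used for
    context classification). Records with end < start are dropped with a
    logged warning count.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises bare ValueError on bad files
        if os.path.getsize(path) == 0 or not _has_feature_lines(path):
            return []
        raise InputFormatError(f"{path}: cannot parse annotation: {exc}")

    genes: list[GeneModel] = []
    n_bad = 0
    for feat in db.all_features():
        if feat.featuretype not in feature_types:
            continue
        if feat.end < feat.start:
            n_bad += 1
            continue
        gene_id = feat.id
        for key in _ID_KEYS:
            if key in feat.attributes:
                gene_id = feat.attributes[key][0]
                break
        genes.append(
            GeneModel(
                gene_id=gene_id,
                feature_class=_FEATURE_CLASSES.get(feat.featuretype, "other"),
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                reference=feat.seqid,
            )
        )
    if n_bad:
        log.warning("%s: dropped %d records with end < start", path, n_bad)
    return genes


def _has_feature_lines(path) -> bool:
    with open(path) as fh:
        return any(line.strip() and not line.startswith("#") for line in fh)


def write_annotation(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write GeneModels as GFF3 (gene rows, plus CDS rows for CDS class)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ftype = {"CDS": "gene", "other": "gene"}.get(g.feature_class, g.feature_class)
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.reference}\tcapseq\t{ftype}\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            if g.feature_class == "CDS":
                fh.write(
                    f"{g.reference}\tcapseq\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds;Parent={g.gene_id}\n"
                )


def read_known_tss(path: str | os.PathLike) -> list[tuple[int, str | None]]:
    """Read a tab-separated known-TSS list: position [strand].

    Lines starting with '#' are skipped; strand is optional (None when
    absent, meaning "match either strand").
    """
    known: list[tuple[int, str | None]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                pos = int(parts[0])
            except ValueError:
                raise InputFormatError(f"{path}:{ln}: bad position {parts[0]!r}")
            strand = parts[1] if len(parts) > 1 and parts[1] in "+-" else None
            known.append((pos, strand))
    return known


# --- TSS GTF/BED output -----------------------------------------------------

def _fmt_enrichment(e: float) -> str:
    if e == float("inf"):
        return "inf"
    if e == float("-inf"):
        return "-inf"
    return f"{e:.6f}"


def write_tss_gtf(tss_set, path: str | os.PathLike) -> None:
    """Write a TssSet as single-base GTF features (start == end == position).

    Attributes carry count, rrs, rrs_control, enrichment and cluster_id so
    the file round-trips through :func:`read_tss_gtf`.
    """
    with open(path, "w") as fh:
        for r in tss_set.sorted():
            peak = "1" if r.is_cluster_peak else "0"
            cluster = "." if r.cluster_id is None else str(r.cluster_id)
            attrs = (
                f'count "{r.count}"; rrs "{r.rrs_cap:.6f}"; '
                f'rrs_control "{r.rrs_control:.6f}"; '
                f'enrichment "{_fmt_enrichment(r.enrichment)}"; '
                f'cluster_id "{cluster}"; peak "{peak}";'
            )
            fh.write(
                f"{r.reference}\tcapseq\tTSS\t{r.position}\t{r.position}\t"
                f"{r.rrs_cap:.6f}\t{r.strand}\t.\t{attrs}\n"
            )


def read_tss_gtf(path: str | os.PathLike):
    """Parse a GTF written by :func:`write_tss_gtf` back into a TssSet."""
    from .calling import TssRecord, TssSet

    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise InputFormatError(f"{path}:{ln}: expected 9 columns")
            attrs = {}
            for item in f[8].split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip('"')
            enr = attrs.get("enrichment", "inf")
            cluster = attrs.get("cluster_id", ".")
            records.append(
                TssRecord(
                    reference=f[0],
                    position=int(f[3]),
                    strand=f[6],
                    count=int(attrs.get("count", 0)),
                    rrs_cap=float(attrs.get("rrs", f[5])),
                    rrs_control=float(attrs.get("rrs_control", 0.0)),
                    enrichment=float(enr),
                    cluster_id=None if cluster == "." else int(cluster),
                    is_cluster_peak=attrs.get("peak", "0") == "1",
                )
            )
    return TssSet(records)


def write_tss_bed(tss_set, path: str | os.PathLike) -> None:
    """BED6 output: 0-based half-open, score = round(RRS) capped at 1000."""
    with open(path, "w") as fh:
        for r in tss_set.sorted():
            name = f"tss_{r.reference}_{r.position}_{r.strand}"
            score = min(1000, round(r.rrs_cap))
            fh.write(
                f"{r.reference}\t{r.position - 1}\t{r.position}\t{name}\t{score}\t{r.strand}\n"
            )
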