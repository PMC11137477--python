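"""Assemblies, annotations and the feature-ID contract between them.

This module owns the gene → transcript → exon/CDS hierarchy shared by every
comparison: parsing GFF3/GTF, strand-aware spliced sequence extraction from a
FASTA assembly, and matching features between a reference and a target
annotation purely by their IDs (the compatibility contract of annotation
lift-over: the mapper preserves feature IDs, so identity of IDs means
"the same gene").

Coordinates are 1-based inclusive throughout, matching GFF3/GTF; conversion to
Python slices happens only inside :meth:`Assembly.fetch`.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

from Bio import SeqIO
from Bio.Seq import reverse_complement
from gffutils.feature import feature_from_line


class LiftCompareError(Exception):
    """Base class for all errors raised by this package."""


class AnnotationParseError(LiftCompareError):
    """A GFF3/GTF line could not be parsed; message names the line number."""


class OrphanFeatureError(LiftCompareError):
    """A child feature references a parent ID absent from the file."""


class CoordinateError(LiftCompareError):
    """A feature lies outside its assembly sequence, or the sequence is missing."""


TRANSCRIPT_STOP_TYPES = {"exon", "CDS", "intron", "five_prime_UTR", "three_prime_UTR",
                         "start_codon", "stop_codon", "UTR"}
DEFAULT_COPY_SUFFIX = r"_(\d+)$"


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# Assembly


class Assembly:
    """A set of named nucleotide sequences with 1-based inclusive slicing."""

    def __init__(self, sequences: dict[str, str]):
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"sequence {name!r} is empty")
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self.sequence_order = list(sequences)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Assembly":
        with _open_text(path) as handle:
            records = {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
        if not records:
            raise LiftCompareError(f"no FASTA records found in {path}")
        return cls(records)

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    def fetch(self, name: str, start: int, end: int, strand: str = "+") -> str:
        """Return bases ``start..end`` (1-based inclusive) of sequence *name*.

        With ``strand='-'`` the reverse complement of that interval is returned.
        """
        if name not in self.sequences:
            raise CoordinateError(f"sequence {name!r} not present in assembly")
        seq = self.sequences[name]
        if start < 1 or end > len(seq) or start > end:
            raise CoordinateError(
                f"interval {start}-{end} outside sequence {name!r} (length {len(seq)})")
        sub = seq[start - 1:end]
        return reverse_complement(sub) if strand == "-" else sub


# ---------------------------------------------------------------------------
# Features and annotations


@dataclass
class Feature:
    id: str
    type: str
    seqid: str
    start: int
    end: int
    strand: str
    phase: int | None = None
    parent_id: str | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.id}: start {self.start} > end {self.end}")
        if self.phase is not None and self.phase not in (0, 1, 2):
            raise ValueError(f"feature {self.id}: phase {self.phase} not in {{0,1,2}}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class Annotation:
    """Hierarchical gene → transcript → exon/CDS annotation.

    Any feature whose parent is a gene is treated as transcript-like regardless
    of its type string (mRNA, transcript, ncRNA, lnc_RNA, ...), which is how
    heterogeneous GFF3s such as RefSeq's behave in practice.
    """

    def __init__(self, source_dialect: str = "GFF3"):
        self.genes: list[Feature] = []
        self.transcripts_of: dict[str, list[Feature]] = {}
        self.children_of: dict[str, list[Feature]] = {}
        self.source_dialect = source_dialect
        self._gene_by_id: dict[str, Feature] = {}
        self._transcript_by_id: dict[str, Feature] = {}

    # -- construction ------------------------------------------------------

    def add_gene(self, feat: Feature) -> None:
        if feat.id in self._gene_by_id:
            raise LiftCompareError(f"duplicate gene ID {feat.id!r}")
        self.genes.append(feat)
        self._gene_by_id[feat.id] = feat
        self.transcripts_of.setdefault(feat.id, [])

    def add_transcript(self, feat: Feature) -> None:
        if feat.parent_id not in self._gene_by_id:
            raise OrphanFeatureError(
                f"transcript {feat.id!r} references missing gene {feat.parent_id!r}")
        if feat.id in self._transcript_by_id:
            raise LiftCompareError(f"duplicate transcript ID {feat.id!r}")
        self.transcripts_of[feat.parent_id].append(feat)
        self._transcript_by_id[feat.id] = feat
        self.children_of.setdefault(feat.id, [])

    def add_child(self, feat: Feature) -> None:
        if feat.parent_id not in self._transcript_by_id:
            raise OrphanFeatureError(
                f"{feat.type} {feat.id!r} references missing transcript {feat.parent_id!r}")
        self.children_of[feat.parent_id].append(feat)

    # -- lookup ------------------------------------------------------------

    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def transcript_ids(self) -> list[str]:
        return list(self._transcript_by_id)

    def gene(self, gene_id: str) -> Feature:
        return self._gene_by_id[gene_id]

    def transcript(self, transcript_id: str) -> Feature:
        return self._transcript_by_id[transcript_id]

    def has_transcript(self, transcript_id: str) -> bool:
        return transcript_id in self._transcript_by_id

    def transcripts(self, gene_id: str) -> list[Feature]:
        return self.transcripts_of[gene_id]

    def exons(self, transcript_id: str) -> list[Feature]:
        return [f for f in self.children_of.get(transcript_id, []) if f.type == "exon"]

    def cds(self, transcript_id: str) -> list[Feature]:
        return [f for f in self.children_of.get(transcript_id, []) if f.type == "CDS"]

    def gene_of_transcript(self, transcript_id: str) -> str:
        parent = self._transcript_by_id[transcript_id].parent_id
        assert parent is not None
        return parent

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        for tid, kids in self.children_of.items():
            exons = [f for f in kids if f.type == "exon"]
            if not exons:
                raise LiftCompareError(f"transcript {tid!r} has no exons")
            tr = self._transcript_by_id[tid]
            for f in exons:
                if f.seqid != tr.seqid or f.strand != tr.strand:
                    raise LiftCompareError(
                        f"exon of {tid!r} disagrees with transcript seqid/strand")
            cds = sorted((f for f in kids if f.type == "CDS"), key=lambda f: f.start)
            for a, b in zip(cds, cds[1:]):
                if b.start <= a.end:
                    raise LiftCompareError(f"overlapping CDS segments in {tid!r}")


# ---------------------------------------------------------------------------
# Parsing


def _detect_dialect(path: str | Path) -> str:
    with _open_text(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            attrs = fields[8]
            if re.search(r'\w+\s+"', attrs) and "=" not in attrs.split(";")[0]:
                return "GTF"
            return "GFF3"
    return "GFF3"


def _iter_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def parse_annotation(path: str | Path, dialect: str = "auto") -> Annotation:
    """Parse a GFF3 or GTF file into an :class:`Annotation`.

    ``dialect`` may be ``GFF3``, ``GTF`` or ``auto`` (sniffed from the first
    data line). Gzip-compressed files are accepted. Malformed lines raise
    :class:`AnnotationParseError` naming the line number; children whose parent
    never appears raise :class:`OrphanFeatureError`.
    """
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect not in ("GFF3", "GTF"):
        raise ValueError(f"unknown dialect {dialect!r}")

    parsed: list[tuple[int, Feature]] = []
    for lineno, line in _iter_lines(path):
        try:
            raw = feature_from_line(line, strict=False)
            attrs = {k: v[0] if v else "" for k, v in raw.attributes.items()}
            phase = int(raw.frame) if raw.frame in ("0", "1", "2") else None
            if dialect == "GFF3":
                fid = attrs.get("ID", "")
                parent = attrs.get("Parent")
            else:
                gene_id = attrs.get("gene_id", "")
                tx_id = attrs.get("transcript_id", "")
                if raw.featuretype == "gene" or not tx_id:
                    fid, parent = gene_id, None
                elif raw.featuretype in TRANSCRIPT_STOP_TYPES:
                    fid, parent = "", tx_id
                else:  # transcript-level line
                    fid, parent = tx_id, gene_id
            feat = Feature(
                id=fid, type=raw.featuretype, seqid=raw.seqid,
                start=int(raw.start), end=int(raw.end), strand=raw.strand,
                phase=phase, parent_id=parent, attributes=attrs)
        except (LiftCompareError, ValueError, TypeError, AttributeError) as exc:
            raise AnnotationParseError(f"{path}: line {lineno}: {exc}") from exc
        parsed.append((lineno, feat))

    ann = Annotation(source_dialect=dialect)
    gene_ids = {f.id for _, f in parsed if f.type == "gene"}
    # first pass: genes, then transcript-like (parent is a gene), then leaves
    for _, f in parsed:
        if f.type == "gene":
            ann.add_gene(f)
    counters: dict[str, int] = {}
    for lineno, f in parsed:
        if f.type == "gene":
            continue
        if f.parent_id in gene_ids and f.type not in TRANSCRIPT_STOP_TYPES:
            ann.add_transcript(f)
    for lineno, f in parsed:
        if f.type == "gene" or (f.parent_id in gene_ids and f.type not in TRANSCRIPT_STOP_TYPES):
            continue
        if f.type not in ("exon", "CDS"):
            continue  # UTRs, codons etc. are not needed downstream
        if not f.id:
            n = counters[f.parent_id, f.type] = counters.get((f.parent_id, f.type), 0) + 1
            f.id = f"{f.parent_id}.{f.type.lower()}{n}"
        try:
            ann.add_child(f)
        except OrphanFeatureError as exc:
            raise OrphanFeatureError(f"{path}: line {lineno}: {exc}") from exc
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# Writing (round-trip support and fixture output)


def write_gff3(ann: Annotation, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for gene in ann.genes:
            out.write(_gff3_line(gene, {"ID": gene.id}))
            for tr in ann.transcripts_of[gene.id]:
                out.write(_gff3_line(tr, {"ID": tr.id, "Parent": gene.id}))
                for child in ann.children_of[tr.id]:
                    out.write(_gff3_line(child, {"ID": child.id, "Parent": tr.id}))


def _gff3_line(f: Feature, id_attrs: dict[str, str]) -> str:
    attrs = dict(id_attrs)
    for k, v in f.attributes.items():
        if k not in ("ID", "Parent"):
            attrs[k] = v
    attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
    phase = "." if f.phase is None else str(f.phase)
    return (f"{f.seqid}\tliftcompare\t{f.type}\t{f.start}\t{f.end}\t.\t"
            f"{f.strand}\t{phase}\t{attr_str}\n")


def write_gtf(ann: Annotation, path: str | Path) -> None:
    def attr_str(pairs: list[tuple[str, str]]) -> str:
        return " ".join(f'{k} "{v}";' for k, v in pairs)

    with open(path, "w") as out:
        for gene in ann.genes:
            for f, pairs in _gtf_rows(ann, gene):
                phase = "." if f.phase is None else str(f.phase)
                out.write(f"{f.seqid}\tliftcompare\t{f.type}\t{f.start}\t{f.end}\t.\t"
                          f"{f.strand}\t{phase}\t{attr_str(pairs)}\n")


def _gtf_rows(ann: Annotation, gene: Feature):
    yield gene, [("gene_id", gene.id)]
    for tr in ann.transcripts_of[gene.id]:
        yield tr, [("gene_id", gene.id), ("transcript_id", tr.id)]
        for child in ann.children_of[tr.id]:
            yield child, [("gene_id", gene.id), ("transcript_id", tr.id)]


def write_fasta(asm: Assembly, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as out:
        for name in asm.sequence_order:
            out.write(f">{name}\n")
            seq = asm.sequences[name]
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Sequence extraction


def extract_transcript_sequence(asm: Assembly, ann: Annotation, transcript_id: str) -> str:
    """Spliced transcript sequence, reverse-complemented as a unit on '-' strand."""
    exons = sorted(ann.exons(transcript_id), key=lambda f: f.start)
    if not exons:
        raise LiftCompareError(f"transcript {transcript_id!r} has no exons")
    strand = exons[0].strand
    seq = "".join(asm.fetch(f.seqid, f.start, f.end, "+") for f in exons)
    return reverse_complement(seq) if strand == "-" else seq


def extract_cds_sequence(asm: Assembly, ann: Annotation, transcript_id: str) -> str | None:
    """Spliced, strand-corrected coding sequence, or None for noncoding transcripts.

    If the first CDS segment in translation order carries phase p > 0, the
    leading p bases are trimmed so translation starts on a codon boundary.
    """
    segments = sorted(ann.cds(transcript_id), key=lambda f: f.start)
    if not segments:
        return None
    strand = segments[0].strand
    seq = "".join(asm.fetch(f.seqid, f.start, f.end, "+") for f in segments)
    if strand == "-":
        seq = reverse_complement(seq)
    first = segments[-1] if strand == "-" else segments[0]
    if first.phase:
        seq = seq[first.phase:]
    return seq


def spliced_length(ann: Annotation, transcript_id: str) -> int:
    return sum(f.length for f in ann.exons(transcript_id))


def longest_isoform(ann: Annotation, gene_id: str) -> str:
    """Transcript ID of the gene's longest spliced isoform (ties: smallest ID)."""
    transcripts = ann.transcripts_of.get(gene_id)
    if not transcripts:
        raise LiftCompareError(f"gene {gene_id!r} has no transcripts")
    return min(transcripts, key=lambda t: (-spliced_length(ann, t.id), t.id)).id


# ---------------------------------------------------------------------------
# ID matching


@dataclass
class FeatureMatch:
    """Correspondence between two annotations established purely by feature IDs."""

    shared_gene_ids: set[str]
    shared_transcript_ids: set[str]
    unmapped_ids: set[str]
    extra_copy_ids: dict[str, str]      # extra-copy gene ID -> source gene ID
    unrecognized_ids: set[str]          # target-only IDs matching nothing

    def __post_init__(self) -> None:
        assert not (self.shared_gene_ids & self.unmapped_ids)


def match_features(ref: Annotation, tgt: Annotation,
                   copy_suffix_pattern: str = DEFAULT_COPY_SUFFIX) -> FeatureMatch:
    """Match genes and transcripts between annotations by ID.

    Target-only gene IDs of the form ``<ref_gene_id><suffix>`` (default suffix
    ``_<n>``, the convention of lift-over copy search) are recognized as extra
    copies of that reference gene; other target-only IDs are reported as
    unrecognized and excluded downstream.
    """
    ref_genes, tgt_genes = set(ref.gene_ids()), set(tgt.gene_ids())
    shared = ref_genes & tgt_genes
    unmapped = ref_genes - tgt_genes
    suffix = re.compile(copy_suffix_pattern)
    extra: dict[str, str] = {}
    unrecognized: set[str] = set()
    for gid in sorted(tgt_genes - ref_genes):
        m = suffix.search(gid)
        if m and gid[:m.start()] in ref_genes:
            extra[gid] = gid[:m.start()]
        else:
            unrecognized.add(gid)
    shared_tx = set(ref.transcript_ids()) & set(tgt.transcript_ids())
    return FeatureMatch(shared_gene_ids=shared, shared_transcript_ids=shared_tx,
                        unmapped_ids=unmapped, extra_copy_ids=extra,
                        unrecognized_ids=unrecognized)
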