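"""Readers/writers for the formats the pipeline touches.

FASTA/FASTQ go through Biopython, SAM placements through pysam. Two small
tabular dialects are owned here: a 9-column BLAST-outfmt-6-like alignment TSV
extended with the subject taxid, and a 5-column CDS annotation table mapping
protein entries onto genome coordinates.

Coordinates are 1-based inclusive at every file boundary and converted to
0-based half-open only inside algorithms (single conversion point). Translated
(aa) alignment records express query coordinates in nucleotide space — the
dialect emitted by translated aligners — so nucleotide and protein per-base
score arrays overlay directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if len(self.seq) < 1:
            raise FormatError(f"empty sequence {self.id}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(f"quality length mismatch for {self.id}")


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment event; the atom of recruitment and classification.

    ``q_start``/``q_end`` are 1-based inclusive on the forward strand of the
    query nucleotide sequence, for aa records too (translated-search
    convention), so per-base scores from nt and aa records are commensurable.
    """

    query_id: str
    subject_id: str
    subject_taxid: int
    kind: str  # {"nt", "aa"}
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identity: float
    bits: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.kind not in ("nt", "aa"):
            raise FormatError(f"alignment kind must be nt or aa, got {self.kind!r}")
        if self.subject_taxid <= 0:
            raise FormatError("taxid must be positive")
        if self.q_start > self.q_end:
            raise FormatError("q_start must be <= q_end after normalization")
        if self.bits <= 0:
            raise FormatError("bits must be > 0")
        if not 0.0 <= self.identity <= 1.0:
            raise FormatError("identity must lie in [0, 1]")
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be + or -, got {self.strand!r}")

    @property
    def aligned_len_q(self) -> int:
        return self.q_end - self.q_start + 1


@dataclass(frozen=True)
class CdsAnnotation:
    protein_id: str
    genome_id: str
    g_start: int
    g_end: int
    strand: str
    warnings: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.g_start > self.g_end:
            raise FormatError(
                f"CDS {self.protein_id}: g_start {self.g_start} > g_end {self.g_end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"CDS {self.protein_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.g_end - self.g_start + 1


@dataclass(frozen=True)
class Placement:
    """A read placed on a reference: 0-based start plus reference-frame bases.

    ``bases`` may contain '-' for deletions relative to the reference;
    insertions (bases absent from the reference frame) were dropped upstream.
    """

    read_id: str
    ref_id: str
    ref_start: int
    bases: str


# ---------------------------------------------------------------- FASTA/FASTQ


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"empty sequence {rec.id}")
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        records.append(SequenceRecord(rec.id, str(rec.seq), qual))
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------- alignments

_ALN_COLUMNS = (
    "query_id subject_id subject_taxid identity q_start q_end s_start s_end bits"
)


def read_alignments(path: str | Path, kind: str) -> list[AlignmentRecord]:
    """Read the 9-column alignment TSV; '#' lines are comments.

    Identity arrives as a percentage and is stored as a fraction. Reversed
    coordinate pairs are normalized ascending with the strand inferred
    (reversal of exactly one of query/subject ⇒ minus strand).
    """
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) != 9:
                raise FormatError(
                    f"{path}: line {ln}: expected 9 columns ({_ALN_COLUMNS})"
                )
            try:
                taxid = int(parts[2])
                identity = float(parts[3]) / 100.0
                qs, qe, ss, se = (int(x) for x in parts[4:8])
                bits = float(parts[8])
            except ValueError as exc:
                raise FormatError(f"{path}: line {ln}: non-numeric field: {exc}") from exc
            if taxid <= 0:
                raise FormatError(f"{path}: taxid must be positive (line {ln})")
            strand = "+"
            if qs > qe:
                qs, qe = qe, qs
                strand = "-" if strand == "+" else "+"
            if ss > se:
                ss, se = se, ss
                strand = "-" if strand == "+" else "+"
            try:
                records.append(
                    AlignmentRecord(
                        query_id=parts[0],
                        subject_id=parts[1],
                        subject_taxid=taxid,
                        kind=kind,
                        q_start=qs,
                        q_end=qe,
                        s_start=ss,
                        s_end=se,
                        identity=identity,
                        bits=bits,
                        strand=strand,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}: line {ln}: {exc}") from exc
    return records


def write_alignments(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + _ALN_COLUMNS.replace(" ", "\t") + "\n")
        for r in records:
            ss, se = (r.s_end, r.s_start) if r.strand == "-" else (r.s_start, r.s_end)
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.subject_taxid}\t"
                f"{r.identity * 100.0:.2f}\t{r.q_start}\t{r.q_end}\t{ss}\t{se}\t"
                f"{r.bits:.2f}\n"
            )


# ----------------------------------------------------------------- CDS table


def read_cds_table(path: str | Path) -> list[CdsAnnotation]:
    """Read the 5-column CDS TSV: protein_id genome_id g_start g_end strand.

    A CDS whose length is not divisible by 3 is kept with a warning attached
    (annotation tables frequently carry partial CDS records).
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) != 5:
                raise FormatError(f"{path}: line {ln}: expected 5 columns")
            try:
                g_start, g_end = int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}: line {ln}: non-numeric coordinate") from exc
            warnings = ()
            if (g_end - g_start + 1) % 3 != 0 and g_start <= g_end:
                warnings = (f"CDS length not divisible by 3 ({parts[0]})",)
            try:
                out.append(
                    CdsAnnotation(parts[0], parts[1], g_start, g_end, parts[4], warnings)
                )
            except FormatError as exc:
                raise FormatError(f"{path}: line {ln}: {exc}") from exc
    return out


def write_cds_table(records: Iterable[CdsAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_id\tgenome_id\tg_start\tg_end\tstrand\n")
        for r in records:
            fh.write(f"{r.protein_id}\t{r.genome_id}\t{r.g_start}\t{r.g_end}\t{r.strand}\n")


# ------------------------------------------------------------------ SAM


def read_sam_placements(path: str | Path) -> Iterator[Placement]:
    """Project SAM read placements into reference-frame base strings.

    CIGAR M/=/X consume read and reference; D emits '-' into the reference
    frame; I (and soft clips) drop read bases — naive-pileup semantics where
    inserted bases have no reference coordinate.
    """
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            seq = aln.query_sequence or ""
            out: list[str] = []
            qpos = 0
            for op, length in aln.cigartuples:
                if op in (0, 7, 8):  # M, =, X
                    out.append(seq[qpos : qpos + length])
                    qpos += length
                elif op == 1 or op == 4:  # I, S
                    qpos += length
                elif op == 2 or op == 3:  # D, N
                    out.append("-" * length)
                # H, P consume nothing we track
            bases = "".join(out)
            if bases:
                yield Placement(
                    read_id=aln.query_name or "",
                    ref_id=aln.reference_name or "",
                    ref_start=aln.reference_start,
                    bases=bases,
                )
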