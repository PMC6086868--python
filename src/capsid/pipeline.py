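"""End-to-end orchestration: recruit → scaffold → improve → classify → report.

The stages consume/produce the standard formats declared in ``aln_io``;
read-vs-reference and contig-vs-database alignments are produced by the
bundled stand-in aligner when no external alignment TSVs are supplied. Every
filter decision (dropped alignment sets, suppressed taxa, filtered contigs)
is emitted as a structured event so runs can be audited post hoc. Reruns
with identical inputs and configuration are bit-identical.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._align import SubjectIndex, revcomp, translate
from .aln_io import (
    AlignmentRecord,
    CdsAnnotation,
    Placement,
    SequenceRecord,
    write_alignments,
    write_fasta,
)
from .classify import (
    Classification,
    ClassifierParams,
    ReportRow,
    UnclassifiedRow,
    aggregate_report,
    classify_contig,
    viral_filter,
    pass1,
)
from .merge import Contig, MergeParams, abundance, improve, split_on_gaps
from .recruitment import (
    GenomeReadSet,
    RecruitParams,
    assign_reads,
    dereplicate,
    filter_alignments,
    jaccard_filter,
    normalize,
)
from .scaffold import (
    AA_ALPHABET,
    AaLayer,
    back_translate_tile,
    build_superscaffold,
    pileup_assemble,
)
from .synth import World, score_alignment
from .taxonomy import TaxonomyTree


class EventLog:
    """Structured JSON-lines log of pipeline and filter events."""

    def __init__(self) -> None:
        self.events: list[dict] = []

    def emit(self, kind: str, **fields) -> None:
        self.events.append({"event": kind, **fields})

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e, sort_keys=True) + "\n")


@dataclass
class NormalizeParams:
    enabled: bool = False
    k: int = 21
    target: int = 40


@dataclass
class AlignerParams:
    min_bits_read: float = 40.0
    min_bits_contig: float = 50.0


@dataclass
class PipelineConfig:
    recruit: RecruitParams = field(default_factory=RecruitParams)
    merge: MergeParams = field(default_factory=MergeParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    normalize: NormalizeParams = field(default_factory=NormalizeParams)
    aligner: AlignerParams = field(default_factory=AlignerParams)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {
            "recruit": RecruitParams,
            "merge": MergeParams,
            "classifier": ClassifierParams,
            "normalize": NormalizeParams,
            "aligner": AlignerParams,
        }
        kwargs = {}
        for key, value in data.items():
            if key not in sections:
                raise ValueError(f"unknown configuration section {key!r}")
            klass = sections[key]
            valid = set(klass.__dataclass_fields__)
            unknown = set(value) - valid
            if unknown:
                raise ValueError(
                    f"unknown key(s) in section {key!r}: {sorted(unknown)}"
                )
            kwargs[key] = klass(**value)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class PipelineResult:
    report: list[ReportRow]
    unclassified: list[UnclassifiedRow]
    classifications: list[Classification]
    contigs: list[Contig]
    abundances: dict[str, int]
    readsets: list[GenomeReadSet]
    log: EventLog
    multiplicity: dict[str, int]


# --------------------------------------------------------------- alignment


def align_reads_to_db(
    reads: list[SequenceRecord],
    nt_entries: list[SequenceRecord],
    aa_entries: list[SequenceRecord],
    entry_taxid: dict[str, int],
    min_bits: float = 40.0,
) -> tuple[list[AlignmentRecord], list[AlignmentRecord]]:
    """All-vs-all read alignment with the stand-in aligner (desk scale)."""
    nt_records: list[AlignmentRecord] = []
    aa_records: list[AlignmentRecord] = []
    nt_idx = [(e, SubjectIndex(e.seq, k=13)) for e in nt_entries]
    aa_idx = [(e, SubjectIndex(e.seq, k=4, ambiguous="X")) for e in aa_entries]
    for read in reads:
        for entry, idx in nt_idx:
            rec = score_alignment(
                read, entry, "nt", entry_taxid[entry.id], index=idx, min_bits=min_bits
            )
            if rec is not None:
                nt_records.append(rec)
        for entry, idx in aa_idx:
            rec = score_alignment(
                read, entry, "aa", entry_taxid[entry.id], index=idx, min_bits=min_bits
            )
            if rec is not None:
                aa_records.append(rec)
    return nt_records, aa_records


def _oriented_segment(read_seq: str, rec: AlignmentRecord) -> str:
    seg = read_seq[rec.q_start - 1 : rec.q_end]
    return revcomp(seg) if rec.strand == "-" else seg


def _best_per_read(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    best: dict[str, AlignmentRecord] = {}
    for r in records:
        cur = best.get(r.query_id)
        if cur is None or (r.bits, r.subject_id) > (cur.bits, cur.subject_id):
            best[r.query_id] = r
    return [best[q] for q in sorted(best)]


# --------------------------------------------------------------- scaffolding


def build_genome_scaffold(
    readset: GenomeReadSet,
    reads_by_id: dict[str, SequenceRecord],
    genome_entry: SequenceRecord,
    proteins: dict[str, SequenceRecord],
    cds: list[CdsAnnotation],
    log: EventLog | None = None,
):
    """Super-scaffold for one recruited genome from its nt and aa evidence."""
    length = len(genome_entry.seq)
    placements = []
    nt_for_genome = [r for r in readset.nt_records if r.subject_id == genome_entry.id]
    for rec in _best_per_read(nt_for_genome):
        read = reads_by_id.get(rec.query_id)
        if read is None:
            continue
        bases = _oriented_segment(read.seq, rec)
        span = rec.s_end - rec.s_start + 1
        if len(bases) != span:  # ungapped records only; length guard
            bases = bases[:span]
        placements.append(Placement(rec.query_id, genome_entry.id, rec.s_start - 1, bases))
    nt_pileup = pileup_assemble(genome_entry.id, length, placements)

    aa_layers: list[AaLayer] = []
    cds_by_protein = {c.protein_id: c for c in cds if c.genome_id == genome_entry.id}
    for protein_id, c in sorted(cds_by_protein.items()):
        entry = proteins.get(protein_id)
        if entry is None:
            continue
        aa_recs = [r for r in readset.aa_records if r.subject_id == protein_id]
        if not aa_recs:
            continue
        pep_placements = []
        calls: dict[int, Counter] = {}
        for rec in _best_per_read(aa_recs):
            read = reads_by_id.get(rec.query_id)
            if read is None:
                continue
            nt_seg = _oriented_segment(read.seq, rec)
            pep = translate(nt_seg)
            n_res = rec.s_end - rec.s_start + 1
            pep = pep[:n_res]
            if not pep:
                continue
            pep_placements.append(
                Placement(rec.query_id, protein_id, rec.s_start - 1, pep)
            )
            # codon-wise nucleotide calls in genome coordinates
            for t in range(len(pep)):
                residue0 = rec.s_start - 1 + t
                codon = nt_seg[3 * t : 3 * t + 3]
                if len(codon) < 3:
                    break
                if c.strand == "+":
                    g0 = (c.g_start - 1) + 3 * residue0
                    ordered = codon
                else:
                    g0 = (c.g_end - 1) - 3 * residue0 - 2
                    ordered = revcomp(codon)
                for off in range(3):
                    pos = g0 + off
                    if 0 <= pos < length:
                        calls.setdefault(pos, Counter())[ordered[off]] += 1
        if not pep_placements:
            continue
        pep_pileup = pileup_assemble(
            protein_id, len(entry.seq), pep_placements, alphabet=AA_ALPHABET, mask_char="X"
        )
        read_calls = {}
        for pos, counter in calls.items():
            (base, n), *rest = counter.most_common(2)
            if not rest or rest[0][1] < n:  # strict majority only
                read_calls[pos] = base
        aa_layers.append(back_translate_tile(pep_pileup, c, length, read_calls))
    if log is not None:
        log.emit(
            "scaffold",
            genome=genome_entry.id,
            nt_placements=len(placements),
            aa_layers=len(aa_layers),
        )
    return build_superscaffold(genome_entry.id, nt_pileup, aa_layers)


# ------------------------------------------------------------------- stages


def run_pipeline(
    reads: list[SequenceRecord],
    references: list[SequenceRecord],
    proteins: list[SequenceRecord],
    cds: list[CdsAnnotation],
    tree: TaxonomyTree,
    entry_taxid: dict[str, int],
    entry_genome: dict[str, str],
    recruit_entries: set[str] | None = None,
    denovo_contigs: list[Contig] | None = None,
    config: PipelineConfig | None = None,
    log: EventLog | None = None,
) -> PipelineResult:
    """Run the full pipeline in memory.

    ``recruit_entries`` restricts recruitment to the viral database division;
    classification always runs against the comprehensive database (every
    entry in ``references`` + ``proteins``).
    """
    config = config or PipelineConfig()
    log = log or EventLog()

    # --- read reduction
    unique, multiplicity = dereplicate(reads)
    log.emit("dereplicate", input=len(reads), unique=len(unique))
    recruited_input = unique
    if config.normalize.enabled:
        recruited_input = normalize(
            unique, config.normalize.k, config.normalize.target
        )
        log.emit("normalize", input=len(unique), kept=len(recruited_input))

    # --- recruitment alignments (viral division only)
    recruit_ids = recruit_entries if recruit_entries is not None else set(entry_taxid)
    nt_entries = [e for e in references if e.id in recruit_ids]
    aa_entries = [e for e in proteins if e.id in recruit_ids]
    nt_raw, aa_raw = align_reads_to_db(
        recruited_input,
        nt_entries,
        aa_entries,
        entry_taxid,
        min_bits=config.aligner.min_bits_read,
    )
    nt_kept = filter_alignments(nt_raw, "nt", config.recruit)
    aa_kept = filter_alignments(aa_raw, "aa", config.recruit)
    log.emit(
        "filter_alignments",
        nt_in=len(nt_raw),
        nt_kept=len(nt_kept),
        aa_in=len(aa_raw),
        aa_kept=len(aa_kept),
    )
    readsets = assign_reads(
        nt_kept + aa_kept,
        entry_genome,
        warn=lambda msg: log.emit("warning", message=msg),
    )
    retained = jaccard_filter(readsets, config.recruit.jaccard_tau)
    for rs in readsets:
        if rs not in retained:
            log.emit(
                "jaccard_drop",
                genome=rs.genome_id,
                reads=len(rs.read_ids),
                tau=config.recruit.jaccard_tau,
            )
    log.emit("recruit", genomes=len(retained))

    # --- super-scaffolds → mapping contigs
    reads_by_id = {r.id: r for r in recruited_input}
    proteins_by_id = {p.id: p for p in proteins}
    refs_by_id = {r.id: r for r in references}
    contigs: list[Contig] = list(denovo_contigs or [])
    for rs in retained:
        genome_entry = refs_by_id.get(rs.genome_id)
        if genome_entry is None:
            log.emit("warning", message=f"no reference entry for {rs.genome_id}")
            continue
        scaffold = build_genome_scaffold(
            rs, reads_by_id, genome_entry, proteins_by_id, cds, log
        )
        pieces = split_on_gaps(scaffold, config.merge.min_contig_len)
        contigs.extend(pieces)
    log.emit("scaffold_contigs", n=len(contigs))

    # --- pre-improve non-viral filter against the comprehensive database
    contigs = _drop_nonviral(
        contigs, references, proteins, entry_taxid, tree, config, log
    )

    # --- iterative improvement on the dereplicated, non-normalized read set
    final_contigs, diag = improve(contigs, unique, config.merge)
    log.emit("improve", **{k: v for k, v in diag.items() if k != "circular"})
    for cid, length in diag["circular"]:
        log.emit("circular_overlap", contig=cid, length=length)

    abundances = abundance(final_contigs, unique, multiplicity, config.merge)
    log.emit("abundance", assigned=sum(abundances.values()))

    # --- classification against the comprehensive database
    classifications = []
    contig_records = {c.id: [] for c in final_contigs}
    nt_idx = [(e, SubjectIndex(e.seq, k=13)) for e in references]
    aa_idx = [(e, SubjectIndex(e.seq, k=4, ambiguous="X")) for e in proteins]
    for c in final_contigs:
        as_record = SequenceRecord(c.id, c.seq)
        for entry, idx in nt_idx:
            rec = score_alignment(
                as_record,
                entry,
                "nt",
                entry_taxid[entry.id],
                index=idx,
                min_bits=config.aligner.min_bits_contig,
            )
            if rec is not None:
                contig_records[c.id].append(rec)
        for entry, idx in aa_idx:
            rec = score_alignment(
                as_record,
                entry,
                "aa",
                entry_taxid[entry.id],
                index=idx,
                min_bits=config.aligner.min_bits_contig,
            )
            if rec is not None:
                contig_records[c.id].append(rec)
        cls = classify_contig(
            c.id, len(c.seq), contig_records[c.id], tree, config.classifier
        )
        classifications.append(cls)
        log.emit(
            "classify",
            contig=c.id,
            verdict=cls.verdict,
            taxid=cls.taxid,
            rank=cls.rank,
            pass1_best=round(cls.pass1_best, 2),
            volume=round(cls.total_volume, 2),
            reason=cls.reason,
        )

    report, unclassified = aggregate_report(
        classifications, abundances, tree, config.classifier
    )
    reported = {r.taxid for r in report}
    for c in classifications:
        if c.verdict == "classified" and c.taxid not in reported:
            agg = sum(
                x.pass1_best for x in classifications
                if x.verdict == "classified" and x.taxid == c.taxid
            )
            log.emit(
                "taxon_suppressed",
                taxid=c.taxid,
                aggregate_bits=round(agg, 2),
                threshold=config.classifier.min_taxon_bits,
            )
    log.emit("report", taxa=len(report), unclassified=len(unclassified))
    return PipelineResult(
        report=report,
        unclassified=unclassified,
        classifications=classifications,
        contigs=final_contigs,
        abundances=abundances,
        readsets=retained,
        log=log,
        multiplicity=multiplicity,
    )


def _drop_nonviral(
    contigs: list[Contig],
    references: list[SequenceRecord],
    proteins: list[SequenceRecord],
    entry_taxid: dict[str, int],
    tree: TaxonomyTree,
    config: PipelineConfig,
    log: EventLog,
) -> list[Contig]:
    """Filter contigs whose pass-one profile resolves outside Viruses."""
    kept = []
    nt_idx = [(e, SubjectIndex(e.seq, k=13)) for e in references]
    for c in contigs:
        as_record = SequenceRecord(c.id, c.seq)
        records = []
        for entry, idx in nt_idx:
            rec = score_alignment(
                as_record,
                entry,
                "nt",
                entry_taxid[entry.id],
                index=idx,
                min_bits=config.aligner.min_bits_contig,
            )
            if rec is not None:
                records.append(rec)
        if records:
            profile = pass1(records, len(c.seq), c.id)
            verdict, reason = viral_filter(profile, tree, config.classifier)
            if verdict == "filtered_nonviral":
                log.emit("contig_nonviral", contig=c.id, reason=reason)
                continue
        kept.append(c)
    return kept


def run_world(
    world: World,
    config: PipelineConfig | None = None,
    log: EventLog | None = None,
) -> PipelineResult:
    """Convenience entry: run the pipeline on a synthetic world."""
    return run_pipeline(
        reads=world.reads,
        references=world.references,
        proteins=world.proteins,
        cds=world.cds,
        tree=world.tree,
        entry_taxid=world.entry_taxid,
        entry_genome=world.entry_genome,
        recruit_entries=world.recruit_entries,
        config=config,
        log=log,
    )


# ----------------------------------------------------------------- scoring


@dataclass
class TruthScore:
    precision: float
    recall: float
    f_score: float
    tp: int
    fp: int
    fn: int


def score_vs_truth(reported_taxids: set[int], truth_taxids: set[int]) -> TruthScore:
    """Precision, recall and F-score of a reported taxon set against truth.

    P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R); taxa matched by taxid.
    """
    tp = len(reported_taxids & truth_taxids)
    fp = len(reported_taxids - truth_taxids)
    fn = len(truth_taxids - reported_taxids)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f_score = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return TruthScore(precision, recall, f_score, tp, fp, fn)


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Materialize pipeline outputs for post hoc analysis."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": out / "final_contigs.fna",
        "report": out / "taxon_report.tsv",
        "contig_calls": out / "contig_classifications.tsv",
        "abundance": out / "abundance.tsv",
        "log": out / "events.jsonl",
    }
    write_fasta(
        [SequenceRecord(c.id, c.seq) for c in result.contigs], paths["contigs"]
    )
    with open(paths["report"], "w") as fh:
        fh.write("taxid\tname\trank\tn_contigs\ttotal_bits\treads\tlongest_contig\n")
        for r in result.report:
            fh.write(
                f"{r.taxid}\t{r.name}\t{r.rank}\t{r.n_contigs}\t"
                f"{r.total_bits:.1f}\t{r.reads}\t{r.longest_contig}\n"
            )
        fh.write("# unclassified contigs >= min_report_len\n")
        for u in result.unclassified:
            fh.write(f"# {u.contig_id}\t{u.length}\t{u.reads}\t{u.reason}\n")
    with open(paths["contig_calls"], "w") as fh:
        fh.write("contig_id\tverdict\ttaxid\trank\tpass1_best\tvolume\treason\n")
        for c in result.classifications:
            fh.write(
                f"{c.contig_id}\t{c.verdict}\t{c.taxid or ''}\t{c.rank or ''}\t"
                f"{c.pass1_best:.1f}\t{c.total_volume:.1f}\t{c.reason}\n"
            )
    with open(paths["abundance"], "w") as fh:
        fh.write("contig_id\treads\n")
        for cid in sorted(result.abundances):
            fh.write(f"{cid}\t{result.abundances[cid]}\n")
    result.log.save(paths["log"])
    return paths
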