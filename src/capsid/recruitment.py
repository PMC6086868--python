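"""Read recruitment: dereplication, optional normalization, alignment
reporting thresholds, read→genome assignment, and Jaccard redundancy
filtering of candidate genome read sets.

The reporting thresholds are score-radius margins: an alignment survives iff
its bit score is within a margin of both the best score seen for its subject
and the best score seen for its query. Defaults follow the translated 20%
(subject) / 8% (query) and nucleotide 90%→10%-complement (see RecruitParams)
conventions used for viral read recruitment; all four are configuration.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from statistics import median

from .aln_io import AlignmentRecord, SequenceRecord


@dataclass
class RecruitParams:
    """Score-radius margins d: keep a record iff bits >= (1-d) * best.

    ``d_subject_aa=0.20`` / ``d_query_aa=0.08`` for translated alignments and
    ``d_subject_nt=0.90`` / ``d_query_nt=0.05`` for nucleotide alignments;
    ``jaccard_tau`` drops a genome read set lying within that Jaccard distance
    of a retained larger set (default 0.05, i.e. ≥95% similar).
    """

    d_subject_aa: float = 0.20
    d_query_aa: float = 0.08
    d_subject_nt: float = 0.90
    d_query_nt: float = 0.05
    jaccard_tau: float = 0.05

    def __post_init__(self) -> None:
        for name in ("d_subject_aa", "d_query_aa", "d_subject_nt", "d_query_nt", "jaccard_tau"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def margins(self, kind: str) -> tuple[float, float]:
        if kind == "nt":
            return self.d_subject_nt, self.d_query_nt
        if kind == "aa":
            return self.d_subject_aa, self.d_query_aa
        raise ValueError(f"unknown alignment kind {kind!r}")


@dataclass
class GenomeReadSet:
    genome_id: str
    read_ids: set[str] = field(default_factory=set)
    nt_records: list[AlignmentRecord] = field(default_factory=list)
    aa_records: list[AlignmentRecord] = field(default_factory=list)


def dereplicate(
    reads: list[SequenceRecord],
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Collapse exact-duplicate sequences, keeping first-seen order.

    Returns the unique reads and a multiplicity map keyed by the retained
    read's id, for later abundance re-expansion.
    """
    by_seq: "OrderedDict[str, SequenceRecord]" = OrderedDict()
    multiplicity: dict[str, int] = {}
    for r in reads:
        kept = by_seq.get(r.seq)
        if kept is None:
            by_seq[r.seq] = r
            multiplicity[r.id] = 1
        else:
            multiplicity[kept.id] += 1
    return list(by_seq.values()), multiplicity


def normalize(
    reads: list[SequenceRecord], k: int = 21, target: int = 40
) -> list[SequenceRecord]:
    """Simplified digital normalization: median k-mer depth capping.

    Streams reads in input order against a running k-mer count table; a read
    is discarded iff the median count of its k-mers already exceeds
    ``target``. Reads shorter than k pass through untouched. This is a
    deliberately simple coverage flattener, not a streaming-sketch
    implementation.
    """
    counts: dict[str, int] = {}
    kept = []
    for r in reads:
        if len(r.seq) < k:
            kept.append(r)
            continue
        kmers = [r.seq[i : i + k] for i in range(len(r.seq) - k + 1)]
        if median(counts.get(km, 0) for km in kmers) > target:
            continue
        kept.append(r)
        for km in kmers:
            counts[km] = counts.get(km, 0) + 1
    return kept


def filter_alignments(
    records: list[AlignmentRecord], kind: str, params: RecruitParams
) -> list[AlignmentRecord]:
    """Apply the per-subject and per-query score-radius reporting thresholds.

    Keep r iff bits(r) >= (1-d_subject)*best-for-r.subject and
    bits(r) >= (1-d_query)*best-for-r.query. Idempotent: survivors define the
    same maxima they were tested against.
    """
    d_subject, d_query = params.margins(kind)
    best_subject: dict[str, float] = {}
    best_query: dict[str, float] = {}
    for r in records:
        if r.kind != kind:
            raise ValueError(f"record kind {r.kind} does not match {kind}")
        best_subject[r.subject_id] = max(best_subject.get(r.subject_id, 0.0), r.bits)
        best_query[r.query_id] = max(best_query.get(r.query_id, 0.0), r.bits)
    return [
        r
        for r in records
        if r.bits >= (1.0 - d_subject) * best_subject[r.subject_id]
        and r.bits >= (1.0 - d_query) * best_query[r.query_id]
    ]


def assign_reads(
    records: list[AlignmentRecord],
    entry2genome: dict[str, str],
    warn=None,
) -> list[GenomeReadSet]:
    """Assign each read to every genome any surviving record points to.

    Records whose subject has no genome mapping are skipped with a warning.
    Output is sorted by genome_id for determinism.
    """
    sets: dict[str, GenomeReadSet] = {}
    for r in records:
        genome = entry2genome.get(r.subject_id)
        if genome is None:
            if warn is not None:
                warn(f"subject {r.subject_id} has no genome mapping; record skipped")
            continue
        grs = sets.setdefault(genome, GenomeReadSet(genome))
        grs.read_ids.add(r.query_id)
        (grs.nt_records if r.kind == "nt" else grs.aa_records).append(r)
    return [sets[g] for g in sorted(sets)]


def jaccard_distance(a: set[str], b: set[str]) -> float:
    union = len(a | b)
    if union == 0:
        return 0.0
    return 1.0 - len(a & b) / union


def jaccard_filter(
    readsets: list[GenomeReadSet], tau: float = 0.05
) -> list[GenomeReadSet]:
    """Drop read sets nearly identical to a retained larger-or-equal set.

    Sets are visited by size descending (genome_id breaks ties); a set is
    dropped iff its Jaccard distance to some already-retained set is <= tau.
    The largest set is always retained.
    """
    ordered = sorted(readsets, key=lambda s: (-len(s.read_ids), s.genome_id))
    retained: list[GenomeReadSet] = []
    for cand in ordered:
        if any(jaccard_distance(kept.read_ids, cand.read_ids) <= tau for kept in retained):
            continue
        retained.append(cand)
    return retained
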