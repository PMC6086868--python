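"""Self-contained synthetic test worlds.

Generates an internally consistent mini ecosystem — a small taxonomy, viral
reference genomes with CDS annotations, diverged "sample" viruses, an
unrelated host genome, error-bearing reads, and a truth table — emulating a
mock-community experiment: known viruses at chosen coverages spiked over a
host background. Alignment records are produced by an honest stand-in
aligner (exact-seed, ungapped extension) whose bit scores are strictly
monotone in mismatch count and calibrated so a perfect nucleotide alignment
scores exactly 2.0 bits per base.

What this emulates — and what it does not: substitution divergence and
substitution sequencing error with uniform read starts; no indels, no
quality-score model, no platform error profile, no GC or coverage bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._align import (
    AA_MATCH,
    AA_MISMATCH,
    SubjectIndex,
    aa_bits,
    best_local_hit,
    nt_bits,
    revcomp,
    translate,
)
from .aln_io import (
    AlignmentRecord,
    CdsAnnotation,
    SequenceRecord,
    write_cds_table,
    write_fasta,
    write_fastq,
)
from .classify import VIRUSES_TAXID
from .taxonomy import TaxonomyTree, load_taxonomy, write_taxonomy

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one synthetic world.

    divergence is the per-base substitution fraction between each planted
    virus and its nearest database reference; coverage is mean read depth
    per virus; host_fraction is the fraction of all reads drawn from the
    (non-viral) host genome.
    """

    seed: int = 1
    n_viruses: int = 4
    genome_len: tuple[int, int] = (3000, 4000)
    divergence: tuple[float, float] = (0.05, 0.15)
    read_len: int = 150
    coverage: float = 20.0
    error_rate: float = 0.01
    host_fraction: float = 0.30
    host_genome_len: int = 10000

    def __post_init__(self) -> None:
        lo, hi = self.divergence
        if not (0.0 <= lo <= hi < 0.5):
            raise ValueError("divergence must lie in [0, 0.5)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must lie in [0, 0.1]")


@dataclass
class World:
    """One generated world, in memory; ``write`` materializes it as files."""

    config: SimConfig
    tree: TaxonomyTree
    tax_nodes: dict[int, tuple[int, str, str]]
    references: list[SequenceRecord]  # nt database entries (viral + host)
    proteins: list[SequenceRecord]  # aa database entries
    cds: list[CdsAnnotation]
    reads: list[SequenceRecord]
    truth_reads: dict[str, int]  # read id → source taxid
    truth_taxa: dict[int, str]  # planted viral taxid → name
    true_genomes: list[SequenceRecord]  # the diverged sample viruses
    entry_taxid: dict[str, int]  # database entry id → subject taxid
    entry_genome: dict[str, str]  # database entry id → genome id
    host_taxid: int = 0
    recruit_entries: set[str] = field(default_factory=set)  # viral-division ids

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "nodes": out / "nodes.dmp",
            "names": out / "names.dmp",
            "references": out / "references.fna",
            "proteins": out / "proteins.faa",
            "cds": out / "cds.tsv",
            "reads": out / "reads.fastq",
            "truth_reads": out / "truth_reads.tsv",
            "truth_taxa": out / "truth_taxa.tsv",
            "true_genomes": out / "true_genomes.fna",
            "entry_map": out / "entry_map.tsv",
        }
        write_taxonomy(self.tax_nodes, paths["nodes"], paths["names"])
        write_fasta(self.references, paths["references"])
        write_fasta(self.proteins, paths["proteins"])
        write_cds_table(self.cds, paths["cds"])
        write_fastq(self.reads, paths["reads"])
        write_fasta(self.true_genomes, paths["true_genomes"])
        with open(paths["truth_reads"], "w") as fh:
            fh.write("# read_id\tsource_taxid\n")
            for rid in sorted(self.truth_reads):
                fh.write(f"{rid}\t{self.truth_reads[rid]}\n")
        with open(paths["truth_taxa"], "w") as fh:
            fh.write("# taxid\tname\n")
            for t in sorted(self.truth_taxa):
                fh.write(f"{t}\t{self.truth_taxa[t]}\n")
        with open(paths["entry_map"], "w") as fh:
            fh.write("# entry_id\tgenome_id\ttaxid\trecruit\n")
            for e in sorted(self.entry_taxid):
                fh.write(
                    f"{e}\t{self.entry_genome[e]}\t{self.entry_taxid[e]}\t"
                    f"{int(e in self.recruit_entries)}\n"
                )
        return paths


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _strip_stops(seq: str, start0: int, end0: int) -> str:
    """Recode in-frame stop codons (to TGG) so CDS regions translate cleanly."""
    s = list(seq)
    for i in range(start0, end0 - 2, 3):
        codon = "".join(s[i : i + 3])
        if codon in ("TAA", "TAG", "TGA"):
            s[i : i + 3] = "TGG"
    return "".join(s)


def make_world(config: SimConfig) -> World:
    """Build one deterministic world from the study conditions in config."""
    rng = np.random.default_rng(config.seed)

    # --- taxonomy: root / two superkingdoms / one viral family, two genera
    nodes: dict[int, tuple[int, str, str]] = {
        1: (1, "no rank", "root"),
        2: (1, "superkingdom", "Bacteria"),
        VIRUSES_TAXID: (1, "superkingdom", "Viruses"),
        11000: (VIRUSES_TAXID, "family", "Synthviridae"),
    }
    host_taxid = 2001
    nodes[2001] = (2, "species", "Synthibacter hostis")
    genus_ids = []
    species_ids = []
    for i in range(config.n_viruses):
        genus = 12001 + i // 2
        if genus not in nodes:
            nodes[genus] = (11000, "genus", f"Synthvirus{'AB'[i // 2 % 2]}")
            genus_ids.append(genus)
        species = 13001 + i
        nodes[species] = (genus, "species", f"synthetic virus {i + 1}")
        species_ids.append(species)
    tree = _tree_from_nodes(nodes)

    # --- reference genomes, CDS annotations, proteins
    references: list[SequenceRecord] = []
    proteins: list[SequenceRecord] = []
    cds_rows: list[CdsAnnotation] = []
    entry_taxid: dict[str, int] = {}
    entry_genome: dict[str, str] = {}
    recruit_entries: set[str] = set()
    true_genomes: list[SequenceRecord] = []
    truth_taxa: dict[int, str] = {}

    lo, hi = config.genome_len
    div_lo, div_hi = config.divergence
    for i, species in enumerate(species_ids):
        length = int(rng.integers(lo, hi + 1))
        gid = f"ref_v{i + 1}"
        seq = _random_seq(rng, length)
        # two CDS per genome: one on each strand, codon-complete, in-bounds
        cds_len = 3 * max(60, (length // 4) // 3)
        c1 = CdsAnnotation(f"{gid}_p1", gid, 31, 30 + cds_len, "+")
        c2_end = length - 30
        c2 = CdsAnnotation(f"{gid}_p2", gid, c2_end - cds_len + 1, c2_end, "-")
        seq = _strip_stops(seq, c1.g_start - 1, c1.g_end)
        rc = revcomp(seq)
        rc_start0 = length - c2.g_end
        rc = _strip_stops(rc, rc_start0, rc_start0 + cds_len)
        seq = revcomp(rc)
        references.append(SequenceRecord(gid, seq))
        entry_taxid[gid] = species
        entry_genome[gid] = gid
        recruit_entries.add(gid)
        for c in (c1, c2):
            sub = seq[c.g_start - 1 : c.g_end]
            if c.strand == "-":
                sub = revcomp(sub)
            proteins.append(SequenceRecord(c.protein_id, translate(sub)))
            cds_rows.append(c)
            entry_taxid[c.protein_id] = species
            entry_genome[c.protein_id] = gid
            recruit_entries.add(c.protein_id)
        divergence = float(rng.uniform(div_lo, div_hi))
        true_genomes.append(
            SequenceRecord(f"sample_v{i + 1}", _mutate(rng, seq, divergence))
        )
        truth_taxa[species] = nodes[species][2]

    host_id = "ref_host"
    host_seq = _random_seq(rng, config.host_genome_len)
    references.append(SequenceRecord(host_id, host_seq))
    entry_taxid[host_id] = host_taxid
    entry_genome[host_id] = host_id

    # --- reads: uniform starts over each sample virus, then host background
    reads: list[SequenceRecord] = []
    truth_reads: dict[str, int] = {}
    n_viral = 0
    for i, tg in enumerate(true_genomes):
        n = max(1, int(round(len(tg.seq) * config.coverage / config.read_len)))
        n_viral += n
        starts = rng.integers(0, max(1, len(tg.seq) - config.read_len + 1), size=n)
        for j, start in enumerate(starts):
            frag = tg.seq[start : start + config.read_len]
            frag = _mutate(rng, frag, config.error_rate)
            if rng.random() < 0.5:
                frag = revcomp(frag)
            rid = f"v{i + 1}_r{j + 1}"
            reads.append(SequenceRecord(rid, frag))
            truth_reads[rid] = entry_taxid[f"ref_v{i + 1}"]
    if config.host_fraction > 0:
        n_host = int(round(n_viral * config.host_fraction / (1.0 - config.host_fraction)))
        starts = rng.integers(
            0, max(1, len(host_seq) - config.read_len + 1), size=n_host
        )
        for j, start in enumerate(starts):
            frag = _mutate(
                rng, host_seq[start : start + config.read_len], config.error_rate
            )
            if rng.random() < 0.5:
                frag = revcomp(frag)
            rid = f"h_r{j + 1}"
            reads.append(SequenceRecord(rid, frag))
            truth_reads[rid] = host_taxid

    return World(
        config=config,
        tree=tree,
        tax_nodes=nodes,
        references=references,
        proteins=proteins,
        cds=cds_rows,
        reads=reads,
        truth_reads=truth_reads,
        truth_taxa=truth_taxa,
        true_genomes=true_genomes,
        entry_taxid=entry_taxid,
        entry_genome=entry_genome,
        host_taxid=host_taxid,
        recruit_entries=recruit_entries,
    )


def _tree_from_nodes(nodes: dict[int, tuple[int, str, str]]) -> TaxonomyTree:
    import io as _io
    import tempfile

    with tempfile.TemporaryDirectory() as d:
        np_, nm = Path(d) / "nodes.dmp", Path(d) / "names.dmp"
        write_taxonomy(nodes, np_, nm)
        return load_taxonomy(np_, nm)


# ------------------------------------------------------------------ aligner


def score_alignment(
    query: SequenceRecord,
    subject: SequenceRecord,
    kind: str,
    subject_taxid: int,
    *,
    index: SubjectIndex | None = None,
    min_bits: float = 40.0,
) -> AlignmentRecord | None:
    """Stand-in for an external aligner: best local ungapped alignment.

    kind="nt": both sequences are nucleotide; both strands are tried.
    kind="aa": the query is nucleotide, the subject is a protein; all six
    reading frames are tried and query coordinates are reported in
    nucleotide space on the forward strand (translated-search convention).
    Returns None when no seeded alignment reaches ``min_bits``.
    """
    if kind == "nt":
        idx = index if index is not None else SubjectIndex(subject.seq, k=13)
        best = None
        for strand, seq in (("+", query.seq), ("-", revcomp(query.seq))):
            hit = best_local_hit(seq, idx)
            if hit is None:
                continue
            bits = nt_bits(hit.score)
            if best is None or bits > best[0]:
                n = len(query.seq)
                if strand == "+":
                    q_start, q_end = hit.q_start + 1, hit.q_end
                else:
                    q_start, q_end = n - hit.q_end + 1, n - hit.q_start
                best = (bits, strand, q_start, q_end, hit)
        if best is None or best[0] < min_bits:
            return None
        bits, strand, q_start, q_end, hit = best
        return AlignmentRecord(
            query_id=query.id,
            subject_id=subject.id,
            subject_taxid=subject_taxid,
            kind="nt",
            q_start=q_start,
            q_end=q_end,
            s_start=hit.s_start + 1,
            s_end=hit.s_end,
            identity=hit.identity,
            bits=bits,
            strand=strand,
        )
    if kind != "aa":
        raise ValueError(f"unknown alignment kind {kind!r}")

    idx = index if index is not None else SubjectIndex(subject.seq, k=4, ambiguous="X")
    n = len(query.seq)
    best = None
    for strand, oriented in (("+", query.seq), ("-", revcomp(query.seq))):
        for frame in range(3):
            pep = translate(oriented, frame)
            if len(pep) < idx.k:
                continue
            hit = best_local_hit(pep, idx, match=AA_MATCH, mismatch=AA_MISMATCH)
            if hit is None:
                continue
            bits = aa_bits(hit.score)
            if best is None or bits > best[0]:
                # peptide span → nt span on the oriented sequence
                o_start = frame + 3 * hit.q_start
                o_end = frame + 3 * hit.q_end - 1  # inclusive, 0-based
                if strand == "+":
                    q_start, q_end = o_start + 1, o_end + 1
                else:
                    q_start, q_end = n - o_end, n - o_start
                best = (bits, strand, q_start, q_end, hit)
    if best is None or best[0] < min_bits:
        return None
    bits, strand, q_start, q_end, hit = best
    return AlignmentRecord(
        query_id=query.id,
        subject_id=subject.id,
        subject_taxid=subject_taxid,
        kind="aa",
        q_start=q_start,
        q_end=q_end,
        s_start=hit.s_start + 1,
        s_end=hit.s_end,
        identity=hit.identity,
        bits=bits,
        strand=strand,
    )


def subsample_reads(
    reads: list[SequenceRecord], fraction: float, seed: int
) -> list[SequenceRecord]:
    """Keep each read independently with probability ``fraction``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return list(reads)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < fraction
    return [r for r, k in zip(reads, keep) if k]
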