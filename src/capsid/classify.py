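"""Two-pass bits-per-base taxonomic classification of contigs.

Pass one spreads each alignment's bit score uniformly over the query bases it
covers (bits / aligned query length) and keeps, per position and per subject
taxon, the best such per-base score; summing a taxon's per-position bests
gives its best potential alignment independent of subject contiguity. Pass
two re-scores every alignment event position-by-position against the global
per-position top, damping each entry's own per-base score by a power of its
relative accuracy r = s / global_top — exponent p for nucleotide records and
p^p for translated records, so protein mismatches are penalized far more
heavily — and sums the damped contributions over all database entries of a
taxon into its "volume", an aggregate-identity-like store of how much of the
database consistently supports that taxon.

Classification then gates on pass one (viral-superkingdom filter and a
minimum-information threshold), admits all taxa within a dynamic score
radius of the best taxon, and resolves them with a rank-wise lowest common
ancestor walk whose majority threshold relaxes as total volume grows: a
poorly represented taxon needs a commanding majority, a well represented one
only a slight majority.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aln_io import AlignmentRecord
from .taxonomy import TaxonomyTree

#: NCBI taxid of the superkingdom Viruses.
VIRUSES_TAXID = 10239


@dataclass
class ClassifierParams:
    """Tunables of the two-pass classifier.

    w_nt_exponent : relative-accuracy damping exponent p for nucleotide
        records; translated records use p**p (w_aa_exponent overrides).
    b_max : bits per base of a perfect nucleotide self-alignment (information
        ceiling used to judge how strong the best hit is); translated-
        dominant contigs may warrant a different ceiling.
    radius_min / radius_max : bounds of the dynamic candidate radius, as a
        fraction of the best pass-one score.
    lca_base_majority / lca_excess / lca_volume_scale : the majority
        threshold is base + excess / (1 + V / scale), capped at 0.95, with V
        the total candidate volume in bits.
    min_contig_bits : contigs whose best pass-one score falls below this are
        dropped as low-information (default 300 bits).
    min_taxon_bits : taxa whose aggregate pass-one bits across all contigs
        fall below this are suppressed from the report (default 1000 bits).
    viral_base_fraction : a contig is dropped when more than this fraction of
        its aligning bases resolve outside the viral superkingdom.
    """

    w_nt_exponent: float = 3.0
    w_aa_exponent: float | None = None  # defaults to p**p
    b_max: float = 2.0
    radius_min: float = 0.02
    radius_max: float = 0.25
    lca_base_majority: float = 0.5
    lca_excess: float = 0.45
    lca_volume_scale: float = 2000.0
    majority_cap: float = 0.95
    min_contig_bits: float = 300.0
    min_taxon_bits: float = 1000.0
    viral_base_fraction: float = 0.5
    viral_taxid: int = VIRUSES_TAXID
    min_report_len: int = 500

    def __post_init__(self) -> None:
        if self.w_nt_exponent < 1:
            raise ValueError("w_nt_exponent must be >= 1")
        if not 0 < self.radius_min <= self.radius_max < 1:
            raise ValueError("need 0 < radius_min <= radius_max < 1")
        if self.min_contig_bits <= 0 or self.min_taxon_bits <= 0:
            raise ValueError("bit thresholds must be positive")

    @property
    def aa_exponent(self) -> float:
        if self.w_aa_exponent is not None:
            return self.w_aa_exponent
        return self.w_nt_exponent**self.w_nt_exponent

    def weight(self, r: float | np.ndarray, kind: str) -> float | np.ndarray:
        """Relative-accuracy damping w(r) = r^p (nt) or r^(p^p) (aa)."""
        exp = self.w_nt_exponent if kind == "nt" else self.aa_exponent
        return r**exp

    def majority_threshold(self, total_volume: float) -> float:
        m = self.lca_base_majority + self.lca_excess / (
            1.0 + total_volume / self.lca_volume_scale
        )
        return min(m, self.majority_cap)


@dataclass
class Pass1Profile:
    contig_id: str
    length: int
    top_per_taxon: dict[int, np.ndarray]
    global_top: np.ndarray
    pass1_score: dict[int, float]

    @property
    def best_taxon(self) -> int:
        """Top pass-one taxon; ties break to the smaller taxid."""
        return min(self.pass1_score, key=lambda t: (-self.pass1_score[t], t))

    @property
    def best_score(self) -> float:
        return max(self.pass1_score.values()) if self.pass1_score else 0.0


@dataclass
class Pass2Volume:
    volume: dict[int, float]
    per_entry: dict[tuple[int, str], float] = field(default_factory=dict)


@dataclass
class Classification:
    contig_id: str
    taxid: int | None
    rank: str | None
    pass1_best: float
    total_volume: float
    verdict: str  # {"classified", "filtered_nonviral", "filtered_lowinfo"}
    reason: str
    length: int = 0


def pass1(
    records: list[AlignmentRecord], length: int, contig_id: str = ""
) -> Pass1Profile:
    """Per-position, per-taxon best bits-per-base profile of one contig.

    Each record contributes s = bits / aligned query length uniformly over
    its query span; overlapping records of one taxon keep the positional max,
    never the sum, so pass-one score is the taxon's best *potential*
    alignment.
    """
    top: dict[int, np.ndarray] = {}
    for r in records:
        if r.q_start < 1 or r.q_end > length:
            raise ValueError(
                f"record {r.query_id}→{r.subject_id} spans [{r.q_start}, {r.q_end}] "
                f"outside contig of length {length}"
            )
        s = r.bits / r.aligned_len_q
        arr = top.get(r.subject_taxid)
        if arr is None:
            arr = np.zeros(length)
            top[r.subject_taxid] = arr
        span = slice(r.q_start - 1, r.q_end)
        np.maximum(arr[span], s, out=arr[span])
    global_top = np.zeros(length)
    for arr in top.values():
        np.maximum(global_top, arr, out=global_top)
    scores = {t: float(arr.sum()) for t, arr in top.items()}
    return Pass1Profile(
        contig_id=contig_id,
        length=length,
        top_per_taxon=top,
        global_top=global_top,
        pass1_score=scores,
    )


def pass2(
    records: list[AlignmentRecord],
    global_top: np.ndarray,
    params: ClassifierParams,
) -> Pass2Volume:
    """Volume: relative-accuracy-damped per-base scores summed per taxon.

    Per record and covered position p: r = s / global_top[p] ∈ (0, 1], and the
    contribution is s·w(r) — the entry's own score damped by how close it
    comes to the best anything achieved there. Contributions sum over
    positions and over database entries (duplicated entries double volume;
    pass one is immune to duplication by its max semantics).
    """
    volume: dict[int, float] = {}
    per_entry: dict[tuple[int, str], float] = {}
    for r in records:
        span = slice(r.q_start - 1, r.q_end)
        g = global_top[span]
        if np.any(g <= 0):
            raise ValueError(
                f"global top is zero under record {r.query_id}→{r.subject_id}; "
                "pass1 must precede pass2 on the same record set"
            )
        s = r.bits / r.aligned_len_q
        contrib = float(np.sum(s * params.weight(np.minimum(s / g, 1.0), r.kind)))
        key = (r.subject_taxid, r.subject_id)
        per_entry[key] = per_entry.get(key, 0.0) + contrib
        volume[r.subject_taxid] = volume.get(r.subject_taxid, 0.0) + contrib
    return Pass2Volume(volume=volume, per_entry=per_entry)


def viral_filter(
    profile: Pass1Profile, tree: TaxonomyTree, params: ClassifierParams
) -> tuple[str, str]:
    """Gate on pass one: (verdict, reason).

    A contig fails if its top pass-one taxon is outside the viral
    superkingdom, or if more than ``viral_base_fraction`` of its aligning
    bases have their global top achieved only by non-viral taxa (a tie at a
    position counts as viral).
    """
    if not profile.pass1_score:
        return "filtered_lowinfo", "no alignments"
    top_taxon = profile.best_taxon
    viral = {
        t: tree.is_descendant(t, params.viral_taxid) for t in profile.pass1_score
    }
    if not viral[top_taxon]:
        return (
            "filtered_nonviral",
            f"top pass-one taxon {top_taxon} outside superkingdom Viruses",
        )
    aligned = profile.global_top > 0
    n_aligned = int(aligned.sum())
    if n_aligned == 0:
        return "filtered_lowinfo", "no aligned bases"
    viral_top = np.zeros(profile.length)
    for t, arr in profile.top_per_taxon.items():
        if viral[t]:
            np.maximum(viral_top, arr, out=viral_top)
    nonviral_frac = float(
        np.sum(aligned & (viral_top < profile.global_top)) / n_aligned
    )
    if nonviral_frac > params.viral_base_fraction:
        return (
            "filtered_nonviral",
            f"{nonviral_frac:.1%} of aligning bases resolve outside Viruses "
            f"(> {params.viral_base_fraction:.0%})",
        )
    return "classified", f"viral top taxon; non-viral base fraction {nonviral_frac:.1%}"


def candidate_set(profile: Pass1Profile, params: ClassifierParams) -> set[int]:
    """Taxa within the dynamic score radius of the best pass-one taxon.

    The radius widens as the best hit weakens relative to a hypothetical
    perfect self-alignment (length × b_max bits): quality q = best/self_max
    gives radius ρ = radius_min + (radius_max − radius_min)·(1 − q); admit
    taxa scoring ≥ (1 − ρ)·best.
    """
    best = profile.best_score
    self_max = profile.length * params.b_max
    q = min(max(best / self_max, 0.0), 1.0) if self_max > 0 else 0.0
    radius = params.radius_min + (params.radius_max - params.radius_min) * (1.0 - q)
    cutoff = (1.0 - radius) * best
    return {t for t, score in profile.pass1_score.items() if score >= cutoff}


def lca_classify(
    candidates: set[int],
    volumes: dict[int, float],
    tree: TaxonomyTree,
    params: ClassifierParams,
) -> tuple[int, str]:
    """Volume-weighted rank-wise LCA with a dynamic majority threshold.

    Walk the configured rank ladder leaf→root; at each rank project candidate
    volumes onto their ancestors at that rank and stop at the first taxon
    holding more than m(V) of the total volume V. If no rank yields a
    majority, fall back to the volume-maximal taxon strictly below the viral
    superkingdom. Ties break to the numerically smaller taxid.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    total = sum(volumes.get(t, 0.0) for t in candidates)
    if total <= 0:
        raise ValueError("candidates carry no volume")
    m = params.majority_threshold(total)
    for rank in tree.ranks:
        projected: dict[int, float] = {}
        for t in candidates:
            anc = tree.ancestor_at_rank(t, rank)
            if anc is not None:
                projected[anc] = projected.get(anc, 0.0) + volumes.get(t, 0.0)
        winners = sorted(
            (t for t, v in projected.items() if v > m * total),
            key=lambda t: (-projected[t], t),
        )
        if winners:
            return winners[0], rank
    below = [
        t
        for t in candidates
        if t != params.viral_taxid and tree.is_descendant(t, params.viral_taxid)
    ]
    pool = below or sorted(candidates)
    winner = min(pool, key=lambda t: (-volumes.get(t, 0.0), t))
    return winner, tree.node(winner).rank


def classify_contig(
    contig_id: str,
    length: int,
    records: list[AlignmentRecord],
    tree: TaxonomyTree,
    params: ClassifierParams | None = None,
) -> Classification:
    """Full per-contig pipeline: pass1 → viral filter → information gate →
    dynamic-radius candidates → pass2 → rank-wise LCA.

    Pass-one scores act only as a barrier to entry for the LCA engine; the
    LCA itself is driven by pass-two volumes.
    """
    params = params or ClassifierParams()
    profile = pass1(records, length, contig_id)
    verdict, reason = viral_filter(profile, tree, params)
    if verdict != "classified":
        top = profile.best_taxon if profile.pass1_score else None
        return Classification(
            contig_id, top, None, profile.best_score, 0.0, verdict, reason, length
        )
    if profile.best_score < params.min_contig_bits:
        return Classification(
            contig_id,
            profile.best_taxon,
            None,
            profile.best_score,
            0.0,
            "filtered_lowinfo",
            f"best pass-one score {profile.best_score:.1f} bits "
            f"< {params.min_contig_bits:.0f}",
            length,
        )
    candidates = {
        t
        for t in candidate_set(profile, params)
        if tree.is_descendant(t, params.viral_taxid)
    }
    volumes = pass2(records, profile.global_top, params).volume
    taxid, rank = lca_classify(candidates, volumes, tree, params)
    total = sum(volumes.get(t, 0.0) for t in candidates)
    return Classification(
        contig_id,
        taxid,
        rank,
        profile.best_score,
        total,
        "classified",
        f"LCA over {len(candidates)} candidate taxa at majority threshold "
        f"{params.majority_threshold(total):.3f}",
        length,
    )


@dataclass
class ReportRow:
    taxid: int
    name: str
    rank: str
    n_contigs: int
    total_bits: float
    reads: int
    longest_contig: int


@dataclass
class UnclassifiedRow:
    contig_id: str
    length: int
    reads: int
    reason: str


def aggregate_report(
    classifications: list[Classification],
    abundances: dict[str, int],
    tree: TaxonomyTree,
    params: ClassifierParams | None = None,
) -> tuple[list[ReportRow], list[UnclassifiedRow]]:
    """Aggregate per-contig calls into the final taxon table.

    Classified contigs group by taxid; taxa with aggregate pass-one bits
    below ``min_taxon_bits`` are suppressed. Contigs at least
    ``min_report_len`` long that were filtered or unclassifiable are listed
    in a separate unclassified section rather than silently dropped.
    """
    params = params or ClassifierParams()
    by_taxon: dict[int, list[Classification]] = {}
    unclassified: list[UnclassifiedRow] = []
    for c in classifications:
        if c.verdict == "classified" and c.taxid is not None:
            by_taxon.setdefault(c.taxid, []).append(c)
        elif c.length >= params.min_report_len:
            unclassified.append(
                UnclassifiedRow(
                    c.contig_id, c.length, abundances.get(c.contig_id, 0), c.reason
                )
            )
    rows = []
    for taxid in sorted(by_taxon):
        members = by_taxon[taxid]
        total_bits = sum(c.pass1_best for c in members)
        if total_bits < params.min_taxon_bits:
            continue
        rows.append(
            ReportRow(
                taxid=taxid,
                name=tree.name_of(taxid) if taxid in tree else str(taxid),
                rank=by_taxon[taxid][0].rank or "",
                n_contigs=len(members),
                total_bits=total_bits,
                reads=sum(abundances.get(c.contig_id, 0) for c in members),
                longest_contig=max(c.length for c in members),
            )
        )
    rows.sort(key=lambda r: (-r.total_bits, r.taxid))
    return rows, unclassified
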