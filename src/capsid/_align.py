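"""Seeded ungapped local alignment used by the stand-in aligner and read mapper.

This is deliberately a small, exact-seed + ungapped-extension aligner adequate
for desk-scale worlds (tens of kilobases). It is honest rather than sensitive:
scores are strictly monotone in mismatch count for a fixed span, and a perfect
nucleotide alignment yields a calibrated bits-per-base ceiling. Real-scale use
consumes external aligner output via the tabular formats instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# bits = BITS_PER_MATCH_NT * score for nucleotide alignments; chosen so a
# perfect self-alignment scores exactly 2.0 bits per base (the information
# ceiling of a 4-letter alphabet).
BITS_PER_MATCH_NT = 2.0
# Amino-acid alignments are scored +2/-1 per residue; the scale below puts a
# perfect translated alignment at 1.5 bits per *nucleotide* base (4.5 bits per
# codon), deliberately under the nucleotide ceiling so that at equal identity
# nucleotide evidence dominates.
AA_MATCH = 2
AA_MISMATCH = -1
BITS_PER_SCORE_AA = 4.5 / AA_MATCH


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class LocalHit:
    """One ungapped local alignment segment (0-based, half-open, query frame)."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: float
    matches: int
    length: int

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0


class SubjectIndex:
    """k-mer position index over one subject sequence.

    Built once per subject and reused across queries; ambiguous letters (N/X)
    never seed.
    """

    def __init__(self, seq: str, k: int = 13, ambiguous: str = "N"):
        self.seq = seq.upper()
        self.k = k
        self.ambiguous = ambiguous
        self.arr = _as_bytes(self.seq)
        self.kmers: dict[str, list[int]] = {}
        bad = set(ambiguous) | {"*"}
        for i in range(len(self.seq) - k + 1):
            kmer = self.seq[i : i + k]
            if bad.intersection(kmer):
                continue
            self.kmers.setdefault(kmer, []).append(i)

    def seed_diagonals(self, query: str, max_diagonals: int = 64) -> list[int]:
        """Candidate diagonals (s_pos - q_pos) ranked by seed support."""
        k = self.k
        hits: dict[int, int] = {}
        q = query.upper()
        for i in range(0, len(q) - k + 1):
            positions = self.kmers.get(q[i : i + k])
            if positions:
                for p in positions:
                    d = p - i
                    hits[d] = hits.get(d, 0) + 1
        ranked = sorted(hits, key=lambda d: (-hits[d], d))
        return ranked[:max_diagonals]


def _kadane_segment(scores: np.ndarray) -> tuple[int, int, float]:
    """Maximum-sum contiguous segment; returns (start, end_exclusive, sum)."""
    best_sum = 0.0
    best = (0, 0)
    run_sum = 0.0
    run_start = 0
    for i, v in enumerate(scores):
        if run_sum <= 0:
            run_sum = float(v)
            run_start = i
        else:
            run_sum += float(v)
        if run_sum > best_sum:
            best_sum = run_sum
            best = (run_start, i + 1)
    return best[0], best[1], best_sum


def best_local_hit(
    query: str,
    index: SubjectIndex,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    min_length: int = 1,
) -> LocalHit | None:
    """Best ungapped local segment of query vs the indexed subject.

    Positions carrying the index's ambiguity letter (N for nt, X for aa)
    score zero — a mask is neither evidence for nor against. The best-scoring
    Kadane segment over each seeded diagonal is taken; ties resolve to the
    smallest diagonal (deterministic).
    """
    q_arr = _as_bytes(query)
    s_arr = index.arr
    amb_codes = [ord(c) for c in index.ambiguous]
    n_pos = np.zeros(len(q_arr), dtype=bool)
    s_npos = np.zeros(len(s_arr), dtype=bool)
    for code in amb_codes:
        n_pos |= q_arr == code
        s_npos |= s_arr == code
    best: LocalHit | None = None
    for d in index.seed_diagonals(query):
        q0 = max(0, -d)
        s0 = q0 + d
        span = min(len(q_arr) - q0, len(s_arr) - s0)
        if span < min_length:
            continue
        qs = q_arr[q0 : q0 + span]
        ss = s_arr[s0 : s0 + span]
        ambiguous = n_pos[q0 : q0 + span] | s_npos[s0 : s0 + span]
        eq = (qs == ss) & ~ambiguous
        scores = np.where(eq, match, np.where(ambiguous, 0.0, mismatch))
        a, b, total = _kadane_segment(scores)
        if b - a < min_length or total <= 0:
            continue
        hit = LocalHit(
            q_start=q0 + a,
            q_end=q0 + b,
            s_start=s0 + a,
            s_end=s0 + b,
            score=total,
            matches=int(np.count_nonzero(eq[a:b])),
            length=b - a,
        )
        if best is None or (hit.score, hit.length, -hit.q_start) > (
            best.score,
            best.length,
            -best.q_start,
        ):
            best = hit
    return best


def nt_bits(score: float) -> float:
    return BITS_PER_MATCH_NT * score


def aa_bits(score: float) -> float:
    return BITS_PER_SCORE_AA * score


_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def translate(seq: str, frame: int = 0) -> str:
    """Translate one forward frame; incomplete/ambiguous codons become X."""
    table = _codon_table()
    seq = seq.upper()
    out = []
    for i in range(frame, len(seq) - 2, 3):
        out.append(table.get(seq[i : i + 3], "X"))
    return "".join(out)


def perfect_nt_bits(length: int) -> float:
    """Bit score of a perfect nucleotide self-alignment of the given length."""
    return nt_bits(float(length))


def lambda_nats() -> float:
    """Scale in nats per score unit implied by the nt calibration."""
    return BITS_PER_MATCH_NT * math.log(2.0)
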