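"""Iterative contig improvement: merge overlapping contigs, re-map reads,
pileup, reassemble, until the contig set converges.

The merge engine assumes a linear genome: a contig whose suffix overlaps its
own prefix (a circular signature) is detected and reported but never joined.
Merging is greedy, largest overlap first, with deterministic tie-breaks.
Read mapping inside the cycle uses an internal exact-seed + ungapped-extend
mapper adequate for desk scale; externally produced SAM placements can be
substituted at the pileup boundary for real-scale use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import SubjectIndex, best_local_hit, revcomp
from .aln_io import Placement, SequenceRecord
from .scaffold import Pileup, SuperScaffold, pileup_assemble


@dataclass
class Contig:
    id: str
    seq: str
    origin: str = "denovo"  # {"mapping", "denovo", "merged"}
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id} is empty")
        if "-" in self.seq:
            raise ValueError(f"contig {self.id} contains gaps; split_on_gaps first")


@dataclass(frozen=True)
class Overlap:
    """Suffix-of-a vs prefix-of-(oriented) b, ungapped.

    a_range/b_range are 0-based half-open; b_range is in the coordinates of b
    after applying ``orientation``. Masked positions (N) count as matches.
    """

    a_id: str
    b_id: str
    a_range: tuple[int, int]
    b_range: tuple[int, int]
    orientation: str  # {"same", "reverse"}
    identity: float
    length: int


@dataclass
class MergeParams:
    k: int = 31
    min_overlap: int = 100
    min_identity: float = 0.98
    min_contig_len: int = 100
    max_rounds: int = 10
    map_min_len: int = 50
    map_min_identity: float = 0.85


def split_on_gaps(
    scaffold: SuperScaffold | str,
    min_contig_len: int = 100,
    id_prefix: str | None = None,
    origin: str = "mapping",
) -> list[Contig]:
    """Cut a (super)scaffold at '-' runs; keep runs >= min_contig_len."""
    if isinstance(scaffold, SuperScaffold):
        seq = scaffold.seq
        prefix = id_prefix if id_prefix is not None else scaffold.genome_id
    else:
        seq = scaffold
        prefix = id_prefix if id_prefix is not None else "contig"
    contigs = []
    start = None
    n = 0
    for i, ch in enumerate(seq + "-"):
        if ch != "-" and start is None:
            start = i
        elif ch == "-" and start is not None:
            if i - start >= min_contig_len:
                n += 1
                contigs.append(Contig(f"{prefix}|{n}", seq[start:i], origin=origin))
            start = None
    return contigs


def _overlap_identity(a_seg: str, b_seg: str) -> float:
    matches = sum(
        1 for x, y in zip(a_seg, b_seg) if x == y or x == "N" or y == "N"
    )
    return matches / len(a_seg) if a_seg else 0.0


def find_overlaps(
    contigs: list[Contig],
    k: int = 31,
    min_overlap: int = 100,
    min_identity: float = 0.98,
) -> tuple[list[Overlap], list[Overlap]]:
    """k-mer anchored end overlaps between contig pairs, either orientation.

    Returns (overlaps, circular): ``circular`` holds self suffix-prefix
    overlaps — the signature of a circular genome — which are reported but
    never merged. Overlaps are sorted longest first (identity, then ids break
    ties) for greedy consumption.
    """
    overlaps: list[Overlap] = []
    circular: list[Overlap] = []
    oriented: dict[tuple[str, str], str] = {}
    indexes: dict[tuple[str, str], SubjectIndex] = {}
    for c in contigs:
        oriented[(c.id, "same")] = c.seq
        oriented[(c.id, "reverse")] = revcomp(c.seq)
    for a in contigs:
        for b in contigs:
            for orientation in ("same", "reverse"):
                if a.id == b.id and orientation == "reverse":
                    continue
                b_seq = oriented[(b.id, orientation)]
                key = (b.id, orientation)
                if key not in indexes:
                    indexes[key] = SubjectIndex(b_seq, k=k)
                best: Overlap | None = None
                for d in indexes[key].seed_diagonals(a.seq):
                    if d > 0:  # prefix-of-a overlap; found from the (b, a) pair
                        continue
                    t = -d
                    if a.id == b.id and t == 0:
                        continue  # identity diagonal of a self-comparison
                    length = min(len(a.seq) - t, len(b_seq))
                    if length < min_overlap:
                        continue
                    a_seg = a.seq[t : t + length]
                    b_seg = b_seq[:length]
                    identity = _overlap_identity(a_seg, b_seg)
                    if identity < min_identity:
                        continue
                    cand = Overlap(
                        a_id=a.id,
                        b_id=b.id,
                        a_range=(t, t + length),
                        b_range=(0, length),
                        orientation=orientation,
                        identity=identity,
                        length=length,
                    )
                    if best is None or (cand.length, cand.identity) > (
                        best.length,
                        best.identity,
                    ):
                        best = cand
                if best is not None:
                    if a.id == b.id:
                        circular.append(best)
                    else:
                        overlaps.append(best)
    key_fn = lambda o: (-o.length, -o.identity, o.a_id, o.b_id, o.orientation)
    return sorted(overlaps, key=key_fn), sorted(circular, key=key_fn)


def merge_pair(a: Contig, b: Contig, overlap: Overlap) -> Contig:
    """Join two contigs over an accepted overlap.

    Merged length = len(a) + len(b) - overlap.length; disagreeing positions
    inside the overlap are masked 'N' (an N on one side defers to the other
    side's base). A reverse-orientation overlap reverse-complements b first.
    """
    if overlap.a_id != a.id or overlap.b_id != b.id:
        raise ValueError("overlap does not reference these contigs")
    b_seq = revcomp(b.seq) if overlap.orientation == "reverse" else b.seq
    t, a_end = overlap.a_range
    if a_end != len(a.seq) or overlap.b_range[0] != 0:
        raise ValueError("overlap coordinates inconsistent with a suffix-prefix join")
    length = overlap.length
    if a.seq[t : t + length] == "" or len(b_seq) < length:
        raise ValueError("overlap exceeds contig bounds")
    merged_core = []
    for x, y in zip(a.seq[t : t + length], b_seq[:length]):
        if x == y:
            merged_core.append(x)
        elif x == "N":
            merged_core.append(y)
        elif y == "N":
            merged_core.append(x)
        else:
            merged_core.append("N")
    seq = a.seq[:t] + "".join(merged_core) + b_seq[length:]
    return Contig(id=f"{a.id}+{b.id}", seq=seq, origin="merged")


class ReadMapper:
    """Exact-seed + ungapped-extend read placement onto a contig set."""

    def __init__(self, contigs: list[Contig], params: MergeParams | None = None):
        self.params = params or MergeParams()
        self.contigs = {c.id: c for c in contigs}
        self._indexes = {
            c.id: SubjectIndex(c.seq, k=min(13, self.params.map_min_len))
            for c in contigs
        }

    def place(self, read: SequenceRecord) -> tuple[Placement, float] | None:
        """Best placement of one read, or None; score used for abundance ties."""
        p = self.params
        best: tuple[float, int, str, Placement] | None = None
        for cid, idx in self._indexes.items():
            for strand, seq in (("+", read.seq), ("-", revcomp(read.seq))):
                hit = best_local_hit(seq, idx, min_length=p.map_min_len)
                if hit is None or hit.identity < p.map_min_identity:
                    continue
                placement = Placement(
                    read_id=read.id,
                    ref_id=cid,
                    ref_start=hit.s_start,
                    bases=seq[hit.q_start : hit.q_end],
                )
                contig_len = len(self.contigs[cid].seq)
                cand = (hit.score, contig_len, cid, placement)
                # higher score wins; ties → longer contig, then lexicographic id
                if best is None or (cand[0], cand[1], _neg_str(cand[2])) > (
                    best[0],
                    best[1],
                    _neg_str(best[2]),
                ):
                    best = cand
        if best is None:
            return None
        return best[3], best[0]


def _neg_str(s: str) -> tuple[int, ...]:
    """Order-reversing key so that lexicographically *smaller* ids win ties."""
    return tuple(-ord(c) for c in s)


def map_reads(
    reads: list[SequenceRecord], contigs: list[Contig], params: MergeParams | None = None
) -> dict[str, list[Placement]]:
    """Place every read on its best contig; returns placements per contig id."""
    mapper = ReadMapper(contigs, params)
    placed: dict[str, list[Placement]] = {c.id: [] for c in contigs}
    for read in reads:
        result = mapper.place(read)
        if result is not None:
            placement, _ = result
            placed[placement.ref_id].append(placement)
    return placed


def _reassemble(
    contigs: list[Contig],
    reads: list[SequenceRecord],
    params: MergeParams,
) -> list[Contig]:
    """Map reads to contigs and replace each contig by its pileup consensus."""
    placed = map_reads(reads, contigs, params)
    out: list[Contig] = []
    for c in contigs:
        pile = pileup_assemble(c.id, len(c.seq), placed[c.id])
        pieces = split_on_gaps(pile.consensus, params.min_contig_len, id_prefix=c.id, origin=c.origin)
        for i, piece in enumerate(pieces, 1):
            piece.id = c.id if len(pieces) == 1 else f"{c.id}.{i}"
            # carry depth over the piece's span for downstream reporting
            out.append(piece)
    return out


def improve(
    contigs: list[Contig],
    reads: list[SequenceRecord],
    params: MergeParams | None = None,
) -> tuple[list[Contig], dict]:
    """Merge / map / pileup / reassemble until the contig set converges.

    Convergence is set-equality of sequences; ``params.max_rounds`` (default
    10) guards oscillation, returning the current set with a warning in the
    diagnostics dict. Reads should be the dereplicated, non-normalized set.
    Deterministic for fixed inputs, independent of input order.
    """
    params = params or MergeParams()
    diagnostics: dict = {"rounds": 0, "circular": [], "converged": False}
    current = sorted(contigs, key=lambda c: (-len(c.seq), c.seq, c.id))
    for round_no in range(1, params.max_rounds + 1):
        diagnostics["rounds"] = round_no
        # --- merge phase: greedy largest-overlap-first to a fixed point
        while True:
            overlaps, circular = find_overlaps(
                current, params.k, params.min_overlap, params.min_identity
            )
            diagnostics["circular"].extend(
                (o.a_id, o.length) for o in circular
            )
            if not overlaps:
                break
            top = overlaps[0]
            by_id = {c.id: c for c in current}
            merged = merge_pair(by_id[top.a_id], by_id[top.b_id], top)
            current = [c for c in current if c.id not in (top.a_id, top.b_id)]
            current.append(merged)
            current.sort(key=lambda c: (-len(c.seq), c.seq, c.id))
        # --- rebuild phase
        rebuilt = _reassemble(current, reads, params)
        rebuilt.sort(key=lambda c: (-len(c.seq), c.seq, c.id))
        if [c.seq for c in rebuilt] == [c.seq for c in current]:
            diagnostics["converged"] = True
            current = rebuilt
            break
        current = rebuilt
    # stable final ids, independent of merge history
    final = []
    for i, c in enumerate(sorted(current, key=lambda c: (-len(c.seq), c.seq)), 1):
        final.append(Contig(id=f"contig_{i}", seq=c.seq, origin=c.origin, depth=c.depth))
    return final, diagnostics


def abundance(
    contigs: list[Contig],
    reads: list[SequenceRecord],
    multiplicity: dict[str, int] | None = None,
    params: MergeParams | None = None,
) -> dict[str, int]:
    """Count reads per contig: best-scoring placement wins, ties go to the
    longer contig then the lexicographically smaller id; dereplication
    multiplicities are re-expanded."""
    params = params or MergeParams()
    mapper = ReadMapper(contigs, params)
    counts = {c.id: 0 for c in contigs}
    for read in reads:
        result = mapper.place(read)
        if result is None:
            continue
        placement, _ = result
        weight = multiplicity.get(read.id, 1) if multiplicity else 1
        counts[placement.ref_id] += weight
    return counts
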