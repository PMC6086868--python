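"""Per-genome super-scaffold construction.

Each nucleotide and protein database entry of a recruited genome is rebuilt
by naive pileup assembly (per-position majority vote over placed reads).
Protein consensuses are tiled back onto genome coordinates through their
annotated CDS positions as a *consistency layer*: a confidently reconstructed
amino acid marks its three genome positions as protein-supported, and
contributes an actual base only where nucleotide-level calls from the
supporting reads are available — back-translation is degenerate, so bases are
never invented from amino acids. Disagreements within an assembly are masked
('N'); where nucleotide and protein layers disagree, the nucleotide call wins.

Masked ('N') and uncovered ('-') are distinct states: masks carry positional
information, gaps do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aln_io import CdsAnnotation, Placement

NT_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY*"


@dataclass
class Pileup:
    """Per-position base counts and majority consensus over one reference.

    consensus characters: alphabet letter (strict plurality), mask char on a
    tie among top letters, '-' where coverage is zero or gap calls strictly
    dominate.
    """

    ref_id: str
    length: int
    counts: np.ndarray  # shape (len(alphabet)+1, length); last row = gap
    consensus: str
    alphabet: str = NT_ALPHABET
    mask_char: str = "N"

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class AaLayer:
    """Protein-tiling evidence in genome coordinates for one CDS."""

    protein_id: str
    genome_id: str
    length: int
    supported: np.ndarray  # bool per genome position
    base: list[str] = field(default_factory=list)  # '' where no nt-level call

    def __post_init__(self) -> None:
        if not self.base:
            self.base = [""] * self.length


@dataclass
class SuperScaffold:
    """Pseudo-assembled nucleotide consensus for one genome.

    source[p] ∈ {"nt", "aa", "none"}; source == "none" exactly where
    seq[p] == '-'.
    """

    genome_id: str
    seq: str
    source: list[str]
    support: np.ndarray  # per-position read depth (aa-only positions: layers)


def pileup_assemble(
    ref_id: str,
    ref_length: int,
    placements: list[Placement],
    alphabet: str = NT_ALPHABET,
    mask_char: str = "N",
) -> Pileup:
    """Naive pileup assembly: per-position strict-majority consensus.

    Tie among top letters → mask; zero coverage → '-'; a gap call wins only
    when gap count strictly exceeds every letter count (conservative at
    deletion edges).
    """
    n = len(alphabet)
    counts = np.zeros((n + 1, ref_length), dtype=np.int32)
    idx = {c: i for i, c in enumerate(alphabet)}
    for p in placements:
        end = p.ref_start + len(p.bases)
        if p.ref_start < 0 or end > ref_length:
            raise ValueError(
                f"placement of {p.read_id} spans [{p.ref_start}, {end}) "
                f"outside reference {ref_id} of length {ref_length}"
            )
        for offset, ch in enumerate(p.bases):
            if ch == "-":
                counts[n, p.ref_start + offset] += 1
            else:
                i = idx.get(ch.upper())
                if i is not None:
                    counts[i, p.ref_start + offset] += 1

    letters = counts[:n]
    gap = counts[n]
    top = letters.max(axis=0)
    n_top = (letters == top[None, :]).sum(axis=0)
    argtop = letters.argmax(axis=0)

    chars = np.full(ref_length, "-", dtype="<U1")
    covered = (top > 0) | (gap > 0)
    call_base = covered & (top > 0) & (gap <= top)
    tie = call_base & (n_top > 1)
    single = call_base & (n_top == 1)
    chars[single] = np.array(list(alphabet))[argtop[single]]
    chars[tie] = mask_char
    # covered but gap-dominated (gap > top) stays '-'
    return Pileup(
        ref_id=ref_id,
        length=ref_length,
        counts=counts,
        consensus="".join(chars),
        alphabet=alphabet,
        mask_char=mask_char,
    )


def back_translate_tile(
    protein_pileup: Pileup,
    cds: CdsAnnotation,
    genome_length: int,
    read_calls: dict[int, str] | None = None,
) -> AaLayer:
    """Tile a reconstructed protein onto its genome via CDS coordinates.

    Each confidently reconstructed amino acid (consensus not masked, not a
    gap) flags its three genome positions as aa-supported. Base letters are
    filled only from ``read_calls`` — nucleotide-level calls derived from the
    aa-supporting reads — at supported positions.
    """
    if cds.g_start < 1 or cds.g_end > genome_length:
        raise ValueError(
            f"CDS {cds.protein_id} [{cds.g_start}, {cds.g_end}] outside genome "
            f"of length {genome_length}"
        )
    supported = np.zeros(genome_length, dtype=bool)
    n_codons = cds.length // 3
    n_aa = min(protein_pileup.length, n_codons)
    consensus = protein_pileup.consensus
    for i in range(n_aa):
        ch = consensus[i]
        if ch == "-" or ch == protein_pileup.mask_char:
            continue
        if cds.strand == "+":
            start0 = (cds.g_start - 1) + 3 * i
        else:
            start0 = (cds.g_end - 1) - 3 * i - 2
        supported[start0 : start0 + 3] = True
    base = [""] * genome_length
    if read_calls:
        for pos0, ch in read_calls.items():
            if 0 <= pos0 < genome_length and supported[pos0]:
                base[pos0] = ch.upper()
    return AaLayer(
        protein_id=cds.protein_id,
        genome_id=cds.genome_id,
        length=genome_length,
        supported=supported,
        base=base,
    )


def build_superscaffold(
    genome_id: str,
    nt_pileup: Pileup | None,
    aa_layers: list[AaLayer],
    genome_length: int | None = None,
) -> SuperScaffold:
    """Combine the nucleotide pileup with protein consistency layers.

    Per position: a nucleotide consensus call (including a mask) takes
    precedence; otherwise agreeing aa-layer base calls supply the base;
    conflicting aa layers — or aa support without a base-level call — yield a
    mask; no evidence yields '-'.
    """
    if nt_pileup is not None:
        length = nt_pileup.length
    elif genome_length is not None:
        length = genome_length
    else:
        raise ValueError("need a nucleotide pileup or an explicit genome length")
    for layer in aa_layers:
        if layer.length != length:
            raise ValueError(
                f"aa layer {layer.protein_id} length {layer.length} != genome "
                f"length {length}"
            )

    seq = []
    source = []
    support = np.zeros(length, dtype=np.int32)
    nt_cons = nt_pileup.consensus if nt_pileup is not None else "-" * length
    nt_depth = nt_pileup.depth if nt_pileup is not None else np.zeros(length, dtype=np.int32)
    for p in range(length):
        ch = nt_cons[p]
        if ch != "-":
            seq.append(ch)
            source.append("nt")
            support[p] = nt_depth[p]
            continue
        calls = set()
        n_layers = 0
        for layer in aa_layers:
            if layer.supported[p]:
                n_layers += 1
                if layer.base[p]:
                    calls.add(layer.base[p])
        if n_layers == 0:
            seq.append("-")
            source.append("none")
        elif len(calls) == 1:
            seq.append(next(iter(calls)))
            source.append("aa")
            support[p] = n_layers
        else:  # conflicting calls, or supported with no base-level call
            seq.append("N")
            source.append("aa")
            support[p] = n_layers
    return SuperScaffold(genome_id=genome_id, seq="".join(seq), source=source, support=support)
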