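# Methods

This note documents the models and procedures implemented in `capsid`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not
demonstrate.

## Pipeline overview

Four stages, each usable independently through the library API:

1. **Recruitment.** Reads are dereplicated (exact-duplicate collapse with
   multiplicity tracking) and optionally depth-normalized, aligned to the
   viral division of the database, threshold-filtered, assigned to candidate
   genomes, and the resulting per-genome read sets de-duplicated by Jaccard
   distance.
2. **Scaffolding.** Each nucleotide and protein database entry of a
   recruited genome is rebuilt by naive pileup assembly; protein consensuses
   are tiled onto genome coordinates via annotated CDS positions; the layers
   combine into a per-genome super-scaffold with nucleotide precedence.
3. **Improvement.** Scaffold-derived contigs (plus any externally assembled
   de novo contigs) are filtered for non-viral signal, then cycled through
   merge → map → pileup → reassemble until the contig set converges; read
   abundance is computed on the final set.
4. **Classification.** Final contigs are aligned to the comprehensive
   (viral + non-viral) database and classified by the two-pass bits-per-base
   engine; per-taxon aggregation applies the reporting filters.

## Two-pass scoring

Alignment events carry a bit score and query coordinates; translated events
express query coordinates in nucleotide space so nucleotide and protein
evidence share one per-position frame. Per event, the per-base score is
s = bits / aligned query length.

*Pass one* records, per position and taxon, the maximum s (overlapping
events of one taxon take the max, never the sum, so duplicated database
entries cannot inflate it), the global per-position maximum g, and the
per-taxon sum of positional maxima — the taxon's best potential alignment
independent of subject contiguity.

*Pass two* computes each entry's volume contribution as s·w(s/g) per
position, summed over positions and entries per taxon. The relative-accuracy
damping is w(r) = r^p for nucleotide and r^(p^p) for translated events. Two
choices here were open and are resolved as follows:

- The damping family. The qualitative requirements are w(1) = 1, strict
  monotonicity on (0, 1], and a drastically harsher penalty for protein
  mismatches (because conserved proteins make an amino-acid mismatch far
  more informative). Power laws r^3 and r^27 satisfy all three with a single
  shared parameter p = 3; both exponents are configuration
  (`ClassifierParams.w_nt_exponent`, `w_aa_exponent`).
- The damped quantity. The contribution is s·w(s/g) — the entry's *own*
  score damped by relative accuracy — rather than g·w(s/g). This keeps each
  entry's volume bounded by its pass-one potential and makes the fixed point
  exact: a taxon holding the global top everywhere has volume equal to its
  pass-one score.

The vectorized implementation is verified against a literal per-position
brute-force oracle to 1e-9 relative error on 1000 random instances (see
`tests/test_acceptance.py` and `scripts/acceptance.py`).

## Gates and the LCA engine

A contig is dropped as non-viral if its top pass-one taxon lies outside the
superkingdom Viruses, or if more than 50% of its aligning bases (positions
with g > 0) have their global top achieved only by non-viral taxa; a
positional tie counts as viral. The 50% fraction counts *positions*, not
position-weighted bits — both readings are defensible, positions are simpler
and are what is implemented (`viral_base_fraction`). Contigs whose best
pass-one score falls below `min_contig_bits` = 300 bits are dropped as
low-information.

Candidate taxa for the LCA are those within a dynamic radius of the best
pass-one score: with quality q = best / (L·b_max) clamped to [0, 1] (b_max =
2.0 bits/base, the nucleotide information ceiling; configurable because
translated-dominant contigs have a lower one), the radius interpolates
linearly from `radius_min` = 0.02 at q = 1 to `radius_max` = 0.25 at q = 0.
A perfect full-length hit therefore keeps a near-exclusive candidate set,
while a weak distant hit lets in everything within ~20% of the best.
Candidates are restricted to the viral superkingdom before the walk (the
viral gate has already established the contig is viral; non-viral candidates
would only force the walk to the root).

The LCA walks a configurable rank ladder leaf→root (default subspecies …
kingdom; ranks outside the ladder, including NCBI "no rank" clades, are
transparent). At each rank, candidate volumes project onto their
ancestor-or-self at that rank; a taxon wins if its share of the total
candidate volume V exceeds

m(V) = 0.5 + 0.45 / (1 + V/V₀), capped at 0.95, V₀ = 2000 bits.

m is strictly decreasing in V and bounded in (0.5, 0.95]: a taxon poorly
represented in the database (small V) must hold a commanding majority, a
well-represented one only a slight majority. The hyperbolic form and the
scale V₀ are package choices satisfying those monotonicity constraints; the
tested invariants pin the behavior, not the formula. If no rank below the
superkingdom yields a majority, the contig is assigned to the
volume-maximal candidate strictly below Viruses. All ties everywhere break
to the numerically smaller taxid, making classification deterministic.

Reporting aggregates classified contigs per taxid, suppressing taxa with
aggregate pass-one bits below `min_taxon_bits` = 1000; filtered or
unclassifiable contigs of at least `min_report_len` = 500 bp are listed in a
separate unclassified section.

## Recruitment thresholds

Alignment reporting uses score-radius margins: a record survives iff its
bits reach (1−d)·best within its subject group **and** within its query
group. Defaults are d_subject = 0.20 / d_query = 0.08 for translated and
d_subject = 0.90 / d_query = 0.05 for nucleotide alignments. The subject
margins as stated in the source conventions are directionally ambiguous
(a 90% margin is extremely permissive); the score-radius reading is the only
one under which the per-query values (8%, 5%) are coherent, so it is applied
uniformly and all four margins are configuration for users who want a
different reading. The filter is idempotent by construction.

Jaccard filtering visits genome read sets largest-first (lexicographic
genome id breaks ties) and drops a set whose Jaccard distance to an
already-retained set is ≤ τ = 0.05, i.e. ≥ 95% similar. The greedy
size-ordered rule and the default τ are package choices; the invariants —
the largest set always survives, and retained sets are pairwise farther than
τ from every larger retained set — are tested. Filtering compares read sets
per *genome*, not per database entry.

Digital normalization is a simplified median-k-mer-depth cap (k = 21, target
40): streaming in input order, a read is discarded iff the median running
count of its k-mers already exceeds the target. It is off by default — the
reduction steps are an optimization, not a correctness requirement — and is
not a streaming-sketch implementation.

## Assembly conventions

Pileup consensus is a strict per-position plurality over {A,C,G,T}: a tie
among top bases is masked 'N', zero coverage is '-', and a deletion ('-' in
a placement) wins only when gap calls strictly outnumber every base —
conservative at deletion edges. Masked and uncovered are distinct states:
masks carry positional information (a disagreement happened here), gaps do
not, and downstream length/coverage accounting ignores gaps but keeps masks.
Insertions relative to the reference frame are dropped (naive-pileup
semantics; novel insertions are the de novo arm's job).

Protein tiling asserts *consistency*, not bases: a confidently reconstructed
amino acid flags its three genome positions as protein-supported, and
contributes an actual base call only where nucleotide-level calls from the
supporting reads exist (back-translation is degenerate; inventing bases from
amino acids would corrupt nucleotide-space classification downstream).
Where nucleotide and protein layers disagree, the nucleotide call wins;
conflicting protein layers mask.

The merge engine accepts k-mer-anchored, ungapped suffix/prefix overlaps
(either orientation) of ≥ 100 bp at ≥ 98% identity, merging greedily
largest-first with deterministic tie-breaks (no canonical order exists, and
determinism is required for testing). Disagreements inside an accepted
overlap are masked. The engine assumes a linear genome: a contig whose
suffix overlaps its own prefix — the circular signature — is reported in the
diagnostics but never joined. Convergence is set-equality of contig
sequences, with a 10-round cap guarding oscillation. Read mapping inside the
cycle uses an internal exact-seed + ungapped-extend mapper adequate for
desk-scale data; externally produced SAM placements can be substituted at
the pileup boundary for real-scale use.

Abundance assigns each read once, to its best-scoring contig; ties go to the
longer contig, then the lexicographically smaller id; dereplication
multiplicities are re-expanded.

## Synthetic worlds and what passing tests show

`capsid.synth` emulates a mock-community experiment: n_viruses = 4 planted
viruses on 3–4 kb reference genomes with two CDS annotations each (one per
strand, in-frame stops recoded), per-virus substitution divergence drawn
from 5–15%, 150 bp reads at 20× coverage with 1% substitution error, and a
30% background of reads from an unrelated 10 kb host genome. These defaults
are the standard study conditions used throughout the tests and the
acceptance script; the problem sizes keep a full pipeline run in seconds on
one core while leaving every stage non-trivial (divergence well above the
merge identity threshold's complement, coverage low enough that edges and
masks occur).

The stand-in aligner is exhaustive-seed (13-mer nt, 4-mer aa) ungapped
extension with Kadane trimming to the best local segment; nucleotide scores
are calibrated so a perfect self-alignment yields exactly 2.0 bits/base
(matching b_max), translated alignments 1.5 bits per nucleotide base, so at
equal identity nucleotide evidence dominates — consistent with nucleotide
precedence. Bit scores are strictly monotone in mismatch count at fixed
span. Honesty, not sensitivity, is the design goal.

What the generator does **not** model: indels (in divergence or error),
quality-score profiles, platform-specific error modes, GC or positional
coverage bias, chimeras, and genuinely novel viruses without any database
neighbour. Passing the synthetic benchmark therefore demonstrates the
correctness of the scoring, assembly and filtering machinery under
substitution-type noise — it does not certify performance on real
sequencing artifacts, and real-scale use is expected to consume external
aligner/assembler outputs through the standard formats.

## Numerical and degenerate-input conventions

- Coordinates are 1-based inclusive at every file boundary, 0-based
  half-open internally; the readers are the single conversion point.
- Empty read sets, empty alignment sets and all-gap scaffolds flow through
  every stage and produce empty outputs, not errors; orphan taxids, cycles,
  out-of-bounds placements and inconsistent layer lengths are hard errors.
- pass2 before pass1 (a record covering a position with zero global top) is
  an internal-consistency error by design.
- All randomness in the synthetic generator flows through one seeded
  generator; reruns with identical inputs and configuration are
  bit-identical.

## Known limitations

- The internal mapper and stand-in aligner are ungapped; indel-rich data
  must come through external SAM/alignment inputs.
- Circular genomes are detected but never closed.
- Digital normalization is a deliberate simplification of streaming-sketch
  normalizers.
- The LCA rank ladder treats unlisted ranks as transparent; taxonomies that
  encode meaningful structure only in "no rank" clades will classify at the
  nearest listed rank.
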