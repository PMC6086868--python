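import numpy as np
import pytest

from capsid._align import revcomp
from capsid.aln_io import SequenceRecord
from capsid.merge import (
    Contig,
    MergeParams,
    Overlap,
    abundance,
    find_overlaps,
    improve,
    merge_pair,
    split_on_gaps,
)


def random_genome(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSplitOnGaps:
    def test_short_runs_discarded(self):
        rng = np.random.default_rng(0)
        long_run = random_genome(rng, 150)
        scaffold = "ACGT" + "-" * 4 + long_run
        contigs = split_on_gaps(scaffold, min_contig_len=100)
        assert [c.seq for c in contigs] == [long_run]

    def test_gap_free_scaffold_is_one_contig(self):
        rng = np.random.default_rng(1)
        seq = random_genome(rng, 200)
        (c,) = split_on_gaps(seq, min_contig_len=100)
        assert c.seq == seq

    def test_all_gap_scaffold_yields_nothing(self):
        assert split_on_gaps("-" * 500, min_contig_len=100) == []


class TestFindOverlaps:
    def test_exact_suffix_prefix_overlap(self):
        rng = np.random.default_rng(2)
        a = random_genome(rng, 400)
        b = a[-150:] + random_genome(rng, 250)
        overlaps, circular = find_overlaps(
            [Contig("a", a), Contig("b", b)], min_overlap=100
        )
        assert circular == []
        top = overlaps[0]
        assert (top.a_id, top.b_id) == ("a", "b")
        assert top.length == 150
        assert top.identity == 1.0
        assert top.orientation == "same"

    def test_overlap_below_min_length_rejected(self):
        rng = np.random.default_rng(3)
        a = random_genome(rng, 400)
        b = a[-80:] + random_genome(rng, 250)
        overlaps, _ = find_overlaps([Contig("a", a), Contig("b", b)], min_overlap=100)
        assert overlaps == []

    def test_low_identity_overlap_rejected(self):
        rng = np.random.default_rng(4)
        a = random_genome(rng, 400)
        shared = list(a[-150:])
        for i in range(0, 150, 25):  # 6 mismatches → 96% identity
            shared[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[shared[i]]
        b = "".join(shared) + random_genome(rng, 250)
        overlaps, _ = find_overlaps(
            [Contig("a", a), Contig("b", b)], min_overlap=100, min_identity=0.98
        )
        assert overlaps == []

    def test_reverse_orientation_detected(self):
        rng = np.random.default_rng(5)
        a = random_genome(rng, 400)
        b = revcomp(a[-150:] + random_genome(rng, 250))
        overlaps, _ = find_overlaps([Contig("a", a), Contig("b", b)], min_overlap=100)
        assert any(o.orientation == "reverse" and o.length == 150 for o in overlaps)

    def test_circular_signature_reported_not_merged(self):
        rng = np.random.default_rng(6)
        core = random_genome(rng, 400)
        circ = core + core[:150]  # own suffix equals own prefix
        overlaps, circular = find_overlaps([Contig("a", circ)], min_overlap=100)
        assert overlaps == []
        assert circular and circular[0].a_id == "a" and circular[0].length == 150


class TestMergePair:
    def test_merged_length_arithmetic(self):
        rng = np.random.default_rng(7)
        a = random_genome(rng, 400)
        b = a[-150:] + random_genome(rng, 150)
        (overlap,), _ = find_overlaps([Contig("a", a), Contig("b", b)], min_overlap=100)
        merged = merge_pair(Contig("a", a), Contig("b", b), overlap)
        assert len(merged.seq) == 400 + 300 - 150
        assert merged.seq == a + b[150:]
        assert merged.origin == "merged"

    def test_single_mismatch_masks_one_position(self):
        rng = np.random.default_rng(8)
        a = random_genome(rng, 400)
        shared = list(a[-150:])
        shared[75] = {"A": "C", "C": "G", "G": "T", "T": "A"}[shared[75]]
        b = "".join(shared) + random_genome(rng, 150)
        (overlap,), _ = find_overlaps(
            [Contig("a", a), Contig("b", b)], min_overlap=100, min_identity=0.99
        )
        merged = merge_pair(Contig("a", a), Contig("b", b), overlap)
        assert merged.seq.count("N") == 1
        assert merged.seq[250 + 75] == "N"

    def test_reverse_overlap_reverse_complements_b(self):
        rng = np.random.default_rng(9)
        a = random_genome(rng, 400)
        b_fwd = a[-150:] + random_genome(rng, 150)
        b = revcomp(b_fwd)
        overlaps, _ = find_overlaps([Contig("a", a), Contig("b", b)], min_overlap=100)
        top = next(o for o in overlaps if o.orientation == "reverse" and o.a_id == "a")
        merged = merge_pair(Contig("a", a), Contig("b", b), top)
        assert merged.seq == a + b_fwd[150:]


def tiled_reads(genome, read_len=100, stride=7, prefix="r"):
    """Error-free reads tiling every position of the genome, both ends included."""
    last = len(genome) - read_len
    starts = sorted(set(range(0, last + 1, stride)) | {last})
    return [
        SequenceRecord(f"{prefix}{i}", genome[s : s + read_len])
        for i, s in enumerate(starts)
    ]


def fragment_world(seed=10, genome_len=1500):
    """A genome, three tiling fragments with 150-base overlaps, and reads."""
    rng = np.random.default_rng(seed)
    genome = random_genome(rng, genome_len)
    fragments = [
        Contig("f1", genome[:650]),
        Contig("f2", genome[500:1150]),
        Contig("f3", genome[1000:]),
    ]
    return genome, fragments, tiled_reads(genome)


class TestImprove:
    def test_tiling_fragments_converge_to_the_genome(self):
        genome, fragments, reads = fragment_world()
        final, diag = improve(fragments, reads)
        assert diag["converged"]
        assert [c.seq for c in final] == [genome]

    def test_no_overlap_fixed_point_in_one_round(self):
        rng = np.random.default_rng(11)
        genome_a, genome_b = random_genome(rng, 600), random_genome(rng, 600)
        reads = tiled_reads(genome_a, prefix="a") + tiled_reads(genome_b, prefix="b")
        contigs = [Contig("a", genome_a), Contig("b", genome_b)]
        final, diag = improve(contigs, reads)
        assert diag["rounds"] == 1 and diag["converged"]
        assert sorted(c.seq for c in final) == sorted([genome_a, genome_b])

    def test_idempotent_on_own_output(self):
        _, fragments, reads = fragment_world()
        once, _ = improve(fragments, reads)
        twice, diag = improve(once, reads)
        assert [c.seq for c in twice] == [c.seq for c in once]
        assert diag["rounds"] == 1

    def test_input_order_permutation_invariant(self):
        _, fragments, reads = fragment_world()
        forward, _ = improve(fragments, reads)
        backward, _ = improve(list(reversed(fragments)), reads)
        assert [c.seq for c in forward] == [c.seq for c in backward]


class TestAbundance:
    def test_unique_mapping_counts(self):
        rng = np.random.default_rng(12)
        genome = random_genome(rng, 600)
        contig = Contig("c1", genome)
        reads = [
            SequenceRecord(f"r{i}", genome[s : s + 100])
            for i, s in enumerate(rng.integers(0, 501, size=100))
        ]
        assert abundance([contig], reads) == {"c1": 100}

    def test_tie_goes_to_longer_contig(self):
        rng = np.random.default_rng(13)
        shared = random_genome(rng, 100)
        c_long = Contig("c1", shared + random_genome(rng, 400))
        c_short = Contig("c2", shared + random_genome(rng, 300))
        counts = abundance([c_long, c_short], [SequenceRecord("r1", shared)])
        assert counts == {"c1": 1, "c2": 0}

    def test_multiplicity_re_expanded(self):
        rng = np.random.default_rng(14)
        genome = random_genome(rng, 300)
        counts = abundance(
            [Contig("c1", genome)],
            [SequenceRecord("r1", genome[50:150])],
            multiplicity={"r1": 7},
        )
        assert counts == {"c1": 7}

    def test_total_assigned_bounded_by_input(self):
        genome, fragments, reads = fragment_world(seed=15)
        final, _ = improve(fragments, reads)
        counts = abundance(final, reads)
        assert sum(counts.values()) <= len(reads)
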