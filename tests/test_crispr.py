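"""CRISPR spacer-array equivalence: strand flips, splits, symmetry."""

import numpy as np
import pytest

from aninull._encoding import revcomp
from aninull.crispr import (SpacerArray, arrays_equivalent, canonicalize,
                            parse_spacers)


def _array(spacers, contig="c1", genome="g"):
    return SpacerArray(genome_label=genome, contig_id=contig, spacers=spacers)


def random_spacers(rng, n):
    return ["".join(rng.choice(list("ACGT"), size=int(rng.integers(25, 40))))
            for _ in range(n)]


class TestParseSpacers:
    def test_one_contig_position_order(self, tmp_path):
        p = tmp_path / "sp.tsv"
        rows = [("ctg1", 500, "ACGTACGT"), ("ctg1", 100, "TTTTAAAA"),
                ("ctg1", 300, "GGGGCCCC"), ("ctg1", 900, "ATATATAT"),
                ("ctg1", 700, "CGCGCGCG")]
        p.write_text("".join(f"{c}\t{s}\t{seq}\n" for c, s, seq in rows))
        (arr,) = parse_spacers(p)
        assert arr.spacers == ["TTTTAAAA", "GGGGCCCC", "ACGTACGT",
                               "CGCGCGCG", "ATATATAT"]

    def test_empty_file_means_no_crispr_system(self, tmp_path):
        p = tmp_path / "none.tsv"
        p.write_text("")
        assert parse_spacers(p) == []

    def test_two_contigs_give_two_arrays(self, tmp_path):
        p = tmp_path / "two.tsv"
        p.write_text("c1\t10\tACGTACGT\nc2\t10\tTTTTAAAA\n")
        assert len(parse_spacers(p)) == 2

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("c1\t10\tACGT\nc1\tnotanint\tACGT\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_spacers(p)


class TestCanonicalize:
    def test_strand_flip_same_canonical_form(self):
        rng = np.random.default_rng(61)
        s = random_spacers(rng, 4)
        fwd = _array(s)
        flipped = _array([revcomp(x) for x in reversed(s)])
        assert canonicalize([fwd]) == canonicalize([flipped])

    def test_palindromic_single_spacer(self):
        arr = _array(["ACGCGT"])  # its own reverse complement
        assert canonicalize([arr]) == [("ACGCGT",)]

    def test_idempotent(self):
        rng = np.random.default_rng(62)
        arrs = [_array(random_spacers(rng, 3))]
        once = canonicalize(arrs)
        again = canonicalize([_array(list(t)) for t in once])
        assert once == again


class TestArraysEquivalent:
    def test_identical_arrays(self):
        rng = np.random.default_rng(63)
        s = random_spacers(rng, 5)
        rep = arrays_equivalent([_array(s)], [_array(list(s))])
        assert rep.verdict == "identical"
        assert (rep.shared_spacers, rep.only_a, rep.only_b) == (5, 0, 0)

    def test_strand_flip_invariance(self):
        rng = np.random.default_rng(64)
        s = random_spacers(rng, 6)
        flipped = [_array([revcomp(x) for x in reversed(s)])]
        rep = arrays_equivalent([_array(s)], flipped)
        assert rep.verdict == "identical"
        assert rep.orientation_used == "reverse-complement"

    def test_split_across_contigs_resolved(self):
        rng = np.random.default_rng(65)
        s = random_spacers(rng, 6)
        whole = [_array(s)]
        split = [_array(s[:2], contig="cA"), _array(s[2:], contig="cB")]
        rep = arrays_equivalent(whole, split)
        assert rep.verdict == "identical"
        assert rep.split_resolved

    def test_split_and_flipped_piece(self):
        rng = np.random.default_rng(66)
        s = random_spacers(rng, 5)
        piece = [revcomp(x) for x in reversed(s[3:])]
        split = [_array(s[:3], contig="cA"), _array(piece, contig="cB")]
        assert arrays_equivalent([_array(s)], split).verdict == "identical"

    def test_disjoint_spacer_sets_counted(self):
        rng = np.random.default_rng(67)
        s1, s2, s3, s4 = random_spacers(rng, 4)
        rep = arrays_equivalent([_array([s1, s2, s3])], [_array([s1, s2, s4])])
        assert rep.verdict == "different"
        assert (rep.shared_spacers, rep.only_a, rep.only_b) == (2, 1, 1)

    def test_order_matters_for_verdict_not_counts(self):
        rng = np.random.default_rng(68)
        s = random_spacers(rng, 4)
        rep = arrays_equivalent([_array(s)], [_array(s[::-1])])
        # reversed order without complementing is a different array
        assert rep.verdict == "different"
        assert rep.shared_spacers == 4

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(69)
        for _ in range(20):
            s = random_spacers(rng, int(rng.integers(1, 5)))
            t = random_spacers(rng, int(rng.integers(1, 5)))
            if rng.random() < 0.5:
                t = s[: len(t)] + t[len(s):]
            a, b = [_array(s)], [_array(t)]
            ab = arrays_equivalent(a, b)
            ba = arrays_equivalent(b, a)
            assert ab.verdict == ba.verdict
            assert (ab.shared_spacers, ab.only_a, ab.only_b) == \
                (ba.shared_spacers, ba.only_b, ba.only_a)

    def test_empty_vs_empty_is_no_crispr_system(self):
        rep = arrays_equivalent([], [])
        assert rep.verdict == "identical"
        assert rep.no_crispr_system
        assert rep.shared_spacers == 0

    def test_empty_vs_nonempty_is_different(self):
        rng = np.random.default_rng(70)
        rep = arrays_equivalent([], [_array(random_spacers(rng, 3))])
        assert rep.verdict == "different"
        assert rep.only_b == 3

    def test_mismatch_budget(self):
        rng = np.random.default_rng(71)
        s = random_spacers(rng, 3)
        mutated = [x[:-1] + ("A" if x[-1] != "A" else "C") for x in s]
        assert arrays_equivalent([_array(s)], [_array(mutated)]).verdict == \
            "different"
        assert arrays_equivalent([_array(s)], [_array(mutated)],
                                 max_mismatch=1).verdict == "identical"
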