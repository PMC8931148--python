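"""Scanner unit tests: alphabet ops, site enumeration, pairing, anti-repeats."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamscape import (
    AlphabetError,
    GenomeRecord,
    PamMotif,
    UnsupportedMotifError,
    find_antirepeats,
    find_back_to_back_pairs,
    find_pam_sites,
    iupac_matches,
    reverse_complement,
)
from pamscape.synth import random_genome

from oracle_helpers import regex_sites, site_keys

dna = st.text(alphabet="ACGTN", max_size=60)


class TestAlphabet:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT", "ACGT"), ("AATA", "TATT"), ("", ""), ("NNA", "TNN")],
    )
    def test_reverse_complement(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(dna)
    @settings(max_examples=100, deadline=None)
    def test_reverse_complement_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_reverse_complement_rejects_non_dna(self):
        with pytest.raises(AlphabetError):
            reverse_complement("ACGU")

    @pytest.mark.parametrize(
        "base,code,expected",
        [
            ("T", "N", True),
            ("G", "R", True),
            ("C", "R", False),
            ("A", "T", False),
            ("C", "Y", True),
        ],
    )
    def test_iupac_matches(self, base, code, expected):
        assert iupac_matches(base, code) is expected

    def test_iupac_invalid_code(self):
        with pytest.raises(AlphabetError):
            iupac_matches("A", "X")

    def test_n_code_matches_all_bases(self):
        assert all(iupac_matches(b, "N") for b in "ACGT")


class TestPamMotif:
    def test_palindromicity_is_strict_set_closure(self):
        assert PamMotif("TA").is_palindromic
        assert PamMotif("GGCC").is_palindromic
        # the NNTA match set is not closed under revcomp (TANN-shaped image)
        assert not PamMotif("NNTA").is_palindromic

    def test_palindromic_core_requires_ta_with_n_flanks(self):
        assert PamMotif("NNTA").palindromic_core() == 2
        assert PamMotif("TA").palindromic_core() == 0
        assert PamMotif("NGG").palindromic_core() is None
        assert PamMotif("NRTA").palindromic_core() is None  # constrained flank

    def test_invalid_code_rejected(self):
        with pytest.raises(AlphabetError):
            PamMotif("NNTZ")


class TestFindPamSites:
    def test_single_plus_site_linear(self):
        sites = find_pam_sites(GenomeRecord("g", "TTTTTTTA"), "NNTA", 4)
        assert len(sites) == 1
        (site,) = sites
        assert site.strand == "+"
        assert site.protospacer == (0, 4)
        assert site.pam == (4, 8)
        assert site.pam_seq == "TTTA"

    def test_no_sites_without_ta(self):
        assert find_pam_sites(GenomeRecord("g", "A" * 8), "NNTA", 4) == []

    def test_circular_wrap_yields_both_strands(self):
        sites = find_pam_sites(GenomeRecord("g", "TAAAAA", circular=True), "NNTA", 2)
        assert len(sites) == 2
        assert {s.strand for s in sites} == {"+", "-"}
        # both sites anchor on the TA at [0, 2)
        plus = next(s for s in sites if s.strand == "+")
        minus = next(s for s in sites if s.strand == "-")
        assert plus.pam == (4, 8)  # wraps: positions 4,5,0,1
        assert minus.pam == (0, 4)

    def test_spacer_longer_than_linear_record_gives_empty(self):
        assert find_pam_sites(GenomeRecord("g", "TTTA"), "NNTA", 22) == []

    def test_invalid_genome_is_alphabet_error(self):
        with pytest.raises(AlphabetError):
            GenomeRecord("g", "ACGU")

    def test_sites_with_n_dropped_by_default(self):
        genome = GenomeRecord("g", "TNTTTTTA")
        assert find_pam_sites(genome, "NNTA", 4) == []
        kept = find_pam_sites(genome, "NNTA", 4, keep_n=True)
        assert len(kept) == 1 and kept[0].protospacer_seq == "TNTT"

    def test_cut_position_three_nt_upstream_of_pam(self):
        genome = GenomeRecord("g", "C" * 30 + "TA" + "C" * 30)
        for site in find_pam_sites(genome, "NNTA", 22):
            if site.strand == "+":
                assert site.cut_pos == site.pam[0] - 3
            else:
                assert site.cut_pos == site.pam[1] + 3

    @pytest.mark.parametrize("motif", ["NNTA", "NGG"])
    @pytest.mark.parametrize("circular", [False, True])
    def test_matches_regex_oracle(self, motif, circular):
        for seed in range(25):
            genome = random_genome(
                180 + 13 * seed, gc=0.45, circular=circular, seed=seed
            )
            sites = find_pam_sites(genome, motif, 12)
            assert site_keys(sites) == regex_sites(genome, motif, 12)

    def test_strand_symmetry_under_genome_revcomp(self):
        genome = random_genome(400, seed=11)
        L = len(genome.seq)
        spacer = 10
        elen = spacer + 4
        fwd = site_keys(find_pam_sites(genome, "NNTA", spacer))
        flipped = GenomeRecord("g", reverse_complement(genome.seq))
        rev = site_keys(find_pam_sites(flipped, "NNTA", spacer))
        remapped = {
            ("-" if strand == "+" else "+", L - start - elen) for strand, start in rev
        }
        assert remapped == fwd

    def test_deterministic_and_sorted(self):
        genome = random_genome(500, seed=3)
        a = find_pam_sites(genome, "NNTA", 22)
        b = find_pam_sites(genome, "NNTA", 22)
        assert a == b
        assert [s.cut_pos for s in a] == sorted(s.cut_pos for s in a)


class TestBackToBackPairs:
    def test_single_ta_gives_one_divergent_pair(self):
        genome = GenomeRecord("g", "A" * 10 + "TA" + "A" * 10)
        sites = find_pam_sites(genome, "NNTA", 4)
        pairs = find_back_to_back_pairs(sites, "NNTA")
        assert len(pairs) == 1
        (pair,) = pairs
        assert pair.plus_site.protospacer == (4, 8)
        assert pair.minus_site.protospacer == (14, 18)
        assert pair.protospacer_gap == 6
        assert pair.ta_pos == 10

    def test_no_ta_no_pairs(self):
        genome = GenomeRecord("g", "C" * 40)
        assert find_back_to_back_pairs(find_pam_sites(genome, "NNTA", 4), "NNTA") == []

    def test_tata_box_core_holds_three_pairs(self):
        # TATAAATAAT carries TA dinucleotides at core offsets 0, 2 and 6
        genome = GenomeRecord("g", "C" * 30 + "TATAAATAAT" + "C" * 30)
        sites = find_pam_sites(genome, "NNTA", 8)
        pairs = find_back_to_back_pairs(sites, "NNTA")
        assert [p.ta_pos for p in pairs] == [30, 32, 36]
        assert all(p.protospacer_gap == 6 for p in pairs)

    def test_non_palindromic_motif_rejected(self):
        with pytest.raises(UnsupportedMotifError):
            find_back_to_back_pairs([], "NGG")

    def test_truncated_flank_leaves_site_unpaired(self):
        # TA close to the left end: the plus-strand protospacer is truncated
        genome = GenomeRecord("g", "ATA" + "A" * 20)
        sites = find_pam_sites(genome, "NNTA", 4)
        assert {s.strand for s in sites} == {"-"}
        assert find_back_to_back_pairs(sites, "NNTA") == []


class TestAntiRepeats:
    REPEAT = "ACGTACGTTGCAGGCATCGT"

    def test_planted_exact_complement_found(self):
        anti = reverse_complement(self.REPEAT)
        genome = GenomeRecord("g", "C" * 25 + anti + "C" * 25)
        hits = find_antirepeats(genome, self.REPEAT, min_identity=0.9)
        assert len(hits) == 1
        assert hits[0].identity == 1.0
        assert hits[0].interval == (25, 45)
        assert hits[0].strand == "+"

    def test_two_mismatches_give_identity_090(self):
        anti = list(reverse_complement(self.REPEAT))
        anti[3] = "A" if anti[3] != "A" else "C"
        anti[15] = "A" if anti[15] != "A" else "C"
        genome = GenomeRecord("g", "C" * 20 + "".join(anti) + "C" * 20)
        hits = find_antirepeats(genome, self.REPEAT, min_identity=0.85)
        assert len(hits) == 1
        assert hits[0].identity == pytest.approx(18 / 20)

    def test_agrees_with_sliding_window_oracle(self):
        genome = random_genome(600, seed=21)
        threshold = 0.7
        hits = find_antirepeats(genome, self.REPEAT, min_identity=threshold)
        # oracle: identity of every full-length window on both strands
        anti = reverse_complement(self.REPEAT)
        n = len(self.REPEAT)
        oracle = set()
        for i in range(len(genome.seq) - n + 1):
            win = genome.seq[i : i + n]
            if sum(a == b for a, b in zip(win, anti)) / n >= threshold:
                oracle.add((i, "+"))
            if sum(a == b for a, b in zip(win, self.REPEAT)) / n >= threshold:
                oracle.add((i, "-"))
        # every oracle window overlaps a reported hit, and every reported hit
        # is itself an above-threshold oracle window (merging keeps the best)
        for start, strand in oracle:
            assert any(
                h.strand == strand and h.interval[0] - n < start < h.interval[1]
                for h in hits
            )
        for h in hits:
            assert (h.interval[0], h.strand) in oracle
        if not oracle:
            assert hits == []

    def test_no_hits_in_plain_random_genome(self):
        genome = random_genome(500, seed=5)
        assert find_antirepeats(genome, self.REPEAT, min_identity=0.9) == []

    def test_bad_identity_parameter(self):
        from pamscape import ParameterError

        with pytest.raises(ParameterError):
            find_antirepeats(GenomeRecord("g", "ACGT" * 10), self.REPEAT, min_identity=1.5)
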