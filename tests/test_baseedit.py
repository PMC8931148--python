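"""Base-editor window geometry and correctable-variant scoping tests."""

import math

import pytest

from pamscape import (
    FRCAS9_ABE710,
    FRCAS9_BE4GAM,
    BaseEditorModel,
    DataError,
    GenomeRecord,
    ParameterError,
    VariantRecord,
    correctable_variants,
    double_window,
    editable_positions,
    find_back_to_back_pairs,
    find_pam_sites,
    reverse_complement,
    scope_difference,
)
from pamscape.synth import random_genome, simulate_variants, VariantSimConfig

from oracle_helpers import brute_correctability


class TestBaseEditorModel:
    def test_frcas9_windows(self):
        assert (FRCAS9_BE4GAM.window_start, FRCAS9_BE4GAM.window_end) == (6, 10)
        assert (FRCAS9_ABE710.window_start, FRCAS9_ABE710.window_end) == (6, 8)

    def test_only_cbe_abe_chemistries(self):
        with pytest.raises(ParameterError):
            BaseEditorModel("bad", "C", "G", 4, 8)

    def test_window_order_enforced(self):
        with pytest.raises(ParameterError):
            BaseEditorModel("bad", "C", "T", 8, 4)


def _plus_site(proto: str, left_flank: int = 4):
    """Genome with one plus-strand NNTA site holding *proto* as protospacer."""
    genome = GenomeRecord("g", "G" * left_flank + proto + "GGTA" + "G" * 4)
    sites = [
        s
        for s in find_pam_sites(genome, "NNTA", len(proto))
        if s.strand == "+" and s.protospacer[0] == left_flank
    ]
    assert sites, "construction error: expected a plus-strand site"
    return genome, sites[0]


class TestEditablePositions:
    def test_plus_strand_coordinates(self):
        # spacer 22 with C at protospacer positions 6 and 9 (1-based)
        proto = "GGGGGCGGCGGGGGGGGGGGGG"
        genome, site = _plus_site(proto)
        coords = editable_positions(site, FRCAS9_BE4GAM)
        # window 6..10 occupies plus coordinates a+5 .. a+9
        a = site.protospacer[0]
        assert coords == [a + 5, a + 8]

    def test_oracle_string_reconstruction_both_strands(self):
        genome = random_genome(300, seed=17)
        for site in find_pam_sites(genome, "NNTA", 22):
            expected = []
            for j in range(6, 11):
                if site.strand == "+":
                    coord = site.protospacer[0] + j - 1
                    base = genome.seq[coord]
                else:
                    coord = site.protospacer[1] - j
                    base = reverse_complement(genome.seq[coord])
                if base == "C":
                    expected.append(coord % len(genome.seq))
            assert editable_positions(site, FRCAS9_BE4GAM) == expected

    def test_no_substrate_in_window(self):
        proto = "G" * 22
        _, site = _plus_site(proto)
        assert editable_positions(site, FRCAS9_BE4GAM) == []

    def test_window_exceeding_spacer_rejected(self):
        _, site = _plus_site("G" * 8)
        with pytest.raises(ParameterError):
            editable_positions(site, FRCAS9_BE4GAM)


class TestCorrectableVariants:
    def _scope(self, genome, variants, editor=FRCAS9_BE4GAM):
        return correctable_variants(variants, genome, "NNTA", 22, editor)

    def test_planted_tc_snv_precise(self):
        # T>C pathogenic SNV at window position 7 of a plus-strand site,
        # no other C in the window -> correctable and precise
        proto = "GGGGGGTGGGGGGGGGGGGGGG"
        genome, site = _plus_site(proto)
        pos = site.protospacer[0] + 6  # protospacer position 7
        variant = VariantRecord("v1", "g", pos, ref="T", alt="C")
        (call,) = self._scope(genome, [variant])
        assert call.correctable and call.precise
        assert call.supporting_sites

    def test_bystander_blocks_precise(self):
        # same construct with an existing C at window position 9
        proto = "GGGGGGTGCGGGGGGGGGGGGG"
        genome, site = _plus_site(proto)
        pos = site.protospacer[0] + 6
        (call,) = self._scope(genome, [VariantRecord("v1", "g", pos, "T", "C")])
        assert call.correctable and not call.precise

    def test_wrong_chemistry_not_correctable(self):
        # G>A variant under a CBE: the patient carries A (plus) / T (minus),
        # neither of which is the C substrate, so no site can revert it
        proto = "GGGGGGGGGGGGGGGGGGGGGG"
        genome, site = _plus_site(proto)
        pos = site.protospacer[0] + 6  # window position 7, reference base G
        (call,) = self._scope(genome, [VariantRecord("v1", "g", pos, "G", "A")])
        assert not call.correctable and not call.precise

    def test_minus_strand_route(self):
        # the reverse complement of a precise plus-strand T>C construct is an
        # A>G variant corrected through a minus-strand site (C>T on that strand)
        proto = "GGGGGGTGGGGGGGGGGGGGGG"
        genome, site = _plus_site(proto)
        pos = site.protospacer[0] + 6
        L = len(genome.seq)
        flipped = GenomeRecord("g", reverse_complement(genome.seq))
        fv = VariantRecord("v1", "g", L - 1 - pos, ref="A", alt="G")
        (call,) = correctable_variants([fv], flipped, "NNTA", 22, FRCAS9_BE4GAM)
        assert call.correctable and call.precise
        assert all(sid.endswith(":-") for sid in call.supporting_sites)

    def test_ref_mismatch_is_data_error(self):
        genome, _ = _plus_site("G" * 22)
        with pytest.raises(DataError):
            self._scope(genome, [VariantRecord("v1", "g", 0, "T", "C")])

    def test_variant_outside_window_never_correctable(self):
        proto = "TGGGGGGGGGGGGGGGGGGGGG"  # T at position 1, outside 6..10
        genome, site = _plus_site(proto)
        pos = site.protospacer[0]
        (call,) = self._scope(genome, [VariantRecord("v1", "g", pos, "T", "C")])
        assert not call.correctable

    def test_matches_brute_force_oracle_on_synthetic_genomes(self):
        for seed in range(20):
            genome = random_genome(400, seed=100 + seed)
            variants, _ = simulate_variants(
                VariantSimConfig(n_variants=2, category="correctable", seed=seed),
                genome, "NNTA", 22, FRCAS9_BE4GAM,
            )
            rng_variants, _ = simulate_variants(
                VariantSimConfig(n_variants=2, category="uncorrectable", seed=seed),
                genome, "NNTA", 22, FRCAS9_BE4GAM,
            )
            for v in variants + rng_variants:
                (call,) = correctable_variants([v], genome, "NNTA", 22, FRCAS9_BE4GAM)
                assert (call.correctable, call.precise) == brute_correctability(
                    v, genome, "NNTA", 22, FRCAS9_BE4GAM
                )

    def test_chemistry_symmetry_under_strand_relabeling(self):
        genome = random_genome(400, seed=55)
        variants, _ = simulate_variants(
            VariantSimConfig(n_variants=3, category="correctable", seed=1),
            genome, "NNTA", 22, FRCAS9_BE4GAM,
        )
        calls = correctable_variants(variants, genome, "NNTA", 22, FRCAS9_BE4GAM)
        L = len(genome.seq)
        flipped = GenomeRecord(genome.id, reverse_complement(genome.seq))
        flipped_variants = [
            VariantRecord(
                v.variant_id, v.record_id, L - 1 - v.pos,
                reverse_complement(v.ref), reverse_complement(v.alt),
            )
            for v in variants
        ]
        flipped_calls = correctable_variants(
            flipped_variants, flipped, "NNTA", 22, FRCAS9_BE4GAM
        )
        for a, b in zip(calls, flipped_calls):
            assert (a.correctable, a.precise) == (b.correctable, b.precise)


class TestScopeDifference:
    def test_published_fraction_cbe(self):
        scope_a = {f"v{i}" for i in range(260)}
        scope_b = {f"v{i}" for i in range(235, 260)} | {f"x{i}" for i in range(500)}
        assert round(scope_difference(scope_a, scope_b), 4) == 0.9038  # 235/260

    def test_published_fraction_abe(self):
        scope_a = {f"v{i}" for i in range(1297)}
        scope_b = {f"v{i}" for i in range(1196, 1297)}
        assert round(scope_difference(scope_a, scope_b), 4) == 0.9221  # 1196/1297

    def test_identical_scopes(self):
        assert scope_difference({"a", "b"}, {"a", "b"}) == 0.0

    def test_empty_scope_a_is_nan_flag(self):
        assert math.isnan(scope_difference(set(), {"a"}))


class TestDoubleWindow:
    def _pair(self, spacer=22):
        genome = GenomeRecord("g", "A" * 30 + "TA" + "A" * 30)
        sites = find_pam_sites(genome, "NNTA", spacer)
        (pair,) = find_back_to_back_pairs(sites, "NNTA")
        return pair

    def test_symmetric_about_core(self):
        pair = self._pair()
        plus_iv, minus_iv = double_window(pair, FRCAS9_BE4GAM)
        ta = pair.ta_pos
        # 5-bp windows symmetric about the 6-bp NNTANN core [ta-2, ta+4)
        assert plus_iv == (ta - 19, ta - 14)
        assert minus_iv == (ta + 16, ta + 21)
        assert (ta - 2) - plus_iv[1] == minus_iv[0] - (ta + 4)
        assert plus_iv[1] <= minus_iv[0]  # disjoint, opposite sides

    def test_full_spacer_window_abuts_gap(self):
        pair = self._pair()
        editor = BaseEditorModel("full", "C", "T", 1, 22)
        plus_iv, minus_iv = double_window(pair, editor)
        assert plus_iv[1] == pair.ta_pos - 2  # touches the core's left edge
        assert minus_iv[0] == pair.ta_pos + 4  # touches the core's right edge
        assert minus_iv[0] - plus_iv[1] == 6

    def test_abe_window_is_three_bp(self):
        pair = self._pair()
        plus_iv, minus_iv = double_window(pair, FRCAS9_ABE710)
        assert plus_iv[1] - plus_iv[0] == 3
        assert minus_iv[1] - minus_iv[0] == 3
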