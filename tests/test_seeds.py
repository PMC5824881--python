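"""Seed-word derivation, pairing profiles, site scanning and the universe."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import mirseed as ms
from mirseed.seeds import classify_pair, revcomp_dna
from helpers_oracles import seed_site_scan

MIR96 = ms.MIR96
MIR182 = ms.MIR182
MIR183 = ms.MIR183

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)
dna_n = st.text(alphabet="ACGTN", min_size=0, max_size=200)


class TestSeedWords:
    @pytest.mark.parametrize(
        "mirna, word_7m8, word_7a1, word_8mer",
        [
            (MIR96, "GTGCCAA", "TGCCAAA", "GTGCCAAA"),
            (ms.MatureMirna("homopolymer", "AAAAAAAA"), "TTTTTTT", "TTTTTTA", "TTTTTTTA"),
        ],
    )
    def test_examples(self, mirna, word_7m8, word_7a1, word_8mer):
        words = ms.seed_words(mirna)
        assert words.word_7m8 == word_7m8
        assert words.word_7a1 == word_7a1
        assert words.word_8mer == word_8mer
        assert words.family_key == word_7m8

    def test_short_sequence_rejected_naming_the_mirna(self):
        with pytest.raises(ValueError, match="tiny"):
            ms.MatureMirna("tiny", "UUUGGCA")

    def test_non_rna_letters_rejected(self):
        with pytest.raises(ValueError, match="non-RNA"):
            ms.MatureMirna("bad", "UUTGGCACU")

    @given(dna)
    def test_revcomp_is_an_involution(self, s):
        assert revcomp_dna(revcomp_dna(s)) == s

    @given(st.text(alphabet="ACGU", min_size=8, max_size=30))
    def test_word_set_internal_consistency(self, seq):
        words = ms.seed_words(ms.MatureMirna("m", seq))
        assert words.word_8mer == words.word_7m8 + "A"
        assert words.word_7a1 == words.word_7m8[1:] + "A"


class TestPairingProfile:
    def test_wobbles_at_positions_4_and_5(self):
        # complement of miR-183 nt 1-8, then wobble partners at nt 4 and 5
        profile = ms.pairing_profile(MIR183, "GTGTTATA")
        assert profile[3] == "GU" and profile[4] == "GU"
        assert [profile[i] for i in (0, 1, 2, 5, 6, 7)] == ["WC"] * 6
        assert set(profile[8:]) == {"unpaired"}

    def test_perfect_duplex_is_all_wc(self):
        window = revcomp_dna(MIR96.sequence.replace("U", "T"))
        assert ms.pairing_profile(MIR96, window) == ["WC"] * len(MIR96.sequence)

    def test_poly_a_window_mismatches_every_non_u_seed_position(self):
        profile = ms.pairing_profile(MIR96, "A" * 8)
        for i in range(8):  # positions 1-8
            expected = "WC" if MIR96.sequence[i] == "U" else "mismatch"
            assert profile[i] == expected

    def test_non_acgt_window_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            ms.pairing_profile(MIR96, "ACGTNCGT")

    @pytest.mark.parametrize(
        "mir_base, utr_base, state",
        [("G", "T", "GU"), ("U", "G", "GU"), ("A", "T", "WC"), ("A", "G", "mismatch")],
    )
    def test_pair_classification(self, mir_base, utr_base, state):
        assert classify_pair(mir_base, utr_base) == state


class TestFindSeedSites:
    words96 = ms.seed_words(MIR96)

    @pytest.mark.parametrize(
        "sequence, expected",
        [
            ("ACGTGCCAAACG", [("8mer", 2, 10)]),
            ("TTTGCCAAA", [("7mer-1A", 2, 9)]),
            ("CCCCCCCC", []),
            ("", []),
            # 8mer suppresses the constituent 7mer-m8 and the shifted 7mer-1A
            ("GTGCCAAA", [("8mer", 0, 8)]),
            # N never matches
            ("GTGNCAAA", []),
        ],
    )
    def test_examples(self, sequence, expected):
        hits = ms.find_seed_sites(ms.UtrRecord("g", sequence), self.words96)
        assert [(h.site_type, h.start, h.end) for h in hits] == [
            (t, s, e) for t, s, e in expected
        ]

    @given(dna_n)
    def test_matches_naive_per_offset_oracle(self, sequence):
        hits = ms.find_seed_sites(ms.UtrRecord("g", sequence), self.words96)
        expected = seed_site_scan(
            sequence.upper(),
            self.words96.word_8mer,
            self.words96.word_7m8,
            self.words96.word_7a1,
        )
        assert sorted((h.site_type, h.start) for h in hits) == sorted(expected)

    @given(st.text(alphabet="ACGU", min_size=8, max_size=24), dna_n)
    def test_matches_oracle_for_arbitrary_mirnas(self, mir_seq, sequence):
        words = ms.seed_words(ms.MatureMirna("m", mir_seq))
        hits = ms.find_seed_sites(ms.UtrRecord("g", sequence), words)
        expected = seed_site_scan(
            sequence.upper(), words.word_8mer, words.word_7m8, words.word_7a1
        )
        assert sorted((h.site_type, h.start) for h in hits) == sorted(expected)


class TestFind3compSites:
    def test_constructed_compensatory_site(self):
        # [revcomp of miR-96 nt 13-16] + 2 nt gap + [7mer-m8 with one G:U]
        utr = ms.UtrRecord("g", "ATGT" + "AA" + "GTGCTAA")
        hits = ms.find_3comp_sites(utr, MIR96)
        assert [(h.site_type, h.start, h.end) for h in hits] == [("3comp", 6, 13)]

    def test_canonical_site_not_reported_as_3comp(self):
        utr = ms.UtrRecord("g", "AAAGTGCCAAGGG")
        assert ms.find_3comp_sites(utr, MIR96) == []

    def test_no_complementarity(self):
        assert ms.find_3comp_sites(ms.UtrRecord("g", "C" * 30), MIR96) == []

    def test_imperfect_seed_without_3p_block_is_not_a_site(self):
        utr = ms.UtrRecord("g", "CCCCCC" + "GTGCTAA")  # wobble seed, no 3' pairing
        assert ms.find_3comp_sites(utr, MIR96) == []


class TestBuildUniverse:
    def test_toy_universe_counts(self):
        utrs = [
            ms.UtrRecord("gene1", "ACGTGCCAAACG"),
            ms.UtrRecord("gene2", "TTTGCCAAA"),
            ms.UtrRecord("gene3", "CCCC"),
        ]
        universe = ms.build_universe(utrs, [MIR96])
        assert universe.genes == ["gene1", "gene2", "gene3"]
        assert universe.site_count("gene1", "GTGCCAA") == 1
        assert universe.site_count("gene2", "GTGCCAA") == 1
        assert universe.site_count("gene3", "GTGCCAA") == 0
        assert universe.n_sites_total == 2
        assert "gene3" in universe.genes  # zero-site genes stay in the background

    def test_identical_seeds_collapse_to_one_family(self):
        twin = ms.MatureMirna("miR-96-like", "CUUGGCACUAGCACAUUUUUGCU")
        universe = ms.build_universe(
            [ms.UtrRecord("g", "ACGTGCCAAACG")], [MIR96, twin]
        )
        assert universe.families == ["GTGCCAA"]

    def test_duplicated_seed_lists_give_identical_universes(self):
        utrs = [ms.UtrRecord("g1", "ACGTGCCAAACG"), ms.UtrRecord("g2", "TTTGCCAAA")]
        u1 = ms.build_universe(utrs, [MIR96])
        u2 = ms.build_universe(utrs, [MIR96, MIR96])
        assert u1 == u2

    def test_mir96_and_mir182_are_distinct_families_sharing_a_heptamer(self):
        w96, w182 = ms.seed_words(MIR96), ms.seed_words(MIR182)
        assert w96.family_key != w182.family_key
        assert w96.word_7a1 == w182.word_7a1 == "TGCCAAA"
        universe = ms.build_universe([ms.UtrRecord("g", "TTTGCCAAA")], [MIR96, MIR182])
        assert len(universe.families) == 2

    def test_duplicate_gene_id_rejected(self):
        utrs = [ms.UtrRecord("g", "ACGT"), ms.UtrRecord("g", "TTTT")]
        with pytest.raises(ValueError, match="'g'"):
            ms.build_universe(utrs, [MIR96])

    def test_conflicting_mirna_names_rejected(self):
        with pytest.raises(ValueError, match="miR-96"):
            ms.build_universe(
                [ms.UtrRecord("g", "ACGT")],
                [MIR96, ms.MatureMirna("miR-96", MIR183.sequence)],
            )

    def test_site_total_conserved(self, rng):
        bases = "ACGT"
        utrs = [
            ms.UtrRecord(
                f"g{i}", "".join(rng.choice(list(bases), size=300))
            )
            for i in range(20)
        ]
        mirnas = [MIR96, MIR182, MIR183]
        universe = ms.build_universe(utrs, mirnas)
        per_gene = sum(
            len(ms.find_seed_sites(u, ms.seed_words(m)))
            for u in utrs
            for m in mirnas
        )
        assert universe.n_sites_total == per_gene
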