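"""Word counting and the ranked-list sliding hypergeometric landscape."""

import math

import numpy as np
import pytest

import mirseed as ms
from mirseed.wordscape import WordCountIndex, default_cutpoints
from helpers_oracles import hypergeom_tail_ge, hypergeom_tail_le


def make_index(counts, positions, k=7):
    """Fabricate a WordCountIndex from {gene: {word: count}} and {gene: positions}."""
    return WordCountIndex(
        k=k,
        per_gene_counts={g: dict(c) for g, c in counts.items()},
        per_gene_positions=dict(positions),
    )


def oracle_signed(N, K, n, k_obs):
    if K == 0:
        return 0.0
    p_enrich = hypergeom_tail_ge(k_obs, N, K, n)
    p_deplete = hypergeom_tail_le(k_obs, N, K, n)
    if p_enrich < p_deplete:
        return -math.log10(p_enrich)
    return math.log10(p_deplete)


class TestCountWords:
    def test_overlap_free_double_occurrence(self):
        index = ms.count_words([ms.UtrRecord("g", "GTGCCAAGTGCCAA")], k=7)
        assert index.per_gene_counts["g"]["GTGCCAA"] == 2
        assert index.per_gene_positions["g"] == 8

    def test_overlapping_occurrences_all_count(self):
        index = ms.count_words([ms.UtrRecord("g", "AAAAAAAA")], k=7)
        assert index.per_gene_counts["g"]["AAAAAAA"] == 2

    def test_empty_sequence(self):
        index = ms.count_words([ms.UtrRecord("g", "")], k=7)
        assert index.per_gene_counts["g"] == {}
        assert index.per_gene_positions["g"] == 0

    def test_windows_containing_n_are_skipped(self):
        index = ms.count_words([ms.UtrRecord("g", "GTGCCAANGTGCCAA")], k=7)
        # N kills every window that spans it, for counts and position totals
        assert index.per_gene_counts["g"]["GTGCCAA"] == 2
        assert index.per_gene_positions["g"] == 2

    def test_panel_restricts_counts_but_not_positions(self):
        index = ms.count_words([ms.UtrRecord("g", "GTGCCAAT")], k=7,
                               word_panel=["GTGCCAA"])
        assert index.per_gene_counts["g"] == {"GTGCCAA": 1}
        assert index.per_gene_positions["g"] == 2

    def test_panel_word_sum_never_exceeds_positions(self, rng):
        utrs = [
            ms.UtrRecord(f"g{i}", "".join(rng.choice(list("ACGT"), size=50)))
            for i in range(10)
        ]
        panel = ms.mirna_word_panel([ms.MIR96, ms.MIR182, ms.MIR183])
        index = ms.count_words(utrs, 7, panel)
        for gene in index.genes:
            assert sum(index.per_gene_counts[gene].values()) <= (
                index.per_gene_positions[gene]
            )


class TestMirnaWordPanel:
    def test_cluster_panel_contains_the_shared_heptamers(self):
        panel = ms.mirna_word_panel([ms.MIR96, ms.MIR182, ms.MIR183])
        assert "GTGCCAA" in panel and "TGCCAAA" in panel
        assert panel == sorted(set(panel))

    def test_seed_mutant_panel(self):
        panel = ms.mirna_word_panel([ms.MIR96_DDL])
        assert panel == ["AGCCAAA", "GAGCCAA"]

    def test_single_mirna_gives_two_words(self):
        assert len(ms.mirna_word_panel([ms.MIR183])) == 2

    def test_degenerate_seed_gives_one_word(self):
        # nt 2-8 all U: the 7mer-m8 and 7mer-1A words coincide (AAAAAAA)
        mirna = ms.MatureMirna("polyU", "AUUUUUUU")
        assert ms.mirna_word_panel([mirna]) == ["AAAAAAA"]


class TestLandscape:
    def test_absent_word_is_flat_zero(self):
        index = make_index({"a": {}, "b": {}}, {"a": 10, "b": 10})
        ranked = ms.RankedGenes(("a", "b"))
        scape = ms.landscape(ranked, index, cutpoints=[1, 2], words=["GTGCCAA"])
        assert np.all(scape.signed == 0.0)

    def test_leading_gene_concentration_matches_enumeration_oracle(self):
        counts = {"a": {"W": 3}, "b": {}, "c": {}, "d": {}}
        positions = {g: 10 for g in "abcd"}
        index = make_index(counts, positions, k=1)
        ranked = ms.RankedGenes(("a", "b", "c", "d"))
        scape = ms.landscape(ranked, index, cutpoints=[1], words=["W"])
        expected = oracle_signed(N=40, K=3, n=10, k_obs=3)
        assert scape.value("W", 1) == pytest.approx(expected, rel=1e-9)
        assert scape.value("W", 1) > 0  # enrichment in the leading set

    def test_random_instances_match_enumeration_oracle(self, rng):
        genes = [f"g{i}" for i in range(6)]
        for _ in range(25):
            positions = {g: int(rng.integers(1, 11)) for g in genes}  # N <= 60
            counts = {
                g: {"W": int(rng.integers(0, positions[g] + 1))} for g in genes
            }
            index = make_index(counts, positions)
            ranked = ms.RankedGenes(tuple(genes))
            cutpoints = [1, 3, 6]
            scape = ms.landscape(ranked, index, cutpoints=cutpoints, words=["W"])
            N = sum(positions.values())
            K = sum(counts[g]["W"] for g in genes)
            for cut in cutpoints:
                n = sum(positions[g] for g in genes[:cut])
                k_obs = sum(counts[g]["W"] for g in genes[:cut])
                assert scape.value("W", cut) == pytest.approx(
                    oracle_signed(N, K, n, k_obs), rel=1e-9, abs=1e-12
                )

    def test_reversal_symmetry(self, rng):
        """Enrichment at cutpoint x equals depletion at n-x on the reversed list."""
        genes = [f"g{i}" for i in range(8)]
        positions = {g: int(rng.integers(2, 9)) for g in genes}
        counts = {g: {"W": int(rng.integers(0, positions[g]))} for g in genes}
        index = make_index(counts, positions)
        cuts = list(range(1, 8))
        fwd = ms.landscape(ms.RankedGenes(tuple(genes)), index,
                           cutpoints=cuts, words=["W"])
        rev = ms.landscape(ms.RankedGenes(tuple(reversed(genes))), index,
                           cutpoints=cuts, words=["W"])
        for x in range(1, 8):
            a = fwd.value("W", x)
            b = rev.value("W", 8 - x)
            assert abs(a) == pytest.approx(abs(b), rel=1e-9, abs=1e-12)

    def test_cutpoint_beyond_gene_count_rejected(self):
        index = make_index({"a": {}}, {"a": 5})
        with pytest.raises(ValueError, match="cutpoint"):
            ms.landscape(ms.RankedGenes(("a",)), index, cutpoints=[2])

    def test_ranking_orders_by_log2fc_descending_with_stable_ties(self):
        records = [
            ms.DeRecord.from_log2fc("a", -1.0, 0.5),
            ms.DeRecord.from_log2fc("b", 2.0, 0.5),
            ms.DeRecord.from_log2fc("c", 0.0, 0.5),
            ms.DeRecord.from_log2fc("d", 0.0, 0.5),
        ]
        assert ms.RankedGenes.from_records(records).gene_ids == ("b", "c", "d", "a")

    def test_default_cutpoints_cover_the_list(self):
        cuts = default_cutpoints(2000)
        assert cuts[0] == 40 and cuts[-1] == 2000 and len(cuts) == 50

    def test_planted_heptamers_dip_on_the_downregulated_side(
        self, repression_scenario, repression_landscape
    ):
        scape = repression_landscape
        n_genes = len(repression_scenario.de_records)
        for word in ms.seed_words(
            repression_scenario.config.planted_family
        ).heptamers:
            i = scape.words.index(word)
            j = int(np.argmin(scape.signed[i]))
            assert scape.signed[i, j] < -scape.bonferroni  # deep depletion
            assert scape.cutpoints[j] > n_genes / 2  # on the downregulated side


class TestBonferroniLine:
    @pytest.mark.parametrize(
        "n_words, expected, places",
        [(912, 4.261, 3), (1, 1.301, 3), (911, 4.2605, 4)],
    )
    def test_examples(self, n_words, expected, places):
        assert round(ms.bonferroni_line(n_words, 0.05), places) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ms.bonferroni_line(0)
        with pytest.raises(ValueError):
            ms.bonferroni_line(10, alpha=1.5)
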