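import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemoshift.enrichment import (
    EnrichmentRecord,
    bh_qvalues,
    directional_enrichment,
    enrich_collection,
    fisher_enrichment,
    fisher_from_counts,
    odds_ratio_from_counts,
    rank_tfs,
    volcano_table,
)
from chemoshift.errors import EmptyUniverseError, SetNotRepresentedError
from chemoshift.interaction import ResponsiveSelection
from chemoshift.io import GeneSet, GeneSetCollection

from oracles import bh_stepup_naive, fisher_two_sided_enumeration


def genes(prefix, n):
    return [f"{prefix}{i}" for i in range(n)]


class TestFisher:
    def test_independence_table_gives_or_one_p_one(self):
        # universe 20, responsive 10, set of 4, overlap 2 = exactly expected
        universe = genes("u", 20)
        responsive = universe[:10]
        gene_set = universe[8:12]  # overlap = u8, u9
        rec = fisher_enrichment(responsive, gene_set, universe)
        assert rec.a == 2 and rec.a + rec.b + rec.c + rec.d == 20
        assert rec.odds_ratio == pytest.approx(1.0)
        assert rec.p_value == pytest.approx(1.0)

    def test_haldane_anscombe_corrected_or(self):
        odds, _ = fisher_from_counts(5, 5, 0, 10)
        assert odds == pytest.approx(21.0)  # (5.5*10.5)/(5.5*0.5)

    def test_uncorrected_or_when_no_zero_cell(self):
        assert odds_ratio_from_counts(4, 2, 3, 6) == pytest.approx(4 * 6 / (2 * 3))

    @pytest.mark.parametrize("table", [(3, 2, 1, 7), (0, 5, 5, 5), (6, 0, 2, 9),
                                       (1, 1, 1, 1), (10, 2, 3, 10)])
    def test_p_matches_enumeration_oracle_spot_checks(self, table):
        _, p = fisher_from_counts(*table)
        assert p == pytest.approx(fisher_two_sided_enumeration(*table), rel=1e-9)

    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_role_swap_symmetry(self, a, b, c, d):
        """Transposing the 2x2 table (swapping set/responsive roles) changes nothing."""
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        or1, p1 = fisher_from_counts(a, b, c, d)
        or2, p2 = fisher_from_counts(a, c, b, d)
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert or1 == pytest.approx(or2, rel=1e-12)

    def test_empty_universe_raises(self):
        with pytest.raises(EmptyUniverseError):
            fisher_enrichment(["a"], ["a"], [])

    def test_unrepresented_set_raises(self):
        with pytest.raises(SetNotRepresentedError):
            fisher_enrichment(["a"], ["zzz"], ["a", "b"])


class TestDirectional:
    def make_selection(self, top, bottom):
        return ResponsiveSelection(0.05, tuple(top), tuple(bottom))

    def test_set_in_top_tail_polarizes_ors(self):
        universe = genes("u", 40)
        sel = self.make_selection(universe[:4], universe[4:8])
        or_all, or_top, or_bottom = directional_enrichment(sel, universe[:4], universe)
        assert or_top > or_bottom

    def test_disjoint_set_all_ors_below_one(self):
        universe = genes("u", 40)
        sel = self.make_selection(universe[:4], universe[4:8])
        ors = directional_enrichment(sel, universe[20:30], universe)
        assert all(v < 1 for v in ors)

    def test_or_all_consistent_with_fisher_record(self):
        universe = genes("u", 30)
        sel = self.make_selection(universe[:3], universe[3:6])
        gene_set = universe[2:10]
        rec = fisher_enrichment(sel.responsive, gene_set, universe)
        or_all, _, _ = directional_enrichment(sel, gene_set, universe)
        assert or_all == pytest.approx(rec.odds_ratio)


class TestRankTfs:
    def rec(self, name, p):
        return EnrichmentRecord(name, 1, 1, 1, 1, 1.0, p)

    def test_strict_cutoff(self):
        ranked = rank_tfs([self.rec("below", 1e-6), self.rec("at", 1e-5)])
        flags = {r.set_name: r.significant for r in ranked}
        assert flags == {"below": True, "at": False}

    def test_empty_input(self):
        assert rank_tfs([]) == []

    def test_order_invariant_to_input_order(self):
        recs = [self.rec("b", 0.2), self.rec("a", 0.2), self.rec("c", 0.1)]
        names = [r.set_name for r in rank_tfs(recs)]
        names_rev = [r.set_name for r in rank_tfs(recs[::-1])]
        assert names == names_rev == ["c", "a", "b"]

    def test_too_small_never_significant(self):
        small = EnrichmentRecord("tiny", 1, 0, 0, 5, 10.0, 1e-9, too_small=True)
        assert rank_tfs([small])[0].significant is False


class TestBH:
    def test_hand_examples(self):
        np.testing.assert_allclose(bh_qvalues([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        np.testing.assert_allclose(bh_qvalues([0.5]), [0.5])
        np.testing.assert_allclose(bh_qvalues([0.04, 0.01]), [0.04, 0.02])

    def test_matches_naive_definition_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            m = rng.integers(1, 60)
            p = rng.uniform(size=m)
            np.testing.assert_allclose(bh_qvalues(p), bh_stepup_naive(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, p):
        q = bh_qvalues(p)
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = bh_qvalues(np.asarray(p)[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)

    @pytest.mark.parametrize("bad", [[-0.1], [1.5], [float("nan")]])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            bh_qvalues(bad)


class TestVolcano:
    def test_coordinates(self):
        recs = [
            EnrichmentRecord("unit", 1, 1, 1, 1, 1.0, 1.0),
            EnrichmentRecord("tiny_p", 5, 1, 1, 10, 50.0, 0.0),
        ]
        table = volcano_table(recs)
        assert len(table) == 2
        assert table.loc[0, "log2_odds_ratio"] == 0.0
        assert table.loc[0, "neg_log10_p"] == 0.0
        assert table.loc[1, "neg_log10_p"] == 300.0  # clipped


class TestEnrichCollection:
    def test_planted_set_attains_smallest_p(self, small_experiment):
        from chemoshift.interaction import InteractionModel

        matrix, design, collection, truth = small_experiment
        sel = InteractionModel(matrix, design).fit().select_responsive()
        ranked = rank_tfs(enrich_collection(sel, collection, matrix.gene_ids))
        assert ranked[0].set_name == truth.active_tf
        assert ranked[0].p_value == min(r.p_value for r in ranked)

    def test_universe_modes(self):
        measured = genes("u", 50)
        coll = GeneSetCollection.from_sets(
            [GeneSet("s1", "", frozenset(measured[:10])),
             GeneSet("s2", "", frozenset(measured[10:20]))]
        )
        sel = ResponsiveSelection(0.05, tuple(measured[:2]), tuple(measured[10:12]))
        rec_i = enrich_collection(sel, coll, measured, universe_mode="intersect")
        rec_m = enrich_collection(sel, coll, measured, universe_mode="measured")
        assert rec_i[0].a + rec_i[0].b + rec_i[0].c + rec_i[0].d == 20
        assert rec_m[0].a + rec_m[0].b + rec_m[0].c + rec_m[0].d == 50
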