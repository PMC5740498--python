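"""TileSeq pair counting, filtering, enrichment scoring and anchoring."""

import numpy as np
import pandas as pd
import pytest

from dmskit.seqcore import OrfSequence
from dmskit.tileseq import (
    CodonCountTable,
    TileDefinition,
    TileSeqModel,
    anchor_scores,
    call_codon_changes,
    count_tile_pairs,
    filter_low_input,
    make_tiles,
    tileseq_score,
)

ORF = OrfSequence(
    "t", "ATG" + "AAA" + "GAA" + "TGG" + "CTG" + "TCC" + "GGT" + "CAT" + "TAA"
)
TILE = TileDefinition("tile1", 2, 8)  # codons 2..8, 21 nt
REF = TILE.reference(ORF)


def _mutate(seq: str, codon_offset: int, new_codon: str) -> str:
    i = 3 * codon_offset
    return seq[:i] + new_codon + seq[i + 3 :]


class TestPairCounting:
    def test_both_mates_agreeing_counted_once(self):
        read = _mutate(REF, 0, "GAA")  # AAA->GAA at codon 2
        counts, depth = count_tile_pairs([read], [read], TILE, ORF)
        assert depth == 1
        (v, n), = counts.items()
        assert (v.codon_index, v.wt_codon, v.mut_codon) == (2, "AAA", "GAA")
        assert n == 1

    def test_single_mate_variant_not_counted(self):
        mutated = _mutate(REF, 0, "GAA")
        counts, depth = count_tile_pairs([mutated], [REF], TILE, ORF)
        assert counts == {} and depth == 1

    def test_disagreeing_mates_not_counted(self):
        counts, _ = count_tile_pairs(
            [_mutate(REF, 0, "GAA")], [_mutate(REF, 0, "CAA")], TILE, ORF
        )
        assert counts == {}

    def test_one_percent_variant_fixture(self):
        mutated = _mutate(REF, 2, "TAG")
        m1 = [mutated if i % 100 == 0 else REF for i in range(1000)]
        counts, depth = count_tile_pairs(m1, list(m1), TILE, ORF)
        assert depth == 1000
        (v, n), = counts.items()
        assert n == 10
        assert v.codon_index == 4 and v.mut_codon == "TAG"

    def test_multi_codon_pair_counts_each_change(self):
        read = _mutate(_mutate(REF, 0, "GAA"), 3, "CTC")
        counts, _ = count_tile_pairs([read], [read], TILE, ORF)
        assert len(counts) == 2

    def test_heavily_mismatched_pairs_discarded(self):
        garbage = "T" * len(REF)
        counts, depth = count_tile_pairs([garbage], [garbage], TILE, ORF)
        assert depth == 0 and counts == {}

    def test_mate_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_tile_pairs([REF], [REF[:-3]], TILE, ORF)

    def test_call_codon_changes_builds_table(self):
        read = _mutate(REF, 0, "GAA")
        table = call_codon_changes(
            {"tile1": ([read, REF], [read, REF])}, ORF, [TILE],
            condition="nonselect", replicate=1,
        )
        assert table.counts["count"].sum() == 1
        assert (table.depths.depth == 2).all()
        assert set(table.depths.codon_index) == set(range(2, 9))


class TestFilterLowInput:
    def test_within_three_sd_removed(self):
        keep = filter_low_input(
            np.array([7e-6]), np.array([5e-6]), np.array([1e-6])
        )
        assert not keep[0]

    def test_above_three_sd_kept(self):
        keep = filter_low_input(
            np.array([9e-6]), np.array([5e-6]), np.array([1e-6])
        )
        assert keep[0]

    def test_boundary_is_removed(self):
        # exactly mean + 3 sd counts as "within"
        keep = filter_low_input(np.array([8e-6]), np.array([5e-6]), np.array([1e-6]))
        assert not keep[0]


def _count_table(rows, depth=10**6, codons=(2,)):
    counts = pd.DataFrame(
        rows, columns=["codon_index", "wt_codon", "mut_codon", "condition",
                       "replicate", "count"]
    )
    depths = pd.DataFrame(
        [
            {"codon_index": ci, "condition": cond, "replicate": rep,
             "depth": depth}
            for ci in codons
            for cond in ("nonselect", "select", "wtctrl")
            for rep in (1, 2)
        ]
    )
    return CodonCountTable(counts, depths)


class TestEnrichmentScoring:
    def test_worked_example(self):
        # f_ns = 1e-4, f_wt = 5e-6, f_sel = 6e-5 -> E = 5.5e-5/9.5e-5
        rows = []
        for rep in (1, 2):
            rows += [
                (2, "AAA", "GAA", "nonselect", rep, 100),
                (2, "AAA", "GAA", "select", rep, 60),
                (2, "AAA", "GAA", "wtctrl", rep, 5),
            ]
        scores = tileseq_score(_count_table(rows))
        row = scores.iloc[0]
        assert not row.filtered
        assert row.E == pytest.approx(5.5e-5 / 9.5e-5, rel=1e-9)
        assert row.E == pytest.approx(0.579, abs=5e-4)

    def test_full_depletion_floors_near_zero(self):
        rows = []
        for rep in (1, 2):
            rows += [
                (2, "AAA", "GAA", "nonselect", rep, 1000),
                (2, "AAA", "GAA", "select", rep, 5),
                (2, "AAA", "GAA", "wtctrl", rep, 5),
            ]
        scores = tileseq_score(_count_table(rows))
        assert scores.iloc[0].E == pytest.approx(0.0, abs=1e-3)

    def test_no_selection_effect_gives_unity(self):
        rows = []
        for rep in (1, 2):
            rows += [
                (2, "AAA", "GAA", "nonselect", rep, 500),
                (2, "AAA", "GAA", "select", rep, 500),
            ]
        scores = tileseq_score(_count_table(rows))
        assert scores.iloc[0].E == pytest.approx(1.0, rel=1e-6)

    def test_zero_wtctrl_with_positive_input_kept(self):
        rows = []
        for rep in (1, 2):
            rows += [
                (2, "AAA", "GAA", "nonselect", rep, 500),
                (2, "AAA", "GAA", "select", rep, 400),
            ]
        scores = tileseq_score(_count_table(rows))
        assert not scores.iloc[0].filtered

    def test_depth_invariance(self):
        rows = []
        for rep in (1, 2):
            rows += [
                (2, "AAA", "GAA", "nonselect", rep, 100),
                (2, "AAA", "GAA", "select", rep, 60),
                (2, "AAA", "GAA", "wtctrl", rep, 5),
            ]
        base = tileseq_score(_count_table(rows))
        scaled_rows = [
            (ci, wt, mut, cond, rep, count * 7 if cond == "select" else count)
            for ci, wt, mut, cond, rep, count in rows
        ]
        table = _count_table(scaled_rows)
        table.depths.loc[table.depths.condition == "select", "depth"] *= 7
        scaled = tileseq_score(table)
        assert scaled.iloc[0].E == pytest.approx(base.iloc[0].E, rel=1e-12)


class TestAnchoring:
    def _scores(self, e_syn, e_non, e_mis):
        rows = []
        for i, e in enumerate(e_syn):
            rows.append({"class": "synonymous", "E": e, "i": i})
        for i, e in enumerate(e_non):
            rows.append({"class": "nonsense", "E": e, "i": i})
        for i, e in enumerate(e_mis):
            rows.append({"class": "missense", "E": e, "i": i})
        df = pd.DataFrame(rows)
        df["filtered"] = False
        df["sd"] = 0.1
        df["se"] = 0.05
        return df

    def test_anchor_medians_map_to_zero_and_one(self):
        df = self._scores([0.9, 1.0, 1.1, 1.2, 0.8], [0.1, 0.2, 0.0, 0.15, 0.05],
                          [0.5])
        anchored, anchors = anchor_scores(df)
        syn = anchored[anchored["class"] == "synonymous"].score
        non = anchored[anchored["class"] == "nonsense"].score
        assert syn.median() == 1.0
        assert non.median() == 0.0

    def test_halfway_point_maps_to_half(self):
        df = self._scores([1.0] * 5, [0.2] * 5, [0.6])
        anchored, _ = anchor_scores(df)
        assert anchored[anchored["class"] == "missense"].score.iloc[0] == \
            pytest.approx(0.5)

    def test_equal_medians_error(self):
        df = self._scores([0.5] * 5, [0.5] * 5, [])
        with pytest.raises(ValueError, match="dynamic range"):
            anchor_scores(df)

    def test_too_few_anchors_error(self):
        df = self._scores([1.0] * 4, [0.0] * 5, [])
        with pytest.raises(ValueError, match=">= 5"):
            anchor_scores(df)


class TestSimulatedRecovery:
    def test_anchored_medians_and_truth_correlation(self, tileseq_sim):
        cfg, orf, pool, truth, table = tileseq_sim
        res = TileSeqModel(table, gene="SYN").fit()
        anchored = res.anchored
        ok = ~anchored.filtered
        assert anchored.loc[
            ok & (anchored["class"] == "nonsense"), "score"
        ].median() == 0.0
        assert anchored.loc[
            ok & (anchored["class"] == "synonymous"), "score"
        ].median() == 1.0
        m = res.score_map()
        key = m.wt_aa + m.position.astype(str) + m.mut_aa
        tm = truth.set_index("key")["true_score"]
        common = key[key.isin(tm.index)]
        r = np.corrcoef(
            m.set_index(key).loc[common, "score"], tm.loc[common]
        )[0, 1]
        assert r >= 0.75  # small instance; full-scale recovery is checked
        # in the acceptance suite

    def test_every_counted_variant_has_truth(self, tileseq_sim):
        cfg, orf, pool, truth, table = tileseq_sim
        from dmskit.seqcore import CodonVariant

        truth_keys = set(truth.key)
        for row in table.counts[["codon_index", "wt_codon", "mut_codon"]
                                ].drop_duplicates().itertuples(index=False):
            v = CodonVariant(row.codon_index, row.wt_codon, row.mut_codon)
            if v.wt_aa != v.mut_aa:  # synonymous changes are truth 1 implicitly
                assert f"{v.wt_aa}{v.codon_index}{v.mut_aa}" in truth_keys

    def test_filter_exercised(self, tileseq_sim):
        cfg, orf, pool, truth, table = tileseq_sim
        res = TileSeqModel(table).fit()
        assert (res.codon_scores.reason == "low_input").sum() > 0


def test_make_tiles_partitions_orf():
    orf = OrfSequence("x", "ATG" + "AAA" * 120 + "TAA")
    tiles = make_tiles(orf)
    assert all(t.nt_span <= 150 for t in tiles)
    covered = sorted(
        ci for t in tiles for ci in range(t.first_codon, t.last_codon + 1)
    )
    assert covered == list(range(2, orf.n_codons))
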