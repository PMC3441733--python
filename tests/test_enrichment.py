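"""DE classification, hypergeometric tail, BH and enrichment tables."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirseed import (
    DEClassification,
    DERecord,
    PredictionSource,
    bh_adjust,
    classify_de,
    classify_de_table,
    enrich_experiment,
    hypergeom_tail,
    regional_enrichment,
    target_set_overlap,
)

# -- independent oracles ----------------------------------------------------


def oracle_hypergeom_tail(k, n, K, N):
    """P(X >= k) by enumerating every size-n draw from N items, K marked."""
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for i in draw if i < K) >= k:
            hits += 1
    return hits / total


def oracle_bh(pvalues):
    """Step-up BH written longhand."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adj[i] = running
    return adj


class TestClassifyDE:
    def _records(self):
        return [
            DERecord("g1", A=9.0, M=-0.8, p=0.001, adjP=0.01),
            DERecord("g2", A=7.0, M=-2.0, p=0.0001, adjP=0.001),
            DERecord("g3", A=9.0, M=0.1, p=0.8, adjP=0.9),
            DERecord("g4", A=10.0, M=1.2, p=0.001, adjP=0.02),
        ]

    def test_thresholds(self):
        dc = classify_de(self._records())
        assert dc.down == {"g1"}
        assert dc.up == {"g4"}
        assert "g2" not in dc.universe  # A below the expression cut
        assert "g3" in dc.universe

    def test_universe_mode_all_keeps_unexpressed(self):
        dc = classify_de(self._records(), universe_mode="all")
        assert "g2" in dc.universe and "g2" in dc.down

    def test_duplicate_ids_rejected(self):
        recs = self._records() + [DERecord("g1", 9, -1, 0.1, 0.2)]
        with pytest.raises(ValueError, match="duplicate"):
            classify_de(recs)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            classify_de([DERecord("g1", 5.0, -1.0, 0.1, 0.2)])

    def test_table_variant_agrees_with_records(self):
        recs = self._records()
        df = pd.DataFrame(
            [(r.transcript_id, r.A, r.M, r.p, r.adjP) for r in recs],
            columns=["transcript_id", "A", "M", "p", "adjP"],
        )
        a, b = classify_de(recs), classify_de_table(df)
        assert (a.universe, a.down, a.up) == (b.universe, b.down, b.up)

    def test_invalid_pvalue_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            DERecord("g1", 9.0, -1.0, 0.5, 1.5)


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "k,n,K,N,expected",
        [
            (0, 5, 3, 10, 1.0),
            (4, 4, 5, 10, 5 / 210),
            (3, 3, 3, 6, 1 / 20),
        ],
    )
    def test_hand_enumerated_values(self, k, n, K, N, expected):
        assert hypergeom_tail(k, n, K, N) == pytest.approx(expected, abs=1e-12)

    def test_bound_violation_raises(self):
        with pytest.raises(ValueError, match="bounds"):
            hypergeom_tail(4, 3, 5, 10)

    def test_matches_enumeration_on_small_grid(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        assert hypergeom_tail(k, n, K, N) == pytest.approx(
                            oracle_hypergeom_tail(k, n, K, N), abs=1e-12
                        )


class TestBHAdjust:
    @pytest.mark.parametrize(
        "pvalues,expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_hand_worked_examples(self, pvalues, expected):
        assert bh_adjust(pvalues) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_matches_longhand_step_up_and_dominates_input(self, pvalues):
        adj = bh_adjust(pvalues)
        assert adj == pytest.approx(oracle_bh(pvalues))
        assert np.all(adj >= np.asarray(pvalues) - 1e-12)


def _declass(universe, down, up=frozenset()):
    return DEClassification(
        universe=set(universe), down=set(down), up=set(up),
        a_min=8, m_cut=0.5, adjp_max=0.05,
    )


class TestEnrichExperiment:
    def test_disjoint_targets_give_p1_fold0(self):
        universe = {f"g{i}" for i in range(20)}
        dc = _declass(universe, {"g0", "g1"})
        src = PredictionSource("s", {("mirX", "g10"), ("mirX", "g11")})
        row = enrich_experiment(dc, [src], ["mirX"], ("down",)).iloc[0]
        assert row.k == 0 and row.p_hyper == 1.0 and row.fold == 0.0

    def test_down_equals_universe_gives_fold1_p1(self):
        universe = {f"g{i}" for i in range(10)}
        dc = _declass(universe, universe)
        src = PredictionSource("s", {("mirX", f"g{i}") for i in range(4)})
        row = enrich_experiment(dc, [src], ["mirX"], ("down",)).iloc[0]
        assert row.fold == pytest.approx(1.0) and row.p_hyper == 1.0

    def test_absent_mirna_reported_as_missing(self):
        dc = _declass({"g0", "g1"}, {"g0"})
        src = PredictionSource("s", {("mirX", "g0")})
        table = enrich_experiment(dc, [src], ["mirX", "mirY"], ("down",))
        missing = table[table["mirna"] == "mirY"].iloc[0]
        assert missing.K == 0 and missing.p_hyper == 1.0
        assert math.isnan(missing.fold) and math.isnan(missing.adjP)

    def test_targets_outside_universe_do_not_count(self):
        dc = _declass({"g0", "g1", "g2", "g3"}, {"g0"})
        src = PredictionSource("s", {("mirX", "g0"), ("mirX", "nope")})
        row = enrich_experiment(dc, [src], ["mirX"], ("down",)).iloc[0]
        assert row.K == 1 and row.k == 1

    def test_identical_target_sets_get_identical_statistics(self):
        universe = {f"g{i}" for i in range(50)}
        dc = _declass(universe, {f"g{i}" for i in range(5)})
        pairs_a = {("mirA", f"g{i}") for i in range(0, 10)}
        pairs_b = {("mirB", f"g{i}") for i in range(0, 10)}
        src = PredictionSource("s", pairs_a | pairs_b)
        table = enrich_experiment(dc, [src], ["mirA", "mirB"], ("down",))
        a = table[table["mirna"] == "mirA"].iloc[0]
        b = table[table["mirna"] == "mirB"].iloc[0]
        for col in ("k", "K", "p_hyper", "fold", "adjP"):
            assert a[col] == b[col]

    def test_bh_family_is_per_source_and_category(self):
        universe = {f"g{i}" for i in range(30)}
        dc = _declass(universe, {f"g{i}" for i in range(6)},
                      {f"g{i}" for i in range(6, 12)})
        rngish = [("mirA", f"g{i}") for i in range(6)]
        src1 = PredictionSource("s1", set(rngish))
        src2 = PredictionSource("s2", {("mirA", "g20")})
        table = enrich_experiment(dc, [src1, src2], ["mirA"])
        # one row per (source, category)
        assert len(table) == 4
        s1_down = table[
            (table.source == "s1") & (table.category == "down")
        ].iloc[0]
        assert s1_down.adjP == pytest.approx(s1_down.p_hyper)  # family of 1

    def test_fold_invariant_under_relabeling(self):
        universe = [f"g{i}" for i in range(40)]
        down = universe[:8]
        pairs = {("mirA", g) for g in universe[:16]}
        dc1 = _declass(universe, down)
        t1 = enrich_experiment(dc1, [PredictionSource("s", pairs)],
                               ["mirA"], ("down",))
        relabel = {g: f"x{i}" for i, g in enumerate(universe)}
        dc2 = _declass(relabel.values(), [relabel[g] for g in down])
        pairs2 = {("mirA", relabel[g]) for g in universe[:16]}
        t2 = enrich_experiment(dc2, [PredictionSource("s", pairs2)],
                               ["mirA"], ("down",))
        assert t1.iloc[0].fold == t2.iloc[0].fold

    def test_random_down_sets_control_type_one_error(self, rng):
        # permuting down labels at random: decoys rarely reach adjP < 0.05
        universe = [f"g{i}" for i in range(400)]
        n_mirnas = 25
        pairs = set()
        for m in range(n_mirnas):
            targets = rng.choice(universe, size=80, replace=False)
            pairs |= {(f"mir{m:02d}", g) for g in targets}
        src = PredictionSource("s", pairs)
        hits = trials = 0
        for _ in range(20):
            down = set(rng.choice(universe, size=40, replace=False))
            dc = _declass(universe, down)
            table = enrich_experiment(dc, [src],
                                      [f"mir{m:02d}" for m in range(n_mirnas)],
                                      ("down",))
            hits += int((table["adjP"] < 0.05).sum())
            trials += n_mirnas
        assert hits / trials <= 0.05


class TestRegionalEnrichment:
    def _sites(self, rows):
        return pd.DataFrame(
            rows,
            columns=["mirna", "transcript", "region", "start", "spec",
                     "wobbles", "distance_to_stop"],
        )

    def test_bins_by_distance_to_stop(self):
        universe = {f"g{i}" for i in range(40)}
        down = {f"g{i}" for i in range(8)}
        rows = [("mirA", f"g{i}", "3UTR", 10 + i, "seed2-7", 0, 9 + i)
                for i in range(8)]  # near-stop sites on the down set
        rows += [("mirA", f"g{i}", "3UTR", 450, "seed2-7", 0, 449)
                 for i in range(20, 30)]  # distal sites off the down set
        table = regional_enrichment(_declass(universe, down),
                                    self._sites(rows))
        near = table[table["bin"] == "3UTR[0,200)"].iloc[0]
        far = table[table["bin"] == "3UTR[400,600)"].iloc[0]
        assert near.fold > far.fold
        assert near.k == 8 and far.k == 0

    def test_cds_whole_region_and_zero_fold(self):
        universe = {f"g{i}" for i in range(10)}
        rows = [("mirA", "g5", "CDS", 3, "seed2-7", 0, -20)]
        table = regional_enrichment(_declass(universe, {"g0"}),
                                    self._sites(rows))
        assert list(table["bin"]) == ["CDS"]
        assert table.iloc[0].fold == 0.0

    def test_empty_site_table(self):
        out = regional_enrichment(_declass({"g0"}, set()), self._sites([]))
        assert out.empty


class TestTargetSetOverlap:
    def test_identical_sets(self):
        t = target_set_overlap({"a": {"x", "y"}, "b": {"x", "y"}})
        assert t.iloc[0].jaccard == 1.0 and t.iloc[0].overlap_pct == 100.0

    def test_disjoint_sets(self):
        t = target_set_overlap({"a": {"x"}, "b": {"y"}})
        assert t.iloc[0].jaccard == 0.0 and t.iloc[0].overlap_pct == 0.0

    def test_hand_counted_partition(self):
        t = target_set_overlap({"A": {"a", "b", "c"}, "B": {"b", "c", "d", "e"}})
        row = t.iloc[0]
        assert row.intersection == 2
        assert row.only_a == 1 and row.only_b == 2
        assert row.jaccard == pytest.approx(2 / 5)
        assert row.overlap_pct == pytest.approx(100 * 2 / 3)

    def test_empty_set_percent_is_missing(self):
        t = target_set_overlap({"a": set(), "b": {"x"}})
        assert math.isnan(t.iloc[0].overlap_pct)

    def test_fewer_than_two_experiments_rejected(self):
        with pytest.raises(ValueError):
            target_set_overlap({"a": {"x"}})
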