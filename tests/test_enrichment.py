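"""Pathway over-representation, Fisher combination, clustering, AIM ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligomir import io as oio
from oligomir.enrichment import (
    EnrichmentCell,
    Pathway,
    PathwayCollection,
    TargetScoreTable,
    assign_groups,
    bh_adjust,
    build_heatmap_matrix,
    cluster_rows,
    combine_fisher,
    enrich_all,
    export_pathway_network,
    pathway_hypergeom,
    rank_by_aim,
    threshold_targets,
)


def make_table(rows):
    df = pd.DataFrame(rows, columns=["mir_id", "gene_id", "score"])
    return TargetScoreTable.from_frame(df)


def make_pathways(layout):
    """layout: {pid: (genes, group)}"""
    return PathwayCollection(
        {pid: Pathway(pid, pid, frozenset(g), grp) for pid, (g, grp) in layout.items()}
    )


class TestThreshold:
    def test_tau_zero_keeps_everything_tau_one_only_perfect(self):
        t = make_table(
            [("m1", "g1", 0.0), ("m1", "g2", 0.7), ("m1", "g3", 1.0)]
        )
        assert threshold_targets(t, tau=0.0)["m1"] == {"g1", "g2", "g3"}
        assert threshold_targets(t, tau=1.0)["m1"] == {"g3"}

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=40, deadline=None)
    def test_sets_shrink_monotonically_in_tau(self, scores):
        t = make_table([("m", f"g{i}", s) for i, s in enumerate(scores)])
        prev = None
        for tau in (0.0, 0.3, 0.6, 0.9, 1.0):
            cur = threshold_targets(t, tau)["m"]
            if prev is not None:
                assert cur <= prev
            prev = cur


def brute_force_overlap_tail(N, K, n, k):
    """Enumerate all C(N, n) target draws; fraction overlapping >= k."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total if total else 1.0


class TestHypergeom:
    def test_hand_enumerated_example(self):
        # universe 20, pathway 5, targets 5, overlap 4:
        # (C(5,4)*C(15,1) + C(5,5)) / C(20,5) = 76/15504
        universe = {f"g{i}" for i in range(20)}
        pathway = {f"g{i}" for i in range(5)}
        targets = {"g0", "g1", "g2", "g3", "g10"}
        cell = pathway_hypergeom(targets, pathway, universe)
        assert cell.overlap == 4
        assert cell.p_hyper == pytest.approx(76 / 15504, rel=1e-12)

    def test_degenerate_cases(self):
        universe = {f"g{i}" for i in range(8)}
        assert pathway_hypergeom(set(), set(list(universe)[:3]), universe).p_hyper == 1.0
        assert pathway_hypergeom({"g0"}, universe, universe).p_hyper == 1.0
        with pytest.raises(ValueError, match="empty"):
            pathway_hypergeom({"g0"}, {"g0"}, set())

    def test_matches_exhaustive_enumeration_small_universes(self):
        for N in (5, 8, 11):
            universe = {f"g{i}" for i in range(N)}
            for K in (1, N // 2, N - 1):
                pathway = {f"g{i}" for i in range(K)}
                for n in (1, N // 2, N):
                    targets = set(
                        np.random.default_rng(N * 100 + K * 10 + n)
                        .choice(sorted(universe), size=n, replace=False)
                        .tolist()
                    )
                    cell = pathway_hypergeom(targets, pathway, universe)
                    expect = brute_force_overlap_tail(N, K, n, cell.overlap)
                    assert cell.p_hyper == pytest.approx(expect, abs=1e-12)


class TestFisher:
    def test_single_value_identity(self):
        for p in np.linspace(0.001, 1.0, 37):
            res = combine_fisher([float(p)])
            assert res.p_combined == pytest.approx(float(p), abs=1e-12)

    def test_df4_closed_form(self):
        res = combine_fisher([0.1, 0.1])
        x = -2 * (math.log(0.1) + math.log(0.1))
        assert res.X2 == pytest.approx(9.2103, abs=1e-3)
        assert res.df == 4
        assert res.p_combined == pytest.approx(math.exp(-x / 2) * (1 + x / 2), rel=1e-12)
        assert res.p_combined == pytest.approx(0.0561, abs=2e-4)

    def test_all_ones_gives_one(self):
        res = combine_fisher([1.0, 1.0, 1.0])
        assert res.X2 == 0.0
        assert res.p_combined == 1.0

    def test_zero_pvalue_rejected_and_floor_applied(self):
        with pytest.raises(ValueError):
            combine_fisher([0.0, 0.5])
        res = combine_fisher([1e-310, 0.5])  # subnormal floored, not fatal
        assert np.isfinite(res.X2)

    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=6
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_order_invariant_and_monotone(self, ps):
        a = combine_fisher(ps).p_combined
        b = combine_fisher(list(reversed(ps))).p_combined
        assert a == pytest.approx(b, rel=1e-12)
        smaller = list(ps)
        smaller[0] = smaller[0] / 2
        assert combine_fisher(smaller).p_combined <= a + 1e-12


class TestHeatmapAndClustering:
    def test_neglog10_entries_and_masking(self):
        cells = [
            EnrichmentCell("m1", "P1", 1, 2, 2, 10, 0.05),
            EnrichmentCell("m1", "P2", 0, 2, 2, 10, 1.0),
        ]
        combined = [
            combine_fisher([0.04], pathway_id="P1"),
            combine_fisher([1.0], pathway_id="P2"),
        ]
        heat = build_heatmap_matrix(cells, combined, alpha=0.05)
        assert list(heat.values.columns) == ["P1"]
        # the cell keeps its own hypergeometric p: -log10(0.05) = 1.301
        assert heat.values.loc["m1", "P1"] == pytest.approx(1.301, abs=1e-3)
        assert bool(heat.significant.loc["m1", "P1"])  # p = 0.05 counts ("<=")
        full = build_heatmap_matrix(cells, combined, alpha=1.0)
        assert set(full.values.columns) == {"P1", "P2"}
        assert full.values.loc["m1", "P2"] == 0.0

    def test_identical_rows_merge_first(self):
        m = pd.DataFrame(
            [[0.0, 0.0], [0.0, 0.0], [9.0, 9.0]], index=["a", "b", "c"]
        )
        order, Z = cluster_rows(m)
        assert {order.index("a"), order.index("b")} == {0, 1} or {
            order.index("a"), order.index("b")
        } == {1, 2}
        assert Z[0, 2] == 0.0  # first merge at height 0
        assert sorted(Z[0, :2]) == [0, 1]

    def test_duplicate_rows_all_merge_at_zero(self):
        m = pd.DataFrame([[1.0, 2.0]] * 4, index=list("abcd"))
        _, Z = cluster_rows(m)
        assert np.allclose(Z[:, 2], 0.0)

    def test_average_linkage_matches_hand_agglomeration(self):
        """4-row toy matrix vs an independent step-by-step UPGMA."""
        X = np.array([[0.0], [1.0], [5.0], [10.0]])
        m = pd.DataFrame(X, index=list("abcd"))
        _, Z = cluster_rows(m)

        # brute-force average-linkage agglomeration on pairwise Euclidean
        clusters = {i: [i] for i in range(4)}
        heights = []
        next_id = 4
        merges = []
        while len(clusters) > 1:
            best = None
            for i, j in itertools.combinations(sorted(clusters), 2):
                d = np.mean(
                    [abs(X[a, 0] - X[b, 0]) for a in clusters[i] for b in clusters[j]]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
            d, i, j = best
            merges.append((i, j, d, len(clusters[i]) + len(clusters[j])))
            clusters[next_id] = clusters.pop(i) + clusters.pop(j)
            next_id += 1
        for row, (i, j, d, size) in zip(Z, merges):
            assert sorted(row[:2]) == sorted([i, j])
            assert row[2] == pytest.approx(d)
            assert row[3] == size


class TestGroupsAndRanking:
    def test_empty_mapping_leaves_all_unassigned(self):
        pw = make_pathways({"P1": (["g1", "g2"], "unassigned")})
        out = assign_groups(pw, {})
        assert out["P1"].group == "unassigned"

    def test_mapping_roundtrip_through_file(self, tmp_path):
        mapping = {"P1": "AIM", "P2": "ICS", "P3": "CSS"}
        path = tmp_path / "groups.tsv"
        oio.write_group_mapping(mapping, path)
        assert oio.load_group_mapping(path) == mapping

    def test_unknown_pathway_in_mapping_warns_not_errors(self):
        pw = make_pathways({"P1": (["g1", "g2"], "unassigned")})
        with pytest.warns(UserWarning, match="unknown pathways"):
            out = assign_groups(pw, {"P1": "AIM", "PX": "ICS"})
        assert out["P1"].group == "AIM"

    def test_primary_key_dominates_score(self):
        cells = [
            EnrichmentCell("A", f"P{i}", 1, 2, 2, 10, 0.04) for i in range(3)
        ] + [EnrichmentCell("B", "P0", 1, 2, 2, 10, 1e-10)]
        pw = make_pathways(
            {f"P{i}": ([f"g{i}", f"h{i}"], "AIM") for i in range(3)}
            | {"P0": (["x", "y"], "AIM")}
        )
        ranking = rank_by_aim(cells, pw, alpha=0.05)
        assert ranking[0].mir_id == "A"
        assert ranking[0].rank == 1

    def test_ordering_matches_oracle_sort(self):
        stats = {"a": (2, 5.0), "b": (2, 7.0), "c": (1, 99.0)}
        cells = []
        pw_spec = {}
        pid = 0
        for mir, (n_sig, score) in stats.items():
            per = score / n_sig
            p = 10 ** (-per)
            for _ in range(n_sig):
                cells.append(EnrichmentCell(mir, f"P{pid}", 1, 2, 2, 10, p))
                pw_spec[f"P{pid}"] = ([f"g{pid}", f"h{pid}"], "AIM")
                pid += 1
        ranking = rank_by_aim(cells, make_pathways(pw_spec), alpha=0.05)
        oracle = sorted(stats, key=lambda m: (-stats[m][0], -stats[m][1], m))
        assert [r.mir_id for r in ranking] == oracle
        assert [r.rank for r in ranking] == [1, 2, 3]


class TestNetworkExport:
    def _cells(self):
        return [
            EnrichmentCell("m1", "P1", 1, 2, 2, 10, 0.01),
            EnrichmentCell("m2", "P1", 1, 2, 2, 10, 0.02),
            EnrichmentCell("m3", "P1", 1, 2, 2, 10, 0.03),
            EnrichmentCell("m1", "P2", 1, 2, 2, 10, 0.01),
            EnrichmentCell("m2", "P2", 1, 2, 2, 10, 0.9),
        ]

    def test_min_mirs_one_keeps_all_significant_pairs(self):
        edges = export_pathway_network(self._cells(), None, alpha=0.05, min_mirs=1)
        assert len(edges) == 4

    def test_single_mir_pathway_excluded_at_min_two(self):
        edges = export_pathway_network(self._cells(), None, alpha=0.05, min_mirs=2)
        assert set(edges["pathway_id"]) == {"P1"}
        assert len(edges) == 3  # degree 3 for the co-targeted pathway

    def test_bh_adjustment_is_optional_and_ordered(self):
        q = bh_adjust(self._cells())
        ps = [0.01, 0.02, 0.03, 0.01, 0.9]
        assert len(q) == 5
        assert all(qv >= pv for qv, pv in zip(
            [q[("m1", "P1")], q[("m2", "P1")]], [0.01, 0.02]))


class TestEnrichAllOnSyntheticTruth:
    def test_planted_pathway_recovered_and_null_uniformish(self, small_cfg):
        import dataclasses

        from oligomir.synthetic import gen_pathways, gen_target_scores

        cfg = dataclasses.replace(small_cfg, targeting_concentration=0.9)
        pathways = gen_pathways(cfg)
        planted = {"mirP": [pathways.ids()[0]]}
        table = gen_target_scores(["mirP", "mirQ"], pathways, cfg, planted=planted)
        targets = threshold_targets(table, tau=0.6)
        cells, combined = enrich_all(targets, pathways, table.gene_universe)
        target_cell = next(
            c for c in cells if c.mir_id == "mirP" and c.pathway_id == pathways.ids()[0]
        )
        assert target_cell.p_hyper < 0.05
        # the non-planted miR shows no systematic signal for that pathway
        null_cell = next(
            c for c in cells if c.mir_id == "mirQ" and c.pathway_id == pathways.ids()[0]
        )
        assert null_cell.p_hyper > 1e-4

    def test_gmt_roundtrip_preserves_collection(self, tmp_path, small_cfg):
        from oligomir.synthetic import gen_pathways

        pw = gen_pathways(small_cfg)
        path = tmp_path / "sets.gmt"
        oio.write_gmt(pw, path)
        back = oio.load_gmt(path)
        assert back.ids() == pw.ids()
        for pid in pw.ids():
            assert back[pid].genes == pw[pid].genes
            assert back[pid].group == pw[pid].group
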