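import pandas as pd
import pytest

from timegrn.chromatin import ACTIVATION, POISED, REPRESSION, IndexedSite
from timegrn.config import TIME_POINTS
from timegrn.expression import DOWN, NONE, UP
from timegrn.grn import (
    InteractionEdge,
    TimedGrn,
    build_grn,
    build_subnetwork,
    chip_epoch,
    dedup_edges,
    edge_sign,
    infer_edges_at,
    prune_isolated,
)


class TestChipEpoch:
    @pytest.mark.parametrize("t,expected", [(1, 5), (3, 5), (5, 5), (7, 9), (9, 9), (12, 12)])
    def test_documented_mapping(self, t, expected):
        assert chip_epoch(t) == expected

    def test_time_zero_falls_back_to_5h(self):
        assert chip_epoch(0) == 5

    def test_unknown_time_raises(self):
        with pytest.raises(ValueError):
            chip_epoch(4)


class TestEdgeSign:
    @pytest.mark.parametrize(
        "r,t,expected",
        [
            (UP, UP, "positive"),
            (DOWN, DOWN, "positive"),
            (UP, DOWN, "negative"),
            (DOWN, UP, "negative"),
            (NONE, UP, None),
            (UP, NONE, None),
            (NONE, NONE, None),
        ],
    )
    def test_activation_site_rules(self, r, t, expected):
        assert edge_sign(r, t, ACTIVATION) == expected
        assert edge_sign(r, t, POISED) == expected

    @pytest.mark.parametrize(
        "r,t,expected",
        [
            (UP, UP, "negative"),
            (DOWN, DOWN, "negative"),
            (UP, DOWN, "positive"),
            (DOWN, UP, "positive"),
            (NONE, UP, None),  # unexpressed regulator -> no interaction
            (UP, NONE, None),
            (NONE, NONE, None),
        ],
    )
    def test_repression_site_rules_reversed(self, r, t, expected):
        assert edge_sign(r, t, REPRESSION) == expected


def profile_frame(rows):
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = list(TIME_POINTS)
    df.index.name = "gene_id"
    return df


def hits_frame(rows):
    cols = ["site_id", "tf_gene", "chip_time", "site_index", "site_category"]
    return pd.DataFrame(rows, columns=cols)


class TestInferEdgesAt:
    PROFILE = profile_frame(
        {
            "R": [NONE, UP, UP, UP, UP, UP, UP],
            "T": [NONE, NONE, NONE, UP, UP, UP, UP],
            "D": [NONE, DOWN, DOWN, DOWN, DOWN, DOWN, DOWN],
            "Q": [NONE, NONE, NONE, NONE, NONE, NONE, NONE],
        }
    )
    LOCI = {"T": ["s1"], "D": ["s2"], "Q": ["s3"]}

    def hits(self, category=ACTIVATION, index=1):
        return hits_frame(
            [
                ("s1", "R", 5, index, category),
                ("s2", "R", 5, index, category),
                ("s3", "R", 5, index, category),
            ]
        )

    def test_coregulated_gives_positive(self):
        edges = infer_edges_at(5, self.PROFILE, self.hits(), self.LOCI)
        assert ("R", "T", "positive") in {(e.regulator, e.target, e.sign) for e in edges}

    def test_opposing_gives_negative(self):
        edges = infer_edges_at(5, self.PROFILE, self.hits(), self.LOCI)
        assert ("R", "D", "negative") in {(e.regulator, e.target, e.sign) for e in edges}

    def test_silent_target_receives_no_edges(self):
        edges = infer_edges_at(5, self.PROFILE, self.hits(), self.LOCI)
        assert not any(e.target == "Q" for e in edges)

    def test_regulator_gate_uses_preceding_time(self):
        profile = profile_frame(
            {
                "R": [NONE, NONE, UP, NONE, NONE, NONE, NONE],  # up at 3 h only
                "T": [NONE, NONE, NONE, UP, UP, UP, UP],
            }
        )
        hits = hits_frame([("s1", "R", 5, 1, ACTIVATION)])
        edges = infer_edges_at(5, profile, hits, {"T": ["s1"]})
        # R is none at 5 h but up at 3 h (just before) -> edge exists
        assert [(e.regulator, e.target, e.sign) for e in edges] == [("R", "T", "positive")]

    def test_regulator_none_at_t_and_before_blocks_edge(self):
        profile = profile_frame(
            {
                "R": [NONE, UP, NONE, NONE, NONE, NONE, NONE],  # up at 1 h only
                "T": [NONE, NONE, NONE, UP, UP, UP, UP],
            }
        )
        hits = hits_frame([("s1", "R", 5, 1, ACTIVATION)])
        assert infer_edges_at(5, profile, hits, {"T": ["s1"]}) == []

    def test_wrong_epoch_sites_ignored(self):
        hits = hits_frame([("s1", "R", 9, 1, ACTIVATION)])
        assert infer_edges_at(5, self.PROFILE, hits, self.LOCI) == []

    def test_mode_excludes_repression_sites(self):
        hits = hits_frame([("s1", "R", 5, 5, REPRESSION)])
        assert infer_edges_at(5, self.PROFILE, hits, self.LOCI, mode="activation_only") == []
        edges = infer_edges_at(
            5, self.PROFILE, hits, self.LOCI, mode="activation_and_repression"
        )
        # co-regulated at a repression site -> negative
        assert [(e.regulator, e.sign) for e in edges] == [("R", "negative")]


class TestDedupEdges:
    def edge(self, sign="positive", time=5, site="s1"):
        return InteractionEdge("R", "T", sign, time, (site,))

    def test_multi_site_support_collapses(self):
        deduped = dedup_edges([self.edge(site="s1"), self.edge(site="s2")])
        assert len(deduped) == 1
        assert deduped[0].sites == ("s1", "s2")

    def test_time_distinct_edges_kept(self):
        assert len(dedup_edges([self.edge(time=5), self.edge(time=9)])) == 2

    def test_sign_distinct_edges_kept(self):
        assert len(dedup_edges([self.edge("positive"), self.edge("negative")])) == 2

    def test_idempotent(self):
        once = dedup_edges([self.edge(site="s1"), self.edge(site="s2")])
        assert dedup_edges(once) == once


class TestPruneIsolated:
    def grn(self, edges, genes):
        profile = profile_frame({g: [NONE] * 7 for g in genes})
        return TimedGrn(profile=profile, edges=edges)

    def test_self_loop_retains_gene(self):
        g = self.grn([InteractionEdge("A", "A", "positive", 5)], ["A", "B"])
        pruned, removed = prune_isolated(g)
        assert removed == ["B"]
        assert list(pruned.profile.index) == ["A"]

    def test_connected_genes_kept(self):
        g = self.grn([InteractionEdge("A", "B", "positive", 5)], ["A", "B", "C"])
        pruned, removed = prune_isolated(g)
        assert removed == ["C"]

    def test_idempotent(self):
        g = self.grn([InteractionEdge("A", "B", "positive", 5)], ["A", "B", "C"])
        once, _ = prune_isolated(g)
        twice, removed = prune_isolated(once)
        assert removed == []
        assert list(twice.profile.index) == list(once.profile.index)

    def test_decoy_genes_pruned_in_scenario(self, zero_noise_result):
        scenario, result = zero_noise_result
        connected = {e[0] for e in scenario.ground_truth.edges} | {
            e[1] for e in scenario.ground_truth.edges
        }
        expected_removed = sorted(set(result.profile.index) - connected)
        assert result.pruned == expected_removed
        cfg = scenario.config
        decoys = [f"G{i:03d}" for i in range(cfg.n_genes - cfg.n_decoy_genes, cfg.n_genes)]
        for d in decoys:
            assert d in result.pruned


class TestTemporalGateAudit:
    def test_no_edge_violates_the_gate(self, zero_noise_result):
        scenario, result = zero_noise_result
        profile = result.profile
        for e in result.grn.edges:
            idx = TIME_POINTS.index(e.time)
            window = [profile.loc[e.regulator, e.time]]
            if idx > 0:
                window.append(profile.loc[e.regulator, TIME_POINTS[idx - 1]])
            assert any(d != NONE for d in window)


class TestBuildSubnetwork:
    def make_sites(self):
        return [
            IndexedSite("chr1", 1000, 1060, 5, 1, ACTIVATION, "sA@5"),
            IndexedSite("chr1", 1400, 1460, 9, 2, ACTIVATION, "sA@9"),  # 340 bp gap
            IndexedSite("chr1", 5000, 5060, 9, 1, ACTIVATION, "sB@9"),
            IndexedSite("chr1", 5000, 5060, 12, 4, REPRESSION, "sB@12"),
        ]

    def profile(self):
        return profile_frame(
            {
                "T": [NONE, NONE, NONE, UP, UP, UP, UP],
                "R": [NONE, UP, UP, UP, UP, UP, UP],
            }
        )

    def hits(self):
        cols = ["site_id", "tf_gene", "chip_time", "site_index", "site_category"]
        return pd.DataFrame(
            [
                ("sA@5", "R", 5, 1, ACTIVATION),
                ("sA@9", "R", 9, 2, ACTIVATION),
                ("sB@9", "R", 9, 1, ACTIVATION),
                ("sB@12", "R", 12, 4, REPRESSION),
            ],
            columns=cols,
        )

    def test_cross_time_merge_with_gap(self):
        sub = build_subnetwork(
            "T", self.profile(), self.make_sites(), self.hits(),
            ["sA@5", "sA@9", "sB@9", "sB@12"], merge_gap=500,
        )
        assert len(sub.nodes) == 2
        merged = sub.nodes[0]
        assert (merged.start, merged.end) == (1000, 1460)
        assert set(merged.member_sites) == {"sA@5", "sA@9"}
        assert merged.states[5] == (1, ACTIVATION)
        assert merged.states[9] == (2, ACTIVATION)

    def test_site_without_early_state_gets_no_early_inputs(self):
        sub = build_subnetwork(
            "T", self.profile(), self.make_sites(), self.hits(),
            ["sB@9", "sB@12"], merge_gap=500,
        )
        (node,) = sub.nodes
        early = [e for e in sub.edges if e["time"] in (0, 1, 3, 5)]
        assert early == []
        later = {(e["time"], e["sign"]) for e in sub.edges}
        # activation at 9 h (co-regulated -> positive), repression rules at 12 h
        assert (9, "positive") in later
        assert (12, "negative") in later

    def test_hand_constructed_expectation(self):
        sub = build_subnetwork(
            "T", self.profile(), self.make_sites(), self.hits(),
            ["sA@5", "sA@9", "sB@9", "sB@12"], merge_gap=500,
        )
        got = {(e["regulator"], e["site_node"], e["sign"], e["time"]) for e in sub.edges}
        expected = {
            # merged node 1 (sA): active at epochs 5 (t=5; T none before 5) and 9 (t=7,9)
            ("R", "T_site1", "positive", 5),
            ("R", "T_site1", "positive", 7),
            ("R", "T_site1", "positive", 9),
            # node 2 (sB): activation at 9 h epoch, repression at 12 h
            ("R", "T_site2", "positive", 7),
            ("R", "T_site2", "positive", 9),
            ("R", "T_site2", "negative", 12),
        }
        assert got == expected


def test_build_grn_end_to_end_recovery(zero_noise_result):
    scenario, result = zero_noise_result
    found = {(e.regulator, e.target, e.sign, e.time) for e in result.grn.edges}
    assert found == scenario.ground_truth.edges
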