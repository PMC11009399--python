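import numpy as np
import pandas as pd
import pytest

from plasmidome.network import (
    NullEnsemble,
    build_sharing_network,
    cross_continental_summary,
    edge_significance,
    group_connectivity_test,
    permute_incidence,
    segment_significance,
    strength_ratio,
)


def _md(diseases, continents=None, index=None):
    index = index if index is not None else [f"s{i}" for i in range(len(diseases))]
    continents = continents or ["X"] * len(diseases)
    return pd.DataFrame({"disease": diseases, "continent": continents}, index=index)


class TestBuild:
    def test_shared_clusters_become_weight(self):
        inc = pd.DataFrame([[1, 1, 1, 0], [1, 1, 1, 1]], index=["s0", "s1"]).astype(bool)
        net = build_sharing_network(inc, _md(["healthy", "IBD"], index=["s0", "s1"]))
        assert net.weights.loc["s0", "s1"] == 3

    def test_disjoint_carriage_is_empty(self):
        inc = pd.DataFrame([[1, 0], [0, 1]], index=["s0", "s1"]).astype(bool)
        net = build_sharing_network(inc, _md(["healthy", "IBD"], index=["s0", "s1"]))
        assert net.density == 0.0
        assert (net.weights.to_numpy() == 0).all()

    def test_missing_metadata_errors(self):
        inc = pd.DataFrame([[1], [1]], index=["s0", "sX"]).astype(bool)
        with pytest.raises(ValueError, match="sX"):
            build_sharing_network(inc, _md(["healthy"], index=["s0"]))

    def test_weight_is_row_dot_product(self, rng):
        inc = pd.DataFrame(rng.random((30, 40)) < 0.3)
        md = _md(rng.choice(["healthy", "IBD"], 30), index=inc.index)
        net = build_sharing_network(inc, md)
        M = inc.to_numpy(int)
        for _ in range(20):
            i, j = rng.choice(30, 2, replace=False)
            assert net.weights.iloc[i, j] == M[i] @ M[j]


class TestPermutation:
    def test_margins_conserved_exactly(self, rng):
        inc = pd.DataFrame(rng.random((40, 60)) < 0.25)
        out, info = permute_incidence(inc, seed=3)
        assert (out.sum(0) == inc.sum(0)).all()
        assert (out.sum(1) == inc.sum(1)).all()
        assert out.to_numpy().sum() == inc.to_numpy().sum()
        assert info["n_swapped"] > 0

    def test_all_ones_has_no_checkerboard(self):
        inc = pd.DataFrame(np.ones((4, 4), dtype=bool))
        out, info = permute_incidence(inc, seed=1)
        assert info["flag_no_swap"]
        pd.testing.assert_frame_equal(out, inc)

    def test_two_state_chain_visits_both_states(self):
        # the 2x2 identity has exactly two degree-preserving configurations
        inc = pd.DataFrame(np.eye(2, dtype=bool))
        flips = sum(not permute_incidence(inc, seed=s)[0].iloc[0, 0]
                    for s in range(1000))
        assert 0.45 <= flips / 1000 <= 0.55

    def test_ensemble_determinism(self, rng):
        inc = pd.DataFrame(rng.random((20, 30)) < 0.3)
        a = NullEnsemble(inc, n_perm=5, seed=7)
        b = NullEnsemble(inc, n_perm=5, seed=7)
        assert (a.members == b.members).all()


class TestGroupTest:
    def test_observed_below_null_gives_p_one(self, rng):
        # put every within-IBD pair weight at 0 by giving IBD samples
        # disjoint segments; nulls will nearly always match or beat that
        inc = pd.DataFrame(np.zeros((20, 20), dtype=bool))
        for i in range(20):
            inc.iloc[i, i] = True
        inc.iloc[:10, 15] = True   # healthy block shares a segment
        md = _md(["healthy"] * 10 + ["IBD"] * 10, index=inc.index)
        ens = NullEnsemble(inc, n_perm=99, seed=1)
        tab = group_connectivity_test(inc, md, ens, include_geography=False)
        ibd = tab[tab["group"] == "IBD|all"].iloc[0]
        assert ibd["observed"] == 0
        assert ibd["p"] == 1.0

    def test_planted_group_connectivity_detected(self, rng):
        inc = pd.DataFrame(rng.random((60, 80)) < 0.05)
        md = _md(["healthy"] * 40 + ["IBD"] * 20, index=inc.index)
        inc.iloc[40:, :10] = True  # IBD samples share ten planted segments
        ens = NullEnsemble(inc, n_perm=199, seed=2)
        tab = group_connectivity_test(inc, md, ens, include_geography=False)
        ibd = tab[tab["group"] == "IBD|all"].iloc[0]
        assert ibd["p"] == pytest.approx(1 / 200)

    def test_small_groups_skipped(self, rng):
        inc = pd.DataFrame(rng.random((5, 10)) < 0.5)
        md = _md(["healthy"] * 4 + ["IBD"], index=inc.index)
        ens = NullEnsemble(inc, n_perm=19, seed=3)
        tab = group_connectivity_test(inc, md, ens, include_geography=False)
        assert set(tab["group"]) == {"healthy|all"}


class TestEdgeAndSegmentSignificance:
    def test_planted_edge_significant(self, rng):
        inc = pd.DataFrame(rng.random((30, 120)) < 0.03)
        inc.iloc[0, :50] = True
        inc.iloc[1, :50] = True   # two samples share 50 planted clusters
        md = _md(["IBD"] * 2 + ["healthy"] * 28, index=inc.index)
        net = build_sharing_network(inc, md)
        ens = NullEnsemble(inc, n_perm=199, seed=4)
        edges = edge_significance(net, ens)
        planted = edges[(edges["sample_a"] == inc.index[0]) &
                        (edges["sample_b"] == inc.index[1])]
        assert planted["significant"].iloc[0]

    def test_null_edge_fdr_controlled(self, rng):
        inc = pd.DataFrame(rng.random((25, 60)) < 0.2)
        md = _md(["healthy"] * 25, index=inc.index)
        net = build_sharing_network(inc, md)
        ens = NullEnsemble(inc, n_perm=199, seed=5)
        edges = edge_significance(net, ens)
        assert edges["significant"].mean() <= 0.05

    def test_single_carrier_segment_never_significant(self, rng):
        inc = pd.DataFrame(rng.random((20, 30)) < 0.2)
        inc.iloc[:, 0] = False
        inc.iloc[0, 0] = True
        md = _md(["healthy"] * 10 + ["IBD"] * 10, index=inc.index)
        ens = NullEnsemble(inc, n_perm=49, seed=6)
        segs = segment_significance(inc, md, ens)
        row = segs[(segs["segment"] == inc.columns[0])]
        assert (row["observed_pairs"] == 0).all()
        assert not row["significant"].any()


class TestStrengthRatio:
    def test_per_capita_arithmetic(self):
        # node u: same-disease weight 3 over 1 partner; other weights 1+2
        # over 2 partners -> (3/1) / (3/2) = 2.0
        weights = pd.DataFrame(0, index=["u", "v", "w", "x"],
                               columns=["u", "v", "w", "x"])
        for a, b, w in [("u", "v", 3), ("u", "w", 1), ("u", "x", 2)]:
            weights.loc[a, b] = w
            weights.loc[b, a] = w
        inc = pd.DataFrame(np.zeros((4, 1), dtype=bool), index=weights.index)
        md = _md(["A", "A", "B", "B"], index=weights.index)
        from plasmidome.network import SharingNetwork
        net = SharingNetwork(weights=weights, incidence=inc, metadata=md, density=1.0)
        table, _ = strength_ratio(net, mode="per_capita")
        assert table.loc["u", "ratio"] == pytest.approx(2.0)
        raw, _ = strength_ratio(net, mode="raw")
        assert raw.loc["u", "ratio"] == pytest.approx(1.0)

    def test_single_disease_errors(self, rng):
        inc = pd.DataFrame(rng.random((6, 10)) < 0.5)
        md = _md(["healthy"] * 6, index=inc.index)
        net = build_sharing_network(inc, md)
        with pytest.raises(ValueError, match="two disease"):
            strength_ratio(net)

    def test_label_shuffle_gives_unit_median(self, neutral_dataset, random_metadata):
        net = build_sharing_network(neutral_dataset["presence"], random_metadata)
        table, _ = strength_ratio(net)
        assert np.nanmedian(table["ratio"]) == pytest.approx(1.0, abs=0.05)

    def test_unknown_mode_rejected(self, rng):
        inc = pd.DataFrame(rng.random((4, 5)) < 0.5)
        md = _md(["A", "A", "B", "B"], index=inc.index)
        net = build_sharing_network(inc, md)
        with pytest.raises(ValueError, match="mode"):
            strength_ratio(net, mode="bogus")


class TestCrossContinental:
    def _edges(self, sig):
        return pd.DataFrame({
            "disease": ["IBD", "IBD", "GRD"],
            "cross_continental": [True, True, True],
            "significant": sig,
        })

    def test_none_significant(self):
        out = cross_continental_summary(self._edges([False, False, False]))
        assert (out["significant_fraction"] == 0.0).all()

    def test_all_significant(self):
        out = cross_continental_summary(self._edges([True, True, True]))
        assert (out["significant_fraction"] == 1.0).all()

    def test_known_fraction(self):
        out = cross_continental_summary(self._edges([True, False, False]))
        ibd = out[out["disease"] == "IBD"]["significant_fraction"].iloc[0]
        assert ibd == pytest.approx(0.5)
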