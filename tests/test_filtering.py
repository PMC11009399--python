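import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmidome.containers import AbundanceMatrix
from plasmidome.filtering import (
    apply_depth_cutoff,
    call_presence,
    dedup_plasmids,
    length_trough,
    richness_ratio,
)


def _am(abund, cov, depth):
    abund = pd.DataFrame(abund)
    return AbundanceMatrix(abund, pd.DataFrame(cov, index=abund.index,
                                               columns=abund.columns),
                           pd.Series(depth, index=abund.index))


class TestDedup:
    def test_singleton_survives(self):
        res = dedup_plasmids({"A": 1000}, [])
        assert res.representatives == ["A"]

    def test_rule_application(self):
        # B merges into the larger A; unrelated C survives
        res = dedup_plasmids({"A": 10_000, "B": 9_000, "C": 5_000},
                             [("A", "B", 0.96, 9_600)])
        assert res.representatives == ["A", "C"]
        assert res.cluster_map["B"] == "A"

    def test_identity_boundary_is_exclusive(self):
        # the merge rule requires identity strictly above 0.95
        res = dedup_plasmids({"A": 10_000, "B": 9_000}, [("A", "B", 0.95, 9_600)])
        assert res.representatives == ["A", "B"]

    def test_coverage_of_larger_required(self):
        res = dedup_plasmids({"A": 10_000, "B": 9_000}, [("A", "B", 0.99, 9_000)])
        assert res.representatives == ["A", "B"]  # 9000 < 0.95 * 10000

    def test_self_match_warns_and_ignored(self):
        with pytest.warns(UserWarning, match="self-match"):
            res = dedup_plasmids({"A": 1000}, [("A", "A", 1.0, 1000)])
        assert res.representatives == ["A"]

    def test_transitive_chain_resolves_to_largest(self):
        matches = [("A", "B", 0.96, 9_000 * 0.96), ("B", "C", 0.97, 8_000)]
        res = dedup_plasmids({"A": 9_000, "B": 9_000, "C": 8_100}, matches)
        assert res.cluster_map["B"] == "A"  # tie on length broken by id
        assert "C" in res.representatives  # its partner was already absorbed

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_idempotent_and_order_invariant(self, rnd):
        ids = [f"P{i}" for i in range(8)]
        lengths = {p: rnd.randint(1_000, 20_000) for p in ids}
        matches = []
        for _ in range(10):
            a, b = rnd.sample(ids, 2)
            identity = rnd.uniform(0.9, 1.0)
            frac = rnd.uniform(0.9, 1.0)
            matches.append((a, b, identity, frac * max(lengths[a], lengths[b])))
        base = dedup_plasmids(lengths, matches)
        shuffled = matches[:]
        rnd.shuffle(shuffled)
        assert dedup_plasmids(lengths, shuffled).representatives == base.representatives
        survivors = {p: lengths[p] for p in base.representatives}
        again = dedup_plasmids(survivors, [m for m in matches
                                           if m[0] in survivors and m[1] in survivors])
        assert again.representatives == base.representatives


class TestPresence:
    def test_coverage_boundaries(self):
        am = _am({"A": [1.0, 1.0, 1.0, 0.0]},
                 {"A": [1.0, 0.70, 0.699, 1.0]}, [100] * 4)
        out = call_presence(am)["A"].tolist()
        assert out == [True, True, False, False]

    def test_missing_coverage_treated_as_zero(self):
        am = _am({"A": [1.0]}, {"A": [1.0]}, [100])
        am.coverage.iloc[0, 0] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            out = call_presence(am)
        assert not out.iloc[0, 0]

    def test_raising_min_cov_is_monotone(self, rng):
        abund = rng.random((20, 15))
        cov = rng.random((20, 15))
        am = _am(pd.DataFrame(abund), pd.DataFrame(cov), [100] * 20)
        loose = call_presence(am, min_cov=0.5)
        tight = call_presence(am, min_cov=0.8)
        assert not (tight & ~loose).to_numpy().any()


class TestDepthCutoff:
    def test_cutoff_arithmetic(self):
        # shallowest sample s2: lowest present abundance 50 -> cutoff 0.5
        abund = pd.DataFrame({"A": [0.4, 50.0], "B": [10.0, 80.0]},
                             index=["s1", "s2"])
        am = _am(abund, pd.DataFrame(1.0, index=abund.index, columns=abund.columns),
                 [1000, 10])
        presence = call_presence(am)
        out, cutoff = apply_depth_cutoff(am, presence)
        assert cutoff == pytest.approx(0.5)
        assert not out.loc["s1", "A"]
        assert out.loc["s2", "A"] and out.loc["s1", "B"]

    def test_no_change_when_all_above(self):
        abund = pd.DataFrame({"A": [5.0, 50.0]}, index=["s1", "s2"])
        am = _am(abund, pd.DataFrame(1.0, index=abund.index, columns=abund.columns),
                 [1000, 10])
        presence = call_presence(am)
        out, _ = apply_depth_cutoff(am, presence)
        pd.testing.assert_frame_equal(out, presence)

    def test_empty_shallow_sample_errors(self):
        abund = pd.DataFrame({"A": [5.0, 0.0]}, index=["s1", "s2"])
        am = _am(abund, pd.DataFrame(1.0, index=abund.index, columns=abund.columns),
                 [1000, 10])
        with pytest.raises(ValueError, match="relax"):
            apply_depth_cutoff(am, call_presence(am))


class TestRichness:
    def test_ratio_arithmetic(self):
        presence = pd.DataFrame(np.ones((1, 10), dtype=bool), index=["s1"])
        taxa = pd.DataFrame(np.ones((1, 5)), index=["s1"])
        md = pd.DataFrame({"disease": ["healthy"]}, index=["s1"])
        table, _ = richness_ratio(presence, taxa, md)
        assert table.loc["s1", "ratio"] == pytest.approx(2.0)

    def test_zero_species_excluded(self):
        presence = pd.DataFrame(np.ones((2, 4), dtype=bool), index=["s1", "s2"])
        taxa = pd.DataFrame([[1, 1], [0, 0]], index=["s1", "s2"])
        md = pd.DataFrame({"disease": ["healthy", "IBD"]}, index=["s1", "s2"])
        with pytest.warns(UserWarning, match="zero species"):
            table, _ = richness_ratio(presence, taxa, md)
        assert list(table.index) == ["s1"]

    def test_type_one_error_calibrated(self, rng):
        # identical distributions: the rank-sum test rejects ~5% of the time
        hits = 0
        reps = 200
        for _ in range(reps):
            vals = pd.Series(rng.normal(size=120))
            groups = pd.Series(["a"] * 60 + ["b"] * 60)
            from plasmidome.filtering import _pairwise_wilcoxon
            p = _pairwise_wilcoxon(vals, groups)["p"].iloc[0]
            hits += p <= 0.05
        assert 0.02 <= hits / reps <= 0.09

    def test_shifted_group_detected(self, rng):
        vals = pd.Series(np.concatenate([rng.normal(1.0, 0.3, 100),
                                         rng.normal(1.5, 0.3, 100)]))
        groups = pd.Series(["a"] * 100 + ["b"] * 100)
        from plasmidome.filtering import _pairwise_wilcoxon
        table = _pairwise_wilcoxon(vals, groups)
        assert table["q"].iloc[0] < 0.05


class TestLengthTrough:
    def test_bimodal_trough_between_modes(self, rng):
        lengths = np.concatenate([
            10 ** rng.normal(np.log10(3_000), 0.15, 800),
            10 ** rng.normal(np.log10(30_000), 0.15, 200),
        ])
        trough = length_trough(lengths)
        assert 3_000 < trough < 30_000

    def test_unimodal_returns_none(self, rng):
        assert length_trough(10 ** rng.normal(3.5, 0.1, 500)) is None

    def test_equal_modes_trough_near_geometric_midpoint(self, rng):
        lengths = np.concatenate([
            10 ** rng.normal(np.log10(3_000), 0.12, 500),
            10 ** rng.normal(np.log10(30_000), 0.12, 500),
        ])
        trough = length_trough(lengths)
        midpoint = np.sqrt(3_000 * 30_000)
        assert abs(np.log10(trough) - np.log10(midpoint)) < 0.15

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            length_trough([1000.0] * 5)
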