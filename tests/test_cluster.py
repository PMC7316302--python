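"""Variance selection, correlation, UPGMA clustering, group specificity and
group comparison tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from selandscape.cluster import (
    ClusterAssignment,
    assign_group_specific,
    compare_groups,
    correlate_samples,
    hierarchical_cluster,
    top_variable,
)


class TestTopVariable:
    def test_constant_feature_never_beats_varying_one(self):
        df = pd.DataFrame(
            {"s1": [1.0, 5.0], "s2": [1.0, 9.0], "s3": [1.0, 2.0]},
            index=["flat", "varying"],
        )
        assert top_variable(df, 0.5) == ["varying"]

    def test_ceiling_rule_on_ten_percent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(size=(10, 4)), index=[f"e{i}" for i in range(10)])
        assert len(top_variable(df, 0.10)) == 1
        assert len(top_variable(df, 0.11)) == 2

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_variance_sort(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.uniform(size=(30, 6)), index=[f"e{i:02d}" for i in range(30)]
        )
        got = top_variable(df, 0.25)
        var = df.var(axis=1, ddof=1)
        expected = sorted(df.index, key=lambda i: (-var[i], i))[:8]
        assert got == expected

    def test_restriction_changes_the_variance_basis(self):
        df = pd.DataFrame(
            {"a": [0.0, 5.0], "b": [0.0, 5.0], "c": [9.0, 5.0], "d": [0.0, 5.0]},
            index=["x", "y"],
        )
        assert top_variable(df, 0.5, restrict_to=["a", "b"]) == ["x"]
        assert top_variable(df, 0.5, restrict_to=["a", "c"]) == ["x"]
        assert top_variable(df, 0.5, restrict_to=["a", "b", "c", "d"]) == ["x"]


class TestCorrelateSamples:
    def test_self_correlation_is_one_and_negation_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        df = pd.DataFrame({"s": x, "t": x, "neg": -x})
        corr = correlate_samples(df)
        assert corr.loc["s", "s"] == pytest.approx(1.0)
        assert corr.loc["s", "t"] == pytest.approx(1.0)
        assert corr.loc["s", "neg"] == pytest.approx(-1.0)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_textbook_pearson(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.uniform(size=(5, 5)), columns=[f"s{i}" for i in range(5)])
        corr = correlate_samples(df)
        for a, b in itertools.combinations(df.columns, 2):
            x, y = df[a].to_numpy(), df[b].to_numpy()
            manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            assert corr.loc[a, b] == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_sample_dropped_with_warning(self):
        df = pd.DataFrame({"s": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.warns(UserWarning, match="flat"):
            corr = correlate_samples(df)
        assert list(corr.columns) == ["s"]


def _block_corr(n_blocks, per_block, rng):
    features = []
    for b in range(n_blocks):
        base = np.zeros(n_blocks * 4)
        base[b * 4 : b * 4 + 4] = 10.0
        features.append(base)
    data = {}
    for b in range(n_blocks):
        for i in range(per_block):
            data[f"b{b}_s{i}"] = np.array([f[b * 4 + i % 4] for f in features]) + rng.normal(
                0, 0.05, n_blocks
            )
    return pd.DataFrame(data)


class TestHierarchicalCluster:
    def test_recovers_two_planted_blocks(self):
        rng = np.random.default_rng(1)
        log_scores = _block_corr(2, 5, rng)
        corr = correlate_samples(log_scores)
        out = hierarchical_cluster(corr, k=2, min_cluster_size=3)
        truth = [s.split("_")[0] for s in out.sample_ids]
        labels = [out.labels[s] for s in out.sample_ids]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_dissolves_everything(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.uniform(size=(10, 6)), columns=[f"s{i}" for i in range(6)])
        corr = correlate_samples(df)
        out = hierarchical_cluster(corr, k=6, min_cluster_size=3)
        assert all(c is None for c in out.labels.values())

    def test_merge_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(size=(20, 12)), columns=[f"s{i:02d}" for i in range(12)])
        out = hierarchical_cluster(correlate_samples(df), k=3, min_cluster_size=2)
        heights = out.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_k_larger_than_n_rejected(self):
        df = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError):
            hierarchical_cluster(correlate_samples(df + 0.1), k=5)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        log_scores = _block_corr(3, 4, rng)
        corr = correlate_samples(log_scores)
        a = hierarchical_cluster(corr, k=3, min_cluster_size=3)
        shuffled = corr.sample(frac=1, axis=1, random_state=0)
        shuffled = shuffled.loc[shuffled.columns]
        b = hierarchical_cluster(shuffled, k=3, min_cluster_size=3)
        part_a = {s: sorted(m for m, c in a.labels.items() if c == lab) for s, lab in a.labels.items()}
        part_b = {s: sorted(m for m, c in b.labels.items() if c == lab) for s, lab in b.labels.items()}
        assert part_a == part_b


def _assignment(groups: dict[int, list[str]]) -> ClusterAssignment:
    labels = {s: g for g, members in groups.items() for s in members}
    return ClusterAssignment(
        labels=labels, linkage=np.empty((0, 4)), chosen_k=len(groups),
        sample_ids=sorted(labels),
    )


class TestGroupSpecific:
    def test_clean_separation_is_specific(self):
        df = pd.DataFrame(
            [[8.0, 8.0, 8.0, 0.0, 0.0, 0.0]],
            index=["e1"],
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        out = assign_group_specific(df, _assignment({1: ["a1", "a2", "a3"], 2: ["b1", "b2", "b3"]}))
        assert out.loc["e1", "specific_to"] == "1"

    def test_overlapping_pair_shared_but_distinct_from_third(self):
        df = pd.DataFrame(
            [[8.0, 8.0, 8.0, 7.5, 8.0, 8.5, 0.0, 0.0, 0.0]],
            index=["e1"],
            columns=["a1", "a2", "a3", "b1", "b2", "b3", "c1", "c2", "c3"],
        )
        groups = {1: ["a1", "a2", "a3"], 2: ["b1", "b2", "b3"], 3: ["c1", "c2", "c3"]}
        out = assign_group_specific(df, _assignment(groups))
        assert out.loc["e1", "specific_to"] == "1,2"

    def test_equal_groups_are_not_specific(self):
        df = pd.DataFrame(
            [[5.0, 5.0, 5.0, 5.0, 5.0, 5.0]],
            index=["e1"],
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        out = assign_group_specific(df, _assignment({1: ["a1", "a2", "a3"], 2: ["b1", "b2", "b3"]}))
        assert out.loc["e1", "specific_to"] == ""


def _u_oracle(a, b):
    # exhaustive pair counting with 0.5 for ties
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


class TestCompareGroups:
    def test_identical_groups(self):
        t, _ = compare_groups([1, 2, 3], [1, 2, 3], test="t")
        assert t == pytest.approx(0.0)
        _, p = compare_groups([1, 2, 3], [1, 2, 3], test="mannwhitney")
        assert p == pytest.approx(1.0)

    def test_separated_groups_closed_form_t(self):
        t, p = compare_groups([1, 2, 3], [101, 102, 103], test="t")
        assert t == pytest.approx(-122.474487, rel=1e-6)
        assert p < 0.01

    def test_zero_variance_both_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 1, 1], [2, 2, 2], test="t")

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_u_statistic_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 6, int(rng.integers(1, 9))).astype(float)
        b = rng.integers(0, 6, int(rng.integers(1, 9))).astype(float)
        u, _ = compare_groups(a, b, test="mannwhitney")
        assert u == pytest.approx(_u_oracle(a, b))
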