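"""Bray–Curtis, UPGMA clustering, detection matrices, marker concordance."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preyid import (
    SampleProfile,
    average_linkage_cluster,
    bray_curtis,
    detection_matrix,
    filter_empty_samples,
    marker_concordance,
    similarity_matrix,
)


def _profile(sample_id, counts, marker="12S"):
    return SampleProfile(sample_id=sample_id, marker=marker, counts=counts)


class TestBrayCurtis:
    def test_identity(self):
        x = {"a": 3, "b": 7}
        assert bray_curtis(x, x) == 1.0

    def test_disjoint_supports(self):
        assert bray_curtis({"a": 5}, {"b": 5}) == 0.0

    def test_hand_computed_example(self):
        x = {"t1": 6, "t2": 0, "t3": 2}
        y = {"t1": 2, "t2": 2, "t3": 0}
        # 2 * (2 + 0 + 0) / (8 + 4) = 1/3, i.e. dissimilarity 2/3
        assert bray_curtis(x, y) == pytest.approx(1 / 3)

    def test_matches_scipy_route(self):
        from scipy.spatial.distance import braycurtis as scipy_bc

        rng = np.random.default_rng(0)
        for _ in range(20):
            keys = [f"t{i}" for i in range(6)]
            x = dict(zip(keys, rng.integers(0, 50, 6)))
            y = dict(zip(keys, rng.integers(0, 50, 6)))
            if sum(x.values()) == 0 or sum(y.values()) == 0:
                continue
            xv = np.array([x[k] for k in keys], dtype=float)
            yv = np.array([y[k] for k in keys], dtype=float)
            assert bray_curtis(x, y) == pytest.approx(1 - scipy_bc(xv, yv))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis({"a": 0}, {"a": 1})

    @given(
        st.lists(st.integers(0, 100), min_size=3, max_size=6),
        st.lists(st.integers(0, 100), min_size=3, max_size=6),
        st.integers(1, 9),
    )
    @settings(deadline=None, max_examples=100)
    def test_symmetry_and_scale_invariance(self, xs, ys, scale):
        n = min(len(xs), len(ys))
        x = {f"t{i}": xs[i] for i in range(n)}
        y = {f"t{i}": ys[i] for i in range(n)}
        if sum(x.values()) == 0 or sum(y.values()) == 0:
            return
        s = bray_curtis(x, y)
        assert bray_curtis(y, x) == pytest.approx(s)
        assert 0.0 <= s <= 1.0
        xs_scaled = {k: v * scale for k, v in x.items()}
        ys_scaled = {k: v * scale for k, v in y.items()}
        assert bray_curtis(xs_scaled, ys_scaled) == pytest.approx(s)


class TestFilterEmpty:
    def test_all_host_sample_dropped(self):
        kept = filter_empty_samples([_profile("a", {"x": 1}), _profile("b", {})])
        assert [p.sample_id for p in kept] == ["a"]

    def test_identity_when_none_empty(self):
        profiles = [_profile("a", {"x": 1}), _profile("b", {"y": 2})]
        assert filter_empty_samples(profiles) == profiles

    def test_all_empty_errors(self):
        with pytest.raises(ValueError):
            filter_empty_samples([_profile("a", {}), _profile("b", {"x": 0})])


class TestUpgma:
    def test_two_samples_single_merge(self):
        sim = pd.DataFrame(
            [[1.0, 0.4], [0.4, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        dendro = average_linkage_cluster(sim)
        assert dendro.merge_heights == [pytest.approx(0.6)]

    def test_three_sample_hand_computation(self):
        # d(A,B)=0.1, d(A,C)=d(B,C)=0.5 -> merge (A,B) at 0.1, then C at 0.5
        sim = pd.DataFrame(
            [[1.0, 0.9, 0.5], [0.9, 1.0, 0.5], [0.5, 0.5, 1.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        dendro = average_linkage_cluster(sim)
        assert dendro.merge_heights == [pytest.approx(0.1), pytest.approx(0.5)]
        first = dendro.linkage_matrix[0, :2]
        assert set(first.astype(int)) == {0, 1}

    def test_heights_non_decreasing_and_label_invariance(self):
        rng = np.random.default_rng(5)
        n = 6
        d = rng.random((n, n)) * 0.8
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"s{i}" for i in range(n)]
        sim = pd.DataFrame(1 - d, index=labels, columns=labels)
        dendro = average_linkage_cluster(sim)
        heights = dendro.merge_heights
        assert heights == sorted(heights)
        # permuting sample order gives the same merge heights
        perm = list(np.random.default_rng(6).permutation(n))
        sim_p = sim.iloc[perm, perm]
        assert average_linkage_cluster(sim_p).merge_heights == pytest.approx(heights)

    def test_fewer_than_two_samples_errors(self):
        with pytest.raises(ValueError):
            average_linkage_cluster(pd.DataFrame([[1.0]], index=["a"], columns=["a"]))

    def test_newick_export_has_all_labels(self):
        sim = pd.DataFrame(
            [[1.0, 0.9, 0.5], [0.9, 1.0, 0.5], [0.5, 0.5, 1.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        nwk = average_linkage_cluster(sim).to_newick()
        for label in "ABC":
            assert label in nwk
        assert nwk.endswith(";")


class TestDetectionAndConcordance:
    def _matrices(self):
        p12 = [
            _profile("S1", {"a": 10, "b": 5}),
            _profile("S2", {"a": 3}),
            _profile("S3", {}),
        ]
        p16 = [
            _profile("S1", {"a": 7}, marker="16S"),
            _profile("S2", {"b": 2}, marker="16S"),
            _profile("S3", {"c": 1}, marker="16S"),
        ]
        return detection_matrix(p12), detection_matrix(p16)

    def test_identical_matrices_fully_corroborated(self):
        d, _ = self._matrices()
        res = marker_concordance(d, d)
        assert res.corroborated_12s == res.instances_12s
        assert res.counts["12S_only"] == res.counts["16S_only"] == 0

    def test_disjoint_matrices_zero_corroboration(self):
        d12, _ = self._matrices()
        empty = d12 & False
        res = marker_concordance(d12, empty)
        assert res.corroborated_12s == 0 and res.instances_16s == 0

    def test_counts_match_brute_force(self):
        d12, d16 = self._matrices()
        res = marker_concordance(d12, d16)
        samples = sorted(d12.index)
        taxa = sorted(set(d12.columns) | set(d16.columns))
        brute = {"both": 0, "12S_only": 0, "16S_only": 0, "neither": 0}
        for s, t in itertools.product(samples, taxa):
            a = bool(d12.at[s, t]) if t in d12.columns else False
            b = bool(d16.at[s, t]) if t in d16.columns else False
            key = "both" if a and b else "12S_only" if a else "16S_only" if b else "neither"
            brute[key] += 1
        assert res.counts == brute
        assert sum(res.counts.values()) == len(samples) * len(taxa)
        assert res.instances_12s == brute["both"] + brute["12S_only"]
        assert res.corroborated_16s == brute["both"]

    def test_union_detections_at_least_per_marker(self):
        d12, d16 = self._matrices()
        taxa = sorted(set(d12.columns) | set(d16.columns))
        a = d12.reindex(columns=taxa, fill_value=False)
        b = d16.reindex(columns=taxa, fill_value=False)
        union = a | b
        for s in d12.index:
            assert union.loc[s].sum() >= max(a.loc[s].sum(), b.loc[s].sum())


def test_similarity_matrix_drops_empty_and_is_symmetric():
    profiles = [
        _profile("S1", {"a": 6, "c": 2}),
        _profile("S2", {"a": 2, "b": 2}),
        _profile("S3", {}),
    ]
    sim = similarity_matrix(profiles)
    assert list(sim.index) == ["S1", "S2"]
    assert sim.loc["S1", "S2"] == pytest.approx(1 / 3)
    assert sim.equals(sim.T)
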