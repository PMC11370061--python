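"""Stability-based cluster validation, label alignment and the Gaussian null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motorstrat.subtyping import (
    DegenerateInputError,
    RevalConfig,
    align_labels,
    fit_and_generalize,
    normalized_stability,
    select_best_k,
    sigclust,
    stratified_split,
)

from _oracles import align_bruteforce


def _blobs(rng, centers, n_per, sd=1.0):
    X = np.vstack([rng.normal(c, sd, size=(n_per, len(c))) for c in centers])
    return X


class TestAlignLabels:
    def test_relabeling_swap_recovers_zero_error(self):
        mapped, err = align_labels(np.array([0, 0, 1, 1]), np.array([1, 1, 0, 0]))
        assert err == 0.0
        np.testing.assert_array_equal(mapped, [0, 0, 1, 1])

    def test_half_disagreement_is_floor(self):
        _, err = align_labels(np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1]))
        assert err == 0.5

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            align_labels(np.array([0, 1]), np.array([0, 1, 0]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.integers(2, 4).flatmap(
            lambda k: st.tuples(
                st.just(k),
                st.lists(st.integers(0, 3).map(lambda v: v % k), min_size=2, max_size=8),
                st.lists(st.integers(0, 3).map(lambda v: v % k), min_size=2, max_size=8),
            )
        )
    )
    def test_matches_exhaustive_permutation_oracle(self, args):
        k, ref, cand = args
        n = min(len(ref), len(cand))
        ref, cand = np.array(ref[:n]), np.array(cand[:n])
        _, err = align_labels(ref, cand)
        assert err == pytest.approx(align_bruteforce(ref, cand, k), abs=1e-12)

    def test_rectangular_matching_when_cluster_counts_differ(self):
        ref = np.array([0, 0, 1, 1, 1, 1])
        cand = np.array([0, 0, 1, 1, 2, 2])  # one extra cluster
        mapped, err = align_labels(ref, cand)
        assert err == pytest.approx(2 / 6)


class TestNormalizedStability:
    def test_separated_blobs_are_trivially_stable(self, rng):
        Z = _blobs(rng, [(0, 0), (10, 10)], 40)
        entry = normalized_stability(Z, 2, RevalConfig(seed=0, cv_repeats=30))
        assert entry["normalized_stability"] < 0.05

    def test_spherical_gaussian_is_unstable_at_k2(self):
        # no preferred split direction -> independent halves disagree
        vals = []
        for seed in range(5):
            Z = np.random.default_rng(seed).normal(size=(100, 2))
            vals.append(
                normalized_stability(Z, 2, RevalConfig(seed=seed, cv_repeats=30))[
                    "normalized_stability"
                ]
            )
        assert np.mean(vals) > 0.3

    def test_duplicated_points_cluster_deterministically(self):
        Z = np.repeat([[0.0, 0.0], [5.0, 5.0]], 30, axis=0)
        entry = normalized_stability(Z, 2, RevalConfig(seed=1, cv_repeats=10))
        assert entry["misclassification"] == 0.0

    def test_label_permutation_invariance(self, rng):
        ref = rng.integers(0, 3, 30)
        cand = rng.integers(0, 3, 30)
        _, e1 = align_labels(ref, cand)
        perm = np.array([2, 0, 1])
        _, e2 = align_labels(ref, perm[cand])
        assert e1 == pytest.approx(e2)


class TestStratifiedSplit:
    def _table(self, n, rng, strata=True):
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "study_id": rng.choice(["A", "B"], n) if strata else "A",
                "sex": rng.choice(["M", "F"], n) if strata else "M",
                "module": rng.choice([1, 2], n) if strata else 1,
                "md": rng.normal(size=n),
                "ac": rng.normal(size=n),
                "bl": rng.normal(size=n),
                "total": rng.normal(size=n),
            }
        )

    def test_cohort_split_sizes(self, rng):
        t = self._table(156, rng)
        tr, va = stratified_split(t, RevalConfig(seed=0))
        assert len(tr) + len(va) == 156
        assert abs(len(tr) - 109) <= 4  # ~70% overall, +-1 subject per stratum
        assert set(tr["subject_id"]).isdisjoint(va["subject_id"])

    def test_single_stratum_arithmetic(self, rng):
        t = self._table(10, rng, strata=False)
        tr, va = stratified_split(t, RevalConfig(seed=0))
        assert (len(tr), len(va)) == (7, 3)

    def test_same_seed_reproduces_split(self, rng):
        t = self._table(60, rng)
        tr1, _ = stratified_split(t, RevalConfig(seed=5))
        tr2, _ = stratified_split(t, RevalConfig(seed=5))
        pd.testing.assert_frame_equal(tr1, tr2)


class TestSelectBestK:
    def test_three_separated_blobs_recovered(self, rng):
        X = _blobs(rng, [(0, 0, 0), (10, 10, 0), (0, 10, 10)], 50)
        df = pd.DataFrame(X, columns=["md", "ac", "bl"])
        cfg = RevalConfig(seed=3, cv_repeats=30)
        best_k, curve, *_ = select_best_k(df, cfg)
        assert best_k == 3
        assert set(curve["k"]) == set(range(2, 11))

    def test_constant_features_rejected(self):
        df = pd.DataFrame(np.ones((50, 3)), columns=["md", "ac", "bl"])
        with pytest.raises(DegenerateInputError):
            select_best_k(df, RevalConfig(seed=0))


class TestFitAndGeneralize:
    def test_validation_copy_of_train_is_perfectly_predicted(self, rng):
        X = _blobs(rng, [(0, 0, 0), (8, 8, 8)], 60)
        df = pd.DataFrame(X, columns=["md", "ac", "bl"])
        df["subject_id"] = [f"s{i}" for i in range(len(df))]
        df["total"] = X.sum(axis=1)
        cfg = RevalConfig(seed=2, cv_repeats=10)
        best_k, curve, scaler, emb = select_best_k(df, cfg)
        model = fit_and_generalize(df, df.copy(), best_k, cfg, scaler, emb, curve)
        assert best_k == 2
        assert model.generalization_accuracy == 1.0
        # semantics: lower mean total labelled Low
        low_cluster = [c for c, s in model.label_semantics.items() if s == "Low"][0]
        means = df.groupby(model.train_labels.to_numpy())["total"].mean()
        assert means.idxmin() == low_cluster


class TestSigclust:
    def test_separated_blobs_reach_minimum_p(self, rng):
        X = _blobs(rng, [(0, 0, 0), (6, 6, 6)], 50)
        res = sigclust(X, n_sim=200, seed=0)
        assert res.p_value == pytest.approx(1 / 201)
        assert res.cluster_index < 0.4

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            sigclust(rng.normal(size=(5, 3)), n_sim=100, seed=0)

    def test_low_n_sim_warns(self, rng):
        with pytest.warns(UserWarning, match="unstable"):
            sigclust(rng.normal(size=(50, 3)), n_sim=50, seed=0)

    def test_p_value_bounded_below(self, rng):
        res = sigclust(rng.normal(size=(50, 3)), n_sim=100, seed=1)
        assert 1 / 101 <= res.p_value <= 1.0
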