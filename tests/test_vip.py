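"""VIP scoring, sign/threshold rules, merging, and clustering."""

import numpy as np
import pandas as pd
import pytest

from adaptsig.pls import PLSRModel
from adaptsig.vip import (cluster_cell_lines, compute_vip,
                          merge_consistent_vip, sign_and_threshold)
from conftest import run_signal_pipeline


class TestVIPFormula:
    def test_single_component_concentrated_weight(self):
        vip = compute_vip(np.array([[1.0], [0.0], [0.0]]), np.array([2.5]))
        np.testing.assert_allclose(vip, [np.sqrt(3), 0, 0], atol=1e-12)

    def test_uniform_weights_give_unit_vip(self):
        K = 4
        W = np.full((K, 2), 1 / np.sqrt(K))
        W[:, 1] *= np.array([1, -1, 1, -1])  # sign-free: w^2 uniform
        vip = compute_vip(W, np.array([3.0, 0.5]))
        np.testing.assert_allclose(vip, 1.0, atol=1e-12)

    def test_zero_explained_variance_rejected(self):
        with pytest.raises(ValueError, match="explains nothing"):
            compute_vip(np.eye(3), np.zeros(3))

    def test_sum_of_squares_equals_variable_count(self, default_study):
        vip = default_study["results"].vip()
        assert len(vip) == 105
        assert float((vip ** 2).sum()) == pytest.approx(105.0, abs=1e-6)

    def test_matches_independent_elementwise_evaluation(self, default_study):
        # independent oracle: explicit double loop over the formula
        res = default_study["results"]
        W, ss = res.weights, res.ss
        K, N = W.shape
        expected = np.empty(K)
        for k in range(K):
            acc = 0.0
            for n in range(N):
                acc += W[k, n] ** 2 * ss[n]
            expected[k] = np.sqrt(K * acc / ss.sum())
        np.testing.assert_allclose(res.vip().to_numpy(), expected,
                                   atol=1e-10)


class TestSignAndThreshold:
    def _xy(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        X = np.column_stack([-y, y, rng.normal(size=30)])
        return X, y

    def test_anticorrelated_variable_gets_minus_sign(self):
        X, y = self._xy()
        prof = sign_and_threshold(np.array([2.0, 1.5, 0.4]), X, y)
        assert prof["signed_vip"].iloc[0] == pytest.approx(-2.0)
        assert prof["signed_vip"].iloc[1] == pytest.approx(1.5)

    @pytest.mark.parametrize("vip_value", [0.99, 1.0])
    def test_scores_at_or_below_one_are_zeroed(self, vip_value):
        X, y = self._xy()
        prof = sign_and_threshold(np.array([vip_value, 2.0, 2.0]), X, y)
        assert prof["signed_vip"].iloc[0] == 0.0

    def test_zero_correlation_defaults_to_positive(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        X = np.ones((4, 1))  # zero variance -> zero correlation
        prof = sign_and_threshold(np.array([1.5]), X, y)
        assert prof["sign"].iloc[0] == 1.0

    def test_coefficient_sign_source(self):
        X, y = self._xy()
        prof = sign_and_threshold(np.array([2.0, 2.0, 2.0]), X, y,
                                  sign_from="coefficient",
                                  coef=np.array([-1.0, 1.0, 1.0]))
        assert prof["sign"].tolist() == [-1.0, 1.0, 1.0]


class TestMerge:
    def _profile(self, signed):
        idx = pd.Index([f"v{i}" for i in range(len(signed))])
        signed = np.asarray(signed, dtype=float)
        return pd.DataFrame({"vip": np.abs(signed),
                             "sign": np.where(signed < 0, -1.0, 1.0),
                             "signed_vip": signed, "kept": True}, index=idx)

    def test_identical_profiles_merge_to_themselves(self):
        a = self._profile([2.0, -1.5, 0.0])
        mask = pd.Series(True, index=a.index)
        merged, report = merge_consistent_vip(a, a.copy(), mask)
        np.testing.assert_allclose(merged["signed_vip"], a["signed_vip"])
        assert report["n_kept"] == 3
        assert report["n_sign_discordant"] == 0

    def test_sign_discordant_variable_dropped_and_counted(self):
        a = self._profile([2.0, 1.5])
        b = self._profile([2.0, -1.5])
        mask = pd.Series(True, index=a.index)
        merged, report = merge_consistent_vip(a, b, mask)
        assert "v1" not in merged.index
        assert report["n_sign_discordant"] == 1

    def test_masked_variables_removed(self):
        a = self._profile([2.0, 1.5, -3.0])
        mask = pd.Series([True, False, True], index=a.index)
        merged, report = merge_consistent_vip(a, a.copy(), mask)
        assert list(merged.index) == ["v0", "v2"]
        assert report["n_masked_out"] == 1

    def test_merge_averages_small_perturbations(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(1.1, 3.0, size=20) * rng.choice([-1, 1], size=20)
        eps = rng.uniform(-0.05, 0.05, size=20)
        a = self._profile(base)
        b = self._profile(base + eps)
        mask = pd.Series(True, index=a.index)
        merged, _ = merge_consistent_vip(a, b, mask)
        assert (np.abs(merged["signed_vip"] - a["signed_vip"])
                <= np.abs(eps) / 2 + 1e-12).all()

    def test_label_mismatch_rejected(self):
        a = self._profile([2.0, 1.5])
        b = self._profile([2.0, 1.5, 1.2])
        with pytest.raises(ValueError):
            merge_consistent_vip(a, b, pd.Series(True, index=a.index))


class TestPlantedRecovery:
    def test_top_vip_variables_are_the_planted_ones(self, recovery_cfg):
        hits = []
        for seed in range(20):
            tensor, truth, fc, design, pheno, viab, y = run_signal_pipeline(
                recovery_cfg(seed))
            res = PLSRModel.from_design(design, y).fit(2)
            vip = res.vip().sort_values(ascending=False)
            top10 = {tuple(c) for c in vip.head(10).index}
            hits.append(len(top10 & truth.informative_variables))
        assert np.mean(hits) >= 8
        assert min(hits) >= 8

    def test_signs_match_generative_coupling(self, recovery_cfg):
        agree = total = 0
        for seed in range(10):
            tensor, truth, fc, design, pheno, viab, y = run_signal_pipeline(
                recovery_cfg(seed))
            res = PLSRModel.from_design(design, y).fit(2)
            prof = sign_and_threshold(res.vip(), design.values,
                                      y.to_numpy())
            cl = recovery_cfg(seed).cell_lines[0]
            nl = truth.noiseless_log2(cl)
            nv = (truth.noiseless_viability(cl, 48.0)
                  + truth.noiseless_viability(cl, 72.0)) / 2
            nv = nv.reindex(nl.index).to_numpy()
            for col in prof.index[prof["signed_vip"] != 0]:
                x = nl[col].to_numpy()
                if np.std(x) < 1e-12:
                    continue
                expected = np.sign(np.corrcoef(x, nv)[0, 1])
                if expected == 0:
                    continue
                total += 1
                agree += np.sign(prof.loc[[col], "sign"].iloc[0]) == expected
        assert total > 50
        assert agree / total >= 0.95


def _naive_average_linkage(X):
    """O(n^3) agglomeration oracle returning cophenetic distances."""
    n = len(X)
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    d = {(i, j): float(np.linalg.norm(X[i] - X[j]))
         for i in range(n) for j in range(i + 1, n)}

    def cdist(a, b):
        return np.mean([d[tuple(sorted((i, j)))]
                        for i in clusters[a] for j in clusters[b]])

    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(((cdist(a, b), a, b) for ai, a in enumerate(keys)
                    for b in keys[ai + 1:]))
        h, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return coph


class TestClustering:
    def test_identical_profiles_merge_at_zero_height(self):
        prof = pd.Series([2.0, -1.5, 0.0], index=["a", "b", "c"])
        result = cluster_cell_lines({"x": prof, "y": prof.copy(),
                                     "z": prof + 5}, exclude=())
        assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(result.leaf_order) == {"x", "y", "z"}

    def test_nearest_pair_merges_first(self):
        profiles = {
            "p": pd.Series([0.0, 0.0]),
            "q": pd.Series([1.0, 0.0]),
            "r": pd.Series([10.0, 0.0]),
        }
        result = cluster_cell_lines(profiles, exclude=())
        first = {result.labels[int(result.linkage[0, 0])],
                 result.labels[int(result.linkage[0, 1])]}
        assert first == {"p", "q"}

    def test_cophenetic_matches_naive_agglomeration(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(7, 12))
        profiles = {f"cl{i}": pd.Series(X[i]) for i in range(7)}
        result = cluster_cell_lines(profiles, exclude=())
        from scipy.spatial.distance import squareform
        ours = squareform(result.cophenetic())
        oracle = _naive_average_linkage(X)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_drug_target_readouts_excluded_from_distance(self):
        cols = pd.MultiIndex.from_product(
            [["pMEK", "pERK", "pS6"], [1.0, 48.0]],
            names=["signal", "time"])
        rng = np.random.default_rng(4)
        base = pd.DataFrame(rng.normal(size=(3, 6)), columns=cols,
                            index=["a", "b", "c"])
        shifted = base.copy()
        shifted.loc[:, ["pMEK", "pERK"]] += rng.normal(size=(3, 4)) * 10
        r1 = cluster_cell_lines(base)
        r2 = cluster_cell_lines(shifted)
        np.testing.assert_allclose(r1.linkage, r2.linkage, atol=1e-12)

    def test_all_zero_profile_retained(self):
        profiles = {"a": pd.Series([0.0, 0.0]), "b": pd.Series([1.0, 1.0]),
                    "c": pd.Series([2.0, 2.0])}
        result = cluster_cell_lines(profiles, exclude=())
        assert len(result.leaf_order) == 3

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            cluster_cell_lines({"a": pd.Series([1.0])})

    def test_newick_export_contains_all_leaves(self):
        rng = np.random.default_rng(5)
        profiles = {f"cl{i}": pd.Series(rng.normal(size=4))
                    for i in range(5)}
        nwk = cluster_cell_lines(profiles, exclude=()).to_newick()
        assert nwk.endswith(";")
        for name in profiles:
            assert name in nwk
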