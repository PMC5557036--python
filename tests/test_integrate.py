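"""Response metrics, Ward clustering/branch lengths, and association statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from synchromet import integrate
from synchromet.integrate import (
    average_branch_length,
    bh_adjust,
    branch_length_wilcoxon,
    cluster_samples,
    correlate,
    fisher_median_dichotomy,
    marker_response_association,
    recist_class,
    response_metrics,
    rf_importance,
    variable_heatmap_prep,
)


# --- response metrics --------------------------------------------------------


class TestResponseMetrics:
    def _sizes(self, rows):
        return pd.DataFrame(
            rows, columns=["patient_id", "lesion_id", "baseline_size", "followup_size"]
        )

    def test_percent_change_and_recist(self):
        sizes = self._sizes([("p1", "a", 50.0, 30.0), ("p1", "b", 40.0, 42.0)])
        lesion, patient = response_metrics(sizes)
        a = lesion.set_index("lesion_id").loc["a"]
        assert a["percent_change"] == pytest.approx(-40.0)
        assert a["recist_class"] == "PR"
        assert lesion.set_index("lesion_id").loc["b", "recist_class"] == "SD"

    def test_recist_thresholds(self):
        assert recist_class(-100.0) == "CR"
        assert recist_class(-30.0) == "PR"
        assert recist_class(-29.9) == "SD"
        assert recist_class(19.9) == "SD"
        assert recist_class(20.0) == "PD"

    def test_heterogeneity_flags(self):
        # +5% and -40%: max diff 45 -> flags at 10 and 20, not 50; mixed classes
        sizes = self._sizes([("p1", "a", 100.0, 105.0), ("p1", "b", 100.0, 60.0)])
        lesion, patient = response_metrics(sizes)
        row = patient.iloc[0]
        assert row["max_pairwise_diff"] == pytest.approx(45.0)
        assert bool(row["heterogeneous_ge_10"]) and bool(row["heterogeneous_ge_20"])
        assert not row["heterogeneous_ge_50"]
        assert bool(row["mixed_recist"])
        assert set(lesion["recist_class"]) == {"SD", "PR"}

    def test_identical_lesions_deterministic_ties(self):
        sizes = self._sizes([("p1", "b", 50.0, 50.0), ("p1", "a", 50.0, 50.0)])
        _, patient = response_metrics(sizes)
        row = patient.iloc[0]
        assert not row["heterogeneous_ge_10"]
        assert row["best_lesion"] == "a" and row["worst_lesion"] == "a"

    def test_best_is_largest_decrease(self):
        sizes = self._sizes([("p1", "a", 100.0, 90.0), ("p1", "b", 100.0, 40.0)])
        _, patient = response_metrics(sizes)
        assert patient.iloc[0]["best_lesion"] == "b"
        assert patient.iloc[0]["worst_lesion"] == "a"

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            response_metrics(self._sizes([("p1", "a", 0.0, 5.0), ("p1", "b", 1.0, 1.0)]))

    def test_single_lesion_patient_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            response_metrics(self._sizes([("p1", "a", 10.0, 5.0)]))


# --- Ward clustering oracle --------------------------------------------------


def ward_d2_cophenetic_oracle(D):
    """Exhaustive-merge agglomeration with the Lance-Williams ward.D2 update.

    At each step every candidate pair is evaluated and the minimum-distance
    pair merged (ties: lowest indices); returns the cophenetic matrix.
    """
    n = D.shape[0]
    d2 = {}
    for i, j in itertools.combinations(range(n), 2):
        d2[(i, j)] = D[i, j] ** 2
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best, best_d2 = None, np.inf
        for a, b in itertools.combinations(keys, 2):
            v = d2[(min(a, b), max(a, b))]
            if v < best_d2 - 1e-15:
                best, best_d2 = (a, b), v
        a, b = best
        h = np.sqrt(best_d2)
        for x in clusters[a]:
            for y in clusters[b]:
                coph[x, y] = coph[y, x] = h
        na, nb = len(clusters[a]), len(clusters[b])
        merged = clusters[a] + clusters[b]
        for k in keys:
            if k in (a, b):
                continue
            nk = len(clusters[k])
            dka = d2[(min(k, a), max(k, a))]
            dkb = d2[(min(k, b), max(k, b))]
            dab = d2[(min(a, b), max(a, b))]
            new = ((na + nk) * dka + (nb + nk) * dkb - nk * dab) / (na + nb + nk)
            d2[(min(k, next_id), max(k, next_id))] = new
        del clusters[a], clusters[b]
        clusters[next_id] = merged
        next_id += 1
    return coph


class TestClusterSamples:
    def test_identical_samples_merge_at_zero(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 9.0, 9.0]],
                         index=["a", "b", "c"])
        dendro = cluster_samples(X, block="genomic")
        assert average_branch_length(dendro, ["a", "b"]) == pytest.approx(0.0)

    @pytest.mark.parametrize("n_samples", [4, 5, 6, 7])
    def test_euclidean_ward_matches_exhaustive_oracle(self, n_samples, rng):
        X = pd.DataFrame(rng.normal(size=(n_samples, 6)),
                         index=[f"s{i}" for i in range(n_samples)])
        dendro = cluster_samples(X, block="genomic")
        D = squareform(pdist(X.to_numpy()))
        expected = ward_d2_cophenetic_oracle(D)
        got = dendro.cophenetic_matrix().to_numpy()
        assert np.allclose(got, expected, rtol=1e-8, atol=1e-10)

    def test_correlation_ward_matches_exhaustive_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 10)), index=[f"s{i}" for i in range(6)])
        dendro = cluster_samples(X, block="immune")
        D = 1.0 - np.corrcoef(X.to_numpy())
        np.fill_diagonal(D, 0.0)
        expected = ward_d2_cophenetic_oracle(np.clip(D, 0, None))
        assert np.allclose(dendro.cophenetic_matrix().to_numpy(), expected,
                           rtol=1e-8, atol=1e-10)

    def test_duplicating_variables_preserves_correlation_tree(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 8)), index=[f"s{i}" for i in range(5)])
        X2 = pd.concat([X, X.add_suffix("_dup", axis=1)], axis=1)
        c1 = cluster_samples(X, block="immune").cophenetic_matrix()
        c2 = cluster_samples(X2, block="immune").cophenetic_matrix()
        assert np.allclose(c1.to_numpy(), c2.to_numpy())

    def test_zero_variance_sample_named_in_error(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 5)), index=["a", "b", "flatline", "d"])
        X.loc["flatline"] = 3.0
        with pytest.raises(ValueError, match="flatline"):
            cluster_samples(X, block="immune")

    def test_heights_nondecreasing(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 4)))
        Z = cluster_samples(X, block="genomic").linkage
        assert (np.diff(Z[:, 2]) >= -1e-12).all()


class TestBranchLength:
    def _four_leaf_fixture(self):
        # two tight pairs far apart
        X = pd.DataFrame(
            [[0.0, 0], [0.1, 0], [10.0, 0], [10.1, 0]], index=list("abcd")
        )
        return cluster_samples(X, block="genomic")

    def test_brute_force_cophenetic(self):
        dendro = self._four_leaf_fixture()
        coph = dendro.cophenetic_matrix()
        # every within-pair distance is small, every cross-pair distance equal
        assert coph.loc["a", "b"] == pytest.approx(0.1)
        assert coph.loc["c", "d"] == pytest.approx(0.1)
        cross = [coph.loc[x, y] for x in "ab" for y in "cd"]
        assert all(c == pytest.approx(cross[0]) for c in cross)
        assert average_branch_length(dendro, list("abcd")) == pytest.approx(
            (0.1 + 0.1 + 4 * cross[0]) / 6
        )

    def test_group_of_duplicates_is_zero(self):
        X = pd.DataFrame([[1.0, 1], [1.0, 1], [5.0, 5]], index=list("abc"))
        dendro = cluster_samples(X, block="genomic")
        assert average_branch_length(dendro, ["a", "b"]) == 0.0

    def test_spanning_height_mode_geq_mean(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 3)), index=[f"s{i}" for i in range(6)])
        dendro = cluster_samples(X, block="genomic")
        group = ["s0", "s1", "s2"]
        assert average_branch_length(dendro, group, mode="spanning_height") >= \
            average_branch_length(dendro, group)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            average_branch_length(self._four_leaf_fixture(), ["a"])

    def test_wilcoxon_enumeration_golden(self):
        # {1,2,3} vs {4,5,6}: 2 of the 20 rank arrangements are as extreme
        _, p = branch_length_wilcoxon([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)


# --- association statistics --------------------------------------------------


class TestMarkerResponseAssociation:
    def _cohort(self, n_patients=8, rng=None):
        rng = rng or np.random.default_rng(0)
        pids = np.repeat([f"p{i}" for i in range(n_patients)], 2)
        indicator = np.tile([1, 0], n_patients)
        return pids, indicator

    def test_constant_marker_p_is_one(self):
        pids, ind = self._cohort()
        X = pd.DataFrame({"flat": np.ones(len(ind))})
        res = marker_response_association(X, ind, pids, n_perm=500, seed=0)
        assert res[0].p_value == 1.0

    def test_perfect_marker_small_p(self):
        """Marker equal to the indicator over 8 patients x 2 lesions: only the
        2 of 2^8 within-patient relabelings reproduce |T|, so p ~ 2/256."""
        pids, ind = self._cohort(8)
        X = pd.DataFrame({"perfect": ind.astype(float)})
        res = marker_response_association(X, ind, pids, n_perm=10000, seed=1)
        assert res[0].p_value <= 0.01

    def test_constant_indicator_patient_excluded_with_warning(self):
        pids = np.array(["p1", "p1", "p2", "p2"])
        ind = [1, 0, 1, 1]  # p2 has no contrast
        X = pd.DataFrame({"m": [1.0, 0.0, 5.0, 6.0]})
        with pytest.warns(UserWarning, match="p2"):
            res = marker_response_association(X, ind, pids, n_perm=200)
        assert len(res) == 1

    def test_bh_adjustment_applied_across_markers(self, rng):
        pids, ind = self._cohort(6, rng)
        X = pd.DataFrame(rng.normal(size=(len(ind), 5)), columns=list("abcde"))
        res = marker_response_association(X, ind, pids, n_perm=200, seed=3)
        ps = [r.p_value for r in res]
        qs = [r.q_value for r in res]
        assert np.allclose(qs, bh_adjust(ps))
        assert all(q >= p - 1e-12 for p, q in zip(ps, qs))

    def test_mixedlm_backend_runs(self, rng):
        pids, ind = self._cohort(8, rng)
        X = pd.DataFrame({"m": rng.normal(size=len(ind)) + ind})
        res = marker_response_association(X, ind, pids, backend="mixedlm")
        assert 0.0 <= res[0].p_value <= 1.0


class TestBhAdjust:
    def test_step_up_golden(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_matches_direct_formula_on_random_vectors(self, rng):
        for _ in range(10):
            p = rng.uniform(size=int(rng.integers(3, 40)))
            m = len(p)
            order = np.argsort(p)
            q_sorted = p[order] * m / (np.arange(m) + 1)
            q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            assert np.allclose(bh_adjust(p), expected)


class TestFisherMedianDichotomy:
    def test_perfect_separation_golden(self):
        # 5 low non-responders, 5 high responders -> table [[5,0],[0,5]]
        values = [1, 1, 1, 1, 1, 9, 9, 9, 9, 9]
        flags = [False] * 5 + [True] * 5
        odds, p, table = fisher_median_dichotomy(values, flags)
        assert table.tolist() == [[5, 0], [0, 5]]
        assert p == pytest.approx(2 / 252, rel=1e-6)  # 0.00793

    def test_balanced_table_p_one(self):
        values = [1, 1, 1, 2, 2, 2, 9, 9, 9, 10, 10, 10]
        flags = [True, True, True, False, False, False] * 2
        _, p, table = fisher_median_dichotomy(values, flags)
        assert table.tolist() == [[3, 3], [3, 3]]
        assert p == pytest.approx(1.0)

    def test_median_ties_go_low(self):
        values = [1, 2, 2, 3]  # median 2; ties at 2 go to the low group
        _, _, table = fisher_median_dichotomy(values, [False, True, False, True])
        assert table.sum(axis=1).tolist() == [3, 1]

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fisher_median_dichotomy([2, 2, 2, 2], [True, False, True, False])

    def test_null_p_roughly_uniform(self, rng):
        """Under independence, the exact p-value is stochastically >= uniform
        (conservative): its empirical CDF at 0.25 should not exceed 0.25 by
        more than noise."""
        ps = []
        for _ in range(300):
            v = rng.normal(size=12)
            f = rng.random(12) < 0.5
            if f.all() or not f.any():
                continue
            ps.append(fisher_median_dichotomy(v, f)[1])
        frac = np.mean(np.asarray(ps) <= 0.25)
        assert frac <= 0.30


class TestRfImportance:
    def test_perfect_feature_ranks_first(self, rng):
        n = 40
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"noise{i}" for i in range(5)])
        X["signal"] = y + 0.01 * rng.normal(size=n)
        imp, oob = rf_importance(X, y, n_trees=300, seed=0)
        assert imp.idxmax() == "signal"
        assert oob < 0.2

    def test_pure_noise_oob_near_half(self, rng):
        n = 40
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame(rng.normal(size=(n, 6)))
        _, oob = rf_importance(X, y, n_trees=500, seed=1)
        assert oob == pytest.approx(0.5, abs=0.15)

    def test_deterministic_under_seed(self, rng):
        n = 30
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(size=(n, 4)))
        imp1, oob1 = rf_importance(X, y, n_trees=200, seed=7)
        imp2, oob2 = rf_importance(X, y, n_trees=200, seed=7)
        assert imp1.equals(imp2) and oob1 == oob2

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.zeros((12, 2)))
        with pytest.raises(ValueError, match="single class"):
            rf_importance(X, np.zeros(12))


class TestCorrelate:
    def test_linear_pearson(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x, method="pearson", n_perm=200)
        assert r == pytest.approx(1.0)

    def test_rank_reversal_spearman(self, rng):
        x = rng.normal(size=12)
        y = -np.argsort(np.argsort(x)).astype(float)
        r, _ = correlate(x, y, method="spearman", n_perm=200)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate([1, 1, 1], [1, 2, 3])

    def test_permutation_p_detects_signal(self, rng):
        x = rng.normal(size=40)
        y = x + 0.1 * rng.normal(size=40)
        _, p = correlate(x, y, n_perm=999, seed=5)
        assert p == pytest.approx(1 / 1000)


class TestVariableHeatmapPrep:
    def test_rows_z_scored(self, rng):
        X = pd.DataFrame(rng.normal(2, 5, size=(10, 4)), columns=list("abcd"))
        z, _ = variable_heatmap_prep(X)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=0), 1.0)

    def test_monotone_transform_preserves_spearman_tree(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
        X2 = X.copy()
        X2["c"] = np.exp(X2["c"])  # strictly monotone: ranks unchanged
        t1 = variable_heatmap_prep(X)[1].cophenetic_matrix()
        t2 = variable_heatmap_prep(X2)[1].cophenetic_matrix()
        assert np.allclose(t1.to_numpy(), t2.to_numpy())

    def test_variable_tree_matches_ward_oracle(self, rng):
        from scipy import stats as sps

        X = pd.DataFrame(rng.normal(size=(9, 3)), columns=list("abc"))
        _, dendro = variable_heatmap_prep(X)
        ranks = np.apply_along_axis(sps.rankdata, 1, X.to_numpy().T)
        D = np.clip(1 - np.corrcoef(ranks), 0, None)
        np.fill_diagonal(D, 0)
        expected = ward_d2_cophenetic_oracle(D)
        assert np.allclose(dendro.cophenetic_matrix().to_numpy(), expected)

    def test_zero_variance_variable_named(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 3)), columns=["a", "deadgene", "c"])
        X["deadgene"] = 1.0
        with pytest.raises(ValueError, match="deadgene"):
            variable_heatmap_prep(X)
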