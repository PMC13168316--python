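"""clr transform, PCA, Spearman correlations, PERMANOVA, dispersion."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from glycofeed.compositional import (
    ClrMatrix,
    clr_transform,
    dispersion_test,
    pca,
    permanova,
    spearman_sample_correlation,
)
from glycofeed.glycoforms import normalize_abundances


def make_clr(values, groups=None, phases=None):
    values = np.asarray(values, float)
    idx = [f"s{i}" for i in range(values.shape[0])]
    meta = pd.DataFrame({
        "strategy": groups if groups is not None else ["A"] * len(idx),
        "phase": phases if phases is not None else ["exp"] * len(idx),
        "replicate": idx,
    }, index=idx)
    cols = [f"g{j}" for j in range(values.shape[1])]
    return ClrMatrix(pd.DataFrame(values, index=idx, columns=cols), meta)


class TestClr:
    def test_uniform_composition_maps_to_zero(self):
        t = normalize_abundances(pd.DataFrame(
            [[25.0] * 4], index=["a"],
            columns=["G0 ⋅ G0", "G0F ⋅ G0F", "G1F ⋅ G1F", "G2F ⋅ G2F"]))
        assert np.allclose(clr_transform(t).to_numpy(), 0.0)

    def test_worked_example(self):
        t = normalize_abundances(pd.DataFrame(
            [[50.0, 25.0, 25.0]], index=["a"],
            columns=["G0F ⋅ G0F", "G0F ⋅ G1F", "G1F ⋅ G1F"]))
        got = clr_transform(t).to_numpy()[0]
        assert np.allclose(got, [0.4621, -0.2310, -0.2310], atol=5e-5)

    def test_row_sums_zero_and_scale_invariance(self, random_table):
        clr = clr_transform(random_table)
        assert np.allclose(clr.to_numpy().sum(axis=1), 0.0, atol=1e-10)
        scaled = normalize_abundances(random_table.abundances * 7.3,
                                      random_table.metadata)
        assert np.allclose(clr_transform(scaled).to_numpy(), clr.to_numpy())

    def test_zero_strict_names_sample_and_glycoform(self, random_table):
        ab = random_table.abundances.copy()
        ab.iloc[1, 2] = 0.0
        table = type(random_table)(ab, random_table.metadata)
        with pytest.raises(ValueError, match="s1"):
            clr_transform(table)

    def test_zero_replace_policy(self, random_table):
        ab = random_table.abundances.copy()
        ab.iloc[1, 2] = 0.0
        table = type(random_table)(ab, random_table.metadata)
        clr = clr_transform(table, zero_policy="replace")
        assert np.isfinite(clr.to_numpy()).all()


class TestPca:
    def test_two_clusters_single_direction(self):
        X = np.array([[1.0, 0, -1], [1.0, 0, -1], [-1.0, 0, 1], [-1.0, 0, 1]])
        res = pca(make_clr(X))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_known_orthogonal_directions_recovered(self):
        rng = np.random.default_rng(0)
        v1 = np.array([1.0, -1.0, 0.0, 0.0]) / np.sqrt(2)
        v2 = np.array([0.0, 0.0, 1.0, -1.0]) / np.sqrt(2)
        scores = rng.normal(size=(40, 2)) * np.array([5.0, 1.0])
        X = scores @ np.vstack([v1, v2])
        res = pca(make_clr(X))
        L = res.loadings.to_numpy()[:2]
        # principal subspace spans {v1, v2}: projections have unit norm
        basis = np.vstack([v1, v2])
        proj = L @ basis.T
        assert np.allclose(np.linalg.norm(proj, axis=1), 1.0, atol=1e-6)

    def test_explained_fractions_sum_to_one(self, random_table):
        res = pca(clr_transform(random_table))
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_reconstruction(self, random_table):
        clr = clr_transform(random_table)
        res = pca(clr)
        X = clr.to_numpy()
        recon = res.scores.to_numpy() @ res.loadings.to_numpy() + X.mean(axis=0)
        assert np.allclose(recon, X, atol=1e-8)

    def test_sign_convention_deterministic(self, random_table):
        res = pca(clr_transform(random_table))
        for _, row in res.loadings.iterrows():
            assert row.iloc[np.argmax(np.abs(row.to_numpy()))] > 0

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca(make_clr(np.ones((3, 4))))


class TestSpearman:
    def test_self_correlation_one(self, random_table):
        corr = spearman_sample_correlation(clr_transform(random_table))
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T, equal_nan=True)

    def test_rank_reversed_profile(self):
        clr = make_clr(np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]]))
        corr = spearman_sample_correlation(clr)
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        # profiles (1,2,3,4) vs (1,3,2,4): d² = (0,1,1,0), ρ = 1-6*2/60 = 0.8
        clr = make_clr(np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0]]))
        corr = spearman_sample_correlation(clr)
        assert corr.iloc[0, 1] == pytest.approx(0.8)

    def test_constant_profile_flagged_nan(self):
        clr = make_clr(np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0],
                                 [3.0, 1.0, 2.0]]))
        corr = spearman_sample_correlation(clr)
        assert np.isnan(corr.iloc[0, 1]) and np.isnan(corr.iloc[2, 0])
        assert corr.iloc[1, 2] == corr.iloc[1, 2]  # defined


def anova_f_oracle(X: np.ndarray, groups: np.ndarray) -> float:
    """Independent multivariate pseudo-F: coordinate-wise ANOVA sums of
    squares (valid for Euclidean distances)."""
    labels = np.unique(groups)
    grand = X.mean(axis=0)
    ss_between = sum(((X[groups == g].mean(axis=0) - grand) ** 2).sum()
                     * (groups == g).sum() for g in labels)
    ss_within = sum(((X[groups == g] - X[groups == g].mean(axis=0)) ** 2).sum()
                    for g in labels)
    df_b = len(labels) - 1
    df_w = len(X) - len(labels)
    return (ss_between / df_b) / (ss_within / df_w)


class TestPermanova:
    def test_separated_identical_groups_full_r2(self):
        X = np.array([[0.0, 0], [0, 0], [0, 0], [5, 5], [5, 5], [5, 5]])
        clr = make_clr(X, groups=list("AAABBB"))
        res = permanova(clr, ["strategy"], exhaustive=True)
        assert res.table.loc["strategy", "R2"] == pytest.approx(1.0)
        # identity relabeling ties only with group-preserving permutations
        assert res.table.loc["strategy", "p"] == pytest.approx(
            (3 * 2 * 1) ** 2 * 2 / 720)

    def test_exhaustive_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 3))
        groups = np.array(list("AAABBB"))
        clr = make_clr(X, groups=list(groups))
        res = permanova(clr, ["strategy"], exhaustive=True)
        F_obs = anova_f_oracle(X, groups)
        assert res.table.loc["strategy", "F"] == pytest.approx(F_obs)
        # brute-force p over the 20 distinct relabelings
        count = 0
        for pos in combinations(range(6), 3):
            g = np.array(["B"] * 6)
            g[list(pos)] = "A"
            count += anova_f_oracle(X, g) >= F_obs - 1e-12
        assert res.table.loc["strategy", "p"] == pytest.approx(count / 20)

    def test_one_dimensional_equals_classical_anova_f(self):
        from scipy.stats import f_oneway
        rng = np.random.default_rng(1)
        y = rng.normal(size=9)
        groups = list("AAABBBCCC")
        clr = make_clr(y[:, None], groups=groups)
        res = permanova(clr, ["strategy"], n_perm=9, seed=0)
        F_classic = f_oneway(y[:3], y[3:6], y[6:]).statistic
        assert res.table.loc["strategy", "F"] == pytest.approx(F_classic,
                                                               abs=1e-10)

    def test_matches_scikit_bio_one_way(self, random_table):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova
        clr = clr_transform(random_table)
        X = clr.to_numpy()
        d = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=list(clr.values.index))
        sk = sk_permanova(dm, grouping=list(clr.metadata["strategy"]),
                          permutations=99)
        res = permanova(clr, ["strategy"], n_perm=99, seed=0)
        assert res.table.loc["strategy", "F"] == pytest.approx(
            sk["test statistic"], abs=1e-8)

    def test_r2_additivity_and_seed_reproducibility(self, random_table):
        clr = clr_transform(random_table)
        res = permanova(clr, ["phase", "strategy"], n_perm=49, seed=11)
        assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0,
                                                                    abs=1e-10)
        res2 = permanova(clr, ["phase", "strategy"], n_perm=49, seed=11)
        pd.testing.assert_frame_equal(res.table, res2.table)

    def test_interaction_term_sums(self):
        rng = np.random.default_rng(2)
        n_per = 3
        groups, phases, rows = [], [], []
        for g in "AB":
            for p in ("exp", "sta"):
                for _ in range(n_per):
                    rows.append(rng.normal(size=4))
                    groups.append(g)
                    phases.append(p)
        clr = make_clr(np.array(rows), groups=groups, phases=phases)
        res = permanova(clr, ["phase", "strategy", "phase:strategy"],
                        n_perm=49, seed=3)
        assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0,
                                                                    abs=1e-10)
        assert (res.table.loc[["phase", "strategy", "phase:strategy"], "df"]
                == 1).all()

    def test_single_level_term_rejected(self):
        clr = make_clr(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ValueError, match="levels"):
            permanova(clr, ["strategy"], n_perm=9)

    def test_invalid_n_perm(self, random_table):
        with pytest.raises(ValueError):
            permanova(clr_transform(random_table), ["strategy"], n_perm=0)


class TestDispersion:
    def test_distances_nonnegative(self, random_table):
        res = dispersion_test(clr_transform(random_table), "strategy",
                              n_perm=19, seed=0)
        assert (res.distances >= 0).all()

    def test_translated_clouds_have_equal_dispersion(self):
        rng = np.random.default_rng(8)
        cloud = rng.normal(size=(4, 3))
        X = np.vstack([cloud, cloud + 10.0])
        clr = make_clr(X, groups=list("AAAABBBB"))
        res = dispersion_test(clr, "strategy", n_perm=199, seed=1)
        assert res.F == pytest.approx(0.0, abs=1e-20)
        assert res.p >= 0.1

    def test_zero_vs_spread_group_exhaustive_extreme(self):
        X = np.array([[0.0, 0], [0, 0], [3, 0], [-3, 0], [0, 4]])
        clr = make_clr(X, groups=list("AABBB"))
        res = dispersion_test(clr, "strategy", exhaustive=True)
        # observed F at least ties every permuted value; only label-preserving
        # permutations tie
        assert res.p <= 24 / 120 + 1e-12

    def test_singleton_group_rejected(self):
        clr = make_clr(np.zeros((3, 2)), groups=["A", "B", "B"])
        with pytest.raises(ValueError, match="fewer than 2"):
            dispersion_test(clr, "strategy")
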