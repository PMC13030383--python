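"""Differential screening: PCA, PLS-DA/VIP, t tests, DAM/DEG rules, Venn,
K-means and ddCt — each numerical path checked against an independent oracle
or closed form."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermomark.containers import OmicsMatrix
from thermomark.differential import (
    ddct,
    fit_plsda,
    kmeans_patterns,
    pca_summary,
    select_dams,
    select_degs,
    univariate_tests,
    validate_model,
    venn_overlap,
)

from conftest import toy_matrix, two_group_matrix


# ------------------------------------------------------------------------- PCA


class TestPca:
    def test_rank_one_data_loads_on_pc1(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        values = np.outer([1.0, 2.0, 0.5], base) + 5.0
        m = toy_matrix(values, ["tolerant"] * 4, [25, 25, 35, 35], [1, 2, 1, 2])
        res = pca_summary(m, n_components=2, scale=False)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        """Variance fractions equal eigenvalue shares of the sample covariance
        computed by a direct eigensolve."""
        rng = np.random.default_rng(0)
        values = rng.normal(size=(3, 4)) + 8.0
        m = toy_matrix(values, ["tolerant"] * 4, [25, 25, 35, 35], [1, 2, 1, 2])
        res = pca_summary(m, n_components=3, scale=False)
        cov = np.cov(values.T, rowvar=False)  # samples as observations
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = eig[eig > 1e-12] / eig.sum()
        np.testing.assert_allclose(res.variance_fraction, expected, atol=1e-10)

    def test_constant_matrix_flagged_degenerate(self):
        m = toy_matrix(
            np.full((5, 4), 3.0), ["tolerant"] * 4, [25, 25, 35, 35], [1, 2, 1, 2]
        )
        res = pca_summary(m)
        assert res.degenerate
        assert np.all(res.variance_fraction == 0)

    def test_isotropic_two_features_split_evenly(self):
        """With isotropic noise the two variance fractions approach (1/2, 1/2)
        as n grows (eigenvalue repulsion keeps PC1 slightly above 1/2)."""
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 1000
            values = rng.normal(size=(2, n)) + 10.0
            m = toy_matrix(
                values, ["tolerant"] * n, [25] * (n // 2) + [35] * (n // 2),
                list(range(1, n // 2 + 1)) * 2,
            )
            fracs.append(pca_summary(m, n_components=2, scale=False).variance_fraction)
        mean_frac = np.mean(fracs, axis=0)
        assert mean_frac[0] == pytest.approx(0.5, abs=0.05)
        assert mean_frac[0] >= mean_frac[1]


# ---------------------------------------------------------------------- PLS-DA


def nipals_vip_oracle(X, y01):
    """Single-component PLS VIP by the covariance-weight formula.

    Independent of the fitted model: w ∝ X_s' y_c, VIP_j = sqrt(p) * |w_j| /
    ||w|| for one component.
    """
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    yc = y01 - y01.mean()
    w = Xs.T @ yc
    w = w / np.linalg.norm(w)
    return np.sqrt(len(w)) * np.abs(w)


class TestPlsda:
    def test_vip_matches_single_component_nipals_oracle(self):
        rng = np.random.default_rng(3)
        values = 2.0 ** rng.normal(10, 1, size=(4, 6))
        m = toy_matrix(
            values, ["tolerant"] * 6, [25, 25, 25, 35, 35, 35], [1, 2, 3, 1, 2, 3]
        )
        labels = ["A", "A", "A", "B", "B", "B"]
        _, vip = fit_plsda(m, labels, n_components=1)
        oracle = nipals_vip_oracle(values.T, np.array([0, 0, 0, 1, 1, 1.0]))
        np.testing.assert_allclose(vip.vip.to_numpy(), oracle, atol=1e-8)

    def test_vip_normalization_identity(self):
        for seed in range(3):
            m = two_group_matrix(p=30, n_per=7, effect=1.0, seed=seed)
            labels = ["A"] * 7 + ["B"] * 7
            _, vip = fit_plsda(m, labels, n_components=2)
            assert float((vip.vip ** 2).mean()) == pytest.approx(1.0, abs=1e-8)

    def test_separating_feature_attains_max_vip(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, size=(11, 12)) + 10
        values[0] = [0.0] * 6 + [20.0] * 6  # perfect separator
        m = toy_matrix(
            values, ["tolerant"] * 12, [25] * 6 + [35] * 6, list(range(1, 7)) * 2
        )
        _, vip = fit_plsda(m, ["A"] * 6 + ["B"] * 6, n_components=1)
        assert vip.vip.idxmax() == "f0"

    def test_exchangeable_noise_vips_near_one(self):
        m = two_group_matrix(p=40, n_per=10, effect=0.0, seed=9)
        _, vip = fit_plsda(m, ["A"] * 10 + ["B"] * 10, n_components=1)
        assert float((vip.vip ** 2).mean()) == pytest.approx(1.0, abs=1e-10)
        assert vip.vip.max() < 3.0

    def test_small_class_rejected(self):
        m = two_group_matrix(p=5, n_per=3, seed=0)
        with pytest.raises(ValueError):
            fit_plsda(m, ["A"] * 5 + ["B"], n_components=1)

    def test_zero_variance_feature_excluded_with_warning(self):
        values = np.abs(np.random.default_rng(0).normal(5, 1, size=(4, 6)))
        values[2] = 1.0
        m = toy_matrix(
            values, ["tolerant"] * 6, [25] * 3 + [35] * 3, [1, 2, 3, 1, 2, 3]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            _, vip = fit_plsda(m, ["A"] * 3 + ["B"] * 3, n_components=1)
        assert vip.excluded_features == ["f2"]
        assert "f2" not in vip.vip.index


class TestValidation:
    def test_perfect_separation_attains_minimum_p(self):
        m = two_group_matrix(p=10, n_per=7, effect=8.0, seed=2)
        labels = ["A"] * 7 + ["B"] * 7
        model, _ = fit_plsda(m, labels, n_components=1)
        q2, p_r2y, p_q2 = validate_model(model, m, labels, n_permutations=49, seed=0)
        assert p_r2y == pytest.approx(1.0 / 50.0)
        assert q2 > 0.5

    def test_planted_effect_beats_null_quantile(self):
        """A clear two-class effect yields Q2 above the permutation-null
        spread in nearly every seed."""
        wins = 0
        for seed in range(10):
            m = two_group_matrix(p=15, n_per=9, effect=3.0, n_signal=5, seed=seed)
            labels = ["A"] * 9 + ["B"] * 9
            model, _ = fit_plsda(m, labels, n_components=1)
            _, _, p_q2 = validate_model(model, m, labels, n_permutations=49, seed=seed)
            wins += p_q2 <= 0.05
        assert wins >= 9

    def test_permutation_count_validated(self):
        m = two_group_matrix(seed=0)
        labels = ["A"] * 7 + ["B"] * 7
        model, _ = fit_plsda(m, labels, n_components=1)
        with pytest.raises(ValueError):
            validate_model(model, m, labels, n_permutations=0, seed=0)


# ------------------------------------------------------------------ univariate


class TestUnivariate:
    def test_matches_pooled_variance_closed_form(self):
        """(3,4,5) vs (6,7,8): t and p equal the hand pooled-variance formula."""
        values = np.array([[3.0, 4.0, 5.0, 6.0, 7.0, 8.0]])
        m = toy_matrix(
            values, ["tolerant"] * 6, [25] * 3 + [35] * 3, [1, 2, 3, 1, 2, 3]
        )
        res = univariate_tests(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        # pooled sd = 1, se = sqrt(2/3), t = 3 / se
        t_expected = 3.0 / np.sqrt(2.0 / 3.0)
        p_expected = 2 * stats.t.sf(t_expected, df=4)
        assert res.loc["f0", "t"] == pytest.approx(t_expected, abs=1e-12)
        assert res.loc["f0", "p_value"] == pytest.approx(p_expected, abs=1e-12)

    def test_identical_groups_give_t0_p1(self):
        values = np.tile(np.array([[2.0, 3.0, 4.0]]), (1, 2))
        m = toy_matrix(
            values, ["tolerant"] * 6, [25] * 3 + [35] * 3, [1, 2, 3, 1, 2, 3]
        )
        res = univariate_tests(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert res.loc["f0", "t"] == 0.0
        assert res.loc["f0", "p_value"] == 1.0

    def test_doubled_mean_gives_unit_log2fc(self):
        values = np.array([[1.0, 2.0, 3.0, 2.0, 4.0, 6.0]])
        m = toy_matrix(
            values, ["tolerant"] * 6, [25] * 3 + [35] * 3, [1, 2, 3, 1, 2, 3]
        )
        res = univariate_tests(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert res.loc["f0", "log2_fold_change"] == pytest.approx(1.0)

    def test_small_groups_rejected(self):
        m = two_group_matrix(p=4, n_per=3)
        with pytest.raises(ValueError):
            univariate_tests(m, ["s0"], ["s3", "s4", "s5"])


# ------------------------------------------------------------------- DAM rule


class TestDamRule:
    def test_toy_table_exact_selection(self):
        """Of six (vip, p) rows only (1.2, 0.01) and (1.01, 0.049) satisfy the
        strict VIP > 1 and p < 0.05 rule."""
        from thermomark.differential import VIPResult

        vip_vals = np.array([1.2, 0.9, 1.5, 1.01, 1.0, 2.0])
        # rescale to satisfy the normalization identity without changing order
        scale = np.sqrt((vip_vals ** 2).mean())
        vip = VIPResult(
            vip=pd.Series(vip_vals / scale, index=[f"f{i}" for i in range(6)]),
            n_components=1,
            r2y=0.9,
        )
        # undo the scale via thresholds: equivalent strict comparisons
        tests = pd.DataFrame(
            {
                "t": np.ones(6),
                "p_value": [0.01, 0.01, 0.2, 0.049, 0.01, 0.06],
                "log2_fold_change": [1.0, -1.0, 0.5, -0.2, 0.3, 0.1],
            },
            index=[f"f{i}" for i in range(6)],
        )
        res = select_dams(vip, tests, vip_threshold=1.0 / scale, p_threshold=0.05)
        assert res.selected_ids == ["f0", "f3"]
        assert res.n_up == 1 and res.n_down == 1

    def test_empty_input_empty_output(self):
        from thermomark.differential import VIPResult

        vip = VIPResult(vip=pd.Series(dtype=float), n_components=1, r2y=0.0)
        tests = pd.DataFrame(columns=["t", "p_value", "log2_fold_change"])
        res = select_dams(vip, tests)
        assert res.selected_ids == []

    def test_rule_membership_exhaustive(self):
        """Every selected feature satisfies the strict rule and every
        non-selected one violates it."""
        rng = np.random.default_rng(4)
        n = 50
        vip_vals = rng.uniform(0.5, 2.0, n)
        scale = np.sqrt((vip_vals ** 2).mean())
        from thermomark.differential import VIPResult

        vip = VIPResult(
            vip=pd.Series(vip_vals / scale, index=[f"f{i}" for i in range(n)]),
            n_components=1,
            r2y=0.5,
        )
        tests = pd.DataFrame(
            {
                "t": rng.normal(size=n),
                "p_value": rng.uniform(0, 0.2, n),
                "log2_fold_change": rng.normal(size=n),
            },
            index=[f"f{i}" for i in range(n)],
        )
        thr = 1.0 / scale
        res = select_dams(vip, tests, vip_threshold=thr)
        for fid in res.table.index:
            in_rule = (vip.vip[fid] > thr) and (tests.loc[fid, "p_value"] < 0.05)
            assert in_rule == bool(res.table.loc[fid, "selected"])


# ------------------------------------------------------------------- DEG rule


def make_counts(mu, seed=0, dispersion=0.01):
    rng = np.random.default_rng(seed)
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(float)
    n = mu.shape[1]
    return toy_matrix(
        counts,
        ["tolerant"] * n,
        [25] * (n // 2) + [35] * (n // 2),
        list(range(1, n // 2 + 1)) * 2,
        role="transcriptome",
    )


class TestDegCaller:
    def test_null_counts_calibrate_and_fdr_controls(self):
        rates, fdr_hits = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            base = 2.0 ** rng.normal(7.6, 1.0, 500)
            mu = np.tile(base[:, None], (1, 6))
            m = make_counts(mu, seed=seed, dispersion=0.05)
            res = select_degs(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
            rates.append((res.table["p_value"] < 0.05).mean())
            fdr_hits.append(len(res.selected_ids))
        assert 0.01 < np.mean(rates) < 0.12
        assert np.mean(fdr_hits) < 2

    def test_planted_twofold_genes_recovered(self):
        """Low-dispersion 2-fold genes at n=3 are recovered almost completely
        with a 1.4-fold selection threshold."""
        recalls = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            base = 2.0 ** rng.normal(7.6, 1.0, 500)
            mu = np.tile(base[:, None], (1, 6))
            mu[:25, 3:] *= 2.0
            m = make_counts(mu, seed=seed, dispersion=0.01)
            res = select_degs(
                m, ["s0", "s1", "s2"], ["s3", "s4", "s5"], lfc_threshold=0.5
            )
            sel = set(res.selected_ids)
            recalls.append(len(sel & {f"f{i}" for i in range(25)}) / 25)
        assert np.median(recalls) >= 0.9

    def test_empty_gene_list(self):
        m = toy_matrix(
            np.zeros((0, 6)), ["tolerant"] * 6, [25] * 3 + [35] * 3,
            [1, 2, 3, 1, 2, 3], role="transcriptome",
        )
        res = select_degs(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert res.selected_ids == []

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(1)
        base = 2.0 ** rng.normal(7.6, 1.0, 200)
        mu = np.tile(base[:, None], (1, 6))
        m = make_counts(mu, seed=1, dispersion=0.05)
        res = select_degs(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        tab = res.table.sort_values("p_value")
        assert (np.diff(tab["padj"].to_numpy()) >= -1e-12).all()
        assert (tab["padj"] >= tab["p_value"] - 1e-12).all()


# ----------------------------------------------------------- Venn and K-means


class TestVenn:
    def test_disjoint_and_identical_sets(self):
        disjoint = venn_overlap({"A": {1, 2}, "B": {3, 4}})
        assert disjoint == {("A",): 2, ("B",): 2}
        identical = venn_overlap({"A": {1, 2}, "B": {1, 2}})
        assert identical == {("A", "B"): 2}

    def test_three_sets_match_enumeration_oracle(self):
        sets = {"A": {1, 2, 3, 4}, "B": {3, 4, 5}, "C": {4, 5, 6, 7}}
        regions = venn_overlap(sets)
        # brute-force: count each element's membership signature
        expected = {}
        for x in {1, 2, 3, 4, 5, 6, 7}:
            key = tuple(n for n in sorted(sets) if x in sets[n])
            expected[key] = expected.get(key, 0) + 1
        assert regions == expected
        assert sum(regions.values()) == len(set().union(*sets.values()))


class TestKmeansPatterns:
    def test_recovers_well_separated_patterns(self):
        """Planted expression patterns at k = truth patterns: ARI >= 0.8."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        patterns = np.array(
            [[0, 0, 5, 5, 0, 0], [5, 0, 0, 0, 0, 5], [0, 5, 0, 0, 5, 0]]
        )
        truth, rows = [], []
        for i, pat in enumerate(patterns):
            for _ in range(30):
                rows.append(pat + rng.normal(0, 0.3, 6))
                truth.append(i)
        m = toy_matrix(
            np.array(rows) + 10.0, ["tolerant"] * 6, [25, 25, 30, 30, 35, 35],
            [1, 2, 1, 2, 1, 2],
        )
        res = kmeans_patterns(m, k=3, seed=0)
        assert adjusted_rand_score(truth, res.labels.to_numpy()) >= 0.8

    def test_k1_single_cluster_total_ss(self):
        m = two_group_matrix(p=10, n_per=4, seed=5)
        res = kmeans_patterns(m, k=1, seed=0)
        assert set(res.labels) == {1}
        X = m.values.to_numpy()
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        total_ss = ((Z - Z.mean(axis=0)) ** 2).sum()
        assert res.inertia == pytest.approx(total_ss, rel=1e-6)

    def test_duplicate_rows_cluster_together(self):
        rng = np.random.default_rng(2)
        row = rng.normal(size=6)
        values = np.vstack([row] * 5 + [row[::-1]] * 5) + 10
        m = toy_matrix(
            values, ["tolerant"] * 6, [25, 25, 30, 30, 35, 35], [1, 2, 1, 2, 1, 2]
        )
        res = kmeans_patterns(m, k=2, seed=0)
        labs = res.labels.to_numpy()
        assert len(set(labs[:5])) == 1 and len(set(labs[5:])) == 1


# ------------------------------------------------------------------------ qPCR


@pytest.mark.parametrize(
    "cts,expected",
    [
        ((20, 18, 22, 20), 1.0),  # ddCt = 0
        ((21, 18, 22, 20), 0.5),  # ddCt = 1
        ((19, 18, 22, 20), 2.0),  # ddCt = -1
        ((22, 18, 25, 18), 8.0),  # worked case: 2^-(4-7)
    ],
)
def test_ddct_hand_cases(cts, expected):
    assert ddct(*cts) == pytest.approx(expected)
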