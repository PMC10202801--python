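"""Edge screening, fold prediction, repeated CPM and stability filtering."""

import numpy as np
import pytest
from scipy import stats as sps

from npfactor.cohort import SYMPTOMS, encode_covariates
from npfactor.cpm import (
    combine_conditions,
    edge_select,
    fit_predict_fold,
    fold_split,
    repeat_cpm,
    repeat_cpm_multi,
    repetition_permutations,
    robust_masks_pruned,
    run_cpm,
    selection_frequencies,
    stability_required_count,
)


def oracle_partial_pvalues(Z, y, C, alpha):
    """Explicit residualization + t CDF, edge by edge."""
    n = len(y)
    C1 = np.column_stack([np.ones(n), C]) if C is not None and C.size else np.ones((n, 1))
    q = C1.shape[1] - 1
    H = C1 @ np.linalg.solve(C1.T @ C1, C1.T)
    ry = y - H @ y
    out_r, out_p = [], []
    for e in range(Z.shape[1]):
        rz = Z[:, e] - H @ Z[:, e]
        r = np.dot(ry, rz) / np.sqrt(np.dot(ry, ry) * np.dot(rz, rz))
        df = n - 2 - q
        t = r * np.sqrt(df / (1 - r**2))
        out_r.append(r)
        out_p.append(2 * sps.t.sf(abs(t), df))
    return np.array(out_r), np.array(out_p)


class TestEdgeSelect:
    def test_matches_brute_force_oracle(self, rng):
        Z = rng.standard_normal((40, 30))
        y = rng.standard_normal(40)
        C = rng.standard_normal((40, 3))
        stats = edge_select(Z, y, C, alpha=0.05)
        r_o, p_o = oracle_partial_pvalues(Z, y, C, 0.05)
        np.testing.assert_allclose(stats.r, r_o, atol=1e-10)
        np.testing.assert_allclose(stats.p, p_o, atol=1e-10)
        np.testing.assert_array_equal(stats.selected, p_o < 0.05)

    def test_symptom_equal_to_edge_is_perfect(self, rng):
        Z = rng.standard_normal((30, 5))
        stats = edge_select(Z, Z[:, 2].copy(), None, alpha=0.01)
        assert stats.r[2] == pytest.approx(1.0)
        assert stats.selected[2] and stats.sign[2] == 1

    def test_covariate_explained_symptom_selects_nothing_in_expectation(self, rng):
        C = rng.standard_normal((100, 2))
        y = C @ np.array([1.5, -2.0]) + 0.01 * rng.standard_normal(100)
        Z = rng.standard_normal((100, 200))
        stats = edge_select(Z, y, C, alpha=0.01)
        assert stats.selected.sum() <= 10  # E[selected] = 2 under the null

    def test_zero_variance_symptom_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance symptom"):
            edge_select(rng.standard_normal((20, 4)), np.ones(20), None)

    def test_zero_variance_edge_excluded(self, rng):
        Z = rng.standard_normal((25, 3))
        Z[:, 1] = 4.2
        stats = edge_select(Z, rng.standard_normal(25), None, alpha=0.5)
        assert not stats.selected[1] and np.isnan(stats.r[1])


class TestFitPredictFold:
    def test_single_edge_noiseless_recovery(self, rng):
        z = rng.standard_normal((20, 1))
        y = 2.0 * z[:, 0] + 1.0
        z_test = rng.standard_normal((5, 1))
        preds, degenerate = fit_predict_fold(z, y, z_test, np.array([0]), np.array([1]))
        np.testing.assert_allclose(preds, 2.0 * z_test[:, 0] + 1.0, atol=1e-10)
        assert not degenerate

    def test_opposite_edges_double_the_signal(self, rng):
        """Six-subject toy: y = z_pos - z_neg exactly, slope recovered as 1."""
        z_pos = np.array([0.1, 0.5, -0.2, 0.9, -0.6, 0.3])
        z_neg = -z_pos + 0.05 * np.arange(6)
        Z = np.column_stack([z_pos, z_neg])
        y = z_pos - z_neg
        Z_test = np.array([[0.4, -0.3], [-0.1, 0.2]])
        preds, _ = fit_predict_fold(Z, y, Z_test, np.array([0, 1]), np.array([1, -1]))
        np.testing.assert_allclose(preds, Z_test[:, 0] - Z_test[:, 1], atol=1e-10)

    def test_no_selected_edges_predicts_training_mean(self, rng):
        y = rng.standard_normal(10)
        preds, degenerate = fit_predict_fold(
            rng.standard_normal((10, 3)), y, rng.standard_normal((4, 3)),
            np.array([], dtype=int), np.array([]),
        )
        assert degenerate
        np.testing.assert_allclose(preds, np.full(4, y.mean()))

    def test_separate_feature_mode(self, rng):
        Z = rng.standard_normal((30, 2))
        y = 1.0 * Z[:, 0] - 3.0 * Z[:, 1] + 0.5
        Zt = rng.standard_normal((6, 2))
        preds, _ = fit_predict_fold(
            Z, y, Zt, np.array([0, 1]), np.array([1, -1]), feature="separate"
        )
        np.testing.assert_allclose(preds, 1.0 * Zt[:, 0] - 3.0 * Zt[:, 1] + 0.5, atol=1e-8)


class TestRunCPM:
    def test_matches_reference_cpm_loop(self, small_cohort):
        """Leave-pair-out (k = n/2) vs an independently coded CPM loop."""
        _, cohort, _ = small_cohort
        sub = cohort.phenotypes[cohort.phenotypes["wave"] == 1].head(20)
        Z_full = cohort.connectomes[(1, "cond_a")].loc[sub["subject_id"]].to_numpy()
        y_full = sub["ADHD"].to_numpy(float)
        C_full = encode_covariates(sub, ("site", "handedness"))

        res = run_cpm(
            _subset_cohort(cohort, sub["subject_id"]), "ADHD", "cond_a",
            k=10, alpha=0.2, seed=77,
        )

        # reference: same fold labels, everything else recoded from scratch
        labels = fold_split(20, 10, np.random.default_rng(77))
        np.testing.assert_array_equal(labels, res.fold_assignments)
        preds = np.empty(20)
        for f in range(10):
            te, tr = labels == f, labels != f
            r_o, p_o = oracle_partial_pvalues(Z_full[tr], y_full[tr], C_full[tr], 0.2)
            sel = np.flatnonzero(p_o < 0.2)
            if sel.size == 0:
                preds[te] = y_full[tr].mean()
                continue
            s_tr = Z_full[tr][:, sel] @ np.sign(r_o[sel])
            s_te = Z_full[te][:, sel] @ np.sign(r_o[sel])
            b, a = np.polyfit(s_tr, y_full[tr], 1)
            preds[te] = a + b * s_te
        np.testing.assert_allclose(res.predictions, preds, atol=1e-8)
        assert res.spearman_rho == pytest.approx(
            sps.spearmanr(preds, y_full).statistic
        )

    def test_null_cohort_rho_centred_at_zero(self, null_cohort):
        _, cohort, _ = null_cohort
        rhos = [
            run_cpm(cohort, "ADHD", "cond_a", k=10, seed=s).spearman_rho
            for s in range(60)
        ]
        assert abs(np.mean(rhos)) < 0.05

    def test_planted_cohort_rho_beats_label_permutation(self):
        from npfactor.synthetic import SimConfig, generate_cohort

        cfg = SimConfig(n_subjects=200, n_nodes=15, conditions=("cond_a",),
                        n_pp=10, n_nn=5, n_pn=5, n_np=3, beta=0.5, seed=19)
        cohort, _ = generate_cohort(cfg)
        obs = run_cpm(cohort, "ADHD", "cond_a", k=25, seed=1).spearman_rho
        null = []
        rng = np.random.default_rng(8)
        for b in range(29):
            shuffled = cohort.phenotypes.copy()
            w1 = shuffled["wave"] == 1
            cols = [c for c in shuffled.columns if c not in ("subject_id", "wave")]
            block = shuffled.loc[w1, cols].to_numpy()
            shuffled.loc[w1, cols] = block[rng.permutation(w1.sum())]
            from npfactor.cohort import CohortTable
            sc = CohortTable(shuffled, cohort.connectomes, cohort.n_nodes)
            null.append(run_cpm(sc, "ADHD", "cond_a", k=25, seed=1).spearman_rho)
        p = (1 + sum(r >= obs for r in null)) / (1 + len(null))
        assert p < 0.05

    def test_small_n_reduces_k_with_warning(self, small_cohort):
        _, cohort, _ = small_cohort
        sub_ids = cohort.pheno_wave(1)["subject_id"].head(30)
        res = run_cpm(_subset_cohort(cohort, sub_ids), "ADHD", "cond_a", k=50, seed=0)
        assert res.settings["k"] == 15

    def test_site_stratified_folds_balance_sites(self, small_cohort):
        from npfactor.cpm import stratified_fold_split

        _, cohort, _ = small_cohort
        site = cohort.pheno_wave(1)["site"].to_numpy()
        labels = stratified_fold_split(site, 5, np.random.default_rng(0))
        for s in np.unique(site):
            per_fold = np.bincount(labels[site == s], minlength=5)
            assert per_fold.max() - per_fold.min() <= 1

    def test_fold_assignment_depends_only_on_seed_n_k(self):
        a = fold_split(100, 10, np.random.default_rng(3))
        b = fold_split(100, 10, np.random.default_rng(3))
        c = fold_split(100, 10, np.random.default_rng(4))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


def _subset_cohort(cohort, subject_ids):
    from npfactor.cohort import CohortTable

    keep = cohort.phenotypes["subject_id"].isin(set(subject_ids))
    return CohortTable(
        phenotypes=cohort.phenotypes[keep].reset_index(drop=True),
        connectomes={
            key: mat[mat.index.isin(set(subject_ids))]
            for key, mat in cohort.connectomes.items()
        },
        n_nodes=cohort.n_nodes,
    )


class TestRepeatCPM:
    def test_fast_engine_equals_run_cpm_reference(self, small_cohort):
        _, cohort, _ = small_cohort
        fast = repeat_cpm_multi(cohort, SYMPTOMS, "cond_a", n_rep=6, seed=5)
        slow = repeat_cpm_multi(
            cohort, SYMPTOMS, "cond_a", n_rep=6, seed=5, compute_rho=True
        )
        for s in SYMPTOMS:
            np.testing.assert_array_equal(fast[s].edge_ids, slow[s].edge_ids)
            np.testing.assert_allclose(fast[s].freq_pos, slow[s].freq_pos)
            np.testing.assert_allclose(fast[s].freq_neg, slow[s].freq_neg)
            assert slow[s].mean_rho is not None

    def test_loop_engine_matches_batched_engine(self, small_cohort):
        """n % k == 0 runs both engines on the same permutations."""
        _, cohort, _ = small_cohort
        from npfactor.cpm import _selection_counts_batched, _selection_counts_loop
        from npfactor.cpm import analysis_arrays

        Z, Y, C, _ = analysis_arrays(cohort, "cond_a", 1, ("site", "handedness"), SYMPTOMS)
        perms = repetition_permutations(Z.shape[0], 4, 13)
        a = _selection_counts_batched(Z, Y, C, 50, 0.01, perms)
        b = _selection_counts_loop(Z, Y, C, 50, 0.01, perms)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_single_repetition_equals_that_repetitions_union(self, small_cohort):
        _, cohort, _ = small_cohort
        sel = repeat_cpm(cohort, "ADHD", "cond_a", n_rep=1, stability=0.5, seed=41)
        child = np.random.SeedSequence(41).spawn(1)[0]
        res = run_cpm(cohort, "ADHD", "cond_a", seed=child)
        expected = np.flatnonzero(res.selected_pos | res.selected_neg)
        np.testing.assert_array_equal(sel.edge_ids, expected)

    def test_stability_above_one_gives_empty_set(self, small_cohort):
        _, cohort, _ = small_cohort
        sel = repeat_cpm(cohort, "ADHD", "cond_a", n_rep=3, stability=1.01, seed=2)
        assert sel.edge_ids.size == 0

    def test_robust_set_shrinks_with_stability_and_alpha(self, small_cohort):
        _, cohort, _ = small_cohort
        loose = repeat_cpm(cohort, "ADHD", "cond_a", n_rep=10, stability=0.5,
                           alpha=0.05, seed=3)
        tight_stab = repeat_cpm(cohort, "ADHD", "cond_a", n_rep=10, stability=0.9,
                                alpha=0.05, seed=3)
        tight_alpha = repeat_cpm(cohort, "ADHD", "cond_a", n_rep=10, stability=0.5,
                                 alpha=0.01, seed=3)
        assert set(tight_stab.edge_ids) <= set(loose.edge_ids)
        assert set(tight_alpha.edge_ids) <= set(loose.edge_ids)
        # frequencies themselves are monotone in alpha
        assert np.all(tight_alpha.freq_pos <= loose.freq_pos + 1e-12)

    def test_pruned_stability_filter_matches_full_frequencies(self, small_cohort):
        _, cohort, _ = small_cohort
        from npfactor.cpm import analysis_arrays

        Z, Y, C, _ = analysis_arrays(cohort, "cond_a", 1, ("site", "handedness"), SYMPTOMS)
        n = Z.shape[0]
        for stability, n_rep in ((0.95, 20), (0.7, 10)):
            blocks = [repetition_permutations(n, n_rep, s) for s in (1, 2)]
            rp, rn = robust_masks_pruned(Z, Y, C, 50, 0.01, n_rep, stability, blocks)
            for i, s in enumerate((1, 2)):
                fp, fn = selection_frequencies(Z, Y, C, 50, 0.01, n_rep, s)
                np.testing.assert_array_equal(rp[i], fp > stability)
                np.testing.assert_array_equal(rn[i], fn > stability)

    def test_required_count_threshold(self):
        assert stability_required_count(20, 0.95) == 20
        assert stability_required_count(200, 0.95) == 191
        assert stability_required_count(10, 1.01) == 11  # unattainable


class TestCombineConditions:
    def test_perfect_predictor_gives_adj_r2_one(self, rng):
        y = rng.standard_normal(50)
        assert combine_conditions({"c1": y.copy()}, y).adj_r2 == pytest.approx(1.0)

    def test_noise_predictors_average_to_zero(self, rng):
        vals = []
        for _ in range(200):
            y = rng.standard_normal(500)
            preds = {f"c{i}": rng.standard_normal(500) for i in range(8)}
            vals.append(combine_conditions(preds, y).adj_r2)
        assert np.mean(vals) == pytest.approx(0.0, abs=0.01)

    def test_duplicate_columns_match_deduplicated_model(self, rng):
        y = rng.standard_normal(80)
        x = rng.standard_normal(80)
        other = rng.standard_normal(80)
        dup = combine_conditions({"a": x, "b": x.copy(), "c": other}, y)
        dedup = combine_conditions({"a": x, "c": other}, y)
        assert "b" in dup.dropped
        assert dup.adj_r2 == pytest.approx(dedup.adj_r2, abs=1e-12)

    def test_adjusted_r2_formula(self, rng):
        y = rng.standard_normal(100)
        preds = {"c1": y + rng.standard_normal(100), "c2": rng.standard_normal(100)}
        out = combine_conditions(preds, y)
        assert out.adj_r2 == pytest.approx(
            1 - (1 - out.r2) * (out.n - 1) / (out.n - out.n_predictors - 1)
        )
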