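"""Cross-disorder edges, enrichment nulls, NP score, persistence filter."""

import numpy as np
import pandas as pd
import pytest

from npfactor.cohort import CohortTable, EXTERNALIZING, SYMPTOMS
from npfactor.cpm import EdgeSelection
from npfactor.crossdisorder import (
    PermutationResult,
    _shuffled_cohort,
    count_statistics_from_masks,
    crossdisorder_pipeline,
    crossdisorder_robust,
    domain_composite,
    find_crossdisorder_edges,
    longitudinal_consistency,
    np_score,
    permutation_enrichment,
    stratified_from_masks,
    stratify_edges,
)
from npfactor.stats import partial_corr
from npfactor.synthetic import SimConfig, generate_cohort


def make_selection(symptom, edge_ids, signs, n_edges=50):
    edge_ids = np.asarray(edge_ids, dtype=int)
    signs = np.asarray(signs, dtype=int)
    fp = np.zeros(n_edges)
    fn = np.zeros(n_edges)
    fp[edge_ids[signs > 0]] = 1.0
    fn[edge_ids[signs < 0]] = 1.0
    return EdgeSelection(
        symptom=symptom, condition="c", edge_ids=edge_ids, signs=signs,
        frequencies=np.ones(len(edge_ids)), freq_pos=fp, freq_neg=fn,
        n_rep=1, stability=0.95,
    )


class TestFindAndStratify:
    def test_disjoint_robust_sets_give_empty_intersection(self):
        sels = {
            "ADHD": make_selection("ADHD", [1, 2], [1, 1]),
            "GAD": make_selection("GAD", [10, 11], [1, -1]),
        }
        assert find_crossdisorder_edges(sels, "c").edge_ids.size == 0

    def test_identical_robust_sets_intersect_fully(self):
        sels = {
            "CD": make_selection("CD", [3, 7, 9], [1, 1, -1]),
            "DEP": make_selection("DEP", [3, 7, 9], [1, -1, -1]),
        }
        np.testing.assert_array_equal(
            find_crossdisorder_edges(sels, "c").edge_ids, [3, 7, 9]
        )

    def test_matches_set_intersection_oracle(self, rng):
        sels = {}
        for sym in ("ADHD", "CD", "GAD"):
            ids = np.sort(rng.choice(50, size=12, replace=False))
            sels[sym] = make_selection(sym, ids, rng.choice([1, -1], size=12))
        cross = find_crossdisorder_edges(sels, "c")
        expected = sorted(
            (set(sels["ADHD"].edge_ids) | set(sels["CD"].edge_ids))
            & set(sels["GAD"].edge_ids)
        )
        np.testing.assert_array_equal(cross.edge_ids, expected)

    def test_sign_groups(self):
        sels = {
            "CD": make_selection("CD", [0, 1, 2, 3], [1, -1, 1, -1]),
            "GAD": make_selection("GAD", [0, 1, 2, 3], [1, -1, -1, 1]),
        }
        strat = stratify_edges(find_crossdisorder_edges(sels, "c"), sels)
        groups = strat.edges.set_index("edge_id")["group"]
        assert groups[0] == "PP" and groups[1] == "NN"
        assert groups[2] == "PN" and groups[3] == "NP"

    def test_within_domain_conflict_excluded(self):
        sels = {
            "CD": make_selection("CD", [5], [1]),
            "ODD": make_selection("ODD", [5], [-1]),
            "GAD": make_selection("GAD", [5], [1]),
        }
        strat = stratify_edges(find_crossdisorder_edges(sels, "c"), sels)
        assert len(strat.edges) == 0
        assert strat.n_conflict == 1
        assert strat.n_cross == 1

    def test_mask_shortcut_equals_object_path(self, rng):
        rp = rng.random((8, 60)) < 0.15
        rn = (rng.random((8, 60)) < 0.15) & ~rp
        sels = {
            sym: make_selection(
                sym,
                np.flatnonzero(rp[i] | rn[i]),
                np.where(rp[i], 1, -1)[rp[i] | rn[i]],
                n_edges=60,
            )
            for i, sym in enumerate(SYMPTOMS)
        }
        via_objects = stratify_edges(find_crossdisorder_edges(sels, "c"), sels)
        via_masks = stratified_from_masks("c", rp, rn)
        pd.testing.assert_frame_equal(via_objects.edges, via_masks.edges)
        assert via_objects.n_conflict == via_masks.n_conflict
        counts = count_statistics_from_masks(rp, rn)
        assert counts["cross"] == via_masks.n_cross
        got = via_masks.group_counts()
        for g in ("PP", "NN", "PN", "NP"):
            assert counts[g] == got[g]

    def test_group_counts_partition_the_cross_set(self, rng):
        rp = rng.random((8, 80)) < 0.2
        rn = (rng.random((8, 80)) < 0.2) & ~rp
        c = count_statistics_from_masks(rp, rn)
        assert c["PP"] + c["NN"] + c["PN"] + c["NP"] + c["conflict"] == c["cross"]


class TestPermutationResult:
    def test_observed_zero_gives_p_one(self):
        res = PermutationResult("cross", 0, np.array([0, 0, 3, 1]))
        assert res.p_perm == 1.0

    def test_add_one_rule_floor(self):
        res = PermutationResult("cross", 99, np.zeros(1000))
        assert res.p_perm == pytest.approx(1 / 1001)

    def test_p_monotone_in_observed(self):
        null = np.array([0, 1, 1, 2, 5])
        ps = [PermutationResult("c", o, null).p_perm for o in range(6)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestPermutationEnrichment:
    def test_refuses_too_few_permutations(self, small_cohort):
        _, cohort, _ = small_cohort
        with pytest.raises(ValueError, match="B < 20"):
            permutation_enrichment(cohort, "cond_a", B=5, inner_n_rep=2)

    def test_matches_object_level_shuffled_pipeline(self, small_cohort):
        """Array-level null equals rebuilding a shuffled cohort per permutation."""
        _, cohort, _ = small_cohort
        res = permutation_enrichment(
            cohort, "cond_a", B=20, inner_n_rep=4, seed=23
        )
        ss = np.random.SeedSequence(23)
        obs_seed, perm_seed, inner_seed = ss.spawn(3)
        strat, _ = crossdisorder_pipeline(cohort, "cond_a", n_rep=4, seed=obs_seed)
        assert res["cross"].observed == strat.n_cross

        rng = np.random.default_rng(perm_seed)
        children = inner_seed.spawn(20)
        for b in range(3):
            perm = rng.permutation(150)
            shuffled = _shuffled_cohort(cohort, 1, perm)
            strat_b, _ = crossdisorder_pipeline(
                shuffled, "cond_a", n_rep=4, seed=children[b]
            )
            assert res["cross"].null[b] == strat_b.n_cross

    def test_planted_condition_is_enriched(self):
        cfg = SimConfig(n_subjects=150, n_nodes=15, conditions=("cond_a",),
                        n_pp=6, n_nn=3, n_pn=4, n_np=2, beta=0.4, seed=13)
        cohort, _ = generate_cohort(cfg)
        res = permutation_enrichment(cohort, "cond_a", B=99, inner_n_rep=20, seed=3)
        assert res["cross"].observed > 0
        assert res["cross"].p_perm < 0.05

    def test_robust_fast_path_equals_pipeline(self, small_cohort):
        _, cohort, _ = small_cohort
        a, _ = crossdisorder_pipeline(cohort, "cond_b", n_rep=15, seed=31)
        b = crossdisorder_robust(cohort, "cond_b", n_rep=15, seed=31)
        pd.testing.assert_frame_equal(a.edges, b.edges)
        assert a.n_conflict == b.n_conflict


class TestNPScore:
    def _toy_cohort(self):
        subjects = ["s1", "s2", "s3"]
        pheno = pd.DataFrame(
            {
                "subject_id": subjects,
                "wave": 1,
                "site": 0,
                "sex": [0, 1, 0],
                "handedness": 1,
                **{s: [1.0, 2.0, 3.0] for s in SYMPTOMS},
            }
        )
        z_a = pd.DataFrame(
            [[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9]], index=subjects
        )
        z_b = pd.DataFrame(
            [[1.0, -1.0, 0.5], [0.0, 2.0, -0.5], [0.3, 0.3, 0.3]], index=subjects
        )
        return CohortTable(pheno, {(1, "a"): z_a, (1, "b"): z_b}, n_nodes=3)

    def test_hand_summed_toy(self):
        cohort = self._toy_cohort()
        scores = np_score(cohort, {"a": np.array([0, 2]), "b": np.array([1, 2])})
        # s1: (0.1 + 0.3) + (-1.0 + 0.5) = -0.1; s2: 1.0 + 1.5; s3: 1.6 + 0.6
        np.testing.assert_allclose(
            scores.loc[["s1", "s2", "s3"]], [-0.1, 2.5, 2.2], atol=1e-12
        )

    def test_empty_edge_set_scores_zero(self):
        cohort = self._toy_cohort()
        scores = np_score(cohort, {"a": np.array([], dtype=int)})
        assert (scores == 0).all()

    def test_linearity_and_edge_order_invariance(self):
        cohort = self._toy_cohort()
        base = np_score(cohort, {"a": np.array([0, 1, 2])})
        reordered = np_score(cohort, {"a": np.array([2, 0, 1])})
        pd.testing.assert_series_equal(base, reordered)
        scaled_conn = {k: 3.0 * v for k, v in cohort.connectomes.items()}
        scaled = CohortTable(cohort.phenotypes, scaled_conn, 3)
        np.testing.assert_allclose(
            np_score(scaled, {"a": np.array([0, 1, 2])}), 3.0 * base, atol=1e-12
        )

    def test_missing_condition_raises(self):
        cohort = self._toy_cohort()
        with pytest.raises(KeyError):
            np_score(cohort, {"zzz": np.array([0])})


class TestLongitudinalConsistency:
    def test_planted_cohort_selects_pp_and_rejects_pn(self):
        cfg = SimConfig(n_subjects=300, n_nodes=15, conditions=("c1", "c2"),
                        n_pp=12, n_nn=6, n_pn=8, n_np=4, beta=0.4, seed=47)
        cohort, truth = generate_cohort(cfg)
        groups = {
            g: {
                w: np_score(
                    cohort,
                    {c: truth.group_edges(g) for c in ("c1", "c2")},
                    wave=w,
                )
                for w in (1, 2)
            }
            for g in ("PP", "NN", "PN", "NP")
        }
        report = longitudinal_consistency(cohort, groups, n_perm=300, seed=5)
        assert report.passing == ["PP"]
        pn = {t.name: t for t in report.per_group["PN"]}
        assert pn["w2_int"].r < 0  # dissensus group fails wave-2 positivity

    def test_no_persistence_passes_nothing(self):
        cfg = SimConfig(
            n_subjects=150, n_nodes=15, conditions=("c1",), n_pp=6, n_nn=3,
            n_pn=4, n_np=2, rho_persist=0.0, decline_coupling=0.0, seed=29,
        )
        cohort, truth = generate_cohort(cfg)
        groups = {
            "PP": {w: np_score(cohort, {"c1": truth.group_edges("PP")}, wave=w)
                   for w in (1, 2)}
        }
        report = longitudinal_consistency(cohort, groups, n_perm=200, seed=6)
        assert report.passing == []
        assert report.selected_group is None

    def test_single_symptom_composite_reduces_to_partial_corr(self, small_cohort):
        _, cohort, truth = small_cohort
        groups = {
            "PP": {w: np_score(cohort, {"cond_a": truth.group_edges("PP")}, wave=w)
                   for w in (1, 2)}
        }
        report = longitudinal_consistency(
            cohort, groups, n_perm=100, seed=7,
            ext_symptoms=("ADHD",), int_symptoms=("GAD",),
        )
        tests = {t.name: t for t in report.per_group["PP"]}
        pheno2 = cohort.pheno_wave(2).set_index("subject_id")
        s2 = groups["PP"][2]
        from npfactor.cohort import encode_covariates
        ph = pheno2.loc[s2.index]
        C = encode_covariates(ph.reset_index(), ("site", "sex", "handedness"))
        direct = partial_corr(
            s2.to_numpy(), ph["ADHD"].to_numpy(), C, tail="greater"
        )
        assert tests["w2_ext"].r == pytest.approx(direct.r, abs=1e-12)
        assert tests["w2_ext"].p == pytest.approx(direct.p, abs=1e-12)

    def test_domain_composite_is_mean_of_zscores(self, small_cohort):
        _, cohort, _ = small_cohort
        pheno = cohort.pheno_wave(1)
        comp = domain_composite(pheno, EXTERNALIZING)
        manual = np.zeros(len(pheno))
        for s in EXTERNALIZING:
            x = pheno[s].to_numpy(float)
            manual += (x - x.mean()) / x.std()
        np.testing.assert_allclose(comp, manual / 4, atol=1e-12)
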