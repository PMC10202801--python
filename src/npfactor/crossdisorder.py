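"""Cross-disorder edges, enrichment nulls, NP-factor score, persistence.

A *cross-disorder* edge for a task condition is one that sits in the
robust (stability-filtered) predictive set of at least one externalizing
and at least one internalizing symptom simultaneously.  Cross-disorder
edges are stratified by their association signs into consensus groups
(PP: positive with both domains, NN: negative with both) and dissensus
groups (PN, NP: opposite signs).  Whether a condition yields more
cross-disorder edges than chance is tested by re-running the whole
selection pipeline on label-shuffled cohorts.  The NP factor is the
summed Fisher-z connectivity over the consensus edges that survive the
longitudinal-consistency filter (in the reference analysis, the
positive-positive group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    ASSOC_COVARIATES,
    CPM_COVARIATES,
    CohortTable,
    EXTERNALIZING,
    INTERNALIZING,
    SYMPTOMS,
    encode_covariates,
)
from . import cpm as cpm_mod
from .cpm import EdgeSelection, _with_intercept, _residualize, repeat_cpm_multi
from . import stats as npstats

logger = logging.getLogger(__name__)

GROUP_SIGNS = {"PP": (1, 1), "NN": (-1, -1), "PN": (1, -1), "NP": (-1, 1)}


# ---------------------------------------------------------------------------
# containers


@dataclass
class CrossDisorderSet:
    """Cross-disorder edges of one condition, optionally sign-stratified."""

    condition: str
    edges: pd.DataFrame  # edge_id [, ext_sign, int_sign, group]
    n_conflict: int = 0

    @property
    def edge_ids(self) -> np.ndarray:
        return self.edges["edge_id"].to_numpy()

    @property
    def n_cross(self) -> int:
        return len(self.edges) + self.n_conflict

    def group_counts(self) -> dict[str, int]:
        if "group" not in self.edges.columns:
            raise ValueError("edge set is not stratified yet")
        counts = self.edges["group"].value_counts().to_dict()
        return {g: int(counts.get(g, 0)) for g in GROUP_SIGNS}

    def group_edges(self, group: str) -> np.ndarray:
        return self.edges.loc[self.edges["group"] == group, "edge_id"].to_numpy()


@dataclass
class PermutationResult:
    """Add-one permutation p-value for a count statistic."""

    statistic: str
    observed: float
    null: np.ndarray
    p_perm: float = field(init=False)

    def __post_init__(self) -> None:
        B = len(self.null)
        self.p_perm = (1.0 + np.sum(self.null >= self.observed)) / (1.0 + B)


# ---------------------------------------------------------------------------
# cross-disorder identification and stratification


def find_crossdisorder_edges(
    selections: dict[str, EdgeSelection], condition: str
) -> CrossDisorderSet:
    """Edges robust for >=1 externalizing AND >=1 internalizing symptom."""
    ext_sel = [s for name, s in selections.items() if name in EXTERNALIZING]
    int_sel = [s for name, s in selections.items() if name in INTERNALIZING]
    if not ext_sel or not int_sel:
        raise ValueError(
            "need robust selections for at least one externalizing and one "
            "internalizing symptom"
        )
    ext_ids = set(np.concatenate([s.edge_ids for s in ext_sel]))
    int_ids = set(np.concatenate([s.edge_ids for s in int_sel]))
    cross = np.array(sorted(ext_ids & int_ids), dtype=int)
    return CrossDisorderSet(
        condition=condition, edges=pd.DataFrame({"edge_id": cross})
    )


def stratify_edges(
    cross_set: CrossDisorderSet, selections: dict[str, EdgeSelection]
) -> CrossDisorderSet:
    """Assign each cross-disorder edge to PP / NN / PN / NP by its signs.

    The domain sign of an edge is the sign shared by every robust
    selection of that domain containing it; edges whose sign conflicts
    within a domain are excluded (and counted in ``n_conflict``).
    """
    records = []
    n_conflict = 0
    for edge in cross_set.edge_ids:
        signs: dict[str, set[int]] = {"ext": set(), "int": set()}
        for name, sel in selections.items():
            pos = np.searchsorted(sel.edge_ids, edge)
            if pos < len(sel.edge_ids) and sel.edge_ids[pos] == edge:
                domain = "ext" if name in EXTERNALIZING else "int"
                signs[domain].add(int(sel.signs[pos]))
        if len(signs["ext"]) != 1 or len(signs["int"]) != 1:
            n_conflict += 1
            logger.info("edge %d has conflicting signs within a domain; excluded", edge)
            continue
        es, is_ = signs["ext"].pop(), signs["int"].pop()
        group = {v: k for k, v in GROUP_SIGNS.items()}[(es, is_)]
        records.append(
            {"edge_id": int(edge), "ext_sign": es, "int_sign": is_, "group": group}
        )
    edges = pd.DataFrame(records, columns=["edge_id", "ext_sign", "int_sign", "group"])
    return CrossDisorderSet(
        condition=cross_set.condition, edges=edges, n_conflict=n_conflict
    )


def crossdisorder_pipeline(
    cohort: CohortTable,
    condition: str,
    wave: int = 1,
    n_rep: int = 100,
    k: int = 50,
    alpha: float = 0.01,
    stability: float = 0.95,
    seed: int | np.random.SeedSequence = 0,
    covariate_cols: tuple[str, ...] = CPM_COVARIATES,
    symptoms: tuple[str, ...] = SYMPTOMS,
) -> tuple[CrossDisorderSet, dict[str, EdgeSelection]]:
    """repeat_cpm for all symptoms -> cross-disorder set, stratified."""
    selections = repeat_cpm_multi(
        cohort,
        symptoms,
        condition,
        wave=wave,
        n_rep=n_rep,
        k=k,
        alpha=alpha,
        stability=stability,
        seed=seed,
        covariate_cols=covariate_cols,
    )
    cross = find_crossdisorder_edges(selections, condition)
    return stratify_edges(cross, selections), selections


# ---------------------------------------------------------------------------
# permutation enrichment


def _shuffled_cohort(
    cohort: CohortTable, wave: int, perm: np.ndarray
) -> CohortTable:
    """Cohort with the wave's phenotype rows re-assigned to connectomes.

    The whole phenotype row (symptoms and covariates) moves together,
    preserving the phenotype-covariate structure under the null.
    """
    pheno = cohort.phenotypes.copy()
    idx = pheno.index[pheno["wave"] == wave]
    cols = [c for c in pheno.columns if c not in ("subject_id", "wave")]
    block = pheno.loc[idx, cols].to_numpy()
    pheno.loc[idx, cols] = block[perm]
    return CohortTable(
        phenotypes=pheno, connectomes=cohort.connectomes, n_nodes=cohort.n_nodes
    )


def stratified_from_masks(
    condition: str,
    robust_pos: np.ndarray,
    robust_neg: np.ndarray,
    symptoms: tuple[str, ...] = SYMPTOMS,
) -> CrossDisorderSet:
    """Stratified cross-disorder set from robust signed masks ``(S, E)``.

    Produces the same result as :func:`find_crossdisorder_edges` followed
    by :func:`stratify_edges` on the edge selections the masks encode.
    """
    ext_idx = [i for i, s in enumerate(symptoms) if s in EXTERNALIZING]
    int_idx = [i for i, s in enumerate(symptoms) if s in INTERNALIZING]
    robust = robust_pos | robust_neg
    cross = robust[ext_idx].any(axis=0) & robust[int_idx].any(axis=0)
    extp = robust_pos[ext_idx].any(axis=0)
    extn = robust_neg[ext_idx].any(axis=0)
    intp = robust_pos[int_idx].any(axis=0)
    intn = robust_neg[int_idx].any(axis=0)
    conflict = cross & ((extp & extn) | (intp & intn))
    records = []
    for edge in np.flatnonzero(cross & ~conflict):
        es = 1 if extp[edge] else -1
        is_ = 1 if intp[edge] else -1
        group = {v: g for g, v in GROUP_SIGNS.items()}[(es, is_)]
        records.append(
            {"edge_id": int(edge), "ext_sign": es, "int_sign": is_, "group": group}
        )
    edges = pd.DataFrame(records, columns=["edge_id", "ext_sign", "int_sign", "group"])
    return CrossDisorderSet(
        condition=condition, edges=edges, n_conflict=int(conflict.sum())
    )


def crossdisorder_robust(
    cohort: CohortTable,
    condition: str,
    wave: int = 1,
    n_rep: int = 100,
    k: int = 50,
    alpha: float = 0.01,
    stability: float = 0.95,
    seed: int | np.random.SeedSequence = 0,
    covariate_cols: tuple[str, ...] = CPM_COVARIATES,
    symptoms: tuple[str, ...] = SYMPTOMS,
) -> CrossDisorderSet:
    """Stratified cross-disorder set via the pruned stability filter.

    Identical output to :func:`crossdisorder_pipeline` with the same
    seed, but skips the full selection-frequency bookkeeping: only edges
    that can still clear the stability threshold are tracked past the
    first repetitions.
    """
    Z, Y, C, pheno = cpm_mod.analysis_arrays(
        cohort, condition, wave, covariate_cols, symptoms
    )
    n = len(pheno)
    k_eff = cpm_mod._effective_k(n, k)
    block = cpm_mod.repetition_permutations(n, n_rep, seed)
    rp, rn = cpm_mod.robust_masks_pruned(
        Z, Y, C, k_eff, alpha, n_rep, stability, [block]
    )
    return stratified_from_masks(condition, rp[0], rn[0], symptoms)


def count_statistics_from_frequencies(
    freq_pos: np.ndarray,
    freq_neg: np.ndarray,
    stability: float,
    symptoms: tuple[str, ...] = SYMPTOMS,
) -> dict[str, np.ndarray]:
    """Cross-disorder and sign-group counts from selection frequencies.

    ``freq_pos``/``freq_neg`` have shape ``(..., S, E)``; leading axes
    (e.g. permutations) are preserved.  Equivalent to running
    :func:`find_crossdisorder_edges` and :func:`stratify_edges` on the
    robust sets implied by the frequencies; ``cross`` counts all
    cross-disorder edges (conflicted ones included), the group keys the
    non-conflicting members.
    """
    rp = freq_pos > stability
    rn = freq_neg > stability
    return count_statistics_from_masks(rp, rn, symptoms)


def count_statistics_from_masks(
    rp: np.ndarray, rn: np.ndarray, symptoms: tuple[str, ...] = SYMPTOMS
) -> dict[str, np.ndarray]:
    """Cross-disorder and sign-group counts from robust signed masks."""
    ext_idx = [i for i, s in enumerate(symptoms) if s in EXTERNALIZING]
    int_idx = [i for i, s in enumerate(symptoms) if s in INTERNALIZING]
    robust = rp | rn
    ext_any = robust[..., ext_idx, :].any(axis=-2)
    int_any = robust[..., int_idx, :].any(axis=-2)
    cross = ext_any & int_any
    extp = rp[..., ext_idx, :].any(axis=-2)
    extn = rn[..., ext_idx, :].any(axis=-2)
    intp = rp[..., int_idx, :].any(axis=-2)
    intn = rn[..., int_idx, :].any(axis=-2)
    conflict = cross & ((extp & extn) | (intp & intn))
    ok = cross & ~conflict
    return {
        "cross": cross.sum(axis=-1),
        "PP": (ok & extp & intp).sum(axis=-1),
        "NN": (ok & extn & intn).sum(axis=-1),
        "PN": (ok & extp & intn).sum(axis=-1),
        "NP": (ok & extn & intp).sum(axis=-1),
        "conflict": conflict.sum(axis=-1),
    }


def permutation_enrichment(
    cohort: CohortTable,
    condition: str,
    wave: int = 1,
    B: int = 1000,
    inner_n_rep: int = 100,
    k: int = 50,
    alpha: float = 0.01,
    stability: float = 0.95,
    seed: int = 0,
    covariate_cols: tuple[str, ...] = CPM_COVARIATES,
    per_group: bool = True,
    symptoms: tuple[str, ...] = SYMPTOMS,
) -> dict[str, PermutationResult]:
    """Permutation null for the cross-disorder edge counts of a condition.

    Each permutation re-assigns whole phenotype rows (symptoms and
    covariates together, preserving their mutual structure) to the
    connectomes and re-runs the full selection chain -- repeated CPM with
    stability filtering, cross-disorder intersection, stratification --
    at ``inner_n_rep`` repetitions.  Returns add-one permutation p-values
    for the total cross-disorder count (key ``"cross"``) and, when
    ``per_group``, each sign group.  The condition counts as *reliable*
    when ``cross``'s p is below 0.05.

    The observed and permuted chains run through one batched selection
    pass; results are identical to calling
    :func:`crossdisorder_pipeline` on each shuffled cohort with the
    matching per-permutation seed.
    """
    if B < 20:
        raise ValueError("B < 20 gives too coarse a p-value resolution")
    ss = np.random.SeedSequence(seed)
    obs_seed, perm_seed, inner_seed = ss.spawn(3)

    Z, Y, C, pheno = cpm_mod.analysis_arrays(
        cohort, condition, wave, covariate_cols, symptoms
    )
    n = len(pheno)
    k_eff = cpm_mod._effective_k(n, k)

    rng = np.random.default_rng(perm_seed)
    label_maps = [np.arange(n)] + [rng.permutation(n) for _ in range(B)]
    inner_children = inner_seed.spawn(B)
    fold_blocks = [cpm_mod.repetition_permutations(n, inner_n_rep, obs_seed)]
    fold_blocks += [
        cpm_mod.repetition_permutations(n, inner_n_rep, child)
        for child in inner_children
    ]
    rp, rn = cpm_mod.robust_masks_pruned(
        Z, Y, C, k_eff, alpha, inner_n_rep, stability, fold_blocks, label_maps
    )
    stats_all = count_statistics_from_masks(rp, rn, symptoms)

    keys = ["cross"] + (list(GROUP_SIGNS) if per_group else [])
    return {
        key: PermutationResult(
            statistic=key,
            observed=int(stats_all[key][0]),
            null=stats_all[key][1:],
        )
        for key in keys
    }


def is_reliable(results: dict[str, PermutationResult], level: float = 0.05) -> bool:
    return results["cross"].p_perm < level


# ---------------------------------------------------------------------------
# NP factor score


def np_score(
    cohort: CohortTable,
    consensus_edges: dict[str, np.ndarray],
    wave: int = 1,
) -> pd.Series:
    """Summed Fisher-z FC over the consensus (condition, edge) set.

    ``consensus_edges`` maps each condition to its edge ids; the score of
    a subject is the plain sum of the corresponding z values over all
    conditions (linear in the connectome, invariant to edge order).
    Wave-2 scores reuse the wave-1-derived edge set -- the set is
    applied, never refit.  Subjects missing any required condition are
    excluded with a log message.
    """
    frames = []
    for cond, edges in consensus_edges.items():
        key = (wave, cond)
        if key not in cohort.connectomes:
            raise KeyError(f"no connectome for wave={wave}, condition={cond!r}")
        mat = cohort.connectomes[key]
        edges = np.asarray(edges, dtype=int)
        frames.append(mat.iloc[:, edges].sum(axis=1) if len(edges) else
                      pd.Series(0.0, index=mat.index))
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    dropped = set().union(*(set(f.index) for f in frames)) - set(common)
    if dropped:
        logger.warning(
            "%d subject(s) miss a condition at wave %d and get no score",
            len(dropped), wave,
        )
    total = sum(f.loc[common] for f in frames)
    total.name = "np_score"
    return total


# ---------------------------------------------------------------------------
# longitudinal consistency


def domain_composite(pheno: pd.DataFrame, domain: tuple[str, ...]) -> pd.Series:
    """Mean of within-domain z-scored symptom totals (complete rows)."""
    block = pheno[list(domain)].astype(float)
    z = (block - block.mean()) / block.std(ddof=0)
    return z.mean(axis=1)


def _partial_r_perm_p(
    score: np.ndarray,
    comp: np.ndarray,
    C: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """One-tailed (positive) permutation p for a partial correlation."""
    n = len(score)
    C1 = _with_intercept(C, n)
    rs = _residualize(score[:, None], C1)[:, 0]
    rc = _residualize(comp[:, None], C1)[:, 0]
    rs = rs / np.sqrt(rs @ rs)
    rc = rc / np.sqrt(rc @ rc)
    r_obs = float(rs @ rc)
    perm_idx = np.stack([rng.permutation(n) for _ in range(n_perm)])
    null = rs[perm_idx] @ rc
    p = (1.0 + np.sum(null >= r_obs)) / (1.0 + n_perm)
    return r_obs, float(p)


@dataclass
class ConsistencyTest:
    name: str
    r: float
    p: float
    method: str  # "permutation" or "parametric"


@dataclass
class ConsistencyReport:
    per_group: dict[str, list[ConsistencyTest]]
    passing: list[str]

    @property
    def selected_group(self) -> str | None:
        return self.passing[0] if self.passing else None


def longitudinal_consistency(
    cohort: CohortTable,
    group_scores: dict[str, dict[int, pd.Series]],
    covariate_cols: tuple[str, ...] = ASSOC_COVARIATES,
    n_perm: int = 1000,
    level: float = 0.05,
    seed: int = 0,
    ext_symptoms: tuple[str, ...] = EXTERNALIZING,
    int_symptoms: tuple[str, ...] = INTERNALIZING,
) -> ConsistencyReport:
    """Persistence filter over candidate edge groups.

    For every candidate group with per-wave scores, partial correlations
    (controlling site, sex, handedness) of the score with the
    externalizing and internalizing composites are computed at wave 1
    (one-tailed permutation p, since the edge sets were trained on these
    data) and wave 2 (parametric one-tailed p), plus the prospective
    wave-1-score -> wave-2-symptom associations with and without
    adjustment for the baseline composite.  A group passes when the four
    same-wave tests are all positive and significant at ``level``; the
    passing group(s) define the NP factor.  An empty ``passing`` list is
    reported as such -- there is no fallback.
    """
    rng = np.random.default_rng(seed)
    report: dict[str, list[ConsistencyTest]] = {}
    passing = []
    waves = cohort.waves
    if len(waves) < 2:
        raise ValueError("longitudinal consistency needs at least two waves")
    w1, w2 = waves[0], waves[1]

    pheno1 = cohort.pheno_wave(w1).set_index("subject_id")
    pheno2 = cohort.pheno_wave(w2).set_index("subject_id")

    for group, scores in group_scores.items():
        tests: list[ConsistencyTest] = []
        gate: list[bool] = []

        for domain_name, domain in (("ext", ext_symptoms), ("int", int_symptoms)):
            # wave 1, permutation p (edge sets were trained at wave 1)
            s1 = scores[w1].dropna()
            ph = pheno1.loc[s1.index].dropna(subset=list(domain) + list(covariate_cols))
            s = s1.loc[ph.index].to_numpy()
            comp = domain_composite(ph, domain).to_numpy()
            C = encode_covariates(ph.reset_index(), covariate_cols)
            r, p = _partial_r_perm_p(s, comp, C, n_perm, rng)
            tests.append(ConsistencyTest(f"w{w1}_{domain_name}", r, p, "permutation"))
            gate.append(r > 0 and p < level)

            # wave 2, parametric one-tailed
            s2 = scores[w2].dropna()
            ph = pheno2.loc[s2.index].dropna(subset=list(domain) + list(covariate_cols))
            s = s2.loc[ph.index].to_numpy()
            comp = domain_composite(ph, domain).to_numpy()
            C = encode_covariates(ph.reset_index(), covariate_cols)
            res = npstats.partial_corr(s, comp, C, tail="greater")
            tests.append(ConsistencyTest(f"w{w2}_{domain_name}", res.r, res.p, "parametric"))
            gate.append(res.r > 0 and res.p < level)

            # prospective: wave-1 score -> wave-2 symptoms
            both = scores[w1].index.intersection(pheno2.index)
            ph = pheno2.loc[both].dropna(subset=list(domain) + list(covariate_cols))
            ph1 = pheno1.loc[ph.index]
            s = scores[w1].loc[ph.index].to_numpy()
            comp = domain_composite(ph, domain).to_numpy()
            C = encode_covariates(ph.reset_index(), covariate_cols)
            res = npstats.partial_corr(s, comp, C, tail="greater")
            tests.append(
                ConsistencyTest(f"w{w1}to{w2}_{domain_name}", res.r, res.p, "parametric")
            )
            baseline = domain_composite(ph1, domain).to_numpy()
            C_adj = np.column_stack([C, baseline]) if C.size else baseline[:, None]
            res_adj = npstats.partial_corr(s, comp, C_adj, tail="greater")
            tests.append(
                ConsistencyTest(
                    f"w{w1}to{w2}_{domain_name}_baseline_adj", res_adj.r, res_adj.p,
                    "parametric",
                )
            )

        report[group] = tests
        if all(gate):
            passing.append(group)

    return ConsistencyReport(per_group=report, passing=passing)


def scores_by_group(
    cohort: CohortTable,
    stratified: dict[str, CrossDisorderSet],
    groups: tuple[str, ...] = ("PP", "NN", "PN", "NP"),
) -> dict[str, dict[int, pd.Series]]:
    """Per-group, per-wave NP-style summed scores over all conditions."""
    out: dict[str, dict[int, pd.Series]] = {}
    for group in groups:
        edges = {
            cond: cds.group_edges(group) for cond, cds in stratified.items()
        }
        if sum(len(e) for e in edges.values()) == 0:
            continue
        out[group] = {w: np_score(cohort, edges, wave=w) for w in cohort.waves}
    return out


def consensus_union(
    stratified: dict[str, CrossDisorderSet], group: str = "PP"
) -> dict[str, np.ndarray]:
    """Per-condition consensus edge ids for the chosen group."""
    return {cond: cds.group_edges(group) for cond, cds in stratified.items()}
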