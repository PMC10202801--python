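"""Connectome-based predictive modelling (CPM) with stability selection.

The CPM procedure: partition subjects into ``k`` folds; within each
training set, correlate every edge with the symptom controlling for
covariates (partial Pearson correlation) and keep edges with two-sided
``p < alpha``; collapse the kept edges into a single network-strength
feature (sum of positive-edge z minus sum of negative-edge z); regress
the symptom on that feature and predict the held-out fold; score the
pooled out-of-fold predictions against the observed symptom with
Spearman correlation.  Repeating the whole procedure over fresh fold
splits yields per-edge selection frequencies; edges selected with a
consistent sign in more than a stability threshold of repetitions form
the robust set.

Two implementations of the per-fold edge screen coexist: a plain
residualize-and-correlate path (:func:`edge_select`, used by
:func:`run_cpm`) and a batched sufficient-statistics path used by
:func:`repeat_cpm` and the permutation machinery, which computes all
folds and repetitions of a split from cross-product downdates.  The two
are algebraically identical and tested for agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortTable, CPM_COVARIATES

logger = logging.getLogger(__name__)

_VAR_TINY = 1e-12


# ---------------------------------------------------------------------------
# result containers


@dataclass
class EdgeStats:
    """Per-edge partial correlation screen on one training set."""

    r: np.ndarray
    p: np.ndarray
    sign: np.ndarray  # +1 / -1 / 0
    selected: np.ndarray  # bool
    df: int


@dataclass
class CPMResult:
    """One repetition of k-fold CPM for a (symptom, condition) pair."""

    symptom: str
    condition: str
    subject_ids: np.ndarray
    predictions: np.ndarray  # pooled out-of-fold predictions
    observed: np.ndarray
    spearman_rho: float
    selected_pos: np.ndarray  # bool (E,): selected positively in >=1 fold, never negatively
    selected_neg: np.ndarray
    fold_assignments: np.ndarray
    n_degenerate_folds: int
    settings: dict = field(default_factory=dict)


@dataclass
class EdgeSelection:
    """Stability-filtered robust edge set for a (symptom, condition)."""

    symptom: str
    condition: str
    edge_ids: np.ndarray  # robust edges
    signs: np.ndarray  # +1 / -1 per robust edge
    frequencies: np.ndarray  # same-sign selection frequency per robust edge
    freq_pos: np.ndarray  # full per-edge frequency vectors
    freq_neg: np.ndarray
    n_rep: int
    stability: float
    mean_rho: float | None = None

    def __post_init__(self) -> None:
        order = np.argsort(self.edge_ids)
        self.edge_ids = np.asarray(self.edge_ids)[order]
        self.signs = np.asarray(self.signs)[order]
        self.frequencies = np.asarray(self.frequencies)[order]

    @property
    def mask(self) -> np.ndarray:
        out = np.zeros(len(self.freq_pos), dtype=bool)
        out[self.edge_ids] = True
        return out

    def signed_mask(self) -> np.ndarray:
        out = np.zeros(len(self.freq_pos), dtype=int)
        out[self.edge_ids] = self.signs
        return out


# ---------------------------------------------------------------------------
# edge screening


def _with_intercept(C: np.ndarray | None, n: int) -> np.ndarray:
    if C is None or C.size == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), C])


def _residualize(M: np.ndarray, C1: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(C1, M, rcond=None)
    return M - C1 @ beta


def r_significance_threshold(alpha: float, df: int) -> float:
    """|r| above which the two-sided partial-correlation p falls below alpha."""
    t_crit = sps.t.isf(alpha / 2.0, df)
    return t_crit / np.sqrt(df + t_crit**2)


def edge_select(
    train_z: np.ndarray,
    train_y: np.ndarray,
    train_covariates: np.ndarray | None = None,
    alpha: float = 0.01,
) -> EdgeStats:
    """Partial-correlation screen of every edge against the symptom.

    Both the edges and the symptom are residualized on the covariates
    (plus intercept); the Pearson correlation of the residuals is tested
    with ``t = r * sqrt(df / (1 - r^2))``, ``df = n - 2 - q`` where ``q``
    counts the covariate columns (intercept excluded).  Edges with
    ``p < alpha`` are selected with ``sign(r)``.
    """
    Z = np.asarray(train_z, dtype=float)
    y = np.asarray(train_y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 training subjects")
    C1 = _with_intercept(train_covariates, n)
    q = C1.shape[1] - 1
    df = n - 2 - q
    if df < 1:
        raise ValueError("not enough subjects for the covariate count")

    ry = _residualize(y[:, None], C1)[:, 0]
    sy = np.sqrt(ry @ ry)
    if sy <= np.sqrt(_VAR_TINY):
        raise ValueError("zero-variance symptom after covariate adjustment")
    RZ = _residualize(Z, C1)
    sz = np.sqrt(np.einsum("ne,ne->e", RZ, RZ))
    dead = sz <= np.sqrt(_VAR_TINY)
    if np.any(dead):
        logger.warning("%d zero-variance edge(s) excluded from selection", dead.sum())
    sz_safe = np.where(dead, 1.0, sz)
    r = (ry @ RZ) / (sy * sz_safe)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, _VAR_TINY))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    selected = (p < alpha) & ~dead
    sign = np.where(selected, np.sign(r).astype(int), 0)
    r[dead] = np.nan
    p[dead] = 1.0
    return EdgeStats(r=r, p=p, sign=sign, selected=selected, df=df)


def fit_predict_fold(
    train_z: np.ndarray,
    train_y: np.ndarray,
    test_z: np.ndarray,
    edge_ids: np.ndarray,
    signs: np.ndarray,
    feature: str = "combined",
) -> tuple[np.ndarray, bool]:
    """Network-strength regression on the training fold, applied to test.

    ``feature="combined"`` (default) uses the single summed feature
    ``s = sum(pos-edge z) - sum(neg-edge z)``; ``feature="separate"``
    fits the classic two-feature variant with separate positive and
    negative sums.  Returns ``(predictions, degenerate)``; a fold with
    no selected edges (or a constant feature) predicts the training mean.
    """
    edge_ids = np.asarray(edge_ids, dtype=int)
    signs = np.asarray(signs, dtype=float)
    y = np.asarray(train_y, dtype=float)
    if edge_ids.size == 0:
        logger.warning("degenerate fold: no edge selected; predicting the mean")
        return np.full(len(test_z), y.mean()), True

    if feature == "combined":
        X_tr = (train_z[:, edge_ids] @ signs)[:, None]
        X_te = (test_z[:, edge_ids] @ signs)[:, None]
    elif feature == "separate":
        pos, neg = signs > 0, signs < 0
        X_tr = np.column_stack(
            [train_z[:, edge_ids[pos]].sum(axis=1), train_z[:, edge_ids[neg]].sum(axis=1)]
        )
        X_te = np.column_stack(
            [test_z[:, edge_ids[pos]].sum(axis=1), test_z[:, edge_ids[neg]].sum(axis=1)]
        )
    else:
        raise ValueError(f"unknown feature mode {feature!r}")

    keep = X_tr.std(axis=0) > np.sqrt(_VAR_TINY)
    if not np.any(keep):
        logger.warning("degenerate fold: constant network strength")
        return np.full(len(test_z), y.mean()), True
    A = np.column_stack([np.ones(len(y)), X_tr[:, keep]])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    preds = np.column_stack([np.ones(len(X_te)), X_te[:, keep]]) @ coef
    return preds, False


# ---------------------------------------------------------------------------
# one CPM repetition


def fold_split(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold label per subject: a seeded permutation cut into k chunks."""
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for f, idx in enumerate(np.array_split(perm, k)):
        labels[idx] = f
    return labels


def stratified_fold_split(
    site: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold labels balancing site composition across folds.

    Members of each site are shuffled and dealt round-robin over the
    folds (starting at a random offset per site), so every fold carries
    a near-proportional share of each site.
    """
    site = np.asarray(site)
    labels = np.empty(len(site), dtype=int)
    for s in np.unique(site):
        members = rng.permutation(np.flatnonzero(site == s))
        offset = int(rng.integers(k))
        labels[members] = (np.arange(len(members)) + offset) % k
    return labels


def _effective_k(n: int, k: int) -> int:
    if n < 2 * k:
        new_k = max(n // 2, 2)
        logger.warning("n=%d too small for k=%d folds; reducing to k=%d", n, k, new_k)
        return new_k
    return k


def run_cpm(
    cohort: CohortTable,
    symptom: str,
    condition: str,
    wave: int = 1,
    k: int = 50,
    alpha: float = 0.01,
    seed: int | np.random.SeedSequence = 0,
    covariate_cols: tuple[str, ...] = CPM_COVARIATES,
    feature: str = "combined",
    stratify_by_site: bool = False,
) -> CPMResult:
    """One repetition of seeded k-fold CPM."""
    Z, y, C, pheno = cohort.analysis_sample(symptom, condition, wave, covariate_cols)
    n = len(y)
    k = _effective_k(n, k)
    rng = np.random.default_rng(seed)
    if stratify_by_site:
        labels = stratified_fold_split(pheno["site"].to_numpy(), k, rng)
    else:
        labels = fold_split(n, k, rng)

    preds = np.empty(n)
    pos_any = np.zeros(Z.shape[1], dtype=bool)
    neg_any = np.zeros(Z.shape[1], dtype=bool)
    n_degenerate = 0
    for f in range(k):
        test = labels == f
        train = ~test
        stats = edge_select(Z[train], y[train], C[train], alpha=alpha)
        edge_ids = np.flatnonzero(stats.selected)
        signs = stats.sign[edge_ids]
        pos_any |= stats.sign > 0
        neg_any |= stats.sign < 0
        preds[test], degenerate = fit_predict_fold(
            Z[train], y[train], Z[test], edge_ids, signs, feature=feature
        )
        n_degenerate += int(degenerate)

    if np.std(preds) <= np.sqrt(_VAR_TINY):
        logger.warning("pooled predictions are constant; recording rho = 0")
        rho = 0.0
    else:
        rho = float(sps.spearmanr(preds, y).statistic)

    return CPMResult(
        symptom=symptom,
        condition=condition,
        subject_ids=pheno["subject_id"].to_numpy(),
        predictions=preds,
        observed=y,
        spearman_rho=rho,
        selected_pos=pos_any & ~neg_any,
        selected_neg=neg_any & ~pos_any,
        fold_assignments=labels,
        n_degenerate_folds=n_degenerate,
        settings={
            "k": k,
            "alpha": alpha,
            "wave": wave,
            "covariates": tuple(covariate_cols),
            "feature": feature,
        },
    )


# ---------------------------------------------------------------------------
# batched selection counts (sufficient statistics over folds/repetitions)


def _solve_batch(G: np.ndarray, B: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(G, B)
    except np.linalg.LinAlgError:  # singular training design in some fold
        out = np.empty_like(B)
        for i in range(G.shape[0]):
            out[i] = np.linalg.pinv(G[i]) @ B[i]
        return out


def _selection_counts_batched(
    Z: np.ndarray,
    Y: np.ndarray,
    C: np.ndarray | None,
    k: int,
    alpha: float,
    perms: np.ndarray,
    label_maps: np.ndarray | None = None,
    n_groups: int = 1,
    max_chunk_bytes: int = 200_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed per-repetition selection counts, all folds batched.

    Requires ``n`` divisible by ``k`` (equal folds).  For every
    repetition's permutation, training-set cross-products are obtained by
    downdating the full-sample cross-products with each fold's block, and
    the partial correlation of every (symptom, edge) pair is thresholded
    from them -- algebraically identical to :func:`edge_select` on each
    training set (selection iff ``Syz^2 > r_crit^2 Syy Szz``, which is
    ``|r_partial| > r_crit``, i.e. ``p < alpha``).

    ``n_groups`` partitions the repetitions into consecutive equal
    blocks whose counts are returned separately (shape
    ``(n_groups, S, E)``; squeezed to ``(S, E)`` when 1).
    ``label_maps`` (shape ``(n_groups, n)``) optionally re-assigns the
    phenotype block of each group -- symptoms and covariates move
    together -- relative to the connectomes, which is how the
    permutation-enrichment null re-labels subjects: connectome row ``j``
    is paired with phenotype row ``label_maps[g, j]``.
    """
    n, E = Z.shape
    S = Y.shape[1]
    if n % k:
        raise ValueError("batched path requires n divisible by k")
    m = n // k
    C1 = _with_intercept(C, n)
    q1 = C1.shape[1]
    df = (n - m) - 2 - (q1 - 1)
    r_crit = r_significance_threshold(alpha, df)

    R = perms.shape[0]
    if R % n_groups:
        raise ValueError("repetition count must divide evenly into groups")
    group_size = R // n_groups
    gids = np.arange(R) // group_size

    # pairing-independent totals
    G = C1.T @ C1
    CY = C1.T @ Y
    zz = np.einsum("ne,ne->e", Z, Z)
    yy = np.einsum("ns,ns->s", Y, Y)
    # pairing-dependent totals, one per group
    if label_maps is None:
        CZg = np.broadcast_to(C1.T @ Z, (n_groups, q1, E))
        YZg = np.broadcast_to(Y.T @ Z, (n_groups, S, E))
    else:
        CZg = np.stack([C1[label_maps[g]].T @ Z for g in range(n_groups)])
        YZg = np.stack([Y[label_maps[g]].T @ Z for g in range(n_groups)])

    counts_pos = np.zeros((n_groups, S, E), dtype=np.int64)
    counts_neg = np.zeros((n_groups, S, E), dtype=np.int64)

    bytes_per_rep = k * (m * (E + S + q1) + 4 * S * E + 2 * q1 * E) * 8
    chunk = max(1, min(R, max_chunk_bytes // max(1, bytes_per_rep)))
    for c0 in range(0, R, chunk):
        P = perms[c0 : c0 + chunk]
        g_chunk = gids[c0 : c0 + P.shape[0]]
        if label_maps is None:
            L = P
        else:
            L = np.take_along_axis(
                label_maps[g_chunk], P, axis=1
            )
        r_reps = P.shape[0]
        b = r_reps * k
        Zp = Z[P.reshape(-1)].reshape(b, m, E)
        Cp = C1[L.reshape(-1)].reshape(b, m, q1)
        Yp = Y[L.reshape(-1)].reshape(b, m, S)

        CpT = Cp.transpose(0, 2, 1)
        Gt = G - CpT @ Cp
        CZt = (CZg[g_chunk, None] - (CpT @ Zp).reshape(r_reps, k, q1, E)).reshape(b, q1, E)
        CYt = CY - CpT @ Yp
        YZt = (
            YZg[g_chunk, None]
            - (Yp.transpose(0, 2, 1) @ Zp).reshape(r_reps, k, S, E)
        ).reshape(b, S, E)
        zzt = zz - np.einsum("bme,bme->be", Zp, Zp)
        yyt = yy - np.einsum("bms,bms->bs", Yp, Yp)

        sol = _solve_batch(Gt, np.concatenate([CZt, CYt], axis=2))
        Bz, By = sol[:, :, :E], sol[:, :, E:]
        Szz = zzt - np.einsum("bqe,bqe->be", CZt, Bz)
        Syy = yyt - np.einsum("bqs,bqs->bs", CYt, By)
        Syz = YZt - CYt.transpose(0, 2, 1) @ Bz  # (b, S, E)

        # zero-variance guards: a degenerate edge/symptom has Syz ~ 0 and
        # a clipped (positive) threshold, so it can never be selected
        thresh = r_crit * np.sqrt(
            np.maximum(Syy, _VAR_TINY)[:, :, None]
            * np.maximum(Szz, _VAR_TINY)[:, None, :]
        )
        pos = (Syz > thresh).reshape(r_reps, k, S, E).any(axis=1)
        np.negative(thresh, out=thresh)
        neg = (Syz < thresh).reshape(r_reps, k, S, E).any(axis=1)
        rep_pos = pos & ~neg
        rep_neg = neg & ~pos
        for g in np.unique(g_chunk):
            sel_g = g_chunk == g
            counts_pos[g] += rep_pos[sel_g].sum(axis=0)
            counts_neg[g] += rep_neg[sel_g].sum(axis=0)
    if n_groups == 1:
        return counts_pos[0], counts_neg[0]
    return counts_pos, counts_neg


def _selection_counts_loop(
    Z: np.ndarray,
    Y: np.ndarray,
    C: np.ndarray | None,
    k: int,
    alpha: float,
    perms: np.ndarray,
    label_maps: np.ndarray | None = None,
    n_groups: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Fold-by-fold fallback for unequal fold sizes (n not divisible by k)."""
    n, E = Z.shape
    S = Y.shape[1]
    C1 = _with_intercept(C, n)
    q = C1.shape[1] - 1
    R = perms.shape[0]
    if R % n_groups:
        raise ValueError("repetition count must divide evenly into groups")
    group_size = R // n_groups
    if label_maps is None:
        label_maps = np.broadcast_to(np.arange(n), (n_groups, n))
    counts_pos = np.zeros((n_groups, S, E), dtype=np.int64)
    counts_neg = np.zeros((n_groups, S, E), dtype=np.int64)
    slots = np.array_split(np.arange(n), k)
    for u, perm in enumerate(perms):
        lab = label_maps[u // group_size][perm]
        pos = np.zeros((S, E), dtype=bool)
        neg = np.zeros((S, E), dtype=bool)
        for f in range(k):
            train_slots = np.concatenate([slots[g] for g in range(k) if g != f])
            # connectome rows and phenotype rows stay paired per slot
            Zt = Z[perm[train_slots]]
            Ct = C1[lab[train_slots]]
            Yt = Y[lab[train_slots]]
            df = len(train_slots) - 2 - q
            r_crit = r_significance_threshold(alpha, df)
            ry = _residualize(Yt, Ct)
            rz = _residualize(Zt, Ct)
            sy = np.sqrt(np.einsum("ns,ns->s", ry, ry))
            sz = np.sqrt(np.einsum("ne,ne->e", rz, rz))
            ok = (sy[:, None] > np.sqrt(_VAR_TINY)) & (sz[None, :] > np.sqrt(_VAR_TINY))
            denom = np.where(ok, sy[:, None] * sz[None, :], 1.0)
            r_part = np.where(ok, (ry.T @ rz) / denom, 0.0)
            pos |= r_part > r_crit
            neg |= r_part < -r_crit
        counts_pos[u // group_size] += pos & ~neg
        counts_neg[u // group_size] += neg & ~pos
    if n_groups == 1:
        return counts_pos[0], counts_neg[0]
    return counts_pos, counts_neg


def _selection_counts(
    Z: np.ndarray,
    Y: np.ndarray,
    C: np.ndarray | None,
    k: int,
    alpha: float,
    perms: np.ndarray,
    label_maps: np.ndarray | None = None,
    n_groups: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch between the batched and the fold-loop counting engines."""
    if Z.shape[0] % k == 0:
        return _selection_counts_batched(
            Z, Y, C, k, alpha, perms, label_maps=label_maps, n_groups=n_groups
        )
    return _selection_counts_loop(
        Z, Y, C, k, alpha, perms, label_maps=label_maps, n_groups=n_groups
    )


def stability_required_count(n_rep: int, stability: float) -> int:
    """Smallest same-sign selection count whose frequency exceeds stability."""
    counts = np.arange(n_rep + 1)
    above = counts / n_rep > stability
    return int(counts[above][0]) if above.any() else n_rep + 1


def robust_masks_pruned(
    Z: np.ndarray,
    Y: np.ndarray,
    C: np.ndarray | None,
    k: int,
    alpha: float,
    n_rep: int,
    stability: float,
    fold_blocks: list[np.ndarray],
    label_maps: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Robust (stability-filtered) signed masks for many pipeline runs.

    ``fold_blocks[i]`` holds run ``i``'s ``n_rep`` fold permutations and
    ``label_maps[i]`` its phenotype relabelling (identity for the
    observed run).  Exploits that an edge whose same-sign frequency must
    exceed ``stability`` can miss selection in at most
    ``n_rep - required`` repetitions: after the first ``allowed + 1``
    repetitions (phase A, batched over all runs at full edge count),
    only still-viable edges are carried into the remaining repetitions
    (phase B, per run on the pruned edge subset).  The result is
    identical to thresholding the full selection frequencies.

    Returns boolean arrays ``(robust_pos, robust_neg)`` of shape
    ``(n_runs, S, E)``.
    """
    n, E = Z.shape
    S = Y.shape[1]
    n_runs = len(fold_blocks)
    if label_maps is None:
        label_maps = [np.arange(n)] * n_runs
    label_maps = np.asarray(label_maps)
    required = stability_required_count(n_rep, stability)
    robust_pos = np.zeros((n_runs, S, E), dtype=bool)
    robust_neg = np.zeros((n_runs, S, E), dtype=bool)
    if required > n_rep:
        return robust_pos, robust_neg
    allowed = n_rep - required
    A = min(allowed + 1, n_rep)

    perms_A = np.concatenate([blk[:A] for blk in fold_blocks], axis=0)
    cpA, cnA = _selection_counts(
        Z, Y, C, k, alpha, perms_A, label_maps=label_maps, n_groups=n_runs
    )
    if n_runs == 1:
        cpA, cnA = cpA[None], cnA[None]

    remaining = n_rep - A
    if remaining == 0:
        robust_pos[:] = cpA >= required
        robust_neg[:] = cnA >= required
        return robust_pos, robust_neg

    viable = ((cpA + remaining) >= required) | ((cnA + remaining) >= required)
    for i in range(n_runs):
        esub = np.flatnonzero(viable[i].any(axis=0))
        if esub.size == 0:
            continue
        blk = fold_blocks[i][A:]
        cpB, cnB = _selection_counts(
            Z[:, esub], Y, C, k, alpha, blk, label_maps=label_maps[i][None]
        )
        robust_pos[i][:, esub] = cpA[i][:, esub] + cpB >= required
        robust_neg[i][:, esub] = cnA[i][:, esub] + cnB >= required
    return robust_pos, robust_neg


def repetition_permutations(
    n: int, n_rep: int, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Per-repetition subject permutations (fold splits), seeded."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_rep)
    return np.stack(
        [np.random.default_rng(c).permutation(n) for c in children]
    )


def selection_frequencies(
    Z: np.ndarray,
    Y: np.ndarray,
    C: np.ndarray | None,
    k: int,
    alpha: float,
    n_rep: int,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(symptom, edge) signed selection frequencies over repetitions."""
    n = Z.shape[0]
    k = _effective_k(n, k)
    perms = repetition_permutations(n, n_rep, seed)
    if n % k == 0:
        cp, cn = _selection_counts_batched(Z, Y, C, k, alpha, perms)
    else:
        cp, cn = _selection_counts_loop(Z, Y, C, k, alpha, perms)
    return cp / n_rep, cn / n_rep


# ---------------------------------------------------------------------------
# repeated CPM with stability filtering


def _selection_from_freqs(
    symptom: str,
    condition: str,
    freq_pos: np.ndarray,
    freq_neg: np.ndarray,
    n_rep: int,
    stability: float,
    mean_rho: float | None,
) -> EdgeSelection:
    robust_pos = freq_pos > stability
    robust_neg = freq_neg > stability
    edge_ids = np.flatnonzero(robust_pos | robust_neg)
    signs = np.where(robust_pos[edge_ids], 1, -1)
    freqs = np.where(robust_pos[edge_ids], freq_pos[edge_ids], freq_neg[edge_ids])
    return EdgeSelection(
        symptom=symptom,
        condition=condition,
        edge_ids=edge_ids,
        signs=signs,
        frequencies=freqs,
        freq_pos=freq_pos,
        freq_neg=freq_neg,
        n_rep=n_rep,
        stability=stability,
        mean_rho=mean_rho,
    )


def analysis_arrays(
    cohort: CohortTable,
    condition: str,
    wave: int,
    covariate_cols: tuple[str, ...],
    symptoms: tuple[str, ...],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Complete-case ``(Z, Y, C, pheno)`` across a whole symptom block."""
    Z, _, C, pheno = cohort.analysis_sample(None, condition, wave, covariate_cols)
    complete = pheno.dropna(subset=list(symptoms))
    if len(complete) < len(pheno):
        keep = pheno.index.isin(complete.index)
        Z, C, pheno = Z[keep], C[keep], complete.reset_index(drop=True)
    Y = pheno[list(symptoms)].to_numpy(dtype=float)
    return Z, Y, C, pheno


def repeat_cpm_multi(
    cohort: CohortTable,
    symptoms: tuple[str, ...],
    condition: str,
    wave: int = 1,
    n_rep: int = 1000,
    k: int = 50,
    alpha: float = 0.01,
    stability: float = 0.95,
    seed: int | np.random.SeedSequence = 0,
    covariate_cols: tuple[str, ...] = CPM_COVARIATES,
    compute_rho: bool = False,
) -> dict[str, EdgeSelection]:
    """Repeated CPM for several symptoms of one condition at once.

    All symptoms share the fold splits of each repetition (the split
    depends only on the seed and the sample), which lets the edge screen
    be computed for the whole symptom block in one pass.  Subjects must
    be complete cases for every requested symptom.

    An edge counts as selected in a repetition when at least one fold
    selects it and every selecting fold agrees on the sign; the robust
    set keeps edges whose same-sign frequency strictly exceeds
    ``stability``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    Z, Y, C, pheno = analysis_arrays(cohort, condition, wave, covariate_cols, symptoms)
    n = len(pheno)
    k_eff = _effective_k(n, k)

    mean_rho: dict[str, float | None] = {s: None for s in symptoms}
    if compute_rho:
        # slow reference path: full run_cpm per repetition and symptom;
        # per-repetition seeds match repetition_permutations(seed)
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        children = ss.spawn(n_rep)
        cp = {s: np.zeros(Z.shape[1], dtype=np.int64) for s in symptoms}
        cn = {s: np.zeros(Z.shape[1], dtype=np.int64) for s in symptoms}
        rhos = {s: [] for s in symptoms}
        for child in children:
            for s in symptoms:
                res = run_cpm(
                    cohort, s, condition, wave=wave, k=k, alpha=alpha,
                    seed=child, covariate_cols=covariate_cols,
                )
                cp[s] += res.selected_pos
                cn[s] += res.selected_neg
                rhos[s].append(res.spearman_rho)
        freq_pos = np.stack([cp[s] / n_rep for s in symptoms])
        freq_neg = np.stack([cn[s] / n_rep for s in symptoms])
        mean_rho = {s: float(np.mean(rhos[s])) for s in symptoms}
    else:
        freq_pos, freq_neg = selection_frequencies(
            Z, Y, C, k_eff, alpha, n_rep, seed
        )

    return {
        s: _selection_from_freqs(
            s, condition, freq_pos[i], freq_neg[i], n_rep, stability, mean_rho[s]
        )
        for i, s in enumerate(symptoms)
    }


def repeat_cpm(
    cohort: CohortTable,
    symptom: str,
    condition: str,
    **kwargs,
) -> EdgeSelection:
    """Repeated CPM with stability filtering for one symptom."""
    return repeat_cpm_multi(cohort, (symptom,), condition, **kwargs)[symptom]


# ---------------------------------------------------------------------------
# combining conditions


@dataclass
class CombinedModel:
    adj_r2: float
    r2: float
    kept: list[str]
    dropped: list[str]
    n: int
    n_predictors: int


def combine_conditions(
    predictions: dict[str, np.ndarray] | pd.DataFrame,
    observed: np.ndarray,
    covariates: np.ndarray | None = None,
) -> CombinedModel:
    """Multiple regression of the symptom on per-condition predictions.

    Collinear prediction columns (including exact duplicates) are dropped
    with a warning before fitting, so the reported adjusted R-squared
    matches the deduplicated model:
    ``adj R2 = 1 - (1 - R2) (n - 1) / (n - p - 1)``.
    """
    if isinstance(predictions, dict):
        predictions = pd.DataFrame(dict(sorted(predictions.items())))
    if predictions.shape[1] < 1:
        raise ValueError("need at least one prediction vector")
    y = np.asarray(observed, dtype=float)
    n = len(y)

    cols = list(predictions.columns)
    X = predictions.to_numpy(dtype=float)
    base = [np.ones(n)]
    if covariates is not None and covariates.size:
        base.append(np.asarray(covariates, dtype=float))
    kept_idx: list[int] = []
    dropped: list[str] = []
    current = np.column_stack(base)
    rank = np.linalg.matrix_rank(current)
    for i, name in enumerate(cols):
        cand = np.column_stack([current, X[:, i]])
        cand_rank = np.linalg.matrix_rank(cand)
        if cand_rank > rank:
            kept_idx.append(i)
            current, rank = cand, cand_rank
        else:
            dropped.append(str(name))
    if dropped:
        logger.warning("dropping collinear prediction column(s): %s", dropped)

    coef, *_ = np.linalg.lstsq(current, y, rcond=None)
    resid = y - current @ coef
    ss_res = resid @ resid
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot
    p = current.shape[1] - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return CombinedModel(
        adj_r2=float(adj),
        r2=float(r2),
        kept=[str(cols[i]) for i in kept_idx],
        dropped=dropped,
        n=n,
        n_predictors=p,
    )
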