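"""Synthetic two-wave, multi-condition connectome cohorts.

The generator plants cross-disorder edge effects in a linear-Gaussian
model so that every downstream stage of the pipeline (edge selection,
stability filtering, cross-disorder stratification, longitudinal
persistence) can be exercised and verified without any real data.

Generative model
----------------
Per subject, three independent standard-normal latents: a general factor
``g``, an externalizing factor ``ext`` and an internalizing factor
``int``.  Each of the eight symptom totals loads on the general factor
and on its domain factor::

    symptom_k = lambda_g * g + lambda_dom * dom_k + sigma_sym * eps

Per condition, edge Fisher-z values are ``mu0 + effect + site + noise``
with unit noise.  Planted groups carry the effects

* PP edges: ``+beta * g``   (positively tied to both domains),
* NN edges: ``-beta * g``,
* PN edges: ``+beta * ext - beta * int``,
* NP edges: ``-beta * ext + beta * int``.

Site enters as an additive mean shift per (site, edge) and per
(site, symptom).  A retained subsample is re-observed at wave 2 with the
*signal part* of the wave-1 edges (everything except the subject-level
noise draw) carried over with factor ``rho_persist``, fresh unit noise,
and an extra decrease of PP edges proportional to the baseline symptom
composite (``decline_coupling``).  Wave-2 symptoms are re-drawn from the
same latents with fresh residual noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, EXTERNALIZING, SYMPTOMS
from .fc import (
    ConditionWeights,
    build_condition_weights,
    edge_pairs,
    n_edges,
)

DEFAULT_CONDITIONS = (
    "stop_success",
    "stop_failure",
    "reward_anticipation",
    "reward_feedback_pos",
)

GROUPS = ("PP", "NN", "PN", "NP")

#: named RNG substreams split from the master seed, in spawn order
_STREAMS = (
    "latents",
    "symptoms",
    "edges",
    "design",
    "wave2",
    "timeseries",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator."""

    n_subjects: int = 400
    n_nodes: int = 60
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_pp: int = 30
    n_nn: int = 15
    n_pn: int = 20
    n_np: int = 10
    beta: float = 0.25  # planted effect size, z units
    lambda_g: float = 0.5  # symptom loading on the general factor
    lambda_dom: float = 0.4  # symptom loading on its domain factor
    sigma_sym: float = 0.8  # residual symptom sd
    mu0: float = 0.3  # null edge mean (positive: FC is typically > 0)
    n_sites: int = 4
    site_sd: float = 0.1  # sd of additive site shifts
    retention: float = 0.7  # wave-2 retention fraction
    rho_persist: float = 0.6  # wave-2 carry-over of the wave-1 signal
    decline_coupling: float = 0.1  # extra wave-2 PP decrease per unit composite
    integer_symptoms: bool = False  # round symptoms to non-negative counts
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_nodes <= 1 or self.n_sites <= 0:
            raise ValueError("counts must be positive (n_nodes >= 2)")
        counts = (self.n_pp, self.n_nn, self.n_pn, self.n_np)
        if any(c < 0 for c in counts):
            raise ValueError("planted group sizes must be non-negative")
        if sum(counts) > n_edges(self.n_nodes):
            raise ValueError(
                f"planted groups ({sum(counts)} edges) exceed the edge budget "
                f"of {n_edges(self.n_nodes)}"
            )
        if not (0 < self.retention <= 1):
            raise ValueError("retention must lie in (0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if len(self.conditions) == 0:
            raise ValueError("need at least one condition")

    @property
    def group_sizes(self) -> dict[str, int]:
        return {"PP": self.n_pp, "NN": self.n_nn, "PN": self.n_pn, "NP": self.n_np}


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    planted: dict[str, dict[str, np.ndarray]]  # condition -> group -> edge ids
    latents: pd.DataFrame  # subject_id, g, ext, int
    effect_directions: dict[str, dict[str, tuple[int, int]]]  # group -> (ext, int) sign

    def group_edges(self, group: str) -> np.ndarray:
        """Planted edge ids of a group (identical across conditions)."""
        first = next(iter(self.planted.values()))
        return first[group]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


def _symptom_matrix(
    cfg: SimConfig, g: np.ndarray, ext: np.ndarray, intl: np.ndarray,
    site: np.ndarray, site_shift: np.ndarray, rng: np.random.Generator,
) -> pd.DataFrame:
    cols = {}
    for k, name in enumerate(SYMPTOMS):
        dom = ext if name in EXTERNALIZING else intl
        val = (
            cfg.lambda_g * g
            + cfg.lambda_dom * dom
            + cfg.sigma_sym * rng.standard_normal(len(g))
            + site_shift[site, k]
        )
        if cfg.integer_symptoms:
            val = np.clip(np.round(val * 4 + 6), 0, None)  # count-like rescaling
        cols[name] = val
    return pd.DataFrame(cols)


def generate_cohort(config: SimConfig) -> tuple[CohortTable, SyntheticTruth]:
    """Draw a two-wave cohort with planted cross-disorder edges.

    Identical seeds give bit-identical output.  Each generation stage
    draws from its own named RNG stream split deterministically from the
    master seed, so adding draws to one stage never perturbs another.
    """
    config.validate()
    cfg = config
    rngs = _streams(cfg.seed)
    n, E = cfg.n_subjects, n_edges(cfg.n_nodes)
    subjects = np.array([f"S{i:05d}" for i in range(n)])

    # latent factors
    lat = rngs["latents"].standard_normal((n, 3))
    g, ext, intl = lat[:, 0], lat[:, 1], lat[:, 2]

    # design: site, sex, handedness, planted edges, retention
    drng = rngs["design"]
    site = drng.integers(0, cfg.n_sites, size=n)
    sex = drng.integers(0, 2, size=n)
    handedness = (drng.random(n) < 0.9).astype(int)  # 1 = right-handed
    site_shift_sym = drng.normal(0.0, cfg.site_sd, size=(cfg.n_sites, len(SYMPTOMS)))
    site_shift_edge = drng.normal(0.0, cfg.site_sd, size=(cfg.n_sites, E))
    sizes = cfg.group_sizes
    total_planted = sum(sizes.values())
    chosen = drng.choice(E, size=total_planted, replace=False)
    planted_ids: dict[str, np.ndarray] = {}
    offset = 0
    for grp in GROUPS:
        planted_ids[grp] = np.sort(chosen[offset : offset + sizes[grp]])
        offset += sizes[grp]
    n_retained = int(round(cfg.retention * n))
    retained = np.sort(drng.choice(n, size=n_retained, replace=False))

    # symptoms, both waves (same latents, fresh residual noise at wave 2)
    sym1 = _symptom_matrix(cfg, g, ext, intl, site, site_shift_sym, rngs["symptoms"])
    sym2_full = _symptom_matrix(cfg, g, ext, intl, site, site_shift_sym, rngs["symptoms"])
    sym2 = sym2_full.iloc[retained].reset_index(drop=True)

    # planted edge effects (shared across conditions)
    effect = np.zeros((n, E))
    effect[:, planted_ids["PP"]] += cfg.beta * g[:, None]
    effect[:, planted_ids["NN"]] -= cfg.beta * g[:, None]
    effect[:, planted_ids["PN"]] += cfg.beta * (ext - intl)[:, None]
    effect[:, planted_ids["NP"]] += cfg.beta * (intl - ext)[:, None]

    # baseline symptom composite (mean of z-scored wave-1 totals)
    z1s = (sym1 - sym1.mean()) / sym1.std(ddof=0)
    composite = z1s.mean(axis=1).to_numpy()

    erng, wrng = rngs["edges"], rngs["wave2"]
    connectomes: dict[tuple[int, str], pd.DataFrame] = {}
    for cond in cfg.conditions:
        signal = cfg.mu0 + effect + site_shift_edge[site]
        z1 = signal + erng.standard_normal((n, E))
        connectomes[(1, cond)] = pd.DataFrame(z1, index=subjects.copy())
        z2 = cfg.rho_persist * signal[retained] + wrng.standard_normal((n_retained, E))
        z2[:, planted_ids["PP"]] -= cfg.decline_coupling * composite[retained, None]
        connectomes[(2, cond)] = pd.DataFrame(z2, index=subjects[retained].copy())

    base = pd.DataFrame(
        {
            "subject_id": subjects,
            "site": site,
            "sex": sex,
            "handedness": handedness,
        }
    )
    pheno1 = base.assign(wave=1, **{c: sym1[c] for c in SYMPTOMS})
    pheno2 = (
        base.iloc[retained]
        .reset_index(drop=True)
        .assign(wave=2, **{c: sym2[c] for c in SYMPTOMS})
    )
    phenotypes = pd.concat([pheno1, pheno2], ignore_index=True)
    phenotypes = phenotypes[
        ["subject_id", "wave", "site", "sex", "handedness", *SYMPTOMS]
    ]

    truth = SyntheticTruth(
        planted={cond: dict(planted_ids) for cond in cfg.conditions},
        latents=pd.DataFrame(
            {"subject_id": subjects, "g": g, "ext": ext, "int": intl}
        ),
        effect_directions={
            "PP": {"signs": (1, 1)},
            "NN": {"signs": (-1, -1)},
            "PN": {"signs": (1, -1)},
            "NP": {"signs": (-1, 1)},
        },
    )
    cohort = CohortTable(
        phenotypes=phenotypes, connectomes=connectomes, n_nodes=cfg.n_nodes
    )
    return cohort, truth


def expected_pp_symptom_correlation(cfg: SimConfig, externalizing: bool = True) -> float:
    """Closed-form population correlation of a PP edge with a symptom.

    With ``edge = mu0 + beta*g + noise`` and ``symptom = lambda_g*g +
    lambda_dom*dom + sigma_sym*eps`` (site shifts off), the correlation is
    ``beta*lambda_g / sqrt((1 + beta^2) * (lambda_g^2 + lambda_dom^2 +
    sigma_sym^2))`` regardless of the symptom's domain.
    """
    num = cfg.beta * cfg.lambda_g
    den = np.sqrt(
        (1.0 + cfg.beta**2)
        * (cfg.lambda_g**2 + cfg.lambda_dom**2 + cfg.sigma_sym**2)
    )
    return num / den


# ---------------------------------------------------------------------------
# ROI time-series generation (feeds the FC-estimation stage)


@dataclass
class TimeSeriesSet:
    """Synthetic ROI time series plus the tables the FC stage consumes."""

    timeseries: dict[str, np.ndarray]  # subject -> T x P
    events: pd.DataFrame  # condition, onset_s, duration_s
    nuisance: dict[str, pd.DataFrame]  # subject -> T x Q named columns
    weights: dict[str, ConditionWeights]
    true_z: dict[str, np.ndarray]  # condition -> population Fisher-z edge vector
    tr: float


def generate_timeseries(
    config: SimConfig,
    tr: float = 2.0,
    n_scans: int = 400,
    target_r: float = 0.5,
    planted_pair: tuple[int, int] = (0, 1),
    block_s: float = 20.0,
    gap_s: float = 40.0,
    n_motion: int = 6,
) -> TimeSeriesSet:
    """Block-design ROI time series with one planted node pair per condition.

    Conditions occupy non-overlapping blocks (``block_s`` seconds on,
    ``gap_s`` off, cycling over conditions).  Within scans where a
    condition's rectified weight is positive, the planted node pair
    shares a latent signal mixed so its population correlation equals
    ``target_r``.  Motion-like nuisance series (random walks) are added
    to every node and recorded in the nuisance table.
    """
    config.validate()
    if not (-1.0 < target_r < 1.0):
        raise ValueError("target correlation must lie in (-1, 1)")
    rng = _streams(config.seed)["timeseries"]
    P = config.n_nodes
    conditions = list(config.conditions)
    if n_scans < 2 * (n_motion + 1):
        raise ValueError("n_scans must be at least twice the nuisance count")

    # block design: cycle conditions, separated by long gaps
    rows = []
    t = gap_s
    total_s = n_scans * tr
    while t + block_s < total_s - gap_s:
        for cond in conditions:
            if t + block_s >= total_s - gap_s:
                break
            rows.append({"condition": cond, "onset_s": t, "duration_s": block_s})
            t += block_s + gap_s
    events = pd.DataFrame(rows)
    if events.empty:
        raise ValueError("scan window too short for the block design")

    weights = {
        cond: build_condition_weights(events, tr, n_scans, condition=cond)
        for cond in conditions
    }

    i0, j0 = planted_pair
    if not (0 <= i0 < j0 < P):
        raise ValueError("planted pair must satisfy 0 <= i < j < n_nodes")
    a = np.sqrt(abs(target_r) / (1.0 - abs(target_r)))
    sign = 1.0 if target_r >= 0 else -1.0

    ii, jj = edge_pairs(P)
    true_z: dict[str, np.ndarray] = {}
    for cond in conditions:
        zvec = np.zeros(n_edges(P))
        zvec[(ii == i0) & (jj == j0)] = np.arctanh(target_r)
        true_z[cond] = zvec

    timeseries: dict[str, np.ndarray] = {}
    nuisance: dict[str, pd.DataFrame] = {}
    for s in range(config.n_subjects):
        x = rng.standard_normal((n_scans, P))
        for cond in conditions:
            active = weights[cond].weights > 0
            shared = rng.standard_normal(int(active.sum()))
            x[active, i0] += a * shared
            x[active, j0] += sign * a * shared
        motion = np.cumsum(rng.normal(0.0, 0.05, size=(n_scans, n_motion)), axis=0)
        loadings = rng.normal(0.0, 0.5, size=(n_motion, P))
        x = x + motion @ loadings
        sid = f"S{s:05d}"
        timeseries[sid] = x
        nuisance[sid] = pd.DataFrame(
            motion, columns=[f"motion_{m}" for m in range(n_motion)]
        )

    return TimeSeriesSet(
        timeseries=timeseries,
        events=events,
        nuisance=nuisance,
        weights=weights,
        true_z=true_z,
        tr=tr,
    )
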