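"""Cohort container joining phenotypes to per-condition connectomes.

The :class:`CohortTable` is the unit every inference stage operates on:
a phenotype table (one row per subject per wave) holding eight symptom
totals -- four externalizing (ADHD, ASD, CD, ODD) and four internalizing
(GAD, DEP, ED, SP) -- plus covariates, linked to Fisher-z edge matrices
(subjects x edges) per task condition and wave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fc import n_edges

EXTERNALIZING: tuple[str, ...] = ("ADHD", "ASD", "CD", "ODD")
INTERNALIZING: tuple[str, ...] = ("GAD", "DEP", "ED", "SP")
SYMPTOMS: tuple[str, ...] = EXTERNALIZING + INTERNALIZING

COVARIATE_COLUMNS: tuple[str, ...] = ("site", "sex", "handedness")
PHENOTYPE_COLUMNS: tuple[str, ...] = ("subject_id", "wave") + COVARIATE_COLUMNS + SYMPTOMS

#: covariate set used inside CPM edge selection
CPM_COVARIATES: tuple[str, ...] = ("site", "handedness")
#: covariate set used for phenotype association analyses
ASSOC_COVARIATES: tuple[str, ...] = ("site", "sex", "handedness")


def encode_covariates(
    pheno: pd.DataFrame, columns: tuple[str, ...] = CPM_COVARIATES
) -> np.ndarray:
    """Design matrix (without intercept) for the requested covariates.

    ``site`` is one-hot encoded with the first level dropped; binary or
    numeric covariates enter as given.  Returns an ``n x q`` float array
    (``q`` may be 0 for an empty covariate set).
    """
    blocks: list[np.ndarray] = []
    for col in columns:
        if col == "site":
            dummies = pd.get_dummies(pheno[col].astype("category"), drop_first=True)
            if dummies.shape[1]:
                blocks.append(dummies.to_numpy(dtype=float))
        else:
            blocks.append(pheno[col].to_numpy(dtype=float)[:, None])
    if not blocks:
        return np.empty((len(pheno), 0))
    return np.column_stack(blocks)


@dataclass
class CohortTable:
    """Phenotypes joined to connectomes; one row per subject per wave."""

    phenotypes: pd.DataFrame
    connectomes: dict[tuple[int, str], pd.DataFrame]
    n_nodes: int

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.phenotypes.columns]
        if missing:
            raise ValueError(f"phenotype table misses mandatory column(s): {missing}")
        dup = self.phenotypes.duplicated(subset=["subject_id", "wave"])
        if dup.any():
            raise ValueError("duplicated (subject_id, wave) rows in phenotype table")
        expected = n_edges(self.n_nodes)
        for key, mat in self.connectomes.items():
            if mat.shape[1] != expected:
                raise ValueError(
                    f"connectome {key} has {mat.shape[1]} edges, expected "
                    f"{expected} for {self.n_nodes} nodes"
                )
            if mat.index.duplicated().any():
                raise ValueError(f"connectome {key} has duplicated subjects")

    # -- convenience views ------------------------------------------------

    @property
    def waves(self) -> list[int]:
        return sorted(self.phenotypes["wave"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted({cond for _, cond in self.connectomes})

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_nodes)

    def pheno_wave(self, wave: int) -> pd.DataFrame:
        return self.phenotypes[self.phenotypes["wave"] == wave]

    def analysis_sample(
        self,
        symptom: str | None,
        condition: str,
        wave: int = 1,
        covariate_cols: tuple[str, ...] = CPM_COVARIATES,
    ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, pd.DataFrame]:
        """Complete-case ``(Z, y, C, pheno)`` for one analysis.

        ``Z`` is the subjects x edges matrix, ``y`` the symptom vector
        (``None`` when ``symptom`` is None), ``C`` the encoded covariate
        design without intercept.  Subjects missing the symptom, any
        covariate, or the connectome are dropped.
        """
        key = (wave, condition)
        if key not in self.connectomes:
            raise KeyError(f"no connectome for wave={wave}, condition={condition!r}")
        pheno = self.pheno_wave(wave)
        needed = list(covariate_cols) + ([symptom] if symptom else [])
        pheno = pheno.dropna(subset=needed)
        mat = self.connectomes[key]
        pheno = pheno[pheno["subject_id"].isin(mat.index)]
        Z = mat.loc[pheno["subject_id"]].to_numpy(dtype=float)
        y = pheno[symptom].to_numpy(dtype=float) if symptom else None
        C = encode_covariates(pheno, covariate_cols)
        return Z, y, C, pheno.reset_index(drop=True)
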