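"""Condition-specific functional connectivity from ROI time series.

Connectivity for a task condition is estimated as a *weighted* Pearson
correlation between nuisance-residualized node time series, where the
temporal weights are the condition's boxcar regressor convolved with a
canonical haemodynamic response function (HRF) and then rectified
(negative lobes set to zero).  The rectified, convolved regressor
up-weights scans where a positive BOLD response to the condition is
expected, de-weights the run's edges, and reduces cross-talk between
adjacent conditions.

Edges are stored as Fisher-z values over the upper triangle of the node
correlation matrix, enumerated row-major over pairs ``(i, j)`` with
``i < j`` (0-based).  That enumeration is part of the on-disk format
contract (see :mod:`npfactor.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: correlations are clipped to this magnitude before atanh so that
#: degenerate (perfectly collinear) pairs still get a finite z.
R_CLIP = 1.0 - 1e-7

#: version tag of the upper-triangle, row-major edge enumeration.
EDGE_ENUMERATION = "upper-row-major-v1"


# ---------------------------------------------------------------------------
# edge vectorization


def edge_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the upper-triangle edge enumeration.

    Edge ``k`` connects nodes ``(i[k], j[k])`` with ``i[k] < j[k]``; pairs
    are enumerated row-major, e.g. for 3 nodes: (0,1), (0,2), (1,2).
    """
    return np.triu_indices(n_nodes, k=1)


def n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def vectorize_upper(matrix: np.ndarray) -> np.ndarray:
    """Vectorize a square symmetric matrix to its upper-triangle edges."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(matrix, matrix.T, atol=1e-10, equal_nan=True):
        raise ValueError("matrix is not symmetric")
    i, j = edge_pairs(matrix.shape[0])
    return matrix[i, j].copy()


def devectorize_upper(vector: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; diagonal is set to zero."""
    vector = np.asarray(vector)
    if vector.shape != (n_edges(n_nodes),):
        raise ValueError(
            f"edge vector of length {vector.shape} does not match "
            f"{n_nodes} nodes ({n_edges(n_nodes)} edges expected)"
        )
    out = np.zeros((n_nodes, n_nodes), dtype=vector.dtype)
    i, j = edge_pairs(n_nodes)
    out[i, j] = vector
    out[j, i] = vector
    return out


def edge_id_to_pair(edge_id: int, n_nodes: int) -> tuple[int, int]:
    i, j = edge_pairs(n_nodes)
    return int(i[edge_id]), int(j[edge_id])


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class ROITimeSeries:
    """Node-by-time BOLD signal for one subject (condition agnostic)."""

    values: np.ndarray  # T scans x P nodes
    tr: float  # seconds
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a T x P matrix")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("need at least 2 scans and 2 nodes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class ConditionWeights:
    """Non-negative temporal weights for one task condition."""

    condition: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be a vector")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if not np.any(self.weights > 0):
            raise ValueError(
                f"condition {self.condition!r} has no positive weights"
            )


@dataclass
class ConditionConnectome:
    """Fisher-z edge vector for one subject under one condition."""

    subject_id: str
    condition: str
    z: np.ndarray
    n_nodes: int = 0
    enumeration: str = EDGE_ENUMERATION

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.n_nodes and self.z.shape != (n_edges(self.n_nodes),):
            raise ValueError("edge count does not match node count")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("connectome contains non-finite z values")


# ---------------------------------------------------------------------------
# HRF and condition weights


def double_gamma_hrf(
    tr: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the scan resolution.

    Shape parameters follow the conventional kernel: response peaking at
    ``peak_delay`` s, undershoot peaking at ``undershoot_delay`` s,
    peak:undershoot amplitude ratio ``ratio``, truncated at ``duration``
    s.  The kernel is normalized to unit peak.
    """
    t = np.arange(0.0, duration + tr / 2, tr)
    # gamma pdfs with unit rate: mode = shape - 1  ->  shape = delay + 1
    pos = sps.gamma.pdf(t, a=peak_delay + 1.0, scale=1.0)
    neg = sps.gamma.pdf(t, a=undershoot_delay + 1.0, scale=1.0)
    h = pos - neg / ratio
    peak = np.max(np.abs(h))
    if peak > 0:
        h = h / peak
    return h


def build_condition_weights(
    events: pd.DataFrame,
    tr: float,
    n_scans: int,
    condition: str | None = None,
    hrf_kernel: np.ndarray | None = None,
    **hrf_params: float,
) -> ConditionWeights:
    """Rectified, HRF-convolved boxcar weights for one condition.

    Parameters
    ----------
    events
        Table with columns ``onset_s`` and ``duration_s`` (and optionally
        ``condition``, filtered on when ``condition`` is given).
    hrf_kernel
        Replacement convolution kernel (mainly for testing); defaults to
        the canonical double-gamma kernel sampled at ``tr``.
    """
    ev = events
    if condition is not None and "condition" in ev.columns:
        ev = ev[ev["condition"] == condition]
    if len(ev) == 0:
        raise ValueError("empty event table: no events for condition")
    onsets = np.asarray(ev["onset_s"], dtype=float)
    durations = np.asarray(ev["duration_s"], dtype=float)
    if np.any(durations < 0):
        raise ValueError("event durations must be >= 0")
    if np.any(onsets < 0) or np.any(onsets >= n_scans * tr):
        raise ValueError("event onsets must lie within the scan window")

    scan_t = np.arange(n_scans) * tr
    boxcar = np.zeros(n_scans)
    for onset, dur in zip(onsets, durations):
        if dur == 0:
            boxcar[int(round(onset / tr))] = 1.0
        else:
            boxcar[(scan_t >= onset) & (scan_t < onset + dur)] = 1.0

    if hrf_kernel is None:
        hrf_kernel = double_gamma_hrf(tr, **hrf_params)
    w = np.convolve(boxcar, np.asarray(hrf_kernel, dtype=float))[:n_scans]
    w = np.clip(w, 0.0, None)  # rectify: only expected-positive BOLD counts
    if not np.any(w > 0):
        raise ValueError("all-zero weights after rectification")
    return ConditionWeights(condition=condition or "", weights=w)


# ---------------------------------------------------------------------------
# nuisance regression


def regress_nuisance(ts: ROITimeSeries, nuisance: np.ndarray | pd.DataFrame) -> ROITimeSeries:
    """OLS-residualize every node series on the nuisance regressors.

    An intercept column is appended when none of the columns is constant.
    A rank-deficient design is handled by the minimum-norm least-squares
    projection (equivalent to dropping collinear columns) and logged.
    """
    X = np.asarray(nuisance, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    T = ts.n_scans
    if X.shape[0] != T:
        raise ValueError("nuisance rows must match the number of scans")
    if X.shape[1] >= T:
        raise ValueError("need fewer nuisance regressors than scans")
    has_intercept = np.any(np.all(X == X[0:1, :], axis=0) & np.any(X != 0, axis=0))
    if not has_intercept:
        X = np.column_stack([np.ones(T), X])
    beta, _, rank, _ = np.linalg.lstsq(X, ts.values, rcond=None)
    if rank < X.shape[1]:
        logger.warning(
            "rank-deficient nuisance matrix (rank %d < %d columns); "
            "collinear columns contribute nothing to the projection",
            rank,
            X.shape[1],
        )
    resid = ts.values - X @ beta
    return ROITimeSeries(values=resid, tr=ts.tr, subject_id=ts.subject_id)


# ---------------------------------------------------------------------------
# weighted correlation


def weighted_correlation_matrix(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation matrix over columns of ``values``.

    Frequency-weight normalization (divide by the weight total) is used;
    the resulting correlations are invariant to rescaling all weights by
    any positive constant.  Zero-variance columns get zero correlations.
    """
    w = np.asarray(weights, dtype=float)
    x = np.asarray(values, dtype=float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights must have a positive sum")
    mean = (w @ x) / wsum
    xc = x - mean
    cov = (xc * w[:, None]).T @ xc / wsum
    var = np.diag(cov).copy()
    bad = var <= 0
    if np.any(bad):
        logger.warning(
            "%d node(s) have zero variance under the weighting; their "
            "edges are set to r=0",
            int(bad.sum()),
        )
    sd = np.sqrt(np.where(bad, 1.0, var))
    r = cov / np.outer(sd, sd)
    r[bad, :] = 0.0
    r[:, bad] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def weighted_fc(ts: ROITimeSeries, w: ConditionWeights) -> ConditionConnectome:
    """Condition-weighted Fisher-z connectome for one subject."""
    if len(w.weights) != ts.n_scans:
        raise ValueError("weight vector length must equal the scan count")
    r = weighted_correlation_matrix(ts.values, w.weights)
    z = np.arctanh(np.clip(vectorize_upper(r), -R_CLIP, R_CLIP))
    return ConditionConnectome(
        subject_id=ts.subject_id, condition=w.condition, z=z, n_nodes=ts.n_nodes
    )
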