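"""Temporal PCA of condition-averaged pupil waveforms.

Timepoints are the variables and participant-condition averaged waveforms
the observations.  The pipeline is: covariance-metric eigendecomposition ->
retention (mean-eigenvalue rule by default, the covariance analogue of the
Kaiser criterion) -> orthogonal Varimax rotation with Kaiser (unit
communality) normalization -> least-squares regression scores.

Loadings stay in raw covariance units (eigenvector times the square root of
its eigenvalue), so rotated loading waveforms are on the scale of the input
waveforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .preprocess import EpochMatrix

log = logging.getLogger("pupilmem")

__all__ = ["WaveformMatrix", "ComponentSolution", "build_waveform_matrix",
           "covariance_pca", "retain_components", "varimax_rotate",
           "varimax_criterion", "component_scores", "summarize",
           "run_pca", "condition_split_pca"]


@dataclass
class WaveformMatrix:
    """Participant-condition averaged, baseline-corrected epoch waveforms."""

    keys: pd.DataFrame            # participant, tone_condition, n_trials
    data: np.ndarray              # (n_rows, n_timepoints)
    times_ms: np.ndarray

    def __post_init__(self) -> None:
        if len(self.keys) != self.data.shape[0]:
            raise ValueError("keys/data row mismatch")
        if np.isnan(self.data).any():
            raise ValueError("waveform matrix contains missing values")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]


@dataclass
class ComponentSolution:
    """Rotated temporal components of the waveform covariance."""

    loadings: np.ndarray          # (n_timepoints, k), raw units
    unrotated: np.ndarray         # (n_timepoints, k)
    rotation: np.ndarray          # (k, k) orthogonal
    eigenvalues: np.ndarray       # full positive spectrum, descending
    times_ms: np.ndarray
    scores: np.ndarray            # (n_rows, k), zero column means
    keys: pd.DataFrame
    retention_rule: str
    converged: bool
    n_iter: int
    total_variance: float

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def peak_latencies_ms(self) -> np.ndarray:
        return self.times_ms[np.argmax(np.abs(self.loadings), axis=0)]

    @property
    def variance_shares(self) -> np.ndarray:
        """Per-component share of the retained variance (sums to 1)."""
        ss = (self.loadings ** 2).sum(axis=0)
        return ss / ss.sum()

    @property
    def variance_of_total(self) -> np.ndarray:
        """Per-component share of the total waveform variance."""
        ss = (self.loadings ** 2).sum(axis=0)
        return ss / self.total_variance


def build_waveform_matrix(epochs: EpochMatrix, window_ms: int = 3000,
                          conditions=("boundary", "same_context"),
                          min_trials: int = 1) -> WaveformMatrix:
    """Average trials into one waveform per participant x condition.

    Participants missing any requested condition are dropped (logged), as
    are cells with fewer than ``min_trials`` trials.
    """
    cols = epochs.times_ms < window_ms
    sub = epochs.subset(epochs.index["tone_condition"].isin(conditions).to_numpy())
    rows, keys = [], []
    for (pid, cond), grp in sub.index.groupby(
            ["participant", "tone_condition"], sort=True).groups.items():
        if len(grp) < min_trials:
            log.warning("dropping cell (%s, %s): %d < %d trials",
                        pid, cond, len(grp), min_trials)
            continue
        rows.append(sub.data[np.asarray(grp)][:, cols].mean(axis=0))
        keys.append((pid, cond, len(grp)))
    keys = pd.DataFrame(keys, columns=["participant", "tone_condition", "n_trials"])
    counts = keys.groupby("participant")["tone_condition"].nunique()
    complete = set(counts[counts == len(conditions)].index)
    dropped = set(keys["participant"]) - complete
    if dropped:
        log.warning("dropping participant(s) missing a condition: %s", sorted(dropped))
    keep = keys["participant"].isin(complete).to_numpy()
    return WaveformMatrix(keys.loc[keep].reset_index(drop=True),
                          np.vstack(rows)[keep], epochs.times_ms[cols])


def covariance_pca(matrix: WaveformMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the timepoint covariance of the row waveforms.

    Returns (eigenvalues descending, loadings) where loading column j is
    ``eigenvector_j * sqrt(eigenvalue_j)`` — the raw covariance metric.
    Numerically-zero eigenvalues (<= 1e-10 x trace) are truncated.
    """
    if matrix.n_rows < 2:
        raise ValueError("need at least 2 rows for a covariance PCA")
    x = matrix.data - matrix.data.mean(axis=0, keepdims=True)
    cov = (x.T @ x) / (matrix.n_rows - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > 1e-10 * np.trace(cov)
    evals, evecs = evals[keep], evecs[:, keep]
    loadings = evecs * np.sqrt(evals)
    return evals, loadings


def retain_components(eigenvalues: np.ndarray, rule: str = "mean_eigenvalue",
                      n_variables: int | None = None) -> int:
    """Number of components to keep.

    ``mean_eigenvalue``: eigenvalues >= the average variance of the original
    variables, i.e. trace / ``n_variables`` (covariance-metric Kaiser
    analogue; defaults to the number of eigenvalues supplied).
    ``unit_eigenvalue``: eigenvalues > 1, meaningful only for
    correlation-metric input.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    ev = ev[ev > 0]
    if ev.size == 0:
        raise ValueError("no positive eigenvalues")
    if rule == "mean_eigenvalue":
        mean = ev.sum() / (n_variables if n_variables else ev.size)
        k = int(np.sum(ev >= mean))
    elif rule == "unit_eigenvalue":
        k = int(np.sum(ev > 1.0))
    else:
        raise ValueError(f"unknown retention rule {rule!r}")
    if k == 0:
        log.warning("retention rule %s kept 0 components; forcing k=1", rule)
        k = 1
    return k


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax objective: sum over components of the variance of
    squared loadings."""
    sq = np.asarray(loadings) ** 2
    return float(np.sum(sq.var(axis=0)))


def varimax_rotate(loadings: np.ndarray, *, kaiser_normalize: bool = True,
                   tol: float = 1e-10, max_iter: int = 1000
                   ) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Orthogonal Varimax rotation (Kaiser-normalized by default).

    Rows are scaled to unit communality before rotation and unscaled after;
    the rotation matrix is found by the SVD fixed-point iteration.  Component
    signs are fixed so each loading waveform's largest-magnitude value is
    positive, and columns are reordered by descending sum of squares.

    Returns (rotated loadings, rotation matrix, converged flag, iterations).
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k == 1:
        sign = np.sign(L[np.argmax(np.abs(L[:, 0])), 0]) or 1.0
        return L * sign, np.array([[sign]]), True, 0
    comm = np.sqrt((L ** 2).sum(axis=1))
    if kaiser_normalize:
        # rows with negligible communality are numerically pure noise after
        # scaling; leave them at (near) zero instead of unit length
        cut = 1e-6 * comm.max()
        W = L / np.where(comm > cut, comm, np.inf)[:, None]
    else:
        W = L

    def iterate(R):
        # classic Kaiser pairwise sweeps: each planar angle has a closed form
        for it in range(1, max_iter + 1):
            max_angle = 0.0
            Wr = W @ R
            for i in range(k - 1):
                for j in range(i + 1, k):
                    x, y = Wr[:, i], Wr[:, j]
                    u = x ** 2 - y ** 2
                    v = 2.0 * x * y
                    a, b = u.sum(), v.sum()
                    c = (u ** 2 - v ** 2).sum()
                    d = 2.0 * (u * v).sum()
                    num = d - 2.0 * a * b / p
                    den = c - (a ** 2 - b ** 2) / p
                    theta = 0.25 * np.arctan2(num, den)
                    if abs(theta) < 1e-14:
                        continue
                    max_angle = max(max_angle, abs(theta))
                    rot = np.array([[np.cos(theta), -np.sin(theta)],
                                    [np.sin(theta), np.cos(theta)]])
                    Wr[:, [i, j]] = Wr[:, [i, j]] @ rot
                    R[:, [i, j]] = R[:, [i, j]] @ rot
            if max_angle < tol:
                return R, True, it
        return R, False, max_iter

    # a sweep can in principle settle on a local optimum, so run from a few
    # deterministic starts and keep the rotation with the best criterion
    start_rng = np.random.default_rng(0)
    starts = [np.eye(k)]
    starts += [np.linalg.qr(start_rng.standard_normal((k, k)))[0] for _ in range(2)]
    best = (-np.inf, None, False, 0)
    for R0 in starts:
        R, conv, it = iterate(R0.copy())
        crit = varimax_criterion(W @ R)
        if crit > best[0]:
            best = (crit, R, conv, it)
    _, R, converged, it = best
    if not converged:
        log.warning("varimax did not converge in %d iterations", max_iter)
    rotated = L @ R
    # sign convention: extremum of each waveform positive
    signs = np.sign(rotated[np.argmax(np.abs(rotated), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    rotated *= signs
    R = R * signs
    # order by descending explained variance
    order = np.argsort((rotated ** 2).sum(axis=0))[::-1]
    return rotated[:, order], R[:, order], converged, it


def component_scores(matrix: WaveformMatrix, loadings: np.ndarray,
                     method: str = "regression") -> np.ndarray:
    """Per-row component scores.

    ``regression``: least-squares coefficients of the centered rows on the
    rotated loading waveforms.  ``correlation``: scaled cross-products
    (loadings' x rows).  Scores have zero mean across rows by construction.
    """
    x = matrix.data - matrix.data.mean(axis=0, keepdims=True)
    if method == "correlation":
        return x @ loadings / (loadings ** 2).sum(axis=0)
    gram = loadings.T @ loadings
    try:
        coef = np.linalg.solve(gram, loadings.T @ x.T)
    except np.linalg.LinAlgError:
        log.warning("singular loading Gram matrix; using pseudo-inverse")
        coef = np.linalg.pinv(gram) @ (loadings.T @ x.T)
    return coef.T


def run_pca(matrix: WaveformMatrix, cfg: AnalysisConfig) -> ComponentSolution:
    """Full decomposition path on a waveform matrix."""
    evals, unrot = covariance_pca(matrix)
    k = retain_components(evals, cfg.retention_rule,
                          n_variables=matrix.data.shape[1])
    rotated, R, converged, n_iter = varimax_rotate(unrot[:, :k])
    scores = component_scores(matrix, rotated, cfg.score_method)
    total_var = float(evals.sum())
    return ComponentSolution(
        loadings=rotated, unrotated=unrot[:, :k], rotation=R,
        eigenvalues=evals, times_ms=matrix.times_ms, scores=scores,
        keys=matrix.keys, retention_rule=cfg.retention_rule,
        converged=converged, n_iter=n_iter, total_variance=total_var)


def condition_split_pca(epochs: EpochMatrix, condition: str, cfg: AnalysisConfig,
                        min_trials: int = 1) -> ComponentSolution:
    """The same decomposition restricted to one condition's rows."""
    matrix = build_waveform_matrix(epochs, window_ms=cfg.pca_window_ms,
                                   conditions=(condition,), min_trials=min_trials)
    return run_pca(matrix, cfg)


def summarize(solution: ComponentSolution) -> dict:
    """Per-component peak latencies and % variance (both definitions)."""
    return {
        "k": solution.k,
        "retention_rule": solution.retention_rule,
        "eigenvalues": solution.eigenvalues[:max(solution.k, 10)].tolist(),
        "peak_latency_ms": solution.peak_latencies_ms.tolist(),
        "pct_variance_of_retained": (100.0 * solution.variance_shares).tolist(),
        "pct_variance_of_total": (100.0 * solution.variance_of_total).tolist(),
        "converged": bool(solution.converged),
        "n_iter": int(solution.n_iter),
    }
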