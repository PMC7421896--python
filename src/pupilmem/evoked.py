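"""Tone-evoked dilation measures and condition contrasts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig, ConfigError
from .preprocess import EpochMatrix

__all__ = ["EvokedSummary", "evoked_dilation", "paired_contrast",
           "against_baseline", "InsufficientDataError"]


class InsufficientDataError(ValueError):
    pass


@dataclass
class EvokedSummary:
    """Per-trial and per-participant evoked dilation values."""

    trials: pd.DataFrame          # trial keys + 'evoked' column
    participant_means: pd.DataFrame  # participant x condition mean

    def condition_vectors(self, conditions=("boundary", "same_context")
                          ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Aligned per-participant mean vectors for a paired contrast."""
        wide = self.participant_means.pivot(index="participant",
                                            columns="tone_condition",
                                            values="evoked")
        wide = wide.dropna(subset=list(conditions))
        return (wide[conditions[0]].to_numpy(), wide[conditions[1]].to_numpy(),
                list(wide.index))


def evoked_dilation(epochs: EpochMatrix, cfg: AnalysisConfig) -> EvokedSummary:
    """Mean baseline-corrected pupil over the evoked window, per trial.

    Participant-condition means aggregate trials across blocks; the
    list-initial tone keeps its own label and is excluded from the
    boundary/same-context contrast by construction.
    """
    v0, v1 = cfg.evoked_window_ms
    w0, w1 = cfg.epoch_window_ms
    if v0 < w0 or v1 > w1:
        raise ConfigError("evoked window outside epoch window")
    cols = (epochs.times_ms >= v0) & (epochs.times_ms < v1)
    trials = epochs.index.copy()
    trials["evoked"] = epochs.data[:, cols].mean(axis=1)
    trials["tonic"] = epochs.baselines
    means = (trials.groupby(["participant", "tone_condition"], as_index=False)
             ["evoked"].mean())
    return EvokedSummary(trials=trials, participant_means=means)


def _describe_paired(diff: np.ndarray) -> dict:
    n = len(diff)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 paired participants, got {n}")
    sd = diff.std(ddof=1)
    mean = diff.mean()
    out = dict(n=n, df=n - 1, mean_diff=float(mean), sd_diff=float(sd))
    if sd == 0:
        # degenerate: identical differences; t/d well defined (0) only when
        # the mean difference is also 0, p undefined either way
        t = 0.0 if mean == 0 else np.inf * np.sign(mean)
        out.update(t=float(t), p=np.nan, d=float(t),
                   ci95=(float(mean), float(mean)), zero_variance=True)
        return out
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    out.update(t=float(t), p=float(p), d=float(mean / sd),
               ci95=(float(mean - half), float(mean + half)),
               zero_variance=False)
    return out


def paired_contrast(a: np.ndarray, b: np.ndarray) -> dict:
    """Two-tailed paired t-test on participant means (a vs b).

    Returns t, df, p, Cohen's d (mean difference over the s.d. of
    differences), and the 95% t-based CI of the mean difference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InsufficientDataError("paired vectors must have equal length")
    if np.isnan(a).any() or np.isnan(b).any():
        raise InsufficientDataError("missing side in paired contrast")
    return _describe_paired(a - b)


def against_baseline(values: np.ndarray, mu0: float = 0.0) -> dict:
    """One-sample two-tailed t-test of participant means against ``mu0``."""
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise InsufficientDataError("missing values in one-sample test")
    return _describe_paired(values - mu0)
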