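"""Artifact handling, block exclusion, epoching, baseline correction.

Detection criteria follow standard pupillometry practice (the block-level
exclusion rule is strict ``< min_valid_fraction``): a sample is invalid when
the pupil is non-positive/missing, the device valid flag is off, or the
absolute sample-to-sample change exceeds a MAD-based velocity threshold; the
invalid mask is then dilated by a configurable pad.  Invalid runs are
repaired by linear interpolation between the nearest good neighbours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .dataio import PupilRecording

log = logging.getLogger("pupilmem")

__all__ = ["EpochMatrix", "detect_artifacts", "interpolate", "exclude_blocks",
           "epoch", "preprocess_recordings", "EmptyEpochsError"]


class EmptyEpochsError(ValueError):
    """No tone could be epoched from the given recording."""


TRIAL_KEYS = ["participant", "block", "list_index", "event_index",
              "position_in_event", "tone_condition"]


@dataclass
class EpochMatrix:
    """Baseline-corrected pupil epochs aligned to tone onsets.

    ``data`` has one row per retained tone trial and one column per timepoint
    of the (half-open) epoch window; ``baselines`` holds the per-trial raw
    baseline mean, kept separately as the tonic measure.
    """

    index: pd.DataFrame          # TRIAL_KEYS columns, one row per trial
    data: np.ndarray             # (n_trials, n_timepoints)
    baselines: np.ndarray        # (n_trials,) raw pre-tone means
    times_ms: np.ndarray         # column timestamps relative to tone onset

    def __post_init__(self) -> None:
        if len(self.index) != self.data.shape[0]:
            raise ValueError("index/data row mismatch")
        if self.data.shape[1] != len(self.times_ms):
            raise ValueError("data/times column mismatch")
        if np.isnan(self.data).any():
            raise ValueError("epochs contain missing values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def subset(self, mask) -> "EpochMatrix":
        mask = np.asarray(mask)
        return EpochMatrix(self.index.loc[mask].reset_index(drop=True),
                           self.data[mask], self.baselines[mask], self.times_ms)

    @staticmethod
    def concatenate(mats: list["EpochMatrix"]) -> "EpochMatrix":
        return EpochMatrix(
            pd.concat([m.index for m in mats], ignore_index=True),
            np.vstack([m.data for m in mats]),
            np.concatenate([m.baselines for m in mats]),
            mats[0].times_ms)


def detect_artifacts(rec: PupilRecording, *, velocity_mad_threshold: float = 5.0,
                     pad_ms: int = 50) -> np.ndarray:
    """Boolean mask of samples to repair (True = invalid)."""
    pupil = rec.pupil
    bad = (~rec.valid) | ~np.isfinite(pupil) | (pupil <= 0)
    if len(pupil) > 1 and velocity_mad_threshold > 0:
        vel = np.diff(pupil)
        good_vel = vel[~(bad[:-1] | bad[1:])]
        if good_vel.size:
            med = np.median(good_vel)
            # robust sd of the sample-to-sample change (1.4826 * MAD)
            sigma = 1.4826 * np.median(np.abs(good_vel - med))
            if sigma > 0:
                spikes = np.abs(vel - med) > velocity_mad_threshold * sigma
                bad[:-1] |= spikes
                bad[1:] |= spikes
    pad_n = int(round(pad_ms * rec.sampling_rate / 1000.0))
    if pad_n > 0 and bad.any():
        idx = np.flatnonzero(bad)
        dil = np.zeros(len(bad) + 1, dtype=int)
        lo = np.maximum(idx - pad_n, 0)
        hi = np.minimum(idx + pad_n + 1, len(bad))
        np.add.at(dil, lo, 1)
        np.add.at(dil, hi, -1)
        bad = np.cumsum(dil[:-1]) > 0
    return bad


def interpolate(rec: PupilRecording, mask: np.ndarray) -> PupilRecording:
    """Replace masked samples by linear interpolation between good neighbours.

    Leading/trailing masked runs are filled by nearest-value extension.  When
    every sample is masked the trace is returned unchanged with all samples
    still invalid; block exclusion handles it downstream.
    """
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != rec.n_samples:
        raise ValueError("mask length does not match recording")
    out = rec.copy()
    if not mask.any():
        return out
    good = np.flatnonzero(~mask)
    if good.size == 0:
        out.valid = np.zeros_like(mask)
        return out
    idx = np.flatnonzero(mask)
    out.pupil[idx] = np.interp(idx, good, rec.pupil[good])
    out.valid = ~mask  # post-repair validity reflects original data quality
    return out


def exclude_blocks(recordings: list[PupilRecording],
                   masks: list[np.ndarray],
                   min_valid_fraction: float = 0.5
                   ) -> tuple[list[PupilRecording], list[np.ndarray], pd.DataFrame]:
    """Drop blocks whose valid fraction is strictly below the threshold."""
    kept_recs, kept_masks, report = [], [], []
    for rec, mask in zip(recordings, masks):
        frac = 1.0 - float(np.mean(mask))
        dropped = frac < min_valid_fraction
        report.append(dict(participant=rec.participant_id, block=rec.block_id,
                           valid_fraction=frac, dropped=dropped))
        if not dropped:
            kept_recs.append(rec)
            kept_masks.append(mask)
    report = pd.DataFrame(report)
    n_drop = int(report["dropped"].sum())
    if n_drop:
        log.info("excluded %d/%d blocks below valid fraction %.2f",
                 n_drop, len(recordings), min_valid_fraction)
    return kept_recs, kept_masks, report


def epoch(rec: PupilRecording, events: pd.DataFrame, cfg: AnalysisConfig) -> EpochMatrix:
    """Cut baseline-corrected epochs around each tone onset of one block.

    Each row is ``pupil[onset + epoch_window) - mean(pupil[onset + baseline
    window))``; tones without full baseline+epoch coverage are dropped with a
    warning.  The list-initial tone is retained under its own label.
    """
    step = 1000.0 / rec.sampling_rate
    w0, w1 = cfg.epoch_window_ms
    b0, b1 = cfg.baseline_window_ms
    n_cols = int(round((w1 - w0) / step))
    n_base = int(round((b1 - b0) / step))
    t0 = float(rec.time[0])

    tones = events[(events["event_type"] == "tone")
                   & (events["participant"] == rec.participant_id)
                   & (events["block"] == rec.block_id)]
    if tones.empty:
        raise EmptyEpochsError(f"no tones for block {rec.key}")

    onsets = tones["onset_ms"].to_numpy(dtype=float)
    i_on = np.round((onsets + w0 - t0) / step).astype(int)
    i_b0 = np.round((onsets + b0 - t0) / step).astype(int)
    ok = (i_b0 >= 0) & (i_on + n_cols <= rec.n_samples)
    if not ok.all():
        log.warning("dropping %d tone(s) with incomplete coverage in block %s",
                    int((~ok).sum()), rec.key)
    if not ok.any():
        raise EmptyEpochsError(f"zero epochable tones in block {rec.key}")
    i_on, i_b0 = i_on[ok], i_b0[ok]
    data = rec.pupil[i_on[:, None] + np.arange(n_cols)]
    bases = rec.pupil[i_b0[:, None] + np.arange(n_base)].mean(axis=1)
    data = data - bases[:, None]
    index = tones.loc[ok, TRIAL_KEYS].reset_index(drop=True)
    times = w0 + np.arange(n_cols) * step
    return EpochMatrix(index, data, bases, times)


def preprocess_recordings(recordings: list[PupilRecording],
                          events: pd.DataFrame, cfg: AnalysisConfig
                          ) -> tuple[EpochMatrix, pd.DataFrame]:
    """Full preprocessing path: detect, exclude, interpolate, epoch, stack."""
    masks = [detect_artifacts(r, velocity_mad_threshold=cfg.velocity_mad_threshold,
                              pad_ms=cfg.artifact_pad_ms) for r in recordings]
    kept, kept_masks, report = exclude_blocks(recordings, masks, cfg.min_valid_fraction)
    if not kept:
        raise EmptyEpochsError("all blocks excluded by the validity threshold")
    by_block = {key: grp for key, grp in events.groupby(["participant", "block"])}
    mats = [epoch(interpolate(r, m), by_block[r.key], cfg)
            for r, m in zip(kept, kept_masks)]
    return EpochMatrix.concatenate(mats), report
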