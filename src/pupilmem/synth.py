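"""Synthetic task designs, pupil recordings, and memory outcomes.

The generator plants known structure so that every downstream estimator can
be tested by parameter recovery:

* pupil traces = participant mean + AR(1) tonic drift + a sum of unimodal
  evoked kernels (one per planted component, with condition-dependent
  amplitudes) + white noise, with blink dropouts;
* memory outcomes carry configurable boundary effects (order, distance,
  source), and participant-level boundary-minus-same-context memory deltas
  receive an additive term proportional to the participant's standardized
  planted amplitude delta, so pupil-memory coupling is controlled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import norm
from scipy.optimize import brentq

from .config import SimulationConfig, ConfigError, FREQUENCIES
from .dataio import PupilRecording, tone_condition

__all__ = [
    "pupil_kernel",
    "generate_design",
    "generate_pupil",
    "generate_memory",
    "draw_ground_truth",
    "simulate",
    "paper_like_config",
    "GroundTruth",
    "distance_rating_moments",
    "expected_accuracy",
    "expected_distance_spearman",
    "distance_coupling_for_spearman",
]

#: condition order of the amplitude arrays
COND_INDEX = {"boundary": 0, "same_context": 1, "list_first": 1}

EPOCH_MS = 3000
TAPER_MS = 300


def pupil_kernel(latency_ms: float, width_ms: float, *,
                 sampling_rate: float = 250.0,
                 window_ms: int = EPOCH_MS,
                 taper_ms: int = TAPER_MS) -> np.ndarray:
    """Unit-peak gamma-family waveform over ``[0, window_ms)``.

    ``f(t) = (t/L)^a exp(a (1 - t/L))`` with shape ``a = (L/w)^2`` rises to a
    single interior maximum of 1 at the sample nearest ``latency_ms`` and is
    non-negative everywhere.  A cosine taper over the final ``taper_ms``
    brings the waveform smoothly to zero at the window edge so that summing
    kernels into a continuous trace introduces no step discontinuities.
    """
    if not (0 < latency_ms < window_ms - taper_ms):
        raise ConfigError(
            f"kernel latency {latency_ms} must lie inside (0, {window_ms - taper_ms})")
    if width_ms <= 0:
        raise ConfigError("kernel width must be positive")
    step = 1000.0 / sampling_rate
    n = int(round(window_ms / step))
    t = np.arange(n) * step
    a = (latency_ms / width_ms) ** 2
    tt = np.where(t > 0, t, np.nan)
    with np.errstate(invalid="ignore"):
        k = np.exp(a * (np.log(tt / latency_ms) + 1.0 - tt / latency_ms))
    k[t <= 0] = 0.0
    ramp_n = int(round(taper_ms / step))
    if ramp_n > 1:
        ramp = 0.5 * (1.0 + np.cos(np.linspace(0.0, np.pi, ramp_n)))
        k[-ramp_n:] *= ramp
    return k / k.max()


@dataclass
class GroundTruth:
    """Latent state of one simulation run, for recovery oracles."""

    kernels: np.ndarray              # (k, n_epoch) unit-peak waveforms
    kernel_step_ms: float
    image_kernel: np.ndarray
    participants: list[str]
    #: (n_participants, k, 2) amplitudes; last axis = (boundary, same_context)
    amplitudes: np.ndarray
    #: (n_participants, k) standardized boundary-minus-same amplitude deltas
    z_deltas: np.ndarray
    #: (n_participants,) standardized tonic-variability draw
    z_tonic: np.ndarray = None
    coupling: dict = field(default_factory=dict)
    stability_coupling: dict = field(default_factory=dict)
    memory_intercepts: dict = field(default_factory=dict)

    def amplitude_delta(self, component: int) -> np.ndarray:
        return self.amplitudes[:, component, 0] - self.amplitudes[:, component, 1]


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def _pair_positions(lag: int) -> tuple[list[tuple], list[int]]:
    """Boundary pair anchors and admissible same-context start positions.

    A boundary pair is ``(event e, pos 8) - (event e+1, pos lag+1)``; a
    same-context pair is ``(e, p) - (e, p+lag+1)`` chosen so that no item is
    reused across pairs.
    """
    second = lag + 1
    if second > 8:
        raise ConfigError(f"lag {lag} incompatible with 8-item events")
    boundary = [((e, 8), (e + 1, second)) for e in (1, 2, 3)]
    options = {}
    for e in range(1, 5):
        # position 1 (boundary/first item) and position 8 (boundary-pair
        # anchor or list-last item) are never same-context pair members
        used = {1, 8}
        if e >= 2:
            used.add(second)
        opts = [p for p in range(2, 8 - lag)
                if p not in used and (p + lag + 1) not in used and p + lag + 1 <= 8]
        if not opts:
            raise ConfigError(f"lag {lag}: no same-context pair placement in event {e}")
        options[e] = opts
    return boundary, options


def generate_design(cfg: SimulationConfig, rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate events plus test-pair and source-item schedules.

    Per block: 32 items in 4 auditory events of 8; a 1-s tone 1.5 s before
    each image; frequencies drawn without within-block event repetition; ears
    strictly alternating with the first ear counterbalanced across blocks;
    ``4 * 8 - 2 * n_pairs = 18`` untested items scheduled for the source test.
    """
    boundary_pairs, sc_options = _pair_positions(cfg.lag)
    event_rows, pair_rows, item_rows = [], [], []
    participants = [f"P{p + 1:03d}" for p in range(cfg.n_participants)]
    for p_idx, pid in enumerate(participants):
        for b in range(1, cfg.n_blocks + 1):
            freqs = rng.choice(FREQUENCIES, size=4, replace=False)
            first_left = (p_idx + b) % 2 == 0
            sc_pairs = [((e, rng.choice(sc_options[e])),) for e in range(1, 5)]
            paired_cells = {}
            for (c1, c2) in boundary_pairs:
                paired_cells[c1] = ("boundary_span", c1, c2)
                paired_cells[c2] = ("boundary_span", c1, c2)
            for (cell,) in sc_pairs:
                e, p = cell
                c1, c2 = (e, p), (e, p + cfg.lag + 1)
                paired_cells[c1] = ("same_context", c1, c2)
                paired_cells[c2] = ("same_context", c1, c2)

            item_of = {}
            for e in range(1, 5):
                for pos in range(1, 9):
                    j = (e - 1) * 8 + (pos - 1)
                    tone_on = cfg.first_tone_ms + j * cfg.trial_spacing_ms
                    item = f"{pid}B{b:02d}I{j + 1:02d}"
                    item_of[(e, pos)] = item
                    ear = ("left" if first_left else "right") if e % 2 == 1 else \
                          ("right" if first_left else "left")
                    base = dict(participant=pid, block=b, list_index=b,
                                event_index=e, position_in_event=pos,
                                tone_condition=tone_condition(e, pos),
                                frequency_hz=int(freqs[e - 1]), ear=ear,
                                item_id=item)
                    event_rows.append(dict(base, onset_ms=tone_on, event_type="tone"))
                    event_rows.append(dict(base, onset_ms=tone_on + cfg.tone_to_image_ms,
                                           event_type="image"))
            seen = set()
            for cell, (cond, c1, c2) in paired_cells.items():
                if (c1, c2) in seen:
                    continue
                seen.add((c1, c2))
                pair_rows.append(dict(
                    participant=pid, block=b,
                    item_a=item_of[c1], item_b=item_of[c2],
                    pair_condition=cond, lag=cfg.lag,
                ))
            for e in range(1, 5):
                for pos in range(1, 9):
                    if (e, pos) in paired_cells:
                        continue
                    if e == 1 and pos == 1:
                        itype = "first"
                    elif e == 4 and pos == 8:
                        itype = "last"
                    elif pos == 1:
                        itype = "boundary"
                    else:
                        itype = "same_context"
                    item_rows.append(dict(participant=pid, block=b,
                                          item_id=item_of[(e, pos)],
                                          item_type=itype))
    events = pd.DataFrame(event_rows)[[
        "participant", "block", "onset_ms", "event_type", "list_index",
        "event_index", "position_in_event", "tone_condition", "frequency_hz",
        "ear", "item_id"]]
    return events, pd.DataFrame(pair_rows), pd.DataFrame(item_rows)


# ---------------------------------------------------------------------------
# pupil traces
# ---------------------------------------------------------------------------

def _draw_amplitudes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_participants, k, 2) amplitudes; last axis = (boundary, same_context).

    Each participant draws a shared level (common to both conditions) plus an
    independent boundary-minus-same delta deviation, so both the overall
    expression of a component and the size of its boundary effect vary
    across participants.
    """
    means = np.asarray(cfg.amplitude_means, dtype=float)          # (k, 2)
    sds = np.asarray(cfg.amplitude_sds, dtype=float)
    dsds = np.asarray(cfg.amplitude_delta_sds, dtype=float)
    level = sds * rng.standard_normal((cfg.n_participants, cfg.n_components))
    delta_dev = dsds * rng.standard_normal((cfg.n_participants, cfg.n_components))
    amps = means[None, :, :] + level[:, :, None]
    amps[:, :, 0] += delta_dev
    return amps


def draw_ground_truth(cfg: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    """Draw the latent per-participant state without rendering traces."""
    kernels = np.vstack([
        pupil_kernel(lat, w, sampling_rate=cfg.sampling_rate)
        for lat, w in zip(cfg.component_latencies_ms, cfg.component_widths_ms)])
    image_kernel = pupil_kernel(cfg.image_latency_ms, cfg.image_width_ms,
                                sampling_rate=cfg.sampling_rate)
    participants = [f"P{p + 1:03d}" for p in range(cfg.n_participants)]
    amplitudes = _draw_amplitudes(cfg, rng)
    deltas = amplitudes[:, :, 0] - amplitudes[:, :, 1]
    sd = deltas.std(axis=0, ddof=0)
    z = np.where(sd > 0, (deltas - deltas.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    z_tonic = rng.standard_normal(cfg.n_participants)
    return GroundTruth(
        kernels=kernels, kernel_step_ms=cfg.sample_step_ms,
        image_kernel=image_kernel, participants=participants,
        amplitudes=amplitudes, z_deltas=z, z_tonic=z_tonic,
        coupling=dict(cfg.coupling),
        stability_coupling=dict(cfg.stability_coupling))


def generate_pupil(events: pd.DataFrame, cfg: SimulationConfig,
                   rng: np.random.Generator
                   ) -> tuple[list[PupilRecording], GroundTruth]:
    """Render continuous pupil traces for every (participant, block).

    trace = participant mean + AR(1) tonic drift + sum over tone onsets of
    condition-amplitude-weighted kernels + a fixed image-evoked response +
    white noise; blinks are inserted as zero/invalid runs.
    """
    step = cfg.sample_step_ms
    gt = draw_ground_truth(cfg, rng)
    kernels, image_kernel = gt.kernels, gt.image_kernel
    n_epoch = kernels.shape[1]

    participants = sorted(events["participant"].unique())
    if participants != gt.participants:
        raise ValueError("event table participants do not match the configuration")
    p_index = {pid: i for i, pid in enumerate(participants)}
    amplitudes = gt.amplitudes

    tones = events[events["event_type"] == "tone"]
    blocks = sorted(set(zip(tones["participant"], tones["block"])))
    n_rows = len(blocks)
    row_index = {key: i for i, key in enumerate(blocks)}

    last_tone = int(tones["onset_ms"].max())
    n_samp = int(round((last_tone + EPOCH_MS + 1000) / step))
    time = (np.arange(n_samp) * step).round().astype(np.int64)

    p_means = cfg.participant_mean + cfg.participant_mean_sd * rng.standard_normal(
        len(participants))
    row_p = np.array([p_index[pid] for pid, _ in blocks])

    traces = np.empty((n_rows, n_samp), dtype=np.float32)
    traces[:] = p_means[row_p][:, None].astype(np.float32)

    if cfg.tonic_sd > 0:
        # the tonic process is slow by construction: generate the AR(1) on a
        # 20x decimated grid and linearly upsample (phi rescaled to keep the
        # same autocorrelation time and stationary sd)
        dec = 20
        n_dec = n_samp // dec + 2
        phi_d = cfg.tonic_ar1_phi ** dec
        # per-participant tonic scale (lognormal, unit mean)
        scale = cfg.tonic_sd * np.exp(
            cfg.tonic_cv * gt.z_tonic - 0.5 * cfg.tonic_cv ** 2)[row_p]
        innov = rng.standard_normal((n_rows, n_dec), dtype=np.float32)
        innov *= (scale * np.sqrt(1.0 - phi_d ** 2)).astype(np.float32)[:, None]
        innov[:, 0] = scale * rng.standard_normal(n_rows)
        tonic = signal.lfilter([np.float32(1.0)],
                               np.array([1.0, -phi_d], dtype=np.float32),
                               innov, axis=1)
        pos = np.arange(n_samp) / dec
        i0 = pos.astype(int)
        frac = (pos - i0).astype(np.float32)
        traces += tonic[:, i0] * (1.0 - frac) + tonic[:, i0 + 1] * frac
        del innov, tonic

    # per-row combined evoked waveform for each condition
    amp_rows = amplitudes[row_p]                                  # (rows, k, 2)
    wave = {
        "boundary": (amp_rows[:, :, 0] @ kernels).astype(np.float32),
        "same_context": (amp_rows[:, :, 1] @ kernels).astype(np.float32),
    }
    wave["list_first"] = (cfg.list_first_amplitude_scale *
                          wave["same_context"]).astype(np.float32)

    # all blocks share the same tone-onset grid
    n_tones = 32
    onsets = cfg.first_tone_ms + np.arange(n_tones) * cfg.trial_spacing_ms
    for j, on in enumerate(onsets):
        e, pos = j // 8 + 1, j % 8 + 1
        cond = tone_condition(e, pos)
        i0 = int(round(on / step))
        traces[:, i0:i0 + n_epoch] += wave[cond]
        im0 = int(round((on + cfg.tone_to_image_ms) / step))
        sl = traces[:, im0:im0 + n_epoch]
        sl += (cfg.image_amplitude * image_kernel[: sl.shape[1]]).astype(np.float32)

    if cfg.noise_sd > 0:
        noise = rng.standard_normal((n_rows, n_samp), dtype=np.float32)
        noise *= np.float32(cfg.noise_sd)
        traces += noise
        del noise

    valid = np.ones((n_rows, n_samp), dtype=bool)
    if cfg.blink_rate_per_min > 0:
        minutes = n_samp * step / 60000.0
        counts = rng.poisson(cfg.blink_rate_per_min * minutes, size=n_rows)
        for r in range(n_rows):
            starts = rng.integers(0, n_samp, size=counts[r])
            durs = np.maximum(rng.normal(cfg.blink_duration_mean_ms,
                                         cfg.blink_duration_sd_ms,
                                         size=counts[r]), step)
            for s, d in zip(starts, durs):
                stop = min(n_samp, s + int(round(d / step)))
                valid[r, s:stop] = False
                traces[r, s:stop] = 0.0

    recordings = []
    for (pid, b), r in sorted(row_index.items(), key=lambda kv: kv[1]):
        recordings.append(PupilRecording(
            participant_id=pid, block_id=int(b), sampling_rate=cfg.sampling_rate,
            time=time, pupil=traces[r], valid=valid[r]))

    return recordings, gt


# ---------------------------------------------------------------------------
# memory outcomes
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _coupling_term(gt: GroundTruth, measure: str) -> np.ndarray:
    out = np.zeros(len(gt.participants))
    for (comp, meas), gamma in gt.coupling.items():
        if meas == measure:
            out += gamma * gt.z_deltas[:, comp]
    return out


def generate_memory(pairs: pd.DataFrame, items: pd.DataFrame, gt: GroundTruth,
                    cfg: SimulationConfig, rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw order/distance/source outcomes with planted boundary effects.

    Couplings act on the boundary side only, so the participant-level
    boundary-minus-same-context delta inherits the term
    ``gamma_k * z_k`` on the relevant latent scale.
    """
    p_index = {pid: i for i, pid in enumerate(gt.participants)}
    nP = len(gt.participants)
    u_order = cfg.order_intercept_sd * rng.standard_normal(nP)
    u_dist = cfg.distance_intercept_sd * rng.standard_normal(nP)
    u_source = cfg.source_intercept_sd * rng.standard_normal(nP)
    gt.memory_intercepts = {"order": u_order, "distance": u_dist, "source": u_source}

    pi = pairs["participant"].map(p_index).to_numpy()
    is_b = (pairs["pair_condition"] == "boundary_span").to_numpy()

    def stab(measure):
        gamma = gt.stability_coupling.get(measure, 0.0)
        return gamma * gt.z_tonic if gamma else np.zeros(nP)

    logit = (cfg.order_base_logit + cfg.order_logit_boundary * is_b +
             u_order[pi] + _coupling_term(gt, "order")[pi] * is_b +
             stab("order")[pi])
    order_correct = (rng.random(len(pairs)) < _sigmoid(logit)).astype(int)

    latent = (cfg.distance_base + cfg.distance_shift_boundary * is_b +
              u_dist[pi] + _coupling_term(gt, "distance")[pi] * is_b +
              stab("distance")[pi] + rng.standard_normal(len(pairs)))
    rating = 1 + np.searchsorted(np.asarray(cfg.distance_cuts), latent, side="left")

    out_pairs = pairs.copy()
    out_pairs["order_correct"] = order_correct
    out_pairs["distance_rating"] = rating.astype(int)

    ii = items["participant"].map(p_index).to_numpy()
    item_b = (items["item_type"] == "boundary").to_numpy()
    s_logit = (cfg.source_base_logit + cfg.source_logit_boundary * item_b +
               u_source[ii] + _coupling_term(gt, "source")[ii] * item_b +
               stab("source")[ii])
    out_items = items.copy()
    out_items["source_correct"] = (rng.random(len(items)) < _sigmoid(s_logit)).astype(int)
    return out_pairs, out_items


def paper_like_config(target_distance_rho: float = 0.5,
                      **overrides) -> SimulationConfig:
    """Default preset with the qualitative coupling pattern of the study:
    early-peaking component -> distance expansion (positive, calibrated to a
    target population Spearman), slowly-decreasing component -> order
    impairment (negative), and lower tonic variability -> better order memory
    / more compressed distance."""
    from dataclasses import replace
    cfg = SimulationConfig(**overrides)
    gamma_d = distance_coupling_for_spearman(target_distance_rho, cfg)
    return replace(cfg,
                   coupling={(3, "distance"): gamma_d, (2, "order"): -0.25},
                   stability_coupling={"order": -0.4, "distance": 0.25})


def simulate(cfg: SimulationConfig, seed: int | None = None):
    """Run the full generator; returns (events, recordings, pairs, items, truth)."""
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    events, pair_sched, item_sched = generate_design(cfg, rng)
    recordings, gt = generate_pupil(events, cfg, rng)
    pairs, items = generate_memory(pair_sched, item_sched, gt, cfg, rng)
    return events, recordings, pairs, items, gt


# ---------------------------------------------------------------------------
# closed-form / numeric-integration oracles for the planted effects
# ---------------------------------------------------------------------------

def distance_rating_moments(mu: float, cuts) -> tuple[float, float]:
    """Mean and variance of the 1..4 rating for latent ``N(mu, 1)`` cut at ``cuts``."""
    c = np.asarray(cuts, dtype=float)
    cdf = norm.cdf(np.concatenate(([-np.inf], c, [np.inf])), loc=mu)
    probs = np.diff(cdf)
    ratings = np.arange(1, len(probs) + 1)
    mean = float(probs @ ratings)
    var = float(probs @ ratings ** 2 - mean ** 2)
    return mean, var


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def expected_accuracy(logit_mean: float, logit_sd: float) -> float:
    """E[sigmoid(x)] for x ~ N(logit_mean, logit_sd^2), by Gauss-Hermite."""
    x = logit_mean + logit_sd * _GH_NODES
    return float(_GH_WEIGHTS @ _sigmoid(x))


def expected_distance_spearman(gamma: float, cfg: SimulationConfig) -> float:
    """Population Spearman between a standardized planted amplitude delta and
    the realized distance delta, by numeric integration.

    The boundary latent mean is ``base + shift + gamma * z`` with ``z ~
    N(0,1)``; the participant delta averages ``3 * n_blocks`` boundary and
    ``4 * n_blocks`` same-context ratings.  The (z, delta) law is treated as
    bivariate-normal for the Pearson-to-Spearman map.
    """
    n_b, n_s = 3 * cfg.n_blocks, 4 * cfg.n_blocks
    z = _GH_NODES
    mu_b = cfg.distance_base + cfg.distance_shift_boundary + gamma * z
    means = np.array([distance_rating_moments(m, cfg.distance_cuts) for m in mu_b])
    m_s, v_s = distance_rating_moments(cfg.distance_base, cfg.distance_cuts)
    d = means[:, 0] - m_s
    e_d = float(_GH_WEIGHTS @ d)
    cov_zd = float(_GH_WEIGHTS @ (z * d))
    var_signal = float(_GH_WEIGHTS @ (d - e_d) ** 2)
    var_noise = float(_GH_WEIGHTS @ means[:, 1]) / n_b + v_s / n_s
    denom = np.sqrt(var_signal + var_noise)
    if denom == 0:
        return 0.0
    r = cov_zd / denom
    return float(6.0 / np.pi * np.arcsin(np.clip(r, -1, 1) / 2.0))


def distance_coupling_for_spearman(target_rho: float, cfg: SimulationConfig) -> float:
    """Latent coupling gamma achieving a target population Spearman rho
    between the component amplitude delta and the distance-rating delta."""
    if target_rho == 0:
        return 0.0
    f = lambda g: expected_distance_spearman(g, cfg) - target_rho
    lo, hi = sorted((1e-6 * np.sign(target_rho), 2.9 * np.sign(target_rho)))
    return float(brentq(f, lo, hi))
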