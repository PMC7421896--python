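"""Analysis and simulation configuration objects.

All time quantities are integer milliseconds from block start; windows are
half-open ``[start, stop)`` so that a 3000 ms window at 250 Hz contains
exactly 750 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

__all__ = ["AnalysisConfig", "SimulationConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check_window(name: str, window: tuple[int, int]) -> tuple[int, int]:
    a, b = int(window[0]), int(window[1])
    if b <= a:
        raise ConfigError(f"{name} must be a non-empty half-open interval, got {window!r}")
    return (a, b)


@dataclass(frozen=True)
class AnalysisConfig:
    """Fixed constants of the pupil analysis pipeline.

    Attributes
    ----------
    epoch_window_ms:
        Half-open window around each tone onset used for epoching.
    baseline_window_ms:
        Window (relative to tone onset) averaged to baseline-correct epochs.
    evoked_window_ms:
        Window whose mean defines the per-trial evoked dilation.
    min_valid_fraction:
        Blocks with a valid-sample fraction strictly below this are excluded.
    retention_rule:
        ``"mean_eigenvalue"`` keeps components with eigenvalue >= the mean of
        the positive spectrum (the covariance-metric Kaiser analogue);
        ``"unit_eigenvalue"`` keeps eigenvalues > 1 (correlation metric only).
    pca_window_ms:
        Length of the waveform submitted to the temporal PCA (3000 or 1500).
    """

    epoch_window_ms: tuple[int, int] = (0, 3000)
    baseline_window_ms: tuple[int, int] = (-500, 0)
    evoked_window_ms: tuple[int, int] = (1000, 2000)
    min_valid_fraction: float = 0.5
    retention_rule: str = "mean_eigenvalue"
    pca_window_ms: int = 3000
    score_method: str = "regression"
    velocity_mad_threshold: float = 5.0
    artifact_pad_ms: int = 50
    min_trials_per_cell: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epoch_window_ms", "baseline_window_ms", "evoked_window_ms"):
            object.__setattr__(self, name, _check_window(name, getattr(self, name)))
        e0, e1 = self.epoch_window_ms
        v0, v1 = self.evoked_window_ms
        if not (e0 <= v0 and v1 <= e1):
            raise ConfigError(
                f"evoked_window_ms {self.evoked_window_ms} must lie inside "
                f"epoch_window_ms {self.epoch_window_ms}"
            )
        if not (0.0 < self.min_valid_fraction <= 1.0):
            raise ConfigError("min_valid_fraction must be in (0, 1]")
        if self.retention_rule not in ("mean_eigenvalue", "unit_eigenvalue"):
            raise ConfigError(f"unknown retention_rule {self.retention_rule!r}")
        if self.pca_window_ms not in (3000, 1500):
            raise ConfigError("pca_window_ms must be 3000 or 1500")
        if self.score_method not in ("regression", "correlation"):
            raise ConfigError(f"unknown score_method {self.score_method!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown AnalysisConfig keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("epoch_window_ms", "baseline_window_ms", "evoked_window_ms"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


#: tone conditions used throughout the package
TONE_CONDITIONS = ("boundary", "same_context", "list_first")

#: source-test item types
ITEM_TYPES = ("boundary", "same_context", "first", "last")

#: admissible tone frequencies (Hz)
FREQUENCIES = (500, 600, 700, 800, 900, 1000)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic task / pupil / memory generator.

    Pupil traces are ``participant mean + AR(1) tonic drift + evoked kernels
    + white noise`` with blink dropouts; memory outcomes carry configurable
    boundary effects and cross-participant pupil-memory couplings.
    """

    n_participants: int = 65
    n_blocks: int = 14
    sampling_rate: float = 250.0
    lag: int = 2

    # trial timing (ms)
    first_tone_ms: int = 1000
    tone_to_image_ms: int = 1500
    trial_spacing_ms: int = 5500

    # planted evoked structure
    component_latencies_ms: tuple[float, ...] = (2424.0, 1316.0, 308.0, 800.0)
    component_widths_ms: tuple[float, ...] = (550.0, 380.0, 180.0, 160.0)
    #: per-component (boundary, same_context) mean amplitudes, arbitrary units
    amplitude_means: tuple[tuple[float, float], ...] = (
        (170.0, 130.0),
        (103.0, 75.0),
        (55.0, 40.0),
        (60.0, 60.0),
    )
    #: per-component cross-participant s.d. of the shared amplitude level
    amplitude_sds: tuple[float, ...] = (175.0, 90.0, 87.0, 80.0)
    #: per-component cross-participant s.d. of the boundary-minus-same delta
    amplitude_delta_sds: tuple[float, ...] = (60.0, 40.0, 20.0, 50.0)
    list_first_amplitude_scale: float = 1.0
    image_amplitude: float = 120.0
    image_latency_ms: float = 900.0
    image_width_ms: float = 500.0

    participant_mean: float = 4000.0
    participant_mean_sd: float = 300.0
    tonic_ar1_phi: float = 0.995
    tonic_sd: float = 4.0
    #: cross-participant lognormal spread of the tonic sd (0 = identical)
    tonic_cv: float = 0.3
    noise_sd: float = 25.0
    blink_rate_per_min: float = 4.0
    blink_duration_mean_ms: float = 150.0
    blink_duration_sd_ms: float = 40.0

    # memory generation
    order_base_logit: float = 0.85
    order_logit_boundary: float = -0.35
    order_intercept_sd: float = 0.35
    distance_base: float = 0.0
    distance_shift_boundary: float = 0.17
    distance_intercept_sd: float = 0.15
    distance_cuts: tuple[float, float, float] = (-1.0, 0.0, 1.0)
    source_base_logit: float = 0.6
    source_logit_boundary: float = 0.30
    source_intercept_sd: float = 0.35

    #: coupling gamma[(component_index, measure)] -> latent-scale coefficient;
    #: measure in {"order", "distance", "source"}; component_index is 0-based.
    coupling: Mapping[tuple[int, str], float] = field(default_factory=dict)
    #: latent-scale coupling of each memory measure to the participant's
    #: tonic-variability z (positive = more variability raises the latent)
    stability_coupling: Mapping[str, float] = field(default_factory=dict)

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_blocks < 1:
            raise ConfigError("n_participants and n_blocks must be >= 1")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if not (2 <= self.lag <= 4):
            raise ConfigError(
                f"lag {self.lag} incompatible with 8-item events: both a "
                "within-event pair and a boundary-spanning pair (plus the "
                "untested boundary/first/last items) must fit in events of 8"
            )
        k = len(self.component_latencies_ms)
        if not (len(self.component_widths_ms) == len(self.amplitude_means)
                == len(self.amplitude_sds) == len(self.amplitude_delta_sds) == k):
            raise ConfigError("component parameter tuples must have equal length")
        for lat in self.component_latencies_ms:
            if not (0 < lat < 3000):
                raise ConfigError(f"component latency {lat} outside the (0, 3000) ms epoch")
        for w in self.component_widths_ms:
            if w <= 0:
                raise ConfigError("component widths must be positive")
        for sd in (*self.amplitude_sds, *self.amplitude_delta_sds,
                   self.tonic_sd, self.noise_sd,
                   self.participant_mean_sd, self.order_intercept_sd,
                   self.distance_intercept_sd, self.source_intercept_sd):
            if sd < 0:
                raise ConfigError("standard deviations must be non-negative")
        if not (0.0 <= self.tonic_ar1_phi < 1.0):
            raise ConfigError("tonic_ar1_phi must be in [0, 1)")
        if list(self.distance_cuts) != sorted(self.distance_cuts):
            raise ConfigError("distance_cuts must be increasing")
        for (comp, measure), gamma in dict(self.coupling).items():
            if measure not in ("order", "distance", "source"):
                raise ConfigError(f"unknown coupling measure {measure!r}")
            if not (0 <= comp < k):
                raise ConfigError(f"coupling component index {comp} out of range")
            if abs(gamma) >= 3:
                raise ConfigError("coupling |gamma| must be < 3")
        for measure, gamma in dict(self.stability_coupling).items():
            if measure not in ("order", "distance", "source"):
                raise ConfigError(f"unknown stability coupling measure {measure!r}")
            if abs(gamma) >= 3:
                raise ConfigError("stability coupling |gamma| must be < 3")
        if self.tonic_cv < 0:
            raise ConfigError("tonic_cv must be non-negative")

    @property
    def n_components(self) -> int:
        return len(self.component_latencies_ms)

    @property
    def sample_step_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coupling"] = {f"{k[0]}:{k[1]}": v for k, v in dict(self.coupling).items()}
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        kwargs = dict(data)
        if "coupling" in kwargs and kwargs["coupling"]:
            coupling = {}
            for key, v in dict(kwargs["coupling"]).items():
                if isinstance(key, str):
                    comp, measure = key.split(":")
                    coupling[(int(comp), measure)] = float(v)
                else:
                    coupling[tuple(key)] = float(v)
            kwargs["coupling"] = coupling
        for key in ("component_latencies_ms", "component_widths_ms",
                    "amplitude_sds", "amplitude_delta_sds", "distance_cuts"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "amplitude_means" in kwargs:
            kwargs["amplitude_means"] = tuple(tuple(r) for r in kwargs["amplitude_means"])
        return cls(**kwargs)
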