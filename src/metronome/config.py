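"""Task and analysis configuration.

All trial-relative times are in milliseconds with zero at the onset of the
first entrainment stimulus; epochs are half-open ``[onset, offset)``.  The
task crosses tempo (interval duration) x start side x go-cue interval; the
analysis constants (bands, window sizes, burst criteria, classifier scheme)
live in :class:`AnalysisConfig` so every stage reads from one place.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its invariants."""


@dataclass(frozen=True)
class TaskConfig:
    """Structure of the visual-metronome task.

    Parameters
    ----------
    tempos_ms:
        Interval durations of the metronome.  The standard task uses
        500, 750 and 1000 ms, pseudo-randomly interleaved.
    n_entrainment:
        Number of visible (entrainment) intervals; 3 in the standard task.
    max_maintenance:
        Maximum number of internally-maintained intervals; the go-cue falls
        in one of these (1..max), uniformly.
    go_cue_fraction:
        Position of the go-cue within its maintenance interval (0.5 = middle).
    baseline_ms:
        Length of the pre-trial baseline used for spectral normalization.
    """

    tempos_ms: tuple[float, ...] = (500.0, 750.0, 1000.0)
    n_entrainment: int = 3
    max_maintenance: int = 4
    go_cue_fraction: float = 0.5
    baseline_ms: float = 500.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tempos_ms", tuple(float(t) for t in self.tempos_ms))
        if len(self.tempos_ms) == 0:
            raise ConfigError("tempos_ms must be non-empty")
        if any(t <= 0 for t in self.tempos_ms):
            raise ConfigError("tempos_ms must be positive")
        if not 0.0 < self.go_cue_fraction < 1.0:
            raise ConfigError("go_cue_fraction must lie in (0, 1)")
        if self.n_entrainment < 1:
            raise ConfigError("n_entrainment must be >= 1")
        if self.max_maintenance < 1:
            raise ConfigError("max_maintenance must be >= 1")
        if self.baseline_ms <= 0:
            raise ConfigError("baseline_ms must be positive")


@dataclass(frozen=True)
class AnalysisConfig:
    """Fixed constants shared by the analysis stages.

    Bands are inclusive on both edges and membership is decided by bin
    center.  The spectrogram uses a single Slepian taper whose
    time-bandwidth product is implied by ``bandwidth_hz`` (half-bandwidth)
    over ``spectrogram_window_ms``.
    """

    gamma_band_hz: tuple[float, float] = (30.0, 40.0)
    alpha_band_hz: tuple[float, float] = (6.0, 10.0)
    beta_band_hz: tuple[float, float] = (15.0, 24.0)
    spectrogram_window_ms: float = 200.0
    spectrogram_step_ms: float = 5.0
    spectrogram_fmin_hz: float = 5.0
    spectrogram_fmax_hz: float = 80.0
    n_tapers: int = 1
    bandwidth_hz: float = 5.0
    burst_percentile: float = 90.0
    burst_min_dur_ms: float = 100.0
    sta_halfwidth_ms: float = 100.0
    jitter_halfwidth_ms: float = 15.0
    n_permutations: int = 1000
    bins_per_interval: int = 10
    sliding_window_bins: int = 5
    holdout_per_class: int = 50
    n_iterations: int = 100
    distance_bins: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spectrogram_window_ms", "spectrogram_step_ms",
                     "burst_min_dur_ms", "sta_halfwidth_ms", "bandwidth_hz"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 < self.burst_percentile < 100.0:
            raise ConfigError("burst_percentile must lie in (0, 100)")
        for name in ("gamma_band_hz", "alpha_band_hz", "beta_band_hz"):
            lo, hi = getattr(self, name)
            if not 0.0 < lo < hi:
                raise ConfigError(f"{name} must satisfy 0 < low < high")

    @property
    def bands(self) -> dict[str, tuple[float, float]]:
        return {"alpha": self.alpha_band_hz, "beta": self.beta_band_hz,
                "gamma": self.gamma_band_hz}


def _apply_overrides(cls, base, overrides: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return dataclasses.replace(base, **overrides)


def load_config(path=None, overrides: dict | None = None
                ) -> tuple[TaskConfig, AnalysisConfig]:
    """Read a YAML config file with optional ``task:`` / ``analysis:`` groups.

    ``overrides`` (e.g. from CLI flags) take precedence over file values.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    overrides = overrides or {}
    task = _apply_overrides(TaskConfig, TaskConfig(), {**raw.get("task", {}),
                                                      **overrides.get("task", {})})
    analysis = _apply_overrides(AnalysisConfig, AnalysisConfig(),
                                {**raw.get("analysis", {}),
                                 **overrides.get("analysis", {})})
    return task, analysis


def dump_config(task: TaskConfig, analysis: AnalysisConfig, path) -> None:
    data = {"task": dataclasses.asdict(task),
            "analysis": dataclasses.asdict(analysis)}
    data["task"]["tempos_ms"] = list(task.tempos_ms)
    for key in ("gamma_band_hz", "alpha_band_hz", "beta_band_hz"):
        data["analysis"][key] = list(getattr(analysis, key))
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
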