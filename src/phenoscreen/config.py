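"""Typed run configuration with strict YAML round-tripping.

Every analysis stage takes a small frozen dataclass of parameters.  The
:class:`RunConfig` document bundles them for whole-pipeline runs; it parses
from YAML with unknown keys rejected (naming the offending path) and
serialises back to the identical canonical form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Canonical order of the three recording windows.
WINDOW_TAGS = ("prestim", "bluelight", "poststim")


class ConfigError(ValueError):
    """A configuration document is structurally or semantically invalid."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of the three-segment recording and the blue-light pulses.

    The default protocol is a 16-minute assay: 5 min pre-stimulus baseline,
    6 min with three 10-s high-intensity blue-light pulses (onsets 60, 170
    and 280 s into the segment, i.e. 100 s gap between pulses), and a 5 min
    post-stimulus recovery segment, recorded at 25 frames per second.
    """

    segment_durations: tuple[float, float, float] = (300.0, 360.0, 300.0)
    pulse_starts: tuple[float, ...] = (60.0, 170.0, 280.0)
    pulse_duration: float = 10.0
    fps: float = 25.0

    def __post_init__(self) -> None:
        _require(len(self.segment_durations) == 3, "segment_durations must have 3 entries")
        _require(all(d > 0 for d in self.segment_durations), "segment durations must be > 0")
        _require(self.pulse_duration > 0, "pulse_duration must be > 0")
        _require(self.fps > 0, "fps must be > 0")
        starts = self.pulse_starts
        _require(all(b > a for a, b in zip(starts, starts[1:])),
                 "pulse_starts must be strictly increasing")
        blue = self.segment_durations[1]
        for s in starts:
            _require(0.0 <= s and s + self.pulse_duration <= blue,
                     f"pulse at {s} s does not lie wholly inside the blue-light segment")

    @property
    def prestim_duration(self) -> float:
        return self.segment_durations[0]

    @property
    def bluelight_duration(self) -> float:
        return self.segment_durations[1]

    @property
    def poststim_duration(self) -> float:
        return self.segment_durations[2]

    @property
    def total_duration(self) -> float:
        return float(sum(self.segment_durations))

    def pulse_onsets_absolute(self) -> tuple[float, ...]:
        """Pulse onset times in seconds from the start of the recording."""
        return tuple(self.prestim_duration + s for s in self.pulse_starts)

    def n_frames(self) -> int:
        return int(round(self.total_duration * self.fps))


@dataclass(frozen=True)
class ResponseWindowSpec:
    """Pulse-aligned scalar windows: width 10 s, centred 5 s before and
    10 s / 20 s after pulse onset (before / response / after)."""

    window_width: float = 10.0
    centre_offsets: tuple[float, float, float] = (-5.0, 10.0, 20.0)

    def __post_init__(self) -> None:
        _require(self.window_width > 0, "window_width must be > 0")
        _require(len(self.centre_offsets) == 3, "centre_offsets must have 3 entries")

    def intervals(self, pulse_onset: float) -> list[tuple[float, float]]:
        """Half-open [start, stop) intervals in absolute seconds."""
        half = self.window_width / 2.0
        return [(pulse_onset + c - half, pulse_onset + c + half) for c in self.centre_offsets]


@dataclass(frozen=True)
class SkeletonFilterSpec:
    """Plausibility bounds for tracked worm skeletons (µm), inclusive."""

    length_bounds: tuple[float, float] = (700.0, 1300.0)
    width_bounds: tuple[float, float] = (20.0, 200.0)

    def __post_init__(self) -> None:
        _require(self.length_bounds[0] < self.length_bounds[1], "length bounds must satisfy lower < upper")
        _require(self.width_bounds[0] < self.width_bounds[1], "width bounds must satisfy lower < upper")


@dataclass(frozen=True)
class StatsConfig:
    """Parameters of the day-blocked permutation test.

    n_permutations
        Monte-Carlo sample size B for the within-day label shuffles.
    fdr_q
        Benjamini–Yekutieli false-discovery-rate level.
    statistic
        ``pooled_t`` (equal-variance two-sample t) or ``welch_t``.
    min_finite_per_group
        A feature is skipped when either group has fewer finite values.
    """

    n_permutations: int = 100_000
    fdr_q: float = 0.05
    statistic: str = "pooled_t"
    min_finite_per_group: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_permutations >= 1, "n_permutations must be >= 1")
        _require(0.0 < self.fdr_q < 1.0, "fdr_q must lie in (0, 1)")
        _require(self.statistic in ("pooled_t", "welch_t"),
                 f"unknown statistic {self.statistic!r}")
        _require(self.min_finite_per_group >= 1, "min_finite_per_group must be >= 1")


@dataclass(frozen=True)
class PhenospaceOptions:
    n_components: int = 2
    linkage_method: str = "average"
    metric: str = "euclidean"
    recovery_threshold: float = 0.5
    error_bars: str = "sd"  # "sd" or "sem"

    def __post_init__(self) -> None:
        _require(self.n_components >= 1, "n_components must be >= 1")
        _require(self.error_bars in ("sd", "sem"), "error_bars must be 'sd' or 'sem'")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative model parameters for the synthetic screen.

    Well entries follow ``y = mu_f + beta_{strain,f} + shift_w + delta_{day,f}
    + eps`` with ``delta ~ N(0, sigma_day^2)`` shared by all wells tracked on
    the same day and ``eps ~ N(0, sigma_well^2)`` per well and window.
    ``effect_size_dist`` draws standardized effects (units of sigma_well);
    ``window_shift_spec`` gives additive per-window shifts in feature units.
    """

    n_strains: int = 2
    wells_per_strain_per_day: int = 5
    n_days: int = 3
    worms_per_well: tuple[int, int] = (3, 5)
    n_features_per_window: int = 2763
    affected_fraction: float = 0.1
    effect_size_dist: Mapping[str, Any] = field(
        default_factory=lambda: {"name": "normal", "mean": 0.0, "sd": 2.0})
    sigma_day: float = 0.5
    sigma_well: float = 1.0
    nan_rate: float = 0.05
    day_assignment: str = "balanced"
    confound_overlap: float = 0.34
    noise_df: int | None = None
    window_shift_spec: Mapping[str, float] = field(
        default_factory=lambda: {"prestim": 0.0, "bluelight": 1.0, "poststim": 0.25})
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_strains", "wells_per_strain_per_day", "n_days", "n_features_per_window"):
            _require(getattr(self, name) >= 1, f"{name} must be >= 1")
        _require(self.n_strains >= 1, "n_strains must be >= 1")
        lo, hi = self.worms_per_well
        _require(1 <= lo <= hi, "worms_per_well must be an increasing range of counts >= 1")
        for name in ("affected_fraction", "nan_rate", "confound_overlap"):
            _require(0.0 <= getattr(self, name) <= 1.0, f"{name} must lie in [0, 1]")
        _require(self.sigma_day >= 0.0, "sigma_day must be >= 0")
        _require(self.sigma_well >= 0.0, "sigma_well must be >= 0")
        _require(self.day_assignment in ("balanced", "confounded"),
                 f"day_assignment must be 'balanced' or 'confounded', got {self.day_assignment!r}")
        if self.noise_df is not None:
            _require(self.noise_df >= 1, "noise_df must be >= 1")
        unknown = set(self.window_shift_spec) - set(WINDOW_TAGS)
        _require(not unknown, f"window_shift_spec has unknown window(s): {sorted(unknown)}")
        _require(isinstance(self.effect_size_dist, Mapping) and "name" in self.effect_size_dist,
                 "effect_size_dist must be a mapping with a 'name' entry")


@dataclass(frozen=True)
class RunConfig:
    """One document bundling every stage's parameters plus output options."""

    stats: StatsConfig = field(default_factory=StatsConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    response_windows: ResponseWindowSpec = field(default_factory=ResponseWindowSpec)
    skeleton_filter: SkeletonFilterSpec = field(default_factory=SkeletonFilterSpec)
    phenospace: PhenospaceOptions = field(default_factory=PhenospaceOptions)
    output_dir: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return _to_plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        return _from_mapping(cls, data, path="")


_SUBCONFIGS: dict[str, type] = {
    "stats": StatsConfig,
    "simulation": SimulationConfig,
    "protocol": StimulusProtocol,
    "response_windows": ResponseWindowSpec,
    "skeleton_filter": SkeletonFilterSpec,
    "phenospace": PhenospaceOptions,
}

# dataclass fields whose YAML list form must become a tuple
_TUPLE_FIELDS = {
    "segment_durations", "pulse_starts", "centre_offsets",
    "length_bounds", "width_bounds", "worms_per_well",
}


def _from_mapping(cls: type, data: Mapping[str, Any], path: str) -> Any:
    label = path or cls.__name__
    if not isinstance(data, Mapping):
        raise ConfigError(f"{label}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in names:
            where = f"{path}.{key}" if path else str(key)
            raise ConfigError(f"unknown configuration key: {where!r}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        sub = _SUBCONFIGS.get(key) if cls is RunConfig else None
        if sub is not None:
            kwargs[key] = _from_mapping(sub, value, path=f"{path}.{key}" if path else key)
        elif key in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:  # wrong arity / types surfaced with location
        raise ConfigError(f"{label}: {exc}") from exc


def _to_plain(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration, rejecting unknown keys."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return RunConfig.from_dict(data)


def dump_run_config(config: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration as canonical YAML (LF, sorted keys)."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)
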