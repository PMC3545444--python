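"""Synthetic trajectories, intensity traces, length and dwell populations.

Generates inputs with the statistical structure the analysis chain assumes,
so every stage is testable without recorded microscopy data:

* 2-D tracks with piecewise-constant velocity, Gaussian localization noise,
  and optional breakage events at which the speed transiently rises and the
  paired fluorescence intensity steps to ~2x its baseline (a dragged
  actin fragment entering the spot);
* lognormal filament-length populations parameterized by their median,
  with a paired post-fragmentation sample at a scaled median;
* exponential attachment-dwell populations whose survival beyond any
  cutoff is known in closed form.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinetics import InvalidParameterError
from .track_analysis import LengthSample, Track

__all__ = [
    "TrackGenSpec",
    "LengthGenSpec",
    "gen_tracks",
    "gen_track_with_breakage",
    "gen_lengths",
    "gen_dwell_population",
]


@dataclass(frozen=True)
class TrackGenSpec:
    """Parameters of the trajectory/intensity generator.

    Frame interval 0.2-0.4 s and speeds of tens of nm/s mirror typical
    TIRF acquisitions of myofilaments on membrane-bound actin.
    """

    n_tracks: int = 20
    dt: float = 0.2  # s, frame interval
    base_speed: float = 0.05  # um/s
    accel_rate: float = 0.05  # breakage/acceleration events per s
    accel_magnitude: float = 3.0  # transient speed multiplier
    accel_duration: float = 1.0  # s
    position_noise_sd: float = 0.02  # um
    duration_mean: float = 8.0  # s, exponential attachment duration
    min_duration: float = 1.0  # s, floor so every track is analyzable
    turn_interval: float = 4.0  # s, mean time between heading changes
    intensity_baseline: float = 100.0
    intensity_noise_sd: float = 4.0
    intensity_step_factor: float = 2.0  # post-breakage intensity multiple
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "n_tracks",
            "dt",
            "base_speed",
            "accel_magnitude",
            "accel_duration",
            "duration_mean",
            "min_duration",
            "turn_interval",
            "intensity_baseline",
            "intensity_step_factor",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        for name in ("accel_rate", "position_noise_sd", "intensity_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not 0.2 - 1e-12 <= self.dt <= 0.4 + 1e-12:
            raise InvalidParameterError("dt must lie in [0.2, 0.4] s")


@dataclass(frozen=True)
class LengthGenSpec:
    """Lognormal length population: ``median`` um, log-scale sd, size n."""

    median: float = 0.56
    log_sd: float = 0.5
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.median <= 0 or self.log_sd <= 0 or self.n < 1:
            raise InvalidParameterError("need median > 0, log_sd > 0, n >= 1")


def _gen_one_track(spec: TrackGenSpec, rng: np.random.Generator, track_id: int) -> Track:
    n_frames = max(
        int(round(spec.min_duration / spec.dt)) + 1,
        int(round(rng.exponential(spec.duration_mean) / spec.dt)) + 1,
    )
    t = np.arange(n_frames) * spec.dt
    # heading changes at exponential intervals -> piecewise-constant velocity
    heading = rng.uniform(0, 2 * math.pi)
    speed_factor = np.ones(n_frames)
    intensity_factor = np.ones(n_frames)
    # breakage/acceleration events (Poisson in time)
    n_events = rng.poisson(spec.accel_rate * t[-1]) if t[-1] > 0 else 0
    event_times = np.sort(rng.uniform(0, t[-1], size=n_events))
    for et in event_times:
        speed_factor[(t >= et) & (t < et + spec.accel_duration)] *= spec.accel_magnitude
        intensity_factor[t >= et] *= spec.intensity_step_factor
    vx = np.empty(n_frames)
    vy = np.empty(n_frames)
    next_turn = rng.exponential(spec.turn_interval)
    for i, ti in enumerate(t):
        if ti >= next_turn:
            heading = rng.uniform(0, 2 * math.pi)
            next_turn = ti + rng.exponential(spec.turn_interval)
        v = spec.base_speed * speed_factor[i]
        vx[i] = v * math.cos(heading)
        vy[i] = v * math.sin(heading)
    x = np.concatenate([[0.0], np.cumsum(vx[:-1] * spec.dt)])
    y = np.concatenate([[0.0], np.cumsum(vy[:-1] * spec.dt)])
    if spec.position_noise_sd > 0:
        x = x + rng.normal(0, spec.position_noise_sd, n_frames)
        y = y + rng.normal(0, spec.position_noise_sd, n_frames)
    intensity = spec.intensity_baseline * intensity_factor
    if spec.intensity_noise_sd > 0:
        intensity = intensity + rng.normal(0, spec.intensity_noise_sd, n_frames)
    return Track(t=t, x=x, y=y, intensity=intensity, track_id=track_id)


def gen_tracks(spec: TrackGenSpec) -> list[Track]:
    """Generate ``spec.n_tracks`` trajectories with paired intensity traces."""
    rng = np.random.default_rng(spec.seed)
    return [_gen_one_track(spec, rng, i) for i in range(spec.n_tracks)]


def gen_track_with_breakage(
    spec: TrackGenSpec, event_time: float, n_frames: int, track_id: int = 0
) -> Track:
    """One track with a single breakage at a prescribed time (for paired tests)."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(n_frames) * spec.dt
    if not (t[0] < event_time < t[-1]):
        raise InvalidParameterError("event_time must fall inside the track")
    heading = rng.uniform(0, 2 * math.pi)
    speed = np.full(n_frames, spec.base_speed)
    speed[(t >= event_time) & (t < event_time + spec.accel_duration)] *= spec.accel_magnitude
    x = np.concatenate([[0.0], np.cumsum(speed[:-1] * math.cos(heading) * spec.dt)])
    y = np.concatenate([[0.0], np.cumsum(speed[:-1] * math.sin(heading) * spec.dt)])
    if spec.position_noise_sd > 0:
        x = x + rng.normal(0, spec.position_noise_sd, n_frames)
        y = y + rng.normal(0, spec.position_noise_sd, n_frames)
    intensity = np.where(
        t > event_time,
        spec.intensity_baseline * spec.intensity_step_factor,
        spec.intensity_baseline,
    ).astype(float)
    if spec.intensity_noise_sd > 0:
        intensity = intensity + rng.normal(0, spec.intensity_noise_sd, n_frames)
    return Track(t=t, x=x, y=y, intensity=intensity, track_id=track_id)


def gen_lengths(
    spec: LengthGenSpec, scale_factor: float = 0.5
) -> tuple[LengthSample, LengthSample]:
    """Lognormal length sample plus a paired post-fragmentation sample.

    The second sample's median is ``scale_factor`` times the first's
    (default 0.5: filaments shortened on average to half their length).
    """
    if scale_factor <= 0:
        raise InvalidParameterError("scale_factor must be > 0")
    rng = np.random.default_rng(spec.seed)
    mu = math.log(spec.median)
    before = rng.lognormal(mu, spec.log_sd, spec.n)
    after = rng.lognormal(mu + math.log(scale_factor), spec.log_sd, spec.n)
    return (
        LengthSample(before, label="before fragmentation"),
        LengthSample(after, label="after fragmentation"),
    )


def gen_dwell_population(rate: float, n: int, seed: int = 0) -> np.ndarray:
    """Exponential attachment durations (s) with detachment ``rate`` (1/s).

    The survival beyond a cutoff c is exp(-rate*c) in closed form, which
    pins down the expected retention of any minimum-dwell filter.
    """
    if rate <= 0 or n < 1:
        raise InvalidParameterError("need rate > 0 and n >= 1")
    rng = np.random.default_rng(seed)
    return rng.exponential(1.0 / rate, n)
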