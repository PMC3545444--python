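"""Analysis of 2-D motor trajectories, intensity traces and length samples.

Mirrors the standard single-particle post-processing chain for TIRF
tracking data: radial (speed) estimation over an n-frame span, sliding
average smoothing, a minimum-dwell filter that removes transient binders,
median/quartile summaries of filament-length populations, and the
before/after intensity ratio around a filament-breakage event.

Tracks travel as tidy TSV with columns ``track_id, frame, t, x, y``
(positions in um, time in s) and an optional ``intensity`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .kinetics import InvalidParameterError

__all__ = [
    "Track",
    "LengthSample",
    "radial_velocity",
    "sliding_average",
    "dwell_filter",
    "DwellFilterResult",
    "length_stats",
    "LengthStats",
    "breakage_intensity_ratio",
    "read_tracks",
    "write_tracks",
]

#: Default radial-velocity span (frames) and sampling interval (s).
DEFAULT_N = 20
DEFAULT_DT = 0.2
#: Default minimum dwell time retained by the filter (s).
DEFAULT_MIN_DWELL = 0.9


@dataclass(frozen=True)
class Track:
    """One trajectory sampled at uniform intervals.

    ``t`` in s, ``x``/``y`` in um; ``intensity`` (arbitrary units) is an
    optional paired fluorescence trace of the same length.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray | None = None
    track_id: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if len(t) < 2:
            raise InvalidParameterError("a track needs at least 2 samples")
        if not (len(t) == len(x) == len(y)):
            raise InvalidParameterError("t, x, y must have equal length")
        steps = np.diff(t)
        if np.any(np.abs(steps - steps[0]) > 1e-9):
            raise InvalidParameterError("sampling must be uniform within 1e-9 s")
        inten = self.intensity
        if inten is not None:
            inten = np.asarray(inten, dtype=float)
            if len(inten) != len(t):
                raise InvalidParameterError("intensity must match track length")
        for name, val in (("t", t), ("x", x), ("y", y), ("intensity", inten)):
            object.__setattr__(self, name, val)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class LengthSample:
    """A population of filament lengths (um) with a free-text label."""

    lengths: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        if len(lengths) < 1:
            raise InvalidParameterError("need at least one length")
        if np.any(lengths <= 0):
            raise InvalidParameterError("lengths must be > 0")
        object.__setattr__(self, "lengths", lengths)


def radial_velocity(track: Track, n: int = DEFAULT_N, dt: float | None = None) -> np.ndarray:
    """Radial speed series v_t = |r_{t+n dt} - r_t| / (n dt), um/s.

    The displacement is the straight-line (chord) distance over a span of
    ``n`` frames; the output has ``len(track) - n`` samples.  ``n = 20``
    frames at 0.2 s suppresses localization noise at the expense of
    temporal resolution.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if len(track.t) <= n:
        raise InvalidParameterError(f"track must be longer than n={n} samples")
    if dt is None:
        dt = track.dt
    dx = track.x[n:] - track.x[:-n]
    dy = track.y[n:] - track.y[:-n]
    return np.hypot(dx, dy) / (n * dt)


def sliding_average(
    series: Sequence[float], window: float = 2.0, dt: float = DEFAULT_DT
) -> np.ndarray:
    """Centered moving mean over a time window (s), shrinking at the edges."""
    if window < dt:
        raise InvalidParameterError("window must be >= dt")
    k = max(1, round(window / dt))
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(window=k, center=True, min_periods=1).mean().to_numpy()


class DwellFilterResult(NamedTuple):
    retained: list
    n_removed: int


def dwell_filter(
    tracks: Iterable[Track], min_dwell: float = DEFAULT_MIN_DWELL
) -> DwellFilterResult:
    """Keep tracks whose duration is at least ``min_dwell`` seconds.

    Removes transiently bound motors (default cutoff 0.9 s); the boundary
    is inclusive.
    """
    if min_dwell < 0:
        raise InvalidParameterError("min_dwell must be >= 0")
    tracks = list(tracks)
    retained = [tr for tr in tracks if tr.duration >= min_dwell]
    return DwellFilterResult(retained, len(tracks) - len(retained))


class LengthStats(NamedTuple):
    median: float
    p25: float
    p75: float


def length_stats(sample: LengthSample) -> LengthStats:
    """Median and quartiles of a length population (linear interpolation)."""
    q25, q50, q75 = np.percentile(sample.lengths, [25, 50, 75])
    return LengthStats(float(q50), float(q25), float(q75))


def breakage_intensity_ratio(
    track: Track,
    event_time: float,
    pre_window: float = 1.0,
    post_window: float = 1.0,
    background: float = 0.0,
) -> float:
    """Mean intensity after a breakage event over the mean before it.

    Intensity roughly doubles when a broken-off actin fragment is dragged
    into the myofilament area, so the expected ratio at a true breakage is
    ~2.  ``background`` is subtracted from both means first.
    """
    if track.intensity is None:
        raise InvalidParameterError("track has no intensity trace")
    t = track.t
    if not (t[0] <= event_time <= t[-1]):
        raise InvalidParameterError("event_time outside track")
    if event_time - pre_window < t[0] - 1e-9 or event_time + post_window > t[-1] + 1e-9:
        raise InvalidParameterError("analysis windows do not fit within the track")
    pre = (t >= event_time - pre_window) & (t < event_time)
    post = (t > event_time) & (t <= event_time + post_window)
    if not pre.any() or not post.any():
        raise InvalidParameterError("empty analysis window")
    pre_mean = float(track.intensity[pre].mean()) - background
    post_mean = float(track.intensity[post].mean()) - background
    if pre_mean <= 0:
        raise InvalidParameterError("non-positive background-subtracted pre-event mean")
    return post_mean / pre_mean


def write_tracks(tracks: Iterable[Track], path: str | Path) -> None:
    """Write tracks as tidy TSV (track_id, frame, t, x, y[, intensity])."""
    frames = []
    for tr in tracks:
        df = pd.DataFrame(
            {"track_id": tr.track_id, "frame": np.arange(len(tr.t)), "t": tr.t, "x": tr.x, "y": tr.y}
        )
        if tr.intensity is not None:
            df["intensity"] = tr.intensity
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_tracks(path: str | Path) -> list[Track]:
    """Read tracks from the tidy TSV dialect written by :func:`write_tracks`."""
    df = pd.read_csv(path, sep="\t")
    required = {"track_id", "frame", "t", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"track file missing column(s): {sorted(missing)}")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        inten = g["intensity"].to_numpy() if "intensity" in g.columns else None
        tracks.append(
            Track(
                t=g["t"].to_numpy(),
                x=g["x"].to_numpy(),
                y=g["y"].to_numpy(),
                intensity=inten,
                track_id=int(tid),
            )
        )
    return tracks
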