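"""Synthetic device/browser timing emulator.

Web applications presenting visual stimuli are at the mercy of the display
refresh cycle (a frame lasts 1000/refresh_hz ms, 16.67 ms at the common
60 Hz) and of the browser's event loop.  This module renders experiment
schedules into the two data streams an external-chronometry rig produces:

* a *sensor trace* -- luminance sampled at a few kHz by an optical sensor
  aimed at the screen, from which realized stimulus durations are recovered;
* *trial logs* -- the timestamps the web application itself records
  (internal chronometry), which may disagree with the sensor.

A :class:`DeviceProfile` parameterizes how a device/browser pair distorts
timing: the distribution of *frame differences* (realized minus requested
frames), systematic single-frame overshoots of CSS-animation timing, the
collapse of brief requests to a single frame seen on some browsers,
additive response-time (RT) overestimation (constant plus a two-component
Gaussian mixture), and quantization of measured RTs to the refresh lattice.

Everything is deterministic given a seed, so downstream pipelines can be
tested end to end without any recorded data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameDist",
    "DeviceProfile",
    "PresentationSchedule",
    "RTSchedule",
    "SensorTrace",
    "ProfileError",
    "METHOD_COMBOS",
    "REQUESTED_FRAMES",
    "RAF_MEASURES",
    "ANIM_MEASURES",
    "RT_MEASURES",
    "PRESETS",
    "build_profile",
    "generate_presentation_schedule",
    "generate_rt_schedule",
    "render_trace",
    "render_rt_session",
]

#: The five (timing, presentation) method combinations under test.
METHOD_COMBOS: tuple[tuple[str, str], ...] = (
    ("css", "background"),
    ("css", "opacity"),
    ("raf", "background"),
    ("raf", "canvas"),
    ("raf", "opacity"),
)

#: Requested stimulus durations in frames (16.67, 50, 100, 250, 500 ms at 60 Hz).
REQUESTED_FRAMES: tuple[int, ...] = (1, 3, 6, 15, 30)

#: Internal duration measures available for every timing method.
RAF_MEASURES: tuple[str, ...] = (
    "raf_before_created",
    "raf_before_called",
    "raf_after_created",
    "raf_after_called",
)

#: Extra internal duration measures available only for CSS-animation timing.
ANIM_MEASURES: tuple[str, ...] = ("anim_created", "anim_called")

#: Internal RT measures (when the response event was created vs. handled).
RT_MEASURES: tuple[str, ...] = ("event_created", "event_called")


class ProfileError(ValueError):
    """A device profile or schedule violates its invariants."""


@dataclass(frozen=True)
class FrameDist:
    """Probability distribution over integer frame offsets."""

    support: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.support) != len(self.probs) or not self.support:
            raise ProfileError("support and probs must be nonempty and equal length")
        if any(p < 0 for p in self.probs):
            raise ProfileError("probabilities must be nonnegative")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ProfileError(f"probabilities must sum to 1, got {sum(self.probs)}")

    @classmethod
    def delta(cls, value: int = 0) -> "FrameDist":
        return cls((int(value),), (1.0,))

    @classmethod
    def from_dict(cls, d: Mapping[int, float]) -> "FrameDist":
        items = sorted(d.items())
        return cls(tuple(int(k) for k, _ in items), tuple(float(v) for _, v in items))

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.support, self.probs))

    def sample(self, rng: np.random.Generator, size=None):
        return rng.choice(np.asarray(self.support), size=size, p=np.asarray(self.probs))


# Lookup keys for frame_diff_dist, most specific first.
_DistKey = tuple


@dataclass(frozen=True)
class DeviceProfile:
    """Parametric description of one device/browser timing behavior.

    ``frame_diff_dist`` maps ``(timing, presentation, requested_frames)``,
    ``(timing, presentation)``, ``(timing,)`` or ``"default"`` to a
    :class:`FrameDist`; the most specific matching key wins.  RT
    overestimation is ``rt_offset_constant_ms`` plus one draw from an
    equal-weight two-component Gaussian mixture ``N(0, sd1)`` / ``N(mean2,
    sd2)``; ``rt_quantize_hz`` optionally snaps measured RTs onto the
    corresponding lattice.
    """

    name: str
    refresh_hz: float = 60.0
    sample_hz: float = 3000.0
    frame_diff_dist: Mapping[_DistKey, FrameDist] = field(default_factory=dict)
    css_plus_one: bool = False
    short_presentation_bug: bool = False
    short_bug_prob: float = 0.7
    omit_prob: float = 0.0
    rt_offset_constant_ms: float = 0.0
    rt_offset_mix: tuple[float, float, float] = (0.0, 0.0, 0.0)  # sd1, sd2, mean2
    rt_quantize_hz: float | None = None
    internal_error_dists: Mapping[str, FrameDist] = field(default_factory=dict)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.refresh_hz <= 0:
            raise ProfileError("refresh_hz must be positive")
        if self.sample_hz < 2 * self.refresh_hz:
            raise ProfileError("sample_hz must be at least twice refresh_hz")
        for key, dist in self.frame_diff_dist.items():
            if not isinstance(dist, FrameDist):
                raise ProfileError(f"frame_diff_dist[{key!r}] is not a FrameDist")
        sd1, sd2, mean2 = self.rt_offset_mix
        if min(sd1, sd2, mean2, self.rt_offset_constant_ms) < 0:
            raise ProfileError("RT offset parameters must be nonnegative")
        if not (0.0 <= self.omit_prob <= 1.0 and 0.0 <= self.short_bug_prob <= 1.0):
            raise ProfileError("probabilities must lie in [0, 1]")
        if self.rt_quantize_hz is not None and self.rt_quantize_hz <= 0:
            raise ProfileError("rt_quantize_hz must be positive when set")

    @property
    def frame_ms(self) -> float:
        return 1000.0 / self.refresh_hz

    def frame_diff_dist_for(self, timing: str, presentation: str, frames: int) -> FrameDist:
        for key in ((timing, presentation, frames), (timing, presentation), (timing,)):
            if key in self.frame_diff_dist:
                return self.frame_diff_dist[key]
        return self.frame_diff_dist.get("default", FrameDist.delta(0))

    def internal_error_dist_for(self, measure: str) -> FrameDist:
        return self.internal_error_dists.get(measure, FrameDist.delta(0))


@dataclass(frozen=True)
class PresentationSchedule:
    """Stimulus-presentation experiment: 120 sequences x 5 method blocks x 5 intervals.

    Each sequence uses one of the 120 possible orderings of the five
    requested durations; the same interval order is applied within each of
    the five (timing, presentation) method blocks.  Every trial and sequence
    is demarcated by 400 ms background, a 400 ms intertrial marker stimulus,
    and another 400 ms background.
    """

    orders: tuple[tuple[int, ...], ...]
    method_blocks: tuple[tuple[str, str], ...] = METHOD_COMBOS
    demarcation_ms: float = 400.0

    def validate(self) -> None:
        expected = set(itertools.permutations(REQUESTED_FRAMES))
        if len(self.orders) != 120 or set(self.orders) != expected:
            raise ProfileError(
                "schedule must contain the 120 distinct orderings of "
                f"{REQUESTED_FRAMES}"
            )
        if len(self.method_blocks) != len(set(self.method_blocks)):
            raise ProfileError("method blocks must be distinct")

    @property
    def n_trials(self) -> int:
        return len(self.orders) * len(self.method_blocks) * len(REQUESTED_FRAMES)

    def trials(self) -> Iterable[tuple[int, int, str, str, int]]:
        """Yield (sequence, trial_index, timing, presentation, requested_frames)."""
        for seq, order in enumerate(self.orders):
            idx = 0
            for timing, presentation in self.method_blocks:
                for requested in order:
                    yield seq, idx, timing, presentation, requested
                    idx += 1


@dataclass(frozen=True)
class RTSchedule:
    """Response-time experiment: per method, every whole-ms interval 150..449 once."""

    intervals: Mapping[tuple[str, str], tuple[int, ...]]
    inter_interval_gap_ms: float = 1200.0
    inter_sequence_gap_ms: float = 5000.0
    solenoid_delay_ms: float = 11.0

    def validate(self) -> None:
        expected = set(range(150, 450))
        for method, seq in self.intervals.items():
            if set(seq) != expected or len(seq) != len(expected):
                raise ProfileError(
                    f"intervals for {method} must be a permutation of 150..449"
                )
            if min(seq) < self.solenoid_delay_ms:
                raise ProfileError("interval shorter than the solenoid travel delay")


@dataclass(frozen=True)
class SensorTrace:
    """Luminance samples from the optical sensor (normalized to [0, 1])."""

    time_ms: np.ndarray
    luminance: np.ndarray
    sample_hz: float

    def __post_init__(self) -> None:
        if len(self.time_ms) != len(self.luminance):
            raise ProfileError("time and luminance must have equal length")


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def _dist(d: Mapping[int, float]) -> FrameDist:
    return FrameDist.from_dict(d)


def _one_frame_safe(d: Mapping[int, float]) -> FrameDist:
    """Variant of a diff distribution for 1-frame requests: negative
    differences (which would yield a zero-frame, i.e. invisible, stimulus)
    are folded onto +1."""
    out: dict[int, float] = {}
    for k, v in d.items():
        out[k if k >= 0 else 1] = out.get(k if k >= 0 else 1, 0.0) + v
    return FrameDist.from_dict(out)


def _symmetric_cell(p0: float) -> dict[int, float]:
    rest = (1.0 - p0) / 2.0
    return {-1: rest, 0: p0, 1: rest}


def _preset_perfect() -> DeviceProfile:
    return DeviceProfile(name="perfect")


def _preset_css_plus_one() -> DeviceProfile:
    return DeviceProfile(name="css_plus_one", css_plus_one=True)


def _with_one_frame_overrides(
    base: dict[_DistKey, FrameDist], combos=METHOD_COMBOS
) -> dict[_DistKey, FrameDist]:
    """Add (timing, presentation, 1) keys folding negative diffs to +1."""
    out = dict(base)
    for timing, presentation in combos:
        for key in ((timing, presentation), (timing,)):
            if key in base:
                out[(timing, presentation, 1)] = _one_frame_safe(base[key].as_dict())
                break
    return out


def _preset_ios_like() -> DeviceProfile:
    # Near-perfect rAF timing; CSS animations consistently one frame long;
    # low constant RT overestimation quantized at the 60 Hz refresh.
    dists: dict[_DistKey, FrameDist] = {("raf",): FrameDist.delta(0)}
    return DeviceProfile(
        name="ios_like",
        frame_diff_dist=dists,
        css_plus_one=True,
        rt_offset_constant_ms=57.9,
        rt_offset_mix=(6.7, 6.7, 0.0),
        rt_quantize_hz=60.0,
    )


def _preset_windows_chrome_like() -> DeviceProfile:
    base: dict[_DistKey, FrameDist] = {
        ("raf",): _dist({-1: 0.0005, 0: 0.999, 1: 0.0005}),
        ("css",): _dist(_symmetric_cell(0.60)),
    }
    return DeviceProfile(
        name="windows_chrome_like",
        frame_diff_dist=_with_one_frame_overrides(base),
        rt_offset_constant_ms=68.5,
        rt_offset_mix=(1.7, 1.7, 0.0),
    )


def _preset_macos_chrome_like() -> DeviceProfile:
    base: dict[_DistKey, FrameDist] = {
        ("raf", "opacity"): _dist(_symmetric_cell(0.515)),
        ("raf",): _dist(_symmetric_cell(0.55)),
        ("css",): _dist(_symmetric_cell(0.53)),
    }
    return DeviceProfile(
        name="macos_chrome_like",
        frame_diff_dist=_with_one_frame_overrides(base),
        short_presentation_bug=True,
        short_bug_prob=0.7,
        rt_offset_constant_ms=95.4,
        rt_offset_mix=(8.1, 8.1, 0.0),
    )


def _preset_macos_firefox_like() -> DeviceProfile:
    # Pronounced bimodal RT overestimation: components 60.0 (12.4) and
    # 89.1 (2.4) ms, modeled as constant 60 plus a N(0,12.4)/N(29.1,2.4)
    # equal-weight mixture.
    base: dict[_DistKey, FrameDist] = {
        ("raf",): _dist(_symmetric_cell(0.60)),
        ("css",): _dist({-1: 0.1, 0: 0.2, 1: 0.7}),
    }
    return DeviceProfile(
        name="macos_firefox_like",
        frame_diff_dist=_with_one_frame_overrides(base),
        rt_offset_constant_ms=60.0,
        rt_offset_mix=(12.4, 2.4, 29.1),
    )


PRESETS: dict[str, callable] = {
    "perfect": _preset_perfect,
    "css_plus_one": _preset_css_plus_one,
    "ios_like": _preset_ios_like,
    "windows_chrome_like": _preset_windows_chrome_like,
    "macos_chrome_like": _preset_macos_chrome_like,
    "macos_firefox_like": _preset_macos_firefox_like,
}


def build_profile(preset: str) -> DeviceProfile:
    """Return a registered :class:`DeviceProfile` preset by name."""
    try:
        factory = PRESETS[preset]
    except KeyError:
        raise KeyError(
            f"unknown preset {preset!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    profile = factory()
    profile.validate()
    return profile


# ---------------------------------------------------------------------------
# Schedule generation
# ---------------------------------------------------------------------------


def generate_presentation_schedule(seed: int) -> PresentationSchedule:
    """All 120 interval orderings in a seeded pseudorandom sequence order."""
    rng = np.random.default_rng(seed)
    orders = list(itertools.permutations(REQUESTED_FRAMES))
    rng.shuffle(orders)
    schedule = PresentationSchedule(orders=tuple(tuple(o) for o in orders))
    schedule.validate()
    return schedule


def generate_rt_schedule(seed: int) -> RTSchedule:
    """Per method, a seeded permutation of every whole-ms interval 150..449."""
    rng = np.random.default_rng(seed)
    intervals = {
        method: tuple(int(v) for v in rng.permutation(np.arange(150, 450)))
        for method in METHOD_COMBOS
    }
    schedule = RTSchedule(intervals=intervals)
    schedule.validate()
    return schedule


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _realized_frames(
    profile: DeviceProfile,
    timing: str,
    presentation: str,
    requested: int,
    rng: np.random.Generator,
) -> int:
    if profile.css_plus_one and timing == "css":
        return requested + 1
    if (
        profile.short_presentation_bug
        and requested in (3, 6)
        and rng.random() < profile.short_bug_prob
    ):
        return 1
    diff = int(profile.frame_diff_dist_for(timing, presentation, requested).sample(rng))
    return max(requested + diff, 0)


def render_trace(
    schedule: PresentationSchedule,
    profile: DeviceProfile,
    seed: int,
    sequences: Sequence[int] | None = None,
) -> tuple[SensorTrace, pd.DataFrame]:
    """Render a presentation schedule into a sensor trace and a trial log.

    The luminance is a binary square wave: background at 0, the intertrial
    marker and the critical stimulus at 1.  Each trial contributes
    ``[400 bg][400 marker][400 bg][stimulus]``; an omitted stimulus is
    skipped entirely, leaving the documented missing-trial signature of
    about 800 ms of darkness followed by the next ~400 ms marker.

    The trial log carries the internal duration estimates (realized duration
    plus a sampled whole-frame estimation error per measure) together with
    ``true_``-prefixed emulator ground-truth columns used only by tests.

    Parameters
    ----------
    sequences
        Optional subset of sequence indices to render (all by default).
    """
    schedule.validate()
    profile.validate()
    rng = np.random.default_rng(seed)
    dem = schedule.demarcation_ms
    frame_ms = profile.frame_ms
    fs = profile.sample_hz

    seq_ids = range(len(schedule.orders)) if sequences is None else list(sequences)
    epochs: list[tuple[float, float]] = []  # (start_ms, duration_ms) of bright epochs
    rows: list[dict] = []
    t = 0.0
    for seq in seq_ids:
        order = schedule.orders[seq]
        idx = 0
        for timing, presentation in schedule.method_blocks:
            measures = RAF_MEASURES + (ANIM_MEASURES if timing == "css" else ())
            for requested in order:
                t += dem
                epochs.append((t, dem))
                t += dem
                t += dem
                omitted = bool(rng.random() < profile.omit_prob)
                frames = _realized_frames(profile, timing, presentation, requested, rng)
                duration = frames * frame_ms
                if not omitted and frames > 0:
                    epochs.append((t, duration))
                    t += duration
                row = {
                    "sequence": seq,
                    "trial": idx,
                    "timing": timing,
                    "presentation": presentation,
                    "requested_frames": requested,
                    "true_realized_frames": frames,
                    "true_omitted": omitted,
                }
                for measure in measures:
                    err = int(profile.internal_error_dist_for(measure).sample(rng))
                    row[measure] = duration + err * frame_ms
                rows.append(row)
                idx += 1
    # closing demarcation so the last stimulus is followed by background
    t += dem
    epochs.append((t, dem))
    t += 2 * dem

    n_samples = int(np.ceil(t * fs / 1000.0)) + 1
    luminance = np.zeros(n_samples)
    for start, duration in epochs:
        i0 = int(np.ceil(start * fs / 1000.0 - 1e-9))
        i1 = int(np.ceil((start + duration) * fs / 1000.0 - 1e-9))
        luminance[i0:i1] = 1.0
    time_ms = np.arange(n_samples) * (1000.0 / fs)

    columns = [
        "sequence",
        "trial",
        "timing",
        "presentation",
        "requested_frames",
        "true_realized_frames",
        "true_omitted",
        *RAF_MEASURES,
        *ANIM_MEASURES,
    ]
    log = pd.DataFrame(rows).reindex(columns=columns)
    return SensorTrace(time_ms=time_ms, luminance=luminance, sample_hz=fs), log


def render_rt_session(
    schedule: RTSchedule,
    profile: DeviceProfile,
    seed: int,
    methods: Sequence[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render an RT schedule into an event table and a trial log.

    Per trial the solenoid trigger is issued ``interval - solenoid_delay``
    after stimulus onset and the touch lands ``solenoid_delay`` later, so
    the realized RT equals the scheduled interval exactly.  The internally
    measured RT adds the profile's constant offset plus one draw from its
    two-component Gaussian overestimation mixture and is optionally
    quantized to the ``rt_quantize_hz`` lattice.
    """
    schedule.validate()
    profile.validate()
    rng = np.random.default_rng(seed)
    sd1, sd2, mean2 = profile.rt_offset_mix

    method_list = list(schedule.intervals) if methods is None else list(methods)
    events: list[pd.DataFrame] = []
    t = schedule.inter_sequence_gap_ms
    trial = 0
    for method in method_list:
        intervals = np.asarray(schedule.intervals[method], dtype=float)
        if intervals.min() < schedule.solenoid_delay_ms:
            raise ProfileError("interval shorter than the solenoid travel delay")
        n = intervals.size
        onsets = t + np.concatenate(
            ([0.0], np.cumsum(intervals[:-1] + schedule.inter_interval_gap_ms))
        )
        touches = onsets + intervals  # trigger at interval - delay, travel = delay
        comp2 = rng.random(n) < 0.5
        z = rng.standard_normal(n)
        offsets = profile.rt_offset_constant_ms + np.where(comp2, mean2 + sd2 * z, sd1 * z)
        measured = intervals + offsets
        if profile.rt_quantize_hz:
            q = 1000.0 / profile.rt_quantize_hz
            measured = np.round(measured / q) * q
        events.append(
            pd.DataFrame(
                {
                    "trial": np.arange(trial, trial + n),
                    "timing": method[0],
                    "presentation": method[1],
                    "scheduled_ms": intervals,
                    "onset_ms": onsets,
                    "touch_ms": touches,
                    "measured_rt_ms": measured,
                }
            )
        )
        trial += n
        t = touches[-1] + schedule.inter_sequence_gap_ms
    table = pd.concat(events, ignore_index=True)
    log = table[["trial", "timing", "presentation"]].copy()
    # the two response-event timestamps coincide in this emulation
    for measure in RT_MEASURES:
        log[measure] = table["measured_rt_ms"].to_numpy()
    return table, log
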