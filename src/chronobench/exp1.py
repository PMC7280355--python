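"""Stimulus-duration accuracy pipeline (external chronometry).

Recovers realized stimulus durations from a luminance trace, matches them
to the logged trials via the intertrial marker pulses, and computes the
frame-difference statistics: per-cell percentages of exactly realized
durations, agreement between internal duration estimates and the sensor,
and frame-difference histograms.

Stimulus onset and offset are defined as the luminance crossing 50% of
maximum screen brightness.  Durations are kept in milliseconds throughout
the pipeline and quantized into frames only by :func:`to_frames`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .emulator import ANIM_MEASURES, RAF_MEASURES, SensorTrace

__all__ = [
    "INTERNAL_MEASURES",
    "MATCH_FAILURE_REASONS",
    "detect_events",
    "match_trials",
    "to_frames",
    "percent_exact",
    "internal_agreement",
    "frame_difference_histogram",
]

INTERNAL_MEASURES: tuple[str, ...] = RAF_MEASURES + ANIM_MEASURES

#: Closed set of trial-invalidity reasons ('' marks a valid trial).
MATCH_FAILURE_REASONS: tuple[str, ...] = (
    "stimulus_missing",
    "alignment_failed",
    "implausible_demarcation",
    "implausible_duration",
)


def detect_events(
    trace: SensorTrace,
    threshold_fraction: float = 0.5,
    min_duration_samples: int = 2,
) -> pd.DataFrame:
    """Detect bright events as maximal supra-threshold runs.

    Onset is the time of the first sample above threshold, offset the time
    of the first sample back below it; runs shorter than
    ``min_duration_samples`` are discarded as single-sample glitches.

    Returns a DataFrame with columns ``onset_ms``, ``offset_ms``,
    ``duration_ms``, time-ordered and non-overlapping.
    """
    lum = np.asarray(trace.luminance, dtype=float)
    if lum.size == 0:
        raise ValueError("empty trace")
    if lum.min() < 0 or lum.max() > 1:
        raise ValueError("luminance must be normalized to [0, 1]")
    t = np.asarray(trace.time_ms, dtype=float)
    period = 1000.0 / trace.sample_hz

    above = lum > threshold_fraction
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [lum.size]))

    keep = (ends - starts) >= min_duration_samples
    starts, ends = starts[keep], ends[keep]
    t_ext = np.concatenate((t, [t[-1] + period]))
    onset = t[starts]
    offset = t_ext[ends]
    return pd.DataFrame(
        {"onset_ms": onset, "offset_ms": offset, "duration_ms": offset - onset}
    )


def to_frames(duration_ms, refresh_hz: float = 60.0):
    """Quantize durations (ms) to the nearest whole number of frames.

    Ties round half up.  Accepts scalars or arrays; raises on negative
    durations.
    """
    d = np.asarray(duration_ms, dtype=float)
    if np.any(d < 0):
        raise ValueError("durations must be nonnegative")
    frames = np.floor(d * refresh_hz / 1000.0 + 0.5).astype(int)
    return int(frames) if np.isscalar(duration_ms) else frames


def match_trials(
    events: pd.DataFrame,
    log: pd.DataFrame,
    *,
    refresh_hz: float = 60.0,
    demarcation_ms: float = 400.0,
    plausibility_tolerance: float = 0.25,
    max_quantization_slop_ms: float = 2.0,
) -> pd.DataFrame:
    """Align detected events with the trial log and measure frame differences.

    The event stream of a well-formed recording alternates marker pulse /
    critical stimulus with ~400 ms gaps.  The walk consumes one marker per
    logged trial, decides from the following gap whether the critical
    stimulus was presented (gap ~400 ms) or omitted (~800 ms of darkness
    before the next marker), and validates marker durations and gaps
    against plausibility windows of ``nominal * (1 +/- tolerance)``.
    Sequences containing an implausible marker are flagged wholesale.

    Every logged trial yields exactly one output row (valid or flagged), so
    valid + flagged always equals the number of scheduled trials.
    """
    lo, hi = (demarcation_ms * (1 - plausibility_tolerance),
              demarcation_ms * (1 + plausibility_tolerance))
    mlo, mhi = 2 * lo, 2 * hi
    frame_ms = 1000.0 / refresh_hz

    ev_on = events["onset_ms"].to_numpy()
    ev_off = events["offset_ms"].to_numpy()
    ev_dur = events["duration_ms"].to_numpy()
    n_ev = len(events)

    out: list[dict] = []
    i = 0
    lost_sync = False
    for row in log.itertuples(index=False):
        reason = ""
        realized_ms = np.nan
        if lost_sync or i >= n_ev:
            reason = "alignment_failed"
        else:
            pulse_dur, pulse_off = ev_dur[i], ev_off[i]
            i += 1
            if not (lo <= pulse_dur <= hi):
                reason = "implausible_demarcation"
            if i < n_ev:
                gap = ev_on[i] - pulse_off
                if lo <= gap <= hi:
                    realized_ms = ev_dur[i]
                    i += 1
                elif gap > hi:
                    # stimulus absent; next event is the next trial's marker
                    if not reason:
                        reason = (
                            "stimulus_missing" if mlo <= gap <= mhi else "alignment_failed"
                        )
                else:
                    # an event too close to the marker: structure lost
                    reason = reason or "alignment_failed"
                    lost_sync = True
            else:
                reason = reason or "stimulus_missing"
        if not reason and np.isfinite(realized_ms):
            snapped = np.round(realized_ms / frame_ms) * frame_ms
            if abs(realized_ms - snapped) > max_quantization_slop_ms:
                reason = "implausible_duration"
        rec = row._asdict()
        rec["realized_ms"] = realized_ms
        rec["reason"] = reason
        out.append(rec)

    matched = pd.DataFrame(out)
    # a sequence with an implausible marker cannot be trusted at all
    bad_seqs = set(
        matched.loc[matched["reason"] == "implausible_demarcation", "sequence"]
    )
    if bad_seqs:
        in_bad = matched["sequence"].isin(bad_seqs)
        keep_reason = matched["reason"] == "implausible_demarcation"
        matched.loc[in_bad & ~keep_reason, "reason"] = "alignment_failed"

    matched["valid"] = matched["reason"] == ""
    realized = matched["realized_ms"].to_numpy()
    frames = np.full(len(matched), np.nan)
    ok = matched["valid"].to_numpy() & np.isfinite(realized)
    frames[ok] = to_frames(realized[ok], refresh_hz)
    matched["realized_frames"] = frames
    matched["frame_diff"] = frames - matched["requested_frames"].to_numpy()
    return matched


def _percent_by_group(
    trials: pd.DataFrame, flag: pd.Series, groupby: Sequence[str]
) -> pd.DataFrame:
    df = trials.assign(_hit=flag.astype(float))
    if not list(groupby):
        return pd.DataFrame(
            {"n": [len(df)], "percent": [100.0 * df["_hit"].mean()]}
        )
    g = df.groupby(list(groupby), sort=True, observed=True)["_hit"]
    out = g.agg(n="count", percent="mean").reset_index()
    out["percent"] *= 100.0
    return out


def percent_exact(
    trials: pd.DataFrame, groupby: Sequence[str] = ("timing", "presentation")
) -> pd.DataFrame:
    """Percentage of trials whose frame difference is exactly zero, per group.

    Callers are expected to pass valid trials only; rows are used as given.
    Groups with no trials are simply absent from the output.
    """
    return _percent_by_group(trials, trials["frame_diff"] == 0, groupby).rename(
        columns={"percent": "percent_exact"}
    )


def internal_agreement(
    trials: pd.DataFrame,
    measure: str = "raf_before_created",
    groupby: Sequence[str] = ("timing", "presentation"),
    refresh_hz: float = 60.0,
) -> pd.DataFrame:
    """Percentage of trials whose internal estimate, quantized into frames,
    equals the realized frame count measured by the sensor."""
    if measure not in INTERNAL_MEASURES:
        raise KeyError(
            f"unknown internal measure {measure!r}; known: {', '.join(INTERNAL_MEASURES)}"
        )
    df = trials.loc[trials[measure].notna()].copy()
    est = np.maximum(df[measure].to_numpy(dtype=float), 0.0)
    agree = to_frames(est, refresh_hz) == df["realized_frames"].to_numpy()
    return _percent_by_group(df, pd.Series(agree, index=df.index), groupby).rename(
        columns={"percent": "percent_agree"}
    )


def frame_difference_histogram(
    trials: pd.DataFrame,
    lo: int = -4,
    hi: int = 4,
    groupby: Sequence[str] = ("timing", "presentation"),
) -> pd.DataFrame:
    """Counts of frame differences per group over ``lo..hi``.

    Differences beyond the range are pooled into the open-ended edge bins,
    so row sums always equal the per-group trial counts.
    """
    diffs = np.clip(trials["frame_diff"].to_numpy(dtype=float), lo, hi)
    df = trials.assign(_diff=diffs)
    counts = (
        df.groupby(list(groupby) + ["_diff"], sort=True, observed=True)
        .size()
        .unstack("_diff", fill_value=0)
    )
    counts = counts.reindex(columns=[float(v) for v in range(lo, hi + 1)], fill_value=0)
    counts.columns = [int(c) for c in counts.columns]
    return counts.reset_index()
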