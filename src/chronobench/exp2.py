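"""RT-measurement accuracy pipeline.

Computes RT overestimation (internally measured RT minus the externally
realized, sensor-to-actuator RT) and its distributional diagnostics: the
descriptive summaries per device/browser group, a circular-statistics
detector for refresh-rate quantization of measured RTs, and a univariate
two-component Gaussian mixture fitted by expectation maximization for
bimodal overestimation distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MixtureFit",
    "QuantizationResult",
    "realized_rt",
    "overestimation",
    "summarize_overestimation",
    "detect_quantization",
    "fit_mixture_em",
]


def realized_rt(onset, touch):
    """Actual RT: time from stimulus detection to the actuator touch."""
    onset = np.asarray(onset, dtype=float)
    touch = np.asarray(touch, dtype=float)
    if np.any(touch <= onset):
        raise ValueError("touch must occur strictly after stimulus onset")
    rt = touch - onset
    return float(rt) if rt.ndim == 0 else rt


def overestimation(events: pd.DataFrame) -> pd.DataFrame:
    """Add ``realized_rt_ms`` and ``overestimation_ms`` columns to an RT
    event table (columns ``onset_ms``, ``touch_ms``, ``measured_rt_ms``)."""
    out = events.copy()
    out["realized_rt_ms"] = realized_rt(
        events["onset_ms"].to_numpy(), events["touch_ms"].to_numpy()
    )
    out["overestimation_ms"] = out["measured_rt_ms"] - out["realized_rt_ms"]
    return out


def summarize_overestimation(
    trials: pd.DataFrame,
    groupby: Sequence[str] = ("timing", "presentation"),
    value: str = "overestimation_ms",
) -> pd.DataFrame:
    """Minimum, maximum, mean and sample SD of RT overestimations per group.

    The SD uses the n-1 denominator and is reported missing for singleton
    groups.
    """
    if trials.empty:
        raise ValueError("no trials to summarize")
    g = trials.groupby(list(groupby), sort=True, observed=True)[value]
    out = g.agg(minimum="min", maximum="max", mean="mean", sd="std", n="count")
    return out.reset_index()


@dataclass(frozen=True)
class QuantizationResult:
    flagged: bool
    score: float
    resolution_ms: float
    n: int


def detect_quantization(
    values, resolution_ms: float = 1000.0 / 60.0, cutoff: float = 0.9
) -> QuantizationResult:
    """Detect whether values are quantized onto a lattice of ``resolution_ms``.

    The score is the circular concentration (resultant length) of the
    phases ``2*pi*value/resolution``: 1.0 for values lying exactly on the
    lattice, near 0 for values spread uniformly across it.  Values are
    flagged as quantized when the score exceeds ``cutoff``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 30:
        raise ValueError("need at least 30 values to assess quantization")
    phases = 2.0 * np.pi * x / resolution_ms
    score = float(np.abs(np.mean(np.exp(1j * phases))))
    return QuantizationResult(
        flagged=score > cutoff, score=score, resolution_ms=resolution_ms, n=x.size
    )


@dataclass(frozen=True)
class MixtureFit:
    """Two-component univariate Gaussian mixture, components in ascending-mean order."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    log_likelihood: float
    n_iter: int
    converged: bool


_LOG_2PI = float(np.log(2.0 * np.pi))


def _loglik_and_resp(x, w, mu, sd):
    # log density of each point under each weighted component
    log_comp = (
        np.log(w)[None, :]
        - np.log(sd)[None, :]
        - 0.5 * _LOG_2PI
        - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
    )
    m = log_comp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
    resp = np.exp(log_comp - lse[:, None])
    return float(lse.sum()), resp


def fit_mixture_em(
    values,
    k: int = 2,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
    max_restarts: int = 5,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture by expectation maximization.

    Initialization splits the sorted sample at the median and
    moment-matches each half, which is deterministic given the data and
    robust for well-separated modes.  Convergence is declared when the
    relative log-likelihood change falls below ``tol``; the log-likelihood
    is checked to be non-decreasing at every step.  A degenerate component
    (vanishing SD or weight) triggers a seeded random-responsibility
    restart, up to ``max_restarts`` times.
    """
    if k != 2:
        raise ValueError("only k=2 components are supported")
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 values to fit a mixture")
    scale = float(np.std(x))
    if scale == 0.0:
        raise ValueError("degenerate data: all values identical")
    sd_floor = 1e-8 * max(scale, 1.0)

    lo_half, hi_half = x[: n // 2], x[n // 2 :]
    mu = np.array([lo_half.mean(), hi_half.mean()])
    sd = np.maximum(np.array([lo_half.std(), hi_half.std()]), 1e-3 * scale)
    w = np.array([0.5, 0.5])

    rng = np.random.default_rng(seed)
    restarts = 0
    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    iteration = 0
    while iteration < max_iter:
        ll, resp = _loglik_and_resp(x, w, mu, sd)
        if ll + 1e-9 * (1.0 + abs(ll)) < prev_ll:
            raise RuntimeError("EM log-likelihood decreased")
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * (1.0 + abs(ll)):
            converged = True
            break
        prev_ll = ll
        # M step
        nk = resp.sum(axis=0)
        if nk.min() < 1e-10:
            mu, sd, w, prev_ll = _random_restart(x, rng)
            restarts += 1
            if restarts > max_restarts:
                raise RuntimeError("EM failed: component weight collapsed")
            iteration += 1
            continue
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(var)
        if sd.min() < sd_floor:
            mu, sd, w, prev_ll = _random_restart(x, rng)
            restarts += 1
            if restarts > max_restarts:
                raise RuntimeError("EM failed: component SD collapsed")
        iteration += 1

    order = np.argsort(mu)
    return MixtureFit(
        means=tuple(float(v) for v in mu[order]),
        sds=tuple(float(v) for v in sd[order]),
        weights=tuple(float(v) for v in w[order]),
        log_likelihood=float(ll),
        n_iter=iteration,
        converged=converged,
    )


def _random_restart(x, rng):
    resp = rng.uniform(0.1, 0.9, size=(x.size, 1))
    resp = np.hstack([resp, 1.0 - resp])
    nk = resp.sum(axis=0)
    w = nk / x.size
    mu = (resp * x[:, None]).sum(axis=0) / nk
    var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
    sd = np.sqrt(np.maximum(var, 1e-6))
    return mu, sd, w, -np.inf
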