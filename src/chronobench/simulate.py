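"""Reliability of absolute vs. relative RT measures under device noise.

Simulated individual-differences experiments: each participant's RTs come
from an exponentially modified Gaussian (ex-Gaussian) whose Gaussian mean
is the participant's latent trait, with Gaussian SD ~ U(25, 75) ms and
exponential mean ~ U(50, 100) ms.  Device measurement noise adds a
per-participant constant offset ~ U(60, 130) ms plus a per-trial draw from
an equal-probability two-component Gaussian mixture (SDs ~ U(2, 12) ms,
component means 0 and ~ U(0, 30) ms) -- the structure observed empirically
in RT overestimations of commodity devices.

Two designs are compared.  *Absolute*: one condition; the score is the mean
measured RT.  *Relative*: two conditions with traits correlated .5 across
participants; the score is the difference of the condition mean RTs, which
cancels any participant-constant offset.  Reliability is the squared
Pearson correlation, across participants, between the latent trait (or
trait difference) and the score.  The grid crosses design x noise x trait
SD (15/25/50 ms) x trial count (10..300 step 10).

Within each (design, trait SD, trial count, replicate) the noise-on and
noise-off runs share one random substream, so the traits, ex-Gaussian
parameters and trial-level RTs are common random numbers and the
noise-induced reliability decrease is a low-variance paired contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NoiseDraw",
    "SimConfig",
    "sample_exgaussian",
    "apply_noise",
    "run_experiment",
    "run_grid",
    "noise_effect",
    "crossover",
    "plot_reliability",
]

TRIAL_GRID: tuple[int, ...] = tuple(range(10, 301, 10))
TRAIT_SDS: tuple[float, ...] = (15.0, 25.0, 50.0)


@dataclass(frozen=True)
class NoiseDraw:
    """One participant's device-noise parameters."""

    constant_ms: float
    sd1_ms: float
    sd2_ms: float
    mean2_ms: float
    enabled: bool = True

    def validate(self) -> None:
        if self.enabled:
            if not (60.0 <= self.constant_ms <= 130.0):
                raise ValueError("constant_ms outside [60, 130]")
            if not (2.0 <= self.sd1_ms <= 12.0 and 2.0 <= self.sd2_ms <= 12.0):
                raise ValueError("mixture SDs outside [2, 12]")
            if not (0.0 <= self.mean2_ms <= 30.0):
                raise ValueError("mean2_ms outside [0, 30]")


@dataclass(frozen=True)
class SimConfig:
    """Full simulation grid configuration."""

    n_participants: int = 100
    trait_sds: tuple[float, ...] = TRAIT_SDS
    trait_correlation: float = 0.5
    trial_counts: tuple[int, ...] = TRIAL_GRID
    n_reps: int = 1000
    seed: int = 0
    designs: tuple[str, ...] = ("absolute", "relative")
    noise_conditions: tuple[bool, ...] = (False, True)

    def validate(self) -> None:
        if self.n_participants < 3 or self.n_reps < 1:
            raise ValueError("need at least 3 participants and 1 replicate")
        if min(self.trait_sds) <= 0 or min(self.trial_counts) <= 0:
            raise ValueError("trait SDs and trial counts must be positive")
        if "relative" in self.designs and any(n % 2 for n in self.trial_counts):
            raise ValueError("trial counts must be even for the relative design")
        for d in self.designs:
            if d not in ("absolute", "relative"):
                raise ValueError(f"unknown design {d!r}")


def sample_exgaussian(mu, sigma, tau, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` ex-Gaussian RTs: Normal(mu, sigma) + Exponential(mean tau)."""
    if sigma < 0 or tau < 0 or n < 1:
        raise ValueError("require sigma >= 0, tau >= 0, n >= 1")
    return mu + sigma * rng.standard_normal(n) + tau * rng.standard_exponential(n)


def apply_noise(rts, noise: NoiseDraw, rng: np.random.Generator) -> np.ndarray:
    """Add one participant's device noise to a vector of RTs.

    Each RT gains the constant offset plus one draw from the equal-weight
    mixture of N(0, sd1) and N(mean2, sd2).  Disabled noise is the identity.
    """
    rts = np.asarray(rts, dtype=float)
    if not noise.enabled:
        return rts
    noise.validate()
    comp2 = rng.random(rts.shape) < 0.5
    z = rng.standard_normal(rts.shape)
    mix = np.where(comp2, noise.mean2_ms + noise.sd2_ms * z, noise.sd1_ms * z)
    return rts + noise.constant_ms + mix


def _squared_pearson(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    ym = y - y.mean()
    vx = float((xm * xm).sum())
    vy = float((ym * ym).sum())
    if vx <= 0.0 or vy <= 0.0:
        return float("nan")
    r = float((xm * ym).sum()) / np.sqrt(vx * vy)
    return r * r


def run_experiment(
    design: str,
    trait_sd: float,
    n_trials: int,
    noise_on: bool,
    rng: np.random.Generator,
    *,
    n_participants: int = 100,
    trait_correlation: float = 0.5,
    trait_mean: float = 300.0,
    sigma_range: tuple[float, float] = (25.0, 75.0),
    tau_range: tuple[float, float] = (50.0, 100.0),
    noise_constant_range: tuple[float, float] = (60.0, 130.0),
    noise_sd_range: tuple[float, float] = (2.0, 12.0),
    noise_mean2_range: tuple[float, float] = (0.0, 30.0),
) -> float:
    """Simulate one experiment and return its reliability (squared Pearson r).

    Draw order (one shared stream): traits, then per-participant ex-Gaussian
    parameters, then all trial-level RT deviations, then -- only when noise
    is enabled -- the per-participant noise parameters and trial-level noise
    draws.  RT draws therefore coincide between paired noise-on/off runs
    started from identically seeded generators.

    Returns NaN when scores or traits have zero variance in a replicate.
    """
    P = n_participants
    if design == "absolute":
        trait = trait_mean + trait_sd * rng.standard_normal(P)
    elif design == "relative":
        if n_trials % 2:
            raise ValueError("relative design needs an even trial count")
        z = rng.standard_normal((P, 2))
        r = trait_correlation
        # explicit Cholesky factor of [[1, r], [r, 1]]
        corr = np.column_stack([z[:, 0], r * z[:, 0] + np.sqrt(1.0 - r * r) * z[:, 1]])
        trait = trait_mean + trait_sd * corr
    else:
        raise ValueError(f"unknown design {design!r}")

    sigma = rng.uniform(*sigma_range, P)
    tau = rng.uniform(*tau_range, P)

    if design == "absolute":
        rts = (
            trait[:, None]
            + sigma[:, None] * rng.standard_normal((P, n_trials))
            + tau[:, None] * rng.standard_exponential((P, n_trials))
        )
    else:
        m = n_trials // 2
        rts = (
            trait[:, :, None]
            + sigma[:, None, None] * rng.standard_normal((P, 2, m))
            + tau[:, None, None] * rng.standard_exponential((P, 2, m))
        )

    if noise_on:
        bshape = (P,) + (1,) * (rts.ndim - 1)
        const = rng.uniform(*noise_constant_range, P).reshape(bshape)
        sd1 = rng.uniform(*noise_sd_range, P).reshape(bshape)
        sd2 = rng.uniform(*noise_sd_range, P).reshape(bshape)
        mean2 = rng.uniform(*noise_mean2_range, P).reshape(bshape)
        comp2 = rng.random(rts.shape) < 0.5
        z = rng.standard_normal(rts.shape)
        rts = rts + const + np.where(comp2, mean2 + sd2 * z, sd1 * z)

    if design == "absolute":
        score = rts.mean(axis=1)
        latent = trait
    else:
        cond_means = rts.mean(axis=2)
        score = cond_means[:, 0] - cond_means[:, 1]
        latent = trait[:, 0] - trait[:, 1]
    return _squared_pearson(latent, score)


def run_grid(config: SimConfig) -> pd.DataFrame:
    """Simulate the full grid; one row per (design, noise, trait SD, trial count).

    Substreams are derived from the root seed by a counter scheme: the
    generator for replicate ``rep`` of grid combination ``ci`` is seeded
    with ``SeedSequence(seed, spawn_key=(ci, rep))`` and shared between the
    noise conditions (common random numbers).
    """
    config.validate()
    combos = [
        (design, trait_sd, n_trials)
        for design in config.designs
        for trait_sd in config.trait_sds
        for n_trials in config.trial_counts
    ]
    rows: list[dict] = []
    for ci, (design, trait_sd, n_trials) in enumerate(combos):
        rel = {noise: np.empty(config.n_reps) for noise in config.noise_conditions}
        for rep in range(config.n_reps):
            for noise_on in config.noise_conditions:
                rng = np.random.default_rng(
                    np.random.SeedSequence(config.seed, spawn_key=(ci, rep))
                )
                rel[noise_on][rep] = run_experiment(
                    design,
                    trait_sd,
                    n_trials,
                    noise_on,
                    rng,
                    n_participants=config.n_participants,
                    trait_correlation=config.trait_correlation,
                )
        for noise_on in config.noise_conditions:
            vals = rel[noise_on]
            good = vals[np.isfinite(vals)]
            rows.append(
                {
                    "design": design,
                    "noise": noise_on,
                    "trait_sd": trait_sd,
                    "n_trials": n_trials,
                    "mean_reliability": float(good.mean()) if good.size else np.nan,
                    "sd_reliability": float(good.std(ddof=1)) if good.size > 1 else np.nan,
                    "n_reps": int(good.size),
                    "n_missing": int(config.n_reps - good.size),
                }
            )
    return pd.DataFrame(rows)


def noise_effect(cells: pd.DataFrame) -> pd.DataFrame:
    """Noise-induced reliability decrease per (design, trait SD).

    ``mean_decrease`` averages the paired (no-noise minus noise) cell-mean
    differences across the trial-count grid; ``max_decrease`` is the largest
    paired difference over the grid.
    """
    pivot = cells.pivot_table(
        index=["design", "trait_sd", "n_trials"],
        columns="noise",
        values="mean_reliability",
    )
    if False not in pivot.columns or True not in pivot.columns or pivot.isna().any().any():
        raise ValueError("cells must cover both noise conditions for every combination")
    dec = (pivot[False] - pivot[True]).rename("decrease").reset_index()
    out = (
        dec.groupby(["design", "trait_sd"], sort=True)["decrease"]
        .agg(mean_decrease="mean", max_decrease="max", n_trial_counts="count")
        .reset_index()
    )
    return out


def crossover(cells: pd.DataFrame, noise_on: bool) -> tuple[dict[float, int | None], int | None]:
    """Smallest grid trial count from which the relative design is at least
    as reliable as the absolute design at every larger grid point.

    Returns ``(per_trait_sd, overall)``; ``overall`` is the maximum across
    trait SDs, or None if any trait SD shows no crossover within the grid.
    """
    sub = cells[cells["noise"] == noise_on]
    per: dict[float, int | None] = {}
    for trait_sd, g in sub.groupby("trait_sd"):
        pivot = g.pivot_table(index="n_trials", columns="design", values="mean_reliability")
        if "absolute" not in pivot.columns or "relative" not in pivot.columns:
            raise ValueError("cells must cover both designs")
        pivot = pivot.sort_index()
        ok = (pivot["relative"] >= pivot["absolute"]).to_numpy()
        # suffix-all-true: smallest index from which every point holds
        holds_from = np.logical_and.accumulate(ok[::-1])[::-1]
        idx = np.flatnonzero(holds_from)
        per[float(trait_sd)] = int(pivot.index[idx[0]]) if idx.size else None
    overall = None if any(v is None for v in per.values()) else max(per.values())
    return per, overall


def plot_reliability(cells: pd.DataFrame, path=None):
    """Line plot of mean reliability vs. trial count (error bars: SD across
    replicates), one panel per design, lines per (trait SD, noise)."""
    from matplotlib.figure import Figure

    designs = sorted(cells["design"].unique())
    fig = Figure(figsize=(5 * len(designs), 4))
    axes = fig.subplots(1, len(designs), sharey=True)
    if len(designs) == 1:
        axes = [axes]
    for ax, design in zip(axes, designs):
        sub = cells[cells["design"] == design]
        for (trait_sd, noise), g in sub.groupby(["trait_sd", "noise"]):
            g = g.sort_values("n_trials")
            ax.errorbar(
                g["n_trials"],
                g["mean_reliability"],
                yerr=g["sd_reliability"],
                label=f"SD {trait_sd:g} ms, {'noise' if noise else 'no noise'}",
                capsize=2,
                linestyle="--" if noise else "-",
            )
        ax.set_title(f"{design} RT")
        ax.set_xlabel("trials")
        ax.set_ylim(0, 1)
    axes[0].set_ylabel("reliability (squared r)")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
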