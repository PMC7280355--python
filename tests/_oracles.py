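"""Independent brute-force oracles used by the test suite.

Every function here re-derives a quantity from first principles (textbook
formulas, scalar loops, step-down enumeration) without touching the
implementation under test, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np


def two_proportion_z_oracle(x1, n1, x2, n2):
    """Pooled-variance two-proportion z statistic and two-sided normal p."""
    p1, p2 = x1 / n1, x2 / n2
    pp = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return z, p


def welch_t_oracle(a, b):
    """Welch t statistic, Welch-Satterthwaite df, two-sided p via scipy's t sf."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, df, p


def levene_oracle(a, b, center="mean"):
    """One-way ANOVA F on absolute deviations from the group center."""
    from scipy.stats import f as fdist

    groups = [np.asarray(a, float), np.asarray(b, float)]
    if center == "mean":
        devs = [np.abs(g - g.mean()) for g in groups]
    else:
        devs = [np.abs(g - np.median(g)) for g in groups]
    n = sum(g.size for g in devs)
    k = len(devs)
    grand = np.concatenate(devs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in devs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in devs)
    stat = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = fdist.sf(stat, k - 1, n - k)
    return stat, p


def pearson_oracle(x, y):
    """Covariance-formula Pearson correlation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm * xm).sum() * (ym * ym).sum()))


def holm_oracle(pvals, alpha=0.05):
    """Step-down Holm rejections by direct enumeration of the rule."""
    p = list(pvals)
    order = sorted(range(len(p)), key=lambda i: p[i])
    reject = [False] * len(p)
    m = len(p)
    for rank, i in enumerate(order):
        if p[i] <= alpha / (m - rank):
            reject[i] = True
        else:
            break
    return reject


def percent_exact_recount(trials, groupby):
    """Brute-force recount of percent-exact over raw rows."""
    counts: dict[tuple, list[int]] = {}
    for _, row in trials.iterrows():
        key = tuple(row[g] for g in groupby)
        hit, total = counts.setdefault(key, [0, 0])
        counts[key][0] = hit + (1 if row["frame_diff"] == 0 else 0)
        counts[key][1] = total + 1
    return {k: 100.0 * h / t for k, (h, t) in counts.items()}


def run_experiment_oracle(design, trait_sd, n_trials, noise_on, seed, *,
                          n_participants, trait_correlation=0.5, trait_mean=300.0):
    """Scalar-loop re-implementation of one simulated experiment.

    Consumes the random stream with the same calls and shapes as the
    vectorized implementation (so the draws are shared), but does every
    piece of arithmetic -- RTs, means, correlation -- with explicit Python
    loops in left-to-right order.
    """
    P = n_participants
    rng = np.random.default_rng(seed)
    if design == "absolute":
        z0 = rng.standard_normal(P)
        trait = [trait_mean + trait_sd * z0[p] for p in range(P)]
    else:
        z = rng.standard_normal((P, 2))
        s = math.sqrt(1.0 - trait_correlation**2)
        trait = [
            (trait_mean + trait_sd * z[p, 0],
             trait_mean + trait_sd * (trait_correlation * z[p, 0] + s * z[p, 1]))
            for p in range(P)
        ]
    sigma = rng.uniform(25.0, 75.0, P)
    tau = rng.uniform(50.0, 100.0, P)

    if design == "absolute":
        zn = rng.standard_normal((P, n_trials))
        ze = rng.standard_exponential((P, n_trials))
        rts = [[trait[p] + sigma[p] * zn[p, t] + tau[p] * ze[p, t]
                for t in range(n_trials)] for p in range(P)]
    else:
        m = n_trials // 2
        zn = rng.standard_normal((P, 2, m))
        ze = rng.standard_exponential((P, 2, m))
        rts = [[[trait[p][c] + sigma[p] * zn[p, c, t] + tau[p] * ze[p, c, t]
                 for t in range(m)] for c in range(2)] for p in range(P)]

    if noise_on:
        shape = (P, n_trials) if design == "absolute" else (P, 2, m)
        const = rng.uniform(60.0, 130.0, P)
        sd1 = rng.uniform(2.0, 12.0, P)
        sd2 = rng.uniform(2.0, 12.0, P)
        mean2 = rng.uniform(0.0, 30.0, P)
        comp2 = rng.random(shape) < 0.5
        zz = rng.standard_normal(shape)
        for p in range(P):
            if design == "absolute":
                for t in range(n_trials):
                    mix = (mean2[p] + sd2[p] * zz[p, t]) if comp2[p, t] else sd1[p] * zz[p, t]
                    rts[p][t] = rts[p][t] + const[p] + mix
            else:
                for c in range(2):
                    for t in range(m):
                        mix = (mean2[p] + sd2[p] * zz[p, c, t]) if comp2[p, c, t] else sd1[p] * zz[p, c, t]
                        rts[p][c][t] = rts[p][c][t] + const[p] + mix

    def mean(vals):
        acc = 0.0
        for v in vals:
            acc += v
        return acc / len(vals)

    if design == "absolute":
        score = [mean(rts[p]) for p in range(P)]
        latent = list(trait)
    else:
        score = [mean(rts[p][0]) - mean(rts[p][1]) for p in range(P)]
        latent = [trait[p][0] - trait[p][1] for p in range(P)]

    mx, my = mean(latent), mean(score)
    sxy = sxx = syy = 0.0
    for p in range(P):
        sxy += (latent[p] - mx) * (score[p] - my)
    for p in range(P):
        sxx += (latent[p] - mx) * (latent[p] - mx)
    for p in range(P):
        syy += (score[p] - my) * (score[p] - my)
    r = sxy / math.sqrt(sxx * syy)
    return r * r
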