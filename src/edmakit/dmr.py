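"""Per-probe linear model with empirical-Bayes variance moderation, DMR calling.

With few biological replicates per group, per-probe variance estimates are
noisy and raw t-tests are unstable.  The standard remedy is hierarchical
shrinkage: the per-probe residual variances s² (d degrees of freedom each)
are treated as draws from a scaled inverse-chi-square prior with parameters
(d0, s0²); the posterior variance

    s̃² = (d0·s0² + d·s²) / (d0 + d)

replaces s² in the t statistic, which then has d0 + d degrees of freedom.
The prior parameters are estimated from the empirical distribution of
log s² by the method of moments (log s² follows a log-F distribution under
the hierarchical model); the trigamma inversion is solved numerically.

A probe/fragment is called a differentially methylated region (DMR) when
its two-sided p-value is below 0.05 *and* its mean log2 ratio is at least
1.5 in magnitude; the sign of the mean gives the direction (positive =
hypermethylated in group A).  Raw p-values define the headline rule;
Benjamini–Hochberg q-values are reported alongside.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FitError",
    "trigamma_inverse",
    "estimate_prior",
    "fit_moderated",
    "call_dmrs",
]


class FitError(ValueError):
    pass


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0.

    trigamma is strictly decreasing from +inf (x→0) to 0 (x→inf), so the
    root is unique; solved by bracketed root finding.
    """
    if y <= 0:
        raise FitError(f"trigamma inverse needs a positive argument, got {y}")
    lo, hi = 1e-8, 1e8

    def f(x: float) -> float:
        return float(special.polygamma(1, x)) - y

    if f(lo) < 0:  # y above trigamma(lo): root below bracket; clamp
        return lo
    if f(hi) > 0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0²) from the spread of log s² around its expectation.

    Under the hierarchical model, e = log s² − ψ(d/2) + log(d/2) has mean
    log s0² + ψ(d0/2) − log(d0/2) and variance ψ′(d/2) + ψ′(d0/2).  Excess
    variance of e beyond ψ′(d/2) identifies d0; no excess (or negative, from
    sampling noise) means the variances are effectively common and d0 = ∞.
    Zero variances cannot enter the log moments and are excluded here.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise FitError("need at least two positive residual variances")
    e = np.log(positive) - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s02 = math.exp(
            e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s02 = math.exp(e_mean)
    return d0, s02


def fit_moderated(
    M: pd.DataFrame | np.ndarray,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """One-sample moderated t per probe on an oriented M matrix.

    Rows are probes, columns hybridizations already oriented so that
    positive M means hypermethylation in group A.  ``prior_df`` overrides
    the estimated d0: 0 recovers the ordinary t-test, ``math.inf`` shrinks
    every variance fully to s0².

    Returns a DataFrame with columns mean_m, s2, df, s2_post, t, p, q and
    attrs ``d0``, ``s02``, ``n``.
    """
    values = np.asarray(M, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise FitError("need an M matrix with at least 2 arrays to estimate variance")
    index = M.index if isinstance(M, pd.DataFrame) else pd.RangeIndex(values.shape[0])
    n = values.shape[1]
    df = float(n - 1)
    mean_m = values.mean(axis=1)
    s2 = values.var(axis=1, ddof=1)

    if prior_df is None:
        d0, s02 = estimate_prior(s2, df)
    else:
        d0 = float(prior_df)
        if d0 < 0:
            raise FitError(f"prior df must be nonnegative, got {d0}")
        # Still anchor s0² to the data so forced-d0 fits remain usable.
        _, s02_moment = estimate_prior(s2, df)
        if math.isinf(d0):
            s02 = s02_moment
        elif d0 == 0:
            s02 = s02_moment  # unused: no shrinkage
        else:
            e = np.log(s2[s2 > 0]) - special.digamma(df / 2) + math.log(df / 2)
            s02 = math.exp(
                float(e.mean()) + float(special.digamma(d0 / 2)) - math.log(d0 / 2)
            )

    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        total_df = math.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        total_df = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_m / np.sqrt(s2_post / n)
    if math.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    # Zero p from numeric underflow would break the (0, 1] contract.
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "mean_m": mean_m,
            "s2": s2,
            "df": df,
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "q": q,
        },
        index=index,
    )
    out.attrs["d0"] = d0
    out.attrs["s02"] = s02
    out.attrs["n"] = n
    return out


def call_dmrs(
    fits: pd.DataFrame,
    p_threshold: float = 0.05,
    m_threshold: float = 1.5,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Select probes with p < p_threshold and |mean M| ≥ m_threshold.

    Direction is ``hyper_in_A`` for positive mean M, ``hyper_in_B``
    otherwise.  When an annotation table indexed like ``fits`` (or carrying
    a matching ``fragment_id``/probe id column) is supplied, its columns are
    joined onto the DMR records.
    """
    required = {"mean_m", "p"}
    if not required.issubset(fits.columns):
        raise FitError(f"fit table must contain columns {sorted(required)}")
    mask = (fits["p"] < p_threshold) & (fits["mean_m"].abs() >= m_threshold)
    dmrs = fits.loc[mask].copy()
    dmrs["direction"] = np.where(dmrs["mean_m"] > 0, "hyper_in_A", "hyper_in_B")
    if annotations is not None:
        ann = annotations
        if "fragment_id" in ann.columns and len(
            fits.index.intersection(ann.index)
        ) == 0:
            ann = ann.set_index("fragment_id")
        dmrs = dmrs.join(ann, how="left", rsuffix="_annotation")
    return dmrs
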