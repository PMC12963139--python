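"""Cohort-level statistics for twin samples.

Drawings come in twin pairs, so observations are not independent: fixed
age effects are estimated with linear mixed models carrying a Gaussian
random intercept per pair, age coefficients of competing outcome metrics
are compared by resampling whole pairs with replacement, and per-angle age
correlations are corrected with the Benjamini–Yekutieli FDR procedure,
which is valid under the arbitrary dependence between neighbouring bins.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CoefEstimate",
    "fit_lmm_age",
    "bootstrap_compare",
    "angle_age_significance",
    "cluster_demographics",
]


@dataclasses.dataclass(frozen=True)
class CoefEstimate:
    """Age-slope estimate with Wald 95% CI and p-value."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    method: str = "lmm"


def _sort_by_pair(age, pair_id, *arrays):
    order = np.argsort(np.asarray(pair_id), kind="stable")
    pid = np.asarray(pair_id)[order]
    return (np.asarray(age, dtype=float)[order], pid,
            *(np.asarray(a, dtype=float)[order] for a in arrays))


def fit_lmm_age(outcome, age, pair_id) -> CoefEstimate:
    """REML linear mixed model: outcome ~ age + (1 | pair).

    Falls back to ordinary least squares (with a logged warning) when the
    mixed fit is singular or fails to converge.
    """
    y = np.asarray(outcome, dtype=float)
    age = np.asarray(age, dtype=float)
    pair_id = np.asarray(pair_id)
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    if len(np.unique(pair_id)) < 2:
        raise ValueError("need at least 2 pairs")
    X = np.column_stack([np.ones_like(age), age])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(y, X, groups=pair_id).fit(reml=True)
        beta = float(res.params[1])
        se = float(res.bse[1])
        if not np.isfinite(se) or se <= 0:
            raise ValueError("singular mixed fit")
        method = "lmm"
    except (ValueError, np.linalg.LinAlgError) as exc:
        logger.warning("mixed model failed (%s); falling back to OLS", exc)
        import statsmodels.api as sm

        res = sm.OLS(y, X).fit()
        beta, se = float(res.params[1]), float(res.bse[1])
        method = "ols"
    zcrit = stats.norm.ppf(0.975)
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return CoefEstimate(beta=beta, se=se, ci_low=beta - zcrit * se,
                        ci_high=beta + zcrit * se, p=float(p), method=method)


# ---------------------------------------------------------------------------
# Fast profiled-REML random-intercept slope, used inside the bootstrap
# ---------------------------------------------------------------------------

def _reml_slope(y: np.ndarray, age: np.ndarray, starts: np.ndarray) -> float:
    """Age slope of y ~ age + (1 | pair) by profiled REML.

    ``starts`` are the group start offsets of pair-contiguous data.  For the
    variance ratio lam = sigma_u^2 / sigma_e^2 the per-pair covariance is
    sigma_e^2 (I + lam J), whose inverse and determinant are closed-form, so
    the REML criterion reduces to a 1-D optimization over lam.
    """
    N = len(y)
    X = np.column_stack([np.ones(N), age])
    sizes = np.diff(np.append(starts, N))
    Sx = np.add.reduceat(X, starts, axis=0)
    Sy = np.add.reduceat(y, starts)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def beta_of(lam):
        w = lam / (1.0 + sizes * lam)
        A = XtX - (Sx.T * w) @ Sx
        b = Xty - Sx.T @ (w * Sy)
        return A, b, np.linalg.solve(A, b), w

    def neg_reml(log_lam):
        lam = np.exp(log_lam)
        A, b, beta, w = beta_of(lam)
        yy = yty - float(w @ (Sy * Sy))
        rss = yy - float(b @ beta)
        if rss <= 0:
            return np.inf
        sigma2 = rss / (N - 2)
        sign, logdetA = np.linalg.slogdet(A)
        return (np.sum(np.log1p(sizes * lam)) + (N - 2) * np.log(sigma2)
                + logdetA)

    sol = optimize.minimize_scalar(neg_reml, bounds=(-12.0, 8.0),
                                   method="bounded",
                                   options={"xatol": 1e-3})
    _, _, beta, _ = beta_of(np.exp(sol.x))
    return float(beta[1])


def _resample_pairs(rng: np.random.Generator, pair_starts: np.ndarray,
                    pair_sizes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Draw whole pairs with replacement; returns (row index, new starts)."""
    P = len(pair_starts)
    chosen = rng.integers(0, P, size=P)
    idx = np.concatenate([np.arange(pair_starts[c], pair_starts[c] + pair_sizes[c])
                          for c in chosen])
    starts = np.concatenate([[0], np.cumsum(pair_sizes[chosen])[:-1]])
    return idx, starts


def bootstrap_compare(outcomes: pd.DataFrame, age, pair_id, B: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Compare age coefficients of several metrics by a twin-pair bootstrap.

    Whole pairs are resampled with replacement ``B`` times; each resample
    refits the random-intercept model for every metric and collects the age
    coefficients.  For each metric pair the two-sided p-value doubles the
    smaller exceedance tail of "one coefficient larger than the other";
    p-values are Benjamini–Yekutieli adjusted across the comparisons.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    names = list(outcomes.columns)
    age, pid, *cols = _sort_by_pair(age, pair_id,
                                    *[outcomes[c].to_numpy() for c in names])
    Y = np.column_stack(cols)
    _, pair_starts = np.unique(pid, return_index=True)
    pair_starts = np.sort(pair_starts)
    pair_sizes = np.diff(np.append(pair_starts, len(pid)))
    rng = np.random.default_rng(seed)
    betas = np.empty((B, len(names)))
    for b in range(B):
        for attempt in range(11):
            idx, starts = _resample_pairs(rng, pair_starts, pair_sizes)
            try:
                betas[b] = [_reml_slope(Y[idx, j], age[idx], starts)
                            for j in range(len(names))]
                break
            except np.linalg.LinAlgError:
                if attempt == 10:
                    raise
                logger.warning("bootstrap resample %d failed; redrawing", b)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        prop = float(np.mean(betas[:, i] > betas[:, j]))
        p_raw = min(1.0, 2.0 * min(prop, 1.0 - prop))
        rows.append({"metric_a": names[i], "metric_b": names[j],
                     "prop_a_gt_b": prop, "p_raw": p_raw})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_by")[1] \
        if len(out) else []
    return out


# ---------------------------------------------------------------------------
# Per-angle age significance
# ---------------------------------------------------------------------------

def _pearson_by_bin(channel: np.ndarray, age: np.ndarray):
    """Vectorized Pearson r and two-sided p per bin; constant bins -> NaN."""
    n = len(age)
    ac = age - age.mean()
    xc = channel - channel.mean(axis=0)
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sa = np.sqrt((ac ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * ac[:, None]).sum(axis=0) / (sx * sa)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    const = sx == 0
    r[const] = np.nan
    p[const] = np.nan
    return r, p


def angle_age_significance(series, ages, alpha: float = 0.05) -> pd.DataFrame:
    """Per-bin Pearson age correlation for density and residual channels.

    Within each channel, p-values are Benjamini–Yekutieli adjusted across
    bins; a bin is flagged iff *both* adjusted p-values fall below alpha.
    Bins with a constant channel are excluded (and logged).
    """
    from .series import SeriesMatrix

    if isinstance(series, SeriesMatrix):
        data, channels = series.data, series.channels
    else:
        data = np.asarray(series, dtype=float)
        channels = ("density", "mean_residual")
    ages = np.asarray(ages, dtype=float)
    if data.shape[0] < 10:
        raise ValueError("need at least 10 drawings")
    nbins = data.shape[1]
    out = pd.DataFrame({"bin_left_deg": np.arange(nbins) * (360.0 / nbins)})
    flag = np.ones(nbins, dtype=bool)
    for c, name in enumerate(channels):
        short = "density" if "density" in name else "residual"
        r, p = _pearson_by_bin(data[:, :, c], ages)
        ok = ~np.isnan(p)
        if (~ok).any():
            logger.warning("%d constant bins excluded in channel %s",
                           int((~ok).sum()), name)
        p_adj = np.full(nbins, np.nan)
        if ok.any():
            p_adj[ok] = multipletests(p[ok], method="fdr_by")[1]
        out[f"r_{short}"] = r
        out[f"p_adj_{short}"] = p_adj
        flag &= ok & (p_adj < alpha)
    out["flagged"] = flag
    return out


def cluster_demographics(labels, age, sex) -> dict:
    """Chi-square test of sex x cluster, Kruskal–Wallis of age across clusters."""
    labels = np.asarray(labels)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    warnings_out = []
    for u in uniq:
        if (labels == u).sum() < 2:
            warnings_out.append(f"cluster {u} has fewer than 2 members")
    table = pd.crosstab(pd.Series(sex, name="sex"),
                        pd.Series(labels, name="cluster")).to_numpy()
    chi2_res = stats.chi2_contingency(table)
    groups = [age[labels == u] for u in uniq]
    if all(np.array_equal(np.sort(g), np.sort(groups[0])) for g in groups):
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = stats.kruskal(*groups)
    return {
        "chi2": float(chi2_res.statistic),
        "chi2_p": float(chi2_res.pvalue),
        "kw_stat": float(kw_stat),
        "kw_p": float(kw_p),
        "warnings": warnings_out,
    }
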