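"""Negative-binomial Wald tests for group contrasts on count data.

A self-contained differential-expression engine sized for desk-scale
matrices. Counts for feature *g* in sample *i* of group *k* are modelled as

    y_i ~ NB(mu_i, alpha_g),   mu_i = s_i * exp(beta_k),
    Var(y_i) = mu_i + alpha_g * mu_i^2,

with *s_i* a median-of-ratios size factor and ``alpha_g`` a per-feature
dispersion estimated by method of moments (floored at 1e-8). Because the
design is group indicators, the likelihood separates by group and each
``beta_k`` is found by a one-dimensional Newton iteration, vectorized over
features. A contrast c tests ``c . beta = 0`` by a Wald z with variance
``sum c_k^2 / I_k`` from the expected Fisher information. ``log2fc`` is
``c . beta / ln 2``. P values are adjusted per contrast by Benjamini–
Hochberg, and a feature is called significant when ``padj < alpha`` and
``|log2fc|`` exceeds the threshold (default 1.2, on the log2 scale).

There is deliberately no fold-change shrinkage, dispersion-trend fitting
or outlier filtering.

The mid-parent contrast of a cross F against parents P1, P2 is
``{F: +1, P1: -1/2, P2: -1/2}``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

DISPERSION_FLOOR = 1e-8
DEFAULT_ALPHA = 0.05
DEFAULT_LFC_THRESHOLD = 1.2


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Features with a zero count in any sample drop out of the median. When
    no feature is nonzero everywhere, falls back to column-sum ratios
    (scaled to geometric mean 1) with a warning.
    """
    x = counts.to_numpy(float)
    if x.size == 0 or (x < 0).any():
        raise ValueError("counts must be a nonempty non-negative matrix")
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        logx = np.log(x[all_pos])
        log_ref = logx.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logx - log_ref, axis=0))
    else:
        warnings.warn(
            "no feature expressed in all samples; using column-sum size factors",
            stacklevel=2,
        )
        totals = x.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("a sample has zero total counts")
        sf = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersion(counts: pd.DataFrame, groups: pd.Series, sf: pd.Series | None = None) -> pd.Series:
    """Per-feature NB dispersion alpha by method of moments.

    On size-factor-normalized counts z = y/s, within each group
    Var(z) ~= mean(z) * mean(1/s) + alpha * mean(z)^2; alpha estimates are
    pooled across groups weighted by group df and floored at 1e-8.
    """
    if sf is None:
        sf = size_factors(counts)
    z = counts.to_numpy(float) / sf.to_numpy()
    num = np.zeros(len(counts))
    den = 0.0
    for g in pd.unique(groups):
        idx = np.flatnonzero((groups == g).to_numpy())
        if len(idx) < 2:
            continue
        zg = z[:, idx]
        m = zg.mean(axis=1)
        v = zg.var(axis=1, ddof=1)
        inv_s = float(np.mean(1.0 / sf.to_numpy()[idx]))
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m * inv_s) / np.square(m), 0.0)
        w = len(idx) - 1
        num += w * a
        den += w
    if den == 0:
        raise ValueError("need at least one group with >= 2 samples")
    return pd.Series(np.maximum(num / den, DISPERSION_FLOOR), index=counts.index, name="dispersion")


def _fit_group_log_means(y, s, alpha, n_iter=60, tol=1e-12):
    """Newton solve of the NB score for one group, vectorized over features.

    y: features × samples counts of the group, s: size factors, alpha:
    per-feature dispersion. Returns (beta, info): the log mean and the
    expected Fisher information at the optimum. All-zero features get the
    continuity value beta = log(0.5 / sum s).
    """
    total = y.sum(axis=1)
    s_sum = s.sum()
    beta = np.log(np.maximum(total, 0.5) / s_sum)
    a = alpha[:, None]
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(beta)[:, None]
        w = 1.0 + a * mu
        score = ((y - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-300), -3.0, 3.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = s[None, :] * np.exp(beta)[:, None]
    info = (mu / (1.0 + a * mu)).sum(axis=1)
    return beta, info


def nb_wald_contrast(
    counts: pd.DataFrame,
    groups: pd.Series,
    contrast: dict[str, float],
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float | None = DEFAULT_LFC_THRESHOLD,
    dispersion: pd.Series | None = None,
    sf: pd.Series | None = None,
    label: str | None = None,
    scale: str = "log",
) -> pd.DataFrame:
    """Wald test of a contrast of group expression levels, per feature.

    ``contrast`` maps group label -> weight (weights need not sum to zero,
    but every tested contrast here does). With ``scale="log"`` (default)
    the statistic is ``c . beta`` on the log-mean scale — for a two-group
    contrast, the log fold change. With ``scale="mean"`` the statistic is
    ``c . exp(beta)`` on the mean scale with a delta-method variance; this
    is the right scale for the mid-parent contrast, whose null is that the
    cross mean equals the *arithmetic* average of the parental means (the
    log-scale contrast would test the geometric average instead).
    ``log2fc`` is always reported as log2 of (positive part / negative
    part) of the weighted group means, which coincides with ``c . beta /
    ln 2`` for the log scale.

    Returns a frame with log2fc, se, z, p, padj and the significance
    call. Features with zero counts in every sample of the involved
    groups are flagged ``all_zero`` and get log2fc 0, p 1.
    """
    if scale not in ("log", "mean"):
        raise ValueError("scale must be 'log' or 'mean'")
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    for g in contrast:
        n_g = int((groups == g).sum())
        if n_g < 2:
            raise ValueError(f"group {g!r} has {n_g} samples; need >= 2")
    if sf is None:
        sf = size_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, groups, sf)
    dispersion = dispersion.reindex(counts.index).to_numpy(float)

    y = counts.to_numpy(float)
    stat = np.zeros(len(counts))
    var = np.zeros(len(counts))
    pos_mean = np.zeros(len(counts))
    neg_mean = np.zeros(len(counts))
    involved = np.zeros(len(counts), dtype=bool)
    for g, c in contrast.items():
        idx = np.flatnonzero((groups == g).to_numpy())
        beta_g, info_g = _fit_group_log_means(y[:, idx], sf.to_numpy()[idx], dispersion)
        mu_g = np.exp(beta_g)
        inv_info = 1.0 / np.maximum(info_g, 1e-300)
        if scale == "log":
            stat += c * beta_g
            var += c * c * inv_info
        else:
            stat += c * mu_g
            var += c * c * mu_g * mu_g * inv_info
        if c > 0:
            pos_mean += c * mu_g
        else:
            neg_mean += -c * mu_g
        involved |= y[:, idx].sum(axis=1) > 0

    se_nat = np.sqrt(var)
    z = np.where(se_nat > 0, stat / se_nat, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    if scale == "log":
        lfc_nat = stat
        se_out = se_nat / np.log(2.0)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc_nat = np.where(
                (pos_mean > 0) & (neg_mean > 0), np.log(pos_mean / neg_mean), 0.0
            )
        se_out = se_nat  # mean-scale SE of the delta-method statistic
    all_zero = ~involved
    log2fc = lfc_nat / np.log(2.0)
    log2fc[all_zero] = 0.0
    p[all_zero] = 1.0
    padj = bh_adjust(p)
    sig = padj < alpha
    if lfc_threshold is not None:
        sig &= np.abs(log2fc) > lfc_threshold
    return pd.DataFrame(
        {
            "contrast": label or "+".join(f"{c:+g}*{g}" for g, c in contrast.items()),
            "log2fc": log2fc,
            "se": se_out,
            "z": z,
            "p": p,
            "padj": padj,
            "significant": sig,
            "all_zero": all_zero,
        },
        index=counts.index,
    )


def mid_parent_contrast(cross: str, parent1: str, parent2: str) -> dict[str, float]:
    return {cross: 1.0, parent1: -0.5, parent2: -0.5}


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
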