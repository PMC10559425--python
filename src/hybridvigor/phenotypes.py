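"""Feed-efficiency trait derivation and residual feed intake (RFI).

Raw per-bird measurements (daily feed intake, start/end body weight, total
egg mass over the test period) are turned into the derived traits used in
layer feed-efficiency work:

* ``mbw``  metabolic body weight, mean body weight (g) to the power 0.75
* ``bwg``  daily body-weight gain, g/d
* ``dem``  daily egg mass, g/d
* ``fcr``  feed conversion ratio, daily feed intake / daily egg mass
* ``rfi``  residual feed intake, the residual of an OLS regression of daily
  feed intake on MBW, BWG and DEM (lower RFI = more efficient bird)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

RAW_COLUMNS = ("bird_id", "group", "dfc", "bw_start", "bw_end", "total_egg_mass", "test_days")

METABOLIC_EXPONENT = 0.75


@dataclass
class RfiModelSummary:
    """OLS fit behind the RFI column: intercept + coefficients and R^2."""

    params: pd.Series
    r_squared: float
    n_used: int


def derive_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """Add mbw/bwg/dem/fcr columns to a raw phenotype table.

    Body weights are in grams; MBW uses the mean of start and end weight.
    Birds with zero egg mass get ``fcr = NaN`` and ``no_eggs = True`` — the
    usual practice is to drop such hens before fitting the RFI regression.
    """
    missing = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"phenotype table is missing required columns: {missing}")
    if (raw["test_days"] <= 0).any():
        raise ValueError("test_days must be positive")
    if (raw[["bw_start", "bw_end"]] <= 0).any().any():
        raise ValueError("body weights must be positive")

    out = raw.copy()
    mean_bw = (out["bw_start"] + out["bw_end"]) / 2.0
    out["mbw"] = mean_bw**METABOLIC_EXPONENT
    out["bwg"] = (out["bw_end"] - out["bw_start"]) / out["test_days"]
    out["dem"] = out["total_egg_mass"] / out["test_days"]
    out["no_eggs"] = out["dem"] <= 0
    out["fcr"] = np.where(out["no_eggs"], np.nan, out["dfc"] / out["dem"])
    return out


def compute_rfi(
    table: pd.DataFrame, drop_zero_egg: bool = True
) -> tuple[pd.DataFrame, RfiModelSummary]:
    """Fill the ``rfi`` column: residual of DFC ~ 1 + MBW + BWG + DEM.

    Birds excluded from the fit (zero-egg hens when ``drop_zero_egg``) keep
    ``rfi = NaN``. Residuals of an OLS fit with intercept sum to zero over
    the fitted set.
    """
    for col in ("mbw", "bwg", "dem"):
        if col not in table.columns:
            raise ValueError("run derive_traits first: missing derived column " + col)
    fit_mask = table[["dfc", "mbw", "bwg", "dem"]].notna().all(axis=1)
    if drop_zero_egg and "no_eggs" in table.columns:
        fit_mask &= ~table["no_eggs"].astype(bool)
    sub = table.loc[fit_mask]
    if len(sub) < 5:
        raise ValueError(f"need at least 5 complete rows to fit RFI, got {len(sub)}")

    X = sm.add_constant(sub[["mbw", "bwg", "dem"]].astype(float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design: mbw/bwg/dem are collinear")
    fit = sm.OLS(sub["dfc"].astype(float), X).fit()

    out = table.copy()
    out["rfi"] = np.nan
    out.loc[fit_mask, "rfi"] = fit.resid
    return out, RfiModelSummary(params=fit.params, r_squared=float(fit.rsquared), n_used=len(sub))


def adjusted_group_means(table: pd.DataFrame, trait: str, groups=None) -> pd.DataFrame:
    """Per-group mean ± SE for a trait (simple fixed-effect group means).

    Equivalent to OLS of the trait on group indicators. ``groups`` may pin
    the expected group labels; a missing group raises. Returns a frame
    indexed by group with columns mean/se/n.
    """
    if trait not in table.columns:
        raise ValueError(f"unknown trait column {trait!r}")
    sub = table[["group", trait]].dropna()
    present = set(sub["group"].unique())
    expect = set(groups) if groups is not None else present
    missing = expect - present
    if missing:
        raise ValueError(f"groups without data for {trait!r}: {sorted(missing)}")
    g = sub.groupby("group")[trait]
    res = pd.DataFrame({"mean": g.mean(), "se": g.std(ddof=1) / np.sqrt(g.count()), "n": g.count()})
    if (res["n"] < 2).any():
        raise ValueError("each group needs at least 2 records")
    return res.loc[sorted(expect)]
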