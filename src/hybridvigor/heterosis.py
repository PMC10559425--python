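"""Mid-parent heterosis and its significance test.

Mid-parent heterosis of a cross for a trait is

    H = (F̄ − MP) / MP,    MP = (P̄f + P̄m) / 2,

the deviation of the cross mean F̄ from the average of the two parental
line means, relative to that average. Significance uses a transformed
Student's t built from the cross individuals' phenotypes F_i:

    t = H / [ 2·SD_F / ((P̄f + P̄m)·√n) ],   SD_F = √(Σ(F_i − F̄)² / (n−1)),

with df = n − 1. Algebraically t = (F̄ − MP)·√n / SD_F, i.e. the ordinary
one-sample t of the cross values against the mid-parent value — so
sign(t) = sign(F̄ − MP) even when MP < 0 flips the sign of H (as happens
for residual feed intake).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedHeterosisError(ZeroDivisionError):
    """Raised when the mid-parent mean is zero: H = (F−MP)/MP is undefined."""


def mid_parent_heterosis(f_mean: float, pf_mean: float, pm_mean: float) -> float:
    """Mid-parent heterosis as a fraction; multiply by 100 for percent."""
    mp = (pf_mean + pm_mean) / 2.0
    if mp == 0:
        raise UndefinedHeterosisError("heterosis undefined (zero mid-parent)")
    return (f_mean - mp) / mp


def heterosis_t_test(
    cross_values, pf_mean: float, pm_mean: float
) -> tuple[float, int, float]:
    """(t, df, p) for H ≠ 0, from the raw phenotypes of the cross birds.

    Two-sided p on a t distribution with n − 1 degrees of freedom. The
    statistic is evaluated literally from H and SD_F; see the module
    docstring for the equivalent one-sample-t form.
    """
    f = np.asarray(cross_values, dtype=float)
    n = f.size
    if n < 2:
        raise ValueError("need at least 2 cross individuals")
    parent_sum = pf_mean + pm_mean
    if parent_sum == 0:
        raise UndefinedHeterosisError("heterosis undefined (zero mid-parent)")
    sd_f = float(np.std(f, ddof=1))
    if sd_f == 0:
        raise ValueError("degenerate cross variance (all cross values identical)")
    h = mid_parent_heterosis(float(f.mean()), pf_mean, pm_mean)
    t = h / (2.0 * sd_f / (parent_sum * np.sqrt(n)))
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, p


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class HeterosisEstimate:
    trait: str
    cross: str
    f_mean: float
    pf_mean: float
    pm_mean: float
    h: float                      # fraction
    sd_f: float | None = None
    n: int | None = None
    t: float | None = None
    df: int | None = None
    p: float | None = None

    @property
    def h_percent(self) -> float:
        return 100.0 * self.h

    @property
    def stars(self) -> str:
        return "" if self.p is None else significance_stars(self.p)


def heterosis_table(
    means: pd.DataFrame | None = None,
    phenotypes: pd.DataFrame | None = None,
    crosses: dict[str, tuple[str, str]] | None = None,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Heterosis for every trait × cross, from group means or raw phenotypes.

    Parameters
    ----------
    means
        Long frame with columns ``trait, group, mean`` (bypass mode: e.g.
        adjusted means copied from a published table). No t test possible.
    phenotypes
        Per-bird table with ``group`` plus one column per trait; group
        means, H and the t test are all computed from it.
    crosses
        Map cross label -> (paternal line, maternal line).
    traits
        Trait columns/labels to evaluate; default: all available.

    Returns a frame with one row per trait × cross: f/pf/pm means,
    ``h_percent``, and t/df/p/stars when raw phenotypes were given. A zero
    mid-parent makes that single cell undefined (NaN + flag) without
    failing the rest.
    """
    if crosses is None or not crosses:
        raise ValueError("need a cross -> (father line, mother line) map")
    if (means is None) == (phenotypes is None):
        raise ValueError("provide exactly one of means= or phenotypes=")

    rows = []
    if means is not None:
        for need in ("trait", "group", "mean"):
            if need not in means.columns:
                raise ValueError(f"means frame is missing column {need!r}")
        todo = traits or list(means["trait"].unique())
        lut = means.set_index(["trait", "group"])["mean"]
        for trait in todo:
            for cross, (pf, pm) in crosses.items():
                try:
                    fm, pfm, pmm = (float(lut[trait, g]) for g in (cross, pf, pm))
                except KeyError as err:
                    raise ValueError(f"missing group mean for trait {trait!r}: {err}") from err
                rows.append(_estimate_row(trait, cross, fm, pfm, pmm, None))
    else:
        group_col = phenotypes["group"]
        todo = traits or [c for c in phenotypes.columns if c not in ("bird_id", "group")]
        for trait in todo:
            for cross, (pf, pm) in crosses.items():
                for g in (cross, pf, pm):
                    if g not in set(group_col):
                        raise ValueError(f"group {g!r} absent from phenotype table")
                vals = {
                    g: phenotypes.loc[group_col == g, trait].dropna().to_numpy(float)
                    for g in (cross, pf, pm)
                }
                rows.append(
                    _estimate_row(
                        trait, cross, vals[cross].mean(), vals[pf].mean(), vals[pm].mean(),
                        vals[cross],
                    )
                )
    return pd.DataFrame(rows)


def _estimate_row(trait, cross, f_mean, pf_mean, pm_mean, cross_values):
    row = {
        "trait": trait, "cross": cross,
        "f_mean": f_mean, "pf_mean": pf_mean, "pm_mean": pm_mean,
        "h_percent": np.nan, "undefined": False,
        "n": np.nan, "t": np.nan, "df": np.nan, "p": np.nan, "stars": "",
    }
    try:
        row["h_percent"] = 100.0 * mid_parent_heterosis(f_mean, pf_mean, pm_mean)
    except UndefinedHeterosisError:
        row["undefined"] = True
        return row
    if cross_values is not None:
        t, df, p = heterosis_t_test(cross_values, pf_mean, pm_mean)
        row.update(n=len(cross_values), t=t, df=df, p=p, stars=significance_stars(p))
    return row
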