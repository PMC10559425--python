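"""Inheritance-mode classification of hybrid expression.

Each feature's expression in a cross F relative to its parents P1 and P2 is
summarized by four contrast outcomes, each one of ``up`` / ``down`` / ``ns``:

* ``p1_vs_p2`` — P1 relative to P2
* ``f_vs_p1``, ``f_vs_p2`` — cross relative to each parent
* ``f_vs_mp`` — cross relative to the parental average (mid-parent)

and classified, with fixed precedence, into

1. OVERDOMINANT   — F significantly above both parents
2. UNDERDOMINANT  — F significantly below both parents
3. DOMINANT_HIGH / DOMINANT_LOW — parents differ; F indistinguishable from
   the higher (lower) parent and significantly above (below) the other
4. ADDITIVE       — parents differ; F indistinguishable from mid-parent
5. CONSERVED      — no significant contrast at all
6. AMBIGUOUS      — any other combination

Two-parent evidence (over/underdominance) outranks one-parent evidence
(dominance), which outranks the mid-parent rule.

The 12 numeric bins refine the categories by which parent is higher and
whether the parents differ at all: additive {4, 10}, dominant-high {3, 11},
dominant-low {5, 9}, overdominant {1, 2, 12} (above high parent with
P1 < P2 / above parent / above high parent with P1 > P2), underdominant
{6, 7, 8}. Bins mirror under a parent relabeling (1<->12, 3<->11, 4<->10,
5<->9, 6<->8); the category does not change.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import pandas as pd

OUTCOMES = ("up", "down", "ns")
CONTRAST_KEYS = ("p1_vs_p2", "f_vs_p1", "f_vs_p2", "f_vs_mp")

CATEGORY_BINS = {
    "ADDITIVE": (4, 10),
    "DOMINANT_HIGH": (3, 11),
    "DOMINANT_LOW": (5, 9),
    "OVERDOMINANT": (1, 2, 12),
    "UNDERDOMINANT": (6, 7, 8),
}
NON_ADDITIVE = ("DOMINANT_HIGH", "DOMINANT_LOW", "OVERDOMINANT", "UNDERDOMINANT")


@dataclass(frozen=True)
class InheritanceCall:
    feature: str
    cross: str
    category: str
    bin: int | None
    outcomes: tuple  # (p1_vs_p2, f_vs_p1, f_vs_p2, f_vs_mp)


def classify_inheritance(
    p1_vs_p2: str, f_vs_p1: str, f_vs_p2: str, f_vs_mp: str
) -> tuple[str, int | None]:
    """(category, bin) from the four contrast outcomes.

    Pure function; see the module docstring for the decision procedure.
    """
    oc = (p1_vs_p2, f_vs_p1, f_vs_p2, f_vs_mp)
    for k, v in zip(CONTRAST_KEYS, oc):
        if v not in OUTCOMES:
            raise ValueError(f"contrast {k!r} has invalid outcome {v!r}")

    p2_higher = p1_vs_p2 == "down"
    parents_differ = p1_vs_p2 != "ns"

    if f_vs_p1 == "up" and f_vs_p2 == "up":
        if not parents_differ:
            return "OVERDOMINANT", 2
        return "OVERDOMINANT", 1 if p2_higher else 12
    if f_vs_p1 == "down" and f_vs_p2 == "down":
        if not parents_differ:
            return "UNDERDOMINANT", 7
        return "UNDERDOMINANT", 6 if p2_higher else 8

    if parents_differ:
        vs_high, vs_low = (f_vs_p2, f_vs_p1) if p2_higher else (f_vs_p1, f_vs_p2)
        if vs_high == "ns" and vs_low == "up":
            return "DOMINANT_HIGH", 3 if p2_higher else 11
        if vs_low == "ns" and vs_high == "down":
            return "DOMINANT_LOW", 5 if p2_higher else 9
        if f_vs_mp == "ns":
            return "ADDITIVE", 4 if p2_higher else 10

    if all(v == "ns" for v in oc):
        return "CONSERVED", None
    return "AMBIGUOUS", None


def outcome_from_result(row, alpha: float = 0.05, lfc_threshold: float | None = None) -> str:
    """Collapse one differential-expression row to up / down / ns.

    Significance is ``padj < alpha``; when ``lfc_threshold`` is given the
    fold-change filter is applied too (selectable because usage differs
    between plain DE lists and inheritance calling).
    """
    sig = row["padj"] < alpha
    if lfc_threshold is not None:
        sig = sig and abs(row["log2fc"]) > lfc_threshold
    if not sig:
        return "ns"
    return "up" if row["log2fc"] > 0 else "down"


def call_features(
    contrast_results: dict[str, pd.DataFrame],
    cross: str,
    alpha: float = 0.05,
    lfc_threshold: float | None = None,
) -> pd.DataFrame:
    """Classify every feature of a cross from its four contrast tables.

    ``contrast_results`` must contain the keys ``p1_vs_p2``, ``f_vs_p1``,
    ``f_vs_p2`` and ``f_vs_mp``, each a frame indexed by feature with
    columns ``log2fc`` and ``padj``.
    """
    missing = [k for k in CONTRAST_KEYS if k not in contrast_results]
    if missing:
        raise ValueError(f"missing contrast result(s): {missing}")
    idx = contrast_results["p1_vs_p2"].index
    rows = []
    for feat in idx:
        oc = tuple(
            outcome_from_result(contrast_results[k].loc[feat], alpha, lfc_threshold)
            for k in CONTRAST_KEYS
        )
        cat, b = classify_inheritance(*oc)
        rows.append((feat, cross, cat, b) + oc)
    return pd.DataFrame(
        rows, columns=["feature", "cross", "category", "bin", *CONTRAST_KEYS]
    ).set_index("feature")


def enumerate_rule_table() -> pd.DataFrame:
    """Category and bin for all 3^4 = 81 outcome combinations."""
    rows = []
    for oc in product(OUTCOMES, repeat=4):
        cat, b = classify_inheritance(*oc)
        rows.append((*oc, cat, b))
    return pd.DataFrame(rows, columns=[*CONTRAST_KEYS, "category", "bin"])


def inheritance_summary(calls: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Counts and proportions per category, optionally per cross/tissue."""
    keys = by or [c for c in ("cross", "tissue") if c in calls.columns]
    grouped = calls.groupby(keys)["category"] if keys else calls["category"]
    counts = (
        grouped.value_counts().unstack(fill_value=0)
        if keys
        else calls["category"].value_counts().to_frame().T
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    counts.columns = [f"n_{c}" for c in counts.columns]
    props.columns = [f"prop_{c.removeprefix('n_')}" for c in counts.columns]
    return pd.concat([counts, props], axis=1)


def non_additive_features(calls: pd.DataFrame) -> set[str]:
    """Features with dominant / overdominant / underdominant expression."""
    mask = calls["category"].isin(NON_ADDITIVE)
    return set(calls.index[mask])


def specific_sets(set_a: set, set_b: set) -> dict[str, set]:
    """Venn partition of two feature sets (e.g. per-cross non-additive sets)."""
    return {"a_only": set_a - set_b, "b_only": set_b - set_a, "shared": set_a & set_b}


def shared_unique_across(sets: dict[str, set]) -> dict[str, object]:
    """Shared-by-all and unique-per-key partition of several feature sets."""
    keys = list(sets)
    shared = set.intersection(*sets.values()) if sets else set()
    unique = {
        k: sets[k] - set.union(*(sets[j] for j in keys if j != k)) if len(keys) > 1 else sets[k]
        for k in keys
    }
    return {"shared": shared, "unique": unique}
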