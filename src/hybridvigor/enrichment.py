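"""Hypergeometric over-representation of a feature list in gene sets.

For a universe of N features, a set with K members in the universe and a
query of n features hitting k of them, the enrichment p value is the
upper hypergeometric tail P(X >= k). Sets with K = 0 or k = 0 are
reported but excluded from the Benjamini–Hochberg family (they cannot be
enriched); a set is called enriched when padj < alpha.

Gene sets come from GMT files (see :mod:`hybridvigor.io`); the universe is
caller-supplied — typically the tissue-expressed feature set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


def hypergeom_enrichment(
    query,
    universe,
    sets: dict[str, set],
    alpha: float = 0.05,
    descriptions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-set enrichment table with k, K, n, N, p, padj and the call.

    ``query`` must be a subset of ``universe``; offending ids raise.
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    outside = query - universe
    if outside:
        raise ValueError(f"query ids outside the universe: {sorted(outside)[:10]}")

    n_univ, n_query = len(universe), len(query)
    rows = []
    for set_id, members in sets.items():
        in_univ = set(members) & universe
        k_set = len(in_univ)
        k_hit = len(in_univ & query)
        if k_set == 0 or k_hit == 0:
            p = None  # untestable / untested, excluded from the BH family
        else:
            p = float(stats.hypergeom.sf(k_hit - 1, n_univ, k_set, n_query))
        rows.append(
            {
                "set_id": set_id,
                "description": (descriptions or {}).get(set_id, ""),
                "k": k_hit, "K": k_set, "n": n_query, "N": n_univ,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("set_id")
    tested = out["p"].notna()
    out["padj"] = np.nan
    if tested.any():
        out.loc[tested, "padj"] = bh_adjust(out.loc[tested, "p"].to_numpy(float))
    out["enriched"] = tested.to_numpy() & (out["padj"].to_numpy(float) < alpha)
    return out.sort_values("p", na_position="last")
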