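"""lncRNA candidate filtering and cis/trans target assignment.

A transcript survives the candidate filter iff it is at least 200 bp long,
reaches FPKM >= 1 and read coverage >= 2, has at least two exons, carries a
GffCompare class code in {i, u, x} (intronic / intergenic / antisense
overlap), is either a known-lncRNA homolog or negative in every
coding-potential screen, and has no Pfam protein-domain hit. The
coding-potential and homology verdicts are consumed as precomputed boolean
columns; the external tools themselves are out of scope.

Targets: a gene is a *cis* target of a lncRNA when both lie on the same
chromosome with an edge-to-edge interval gap of at most ``window`` bp
(default 100 kb; 0 for overlapping features; boundary inclusive; strand
ignored). A gene is a *trans* target when the Pearson correlation of the
two expression profiles satisfies |r| >= 0.95 across the shared samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 100_000
DEFAULT_TRANS_COR = 0.95

LNCRNA_CLASS_CODES = frozenset({"i", "u", "x"})

FILTER_STAGES = (
    "length", "fpkm", "coverage", "exons", "class_code", "coding_potential", "pfam",
)


@dataclass
class FilterReport:
    candidates: list
    attrition: pd.Series  # removed at each stage, applied in order


def filter_lncrna_candidates(
    features: pd.DataFrame,
    min_len: int = 200,
    min_fpkm: float = 1.0,
    min_cov: float = 2.0,
    classes: frozenset = LNCRNA_CLASS_CODES,
    coding_flag_columns: tuple = ("cpc_coding", "cnci_coding", "plek_coding"),
) -> FilterReport:
    """Apply the lncRNA candidate filter chain, reporting per-stage attrition.

    ``features`` is indexed by transcript id with columns ``length``,
    ``max_fpkm``, ``coverage``, ``exons``, ``class_code``,
    ``known_lncrna_hit``, ``pfam_hit`` and the coding-potential columns.
    Unknown class codes simply fail the class stage (logged).
    """
    required = ["length", "max_fpkm", "coverage", "exons", "class_code",
                "known_lncrna_hit", "pfam_hit", *coding_flag_columns]
    missing = [c for c in required if c not in features.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")

    unknown = set(features["class_code"].unique()) - set("iuxjkmnoepsc=. ")
    if unknown:
        logger.warning("unknown GffCompare class codes retained and failed: %s", sorted(unknown))

    no_coding_evidence = ~features[list(coding_flag_columns)].any(axis=1)
    stage_pass = {
        "length": features["length"] >= min_len,
        "fpkm": features["max_fpkm"] >= min_fpkm,
        "coverage": features["coverage"] >= min_cov,
        "exons": features["exons"] >= 2,
        "class_code": features["class_code"].isin(classes),
        "coding_potential": features["known_lncrna_hit"].astype(bool) | no_coding_evidence,
        "pfam": ~features["pfam_hit"].astype(bool),
    }
    alive = pd.Series(True, index=features.index)
    attrition = {}
    for stage in FILTER_STAGES:
        removed = alive & ~stage_pass[stage]
        attrition[stage] = int(removed.sum())
        alive &= stage_pass[stage]
    return FilterReport(list(features.index[alive]), pd.Series(attrition, name="removed"))


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Edge-to-edge gap between two 1-based inclusive intervals; 0 if they touch/overlap."""
    if start_a > end_a or start_b > end_b:
        raise ValueError("malformed interval: start > end")
    return max(0, max(start_a, start_b) - min(end_a, end_b) - 1)


def cis_pairs(
    lncrna: pd.DataFrame, genes: pd.DataFrame, window: int = DEFAULT_CIS_WINDOW
) -> pd.DataFrame:
    """All (lncRNA, gene) same-chromosome pairs with gap <= window.

    Both frames are indexed by feature id with columns ``chrom``, ``start``,
    ``end`` (1-based inclusive). Strand is ignored. Returns a frame with
    columns lncrna/gene/mode/distance sorted by (lncrna, gene).
    """
    for frame, name in ((lncrna, "lncrna"), (genes, "genes")):
        if (frame["start"] > frame["end"]).any():
            bad = frame.index[frame["start"] > frame["end"]].tolist()
            raise ValueError(f"malformed coordinates (start > end) in {name}: {bad}")
    rows = []
    for chrom, lsub in lncrna.groupby("chrom"):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        ls, le = lsub["start"].to_numpy()[:, None], lsub["end"].to_numpy()[:, None]
        gs, ge = gsub["start"].to_numpy()[None, :], gsub["end"].to_numpy()[None, :]
        gap = np.maximum(0, np.maximum(ls, gs) - np.minimum(le, ge) - 1)
        li, gi = np.nonzero(gap <= window)
        rows.extend(
            (lsub.index[i], gsub.index[j], "cis", int(gap[i, j])) for i, j in zip(li, gi)
        )
    out = pd.DataFrame(rows, columns=["lncrna", "gene", "mode", "distance"])
    return out.sort_values(["lncrna", "gene"], ignore_index=True)


def trans_pairs(
    lncrna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    min_abs_cor: float = DEFAULT_TRANS_COR,
) -> pd.DataFrame:
    """All (lncRNA, gene) pairs with |Pearson r| >= min_abs_cor.

    Expression frames are features × samples over a shared sample set
    (>= 3 samples). Zero-variance features are skipped with a warning
    (their correlation is undefined). Returns columns
    lncrna/gene/mode/correlation.
    """
    shared = lncrna_expr.columns.intersection(gene_expr.columns)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    lx = lncrna_expr[shared].to_numpy(float)
    gx = gene_expr[shared].to_numpy(float)
    l_ok = lx.std(axis=1) > 0
    g_ok = gx.std(axis=1) > 0
    if (~l_ok).any() or (~g_ok).any():
        warnings.warn(
            f"skipping zero-variance features: {int((~l_ok).sum())} lncRNA, "
            f"{int((~g_ok).sum())} genes",
            stacklevel=2,
        )
    lz = (lx[l_ok] - lx[l_ok].mean(1, keepdims=True))
    gz = (gx[g_ok] - gx[g_ok].mean(1, keepdims=True))
    lz /= np.linalg.norm(lz, axis=1, keepdims=True)
    gz /= np.linalg.norm(gz, axis=1, keepdims=True)
    r = lz @ gz.T
    li, gi = np.nonzero(np.abs(r) >= min_abs_cor)
    l_ids = lncrna_expr.index[l_ok]
    g_ids = gene_expr.index[g_ok]
    out = pd.DataFrame(
        {
            "lncrna": l_ids[li],
            "gene": g_ids[gi],
            "mode": "trans",
            "correlation": r[li, gi],
        }
    )
    return out.sort_values(["lncrna", "gene"], ignore_index=True)
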