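"""Signed weighted co-expression networks: soft threshold, TOM, modules,
eigengenes, module–trait statistics, hubs and permutation preservation.

The pipeline mirrors the standard weighted co-expression workflow:

1. keep the top fraction (default 40%) most variable features;
2. signed adjacency ``a_ij = ((1 + r_ij) / 2) ** beta`` from the Pearson
   correlation of feature profiles, with ``beta`` the smallest power in a
   grid whose network is approximately scale-free (signed R^2 of the
   log-log degree distribution >= 0.8);
3. topological overlap ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)``
   with ``L_ij = sum_u a_iu a_uj``; modules are branches of an
   average-linkage tree on ``1 − TOM``, cut at the height that yields the
   most clusters of at least ``min_size`` members (a deterministic static
   stand-in for the dynamic tree cut), remainder unassigned (label 0);
4. each module is summarized by its eigengene — the first principal
   component of the standardized member expression, sign-oriented to
   correlate non-negatively with the module's mean expression — and
   modules with eigengene dissimilarity ``1 − r`` below the merge cut are
   merged iteratively;
5. module–trait association is the Pearson correlation of eigengene and
   trait with the Student-t p value; hub features have both |gene
   significance| and |module membership| strictly above 0.7;
6. preservation of reference modules in a test network is scored by a
   permutation Z for a density statistic (mean within-module adjacency)
   and a connectivity statistic (correlation of intramodular connectivity
   vectors), summarized by Zsummary = median of the class Zs, read against
   the conventional thresholds (>10 strong, 2–10 weak-to-moderate, <2 none).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def select_most_variable(expr: pd.DataFrame, fraction: float = 0.40) -> pd.DataFrame:
    """Top ``ceil(fraction * n)`` features by variance (ties: id order)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to rank variance")
    n_keep = int(np.ceil(fraction * len(expr)))
    var = expr.var(axis=1, ddof=1)
    order = pd.DataFrame({"var": var, "id": expr.index.astype(str)}).sort_values(
        ["var", "id"], ascending=[False, True]
    )
    return expr.loc[order.index[:n_keep]]


def signed_adjacency(expr: pd.DataFrame, power: float) -> pd.DataFrame:
    """Signed adjacency ((1 + r)/2)^power with zero diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    x = expr.to_numpy(float)
    if (x.std(axis=1) == 0).any():
        raise ValueError("zero-variance features present; pre-filter them")
    r = np.corrcoef(x)
    a = ((1.0 + r) / 2.0) ** power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(np.clip(a, 0.0, 1.0), index=expr.index, columns=expr.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) vs log10 k over equal-count bins.

    Positive when the degree distribution decays (negative slope), the
    signature of approximate scale-free topology.
    """
    k = np.asarray(connectivity, float)
    k = k[k > 0]
    if k.size < n_bins:
        n_bins = max(2, k.size // 2)
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return 0.0
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    total = k.size
    for b in range(len(edges) - 1):
        members = k[idx == b]
        width = edges[b + 1] - edges[b]
        if members.size == 0 or width <= 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / total / width))
    if len(xs) < 3:
        return 0.0
    slope, _, r_value, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r_value**2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers=range(1, 31),
    fit_target: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Smallest power reaching the scale-free fit target (else argmax, flagged).

    Returns (beta, table) where the table lists fit and mean/median
    connectivity per candidate power.
    """
    if expr.shape[1] < 8:
        warnings.warn("fewer than 8 samples: soft-threshold fit is unreliable", stacklevel=2)
    x = expr.to_numpy(float)
    if (x.std(axis=1) == 0).any():
        raise ValueError("zero-variance features present; pre-filter them")
    r = np.corrcoef(x)
    base = (1.0 + r) / 2.0
    np.fill_diagonal(base, 0.0)
    rows = []
    for p in powers:
        k = (base**p).sum(axis=1)
        rows.append({"power": p, "fit": scale_free_fit(k),
                     "mean_k": float(k.mean()), "median_k": float(np.median(k))})
    table = pd.DataFrame(rows)
    reaching = table[table["fit"] >= fit_target]
    if len(reaching):
        beta = int(reaching["power"].iloc[0])
        table.attrs["fit_target_reached"] = True
    else:
        beta = int(table.loc[table["fit"].idxmax(), "power"])
        table.attrs["fit_target_reached"] = False
        warnings.warn(
            f"no power reaches scale-free fit {fit_target}; using argmax power {beta}",
            stacklevel=2,
        )
    return beta, table


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted network (diagonal 1)."""
    a = np.asarray(adjacency, float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    if np.abs(np.diag(a)).max() > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    l_mat = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l_mat + a) / denom
    np.fill_diagonal(tom, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return pd.DataFrame(tom)


@dataclass
class ModuleSet:
    """Module labels (0 = unassigned) with eigengenes and optional statistics."""

    labels: pd.Series                      # feature -> module id
    eigengenes: pd.DataFrame               # modules × samples, unit-norm rows
    membership: pd.DataFrame | None = None  # features × modules (MM)
    gene_significance: pd.DataFrame | None = None  # features × traits (GS)
    module_trait_r: pd.DataFrame | None = None
    module_trait_p: pd.DataFrame | None = None

    @property
    def module_ids(self) -> list[int]:
        return [m for m in sorted(self.labels.unique()) if m != 0]

    def members(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]


def module_eigengene(expr_members: pd.DataFrame) -> pd.Series:
    """First PC of the standardized member expression, over samples.

    Unit norm; sign chosen so the eigengene correlates non-negatively with
    the mean standardized member profile.
    """
    x = expr_members.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    if np.dot(eig, z.mean(axis=0)) < 0:
        eig = -eig
    return pd.Series(eig, index=expr_members.columns)


def _cut_tree_static(linkage_matrix, n: int, min_size: int) -> np.ndarray:
    """Static height cut maximizing the number of clusters of >= min_size.

    Scans the unique merge heights (midpoints between consecutive heights);
    ties prefer the lower cut. Features in clusters below min_size are
    labelled 0.
    """
    heights = np.unique(linkage_matrix[:, 2])
    grid = np.concatenate([(heights[:-1] + heights[1:]) / 2, [heights[-1] * 0.9999]])
    best = (-1, None)
    for h in grid:  # ties prefer the lower cut: clusters stay pure
        flat = hierarchy.fcluster(linkage_matrix, t=h, criterion="distance")
        sizes = np.bincount(flat)
        n_good = int((sizes[1:] >= min_size).sum())
        if n_good > best[0]:
            best = (n_good, flat)
    flat = best[1]
    sizes = pd.Series(flat).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_size]
    remap = {c: i + 1 for i, c in enumerate(sorted(keep, key=lambda c: (-sizes[c], c)))}
    return np.array([remap.get(c, 0) for c in flat])


def detect_modules(
    diss_tom: pd.DataFrame,
    expr: pd.DataFrame,
    min_size: int = 50,
    merge_cut: float = 0.25,
    merge_on_correlation: bool = False,
    rescue_kme: float = 0.7,
) -> ModuleSet:
    """Average-linkage modules from a TOM dissimilarity, with eigengene merging.

    The static cut keeps clusters of at least ``min_size``; remaining
    features are then *rescued* into the module whose eigengene they
    correlate with most strongly, provided that correlation exceeds
    ``rescue_kme`` (a deterministic stand-in for the dynamic hybrid cut's
    assignment stage; uncorrelated background stays unassigned).

    ``merge_cut`` is the eigengene dissimilarity 1 − r below which two
    modules merge (the conventional reading; r > 0.75 by default).
    ``merge_on_correlation=True`` switches to the literal alternative of
    merging whenever eigengene correlation >= merge_cut.
    """
    d = np.asarray(diss_tom, float)
    if d.min() < -1e-9 or d.max() > 1 + 1e-9:
        raise ValueError("dissimilarity must lie in [0, 1]")
    features = diss_tom.index
    if len(features) < min_size:
        warnings.warn("fewer features than min module size; everything unassigned", stacklevel=2)
        labels = pd.Series(0, index=features)
        return ModuleSet(labels, pd.DataFrame(columns=expr.columns))
    condensed = squareform((d + d.T) / 2, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    raw = _cut_tree_static(link, len(features), min_size)
    labels = pd.Series(raw, index=features)
    labels = _rescue_unassigned(labels, expr, rescue_kme)
    labels = _merge_modules(labels, expr, merge_cut, merge_on_correlation)
    eig = compute_eigengenes(labels, expr)
    return ModuleSet(labels, eig)


def _rescue_unassigned(labels: pd.Series, expr: pd.DataFrame, kme_threshold: float) -> pd.Series:
    """Attach unassigned features with |eigengene correlation| above threshold."""
    mods = [m for m in sorted(labels.unique()) if m != 0]
    loose = labels.index[labels == 0]
    if not mods or loose.empty or kme_threshold >= 1:
        return labels
    eig = compute_eigengenes(labels, expr)
    x = expr.loc[loose].to_numpy(float)
    zx = x - x.mean(1, keepdims=True)
    norm = np.linalg.norm(zx, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    zx /= norm
    ze = eig.to_numpy() - eig.to_numpy().mean(1, keepdims=True)
    ze /= np.linalg.norm(ze, axis=1, keepdims=True)
    kme = zx @ ze.T  # loose features × modules
    best = np.abs(kme).argmax(axis=1)
    best_val = np.abs(kme)[np.arange(len(loose)), best]
    assign = best_val > kme_threshold
    if not assign.any():
        return labels
    labels = labels.copy()
    labels.loc[loose[assign]] = [eig.index[b] for b in best[assign]]
    return labels


def compute_eigengenes(labels: pd.Series, expr: pd.DataFrame) -> pd.DataFrame:
    mods = [m for m in sorted(labels.unique()) if m != 0]
    rows = {m: module_eigengene(expr.loc[labels.index[labels == m]]) for m in mods}
    return pd.DataFrame(rows).T.rename_axis("module")


def _merge_modules(labels, expr, merge_cut, merge_on_correlation):
    """Iteratively merge the closest eigengene pair until no pair qualifies."""
    labels = labels.copy()
    while True:
        mods = [m for m in sorted(labels.unique()) if m != 0]
        if len(mods) < 2:
            break
        eig = compute_eigengenes(labels, expr)
        r = np.corrcoef(eig.to_numpy())
        np.fill_diagonal(r, -np.inf)
        i, j = np.unravel_index(np.argmax(r), r.shape)
        best_r = r[i, j]
        qualifies = best_r >= merge_cut if merge_on_correlation else (1 - best_r) < merge_cut
        if not qualifies:
            break
        keep, drop = sorted((mods[i], mods[j]))
        labels[labels == drop] = keep
    # relabel 1..M by decreasing size for stable output
    sizes = labels[labels != 0].value_counts()
    remap = {m: i + 1 for i, m in enumerate(sorted(sizes.index, key=lambda m: (-sizes[m], m)))}
    return labels.map(lambda m: remap.get(m, 0))


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def module_trait_stats(
    module_set: ModuleSet, expr: pd.DataFrame, traits: pd.DataFrame, p_cut: float = 0.01
) -> ModuleSet:
    """Fill GS, MM and the module–trait r/p matrices of a ModuleSet.

    ``traits`` is samples × traits aligned to the expression columns. A
    perfectly correlated pair underflows to p = 0.0. Significance is read
    at p < ``p_cut``.
    """
    traits = traits.reindex(expr.columns)
    n = traits.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for module-trait statistics")
    if (traits.std(ddof=0) == 0).any():
        raise ValueError("constant trait supplied")
    eig = module_set.eigengenes
    r_mt = np.zeros((len(eig), traits.shape[1]))
    for a, (_, e) in enumerate(eig.iterrows()):
        for b, tname in enumerate(traits.columns):
            r_mt[a, b] = np.corrcoef(e.to_numpy(), traits[tname].to_numpy(float))[0, 1]
    module_set.module_trait_r = pd.DataFrame(r_mt, index=eig.index, columns=traits.columns)
    module_set.module_trait_p = pd.DataFrame(
        _pearson_p(r_mt, n), index=eig.index, columns=traits.columns
    )

    x = expr.to_numpy(float)
    zx = (x - x.mean(1, keepdims=True))
    norm = np.linalg.norm(zx, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    zx /= norm
    # MM: correlation of each feature with each module eigengene
    ze = eig.to_numpy() - eig.to_numpy().mean(1, keepdims=True)
    ze /= np.linalg.norm(ze, axis=1, keepdims=True)
    module_set.membership = pd.DataFrame(zx @ ze.T, index=expr.index, columns=eig.index)
    # GS: correlation with each trait
    zt = traits.to_numpy(float).T
    zt = zt - zt.mean(1, keepdims=True)
    zt /= np.linalg.norm(zt, axis=1, keepdims=True)
    module_set.gene_significance = pd.DataFrame(zx @ zt.T, index=expr.index, columns=traits.columns)
    return module_set


def hub_genes(
    module_set: ModuleSet, trait: str, gs_cut: float = 0.7, mm_cut: float = 0.7
) -> dict[int, list]:
    """Per-module hubs: |GS| > gs_cut and |MM with own eigengene| > mm_cut."""
    if module_set.membership is None or module_set.gene_significance is None:
        raise ValueError("run module_trait_stats first")
    gs = module_set.gene_significance[trait]
    out = {}
    for m in module_set.module_ids:
        members = module_set.members(m)
        mm = module_set.membership.loc[members, m]
        mask = (gs.loc[members].abs() > gs_cut) & (mm.abs() > mm_cut)
        out[m] = list(members[mask])
    return out


@dataclass
class PreservationReport:
    table: pd.DataFrame  # per module: obs/Z for density & connectivity, Zsummary, interpretation
    n_permutations: int


def _interpret_z(z: float) -> str:
    if np.isnan(z):
        return "NA"
    if z > 10:
        return "strong"
    if z >= 2:
        return "weak-to-moderate"
    return "none"


def module_preservation(
    reference: ModuleSet,
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    power: float,
    n_perm: int = 50,
    seed: int = 0,
) -> PreservationReport:
    """Permutation Zsummary preservation of reference modules in test data.

    Density statistic: mean within-module signed adjacency in the test
    network. Connectivity statistic: Pearson correlation of the
    intramodular connectivity vectors between reference and test. The null
    reassigns module labels uniformly at random among the shared features
    of the test network. Zsummary is the median of the two class Zs; >10
    strong, 2–10 weak-to-moderate, <2 none.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    rng = np.random.default_rng(seed)
    shared = reference.labels.index.intersection(test_expr.index)
    labels = reference.labels.loc[shared]
    adj_ref = signed_adjacency(ref_expr.loc[shared], power).to_numpy()
    adj_test = signed_adjacency(test_expr.loc[shared], power).to_numpy()
    pos = {f: i for i, f in enumerate(shared)}

    rows = []
    lab_arr = labels.to_numpy()
    for m in reference.module_ids:
        members = reference.members(m)
        if len(members) < 2:
            raise ValueError(f"module {m} has fewer than 2 features; preservation undefined")
        present = [f for f in members if f in pos]
        if len(present) < 2:
            warnings.warn(f"module {m} absent from test features; reported NA", stacklevel=2)
            rows.append({"module": m, "size": len(present), "density_obs": np.nan,
                         "z_density": np.nan, "connectivity_obs": np.nan,
                         "z_connectivity": np.nan, "z_summary": np.nan,
                         "interpretation": "NA"})
            continue
        idx = np.array([pos[f] for f in present])
        dens_obs = _mean_offdiag(adj_test[np.ix_(idx, idx)])
        kim_ref = adj_ref[np.ix_(idx, idx)].sum(axis=1)
        kim_test = adj_test[np.ix_(idx, idx)].sum(axis=1)
        conn_obs = _safe_corr(kim_ref, kim_test)

        dens_null = np.empty(n_perm)
        conn_null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(lab_arr)
            sel = np.flatnonzero(perm == m)
            if len(sel) != len(idx):  # permutation preserves label counts
                sel = rng.choice(len(lab_arr), size=len(idx), replace=False)
            dens_null[b] = _mean_offdiag(adj_test[np.ix_(sel, sel)])
            conn_null[b] = _safe_corr(kim_ref, adj_test[np.ix_(sel, sel)].sum(axis=1))
        z_d = _z(dens_obs, dens_null)
        z_c = _z(conn_obs, conn_null)
        z_sum = float(np.median([z_d, z_c]))
        rows.append({"module": m, "size": len(present), "density_obs": dens_obs,
                     "z_density": z_d, "connectivity_obs": conn_obs,
                     "z_connectivity": z_c, "z_summary": z_sum,
                     "interpretation": _interpret_z(z_sum)})
    return PreservationReport(pd.DataFrame(rows).set_index("module"), n_perm)


def _mean_offdiag(a: np.ndarray) -> float:
    n = a.shape[0]
    return float((a.sum() - np.trace(a)) / (n * (n - 1)))


def _safe_corr(x, y) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _z(obs: float, null: np.ndarray) -> float:
    sd = null.std(ddof=1)
    if sd == 0:
        return np.nan
    return float((obs - null.mean()) / sd)
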