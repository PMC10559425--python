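"""Synthetic data with planted ground truth for every pipeline stage.

Four generators emulate the study design of a two-breed layer cross
(purebreds WL and YY, reciprocal crosses WY and YW, laying-period feed
trial) so that heterosis estimation, inheritance classification, target
calling and network detection can all be validated against known truth:

* :func:`simulate_phenotypes` — per-bird feed-trial records whose group
  means are planted (defaults on the scale of the published adjusted
  means) and whose daily feed intake is built from the regression
  structure behind residual feed intake, so the planted RFI structure is
  exact;
* :func:`simulate_counts` — negative-binomial count matrices whose group
  means realize planted inheritance bins;
* :func:`simulate_coexpression` — latent-factor modular expression with a
  trait driven by one module;
* :func:`simulate_annotation` — a toy genome layout with a known list of
  cis (lncRNA, gene) pairs.

Every generator takes an explicit seed, uses one local RNG stream, and is
byte-reproducible for a fixed seed. All phenotype units are grams /
grams-per-day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("WL", "WY", "YW", "YY")
PARENTS = ("WL", "YY")
CROSSES = ("WY", "YW")

#: Published-scale adjusted group means used as planted defaults
#: (DFC/DEM in g/d, BW in g, BWG in g/d).
DEFAULT_TRAIT_MEANS = {
    "WL": {"dfc": 100.27, "bw": 1700.0, "dem": 52.90, "bwg": 1.0},
    "WY": {"dfc": 94.87, "bw": 1800.0, "dem": 47.80, "bwg": 1.2},
    "YW": {"dfc": 103.28, "bw": 1800.0, "dem": 45.45, "bwg": 1.2},
    "YY": {"dfc": 90.77, "bw": 1900.0, "dem": 36.77, "bwg": 1.5},
}
#: Individual-bird SDs consistent with SEs near 1 g/d at n ~ 200.
DEFAULT_TRAIT_SDS = {
    g: {"dfc": 14.0, "bw": 150.0, "dem": 9.0, "bwg": 2.0} for g in GROUPS
}


@dataclass
class PhenoSimConfig:
    group_names: tuple = GROUPS
    n_per_group: int | dict = 200
    trait_means: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_TRAIT_MEANS.items()})
    trait_sds: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_TRAIT_SDS.items()})
    rfi_betas: tuple = (0.2, 1.0, 1.0)  # coefficients of (mbw, bwg, dem) in DFC
    noise_sd: float = 5.0               # g/d, the planted RFI scale
    test_days: int = 28
    seed: int = 0

    def n_for(self, group: str) -> int:
        n = self.n_per_group[group] if isinstance(self.n_per_group, dict) else self.n_per_group
        if n < 2:
            raise ValueError("n_per_group must be >= 2")
        return int(n)

    def validate(self) -> None:
        if len(self.group_names) != 4:
            raise ValueError("expected 4 group labels (two purebreds, two crosses)")
        for g in self.group_names:
            self.n_for(g)
            if any(sd < 0 for sd in self.trait_sds[g].values()):
                raise ValueError("trait SDs must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_phenotypes(cfg: PhenoSimConfig) -> tuple[pd.DataFrame, dict]:
    """Per-bird feed-trial table plus the planted truth record.

    Body weight and gain are drawn per bird; start/end weights reconstruct
    the mean weight and gain exactly. Daily feed intake is the planted
    group mean plus the RFI regression structure
    ``beta . (X_i − E[X_group])`` plus N(0, noise_sd) — so the planted
    group means of every trait are exact in expectation and the planted
    residual-feed-intake variation has SD ``noise_sd``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for g in cfg.group_names:
        n = cfg.n_for(g)
        mean, sd = cfg.trait_means[g], cfg.trait_sds[g]
        bw = rng.normal(mean["bw"], sd["bw"], n)
        bwg = rng.normal(mean["bwg"], sd["bwg"], n)
        dem = np.clip(rng.normal(mean["dem"], sd["dem"], n), 0.0, None)
        mbw = bw**0.75
        mbw_mean = mean["bw"] ** 0.75
        b1, b2, b3 = cfg.rfi_betas
        dfc = (
            mean["dfc"]
            + b1 * (mbw - mbw_mean)
            + b2 * (bwg - mean["bwg"])
            + b3 * (dem - mean["dem"])
            + rng.normal(0.0, cfg.noise_sd, n)
        )
        bw_start = bw - bwg * cfg.test_days / 2.0
        bw_end = bw + bwg * cfg.test_days / 2.0
        for i in range(n):
            rows.append(
                {
                    "bird_id": f"{g}_{i + 1:04d}", "group": g, "dfc": dfc[i],
                    "bw_start": bw_start[i], "bw_end": bw_end[i],
                    "total_egg_mass": dem[i] * cfg.test_days, "test_days": cfg.test_days,
                }
            )
    truth = {
        "trait_means": {g: dict(cfg.trait_means[g]) for g in cfg.group_names},
        "rfi_betas": tuple(cfg.rfi_betas),
        "noise_sd": cfg.noise_sd,
    }
    return pd.DataFrame(rows), truth


# --- counts with planted inheritance bins -------------------------------

#: log2 offsets (P1, P2, F) relative to baseline, in units of the effect
#: size delta; F applies to both reciprocal crosses.
_BIN_PATTERNS = {
    1: (0.0, 1.0, 2.0),    # overdominant, above high parent, P2 high
    2: (0.0, 0.0, 1.0),    # overdominant, above parent (parents equal)
    12: (1.0, 0.0, 2.0),   # overdominant, above high parent, P1 high
    3: (0.0, 1.0, 1.0),    # dominant high, P2 high
    11: (1.0, 0.0, 1.0),   # dominant high, P1 high
    5: (0.0, 1.0, 0.0),    # dominant low, P1 low
    9: (1.0, 0.0, 0.0),    # dominant low, P2 low
    6: (0.0, 1.0, -1.0),   # underdominant, below low parent, P2 high
    7: (0.0, 0.0, -1.0),   # underdominant, below parent
    8: (1.0, 0.0, -1.0),   # underdominant, below low parent, P1 high
    "conserved": (0.0, 0.0, 0.0),
}
# additive bins: F sits at the linear mid-parent, handled specially
_ADDITIVE_BINS = {4: (0.0, 1.0), 10: (1.0, 0.0)}

VALID_BINS = tuple(_BIN_PATTERNS) + tuple(_ADDITIVE_BINS)


@dataclass
class ExprSimConfig:
    n_genes: int = 200
    n_lncrna: int = 0
    n_per_group: int = 8
    bin_assignment: dict | None = None   # feature id -> bin (1-12 or "conserved")
    baseline_mean: float = 500.0
    effect_log2fc: float = 3.0
    dispersion: float = 0.05
    group_names: tuple = GROUPS
    seed: int = 0

    def validate(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.bin_assignment:
            bad = {b for b in self.bin_assignment.values() if b not in VALID_BINS}
            if bad:
                raise ValueError(f"unknown bin label(s) {sorted(map(str, bad))}; valid: {VALID_BINS}")


def _group_means(bin_label, baseline: float, delta: float) -> dict:
    p1, p2 = PARENTS
    wy, yw = CROSSES
    if bin_label in _ADDITIVE_BINS:
        o1, o2 = _ADDITIVE_BINS[bin_label]
        m1, m2 = baseline * 2.0 ** (o1 * delta), baseline * 2.0 ** (o2 * delta)
        f = (m1 + m2) / 2.0
        return {p1: m1, p2: m2, wy: f, yw: f}
    o1, o2, of = _BIN_PATTERNS[bin_label]
    return {
        p1: baseline * 2.0 ** (o1 * delta),
        p2: baseline * 2.0 ** (o2 * delta),
        wy: baseline * 2.0 ** (of * delta),
        yw: baseline * 2.0 ** (of * delta),
    }


def simulate_counts(cfg: ExprSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """NB count matrix with planted inheritance bins per feature.

    Returns (counts features × samples, sample metadata, truth bins).
    Features without an entry in ``bin_assignment`` are conserved.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    feats = [f"gene_{i + 1:05d}" for i in range(cfg.n_genes)] + [
        f"lnc_{i + 1:05d}" for i in range(cfg.n_lncrna)
    ]
    assignment = cfg.bin_assignment or {}
    samples, groups = [], []
    for g in cfg.group_names:
        for i in range(cfg.n_per_group):
            samples.append(f"{g}_{i + 1:02d}")
            groups.append(g)
    sample_meta = pd.DataFrame({"sample": samples, "group": groups}).set_index("sample")

    counts = np.zeros((len(feats), len(samples)), dtype=np.int64)
    truth = {}
    for row, fid in enumerate(feats):
        b = assignment.get(fid, "conserved")
        truth[fid] = b
        means = _group_means(b, cfg.baseline_mean, cfg.effect_log2fc)
        mu = np.array([means[g] for g in groups])
        counts[row] = _nb_draw(rng, mu, cfg.dispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(feats, name="feature"), columns=samples)
    return counts_df, sample_meta, pd.Series(truth, name="bin")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha < 1e-8:
        return rng.poisson(mu)
    size = 1.0 / alpha
    return rng.negative_binomial(size, size / (size + mu))


# --- modular co-expression ----------------------------------------------


@dataclass
class NetworkSimConfig:
    n_modules: int = 3
    genes_per_module: int = 60
    n_background: int = 60
    factor_sd: float = 1.0
    loading_range: tuple = (0.7, 0.9)
    gene_noise_sd: float = 0.5
    trait_module_index: int = 0
    trait_noise_sd: float = 0.5
    n_samples: int = 24
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.trait_module_index < self.n_modules:
            raise ValueError(
                f"trait_module_index {self.trait_module_index} out of range "
                f"[0, {self.n_modules})"
            )
        if self.factor_sd <= 0 or self.gene_noise_sd < 0 or self.trait_noise_sd < 0:
            raise ValueError("SDs must be non-negative (factor SD positive)")


def simulate_coexpression(cfg: NetworkSimConfig) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Latent-factor modular expression, a module-driven trait, truth labels.

    Gene j of module m is ``loading_j * factor_m + noise``; background
    genes are pure noise (truth label 0). The trait equals the chosen
    module's factor plus N(0, trait_noise_sd).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    factors = rng.normal(0.0, cfg.factor_sd, size=(cfg.n_modules, cfg.n_samples))
    rows, labels, ids = [], [], []
    lo, hi = cfg.loading_range
    for m in range(cfg.n_modules):
        loadings = rng.uniform(lo, hi, cfg.genes_per_module)
        noise = rng.normal(0.0, cfg.gene_noise_sd, size=(cfg.genes_per_module, cfg.n_samples))
        rows.append(loadings[:, None] * factors[m] + noise)
        labels += [m + 1] * cfg.genes_per_module
        ids += [f"mod{m + 1}_g{j + 1:03d}" for j in range(cfg.genes_per_module)]
    if cfg.n_background:
        rows.append(rng.normal(0.0, cfg.gene_noise_sd + cfg.factor_sd,
                               size=(cfg.n_background, cfg.n_samples)))
        labels += [0] * cfg.n_background
        ids += [f"bg_g{j + 1:03d}" for j in range(cfg.n_background)]
    expr = pd.DataFrame(
        np.vstack(rows), index=pd.Index(ids, name="feature"),
        columns=[f"s{i + 1:02d}" for i in range(cfg.n_samples)],
    )
    trait = pd.Series(
        factors[cfg.trait_module_index] + rng.normal(0.0, cfg.trait_noise_sd, cfg.n_samples),
        index=expr.columns, name="trait",
    )
    return expr, trait, pd.Series(labels, index=expr.index, name="module")


# --- toy genome annotation ----------------------------------------------


@dataclass
class GenomeSimConfig:
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    n_genes: int = 50
    n_lncrna: int = 20
    cis_fraction: float = 0.5
    window: int = 100_000
    gene_length: tuple = (2_000, 20_000)
    lncrna_length: tuple = (200, 5_000)
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.cis_fraction <= 1:
            raise ValueError("cis_fraction must be in [0, 1]")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        for c, ln in self.chrom_lengths.items():
            if ln < max(self.gene_length[1], self.lncrna_length[1]):
                raise ValueError(f"chromosome {c} too short for the feature lengths")


def _place(rng, chrom_lengths, length_range):
    chroms = list(chrom_lengths)
    c = chroms[rng.integers(len(chroms))]
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    start = int(rng.integers(1, chrom_lengths[c] - length + 1))
    return c, start, start + length - 1


def simulate_annotation(cfg: GenomeSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Toy genome layout: (genes, lncRNA, truth cis pairs).

    A ``cis_fraction`` share of the lncRNA is planted within the window of
    a random gene; the truth list is nevertheless computed by brute force
    over *all* same-chromosome pairs, so incidental proximity counts too.
    Raises if a feature would exceed its chromosome.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    strands = np.array(["+", "-"])

    genes = []
    for i in range(cfg.n_genes):
        c, s, e = _place(rng, cfg.chrom_lengths, cfg.gene_length)
        genes.append({"id": f"gene_{i + 1:04d}", "chrom": c, "start": s, "end": e,
                      "strand": strands[rng.integers(2)], "feature_type": "gene"})
    genes = pd.DataFrame(genes).set_index("id")

    lncs = []
    n_cis = int(round(cfg.cis_fraction * cfg.n_lncrna))
    for i in range(cfg.n_lncrna):
        length = int(rng.integers(cfg.lncrna_length[0], cfg.lncrna_length[1] + 1))
        if i < n_cis and len(genes):
            anchor = genes.iloc[int(rng.integers(len(genes)))]
            c = anchor["chrom"]
            gap = int(rng.integers(0, cfg.window + 1))
            start = anchor["end"] + gap + 1
            if start + length - 1 > cfg.chrom_lengths[c]:
                start = max(1, int(anchor["start"]) - gap - length)
        else:
            c, start, _ = _place(rng, cfg.chrom_lengths, cfg.lncrna_length)
        end = start + length - 1
        if start < 1 or end > cfg.chrom_lengths[c]:
            raise ValueError(f"feature exceeds chromosome {c} bounds")
        lncs.append({"id": f"lnc_{i + 1:04d}", "chrom": c, "start": start, "end": end,
                     "strand": strands[rng.integers(2)], "feature_type": "lncRNA"})
    lncs = pd.DataFrame(lncs).set_index("id")

    truth = []
    for lid, lrow in lncs.iterrows():
        for gid, grow in genes.iterrows():
            if lrow["chrom"] != grow["chrom"]:
                continue
            gap = max(0, max(lrow["start"], grow["start"]) - min(lrow["end"], grow["end"]) - 1)
            if gap <= cfg.window:
                truth.append({"lncrna": lid, "gene": gid, "distance": int(gap)})
    truth = pd.DataFrame(truth, columns=["lncrna", "gene", "distance"]).sort_values(
        ["lncrna", "gene"], ignore_index=True
    )
    return genes, lncs, truth
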