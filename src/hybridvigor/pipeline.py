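"""End-to-end driver chaining every stage on synthetic or supplied data.

``run_pipeline(PipelineConfig)`` executes, in order: phenotype simulation
-> trait derivation and RFI -> heterosis estimation; count simulation ->
normalization and filtering -> differential expression -> inheritance
classification; toy annotation -> cis/trans target calling; modular
expression -> network construction, module-trait statistics, hubs and
preservation; and gene-set enrichment of the trait module's members. Each
stage logs its parameters and row counts to a machine-readable run log,
and a fixed seed reproduces the whole bundle exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, enrichment, expression, heterosis, inheritance, network
from . import phenotypes as pheno
from . import simulate, targets

DEFAULT_CROSSES = {"WY": ("WL", "YY"), "YW": ("WL", "YY")}


@dataclass
class PipelineConfig:
    """Every stage threshold in one serializable place."""

    seed: int = 0
    alpha: float = 0.05
    lfc_threshold: float = 1.2
    inheritance_use_lfc: bool = False
    cis_window: int = 100_000
    trans_min_abs_cor: float = 0.95
    variance_fraction: float = 0.40
    min_module_size: int = 50
    merge_cut: float = 0.25
    gs_cut: float = 0.7
    mm_cut: float = 0.7
    module_trait_p: float = 0.01
    n_preservation_perm: int = 50
    # synthetic-stage sizing
    pheno: simulate.PhenoSimConfig = field(default_factory=simulate.PhenoSimConfig)
    expr: simulate.ExprSimConfig = field(default_factory=simulate.ExprSimConfig)
    net: simulate.NetworkSimConfig = field(default_factory=simulate.NetworkSimConfig)
    genome: simulate.GenomeSimConfig = field(default_factory=simulate.GenomeSimConfig)

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.module_trait_p < 1:
            raise ValueError("significance levels must be in (0, 1)")
        if not 0 < self.variance_fraction <= 1:
            raise ValueError("variance_fraction must be in (0, 1]")
        if not 0 < self.merge_cut < 1:
            raise ValueError("merge_cut must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("pheno", simulate.PhenoSimConfig), ("expr", simulate.ExprSimConfig),
                         ("net", simulate.NetworkSimConfig), ("genome", simulate.GenomeSimConfig)):
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                for tup_field in ("group_names", "rfi_betas", "loading_range", "gene_length",
                                  "lncrna_length"):
                    if tup_field in sub_d and isinstance(sub_d[tup_field], list):
                        sub_d[tup_field] = tuple(sub_d[tup_field])
                d[key] = sub(**sub_d)
        return cls(**d)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute all stages; returns the result bundle (+ writes TSVs if asked)."""
    log: list[dict] = []
    bundle: dict = {"log": log}
    seed = config.seed

    def stage(name, fn, **params):
        try:
            result = fn()
        except Exception as err:  # annotate the failing stage
            raise PipelineError(name, err) from err
        log.append({"stage": name, "params": params})
        return result

    # 1. phenotypes -> traits -> RFI -> heterosis
    config.pheno.seed = seed
    raw, pheno_truth = stage("simulate_phenotypes", lambda: simulate.simulate_phenotypes(config.pheno))
    traits_tbl = stage("derive_traits", lambda: pheno.derive_traits(raw), n=len(raw))
    traits_tbl, rfi_fit = stage("compute_rfi", lambda: pheno.compute_rfi(traits_tbl))
    het = stage(
        "heterosis",
        lambda: heterosis.heterosis_table(
            phenotypes=traits_tbl, crosses=DEFAULT_CROSSES,
            traits=["dfc", "rfi", "fcr", "dem"],
        ),
    )
    bundle.update(phenotypes=traits_tbl, pheno_truth=pheno_truth,
                  rfi_model=rfi_fit, heterosis=het)

    # 2. counts -> normalize/filter -> DE -> inheritance
    config.expr.seed = seed + 1
    if config.expr.bin_assignment is None:
        config.expr.bin_assignment = default_bin_assignment(config.expr)
    counts, sample_meta, truth_bins = stage(
        "simulate_counts", lambda: simulate.simulate_counts(config.expr)
    )
    lengths = pd.Series(1000.0, index=counts.index)
    fpkm = stage("fpkm", lambda: expression.fpkm(counts, lengths))
    expressed = stage(
        "expressed_filter", lambda: expression.expressed_filter(fpkm, "any_sample")
    )
    groups = sample_meta["group"]
    sf = diffexpr.size_factors(counts)
    disp = diffexpr.estimate_dispersion(counts, groups, sf)
    calls = {}
    for cross, (p1, p2) in DEFAULT_CROSSES.items():
        contrasts = {
            "p1_vs_p2": {p1: 1.0, p2: -1.0},
            "f_vs_p1": {cross: 1.0, p1: -1.0},
            "f_vs_p2": {cross: 1.0, p2: -1.0},
            "f_vs_mp": diffexpr.mid_parent_contrast(cross, p1, p2),
        }
        de = {
            k: diffexpr.nb_wald_contrast(
                counts, groups, c, alpha=config.alpha,
                lfc_threshold=config.lfc_threshold, dispersion=disp, sf=sf, label=k,
                scale="mean" if k == "f_vs_mp" else "log",
            )
            for k, c in contrasts.items()
        }
        calls[cross] = inheritance.call_features(
            de, cross, alpha=config.alpha,
            lfc_threshold=config.lfc_threshold if config.inheritance_use_lfc else None,
        )
    log.append({"stage": "diffexpr+inheritance", "params": {
        "alpha": config.alpha, "lfc_threshold": config.lfc_threshold,
        "n_features": len(counts)}})
    all_calls = pd.concat(calls.values())
    bundle.update(counts=counts, fpkm=fpkm, expressed_mask=expressed,
                  truth_bins=truth_bins, inheritance_calls=all_calls,
                  inheritance_summary=inheritance.inheritance_summary(all_calls))

    # 3. annotation -> cis; fpkm -> trans
    config.genome.seed = seed + 2
    config.genome.window = config.cis_window
    genes_ann, lnc_ann, cis_truth = stage(
        "simulate_annotation", lambda: simulate.simulate_annotation(config.genome)
    )
    cis = stage(
        "cis_pairs",
        lambda: targets.cis_pairs(lnc_ann, genes_ann, window=config.cis_window),
        window=config.cis_window,
    )
    lnc_mask = fpkm.index.str.startswith("lnc_")
    trans = None
    if lnc_mask.any():
        trans = targets.trans_pairs(
            fpkm[lnc_mask], fpkm[~lnc_mask], min_abs_cor=config.trans_min_abs_cor
        )
    bundle.update(genes_annotation=genes_ann, lncrna_annotation=lnc_ann,
                  cis_pairs=cis, cis_truth=cis_truth, trans_pairs=trans)

    # 4. co-expression network
    config.net.seed = seed + 3
    expr, trait, truth_modules = stage(
        "simulate_coexpression", lambda: simulate.simulate_coexpression(config.net)
    )
    kept = network.select_most_variable(expr, 1.0)  # synthetic matrix is already compact
    beta, fit_table = network.pick_soft_threshold(kept)
    adj = network.signed_adjacency(kept, beta)
    tom = network.tom_similarity(adj)
    modules = network.detect_modules(
        1.0 - tom, kept, min_size=min(config.min_module_size, config.net.genes_per_module),
        merge_cut=config.merge_cut,
    )
    modules = network.module_trait_stats(
        modules, kept, trait.to_frame("trait"), p_cut=config.module_trait_p
    )
    hubs = network.hub_genes(modules, "trait", config.gs_cut, config.mm_cut)
    log.append({"stage": "network", "params": {"power": beta, "n_features": len(kept)}})
    bundle.update(network_expr=kept, network_trait=trait, truth_modules=truth_modules,
                  soft_threshold=beta, fit_table=fit_table, modules=modules, hubs=hubs)

    # 5. enrichment of the trait module against truth-derived sets
    sets = {
        f"truth_module_{m}": set(truth_modules.index[truth_modules == m])
        for m in sorted(truth_modules.unique()) if m != 0
    }
    trait_mod = modules.module_trait_r["trait"].abs().idxmax()
    enrich = stage(
        "enrichment",
        lambda: enrichment.hypergeom_enrichment(
            set(modules.members(trait_mod)), set(kept.index), sets, alpha=config.alpha
        ),
    )
    bundle["enrichment"] = enrich

    if out_dir is not None:
        _write_bundle(bundle, config, Path(out_dir))
    return bundle


def default_bin_assignment(cfg: simulate.ExprSimConfig) -> dict:
    """Spread a quarter of genes across all 12 bins, rest conserved."""
    n_planted = cfg.n_genes // 4
    bins = [b for b in simulate.VALID_BINS if b != "conserved"]
    return {
        f"gene_{i + 1:05d}": bins[i % len(bins)] for i in range(n_planted)
    }


def _write_bundle(bundle: dict, config: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["phenotypes"].to_csv(out_dir / "traits.csv", index=False)
    bundle["heterosis"].to_csv(out_dir / "heterosis.tsv", sep="\t", index=False)
    bundle["counts"].to_csv(out_dir / "counts.tsv", sep="\t")
    bundle["inheritance_calls"].to_csv(out_dir / "inheritance_calls.tsv", sep="\t")
    bundle["cis_pairs"].to_csv(out_dir / "cis_pairs.tsv", sep="\t", index=False)
    if bundle["trans_pairs"] is not None:
        bundle["trans_pairs"].to_csv(out_dir / "trans_pairs.tsv", sep="\t", index=False)
    bundle["modules"].labels.rename("module").to_csv(out_dir / "modules.tsv", sep="\t")
    bundle["enrichment"].to_csv(out_dir / "enrichment.tsv", sep="\t")
    (out_dir / "run_log.jsonl").write_text(
        "\n".join(json.dumps(entry) for entry in bundle["log"]) + "\n"
    )
    (out_dir / "config.json").write_text(json.dumps(config.to_dict(), indent=2, default=str))
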