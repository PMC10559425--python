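"""Run every analysis stage end-to-end on synthetic data.

One seeded configuration drives phenotype simulation and heterosis,
count simulation through differential expression and inheritance
classification, cis/trans target calling, network construction, and
gene-set enrichment of the trait-associated module. Artifacts are written
as plain TSV/JSON under the chosen output directory.
"""

import sys
from pathlib import Path

from hybridvigor.pipeline import PipelineConfig, run_pipeline

out = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("pipeline_out")
bundle = run_pipeline(PipelineConfig(seed=0), out_dir=out)

print("heterosis:")
print(bundle["heterosis"][["trait", "cross", "h_percent", "p", "stars"]]
      .round(3).to_string(index=False))
print("\ninheritance summary:")
print(bundle["inheritance_summary"].T.to_string())
print(f"\ncis pairs: {len(bundle['cis_pairs'])}; "
      f"soft threshold: {bundle['soft_threshold']}; "
      f"modules: {sorted(int(m) for m in bundle['modules'].module_ids)}")
print("\nenrichment of the trait module:")
print(bundle["enrichment"][["k", "K", "p", "padj", "enriched"]].to_string())
print(f"\nartifacts written to {out}/")
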