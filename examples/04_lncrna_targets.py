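"""Call cis and trans targets of lncRNA on a toy genome.

A synthetic annotation plants half the lncRNA near genes; cis targets are
genes within 100 kb on the same chromosome (edge-to-edge gap), trans
targets are genes whose expression correlates with the lncRNA at
|r| >= 0.95 regardless of location.
"""

import numpy as np
import pandas as pd

from hybridvigor.simulate import GenomeSimConfig, simulate_annotation
from hybridvigor.targets import cis_pairs, trans_pairs

genes, lncs, truth = simulate_annotation(GenomeSimConfig(seed=5))
cis = cis_pairs(lncs, genes, window=100_000)
print(f"cis pairs called: {len(cis)} (generator truth: {len(truth)})")
print(cis.head(5).to_string(index=False), "\n")

rng = np.random.default_rng(5)
base = rng.normal(size=12)
lnc_expr = pd.DataFrame(
    [base + rng.normal(0, 0.1, 12), rng.normal(size=12)],
    index=["lnc_correlated", "lnc_noise"],
)
gene_expr = pd.DataFrame([base, -base, rng.normal(size=12)], index=["gA", "gB", "gC"])
trans = trans_pairs(lnc_expr, gene_expr, min_abs_cor=0.95)
print(trans.round(3).to_string(index=False))
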