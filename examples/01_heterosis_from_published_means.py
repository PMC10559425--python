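"""Reproduce a published heterosis table from adjusted group means.

Given only the adjusted group means of four feed-efficiency traits for two
purebred layer lines (WL, YY) and their reciprocal crosses (WY, YW), the
mid-parent heterosis of each cross is H = (F − MP)/MP with MP the average
of the parental means. Feeding the printed means back through the formula
reproduces the printed percentages.
"""

import pandas as pd

from hybridvigor.heterosis import heterosis_table

means = pd.DataFrame(
    [
        {"trait": t, "group": g, "mean": m}
        for t, by_group in {
            "dfc": {"WL": 100.27, "WY": 94.87, "YW": 103.28, "YY": 90.77},
            "rfi": {"WL": 1.77, "WY": -3.14, "YW": 3.72, "YY": -2.26},
            "fcr": {"WL": 2.67, "WY": 2.06, "YW": 2.94, "YY": 3.33},
            "dem": {"WL": 52.90, "WY": 47.80, "YW": 45.45, "YY": 36.77},
        }.items()
        for g, m in by_group.items()
    ]
)

crosses = {"WY": ("WL", "YY"), "YW": ("WL", "YY")}
table = heterosis_table(means=means, crosses=crosses)
print(table[["trait", "cross", "f_mean", "pf_mean", "pm_mean", "h_percent"]]
      .round(2).to_string(index=False))
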