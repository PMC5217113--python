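"""Scaling arithmetic: how many constructs can one testis screen support?

An adult mouse testis holds ~1e8 cells; at a given transfection efficiency
only a fraction receive a construct, and each construct must independently
transfect enough cells to yield a reproducible abundance signal.
"""

import pandas as pd

from _common import RESULTS
from shscreen import screen_capacity

rows = []
for eff in (0.01, 0.02, 0.05):
    cap = screen_capacity(
        1e8, eff, min_cells_per_construct=100, constructs_per_gene=5
    )
    rows.append(
        {
            "transfection_efficiency": eff,
            "cells_transfected": int(cap.cells_transfected),
            "mean_cells_per_construct_L119": cap.mean_cells_per_construct(119),
            "max_constructs_at_100_cells": cap.max_constructs,
            "max_genes_at_5_per_gene": cap.max_genes,
        }
    )
df = pd.DataFrame(rows)
df.to_csv(RESULTS / "screen_capacity.tsv", sep="\t", index=False)

print("screen capacity of one testis (1e8 cells):")
print(df.to_string(index=False))
base = rows[0]
print(
    f"  at 1% efficiency a 119-construct pool averages "
    f"{base['mean_cells_per_construct_L119']} cells/construct; requiring 100 "
    f"cells/construct supports {base['max_constructs_at_100_cells']:,} "
    f"constructs = {base['max_genes_at_5_per_gene']:,} genes at 5/gene"
)
print(f"  table -> {RESULTS / 'screen_capacity.tsv'}")
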