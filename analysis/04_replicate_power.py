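"""How many biological replicates does the screen need?

Subsample replicates from a graded-effect simulated screen (test-construct
effects spread continuously over (-4, 0) log2 units, so there is always
something near the detection boundary) and record the smallest |median
log2FC| still declared significantly depleted.
"""

import pandas as pd

from _common import ANALYSIS_SEED, RESULTS, graded_screen
from shscreen import replicate_subsample_curve, run_count_pipeline

cfg, screen, groups = graded_screen()
_, _, fc = run_count_pipeline(groups, screen.input_pool_counts, cfg.manifest)
curve = replicate_subsample_curve(
    fc, cfg.manifest, alphas=(0.1, 0.05, 0.01), n_draws=200, seed=ANALYSIS_SEED
)

df = pd.DataFrame(
    [
        (e.n_replicates, e.alpha, round(e.median_min_abs_log2fc, 3),
         round(e.sd, 3), e.n_draws_with_hits)
        for e in curve.entries
    ],
    columns=["n_replicates", "alpha", "median_min_abs_log2fc", "sd",
             "n_draws_with_hits"],
)
df.to_csv(RESULTS / "replicate_curve.tsv", sep="\t", index=False)

print("minimum detectable |log2FC| by biological replicates (200 draws):")
for alpha in (0.1, 0.05, 0.01):
    sub = df[df.alpha == alpha]
    vals = [
        f"r={r}: {v}" if pd.notna(v) else f"r={r}: none"
        for r, v in zip(sub.n_replicates, sub.median_min_abs_log2fc)
    ]
    print(f"  P<={alpha}: " + ", ".join(vals))
print(f"  table -> {RESULTS / 'replicate_curve.tsv'}")
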