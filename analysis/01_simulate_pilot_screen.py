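"""Simulate a pilot-like pooled shRNA screen with known ground truth.

119 hairpin constructs over 25 genes (17 positive controls known to perturb
spermatogenesis, 8 negative controls), nine biological replicates with three
technical sequencing libraries each at ~5000 reads per construct, 2%
transfection efficiency of 1e8 germ cells.  Three positive genes carry only
one effective construct (noneffective RNAi), so the designed screen truth is
14 of 17 positives detectable under the two-hit rule.
"""

import pandas as pd

from _common import RESULTS, pilot_screen_dir, PILOT_SEED
from shscreen.io import read_count_table
from shscreen.library import load_manifest, manifest_summary

d = pilot_screen_dir()
manifest = load_manifest(d / "manifest.tsv")
s = manifest_summary(manifest)
pool = read_count_table(d / "input_pool.tsv")

truth = pd.read_csv(d / "truth.tsv", sep="\t")
per_gene = truth.groupby("gene").agg(
    n_constructs=("construct_id", "size"),
    n_effective=("selection_log2", lambda v: int((v <= -1).sum())),
    essential_true=("gene_essential_true", "first"),
)
RESULTS.mkdir(exist_ok=True)
per_gene.to_csv(RESULTS / "pilot_truth_by_gene.tsv", sep="\t")

print(f"simulated pilot-like screen (seed {PILOT_SEED}) -> {d}")
print(
    f"  {s.n_constructs} constructs, {s.n_genes} genes "
    f"(mode {s.mode_constructs_per_gene}/gene); classes {s.class_counts}"
)
print(f"  input pool sequenced to {pool.n_reads_total:,} reads")
print(
    f"  ground truth: {int(per_gene.essential_true.sum())} of "
    f"{len(manifest.genes_in_class('positive'))} positive genes carry >=2 "
    "effective constructs (detectable under the two-hit rule)"
)
print(f"  per-gene truth table -> {RESULTS / 'pilot_truth_by_gene.tsv'}")
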