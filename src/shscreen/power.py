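"""Design analyses: detectable effect size vs replicates, power vs coverage,
and screen-capacity arithmetic.

Two resampling analyses mirror how a completed screen is mined for design
guidance:

* ``replicate_subsample_curve`` reruns the construct tests on random subsets
  of biological replicates and records the smallest |median log2 fold change|
  that still reached significance — the minimum detectable effect size as a
  function of replicate number.
* ``coverage_power_curve`` thins the raw counts binomially (equivalent to
  uniform read subsampling), reruns the whole pipeline, and reports the
  fraction of positive-control genes recovered by the two-hit rule as a
  function of mean reads per construct.

``screen_capacity`` is the cell-budget arithmetic for scaling a pooled
in-vivo screen: cells transfected = total cells x efficiency, and the library
size is capped by the minimum acceptable number of independently transfected
cells per construct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .inference import InferenceConfig, construct_tests, gene_two_hit_calls
from .library import LibraryManifest
from .mapping import RawCountTable
from .quantify import (
    CountTable,
    FoldChangeMatrix,
    aggregate_technical,
    build_fold_change_matrix,
    raw_to_count_table,
)


@dataclass(frozen=True)
class ReplicateCurveEntry:
    n_replicates: int
    alpha: float
    median_min_abs_log2fc: float  # nan when no draw produced a significant hit
    sd: float
    n_draws_with_hits: int


@dataclass
class ReplicateCurve:
    entries: list[ReplicateCurveEntry]
    n_draws: int
    seed: int

    def entry(self, n_replicates: int, alpha: float) -> ReplicateCurveEntry:
        for e in self.entries:
            if e.n_replicates == n_replicates and e.alpha == alpha:
                return e
        raise KeyError((n_replicates, alpha))


@dataclass(frozen=True)
class PowerCurveEntry:
    mean_coverage: float
    power: float


@dataclass
class PowerCurve:
    entries: list[PowerCurveEntry]
    n_draws: int
    seed: int

    def power_at(self, coverage: float) -> float:
        for e in self.entries:
            if e.mean_coverage == coverage:
                return e.power
        raise KeyError(coverage)


def replicate_subsample_curve(
    fc: FoldChangeMatrix,
    manifest: LibraryManifest,
    alphas: Sequence[float] = (0.1, 0.05, 0.01),
    n_draws: int = 200,
    seed: int = 0,
    config: InferenceConfig | None = None,
    min_replicates: int = 1,
) -> ReplicateCurve:
    """Minimum detectable |log2FC| as a function of biological replicates.

    For each r from ``min_replicates`` to the full replicate count, draw
    ``n_draws`` random r-subsets of replicate columns (the single full-size
    subset when r equals the total), rerun the construct tests, and record
    per draw the smallest |median log2fc| among significantly depleted
    constructs.  Entries report the median and SD of that minimum across
    draws with at least one hit.
    """
    base = config or InferenceConfig()
    cols = fc.replicate_ids
    R = len(cols)
    if R < 1:
        raise ValueError("fold-change matrix has no replicates")
    if min_replicates > R:
        raise ValueError(f"cannot draw {min_replicates} of {R} replicates")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 17])
    entries: list[ReplicateCurveEntry] = []
    for r in range(min_replicates, R + 1):
        draws = (
            [list(cols)]
            if r == R
            else [
                list(rng.choice(cols, size=r, replace=False))
                for _ in range(n_draws)
            ]
        )
        mins: dict[float, list[float]] = {a: [] for a in alphas}
        for subset in draws:
            with warnings.catch_warnings():
                # r = 1 subsets are an intended regime of this analysis
                warnings.filterwarnings(
                    "ignore", message="single biological replicate"
                )
                calls = construct_tests(
                    fc.subset_replicates(subset), manifest, base
                )
            for a in alphas:
                sig = [
                    abs(c.median_log2fc)
                    for c in calls
                    if c.direction == "depleted" and c.p_value <= a
                ]
                mins[a].append(min(sig) if sig else np.nan)
        for a in alphas:
            vals = np.asarray(mins[a])
            ok = vals[~np.isnan(vals)]
            entries.append(
                ReplicateCurveEntry(
                    n_replicates=r,
                    alpha=a,
                    median_min_abs_log2fc=(
                        float(np.median(ok)) if ok.size else float("nan")
                    ),
                    sd=float(np.std(ok)) if ok.size else float("nan"),
                    n_draws_with_hits=int(ok.size),
                )
            )
    return ReplicateCurve(entries=entries, n_draws=n_draws, seed=seed)


def downsample_counts(
    table: RawCountTable, target_mean_coverage: float, seed: int = 0
) -> RawCountTable:
    """Binomially thin a count table to a target mean reads-per-construct.

    Each read is kept independently with probability p = target/current, so
    a count k becomes Binomial(k, p) — exactly equivalent to uniform read
    subsampling without replacement in expectation.  Unmapped/multimapped
    tallies are thinned with the same probability to preserve the count
    conservation invariant.  Thinning with p = 1 is the identity.
    """
    current = table.mean_coverage()
    if current == 0:
        raise ValueError(f"library {table.library_id!r} has no mapped reads")
    p = target_mean_coverage / current
    if p > 1 + 1e-12:
        raise ValueError(
            f"target coverage {target_mean_coverage} exceeds current {current}"
        )
    if p >= 1:
        return RawCountTable(
            library_id=table.library_id,
            counts=dict(table.counts),
            n_reads_total=table.n_reads_total,
            n_unmapped=table.n_unmapped,
            n_multimapped=table.n_multimapped,
        )
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 23])
    ids = list(table.counts)
    kept = rng.binomial([table.counts[c] for c in ids], p)
    unmapped = int(rng.binomial(table.n_unmapped, p))
    multi = int(rng.binomial(table.n_multimapped, p))
    counts = dict(zip(ids, (int(k) for k in kept)))
    return RawCountTable(
        library_id=table.library_id,
        counts=counts,
        n_reads_total=int(kept.sum()) + unmapped + multi,
        n_unmapped=unmapped,
        n_multimapped=multi,
    )


def run_count_pipeline(
    replicate_tables: Mapping[object, Sequence[RawCountTable]],
    input_pool: RawCountTable,
    manifest: LibraryManifest,
    config: InferenceConfig | None = None,
    pseudocount: float = 0.5,
):
    """Raw per-tech-replicate counts -> gene calls (aggregate, normalize,
    fold changes, rank-sum tests, two-hit rule).  Returns (construct calls,
    gene calls, fold-change matrix)."""
    config = config or InferenceConfig()
    samples: list[CountTable] = []
    for bio_id in sorted(replicate_tables, key=str):
        samples.append(
            aggregate_technical(replicate_tables[bio_id], sample_id=str(bio_id))
        )
    fc = build_fold_change_matrix(
        samples, raw_to_count_table(input_pool), pseudocount=pseudocount
    )
    calls = construct_tests(fc, manifest, config)
    genes = gene_two_hit_calls(calls, config)
    return calls, genes, fc


def coverage_power_curve(
    replicate_tables: Mapping[object, Sequence[RawCountTable]],
    input_pool: RawCountTable,
    manifest: LibraryManifest,
    config: InferenceConfig | None = None,
    coverages: Sequence[float] = (5, 50, 250, 1000, 5000),
    n_draws: int = 20,
    seed: int = 0,
    pseudocount: float = 0.5,
) -> PowerCurve:
    """Power to recover positive-control genes vs mean read coverage.

    For each target coverage, the testis tables are independently thinned
    ``n_draws`` times (the input pool stays at full depth) and the whole
    pipeline is rerun; power is the mean fraction of positive-class genes
    called essential.  At the observed mean coverage thinning is the
    identity, so the curve endpoint with ``n_draws=1`` equals the plain
    full-depth analysis exactly.  No monotone smoothing is applied.
    """
    config = config or InferenceConfig()
    pos_genes = set(manifest.genes_in_class("positive"))
    if not pos_genes:
        raise ValueError("manifest has no positive-control genes")
    all_tables = [t for ts in replicate_tables.values() for t in ts]
    observed = float(np.mean([t.mean_coverage() for t in all_tables]))
    entries: list[PowerCurveEntry] = []
    counter = 0
    for cov in sorted(coverages):
        if cov > observed * (1 + 1e-9):
            raise ValueError(
                f"target coverage {cov} exceeds observed mean {observed:.1f}"
            )
        powers = []
        for _ in range(n_draws):
            thinned: dict[object, list[RawCountTable]] = {}
            for bio_id, ts in replicate_tables.items():
                new = []
                for t in ts:
                    counter += 1
                    new.append(
                        downsample_counts(t, cov, seed=(seed * 100003 + counter) & 0x7FFFFFFF)
                    )
                thinned[bio_id] = new
            _, genes, _ = run_count_pipeline(
                thinned, input_pool, manifest, config, pseudocount
            )
            called = {g.gene for g in genes if g.essential_call}
            powers.append(len(called & pos_genes) / len(pos_genes))
        entries.append(
            PowerCurveEntry(mean_coverage=float(cov), power=float(np.mean(powers)))
        )
    return PowerCurve(entries=entries, n_draws=n_draws, seed=seed)


@dataclass(frozen=True)
class CapacityEstimate:
    n_cells_total: float
    transfection_efficiency: float
    cells_transfected: float
    max_constructs: int | None
    max_genes: int | None

    def mean_cells_per_construct(self, library_size: int) -> int:
        """Average independently transfected cells per construct for a
        library of the given size (floor)."""
        return int(self.cells_transfected // library_size)


def screen_capacity(
    n_cells_total: float,
    transfection_efficiency: float,
    min_cells_per_construct: int | None = None,
    constructs_per_gene: int | None = None,
) -> CapacityEstimate:
    """Cell-budget arithmetic for scaling a pooled in-vivo screen.

    cells_transfected = n_cells_total x efficiency; requiring at least
    ``min_cells_per_construct`` independent transfections per construct caps
    the library at floor(cells_transfected / min_cells_per_construct)
    constructs, i.e. floor(that / constructs_per_gene) genes.
    """
    if n_cells_total <= 0 or not 0 < transfection_efficiency <= 1:
        raise ValueError("need positive cell count and efficiency in (0, 1]")
    cells = n_cells_total * transfection_efficiency
    max_constructs = (
        int(cells // min_cells_per_construct) if min_cells_per_construct else None
    )
    max_genes = (
        int(max_constructs // constructs_per_gene)
        if max_constructs is not None and constructs_per_gene
        else None
    )
    return CapacityEstimate(
        n_cells_total=float(n_cells_total),
        transfection_efficiency=float(transfection_efficiency),
        cells_transfected=float(cells),
        max_constructs=max_constructs,
        max_genes=max_genes,
    )
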