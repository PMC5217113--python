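"""Depletion/enrichment calling and gene-level two-hit aggregation.

The statistical engine of the screen: each construct's log2 fold changes
across biological replicates are compared to the pooled fold changes of the
negative-control constructs with a Wilcoxon rank-sum (Mann-Whitney) test.  A
gene is called essential for the selected phenotype only when at least
``min_hits`` (default 2) distinct constructs targeting it are significantly
depleted — the standard RNAi-screen guard against off-target effects.  Under
a low-MOI transfection the constructs behave independently under the null, so
with a per-construct cutoff alpha the chance of a spurious two-hit gene is
roughly alpha squared.

Error control is by fixed cutoff plus the two-hit rule, as is conventional
for small pools with curated controls; Benjamini-Hochberg adjustment across
constructs is available behind ``InferenceConfig.fdr_correct``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats

from .library import LibraryManifest
from .quantify import FoldChangeMatrix

SIDEDNESS = ("two_sided", "one_sided_less", "one_sided_greater")

#: largest combined sample size for which the exact null distribution of U is
#: enumerated; larger (or tied) samples use the normal approximation with tie
#: and continuity corrections
EXACT_LIMIT = 12


@dataclass
class InferenceConfig:
    alpha: float = 0.01
    min_hits: int = 2
    sidedness: str = "two_sided"
    null_class: str = "negative"
    fdr_correct: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_hits < 1:
            raise ValueError("min_hits must be >= 1")
        if self.sidedness not in SIDEDNESS:
            raise ValueError(f"sidedness must be one of {SIDEDNESS}")


@dataclass
class ConstructCall:
    construct_id: str
    gene: str
    control_class: str
    median_log2fc: float
    U_statistic: float
    p_value: float
    direction: str  # depleted | enriched | neutral
    significant: bool


@dataclass
class GeneCall:
    gene: str
    control_class: str
    n_constructs: int
    n_depleted_significant: int
    n_enriched_significant: int
    essential_call: bool


@dataclass
class PerformanceReport:
    """Control-based screen performance: FNR over positive-control genes
    (fraction missed) and FPR over negative-control genes (fraction called)."""

    n_positive: int
    n_positive_called: int
    fnr: float | None
    n_negative: int
    n_negative_called: int
    fpr: float | None

    @property
    def fnr_percent(self) -> float | None:
        return None if self.fnr is None else round(100.0 * self.fnr, 1)

    @property
    def fpr_percent(self) -> float | None:
        return None if self.fpr is None else round(100.0 * self.fpr, 1)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _u_counts(m: int, n: int) -> tuple[int, ...]:
    """Number of m-subsets of ranks 1..m+n attaining each U value 0..m*n.

    Classic recurrence f(u; m, n) = f(u - n; m - 1, n) + f(u; m, n - 1).
    """
    if m == 0 or n == 0:
        return (1,)
    a = _u_counts(m - 1, n)
    b = _u_counts(m, n - 1)
    res = [0] * (m * n + 1)
    for u, c in enumerate(a):
        res[u + n] += c
    for u, c in enumerate(b):
        res[u] += c
    return tuple(res)


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], sidedness: str = "two_sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) test of sample ``x`` against ``y``.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x`` (number
    of (x, y) pairs with x > y, ties counted half, computed via average
    ranks).  The p-value is exact (full enumeration of the U null
    distribution) when ``len(x) + len(y) <= 12`` with no ties, otherwise a
    normal approximation with tie correction and a 0.5 continuity correction.
    ``one_sided_less`` tests whether x tends below y (small U).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    rx = float(ranks[:m].sum())
    u = rx - m * (m + 1) / 2.0
    has_ties = len(np.unique(combined)) < m + n

    if m + n <= EXACT_LIMIT and not has_ties:
        counts = np.asarray(_u_counts(m, n), dtype=float)
        total = counts.sum()
        k = int(round(u))
        p_le = counts[: k + 1].sum() / total
        p_ge = counts[k:].sum() / total
    else:
        mu = m * n / 2.0
        N = m + n
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
        if var <= 0:  # all observations identical
            return u, 1.0
        sd = np.sqrt(var)
        p_le = stats.norm.cdf((u - mu + 0.5) / sd)
        p_ge = stats.norm.sf((u - mu - 0.5) / sd)

    if sidedness == "one_sided_less":
        p = p_le
    elif sidedness == "one_sided_greater":
        p = p_ge
    else:
        p = 2.0 * min(p_le, p_ge)
    return u, float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Per-construct and per-gene calls
# ---------------------------------------------------------------------------


def construct_tests(
    fc: FoldChangeMatrix,
    manifest: LibraryManifest,
    config: InferenceConfig | None = None,
) -> list[ConstructCall]:
    """Test every construct's fold changes against the negative-control null.

    For construct c, x = its fold changes across replicates and y = the
    pooled fold changes of all null-class constructs across all replicates;
    a null-class construct under test is excluded from its own null sample.
    Direction is taken from the sign of (median(x) - median(null)); exact
    ties are neutral and never count as depletion hits.
    """
    config = config or InferenceConfig()
    null_ids = [
        c.construct_id
        for c in manifest.constructs
        if c.control_class == config.null_class
    ]
    if not null_ids:
        raise ValueError(
            f"manifest has no constructs in null class {config.null_class!r}"
        )
    matrix = fc.log2fc
    if matrix.shape[1] == 0:
        raise ValueError("fold-change matrix has no replicate columns")
    if matrix.shape[1] == 1:
        warnings.warn(
            "single biological replicate: rank-sum tests have minimal power",
            stacklevel=2,
        )
    null_block = matrix.loc[null_ids].to_numpy()
    null_pos = {cid: i for i, cid in enumerate(null_ids)}

    calls: list[ConstructCall] = []
    for c in manifest.constructs:
        x = matrix.loc[c.construct_id].to_numpy()
        if c.construct_id in null_pos:
            rows = np.ones(len(null_ids), dtype=bool)
            rows[null_pos[c.construct_id]] = False
            y = null_block[rows].ravel()
            if y.size == 0:
                raise ValueError(
                    "null class has a single construct; cannot test it "
                    "against an empty null"
                )
        else:
            y = null_block.ravel()
        u, p = rank_sum_test(x, y, config.sidedness)
        med = float(np.median(x))
        null_med = float(np.median(y))
        if med < null_med:
            direction = "depleted"
        elif med > null_med:
            direction = "enriched"
        else:
            direction = "neutral"
        calls.append(
            ConstructCall(
                construct_id=c.construct_id,
                gene=c.gene,
                control_class=c.control_class,
                median_log2fc=med,
                U_statistic=u,
                p_value=p,
                direction=direction,
                significant=False,  # set below
            )
        )

    if config.fdr_correct:
        from statsmodels.stats.multitest import multipletests

        rej, _, _, _ = multipletests(
            [c.p_value for c in calls], alpha=config.alpha, method="fdr_bh"
        )
        for call, r in zip(calls, rej):
            call.significant = bool(r)
    else:
        for call in calls:
            call.significant = call.p_value <= config.alpha
    return calls


def gene_two_hit_calls(
    calls: Sequence[ConstructCall], config: InferenceConfig | None = None
) -> list[GeneCall]:
    """Aggregate construct calls per gene under the two-hit rule.

    A gene is essential iff >= ``min_hits`` of its constructs are
    significantly depleted.  Enriched hits are reported but never contribute
    to the essential call.
    """
    config = config or InferenceConfig()
    by_gene: dict[str, list[ConstructCall]] = {}
    for c in calls:
        by_gene.setdefault(c.gene, []).append(c)
    out = []
    for gene, cs in by_gene.items():
        n_dep = sum(1 for c in cs if c.significant and c.direction == "depleted")
        n_enr = sum(1 for c in cs if c.significant and c.direction == "enriched")
        out.append(
            GeneCall(
                gene=gene,
                control_class=cs[0].control_class,
                n_constructs=len(cs),
                n_depleted_significant=n_dep,
                n_enriched_significant=n_enr,
                essential_call=n_dep >= config.min_hits,
            )
        )
    return out


def two_hit_null_probability(
    alpha: float, n_constructs: int, mode: str = "paper_pairwise"
) -> float:
    """Null probability that a gene shows >= 2 significantly depleted constructs.

    ``paper_pairwise`` is the back-of-envelope alpha**2 (probability that a
    specific pair of independent constructs both pass the cutoff);
    ``binomial_at_least_2`` accounts for the number of constructs per gene,
    returning P(X >= 2) with X ~ Binomial(n_constructs, alpha).
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    if mode == "paper_pairwise":
        if n_constructs < 2:
            raise ValueError("pairwise mode needs at least 2 constructs")
        return alpha**2
    if mode == "binomial_at_least_2":
        if n_constructs < 2:
            return 0.0
        return float(stats.binom.sf(1, n_constructs, alpha))
    raise ValueError(f"unknown mode {mode!r}")


def control_performance(
    gene_calls: Sequence[GeneCall], manifest: LibraryManifest
) -> PerformanceReport:
    """Estimate screen error rates from the control genes.

    FNR = fraction of positive-control genes *not* called essential;
    FPR = fraction of negative-control genes called essential.  A rate whose
    class is absent from the manifest is reported as ``None``.
    """
    calls = {g.gene: g for g in gene_calls}
    pos_genes = manifest.genes_in_class("positive")
    neg_genes = manifest.genes_in_class("negative")
    n_pos_called = sum(
        1 for g in pos_genes if g in calls and calls[g].essential_call
    )
    n_neg_called = sum(
        1 for g in neg_genes if g in calls and calls[g].essential_call
    )
    return PerformanceReport(
        n_positive=len(pos_genes),
        n_positive_called=n_pos_called,
        fnr=(len(pos_genes) - n_pos_called) / len(pos_genes) if pos_genes else None,
        n_negative=len(neg_genes),
        n_negative_called=n_neg_called,
        fpr=n_neg_called / len(neg_genes) if neg_genes else None,
    )


@dataclass
class ClassRates:
    control_class: str
    n_constructs: int
    n_depleted_significant: int
    n_enriched_significant: int

    @property
    def depleted_percent(self) -> float:
        return 100.0 * self.n_depleted_significant / self.n_constructs

    @property
    def enriched_percent(self) -> float:
        return 100.0 * self.n_enriched_significant / self.n_constructs


def construct_class_rates(
    calls: Sequence[ConstructCall],
) -> dict[str, ClassRates]:
    """Per control class, the fraction of constructs significantly depleted /
    enriched — e.g. the share of positive-control constructs that show
    spurious enrichment."""
    out: dict[str, ClassRates] = {}
    for cls in sorted({c.control_class for c in calls}):
        cs = [c for c in calls if c.control_class == cls]
        out[cls] = ClassRates(
            control_class=cls,
            n_constructs=len(cs),
            n_depleted_significant=sum(
                1 for c in cs if c.significant and c.direction == "depleted"
            ),
            n_enriched_significant=sum(
                1 for c in cs if c.significant and c.direction == "enriched"
            ),
        )
    return out
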