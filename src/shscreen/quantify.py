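"""Technical-replicate aggregation, RPM normalization and log2 fold changes.

The quantification convention follows standard pooled-screen practice: the
per-construct count of a biological sample is the median over its technical
sequencing libraries (robust to PCR jackpotting in any single library), counts
are scaled to reads per million (RPM) so libraries of different depth are
comparable, and each construct's abundance change is the log2 ratio of its
sample RPM to its input-pool RPM.  A symmetric pseudocount (default 0.5),
folded into both numerator and denominator *and* the library total, keeps
fold changes finite at zero counts with minimal bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mapping import RawCountTable

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class CountTable:
    """Median-aggregated counts for one biological sample (may be half-integer)."""

    sample_id: str
    counts: pd.Series
    n_tech_reps: int = 1


@dataclass
class NormalizedTable:
    """Reads-per-million abundances for one sample."""

    sample_id: str
    rpm: pd.Series
    pseudocount_used: float = 0.0


@dataclass
class FoldChangeMatrix:
    """Per-construct log2 fold changes across biological replicates.

    ``log2fc`` is a constructs x replicates DataFrame; every entry is finite
    (guaranteed by a positive pseudocount).
    """

    log2fc: pd.DataFrame
    reference_id: str
    pseudocount: float

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.log2fc.columns)

    @property
    def construct_ids(self) -> list[str]:
        return list(self.log2fc.index)

    def subset_replicates(self, replicate_ids: Sequence[str]) -> "FoldChangeMatrix":
        return FoldChangeMatrix(
            log2fc=self.log2fc.loc[:, list(replicate_ids)],
            reference_id=self.reference_id,
            pseudocount=self.pseudocount,
        )


def raw_to_count_table(table: RawCountTable, sample_id: str | None = None) -> CountTable:
    """View a single raw library as a (trivially aggregated) sample count table."""
    return CountTable(
        sample_id=sample_id or table.library_id,
        counts=table.as_series(),
        n_tech_reps=1,
    )


def aggregate_technical(
    tables: Sequence[RawCountTable], sample_id: str | None = None
) -> CountTable:
    """Collapse technical replicates to one count per construct via the median.

    Even numbers of replicates use the standard convention (mean of the two
    middle values), so aggregated counts may be half-integer.  The result is
    invariant to table order and is the identity on a single table.
    """
    if not tables:
        raise ValueError("aggregate_technical requires at least one count table")
    series = [t.as_series() for t in tables]
    index = series[0].index
    for s, t in zip(series[1:], tables[1:]):
        if set(s.index) != set(index):
            raise ValueError(
                f"construct set of library {t.library_id!r} does not match "
                f"library {tables[0].library_id!r}"
            )
    df = pd.concat([s.reindex(index) for s in series], axis=1)
    return CountTable(
        sample_id=sample_id or tables[0].library_id,
        counts=df.median(axis=1),
        n_tech_reps=len(tables),
    )


def normalize_rpm(table: CountTable, pseudocount: float = 0.0) -> NormalizedTable:
    """Scale counts (plus pseudocount) to reads per million.

    rpm[c] = 1e6 * (counts[c] + pseudocount) / sum_c'(counts[c'] + pseudocount),
    so the output always sums to 1e6 regardless of pseudocount.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    shifted = table.counts + pseudocount
    total = float(shifted.sum())
    if total <= 0:
        raise ValueError(
            f"sample {table.sample_id!r}: all counts zero with pseudocount 0; "
            "cannot normalize"
        )
    return NormalizedTable(
        sample_id=table.sample_id,
        rpm=1e6 * shifted / total,
        pseudocount_used=pseudocount,
    )


def log2_fold_change(sample: NormalizedTable, reference: NormalizedTable) -> pd.Series:
    """log2(sample RPM / input-pool RPM) per construct."""
    missing = sample.rpm.index.difference(reference.rpm.index)
    if len(missing):
        raise ValueError(
            f"constructs missing from reference {reference.sample_id!r}: "
            f"{list(missing)[:5]}"
        )
    ref = reference.rpm.reindex(sample.rpm.index)
    lfc = np.log2(sample.rpm / ref)
    lfc.name = sample.sample_id
    return lfc


def build_fold_change_matrix(
    samples: Sequence[CountTable],
    reference: CountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FoldChangeMatrix:
    """Fold changes of each biological replicate against its input pool.

    All samples and the reference must share the manifest construct set; the
    pseudocount is applied symmetrically to samples and reference.  A
    pseudocount of 0 is allowed only if no construct has a zero count in
    either member of a ratio (otherwise fold changes would be infinite).
    """
    if not samples:
        raise ValueError("no biological samples given")
    ref_idx = set(reference.counts.index)
    for s in samples:
        if set(s.counts.index) != ref_idx:
            raise ValueError(
                f"sample {s.sample_id!r} construct set differs from reference "
                f"{reference.sample_id!r}; mixing pool designs is not allowed"
            )
    if pseudocount == 0:
        warnings.warn(
            "pseudocount 0: zero counts will produce infinite fold changes",
            stacklevel=2,
        )
    ref_norm = normalize_rpm(reference, pseudocount)
    cols = {}
    for s in samples:
        cols[s.sample_id] = log2_fold_change(normalize_rpm(s, pseudocount), ref_norm)
    df = pd.DataFrame(cols)
    return FoldChangeMatrix(
        log2fc=df, reference_id=reference.sample_id, pseudocount=pseudocount
    )


def merge_fold_change_matrices(
    matrices: Sequence[FoldChangeMatrix],
) -> FoldChangeMatrix:
    """Merge replicate columns from experiments sharing one pool design.

    Each experiment's fold changes must already be normalized to its own
    sequenced input pool; merging only concatenates replicate columns.
    Construct sets must match exactly, and replicate ids must not collide.
    """
    if not matrices:
        raise ValueError("nothing to merge")
    base = matrices[0]
    frames = [base.log2fc]
    for m in matrices[1:]:
        if set(m.log2fc.index) != set(base.log2fc.index):
            raise ValueError("cannot merge fold changes from different pool designs")
        if m.pseudocount != base.pseudocount:
            raise ValueError("cannot merge matrices built with different pseudocounts")
        frames.append(m.log2fc.reindex(base.log2fc.index))
    merged = pd.concat(frames, axis=1)
    if merged.columns.duplicated().any():
        dupes = merged.columns[merged.columns.duplicated()].tolist()
        raise ValueError(f"replicate id collision on merge: {dupes}")
    refs = sorted({m.reference_id for m in matrices})
    return FoldChangeMatrix(
        log2fc=merged, reference_id="+".join(refs), pseudocount=base.pseudocount
    )
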