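"""Amplicon read counting by exact matching of each hairpin's unique half.

A read is assigned to a construct iff that construct's unique sequence (or its
reverse complement — amplicons may be sequenced in either orientation) occurs
verbatim as a substring of the read.  No mismatches, no indels, no quality
weighting.  Reads matching no construct are tallied as unmapped; reads
matching more than one construct are discarded and tallied as multimapped
(a QC signal — a collision-free manifest makes this essentially impossible).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .library import LibraryManifest, ManifestValidationError

SOURCES = ("input_pool", "testis", "cell_line")


class ReadParseError(ValueError):
    """A sequence record could not be parsed; carries the record index."""


@dataclass
class SequencingLibrary:
    """One sequencing library: metadata plus a source of reads.

    ``reads`` may be a path to a FASTA/FASTQ file (optionally gzipped) or any
    iterable of sequence strings (handy in tests and simulations).
    """

    library_id: str
    sample_id: str = ""
    tech_rep: int = 1
    source: str = "testis"
    reads: str | Path | Iterable[str] | None = None

    def iter_sequences(self) -> Iterator[str]:
        if self.reads is None:
            return iter(())
        if isinstance(self.reads, (str, Path)):
            return iter_read_file(self.reads)
        return iter(self.reads)


def _sniff_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    if name.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    raise ValueError(f"cannot infer read format from file name: {path}")


def iter_read_file(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTA/FASTQ file, gzip handled transparently."""
    path = Path(path)
    fmt = _sniff_format(path)
    opener = gzip.open if path.name.lower().endswith(".gz") else open
    with opener(path, "rt") as handle:
        records = SeqIO.parse(handle, fmt)
        i = 0
        while True:
            try:
                rec = next(records)
            except StopIteration:
                return
            except ValueError as e:
                raise ReadParseError(
                    f"{path}: malformed {fmt} record at index {i}: {e}"
                ) from e
            yield str(rec.seq)
            i += 1


@dataclass
class RawCountTable:
    """Per-construct read counts for one sequencing library.

    Invariant: ``sum(counts) + n_unmapped + n_multimapped == n_reads_total``.
    Every manifest construct appears as a key (zero counts allowed).
    """

    library_id: str
    counts: dict[str, int]
    n_reads_total: int = 0
    n_unmapped: int = 0
    n_multimapped: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, name=self.library_id, dtype=float)

    @property
    def n_mapped(self) -> int:
        return int(sum(self.counts.values()))

    def mean_coverage(self) -> float:
        """Mean mapped reads per construct."""
        return self.n_mapped / len(self.counts)


class HairpinMatcher:
    """Exact-substring index over every unique_seq and its reverse complement.

    Lookup slides a window of each distinct sequence length over the read and
    probes a hash table, so matching is O(read length x number of distinct
    lengths) independent of pool size.
    """

    def __init__(self, manifest: LibraryManifest):
        table: dict[str, str] = {}
        owner_strings: list[tuple[str, str]] = []
        for c in manifest.constructs:
            rc = reverse_complement(c.unique_seq)
            for s in {c.unique_seq, rc}:  # palindromes collapse to one key
                if s in table and table[s] != c.construct_id:
                    raise ManifestValidationError(
                        f"unique_seq collision between orientations: sequence "
                        f"{s!r} maps to both {table[s]!r} and "
                        f"{c.construct_id!r}"
                    )
                table[s] = c.construct_id
                owner_strings.append((s, c.construct_id))
        # substring collisions across orientations are as fatal as forward ones
        for si, ci in owner_strings:
            for sj, cj in owner_strings:
                if ci != cj and si in sj:
                    raise ManifestValidationError(
                        f"unique_seq of {ci!r} (or its reverse complement) is "
                        f"a substring of {cj!r}'s"
                    )
        self._table = table
        self._lengths = sorted({len(s) for s in table})
        self.construct_ids = list(manifest.construct_ids)

    def match(self, read: str) -> set[str]:
        """Construct ids whose unique sequence occurs in `read` (either strand)."""
        read = read.upper()
        found: set[str] = set()
        table = self._table
        for L in self._lengths:
            for i in range(len(read) - L + 1):
                hit = table.get(read[i : i + L])
                if hit is not None:
                    found.add(hit)
        return found


def build_matcher(manifest: LibraryManifest) -> HairpinMatcher:
    """Build the exact-match index for a validated manifest."""
    return HairpinMatcher(manifest)


def count_reads(
    library: SequencingLibrary,
    matcher: HairpinMatcher,
    manifest: LibraryManifest,
) -> RawCountTable:
    """Count reads per construct by exact unique-half matching.

    Each read increments exactly one construct iff exactly one unique
    sequence occurs in it (either orientation); otherwise it is tallied as
    unmapped (zero matches) or multimapped (two or more).  Deterministic and
    invariant to read order.
    """
    counts = dict.fromkeys(manifest.construct_ids, 0)
    n_total = n_unmapped = n_multi = 0
    for seq in library.iter_sequences():
        n_total += 1
        hits = matcher.match(seq)
        if len(hits) == 1:
            counts[next(iter(hits))] += 1
        elif not hits:
            n_unmapped += 1
        else:
            n_multi += 1
    return RawCountTable(
        library_id=library.library_id,
        counts=counts,
        n_reads_total=n_total,
        n_unmapped=n_unmapped,
        n_multimapped=n_multi,
    )


def count_paired(
    lib_r1: SequencingLibrary,
    lib_r2: SequencingLibrary,
    matcher: HairpinMatcher,
    manifest: LibraryManifest,
) -> tuple[RawCountTable, RawCountTable, float | None]:
    """Map both mates separately and report their count concordance.

    Returns (R1 table, R2 table, Pearson correlation of the two count
    vectors).  Concordance is ``None`` when either vector is constant (e.g.
    one mate entirely unmappable).  Downstream analysis uses the R1 table by
    default.
    """
    t1 = count_reads(lib_r1, matcher, manifest)
    t2 = count_reads(lib_r2, matcher, manifest)
    if t1.n_reads_total != t2.n_reads_total:
        raise ValueError(
            f"mate count mismatch: {t1.n_reads_total} reads in "
            f"{lib_r1.library_id} vs {t2.n_reads_total} in {lib_r2.library_id}"
        )
    v1 = np.array([t1.counts[c] for c in manifest.construct_ids], dtype=float)
    v2 = np.array([t2.counts[c] for c in manifest.construct_ids], dtype=float)
    if v1.std() == 0 or v2.std() == 0:
        conc: float | None = None
    else:
        conc = float(np.corrcoef(v1, v2)[0, 1])
    return t1, t2, conc
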