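"""shRNA pool design: constructs, target genes, control classes.

Every downstream stage (read counting, fold changes, hit calling) keys on the
manifest defined here.  A manifest row is one hairpin construct: a unique id,
the gene it targets, its control class (``positive`` = known essential for the
selected phenotype, ``negative`` = believed irrelevant and used as the
empirical null, ``test`` = to be determined), and the designated unique half
of the hairpin sequence that read counting matches exactly.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

CONTROL_CLASSES = ("positive", "negative", "test")
MANIFEST_COLUMNS = ("construct_id", "gene", "control_class", "unique_seq")

_DNA = frozenset("ACGT")


class ManifestFormatError(ValueError):
    """The manifest file is structurally malformed (missing columns etc.)."""


class ManifestValidationError(ValueError):
    """The manifest content violates a pool-design invariant."""


@dataclass(frozen=True)
class ShRNAConstruct:
    """One hairpin construct in the pool."""

    construct_id: str
    gene: str
    control_class: str
    unique_seq: str

    def __post_init__(self) -> None:
        if self.control_class not in CONTROL_CLASSES:
            raise ManifestValidationError(
                f"construct {self.construct_id!r}: control_class "
                f"{self.control_class!r} not in {CONTROL_CLASSES}"
            )
        if not self.unique_seq:
            raise ManifestValidationError(
                f"construct {self.construct_id!r}: empty unique_seq"
            )
        bad = set(self.unique_seq) - _DNA
        if bad:
            raise ManifestValidationError(
                f"construct {self.construct_id!r}: non-ACGT characters "
                f"{sorted(bad)} in unique_seq (uppercase ACGT required)"
            )


@dataclass
class LibraryManifest:
    """An ordered, validated collection of constructs.

    Validation enforces: unique construct ids, unique hairpin sequences with
    no substring collisions (exact-substring read matching would otherwise be
    ill-defined), one control class per gene, and at least one negative-class
    construct (required to form the test null).
    """

    constructs: list[ShRNAConstruct]
    name: str = "pool"

    def __post_init__(self) -> None:
        if not self.constructs:
            raise ManifestValidationError("manifest has no constructs")
        self._check_unique_ids()
        self._check_unique_seqs()
        self._check_gene_classes()
        if not any(c.control_class == "negative" for c in self.constructs):
            raise ManifestValidationError(
                "manifest has no negative-control constructs; the depletion "
                "test null cannot be formed"
            )

    def _check_unique_ids(self) -> None:
        seen: dict[str, int] = {}
        for i, c in enumerate(self.constructs):
            if c.construct_id in seen:
                raise ManifestValidationError(
                    f"duplicate construct_id {c.construct_id!r} at rows "
                    f"{seen[c.construct_id]} and {i}"
                )
            seen[c.construct_id] = i

    def _check_unique_seqs(self) -> None:
        seen: dict[str, int] = {}
        for i, c in enumerate(self.constructs):
            if c.unique_seq in seen:
                raise ManifestValidationError(
                    f"duplicate unique_seq shared by rows {seen[c.unique_seq]} "
                    f"and {i} ({c.construct_id!r})"
                )
            seen[c.unique_seq] = i
        # substring collisions are a hard error: a read containing the longer
        # sequence would always also match the shorter one
        seqs = [(c.unique_seq, i) for i, c in enumerate(self.constructs)]
        for si, i in seqs:
            for sj, j in seqs:
                if i != j and si in sj:
                    raise ManifestValidationError(
                        f"unique_seq of row {i} "
                        f"({self.constructs[i].construct_id!r}) is a substring "
                        f"of row {j} ({self.constructs[j].construct_id!r})"
                    )

    def _check_gene_classes(self) -> None:
        classes: dict[str, str] = {}
        for c in self.constructs:
            prev = classes.setdefault(c.gene, c.control_class)
            if prev != c.control_class:
                raise ManifestValidationError(
                    f"gene {c.gene!r} has constructs in more than one control "
                    f"class ({prev!r} and {c.control_class!r})"
                )

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.constructs)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LibraryManifest)
            and self.constructs == other.constructs
        )

    @property
    def construct_ids(self) -> list[str]:
        return [c.construct_id for c in self.constructs]

    @property
    def genes(self) -> list[str]:
        """Target genes in order of first appearance."""
        return list(dict.fromkeys(c.gene for c in self.constructs))

    def constructs_for_gene(self, gene: str) -> list[ShRNAConstruct]:
        return [c for c in self.constructs if c.gene == gene]

    def gene_class(self, gene: str) -> str:
        for c in self.constructs:
            if c.gene == gene:
                return c.control_class
        raise KeyError(gene)

    def class_of(self, construct_id: str) -> str:
        for c in self.constructs:
            if c.construct_id == construct_id:
                return c.control_class
        raise KeyError(construct_id)

    def ids_in_class(self, control_class: str) -> list[str]:
        return [
            c.construct_id
            for c in self.constructs
            if c.control_class == control_class
        ]

    def genes_in_class(self, control_class: str) -> list[str]:
        return [g for g in self.genes if self.gene_class(g) == control_class]


@dataclass(frozen=True)
class ManifestSummary:
    n_constructs: int
    n_genes: int
    class_counts: dict[str, int]
    constructs_per_gene: dict[str, int]
    per_gene_histogram: dict[int, int]

    @property
    def mode_constructs_per_gene(self) -> int:
        return max(self.per_gene_histogram, key=lambda k: (self.per_gene_histogram[k], k))


def manifest_summary(manifest: LibraryManifest) -> ManifestSummary:
    """Pool-design summary: sizes, class composition, constructs/gene histogram."""
    per_gene = collections.Counter(c.gene for c in manifest.constructs)
    class_counts = collections.Counter(c.control_class for c in manifest.constructs)
    hist = collections.Counter(per_gene.values())
    return ManifestSummary(
        n_constructs=len(manifest),
        n_genes=len(per_gene),
        class_counts={k: class_counts.get(k, 0) for k in CONTROL_CLASSES},
        constructs_per_gene=dict(per_gene),
        per_gene_histogram=dict(sorted(hist.items())),
    )


def load_manifest(path: str | Path, name: str | None = None) -> LibraryManifest:
    """Read a manifest from TSV (default) or CSV.

    The file must have a header row with columns ``construct_id``, ``gene``,
    ``control_class``, ``unique_seq``; lines starting with ``#`` are comments.
    Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest file not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    constructs = [
        ShRNAConstruct(
            construct_id=str(r.construct_id),
            gene=str(r.gene),
            control_class=str(r.control_class),
            unique_seq=str(r.unique_seq),
        )
        for r in df.itertuples(index=False)
    ]
    return LibraryManifest(constructs, name=name or path.stem)


def write_manifest(manifest: LibraryManifest, path: str | Path) -> Path:
    """Write a manifest as TSV/CSV; inverse of :func:`load_manifest`."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(
        [
            (c.construct_id, c.gene, c.control_class, c.unique_seq)
            for c in manifest.constructs
        ],
        columns=list(MANIFEST_COLUMNS),
    )
    df.to_csv(path, sep=sep, index=False)
    return path
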