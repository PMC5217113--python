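"""Synthetic pooled-screen generator with known ground truth.

The generative model mirrors an in-vivo pooled shRNA screen read out by
amplicon sequencing:

1. *Transfection*: of ``n_cells_total`` germ cells, a Binomial draw with the
   (low, 1-5%) transfection efficiency receives construct; each transfected
   cell integrates exactly one construct (strict low MOI), assigned by a
   multinomial over the input-pool composition.
2. *Selection*: each construct c carries a log2 survival effect ``s_c``
   (negative = its knockdown depletes the lineage).  Per biological
   replicate, cells survive with probability ``clip(2**(s_c + eps), 0, 1)``
   where ``eps ~ Normal(0, bio_sd)`` is per-construct, per-replicate
   biological noise.
3. *Library prep / sequencing*: per technical replicate, each construct
   lineage receives a Gamma(shape, scale=1/shape) amplification factor
   (mean 1; smaller shape = heavier PCR jackpotting at low template), then
   reads are a multinomial over the amplified mass with total
   ``mean_coverage * n_constructs``.

The input pool is sequenced directly from its composition (plain multinomial,
no jackpot: plasmid template is abundant) and no selection.  All randomness
flows from one master seed through named substreams, so a config reproduces
its screen bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio.Seq import reverse_complement

from .library import LibraryManifest, ShRNAConstruct
from .mapping import RawCountTable

#: ground-truth effect threshold: a construct with s_c at or below this is
#: considered truly effective, and a gene with >= 2 such constructs truly
#: essential (the detectable ground truth for power calculations)
EFFECT_THRESHOLD = -1.0


@dataclass
class SimulationConfig:
    """Study-design parameters of a simulated screen.

    Defaults emulate the pilot in-vivo design: ~1e8 cells in an adult testis,
    low transfection efficiency, nine biological replicates with three
    technical sequencing libraries each, and a few thousand reads per
    construct.
    """

    manifest: LibraryManifest
    n_cells_total: int = 100_000_000
    transfection_efficiency: float = 0.02
    input_pool_weights: np.ndarray | None = None  # uniform when None
    selection_log2: Mapping[str, float] | None = None  # 0 when None
    bio_sd: float = 0.3
    jackpot_shape: float = 2.0
    n_bio_reps: int = 9
    n_tech_reps: int = 3
    mean_coverage: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.transfection_efficiency <= 1:
            raise ValueError("transfection_efficiency must be in (0, 1]")
        if self.bio_sd < 0:
            raise ValueError("bio_sd must be >= 0")
        if not self.jackpot_shape > 0:
            raise ValueError("jackpot_shape must be > 0 (may be inf)")
        if self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ValueError("need at least one biological and technical replicate")
        if self.input_pool_weights is not None:
            w = np.asarray(self.input_pool_weights, dtype=float)
            if len(w) != len(self.manifest) or (w <= 0).any():
                raise ValueError(
                    "input_pool_weights must be positive, one per construct"
                )

    def weights(self) -> np.ndarray:
        n = len(self.manifest)
        if self.input_pool_weights is None:
            w = np.ones(n)
        else:
            w = np.asarray(self.input_pool_weights, dtype=float)
        return w / w.sum()

    def selection_vector(self) -> np.ndarray:
        s = np.zeros(len(self.manifest))
        if self.selection_log2:
            for i, cid in enumerate(self.manifest.construct_ids):
                s[i] = self.selection_log2.get(cid, 0.0)
        return s


@dataclass
class SyntheticScreen:
    """A simulated screen: all count tables plus the generating truth."""

    input_pool_counts: RawCountTable
    replicate_counts: dict[tuple[int, int], RawCountTable]
    truth_selection: dict[str, float]
    truth_gene_essential: dict[str, bool]
    config: SimulationConfig

    def tables_for_bio_rep(self, bio_rep: int) -> list[RawCountTable]:
        return [
            t
            for (b, _), t in sorted(self.replicate_counts.items())
            if b == bio_rep
        ]

    @property
    def bio_rep_ids(self) -> list[int]:
        return sorted({b for b, _ in self.replicate_counts})


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Named substream: one generator per (seed, stage, rep, tech...) key."""
    return np.random.default_rng([seed & 0x7FFFFFFF, *stream])


def _sequence_library(
    rng: np.random.Generator,
    mass: np.ndarray,
    total_reads: int,
    library_id: str,
    construct_ids: list[str],
) -> RawCountTable:
    if mass.sum() <= 0:
        counts = np.zeros(len(mass), dtype=int)
    else:
        counts = rng.multinomial(total_reads, mass / mass.sum())
    table = dict(zip(construct_ids, (int(c) for c in counts)))
    return RawCountTable(
        library_id=library_id,
        counts=table,
        n_reads_total=int(counts.sum()),
        n_unmapped=0,
        n_multimapped=0,
    )


def simulate_screen(config: SimulationConfig) -> SyntheticScreen:
    """Run the full generative model and return counts plus ground truth."""
    manifest = config.manifest
    ids = manifest.construct_ids
    n = len(ids)
    w = config.weights()
    s = config.selection_vector()
    total_reads = int(round(config.mean_coverage * n))

    input_counts = _sequence_library(
        _rng(config.seed, 0), w, total_reads, "input_pool", ids
    )

    replicate_counts: dict[tuple[int, int], RawCountTable] = {}
    for b in range(1, config.n_bio_reps + 1):
        rng_b = _rng(config.seed, 1, b)
        n_trans = rng_b.binomial(config.n_cells_total, config.transfection_efficiency)
        cells = rng_b.multinomial(n_trans, w)
        eps = rng_b.normal(0.0, config.bio_sd, size=n) if config.bio_sd > 0 else 0.0
        surv_p = np.clip(2.0 ** (s + eps), 0.0, 1.0)
        surviving = rng_b.binomial(cells, surv_p)
        for t in range(1, config.n_tech_reps + 1):
            rng_bt = _rng(config.seed, 2, b, t)
            if math.isinf(config.jackpot_shape):
                gain = np.ones(n)
            else:
                gain = rng_bt.gamma(
                    config.jackpot_shape, scale=1.0 / config.jackpot_shape, size=n
                )
            mass = surviving * gain
            replicate_counts[(b, t)] = _sequence_library(
                rng_bt, mass, total_reads, f"rep{b}_tech{t}", ids
            )

    truth_sel = dict(zip(ids, (float(v) for v in s)))
    truth_gene = {}
    for gene in manifest.genes:
        hits = sum(
            1
            for c in manifest.constructs_for_gene(gene)
            if truth_sel[c.construct_id] <= EFFECT_THRESHOLD
        )
        truth_gene[gene] = hits >= 2
    return SyntheticScreen(
        input_pool_counts=input_counts,
        replicate_counts=replicate_counts,
        truth_selection=truth_sel,
        truth_gene_essential=truth_gene,
        config=config,
    )


# ---------------------------------------------------------------------------
# Read-level simulation (end-to-end tests of the mapping stage)
# ---------------------------------------------------------------------------

# fixed amplicon backbone used as flanking filler around the hairpin
_VECTOR = (
    "TTGTGGAAAGGACGAAACACCGGTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCA"
    "ACTTGAAAAAGTGGCACCGAGTCGGTGCTTTTTTGAATTCTCGACCTCGAGACAAATGGCAGTATTCATC"
)


def simulate_reads(
    screen: SyntheticScreen,
    manifest: LibraryManifest,
    read_length: int = 100,
    seed: int = 0,
    out_dir: str | Path = ".",
    error_rate: float = 0.0,
    compress: bool = False,
) -> dict[str, Path]:
    """Expand count tables into FASTQ files that map back to the same counts.

    Each counted read embeds its construct's unique sequence at a random
    offset, in a random orientation, flanked by fixed vector backbone.  With
    ``error_rate`` 0, running the exact-match counter on the output recovers
    every count; with a per-base substitution rate e, a read survives
    counting with probability about (1-e)**len(unique_seq).
    """
    import gzip

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    max_len = max(len(c.unique_seq) for c in manifest.constructs)
    if read_length < max_len + 4:
        raise ValueError(
            f"read_length {read_length} too short; need >= {max_len + 4}"
        )
    seq_by_id = {c.construct_id: c.unique_seq for c in manifest.constructs}
    bases = np.array(list("ACGT"))

    libraries = {"input_pool": screen.input_pool_counts}
    for (b, t), tab in sorted(screen.replicate_counts.items()):
        libraries[tab.library_id] = tab

    paths: dict[str, Path] = {}
    for li, (lib_id, table) in enumerate(libraries.items()):
        rng = _rng(seed, 3, li)
        suffix = ".fastq.gz" if compress else ".fastq"
        path = out_dir / f"{lib_id}{suffix}"
        opener = gzip.open if compress else open
        with opener(path, "wt") as fh:
            ridx = 0
            for cid in manifest.construct_ids:
                insert = seq_by_id[cid]
                for _ in range(int(table.counts[cid])):
                    L = len(insert)
                    offset = int(rng.integers(0, read_length - L + 1))
                    core = (
                        insert
                        if rng.random() < 0.5
                        else reverse_complement(insert)
                    )
                    left = _VECTOR[-offset:] if offset else ""
                    right = _VECTOR[: read_length - offset - L]
                    read = left + core + right
                    if error_rate > 0:
                        arr = np.array(list(read))
                        hit = np.flatnonzero(rng.random(read_length) < error_rate)
                        if hit.size:
                            # substitute with one of the three *other* bases
                            idx = np.searchsorted(bases, arr[hit])
                            shift = rng.integers(1, 4, size=hit.size)
                            arr[hit] = bases[(idx + shift) % 4]
                            read = "".join(arr)
                    fh.write(f"@{lib_id}:{ridx}\n{read}\n+\n{'I' * read_length}\n")
                    ridx += 1
        paths[lib_id] = path
    return paths


# ---------------------------------------------------------------------------
# Pilot-like study design
# ---------------------------------------------------------------------------


def _random_unique_seqs(
    n: int, length: int, rng: np.random.Generator
) -> list[str]:
    """Collision-free random hairpin halves (no seq equals or reverse-
    complements another; equal length makes substring checks equality checks)."""
    seqs: list[str] = []
    seen: set[str] = set()
    bases = "ACGT"
    while len(seqs) < n:
        s = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        rc = reverse_complement(s)
        if s in seen or rc in seen or s == rc:
            continue
        seen.add(s)
        seen.add(rc)
        seqs.append(s)
    return seqs


def make_pilot_like_config(
    seed: int = 0,
    effective_fraction: float = 0.5,
    effect_range: tuple[float, float] = (-4.0, -1.0),
    n_refractory_positive: int = 3,
    mean_coverage: float = 5000.0,
    transfection_efficiency: float = 0.02,
) -> SimulationConfig:
    """A simulated screen shaped like the pilot pool.

    119 constructs over 25 genes (mode five constructs per gene): 17
    positive-control genes known to perturb the selected phenotype, and 8
    negative-control genes.  Emulating noneffective RNAi,
    ``n_refractory_positive`` positive genes get exactly one effective
    construct (they cannot satisfy the two-hit rule however deep the data —
    true false negatives of the screen chemistry, not the statistics); every
    other positive gene gets at least two effective constructs, with log2
    selection effects drawn uniformly from ``effect_range``.  Negative-gene
    constructs are inert (s = 0).
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 99])
    genes = (
        [f"POS{i:02d}" for i in range(1, 18)]
        + [f"NEG{i:02d}" for i in range(1, 6)]
        + [f"NEX{i:02d}" for i in range(1, 4)]  # non-expressed negatives
    )
    classes = ["positive"] * 17 + ["negative"] * 8
    # 19 genes with five constructs + 6 with four = 119, mode 5; the split
    # gives 83 positive-class and 36 negative-class constructs
    four_construct_genes = {genes[i] for i in (7, 15, 18, 20, 21, 23)}
    sizes = [4 if g in four_construct_genes else 5 for g in genes]

    seqs = iter(_random_unique_seqs(sum(sizes), 21, rng))
    constructs: list[ShRNAConstruct] = []
    selection: dict[str, float] = {}
    refractory = set(genes[17 - n_refractory_positive : 17])
    for gene, cls, size in zip(genes, classes, sizes):
        n_eff = 0
        if cls == "positive":
            if gene in refractory:
                n_eff = 1
            else:
                n_eff = max(2, int(rng.binomial(size, effective_fraction)))
        eff_idx = set(rng.choice(size, size=n_eff, replace=False)) if n_eff else set()
        for k in range(size):
            cid = f"{gene}_sh{k + 1}"
            constructs.append(
                ShRNAConstruct(
                    construct_id=cid,
                    gene=gene,
                    control_class=cls,
                    unique_seq=next(seqs),
                )
            )
            if k in eff_idx:
                lo, hi = effect_range
                selection[cid] = float(rng.uniform(lo, hi))
            else:
                selection[cid] = 0.0
    manifest = LibraryManifest(constructs, name="pilot_like")
    return SimulationConfig(
        manifest=manifest,
        transfection_efficiency=transfection_efficiency,
        selection_log2=selection,
        mean_coverage=mean_coverage,
        seed=seed,
    )


def make_graded_config(
    seed: int = 0,
    n_test_genes: int = 12,
    n_negative_genes: int = 3,
    constructs_per_gene: int = 5,
    max_effect: float = -4.0,
    **overrides,
) -> SimulationConfig:
    """A screen whose test constructs span a continuum of effect sizes.

    Test-construct log2 selection effects are drawn uniformly from
    (``max_effect``, 0), so effects reach arbitrarily close to zero — the
    design appropriate for minimum-detectable-effect analyses, where the
    question is how weak an effect still clears significance (a pool with
    only strong effects has nothing near the detection boundary to resolve).
    Negative-control constructs are inert.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 97])
    constructs = []
    selection: dict[str, float] = {}
    for i in range(n_test_genes + n_negative_genes):
        if i < n_test_genes:
            gene, cls = f"TST{i + 1:02d}", "test"
        else:
            gene, cls = f"NEG{i - n_test_genes + 1:02d}", "negative"
        for k in range(constructs_per_gene):
            cid = f"{gene}_sh{k + 1}"
            constructs.append((cid, gene, cls))
            selection[cid] = (
                float(rng.uniform(max_effect, 0.0)) if cls == "test" else 0.0
            )
    seqs = _random_unique_seqs(len(constructs), 21, rng)
    manifest = LibraryManifest(
        [
            ShRNAConstruct(cid, gene, cls, sq)
            for (cid, gene, cls), sq in zip(constructs, seqs)
        ],
        name="graded_pool",
    )
    return SimulationConfig(
        manifest=manifest, selection_log2=selection, seed=seed, **overrides
    )


def make_null_config(
    seed: int = 0,
    n_test_genes: int = 6,
    n_negative_genes: int = 3,
    constructs_per_gene: int = 5,
    **overrides,
) -> SimulationConfig:
    """A small all-null screen (every s_c = 0) for calibration studies.

    Defaults give 45 constructs: 15 negative controls plus 30 test constructs
    over six 5-construct genes.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 98])
    constructs = []
    for i in range(n_test_genes + n_negative_genes):
        if i < n_test_genes:
            gene, cls = f"TST{i + 1:02d}", "test"
        else:
            gene, cls = f"NEG{i - n_test_genes + 1:02d}", "negative"
        for k in range(constructs_per_gene):
            constructs.append((f"{gene}_sh{k + 1}", gene, cls))
    seqs = _random_unique_seqs(len(constructs), 21, rng)
    manifest = LibraryManifest(
        [
            ShRNAConstruct(cid, gene, cls, sq)
            for (cid, gene, cls), sq in zip(constructs, seqs)
        ],
        name="null_pool",
    )
    return SimulationConfig(manifest=manifest, seed=seed, **overrides)
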