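"""Plain-text serialization: count tables, fold-change matrices, screens.

Everything is TSV with a header row (JSON sidecars carry mapping totals), so
outputs diff cleanly and round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .library import write_manifest
from .mapping import RawCountTable
from .quantify import FoldChangeMatrix
from .simulate import SyntheticScreen


def write_count_table(table: RawCountTable, path: str | Path) -> Path:
    """TSV (construct_id, count) plus a .json sidecar with mapping totals."""
    path = Path(path)
    df = pd.DataFrame(
        {"construct_id": list(table.counts), "count": list(table.counts.values())}
    )
    df.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "library_id": table.library_id,
                "n_reads_total": table.n_reads_total,
                "n_mapped": table.n_mapped,
                "n_unmapped": table.n_unmapped,
                "n_multimapped": table.n_multimapped,
            },
            indent=2,
        )
        + "\n"
    )
    return path


def read_count_table(path: str | Path, library_id: str | None = None) -> RawCountTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"construct_id", "count"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns construct_id, count")
    counts = {str(r.construct_id): int(r.count) for r in df.itertuples(index=False)}
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    total = int(meta.get("n_reads_total", sum(counts.values())))
    return RawCountTable(
        library_id=library_id or meta.get("library_id", path.stem),
        counts=counts,
        n_reads_total=total,
        n_unmapped=int(meta.get("n_unmapped", 0)),
        n_multimapped=int(meta.get("n_multimapped", 0)),
    )


def write_fold_change_matrix(fc: FoldChangeMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = fc.log2fc.copy()
    df.index.name = "construct_id"
    with open(path, "w") as fh:
        fh.write(f"# reference={fc.reference_id} pseudocount={fc.pseudocount}\n")
        df.to_csv(fh, sep="\t")
    return path


def read_fold_change_matrix(path: str | Path) -> FoldChangeMatrix:
    path = Path(path)
    reference_id, pseudocount = "input_pool", 0.5
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            k, _, v = tok.partition("=")
            if k == "reference":
                reference_id = v
            elif k == "pseudocount":
                pseudocount = float(v)
    df = pd.read_csv(path, sep="\t", comment="#", index_col="construct_id")
    return FoldChangeMatrix(log2fc=df, reference_id=reference_id, pseudocount=pseudocount)


def write_screen(screen: SyntheticScreen, out_dir: str | Path) -> Path:
    """Materialize a simulated screen: manifest, counts, ground truth."""
    out_dir = Path(out_dir)
    counts_dir = out_dir / "counts"
    counts_dir.mkdir(parents=True, exist_ok=True)
    write_manifest(screen.config.manifest, out_dir / "manifest.tsv")
    write_count_table(screen.input_pool_counts, out_dir / "input_pool.tsv")
    for (b, t), tab in sorted(screen.replicate_counts.items()):
        write_count_table(tab, counts_dir / f"rep{b}_tech{t}.tsv")
    truth = pd.DataFrame(
        {
            "construct_id": list(screen.truth_selection),
            "selection_log2": list(screen.truth_selection.values()),
        }
    )
    truth["gene"] = [
        c.gene for c in screen.config.manifest.constructs
    ]
    truth["gene_essential_true"] = [
        screen.truth_gene_essential[g] for g in truth["gene"]
    ]
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return out_dir


def load_screen_counts(
    screen_dir: str | Path,
) -> tuple[RawCountTable, dict[str, list[RawCountTable]]]:
    """Read a screen directory written by :func:`write_screen`.

    Returns the input-pool table and a mapping biological sample id ->
    technical-replicate tables, grouped by the ``<bio>_tech<k>`` naming
    convention (files without a ``_tech`` suffix form single-table samples).
    """
    screen_dir = Path(screen_dir)
    input_pool = read_count_table(screen_dir / "input_pool.tsv")
    groups: dict[str, list[RawCountTable]] = {}
    for p in sorted((screen_dir / "counts").glob("*.tsv")):
        stem = p.stem
        bio = stem.rsplit("_tech", 1)[0] if "_tech" in stem else stem
        groups.setdefault(bio, []).append(read_count_table(p))
    if not groups:
        raise FileNotFoundError(f"no count tables under {screen_dir / 'counts'}")
    return input_pool, groups
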