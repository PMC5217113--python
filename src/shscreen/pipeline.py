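"""End-to-end run orchestration: counts -> fold changes -> calls -> report.

A run is fully described by a :class:`RunConfig`; the config is echoed
verbatim into the output directory, and re-running with the saved config and
the same seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .inference import (
    ConstructCall,
    GeneCall,
    InferenceConfig,
    construct_class_rates,
    control_performance,
)
from .io import load_screen_counts, write_fold_change_matrix
from .library import load_manifest
from .power import run_count_pipeline

logger = logging.getLogger("shscreen")


@dataclass
class RunConfig:
    manifest_path: str
    screen_dir: str  # directory holding input_pool.tsv and counts/*.tsv
    outdir: str
    pseudocount: float = 0.5
    alpha: float = 0.01
    min_hits: int = 2
    sidedness: str = "two_sided"
    fdr_correct: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def inference_config(self) -> InferenceConfig:
        return InferenceConfig(
            alpha=self.alpha,
            min_hits=self.min_hits,
            sidedness=self.sidedness,
            fdr_correct=self.fdr_correct,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def constructs_frame(calls: list[ConstructCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.construct_id,
                c.gene,
                c.control_class,
                round(c.median_log2fc, 6),
                c.U_statistic,
                c.p_value,
                c.direction,
                c.significant,
            )
            for c in calls
        ],
        columns=[
            "construct_id",
            "gene",
            "control_class",
            "median_log2fc",
            "U",
            "p_value",
            "direction",
            "significant",
        ],
    )


def genes_frame(genes: list[GeneCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                g.gene,
                g.control_class,
                g.n_constructs,
                g.n_depleted_significant,
                g.n_enriched_significant,
                g.essential_call,
            )
            for g in genes
        ],
        columns=[
            "gene",
            "control_class",
            "n_constructs",
            "n_depleted_significant",
            "n_enriched_significant",
            "essential_call",
        ],
    )


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute counts -> quantify -> test -> performance and write reports.

    Returns a run-report dict (also written as report.md / performance.json
    in the output directory).  Stage failures propagate with the stage name
    and offending path in the message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    try:
        logger.info("run config: %s", dataclasses.asdict(config))
        config.to_yaml(outdir / "run_config.yaml")

        try:
            manifest = load_manifest(config.manifest_path)
        except Exception as e:
            raise RuntimeError(
                f"[manifest] failed loading {config.manifest_path}: {e}"
            ) from e
        logger.info("manifest %s: %d constructs", manifest.name, len(manifest))

        try:
            input_pool, groups = load_screen_counts(config.screen_dir)
        except Exception as e:
            raise RuntimeError(
                f"[counts] failed loading {config.screen_dir}: {e}"
            ) from e
        logger.info(
            "loaded %d biological samples (input pool depth %d)",
            len(groups),
            input_pool.n_reads_total,
        )

        inf = config.inference_config()
        try:
            calls, genes, fc = run_count_pipeline(
                groups, input_pool, manifest, inf, config.pseudocount
            )
        except Exception as e:
            raise RuntimeError(f"[test] pipeline failed: {e}") from e

        write_fold_change_matrix(fc, outdir / "fold_changes.tsv")
        cdf = constructs_frame(calls)
        gdf = genes_frame(genes)
        cdf.to_csv(outdir / "constructs.tsv", sep="\t", index=False)
        gdf.to_csv(outdir / "genes.tsv", sep="\t", index=False)

        perf = control_performance(genes, manifest)
        rates = construct_class_rates(calls)
        report = {
            "n_constructs": len(manifest),
            "n_genes": len(manifest.genes),
            "n_replicates": len(groups),
            "alpha": inf.alpha,
            "min_hits": inf.min_hits,
            "n_significant_depleted": int(
                sum(c.significant and c.direction == "depleted" for c in calls)
            ),
            "n_essential_genes": int(sum(g.essential_call for g in genes)),
            "performance": {
                "n_positive": perf.n_positive,
                "n_positive_called": perf.n_positive_called,
                "fnr_percent": perf.fnr_percent,
                "n_negative": perf.n_negative,
                "n_negative_called": perf.n_negative_called,
                "fpr_percent": perf.fpr_percent,
            },
            "class_rates": {
                cls: {
                    "n_constructs": r.n_constructs,
                    "depleted_percent": round(r.depleted_percent, 1),
                    "enriched_percent": round(r.enriched_percent, 1),
                }
                for cls, r in rates.items()
            },
            "seed": config.seed,
        }
        (outdir / "performance.json").write_text(json.dumps(report, indent=2) + "\n")
        _write_markdown_report(outdir / "report.md", report, gdf)
        logger.info("run complete: %d essential genes", report["n_essential_genes"])
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_markdown_report(path: Path, report: dict, genes: pd.DataFrame) -> None:
    perf = report["performance"]
    lines = [
        "# Screen run report",
        "",
        f"- constructs: {report['n_constructs']}, genes: {report['n_genes']},"
        f" biological replicates: {report['n_replicates']}",
        f"- alpha = {report['alpha']}, two-hit threshold = {report['min_hits']}",
        f"- significantly depleted constructs: {report['n_significant_depleted']}",
        f"- essential gene calls: {report['n_essential_genes']}",
        "",
        "## Control-based error rates",
        "",
        f"- positive-control genes: {perf['n_positive']} "
        f"({perf['n_positive_called']} recovered) -> FNR {perf['fnr_percent']}%",
        f"- negative-control genes: {perf['n_negative']} "
        f"({perf['n_negative_called']} called) -> FPR {perf['fpr_percent']}%",
        "",
        "## Gene calls",
        "",
        "```",
        genes.sort_values(
            ["essential_call", "n_depleted_significant"], ascending=False
        ).to_string(index=False),
        "```",
        "",
    ]
    path.write_text("\n".join(lines))
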