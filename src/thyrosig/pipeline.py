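"""End-to-end orchestration: from an expression matrix to the report bundle.

Stage order: log-ratio transform -> ATC and PTC consensus lists -> overlap
summary -> aggressiveness signature (+ gene collapse) -> MDS embedding +
hierarchical clustering -> ARE enrichment (if an ARE table is given) ->
mutation frequencies (if a mutation table is given) -> microarray/qPCR
direction concordance (if qPCR tables are given).

The run is a pure function of (inputs, config, seed): the JSON report
contains no timestamps and is written with sorted keys, so a rerun with the
same config is byte-identical. Partial outputs survive a failing stage; the
manifest records per-stage completion.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from .cohort_stats import (
    amplification_stat,
    direction_concordance,
    mutation_frequencies,
    overlap_summary,
)
from .consensus import collapse_to_genes, consensus_lists
from .embedding import correlation_distances, hierarchical_cluster, nonmetric_mds
from .enrichment import are_proportions
from .exceptions import ConfigurationError, DataError, PipelineStageError
from .ratios import log_ratio, qpcr_log_ratio
from .signature import derive_signature

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("thyrosig")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and parameters of a pipeline run.

    ``matrix`` and ``sample_sheet`` are required; the remaining inputs are
    optional and switch their stages on. ``input_type`` is ``'intensities'``
    (matrix holds log2 intensities including NORMAL pool columns; the ratio
    stage subtracts the pool mean) or ``'ratios'`` (matrix already holds
    log2 tumor/pool ratios, e.g. generator output).
    """

    matrix: str
    sample_sheet: str
    outdir: str
    annotation: str | None = None
    are_table: str | None = None
    mutation_table: str | None = None
    qpcr_tumor: str | None = None
    qpcr_normal: str | None = None
    input_type: str = "intensities"
    list_fold: float = 2.0
    signature_fold: float = 1.5
    mds_components: int = 2
    mds_max_iter: int = 300
    mds_tol: float = 1e-6
    mds_restarts: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.list_fold < 1 or self.signature_fold < 1:
            raise ConfigurationError("fold thresholds must be >= 1")
        if self.input_type not in ("intensities", "ratios"):
            raise ConfigurationError(
                f"input_type must be 'intensities' or 'ratios', got {self.input_type!r}"
            )
        for name in ("matrix", "sample_sheet"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")
        for name in (
            "annotation",
            "are_table",
            "mutation_table",
            "qpcr_tumor",
            "qpcr_normal",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if not any(
        isinstance(h, logging.StreamHandler) and h.stream is sys.stderr
        for h in logger.handlers
    ):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(stream)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write the report bundle to outdir.

    Returns the aggregated report dict (also written to ``report.json``).
    A failing stage raises :class:`PipelineStageError` naming the stage;
    artifacts of completed stages and the manifest are preserved.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = _setup_logging(outdir)

    from . import __version__

    report: dict = {
        "version": __version__,
        "parameters": config.to_dict(),
    }
    manifest: dict[str, str] = {}
    stage = "setup"

    def finish_stage(name: str) -> None:
        manifest[name] = "completed"
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    try:
        matrix = tio.read_matrix(config.matrix)
        sheet = tio.read_sample_sheet(config.sample_sheet)
        tio.check_sheet_covers(matrix, sheet)
        annotation = (
            tio.read_annotation(config.annotation) if config.annotation else None
        )
        finish_stage("setup")

        stage = "ratios"
        if config.input_type == "intensities":
            ratios = log_ratio(matrix, sheet)
        else:
            if (sheet.loc[matrix.columns] == "NORMAL").any():
                raise DataError(
                    "input_type 'ratios' but matrix contains NORMAL columns"
                )
            ratios = matrix
        tio.write_matrix(ratios, outdir / "log_ratios.tsv")
        logger.info(
            "ratios: %d probes x %d tumor samples", ratios.shape[0], ratios.shape[1]
        )
        report["ratios"] = {"n_probes": int(ratios.shape[0]),
                            "n_samples": int(ratios.shape[1])}
        finish_stage("ratios")

        stage = "consensus"
        lists = {}
        for group in ("ATC", "PTC"):
            clist = consensus_lists(ratios, sheet, group, config.list_fold)
            lists[group] = clist
            tio.write_gene_list(
                clist.to_frame(), annotation, outdir / f"{group.lower()}_list.tsv"
            )
            genes = collapse_to_genes(clist, annotation)
            logger.info(
                "consensus %s: %d up, %d down (%d genes, %d conflicts)",
                group, len(clist.up), len(clist.down), genes.size,
                len(genes.conflicts),
            )
            report[f"consensus_{group.lower()}"] = {
                "up": len(clist.up),
                "down": len(clist.down),
                "genes": genes.size,
                "gene_conflicts": genes.conflicts,
            }
        finish_stage("consensus")

        stage = "overlap"
        ov = overlap_summary(lists["PTC"], lists["ATC"])
        report["overlap"] = ov.to_dict()
        logger.info("overlap: %s", report["overlap"])
        shared = sorted(
            (set(lists["PTC"].up) & set(lists["ATC"].up))
            | (set(lists["PTC"].down) & set(lists["ATC"].down)),
        )
        if shared:
            amp = amplification_stat(ratios, sheet, shared)
            report["amplification"] = {
                "median": amp.median,
                "n_probes": int(len(amp.per_probe)),
                "excluded": amp.excluded,
            }
        finish_stage("overlap")

        stage = "signature"
        sig = derive_signature(ratios, sheet, config.signature_fold)
        tio.write_gene_list(sig.to_frame(), annotation, outdir / "signature.tsv")
        sig_genes = sig.collapse(annotation)
        report["signature"] = {
            "threshold_fold": config.signature_fold,
            "n_probes": sig.size,
            "n_genes": sig_genes.size,
            "patterns": {p: sig.frame.loc[p, "pattern"] for p in sig.probes},
        }
        logger.info("signature: %d probes / %d genes", sig.size, sig_genes.size)
        finish_stage("signature")

        stage = "embedding"
        D = correlation_distances(ratios)
        emb = nonmetric_mds(
            D,
            k=config.mds_components,
            max_iter=config.mds_max_iter,
            tol=config.mds_tol,
            n_restarts=config.mds_restarts,
            seed=config.seed,
        )
        emb.to_frame().to_csv(outdir / "mds_coordinates.tsv", sep="\t",
                              index_label="sample_id")
        report["mds"] = {
            "stress": emb.stress,
            "n_iter": emb.n_iter,
            "converged": emb.converged,
        }
        cluster_probes = sig.probes if sig.size >= 1 else None
        dendro = hierarchical_cluster(ratios, probe_subset=cluster_probes)
        (outdir / "dendrogram.json").write_text(
            json.dumps(
                {
                    "leaf_order": dendro.leaf_order,
                    "merges": dendro.linkage.tolist(),
                    "newick": dendro.to_newick(),
                },
                indent=2,
            )
            + "\n"
        )
        report["clustering"] = {
            "n_probes_used": len(cluster_probes) if cluster_probes else
            int(ratios.shape[0]),
            "leaf_order": dendro.leaf_order,
        }
        logger.info("mds stress %.4g; clustering done", emb.stress)
        finish_stage("embedding")

        if config.are_table:
            stage = "are_enrichment"
            are = tio.read_are_table(config.are_table)
            regulated = sorted(
                set(lists["ATC"].up) | set(lists["ATC"].down)
                | set(lists["PTC"].up) | set(lists["PTC"].down)
            )
            non_regulated = [p for p in ratios.index if p not in set(regulated)]
            up = set(lists["ATC"].up) | set(lists["PTC"].up)
            down = set(lists["ATC"].down) | set(lists["PTC"].down)
            both = up & down
            up, down = sorted(up - both), sorted(down - both)
            enr: dict = {}
            if regulated and non_regulated:
                e = are_proportions(regulated, non_regulated, are)
                enr["regulated_vs_non"] = e.to_dict()
            if up and down:
                e = are_proportions(up, down, are)
                enr["up_vs_down"] = e.to_dict()
            report["are_enrichment"] = enr
            logger.info("ARE enrichment: %s", list(enr))
            finish_stage("are_enrichment")

        if config.mutation_table:
            stage = "mutations"
            mut = tio.read_mutation_table(config.mutation_table)
            report["mutations"] = mutation_frequencies(mut).to_dict()
            logger.info("mutations: %s", report["mutations"]["percents"])
            finish_stage("mutations")

        if config.qpcr_tumor and config.qpcr_normal:
            stage = "concordance"
            qt = tio.read_qpcr_table(config.qpcr_tumor)
            qn = tio.read_qpcr_table(config.qpcr_normal)
            _, qpcr_mean = qpcr_log_ratio(qt, qn)
            if annotation is not None:
                gene_of = annotation.reindex(ratios.index).fillna(
                    pd.Series(ratios.index, index=ratios.index)
                )
            else:
                gene_of = pd.Series(ratios.index, index=ratios.index)
            array_mean = (
                ratios.mean(axis=1).groupby(gene_of).mean()
            )
            common = [g for g in qpcr_mean.index if g in array_mean.index]
            if not common:
                raise DataError("no genes shared between qPCR and array data")
            conc = direction_concordance(
                array_mean.loc[common], qpcr_mean.loc[common]
            )
            report["concordance"] = {
                "fraction": conc.fraction,
                "n_compared": conc.n_compared,
                "ties": conc.ties,
            }
            logger.info("concordance: %.3f over %d genes",
                        conc.fraction, conc.n_compared)
            finish_stage("concordance")

        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        finish_stage("report")
        return report
    except Exception as exc:
        manifest[stage] = "failed"
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineStageError(stage, exc) from exc
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
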