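"""End-to-end orchestration: simulate -> call -> contrasts -> annotate ->
critical window -> enrichment, with a machine-readable run report.

The report (``report.json`` in the output directory) echoes every threshold
and carries, per contrast and context, total/hyper/hypo counts plus the
chromosome / feature / island-zone decompositions and the critical-window
set sizes. With a fixed seed the report is byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import annotate as annotate_mod
from . import calling, diff, enrich, io, simulate, window

logger = logging.getLogger(__name__)

REPORT_FILENAME = "report.json"

TREATMENT_CONTRAST_BY_AGE = {"Y": "YT-YC", "M": "MT-MC", "A": "AT-AC"}


def _asdict(obj) -> dict:
    d = dataclasses.asdict(obj)
    out = {}
    for k, v in d.items():
        if isinstance(v, frozenset):
            v = sorted(v)
        out[k] = v
    return out


def _config_echo(sim_cfg, unite_cfg, ann_cfg, enr_cfg, alpha_site, min_sites_per_call) -> dict:
    echo = {
        "alpha_site": alpha_site,
        "min_sites_per_call": min_sites_per_call,
        "unite": _asdict(unite_cfg),
        "annotation": _asdict(ann_cfg),
        "enrichment": _asdict(enr_cfg),
    }
    sim = _asdict(sim_cfg)
    sim["group_sizes"] = {f"{a}{t}": n for (a, t), n in sim_cfg.group_sizes.items()}
    sim["planted_effects"] = [_asdict(e) for e in sim_cfg.planted_effects]
    echo["simulation"] = sim
    return echo


def run_pipeline(
    sim_config: simulate.SimulationConfig,
    out_dir: str | Path,
    unite_config: diff.UniteConfig | None = None,
    annotation_config: annotate_mod.AnnotationConfig | None = None,
    enrichment_config: enrich.EnrichmentConfig | None = None,
    gmt_path: str | Path | None = None,
    alpha_site: float = 0.01,
    min_sites_per_call: int = 1,
    contexts: tuple = calling.CONTEXTS,
) -> dict:
    """Run all stages on a synthetic dataset and write stage outputs.

    Returns the report dict (also written to ``report.json``).
    """
    unite_cfg = unite_config or diff.UniteConfig()
    ann_cfg = annotation_config or annotate_mod.AnnotationConfig()
    enr_cfg = enrichment_config or enrich.EnrichmentConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    genome, genes, islands = simulate.generate_genome(sim_config)
    io.write_fasta(genome, out / "genome.fa")
    io.write_genes_bed12(genes, out / "genes.bed")
    io.write_islands_bed(islands, out / "islands.bed")
    logger.info("simulate genome: %d chrom, %d genes, %d islands (%.1fs)",
                len(genome), len(genes), len(islands), time.perf_counter() - t0)

    matrix, truth = simulate.simulate_methylomes(genome, genes, islands, sim_config)
    io.write_sample_sheet(matrix.sample_sheet, out / "samples.tsv")
    truth.gene_labels.to_csv(out / "gene_truth.tsv", sep="\t", index=False)
    logger.info("simulate methylomes: %d sites x %d samples",
                len(matrix.sites), len(matrix.samples))

    annotated_sites = annotate_mod.annotate_sites(
        matrix.sites, genes, islands, ann_cfg
    )

    report: dict = {
        "config": _config_echo(sim_config, unite_cfg, ann_cfg, enr_cfg,
                               alpha_site, min_sites_per_call),
        "n_sites": len(matrix.sites),
        "n_samples": len(matrix.samples),
        "contrasts": {},
        "critical_window": {},
    }

    contrast_dir = out / "contrasts"
    contrast_dir.mkdir(exist_ok=True)
    calls_by_contrast_context: dict = {}
    for contrast in diff.study_contrasts(matrix.sample_sheet, alpha_site=alpha_site):
        t1 = time.perf_counter()
        result = diff.run_contrast(matrix, contrast, unite_cfg, contexts=contexts)
        ann_table = result.table.merge(
            annotated_sites[["chrom", "pos", "strand", "feature", "gene_id", "island_zone"]],
            on=["chrom", "pos", "strand"],
            how="left",
        )
        out_table = ann_table.copy()
        out_table["pos"] = out_table["pos"] + 1  # 1-based on disk
        out_table.to_csv(contrast_dir / f"{contrast.name}.tsv", sep="\t", index=False)
        per_context = {}
        for ctx in contexts:
            sub = ann_table[ann_table["context"] == ctx]
            summary = annotate_mod.summarize_contrast(sub)
            summary["n_tested"] = int(len(sub))
            summary["n_significant"] = summary["n_hyper"] + summary["n_hypo"]
            per_context[ctx] = summary
            calls_by_contrast_context[(contrast.name, ctx)] = window.gene_calls(
                sub, contrast.name, context=ctx, min_sites_per_call=min_sites_per_call
            )
        report["contrasts"][contrast.name] = {
            "n_tested": result.n_tested,
            "n_significant": result.n_significant,
            "n_hyper": result.n_hyper,
            "n_hypo": result.n_hypo,
            "by_context": per_context,
        }
        logger.info("contrast %s: %d tested, %d significant (%.1fs)",
                    contrast.name, result.n_tested, result.n_significant,
                    time.perf_counter() - t1)

    window_dir = out / "window"
    window_dir.mkdir(exist_ok=True)
    cw_by_context: dict = {}
    for ctx in contexts:
        cw = window.critical_window_genes(
            calls_by_contrast_context[("YT-YC", ctx)],
            calls_by_contrast_context[("MT-MC", ctx)],
            calls_by_contrast_context[("AT-AC", ctx)],
            context=ctx,
        )
        cw_by_context[ctx] = cw
        cw.to_frame().to_csv(window_dir / f"critical_window_{ctx}.tsv", sep="\t", index=False)
        report["critical_window"][ctx] = cw.sizes()

    if gmt_path is not None:
        enr_cfg.validate()
        collection = enrich.GeneSetCollection.from_gmt(
            gmt_path, universe={g.gene_id for g in genes}
        )
        enrichment_report = {}
        for ctx, cw in cw_by_context.items():
            if not cw.nonresponsive_in_aged:
                continue
            table = enrich.hypergeom_enrichment(cw.nonresponsive_in_aged, collection)
            table.to_csv(out / f"enrichment_{ctx}.tsv", sep="\t", index=False)
            enrichment_report[ctx] = {
                "n_sets_tested": int(len(table)),
                "n_significant_fdr": int((table["q"] < enr_cfg.fdr_threshold).sum()),
            }
        report["enrichment"] = enrichment_report

    _check_conservation(report)
    with open(out / REPORT_FILENAME, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _check_conservation(report: Mapping) -> None:
    """Fail fast if any hyper+hypo decomposition disagrees with its total."""
    for name, entry in report["contrasts"].items():
        if entry["n_hyper"] + entry["n_hypo"] != entry["n_significant"]:
            raise AssertionError(f"conservation violated for contrast {name}")
        for ctx, summary in entry["by_context"].items():
            total = summary["n_significant"]
            if summary["n_hyper"] + summary["n_hypo"] != total:
                raise AssertionError(f"conservation violated for {name}/{ctx}")
            for key in ("by_chromosome", "by_feature", "by_island_zone"):
                tab = summary[key]
                hyper = sum(v["hyper"] for v in tab.values())
                hypo = sum(v["hypo"] for v in tab.values())
                if hyper + hypo != total:
                    raise AssertionError(
                        f"conservation violated for {name}/{ctx}/{key}"
                    )


def recompute_window_from_tsvs(
    contrast_tsvs: Mapping[str, str | Path],
    context: str,
    min_sites_per_call: int = 1,
) -> window.CriticalWindowResult:
    """Independent recomputation of the critical-window sets from emitted
    per-contrast TSVs (young/middle/aged treatment contrasts)."""
    calls = {}
    for key in ("young", "middle", "aged"):
        df = pd.read_csv(contrast_tsvs[key], sep="\t", dtype={"gene_id": str})
        df["gene_id"] = df["gene_id"].fillna("")
        calls[key] = window.gene_calls(df, key, context=context,
                                       min_sites_per_call=min_sites_per_call)
    return window.critical_window_genes(
        calls["young"], calls["middle"], calls["aged"], context=context
    )
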