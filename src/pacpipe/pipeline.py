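"""End-to-end orchestration and candidate selection.

Runs the full chain — site calling, internal-priming filtering, PAC
clustering and annotation, gene-level differential expression, per-PAC
differential usage, event classification, G4 flank scanning — and then
applies the candidate-selection funnel:

1. keep genes with a classified APA event confined to a single last
   exon (categories lengthening / shortening / both; splicing events
   and any gene whose retained PACs touch an intron or span several
   exons are dropped);
2. require at least one G4-positive window among the gene's retained
   PAC flanks (windows positive only by cG/cC are flagged and, by
   default, do not count — the mechanized equivalent of curating
   cG/cC-only false positives);
3. require |delta PDU| >= the configured minimum (0.12 by default,
   inclusive).

The run report counts genes at each funnel stage and echoes the
effective configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from . import apastats, clusters, g4scan, sites
from .config import PipelineConfig
from .formats_io import (
    read_design,
    read_end_records,
    read_gene_models,
    write_table,
    write_tracks_and_tables,
)

log = logging.getLogger(__name__)

FILTER_APA_EXON = "apa_exon"
FILTER_PG4 = "pg4"
FILTER_DPDU = "dpdu"

NON_SPLICING_CATEGORIES = (
    apastats.CATEGORY_LENGTHENING,
    apastats.CATEGORY_SHORTENING,
    apastats.CATEGORY_BOTH,
)


@dataclass
class PipelineResult:
    """All persisted stage outputs of one run."""

    sites: pd.DataFrame
    pacs: pd.DataFrame
    gene_counts: pd.DataFrame
    de_table: pd.DataFrame
    usage: pd.DataFrame
    pac_tests: pd.DataFrame
    events: pd.DataFrame
    g4_windows: pd.DataFrame
    candidates: pd.DataFrame
    report: dict = field(default_factory=dict)


def select_candidates(
    events: pd.DataFrame,
    usage: pd.DataFrame,
    g4_windows: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Apply the candidate funnel to classified events.

    ``usage`` supplies each gene's occupancy-passing PACs (the same set
    classification used) whose flank windows may satisfy the G4
    requirement.
    """
    rows = []
    win = g4_windows.set_index("pac_id") if len(g4_windows) else g4_windows
    retained_pacs = usage.loc[usage["occupancy"] >= config.occupancy_min]
    for event in events.itertuples():
        if event.category not in NON_SPLICING_CATEGORIES:
            continue
        gene_pacs = retained_pacs.loc[retained_pacs["gene_id"] == event.gene_id]
        multi_exon = (
            (gene_pacs["region"] == clusters.REGION_INTRON).any()
            or gene_pacs["exon_index"].dropna().nunique() > 1
            or gene_pacs["exon_index"].isna().any()
        )
        if multi_exon:
            continue
        filters = [FILTER_APA_EXON]
        flags = []

        gene_windows = win.loc[win.index.intersection(gene_pacs["pac_id"])]
        positive = gene_windows.loc[gene_windows["positive"]]
        cgcc_only = positive.loc[positive["positive_by"] == "cGcC"]
        if len(cgcc_only):
            flags.append("cgcc_only")
        effective = (
            positive.loc[positive["positive_by"] != "cGcC"]
            if config.exclude_cgcc_only
            else positive
        )
        if not len(effective):
            continue
        filters.append(FILTER_PG4)

        if not abs(event.delta_pdu) >= config.dpdu_min:
            continue
        filters.append(FILTER_DPDU)

        rows.append(
            {
                "gene_id": event.gene_id,
                "category": event.category,
                "delta_pdu": event.delta_pdu,
                "n_positive_windows": int(len(effective)),
                "cgcc_only_windows": int(len(cgcc_only)),
                "filters_passed": ",".join(filters),
                "flags": ",".join(flags),
            }
        )
    columns = ["gene_id", "category", "delta_pdu", "n_positive_windows",
               "cgcc_only_windows", "filters_passed", "flags"]
    return pd.DataFrame(rows, columns=columns)


def funnel_counts(events: pd.DataFrame, usage: pd.DataFrame,
                  g4_windows: pd.DataFrame, candidates: pd.DataFrame,
                  config: PipelineConfig) -> dict[str, int]:
    """Nested gene counts along the selection funnel."""
    tested_genes = usage.loc[
        usage["occupancy"] >= config.occupancy_min
    ].groupby("gene_id")["pac_id"].count()
    analyzed = set(tested_genes.index[tested_genes >= 2])
    significant = set(events["gene_id"])
    non_splicing = set(
        events.loc[events["category"].isin(NON_SPLICING_CATEGORIES), "gene_id"]
    )
    # recompute the with-pG4 stage as candidates ignoring the dPDU filter
    relaxed = select_candidates(
        events, usage, g4_windows,
        PipelineConfig(**{**config.to_dict(), "dpdu_min": 1e-12}),
    )
    with_pg4 = set(relaxed["gene_id"]) & non_splicing
    final = set(candidates["gene_id"])
    return {
        "analyzed": len(analyzed),
        "significant_apa": len(significant),
        "non_splicing": len(non_splicing),
        "with_pg4": len(with_pg4),
        "dpdu_passing": len(final),
    }


def run_pipeline(
    data_dir: str | Path,
    config: PipelineConfig,
    out_dir: str | Path,
) -> PipelineResult:
    """Run every stage on a dataset directory and persist the outputs.

    ``data_dir`` must contain ``genome.fa``, ``annotation.gtf``,
    ``design.tsv`` and one ``reads_<sample_id>.bed`` per design row (the
    layout the simulator writes).
    """
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        log.info("stage: %s", name)

    try:
        stage("load")
        design = read_design(data_dir / "design.tsv")
        samples = design["sample_id"].tolist()
        genome = Fasta(str(data_dir / "genome.fa"))
        gene_models = read_gene_models(data_dir / "annotation.gtf")
        records = pd.concat(
            [
                read_end_records(data_dir / f"reads_{s}.bed", s)
                for s in samples
            ],
            ignore_index=True,
        )
    except Exception as exc:
        raise PipelineStageError("load", exc) from exc

    try:
        stage("call-sites")
        called = sites.call_polya_sites(records, config, samples)
        called = sites.filter_internal_priming(called, genome, config)
    except Exception as exc:
        raise PipelineStageError("call-sites", exc) from exc

    try:
        stage("cluster")
        pacs = clusters.cluster_sites(called, config)
        pacs = clusters.annotate_pacs(pacs, gene_models)
    except Exception as exc:
        raise PipelineStageError("cluster", exc) from exc

    try:
        stage("apa")
        counts = apastats.gene_counts(pacs, samples)
        de_table = apastats.test_gene_de(counts, design, config)
        usage = apastats.usage_table(pacs, samples)
        pac_tests = apastats.test_pac_usage(usage, design, config)
        events, _ = apastats.classify_events(usage, pac_tests, design, config)
    except Exception as exc:
        raise PipelineStageError("apa", exc) from exc

    try:
        stage("g4scan")
        g4_windows = g4scan.scan_pac_flanks(pacs, genome, config)
    except Exception as exc:
        raise PipelineStageError("g4scan", exc) from exc

    try:
        stage("select")
        candidates = select_candidates(events, usage, g4_windows, config)
    except Exception as exc:
        raise PipelineStageError("select", exc) from exc

    stage("report")
    report = {
        "config": config.to_dict(),
        "n_samples": len(samples),
        "n_sites": int(len(called)),
        "n_pacs": int(len(pacs)),
        "n_genes_counted": int(len(counts)),
        "n_de_called": int(de_table["called"].sum()),
        "funnel": funnel_counts(events, usage, g4_windows, candidates, config),
        "category_counts": events["category"].value_counts().to_dict(),
    }

    write_table(called, out_dir / "sites.tsv")
    write_table(usage, out_dir / "usage.tsv")
    write_table(pac_tests, out_dir / "pac_tests.tsv")
    write_table(de_table.reset_index(), out_dir / "de.tsv")
    write_tracks_and_tables(pacs, events, candidates, samples, out_dir)
    with open(out_dir / "report.json", "w") as handle:
        json.dump(report, handle, indent=1, sort_keys=True)
        handle.write("\n")
    with open(out_dir / "report.txt", "w") as handle:
        handle.write(format_report(report))

    return PipelineResult(
        sites=called, pacs=pacs, gene_counts=counts, de_table=de_table,
        usage=usage, pac_tests=pac_tests, events=events,
        g4_windows=g4_windows, candidates=candidates, report=report,
    )


def format_report(report: dict) -> str:
    funnel = report["funnel"]
    lines = [
        "pacpipe run report",
        "==================",
        f"samples:                {report['n_samples']}",
        f"polyA sites called:     {report['n_sites']}",
        f"polyA clusters (PACs):  {report['n_pacs']}",
        f"genes with counts:      {report['n_genes_counted']}",
        f"DE genes called:        {report['n_de_called']}",
        "",
        "candidate funnel (genes)",
        f"  analyzed (>=2 PACs):  {funnel['analyzed']}",
        f"  significant APA:      {funnel['significant_apa']}",
        f"  non-splicing:         {funnel['non_splicing']}",
        f"  with pG4 window:      {funnel['with_pg4']}",
        f"  |dPDU| passing:       {funnel['dpdu_passing']}",
        "",
        "event categories: "
        + ", ".join(f"{k}={v}" for k, v in sorted(
            report["category_counts"].items())),
        "",
    ]
    return "\n".join(lines) + "\n"


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable status."""

    def __init__(self, stage_name: str, cause: Exception):
        self.stage_name = stage_name
        self.status = {"stage": stage_name, "error": repr(cause)}
        super().__init__(f"pipeline stage {stage_name!r} failed: {cause}")
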