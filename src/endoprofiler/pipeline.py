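"""End-to-end pipeline: correct -> ratios -> filter -> enrich -> topn -> integrate.

``run_pipeline`` chains every stage on in-memory objects and returns all
stage outputs plus a run manifest recording the filter-cascade counts; the
counts are asserted monotone at run time. ``run_pipeline_files`` is the
path-based wrapper used by the command-line interface: it reads the inputs,
runs the pipeline, and writes every stage output plus the manifest and a
Markdown summary into an output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .compartment_analysis import overlap_fraction, subset_by_category, top_n_tm
from .enrichment_stats import CALL_ENDO, CALL_SURF, compartment_enrichment
from .filtering import FilteredProteome, apply_filter_cascade
from .io_model import (
    AnnotationTable,
    Condition,
    ImpurityMatrix,
    ProteinQuantTable,
    RunConfig,
    file_digest,
    read_annotations,
    read_expression_summary,
    read_impurity_matrix,
    read_quant_table,
)
from .multiomic_integration import (
    LigandReceptorRecord,
    average_timepoints,
    call_cell_types,
    join_ligand_receptors,
)
from .tmt_quant import compute_nc_ratios, correct_impurities

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_files", "build_manifest"]

logger = logging.getLogger(__name__)

CASCADE_KEYS = ("detected", "min_peptides", "union")


@dataclass
class PipelineResult:
    config: RunConfig
    counts: dict[str, int]
    proteome: FilteredProteome
    cutoffs: dict[Condition, list]
    enrichment: pd.DataFrame
    top_reports: dict[str, Any]
    secreted_endo: pd.DataFrame
    cell_type_calls: pd.DataFrame | None
    ligand_receptor: list[LigandReceptorRecord]
    manifest: dict[str, Any] = field(default_factory=dict)


def _check_cascade_monotone(counts: dict[str, int]) -> None:
    seq = [counts[k] for k in CASCADE_KEYS if k in counts]
    if any(a < b for a, b in zip(seq, seq[1:])):
        raise AssertionError(f"filter cascade counts must be non-increasing: {counts}")
    for cond in ("endo", "surf"):
        if counts.get(f"{cond}_retained", 0) > counts.get("min_peptides", 0):
            raise AssertionError(f"condition set exceeds peptide-filtered count: {counts}")


def build_manifest(
    config: RunConfig,
    counts: dict[str, int],
    input_digests: dict[str, str] | None = None,
) -> dict[str, Any]:
    return {
        "tool": "endoprofiler",
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "inputs": input_digests or {},
        "counts": counts,
    }


def run_pipeline(
    quant: ProteinQuantTable,
    ann: AnnotationTable,
    config: RunConfig | None = None,
    impurities: ImpurityMatrix | None = None,
    expression: pd.DataFrame | None = None,
    input_digests: dict[str, str] | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs.

    ``impurities`` (optional) triggers reporter-ion correction first;
    ``expression`` (optional, long-format summary) enables the cell-type and
    ligand-receptor integration stages.
    """
    config = config or RunConfig()

    if impurities is not None:
        logger.info("stage correct: inverting isotope-impurity mixing")
        quant = correct_impurities(quant, impurities)

    logger.info("stage ratios: experimental-to-NC ratios (pseudocount %g)", config.nc_pseudocount)
    ratios = compute_nc_ratios(quant, quant.design, pseudocount=config.nc_pseudocount)

    logger.info("stage filter: peptide gate + ROC cutoffs + replicate intersection")
    proteome, cutoffs, counts = apply_filter_cascade(
        quant,
        ratios,
        ann,
        min_unique_peptides=config.min_unique_peptides,
        inclusive=config.inclusive_threshold,
    )

    logger.info("stage enrich: moderated t on %d union proteins", counts["union"])
    enrichment = compartment_enrichment(
        ratios,
        alpha=config.significance_alpha,
        use_adjusted=config.adjust_method == "bh",
        restrict_to=proteome.union,
    )
    counts["endo_enriched"] = int((enrichment["call"] == CALL_ENDO).sum())
    counts["surf_enriched"] = int((enrichment["call"] == CALL_SURF).sum())

    logger.info("stage topn: top-%d TM proteins per condition", config.top_n)
    top_reports: dict[str, Any] = {}
    for cond in (Condition.ENDO, Condition.SURF):
        top_reports[cond.value] = top_n_tm(
            enrichment,
            ann,
            ratios,
            cond,
            n=config.top_n,
            metric=config.topn_metric,
            intensities=quant.data,
        )
    a = top_reports["ENDO"].ranked_ids
    b = top_reports["SURF"].ranked_ids
    if a and b:
        top_reports["ENDO"].overlap_with_other = overlap_fraction(a, b)
        top_reports["SURF"].overlap_with_other = overlap_fraction(b, a)

    secreted = subset_by_category(enrichment, ann, "secreted")
    secreted_endo = secreted[secreted["call"] == CALL_ENDO]
    counts["secreted_endo_enriched"] = len(secreted_endo)

    calls = None
    if expression is not None:
        logger.info("stage integrate: cell-type calls and ligand-receptor join")
        averaged = average_timepoints(expression)
        calls = call_cell_types(averaged, config)
    records = join_ligand_receptors(secreted_endo, ann, enrichment, proteome, calls)

    _check_cascade_monotone(counts)
    manifest = build_manifest(config, counts, input_digests)
    return PipelineResult(
        config=config,
        counts=counts,
        proteome=proteome,
        cutoffs=cutoffs,
        enrichment=enrichment,
        top_reports=top_reports,
        secreted_endo=secreted_endo,
        cell_type_calls=calls,
        ligand_receptor=records,
        manifest=manifest,
    )


def _records_frame(records: list[LigandReceptorRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        if r.receptor_status:
            for rec, status in r.receptor_status.items():
                rows.append(
                    (r.ligand_id, r.ligand_compartment_call, r.ligand_cell_type, rec, status)
                )
        else:
            rows.append(
                (r.ligand_id, r.ligand_compartment_call, r.ligand_cell_type, "", "")
            )
    return pd.DataFrame(
        rows,
        columns=["ligand_id", "ligand_call", "ligand_cell_type", "receptor_id", "receptor_status"],
    )


def _summary_markdown(result: PipelineResult) -> str:
    c = result.counts
    lines = [
        "# endoprofiler run summary",
        "",
        "| stage | proteins |",
        "|---|---|",
        f"| detected | {c['detected']} |",
        f"| >= min unique peptides | {c['min_peptides']} |",
        f"| endosome set (all replicates) | {c['endo_retained']} |",
        f"| surface set (all replicates) | {c['surf_retained']} |",
        f"| union | {c['union']} |",
        f"| endosome-enriched | {c['endo_enriched']} |",
        f"| surface-enriched | {c['surf_enriched']} |",
        f"| endosome-enriched secreted | {c['secreted_endo_enriched']} |",
    ]
    endo_top = result.top_reports.get("ENDO")
    if endo_top is not None and endo_top.overlap_with_other is not None:
        lines.append("")
        lines.append(
            f"Top-{endo_top.n} TM overlap (endosome list found in surface list): "
            f"{endo_top.overlap_with_other:.1%}"
        )
    return "\n".join(lines) + "\n"


def run_pipeline_files(
    quant_path: str | Path,
    annotations_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    impurity_path: str | Path | None = None,
    expression_path: str | Path | None = None,
) -> PipelineResult:
    """Read inputs from disk, run the pipeline, write all stage outputs."""
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    from .io_model import ChannelDesign

    design = ChannelDesign.default_8plex()
    quant = read_quant_table(quant_path, design)
    ann = read_annotations(annotations_path)
    impurities = read_impurity_matrix(impurity_path) if impurity_path else None
    expression = (
        read_expression_summary(expression_path) if expression_path else None
    )
    digests = {"quant": file_digest(quant_path), "annotations": file_digest(annotations_path)}
    if impurity_path:
        digests["impurities"] = file_digest(impurity_path)
    if expression_path:
        digests["expression"] = file_digest(expression_path)

    result = run_pipeline(
        quant, ann, config=config, impurities=impurities, expression=expression,
        input_digests=digests,
    )

    result.enrichment.to_csv(out / "enrichment.tsv", sep="\t")
    result.proteome.provenance.to_csv(out / "filtered_proteome.tsv", sep="\t")
    for cond, results in result.cutoffs.items():
        for res in results:
            res.curve_frame().to_csv(
                out / f"roc_{res.channel_id}.tsv", sep="\t", index=False
            )
    cutoff_summary = {
        res.channel_id: {"threshold": res.chosen_threshold, "youden": res.youden,
                         "retained": len(res.retained)}
        for results in result.cutoffs.values()
        for res in results
    }
    (out / "cutoffs.json").write_text(json.dumps(cutoff_summary, indent=2))
    for cond, report in result.top_reports.items():
        report.heatmap_frame().to_csv(
            out / f"top{report.n}_tm_{cond.lower()}.tsv", sep="\t", index=False
        )
    result.secreted_endo.to_csv(out / "secreted_endo.tsv", sep="\t")
    _records_frame(result.ligand_receptor).to_csv(
        out / "ligand_receptor.tsv", sep="\t", index=False
    )
    if result.cell_type_calls is not None:
        result.cell_type_calls.to_csv(out / "cell_type_calls.tsv", sep="\t")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    (out / "summary.md").write_text(_summary_markdown(result))
    return result
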