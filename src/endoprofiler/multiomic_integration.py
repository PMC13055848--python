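"""Ligand-receptor multi-omic integration.

Endosome-enriched secreted proteins can originate from neighbouring cells and
enter via receptor-mediated internalization. This module assigns each such
ligand to the cell class(es) robustly expressing its transcript — olfactory
receptor neurons (ORN, presynaptic) and/or projection neurons (PN,
postsynaptic) — and joins it to annotated receptors, reporting each
receptor's detection status in the profiled proteome.

A transcript counts as robustly expressed in a class when, after averaging
the two developmental time points (24 h and 48 h APF), it is expressed in
more than 30% of cells at a mean log2(CPM+1) of at least 4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment_stats import CALL_ENDO, CALL_SURF
from .filtering import FilteredProteome
from .io_model import CELL_CLASSES, TIME_POINTS, AnnotationTable, RunConfig

__all__ = [
    "CellTypeCall",
    "LigandReceptorRecord",
    "RECEPTOR_STATUSES",
    "average_timepoints",
    "is_enriched",
    "call_cell_types",
    "join_ligand_receptors",
    "summarize_expression_matrix",
]

logger = logging.getLogger(__name__)

ORN_ONLY = "ORN_ONLY"
PN_ONLY = "PN_ONLY"
BOTH = "BOTH"
NEITHER = "NEITHER"
CELL_TYPE_CATEGORIES = (ORN_ONLY, PN_ONLY, BOTH, NEITHER)

# Receptor detection statuses; the first two carry the display markers
# "*" (endosome-enriched) and "**" (similarly labeled in both compartments).
RECEPTOR_STATUSES = ("ENDO_ENRICHED", "DUAL", "SURF_ENRICHED", "NOT_DETECTED")
STATUS_MARKERS = {"ENDO_ENRICHED": "*", "DUAL": "**", "SURF_ENRICHED": "", "NOT_DETECTED": ""}


@dataclass
class CellTypeCall:
    gene: str
    enriched_in: str  # one of CELL_TYPE_CATEGORIES
    avg_mean_log2cpm1: dict[str, float]
    avg_frac: dict[str, float]


@dataclass
class LigandReceptorRecord:
    ligand_id: str
    ligand_compartment_call: str
    ligand_cell_type: str  # CellTypeCall category, or "NOT_PROFILED"
    receptor_status: dict[str, str] = field(default_factory=dict)
    unmatched_receptors: tuple[str, ...] = ()

    @property
    def receptor_ids(self) -> list[str]:
        return list(self.receptor_status)


def average_timepoints(expr: pd.DataFrame) -> pd.DataFrame:
    """Average mean expression and expressing-fraction across the two
    developmental time points, per gene and cell class.

    Genes lacking either time point in any class are excluded with a warning.
    Returns a frame indexed by (gene, cell_class) with columns
    mean_log2cpm1 and frac_expressing.
    """
    counts = expr.groupby(["gene", "cell_class"])["time_point"].nunique()
    complete = counts.groupby("gene").agg(
        lambda s: len(s) == len(CELL_CLASSES) and (s == len(TIME_POINTS)).all()
    )
    incomplete = complete.index[~complete].tolist()
    if incomplete:
        logger.warning(
            "excluding %d gene(s) missing a time point or cell class: %s",
            len(incomplete),
            incomplete[:10],
        )
    kept = expr[~expr["gene"].isin(incomplete)]
    return (
        kept.groupby(["gene", "cell_class"])[["mean_log2cpm1", "frac_expressing"]]
        .mean()
        .sort_index()
    )


def is_enriched(
    mean_log2cpm1: float, frac_expressing: float, cfg: RunConfig | None = None
) -> bool:
    """Robust-expression rule: frac strictly above the fraction threshold AND
    mean at or above the level threshold (defaults: > 0.30 and >= 4)."""
    cfg = cfg or RunConfig()
    return (
        frac_expressing > cfg.expr_fraction_threshold
        and mean_log2cpm1 >= cfg.expr_level_threshold
    )


def call_cell_types(
    averaged: pd.DataFrame, cfg: RunConfig | None = None
) -> pd.DataFrame:
    """Classify each gene as ORN_ONLY / PN_ONLY / BOTH / NEITHER.

    ``averaged`` is the output of :func:`average_timepoints`. Returns a frame
    indexed by gene with the per-class averaged values and the call; the four
    categories partition the gene set.
    """
    cfg = cfg or RunConfig()
    wide_mean = averaged["mean_log2cpm1"].unstack("cell_class")
    wide_frac = averaged["frac_expressing"].unstack("cell_class")
    out = pd.DataFrame(index=wide_mean.index)
    for cls in CELL_CLASSES:
        out[f"mean_{cls}"] = wide_mean[cls]
        out[f"frac_{cls}"] = wide_frac[cls]
        out[f"enriched_{cls}"] = [
            is_enriched(m, f, cfg)
            for m, f in zip(wide_mean[cls], wide_frac[cls])
        ]
    orn = out["enriched_ORN"]
    pn = out["enriched_PN"]
    out["enriched_in"] = np.select(
        [orn & pn, orn & ~pn, ~orn & pn],
        [BOTH, ORN_ONLY, PN_ONLY],
        default=NEITHER,
    )
    # "More abundant in PN": robustly expressed there and with the higher mean.
    out["more_abundant_in_pn"] = pn & (out["mean_PN"] > out["mean_ORN"])
    return out


def _receptor_status(
    receptor_id: str, enr: pd.DataFrame, proteome: FilteredProteome
) -> str:
    if receptor_id not in proteome.union:
        return "NOT_DETECTED"
    if receptor_id in enr.index:
        call = enr.loc[receptor_id, "call"]
        if call == CALL_ENDO:
            return "ENDO_ENRICHED"
        if call == CALL_SURF:
            return "SURF_ENRICHED"
    # Detected without a significant compartment preference.
    return "DUAL"


def join_ligand_receptors(
    secreted_endo: pd.DataFrame,
    ann: AnnotationTable,
    enr: pd.DataFrame,
    proteome: FilteredProteome,
    calls: pd.DataFrame | None = None,
) -> list[LigandReceptorRecord]:
    """One record per endosome-enriched secreted ligand.

    ``secreted_endo`` is the (already endosome-restricted) subset from
    :func:`~endoprofiler.compartment_analysis.subset_by_category`; its row
    order is preserved. Receptors come from the annotation table; each is
    marked ENDO_ENRICHED, DUAL (detected in the proteome without significant
    preference), SURF_ENRICHED, or NOT_DETECTED. ``calls`` is the
    :func:`call_cell_types` output keyed by gene; ligands absent from it get
    cell type "NOT_PROFILED".
    """
    records: list[LigandReceptorRecord] = []
    for ligand in secreted_endo.index:
        if ligand in ann.data.index:
            receptor_ids = ann.data.loc[ligand, "receptor_ids"]
            gene = ann.data.loc[ligand, "gene_id"]
        else:
            receptor_ids, gene = (), ligand
        known = [r for r in receptor_ids if r in ann.data.index or r in enr.index or r in proteome.union]
        unmatched = tuple(r for r in receptor_ids if r not in known)
        status = {r: _receptor_status(r, enr, proteome) for r in known}
        if calls is not None and gene in calls.index:
            cell_type = calls.loc[gene, "enriched_in"]
        else:
            cell_type = "NOT_PROFILED"
        records.append(
            LigandReceptorRecord(
                ligand_id=ligand,
                ligand_compartment_call=str(secreted_endo.loc[ligand, "call"]),
                ligand_cell_type=str(cell_type),
                receptor_status=status,
                unmatched_receptors=unmatched,
            )
        )
    return records


def summarize_expression_matrix(
    counts: pd.DataFrame,
    cell_class: pd.Series,
    time_point: str,
) -> pd.DataFrame:
    """Summarize a raw cell x gene count matrix into the long expression format.

    Counts are CPM-normalized per cell, log2(CPM+1)-transformed, then averaged
    per cell class; the expressing fraction counts cells with count > 0.
    """
    if not counts.index.equals(cell_class.index):
        raise ValueError("cell_class must be indexed like the count matrix rows")
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    if (totals <= 0).any():
        raise ValueError("every cell needs a positive total count for CPM")
    cpm = counts.to_numpy(dtype=float) / totals[:, None] * 1e6
    logc = pd.DataFrame(np.log2(cpm + 1.0), index=counts.index, columns=counts.columns)
    rows = []
    for cls in CELL_CLASSES:
        mask = (cell_class == cls).to_numpy()
        if not mask.any():
            continue
        mean = logc.loc[mask].mean(axis=0)
        frac = (counts.loc[mask] > 0).mean(axis=0)
        for gene in counts.columns:
            rows.append((gene, cls, time_point, float(mean[gene]), float(frac[gene])))
    return pd.DataFrame(
        rows,
        columns=["gene", "cell_class", "time_point", "mean_log2cpm1", "frac_expressing"],
    )
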