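"""Four-step contaminant-filtering cascade.

1. Keep proteins with at least ``k`` unique peptides (default 2).
2. Per experimental replicate, rank proteins by their NC-ratio and choose the
   ratio cutoff maximizing TPR - FPR (Youden index), where truth labels come
   from annotation: a signal peptide and/or a TM domain marks a plausible
   labeling substrate (TP), neither marks a putative contaminant (FP).
3. Per condition, keep proteins retained in every replicate.
4. Union the two condition sets into the final filtered proteome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    AnnotationTable,
    ChannelDesign,
    Condition,
    DegenerateInputError,
    ProteinQuantTable,
)
from .tmt_quant import RatioTable

__all__ = [
    "RocPoint",
    "CutoffResult",
    "FilteredProteome",
    "filter_min_peptides",
    "annotate_tp_fp",
    "roc_cutoff",
    "replicate_cutoffs",
    "intersect_replicates",
    "assemble_filtered_proteome",
    "apply_filter_cascade",
]


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    tpr: float
    fpr: float


@dataclass
class CutoffResult:
    """ROC curve and chosen Youden-optimal ratio cutoff for one replicate."""

    channel_id: str
    curve: list[RocPoint]
    chosen_threshold: float
    youden: float
    retained: set[str]

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.threshold, p.tpr, p.fpr) for p in self.curve],
            columns=["threshold", "tpr", "fpr"],
        )


@dataclass
class FilteredProteome:
    """Per-condition replicate-intersected sets and their union, with provenance."""

    endo: set[str]
    surf: set[str]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def union(self) -> set[str]:
        return self.endo | self.surf

    @property
    def both(self) -> set[str]:
        return self.endo & self.surf

    def condition_set(self, condition: Condition | str) -> set[str]:
        return self.endo if Condition(condition) == Condition.ENDO else self.surf


def filter_min_peptides(table: ProteinQuantTable, k: int) -> ProteinQuantTable:
    """Keep rows with ``unique_peptides >= k``; row order is preserved."""
    if k < 0:
        raise ValueError("k must be >= 0")
    kept = table.data[table.data["unique_peptides"] >= k]
    return ProteinQuantTable(data=kept.copy(), design=table.design)


def annotate_tp_fp(ann: AnnotationTable, ids: Iterable[str]) -> dict[str, str]:
    """Label each id TP (signal peptide and/or TM domain) or FP (neither)."""
    ids = list(ids)
    missing = [i for i in ids if i not in ann.data.index]
    if missing:
        raise KeyError(f"ids missing from annotations: {missing[:10]}")
    sp = ann.data["has_signal_peptide"]
    tm = ann.data["has_tm_domain"]
    return {i: ("TP" if bool(sp[i]) or bool(tm[i]) else "FP") for i in ids}


def roc_cutoff(
    ratios: Mapping[str, float],
    labels: Mapping[str, str],
    channel_id: str = "",
    inclusive: bool = True,
) -> CutoffResult:
    """Choose the ratio cutoff maximizing TPR - FPR on the ranked protein list.

    Proteins are sorted by ratio descending; after each distinct ratio value
    (ties processed as one block) the cumulative TPR and FPR are recorded.
    The chosen threshold is the ratio at the earliest (most stringent)
    maximizer of TPR - FPR. Retention at the threshold is inclusive
    (``ratio >= cutoff``) by default; ``inclusive=False`` retains strictly
    above.

    Raises
    ------
    DegenerateInputError
        If either class is absent — the cutoff is undefined without both
        TPs and FPs.
    """
    ids = list(ratios)
    if set(ids) - set(labels):
        raise KeyError("every ratio id needs a TP/FP label")
    y = np.array([labels[i] == "TP" for i in ids], dtype=bool)
    n_tp = int(y.sum())
    n_fp = int((~y).sum())
    if n_tp == 0 or n_fp == 0:
        raise DegenerateInputError(
            f"ROC cutoff undefined: need both classes (TP={n_tp}, FP={n_fp})"
        )
    r = np.array([ratios[i] for i in ids], dtype=float)
    order = np.argsort(-r, kind="stable")
    r_sorted = r[order]
    y_sorted = y[order]

    curve: list[RocPoint] = []
    best_j = -np.inf
    best_threshold = r_sorted[0]
    tp = fp = 0
    i = 0
    n = len(ids)
    while i < n:
        j = i
        while j < n and r_sorted[j] == r_sorted[i]:
            tp += int(y_sorted[j])
            fp += int(not y_sorted[j])
            j += 1
        tpr = tp / n_tp
        fpr = fp / n_fp
        curve.append(RocPoint(threshold=float(r_sorted[i]), tpr=tpr, fpr=fpr))
        if tpr - fpr > best_j:  # strict: earliest (highest-threshold) maximizer
            best_j = tpr - fpr
            best_threshold = float(r_sorted[i])
        i = j

    if inclusive:
        retained = {i_ for i_ in ids if ratios[i_] >= best_threshold}
    else:
        retained = {i_ for i_ in ids if ratios[i_] > best_threshold}
    return CutoffResult(
        channel_id=channel_id,
        curve=curve,
        chosen_threshold=best_threshold,
        youden=float(best_j),
        retained=retained,
    )


def replicate_cutoffs(
    ratios: RatioTable,
    labels: Mapping[str, str],
    condition: Condition | str,
    inclusive: bool = True,
) -> list[CutoffResult]:
    """One ROC cutoff per replicate channel of ``condition``."""
    chans = ratios.design.channels(condition)
    return [
        roc_cutoff(
            ratios.data[c].to_dict(), labels, channel_id=c, inclusive=inclusive
        )
        for c in chans
    ]


def intersect_replicates(results: Sequence[CutoffResult]) -> set[str]:
    """Proteins retained in every replicate of one condition."""
    if len(results) < 2:
        raise ValueError("replicate intersection needs >= 2 cutoff results")
    out = set(results[0].retained)
    for res in results[1:]:
        out &= res.retained
    return out


def assemble_filtered_proteome(
    endo: set[str],
    surf: set[str],
    provenance: pd.DataFrame | None = None,
) -> FilteredProteome:
    """Bundle the per-condition sets; union/both are derived properties."""
    if provenance is None:
        ids = sorted(endo | surf)
        provenance = pd.DataFrame(
            {
                "in_endo": [i in endo for i in ids],
                "in_surf": [i in surf for i in ids],
            },
            index=pd.Index(ids, name="protein_id"),
        )
    return FilteredProteome(endo=set(endo), surf=set(surf), provenance=provenance)


def apply_filter_cascade(
    table: ProteinQuantTable,
    ratios: RatioTable,
    ann: AnnotationTable,
    min_unique_peptides: int = 2,
    inclusive: bool = True,
) -> tuple[FilteredProteome, dict[Condition, list[CutoffResult]], dict[str, int]]:
    """Run the full cascade; returns the proteome, per-condition cutoff
    results, and the count of proteins surviving each step.

    ``ratios`` must be computed on the peptide-filtered table (or a superset;
    it is subset here).
    """
    counts: dict[str, int] = {"detected": len(table)}
    filtered = filter_min_peptides(table, min_unique_peptides)
    counts["min_peptides"] = len(filtered)

    keep = filtered.data.index
    sub = RatioTable(data=ratios.data.loc[keep].copy(), design=ratios.design)
    labels = annotate_tp_fp(ann, keep)

    per_condition: dict[Condition, list[CutoffResult]] = {}
    cond_sets: dict[Condition, set[str]] = {}
    for cond in (Condition.ENDO, Condition.SURF):
        results = replicate_cutoffs(sub, labels, cond, inclusive=inclusive)
        per_condition[cond] = results
        cond_sets[cond] = intersect_replicates(results)
        counts[f"{cond.value.lower()}_retained"] = len(cond_sets[cond])

    prov = pd.DataFrame(index=pd.Index(keep, name="protein_id"))
    prov["passed_min_peptides"] = True
    for cond, results in per_condition.items():
        for res in results:
            prov[f"retained_{res.channel_id}"] = prov.index.isin(res.retained)
        prov[f"in_{cond.value.lower()}"] = prov.index.isin(cond_sets[cond])
    proteome = assemble_filtered_proteome(
        cond_sets[Condition.ENDO], cond_sets[Condition.SURF], provenance=prov
    )
    counts["union"] = len(proteome.union)
    return proteome, per_condition, counts
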