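"""Post-enrichment compartment analyses.

Ranks the top-N transmembrane proteins labeled in each compartment, measures
the overlap between the two top lists (abundant proteins tend to be labeled
in both, so dual-compartment profiling is needed to resolve residence), and
extracts annotation-defined subsets ordered by endosomal enrichment for
downstream display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io_model import AnnotationTable, Condition
from .tmt_quant import RatioTable

__all__ = ["TopNReport", "top_n_tm", "overlap_fraction", "subset_by_category"]

logger = logging.getLogger(__name__)

RANKING_METRICS = ("mean_nc_ratio", "mean_intensity")


@dataclass
class TopNReport:
    condition: Condition
    n: int
    ranked_ids: list[str]
    ranking_metric: str
    log2fc: pd.Series  # per ranked protein, for heatmap export
    overlap_with_other: float | None = None

    def heatmap_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.ranked_ids,
                "rank": range(1, len(self.ranked_ids) + 1),
                "log2fc": [self.log2fc.get(i) for i in self.ranked_ids],
            }
        )


def top_n_tm(
    enr: pd.DataFrame,
    ann: AnnotationTable,
    ratios: RatioTable,
    condition: Condition | str,
    n: int = 200,
    metric: str = "mean_nc_ratio",
    intensities: pd.DataFrame | None = None,
) -> TopNReport:
    """Rank TM proteins by per-condition labeling and keep the top n.

    The metric is the mean over the condition's replicate channels of either
    the NC-ratio (default) or the raw intensity (requires ``intensities``).
    Ties break lexicographically by protein_id, so the ranking is invariant
    to input row order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if metric not in RANKING_METRICS:
        raise ValueError(f"metric must be one of {RANKING_METRICS}")
    cond = Condition(condition)
    tm_ids = [
        i
        for i in enr.index
        if i in ann.data.index and bool(ann.data.loc[i, "has_tm_domain"])
    ]
    chans = ratios.design.channels(cond)
    if metric == "mean_nc_ratio":
        score = ratios.data.loc[tm_ids, chans].mean(axis=1)
    else:
        if intensities is None:
            raise ValueError("metric 'mean_intensity' requires intensities")
        score = intensities.loc[tm_ids, chans].mean(axis=1)
    ranked = (
        pd.DataFrame({"score": score})
        .sort_values(["score"], ascending=False, kind="stable")
        .sort_index(kind="stable")
        .sort_values(["score"], ascending=False, kind="stable")
        .index.tolist()
    )
    if len(ranked) < n:
        logger.warning(
            "only %d TM proteins available for top-%d ranking (%s)",
            len(ranked),
            n,
            cond.value,
        )
    ranked = ranked[:n]
    return TopNReport(
        condition=cond,
        n=n,
        ranked_ids=ranked,
        ranking_metric=metric,
        log2fc=enr.loc[ranked, "log2fc"],
    )


def overlap_fraction(a: Sequence[str], b: Sequence[str]) -> float:
    """|set(a) & set(b)| / |set(a)| — the fraction of a's members also in b."""
    sa = set(a)
    if not sa:
        raise ValueError("overlap undefined for an empty first list")
    return len(sa & set(b)) / len(sa)


_CATEGORY_COLUMNS = {
    "secreted": "is_secreted",
    "tm": "has_tm_domain",
    "sp": "has_signal_peptide",
}


def subset_by_category(
    enr: pd.DataFrame, ann: AnnotationTable, category: str
) -> pd.DataFrame:
    """Enrichment rows for one annotation category, ordered by ascending
    log2(surf/endo) — i.e. from most to least endosome-enriched.

    ``category`` is 'secreted', 'tm', 'sp', or the name of any boolean column
    in the annotation table (custom tags such as junction markers).
    """
    col = _CATEGORY_COLUMNS.get(category, category)
    if col not in ann.data.columns:
        known = sorted(set(_CATEGORY_COLUMNS) | set(ann.data.columns))
        raise KeyError(f"unknown category {category!r}; known: {known}")
    flagged = set(ann.data.index[ann.data[col].astype(bool)])
    sub = enr.loc[[i for i in enr.index if i in flagged]]
    return sub.sort_values("log2fc", ascending=True, kind="stable")
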