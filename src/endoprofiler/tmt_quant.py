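"""Reporter-ion impurity correction and experimental-to-negative-control ratios.

Isobaric-label reporter ions bleed into neighbouring channels with known
isotope-impurity fractions. With the column convention (entry (i, j) = fraction
of channel j's true signal read in channel i) the measured vector per protein
is ``measured = M @ true``, so correction is an exact linear solve followed by
clamping physically impossible negative components to zero.

Ratios against the averaged negative control quantify labeling specificity:
background binders show ratios near 1, genuine labeling substrates well above.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_model import (
    ChannelDesign,
    Condition,
    ImpurityMatrix,
    NumericalError,
    ProteinQuantTable,
)

__all__ = ["correct_impurities", "compute_nc_ratios", "RatioTable"]

# Above this condition-number estimate the solve is numerically meaningless.
MAX_CONDITION_NUMBER = 1e8


def correct_impurities(
    table: ProteinQuantTable, impurities: ImpurityMatrix
) -> ProteinQuantTable:
    """Invert isotope-impurity mixing on every protein's channel intensities.

    Solves ``measured = M @ x`` exactly per protein (LAPACK solve; any exact
    method is equivalent), then clamps negative components of ``x`` to zero.

    Raises
    ------
    NumericalError
        If the matrix is singular or its condition number exceeds
        ``MAX_CONDITION_NUMBER``.
    ValueError
        If the matrix channels do not match the table design.
    """
    if tuple(impurities.channel_ids) != tuple(table.design.channel_ids):
        raise ValueError(
            "impurity matrix channels do not match the table design: "
            f"{impurities.channel_ids} vs {table.design.channel_ids}"
        )
    m = impurities.values
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > MAX_CONDITION_NUMBER:
        raise NumericalError(
            f"impurity matrix is singular or ill-conditioned (cond ~ {cond:.3g})"
        )
    chans = list(table.design.channel_ids)
    measured = table.data[chans].to_numpy(dtype=float)
    corrected = np.linalg.solve(m, measured.T).T
    corrected = np.clip(corrected, 0.0, None)
    out = table.data.copy()
    out[chans] = corrected
    return ProteinQuantTable(data=out, design=table.design)


class RatioTable:
    """Per-protein experimental-to-NC ratios.

    ``data`` is indexed by protein_id with one ratio column per experimental
    channel plus an ``nc_mean`` column (arithmetic mean of the two NC
    channels, before pseudocount).
    """

    def __init__(self, data: pd.DataFrame, design: ChannelDesign):
        exp = design.experimental_channels
        missing = [c for c in (*exp, "nc_mean") if c not in data.columns]
        if missing:
            raise ValueError(f"ratio table missing column(s): {missing}")
        vals = data[exp].to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError("ratios must be finite and > 0")
        self.data = data
        self.design = design

    @property
    def protein_ids(self) -> list[str]:
        return self.data.index.tolist()

    def ratios(self, channel: str) -> pd.Series:
        return self.data[channel]

    def condition_mean(self, condition: Condition | str) -> pd.Series:
        """Mean NC-ratio across a condition's replicate channels."""
        return self.data[self.design.channels(condition)].mean(axis=1)

    def __len__(self) -> int:
        return len(self.data)


def compute_nc_ratios(
    table: ProteinQuantTable, design: ChannelDesign, pseudocount: float = 1.0
) -> RatioTable:
    """Ratio each experimental channel against the averaged negative control.

    ``ratio(c) = (intensity(c) + pseudocount) / (nc_mean + pseudocount)``
    where ``nc_mean`` is the arithmetic mean of the two NC channels. A
    positive pseudocount keeps ratios finite and positive when channels
    drop to zero.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    nc = table.data[design.nc_channels].to_numpy(dtype=float)
    nc_mean = nc.mean(axis=1)
    exp = design.experimental_channels
    num = table.data[exp].to_numpy(dtype=float) + pseudocount
    denom = nc_mean + pseudocount
    if (denom <= 0).any():
        raise ValueError(
            "zero NC mean with zero pseudocount produces undefined ratios; "
            "use a positive pseudocount"
        )
    out = pd.DataFrame(num / denom[:, None], index=table.data.index, columns=exp)
    out["nc_mean"] = nc_mean
    return RatioTable(data=out, design=design)
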