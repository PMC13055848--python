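"""Domain types, table readers/writers, design validation, and run configuration.

The pipeline's substrate is a protein x TMT-channel reporter-intensity table
with a channel design assigning each channel to a biological condition:
endosome-lumen labeling (ENDO), cell-surface labeling (SURF), or negative
control (NC, no-enzyme/no-peroxide background). All tabular I/O is plain
TSV/CSV with a one-line header; ``protein_id`` is always the first column.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "SchemaError",
    "TableValidationError",
    "DegenerateInputError",
    "NumericalError",
    "ChannelDesign",
    "validate_design",
    "ProteinQuantTable",
    "AnnotationTable",
    "ImpurityMatrix",
    "RunConfig",
    "read_quant_table",
    "write_quant_table",
    "read_annotations",
    "write_annotations",
    "read_impurity_matrix",
    "write_impurity_matrix",
    "read_expression_summary",
    "write_expression_summary",
    "file_digest",
]


class Condition(str, enum.Enum):
    """Biological condition encoded by a TMT channel."""

    ENDO = "ENDO"
    SURF = "SURF"
    NC = "NC"


class SchemaError(ValueError):
    """A table's columns or header do not match the expected schema."""


class TableValidationError(ValueError):
    """A table parses but violates a content invariant."""


class DegenerateInputError(ValueError):
    """An operation's input is degenerate (e.g. single-class ROC labels)."""


class NumericalError(ArithmeticError):
    """A numerical precondition failed (e.g. near-singular impurity matrix)."""


# ---------------------------------------------------------------------------
# Channel design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelDesign:
    """Assignment of TMT channels to conditions and replicates.

    The profiled design uses 8 channels: three endosome-labeled replicates,
    three surface-labeled replicates, and two negative controls.
    """

    channel_ids: tuple[str, ...]
    condition_of: Mapping[str, Condition]
    replicate_index: Mapping[str, int]

    def channels(self, condition: Condition | str) -> list[str]:
        cond = Condition(condition)
        return [c for c in self.channel_ids if self.condition_of[c] == cond]

    @property
    def experimental_channels(self) -> list[str]:
        return [
            c for c in self.channel_ids if self.condition_of[c] != Condition.NC
        ]

    @property
    def nc_channels(self) -> list[str]:
        return self.channels(Condition.NC)

    @classmethod
    def default_8plex(cls) -> "ChannelDesign":
        """Three ENDO + three SURF replicates and two negative controls."""
        ids = (
            "endo_1",
            "endo_2",
            "endo_3",
            "surf_1",
            "surf_2",
            "surf_3",
            "nc_1",
            "nc_2",
        )
        cond = {}
        rep = {}
        for c in ids:
            name, idx = c.rsplit("_", 1)
            cond[c] = {"endo": Condition.ENDO, "surf": Condition.SURF, "nc": Condition.NC}[name]
            rep[c] = int(idx)
        return cls(channel_ids=ids, condition_of=cond, replicate_index=rep)


def validate_design(design: ChannelDesign) -> list[str]:
    """Return a list of invariant violations (empty iff the design is valid).

    Findings, not exceptions: callers decide whether to abort.
    """
    findings: list[str] = []
    ids = list(design.channel_ids)
    if len(set(ids)) != len(ids):
        findings.append("channel ids unique: duplicate channel ids present")
    missing_cond = [c for c in ids if c not in design.condition_of]
    if missing_cond:
        findings.append(f"every channel needs a condition: missing {missing_cond}")
        return findings
    missing_rep = [c for c in ids if c not in design.replicate_index]
    if missing_rep:
        findings.append(f"every channel needs a replicate index: missing {missing_rep}")
    n_nc = len(design.channels(Condition.NC))
    if n_nc != 2:
        findings.append(f"requires exactly 2 NC channels (got {n_nc})")
    for cond in (Condition.ENDO, Condition.SURF):
        n = len(design.channels(cond))
        if n < 2:
            findings.append(
                f"requires >=2 replicates per experimental condition ({cond.value} has {n})"
            )
    bad_rep = [
        c
        for c in ids
        if c in design.replicate_index
        and (not isinstance(design.replicate_index[c], int) or design.replicate_index[c] < 1)
    ]
    if bad_rep:
        findings.append(f"replicate indices must be positive integers: {bad_rep}")
    return findings


# ---------------------------------------------------------------------------
# Quantification table
# ---------------------------------------------------------------------------


@dataclass
class ProteinQuantTable:
    """Per-protein TMT reporter intensities plus a unique-peptide count.

    ``data`` is indexed by ``protein_id`` with a ``unique_peptides`` column
    followed by one intensity column per channel of ``design``.
    """

    data: pd.DataFrame
    design: ChannelDesign

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        if df.index.name != "protein_id":
            raise SchemaError("quant table must be indexed by 'protein_id'")
        dups = df.index[df.index.duplicated()].unique().tolist()
        if dups:
            raise TableValidationError(f"duplicate protein_id: {dups}")
        if "unique_peptides" not in df.columns:
            raise SchemaError("missing column 'unique_peptides'")
        missing = [c for c in self.design.channel_ids if c not in df.columns]
        if missing:
            raise SchemaError(f"missing channel column(s): {missing}")
        chans = list(self.design.channel_ids)
        vals = df[chans].to_numpy(dtype=float)
        if np.isnan(vals).any():
            bad = df.index[np.isnan(vals).any(axis=1)].tolist()
            raise TableValidationError(f"missing intensity cells for: {bad[:10]}")
        if not np.isfinite(vals).all():
            raise TableValidationError("non-finite intensity values present")
        if (vals < 0).any():
            bad = df.index[(vals < 0).any(axis=1)].tolist()
            raise TableValidationError(f"negative intensity for: {bad[:10]}")
        up = df["unique_peptides"].to_numpy()
        if (up < 0).any() or np.isnan(up.astype(float)).any():
            raise TableValidationError("unique_peptides must be non-negative integers")

    @property
    def protein_ids(self) -> list[str]:
        return self.data.index.tolist()

    def intensities(self, channels: Sequence[str] | None = None) -> pd.DataFrame:
        chans = list(channels) if channels is not None else list(self.design.channel_ids)
        return self.data[chans]

    def __len__(self) -> int:
        return len(self.data)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_quant_table(path: str | Path, design: ChannelDesign) -> ProteinQuantTable:
    """Read a TSV/CSV quantification table and validate it against ``design``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.columns[0] != "protein_id":
        raise SchemaError(
            f"first column must be 'protein_id' (got {df.columns[0]!r})"
        )
    df = df.set_index("protein_id")
    return ProteinQuantTable(data=df, design=design)


def write_quant_table(table: ProteinQuantTable, path: str | Path) -> None:
    path = Path(path)
    cols = ["unique_peptides", *table.design.channel_ids]
    table.data[cols].to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_ANN_BOOL_COLS = ("has_signal_peptide", "has_tm_domain", "is_secreted")


@dataclass
class AnnotationTable:
    """Per-protein signal-peptide / TM-domain / secreted flags and receptor links.

    ``receptor_ids`` holds a tuple of protein ids per row (possibly empty);
    ``gene_id`` links proteomic ids to the expression summary. Flags serve as
    the TP/FP truth for the ratiometric cutoff: proteins with a signal peptide
    and/or a TM domain are plausible labeling substrates, others contaminants.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "protein_id":
            raise SchemaError("annotation table must be indexed by 'protein_id'")
        for col in _ANN_BOOL_COLS:
            if col not in df.columns:
                raise SchemaError(f"missing annotation column '{col}'")
        if "gene_id" not in df.columns:
            self.data = df = df.assign(gene_id=df.index)
        if "receptor_ids" not in df.columns:
            self.data = df = df.assign(receptor_ids=[() for _ in range(len(df))])
        df["receptor_ids"] = df["receptor_ids"].map(_as_receptor_tuple)
        bad = df.index[df["is_secreted"] & ~df["has_signal_peptide"]].tolist()
        if bad:
            raise TableValidationError(
                f"is_secreted implies has_signal_peptide; violated by: {bad[:10]}"
            )

    def unmatched_receptors(self) -> set[str]:
        known = set(self.data.index)
        out: set[str] = set()
        for recs in self.data["receptor_ids"]:
            out.update(r for r in recs if r not in known)
        return out

    def __len__(self) -> int:
        return len(self.data)


def _as_receptor_tuple(value) -> tuple[str, ...]:
    if isinstance(value, tuple):
        return value
    if isinstance(value, (list, set)):
        return tuple(value)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ()
    s = str(value).strip()
    if not s:
        return ()
    return tuple(p for p in (x.strip() for x in s.split(";")) if p)


def read_annotations(path: str | Path) -> AnnotationTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.columns[0] != "protein_id":
        raise SchemaError("first column must be 'protein_id'")
    df = df.set_index("protein_id")
    for col in _ANN_BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return AnnotationTable(data=df)


def write_annotations(ann: AnnotationTable, path: str | Path) -> None:
    path = Path(path)
    df = ann.data.copy()
    df["receptor_ids"] = df["receptor_ids"].map(";".join)
    df.to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# Impurity matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImpurityMatrix:
    """k x k isotope-impurity matrix: entry (i, j) is the fraction of channel
    j's true signal observed in channel i (column convention).
    """

    values: np.ndarray
    channel_ids: tuple[str, ...]

    COLUMN_SUM_TOL = 1e-6

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        k = len(self.channel_ids)
        if vals.shape != (k, k):
            raise TableValidationError(
                f"impurity matrix must be {k}x{k}, got {vals.shape}"
            )
        if not np.isfinite(vals).all():
            raise TableValidationError("impurity matrix has non-finite entries")
        colsum = vals.sum(axis=0)
        if (colsum > 1.0 + self.COLUMN_SUM_TOL).any():
            raise TableValidationError(
                "impurity matrix columns must sum to <= 1 (+tolerance)"
            )
        diag = np.diag(vals)
        off = vals - np.diag(diag)
        if not all(diag[j] > off[:, j].max(initial=0.0) for j in range(k)):
            raise TableValidationError(
                "impurity matrix must be diagonally dominant per column"
            )

    @property
    def k(self) -> int:
        return len(self.channel_ids)

    @classmethod
    def identity(cls, channel_ids: Sequence[str]) -> "ImpurityMatrix":
        k = len(channel_ids)
        return cls(values=np.eye(k), channel_ids=tuple(channel_ids))


def read_impurity_matrix(path: str | Path) -> ImpurityMatrix:
    """Read a CSV impurity matrix with channel ids as header and first column."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise SchemaError(
            "impurity matrix rows and columns must list the same channel ids"
        )
    return ImpurityMatrix(values=df.to_numpy(dtype=float), channel_ids=tuple(df.columns))


def write_impurity_matrix(m: ImpurityMatrix, path: str | Path) -> None:
    pd.DataFrame(m.values, index=list(m.channel_ids), columns=list(m.channel_ids)).to_csv(
        Path(path)
    )


# ---------------------------------------------------------------------------
# Expression summary
# ---------------------------------------------------------------------------

EXPR_COLUMNS = ("gene", "cell_class", "time_point", "mean_log2cpm1", "frac_expressing")
CELL_CLASSES = ("ORN", "PN")
TIME_POINTS = ("24h", "48h")


def read_expression_summary(path: str | Path) -> pd.DataFrame:
    """Read a long-format gene x cell-class x time-point expression summary.

    Columns: gene, cell_class (ORN/PN), time_point (24h/48h),
    mean_log2cpm1 (log2(CPM+1) units, >= 0), frac_expressing in [0, 1].
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in EXPR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"expression summary missing column(s): {missing}")
    bad_class = set(df["cell_class"]) - set(CELL_CLASSES)
    if bad_class:
        raise TableValidationError(f"unknown cell_class values: {sorted(bad_class)}")
    frac = df["frac_expressing"].to_numpy(dtype=float)
    if ((frac < 0) | (frac > 1)).any():
        raise TableValidationError("frac_expressing must lie in [0, 1]")
    if (df["mean_log2cpm1"].to_numpy(dtype=float) < 0).any():
        raise TableValidationError("mean_log2cpm1 must be non-negative")
    return df[list(EXPR_COLUMNS)].copy()


def write_expression_summary(df: pd.DataFrame, path: str | Path) -> None:
    df[list(EXPR_COLUMNS)].to_csv(Path(path), sep=_sep_for(Path(path)), index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Tunable thresholds for a pipeline run.

    Defaults follow the profiled study's stated rules: proteins need at least
    two unique peptides; the top-N TM ranking uses N = 200; a transcript is
    cell-type enriched when expressed in > 30% of cells at log2(CPM+1) >= 4.
    """

    min_unique_peptides: int = 2
    nc_pseudocount: float = 1.0
    significance_alpha: float = 0.05
    adjust_method: str = "bh"  # "bh" or "none"
    inclusive_threshold: bool = True
    top_n: int = 200
    topn_metric: str = "mean_nc_ratio"  # or "mean_intensity"
    expr_fraction_threshold: float = 0.30
    expr_level_threshold: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_unique_peptides < 0:
            raise TableValidationError("min_unique_peptides must be >= 0")
        if self.nc_pseudocount < 0:
            raise TableValidationError("nc_pseudocount must be >= 0")
        if not 0.0 < self.significance_alpha < 1.0:
            raise TableValidationError("significance_alpha must lie in (0, 1)")
        if self.adjust_method not in ("bh", "none"):
            raise TableValidationError("adjust_method must be 'bh' or 'none'")
        if self.top_n < 1:
            raise TableValidationError("top_n must be >= 1")
        if self.topn_metric not in ("mean_nc_ratio", "mean_intensity"):
            raise TableValidationError(
                "topn_metric must be 'mean_nc_ratio' or 'mean_intensity'"
            )
        if not 0.0 <= self.expr_fraction_threshold <= 1.0:
            raise TableValidationError("expr_fraction_threshold must lie in [0, 1]")
        if self.expr_level_threshold < 0:
            raise TableValidationError("expr_level_threshold must be >= 0")

    def to_toml(self, path: str | Path) -> None:
        lines = [f"schema_version = {CONFIG_SCHEMA_VERSION}"]
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                lines.append(f"{f.name} = {'true' if v else 'false'}")
            elif isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            else:
                lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        version = raw.pop("schema_version", None)
        if version != CONFIG_SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported config schema_version {version!r} "
                f"(expected {CONFIG_SCHEMA_VERSION})"
            )
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(
            {f.name: getattr(self, f.name) for f in fields(self)}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
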