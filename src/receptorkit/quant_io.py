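"""Reading, validation and filtering of protein-level LFQ quantification tables.

The tables handled here sit at the protein level of a label-free pull-down
experiment: one row per protein group, one intensity column per MS sample,
plus a unique-peptide count and a contaminant flag.  Zero or empty intensity
cells denote non-detection and are stored as missing (NaN), never as a
numeric zero — downstream imputation treats them as missing-not-at-random
low-abundance dropouts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CONTAMINANT_PREFIXES = ("contam_",)

PROVENANCE_ORDER = ("raw", "normalized", "imputed")


@dataclass
class ProteinQuantTable:
    """Protein-level quantification: linear-scale intensities plus row metadata.

    Attributes
    ----------
    meta : pandas.DataFrame
        Indexed by unique ``protein_id``; columns ``gene`` (str),
        ``peptide_count`` (int, unique peptides per protein group) and
        ``is_contaminant`` (bool).
    intensities : pandas.DataFrame
        Same index as ``meta``; one column per sample, linear LFQ scale,
        strictly positive where present, NaN where missing.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def protein_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_proteins(self) -> int:
        return len(self.meta)

    def validate(self) -> None:
        if self.meta.index.has_duplicates:
            dups = self.meta.index[self.meta.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein_id(s): {dups}")
        if self.intensities.columns.has_duplicates:
            raise ValueError("duplicate sample_ids in intensity columns")
        if not self.meta.index.equals(self.intensities.index):
            raise ValueError("meta and intensities indexed by different proteins")
        for col in ("gene", "peptide_count", "is_contaminant"):
            if col not in self.meta.columns:
                raise ValueError(f"meta missing required column {col!r}")
        vals = self.intensities.to_numpy(dtype=float)
        observed = ~np.isnan(vals)
        if np.any(vals[observed] <= 0):
            raise ValueError("intensities must be strictly positive where present")
        if (self.meta["peptide_count"] < 0).any():
            raise ValueError("peptide_count must be non-negative")


@dataclass(frozen=True)
class SampleDesign:
    """Maps each sample to a (group label, replicate index) pair.

    Group labels name the pull-down bait (e.g. ``NIX``, ``BNIP3``) or the
    tag-only control (e.g. ``GST``).
    """

    assignments: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        for sid, (group, rep) in self.assignments.items():
            if rep < 1:
                raise ValueError(f"replicate index must be >=1 for sample {sid!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for group, _ in self.assignments.values():
            seen.setdefault(group, None)
        return list(seen)

    def samples(self, group: str) -> list[str]:
        out = [s for s, (g, _) in self.assignments.items() if g == group]
        if not out:
            raise KeyError(f"unknown group {group!r}")
        return out

    def require_replicates(self, group: str, min_n: int = 2) -> None:
        n = len(self.samples(group))
        if n < min_n:
            raise ValueError(f"group {group!r} has {n} replicate(s); need >= {min_n}")


@dataclass
class Log2Matrix:
    """A proteins x samples matrix of log2 intensities with provenance.

    ``provenance`` advances only along raw -> normalized -> imputed.
    """

    values: pd.DataFrame
    provenance: str = "raw"

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCE_ORDER:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        arr = self.values.to_numpy(dtype=float)
        if np.any(np.isinf(arr)):
            raise ValueError("log2 values must be finite where present")

    def with_values(self, values: pd.DataFrame, provenance: str) -> "Log2Matrix":
        old = PROVENANCE_ORDER.index(self.provenance)
        new = PROVENANCE_ORDER.index(provenance)
        if new < old:
            raise ValueError(
                f"provenance may not go backwards ({self.provenance} -> {provenance})"
            )
        return Log2Matrix(values=values, provenance=provenance)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_FRAGPIPE_PROTEIN_COLS = ("Protein ID", "Protein")
_FRAGPIPE_GENE_COLS = ("Gene", "Gene Names")
_FRAGPIPE_PEPTIDE_COLS = (
    "Combined Unique Peptides",
    "Unique Peptides",
    "Combined Total Peptides",
)
_FRAGPIPE_INTENSITY_SUFFIXES = (" MaxLFQ Intensity", " Intensity")


def _coerce_intensity_column(
    raw: pd.Series, protein_ids: pd.Index, column: str
) -> pd.Series:
    """Parse one intensity column; empty and zero become NaN, junk is an error."""
    stripped = raw.astype("string").str.strip()
    empty = stripped.isna() | (stripped == "")
    numeric = pd.to_numeric(stripped, errors="coerce")
    bad = numeric.isna() & ~empty
    if bad.any():
        row = protein_ids[bad.to_numpy().nonzero()[0][0]]
        raise ValueError(
            f"non-numeric intensity cell at protein {row!r}, column {column!r}: "
            f"{stripped[bad].iloc[0]!r}"
        )
    numeric = numeric.astype(float)
    numeric[numeric == 0] = np.nan
    if (numeric < 0).any():
        row = protein_ids[(numeric < 0).to_numpy().nonzero()[0][0]]
        raise ValueError(f"negative intensity at protein {row!r}, column {column!r}")
    return numeric


def read_protein_table(
    path: str | Path,
    dialect: str = "fragpipe_combined",
    contaminant_prefixes: Sequence[str] = DEFAULT_CONTAMINANT_PREFIXES,
    peptide_column: str | None = None,
) -> ProteinQuantTable:
    """Read a protein-level LFQ table from TSV.

    Parameters
    ----------
    path : path to a tab-separated file with a header row.
    dialect : ``"fragpipe_combined"`` (named columns ``Protein ID``, ``Gene``,
        a unique-peptides column and per-sample ``<sample> MaxLFQ Intensity``
        or ``<sample> Intensity`` columns) or ``"generic_wide"``
        (``protein_id``, ``gene``, ``peptide_count``, optional
        ``is_contaminant``, remaining columns are sample intensities).
    contaminant_prefixes : used to flag contaminants by protein_id prefix when
        no explicit contaminant column is present.
    peptide_column : override the auto-detected peptide-count column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a tab-separated table with a header row")

    if dialect == "fragpipe_combined":
        return _parse_fragpipe(df, contaminant_prefixes, peptide_column)
    if dialect == "generic_wide":
        return _parse_generic(df, contaminant_prefixes, peptide_column)
    raise ValueError(f"unknown dialect {dialect!r}")


def _pick(columns: Iterable[str], candidates: Sequence[str], what: str) -> str:
    for c in candidates:
        if c in columns:
            return c
    raise ValueError(f"could not find a {what} column among {list(candidates)}")


def _finish_table(
    protein_id: pd.Series,
    gene: pd.Series,
    peptides: pd.Series,
    contaminant: pd.Series,
    intensity_raw: pd.DataFrame,
) -> ProteinQuantTable:
    pid = pd.Index(protein_id.astype(str).str.strip(), name="protein_id")
    if pid.has_duplicates:
        dups = pid[pid.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein_id(s): {dups}")
    pep = pd.to_numeric(peptides, errors="coerce")
    if pep.isna().any():
        row = pid[pep.isna().to_numpy().nonzero()[0][0]]
        raise ValueError(f"non-numeric peptide count at protein {row!r}")
    meta = pd.DataFrame(
        {
            "gene": gene.astype(str).str.strip().to_numpy(),
            "peptide_count": pep.astype(int).to_numpy(),
            "is_contaminant": contaminant.astype(bool).to_numpy(),
        },
        index=pid,
    )
    cols = {}
    for col in intensity_raw.columns:
        cols[col] = _coerce_intensity_column(intensity_raw[col], pid, col).to_numpy()
    intensities = pd.DataFrame(cols, index=pid)
    n_missing = int(intensities.isna().to_numpy().sum())
    logger.info(
        "read %d proteins x %d samples (%d missing cells)",
        len(meta), intensities.shape[1], n_missing,
    )
    return ProteinQuantTable(meta=meta, intensities=intensities)


def _contaminant_flags(
    df: pd.DataFrame, protein_id: pd.Series, prefixes: Sequence[str]
) -> pd.Series:
    for name in ("Contaminant", "is_contaminant", "contaminant"):
        if name in df.columns:
            s = df[name].astype(str).str.strip().str.lower()
            return s.isin({"true", "1", "yes", "+", "t"})
    pid = protein_id.astype(str)
    flag = pd.Series(False, index=df.index)
    for p in prefixes:
        flag |= pid.str.startswith(p)
    return flag


def _parse_fragpipe(
    df: pd.DataFrame, prefixes: Sequence[str], peptide_column: str | None
) -> ProteinQuantTable:
    pid_col = _pick(df.columns, _FRAGPIPE_PROTEIN_COLS, "protein id")
    gene_col = _pick(df.columns, _FRAGPIPE_GENE_COLS, "gene")
    pep_col = peptide_column or _pick(df.columns, _FRAGPIPE_PEPTIDE_COLS, "peptide count")
    # Prefer MaxLFQ columns; fall back to plain Intensity if no MaxLFQ present.
    for suffix in _FRAGPIPE_INTENSITY_SUFFIXES:
        samples = [c for c in df.columns if c.endswith(suffix)]
        if suffix == " Intensity":
            samples = [c for c in samples if not c.endswith(" MaxLFQ Intensity")]
        if samples:
            intensity = df[samples].copy()
            intensity.columns = [c[: -len(suffix)] for c in samples]
            break
    else:
        raise ValueError("no intensity columns found (MaxLFQ Intensity / Intensity)")
    return _finish_table(
        df[pid_col], df[gene_col], df[pep_col],
        _contaminant_flags(df, df[pid_col], prefixes), intensity,
    )


def _parse_generic(
    df: pd.DataFrame, prefixes: Sequence[str], peptide_column: str | None
) -> ProteinQuantTable:
    pep_col = peptide_column or "peptide_count"
    required = {"protein_id", "gene", pep_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"generic_wide table missing columns {sorted(missing)}")
    known = required | {"is_contaminant"}
    sample_cols = [c for c in df.columns if c not in known]
    if not sample_cols:
        raise ValueError("generic_wide table has no intensity columns")
    return _finish_table(
        df["protein_id"], df["gene"], df[pep_col],
        _contaminant_flags(df, df["protein_id"], prefixes), df[sample_cols],
    )


def write_protein_table(table: ProteinQuantTable, path: str | Path) -> None:
    """Write a table in the ``generic_wide`` dialect; missing cells are empty."""
    out = pd.DataFrame(
        {
            "protein_id": table.meta.index,
            "gene": table.meta["gene"].to_numpy(),
            "peptide_count": table.meta["peptide_count"].to_numpy(),
            "is_contaminant": table.meta["is_contaminant"].to_numpy(),
        }
    )
    inten = table.intensities.reset_index(drop=True)
    out = pd.concat([out, inten], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.10g")


def read_sample_design(path: str | Path) -> SampleDesign:
    """Read a 3-column TSV: sample_id, group, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample design missing columns {sorted(missing)}")
    assignments = {
        str(r.sample_id): (str(r.group), int(r.replicate)) for r in df.itertuples()
    }
    if len(assignments) != len(df):
        raise ValueError("duplicate sample_id in design")
    return SampleDesign(assignments=assignments)


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    rows = [
        {"sample_id": s, "group": g, "replicate": r}
        for s, (g, r) in design.assignments.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering and transforms
# ---------------------------------------------------------------------------

def filter_quantifiable(
    table: ProteinQuantTable, min_peptides: int = 2
) -> ProteinQuantTable:
    """Keep non-contaminant proteins with at least ``min_peptides`` unique peptides.

    Row order is preserved.  An empty result is legal and raises a warning,
    not an error.
    """
    if min_peptides < 1:
        raise ValueError("min_peptides must be a positive integer")
    keep = (~table.meta["is_contaminant"]) & (
        table.meta["peptide_count"] >= min_peptides
    )
    n_contam = int(table.meta["is_contaminant"].sum())
    n_low = int(
        ((~table.meta["is_contaminant"]) & (table.meta["peptide_count"] < min_peptides)).sum()
    )
    logger.info(
        "filter_quantifiable: kept %d/%d (removed %d contaminants, %d below %d peptides)",
        int(keep.sum()), len(keep), n_contam, n_low, min_peptides,
    )
    if not keep.any():
        warnings.warn("filter_quantifiable produced an empty table", stacklevel=2)
    return ProteinQuantTable(
        meta=table.meta.loc[keep].copy(), intensities=table.intensities.loc[keep].copy()
    )


def log2_transform(table: ProteinQuantTable) -> Log2Matrix:
    """log2-transform linear intensities; missing stays missing; provenance 'raw'."""
    arr = table.intensities.to_numpy(dtype=float)
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise ValueError("cannot log2-transform non-positive intensities")
    with np.errstate(invalid="ignore"):
        values = pd.DataFrame(
            np.log2(arr), index=table.intensities.index, columns=table.intensities.columns
        )
    return Log2Matrix(values=values, provenance="raw")
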