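"""Readers and writers for the tabular formats the pipeline touches.

Two matrix dialects are supported:

* ``maxquant_proteingroups`` — a tab-delimited subset of a MaxQuant
  ``proteinGroups.txt``: a ``Protein IDs`` column plus one
  ``LFQ intensity <sample>`` column per run.  The first entry of the
  semicolon-separated group id becomes the display id; the full group
  string is retained on the matrix.
* ``plain_matrix`` — protein id in the first column, one column per run.

On the raw-intensity scale a stored 0, an empty field, or the literal
string ``NaN`` all mean "not detected" (MaxQuant writes 0 for
non-detection).  Writers serialize missing values as empty fields; a
write→read round trip is the identity on values, mask and orderings.
"""

from __future__ import annotations

import pandas as pd

from .datamodel import (
    SCALE_RAW,
    BiomarkerTable,
    FormatError,
    ProteinAbundanceMatrix,
    SampleTable,
    ValidationError,
)

DIALECTS = ("maxquant_proteingroups", "plain_matrix")
_MAXQUANT_ID_COLUMN = "Protein IDs"
_LFQ_PREFIX = "LFQ intensity "


def _read_raw_table(path, sep: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed table: {exc}") from exc


def read_lfq_matrix(path, dialect: str = "plain_matrix",
                    scale_tag: str = SCALE_RAW) -> ProteinAbundanceMatrix:
    """Read a protein × sample LFQ matrix.

    Parameters
    ----------
    path
        Tab-delimited input file.
    dialect
        ``"maxquant_proteingroups"`` or ``"plain_matrix"``.
    scale_tag
        Scale of the stored values.  On ``"raw_intensity"`` (the default,
        matching MaxQuant output) zeros are converted to missing; on
        ``"log2"`` zeros are legitimate values and only blank/NaN fields
        are missing.
    """
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    raw = _read_raw_table(path, sep="\t")
    protein_groups = None
    if dialect == "maxquant_proteingroups":
        if _MAXQUANT_ID_COLUMN not in raw.columns:
            raise FormatError(f"{path}: missing {_MAXQUANT_ID_COLUMN!r} column")
        lfq_cols = [c for c in raw.columns if c.startswith(_LFQ_PREFIX)]
        if not lfq_cols:
            raise FormatError(f"{path}: no '{_LFQ_PREFIX}<sample>' columns")
        full_ids = raw[_MAXQUANT_ID_COLUMN].astype(str)
        display = full_ids.str.split(";").str[0]
        if display.duplicated().any():
            dups = display[display.duplicated()].tolist()
            raise ValidationError(f"duplicate protein ids after group collapse: {dups[:5]}")
        protein_groups = dict(zip(display, full_ids))
        values = raw[lfq_cols].copy()
        values.columns = [c[len(_LFQ_PREFIX):] for c in lfq_cols]
        values.index = display
    else:
        if raw.shape[1] < 2:
            raise FormatError(f"{path}: plain matrix needs an id column and >=1 sample")
        values = raw.set_index(raw.columns[0])
        values.index = values.index.astype(str)
    try:
        values = values.apply(pd.to_numeric, errors="raise")
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric abundance value: {exc}") from exc
    if scale_tag == SCALE_RAW:
        values = values.where(values != 0)  # 0 encodes non-detection
    return ProteinAbundanceMatrix(values, scale_tag=scale_tag,
                                  protein_groups=protein_groups)


def write_matrix(matrix: ProteinAbundanceMatrix, path) -> None:
    """Write a matrix as a plain tab-delimited table (missing → empty field)."""
    matrix.values.to_csv(path, sep="\t", index_label="protein_id", na_rep="")


def read_sample_metadata(path) -> SampleTable:
    """Read and validate the per-run sample metadata CSV."""
    return SampleTable(_read_raw_table(path, sep=","))


def read_biomarker_table(path) -> BiomarkerTable:
    """Read and validate the per-infant immunoassay concentration CSV."""
    return BiomarkerTable(_read_raw_table(path, sep=","))


def write_table(table, path) -> None:
    """Write a SampleTable, BiomarkerTable or plain DataFrame as CSV."""
    df = getattr(table, "df", table)
    df.to_csv(path, index=False, na_rep="")
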