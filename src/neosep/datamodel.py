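"""Core data containers for the cord-blood sepsis-biomarker pipeline.

Three tabular objects flow through every stage:

* :class:`ProteinAbundanceMatrix` — a protein × sample grid of label-free
  quantification (LFQ) intensities with an explicit missingness mask.
  MaxQuant reports an LFQ intensity of 0 when a protein group was not
  quantified in a run; readers translate that into "missing", never into a
  numeric zero.  The matrix carries a ``scale_tag`` so that downstream
  operations can refuse to, e.g., log-transform twice.
* :class:`SampleTable` — per-run metadata: sepsis group, MS batch,
  technical-replicate id, gestational age and the clinical covariates used
  by the predictive models.
* :class:`BiomarkerTable` — per-infant immunoassay concentrations (CRP,
  SAA, LBP in mg/mL).

All validation errors raise typed exceptions so that malformed inputs never
coerce silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_EOS = "EOS"
GROUP_CONTROL = "control"
GROUP_PS = "PS"
GROUP_POOLED = "pooled_control"
VALID_GROUPS = (GROUP_EOS, GROUP_CONTROL, GROUP_PS, GROUP_POOLED)

SCALE_RAW = "raw_intensity"
SCALE_LOG2 = "log2"
VALID_SCALES = (SCALE_RAW, SCALE_LOG2)

GA_LOW = 20.0
GA_HIGH = 44.0


class NeosepError(Exception):
    """Base class for every error this package raises deliberately."""


class ValidationError(NeosepError, ValueError):
    """A value or table violates a documented invariant."""


class FormatError(NeosepError, ValueError):
    """A file does not parse as the declared dialect."""


class ConfigurationError(NeosepError):
    """A stage was invoked with an unusable configuration."""


class PipelineStageError(NeosepError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class ProteinAbundanceMatrix:
    """Protein × sample abundance grid with NaN as the missing marker.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample run.
        NaN means "not detected / not quantified".
    scale_tag
        ``"raw_intensity"`` (all non-missing values strictly positive) or
        ``"log2"``.
    protein_groups
        Optional mapping from the display id (first entry of a
        semicolon-separated MaxQuant protein-group id) to the full group
        string, preserved for auditability.
    """

    values: pd.DataFrame
    scale_tag: str = SCALE_RAW
    protein_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        self.values.index.name = None
        self.values.columns.name = None
        if self.scale_tag not in VALID_SCALES:
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate protein ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr) | np.isnan(arr)):
            raise ValidationError("matrix contains non-finite, non-missing values")
        if self.scale_tag == SCALE_RAW and arr.size and np.nanmin(arr) <= 0:
            raise ValidationError("raw-intensity values must be > 0 (0 encodes missing)")

    # -- views -----------------------------------------------------------
    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the value is missing."""
        return self.values.isna()

    def detection_fraction(self) -> pd.Series:
        """Per-protein fraction of samples with a non-missing value."""
        return self.values.notna().mean(axis=1)

    # -- manipulation ----------------------------------------------------
    def copy(self) -> "ProteinAbundanceMatrix":
        return ProteinAbundanceMatrix(
            self.values.copy(), self.scale_tag,
            dict(self.protein_groups) if self.protein_groups else None,
        )

    def subset_proteins(self, ids) -> "ProteinAbundanceMatrix":
        missing = [i for i in ids if i not in self.values.index]
        if missing:
            raise ValidationError(f"unknown protein ids: {missing[:5]}")
        return ProteinAbundanceMatrix(self.values.loc[list(ids)].copy(), self.scale_tag,
                                      self.protein_groups)

    def subset_samples(self, ids) -> "ProteinAbundanceMatrix":
        missing = [i for i in ids if i not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        return ProteinAbundanceMatrix(self.values[list(ids)].copy(), self.scale_tag,
                                      self.protein_groups)


REQUIRED_SAMPLE_COLUMNS = (
    "sample_id", "infant_id", "group", "batch", "replicate_id",
    "gestational_age", "sex", "chorioamnionitis", "prom", "preeclampsia",
    "multiple_gestation", "delivery_route", "labor", "plasma_protein_conc",
    "outlier_flag",
)
BOOL_SAMPLE_COLUMNS = (
    "chorioamnionitis", "prom", "preeclampsia", "multiple_gestation",
    "labor", "outlier_flag",
)

_BOOL_MAP = {
    True: True, False: False, 1: True, 0: False, "1": True, "0": False,
    "true": True, "false": False, "True": True, "False": False,
    "TRUE": True, "FALSE": False,
}


def coerce_bool(series: pd.Series, name: str) -> pd.Series:
    out = series.map(_BOOL_MAP)
    bad = series[out.isna() & series.notna()]
    if len(bad) or series.isna().any():
        raise ValidationError(
            f"column {name!r} has non-boolean entries: {bad.unique()[:5].tolist()}")
    return out.astype(bool)


@dataclass
class SampleTable:
    """Per-run sample metadata with pooled-control bookkeeping.

    One row per MS run.  Pooled-control rows anchor the batch
    normalization; they carry no infant covariates (gestational age, sex,
    etc. may be blank for them).  Validation warnings (a batch without a
    pooled-control row) are recorded on :attr:`warnings` rather than
    raised, because single-batch inputs are legitimate.
    """

    df: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["infant_id"] = df["infant_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        bad_groups = set(df["group"]) - set(VALID_GROUPS)
        if bad_groups:
            raise ValidationError(f"unknown group labels: {sorted(bad_groups)}")
        try:
            df["batch"] = df["batch"].astype(int)
            df["replicate_id"] = df["replicate_id"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"batch/replicate_id must be integers: {exc}") from exc
        if (df["batch"] < 1).any():
            raise ValidationError("batch must be >= 1")
        for col in BOOL_SAMPLE_COLUMNS:
            df[col] = coerce_bool(df[col], col)
        infants = df["group"] != GROUP_POOLED
        ga = pd.to_numeric(df["gestational_age"], errors="coerce")
        bad_ga = infants & (ga.isna() | (ga <= GA_LOW) | (ga >= GA_HIGH))
        if bad_ga.any():
            raise ValidationError(
                f"gestational_age outside ({GA_LOW}, {GA_HIGH}) for samples "
                f"{df.loc[bad_ga, 'sample_id'].tolist()[:5]}")
        df["gestational_age"] = ga
        bad_sex = infants & ~df["sex"].isin(["F", "M"])
        if bad_sex.any():
            raise ValidationError("sex must be 'F' or 'M' for infant samples")
        bad_route = infants & ~df["delivery_route"].isin(["vaginal", "cesarean"])
        if bad_route.any():
            raise ValidationError("delivery_route must be 'vaginal' or 'cesarean'")
        df["plasma_protein_conc"] = pd.to_numeric(df["plasma_protein_conc"],
                                                  errors="coerce")
        self.df = df.reset_index(drop=True)
        batches_with_pool = set(df.loc[df["group"] == GROUP_POOLED, "batch"])
        for b in sorted(set(df["batch"])):
            if b not in batches_with_pool:
                self.warnings.append(f"batch {b} has no pooled_control sample")

    # -- lookups ---------------------------------------------------------
    def group_of(self) -> pd.Series:
        """sample_id → group mapping."""
        return self.df.set_index("sample_id")["group"]

    def batch_of(self) -> pd.Series:
        return self.df.set_index("sample_id")["batch"]

    def rows_for(self, sample_ids) -> pd.DataFrame:
        idx = self.df.set_index("sample_id")
        missing = [s for s in sample_ids if s not in idx.index]
        if missing:
            raise ValidationError(f"sample ids without metadata rows: {missing[:5]}")
        return idx.loc[list(sample_ids)].reset_index()

    def infants(self) -> pd.DataFrame:
        """One row per infant specimen (pooled controls excluded)."""
        df = self.df[self.df["group"] != GROUP_POOLED]
        return (df.sort_values(["infant_id", "replicate_id"])
                  .drop_duplicates("infant_id")
                  .reset_index(drop=True))

    def copy(self) -> "SampleTable":
        return SampleTable(self.df.copy())


BIOMARKER_COLUMNS = ("crp", "saa", "lbp")
REQUIRED_BIOMARKER_COLUMNS = ("infant_id",) + BIOMARKER_COLUMNS + ("group",)
_BIOMARKER_GROUPS = (GROUP_EOS, GROUP_CONTROL, GROUP_PS)


@dataclass
class BiomarkerTable:
    """Per-infant immunoassay concentrations (CRP, SAA, LBP; mg/mL)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_BIOMARKER_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"biomarker table missing columns: {missing}")
        df = df.copy()
        df["infant_id"] = df["infant_id"].astype(str)
        if df["infant_id"].duplicated().any():
            dups = df.loc[df["infant_id"].duplicated(), "infant_id"].tolist()
            raise ValidationError(f"duplicate infant ids: {dups[:5]}")
        bad_groups = set(df["group"]) - set(_BIOMARKER_GROUPS)
        if bad_groups:
            raise ValidationError(f"unknown biomarker group labels: {sorted(bad_groups)}")
        for col in BIOMARKER_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce")
            if (df[col].dropna() < 0).any():
                raise ValidationError(f"negative concentration in column {col!r}")
        self.df = df.reset_index(drop=True)

    def for_group(self, group: str) -> pd.DataFrame:
        return self.df[self.df["group"] == group].reset_index(drop=True)

    def copy(self) -> "BiomarkerTable":
        return BiomarkerTable(self.df.copy())
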