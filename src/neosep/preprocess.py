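"""Normalization, filtering and imputation of the LFQ matrix.

The stage order mirrors the analysis workflow: log2 transform → drop
proteins detected in only one batch → pooled-control batch normalization →
technical-replicate averaging → 20% detection partition → (for
visualization/ordering only) two-step imputation.  All inferential
statistics downstream run on the non-imputed matrix; the imputed matrix
exists solely to feed complete-data consumers such as hierarchical
ordering and PCA.

Batch normalization subtracts, per protein and batch, the mean log2
pooled-control abundance difference between that batch and the reference
batch, so after correction the pooled-control means agree across batches
exactly.  A missing pooled anchor for a (protein, batch) pair yields an
offset of 0 and is logged rather than dropping the protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    GROUP_POOLED,
    SCALE_LOG2,
    SCALE_RAW,
    ConfigurationError,
    ProteinAbundanceMatrix,
    SampleTable,
    ValidationError,
)


def log2_transform(matrix: ProteinAbundanceMatrix) -> ProteinAbundanceMatrix:
    """log2 every non-missing intensity; the mask is unchanged."""
    if matrix.scale_tag != SCALE_RAW:
        raise ValidationError("log2_transform expects a raw_intensity matrix")
    return ProteinAbundanceMatrix(np.log2(matrix.values), scale_tag=SCALE_LOG2,
                                  protein_groups=matrix.protein_groups)


def exclude_single_batch_proteins(matrix: ProteinAbundanceMatrix,
                                  samples: SampleTable):
    """Drop proteins observed in fewer than two distinct batches.

    Returns ``(filtered_matrix, excluded_protein_ids)``.  A protein is
    retained iff it has at least one non-missing value in at least two
    batches; all-missing proteins are excluded.
    """
    batch_of = samples.batch_of()
    missing_meta = [s for s in matrix.samples if s not in batch_of.index]
    if missing_meta:
        raise ValidationError(f"samples without metadata: {missing_meta[:5]}")
    batches = batch_of.loc[matrix.samples].to_numpy()
    detected = matrix.values.notna().to_numpy()
    n_batches_detected = np.array([
        len(np.unique(batches[row])) for row in detected])
    keep = n_batches_detected >= 2
    excluded = [p for p, k in zip(matrix.proteins, keep) if not k]
    return matrix.subset_proteins(
        [p for p, k in zip(matrix.proteins, keep) if k]), excluded


@dataclass
class BatchNormReport:
    """Per-protein, per-batch correction terms (log2 units).

    ``offsets`` has one column per batch; the reference-batch column is
    exactly zero.  ``missing_anchor`` lists (protein, batch) pairs whose
    pooled-control mean was unavailable — their offset was left at 0.
    """

    reference_batch: int
    offsets: pd.DataFrame
    missing_anchor: list[tuple[str, int]] = field(default_factory=list)

    def invert(self, matrix: ProteinAbundanceMatrix,
               samples: SampleTable) -> ProteinAbundanceMatrix:
        """Undo the normalization exactly (adds the offsets back)."""
        batch_of = samples.batch_of()
        values = matrix.values.copy()
        for b in self.offsets.columns:
            cols = [s for s in values.columns if batch_of[s] == b]
            values[cols] = values[cols].add(self.offsets[b], axis=0)
        return ProteinAbundanceMatrix(values, matrix.scale_tag,
                                      matrix.protein_groups)


def batch_normalize(matrix: ProteinAbundanceMatrix, samples: SampleTable,
                    reference_batch: int = 1):
    """Pooled-control anchored batch correction.

    For protein *p* and batch *n*, ``offset(p, n) = mean_pooled(p, n) −
    mean_pooled(p, reference)``; that offset is subtracted from every
    non-missing value of *p* in batch-*n* runs (pooled controls included).
    Returns ``(normalized_matrix, BatchNormReport)``.
    """
    if matrix.scale_tag != SCALE_LOG2:
        raise ValidationError("batch_normalize expects a log2-scale matrix")
    meta = samples.rows_for(matrix.samples)
    batches = sorted(meta["batch"].unique())
    pooled = meta[meta["group"] == GROUP_POOLED]
    if len(batches) > 1 and pooled.empty:
        raise ConfigurationError("no pooled_control samples; cannot batch-normalize")
    offsets = pd.DataFrame(0.0, index=matrix.proteins, columns=batches)
    missing_anchor: list[tuple[str, int]] = []
    if len(batches) > 1:
        if reference_batch not in batches:
            raise ConfigurationError(f"reference batch {reference_batch} absent")
        pooled_means = {}
        for b in batches:
            cols = pooled.loc[pooled["batch"] == b, "sample_id"]
            pooled_means[b] = (matrix.values[list(cols)].mean(axis=1)
                               if len(cols) else
                               pd.Series(np.nan, index=matrix.proteins))
        ref = pooled_means[reference_batch]
        for b in batches:
            if b == reference_batch:
                continue
            off = pooled_means[b] - ref
            bad = off.isna()
            for p in off.index[bad]:
                missing_anchor.append((p, int(b)))
            offsets[b] = off.fillna(0.0)
    values = matrix.values.copy()
    batch_of = meta.set_index("sample_id")["batch"]
    for b in batches:
        cols = [s for s in values.columns if batch_of[s] == b]
        values[cols] = values[cols].sub(offsets[b], axis=0)
    report = BatchNormReport(reference_batch=reference_batch, offsets=offsets,
                             missing_anchor=missing_anchor)
    return ProteinAbundanceMatrix(values, SCALE_LOG2,
                                  matrix.protein_groups), report


def average_technical_replicates(matrix: ProteinAbundanceMatrix,
                                 samples: SampleTable):
    """Collapse runs to one specimen column per infant.

    A cell is the mean of the non-missing replicate values and missing
    only when every replicate is missing.  Pooled-control runs are dropped
    from the specimen-level output.  Returns ``(specimen_matrix,
    specimen_samples)``.
    """
    meta = samples.rows_for(matrix.samples)
    infant_meta = meta[meta["group"] != GROUP_POOLED]
    infant_order = infant_meta["infant_id"].drop_duplicates().tolist()
    spec_values = {}
    for infant in infant_order:
        cols = infant_meta.loc[infant_meta["infant_id"] == infant, "sample_id"]
        spec_values[infant] = matrix.values[list(cols)].mean(axis=1, skipna=True)
    spec_df = pd.DataFrame(spec_values, index=matrix.proteins)[infant_order]
    spec_meta = (infant_meta.sort_values(["infant_id", "replicate_id"])
                 .drop_duplicates("infant_id").copy())
    spec_meta["sample_id"] = spec_meta["infant_id"]
    spec_meta["replicate_id"] = 0
    spec_meta = spec_meta.set_index("infant_id").loc[infant_order].reset_index()
    spec_meta = spec_meta[list(samples.df.columns)]
    return (ProteinAbundanceMatrix(spec_df, matrix.scale_tag,
                                   matrix.protein_groups),
            SampleTable(spec_meta))


@dataclass
class DetectionPartition:
    """Exact split of proteins into commonly detected vs rare."""

    kept: ProteinAbundanceMatrix    # detection fraction strictly > threshold
    rare: ProteinAbundanceMatrix    # detection fraction <= threshold
    threshold: float


def detection_filter(matrix: ProteinAbundanceMatrix,
                     threshold: float = 0.20) -> DetectionPartition:
    """Partition proteins at the detection-fraction threshold (strict >)."""
    if not 0.0 <= threshold < 1.0:
        raise ValidationError("detection threshold must be in [0, 1)")
    frac = matrix.detection_fraction()
    kept_ids = [p for p in matrix.proteins if frac[p] > threshold]
    rare_ids = [p for p in matrix.proteins if frac[p] <= threshold]
    return DetectionPartition(kept=matrix.subset_proteins(kept_ids),
                              rare=matrix.subset_proteins(rare_ids),
                              threshold=threshold)


def impute_two_step(matrix: ProteinAbundanceMatrix, samples: SampleTable,
                    missing_threshold: float = 0.30, decile: float = 0.10,
                    seed: int = 0):
    """MNAR-aware two-step imputation, applied separately per sample group.

    Within each group: proteins with missingness strictly below
    ``missing_threshold`` are completed by iterated conditional (ridge-style
    Bayesian) regression on the other low-missingness proteins; proteins
    with higher missingness have each missing cell drawn uniformly from
    that protein's observed within-group values at or below the ``decile``
    quantile — the left-censoring assumption for rarely detected proteins.
    Observed cells are never altered.  Proteins with zero observations in a
    group stay missing and are logged.

    Returns ``(imputed_matrix, log_events)``.  Intended for
    visualization/ordering outputs only; inferential statistics use the
    non-imputed matrix.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    if matrix.scale_tag != SCALE_LOG2:
        raise ValidationError("impute_two_step expects a log2-scale matrix")
    meta = samples.rows_for(matrix.samples)
    out = matrix.values.copy()
    log: list[str] = []
    groups = sorted(meta["group"].unique())
    for gi, group in enumerate(groups):
        cols = meta.loc[meta["group"] == group, "sample_id"].tolist()
        sub = out[cols]
        frac = sub.isna().mean(axis=1)
        never = frac == 1.0
        for p in sub.index[never]:
            log.append(f"group {group}: protein {p} has no observations; left missing")
        iter_rows = sub.index[(frac < missing_threshold)]
        tail_rows = sub.index[(frac >= missing_threshold) & ~never]
        if sub.loc[iter_rows].isna().any().any():
            imputer = IterativeImputer(max_iter=10, tol=1e-3,
                                       initial_strategy="mean",
                                       imputation_order="ascending",
                                       random_state=int(seed) % (2 ** 31),
                                       keep_empty_features=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tiny groups rarely converge in 10 cycles
                filled = imputer.fit_transform(sub.loc[iter_rows].T.to_numpy())
            out.loc[iter_rows, cols] = filled.T
        rng = np.random.default_rng([int(seed), gi])
        for p in tail_rows:
            obs = sub.loc[p].dropna().to_numpy()
            q = np.quantile(obs, decile)
            pool = obs[obs <= q]
            miss_cols = sub.columns[sub.loc[p].isna()]
            out.loc[p, miss_cols] = rng.choice(pool, size=len(miss_cols))
    return ProteinAbundanceMatrix(out, SCALE_LOG2, matrix.protein_groups), log
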