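"""Differential abundance, presence/absence and demographics statistics.

Two-group protein comparisons use the Mann-Whitney U test with
Benjamini-Hochberg FDR control across the commonly-detected proteins.
The two-sided p-value is defined as ``min(1, 2 * min(tail probabilities))``:
exact by enumeration of the rank distribution for small tie-free samples
(n_x + n_y <= 12), otherwise the normal approximation with tie and
continuity correction.  Rare (presence/absence) proteins are summarized by
per-group detection fractions and are never assigned p-values — their
observed abundances are too censored to compare.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    GROUP_CONTROL,
    GROUP_EOS,
    GROUP_POOLED,
    ConfigurationError,
    ProteinAbundanceMatrix,
    SampleTable,
    ValidationError,
)

EXACT_MAX_N = 12


@lru_cache(maxsize=None)
def _u_counts(n_x: int, n_y: int) -> tuple[int, ...]:
    """Number of rank configurations giving each U value (no ties).

    Classic recursion c(u; n, m) = c(u - m; n - 1, m) + c(u; n, m - 1):
    either the largest rank belongs to x (contributing m to U) or to y.
    """
    if n_x == 0 or n_y == 0:
        return (1,)
    a = _u_counts(n_x - 1, n_y)
    b = _u_counts(n_x, n_y - 1)
    size = n_x * n_y + 1
    out = [0] * size
    for u, c in enumerate(a):
        out[u + n_y] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def mann_whitney_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U_x, p)``.

    ``U_x`` is computed with midranks for ties.  The p-value is exact for
    tie-free samples with ``n_x + n_y <= 12`` and otherwise uses the
    normal approximation with tie and continuity correction, clipped to
    (0, 1].  Samples where every value ties across both groups give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups need at least one non-missing value")
    n_x, n_y = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u_x = float(ranks[:n_x].sum() - n_x * (n_x + 1) / 2)
    has_ties = len(np.unique(combined)) < len(combined)
    if np.all(combined == combined[0]):
        return n_x * n_y / 2.0, 1.0
    if not has_ties and n_x + n_y <= EXACT_MAX_N:
        counts = np.asarray(_u_counts(n_x, n_y), dtype=float)
        total = counts.sum()
        u = int(round(u_x))
        lower = counts[: u + 1].sum() / total
        upper = counts[u:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
        if np.isnan(p):  # degenerate tie structure
            p = 1.0
    return u_x, float(min(max(p, np.nextafter(0, 1)), 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_columns(matrix: ProteinAbundanceMatrix, samples: SampleTable,
                   group: str) -> list[str]:
    group_of = samples.group_of()
    return [s for s in matrix.samples if group_of.get(s) == group]


def differential_abundance(matrix: ProteinAbundanceMatrix, samples: SampleTable,
                           groups: tuple[str, str] = (GROUP_EOS, GROUP_CONTROL),
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-protein Mann-Whitney tests with BH correction across proteins.

    Expects the detection-filtered, NON-imputed specimen-level matrix.
    Returns a DataFrame indexed by protein with columns ``mean_<a>``,
    ``mean_<b>`` (these are the mean-vs-mean scatter coordinates),
    ``n_<a>``, ``n_<b>``, ``U``, ``p_raw``, ``q_bh`` and ``significant``
    (q < alpha).  Proteins with an empty group are recorded with missing
    test results and excluded from the BH family.
    """
    g_a, g_b = groups
    cols_a = _group_columns(matrix, samples, g_a)
    cols_b = _group_columns(matrix, samples, g_b)
    if not cols_a or not cols_b:
        raise ConfigurationError(f"groups {groups} not both present in matrix")
    rows = []
    for p in matrix.proteins:
        x = matrix.values.loc[p, cols_a].dropna().to_numpy()
        y = matrix.values.loc[p, cols_b].dropna().to_numpy()
        row = dict(protein=p,
                   **{f"mean_{g_a.lower()}": x.mean() if len(x) else np.nan,
                      f"mean_{g_b.lower()}": y.mean() if len(y) else np.nan,
                      f"n_{g_a.lower()}": len(x), f"n_{g_b.lower()}": len(y)})
        if len(x) and len(y):
            row["U"], row["p_raw"] = mann_whitney_test(x, y)
        else:
            row["U"] = np.nan
            row["p_raw"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("protein")
    tested = table["p_raw"].notna()
    table["q_bh"] = np.nan
    if tested.any():
        table.loc[tested, "q_bh"] = bh_adjust(table.loc[tested, "p_raw"])
    table["significant"] = table["q_bh"] < alpha
    return table


def presence_absence(rare_matrix: ProteinAbundanceMatrix, samples: SampleTable,
                     groups: tuple[str, str] = (GROUP_EOS, GROUP_CONTROL),
                     margin: float = 0.15) -> pd.DataFrame:
    """Per-group detection fractions for the rare-protein partition.

    ``enriched_in`` is the group whose detection fraction exceeds the
    other's by more than ``margin``, else ``"neither"``.  No p-values: the
    abundances of these proteins are too rarely observed to test.
    """
    g_a, g_b = groups
    cols_a = _group_columns(rare_matrix, samples, g_a)
    cols_b = _group_columns(rare_matrix, samples, g_b)
    frac_a = rare_matrix.values[cols_a].notna().mean(axis=1)
    frac_b = rare_matrix.values[cols_b].notna().mean(axis=1)
    diff = frac_a - frac_b
    enriched = np.where(diff > margin, g_a, np.where(-diff > margin, g_b, "neither"))
    return pd.DataFrame({f"detect_frac_{g_a.lower()}": frac_a,
                         f"detect_frac_{g_b.lower()}": frac_b,
                         "enriched_in": enriched},
                        index=rare_matrix.proteins)


def sensitivity_subset(samples: SampleTable, ga_cutoff: float = 37.0) -> SampleTable:
    """GA-matched subset: drop full-term controls (GA >= cutoff).

    EOS rows are always retained (all EOS infants are preterm); pooled
    controls, which carry no GA, are kept for upstream consistency.
    """
    df = samples.df
    keep = ((df["group"] == GROUP_EOS) | (df["group"] == GROUP_POOLED)
            | (df["gestational_age"] < ga_cutoff))
    if not keep.any():
        raise ConfigurationError("GA cutoff removed every sample")
    return SampleTable(df[keep].reset_index(drop=True))


def demographics_table(samples: SampleTable, continuous_vars, categorical_vars,
                       groups: tuple[str, str] = (GROUP_EOS, GROUP_CONTROL)):
    """Per-variable group summaries with the matching hypothesis test.

    Continuous variables: median and mean ± sd per group, Mann-Whitney p.
    Categorical variables: count and percent per level per group, Pearson
    chi-square p (no continuity correction).  Constant categorical
    variables are skipped and logged.  Returns ``(table, log_events)``.
    """
    infants = samples.infants()
    g_a, g_b = groups
    sub = infants[infants["group"].isin(groups)]
    missing = [v for v in list(continuous_vars) + list(categorical_vars)
               if v not in sub.columns]
    if missing:
        raise ValidationError(f"variables not in sample table: {missing}")
    rows, log = [], []
    for var in continuous_vars:
        a = pd.to_numeric(sub.loc[sub["group"] == g_a, var], errors="coerce").dropna()
        b = pd.to_numeric(sub.loc[sub["group"] == g_b, var], errors="coerce").dropna()
        _, p = mann_whitney_test(a, b)
        rows.append(dict(variable=var, kind="continuous",
                         **{f"median_{g_a.lower()}": a.median(),
                            f"mean_{g_a.lower()}": a.mean(),
                            f"sd_{g_a.lower()}": a.std(),
                            f"median_{g_b.lower()}": b.median(),
                            f"mean_{g_b.lower()}": b.mean(),
                            f"sd_{g_b.lower()}": b.std()},
                         statistic=np.nan, p_value=p))
    for var in categorical_vars:
        contingency = pd.crosstab(sub[var], sub["group"])
        contingency = contingency.reindex(columns=list(groups), fill_value=0)
        if contingency.shape[0] < 2:
            log.append(f"variable {var} is constant; chi-square skipped")
            continue
        chi2, p, _, _ = stats.chi2_contingency(contingency.to_numpy(),
                                               correction=False)
        counts_a = contingency[g_a]
        counts_b = contingency[g_b]
        rows.append(dict(variable=var, kind="categorical",
                         **{f"counts_{g_a.lower()}":
                            "; ".join(f"{lvl}={c} ({100 * c / max(counts_a.sum(), 1):.1f}%)"
                                      for lvl, c in counts_a.items()),
                            f"counts_{g_b.lower()}":
                            "; ".join(f"{lvl}={c} ({100 * c / max(counts_b.sum(), 1):.1f}%)"
                                      for lvl, c in counts_b.items())},
                         statistic=chi2, p_value=p))
    return pd.DataFrame(rows), log
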