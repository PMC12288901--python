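"""Predictive modeling of EOS from biomarkers and clinical covariates.

Two model families are compared:

* Small logistic regressions (sex + gestational age + one candidate
  variable), ranked by AIC, mirroring a conventional clinical-risk
  analysis.
* A class-weighted random-forest evaluation protocol
  (:class:`RandomForestProtocol`): 10 stratified 50/50 shuffle splits,
  inner grid-search cross-validation on each training half over the fixed
  hyperparameter grid, a 10:1 EOS class weight against the heavy class
  imbalance, metrics on each held-out half with EOS as the positive
  class, and permutation variable importance (20 repetitions, accuracy
  scorer) per run.

Biomarker concentrations span orders of magnitude and enter models
log10-transformed by default.  The fitted protocol's modal hyperparameters
drive :func:`classify_presumed`, which refits on all labeled infants and
assigns each unlabeled presumed-sepsis (PS) infant a predicted group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import (
    f1_score,
    make_scorer,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler

from .datamodel import (
    GROUP_CONTROL,
    GROUP_EOS,
    GROUP_PS,
    BiomarkerTable,
    ConfigurationError,
    SampleTable,
    ValidationError,
)
from .diffabund import bh_adjust, mann_whitney_test

ALL_BIOMARKERS = ("crp", "saa", "lbp")
ALL_CLINICAL = ("gestational_age", "sex", "chorioamnionitis", "prom",
                "preeclampsia", "multiple_gestation", "delivery_route",
                "labor", "delivery_sum_score", "plasma_protein_conc")

DEFAULT_GRID = {
    "n_estimators": [50, 100],
    "criterion": ["gini", "entropy"],
    "max_depth": [4, 5, 6],
    "min_samples_leaf": [2, 3],
}

_TINY_CONC = 1e-12  # floor before log10 of an immunoassay concentration


def delivery_sum_score(delivery_route, labor) -> np.ndarray:
    """0-2 score: one point for vaginal delivery, one for labor."""
    route = np.asarray(delivery_route)
    lab = np.asarray(labor, dtype=bool)
    return (route == "vaginal").astype(int) + lab.astype(int)


@dataclass(frozen=True)
class FeatureSpec:
    """Which variables enter a model, and which infants are excluded."""

    biomarkers: tuple[str, ...] = ALL_BIOMARKERS
    clinical: tuple[str, ...] = ("gestational_age", "sex", "chorioamnionitis",
                                 "prom", "preeclampsia", "multiple_gestation",
                                 "delivery_sum_score", "plasma_protein_conc")
    log_biomarkers: bool = True
    outlier_ids_excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.biomarkers) - set(ALL_BIOMARKERS)
        if bad:
            raise ValidationError(f"unknown biomarkers: {sorted(bad)}")
        bad = set(self.clinical) - set(ALL_CLINICAL)
        if bad:
            raise ValidationError(f"unknown clinical variables: {sorted(bad)}")
        if not self.biomarkers and not self.clinical:
            raise ValidationError("feature spec selects no variables")

    def replace(self, **kwargs) -> "FeatureSpec":
        return replace(self, **kwargs)


def _encode_clinical(infants: pd.DataFrame, variables) -> pd.DataFrame:
    cols = {}
    for var in variables:
        if var == "sex":
            cols["sex_male"] = (infants["sex"] == "M").astype(int)
        elif var == "delivery_route":
            cols["delivery_vaginal"] = (infants["delivery_route"] == "vaginal").astype(int)
        elif var == "delivery_sum_score":
            cols["delivery_sum_score"] = delivery_sum_score(
                infants["delivery_route"], infants["labor"])
        elif var in ("chorioamnionitis", "prom", "preeclampsia",
                     "multiple_gestation", "labor"):
            cols[var] = infants[var].astype(int)
        else:
            cols[var] = pd.to_numeric(infants[var], errors="coerce")
    return pd.DataFrame(cols, index=infants.index)


def build_feature_frame(samples: SampleTable, biomarkers: BiomarkerTable,
                        spec: FeatureSpec) -> pd.DataFrame:
    """Design matrix indexed by infant_id, with a ``group`` column retained.

    Outlier-excluded infants are removed from the frame; unknown ids in
    the exclusion list raise.
    """
    infants = samples.infants().set_index("infant_id")
    unknown = [i for i in spec.outlier_ids_excluded if i not in infants.index]
    if unknown:
        raise ValidationError(f"unknown outlier ids: {unknown}")
    infants = infants.drop(index=list(spec.outlier_ids_excluded))
    frame = _encode_clinical(infants, spec.clinical)
    if spec.biomarkers:
        bm = biomarkers.df.set_index("infant_id")
        missing = [i for i in infants.index if i not in bm.index]
        if missing:
            raise ValidationError(
                f"infants without biomarker rows: {missing[:5]}")
        for marker in spec.biomarkers:
            conc = pd.to_numeric(bm.loc[infants.index, marker], errors="coerce")
            frame[marker] = (np.log10(conc.clip(lower=_TINY_CONC))
                             if spec.log_biomarkers else conc)
    frame["group"] = infants["group"]
    return frame


def _split_xy(frame: pd.DataFrame, groups=(GROUP_EOS, GROUP_CONTROL)):
    labeled = frame[frame["group"].isin(groups)]
    X = labeled.drop(columns="group")
    y = (labeled["group"] == GROUP_EOS).astype(int)
    return X, y


@dataclass
class LogisticResult:
    """Maximum-likelihood logistic fit with AIC and 0.5-threshold metrics."""

    feature_names: list[str]
    params: pd.Series
    llf: float
    aic: float
    n_obs: int
    converged: bool
    separation: bool
    precision: float
    recall: float
    f1: float

    def summary(self) -> str:
        lines = [f"Logistic regression (n={self.n_obs}, EOS positive)",
                 f"  log-likelihood {self.llf:.3f}   AIC "
                 + ("not comparable (separation)" if self.separation
                    else f"{self.aic:.3f}"),
                 f"  precision {self.precision:.3f}  recall {self.recall:.3f}"
                 f"  F1 {self.f1:.3f}",
                 "  coefficients:"]
        lines += [f"    {k:>24s} {v: .4f}" for k, v in self.params.items()]
        return "\n".join(lines)


def fit_logistic(features: FeatureSpec, samples: SampleTable,
                 biomarkers: BiomarkerTable) -> LogisticResult:
    """Fit EOS ~ features by maximum likelihood (EOS vs control infants).

    AIC = 2k − 2·lnL with k counting every estimated coefficient
    including the intercept.  Perfect separation is flagged and the AIC
    reported as not comparable (NaN).
    """
    frame = build_feature_frame(samples, biomarkers, features)
    X, y = _split_xy(frame)
    if y.nunique() < 2:
        raise ValidationError("outcome has a single class; cannot fit")
    design = sm.add_constant(X.astype(float), has_constant="add")
    constant = [c for c in design.columns
                if c != "const" and design[c].nunique() <= 1]
    design = design.drop(columns=constant)  # avoid singular designs
    separation = False
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # separation/convergence chatter
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
            params = res.params
            llf = float(res.llf)
            aic = float(res.aic)
            prob = np.asarray(res.predict(design))
        except Exception:  # statsmodels raises on perfect separation
            separation = True
            converged = False
            ridge = sm.Logit(y, design).fit_regularized(alpha=1e-4, disp=0)
            params = ridge.params
            llf = float(ridge.llf)
            aic = float("nan")
            prob = np.asarray(ridge.predict(design))
    coef_max = (np.abs(params.drop("const", errors="ignore")).max()
                if len(params) > 1 else 0.0)
    if not separation and (not converged or coef_max > 15):
        separation = True  # (quasi-)separation: likelihood has no interior max
        aic = float("nan")
    pred = (prob >= 0.5).astype(int)
    return LogisticResult(
        feature_names=list(X.columns), params=params, llf=llf, aic=aic,
        n_obs=len(y), converged=converged, separation=separation,
        precision=float(precision_score(y, pred, zero_division=0)),
        recall=float(recall_score(y, pred, zero_division=0)),
        f1=float(f1_score(y, pred, zero_division=0)))


def _association(a: pd.Series, b: pd.Series) -> float:
    """Pairwise association in [0, 1]: Cramér's V for binary pairs, else |r|."""
    a_bin, b_bin = a.nunique() <= 2, b.nunique() <= 2
    if a.nunique() < 2 or b.nunique() < 2:
        return 0.0
    if a_bin and b_bin:
        table = pd.crosstab(a, b).to_numpy()
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        n = table.sum()
        k = min(table.shape) - 1
        return float(np.sqrt(chi2 / (n * k))) if k else 0.0
    r = np.corrcoef(a.astype(float), b.astype(float))[0, 1]
    return float(abs(r)) if np.isfinite(r) else 0.0


def prune_correlated(features: FeatureSpec, samples: SampleTable,
                     biomarkers: BiomarkerTable,
                     assoc_threshold: float = 0.7) -> FeatureSpec:
    """Collapse clusters of associated clinical variables to one survivor.

    Variables whose pairwise association exceeds the threshold are linked;
    within each linked component the variable whose single-variable
    logistic model has the lowest AIC is kept.
    """
    if len(features.clinical) < 2:
        return features
    frame = build_feature_frame(samples, biomarkers,
                                features.replace(biomarkers=()))
    X, _ = _split_xy(frame)
    cols = list(X.columns)
    parent = {c: c for c in cols}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if _association(X[a], X[b]) > assoc_threshold:
                parent[find(a)] = find(b)
    components: dict[str, list[str]] = {}
    for c in cols:
        components.setdefault(find(c), []).append(c)
    encoded_to_var = {"sex_male": "sex", "delivery_vaginal": "delivery_route"}
    survivors = []
    for members in components.values():
        if len(members) == 1:
            survivors.append(members[0])
            continue
        best, best_aic = None, np.inf
        for m in sorted(members):
            var = encoded_to_var.get(m, m)
            res = fit_logistic(features.replace(clinical=(var,), biomarkers=()),
                               samples, biomarkers)
            aic = res.aic if np.isfinite(res.aic) else np.inf
            if aic < best_aic:
                best, best_aic = m, aic
        survivors.append(best)
    kept_vars = tuple(v for v in features.clinical
                      if {"sex": "sex_male",
                          "delivery_route": "delivery_vaginal"}.get(v, v)
                      in survivors)
    return features.replace(clinical=kept_vars)


@dataclass
class RFEvaluation:
    """Results of the random-forest evaluation protocol.

    ``runs`` has one row per shuffle split (precision, recall, roc_auc,
    f1 with EOS positive, plus the grid point selected by the inner CV);
    ``importances`` holds the per-run permutation-importance mean ± sd per
    variable.
    """

    runs: pd.DataFrame
    importances: pd.DataFrame
    feature_names: list[str]
    seed: int
    redraw_events: list[str] = field(default_factory=list)

    def mean_metrics(self) -> dict[str, float]:
        return {m: float(self.runs[m].mean())
                for m in ("precision", "recall", "roc_auc", "f1")}

    def mean_importance(self) -> pd.Series:
        return (self.importances.groupby("variable")["importance_mean"]
                .mean().sort_values(ascending=False))

    def modal_params(self) -> dict:
        keys = [c for c in self.runs.columns if c.startswith("best_")]
        tuples = [tuple(row) for row in self.runs[keys].itertuples(index=False)]
        winner = min(Counter(tuples).items(),
                     key=lambda kv: (-kv[1], repr(kv[0])))[0]
        params = dict(zip((k[len("best_"):] for k in keys), winner))
        params["n_estimators"] = int(params["n_estimators"])
        params["max_depth"] = int(params["max_depth"])
        params["min_samples_leaf"] = int(params["min_samples_leaf"])
        return params

    def summary(self) -> str:
        mm = self.mean_metrics()
        lines = [f"Random-forest protocol ({len(self.runs)} stratified "
                 f"shuffle splits, EOS positive class)",
                 "  mean  " + "  ".join(f"{k}={v:.3f}" for k, v in mm.items()),
                 f"  modal hyperparameters: {self.modal_params()}",
                 "  mean permutation importance (top 5):"]
        lines += [f"    {k:>24s} {v: .4f}"
                  for k, v in self.mean_importance().head(5).items()]
        return "\n".join(lines)


class RandomForestProtocol:
    """Class-weighted RF evaluation over repeated stratified 50/50 splits.

    Each of ``n_runs`` stratified shuffle splits tunes the hyperparameter
    grid by stratified k-fold cross-validation on the training half
    (scored by F1 with EOS positive), refits the best grid point, and
    evaluates on the held-out half.  EOS carries a ``class_weight_eos``:1
    weight.  Deterministic for a fixed seed.
    """

    def __init__(self, features: FeatureSpec, samples: SampleTable,
                 biomarkers: BiomarkerTable, n_runs: int = 10,
                 test_fraction: float = 0.5, class_weight_eos: float = 10.0,
                 grid: dict | None = None, cv_folds: int = 3,
                 n_permutation_repeats: int = 20, seed: int = 0):
        self.features = features
        self.samples = samples
        self.biomarkers = biomarkers
        self.n_runs = n_runs
        self.test_fraction = test_fraction
        self.class_weight_eos = class_weight_eos
        self.grid = dict(grid) if grid else {k: list(v)
                                             for k, v in DEFAULT_GRID.items()}
        if not self.grid:
            raise ConfigurationError("hyperparameter grid is empty")
        self.cv_folds = cv_folds
        self.n_permutation_repeats = n_permutation_repeats
        self.seed = int(seed)

    def _splits(self, X, y, redraw_log):
        sss = StratifiedShuffleSplit(n_splits=self.n_runs,
                                     test_size=self.test_fraction,
                                     random_state=self.seed)
        splits = []
        spare = StratifiedShuffleSplit(n_splits=4 * self.n_runs,
                                       test_size=self.test_fraction,
                                       random_state=self.seed + 1).split(X, y)
        for i, (train, test) in enumerate(sss.split(X, y)):
            while y.iloc[train].sum() == 0 or y.iloc[test].sum() == 0:
                redraw_log.append(f"run {i}: split lacked an EOS case; redrawn")
                train, test = next(spare)
            splits.append((train, test))
        return splits

    def fit(self) -> RFEvaluation:
        frame = build_feature_frame(self.samples, self.biomarkers, self.features)
        X, y = _split_xy(frame)
        if y.nunique() < 2:
            raise ValidationError("both classes must be present")
        seeds = [int(s % (2 ** 31))
                 for s in np.random.SeedSequence(self.seed).generate_state(
                     2 * self.n_runs, dtype=np.uint64)]
        redraw_log: list[str] = []
        run_rows, imp_rows = [], []
        for i, (train, test) in enumerate(self._splits(X, y, redraw_log)):
            rs, rs_perm = seeds[2 * i], seeds[2 * i + 1]
            base = RandomForestClassifier(
                class_weight={0: 1.0, 1: float(self.class_weight_eos)},
                random_state=rs)
            search = GridSearchCV(
                base, self.grid,
                cv=StratifiedKFold(self.cv_folds, shuffle=True, random_state=rs),
                scoring=make_scorer(f1_score, pos_label=1, zero_division=0))
            search.fit(X.iloc[train], y.iloc[train])
            best = search.best_estimator_
            proba = best.predict_proba(X.iloc[test])[:, 1]
            pred = best.predict(X.iloc[test])
            run_rows.append(dict(
                run=i,
                precision=precision_score(y.iloc[test], pred, zero_division=0),
                recall=recall_score(y.iloc[test], pred, zero_division=0),
                roc_auc=roc_auc_score(y.iloc[test], proba),
                f1=f1_score(y.iloc[test], pred, zero_division=0),
                **{f"best_{k}": v for k, v in search.best_params_.items()}))
            imp = permutation_variable_importance(
                best, X.iloc[test], y.iloc[test],
                n_repeats=self.n_permutation_repeats, seed=rs_perm)
            imp.insert(0, "run", i)
            imp_rows.append(imp)
        return RFEvaluation(runs=pd.DataFrame(run_rows),
                            importances=pd.concat(imp_rows, ignore_index=True),
                            feature_names=list(X.columns), seed=self.seed,
                            redraw_events=redraw_log)


def rf_protocol(features: FeatureSpec, samples: SampleTable,
                biomarkers: BiomarkerTable, **kwargs) -> RFEvaluation:
    """Functional wrapper around :class:`RandomForestProtocol`."""
    return RandomForestProtocol(features, samples, biomarkers, **kwargs).fit()


def permutation_variable_importance(model, X_test, y_test, n_repeats: int = 20,
                                    seed: int = 0,
                                    scoring: str = "accuracy") -> pd.DataFrame:
    """Permutation importance on held-out data.

    Importance of a variable is the baseline score minus the mean score
    over ``n_repeats`` shuffles of that variable's column; a feature that
    is constant in ``X_test`` has importance exactly 0.
    """
    res = _sk_permutation_importance(model, X_test, y_test,
                                     n_repeats=n_repeats,
                                     random_state=int(seed) % (2 ** 31),
                                     scoring=scoring)
    names = (list(X_test.columns) if hasattr(X_test, "columns")
             else [f"x{i}" for i in range(np.asarray(X_test).shape[1])])
    return pd.DataFrame({"variable": names,
                         "importance_mean": res.importances_mean,
                         "importance_std": res.importances_std})


def exclude_outliers(samples: SampleTable, outlier_ids) -> SampleTable:
    """Remove the given infants (all their runs) from the sample table."""
    ids = list(outlier_ids)
    known = set(samples.df["infant_id"])
    unknown = [i for i in ids if i not in known]
    if unknown:
        raise ValidationError(f"unknown outlier infant ids: {unknown}")
    df = samples.df[~samples.df["infant_id"].isin(ids)]
    return SampleTable(df.reset_index(drop=True))


def flag_biomarker_outliers(biomarkers: BiomarkerTable,
                            reference_group: str = GROUP_CONTROL,
                            target_group: str = GROUP_EOS,
                            quantile: float = 0.975,
                            log_scale: bool = True):
    """Advisory flagging of target-group infants with reference-like markers.

    An infant is flagged when its (log10) biomarker vector falls inside
    the reference group's Mahalanobis ellipsoid at the given chi-square
    quantile.  A singular reference covariance falls back to a per-marker
    quantile box.  Returns ``(flagged_ids, log_events)``; exclusion always
    requires explicit ids downstream.
    """
    markers = list(ALL_BIOMARKERS)
    ref = biomarkers.for_group(reference_group)[markers].dropna()
    if len(ref) < 3:
        raise ValidationError("need at least 3 reference infants")
    target = biomarkers.for_group(target_group).set_index("infant_id")[markers].dropna()
    if log_scale:
        ref = np.log10(ref.clip(lower=_TINY_CONC))
        target = np.log10(target.clip(lower=_TINY_CONC))
    log: list[str] = []
    center = ref.mean().to_numpy()
    cov = np.cov(ref.to_numpy(), rowvar=False)
    try:
        inv = np.linalg.inv(cov)
        if not np.all(np.isfinite(inv)):
            raise np.linalg.LinAlgError("non-finite inverse")
        delta = target.to_numpy() - center
        d2 = np.einsum("ij,jk,ik->i", delta, inv, delta)
        cut = stats.chi2.ppf(quantile, df=len(markers))
        flagged = target.index[d2 <= cut]
    except np.linalg.LinAlgError:
        log.append("singular reference covariance; per-marker quantile fallback")
        lo = ref.quantile(1 - quantile)
        hi = ref.quantile(quantile)
        inside = ((target >= lo) & (target <= hi)).all(axis=1)
        flagged = target.index[inside]
    return sorted(flagged), log


def pca_embed(X, n_components: int = 2, standardize: bool = False):
    """Principal-component scores and explained-variance fractions.

    ``X`` must be complete (no missing entries) with >= 2 rows and
    columns; callers impute or drop first.
    """
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("PCA needs a 2-D matrix with >= 2 rows and columns")
    if np.isnan(arr).any():
        raise ValidationError("PCA input has missing entries; impute or drop first")
    if standardize:
        arr = StandardScaler().fit_transform(arr)
    k = min(n_components, arr.shape[1], arr.shape[0])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(arr)
    return scores, pca.explained_variance_ratio_


@dataclass
class PresumedSepsisResult:
    """Predicted labels for the unlabeled presumed-sepsis cohort."""

    predictions: pd.DataFrame        # infant_id, p_eos, predicted_group
    n_predicted_eos: int
    n_ps: int
    comparison: pd.DataFrame         # per-marker MW + BH between predicted groups
    pca_scores: pd.DataFrame         # PC1/PC2 + display label per infant
    explained_variance: np.ndarray
    hyperparameters: dict

    @property
    def fraction_predicted_eos(self) -> float:
        return self.n_predicted_eos / self.n_ps if self.n_ps else float("nan")

    def summary(self) -> str:
        return (f"Presumed-sepsis classification: {self.n_predicted_eos} of "
                f"{self.n_ps} infants predicted EOS "
                f"({100 * self.fraction_predicted_eos:.1f}%), "
                f"{self.n_ps - self.n_predicted_eos} predicted control")


def classify_presumed(samples: SampleTable, biomarkers: BiomarkerTable,
                      features: FeatureSpec, hyperparameters: dict,
                      threshold: float = 0.5, class_weight_eos: float = 10.0,
                      seed: int = 0) -> PresumedSepsisResult:
    """Label the PS cohort with a final model fit on all labeled infants.

    The classifier is a random forest with the protocol-selected
    hyperparameters and the 10:1 EOS class weight, fit on every labeled
    EOS/control infant (outliers excluded via ``features``).  A PS infant
    is predicted EOS iff its predicted probability is >= ``threshold``
    (ties classify toward sepsis).  Also emits per-marker Mann-Whitney +
    BH comparisons between the predicted groups and a PCA overlay of the
    log10 biomarker space.
    """
    frame = build_feature_frame(samples, biomarkers, features)
    X, y = _split_xy(frame)
    ps_frame = frame[frame["group"] == GROUP_PS]
    if ps_frame.empty:
        raise ConfigurationError("no PS infants to classify")
    X_ps = ps_frame.drop(columns="group")
    if list(X_ps.columns) != list(X.columns):
        raise ValidationError("feature mismatch between labeled and PS cohorts")
    clf = RandomForestClassifier(
        **hyperparameters, class_weight={0: 1.0, 1: float(class_weight_eos)},
        random_state=int(seed) % (2 ** 31))
    clf.fit(X, y)
    p_eos = clf.predict_proba(X_ps)[:, 1]
    predicted = np.where(p_eos >= threshold, GROUP_EOS, GROUP_CONTROL)
    predictions = pd.DataFrame({"infant_id": X_ps.index, "p_eos": p_eos,
                                "predicted_group": predicted})

    # biomarker comparison between the predicted groups
    bm = biomarkers.for_group(GROUP_PS).set_index("infant_id")
    rows = []
    pred_of = predictions.set_index("infant_id")["predicted_group"]
    for marker in ALL_BIOMARKERS:
        a = bm.loc[pred_of[pred_of == GROUP_EOS].index, marker].dropna()
        b = bm.loc[pred_of[pred_of == GROUP_CONTROL].index, marker].dropna()
        if len(a) and len(b):
            u, p = mann_whitney_test(a, b)
        else:
            u, p = np.nan, np.nan
        rows.append(dict(marker=marker, median_pred_eos=a.median(),
                         median_pred_control=b.median(), U=u, p_raw=p))
    comparison = pd.DataFrame(rows)
    tested = comparison["p_raw"].notna()
    comparison["q_bh"] = np.nan
    if tested.any():
        comparison.loc[tested, "q_bh"] = bh_adjust(comparison.loc[tested, "p_raw"])

    # PCA overlay of labeled + PS infants in log10 biomarker space
    all_bm = biomarkers.df.set_index("infant_id")
    ids = [i for i in list(X.index) + list(X_ps.index) if i in all_bm.index]
    space = np.log10(all_bm.loc[ids, list(ALL_BIOMARKERS)].clip(lower=_TINY_CONC))
    scores, evr = pca_embed(space.to_numpy(), n_components=2, standardize=True)
    labels = []
    for i in ids:
        g = all_bm.loc[i, "group"]
        if g == GROUP_PS:
            labels.append("PS-pEOS" if pred_of[i] == GROUP_EOS else "PS-pControl")
        else:
            labels.append(g)
    pca_scores = pd.DataFrame({"infant_id": ids, "PC1": scores[:, 0],
                               "PC2": scores[:, 1], "label": labels})
    return PresumedSepsisResult(
        predictions=predictions,
        n_predicted_eos=int((predicted == GROUP_EOS).sum()),
        n_ps=len(predictions), comparison=comparison, pca_scores=pca_scores,
        explained_variance=evr, hyperparameters=dict(hyperparameters))


def logistic_comparison(samples: SampleTable, biomarkers: BiomarkerTable,
                        outlier_ids=(), log_biomarkers: bool = True,
                        assoc_threshold: float = 0.7) -> pd.DataFrame:
    """AIC league table of small logistic models (sex + GA + one variable).

    Adds multivariate rows: the pruned clinical set alone, with SAA, and
    with all three biomarkers.
    """
    base = ("sex", "gestational_age")
    excl = tuple(outlier_ids)
    rows = []

    def record(label, spec):
        res = fit_logistic(spec, samples, biomarkers)
        rows.append(dict(model=label, n_features=len(res.feature_names),
                         aic=res.aic, log_likelihood=res.llf,
                         precision=res.precision, recall=res.recall,
                         f1=res.f1, separation=res.separation))

    record("base (sex + GA)", FeatureSpec(biomarkers=(), clinical=base,
                                          outlier_ids_excluded=excl))
    for marker in ALL_BIOMARKERS:
        record(f"base + {marker}",
               FeatureSpec(biomarkers=(marker,), clinical=base,
                           log_biomarkers=log_biomarkers,
                           outlier_ids_excluded=excl))
    for var in ("chorioamnionitis", "prom", "preeclampsia", "multiple_gestation",
                "delivery_route", "labor", "delivery_sum_score",
                "plasma_protein_conc"):
        record(f"base + {var}",
               FeatureSpec(biomarkers=(), clinical=base + (var,),
                           outlier_ids_excluded=excl))
    full = FeatureSpec(biomarkers=(), clinical=tuple(
        v for v in ALL_CLINICAL if v not in ("delivery_route", "labor")),
        outlier_ids_excluded=excl)
    pruned = prune_correlated(full, samples, biomarkers, assoc_threshold)
    record("multivariate clinical (pruned)", pruned)
    record("multivariate clinical + saa",
           pruned.replace(biomarkers=("saa",), log_biomarkers=log_biomarkers))
    record("multivariate clinical + all biomarkers",
           pruned.replace(biomarkers=ALL_BIOMARKERS,
                          log_biomarkers=log_biomarkers))
    return pd.DataFrame(rows)
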