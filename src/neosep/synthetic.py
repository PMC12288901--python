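"""Synthetic cord-blood cohort generator.

Emulates the post-MaxQuant structure of the study data so every downstream
stage is testable without the deposited raw files: ~437 protein groups
quantified across 14 EOS and 150 control specimens run in technical
duplicate over 4 MS batches with pooled-control anchor runs, plus a
presumed-sepsis (PS) cohort that is a latent mixture of EOS-like and
control-like infants.

The generative model, on the log2 LFQ scale:

``value(p, specimen, run) = mu_p + spike_p·[EOS-like] + shift_batch
                            + specimen_effect(p) + replicate_noise``

* ``mu_p ~ Normal(25, 3)`` for background proteins; spiked
  differential-abundance proteins (acute-phase reactant analogs) are drawn
  from the abundant end, ``Normal(28, 1)``; rare presence/absence proteins
  from the faint end, ``Normal(21, 1)``.
* ``specimen_effect ~ Normal(0, 0.7)`` per (protein, specimen);
  ``replicate_noise ~ Normal(0, 0.2)`` per run — technical duplicates share
  the specimen effect.
* ``shift_batch ~ Normal(0, batch_shift_sd)`` applied to every run of a
  batch, pooled controls included.  Pooled-control runs are the same
  physical pool in every batch: ``mu_p + shift_batch + replicate_noise``.

Missingness is missing-not-at-random: each non-rare cell is dropped
independently with probability ``logistic((midpoint − value) · slope)``,
the standard abundance-dependent dropout model for LFQ proteomics.  Rare
presence/absence proteins instead toggle per specimen with a per-group
Bernoulli detection probability.

Biomarker immunoassay concentrations (CRP, SAA, LBP; mg/mL) are log-normal
per group.  PS infants draw biomarkers (and non-matched clinical
covariates) from the EOS or control distribution according to their latent
label; gestational age, sex and delivery route are EOS-like for every PS
infant, mirroring the frequency matching of the PS cohort to the EOS
cohort on those variables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .datamodel import (
    GROUP_CONTROL,
    GROUP_EOS,
    GROUP_POOLED,
    GROUP_PS,
    SCALE_LOG2,
    SCALE_RAW,
    BiomarkerTable,
    ProteinAbundanceMatrix,
    SampleTable,
    ValidationError,
)

# Spiked differential-abundance proteins are named after the acute-phase
# reactants they emulate when the default count of 5 is used.
_SPIKED_NAMES = ("CRP", "LBP", "SAA1", "LRG1", "SERPINA3")
_RARE_NAMES = ("SAA2", "HP", "LCN2")

# Per-group clinical covariate rates.  EOS/control rates follow the cohort
# demographics table; PS is clinically EOS-like (the cohort was frequency
# matched to EOS on GA, sex and delivery route).
DEFAULT_CLINICAL_RATES: dict[str, dict[str, float]] = {
    GROUP_EOS: dict(female=0.36, chorioamnionitis=0.43, prom=0.64,
                    preeclampsia=0.07, multiple_gestation=0.14,
                    vaginal_delivery=0.71, labor_given_cesarean=0.5,
                    plasma_protein_mean=45.0, plasma_protein_sd=6.0,
                    ga_mean=30.7, ga_sd=3.3, ga_min=23.0, ga_max=36.9),
    GROUP_CONTROL: dict(female=0.49, chorioamnionitis=0.007, prom=0.113,
                        preeclampsia=0.10, multiple_gestation=0.10,
                        vaginal_delivery=0.51, labor_given_cesarean=0.3,
                        plasma_protein_mean=48.0, plasma_protein_sd=6.0,
                        ga_mean=33.6, ga_sd=4.5, ga_min=23.0, ga_max=41.9),
    GROUP_PS: dict(female=0.36, chorioamnionitis=0.43, prom=0.64,
                   preeclampsia=0.07, multiple_gestation=0.14,
                   vaginal_delivery=0.71, labor_given_cesarean=0.5,
                   plasma_protein_mean=46.0, plasma_protein_sd=6.0,
                   ga_mean=31.3, ga_sd=3.4, ga_min=23.0, ga_max=36.9),
}

# log10 mg/mL (mean, sd) per marker per group.  SAA separates most, CRP
# least (its distributions overlap more), matching the relative behaviour
# of the three immunoassay markers.
DEFAULT_BIOMARKER_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "crp": {GROUP_EOS: (-1.9, 0.50), GROUP_CONTROL: (-3.0, 0.45)},
    "saa": {GROUP_EOS: (-0.9, 0.50), GROUP_CONTROL: (-2.7, 0.40)},
    "lbp": {GROUP_EOS: (-1.2, 0.45), GROUP_CONTROL: (-2.3, 0.40)},
}

GA_EPOCHS = (25.0, 29.0, 33.0, 37.0)  # epoch edges: 25-28, 29-32, 33-36, 37+


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_eos: int = 14
    n_control: int = 150
    n_ps: int = 56
    n_proteins: int = 437
    n_batches: int = 4
    n_tech_reps: int = 2
    n_pooled_per_batch: int = 1
    spiked_da_proteins: int = 5
    da_log2_effect: float = 2.0
    rare_presence_proteins: int = 3
    rare_detect_prob_eos: float = 0.7
    rare_detect_prob_control: float = 0.05
    batch_shift_sd: float = 0.5
    mnar_midpoint: float = 26.5
    mnar_slope: float = 1.0
    ps_mixture_fraction: float = 0.25
    n_outlier_eos: int = 0  # planted control-like "late positivity" EOS infants
    base_mean: float = 25.0
    base_sd: float = 3.0
    spiked_base_mean: float = 28.0
    spiked_base_sd: float = 1.0
    rare_base_mean: float = 21.0
    rare_base_sd: float = 1.0
    sample_noise_sd: float = 0.7
    replicate_noise_sd: float = 0.2
    biomarker_lognormal_params: dict = field(
        default_factory=lambda: {m: dict(g) for m, g in DEFAULT_BIOMARKER_PARAMS.items()})
    clinical_covariate_rates: dict = field(
        default_factory=lambda: {g: dict(r) for g, r in DEFAULT_CLINICAL_RATES.items()})
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_eos=self.n_eos, n_control=self.n_control, n_ps=self.n_ps,
                      n_proteins=self.n_proteins, n_batches=self.n_batches,
                      n_tech_reps=self.n_tech_reps,
                      n_pooled_per_batch=self.n_pooled_per_batch)
        for name, value in counts.items():
            if value < 1:
                raise ValidationError(f"{name} must be >= 1 (got {value})")
        if self.spiked_da_proteins < 0 or self.rare_presence_proteins < 0:
            raise ValidationError("spiked/rare protein counts must be >= 0")
        if self.spiked_da_proteins + self.rare_presence_proteins > self.n_proteins:
            raise ValidationError("spiked + rare proteins exceed n_proteins")
        for name in ("rare_detect_prob_eos", "rare_detect_prob_control",
                     "ps_mixture_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1] (got {p})")
        if self.mnar_slope < 0:
            raise ValidationError("mnar_slope must be >= 0")
        if self.n_outlier_eos < 0 or self.n_outlier_eos > self.n_eos:
            raise ValidationError("n_outlier_eos must be in [0, n_eos]")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Cohort truth record for test oracles (never consumed by the pipeline)."""

    spiked_proteins: dict[str, float]          # id -> true log2 effect
    rare_proteins: dict[str, dict[str, float]]  # id -> per-group detection prob
    batch_shifts: dict[int, float]             # batch -> true additive log2 shift
    ps_true_eos: dict[str, bool]               # PS infant id -> EOS-like latent label
    outlier_infants: list[str]                 # planted control-like EOS infants
    biomarker_log10_means: dict[str, dict[str, float]]
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        d["batch_shifts"] = {int(k): v for k, v in d["batch_shifts"].items()}
        return cls(**d)


def apply_mnar_missingness(matrix: ProteinAbundanceMatrix, mnar_midpoint: float,
                           mnar_slope: float, seed: int,
                           exclude_proteins=()) -> ProteinAbundanceMatrix:
    """Abundance-dependent (MNAR) dropout on a log2-scale matrix.

    Each cell is dropped independently with probability
    ``logistic((midpoint − value) · slope)``; low-abundance values are
    preferentially lost.  ``exclude_proteins`` (e.g. rare presence/absence
    proteins handled by a Bernoulli mechanism) are left untouched.
    """
    if mnar_slope < 0:
        raise ValidationError("mnar_slope must be >= 0")
    if matrix.scale_tag != SCALE_LOG2:
        raise ValidationError("MNAR dropout expects a log2-scale matrix")
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    arr = values.to_numpy()
    p_drop = expit((mnar_midpoint - arr) * mnar_slope)
    drop = rng.random(arr.shape) < p_drop
    if len(exclude_proteins):
        keep_rows = values.index.isin(list(exclude_proteins))
        drop[keep_rows, :] = False
    arr[drop] = np.nan
    return ProteinAbundanceMatrix(pd.DataFrame(arr, index=values.index,
                                               columns=values.columns),
                                  scale_tag=SCALE_LOG2,
                                  protein_groups=matrix.protein_groups)


def _truncated_normal(rng, mean, sd, low, high, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = (out <= low) | (out >= high)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, low + 1e-6, high - 1e-6)


def _draw_infants(rng, ids, rates, eos_like: np.ndarray | None = None,
                  clinical_rates_by_latent=None) -> pd.DataFrame:
    """Draw per-infant covariates.

    ``rates`` supplies the matched variables (GA, sex, delivery route) for
    the whole group; when ``eos_like``/``clinical_rates_by_latent`` are
    given, the remaining covariates follow the latent class instead (PS
    cohort).
    """
    n = len(ids)
    ga = _truncated_normal(rng, rates["ga_mean"], rates["ga_sd"],
                           rates["ga_min"], rates["ga_max"], n)
    female = rng.random(n) < rates["female"]
    vaginal = rng.random(n) < rates["vaginal_delivery"]
    if eos_like is None:
        row_rates = [rates] * n
    else:
        row_rates = [clinical_rates_by_latent[GROUP_EOS if e else GROUP_CONTROL]
                     for e in eos_like]
    chorio = np.array([rng.random() < r["chorioamnionitis"] for r in row_rates])
    prom = np.array([rng.random() < r["prom"] for r in row_rates])
    preec = np.array([rng.random() < r["preeclampsia"] for r in row_rates])
    multi = np.array([rng.random() < r["multiple_gestation"] for r in row_rates])
    labor = vaginal | np.array(
        [rng.random() < r["labor_given_cesarean"] for r in row_rates])
    plasma = np.array([max(20.0, rng.normal(r["plasma_protein_mean"],
                                            r["plasma_protein_sd"]))
                       for r in row_rates])
    return pd.DataFrame({
        "infant_id": ids,
        "gestational_age": np.round(ga, 2),
        "sex": np.where(female, "F", "M"),
        "chorioamnionitis": chorio, "prom": prom, "preeclampsia": preec,
        "multiple_gestation": multi,
        "delivery_route": np.where(vaginal, "vaginal", "cesarean"),
        "labor": labor,
        "plasma_protein_conc": np.round(plasma, 1),
    })


def _assign_batches(rng, infants: pd.DataFrame, n_batches: int) -> np.ndarray:
    """Stratified randomization of specimens to batches on (group, sex, GA epoch)."""
    epoch = np.digitize(infants["gestational_age"], GA_EPOCHS)
    strata = list(zip(infants["group"], infants["sex"], epoch))
    order = np.lexsort((infants["infant_id"], [str(s) for s in strata]))
    batches = np.empty(len(infants), dtype=int)
    start = rng.integers(n_batches)
    for rank, idx in enumerate(order):
        batches[idx] = (start + rank) % n_batches + 1
    return batches


def generate_cohort(config: SyntheticConfig):
    """Generate (matrix, samples, biomarkers, truth) for one synthetic cohort.

    The matrix is emitted on the raw-intensity scale (``2**log2`` values,
    MaxQuant-style) so the full preprocessing chain is exercised; the PS
    cohort appears in the sample and biomarker tables but not in the LFQ
    matrix, matching the study layout.  Bit-identical for a fixed seed.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rates = cfg.clinical_covariate_rates

    # -- protein panel ---------------------------------------------------
    if cfg.spiked_da_proteins == len(_SPIKED_NAMES):
        spiked_ids = list(_SPIKED_NAMES)
    else:
        spiked_ids = [f"SPIKE{i + 1:02d}" for i in range(cfg.spiked_da_proteins)]
    if cfg.rare_presence_proteins == len(_RARE_NAMES):
        rare_ids = list(_RARE_NAMES)
    else:
        rare_ids = [f"RARE{i + 1:02d}" for i in range(cfg.rare_presence_proteins)]
    n_bg = cfg.n_proteins - len(spiked_ids) - len(rare_ids)
    bg_ids = [f"BG{i + 1:04d}" for i in range(n_bg)]
    protein_ids = spiked_ids + rare_ids + bg_ids

    mu = np.concatenate([
        rng.normal(cfg.spiked_base_mean, cfg.spiked_base_sd, len(spiked_ids)),
        rng.normal(cfg.rare_base_mean, cfg.rare_base_sd, len(rare_ids)),
        rng.normal(cfg.base_mean, cfg.base_sd, n_bg),
    ])
    spiked_rows = np.arange(len(spiked_ids))
    rare_rows = np.arange(len(spiked_ids), len(spiked_ids) + len(rare_ids))

    # -- infants ---------------------------------------------------------
    eos_ids = [f"EOS{i + 1:03d}" for i in range(cfg.n_eos)]
    ctl_ids = [f"C{i + 1:03d}" for i in range(cfg.n_control)]
    ps_ids = [f"PS{i + 1:03d}" for i in range(cfg.n_ps)]
    ps_true = rng.random(cfg.n_ps) < cfg.ps_mixture_fraction
    outliers = sorted(rng.choice(eos_ids, size=cfg.n_outlier_eos, replace=False)
                      ) if cfg.n_outlier_eos else []

    eos_df = _draw_infants(rng, eos_ids, rates[GROUP_EOS])
    eos_df["group"] = GROUP_EOS
    ctl_df = _draw_infants(rng, ctl_ids, rates[GROUP_CONTROL])
    ctl_df["group"] = GROUP_CONTROL
    ps_df = _draw_infants(rng, ps_ids, rates[GROUP_PS], eos_like=ps_true,
                          clinical_rates_by_latent=rates)
    ps_df["group"] = GROUP_PS
    infants = pd.concat([eos_df, ctl_df, ps_df], ignore_index=True)
    infants["outlier_flag"] = infants["infant_id"].isin(outliers)

    # -- batch layout (proteomics cohort = EOS + control) ----------------
    prot_infants = infants[infants["group"].isin([GROUP_EOS, GROUP_CONTROL])]
    prot_infants = prot_infants.reset_index(drop=True)
    batch = _assign_batches(rng, prot_infants, cfg.n_batches)
    shifts = rng.normal(0.0, cfg.batch_shift_sd, cfg.n_batches)

    # -- log2 abundance grid --------------------------------------------
    n_spec = len(prot_infants)
    spec_eff = rng.normal(0.0, cfg.sample_noise_sd, (cfg.n_proteins, n_spec))
    is_eos_like = (prot_infants["group"].to_numpy() == GROUP_EOS) & \
        ~prot_infants["infant_id"].isin(outliers).to_numpy()
    spike = np.zeros((cfg.n_proteins, n_spec))
    spike[np.ix_(spiked_rows, np.where(is_eos_like)[0])] = cfg.da_log2_effect
    base = mu[:, None] + spec_eff + spike + shifts[batch - 1][None, :]

    run_cols, run_rows, run_values = [], [], []
    for k in range(cfg.n_tech_reps):
        vals = base + rng.normal(0.0, cfg.replicate_noise_sd,
                                 (cfg.n_proteins, n_spec))
        for j, infant in enumerate(prot_infants.itertuples()):
            run_cols.append(f"{infant.infant_id}_r{k + 1}")
            row = infant._asdict()
            row.update(sample_id=run_cols[-1], batch=int(batch[j]),
                       replicate_id=k + 1)
            run_rows.append(row)
            run_values.append(vals[:, j])

    # pooled-control runs: same physical pool in every batch
    for b in range(1, cfg.n_batches + 1):
        for p in range(cfg.n_pooled_per_batch):
            for k in range(cfg.n_tech_reps):
                sid = f"POOL_b{b}_p{p + 1}_r{k + 1}"
                run_cols.append(sid)
                run_rows.append(dict(sample_id=sid, infant_id="POOLED",
                                     group=GROUP_POOLED, batch=b,
                                     replicate_id=k + 1, gestational_age=np.nan,
                                     sex="", chorioamnionitis=False, prom=False,
                                     preeclampsia=False, multiple_gestation=False,
                                     delivery_route="", labor=False,
                                     plasma_protein_conc=np.nan,
                                     outlier_flag=False))
                run_values.append(mu + shifts[b - 1]
                                  + rng.normal(0.0, cfg.replicate_noise_sd,
                                               cfg.n_proteins))

    log2_values = pd.DataFrame(np.column_stack(run_values),
                               index=protein_ids, columns=run_cols)

    # -- rare presence/absence proteins ---------------------------------
    rare_probs = {GROUP_EOS: cfg.rare_detect_prob_eos,
                  GROUP_CONTROL: cfg.rare_detect_prob_control,
                  GROUP_POOLED: cfg.rare_detect_prob_control}
    run_meta = pd.DataFrame(run_rows)
    specimen_of = run_meta.groupby("infant_id", sort=False).first()
    for r, rid in zip(rare_rows, rare_ids):
        for infant_id, meta in specimen_of.iterrows():
            present = rng.random() < rare_probs[meta["group"]]
            if not present:
                cols = run_meta.loc[run_meta["infant_id"] == infant_id, "sample_id"]
                log2_values.loc[rid, cols] = np.nan

    matrix = ProteinAbundanceMatrix(log2_values, scale_tag=SCALE_LOG2)
    mnar_seed = int(rng.integers(2 ** 31))
    matrix = apply_mnar_missingness(matrix, cfg.mnar_midpoint, cfg.mnar_slope,
                                    seed=mnar_seed, exclude_proteins=rare_ids)
    raw = ProteinAbundanceMatrix(np.exp2(matrix.values), scale_tag=SCALE_RAW)

    # -- sample table ----------------------------------------------------
    ps_runs = []
    for infant in ps_df.itertuples():
        row = infants.loc[infants["infant_id"] == infant.infant_id].iloc[0].to_dict()
        row.update(sample_id=infant.infant_id, batch=1, replicate_id=1)
        ps_runs.append(row)
    sample_df = pd.concat([run_meta, pd.DataFrame(ps_runs)], ignore_index=True)
    sample_df.loc[sample_df["group"] == GROUP_POOLED,
                  ["sex", "delivery_route"]] = np.nan
    samples = SampleTable(sample_df[list(
        ("sample_id", "infant_id", "group", "batch", "replicate_id",
         "gestational_age", "sex", "chorioamnionitis", "prom", "preeclampsia",
         "multiple_gestation", "delivery_route", "labor",
         "plasma_protein_conc", "outlier_flag"))])

    # -- biomarkers ------------------------------------------------------
    bm_params = cfg.biomarker_lognormal_params
    rows = []
    latent = dict(zip(ps_ids, ps_true))
    for infant in infants.itertuples():
        group = infant.group
        if group == GROUP_PS:
            dist_group = GROUP_EOS if latent[infant.infant_id] else GROUP_CONTROL
        else:
            dist_group = group
        row = {"infant_id": infant.infant_id, "group": group}
        for marker in ("crp", "saa", "lbp"):
            m, s = bm_params[marker][dist_group]
            if infant.infant_id in outliers:  # control-like late-positivity case
                m, s = bm_params[marker][GROUP_CONTROL]
                s *= 0.5
            row[marker] = float(10.0 ** rng.normal(m, s))
        rows.append(row)
    biomarkers = BiomarkerTable(pd.DataFrame(rows))

    truth = GroundTruth(
        spiked_proteins={pid: cfg.da_log2_effect for pid in spiked_ids},
        rare_proteins={pid: {GROUP_EOS: cfg.rare_detect_prob_eos,
                             GROUP_CONTROL: cfg.rare_detect_prob_control}
                       for pid in rare_ids},
        batch_shifts={b + 1: float(shifts[b]) for b in range(cfg.n_batches)},
        ps_true_eos={pid: bool(t) for pid, t in zip(ps_ids, ps_true)},
        outlier_infants=list(outliers),
        biomarker_log10_means={m: {g: p[0] for g, p in d.items()}
                               for m, d in bm_params.items()},
        seed=cfg.seed,
    )
    return raw, samples, biomarkers, truth
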