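import numpy as np
import pandas as pd
import pytest

from neosep import (
    SyntheticConfig,
    average_technical_replicates,
    batch_normalize,
    detection_filter,
    exclude_single_batch_proteins,
    generate_cohort,
    log2_transform,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across read-only tests."""
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, reduced cohort for smoke tests of heavier stages."""
    cfg = SyntheticConfig(n_eos=8, n_control=30, n_ps=12, n_proteins=40, seed=5)
    return generate_cohort(cfg)


def preprocess_chain(matrix, samples, detect_threshold=0.20):
    """Raw matrix → (detection partition, specimen-level samples)."""
    log2 = log2_transform(matrix)
    filtered, _ = exclude_single_batch_proteins(log2, samples)
    normalized, _ = batch_normalize(filtered, samples)
    spec_matrix, spec_samples = average_technical_replicates(normalized, samples)
    return detection_filter(spec_matrix, threshold=detect_threshold), spec_samples


@pytest.fixture(scope="session")
def preprocessed_default(default_cohort):
    matrix, samples, _, _ = default_cohort
    return preprocess_chain(matrix, samples)


def tiny_sample_df(rows):
    """Build a sample-table DataFrame from compact per-row dicts."""
    defaults = dict(group="control", batch=1, replicate_id=1,
                    gestational_age=33.0, sex="F", chorioamnionitis=False,
                    prom=False, preeclampsia=False, multiple_gestation=False,
                    delivery_route="vaginal", labor=True,
                    plasma_protein_conc=48.0, outlier_flag=False)
    out = []
    for row in rows:
        r = dict(defaults, **row)
        r.setdefault("infant_id", r["sample_id"])
        out.append(r)
    return pd.DataFrame(out)


def matrix_df(values, proteins=None, samples=None):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=proteins, columns=samples)
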