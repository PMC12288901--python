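import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neosep import (
    ConfigurationError,
    ProteinAbundanceMatrix,
    SampleTable,
    SyntheticConfig,
    ValidationError,
    bh_adjust,
    demographics_table,
    differential_abundance,
    generate_cohort,
    log2_transform,
    mann_whitney_test,
    presence_absence,
    sensitivity_subset,
)

from conftest import matrix_df, preprocess_chain, tiny_sample_df


def exact_mw_oracle(x, y):
    """Enumerate every relabeling of the pooled values (tie-free inputs).

    Independent check of the exact two-sided p: 2 * min(tail probs of the
    observed U over all C(n_x+n_y, n_x) group assignments), capped at 1.
    """
    pooled = list(x) + list(y)
    n_x = len(x)

    def u_stat(xs, ys):
        return sum(1.0 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    us = []
    for ix in itertools.combinations(range(len(pooled)), n_x):
        chosen = set(ix)
        xs = [pooled[i] for i in ix]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    lower = np.mean(us <= u_obs)
    upper = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(lower, upper))


def bh_oracle(p):
    """Brute-force q_(i) = min_{j >= i} m * p_(j) / j on the sorted vector."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = [min(min(1.0, m * p[order[j]] / (j + 1)) for j in range(i, m))
                for i in range(m)]
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        u, p = mann_whitney_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_interleaved_groups_clip_to_one(self):
        u, p = mann_whitney_test([1, 4], [2, 3])
        assert u == 2.0
        assert p == 1.0

    def test_all_tied_values_give_p_one(self):
        u, p = mann_whitney_test([5.0] * 30, [5.0] * 40)
        assert p == 1.0
        assert u == 30 * 40 / 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_test([], [1.0])

    def test_large_sample_null_type_i_error(self):
        # identical distributions: rejections at 0.05 stay near nominal
        rng = np.random.default_rng(7)
        rejections = sum(
            mann_whitney_test(rng.normal(size=40), rng.normal(size=40))[1] < 0.05
            for _ in range(1000))
        assert rejections <= 60  # >=94% non-significant

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.data())
    def test_exact_path_matches_enumeration_oracle(self, data):
        n_x = data.draw(st.integers(1, 5))
        n_y = data.draw(st.integers(1, 10 - n_x))
        values = data.draw(st.lists(
            st.floats(-100, 100, allow_nan=False),
            min_size=n_x + n_y, max_size=n_x + n_y, unique=True))
        x, y = values[:n_x], values[n_x:]
        u, p = mann_whitney_test(x, y)
        u_ref, p_ref = exact_mw_oracle(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_u_statistics_sum_to_nx_ny(self, data):
        n_x = data.draw(st.integers(1, 12))
        n_y = data.draw(st.integers(1, 12))
        values = data.draw(st.lists(
            st.floats(-100, 100, allow_nan=False),
            min_size=n_x + n_y, max_size=n_x + n_y, unique=True))
        u_x, _ = mann_whitney_test(values[:n_x], values[n_x:])
        u_y, _ = mann_whitney_test(values[n_x:], values[:n_x])
        assert u_x + u_y == pytest.approx(n_x * n_y)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.5]),
                                   [0.04, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 7), [0.2] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 0.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0, allow_nan=False), min_size=1,
                    max_size=50))
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0, allow_nan=False), min_size=1,
                    max_size=50))
    def test_q_never_below_p(self, p):
        assert (bh_adjust(p) >= np.asarray(p) - 1e-15).all()


class TestDifferentialAbundance:
    def test_recovers_spiked_proteins(self, preprocessed_default, default_cohort):
        partition, spec_samples = preprocessed_default
        truth = default_cohort[3]
        table = differential_abundance(partition.kept, spec_samples)
        hits = set(table.index[table["significant"]])
        assert set(truth.spiked_proteins) <= hits
        assert len(hits - set(truth.spiked_proteins)) <= 1
        # result-table invariants
        tested = table["p_raw"].notna()
        assert (table.loc[tested, "q_bh"] >= table.loc[tested, "p_raw"] - 1e-15).all()
        assert (table.loc[tested, "U"]
                <= table.loc[tested, "n_eos"] * table.loc[tested, "n_control"]).all()

    def test_alpha_zero_yields_nothing(self, preprocessed_default):
        partition, spec_samples = preprocessed_default
        table = differential_abundance(partition.kept, spec_samples, alpha=0.0)
        assert not table["significant"].any()

    def test_absent_group_is_config_error(self, preprocessed_default):
        partition, spec_samples = preprocessed_default
        controls_only = SampleTable(
            spec_samples.df[spec_samples.df.group == "control"].reset_index(drop=True))
        sub = partition.kept.subset_samples(list(controls_only.df["sample_id"]))
        with pytest.raises(ConfigurationError):
            differential_abundance(sub, controls_only)


class TestPresenceAbsence:
    def test_detection_fractions_and_enrichment(self):
        eos_cols = [f"E{i}" for i in range(14)]
        ctl_cols = [f"C{i}" for i in range(20)]
        row = [20.0] * 10 + [np.nan] * 4 + [20.0] * 1 + [np.nan] * 19
        never = [np.nan] * 34
        m = ProteinAbundanceMatrix(matrix_df([row, never],
                                             samples=eos_cols + ctl_cols),
                                   scale_tag="log2")
        samples = SampleTable(tiny_sample_df(
            [dict(sample_id=s, group="EOS", gestational_age=30.0) for s in eos_cols]
            + [dict(sample_id=s) for s in ctl_cols]))
        table = presence_absence(m, samples)
        assert table.loc["P1", "detect_frac_eos"] == pytest.approx(10 / 14)
        assert table.loc["P1", "enriched_in"] == "EOS"
        assert table.loc["P2", "detect_frac_eos"] == 0.0
        assert table.loc["P2", "enriched_in"] == "neither"

    def test_rare_proteins_flagged_across_seeds(self):
        cfg = SyntheticConfig(n_eos=14, n_control=100, n_ps=2, n_proteins=60,
                              spiked_da_proteins=0)
        flagged = 0
        n_seeds = 10
        for seed in range(n_seeds):
            matrix, samples, _, truth = generate_cohort(cfg.replace(seed=seed))
            partition, spec_samples = preprocess_chain(matrix, samples)
            table = presence_absence(partition.rare, spec_samples)
            rare_in_partition = [p for p in truth.rare_proteins
                                 if p in table.index]
            flagged += all(table.loc[p, "enriched_in"] == "EOS"
                           for p in rare_in_partition) and \
                len(rare_in_partition) == len(truth.rare_proteins)
        assert flagged >= n_seeds - 1


class TestSensitivitySubset:
    def test_ga_cutoff_boundaries(self):
        samples = SampleTable(tiny_sample_df([
            dict(sample_id="C1", gestational_age=38.0),
            dict(sample_id="C2", gestational_age=36.9),
            dict(sample_id="C3", gestational_age=37.0),
            dict(sample_id="E1", group="EOS", gestational_age=30.0),
        ]))
        out = sensitivity_subset(samples)
        kept = set(out.df["sample_id"])
        assert kept == {"C2", "E1"}

    def test_empty_result_is_config_error(self):
        samples = SampleTable(tiny_sample_df(
            [dict(sample_id="C1", gestational_age=40.0)]))
        with pytest.raises(ConfigurationError):
            sensitivity_subset(samples, ga_cutoff=25.0)


class TestDemographics:
    def _samples(self):
        rows = []
        for i in range(50):
            rows.append(dict(sample_id=f"C{i}", group="control",
                             chorioamnionitis=i < 40, gestational_age=33.0))
        for i in range(50):
            rows.append(dict(sample_id=f"E{i}", group="EOS",
                             chorioamnionitis=i < 20, gestational_age=31.0))
        return SampleTable(tiny_sample_df(rows))

    def test_chi_square_hand_example(self):
        # contingency [[10, 40], [30, 20]] -> chi2 = 16.667, p ~ 4.5e-5
        table, _ = demographics_table(self._samples(), continuous_vars=(),
                                      categorical_vars=("chorioamnionitis",),
                                      groups=("EOS", "control"))
        row = table.iloc[0]
        assert row["statistic"] == pytest.approx(16.6667, abs=1e-3)
        assert row["p_value"] == pytest.approx(4.45e-5, rel=0.05)

    def test_identical_groups_chi_square_zero(self):
        rows = ([dict(sample_id=f"C{i}", group="control", prom=i < 5)
                 for i in range(10)]
                + [dict(sample_id=f"E{i}", group="EOS", prom=i < 5,
                        gestational_age=30.0) for i in range(10)])
        table, _ = demographics_table(SampleTable(tiny_sample_df(rows)),
                                      continuous_vars=(),
                                      categorical_vars=("prom",))
        assert table.iloc[0]["statistic"] == pytest.approx(0.0)
        assert table.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_constant_categorical_skipped_and_logged(self):
        table, log = demographics_table(self._samples(), continuous_vars=(),
                                        categorical_vars=("preeclampsia",))
        assert table.empty
        assert any("constant" in entry for entry in log)

    def test_all_tied_continuous_p_one(self):
        table, _ = demographics_table(self._samples(),
                                      continuous_vars=("plasma_protein_conc",),
                                      categorical_vars=())
        assert table.iloc[0]["p_value"] == 1.0
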