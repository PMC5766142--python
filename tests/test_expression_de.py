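import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methex.expression_de import (
    cell_means_contrast,
    differential_expression,
    log2_transform,
    quantile_normalize,
)
from methex.io_core import ExpressionMatrix, SampleDesign
from methex.sim_data import SimulationConfig, simulate_dataset


def _matrix(values, columns, probes=None):
    probes = probes or [f"p{i}" for i in range(len(values))]
    frame = pd.DataFrame(values, index=probes, columns=columns)
    meta = pd.DataFrame({"probe": probes, "chrom": "chrS",
                         "start": 100, "end": 160, "testable": True})
    return ExpressionMatrix(values=frame, probes=meta)


class TestQuantileNormalize:
    def test_two_by_two_hand_computed(self):
        m = _matrix([[1.0, 3.0], [2.0, 4.0]], ["a", "b"])
        out = quantile_normalize(m)
        assert out.values.to_numpy() == pytest.approx(np.array([[2.0, 2.0], [3.0, 3.0]]))

    def test_identical_columns_unchanged(self):
        col = [5.0, 1.0, 3.0, 2.0]
        m = _matrix(np.column_stack([col, col, col]), ["a", "b", "c"])
        out = quantile_normalize(m)
        assert out.values.to_numpy() == pytest.approx(np.column_stack([col, col, col]))

    def test_single_column_unchanged(self):
        m = _matrix(np.array([[4.0], [1.0], [9.0]]), ["a"])
        assert quantile_normalize(m).values.to_numpy() == pytest.approx(m.values.to_numpy())

    def test_columns_share_distribution_after(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.lognormal(2, 1, size=(40, 5)), list("abcde"))
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            assert np.sort(out[:, j]) == pytest.approx(ref)

    def test_ties_get_mean_of_rank_range(self):
        m = _matrix([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]], ["a", "b"])
        out = quantile_normalize(m).values.to_numpy()
        rank_means = [(1 + 10) / 2, (1 + 20) / 2, (5 + 30) / 2]
        tie_value = (rank_means[0] + rank_means[1]) / 2
        assert out[:, 0] == pytest.approx([tie_value, tie_value, rank_means[2]])


class TestLog2:
    def test_offset_avoids_log_of_zero(self):
        m = _matrix([[0.0, 3.0]], ["a", "b"])
        out = log2_transform(m, offset=1.0)
        assert out.values.to_numpy() == pytest.approx(np.array([[0.0, 2.0]]))


class TestContrast:
    def test_saturated_model_equals_pooled_t(self, small_design):
        # with only the two contrasted cells present the contrast t equals
        # the classical pooled two-sample t-test
        rows = small_design.frame[small_design.frame["treatment"] == "HDM"]
        design = SampleDesign(rows.reset_index(drop=True))
        rng = np.random.default_rng(1)
        vals = rng.normal(8, 1, size=(30, len(design.samples)))
        m = _matrix(vals, design.samples)
        res = cell_means_contrast(m.values, design, "KO_HDM:WT_HDM")
        ko = design.group_samples("KO", "HDM")
        wt = design.group_samples("WT", "HDM")
        for i, probe in enumerate(m.values.index):
            t, p = stats.ttest_ind(m.values.loc[probe, ko], m.values.loc[probe, wt])
            assert res.loc[probe, "t"] == pytest.approx(t)
            assert res.loc[probe, "p_raw"] == pytest.approx(p)

    def test_constant_probe_degenerate(self, small_design):
        vals = np.vstack([np.full(12, 7.0), np.random.default_rng(0).normal(8, 1, 12)])
        m = _matrix(vals, small_design.samples)
        res = cell_means_contrast(m.values, small_design, "KO_HDM:WT_HDM")
        assert res.iloc[0]["p_raw"] == 1.0
        assert bool(res.iloc[0]["degenerate"])
        assert res.iloc[1]["p_raw"] < 1.0


class TestDifferentialExpression:
    def test_baseline_shared_probe_excluded_from_headline(self, small_design):
        rng = np.random.default_rng(2)
        vals = rng.normal(8, 0.3, size=(50, 12))
        is_ko = np.array([small_design.genotype_of(s) == "KO" for s in small_design.samples])
        vals[0, is_ko] += 4.0  # KO shift under both treatments: baseline-shared
        is_hdm = (small_design.frame["treatment"] == "HDM").to_numpy()
        vals[1, is_ko & is_hdm] += 4.0  # treatment-specific: headline call
        m = _matrix(vals, small_design.samples)
        res = differential_expression(m, small_design, "KO_HDM:WT_HDM",
                                      "KO_saline:WT_saline", q_threshold=0.05)
        assert res.iloc[0]["p_adj"] < 0.05 and bool(res.iloc[0]["baseline_shared"])
        assert not bool(res.iloc[0]["significant"])
        assert bool(res.iloc[1]["significant"])

    def test_planted_probes_recovered_on_simulated_data(self):
        cfg = SimulationConfig(
            n_sites=150, n_clusters_true=30, n_dmrs_true=2, n_dmrs_baseline=1,
            n_dmrs_contam=0, contam_region=None, n_probes=400, n_cis_true=0,
            n_de_true=25, n_de_baseline=3, n_per_group=5, de_log2fc=1.5, seed=19,
        )
        ds = simulate_dataset(cfg)
        norm = quantile_normalize(ds.expression)
        res = differential_expression(norm, ds.design, "KO_HDM:WT_HDM",
                                      "KO_saline:WT_saline", q_threshold=0.05)
        truth = ds.truth.true_de_probes
        hdm_probes = set(truth.query("category == 'hdm'").probe)
        recovered = set(res[res["significant"]].probe) & hdm_probes
        assert len(recovered) >= 0.8 * len(hdm_probes)
        # realized false-discovery proportion consistent with the target rate
        called = res[res["significant"]]
        false = [p for p in called.probe if p not in set(truth.probe)]
        if len(called):
            assert len(false) / len(called) <= 0.2
        # baseline-shared planted probes are flagged
        base_probes = set(truth.query("category == 'baseline'").probe)
        flagged = set(res[res["baseline_shared"]].probe)
        assert base_probes <= flagged
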