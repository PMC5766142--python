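import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import special

from methex.io_core import ConfigurationError
from methex.sim_data import (
    SimulationConfig,
    simulate_cluster_counts,
    simulate_dataset,
    simulate_strain_snps,
    write_dataset,
)

SMALL = dict(
    n_sites=240, n_clusters_true=40, n_dmrs_true=2, n_dmrs_baseline=1,
    n_dmrs_contam=1, n_probes=40, n_cis_true=4, n_de_true=4, n_de_baseline=1,
    n_genes=20, n_islands=10, n_per_group=3,
)


def _tree_hash(root: Path) -> dict:
    return {
        p.relative_to(root).as_posix(): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("within_cluster_rho", 1.5),
            ("depth_mean", 0.0),
            ("n_dmrs_true", 500),
            ("n_per_group", 1),
            ("contam_region", ("chrS", -5, 10)),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        cfg = SimulationConfig(**{**SMALL, field: value})
        with pytest.raises(ConfigurationError, match="invalid config field"):
            cfg.validate()


class TestSimulateDataset:
    def test_no_planted_dmrs_gives_empty_truth(self):
        cfg = SimulationConfig(**{**SMALL, "n_dmrs_true": 0, "n_dmrs_baseline": 0,
                                  "n_dmrs_contam": 0}, seed=3)
        ds = simulate_dataset(cfg)
        assert ds.truth.true_dmr_intervals.empty

    def test_counts_bounded_and_positions_sorted(self):
        ds = simulate_dataset(SimulationConfig(**SMALL, seed=4))
        assert np.all(ds.counts.meth <= ds.counts.depth)
        assert np.all(ds.counts.meth >= 0)
        assert np.all(np.diff(ds.counts.pos) > 0)

    def test_same_seed_is_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            ds = simulate_dataset(SimulationConfig(**SMALL, seed=7))
            write_dataset(ds, tmp_path / d)
        assert _tree_hash(tmp_path / "a") == _tree_hash(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        h = []
        for seed in (7, 8):
            ds = simulate_dataset(SimulationConfig(**SMALL, seed=seed))
            write_dataset(ds, tmp_path / str(seed))
            h.append(_tree_hash(tmp_path / str(seed)))
        assert h[0] != h[1]

    def test_grand_mean_near_half_with_zero_baseline(self):
        # Monte-Carlo oracle: with a symmetric baseline distribution around
        # logit 0.5 and no effects, the overall methylation mass is 1/2
        means = []
        for seed in range(20):
            cfg = SimulationConfig(**{**SMALL, "n_dmrs_true": 0, "n_dmrs_baseline": 0,
                                      "n_dmrs_contam": 0}, seed=seed)
            ds = simulate_dataset(cfg)
            means.append(ds.counts.meth.sum() / ds.counts.depth.sum())
        assert abs(np.mean(means) - 0.5) < 0.02

    def test_truth_dmrs_have_at_least_three_sites(self):
        ds = simulate_dataset(SimulationConfig(**SMALL, seed=5))
        for r in ds.truth.true_dmr_intervals.itertuples():
            sites = ds.truth.true_cluster_sites[r.cluster_id]
            assert len(sites) >= 3
            assert r.start == sites.min() and r.end == sites.max() + 2

    def test_cis_pairs_attach_to_effect_clusters(self):
        ds = simulate_dataset(SimulationConfig(**SMALL, seed=6))
        effect_ids = set(ds.truth.true_dmr_intervals.query("category != 'contam'").cluster_id)
        assert set(ds.truth.true_cis_pairs.cluster_id) <= effect_ids


class TestClusterModel:
    def test_within_cluster_correlation_approaches_rho(self):
        # high-depth limit: latent logit correlation = rho
        rng = np.random.default_rng(0)
        rho = 0.6
        m, d = simulate_cluster_counts(
            rng, n_samples=4000, n_sites=2, baseline_logit=0.0,
            effect_per_sample=np.zeros(4000), rho=rho, sample_logit_sd=1.0,
            depth_mean=3000, depth_dispersion=0.0, site_jitter_sd=0.0,
        )
        z = special.logit(m / d)
        got = np.corrcoef(z[0], z[1])[0, 1]
        assert abs(got - rho) < 0.05

    def test_planted_logit_effect_recovered_in_group_means(self):
        rng = np.random.default_rng(1)
        eff = np.concatenate([np.full(2000, 1.5), np.zeros(2000)])
        m, d = simulate_cluster_counts(
            rng, n_samples=4000, n_sites=3, baseline_logit=0.3,
            effect_per_sample=eff, rho=0.9, sample_logit_sd=0.05,
            depth_mean=3000, depth_dispersion=0.0, site_jitter_sd=0.0,
        )
        z = special.logit(m.sum(axis=0) / d.sum(axis=0))
        assert abs((z[:2000].mean() - z[2000:].mean()) - 1.5) < 0.05


class TestStrainSnps:
    def test_contaminated_block_rates(self):
        cfg = SimulationConfig(**SMALL, seed=9)
        ds = simulate_dataset(cfg)
        panel = ds.snp_panel
        ko = ds.design.group_samples("KO", "saline") + ds.design.group_samples("KO", "HDM")
        wt = ds.design.group_samples("WT", "saline") + ds.design.group_samples("WT", "HDM")
        _, cs, ce = cfg.contam_region
        inside = (panel["pos"] >= cs) & (panel["pos"] < ce)
        assert panel.loc[inside, ko].to_numpy().mean() > 0.9
        assert panel.loc[inside, wt].to_numpy().mean() < 0.05
        assert panel.loc[~inside, ko].to_numpy().mean() < 0.05

    def test_no_contamination_no_enrichment(self):
        cfg = SimulationConfig(**{**SMALL, "contam_region": None, "n_dmrs_contam": 0}, seed=9)
        panel = simulate_strain_snps(cfg)
        sample_cols = [c for c in panel.columns if c not in ("chrom", "pos")]
        assert panel[sample_cols].to_numpy().mean() < 0.05

    def test_reproducible(self):
        cfg = SimulationConfig(**SMALL, seed=13)
        a = simulate_strain_snps(cfg)
        b = simulate_strain_snps(cfg)
        assert a.equals(b)
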