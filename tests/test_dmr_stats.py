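import numpy as np
import pandas as pd
import pytest

from methex.aclust import cluster_adjacent_sites, summarize_clusters
from methex.dmr_stats import (
    apply_blacklist,
    bh_adjust,
    call_dmrs,
    detect_strain_blacklist,
    final_calls,
    nearest_gene,
    subset_near_genes,
    subtract_baseline,
)
from methex.io_core import GeneModel, GenomicInterval
from methex.sim_data import SimulationConfig, simulate_strain_snps, _make_design


def brute_force_bh(p):
    """Step-up formula applied literally: q_(i) = min_{j>=i} p_(j) n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for rank, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * n / j for j in range(rank, n + 1)), 1.0
        )
    return q


class TestBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.1, 0.9], [0.015, 0.15, 0.9]),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_literal_formula_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(1, 40)))
        assert bh_adjust(p) == pytest.approx(brute_force_bh(p))

    def test_reordering_permutes_outputs_identically(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))


def _simulated_clusters(seed=0, n_clusters=30, n_dmr=3, effect=1.5, n_per_group=10):
    """Build summarized clusters directly from the generator primitives."""
    from methex.sim_data import simulate_cluster_counts
    from methex.aclust import MethylationCluster
    from scipy import special

    rng = np.random.default_rng(seed)
    design = _make_design(n_per_group)
    is_ko = (design.frame["genotype"] == "KO").to_numpy()
    is_hdm = (design.frame["treatment"] == "HDM").to_numpy()
    n = len(design.samples)
    clusters, truth = [], []
    pos0 = 1000
    for k in range(n_clusters):
        eff = np.zeros(n)
        if k < n_dmr:
            eff[is_ko & is_hdm] = effect
        b = rng.uniform(special.logit(0.3), special.logit(0.7))
        m, d = simulate_cluster_counts(rng, n, 5, b, eff, 0.95, 0.5, 30, 0.3)
        sites = pos0 + np.arange(5) * 100
        pos0 += 10_000
        cl = MethylationCluster(chrom="chrS", sites=sites, samples=design.samples,
                                pooled_meth=m.sum(0), pooled_depth=d.sum(0))
        clusters.append(cl)
        if k < n_dmr:
            truth.append((int(sites.min()), int(sites.max()) + 2))
    return clusters, design, truth


class TestCallDmrs:
    def test_planted_dmrs_called_and_direction_consistent(self):
        clusters, design, truth = _simulated_clusters(seed=1)
        table = call_dmrs(clusters, design, "KO_HDM:WT_HDM", q_threshold=0.10)
        called = table[table["called"]]
        for start, end in truth:
            assert ((called["start"] == start) & (called["end"] == end)).any()
        hyper = table["beta1"] > 0
        assert (table.loc[hyper, "direction"] == "hyper").all()
        assert (table["p_adj"] >= table["p_raw"] - 1e-12).all()

    def test_threshold_boundary_is_inclusive(self):
        clusters, design, _ = _simulated_clusters(seed=2, n_clusters=12, n_dmr=2)
        table = call_dmrs(clusters, design, "KO_HDM:WT_HDM", q_threshold=0.10)
        some_q = float(table["p_adj"].dropna().iloc[5])
        again = call_dmrs(clusters, design, "KO_HDM:WT_HDM", q_threshold=some_q)
        row = again[again["p_adj"] == some_q]
        assert row["called"].all()

    def test_group_without_data_skipped_with_reason(self):
        clusters, design, _ = _simulated_clusters(seed=3, n_clusters=2, n_dmr=0)
        ko = [s in design.group_samples("KO", "HDM") for s in design.samples]
        clusters[0].pooled_depth = np.where(ko, 0, clusters[0].pooled_depth)
        table = call_dmrs(clusters, design, "KO_HDM:WT_HDM")
        assert table.loc[0, "skip_reason"] != ""
        assert np.isnan(table.loc[0, "p_raw"])


def _dmr_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "nearest_gene"])
    df["called"] = True
    df["p_raw"] = 0.01
    df["baseline_shared"] = False
    df["blacklisted"] = False
    return df


class TestSubtractBaseline:
    def test_empty_baseline_changes_nothing(self):
        treated = _dmr_frame([("chrS", 100, 200, "g1")])
        out = subtract_baseline(treated, treated.iloc[0:0])
        assert not out["baseline_shared"].any()

    def test_single_bp_overlap_is_flagged(self):
        treated = _dmr_frame([("chrS", 100, 200, "g1")])
        baseline = _dmr_frame([("chrS", 199, 300, "g2")])
        out = subtract_baseline(treated, baseline)
        assert out["baseline_shared"].all()
        # abutting (zero overlap) is not shared
        baseline2 = _dmr_frame([("chrS", 200, 300, "g2")])
        assert not subtract_baseline(treated, baseline2)["baseline_shared"].any()

    def test_shared_nearest_gene_is_flagged(self):
        treated = _dmr_frame([("chrS", 100, 200, "shared_gene")])
        baseline = _dmr_frame([("chrS", 900_000, 900_100, "shared_gene")])
        assert subtract_baseline(treated, baseline)["baseline_shared"].all()

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(8)]
        def rand_rows(n):
            rows = []
            for _ in range(n):
                s = int(rng.integers(0, 100_000))
                rows.append(("chrS", s, s + int(rng.integers(10, 3000)), str(rng.choice(genes))))
            return rows
        treated = _dmr_frame(rand_rows(20))
        baseline = _dmr_frame(rand_rows(10))
        got = subtract_baseline(treated, baseline)["baseline_shared"]
        for i, r in treated.iterrows():
            expected = any(
                (r.start < b.end and b.start < r.end) or r.nearest_gene == b.nearest_gene
                for b in baseline.itertuples()
            )
            assert got[i] == expected


class TestBlacklist:
    def test_clean_panel_gives_empty_blacklist(self):
        cfg = SimulationConfig(n_per_group=3, contam_region=None, n_dmrs_contam=0)
        panel = simulate_strain_snps(cfg)
        design = _make_design(3)
        # remove even the background noise
        cols = [c for c in panel.columns if c not in ("chrom", "pos")]
        panel[cols] = 0
        assert detect_strain_blacklist(panel, design) == []

    def test_group_specificity_required(self):
        cfg = SimulationConfig(n_per_group=3)
        panel = simulate_strain_snps(cfg)
        design = _make_design(3)
        cols = [c for c in panel.columns if c not in ("chrom", "pos")]
        panel[cols] = 1  # everyone matches the alternate strain everywhere
        assert detect_strain_blacklist(panel, design) == []

    def test_planted_block_detected_with_high_jaccard(self):
        cfg = SimulationConfig(n_per_group=10, seed=17)
        panel = simulate_strain_snps(cfg)
        design = _make_design(10)
        regions = detect_strain_blacklist(panel, design)
        assert len(regions) == 1
        got = regions[0]
        _, cs, ce = cfg.contam_region
        inter = max(0, min(got.end, ce) - max(got.start, cs))
        union = max(got.end, ce) - min(got.start, cs)
        assert inter / union >= 0.9

    def test_apply_blacklist_flags_overlaps_only(self):
        table = _dmr_frame([("chrS", 100, 200, "a"), ("chrS", 5000, 5100, "b")])
        out = apply_blacklist(table, [GenomicInterval("chrS", 150, 1000)])
        assert list(out["blacklisted"]) == [True, False]
        assert len(final_calls(out)) == 1


def _gene(name, start, end, strand="+"):
    return GeneModel(name=name, chrom="chrS", start=start, end=end, strand=strand,
                     exon_starts=(start,), exon_ends=(end,), cds_start=start, cds_end=end)


class TestSubsetNearGenes:
    def test_empty_gene_list_gives_empty_subset(self):
        table = _dmr_frame([("chrS", 100, 200, "a")])
        out = subset_near_genes(table, [_gene("g", 10, 20)], [], 25_000)
        assert out.empty

    def test_distance_boundary_inclusive_at_25kb(self):
        gene = _gene("target", 100_000, 110_000)
        near = _dmr_frame([("chrS", 135_000, 135_050, "x")])   # gap exactly 25,000
        far = _dmr_frame([("chrS", 135_001, 135_051, "x")])    # gap 25,001
        assert len(subset_near_genes(near, [gene], ["target"], 25_000)) == 1
        assert len(subset_near_genes(far, [gene], ["target"], 25_000)) == 0

    def test_within_subset_adjustment_is_hand_step_up(self):
        gene = _gene("target", 0, 1000)
        rows = [("chrS", 1000 + 10 * i, 1005 + 10 * i, "x") for i in range(5)]
        table = _dmr_frame(rows)
        table["p_raw"] = [0.01, 0.02, 0.03, 0.04, 0.05]
        out = subset_near_genes(table, [gene], ["target"], 25_000, q_threshold=0.10)
        assert out["p_adj_subset"].to_numpy() == pytest.approx([0.05] * 5)
        assert out["called_subset"].all()

    def test_unresolvable_name_warned_and_skipped(self, caplog):
        table = _dmr_frame([("chrS", 100, 200, "a")])
        with caplog.at_level("WARNING"):
            out = subset_near_genes(table, [_gene("g", 50, 400)], ["g", "ghost"], 25_000)
        assert "ghost" in caplog.text
        assert len(out) == 1


class TestNearestGene:
    def test_overlap_distance_zero_and_ties_by_name(self):
        iv = GenomicInterval("chrS", 100, 200)
        inside = [_gene("b", 50, 400), _gene("a", 50, 400)]
        assert nearest_gene(iv, inside) == ("a", 0.0)
        away = [_gene("far", 1000, 2000)]
        name, d = nearest_gene(iv, away)
        assert name == "far" and d == 1000 - 150
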