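"""Synthetic data generator for the methylation/expression pipeline.

Emulates the data structure of a targeted bisulfite-sequencing +
expression-array mouse study with a 2x2 genotype (WT/KO) x treatment
(saline/HDM) design: spatially clustered CpG sites with correlated
methylation within a cluster, planted group effects on the logit scale,
negative-binomial read depths, a contiguous alternate-strain
("contaminated") genomic block visible in a strain-informative SNP panel,
and expression probes with planted cis methylation-expression couplings of
both signs.

The per-site model, for sample ``s`` and site ``i`` in cluster ``c``::

    logit(p_is) = b_i + sigma * (sqrt(rho) * u_cs + sqrt(1-rho) * e_is)
                      + delta_c * 1[s in affected group]
    m_is ~ Binomial(d_is, p_is),   d_is ~ NB(depth_mean, depth_dispersion), floored at 1

where ``u_cs`` is a shared per-(cluster, sample) latent inducing the
within-cluster correlation ``rho`` of the site-level logits and ``b_i`` is a
per-site baseline (shared cluster level plus small site jitter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special
from scipy.special import expit

from .io_core import (
    ConfigurationError,
    CpGCountTable,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    SampleDesign,
    write_bed,
    write_coverage,
    write_expression,
    write_gene_models,
    write_sample_sheet,
    write_snp_panel,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_strain_snps",
    "simulate_cluster_counts",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    """All knobs of the generator. Defaults are the reference study
    conditions used throughout the test suite."""

    n_per_group: int = 10          # samples per genotype x treatment cell
    n_sites: int = 1800            # total CpG sites (clustered + background)
    n_clusters_true: int = 200     # planted correlated clusters
    n_dmrs_true: int = 5           # planted clusters with a KO-vs-WT effect under HDM only
    n_dmrs_baseline: int = 2       # planted KO effect under both treatments (baseline DMRs)
    n_dmrs_contam: int = 2         # planted KO effect inside the contaminated block
    effect_logit: float = 1.5      # group effect size on the logit scale
    baseline_logit_mean: float = 0.0
    baseline_logit_sd: float = 1.0
    site_jitter_sd: float = 0.3    # within-cluster spread of per-site baselines
    within_cluster_rho: float = 0.95
    sample_logit_sd: float = 0.5   # between-sample biological noise (logit scale)
    depth_mean: float = 30.0
    depth_dispersion: float = 0.3  # NB: var = mean + dispersion * mean^2
    n_probes: int = 300
    n_cis_true: int = 20
    cis_slope: float = 8.0         # log2 expression units per methylation proportion unit
    expr_noise_sd: float = 0.4     # log2-scale expression noise
    n_de_true: int = 20            # planted DE probes (KO vs WT under HDM)
    n_de_baseline: int = 3         # planted DE probes shared at baseline (KO effect, both treatments)
    de_log2fc: float = 1.0
    chrom: str = "chrS"
    chrom_length: int = 50_000_000
    contam_region: tuple[str, int, int] | None = ("chrS", 30_000_000, 44_000_000)
    snp_spacing: int = 10_000
    contam_match_rate: float = 0.98
    background_match_rate: float = 0.02
    n_genes: int = 120
    n_islands: int = 80
    seed: int = 0

    def validate(self) -> None:
        def bad(name: str, why: str) -> ConfigurationError:
            return ConfigurationError(f"invalid config field {name!r}: {why}")

        n_planted = self.n_dmrs_true + self.n_dmrs_baseline + self.n_dmrs_contam
        if self.n_per_group < 2:
            raise bad("n_per_group", "need >= 2 samples per cell")
        if n_planted > self.n_clusters_true:
            raise bad("n_dmrs_true", "planted DMR clusters exceed n_clusters_true")
        if not (0.0 <= self.within_cluster_rho <= 1.0):
            raise bad("within_cluster_rho", "must be in [0, 1]")
        if self.depth_mean <= 0:
            raise bad("depth_mean", "must be > 0")
        if self.depth_dispersion < 0:
            raise bad("depth_dispersion", "must be >= 0")
        for name in ("n_sites", "n_clusters_true", "n_dmrs_true", "n_dmrs_baseline",
                     "n_dmrs_contam", "n_probes", "n_cis_true", "n_de_true", "n_de_baseline"):
            if getattr(self, name) < 0:
                raise bad(name, "must be nonnegative")
        if self.contam_region is not None:
            c, s, e = self.contam_region
            if c != self.chrom or s < 0 or e > self.chrom_length or s >= e:
                raise bad("contam_region", "outside simulated genome bounds")
        if self.n_dmrs_contam > 0 and self.contam_region is None:
            raise bad("n_dmrs_contam", "requires a contam_region")
        if 3 * self.n_clusters_true > self.n_sites:
            raise bad("n_sites", "too few sites to host the requested clusters")


@dataclass
class GroundTruth:
    """Planted structure recorded by the generator."""

    true_dmr_intervals: pd.DataFrame   # chrom, start, end, sign, category, cluster_id
    true_cis_pairs: pd.DataFrame       # chrom, start, end, cluster_id, probe, sign
    true_de_probes: pd.DataFrame       # probe, category, sign
    true_cluster_sites: dict[int, np.ndarray]  # cluster_id -> site positions
    contam_region: GenomicInterval | None


@dataclass
class SimulatedDataset:
    counts: CpGCountTable
    expression: ExpressionMatrix
    design: SampleDesign
    genes: list[GeneModel]
    islands: list[GenomicInterval]
    snp_panel: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def _make_design(n_per_group: int) -> SampleDesign:
    rows = []
    for g in ("WT", "KO"):
        for t in ("saline", "HDM"):
            for i in range(1, n_per_group + 1):
                rows.append((f"{g}_{t}_{i}", g, t))
    return SampleDesign(pd.DataFrame(rows, columns=["sample", "genotype", "treatment"]))


def _nb_depths(rng: np.random.Generator, shape, mean: float, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        d = rng.poisson(mean, size=shape)
    else:
        r = 1.0 / dispersion
        p = r / (r + mean)
        d = rng.negative_binomial(r, p, size=shape)
    return np.maximum(d, 1)


def simulate_cluster_counts(
    rng: np.random.Generator,
    n_samples: int,
    n_sites: int,
    baseline_logit: float,
    effect_per_sample: np.ndarray,
    rho: float,
    sample_logit_sd: float,
    depth_mean: float,
    depth_dispersion: float,
    site_jitter_sd: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one cluster's (meth, depth) arrays of shape (n_sites, n_samples).

    ``effect_per_sample`` is the planted logit shift per sample (zeros for a
    null cluster). Shared building block of :func:`simulate_dataset` and the
    calibration studies.
    """
    b = baseline_logit + rng.normal(0.0, site_jitter_sd, size=n_sites)
    u = rng.normal(size=n_samples)                      # shared latent per sample
    e = rng.normal(size=(n_sites, n_samples))           # site-level noise
    z = (
        b[:, None]
        + sample_logit_sd * (np.sqrt(rho) * u[None, :] + np.sqrt(1.0 - rho) * e)
        + effect_per_sample[None, :]
    )
    depth = _nb_depths(rng, (n_sites, n_samples), depth_mean, depth_dispersion)
    meth = rng.binomial(depth, expit(z))
    return meth, depth


def _place_clusters(cfg: SimulationConfig, rng: np.random.Generator):
    """Choose cluster anchor positions and per-cluster site positions.

    Planted HDM-specific and baseline DMR clusters are anchored outside the
    contaminated block; contaminated-block artifacts inside it. Background
    sites are kept >=200 bp clear of cluster spans so that planted cluster
    membership is unambiguous ground truth.
    """
    n_c = cfg.n_clusters_true
    slot = cfg.chrom_length / (n_c + 1)
    anchors = np.array([(k + 1) * slot + rng.uniform(-0.2 * slot, 0.2 * slot) for k in range(n_c)])
    anchors = np.sort(anchors).astype(int)

    if cfg.contam_region is not None:
        _, cs, ce = cfg.contam_region
        inside = np.where((anchors >= cs) & (anchors + 2000 <= ce))[0]
        outside = np.where((anchors + 2000 < cs) | (anchors > ce))[0]
    else:
        inside = np.array([], dtype=int)
        outside = np.arange(n_c)

    n_eff = cfg.n_dmrs_true + cfg.n_dmrs_baseline
    if len(outside) < n_eff or len(inside) < cfg.n_dmrs_contam:
        raise ConfigurationError("genome too small to place the requested DMR clusters")
    out_pick = rng.choice(outside, size=n_eff, replace=False)
    categories = {}
    for idx in out_pick[: cfg.n_dmrs_true]:
        categories[int(idx)] = "hdm"
    for idx in out_pick[cfg.n_dmrs_true:]:
        categories[int(idx)] = "baseline"
    for idx in rng.choice(inside, size=cfg.n_dmrs_contam, replace=False) if cfg.n_dmrs_contam else []:
        categories[int(idx)] = "contam"

    sites_per_cluster = {}
    for k in range(n_c):
        n_s = int(rng.integers(5, 9)) if k in categories else int(rng.integers(3, 9))
        gaps = rng.integers(20, 151, size=n_s - 1)
        pos = anchors[k] + np.concatenate([[0], np.cumsum(gaps)])
        sites_per_cluster[k] = pos.astype(int)
    return sites_per_cluster, categories


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full synthetic dataset plus ground truth.

    Identical config (including seed) gives identical output.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 11])
    design = _make_design(cfg.n_per_group)
    samples = design.samples
    n_samp = len(samples)
    geno = design.frame["genotype"].to_numpy()
    treat = design.frame["treatment"].to_numpy()
    is_ko = geno == "KO"
    is_hdm = treat == "HDM"

    sites_per_cluster, categories = _place_clusters(cfg, rng)

    # background site positions, clear of cluster spans
    spans = [(p.min() - 200, p.max() + 200) for p in sites_per_cluster.values()]
    n_cluster_sites = sum(len(p) for p in sites_per_cluster.values())
    n_bg = max(cfg.n_sites - n_cluster_sites, 0)
    bg = []
    while len(bg) < n_bg:
        cand = rng.integers(0, cfg.chrom_length, size=n_bg)
        for c in cand:
            if len(bg) >= n_bg:
                break
            if not any(lo <= c <= hi for lo, hi in spans):
                bg.append(int(c))
    bg = np.array(sorted(set(bg)), dtype=int)

    # effect direction per planted DMR cluster
    signs = {k: int(rng.choice([-1, 1])) for k in categories}

    # generate counts cluster by cluster, then background sites
    pos_list, meth_list, depth_list = [], [], []
    cluster_means: dict[int, np.ndarray] = {}
    dmr_rows = []
    for k in sorted(sites_per_cluster):
        pos = sites_per_cluster[k]
        cat = categories.get(k)
        effect = np.zeros(n_samp)
        if cat == "hdm":
            effect[is_ko & is_hdm] = signs[k] * cfg.effect_logit
        elif cat in ("baseline", "contam"):
            effect[is_ko] = signs[k] * cfg.effect_logit
        if cat is not None:
            # effect-bearing clusters sit at intermediate methylation, where
            # a logit-scale group shift is expressed on the proportion scale
            # (reported DMRs concentrate in such variable regions)
            b_c = rng.uniform(special.logit(0.25), special.logit(0.75))
        else:
            b_c = rng.normal(cfg.baseline_logit_mean, cfg.baseline_logit_sd)
        meth, depth = simulate_cluster_counts(
            rng, n_samp, len(pos), b_c, effect, cfg.within_cluster_rho,
            cfg.sample_logit_sd, cfg.depth_mean, cfg.depth_dispersion, cfg.site_jitter_sd,
        )
        pos_list.append(pos)
        meth_list.append(meth)
        depth_list.append(depth)
        cluster_means[k] = meth.sum(axis=0) / depth.sum(axis=0)
        if cat is not None:
            dmr_rows.append(
                (cfg.chrom, int(pos.min()), int(pos.max()) + 2, signs[k], cat, k)
            )

    if len(bg):
        b_bg = rng.normal(cfg.baseline_logit_mean, cfg.baseline_logit_sd, size=len(bg))
        e = rng.normal(size=(len(bg), n_samp))
        z = b_bg[:, None] + cfg.sample_logit_sd * e
        depth_bg = _nb_depths(rng, (len(bg), n_samp), cfg.depth_mean, cfg.depth_dispersion)
        meth_bg = rng.binomial(depth_bg, expit(z))
        pos_list.append(bg)
        meth_list.append(meth_bg)
        depth_list.append(depth_bg)

    pos_all = np.concatenate(pos_list)
    order = np.argsort(pos_all, kind="stable")
    pos_all = pos_all[order]
    meth_all = np.vstack(meth_list)[order]
    depth_all = np.vstack(depth_list)[order]
    # drop duplicate positions (background collisions), keeping first
    keep = np.concatenate([[True], np.diff(pos_all) > 0])
    counts = CpGCountTable(
        chrom=np.array([cfg.chrom] * int(keep.sum()), dtype=object),
        pos=pos_all[keep],
        samples=samples,
        meth=meth_all[keep],
        depth=depth_all[keep],
    )

    genes = _simulate_genes(cfg, rng)
    islands = _simulate_islands(cfg, rng, sites_per_cluster)
    expression, cis_rows, de_rows = _simulate_expression(
        cfg, rng, design, sites_per_cluster, categories, cluster_means
    )

    truth = GroundTruth(
        true_dmr_intervals=pd.DataFrame(
            dmr_rows, columns=["chrom", "start", "end", "sign", "category", "cluster_id"]
        ).sort_values(["start"]).reset_index(drop=True),
        true_cis_pairs=pd.DataFrame(
            cis_rows, columns=["chrom", "start", "end", "cluster_id", "probe", "sign"]
        ),
        true_de_probes=pd.DataFrame(de_rows, columns=["probe", "category", "sign"]),
        true_cluster_sites={k: v for k, v in sites_per_cluster.items()},
        contam_region=(
            GenomicInterval(*cfg.contam_region) if cfg.contam_region is not None else None
        ),
    )
    snp_panel = simulate_strain_snps(cfg, design)
    return SimulatedDataset(counts, expression, design, genes, islands, snp_panel, truth, cfg)


def _simulate_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    slot = cfg.chrom_length / (cfg.n_genes + 1)
    for k in range(cfg.n_genes):
        length = int(rng.integers(5_000, 50_000))
        start = int((k + 1) * slot + rng.uniform(-0.2 * slot, 0.2 * slot))
        start = max(0, min(start, cfg.chrom_length - length - 1))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(2, 7))
        cuts = np.sort(rng.choice(np.arange(start + 100, end - 100), size=2 * n_ex - 2, replace=False))
        bounds = np.concatenate([[start], cuts, [end]])
        ex_starts = tuple(int(b) for b in bounds[0::2])
        ex_ends = tuple(int(b) for b in bounds[1::2])
        exonic = [(s, e) for s, e in zip(ex_starts, ex_ends)]
        # CDS: trim a UTR off each end (within first/last exon)
        utr5 = int(rng.integers(50, max(51, (exonic[0][1] - exonic[0][0]) // 2 + 1)))
        utr3 = int(rng.integers(50, max(51, (exonic[-1][1] - exonic[-1][0]) // 2 + 1)))
        cds_start = exonic[0][0] + utr5
        cds_end = exonic[-1][1] - utr3
        genes.append(
            GeneModel(
                name=f"gene{k + 1:04d}", chrom=cfg.chrom, start=start, end=end,
                strand=strand, exon_starts=ex_starts, exon_ends=ex_ends,
                cds_start=cds_start, cds_end=cds_end,
            )
        )
    return genes


def _simulate_islands(
    cfg: SimulationConfig, rng: np.random.Generator, sites_per_cluster: dict[int, np.ndarray]
) -> list[GenomicInterval]:
    islands = []
    anchors = rng.choice(cfg.n_clusters_true, size=min(cfg.n_islands // 2, cfg.n_clusters_true), replace=False)
    for k in anchors:
        pos = sites_per_cluster[int(k)]
        pad = int(rng.integers(50, 300))
        islands.append(GenomicInterval(cfg.chrom, max(0, int(pos.min()) - pad), int(pos.max()) + pad,
                                       name=f"island_c{k}"))
    n_rand = cfg.n_islands - len(islands)
    starts = rng.integers(0, cfg.chrom_length - 2000, size=n_rand)
    for j, s in enumerate(sorted(starts)):
        length = int(rng.integers(300, 1500))
        islands.append(GenomicInterval(cfg.chrom, int(s), int(s) + length, name=f"island_r{j}"))
    islands.sort(key=lambda iv: (iv.chrom, iv.start))
    return islands


def _simulate_expression(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    design: SampleDesign,
    sites_per_cluster: dict[int, np.ndarray],
    categories: dict[int, str],
    cluster_means: dict[int, np.ndarray],
):
    samples = design.samples
    n_samp = len(samples)
    is_ko = (design.frame["genotype"] == "KO").to_numpy()
    is_hdm = (design.frame["treatment"] == "HDM").to_numpy()

    # cis probes attach to planted DMR clusters (HDM-specific first, then
    # baseline, then any planted cluster) — these are the clusters a gated
    # cis scan would test
    pref = sorted(k for k, c in categories.items() if c == "hdm")
    pref += sorted(k for k, c in categories.items() if c == "baseline")
    if not pref:  # no effect-bearing clusters: fall back to arbitrary ones
        pref = sorted(sites_per_cluster)
    cis_clusters = [pref[i % len(pref)] for i in range(cfg.n_cis_true)] if pref else []

    base = rng.normal(8.0, 1.0, size=cfg.n_probes)
    values = base[:, None] + rng.normal(0.0, cfg.expr_noise_sd, size=(cfg.n_probes, n_samp))
    probe_pos = rng.integers(0, cfg.chrom_length - 60, size=cfg.n_probes)

    cis_rows, de_rows = [], []
    for j, k in enumerate(cis_clusters):
        sign = -1 if j % 2 else 1
        y = cluster_means[k]
        values[j] += sign * cfg.cis_slope * (y - y.mean())
        pos = sites_per_cluster[k]
        mid = int(0.5 * (pos.min() + pos.max()))
        probe_pos[j] = int(np.clip(mid + rng.integers(-400_000, 400_000), 0, cfg.chrom_length - 60))
        cis_rows.append((cfg.chrom, int(pos.min()), int(pos.max()) + 2, int(k), f"probe{j + 1:05d}", sign))

    n_cis = len(cis_clusters)
    de_idx = np.arange(n_cis, n_cis + cfg.n_de_true + cfg.n_de_baseline)
    if len(de_idx) and de_idx.max() >= cfg.n_probes:
        raise ConfigurationError("n_probes too small for planted cis + DE probes")
    for rank, j in enumerate(de_idx):
        sign = -1 if rank % 2 else 1
        if rank < cfg.n_de_true:
            values[j, is_ko & is_hdm] += sign * cfg.de_log2fc
            de_rows.append((f"probe{j + 1:05d}", "hdm", sign))
        else:
            values[j, is_ko] += sign * cfg.de_log2fc
            de_rows.append((f"probe{j + 1:05d}", "baseline", sign))

    probe_ids = [f"probe{i + 1:05d}" for i in range(cfg.n_probes)]
    frame = pd.DataFrame(values, index=probe_ids, columns=samples)
    probes = pd.DataFrame(
        {
            "probe": probe_ids,
            "chrom": cfg.chrom,
            "start": probe_pos.astype(int),
            "end": probe_pos.astype(int) + 60,
            "testable": True,
        }
    )
    expr = ExpressionMatrix(values=frame, probes=probes)
    return expr, cis_rows, de_rows


def simulate_strain_snps(config: SimulationConfig, design: SampleDesign | None = None) -> pd.DataFrame:
    """Strain-informative SNP panel with a per-sample alternate-strain match
    indicator. Inside the contaminated block, KO samples match the alternate
    strain at a high rate; WT samples and all samples elsewhere match only at
    the background genotyping-noise rate."""
    cfg = config
    cfg.validate()
    if design is None:
        design = _make_design(cfg.n_per_group)
    rng = np.random.default_rng([cfg.seed, 23])
    pos = np.arange(cfg.snp_spacing // 2, cfg.chrom_length, cfg.snp_spacing, dtype=int)
    inside = np.zeros(len(pos), dtype=bool)
    if cfg.contam_region is not None:
        _, cs, ce = cfg.contam_region
        inside = (pos >= cs) & (pos < ce)
    panel = {"chrom": [cfg.chrom] * len(pos), "pos": pos}
    is_ko = (design.frame["genotype"] == "KO").to_numpy()
    for j, sample in enumerate(design.samples):
        rate = np.where(inside & is_ko[j], cfg.contam_match_rate, cfg.background_match_rate)
        panel[sample] = rng.binomial(1, rate)
    return pd.DataFrame(panel)


def write_dataset(ds: SimulatedDataset, out_dir: str | Path, dialect: str = "bed-0-based") -> dict[str, Path]:
    """Write every component of a simulated dataset to ``out_dir``; returns a
    name -> path map. Output is deterministic for a fixed config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cov_dir = out / "coverage"
    cov_dir.mkdir(exist_ok=True)
    for s in ds.design.samples:
        p = cov_dir / f"{s}.cov.tsv"
        write_coverage(ds.counts, s, p, dialect=dialect)
        paths[f"coverage/{s}"] = p

    paths["sample_sheet"] = out / "samples.tsv"
    write_sample_sheet(ds.design, paths["sample_sheet"])

    paths["expression"] = out / "expression.tsv"
    paths["probe_bed"] = out / "probes.bed"
    # write on the raw intensity scale; the pipeline applies log2(x + 1)
    raw = ds.expression.values.apply(lambda v: np.power(2.0, v) - 1.0)
    raw_mat = ExpressionMatrix(values=raw, probes=ds.expression.probes.copy())
    write_expression(raw_mat, paths["expression"], paths["probe_bed"])

    paths["genes"] = out / "genes.tsv"
    write_gene_models(ds.genes, paths["genes"])
    paths["islands"] = out / "islands.bed"
    write_bed(ds.islands, paths["islands"])
    paths["snp_panel"] = out / "snp_panel.tsv"
    write_snp_panel(ds.snp_panel, paths["snp_panel"])

    t = ds.truth
    paths["truth_dmrs"] = out / "truth_dmrs.tsv"
    t.true_dmr_intervals.to_csv(paths["truth_dmrs"], sep="\t", index=False)
    paths["truth_cis"] = out / "truth_cis_pairs.tsv"
    t.true_cis_pairs.to_csv(paths["truth_cis"], sep="\t", index=False)
    paths["truth_de"] = out / "truth_de_probes.tsv"
    t.true_de_probes.to_csv(paths["truth_de"], sep="\t", index=False)
    if t.contam_region is not None:
        paths["truth_contam"] = out / "truth_contam.bed"
        write_bed([t.contam_region], paths["truth_contam"])
    return paths
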