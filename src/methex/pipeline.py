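"""End-to-end pipeline orchestration.

One configuration object drives every stage: (optional) synthetic-data
generation -> coverage ingest -> adjacent-site clustering -> DMR testing
under the treated and baseline contrasts -> strain blacklist -> baseline
subtraction -> annotation -> expression contrasts -> cis scan ->
enrichment. All outputs land in a run directory together with a
machine-readable run report carrying the config hash, the seed, and the
count at every filter step. Identical config and seed reproduce identical
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import aclust, annotate, dmr_stats, expression_de, meqtr, sim_data
from .io_core import (
    ConfigurationError,
    GenomicInterval,
    read_bed,
    read_coverage,
    read_expression,
    read_gene_models,
    read_sample_sheet,
    read_snp_panel,
    write_bed,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """All stage parameters and input paths.

    With ``simulate`` True the input files are generated into the run
    directory from ``sim`` before the analysis stages run; otherwise the
    explicit paths must exist.
    """

    simulate: bool = True
    sim: sim_data.SimulationConfig = field(default_factory=sim_data.SimulationConfig)
    # explicit inputs (ignored when simulate=True)
    sample_sheet: str | None = None
    coverage_dir: str | None = None
    coverage_dialect: str = "bismark-1-based"
    expression: str | None = None
    probe_bed: str | None = None
    genes: str | None = None
    islands: str | None = None
    snp_panel: str | None = None
    # clustering
    max_gap_bp: int = 1000
    corr_threshold: float = 0.3
    min_sites: int = 3
    min_depth: int = 5
    # contrasts and thresholds
    contrast: str = "KO_HDM:WT_HDM"
    baseline_contrast: str = "KO_saline:WT_saline"
    q_dmr: float = 0.10
    q_de: float = 0.05
    q_meqtr: float = 0.05
    p_gate: float = 0.05
    window_bp: int = 1_000_000
    subset_distance_bp: int = 25_000
    subset_genes: list[str] = field(default_factory=list)
    promoter_bp: int = 2000
    log2_offset: float = 1.0
    # blacklist
    blacklist: str = "auto"  # "auto", "none", or a BED path
    blacklist_window_bp: int = 1_000_000
    blacklist_step_bp: int = 500_000
    blacklist_match_frac: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_dmr", "q_de", "q_meqtr", "p_gate"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1], got {v}")
        for name in ("max_gap_bp", "window_bp", "subset_distance_bp", "promoter_bp"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        self.sim.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["contam_region"] = (
            list(d["sim"]["contam_region"]) if d["sim"]["contam_region"] else None
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim_d = dict(d.pop("sim", {}))
        if sim_d.get("contam_region"):
            sim_d["contam_region"] = tuple(sim_d["contam_region"])
        return cls(sim=sim_data.SimulationConfig(**sim_d), **d)

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict | None = None) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key, value in (overrides or {}).items():
            target = d
            parts = key.split(".")
            for p in parts[:-1]:
                target = target.setdefault(p, {})
            target[parts[-1]] = value
        return cls.from_dict(d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise ConfigurationError(f"missing input path: {what}")
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"input file not found: {what} = {p}")
    return p


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns the run report (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": {},
        "enrichment": [],
    }
    counts = report["counts"]

    # ---- inputs -----------------------------------------------------------
    if config.simulate:
        ds = sim_data.simulate_dataset(config.sim)
        data_dir = out / "data"
        sim_data.write_dataset(ds, data_dir)
        design = ds.design
        cov_paths = {s: data_dir / "coverage" / f"{s}.cov.tsv" for s in design.samples}
        table = read_coverage(cov_paths, design, dialect="bed-0-based")
        expr_raw = read_expression(data_dir / "expression.tsv", data_dir / "probes.bed", design)
        genes = ds.genes
        islands = ds.islands
        panel = ds.snp_panel
    else:
        design = read_sample_sheet(_require(config.sample_sheet, "sample_sheet"))
        cov_dir = _require(config.coverage_dir, "coverage_dir")
        cov_paths = {s: cov_dir / f"{s}.cov.tsv" for s in design.samples}
        table = read_coverage(cov_paths, design, dialect=config.coverage_dialect)
        expr_raw = read_expression(
            _require(config.expression, "expression"),
            _require(config.probe_bed, "probe_bed"),
            design,
        )
        genes = read_gene_models(_require(config.genes, "genes"))
        islands = read_bed(_require(config.islands, "islands"))
        panel = read_snp_panel(_require(config.snp_panel, "snp_panel")) if config.snp_panel else pd.DataFrame()

    counts["sites"] = int(table.n_sites)
    counts["samples"] = len(design.samples)

    # ---- clustering -------------------------------------------------------
    clusters = aclust.cluster_adjacent_sites(
        table, config.max_gap_bp, config.corr_threshold, config.min_sites, config.min_depth
    )
    aclust.summarize_clusters(clusters, table)
    counts["clusters_formed"] = len(clusters)
    aclust.clusters_to_frame(clusters).to_csv(out / "clusters.tsv", sep="\t", index=False, float_format="%.6g")

    # ---- DMR testing: treated and baseline contrasts ----------------------
    treated = dmr_stats.call_dmrs(clusters, design, config.contrast, config.q_dmr, genes)
    baseline = dmr_stats.call_dmrs(clusters, design, config.baseline_contrast, config.q_dmr, genes)
    counts["clusters_tested"] = int(treated["p_raw"].notna().sum()) if not treated.empty else 0
    counts["dmrs_called"] = int(treated["called"].sum()) if not treated.empty else 0
    counts["baseline_dmrs_called"] = int(baseline["called"].sum()) if not baseline.empty else 0

    # ---- strain blacklist -------------------------------------------------
    if config.blacklist == "auto" and not panel.empty:
        blacklist = dmr_stats.detect_strain_blacklist(
            panel, design, config.blacklist_window_bp, config.blacklist_step_bp,
            config.blacklist_match_frac,
        )
    elif config.blacklist not in ("auto", "none"):
        blacklist = read_bed(config.blacklist)
    else:
        blacklist = []
    write_bed(blacklist, out / "blacklist.bed")
    counts["blacklist_regions"] = len(blacklist)

    # ---- filters ----------------------------------------------------------
    treated = dmr_stats.subtract_baseline(treated, baseline)
    treated = dmr_stats.apply_blacklist(treated, blacklist)
    called = treated[treated["called"]] if not treated.empty else treated
    n_base = int((called["baseline_shared"]).sum()) if not called.empty else 0
    n_black = int((called["blacklisted"] & ~called["baseline_shared"]).sum()) if not called.empty else 0
    final = dmr_stats.final_calls(treated)
    counts["baseline_shared_removed"] = n_base
    counts["blacklisted_removed"] = n_black
    counts["dmrs_final"] = len(final)
    treated.to_csv(out / "dmr_full.tsv", sep="\t", index=False, float_format="%.6g")
    baseline.to_csv(out / "dmr_baseline.tsv", sep="\t", index=False, float_format="%.6g")
    write_bed(
        [GenomicInterval(r.chrom, int(r.start), int(r.end), name=f"dmr{r.cluster_id}")
         for r in final.itertuples()],
        out / "dmr_calls.bed",
    )

    # ---- annotation -------------------------------------------------------
    annotated = annotate.annotate_table(final, genes, islands, config.promoter_bp)
    annotated.to_csv(out / "dmr_annotated.tsv", sep="\t", index=False, float_format="%.6g")
    anns = [
        annotate.DMRAnnotation(r.gene_context, r.island_context, r.nearest_gene,
                               r.gene_distance, r.length_bp)
        for r in annotated.itertuples()
    ]
    summary = annotate.genomic_distribution_summary(anns)
    summary.to_csv(out / "dmr_context_summary.tsv", sep="\t", index=False, float_format="%.6g")
    counts["hypo_dmrs"] = int((final["direction"] == "hypo").sum()) if not final.empty else 0

    # ---- optional gene-subset analysis ------------------------------------
    if config.subset_genes:
        sub = dmr_stats.subset_near_genes(
            treated, genes, config.subset_genes, config.subset_distance_bp, config.q_dmr
        )
        sub.to_csv(out / "dmr_subset.tsv", sep="\t", index=False, float_format="%.6g")
        counts["subset_clusters"] = len(sub)
        counts["subset_called"] = int(sub["called_subset"].sum()) if not sub.empty else 0

    # ---- expression -------------------------------------------------------
    expr_log = expression_de.log2_transform(expr_raw, config.log2_offset)
    expr_norm = expression_de.quantile_normalize(expr_log)
    de = expression_de.differential_expression(
        expr_norm, design, config.contrast, config.baseline_contrast, config.q_de
    )
    de.to_csv(out / "de.tsv", sep="\t", index=False, float_format="%.6g")
    counts["probes_total"] = len(de)
    counts["de_called"] = int((de["p_adj"] < config.q_de).sum())
    counts["de_baseline_removed"] = int(((de["p_adj"] < config.q_de) & de["baseline_shared"]).sum())
    counts["de_final"] = int(de["significant"].sum())

    # ---- cis scan ---------------------------------------------------------
    hdm_samples = [s for s in design.samples
                   if design.frame.set_index("sample").loc[s, "treatment"] == "HDM"]
    scan = meqtr.cis_scan(
        treated, clusters, expr_norm, design, samples=hdm_samples,
        p_gate=config.p_gate, window_bp=config.window_bp, q_threshold=config.q_meqtr,
    )
    scan.to_csv(out / "meqtr.tsv", sep="\t", index=False, float_format="%.6g")
    counts["clusters_gated"] = int((treated["p_raw"] < config.p_gate).sum()) if not treated.empty else 0
    counts["pairs_tested"] = len(scan)
    counts["pairs_significant"] = int(scan["significant"].sum()) if not scan.empty else 0

    enr = meqtr.enrichment_tests(scan)
    # direction balance of the surviving DMRs (hypomethylation enrichment)
    n_hypo = counts["hypo_dmrs"]
    if len(final):
        enr.append(
            meqtr.binomial_enrichment(n_hypo, len(final), 0.5, "greater",
                                      test="hypomethylated_dmrs")
        )
    report["enrichment"] = [dataclasses.asdict(e) for e in enr]
    pd.DataFrame(report["enrichment"]).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("run complete: %s", json.dumps(counts))
    return report
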