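"""Cluster-level differential-methylation testing and downstream filters.

Each methylation cluster is tested with a depth-weighted beta regression of
its per-sample pooled proportion on a group indicator; Benjamini-Hochberg
correction is applied across all fitted clusters and calls are made at an
inclusive adjusted-p threshold (default q <= 0.10). Two provenance filters
follow: subtraction of DMRs shared with the baseline (saline) contrast —
matched by physical overlap or by shared nearest gene — and exclusion of
DMRs inside genomic blocks where the knockout line carries an alternate
strain background, detected from a strain-informative SNP panel.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

from .aclust import MethylationCluster
from .betareg import fit_beta_regression
from .io_core import GeneModel, GenomicInterval, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "bh_adjust",
    "call_dmrs",
    "subtract_baseline",
    "detect_strain_blacklist",
    "apply_blacklist",
    "subset_near_genes",
    "nearest_gene",
]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nearest_gene(
    interval: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[str | None, float]:
    """Gene with minimum distance from the interval midpoint to the gene
    body (0 if the midpoint falls inside); ties broken by gene name."""
    mid = interval.midpoint
    best: tuple[float, str] | None = None
    for g in genes:
        if g.chrom != interval.chrom:
            continue
        if g.start <= mid < g.end:
            d = 0.0
        else:
            d = min(abs(mid - g.start), abs(mid - (g.end - 1)))
        if best is None or (d, g.name) < best:
            best = (d, g.name)
    if best is None:
        return None, np.inf
    return best[1], best[0]


def call_dmrs(
    clusters: list[MethylationCluster],
    design: SampleDesign,
    contrast: str,
    q_threshold: float = 0.10,
    genes: Sequence[GeneModel] | None = None,
) -> pd.DataFrame:
    """Test every eligible cluster for the given contrast (``"KO_HDM:WT_HDM"``
    style: group A vs group B) and BH-adjust across all fitted clusters.

    Returns the full per-cluster table; called DMRs are the rows with
    ``called`` True (p_adj <= q_threshold, inclusive). Clusters skipped for
    lack of data carry a ``skip_reason``. ``direction`` is ``hypo`` when
    group A (first in the contrast, conventionally KO) is less methylated.
    """
    group_a, group_b = design.parse_contrast(contrast)
    rows = []
    for k, cl in enumerate(clusters):
        if cl.pooled_meth is None:
            raise ValueError("clusters must be summarized before testing")
        samp_index = {s: j for j, s in enumerate(cl.samples)}
        sel = [samp_index[s] for s in group_a + group_b]
        grp = np.array([1.0] * len(group_a) + [0.0] * len(group_b))
        y = cl.y[sel]
        d = cl.pooled_depth[sel].astype(float)
        ok = ~np.isnan(y) & (d > 0)
        row: dict = {
            "cluster_id": k,
            "chrom": cl.chrom,
            "start": int(cl.sites.min()),
            "end": int(cl.sites.max()) + 2,
            "n_sites": cl.n_sites,
        }
        if (grp[ok] == 1).sum() < 2 or (grp[ok] == 0).sum() < 2:
            row.update(
                beta1=np.nan, se=np.nan, z=np.nan, p_raw=np.nan, converged=False,
                skip_reason="fewer than 2 samples with data in a group",
            )
        else:
            X = np.column_stack([np.ones(ok.sum()), grp[ok]])
            fit = fit_beta_regression(y[ok], d[ok], X)
            row.update(
                beta1=fit.beta1, se=fit.se_beta1, z=fit.z, p_raw=fit.p,
                converged=fit.converged, skip_reason="",
            )
        if genes is not None:
            name, dist = nearest_gene(
                GenomicInterval(cl.chrom, int(cl.sites.min()), int(cl.sites.max()) + 2), genes
            )
            row["nearest_gene"] = name
            row["gene_distance"] = dist
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        logger.warning("no eligible clusters to test")
        return table

    fitted = table["p_raw"].notna()
    table["p_adj"] = np.nan
    if fitted.any():
        table.loc[fitted, "p_adj"] = bh_adjust(table.loc[fitted, "p_raw"])
    table["direction"] = np.where(table["beta1"] < 0, "hypo", "hyper")
    table.loc[table["beta1"].isna(), "direction"] = ""
    table["called"] = fitted & (table["p_adj"] <= q_threshold)
    table["baseline_shared"] = False
    table["blacklisted"] = False
    return table


def _interval_tree(frame: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in frame.itertuples():
        trees.setdefault(r.chrom, IntervalTree()).addi(int(r.start), int(r.end), r.Index)
    return trees


def subtract_baseline(treated: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Flag treated DMRs shared with the baseline contrast's calls, by
    physical overlap (>= 1 bp) or by shared nearest gene. Flagged rows keep
    their statistics but are dropped from the headline call set (``called``
    stays True only for unshared rows; the flag records why)."""
    out = treated.copy()
    base_called = baseline[baseline["called"]] if "called" in baseline.columns else baseline
    if base_called.empty:
        return out
    trees = _interval_tree(base_called)
    base_genes = set()
    if "nearest_gene" in base_called.columns:
        base_genes = set(base_called["nearest_gene"].dropna()) - {None, ""}

    shared = []
    for r in out.itertuples():
        hit = False
        tree = trees.get(r.chrom)
        if tree is not None and tree.overlap(int(r.start), int(r.end)):
            hit = True
        if not hit and base_genes and getattr(r, "nearest_gene", None) in base_genes:
            hit = True
        shared.append(hit)
    out["baseline_shared"] = np.asarray(shared, dtype=bool)
    return out


def detect_strain_blacklist(
    panel: pd.DataFrame,
    design: SampleDesign,
    window_bp: int = 1_000_000,
    step_bp: int = 500_000,
    match_frac: float = 0.9,
) -> list[GenomicInterval]:
    """Scan the strain-informative SNP panel in sliding windows and flag
    windows where KO samples match the alternate strain at rate >=
    ``match_frac`` while WT samples match at rate <= 1 - ``match_frac``
    (group specificity is required); overlapping flagged windows are merged
    into maximal intervals. Windows without informative SNPs are skipped."""
    if panel.empty:
        return []
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    ko = [s for s in design.samples if design.genotype_of(s) == "KO" and s in panel.columns]
    wt = [s for s in design.samples if design.genotype_of(s) == "WT" and s in panel.columns]
    flagged: list[GenomicInterval] = []
    for chrom, sub in panel.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        ko_m = sub[ko].to_numpy()
        wt_m = sub[wt].to_numpy()
        last = int(pos.max())
        for start in range(0, last + 1, step_bp):
            in_w = (pos >= start) & (pos < start + window_bp)
            if not in_w.any():
                continue
            ko_frac = ko_m[in_w].mean() if ko else 0.0
            wt_frac = wt_m[in_w].mean() if wt else 1.0
            if ko_frac >= match_frac and wt_frac <= 1.0 - match_frac:
                flagged.append(GenomicInterval(str(chrom), start, start + window_bp))
    return _merge_intervals(flagged)


def _merge_intervals(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
    merged: list[GenomicInterval] = []
    for iv in sorted(ivs, key=lambda v: (v.chrom, v.start)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged.pop()
            merged.append(GenomicInterval(last.chrom, last.start, max(last.end, iv.end)))
        else:
            merged.append(iv)
    return merged


def apply_blacklist(table: pd.DataFrame, blacklist: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Flag DMRs whose interval overlaps any blacklisted region."""
    out = table.copy()
    if out.empty or not blacklist:
        return out
    trees: dict[str, IntervalTree] = {}
    for iv in blacklist:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    out["blacklisted"] = [
        bool(trees.get(r.chrom) and trees[r.chrom].overlap(int(r.start), int(r.end)))
        for r in out.itertuples()
    ]
    return out


def final_calls(table: pd.DataFrame) -> pd.DataFrame:
    """Called DMRs surviving both the baseline and blacklist filters."""
    if table.empty:
        return table
    return table[table["called"] & ~table["baseline_shared"] & ~table["blacklisted"]]


def subset_near_genes(
    table: pd.DataFrame,
    genes: Sequence[GeneModel],
    gene_names: Sequence[str],
    distance_bp: int = 25_000,
    q_threshold: float = 0.10,
) -> pd.DataFrame:
    """Subset analysis: clusters whose interval lies within ``distance_bp``
    of a listed gene's body (boundary inclusive; 0 if overlapping), with BH
    re-applied within the subset only. Returns the subset table with
    ``p_adj_subset`` and ``called_subset`` (p_adj <= q, inclusive).
    Unresolvable gene names are warned about and skipped."""
    by_name = {g.name: g for g in genes}
    targets = []
    missing = []
    for name in gene_names:
        g = by_name.get(name)
        (targets if g is not None else missing).append(g if g is not None else name)
    if missing:
        logger.warning("gene names not found in gene models, skipped: %s", missing)
    if not targets or table.empty:
        return table.iloc[0:0].assign(p_adj_subset=[], called_subset=[])

    keep = []
    for r in table.itertuples():
        iv = GenomicInterval(r.chrom, int(r.start), int(r.end))
        near = False
        for g in targets:
            d = iv.distance_to(g.interval)
            if d is not None and d <= distance_bp:
                near = True
                break
        keep.append(near)
    sub = table[np.asarray(keep)].copy()
    fitted = sub["p_raw"].notna()
    sub["p_adj_subset"] = np.nan
    if fitted.any():
        sub.loc[fitted, "p_adj_subset"] = bh_adjust(sub.loc[fitted, "p_raw"])
    sub["called_subset"] = fitted & (sub["p_adj_subset"] <= q_threshold)
    return sub
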