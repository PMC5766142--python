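"""Adjacent-site clustering: group correlated neighbouring CpG sites into
methylation clusters and summarize each cluster per sample.

The algorithm is a deterministic bottom-up agglomeration within each
chromosome. Every site starts as a singleton cluster; an adjacent pair of
clusters is merged when (a) the genomic gap between their nearest member
sites is at most ``max_gap_bp`` and (b) the between-cluster similarity —
complete linkage, i.e. the *minimum* Spearman correlation of per-site
methylation proportions over all cross pairs of member sites — is at least
``corr_threshold``. Merging sweeps left to right and repeats until stable;
clusters with fewer than ``min_sites`` sites are then discarded.

Correlations are computed across samples with read depth >= ``min_depth`` at
both sites; a pair with fewer than 3 such samples is treated as
uncorrelatable (never merged across).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CpGCountTable, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = ["MethylationCluster", "cluster_adjacent_sites", "summarize_clusters", "site_correlation"]


@dataclass
class MethylationCluster:
    """An ordered run of >=3 correlated adjacent CpG sites.

    The interval spans min site position to max site position + 2, covering
    the final CG dinucleotide. ``pooled_meth``/``pooled_depth`` (per sample)
    and ``y`` (pooled proportion) are filled by :func:`summarize_clusters`;
    samples with zero pooled depth are flagged missing.
    """

    chrom: str
    sites: np.ndarray  # ordered site positions
    samples: list[str] = field(default_factory=list)
    pooled_meth: np.ndarray | None = None
    pooled_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=int)
        if np.any(np.diff(self.sites) <= 0):
            raise ValueError("cluster sites must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, int(self.sites.min()), int(self.sites.max()) + 2)

    @property
    def y(self) -> np.ndarray:
        """Per-sample pooled methylation proportion (NaN where missing)."""
        if self.pooled_meth is None:
            raise ValueError("cluster not summarized")
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.pooled_depth > 0, self.pooled_meth / self.pooled_depth, np.nan
            )

    @property
    def missing(self) -> np.ndarray:
        if self.pooled_depth is None:
            raise ValueError("cluster not summarized")
        return self.pooled_depth == 0


def site_correlation(
    m1: np.ndarray, d1: np.ndarray, m2: np.ndarray, d2: np.ndarray, min_depth: int
) -> float | None:
    """Spearman correlation of two sites' methylation proportions across the
    samples with depth >= min_depth at both; None if fewer than 3 such
    samples or either proportion is constant."""
    ok = (d1 >= min_depth) & (d2 >= min_depth)
    if ok.sum() < 3:
        return None
    p1 = m1[ok] / d1[ok]
    p2 = m2[ok] / d2[ok]
    if np.all(p1 == p1[0]) or np.all(p2 == p2[0]):
        return None
    rho = stats.spearmanr(p1, p2).statistic
    return None if np.isnan(rho) else float(rho)


def cluster_adjacent_sites(
    table: CpGCountTable,
    max_gap_bp: int = 1000,
    corr_threshold: float = 0.3,
    min_sites: int = 3,
    min_depth: int = 5,
) -> list[MethylationCluster]:
    """Cluster correlated adjacent CpG sites; see the module docstring for
    the merge rule. Output clusters are non-overlapping and position-ordered;
    results do not depend on sample order."""
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    if not (-1.0 <= corr_threshold <= 1.0):
        raise ValueError("corr_threshold must be in [-1, 1]")

    clusters: list[MethylationCluster] = []
    n_uncorrelatable = 0
    for chrom in sorted(pd.unique(table.chrom)):
        idx = np.where(table.chrom == chrom)[0]
        pos = table.pos[idx]
        meth = table.meth[idx]
        depth = table.depth[idx]

        corr_cache: dict[tuple[int, int], float | None] = {}

        def corr(i: int, j: int) -> float | None:
            key = (i, j) if i < j else (j, i)
            if key not in corr_cache:
                corr_cache[key] = site_correlation(
                    meth[i], depth[i], meth[j], depth[j], min_depth
                )
            return corr_cache[key]

        def mergeable(left: list[int], right: list[int]) -> bool:
            if pos[right[0]] - pos[left[-1]] > max_gap_bp:
                return False
            nonlocal n_uncorrelatable
            for i in left:
                for j in right:
                    r = corr(i, j)
                    if r is None:
                        n_uncorrelatable += 1
                        return False
                    if r < corr_threshold:
                        return False
            return True

        # greedy left-to-right sweep; with complete linkage a merge can never
        # make a previously unmergeable upstream pair mergeable, so a single
        # stay-in-place sweep reaches the fixed point
        groups: list[list[int]] = [[i] for i in range(len(idx))]
        k = 0
        while k < len(groups) - 1:
            if mergeable(groups[k], groups[k + 1]):
                groups[k] = groups[k] + groups.pop(k + 1)
            else:
                k += 1

        for g in groups:
            if len(g) >= min_sites:
                clusters.append(MethylationCluster(chrom=chrom, sites=pos[g]))

    if n_uncorrelatable:
        logger.warning(
            "%d site pairs lacked 3 samples with adequate depth (or were constant); treated as uncorrelatable",
            n_uncorrelatable,
        )
    return clusters


def summarize_clusters(
    clusters: list[MethylationCluster], table: CpGCountTable
) -> list[MethylationCluster]:
    """Fill per-sample pooled counts: M_s = sum of member-site methylated
    counts, D_s = sum of member-site depths; y_s = M_s / D_s."""
    # index site rows by (chrom, pos)
    key = {(c, int(p)): i for i, (c, p) in enumerate(zip(table.chrom, table.pos))}
    for cl in clusters:
        rows = [key[(cl.chrom, int(p))] for p in cl.sites]
        cl.samples = list(table.samples)
        cl.pooled_meth = table.meth[rows].sum(axis=0)
        cl.pooled_depth = table.depth[rows].sum(axis=0)
    return clusters


def clusters_to_frame(clusters: list[MethylationCluster]) -> pd.DataFrame:
    """Tabular view of summarized clusters: one row per cluster with interval,
    site list, and per-sample y and D columns."""
    rows = []
    for k, cl in enumerate(clusters):
        row: dict = {
            "cluster_id": k,
            "chrom": cl.chrom,
            "start": int(cl.sites.min()),
            "end": int(cl.sites.max()) + 2,
            "n_sites": cl.n_sites,
            "sites": ",".join(map(str, cl.sites)),
        }
        if cl.pooled_meth is not None:
            y = cl.y
            for j, s in enumerate(cl.samples):
                row[f"y_{s}"] = y[j]
                row[f"D_{s}"] = int(cl.pooled_depth[j])
        rows.append(row)
    return pd.DataFrame(rows)
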