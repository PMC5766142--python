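"""cis methylation-expression association scan and enrichment statistics.

Candidate clusters are those with an uncorrected differential-methylation
p-value below a gate (strict <, default 0.05); candidate pairs are
(cluster, probe) combinations on the same chromosome with midpoint distance
at most the cis window (default 1 Mb). For each pair, cluster methylation is
regressed on probe expression with genotype as an additive covariate, using
the same depth-weighted beta regression as the DMR stage (methylation is
the response, expression the predictor). BH correction runs across all
tested pairs; significance is strict (p_adj < q).

Enrichment statistics are one- or two-sided exact binomial tail tests: the
excess of negative (canonically anti-correlated) methylation-expression
coefficients against a 0.5 null, the excess of nominally significant pairs
against the nominal rate, and the sign balance among significant pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aclust import MethylationCluster
from .betareg import fit_beta_regression
from .dmr_stats import bh_adjust
from .io_core import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = ["MeQTRResult", "EnrichmentResult", "cis_scan", "enrichment_tests", "binomial_enrichment"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Exact binomial tail test of a count against a null proportion."""

    test: str
    n_total: int
    n_in_class: int
    null_proportion: float
    p: float
    alternative: str


def binomial_enrichment(
    n_in_class: int, n_total: int, null_proportion: float,
    alternative: str = "greater", test: str = "",
) -> EnrichmentResult:
    """Exact binomial tail (scipy.stats.binomtest)."""
    res = stats.binomtest(n_in_class, n_total, null_proportion, alternative=alternative)
    return EnrichmentResult(
        test=test, n_total=n_total, n_in_class=n_in_class,
        null_proportion=null_proportion, p=float(res.pvalue), alternative=alternative,
    )


@dataclass(frozen=True)
class MeQTRResult:
    cluster_id: int
    chrom: str
    start: int
    end: int
    probe: str
    distance_bp: float
    coef: float
    sign: str
    p_raw: float
    p_adj: float


def cis_scan(
    cluster_table: pd.DataFrame,
    clusters: list[MethylationCluster],
    expr: ExpressionMatrix,
    design: SampleDesign,
    samples: list[str] | None = None,
    p_gate: float = 0.05,
    window_bp: int = 1_000_000,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Scan all cis (cluster, probe) pairs; returns one row per tested pair.

    ``cluster_table`` is the full per-cluster DMR table (carries ``p_raw``
    from the treated contrast, used as the gate). ``samples`` restricts the
    regression to a sample subset (e.g. the treated arm); genotype is always
    included as a covariate, so the association is adjusted for knockout
    status. Distance is midpoint to midpoint. Probes without coordinates are
    excluded and counted in the log.
    """
    if samples is None:
        samples = design.samples
    gated = cluster_table[cluster_table["p_raw"].notna() & (cluster_table["p_raw"] < p_gate)]
    if gated.empty:
        logger.warning("no clusters pass the p < %g gate; empty cis scan", p_gate)
        return _empty_scan()

    testable = expr.probes[expr.probes["testable"]]
    n_skipped = len(expr.probes) - len(testable)
    if n_skipped:
        logger.info("%d probes lack coordinates; excluded from cis scan", n_skipped)
    probe_mid = (testable["start"].to_numpy() + testable["end"].to_numpy()) / 2.0
    probe_chrom = testable["chrom"].to_numpy()
    probe_ids = testable["probe"].to_numpy()

    is_ko = np.array([design.genotype_of(s) == "KO" for s in samples], dtype=float)
    expr_vals = expr.values[samples]

    rows = []
    for r in gated.itertuples():
        cl = clusters[int(r.cluster_id)]
        mid = 0.5 * (r.start + r.end)
        near = (probe_chrom == r.chrom) & (np.abs(probe_mid - mid) <= window_bp)
        if not near.any():
            continue
        samp_index = {s: j for j, s in enumerate(cl.samples)}
        sel = [samp_index[s] for s in samples]
        y = cl.y[sel]
        d = cl.pooled_depth[sel].astype(float)
        for probe, dist in zip(probe_ids[near], np.abs(probe_mid[near] - mid)):
            e = expr_vals.loc[probe].to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(samples)), e, is_ko])
            fit = fit_beta_regression(y, d, X, test_index=1)
            rows.append(
                {
                    "cluster_id": int(r.cluster_id),
                    "chrom": r.chrom,
                    "start": int(r.start),
                    "end": int(r.end),
                    "probe": probe,
                    "distance_bp": float(dist),
                    "coef": fit.beta1,
                    "sign": "-" if fit.beta1 < 0 else "+",
                    "p_raw": fit.p,
                    "converged": fit.converged,
                }
            )
    if not rows:
        logger.warning("zero candidate cis pairs")
        return _empty_scan()
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"])
    table["significant"] = table["p_adj"] < q_threshold
    return table


def _empty_scan() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "cluster_id", "chrom", "start", "end", "probe", "distance_bp",
            "coef", "sign", "p_raw", "converged", "p_adj", "significant",
        ]
    )


def enrichment_tests(
    scan: pd.DataFrame, nominal_alpha: float = 0.05
) -> list[EnrichmentResult]:
    """The three headline enrichment statistics of a cis scan.

    (a) direction enrichment: one-sided excess of negative-coefficient pairs
    over a 0.5 null; (b) nominal-significance enrichment: one-sided excess
    of pairs with p_raw < ``nominal_alpha`` over a ``nominal_alpha`` null;
    (c) sign balance among significant pairs: two-sided test of the negative
    count against 0.5. Tests with an empty denominator are skipped.
    Additionally reports a Shapiro-Wilk normality check of the coefficient
    distribution (descriptive only, never a gate).
    """
    out: list[EnrichmentResult] = []
    n = len(scan)
    if n == 0:
        logger.warning("empty scan: enrichment tests skipped")
        return out
    n_neg = int((scan["sign"] == "-").sum())
    out.append(binomial_enrichment(n_neg, n, 0.5, "greater", test="anticorrelated_direction"))
    n_nom = int((scan["p_raw"] < nominal_alpha).sum())
    out.append(binomial_enrichment(n_nom, n, nominal_alpha, "greater", test="nominal_significance"))
    sig = scan[scan["significant"]]
    if len(sig):
        n_sig_neg = int((sig["sign"] == "-").sum())
        out.append(binomial_enrichment(n_sig_neg, len(sig), 0.5, "two-sided", test="significant_sign_balance"))
    else:
        logger.info("no significant pairs: sign-balance test skipped")
    coefs = scan["coef"].dropna()
    if len(coefs) >= 3:
        w = stats.shapiro(coefs)
        logger.info("coefficient normality (Shapiro-Wilk): W=%.4f p=%.3g", w.statistic, w.pvalue)
    return out
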