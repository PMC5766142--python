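"""Expression stage: quantile normalization, log2 transform, per-probe
cell-means contrasts with BH correction, and baseline gene subtraction.

The contrast framework is a two-factor (genotype x treatment) cell-means
linear model per probe: the tested difference between two cells uses the
pooled within-cell residual variance (df = n - number of occupied cells),
which for a saturated model equals the classical pooled-variance t-test on
the two cells' samples. Probes significant in the baseline (saline)
contrast are flagged and excluded from the headline list of the treated
contrast, mirroring the methylation-stage baseline subtraction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .dmr_stats import bh_adjust
from .io_core import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = ["quantile_normalize", "log2_transform", "cell_means_contrast", "differential_expression"]


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(x + offset) on raw intensities; offset avoids log of zero."""
    if (matrix.values.to_numpy() + offset <= 0).any():
        raise ValueError("negative intensities after offset")
    return ExpressionMatrix(values=np.log2(matrix.values + offset), probes=matrix.probes.copy())


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Classical rank-mean quantile normalization.

    Each sample column is sorted, the mean across samples is taken at each
    rank, and each value is replaced by the mean for its original rank; a
    run of tied values receives the mean of the rank means it spans. After
    normalization every column has the identical empirical distribution.
    """
    vals = matrix.values.to_numpy(dtype=float)
    n, k = vals.shape
    if k < 1:
        raise ValueError("need at least one sample column")
    rank_means = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(k):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        i = 0
        while i < n:
            h = i
            while h + 1 < n and col[order[h + 1]] == col[order[i]]:
                h += 1
            assigned[order[i : h + 1]] = rank_means[i : h + 1].mean()
            i = h + 1
        if np.all(col == col[0]):
            logger.warning("constant sample column %s quantile-normalized", matrix.values.columns[j])
        out[:, j] = assigned
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=frame, probes=matrix.probes.copy())


def cell_means_contrast(
    values: pd.DataFrame, design: SampleDesign, contrast: str
) -> pd.DataFrame:
    """Per-probe t-test of one cell difference under the cell-means model.

    Returns a frame with log2fc (cell A mean - cell B mean), t, df, p_raw;
    probes constant across all samples get p = 1 and a degenerate flag.
    """
    cells = {
        (g, t): design.group_samples(g, t)
        for g in ("WT", "KO")
        for t in ("saline", "HDM")
    }
    cells = {k: v for k, v in cells.items() if v}
    a, b = contrast.split(":")
    cell_a = tuple(a.split("_"))
    cell_b = tuple(b.split("_"))
    if cell_a not in cells or cell_b not in cells:
        raise ValueError(f"contrast {contrast!r} names an empty cell")

    X = values.to_numpy(dtype=float)
    n_total = sum(len(v) for v in cells.values())
    df_resid = n_total - len(cells)
    # pooled within-cell residual sum of squares
    rss = np.zeros(X.shape[0])
    for members in cells.values():
        sub = values[members].to_numpy(dtype=float)
        rss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = rss / df_resid
    ma = values[cells[cell_a]].to_numpy().mean(axis=1)
    mb = values[cells[cell_b]].to_numpy().mean(axis=1)
    na, nb = len(cells[cell_a]), len(cells[cell_b])
    se = np.sqrt(s2 * (1.0 / na + 1.0 / nb))
    degenerate = np.ptp(X, axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    p = 2.0 * stats.t.sf(np.abs(t), df_resid)
    p = np.where(se == 0, 1.0, p)
    t = np.where(se == 0, 0.0, t)
    p[degenerate] = 1.0
    return pd.DataFrame(
        {
            "probe": values.index,
            "log2fc": ma - mb,
            "t": t,
            "df": df_resid,
            "p_raw": p,
            "degenerate": degenerate,
        }
    ).set_index("probe", drop=False)


def differential_expression(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    contrast: str,
    baseline_contrast: str | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Probe-level differential expression with BH correction and baseline
    subtraction.

    ``matrix`` must already be normalized log2 intensities. Probes with
    p_adj < q in the baseline contrast are flagged ``baseline_shared`` and
    excluded from the headline set (``significant`` False) while staying in
    the full table.
    """
    res = cell_means_contrast(matrix.values, design, contrast)
    res["p_adj"] = bh_adjust(res["p_raw"])
    res["baseline_shared"] = False
    if baseline_contrast is not None:
        base = cell_means_contrast(matrix.values, design, baseline_contrast)
        base_adj = bh_adjust(base["p_raw"])
        res["baseline_shared"] = base_adj < q_threshold
    res["significant"] = (res["p_adj"] < q_threshold) & ~res["baseline_shared"]
    return res
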