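"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methex.io_core import CpGCountTable, SampleDesign
from methex.pipeline import PipelineConfig, run_all
from methex.sim_data import SimulationConfig, simulate_dataset


# ---------------------------------------------------------------------------
# independent brute-force re-implementation of the greedy clustering rule
# (restart-from-left repeat-until-stable formulation; kept deliberately
# separate from the production single-sweep implementation)
# ---------------------------------------------------------------------------

def brute_force_cluster(pos, meth, depth, max_gap_bp, corr_threshold, min_sites, min_depth):
    cache: dict = {}

    def pair_corr(i, j):
        if (i, j) in cache:
            return cache[(i, j)]
        ok = (depth[i] >= min_depth) & (depth[j] >= min_depth)
        if ok.sum() < 3:
            return None
        a = meth[i][ok] / depth[i][ok]
        b = meth[j][ok] / depth[j][ok]
        if np.all(a == a[0]) or np.all(b == b[0]):
            return None
        r = stats.spearmanr(a, b).statistic
        cache[(i, j)] = None if np.isnan(r) else r
        return cache[(i, j)]

    groups = [[i] for i in range(len(pos))]
    changed = True
    while changed:
        changed = False
        for k in range(len(groups) - 1):
            left, right = groups[k], groups[k + 1]
            if pos[right[0]] - pos[left[-1]] > max_gap_bp:
                continue
            mergeable = True
            for i in left:
                for j in right:
                    r = pair_corr(i, j)
                    if r is None or r < corr_threshold:
                        mergeable = False
                        break
                if not mergeable:
                    break
            if mergeable:
                groups[k : k + 2] = [left + right]
                changed = True
                break
    return [g for g in groups if len(g) >= min_sites]


def random_panel(rng, n_sites=30, n_samples=8, block_corr=0.9):
    """A random CpG panel with latent block structure so that merges occur."""
    gaps = rng.integers(10, 2500, size=n_sites - 1)
    pos = np.concatenate([[100], 100 + np.cumsum(gaps)]).astype(int)
    # latent blocks of 1-6 sites sharing a per-sample signal
    meth = np.zeros((n_sites, n_samples), dtype=int)
    depth = rng.integers(0, 60, size=(n_sites, n_samples))
    i = 0
    from scipy.special import expit
    while i < n_sites:
        w = int(rng.integers(1, 7))
        u = rng.normal(size=n_samples)
        for k in range(i, min(i + w, n_sites)):
            z = rng.normal(0, 0.6) + 1.2 * (
                np.sqrt(block_corr) * u + np.sqrt(1 - block_corr) * rng.normal(size=n_samples)
            )
            meth[k] = rng.binomial(depth[k], expit(z))
        i += w
    return pos, meth, depth


def make_table(pos, meth, depth, chrom="chrS"):
    samples = [f"s{j}" for j in range(meth.shape[1])]
    return CpGCountTable(
        chrom=np.array([chrom] * len(pos), dtype=object),
        pos=np.asarray(pos, dtype=int),
        samples=samples,
        meth=np.asarray(meth, dtype=int),
        depth=np.asarray(depth, dtype=int),
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_dataset():
    """One simulated dataset at the reference study conditions."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run at the reference conditions (seed 1)."""
    out = tmp_path_factory.mktemp("run")
    config = PipelineConfig(seed=1)
    report = run_all(config, out)
    return out, report


@pytest.fixture
def small_design():
    rows = []
    for g in ("WT", "KO"):
        for t in ("saline", "HDM"):
            for i in (1, 2, 3):
                rows.append((f"{g}_{t}_{i}", g, t))
    return SampleDesign(pd.DataFrame(rows, columns=["sample", "genotype", "treatment"]))
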