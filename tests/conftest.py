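"""Shared fixtures: small simulated cohorts and the toy filtering fixture."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epimark import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale cohort (3,000 probes) with planted effects, shared across
    read-only tests."""
    cfg = GeneratorConfig(n_probes=3000, n_differential=20, n_predictive=5,
                          seed=42)
    return generate_dataset(cfg)


@pytest.fixture()
def toy_filter_fixture():
    """Ten probes: 2 on chrX, 1 autosomal SNP-flagged, 1 autosomal probe
    failing detection in 2/10 samples -> 6 retained."""
    ids = [f"cg{i:08d}" for i in range(1, 11)]
    manifest = pd.DataFrame({
        "chrom": ["chrX", "chrX", "chr1", "chr2", "chr3", "chr4", "chr5",
                  "chr6", "chr7", "chr8"],
        "pos": np.arange(1000, 11000, 1000),
        "gene": [""] * 10,
        "design_type": ["II"] * 10,
        "snp_flag": [False, False, True, False, False, False, False, False,
                     False, False],
    }, index=pd.Index(ids, name="probe_id"))
    samples = [f"s{j}" for j in range(10)]
    rng = np.random.default_rng(0)
    beta = pd.DataFrame(rng.uniform(0.1, 0.9, (10, 10)), index=manifest.index,
                        columns=samples)
    detp = pd.DataFrame(np.full((10, 10), 0.001), index=manifest.index,
                        columns=samples)
    detp.loc[ids[3], ["s0", "s1"]] = 0.2  # fails in exactly 2/10 samples
    return beta, detp, manifest


def kw_permutation_midp(values: np.ndarray, n1: int, n_perm: int,
                        rng: np.random.Generator) -> float:
    """Independent permutation oracle for the two-group Kruskal-Wallis test.

    Computes the continuity-corrected (mid-p) permutation tail probability
    of H from first principles: midranks with tie correction, rank-sum
    resampling over random group relabelings.  Because ranks are invariant
    under permutation only the group-1 rank sum needs resampling.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    n2 = n - n1
    ranks = stats.rankdata(x)
    _, counts = np.unique(x, return_counts=True)
    correction = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    total = ranks.sum()

    def h_of(r1sum):
        h = 12.0 / (n * (n + 1)) * (r1sum ** 2 / n1 + (total - r1sum) ** 2 / n2) \
            - 3.0 * (n + 1)
        return h / correction

    h_obs = h_of(ranks[:n1].sum())
    perm = rng.permuted(np.tile(ranks, (n_perm, 1)), axis=1)
    h_perm = h_of(perm[:, :n1].sum(axis=1))
    greater = float((h_perm > h_obs + 1e-9).mean())
    equal = float((np.abs(h_perm - h_obs) <= 1e-9).mean())
    return greater + 0.5 * equal
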