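"""Per-site Kruskal-Wallis validation, direction calls, gene-level
summaries and cohort descriptives.

A selected CpG is *validated* when the Kruskal-Wallis test on M-values
rejects at both timepoints (raw p < alpha at each; no multiple-testing
correction by default, optional Benjamini-Hochberg) and, by default, the
group ordering of mean beta agrees across timepoints.  Direction is
reported on the beta scale: a site is hypermethylated in the stable group
when mean beta(stable) - mean beta(unstable) is positive at both
timepoints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SiteTestResult",
    "GeneSummary",
    "kruskal_wallis",
    "test_sites",
    "validate_sites",
    "gene_summary",
    "group_descriptives",
]


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis H on midranks with tie correction; p from the
    chi-square approximation with (k - 1) degrees of freedom.

    The degenerate all-tied case returns (0, 1); a single group is an
    error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups have different lengths")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


@dataclass
class SiteTestResult:
    probe_id: str
    H_baseline: float
    H_followup: float
    p_baseline: float
    p_followup: float
    delta_beta_baseline: float   # mean beta(stable) - mean beta(unstable)
    delta_beta_followup: float
    direction: str               # hyper_in_stable / hypo_in_stable / discordant

    def to_dict(self) -> dict:
        return asdict(self)


def _direction(d_base: float, d_fup: float) -> str:
    if d_base > 0 and d_fup > 0:
        return "hyper_in_stable"
    if d_base < 0 and d_fup < 0:
        return "hypo_in_stable"
    return "discordant"


def _group_arrays(columns: pd.Index, groups: Mapping) -> np.ndarray:
    if isinstance(groups, pd.Series):
        return groups.reindex(columns).to_numpy()
    return np.array([groups[c] for c in columns])


def test_sites(
    probe_ids: Iterable[str],
    baseline_beta: pd.DataFrame,
    followup_beta: pd.DataFrame,
    baseline_m: pd.DataFrame,
    followup_m: pd.DataFrame,
    groups: Mapping,
) -> list[SiteTestResult]:
    """Kruskal-Wallis on M-values at both timepoints for each probe, with
    beta-scale group deltas; no filtering."""
    g_base = _group_arrays(baseline_m.columns, groups)
    g_fup = _group_arrays(followup_m.columns, groups)
    stable_b = g_base == "stable_MHO"
    stable_f = g_fup == "stable_MHO"
    results = []
    for pid in probe_ids:
        hb, pb = kruskal_wallis(baseline_m.loc[pid].to_numpy(), g_base)
        hf, pf = kruskal_wallis(followup_m.loc[pid].to_numpy(), g_fup)
        bb = baseline_beta.loc[pid].to_numpy()
        bf = followup_beta.loc[pid].to_numpy()
        db = float(bb[stable_b].mean() - bb[~stable_b].mean())
        df_ = float(bf[stable_f].mean() - bf[~stable_f].mean())
        results.append(SiteTestResult(
            probe_id=pid, H_baseline=hb, H_followup=hf,
            p_baseline=pb, p_followup=pf,
            delta_beta_baseline=db, delta_beta_followup=df_,
            direction=_direction(db, df_)))
    return results


def validate_sites(
    selected,
    baseline_beta: pd.DataFrame,
    followup_beta: pd.DataFrame,
    baseline_m: pd.DataFrame,
    followup_m: pd.DataFrame,
    groups: Mapping,
    alpha: float = 0.05,
    require_concordance: bool = True,
    fdr_correct: bool = False,
) -> list[SiteTestResult]:
    """Keep stage-2 sites significant at *both* timepoints (and direction
    concordant unless disabled), sorted by min(p) ascending then probe id.

    ``selected`` may be a SelectionResult-like object (``stage2_ids``
    attribute) or a plain iterable of probe ids.  With ``fdr_correct``
    the per-timepoint p-values are Benjamini-Hochberg adjusted across the
    candidate set before the alpha rule.
    """
    ids = list(getattr(selected, "stage2_ids", selected))
    if not ids:
        raise ValueError("no candidate sites to validate")
    tests = test_sites(ids, baseline_beta, followup_beta,
                       baseline_m, followup_m, groups)
    p_base = np.array([t.p_baseline for t in tests])
    p_fup = np.array([t.p_followup for t in tests])
    if fdr_correct:
        p_base = stats.false_discovery_control(p_base)
        p_fup = stats.false_discovery_control(p_fup)
    kept = []
    for t, pb, pf in zip(tests, p_base, p_fup):
        if pb < alpha and pf < alpha:
            if require_concordance and t.direction == "discordant":
                continue
            kept.append(t)
    kept.sort(key=lambda t: (min(t.p_baseline, t.p_followup), t.probe_id))
    return kept


@dataclass
class GeneSummary:
    gene: str
    n_cpgs_on_array: int
    n_differential: int
    fraction_differential: float  # percent

    def to_dict(self) -> dict:
        return asdict(self)


def gene_summary(
    validated: list[SiteTestResult],
    all_site_tests: list[SiteTestResult],
    manifest: pd.DataFrame,
    alpha: float = 0.05,
) -> list[GeneSummary]:
    """Differential fraction per gene hit by a validated site.

    For each gene carrying at least one validated CpG, *all* manifest CpGs
    of that gene are looked up in ``all_site_tests`` (produced by
    :func:`test_sites`) and counted as differential when significant at
    both timepoints at the same alpha.  Fractions are percentages of the
    gene's CpGs on the array.
    """
    by_probe = {t.probe_id: t for t in all_site_tests}
    genes: list[str] = []
    for t in validated:
        if t.probe_id not in manifest.index:
            warnings.warn(f"validated probe {t.probe_id} absent from manifest")
            continue
        g = manifest.loc[t.probe_id, "gene"]
        if g and g not in genes:
            genes.append(g)
    summaries = []
    for g in genes:
        probes = manifest.index[manifest["gene"] == g]
        n_diff = 0
        n_tested = 0
        for pid in probes:
            t = by_probe.get(pid)
            if t is None:
                # expected for gene CpGs removed by probe filtering
                logging.getLogger("epimark").debug(
                    "no site test available for %s (gene %s)", pid, g)
                continue
            n_tested += 1
            if t.p_baseline < alpha and t.p_followup < alpha:
                n_diff += 1
        if n_tested == 0:
            continue
        summaries.append(GeneSummary(
            gene=g, n_cpgs_on_array=len(probes), n_differential=n_diff,
            fraction_differential=100.0 * n_diff / len(probes)))
    summaries.sort(key=lambda s: (-s.fraction_differential, s.gene))
    return summaries


# ---------------------------------------------------------------------------
# cohort descriptives
# ---------------------------------------------------------------------------

_CONTINUOUS = ("age", "fasting_glucose", "triglycerides", "hdl", "sbp",
               "dbp", "waist")
_CATEGORICAL = ("sex", "on_treatment")


def _categorical_p(sub: pd.DataFrame, var: str) -> tuple[float, str]:
    table = pd.crosstab(sub["group"], sub[var])
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0, "degenerate"
    expected = stats.contingency.expected_freq(table.to_numpy())
    if table.shape == (2, 2) and (expected < 5).any():
        _, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
        return float(p), "fisher"
    chi2 = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2.pvalue), "chi2"


def group_descriptives(sheet: pd.DataFrame) -> pd.DataFrame:
    """Table-style descriptives: per timepoint, mean +/- SD per group with a
    Kruskal-Wallis p for continuous covariates; percentages with a
    chi-square p (Fisher's exact when any expected 2x2 cell count is
    below 5) for categorical ones.
    """
    groups = sorted(sheet["group"].unique())
    if len(groups) < 2:
        raise ValueError("descriptives need two groups")
    rows = []
    for timepoint in ("baseline", "followup"):
        sub = sheet[sheet["timepoint"] == timepoint]
        if sub.empty:
            continue
        for var in _CONTINUOUS:
            if var not in sub.columns:
                continue
            row = {"variable": var, "timepoint": timepoint, "type": "continuous"}
            for g in groups:
                vals = sub.loc[sub["group"] == g, var].astype(float)
                row[f"mean_{g}"] = float(vals.mean())
                row[f"sd_{g}"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            _, p = kruskal_wallis(sub[var].astype(float).to_numpy(),
                                  sub["group"].to_numpy())
            row["p_value"] = p
            row["test"] = "kruskal_wallis"
            rows.append(row)
        for var in _CATEGORICAL:
            if var not in sub.columns:
                continue
            row = {"variable": var, "timepoint": timepoint, "type": "categorical"}
            for g in groups:
                vals = sub.loc[sub["group"] == g, var]
                # report the frequency of the positive / first level
                level = True if vals.dtype == bool else sorted(sub[var].unique())[0]
                row[f"pct_{g}"] = float(100.0 * (vals == level).mean())
                row["level"] = str(level)
            p, test = _categorical_p(sub, var)
            row["p_value"] = p
            row["test"] = test
            rows.append(row)
    return pd.DataFrame(rows)
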