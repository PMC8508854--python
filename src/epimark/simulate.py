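"""Synthetic EPIC-like longitudinal methylation cohorts with planted effects.

The generator emulates the study design this package targets: two groups of
obese subjects — a *stable* metabolically-healthy-obesity (MHO) group that
stays healthy and an *unstable* group that transitions to metabolically
unhealthy obesity (MUO) — measured on an Illumina-EPIC-style beta-value
array at baseline and at a long-term follow-up (default nine subjects per
group, the size at which the downstream statistics are meant to operate).

Every output is a pure function of ``(config, seed)``.  Ground truth about
planted group-differential and baseline-predictive CpGs is returned as a
:class:`TruthSet` so that downstream selection stages have a
parameter-recovery test surface (sensitivity / false-discovery rate).

The noise model is a per-probe three-state beta landscape (unmethylated /
hemi-methylated / methylated), beta-distributed measurement noise with
concentration ``beta_precision``, a subject-level random intercept on the
M scale that induces the within-subject correlation across timepoints, a
multiplicative shrink of type-II probe values toward 0.5 (the design bias
BMIQ corrects), and separable detection p-values for good vs failed cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "TruthSet",
    "SimulatedDataset",
    "generate_manifest",
    "generate_cohort",
    "generate_betas",
    "generate_dataset",
    "classify_metabolic_status",
    "count_metabolic_criteria",
]

AUTOSOMES = [f"chr{i}" for i in range(1, 23)]
SEX_CHROMS = ["chrX", "chrY"]
CHROMS = AUTOSOMES + SEX_CHROMS

# distinct sub-streams so each operation is independently deterministic
_S_MANIFEST, _S_MEANS, _S_TRUTH, _S_COHORT, _S_BETAS = 11, 13, 17, 19, 23

_LN2_SQ = math.log(2.0) ** 2

# three-state beta landscape: (mean, sd, weight) for low / mid / high
_STATE_MEANS = np.array([0.08, 0.50, 0.92])
_STATE_SDS = np.array([0.04, 0.08, 0.04])
_STATE_WEIGHTS = np.array([0.42, 0.18, 0.40])


class ConfigurationError(ValueError):
    """Raised when a GeneratorConfig violates its invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults are the desk-scale study conditions: a 20,000-probe manifest
    (preserving the p >> n regime of the 850k array at tractable size),
    9 + 9 subjects, 60 differential CpGs at |delta beta| = 0.15 stable
    across both timepoints, 10 baseline-predictive CpGs at 1.5 log-odds
    per SD of M, within-subject correlation 0.7.
    """

    n_probes: int = 20_000
    n_subjects_per_group: int = 9
    frac_sex_chrom: float = 0.025
    frac_snp_flag: float = 0.04
    frac_type2: float = 0.84
    n_differential: int = 60
    delta_beta: float = 0.15
    n_predictive: int = 10
    predictive_log_or: float = 1.5
    within_subject_corr: float = 0.7
    beta_precision: float = 20_000.0
    detection_fail_rate: float = 0.005
    type2_shrink: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_sex_chrom", "frac_snp_flag", "frac_type2",
                     "detection_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.within_subject_corr < 1.0:
            raise ConfigurationError("within_subject_corr must be in [0, 1)")
        if not 0.0 <= self.type2_shrink < 1.0:
            raise ConfigurationError("type2_shrink must be in [0, 1)")
        if self.beta_precision <= 0:
            raise ConfigurationError("beta_precision must be > 0")
        if not 0.0 <= self.delta_beta < 1.0:
            raise ConfigurationError("delta_beta must be in [0, 1)")
        if self.n_probes < 1 or self.n_subjects_per_group < 1:
            raise ConfigurationError("n_probes and n_subjects_per_group must be >= 1")
        if self.n_differential + self.n_predictive > self.n_probes:
            raise ConfigurationError(
                "n_differential + n_predictive exceeds n_probes")


@dataclass(frozen=True)
class TruthSet:
    """Planted ground truth for parameter-recovery scoring.

    ``differential`` maps probe id -> signed delta beta, defined as
    mean beta(stable) - mean beta(unstable), identical at both timepoints.
    ``predictive`` maps probe id -> log odds ratio (transition to MUO) per
    1 SD of baseline M-value.  The two sets are disjoint.
    """

    differential: dict[str, float]
    predictive: dict[str, float]
    seed: int

    @property
    def differential_cpgs(self) -> set[str]:
        return set(self.differential)

    @property
    def predictive_cpgs(self) -> set[str]:
        return set(self.predictive)

    def to_dict(self) -> dict:
        return {"differential": dict(sorted(self.differential.items())),
                "predictive": dict(sorted(self.predictive.items())),
                "seed": self.seed}


@dataclass
class SimulatedDataset:
    """Bundle of everything one self-contained run needs."""

    config: GeneratorConfig
    manifest: pd.DataFrame
    sheet: pd.DataFrame
    truth: TruthSet
    beta_baseline: pd.DataFrame
    beta_followup: pd.DataFrame
    detp_baseline: pd.DataFrame
    detp_followup: pd.DataFrame


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def generate_manifest(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a probe manifest (index probe_id; chrom, pos, gene,
    design_type, snp_flag).

    Sex-chromosome, SNP-flagged and type-II counts are rounding-exact
    fractions of ``n_probes``.  Genes are contiguous runs of probes along
    each chromosome with a long-tailed size distribution so that a
    non-trivial share of genes carries four or more probes.
    """
    rng = np.random.default_rng([_S_MANIFEST, config.seed])
    n = config.n_probes
    ids = np.array([f"cg{i:08d}" for i in range(1, n + 1)])

    chrom = np.empty(n, dtype=object)
    perm = rng.permutation(n)
    n_sex = int(round(config.frac_sex_chrom * n))
    sex_idx = perm[:n_sex]
    auto_idx = perm[n_sex:]
    chrom[sex_idx] = rng.choice(SEX_CHROMS, size=n_sex, p=[0.9, 0.1])
    chrom[auto_idx] = rng.choice(AUTOSOMES, size=n - n_sex)
    pos = rng.integers(1, 200_000_000, size=n)

    snp_flag = np.zeros(n, dtype=bool)
    n_snp = int(round(config.frac_snp_flag * n))
    n_snp = min(n_snp, len(auto_idx))
    if n_snp:
        snp_flag[rng.choice(auto_idx, size=n_snp, replace=False)] = True

    design = np.full(n, "I", dtype=object)
    n_t2 = int(round(config.frac_type2 * n))
    if n_t2:
        design[rng.choice(n, size=n_t2, replace=False)] = "II"

    gene = np.full(n, "", dtype=object)
    order = np.lexsort((pos, chrom))
    sizes = np.array([1, 2, 3, 4, 5, 6, 8, 10])
    size_p = np.array([0.33, 0.24, 0.15, 0.10, 0.07, 0.05, 0.04, 0.02])
    i = 0
    g = 0
    while i < n:
        if rng.random() < 0.25:  # intergenic probe
            i += 1
            continue
        s = int(rng.choice(sizes, p=size_p))
        g += 1
        name = f"GENE{g:05d}"
        c0 = chrom[order[i]]
        j = i
        while j < n and j - i < s and chrom[order[j]] == c0:
            gene[order[j]] = name
            j += 1
        i = j

    manifest = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "gene": gene,
         "design_type": design, "snp_flag": snp_flag},
        index=pd.Index(ids, name="probe_id"),
    )
    return manifest


# ---------------------------------------------------------------------------
# per-probe methylation landscape (shared by cohort truth and beta draws)
# ---------------------------------------------------------------------------

def _probe_baseline_means(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng([_S_MEANS, config.seed])
    state = rng.choice(3, size=config.n_probes, p=_STATE_WEIGHTS)
    m = rng.normal(_STATE_MEANS[state], _STATE_SDS[state])
    return np.clip(m, 0.02, 0.98), state


def _plant_truth(manifest: pd.DataFrame, config: GeneratorConfig) -> TruthSet:
    rng = np.random.default_rng([_S_TRUTH, config.seed])
    m, state = _probe_baseline_means(config)
    autosomal = ~manifest["chrom"].isin(SEX_CHROMS).to_numpy()
    clean = autosomal & ~manifest["snp_flag"].to_numpy()
    half = config.delta_beta / 2.0
    # differential effects live at intermediately methylated CpGs so that
    # both group means stay well inside (0, 1)
    eligible = clean & (state == 1) & (m - half >= 0.22) & (m + half <= 0.78)
    idx = np.flatnonzero(eligible)
    need = config.n_differential + config.n_predictive
    if len(idx) < need:
        raise ConfigurationError(
            f"only {len(idx)} eligible mid-methylated probes for "
            f"{need} planted effects; increase n_probes")
    chosen = rng.choice(idx, size=need, replace=False)
    ids = manifest.index.to_numpy()
    diff_idx = chosen[:config.n_differential]
    pred_idx = chosen[config.n_differential:]
    diff_signs = rng.choice([-1.0, 1.0], size=len(diff_idx))
    pred_signs = rng.choice([-1.0, 1.0], size=len(pred_idx))
    differential = {ids[i]: float(s * config.delta_beta)
                    for i, s in zip(diff_idx, diff_signs)}
    predictive = {ids[i]: float(s * config.predictive_log_or)
                  for i, s in zip(pred_idx, pred_signs)}
    return TruthSet(differential=differential, predictive=predictive,
                    seed=config.seed)


# ---------------------------------------------------------------------------
# phenotype classification (NCEP ATPIII)
# ---------------------------------------------------------------------------

_REQUIRED_COVARIATES = ("fasting_glucose", "triglycerides", "hdl",
                        "sbp", "dbp", "on_treatment")


def count_metabolic_criteria(covariates: Mapping, sex: str) -> int:
    """Count NCEP ATPIII metabolic-syndrome criteria (abdominal obesity
    excluded: all study subjects are obese by construction).

    Criteria (each thresholds inclusive where stated with >=):
    blood pressure SBP >= 135 or DBP >= 85 (one criterion together);
    fasting glucose >= 100 mg/dL; HDL < 40 (men) / < 50 (women) mg/dL;
    triglycerides >= 150 mg/dL; any antihypertensive / lipid-lowering /
    glucose-lowering medication.
    """
    missing = [k for k in _REQUIRED_COVARIATES if k not in covariates]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    c = covariates
    count = 0
    count += int(c["sbp"] >= 135 or c["dbp"] >= 85)
    count += int(c["fasting_glucose"] >= 100)
    count += int(c["hdl"] < (40 if sex == "M" else 50))
    count += int(c["triglycerides"] >= 150)
    count += int(bool(c["on_treatment"]))
    return count


def classify_metabolic_status(covariates: Mapping, sex: str) -> str:
    """Return ``"MHO"`` iff fewer than two criteria are met, else ``"MUO"``."""
    return "MHO" if count_metabolic_criteria(covariates, sex) < 2 else "MUO"


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

_CRITERIA = ("glucose", "bp", "hdl", "tg", "treatment")


def _draw_covariates(rng: np.random.Generator, sex: str, active: set[str],
                     group: str, timepoint: str) -> dict:
    """Draw covariate values consistent with the chosen active criteria.

    Value ranges are loosely matched to the descriptive table of the study
    population (e.g. baseline triglycerides run higher in the unstable
    group even below the 150 mg/dL criterion threshold); clipping margins
    keep every draw unambiguously on its side of each threshold.
    """
    def tn(mean, sd, lo, hi):
        return float(np.clip(rng.normal(mean, sd), lo, hi))

    if "glucose" in active:
        glucose = tn(112, 8, 100.5, 160)
    else:
        glucose = tn(92, 4, 75, 98.5)

    if "tg" in active:
        tg = tn(175, 20, 150.5, 260)
    else:
        tg_mean = {("stable_MHO", "baseline"): 55,
                   ("stable_MHO", "followup"): 82,
                   ("unstable_MHO", "baseline"): 95,
                   ("unstable_MHO", "followup"): 100}[(group, timepoint)]
        tg = tn(tg_mean, 20, 40, 144)

    if sex == "F":
        hdl = tn(44, 4, 30, 49.5) if "hdl" in active else tn(58, 7, 50.5, 85)
    else:
        hdl = tn(35, 3, 25, 39.5) if "hdl" in active else tn(48, 6, 40.5, 75)

    if "bp" in active:
        sbp = tn(147, 9, 135.5, 185)
        dbp = tn(88, 8, 70, 105)
    else:
        sbp = tn(121, 7, 100, 134.4)
        dbp = tn(77, 5, 60, 84.4)

    waist = tn(108, 4, 102.5, 130) if sex == "M" else tn(95, 4, 88.5, 120)

    return {
        "fasting_glucose": round(glucose, 1),
        "triglycerides": round(tg, 1),
        "hdl": round(hdl, 1),
        "sbp": round(sbp, 1),
        "dbp": round(dbp, 1),
        "waist": round(waist, 1),
        "on_treatment": "treatment" in active,
    }


def _draw_criteria_set(rng: np.random.Generator, n_active: int) -> set[str]:
    weights = np.array([0.30, 0.30, 0.15, 0.10, 0.15])
    chosen = rng.choice(len(_CRITERIA), size=n_active, replace=False,
                        p=weights)
    return {_CRITERIA[i] for i in chosen}


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, TruthSet]:
    """Generate a sample sheet (one row per subject x timepoint) and the
    planted :class:`TruthSet`.

    Stable subjects classify as MHO at both timepoints; unstable subjects
    classify as MHO at baseline and MUO at follow-up, by construction (the
    generated covariates are verified against
    :func:`classify_metabolic_status`).
    """
    rng = np.random.default_rng([_S_COHORT, config.seed])
    manifest = generate_manifest(config)
    truth = _plant_truth(manifest, config)

    n = config.n_subjects_per_group
    rows = []
    for gi, group in enumerate(("stable_MHO", "unstable_MHO")):
        for si in range(n):
            subject = f"S{gi * n + si + 1:03d}"
            sex = "F" if rng.random() < 0.7 else "M"
            age0 = float(np.clip(rng.normal(45 if group == "stable_MHO" else 53,
                                            10), 18, 65))
            for timepoint in ("baseline", "followup"):
                if group == "unstable_MHO" and timepoint == "followup":
                    n_active = 2 if rng.random() < 0.7 else 3
                else:
                    n_active = int(rng.random() < 0.5)
                active = _draw_criteria_set(rng, n_active)
                cov = _draw_covariates(rng, sex, active, group, timepoint)
                expected = "MHO" if n_active < 2 else "MUO"
                got = classify_metabolic_status(cov, sex)
                if got != expected:  # pragma: no cover - construction guard
                    raise RuntimeError(
                        f"covariate draw for {subject}/{timepoint} classifies "
                        f"as {got}, expected {expected}")
                rows.append({
                    "sample_id": f"{subject}_{timepoint}",
                    "subject_id": subject,
                    "timepoint": timepoint,
                    "group": group,
                    "sex": sex,
                    "age": round(age0 + (11 if timepoint == "followup" else 0), 1),
                    **cov,
                })
    sheet = pd.DataFrame(rows).set_index("sample_id")
    return sheet, truth


# ---------------------------------------------------------------------------
# beta matrices
# ---------------------------------------------------------------------------

def _m_noise_var(mu: np.ndarray, kappa: float) -> np.ndarray:
    """Delta-method variance of M = log2(b/(1-b)) for b ~ Beta(mu*k,(1-mu)*k)."""
    return 1.0 / ((kappa + 1.0) * _LN2_SQ * mu * (1.0 - mu))


def _logit2(x: np.ndarray) -> np.ndarray:
    return np.log2(x / (1.0 - x))


def _expit2(m: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp2(-m))


def generate_betas(
    manifest: pd.DataFrame,
    sheet: pd.DataFrame,
    truth: TruthSet,
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate beta and detection-p matrices (probes x samples) for both
    timepoints.

    Group effects are planted additively on the beta scale (differential
    probes, both timepoints) or on the M scale (predictive probes, baseline
    only, scaled so a logistic fit of group on the standardized baseline
    M-value has the planted per-SD log odds ratio in expectation).  Type-II
    probes are shrunk toward 0.5 *after* effect planting — the design bias
    is a measurement distortion, which is why BMIQ matters downstream.
    """
    if len(manifest) != config.n_probes:
        raise ValueError("manifest size does not match config.n_probes")
    missing = (set(truth.differential) | set(truth.predictive)) - set(manifest.index)
    if missing:
        raise ValueError(f"truth probes absent from manifest: {sorted(missing)[:5]}")

    rng = np.random.default_rng([_S_BETAS, config.seed])
    kappa = config.beta_precision
    rho = config.within_subject_corr

    subjects = sheet["subject_id"].unique()
    sub_rows = sheet[sheet["timepoint"] == "baseline"].set_index("subject_id")
    groups = sub_rows.loc[subjects, "group"].to_numpy()
    unstable = groups == "unstable_MHO"
    n_sub = len(subjects)

    m0, _state = _probe_baseline_means(config)
    p = config.n_probes
    probe_pos = {pid: i for i, pid in enumerate(manifest.index)}

    # group-mean surfaces, probes x subjects, per timepoint
    mu_base = np.repeat(m0[:, None], n_sub, axis=1)
    mu_fup = mu_base.copy()
    for pid, d in truth.differential.items():
        i = probe_pos[pid]
        # d = mean(stable) - mean(unstable), centred on the landscape mean
        mu_base[i, ~unstable] = m0[i] + d / 2.0
        mu_base[i, unstable] = m0[i] - d / 2.0
        mu_fup[i, :] = mu_base[i, :]
    for pid, lor in truth.predictive.items():
        i = probe_pos[pid]
        sigma_w2 = _m_noise_var(np.array(m0[i]), kappa) / (1.0 - rho)
        if abs(lor) < 1.9:
            sigma_x2 = sigma_w2 / (1.0 - lor ** 2 / 4.0)
        else:
            sigma_x2 = sigma_w2
        delta_m = lor * math.sqrt(float(sigma_x2))
        base_m = float(_logit2(np.array(m0[i])))
        mu_base[i, unstable] = float(_expit2(np.array(base_m + delta_m / 2.0)))
        mu_base[i, ~unstable] = float(_expit2(np.array(base_m - delta_m / 2.0)))

    type2 = (manifest["design_type"] == "II").to_numpy()
    shrink = config.type2_shrink

    def measured(mu):
        mu = mu.copy()
        mu[type2] = 0.5 + (1.0 - shrink) * (mu[type2] - 0.5)
        return np.clip(mu, 0.01, 0.99)

    mu_base_m = measured(mu_base)
    mu_fup_m = measured(mu_fup)

    # beta noise, then subject random intercept on the M scale
    tau = np.sqrt(rho / (1.0 - rho) * _m_noise_var(mu_base_m, kappa))
    b_subj = rng.normal(0.0, tau)  # probes x subjects, shared across timepoints

    out = {}
    for tp, mu in (("baseline", mu_base_m), ("followup", mu_fup_m)):
        draw = rng.beta(mu * kappa, (1.0 - mu) * kappa)
        m_vals = _logit2(np.clip(draw, 1e-9, 1 - 1e-9)) + b_subj
        beta = np.clip(_expit2(m_vals), 1e-6, 1.0 - 1e-6)
        cols = [f"{s}_{tp}" for s in subjects]
        out[tp] = pd.DataFrame(beta, index=manifest.index.copy(), columns=cols)

    detp = {}
    for tp in ("baseline", "followup"):
        fail = rng.random((p, n_sub)) < config.detection_fail_rate
        vals = np.where(fail,
                        rng.uniform(0.02, 0.5, size=(p, n_sub)),
                        rng.uniform(0.0, 0.005, size=(p, n_sub)))
        detp[tp] = pd.DataFrame(vals, index=manifest.index.copy(),
                                columns=out[tp].columns.copy())

    return out["baseline"], out["followup"], detp["baseline"], detp["followup"]


def generate_dataset(config: GeneratorConfig) -> SimulatedDataset:
    """Convenience wrapper: manifest + cohort + matrices in one call."""
    manifest = generate_manifest(config)
    sheet, truth = generate_cohort(config)
    bb, bf, db, df_ = generate_betas(manifest, sheet, truth, config)
    return SimulatedDataset(config=config, manifest=manifest, sheet=sheet,
                            truth=truth, beta_baseline=bb, beta_followup=bf,
                            detp_baseline=db, detp_followup=df_)
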