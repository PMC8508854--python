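"""Array preprocessing: probe filtering, BMIQ design-bias normalization and
beta <-> M transforms.

Filtering removes sex-chromosome probes, probes flagged as lying near SNPs,
and low-quality probes (detection p-value > ``p_cut`` in at least
``frac_cut`` of samples, boundary inclusive).  BMIQ fits, per sample, a
three-state beta mixture (unmethylated / hemi-methylated / methylated) by
EM separately to the type-I and type-II probe populations and
quantile-maps each type-II state onto the corresponding type-I state
distribution; type-I values are returned unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FilterReport",
    "ProbeFilter",
    "filter_probes",
    "BMIQNormalizer",
    "bmiq_normalize",
    "beta_to_m",
    "m_to_beta",
]


@dataclass
class FilterReport:
    """Per-reason probe-removal accounting.

    A probe failing several rules is counted once, with precedence
    sex > snp > detection; counts therefore sum exactly to
    ``n_input - n_retained``.
    """

    n_input: int
    n_removed_sex: int
    n_removed_snp: int
    n_removed_detection: int
    n_retained: int
    removed_sex: list[str] = field(default_factory=list)
    removed_snp: list[str] = field(default_factory=list)
    removed_detection: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def filter_probes(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    manifest: pd.DataFrame,
    p_cut: float = 0.01,
    frac_cut: float = 0.10,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove sex-chromosome, SNP-flagged and detection-failing probes.

    Parameters
    ----------
    beta, detp : DataFrame
        Probes x samples matrices with aligned axes.
    manifest : DataFrame
        Must cover every probe in ``beta`` (chrom, snp_flag columns).
    p_cut, frac_cut : float
        A probe is low quality when the fraction of samples with
        detection p > ``p_cut`` is **at least** ``frac_cut``.
    """
    if not beta.index.equals(detp.index) or not beta.columns.equals(detp.columns):
        raise ValueError("beta and detection-p matrices are not aligned")
    missing = beta.index.difference(manifest.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} probes absent from manifest, e.g. {list(missing[:3])}")

    man = manifest.loc[beta.index]
    sex = man["chrom"].isin(["chrX", "chrY"]).to_numpy()
    snp = man["snp_flag"].to_numpy(dtype=bool) & ~sex
    fail_frac = (detp.to_numpy() > p_cut).mean(axis=1)
    det = (fail_frac >= frac_cut) & ~sex & ~snp

    keep = ~(sex | snp | det)
    ids = beta.index.to_numpy()
    report = FilterReport(
        n_input=len(ids),
        n_removed_sex=int(sex.sum()),
        n_removed_snp=int(snp.sum()),
        n_removed_detection=int(det.sum()),
        n_retained=int(keep.sum()),
        removed_sex=[str(x) for x in ids[sex]],
        removed_snp=[str(x) for x in ids[snp]],
        removed_detection=[str(x) for x in ids[det]],
    )
    return beta.loc[keep], report


class ProbeFilter(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper around :func:`filter_probes`.

    Operates on samples x probes frames (sklearn orientation); the fitted
    attribute ``retained_probes_`` lists surviving probe ids and
    ``report_`` holds the :class:`FilterReport`.
    """

    def __init__(self, manifest: pd.DataFrame | None = None,
                 p_cut: float = 0.01, frac_cut: float = 0.10):
        self.manifest = manifest
        self.p_cut = p_cut
        self.frac_cut = frac_cut

    def fit(self, X: pd.DataFrame, y=None, *, detection_p: pd.DataFrame = None):
        if self.manifest is None:
            raise ValueError("ProbeFilter requires a manifest")
        if detection_p is None:
            raise ValueError("ProbeFilter.fit requires detection_p")
        filtered, report = filter_probes(X.T, detection_p.T, self.manifest,
                                         self.p_cut, self.frac_cut)
        self.retained_probes_ = list(filtered.index)
        self.report_ = report
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, self.retained_probes_]


# ---------------------------------------------------------------------------
# BMIQ
# ---------------------------------------------------------------------------

def _beta_logpdf(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # x: (n, 1); a, b: (k,)
    return (special.xlogy(a - 1.0, x) + special.xlog1py(b - 1.0, -x)
            - special.betaln(a, b))


def _moments_to_ab(mean: np.ndarray, var: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = np.clip(mean, 1e-4, 1 - 1e-4)
    var = np.maximum(var, 1e-8)
    conc = np.clip(mean * (1 - mean) / var - 1.0, 2.0, 1e6)
    return mean * conc, (1 - mean) * conc


@dataclass
class _BetaMixture:
    a: np.ndarray        # (k,) shape-1 parameters, states ordered by mean
    b: np.ndarray        # (k,)
    weights: np.ndarray  # (k,)
    converged: bool
    n_iter: int

    @property
    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)


def _fit_beta_mixture(x: np.ndarray, n_states: int = 3, max_iter: int = 200,
                      tol: float = 1e-5) -> _BetaMixture:
    """EM for a k-state beta mixture with a moment-matching M-step.

    Initialization is by fixed quantile cut-points (0.2 / 0.8 for three
    states), so the fit is deterministic.  On non-convergence the
    best-log-likelihood iterate is returned with a warning.
    """
    x = np.clip(np.asarray(x, dtype=float), 1e-6, 1 - 1e-6)[:, None]
    n = len(x)
    if n_states == 3:
        edges = np.array([0.0, 0.2, 0.8, 1.0])
    else:
        edges = np.linspace(0.0, 1.0, n_states + 1)
    resp = np.zeros((n, n_states))
    lab = np.clip(np.searchsorted(edges, x[:, 0], side="right") - 1,
                  0, n_states - 1)
    resp[np.arange(n), lab] = 1.0

    a = b = w = None
    best = (-np.inf, None)
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        nk = resp.sum(axis=0) + 1e-10
        w = nk / n
        mean = (resp * x).sum(axis=0) / nk
        var = (resp * (x - mean) ** 2).sum(axis=0) / nk
        a, b = _moments_to_ab(mean, var)
        logp = _beta_logpdf(x, a, b) + np.log(w)
        ll = float(special.logsumexp(logp, axis=1).sum())
        if ll > best[0]:
            best = (ll, (a.copy(), b.copy(), w.copy()))
        resp = np.exp(logp - special.logsumexp(logp, axis=1, keepdims=True))
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            converged = True
            break
        prev_ll = ll

    if not converged:
        warnings.warn("beta-mixture EM did not converge; using best iterate",
                      RuntimeWarning)
        a, b, w = best[1]
    order = np.argsort(a / (a + b))
    return _BetaMixture(a=a[order], b=b[order], weights=w[order],
                        converged=converged, n_iter=it)


def _bmiq_map_sample(t1: np.ndarray, t2: np.ndarray, n_states: int,
                     max_iter: int, tol: float) -> np.ndarray:
    """Map one sample's type-II betas onto the type-I state distributions."""
    fit1 = _fit_beta_mixture(t1, n_states, max_iter, tol)
    fit2 = _fit_beta_mixture(t2, n_states, max_iter, tol)
    x = np.clip(t2, 1e-6, 1 - 1e-6)[:, None]
    logp = _beta_logpdf(x, fit2.a, fit2.b) + np.log(fit2.weights)
    state = np.argmax(logp, axis=1)  # hard assignment by maximum posterior
    out = np.empty_like(t2)
    for k in range(n_states):
        sel = state == k
        if not sel.any():
            continue
        u = stats.beta.cdf(x[sel, 0], fit2.a[k], fit2.b[k])
        u = np.clip(u, 1e-12, 1 - 1e-12)
        out[sel] = stats.beta.ppf(u, fit1.a[k], fit1.b[k])
    return np.clip(out, 1e-6, 1 - 1e-6)


def bmiq_normalize(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    n_states: int = 3,
    max_iter: int = 200,
    tol: float = 1e-5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample beta-mixture quantile normalization of type-II probes.

    Type-I probes are returned bit-identical; within each assigned state
    the mapping is strictly monotone, so type-II rank order is preserved
    per state.  ``seed`` is accepted for interface stability; the EM
    initialization is deterministic (fixed quantile cut-points) so it only
    matters for exact ties, which the hard argmax already resolves
    deterministically.
    """
    missing = beta.index.difference(manifest.index)
    if len(missing):
        raise ValueError("manifest does not cover all probes")
    design = manifest.loc[beta.index, "design_type"].to_numpy()
    t1_mask = design == "I"
    t2_mask = design == "II"
    min_class = min(int(t1_mask.sum()), int(t2_mask.sum()))
    if min_class < 50:
        raise ValueError(
            f"smallest design class has {min_class} probes (< 50); "
            "BMIQ needs both probe chemistries represented")

    values = beta.to_numpy(dtype=float, copy=True)
    for j in range(values.shape[1]):
        values[t2_mask, j] = _bmiq_map_sample(
            values[t1_mask, j], values[t2_mask, j], n_states, max_iter, tol)
    return pd.DataFrame(values, index=beta.index.copy(),
                        columns=beta.columns.copy())


class BMIQNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer over :func:`bmiq_normalize`.

    The normalization is per-sample (stateless across samples), so ``fit``
    only validates the manifest; ``transform`` maps each row (sample) of a
    samples x probes frame.
    """

    def __init__(self, manifest: pd.DataFrame | None = None, n_states: int = 3,
                 max_iter: int = 200, tol: float = 1e-5, seed: int = 0):
        self.manifest = manifest
        self.n_states = n_states
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        if self.manifest is None:
            raise ValueError("BMIQNormalizer requires a manifest")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return bmiq_normalize(X.T, self.manifest, self.n_states,
                              self.max_iter, self.tol, self.seed).T


# ---------------------------------------------------------------------------
# beta <-> M
# ---------------------------------------------------------------------------

def beta_to_m(beta: pd.DataFrame | np.ndarray, eps: float = 1e-6):
    """M = log2(beta / (1 - beta)), with beta clipped to [eps, 1 - eps]."""
    values = beta.to_numpy() if isinstance(beta, pd.DataFrame) else np.asarray(beta, float)
    if np.any(values < 0) or np.any(values > 1) or np.any(~np.isfinite(values)):
        raise ValueError("beta values outside [0, 1]")
    clipped = np.clip(values, eps, 1.0 - eps)
    m = np.log2(clipped / (1.0 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index.copy(), columns=beta.columns.copy())
    return m


def m_to_beta(m: pd.DataFrame | np.ndarray):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    values = m.to_numpy() if isinstance(m, pd.DataFrame) else np.asarray(m, float)
    beta = 1.0 / (1.0 + np.exp2(-values))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index.copy(), columns=m.columns.copy())
    return beta
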