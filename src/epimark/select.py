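"""Two-stage longitudinal PCA-contribution selection of candidate CpGs.

Stage 1 fits PCA on the follow-up M-values and keeps the top contributors
of the first components, walked rank by rank across components until the
union reaches ``round(stage1_fraction * n_probes)`` probes (about 1% by
default).  Stage 2 refits PCA at baseline on the stage-1 subset only and
applies the half-max rule per component: keep probes whose contribution
strictly exceeds half the best variable's contribution, combining the
per-component keeps by union (default) or intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import pandas as pd
from sklearn.base import BaseEstimator

from .pca import ContributionPCA, pca_fit

__all__ = [
    "SelectionParams",
    "SelectionResult",
    "stage1_select",
    "stage2_select",
    "DoublePCASelector",
    "double_pca_select",
]


@dataclass(frozen=True)
class SelectionParams:
    stage1_fraction: float = 0.01
    n_components: int = 2
    stage2_rule: str = "half_max"
    combine: str = "union"

    def __post_init__(self):
        if not 0.0 < self.stage1_fraction < 1.0:
            raise ValueError("stage1_fraction must be in (0, 1)")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.stage2_rule != "half_max":
            raise ValueError(f"unknown stage2_rule {self.stage2_rule!r}")
        if self.combine not in ("union", "intersection"):
            raise ValueError(f"unknown combine {self.combine!r}")


@dataclass
class SelectionResult:
    """Outcome of the two-stage selection with full provenance."""

    stage1_ids: list[str]
    stage2_ids: list[str]
    stage1_contributions: pd.DataFrame   # stage-1 probes x components (%)
    stage2_contributions: pd.DataFrame   # stage-1 probes x components (%)
    thresholds_used: dict[str, float]    # component -> half-max threshold (%)
    params: SelectionParams

    def to_dict(self) -> dict:
        return {
            "stage1_ids": list(self.stage1_ids),
            "stage2_ids": list(self.stage2_ids),
            "thresholds_used": dict(self.thresholds_used),
            "params": asdict(self.params),
        }


def _ranked_ids(contrib: pd.Series) -> list[str]:
    # deterministic tie-break: contribution descending, probe id ascending
    order = sorted(contrib.items(), key=lambda kv: (-kv[1], kv[0]))
    return [k for k, _ in order]


def stage1_select(followup: ContributionPCA, params: SelectionParams) -> list[str]:
    """Top-contributor union across the first components, sized to
    ``round(stage1_fraction * n_probes)``.

    The union is built by walking ranks: at rank r the rank-r probe of each
    component is added in component order, stopping exactly at the target
    size — the only construction that uses *both* components and still
    lands on a fixed fraction.
    """
    contrib = followup.contributions_
    n_probes = contrib.shape[0]
    n_comp = min(params.n_components, contrib.shape[1])
    target = int(round(params.stage1_fraction * n_probes))
    if target < 1:
        raise ValueError(
            f"stage1_fraction {params.stage1_fraction} selects no probes "
            f"from {n_probes}")
    rankings = [_ranked_ids(contrib.iloc[:, k]) for k in range(n_comp)]
    chosen: list[str] = []
    seen: set[str] = set()
    for r in range(n_probes):
        for ranking in rankings:
            pid = ranking[r]
            if pid not in seen:
                seen.add(pid)
                chosen.append(pid)
                if len(chosen) == target:
                    return sorted(chosen)
    return sorted(chosen)


def stage2_select(baseline: ContributionPCA, params: SelectionParams,
                  stage1_ids: list[str] | None = None,
                  stage1_contributions: pd.DataFrame | None = None) -> SelectionResult:
    """Half-max contribution rule on the baseline PCA of the stage-1 subset.

    For each of the first two components the threshold is half the maximum
    contribution; probes strictly above threshold are kept, combined
    across components per ``params.combine``.
    """
    contrib = baseline.contributions_
    if contrib.shape[0] == 0:
        raise ValueError("empty stage-1 set")
    if stage1_ids is None:
        stage1_ids = sorted(contrib.index)
    n_comp = min(2, contrib.shape[1])
    thresholds: dict[str, float] = {}
    kept_sets = []
    for k in range(n_comp):
        col = contrib.iloc[:, k]
        thr = float(col.max()) / 2.0
        thresholds[contrib.columns[k]] = thr
        kept_sets.append(set(col.index[col > thr]))
    if params.combine == "union":
        kept = set().union(*kept_sets)
    else:
        kept = set.intersection(*kept_sets)
    return SelectionResult(
        stage1_ids=sorted(stage1_ids),
        stage2_ids=sorted(kept),
        stage1_contributions=(stage1_contributions
                              if stage1_contributions is not None
                              else contrib),
        stage2_contributions=contrib,
        thresholds_used=thresholds,
        params=params,
    )


class DoublePCASelector(BaseEstimator):
    """Feature selector composing the two PCA-contribution stages.

    ``fit(followup_m, baseline_m)`` takes probes x samples M-value frames
    for the two timepoints (stage 1 runs on follow-up, stage 2 at baseline
    on the stage-1 subset).  ``transform`` restricts a probes x samples
    frame to the stage-2 probes.
    """

    def __init__(self, stage1_fraction: float = 0.01, n_components: int = 2,
                 combine: str = "union", center: bool = True,
                 scale: bool = False):
        self.stage1_fraction = stage1_fraction
        self.n_components = n_components
        self.combine = combine
        self.center = center
        self.scale = scale

    def _params(self) -> SelectionParams:
        return SelectionParams(stage1_fraction=self.stage1_fraction,
                               n_components=self.n_components,
                               combine=self.combine)

    def fit(self, followup_m: pd.DataFrame, baseline_m: pd.DataFrame):
        if not followup_m.index.equals(baseline_m.index):
            raise ValueError("timepoints carry different probe sets")
        params = self._params()
        followup_pca = pca_fit(followup_m, center=self.center, scale=self.scale)
        stage1 = stage1_select(followup_pca, params)
        baseline_pca = pca_fit(baseline_m.loc[stage1], center=self.center,
                               scale=self.scale)
        stage1_contrib = followup_pca.contributions_.loc[stage1]
        result = stage2_select(baseline_pca, params, stage1_ids=stage1,
                               stage1_contributions=stage1_contrib)
        self.followup_pca_ = followup_pca
        self.baseline_pca_ = baseline_pca
        self.stage1_ids_ = result.stage1_ids
        self.stage2_ids_ = result.stage2_ids
        self.thresholds_ = result.thresholds_used
        self.result_ = result
        return self

    def transform(self, m: pd.DataFrame) -> pd.DataFrame:
        return m.loc[self.stage2_ids_]


def double_pca_select(baseline_m: pd.DataFrame, followup_m: pd.DataFrame,
                      params: SelectionParams | None = None) -> SelectionResult:
    """Functional interface over :class:`DoublePCASelector`."""
    params = params or SelectionParams()
    sel = DoublePCASelector(stage1_fraction=params.stage1_fraction,
                            n_components=params.n_components,
                            combine=params.combine)
    sel.fit(followup_m, baseline_m)
    return sel.result_
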