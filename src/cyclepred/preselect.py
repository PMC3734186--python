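"""Univariate feature pre-selection ahead of model fitting.

The binary classifier keeps features whose scores differ between the
cell-cycle and non-cell-cycle sets by a two-sample Student t-test
(p < 0.001 by default); the phase model keeps features that vary across
the four phases by one-way ANOVA (p < 0.01 by default).  Thresholds are
raw p-values — no multiplicity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cyclepred.feature_io import CLASS_UNLABELED, FeatureMatrix, GeneLabels


@dataclass
class SelectionResult:
    """Per-feature p-values and the kept set for one selection run."""

    pvalues: pd.Series
    alpha: float
    test: str  # "t" or "anova"

    @property
    def kept(self) -> list[str]:
        mask = self.pvalues < self.alpha
        return list(self.pvalues.index[mask])

    def apply(self, m: FeatureMatrix) -> FeatureMatrix:
        return m.subset_features(self.kept)

    def to_frame(self, kinds: pd.Series | None = None) -> pd.DataFrame:
        out = pd.DataFrame({"p_value": self.pvalues})
        if kinds is not None:
            out.insert(0, "kind", kinds.reindex(out.index))
        out["kept"] = out.index.isin(set(self.kept))
        out.index.name = "feature"
        return out

    def write(self, path, kinds: pd.Series | None = None) -> None:
        self.to_frame(kinds).to_csv(path, sep="\t")


def _guard_degenerate(stat: np.ndarray, p: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Zero variance in every group: p = 1 when the group means agree
    (nothing to detect), 0 when they differ with certainty."""
    within_var = np.sum([g.var(axis=0, ddof=0) * len(g) for g in groups], axis=0)
    means = np.array([g.mean(axis=0) for g in groups])
    degenerate = within_var == 0
    equal_means = np.ptp(means, axis=0) == 0
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    return p


def ttest_select(
    m: FeatureMatrix,
    labels: GeneLabels,
    alpha: float = 0.001,
    equal_var: bool = True,
) -> SelectionResult:
    """Two-sided two-sample t-test per feature, positives vs negatives.

    ``equal_var=True`` is the classical pooled-variance Student test;
    set it False for the Welch variant.
    """
    labeled = [g for g in labels.labeled_genes]
    cls = labels.classes.loc[labeled]
    if (cls == CLASS_UNLABELED).any():
        raise ValueError("unlabeled genes in labeled set")
    pos = m.values.loc[cls.index[cls == "pos"]].to_numpy(dtype=float)
    neg = m.values.loc[cls.index[cls == "neg"]].to_numpy(dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least 2 genes for a t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = stats.ttest_ind(pos, neg, axis=0, equal_var=equal_var)
    p = _guard_degenerate(np.asarray(stat), np.nan_to_num(p, nan=1.0), [pos, neg])
    return SelectionResult(pd.Series(p, index=m.values.columns), alpha, "t")


def anova_select(
    m: FeatureMatrix, phases: pd.Series, alpha: float = 0.01
) -> SelectionResult:
    """One-way fixed-effects ANOVA per feature across phase groups.

    ``phases`` maps positive genes to their peak phase; applied within
    the positive set only.
    """
    phases = phases[phases != "NA"]
    levels = sorted(phases.unique())
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least 2 phases")
    groups = []
    for level in levels:
        members = phases.index[phases == level]
        if len(members) < 2:
            raise ValueError(f"phase {level!r} has fewer than 2 genes")
        groups.append(m.values.loc[members].to_numpy(dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = stats.f_oneway(*groups, axis=0)
    p = _guard_degenerate(np.asarray(stat), np.nan_to_num(p, nan=1.0), groups)
    return SelectionResult(pd.Series(p, index=m.values.columns), alpha, "anova")
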