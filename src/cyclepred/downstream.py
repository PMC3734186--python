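"""Novel-gene calling and validation statistics.

After the binary model is trained on the labeled sets, every unlabeled
gene gets a cell-cycle probability; genes strictly above the cutoff
(default 0.8) form the called set and the remainder the predicted-
negative set.  Validation asks whether the called set behaves like known
cell-cycle genes: more physical interactions with them (Fisher's exact
test on a 2x2 pair-count table), lower periodicity/regulation p-values
and expression (Wilcoxon rank-sum), and more support from external
evidence sets (Fisher on supported/unsupported counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cyclepred.classify import PLRModel, predict_proba
from cyclepred.feature_io import FeatureMatrix


@dataclass
class ContingencyTable:
    """2x2 pair-count table: rows = predicted pos/neg, cols = with/without."""

    a: int  # called pairs with interaction
    b: int  # called pairs without
    c: int  # predicted-negative pairs with interaction
    d: int  # predicted-negative pairs without

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class PredictionSet:
    """Per-unlabeled-gene probabilities and the thresholded call set."""

    probabilities: pd.Series
    cutoff: float
    phase_calls: pd.Series | None = None
    phase_proba: pd.DataFrame | None = None

    @property
    def called(self) -> list[str]:
        return list(self.probabilities.index[self.probabilities > self.cutoff])

    @property
    def predicted_negative(self) -> list[str]:
        return list(self.probabilities.index[self.probabilities <= self.cutoff])

    def write(self, path, evidence_counts: pd.Series | None = None) -> None:
        out = pd.DataFrame({"probability": self.probabilities.loc[self.called]})
        if self.phase_calls is not None:
            out["phase"] = self.phase_calls.reindex(out.index)
        if self.phase_proba is not None:
            for c in self.phase_proba.columns:
                out[f"p_{c}"] = self.phase_proba[c].reindex(out.index)
        if evidence_counts is not None:
            out["evidence_count"] = evidence_counts.reindex(out.index).fillna(0).astype(int)
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def predict_novel(model: PLRModel, m_unlabeled: FeatureMatrix, cutoff: float = 0.8) -> PredictionSet:
    """Score unlabeled genes and call those strictly above the cutoff."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie strictly inside (0, 1)")
    if m_unlabeled.n_genes == 0:
        warnings.warn("no unlabeled genes to score")
        return PredictionSet(pd.Series(dtype=float), cutoff)
    return PredictionSet(predict_proba(model, m_unlabeled), cutoff)


def _edge_set(edges) -> set:
    if isinstance(edges, pd.DataFrame):
        pairs = edges.itertuples(index=False)
    else:
        pairs = edges
    return {frozenset((str(a), str(b))) for a, b in pairs if a != b}


def ppi_contingency(called, predicted_negative, known_positive, edges) -> ContingencyTable:
    """Count cross-set gene pairs with and without a physical interaction.

    Pairs run between each prediction set and the known positives; each
    unordered pair is counted once.
    """
    called, predneg, known = set(called), set(predicted_negative), set(known_positive)
    if called & predneg:
        raise ValueError("called and predicted-negative sets overlap")
    if known & (called | predneg):
        raise ValueError("known positives overlap a prediction set")
    a = c = 0
    for pair in _edge_set(edges):
        if len(pair) != 2:
            continue
        g, h = tuple(pair)
        if h in known:
            g, h = h, g
        if g not in known:
            continue
        # g is a known positive; classify the partner (cross-set pairs only)
        if h in called:
            a += 1
        elif h in predneg:
            c += 1
    return ContingencyTable(
        a=a,
        b=len(called) * len(known) - a,
        c=c,
        d=len(predneg) * len(known) - c,
    )


def fisher_exact(t: ContingencyTable, alternative: str = "greater") -> tuple[float, float]:
    """Fisher's exact test on the pair-count table.

    Returns (sample odds ratio a*d / b*c, p-value).  The two-sided
    p-value sums the probabilities of all tables as or less probable
    than the observed one.  A zero margin carries no information:
    p = 1 and the odds ratio is NA.
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    _, p = stats.fisher_exact(arr, alternative=alternative)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (t.a * t.d) / (t.b * t.c) if t.b * t.c > 0 else float("inf")
    return float(odds), float(p)


def ranksum_compare(values_a, values_b, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value comparing two samples.

    Exact null enumeration when the pooled sample has at most 20
    observations and no ties; otherwise the tie-corrected normal
    approximation (no continuity correction, so identical samples give
    exactly p = 1 two-sided).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    exact_ok = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


@dataclass
class SupportTally:
    """Evidence support of a called set versus the predicted negatives."""

    counts: pd.Series  # per-called-gene number of supporting sources
    supported_fraction: float
    sources: list = field(default_factory=list)


def support_tally(called, evidence_lists: dict) -> SupportTally:
    """Count, per called gene, the evidence sources containing it."""
    called = list(called)
    counts = pd.Series(0, index=pd.Index(called, name="gene"), dtype=int)
    for genes in evidence_lists.values():
        genes = set(genes)
        counts += pd.Series([g in genes for g in called], index=counts.index).astype(int)
    frac = float((counts > 0).mean()) if called else 0.0
    return SupportTally(counts=counts, supported_fraction=frac, sources=sorted(evidence_lists))


def proportion_test(
    called, negative, evidence_lists: dict, alternative: str = "greater"
) -> tuple[float, float]:
    """Fisher's exact test that called genes are supported more often.

    Builds the 2x2 supported/unsupported x called/negative table and
    returns (odds ratio, p-value).
    """
    tally_c = support_tally(called, evidence_lists)
    tally_n = support_tally(negative, evidence_lists)
    sup_c = int((tally_c.counts > 0).sum())
    sup_n = int((tally_n.counts > 0).sum())
    table = ContingencyTable(
        a=sup_c, b=len(tally_c.counts) - sup_c, c=sup_n, d=len(tally_n.counts) - sup_n
    )
    return fisher_exact(table, alternative=alternative)
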