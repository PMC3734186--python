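"""Core data containers and TSV I/O for gene x feature score matrices.

A :class:`FeatureMatrix` holds a real-valued genes x features table in
which every feature is tagged either ``"tf"`` (a ChIP-chip occupancy
ratio for one transcription factor, strictly positive on the raw scale)
or ``"motif"`` (an aggregated motif matching score, non-negative with
exact zeros where the motif is absent from the promoter).

On disk the kind tag is carried by the header: TF columns are prefixed
``TF:`` and motif columns ``M:``.  In memory feature ids are stored
without the prefix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KIND_TF = "tf"
KIND_MOTIF = "motif"
_KINDS = (KIND_TF, KIND_MOTIF)
_PREFIX = {KIND_TF: "TF:", KIND_MOTIF: "M:"}

PHASES = ("G1", "S", "G2", "M")
CLASS_POS = "pos"
CLASS_NEG = "neg"
CLASS_UNLABELED = "unlabeled"


class ParseError(ValueError):
    """A TSV table could not be parsed (ragged row, bad cell, duplicate id)."""


@dataclass
class FeatureMatrix:
    """Genes x features score table with per-feature kind tags.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with feature ids as columns.
    kinds
        Series aligned to ``values.columns`` with entries in
        ``{"tf", "motif"}``.
    """

    values: pd.DataFrame
    kinds: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ParseError(f"duplicate gene id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ParseError(f"duplicate feature id: {dup!r}")
        self.kinds = pd.Series(self.kinds, index=self.values.columns)
        bad = set(self.kinds.unique()) - set(_KINDS)
        if bad:
            raise ValueError(f"unknown feature kinds: {sorted(bad)}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def block(self, kind: str) -> "FeatureMatrix":
        """Sub-matrix of one feature kind (column order preserved)."""
        cols = [f for f, k in self.kinds.items() if k == kind]
        return FeatureMatrix(self.values[cols].copy(), self.kinds[cols].copy())

    def subset_genes(self, gene_ids) -> "FeatureMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return FeatureMatrix(self.values.loc[list(gene_ids)].copy(), self.kinds.copy())

    def subset_features(self, feature_ids) -> "FeatureMatrix":
        missing = [f for f in feature_ids if f not in self.values.columns]
        if missing:
            raise KeyError(f"features absent from matrix: {missing[:5]}")
        return FeatureMatrix(self.values[list(feature_ids)].copy(), self.kinds[list(feature_ids)].copy())


@dataclass
class GeneLabels:
    """Per-gene class (pos / neg / unlabeled) and peak phase (G1/S/G2/M/NA).

    A phase other than ``"NA"`` is only meaningful for positive
    (cell-cycle) genes.
    """

    classes: pd.Series
    phases: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        self.classes = pd.Series(self.classes)
        if self.phases is None:
            self.phases = pd.Series("NA", index=self.classes.index)
        self.phases = pd.Series(self.phases).reindex(self.classes.index).fillna("NA")
        bad = set(self.classes.unique()) - {CLASS_POS, CLASS_NEG, CLASS_UNLABELED}
        if bad:
            raise ValueError(f"unknown gene classes: {sorted(bad)}")
        bad = set(self.phases.unique()) - set(PHASES) - {"NA"}
        if bad:
            raise ValueError(f"unknown phases: {sorted(bad)}")
        offender = (self.phases != "NA") & (self.classes != CLASS_POS)
        if offender.any():
            g = self.phases.index[offender][0]
            raise ValueError(f"gene {g!r} has a phase but is not a positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.classes.index)

    @property
    def labeled_genes(self) -> list[str]:
        mask = self.classes != CLASS_UNLABELED
        return list(self.classes.index[mask])

    @property
    def unlabeled_genes(self) -> list[str]:
        return list(self.classes.index[self.classes == CLASS_UNLABELED])

    def y(self, genes=None) -> pd.Series:
        """Binary response (1 = cell cycle, 0 = not) over labeled genes."""
        cls = self.classes if genes is None else self.classes.loc[list(genes)]
        cls = cls[cls != CLASS_UNLABELED]
        return (cls == CLASS_POS).astype(int)

    def phase_of(self, genes=None) -> pd.Series:
        """Phases of positive genes (optionally restricted to ``genes``)."""
        ph = self.phases if genes is None else self.phases.loc[list(genes)]
        return ph[ph != "NA"]


# ---------------------------------------------------------------------------
# TSV I/O


def _diagnose_table(path) -> None:
    """Re-scan a TSV that pandas rejected and raise a line-numbered error."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        width = len(header)
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != width:
                raise ParseError(
                    f"{path}: line {lineno}: expected {width} columns, found {len(cells)}"
                )
            for cell in cells[1:]:
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric cell {cell!r}"
                    ) from None


def _split_prefixed(feature_id: str):
    for kind, prefix in _PREFIX.items():
        if feature_id.startswith(prefix):
            return feature_id[len(prefix):], kind
    return feature_id, None


def read_feature_table(path, kind: str | None = None) -> FeatureMatrix:
    """Read a genes x features TSV.

    Column kinds are taken from the ``TF:`` / ``M:`` header prefixes; for
    unprefixed columns ``kind`` must be supplied and applies to all of them.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        df = df.apply(lambda col: col.astype(float))
    except (ValueError, pd.errors.ParserError):
        _diagnose_table(path)
        raise  # unreachable if the diagnosis finds the defect
    if df.isna().to_numpy().any():
        _diagnose_table(path)  # pandas NaN-pads ragged rows; locate the line
        raise ParseError(f"{path}: table contains missing cells")
    ids, kinds = [], []
    for col in df.columns:
        fid, k = _split_prefixed(str(col))
        if k is None:
            if kind is None:
                raise ParseError(
                    f"{path}: column {col!r} has no TF:/M: prefix and no kind was given"
                )
            k = kind
        ids.append(fid)
        kinds.append(k)
    if kind is not None and any(k != kind for k in kinds):
        raise ParseError(f"{path}: header prefixes disagree with kind={kind!r}")
    df.columns = ids
    df.index = df.index.astype(str)
    df.index.name = None
    return FeatureMatrix(df, pd.Series(kinds, index=df.columns))


def write_feature_table(m: FeatureMatrix, path) -> None:
    """Write a FeatureMatrix as TSV with kind-prefixed header ids."""
    out = m.values.copy()
    out.columns = [_PREFIX[m.kinds[f]] + f for f in m.values.columns]
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_labels(path) -> GeneLabels:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.set_index(df.columns[0])
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    return GeneLabels(df.iloc[:, 0], df.iloc[:, 1] if df.shape[1] > 1 else None)


def write_labels(labels: GeneLabels, path) -> None:
    df = pd.DataFrame({"class": labels.classes, "phase": labels.phases})
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Matrix operations


def combine_matrices(tf: FeatureMatrix, motif: FeatureMatrix) -> FeatureMatrix:
    """Join the TF-binding and motif blocks on their shared genes.

    The gene set is the intersection of the two gene lists in the TF
    matrix's order; columns are the TF block followed by the motif block.
    """
    shared = [g for g in tf.gene_ids if g in set(motif.gene_ids)]
    if not shared:
        raise ValueError("no genes shared between the TF and motif matrices")
    clash = set(tf.feature_ids) & set(motif.feature_ids)
    if clash:
        raise ValueError(f"feature id collision across blocks: {sorted(clash)[:5]}")
    values = pd.concat(
        [tf.values.loc[shared], motif.values.loc[shared]], axis=1
    )
    kinds = pd.concat([tf.kinds, motif.kinds])
    return FeatureMatrix(values, kinds)


def quantile_normalize(m: FeatureMatrix) -> FeatureMatrix:
    """Force every feature column onto the shared reference distribution.

    The reference's k-th smallest value is the mean over columns of each
    column's k-th smallest value; within a column, original ranks are
    preserved and tied values all receive the mean of the reference values
    at their tied ranks (average-ties convention, relevant for the exact
    zeros of motif columns).
    """
    if m.n_genes <= 1:
        return FeatureMatrix(m.values.copy(), m.kinds.copy())
    vals = m.values.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average reference values over groups of tied originals
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return FeatureMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        m.kinds.copy(),
    )


def log_transform_tf(m: FeatureMatrix, base: float = 2.0) -> FeatureMatrix:
    """Replace TF columns by log_base(occupancy ratio); motif columns untouched."""
    tf_cols = [f for f, k in m.kinds.items() if k == KIND_TF]
    values = m.values.copy()
    if tf_cols:
        block = values[tf_cols].to_numpy(dtype=float)
        if (block <= 0).any():
            raise ValueError("TF occupancy ratios must be strictly positive for log transform")
        values[tf_cols] = np.log(block) / math.log(base)
    return FeatureMatrix(values, m.kinds.copy())


def align(m: FeatureMatrix, labels: GeneLabels) -> tuple[FeatureMatrix, GeneLabels]:
    """Restrict labels to genes present in the matrix, erroring on orphans."""
    missing = [g for g in labels.labeled_genes if g not in m.values.index]
    if missing:
        raise KeyError(f"labeled genes missing from feature matrix: {missing[:5]}")
    keep = [g for g in labels.gene_ids if g in m.values.index]
    return m, GeneLabels(labels.classes.loc[keep], labels.phases.loc[keep])
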