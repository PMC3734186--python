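import numpy as np
import pandas as pd
import pytest

from cyclepred import classify, evaluate, preselect, synthgen
from cyclepred.feature_io import FeatureMatrix, GeneLabels
from cyclepred.pipeline import rmlr_fitter


@pytest.fixture(scope="session")
def scaled_dataset():
    """One planted dataset at the standard desk scale (shared, read-only)."""
    cfg = synthgen.scaled_config(seed=11)
    matrix, labels, truth = synthgen.simulate_dataset(cfg)
    return cfg, matrix, labels, truth


@pytest.fixture(scope="session")
def fitted_binary(scaled_dataset):
    """Pre-selected matrix and fitted binary model on the scaled dataset."""
    cfg, matrix, labels, truth = scaled_dataset
    sub = matrix.subset_genes(labels.labeled_genes)
    sel = preselect.ttest_select(sub, labels, 0.001)
    sub = sel.apply(sub)
    model = classify.fit_plr(sub, labels, 1.0)
    classify.coef_zscores(model, sub, labels)
    return sub, model


@pytest.fixture(scope="session")
def phase_cv(scaled_dataset):
    """Out-of-fold phase probabilities from the multinomial model."""
    cfg, matrix, labels, truth = scaled_dataset
    phases = labels.phase_of()
    pos_m = matrix.subset_genes(list(phases.index))
    sel = preselect.anova_select(pos_m, phases, 0.01)
    cv = evaluate.kfold_cv(sel.apply(pos_m), phases, 5, rmlr_fitter(1.0), seed=2)
    proba = cv.scores
    proba.columns = list(synthgen.PHASES)
    return proba, phases


def toy_matrix(values, kinds=None, genes=None, features=None) -> FeatureMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    features = features or [f"f{j}" for j in range(arr.shape[1])]
    kinds = kinds or ["tf"] * arr.shape[1]
    return FeatureMatrix(
        pd.DataFrame(arr, index=genes, columns=features),
        pd.Series(kinds, index=features),
    )


def binary_labels(y, genes=None) -> GeneLabels:
    y = np.asarray(y)
    genes = genes or [f"g{i}" for i in range(len(y))]
    cls = pd.Series(np.where(y == 1, "pos", "neg"), index=genes, dtype=object)
    return GeneLabels(cls)
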