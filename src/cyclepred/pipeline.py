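"""End-to-end orchestration of the analysis stages.

``run_pipeline`` sequences: combine -> quantile-normalize (for the
circuit) -> pre-select -> cross-validated evaluation -> final fit ->
novel-gene calling -> phase assignment -> enrichment validation ->
circuit inference, writing each stage's TSV outputs plus a JSON run
summary.  The same stage functions back the CLI subcommands, so running
stages individually reproduces the pipeline outputs exactly.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from cyclepred import circuit as circuit_mod
from cyclepred import classify, downstream, evaluate, preselect
from cyclepred.feature_io import (
    CLASS_POS,
    KIND_MOTIF,
    KIND_TF,
    PHASES,
    FeatureMatrix,
    GeneLabels,
    combine_matrices,
    quantile_normalize,
    read_feature_table,
    read_labels,
    write_feature_table,
)

log = logging.getLogger("cyclepred")


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    Threshold defaults are the analysis' canonical values: t-test
    pre-selection at p < 0.001, ANOVA at p < 0.01, 10-fold CV, call
    cutoff 0.8, circuit criteria (NS > 0.9, log occupancy > 2, motif
    score > 0.5).
    """

    tf_matrix: str = "features_tf.tsv"
    motif_matrix: str = "features_motif.tsv"
    labels: str = "labels.tsv"
    ppi_edges: str | None = "ppi.tsv"
    aux_scores: str | None = "aux_scores.tsv"
    evidence: str | None = "evidence.tsv"
    tf_map: str | None = "tf_map.tsv"
    lam: float = 1.0
    alpha_ttest: float = 0.001
    alpha_anova: float = 0.01
    k_folds: int = 10
    call_cutoff: float = 0.8
    phase_threshold: float = 0.5
    ns_threshold: float = 0.9
    tf_log_threshold: float = 2.0
    motif_score_threshold: float = 0.5
    log_base: float = 2.0
    seed: int = 0
    select_within_folds: bool = False
    circuit_targets: list = field(default_factory=list)

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if not 0.0 < self.call_cutoff < 1.0:
            raise ValueError("call_cutoff must lie in (0, 1)")
        if not 0.0 <= self.phase_threshold <= 1.0:
            raise ValueError("phase_threshold must lie in [0, 1]")
        for name in ("alpha_ttest", "alpha_anova"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.log_base <= 1.0:
            raise ValueError("log_base must exceed 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def plr_fitter(lam: float, alpha: float | None = None):
    """kfold_cv fitter for the binary model.

    With ``alpha`` set, the t-test pre-selection runs inside each
    training fold (the leakage-free variant); otherwise the matrix is
    assumed pre-selected.
    """

    def fit(train_m: FeatureMatrix, train_y: pd.Series):
        y = pd.Series(train_y).astype(int)
        m = train_m
        if alpha is not None:
            labels = GeneLabels(
                pd.Series(np.where(y == 1, "pos", "neg"), index=y.index, dtype=object)
            )
            sel = preselect.ttest_select(m, labels, alpha)
            if sel.kept:
                m = sel.apply(m)
        model = classify.fit_plr(m, y, lam)

        def score(test_m: FeatureMatrix):
            return classify.predict_proba(model, test_m).to_numpy()

        return score

    return fit


def rmlr_fitter(lam: float, alpha: float | None = None):
    """kfold_cv fitter for the multinomial phase model."""

    def fit(train_m: FeatureMatrix, train_phases: pd.Series):
        m = train_m
        if alpha is not None:
            sel = preselect.anova_select(m, train_phases, alpha)
            if sel.kept:
                m = sel.apply(m)
        model = classify.fit_rmlr(m, train_phases, lam)

        def score(test_m: FeatureMatrix):
            proba = classify.predict_phase_proba(model, test_m)
            return proba.reindex(columns=list(PHASES), fill_value=0.0).to_numpy()

        return score

    return fit


def _evaluate_binary(m, labels, cfg) -> tuple[evaluate.CVResult, evaluate.ROCCurve]:
    y = labels.y()
    genes = [g for g in y.index if g in m.values.index]
    sub = m.subset_genes(genes)
    if cfg.select_within_folds:
        fitter = plr_fitter(cfg.lam, cfg.alpha_ttest)
    else:
        sel = preselect.ttest_select(sub, labels, cfg.alpha_ttest)
        if sel.kept:
            sub = sel.apply(sub)
        fitter = plr_fitter(cfg.lam)
    cv = evaluate.kfold_cv(sub, y.loc[genes], cfg.k_folds, fitter, cfg.seed)
    roc = evaluate.roc_auc(cv.binary_scores, cv.labels)
    return cv, roc


def run_pipeline(config: RunConfig, workdir, outdir) -> dict:
    """Execute every stage on the files under ``workdir``; write results
    to ``outdir`` and return the machine-readable summary dict."""
    config.validate()
    os.makedirs(outdir, exist_ok=True)

    def path(p):
        return p if os.path.isabs(p) else os.path.join(workdir, p)

    tf_m = read_feature_table(path(config.tf_matrix), kind=KIND_TF)
    motif_m = read_feature_table(path(config.motif_matrix), kind=KIND_MOTIF)
    labels = read_labels(path(config.labels))
    log.info(
        "inputs: %d TF x %d genes, %d motif x %d genes, %d labeled",
        tf_m.n_features, tf_m.n_genes, motif_m.n_features, motif_m.n_genes,
        len(labels.labeled_genes),
    )

    # combine + normalize
    combined = combine_matrices(tf_m, motif_m)
    write_feature_table(combined, os.path.join(outdir, "combined.tsv"))
    normalized = quantile_normalize(combined)
    write_feature_table(normalized, os.path.join(outdir, "normalized.tsv"))
    log.info("combined matrix: %d genes x %d features", combined.n_genes, combined.n_features)

    # pre-selection report (full labeled set)
    sel = preselect.ttest_select(
        combined.subset_genes([g for g in labels.labeled_genes if g in combined.values.index]),
        labels,
        config.alpha_ttest,
    )
    sel.write(os.path.join(outdir, "selection.tsv"), combined.kinds)
    log.info("t-test selection kept %d / %d features", len(sel.kept), combined.n_features)

    # cross-validated evaluation: TF-only, motif-only, combined
    summary: dict = {"seed": config.seed, "k_folds": config.k_folds, "lambda": config.lam}
    for name, matrix in (
        ("tf", combined.block(KIND_TF)),
        ("motif", combined.block(KIND_MOTIF)),
        ("combined", combined),
    ):
        cv, roc = _evaluate_binary(matrix, labels, config)
        roc.write(os.path.join(outdir, f"roc_{name}.tsv"))
        cv.write(os.path.join(outdir, f"cv_{name}.tsv"))
        summary[f"auc_{name}"] = roc.auc
        log.info("%s model CV AUC = %.3f", name, roc.auc)
        if name == "combined":
            fpr, sens = evaluate.operating_point(
                cv.binary_scores, cv.labels, config.call_cutoff
            )
            summary["operating_fpr"] = fpr
            summary["operating_sensitivity"] = sens
            combined_cv = cv

    # final binary fit on all labeled genes (pre-selected features)
    fit_m = combined.subset_genes(
        [g for g in labels.labeled_genes if g in combined.values.index]
    )
    fit_m = sel.apply(fit_m) if sel.kept else fit_m
    model = classify.fit_plr(fit_m, labels, config.lam)
    classify.coef_zscores(model, fit_m, labels)
    classify.write_plr_model(model, os.path.join(outdir, "model_plr.tsv"))
    n_sig = int((model.pvalues < 0.01).sum())
    summary["n_significant_features"] = n_sig
    log.info("final model: %d features significant at p < 0.01", n_sig)

    # novel calls
    unlabeled = [g for g in labels.unlabeled_genes if g in combined.values.index]
    pred = downstream.predict_novel(
        model, combined.subset_genes(unlabeled).subset_features(model.feature_ids),
        config.call_cutoff,
    )
    summary["n_unlabeled"] = len(unlabeled)
    summary["n_called"] = len(pred.called)
    log.info("%d of %d unlabeled genes called at cutoff %.2f",
             len(pred.called), len(unlabeled), config.call_cutoff)

    # phase models: one-vs-rest AUCs and multinomial CV
    positives = [g for g in labels.classes.index[labels.classes == CLASS_POS]
                 if g in combined.values.index]
    phases = labels.phase_of(positives)
    pos_m = combined.subset_genes(list(phases.index))
    phase_sel = preselect.anova_select(pos_m, phases, config.alpha_anova)
    phase_sel.write(os.path.join(outdir, "selection_phase.tsv"), combined.kinds)
    pos_sel_m = phase_sel.apply(pos_m) if phase_sel.kept else pos_m
    for phase in PHASES:
        y_phase = (phases == phase).astype(int)
        if y_phase.sum() < config.k_folds:
            continue
        sel_p = preselect.ttest_select(
            pos_m,
            GeneLabels(pd.Series(np.where(y_phase == 1, "pos", "neg"),
                                 index=y_phase.index, dtype=object)),
            config.alpha_ttest,
        )
        m_p = sel_p.apply(pos_m) if sel_p.kept else pos_m
        cv_p = evaluate.kfold_cv(m_p, y_phase, config.k_folds, plr_fitter(config.lam), config.seed)
        summary[f"auc_phase_{phase}"] = evaluate.roc_auc(cv_p.binary_scores, cv_p.labels).auc
        log.info("phase %s one-vs-rest CV AUC = %.3f", phase, summary[f"auc_phase_{phase}"])

    k_phase = min(config.k_folds, int(phases.value_counts().min()))
    if k_phase >= 2:
        cv_mc = evaluate.kfold_cv(
            pos_sel_m, phases, k_phase, rmlr_fitter(config.lam), config.seed
        )
        proba = cv_mc.scores
        proba.columns = list(PHASES)
        present = [c for c in PHASES if (phases == c).any()]
        summary["hand_till_auc"] = evaluate.hand_till_auc(proba[present], phases)
        table = evaluate.precision_vs_threshold(
            proba[present], phases, np.arange(0.0, 1.0, 0.05)
        )
        table.to_csv(os.path.join(outdir, "phase_precision.tsv"), sep="\t", index=False)
        summary["phase_accuracy"] = float(table.iloc[0]["precision"])
        log.info("multinomial phase model: Hand-Till AUC = %.3f, accuracy = %.3f",
                 summary["hand_till_auc"], summary["phase_accuracy"])

    # phase calls for the novel genes
    rmlr = classify.fit_rmlr(pos_sel_m, phases, config.lam)
    classify.write_rmlr_model(rmlr, os.path.join(outdir, "model_rmlr.tsv"))
    if pred.called:
        calls, call_proba = classify.predict_phase(
            rmlr,
            combined.subset_genes(pred.called).subset_features(rmlr.feature_ids),
            config.phase_threshold,
        )
        pred.phase_calls = calls
        pred.phase_proba = call_proba
        summary["n_unclear_phase"] = int((calls == "unclear").sum())

    # enrichment validation
    known_pos = set(positives)
    if config.ppi_edges and os.path.exists(path(config.ppi_edges)):
        edges = pd.read_csv(path(config.ppi_edges), sep="\t", dtype=str)
        table = downstream.ppi_contingency(
            pred.called, pred.predicted_negative, known_pos, edges
        )
        odds, p = downstream.fisher_exact(table, "greater")
        summary["ppi_contingency"] = [table.a, table.b, table.c, table.d]
        summary["ppi_odds_ratio"] = odds
        summary["ppi_enrichment_p"] = p
        log.info("PPI enrichment: OR = %.2f, p = %.3g", odds, p)

    if config.aux_scores and os.path.exists(path(config.aux_scores)):
        aux = pd.read_csv(path(config.aux_scores), sep="\t", index_col=0)
        for col in aux.columns:
            a = aux[col].reindex(pred.called).dropna()
            b = aux[col].reindex(pred.predicted_negative).dropna()
            if len(a) and len(b):
                summary[f"ranksum_{col}_p"] = downstream.ranksum_compare(a, b, "less")

    evidence_counts = None
    if config.evidence and os.path.exists(path(config.evidence)):
        ev = pd.read_csv(path(config.evidence), sep="\t", dtype=str)
        lists: dict[str, set] = {}
        for source, group in ev.groupby(ev.columns[0]):
            lists[str(source)] = set(group.iloc[:, 1])
        tally = downstream.support_tally(pred.called, lists)
        evidence_counts = tally.counts
        summary["supported_fraction"] = tally.supported_fraction
        if pred.called and pred.predicted_negative:
            _, p = downstream.proportion_test(pred.called, pred.predicted_negative, lists)
            summary["support_enrichment_p"] = p

    pred.write(os.path.join(outdir, "called_genes.tsv"), evidence_counts)

    # circuit inference
    if config.tf_map and os.path.exists(path(config.tf_map)):
        tf_map = circuit_mod.read_tf_map(path(config.tf_map))
        if config.circuit_targets:
            targets = [g for g in config.circuit_targets if g in combined.values.index]
        else:
            # default: the first few TF-coding genes (the real analysis
            # examined 9 key cell-cycle TFs)
            targets = [
                f for f, k in combined.kinds.items()
                if k == KIND_TF and f in combined.values.index
            ][:9]
        if targets:
            edges_c = circuit_mod.infer_edges(
                combined, normalized, tf_map, targets,
                log_base=config.log_base,
                ns_threshold=config.ns_threshold,
                tf_log_threshold=config.tf_log_threshold,
                motif_score_threshold=config.motif_score_threshold,
            )
            circuit_mod.export_graph(edges_c, os.path.join(outdir, "circuit.dot"), "dot")
            circuit_mod.export_graph(edges_c, os.path.join(outdir, "circuit.graphml"), "graphml")
            report = circuit_mod.edge_report(
                combined, normalized, tf_map, targets, log_base=config.log_base
            )
            report.to_csv(os.path.join(outdir, "circuit_report.tsv"), sep="\t", index=False)
            summary["n_circuit_edges"] = len(edges_c)
            log.info("circuit: %d edges over %d target TFs", len(edges_c), len(targets))

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def write_default_config(path, **overrides) -> None:
    cfg = asdict(RunConfig(**overrides))
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
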