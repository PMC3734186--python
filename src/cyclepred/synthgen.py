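"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates, at configurable scale, the inputs of the real
study: a strictly positive TF-binding occupancy matrix (log-normal
background), a sparse non-negative motif matching-score matrix (each
non-zero cell is a sum of per-occurrence match scores; absent motifs are
exact zeros), binary cell-cycle labels with per-positive peak phases, a
protein-protein interaction graph denser among cell-cycle genes, and
per-gene auxiliary scores mimicking periodicity/regulation p-values and
mRNA expression level.

"Driver" features carry the planted signal: a global driver's scores are
shifted upward in all true cell-cycle genes, a phase driver's only in the
positives of its phase.  The shift is ``effect_size`` times the standard
deviation of that block's background distribution, so power is directly
controllable.  All planted structure is recorded in a
:class:`SyntheticTruth` for downstream oracle checks.

The distributional families here are stand-ins: the real study's data
carry no published noise model, so the generator aims for the right
qualitative shape (positivity, right skew, exact zeros, class-conditional
shifts), not for distributional fidelity to ChIP-chip or motif-scan
scores.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cyclepred.feature_io import (
    CLASS_NEG,
    CLASS_POS,
    CLASS_UNLABELED,
    KIND_MOTIF,
    KIND_TF,
    PHASES,
    FeatureMatrix,
    GeneLabels,
    write_feature_table,
    write_labels,
)

# Phase mix of the curated positive set (219/156/100/95 G1/S/G2/M).
PHASE_PROPORTIONS = (219 / 570, 156 / 570, 100 / 570, 95 / 570)


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Scale, signal and noise knobs for one synthetic dataset.

    Defaults mirror the real study's dimensions: 6,229 genes with 203 TF
    and 539 motif features, 599 positive / 454 negative training labels.
    ``effect_size`` is the planted mean shift in units of the background
    SD of the feature's block.
    """

    n_genes: int = 6229
    n_tfs: int = 203
    n_motifs: int = 539
    n_pos: int = 599
    n_neg: int = 454
    n_drivers_per_phase: int = 2
    effect_size: float = 3.0
    motif_sparsity: float = 0.7
    ppi_base_rate: float = 0.003
    ppi_pos_enrichment: float = 5.0
    unlabeled_pos_frac: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_tfs": self.n_tfs,
            "n_motifs": self.n_motifs,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if self.n_drivers_per_phase < 0:
            raise ConfigError("n_drivers_per_phase must be non-negative")
        if self.n_pos + self.n_neg > self.n_genes:
            raise ConfigError("n_pos + n_neg exceeds n_genes")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be non-negative")
        for name in ("motif_sparsity", "ppi_base_rate", "unlabeled_pos_frac"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.ppi_pos_enrichment < 1.0:
            raise ConfigError("ppi_pos_enrichment must be >= 1")
        n_driver_features = self.n_drivers_per_phase * (len(PHASES) + 1)
        if n_driver_features > self.n_tfs + self.n_motifs:
            raise ConfigError("more drivers requested than features available")


@dataclass
class SyntheticTruth:
    """Book-keeping of everything the generator planted.

    ``gene_classes`` is the latent truth for every gene (including genes
    left unlabeled in the emitted label table); ``gene_phases`` assigns
    exactly one phase to every true positive.
    """

    driver_features: list = field(default_factory=list)  # (feature_id, phase|"global", +1)
    gene_classes: pd.Series = None
    gene_phases: pd.Series = None

    def drivers_for(self, scope: str) -> list[str]:
        return [f for f, s, _ in self.driver_features if s == scope]

    @property
    def driver_ids(self) -> list[str]:
        return [f for f, _, _ in self.driver_features]


# Background moments -------------------------------------------------------

#: SD of the log-normal(0, 1) TF occupancy background.
TF_BACKGROUND_SD = math.sqrt((math.e - 1.0) * math.e)


def motif_background_sd(sparsity: float) -> float:
    """SD of the marginal motif score: 0 w.p. s, else a sum of
    1+Poisson(1) Uniform(0.5, 1) per-occurrence match scores."""
    var_u, mean_u = 0.25**2 / 12.0, 0.75
    # N ~ 1 + Poisson(1): E[N] = 2, Var[N] = 1
    mean_nz = 2.0 * mean_u
    var_nz = 2.0 * var_u + 1.0 * mean_u**2
    p = 1.0 - sparsity
    return math.sqrt(p * (var_nz + mean_nz**2) - (p * mean_nz) ** 2)


_MOTIF_NZ_MEAN = 1.5  # E[sum of 1+Poisson(1) Uniform(0.5, 1) match scores]


def _motif_nonzero(rng: np.random.Generator, size: int) -> np.ndarray:
    """Aggregated matching scores for promoters that do contain the motif:
    the sum of one Uniform(0.5, 1) score per occurrence, 1+Poisson(1)
    occurrences."""
    values = np.zeros(size, dtype=float)
    n_occurrences = 1 + rng.poisson(1.0, size=size)
    for k in np.unique(n_occurrences):
        mask = n_occurrences == k
        values[mask] = rng.uniform(0.5, 1.0, size=(int(mask.sum()), int(k))).sum(axis=1)
    return values


def _motif_background(rng: np.random.Generator, shape, sparsity: float) -> np.ndarray:
    """Sparse aggregated matching scores: exact zero where the motif is
    absent, otherwise a :func:`_motif_nonzero` draw."""
    present = rng.random(shape) >= sparsity
    values = np.zeros(shape, dtype=float)
    values[present] = _motif_nonzero(rng, int(present.sum()))
    return values


def motif_target_params(effect_size: float, sparsity: float) -> tuple[float, float]:
    """Target-class motif distribution achieving an effect_size*SD mean shift.

    An elevated motif first occurs in more promoters (sparsity drops from
    ``sparsity`` toward 0), then — once every target promoter carries it —
    its per-promoter score gains a constant boost.  Returns
    (target sparsity, score boost); both collapse to the background at
    effect_size 0 and the shift is continuous and monotone in between.
    Scores stay non-negative and extra presence never exceeds certainty.
    """
    shift = effect_size * motif_background_sd(sparsity)
    max_densify = sparsity * _MOTIF_NZ_MEAN  # shift from presence alone
    if shift <= max_densify:
        return sparsity - shift / _MOTIF_NZ_MEAN, 0.0
    return 0.0, shift - max_densify


def simulate_dataset(config: SimConfig) -> tuple[FeatureMatrix, GeneLabels, SyntheticTruth]:
    """Generate one combined (TF + motif) feature matrix with planted drivers.

    Returns the matrix, the observed labels (``n_pos`` positives with
    phases, ``n_neg`` negatives, the rest unlabeled) and the full latent
    truth.  Identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    n, n_tf, n_motif = config.n_genes, config.n_tfs, config.n_motifs
    gene_ids = [f"G{i + 1:05d}" for i in range(n)]
    # TF features are genes too (TFs are gene products); the first n_tfs
    # gene ids double as the TF feature ids so circuit inference has real
    # regulator genes to point at.
    tf_ids = gene_ids[:n_tf]
    motif_ids = [f"M{j + 1:03d}" for j in range(n_motif)]

    # latent truth: which genes are truly periodic, and their peak phase
    n_true_extra = int(round(config.unlabeled_pos_frac * (n - config.n_pos - config.n_neg)))
    order = rng.permutation(n)
    pos_idx = order[: config.n_pos]
    neg_idx = order[config.n_pos : config.n_pos + config.n_neg]
    latent_idx = order[config.n_pos + config.n_neg : config.n_pos + config.n_neg + n_true_extra]
    true_pos = np.zeros(n, dtype=bool)
    true_pos[pos_idx] = True
    true_pos[latent_idx] = True

    classes_true = pd.Series(
        np.where(true_pos, CLASS_POS, CLASS_NEG), index=gene_ids, dtype=object
    )
    phases_true = pd.Series("NA", index=gene_ids, dtype=object)
    phases_true.iloc[np.flatnonzero(true_pos)] = rng.choice(
        PHASES, size=int(true_pos.sum()), p=PHASE_PROPORTIONS
    )

    observed = pd.Series(CLASS_UNLABELED, index=gene_ids, dtype=object)
    observed.iloc[pos_idx] = CLASS_POS
    observed.iloc[neg_idx] = CLASS_NEG
    observed_phases = pd.Series("NA", index=gene_ids, dtype=object)
    observed_phases.iloc[pos_idx] = phases_true.iloc[pos_idx]

    # backgrounds
    tf_block = rng.lognormal(mean=0.0, sigma=1.0, size=(n, n_tf))
    motif_block = _motif_background(rng, (n, n_motif), config.motif_sparsity)

    # drivers: alternate blocks so both cis and trans signal exists
    scopes = ["global"] * config.n_drivers_per_phase
    for phase in PHASES:
        scopes += [phase] * config.n_drivers_per_phase
    tf_pool = list(rng.permutation(n_tf))
    motif_pool = list(rng.permutation(n_motif))
    truth = SyntheticTruth(gene_classes=classes_true, gene_phases=phases_true)
    tf_shift = config.effect_size * TF_BACKGROUND_SD
    # motif drivers re-draw target-class cells: the motif becomes more
    # prevalent in target promoters (and, for large effects, stronger),
    # so the class-conditional mean moves by exactly effect_size*SD
    s_target, boost = motif_target_params(config.effect_size, config.motif_sparsity)

    for i, scope in enumerate(scopes):
        use_tf = (i % 2 == 0) if tf_pool else False
        if not motif_pool:
            use_tf = True
        if scope == "global":
            target = true_pos.copy()
        else:
            target = true_pos & (phases_true == scope).to_numpy()
        if use_tf:
            j = tf_pool.pop(0)
            tf_block[target, j] += tf_shift
            truth.driver_features.append((tf_ids[j], scope, +1))
        else:
            j = motif_pool.pop(0)
            if config.effect_size > 0:
                n_t = int(target.sum())
                cells = np.zeros(n_t)
                present = rng.random(n_t) >= s_target
                cells[present] = _motif_nonzero(rng, int(present.sum())) + boost
                motif_block[target, j] = cells
            truth.driver_features.append((motif_ids[j], scope, +1))

    values = pd.DataFrame(
        np.hstack([tf_block, motif_block]), index=gene_ids, columns=tf_ids + motif_ids
    )
    kinds = pd.Series(
        [KIND_TF] * n_tf + [KIND_MOTIF] * n_motif, index=values.columns
    )
    matrix = FeatureMatrix(values, kinds)
    labels = GeneLabels(observed, observed_phases)
    return matrix, labels, truth


def expected_zero_fraction(config: SimConfig) -> float:
    """Expected fraction of exact zeros in the motif block, accounting for
    the densified driver cells (oracle for sparsity checks)."""
    n_cells = config.n_genes * config.n_motifs
    if config.effect_size == 0 or config.n_drivers_per_phase == 0:
        return config.motif_sparsity
    s_target, _ = motif_target_params(config.effect_size, config.motif_sparsity)
    n_true = config.n_pos + int(
        round(config.unlabeled_pos_frac * (config.n_genes - config.n_pos - config.n_neg))
    )
    # motif drivers occupy the odd slots of the (global, G1, S, G2, M) x d
    # planting sequence; expected target size is all true positives for a
    # global driver, the phase share for a phase driver
    scopes = ["global"] * config.n_drivers_per_phase
    for phase in PHASES:
        scopes += [phase] * config.n_drivers_per_phase
    props = dict(zip(PHASES, PHASE_PROPORTIONS))
    target_cells = sum(
        n_true * (1.0 if scope == "global" else props[scope])
        for i, scope in enumerate(scopes)
        if i % 2 == 1
    )
    return (
        config.motif_sparsity * (n_cells - target_cells) + s_target * target_cells
    ) / n_cells


def simulate_aux_scores(truth: SyntheticTruth, config: SimConfig) -> pd.DataFrame:
    """Mock per-gene periodicity/regulation p-values and expression level.

    True positives are stochastically lower on all three scores (periodic
    genes have small meta-analysis p-values; newly discovered periodic
    genes tend to be lowly expressed).
    """
    rng = np.random.default_rng(config.seed + 1)
    pos = (truth.gene_classes == CLASS_POS).to_numpy()
    n = len(truth.gene_classes)
    pper = rng.uniform(0.0, 1.0, size=n)
    preg = rng.uniform(0.0, 1.0, size=n)
    pper[pos] = rng.beta(1.0, 9.0, size=int(pos.sum()))
    preg[pos] = rng.beta(1.0, 6.0, size=int(pos.sum()))
    expression = rng.lognormal(mean=0.7, sigma=1.0, size=n)
    expression[pos] = rng.lognormal(mean=0.0, sigma=1.0, size=int(pos.sum()))
    return pd.DataFrame(
        {"pper": pper, "preg": preg, "expression": expression},
        index=truth.gene_classes.index,
    )


def simulate_ppi(labels: GeneLabels, config: SimConfig) -> pd.DataFrame:
    """Undirected interaction edge list, denser between positive genes.

    Each unordered pair is an independent edge with probability
    ``ppi_base_rate``, multiplied by ``ppi_pos_enrichment`` (capped at 1)
    when both endpoints are positive.  Pass truth-derived labels to plant
    enrichment for latent positives as well.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = np.asarray(labels.gene_ids)
    pos = (labels.classes == CLASS_POS).to_numpy()
    n = len(genes)
    p_base = config.ppi_base_rate
    p_pos = min(p_base * config.ppi_pos_enrichment, 1.0)
    rows_a, rows_b = [], []
    for i in range(n - 1):
        u = rng.random(n - 1 - i)
        probs = np.where(pos[i] & pos[i + 1 :], p_pos, p_base)
        hits = np.flatnonzero(u < probs) + i + 1
        if hits.size:
            rows_a.append(np.full(hits.size, i))
            rows_b.append(hits)
    if rows_a:
        a = np.concatenate(rows_a)
        b = np.concatenate(rows_b)
        edges = pd.DataFrame({"gene_a": genes[a], "gene_b": genes[b]})
    else:
        edges = pd.DataFrame({"gene_a": [], "gene_b": []}, dtype=object)
    return edges


def simulate_evidence_lists(
    truth: SyntheticTruth,
    config: SimConfig,
    n_lists: int = 9,
    pos_rate: float = 0.06,
    neg_rate: float = 0.023,
) -> dict[str, set]:
    """Mock external support sets (prior screens / predictions).

    Each of the ``n_lists`` sources independently reports each true
    positive with probability ``pos_rate`` and each true negative with
    probability ``neg_rate``, so ~40% of true positives end up supported
    by at least one source versus ~19% of negatives.
    """
    rng = np.random.default_rng(config.seed + 3)
    genes = np.asarray(truth.gene_classes.index)
    pos = (truth.gene_classes == CLASS_POS).to_numpy()
    lists: dict[str, set] = {}
    for k in range(n_lists):
        rate = np.where(pos, pos_rate, neg_rate)
        hit = rng.random(len(genes)) < rate
        lists[f"source_{k + 1}"] = set(genes[hit])
    return lists


def simulate_tf_map(config: SimConfig) -> pd.DataFrame:
    """Injective motif -> TF-gene map for a subset of motifs (the real
    study could assign TFs to 46 of its motifs)."""
    rng = np.random.default_rng(config.seed + 4)
    n_mapped = min(config.n_motifs, config.n_tfs, max(1, min(config.n_motifs, 46)))
    motifs = [f"M{j + 1:03d}" for j in sorted(rng.choice(config.n_motifs, size=n_mapped, replace=False))]
    tfs = [f"G{i + 1:05d}" for i in sorted(rng.choice(config.n_tfs, size=n_mapped, replace=False))]
    return pd.DataFrame({"motif": motifs, "tf": tfs})


# ---------------------------------------------------------------------------
# Fixture writing


def write_truth(truth: SyntheticTruth, directory) -> None:
    drivers = pd.DataFrame(
        truth.driver_features, columns=["feature", "scope", "direction"]
    )
    drivers.to_csv(os.path.join(directory, "truth_drivers.tsv"), sep="\t", index=False)
    classes = pd.DataFrame(
        {"class": truth.gene_classes, "phase": truth.gene_phases}
    )
    classes.index.name = "gene"
    classes.to_csv(os.path.join(directory, "truth_classes.tsv"), sep="\t")


def read_truth(directory) -> SyntheticTruth:
    drivers = pd.read_csv(os.path.join(directory, "truth_drivers.tsv"), sep="\t")
    classes = pd.read_csv(
        os.path.join(directory, "truth_classes.tsv"), sep="\t", index_col=0
    )
    return SyntheticTruth(
        driver_features=[tuple(r) for r in drivers.itertuples(index=False)],
        gene_classes=classes["class"],
        gene_phases=classes["phase"],
    )


def write_fixture(directory, config: SimConfig) -> dict:
    """Simulate a full dataset and write every piece as TSV.

    Emits the TF and motif matrices, label table, truth files, PPI edge
    list, auxiliary scores, evidence lists and motif->TF map; returns the
    in-memory objects keyed by name.
    """
    os.makedirs(directory, exist_ok=True)
    matrix, labels, truth = simulate_dataset(config)
    true_labels = GeneLabels(truth.gene_classes.copy())
    edges = simulate_ppi(true_labels, config)
    aux = simulate_aux_scores(truth, config)
    evidence = simulate_evidence_lists(truth, config)
    tf_map = simulate_tf_map(config)

    write_feature_table(matrix.block(KIND_TF), os.path.join(directory, "features_tf.tsv"))
    write_feature_table(matrix.block(KIND_MOTIF), os.path.join(directory, "features_motif.tsv"))
    write_labels(labels, os.path.join(directory, "labels.tsv"))
    write_truth(truth, directory)
    edges.to_csv(os.path.join(directory, "ppi.tsv"), sep="\t", index=False)
    aux_out = aux.copy()
    aux_out.index.name = "gene"
    aux_out.to_csv(os.path.join(directory, "aux_scores.tsv"), sep="\t")
    rows = [(name, gene) for name in sorted(evidence) for gene in sorted(evidence[name])]
    pd.DataFrame(rows, columns=["source", "gene"]).to_csv(
        os.path.join(directory, "evidence.tsv"), sep="\t", index=False
    )
    tf_map.to_csv(os.path.join(directory, "tf_map.tsv"), sep="\t", index=False)
    return {
        "matrix": matrix,
        "labels": labels,
        "truth": truth,
        "edges": edges,
        "aux": aux,
        "evidence": evidence,
        "tf_map": tf_map,
    }


KEY_TFS = ("SWI5", "ACE2", "MBP1", "FKH1", "SWI4", "SWI6", "NDD1", "FKH2", "MCM1")


def circuit_chain_fixture() -> tuple[FeatureMatrix, dict[str, str], list[str], list[tuple]]:
    """Engineered miniature dataset carrying the known regulator cascade.

    Synthetic stand-in (not measured data): 20 promoter rows — the nine
    key cell-cycle TFs plus eleven filler genes — with hand-placed scores
    such that exactly three regulatory calls survive the circuit criteria:
    Mbp1's motif in Swi4's promoter, Swi4's motif in Ndd1's promoter
    (both motif evidence) and Ndd1's binding in Swi5's promoter (ChIP
    evidence).  A deliberately unmapped motif scores high in Mcm1's
    promoter to exercise the no-map-no-edge rule.

    Returns (raw matrix, motif->TF map, target TF list, expected edges as
    (regulator, target, evidence) triples).
    """
    genes = list(KEY_TFS) + [f"FILLER{i:02d}" for i in range(1, 12)]
    n = len(genes)
    tf_cols = {}
    for j, tf in enumerate(KEY_TFS):
        # distinct sub-threshold occupancy background (log2 < 2 everywhere)
        tf_cols[tf] = np.linspace(0.85, 1.15, n) + 0.001 * j
    tf_cols["NDD1"][genes.index("SWI5")] = 8.0  # log2 = 3, top rank
    motif_cols = {m: np.zeros(n) for m in ("M_MBP1", "M_SWI4", "M_UNMAPPED")}
    for m in motif_cols:  # sprinkle weak sub-threshold occurrences
        motif_cols[m][genes.index("FILLER03")] = 0.2
        motif_cols[m][genes.index("FILLER07")] = 0.3
    motif_cols["M_MBP1"][genes.index("SWI4")] = 0.9
    motif_cols["M_SWI4"][genes.index("NDD1")] = 0.9
    motif_cols["M_UNMAPPED"][genes.index("MCM1")] = 0.95  # high but unmapped

    values = pd.DataFrame(
        {**tf_cols, **motif_cols}, index=genes,
        columns=list(KEY_TFS) + list(motif_cols),
    )
    kinds = pd.Series(
        [KIND_TF] * len(KEY_TFS) + [KIND_MOTIF] * len(motif_cols), index=values.columns
    )
    tf_map = {"M_MBP1": "MBP1", "M_SWI4": "SWI4"}
    expected = [
        ("MBP1", "SWI4", "motif"),
        ("NDD1", "SWI5", "binding"),
        ("SWI4", "NDD1", "motif"),
    ]
    return FeatureMatrix(values, kinds), tf_map, list(KEY_TFS), expected


def scaled_config(**overrides) -> SimConfig:
    """A desk-scale configuration (same structure, smaller matrices)."""
    base = dict(
        n_genes=700,
        n_tfs=60,
        n_motifs=120,
        n_pos=300,
        n_neg=300,
        n_drivers_per_phase=2,
        effect_size=3.0,
        motif_sparsity=0.7,
        ppi_base_rate=0.01,
        ppi_pos_enrichment=5.0,
        unlabeled_pos_frac=0.3,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)
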