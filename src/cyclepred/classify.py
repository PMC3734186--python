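"""Ridge-penalized logistic regression (binary and multinomial).

The binary model is the classical logit

    log Pr(y=1|x) / Pr(y=0|x) = beta0 + x' beta

fitted by minimizing the penalized negative binomial log-likelihood

    L(beta0, beta) = -l(beta0, beta) + (lambda/2) * ||beta||_2^2

with the intercept unpenalized.  The multinomial extension puts one
intercept and one coefficient vector per phase under a softmax link and
penalizes (lambda/2) * sum_c ||beta_c||^2.  Because the slope penalty
leaves the common intercept direction flat, intercepts are constrained
to sum to zero (a pure reparameterization of the same probabilities).

Both solvers are damped Newton (IRLS) with step halving, so the
objective decreases monotonically; convergence is declared when the
gradient max-norm drops below ``tol``.

Per-coefficient z-scores follow the Wald construction with standard
errors from the inverse of the penalized Hessian at the optimum — the
machinery behind "significant features" in the analysis.

Features are standardized (mean 0, SD 1) on the training data by
default, so a single lambda is meaningful across heterogeneous TF and
motif scales; coefficients are reported on the standardized scale and
standardization constants travel with the model for prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logsumexp, softmax

from cyclepred.feature_io import PHASES, FeatureMatrix, GeneLabels

_MAX_ITER = 100
_TOL = 1e-6


@dataclass
class PLRModel:
    """Fitted binary ridge-logistic model."""

    beta0: float
    beta: np.ndarray
    lam: float
    feature_ids: list
    means: np.ndarray
    sds: np.ndarray
    converged: bool
    objective_value: float
    objective_history: list = field(default_factory=list)
    zscores: np.ndarray | None = None
    pvalues: np.ndarray | None = None

    def linear_predictor(self, m: FeatureMatrix) -> pd.Series:
        X = _design(m, self.feature_ids, self.means, self.sds)
        return pd.Series(self.beta0 + X @ self.beta, index=m.values.index)


@dataclass
class RMLRModel:
    """Fitted multinomial (phase) ridge-logistic model."""

    classes: list
    intercepts: np.ndarray  # (K,)
    coefs: np.ndarray  # (K, p)
    lam: float
    feature_ids: list
    means: np.ndarray
    sds: np.ndarray
    converged: bool
    objective_value: float
    objective_history: list = field(default_factory=list)


def _standardize_fit(X: np.ndarray, standardize: bool):
    if not standardize:
        return np.zeros(X.shape[1]), np.ones(X.shape[1])
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds == 0, 1.0, sds)
    return means, sds


def _design(m: FeatureMatrix, feature_ids, means, sds) -> np.ndarray:
    missing = [f for f in feature_ids if f not in m.values.columns]
    if missing:
        raise KeyError(f"feature columns missing from matrix: {missing[:5]}")
    X = m.values[list(feature_ids)].to_numpy(dtype=float)
    return (X - means) / sds


# ---------------------------------------------------------------------------
# Binary PLR


def _binary_objective(theta, Z, y, lam):
    eta = Z @ theta
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    return nll + 0.5 * lam * float(theta[1:] @ theta[1:])


def fit_plr(
    m: FeatureMatrix,
    labels: GeneLabels | pd.Series,
    lam: float = 1.0,
    standardize: bool = True,
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> PLRModel:
    """Fit the binary ridge-logistic model on labeled genes.

    ``labels`` may be a :class:`GeneLabels` (its labeled genes are used)
    or a 0/1 Series indexed by gene id.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if isinstance(labels, GeneLabels):
        y_ser = labels.y()
    else:
        y_ser = pd.Series(labels).astype(int)
    genes = [g for g in y_ser.index if g in m.values.index]
    y = y_ser.loc[genes].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("training data must contain both classes")
    Xraw = m.values.loc[genes].to_numpy(dtype=float)
    means, sds = _standardize_fit(Xraw, standardize)
    X = (Xraw - means) / sds
    n, p = X.shape
    Z = np.hstack([np.ones((n, 1)), X])
    pen = np.concatenate([[0.0], np.full(p, lam)])

    theta = np.zeros(p + 1)
    history = [_binary_objective(theta, Z, y, lam)]
    converged = False
    for _ in range(max_iter):
        eta = Z @ theta
        mu = expit(eta)
        grad = Z.T @ (mu - y) + pen * theta
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (Z * w[:, None]).T @ Z + np.diag(pen)
        step = np.linalg.solve(H, grad)
        t = 1.0
        base = history[-1]
        while True:
            cand = theta - t * step
            obj = _binary_objective(cand, Z, y, lam)
            if obj <= base or t < 1e-10:
                break
            t *= 0.5
        theta = cand
        history.append(obj)
    else:
        # final gradient check after exhausting iterations
        mu = expit(Z @ theta)
        grad = Z.T @ (mu - y) + pen * theta
        converged = bool(np.max(np.abs(grad)) < tol)

    return PLRModel(
        beta0=float(theta[0]),
        beta=theta[1:].copy(),
        lam=lam,
        feature_ids=list(m.values.columns),
        means=means,
        sds=sds,
        converged=converged,
        objective_value=history[-1],
        objective_history=history,
    )


def predict_proba(model: PLRModel, m: FeatureMatrix) -> pd.Series:
    """Pr(cell cycle) for each gene in ``m`` under a fitted binary model."""
    return model.linear_predictor(m).map(expit)


def coef_zscores(model: PLRModel, m: FeatureMatrix, labels: GeneLabels | pd.Series):
    """Wald z-scores and two-sided p-values for the fitted coefficients.

    Standard errors come from the inverse of the penalized Hessian of
    the objective evaluated at the optimum.  Returns (z, p) Series
    indexed by feature id and caches them on the model.
    """
    if not model.converged:
        raise ValueError("z-scores require a converged model")
    if isinstance(labels, GeneLabels):
        y_ser = labels.y()
    else:
        y_ser = pd.Series(labels).astype(int)
    genes = [g for g in y_ser.index if g in m.values.index]
    X = _design(m.subset_genes(genes), model.feature_ids, model.means, model.sds)
    n, p = X.shape
    Z = np.hstack([np.ones((n, 1)), X])
    theta = np.concatenate([[model.beta0], model.beta])
    mu = expit(Z @ theta)
    w = mu * (1.0 - mu)
    pen = np.concatenate([[0.0], np.full(p, model.lam)])
    H = (Z * w[:, None]).T @ Z + np.diag(pen)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "penalized Hessian is singular; refit with lambda > 0"
        ) from None
    se = np.sqrt(np.clip(np.diag(cov)[1:], 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(model.beta == 0.0, 0.0, model.beta / se)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    model.zscores = z
    model.pvalues = pvals
    idx = pd.Index(model.feature_ids, name="feature")
    return pd.Series(z, index=idx), pd.Series(pvals, index=idx)


# ---------------------------------------------------------------------------
# Multinomial RMLR


def _mn_objective(a, B, X, Y, lam):
    eta = a[None, :] + X @ B.T
    nll = float(np.sum(logsumexp(eta, axis=1) - np.sum(Y * eta, axis=1)))
    return nll + 0.5 * lam * float(np.sum(B * B))


def fit_rmlr(
    m: FeatureMatrix,
    phases: pd.Series,
    lam: float = 1.0,
    classes: tuple = PHASES,
    standardize: bool = True,
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> RMLRModel:
    """Fit the multinomial ridge model over phase classes.

    ``phases`` maps gene id to class label; only classes actually present
    (in ``classes`` order) are modeled.  Intercepts are constrained to
    sum to zero, which pins down the softmax's flat direction without
    changing any probability.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    phases = phases[phases != "NA"]
    present = [c for c in classes if (phases == c).sum() > 0]
    extra = sorted(set(phases.unique()) - set(classes))
    if extra:
        raise ValueError(f"labels outside the class set: {extra}")
    if len(present) < 2:
        raise ValueError("need at least 2 phases with members")
    for c in present:
        if (phases == c).sum() < 2:
            raise ValueError(f"phase {c!r} has fewer than 2 genes")
    genes = [g for g in phases.index if g in m.values.index]
    Xraw = m.values.loc[genes].to_numpy(dtype=float)
    means, sds = _standardize_fit(Xraw, standardize)
    X = (Xraw - means) / sds
    n, p = X.shape
    K = len(present)
    Y = np.zeros((n, K))
    for k, c in enumerate(present):
        Y[(phases.loc[genes] == c).to_numpy(), k] = 1.0

    # free parameters: K-1 intercepts (last = -sum) then vec(B)
    Ta = np.vstack([np.eye(K - 1), -np.ones((1, K - 1))])  # (K, K-1)

    def unpack(free):
        a = Ta @ free[: K - 1]
        B = free[K - 1 :].reshape(K, p)
        return a, B

    free = np.zeros((K - 1) + K * p)
    a, B = unpack(free)
    history = [_mn_objective(a, B, X, Y, lam)]
    converged = False
    for _ in range(max_iter):
        eta = a[None, :] + X @ B.T
        P = softmax(eta, axis=1)
        R = P - Y  # (n, K)
        grad_a = R.sum(axis=0)  # (K,)
        grad_B = R.T @ X + lam * B  # (K, p)
        grad_free = np.concatenate([Ta.T @ grad_a, grad_B.ravel()])
        if np.max(np.abs(grad_free)) < tol:
            converged = True
            break
        # full Hessian over (a, vec(B)): sum_i M_i kron z_i z_i'
        Z = np.hstack([np.ones((n, 1)), X])  # (n, p+1)
        M = np.einsum("ik,kl->ikl", P, np.eye(K)) - np.einsum("ik,il->ikl", P, P)
        Hfull = np.einsum("ikl,ia,ib->kalb", M, Z, Z)  # (K, p+1, K, p+1)
        d = K * (p + 1)
        Hfull = Hfull.reshape(d, d)
        # reorder from per-class (intercept, coefs) blocks to (all a, vec(B))
        idx_a = [k * (p + 1) for k in range(K)]
        idx_B = [k * (p + 1) + 1 + j for k in range(K) for j in range(p)]
        perm = idx_a + idx_B
        Hfull = Hfull[np.ix_(perm, perm)]
        Hfull[K:, K:] += lam * np.eye(K * p)
        # project intercepts onto the sum-zero subspace
        T = np.zeros((d, (K - 1) + K * p))
        T[:K, : K - 1] = Ta
        T[K:, K - 1 :] = np.eye(K * p)
        Hfree = T.T @ Hfull @ T
        step = np.linalg.solve(Hfree, grad_free)
        t = 1.0
        base = history[-1]
        while True:
            cand = free - t * step
            ca, cB = unpack(cand)
            obj = _mn_objective(ca, cB, X, Y, lam)
            if obj <= base or t < 1e-10:
                break
            t *= 0.5
        free = cand
        a, B = unpack(free)
        history.append(obj)
    else:
        eta = a[None, :] + X @ B.T
        P = softmax(eta, axis=1)
        R = P - Y
        grad_free = np.concatenate([Ta.T @ R.sum(axis=0), (R.T @ X + lam * B).ravel()])
        converged = bool(np.max(np.abs(grad_free)) < tol)

    return RMLRModel(
        classes=present,
        intercepts=a.copy(),
        coefs=B.copy(),
        lam=lam,
        feature_ids=list(m.values.columns),
        means=means,
        sds=sds,
        converged=converged,
        objective_value=history[-1],
        objective_history=history,
    )


def predict_phase_proba(model: RMLRModel, m: FeatureMatrix) -> pd.DataFrame:
    """Softmax class-probability matrix (genes x classes, rows sum to 1)."""
    X = _design(m, model.feature_ids, model.means, model.sds)
    eta = model.intercepts[None, :] + X @ model.coefs.T
    return pd.DataFrame(softmax(eta, axis=1), index=m.values.index, columns=model.classes)


def predict_phase(
    model: RMLRModel, m: FeatureMatrix, threshold: float = 0.0
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each gene the most probable phase, or "unclear" below threshold.

    Ties break toward the earlier class in (G1, S, G2, M) order.
    Returns (calls, probability matrix).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    proba = predict_phase_proba(model, m)
    return assign_phases(proba, threshold), proba


def assign_phases(proba: pd.DataFrame, threshold: float = 0.0) -> pd.Series:
    """Argmax phase call with an "unclear" floor on the top probability."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    arr = proba.to_numpy()
    best = arr.argmax(axis=1)  # argmax takes the first maximum: earliest class wins ties
    calls = pd.Series(np.asarray(proba.columns)[best], index=proba.index, dtype=object)
    calls[arr.max(axis=1) < threshold] = "unclear"
    return calls


# ---------------------------------------------------------------------------
# Model serialization (flat TSV with a commented header block)


def write_plr_model(model: PLRModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# beta0\t{float(model.beta0)!r}\n")
        fh.write(f"# lambda\t{float(model.lam)!r}\n")
        fh.write(f"# converged\t{model.converged}\n")
        fh.write("feature\tcoefficient\tmean\tsd\tz_score\tp_value\n")
        z = model.zscores if model.zscores is not None else [math.nan] * len(model.beta)
        pv = model.pvalues if model.pvalues is not None else [math.nan] * len(model.beta)
        for f, b, mu, sd, zi, pi in zip(
            model.feature_ids, model.beta, model.means, model.sds, z, pv
        ):
            fh.write(
                f"{f}\t{float(b)!r}\t{float(mu)!r}\t{float(sd)!r}"
                f"\t{float(zi)!r}\t{float(pi)!r}\n"
            )


def read_plr_model(path) -> PLRModel:
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# "):
            key, value = line[2:].rstrip("\n").split("\t")
            header[key] = value
        else:
            body_start = i
            break
    df = pd.read_csv(path, sep="\t", skiprows=body_start)
    return PLRModel(
        beta0=float(header["beta0"]),
        beta=df["coefficient"].to_numpy(dtype=float),
        lam=float(header["lambda"]),
        feature_ids=list(df["feature"].astype(str)),
        means=df["mean"].to_numpy(dtype=float),
        sds=df["sd"].to_numpy(dtype=float),
        converged=header["converged"] == "True",
        objective_value=math.nan,
        zscores=df["z_score"].to_numpy(dtype=float),
        pvalues=df["p_value"].to_numpy(dtype=float),
    )


def write_rmlr_model(model: RMLRModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# classes\t{','.join(model.classes)}\n")
        fh.write("# intercepts\t" + ",".join(repr(float(v)) for v in model.intercepts) + "\n")
        fh.write(f"# lambda\t{float(model.lam)!r}\n")
        fh.write(f"# converged\t{model.converged}\n")
        cols = "\t".join(f"coef_{c}" for c in model.classes)
        fh.write(f"feature\tmean\tsd\t{cols}\n")
        for j, f in enumerate(model.feature_ids):
            coefs = "\t".join(repr(float(model.coefs[k, j])) for k in range(len(model.classes)))
            fh.write(f"{f}\t{float(model.means[j])!r}\t{float(model.sds[j])!r}\t{coefs}\n")


def read_rmlr_model(path) -> RMLRModel:
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# "):
            key, value = line[2:].rstrip("\n").split("\t")
            header[key] = value
        else:
            body_start = i
            break
    df = pd.read_csv(path, sep="\t", skiprows=body_start)
    classes = header["classes"].split(",")
    coefs = df[[f"coef_{c}" for c in classes]].to_numpy(dtype=float).T
    return RMLRModel(
        classes=classes,
        intercepts=np.array([float(v) for v in header["intercepts"].split(",")]),
        coefs=coefs,
        lam=float(header["lambda"]),
        feature_ids=list(df["feature"].astype(str)),
        means=df["mean"].to_numpy(dtype=float),
        sds=df["sd"].to_numpy(dtype=float),
        converged=header["converged"] == "True",
        objective_value=math.nan,
    )
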