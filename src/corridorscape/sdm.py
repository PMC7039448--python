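"""Species distribution models, evaluation, ensembling, variable importance.

Three model families are fitted on presence / pseudo-absence covariate
tables:

* **GLM** — binomial-logit regression with a small ridge stabiliser (keeps
  coefficients finite under complete separation), with Fisher-information
  standard errors;
* **GBM** — stagewise gradient boosting on the logistic deviance with
  depth-limited regression trees;
* **MaxEnt** — a Gibbs distribution over the background (pseudo-absence)
  sample with linear + quadratic features, fitted by maximising the
  L1-penalised presence log-likelihood; reported on the usual logistic
  output scale.

Models are evaluated with ROC AUC (Mann-Whitney form, ties half-counted)
and the true skill statistic (max over thresholds of sensitivity +
specificity - 1) on replicated stratified 75/25 splits, then combined by a
weighted average with weights proportional to mean test AUC. Variable
importance follows the randomisation convention: one minus the absolute
Pearson correlation between predictions on the intact table and on the
table with that single column permuted, averaged over permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression

from .covariates import covariate_columns
from .synthetic import PRESENCE

GLM = "glm"
GBM = "gbm"
MAXENT = "maxent"
MODEL_KINDS = (GLM, GBM, MAXENT)


def _split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = covariate_columns(table)
    X = table[cols].to_numpy(dtype=float)
    y = (table["label"].to_numpy() == PRESENCE).astype(int)
    return X, y, cols


def _require_both_labels(y: np.ndarray, kind: str) -> None:
    if y.min() == y.max():
        raise ValueError(f"{kind}: training labels are single-class")


@dataclass
class SDMFit:
    """One fitted distribution model; ``predict`` maps a covariate table
    (or array in ``columns`` order) to probabilities in [0, 1]."""

    kind: str
    columns: list[str]
    params: dict = field(default_factory=dict)
    replicate: int | None = None
    train_ids: np.ndarray | None = None

    def _matrix(self, table) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            return table[self.columns].to_numpy(dtype=float)
        X = np.asarray(table, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.columns):
            raise ValueError("covariate matrix width does not match fit")
        return X

    def predict(self, table) -> np.ndarray:
        X = self._matrix(table)
        if self.kind == GLM:
            eta = self.params["intercept"] + X @ self.params["coef"]
            return expit(eta)
        if self.kind == GBM:
            model = self.params["model"]
            return model.predict_proba(X)[:, 1]
        if self.kind == MAXENT:
            return _maxent_predict(self.params, X)
        raise ValueError(f"unknown model kind {self.kind!r}")


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

def fit_glm(table: pd.DataFrame, ridge: float = 1e-4,
            max_iter: int = 1000) -> SDMFit:
    """Binomial-logit fit with a small ridge stabiliser.

    ``ridge`` is the L2 penalty weight on the *mean* log-likelihood scale
    (intercept unpenalised); at the default it is negligible against any
    informative sample yet bounds coefficients under complete separation.
    Fisher-information standard errors are stored under ``params["se"]``
    (intercept first).
    """
    X, y, cols = _split_xy(table)
    _require_both_labels(y, GLM)
    if X.shape[1] == 0:
        # intercept-only model
        p = y.mean()
        return SDMFit(kind=GLM, columns=[],
                      params={"intercept": float(logit(p)),
                              "coef": np.zeros(0), "se": np.array([np.nan]),
                              "n_iter": 0, "converged": True})
    spread = X.max(axis=0) - X.min(axis=0)
    if np.any(spread == 0):
        bad = [c for c, s in zip(cols, spread) if s == 0]
        raise ValueError(f"zero-variance covariates (drop before fitting): {bad}")
    # sklearn minimises C * sum(loss) + 0.5 ||w||^2; per-sample ridge = 1/(C n)
    C = 1.0 / (ridge * len(y))
    clf = LogisticRegression(penalty="l2", C=C, solver="lbfgs",
                             max_iter=max_iter, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    n_iter = int(np.max(clf.n_iter_))
    converged = n_iter < max_iter
    if not converged:
        warnings.warn(f"glm did not converge in {n_iter} iterations")
    coef = clf.coef_.ravel()
    intercept = float(clf.intercept_[0])
    # Fisher information at the fit: (D' W D)^-1 with D = [1 | X]
    D = np.column_stack([np.ones(len(y)), X])
    p = expit(D @ np.concatenate([[intercept], coef]))
    W = p * (1 - p)
    info = D.T @ (D * W[:, None])
    try:
        cov = np.linalg.inv(info)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(D.shape[1], np.nan)
    return SDMFit(kind=GLM, columns=cols,
                  params={"intercept": intercept, "coef": coef, "se": se,
                          "n_iter": n_iter, "converged": converged})


# ---------------------------------------------------------------------------
# GBM
# ---------------------------------------------------------------------------

def fit_gbm(table: pd.DataFrame, n_stages: int = 500,
            learning_rate: float = 0.05, max_depth: int = 3,
            seed: int = 0) -> SDMFit:
    """Stagewise gradient boosting on logistic deviance with depth-limited
    trees; defaults are this package's declared settings. Per-stage training
    deviance is exposed as ``params["train_deviance"]`` (non-increasing with
    bag fraction 1)."""
    X, y, cols = _split_xy(table)
    _require_both_labels(y, GBM)
    model = GradientBoostingClassifier(
        n_estimators=n_stages, learning_rate=learning_rate,
        max_depth=max_depth, subsample=1.0, random_state=seed)
    model.fit(X, y)
    return SDMFit(kind=GBM, columns=cols,
                  params={"model": model,
                          "train_deviance": np.asarray(model.train_score_)})


# ---------------------------------------------------------------------------
# MaxEnt
# ---------------------------------------------------------------------------

def _maxent_features(X: np.ndarray, mean: np.ndarray, scale: np.ndarray,
                     quadratic: bool) -> np.ndarray:
    F = [(X - mean) / scale]
    if quadratic:
        F.append(((X - mean) / scale) ** 2)
    return np.hstack(F)


def _maxent_nll(w: np.ndarray, Fp: np.ndarray, Fb: np.ndarray):
    """Negative presence log-likelihood of the Gibbs model (up to constants)
    and its gradient: -(mean_p F.w - log mean_b exp(F.w))."""
    eta_b = Fb @ w
    m = eta_b.max()
    z = np.exp(eta_b - m)
    logZ = m + np.log(z.mean())
    nll = -(Fp @ w).mean() + logZ
    gibbs = z / z.sum()
    grad = -Fp.mean(axis=0) + gibbs @ Fb
    return nll, grad


def _fit_maxent_weights(Fp: np.ndarray, Fb: np.ndarray,
                        l1: float) -> np.ndarray:
    """L1-penalised fit via the split w = w+ - w-, both nonnegative, which
    keeps the objective smooth for L-BFGS-B."""
    d = Fp.shape[1]

    def obj(theta):
        w = theta[:d] - theta[d:]
        nll, grad = _maxent_nll(w, Fp, Fb)
        return (nll + l1 * theta.sum(),
                np.concatenate([grad + l1, -grad + l1]))

    res = minimize(obj, np.zeros(2 * d), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * d),
                   options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10})
    return res.x[:d] - res.x[d:]


def _maxent_predict(params: dict, X: np.ndarray) -> np.ndarray:
    F = _maxent_features(X, params["mean"], params["scale"],
                         params["quadratic"])
    eta = F @ params["w"]
    # logistic output: expit(H + log qhat(x)), where qhat is the Gibbs
    # density estimate over the background and H its entropy.
    return expit(params["entropy"] + eta - params["log_sumexp_b"])


def fit_maxent(table: pd.DataFrame, features: str = "lq",
               l1_penalty: float | None = None, seed: int = 0) -> SDMFit:
    """Maximum-entropy model: presences against the pseudo-absence rows as
    background. ``features`` is ``"l"`` (linear) or ``"lq"`` (linear +
    quadratic). When ``l1_penalty`` is None it is chosen by held-out
    log-likelihood on a 20% presence holdout."""
    X, y, cols = _split_xy(table)
    _require_both_labels(y, MAXENT)
    quadratic = features == "lq"
    Xp, Xb = X[y == 1], X[y == 0]
    mean = Xb.mean(axis=0)
    scale = Xb.std(axis=0)
    scale[scale == 0] = 1.0
    if np.all(X.std(axis=0) == 0):
        raise ValueError("maxent: all features are zero-variance")
    Fp = _maxent_features(Xp, mean, scale, quadratic)
    Fb = _maxent_features(Xb, mean, scale, quadratic)

    if l1_penalty is None:
        rng = np.random.default_rng(seed)
        n_hold = max(1, int(round(0.2 * len(Fp))))
        perm = rng.permutation(len(Fp))
        hold, train = perm[:n_hold], perm[n_hold:]
        if len(train) == 0:
            train, hold = perm, perm
        best, l1_penalty = -np.inf, 0.01
        for lam in (0.2, 0.1, 0.05, 0.02, 0.01, 0.005):
            w = _fit_maxent_weights(Fp[train], Fb, lam)
            ll, _ = _maxent_nll(w, Fp[hold], Fb)
            if -ll > best:
                best, l1_penalty = -ll, lam
    w = _fit_maxent_weights(Fp, Fb, l1_penalty)

    eta_b = Fb @ w
    m = eta_b.max()
    log_sumexp_b = m + np.log(np.exp(eta_b - m).sum())
    gibbs = np.exp(eta_b - log_sumexp_b)
    entropy = float(-(gibbs * np.log(np.clip(gibbs, 1e-300, None))).sum())
    return SDMFit(kind=MAXENT, columns=cols,
                  params={"w": w, "mean": mean, "scale": scale,
                          "quadratic": quadratic, "l1_penalty": l1_penalty,
                          "log_sumexp_b": float(log_sumexp_b),
                          "entropy": entropy})


FIT_OPS = {GLM: fit_glm, GBM: fit_gbm, MAXENT: fit_maxent}


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_auc(scores, labels) -> float:
    """ROC AUC in the Mann-Whitney form: the probability that a random
    presence outranks a random pseudo-absence, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == PRESENCE).astype(int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both labels present")
    ranks = rankdata(scores)  # average ranks => half-credit for ties
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def evaluate_tss(scores, labels) -> float:
    """True skill statistic: max over candidate thresholds (midpoints of
    sorted unique scores, plus +/-inf) of sensitivity + specificity - 1."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == PRESENCE).astype(int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("TSS needs both labels present")
    uniq = np.unique(scores)
    thresholds = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2,
                                 [np.inf]])
    pred = scores[None, :] > thresholds[:, None]   # predicted presence
    sens = (pred & (y == 1)).sum(axis=1) / n1
    spec = (~pred & (y == 0)).sum(axis=1) / n0
    return float((sens + spec - 1).max())


@dataclass
class EvalRecord:
    kind: str
    replicate: int
    auc: float
    tss: float
    test_ids: np.ndarray


def _stratified_split(y: np.ndarray, train_fraction: float,
                      rng: np.random.Generator,
                      max_redraw: int = 100) -> tuple[np.ndarray, np.ndarray]:
    for _ in range(max_redraw):
        train_idx, test_idx = [], []
        for cls in (0, 1):
            idx = np.nonzero(y == cls)[0]
            idx = rng.permutation(idx)
            k = int(round(train_fraction * idx.size))
            train_idx.append(idx[:k])
            test_idx.append(idx[k:])
        train = np.sort(np.concatenate(train_idx))
        test = np.sort(np.concatenate(test_idx))
        if (len(np.unique(y[train])) == 2 and len(np.unique(y[test])) == 2):
            return train, test
    raise ValueError("could not draw a split with both classes in both "
                     "partitions after 100 attempts")


def cross_validate(fit_ops: dict, table: pd.DataFrame,
                   train_fraction: float = 0.75, n_reps: int = 3,
                   seed: int = 0) -> list[EvalRecord]:
    """Replicated stratified splits; identical split memberships are used for
    every model kind so their metrics are directly comparable."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1) — an empty train "
                         "or test set is not allowed")
    _, y, _ = _split_xy(table)
    _require_both_labels(y, "cross_validate")
    rng = np.random.default_rng(seed)
    splits = [_stratified_split(y, train_fraction, rng) for _ in range(n_reps)]
    records: list[EvalRecord] = []
    for kind, fit_op in fit_ops.items():
        for rep, (train, test) in enumerate(splits):
            sub = table.iloc[train].reset_index(drop=True)
            # a covariate can be constant within one split even when it
            # varies overall; every kind sees the same reduced table
            const = [c for c in covariate_columns(sub)
                     if np.ptp(sub[c].to_numpy()) == 0.0]
            if const:
                sub = sub.drop(columns=const)
            fit = fit_op(sub)
            fit.replicate = rep
            fit.train_ids = train
            scores = fit.predict(table.iloc[test])
            records.append(EvalRecord(
                kind=kind, replicate=rep,
                auc=evaluate_auc(scores, y[test]),
                tss=evaluate_tss(scores, y[test]), test_ids=test))
    return records


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Accuracy-weighted collection of fitted models."""

    members: list[SDMFit]
    weights: np.ndarray
    metric: str = "auc"
    eval_records: list[EvalRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("ensemble weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("ensemble weights must sum to 1")

    def predict(self, table) -> np.ndarray:
        preds = np.stack([m.predict(table) for m in self.members])
        return self.weights @ preds


def ensemble_weights(members: list[SDMFit],
                     records: list[EvalRecord]) -> np.ndarray:
    """Weights proportional to each member's mean test AUC."""
    means = []
    for m in members:
        aucs = [r.auc for r in records if r.kind == m.kind]
        if not aucs:
            raise ValueError(f"member {m.kind!r} has no evaluation records")
        means.append(float(np.mean(aucs)))
    w = np.asarray(means, dtype=float)
    if w.sum() <= 0:
        raise ValueError("all ensemble weights are zero")
    return w / w.sum()


def ensemble_predict(members: list[SDMFit], records: list[EvalRecord],
                     table) -> np.ndarray:
    """Weighted-mean suitability; weight proportional to mean test AUC."""
    w = ensemble_weights(members, records)
    preds = np.stack([m.predict(table) for m in members])
    return w @ preds


def build_ensemble(table: pd.DataFrame, kinds=MODEL_KINDS,
                   train_fraction: float = 0.75, n_reps: int = 3,
                   seed: int = 0, gbm_params: dict | None = None,
                   maxent_params: dict | None = None) -> EnsembleModel:
    """Cross-validate every requested kind for weights, then refit each on
    the full table as the ensemble members."""
    gbm_params = gbm_params or {}
    maxent_params = maxent_params or {}
    fit_ops = {}
    for kind in kinds:
        if kind == GBM:
            fit_ops[GBM] = lambda t: fit_gbm(t, seed=seed, **gbm_params)
        elif kind == MAXENT:
            fit_ops[MAXENT] = lambda t: fit_maxent(t, seed=seed,
                                                   **maxent_params)
        elif kind == GLM:
            fit_ops[GLM] = fit_glm
        else:
            raise ValueError(f"unknown model kind {kind!r}")
    records = cross_validate(fit_ops, table, train_fraction=train_fraction,
                             n_reps=n_reps, seed=seed)
    members = [fit_ops[kind](table) for kind in kinds]
    weights = ensemble_weights(members, records)
    return EnsembleModel(members=members, weights=weights, metric="auc",
                         eval_records=records)


# ---------------------------------------------------------------------------
# Variable importance
# ---------------------------------------------------------------------------

def variable_importance(model, table: pd.DataFrame, n_permutations: int = 10,
                        seed: int = 0) -> pd.DataFrame:
    """Randomisation importance: 1 - |Pearson r| between predictions on the
    intact table and predictions with one column permuted, averaged over
    ``n_permutations`` permutations. ``model`` is anything with a
    ``predict(table)`` method (an :class:`SDMFit` or an ensemble)."""
    cols = covariate_columns(table)
    base = np.asarray(model.predict(table), dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    if base.std() == 0:
        warnings.warn("predictions have zero variance; importances are 0")
    for col in cols:
        vals = []
        for _ in range(n_permutations):
            shuffled = table.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            pred = np.asarray(model.predict(shuffled), dtype=float)
            if base.std() == 0 or pred.std() == 0:
                vals.append(0.0)
                continue
            r = np.corrcoef(base, pred)[0, 1]
            vals.append(1.0 - abs(float(r)))
        rows.append((col, float(np.mean(vals)), n_permutations, seed))
    return pd.DataFrame(rows, columns=["variable", "importance",
                                       "n_permutations", "seed"])
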