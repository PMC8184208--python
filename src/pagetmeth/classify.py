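"""Discriminant analysis on the pooled significant sites.

OPLS-DA (orthogonal projections to latent structures discriminant
analysis): after unit-variance scaling and mean centering, the label-
orthogonal variation is iteratively removed from X (orthogonal signal
correction), and a single predictive PLS component is fitted to the
corrected matrix. Performance is read off the cross-validation scores via
a Mann-Whitney AUC and sensitivity/specificity at a median-score
threshold. An elastic-net penalized logistic regression selects the best
discriminatory subset of sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .errors import ConfigError, DataError, NumericalError

__all__ = [
    "OPLSDAModel",
    "fit_oplsda",
    "predict_scores",
    "ClassifierEval",
    "evaluate_roc",
    "BestSubset",
    "elastic_net_select",
    "compare_effect_sizes",
]

logger = logging.getLogger(__name__)


@dataclass
class OPLSDAModel:
    feature_ids: list
    mean: np.ndarray
    scale: np.ndarray
    w: np.ndarray          # predictive weights, unit norm
    p_load: np.ndarray     # predictive loading
    c: float               # response loading
    W_o: np.ndarray        # orthogonal weights, columns
    P_o: np.ndarray        # orthogonal loadings, columns
    t_train: np.ndarray    # predictive scores of the training samples
    t_ortho_train: np.ndarray
    n_ortho: int

    def to_dict(self) -> dict:
        return {
            "feature_ids": list(self.feature_ids),
            "mean": self.mean.tolist(), "scale": self.scale.tolist(),
            "w": self.w.tolist(), "p_load": self.p_load.tolist(),
            "c": self.c, "W_o": self.W_o.tolist(), "P_o": self.P_o.tolist(),
            "n_ortho": self.n_ortho,
        }


def _prepare(X: pd.DataFrame, drop_constant: bool = True):
    mean = X.mean(axis=0).to_numpy()
    sd = X.std(axis=0, ddof=1).to_numpy()
    keep = sd > 0
    if drop_constant and not keep.all():
        dropped = X.columns[~keep].tolist()
        logger.warning("dropping %d constant features: %s...",
                       len(dropped), dropped[:3])
        X = X.loc[:, keep]
        mean, sd = mean[keep], sd[keep]
    elif not keep.all():
        raise DataError("constant feature in matrix")
    return X, mean, sd


def fit_oplsda(X: pd.DataFrame, y, n_ortho: int = 1) -> OPLSDAModel:
    """Fit an OPLS-DA model (samples x features, labels coded +/-1).

    ``n_ortho`` label-orthogonal components are removed from the scaled X
    (each orthogonal weight vector is orthogonal to the predictive
    direction), after which one predictive PLS component is fitted.
    ``n_ortho=0`` reduces to single-component PLS1.
    """
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if len(classes) != 2:
        raise DataError("need exactly two classes")
    for cls in classes:
        if (y == cls).sum() < 2:
            raise DataError("need at least 2 samples per class")
    yy = np.where(y == classes.max(), 1.0, -1.0)
    yc = yy - yy.mean()

    X, mean, sd = _prepare(X)
    feature_ids = list(X.columns)
    Xs = (X.to_numpy(dtype=float) - mean) / sd
    if n_ortho < 0:
        raise ConfigError("n_ortho must be nonnegative")
    if n_ortho >= min(Xs.shape):
        raise NumericalError(f"n_ortho={n_ortho} >= rank bound {min(Xs.shape)}")

    W_o, P_o, T_o = [], [], []
    Xd = Xs.copy()
    for _ in range(n_ortho):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise NumericalError("labels orthogonal to every feature")
        w = w / nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            logger.warning("no label-orthogonal variation left; stopping early")
            break
        w_o = w_o / n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    w = Xd.T @ yc
    w = w / np.linalg.norm(w)
    t = Xd @ w
    p_load = Xd.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))

    k = len(W_o)
    return OPLSDAModel(
        feature_ids=feature_ids, mean=mean, scale=sd, w=w, p_load=p_load,
        c=c,
        W_o=np.column_stack(W_o) if k else np.zeros((Xs.shape[1], 0)),
        P_o=np.column_stack(P_o) if k else np.zeros((Xs.shape[1], 0)),
        t_train=t,
        t_ortho_train=np.column_stack(T_o) if k else np.zeros((len(yc), 0)),
        n_ortho=k,
    )


def predict_scores(model: OPLSDAModel, X_new: pd.DataFrame) -> np.ndarray:
    """Predictive scores of new samples under a fitted OPLS-DA model.

    Applies the training centering/scaling, removes the stored orthogonal
    components, and projects onto the predictive weight vector. The
    feature set must match the training features.
    """
    missing = [f for f in model.feature_ids if f not in X_new.columns]
    if missing:
        raise DataError(f"{len(missing)} training features missing from new data")
    Xs = (X_new[model.feature_ids].to_numpy(dtype=float) - model.mean) / model.scale
    for j in range(model.n_ortho):
        t_o = Xs @ model.W_o[:, j]
        Xs = Xs - np.outer(t_o, model.P_o[:, j])
    return Xs @ model.w


@dataclass
class ClassifierEval:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    roc_points: list  # (fpr, tpr) pairs, monotone in both coordinates


def evaluate_roc(scores, labels, threshold: str | float = "median") -> ClassifierEval:
    """ROC evaluation with the Mann-Whitney AUC and a median-score cut.

    AUC counts concordant case/control score pairs, ties as 1/2. The
    classification threshold defaults to the median of all supplied
    scores; sensitivity is the fraction of cases at or above it,
    specificity the fraction of controls below it.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise DataError("both classes must be present")
    pos = labels == classes.max()
    n1, n0 = int(pos.sum()), int((~pos).sum())

    ranks = stats.rankdata(scores)
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    thr = float(np.median(scores)) if threshold == "median" else float(threshold)
    sens = float((scores[pos] >= thr).mean())
    spec = float((scores[~pos] < thr).mean())

    # ROC polyline over all score cut points
    order = np.argsort(-scores, kind="mergesort")
    tp = np.cumsum(pos[order])
    fp = np.cumsum(~pos[order])
    pts = [(0.0, 0.0)]
    uniq = np.flatnonzero(np.diff(scores[order])).tolist() + [len(scores) - 1]
    for i in uniq:
        pts.append((fp[i] / n0, tp[i] / n1))
    return ClassifierEval(float(auc), sens, spec, thr, pts)


@dataclass
class BestSubset:
    probe_ids: list
    coefs: pd.Series
    mixing: float
    lam: float


def elastic_net_select(X: pd.DataFrame, y, mixing: float = 0.5,
                       lam: float | None = None, n_folds: int = 10,
                       n_lambdas: int = 40, seed: int = 0) -> BestSubset:
    """Elastic-net penalized logistic regression for subset selection.

    Features are standardized internally. When ``lam`` is not given it is
    chosen on a log-spaced grid by k-fold cross-validated binomial
    deviance using the one-standard-error rule (the most regularized model
    within one SE of the best). The selected subset is the set of features
    with nonzero coefficients at the chosen penalty.
    """
    if lam is not None and lam < 0:
        raise ConfigError("lambda must be nonnegative")
    if not 0.0 <= mixing <= 1.0:
        raise ConfigError("mixing must be in [0, 1]")
    y = np.asarray(y, dtype=float).ravel()
    yy = (y == np.unique(y).max()).astype(float)
    X, mean, sd = _prepare(X)
    Xs = (X.to_numpy(dtype=float) - mean) / sd
    n = Xs.shape[0]

    def fit_at(lam_value):
        if lam_value <= 0:
            model = LogisticRegression(penalty=None, max_iter=2000)
        else:
            C = 1.0 / (n * lam_value)
            if mixing == 0.0:
                model = LogisticRegression(penalty="l2", C=C, solver="lbfgs",
                                           max_iter=5000)
            else:
                model = LogisticRegression(
                    penalty="elasticnet", l1_ratio=mixing, C=C,
                    solver="saga", max_iter=5000, tol=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xs, yy)
        return model

    if lam is None:
        # lambda_max: smallest penalty that zeroes every coefficient (glmnet form)
        r = yy - yy.mean()
        lam_max = np.abs(Xs.T @ r).max() / (n * max(mixing, 1e-3))
        grid = lam_max * np.logspace(0, -2, n_lambdas)
        rng = np.random.default_rng(seed)
        fold = rng.permutation(n) % n_folds
        dev = np.zeros((n_folds, n_lambdas))
        for f in range(n_folds):
            tr, te = fold != f, fold == f
            # re-standardize inside the fold: no leakage into lambda choice
            mu_f = Xs[tr].mean(axis=0)
            sd_f = Xs[tr].std(axis=0, ddof=1)
            sd_f[sd_f == 0] = 1.0
            Xtr = (Xs[tr] - mu_f) / sd_f
            Xte = (Xs[te] - mu_f) / sd_f
            for j, lv in enumerate(grid):
                C = 1.0 / (tr.sum() * lv)
                if mixing == 0.0:
                    m = LogisticRegression(penalty="l2", C=C, solver="lbfgs",
                                           max_iter=5000)
                else:
                    m = LogisticRegression(penalty="elasticnet",
                                           l1_ratio=mixing, C=C,
                                           solver="saga", max_iter=2000,
                                           tol=1e-3)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m.fit(Xtr, yy[tr])
                prob = np.clip(m.predict_proba(Xte)[:, 1], 1e-12, 1 - 1e-12)
                dev[f, j] = -2.0 * np.mean(yy[te] * np.log(prob)
                                           + (1 - yy[te]) * np.log(1 - prob))
        mean_dev = dev.mean(axis=0)
        se_dev = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
        best = int(np.argmin(mean_dev))
        limit = mean_dev[best] + se_dev[best]
        chosen = next(j for j in range(n_lambdas) if mean_dev[j] <= limit)
        lam = float(grid[chosen])

    model = fit_at(lam)
    coef = model.coef_.ravel()
    nz = np.abs(coef) > 1e-10
    sel = pd.Series(coef[nz], index=np.asarray(X.columns)[nz])
    return BestSubset(list(sel.index), sel, mixing, float(lam))


def compare_effect_sizes(delta_betas: pd.Series, subset_ids,
                         test: str = "wilcoxon") -> float:
    """Two-sided comparison of |delta_beta| between a subset and its complement.

    Defaults to the Wilcoxon rank-sum test (robust to the skew of absolute
    methylation differences); ``test="welch"`` switches to Welch's t.
    """
    subset_ids = set(subset_ids)
    in_sub = delta_betas.index.isin(subset_ids)
    a = np.abs(delta_betas[in_sub].to_numpy())
    b = np.abs(delta_betas[~in_sub].to_numpy())
    if len(a) == 0 or len(b) == 0:
        raise DataError("both the subset and its complement must be nonempty")
    if test == "wilcoxon":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if test == "welch":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    raise ConfigError(f"unknown test {test!r}")
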