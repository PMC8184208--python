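"""Site-level differential methylation.

Per-probe ordinary least squares of M-values on phenotype plus confounders,
empirical-Bayes variance moderation (hierarchical shrinkage of residual
variances toward a common prior, with moderated t-statistics), BH false
discovery rate and Bonferroni control, a discovery -> cross-validation
replication filter, and inverse-variance fixed-effect meta-analysis of the
two stages.

Effect-size reporting follows the blood-methylation convention used for
case/control tables: ``delta_beta`` is the raw control-minus-case group
mean difference on the beta scale, so a negative value means
hypermethylation in cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError, NumericalError

__all__ = [
    "fit_site_models",
    "ModeratedStats",
    "empirical_bayes_moderation",
    "bh_fdr",
    "bonferroni_threshold",
    "bonferroni_adjust",
    "ReplicationResult",
    "discovery_replication",
    "MetaResult",
    "meta_fixed_effect",
    "se_from_p",
]


def _check_full_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, mode="economic", pivoting=True)
        collinear = [names[j] for j in sorted(piv[rank:])]
        raise NumericalError(f"design matrix rank-deficient; collinear columns: "
                             f"{collinear}")


def fit_site_models(M: pd.DataFrame, phenotype: pd.Series,
                    confounders: pd.DataFrame | None = None,
                    beta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fit ``M ~ phenotype + confounders`` per probe by OLS.

    Parameters
    ----------
    M : probes x samples M-value matrix.
    phenotype : 0/1 series over samples (1 = case).
    confounders : samples x covariates frame (age, sex, batches, cell
        fractions, surrogate components, ...); categorical columns are
        dummy-encoded with a dropped reference level.
    beta : optional probes x samples beta matrix used only to report the
        raw control-minus-case mean difference (``delta_beta``).

    Returns a frame indexed by probe with columns ``coef_M``, ``se_M``,
    ``sigma2``, ``df_resid``, ``t``, ``p`` and (if ``beta`` is given)
    ``delta_beta``.
    """
    samples = M.columns
    y01 = phenotype.reindex(samples).to_numpy(dtype=float)
    if np.isnan(y01).any():
        raise DataError("phenotype missing for some samples")
    parts = [np.ones(len(samples)), y01]
    names = ["intercept", "phenotype"]
    if confounders is not None and confounders.shape[1]:
        conf = pd.get_dummies(confounders.reindex(samples), drop_first=True)
        parts.extend(conf.to_numpy(dtype=float).T)
        names.extend(conf.columns.astype(str))
    X = np.column_stack(parts)
    n, p = X.shape
    if n <= p:
        raise NumericalError(f"{n} samples cannot identify {p} coefficients")
    _check_full_rank(X, names)

    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T                      # p x n
    Y = M.to_numpy(dtype=float)            # probes x n
    coefs = Y @ H.T                        # probes x p
    resid = Y - coefs @ X.T
    df_resid = n - p
    sigma2 = (resid ** 2).sum(axis=1) / df_resid
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coefs[:, 1] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df_resid)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame({
        "coef_M": coefs[:, 1], "se_M": se, "sigma2": sigma2,
        "df_resid": df_resid, "t": t, "p": pvals,
    }, index=M.index)
    if beta is not None:
        case = y01 == 1
        b = beta.reindex(index=M.index, columns=samples).to_numpy(dtype=float)
        out["delta_beta"] = b[:, ~case].mean(axis=1) - b[:, case].mean(axis=1)
    return out


@dataclass
class ModeratedStats:
    """Posterior variances and moderated test statistics."""

    s0_sq: float
    d0: float
    s_tilde_sq: np.ndarray
    t_mod: np.ndarray
    p_mod: np.ndarray
    df_total: float


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = polygamma(1, y)
        step = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def empirical_bayes_moderation(results: pd.DataFrame) -> ModeratedStats:
    """Shrink per-probe residual variances toward an estimated prior.

    Method-of-moments on log sample variances: with d residual df, the
    log-variances follow a scaled log-chi-square whose mean and spread
    identify the prior variance ``s0^2`` and prior df ``d0``. Posterior
    variances ``s~^2 = (d0 s0^2 + d s^2)/(d0 + d)`` feed moderated
    t-statistics on ``d0 + d`` df. When the observed spread of
    log-variances is no larger than sampling noise, ``d0`` is infinite and
    all posterior variances collapse to ``s0^2``.
    """
    s2 = results["sigma2"].to_numpy(dtype=float)
    if len(s2) < 10:
        raise DataError("need at least 10 probes to estimate the variance prior")
    dfs = results["df_resid"].to_numpy(dtype=float)
    if not np.all(dfs == dfs[0]):
        raise DataError("moderation requires equal residual df across probes")
    d = float(dfs[0])
    if np.all(s2 <= 0):
        raise NumericalError("all residual variances are zero")
    s2 = np.maximum(s2, 1e-300)

    z = np.log(s2)
    e = z - polygamma(0, d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(polygamma(1, d / 2.0))
    if excess > 1e-12:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
        s_tilde_sq = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    else:
        # observed spread of log-variances no larger than sampling noise:
        # infinite prior df, prior variance = pooled mean sample variance
        d0 = np.inf
        s0_sq = float(s2.mean())
        s_tilde_sq = np.full_like(s2, s0_sq)
        df_total = np.inf

    scale = np.sqrt(s_tilde_sq / s2)
    t_mod = results["t"].to_numpy(dtype=float) / scale
    if np.isinf(df_total):
        p_mod = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_mod = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_mod = np.clip(p_mod, np.finfo(float).tiny, 1.0)
    return ModeratedStats(s0_sq=s0_sq, d0=float(d0), s_tilde_sq=s_tilde_sq,
                          t_mod=t_mod, p_mod=p_mod, df_total=float(df_total))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values outside [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ConfigError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def bonferroni_adjust(p, m: int):
    """Adjusted p = min(1, m * p)."""
    if m < 1:
        raise ConfigError(f"number of tests must be >= 1, got {m}")
    p = np.asarray(p, dtype=float)
    out = np.minimum(1.0, m * p)
    return float(out) if out.ndim == 0 else out


@dataclass
class ReplicationResult:
    """Two-stage discovery -> cross-validation selection."""

    disc_q: pd.Series
    stage1_probes: list
    cv_q: pd.Series               # BH over the stage-1 subset (or genome-wide)
    replicated_probes: list
    concordant: pd.Series         # sign agreement, indexed by replicated probes


def discovery_replication(disc: pd.DataFrame, cv: pd.DataFrame,
                          q_threshold: float = 0.05,
                          cv_fdr_scope: str = "subset") -> ReplicationResult:
    """Select discovery-significant probes, then confirm them in the held-out split.

    Stage 1 keeps probes with discovery BH q below ``q_threshold``; stage 2
    recomputes BH over the cross-validation p-values of that subset only
    (``cv_fdr_scope="genome"`` switches to a genome-wide correction) and
    keeps those below the threshold again. Effect-direction concordance
    between the stages is reported per replicated probe.
    """
    shared = disc.index.intersection(cv.index)
    if len(shared) == 0:
        raise DataError("discovery and cross-validation probe universes are disjoint")
    if cv_fdr_scope not in ("subset", "genome"):
        raise ConfigError(f"unknown cv_fdr_scope {cv_fdr_scope!r}")

    disc_q = pd.Series(bh_fdr(disc.loc[shared, "p"]), index=shared)
    stage1 = disc_q.index[disc_q < q_threshold].tolist()
    if not stage1:
        return ReplicationResult(disc_q, [], pd.Series(dtype=float), [],
                                 pd.Series(dtype=bool))
    if cv_fdr_scope == "subset":
        cv_q = pd.Series(bh_fdr(cv.loc[stage1, "p"]), index=stage1)
    else:
        q_all = pd.Series(bh_fdr(cv.loc[shared, "p"]), index=shared)
        cv_q = q_all.loc[stage1]
    replicated = cv_q.index[cv_q < q_threshold].tolist()
    concordant = pd.Series(
        np.sign(disc.loc[replicated, "coef_M"]).to_numpy()
        == np.sign(cv.loc[replicated, "coef_M"]).to_numpy(),
        index=replicated, dtype=bool)
    return ReplicationResult(disc_q, stage1, cv_q, replicated, concordant)


@dataclass
class MetaResult:
    beta_meta: np.ndarray
    se_meta: np.ndarray
    z: np.ndarray
    p_meta: np.ndarray
    weighting: str


def meta_fixed_effect(beta1, se1, beta2, se2, method: str = "fixed") -> MetaResult:
    """Combine two stage estimates by inverse-variance weighting.

    Fixed effect: ``w_i = 1/se_i^2``, combined estimate
    ``sum(w b)/sum(w)``, standard error ``sum(w)^{-1/2}``, normal z test.
    ``method="random"`` adds a DerSimonian-Laird between-stage variance to
    each weight.
    """
    beta1, se1 = np.atleast_1d(np.asarray(beta1, float)), np.atleast_1d(np.asarray(se1, float))
    beta2, se2 = np.atleast_1d(np.asarray(beta2, float)), np.atleast_1d(np.asarray(se2, float))
    if (se1 <= 0).any() or (se2 <= 0).any():
        raise DataError("standard errors must be positive")
    if method not in ("fixed", "random"):
        raise ConfigError(f"unknown meta-analysis method {method!r}")

    tau2 = np.zeros_like(beta1)
    if method == "random":
        w1, w2 = 1.0 / se1 ** 2, 1.0 / se2 ** 2
        sw = w1 + w2
        b_fe = (w1 * beta1 + w2 * beta2) / sw
        Q = w1 * (beta1 - b_fe) ** 2 + w2 * (beta2 - b_fe) ** 2
        c = sw - (w1 ** 2 + w2 ** 2) / sw
        tau2 = np.maximum(0.0, (Q - 1.0) / c)

    w1 = 1.0 / (se1 ** 2 + tau2)
    w2 = 1.0 / (se2 ** 2 + tau2)
    sw = w1 + w2
    beta_meta = (w1 * beta1 + w2 * beta2) / sw
    se_meta = sw ** -0.5
    z = beta_meta / se_meta
    p_meta = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return MetaResult(beta_meta, se_meta, z, p_meta,
                      weighting="inverse_variance_" + method)


def se_from_p(beta, p):
    """Back out a standard error from a two-sided normal test.

    ``se = |beta| / Phi^{-1}(1 - p/2)``; used to reconstruct stage standard
    errors from published effect estimates and p-values.
    """
    beta = np.atleast_1d(np.asarray(beta, float))
    p = np.atleast_1d(np.asarray(p, float))
    if ((p <= 0) | (p >= 1)).any():
        raise DataError("p must be strictly inside (0, 1)")
    if (beta == 0).any():
        raise DataError("cannot recover a standard error for a zero effect")
    se = np.abs(beta) / stats.norm.isf(p / 2.0)
    return se
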