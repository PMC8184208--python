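"""Region-level differential methylation by deviance accumulation.

A region (CpG island, gene body, or promoter) is tested by comparing two
binomial (logistic) regressions of disease status:

    null: phenotype ~ confounders
    full: phenotype ~ confounders + site_1 + ... + site_n

The drop in deviance between the null and full fits is referred to a
chi-square distribution with n degrees of freedom, one per site entered.
Because every site contributes its own coefficient, hyper- and
hypo-methylated sites along the same region accumulate evidence instead of
cancelling, unlike mean-aggregate region statistics.

The logistic fits use iteratively reweighted least squares with a tiny
ridge penalty (1e-6, intercept unpenalized) for numerical stability in
wide regions; perfect separation is detected and flagged rather than
reported as p = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .dms import bh_fdr, bonferroni_adjust
from .errors import DataError

__all__ = [
    "Region",
    "RegionMap",
    "build_region_map",
    "fit_logistic",
    "RegionTestResult",
    "region_deviance_test",
    "region_workflow",
    "site_level_within_region",
    "PooledSites",
    "pool_sites",
]

logger = logging.getLogger(__name__)

REGION_TYPES = ("island", "gene_body", "promoter")
PROMOTER_FEATURES = ("TSS200", "TSS1500")
GENE_BODY_FEATURES = ("5'UTR", "Body")


@dataclass
class Region:
    region_id: str
    region_type: str
    probe_ids: list
    gene: str = ""


@dataclass
class RegionMap:
    islands: list = field(default_factory=list)
    gene_bodies: list = field(default_factory=list)
    promoters: list = field(default_factory=list)
    n_skipped: int = 0

    @property
    def by_type(self) -> dict:
        return {"island": self.islands, "gene_body": self.gene_bodies,
                "promoter": self.promoters}

    def all_regions(self) -> list:
        return self.islands + self.gene_bodies + self.promoters


def build_region_map(manifest: pd.DataFrame) -> RegionMap:
    """Group manifest probes into islands, promoters, and gene bodies.

    Islands come straight from the manifest's island ids. Probes annotated
    to a transcription start site (TSS200/TSS1500) form a promoter region
    per gene; probes in the 5'UTR or gene body form a gene-body region per
    gene. A probe with a gene-body or promoter feature but no gene symbol
    cannot be assigned and is skipped (counted in ``n_skipped``).
    """
    rmap = RegionMap()
    isl = manifest[manifest["island_id"].astype(str) != ""]
    for rid, sub in isl.groupby("island_id", sort=True):
        gene = next((g for g in sub["gene"].astype(str) if g), "")
        rmap.islands.append(Region(str(rid), "island", list(sub.index), gene))

    for feats, bucket, rtype, prefix in (
            (PROMOTER_FEATURES, rmap.promoters, "promoter", "promoter"),
            (GENE_BODY_FEATURES, rmap.gene_bodies, "gene_body", "body")):
        sel = manifest[manifest["feature"].isin(feats)]
        no_gene = (sel["gene"].astype(str) == "").sum()
        if no_gene:
            rmap.n_skipped += int(no_gene)
            logger.warning("%d %s-feature probes lack a gene symbol; skipped",
                           no_gene, rtype)
            sel = sel[sel["gene"].astype(str) != ""]
        for gene, sub in sel.groupby("gene", sort=True):
            bucket.append(Region(f"{prefix}:{gene}", rtype, list(sub.index),
                                 str(gene)))
    return rmap


def fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6,
                 max_iter: int = 200, tol: float = 1e-10):
    """IRLS logistic regression returning (coef, deviance, cov, converged).

    ``X`` must include the intercept column first; the ridge penalty is
    applied to every other coefficient. Divergence of any coefficient
    beyond |30| is treated as separation and reported as non-convergence.
    """
    n, p = X.shape
    beta = np.zeros(p)
    penalty = np.eye(p) * ridge
    penalty[0, 0] = 0.0
    converged = False
    dev = np.inf
    cov = np.full((p, p), np.nan)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        A = X.T @ (w[:, None] * X) + penalty
        try:
            beta_new = np.linalg.solve(A, X.T @ (w * z))
        except np.linalg.LinAlgError:
            return beta, dev, cov, False
        mu_new = expit(np.clip(X @ beta_new, -30.0, 30.0))
        mu_new = np.clip(mu_new, 1e-12, 1.0 - 1e-12)
        dev_new = -2.0 * float(np.sum(y * np.log(mu_new)
                                      + (1.0 - y) * np.log(1.0 - mu_new)))
        step = np.abs(beta_new - beta).max()
        beta = beta_new
        if np.abs(dev_new - dev) < tol * (np.abs(dev_new) + 0.1) and step < 1e-6:
            dev = dev_new
            converged = True
            break
        dev = dev_new
    if np.abs(beta).max() > 30.0:
        converged = False
    else:
        # perfect separation: the ridge caps the coefficients at a finite
        # value, but the fit classifies every sample exactly
        mu = expit(np.clip(X @ beta, -30.0, 30.0))
        if np.abs(y - mu).max() < 1e-3:
            converged = False
    if converged:
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        A = X.T @ (w[:, None] * X) + penalty
        try:
            cov = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            converged = False
    return beta, dev, cov, converged


@dataclass
class RegionTestResult:
    region_id: str
    n_sites: int
    null_deviance: float
    full_deviance: float
    chi2: float
    p: float
    site_coefs: pd.DataFrame  # index probe_id; columns coef, se, p
    converged: bool


def _design(confounders: pd.DataFrame | None, samples) -> np.ndarray:
    parts = [np.ones(len(samples))]
    if confounders is not None and confounders.shape[1]:
        conf = pd.get_dummies(confounders.reindex(samples), drop_first=True)
        parts.append(conf.to_numpy(dtype=float))
    return np.column_stack(parts)


def region_deviance_test(M_sites: pd.DataFrame, phenotype: pd.Series,
                         confounders: pd.DataFrame | None = None,
                         region_id: str = "", ridge: float = 1e-6) -> RegionTestResult:
    """Deviance-accumulation test of one region.

    ``M_sites`` is samples x n_sites (M values of the region's probes).
    Returns the null/full binomial deviances, their difference referred to
    chi-square with n_sites df, and the full model's per-site Wald
    coefficients. A zero-site region follows the degenerate convention
    chi2 = 0, df = 0, p = 1. Non-convergence (e.g. separation) yields a
    flagged result with ``p`` recorded as NaN.
    """
    samples = M_sites.index
    y = phenotype.reindex(samples).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise DataError("phenotype missing for some samples")
    n_sites = M_sites.shape[1]
    X0 = _design(confounders, samples)
    empty = pd.DataFrame(columns=["coef", "se", "p"])
    if n_sites == 0:
        b0, dev0, _, ok0 = fit_logistic(X0, y, ridge)
        return RegionTestResult(region_id, 0, dev0, dev0, 0.0, 1.0, empty, ok0)

    S = M_sites.to_numpy(dtype=float)
    X1 = np.column_stack([X0, S])
    b0, dev0, _, ok0 = fit_logistic(X0, y, ridge)
    b1, dev1, cov1, ok1 = fit_logistic(X1, y, ridge)
    converged = ok0 and ok1
    if not converged:
        return RegionTestResult(region_id, n_sites, dev0, dev1, np.nan, np.nan,
                                empty, False)
    chi2 = max(0.0, dev0 - dev1)
    p = float(stats.chi2.sf(chi2, df=n_sites))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    k0 = X0.shape[1]
    coefs = b1[k0:]
    ses = np.sqrt(np.maximum(np.diag(cov1)[k0:], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = coefs / ses
    site_p = np.clip(2.0 * stats.norm.sf(np.abs(zstat)),
                     np.finfo(float).tiny, 1.0)
    site_coefs = pd.DataFrame({"coef": coefs, "se": ses, "p": site_p},
                              index=M_sites.columns)
    return RegionTestResult(region_id, n_sites, dev0, dev1, chi2, p,
                            site_coefs, True)


def _test_regions(regions, M: pd.DataFrame, phenotype: pd.Series,
                  confounders: pd.DataFrame | None, ridge: float):
    results = {}
    skipped = 0
    for reg in regions:
        probes = [p for p in reg.probe_ids if p in M.index]
        if not probes:
            skipped += 1
            logger.warning("region %s absent from matrix; excluded", reg.region_id)
            continue
        results[reg.region_id] = region_deviance_test(
            M.loc[probes].T, phenotype, confounders, reg.region_id, ridge)
    return results, skipped


@dataclass
class RegionWorkflowResult:
    table: pd.DataFrame            # per-region summary for one region type
    disc_results: dict             # region_id -> RegionTestResult (discovery)
    cv_results: dict               # region_id -> RegionTestResult (CV subset)
    fdr_selected: list             # discovery FDR < alpha
    replicated: list               # CV FDR < alpha within the selected subset
    bonferroni_disc: list
    bonferroni_replicated: list


def region_workflow(M_disc: pd.DataFrame, phenotype_disc: pd.Series,
                    confounders_disc: pd.DataFrame | None,
                    M_cv: pd.DataFrame, phenotype_cv: pd.Series,
                    confounders_cv: pd.DataFrame | None,
                    regions: list, alpha: float = 0.05,
                    ridge: float = 1e-6) -> RegionWorkflowResult:
    """Discovery -> cross-validation workflow for one region type.

    Discovery regions are tested and BH-corrected over all converged
    regions of the type; those below ``alpha`` are re-tested in the
    cross-validation split, where BH runs over that subset only. The
    family-wise track mirrors this: Bonferroni over all discovery regions,
    then Bonferroni of the cross-validation p-values over the
    discovery-Bonferroni-significant subset.
    """
    disc_res, _ = _test_regions(regions, M_disc, phenotype_disc,
                                confounders_disc, ridge)
    ids = [r for r, res in disc_res.items() if res.converged]
    p_disc = pd.Series({r: disc_res[r].p for r in ids})
    q_disc = pd.Series(bh_fdr(p_disc.to_numpy()), index=p_disc.index) \
        if len(ids) else pd.Series(dtype=float)
    m_all = len(ids)
    bonf_disc = pd.Series(bonferroni_adjust(p_disc.to_numpy(), m_all),
                          index=p_disc.index) if m_all else pd.Series(dtype=float)

    fdr_selected = q_disc.index[q_disc < alpha].tolist()
    bonf_sig_disc = bonf_disc.index[bonf_disc < alpha].tolist()

    cv_ids = sorted(set(fdr_selected) | set(bonf_sig_disc))
    region_lookup = {r.region_id: r for r in regions}
    cv_res, _ = _test_regions([region_lookup[r] for r in cv_ids],
                              M_cv, phenotype_cv, confounders_cv, ridge)

    replicated: list = []
    q_cv = pd.Series(dtype=float)
    if fdr_selected:
        sub = [r for r in fdr_selected if r in cv_res and cv_res[r].converged]
        p_cv = pd.Series({r: cv_res[r].p for r in sub})
        if len(sub):
            q_cv = pd.Series(bh_fdr(p_cv.to_numpy()), index=p_cv.index)
            replicated = q_cv.index[q_cv < alpha].tolist()

    bonf_replicated: list = []
    bonf_cv = pd.Series(dtype=float)
    if bonf_sig_disc:
        sub = [r for r in bonf_sig_disc if r in cv_res and cv_res[r].converged]
        if sub:
            p_cv_b = pd.Series({r: cv_res[r].p for r in sub})
            bonf_cv = pd.Series(bonferroni_adjust(p_cv_b.to_numpy(), len(sub)),
                                index=p_cv_b.index)
            bonf_replicated = bonf_cv.index[bonf_cv < alpha].tolist()

    rows = []
    for r in ids:
        rows.append({
            "region_id": r,
            "region_type": region_lookup[r].region_type,
            "gene": region_lookup[r].gene,
            "n_sites": disc_res[r].n_sites,
            "p_disc": disc_res[r].p,
            "q_disc": q_disc.get(r, np.nan),
            "bonf_disc": bonf_disc.get(r, np.nan),
            "p_cv": cv_res[r].p if r in cv_res else np.nan,
            "q_cv": q_cv.get(r, np.nan),
            "bonf_cv": bonf_cv.get(r, np.nan),
            "replicated": r in replicated,
            "bonferroni_replicated": r in bonf_replicated,
        })
    table = pd.DataFrame(rows).set_index("region_id") if rows else pd.DataFrame()
    return RegionWorkflowResult(table, disc_res, cv_res, fdr_selected,
                                replicated, bonf_sig_disc, bonf_replicated)


def site_level_within_region(result: RegionTestResult,
                             q_threshold: float = 0.05) -> pd.Series:
    """BH within one region's own site p-values; returns the q-value series.

    Only the region's n site p-values enter the correction. A
    non-converged region yields an empty series.
    """
    if not result.converged or result.site_coefs.empty:
        return pd.Series(dtype=float)
    q = bh_fdr(result.site_coefs["p"].to_numpy())
    return pd.Series(q, index=result.site_coefs.index)


@dataclass
class PooledSites:
    """De-duplicated union of DMS and within-region significant sites."""

    probe_ids: list
    provenance: dict  # probe_id -> set of tags


def pool_sites(dms_probes, region_sites: dict) -> PooledSites:
    """Union site-level and region-derived significant probes with provenance.

    ``region_sites`` maps region_type -> iterable of probe ids. Provenance
    tags are ``dms``, ``dmr_island``, ``dmr_gene_body``, ``dmr_promoter``;
    a probe arriving through several routes keeps every tag but appears
    once.
    """
    provenance: dict[str, set] = {}
    for p in dms_probes:
        provenance.setdefault(p, set()).add("dms")
    for rtype, probes in region_sites.items():
        tag = f"dmr_{rtype}"
        for p in probes:
            provenance.setdefault(p, set()).add(tag)
    return PooledSites(sorted(provenance), provenance)
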