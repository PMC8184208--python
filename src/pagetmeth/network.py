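"""Partial-correlation structure of the pooled sites and keyword networks.

Gaussian-graphical-model partial correlations are estimated from a
shrinkage-regularized correlation matrix (Schafer-Strimmer: convex
combination of the sample correlation matrix with the identity at an
analytically chosen intensity), inverted to a precision matrix. Pairs of
functional keywords are then linked when site pairs crossing the two
keywords are enriched for significant partial correlations relative to
background pairs, by a two-sided Fisher exact test with BH correction
over all keyword pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dms import bh_fdr
from .errors import DataError

__all__ = [
    "PartialCorrelationResult",
    "estimate_partial_correlations",
    "KeywordEdge",
    "keyword_pair_enrichment",
    "build_keyword_network",
    "edges_to_graphml",
]

logger = logging.getLogger(__name__)


@dataclass
class PartialCorrelationResult:
    site_ids: list
    pcor: pd.DataFrame        # symmetric, unit diagonal
    shrinkage_intensity: float
    p: pd.DataFrame           # symmetric; NaN when the effective df vanishes
    q: pd.DataFrame           # BH over the upper triangle

    def significant_pairs(self, q_threshold: float = 0.05,
                          use_raw_p: bool = False) -> set:
        """Unordered site pairs whose partial correlation is significant."""
        mat = self.p if use_raw_p else self.q
        out = set()
        k = len(self.site_ids)
        for i in range(k):
            for j in range(i + 1, k):
                v = mat.iat[i, j]
                if np.isfinite(v) and v < q_threshold:
                    out.add(frozenset((self.site_ids[i], self.site_ids[j])))
        return out


def _shrinkage_intensity(Xs: np.ndarray) -> float:
    """Analytic shrinkage of the correlation matrix toward the identity.

    With standardized columns x, r_ij = n/(n-1) * mean_k(x_ki x_kj); the
    optimal intensity is sum Var(r_ij) / sum r_ij^2 over off-diagonal
    entries, clipped to [0, 1].
    """
    n, k = Xs.shape
    W = np.einsum("ni,nj->nij", Xs, Xs)  # n x k x k products
    w_mean = W.mean(axis=0)
    r = n / (n - 1.0) * w_mean
    var_r = n / (n - 1.0) ** 3 * ((W - w_mean) ** 2).sum(axis=0)
    mask = ~np.eye(k, dtype=bool)
    denom = (r[mask] ** 2).sum()
    if denom == 0:
        return 1.0
    return float(np.clip(var_r[mask].sum() / denom, 0.0, 1.0))


def estimate_partial_correlations(X: pd.DataFrame,
                                  shrinkage: float | None = None
                                  ) -> PartialCorrelationResult:
    """Shrinkage partial correlations among the columns of samples x sites X.

    The shrunk correlation matrix ``(1-lambda) R + lambda I`` is inverted
    to a precision matrix Omega, and
    ``pcor_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)``. Two-sided p-values
    use the Fisher z transform with effective sample size
    ``n - (k - 2) - 3`` (NaN, with a warning, when that is not positive).
    ``shrinkage`` overrides the analytic intensity (0 disables shrinkage).
    """
    n, k = X.shape
    if k < 3:
        raise DataError("need at least 3 sites for partial correlations")
    if n < 10:
        raise DataError("need at least 10 samples")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = X.columns[sd == 0].tolist()
        raise DataError(f"constant site column(s): {bad[:5]}")
    Xs = ((X - X.mean(axis=0)) / sd).to_numpy(dtype=float)

    lam = _shrinkage_intensity(Xs) if shrinkage is None else float(shrinkage)
    R = np.corrcoef(Xs, rowvar=False)
    R_shrunk = (1.0 - lam) * R + lam * np.eye(k)
    try:
        omega = np.linalg.inv(R_shrunk)
    except np.linalg.LinAlgError:
        omega = np.linalg.pinv(R_shrunk)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = np.clip(pcor, -1.0, 1.0)

    n_eff = n - (k - 2) - 3
    pmat = np.full((k, k), np.nan)
    if n_eff > 0:
        with np.errstate(divide="ignore"):
            z = np.arctanh(np.clip(pcor, -1 + 1e-12, 1 - 1e-12))
        pmat = np.clip(2.0 * stats.norm.sf(np.abs(z) * np.sqrt(n_eff)),
                       np.finfo(float).tiny, 1.0)
        np.fill_diagonal(pmat, np.nan)
    else:
        logger.warning("effective sample size n-(k-2)-3 = %d <= 0; "
                       "p-values unavailable", n_eff)

    iu = np.triu_indices(k, 1)
    qmat = np.full((k, k), np.nan)
    pvec = pmat[iu]
    if np.isfinite(pvec).all():
        qvec = bh_fdr(pvec)
        qmat[iu] = qvec
        qmat[(iu[1], iu[0])] = qvec

    ids = list(X.columns)
    return PartialCorrelationResult(
        ids,
        pd.DataFrame(pcor, index=ids, columns=ids),
        lam,
        pd.DataFrame(pmat, index=ids, columns=ids),
        pd.DataFrame(qmat, index=ids, columns=ids),
    )


@dataclass
class KeywordEdge:
    keyword_a: str
    keyword_b: str
    table: tuple              # ((cross_sig, cross_not), (bg_sig, bg_not))
    odds_ratio: float         # NaN when undefined
    fisher_p: float
    q: float = np.nan


def _sites_for_keyword(keyword: str, annotation: dict, probe_gene: pd.Series,
                       universe) -> set:
    genes = annotation.get(keyword)
    if not genes:
        raise DataError(f"keyword {keyword!r} has no annotated genes")
    sites = {p for p in universe if probe_gene.get(p, "") in genes}
    if not sites:
        raise DataError(f"keyword {keyword!r} maps to no pooled site")
    return sites


def keyword_pair_enrichment(significant_pairs: set, annotation: dict,
                            probe_gene: pd.Series, universe,
                            keyword_a: str, keyword_b: str) -> KeywordEdge:
    """Fisher enrichment of significant partial correlations across two keywords.

    Cross pairs have one site annotated to ``keyword_a`` and the other to
    ``keyword_b``; background pairs are all remaining pooled-site pairs
    except those internal to a single keyword (both sites in the same
    keyword's set). The 2x2 table crosses pair class against
    partial-correlation significance; p is the two-sided Fisher exact
    probability.
    """
    universe = list(universe)
    sites_a = _sites_for_keyword(keyword_a, annotation, probe_gene, universe)
    sites_b = _sites_for_keyword(keyword_b, annotation, probe_gene, universe)

    cross_sig = cross_not = bg_sig = bg_not = 0
    for x, y in itertools.combinations(universe, 2):
        pair = frozenset((x, y))
        in_a = (x in sites_a, y in sites_a)
        in_b = (x in sites_b, y in sites_b)
        if all(in_a) or all(in_b):
            continue  # internal to one keyword
        cross = (in_a[0] and in_b[1]) or (in_a[1] and in_b[0])
        sig = pair in significant_pairs
        if cross:
            cross_sig += sig
            cross_not += not sig
        else:
            bg_sig += sig
            bg_not += not sig

    table = ((cross_sig, cross_not), (bg_sig, bg_not))
    if cross_sig + bg_sig == 0:
        return KeywordEdge(keyword_a, keyword_b, table, np.nan, 1.0)
    res = stats.fisher_exact(table, alternative="two-sided")
    # infinite odds ratio (empty off-diagonal) is still a valid enrichment
    return KeywordEdge(keyword_a, keyword_b, table, float(res.statistic),
                       float(res.pvalue))


def build_keyword_network(X: pd.DataFrame, annotation: dict,
                          probe_gene: pd.Series, q_threshold: float = 0.05,
                          pcor_q_threshold: float = 0.05,
                          pcor_use_raw_p: bool = False,
                          shrinkage: float | None = None) -> list:
    """Enrichment-tested keyword pair edges from pooled-site methylation.

    Estimates partial correlations among X's sites, takes the significant
    pairs, tests every keyword pair for cross-keyword enrichment, applies
    BH over the keyword pairs, and returns the edges with q below
    ``q_threshold`` (sorted, with q filled in). Probes without a gene
    annotation never map to keywords and so drop out of the stage.
    """
    keywords = sorted(annotation)
    if len(keywords) < 2:
        return []
    pc = estimate_partial_correlations(X, shrinkage=shrinkage)
    sig = pc.significant_pairs(pcor_q_threshold, use_raw_p=pcor_use_raw_p)

    edges = []
    for a, b in itertools.combinations(keywords, 2):
        try:
            edges.append(keyword_pair_enrichment(sig, annotation, probe_gene,
                                                 list(X.columns), a, b))
        except DataError:
            continue  # keyword with no mapped site: no testable edge
    if not edges:
        return []
    q = bh_fdr([e.fisher_p for e in edges])
    kept = []
    for e, qv in zip(edges, q):
        e.q = float(qv)
        # an edge means functional relatedness: enrichment only, so a
        # significant *depletion* of cross-keyword correlations is not kept
        if qv < q_threshold and not np.isnan(e.odds_ratio) and e.odds_ratio > 1:
            kept.append(e)
    return sorted(kept, key=lambda e: e.q)


def edges_to_graphml(edges, path) -> None:
    """Write keyword edges as GraphML (node degree stored as an attribute)."""
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.keyword_a, e.keyword_b, odds_ratio=float(e.odds_ratio)
                   if np.isfinite(e.odds_ratio) else 0.0,
                   p=float(e.fisher_p), q=float(e.q))
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree[node]
    nx.write_graphml(g, path)
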