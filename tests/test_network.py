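"""Partial correlations and keyword-pair enrichment networks."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pagetmeth.errors import DataError
from pagetmeth.network import (build_keyword_network,
                               estimate_partial_correlations,
                               keyword_pair_enrichment)


def _with_exact_correlation(rng, n, target):
    """Data whose *sample* correlation matrix equals ``target`` exactly."""
    k = target.shape[0]
    X = rng.normal(size=(n, k))
    X -= X.mean(axis=0)
    # whiten the empirical covariance, then color with the target
    cov = X.T @ X / (n - 1)
    X = X @ np.linalg.inv(np.linalg.cholesky(cov)).T
    X = X @ np.linalg.cholesky(target).T
    return pd.DataFrame(X, columns=[f"v{i}" for i in range(k)])


class TestPartialCorrelations:
    def test_closed_form_equicorrelated(self, rng):
        """pcor(X,Y|Z) = (r-r^2)/(1-r^2) = 1/3 when all pairwise r = 0.5."""
        target = np.full((3, 3), 0.5)
        np.fill_diagonal(target, 1.0)
        X = _with_exact_correlation(rng, 50, target)
        res = estimate_partial_correlations(X, shrinkage=0.0)
        assert res.pcor.iloc[0, 1] == pytest.approx(1 / 3, abs=1e-10)

    def test_chain_conditional_independence(self, rng):
        """X -> Z -> Y: partialling out Z removes the marginal X-Y correlation."""
        n = 2000
        x = rng.normal(size=n)
        z = 0.8 * x + rng.normal(size=n) * 0.6
        y = 0.8 * z + rng.normal(size=n) * 0.6
        X = pd.DataFrame({"x": x, "z": z, "y": y})
        res = estimate_partial_correlations(X)
        assert abs(np.corrcoef(x, y)[0, 1]) > 0.3
        assert abs(res.pcor.loc["x", "y"]) < 0.05

    def test_null_calibration_without_shrinkage(self, rng):
        """Fisher-z p-values are calibrated on independent Gaussian sites."""
        X = pd.DataFrame(rng.normal(size=(200, 10)),
                         columns=[f"v{i}" for i in range(10)])
        res = estimate_partial_correlations(X, shrinkage=0.0)
        iu = np.triu_indices(10, 1)
        frac = (res.p.to_numpy()[iu] < 0.05).mean()
        m = len(iu[0])
        band = 3 * np.sqrt(0.05 * 0.95 / m)
        assert abs(frac - 0.05) < band + 0.03

    def test_symmetry_and_unit_diagonal(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 5)))
        X.columns = [f"v{i}" for i in range(5)]
        res = estimate_partial_correlations(X)
        P = res.pcor.to_numpy()
        assert np.allclose(P, P.T)
        assert np.allclose(np.diag(P), 1.0)
        assert 0.0 <= res.shrinkage_intensity <= 1.0

    def test_shrunk_matrix_positive_definite_when_wide(self, rng):
        """More sites than samples: shrinkage keeps the system invertible."""
        X = pd.DataFrame(rng.normal(size=(20, 40)),
                         columns=[f"v{i}" for i in range(40)])
        res = estimate_partial_correlations(X)
        lam = res.shrinkage_intensity
        R = np.corrcoef(X.to_numpy(), rowvar=False)
        shrunk = (1 - lam) * R + lam * np.eye(40)
        assert np.linalg.eigvalsh(shrunk).min() > 0

    def test_constant_column_named_in_error(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        X["b"] = 1.0
        with pytest.raises(DataError, match="b"):
            estimate_partial_correlations(X)


def _fisher_two_sided_enumeration(table):
    """Exhaustive two-sided Fisher p over all 2x2 tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (comb(r1, x) * comb(r2, c1 - x)) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestKeywordEnrichment:
    @staticmethod
    def _setup():
        universe = [f"s{i}" for i in range(8)]
        probe_gene = pd.Series({f"s{i}": f"G{i}" for i in range(8)})
        annotation = {"ka": {"G0", "G1"}, "kb": {"G2", "G3"},
                      "kc": {"G4", "G5", "G6", "G7"}}
        return universe, probe_gene, annotation

    def test_worked_fisher_example(self):
        """3/4 significant cross pairs vs 1/4 background -> two-sided p 0.4857."""
        universe, probe_gene, annotation = self._setup()
        # cross pairs of ka x kb: (s0,s2),(s0,s3),(s1,s2),(s1,s3)
        sig = {frozenset(p) for p in
               [("s0", "s2"), ("s0", "s3"), ("s1", "s2"), ("s4", "s5")]}
        # restrict universe so background has exactly 4 pairs
        uni = ["s0", "s1", "s2", "s3", "s4", "s5"]
        # within-kc pair (s4,s5) is internal; rebuild kc to avoid that
        annotation = {"ka": {"G0", "G1"}, "kb": {"G2", "G3"},
                      "kc": {"G4"}, "kd": {"G5"}}
        edge = keyword_pair_enrichment(sig, annotation, probe_gene, uni,
                                       "ka", "kb")
        assert edge.table[0] == (3, 1)
        assert edge.fisher_p == pytest.approx(
            _fisher_two_sided_enumeration(edge.table), abs=1e-9)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(30):
            t = tuple(tuple(int(v) for v in rng.integers(0, 8, 2))
                      for _ in range(2))
            if sum(map(sum, t)) == 0 or sum(map(sum, t)) > 30:
                continue
            p_scipy = stats.fisher_exact(t, alternative="two-sided").pvalue
            assert p_scipy == pytest.approx(_fisher_two_sided_enumeration(t),
                                            abs=1e-9)

    def test_no_significant_pairs(self):
        universe, probe_gene, annotation = self._setup()
        edge = keyword_pair_enrichment(set(), annotation, probe_gene,
                                       universe, "ka", "kb")
        assert edge.fisher_p == 1.0
        assert np.isnan(edge.odds_ratio)

    def test_extreme_enrichment_significant(self):
        universe = [f"s{i}" for i in range(12)]
        probe_gene = pd.Series({f"s{i}": f"G{i}" for i in range(12)})
        annotation = {"ka": {f"G{i}" for i in range(3)},
                      "kb": {f"G{i}" for i in range(3, 6)}}
        cross = {frozenset((a, b)) for a in ["s0", "s1", "s2"]
                 for b in ["s3", "s4", "s5"]}
        edge = keyword_pair_enrichment(cross, annotation, probe_gene,
                                       universe, "ka", "kb")
        assert edge.fisher_p < 0.05

    def test_unmapped_keyword_rejected(self):
        universe, probe_gene, annotation = self._setup()
        annotation["kz"] = {"NOT_A_GENE"}
        with pytest.raises(DataError):
            keyword_pair_enrichment(set(), annotation, probe_gene, universe,
                                    "ka", "kz")


class TestKeywordNetwork:
    @staticmethod
    def _module_data(rng, n=150):
        """Two keywords sharing one strongly correlated site module."""
        shared = rng.normal(size=n)
        cols, gene_map, annot = {}, {}, {"ka": set(), "kb": set(), "kc": set()}
        for i in range(4):  # correlated module: 2 genes in ka, 2 in kb
            cols[f"s{i}"] = shared + rng.normal(size=n) * 0.3
            gene_map[f"s{i}"] = f"G{i}"
            annot["ka" if i < 2 else "kb"].add(f"G{i}")
        for i in range(4, 10):  # independent filler across kc
            cols[f"s{i}"] = rng.normal(size=n)
            gene_map[f"s{i}"] = f"G{i}"
            annot["kc"].add(f"G{i}")
        return pd.DataFrame(cols), pd.Series(gene_map), annot

    def test_planted_module_edge_found(self):
        found = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, probe_gene, annot = self._module_data(rng)
            edges = build_keyword_network(X, annot, probe_gene, shrinkage=0.0)
            pairs = {frozenset((e.keyword_a, e.keyword_b)) for e in edges}
            found += frozenset(("ka", "kb")) in pairs
            assert frozenset(("ka", "kc")) not in pairs
        assert found >= 8

    def test_single_keyword_empty(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)),
                         columns=[f"s{i}" for i in range(4)])
        pg = pd.Series({f"s{i}": f"G{i}" for i in range(4)})
        assert build_keyword_network(X, {"only": {"G0", "G1"}}, pg) == []

    def test_shuffled_annotation_rarely_makes_edges(self):
        """Random keyword assignment yields edges at about the FDR rate."""
        total_edges, total_pairs = 0, 0
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame(rng.normal(size=(80, 12)),
                             columns=[f"s{i}" for i in range(12)])
            pg = pd.Series({f"s{i}": f"G{i}" for i in range(12)})
            genes = list(pg.sample(frac=1, random_state=seed))
            annot = {f"k{j}": set(genes[4 * j: 4 * (j + 1)]) for j in range(3)}
            edges = build_keyword_network(X, annot, pg, shrinkage=0.0)
            total_edges += len(edges)
            total_pairs += 3
        assert total_edges / total_pairs <= 0.05 + 3 * np.sqrt(
            0.05 * 0.95 / total_pairs)

    def test_edge_symmetric_in_keyword_order(self):
        rng = np.random.default_rng(3)
        X, probe_gene, annot = self._module_data(rng)
        sig = estimate_partial_correlations(X, shrinkage=0.0) \
            .significant_pairs(0.05)
        uni = list(X.columns)
        e1 = keyword_pair_enrichment(sig, annot, probe_gene, uni, "ka", "kb")
        e2 = keyword_pair_enrichment(sig, annot, probe_gene, uni, "kb", "ka")
        assert e1.fisher_p == pytest.approx(e2.fisher_p)
        assert e1.table == e2.table
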