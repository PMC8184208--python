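"""QC, M-values, normalization, deconvolution, surrogate variables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pagetmeth.errors import ConfigError, DataError
from pagetmeth.preprocess import (FilterLedger, compute_m_values,
                                  estimate_cell_composition, filter_probes,
                                  filter_samples, predict_sex,
                                  quantile_normalize, surrogate_variables)


class TestMValues:
    @pytest.mark.parametrize("meth,unmeth,expected", [
        (255, 63, 2.0),        # log2(256/64)
        (100, 100, 0.0),       # symmetry
        (0, 0, 0.0),           # offsets force log2(1)
    ])
    def test_worked_examples(self, meth, unmeth, expected):
        assert compute_m_values(meth, unmeth) == pytest.approx(expected)

    def test_negative_intensity_rejected(self):
        with pytest.raises(DataError):
            compute_m_values(-1.0, 5.0)

    @given(st.floats(0, 1e6), st.floats(0, 1e6), st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, meth, unmeth, step):
        m0 = compute_m_values(meth, unmeth)
        assert compute_m_values(meth + step, unmeth) > m0
        assert compute_m_values(meth, unmeth + step) < m0

    def test_dataframe_roundtrip_shape(self):
        df = pd.DataFrame([[1.0, 3.0], [7.0, 15.0]], index=["a", "b"],
                          columns=["s1", "s2"])
        out = compute_m_values(df, df * 0 + 1.0)
        assert list(out.index) == ["a", "b"]
        assert out.loc["b", "s2"] == pytest.approx(3.0)


def _intensity_frame(medians_log2, n_probes=101):
    cols = [f"S{i}" for i in range(len(medians_log2))]
    data = {c: np.full(n_probes, 2.0 ** m) for c, m in zip(cols, medians_log2)}
    return pd.DataFrame(data, index=[f"cg{i}" for i in range(n_probes)])


class TestSampleFilter:
    def test_all_pass(self):
        meth = _intensity_frame([12, 12.5, 13])
        sheet = pd.DataFrame({"sex": ["M", "F", "M"]}, index=meth.columns)
        retained, ledger = filter_samples(meth, meth, sheet)
        assert retained == list(meth.columns)
        assert ledger.excluded_samples_by_category == {}

    def test_threshold_boundary(self):
        meth = _intensity_frame([10.9, 12.0])
        sheet = pd.DataFrame({"sex": ["M", "F"]}, index=meth.columns)
        retained, ledger = filter_samples(meth, meth, sheet)
        assert retained == ["S1"]
        assert ledger.excluded_samples_by_category == {"intensity": 1}

    def test_bulk_low_intensity_cohort(self):
        """A cohort with 35 weak samples loses exactly those 35, none to sex."""
        meds = [10.0] * 35 + [12.5] * 65
        meth = _intensity_frame(meds)
        sheet = pd.DataFrame({"sex": ["F"] * 100}, index=meth.columns)
        predicted = pd.Series(["F"] * 100, index=meth.columns)
        retained, ledger = filter_samples(meth, meth, sheet, predicted)
        assert ledger.excluded_samples_by_category == {"intensity": 35}
        assert ledger.retained_samples == 65
        ledger.check_conservation()

    def test_sex_mismatch_and_missing(self):
        meth = _intensity_frame([12, 12, 12])
        sheet = pd.DataFrame({"sex": ["M", "F", np.nan]}, index=meth.columns)
        predicted = pd.Series(["F", "F", "F"], index=meth.columns)
        retained, ledger = filter_samples(meth, meth, sheet, predicted)
        assert retained == ["S1"]
        assert ledger.excluded_samples_by_category == {"sex": 1, "sex_missing": 1}


class TestProbeFilter:
    def test_no_flags_all_detected(self, toy_manifest):
        man = toy_manifest.copy()
        man["flags"] = ""
        man["chr"] = "1"
        det = pd.DataFrame(0.01, index=man.index, columns=["S0", "S1"])
        retained, ledger = filter_probes(man, det)
        assert len(retained) == len(man)
        assert ledger.excluded_probes_by_category == {}

    def test_first_match_accounting(self, toy_manifest):
        """A probe flagged cross_reactive and smoking counts once, as cross_reactive."""
        retained, ledger = filter_probes(toy_manifest)
        by_cat = ledger.excluded_probes_by_category
        assert by_cat["cross_reactive"] == 2  # includes the doubly flagged probe
        assert "smoking" not in by_cat
        assert by_cat["sex_chromosome"] == 1
        ledger.check_conservation()

    def test_detection_rule_precedes_flags(self, toy_manifest):
        det = pd.DataFrame(0.01, index=toy_manifest.index, columns=["S0", "S1"])
        det.loc["cg3"] = 0.5  # cg3 also carries cross_reactive; detection wins
        retained, ledger = filter_probes(toy_manifest, det)
        assert ledger.excluded_probes_by_category["detection"] == 1
        assert ledger.excluded_probes_by_category["cross_reactive"] == 1

    def test_unknown_probe_in_detection_matrix(self, toy_manifest):
        det = pd.DataFrame(0.01, index=["nope"], columns=["S0"])
        with pytest.raises(DataError):
            filter_probes(toy_manifest, det)

    def test_idempotent(self, toy_manifest):
        retained, _ = filter_probes(toy_manifest)
        again, ledger2 = filter_probes(toy_manifest.loc[retained])
        assert again == retained
        assert ledger2.excluded_probes_by_category == {}


class TestQuantileNormalize:
    def test_hand_worked(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        assert out["a"].tolist() == [1.5, 3.0, 4.5]
        assert out["b"].tolist() == [1.5, 3.0, 4.5]

    def test_permuted_columns_identical_multisets(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": rng.permutation(x)})
        out = quantile_normalize(df)
        assert sorted(out["a"]) == pytest.approx(sorted(out["b"]))

    def test_single_column_identity(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_ties_averaged(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [1.0, 2.0, 3.0]})
        out = quantile_normalize(df)
        assert out["a"].iloc[0] == out["a"].iloc[1]


class TestDeconvolution:
    def _reference(self, rng, n_probes=60, n_types=3):
        ref = rng.uniform(0.05, 0.95, (n_probes, n_types))
        return pd.DataFrame(ref, index=[f"cg{i}" for i in range(n_probes)],
                            columns=["A", "B", "C"])

    def test_exact_mixture_recovered(self, rng):
        ref = self._reference(rng)
        x = 0.6 * ref["A"] + 0.4 * ref["B"]
        out = estimate_cell_composition(x.to_frame("s"), ref, n_per_type=20)
        assert out.loc["s"].to_numpy() == pytest.approx([0.6, 0.4, 0.0], abs=1e-8)

    def test_pure_sample(self, rng):
        ref = self._reference(rng)
        out = estimate_cell_composition(ref[["C"]].rename(columns={"C": "s"}),
                                        ref, n_per_type=20)
        assert out.loc["s", "C"] == pytest.approx(1.0, abs=1e-8)

    def test_too_few_probes_rejected(self, rng):
        ref = self._reference(rng).iloc[:2]
        with pytest.raises(DataError):
            estimate_cell_composition(ref[["A"]], ref)

    def test_objective_never_worse_than_zero_weights(self, rng):
        """Returned weights never fit worse than predicting all zeros."""
        ref = self._reference(rng)
        x = pd.DataFrame(rng.uniform(0, 1, (60, 4)), index=ref.index,
                         columns=list("wxyz"))
        w = estimate_cell_composition(x, ref, n_per_type=20)
        R = ref.to_numpy()
        for j, s in enumerate(x.columns):
            r_fit = np.linalg.norm(x[s].to_numpy() - R @ w.loc[s].to_numpy())
            assert r_fit <= np.linalg.norm(x[s].to_numpy()) + 1e-9


class TestSurrogateVariables:
    def _data(self, rng, n=200, p=300, batch_shift=0.0, noise=1.0):
        batch = np.repeat([0, 1], n // 2)
        pheno = rng.integers(0, 2, n)
        M = rng.normal(0, noise, (p, n))
        M[: p // 2] += batch_shift * batch
        cov = pd.DataFrame({"phenotype": pheno})
        return pd.DataFrame(M, columns=[f"S{i}" for i in range(n)]), cov, batch

    def test_k_zero_empty(self, rng):
        M, cov, _ = self._data(rng, n=30, p=20)
        assert surrogate_variables(M, cov, k=0).empty

    def test_recovers_planted_batch(self, rng):
        M, cov, batch = self._data(rng, batch_shift=2.0, noise=1.0)
        sv = surrogate_variables(M, cov, k=5)
        r = np.corrcoef(sv["SV1"], batch)[0, 1]
        assert abs(r) > 0.9

    def test_orthogonal_to_covariates_and_each_other(self, rng):
        M, cov, _ = self._data(rng, batch_shift=1.0)
        sv = surrogate_variables(M, cov, k=4)
        resid_cov = cov["phenotype"] - cov["phenotype"].mean()
        for c in sv.columns:
            assert abs(np.dot(sv[c], resid_cov)) < 1e-6 * np.linalg.norm(sv[c]) \
                * np.linalg.norm(resid_cov) + 1e-8
        G = sv.to_numpy().T @ sv.to_numpy()
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_pure_noise_uncorrelated_with_phenotype(self, rng):
        M, cov, _ = self._data(rng, batch_shift=0.0)
        sv = surrogate_variables(M, cov, k=5)
        for c in sv.columns:
            r = np.corrcoef(sv[c], cov["phenotype"])[0, 1]
            assert abs(r) < 0.3

    def test_k_too_large_rejected(self, rng):
        M, cov, _ = self._data(rng, n=10, p=20)
        with pytest.raises(ConfigError):
            surrogate_variables(M, cov, k=9)


def test_predict_sex_from_x_methylation():
    beta = pd.DataFrame({"m": [0.25, 0.3], "f": [0.5, 0.55]},
                        index=["x1", "x2"])
    out = predict_sex(beta, ["x1", "x2"])
    assert out.tolist() == ["M", "F"]
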