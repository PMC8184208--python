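"""Quality control, M-values, normalization, deconvolution, surrogate variables.

Filtering keeps an exact conservation ledger: every excluded probe or sample
is counted once, under the first category that matched, and
``retained + sum(excluded) == initial`` always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import ConfigError, DataError, NumericalError

__all__ = [
    "FilterLedger",
    "compute_m_values",
    "predict_sex",
    "filter_samples",
    "filter_probes",
    "quantile_normalize",
    "select_discriminating_probes",
    "estimate_cell_composition",
    "surrogate_variables",
]

PROBE_CATEGORIES = ("detection", "cross_reactive", "snp_within_3bp",
                    "sex_chromosome", "smoking")


@dataclass
class FilterLedger:
    """First-match accounting of probe and sample exclusions."""

    initial_probes: int = 0
    excluded_probes_by_category: dict = field(default_factory=dict)
    retained_probes: int = 0
    initial_samples: int = 0
    excluded_samples_by_category: dict = field(default_factory=dict)
    retained_samples: int = 0

    def check_conservation(self) -> None:
        if self.retained_probes + sum(self.excluded_probes_by_category.values()) \
                != self.initial_probes:
            raise DataError("probe ledger does not conserve counts")
        if self.retained_samples + sum(self.excluded_samples_by_category.values()) \
                != self.initial_samples:
            raise DataError("sample ledger does not conserve counts")

    def to_dict(self) -> dict:
        return {
            "initial_probes": self.initial_probes,
            "excluded_probes_by_category": dict(self.excluded_probes_by_category),
            "retained_probes": self.retained_probes,
            "initial_samples": self.initial_samples,
            "excluded_samples_by_category": dict(self.excluded_samples_by_category),
            "retained_samples": self.retained_samples,
        }


def compute_m_values(meth, unmeth):
    """M = log2((meth + 1) / (unmeth + 1)), elementwise.

    The +1 offsets keep the ratio finite at zero signal; equal intensities
    give M = 0. Negative intensities are rejected.
    """
    meth_a = np.asarray(meth, dtype=float)
    unmeth_a = np.asarray(unmeth, dtype=float)
    if (meth_a < 0).any() or (unmeth_a < 0).any():
        raise DataError("negative signal intensities")
    m = np.log2((meth_a + 1.0) / (unmeth_a + 1.0))
    if isinstance(meth, pd.DataFrame):
        return pd.DataFrame(m, index=meth.index, columns=meth.columns)
    return m


def predict_sex(beta: pd.DataFrame, x_probe_ids, threshold: float = 0.4) -> pd.Series:
    """Predict sample sex from mean X-chromosome beta.

    Females carry an inactive X and sit at intermediate methylation, males
    lower; mean X beta above ``threshold`` predicts female. Returns "F"/"M",
    or NaN when no X probes are present.
    """
    x_ids = [p for p in x_probe_ids if p in beta.index]
    if not x_ids:
        return pd.Series(np.nan, index=beta.columns, dtype=object)
    mean_x = beta.loc[x_ids].mean(axis=0)
    return pd.Series(np.where(mean_x > threshold, "F", "M"),
                     index=beta.columns, dtype=object)


def filter_samples(meth: pd.DataFrame, unmeth: pd.DataFrame,
                   sample_sheet: pd.DataFrame,
                   predicted_sex: pd.Series | None = None,
                   intensity_threshold: float = 11.0,
                   ledger: FilterLedger | None = None):
    """Exclude low-intensity samples, then sex-discordant ones.

    A sample fails QC when log2 of its median methylated OR unmethylated
    raw intensity falls below ``intensity_threshold``. Samples whose
    reported sex is missing are excluded under ``sex_missing`` rather than
    silently passed; a reported/predicted mismatch excludes under ``sex``.
    """
    ledger = ledger or FilterLedger()
    samples = list(meth.columns)
    ledger.initial_samples = len(samples)
    excluded: dict[str, str] = {}

    log2_med_m = np.log2(np.maximum(meth.median(axis=0), 1e-12))
    log2_med_u = np.log2(np.maximum(unmeth.median(axis=0), 1e-12))
    for s in samples:
        if log2_med_m[s] < intensity_threshold or log2_med_u[s] < intensity_threshold:
            excluded[s] = "intensity"

    for s in samples:
        if s in excluded:
            continue
        reported = sample_sheet.loc[s, "sex"] if "sex" in sample_sheet.columns else None
        if reported is None or (isinstance(reported, float) and np.isnan(reported)):
            excluded[s] = "sex_missing"
        elif predicted_sex is not None and isinstance(predicted_sex.get(s), str) \
                and predicted_sex[s] != reported:
            excluded[s] = "sex"

    retained = [s for s in samples if s not in excluded]
    counts: dict[str, int] = {}
    for cat in excluded.values():
        counts[cat] = counts.get(cat, 0) + 1
    ledger.excluded_samples_by_category = counts
    ledger.retained_samples = len(retained)
    ledger.check_conservation()
    return retained, ledger


def filter_probes(manifest: pd.DataFrame,
                  detection_p: pd.DataFrame | None = None,
                  detection_alpha: float = 0.05,
                  detection_sample_frac: float = 0.05,
                  smoking_probes=(),
                  ledger: FilterLedger | None = None):
    """Exclude failing probes with first-match category accounting.

    Categories, in order: ``detection`` (detection p > ``detection_alpha``
    in more than ``detection_sample_frac`` of samples), ``cross_reactive``
    and ``snp_within_3bp`` manifest flags, ``sex_chromosome`` (chr X/Y),
    and membership on the ``smoking`` probe list. Each excluded probe is
    counted once, under the first category that matched it.
    """
    ledger = ledger or FilterLedger()
    probes = manifest.index
    ledger.initial_probes = len(probes)

    if detection_p is not None:
        missing = detection_p.index.difference(probes)
        if len(missing):
            raise DataError(
                f"{len(missing)} probes in detection matrix absent from manifest")

    reasons = pd.Series("", index=probes, dtype=object)

    if detection_p is not None:
        fail_frac = (detection_p.reindex(probes) > detection_alpha).mean(axis=1)
        reasons[(fail_frac > detection_sample_frac) & (reasons == "")] = "detection"

    flags = manifest["flags"].fillna("") if "flags" in manifest.columns \
        else pd.Series("", index=probes)
    for flag, cat in (("cross_reactive", "cross_reactive"),
                      ("snp_within_3bp", "snp_within_3bp")):
        hit = flags.str.contains(flag, regex=False)
        reasons[hit & (reasons == "")] = cat

    sex_chrom = manifest["chr"].astype(str).isin(["X", "Y"])
    reasons[sex_chrom & (reasons == "")] = "sex_chromosome"

    if len(smoking_probes):
        smoking = probes.isin(set(smoking_probes)) | \
            flags.str.contains("smoking_associated", regex=False)
    else:
        smoking = flags.str.contains("smoking_associated", regex=False)
    reasons[smoking & (reasons == "")] = "smoking"

    retained = probes[reasons == ""].tolist()
    counts = reasons[reasons != ""].value_counts().to_dict()
    ledger.excluded_probes_by_category = {k: int(v) for k, v in counts.items()}
    ledger.retained_probes = len(retained)
    ledger.check_conservation()
    return retained, ledger


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the rank-wise mean reference distribution.

    After normalization all columns share an identical multiset of values.
    Ties within a column receive the mean of the reference values at the
    tied ranks. A single-column matrix is returned unchanged.
    """
    if matrix.isna().any().any():
        raise DataError("missing values before quantile normalization")
    if matrix.shape[1] <= 1:
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty_like(reference)
        ranked[order] = reference
        # average reference values across ties
        s = pd.Series(ranked).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def select_discriminating_probes(reference: pd.DataFrame,
                                 n_per_type: int = 100) -> list:
    """Pick the probes with the largest between-cell-type beta range.

    For each cell type, take the ``n_per_type`` probes (among those where
    that type is the extreme one) with the widest max-min spread across
    types; the union is the deconvolution basis.
    """
    vals = reference.to_numpy(dtype=float)
    spread = vals.max(axis=1) - vals.min(axis=1)
    extreme = np.abs(vals - vals.mean(axis=1, keepdims=True)).argmax(axis=1)
    chosen: list = []
    for t in range(reference.shape[1]):
        idx = np.where(extreme == t)[0]
        top = idx[np.argsort(spread[idx])[::-1][:n_per_type]]
        chosen.extend(reference.index[top])
    return sorted(set(chosen))


def estimate_cell_composition(betas: pd.DataFrame, reference: pd.DataFrame,
                              n_per_type: int = 100,
                              sum_to_one: bool = False) -> pd.DataFrame:
    """Reference-based deconvolution: nonnegative least squares per sample.

    Solves min ||x - R w||^2 subject to w >= 0 over a discriminating probe
    subset shared between the sample matrix and the sorted-cell reference.
    With ``sum_to_one`` the weights are renormalized to sum to 1.
    """
    shared = reference.index.intersection(betas.index)
    if len(shared) < reference.shape[1]:
        raise DataError(
            f"reference shares only {len(shared)} probes with the matrix; "
            f"need at least {reference.shape[1]}")
    ref = reference.loc[shared]
    probes = select_discriminating_probes(ref, n_per_type)
    R = ref.loc[probes].to_numpy(dtype=float)
    X = betas.loc[probes].to_numpy(dtype=float)
    weights = np.empty((betas.shape[1], reference.shape[1]))
    for j in range(betas.shape[1]):
        weights[j], _ = nnls(R, X[:, j])
    if sum_to_one:
        sums = weights.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        weights = weights / sums
    return pd.DataFrame(weights, index=betas.columns, columns=reference.columns)


def surrogate_variables(M: pd.DataFrame, covariates: pd.DataFrame,
                        k: int = 10) -> pd.DataFrame:
    """Residual-PCA surrogate components for unmeasured structured variation.

    Projects known covariates (including the phenotype) out of the probes x
    samples matrix and returns the top ``k`` principal-component score
    vectors of the residual, ordered by decreasing variance. The scores are
    mutually orthogonal and orthogonal to every covariate column.
    """
    if k <= 0:
        return pd.DataFrame(index=M.columns)
    X = np.column_stack([np.ones(M.shape[1]),
                         covariates.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if k >= M.shape[1] - rank:
        raise ConfigError(
            f"k={k} too large for {M.shape[1]} samples and covariate rank {rank}")
    Y = M.to_numpy(dtype=float).T  # samples x probes
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    try:
        U, s, _ = np.linalg.svd(resid, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise NumericalError(f"SVD failed in surrogate-variable step: {exc}")
    scores = U[:, :k] * s[:k]
    return pd.DataFrame(scores, index=M.columns,
                        columns=[f"SV{i + 1}" for i in range(k)])
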