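"""Seeded generator of Infinium-450K-style cohorts with known ground truth.

Emulates a two-group blood-methylation study split into a discovery and a
cross-validation cohort: beta-distributed methylation observed through
methylated/unmethylated signal intensities, logit-normal noise on the
M scale, confounder structure (age, sex, array, batch, an 8-part blood
cell-composition mixture), genomic region structure (CpG islands, gene
bodies, promoters), and planted site- and region-level case/control
effects on the beta scale.

Everything is reproducible: the same configuration and seed yield
byte-identical outputs. Randomness is drawn from named substreams of the
single configuration seed, so the manifest and the cohort can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "CELL_TYPES",
    "SyntheticConfig",
    "GroundTruth",
    "SimulatedCohort",
    "generate_manifest",
    "simulate_cohort",
    "generate_keyword_annotation",
    "beta_to_m",
    "m_to_beta",
]

#: The eight sorted-blood-cell reference populations used for deconvolution.
CELL_TYPES = (
    "CD14_monocytes",
    "CD19_B",
    "CD4_T",
    "CD56_NK",
    "CD8_T",
    "eosinophils",
    "granulocytes",
    "neutrophils",
)

FLAG_CATEGORIES = ("cross_reactive", "snp_within_3bp", "smoking_associated")

LN2 = np.log(2.0)


def beta_to_m(beta):
    """Base-2 logit: M = log2(beta / (1 - beta)). Preserves pandas containers."""
    if isinstance(beta, (pd.DataFrame, pd.Series)):
        return np.log2(beta / (1.0 - beta))
    beta = np.asarray(beta, dtype=float)
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 1 / (1 + 2**(-M))."""
    if isinstance(m, (pd.DataFrame, pd.Series)):
        return 1.0 / (1.0 + np.exp2(-m))
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the target study design: 116 cases / 130 controls in
    each of the discovery and cross-validation splits, planted site
    effects on the beta-value scale (positive = hypermethylated in
    cases), logit-normal measurement noise on the M scale, and a
    Dirichlet blood cell-composition mixture per sample.
    """

    seed: int = 0

    # cohort sizes (per split)
    n_cases_disc: int = 116
    n_controls_disc: int = 130
    n_cases_cv: int = 116
    n_controls_cv: int = 130

    # array layout
    n_probes: int = 10_000
    n_islands: int = 40
    n_gene_bodies: int = 40
    n_promoters: int = 40
    sites_per_region: tuple[int, int] = (3, 8)
    n_x_probes: int = 0
    n_y_probes: int = 0

    # planted effects; delta_beta = beta_case - beta_control
    planted_dms: list = field(default_factory=list)  # [(probe index, delta_beta)]
    planted_dmr: list = field(default_factory=list)  # [(region_id, [delta per site])]

    # confounder model
    age_mean_case: float = 72.3
    age_mean_control: float = 71.1
    age_sd: float = 8.0
    male_prop_case: float = 0.53
    male_prop_control: float = 0.39
    n_batches: int = 4
    samples_per_array: int = 12
    cell_alpha_case: tuple = (4.0, 3.0, 9.0, 3.0, 5.0, 2.0, 4.0, 30.0)
    cell_alpha_control: tuple = (4.0, 3.0, 9.0, 3.0, 5.0, 2.0, 4.0, 30.0)
    batch_effect_sd: float = 0.2
    batch_effect_frac: float = 0.05
    age_effect_sd: float = 0.01
    age_effect_frac: float = 0.02
    sex_effect_sd: float = 0.2
    sex_effect_frac: float = 0.02
    n_cell_informative: int = 200

    # noise and signal model
    noise_sd: float = 0.5
    region_correlation: float = 0.0
    intensity_log2_median: float = 13.0
    intensity_log2_sd: float = 0.5
    n_low_intensity_samples: int = 0
    low_intensity_log2_median: float = 10.0
    detection_fail_rate: float = 0.001

    # manifest exclusion flags (counts per category, drawn on disjoint probes)
    n_excluded_flags: dict = field(default_factory=dict)

    def validate(self) -> None:
        counts = {
            "n_cases_disc": self.n_cases_disc,
            "n_controls_disc": self.n_controls_disc,
            "n_cases_cv": self.n_cases_cv,
            "n_controls_cv": self.n_controls_cv,
            "n_probes": self.n_probes,
            "n_batches": self.n_batches,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        for name, v in {"n_islands": self.n_islands,
                        "n_gene_bodies": self.n_gene_bodies,
                        "n_promoters": self.n_promoters,
                        "n_x_probes": self.n_x_probes,
                        "n_y_probes": self.n_y_probes,
                        "n_cell_informative": self.n_cell_informative}.items():
            if v < 0:
                raise ConfigError(f"{name} must be nonnegative, got {v}")
        lo, hi = self.sites_per_region
        if not (1 <= lo <= hi):
            raise ConfigError(f"sites_per_region range invalid: {self.sites_per_region}")
        for _, db in self.planted_dms:
            if not -1.0 < db < 1.0:
                raise ConfigError(f"planted delta_beta {db} outside (-1, 1)")
        for _, deltas in self.planted_dmr:
            for db in deltas:
                if not -1.0 < db < 1.0:
                    raise ConfigError(f"planted region delta_beta {db} outside (-1, 1)")
        for alphas in (self.cell_alpha_case, self.cell_alpha_control):
            if len(alphas) != len(CELL_TYPES):
                raise ConfigError(f"need {len(CELL_TYPES)} cell concentrations")
            if any(a <= 0 for a in alphas):
                raise ConfigError("cell-fraction concentrations must be positive")
        if not 0.0 <= self.detection_fail_rate < 1.0:
            raise ConfigError("detection_fail_rate must be in [0, 1)")
        if not 0.0 <= self.region_correlation < 1.0:
            raise ConfigError("region_correlation must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        for cat in self.n_excluded_flags:
            if cat not in FLAG_CATEGORIES:
                raise ConfigError(f"unknown flag category {cat!r}")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Record of every planted feature of a simulated cohort."""

    true_dms: dict          # probe_id -> delta_beta (beta_case - beta_control)
    true_dmr: dict          # region_id -> [delta_beta per planted site]
    dmr_probes: dict        # region_id -> [probe_id per planted site]
    cell_fractions: pd.DataFrame  # samples x 8, rows sum to 1
    batch_labels: pd.Series
    case_labels: pd.Series  # 1 = case, 0 = control


@dataclass
class SimulatedCohort:
    """All observable outputs of one simulated study plus its ground truth."""

    meth: pd.DataFrame       # probes x samples methylated intensity
    unmeth: pd.DataFrame     # probes x samples unmethylated intensity
    detection: pd.DataFrame  # probes x samples detection p-values
    sample_sheet: pd.DataFrame
    cell_reference: pd.DataFrame  # informative probes x 8, beta scale
    truth: GroundTruth


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def generate_manifest(config: SyntheticConfig) -> pd.DataFrame:
    """Build a probe manifest with islands, gene bodies, promoters and flags.

    Probes are laid out region-block by region-block, each region kept on a
    single autosome (round-robin over chr1..22), followed by any requested
    X/Y probes and intergenic filler. Island sizes are drawn from
    ``sites_per_region`` with a floor of 2 so every island id groups at
    least two probes. Exclusion-flag categories are drawn on disjoint probe
    sets outside planted sites and regions, so configured counts are exact.
    """
    config.validate()
    rng = _rng(config.seed, 1)

    lo, hi = config.sites_per_region
    island_sizes = [max(2, int(k)) for k in rng.integers(lo, hi + 1, config.n_islands)]
    body_sizes = list(rng.integers(lo, hi + 1, config.n_gene_bodies))
    prom_sizes = list(rng.integers(lo, hi + 1, config.n_promoters))

    demand = sum(island_sizes) + sum(body_sizes) + sum(prom_sizes) \
        + config.n_x_probes + config.n_y_probes
    if demand > config.n_probes:
        raise ConfigError(
            f"region/sex-probe demand ({demand}) exceeds n_probes ({config.n_probes})")

    n = config.n_probes
    chrom = np.empty(n, dtype=object)
    gene = np.full(n, "", dtype=object)
    feature = np.full(n, "intergenic", dtype=object)
    island_id = np.full(n, "", dtype=object)

    ptr = 0
    autosome = 0
    region_spans: list[tuple[int, int]] = []  # probe index spans of all regions

    def next_autosome():
        nonlocal autosome
        autosome += 1
        return str((autosome - 1) % 22 + 1)

    for i, k in enumerate(island_sizes):
        sl = slice(ptr, ptr + k)
        chrom[sl] = next_autosome()
        island_id[sl] = f"CGI_{i:04d}"
        gene[sl] = f"GENEI{i:03d}"
        region_spans.append((ptr, ptr + k))
        ptr += k
    for i, k in enumerate(body_sizes):
        sl = slice(ptr, ptr + k)
        chrom[sl] = next_autosome()
        gene[sl] = f"GENEB{i:03d}"
        feats = rng.choice(["Body", "5'UTR"], size=k, p=[0.8, 0.2])
        feature[sl] = feats
        region_spans.append((ptr, ptr + k))
        ptr += k
    for i, k in enumerate(prom_sizes):
        sl = slice(ptr, ptr + k)
        chrom[sl] = next_autosome()
        gene[sl] = f"GENEP{i:03d}"
        feature[sl] = rng.choice(["TSS200", "TSS1500"], size=k)
        region_spans.append((ptr, ptr + k))
        ptr += k
    if config.n_x_probes:
        chrom[ptr:ptr + config.n_x_probes] = "X"
        ptr += config.n_x_probes
    if config.n_y_probes:
        chrom[ptr:ptr + config.n_y_probes] = "Y"
        ptr += config.n_y_probes
    if ptr < n:
        fill = np.arange(ptr, n)
        chrom[fill] = [str(c % 22 + 1) for c in fill]

    # positions: increasing per chromosome; region probes get tight spacing
    pos = np.zeros(n, dtype=np.int64)
    order = pd.Series(np.arange(n)).groupby(pd.Series(chrom)).groups
    in_region = np.zeros(n, dtype=bool)
    for a, b in region_spans:
        in_region[a:b] = True
    for _, idx in order.items():
        idx = np.asarray(idx)
        gaps = np.where(in_region[idx], rng.integers(30, 500, idx.size),
                        rng.integers(2_000, 50_000, idx.size))
        pos[idx] = 1 + np.cumsum(gaps)

    probe_ids = np.array([f"cg{i:08d}" for i in range(n)], dtype=object)

    # exclusion flags on disjoint, unplanted, non-region probes when possible
    flags = np.full(n, "", dtype=object)
    planted_idx = {int(i) for i, _ in config.planted_dms}
    eligible = np.array([i for i in range(n)
                         if i not in planted_idx and not in_region[i]
                         and chrom[i] not in ("X", "Y")])
    total_flags = sum(config.n_excluded_flags.values())
    if total_flags > eligible.size:
        eligible = np.array([i for i in range(n) if i not in planted_idx])
        if total_flags > eligible.size:
            raise ConfigError("more exclusion flags requested than available probes")
    drawn = rng.choice(eligible, size=total_flags, replace=False) if total_flags else []
    start = 0
    for cat in FLAG_CATEGORIES:
        k = config.n_excluded_flags.get(cat, 0)
        for i in drawn[start:start + k]:
            flags[i] = cat
        start += k

    manifest = pd.DataFrame(
        {"chr": chrom, "pos": pos, "gene": gene, "feature": feature,
         "island_id": island_id, "flags": flags},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return manifest


def _gauss_hermite(sigma: float, order: int = 31):
    """Nodes/weights for E[f(mu + sigma Z)], Z standard normal."""
    x, w = np.polynomial.hermite.hermgauss(order)
    return np.sqrt(2.0) * sigma * x, w / np.sqrt(np.pi)


def _m_offset_for_delta_beta(m0: float, delta_beta: float, sigma: float) -> float:
    """M-scale shift whose noise-averaged beta difference equals ``delta_beta``.

    Solves E[logistic2(m0 + d + e)] - E[logistic2(m0 + e)] = delta_beta with
    e ~ N(0, sigma^2), by bisection on d; this removes the Jensen attenuation
    a plain logit-derivative conversion would leave behind.
    """
    nodes, w = _gauss_hermite(sigma)
    base = float(w @ m_to_beta(m0 + nodes))
    target = base + delta_beta
    if not 0.0 < target < 1.0:
        raise ConfigError(
            f"delta_beta {delta_beta} unreachable from baseline beta {base:.3f}")

    def smoothed(d):
        return float(w @ m_to_beta(m0 + d + nodes)) - target

    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if smoothed(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _region_probe_index(manifest: pd.DataFrame) -> dict:
    """region_id -> list of probe positional indices, for all three region types."""
    out: dict[str, list[int]] = {}
    positions = {p: i for i, p in enumerate(manifest.index)}
    isl = manifest[manifest["island_id"] != ""]
    for rid, sub in isl.groupby("island_id"):
        out[str(rid)] = [positions[p] for p in sub.index]
    bodies = manifest[manifest["feature"].isin(["Body", "5'UTR"]) & (manifest["gene"] != "")]
    for g, sub in bodies.groupby("gene"):
        out[f"body:{g}"] = [positions[p] for p in sub.index]
    proms = manifest[manifest["feature"].isin(["TSS200", "TSS1500"]) & (manifest["gene"] != "")]
    for g, sub in proms.groupby("gene"):
        out[f"promoter:{g}"] = [positions[p] for p in sub.index]
    return out


def simulate_cohort(config: SyntheticConfig, manifest: pd.DataFrame) -> SimulatedCohort:
    """Draw intensities, detection p-values and a sample sheet for one study.

    The observation model: each probe has a baseline M value (bimodal across
    the array, as on real 450K data); cell-informative probes instead take
    the per-sample mixture of the sorted-cell reference profiles. Case
    status, batch, age and sex shift M on subsets of probes; measurement
    noise is Gaussian on the M scale. Betas are the base-2 logistic of M,
    and signals are ``meth = beta*T``, ``unmeth = (1-beta)*T`` for a
    lognormal total intensity T, so the standard M-value formula recovers
    the intended value up to the +1 offsets.
    """
    config.validate()
    n = config.n_probes
    if len(manifest) != n:
        raise ConfigError(f"manifest has {len(manifest)} probes, config says {n}")
    rng = _rng(config.seed, 2)

    region_index = _region_probe_index(manifest)
    for rid, deltas in config.planted_dmr:
        if rid not in region_index:
            raise ConfigError(f"planted region {rid!r} not in manifest")
        if len(deltas) > len(region_index[rid]):
            raise ConfigError(f"region {rid!r} has fewer sites than planted effects")
    for i, _ in config.planted_dms:
        if not 0 <= int(i) < n:
            raise ConfigError(f"planted probe index {i} out of range")

    # ---- samples -------------------------------------------------------
    groups = [("discovery", 1, config.n_cases_disc),
              ("discovery", 0, config.n_controls_disc),
              ("cross_validation", 1, config.n_cases_cv),
              ("cross_validation", 0, config.n_controls_cv)]
    split, case = [], []
    for sp, ph, k in groups:
        split += [sp] * k
        case += [ph] * k
    split = np.array(split)
    case = np.array(case)
    n_samples = case.size
    sample_ids = np.array([f"S{i:04d}" for i in range(n_samples)])

    age = np.where(case == 1,
                   rng.normal(config.age_mean_case, config.age_sd, n_samples),
                   rng.normal(config.age_mean_control, config.age_sd, n_samples))
    male_p = np.where(case == 1, config.male_prop_case, config.male_prop_control)
    sex = np.where(rng.random(n_samples) < male_p, "M", "F")
    batch = rng.integers(0, config.n_batches, n_samples)
    array = np.arange(n_samples) // config.samples_per_array

    alpha_case = np.asarray(config.cell_alpha_case, dtype=float)
    alpha_ctrl = np.asarray(config.cell_alpha_control, dtype=float)
    fracs = np.empty((n_samples, len(CELL_TYPES)))
    for s in range(n_samples):
        fracs[s] = rng.dirichlet(alpha_case if case[s] else alpha_ctrl)

    # ---- probe baselines ----------------------------------------------
    comp = rng.choice(3, size=n, p=[0.3, 0.3, 0.4])
    m0 = np.where(comp == 0, rng.normal(-2.5, 0.7, n),
                  np.where(comp == 1, rng.normal(2.5, 0.7, n),
                           rng.normal(0.0, 1.2, n)))

    # planted probes get a moderate baseline so beta-scale effects are realizable
    planted_sites = {int(i): float(db) for i, db in config.planted_dms}
    dmr_site_map: dict[int, float] = {}
    dmr_probe_record: dict[str, list[str]] = {}
    for rid, deltas in config.planted_dmr:
        idxs = region_index[rid][: len(deltas)]
        dmr_probe_record[rid] = [manifest.index[j] for j in idxs]
        for j, db in zip(idxs, deltas):
            dmr_site_map[j] = float(db)
    for j in set(planted_sites) | set(dmr_site_map):
        m0[j] = rng.normal(0.0, 0.5)

    # cell-informative probes: per-sample beta is the reference mixture
    flagged_or_planted = set(planted_sites) | set(dmr_site_map)
    in_region = np.zeros(n, dtype=bool)
    for idxs in region_index.values():
        in_region[idxs] = True
    free = np.array([i for i in range(n)
                     if i not in flagged_or_planted and not in_region[i]
                     and manifest["chr"].iloc[i] not in ("X", "Y")])
    n_inf = min(config.n_cell_informative, free.size)
    inf_idx = rng.choice(free, size=n_inf, replace=False) if n_inf else np.array([], int)
    n_types = len(CELL_TYPES)
    ref = np.clip(rng.normal(0.15, 0.03, (n_inf, n_types)), 0.02, 0.98)
    for j in range(n_inf):
        t = j % n_types
        ref[j, t] = np.clip(rng.normal(0.85, 0.03), 0.02, 0.98)

    # ---- M matrix ------------------------------------------------------
    M = np.tile(m0[:, None], (1, n_samples))
    if n_inf:
        mix = np.clip(ref @ fracs.T, 1e-3, 1 - 1e-3)  # n_inf x samples
        M[inf_idx, :] = beta_to_m(mix)

    # case effects (noise-calibrated M offsets)
    for j, db in {**planted_sites, **dmr_site_map}.items():
        d = _m_offset_for_delta_beta(m0[j], db, config.noise_sd)
        M[j, case == 1] += d

    # batch effects on a random probe subset
    n_batch_probes = int(round(config.batch_effect_frac * n))
    if n_batch_probes and config.batch_effect_sd > 0:
        bidx = rng.choice(n, size=n_batch_probes, replace=False)
        shifts = rng.normal(0.0, config.batch_effect_sd,
                            (n_batch_probes, config.n_batches))
        M[bidx, :] += shifts[:, batch]

    # age effects
    n_age_probes = int(round(config.age_effect_frac * n))
    if n_age_probes and config.age_effect_sd > 0:
        aidx = rng.choice(n, size=n_age_probes, replace=False)
        slopes = rng.normal(0.0, config.age_effect_sd, n_age_probes)
        M[aidx, :] += slopes[:, None] * (age - age.mean())[None, :]

    # sex effects on autosomes, plus the X-chromosome signature used for
    # sex prediction (males hypomethylated on X relative to females)
    n_sex_probes = int(round(config.sex_effect_frac * n))
    male = (sex == "M")
    if n_sex_probes and config.sex_effect_sd > 0:
        sidx = rng.choice(n, size=n_sex_probes, replace=False)
        offs = rng.normal(0.0, config.sex_effect_sd, n_sex_probes)
        M[np.ix_(sidx, male)] += offs[:, None]
    x_mask = (manifest["chr"] == "X").to_numpy()
    if x_mask.any():
        M[x_mask, :] = 0.0
        M[np.ix_(x_mask, male)] = -1.6

    # noise, optionally correlated within regions
    rho = config.region_correlation
    eps = rng.normal(0.0, 1.0, (n, n_samples))
    if rho > 0:
        for idxs in region_index.values():
            shared = rng.normal(0.0, 1.0, n_samples)
            eps[idxs, :] = np.sqrt(rho) * shared[None, :] \
                + np.sqrt(1 - rho) * eps[idxs, :]
    M = M + config.noise_sd * eps

    beta = m_to_beta(M)

    # ---- intensities and detection ------------------------------------
    med = np.full(n_samples, config.intensity_log2_median)
    med[: config.n_low_intensity_samples] = config.low_intensity_log2_median
    log2_T = rng.normal(med[None, :], config.intensity_log2_sd, (n, n_samples))
    T = np.exp2(log2_T)
    meth = beta * T
    unmeth = (1.0 - beta) * T

    det = rng.uniform(0.0, 0.05, (n, n_samples))
    if config.detection_fail_rate > 0:
        fail = rng.random((n, n_samples)) < config.detection_fail_rate
        det[fail] = rng.uniform(0.05, 1.0, int(fail.sum()))

    probe_index = manifest.index
    cols = pd.Index(sample_ids, name="sample_id")
    sheet = pd.DataFrame(
        {"split": split, "phenotype": np.where(case == 1, "case", "control"),
         "age": age, "sex": sex,
         "batch": [f"B{b}" for b in batch],
         "array": [f"A{a}" for a in array]},
        index=cols,
    )
    truth = GroundTruth(
        true_dms={probe_index[j]: db for j, db in planted_sites.items()},
        true_dmr={rid: list(map(float, deltas)) for rid, deltas in config.planted_dmr},
        dmr_probes=dmr_probe_record,
        cell_fractions=pd.DataFrame(fracs, index=cols, columns=list(CELL_TYPES)),
        batch_labels=pd.Series([f"B{b}" for b in batch], index=cols, name="batch"),
        case_labels=pd.Series(case, index=cols, name="case"),
    )
    return SimulatedCohort(
        meth=pd.DataFrame(meth, index=probe_index, columns=cols),
        unmeth=pd.DataFrame(unmeth, index=probe_index, columns=cols),
        detection=pd.DataFrame(det, index=probe_index, columns=cols),
        sample_sheet=sheet,
        cell_reference=pd.DataFrame(ref, index=probe_index[inf_idx],
                                    columns=list(CELL_TYPES)),
        truth=truth,
    )


def generate_keyword_annotation(genes, n_keywords: int = 6,
                                genes_per_keyword: int = 8,
                                overlap_frac: float = 0.25,
                                seed: int = 0) -> dict:
    """Small keyword -> gene-set table for the network stage.

    ``overlap_frac`` of each keyword's genes are drawn from a common shared
    pool so that keywords overlap, as reduced GO keyword sets do.
    """
    genes = list(genes)
    if genes_per_keyword > len(genes):
        raise ConfigError("genes_per_keyword exceeds available genes")
    rng = _rng(seed, 3)
    n_shared = max(1, int(round(overlap_frac * genes_per_keyword)))
    shared_pool = list(rng.choice(genes, size=min(len(genes), 3 * n_shared),
                                  replace=False))
    annotation = {}
    for k in range(n_keywords):
        own = list(rng.choice(genes, size=genes_per_keyword - n_shared, replace=False))
        sh = list(rng.choice(shared_pool, size=n_shared, replace=False))
        annotation[f"keyword_{k}"] = set(own) | set(sh)
    return annotation
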