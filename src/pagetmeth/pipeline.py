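"""End-to-end pipeline: simulate -> qc -> dms -> dmr -> pool -> classify -> network.

Each stage consumes the previous stage's outputs; structured logs record
the headline counts (probes retained, DMS, DMR, pooled sites, best-subset
size, AUC). All randomness flows from the single configuration seed
through named substreams, and a run manifest records the configuration
hash plus a checksum per stage output so identical runs are verifiably
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import dmr as dmr_mod
from . import dms as dms_mod
from . import io as pio
from . import network as net_mod
from . import preprocess as prep
from .errors import ConfigError
from .synthetic import (SyntheticConfig, generate_keyword_annotation,
                        generate_manifest, m_to_beta, simulate_cohort)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "dms", "dmr", "pool", "classify", "network")


@dataclass
class PipelineConfig:
    """Thresholds, stage toggles and synthetic-cohort settings for one run."""

    seed: int = 0
    outdir: str = "pagetmeth_run"
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    fdr: float = 0.05
    bonferroni_alpha: float = 0.05
    detection_alpha: float = 0.05
    detection_sample_frac: float = 0.05
    intensity_threshold: float = 11.0
    normalization: str = "quantile"   # or "none"
    n_surrogate: int = 10
    n_ortho: int = 1
    enet_mixing: float = 0.5
    run_classify: bool = True
    run_network: bool = True
    n_keywords: int = 6
    keyword_genes: int = 8

    def validate(self) -> None:
        for name in ("fdr", "bonferroni_alpha", "detection_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.normalization not in ("quantile", "none"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    seed: int
    stage_checksums: dict
    timestamps: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _hash_df(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(",".join(map(str, df.index)).encode())
    h.update(",".join(map(str, df.columns)).encode())
    vals = df.to_numpy()
    if vals.dtype == object:
        h.update(df.to_csv().encode())
    else:
        h.update(np.ascontiguousarray(vals).tobytes())
    return h.hexdigest()


def _hash_config(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class PipelineResult:
    manifest_table: pd.DataFrame | None = None
    cohort: object = None
    ledger: prep.FilterLedger | None = None
    m_values: dict = field(default_factory=dict)       # split -> probes x samples
    betas: dict = field(default_factory=dict)
    confounders: dict = field(default_factory=dict)
    phenotype: dict = field(default_factory=dict)
    site_results: dict = field(default_factory=dict)   # split -> DataFrame
    replication: dms_mod.ReplicationResult | None = None
    meta: pd.DataFrame | None = None
    meta_significant: list = field(default_factory=list)
    region_results: dict = field(default_factory=dict)  # type -> workflow result
    pooled: dmr_mod.PooledSites | None = None
    oplsda: clf.OPLSDAModel | None = None
    evaluation: clf.ClassifierEval | None = None
    best_subset: clf.BestSubset | None = None
    effect_size_p: float | None = None
    edges: list = field(default_factory=list)
    run_manifest: RunManifest | None = None


def run_pipeline(config: PipelineConfig, until: str = "network",
                 write_outputs: bool = True) -> PipelineResult:
    """Execute the workflow up to and including stage ``until``."""
    config.validate()
    if until not in STAGES:
        raise ConfigError(f"unknown stage {until!r}")
    last = STAGES.index(until)
    out = Path(config.outdir)
    res = PipelineResult()
    checksums: dict[str, str] = {}
    stamps: dict[str, float] = {}

    def done(stage: str) -> bool:
        stamps[stage] = time.time()
        return STAGES.index(stage) >= last

    # ---- simulate ------------------------------------------------------
    syn = SyntheticConfig(seed=config.seed, **config.synthetic)
    manifest = generate_manifest(syn)
    cohort = simulate_cohort(syn, manifest)
    res.manifest_table = manifest
    res.cohort = cohort
    checksums["simulate"] = _hash_df(cohort.meth)
    logger.info("simulate: %d probes, %d samples", len(manifest),
                cohort.sample_sheet.shape[0])
    if write_outputs:
        pio.write_manifest(out / "manifest.tsv", manifest)
        pio.write_sample_sheet(out / "sample_sheet.csv", cohort.sample_sheet)
        pio.write_json(out / "ground_truth.json", {
            "true_dms": cohort.truth.true_dms,
            "true_dmr": cohort.truth.true_dmr,
            "dmr_probes": cohort.truth.dmr_probes,
        })
    if done("simulate"):
        return _finish(res, config, checksums, stamps, out, write_outputs)

    # ---- qc ------------------------------------------------------------
    ledger = prep.FilterLedger()
    beta_raw = cohort.meth / (cohort.meth + cohort.unmeth).clip(lower=1e-12)
    x_probes = manifest.index[manifest["chr"] == "X"]
    predicted = prep.predict_sex(beta_raw, x_probes) if len(x_probes) else None
    samples, ledger = prep.filter_samples(
        cohort.meth, cohort.unmeth, cohort.sample_sheet, predicted,
        config.intensity_threshold, ledger)
    probes, ledger = prep.filter_probes(
        manifest, cohort.detection[samples], config.detection_alpha,
        config.detection_sample_frac, ledger=ledger)
    res.ledger = ledger
    logger.info("qc: retained %d/%d probes, %d/%d samples",
                ledger.retained_probes, ledger.initial_probes,
                ledger.retained_samples, ledger.initial_samples)

    M = prep.compute_m_values(cohort.meth.loc[probes, samples],
                              cohort.unmeth.loc[probes, samples])
    if config.normalization == "quantile":
        M = prep.quantile_normalize(M)
    beta = m_to_beta(M)

    sheet = cohort.sample_sheet.loc[samples]
    cellcomp = prep.estimate_cell_composition(beta, cohort.cell_reference) \
        if len(cohort.cell_reference) else None

    for split in ("discovery", "cross_validation"):
        ids = sheet.index[sheet["split"] == split]
        Ms = M[ids]
        res.m_values[split] = Ms
        res.betas[split] = beta[ids]
        pheno = (sheet.loc[ids, "phenotype"] == "case").astype(int)
        res.phenotype[split] = pheno
        conf = pd.DataFrame({"age": sheet.loc[ids, "age"],
                             "sex": sheet.loc[ids, "sex"],
                             "batch": sheet.loc[ids, "batch"]})
        if cellcomp is not None:
            # drop the last cell type: fractions sum to ~1
            conf = pd.concat([conf, cellcomp.loc[ids].iloc[:, :-1]], axis=1)
        if config.n_surrogate > 0:
            known = pd.get_dummies(conf, drop_first=True).astype(float)
            known["phenotype"] = pheno.to_numpy()
            sv = prep.surrogate_variables(Ms, known, config.n_surrogate)
            conf = pd.concat([conf, sv], axis=1)
        res.confounders[split] = conf
    checksums["qc"] = _hash_df(M)
    if write_outputs:
        pio.write_json(out / "filter_ledger.json", ledger.to_dict())
    if done("qc"):
        return _finish(res, config, checksums, stamps, out, write_outputs)

    # ---- dms -----------------------------------------------------------
    for split in ("discovery", "cross_validation"):
        fit = dms_mod.fit_site_models(res.m_values[split], res.phenotype[split],
                                      res.confounders[split], res.betas[split])
        mod = dms_mod.empirical_bayes_moderation(fit)
        fit["p"] = mod.p_mod
        fit["t"] = mod.t_mod
        fit["se_mod"] = fit["se_M"] * np.sqrt(mod.s_tilde_sq / fit["sigma2"])
        res.site_results[split] = fit
    disc, cv = res.site_results["discovery"], res.site_results["cross_validation"]
    res.replication = dms_mod.discovery_replication(disc, cv, config.fdr)
    meta = dms_mod.meta_fixed_effect(
        disc["coef_M"].to_numpy(), disc["se_mod"].to_numpy(),
        cv["coef_M"].to_numpy(), cv["se_mod"].to_numpy())
    res.meta = pd.DataFrame({
        "coef_meta": meta.beta_meta, "se_meta": meta.se_meta,
        "p_meta": meta.p_meta,
        "delta_beta_meta": dms_mod.meta_fixed_effect(
            disc["delta_beta"].to_numpy(), disc["se_mod"].to_numpy(),
            cv["delta_beta"].to_numpy(), cv["se_mod"].to_numpy()).beta_meta,
    }, index=disc.index)
    thr = dms_mod.bonferroni_threshold(config.bonferroni_alpha, len(disc))
    res.meta_significant = res.meta.index[res.meta["p_meta"] < thr].tolist()
    logger.info("dms: %d discovery FDR-significant, %d replicated, %d meta",
                len(res.replication.stage1_probes),
                len(res.replication.replicated_probes),
                len(res.meta_significant))
    checksums["dms"] = _hash_df(res.meta)
    if write_outputs:
        table = pd.DataFrame({
            "chr": manifest.loc[disc.index, "chr"],
            "pos": manifest.loc[disc.index, "pos"],
            "delta_beta_disc": disc["delta_beta"], "p_disc": disc["p"],
            "delta_beta_cv": cv["delta_beta"], "p_cv": cv["p"],
            "delta_beta_meta": res.meta["delta_beta_meta"],
            "p_meta": res.meta["p_meta"],
            "gene": manifest.loc[disc.index, "gene"],
        })
        pio.write_matrix(out / "dms_results.tsv", table)
    if done("dms"):
        return _finish(res, config, checksums, stamps, out, write_outputs)

    # ---- dmr -----------------------------------------------------------
    rmap = dmr_mod.build_region_map(manifest.loc[probes])
    for rtype, regions in rmap.by_type.items():
        if not regions:
            continue
        res.region_results[rtype] = dmr_mod.region_workflow(
            res.m_values["discovery"], res.phenotype["discovery"],
            res.confounders["discovery"],
            res.m_values["cross_validation"], res.phenotype["cross_validation"],
            res.confounders["cross_validation"],
            regions, alpha=config.fdr)
        logger.info("dmr[%s]: %d tested, %d FDR-selected, %d replicated",
                    rtype, len(res.region_results[rtype].table),
                    len(res.region_results[rtype].fdr_selected),
                    len(res.region_results[rtype].replicated))
    if write_outputs and res.region_results:
        combined = pd.concat([r.table for r in res.region_results.values()])
        pio.write_matrix(out / "dmr_results.tsv", combined)
    checksums["dmr"] = hashlib.sha256(str(sorted(
        (t, tuple(r.fdr_selected)) for t, r in res.region_results.items()
    )).encode()).hexdigest()
    if done("dmr"):
        return _finish(res, config, checksums, stamps, out, write_outputs)

    # ---- pool ----------------------------------------------------------
    region_sites: dict[str, list] = {}
    for rtype, wf in res.region_results.items():
        sites: list = []
        for rid in wf.fdr_selected:
            q = dmr_mod.site_level_within_region(wf.disc_results[rid], config.fdr)
            sites.extend(q.index[q < config.fdr])
        region_sites[rtype] = sites
    res.pooled = dmr_mod.pool_sites(res.replication.stage1_probes, region_sites)
    logger.info("pool: %d pooled sites", len(res.pooled.probe_ids))
    checksums["pool"] = hashlib.sha256(
        ",".join(res.pooled.probe_ids).encode()).hexdigest()
    if write_outputs:
        pio.write_json(out / "pooled_sites.json",
                       {p: sorted(t) for p, t in res.pooled.provenance.items()})
    if done("pool"):
        return _finish(res, config, checksums, stamps, out, write_outputs)

    # ---- classify ------------------------------------------------------
    pooled_ids = res.pooled.probe_ids
    if config.run_classify and len(pooled_ids) >= 2:
        Xtr = res.m_values["discovery"].loc[pooled_ids].T
        ytr = res.phenotype["discovery"].to_numpy()
        Xte = res.m_values["cross_validation"].loc[pooled_ids].T
        yte = res.phenotype["cross_validation"].to_numpy()
        res.oplsda = clf.fit_oplsda(Xtr, ytr, n_ortho=config.n_ortho)
        scores = clf.predict_scores(res.oplsda, Xte)
        res.evaluation = clf.evaluate_roc(scores, yte)
        logger.info("classify: CV AUC %.3f sens %.2f spec %.2f",
                    res.evaluation.auc, res.evaluation.sensitivity,
                    res.evaluation.specificity)
        if len(pooled_ids) >= 3:
            res.best_subset = clf.elastic_net_select(
                Xtr, ytr, mixing=config.enet_mixing, seed=config.seed)
            logger.info("classify: best subset %d sites",
                        len(res.best_subset.probe_ids))
            sub = res.best_subset.probe_ids
            if 0 < len(sub) < len(pooled_ids):
                res.effect_size_p = clf.compare_effect_sizes(
                    disc.loc[pooled_ids, "delta_beta"], sub)
        checksums["classify"] = hashlib.sha256(
            np.asarray(scores).tobytes()).hexdigest()
        if write_outputs:
            pio.write_json(out / "oplsda_model.json", res.oplsda.to_dict())
            pio.write_json(out / "classifier_eval.json", {
                "auc": res.evaluation.auc,
                "sensitivity": res.evaluation.sensitivity,
                "specificity": res.evaluation.specificity,
                "threshold": res.evaluation.threshold})
    elif config.run_classify:
        logger.info("classify: skipped, fewer than 2 pooled sites")
    else:
        logger.info("classify: disabled by configuration")
    if done("classify"):
        return _finish(res, config, checksums, stamps, out, write_outputs)

    # ---- network -------------------------------------------------------
    if config.run_network and len(pooled_ids) >= 3:
        M_all = pd.concat([res.m_values["discovery"],
                           res.m_values["cross_validation"]], axis=1)
        genes = manifest.loc[pooled_ids, "gene"]
        with_gene = genes.index[genes.astype(str) != ""].tolist()
        if len(with_gene) >= 3:
            annot = generate_keyword_annotation(
                sorted(set(genes[with_gene])), n_keywords=config.n_keywords,
                genes_per_keyword=min(config.keyword_genes,
                                      len(set(genes[with_gene]))),
                seed=config.seed)
            res.edges = net_mod.build_keyword_network(
                M_all.loc[with_gene].T, annot, manifest["gene"],
                q_threshold=config.fdr)
            logger.info("network: %d keyword edges", len(res.edges))
            if write_outputs and res.edges:
                net_mod.edges_to_graphml(res.edges, out / "keyword_network.graphml")
        else:
            logger.info("network: skipped, too few gene-annotated pooled sites")
    elif config.run_network:
        logger.info("network: skipped, fewer than 3 pooled sites")
    else:
        logger.info("network: disabled by configuration")
    done("network")
    return _finish(res, config, checksums, stamps, out, write_outputs)


def _finish(res: PipelineResult, config: PipelineConfig, checksums, stamps,
            out: Path, write_outputs: bool) -> PipelineResult:
    from . import __version__
    res.run_manifest = RunManifest(
        tool_version=__version__, config_hash=_hash_config(config),
        seed=config.seed, stage_checksums=dict(checksums),
        timestamps=dict(stamps))
    if write_outputs:
        pio.write_json(out / "run_manifest.json", res.run_manifest.to_dict())
    return res
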