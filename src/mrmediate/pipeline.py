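"""Config-driven orchestration of the full drug-target MR + mediation study.

One declarative YAML config describes the exposures (biomarker GWAS plus
target-gene region and LD source), the outcome GWAS, and the candidate
mediator GWASs; :func:`run_pipeline` then executes, per exposure:
instrument selection → harmonization → MR estimation → the sensitivity
battery, applies Bonferroni control across the exposure family, screens
mediators for the exposures that pass, estimates the mediator→outcome
effects with the mediators' own pQTL instruments, and finishes with the
product-of-coefficients mediation decomposition.  All result families are
written as TSVs plus a JSON run manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators, gwas_io, instruments, mediation, sensitivity
from .gwas_io import GwasTable, HarmonizedSet, read_gwas
from .instruments import (ClumpParams, DRUG_TARGET_PRESET, GeneRegion,
                          LdMatrix, PQTL_PRESET)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ExposureSpec", "MediatorSpec", "load_config",
           "run_pipeline", "select_drug_target_instruments",
           "select_pqtl_instruments"]


@dataclass
class ExposureSpec:
    name: str
    gwas: Path
    region: GeneRegion
    ld: Path


@dataclass
class MediatorSpec:
    name: str
    gwas: Path
    ld: Path


@dataclass
class RunConfig:
    """Validated study configuration (see the example config in README)."""

    exposures: list[ExposureSpec]
    outcome_name: str
    outcome_gwas: Path
    mediators: list[MediatorSpec] = field(default_factory=list)
    blocklist: Path | None = None
    output_dir: Path = Path("results")
    seed: int = 0
    p_exposure: float = 5e-8
    p_mediator: float = 5e-6
    eaf_min: float = 0.01
    r2: float = 0.3
    r2_fallback: float = 0.4
    min_snps: int = 3
    clump_kb: float = 10_000.0
    n_boot: int = 1000
    n_sim: int = 1000
    estimator_mode: str = "auto"
    palindrome_policy: str = "infer-by-frequency"
    overlap_policy: str = "drop-shared"
    m_exposures: int | None = None
    m_mediators: int | None = None

    def drug_target_params(self) -> ClumpParams:
        return ClumpParams(r2_primary=self.r2, r2_fallback=self.r2_fallback,
                           min_snps=self.min_snps, window_kb=self.clump_kb,
                           p_threshold=self.p_exposure)

    def pqtl_params(self) -> ClumpParams:
        return ClumpParams(r2_primary=PQTL_PRESET.r2_primary,
                           r2_fallback=PQTL_PRESET.r2_fallback,
                           min_snps=1, window_kb=self.clump_kb,
                           p_threshold=self.p_mediator)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; paths resolve relative to it."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def _p(rel) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else base / p

    exposures = []
    for e in raw["exposures"]:
        r = e["region"]
        exposures.append(ExposureSpec(
            name=e["name"], gwas=_p(e["gwas"]),
            region=GeneRegion(r.get("gene_symbol", e["name"]),
                              str(r["chrom"]), int(r["start"]),
                              int(r["end"]), float(r.get("flank_kb", 100))),
            ld=_p(e["ld"])))
    mediators = [MediatorSpec(m["name"], _p(m["gwas"]), _p(m["ld"]))
                 for m in raw.get("mediators", [])]
    out = raw["outcome"]
    cfg = RunConfig(
        exposures=exposures,
        outcome_name=out["name"], outcome_gwas=_p(out["gwas"]),
        mediators=mediators,
        blocklist=_p(raw["blocklist"]) if raw.get("blocklist") else None,
        output_dir=_p(raw.get("output_dir", "results")),
        **{k: raw[k] for k in (
            "seed", "p_exposure", "p_mediator", "eaf_min", "r2",
            "r2_fallback", "min_snps", "clump_kb", "n_boot", "n_sim",
            "estimator_mode", "palindrome_policy", "overlap_policy",
            "m_exposures", "m_mediators") if k in raw},
    )
    for spec in cfg.exposures:
        for p in (spec.gwas, spec.ld):
            if not Path(p).exists():
                raise FileNotFoundError(f"exposure {spec.name}: {p}")
    if not Path(cfg.outcome_gwas).exists():
        raise FileNotFoundError(f"outcome gwas: {cfg.outcome_gwas}")
    return cfg


def select_drug_target_instruments(
        table: GwasTable, region: GeneRegion, ld: LdMatrix,
        params: ClumpParams = DRUG_TARGET_PRESET, eaf_min: float = 0.01,
        blocklist: pd.DataFrame | None = None,
) -> tuple[instruments.InstrumentSet, GwasTable]:
    """Full drug-target instrument selection: cis window + significance +
    EAF filter, greedy adaptive clumping, confounder exclusion, F stats."""
    cis = instruments.select_cis_snps(table, region,
                                      p_threshold=params.p_threshold,
                                      eaf_min=eaf_min)
    if len(cis) == 0:
        return instruments.InstrumentSet(snp_ids=[]), cis
    inst = instruments.clump(cis, ld, params)
    if blocklist is not None:
        inst = instruments.exclude_confounder_snps(inst, blocklist)
    return inst, table.restrict(inst.snp_ids)


def select_pqtl_instruments(
        table: GwasTable, ld: LdMatrix,
        params: ClumpParams = PQTL_PRESET, eaf_min: float = 0.01,
) -> tuple[instruments.InstrumentSet, GwasTable]:
    """Mediator (pQTL) instrument selection: genome-wide significance
    filter at the pQTL threshold plus stringent clumping; no cis window."""
    df = table.df
    keep = (df["pval"] < params.p_threshold) & \
        (df["eaf"].isna() | (df["eaf"] > eaf_min))
    cand = GwasTable(df.loc[keep].reset_index(drop=True), table.trait)
    if len(cand) == 0:
        return instruments.InstrumentSet(snp_ids=[]), cand
    inst = instruments.clump(cand, ld, params)
    return inst, table.restrict(inst.snp_ids)


def _mr_battery(hset: HarmonizedSet, cfg: RunConfig, label: dict,
                results: list, het: list, loo_rows: list,
                presso_rows: list, seed: int) -> estimators.MrResult:
    """All estimators + sensitivity diagnostics for one harmonized pair."""
    J = hset.n_snps
    headline = estimators.ivw(hset, mode=cfg.estimator_mode)
    results.append({**label, **headline.to_row()})
    if J >= 3:
        egg = estimators.egger(hset)
        results.append({**label, **egg.to_row()})
        wm = estimators.weighted_median(hset, n_boot=cfg.n_boot, seed=seed)
        results.append({**label, **wm.to_row()})
        for basis in ("ivw", "egger"):
            q = sensitivity.cochran_q(hset, basis=basis)
            het.append({**label, "basis": basis, "Q": q.Q, "df": q.df,
                        "pval": q.pval})
        loo = sensitivity.leave_one_out(hset)
        for row in loo.rows.to_dict("records"):
            loo_rows.append({**label, **row})
    if J >= 4:
        rerun = sensitivity.presso_rerun(hset, n_sim=cfg.n_sim, seed=seed)
        for pass_name, pres in (("first", rerun.first_pass),
                                ("second", rerun.second_pass)):
            if pres is None:
                continue
            presso_rows.append({
                **label, "pass": pass_name,
                "global_rss": pres.global_rss_obs,
                "global_pval": pres.global_pval,
                "outliers": ",".join(pres.outlier_ids),
                "distortion_pval": pres.distortion_pval,
                "beta_before": pres.estimate_before.beta,
                "beta_after": (pres.estimate_after.beta
                               if pres.estimate_after else None),
            })
    return headline


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full study described by ``cfg``; returns a summary dict.

    Output files: ``mr_results.tsv`` (all estimators, all pairs),
    ``heterogeneity.tsv``, ``leave_one_out.tsv``, ``presso.tsv``,
    ``mediation.tsv``, ``families.tsv``, and ``run_manifest.json``.
    """
    rng_seq = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             rng_seq.spawn(2 + len(cfg.exposures) * (1 + len(cfg.mediators))
                           + len(cfg.mediators))]
    seed_iter = iter(seeds)

    outcome = read_gwas(cfg.outcome_gwas,
                        trait_meta=gwas_io.TraitMeta(cfg.outcome_name,
                                                     "binary", "log_or"))
    blocklist = (instruments.read_blocklist(cfg.blocklist)
                 if cfg.blocklist else None)

    results: list[dict] = []
    het: list[dict] = []
    loo_rows: list[dict] = []
    presso_rows: list[dict] = []
    mediation_rows: list[dict] = []
    family_rows: list[dict] = []

    exposure_state: dict[str, dict] = {}
    for spec in cfg.exposures:
        label = {"exposure": spec.name, "outcome": cfg.outcome_name}
        table = read_gwas(spec.gwas)
        ld = instruments.read_ld_matrix(spec.ld)
        inst, inst_table = select_drug_target_instruments(
            table, spec.region, ld, cfg.drug_target_params(),
            eaf_min=cfg.eaf_min, blocklist=blocklist)
        logger.info("%s: %d instruments (mean F %.1f, r2<%g)", spec.name,
                    len(inst), inst.mean_f, inst.r2_applied)
        if len(inst) == 0:
            logger.warning("%s: no instruments; skipped", spec.name)
            exposure_state[spec.name] = {"skipped": True}
            continue
        hset = gwas_io.harmonize(inst_table, outcome,
                                 palindrome_policy=cfg.palindrome_policy)
        headline = _mr_battery(hset, cfg, label, results, het, loo_rows,
                               presso_rows, next(seed_iter))
        exposure_state[spec.name] = {
            "skipped": False, "instruments": inst, "table": inst_table,
            "headline": headline, "mean_f": inst.mean_f,
        }

    tested = [n for n, s in exposure_state.items() if not s["skipped"]]
    fam_exp = mediation.bonferroni_family(
        [exposure_state[n]["headline"].pval for n in tested],
        m=cfg.m_exposures or len(cfg.exposures),
        labels=tested, name="exposures")
    family_rows += [{"family": "exposures", "m": fam_exp.m,
                     "threshold": fam_exp.threshold, **row}
                    for row in fam_exp.table.to_dict("records")]

    for exp_name in fam_exp.significant:
        state = exposure_state[exp_name]
        inst_table: GwasTable = state["table"]
        alpha: estimators.MrResult = state["headline"]

        beta1_by_mediator: dict[str, estimators.MrResult] = {}
        for med in cfg.mediators:
            med_table = read_gwas(med.gwas)
            try:
                hset1 = gwas_io.harmonize(inst_table, med_table,
                                          palindrome_policy=cfg.palindrome_policy)
            except gwas_io.GwasIOError as exc:
                logger.warning("beta1 %s->%s: %s", exp_name, med.name, exc)
                continue
            b1 = estimators.ivw(hset1, mode=cfg.estimator_mode)
            results.append({"exposure": exp_name, "outcome": med.name,
                            **b1.to_row()})
            beta1_by_mediator[med.name] = b1
        if not beta1_by_mediator:
            continue
        fam_med = mediation.bonferroni_family(
            [r.pval for r in beta1_by_mediator.values()],
            m=cfg.m_mediators or len(cfg.mediators),
            labels=list(beta1_by_mediator), name=f"mediators[{exp_name}]")
        family_rows += [{"family": f"mediators[{exp_name}]",
                         "m": fam_med.m, "threshold": fam_med.threshold,
                         **row} for row in fam_med.table.to_dict("records")]

        for med in cfg.mediators:
            if med.name not in fam_med.significant:
                continue
            med_table = read_gwas(med.gwas)
            med_ld = instruments.read_ld_matrix(med.ld)
            pq_inst, pq_table = select_pqtl_instruments(
                med_table, med_ld, cfg.pqtl_params(), eaf_min=cfg.eaf_min)
            if len(pq_inst) == 0:
                logger.warning("%s: no pQTL instruments", med.name)
                continue
            try:
                hset2 = gwas_io.harmonize(pq_table, outcome,
                                          palindrome_policy=cfg.palindrome_policy)
            except gwas_io.GwasIOError as exc:
                logger.warning("beta2 %s->%s: %s", med.name,
                               cfg.outcome_name, exc)
                continue
            b1 = beta1_by_mediator[med.name]
            b2 = _beta2(hset2, inst_table, cfg)
            if b2 is None:
                logger.warning("%s: beta2 non-estimable after overlap "
                               "exclusion", med.name)
                continue
            results.append({"exposure": med.name,
                            "outcome": cfg.outcome_name, **b2.to_row()})
            med_res = mediation.mediate(alpha.beta, alpha.se,
                                        b1.beta, b1.se, b2.beta, b2.se)
            mediation_rows.append({
                "exposure": exp_name, "mediator": med.name,
                "outcome": cfg.outcome_name, **med_res.to_row()})

    tables = {
        "mr_results": pd.DataFrame(results),
        "heterogeneity": pd.DataFrame(het),
        "leave_one_out": pd.DataFrame(loo_rows),
        "presso": pd.DataFrame(presso_rows),
        "mediation": pd.DataFrame(mediation_rows),
        "families": pd.DataFrame(family_rows),
    }
    gwas_io.write_results(tables, cfg.output_dir, manifest_extra={
        "seed": cfg.seed,
        "thresholds": {"p_exposure": cfg.p_exposure,
                       "p_mediator": cfg.p_mediator,
                       "eaf_min": cfg.eaf_min, "r2": cfg.r2,
                       "r2_fallback": cfg.r2_fallback,
                       "min_snps": cfg.min_snps, "clump_kb": cfg.clump_kb},
        "n_boot": cfg.n_boot, "n_sim": cfg.n_sim,
    })
    return {"tables": tables, "exposure_family": fam_exp,
            "output_dir": cfg.output_dir}


def _beta2(hset2: HarmonizedSet, inst_table: GwasTable,
           cfg: RunConfig) -> estimators.MrResult | None:
    """Mediator→outcome effect with the overlap policy applied."""
    if cfg.overlap_policy == "drop-shared":
        shared = set(inst_table.df["snp_id"].astype(str))
        keep = ~np.isin(hset2.snp_id.astype(str), list(shared))
        if not keep.any():
            return None
        hset2 = hset2.subset(keep)
    return estimators.ivw(hset2, mode=cfg.estimator_mode)
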