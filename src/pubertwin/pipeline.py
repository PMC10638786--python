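"""End-to-end orchestration: simulate -> phenotypes -> EWAS -> meta ->
candidate follow-up (twin models, sex differences, discordant pairs,
meQTL-heritability correlation), with fixed seeds and a reproducible report.

Candidate CpGs for every follow-up stage are those reaching the suggestive
meta-analysis tier (p <= 1e-5) in any model, mirroring the follow-up gating
of the analysis design. Every output file embeds the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import discordant as disc
from . import ewas as ew
from . import meqtl as mq
from . import meta as mt
from . import phenotypes as ph
from . import sexdiff as sx
from . import twin as tw
from .synthetic import (CohortConfig, SnpConfig, TwinCohort, generate_cohort,
                        generate_methylation, generate_meqtl_table,
                        generate_questionnaires, make_cpg_specs)

__all__ = ["PipelineConfig", "run_full_analysis", "render_report"]

log = logging.getLogger("pubertwin")

DEFAULT_MODELS = ("pds12:all", "pds12:M", "pds12:F",
                  "pds14:M", "pds14:F", "pa:M", "pa:F")


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_null_cpgs: int = 200
    n_causal_cpgs: int = 5
    causal_beta: float = 0.02
    models: tuple = DEFAULT_MODELS
    suggestive_p: float = mt.SUGGESTIVE_P
    strict_p: float = mt.STRICT_P
    het_q_bh: float = mt.HET_Q_BH
    effect_filter: float = mt.EFFECT_FILTER
    sd_filter: float = 0.05
    followup_alpha: float = 0.01
    t_column: str = "t"            # or "t_moderated"
    meqtl_snps_per_cpg: int = 30

    def validate(self) -> None:
        self.cohort.validate()
        for nm in ("suggestive_p", "strict_p", "het_q_bh", "effect_filter",
                   "sd_filter", "followup_alpha"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        for m in self.models:
            exp, _, sexes = m.partition(":")
            if exp not in ("pds12", "pds14", "pa") or \
                    sexes not in ("all", "M", "F"):
                raise ValueError(f"unknown model spec {m!r}")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        models = tuple(raw.pop("models", DEFAULT_MODELS))
        return cls(cohort=cohort, models=models, **raw)


class StageError(RuntimeError):
    pass


def _subset_cohort(cohort: TwinCohort, ids) -> TwinCohort:
    keep = cohort.samples[cohort.samples.individual_id.isin(set(ids))]
    return TwinCohort(samples=keep.reset_index(drop=True))


def _build_design(cohort: TwinCohort, exposure: pd.Series, exposure_name: str,
                  include_sex: bool, include_cohort: bool) -> ew.EwasDesign:
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", UserWarning)   # constant-column drops
        cov = ph.prepare_covariates(cohort, include_sex=include_sex,
                                    include_cohort=include_cohort)
    X = pd.DataFrame({"intercept": 1.0}, index=cov.index)
    X[exposure_name] = exposure.reindex(cov.index).values
    X = pd.concat([X, cov], axis=1)
    fam = cohort.samples.set_index("individual_id").family_id
    return ew.EwasDesign(X=X, family=fam.reindex(X.index).values,
                        exposure=exposure_name)


def _exposures(cohort, pds_scores, pa_coded) -> dict[str, pd.Series]:
    out = {}
    for wave in (12, 14):
        s = pds_scores[pds_scores.wave == wave].set_index("individual_id").pds
        out[f"pds{wave}"] = s
    out["pa"] = pa_coded.set_index("individual_id").pa
    return out


def _pairs_for_cpg(cohort: TwinCohort, methylation, cpg_id: str,
                   exposure: pd.Series | None = None) -> pd.DataFrame:
    """Pair table (y1, y2, zygosity, age, sex, platform, x1/x2) for one CpG."""
    panel = methylation.panel[cpg_id]
    vals = methylation.values.loc[cpg_id]
    s = cohort.samples
    if panel != "both":
        s = s[s.platform == panel]
    p = TwinCohort(samples=s.reset_index(drop=True)).pairs
    out = pd.DataFrame({
        "family_id": p.family_id, "zygosity": p.zygosity,
        "platform": p.platform,
        "y1": vals.reindex(p.id1).values, "y2": vals.reindex(p.id2).values,
        "sex1": p.sex1, "sex2": p.sex2,
    })
    meta_s = cohort.samples.set_index("individual_id")
    out["age1"] = meta_s.age_at_sampling.reindex(p.id1).values
    out["age2"] = meta_s.age_at_sampling.reindex(p.id2).values
    if exposure is not None:
        out["x1"] = exposure.reindex(p.id1).values
        out["x2"] = exposure.reindex(p.id2).values
    return out


def run_full_analysis(config: PipelineConfig, outdir=None) -> dict:
    """Execute every stage; returns the results bundle (dict of DataFrames).

    Deterministic given (config, config.seed); any stage failure raises
    :class:`StageError` naming the stage.
    """
    config.validate()
    seed = int(config.seed)
    bundle: dict = {"config_hash": config.hash(), "seed": seed}

    def stage(name):
        log.info(json.dumps({"stage": name, "seed": seed}))

    try:
        stage("simulate")
        cohort = generate_cohort(config.cohort, seed)
        specs = make_cpg_specs(config.n_null_cpgs, config.n_causal_cpgs,
                               causal_beta=config.causal_beta, seed=seed)
        methylation, truth = generate_methylation(cohort, specs,
                                                  truth_out=True,
                                                  seed=seed + 1)
        pds_items, pa_reports = generate_questionnaires(
            cohort, seed=seed + 2,
            female_shift=config.cohort.phenotype_female_shift)
    except Exception as e:
        raise StageError(f"stage simulate failed: {e}") from e

    try:
        stage("phenotypes")
        pds_scores, n_pds_excl = ph.score_pds_table(pds_items)
        pa_coded, n_pa_excl = ph.code_pubertal_age_table(pa_reports)
        exposures = _exposures(cohort, pds_scores, pa_coded)
    except Exception as e:
        raise StageError(f"stage phenotypes failed: {e}") from e

    ewas_results: dict[str, dict[str, pd.DataFrame]] = {}
    meta_results: dict[str, pd.DataFrame] = {}
    for model in config.models:
        expname, _, sexes = model.partition(":")
        exposure = exposures[expname].dropna()
        try:
            stage(f"ewas:{model}")
            per_platform = {}
            for platform in ("P450K", "PEPIC"):
                Y = methylation.for_platform(cohort, platform)
                ids = [i for i in Y.columns if i in exposure.index]
                if sexes != "all":
                    sex_map = cohort.samples.set_index("individual_id").sex
                    ids = [i for i in ids if sex_map[i] == sexes]
                sub = _subset_cohort(cohort, ids)
                Ysub = Y.loc[:, list(sub.samples.individual_id)]
                design = _build_design(
                    sub, exposure, expname,
                    include_sex=(sexes == "all"),
                    include_cohort=(expname == "pa"))
                res = ew.run_ewas(Ysub, design)
                if len(res) >= 10:
                    res = ew.moderate_statistics(res)
                per_platform[platform] = res
            ewas_results[model] = per_platform
        except Exception as e:
            raise StageError(f"stage ewas ({model}) failed: {e}") from e
        try:
            stage(f"meta:{model}")
            meta_results[model] = mt.run_meta_pipeline(
                per_platform["P450K"], per_platform["PEPIC"],
                t_column=config.t_column)
        except Exception as e:
            raise StageError(f"stage meta ({model}) failed: {e}") from e
    bundle["ewas"] = ewas_results
    bundle["meta"] = meta_results

    # candidate set: suggestive tier in any model (best model per CpG)
    stage("candidates")
    cand_rows = []
    for model, res in meta_results.items():
        hits = res[res.tier != "none"]
        for cpg, row in hits.iterrows():
            cand_rows.append({"cpg_id": cpg, "model": model,
                              "p_value": row.p_value, "r_meta": row.r_meta,
                              "tier": row.tier})
    candidates = (pd.DataFrame(cand_rows,
                               columns=["cpg_id", "model", "p_value",
                                        "r_meta", "tier"])
                  .sort_values("p_value")
                  .drop_duplicates("cpg_id"))
    bundle["candidates"] = candidates.reset_index(drop=True)
    if candidates.empty:
        log.info(json.dumps({"stage": "followup", "note": "no candidates"}))
        for key in ("twin", "sexdiff", "discordant"):
            bundle[key] = pd.DataFrame()
        bundle["meqtl"] = {"counts": pd.DataFrame(),
                           "rho": float("nan"), "rho_p": float("nan"),
                           "note": "no candidates"}
        if outdir is not None:
            _write_bundle(bundle, config, outdir)
        return bundle

    try:
        stage("twin")
        twin_rows = []
        for _, crow in candidates.iterrows():
            pairs = _pairs_for_cpg(cohort, methylation, crow.cpg_id)
            eligible, reasons = tw.check_candidate(
                pairs, sd_threshold=config.sd_filter,
                alpha=config.followup_alpha)
            rec = {"cpg_id": crow.cpg_id, "eligible": eligible,
                   "reasons": "; ".join(reasons)}
            if eligible:
                best = tw.select_best_model(pairs)
                rec.update(best_model=best.model, a2=best.a2, c2=best.c2,
                           d2=best.d2, e2=best.e2, r_mz=best.r_mz,
                           r_dz=best.r_dz, loglik=best.loglik)
            twin_rows.append(rec)
        twin_table = pd.DataFrame(twin_rows)
        bundle["twin"] = twin_table
    except Exception as e:
        raise StageError(f"stage twin failed: {e}") from e

    try:
        stage("sexdiff")
        m_tests = len(candidates)
        sex_rows = []
        sex_map = cohort.samples.set_index("individual_id").sex
        modelled = twin_table[twin_table.eligible] \
            if "eligible" in twin_table else twin_table.iloc[:0]
        for _, crow in candidates.iterrows():
            vals = methylation.values.loc[crow.cpg_id]
            wt = sx.wilcoxon_sex_test(vals.values,
                                      sex_map.reindex(vals.index).values,
                                      m_tests=m_tests)
            rec = {"cpg_id": crow.cpg_id, "wilcoxon_p": wt.p_raw,
                   "wilcoxon_p_bonf": wt.p_bonferroni,
                   "differentially_methylated": wt.significant,
                   "sex_differences": ""}
            if crow.cpg_id in set(modelled.cpg_id):
                pairs = _pairs_for_cpg(cohort, methylation, crow.cpg_id)
                free = sx.fit_sex_limitation(pairs, rg="free")
                equated = sx.fit_sex_limitation(
                    pairs, equate=("mean", "a", "e"), rg=0.5)
                omni = sx.omnibus_sex_test(free, equated,
                                           m_tests=len(modelled))
                rec["omnibus_p_adj"] = omni.p_adjusted
                labels = []
                if omni.significant:
                    ptests = sx.parameter_sex_tests(
                        free, ["mean", "a", "e", "total_variance", "rg"],
                        m_tests=len(modelled))
                    names = {"mean": "Mean structure",
                             "a": "Unstandardised genetic variance",
                             "e": "Unstandardised environmental variance",
                             "total_variance": "Total phenotypic variance",
                             "rg": "Qualitative (rg)"}
                    labels = [names[k] for k, v in ptests.items()
                              if v.significant]
                rec["sex_differences"] = ", ".join(labels) or "None"
            sex_rows.append(rec)
        bundle["sexdiff"] = pd.DataFrame(sex_rows)
    except Exception as e:
        raise StageError(f"stage sexdiff failed: {e}") from e

    try:
        stage("discordant")
        disc_rows = []
        for _, crow in candidates.iterrows():
            expname = crow.model.partition(":")[0]
            pairs = _pairs_for_cpg(cohort, methylation, crow.cpg_id,
                                   exposure=exposures[expname].dropna())
            result = disc.run_discordance(pairs, covariates=("age", "sex",
                                                             "platform"),
                                          cpg_id=crow.cpg_id)
            pooled, mz = result["pooled"], result["mz_only"]
            disc_rows.append({
                "cpg_id": crow.cpg_id,
                "beta_between": pooled.beta_between,
                "p_between": pooled.p_between,
                "beta_within": pooled.beta_within,
                "p_within": pooled.p_within,
                "beta_within_mz": mz.beta_within if mz else np.nan,
                "p_within_mz": mz.p_within if mz else np.nan,
                "classified": result["classified"],
                "reason": result["reason"]})
        bundle["discordant"] = pd.DataFrame(disc_rows)
    except Exception as e:
        raise StageError(f"stage discordant failed: {e}") from e

    try:
        stage("meqtl")
        modelled = bundle["twin"]
        modelled = modelled[modelled.eligible] if len(modelled) else modelled
        causal = {}
        spec_by_id = truth.specs.set_index("cpg_id")
        for cpg in candidates.cpg_id:
            a2 = float(spec_by_id.loc[cpg, "a2"])
            causal[cpg] = int(round(8 * a2))
        snp_cfg = SnpConfig(n_snps_per_cpg=config.meqtl_snps_per_cpg,
                            causal=causal)
        cand_specs = [s for s in specs if s.cpg_id in set(candidates.cpg_id)]
        table = generate_meqtl_table(cohort, cand_specs, snp_cfg,
                                     seed=seed + 3)
        counts = mq.count_meqtls(table, candidates.cpg_id)
        rho = rho_p = float("nan")
        if len(modelled) >= 3 and "a2" in modelled:
            merged = modelled.set_index("cpg_id").join(counts)
            rho, rho_p = mq.spearman_correlation(merged.n_meqtl.values,
                                                 merged.a2.values)
        bundle["meqtl"] = {"counts": counts, "rho": rho, "rho_p": rho_p,
                           "table": table}
    except Exception as e:
        raise StageError(f"stage meqtl failed: {e}") from e

    if outdir is not None:
        _write_bundle(bundle, config, outdir)
    return bundle


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str, seed: int,
               **kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", float_format="%.6g", **kw)


def _write_bundle(bundle: dict, config: PipelineConfig, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    h, s = bundle["config_hash"], bundle["seed"]
    for model, res in bundle["meta"].items():
        name = model.replace(":", "_")
        _write_tsv(res, out / f"{name}.meta.tsv", h, s)
    for model, platforms in bundle["ewas"].items():
        name = model.replace(":", "_")
        for platform, res in platforms.items():
            suffix = "450K" if platform == "P450K" else "EPIC"
            _write_tsv(res, out / f"{name}_{suffix}.ewas.tsv", h, s)
    for key in ("candidates", "twin", "sexdiff", "discordant"):
        _write_tsv(pd.DataFrame(bundle[key]), out / f"{key}.tsv", h, s,
                   index=False)
    meqtl = bundle["meqtl"]
    if isinstance(meqtl.get("counts"), pd.DataFrame):
        _write_tsv(meqtl["counts"], out / "meqtl_counts.tsv", h, s)
    summary = pd.DataFrame([{"rho": meqtl.get("rho"),
                             "rho_p": meqtl.get("rho_p")}])
    _write_tsv(summary, out / "meqtl_correlation.tsv", h, s, index=False)


def qq_data(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot, smallest p last."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.clip(p, 1e-300, 1.0))
    return pd.DataFrame({"expected": expected[::-1], "observed": observed[::-1]})


def render_report(bundle: dict, outdir) -> dict:
    """Summary tables and QQ/Manhattan-style plot data (+ figures).

    The plot data are written as TSV so downstream checks assert on numbers;
    figures are a convenience rendering of the same data.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    h, s = bundle["config_hash"], bundle["seed"]
    written = {}
    for model, res in bundle["meta"].items():
        name = model.replace(":", "_")
        qq = qq_data(res.p_value.values)
        _write_tsv(qq, out / f"{name}.qq.tsv", h, s, index=False)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(qq.expected, qq.observed, s=4)
        lim = max(qq.expected.max(), qq.observed.max()) * 1.05
        ax.plot([0, lim], [0, lim], lw=1, color="grey")
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        ax.set_title(name)
        fig.savefig(out / f"{name}.qq.png", dpi=100)
        plt.close(fig)
        written[model] = qq
    cand = pd.DataFrame(bundle["candidates"])
    _write_tsv(cand, out / "candidate_table.tsv", h, s, index=False)
    if len(bundle.get("twin", [])):
        _write_tsv(pd.DataFrame(bundle["twin"]), out / "twin_table.tsv",
                   h, s, index=False)
    return written
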