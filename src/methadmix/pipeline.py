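"""Config-driven end-to-end runs.

One call simulates a cohort, applies QC, estimates cell composition and
global ancestry, summarises global structure, runs the ethnicity and
ancestry EWAS, classifies ethnicity hits as ancestry-explained vs residual,
partitions variance, mediates the ethnicity->PC associations through
ancestry, admixture-maps the fixed-difference locus, and tests exposure-set
enrichment — writing a JSON + markdown report.  Each stochastic stage draws
from an independent substream of the master seed, so a rerun with the same
config is byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from ._utils import derived_rng
from .ancestry import dosage_cube, global_from_local, interpolate_at
from .data import estimate_cell_proportions, filter_probes, qc_genotypes
from .decomp import Mediation, joint_partition, local_global_partition
from .ewas import (
    AncestryScan,
    EthnicityScan,
    block_f_scan,
    bonferroni,
    build_design,
    cis_scan,
    classify_adjustment,
    enrichment,
    ethnicity_block,
    nonlinearity_test,
    stability_flags_scan,
)
from .simulate import EthnicityProfile, SimulationConfig, ethnicity_profile, simulate_study
from .structure import associate_pc, genotype_pca, pcoa

__all__ = ["RunConfig", "run_pipeline", "downsample_rerun", "site_sensitivity", "PipelineResult"]

DEFAULT_COVARIATES = ["case", "age", "sex", "granulocytes", "lymphocytes", "plate", "position"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    seed: int = 0
    group_sizes: dict = field(default_factory=dict)  # e.g. {"Mexican": 276, ...}
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    p_cut: float = 0.01
    max_fail_frac: float = 0.01
    miss_cut: float = 0.05
    hwe_cut: float = 1e-6
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    alpha: float = 0.05
    n_pcs: int = 10
    fine_pcs: tuple = (3, 10)  # genotype PCs used as fine-structure covariates
    mediation_sims: int = 1000
    max_partition_cpgs: int = 500
    outdir: str | None = None

    def simulation_config(self) -> SimulationConfig:
        kwargs = dict(self.sim)
        if self.group_sizes:
            kwargs["profiles"] = [ethnicity_profile(g, n) for g, n in self.group_sizes.items()]
        elif "profiles" in kwargs and kwargs["profiles"] and isinstance(kwargs["profiles"][0], dict):
            kwargs["profiles"] = [
                EthnicityProfile(p["label"], np.asarray(p["alpha"], float), int(p["n"]))
                for p in kwargs["profiles"]
            ]
        return SimulationConfig(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fine_pcs" in raw:
            raw["fine_pcs"] = tuple(raw["fine_pcs"])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: RunConfig
    report: dict
    study: object = None
    scans: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.report, sort_keys=True, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _median_iqr(x) -> dict:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        return {"median": None, "q25": None, "q75": None, "n": 0}
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "q25": float(q25), "q75": float(q75), "n": int(len(x))}


def _stage(log: list, name: str, **info):
    entry = {"stage": name, **info}
    log.append(entry)
    return entry


def run_pipeline(config: RunConfig) -> PipelineResult:
    log: list[dict] = []
    report: dict = {"seed": config.seed, "log": log}
    try:
        return _run_pipeline(config, report, log)
    except Exception as err:  # annotate with the failing stage, then re-raise
        stage = log[-1]["stage"] if log else "setup"
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def _run_pipeline(config: RunConfig, report: dict, log: list) -> PipelineResult:
    # --- simulate -----------------------------------------------------------
    _stage(log, "simulate", seed=config.seed)
    study = simulate_study(config.simulation_config(), seed=config.seed)
    log[-1].update(n_samples=len(study.samples), n_cpgs=len(study.meth.probes), n_snps=study.panel.n_snps)

    # --- QC -----------------------------------------------------------------
    _stage(log, "qc", p_cut=config.p_cut, max_fail_frac=config.max_fail_frac, miss_cut=config.miss_cut, hwe_cut=config.hwe_cut)
    meth = filter_probes(study.meth, config.p_cut, config.max_fail_frac)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        geno, qc_log = qc_genotypes(
            study.genotypes, study.samples["ethnicity"], config.miss_cut, config.hwe_cut
        )
    log[-1].update(probes_kept=len(meth.probes), probes_removed=len(study.meth.probes) - len(meth.probes), snps_removed=len(qc_log))
    report["qc"] = {
        "probes_kept": len(meth.probes),
        "probes_removed": int(len(study.meth.probes) - len(meth.probes)),
        "snps_removed": int(len(qc_log)),
    }

    # --- cell composition + global ancestry --------------------------------
    _stage(log, "cells")
    cell_props, _ = estimate_cell_proportions(study.cell_probe_meth, study.cell_reference)
    samples = study.samples.join(cell_props)
    _stage(log, "global_ancestry")
    q_hat = global_from_local(study.local)
    q_hat.index = samples.index

    meth_m = meth.to_m()
    covs = [c for c in config.covariates if c in samples.columns]

    # --- structure ----------------------------------------------------------
    _stage(log, "structure", n_pcs=config.n_pcs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pcs = pcoa(meth_m.values, k=config.n_pcs)
        gpcs, _, _ = genotype_pca(geno, k=max(config.n_pcs, config.fine_pcs[1]))
    cov_df = samples[covs]
    pc_assoc = {}
    for pc in pcs.coordinates.columns:
        eth_a = associate_pc(pcs.coordinates[pc], samples["ethnicity"], cov_df)
        anc_a = associate_pc(pcs.coordinates[pc], q_hat, cov_df)
        pc_assoc[pc] = {"p_ethnicity": eth_a.p, "p_ancestry": anc_a.p}
    report["pc_associations"] = pc_assoc

    # --- mediation of ethnicity->PC associations ----------------------------
    _stage(log, "pc_mediation", n_sims=config.mediation_sims)
    med_summaries = {}
    counts = samples["ethnicity"].value_counts()
    contrast = tuple(counts.index[:2][::-1]) if len(counts) >= 2 else None
    for pc, assoc in pc_assoc.items():
        if assoc["p_ethnicity"] is not None and assoc["p_ethnicity"] < 0.05:
            res = Mediation(
                pcs.coordinates[pc], samples["ethnicity"], q_hat["NAM"], cov_df, contrast=contrast
            ).fit(n_sims=config.mediation_sims, seed=int(derived_rng(config.seed, "mediation").integers(2**31)))
            med_summaries[pc] = {
                "prop_mediated": res.prop_mediated,
                "ci": list(res.ci["prop_mediated"]),
                "p_acme": res.p_acme,
            }
    report["pc_mediation"] = med_summaries

    # --- EWAS ---------------------------------------------------------------
    _stage(log, "ewas", alpha=config.alpha)
    eth_scan = EthnicityScan(meth_m, samples, covs, config.alpha).fit()
    adj_scan = EthnicityScan(meth_m, samples, covs, config.alpha, ancestry=q_hat).fit()
    anc_scan = AncestryScan(meth_m, samples, q_hat, covs, config.alpha).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        unstable = stability_flags_scan(meth_m, samples, q_hat, covs)
    classification = classify_adjustment(eth_scan, adj_scan, unstable)
    cls_counts = {k: int(v) for k, v in classification.attrs["counts"].items()}
    report["ewas"] = {
        "threshold": eth_scan.threshold,
        "ethnicity_hits": eth_scan.n_hits,
        "ancestry_hits": anc_scan.n_hits,
        "classification": cls_counts,
        "driven_by": anc_scan.table.loc[anc_scan.hits, "driven_by"].value_counts().to_dict()
        if anc_scan.n_hits
        else {},
    }

    # --- non-linearity screen on residual-ethnicity CpGs --------------------
    _stage(log, "nonlinearity")
    remains = classification.index[classification["classification"] == "remains"]
    nl_counts = {"poly": 0, "spline": 0, "tested": 0}
    cov_design = samples[covs]
    for cpg in remains[: config.max_partition_cpgs]:
        y = meth_m.values[cpg]
        nl_counts["tested"] += 1
        for method in ("poly", "spline"):
            try:
                r = nonlinearity_test(y, q_hat["NAM"], cov_design, method, samples["ethnicity"])
            except ValueError:
                continue
            if r.p_nonlinear < 0.05:
                nl_counts[method] += 1
    report["nonlinearity"] = nl_counts

    # --- fine-scale structure adjustment ------------------------------------
    _stage(log, "fine_structure", pcs=list(config.fine_pcs))
    lo, hi = config.fine_pcs
    fine = gpcs[[f"gPC{j}" for j in range(lo, hi + 1) if f"gPC{j}" in gpcs.columns]]
    fine_scan = EthnicityScan(meth_m, samples, covs, config.alpha, ancestry=q_hat, extra=fine).fit()
    still = [c for c in remains if fine_scan.table.loc[c, "p"] < eth_scan.threshold]
    report["fine_structure"] = {
        "remains_after_fine_pcs": len(still),
        "explained_by_fine_pcs": int(len(remains) - len(still)),
    }

    # --- variance partition (Table-2-style, over discovery hits) ------------
    _stage(log, "partition")
    hit_cpgs = list(eth_scan.hits[: config.max_partition_cpgs])
    parts = []
    for cpg in hit_cpgs:
        vp = joint_partition(meth_m.values[cpg], samples["ethnicity"], q_hat, cov_design)
        if vp.stable:
            parts.append(
                {
                    "cpg": cpg,
                    "joint": vp.pve_joint,
                    "ethnicity": vp.pve_blocks["ethnicity"],
                    "ancestry": vp.pve_blocks["ancestry"],
                    "ancestry_share": vp.shares["ancestry"],
                }
            )
    part_df = pd.DataFrame(parts)
    report["variance_partition"] = {
        k: _median_iqr(part_df[k]) if len(part_df) else _median_iqr([])
        for k in ("joint", "ethnicity", "ancestry", "ancestry_share")
    }

    # --- local vs global ancestry at ancestry hits ---------------------------
    _stage(log, "local_global")
    cube = dosage_cube(study.local, study.panel.positions_m)
    gmap = study.panel.genetic_map
    lg = []
    for cpg in list(anc_scan.hits[: config.max_partition_cpgs]):
        pos_m = float(gmap.bp_to_morgans(meth_m.manifest.loc[cpg, "pos"]))
        local_dos = pd.DataFrame(
            interpolate_at(cube, study.panel.positions_m, pos_m),
            index=samples.index,
            columns=list(study.local.labels),
        )
        try:
            vp = local_global_partition(meth_m.values[cpg], local_dos, q_hat, cov_design)
        except ValueError:
            continue
        if vp.stable:
            lg.append({"cpg": cpg, "local": vp.pve_blocks["local"], "local_share": vp.shares["local"]})
    lg_df = pd.DataFrame(lg)
    report["local_global"] = {
        "local_pve": _median_iqr(lg_df["local"]) if len(lg_df) else _median_iqr([]),
        "local_share": _median_iqr(lg_df["local_share"]) if len(lg_df) else _median_iqr([]),
    }

    # --- admixture mapping at the fixed-difference locus ---------------------
    duffy = None
    if "cg_duffy_like" in meth_m.probes and "rs_duffy_like" in geno.snps:
        _stage(log, "admixture_map", locus="cg_duffy_like")
        y = meth_m.values["cg_duffy_like"]
        pos_m = float(gmap.bp_to_morgans(meth_m.manifest.loc["cg_duffy_like", "pos"]))
        local_dos = pd.DataFrame(
            interpolate_at(cube, study.panel.positions_m, pos_m),
            index=samples.index,
            columns=list(study.local.labels),
        )
        from .ewas import admixture_map

        amap = admixture_map(y, local_dos, cov_design)
        table = cis_scan(
            y,
            geno,
            float(meth_m.manifest.loc["cg_duffy_like", "pos"]),
            covariates=cov_design,
            local_dosage=local_dos,
        )
        duffy = {
            "afr_effect_per_haplotype": float(amap.effects.get("AFR", np.nan)),
            "afr_fold_change": float(amap.fold_changes().get("AFR", np.nan)),
            "p_omnibus": amap.p_omnibus,
            "best_snp": table.attrs.get("best_snp"),
            "p_local_unconditional": table.attrs.get("p_local_unconditional"),
            "p_local_given_best_snp": table.attrs.get("p_local_given_best"),
        }
    report["admixture_mapping"] = duffy

    # --- enrichment against the exposure-associated candidate set ------------
    _stage(log, "enrichment")
    env_ids = [study.truth.cpg_ids[i] for i in study.truth.env_cpgs]
    candidates = [c for c in env_ids if c in meth_m.probes]
    if candidates:
        enr = enrichment(eth_scan.hits, candidates, meth_m.probes, eth_scan.table["p"])
        report["enrichment"] = {
            "n_candidates": enr.n_candidates,
            "n_nominal": enr.n_nominal,
            "nominal_rate": enr.nominal_rate,
            "binomial_p": enr.binomial_p,
            "hypergeom_p": enr.hypergeom_p,
        }
    else:
        report["enrichment"] = None

    result = PipelineResult(
        config=config,
        report=report,
        study=study,
        scans={"ethnicity": eth_scan, "adjusted": adj_scan, "ancestry": anc_scan, "fine": fine_scan},
        tables={
            "classification": classification,
            "partition": part_df,
            "local_global": lg_df,
            "ancestry": q_hat,
            "pcoa_scores": pcs.coordinates,
            "genotype_pcs": gpcs,
            "cell_proportions": cell_props,
        },
    )
    if config.outdir:
        _write_outputs(result)
    return result


def _write_outputs(result: PipelineResult):
    outdir = Path(result.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(result.to_json())
    (outdir / "report.md").write_text(render_report_md(result.report))
    for name, scan in result.scans.items():
        scan.table.to_csv(outdir / f"scan_{name}.tsv", sep="\t", index_label="cpg", float_format="%.6g")
    for name, table in result.tables.items():
        if len(table):
            table.to_csv(outdir / f"{name}.tsv", sep="\t", float_format="%.6g")
    mio.write_study(result.study, outdir / "data")


def render_report_md(report: dict) -> str:
    lines = ["# methadmix pipeline report", "", f"Master seed: {report['seed']}", ""]
    ew = report.get("ewas", {})
    lines += [
        "## EWAS",
        f"- Bonferroni threshold: {ew.get('threshold'):.3g}" if ew.get("threshold") else "",
        f"- ethnicity-associated CpGs: {ew.get('ethnicity_hits')}",
        f"- ancestry-associated CpGs (ethnicity-adjusted): {ew.get('ancestry_hits')}",
        f"- classification of ethnicity hits: {ew.get('classification')}",
        f"- ancestry hits driven by: {ew.get('driven_by')}",
        "",
        "## Variance partition (median [IQR] over ethnicity hits)",
    ]
    for k, v in report.get("variance_partition", {}).items():
        if v.get("median") is not None:
            lines.append(f"- {k}: {100 * v['median']:.1f}% [{100 * v['q25']:.1f}%, {100 * v['q75']:.1f}%] (n={v['n']})")
    lg = report.get("local_global", {})
    if lg.get("local_share", {}).get("median") is not None:
        ls = lg["local_share"]
        lines += ["", "## Local vs global ancestry", f"- local share of joint ancestry PVE: {100 * ls['median']:.1f}% [{100 * ls['q25']:.1f}%, {100 * ls['q75']:.1f}%]"]
    duffy = report.get("admixture_mapping")
    if duffy:
        lines += [
            "",
            "## Fixed-difference (Duffy-like) locus",
            f"- effect per African haplotype: {duffy['afr_effect_per_haplotype']:.2f} M ({duffy['afr_fold_change']:.2f}-fold)",
            f"- local-ancestry p unconditional: {duffy['p_local_unconditional']:.3g}",
            f"- after conditioning on {duffy['best_snp']}: p = {duffy['p_local_given_best_snp']:.3g}",
        ]
    enr = report.get("enrichment")
    if enr:
        lines += [
            "",
            "## Exposure-set enrichment",
            f"- {enr['n_nominal']}/{enr['n_candidates']} nominal ({100 * enr['nominal_rate']:.1f}%), binomial p={enr['binomial_p']:.3g}",
        ]
    med = report.get("pc_mediation")
    if med:
        lines += ["", "## Mediation of ethnicity–PC associations by NAM ancestry"]
        for pc, m in med.items():
            lines.append(f"- {pc}: proportion mediated {100 * m['prop_mediated']:.0f}% (CI {100 * m['ci'][0]:.0f}–{100 * m['ci'][1]:.0f}%), p={m['p_acme']:.3g}")
    return "\n".join(str(l) for l in lines) + "\n"


# ---------------------------------------------------------------------------
# sensitivity utilities


def downsample_rerun(
    config: RunConfig, n_target: int, seed: int | None = None, study=None
) -> dict:
    """Rerun the ethnicity and ancestry scans on a random subsample without
    replacement (sample-size sensitivity).  Pass ``study`` to reuse an
    already-simulated cohort."""
    if study is None:
        study = simulate_study(config.simulation_config(), seed=config.seed)
    n = len(study.samples)
    if n_target > n:
        raise ValueError(f"n_target {n_target} exceeds cohort size {n}")
    rng = derived_rng(config.seed if seed is None else seed, "downsample")
    keep = study.samples.index[np.sort(rng.choice(n, size=n_target, replace=False))]
    meth = filter_probes(study.meth, config.p_cut, config.max_fail_frac).subset_samples(keep)
    samples = study.samples.loc[keep]
    cell_props, _ = estimate_cell_proportions(study.cell_probe_meth.subset_samples(keep), study.cell_reference)
    samples = samples.join(cell_props)
    q_hat = global_from_local(study.local)
    q_hat.index = study.samples.index
    q_hat = q_hat.loc[keep]
    covs = [c for c in config.covariates if c in samples.columns]
    eth = EthnicityScan(meth, samples, covs, config.alpha).fit()
    anc = AncestryScan(meth, samples, q_hat, covs, config.alpha).fit()
    return {
        "n": int(n_target),
        "ethnicity_hits": eth.n_hits,
        "ancestry_hits": anc.n_hits,
        "threshold": eth.threshold,
        "subsample": list(keep),
    }


def site_sensitivity(
    meth,
    samples: pd.DataFrame,
    site_column: str = "site",
    covariates: list | None = None,
    alpha: float = 0.05,
) -> dict:
    """Per-CpG omnibus test of recruitment site adjusted for ethnicity and
    covariates; counts Bonferroni-significant sites."""
    if site_column not in samples.columns:
        raise ValueError(f"sample sheet has no column {site_column!r}")
    meth_m = meth.to_m()
    samples = samples.loc[meth_m.samples]
    n_sites = samples[site_column].nunique()
    if n_sites < 2:
        raise ValueError("recruitment-site analysis needs at least two sites")
    covs = [c for c in (covariates or DEFAULT_COVARIATES) if c in samples.columns]
    X_red = pd.concat(
        [build_design(meth_m.samples, samples[covs]), ethnicity_block(samples["ethnicity"])], axis=1
    )
    site = pd.get_dummies(samples[site_column], prefix="site", drop_first=True, dtype=float)
    X_full = pd.concat([X_red, site], axis=1)
    Y = meth_m.values.to_numpy()
    F, df1, df2, p = block_f_scan(Y, X_full.to_numpy(float), X_red.to_numpy(float))
    thr = bonferroni(alpha, Y.shape[1])
    return {
        "n_sites": int(n_sites),
        "df1": int(df1),
        "threshold": thr,
        "n_significant": int((p < thr).sum()),
        "p": pd.Series(p, index=meth_m.probes),
    }
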