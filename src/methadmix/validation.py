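"""Canonical validation studies.

Self-contained study designs with known generative truth, used to check
that the pipeline recovers what it should: null calibration of the omnibus
tests, mediation recovery and interval coverage, classification of
ancestry-mediated vs environmental ethnicity effects, and the
fixed-difference (Duffy-like) admixture-mapping chain.  Each takes a seed
and returns plain numbers.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ancestry import dosage_cube, interpolate_at
from .data import MethylationMatrix
from .decomp import mediate
from .ewas import (
    AncestryScan,
    EthnicityScan,
    admixture_map,
    cis_scan,
    classify_adjustment,
    stability_flags_scan,
)
from .simulate import SimulationConfig, ethnicity_profile, simulate_study

__all__ = [
    "null_calibration",
    "run_mediation_recovery",
    "classification_study_config",
    "run_classification_recovery",
    "run_darc_logic",
]


def null_calibration(seed: int, n: int = 200, n_cpgs: int = 2000) -> dict:
    """KS uniformity of the ethnicity omnibus and 2-df ancestry p-values
    under the global null (noise methylation, real group/ancestry
    structure)."""
    rng = np.random.default_rng([seed, 41])
    idx = pd.Index([f"S{i}" for i in range(n)])
    eth = pd.Series(rng.choice(["Mexican", "PuertoRican", "Other", "Mixed"], n), index=idx)
    q = pd.DataFrame(rng.dirichlet([2, 2, 2], size=n), index=idx, columns=["AFR", "EUR", "NAM"])
    meth = MethylationMatrix(
        pd.DataFrame(
            rng.normal(0, 0.45, (n, n_cpgs)), index=idx, columns=[f"cg{j}" for j in range(n_cpgs)]
        ),
        scale="m",
    )
    samples = pd.DataFrame({"ethnicity": eth, "age": rng.normal(12, 2, n)}, index=idx)
    p_eth = EthnicityScan(meth, samples, covariates=["age"]).fit().table["p"]
    p_anc = AncestryScan(meth, samples, q, covariates=["age"]).fit().table["p"]
    return {
        "ks_p_ethnicity": float(stats.kstest(p_eth, "uniform").pvalue),
        "ks_p_ancestry": float(stats.kstest(p_anc, "uniform").pvalue),
        "n": n,
        "n_cpgs": n_cpgs,
    }


def run_mediation_recovery(seed: int, n_reps: int = 200, n: int = 500):
    """Quasi-Bayesian mediation under a true proportion mediated of 0.75
    (a=0.5, b=0.6, c'=0.1): returns (truth, mean point estimate, 95%-CI
    coverage)."""
    rng = np.random.default_rng([seed, 42])
    a_true, b_true, c_true = 0.5, 0.6, 0.1
    truth = a_true * b_true / (a_true * b_true + c_true)
    idx = pd.Index([f"S{i}" for i in range(n)])
    t = pd.Series(np.tile([0.0, 1.0], n // 2), index=idx)
    est, covered = [], 0
    for _ in range(n_reps):
        m = pd.Series(a_true * t + rng.normal(0, 0.2, n), index=idx)
        y = pd.Series(c_true * t + b_true * m + rng.normal(0, 0.3, n), index=idx)
        res = mediate(y, t, m, n_sims=1000, seed=int(rng.integers(2**31)))
        est.append(res.prop_mediated_raw)
        lo, hi = res.ci["prop_mediated"]
        covered += lo <= truth <= hi
    return truth, float(np.mean(est)), covered / n_reps


def classification_study_config(n_per_group: int = 250) -> SimulationConfig:
    """Cohort where 200 CpG ethnicity effects are fully ancestry-mediated
    (theta on Native American ancestry scaled to a 0.5 M group contrast)
    and 100 are pure environment (0.5 M), at noise sd 0.45."""
    mex = ethnicity_profile("Mexican", n_per_group)
    pr = ethnicity_profile("PuertoRican", n_per_group)
    delta_nam = abs(mex.mean[2] - pr.mean[2])
    return SimulationConfig(
        profiles=[mex, pr],
        n_snps=60,
        n_cpgs=400,
        n_meqtl=0,
        n_ancestry_cpgs=200,
        theta_effect=0.5 / delta_nam,
        theta_component="NAM",
        n_env_cpgs=100,
        env_effect=0.5,
        duffy_like=False,
        cell_frac=0.0,
        plate_effect_sd=0.0,
        detection_fail_rate=0.0,
    )


def run_classification_recovery(seed: int):
    """Accuracy of the explained/remains partition against the generative
    truth: returns (accuracy, explained fraction, discovered effect CpGs)."""
    study = simulate_study(classification_study_config(), seed=seed)
    meth = study.m_values()
    samples = study.samples
    q = study.truth.q
    covs = ["case", "age", "sex"]
    un = EthnicityScan(meth, samples, covs).fit()
    ad = EthnicityScan(meth, samples, covs, ancestry=q).fit()
    flags = stability_flags_scan(meth, samples, q, covs)
    cls = classify_adjustment(un, ad, flags)
    truth_cls = pd.Series("null", index=meth.probes)
    truth_cls.iloc[study.truth.ancestry_cpgs] = "explained"
    truth_cls.iloc[study.truth.env_cpgs] = "remains"
    effect_hits = cls.index[truth_cls.loc[cls.index] != "null"]
    correct = (cls.loc[effect_hits, "classification"] == truth_cls.loc[effect_hits]).mean()
    explained_frac = (cls.loc[effect_hits, "classification"] == "explained").mean()
    return float(correct), float(explained_frac), len(effect_hits)


def run_darc_logic(seed: int) -> dict:
    """The fixed-difference cis-meQTL chain at a Duffy-like locus:
    methylation tracks local African dosage, the causal SNP ranks first in
    the 10 kb window, and conditioning on it abolishes the local-ancestry
    association."""
    cfg = SimulationConfig(
        profiles=[ethnicity_profile("Mexican", 250), ethnicity_profile("PuertoRican", 250)],
        n_snps=120,
        n_cpgs=100,
        n_meqtl=5,
        n_ancestry_cpgs=5,
        n_env_cpgs=5,
        duffy_like=True,
        duffy_effect=1.35,
    )
    study = simulate_study(cfg, seed=seed)
    meth = study.m_values()
    y = meth.values["cg_duffy_like"]
    pos_bp = float(meth.manifest.loc["cg_duffy_like", "pos"])
    pos_m = float(study.panel.genetic_map.bp_to_morgans(pos_bp))
    cube = dosage_cube(study.local, study.panel.positions_m)
    local = pd.DataFrame(
        interpolate_at(cube, study.panel.positions_m, pos_m),
        index=meth.samples,
        columns=list(study.local.labels),
    )
    amap = admixture_map(y, local)
    table = cis_scan(y, study.genotypes, pos_bp, local_dosage=local)
    return {
        "corr_local_afr": float(np.corrcoef(y, local["AFR"])[0, 1]),
        "afr_effect": float(amap.effects["AFR"]),
        "afr_se": float(amap.bse["AFR"]),
        "afr_fold_change": float(amap.fold_changes()["AFR"]),
        "best_snp": str(table.attrs["best_snp"]),
        "best_rank_is_causal": bool(table.attrs["best_snp"] == "rs_duffy_like"),
        "p_local_unconditional": float(table.attrs["p_local_unconditional"]),
        "p_local_given_best": float(table.attrs["p_local_given_best"]),
    }
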