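"""Variance partitioning and causal mediation.

Variance partitioning asks how much of the methylation variance at a CpG a
predictor block accounts for: PVE(block) = Var(X_block @ beta_block) /
Var(y) from a single joint fit.  For one standardised predictor this
reduces to beta^2 * Var(x) / Var(y).  The joint PVE uses the combined
ethnicity+ancestry block, so cross-block covariance appears only in the
joint term and each share = block PVE / joint PVE.

Mediation decomposes an ethnicity effect on methylation into the part
transmitted through genetic ancestry (ACME, the indirect effect) and the
direct remainder (ADE), via the standard two-regression product-of-
coefficients estimator with quasi-Bayesian (normal-approximation)
uncertainty.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ewas import ModelFit, RankError, ancestry_block, build_design, ethnicity_block, fit_ols

__all__ = [
    "VariancePartition",
    "pve_block",
    "joint_partition",
    "local_global_partition",
    "Mediation",
    "MediationResult",
    "mediate",
]


# ---------------------------------------------------------------------------
# PVE


def pve_block(fit: ModelFit, block: list[str], y=None) -> float:
    """Proportion of outcome variance carried by a design block's fitted
    contribution."""
    missing = [c for c in block if c not in fit.columns]
    if missing:
        raise ValueError(f"block columns not in design: {missing}")
    yv = fit.y if y is None else np.asarray(y, dtype=float)
    var_y = np.var(yv)
    if var_y <= 0:
        raise ValueError("outcome has zero variance")
    return float(np.var(fit.predict_block(block)) / var_y)


@dataclass
class VariancePartition:
    """Per-CpG decomposition of methylation variance between two predictor
    blocks fitted jointly."""

    pve_joint: float
    pve_blocks: dict[str, float]
    shares: dict[str, float]  # block PVE / joint PVE, truncated to [0,1]
    stable: bool = True

    def summary(self) -> str:
        if not self.stable:
            return "variance partition: unstable (collinear design), no shares reported"
        parts = ", ".join(
            f"{k}: {100 * v:.1f}% (share {100 * self.shares[k]:.1f}%)"
            for k, v in self.pve_blocks.items()
        )
        return f"joint PVE {100 * self.pve_joint:.1f}%; {parts}"


def _two_block_partition(y, blocks: dict[str, pd.DataFrame], covariates) -> VariancePartition:
    index = next(iter(blocks.values())).index
    X_cov = build_design(index, covariates)
    X = pd.concat([X_cov, *blocks.values()], axis=1)
    try:
        fit = fit_ols(y, X)
    except RankError:
        return VariancePartition(np.nan, {k: np.nan for k in blocks}, {}, stable=False)
    joint_cols = [c for b in blocks.values() for c in b.columns]
    pve_j = pve_block(fit, joint_cols)
    pves = {k: pve_block(fit, list(b.columns)) for k, b in blocks.items()}
    shares = {
        k: float(np.clip(v / pve_j, 0.0, 1.0)) if pve_j > 0 else 0.0 for k, v in pves.items()
    }
    return VariancePartition(pve_j, pves, shares)


def joint_partition(
    y,
    ethnicity: pd.Series,
    ancestry: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    reference: str = "EUR",
) -> VariancePartition:
    """Ethnicity-vs-global-ancestry partition of one CpG's variance."""
    blocks = {
        "ethnicity": ethnicity_block(ethnicity),
        "ancestry": ancestry_block(ancestry, reference),
    }
    return _two_block_partition(y, blocks, covariates)


def local_global_partition(
    y,
    local_dosage: pd.DataFrame,
    global_ancestry: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    reference: str = "EUR",
) -> VariancePartition:
    """Local (cis, gamma) vs global (theta) ancestry partition at one CpG."""
    loc = local_dosage[[c for c in local_dosage.columns if c != reference]]
    loc = loc.loc[:, loc.std(axis=0) > 1e-12].add_prefix("local_")
    if loc.shape[1] == 0:
        raise ValueError("local dosage has zero variance")
    blocks = {
        "local": loc,
        "global": ancestry_block(global_ancestry, reference),
    }
    return _two_block_partition(y, blocks, covariates)


# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    """Product-of-coefficients mediation with quasi-Bayesian intervals.

    In the linear, no-interaction model ACME + ADE = total effect; the
    proportion mediated is reported truncated to [0,1] (untruncated value
    retained).
    """

    acme: float
    ade: float
    total: float
    prop_mediated: float
    prop_mediated_raw: float
    ci: dict[str, tuple[float, float]]
    p_acme: float
    p_total: float
    n_sims: int
    seed: int | None
    treatment: str = "treatment"
    mediator: str = "mediator"

    def summary(self) -> str:
        def fmt(name, est, ci):
            return f"  {name:<18} {est:+.4f}  [{ci[0]:+.4f}, {ci[1]:+.4f}]"

        return "\n".join(
            [
                f"Mediation of {self.treatment} by {self.mediator} "
                f"(quasi-Bayesian, {self.n_sims} draws)",
                fmt("ACME (indirect)", self.acme, self.ci["acme"]) + f"  p={self.p_acme:.3g}",
                fmt("ADE (direct)", self.ade, self.ci["ade"]),
                fmt("Total effect", self.total, self.ci["total"]) + f"  p={self.p_total:.3g}",
                fmt("Prop. mediated", self.prop_mediated, self.ci["prop_mediated"]),
            ]
        )


def _two_sided(draws: np.ndarray) -> float:
    lo = float(np.mean(draws <= 0))
    hi = float(np.mean(draws >= 0))
    return min(1.0, 2 * min(lo, hi))


class Mediation:
    """Mediation model: does the mediator (an ancestry proportion) carry
    the treatment (ethnicity contrast) effect on the outcome?

    Fits ``mediator ~ a*treatment + covariates`` and ``outcome ~
    c'*treatment + b*mediator + covariates``; ACME = a*b, ADE = c', total =
    a*b + c'.  ``fit`` simulates (a, b, c') from their asymptotic normals
    for percentile intervals.
    """

    def __init__(
        self,
        outcome: pd.Series,
        treatment: pd.Series,
        mediator: pd.Series,
        covariates: pd.DataFrame | None = None,
        contrast: tuple[str, str] | None = None,
    ):
        index = outcome.index
        t = treatment.loc[index]
        is_factor = t.dtype == object or str(t.dtype) == "category"
        if is_factor:
            if contrast is None:
                # default: the two largest groups
                contrast = tuple(t.value_counts().index[:2][::-1])
            keep = t.isin(contrast)
            index = index[keep.loc[index]]
            t = (t.loc[index] == contrast[1]).astype(float)
            self.contrast = contrast
        else:
            vals = sorted(t.unique())
            if len(vals) > 2:
                if contrast is None:
                    raise ValueError("treatment must be binary or carry a contrast spec")
                keep = t.isin(contrast)
                index = index[keep.loc[index]]
                t = (t.loc[index] == contrast[1]).astype(float)
                self.contrast = tuple(str(v) for v in contrast)
            else:
                t = (t == vals[-1]).astype(float) if len(vals) == 2 else t.astype(float)
                self.contrast = tuple(str(v) for v in vals)
        self.y = outcome.loc[index].astype(float)
        self.t = t
        self.m = mediator.loc[index].astype(float)
        self.covariates = None if covariates is None else covariates.loc[index]
        self.treatment_name = treatment.name or "treatment"
        self.mediator_name = mediator.name or "mediator"

    def fit(self, n_sims: int = 1000, seed: int | None = None) -> MediationResult:
        index = self.y.index
        X_cov = build_design(index, self.covariates)
        med_fit = fit_ols(self.m, X_cov.assign(treat=self.t.to_numpy()))
        out_fit = fit_ols(
            self.y, X_cov.assign(treat=self.t.to_numpy(), mediator=self.m.to_numpy())
        )
        a, se_a = med_fit.params["treat"], med_fit.bse["treat"]
        b, se_b = out_fit.params["mediator"], out_fit.bse["mediator"]
        c_p, se_c = out_fit.params["treat"], out_fit.bse["treat"]

        rng = np.random.default_rng(seed)
        a_d = rng.normal(a, se_a, n_sims)
        # b and c' come from the same fit: draw jointly from their 2x2
        # asymptotic covariance
        Xo = out_fit.X
        cov = out_fit.sigma2 * np.linalg.inv(Xo.T @ Xo)
        cols = out_fit.columns
        ii = [cols.index("treat"), cols.index("mediator")]
        sub = cov[np.ix_(ii, ii)]
        cb = rng.multivariate_normal([c_p, b], sub, size=n_sims)
        c_d, b_d = cb[:, 0], cb[:, 1]

        acme_d = a_d * b_d
        ade_d = c_d
        tot_d = acme_d + ade_d
        with np.errstate(divide="ignore", invalid="ignore"):
            prop_d = np.where(np.abs(tot_d) > 1e-300, acme_d / tot_d, np.nan)

        def ci(x):
            return tuple(np.nanpercentile(x, [2.5, 97.5]))

        acme, ade = a * b, c_p
        total = acme + ade
        prop_raw = acme / total if abs(total) > 1e-300 else np.nan
        return MediationResult(
            acme=float(acme),
            ade=float(ade),
            total=float(total),
            prop_mediated=float(np.clip(prop_raw, 0.0, 1.0)),
            prop_mediated_raw=float(prop_raw),
            ci={
                "acme": ci(acme_d),
                "ade": ci(ade_d),
                "total": ci(tot_d),
                "prop_mediated": tuple(np.clip(ci(prop_d), 0.0, 1.0)),
            },
            p_acme=_two_sided(acme_d),
            p_total=_two_sided(tot_d),
            n_sims=n_sims,
            seed=seed,
            treatment=f"{self.treatment_name}[{self.contrast[1]} vs {self.contrast[0]}]",
            mediator=self.mediator_name,
        )


def mediate(
    y,
    treatment,
    mediator,
    covariates: pd.DataFrame | None = None,
    n_sims: int = 1000,
    seed: int | None = None,
    contrast: tuple[str, str] | None = None,
) -> MediationResult:
    """Functional wrapper over :class:`Mediation`."""
    if not isinstance(y, pd.Series):
        y = pd.Series(np.asarray(y, float), index=treatment.index, name="outcome")
    return Mediation(y, treatment, mediator, covariates, contrast).fit(n_sims=n_sims, seed=seed)
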