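"""Per-CpG association machinery.

Everything is ordinary least squares on M-values.  Multi-level or
compositional predictors (ethnicity; the K ancestry proportions, of which
K-1 enter the design) are tested with a nested-ANOVA omnibus F comparing
the model with and without the predictor block — for Gaussian OLS this is
the exact-F version of the likelihood-ratio test.  Genome-wide significance
uses a Bonferroni threshold of alpha / n_probes.

Scans (`EthnicityScan`, `AncestryScan`) follow a model-object convention:
construct from data, call ``fit()``, get a results object with a table,
threshold and ``summary()``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix, MethylationMatrix

__all__ = [
    "RankError",
    "ModelFit",
    "fit_ols",
    "nested_anova",
    "build_design",
    "EthnicityScan",
    "AncestryScan",
    "ScanResults",
    "ewas_ethnicity",
    "ewas_ancestry",
    "classify_adjustment",
    "stability_flag",
    "nonlinearity_test",
    "bonferroni",
    "enrichment",
    "EnrichmentResult",
    "admixture_map",
    "cis_scan",
    "m_to_fold",
]

DEFAULT_COVARIATES = ("case", "age", "sex", "granulocytes", "lymphocytes", "plate", "position")
ANCESTRY_REFERENCE = "EUR"


class RankError(ValueError):
    """Design matrix is rank deficient; carries the dependent columns."""

    def __init__(self, dependent: list[str]):
        self.dependent_columns = list(dependent)
        super().__init__(f"design matrix rank deficient; dependent columns: {self.dependent_columns}")


@dataclass
class ModelFit:
    """OLS fit: coefficients, standard errors, residual sum of squares."""

    params: pd.Series
    bse: pd.Series
    rss: float
    df_resid: int
    nobs: int
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def columns(self) -> list[str]:
        return list(self.params.index)

    @property
    def sigma2(self) -> float:
        return self.rss / self.df_resid

    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def predict_block(self, block: list[str]) -> np.ndarray:
        """Fitted contribution of a subset of design columns."""
        cols = [self.columns.index(c) for c in block]
        return self.X[:, cols] @ self.params.iloc[cols].to_numpy()


def _check_rank(X: np.ndarray, names: list[str]):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR exposes which trailing columns are dependent
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        dependent = [names[j] for j in piv[rank:]]
        raise RankError(dependent)


def fit_ols(y, X) -> ModelFit:
    """Least squares of y on design X (DataFrame; include your own
    intercept or use :func:`build_design`)."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float)
    _check_rank(Xa, names)
    n, k = Xa.shape
    if n - k < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    beta, _, _, _ = np.linalg.lstsq(Xa, ya, rcond=None)
    resid = ya - Xa @ beta
    rss = float(resid @ resid)
    df = n - k
    xtx_inv = np.linalg.inv(Xa.T @ Xa)
    se = np.sqrt(np.clip(rss / df * np.diag(xtx_inv), 0, None))
    se = np.where(se <= 0, np.finfo(float).tiny, se)
    return ModelFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        rss=rss,
        df_resid=df,
        nobs=n,
        X=Xa,
        y=ya,
    )


class AnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float


def nested_anova(full: ModelFit, reduced: ModelFit) -> AnovaResult:
    """Omnibus F test of the block distinguishing two nested OLS fits."""
    if not set(reduced.columns) <= set(full.columns):
        raise ValueError("reduced model columns must nest inside the full model")
    df1 = reduced.df_resid - full.df_resid
    if df1 < 0 or reduced.rss < full.rss - 1e-8 * max(1.0, full.rss):
        raise ValueError("models are not nested (reduced fits better than full)")
    if df1 == 0:
        return AnovaResult(0.0, 0, full.df_resid, 1.0)
    F = ((reduced.rss - full.rss) / df1) / (full.rss / full.df_resid)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df1, full.df_resid))
    return AnovaResult(float(F), df1, full.df_resid, p)


# ---------------------------------------------------------------------------
# design construction


def build_design(index: pd.Index, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Intercept + covariates; categorical/string columns are expanded to
    k-1 indicator columns."""
    parts = [pd.DataFrame({"const": np.ones(len(index))}, index=index)]
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.loc[index]
        num = cov.select_dtypes(include=[np.number]).astype(float)
        # constant columns are unidentifiable next to the intercept
        num = num.loc[:, num.std(axis=0) > 0]
        cat = cov.select_dtypes(exclude=[np.number])
        if num.shape[1]:
            parts.append(num)
        if cat.shape[1]:
            parts.append(pd.get_dummies(cat, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1)


def ethnicity_block(ethnicity: pd.Series, min_per_level: int = 2) -> pd.DataFrame:
    """k-1 indicator columns; levels with fewer than ``min_per_level``
    members are dropped with a warning (their samples keep zero rows)."""
    counts = ethnicity.value_counts()
    small = counts[counts < min_per_level]
    eth = ethnicity.copy()
    if len(small):
        warnings.warn(f"ethnicity level(s) with <{min_per_level} samples dropped: {list(small.index)}", stacklevel=2)
        eth = eth[~eth.isin(small.index)]
    dummies = pd.get_dummies(eth, prefix="eth", drop_first=True, dtype=float)
    return dummies.reindex(ethnicity.index, fill_value=0.0)


def ancestry_block(q: pd.DataFrame, reference: str = ANCESTRY_REFERENCE) -> pd.DataFrame:
    """K-1 ancestry-proportion columns (the reference ancestry is omitted —
    the proportions are compositional, so only K-1 are identifiable)."""
    cols = [c for c in q.columns if c != reference]
    if len(cols) == len(q.columns):
        cols = cols[:-1]
    return q[cols].astype(float).add_prefix("anc_")


# ---------------------------------------------------------------------------
# vectorised scan core


def _scan_rss(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """RSS per column of Y for one design; returns (rss vector, rank)."""
    Q, R = np.linalg.qr(X)
    rank = int((np.abs(np.diag(R)) > np.abs(R).max() * 1e-12).sum())
    proj = Q.T @ Y
    rss = (Y**2).sum(axis=0) - (proj**2).sum(axis=0)
    return np.clip(rss, 0.0, None), rank


def block_f_scan(Y: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray):
    """Vectorised nested-ANOVA F across many outcomes sharing a design."""
    rss_f, rank_f = _scan_rss(Y, X_full)
    rss_r, rank_r = _scan_rss(Y, X_reduced)
    df1 = rank_f - rank_r
    df2 = Y.shape[0] - rank_f
    if df1 <= 0 or df2 < 1:
        raise ValueError("full design must add estimable columns and leave residual df")
    F = ((rss_r - rss_f) / df1) / np.where(rss_f > 0, rss_f / df2, np.nan)
    F = np.clip(F, 0.0, None)
    p = stats.f.sf(F, df1, df2)
    return F, df1, df2, p


# ---------------------------------------------------------------------------
# scans


@dataclass
class ScanResults:
    """Per-CpG omnibus results.

    ``table`` has one row per CpG: chrom, pos, F, df1, df2, p and a
    Bonferroni ``significant`` flag at ``threshold``.
    """

    table: pd.DataFrame
    threshold: float
    predictor: str
    n_samples: int

    @property
    def hits(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    @property
    def n_hits(self) -> int:
        return int(self.table["significant"].sum())

    def summary(self) -> str:
        t = self.table
        lines = [
            f"{self.predictor} scan: {len(t)} CpGs, {self.n_samples} samples",
            f"omnibus df1={int(t['df1'].iloc[0])}, Bonferroni threshold={self.threshold:.3g}",
            f"significant CpGs: {self.n_hits}",
        ]
        top = t.nsmallest(min(5, len(t)), "p")
        for cpg, row in top.iterrows():
            lines.append(f"  {cpg}  F={row['F']:.2f}  p={row['p']:.3g}")
        return "\n".join(lines)


class _Scan:
    """Base class: M-value matrix + sample sheet + covariate adjustment."""

    def __init__(
        self,
        meth: MethylationMatrix,
        samples: pd.DataFrame,
        covariates: list[str] | None = None,
        alpha: float = 0.05,
    ):
        self.meth = meth.to_m()
        self.samples = samples.loc[self.meth.samples]
        cov_names = [c for c in (covariates or DEFAULT_COVARIATES) if c in self.samples.columns]
        self.covariates = self.samples[cov_names]
        self.alpha = alpha

    def _base_design(self) -> pd.DataFrame:
        return build_design(self.meth.samples, self.covariates)

    def _run(self, block: pd.DataFrame, predictor: str) -> ScanResults:
        X_red = self._base_design()
        X_full = pd.concat([X_red, block], axis=1)
        Y = self.meth.values.to_numpy()
        F, df1, df2, p = block_f_scan(Y, X_full.to_numpy(float), X_red.to_numpy(float))
        man = self.meth.manifest
        table = pd.DataFrame(
            {
                "chrom": man["chrom"] if man is not None else "NA",
                "pos": man["pos"] if man is not None else -1,
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
            },
            index=self.meth.probes,
        )
        thr = bonferroni(self.alpha, len(table))
        table["significant"] = table["p"] < thr
        return ScanResults(table, thr, predictor, len(self.samples))


class EthnicityScan(_Scan):
    """Omnibus EWAS of self-identified ethnicity (k-1 df per CpG),
    optionally additionally adjusted for global ancestry and/or genotype
    PCs."""

    def __init__(
        self,
        meth: MethylationMatrix,
        samples: pd.DataFrame,
        covariates: list[str] | None = None,
        alpha: float = 0.05,
        ancestry: pd.DataFrame | None = None,
        extra: pd.DataFrame | None = None,
        ancestry_reference: str = ANCESTRY_REFERENCE,
    ):
        super().__init__(meth, samples, covariates, alpha)
        self.ancestry = ancestry
        self.extra = extra
        self.reference = ancestry_reference

    def _base_design(self) -> pd.DataFrame:
        X = super()._base_design()
        if self.ancestry is not None:
            X = pd.concat([X, ancestry_block(self.ancestry.loc[X.index], self.reference)], axis=1)
        if self.extra is not None:
            X = pd.concat([X, self.extra.loc[X.index].astype(float)], axis=1)
        return X

    def fit(self) -> ScanResults:
        block = ethnicity_block(self.samples["ethnicity"])
        label = "ethnicity" if self.ancestry is None else "ethnicity|ancestry"
        return self._run(block, label)


class AncestryScan(_Scan):
    """Omnibus EWAS of global ancestry (K-1 df), adjusted for ethnicity;
    per-component marginal tests assign which ancestry drives each hit."""

    def __init__(
        self,
        meth: MethylationMatrix,
        samples: pd.DataFrame,
        ancestry: pd.DataFrame,
        covariates: list[str] | None = None,
        alpha: float = 0.05,
        ancestry_reference: str = ANCESTRY_REFERENCE,
        adjust_ethnicity: bool = True,
    ):
        super().__init__(meth, samples, covariates, alpha)
        self.ancestry = ancestry.loc[self.meth.samples]
        self.reference = ancestry_reference
        self.adjust_ethnicity = adjust_ethnicity

    def _base_design(self) -> pd.DataFrame:
        X = super()._base_design()
        if self.adjust_ethnicity and "ethnicity" in self.samples.columns:
            X = pd.concat([X, ethnicity_block(self.samples["ethnicity"])], axis=1)
        return X

    def fit(self) -> ScanResults:
        res = self._run(ancestry_block(self.ancestry, self.reference), "ancestry|ethnicity")
        # single-component marginal tests: smallest p names the driver
        X_red = self._base_design().to_numpy(float)
        Y = self.meth.values.to_numpy()
        marg = {}
        for comp in self.ancestry.columns:
            X_full = np.column_stack([X_red, self.ancestry[comp].to_numpy(float)])
            _, _, _, p = block_f_scan(Y, X_full, X_red)
            marg[comp] = p
            res.table[f"p_{comp}"] = p
        marg_df = pd.DataFrame(marg, index=self.meth.probes)
        res.table["driven_by"] = marg_df.idxmin(axis=1)
        return res


def ewas_ethnicity(meth, samples, covariates=None, alpha=0.05, **kw) -> ScanResults:
    return EthnicityScan(meth, samples, covariates, alpha, **kw).fit()


def ewas_ancestry(meth, ancestry, samples, covariates=None, alpha=0.05, **kw) -> ScanResults:
    return AncestryScan(meth, samples, ancestry, covariates, alpha, **kw).fit()


# ---------------------------------------------------------------------------
# classification of hits after ancestry adjustment


def classify_adjustment(
    unadjusted: ScanResults,
    adjusted: ScanResults,
    unstable: pd.Series | None = None,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Partition discovery hits into remains / explained / unstable.

    A CpG significant in the unadjusted ethnicity scan is ``unstable`` if
    flagged (collinear ethnicity/ancestry), ``remains`` if its ethnicity
    association survives ancestry adjustment at ``threshold``, else
    ``explained``.  Retention defaults to nominal 0.05: adjustment that
    merely attenuates a real residual effect (collinearity inflates its SE)
    should not count as explaining it; pass the genome-wide threshold to
    require full significance instead.
    """
    if not unadjusted.table.index.equals(adjusted.table.index):
        raise ValueError("scans must cover the same CpGs")
    thr = threshold
    hits = unadjusted.hits
    cls = pd.Series("explained", index=hits, name="classification")
    cls[adjusted.table.loc[hits, "p"] < thr] = "remains"
    if unstable is not None:
        cls[unstable.reindex(hits, fill_value=False)] = "unstable"
    out = pd.DataFrame(
        {
            "p_unadjusted": unadjusted.table.loc[hits, "p"],
            "p_adjusted": adjusted.table.loc[hits, "p"],
            "classification": cls,
        }
    )
    out.attrs["counts"] = cls.value_counts().to_dict()
    return out


def stability_flag(
    fit_adj: ModelFit,
    fit_unadj: ModelFit,
    vif_cut: float = 100.0,
    se_ratio_cut: float = 10.0,
) -> bool:
    """True when ancestry adjustment destabilises the ethnicity
    coefficients: any shared coefficient's SE inflates by more than
    ``se_ratio_cut``, or the adjusted design has a VIF above ``vif_cut``."""
    shared = [c for c in fit_unadj.columns if c in fit_adj.columns and c.startswith("eth_")]
    if shared:
        ratio = (fit_adj.bse[shared] / fit_unadj.bse[shared]).max()
        if ratio > se_ratio_cut:
            return True
    return design_max_vif(fit_adj.X, fit_adj.columns) > vif_cut


def design_max_vif(X: np.ndarray, names: list[str], prefixes=("eth_", "anc_")) -> float:
    """Largest variance-inflation factor among predictor columns of
    interest (ethnicity indicators and ancestry proportions)."""
    cols = [j for j, c in enumerate(names) if c.startswith(prefixes)]
    if not cols:
        return 1.0
    vifs = []
    for j in cols:
        others = [i for i in range(X.shape[1]) if i != j]
        xj = X[:, j]
        beta, *_ = np.linalg.lstsq(X[:, others], xj, rcond=None)
        resid = xj - X[:, others] @ beta
        tss = ((xj - xj.mean()) ** 2).sum()
        r2 = 1 - (resid @ resid) / tss if tss > 0 else 1.0
        vifs.append(1.0 / max(1 - r2, 1e-300))
    return float(max(vifs))


def stability_flags_scan(
    meth: MethylationMatrix,
    samples: pd.DataFrame,
    ancestry: pd.DataFrame,
    covariates: list[str] | None = None,
    vif_cut: float = 100.0,
    se_ratio_cut: float = 10.0,
    ancestry_reference: str = ANCESTRY_REFERENCE,
) -> pd.Series:
    """Vectorised per-CpG stability flags for the ethnicity coefficients
    before vs after ancestry adjustment."""
    meth = meth.to_m()
    samples = samples.loc[meth.samples]
    scan = _Scan(meth, samples, covariates)
    eth = ethnicity_block(samples["ethnicity"])
    X_un = pd.concat([scan._base_design(), eth], axis=1)
    X_ad = pd.concat([X_un, ancestry_block(ancestry.loc[meth.samples], ancestry_reference)], axis=1)
    eth_cols = list(eth.columns)
    Y = meth.values.to_numpy()

    def se_per_cpg(Xdf):
        X = Xdf.to_numpy(float)
        rss, rank = _scan_rss(Y, X)
        df = len(X) - rank
        diag = np.diag(np.linalg.pinv(X.T @ X))
        idx = [list(Xdf.columns).index(c) for c in eth_cols]
        return np.sqrt(np.outer(rss / df, diag[idx]))  # p x len(eth_cols)

    ratio = (se_per_cpg(X_ad) / se_per_cpg(X_un)).max(axis=1)
    vif = design_max_vif(X_ad.to_numpy(float), list(X_ad.columns))
    return pd.Series((ratio > se_ratio_cut) | (vif > vif_cut), index=meth.probes, name="unstable")


# ---------------------------------------------------------------------------
# non-linearity


def _spline_block(a: np.ndarray, quantiles=(0.25, 0.5, 0.75)) -> np.ndarray:
    """Three truncated-cubic columns (a - k)^3_+ with knots at the ancestry
    quantiles: a cubic-spline departure block adding exactly 3 df beside an
    existing linear term."""
    knots = np.quantile(a, quantiles)
    if len(np.unique(knots)) < len(quantiles):
        raise ValueError("insufficient distinct ancestry values for spline knots")
    return np.clip(a[:, None] - knots[None, :], 0.0, None) ** 3


@dataclass
class NonlinearityResult:
    p_nonlinear: float
    df_block: int
    p_ethnicity_adjusted: float | None
    method: str


def nonlinearity_test(
    y,
    ancestry: pd.Series,
    covariates: pd.DataFrame | None = None,
    method: str = "poly",
    ethnicity: pd.Series | None = None,
) -> NonlinearityResult:
    """Nested-ANOVA test of non-linear ancestry terms.

    ``poly`` adds squared and cubed ancestry (2 df); ``spline`` adds a
    3-df truncated-cubic block with knots at the 25/50/75% quantiles.  The
    linear ancestry term is always in the reduced model.  When ``ethnicity``
    is supplied, the ethnicity omnibus p with the non-linear block included
    is also reported.
    """
    a = np.asarray(ancestry, dtype=float)
    index = ancestry.index
    X_cov = build_design(index, covariates)
    X_red = X_cov.assign(anc=a)
    if method == "poly":
        block = pd.DataFrame({"anc2": a**2, "anc3": a**3}, index=index)
    elif method == "spline":
        B = _spline_block(a)
        block = pd.DataFrame(B, index=index, columns=[f"spl{i}" for i in range(B.shape[1])])
    else:
        raise ValueError("method must be 'poly' or 'spline'")
    X_full = pd.concat([X_red, block], axis=1)
    eth = ethnicity_block(ethnicity) if ethnicity is not None else None
    if eth is not None:
        X_red = pd.concat([X_red, eth], axis=1)
        X_full = pd.concat([X_full, eth], axis=1)
    res = nested_anova(fit_ols(y, X_full), fit_ols(y, X_red))
    p_eth = None
    if eth is not None:
        no_eth = X_full[[c for c in X_full.columns if not c.startswith("eth_")]]
        p_eth = nested_anova(fit_ols(y, X_full), fit_ols(y, no_eth)).p
    return NonlinearityResult(res.p, res.df1, p_eth, method)


# ---------------------------------------------------------------------------
# thresholds, enrichment, fold change


def bonferroni(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class EnrichmentResult:
    """Enrichment of a candidate CpG set for association signal."""

    n_candidates: int
    n_nominal: int
    nominal_rate: float
    binomial_p: float
    n_overlap: int
    hypergeom_p: float
    n_bonferroni_within: int

    def summary(self) -> str:
        return (
            f"{self.n_nominal}/{self.n_candidates} candidates nominally significant "
            f"({100 * self.nominal_rate:.1f}%), binomial p={self.binomial_p:.3g}; "
            f"overlap with hits {self.n_overlap}, hypergeometric p={self.hypergeom_p:.3g}; "
            f"{self.n_bonferroni_within} pass within-set Bonferroni"
        )


def enrichment(
    hit_set,
    candidate_set,
    universe,
    nominal_p_map: pd.Series,
    rate0: float = 0.05,
    nominal_alpha: float = 0.05,
) -> EnrichmentResult:
    """Two enrichment views of a candidate set (e.g. exposure-associated
    CpGs): a one-sided binomial test of the nominally-significant rate
    against ``rate0``, and a hypergeometric tail for overlap with the hit
    set within the universe."""
    universe = pd.Index(universe)
    candidates = pd.Index(candidate_set).intersection(universe)
    if len(candidates) == 0:
        raise ValueError("candidate set is empty after intersecting with the universe")
    hits = pd.Index(hit_set).intersection(universe)
    p_cand = nominal_p_map.loc[candidates]
    n_nom = int((p_cand < nominal_alpha).sum())
    binom = stats.binomtest(n_nom, len(candidates), rate0, alternative="greater")
    overlap = len(candidates.intersection(hits))
    hyper = float(stats.hypergeom.sf(overlap - 1, len(universe), len(hits), len(candidates)))
    n_bonf = int((p_cand < bonferroni(nominal_alpha, len(candidates))).sum())
    return EnrichmentResult(
        n_candidates=len(candidates),
        n_nominal=n_nom,
        nominal_rate=n_nom / len(candidates),
        binomial_p=float(binom.pvalue),
        n_overlap=overlap,
        hypergeom_p=hyper,
        n_bonferroni_within=n_bonf,
    )


def m_to_fold(delta_m: float) -> float:
    """M-value difference -> fold change of the methylated:unmethylated
    ratio (2**delta_m)."""
    return float(2.0**delta_m)


# ---------------------------------------------------------------------------
# admixture mapping and cis scan


@dataclass
class AdmixtureMapResult:
    """Local-ancestry association at one CpG."""

    effects: pd.Series  # M units per haplotype, per ancestry (ref omitted)
    bse: pd.Series
    p_marginal: pd.Series
    F: float
    df1: int
    df2: int
    p_omnibus: float

    def fold_changes(self) -> pd.Series:
        return self.effects.map(m_to_fold)

    def summary(self) -> str:
        lines = [f"local-ancestry omnibus F={self.F:.2f} ({self.df1} df), p={self.p_omnibus:.3g}"]
        for anc in self.effects.index:
            lines.append(
                f"  {anc}: {self.effects[anc]:+.3f} M/haplotype "
                f"({self.fold_changes()[anc]:.2f}-fold), p={self.p_marginal[anc]:.3g}"
            )
        return "\n".join(lines)


def admixture_map(
    y,
    local_dosage: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    reference: str = ANCESTRY_REFERENCE,
) -> AdmixtureMapResult:
    """Regress methylation on local-ancestry dosage at the CpG (K-1
    dosage columns; effects are M units per haplotype of each ancestry)."""
    dos = local_dosage.astype(float)
    if (dos.std(axis=0) < 1e-12).all():
        raise ValueError("local-ancestry dosage has zero variance at this position")
    cols = [c for c in dos.columns if c != reference]
    cols = [c for c in cols if dos[c].std() > 1e-12]
    if not cols:
        raise ValueError("no variable non-reference dosage columns")
    index = dos.index
    X_red = build_design(index, covariates)
    block = dos[cols].add_prefix("la_")
    full = fit_ols(y, pd.concat([X_red, block], axis=1))
    red = fit_ols(y, X_red)
    omni = nested_anova(full, red)
    eff = full.params[[f"la_{c}" for c in cols]]
    eff.index = cols
    bse = full.bse[[f"la_{c}" for c in cols]]
    bse.index = cols
    t = eff / bse
    p_marg = pd.Series(2 * stats.t.sf(np.abs(t), full.df_resid), index=cols)
    return AdmixtureMapResult(eff, bse, p_marg, omni.F, omni.df1, omni.df2, omni.p)


def cis_scan(
    y,
    geno: GenotypeMatrix,
    cpg_pos: float,
    window_bp: float = 10_000,
    covariates: pd.DataFrame | None = None,
    local_dosage: pd.DataFrame | None = None,
    reference: str = ANCESTRY_REFERENCE,
) -> pd.DataFrame:
    """Additive-dosage scan of SNPs within ``window_bp`` of the CpG
    (boundaries inclusive), ranked by p.

    When ``local_dosage`` is supplied the scan also reports, via nested
    ANOVA, whether the local-ancestry association survives conditioning on
    the best SNP (``attrs['p_local_given_best']``).
    """
    pos = geno.positions_bp
    in_win = (pos >= cpg_pos - window_bp) & (pos <= cpg_pos + window_bp)
    snps = pos.index[in_win]
    X_red = build_design(geno.samples, covariates)
    rows = []
    for snp in snps:
        g = geno.dosages[snp].to_numpy(float)
        if np.nanstd(g) < 1e-12:
            continue
        g = np.where(np.isnan(g), np.nanmean(g), g)
        fit = fit_ols(y, X_red.assign(snp=g))
        t = fit.params["snp"] / fit.bse["snp"]
        rows.append(
            {
                "snp": snp,
                "pos": int(pos[snp]),
                "distance": int(abs(pos[snp] - cpg_pos)),
                "beta": fit.params["snp"],
                "se": fit.bse["snp"],
                "p": 2 * stats.t.sf(abs(t), fit.df_resid),
            }
        )
    table = pd.DataFrame(rows, columns=["snp", "pos", "distance", "beta", "se", "p"])
    if len(table):
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    if local_dosage is not None and len(table):
        best = table.iloc[0]["snp"]
        g = geno.dosages[best].to_numpy(float)
        g = np.where(np.isnan(g), np.nanmean(g), g)
        cols = [c for c in local_dosage.columns if c != reference and local_dosage[c].std() > 1e-12]
        base = X_red.assign(snp=g)
        # at a perfect fixed-difference SNP the genotype *equals* a local
        # dosage column; drop local columns absorbed by the conditioning SNP
        # (their signal is fully explained) and test what remains
        block = local_dosage[cols].add_prefix("la_")
        keep = []
        Xb = base.to_numpy(float)
        for c in block.columns:
            x = block[c].to_numpy(float)
            basis = np.column_stack([Xb] + [block[k].to_numpy(float) for k in keep])
            resid = x - basis @ np.linalg.lstsq(basis, x, rcond=None)[0]
            if resid @ resid > 1e-8 * max(1.0, x @ x):
                keep.append(c)
        red = fit_ols(y, base)
        if keep:
            full = fit_ols(y, pd.concat([base, block[keep]], axis=1))
            cond = nested_anova(full, red)
        else:
            cond = AnovaResult(0.0, 0, red.df_resid, 1.0)
        table.attrs["best_snp"] = best
        table.attrs["p_local_given_best"] = cond.p
        table.attrs["p_local_unconditional"] = admixture_map(
            y, local_dosage, covariates, reference
        ).p_omnibus
    return table
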