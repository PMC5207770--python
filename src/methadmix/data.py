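"""Methylation and genotype data containers, beta/M transforms, QC and
reference-based cell-type deconvolution.

The methylation array reports, per CpG probe, a *beta value* — the fraction
methylated/(methylated+unmethylated), strictly inside (0, 1).  All modelling
here happens on the *M-value* scale, M = log2(beta / (1 - beta)), which is
unbounded and closer to homoscedastic.  An M difference of d corresponds to a
2**d-fold change in the methylated:unmethylated ratio.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "GenotypeMatrix",
    "CellReference",
    "beta_to_m",
    "m_to_beta",
    "filter_probes",
    "qc_genotypes",
    "hwe_exact_p",
    "estimate_cell_proportions",
]


# ---------------------------------------------------------------------------
# beta <-> M


def beta_to_m(beta, eps: float = 1e-6):
    """logit2 transform: M = log2(beta/(1-beta)).

    Beta values of exactly 0 or 1 (impossible analytically, possible in
    exported files) are clipped to [eps, 1-eps] with a warning.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0) or np.any(beta > 1):
        raise ValueError("beta values must lie in [0, 1]")
    if np.any(beta <= 0) or np.any(beta >= 1):
        warnings.warn(
            f"beta values at the 0/1 boundary clipped to [{eps}, {1 - eps}]",
            stacklevel=2,
        )
        beta = np.clip(beta, eps, 1 - eps)
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2**M / (2**M + 1)."""
    m = np.asarray(m, dtype=float)
    # expit in base 2, numerically stable on both tails
    out = np.empty_like(m)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-m[pos]))
    e = np.exp2(m[~pos])
    out[~pos] = e / (1.0 + e)
    return out


# ---------------------------------------------------------------------------
# containers


@dataclass
class MethylationMatrix:
    """Samples x probes methylation values with probe coordinates.

    ``values`` rows are samples, columns probes; ``scale`` tags whether the
    numbers are beta or M.  ``manifest`` is indexed by probe id with columns
    ``chrom`` and ``pos`` (1-based).  ``detection_p`` (optional) matches the
    shape of ``values``.
    """

    values: pd.DataFrame
    scale: str = "beta"
    manifest: pd.DataFrame | None = None
    detection_p: pd.DataFrame | None = None

    def __post_init__(self):
        if self.scale not in ("beta", "m"):
            raise ValueError(f"scale must be 'beta' or 'm', got {self.scale!r}")
        if self.values.columns.has_duplicates:
            raise ValueError("probe ids must be unique")
        if self.scale == "beta":
            v = self.values.to_numpy()
            if np.any(v <= 0) or np.any(v >= 1):
                raise ValueError("beta-scale values must be strictly in (0, 1)")
        if self.manifest is not None:
            missing = self.values.columns.difference(self.manifest.index)
            if len(missing):
                raise ValueError(f"probes absent from manifest: {list(missing)[:5]}")

    @property
    def probes(self) -> pd.Index:
        return self.values.columns

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    def to_m(self, eps: float = 1e-6) -> "MethylationMatrix":
        if self.scale == "m":
            return self
        m = pd.DataFrame(
            beta_to_m(self.values.to_numpy(), eps=eps),
            index=self.values.index,
            columns=self.values.columns,
        )
        return replace(self, values=m, scale="m")

    def to_beta(self) -> "MethylationMatrix":
        if self.scale == "beta":
            return self
        b = pd.DataFrame(
            m_to_beta(self.values.to_numpy()),
            index=self.values.index,
            columns=self.values.columns,
        )
        return replace(self, values=b, scale="beta")

    def subset_probes(self, probes) -> "MethylationMatrix":
        probes = pd.Index(probes)
        det = None if self.detection_p is None else self.detection_p[probes]
        man = None if self.manifest is None else self.manifest.loc[probes]
        return replace(self, values=self.values[probes], detection_p=det, manifest=man)

    def subset_samples(self, samples) -> "MethylationMatrix":
        samples = pd.Index(samples)
        det = None if self.detection_p is None else self.detection_p.loc[samples]
        return replace(self, values=self.values.loc[samples], detection_p=det)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosages in {0,1,2}, NaN for missing."""

    dosages: pd.DataFrame
    positions_bp: pd.Series  # indexed by SNP id
    positions_m: pd.Series | None = None
    chrom: str = "chr1"

    def __post_init__(self):
        self.positions_bp = self.positions_bp.loc[self.dosages.columns]
        if not self.positions_bp.is_monotonic_increasing:
            raise ValueError("SNP positions must be sorted increasing")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or missing")
        if self.positions_m is not None:
            self.positions_m = self.positions_m.loc[self.dosages.columns]

    @property
    def snps(self) -> pd.Index:
        return self.dosages.columns

    @property
    def samples(self) -> pd.Index:
        return self.dosages.index

    def subset_snps(self, snps) -> "GenotypeMatrix":
        snps = pd.Index(snps)
        pm = None if self.positions_m is None else self.positions_m.loc[snps]
        return GenotypeMatrix(self.dosages[snps], self.positions_bp.loc[snps], pm, self.chrom)


@dataclass
class CellReference:
    """Cell-type x probe reference mean M-value profiles."""

    profiles: pd.DataFrame  # cell types (rows) x probes (columns)

    def __post_init__(self):
        if self.profiles.shape[0] < 2:
            raise ValueError("need at least 2 cell types")

    @property
    def cell_types(self) -> pd.Index:
        return self.profiles.index


# ---------------------------------------------------------------------------
# probe QC


def filter_probes(
    meth: MethylationMatrix, p_cut: float = 0.01, max_fail_frac: float = 0.01
) -> MethylationMatrix:
    """Drop probes whose detection p exceeds ``p_cut`` in more than
    ``max_fail_frac`` of samples; probe order of survivors is preserved."""
    if meth.detection_p is None:
        raise ValueError("detection p-values required for probe QC")
    fail_frac = (meth.detection_p.to_numpy() > p_cut).mean(axis=0)
    keep = meth.probes[fail_frac <= max_fail_frac]
    if len(keep) == 0:
        raise ValueError("all probes removed by detection-p filter")
    return meth.subset_probes(keep)


# ---------------------------------------------------------------------------
# genotype QC


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy–Weinberg test p-value (two-sided, no mid-p correction).

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts and sums the probabilities of all outcomes no more
    likely than the observed one.  Monomorphic sites return 1.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n == 0 or n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    # heterozygote count shares the parity of the rare allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    # log P(het) up to a constant: enumerate via log-factorials
    from scipy.special import gammaln

    def logp(h):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (
            h * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(hom_r + 1)
            - gammaln(hom_c + 1)
        )

    lp = logp(het_values.astype(float))
    lp -= lp.max()
    probs = np.exp(lp)
    probs /= probs.sum()
    obs = probs[het_values == n_ab][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def qc_genotypes(
    geno: GenotypeMatrix,
    group_labels: pd.Series,
    miss_cut: float = 0.05,
    hwe_cut: float = 1e-6,
    min_group_size: int = 5,
):
    """Missingness then per-group exact-HWE SNP filters.

    Removes SNPs with missingness > ``miss_cut``, then SNPs with exact HWE
    p < ``hwe_cut`` within any ethnic group of at least ``min_group_size``
    individuals.  Returns ``(kept GenotypeMatrix, removal log DataFrame)``.
    """
    group_labels = group_labels.loc[geno.samples]
    dos = geno.dosages.to_numpy(dtype=float)
    removed = []

    miss = np.isnan(dos).mean(axis=0)
    for snp, m in zip(geno.snps[miss > miss_cut], miss[miss > miss_cut]):
        removed.append((snp, "missingness", float(m)))
    keep_mask = miss <= miss_cut

    groups = [g for g, idx in group_labels.groupby(group_labels).groups.items()]
    for g in groups:
        members = group_labels.index[group_labels == g]
        if len(members) < min_group_size:
            warnings.warn(
                f"group {g!r} has <{min_group_size} individuals; skipped in HWE test",
                stacklevel=2,
            )
            continue
        sub = geno.dosages.loc[members].to_numpy(dtype=float)
        for j in np.flatnonzero(keep_mask):
            col = sub[:, j]
            col = col[~np.isnan(col)]
            p = hwe_exact_p(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
            if p < hwe_cut:
                removed.append((geno.snps[j], f"hwe:{g}", p))
                keep_mask[j] = False

    log = pd.DataFrame(removed, columns=["snp", "reason", "value"])
    return geno.subset_snps(geno.snps[keep_mask]), log


# ---------------------------------------------------------------------------
# cell-type deconvolution


def _constrained_ls(W: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Minimise ||x - W^T p||^2 subject to p >= 0, sum(p) <= 1.

    Exact small-scale QP solved by enumerating active sets (zeroed
    components x sum-constraint active), solving each equality-constrained
    least-squares problem and taking the feasible candidate with the lowest
    objective.  Exact for the <=6 cell types used in blood deconvolution.
    """
    C = W.shape[0]
    A = W.T  # probes x cells
    best, best_obj = None, np.inf
    for zeroed in itertools.chain.from_iterable(
        itertools.combinations(range(C), r) for r in range(C)
    ):
        free = [c for c in range(C) if c not in zeroed]
        Af = A[:, free]
        for sum_active in (False, True):
            if sum_active:
                # solve with equality sum(p_free) = 1 via KKT system
                AtA = Af.T @ Af
                ones = np.ones((len(free), 1))
                kkt = np.block([[2 * AtA, ones], [ones.T, np.zeros((1, 1))]])
                rhs = np.concatenate([2 * Af.T @ x, [1.0]])
                try:
                    sol = np.linalg.solve(kkt, rhs)
                except np.linalg.LinAlgError:
                    continue
                pf = sol[: len(free)]
            else:
                pf, *_ = np.linalg.lstsq(Af, x, rcond=None)
            if np.any(pf < -1e-9) or pf.sum() > 1 + 1e-9:
                continue
            p = np.zeros(C)
            p[free] = np.clip(pf, 0.0, None)
            if p.sum() > 1:
                p /= p.sum()
            obj = float(np.sum((x - A @ p) ** 2))
            if obj < best_obj - 1e-15:
                best, best_obj = p, obj
    return best


def estimate_cell_proportions(meth: MethylationMatrix, ref: CellReference):
    """Reference-based (constrained-projection) cell-mixture estimation.

    For each sample, the M-value vector over the probes shared with the
    reference is modelled as a nonnegative mixture (summing to at most 1)
    of the cell-type mean profiles; the estimate is the constrained
    least-squares solution.  Returns ``(proportions DataFrame,
    residual-norm Series)``.
    """
    meth_m = meth.to_m()
    shared = meth_m.probes.intersection(ref.profiles.columns)
    C = ref.profiles.shape[0]
    if len(shared) < C:
        raise ValueError(f"need at least {C} shared probes, have {len(shared)}")
    W = ref.profiles[shared].to_numpy(dtype=float)  # cells x probes
    if np.linalg.matrix_rank(W) < C:
        corr = np.corrcoef(W)
        pairs = [
            (ref.cell_types[i], ref.cell_types[j])
            for i in range(C)
            for j in range(i + 1, C)
            if abs(corr[i, j]) > 1 - 1e-8
        ]
        raise ValueError(f"reference profiles are rank-deficient; collinear cell types: {pairs}")
    X = meth_m.values[shared].to_numpy(dtype=float)
    props = np.empty((X.shape[0], C))
    resid = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        p = _constrained_ls(W, X[i])
        props[i] = p
        resid[i] = float(np.linalg.norm(X[i] - W.T @ p))
    return (
        pd.DataFrame(props, index=meth_m.samples, columns=ref.cell_types),
        pd.Series(resid, index=meth_m.samples, name="residual_norm"),
    )
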