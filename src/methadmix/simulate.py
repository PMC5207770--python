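"""Synthetic admixed-cohort generator.

Emulates a three-way admixed (African / European / Native American) study
population in which ethnic groups differ in their global-ancestry
distributions, genotypes arise from ancestry-specific allele frequencies on
Markov local-ancestry tracts, and whole-blood methylation is driven by cell
composition, cis meQTLs, global ancestry, ethnicity-specific environment,
batch and noise.  Every downstream stage (QC, structure, EWAS, variance
partitioning, mediation, admixture mapping) is testable against the recorded
generative truth.

Default group ancestry distributions are Dirichlet with means anchored to
the published cohort's per-group ancestry medians (e.g. Mexican ~4%/41%/55%
and Puerto Rican ~23%/66%/11% AFR/EUR/NAM) and the default residual noise
s.d. of 0.45 M-units matches that study's pilot estimate of the 90th
percentile of per-CpG M-value variance (0.2).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import GeneticMap, derived_rng
from .ancestry import HaplotypeTracts, LocalAncestryMatrix, global_from_local
from .data import CellReference, GenotypeMatrix, MethylationMatrix, m_to_beta

__all__ = [
    "ANCESTRIES",
    "CELL_TYPES",
    "AncestralPanel",
    "EthnicityProfile",
    "SimulationTruth",
    "SimulationConfig",
    "SimulatedStudy",
    "default_panel",
    "default_profiles",
    "simulate_global_ancestry",
    "simulate_local_tracts",
    "simulate_genotypes",
    "simulate_methylation",
    "simulate_study",
]

ANCESTRIES = ("AFR", "EUR", "NAM")
CELL_TYPES = ("granulocytes", "lymphocytes", "monocytes")

# per-group ancestry medians (AFR, EUR, NAM) from the source cohort's
# baseline table, renormalised to the simplex
_GROUP_MEANS = {
    "Mexican": (0.043, 0.405, 0.554),
    "PuertoRican": (0.228, 0.657, 0.112),
    "MixedLatino": (0.085, 0.505, 0.315),
    "OtherLatino": (0.123, 0.489, 0.328),
}
_GROUP_N = {"Mexican": 276, "PuertoRican": 220, "MixedLatino": 16, "OtherLatino": 61}
_CASE_RATE = {"Mexican": 0.449, "PuertoRican": 0.668, "MixedLatino": 0.563, "OtherLatino": 0.508}
_SITE_DIST = {
    "Mexican": {"Chicago": 0.507, "NewYork": 0.065, "SanFrancisco": 0.283, "Houston": 0.145},
    "PuertoRican": {"Chicago": 0.068, "NewYork": 0.045, "PuertoRico": 0.877, "Houston": 0.010},
    "MixedLatino": {"Chicago": 0.689, "NewYork": 0.063, "SanFrancisco": 0.125, "Houston": 0.123},
    "OtherLatino": {"Chicago": 0.246, "NewYork": 0.377, "SanFrancisco": 0.377},
}
_CELL_MEAN = (0.51, 0.42, 0.07)


# ---------------------------------------------------------------------------
# ancestral panel


@dataclass(frozen=True)
class AncestralPanel:
    """Ancestry-specific allele frequencies at ordered SNP positions."""

    allele_freqs: np.ndarray  # S x K
    positions_bp: np.ndarray  # 1-based, strictly increasing
    snp_ids: tuple[str, ...]
    labels: tuple[str, ...] = ANCESTRIES
    genetic_map: GeneticMap = field(default_factory=GeneticMap)

    def __post_init__(self):
        f = np.asarray(self.allele_freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] < 2:
            raise ValueError("allele_freqs must be S x K with K >= 2")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("SNP positions must be strictly increasing")
        if f.shape[0] != len(self.positions_bp) or f.shape[0] != len(self.snp_ids):
            raise ValueError("allele_freqs, positions and ids must agree in length")

    @property
    def n_snps(self) -> int:
        return self.allele_freqs.shape[0]

    @property
    def positions_m(self) -> np.ndarray:
        return self.genetic_map.bp_to_morgans(self.positions_bp)


def default_panel(
    n_snps: int = 200,
    length_m: float = 2.0,
    fst: float = 0.2,
    seed: int = 0,
    duffy_like: bool = True,
) -> AncestralPanel:
    """Balding–Nichols-style panel: per-population frequencies drawn around a
    shared ancestral frequency with divergence ``fst``.

    With ``duffy_like`` a single fixed-difference SNP (frequency 1 in AFR, 0
    elsewhere, mirroring the Duffy-null variant) is placed mid-chromosome.
    """
    rng = np.random.default_rng([seed, 101])
    gmap = GeneticMap()
    length_bp = int(gmap.morgans_to_bp(length_m)) - 1
    pos = np.sort(rng.choice(np.arange(1, length_bp), size=n_snps, replace=False))
    p0 = rng.uniform(0.05, 0.95, size=n_snps)
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    freqs = rng.beta(a[:, None], b[:, None], size=(n_snps, len(ANCESTRIES)))
    ids = [f"rs{i:06d}" for i in range(n_snps)]
    if duffy_like:
        j = n_snps // 2
        freqs[j] = [1.0, 0.0, 0.0]
        ids[j] = "rs_duffy_like"
    return AncestralPanel(freqs, pos, tuple(ids), ANCESTRIES, gmap)


# ---------------------------------------------------------------------------
# ethnic groups


@dataclass(frozen=True)
class EthnicityProfile:
    """An ethnic group's global-ancestry Dirichlet and its size."""

    label: str
    dirichlet_alpha: np.ndarray
    n: int

    def __post_init__(self):
        a = np.asarray(self.dirichlet_alpha, dtype=float)
        if np.any(a <= 0):
            raise ValueError("dirichlet_alpha components must be strictly positive")
        if self.n < 0:
            raise ValueError("group size must be nonnegative")

    @property
    def mean(self) -> np.ndarray:
        a = np.asarray(self.dirichlet_alpha, dtype=float)
        return a / a.sum()


def ethnicity_profile(label: str, n: int | None = None, concentration: float = 30.0) -> EthnicityProfile:
    """Default profile for one of the four built-in ethnic groups."""
    mean = np.asarray(_GROUP_MEANS[label], dtype=float)
    mean = mean / mean.sum()
    return EthnicityProfile(label, mean * concentration, _GROUP_N[label] if n is None else n)


def default_profiles(concentration: float = 30.0) -> list[EthnicityProfile]:
    return [ethnicity_profile(g, concentration=concentration) for g in _GROUP_N]


def simulate_global_ancestry(
    profile: EthnicityProfile, n: int | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw n global-ancestry vectors from the group's Dirichlet."""
    rng = np.random.default_rng() if rng is None else rng
    n = profile.n if n is None else n
    return rng.dirichlet(np.asarray(profile.dirichlet_alpha, dtype=float), size=n)


# ---------------------------------------------------------------------------
# tracts and genotypes


def simulate_local_tracts(
    q: np.ndarray, length_m: float, generations: float, rng: np.random.Generator
) -> HaplotypeTracts:
    """One haplotype's ancestry mosaic under a Markov admixture model.

    Switch points form a Poisson process of rate ``generations`` per Morgan;
    the state after each switch (and the initial state) is drawn from the
    individual's global ancestry ``q``.  Same-state switches are admitted, so
    mean inter-switch distance is exactly 1/G and the stationary ancestry
    distribution is q.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-8:
        raise ValueError("q must be a probability vector")
    if generations < 0:
        raise ValueError("generations must be nonnegative")
    if length_m <= 0:
        raise ValueError("length must be positive")
    n_switch = rng.poisson(generations * length_m)
    cuts = np.sort(rng.uniform(0.0, length_m, size=n_switch))
    starts = np.concatenate([[0.0], cuts])
    ends = np.concatenate([cuts, [length_m]])
    states = rng.choice(len(q), size=n_switch + 1, p=q)
    return HaplotypeTracts(starts, ends, states)


def simulate_cohort_tracts(
    q_matrix: np.ndarray,
    length_m: float,
    generations: float,
    rng: np.random.Generator,
    labels: tuple[str, ...] = ANCESTRIES,
    sample_ids: list[str] | None = None,
    genetic_map: GeneticMap | None = None,
) -> LocalAncestryMatrix:
    """Two independent haplotypes per individual."""
    haps = [
        (
            simulate_local_tracts(q, length_m, generations, rng),
            simulate_local_tracts(q, length_m, generations, rng),
        )
        for q in np.asarray(q_matrix, dtype=float)
    ]
    return LocalAncestryMatrix(haps, labels, sample_ids, genetic_map or GeneticMap())


def simulate_genotypes(
    local: LocalAncestryMatrix, panel: AncestralPanel, rng: np.random.Generator
) -> GenotypeMatrix:
    """Dosages: each haplotype's allele is Bernoulli with the frequency of
    its local ancestry at the SNP."""
    pos_m = panel.positions_m
    length = local.haplotypes[0][0].ends[-1]
    if np.any(pos_m < 0) or np.any(pos_m > length):
        raise ValueError("SNP positions fall outside the simulated interval")
    n, s = local.n, panel.n_snps
    dosage = np.zeros((n, s), dtype=np.int8)
    freqs = panel.allele_freqs
    for i, (h1, h2) in enumerate(local.haplotypes):
        for h in (h1, h2):
            states = h.state_at(pos_m)
            dosage[i] += rng.random(s) < freqs[np.arange(s), states]
    dos = pd.DataFrame(dosage, index=local.sample_ids, columns=list(panel.snp_ids), dtype=float)
    pos_bp = pd.Series(panel.positions_bp, index=list(panel.snp_ids))
    pos_mor = pd.Series(pos_m, index=list(panel.snp_ids))
    return GenotypeMatrix(dos, pos_bp, pos_mor)


# ---------------------------------------------------------------------------
# methylation truth + generation


@dataclass
class SimulationTruth:
    """Per-CpG generative effects and per-individual latent variables."""

    cpg_ids: list[str]
    cpg_pos_bp: np.ndarray
    intercept: np.ndarray  # p
    meqtl_snp: np.ndarray  # p, SNP index or -1
    meqtl_effect: np.ndarray  # p, M units per allele
    theta: np.ndarray  # p x K, M units per unit global-ancestry proportion
    env: np.ndarray  # p x G, M units per ethnic group
    cell_delta: np.ndarray  # p x C
    noise_sd: np.ndarray  # p
    group_order: list[str]
    q: pd.DataFrame  # n x K true global ancestry
    cell_props: pd.DataFrame  # n x C true cell proportions

    def __post_init__(self):
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise sd must be strictly positive")
        if not np.allclose(self.q.to_numpy().sum(axis=1), 1.0):
            raise ValueError("true global ancestry must sum to 1 per individual")

    @property
    def ancestry_cpgs(self) -> np.ndarray:
        return np.flatnonzero(np.any(self.theta != 0, axis=1))

    @property
    def env_cpgs(self) -> np.ndarray:
        return np.flatnonzero(np.any(self.env != 0, axis=1))

    @property
    def meqtl_cpgs(self) -> np.ndarray:
        return np.flatnonzero(self.meqtl_snp >= 0)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    profiles: list[EthnicityProfile] = field(default_factory=default_profiles)
    n_snps: int = 200
    n_cpgs: int = 500
    length_m: float = 2.0
    generations: float = 8.0
    fst: float = 0.2
    duffy_like: bool = True
    duffy_effect: float = 1.35  # M units per allele at the fixed-difference meQTL
    n_meqtl: int = 40
    meqtl_effect: float = 1.0
    n_ancestry_cpgs: int = 50
    theta_effect: float = 1.0
    theta_component: str | None = None  # None: AFR or NAM at random per CpG
    n_env_cpgs: int = 50
    env_effect: float = 0.5
    env_group: str = "PuertoRican"
    noise_sd: float = 0.45
    cell_frac: float = 0.2
    cell_effect_sd: float = 2.0
    n_plates: int = 8
    plate_effect_sd: float = 0.05
    site_effect: float = 0.0  # optional recruitment-site batch shift, M units
    detection_fail_rate: float = 0.002
    cell_concentration: float = 200.0
    n_cell_ref_probes: int = 100

    @property
    def n(self) -> int:
        return sum(p.n for p in self.profiles)


@dataclass
class SimulatedStudy:
    """Everything one synthetic run produced, including the truth record."""

    config: SimulationConfig
    seed: int
    panel: AncestralPanel
    samples: pd.DataFrame
    local: LocalAncestryMatrix
    genotypes: GenotypeMatrix
    meth: MethylationMatrix
    truth: SimulationTruth
    cell_reference: CellReference
    cell_probe_meth: MethylationMatrix

    @property
    def ancestry_true(self) -> pd.DataFrame:
        return self.truth.q

    def m_values(self) -> MethylationMatrix:
        return self.meth.to_m()


def _draw_samples(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for prof in config.profiles:
        for _ in range(prof.n):
            g = prof.label
            sites, probs = zip(*_SITE_DIST.get(g, {"Chicago": 1.0}).items())
            probs = np.asarray(probs, dtype=float)
            rows.append(
                {
                    "sample_id": f"S{i:04d}",
                    "ethnicity": g,
                    "age": float(np.clip(rng.normal(12.0, 2.5), 8, 21)),
                    "sex": rng.choice(["F", "M"]),
                    "case": int(rng.random() < _CASE_RATE.get(g, 0.5)),
                    "site": rng.choice(sites, p=probs / probs.sum()),
                    "plate": f"P{rng.integers(config.n_plates) + 1}",
                    "position": f"R{rng.integers(12) + 1:02d}",
                }
            )
            i += 1
    return pd.DataFrame(rows).set_index("sample_id")


def _draw_truth(
    config: SimulationConfig,
    panel: AncestralPanel,
    q: pd.DataFrame,
    cells: pd.DataFrame,
    rng: np.random.Generator,
) -> SimulationTruth:
    p = config.n_cpgs
    k = len(ANCESTRIES)
    groups = [prof.label for prof in config.profiles]
    gmap = panel.genetic_map
    length_bp = int(gmap.morgans_to_bp(config.length_m)) - 1
    pos = np.sort(rng.choice(np.arange(1, length_bp), size=p, replace=False))
    ids = [f"cg{i:06d}" for i in range(p)]

    intercept = rng.choice([-2.5, 2.5], size=p) + rng.normal(0, 1.0, size=p)
    meqtl_snp = np.full(p, -1, dtype=int)
    meqtl_eff = np.zeros(p)
    theta = np.zeros((p, k))
    env = np.zeros((p, len(groups)))
    cell_delta = np.zeros((p, len(CELL_TYPES)))
    noise_sd = np.full(p, config.noise_sd)

    # disjoint effect classes so each CpG has a single known architecture
    idx = rng.permutation(p)
    n_eff = config.n_meqtl + config.n_ancestry_cpgs + config.n_env_cpgs
    if n_eff > p:
        raise ValueError("more effect CpGs requested than CpGs simulated")
    meqtl_idx = idx[: config.n_meqtl]
    anc_idx = idx[config.n_meqtl : config.n_meqtl + config.n_ancestry_cpgs]
    env_idx = idx[config.n_meqtl + config.n_ancestry_cpgs : n_eff]

    if config.n_meqtl:
        snp_choice = rng.integers(panel.n_snps, size=config.n_meqtl)
        meqtl_snp[meqtl_idx] = snp_choice
        meqtl_eff[meqtl_idx] = config.meqtl_effect * rng.choice([-1, 1], size=config.n_meqtl)
        # place each meQTL CpG near its SNP (cis): within 5 kb
        pos[meqtl_idx] = np.clip(
            panel.positions_bp[snp_choice] + rng.integers(-5000, 5000, size=config.n_meqtl),
            1,
            length_bp,
        )
    # ancestry-effect CpGs: effect loaded on AFR or NAM (EUR the reference)
    for j in anc_idx:
        if config.theta_component is None:
            comp = rng.choice([0, 2])
        else:
            comp = ANCESTRIES.index(config.theta_component)
        theta[j, comp] = config.theta_effect * rng.choice([-1, 1])
    # environment: shift one ethnic group relative to the others
    g_env = groups.index(config.env_group) if config.env_group in groups else 0
    env[env_idx, g_env] = config.env_effect * rng.choice([-1, 1], size=len(env_idx))

    n_cell = int(round(config.cell_frac * p))
    cell_idx = rng.choice(p, size=n_cell, replace=False)
    cell_delta[cell_idx] = rng.normal(0, config.cell_effect_sd, size=(n_cell, len(CELL_TYPES)))

    if config.duffy_like and "rs_duffy_like" in panel.snp_ids:
        s = panel.snp_ids.index("rs_duffy_like")
        # dedicated CpG 212 bp from the fixed-difference SNP, pure cis meQTL
        j = int(np.argmin(np.abs(pos - panel.positions_bp[s])))
        pos[j] = panel.positions_bp[s] + 212
        ids[j] = "cg_duffy_like"
        meqtl_snp[j], meqtl_eff[j] = s, config.duffy_effect
        theta[j] = 0.0
        env[j] = 0.0
        cell_delta[j] = 0.0

    order = np.argsort(pos, kind="stable")
    return SimulationTruth(
        cpg_ids=[ids[i] for i in order],
        cpg_pos_bp=pos[order],
        intercept=intercept[order],
        meqtl_snp=meqtl_snp[order],
        meqtl_effect=meqtl_eff[order],
        theta=theta[order],
        env=env[order],
        cell_delta=cell_delta[order],
        noise_sd=noise_sd[order],
        group_order=groups,
        q=q,
        cell_props=cells,
    )


def simulate_methylation(
    samples: pd.DataFrame,
    genotypes: GenotypeMatrix,
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    detection_rng: np.random.Generator | None = None,
) -> MethylationMatrix:
    """Generate beta-scale methylation plus detection p-values from the
    linear M-scale generative model."""
    n = len(samples)
    p = len(truth.cpg_ids)
    missing = [s for s in pd.unique(truth.meqtl_snp[truth.meqtl_snp >= 0]) if s >= genotypes.dosages.shape[1]]
    if missing:
        raise ValueError(f"meQTL references SNP index outside genotype matrix: {missing}")

    M = np.tile(truth.intercept, (n, 1))
    M += truth.cell_props.loc[samples.index].to_numpy() @ truth.cell_delta.T
    M += truth.q.loc[samples.index].to_numpy() @ truth.theta.T
    group_mat = np.stack(
        [(samples["ethnicity"] == g).to_numpy(float) for g in truth.group_order], axis=1
    )
    M += group_mat @ truth.env.T
    has_qtl = truth.meqtl_snp >= 0
    if has_qtl.any():
        dos = genotypes.dosages.loc[samples.index].to_numpy()
        M[:, has_qtl] += dos[:, truth.meqtl_snp[has_qtl]] * truth.meqtl_effect[has_qtl]
    plates = pd.get_dummies(samples["plate"]).to_numpy(float)
    plate_eff = rng.normal(0, config.plate_effect_sd, size=(plates.shape[1], p))
    M += plates @ plate_eff
    if config.site_effect:
        sites = pd.get_dummies(samples["site"]).to_numpy(float)
        M += sites @ rng.normal(0, config.site_effect, size=(sites.shape[1], p))
    M += rng.normal(0, 1.0, size=(n, p)) * truth.noise_sd

    det_rng = rng if detection_rng is None else detection_rng
    det = det_rng.uniform(0, 0.005, size=(n, p))
    failed = det_rng.random(p) < config.detection_fail_rate
    if failed.any():
        det[:, failed] = det_rng.uniform(0.02, 1.0, size=(n, int(failed.sum())))

    beta = pd.DataFrame(m_to_beta(M), index=samples.index, columns=truth.cpg_ids)
    manifest = pd.DataFrame(
        {"chrom": "chr1", "pos": truth.cpg_pos_bp}, index=pd.Index(truth.cpg_ids, name="probe_id")
    )
    det_df = pd.DataFrame(det, index=samples.index, columns=truth.cpg_ids)
    return MethylationMatrix(beta, scale="beta", manifest=manifest, detection_p=det_df)


def _simulate_cell_reference(
    cells: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> tuple[CellReference, MethylationMatrix]:
    """Discriminating-probe reference panel plus the cohort's methylation at
    those probes (mixture of the profiles + noise)."""
    probes = [f"cellref{i:04d}" for i in range(config.n_cell_ref_probes)]
    base = rng.normal(0, 2.0, size=config.n_cell_ref_probes)
    W = base + rng.normal(0, 2.0, size=(len(CELL_TYPES), config.n_cell_ref_probes))
    ref = CellReference(pd.DataFrame(W, index=list(CELL_TYPES), columns=probes))
    mix = cells.to_numpy() @ W + rng.normal(0, 0.1, size=(len(cells), len(probes)))
    meth = MethylationMatrix(
        pd.DataFrame(mix, index=cells.index, columns=probes),
        scale="m",
        manifest=pd.DataFrame(
            {"chrom": "chr0", "pos": np.arange(1, len(probes) + 1)},
            index=pd.Index(probes, name="probe_id"),
        ),
    )
    return ref, meth


def simulate_study(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedStudy:
    """Run the full generator; every stage uses an independent substream of
    ``seed``, so repeated calls are bit-identical."""
    config = config or SimulationConfig()
    panel = default_panel(
        n_snps=config.n_snps,
        length_m=config.length_m,
        fst=config.fst,
        seed=seed,
        duffy_like=config.duffy_like,
    )
    samples = _draw_samples(config, derived_rng(seed, "covariates"))

    rng_q = derived_rng(seed, "ancestry")
    q_blocks = [simulate_global_ancestry(p, rng=rng_q) for p in config.profiles]
    q = pd.DataFrame(np.vstack(q_blocks), index=samples.index, columns=list(ANCESTRIES))

    local = simulate_cohort_tracts(
        q.to_numpy(),
        config.length_m,
        config.generations,
        derived_rng(seed, "tracts"),
        labels=ANCESTRIES,
        sample_ids=list(samples.index),
        genetic_map=panel.genetic_map,
    )
    genotypes = simulate_genotypes(local, panel, derived_rng(seed, "genotypes"))

    rng_cells = derived_rng(seed, "cells")
    alpha = np.asarray(_CELL_MEAN) * config.cell_concentration
    cells = pd.DataFrame(
        rng_cells.dirichlet(alpha, size=len(samples)), index=samples.index, columns=list(CELL_TYPES)
    )
    cell_ref, cell_meth = _simulate_cell_reference(cells, config, rng_cells)

    truth = _draw_truth(config, panel, q, cells, derived_rng(seed, "effects"))
    meth = simulate_methylation(
        samples,
        genotypes,
        truth,
        config,
        derived_rng(seed, "methylation"),
        detection_rng=derived_rng(seed, "detection"),
    )
    return SimulatedStudy(
        config=config,
        seed=seed,
        panel=panel,
        samples=samples,
        local=local,
        genotypes=genotypes,
        meth=meth,
        truth=truth,
        cell_reference=cell_ref,
        cell_probe_meth=cell_meth,
    )
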