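"""Local-ancestry representation and queries.

In an admixed individual each haplotype is a mosaic of tracts inherited from
the ancestral populations (here African, European, Native American).  This
module stores those tracts, derives *global* ancestry (genome-wide
proportions) as the length-weighted average of the tract states, and
interpolates diploid ancestry *dosage* at arbitrary coordinates (e.g. CpG
sites that sit between the SNPs at which ancestry was called).  Ancestry
linkage decays with genetic distance, so interpolation works in genetic
(Morgan) coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import GeneticMap

__all__ = [
    "HaplotypeTracts",
    "LocalAncestryMatrix",
    "global_from_local",
    "dosage_cube",
    "interpolate_at",
]


@dataclass(frozen=True)
class HaplotypeTracts:
    """Ordered ancestry tracts of one haplotype on [0, L) Morgans.

    ``starts``/``ends`` are 0-based half-open genetic coordinates;
    ``states`` are integer ancestry codes.  Tracts must tile the interval
    without gaps or overlaps (adjacent tracts of equal state are allowed).
    """

    starts: np.ndarray
    ends: np.ndarray
    states: np.ndarray

    def __post_init__(self):
        if len(self.starts) == 0:
            raise ValueError("haplotype must carry at least one tract")
        if not (
            np.all(self.ends > self.starts)
            and np.allclose(self.starts[1:], self.ends[:-1])
        ):
            raise ValueError("tracts must tile the interval without gaps or overlap")

    @property
    def length(self) -> float:
        return float(self.ends[-1] - self.starts[0])

    def state_at(self, pos_m) -> np.ndarray:
        """Ancestry code at genetic position(s) in [0, L)."""
        pos_m = np.asarray(pos_m, dtype=float)
        idx = np.searchsorted(self.ends, pos_m, side="right")
        idx = np.clip(idx, 0, len(self.states) - 1)
        return self.states[idx]

    def proportions(self, k: int) -> np.ndarray:
        """Length-weighted ancestry fractions (length k)."""
        out = np.zeros(k)
        np.add.at(out, self.states, self.ends - self.starts)
        return out / self.length


@dataclass
class LocalAncestryMatrix:
    """Per-individual diploid local ancestry: two tract mosaics each.

    ``labels`` orders the K ancestries; diploid dosage at any position sums
    to 2 over K.
    """

    haplotypes: list[tuple[HaplotypeTracts, HaplotypeTracts]]
    labels: tuple[str, ...]
    sample_ids: list[str] | None = None
    genetic_map: GeneticMap = field(default_factory=GeneticMap)

    def __post_init__(self):
        if self.sample_ids is None:
            self.sample_ids = [f"S{i:04d}" for i in range(len(self.haplotypes))]

    @property
    def n(self) -> int:
        return len(self.haplotypes)

    @property
    def k(self) -> int:
        return len(self.labels)

    def dosage_at(self, pos_m: float) -> pd.DataFrame:
        """Diploid ancestry dosage (n x K, entries in {0,1,2}) at one
        genetic position."""
        out = np.zeros((self.n, self.k))
        for i, (h1, h2) in enumerate(self.haplotypes):
            out[i, int(h1.state_at(pos_m))] += 1
            out[i, int(h2.state_at(pos_m))] += 1
        return pd.DataFrame(out, index=self.sample_ids, columns=self.labels)

    def dosage_at_bp(self, pos_bp: float) -> pd.DataFrame:
        return self.dosage_at(float(self.genetic_map.bp_to_morgans(pos_bp)))

    def global_proportions(self) -> pd.DataFrame:
        return global_from_local(self)


def global_from_local(local: LocalAncestryMatrix) -> pd.DataFrame:
    """Global ancestry = length-weighted mean tract ancestry over both
    haplotypes; rows sum to 1."""
    out = np.zeros((local.n, local.k))
    for i, (h1, h2) in enumerate(local.haplotypes):
        out[i] = (h1.proportions(local.k) + h2.proportions(local.k)) / 2.0
    return pd.DataFrame(out, index=local.sample_ids, columns=local.labels)


def dosage_cube(local: LocalAncestryMatrix, positions_m: np.ndarray) -> np.ndarray:
    """Diploid dosage at many positions: (n individuals x S positions x K).

    This is the per-SNP local-ancestry call matrix from which dosage at CpG
    coordinates is interpolated.
    """
    positions_m = np.asarray(positions_m, dtype=float)
    out = np.zeros((local.n, len(positions_m), local.k))
    rows = np.arange(len(positions_m))
    for i, (h1, h2) in enumerate(local.haplotypes):
        out[i, rows, h1.state_at(positions_m)] += 1
        out[i, rows, h2.state_at(positions_m)] += 1
    return out


def interpolate_at(snp_dosages: np.ndarray, positions_m: np.ndarray, query_m: float) -> np.ndarray:
    """Interpolate diploid ancestry dosage at a query coordinate.

    ``snp_dosages`` is (S x K) for one individual or (n x S x K) for a
    cohort; ``positions_m`` the S SNP genetic positions, strictly
    increasing.  Between SNPs whose dosages agree the shared dosage is
    returned; where they disagree, dosage is linearly interpolated by
    genetic distance (agreement is the w=0/1 limit of the same rule).
    Queries outside the SNP range take the nearest SNP's dosage.
    """
    positions_m = np.asarray(positions_m, dtype=float)
    if len(positions_m) == 0:
        raise ValueError("at least one SNP required")
    if np.any(np.diff(positions_m) <= 0):
        raise ValueError("SNP positions must be strictly increasing")
    d = np.asarray(snp_dosages, dtype=float)
    if query_m <= positions_m[0]:
        return d[..., 0, :].copy()
    if query_m >= positions_m[-1]:
        return d[..., -1, :].copy()
    right = int(np.searchsorted(positions_m, query_m, side="left"))
    if positions_m[right] == query_m:
        return d[..., right, :].copy()
    left = right - 1
    span = positions_m[right] - positions_m[left]
    w = (query_m - positions_m[left]) / span
    return (1.0 - w) * d[..., left, :] + w * d[..., right, :]
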