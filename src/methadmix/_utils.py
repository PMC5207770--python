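"""Shared helpers: seeded RNG derivation and the physical<->genetic map."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# fixed stage tags so that each pipeline stage gets an independent,
# reproducible substream of the master seed
STAGE_TAGS = {
    "ancestry": 11,
    "tracts": 12,
    "genotypes": 13,
    "cells": 14,
    "methylation": 15,
    "covariates": 16,
    "detection": 17,
    "effects": 18,
    "mediation": 19,
    "downsample": 20,
}


def derived_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named stage, deterministic in (seed, stage)."""
    return np.random.default_rng([int(seed), STAGE_TAGS[stage]])


@dataclass(frozen=True)
class GeneticMap:
    """Linear physical<->genetic map (default 1 cM/Mb).

    Positions are 1-based base pairs; genetic coordinates are Morgans with
    bp 1 mapping to 0 M.
    """

    cm_per_mb: float = 1.0

    def bp_to_morgans(self, pos_bp):
        return (np.asarray(pos_bp, dtype=float) - 1.0) * self.cm_per_mb * 1e-8

    def morgans_to_bp(self, pos_m):
        return np.asarray(pos_m, dtype=float) / (self.cm_per_mb * 1e-8) + 1.0
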