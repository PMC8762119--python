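"""Marker ascertainment: the target variant universe and scaffold selection.

Builds the set of imputable variants (biallelic, minor-allele frequency at
least ``maf_min`` in the target individuals) and then selects the observed
scaffold markers for a density level under one of two schemes:

* ``chip``  -- deterministic, evenly spaced in site rank, emulating a SNP
  array whose markers tile the chromosome;
* ``lcwgs`` -- a uniform random subset, emulating the variant set recovered
  from low-coverage whole-genome sequencing.

The remaining (hidden) universe sites are the imputation targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from imputesim.demography import HaplotypePanel

__all__ = [
    "VariantTable",
    "MarkerSelection",
    "AscertainmentError",
    "compute_maf",
    "filter_target_universe",
    "marker_count",
    "select_evenly_spaced",
    "select_random",
    "mask_panel",
]

DENSITY_LEVELS = (0.01, 0.05, 0.10, 0.30, 0.50, 0.90)


class AscertainmentError(ValueError):
    """Invalid ascertainment input."""


@dataclass
class VariantTable:
    """Candidate variant universe: panel site indices with target-population MAF."""

    site_indices: np.ndarray  # indices into the source panel's site axis
    positions: np.ndarray  # bp, strictly increasing
    maf: np.ndarray  # minor-allele frequency in the target individuals
    biallelic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.site_indices = np.asarray(self.site_indices, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.biallelic is None:
            self.biallelic = np.ones(len(self.site_indices), dtype=bool)
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise AscertainmentError("positions must be strictly increasing")
        if np.any((self.maf < 0) | (self.maf > 0.5)):
            raise AscertainmentError("MAF must lie in [0, 0.5]")

    def __len__(self) -> int:
        return len(self.site_indices)


@dataclass
class MarkerSelection:
    """Observed scaffold sites and hidden imputation targets for one density.

    ``observed`` and ``hidden`` partition the variant universe; both hold
    panel site indices, sorted.
    """

    scheme: str  # "chip" | "lcwgs"
    proportion: float
    observed: np.ndarray
    hidden: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("chip", "lcwgs"):
            raise AscertainmentError(f"unknown scheme {self.scheme!r}")
        self.observed = np.asarray(self.observed, dtype=np.int64)
        self.hidden = np.asarray(self.hidden, dtype=np.int64)
        if np.intersect1d(self.observed, self.hidden).size:
            raise AscertainmentError("observed and hidden sets overlap")


def compute_maf(genotypes) -> float:
    """Minor-allele frequency from diploid 0/1/2 genotypes at one site."""
    g = np.asarray(genotypes)
    if g.size == 0:
        raise AscertainmentError("cannot compute MAF of an empty genotype vector")
    if np.any((g < 0) | (g > 2)):
        raise AscertainmentError("genotypes must be coded 0/1/2")
    f = float(g.sum()) / (2 * g.size)
    return min(f, 1.0 - f)


def filter_target_universe(
    panel: HaplotypePanel,
    target_population,
    maf_min: float = 0.01,
    *,
    target_individuals=None,
) -> VariantTable:
    """Variants with MAF >= ``maf_min`` among the target individuals.

    The frequency filter uses only the target population (by default every
    individual labelled ``target_population``; pass ``target_individuals`` to
    restrict to an explicit subset, e.g. the designated target cohort).
    All simulated sites are biallelic by the infinite-sites construction.
    """
    if target_individuals is None:
        target_individuals = panel.individuals_of(target_population)
        if target_individuals.size == 0:
            raise AscertainmentError(f"unknown or unsampled population {target_population!r}")
    idx = np.asarray(target_individuals, dtype=np.int64)
    geno = panel.genotypes()[idx]  # individuals x sites
    f = geno.sum(axis=0) / (2.0 * len(idx))
    maf = np.minimum(f, 1.0 - f)
    keep = np.flatnonzero(maf >= maf_min)
    return VariantTable(
        site_indices=keep,
        positions=panel.positions[keep],
        maf=maf[keep],
    )


def marker_count(total_sites: int, proportion: float) -> int:
    """Number of scaffold markers at a density level: floor(proportion * total)."""
    if total_sites < 0:
        raise AscertainmentError("total_sites must be >= 0")
    if not (0 < proportion <= 1):
        raise AscertainmentError("proportion must lie in (0, 1]")
    return math.floor(proportion * total_sites)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def select_evenly_spaced(variants: VariantTable, count: int) -> MarkerSelection:
    """Chip-style scaffold: markers evenly spaced in site rank.

    Deterministic: rank ``j`` maps to index ``round_half_up(j*(S-1)/(count-1))``;
    a single marker selects the first site.  Rank spacing (not bp spacing) is
    density-exact; index collisions in degenerate cases advance to the next
    unused index.
    """
    S = len(variants)
    if not (1 <= count <= S):
        raise AscertainmentError(f"count must lie in [1, {S}], got {count}")
    if count == 1:
        chosen = np.array([0], dtype=np.int64)
    else:
        used: set[int] = set()
        chosen_list: list[int] = []
        for j in range(count):
            k = _round_half_up(j * (S - 1) / (count - 1))
            while k in used:
                k += 1
            used.add(k)
            chosen_list.append(k)
        chosen = np.sort(np.array(chosen_list, dtype=np.int64))
    observed = variants.site_indices[chosen]
    hidden = np.setdiff1d(variants.site_indices, observed)
    return MarkerSelection("chip", count / S, observed, hidden)


def select_random(variants: VariantTable, count: int, seed: int) -> MarkerSelection:
    """LCWGS-style scaffold: a uniform random subset of the universe."""
    S = len(variants)
    if not (1 <= count <= S):
        raise AscertainmentError(f"count must lie in [1, {S}], got {count}")
    rng = np.random.Generator(np.random.PCG64(seed))
    chosen = np.sort(rng.choice(S, size=count, replace=False))
    observed = variants.site_indices[chosen]
    hidden = np.setdiff1d(variants.site_indices, observed)
    return MarkerSelection("lcwgs", count / S, observed, hidden, seed=seed)


def mask_panel(panel: HaplotypePanel, selection: MarkerSelection):
    """Split a panel into the observed scaffold and the hidden truth panel."""
    all_idx = np.concatenate([selection.observed, selection.hidden])
    if all_idx.size and (all_idx.min() < 0 or all_idx.max() >= panel.n_sites):
        raise AscertainmentError("selection indices out of range for panel")
    scaffold = panel.subset_sites(selection.observed)
    truth = panel.subset_sites(selection.hidden)
    return scaffold, truth
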