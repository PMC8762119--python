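"""Factorial experiment runner: simulate -> ascertain -> impute -> evaluate.

The benchmark design crosses five factors: imputation reference population
(P1..P4, ordered by genetic distance from the target cohort), reference
panel size, scaffold density (proportion of universe variants observed),
ascertainment scheme (chip = evenly spaced, lcwgs = random) and imputation
method.  The published grid has 14 population/size combinations x 6
densities x 2 methods x 2 schemes = 336 scenarios.

Full-scale simulation (20,000 diploids x 10 Mb) is cluster-sized, so runs
are organized through scale profiles: the ``desk`` profile keeps the same
demography on a shorter chromosome with proportionally mapped sample and
reference sizes, preserving every factor contrast at workstation cost.
The target cohort is fixed (the first individuals of P1) across scenarios,
and reference individuals never overlap it.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from imputesim import accuracy as acc
from imputesim.ascertainment import (
    DENSITY_LEVELS,
    filter_target_universe,
    marker_count,
    mask_panel,
    select_evenly_spaced,
    select_random,
)
from imputesim.demography import DemographicModel, HaplotypePanel, pig_demography_model, simulate_panel
from imputesim.imputation import HMMParams, ImputationResult, ReferencePanel, impute_panel

__all__ = [
    "ScenarioSpec",
    "GridSpec",
    "ScenarioResult",
    "ScaleProfile",
    "RunnerError",
    "FULL_PROFILE",
    "DESK_PROFILE",
    "BENCHMARK_SIZE_LEVELS",
    "build_benchmark_grid",
    "desk_reference_size",
    "simulate_profile_panel",
    "run_scenario",
    "run_grid",
    "summarize",
]

logger = logging.getLogger("imputesim")

BENCHMARK_SIZE_LEVELS = {
    "P1": (100, 1_000, 3_000, 5_000, 10_000),
    "P2": (100, 1_000, 3_000),
    "P3": (100, 1_000, 3_000),
    "P4": (100, 1_000, 3_000),
}

_FULL_SAMPLES = {"P1": 11_000, "P2": 3_000, "P3": 3_000, "P4": 3_000}


class RunnerError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """One factorial cell of the benchmark design."""

    reference_population: str
    reference_size: int  # full-scale level; mapped down under a desk profile
    proportion: float
    scheme: str  # "chip" | "lcwgs"
    method: str = "internal-ls"  # or "external:<command template>"
    seed: int = 0

    def key(self) -> tuple:
        return (
            self.reference_population,
            self.reference_size,
            self.proportion,
            self.scheme,
            self.method,
        )


@dataclass(frozen=True)
class ScaleProfile:
    """Sample sizes and sequence length of a run scale."""

    name: str
    samples: dict
    sequence_length: float
    n_targets: int

    def model(self, base: DemographicModel | None = None) -> DemographicModel:
        m = base if base is not None else pig_demography_model()
        return replace(m, sequence_length=self.sequence_length)


FULL_PROFILE = ScaleProfile("full", dict(_FULL_SAMPLES), 10_000_000, 1_000)
DESK_PROFILE = ScaleProfile(
    "desk", {"P1": 110, "P2": 30, "P3": 30, "P4": 30}, 250_000, 25
)


@dataclass
class GridSpec:
    """The scenario list plus the scale profile it is meant to run under."""

    scenarios: list[ScenarioSpec]
    profile: ScaleProfile = FULL_PROFILE

    def __post_init__(self) -> None:
        keys = [s.key() for s in self.scenarios]
        if len(set(keys)) != len(keys):
            raise RunnerError("duplicate scenario keys in grid")

    def __len__(self) -> int:
        return len(self.scenarios)


def build_benchmark_grid(
    methods=("internal-ls", "internal-ls-dosage"),
    schemes=("chip", "lcwgs"),
    *,
    densities=DENSITY_LEVELS,
    base_seed: int = 0,
    profile: ScaleProfile = FULL_PROFILE,
) -> GridSpec:
    """Enumerate the full factorial grid (336 scenarios at the benchmark levels).

    Population/size pairs follow the published levels (five sizes for P1,
    three for each of P2-P4); every combination with each density, scheme
    and method becomes one scenario with a deterministically derived seed.
    """
    scenarios = []
    idx = 0
    for pop, sizes in BENCHMARK_SIZE_LEVELS.items():
        for size in sizes:
            for prop in densities:
                for method in methods:
                    for scheme in schemes:
                        scenarios.append(
                            ScenarioSpec(
                                reference_population=pop,
                                reference_size=size,
                                proportion=prop,
                                scheme=scheme,
                                method=method,
                                seed=(base_seed * 1_000_003 + idx) % (2**31 - 1),
                            )
                        )
                        idx += 1
    return GridSpec(scenarios=scenarios, profile=profile)


def desk_reference_size(full_size: int, population: str, profile: ScaleProfile) -> int:
    """Map a full-scale reference size level onto a scaled panel.

    Proportional to the fraction of the full-scale pool the level uses,
    floored at 4 diploids and capped at the available non-target pool.
    """
    avail = profile.samples[population] - (profile.n_targets if population == "P1" else 0)
    full_avail = _FULL_SAMPLES[population] - (1_000 if population == "P1" else 0)
    size = max(4, round(full_size * avail / full_avail))
    return min(size, avail)


def simulate_profile_panel(
    profile: ScaleProfile, seed: int, *, model: DemographicModel | None = None,
    engine: str = "internal",
) -> HaplotypePanel:
    """Simulate the shared panel for a profile (one panel serves all scenarios)."""
    m = profile.model(model)
    return simulate_panel(m, profile.samples, seed, engine=engine)


@dataclass
class ScenarioResult:
    """Per-locus accuracy records and cell aggregates for one scenario."""

    spec: ScenarioSpec
    records: pd.DataFrame  # locus, position, maf, r2, error_rate
    mean_r2: float
    mean_error_rate: float
    n_observed: int
    n_hidden: int
    n_targets: int
    n_reference: int
    imputation: ImputationResult | None = None
    wall_time: float = 0.0
    provenance: dict = field(default_factory=dict)

    def row(self) -> dict:
        s = self.spec
        return {
            "reference_population": s.reference_population,
            "reference_size": s.reference_size,
            "proportion": s.proportion,
            "scheme": s.scheme,
            "method": s.method,
            "mean_r2": self.mean_r2,
            "mean_error_rate": self.mean_error_rate,
            "n_observed": self.n_observed,
            "n_hidden": self.n_hidden,
        }


def run_scenario(
    spec: ScenarioSpec,
    panel: HaplotypePanel,
    *,
    profile: ScaleProfile = DESK_PROFILE,
    params: HMMParams | None = None,
    maf_min: float = 0.01,
    keep_imputation: bool = False,
) -> ScenarioResult:
    """Execute one factorial cell on a shared panel.

    The target cohort is the first ``profile.n_targets`` individuals of P1;
    the reference is drawn without replacement from the scenario's
    population, never overlapping the targets, seeded by ``spec.seed``.
    Scaffold markers are selected from the MAF-filtered universe at the
    scenario's density and scheme; hidden sites are imputed with the
    built-in haplotype-copying HMM and scored per locus.  Deterministic
    given ``(panel, spec)``.
    """
    t0 = time.perf_counter()
    p1 = panel.individuals_of("P1")
    if len(p1) < profile.n_targets:
        raise RunnerError(
            f"panel has {len(p1)} P1 individuals; profile needs {profile.n_targets} targets"
        )
    targets = p1[: profile.n_targets]

    pool = np.setdiff1d(panel.individuals_of(spec.reference_population), targets)
    n_ref = (
        spec.reference_size
        if profile.name == "full"
        else desk_reference_size(spec.reference_size, spec.reference_population, profile)
    )
    if n_ref > len(pool):
        raise RunnerError(
            f"reference size {n_ref} exceeds the {len(pool)} available non-target "
            f"individuals of {spec.reference_population}"
        )
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    ref_ids = np.sort(rng.choice(pool, size=n_ref, replace=False))

    universe = filter_target_universe(panel, "P1", maf_min, target_individuals=targets)
    if len(universe) < 2:
        raise RunnerError("fewer than two universe variants after MAF filtering")
    count = max(1, marker_count(len(universe), spec.proportion))
    if spec.scheme == "chip":
        selection = select_evenly_spaced(universe, count)
    else:
        selection = select_random(universe, count, seed=spec.seed)
    if selection.hidden.size == 0:
        raise RunnerError("selection leaves no hidden sites to impute")

    ref_panel_haps = panel.subset_individuals(ref_ids).matrix[:, universe.site_indices]
    reference = ReferencePanel(
        haplotypes=ref_panel_haps, positions=panel.positions[universe.site_indices]
    )
    obs_u = np.searchsorted(universe.site_indices, selection.observed)
    hid_u = np.searchsorted(universe.site_indices, selection.hidden)

    target_hap_idx = np.empty(2 * len(targets), dtype=np.int64)
    target_hap_idx[0::2] = 2 * targets
    target_hap_idx[1::2] = 2 * targets + 1
    scaffold_haps = panel.matrix[target_hap_idx][:, selection.observed]

    if params is None:
        params = HMMParams.from_rates(recombination_rate=1e-7, ne_eff=1600.0)
    if spec.method.startswith("external:"):
        result = _run_external(
            spec, panel, targets, ref_ids, selection, universe
        )
    else:
        result = impute_panel(scaffold_haps, reference, obs_u, hid_u, params)

    truth = panel.genotypes()[np.ix_(targets, selection.hidden)]
    records = acc.per_locus_accuracy(
        result.best_guess, truth, universe.maf[hid_u], positions=result.positions
    )
    if spec.method.endswith("-dosage"):
        # method variant: reliability on dosages; error rate stays allelic
        records["r2"] = acc.per_locus_accuracy(
            result.dosage, truth, universe.maf[hid_u], positions=result.positions
        )["r2"]
    mean_r2 = float(np.nanmean(records["r2"])) if records["r2"].notna().any() else float("nan")
    elapsed = time.perf_counter() - t0
    logger.info(
        "scenario %s: %d obs / %d hidden sites, %d refs, mean r2=%.3f er=%.2f%% (%.2fs)",
        spec.key(), len(selection.observed), len(selection.hidden), n_ref,
        mean_r2, float(records["error_rate"].mean()), elapsed,
    )
    return ScenarioResult(
        spec=spec,
        records=records,
        mean_r2=mean_r2,
        mean_error_rate=float(records["error_rate"].mean()),
        n_observed=int(len(selection.observed)),
        n_hidden=int(len(selection.hidden)),
        n_targets=len(targets),
        n_reference=n_ref,
        imputation=result if keep_imputation else None,
        wall_time=elapsed,
        provenance={
            "seed": spec.seed,
            "panel_seed": panel.seed,
            "model_hash": panel.model_hash,
            "profile": profile.name,
        },
    )


def _run_external(spec, panel, targets, ref_ids, selection, universe):
    """Route a scenario through an external imputer via VCF files."""
    import tempfile
    from pathlib import Path

    from imputesim.imputation import external_imputer_roundtrip
    from imputesim.io import write_vcf

    template = spec.method.split(":", 1)[1]
    with tempfile.TemporaryDirectory() as tmp:
        scaffold_panel, _ = mask_panel(panel.subset_individuals(targets), selection)
        ref_full = panel.subset_individuals(ref_ids).subset_sites(universe.site_indices)
        sc_path = str(Path(tmp) / "scaffold.vcf")
        ref_path = str(Path(tmp) / "reference.vcf")
        write_vcf(scaffold_panel, sc_path)
        write_vcf(ref_full, ref_path)
        return external_imputer_roundtrip(
            sc_path, ref_path, template,
            expected_positions=panel.positions[selection.hidden],
            workdir=tmp,
        )


def run_grid(
    grid: GridSpec,
    panel: HaplotypePanel,
    *,
    params: HMMParams | None = None,
) -> list[ScenarioResult]:
    """Run every scenario of a grid on a shared panel."""
    results = []
    for i, spec in enumerate(grid.scenarios):
        results.append(run_scenario(spec, panel, profile=grid.profile, params=params))
        if (i + 1) % 25 == 0:
            logger.info("grid progress: %d / %d scenarios", i + 1, len(grid))
    return results


# ---------------------------------------------------------------------------
# Summaries: size x density matrices, factor CVs, marginal means
# ---------------------------------------------------------------------------

_FACTORS = ("proportion", "reference_size", "reference_population")
_CRITERIA = {"mean_r2": "reliability", "mean_error_rate": "error_rate"}


def results_table(results) -> pd.DataFrame:
    """Tidy one-row-per-scenario table from results (passes DataFrames through)."""
    if isinstance(results, pd.DataFrame):
        return results.copy()
    if not results:
        raise RunnerError("no results to summarize")
    return pd.DataFrame([r.row() for r in results])


def summarize(results) -> dict:
    """Aggregate scenario results into the benchmark's summary tables.

    Returns a dict with ``grid`` (tidy per-scenario rows), ``reliability``
    and ``error_rate`` (reference size x density matrices per method),
    ``cv`` (factor-level coefficient of variation per method, scheme and
    criterion, with the most influential factor flagged) and
    ``marginal_means`` (factor-level means).  Accepts a list of
    ScenarioResult or an equivalent tidy DataFrame.
    """
    df = results_table(results)
    out: dict = {"grid": df}

    matrices: dict[str, dict] = {"reliability": {}, "error_rate": {}}
    for method, sub in df.groupby("method"):
        if {"reference_size", "proportion"}.issubset(sub.columns):
            for name, col in (("reliability", "mean_r2"), ("error_rate", "mean_error_rate")):
                if col in sub.columns:
                    matrices[name][method] = sub.pivot_table(
                        index="reference_size", columns="proportion", values=col,
                        aggfunc="mean",
                    )
    out["reliability"] = matrices["reliability"]
    out["error_rate"] = matrices["error_rate"]

    cv_rows = []
    mm_rows = []
    group_cols = [c for c in ("method", "scheme") if c in df.columns]
    grouped = df.groupby(group_cols) if group_cols else [((), df)]
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        meta = dict(zip(group_cols, key))
        for crit_col, crit_name in _CRITERIA.items():
            if crit_col not in sub.columns:
                continue
            for factor in _FACTORS:
                if factor not in sub.columns or sub[factor].nunique() < 2:
                    continue
                level_means = sub.groupby(factor)[crit_col].mean()
                mm_rows.extend(
                    {**meta, "criterion": crit_name, "factor": factor,
                     "level": lv, "mean": float(m)}
                    for lv, m in level_means.items()
                )
                cv_rows.append(
                    {**meta, "criterion": crit_name, "factor": factor,
                     "cv": acc.coefficient_of_variation(level_means.to_numpy())}
                )
    cv = pd.DataFrame(cv_rows)
    if not cv.empty:
        flag_cols = group_cols + ["criterion"]
        cv["most_influential"] = (
            cv.groupby(flag_cols)["cv"].transform("max") == cv["cv"]
        )
    out["cv"] = cv
    out["marginal_means"] = pd.DataFrame(mm_rows)
    return out
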