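"""Structured-coalescent simulation of phased haplotype panels.

This module generates the synthetic data for the imputation benchmark: a
multi-population demographic model (constant-size demes joined backward in
time by split events, exchanging migrants at constant pairwise rates) is
simulated under the coalescent with recombination (Hudson's algorithm on the
ancestral recombination graph), and neutral mutations are then overlaid on
the resulting genealogies under the infinite-sites model.

The default parameterization, :func:`pig_demography_model`, describes a pig
demography: an ancestral population P0 from which a chain of populations
P1 -> P2 -> P3 -> P4 successively diverged, with migration between selected
pairs.  The divergence topology is one consistent reading of the published
split times and is configurable; see ``docs/methods.md``.

Coordinates are 0-based half-open ``[a, b)`` in base pairs; time is
continuous and measured in generations before present; coalescence in a deme
of diploid effective size ``N`` occurs at rate ``1/(2N)`` per lineage pair.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Population",
    "DemographicEvent",
    "DemographicModel",
    "SampleSpec",
    "GenealogyForest",
    "HaplotypePanel",
    "pig_demography_model",
    "event_rates",
    "simulate_ancestry",
    "overlay_mutations",
    "simulate_panel",
    "simulate_ancestry_msprime",
    "DemographyError",
]


class DemographyError(ValueError):
    """Invalid demographic model, sample specification, or simulator state."""


# ---------------------------------------------------------------------------
# Model types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Population:
    """A deme with a constant diploid effective size."""

    id: str
    effective_size: float

    def __post_init__(self) -> None:
        if self.effective_size <= 0:
            raise DemographyError(f"population {self.id!r}: effective size must be > 0")


@dataclass(frozen=True)
class DemographicEvent:
    """A demographic event at ``time`` generations before present.

    kind "split": backward in time, all lineages of ``derived`` move into
    ``ancestral`` and the derived deme ceases to exist.
    kind "size_change": ``population`` takes ``size`` from ``time`` backward.
    kind "migration_change": the symmetric pair rate becomes ``rate``.
    """

    time: float
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise DemographyError("event times must be strictly positive")
        if self.kind not in ("split", "size_change", "migration_change"):
            raise DemographyError(f"unknown event kind {self.kind!r}")


def _canon_pop(pid) -> str:
    """Accept 'P3' or bare 3 as a population key."""
    return pid if isinstance(pid, str) else f"P{int(pid)}"


class MigrationRates(dict):
    """Symmetric pairwise migration rates keyed by unordered population pair.

    Keys are normalized so ``rates[(3, 4)]``, ``rates[("P4", "P3")]`` and
    ``rates[("P3", "P4")]`` all address the same entry.
    """

    @staticmethod
    def _key(pair) -> tuple[str, str]:
        a, b = pair
        a, b = _canon_pop(a), _canon_pop(b)
        return (a, b) if a <= b else (b, a)

    def __getitem__(self, pair):
        return dict.__getitem__(self, self._key(pair))

    def __setitem__(self, pair, value):
        if value < 0:
            raise DemographyError("migration rates must be >= 0")
        dict.__setitem__(self, self._key(pair), value)

    def __contains__(self, pair):
        return dict.__contains__(self, self._key(pair))

    def get(self, pair, default=0.0):
        return dict.get(self, self._key(pair), default)


@dataclass
class DemographicModel:
    """Populations, sizes, migration, and the backward-time event schedule."""

    sequence_length: float
    mutation_rate: float
    recombination_rate: float
    populations: list[Population]
    migration_rates: MigrationRates = field(default_factory=MigrationRates)
    events: list[DemographicEvent] = field(default_factory=list)
    origin_time: float | None = None

    def __post_init__(self) -> None:
        if self.sequence_length <= 0:
            raise DemographyError("sequence_length must be > 0")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise DemographyError("mutation and recombination rates must be >= 0")
        ids = [p.id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise DemographyError("duplicate population ids")
        if not isinstance(self.migration_rates, MigrationRates):
            mr = MigrationRates()
            for k, v in dict(self.migration_rates).items():
                mr[k] = v
            self.migration_rates = mr
        known = set(ids)
        for (a, b), v in self.migration_rates.items():
            if a not in known or b not in known:
                raise DemographyError(f"migration pair ({a}, {b}) references unknown population")
            if v < 0:
                raise DemographyError("migration rates must be >= 0")
        self.events = sorted(self.events, key=lambda e: e.time)
        for ev in self.events:
            for key in ("derived", "ancestral", "population"):
                if key in ev.params and _canon_pop(ev.params[key]) not in known:
                    raise DemographyError(f"event references unknown population {ev.params[key]!r}")

    def population(self, pid) -> Population:
        pid = _canon_pop(pid)
        for p in self.populations:
            if p.id == pid:
                return p
        raise DemographyError(f"unknown population {pid!r}")

    def population_ids(self) -> list[str]:
        return [p.id for p in self.populations]

    def check_connected(self, sampled: Sequence[str]) -> None:
        """Verify all sampled demes can reach a common ancestor.

        Demes are connected by split events and by positive migration rates;
        either channel lets lineages eventually share a deme and coalesce.
        """
        parent = {p.id: p.id for p in self.populations}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        for (a, b), rate in self.migration_rates.items():
            if rate > 0:
                union(a, b)
        for ev in self.events:
            if ev.kind == "split":
                union(_canon_pop(ev.params["derived"]), _canon_pop(ev.params["ancestral"]))
        roots = {find(_canon_pop(s)) for s in sampled}
        if len(roots) > 1:
            raise DemographyError(
                "split graph is not connected: sampled populations "
                f"{sorted(sampled)} cannot reach a common ancestral population"
            )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        # numeric fields normalized to float so serialization is type-stable
        return {
            "sequence_length": float(self.sequence_length),
            "mutation_rate": float(self.mutation_rate),
            "recombination_rate": float(self.recombination_rate),
            "populations": [
                {"id": p.id, "effective_size": float(p.effective_size)} for p in self.populations
            ],
            "migration_rates": {f"{a},{b}": float(v) for (a, b), v in sorted(self.migration_rates.items())},
            "events": [
                {"time": float(e.time), "kind": e.kind, "params": dict(e.params)}
                for e in self.events
            ],
            "origin_time": None if self.origin_time is None else float(self.origin_time),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DemographicModel":
        mr = MigrationRates()
        for k, v in d.get("migration_rates", {}).items():
            a, b = k.split(",") if isinstance(k, str) else k
            mr[(a, b)] = float(v)
        return cls(
            sequence_length=float(d["sequence_length"]),
            mutation_rate=float(d["mutation_rate"]),
            recombination_rate=float(d["recombination_rate"]),
            populations=[Population(p["id"], float(p["effective_size"])) for p in d["populations"]],
            migration_rates=mr,
            events=[
                DemographicEvent(float(e["time"]), e["kind"], dict(e.get("params", {})))
                for e in d.get("events", [])
            ],
            origin_time=d.get("origin_time"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DemographicModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def stable_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


class SampleSpec(dict):
    """Per-population diploid sample counts, ``{population id: n diploids}``."""

    def __init__(self, counts: Mapping):
        super().__init__({_canon_pop(k): int(v) for k, v in dict(counts).items()})
        if any(v < 0 for v in self.values()):
            raise DemographyError("sample counts must be >= 0")
        if sum(self.values()) == 0:
            raise DemographyError("at least one population must be sampled")

    def validate_against(self, model: DemographicModel) -> None:
        known = set(model.population_ids())
        for pid in self:
            if pid not in known:
                raise DemographyError(f"sampled population {pid!r} not in model")

    @property
    def n_diploids(self) -> int:
        return sum(self.values())


def pig_demography_model() -> DemographicModel:
    """The four-population pig demography used throughout the benchmark.

    An ancestral population P0 (N0 = 10,873) persists as an unsampled deme;
    P1 (N1 = 1,600) merges into it 9,000 generations ago; P2 (N2 = 1,200)
    splits from P1 3,000 generations ago; P3 (N3 = 1,000) from P2 200
    generations ago; and P4 (N4 = 1,400) from P3 20 generations ago.  The
    simulated chromosome is 10 Mb with mutation and recombination rates of
    1e-7 per bp per generation.  Migration is symmetric between the pairs
    (P0,P1), (P1,P2), (P1,P4), (P2,P3), (P3,P4).
    """
    mr = MigrationRates()
    mr[(0, 1)] = 2.1e-5
    mr[(1, 2)] = 1.1e-3
    mr[(1, 4)] = 3.7e-4
    mr[(2, 3)] = 5.2e-5
    mr[(3, 4)] = 1.6e-3
    return DemographicModel(
        sequence_length=10_000_000,
        mutation_rate=1e-7,
        recombination_rate=1e-7,
        populations=[
            Population("P0", 10_873),
            Population("P1", 1_600),
            Population("P2", 1_200),
            Population("P3", 1_000),
            Population("P4", 1_400),
        ],
        migration_rates=mr,
        events=[
            DemographicEvent(20, "split", {"derived": "P4", "ancestral": "P3"}),
            DemographicEvent(200, "split", {"derived": "P3", "ancestral": "P2"}),
            DemographicEvent(3_000, "split", {"derived": "P2", "ancestral": "P1"}),
            DemographicEvent(9_000, "split", {"derived": "P1", "ancestral": "P0"}),
        ],
        origin_time=58_000,
    )


def full_scale_sample_spec() -> SampleSpec:
    """Full-scale sample sizes: 11,000 diploids in P1 and 3,000 in each of P2-P4."""
    return SampleSpec({"P1": 11_000, "P2": 3_000, "P3": 3_000, "P4": 3_000})


# ---------------------------------------------------------------------------
# Event rates (structured-coalescent intensities)
# ---------------------------------------------------------------------------


def event_rates(
    lineage_counts: Mapping[str, int],
    spans: Mapping[str, Sequence[float]],
    model: DemographicModel,
    *,
    sizes: Mapping[str, float] | None = None,
    migration: MigrationRates | None = None,
    active: set[str] | None = None,
) -> dict:
    """Per-generation intensities of coalescence, migration and recombination.

    ``lineage_counts`` maps deme id to the number of extant ancestral
    lineages; ``spans`` maps deme id to the ancestral-material extents
    (rightmost minus leftmost bp) of those lineages.  ``sizes``/``migration``/
    ``active`` override the model's time-zero state (the simulator passes its
    epoch-updated values).

    Returns ``{"coalescence": {deme: rate}, "migration": {(x, y): rate},
    "recombination": total, "total": sum}`` where the coalescence rate in a
    deme with ``k`` lineages and size ``N`` is ``k(k-1)/2 / (2N)`` and the
    migration rate for lineages in ``x`` tracing ancestry into ``y`` is
    ``k_x * m_xy``.
    """
    known = set(model.population_ids())
    if active is None:
        active = known
    if sizes is None:
        sizes = {p.id: p.effective_size for p in model.populations}
    if migration is None:
        migration = model.migration_rates

    coal: dict[str, float] = {}
    for deme, k in lineage_counts.items():
        deme = _canon_pop(deme)
        if deme not in known:
            raise DemographyError(f"unknown population {deme!r}")
        if k < 0:
            raise DemographyError("lineage counts must be >= 0")
        coal[deme] = (k * (k - 1) / 2.0) / (2.0 * sizes[deme])

    mig: dict[tuple[str, str], float] = {}
    for (a, b), rate in migration.items():
        if rate <= 0 or a not in active or b not in active:
            continue
        ka = lineage_counts.get(a, 0)
        kb = lineage_counts.get(b, 0)
        if ka:
            mig[(a, b)] = ka * rate
        if kb:
            mig[(b, a)] = kb * rate

    rec = 0.0
    for deme, deme_spans in spans.items():
        if _canon_pop(deme) not in known:
            raise DemographyError(f"unknown population {deme!r}")
        for s in deme_spans:
            if s < 0:
                raise DemographyError("ancestral spans must be >= 0")
            rec += model.recombination_rate * s

    total = sum(coal.values()) + sum(mig.values()) + rec
    return {"coalescence": coal, "migration": mig, "recombination": rec, "total": total}


# ---------------------------------------------------------------------------
# Ancestry simulation (Hudson's algorithm on the ARG)
# ---------------------------------------------------------------------------

# A lineage is a sorted list of segments (left, right, node, n_leaves):
# the lineage is ancestral to `n_leaves` of the sampled haplotypes over
# [left, right), and `node` is the genealogy node representing that block.


@dataclass
class GenealogyForest:
    """Marginal genealogies along the chromosome, in node/edge table form.

    Nodes ``0 .. n_samples-1`` are the sampled haplotypes (time 0, ordered by
    population then individual; haplotypes ``2k`` and ``2k+1`` form diploid
    ``k``).  Each edge ``(left, right, parent, child)`` states that ``child``
    attaches to ``parent`` over the interval ``[left, right)``.
    """

    node_times: np.ndarray
    edges_left: np.ndarray
    edges_right: np.ndarray
    edges_parent: np.ndarray
    edges_child: np.ndarray
    n_samples: int
    sequence_length: float
    sample_populations: np.ndarray  # per-haplotype population id, length n_samples
    seed: int | None = None
    model_hash: str | None = None

    @property
    def num_edges(self) -> int:
        return len(self.edges_left)

    def breakpoints(self) -> np.ndarray:
        pts = np.unique(np.concatenate([[0.0], self.edges_left, self.edges_right, [self.sequence_length]]))
        return pts

    def trees(self) -> Iterator[tuple[float, float, dict]]:
        """Yield ``(left, right, parent_map)`` for each marginal tree."""
        order_in = np.argsort(self.edges_left, kind="stable")
        order_out = np.argsort(self.edges_right, kind="stable")
        parent: dict[int, int] = {}
        i = j = 0
        pts = self.breakpoints()
        ne = self.num_edges
        for a, b in zip(pts[:-1], pts[1:]):
            while j < ne and self.edges_right[order_out[j]] <= a:
                e = order_out[j]
                parent.pop(int(self.edges_child[e]), None)
                j += 1
            while i < ne and self.edges_left[order_in[i]] <= a:
                e = order_in[i]
                parent[int(self.edges_child[e])] = int(self.edges_parent[e])
                i += 1
            if parent:
                yield float(a), float(b), dict(parent)

    def num_marginal_trees(self) -> int:
        return sum(1 for _ in self.trees())

    def tmrca(self, position: float = 0.0) -> float:
        """Time of the grand MRCA of all samples at ``position``."""
        for a, b, parent in self.trees():
            if a <= position < b:
                node = 0
                while node in parent:
                    node = parent[node]
                return float(self.node_times[node])
        raise DemographyError(f"position {position} not covered by any tree")

    def total_branch_length(self, position: float = 0.0) -> float:
        for a, b, parent in self.trees():
            if a <= position < b:
                return float(
                    sum(self.node_times[p] - self.node_times[c] for c, p in parent.items())
                )
        raise DemographyError(f"position {position} not covered by any tree")


def simulate_ancestry(
    model: DemographicModel, samples: SampleSpec | Mapping, seed: int
) -> GenealogyForest:
    """Simulate the ancestral recombination graph of a structured sample.

    Backward-in-time Hudson algorithm: exponential waiting times are drawn
    from the total event intensity (:func:`event_rates`); the event is chosen
    proportionally to its intensity.  Coalescence merges two lineages' segment
    sets (creating a genealogy node over intervals where both carry ancestral
    material), migration relabels a lineage's deme, and recombination splits a
    lineage at a uniform breakpoint within its ancestral extent.  Split events
    move all lineages of the derived deme into the ancestral deme.  The
    simulation ends when every locus has fully coalesced.

    Identical ``(model, samples, seed)`` give identical output.
    """
    if not isinstance(samples, SampleSpec):
        samples = SampleSpec(samples)
    samples.validate_against(model)
    sampled_pops = [pid for pid, n in samples.items() if n > 0]
    model.check_connected(sampled_pops)

    rng = np.random.Generator(np.random.PCG64(seed))
    L = float(model.sequence_length)
    r = model.recombination_rate

    # mutable demographic state
    sizes = {p.id: p.effective_size for p in model.populations}
    migration = MigrationRates()
    for k, v in model.migration_rates.items():
        migration[k] = v
    active = set(model.population_ids())

    # sample lineages in model population order for a stable haplotype layout;
    # deme insertion order must be deterministic (it drives event selection)
    node_times: list[float] = []
    sample_populations: list[str] = []
    demes: dict[str, list[list[tuple]]] = {pid: [] for pid in model.population_ids()}
    node = 0
    for pop in model.populations:
        n = samples.get(pop.id, 0)
        for _ in range(2 * n):
            demes[pop.id].append([(0.0, L, node, 1)])
            node_times.append(0.0)
            sample_populations.append(pop.id)
            node += 1
    n_total = node

    edges: list[tuple[float, float, int, int]] = []
    t = 0.0
    ev_idx = 0
    events = model.events

    def n_lineages() -> int:
        return sum(len(v) for v in demes.values())

    while n_lineages() > 0:
        counts = {d: len(v) for d, v in demes.items() if v}
        spans = {
            d: [segs[-1][1] - segs[0][0] for segs in v] for d, v in demes.items() if v
        }
        rates = event_rates(counts, spans, model, sizes=sizes, migration=migration, active=active)
        lam = rates["total"]

        if lam <= 0.0:
            if ev_idx < len(events):
                ev = events[ev_idx]
                ev_idx += 1
                t = ev.time
                _apply_event(ev, demes, sizes, migration, active)
                continue
            raise DemographyError(
                "no events possible but uncoalesced lineages remain; "
                "check the split/migration structure"
            )

        wait = rng.exponential(1.0 / lam)
        if ev_idx < len(events) and t + wait >= events[ev_idx].time:
            ev = events[ev_idx]
            ev_idx += 1
            t = ev.time
            _apply_event(ev, demes, sizes, migration, active)
            continue
        t += wait

        u = rng.uniform(0.0, lam)
        # coalescence
        done = False
        for deme, rate in rates["coalescence"].items():
            if u < rate:
                lin = demes[deme]
                i, j = rng.choice(len(lin), size=2, replace=False)
                i, j = (int(i), int(j)) if i < j else (int(j), int(i))
                b = lin.pop(j)
                a = lin.pop(i)
                merged, new_node = _merge_lineages(a, b, t, n_total, node_times, edges)
                if merged:
                    lin.append(merged)
                done = True
                break
            u -= rate
        if done:
            continue
        # migration
        for (x, y), rate in rates["migration"].items():
            if u < rate:
                lin = demes[x]
                i = int(rng.integers(len(lin)))
                demes[y].append(lin.pop(i))
                done = True
                break
            u -= rate
        if done:
            continue
        # recombination: pick lineage proportional to its ancestral extent
        target = rng.uniform(0.0, rates["recombination"])
        acc = 0.0
        for deme, v in demes.items():
            for i, segs in enumerate(v):
                acc += r * (segs[-1][1] - segs[0][0])
                if acc > target:
                    left_part, right_part = _split_lineage(segs, rng)
                    v[i] = left_part
                    v.append(right_part)
                    done = True
                    break
            if done:
                break

    el = np.array([e[0] for e in edges])
    er = np.array([e[1] for e in edges])
    ep = np.array([e[2] for e in edges], dtype=np.int64)
    ec = np.array([e[3] for e in edges], dtype=np.int64)
    return GenealogyForest(
        node_times=np.array(node_times),
        edges_left=el,
        edges_right=er,
        edges_parent=ep,
        edges_child=ec,
        n_samples=n_total,
        sequence_length=L,
        sample_populations=np.array(sample_populations),
        seed=seed,
        model_hash=model.stable_hash(),
    )


def _apply_event(ev: DemographicEvent, demes, sizes, migration, active) -> None:
    if ev.kind == "split":
        derived = _canon_pop(ev.params["derived"])
        ancestral = _canon_pop(ev.params["ancestral"])
        demes[ancestral].extend(demes[derived])
        demes[derived] = []
        active.discard(derived)
    elif ev.kind == "size_change":
        sizes[_canon_pop(ev.params["population"])] = float(ev.params["size"])
    elif ev.kind == "migration_change":
        migration[tuple(ev.params["pair"])] = float(ev.params["rate"])


def _merge_lineages(a, b, time, n_total, node_times, edges):
    """Coalesce two lineages at ``time``; returns (merged lineage or None, node).

    Over intervals where both carry ancestral material a new genealogy node is
    created (one per coalescence event) and edges are recorded; elsewhere
    segments pass through unchanged.  Fully coalesced intervals (all samples
    below) are dropped from further simulation.
    """
    new_node = None
    out = []
    i = j = 0
    na, nb = len(a), len(b)
    # sweep atomic intervals
    cuts = sorted({s[0] for s in a} | {s[1] for s in a} | {s[0] for s in b} | {s[1] for s in b})
    for left, right in zip(cuts[:-1], cuts[1:]):
        while i < na and a[i][1] <= left:
            i += 1
        while j < nb and b[j][1] <= left:
            j += 1
        sa = a[i] if i < na and a[i][0] <= left else None
        sb = b[j] if j < nb and b[j][0] <= left else None
        if sa is not None and sb is not None:
            if new_node is None:
                new_node = len(node_times)
                node_times.append(time)
            edges.append((left, right, new_node, sa[2]))
            edges.append((left, right, new_node, sb[2]))
            k = sa[3] + sb[3]
            if k < n_total:
                out.append((left, right, new_node, k))
        elif sa is not None:
            out.append((left, right, sa[2], sa[3]))
        elif sb is not None:
            out.append((left, right, sb[2], sb[3]))
    # squash adjacent pieces of the same node
    squashed: list[tuple] = []
    for seg in out:
        if squashed and squashed[-1][1] == seg[0] and squashed[-1][2] == seg[2] and squashed[-1][3] == seg[3]:
            prev = squashed[-1]
            squashed[-1] = (prev[0], seg[1], prev[2], prev[3])
        else:
            squashed.append(seg)
    return (squashed if squashed else None), new_node


def _split_lineage(segs, rng):
    """Recombination: split at a uniform breakpoint within the ancestral extent."""
    lo, hi = segs[0][0], segs[-1][1]
    bp = rng.uniform(lo, hi)
    left_part: list[tuple] = []
    right_part: list[tuple] = []
    for seg in segs:
        sl, sr, node, k = seg
        if sr <= bp:
            left_part.append(seg)
        elif sl >= bp:
            right_part.append(seg)
        else:
            left_part.append((sl, bp, node, k))
            right_part.append((bp, sr, node, k))
    if not left_part or not right_part:
        # breakpoint exactly at a segment boundary (measure-zero); retry
        return _split_lineage(segs, rng)
    return left_part, right_part


# ---------------------------------------------------------------------------
# Mutation overlay (infinite sites)
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotypes at segregating sites.

    ``matrix`` has one row per haplotype (0 = ancestral, 1 = derived allele)
    and one column per site; ``positions`` are 0-based integer bp, strictly
    increasing.  Haplotypes ``2k`` and ``2k+1`` belong to diploid ``k``.
    """

    matrix: np.ndarray
    positions: np.ndarray
    sample_populations: np.ndarray
    sequence_length: float
    seed: int | None = None
    model_hash: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.sample_populations = np.asarray(self.sample_populations)
        if self.matrix.ndim != 2:
            raise DemographyError("haplotype matrix must be 2-D")
        if self.matrix.shape[1] != len(self.positions):
            raise DemographyError("positions do not match matrix columns")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise DemographyError("positions must be strictly increasing")
        if self.matrix.shape[0] % 2:
            raise DemographyError("haplotype count must be even (diploid pairing)")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def genotypes(self) -> np.ndarray:
        """Diploid 0/1/2 genotype matrix, individuals x sites."""
        return (self.matrix[0::2].astype(np.int8) + self.matrix[1::2]).astype(np.int8)

    @property
    def individual_populations(self) -> np.ndarray:
        return self.sample_populations[0::2]

    def individuals_of(self, population) -> np.ndarray:
        pid = _canon_pop(population)
        return np.flatnonzero(self.individual_populations == pid)

    def subset_sites(self, site_indices) -> "HaplotypePanel":
        idx = np.asarray(site_indices, dtype=np.int64)
        return HaplotypePanel(
            matrix=self.matrix[:, idx],
            positions=self.positions[idx],
            sample_populations=self.sample_populations,
            sequence_length=self.sequence_length,
            seed=self.seed,
            model_hash=self.model_hash,
        )

    def subset_individuals(self, individual_indices) -> "HaplotypePanel":
        """Subset diploids; the site set is kept intact to preserve alignment."""
        idx = np.asarray(individual_indices, dtype=np.int64)
        hap_idx = np.empty(2 * len(idx), dtype=np.int64)
        hap_idx[0::2] = 2 * idx
        hap_idx[1::2] = 2 * idx + 1
        return HaplotypePanel(
            matrix=self.matrix[hap_idx],
            positions=self.positions,
            sample_populations=self.sample_populations[hap_idx],
            sequence_length=self.sequence_length,
            seed=self.seed,
            model_hash=self.model_hash,
        )


def overlay_mutations(forest: GenealogyForest, mu: float, seed: int) -> HaplotypePanel:
    """Throw infinite-sites mutations onto the genealogies.

    Mutations fall on each edge as a Poisson process with intensity
    ``mu * branch_length * edge_span``; each gets a continuous position,
    later floored to a unique integer bp (collisions redrawn within the
    edge interval).  Carriers are the sampled haplotypes below the mutated
    edge in the marginal tree at that position.  Only segregating sites are
    emitted (guaranteed: edges above a local grand MRCA do not exist).
    """
    if mu < 0:
        raise DemographyError("mutation rate must be >= 0")
    rng = np.random.Generator(np.random.PCG64(seed))
    n = forest.n_samples

    if mu == 0.0 or forest.num_edges == 0:
        return HaplotypePanel(
            matrix=np.zeros((n, 0), dtype=np.uint8),
            positions=np.array([], dtype=np.int64),
            sample_populations=forest.sample_populations,
            sequence_length=forest.sequence_length,
            seed=seed,
            model_hash=forest.model_hash,
        )

    blen = forest.node_times[forest.edges_parent] - forest.node_times[forest.edges_child]
    span = forest.edges_right - forest.edges_left
    n_mut = rng.poisson(mu * blen * span)
    muts: list[tuple[float, int, int]] = []  # (float position, edge index, child node)
    for e in np.flatnonzero(n_mut):
        for _ in range(int(n_mut[e])):
            pos = rng.uniform(forest.edges_left[e], forest.edges_right[e])
            muts.append((pos, int(e), int(forest.edges_child[e])))
    if not muts:
        return HaplotypePanel(
            matrix=np.zeros((n, 0), dtype=np.uint8),
            positions=np.array([], dtype=np.int64),
            sample_populations=forest.sample_populations,
            sequence_length=forest.sequence_length,
            seed=seed,
            model_hash=forest.model_hash,
        )
    muts.sort()

    # sweep marginal trees to resolve carriers at each mutation position
    order_in = np.argsort(forest.edges_left, kind="stable")
    order_out = np.argsort(forest.edges_right, kind="stable")
    children: dict[int, list[int]] = {}
    i = j = 0
    ne = forest.num_edges
    carriers_per_mut: list[np.ndarray] = []
    used_positions: set[int] = set()
    int_positions: list[int] = []
    for pos, e, child in muts:
        # insertions first: a position jump may skip whole edge lifespans
        while i < ne and forest.edges_left[order_in[i]] <= pos:
            k = order_in[i]
            children.setdefault(int(forest.edges_parent[k]), []).append(int(forest.edges_child[k]))
            i += 1
        while j < ne and forest.edges_right[order_out[j]] <= pos:
            k = order_out[j]
            children[int(forest.edges_parent[k])].remove(int(forest.edges_child[k]))
            j += 1
        # collect sampled leaves below `child`
        stack = [child]
        leaves = []
        while stack:
            v = stack.pop()
            if v < n:
                leaves.append(v)
            stack.extend(children.get(v, ()))
        # discretize, infinite sites preserved by rejection
        lo, hi = forest.edges_left[e], forest.edges_right[e]
        ipos = int(math.floor(pos))
        tries = 0
        while ipos in used_positions:
            ipos = int(math.floor(rng.uniform(lo, hi)))
            tries += 1
            if tries > 1000:
                ipos = -1
                break
        if ipos < 0:
            continue  # saturated interval; drop (practically unreachable)
        used_positions.add(ipos)
        int_positions.append(ipos)
        carriers_per_mut.append(np.array(leaves, dtype=np.int64))

    order = np.argsort(int_positions, kind="stable")
    positions = np.array([int_positions[k] for k in order], dtype=np.int64)
    matrix = np.zeros((n, len(order)), dtype=np.uint8)
    for col, k in enumerate(order):
        matrix[carriers_per_mut[k], col] = 1
    return HaplotypePanel(
        matrix=matrix,
        positions=positions,
        sample_populations=forest.sample_populations,
        sequence_length=forest.sequence_length,
        seed=seed,
        model_hash=forest.model_hash,
    )


def simulate_panel(
    model: DemographicModel,
    samples: SampleSpec | Mapping,
    seed: int,
    *,
    engine: str = "internal",
) -> HaplotypePanel:
    """Simulate ancestry and mutations in one call.

    Independent sub-streams for the ancestry and mutation stages are derived
    deterministically from ``seed`` so each stage is reproducible on its own.
    ``engine="msprime"`` delegates ancestry to msprime (optional adapter).
    """
    ss = np.random.SeedSequence(seed)
    anc_seed, mut_seed = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    if engine == "internal":
        forest = simulate_ancestry(model, samples, anc_seed)
    elif engine == "msprime":
        forest = simulate_ancestry_msprime(model, samples, anc_seed)
    else:
        raise DemographyError(f"unknown ancestry engine {engine!r}")
    return overlay_mutations(forest, model.mutation_rate, mut_seed)


# ---------------------------------------------------------------------------
# Optional adapter: delegate ancestry to msprime behind the same interface
# ---------------------------------------------------------------------------


def simulate_ancestry_msprime(
    model: DemographicModel, samples: SampleSpec | Mapping, seed: int
) -> GenealogyForest:
    """Ancestry via the msprime coalescent engine, returned as a GenealogyForest.

    Optional; the internal simulator is the default and tests never require
    this adapter.
    """
    import msprime

    if not isinstance(samples, SampleSpec):
        samples = SampleSpec(samples)
    samples.validate_against(model)

    dem = msprime.Demography()
    for p in model.populations:
        dem.add_population(name=p.id, initial_size=p.effective_size)
    for (a, b), rate in model.migration_rates.items():
        if rate > 0:
            dem.set_symmetric_migration_rate([a, b], rate)
    for ev in model.events:
        if ev.kind == "split":
            dem.add_population_split(
                time=ev.time,
                derived=[_canon_pop(ev.params["derived"])],
                ancestral=_canon_pop(ev.params["ancestral"]),
            )
        elif ev.kind == "size_change":
            dem.add_population_parameters_change(
                time=ev.time,
                population=_canon_pop(ev.params["population"]),
                initial_size=float(ev.params["size"]),
            )
        elif ev.kind == "migration_change":
            a, b = ev.params["pair"]
            dem.add_symmetric_migration_rate_change(
                time=ev.time, populations=[_canon_pop(a), _canon_pop(b)], rate=float(ev.params["rate"])
            )
    dem.sort_events()

    sample_sets = [
        msprime.SampleSet(samples[p.id], population=p.id, ploidy=2)
        for p in model.populations
        if samples.get(p.id, 0) > 0
    ]
    ts = msprime.sim_ancestry(
        samples=sample_sets,
        demography=dem,
        sequence_length=model.sequence_length,
        recombination_rate=model.recombination_rate,
        random_seed=max(1, seed % (2**31 - 1)),
    )
    pops = []
    for p in model.populations:
        pops.extend([p.id] * (2 * samples.get(p.id, 0)))
    tables = ts.tables
    return GenealogyForest(
        node_times=np.asarray(tables.nodes.time, dtype=float),
        edges_left=np.asarray(tables.edges.left, dtype=float),
        edges_right=np.asarray(tables.edges.right, dtype=float),
        edges_parent=np.asarray(tables.edges.parent, dtype=np.int64),
        edges_child=np.asarray(tables.edges.child, dtype=np.int64),
        n_samples=ts.num_samples,
        sequence_length=model.sequence_length,
        sample_populations=np.array(pops),
        seed=seed,
        model_hash=model.stable_hash(),
    )
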