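"""Greedy candidate-module discovery inside local networks.

Each eligible gene seeds one local network (a bounded BFS neighbourhood
of the reduced influence network). Starting from the seed, the module is
grown one gene at a time: at every step the pool gene that maximises the
exclusive score Ex of the grown module is added, ties broken by the
larger union coverage of the grown module and finally lexicographically.
Growth stops at the maximum size (5) or as soon as the best attainable
Ex falls below the cutoff (0.95, strict). Every intermediate snapshot of
size >= 2 is kept — smaller sub-modules are candidates in their own
right.

Candidates from all seeds are scored, deduplicated by gene set, and
ranked by composite score within each size; per size, top modules are
selected in score order until every coverable sample is covered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .mutations import MutationMatrix, exclusive_sample_sets, filter_min_recurrence
from .network import InfluenceNetwork, LocalNetwork, extract_local_network
from .scoring import ModuleScore, unicovex_score

__all__ = [
    "GeneModule",
    "ModuleCatalog",
    "SelectionResult",
    "grow_module",
    "build_catalog",
    "select_covering_modules",
    "DiscoveryConfig",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscoveryConfig:
    """Search parameters; defaults are the published operating point."""

    local_size: int = 100
    max_size: int = 5
    ex_cutoff: float = 0.95
    min_recurrence: int = 2


@dataclass(frozen=True)
class GeneModule:
    """An ordered gene set found by greedy growth.

    ``genes`` is the insertion order (seed first); ``center`` the seed
    gene; ``network`` the provenance tag of the source network.
    """

    genes: tuple[str, ...]
    center: str
    network: str = ""
    score: ModuleScore | None = None

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass
class ModuleCatalog:
    """Distinct candidate modules grouped by size, ranked by composite.

    ``by_size[s]`` is sorted by (composite desc, gene list asc); no two
    entries anywhere share a gene set.
    """

    by_size: dict[int, list[GeneModule]] = field(default_factory=dict)
    network: str = ""

    def all_modules(self) -> list[GeneModule]:
        return [mod for s in sorted(self.by_size) for mod in self.by_size[s]]

    @property
    def n_modules(self) -> int:
        return sum(len(v) for v in self.by_size.values())

    def genes(self) -> set[str]:
        return {g for mod in self.all_modules() for g in mod.genes}


@dataclass(frozen=True)
class SelectionResult:
    """Per-size selection outcome of the coverage walk."""

    size: int
    selected: tuple[GeneModule, ...]
    covered: frozenset[str]
    uncoverable: frozenset[str]


def _ex_of(m: MutationMatrix, genes: Sequence[str]) -> float:
    ep = exclusive_sample_sets(m, genes)
    return sum(len(e) / m.coverage(g) for g, e in zip(genes, ep)) / len(genes)


def grow_module(
    m: MutationMatrix,
    local: LocalNetwork,
    max_size: int = 5,
    ex_cutoff: float = 0.95,
    min_recurrence: int = 2,
    network: str = "",
) -> list[GeneModule]:
    """Grow one module from ``local.center`` and return all snapshots.

    Returns the nested chain of intermediate modules of sizes
    2..final (possibly empty when no admissible extension exists or the
    center itself fails the recurrence filter).
    """
    center = local.center
    if center not in m.mutated_samples or m.coverage(center) < min_recurrence:
        log.debug("skipping seed %s: below recurrence filter", center)
        return []
    pool = [
        g
        for g in local.members
        if g != center
        and g in m.mutated_samples
        and m.coverage(g) >= min_recurrence
    ]
    module: list[str] = [center]
    snapshots: list[GeneModule] = []
    while len(module) < max_size:
        candidates = [
            (-_ex_of(m, module + [g]), -m.union_coverage(module + [g]), g)
            for g in pool
            if g not in module
        ]
        if not candidates:
            break
        neg_ex, _, best_gene = min(candidates)
        if -neg_ex < ex_cutoff:
            break
        module.append(best_gene)
        snapshots.append(GeneModule(genes=tuple(module), center=center, network=network))
    return snapshots


def build_catalog(
    m: MutationMatrix,
    net: InfluenceNetwork,
    config: DiscoveryConfig = DiscoveryConfig(),
) -> ModuleCatalog:
    """Run local-network extraction and greedy growth from every seed.

    Seeds are the genes present in both the (reduced) network and the
    recurrence-filtered mutation matrix. Every snapshot is scored; the
    catalog is deduplicated by gene set and ranked.
    """
    mf = filter_min_recurrence(m, config.min_recurrence)
    seeds = sorted(set(mf.gene_ids) & net.nodes)
    if not seeds:
        log.warning("no eligible seed genes: empty catalog for %s", net.name)
        return ModuleCatalog(network=net.name)
    seen: dict[frozenset[str], GeneModule] = {}
    for seed in seeds:
        local = extract_local_network(net, seed, config.local_size)
        for mod in grow_module(
            m,
            local,
            max_size=config.max_size,
            ex_cutoff=config.ex_cutoff,
            min_recurrence=config.min_recurrence,
            network=net.name,
        ):
            key = mod.gene_set
            if key not in seen:
                seen[key] = replace(mod, score=unicovex_score(m, mod.genes))
    catalog = ModuleCatalog(network=net.name)
    for mod in seen.values():
        catalog.by_size.setdefault(mod.size, []).append(mod)
    for size in catalog.by_size:
        catalog.by_size[size].sort(
            key=lambda mod: (-mod.score.composite, sorted(mod.genes))
        )
    return catalog


def _covered_samples(m: MutationMatrix, mod: GeneModule) -> set[str]:
    covered: set[str] = set()
    for g in mod.genes:
        covered |= m.samples_of(g)
    return covered


def select_covering_modules(
    catalog: ModuleCatalog, m: MutationMatrix
) -> dict[int, SelectionResult]:
    """Per size, take modules in descending composite order until every
    coverable sample is covered.

    A sample is *coverable* at size s when at least one catalog gene of
    that size class is mutated in it; uncoverable samples are reported,
    never looped on.
    """
    results: dict[int, SelectionResult] = {}
    for size in sorted(catalog.by_size):
        entries = catalog.by_size[size]
        coverable: set[str] = set()
        for mod in entries:
            coverable |= _covered_samples(m, mod)
        covered: set[str] = set()
        selected: list[GeneModule] = []
        for mod in entries:
            if covered >= coverable:
                break
            selected.append(mod)
            covered |= _covered_samples(m, mod)
        results[size] = SelectionResult(
            size=size,
            selected=tuple(selected),
            covered=frozenset(covered),
            uncoverable=frozenset(set(m.sample_ids) - coverable),
        )
    return results
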