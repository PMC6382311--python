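"""Sample-specific driver modules via greedy minimum set cover, and
consensus calls across interaction networks.

Choosing the fewest modules whose gene mutations touch every cohort
sample is a minimum set cover instance (NP-hard); the classic greedy
approximation is used: repeatedly pick the module covering the most
not-yet-covered samples. Because larger modules trivially cover more,
module sizes (2–5) compete in separate groups. Each sample's driver
modules are then all chosen modules with a mutated gene in that sample.

A module is called by consensus when it is supported by at least
``min_support`` of the input networks — exactly (identical gene set) or
by Jaccard merging, since cross-network module identity is fuzzy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .discovery import GeneModule
from .mutations import MutationMatrix

__all__ = [
    "CoverSolution",
    "ConsensusModule",
    "ConsensusSet",
    "greedy_set_cover",
    "consensus_modules",
]


@dataclass(frozen=True)
class CoverSolution:
    """Greedy set-cover outcome for one module-size group."""

    size_group: int
    chosen_modules: tuple[GeneModule, ...]  # greedy pick order
    marginal_gains: tuple[int, ...]  # new samples covered at each pick
    sample_assignment: Mapping[str, tuple[GeneModule, ...]]
    uncovered: frozenset[str]


@dataclass(frozen=True)
class ConsensusModule:
    genes: frozenset[str]
    support_networks: tuple[str, ...]
    representative: GeneModule  # highest-composite supporting module

    @property
    def support(self) -> int:
        return len(self.support_networks)


@dataclass(frozen=True)
class ConsensusSet:
    modules: tuple[ConsensusModule, ...]
    min_support: int

    def genes(self) -> set[str]:
        return {g for mod in self.modules for g in mod.genes}


def _module_cover(m: MutationMatrix, mod: GeneModule) -> frozenset[str]:
    covered: set[str] = set()
    for g in mod.genes:
        covered |= m.samples_of(g)
    return frozenset(covered)


def _composite(mod: GeneModule) -> float:
    return mod.score.composite if mod.score is not None else 0.0


def greedy_set_cover(
    modules: Sequence[GeneModule],
    m: MutationMatrix,
    size_group: int,
) -> CoverSolution:
    """Greedy cover of the cohort with modules of one size.

    Ties on marginal gain go to the higher composite score, then to the
    lexicographically smaller gene list. The loop stops when no module
    adds coverage; the remaining samples are uncoverable by this group.
    The result is the greedy pick sequence — not a guaranteed optimum.
    """
    for mod in modules:
        if mod.size != size_group:
            raise ValueError(
                f"module {mod.genes} has size {mod.size}, expected {size_group}"
            )
    covers = {i: _module_cover(m, mod) for i, mod in enumerate(modules)}
    remaining = set(range(len(modules)))
    covered: set[str] = set()
    chosen: list[GeneModule] = []
    gains: list[int] = []
    while remaining:
        best = min(
            remaining,
            key=lambda i: (
                -len(covers[i] - covered),
                -_composite(modules[i]),
                sorted(modules[i].genes),
            ),
        )
        gain = len(covers[best] - covered)
        if gain == 0:
            break
        chosen.append(modules[best])
        gains.append(gain)
        covered |= covers[best]
        remaining.discard(best)
    assignment = {
        s: tuple(mod for mod in chosen if s in _module_cover(m, mod))
        for s in m.sample_ids
        if s in covered
    }
    return CoverSolution(
        size_group=size_group,
        chosen_modules=tuple(chosen),
        marginal_gains=tuple(gains),
        sample_assignment=assignment,
        uncovered=frozenset(set(m.sample_ids) - covered),
    )


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    return len(a & b) / len(a | b)


def consensus_modules(
    catalogs: Mapping[str, Sequence[GeneModule]],
    min_support: int = 2,
    agreement: str = "exact",
    jaccard_threshold: float = 0.5,
) -> ConsensusSet:
    """Call modules supported by at least ``min_support`` networks.

    ``agreement="exact"`` requires the identical frozen gene set in each
    supporting network. ``agreement="jaccard"`` merges modules from
    different networks into one group whenever their pairwise Jaccard
    index reaches ``jaccard_threshold`` (transitively); the group counts
    if it spans >= min_support networks, represented by its
    highest-composite member.
    """
    if min_support > len(catalogs):
        raise ValueError(
            f"min_support={min_support} exceeds the {len(catalogs)} provided catalogs"
        )
    if len(catalogs) < 2:
        raise ValueError("consensus requires at least 2 network catalogs")
    entries = [
        (net, mod)
        for net in sorted(catalogs)
        for mod in catalogs[net]
    ]
    if agreement == "exact":
        groups: dict[frozenset[str], list[tuple[str, GeneModule]]] = {}
        for net, mod in entries:
            groups.setdefault(mod.gene_set, []).append((net, mod))
        merged = list(groups.values())
    elif agreement == "jaccard":
        # transitive single-link merging across networks
        parent = list(range(len(entries)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                if entries[i][0] == entries[j][0]:
                    continue
                if _jaccard(entries[i][1].gene_set, entries[j][1].gene_set) >= jaccard_threshold:
                    parent[find(i)] = find(j)
        comp: dict[int, list[tuple[str, GeneModule]]] = {}
        for i, e in enumerate(entries):
            comp.setdefault(find(i), []).append(e)
        merged = list(comp.values())
    else:
        raise ValueError(f"agreement must be exact|jaccard, got {agreement!r}")

    out: list[ConsensusModule] = []
    for group in merged:
        nets = sorted({net for net, _ in group})
        if len(nets) < min_support:
            continue
        rep = min(group, key=lambda e: (-_composite(e[1]), sorted(e[1].genes)))[1]
        out.append(
            ConsensusModule(
                genes=rep.gene_set if agreement == "jaccard" else group[0][1].gene_set,
                support_networks=tuple(nets),
                representative=rep,
            )
        )
    out.sort(key=lambda cm: (-_composite(cm.representative), sorted(cm.genes)))
    return ConsensusSet(modules=tuple(out), min_support=min_support)
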