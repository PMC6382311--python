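"""Synthetic cohorts with planted exclusive modules and known truth.

The generator emulates the shape of a tumour-cohort analysis input:

* a binary mutation matrix whose background (passenger) gene
  frequencies follow a long-tail power law — most mutated genes are
  rare;
* a small number of planted driver modules: disjoint gene sets whose
  member genes are mutated mutually exclusively across a block of
  samples, with a configurable balance of exclusive coverage and a
  configurable *leak* rate that co-mutates a second module gene;
* a weighted gene network in which every planted module is wired as a
  heavy clique embedded in a light random background graph.

Deterministic allocation mode assigns exact per-gene sample counts
(largest-remainder rounding of the balance weights), so entropy and
exclusivity worked examples are exact rather than stochastic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .discovery import DiscoveryConfig, ModuleCatalog, build_catalog
from .mutations import MutationMatrix, write_mutations
from .network import InfluenceNetwork, reduce_to_average_degree, write_edge_list

__all__ = [
    "PlantedCohortParams",
    "PlantedCohort",
    "RecoveryMetrics",
    "generate_planted_cohort",
    "recovery_harness",
    "write_cohort",
]


@dataclass(frozen=True)
class PlantedCohortParams:
    """Generator knobs.

    balance: "uniform" for evenly shared exclusive coverage, or a
    weight vector (one weight per module gene, applied to every
    module). leak_rate is the probability that a module-covered sample
    additionally mutates a second module gene (breaking exclusivity).
    passenger_rate is the mutation frequency of the most frequent decoy
    gene; decoy ranks decay as rank**-powerlaw_exponent.
    """

    seed: int
    n_samples: int = 200
    n_genes: int = 300
    module_sizes: tuple[int, ...] = (4, 4, 4)
    module_coverage: int = 60
    balance: str | tuple[float, ...] = "uniform"
    deterministic_allocation: bool = False
    leak_rate: float = 0.0
    passenger_rate: float = 0.02
    powerlaw_exponent: float = 2.0
    background_edge_prob: float = 0.03

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("planted module genes exceed n_genes")
        if len(self.module_sizes) * self.module_coverage > self.n_samples:
            raise ValueError("module coverage blocks exceed n_samples")
        for name in ("leak_rate", "passenger_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedCohort:
    matrix: MutationMatrix
    network: InfluenceNetwork
    truth_modules: tuple[frozenset[str], ...]
    params: PlantedCohortParams


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well the pipeline recovered the planted truth."""

    exact_recovered: tuple[bool, ...]  # per truth module, in planting order
    recovered_fraction: float
    gene_precision: float
    gene_recall: float


def _balance_weights(params: PlantedCohortParams, size: int) -> np.ndarray:
    if isinstance(params.balance, str):
        if params.balance != "uniform":
            raise ValueError(f"unknown balance spec {params.balance!r}")
        w = np.ones(size)
    else:
        if len(params.balance) != size:
            raise ValueError("balance weight vector length must equal module size")
        w = np.asarray(params.balance, dtype=float)
    return w / w.sum()


def _exact_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` samples to weights."""
    raw = weights * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def generate_planted_cohort(params: PlantedCohortParams) -> PlantedCohort:
    """Generate a seeded cohort; identical params give identical output."""
    rng = np.random.default_rng(params.seed)
    gene_width = len(str(params.n_genes))
    sample_width = len(str(params.n_samples))
    genes = [f"G{str(i).zfill(gene_width)}" for i in range(params.n_genes)]
    samples = [f"S{str(i).zfill(sample_width)}" for i in range(params.n_samples)]

    truth: list[frozenset[str]] = []
    mutated: dict[str, set[str]] = {g: set() for g in genes}
    gi = 0
    si = 0
    for size in params.module_sizes:
        module = genes[gi : gi + size]
        gi += size
        block = samples[si : si + params.module_coverage]
        si += params.module_coverage
        truth.append(frozenset(module))
        weights = _balance_weights(params, size)
        if params.deterministic_allocation:
            counts = _exact_counts(weights, len(block))
            owner = np.repeat(np.arange(size), counts)
        else:
            owner = rng.choice(size, size=len(block), p=weights)
        for sample, k in zip(block, owner):
            mutated[module[int(k)]].add(sample)
            if size > 1 and params.leak_rate > 0 and rng.random() < params.leak_rate:
                others = [j for j in range(size) if j != int(k)]
                mutated[module[others[rng.integers(len(others))]]].add(sample)

    # long-tail passengers on decoy genes only, so leak_rate alone
    # controls the exclusivity of planted modules
    decoys = genes[gi:]
    for rank, g in enumerate(decoys, start=1):
        freq = params.passenger_rate * rank ** -params.powerlaw_exponent
        hits = rng.random(params.n_samples) < freq
        mutated[g].update(s for s, h in zip(samples, hits) if h)

    matrix = MutationMatrix(
        gene_ids=tuple(genes),
        sample_ids=tuple(samples),
        mutated_samples={g: frozenset(s) for g, s in mutated.items()},
    )
    network = _planted_network(params, genes, truth, rng)
    return PlantedCohort(
        matrix=matrix,
        network=network,
        truth_modules=tuple(truth),
        params=params,
    )


def _planted_network(
    params: PlantedCohortParams,
    genes: list[str],
    truth: Sequence[frozenset[str]],
    rng: np.random.Generator,
) -> InfluenceNetwork:
    """One graph component per planted module, plus a decoy component.

    Each truth module is a heavy clique; the decoy genes are split
    evenly across the components and wired with light random edges
    *within* their component. Because the sample blocks of different
    planted modules are disjoint, their genes are mutually exclusive of
    each other by construction — only the network topology can separate
    the modules, which is exactly the constraint the influence network
    supplies on real data. Planting each module in its own component
    makes the ground truth identifiable.
    """
    edges: dict[tuple[str, str], float] = {}
    planted = [sorted(module) for module in truth]
    decoys = [g for g in genes if all(g not in module for module in truth)]
    n_comp = len(planted) + 1  # last component is passenger-only
    components: list[list[str]] = [list(module) for module in planted] + [[]]
    for i, g in enumerate(decoys):
        components[i % n_comp].append(g)
    for module in planted:
        for i in range(len(module)):
            for j in range(i + 1, len(module)):
                edges[(module[i], module[j])] = float(rng.uniform(1.5, 2.0))
    for comp in components:
        comp = sorted(comp)
        for i in range(len(comp)):
            for j in range(i + 1, len(comp)):
                key = (comp[i], comp[j])
                if key in edges:
                    continue
                if rng.random() < params.background_edge_prob:
                    edges[key] = float(rng.uniform(0.01, 1.0))
    return InfluenceNetwork(
        ((a, b, w) for (a, b), w in edges.items()),
        name="planted",
        nodes=genes,
    )


def recovery_harness(
    cohort: PlantedCohort,
    config: DiscoveryConfig = DiscoveryConfig(),
    target_avg_degree: float = 15.0,
) -> RecoveryMetrics:
    """Run reduction + discovery and compare the catalog with the truth.

    A truth module counts as exactly recovered when its gene set appears
    in the catalog at its size. Gene-level precision/recall compare the
    union of the top-k catalog entries per planted size (k = number of
    planted modules of that size) with the planted genes.
    """
    net = reduce_to_average_degree(cohort.network, target_avg_degree)
    catalog = build_catalog(cohort.matrix, net, config)
    catalog_sets = {mod.gene_set for mod in catalog.all_modules()}
    flags = tuple(t in catalog_sets for t in cohort.truth_modules)

    sizes: dict[int, int] = {}
    for t in cohort.truth_modules:
        sizes[len(t)] = sizes.get(len(t), 0) + 1
    predicted: set[str] = set()
    for size, k in sizes.items():
        for mod in catalog.by_size.get(size, [])[:k]:
            predicted |= mod.gene_set
    truth_genes = {g for t in cohort.truth_modules for g in t}
    hits = predicted & truth_genes
    return RecoveryMetrics(
        exact_recovered=flags,
        recovered_fraction=sum(flags) / len(flags),
        gene_precision=len(hits) / len(predicted) if predicted else 0.0,
        gene_recall=len(hits) / len(truth_genes),
    )


def write_cohort(cohort: PlantedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write mutations.tsv, network.tsv and truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": out / "mutations.tsv",
        "network": out / "network.tsv",
        "truth": out / "truth.json",
    }
    write_mutations(cohort.matrix, paths["mutations"])
    write_edge_list(cohort.network, paths["network"])
    payload = {
        "truth_modules": [sorted(t) for t in cohort.truth_modules],
        "params": asdict(cohort.params),
    }
    paths["truth"].write_text(json.dumps(payload, indent=2) + "\n")
    return paths
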