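"""End-to-end orchestration: reduce networks, discover and select
modules, cover samples, call consensus, evaluate.

Every stage is a plain library call; this module only sequences them
and serialises the interface files into an output directory together
with a provenance manifest. Given an identical configuration the
catalog, cover and consensus files are byte-identical across runs — the
pipeline itself has no source of randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .discovery import (
    DiscoveryConfig,
    GeneModule,
    ModuleCatalog,
    build_catalog,
    select_covering_modules,
)
from .evaluation import (
    precision_recall,
    rank_genes_by_module_score,
    ranked_curves,
    read_gene_list,
)
from .mutations import read_mutations
from .network import read_edge_list, reduce_to_average_degree
from .prediction import consensus_modules, greedy_set_cover
from .scoring import dendrix_weight

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; defaults are the published values."""

    mutations: str
    networks: tuple[str, ...]
    out_dir: str
    reference: str | None = None
    mutation_format: str = "tsv_pairs"
    local_size: int = 100
    max_size: int = 5
    ex_cutoff: float = 0.95
    min_recurrence: int = 2
    target_avg_degree: float = 15.0
    min_support: int = 2
    agreement: str = "exact"
    jaccard_threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.networks:
            raise ValueError("at least one network is required")
        if len(self.networks) >= 2 and self.min_support > len(self.networks):
            raise ValueError(
                f"min_support={self.min_support} exceeds {len(self.networks)} networks"
            )

    def discovery(self) -> DiscoveryConfig:
        return DiscoveryConfig(
            local_size=self.local_size,
            max_size=self.max_size,
            ex_cutoff=self.ex_cutoff,
            min_recurrence=self.min_recurrence,
        )


def _genes_str(mod: GeneModule) -> str:
    return ";".join(mod.genes)


def write_catalog_tsv(
    catalog: ModuleCatalog,
    selected_sets: set[frozenset[str]],
    matrix,
    path: Path,
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "network\tsize\tgenes\tcomposite\tex\tentropy\tmin_cov\tunion_cov\t"
            "dendrix_w\tselected_flag\n"
        )
        for mod in catalog.all_modules():
            s = mod.score
            fh.write(
                f"{catalog.network}\t{mod.size}\t{_genes_str(mod)}\t"
                f"{s.composite:.6g}\t{s.ex_score:.6g}\t{s.entropy:.6g}\t"
                f"{s.min_coverage}\t{s.union_coverage}\t"
                f"{dendrix_weight(matrix, mod.genes)}\t"
                f"{int(mod.gene_set in selected_sets)}\n"
            )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the whole pipeline and return the output directory."""
    config.validate()
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = yaml.safe_dump(asdict(config), sort_keys=True)
    (out / "config.yaml").write_text(cfg_text)

    log.info("reading mutations from %s", config.mutations)
    matrix = read_mutations(config.mutations, format=config.mutation_format)
    dconf = config.discovery()

    selected_per_network: dict[str, list[GeneModule]] = {}
    catalogs: dict[str, ModuleCatalog] = {}
    for net_path in config.networks:
        net = read_edge_list(net_path)
        log.info("network %s: %d nodes, %d edges", net.name, len(net.nodes), net.n_edges)
        reduced = reduce_to_average_degree(net, config.target_avg_degree)
        t = time.monotonic()
        catalog = build_catalog(matrix, reduced, dconf)
        log.info(
            "network %s: %d candidate modules in %.1fs",
            net.name,
            catalog.n_modules,
            time.monotonic() - t,
        )
        selections = select_covering_modules(catalog, matrix)
        selected = [mod for sel in selections.values() for mod in sel.selected]
        catalogs[net.name] = catalog
        selected_per_network[net.name] = selected
        write_catalog_tsv(
            catalog,
            {mod.gene_set for mod in selected},
            matrix,
            out / f"catalog_{net.name}.tsv",
        )
        _write_cover(selected, matrix, dconf, out, net.name)

    if len(config.networks) >= 2:
        consensus = consensus_modules(
            selected_per_network,
            min_support=config.min_support,
            agreement=config.agreement,
            jaccard_threshold=config.jaccard_threshold,
        )
    else:
        consensus = None
    if consensus is not None:
        with open(out / "consensus.tsv", "w") as fh:
            fh.write("genes\tsupport_networks\tbest_composite\n")
            for cm in consensus.modules:
                fh.write(
                    f"{';'.join(sorted(cm.genes))}\t{','.join(cm.support_networks)}\t"
                    f"{cm.representative.score.composite:.6g}\n"
                )

    if config.reference is not None:
        _write_evaluation(config, matrix, catalogs, consensus, selected_per_network, out)

    manifest = {
        "tool": "unicovex",
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "n_genes": matrix.n_genes,
        "n_samples": matrix.n_samples,
        "networks": {
            name: len(mods) for name, mods in selected_per_network.items()
        },
        "n_consensus_modules": len(consensus.modules) if consensus else None,
        "wall_time_s": round(time.monotonic() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def _write_cover(selected, matrix, dconf, out: Path, net_name: str) -> None:
    by_size: dict[int, list[GeneModule]] = {}
    for mod in selected:
        by_size.setdefault(mod.size, []).append(mod)
    cover_path = out / f"cover_{net_name}.tsv"
    assign_path = out / f"assignment_{net_name}.tsv"
    with open(cover_path, "w") as cfh, open(assign_path, "w") as afh:
        cfh.write("size_group\tpick_rank\tgenes\tmarginal_gain\tcumulative_coverage\n")
        afh.write("sample\tsize_group\tmodules\n")
        for size in sorted(by_size):
            solution = greedy_set_cover(by_size[size], matrix, size)
            cum = 0
            for rank, (mod, gain) in enumerate(
                zip(solution.chosen_modules, solution.marginal_gains), start=1
            ):
                cum += gain
                cfh.write(f"{size}\t{rank}\t{_genes_str(mod)}\t{gain}\t{cum}\n")
            for sample in matrix.sample_ids:
                mods = solution.sample_assignment.get(sample, ())
                if mods:
                    afh.write(
                        f"{sample}\t{size}\t{'|'.join(_genes_str(m) for m in mods)}\n"
                    )


def _write_evaluation(config, matrix, catalogs, consensus, selected_per_network, out):
    reference = read_gene_list(config.reference)
    cohort_mutated = set(matrix.gene_ids)
    if consensus is not None:
        predicted = consensus.genes()
    else:
        predicted = {
            g
            for mods in selected_per_network.values()
            for mod in mods
            for g in mod.genes
        }
    precision, recall = precision_recall(predicted, reference, cohort_mutated)

    best: dict[str, float] = {}
    for catalog in catalogs.values():
        for gene, score in rank_genes_by_module_score(catalog, cohort_mutated):
            if score > best.get(gene, -1.0):
                best[gene] = score
    ranking = sorted(best.items(), key=lambda t: (-t[1], t[0]))
    report = None
    if reference & cohort_mutated:
        report = ranked_curves(ranking, reference, cohort_mutated)
    payload = {
        "n_predicted": len(predicted),
        "n_hits": len(predicted & reference),
        "precision": precision,
        "recall": recall,
        "aupr": report.aupr if report else None,
        "auc": report.auc if report else None,
        "pr_points": [list(p) for p in report.pr_points] if report else [],
        "roc_points": [list(p) for p in report.roc_points] if report else [],
    }
    (out / "evaluation.json").write_text(json.dumps(payload, indent=2) + "\n")
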