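"""Binary somatic mutation data as gene -> sample-set maps.

A cohort's somatic mutations are reduced to a binary incidence structure:
for every gene *g* the set of samples in which *g* carries at least one
somatic mutation. Multiplicity (several variants of a gene in one sample)
is deliberately discarded — the exclusivity model downstream is binary.

Two input dialects are supported:

* ``tsv_pairs`` — two tab-separated columns ``gene<TAB>sample``; an
  optional header is recognised when the first field of the first line is
  the literal ``gene``.
* ``maf`` — a MAF-style table from which only the ``Hugo_Symbol`` and
  ``Tumor_Sample_Barcode`` columns are consumed.

The sample universe is defined by the input file, never by a network:
a sample whose mutations are all filtered away still counts in coverage
denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MutationMatrix",
    "GeneExclusivityProfile",
    "read_mutations",
    "write_mutations",
    "filter_min_recurrence",
    "exclusivity_profiles",
]


class MutationFormatError(ValueError):
    """Raised when a mutation file violates its declared dialect."""


@dataclass(frozen=True)
class MutationMatrix:
    """Binary gene x sample mutation incidence.

    Attributes
    ----------
    gene_ids : tuple of str
        Ordered, duplicate-free gene symbols (verbatim case).
    sample_ids : tuple of str
        Ordered, duplicate-free sample identifiers — the cohort universe.
    mutated_samples : mapping gene -> frozenset of samples
        For gene *g_i*, the sample set P_i in which it is mutated;
        ``n_i = |P_i|`` is the gene's coverage.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    mutated_samples: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        universe = set(self.sample_ids)
        for gene, samples in self.mutated_samples.items():
            if gene not in set(self.gene_ids):
                raise ValueError(f"gene {gene!r} not in gene_ids")
            if not samples <= universe:
                raise ValueError(f"gene {gene!r} mutated in unknown samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_of(self, gene: str) -> frozenset[str]:
        """P_i for one gene; raises KeyError naming an unknown gene."""
        try:
            return self.mutated_samples[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in the mutation matrix") from None

    def coverage(self, gene: str) -> int:
        """n_i = |P_i|."""
        return len(self.samples_of(gene))

    def union_coverage(self, genes: Iterable[str]) -> int:
        """Number of samples in which at least one of ``genes`` is mutated."""
        covered: set[str] = set()
        for g in genes:
            covered |= self.samples_of(g)
        return len(covered)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        samples: Iterable[str] | None = None,
    ) -> "MutationMatrix":
        """Build a matrix from (gene, sample) pairs, collapsing duplicates.

        ``samples`` may extend the universe beyond the samples seen in
        ``pairs`` (e.g. mutation-free samples of the cohort).
        """
        gene_order: dict[str, None] = {}
        sample_order: dict[str, None] = {}
        sets: dict[str, set[str]] = {}
        for gene, sample in pairs:
            gene_order.setdefault(gene, None)
            sample_order.setdefault(sample, None)
            sets.setdefault(gene, set()).add(sample)
        if samples is not None:
            for s in samples:
                sample_order.setdefault(s, None)
        return cls(
            gene_ids=tuple(gene_order),
            sample_ids=tuple(sample_order),
            mutated_samples={g: frozenset(s) for g, s in sets.items()},
        )


@dataclass(frozen=True)
class GeneExclusivityProfile:
    """Exclusivity bookkeeping for one gene inside a module.

    ``exclusive_samples`` is EP_i: the samples where the gene is mutated
    and no other module gene is. ``n'_i = |EP_i| <= n_i = mutated_count``.
    For a single-gene module EP_i = P_i.
    """

    gene: str
    module: tuple[str, ...]
    exclusive_samples: frozenset[str]
    mutated_count: int

    @property
    def exclusive_count(self) -> int:
        return len(self.exclusive_samples)


def read_mutations(path: str | Path, format: str = "tsv_pairs") -> MutationMatrix:
    """Read a mutation file into a :class:`MutationMatrix`.

    Parameters
    ----------
    path
        Input file.
    format
        ``"tsv_pairs"`` or ``"maf"`` (see module docstring).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv_pairs":
        return _read_tsv_pairs(path)
    if format == "maf":
        return _read_maf(path)
    raise ValueError(f"unknown mutation format {format!r}")


def _read_tsv_pairs(path: Path) -> MutationMatrix:
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise MutationFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            if lineno == 1 and fields[0] == "gene":
                continue
            pairs.append((fields[0], fields[1]))
    if not pairs:
        raise MutationFormatError(f"{path}: no mutation records found")
    return MutationMatrix.from_pairs(pairs)


def _read_maf(path: Path) -> MutationMatrix:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise MutationFormatError(f"{path}: empty MAF file") from None
    for col in ("Hugo_Symbol", "Tumor_Sample_Barcode"):
        if col not in df.columns:
            raise MutationFormatError(f"{path}: missing required MAF column {col!r}")
    if df.empty:
        raise MutationFormatError(f"{path}: MAF file has a header but no records")
    pairs = list(
        df[["Hugo_Symbol", "Tumor_Sample_Barcode"]].itertuples(index=False, name=None)
    )
    return MutationMatrix.from_pairs(pairs)


def write_mutations(m: MutationMatrix, path: str | Path) -> None:
    """Write ``tsv_pairs`` with a header, rows sorted by (gene, sample)."""
    rows = sorted(
        (gene, sample)
        for gene, samples in m.mutated_samples.items()
        for sample in samples
    )
    with open(path, "w") as fh:
        fh.write("gene\tsample\n")
        for gene, sample in rows:
            fh.write(f"{gene}\t{sample}\n")


def filter_min_recurrence(m: MutationMatrix, k: int) -> MutationMatrix:
    """Drop genes mutated in fewer than ``k`` samples.

    The sample universe is untouched: coverage denominators never shrink.
    """
    if k < 1:
        raise ValueError("minimum recurrence k must be >= 1")
    kept = tuple(g for g in m.gene_ids if len(m.mutated_samples.get(g, frozenset())) >= k)
    return MutationMatrix(
        gene_ids=kept,
        sample_ids=m.sample_ids,
        mutated_samples={g: m.mutated_samples[g] for g in kept},
    )


def exclusive_sample_sets(
    m: MutationMatrix, module: Sequence[str]
) -> list[frozenset[str]]:
    """EP_i for each module gene: samples where exactly that gene (of the
    module) is mutated. Order follows ``module``."""
    sets = [m.samples_of(g) for g in module]
    hit_counts: dict[str, int] = {}
    for samples in sets:
        for s in samples:
            hit_counts[s] = hit_counts.get(s, 0) + 1
    return [frozenset(s for s in samples if hit_counts[s] == 1) for samples in sets]


def exclusivity_profiles(
    m: MutationMatrix, module: Sequence[str]
) -> list[GeneExclusivityProfile]:
    """Per-gene exclusivity profiles for a module, in module gene order."""
    module = tuple(module)
    if not module:
        raise ValueError("module must be nonempty")
    ep_sets = exclusive_sample_sets(m, module)
    return [
        GeneExclusivityProfile(
            gene=g,
            module=module,
            exclusive_samples=ep,
            mutated_count=m.coverage(g),
        )
        for g, ep in zip(module, ep_sets)
    ]
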