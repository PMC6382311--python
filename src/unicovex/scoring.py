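"""Module evaluation: exclusivity, exclusive entropy, coverage, composite.

For a module M = {g_1, ..., g_s} with per-gene mutated-sample sets P_i
and exclusively mutated sets EP_i (samples where g_i is the only mutated
module gene), with n_i = |P_i| and n'_i = |EP_i|:

* exclusive degree      Ex(g_i) = n'_i / n_i
* exclusive score       Ex(M)   = (1/s) * sum_i Ex(g_i)        in [0, 1]
* exclusive entropy     H(M)    = -sum_i p_i log2 p_i  bits,
  with p_i = n'_i / n' and n' = sum_i n'_i; 0 log 0 := 0; H := 0 when
  n' = 0 (no exclusive mass carries no balance information)
* minimum coverage      cov(M)  = min_i n_i
* composite             UniCovEx(M) = cov(M) * Ex(M) * H(M)

H(M) is maximal (log2 s) exactly when the exclusive coverage is evenly
balanced across the genes; the composite therefore rewards modules that
are simultaneously recurrent, mutually exclusive, and balanced.
A single-gene module has H = 0 and composite 0 by construction.

The Dendrix weight W(M) = 2 * |union_i P_i| - sum_i n_i (coverage minus
coverage overlap) is provided for comparison output only; selection
never uses it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .mutations import (
    GeneExclusivityProfile,
    MutationMatrix,
    exclusive_sample_sets,
)

__all__ = [
    "ModuleScore",
    "exclusive_degree",
    "exclusive_score",
    "exclusive_entropy",
    "min_coverage",
    "union_coverage",
    "unicovex_score",
    "dendrix_weight",
]


@dataclass(frozen=True)
class ModuleScore:
    """All evaluation quantities for one gene module."""

    module: tuple[str, ...]
    ex_score: float
    entropy: float  # bits
    min_coverage: int
    union_coverage: int
    composite: float
    exclusive_total: int  # n': samples with exactly one module gene mutated
    ratios: tuple[float, ...]  # p_i per gene, module order; empty-sum safe

    @property
    def size(self) -> int:
        return len(self.module)


def exclusive_degree(profile: GeneExclusivityProfile) -> float:
    """Ex(g_i) = n'_i / n_i for one gene's profile within its module."""
    if profile.mutated_count < 1:
        raise ValueError(
            f"gene {profile.gene!r} has no mutated samples; exclusive degree undefined"
        )
    return profile.exclusive_count / profile.mutated_count


def _counts(m: MutationMatrix, module: Sequence[str]) -> tuple[list[int], list[int]]:
    """(n_i, n'_i) vectors in module order."""
    module = tuple(module)
    if not module:
        raise ValueError("module must be nonempty")
    ep = exclusive_sample_sets(m, module)
    n = [m.coverage(g) for g in module]
    return n, [len(s) for s in ep]


def exclusive_score(m: MutationMatrix, module: Sequence[str]) -> float:
    """Ex(M): mean exclusive degree over the module's genes."""
    n, n_ex = _counts(m, module)
    for g, ni in zip(module, n):
        if ni < 1:
            raise ValueError(f"gene {g!r} has no mutated samples")
    return sum(ne / ni for ne, ni in zip(n_ex, n)) / len(n)


def exclusive_entropy(m: MutationMatrix, module: Sequence[str]) -> float:
    """H(M): Shannon entropy (bits) of the exclusive-coverage shares p_i."""
    _, n_ex = _counts(m, module)
    total = sum(n_ex)
    if total == 0:
        return 0.0
    return -sum(
        (c / total) * math.log2(c / total) for c in n_ex if c > 0
    )


def min_coverage(m: MutationMatrix, module: Sequence[str]) -> int:
    """cov(M): the smallest per-gene coverage in the module."""
    n, _ = _counts(m, module)
    return min(n)


def union_coverage(m: MutationMatrix, module: Sequence[str]) -> int:
    """Samples hit by at least one module gene (the Introduction-style
    module coverage; reported alongside cov(M), never in the composite)."""
    if not module:
        raise ValueError("module must be nonempty")
    return m.union_coverage(module)


def unicovex_score(m: MutationMatrix, module: Sequence[str]) -> ModuleScore:
    """Full evaluation of a module, composite = cov(M) * Ex(M) * H(M)."""
    module = tuple(module)
    n, n_ex = _counts(m, module)
    for g, ni in zip(module, n):
        if ni < 1:
            raise ValueError(f"gene {g!r} has no mutated samples")
    total = sum(n_ex)
    ex = sum(ne / ni for ne, ni in zip(n_ex, n)) / len(n)
    if total > 0:
        ratios = tuple(c / total for c in n_ex)
        entropy = -sum(p * math.log2(p) for p in ratios if p > 0)
    else:
        ratios = tuple(0.0 for _ in n_ex)
        entropy = 0.0
    cov = min(n)
    return ModuleScore(
        module=module,
        ex_score=ex,
        entropy=entropy,
        min_coverage=cov,
        union_coverage=m.union_coverage(module),
        composite=cov * ex * entropy,
        exclusive_total=total,
        ratios=ratios,
    )


def dendrix_weight(m: MutationMatrix, module: Sequence[str]) -> int:
    """W(M) = 2 * |union P_i| - sum |P_i| (coverage minus overlap)."""
    if not module:
        raise ValueError("module must be nonempty")
    n, _ = _counts(m, module)
    return 2 * m.union_coverage(module) - sum(n)
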