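"""Shared fixtures: small hand-built matrices and random-instance factories."""

from __future__ import annotations

import numpy as np
import pytest

from unicovex.mutations import MutationMatrix


def make_random_matrix(
    rng: np.random.Generator, n_genes: int, n_samples: int, density: float = 0.3
) -> MutationMatrix:
    """Random binary matrix; every gene mutated in >= 1 sample."""
    genes = [f"g{i:02d}" for i in range(n_genes)]
    samples = [f"s{i:02d}" for i in range(n_samples)]
    sets = {}
    for g in genes:
        hits = [s for s in samples if rng.random() < density]
        if not hits:
            hits = [samples[int(rng.integers(n_samples))]]
        sets[g] = frozenset(hits)
    return MutationMatrix(tuple(genes), tuple(samples), sets)


def brute_force_exclusive_sets(m: MutationMatrix, module) -> list[frozenset[str]]:
    """Independent per-sample enumeration of 'exactly one module gene mutated'."""
    out = []
    for g in module:
        ep = set()
        for s in m.sample_ids:
            hits = [h for h in module if s in m.samples_of(h)]
            if hits == [g]:
                ep.add(s)
        out.append(frozenset(ep))
    return out


@pytest.fixture
def balanced_exclusive_matrix() -> MutationMatrix:
    """4 genes over 8 samples, strictly exclusive, 2 samples per gene."""
    pairs = [(f"g{i}", f"s{2 * i + j}") for i in range(4) for j in range(2)]
    return MutationMatrix.from_pairs(pairs)


@pytest.fixture
def unbalanced_exclusive_matrix() -> MutationMatrix:
    """4 genes over 8 samples, strictly exclusive, counts (4, 2, 1, 1)."""
    pairs = (
        [("g0", f"s{i}") for i in range(4)]
        + [("g1", f"s{i}") for i in range(4, 6)]
        + [("g2", "s6"), ("g3", "s7")]
    )
    return MutationMatrix.from_pairs(pairs)


@pytest.fixture
def random_matrix_factory():
    return make_random_matrix
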