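"""Shared fixtures: small simulated families and random additive trees."""

from __future__ import annotations

import collections

import numpy as np
import pytest

from rlkscan.phylo import DistanceMatrix
from rlkscan.records import SeqRecord
from rlkscan.simulate import SimConfig, canonical_kinase_protein, simulate_family

AA20 = list("ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture(scope="session")
def canonical_protein() -> SeqRecord:
    """Synthetic canonical kinase-domain fragment with all anchors planted."""
    return SeqRecord(id="canonical", residues=canonical_kinase_protein(rd=True),
                     alphabet="aa")


@pytest.fixture(scope="session")
def small_family():
    """A 2-group × 6-member simulated family (165 codons, default regions)."""
    return simulate_family(SimConfig(n_groups=2, members_per_group=6, seed=7))


@pytest.fixture(scope="session")
def four_group_family():
    """Default-scale family: 4 groups × 8 members, alternating RD/non-RD."""
    return simulate_family(SimConfig(seed=42))


def random_additive_matrix(n: int, rng: np.random.Generator) -> DistanceMatrix:
    """Patristic distance matrix of a random binary tree with branch
    lengths in [0.05, 1.0] — an additive matrix by construction."""
    adj: dict[str, list[tuple[str, float]]] = collections.defaultdict(list)
    active = [f"L{i}" for i in range(n)]
    next_id = 0
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[int(i)], active[int(j)]
        new = f"N{next_id}"
        next_id += 1
        for x in (a, b):
            w = float(rng.uniform(0.05, 1.0))
            adj[new].append((x, w))
            adj[x].append((new, w))
        active = [x for x in active if x not in (a, b)] + [new]
    a, b = active
    w = float(rng.uniform(0.05, 1.0))
    adj[a].append((b, w))
    adj[b].append((a, w))
    labels = tuple(sorted(f"L{i}" for i in range(n)))
    d = np.zeros((n, n))
    for ii, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        seen = {src}
        while stack:
            u = stack.pop()
            for v, wt in adj[u]:
                if v not in seen:
                    seen.add(v)
                    dist[v] = dist[u] + wt
                    stack.append(v)
        for jj, dst in enumerate(labels):
            d[ii, jj] = dist[dst]
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, d=d)


def perturb_protein(s: str, n_changes: int, rng: np.random.Generator) -> str:
    chars = list(s)
    for pos in rng.choice(len(chars), size=n_changes, replace=False):
        chars[pos] = str(rng.choice(AA20))
    return "".join(chars)
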