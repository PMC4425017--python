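"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from barcodeval import LabeledAlignment, SequenceRecord
from barcodeval.distances import DistanceMatrix


def make_aln(rows, region="") -> LabeledAlignment:
    """Build an alignment from (species, sample_id, residues) triples."""
    return LabeledAlignment(
        records=[
            SequenceRecord(sample_id=sid, species=sp, residues=seq, region=region)
            for sp, sid, seq in rows
        ],
        region=region,
    )


def make_dm(species, values, defined=None) -> DistanceMatrix:
    """Build a DistanceMatrix directly from a species list and a square array."""
    values = np.asarray(values, dtype=float)
    if defined is None:
        defined = ~np.isnan(values)
        np.fill_diagonal(defined, True)
    labels = [(sp, f"s{i}") for i, sp in enumerate(species)]
    return DistanceMatrix(labels=labels, values=values, defined=np.asarray(defined))


def random_dataset(rng, max_records=30, max_species=8, length=60):
    """A small random species-labeled alignment with erratic divergences.

    Sequences are built species-by-species from random ancestors with random
    per-individual noise, so nearest neighbours are not guaranteed to be
    conspecific — deliberately messy input for identification tests.
    """
    from barcodeval import SimulationConfig, simulate_dataset

    n_species = int(rng.integers(2, max_species + 1))
    counts = [int(rng.integers(1, 5)) for _ in range(n_species)]
    while sum(counts) > max_records:
        counts[int(rng.integers(0, n_species))] = 1
    cfg = SimulationConfig(
        n_species=n_species,
        individuals_per_species=counts,
        seq_length=length,
        intra_divergence=float(rng.uniform(0.0, 0.15)),
        inter_divergence=float(rng.uniform(0.0, 0.4)),
        kappa=float(rng.uniform(0.5, 4.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    aln, _ = simulate_dataset(cfg)
    return aln


def brute_force_best_match(dm: DistanceMatrix, tie_tolerance=1e-10):
    """Plain-loop enumeration of BM verdicts, independent of the implementation."""
    out = {}
    n = len(dm)
    for i in range(n):
        cands = [
            (float(dm.values[i, j]), dm.labels[j][0])
            for j in range(n)
            if j != i and dm.defined[i, j]
        ]
        if not cands:
            out[dm.labels[i]] = None
            continue
        best = min(d for d, _ in cands)
        tied = {sp for d, sp in cands if d <= best + tie_tolerance}
        q_sp = dm.labels[i][0]
        if tied == {q_sp}:
            cat = "correct"
        elif q_sp in tied:
            cat = "ambiguous"
        else:
            cat = "incorrect"
        out[dm.labels[i]] = (best, frozenset(tied), cat)
    return out


class RandomAdditiveTree:
    """Random binary unrooted tree with positive edge lengths.

    Provides the exact path-length (additive) distance matrix and the set of
    nontrivial bipartitions, canonicalized as the side not containing leaf 0
    — an independent oracle for neighbor joining.
    """

    def __init__(self, n_leaves: int, rng: np.random.Generator):
        # Sequential random joining of subtrees until three remain, then a
        # star root: yields a uniform-ish unrooted binary topology.
        self.n = n_leaves
        nodes = list(range(n_leaves))  # node ids; leaves are 0..n-1
        next_id = n_leaves
        self.adj: dict[int, list[tuple[int, float]]] = {i: [] for i in nodes}

        def connect(a, b):
            w = float(rng.uniform(0.05, 1.0))
            self.adj.setdefault(a, []).append((b, w))
            self.adj.setdefault(b, []).append((a, w))

        while len(nodes) > 3:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            a, b = nodes[i], nodes[j]
            parent = next_id
            next_id += 1
            connect(parent, a)
            connect(parent, b)
            nodes = [x for x in nodes if x not in (a, b)] + [parent]
        root = next_id
        for x in nodes:
            connect(root, x)

    def distance_matrix(self) -> np.ndarray:
        import heapq

        D = np.zeros((self.n, self.n))
        for src in range(self.n):
            dist = {src: 0.0}
            heap = [(0.0, src)]
            while heap:
                d, u = heapq.heappop(heap)
                if d > dist.get(u, np.inf):
                    continue
                for v, w in self.adj[u]:
                    nd = d + w
                    if nd < dist.get(v, np.inf):
                        dist[v] = nd
                        heapq.heappush(heap, (nd, v))
            for t in range(self.n):
                D[src, t] = dist[t]
        return D

    def splits(self) -> set[frozenset[int]]:
        out = set()
        full = frozenset(range(self.n))
        for u in self.adj:
            for v, _ in self.adj[u]:
                if u > v:
                    continue
                # leaves on v's side of edge (u, v)
                seen = {u, v}
                stack = [v]
                side = set()
                while stack:
                    x = stack.pop()
                    if x < self.n:
                        side.add(x)
                    for y, _ in self.adj[x]:
                        if y not in seen:
                            seen.add(y)
                            stack.append(y)
                if 2 <= len(side) <= self.n - 2:
                    fs = frozenset(side)
                    out.add(fs if 0 not in fs else full - fs)
        return out


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)
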