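"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithmic paths: alignment
scores come from exhaustive path enumeration, trees from least-squares
fits over all unrooted topologies, and isoelectric points from a dense
grid search.
"""

from __future__ import annotations

import itertools
import sys

import numpy as np
from Bio.Align import substitution_matrices

sys.setrecursionlimit(200_000)

_B62 = substitution_matrices.load("BLOSUM62")


def exhaustive_global_score(a: str, b: str, gap_open=-10.0, gap_extend=-0.5) -> float:
    """Optimal global affine-gap score by enumerating every alignment path."""
    best = [-1e18]

    def rec(i, j, last, score):
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "D", score + _B62[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "A", score + (gap_extend if last == "A" else gap_open))
        if j < len(b):
            rec(i, j + 1, "B", score + (gap_extend if last == "B" else gap_open))

    rec(0, 0, None, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# grid-search isoelectric point

def grid_isoelectric_point(aa_seq: str, step: float = 1e-4) -> float:
    """argmin |charge| over a dense pH grid on [2, 13] (Bjellqvist constants)."""
    from laccmine.physchem import (
        PKA_CTERM,
        PKA_NEGATIVE_SIDECHAIN,
        PKA_NTERM_BY_RESIDUE,
        PKA_NTERM_DEFAULT,
        PKA_POSITIVE_SIDECHAIN,
    )

    pH = np.arange(2.0, 13.0 + step / 2, step)
    q = np.zeros_like(pH)
    nterm = PKA_NTERM_BY_RESIDUE.get(aa_seq[0], PKA_NTERM_DEFAULT)
    for count, pka in [(1, nterm)] + [
        (aa_seq.count(r), p) for r, p in PKA_POSITIVE_SIDECHAIN.items()
    ]:
        if count:
            q += count / (1.0 + 10.0 ** (pH - pka))
    for count, pka in [(1, PKA_CTERM)] + [
        (aa_seq.count(r), p) for r, p in PKA_NEGATIVE_SIDECHAIN.items()
    ]:
        if count:
            q -= count / (1.0 + 10.0 ** (pka - pH))
    return float(pH[np.argmin(np.abs(q))])


# ---------------------------------------------------------------------------
# unrooted tree enumeration + least-squares fit

def enumerate_topologies(names: list[str]) -> list[list[tuple]]:
    """All unrooted binary topologies on the given leaves, as edge lists."""
    if len(names) < 3:
        raise ValueError("need >= 3 leaves")
    trees = [([(names[0], "i0"), (names[1], "i0"), (names[2], "i0")], 1)]
    for taxon in names[3:]:
        nxt = []
        for edges, ni in trees:
            for k, (u, v) in enumerate(edges):
                w = f"i{ni}"
                e2 = edges[:k] + edges[k + 1 :] + [(u, w), (v, w), (taxon, w)]
                nxt.append((e2, ni + 1))
        trees = nxt
    return [e for e, _ in trees]


def _paths(edges: list[tuple], leaves: list[str]) -> dict:
    adj: dict = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    paths = {}
    for leaf in leaves:
        stack = [(leaf, frozenset())]
        seen = {leaf}
        while stack:
            node, used = stack.pop()
            for nbr, eidx in adj[node]:
                if nbr in seen:
                    continue
                seen.add(nbr)
                nused = used | {eidx}
                if isinstance(nbr, str) and not nbr.startswith("i"):
                    paths[(leaf, nbr)] = nused
                stack.append((nbr, nused))
    return paths


def least_squares_fit(edges: list[tuple], leaves: list[str], dmat: np.ndarray) -> float:
    """Sum of squared errors of the best branch-length fit for one topology."""
    paths = _paths(edges, leaves)
    idx = {n: i for i, n in enumerate(leaves)}
    A, y = [], []
    for a, b in itertools.combinations(leaves, 2):
        row = np.zeros(len(edges))
        for e in paths[(a, b)]:
            row[e] = 1.0
        A.append(row)
        y.append(dmat[idx[a], idx[b]])
    A, y = np.asarray(A), np.asarray(y)
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ x - y) ** 2))


def best_ls_topology(leaves: list[str], dmat: np.ndarray) -> set[frozenset]:
    """Bipartitions of the least-squares-optimal topology (brute force)."""
    best_sse, best_edges = np.inf, None
    for edges in enumerate_topologies(leaves):
        sse = least_squares_fit(edges, leaves, dmat)
        if sse < best_sse - 1e-12:
            best_sse, best_edges = sse, edges
    return edge_bipartitions(best_edges, leaves)


def edge_bipartitions(edges: list[tuple], leaves: list[str]) -> set[frozenset]:
    """Canonical internal bipartitions (smaller side) of an edge-list tree."""
    out: set[frozenset] = set()
    all_leaves = frozenset(leaves)
    for k, (u, v) in enumerate(edges):
        adj: dict = {}
        for idx, (a, b) in enumerate(edges):
            if idx == k:
                continue
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        side = set()
        stack = [u]
        seen = {u}
        while stack:
            node = stack.pop()
            if isinstance(node, str) and not node.startswith("i"):
                side.add(node)
            for nbr in adj.get(node, []):
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        side_f = frozenset(side)
        if 1 < len(side_f) < len(all_leaves) - 1:
            out.add(min(side_f, other_side(side_f, all_leaves),
                        key=lambda s: (len(s), tuple(sorted(s)))))
    return out


def other_side(side: frozenset, universe: frozenset) -> frozenset:
    return universe - side


def random_additive_tree(rng: np.random.Generator, names: list[str]):
    """A random topology with positive lengths and its additive distances."""
    topos = enumerate_topologies(names)
    edges = topos[int(rng.integers(len(topos)))]
    lengths = rng.uniform(0.05, 1.0, size=len(edges))
    paths = _paths(edges, names)
    n = len(names)
    d = np.zeros((n, n))
    idx = {n_: i for i, n_ in enumerate(names)}
    for a, b in itertools.combinations(names, 2):
        val = sum(lengths[e] for e in paths[(a, b)])
        d[idx[a], idx[b]] = d[idx[b], idx[a]] = val
    return edges, lengths, d
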