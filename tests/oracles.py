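"""Independent reference implementations used only to check the package.

These share no code with panfam: the MCL reference is a dense pure-numpy
implementation with its own cluster extraction; the query oracle is a
brute-force scan; the GPR oracle evaluates rule text through Python's own
boolean operators. They exist so the package's sparse/vectorized routes can
be compared against straightforward, obviously-correct computations.
"""

from __future__ import annotations

import itertools
import math
import re

import numpy as np


def mcl_reference(
    nodes: list[str],
    weights: dict[tuple[str, str], float],
    inflation: float,
    max_iter: int = 100,
    prune: float = 1e-5,
    tol: float = 1e-6,
) -> list[frozenset[str]]:
    """Dense MCL: same parameters and contract as panfam.mcl, fresh code.

    Self-loops are the max incident weight (1 for isolated nodes); clusters
    are attractor systems; a node flowing to several systems goes to the one
    whose smallest member sorts first.
    """
    n = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    m = np.zeros((n, n))
    for (a, b), w in weights.items():
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    for i in range(n):
        mx = m[i].max()
        m[i, i] = mx if mx > 0 else 1.0
    m = m / m.sum(axis=0)
    for _ in range(max_iter):
        prev = m.copy()
        m = m @ m
        m = m ** inflation
        m = m / m.sum(axis=0)
        m[m < prune] = 0.0
        s = m.sum(axis=0)
        s[s == 0] = 1.0
        m = m / s
        if np.abs(m - prev).max() < tol:
            break

    attractors = [i for i in range(n) if m[i, i] > 0]
    # union-find over attractors sharing support
    parent = {a: a for a in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    aset = set(attractors)
    for a in attractors:
        for j in np.flatnonzero(m[a] > 0):
            if int(j) in aset:
                ra, rj = find(a), find(int(j))
                if ra != rj:
                    parent[max(ra, rj)] = min(ra, rj)
    systems: dict[int, set[int]] = {}
    for a in attractors:
        systems.setdefault(find(a), set()).add(a)
    clusters = list(systems.values())
    if not clusters:
        return [frozenset([x]) for x in nodes]
    claimed = set().union(*clusters)
    for j in range(n):
        if j in claimed:
            continue
        cands = [c for c in clusters if any(m[a, j] > 0 for a in c & aset)]
        if not cands:
            clusters.append({j})
            continue
        cands.sort(key=lambda c: min(nodes[i] for i in c))
        cands[0].add(j)
    return [frozenset(nodes[i] for i in c) for c in clusters]


def random_weighted_graph(n_max: int, rng: np.random.Generator,
                          p_edge: float = 0.4) -> tuple[list[str], dict]:
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"n{i:02d}" for i in range(n)]
    weights = {}
    for a, b in itertools.combinations(nodes, 2):
        if rng.random() < p_edge:
            weights[(a, b)] = float(np.round(rng.uniform(0.05, 1.0), 3))
    return nodes, weights


# ---------------------------------------------------------------------------
# Brute-force presence-pattern queries


def brute_force_pattern(counts: dict, genomes: list[str], group: list[str],
                        mode: str, fraction: float = 1.0,
                        all_organisms: list[str] | None = None) -> set:
    """counts: family -> genome -> copy number. Plain loops, no vectorization."""
    out = set()
    others = sorted(set(all_organisms or genomes) - set(group))
    for fam, per in counts.items():
        n_in = sum(1 for g in group if per.get(g, 0) >= 1)
        n_out = sum(1 for g in others if per.get(g, 0) >= 1)
        if mode == "all" and n_in >= math.ceil(fraction * len(group)):
            out.add(fam)
        elif mode == "any" and n_in >= 1:
            out.add(fam)
        elif mode == "only" and n_in >= 1 and n_out == 0:
            out.add(fam)
        elif mode == "none" and n_in == 0:
            out.add(fam)
    return out


def brute_force_single_copy(counts: dict, group: list[str]) -> set:
    return {fam for fam, per in counts.items()
            if all(per.get(g, 0) == 1 for g in group)}


# ---------------------------------------------------------------------------
# GPR truth-table oracle: evaluate the rule text with Python's own and/or


def eval_gpr_via_python(text: str, assignment: dict[str, bool]) -> bool:
    expr = text
    for gene, val in sorted(assignment.items(), key=lambda kv: -len(kv[0])):
        expr = re.sub(rf"(?<![\w.]){re.escape(gene)}(?![\w.])", str(bool(val)), expr)
    return bool(eval(expr, {"__builtins__": {}}, {}))


def random_gpr(rng: np.random.Generator, genes: list[str], max_depth: int = 4) -> str:
    if max_depth == 0 or rng.random() < 0.35:
        return str(rng.choice(genes))
    op = " and " if rng.random() < 0.5 else " or "
    k = int(rng.integers(2, 4))
    return "(" + op.join(random_gpr(rng, genes, max_depth - 1)
                         for _ in range(k)) + ")"
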