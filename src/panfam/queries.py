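"""Presence/absence matrices and core/variable/unique gene-content queries.

The central object is the family × genome copy-number matrix derived from a
cluster run. On top of it sit the four presence-pattern queries (all / any /
only / none of an organism group, with an optional conservation fraction for
"all"), single-copy core families, per-clade conservation and uniqueness on
a rooted organism phylogeny, and comparison of family presence between two
cluster runs (e.g. complete-only vs complete+draft genome sets).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .store import ClusterRun

__all__ = [
    "PresenceAbsenceMatrix",
    "CladeTree",
    "presence_matrix",
    "families_by_pattern",
    "single_copy_core",
    "clade_conservation",
    "clade_unique_families",
    "cross_run_presence",
]


@dataclass
class PresenceAbsenceMatrix:
    """Copy-number counts of each family in each genome for one cluster run."""

    counts: pd.DataFrame  # index: family_id, columns: genome_id, values >= 0
    run_id: str = ""

    @property
    def families(self) -> list:
        return list(self.counts.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.columns)

    def presence(self) -> pd.DataFrame:
        return self.counts >= 1

    def to_tsv(self, fh) -> None:
        self.counts.to_csv(fh, sep="\t")


def presence_matrix(
    run: ClusterRun,
    gene_genomes: Mapping[str, str],
    genomes: Iterable[str] | None = None,
) -> PresenceAbsenceMatrix:
    """Count genes of each genome in each family of a run.

    ``gene_genomes`` maps gene id to genome id (e.g. store.gene_genome_map()).
    ``genomes`` fixes the column set; by default it is every genome with at
    least one gene in the run.
    """
    fam_ids = sorted(run.families)
    if genomes is None:
        genomes = sorted({gene_genomes[g] for fam in run.families.values() for g in fam})
    else:
        genomes = sorted(genomes)
    gidx = {g: j for j, g in enumerate(genomes)}
    mat = np.zeros((len(fam_ids), len(genomes)), dtype=int)
    for i, fid in enumerate(fam_ids):
        for gene in run.families[fid]:
            genome = gene_genomes[gene]
            if genome in gidx:
                mat[i, gidx[genome]] += 1
    df = pd.DataFrame(mat, index=pd.Index(fam_ids, name="family_id"), columns=genomes)
    return PresenceAbsenceMatrix(counts=df, run_id=run.run_id)


def families_by_pattern(
    mat: PresenceAbsenceMatrix,
    group: Iterable[str],
    mode: str,
    fraction: float = 1.0,
    all_organisms: Iterable[str] | None = None,
) -> set:
    """Families matching a presence pattern over an organism group.

    mode="all": present in at least ceil(fraction * |group|) group genomes
    (conserved genes); "any": present in >= 1 (present genes); "only":
    present in >= 1 group genome and absent from every other organism in
    ``all_organisms`` (unique genes); "none": absent from every group genome.
    ``fraction`` applies to mode="all" only.
    """
    group = sorted(set(group))
    if not group:
        raise ValueError("empty organism group")
    missing = [g for g in group if g not in mat.counts.columns]
    if missing:
        raise ValueError(f"group genomes not in matrix: {missing}")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")

    pres = mat.presence()
    in_group = pres[group].sum(axis=1)

    if mode == "all":
        need = math.ceil(fraction * len(group))
        sel = in_group >= need
    elif mode == "any":
        sel = in_group >= 1
    elif mode == "none":
        sel = in_group == 0
    elif mode == "only":
        if all_organisms is None:
            all_organisms = mat.genomes
        others = sorted(set(all_organisms) - set(group))
        bad = [g for g in others if g not in mat.counts.columns]
        if bad:
            raise ValueError(f"organisms not in matrix: {bad}")
        outside = pres[others].sum(axis=1) if others else pd.Series(0, index=pres.index)
        sel = (in_group >= 1) & (outside == 0)
    else:
        raise ValueError(f"unknown mode {mode!r}; choose all/any/only/none")
    return set(pres.index[sel])


def single_copy_core(mat: PresenceAbsenceMatrix, group: Iterable[str]) -> set:
    """Families with exactly one copy in every genome of the group."""
    group = sorted(set(group))
    if not group:
        raise ValueError("empty organism group")
    sub = mat.counts[group]
    sel = (sub == 1).all(axis=1)
    return set(sub.index[sel])


# ---------------------------------------------------------------------------
# Clade-based queries


class CladeTree:
    """Rooted organism phylogeny with stable internal-node ids.

    Leaves are labeled with genome ids. Internal nodes keep their Newick
    labels when present; unlabeled nodes get deterministic post-order ids
    "N<k>" so query results can be tied back to tree positions.
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        self.tree = tree
        counter = 0
        labels = set()
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                continue
            if node.label:
                labels.add(node.label)
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                node.node_id = node.taxon.label if node.taxon else node.label
            elif node.label:
                node.node_id = node.label
            else:
                while f"N{counter}" in labels:
                    counter += 1
                node.node_id = f"N{counter}"
                counter += 1

    @classmethod
    def from_newick(cls, source: str) -> "CladeTree":
        if "(" in source:
            tree = dendropy.Tree.get(data=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=source, schema="newick")
        return cls(tree)

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def nodes(self):
        return list(self.tree.postorder_node_iter())

    @staticmethod
    def leaves_under(node) -> list[str]:
        return [lf.taxon.label for lf in node.leaf_iter()]


def _check_leaves(tree: CladeTree, mat: PresenceAbsenceMatrix) -> None:
    missing = [l for l in tree.leaf_labels() if l not in mat.counts.columns]
    if missing:
        raise ValueError(f"tree leaves missing from matrix: {missing}")


def clade_conservation(
    mat: PresenceAbsenceMatrix,
    tree: CladeTree,
    reading: str = "organisms",
) -> pd.DataFrame:
    """Number (and identity) of families conserved in each clade.

    reading="organisms": a family counts at a node when it is present in
    every leaf genome under the node. reading="children": it counts when it
    has at least one representative under each child of the node (a weaker
    condition for families patchily present within a child clade). Leaf rows
    are included; under both readings they reduce to presence in that genome.
    """
    if reading not in ("organisms", "children"):
        raise ValueError(f"unknown reading {reading!r}")
    _check_leaves(tree, mat)
    pres = mat.presence()
    rows = []
    conserved_at: dict[int, frozenset] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            fams = frozenset(pres.index[pres[label]])
        elif reading == "organisms":
            leaves = CladeTree.leaves_under(node)
            sel = pres[leaves].all(axis=1)
            fams = frozenset(pres.index[sel])
        else:
            child_sets = [conserved_if_any(pres, CladeTree.leaves_under(c))
                          for c in node.child_nodes()]
            fams = frozenset.intersection(*child_sets) if child_sets else frozenset()
        conserved_at[id(node)] = fams
        rows.append((node.node_id, len(fams), sorted(fams)))
    out = pd.DataFrame(rows, columns=["node_id", "n_conserved_families", "families"])
    return out.sort_values("node_id", kind="stable").reset_index(drop=True)


def conserved_if_any(pres: pd.DataFrame, leaves: list[str]) -> frozenset:
    sel = pres[leaves].any(axis=1)
    return frozenset(pres.index[sel])


def clade_unique_families(mat: PresenceAbsenceMatrix, tree: CladeTree) -> pd.DataFrame:
    """Families present under a node and absent from every leaf outside it."""
    _check_leaves(tree, mat)
    pres = mat.presence()
    all_leaves = set(tree.leaf_labels())
    rows = []
    for node in tree.tree.postorder_node_iter():
        inside = CladeTree.leaves_under(node) if not node.is_leaf() \
            else [node.taxon.label]
        outside = sorted(all_leaves - set(inside))
        sel = pres[inside].any(axis=1)
        if outside:
            sel &= ~pres[outside].any(axis=1)
        fams = sorted(pres.index[sel])
        rows.append((node.node_id, len(fams), fams))
    out = pd.DataFrame(rows, columns=["node_id", "n_unique_families", "families"])
    return out.sort_values("node_id", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cross-run comparison


def cross_run_presence(
    run_a: ClusterRun,
    run_b: ClusterRun,
    focus_genomes: Iterable[str],
    gene_genomes: Mapping[str, str],
) -> pd.DataFrame:
    """Map each family of run A onto run B via shared genes and report which
    focus genomes lose coverage.

    For every family of A: the B families sharing at least one gene, the
    union of genomes those B families cover, and the focus genomes not
    covered ("missing_in"). This is the computation behind comparing a
    complete-genomes-only clustering against one that also includes drafts.
    """
    focus = sorted(set(focus_genomes))
    b_of_gene = run_b.gene_to_family()
    if not set(b_of_gene) & run_a.all_genes():
        warnings.warn("cluster runs share no gene ids; every family will be unmapped")
    b_genomes = {
        fid: frozenset(gene_genomes[g] for g in fam)
        for fid, fam in run_b.families.items()
    }
    rows = []
    for fid in sorted(run_a.families):
        fam = run_a.families[fid]
        covered_a = sorted({gene_genomes[g] for g in fam})
        mapped = sorted({b_of_gene[g] for g in fam if g in b_of_gene})
        covered_b: set[str] = set()
        for bfid in mapped:
            covered_b |= b_genomes[bfid]
        missing = sorted(set(focus) - covered_b)
        rows.append((fid, covered_a, mapped, sorted(covered_b), missing))
    return pd.DataFrame(rows, columns=[
        "family_a", "covered_genomes_in_a", "mapped_families_b",
        "covered_genomes_in_b", "missing_in",
    ])
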