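"""Boolean gene-protein-reaction (GPR) rules and draft-model propagation.

A metabolic reconstruction ties each reaction to its genes through a Boolean
GPR: genes that must all be present (enzyme complexes) are joined with AND,
isozymes with OR. A reaction is called present in a target genome when its
GPR evaluates TRUE under the gene presence implied by protein families: a
reference gene counts as present in a target iff its family contains at
least one gene from that genome.

Grammar: AND binds tighter than OR, parentheses override, keywords are
case-insensitive. Reactions with no GPR carry no gene evidence and are
reported as such rather than being forced to a binary call.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .store import ClusterRun

__all__ = [
    "GprError",
    "Gene",
    "And",
    "Or",
    "parse_gpr",
    "render_gpr",
    "gpr_genes",
    "evaluate_gpr",
    "ReactionRecord",
    "read_reactions_tsv",
    "read_reactions_sbml",
    "gene_presence",
    "PropagationResult",
    "propagate_model",
    "cutoff_sweep",
]

logger = logging.getLogger(__name__)


class GprError(ValueError):
    pass


@dataclass(frozen=True)
class Gene:
    name: str


@dataclass(frozen=True)
class And:
    children: tuple


@dataclass(frozen=True)
class Or:
    children: tuple


GprNode = Gene | And | Or

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> GprNode | None:
    """Parse a GPR string into an expression tree; None for an empty rule."""
    tokens = _TOKEN.findall(text)
    if not tokens:
        return None
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def _flatten(parts: list[GprNode], kind) -> tuple:
        # canonical tree: nested same-operator nodes are spliced in place
        flat: list[GprNode] = []
        for p in parts:
            if isinstance(p, kind):
                flat.extend(p.children)
            else:
                flat.append(p)
        return tuple(flat)

    def parse_or() -> GprNode:
        parts = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            parts.append(parse_and())
        return parts[0] if len(parts) == 1 else Or(_flatten(parts, Or))

    def parse_and() -> GprNode:
        parts = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            parts.append(parse_atom())
        return parts[0] if len(parts) == 1 else And(_flatten(parts, And))

    def parse_atom() -> GprNode:
        tok = peek()
        if tok is None:
            raise GprError(f"unexpected end of expression at token {pos} in {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GprError(f"unbalanced parentheses at token {pos} in {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprError(f"unexpected {tok!r} at token {pos} in {text!r}")
        return Gene(take())

    node = parse_or()
    if pos != len(tokens):
        raise GprError(f"trailing input at token {pos} in {text!r}")
    return node


def render_gpr(node: GprNode | None) -> str:
    """Canonical text form; round-trips through parse_gpr semantics-preserving."""
    if node is None:
        return ""
    if isinstance(node, Gene):
        return node.name
    if isinstance(node, And):
        return " and ".join(
            f"({render_gpr(c)})" if isinstance(c, Or) else render_gpr(c)
            for c in node.children
        )
    return " or ".join(render_gpr(c) for c in node.children)


def gpr_genes(node: GprNode | None) -> set[str]:
    if node is None:
        return set()
    if isinstance(node, Gene):
        return {node.name}
    return set().union(*(gpr_genes(c) for c in node.children))


def evaluate_gpr(node: GprNode | None, presence: Mapping[str, bool]) -> bool:
    """Standard Boolean evaluation; leaves absent from ``presence`` default
    to False (logged), matching the fail-soft handling of id drift between a
    published model and the genome's gene table."""
    if node is None:
        return False
    if isinstance(node, Gene):
        if node.name not in presence:
            logger.info("GPR gene %s has no presence value; defaulting to absent",
                        node.name)
            return False
        return bool(presence[node.name])
    if isinstance(node, And):
        return all(evaluate_gpr(c, presence) for c in node.children)
    return any(evaluate_gpr(c, presence) for c in node.children)


# ---------------------------------------------------------------------------
# Reactions and propagation


@dataclass
class ReactionRecord:
    reaction_id: str
    name: str
    gpr: str  # textual rule; "" for spontaneous / orphan reactions
    reference_genome_id: str = ""
    _tree: GprNode | None = field(default=None, repr=False, compare=False)

    @property
    def tree(self) -> GprNode | None:
        if self._tree is None and self.gpr.strip():
            self._tree = parse_gpr(self.gpr)
        return self._tree

    @property
    def gene_associated(self) -> bool:
        return bool(self.gpr.strip())


def read_reactions_tsv(path: str | Path, reference_genome_id: str = "") -> list[ReactionRecord]:
    """Read a reaction table: reaction_id, name, gpr (tab-separated)."""
    out = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) < 3:
                raise GprError(f"line {lineno}: expected 3 columns, got {len(p)}")
            if p[0] in seen:
                raise GprError(f"line {lineno}: duplicate reaction_id {p[0]}")
            seen.add(p[0])
            out.append(ReactionRecord(p[0], p[1], p[2], reference_genome_id))
    return out


def read_reactions_sbml(path: str | Path, reference_genome_id: str = "") -> list[ReactionRecord]:
    """Import reaction ids + GPR strings from an SBML model (via cobrapy)."""
    import cobra.io

    model = cobra.io.read_sbml_model(str(path))
    return [
        ReactionRecord(rxn.id, rxn.name or "", rxn.gene_reaction_rule or "",
                       reference_genome_id)
        for rxn in model.reactions
    ]


def gene_presence(
    reference_gene_id: str,
    target_genome_id: str,
    run: ClusterRun,
    gene_genomes: Mapping[str, str],
    _fam_genomes: Mapping[int, frozenset] | None = None,
) -> bool:
    """True iff the family containing the reference gene has >= 1 gene from
    the target genome. A reference gene in no family is treated as absent."""
    g2f = run.gene_to_family()
    fid = g2f.get(reference_gene_id)
    if fid is None:
        warnings.warn(f"reference gene {reference_gene_id} is in no family; "
                      "treated as absent")
        return False
    fams = _fam_genomes or {}
    genomes = fams.get(fid) or frozenset(
        gene_genomes[g] for g in run.families[fid]
    )
    return target_genome_id in genomes


@dataclass
class PropagationResult:
    """Reaction × genome status matrix: present / absent / no_gene_evidence."""

    status: pd.DataFrame  # index reaction_id, columns target genomes
    run_id: str
    cutoff: float

    def n_missing(self, genome: str) -> int:
        return int((self.status[genome] == "absent").sum())

    def to_tsv(self, fh) -> None:
        self.status.to_csv(fh, sep="\t")


def propagate_model(
    model: Sequence[ReactionRecord],
    targets: Iterable[str],
    run: ClusterRun,
    gene_genomes: Mapping[str, str],
) -> PropagationResult:
    """Evaluate every reaction's GPR in every target genome under family-based
    gene presence. Reactions with empty GPRs get no_gene_evidence."""
    targets = sorted(set(targets))
    if not model:
        raise GprError("empty model")
    ref = model[0].reference_genome_id
    run_genomes = {gene_genomes[g] for g in run.all_genes()}
    if ref and ref not in run_genomes:
        raise GprError(f"reference genome {ref} is not in the cluster run's group")
    bad = [t for t in targets if t not in run_genomes]
    if bad:
        raise GprError(f"target genomes not in the cluster run's group: {bad}")

    g2f = run.gene_to_family()
    fam_genomes = {
        fid: frozenset(gene_genomes[g] for g in fam)
        for fid, fam in run.families.items()
    }
    all_genes = {g for rxn in model for g in gpr_genes(rxn.tree)}
    data = {}
    for target in targets:
        presence = {}
        for g in all_genes:
            fid = g2f.get(g)
            presence[g] = fid is not None and target in fam_genomes[fid]
        col = []
        for rxn in model:
            if not rxn.gene_associated:
                col.append("no_gene_evidence")
            else:
                col.append("present" if evaluate_gpr(rxn.tree, presence) else "absent")
        data[target] = col
    df = pd.DataFrame(data, index=pd.Index([r.reaction_id for r in model],
                                           name="reaction_id"))
    return PropagationResult(status=df, run_id=run.run_id, cutoff=run.cutoff)


def cutoff_sweep(
    model: Sequence[ReactionRecord],
    target: str,
    runs: Sequence[ClusterRun],
    gene_genomes: Mapping[str, str],
) -> pd.DataFrame:
    """Missing gene-associated reactions in a target as a function of the
    homology cutoff, across runs sharing group and metric."""
    if not runs:
        raise GprError("no cluster runs supplied")
    groups = {(r.group, r.metric) for r in runs}
    if len(groups) > 1:
        raise GprError(f"runs mix groups/metrics: {sorted(groups)}")
    rows = []
    for run in sorted(runs, key=lambda r: r.cutoff):
        res = propagate_model(model, [target], run, gene_genomes)
        rows.append((run.cutoff, res.n_missing(target)))
    return pd.DataFrame(rows, columns=["cutoff", "n_missing_reactions"])
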