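"""Ground-truth pan-genome simulator.

Generates everything the rest of the toolkit consumes — gene-call tables,
contig sequences, all-vs-all BLAST tables, an organism phylogeny, a reference
reaction model with random GPRs, and tBLASTn hit tables — together with the
ground truth used to score recovery: which genes belong to which family,
where gain/loss events happened, and which defects (uncalled genes,
frameshifts, nonsense mutations) were engineered in.

Family content evolves on a rooted tree: core families are present in every
leaf; accessory families are gained along branches as Poisson events and can
subsequently be lost the same way. Homology is simulated directly in metric
space: within-family pairs receive bit scores whose maxbit value falls in a
"signal" range, spurious cross-family pairs in a disjoint "noise" range, so
a cutoff between the two ranges separates families exactly. Sequence-level
simulation of alignment statistics is deliberately out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .store import BlastEdge, GeneRecord, format_blast_row

__all__ = [
    "PangenomeTruth",
    "random_tree",
    "simulate_pangenome",
    "emit_blast_table",
    "emit_tblastn_hits",
    "inject_defects",
    "generate_model",
    "write_fixture",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
# fixed reverse-translation codon per amino acid (deterministic round trip)
_AA_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"


def _reverse_translate(aa: str) -> str:
    return "".join(_AA_CODON[a] for a in aa) + _STOP


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PangenomeTruth:
    """Everything needed to regenerate the fixture and score recovery."""

    tree_newick: str
    genomes: list[str]
    families: dict[str, dict[str, int]]          # family -> genome -> copies
    family_genes: dict[str, dict[str, list[str]]]  # family -> genome -> gene ids
    genes: dict[str, GeneRecord]
    contigs: dict[str, tuple[str, str]]          # contig -> (genome, seq)
    events: list[dict]
    defects: list[dict] = field(default_factory=list)
    seed: int = 0

    def family_of_gene(self) -> dict[str, str]:
        return {
            g: fam
            for fam, per in self.family_genes.items()
            for genes in per.values()
            for g in genes
        }

    def true_partition(self) -> list[frozenset[str]]:
        """Gene-id sets per family, restricted to genes still called."""
        called = set(self.genes)
        out = []
        for per in self.family_genes.values():
            members = frozenset(g for genes in per.values() for g in genes) & called
            if members:
                out.append(frozenset(members))
        return out

    def gene_genome_map(self) -> dict[str, str]:
        return {g: rec.genome_id for g, rec in self.genes.items()}


def random_tree(n_genomes: int, seed: int = 0) -> str:
    """Random rooted binary tree over genomes G00..; branch lengths U(0.2, 1)."""
    rng = np.random.default_rng(seed)
    nodes = [f"G{i:02d}" for i in range(n_genomes)]
    if n_genomes == 1:
        return f"({nodes[0]}:1.0);"
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.2, 1.0, size=2)
        merged = f"({a}:{la:.3f},{b}:{lb:.3f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def simulate_pangenome(
    tree: str | dendropy.Tree | None = None,
    n_core: int = 100,
    gain_rate: float = 2.0,
    loss_rate: float = 0.3,
    seed: int = 0,
    n_genomes: int = 12,
) -> PangenomeTruth:
    """Evolve family content on a tree and materialize genes and contigs.

    ``tree`` may be a Newick string, a dendropy tree, or None (a random tree
    over ``n_genomes`` leaves is generated). Core families are present in all
    leaves; accessory families arise from Poisson(gain_rate * branch length)
    gain events and are lost when Poisson(loss_rate * branch length) draws
    at least one event for a present family. Copy number is 1 per genome.
    """
    rng = np.random.default_rng(seed)
    if tree is None:
        newick = random_tree(n_genomes, seed=seed)
    elif isinstance(tree, dendropy.Tree):
        newick = tree.as_string(schema="newick").strip()
    else:
        newick = tree
    dtree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    if not leaves:
        raise ValueError("empty tree")

    core = [f"fam{i:04d}" for i in range(n_core)]
    next_fam = n_core
    events: list[dict] = []
    leaf_content: dict[str, list[str]] = {}

    # preorder walk carrying the accessory-family state
    root = dtree.seed_node
    stack = [(root, [])]
    while stack:
        node, acc = stack.pop()
        if node is not root:
            elen = node.edge.length if node.edge.length is not None else 1.0
            acc = list(acc)
            n_gain = rng.poisson(gain_rate * elen)
            for _ in range(n_gain):
                fam = f"fam{next_fam:04d}"
                next_fam += 1
                acc.append(fam)
                events.append({"type": "gain", "family": fam,
                               "branch_to": _node_label(node)})
            surviving = []
            for fam in acc:
                if rng.poisson(loss_rate * elen) >= 1:
                    events.append({"type": "loss", "family": fam,
                                   "branch_to": _node_label(node)})
                else:
                    surviving.append(fam)
            acc = surviving
        if node.is_leaf():
            leaf_content[node.taxon.label] = core + sorted(acc)
        else:
            for child in node.child_nodes():
                stack.append((child, acc))

    all_fams = sorted({f for fams in leaf_content.values() for f in fams})
    families = {
        fam: {g: (1 if fam in leaf_content[g] else 0) for g in leaves}
        for fam in all_fams
    }

    # one base protein per family
    fam_protein = {
        fam: "M" + "".join(rng.choice(list(_AA), size=int(rng.integers(80, 250))))
        for fam in all_fams
    }

    genes: dict[str, GeneRecord] = {}
    family_genes: dict[str, dict[str, list[str]]] = {f: {} for f in all_fams}
    contigs: dict[str, tuple[str, str]] = {}
    for genome in sorted(leaves):
        contig_id = f"{genome}.c0"
        pos = int(rng.integers(60, 160))
        seq_parts = [_random_nt(rng, pos)]
        idx = 0
        for fam in leaf_content[genome]:
            aa = fam_protein[fam]
            nt = _reverse_translate(aa)
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"{genome}.g{idx:04d}"
            idx += 1
            start, end = pos, pos + len(nt)
            seq_parts.append(nt if strand == "+" else _revcomp(nt))
            genes[gene_id] = GeneRecord(
                gene_id=gene_id, genome_id=genome, contig_id=contig_id,
                start=start, end=end, strand=strand,
                annotation=f"{fam} protein", aa_seq=aa, nt_seq=nt,
            )
            family_genes[fam].setdefault(genome, []).append(gene_id)
            spacer = int(rng.integers(60, 160))
            seq_parts.append(_random_nt(rng, spacer))
            pos = end + spacer
        contigs[contig_id] = (genome, "".join(seq_parts))

    return PangenomeTruth(
        tree_newick=newick, genomes=sorted(leaves), families=families,
        family_genes=family_genes, genes=genes, contigs=contigs,
        events=events, seed=seed,
    )


def _node_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label or "internal"


def _random_nt(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# BLAST table emission


def emit_blast_table(
    truth: PangenomeTruth,
    within_family_score_range: tuple[float, float] = (0.6, 0.95),
    noise_score_range: tuple[float, float] = (0.05, 0.2),
    n_noise_edges: int | None = None,
    seed: int = 0,
) -> list[BlastEdge]:
    """Simulated all-vs-all protein BLAST for the truth's called genes.

    Every gene gets a self-hit (bit score 2 per residue). Within-family
    pairs get bit scores whose maxbit value lies in the signal range (a
    family-level base score plus small per-pair jitter); ``n_noise_edges``
    random cross-family pairs land in the noise range. Rows are emitted in
    both directions. The ranges must be disjoint — separability between
    them is what downstream tests rely on.
    """
    lo_s, hi_s = within_family_score_range
    lo_n, hi_n = noise_score_range
    if not (0 < lo_s < hi_s <= 1 and 0 <= lo_n < hi_n <= 1):
        raise ValueError("score ranges must be ordered sub-intervals of [0, 1]")
    if max(lo_s, lo_n) <= min(hi_s, hi_n):
        raise ValueError("signal and noise score ranges overlap")
    rng = np.random.default_rng(seed)
    called = set(truth.genes)
    selfbit = {g: 2.0 * len(truth.genes[g].aa_seq) for g in called}

    edges: list[BlastEdge] = []

    def add_pair(q: str, t: str, maxbit: float) -> None:
        bit = round(maxbit * max(selfbit[q], selfbit[t]), 1)
        alen = min(len(truth.genes[q].aa_seq), len(truth.genes[t].aa_seq))
        ident = round(min(99.0, 100.0 * maxbit), 2)
        for a, b in ((q, t), (t, q)):
            edges.append(BlastEdge(
                query_id=a, subject_id=b, pct_identity=ident, aln_length=alen,
                mismatches=max(0, int(alen * (1 - maxbit))), gap_opens=0,
                q_start=1, q_end=alen, s_start=1, s_end=alen,
                evalue=1e-50, bit_score=bit,
            ))

    for g in sorted(called):
        alen = len(truth.genes[g].aa_seq)
        edges.append(BlastEdge(
            query_id=g, subject_id=g, pct_identity=100.0, aln_length=alen,
            mismatches=0, gap_opens=0, q_start=1, q_end=alen,
            s_start=1, s_end=alen, evalue=0.0, bit_score=selfbit[g],
        ))

    jitter = min(0.02, (hi_s - lo_s) / 4)
    for fam in sorted(truth.family_genes):
        members = sorted(
            g for genes in truth.family_genes[fam].values() for g in genes
            if g in called
        )
        base = rng.uniform(lo_s + jitter, hi_s - jitter)
        for i, q in enumerate(members):
            for t in members[i + 1:]:
                add_pair(q, t, float(np.clip(base + rng.uniform(-jitter, jitter),
                                             lo_s, hi_s)))

    fam_of = truth.family_of_gene()
    gene_list = sorted(called)
    if n_noise_edges is None:
        n_noise_edges = len(gene_list)
    added = 0
    if len(gene_list) > 1 and n_noise_edges > 0:
        idx = rng.integers(0, len(gene_list), size=(20 * n_noise_edges, 2))
        for i, j in idx:
            if added >= n_noise_edges:
                break
            q, t = gene_list[i], gene_list[j]
            if q == t or fam_of.get(q) == fam_of.get(t):
                continue
            add_pair(q, t, float(rng.uniform(lo_n, hi_n)))
            added += 1
    return edges


# ---------------------------------------------------------------------------
# tBLASTn hit emission and defect injection


def _frame_of(start0: int, strand: str, contig_len: int) -> int:
    if strand == "+":
        return (start0 % 3) + 1
    return -(((contig_len - start0) % 3) + 1)


def _homolog_query(truth: PangenomeTruth, gene_id: str, fam: str) -> str:
    """A family member from another genome to serve as the tBLASTn query."""
    genome = truth.genes[gene_id].genome_id if gene_id in truth.genes else None
    candidates = sorted(
        g for gm, genes in truth.family_genes[fam].items() for g in genes
        if gm != genome and g in truth.genes
    )
    return candidates[0] if candidates else gene_id


def _hit_row(truth, query_id, rec, q_start, q_end, s_lo, s_hi, frame, translation,
             pct=95.0, evalue=1e-60):
    """Build a 15-column tBLASTn row for a locus (0-based s_lo/s_hi half-open)."""
    if rec.strand == "+":
        s_start, s_end = s_lo + 1, s_hi
    else:
        s_start, s_end = s_hi, s_lo + 1
    alen = q_end - q_start + 1
    bit = 2.0 * alen
    return "\t".join(map(str, [
        query_id, rec.contig_id, f"{pct:.2f}", alen, int(alen * 0.05), 0,
        q_start, q_end, s_start, s_end, f"{evalue:.2g}", f"{bit:.1f}",
        rec.genome_id, frame, translation,
    ]))


def emit_tblastn_hits(truth: PangenomeTruth, gene_ids: list[str]) -> list[str]:
    """Clean full-length hits (query = a homolog from another genome) for a
    set of called genes — negative controls for event detection."""
    rows = []
    fam_of = truth.family_of_gene()
    for gid in gene_ids:
        rec = truth.genes[gid]
        query = _homolog_query(truth, gid, fam_of[gid])
        clen = len(truth.contigs[rec.contig_id][1])
        frame = _frame_of(rec.start, rec.strand, clen)
        naa = len(rec.aa_seq)
        rows.append(_hit_row(truth, query, rec, 1, naa,
                             rec.start, rec.start + 3 * naa, frame, rec.aa_seq))
    return rows


def inject_defects(
    truth: PangenomeTruth,
    n_uncalled: int = 1,
    n_frameshift: int = 1,
    n_nonsense: int = 1,
    seed: int = 0,
) -> list[str]:
    """Engineer defects into the truth (in place) and return tBLASTn rows
    that a translated search of the defective loci would produce.

    uncalled: the gene is dropped from the call table, its sequence stays in
    the contig, and a full-length hit from a homolog covers the locus.
    frameshift: a 1-nt deletion mid-gene; two hits in different frames with a
    small genomic/query gap. nonsense: an internal stop codon; one hit whose
    subject translation carries '*'. Only plus-strand genes with at least
    one family member in another genome are eligible.
    """
    rng = np.random.default_rng(seed)
    fam_of = truth.family_of_gene()
    eligible = sorted(
        g for g, rec in truth.genes.items()
        if rec.strand == "+"
        and len([gm for gm, gl in truth.family_genes[fam_of[g]].items() if gl]) >= 2
    )
    total = n_uncalled + n_frameshift + n_nonsense
    if total > len(eligible):
        raise ValueError(
            f"requested {total} defects but only {len(eligible)} eligible genes")
    chosen = list(rng.choice(eligible, size=total, replace=False))
    picks = {
        "uncalled": chosen[:n_uncalled],
        "frameshift": chosen[n_uncalled:n_uncalled + n_frameshift],
        "nonsense": chosen[n_uncalled + n_frameshift:],
    }
    rows: list[str] = []

    for gid in picks["uncalled"]:
        rec = truth.genes[gid]
        query = _homolog_query(truth, gid, fam_of[gid])
        clen = len(truth.contigs[rec.contig_id][1])
        naa = len(rec.aa_seq)
        frame = _frame_of(rec.start, "+", clen)
        rows.append(_hit_row(truth, query, rec, 1, naa,
                             rec.start, rec.start + 3 * naa, frame, rec.aa_seq))
        truth.defects.append({
            "type": "uncalled", "gene_id": gid, "genome_id": rec.genome_id,
            "contig_id": rec.contig_id, "start": rec.start, "end": rec.end,
            "family": fam_of[gid],
        })
        del truth.genes[gid]

    for gid in picks["frameshift"]:
        rec = truth.genes[gid]
        naa = len(rec.aa_seq)
        cut_aa = naa // 2
        del_pos = rec.start + 3 * cut_aa  # deletion at a codon boundary
        genome, seq = truth.contigs[rec.contig_id]
        truth.contigs[rec.contig_id] = (genome, seq[:del_pos] + seq[del_pos + 1:])
        _shift_genes_after(truth, rec.contig_id, del_pos)
        rec = truth.genes[gid]  # refreshed after shift
        clen = len(truth.contigs[rec.contig_id][1])
        query = _homolog_query(truth, gid, fam_of[gid])
        f1 = _frame_of(rec.start, "+", clen)
        s1_lo, s1_hi = rec.start, rec.start + 3 * cut_aa
        s2_lo = s1_hi  # second hit resumes right after the deletion point
        s2_hi = s2_lo + 3 * (naa - cut_aa - 1)
        f2 = ((s2_lo % 3) + 1)
        if f2 == f1:  # deletion guarantees a shift; force distinct label
            f2 = f1 % 3 + 1
        rows.append(_hit_row(truth, query, rec, 1, cut_aa,
                             s1_lo, s1_hi, f1, rec.aa_seq[:cut_aa]))
        rows.append(_hit_row(truth, query, rec, cut_aa + 2, naa,
                             s2_lo, s2_hi, f2, rec.aa_seq[cut_aa + 1:]))
        truth.defects.append({
            "type": "frameshift", "gene_id": gid, "genome_id": rec.genome_id,
            "contig_id": rec.contig_id, "position": del_pos,
            "family": fam_of[gid],
        })

    for gid in picks["nonsense"]:
        rec = truth.genes[gid]
        naa = len(rec.aa_seq)
        stop_aa = naa // 2
        stop_pos = rec.start + 3 * stop_aa
        genome, seq = truth.contigs[rec.contig_id]
        truth.contigs[rec.contig_id] = (
            genome, seq[:stop_pos] + _STOP + seq[stop_pos + 3:])
        clen = len(truth.contigs[rec.contig_id][1])
        query = _homolog_query(truth, gid, fam_of[gid])
        frame = _frame_of(rec.start, "+", clen)
        trans = rec.aa_seq[:stop_aa] + "*" + rec.aa_seq[stop_aa + 1:]
        rows.append(_hit_row(truth, query, rec, 1, naa,
                             rec.start, rec.start + 3 * naa, frame, trans))
        truth.defects.append({
            "type": "nonsense", "gene_id": gid, "genome_id": rec.genome_id,
            "contig_id": rec.contig_id, "position": stop_pos,
            "family": fam_of[gid],
        })
    return rows


def _shift_genes_after(truth: PangenomeTruth, contig_id: str, pos: int) -> None:
    """After a 1-nt deletion at ``pos``, shift downstream gene coordinates."""
    for gid, rec in list(truth.genes.items()):
        if rec.contig_id != contig_id:
            continue
        if rec.start >= pos:
            truth.genes[gid] = GeneRecord(
                gene_id=rec.gene_id, genome_id=rec.genome_id,
                contig_id=rec.contig_id, start=rec.start - 1, end=rec.end - 1,
                strand=rec.strand, annotation=rec.annotation,
                aa_seq=rec.aa_seq, nt_seq=rec.nt_seq,
            )
        elif rec.start < pos < rec.end:
            truth.genes[gid] = GeneRecord(
                gene_id=rec.gene_id, genome_id=rec.genome_id,
                contig_id=rec.contig_id, start=rec.start, end=rec.end - 1,
                strand=rec.strand, annotation=rec.annotation,
                aa_seq=rec.aa_seq, nt_seq=rec.nt_seq,
            )


# ---------------------------------------------------------------------------
# Reference model with random GPRs


def generate_model(
    truth: PangenomeTruth,
    reference_genome: str | None = None,
    n_reactions: int = 40,
    n_spontaneous: int = 5,
    max_depth: int = 3,
    seed: int = 0,
) -> list[str]:
    """Random reaction table (reaction_id, name, gpr) over the reference
    genome's genes: random AND/OR trees of depth <= ``max_depth``."""
    rng = np.random.default_rng(seed)
    ref = reference_genome or truth.genomes[0]
    ref_genes = sorted(g for g, rec in truth.genes.items() if rec.genome_id == ref)
    if not ref_genes:
        raise ValueError(f"reference genome {ref} has no called genes")

    def expr(depth: int) -> str:
        if depth >= max_depth or rng.random() < 0.4:
            return str(rng.choice(ref_genes))
        op = " and " if rng.random() < 0.5 else " or "
        k = int(rng.integers(2, 4))
        parts = [expr(depth + 1) for _ in range(k)]
        return "(" + op.join(parts) + ")"

    rows = []
    for i in range(n_reactions):
        rows.append(f"rxn{i:04d}\treaction {i}\t{expr(0)}")
    for i in range(n_spontaneous):
        rows.append(f"rxn{n_reactions + i:04d}\tspontaneous {i}\t")
    return rows


# ---------------------------------------------------------------------------
# Fixture writing


def write_fixture(
    truth: PangenomeTruth,
    outdir: str | Path,
    blast_edges: list[BlastEdge] | None = None,
    tblastn_rows: list[str] | None = None,
    model_rows: list[str] | None = None,
) -> dict[str, Path]:
    """Write genes.tsv, contigs.fasta, blast.tsv, tree.nwk, model.tsv,
    tblastn.tsv and truth.json under ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = outdir / "genes.tsv"
    with open(p, "w") as fh:
        for gid in sorted(truth.genes):
            r = truth.genes[gid]
            fh.write("\t".join([r.gene_id, r.genome_id, r.contig_id,
                                str(r.start), str(r.end), r.strand,
                                r.annotation, r.aa_seq, r.nt_seq or ""]) + "\n")
    paths["genes"] = p

    p = outdir / "contigs.fasta"
    with open(p, "w") as fh:
        for cid in sorted(truth.contigs):
            genome, seq = truth.contigs[cid]
            fh.write(f">{cid} genome={genome}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    paths["contigs"] = p

    p = outdir / "blast.tsv"
    with open(p, "w") as fh:
        for e in blast_edges or []:
            fh.write(format_blast_row(e) + "\n")
    paths["blast"] = p

    p = outdir / "tree.nwk"
    p.write_text(truth.tree_newick + ("\n" if not truth.tree_newick.endswith("\n") else ""))
    paths["tree"] = p

    p = outdir / "model.tsv"
    p.write_text("\n".join(model_rows or []) + ("\n" if model_rows else ""))
    paths["model"] = p

    p = outdir / "tblastn.tsv"
    p.write_text("\n".join(tblastn_rows or []) + ("\n" if tblastn_rows else ""))
    paths["tblastn"] = p

    p = outdir / "truth.json"
    with open(p, "w") as fh:
        json.dump({
            "seed": truth.seed,
            "tree_newick": truth.tree_newick,
            "genomes": truth.genomes,
            "families": truth.families,
            "family_genes": truth.family_genes,
            "events": truth.events,
            "defects": truth.defects,
        }, fh, indent=1, sort_keys=True)
    paths["truth"] = p
    return paths
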