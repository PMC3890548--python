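"""Interpretation of tBLASTn hits: finding uncalled, fragmented or miscalled genes.

A protein searched against six-frame translations of genomic contigs leaves
hits wherever a homolog is encoded — whether or not a gene was called there.
This module classifies each significant hit against the gene-call table
(same strand / opposite strand / uncalled), flags candidate frameshift,
insertion and nonsense-mutation events from the hit geometry, and reports
uncalled loci with their flanking genes as candidates for curation.

The event heuristics are a reconstruction from hit geometry (adjacent hit
pairs with a frame change or an oversized genomic gap; internal stops in the
aligned subject translation); all thresholds are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .store import GeneRecord, PangenomeStore, StoreError

__all__ = [
    "TblastnHit",
    "HitClassification",
    "MutationEvent",
    "read_tblastn_table",
    "classify_hits",
    "detect_events",
    "find_uncalled_candidates",
]

_CODON = {}


def _codon_table() -> dict[str, str]:
    global _CODON
    if not _CODON:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON[stop] = "*"
    return _CODON


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TblastnHit:
    """One tBLASTn hit. Query coordinates are amino acids, subject coordinates
    nucleotides, both 1-based inclusive; s_start > s_end marks the minus strand."""

    query_protein_id: str
    contig_id: str
    target_genome_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    frame: int | None = None
    subject_translation: str | None = None

    @property
    def strand(self) -> str:
        if self.frame is not None:
            return "+" if self.frame > 0 else "-"
        return "+" if self.s_start <= self.s_end else "-"

    @property
    def interval(self) -> tuple[int, int]:
        """Genomic footprint as a 0-based half-open interval on the plus strand."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi

    @property
    def length_nt(self) -> int:
        lo, hi = self.interval
        return hi - lo


@dataclass(frozen=True)
class HitClassification:
    hit: TblastnHit
    status: str  # called_same_strand | called_opposite_strand | uncalled
    overlapping_gene_id: str | None = None
    overlap_fraction: float = 0.0


@dataclass(frozen=True)
class MutationEvent:
    kind: str  # frameshift | insertion | nonsense
    query_protein_id: str
    contig_id: str
    position: int  # 0-based nucleotide coordinate
    evidence: str = ""


def read_tblastn_table(path: str | Path, target_genome_id: str = "") -> list[TblastnHit]:
    """Read a tBLASTn tabular file: the 12 standard columns, optionally
    followed by genome id, frame, and aligned subject translation."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise StoreError(f"line {lineno}: expected >= 12 columns, got {len(p)}")
            hits.append(TblastnHit(
                query_protein_id=p[0], contig_id=p[1],
                target_genome_id=p[12] if len(p) > 12 else target_genome_id,
                pct_identity=float(p[2]), aln_length=int(p[3]),
                mismatches=int(p[4]), gap_opens=int(p[5]),
                q_start=int(p[6]), q_end=int(p[7]),
                s_start=int(p[8]), s_end=int(p[9]),
                evalue=float(p[10]), bit_score=float(p[11]),
                frame=int(p[13]) if len(p) > 13 and p[13] not in ("", ".") else None,
                subject_translation=p[14] if len(p) > 14 and p[14] else None,
            ))
    return hits


def classify_hits(
    hits: Iterable[TblastnHit],
    gene_calls: Sequence[GeneRecord] | PangenomeStore,
    evalue_cutoff: float = 1e-5,
    min_overlap_fraction: float = 0.5,
) -> list[HitClassification]:
    """Classify each significant hit against the called genes of its contig.

    A hit is "to a called gene" when a gene's interval covers at least
    ``min_overlap_fraction`` of the hit's genomic length; the gene with the
    largest overlap is reported (ties go to the leftmost gene). The strand
    comparison uses the hit's frame sign against the gene's strand.
    """
    if isinstance(gene_calls, PangenomeStore):
        store = gene_calls
        by_contig: dict[str, list[GeneRecord]] = {}
        known_contigs = {r[0] for r in store.con.execute("SELECT contig_id FROM contigs")}
        getter = store.genes_on_contig
    else:
        store = None
        by_contig = {}
        for rec in gene_calls:
            by_contig.setdefault(rec.contig_id, []).append(rec)
        for genes in by_contig.values():
            genes.sort(key=lambda g: g.start)
        known_contigs = set(by_contig)
        getter = lambda c: by_contig.get(c, [])

    out = []
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            continue
        if hit.contig_id not in known_contigs:
            raise StoreError(f"unknown contig: {hit.contig_id}")
        lo, hi = hit.interval
        best_gene: GeneRecord | None = None
        best_ov = 0
        for gene in getter(hit.contig_id):
            ov = min(hi, gene.end) - max(lo, gene.start)
            if ov > best_ov or (ov == best_ov and ov > 0 and best_gene is not None
                                and gene.start < best_gene.start):
                best_ov, best_gene = ov, gene
        frac = best_ov / hit.length_nt if hit.length_nt else 0.0
        if best_gene is not None and frac >= min_overlap_fraction:
            status = ("called_same_strand" if best_gene.strand == hit.strand
                      else "called_opposite_strand")
            out.append(HitClassification(hit, status, best_gene.gene_id, frac))
        else:
            out.append(HitClassification(hit, "uncalled", None, 0.0))
    return out


def _translate_interval(seq: str, lo: int, hi: int, strand: str) -> str:
    sub = seq[lo:hi]
    if strand == "-":
        sub = _revcomp(sub)
    table = _codon_table()
    return "".join(table.get(sub[i:i + 3].upper(), "X")
                   for i in range(0, len(sub) - 2, 3))


def _stop_position(hit: TblastnHit, aa_index: int) -> int:
    """0-based genomic coordinate of the first nucleotide of the stop codon
    at amino-acid offset ``aa_index`` within the hit."""
    if hit.strand == "+":
        return (hit.s_start - 1) + 3 * aa_index
    return (hit.s_start - 1) - 3 * aa_index - 2


def detect_events(
    hits: Iterable[TblastnHit],
    contig_seqs: dict[str, str] | None = None,
    max_query_gap_aa: int = 10,
    max_frameshift_gap_nt: int = 60,
    min_insertion_nt: int = 30,
) -> list[MutationEvent]:
    """Flag candidate frameshift, insertion and nonsense events.

    Hits are grouped by (query protein, contig, strand) and sorted along the
    query. For each adjacent pair: a FRAMESHIFT when the frames differ, the
    query gap is at most ``max_query_gap_aa`` residues and the genomic gap at
    most ``max_frameshift_gap_nt`` nucleotides; an INSERTION when the frames
    agree and the genomic gap exceeds the query gap's coding length by at
    least ``min_insertion_nt``. A NONSENSE event is any '*' strictly inside a
    hit's aligned subject translation (or, with translations absent, inside
    the translation of the hit interval from the contig sequence).
    """
    groups: dict[tuple[str, str, str], list[TblastnHit]] = {}
    for h in hits:
        groups.setdefault((h.query_protein_id, h.contig_id, h.strand), []).append(h)

    events: list[MutationEvent] = []
    warned = False
    for (query, contig, strand), ghits in sorted(groups.items()):
        ghits.sort(key=lambda h: h.q_start)
        for prev, nxt in zip(ghits, ghits[1:]):
            q_gap = nxt.q_start - prev.q_end - 1
            if strand == "+":
                g_gap = nxt.interval[0] - prev.interval[1]
            else:
                g_gap = prev.interval[0] - nxt.interval[1]
            prev_frame = prev.frame if prev.frame is not None else 0
            nxt_frame = nxt.frame if nxt.frame is not None else 0
            boundary = prev.interval[1] if strand == "+" else prev.interval[0]
            if prev_frame != nxt_frame and q_gap <= max_query_gap_aa \
                    and abs(g_gap) <= max_frameshift_gap_nt:
                events.append(MutationEvent(
                    "frameshift", query, contig, boundary,
                    evidence=f"frames {prev_frame}/{nxt_frame}, "
                             f"q_gap {q_gap} aa, g_gap {g_gap} nt",
                ))
            elif prev_frame == nxt_frame and g_gap - 3 * max(q_gap, 0) >= min_insertion_nt:
                events.append(MutationEvent(
                    "insertion", query, contig, boundary,
                    evidence=f"g_gap {g_gap} nt vs q_gap {q_gap} aa",
                ))
        for h in ghits:
            trans = h.subject_translation
            if trans is None:
                if contig_seqs is None or contig not in contig_seqs:
                    if not warned:
                        warnings.warn(
                            "no subject translations or contig sequences; "
                            "nonsense detection skipped for some hits")
                        warned = True
                    continue
                lo, hi = h.interval
                trans = _translate_interval(contig_seqs[contig], lo, hi, strand)
            for i, aa in enumerate(trans[:-1]):  # terminal stop is not internal
                if aa == "*":
                    events.append(MutationEvent(
                        "nonsense", query, contig, _stop_position(h, i),
                        evidence=f"internal stop at aa offset {i}",
                    ))
    return events


def find_uncalled_candidates(
    classifications: Iterable[HitClassification],
    gene_calls: Sequence[GeneRecord] | PangenomeStore,
    contig_lengths: dict[str, int] | None = None,
    edge_window_nt: int = 100,
) -> pd.DataFrame:
    """Table of uncalled hits with flanking called genes and contig-edge flags.

    Each uncalled hit is annotated with the nearest called gene on each side
    and its distance; hits whose footprint ends within ``edge_window_nt`` of
    a contig edge are flagged as possible fragments running off the contig.
    """
    if isinstance(gene_calls, PangenomeStore):
        store = gene_calls
        contig_genes = lambda c: store.genes_on_contig(c)
        if contig_lengths is None:
            contig_lengths = {}
    else:
        by_contig: dict[str, list[GeneRecord]] = {}
        for rec in gene_calls:
            by_contig.setdefault(rec.contig_id, []).append(rec)
        for genes in by_contig.values():
            genes.sort(key=lambda g: g.start)
        contig_genes = lambda c: by_contig.get(c, [])
        contig_lengths = contig_lengths or {}

    rows = []
    for cl in classifications:
        if cl.status != "uncalled":
            continue
        hit = cl.hit
        lo, hi = hit.interval
        left = right = None
        for gene in contig_genes(hit.contig_id):
            if gene.end <= lo and (left is None or gene.end > left.end):
                left = gene
            if gene.start >= hi and (right is None or gene.start < right.start):
                right = gene
        clen = contig_lengths.get(hit.contig_id)
        near_edge = lo < edge_window_nt or (clen is not None and clen - hi < edge_window_nt)
        rows.append((
            hit.query_protein_id, hit.contig_id, hit.target_genome_id, lo, hi,
            hit.strand,
            left.gene_id if left else None, lo - left.end if left else None,
            right.gene_id if right else None, right.start - hi if right else None,
            bool(near_edge),
        ))
    return pd.DataFrame(rows, columns=[
        "query_protein_id", "contig_id", "target_genome_id", "start", "end",
        "strand", "left_gene", "left_distance", "right_gene", "right_distance",
        "contig_end_fragment",
    ])
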