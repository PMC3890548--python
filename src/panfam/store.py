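"""SQLite-backed store for genomes, genes, homology edges, cluster runs and domain hits.

Every other module reads from this hub. Internal gene coordinates are 0-based
half-open; BLAST-dialect files are 1-based inclusive and converted at the
boundary by the readers. Gene ids are opaque strings — no naming convention is
enforced.
"""

from __future__ import annotations

import sqlite3
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GeneRecord",
    "BlastEdge",
    "DomainHit",
    "ClusterRun",
    "PangenomeStore",
    "StoreError",
    "parse_blast_row",
    "read_gene_calls_tsv",
    "read_genbank_genes",
]


class StoreError(ValueError):
    """Raised on constraint violations (duplicate ids, malformed rows, ...)."""


@dataclass(frozen=True)
class GeneRecord:
    """One called gene. Coordinates are 0-based half-open on the contig."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    annotation: str = ""
    aa_seq: str = ""
    nt_seq: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise StoreError("empty gene_id")
        if not self.genome_id:
            raise StoreError(f"gene {self.gene_id}: empty genome_id")
        if self.start < 0 or self.end <= self.start:
            raise StoreError(
                f"gene {self.gene_id}: invalid coordinates [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise StoreError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class BlastEdge:
    """One pairwise protein hit in BLAST tabular convention (1-based inclusive)."""

    query_id: str
    subject_id: str
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

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise StoreError(f"edge {self.query_id}->{self.subject_id}: q_start > q_end")
        if self.bit_score <= 0:
            raise StoreError(f"edge {self.query_id}->{self.subject_id}: bit_score <= 0")
        if self.evalue < 0:
            raise StoreError(f"edge {self.query_id}->{self.subject_id}: negative evalue")

    def as_row(self) -> tuple:
        return (
            self.query_id, self.subject_id, self.pct_identity, self.aln_length,
            self.mismatches, self.gap_opens, self.q_start, self.q_end,
            self.s_start, self.s_end, self.evalue, self.bit_score,
        )


@dataclass(frozen=True)
class DomainHit:
    """A conserved-domain (e.g. CDD) hit on a protein, 1-based inclusive."""

    protein_id: str
    domain_accession: str
    domain_name: str
    q_start: int
    q_end: int
    evalue: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise StoreError(f"domain hit on {self.protein_id}: q_start > q_end")
        if self.evalue < 0:
            raise StoreError(f"domain hit on {self.protein_id}: negative evalue")


def make_run_id(group: str, method: str, metric: str, cutoff: float, inflation: float) -> str:
    return f"{group}|{method}|{metric}|{cutoff:g}|{inflation:g}"


@dataclass
class ClusterRun:
    """A clustering result: a partition of (a subset of) a group's genes.

    ``families`` maps integer family ids to non-empty frozensets of gene ids.
    Ids are canonical: families sorted by size descending, ties broken by the
    lexicographically smallest member, numbered consecutively from 0.
    """

    group: str
    method: str
    metric: str
    cutoff: float
    inflation: float
    families: dict[int, frozenset[str]] = field(default_factory=dict)

    @property
    def run_id(self) -> str:
        return make_run_id(self.group, self.method, self.metric, self.cutoff, self.inflation)

    def gene_to_family(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for fid, members in self.families.items():
            for g in members:
                if g in out:
                    raise StoreError(f"gene {g} appears in two families of run {self.run_id}")
                out[g] = fid
        return out

    def all_genes(self) -> frozenset[str]:
        return frozenset(g for fam in self.families.values() for g in fam)


def canonical_families(partition: Iterable[Iterable[str]]) -> dict[int, frozenset[str]]:
    """Assign deterministic consecutive ids: size desc, then smallest member."""
    fams = [frozenset(f) for f in partition if f]
    fams.sort(key=lambda f: (-len(f), min(f)))
    return {i: f for i, f in enumerate(fams)}


# ---------------------------------------------------------------------------
# Readers


def parse_blast_row(line: str, lineno: int = 0) -> BlastEdge:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 12:
        raise StoreError(f"line {lineno}: expected 12 tab-separated columns, got {len(parts)}")
    try:
        return BlastEdge(
            query_id=parts[0],
            subject_id=parts[1],
            pct_identity=float(parts[2]),
            aln_length=int(parts[3]),
            mismatches=int(parts[4]),
            gap_opens=int(parts[5]),
            q_start=int(parts[6]),
            q_end=int(parts[7]),
            s_start=int(parts[8]),
            s_end=int(parts[9]),
            evalue=float(parts[10]),
            bit_score=float(parts[11]),
        )
    except ValueError as exc:
        raise StoreError(f"line {lineno}: {exc}") from exc


def read_gene_calls_tsv(path: str | Path, one_based: bool = False) -> list[GeneRecord]:
    """Read a gene-call table.

    Columns: gene_id, genome_id, contig_id, start, end, strand, annotation,
    aa_seq[, nt_seq]. With ``one_based=True`` coordinates are interpreted as
    1-based inclusive and converted to the internal 0-based half-open form.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise StoreError(f"line {lineno}: expected >= 8 columns, got {len(parts)}")
            start, end = int(parts[3]), int(parts[4])
            if one_based:
                start -= 1
            records.append(GeneRecord(
                gene_id=parts[0], genome_id=parts[1], contig_id=parts[2],
                start=start, end=end, strand=parts[5], annotation=parts[6],
                aa_seq=parts[7], nt_seq=parts[8] if len(parts) > 8 else None,
            ))
    return records


def read_genbank_genes(path: str | Path, genome_id: str | None = None) -> list[GeneRecord]:
    """Extract CDS features from a GenBank file as GeneRecords.

    Biopython already exposes locations 0-based half-open, matching the
    internal convention directly.
    """
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        gid = genome_id or rec.annotations.get("organism", rec.id)
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            gene_id = (quals.get("locus_tag") or quals.get("protein_id") or [None])[0]
            if gene_id is None:
                continue
            records.append(GeneRecord(
                gene_id=gene_id,
                genome_id=gid,
                contig_id=rec.id,
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand="+" if feat.location.strand >= 0 else "-",
                annotation=(quals.get("product") or [""])[0],
                aa_seq=(quals.get("translation") or [""])[0],
                nt_seq=None,
            ))
    return records


def orthomcl_to_families(lines: Iterable[str]) -> list[list[str]]:
    """Convert OrthoMCL groups output ("NAME: geneA(taxon) geneB(taxon) ...")
    to the one-family-per-line gene-id lists import_cluster_run accepts.
    A trailing parenthesized taxon tag on each member is stripped."""
    fams = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        body = line.split(":", 1)[1] if ":" in line else line
        members = []
        for tok in body.split():
            if tok.endswith(")") and "(" in tok:
                tok = tok[:tok.rindex("(")]
            members.append(tok)
        if members:
            fams.append(members)
    return fams


def read_domain_hits_tsv(path: str | Path) -> list[DomainHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) < 6:
                raise StoreError(f"line {lineno}: expected 6 columns, got {len(p)}")
            hits.append(DomainHit(p[0], p[1], p[2], int(p[3]), int(p[4]), float(p[5])))
    return hits


# ---------------------------------------------------------------------------
# The store


_SCHEMA = """
CREATE TABLE IF NOT EXISTS genomes (
    genome_id TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS contigs (
    contig_id TEXT PRIMARY KEY,
    genome_id TEXT NOT NULL REFERENCES genomes(genome_id),
    seq TEXT
);
CREATE TABLE IF NOT EXISTS genes (
    gene_id TEXT PRIMARY KEY,
    genome_id TEXT NOT NULL,
    contig_id TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    strand TEXT NOT NULL,
    annotation TEXT,
    aa_seq TEXT,
    nt_seq TEXT
);
CREATE INDEX IF NOT EXISTS idx_genes_genome ON genes(genome_id);
CREATE INDEX IF NOT EXISTS idx_genes_region ON genes(contig_id, start, end);
CREATE TABLE IF NOT EXISTS blast (
    query_id TEXT NOT NULL,
    subject_id TEXT NOT NULL,
    pct_identity REAL, aln_length INTEGER, mismatches INTEGER, gap_opens INTEGER,
    q_start INTEGER, q_end INTEGER, s_start INTEGER, s_end INTEGER,
    evalue REAL, bit_score REAL NOT NULL,
    PRIMARY KEY (query_id, subject_id)
);
CREATE TABLE IF NOT EXISTS domain_hits (
    protein_id TEXT NOT NULL,
    domain_accession TEXT NOT NULL,
    domain_name TEXT,
    q_start INTEGER, q_end INTEGER, evalue REAL
);
CREATE INDEX IF NOT EXISTS idx_domains_protein ON domain_hits(protein_id);
CREATE TABLE IF NOT EXISTS organism_groups (
    group_name TEXT NOT NULL,
    genome_id TEXT NOT NULL,
    PRIMARY KEY (group_name, genome_id)
);
CREATE TABLE IF NOT EXISTS cluster_runs (
    run_id TEXT PRIMARY KEY,
    group_name TEXT, method TEXT, metric TEXT, cutoff REAL, inflation REAL
);
CREATE TABLE IF NOT EXISTS cluster_members (
    run_id TEXT NOT NULL REFERENCES cluster_runs(run_id),
    family_id INTEGER NOT NULL,
    gene_id TEXT NOT NULL,
    PRIMARY KEY (run_id, gene_id)
);
"""


class PangenomeStore:
    """Single-file embedded store; all tables exportable as tab-delimited text."""

    def __init__(self, path: str | Path = ":memory:") -> None:
        self.path = str(path)
        self.con = sqlite3.connect(self.path)
        self.con.executescript(_SCHEMA)
        self.con.commit()

    def close(self) -> None:
        self.con.close()

    def __enter__(self) -> "PangenomeStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- genomes / contigs / genes -----------------------------------------

    def add_genome(self, genome_id: str) -> None:
        self.con.execute("INSERT OR IGNORE INTO genomes VALUES (?)", (genome_id,))

    def add_contig(self, contig_id: str, genome_id: str, seq: str | None = None) -> None:
        self.add_genome(genome_id)
        self.con.execute(
            "INSERT OR REPLACE INTO contigs VALUES (?,?,?)", (contig_id, genome_id, seq)
        )
        self.con.commit()

    def contig_seq(self, contig_id: str) -> str | None:
        row = self.con.execute(
            "SELECT seq FROM contigs WHERE contig_id=?", (contig_id,)
        ).fetchone()
        return row[0] if row else None

    def contig_length(self, contig_id: str) -> int | None:
        seq = self.contig_seq(contig_id)
        return len(seq) if seq is not None else None

    def genomes(self) -> list[str]:
        return [r[0] for r in self.con.execute("SELECT genome_id FROM genomes ORDER BY 1")]

    def import_gene_calls(self, records: Iterable[GeneRecord]) -> int:
        """Insert validated gene records; hard error on duplicate gene_id."""
        records = list(records)
        n = 0
        for rec in records:
            existing = self.con.execute(
                "SELECT 1 FROM genes WHERE gene_id=?", (rec.gene_id,)
            ).fetchone()
            if existing:
                self.con.rollback()
                raise StoreError(f"duplicate gene_id: {rec.gene_id}")
            self.add_genome(rec.genome_id)
            self.con.execute(
                "INSERT OR IGNORE INTO contigs (contig_id, genome_id) VALUES (?,?)",
                (rec.contig_id, rec.genome_id),
            )
            self.con.execute(
                "INSERT INTO genes VALUES (?,?,?,?,?,?,?,?,?)",
                (rec.gene_id, rec.genome_id, rec.contig_id, rec.start, rec.end,
                 rec.strand, rec.annotation, rec.aa_seq, rec.nt_seq),
            )
            n += 1
        self.con.commit()
        return n

    def _gene_from_row(self, row: tuple) -> GeneRecord:
        return GeneRecord(*row)

    def gene(self, gene_id: str) -> GeneRecord:
        row = self.con.execute("SELECT * FROM genes WHERE gene_id=?", (gene_id,)).fetchone()
        if row is None:
            raise StoreError(f"unknown gene: {gene_id}")
        return self._gene_from_row(row)

    def has_gene(self, gene_id: str) -> bool:
        return self.con.execute(
            "SELECT 1 FROM genes WHERE gene_id=?", (gene_id,)
        ).fetchone() is not None

    def genes_by_genome(self, genome_id: str) -> list[GeneRecord]:
        rows = self.con.execute(
            "SELECT * FROM genes WHERE genome_id=? ORDER BY contig_id, start", (genome_id,)
        ).fetchall()
        return [self._gene_from_row(r) for r in rows]

    def genes_in_region(self, contig_id: str, start: int, end: int) -> list[GeneRecord]:
        """Genes overlapping [start, end): start < end of query and vice versa."""
        rows = self.con.execute(
            "SELECT * FROM genes WHERE contig_id=? AND start < ? AND end > ? "
            "ORDER BY start", (contig_id, end, start),
        ).fetchall()
        return [self._gene_from_row(r) for r in rows]

    def genes_on_contig(self, contig_id: str) -> list[GeneRecord]:
        rows = self.con.execute(
            "SELECT * FROM genes WHERE contig_id=? ORDER BY start", (contig_id,)
        ).fetchall()
        return [self._gene_from_row(r) for r in rows]

    def gene_genome_map(self, gene_ids: Iterable[str] | None = None) -> dict[str, str]:
        if gene_ids is None:
            rows = self.con.execute("SELECT gene_id, genome_id FROM genes")
            return dict(rows.fetchall())
        out = {}
        for gid in gene_ids:
            out[gid] = self.gene(gid).genome_id
        return out

    # -- organism groups ----------------------------------------------------

    def define_group(self, group_name: str, genome_ids: Iterable[str]) -> None:
        genome_ids = sorted(set(genome_ids))
        if not genome_ids:
            raise StoreError(f"group {group_name}: empty genome set")
        known = set(self.genomes())
        missing = [g for g in genome_ids if g not in known]
        if missing:
            raise StoreError(f"group {group_name}: unknown genomes {missing}")
        self.con.execute("DELETE FROM organism_groups WHERE group_name=?", (group_name,))
        self.con.executemany(
            "INSERT INTO organism_groups VALUES (?,?)",
            [(group_name, g) for g in genome_ids],
        )
        self.con.commit()

    def group_genomes(self, group_name: str) -> list[str]:
        rows = self.con.execute(
            "SELECT genome_id FROM organism_groups WHERE group_name=? ORDER BY 1",
            (group_name,),
        ).fetchall()
        if not rows:
            raise StoreError(f"unknown group: {group_name}")
        return [r[0] for r in rows]

    def group_genes(self, group_name: str) -> list[str]:
        genomes = self.group_genomes(group_name)
        qmarks = ",".join("?" * len(genomes))
        rows = self.con.execute(
            f"SELECT gene_id FROM genes WHERE genome_id IN ({qmarks}) ORDER BY gene_id",
            genomes,
        ).fetchall()
        return [r[0] for r in rows]

    # -- BLAST edges ---------------------------------------------------------

    def import_blast_table(
        self,
        source: str | Path | Iterable[str] | Iterable[BlastEdge],
        on_unknown: str = "warn",
    ) -> int:
        """Import 12-column BLAST tabular rows.

        Duplicate (query, subject) rows — multiple HSPs — are collapsed keeping
        the highest bit score; self-hits are retained. ``on_unknown`` controls
        handling of ids absent from the gene table: "warn", "error" or "ignore".
        """
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                edges = [parse_blast_row(ln, i) for i, ln in enumerate(fh, 1)
                         if ln.strip()]
        else:
            source = list(source)
            if source and isinstance(source[0], BlastEdge):
                edges = list(source)  # type: ignore[arg-type]
            else:
                edges = [parse_blast_row(ln, i) for i, ln in enumerate(source, 1)  # type: ignore[arg-type]
                         if str(ln).strip()]

        if on_unknown != "ignore":
            ids = {e.query_id for e in edges} | {e.subject_id for e in edges}
            unknown = sorted(i for i in ids if not self.has_gene(i))
            if unknown:
                msg = f"BLAST ids not in gene table: {unknown[:5]}{'...' if len(unknown) > 5 else ''}"
                if on_unknown == "error":
                    raise StoreError(msg)
                warnings.warn(msg)

        best: dict[tuple[str, str], BlastEdge] = {}
        for e in edges:
            key = (e.query_id, e.subject_id)
            if key not in best or e.bit_score > best[key].bit_score:
                best[key] = e
        self.con.executemany(
            "INSERT OR REPLACE INTO blast VALUES (?,?,?,?,?,?,?,?,?,?,?,?)",
            [e.as_row() for e in best.values()],
        )
        self.con.commit()
        return len(best)

    def blast_edges(self, gene_ids: Iterable[str] | None = None) -> list[BlastEdge]:
        """All stored edges, canonically ordered by (query, subject)."""
        if gene_ids is None:
            rows = self.con.execute("SELECT * FROM blast ORDER BY query_id, subject_id")
            return [BlastEdge(*r) for r in rows.fetchall()]
        idset = sorted(set(gene_ids))
        qmarks = ",".join("?" * len(idset))
        rows = self.con.execute(
            f"SELECT * FROM blast WHERE query_id IN ({qmarks}) AND subject_id IN ({qmarks}) "
            "ORDER BY query_id, subject_id", idset + idset,
        )
        return [BlastEdge(*r) for r in rows.fetchall()]

    def self_hit(self, gene_id: str) -> float | None:
        row = self.con.execute(
            "SELECT bit_score FROM blast WHERE query_id=? AND subject_id=?",
            (gene_id, gene_id),
        ).fetchone()
        return row[0] if row else None

    def export_blast_table(self, path: str | Path) -> int:
        edges = self.blast_edges()
        with open(path, "w") as fh:
            for e in edges:
                fh.write(format_blast_row(e) + "\n")
        return len(edges)

    # -- cluster runs ---------------------------------------------------------

    def store_cluster_run(self, run: ClusterRun) -> None:
        self.con.execute(
            "INSERT OR REPLACE INTO cluster_runs VALUES (?,?,?,?,?,?)",
            (run.run_id, run.group, run.method, run.metric, run.cutoff, run.inflation),
        )
        self.con.execute("DELETE FROM cluster_members WHERE run_id=?", (run.run_id,))
        self.con.executemany(
            "INSERT INTO cluster_members VALUES (?,?,?)",
            [(run.run_id, fid, g) for fid, fam in run.families.items() for g in fam],
        )
        self.con.commit()

    def get_cluster_run(self, run_id: str) -> ClusterRun:
        meta = self.con.execute(
            "SELECT group_name, method, metric, cutoff, inflation FROM cluster_runs "
            "WHERE run_id=?", (run_id,),
        ).fetchone()
        if meta is None:
            raise StoreError(f"unknown cluster run: {run_id}")
        fams: dict[int, set[str]] = {}
        for fid, gid in self.con.execute(
            "SELECT family_id, gene_id FROM cluster_members WHERE run_id=?", (run_id,)
        ):
            fams.setdefault(fid, set()).add(gid)
        return ClusterRun(
            group=meta[0], method=meta[1], metric=meta[2], cutoff=meta[3],
            inflation=meta[4], families={k: frozenset(v) for k, v in fams.items()},
        )

    def list_cluster_runs(self) -> list[str]:
        return [r[0] for r in self.con.execute("SELECT run_id FROM cluster_runs ORDER BY 1")]

    def import_cluster_run(
        self,
        source: str | Path | Iterable[Sequence[str]],
        group: str,
        method: str,
        metric: str = "external",
        cutoff: float = 0.0,
        inflation: float = 0.0,
        on_unknown: str = "error",
    ) -> ClusterRun:
        """Import an externally computed clustering: one family per line,
        tab-separated gene ids. Downstream queries treat it like a native run.
        """
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                lines = [ln.rstrip("\n").split("\t") for ln in fh if ln.strip()]
        else:
            lines = [list(fam) for fam in source]
        if not lines:
            raise StoreError("empty cluster file")
        seen: dict[str, int] = {}
        for i, fam in enumerate(lines):
            for g in fam:
                if g in seen:
                    raise StoreError(
                        f"partition violation: gene {g} in families on lines "
                        f"{seen[g] + 1} and {i + 1}"
                    )
                seen[g] = i
                if on_unknown == "error" and not self.has_gene(g):
                    raise StoreError(f"unknown gene id in cluster file: {g}")
        run = ClusterRun(
            group=group, method=method, metric=metric, cutoff=cutoff,
            inflation=inflation, families=canonical_families(lines),
        )
        self.store_cluster_run(run)
        return run

    # -- domain hits -----------------------------------------------------------

    def import_domain_hits(self, hits: Iterable[DomainHit]) -> int:
        hits = list(hits)
        self.con.executemany(
            "INSERT INTO domain_hits VALUES (?,?,?,?,?,?)",
            [(h.protein_id, h.domain_accession, h.domain_name, h.q_start, h.q_end,
              h.evalue) for h in hits],
        )
        self.con.commit()
        return len(hits)

    def query_domains(self, keyword: str) -> list[str]:
        """Accessions whose domain_name contains the keyword, case-insensitive."""
        kw = keyword.lower()
        rows = self.con.execute(
            "SELECT DISTINCT domain_accession, domain_name FROM domain_hits"
        ).fetchall()
        return sorted({acc for acc, name in rows if kw in (name or "").lower()})

    def domain_architecture(self, protein_id: str, evalue_cutoff: float = float("inf")) -> list[DomainHit]:
        """Domain hits on a protein with evalue <= cutoff, ordered along the protein."""
        if not self.has_gene(protein_id):
            raise StoreError(f"unknown protein: {protein_id}")
        rows = self.con.execute(
            "SELECT * FROM domain_hits WHERE protein_id=?", (protein_id,)
        ).fetchall()
        hits = [DomainHit(*r) for r in rows if r[5] <= evalue_cutoff]
        hits.sort(key=lambda h: (h.q_start, h.evalue))
        return hits

    # -- FASTA export ----------------------------------------------------------

    def export_fasta(self, gene_ids: Iterable[str], path: str | Path, kind: str = "aa") -> int:
        n = 0
        with open(path, "w") as fh:
            for gid in gene_ids:
                rec = self.gene(gid)
                seq = rec.aa_seq if kind == "aa" else (rec.nt_seq or "")
                if not seq:
                    continue
                fh.write(f">{gid}\n{seq}\n")
                n += 1
        return n


def format_blast_row(e: BlastEdge) -> str:
    return "\t".join([
        e.query_id, e.subject_id, f"{e.pct_identity:.2f}", str(e.aln_length),
        str(e.mismatches), str(e.gap_opens), str(e.q_start), str(e.q_end),
        str(e.s_start), str(e.s_end), f"{e.evalue:.2g}", f"{e.bit_score:.1f}",
    ])
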