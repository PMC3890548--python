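"""Store behavior: imports, coordinate conventions, collapsing, round trips."""

import pytest

from panfam.store import (BlastEdge, DomainHit, GeneRecord, PangenomeStore,
                          StoreError, canonical_families, format_blast_row,
                          orthomcl_to_families, parse_blast_row,
                          read_gene_calls_tsv)


def _gene(gid, genome="G1", contig="c1", start=0, end=300, strand="+", **kw):
    return GeneRecord(gid, genome, contig, start, end, strand, **kw)


def _blast_line(q, s, bit, **kw):
    vals = dict(pct=90.0, alen=100, mm=5, go=0, qs=1, qe=100, ss=1, se=100,
                ev=1e-50)
    vals.update(kw)
    return (f"{q}\t{s}\t{vals['pct']}\t{vals['alen']}\t{vals['mm']}\t{vals['go']}"
            f"\t{vals['qs']}\t{vals['qe']}\t{vals['ss']}\t{vals['se']}"
            f"\t{vals['ev']}\t{bit}")


class TestGeneImport:
    def test_import_count_and_lookup(self):
        store = PangenomeStore()
        n = store.import_gene_calls([_gene("g1"), _gene("g2", start=400, end=700),
                                     _gene("g3", start=800, end=1100)])
        assert n == 3
        assert store.gene("g2").start == 400
        assert [g.gene_id for g in store.genes_by_genome("G1")] == ["g1", "g2", "g3"]

    def test_duplicate_gene_id_is_hard_error_naming_the_id(self):
        store = PangenomeStore()
        store.import_gene_calls([_gene("g1")])
        with pytest.raises(StoreError, match="g1"):
            store.import_gene_calls([_gene("g1")])

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(StoreError):
            _gene("g1", start=300, end=300)
        with pytest.raises(StoreError):
            _gene("g1", strand="?")

    def test_one_based_reader_converts_to_half_open(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("g1\tG1\tc1\t1\t300\t+\tanno\tMKT\n")
        (rec,) = read_gene_calls_tsv(p, one_based=True)
        assert (rec.start, rec.end) == (0, 300)

    def test_region_query_uses_overlap_semantics(self):
        store = PangenomeStore()
        store.import_gene_calls([_gene("g1", start=100, end=200),
                                 _gene("g2", start=200, end=300)])
        # [a, b) overlap: start < b and end > a; abutting gene excluded
        assert [g.gene_id for g in store.genes_in_region("c1", 150, 200)] == ["g1"]
        assert [g.gene_id for g in store.genes_in_region("c1", 150, 201)] == ["g1", "g2"]


class TestBlastImport:
    def _store(self):
        store = PangenomeStore()
        store.import_gene_calls([_gene("gA"), _gene("gB", start=400, end=700)])
        return store

    def test_duplicate_pair_collapsed_to_max_bit(self):
        store = self._store()
        n = store.import_blast_table([_blast_line("gA", "gB", 100.0),
                                      _blast_line("gA", "gB", 150.0)])
        assert n == 1
        (edge,) = store.blast_edges()
        assert edge.bit_score == 150.0

    def test_malformed_row_cites_line_number(self):
        store = self._store()
        bad = "\t".join(["gA", "gB"] + ["1"] * 9)  # 11 columns
        with pytest.raises(StoreError, match="line 2"):
            store.import_blast_table([_blast_line("gA", "gB", 100.0), bad])

    def test_non_numeric_bit_score_cites_line(self):
        with pytest.raises(StoreError, match="line 3"):
            parse_blast_row(_blast_line("gA", "gB", "high"), 3)

    def test_self_hit_retained_and_retrievable(self):
        store = self._store()
        store.import_blast_table([_blast_line("gA", "gA", 200.0)])
        assert store.self_hit("gA") == 200.0

    def test_unknown_ids_warn_or_error(self):
        store = self._store()
        with pytest.warns(UserWarning, match="gX"):
            store.import_blast_table([_blast_line("gX", "gA", 50.0)])
        with pytest.raises(StoreError):
            store.import_blast_table([_blast_line("gY", "gA", 50.0)],
                                     on_unknown="error")

    def test_round_trip_is_byte_identical_under_canonical_order(self, tmp_path):
        store = self._store()
        store.import_blast_table([
            _blast_line("gB", "gA", 90.0), _blast_line("gA", "gB", 150.0),
            _blast_line("gA", "gB", 100.0), _blast_line("gA", "gA", 200.0),
        ])
        out1 = tmp_path / "a.tsv"
        store.export_blast_table(out1)
        store2 = self._store()
        store2.import_blast_table(str(out1))
        out2 = tmp_path / "b.tsv"
        store2.export_blast_table(out2)
        assert out1.read_bytes() == out2.read_bytes()


class TestClusterRunImport:
    def _store(self):
        store = PangenomeStore()
        store.import_gene_calls([
            _gene("g1"), _gene("g2", start=400, end=700),
            _gene("g3", "G2", "c2"),
        ])
        return store

    def test_two_line_file_gives_two_families(self):
        store = self._store()
        run = store.import_cluster_run([["g1", "g2"], ["g3"]], group="all",
                                       method="ext")
        assert len(run.families) == 2
        assert run.families[0] == frozenset({"g1", "g2"})

    def test_gene_in_two_lines_is_partition_error(self):
        store = self._store()
        with pytest.raises(StoreError, match="g2"):
            store.import_cluster_run([["g1", "g2"], ["g2", "g3"]], group="all",
                                     method="ext")

    def test_empty_file_is_error(self):
        with pytest.raises(StoreError, match="empty"):
            self._store().import_cluster_run([], group="all", method="ext")

    def test_orthomcl_adapter_matches_hand_built_run(self):
        store = self._store()
        lines = ["OG1: g1(tax1) g2(tax1)", "OG2: g3(tax2)"]
        run_a = store.import_cluster_run(orthomcl_to_families(lines),
                                         group="all", method="orthomcl")
        run_b = store.import_cluster_run([["g1", "g2"], ["g3"]], group="all",
                                         method="hand")
        assert run_a.families == run_b.families

    def test_store_and_reload_preserves_families(self):
        store = self._store()
        run = store.import_cluster_run([["g1", "g2"], ["g3"]], group="all",
                                       method="ext")
        reloaded = store.get_cluster_run(run.run_id)
        assert reloaded.families == run.families


class TestDomains:
    def _store(self):
        store = PangenomeStore()
        store.import_gene_calls([_gene("p1"), _gene("p2", start=400, end=700)])
        store.import_domain_hits([
            DomainHit("p1", "cd0001", "purine synthesis PurD", 1, 400, 1e-120),
            DomainHit("p1", "cd0002", "ribosomal L20", 10, 50, 1e-50),
            DomainHit("p2", "cd0003", "PurL domain", 420, 1300, 1e-110),
        ])
        return store

    def test_keyword_search_is_case_insensitive_substring(self):
        store = self._store()
        assert store.query_domains("purine") == ["cd0001"]
        assert store.query_domains("PURINE") == ["cd0001"]

    def test_empty_keyword_matches_everything(self):
        assert self._store().query_domains("") == ["cd0001", "cd0002", "cd0003"]

    def test_architecture_threshold_and_order(self):
        store = self._store()
        hits = store.domain_architecture("p1", 1e-100)
        assert [h.domain_accession for h in hits] == ["cd0001"]
        hits = store.domain_architecture("p1", float("inf"))
        assert [h.domain_accession for h in hits] == ["cd0001", "cd0002"]

    def test_fusion_architecture_ordered_along_protein(self):
        # fusion-style layout: one domain at 1-400, a second at 420-1300
        store = PangenomeStore()
        store.import_gene_calls([_gene("fus", end=4000)])
        store.import_domain_hits([
            DomainHit("fus", "cdB", "domB", 420, 1300, 1e-150),
            DomainHit("fus", "cdA", "domA", 1, 400, 1e-120),
        ])
        hits = store.domain_architecture("fus", 1e-100)
        assert [h.domain_accession for h in hits] == ["cdA", "cdB"]

    def test_unknown_protein_is_error(self):
        with pytest.raises(StoreError):
            self._store().domain_architecture("nope", 1.0)


def test_canonical_family_ordering():
    fams = canonical_families([["z"], ["b", "c"], ["a", "d"]])
    # size desc first, then smallest member: {a,d} before {b,c}, singleton last
    assert fams == {0: frozenset({"a", "d"}), 1: frozenset({"b", "c"}),
                    2: frozenset({"z"})}


def test_format_parse_round_trip():
    edge = BlastEdge("a", "b", 91.25, 120, 10, 1, 1, 120, 3, 122, 1e-42, 233.5)
    assert parse_blast_row(format_blast_row(edge)) == BlastEdge(
        "a", "b", 91.25, 120, 10, 1, 1, 120, 3, 122, 1e-42, 233.5)
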