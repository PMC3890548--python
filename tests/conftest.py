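import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from panfam import (PangenomeStore, build_graph, mcl, simulate_pangenome,
                    singleton_completion)
from panfam.simulate import emit_blast_table


@pytest.fixture(scope="session")
def small_truth():
    """6-genome / 30-core-family simulated pan-genome (deterministic)."""
    return simulate_pangenome(n_core=30, gain_rate=2.0, loss_rate=0.3,
                              seed=1, n_genomes=6)


@pytest.fixture(scope="session")
def small_store(small_truth):
    store = PangenomeStore()
    store.import_gene_calls(small_truth.genes.values())
    for cid, (genome, seq) in small_truth.contigs.items():
        store.add_contig(cid, genome, seq)
    store.import_blast_table(emit_blast_table(small_truth, seed=2))
    store.define_group("all", small_truth.genomes)
    return store


@pytest.fixture(scope="session")
def small_run(small_store):
    graph = build_graph(small_store, "all", metric="maxbit", cutoff=0.3)
    run = mcl(graph, inflation=2.0)
    return singleton_completion(run, small_store.group_genes("all"))
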