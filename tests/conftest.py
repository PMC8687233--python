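import numpy as np
import pytest

from wspia.expression import ExpressionDataset
from wspia.pathways import PathwayGraph

KGML_TOY = """<?xml version="1.0"?>
<pathway name="path:toy01" org="hsa" number="01" title="Toy pathway">
  <entry id="1" name="hsa:10" type="gene"><graphics name="A"/></entry>
  <entry id="2" name="hsa:20 hsa:21" type="gene"/>
  <entry id="3" name="cpd:C00001" type="compound"/>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="2" entry2="1" type="PPrel">
    <subtype name="inhibition" value="--|"/>
  </relation>
  <relation entry1="1" entry2="3" type="PCrel">
    <subtype name="binding/association" value="---"/>
  </relation>
</pathway>
"""


@pytest.fixture
def kgml_file(tmp_path):
    path = tmp_path / "toy01.xml"
    path.write_text(KGML_TOY)
    return path


@pytest.fixture
def chain_graph():
    """g1 -> g2 -> g3 -> g4, all activating."""
    genes = ["g1", "g2", "g3", "g4"]
    edges = [("g1", "g2", +1), ("g2", "g3", +1), ("g3", "g4", +1)]
    return PathwayGraph("chain", "chain", genes, edges)


@pytest.fixture
def two_gene_chain():
    return PathwayGraph("pair", "pair", ["g1", "g2"], [("g1", "g2", +1)])


def random_dag(rng, n_genes):
    """Random DAG on n_genes with random signs; edges only i -> j for i < j."""
    genes = [f"g{i}" for i in range(n_genes)]
    edges = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < 0.4:
                beta = -1 if rng.random() < 0.3 else +1
                edges.append((genes[i], genes[j], beta))
    return PathwayGraph("dag", "dag", genes, edges)


def small_dataset(seed=0, n_genes=8, n_per_group=5, shift_genes=(), shift=2.0):
    """Gaussian toy dataset; genes in shift_genes get +shift in the test group."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1}" for i in range(n_genes)]
    n = 2 * n_per_group
    values = rng.normal(0, 1, size=(n_genes, n))
    for g in shift_genes:
        values[genes.index(g), n_per_group:] += shift
    return ExpressionDataset(
        genes=genes,
        samples=[f"s{k}" for k in range(n)],
        values=values,
        labels=["control"] * n_per_group + ["test"] * n_per_group,
    )
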