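"""Seeded synthetic pathways and two-condition expression matrices.

The generator emulates a two-group (control vs test) normalised,
log-scale expression study at toy scale: random signed directed pathway
topologies, per-gene Gaussian noise, edge-wise co-expression induced by
shared latent factors, and an optional coherently perturbed pathway whose
genes are shifted by a stated log fold-change in the test group only,
with the shift's sign propagated through inhibition edges so that the
perturbation accumulates rather than cancels.  Everything is a pure
function of the spec (same seed, byte-identical output).
"""

from __future__ import annotations

import os
from collections import deque
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .expression import CONTROL, TEST, ExpressionDataset
from .pathways import PathwayGraph, write_edge_list


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    ``edge_correlation`` is the target Pearson correlation of
    edge-adjacent gene pairs (its sign applies across activation edges;
    inhibition edges flip it).  ``effect_size`` is the mean log
    fold-change given to perturbed/DE genes; ``de_fraction`` adds that
    shift, with random sign, to a random fraction of the genes outside
    the perturbed pathway so the genome-wide DEG pool is non-trivial.
    """

    n_genes: int = 100
    n_pathways: int = 4
    genes_per_pathway: int = 10
    edge_density: float = 0.25
    inhibition_fraction: float = 0.0
    n_control: int = 10
    n_test: int = 10
    de_fraction: float = 0.0
    effect_size: float = 1.0
    edge_correlation: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    #: feed-forward cascades (edges only from earlier to later block genes).
    #: Dense cyclic digraphs with uniform activation make I - M exactly
    #: singular (column-stochastic propagation), i.e. unsolvable pathways;
    #: cascades are always solvable and mirror receptor -> effector flow.
    acyclic: bool = True

    def __post_init__(self) -> None:
        if self.genes_per_pathway < 2:
            raise ValueError("genes_per_pathway must be >= 2")
        if self.n_pathways * self.genes_per_pathway > self.n_genes:
            raise ValueError("pathways need disjoint gene blocks: raise n_genes")
        if not (0.0 < self.edge_density <= 1.0):
            raise ValueError("edge_density must be in (0, 1]")
        for name in ("inhibition_fraction", "de_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (-1.0 <= self.edge_correlation <= 1.0):
            raise ValueError("edge_correlation must be in [-1, 1]")
        if abs(self.edge_correlation) == 1.0 and self.noise_sd > 0.0:
            raise ValueError("|edge_correlation| = 1 is unachievable with noise_sd > 0")
        if min(self.n_control, self.n_test) < 2:
            raise ValueError("need >= 2 samples per group")


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def make_pathways(spec: FixtureSpec) -> list[PathwayGraph]:
    """Random directed signed pathways on disjoint gene blocks.

    Each ordered gene pair (no self-loops) becomes an edge with
    probability ``edge_density``; each edge is inhibitory (beta = -1)
    with probability ``inhibition_fraction``.  A pathway that comes out
    edgeless is regenerated once, then an error is raised.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    pathways: list[PathwayGraph] = []
    for p in range(spec.n_pathways):
        block = [_gene_name(p * spec.genes_per_pathway + k) for k in range(spec.genes_per_pathway)]
        for attempt in range(2):
            edges = []
            for i, src in enumerate(block):
                for j, tgt in enumerate(block):
                    if i == j or (spec.acyclic and j <= i):
                        continue
                    if rng.random() < spec.edge_density:
                        beta = -1 if rng.random() < spec.inhibition_fraction else +1
                        edges.append((src, tgt, beta))
            if edges:
                break
        else:
            raise ValueError(f"pathway {p}: zero edges twice at density {spec.edge_density}")
        pathways.append(
            PathwayGraph(f"SYN{p:03d}", f"synthetic pathway {p}", block, edges)
        )
    return pathways


def _coherence_signs(graph: PathwayGraph, corr_sign: int) -> dict[str, int]:
    """Per-gene sign in {-1, +1} propagated breadth-first over the
    (undirected) edge set: traversing an edge multiplies by
    beta * corr_sign.  Sign conflicts on cycles keep the first-assigned
    value."""
    adj: dict[str, list[tuple[str, int]]] = {g: [] for g in graph.genes}
    for src, tgt, beta in graph.edges:
        adj[src].append((tgt, beta))
        adj[tgt].append((src, beta))
    signs: dict[str, int] = {}
    for root in graph.genes:
        if root in signs:
            continue
        signs[root] = +1
        queue = deque([root])
        while queue:
            g = queue.popleft()
            for nb, beta in adj[g]:
                if nb not in signs:
                    signs[nb] = signs[g] * beta * corr_sign
                    queue.append(nb)
    return signs


def make_expression(
    spec: FixtureSpec,
    pathways: list[PathwayGraph],
    perturbed_pathway_index: int | None = None,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Two-condition expression matrix plus a ground-truth table.

    Baseline expression is Gaussian with sd ``noise_sd``.  Within each
    pathway a per-component latent factor gives edge-adjacent pairs a
    correlation of about ``edge_correlation`` (flipped across inhibition
    edges).  If ``perturbed_pathway_index`` is set, that pathway's genes
    gain ``effect_size`` (sign-matched to the coherence pattern) in test
    samples only; ``de_fraction`` of the remaining genes gain the same
    shift with random sign.  The truth table records, per gene, the
    intended test-vs-control shift, the DE flag, and the owning pathway.
    """
    if perturbed_pathway_index is not None and not (0 <= perturbed_pathway_index < len(pathways)):
        raise ValueError("perturbed_pathway_index out of range")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n_samples = spec.n_control + spec.n_test
    genes = [_gene_name(i) for i in range(spec.n_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    samples = [f"ctrl{k:03d}" for k in range(spec.n_control)] + [
        f"test{k:03d}" for k in range(spec.n_test)
    ]
    labels = [CONTROL] * spec.n_control + [TEST] * spec.n_test
    test_cols = np.array([lab == TEST for lab in labels])

    rho = abs(spec.edge_correlation)
    corr_sign = -1 if spec.edge_correlation < 0 else +1
    values = rng.normal(0.0, 1.0, size=(spec.n_genes, n_samples))
    pathway_of = np.full(spec.n_genes, -1, dtype=int)
    signs_by_gene: dict[str, int] = {}
    for p, graph in enumerate(pathways):
        signs = _coherence_signs(graph, corr_sign)
        signs_by_gene.update(signs)
        # one latent factor per connected component -> corr(i,j) = s_i s_j rho
        comp_latent: dict[str, np.ndarray] = {}
        if rho > 0:
            roots = _component_roots(graph)
            latents = {r: rng.normal(0.0, 1.0, size=n_samples) for r in roots}
            comp_latent = {g: latents[r] for g, r in _component_of(graph, roots).items()}
        for g in graph.genes:
            i = gene_pos[g]
            pathway_of[i] = p
            if rho > 0:
                values[i] = signs[g] * np.sqrt(rho) * comp_latent[g] + np.sqrt(1 - rho) * values[i]
    values *= spec.noise_sd

    shift = np.zeros(spec.n_genes)
    if perturbed_pathway_index is not None and spec.effect_size != 0.0:
        for g in pathways[perturbed_pathway_index].genes:
            shift[gene_pos[g]] = spec.effect_size * signs_by_gene.get(g, 1)
    if spec.de_fraction > 0.0 and spec.effect_size != 0.0:
        eligible = np.flatnonzero(
            pathway_of != (perturbed_pathway_index if perturbed_pathway_index is not None else -2)
        )
        eligible = eligible[shift[eligible] == 0.0]
        n_extra = int(round(spec.de_fraction * eligible.size))
        chosen = rng.choice(eligible, size=n_extra, replace=False)
        shift[chosen] = spec.effect_size * rng.choice([-1.0, 1.0], size=n_extra)
    values[:, test_cols] += shift[:, None]

    data = ExpressionDataset(genes=genes, samples=samples, values=values, labels=labels)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "is_de": shift != 0.0,
            "effect": shift,
            "pathway": pathway_of,
            "perturbed_pathway": (
                -1 if perturbed_pathway_index is None else perturbed_pathway_index
            ),
        }
    )
    return data, truth


def _component_roots(graph: PathwayGraph) -> list[str]:
    comp = _component_of(graph, None)
    return sorted(set(comp.values()), key=graph.gene_index)


def _component_of(graph: PathwayGraph, roots) -> dict[str, str]:
    """Map gene -> root gene of its undirected connected component."""
    adj: dict[str, list[str]] = {g: [] for g in graph.genes}
    for src, tgt, _beta in graph.edges:
        adj[src].append(tgt)
        adj[tgt].append(src)
    comp: dict[str, str] = {}
    for root in graph.genes:
        if root in comp:
            continue
        comp[root] = root
        queue = deque([root])
        while queue:
            g = queue.popleft()
            for nb in adj[g]:
                if nb not in comp:
                    comp[nb] = root
                    queue.append(nb)
    return comp


def write_fixture(
    spec: FixtureSpec,
    out_dir: str | os.PathLike,
    perturbed_pathway_index: int | None = None,
) -> None:
    """Materialise a fixture on disk: ``pathways/*.tsv`` edge lists,
    ``expression.tsv``, ``labels.tsv``, ``truth.tsv``, ``spec.tsv``."""
    out_dir = os.fspath(out_dir)
    pw_dir = os.path.join(out_dir, "pathways")
    os.makedirs(pw_dir, exist_ok=True)
    pathways = make_pathways(spec)
    for graph in pathways:
        write_edge_list(graph, os.path.join(pw_dir, f"{graph.pathway_id}.tsv"))
    data, truth = make_expression(spec, pathways, perturbed_pathway_index)
    data.to_frame().to_csv(os.path.join(out_dir, "expression.tsv"), sep="\t")
    with open(os.path.join(out_dir, "labels.tsv"), "w", encoding="utf-8") as fh:
        for s, lab in zip(data.samples, data.labels):
            fh.write(f"{s}\t{lab}\n")
    truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    pd.Series(asdict(spec)).to_csv(
        os.path.join(out_dir, "spec.tsv"), sep="\t", header=False
    )
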