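"""Per-edge interaction intensities w_ij.

Three weighting schemes:

* ``unit`` — every weight 1 (classic SPIA; edge signs beta carry all
  information);
* ``pearson`` — sample Pearson correlation (n-1 denominator) of the two
  genes' expression profiles, signed by default so a negative
  correlation flips the effective edge sign in the propagation
  (PSPIA);
* ``mi`` — plug-in mutual information, in bits by default, of the two
  genes' median-binarized profiles (MSPIA); always >= 0, not
  normalised, so MI and Pearson weights live on different scales.

Weights are computed over all samples, both conditions pooled, unless
restricted via ``samples=``.  A gene missing from the expression data or
with zero variance falls back to weight 1 (SPIA strength) with the event
counted in the report — the topology is never silently rewired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionDataset, binarize
from .pathways import PathwayGraph

logger = logging.getLogger(__name__)

METHODS = ("unit", "pearson", "mi")


@dataclass
class WeightReport:
    missing_genes: int = 0
    zero_variance: int = 0


@dataclass
class WeightMatrix:
    """Interaction intensity per edge of one pathway, for one method."""

    method: str
    weights: dict[tuple[str, str], float]
    report: WeightReport = field(default_factory=WeightReport)

    def __getitem__(self, edge: tuple[str, str]) -> float:
        return self.weights[edge]

    @classmethod
    def unit(cls, graph: PathwayGraph) -> "WeightMatrix":
        return cls("unit", {(s, t): 1.0 for s, t, _b in graph.edges})


def pearson_weight(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation of two expression profiles.

    Computed as the standardized cross-product with an n-1 denominator;
    requires n >= 3 and nonzero standard deviation in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("zero standard deviation: Pearson weight undefined")
    r = float(np.sum((x - x.mean()) / sx * (y - y.mean()) / sy) / (n - 1))
    return min(1.0, max(-1.0, r))


class ZeroVarianceError(ValueError):
    pass


def mi_weight(bx: np.ndarray, by: np.ndarray, log_base: float = 2.0) -> float:
    """Plug-in mutual information of two binary vectors.

    Empirical joint frequencies over the 2x2 table; cells with zero joint
    probability contribute 0.  Degenerate (constant) marginals give 0.
    """
    bx = np.asarray(bx, dtype=int)
    by = np.asarray(by, dtype=int)
    if bx.shape != by.shape or bx.ndim != 1 or bx.size < 2:
        raise ValueError("vectors must be 1-D, equal length, n >= 2")
    if not (np.isin(bx, (0, 1)).all() and np.isin(by, (0, 1)).all()):
        raise ValueError("entries must be 0/1")
    n = bx.size
    mi = 0.0
    for xv in (0, 1):
        px = float(np.mean(bx == xv))
        if px == 0.0:
            continue
        for yv in (0, 1):
            py = float(np.mean(by == yv))
            pxy = float(np.count_nonzero((bx == xv) & (by == yv))) / n
            if pxy == 0.0 or py == 0.0:
                continue
            mi += pxy * np.log(pxy / (px * py))
    mi /= np.log(log_base)
    return max(0.0, float(mi))


def edge_weights(
    graph: PathwayGraph,
    data: ExpressionDataset | None,
    method: str = "unit",
    *,
    log_base: float = 2.0,
    abs_weights: bool = False,
    samples: str = "all",
) -> WeightMatrix:
    """One weight per edge of ``graph`` under the given method.

    ``samples`` selects the profiles used ("all", "control" or "test").
    Genes absent from the data, and zero-variance genes under
    ``pearson``, fall back to weight 1 and are counted in the report.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if method == "unit":
        return WeightMatrix.unit(graph)
    if data is None:
        raise ValueError(f"method {method!r} requires expression data")

    if samples == "all":
        mask = np.ones(data.n_samples, dtype=bool)
    elif samples == "control":
        mask = data.control_mask
    elif samples == "test":
        mask = data.test_mask
    else:
        raise ValueError(f"samples must be 'all', 'control' or 'test', got {samples!r}")

    binary = binarize(data) if method == "mi" else None
    report = WeightReport()
    weights: dict[tuple[str, str], float] = {}
    cache: dict[tuple[str, str], float] = {}
    for src, tgt, _beta in graph.edges:
        key = (src, tgt) if src <= tgt else (tgt, src)  # both measures are symmetric
        if key in cache:
            weights[(src, tgt)] = cache[key]
            continue
        if src not in data or tgt not in data:
            report.missing_genes += 1
            w = 1.0
        elif method == "pearson":
            try:
                w = pearson_weight(data.gene_values(src)[mask], data.gene_values(tgt)[mask])
            except ZeroVarianceError:
                report.zero_variance += 1
                logger.warning(
                    "%s: zero-variance gene on edge %s->%s, weight falls back to 1",
                    graph.pathway_id, src, tgt,
                )
                w = 1.0
            if abs_weights:
                w = abs(w)
        else:  # mi
            w = mi_weight(
                binary.gene_values(src)[mask], binary.gene_values(tgt)[mask], log_base=log_base
            )
        cache[key] = w
        weights[(src, tgt)] = w
    return WeightMatrix(method, weights, report=report)


def write_weights_tsv(graph: PathwayGraph, wm: WeightMatrix, fh) -> None:
    """Dump per-edge weights: pathway_id, source, target, beta, weight."""
    for src, tgt, beta in graph.edges:
        fh.write(f"{graph.pathway_id}\t{src}\t{tgt}\t{beta:+d}\t{wm.weights[(src, tgt)]:.10g}\n")
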