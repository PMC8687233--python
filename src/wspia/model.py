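"""Model-style front end: build an analysis from data, fit, inspect results.

``PathwayImpactAnalysis`` holds the inputs (expression dataset, pathway
set, weighting method, DEG threshold); ``fit`` runs DEG calling, edge
weighting, perturbation propagation and the bootstrap, returning a
``PathwayImpactResults`` with the per-pathway table, significance calls
and a text summary.
"""

from __future__ import annotations

import os

import pandas as pd

from .engine import PathwayResult, results_frame, run_analysis, write_results_tsv
from .expression import DEGTable, ExpressionDataset, call_degs, load_expression
from .pathways import PathwayGraph, load_pathway_dir


def read_labels(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column ``sample<TAB>group`` labels file."""
    labels: dict[str, str] = {}
    with open(os.fspath(path), encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path!s} line {lineno}: expected sample<TAB>group")
            labels[parts[0]] = parts[1]
    return labels


class PathwayImpactAnalysis:
    """Topology-based pathway impact analysis of a two-group expression study.

    Parameters
    ----------
    data : ExpressionDataset
        Genes x samples log-scale expression with control/test labels.
    pathways : list of PathwayGraph or path
        Signed pathway topologies (a directory is loaded file-by-file).
    method : {"spia", "pspia", "mspia"}
        Edge weighting: unit (classic SPIA), Pearson correlation of
        expression profiles, or mutual information of binarized profiles.
    alpha : float
        Raw p-value threshold for calling a gene differentially expressed.
    """

    def __init__(
        self,
        data: ExpressionDataset,
        pathways,
        method: str = "spia",
        alpha: float = 0.05,
        *,
        mi_log_base: float = 2.0,
        abs_weights: bool = False,
        weight_samples: str = "all",
    ) -> None:
        self.data = data
        if isinstance(pathways, (str, os.PathLike)):
            pathways = load_pathway_dir(pathways)
        self.pathways: list[PathwayGraph] = list(pathways)
        self.method = method
        self.alpha = alpha
        self.mi_log_base = mi_log_base
        self.abs_weights = abs_weights
        self.weight_samples = weight_samples

    @classmethod
    def from_files(
        cls,
        expression_path: str | os.PathLike,
        labels,
        pathway_dir: str | os.PathLike,
        **kwargs,
    ) -> "PathwayImpactAnalysis":
        """Build from a TSV expression matrix, a labels mapping or labels
        file, and a directory of pathway files."""
        if isinstance(labels, (str, os.PathLike)):
            labels = read_labels(labels)
        data = load_expression(expression_path, labels)
        return cls(data, pathway_dir, **kwargs)

    def fit(
        self,
        iterations: int = 2000,
        seed: int = 0,
        *,
        force_unit_weights: bool = False,
    ) -> "PathwayImpactResults":
        """Run the analysis; deterministic given ``seed``."""
        deg = call_degs(self.data, alpha=self.alpha)
        results = run_analysis(
            self.data,
            self.pathways,
            method=self.method,
            alpha=self.alpha,
            iterations=iterations,
            seed=seed,
            deg_table=deg,
            force_unit_weights=force_unit_weights,
            mi_log_base=self.mi_log_base,
            abs_weights=self.abs_weights,
            weight_samples=self.weight_samples,
        )
        return PathwayImpactResults(self, results, deg, iterations=iterations, seed=seed)


class PathwayImpactResults:
    """Fitted per-pathway significance results."""

    def __init__(
        self,
        model: PathwayImpactAnalysis,
        results: list[PathwayResult],
        deg_table: DEGTable,
        *,
        iterations: int,
        seed: int,
    ) -> None:
        self.model = model
        self.results = results
        self.deg_table = deg_table
        self.iterations = iterations
        self.seed = seed

    @property
    def frame(self) -> pd.DataFrame:
        """Per-pathway table sorted ascending by combined p-value."""
        return results_frame(self.results)

    def significant(self, fdr_threshold: float = 0.01) -> pd.DataFrame:
        """Pathways with BH-adjusted combined p-value below the threshold."""
        df = self.frame
        return df[df["p_g_fdr"] < fdr_threshold].reset_index(drop=True)

    def to_tsv(self, path: str | os.PathLike) -> None:
        write_results_tsv(self.results, path)

    def summary(self, fdr_threshold: float = 0.01) -> str:
        df = self.frame
        n_ok = int((df["status"] == "ok").sum())
        n_sig = int((df["p_g_fdr"] < fdr_threshold).sum())
        lines = [
            "Pathway impact analysis",
            "=======================",
            f"method:            {self.model.method}",
            f"genes x samples:   {self.model.data.n_genes} x {self.model.data.n_samples}",
            f"DEGs (p < {self.model.alpha:g}):  {self.deg_table.n_de}",
            f"pathways:          {len(self.results)} ({n_ok} analysed)",
            f"significant (FDR < {fdr_threshold:g}): {n_sig}",
            f"bootstrap:         {self.iterations} iterations, seed {self.seed}",
            "",
            df.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
                max_rows=40,
            ),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<PathwayImpactResults: {len(self.results)} pathways, "
            f"method={self.model.method!r}>"
        )
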