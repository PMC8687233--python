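"""Expression matrices, differential-expression calling, and binarization.

The dataset is a genes x samples matrix of log2-scale intensities with a
two-group design (control vs test).  Differentially expressed genes (DEGs)
are called with a two-sided Welch two-sample t-test at p < alpha; the
signed log fold-change mean(test) - mean(control) is the gene's measured
expression change fed into the perturbation recursion.  For the
mutual-information weights the matrix is binarized per gene at its median
across all samples (>= median -> 1, "overexpressed").
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONTROL = "control"
TEST = "test"


@dataclass
class ExpressionDataset:
    """Genes x samples expression values with two-group labels."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float
    labels: list[str]  # per sample, each "control" or "test"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.genes)} genes, {len(self.samples)} samples)"
            )
        if len(self.labels) != len(self.samples):
            raise ValueError("one label per sample required")
        bad = set(self.labels) - {CONTROL, TEST}
        if bad:
            raise ValueError(f"labels must be 'control' or 'test', got {sorted(bad)}")
        for group in (CONTROL, TEST):
            if self.labels.count(group) < 2:
                raise ValueError(f"need >= 2 '{group}' samples, got {self.labels.count(group)}")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values contain non-finite entries after load")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def control_mask(self) -> np.ndarray:
        return np.array([lab == CONTROL for lab in self.labels])

    @property
    def test_mask(self) -> np.ndarray:
        return np.array([lab == TEST for lab in self.labels])

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class DEGTable:
    """Per-gene differential statistics (log_fc, p_value, is_de)."""

    frame: pd.DataFrame  # index = genes; columns log_fc, p_value, is_de
    alpha: float = 0.05

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def de_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["is_de"]])

    @property
    def n_de(self) -> int:
        return int(self.frame["is_de"].sum())

    def delta_e(self, gene: str) -> float:
        """Signed expression change used for perturbation: log_fc for DEGs, 0 otherwise."""
        if gene not in self.frame.index:
            return 0.0
        row = self.frame.loc[gene]
        return float(row["log_fc"]) if bool(row["is_de"]) else 0.0

    def de_pool(self) -> np.ndarray:
        """Log fold-changes of all DEGs (the bootstrap sampling pool)."""
        return self.frame.loc[self.frame["is_de"], "log_fc"].to_numpy()


@dataclass
class BinaryMatrix:
    """Genes x samples 0/1 matrix, same ordering as its source dataset."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # int {0,1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]


def load_expression(path: str | os.PathLike, labels: dict[str, str]) -> ExpressionDataset:
    """Load a TSV expression matrix (header = sample IDs, first column = gene IDs).

    ``labels`` maps every sample ID to "control" or "test".  Rows with
    missing values are dropped and duplicate gene IDs collapsed by mean
    (both logged).  Samples absent from ``labels`` raise an error.
    """
    df = pd.read_csv(os.fspath(path), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    missing = [s for s in df.columns if s not in labels]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    absent = [s for s in labels if s not in df.columns]
    if absent:
        raise ValueError(f"labelled samples missing from the matrix header: {absent}")

    n_before = len(df)
    df = df.dropna(axis=0)
    if len(df) < n_before:
        logger.warning("dropped %d rows with missing values", n_before - len(df))
    if df.index.has_duplicates:
        n_dup = len(df) - df.index.nunique()
        logger.warning("collapsed %d duplicate gene rows by mean", n_dup)
        df = df.groupby(level=0, sort=False).mean()

    samples = list(df.columns)
    return ExpressionDataset(
        genes=list(df.index),
        samples=samples,
        values=df.to_numpy(dtype=float),
        labels=[labels[s] for s in samples],
    )


def call_degs(data: ExpressionDataset, alpha: float = 0.05) -> DEGTable:
    """Per-gene two-sided Welch t-test (test vs control) and signed log fold-change.

    A gene with zero variance in both groups gets p = 1 when the group
    means are equal and p = 0 when they differ (a deterministic, noiseless
    shift).  is_de is the raw p < alpha call.
    """
    ctrl = data.values[:, data.control_mask]
    test = data.values[:, data.test_mask]
    log_fc = test.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(test, ctrl, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        p[degenerate] = np.where(np.isclose(log_fc[degenerate], 0.0), 1.0, 0.0)
    frame = pd.DataFrame(
        {"log_fc": log_fc, "p_value": p, "is_de": p < alpha}, index=pd.Index(data.genes)
    )
    return DEGTable(frame=frame, alpha=alpha)


def binarize(data: ExpressionDataset, threshold: str = "median") -> BinaryMatrix:
    """Binarize per gene: entries >= the gene's median (or mean) over all
    samples become 1 (overexpression), the rest 0."""
    if threshold == "median":
        cut = np.median(data.values, axis=1, keepdims=True)
    elif threshold == "mean":
        cut = data.values.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"threshold must be 'median' or 'mean', got {threshold!r}")
    return BinaryMatrix(
        genes=list(data.genes),
        samples=list(data.samples),
        values=(data.values >= cut).astype(int),
    )
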