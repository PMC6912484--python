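"""Breed-parameter table assembly and standardized PCA.

Breed-level summaries (inbreeding, relatedness, effective size,
gene-origin, census and generation-interval statistics) span several
orders of magnitude, so the PCA standardizes each column to z-scores by
default — equivalently, it eigendecomposes the correlation matrix.  A
covariance-matrix variant (``standardize='none'``) is available for
pre-scaled tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import PedigreeError

BREED_PARAMETER_COLUMNS = (
    "AVG_F",
    "TMI",
    "AR",
    "Ne",
    "fe_fa_ratio",
    "ANC_50",
    "P_CONT",
    "APSR",
    "APSSD",
    "GI",
)


def assemble_parameters(results: Mapping[str, "object"] | pd.DataFrame) -> pd.DataFrame:
    """Build the population × parameter matrix feeding the PCA.

    Accepts either a mapping of population label ->
    :class:`~pedimetrics.model.PedigreeAnalysisResults` (each contributing
    one row via ``parameter_row``) or a ready DataFrame, which is
    validated for the expected columns.  Missing cells raise, naming the
    offending parameter.
    """
    if isinstance(results, pd.DataFrame):
        table = results.copy()
        missing_cols = set(BREED_PARAMETER_COLUMNS) - set(table.columns)
        if missing_cols:
            raise PedigreeError(f"parameter table lacks columns: {sorted(missing_cols)}")
        table = table.loc[:, list(BREED_PARAMETER_COLUMNS)]
    else:
        rows = {}
        for label, res in results.items():
            rows[label] = res.parameter_row()
        table = pd.DataFrame.from_dict(rows, orient="index")
        table = table.loc[:, list(BREED_PARAMETER_COLUMNS)]
    bad = table.columns[table.isna().any(axis=0)]
    if len(bad):
        raise PedigreeError(f"missing parameter values in columns: {list(bad)}")
    return table.astype(float)


@dataclass
class PCAResult:
    """Scores, loadings and percent variance of a principal component
    analysis; components are ordered by decreasing variance and each
    loading vector's largest-magnitude entry is positive."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_pct: np.ndarray
    standardize: str

    def explained(self, n_components: int) -> float:
        """Percent variance captured by the first ``n_components``."""
        return float(self.variance_pct[:n_components].sum())

    def biplot_frame(self, n_components: int = 2) -> pd.DataFrame:
        """Long-format biplot data: one row per population score and one
        per variable loading."""
        cols = [f"PC{i + 1}" for i in range(n_components)]
        rows = []
        for label, row in self.scores.iterrows():
            rows.append({"entity": label, "type": "score", **row[cols].to_dict()})
        for label, row in self.loadings.iterrows():
            rows.append({"entity": label, "type": "loading", **row[cols].to_dict()})
        return pd.DataFrame(rows)

    def plot_biplot(self, ax=None):
        """Biplot of the first two components (scores as points, loadings
        as arrows)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        ax.axhline(0, color="0.8", lw=0.8)
        ax.axvline(0, color="0.8", lw=0.8)
        for label, row in self.scores.iterrows():
            ax.scatter(row["PC1"], row["PC2"], color="tab:blue")
            ax.annotate(str(label), (row["PC1"], row["PC2"]), fontsize=8)
        scale = np.abs(self.scores[["PC1", "PC2"]].values).max()
        for label, row in self.loadings.iterrows():
            ax.arrow(0, 0, row["PC1"] * scale, row["PC2"] * scale,
                     color="tab:red", alpha=0.6, head_width=0.02 * scale)
            ax.annotate(str(label), (row["PC1"] * scale, row["PC2"] * scale),
                        fontsize=8, color="tab:red")
        ax.set_xlabel(f"PC1 ({self.variance_pct[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({self.variance_pct[1]:.1f}%)")
        return ax


def run_pca(table: pd.DataFrame, standardize: str = "zscore", ddof: int = 1) -> PCAResult:
    """PCA of a populations × parameters table.

    ``standardize='zscore'`` centers and scales each column by its sample
    SD (``ddof`` selectable), then eigendecomposes the resulting
    correlation matrix; ``'none'`` uses the covariance matrix of centered
    columns.  Percent variance is reported over all variables, so it sums
    to 100.
    """
    if standardize not in ("zscore", "none"):
        raise PedigreeError(f"unknown standardize option {standardize!r}")
    X = table.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise PedigreeError("PCA needs at least 2 populations (rows)")
    if np.isnan(X).any():
        bad = table.columns[np.isnan(X).any(axis=0)]
        raise PedigreeError(f"missing cells in columns: {list(bad)}")
    centered = X - X.mean(axis=0)
    if standardize == "zscore":
        sd = X.std(axis=0, ddof=ddof)
        zero = table.columns[sd == 0]
        if len(zero):
            raise PedigreeError(f"zero-variance columns cannot be z-scored: {list(zero)}")
        Z = centered / sd
    else:
        Z = centered
    C = (Z.T @ Z) / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude entry of each loading positive
    for k in range(eigvec.shape[1]):
        lead = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[lead, k] < 0:
            eigvec[:, k] *= -1
    pcs = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(Z @ eigvec, index=table.index, columns=pcs),
        loadings=pd.DataFrame(eigvec, index=table.columns, columns=pcs),
        variance_pct=100.0 * eigval / eigval.sum(),
        standardize=standardize,
    )
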