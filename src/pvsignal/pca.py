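"""Drug x adverse-event ln(ROR) matrix and its correlation-matrix PCA.

Drugs passing the disproportionality screen (with strictly more than a
minimum number of target-class reports) form the rows; target-class preferred
terms with strictly more than a minimum number of reports form the columns.
Entry (i, j) is the natural log of the Haldane-corrected ROR of drug i for
event term j computed against the full cohort, so every entry is finite.

The matrix columns are standardised (mean 0, SD 1 over drugs, sample SD with
n-1) and the correlation matrix eigendecomposed.  Scores are the standardised
data projected on the eigenvectors; loadings are reported as variable-to-
component correlations (eigenvector times sqrt(eigenvalue)).  Component signs
are fixed by orienting each eigenvector so its largest-magnitude loading is
positive, which makes outputs deterministic; signs may therefore be flipped
relative to other software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConstantColumnError

__all__ = ["RorMatrix", "PcaMap", "select_entities", "build_ror_matrix",
           "pca_correlation", "biplot"]


@dataclass
class RorMatrix:
    """ln(ROR) values for selected drugs (rows) by event terms (columns)."""

    drugs: List[str]
    events: List[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.drugs), len(self.events)):
            raise ValueError("matrix shape does not match drug/event lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drugs, columns=self.events)


@dataclass
class PcaMap:
    """Correlation-PCA decomposition of a :class:`RorMatrix`."""

    drugs: List[str]
    events: List[str]
    eigenvalues: np.ndarray               # descending
    components: np.ndarray                # events x k orthonormal eigenvectors
    loadings: np.ndarray                  # events x k variable-PC correlations
    scores: np.ndarray                    # drugs x k
    explained_variance_ratio: np.ndarray  # eigenvalues / n_events

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.events, columns=cols)

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.drugs, columns=cols)


def select_entities(
    rows: pd.DataFrame,
    signal_drugs: Sequence[str],
    drug_min_reports: int = 50,
    event_min_reports: int = 70,
) -> Tuple[List[str], List[str]]:
    """Drugs and event terms admitted to the map (strict > thresholds).

    Drug counts are target-class rows naming the drug; event counts are
    occurrences of the term among target-class rows.
    """
    target = rows[rows["is_target_event"].astype(bool)]
    drug_counts = target["drug_name"].value_counts()
    drugs = [d for d in signal_drugs
             if int(drug_counts.get(d, 0)) > drug_min_reports]
    event_counts = target["preferred_term"].value_counts()
    events = [t for t, n in event_counts.items() if int(n) > event_min_reports]
    if not drugs or not events:
        raise ConfigurationError(
            "thresholds",
            f"selection is empty (drugs={len(drugs)}, events={len(events)}); "
            f"lower drug_min_reports ({drug_min_reports}) or "
            f"event_min_reports ({event_min_reports})")
    return drugs, sorted(events)


def build_ror_matrix(rows: pd.DataFrame, drugs: Sequence[str],
                     events: Sequence[str]) -> RorMatrix:
    """ln(ROR) of each drug for each single event term, corrected cells.

    For column j the "target" is the single preferred term; b, c, d are taken
    against the full cohort (all analysis rows), matching the per-drug screen.
    """
    if not len(drugs) or not len(events):
        raise ConfigurationError("thresholds", "empty drug or event selection")
    ct = pd.crosstab(rows["drug_name"], rows["preferred_term"])
    ct = ct.reindex(index=list(drugs), columns=list(events), fill_value=0)
    drug_totals = rows["drug_name"].value_counts().reindex(list(drugs), fill_value=0)
    event_totals = rows["preferred_term"].value_counts().reindex(list(events), fill_value=0)
    n = len(rows)
    a = ct.to_numpy(dtype=float)
    c = drug_totals.to_numpy(dtype=float)[:, None] - a
    b = event_totals.to_numpy(dtype=float)[None, :] - a
    d = n - a - b - c
    a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    values = np.log((a * d) / (b * c))
    return RorMatrix(drugs=list(drugs), events=list(events), values=values)


def pca_correlation(matrix: RorMatrix) -> PcaMap:
    """Correlation-matrix PCA of the ln(ROR) matrix.

    Raises :class:`ConstantColumnError` naming the event term if a column has
    zero variance.  Eigenvalues sum to the number of events (trace identity);
    explained-variance ratios sum to 1 over all components.
    """
    X = matrix.values
    n, p = X.shape
    if n < 2 or p < 2:
        raise ConfigurationError("matrix", "need at least 2 drugs and 2 events")
    sd = X.std(axis=0, ddof=1)
    # a column is constant up to floating point of the mean subtraction
    const = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0)))
    if const.size:
        raise ConstantColumnError(
            f"event column {matrix.events[const[0]]!r} is constant across drugs")
    Z = (X - X.mean(axis=0)) / sd
    R = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude loading of each component positive
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    loadings = eigvec * np.sqrt(eigval)[None, :]
    scores = Z @ eigvec
    return PcaMap(
        drugs=list(matrix.drugs),
        events=list(matrix.events),
        eigenvalues=eigval,
        components=eigvec,
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=eigval / p,
    )


def biplot(pca_map: PcaMap, loadings_path, scores_path):
    """Write the event-loading vector plot and the drug score scatter.

    Axis labels carry the explained-variance percentages of PC1 and PC2.
    Returns the two paths.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if pca_map.loadings.shape[1] < 2:
        raise ValueError("need at least 2 components for a biplot")
    pc1 = 100.0 * pca_map.explained_variance_ratio[0]
    pc2 = 100.0 * pca_map.explained_variance_ratio[1]
    xlabel = f"PC1 ({pc1:.1f}%)"
    ylabel = f"PC2 ({pc2:.1f}%)"

    fig, ax = plt.subplots(figsize=(7, 6))
    for j, term in enumerate(pca_map.events):
        x, y = pca_map.loadings[j, 0], pca_map.loadings[j, 1]
        ax.annotate("", xy=(x, y), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="tab:blue", lw=1.2))
        ax.annotate(term, xy=(x, y), fontsize=7)
    lim = max(1.05, float(np.abs(pca_map.loadings[:, :2]).max()) * 1.15)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title("Event loading vectors")
    fig.tight_layout()
    loadings_path = Path(loadings_path)
    loadings_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(loadings_path, dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 6))
    ax.scatter(pca_map.scores[:, 0], pca_map.scores[:, 1], s=22, color="tab:red")
    for i, drug in enumerate(pca_map.drugs):
        ax.annotate(drug, xy=(pca_map.scores[i, 0], pca_map.scores[i, 1]), fontsize=7)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title("Drug scores")
    fig.tight_layout()
    scores_path = Path(scores_path)
    scores_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(scores_path, dpi=150)
    plt.close(fig)
    return loadings_path, scores_path
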