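"""Per-drug disproportionality screening.

For each drug a 2x2 contingency table splits the analysis rows by
drug-of-interest vs all other drugs and target event vs all other events:

=====================  ==========  ============
..                     target      non-target
drug of interest       a           c
all other drugs        b           d
=====================  ==========  ============

The reporting odds ratio (ROR) is the cross-product ratio a*d / (b*c) after
the Haldane-Anscombe correction (0.5 added to every cell, unconditionally, so
the ROR and its log stay finite with zero cells).  The 95% CI is the Woolf
(log-normal) interval on the corrected cells.  Significance comes from a
two-sided Fisher exact test on the *uncorrected* integer counts (correcting an
exact test would be incoherent).  A drug is a signal when ROR >= 1 and
p <= 0.05.  The volcano plot shows ln(ROR) against -log10(p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Contingency2x2", "SignalResult", "build_contingency", "haldane_correct",
    "compute_ror", "fisher_exact_p", "screen_drugs", "results_frame",
    "volcano_plot",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class Contingency2x2:
    """Raw counts a, b, c, d (see module docstring for orientation)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def corrected(self) -> Tuple[float, float, float, float]:
        return haldane_correct(self)


@dataclass(frozen=True)
class SignalResult:
    """Screening result for one drug."""

    drug_name: str
    n_reports: int            # a: target-event rows naming the drug
    n_total_reports: int      # a + c: all rows naming the drug
    ror: float
    ln_ror: float
    ci95: Tuple[float, float]
    p_value: float
    neg_log10_p: float
    is_signal: bool
    table: Contingency2x2


def build_contingency(rows: pd.DataFrame, drug_name: str) -> Contingency2x2:
    """2x2 split of the analysis rows for one drug vs all others."""
    if not len(rows):
        raise ValueError("analysis rows are empty")
    is_drug = (rows["drug_name"] == drug_name).to_numpy()
    is_target = rows["is_target_event"].to_numpy(dtype=bool)
    a = int((is_drug & is_target).sum())
    b = int((~is_drug & is_target).sum())
    c = int((is_drug & ~is_target).sum())
    d = int((~is_drug & ~is_target).sum())
    return Contingency2x2(a, b, c, d)


def haldane_correct(t: Contingency2x2) -> Tuple[float, float, float, float]:
    """Add 0.5 to every cell, unconditionally (applied to all tables)."""
    return (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)


def compute_ror(t: Contingency2x2) -> Tuple[float, float, Tuple[float, float]]:
    """(ROR, ln ROR, Woolf 95% CI) on the corrected cells."""
    a, b, c, d = haldane_correct(t)
    ror = (a * d) / (b * c)
    ln_ror = math.log(ror)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    ci = (math.exp(ln_ror - Z_95 * se), math.exp(ln_ror + Z_95 * se))
    return ror, ln_ror, ci


def fisher_exact_p(t: Contingency2x2) -> float:
    """Two-sided Fisher exact p on the raw integer counts.

    Two-sided by the sum-of-smaller-probabilities definition (the sum of the
    hypergeometric probabilities of all tables with the observed margins that
    are no more probable than the observed table).
    """
    _, p = stats.fisher_exact([[t.a, t.c], [t.b, t.d]], alternative="two-sided")
    return float(min(p, 1.0))


def screen_drugs(
    rows: pd.DataFrame,
    min_reports: int = 0,
    drugs: Optional[Sequence[str]] = None,
    signal_ror: float = 1.0,
    signal_p: float = 0.05,
) -> List[SignalResult]:
    """One :class:`SignalResult` per drug with a >= ``min_reports``.

    All drugs appearing in the analysis rows are screened by default,
    including drugs with zero target-event reports.  Results are sorted by
    p ascending then ROR descending.
    """
    if not len(rows):
        raise ValueError("analysis rows are empty")
    is_target = rows["is_target_event"].to_numpy(dtype=bool)
    n_total = len(rows)
    n_target = int(is_target.sum())
    per_drug = rows.groupby("drug_name", sort=True).agg(
        n_rows=("drug_name", "size"), a=("is_target_event", "sum"))
    if drugs is not None:
        per_drug = per_drug.reindex(drugs, fill_value=0)
    results: List[SignalResult] = []
    for drug_name, row in per_drug.iterrows():
        a = int(row["a"])
        if a < min_reports:
            continue
        c = int(row["n_rows"]) - a
        b = n_target - a
        d = n_total - n_target - c
        t = Contingency2x2(a, b, c, d)
        ror, ln_ror, ci = compute_ror(t)
        p = fisher_exact_p(t)
        results.append(SignalResult(
            drug_name=str(drug_name),
            n_reports=a,
            n_total_reports=a + c,
            ror=ror,
            ln_ror=ln_ror,
            ci95=ci,
            p_value=p,
            neg_log10_p=-math.log10(p),
            is_signal=bool(ror >= signal_ror and p <= signal_p),
            table=t,
        ))
    results.sort(key=lambda r: (r.p_value, -r.ror))
    return results


def results_frame(results: Sequence[SignalResult],
                  benjamini_hochberg: bool = True) -> pd.DataFrame:
    """Tabulate screening results; optionally append a BH-adjusted p column.

    The BH column is supplementary output: the screening rule itself applies
    no multiple-testing adjustment.
    """
    df = pd.DataFrame([{
        "drug_name": r.drug_name,
        "n_target_reports": r.n_reports,
        "n_reports": r.n_total_reports,
        "ror": r.ror,
        "ci95_low": r.ci95[0],
        "ci95_high": r.ci95[1],
        "p_value": r.p_value,
        "ln_ror": r.ln_ror,
        "neg_log10_p": r.neg_log10_p,
        "is_signal": r.is_signal,
    } for r in results])
    if benjamini_hochberg and len(df):
        from statsmodels.stats.multitest import multipletests
        df["p_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def volcano_plot(results: Sequence[SignalResult], path,
                 color_bounds: Optional[Tuple[float, float]] = None):
    """Scatter of ln(ROR) vs -log10(p), colored by log10 of report count.

    A dotted horizontal reference marks p = 0.05.  Returns the output path.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not results:
        raise ValueError("no screening results to plot")
    x = np.array([r.ln_ror for r in results])
    y = np.array([r.neg_log10_p for r in results])
    n = np.array([max(r.n_total_reports, 1) for r in results], dtype=float)
    color = np.log10(n)
    vmin, vmax = color_bounds if color_bounds is not None else (color.min(), color.max())
    fig, ax = plt.subplots(figsize=(7, 5))
    sc = ax.scatter(x, y, c=color, cmap="rainbow", vmin=vmin, vmax=vmax if vmax > vmin else vmin + 1,
                    s=18, edgecolors="none")
    ax.axhline(-math.log10(0.05), linestyle=":", color="grey", linewidth=1)
    ax.set_xlabel("ln(ROR)")
    ax.set_ylabel("-log10(p)")
    fig.colorbar(sc, ax=ax, label="log10(reports)")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
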