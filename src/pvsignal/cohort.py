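"""Build the analysis table from linked DEMO/DRUG/REAC tables.

The unit of analysis is the (case, suspected drug, adverse event) triple:
spontaneous-report "records" are finer than cases because one report can name
several suspected drugs and several reactions.  The stages run in a fixed
order: keep suspected drugs only, drop exact duplicate DRUG/REAC rows, join
the three tables on the case identifier, convert banded demographics
(decade age bands to midpoints, "X0 kg range" weights to X0+5), compute BMI,
exclude rows with BMI < 10 or > 100 (rows with missing BMI are retained and
drop out only of analyses that require BMI), and flag the target adverse-event
class (default: any preferred term containing "fracture", case-insensitive).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Tuple

import numpy as np
import pandas as pd

from .errors import UndefinedComparisonError  # noqa: F401  (re-export convenience)

logger = logging.getLogger(__name__)

__all__ = [
    "CohortReport", "filter_suspected", "deduplicate",
    "convert_age_band", "convert_weight_band", "compute_bmi",
    "apply_bmi_filter", "flag_target_events", "build_analysis_table",
]

_AGE_BAND_RE = re.compile(r"^\s*(\d+)0\s*s\s*$", re.IGNORECASE)
_UNDER_10_RE = re.compile(r"^\s*under\s*10\s*$", re.IGNORECASE)
_WEIGHT_BAND_RE = re.compile(r"^\s*(\d+)0\s*kg\s*range\s*$", re.IGNORECASE)


@dataclass
class CohortReport:
    """Counts for every box of the cohort-construction flowchart."""

    n_demo_rows: int = 0
    n_drug_rows: int = 0
    n_reac_rows: int = 0
    n_suspected_rows: int = 0
    n_drug_after_dedup: int = 0
    n_reac_after_dedup: int = 0
    n_joined_rows: int = 0
    n_unmatched_case_rows: int = 0
    n_bmi_low_excluded: int = 0
    n_bmi_high_excluded: int = 0
    n_final: int = 0
    n_target_event_rows: int = 0
    extra: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [f"{k}\t{v}" for k, v in asdict(self).items() if k != "extra"]
        return "\n".join(lines) + "\n"

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_text())
        return path


def filter_suspected(drug_table: pd.DataFrame) -> pd.DataFrame:
    """Keep only rows whose involvement category is ``suspected``."""
    return drug_table[drug_table["involvement"] == "suspected"].reset_index(drop=True)


def deduplicate(
    drug_table: pd.DataFrame,
    reac_table: pd.DataFrame,
    drug_keys: Tuple[str, ...] = ("case_id", "drug_name", "involvement"),
    reac_keys: Tuple[str, ...] = ("case_id", "preferred_term"),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop exact duplicate rows within DRUG and within REAC; first kept.

    The key columns are pluggable; the default is the minimal exact-row
    strategy (no cross-report fuzzy matching).
    """
    drug_out = drug_table.drop_duplicates(subset=list(drug_keys)).reset_index(drop=True)
    reac_out = reac_table.drop_duplicates(subset=list(reac_keys)).reset_index(drop=True)
    return drug_out, reac_out


def convert_age_band(value) -> float:
    """Decade band midpoint: ``"60s"`` -> 65, ``"under 10"`` -> 5.

    Plain numerics pass through; anything unparseable becomes missing with a
    logged warning (lenient by contract).
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value)
    if _UNDER_10_RE.match(s):
        return 5.0
    m = _AGE_BAND_RE.match(s)
    if m:
        return float(m.group(1)) * 10.0 + 5.0
    try:
        return float(s)
    except ValueError:
        logger.warning("unparseable age band %r; set to missing", value)
        return np.nan


def convert_weight_band(value) -> float:
    """``"60 kg range"`` -> 65; numerics pass through; else missing + warning."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value)
    m = _WEIGHT_BAND_RE.match(s)
    if m:
        return float(m.group(1)) * 10.0 + 5.0
    try:
        return float(s)
    except ValueError:
        logger.warning("unparseable weight %r; set to missing", value)
        return np.nan


def compute_bmi(height_cm, weight_kg):
    """BMI in kg/m**2; inputs must be positive (missing propagates)."""
    height_cm = np.asarray(height_cm, dtype=float)
    weight_kg = np.asarray(weight_kg, dtype=float)
    bad = (np.nan_to_num(height_cm, nan=1.0) <= 0) | (np.nan_to_num(weight_kg, nan=1.0) <= 0)
    if np.any(bad):
        raise ValueError("height and weight must be positive to compute BMI")
    out = weight_kg / (height_cm / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def apply_bmi_filter(
    rows: pd.DataFrame, bounds: Tuple[float, float] = (10.0, 100.0)
) -> Tuple[pd.DataFrame, int, int]:
    """Remove rows with BMI strictly below/above the bounds; missing BMI kept."""
    lo, hi = bounds
    bmi = rows["bmi"]
    low_mask = bmi.notna() & (bmi < lo)
    high_mask = bmi.notna() & (bmi > hi)
    kept = rows[~(low_mask | high_mask)].reset_index(drop=True)
    return kept, int(low_mask.sum()), int(high_mask.sum())


def flag_target_events(rows: pd.DataFrame, term_rule="fracture") -> pd.DataFrame:
    """Set ``is_target_event`` from the preferred term.

    ``term_rule`` is either a case-insensitive substring (default
    ``"fracture"``) or an explicit iterable of terms matched exactly.
    """
    rows = rows.copy()
    if isinstance(term_rule, str):
        rows["is_target_event"] = (
            rows["preferred_term"].str.contains(term_rule, case=False, regex=False)
            .fillna(False).astype(bool))
    else:
        allow = set(term_rule)
        rows["is_target_event"] = rows["preferred_term"].isin(allow)
    return rows


def build_analysis_table(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    term_rule="fracture",
    bmi_bounds: Tuple[float, float] = (10.0, 100.0),
    dedup: bool = True,
) -> Tuple[pd.DataFrame, CohortReport]:
    """Run every cohort stage in order and return (analysis rows, report)."""
    report = CohortReport(
        n_demo_rows=len(demo), n_drug_rows=len(drug), n_reac_rows=len(reac))

    drug_s = filter_suspected(drug)
    report.n_suspected_rows = len(drug_s)

    if dedup:
        drug_s, reac_d = deduplicate(drug_s, reac)
    else:
        reac_d = reac
    report.n_drug_after_dedup = len(drug_s)
    report.n_reac_after_dedup = len(reac_d)

    joined = drug_s.merge(reac_d, on="case_id", how="inner")
    n_before_demo = len(joined)
    joined = joined.merge(
        demo[["case_id", "sex", "age_band", "height_cm", "weight_kg"]],
        on="case_id", how="inner")
    report.n_unmatched_case_rows = n_before_demo - len(joined)
    if report.n_unmatched_case_rows:
        logger.warning("%d joined rows dropped: case_id absent from DEMO",
                       report.n_unmatched_case_rows)
    report.n_joined_rows = len(joined)
    if not len(joined):
        logger.warning("join produced zero analysis rows")

    joined["age_years"] = joined["age_band"].map(convert_age_band).astype(float)
    joined["weight_kg"] = joined["weight_kg"].map(convert_weight_band).astype(float)
    joined["height_cm"] = pd.to_numeric(joined["height_cm"], errors="coerce")
    both = joined["height_cm"].notna() & joined["weight_kg"].notna()
    bmi = np.full(len(joined), np.nan)
    if both.any():
        bmi[both.to_numpy()] = compute_bmi(
            joined.loc[both, "height_cm"], joined.loc[both, "weight_kg"])
    joined["bmi"] = bmi

    joined, n_low, n_high = apply_bmi_filter(joined, bmi_bounds)
    report.n_bmi_low_excluded = n_low
    report.n_bmi_high_excluded = n_high
    report.n_final = len(joined)

    joined = flag_target_events(joined, term_rule)
    report.n_target_event_rows = int(joined["is_target_event"].sum())

    columns = ["case_id", "drug_name", "preferred_term", "sex", "age_years",
               "height_cm", "weight_kg", "bmi", "is_target_event"]
    extras = [c for c in ("atc_code", "outcome") if c in joined.columns]
    return joined[columns + extras], report
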