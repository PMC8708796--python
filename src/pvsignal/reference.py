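"""Bundled reference data.

``fracture_terms`` is the published frequency tabulation of the 58 preferred
terms reported as drug-induced fractures in the Japanese spontaneous-report
database (2004-2020 extract): term, report count, and the printed reporting
ratio as a percentage of all fracture reports.  It serves as the default
explicit term list for exact target-class flagging and as a fixture for
count/ratio consistency checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_fracture_terms", "fracture_term_list"]


def load_fracture_terms() -> pd.DataFrame:
    """The reference fracture-term table (preferred_term, reporting_times,
    reporting_ratio_pct).  ``reporting_ratio_pct`` is a string column because
    ratios under 0.05% are printed as ``"<0.1"``."""
    with resources.files("pvsignal.data").joinpath("fracture_terms.csv").open("rb") as fh:
        return pd.read_csv(fh, dtype={"preferred_term": str,
                                      "reporting_times": int,
                                      "reporting_ratio_pct": str})


def fracture_term_list() -> tuple:
    """The 58 reference preferred terms, as an explicit allow-list."""
    return tuple(load_fracture_terms()["preferred_term"])
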