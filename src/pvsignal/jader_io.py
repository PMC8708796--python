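"""Read/write the three-table spontaneous-report layout (DEMO/DRUG/REAC).

The logical schemas are fixed; the physical dialect (delimiter, encoding,
missing-value tokens, involvement-category labels) is configurable because
real exports of the Japanese spontaneous-report database are Shift-JIS
encoded and use Japanese category labels, while synthetic fixtures are plain
UTF-8.  The reader never silently coerces: every value it drops or alters is
logged with its row index, and structural problems raise :class:`SchemaError`.

Canonical in-memory form: ``pandas.DataFrame`` with string columns as
``object`` dtype, missing values as ``NaN``; ``height_cm`` is float;
``weight_kg`` is float when fully numeric, otherwise ``object`` so banded
encodings like ``"60 kg range"`` survive for the cohort stage to convert.
"""

from __future__ import annotations

import io
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EncodingError, SchemaError

logger = logging.getLogger(__name__)

#: required columns per logical schema
SCHEMAS: Mapping[str, Sequence[str]] = {
    "DEMO": ("case_id", "sex", "age_band", "height_cm", "weight_kg"),
    "DRUG": ("case_id", "drug_name", "involvement", "atc_code"),
    "REAC": ("case_id", "preferred_term", "outcome"),
}

SEX_VALUES = ("male", "female")

#: shipped involvement-label lookup; callers may supply their own for other
#: export dialects.  Includes the Japanese category labels of the source
#: database alongside the English enums.
DEFAULT_INVOLVEMENT_MAP: Mapping[str, str] = {
    "suspected": "suspected",
    "concomitant": "concomitant",
    "interaction": "interaction",
    "被疑薬": "suspected",
    "併用薬": "concomitant",
    "相互作用": "interaction",
}


def _decode(path: Path, encoding: str) -> str:
    raw = path.read_bytes()
    try:
        return raw.decode(encoding)
    except UnicodeDecodeError as exc:
        raise EncodingError(
            f"{path}: undecodable byte under encoding {encoding!r} "
            f"at byte offset {exc.start}") from exc


def read_table(
    path,
    schema_name: str,
    *,
    encoding: str = "utf-8",
    delimiter: str = ",",
    missing_tokens: Sequence[str] = ("",),
    involvement_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read one table and validate it against its logical schema.

    Unknown columns are preserved (and ignored downstream).  Empty strings
    and any additional ``missing_tokens`` map to missing.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    text = _decode(path, encoding)
    df = pd.read_csv(io.StringIO(text), sep=delimiter, dtype=str, keep_default_na=False)
    required = SCHEMAS[schema_name]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing_cols} "
                          f"for schema {schema_name}")
    df = df.apply(lambda s: s.mask(s.isin(list(missing_tokens))))

    if schema_name == "DEMO":
        _check_unique(df, "case_id", path)
        df["height_cm"] = _to_numeric_logged(df["height_cm"], "height_cm")
        df["weight_kg"] = _parse_weight(df["weight_kg"])
        bad_sex = df["sex"].notna() & ~df["sex"].isin(SEX_VALUES)
        for i in df.index[bad_sex]:
            logger.warning("row %d: sex value %r outside vocabulary; set to missing",
                           i, df.at[i, "sex"])
        df.loc[bad_sex, "sex"] = np.nan
    elif schema_name == "DRUG":
        lookup = dict(DEFAULT_INVOLVEMENT_MAP if involvement_map is None else involvement_map)
        mapped = df["involvement"].map(lookup)
        bad = df["involvement"].notna() & mapped.isna()
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(
                f"{path}: involvement value {df.at[row, 'involvement']!r} at row {row} "
                f"is outside the vocabulary {sorted(set(lookup.values()))}")
        if df["involvement"].isna().any():
            row = int(df.index[df["involvement"].isna()][0])
            raise SchemaError(f"{path}: missing involvement category at row {row}")
        df["involvement"] = mapped
    elif schema_name == "REAC":
        bad = df["preferred_term"].isna()
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(f"{path}: empty preferred_term at row {row}")
    return df


def _check_unique(df: pd.DataFrame, column: str, path: Path) -> None:
    dup = df[column][df[column].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate {column} value {dup.iloc[0]!r}")


def _to_numeric_logged(series: pd.Series, name: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = series.notna() & out.isna()
    for i in series.index[bad]:
        logger.warning("row %d: %s value %r is not numeric; set to missing",
                       i, name, series[i])
    neg = out.notna() & (out < 0)
    for i in series.index[neg]:
        logger.warning("row %d: %s value %r is negative; set to missing",
                       i, name, series[i])
    out[neg] = np.nan
    return out.astype(float)


def _parse_weight(series: pd.Series) -> pd.Series:
    """Weight column: float when fully numeric, else object keeping band strings."""
    numeric = pd.to_numeric(series, errors="coerce")
    non_numeric = series.notna() & numeric.isna()
    if not non_numeric.any():
        neg = numeric.notna() & (numeric < 0)
        for i in series.index[neg]:
            logger.warning("row %d: weight_kg value %r is negative; set to missing",
                           i, series[i])
        numeric[neg] = np.nan
        return numeric.astype(float)
    out = series.copy().astype(object)
    ok_num = numeric.notna()
    out[ok_num] = numeric[ok_num]
    return out


def write_table(
    table: pd.DataFrame,
    path,
    schema_name: str,
    *,
    encoding: str = "utf-8",
    delimiter: str = ",",
) -> Path:
    """Write a schema-valid table; ``read_table(write_table(t)) == t``."""
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}; expected one of {sorted(SCHEMAS)}")
    missing_cols = [c for c in SCHEMAS[schema_name] if c not in table.columns]
    if missing_cols:
        raise SchemaError(f"cannot write {schema_name}: missing column(s) {missing_cols}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=delimiter, index=False, encoding=encoding, na_rep="")
    return path
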