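"""Reading FAERS-style quarterly tables and building the integrated table.

FAERS ships as $-delimited ASCII files with a header row.  Four tables are
used here: DRUG (one row per case x reported drug), REAC (one row per case x
MedDRA preferred term), DEMO (one row per case) and THER (therapy dates).
The analysis table is the inner join of DRUG and REAC on the case
identifier, deduplicated on the (case, drug, preferred term) triple and —
for unambiguous attribution — restricted to monotherapy cases.

All tables are carried as :class:`pandas.DataFrame` with canonical column
names (``case_id``, ``drug_name``, ``pt``, ...).  Drug names and preferred
terms are normalized to uppercase with collapsed internal whitespace so that
they can serve as case-insensitive join keys.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")

#: age in years considered plausible after unit conversion
AGE_RANGE = (0.0, 130.0)

#: multiplier from FAERS age_cod unit to years
AGE_UNIT_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

# raw FAERS column -> canonical column, per table kind
_SCHEMAS: dict[str, dict[str, dict[str, str]]] = {
    "drug": {
        "required": {"primaryid": "case_id", "drugname": "drug_name"},
        "optional": {"role_cod": "role_code", "route": "route",
                     "caseversion": "caseversion"},
    },
    "reac": {
        "required": {"primaryid": "case_id", "pt": "pt"},
        "optional": {},
    },
    "demo": {
        "required": {"primaryid": "case_id", "sex": "sex"},
        "optional": {"age": "age", "age_cod": "age_cod"},
    },
    "ther": {
        "required": {"primaryid": "case_id", "drugname": "drug_name"},
        "optional": {"start_dt": "start_date"},
    },
}


def normalize_name(name: str) -> str:
    """Uppercase, trim and collapse internal whitespace of a name key."""
    return _WS.sub(" ", str(name).strip()).upper()


def _normalize_series(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.replace(_WS, " ", regex=True).str.upper()


def read_table(path: str | Path, kind: str, dialect: str = "$") -> pd.DataFrame:
    """Read one FAERS-style table into a canonical DataFrame.

    Parameters
    ----------
    path : str or Path
        File with a header row; ``$``-delimited by default.
    kind : {"drug", "reac", "demo", "ther"}
        Which table schema to apply.
    dialect : str
        Field delimiter; pass ``","`` for CSV exports.

    Returns
    -------
    pandas.DataFrame
        Canonical columns for the kind.  Lines whose mandatory fields are
        empty are dropped, counted in ``df.attrs["n_skipped"]`` and logged,
        never fatal.  For DEMO, ages are converted to years using
        ``age_cod`` and values outside the plausible range are set to NaN
        and counted in ``df.attrs["n_invalid_age"]``.

    Raises
    ------
    ValueError
        If ``kind`` is unknown or a mandatory column is missing (the error
        names the column).
    OSError
        If the file cannot be read.
    """
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of "
                         f"{sorted(_SCHEMAS)}")
    schema = _SCHEMAS[kind]
    path = Path(path)
    df = pd.read_csv(path, sep=dialect, dtype=str, keep_default_na=False,
                     engine="python", on_bad_lines="warn")
    df.columns = [c.strip().lower() for c in df.columns]

    for raw in schema["required"]:
        if raw not in df.columns:
            raise ValueError(
                f"{path.name}: mandatory column {raw!r} missing for "
                f"table kind {kind!r}")

    keep = {raw: canon for raw, canon in
            {**schema["required"], **schema["optional"]}.items()
            if raw in df.columns}
    df = df[list(keep)].rename(columns=keep)

    n_before = len(df)
    for canon in schema["required"].values():
        df = df[df[canon].astype(str).str.strip() != ""]
    n_skipped = n_before - len(df)
    if n_skipped:
        logger.warning("%s: skipped %d line(s) with empty mandatory fields",
                       path.name, n_skipped)
    df = df.copy()

    df["case_id"] = df["case_id"].astype(str).str.strip()
    if "drug_name" in df.columns:
        df["drug_name"] = _normalize_series(df["drug_name"])
    if "pt" in df.columns:
        df["pt"] = _normalize_series(df["pt"])
    n_invalid_age = 0
    if kind == "demo":
        df["sex"] = df["sex"].astype(str).str.strip().str.upper()
        df.loc[~df["sex"].isin(["F", "M"]), "sex"] = "unknown"
        if "age" in df.columns:
            age = pd.to_numeric(df["age"], errors="coerce")
            unit = (df["age_cod"].astype(str).str.strip().str.upper()
                    if "age_cod" in df.columns
                    else pd.Series("YR", index=df.index))
            unit = unit.replace("", "YR")
            factor = unit.map(AGE_UNIT_YEARS)
            age_years = age * factor
            bad = age_years.notna() & ~age_years.between(*AGE_RANGE)
            bad |= age.notna() & factor.isna()
            n_invalid_age = int(bad.sum())
            age_years[bad] = np.nan
            df["age_years"] = age_years
            if n_invalid_age:
                logger.warning("%s: %d age value(s) out of range or with "
                               "unknown unit, set to missing",
                               path.name, n_invalid_age)

    df = df.reset_index(drop=True)
    df.attrs["n_skipped"] = n_skipped
    df.attrs["n_invalid_age"] = n_invalid_age
    return df


def integrate(drugs: pd.DataFrame, reacs: pd.DataFrame) -> pd.DataFrame:
    """Inner-join DRUG and REAC on the case identifier.

    Each output row is one (case_id, drug_name, pt) combination — the cross
    product of a case's drugs and its preferred terms.  If a ``caseversion``
    column is present, only the highest version per case contributes.
    """
    if drugs.empty or reacs.empty:
        raise ValueError("integrate() requires nonempty DRUG and REAC tables")
    d = drugs
    if "caseversion" in d.columns:
        ver = pd.to_numeric(d["caseversion"], errors="coerce").fillna(0)
        top = ver.groupby(d["case_id"]).transform("max")
        d = d[ver == top]
    rows = d[["case_id", "drug_name"]].merge(
        reacs[["case_id", "pt"]], on="case_id", how="inner")
    if rows.empty:
        logger.warning("integrate(): DRUG and REAC share no case_id; "
                       "result is empty")
    return rows.reset_index(drop=True)


def deduplicate(rows: pd.DataFrame) -> pd.DataFrame:
    """Drop duplicate (case_id, drug_name, pt) triples, keeping the first.

    Order-stable and idempotent.
    """
    return rows.drop_duplicates(
        subset=["case_id", "drug_name", "pt"], keep="first"
    ).reset_index(drop=True)


def monotherapy_filter(rows: pd.DataFrame) -> pd.DataFrame:
    """Keep only rows from cases reporting exactly one distinct drug.

    Combination-therapy cases cannot attribute an event to a single drug and
    are excluded wholesale; the preferred-term multiset of retained cases is
    untouched.
    """
    n_drugs = rows.groupby("case_id")["drug_name"].transform("nunique")
    return rows[n_drugs == 1].reset_index(drop=True)


def write_integrated(rows: pd.DataFrame, path: str | Path) -> None:
    """Write the integrated table as CSV (case_id, drug_name, pt)."""
    rows[["case_id", "drug_name", "pt"]].to_csv(path, index=False)
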