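"""Tab-separated readers/writers for cohort, pair and FH tables.

Missing values are written as empty strings; identifier columns are always
strings. Pedigree links are additionally exportable in PED-like format
(family, id, father, mother, sex, phenotype).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

__all__ = [
    "write_table",
    "read_cohort",
    "read_pairs",
    "read_fh",
    "write_ped",
]

_ID_COLS = ("id", "family_id", "father_id", "mother_id", "individual_id",
            "index_id", "relative_id", "sex", "death_causes", "disease_id",
            "degree", "relationship", "stratum", "prs_group", "fh")


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write any pipeline table as TSV (missing values as empty strings)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def _read_tsv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    for col in df.columns:
        if col in _ID_COLS:
            continue
        converted = pd.to_numeric(df[col].replace("", None), errors="coerce")
        # only adopt the numeric view when nothing non-empty was lost
        nonempty = df[col] != ""
        if converted.notna().to_numpy()[nonempty.to_numpy()].all():
            df[col] = converted
    return df


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort TSV, restoring numeric and integer-with-missing columns."""
    df = _read_tsv(path)
    if "death_year" in df.columns:
        df["death_year"] = df["death_year"].astype("Int64")
    for col in df.columns:
        if col.endswith("_status") or col in ("birth_year", "generation"):
            df[col] = df[col].astype(int)
    return df


def read_pairs(path: Union[str, Path]) -> pd.DataFrame:
    return _read_tsv(path)


def read_fh(path: Union[str, Path]) -> pd.DataFrame:
    df = _read_tsv(path)
    if "fhp_age_tertile" in df.columns:
        df["fhp_age_tertile"] = df["fhp_age_tertile"].astype("Int64")
    if "fhp_eligible" in df.columns:
        df["fhp_eligible"] = df["fhp_eligible"].map(
            {"True": True, "False": False, True: True, False: False}
        ).astype(bool)
    for col in ("fh1_analysis_set", "fh2_analysis_set"):
        if col in df.columns:
            df[col] = df[col].map(
                {"True": True, "False": False, True: True, False: False}
            ).astype(bool)
    return df


def write_ped(
    cohort: pd.DataFrame, path: Union[str, Path], phenotype_disease: Optional[str] = None
) -> None:
    """Export pedigree links in PED-like format.

    Columns: family, id, father (0 if unknown), mother, sex (1 male /
    2 female), phenotype (2 affected / 1 unaffected for the given disease,
    0 if no disease given).
    """
    ped = pd.DataFrame({
        "family": cohort["family_id"],
        "id": cohort["id"],
        "father": cohort["father_id"].replace("", "0"),
        "mother": cohort["mother_id"].replace("", "0"),
        "sex": cohort["sex"].map({"male": 1, "female": 2}),
    })
    if phenotype_disease is not None:
        ped["phenotype"] = cohort[f"{phenotype_disease}_status"].astype(int) + 1
    else:
        ped["phenotype"] = 0
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ped.to_csv(path, sep="\t", index=False, header=False)
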