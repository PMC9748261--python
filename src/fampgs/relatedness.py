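"""Relative-pair classification and family-history derivation.

Three binary family-history (FH) exposures are derived per disease:

* ``fh1`` — any first-degree relative in the cohort affected (diagnosis
  within the relevant registry window, or the disease among recorded
  causes of death): morbidity or mortality.
* ``fh2`` — the same for second-degree relatives only; first-degree
  relatives never contribute to ``fh2``.
* ``fhp`` — the disease listed among any cause (immediate, contributing
  or underlying) on an observable parental death record. Individuals
  whose parents both died before the death registry opened, or with
  missing data on both parents, are ineligible and excluded from
  ``fhp`` analyses. Among fhp-positive individuals, parental age at
  death is split into tertiles per disease.

Degree classification follows the standard KING kinship conventions:
first degree for kinship in (0.177, 0.354], second degree in
(0.0884, 0.177] — half-open below, closed above, so boundary values go
to the more distant class's upper bound.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd

from .config import ConfigError, DiseaseModelConfig, RegistryWindows

__all__ = [
    "classify_relationship",
    "derive_fh1",
    "derive_fh2",
    "derive_fhp",
    "derive_fh_table",
]

_FIRST = (0.177, 0.354)
_SECOND = (0.0884, 0.177)


def classify_relationship(kinship: Union[float, np.ndarray]) -> Union[str, np.ndarray]:
    """Map kinship coefficients to relatedness degree.

    Returns ``'first'``, ``'second'`` or ``'other'``; accepts scalars or
    arrays. Kinship outside [0, 0.5] raises.
    """
    arr = np.asarray(kinship, dtype=float)
    if np.any((arr < 0.0) | (arr > 0.5)):
        raise ValueError("kinship coefficients must lie in [0, 0.5]")
    out = np.where(
        (arr > _FIRST[0]) & (arr <= _FIRST[1]),
        "first",
        np.where((arr > _SECOND[0]) & (arr <= _SECOND[1]), "second", "other"),
    )
    if np.isscalar(kinship) or arr.ndim == 0:
        return str(out)
    return out.astype(object)


# ---------------------------------------------------------------------------
# affection status of relatives, subject to registry windows
# ---------------------------------------------------------------------------


def _require_disease(cohort: pd.DataFrame, disease: DiseaseModelConfig) -> None:
    col = f"{disease.disease_id}_status"
    if col not in cohort.columns:
        raise KeyError(f"cohort has no column {col!r}; disease not simulated/supplied")


def _affected_observable(
    cohort: pd.DataFrame, disease: DiseaseModelConfig, registry: RegistryWindows
) -> pd.Series:
    """A relative counts as affected if diagnosed inside the diagnosis
    registry window (cancer registry from its earlier start) or if the
    disease appears among observable death-record causes."""
    p = disease.disease_id
    status = cohort[f"{p}_status"].astype(int) == 1
    onset = pd.to_numeric(cohort[f"{p}_onset_age"], errors="coerce")
    diag_year = cohort["birth_year"] + onset
    start = registry.diagnosis_start(disease)
    diagnosed = status & diag_year.ge(start) & diag_year.le(registry.followup_end)

    if "death_record_observable" in cohort.columns:
        observable = cohort["death_record_observable"].astype(bool)
    else:
        dy = pd.to_numeric(cohort["death_year"], errors="coerce")
        observable = (
            dy.ge(registry.death_registry_start) & dy.le(registry.death_registry_end)
        ).fillna(False)
    causes = cohort["death_causes"].fillna("").astype(str)
    cause_listed = causes.str.split(";").apply(lambda cs: p in cs)
    died_of = observable & cause_listed

    return (diagnosed | died_of).fillna(False)


def _sex_restrict(cohort: pd.DataFrame, disease: DiseaseModelConfig) -> pd.DataFrame:
    if disease.sex_restriction is None:
        return cohort
    return cohort[cohort["sex"] == disease.sex_restriction]


def _derive_fh_degree(
    cohort: pd.DataFrame,
    pairs: pd.DataFrame,
    disease: DiseaseModelConfig,
    registry: RegistryWindows,
    degree: str,
    colname: str,
) -> pd.DataFrame:
    _require_disease(cohort, disease)
    eligible = _sex_restrict(cohort, disease)
    affected = _affected_observable(cohort, disease, registry)
    aff_map = pd.Series(affected.to_numpy(), index=cohort["id"].to_numpy())

    sub = pairs[pairs["degree"] == degree]
    # sex-restricted diseases count only relatives of the relevant sex
    keep_ids = set(eligible["id"])
    sub = sub[sub["index_id"].isin(keep_ids) & sub["relative_id"].isin(keep_ids)]

    rel_aff = aff_map.reindex(sub["relative_id"].to_numpy()).to_numpy(dtype=float)
    agg = (
        pd.DataFrame({"index_id": sub["index_id"].to_numpy(), "aff": rel_aff})
        .groupby("index_id")["aff"]
        .agg(["max", "size"])
    )

    out = pd.DataFrame({"individual_id": eligible["id"].to_numpy()})
    out["disease_id"] = disease.disease_id
    out[colname] = (
        agg["max"].reindex(out["individual_id"]).fillna(0).astype(int).to_numpy()
    )
    n_rel = agg["size"].reindex(out["individual_id"]).fillna(0).astype(int).to_numpy()
    out[f"n_{degree}_degree_relatives"] = n_rel
    # FH from relatives present in the cohort only: no relatives observed
    # means fh stays 0 but the row is flagged low-information and left out
    # of the regression analysis set
    out["in_analysis_set"] = n_rel > 0
    return out


def derive_fh1(
    cohort: pd.DataFrame,
    pairs: pd.DataFrame,
    disease: DiseaseModelConfig,
    registry: Optional[RegistryWindows] = None,
) -> pd.DataFrame:
    """First-degree family history (morbidity or mortality) per individual."""
    return _derive_fh_degree(cohort, pairs, disease, registry or RegistryWindows(),
                             "first", "fh1")


def derive_fh2(
    cohort: pd.DataFrame,
    pairs: pd.DataFrame,
    disease: DiseaseModelConfig,
    registry: Optional[RegistryWindows] = None,
) -> pd.DataFrame:
    """Second-degree family history; first-degree relatives do not contribute."""
    return _derive_fh_degree(cohort, pairs, disease, registry or RegistryWindows(),
                             "second", "fh2")


# ---------------------------------------------------------------------------
# parental cause of death
# ---------------------------------------------------------------------------


def derive_fhp(
    cohort: pd.DataFrame,
    disease: DiseaseModelConfig,
    registry: Optional[RegistryWindows] = None,
) -> pd.DataFrame:
    """Parental-cause-of-death family history with eligibility and age tertiles.

    Ineligible (excluded) individuals are exactly those whose parents both
    died before the death-registry start or who have missing data on both
    parents. A parent dying after the parental-cause cutoff leaves the
    record cause-unobservable but does not make the index ineligible.
    Among fhp-positive individuals the (youngest) cause-positive parent's
    age at death is split into per-disease tertiles, boundary ties going
    to the lower tertile.
    """
    registry = registry or RegistryWindows()
    _require_disease(cohort, disease)
    p = disease.disease_id

    parent_cols = ["id", "death_year", "death_age", "death_causes"]
    parents = cohort[parent_cols].copy()
    parents["death_year"] = pd.to_numeric(parents["death_year"], errors="coerce")
    parents["cause_pos"] = (
        parents["death_causes"].fillna("").astype(str).str.split(";").apply(lambda cs: p in cs)
    )

    eligible_rows = _sex_restrict(cohort, disease)
    base = eligible_rows[["id", "father_id", "mother_id"]].copy()
    for side in ("father", "mother"):
        merged = base.merge(
            parents.add_prefix(f"{side[0]}_"),
            left_on=f"{side}_id",
            right_on=f"{side[0]}_id",
            how="left",
        )
        base = merged.drop(columns=[f"{side[0]}_id"])

    def side_flags(prefix: str, id_col: str):
        missing = base[id_col].fillna("").astype(str) == ""
        dy = base[f"{prefix}_death_year"]
        died_pre = dy.notna() & (dy < registry.death_registry_start)
        observable = dy.notna() & dy.ge(registry.death_registry_start) & dy.le(registry.death_registry_end)
        pos = observable & base[f"{prefix}_cause_pos"].eq(True)
        uninformative = missing | died_pre
        return uninformative, pos

    f_unin, f_pos = side_flags("f", "father_id")
    m_unin, m_pos = side_flags("m", "mother_id")
    eligible = ~(f_unin & m_unin)
    fhp = (f_pos | m_pos).astype(int)

    # parental age at death for fhp-positive rows: youngest cause-positive parent
    f_age = base["f_death_age"].where(f_pos)
    m_age = base["m_death_age"].where(m_pos)
    death_age = pd.concat([f_age, m_age], axis=1).min(axis=1)

    out = pd.DataFrame({
        "individual_id": base["id"].to_numpy(),
        "disease_id": p,
        "fhp_eligible": eligible.to_numpy(),
        "fhp": np.where(eligible, fhp, np.nan),
        "fhp_parent_death_age": np.where(eligible & (fhp == 1), death_age, np.nan),
    })

    pos_ages = out.loc[out["fhp"] == 1.0, "fhp_parent_death_age"].dropna()
    tert = np.full(len(out), np.nan)
    if len(pos_ages) >= 3:
        q1, q2 = np.quantile(pos_ages, [1.0 / 3.0, 2.0 / 3.0])
        ages = out["fhp_parent_death_age"].to_numpy()
        with np.errstate(invalid="ignore"):
            t = 1 + (ages > q1).astype(int) + (ages > q2).astype(int)
        mask = (out["fhp"] == 1.0) & ~np.isnan(ages)
        tert[mask.to_numpy()] = t[mask.to_numpy()]
    out["fhp_age_tertile"] = pd.array(tert, dtype="Int64")
    return out


def derive_fh_table(
    cohort: pd.DataFrame,
    pairs: pd.DataFrame,
    diseases,
    registry: Optional[RegistryWindows] = None,
) -> pd.DataFrame:
    """All three FH exposures for every disease, long-format keyed by
    (individual_id, disease_id)."""
    registry = registry or RegistryWindows()
    blocks = []
    for dz in diseases:
        f1 = derive_fh1(cohort, pairs, dz, registry)
        f2 = derive_fh2(cohort, pairs, dz, registry)
        fp = derive_fhp(cohort, dz, registry)
        block = f1.rename(columns={"in_analysis_set": "fh1_analysis_set"}).merge(
            f2.drop(columns=["disease_id"]).rename(columns={"in_analysis_set": "fh2_analysis_set"}),
            on="individual_id", how="outer",
        ).merge(fp.drop(columns=["disease_id"]), on="individual_id", how="outer")
        block["disease_id"] = dz.disease_id
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)
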