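import numpy as np
import pandas as pd
import pytest

from fampgs import (
    DiseaseModelConfig,
    SimulationPlan,
    derive_fh_table,
    record_parental_deaths,
    simulate_cohort,
)

pytest_plugins = ()


def make_cohort(people, disease_ids=("d",)):
    """Hand-built minimal cohort table for toy pedigree tests.

    ``people`` is a list of dicts; unspecified fields get neutral defaults
    (male, born 1950, alive, unaffected).
    """
    rows = []
    for p in people:
        row = {
            "id": p["id"],
            "family_id": p.get("family_id", "FAM"),
            "father_id": p.get("father_id", ""),
            "mother_id": p.get("mother_id", ""),
            "sex": p.get("sex", "male"),
            "generation": p.get("generation", 0),
            "birth_year": p.get("birth_year", 1950),
            "death_year": p.get("death_year", pd.NA),
            "death_age": p.get("death_age", np.nan),
            "death_causes": p.get("death_causes", ""),
        }
        for dz in disease_ids:
            row[f"{dz}_status"] = p.get(f"{dz}_status", 0)
            row[f"{dz}_onset_age"] = p.get(f"{dz}_onset_age", np.nan)
            row[f"{dz}_PRS"] = p.get(f"{dz}_PRS", 0.0)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["death_year"] = df["death_year"].astype("Int64")
    return df


@pytest.fixture(scope="session")
def cad_config():
    """A coronary-artery-disease-like generative model."""
    return DiseaseModelConfig("cad", K=0.10, h2=0.5, rho2=0.3, c2=0.05)


@pytest.fixture(scope="session")
def demo_data(cad_config):
    """Moderate cohort shared by unit tests: 1,500 families, two diseases."""
    breast = DiseaseModelConfig(
        "breast_cancer", K=0.08, h2=0.35, rho2=0.15, c2=0.0,
        registry_kind="cancer", sex_restriction="female",
    )
    plan = SimulationPlan(n_families=1500, seed=7, diseases=(cad_config, breast))
    cohort, pairs = simulate_cohort(plan)
    cohort = record_parental_deaths(cohort, plan.registry)
    fh = derive_fh_table(cohort, pairs, plan.diseases, plan.registry)
    return plan, cohort, pairs, fh


@pytest.fixture(scope="session")
def big_data(cad_config):
    """Large cohort for Monte-Carlo checks: >= 1e5 pairs per degree."""
    plan = SimulationPlan(n_families=20000, seed=20250930 % 2**31, diseases=(cad_config,))
    cohort, pairs = simulate_cohort(plan)
    return plan, cohort, pairs
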