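"""Family-structured liability-threshold cohort simulator.

Generates multi-generation pedigrees in which additive polygenic liability
is transmitted from parents to children (midparent average plus a
Mendelian-sampling deviation), a polygenic score (PRS) measures the scored
sub-component of that liability, full siblings share a family environment,
and disease is defined by liability exceeding the prevalence-calibrated
threshold. Death years and recorded causes of death are generated so that
registry availability windows can censor what family-history derivation
is allowed to see.

Randomness: one root seed; every draw site gets its own PCG64 stream
(seeded ``[root_seed, site_index]``) and draws a ``(n_families, k)``
row-major block, so family *i* consumes an identical slice regardless of
``n_families`` — growing the cohort never reshuffles existing families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .config import ConfigError, DiseaseModelConfig, RegistryWindows, SimulationPlan

__all__ = [
    "liability_threshold",
    "simulate_cohort",
    "build_pair_table",
    "record_parental_deaths",
]

# expected kinship coefficients by relationship
KINSHIP = {
    "parent-offspring": 0.25,
    "full-sibling": 0.25,
    "grandparent": 0.125,
    "avuncular": 0.125,
    "half-sibling": 0.125,
}


def liability_threshold(K: float) -> float:
    """Liability threshold T with standard-normal upper-tail mass ``K``.

    Disease prevalence K corresponds to P(L > T) = K for L ~ N(0, 1).
    """
    if not 0.0 < K < 1.0:
        raise ConfigError(f"prevalence K must be in (0,1), got {K}")
    return float(norm.isf(K))


# ---------------------------------------------------------------------------
# pedigree layout
# ---------------------------------------------------------------------------


@dataclass
class _Layout:
    """Fixed within-family slot structure shared by every family."""

    m: int                      # members per family
    father_slot: np.ndarray     # per slot; -1 for founders
    mother_slot: np.ndarray
    generation: np.ndarray
    sex_fixed: np.ndarray       # 0 male, 1 female, -1 random
    founder_slots: np.ndarray
    child_order: List[int]      # non-founders in topological order
    nuclear_units: List[Tuple[int, int, List[int]]]  # (father, mother, children)


def _build_layout(plan: SimulationPlan) -> _Layout:
    nps, nch = plan.n_parent_siblings, plan.n_children
    father_slot: List[int] = []
    mother_slot: List[int] = []
    generation: List[int] = []
    sex_fixed: List[int] = []

    def add(f: int, m: int, gen: int, sex: int) -> int:
        father_slot.append(f)
        mother_slot.append(m)
        generation.append(gen)
        sex_fixed.append(sex)
        return len(father_slot) - 1

    if plan.generations == 3:
        pgf = add(-1, -1, 0, 0)
        pgm = add(-1, -1, 0, 1)
        mgf = add(-1, -1, 0, 0)
        mgm = add(-1, -1, 0, 1)
        father = add(pgf, pgm, 1, 0)
        for _ in range(nps):
            add(pgf, pgm, 1, -1)
        mother = add(mgf, mgm, 1, 1)
        for _ in range(nps):
            add(mgf, mgm, 1, -1)
        for _ in range(nch):
            add(father, mother, 2, -1)
    else:  # two generations: founder couple plus children
        father = add(-1, -1, 0, 0)
        mother = add(-1, -1, 0, 1)
        for _ in range(nch):
            add(father, mother, 1, -1)

    fs = np.asarray(father_slot)
    ms = np.asarray(mother_slot)
    gen = np.asarray(generation)
    founders = np.flatnonzero(fs < 0)
    child_order = [int(i) for i in np.argsort(gen, kind="stable") if fs[i] >= 0]
    units: List[Tuple[int, int, List[int]]] = []
    seen = {}
    for s in child_order:
        key = (int(fs[s]), int(ms[s]))
        if key not in seen:
            seen[key] = len(units)
            units.append((key[0], key[1], []))
        units[seen[key]][2].append(s)
    return _Layout(
        m=len(fs),
        father_slot=fs,
        mother_slot=ms,
        generation=gen,
        sex_fixed=np.asarray(sex_fixed),
        founder_slots=founders,
        child_order=child_order,
        nuclear_units=units,
    )


class _Streams:
    """Sequential allocator of independent per-site PCG64 streams."""

    def __init__(self, seed: int) -> None:
        self._seed = int(seed)
        self._next = 0

    def rng(self) -> np.random.Generator:
        g = np.random.default_rng([self._seed, self._next])
        self._next += 1
        return g


def _transmit(
    layout: _Layout, var: float, founder_std: np.ndarray, mendel_std: np.ndarray
) -> np.ndarray:
    """Additive component with variance ``var``: founders N(0, var), children
    midparent mean plus Mendelian-sampling N(0, var/2). Shapes are
    (n_families, m); inputs are standard-normal draws."""
    n_fam = founder_std.shape[0]
    x = np.zeros((n_fam, layout.m))
    if var <= 0.0:
        return x
    x[:, layout.founder_slots] = founder_std * np.sqrt(var)
    half_sd = np.sqrt(var / 2.0)
    for j, s in enumerate(layout.child_order):
        mid = 0.5 * (x[:, layout.father_slot[s]] + x[:, layout.mother_slot[s]])
        x[:, s] = mid + mendel_std[:, j] * half_sd
    return x


def _shared_env(
    layout: _Layout, c2: float, po_share: float,
    founder_std: np.ndarray, unit_std: np.ndarray,
) -> np.ndarray:
    """Shared-family environment: full siblings share C entirely (one draw
    per nuclear unit); a child's C correlates with each parent's at
    ``po_share`` via a parental-mean component."""
    n_fam = founder_std.shape[0]
    c = np.zeros((n_fam, layout.m))
    if c2 <= 0.0:
        return c
    c[:, layout.founder_slots] = founder_std * np.sqrt(c2)
    alpha = 2.0 * po_share
    var_eps = c2 * (1.0 - 2.0 * po_share**2)
    for u, (f, mo, kids) in enumerate(layout.nuclear_units):
        shared = alpha * 0.5 * (c[:, f] + c[:, mo]) + unit_std[:, u] * np.sqrt(var_eps)
        for s in kids:
            c[:, s] = shared
    return c


def _trunc_ppf(u: np.ndarray, lo: float, hi: float, loc, scale) -> np.ndarray:
    """Inverse-CDF sampling of a truncated normal (keeps stream usage fixed)."""
    a = (lo - np.asarray(loc, dtype=float)) / scale
    b = (hi - np.asarray(loc, dtype=float)) / scale
    return truncnorm.ppf(u, a, b, loc=loc, scale=scale)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def simulate_cohort(plan: SimulationPlan) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort table and its relative-pair table.

    Returns ``(cohort, pairs)``. The cohort has one row per individual with
    pedigree links, sex, birth year, death record and, per disease ``d``,
    columns ``{d}_G, {d}_G_s, {d}_C, {d}_L, {d}_PRS, {d}_status,
    {d}_onset_age`` (plus ``{d}_PRS_small`` when a nested low-capture score
    is configured). The pair table lists every first- and second-degree
    pair in both (index, relative) directions with its expected kinship.
    """
    layout = _build_layout(plan)
    streams = _Streams(plan.seed)
    n_fam, m = plan.n_families, layout.m
    max_gen = int(layout.generation.max())

    # birth years: one stream per generation, youngest gets the plan range
    lo, hi = plan.birth_year_range
    birth = np.zeros((n_fam, m), dtype=int)
    for g in range(max_gen + 1):
        slots = np.flatnonzero(layout.generation == g)
        shift = plan.generation_gap * (max_gen - g)
        birth[:, slots] = streams.rng().integers(lo - shift, hi - shift + 1,
                                                 size=(n_fam, len(slots)))

    # sexes for random-sex slots
    sex = np.broadcast_to(layout.sex_fixed, (n_fam, m)).copy()
    rand_slots = np.flatnonzero(layout.sex_fixed < 0)
    if len(rand_slots):
        sex[:, rand_slots] = streams.rng().integers(0, 2, size=(n_fam, len(rand_slots)))

    # per-disease liability stacks
    per_disease: dict[str, dict[str, np.ndarray]] = {}
    for dz in plan.diseases:
        nf, nc, nu = len(layout.founder_slots), len(layout.child_order), len(layout.nuclear_units)
        parts = {}
        if dz.rho2_small is not None:
            comp_vars = [
                ("gs1", dz.rho2_small),
                ("gs2", dz.rho2 - dz.rho2_small),
                ("gr", dz.h2 - dz.rho2),
            ]
        else:
            comp_vars = [("gs1", dz.rho2), ("gr", dz.h2 - dz.rho2)]
        for name, var in comp_vars:
            f_std = streams.rng().standard_normal((n_fam, nf))
            m_std = streams.rng().standard_normal((n_fam, nc))
            parts[name] = _transmit(layout, var, f_std, m_std)
        c_f = streams.rng().standard_normal((n_fam, nf))
        c_u = streams.rng().standard_normal((n_fam, max(nu, 1)))
        C = _shared_env(layout, dz.c2, plan.po_env_share, c_f, c_u)
        e_var = 1.0 - dz.h2 - dz.c2
        E = streams.rng().standard_normal((n_fam, m)) * np.sqrt(max(e_var, 0.0))
        u_onset = streams.rng().random((n_fam, m))
        u_cause = streams.rng().random((n_fam, m))
        u_lag = streams.rng().random((n_fam, m)) if dz.onset_death_link else None

        G_s = parts["gs1"] + parts.get("gs2", 0.0)
        G = G_s + parts["gr"]
        L = G + C + E
        T = liability_threshold(dz.K)
        status = L > T

        # onset: truncated normal on (0, 100], optionally shifted earlier
        # for liability above the threshold
        mu = dz.onset_mean - dz.onset_liability_shift * (L - T)
        onset = np.full((n_fam, m), np.nan)
        if status.any():
            onset[status] = _trunc_ppf(u_onset[status], 0.0, 100.0,
                                       mu[status], dz.onset_sd)

        d = {"status": status, "onset": onset, "G": G, "G_s": G_s, "C": C, "L": L,
             "u_cause": u_cause}
        if dz.rho2 > 0.0:
            d["PRS"] = G_s / np.sqrt(dz.rho2)
        if dz.rho2_small is not None:
            d["PRS_small"] = parts["gs1"] / np.sqrt(dz.rho2_small)
        if dz.onset_death_link:
            lag = _trunc_ppf(u_lag, 0.0, np.inf,
                             dz.post_onset_survival_mean, dz.post_onset_survival_sd)
            d["death_cap"] = np.where(status, onset + lag, np.inf)
        per_disease[dz.disease_id] = d

    # mortality: background truncated-normal death age, optionally capped
    # at onset + post-onset survival for linked diseases
    u_death = streams.rng().random((n_fam, m))
    death_age = _trunc_ppf(u_death, 30.0, 105.0, plan.death_age_mean, plan.death_age_sd)
    for dz in plan.diseases:
        cap = per_disease[dz.disease_id].get("death_cap")
        if cap is not None:
            death_age = np.minimum(death_age, np.maximum(cap, 1.0))
    death_year = birth + np.floor(death_age).astype(int)
    alive = death_year > plan.registry.followup_end
    death_age = np.where(alive, np.nan, death_age)

    # causes of death: diseased decedents list the disease with
    # probability cause_of_death_prob
    causes = np.empty((n_fam, m), dtype=object)
    causes[:] = ""
    for dz in plan.diseases:
        d = per_disease[dz.disease_id]
        listed = d["status"] & ~alive & (d["u_cause"] < dz.cause_of_death_prob)
        idx = np.nonzero(listed)
        for i, j in zip(*idx):
            causes[i, j] = f"{causes[i, j]};{dz.disease_id}" if causes[i, j] else dz.disease_id

    # assemble long table, family-major then slot order
    fam_idx = np.repeat(np.arange(n_fam), m)
    slot_idx = np.tile(np.arange(m), n_fam)
    ids = np.array([f"F{f:06d}-{s:02d}" for f, s in zip(fam_idx, slot_idx)])

    def parent_ids(which: np.ndarray) -> np.ndarray:
        out = np.empty(n_fam * m, dtype=object)
        for s in range(m):
            p = which[s]
            col = "" if p < 0 else None
            for f in range(n_fam):
                k = f * m + s
                out[k] = "" if p < 0 else f"F{f:06d}-{p:02d}"
        return out

    cohort = pd.DataFrame(
        {
            "id": ids,
            "family_id": np.array([f"F{f:06d}" for f in fam_idx]),
            "father_id": parent_ids(layout.father_slot),
            "mother_id": parent_ids(layout.mother_slot),
            "sex": np.where(sex.ravel() == 1, "female", "male"),
            "generation": layout.generation[slot_idx],
            "birth_year": birth.ravel(),
            "death_year": np.where(alive.ravel(), np.nan, death_year.ravel()),
            "death_age": death_age.ravel(),
            "death_causes": causes.ravel(),
        }
    )
    cohort["death_year"] = cohort["death_year"].astype("Int64")

    for dz in plan.diseases:
        d = per_disease[dz.disease_id]
        p = dz.disease_id
        cohort[f"{p}_G"] = d["G"].ravel()
        cohort[f"{p}_G_s"] = d["G_s"].ravel()
        cohort[f"{p}_C"] = d["C"].ravel()
        cohort[f"{p}_L"] = d["L"].ravel()
        cohort[f"{p}_PRS"] = d["PRS"].ravel() if "PRS" in d else np.nan
        if "PRS_small" in d:
            cohort[f"{p}_PRS_small"] = d["PRS_small"].ravel()
        cohort[f"{p}_status"] = d["status"].ravel().astype(int)
        cohort[f"{p}_onset_age"] = d["onset"].ravel()

    pairs = build_pair_table(cohort)
    return cohort, pairs


# ---------------------------------------------------------------------------
# relative pairs from pedigree links
# ---------------------------------------------------------------------------


def _po_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """(child, parent) links, one row per known parent."""
    links = []
    for col in ("father_id", "mother_id"):
        sub = cohort.loc[cohort[col].astype(str) != "", ["id", col]]
        links.append(sub.rename(columns={col: "parent"}))
    return pd.concat(links, ignore_index=True)


def build_pair_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Enumerate first- and second-degree relative pairs from pedigree links.

    Detects parent-offspring, full-sibling, half-sibling,
    grandparent-grandchild and avuncular pairs; each unordered pair is
    emitted in both (index, relative) directions with its expected kinship
    coefficient and KING-style degree classification.
    """
    from .relatedness import classify_relationship

    po = _po_frame(cohort)
    rows = []

    def emit(a: pd.Series, b: pd.Series, rel: str) -> None:
        if len(a):
            rows.append(pd.DataFrame({
                "index_id": np.asarray(a), "relative_id": np.asarray(b),
                "relationship": rel, "kinship": KINSHIP[rel],
            }))

    emit(po["id"], po["parent"], "parent-offspring")

    # full siblings: same (father, mother), both known
    known = cohort.loc[
        (cohort["father_id"].astype(str) != "") & (cohort["mother_id"].astype(str) != ""),
        ["id", "father_id", "mother_id"],
    ]
    sib = known.merge(known, on=["father_id", "mother_id"])
    sib = sib[sib["id_x"] < sib["id_y"]]
    emit(sib["id_x"], sib["id_y"], "full-sibling")

    # half siblings: exactly one shared parent (both relevant parents known)
    halves = []
    for shared, other in (("father_id", "mother_id"), ("mother_id", "father_id")):
        sub = cohort.loc[cohort[shared].astype(str) != "", ["id", shared, other]]
        h = sub.merge(sub, on=shared)
        h = h[(h["id_x"] < h["id_y"]) & (h[f"{other}_x"] != h[f"{other}_y"])]
        halves.append(h[["id_x", "id_y"]])
    half = pd.concat(halves, ignore_index=True).drop_duplicates()
    emit(half["id_x"], half["id_y"], "half-sibling")

    # grandparents: parent of parent
    gp = po.merge(po, left_on="parent", right_on="id", suffixes=("", "_p"))
    emit(gp["id"], gp["parent_p"], "grandparent")

    # avuncular: full sibling of a parent
    sib_sym = pd.concat(
        [sib[["id_x", "id_y"]],
         sib.rename(columns={"id_x": "id_y", "id_y": "id_x"})[["id_x", "id_y"]]],
        ignore_index=True,
    )
    av = po.merge(sib_sym, left_on="parent", right_on="id_x")
    emit(av["id"], av["id_y"], "avuncular")

    if not rows:
        return pd.DataFrame(columns=["index_id", "relative_id", "kinship", "degree", "relationship"])
    uni = pd.concat(rows, ignore_index=True)
    both = pd.concat(
        [uni, uni.rename(columns={"index_id": "relative_id", "relative_id": "index_id"})],
        ignore_index=True,
    ).drop_duplicates(subset=["index_id", "relative_id"])
    both["degree"] = classify_relationship(both["kinship"].to_numpy())
    both = both[["index_id", "relative_id", "kinship", "degree", "relationship"]]
    return both.sort_values(["index_id", "relative_id"], kind="stable").reset_index(drop=True)


def record_parental_deaths(
    cohort: pd.DataFrame, registry: Optional[RegistryWindows] = None
) -> pd.DataFrame:
    """Flag which death records are visible through the causes-of-death registry.

    Adds a boolean ``death_record_observable`` column: True only when the
    death year falls inside [death_registry_start, death_registry_end].
    Deaths before the registry opened or after the parental-cause cutoff
    are unobservable to offspring family-history derivation.
    """
    registry = registry or RegistryWindows()
    out = cohort.copy()
    dy = pd.to_numeric(out["death_year"], errors="coerce")
    out["death_record_observable"] = (
        dy.ge(registry.death_registry_start) & dy.le(registry.death_registry_end)
    ).fillna(False).astype(bool)
    return out
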