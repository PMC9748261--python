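"""End-to-end orchestration: simulate -> derive FH -> analyze -> concordance
-> incidence, with a machine-readable summary and a run manifest.

The JSON summary holds only headline statistics computed in the run (mean
cross-adjustment attenuations, concordance by degree, interaction-test
counts, per-disease odds ratios); it contains no timestamps, so identical
config + seed reproduce it byte for byte. The manifest records config
hash, seed, package version, file paths and a timestamp.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    AttenuationResult,
    PrsCategorization,
    attenuation_summary,
    cross_adjust,
    display_threshold,
    interaction_test,
    prepare_analysis_frame,
)
from .concordance import observed_concordance
from .config import ConfigError, SimulationPlan, load_plan
from .incidence import km_cumulative_incidence, prepare_survival_frame
from .io import write_ped, write_table
from .relatedness import derive_fh_table
from .simulate import record_parental_deaths, simulate_cohort

log = logging.getLogger("fampgs")

SUMMARY_SCHEMA_VERSION = 1


def _result_row(disease, exposure, model, r) -> dict:
    lo, hi = r.ci95
    return {
        "disease_id": disease, "exposure": exposure, "model": model,
        "beta": r.beta, "se": r.se, "or": r.or_, "ci_low": lo, "ci_high": hi,
        "p": r.p, "n": r.n, "n_cases": r.n_cases,
    }


def run_pipeline(
    config: "SimulationPlan | str | Path",
    out_dir: "str | Path",
    seed: Optional[int] = None,
    q: float = 0.9,
    interaction_n_tests: int = 39,
) -> dict:
    """Run every stage on one simulated cohort and write the report bundle.

    Returns the summary dictionary that is also written to summary.json.
    Stage failures abort with a stage-labelled error; per-disease soft
    problems (empty strata, non-converged fits) are collected as warnings.
    """
    plan = config if isinstance(config, SimulationPlan) else load_plan(config, seed=seed)
    if seed is not None and plan.seed != seed:
        plan = SimulationPlan.from_dict({**plan.to_dict(), "seed": int(seed)})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: List[str] = []

    log.info("simulate: %d families, %d diseases, seed %d",
             plan.n_families, len(plan.diseases), plan.seed)
    try:
        cohort, pairs = simulate_cohort(plan)
        cohort = record_parental_deaths(cohort, plan.registry)
    except Exception as exc:
        raise RuntimeError(f"[simulate] {exc}") from exc
    write_table(cohort, out / "cohort.tsv")
    write_table(pairs, out / "pairs.tsv")
    write_ped(cohort, out / "cohort.ped", phenotype_disease=plan.diseases[0].disease_id)

    log.info("derive-fh: %d diseases", len(plan.diseases))
    try:
        fh_table = derive_fh_table(cohort, pairs, plan.diseases, plan.registry)
    except Exception as exc:
        raise RuntimeError(f"[derive-fh] {exc}") from exc
    write_table(fh_table, out / "fh.tsv")

    log.info("analyze: logistic regressions and cross-adjustment")
    assoc_rows: List[dict] = []
    atten_rows: List[dict] = []
    inter_rows: List[dict] = []
    decreases: Dict[str, List[AttenuationResult]] = {
        "prs_by_fh1": [], "fh1_by_prs": [], "prs_by_fhp": [], "fhp_by_prs": [],
    }
    for dz in plan.diseases:
        for fh_kind in ("fh1", "fh2", "fhp"):
            try:
                frame = prepare_analysis_frame(cohort, fh_table, dz.disease_id, fh_kind)
                prs_by, fh_by = cross_adjust(frame)
            except (ConfigError, ValueError, RuntimeError) as exc:
                warnings.append(f"{dz.disease_id}/{fh_kind}: {exc}")
                continue
            for res, model in (
                (prs_by, "cross_adjust"), (fh_by, "cross_adjust"),
            ):
                atten_rows.append({
                    "disease_id": dz.disease_id, "fh_kind": fh_kind,
                    "exposure": res.exposure, "adjustment": res.adjustment,
                    "beta_unadj": res.beta_unadj, "beta_adj": res.beta_adj,
                    "ratio": res.ratio, "decrease": res.decrease,
                })
            key_prs, key_fh = f"prs_by_{fh_kind}", f"{fh_kind}_by_prs"
            if key_prs in decreases:
                decreases[key_prs].append(prs_by)
                decreases[key_fh].append(fh_by)
            if fh_kind == "fh1":
                try:
                    it = interaction_test(frame, n_tests=interaction_n_tests)
                    inter_rows.append({
                        "disease_id": dz.disease_id, "fh_kind": fh_kind,
                        "p": it.p, "beta": it.beta, "significant": it.significant,
                        "threshold": it.threshold,
                    })
                except (ConfigError, RuntimeError) as exc:
                    warnings.append(f"{dz.disease_id}/interaction: {exc}")
                from .association import fit_logistic
                try:
                    fits = fit_logistic(frame, "y", ["PRS", "fh"], standardize=["PRS"])
                    assoc_rows.append(_result_row(dz.disease_id, "PRS_per_sd", "joint_fh1", fits[0]))
                    assoc_rows.append(_result_row(dz.disease_id, "fh1", "joint_prs", fits[1]))
                except (ConfigError, RuntimeError) as exc:
                    warnings.append(f"{dz.disease_id}/fit: {exc}")
    write_table(pd.DataFrame(assoc_rows), out / "association.tsv")
    write_table(pd.DataFrame(atten_rows), out / "attenuation.tsv")
    write_table(pd.DataFrame(inter_rows), out / "interactions.tsv")

    log.info("concordance: q = %.2f", q)
    first_dz = plan.diseases[0].disease_id
    prs = cohort.set_index("id")[f"{first_dz}_PRS"]
    status = cohort.set_index("id")[f"{first_dz}_status"]
    try:
        conc = observed_concordance(pairs, prs, q=q, status=status)
    except ValueError as exc:
        raise RuntimeError(f"[concordance] {exc}") from exc
    conc_rows = [{
        "degree": c.degree, "q": c.q, "observed": c.observed,
        "theoretical": c.theoretical, "n_pairs": c.n_pairs,
        "observed_given_affected_relative": c.observed_given_affected_relative,
        "observed_given_unaffected_relative": c.observed_given_unaffected_relative,
    } for c in conc]
    write_table(pd.DataFrame(conc_rows), out / "concordance.tsv")

    log.info("incidence: Kaplan-Meier by FH x PRS group")
    km_rows: List[dict] = []
    km80: Dict[str, Dict[str, float]] = {}
    for dz in plan.diseases:
        try:
            sframe = prepare_survival_frame(cohort, fh_table, dz.disease_id, "fh1",
                                            registry=plan.registry)
            curves = km_cumulative_incidence(sframe)
        except (ConfigError, ValueError) as exc:
            warnings.append(f"{dz.disease_id}/incidence: {exc}")
            continue
        km80[dz.disease_id] = {}
        for c in curves:
            if c.omitted:
                warnings.append(
                    f"{dz.disease_id}/incidence: stratum {c.stratum} omitted ({c.n_cases} cases)")
                continue
            km80[dz.disease_id][c.stratum] = c.cum_inc_80
            for t, ci, nr, ne in zip(c.time_grid, c.cum_inc, c.n_risk, c.n_event):
                km_rows.append({
                    "disease_id": dz.disease_id, "stratum": c.stratum,
                    "age": t, "n_risk": nr, "n_event": ne, "cum_inc": ci,
                })
    write_table(pd.DataFrame(km_rows), out / "km_curves.tsv")

    def _summ(key: str):
        vals = decreases[key]
        if len(vals) < 2:
            return None
        mean, sd = attenuation_summary(vals)
        return {"mean": round(mean, 10), "sd": round(sd, 10), "n_diseases": len(vals)}

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": plan.seed,
        "config_hash": plan.config_hash(),
        "n_individuals": int(len(cohort)),
        "n_pairs": int(len(pairs)),
        "attenuation": {k: _summ(k) for k in decreases},
        "concordance": {
            c["degree"]: {
                "observed": round(c["observed"], 10),
                "theoretical": round(c["theoretical"], 10),
                "n_pairs": c["n_pairs"],
            }
            for c in conc_rows
        },
        "interactions": {
            "n_tested": len(inter_rows),
            "n_significant": int(sum(r["significant"] for r in inter_rows)),
            "threshold": display_threshold(0.05, interaction_n_tests),
        },
        "cumulative_incidence_80": km80,
        "warnings": sorted(warnings),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "config_hash": plan.config_hash(),
        "seed": plan.seed,
        "fampgs_version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
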