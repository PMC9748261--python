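"""Covariate-adjusted logistic regression for FH and PRS effects.

Implements the effect-estimation layer: per-SD PRS and binary FH odds
ratios (Wald CIs), mutual cross-adjustment with proportional decreases in
log odds, FH x PRS interaction tests against a Bonferroni threshold,
percentile-band PRS categorisations, parental-death age-tertile effects
and nested-score (capture-fraction) comparisons.

Sign convention: ``decrease = 1 - beta_adj / beta_unadj`` so that a
*positive* decrease means attenuation (the adjusted effect is smaller).
Summaries across diseases are plain unweighted means and SDs of the
decreases, computed on the log-odds scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .config import ConfigError

__all__ = [
    "RegressionResult",
    "AttenuationResult",
    "PrsCategorization",
    "ConvergenceError",
    "SeparationError",
    "fit_logistic",
    "cross_adjust",
    "attenuation_summary",
    "interaction_test",
    "bonferroni_threshold",
    "display_threshold",
    "prs_percentiles",
    "assign_bands",
    "prs_banded_effects",
    "fhp_age_tertile_effects",
    "stratified_prs_effects",
    "compare_prs_capture",
    "prepare_analysis_frame",
    "one_index_per_family",
]

DEFAULT_COVARIATES = ("sex_code", "birth_year")


class ConvergenceError(RuntimeError):
    """Maximum-likelihood fit failed to converge."""


class SeparationError(ConvergenceError):
    """Complete or quasi-complete separation in the design."""


@dataclass
class RegressionResult:
    """One exposure's effect from a fitted logistic model."""

    exposure: str
    beta: float
    se: float
    p: float
    covariates: Tuple[str, ...]
    n: int
    n_cases: int

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci95(self) -> Tuple[float, float]:
        return (math.exp(self.beta - 1.96 * self.se), math.exp(self.beta + 1.96 * self.se))


@dataclass
class AttenuationResult:
    """Proportional change in an exposure's log odds after adjustment."""

    exposure: str
    adjustment: str
    beta_unadj: float
    beta_adj: float

    @property
    def ratio(self) -> float:
        return self.beta_adj / self.beta_unadj

    @property
    def decrease(self) -> float:
        return 1.0 - self.ratio


# ---------------------------------------------------------------------------
# core fit
# ---------------------------------------------------------------------------


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ConfigError("cannot standardize a zero-variance column")
    return (x - x.mean()) / sd


def fit_logistic(
    df: pd.DataFrame,
    outcome: str,
    exposures: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    standardize: Sequence[str] = (),
    maxiter: int = 100,
) -> List[RegressionResult]:
    """Maximum-likelihood logistic regression; one result per exposure.

    All exposures and covariates enter a single model. Columns named in
    ``standardize`` are scaled to zero mean / unit variance within the
    analysis frame before fitting (per-SD effects). Continuous covariates
    are internally centred and scaled for conditioning; exposure
    coefficients are unaffected. Separation and non-convergence raise
    explicit errors rather than returning silent garbage.
    """
    exposures = list(exposures)
    covariates = [c for c in covariates if c in df.columns]
    cols = [outcome, *exposures, *covariates]
    work = df[cols].dropna().copy()
    if work.empty:
        raise ConfigError("analysis frame is empty after dropping missing values")

    y = work[outcome].to_numpy(dtype=float)
    uniq = np.unique(y)
    if not np.isin(uniq, [0.0, 1.0]).all() or len(uniq) < 2:
        raise ConfigError(f"outcome {outcome!r} must be binary with both classes present")

    for col in exposures:
        if work[col].nunique() < 2:
            raise ConfigError(f"exposure {col!r} has zero variance in the analysis set")
    for col in standardize:
        work[col] = _zscore(work[col].to_numpy(dtype=float))
    for col in covariates:
        v = work[col].to_numpy(dtype=float)
        if work[col].nunique() > 2:
            sd = v.std(ddof=0)
            work[col] = (v - v.mean()) / (sd if sd > 0 else 1.0)

    X = sm.add_constant(work[[*exposures, *covariates]].to_numpy(dtype=float),
                        has_constant="add")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=maxiter, method="newton")
    except PerfectSeparationError as exc:
        raise SeparationError(f"complete separation fitting {outcome!r}: {exc}") from exc
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"singular information matrix fitting {outcome!r}: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(f"logistic fit for {outcome!r} did not converge in {maxiter} iterations")
    if np.isnan(res.bse).any() or np.abs(res.params[1:1 + len(exposures)]).max(initial=0.0) > 15:
        raise SeparationError(f"degenerate estimates fitting {outcome!r} (likely separation)")

    n, n_cases = len(y), int(y.sum())
    out = []
    for j, col in enumerate(exposures, start=1):
        out.append(
            RegressionResult(
                exposure=col,
                beta=float(res.params[j]),
                se=float(res.bse[j]),
                p=float(res.pvalues[j]),
                covariates=tuple(covariates),
                n=n,
                n_cases=n_cases,
            )
        )
    return out


# ---------------------------------------------------------------------------
# cross-adjustment
# ---------------------------------------------------------------------------


def cross_adjust(
    df: pd.DataFrame,
    outcome: str = "y",
    prs_col: str = "PRS",
    fh_col: str = "fh",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> Tuple[AttenuationResult, AttenuationResult]:
    """Mutual adjustment of the per-SD PRS effect and the FH effect.

    Returns ``(prs_by_fh, fh_by_prs)``: the attenuation of the PRS when FH
    joins the model, and of FH when the PRS joins, from exposure-alone and
    joint fits sharing the same covariates and analysis rows.
    """
    work = df[[outcome, prs_col, fh_col, *[c for c in covariates if c in df.columns]]].dropna().copy()
    fh_prev = work[fh_col].mean()
    if fh_prev in (0.0, 1.0):
        raise ConfigError(f"{fh_col!r} prevalence is {fh_prev:.0%} in the analysis set")
    work[prs_col] = _zscore(work[prs_col].to_numpy(dtype=float))

    prs_alone = fit_logistic(work, outcome, [prs_col], covariates)[0]
    fh_alone = fit_logistic(work, outcome, [fh_col], covariates)[0]
    joint = fit_logistic(work, outcome, [prs_col, fh_col], covariates)
    prs_joint, fh_joint = joint[0], joint[1]

    return (
        AttenuationResult(prs_col, fh_col, prs_alone.beta, prs_joint.beta),
        AttenuationResult(fh_col, prs_col, fh_alone.beta, fh_joint.beta),
    )


def attenuation_summary(results: Sequence) -> Tuple[float, float]:
    """Unweighted mean and sample SD of proportional decreases across diseases.

    Accepts AttenuationResults or raw decrease values; needs at least two.
    """
    vals = np.asarray(
        [r.decrease if isinstance(r, AttenuationResult) else float(r) for r in results]
    )
    if len(vals) < 2:
        raise ConfigError("attenuation summary needs at least two diseases")
    return float(vals.mean()), float(vals.std(ddof=1))


# ---------------------------------------------------------------------------
# interaction testing
# ---------------------------------------------------------------------------


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must be in (0,1), got {alpha}")
    if n_tests < 1:
        raise ConfigError("n_tests must be >= 1")
    return alpha / n_tests


def display_threshold(alpha: float, n_tests: int, sig_digits: int = 2) -> float:
    """Threshold rounded to ``sig_digits`` significant digits for reporting."""
    t = bonferroni_threshold(alpha, n_tests)
    if t == 0:
        return 0.0
    exp = math.floor(math.log10(abs(t)))
    return round(t, -exp + sig_digits - 1)


@dataclass
class InteractionResult:
    p: float
    beta: float
    significant: bool
    threshold: float
    n_tests: int
    n: int
    n_cases: int


def interaction_test(
    df: pd.DataFrame,
    outcome: str = "y",
    prs_col: str = "PRS",
    fh_col: str = "fh",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
    n_tests: int = 39,
) -> InteractionResult:
    """Wald test of the FH x PRS product term in the joint logistic model.

    The PRS is scaled to zero mean and unit variance before the product is
    formed. Significance is flagged against the Bonferroni threshold
    ``alpha / n_tests`` (default 0.05 / 39 = 0.0013 at two significant
    digits, matching a 24 + 15 test family).
    """
    work = df[[outcome, prs_col, fh_col, *[c for c in covariates if c in df.columns]]].dropna().copy()
    work[prs_col] = _zscore(work[prs_col].to_numpy(dtype=float))
    work["_fh_x_prs"] = work[fh_col] * work[prs_col]
    res = fit_logistic(work, outcome, [prs_col, fh_col, "_fh_x_prs"], covariates)
    inter = res[2]
    thr = bonferroni_threshold(alpha, n_tests)
    return InteractionResult(
        p=inter.p, beta=inter.beta, significant=inter.p < thr,
        threshold=thr, n_tests=n_tests, n=inter.n, n_cases=inter.n_cases,
    )


# ---------------------------------------------------------------------------
# PRS percentile categorisations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrsCategorization:
    """A percentile-band scheme: boundaries span [0, 1], one band is the
    reference. Band i covers (boundaries[i], boundaries[i+1]]; values at a
    boundary fall in the lower band."""

    scheme: str
    boundaries: Tuple[float, ...]
    labels: Tuple[str, ...]
    reference: str

    def __post_init__(self):
        b = self.boundaries
        if b[0] != 0.0 or b[-1] != 1.0 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ConfigError("boundaries must increase from 0 to 1")
        if len(self.labels) != len(b) - 1 or self.reference not in self.labels:
            raise ConfigError("labels must match bands and include the reference")

    @classmethod
    def top_decile_vs_rest(cls) -> "PrsCategorization":
        return cls("top_decile_vs_rest", (0.0, 0.9, 1.0), ("0-90", "90-100"), "0-90")

    @classmethod
    def seven_band(cls) -> "PrsCategorization":
        return cls(
            "seven_band",
            (0.0, 0.1, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0),
            ("0-10", "10-20", "20-40", "40-60", "60-80", "80-90", "90-100"),
            "40-60",
        )

    @classmethod
    def three_group(cls) -> "PrsCategorization":
        # low = bottom tertile, average = 33rd-90th percentile, high = top decile
        return cls("three_group", (0.0, 1.0 / 3.0, 0.9, 1.0),
                   ("low", "average", "high"), "average")


def prs_percentiles(values: np.ndarray) -> np.ndarray:
    """Within-sample percentile ranks in (0, 1], average ranks for ties."""
    v = np.asarray(values, dtype=float)
    return rankdata(v, method="average") / len(v)


def assign_bands(percentiles: np.ndarray, scheme: PrsCategorization) -> np.ndarray:
    """Band labels for percentile ranks; boundary values go to the lower band."""
    inner = np.asarray(scheme.boundaries[1:-1])
    idx = np.searchsorted(inner, np.asarray(percentiles, dtype=float), side="left")
    return np.asarray(scheme.labels, dtype=object)[idx]


def prs_banded_effects(
    df: pd.DataFrame,
    scheme: PrsCategorization,
    outcome: str = "y",
    prs_col: str = "PRS",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> Dict[str, RegressionResult]:
    """Odds ratios for each PRS percentile band versus the scheme's reference.

    Percentiles are computed within the supplied analysis frame (after any
    sex restriction); one joint model contains all non-reference bands.
    """
    work = df[[outcome, prs_col, *[c for c in covariates if c in df.columns]]].dropna().copy()
    bands = assign_bands(prs_percentiles(work[prs_col].to_numpy()), scheme)
    counts = pd.Series(bands).value_counts()
    for lab in scheme.labels:
        if counts.get(lab, 0) == 0:
            raise ConfigError(f"PRS band {lab!r} is empty in the analysis set")
    dummy_cols = []
    for lab in scheme.labels:
        if lab == scheme.reference:
            continue
        col = f"band_{lab}"
        work[col] = (bands == lab).astype(float)
        dummy_cols.append((lab, col))
    fits = fit_logistic(work, outcome, [c for _, c in dummy_cols], covariates)
    return {lab: fit for (lab, _), fit in zip(dummy_cols, fits)}


# ---------------------------------------------------------------------------
# parental-death age tertiles
# ---------------------------------------------------------------------------


def fhp_age_tertile_effects(
    df: pd.DataFrame,
    outcome: str = "y",
    prs_col: str = "PRS",
    tertile_col: str = "fhp_age_tertile",
    fhp_col: str = "fhp",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> Dict[str, object]:
    """Tertile-specific FH_P odds ratios versus FH_P-negative individuals.

    Fits the three tertile indicators jointly, without and with PRS
    adjustment, and reports the per-tertile proportional decreases.
    Tertiles without cases are flagged and omitted rather than fitted.
    """
    cols = [outcome, fhp_col, tertile_col, prs_col, *[c for c in covariates if c in df.columns]]
    work = df[cols].copy()
    work = work[work[fhp_col].notna()]  # eligible rows only
    work = work.dropna(subset=[outcome, prs_col])
    work[prs_col] = _zscore(work[prs_col].to_numpy(dtype=float))

    warnings: List[str] = []
    dummy_cols = []
    for t in (1, 2, 3):
        mask = (work[fhp_col] == 1) & (work[tertile_col] == t)
        n_cases = int(work.loc[mask, outcome].sum())
        if mask.sum() == 0 or n_cases == 0:
            warnings.append(f"tertile {t}: no cases, OR omitted")
            continue
        col = f"tertile_{t}"
        work[col] = mask.astype(float)
        dummy_cols.append((t, col))
    if not dummy_cols:
        raise ConfigError("no informative FH_P age tertiles")

    names = [c for _, c in dummy_cols]
    unadj = fit_logistic(work, outcome, names, covariates)
    adj = fit_logistic(work, outcome, [*names, prs_col], covariates)
    out_unadj = {t: r for (t, _), r in zip(dummy_cols, unadj)}
    out_adj = {t: r for (t, _), r in zip(dummy_cols, adj[: len(dummy_cols)])}
    atten = {
        t: AttenuationResult(f"fhp_tertile_{t}", prs_col,
                             out_unadj[t].beta, out_adj[t].beta)
        for t, _ in dummy_cols
    }
    return {"unadjusted": out_unadj, "adjusted": out_adj,
            "attenuation": atten, "warnings": warnings}


# ---------------------------------------------------------------------------
# stratified and nested-score analyses
# ---------------------------------------------------------------------------


def stratified_prs_effects(
    df: pd.DataFrame,
    outcome: str = "y",
    prs_col: str = "PRS",
    fh_col: str = "fh",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> Dict[str, Optional[RegressionResult]]:
    """Per-SD PRS effect fitted separately in FH-positive and FH-negative
    subsets; the PRS is standardized once on the full analysis set so the
    per-SD unit is shared. Strata without cases yield None with a flag."""
    work = df[[outcome, prs_col, fh_col, *[c for c in covariates if c in df.columns]]].dropna().copy()
    work[prs_col] = _zscore(work[prs_col].to_numpy(dtype=float))
    out: Dict[str, Optional[RegressionResult]] = {}
    for label, flag in (("fh_negative", 0), ("fh_positive", 1)):
        sub = work[work[fh_col] == flag]
        if sub.empty or sub[outcome].nunique() < 2:
            out[label] = None
            continue
        out[label] = fit_logistic(sub, outcome, [prs_col], covariates)[0]
    return out


def compare_prs_capture(
    df: pd.DataFrame,
    outcome: str = "y",
    prs_large: str = "PRS",
    prs_small: str = "PRS_small",
    fh_col: str = "fh",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    rho2_large: Optional[float] = None,
    rho2_small: Optional[float] = None,
) -> Dict[str, object]:
    """Compare a genome-wide-capture score against a nested lower-capture one.

    Returns per-SD effects for both scores and the attenuation of FH by
    each; the larger-capture score is expected to show the larger per-SD
    effect and the larger FH attenuation.
    """
    if rho2_large is not None and rho2_small is not None and rho2_small > rho2_large:
        raise ConfigError("rho2_small must not exceed rho2_large")
    out: Dict[str, object] = {}
    for tag, col in (("large", prs_large), ("small", prs_small)):
        out[f"effect_{tag}"] = fit_logistic(
            df, outcome, [col], covariates, standardize=[col]
        )[0]
        _, fh_by = cross_adjust(df, outcome, col, fh_col, covariates)
        out[f"fh_attenuation_by_{tag}"] = fh_by
    return out


# ---------------------------------------------------------------------------
# frame preparation
# ---------------------------------------------------------------------------


def prepare_analysis_frame(
    cohort: pd.DataFrame,
    fh_table: pd.DataFrame,
    disease_id: str,
    fh_kind: str = "fh1",
) -> pd.DataFrame:
    """Join cohort and FH columns into a regression-ready frame.

    Produces ``y`` (disease status), ``PRS`` (and ``PRS_small`` when
    present), ``fh``, ``sex_code``, ``birth_year`` plus the FH_P
    eligibility/tertile columns, restricted to the disease's FH analysis
    set (individuals with at least one relevant relative for fh1/fh2,
    FH_P-eligible individuals for fhp).
    """
    if fh_kind not in ("fh1", "fh2", "fhp"):
        raise ConfigError(f"fh_kind must be fh1/fh2/fhp, got {fh_kind!r}")
    fh = fh_table[fh_table["disease_id"] == disease_id]
    if fh.empty:
        raise ConfigError(f"no FH rows for disease {disease_id!r}")
    prs_col = f"{disease_id}_PRS"
    if prs_col not in cohort.columns or cohort[prs_col].isna().all():
        raise ConfigError(
            f"PRS undefined for {disease_id!r} (rho2 = 0?); PRS analyses need rho2 > 0"
        )

    keep = ["id", "sex", "birth_year", prs_col, f"{disease_id}_status"]
    small_col = f"{disease_id}_PRS_small"
    if small_col in cohort.columns:
        keep.append(small_col)
    frame = cohort[keep].merge(fh, left_on="id", right_on="individual_id", how="inner")
    frame = frame.rename(columns={
        f"{disease_id}_status": "y", prs_col: "PRS", small_col: "PRS_small",
    })
    frame["sex_code"] = (frame["sex"] == "female").astype(int)

    if "family_id" in cohort.columns:
        frame = frame.merge(cohort[["id", "family_id", "generation"]],
                            on="id", how="left")
    if fh_kind == "fhp":
        frame = frame[frame["fhp_eligible"].astype(bool)]
        frame["fh"] = frame["fhp"].astype(float)
    else:
        flag = f"{fh_kind}_analysis_set"
        if flag in frame.columns:
            frame = frame[frame[flag].astype(bool)]
        frame["fh"] = frame[fh_kind].astype(float)
    return frame.reset_index(drop=True)


def one_index_per_family(frame: pd.DataFrame) -> pd.DataFrame:
    """Keep one index person per family: the first youngest-generation member.

    Simulated relatives share liability components, so regressions over
    whole families hold correlated rows and independence-based Wald
    standard errors are too small; calibrated tests (type-I error,
    CI coverage) should run on independent index persons, with family
    history still derived from the full pedigree.
    """
    if "family_id" not in frame.columns:
        raise ConfigError("frame lacks family_id; build it via prepare_analysis_frame")
    sub = frame[frame["generation"] == frame["generation"].max()]
    return sub.drop_duplicates("family_id").reset_index(drop=True)
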