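"""Typed configuration for cohort simulation and downstream analyses.

The simulator works on the liability scale: for each disease, an individual's
latent liability is ``L = G + C + E`` with additive genetic variance ``h2``,
shared-family environment variance ``c2`` and unique environment
``1 - h2 - c2``, so that ``Var(L) = 1``. A polygenic score captures a
sub-component of ``G`` with variance ``rho2``. Disease occurs when ``L``
exceeds the threshold implied by the lifetime prevalence ``K``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import yaml

__all__ = [
    "ConfigError",
    "DiseaseModelConfig",
    "RegistryWindows",
    "SimulationPlan",
    "load_plan",
]


class ConfigError(ValueError):
    """A configuration violates its invariants."""


@dataclass(frozen=True)
class DiseaseModelConfig:
    """Generative parameters for one disease.

    Parameters
    ----------
    disease_id:
        Short identifier used as a column prefix in the cohort table.
    K:
        Lifetime prevalence in (0, 1); sets the liability threshold.
    h2:
        Narrow-sense heritability of liability, in [0, 1].
    rho2:
        Liability variance captured by the polygenic score, in [0, h2].
        The per-SD association of the score with liability is sqrt(rho2).
    c2:
        Shared-family environment variance, in [0, 1 - h2].
    onset_mean, onset_sd:
        Normal (truncated to (0, 100]) age-at-onset distribution, years.
    cause_of_death_prob:
        Probability that a diseased parent's death record lists the disease
        among its causes (immediate, contributing and underlying lumped).
    onset_liability_shift:
        Years of *earlier* onset per unit of liability above the threshold
        (0 disables the early-onset/high-liability link).
    onset_death_link:
        If True, a case's death age is capped at onset age plus a
        post-onset survival time, tying parental death age to liability.
    registry_kind:
        'cancer' diseases use the earlier cancer-registry start for
        relatives' diagnoses; everything else uses the discharge registry.
    sex_restriction:
        'female' / 'male' for sex-specific diseases (breast, prostate
        cancer): both index persons and counted relatives are restricted.
    rho2_small:
        Optional variance of a nested, lower-capture score (a sparse
        published score versus the genome-wide one); must be <= rho2.
    """

    disease_id: str
    K: float
    h2: float
    rho2: float
    c2: float = 0.0
    onset_mean: float = 60.0
    onset_sd: float = 12.0
    cause_of_death_prob: float = 0.7
    onset_liability_shift: float = 0.0
    onset_death_link: bool = False
    post_onset_survival_mean: float = 15.0
    post_onset_survival_sd: float = 5.0
    registry_kind: str = "discharge"
    sex_restriction: Optional[str] = None
    rho2_small: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.disease_id or not str(self.disease_id).strip():
            raise ConfigError("disease_id must be a non-empty string")
        if not 0.0 < self.K < 1.0:
            raise ConfigError(f"{self.disease_id}: prevalence K must be in (0,1), got {self.K}")
        if not 0.0 <= self.h2 <= 1.0:
            raise ConfigError(f"{self.disease_id}: h2 must be in [0,1], got {self.h2}")
        if not 0.0 <= self.rho2 <= self.h2 + 1e-12:
            raise ConfigError(
                f"{self.disease_id}: rho2 must be in [0, h2={self.h2}], got {self.rho2}"
            )
        if self.c2 < 0.0 or self.h2 + self.c2 > 1.0 + 1e-12:
            raise ConfigError(
                f"{self.disease_id}: need c2 >= 0 and h2 + c2 <= 1, got h2={self.h2}, c2={self.c2}"
            )
        if self.onset_sd <= 0.0:
            raise ConfigError(f"{self.disease_id}: onset_sd must be > 0")
        if not 0.0 < self.cause_of_death_prob <= 1.0:
            raise ConfigError(f"{self.disease_id}: cause_of_death_prob must be in (0,1]")
        if self.post_onset_survival_sd <= 0.0:
            raise ConfigError(f"{self.disease_id}: post_onset_survival_sd must be > 0")
        if self.registry_kind not in ("discharge", "cancer"):
            raise ConfigError(f"{self.disease_id}: registry_kind must be 'discharge' or 'cancer'")
        if self.sex_restriction not in (None, "female", "male"):
            raise ConfigError(f"{self.disease_id}: sex_restriction must be None/'female'/'male'")
        if self.rho2_small is not None and not 0.0 < self.rho2_small <= self.rho2 + 1e-12:
            raise ConfigError(
                f"{self.disease_id}: rho2_small must be in (0, rho2={self.rho2}]"
            )


@dataclass(frozen=True)
class RegistryWindows:
    """Calendar windows during which each national registry records events.

    Defaults mirror the Finnish registries: hospital discharges from 1968,
    causes of death from 1964 (parental causes available through 2018),
    cancer diagnoses from 1953, follow-up ending 2019.
    """

    death_registry_start: int = 1964
    discharge_registry_start: int = 1968
    cancer_registry_start: int = 1953
    death_registry_end: int = 2018
    followup_end: int = 2019

    def __post_init__(self) -> None:
        if self.death_registry_start >= self.death_registry_end:
            raise ConfigError("death registry start must precede its end")
        if self.discharge_registry_start >= self.followup_end:
            raise ConfigError("discharge registry start must precede follow-up end")
        if self.cancer_registry_start >= self.followup_end:
            raise ConfigError("cancer registry start must precede follow-up end")

    def diagnosis_start(self, disease: DiseaseModelConfig) -> int:
        return (
            self.cancer_registry_start
            if disease.registry_kind == "cancer"
            else self.discharge_registry_start
        )


@dataclass(frozen=True)
class SimulationPlan:
    """Everything needed to generate one synthetic cohort deterministically.

    ``birth_year_range`` applies to the youngest generation; each generation
    above is shifted earlier by ``generation_gap`` years. ``po_env_share``
    is the fraction of the shared-environment variance a child shares with
    each parent (full siblings always share C completely); it must not
    exceed sqrt(1/2) for the variance decomposition to stay valid.
    """

    n_families: int
    seed: int
    diseases: Tuple[DiseaseModelConfig, ...]
    generations: int = 3
    birth_year_range: Tuple[int, int] = (1945, 1975)
    registry: RegistryWindows = field(default_factory=RegistryWindows)
    n_children: int = 2
    n_parent_siblings: int = 1
    generation_gap: int = 28
    death_age_mean: float = 75.0
    death_age_sd: float = 12.0
    po_env_share: float = 0.5

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if self.generations not in (2, 3):
            raise ConfigError("generations must be 2 or 3")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool) or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        if not self.diseases:
            raise ConfigError("at least one disease must be configured")
        object.__setattr__(self, "diseases", tuple(self.diseases))
        ids = [d.disease_id for d in self.diseases]
        if len(set(ids)) != len(ids):
            raise ConfigError("disease_id values must be unique")
        lo, hi = self.birth_year_range
        if lo > hi:
            raise ConfigError("birth_year_range must be (low, high)")
        object.__setattr__(self, "birth_year_range", (int(lo), int(hi)))
        if self.n_children < 1:
            raise ConfigError("n_children must be >= 1")
        if self.n_parent_siblings < 0:
            raise ConfigError("n_parent_siblings must be >= 0")
        if self.generation_gap < 15:
            raise ConfigError("generation_gap must be >= 15 years")
        if self.death_age_sd <= 0:
            raise ConfigError("death_age_sd must be > 0")
        if not 0.0 <= self.po_env_share <= math.sqrt(0.5) + 1e-12:
            raise ConfigError("po_env_share must be in [0, sqrt(1/2)]")

    def disease(self, disease_id: str) -> DiseaseModelConfig:
        for d in self.diseases:
            if d.disease_id == disease_id:
                return d
        raise KeyError(f"disease {disease_id!r} not in plan")

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["birth_year_range"] = list(self.birth_year_range)
        d["diseases"] = [asdict(x) for x in self.diseases]
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationPlan":
        raw = dict(raw)
        try:
            diseases = tuple(DiseaseModelConfig(**d) for d in raw.pop("diseases"))
            registry = RegistryWindows(**raw.pop("registry", {}))
            byr = raw.pop("birth_year_range", (1945, 1975))
            return cls(
                diseases=diseases,
                registry=registry,
                birth_year_range=(int(byr[0]), int(byr[1])),
                **raw,
            )
        except TypeError as exc:  # unknown / missing keys
            raise ConfigError(f"invalid simulation plan: {exc}") from exc

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_plan(path: str | Path, seed: Optional[int] = None) -> SimulationPlan:
    """Read a :class:`SimulationPlan` from a YAML or JSON file.

    ``seed`` overrides the seed stored in the file when given.
    """
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            raw = json.load(fh)
        else:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    if seed is not None:
        raw["seed"] = int(seed)
    return SimulationPlan.from_dict(raw)
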