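"""Scenario configuration for the synthetic spontaneous-report generator.

A :class:`ScenarioConfig` fully determines one synthetic reporting database:
the case count, the drug and adverse-event catalogs with their marginal
probabilities, planted drug-event log odds ratios, a demographic model with
confounding of the target event class, and the data-quality nuisances a real
spontaneous reporting system exhibits (missing demographics, duplicate rows,
implausible height/weight, involvement categories).  The same configuration
and seed always produce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

from .errors import ConfigurationError

#: Decade age bands as encoded in the DEMO table, with their midpoints in years.
AGE_BANDS: Tuple[str, ...] = (
    "under 10", "10s", "20s", "30s", "40s",
    "50s", "60s", "70s", "80s", "90s",
)
AGE_BAND_MIDPOINTS: Mapping[str, float] = {
    "under 10": 5.0, "10s": 15.0, "20s": 25.0, "30s": 35.0, "40s": 45.0,
    "50s": 55.0, "60s": 65.0, "70s": 75.0, "80s": 85.0, "90s": 95.0,
}

INVOLVEMENT_CATEGORIES: Tuple[str, ...] = ("suspected", "concomitant", "interaction")

#: Covariates accepted in the confounding map.  Contributions are to the
#: log-odds of target-class events: per year of age relative to 60, per BMI
#: unit relative to 22, and an indicator contribution for female sex.
CONFOUNDER_NAMES: Tuple[str, ...] = ("age", "female", "bmi")
CONFOUNDER_CENTERS: Mapping[str, float] = {"age": 60.0, "bmi": 22.0}

MISSINGNESS_FIELDS: Tuple[str, ...] = ("sex", "age", "height", "weight")


@dataclass(frozen=True)
class DrugSpec:
    """One drug in the catalog: name, ATC label, marginal exposure probability."""

    name: str
    atc_code: str
    p_exposure: float


@dataclass(frozen=True)
class EventSpec:
    """One preferred term: target-class flag and baseline per-case probability."""

    term: str
    is_target: bool
    p_baseline: float


@dataclass(frozen=True)
class DemographicModel:
    """Sex proportion, age-band distribution and anthropometrics by sex.

    Heights are N(mean, sd) in cm and weights N(mean, sd) in kg, truncated to
    plausible ranges before any deliberate outlier injection.
    """

    p_female: float = 0.55
    age_band_probs: Mapping[str, float] = field(default_factory=lambda: {
        "under 10": 0.02, "10s": 0.03, "20s": 0.06, "30s": 0.08, "40s": 0.10,
        "50s": 0.13, "60s": 0.19, "70s": 0.21, "80s": 0.14, "90s": 0.04,
    })
    height_cm: Mapping[str, Tuple[float, float]] = field(default_factory=lambda: {
        "male": (165.0, 7.0), "female": (152.0, 7.0),
    })
    weight_kg: Mapping[str, Tuple[float, float]] = field(default_factory=lambda: {
        "male": (63.0, 11.0), "female": (51.0, 10.0),
    })


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete specification of one synthetic reporting database."""

    n_cases: int
    drugs: Tuple[DrugSpec, ...]
    events: Tuple[EventSpec, ...]
    planted_effects: Mapping[Tuple[str, str], float] = field(default_factory=dict)
    demographics: DemographicModel = field(default_factory=DemographicModel)
    confounding: Mapping[str, float] = field(default_factory=dict)
    missingness: Mapping[str, float] = field(default_factory=dict)
    duplicate_rate: float = 0.0
    outlier_rate: float = 0.0
    involvement_mix: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    weight_banded: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first offending field."""
        if not isinstance(self.n_cases, int) or self.n_cases <= 0:
            raise ConfigurationError("n_cases", "must be a positive integer")
        if not self.drugs:
            raise ConfigurationError("drugs", "catalog must be nonempty")
        if not self.events:
            raise ConfigurationError("events", "catalog must be nonempty")
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ConfigurationError("drugs", "drug names must be unique")
        terms = [e.term for e in self.events]
        if len(set(terms)) != len(terms):
            raise ConfigurationError("events", "preferred terms must be unique")
        for d in self.drugs:
            if not 0.0 < d.p_exposure < 1.0:
                raise ConfigurationError(
                    "drugs", f"exposure probability for {d.name!r} must lie strictly in (0, 1)")
        for e in self.events:
            if not 0.0 < e.p_baseline < 1.0:
                raise ConfigurationError(
                    "events", f"baseline probability for {e.term!r} must lie strictly in (0, 1)")
        target_terms = {e.term for e in self.events if e.is_target}
        for (drug, term), beta in self.planted_effects.items():
            if drug not in set(names):
                raise ConfigurationError("planted_effects", f"unknown drug {drug!r}")
            if term not in target_terms:
                raise ConfigurationError(
                    "planted_effects", f"{term!r} is not a target-class term in the event catalog")
            float(beta)
        for key in self.confounding:
            if key not in CONFOUNDER_NAMES:
                raise ConfigurationError(
                    "confounding", f"unknown covariate {key!r}; expected one of {CONFOUNDER_NAMES}")
        for key, p in self.missingness.items():
            if key not in MISSINGNESS_FIELDS:
                raise ConfigurationError(
                    "missingness", f"unknown field {key!r}; expected one of {MISSINGNESS_FIELDS}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("missingness", f"probability for {key!r} outside [0, 1]")
        for name, value in (("duplicate_rate", self.duplicate_rate),
                            ("outlier_rate", self.outlier_rate)):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(name, "must lie in [0, 1]")
        mix = self.involvement_mix
        if len(mix) != 3 or any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ConfigurationError(
                "involvement_mix", "must be three nonnegative probabilities summing to 1")
        demo = self.demographics
        if not 0.0 <= demo.p_female <= 1.0:
            raise ConfigurationError("demographics", "p_female outside [0, 1]")
        band_p = demo.age_band_probs
        if set(band_p) - set(AGE_BANDS):
            raise ConfigurationError(
                "demographics", f"unknown age bands {sorted(set(band_p) - set(AGE_BANDS))}")
        if any(p < 0 for p in band_p.values()) or abs(sum(band_p.values()) - 1.0) > 1e-9:
            raise ConfigurationError(
                "demographics", "age_band_probs must be nonnegative and sum to 1")
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed", "must be an integer")

    # -- convenience --------------------------------------------------------
    @property
    def target_terms(self) -> Tuple[str, ...]:
        return tuple(e.term for e in self.events if e.is_target)

    @property
    def background_terms(self) -> Tuple[str, ...]:
        return tuple(e.term for e in self.events if not e.is_target)

    def drug_names(self) -> Tuple[str, ...]:
        return tuple(d.name for d in self.drugs)


def _as_drugs(entries: Sequence[Tuple[str, str, float]]) -> Tuple[DrugSpec, ...]:
    return tuple(DrugSpec(*e) for e in entries)


def _as_events(entries: Sequence[Tuple[str, bool, float]]) -> Tuple[EventSpec, ...]:
    return tuple(EventSpec(*e) for e in entries)
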