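"""Cohort schema: the 18-variable heart-failure record layout.

The schema mirrors a multi-centre cardiology study data set: demographics,
patient history, medication, echocardiography and laboratory values, with
per-variable flags marking which variables the Barcelona BioHF ("B") and
MAGGIC ("M") risk scores consume.  Variable specs also carry the marginal
distribution parameters the synthetic cohort generator uses and a plausible
range used for data cleaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

CATEGORIES = (
    "demographics",
    "patient_history",
    "medication",
    "echocardiography",
    "laboratory",
)
KINDS = ("continuous", "boolean", "ordinal_categorical")

NYHA_CLASSES = ("I", "II", "III", "IV")

MISSING = ""  # CSV representation of a missing cell


@dataclass(frozen=True)
class VariableSpec:
    """One variable of the cohort: type, units, plausible range, marginal.

    ``marginal`` holds generator parameters: ``{"mean", "sd"}`` for a
    continuous variable (truncated to ``plausible_range``), ``{"prevalence"}``
    for a boolean, ``{"probs": {label: p}}`` for an ordinal categorical.
    """

    name: str
    category: str
    kind: str
    units: str = ""
    plausible_range: tuple = ()
    score_flags: frozenset = field(default_factory=frozenset)
    marginal: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if not self.score_flags <= {"B", "M"}:
            raise ValueError("score_flags must be a subset of {'B', 'M'}")
        if self.kind == "continuous":
            lo, hi = self.plausible_range
            if not lo < hi:
                raise ValueError(f"{self.name}: range must have min < max")
            if self.marginal:
                if self.marginal["sd"] <= 0:
                    raise ValueError(f"{self.name}: sd must be positive")
        elif self.kind == "boolean":
            p = self.marginal.get("prevalence", 0.5)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: prevalence outside [0,1]")
        else:  # ordinal_categorical
            if not self.plausible_range:
                raise ValueError(f"{self.name}: empty category set")
            probs = self.marginal.get("probs")
            if probs is not None:
                if set(probs) != set(self.plausible_range):
                    raise ValueError(f"{self.name}: probs/categories mismatch")
                if abs(sum(probs.values()) - 1.0) > 1e-9:
                    raise ValueError(f"{self.name}: probs must sum to 1")

    @property
    def categories(self) -> tuple:
        """Category labels for an ordinal variable."""
        if self.kind != "ordinal_categorical":
            raise TypeError(f"{self.name} is not categorical")
        return tuple(self.plausible_range)


@dataclass(frozen=True)
class CohortSchema:
    """Ordered collection of :class:`VariableSpec` with flag bookkeeping."""

    variables: tuple

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")

    @property
    def names(self) -> list:
        return [v.name for v in self.variables]

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def flagged(self, flag: str) -> list:
        """Names of variables carrying score flag ``flag`` ('B' or 'M')."""
        return [v.name for v in self.variables if flag in v.score_flags]

    def of_kind(self, kind: str) -> list:
        return [v.name for v in self.variables if v.kind == kind]

    def subset(self, names) -> "CohortSchema":
        """Schema restricted to ``names``, preserving schema order."""
        keep = set(names)
        missing = keep - set(self.names)
        if missing:
            raise KeyError(f"variables not in schema: {sorted(missing)}")
        return CohortSchema(tuple(v for v in self.variables if v.name in keep))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    "name": v.name,
                    "category": v.category,
                    "kind": v.kind,
                    "units": v.units,
                    "plausible_range": list(v.plausible_range),
                    "score_flags": sorted(v.score_flags),
                    "marginal": v.marginal,
                }
                for v in self.variables
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSchema":
        return cls(
            tuple(
                VariableSpec(
                    name=v["name"],
                    category=v["category"],
                    kind=v["kind"],
                    units=v.get("units", ""),
                    plausible_range=tuple(v.get("plausible_range", ())),
                    score_flags=frozenset(v.get("score_flags", ())),
                    marginal=v.get("marginal", {}),
                )
                for v in d["variables"]
            )
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _cont(name, category, units, rng, mean, sd, flags=""):
    return VariableSpec(
        name=name,
        category=category,
        kind="continuous",
        units=units,
        plausible_range=rng,
        score_flags=frozenset(flags),
        marginal={"mean": mean, "sd": sd},
    )


def _bool(name, category, prevalence, flags=""):
    return VariableSpec(
        name=name,
        category=category,
        kind="boolean",
        plausible_range=(False, True),
        score_flags=frozenset(flags),
        marginal={"prevalence": prevalence},
    )


def default_schema() -> CohortSchema:
    """The 18-variable heart-failure cohort schema.

    Flags: 11 variables feed the Barcelona BioHF score (B), 13 the MAGGIC
    score (M).  Marginal means/SDs for age, sodium and haemoglobin follow
    the study cohort's printed summary statistics (67.47 (14.28) years,
    139.17 (3.25) mmol/L, 13.07 (2.10) g/dL); the remaining marginals are
    clinically plausible defaults for a chronic heart-failure population,
    not study values, and can be overridden via a custom schema.

    "Time of first diagnosis of HF" is represented as the boolean the
    MAGGIC score consumes: first diagnosed at least 18 months ago.
    """
    return CohortSchema(
        (
            _cont("age", "demographics", "years", (18.0, 110.0), 67.47, 14.28, "BM"),
            _bool("sex_male", "demographics", 0.70, "BM"),
            _cont("bmi", "patient_history", "kg/m2", (12.0, 60.0), 28.0, 5.0, "M"),
            _cont("systolic_bp", "patient_history", "mmHg", (60.0, 250.0), 125.0, 20.0, "M"),
            VariableSpec(
                name="nyha",
                category="patient_history",
                kind="ordinal_categorical",
                plausible_range=NYHA_CLASSES,
                score_flags=frozenset("BM"),
                marginal={"probs": {"I": 0.15, "II": 0.45, "III": 0.32, "IV": 0.08}},
            ),
            _bool("current_smoking", "patient_history", 0.18, "M"),
            _bool("hf_duration_ge_18m", "patient_history", 0.55, "M"),
            _bool("diabetes", "patient_history", 0.35, "M"),
            _bool("chronic_lung_disease", "patient_history", 0.15, "M"),
            _bool("beta_blocker", "medication", 0.85, "BM"),
            _bool("acei_arb", "medication", 0.75, "BM"),
            _bool("statin", "medication", 0.55, "B"),
            _bool("loop_diuretic", "medication", 0.70, "B"),
            _cont("lvef", "echocardiography", "%", (5.0, 80.0), 40.0, 12.0, "BM"),
            _cont("creatinine", "laboratory", "mg/dL", (0.2, 15.0), 1.25, 0.5, "M"),
            _cont("sodium", "laboratory", "mmol/L", (110.0, 160.0), 139.17, 3.25, "B"),
            _cont("haemoglobin", "laboratory", "g/dL", (4.0, 20.0), 13.07, 2.10, "B"),
            _cont("egfr", "laboratory", "mL/min/1.73m2", (2.0, 200.0), 60.0, 25.0, "B"),
        )
    )
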