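"""Generic heart-failure risk-score engines.

Two engine families cover the scores used as utility probes:

* a *banded additive point score* (MAGGIC style): each variable maps to an
  integer point contribution through half-open numeric bands or category
  tables, some of which are conditional on another variable's band (e.g.
  the age and systolic-BP point tables depend on the ejection-fraction
  band); the total is the sum, and a monotone lookup converts it into a
  1-year mortality probability;

* a *Cox-type survival score* (Barcelona BioHF style): a linear predictor
  ``lp = sum(beta_i * (x_i - center_i))`` over transformed covariates and a
  baseline survival ``S0(t)``, giving predicted mortality
  ``1 - S0(t) ** exp(lp)`` at horizons of 1, 2 or 3 years.

The engines are fully generic; the parameter sets live in packaged YAML
files and can be replaced without touching code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from ..cohort import CohortTable, ConfigurationError


class NotCalculableError(ValueError):
    """A required input of the score is missing for this record."""


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def _match_band(value: float, bands) -> float:
    """Return the points of the half-open band [lo, hi) containing value."""
    for lo, hi, pts in bands:
        if lo <= value < hi:
            return pts
    raise ConfigurationError(f"value {value!r} matches no band")


def _check_partition(bands, context: str) -> None:
    srt = sorted(bands, key=lambda b: b[0])
    for (lo1, hi1, _), (lo2, _, _) in zip(srt, srt[1:]):
        if not math.isclose(hi1, lo2, rel_tol=0, abs_tol=1e-12):
            raise ConfigurationError(f"{context}: bands have a gap/overlap at {hi1}")
    for lo, hi, pts in bands:
        if lo >= hi:
            raise ConfigurationError(f"{context}: empty band [{lo}, {hi})")
        if pts != int(pts):
            raise ConfigurationError(f"{context}: non-integer points {pts}")


@dataclass
class BandedPointTable:
    """Declarative additive integer point score."""

    name: str
    components: list

    def __post_init__(self):
        for comp in self.components:
            kind = comp["kind"]
            ctx = f"{self.name}:{comp['variable']}"
            if kind == "bands":
                _check_partition(comp["bands"], ctx)
            elif kind == "conditional_bands":
                for case in comp["cases"]:
                    _check_partition(case["bands"], ctx)
            elif kind == "categories":
                if any(p != int(p) for p in comp["points"].values()):
                    raise ConfigurationError(f"{ctx}: non-integer points")
            elif kind == "boolean":
                pass
            else:
                raise ConfigurationError(f"{ctx}: unknown component kind {kind!r}")

    @property
    def required_variables(self) -> list:
        req = []
        for comp in self.components:
            for v in (comp["variable"], comp.get("condition_variable")):
                if v is not None and v not in req:
                    req.append(v)
        return req

    @property
    def max_points(self) -> int:
        total = 0
        for comp in self.components:
            kind = comp["kind"]
            if kind == "bands":
                total += max(p for _, _, p in comp["bands"])
            elif kind == "conditional_bands":
                total += max(p for c in comp["cases"] for _, _, p in c["bands"])
            elif kind == "categories":
                total += max(comp["points"].values())
            else:
                total += max(comp.get("if_true", 0), comp.get("if_false", 0))
        return int(total)

    def _component_points(self, comp, record) -> float:
        value = record.get(comp["variable"])
        if _is_missing(value):
            raise NotCalculableError(comp["variable"])
        scale = comp.get("scale", 1.0)
        kind = comp["kind"]
        if kind == "bands":
            return _match_band(float(value) * scale, comp["bands"])
        if kind == "conditional_bands":
            cond = record.get(comp["condition_variable"])
            if _is_missing(cond):
                raise NotCalculableError(comp["condition_variable"])
            for case in comp["cases"]:
                lo, hi = case["condition_band"]
                if lo <= float(cond) < hi:
                    return _match_band(float(value) * scale, case["bands"])
            raise ConfigurationError(
                f"condition value {cond!r} matches no case of {comp['variable']}"
            )
        if kind == "categories":
            try:
                return comp["points"][value]
            except KeyError:
                raise ConfigurationError(
                    f"category {value!r} not in point table for {comp['variable']}"
                ) from None
        # boolean
        return comp.get("if_true", 0) if bool(value) else comp.get("if_false", 0)

    def compute(self, record) -> int:
        """Total integer points for one record (dict or pandas Series)."""
        if isinstance(record, pd.Series):
            record = record.to_dict()
        return int(sum(self._component_points(c, record) for c in self.components))


@dataclass
class MortalityLookup:
    """Integer score -> probability of death within the horizon."""

    table: dict

    def __post_init__(self):
        if not self.table:
            raise ConfigurationError("empty mortality lookup")
        keys = sorted(self.table)
        probs = [self.table[k] for k in keys]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("mortality probabilities outside [0,1]")
        if any(b < a for a, b in zip(probs, probs[1:])):
            raise ConfigurationError("mortality lookup must be nondecreasing")
        self._keys = keys

    def __call__(self, score: int) -> float:
        s = min(max(int(score), self._keys[0]), self._keys[-1])
        return float(self.table[s])


@dataclass
class CoxScore:
    """Cox-type survival score: mortality(t) = 1 - S0(t) ** exp(lp)."""

    name: str
    covariates: list
    baseline_survival: dict  # horizon (years) -> S0(t)

    def __post_init__(self):
        horizons = sorted(self.baseline_survival)
        s0 = [self.baseline_survival[t] for t in horizons]
        if any(not 0.0 < s <= 1.0 for s in s0):
            raise ConfigurationError("S0(t) must lie in (0, 1]")
        if any(b > a for a, b in zip(s0, s0[1:])):
            raise ConfigurationError("S0 must be nonincreasing in t")

    @property
    def required_variables(self) -> list:
        seen = []
        for cov in self.covariates:
            if cov["variable"] not in seen:
                seen.append(cov["variable"])
        return seen

    def _x(self, cov, value) -> float:
        kind = cov.get("transform", "linear")
        if kind == "linear":
            return float(value)
        if kind == "boolean":
            return 1.0 if bool(value) else 0.0
        if kind == "categories":
            try:
                return float(cov["mapping"][value])
            except KeyError:
                raise ConfigurationError(
                    f"category {value!r} unmapped for {cov['variable']}"
                ) from None
        raise ConfigurationError(f"unknown transform {kind!r}")

    def linear_predictor(self, record) -> float:
        if isinstance(record, pd.Series):
            record = record.to_dict()
        lp = 0.0
        for cov in self.covariates:
            value = record.get(cov["variable"])
            if _is_missing(value):
                raise NotCalculableError(cov["variable"])
            lp += cov["coefficient"] * (self._x(cov, value) - cov.get("center", 0.0))
        return lp

    def compute(self, record, horizon: int = 1) -> float:
        """Predicted mortality probability at ``horizon`` years."""
        if horizon not in self.baseline_survival:
            raise ConfigurationError(f"no baseline survival for horizon {horizon}")
        lp = self.linear_predictor(record)
        return 1.0 - self.baseline_survival[horizon] ** math.exp(lp)


@dataclass
class ScoreResult:
    """Per-record score values with calculability flags."""

    values: pd.Series  # float; NaN where not calculable
    calculable: pd.Series  # bool
    kind: str  # "points" or "probability"
    horizon: int | None = None

    @property
    def calculable_values(self) -> pd.Series:
        return self.values[self.calculable]


def score_table(table: CohortTable, definition, horizon: int = 1) -> ScoreResult:
    """Apply a score definition row-wise; rows with missing required inputs
    are flagged not calculable, all others get a value."""
    values, ok = [], []
    is_cox = isinstance(definition, CoxScore)
    for _, row in table.df.iterrows():
        try:
            if is_cox:
                values.append(definition.compute(row, horizon=horizon))
            else:
                values.append(float(definition.compute(row)))
            ok.append(True)
        except NotCalculableError:
            values.append(np.nan)
            ok.append(False)
    return ScoreResult(
        values=pd.Series(values, index=table.df.index, dtype=float),
        calculable=pd.Series(ok, index=table.df.index, dtype=bool),
        kind="probability" if is_cox else "points",
        horizon=horizon if is_cox else None,
    )


# -- packaged parameter files ---------------------------------------------


def _load_yaml(fname: str) -> dict:
    with resources.files("hfprivacy.scores").joinpath("params", fname).open() as fh:
        return yaml.safe_load(fh)


def load_maggic() -> tuple:
    """Load the MAGGIC point table and its 1-year mortality lookup."""
    raw = _load_yaml("maggic.yaml")
    comps = []
    for comp in raw["components"]:
        comp = dict(comp)
        if "bands" in comp:
            comp["bands"] = [(float(a), float(b), int(p)) for a, b, p in comp["bands"]]
        if "cases" in comp:
            comp["cases"] = [
                {
                    "condition_band": (float(c["condition_band"][0]), float(c["condition_band"][1])),
                    "bands": [(float(a), float(b), int(p)) for a, b, p in c["bands"]],
                }
                for c in comp["cases"]
            ]
        comps.append(comp)
    table = BandedPointTable(name="MAGGIC", components=comps)
    lut = MortalityLookup({int(k): float(v) for k, v in raw["mortality_1y"].items()})
    return table, lut


def load_biohf() -> CoxScore:
    """Load the Barcelona BioHF (biomarker-free) Cox score parameters.

    The packaged coefficient file is a SYNTHETIC parameter set: it follows
    the published model's structure (covariate list, clinically sensible
    coefficient signs, nonincreasing baseline survival) but its numeric
    values are stand-ins, not the original publication's estimates.
    """
    raw = _load_yaml("biohf_synthetic.yaml")
    return CoxScore(
        name="BioHF",
        covariates=raw["covariates"],
        baseline_survival={int(k): float(v) for k, v in raw["baseline_survival"].items()},
    )
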