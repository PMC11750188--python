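"""Plausibility-range cleaning and score-specific complete-case subsetting.

Cleaning replaces values outside a plausible range with missing markers;
the table is then cut down to the variables a given risk score needs, and
to the records complete on those variables (no imputation is performed).
The shipped default ranges are editable configuration, not values from the
originating study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, ConfigurationError
from .schema import CohortSchema

SCORE_FLAGS = {"BioHF": "B", "MAGGIC": "M"}


@dataclass
class RangeRuleSet:
    """Per-variable plausible interval (continuous) or category set."""

    rules: dict

    @classmethod
    def from_schema(cls, schema: CohortSchema) -> "RangeRuleSet":
        rules = {}
        for v in schema.variables:
            if v.kind == "continuous":
                rules[v.name] = tuple(v.plausible_range)
            elif v.kind == "ordinal_categorical":
                rules[v.name] = set(v.categories)
        return cls(rules)

    def to_yaml(self, path) -> None:
        enc = {
            k: (list(v) if isinstance(v, (set, frozenset)) else list(v))
            for k, v in self.rules.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(enc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path, schema: CohortSchema) -> "RangeRuleSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rules = {}
        for name, v in raw.items():
            if name not in schema:
                raise ConfigurationError(f"range rule for unknown variable {name!r}")
            if schema[name].kind == "continuous":
                rules[name] = (float(v[0]), float(v[1]))
            else:
                rules[name] = set(v)
        return cls(rules)


def clean(table: CohortTable, rules: RangeRuleSet | None = None) -> CohortTable:
    """Replace out-of-range cells with missing markers (N/A indicators).

    Row count is unchanged; in-range and already-missing cells are
    untouched.  Idempotent.
    """
    if rules is None:
        rules = RangeRuleSet.from_schema(table.schema)
    unknown = set(rules.rules) - set(table.schema.names)
    if unknown:
        raise ConfigurationError(f"range rules for unknown variables: {sorted(unknown)}")
    for spec in table.schema.variables:
        if spec.kind == "continuous" and spec.name not in rules.rules:
            raise ConfigurationError(f"no range rule for continuous {spec.name!r}")
    df = table.df.copy()
    for name, rule in rules.rules.items():
        spec = table.schema[name]
        col = df[name]
        if spec.kind == "continuous":
            lo, hi = rule
            bad = col.notna() & ((col < lo) | (col > hi))
        else:
            bad = col.notna() & ~col.isin(list(rule))
        if bad.any():
            col = col.copy()
            col[bad] = np.nan
            df[name] = col
    return CohortTable(table.schema, df)


def score_subset(table: CohortTable, score_id: str) -> CohortTable:
    """Restrict to the variables flagged for ``score_id`` ('BioHF' or
    'MAGGIC') and to records complete on those variables."""
    try:
        flag = SCORE_FLAGS[score_id]
    except KeyError:
        raise ConfigurationError(f"unknown score {score_id!r}") from None
    cols = table.schema.flagged(flag)
    if not cols:
        raise ConfigurationError(f"schema has no variables flagged {flag!r}")
    sub_schema = table.schema.subset(cols)
    df = table.df[sub_schema.names]
    keep = df.notna().all(axis=1)
    return CohortTable(sub_schema, df.loc[keep].reset_index(drop=True))
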