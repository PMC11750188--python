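import numpy as np
import pandas as pd
import pytest

from hfprivacy import CohortTable, GeneratorConfig, generate_cohort
from hfprivacy.schema import CohortSchema, VariableSpec, default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_cohort(schema):
    """300 records with default missingness; shared across read-only tests."""
    return generate_cohort(schema, GeneratorConfig(n_records=300, seed=42))


@pytest.fixture(scope="session")
def complete_cohort(schema):
    """500 fully observed, in-range records."""
    return generate_cohort(
        schema, GeneratorConfig(n_records=500, seed=7, missingness_rate=0.0)
    )


def make_schema(*specs) -> CohortSchema:
    return CohortSchema(tuple(specs))


def cont_spec(name, lo=0.0, hi=100.0, mean=50.0, sd=10.0, flags=""):
    return VariableSpec(
        name=name,
        category="laboratory",
        kind="continuous",
        plausible_range=(lo, hi),
        score_flags=frozenset(flags),
        marginal={"mean": mean, "sd": sd},
    )


def bool_spec(name, prevalence=0.5, flags=""):
    return VariableSpec(
        name=name,
        category="medication",
        kind="boolean",
        plausible_range=(False, True),
        score_flags=frozenset(flags),
        marginal={"prevalence": prevalence},
    )


def ord_spec(name, probs, flags=""):
    return VariableSpec(
        name=name,
        category="patient_history",
        kind="ordinal_categorical",
        plausible_range=tuple(probs),
        score_flags=frozenset(flags),
        marginal={"probs": probs},
    )


def table_from_dict(schema: CohortSchema, data: dict) -> CohortTable:
    df = pd.DataFrame(data)[schema.names]
    for spec in schema.variables:
        if spec.kind == "continuous":
            df[spec.name] = df[spec.name].astype(float)
        else:
            df[spec.name] = df[spec.name].astype(object).where(df[spec.name].notna(), np.nan)
    return CohortTable(schema, df)
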