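"""Seeded synthetic cohort generation and cohort table I/O.

A stand-in for the access-restricted study records: draws a latent
multivariate normal (Gaussian copula), maps each axis through the
variable's marginal — truncated-normal quantile transform for continuous
variables, threshold cuts at cumulative probabilities for booleans and
ordinals — and optionally injects missing values (MCAR) and out-of-range
outliers so downstream cleaning and complete-case filtering are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .schema import CohortSchema, default_schema
from .seeding import derive_seed

#: default latent (Gaussian-copula) correlations: clinically motivated
#: structure (renal function couples creatinine/eGFR/age; congestion couples
#: NYHA, LVEF and loop diuretics), exposed here rather than hard-coded in
#: the generator.  These are plausibility choices, not study estimates.
DEFAULT_LATENT_CORRELATION = {
    ("creatinine", "egfr"): -0.80,
    ("age", "egfr"): -0.45,
    ("nyha", "lvef"): -0.40,
    ("nyha", "loop_diuretic"): 0.30,
    ("age", "systolic_bp"): 0.15,
    ("bmi", "diabetes"): 0.25,
    ("haemoglobin", "egfr"): 0.25,
    ("sex_male", "haemoglobin"): 0.30,
    ("sodium", "loop_diuretic"): -0.15,
    ("current_smoking", "chronic_lung_disease"): 0.35,
    ("creatinine", "loop_diuretic"): 0.20,
}


class ConfigurationError(ValueError):
    """Raised for invalid generator / pipeline configuration."""


def latent_correlation_matrix(schema: CohortSchema, pairs=None) -> np.ndarray:
    """Materialize a pairwise-specified correlation dict into a full matrix."""
    if pairs is None:
        pairs = DEFAULT_LATENT_CORRELATION
    names = schema.names
    idx = {n: i for i, n in enumerate(names)}
    corr = np.eye(len(names))
    for (a, b), rho in pairs.items():
        if a not in idx or b not in idx:
            continue  # pair refers to a variable absent from this schema
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    return corr


@dataclass
class CohortTable:
    """A typed patient table: schema plus a pandas DataFrame.

    Continuous cells are float64 (NaN = missing); booleans are Python
    bools in object columns (NaN = missing); ordinal categoricals are
    strings (NaN = missing).
    """

    schema: CohortSchema
    df: pd.DataFrame

    def __post_init__(self):
        if list(self.df.columns) != self.schema.names:
            raise ValueError("DataFrame columns must match schema order")

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.schema, self.df.copy())

    def equals(self, other: "CohortTable") -> bool:
        return self.schema == other.schema and self.df.equals(other.df)

    def complete_mask(self, columns=None) -> np.ndarray:
        cols = self.schema.names if columns is None else list(columns)
        return self.df[cols].notna().all(axis=1).to_numpy()

    def n_missing(self, column=None) -> int:
        if column is None:
            return int(self.df.isna().to_numpy().sum())
        return int(self.df[column].isna().sum())

    # -- CSV round trip ---------------------------------------------------

    def to_csv(self, path) -> None:
        """RFC-4180 CSV, UTF-8, header row; empty field encodes missing."""
        out = {}
        for spec in self.schema.variables:
            col = self.df[spec.name]
            if spec.kind == "boolean":
                out[spec.name] = col.map(
                    lambda v: "" if pd.isna(v) else ("1" if v else "0")
                )
            elif spec.kind == "continuous":
                out[spec.name] = col.map(lambda v: "" if pd.isna(v) else repr(float(v)))
            else:
                out[spec.name] = col.map(lambda v: "" if pd.isna(v) else str(v))
        pd.DataFrame(out).to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path, schema: CohortSchema) -> "CohortTable":
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        if list(raw.columns) != schema.names:
            raise ValueError("CSV columns do not match schema")
        cols = {}
        for spec in schema.variables:
            col = raw[spec.name]
            if spec.kind == "continuous":
                # exact round trip: Python float() parses shortest repr exactly
                cols[spec.name] = col.map(lambda s: np.nan if s == "" else float(s))
            elif spec.kind == "boolean":
                cols[spec.name] = col.map(
                    {"1": True, "0": False, "": np.nan, "True": True, "False": False}
                )
            else:
                cols[spec.name] = col.replace("", np.nan)
        df = pd.DataFrame(cols)[schema.names]
        return cls(schema, df)


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    ``missingness_rate`` / ``outlier_rate`` may be a scalar (applied to all
    variables; outliers only ever hit continuous ones) or a per-variable
    dict.  ``latent_correlation`` is a full matrix over schema axes or
    ``None`` for the package default.
    """

    n_records: int = 2441
    seed: int = 0
    latent_correlation: np.ndarray | None = None
    missingness_rate: float | dict = 0.05
    outlier_rate: float | dict = 0.0

    def rates(self, which: str, schema: CohortSchema) -> dict:
        raw = self.missingness_rate if which == "missing" else self.outlier_rate
        if not isinstance(raw, dict):
            names = (
                schema.names if which == "missing" else schema.of_kind("continuous")
            )
            raw = {n: float(raw) for n in names}
        for n, r in raw.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"{which} rate for {n} outside [0,1]")
        return raw


def _validate_correlation(corr: np.ndarray, dim: int) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (dim, dim):
        raise ConfigurationError(f"correlation must be {dim}x{dim}")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ConfigurationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ConfigurationError("correlation diagonal must be 1")
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-8:
        raise ConfigurationError(
            f"correlation matrix not positive semi-definite (min eig {w.min():.3g})"
        )
    return corr


def _latent_factor(corr: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(corr)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _uniform_to_values(u: np.ndarray, spec) -> np.ndarray:
    """Map uniform(0,1) draws through a variable's marginal."""
    if spec.kind == "continuous":
        lo, hi = spec.plausible_range
        mean, sd = spec.marginal["mean"], spec.marginal["sd"]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)
    if spec.kind == "boolean":
        p = spec.marginal["prevalence"]
        # high latent value -> True, so positive latent correlations align
        # with the False < True ordering (object dtype: Python bools survive
        # CSV round trips)
        return (u >= 1.0 - p).astype(object)
    probs = spec.marginal["probs"]
    cats = list(spec.categories)
    cum = np.cumsum([probs[c] for c in cats])
    idx = np.searchsorted(cum, u, side="right").clip(0, len(cats) - 1)
    return np.asarray(cats, dtype=object)[idx]


def generate_cohort(
    schema: CohortSchema | None = None, config: GeneratorConfig | None = None
) -> CohortTable:
    """Draw a seeded synthetic cohort from the Gaussian-copula generator.

    Values are generated inside each variable's plausible range; missing
    values and out-of-range outliers are then injected at the configured
    rates (sub-seeds derived from ``config.seed``, so identical configs give
    bit-identical tables).
    """
    schema = schema if schema is not None else default_schema()
    config = config if config is not None else GeneratorConfig()
    if config.n_records <= 0:
        raise ConfigurationError("n_records must be positive")
    corr = (
        latent_correlation_matrix(schema)
        if config.latent_correlation is None
        else config.latent_correlation
    )
    corr = _validate_correlation(corr, len(schema))
    rng = np.random.default_rng(derive_seed(config.seed, "generate"))
    z = rng.standard_normal((config.n_records, len(schema))) @ _latent_factor(corr).T
    u = stats.norm.cdf(z)
    cols = {}
    for j, spec in enumerate(schema.variables):
        vals = _uniform_to_values(u[:, j], spec)
        if spec.kind == "continuous":
            cols[spec.name] = pd.Series(vals, dtype=float)
        else:
            cols[spec.name] = pd.Series(vals, dtype=object)
    table = CohortTable(schema, pd.DataFrame(cols)[schema.names])
    out_rates = config.rates("outlier", schema)
    if any(r > 0 for r in out_rates.values()):
        table = inject_outliers(table, out_rates, derive_seed(config.seed, "outliers"))
    miss_rates = config.rates("missing", schema)
    if any(r > 0 for r in miss_rates.values()):
        table = inject_missingness(
            table, miss_rates, derive_seed(config.seed, "missingness")
        )
    return table


def _codes_and_probs(spec, col: pd.Series):
    if spec.kind == "boolean":
        order = {False: 0, True: 1}
        levels = 2
    else:
        order = {c: i for i, c in enumerate(spec.categories)}
        levels = len(spec.categories)
    codes = col.map(order).to_numpy(dtype=int)
    probs = np.bincount(codes, minlength=levels) / len(codes)
    return codes, probs


def _cond_mean_scores(codes: np.ndarray, probs: np.ndarray):
    """Conditional-mean normal scores E[Z | category] from empirical
    category probabilities, plus Var(score)."""
    cum = np.concatenate(([0.0], np.cumsum(probs)))
    taus = stats.norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))
    widths = np.diff(cum)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (stats.norm.pdf(taus[:-1]) - stats.norm.pdf(taus[1:])) / widths
    s = np.where(widths > 0, s, 0.0)
    var = float(np.sum(widths * s**2))
    return s[codes], s, taus, var


def _polychoric_moment(rho, taus_x, taus_y, s_x, s_y):
    """E[s_x(X) s_y(Y)] under a bivariate normal with correlation rho."""
    mvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])

    def F(a, b):
        if np.isinf(a) and a < 0 or np.isinf(b) and b < 0:
            return 0.0
        return float(mvn.cdf([min(a, 8.0), min(b, 8.0)]))

    total = 0.0
    for k in range(len(s_x)):
        for l in range(len(s_y)):
            p = (
                F(taus_x[k + 1], taus_y[l + 1])
                - F(taus_x[k], taus_y[l + 1])
                - F(taus_x[k + 1], taus_y[l])
                + F(taus_x[k], taus_y[l])
            )
            total += p * s_x[k] * s_y[l]
    return total


def estimate_latent_correlation(table: CohortTable) -> np.ndarray:
    """Estimate the Gaussian-copula latent correlation matrix of a cohort.

    Continuous pairs use Pearson correlation of rank-based normal scores;
    discrete-continuous pairs use conditional-mean (polyserial) scores with
    exact de-attenuation; discrete-discrete pairs solve the polychoric
    moment equation by root finding.  Complete-case per pair.
    """
    from scipy.optimize import brentq

    schema = table.schema
    n = table.n_rows
    p = len(schema)
    z_cont = {}
    disc = {}
    for spec in schema.variables:
        col = table.df[spec.name].dropna()
        if spec.kind == "continuous":
            ranks = col.rank(method="average")
            z_cont[spec.name] = pd.Series(
                stats.norm.ppf(ranks / (len(col) + 1)), index=col.index
            )
        else:
            codes, probs = _codes_and_probs(spec, col)
            scores, s_levels, taus, var = _cond_mean_scores(codes, probs)
            disc[spec.name] = {
                "scores": pd.Series(scores, index=col.index),
                "levels": s_levels,
                "taus": taus,
                "var": var,
            }
    corr = np.eye(p)
    names = schema.names
    for i in range(p):
        for j in range(i + 1, p):
            a, b = names[i], names[j]
            if a in z_cont and b in z_cont:
                sub = pd.concat([z_cont[a], z_cont[b]], axis=1).dropna()
                rho = float(np.corrcoef(sub.iloc[:, 0], sub.iloc[:, 1])[0, 1])
            elif a in z_cont or b in z_cont:
                zc = z_cont[a] if a in z_cont else z_cont[b]
                d = disc[b] if a in z_cont else disc[a]
                sub = pd.concat([zc, d["scores"]], axis=1).dropna()
                rho = float(sub.iloc[:, 0].mul(sub.iloc[:, 1]).mean() / d["var"])
            else:
                da, db = disc[a], disc[b]
                sub = pd.concat([da["scores"], db["scores"]], axis=1).dropna()
                m_emp = float(sub.iloc[:, 0].mul(sub.iloc[:, 1]).mean())

                def f(r):
                    return (
                        _polychoric_moment(
                            r, da["taus"], db["taus"], da["levels"], db["levels"]
                        )
                        - m_emp
                    )

                try:
                    rho = brentq(f, -0.995, 0.995, xtol=1e-4)
                except ValueError:  # moment outside attainable range
                    rho = 0.995 if m_emp > 0 else -0.995
            corr[i, j] = corr[j, i] = float(np.clip(rho, -1.0, 1.0))
    return corr


def inject_missingness(table: CohortTable, rates, seed: int) -> CohortTable:
    """Set cells missing independently (MCAR) at per-variable rates."""
    if not isinstance(rates, dict):
        rates = {n: float(rates) for n in table.schema.names}
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    for name in table.schema.names:
        r = rates.get(name, 0.0)
        if not 0.0 <= r <= 1.0:
            raise ConfigurationError(f"missingness rate for {name} outside [0,1]")
        if r == 0.0:
            continue
        mask = rng.random(len(df)) < r
        if mask.any():
            col = df[name].copy()
            col[mask] = np.nan
            df[name] = col
    return CohortTable(table.schema, df)


def inject_outliers(table: CohortTable, rates, seed: int) -> CohortTable:
    """Replace continuous cells with values strictly outside the plausible
    range (for exercising range-based cleaning); rate 0 is the identity."""
    if not isinstance(rates, dict):
        rates = {n: float(rates) for n in table.schema.of_kind("continuous")}
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    for spec in table.schema.variables:
        r = rates.get(spec.name, 0.0)
        if r == 0.0:
            continue
        if spec.kind != "continuous":
            raise ConfigurationError(f"outliers only apply to continuous ({spec.name})")
        lo, hi = spec.plausible_range
        sd = spec.marginal.get("sd", (hi - lo) / 10.0)
        n = len(df)
        mask = rng.random(n) < r
        side_hi = rng.random(n) < 0.5
        bump = sd * (0.5 + rng.random(n))
        vals = np.where(side_hi, hi + bump, lo - bump)
        if mask.any():
            col = df[spec.name].to_numpy(dtype=float, copy=True)
            col[mask] = vals[mask]
            df[spec.name] = col
    return CohortTable(table.schema, df)
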