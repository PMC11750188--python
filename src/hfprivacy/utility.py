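"""Utility measurements for protected tables.

Two complementary views:

* an SDMetrics-style fidelity report — per-column *shape* scores
  (Kolmogorov–Smirnov complement for continuous columns, total-variation
  complement for categorical/boolean ones), per-pair *trend* scores
  (correlation similarity for continuous pairs, contingency similarity
  otherwise) and their unweighted mean as the overall score, all in [0,1];

* classical distribution comparisons — two-sample KS tests for continuous
  variables, chi-square tests for categorical ones, Cohen's d effect sizes,
  and a non-uniform-entropy similarity for variables protected through
  generalization — plus a risk-score distribution comparison with ECDF and
  violin-summary exports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anonymize import NYHA_HIERARCHY, Hierarchy
from .cohort import CohortTable, ConfigurationError
from .scores.engine import score_table

log = logging.getLogger(__name__)


# -- elementary fidelity scores -------------------------------------------


def ks_complement(x, y) -> float:
    """1 minus the two-sample Kolmogorov–Smirnov statistic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ConfigurationError("ks_complement requires non-empty samples")
    d = stats.ks_2samp(x, y, method="asymp").statistic
    return float(1.0 - d)


def _check_freqs(f: dict, label: str) -> None:
    if abs(sum(f.values()) - 1.0) > 1e-9:
        raise ConfigurationError(f"{label} frequencies must sum to 1")
    if any(v < -1e-12 for v in f.values()):
        raise ConfigurationError(f"{label} frequencies must be nonnegative")


def tvd_complement(r: dict, s: dict) -> float:
    """1 minus the total variation distance between category frequencies."""
    _check_freqs(r, "first")
    _check_freqs(s, "second")
    cats = set(r) | set(s)
    tvd = 0.5 * sum(abs(r.get(c, 0.0) - s.get(c, 0.0)) for c in cats)
    return float(1.0 - tvd)


def correlation_similarity(rho_r: float, rho_s: float) -> float:
    """1 - |rho_R - rho_S| / 2 for two Pearson correlations."""
    for rho in (rho_r, rho_s):
        if not -1.0 - 1e-12 <= rho <= 1.0 + 1e-12:
            raise ConfigurationError(f"correlation {rho} outside [-1,1]")
    return float(1.0 - abs(rho_r - rho_s) / 2.0)


def contingency_similarity(joint_r: dict, joint_s: dict) -> float:
    """1 - 1/2 * sum |sigma_S(a,b) - sigma_R(a,b)| over the joint grid."""
    _check_freqs(joint_r, "first joint")
    _check_freqs(joint_s, "second joint")
    cells = set(joint_r) | set(joint_s)
    tvd = 0.5 * sum(abs(joint_r.get(c, 0.0) - joint_s.get(c, 0.0)) for c in cells)
    return float(1.0 - tvd)


# -- table-level quality report -------------------------------------------


@dataclass
class QualityReport:
    """Fidelity report: per-column shapes, per-pair trends, overall mean."""

    shapes: dict
    pairs: dict
    overall: float

    def to_dict(self) -> dict:
        return {
            "shapes": self.shapes,
            "pairs": {f"{a}|{b}": v for (a, b), v in self.pairs.items()},
            "overall": self.overall,
        }


def _is_continuous(table: CohortTable, name: str) -> bool:
    return table.schema[name].kind == "continuous"


def _decile_bins(col: pd.Series) -> np.ndarray:
    """Decile edges of the original column, shared by both tables."""
    edges = np.unique(np.quantile(col.dropna(), np.linspace(0, 1, 11)))
    if len(edges) < 2:
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    edges[0], edges[-1] = -np.inf, np.inf
    return edges


def _as_categorical(col: pd.Series, table: CohortTable, name: str, bins=None):
    if _is_continuous(table, name):
        return pd.cut(col, bins=bins, labels=False)
    return col


def _joint_freqs(a: pd.Series, b: pd.Series) -> dict:
    df = pd.DataFrame({"a": a, "b": b}).dropna()
    if len(df) == 0:
        return {}
    counts = df.value_counts(normalize=True)
    return {(ka, kb): float(v) for (ka, kb), v in counts.items()}


def overall_quality(original: CohortTable, protected: CohortTable) -> QualityReport:
    """Full fidelity report over the shared columns of two tables.

    A table compared with itself scores exactly 1.0.
    """
    shared = [n for n in original.schema.names if n in protected.schema.names]
    if not shared:
        raise ConfigurationError("tables share no columns")
    shapes = {}
    for name in shared:
        o, p = original.df[name], protected.df[name]
        if _is_continuous(original, name):
            shapes[name] = ks_complement(o, p)
        else:
            r = {k: float(v) for k, v in o.dropna().value_counts(normalize=True).items()}
            s = {k: float(v) for k, v in p.dropna().value_counts(normalize=True).items()}
            shapes[name] = tvd_complement(r, s)
    pairs = {}
    for i, a in enumerate(shared):
        for b in shared[i + 1 :]:
            if _is_continuous(original, a) and _is_continuous(original, b):
                pairs[(a, b)] = _numeric_pair_score(original, protected, a, b)
            else:
                bins_a = _decile_bins(original.df[a]) if _is_continuous(original, a) else None
                bins_b = _decile_bins(original.df[b]) if _is_continuous(original, b) else None
                jr = _joint_freqs(
                    _as_categorical(original.df[a], original, a, bins_a),
                    _as_categorical(original.df[b], original, b, bins_b),
                )
                js = _joint_freqs(
                    _as_categorical(protected.df[a], original, a, bins_a),
                    _as_categorical(protected.df[b], original, b, bins_b),
                )
                pairs[(a, b)] = contingency_similarity(jr, js)
    scores = list(shapes.values()) + list(pairs.values())
    return QualityReport(shapes=shapes, pairs=pairs, overall=float(np.mean(scores)))


def _pearson(df: pd.DataFrame, a: str, b: str) -> float:
    sub = df[[a, b]].dropna()
    if len(sub) < 2:
        return 0.0
    sa, sb = sub[a].std(), sub[b].std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.clip(sub[a].corr(sub[b]), -1.0, 1.0))


def _numeric_pair_score(original, protected, a, b) -> float:
    return correlation_similarity(
        _pearson(original.df, a, b), _pearson(protected.df, a, b)
    )


# -- classical comparison stats -------------------------------------------


@dataclass
class ComparisonStats:
    """Per-variable test statistics comparing original vs protected."""

    per_variable: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"per_variable": self.per_variable, "warnings": self.warnings}


def cohens_d(x, y) -> float:
    """Pooled-SD Cohen's d; 0 when both SDs are 0 and means agree, NaN
    (flagged by the caller) when the pooled SD vanishes with unequal means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    pooled = math.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / max(n1 + n2 - 2, 1)
    )
    diff = x.mean() - y.mean()
    if pooled == 0:
        return 0.0 if diff == 0 else float("nan")
    return float(diff / pooled)


def compare_variables(original: CohortTable, protected: CohortTable) -> ComparisonStats:
    """KS test + Cohen's d per continuous variable, chi-square per
    categorical/boolean variable, over the union of observed categories."""
    shared = [n for n in original.schema.names if n in protected.schema.names]
    if not shared:
        raise ConfigurationError("tables share no columns")
    out = ComparisonStats()
    for name in shared:
        o = original.df[name].dropna()
        p = protected.df[name].dropna()
        if len(o) == 0 or len(p) == 0:
            out.warnings.append(f"{name}: empty after complete-case filtering")
            continue
        if _is_continuous(original, name):
            ks = stats.ks_2samp(o.astype(float), p.astype(float))
            d = cohens_d(o, p)
            entry = {
                "test": "ks",
                "statistic": float(ks.statistic),
                "p": float(ks.pvalue),
                "cohens_d": d,
            }
            if math.isnan(d):
                entry["d_undefined"] = True
            out.per_variable[name] = entry
        else:
            cats = sorted(set(o) | set(p), key=str)
            oc = o.value_counts().reindex(cats, fill_value=0)
            pc = p.value_counts().reindex(cats, fill_value=0)
            contingency = np.vstack([oc.to_numpy(), pc.to_numpy()])
            nonzero = contingency.sum(axis=0) > 0
            contingency = contingency[:, nonzero]
            if contingency.shape[1] < 2:
                out.per_variable[name] = {"test": "chi2", "statistic": 0.0, "p": 1.0}
                continue
            chi2, pval, _, expected = stats.chi2_contingency(contingency)
            entry = {"test": "chi2", "statistic": float(chi2), "p": float(pval)}
            if (expected < 5).any():
                msg = f"{name}: chi-square expected counts < 5"
                out.warnings.append(msg)
                log.warning(msg)
            out.per_variable[name] = entry
    return out


# -- non-uniform entropy ---------------------------------------------------


def nue_similarity(
    original_col: pd.Series,
    anonymized_col: pd.Series,
    hierarchy: Hierarchy | None = None,
) -> float:
    """Non-uniform-entropy similarity of a generalized/suppressed column.

    Each record loses ``-log2(count(original value) / count(generalized
    group))`` bits, where the group is the record's own value (no loss), the
    hierarchy class it was generalized to, or the whole column for a
    suppressed cell; the similarity is 1 minus the loss normalized by the
    loss of full suppression.
    """
    hierarchy = hierarchy if hierarchy is not None else Hierarchy(NYHA_HIERARCHY)
    mask = original_col.notna()
    orig = original_col[mask]
    anon = anonymized_col[mask]
    n = len(orig)
    if n == 0:
        raise ConfigurationError("empty column")
    value_counts = orig.value_counts()
    label_counts = {}
    for g in set(hierarchy.mapping.values()):
        members = [v for v, lab in hierarchy.mapping.items() if lab == g]
        label_counts[g] = int(value_counts.reindex(members, fill_value=0).sum())
    loss = 0.0
    max_loss = 0.0
    for v, a in zip(orig, anon):
        cv = int(value_counts[v])
        max_loss += -math.log2(cv / n)
        if pd.isna(a):
            loss += -math.log2(cv / n)
        elif a == v:
            pass  # untouched: no loss
        elif a in label_counts:
            if label_counts[a] < cv:
                raise ConfigurationError(f"label {a!r} inconsistent with data")
            loss += -math.log2(cv / label_counts[a])
        else:
            raise ConfigurationError(
                f"value {a!r} not explicable by hierarchy or suppression"
            )
    if max_loss == 0.0:
        return 1.0
    return float(1.0 - loss / max_loss)


# -- risk-score distribution comparison -----------------------------------


@dataclass
class ScoreUtilityReport:
    """Distribution comparison of a risk score on original vs protected."""

    score_name: str
    ks_statistic: float
    ks_p: float
    cohens_d: float
    summary: dict  # per table: mean, sd, quantiles, n_calculable
    ecdf: pd.DataFrame  # long format: table, value, ecdf
    violin: pd.DataFrame  # per table: quantile rows

    def to_dict(self) -> dict:
        return {
            "score": self.score_name,
            "ks_statistic": self.ks_statistic,
            "ks_p": self.ks_p,
            "cohens_d": self.cohens_d,
            "summary": self.summary,
        }


_VIOLIN_QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


def score_utility(
    original: CohortTable,
    protected: CohortTable,
    definition,
    horizon: int = 1,
    score_name: str = "score",
) -> ScoreUtilityReport:
    """Compare the per-record risk-score distributions of two tables."""
    res_o = score_table(original, definition, horizon=horizon)
    res_p = score_table(protected, definition, horizon=horizon)
    vo = res_o.calculable_values.to_numpy(dtype=float)
    vp = res_p.calculable_values.to_numpy(dtype=float)
    if len(vo) == 0 or len(vp) == 0:
        raise ConfigurationError("no calculable scores in one of the tables")
    ks = stats.ks_2samp(vo, vp)
    frames = []
    summary = {}
    violin_rows = []
    for label, vals in (("original", vo), ("protected", vp)):
        xs = np.sort(vals)
        ec = np.arange(1, len(xs) + 1) / len(xs)
        frames.append(pd.DataFrame({"table": label, "value": xs, "ecdf": ec}))
        summary[label] = {
            "n_calculable": int(len(vals)),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        }
        for q in _VIOLIN_QUANTILES:
            violin_rows.append(
                {"table": label, "quantile": q, "value": float(np.quantile(vals, q))}
            )
    return ScoreUtilityReport(
        score_name=score_name,
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        cohens_d=cohens_d(vo, vp),
        summary=summary,
        ecdf=pd.concat(frames, ignore_index=True),
        violin=pd.DataFrame(violin_rows),
    )
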