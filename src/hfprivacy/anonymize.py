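"""k-anonymization by microaggregation, generalization and suppression.

The protection target is k-anonymity (default k=2): every retained record's
quasi-identifier tuple must be shared with at least k-1 other records.  The
toolbox mirrors common anonymization practice for mixed clinical tables:

* numeric quasi-identifiers are *microaggregated* — clustered, then every
  member replaced by the cluster's geometric mean (arithmetic-mean fallback
  for non-positive values);
* NYHA class may be *generalized* to severity groups I/II and III/IV;
* binary quasi-identifiers are protected by *cell suppression* (individual
  entries removed; a missing marker is itself a quasi-identifier value);
* variables not needed downstream can be *attribute-suppressed* (dropped);
* records whose equivalence class cannot be brought to size >= k are
  *record-suppressed*.

A greedy, budgeted optimizer applies these in escalating order: categorical
quasi-identifiers are brought to k-anonymity first (generalize, then cell
suppress, then record suppress), after which the numeric quasi-identifiers
are microaggregated with one shared partition inside each categorical
equivalence class, so the *joint* quasi-identifier tuple provably occurs at
least k times.  Every action is logged in an audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, ConfigurationError

_MISSING_KEY = "\x00<NA>"  # sentinel: missing is a distinct QI value

#: NYHA severity generalization: lower (I, II) vs higher (III, IV)
NYHA_HIERARCHY = {"I": "I/II", "II": "I/II", "III": "III/IV", "IV": "III/IV"}


@dataclass
class Hierarchy:
    """Total mapping from categories to generalized labels."""

    mapping: dict

    def apply(self, value):
        if pd.isna(value):
            return value
        try:
            return self.mapping[value]
        except KeyError:
            raise ConfigurationError(f"category {value!r} not in hierarchy") from None


@dataclass
class AnonConfig:
    """Anonymizer settings.

    ``strategies`` maps variable name to one of {"microaggregate",
    "generalize", "cell_suppress", "attribute_suppress"}; unlisted
    quasi-identifiers default by kind (continuous -> microaggregate,
    nyha -> generalize, boolean -> cell_suppress).
    """

    k: int = 2
    quasi_identifiers: list | None = None  # None -> all schema variables
    strategies: dict = field(default_factory=dict)
    hierarchies: dict = field(default_factory=lambda: {"nyha": Hierarchy(NYHA_HIERARCHY)})
    iterations: int = 1000
    steps: int = 50000
    record_suppression_limit: float = 0.05

    def __post_init__(self):
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")
        if self.iterations <= 0 or self.steps <= 0:
            raise ConfigurationError("optimizer budget must be positive")


@dataclass
class AnonymizedTable:
    """Protected table plus audit trail and k-verification."""

    table: CohortTable
    audit: dict

    @property
    def k_achieved(self) -> int:
        return self.audit["k_achieved"]


# -- 1D microaggregation ---------------------------------------------------


def _optimal_contiguous_partition(cost, n: int, min_size: int) -> list:
    """DP over contiguous partitions of 0..n-1 with all parts >= min_size,
    minimizing total cost; cost(i, j) prices the part [i, j).  Returns the
    part boundaries.  Falls back to one part when n < min_size."""
    if n < min_size:
        return [(0, n)]
    INF = float("inf")
    best = [INF] * (n + 1)
    back = [0] * (n + 1)
    best[0] = 0.0
    for i in range(min_size, n + 1):
        # predecessor j: part [j, i) with i-j >= min_size and j == 0 or j >= min_size
        for j in range(0, i - min_size + 1):
            if j != 0 and j < min_size:
                continue
            if best[j] == INF:
                continue
            c = best[j] + cost(j, i)
            if c < best[i] - 1e-15:
                best[i] = c
                back[i] = j
    bounds = []
    i = n
    while i > 0:
        j = back[i]
        bounds.append((j, i))
        i = j
    return bounds[::-1]


def _sse_cost(prefix, prefix2):
    def cost(i, j):
        m = j - i
        s = prefix[j] - prefix[i]
        s2 = prefix2[j] - prefix2[i]
        return s2 - s * s / m

    return cost


def microaggregate(values, min_size: int) -> tuple:
    """Cluster a numeric vector into groups of size >= min_size and replace
    each value with its cluster's geometric mean.

    Clustering sorts the values (stable on (value, index)) and chooses the
    contiguous partition minimizing within-cluster sum of squared deviations
    of log-values — the geometric mean is the natural centroid in log space.
    Vectors containing non-positive values fall back to arithmetic means on
    the raw scale (flagged in the returned assignment metadata).

    Returns ``(assignment, replaced)``: integer cluster ids (in sorted-value
    order) and the replaced vector, both aligned with the input order.
    """
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    if n == 0:
        return np.empty(0, dtype=int), vals.copy()
    if np.isnan(vals).any():
        raise ConfigurationError("microaggregate does not accept missing values")
    use_log = bool((vals > 0).all())
    order = np.lexsort((np.arange(n), vals))
    work = np.log(vals[order]) if use_log else vals[order]
    prefix = np.concatenate(([0.0], np.cumsum(work)))
    prefix2 = np.concatenate(([0.0], np.cumsum(work**2)))
    bounds = _optimal_contiguous_partition(_sse_cost(prefix, prefix2), n, min_size)
    assignment = np.empty(n, dtype=int)
    replaced = np.empty(n, dtype=float)
    for cid, (i, j) in enumerate(bounds):
        idx = order[i:j]
        centroid = np.mean(work[i:j])
        assignment[idx] = cid
        replaced[idx] = np.exp(centroid) if use_log else centroid
    return assignment, replaced


def generalize(column: pd.Series, hierarchy: Hierarchy) -> pd.Series:
    """Replace each cell with its generalized label; missing stays missing."""
    return column.map(hierarchy.apply)


# -- k verification / enforcement -----------------------------------------


def _key_frame(df: pd.DataFrame, qis) -> pd.Series:
    keyed = df[list(qis)].astype(object).where(df[list(qis)].notna(), _MISSING_KEY)
    return pd.Series(list(map(tuple, keyed.itertuples(index=False, name=None))), index=df.index)


def verify_k(table: CohortTable, quasi_identifiers=None) -> int:
    """Exact minimum multiplicity of quasi-identifier tuples (0 if empty)."""
    qis = list(quasi_identifiers) if quasi_identifiers else table.schema.names
    missing = set(qis) - set(table.schema.names)
    if missing:
        raise ConfigurationError(f"quasi-identifiers not in schema: {sorted(missing)}")
    if table.n_rows == 0:
        return 0
    return int(_key_frame(table.df, qis).value_counts().min())


def enforce_k(table: CohortTable, quasi_identifiers, k: int) -> tuple:
    """Drop every record whose quasi-identifier class has size < k.

    Returns ``(table, audit)`` where audit lists the suppressed row
    positions.  Greedy-minimal: only records in violating classes go.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    keys = _key_frame(table.df, quasi_identifiers)
    sizes = keys.map(keys.value_counts())
    keep = sizes >= k
    out = CohortTable(table.schema, table.df.loc[keep].reset_index(drop=True))
    audit = {
        "suppressed_records": int((~keep).sum()),
        "suppressed_row_positions": [int(i) for i in np.flatnonzero(~keep.to_numpy())],
    }
    return out, audit


# -- full anonymization pipeline ------------------------------------------


def _default_strategy(spec) -> str:
    if spec.kind == "continuous":
        return "microaggregate"
    if spec.name == "nyha":
        return "generalize"
    return "cell_suppress"


def anonymize(table: CohortTable, config: AnonConfig | None = None) -> AnonymizedTable:
    """Protect a table to k-anonymity over its quasi-identifiers.

    Escalation order (each step budgeted and logged): generalize NYHA if
    needed -> cell-suppress binary quasi-identifiers of violating records,
    one column per pass -> record-suppress irreducible violators; then
    microaggregate numeric quasi-identifiers with a shared partition inside
    each categorical equivalence class.  Deterministic.
    """
    config = config if config is not None else AnonConfig()
    qis = list(config.quasi_identifiers) if config.quasi_identifiers else table.schema.names
    unknown = set(qis) - set(table.schema.names)
    if unknown:
        raise ConfigurationError(f"quasi-identifiers not in schema: {sorted(unknown)}")
    strategies = {
        name: config.strategies.get(name, _default_strategy(table.schema[name]))
        for name in qis
    }

    audit = {
        "k": config.k,
        "quasi_identifiers": qis,
        "strategies": strategies,
        "generalization_applied": {},
        "suppressed_cells": 0,
        "suppressed_records": 0,
        "attribute_suppressed": [],
        "clusters": {},
        "arithmetic_mean_fallback": [],
        "warnings": [],
        "steps_used": 0,
    }

    df = table.df.copy()
    schema = table.schema

    # attribute suppression: drop the column entirely
    drop = [n for n, s in strategies.items() if s == "attribute_suppress"]
    if drop:
        keep_names = [n for n in schema.names if n not in drop]
        schema = schema.subset(keep_names)
        df = df[keep_names]
        qis = [q for q in qis if q not in drop]
        audit["attribute_suppressed"] = drop

    numeric_qis = [q for q in qis if strategies[q] == "microaggregate"]
    cat_qis = [q for q in qis if q not in numeric_qis]

    n_input = len(df)
    steps = 0

    # --- stage A: k-anonymity of the categorical quasi-identifiers -------
    suppress_order = [q for q in cat_qis if strategies[q] == "cell_suppress"]
    gen_candidates = [q for q in cat_qis if strategies[q] == "generalize"]
    next_suppress = 0
    for _ in range(config.iterations):
        if not cat_qis:
            break
        keys = _key_frame(df, cat_qis)
        sizes = keys.map(keys.value_counts())
        steps += len(df)
        violating = sizes < config.k
        if not violating.any() or steps >= config.steps:
            break
        progressed = False
        for q in gen_candidates:
            if audit["generalization_applied"].get(q):
                continue
            df[q] = generalize(df[q], config.hierarchies[q])
            audit["generalization_applied"][q] = True
            progressed = True
            break
        if progressed:
            continue
        if next_suppress < len(suppress_order):
            q = suppress_order[next_suppress]
            next_suppress += 1
            n_cells = int((violating & df[q].notna()).sum())
            if n_cells:
                col = df[q].copy()
                col[violating] = np.nan
                df[q] = col
                audit["suppressed_cells"] += n_cells
            continue
        break  # options exhausted; fall through to record suppression
    audit["steps_used"] = steps

    if cat_qis and len(df):
        keys = _key_frame(df, cat_qis)
        keep = keys.map(keys.value_counts()) >= config.k
        audit["suppressed_records"] += int((~keep).sum())
        df = df.loc[keep]

    # --- stage B: shared-partition microaggregation of numeric QIs -------
    if numeric_qis and len(df):
        cat_key = (
            _key_frame(df, cat_qis)
            if cat_qis
            else pd.Series([()] * len(df), index=df.index)
        )
        # records must also agree on their numeric-missingness pattern
        miss_pattern = df[numeric_qis].isna().apply(tuple, axis=1)
        group_key = pd.Series(list(zip(cat_key, miss_pattern)), index=df.index)
        group_sizes = group_key.map(group_key.value_counts())
        drop_mask = group_sizes < config.k
        if drop_mask.any():
            audit["suppressed_records"] += int(drop_mask.sum())
            df = df.loc[~drop_mask]
            group_key = group_key.loc[~drop_mask]
        pos = {label: i for i, label in enumerate(df.index)}
        cluster_labels = {q: np.full(len(df), -1, dtype=int) for q in numeric_qis}
        next_cluster = 0
        for _, idx in df.groupby(group_key, sort=False).groups.items():
            idx = np.asarray(idx)
            observed = [q for q in numeric_qis if not pd.isna(df.at[idx[0], q])]
            if not observed:
                continue
            block = df.loc[idx, observed].to_numpy(dtype=float)
            # shared partition: lexicographic order, cost summed over columns
            order = np.lexsort(
                tuple(block[:, c] for c in reversed(range(block.shape[1])))
            )
            use_log = bool((block > 0).all())
            if not use_log:
                for q in observed:
                    if q not in audit["arithmetic_mean_fallback"]:
                        audit["arithmetic_mean_fallback"].append(q)
            work_block = np.log(block[order]) if use_log else block[order]
            # standardize columns so no variable dominates the joint cost
            sd = work_block.std(axis=0)
            sd[sd == 0] = 1.0
            scaled = work_block / sd
            pref = np.vstack(
                [np.zeros(scaled.shape[1]), np.cumsum(scaled, axis=0)]
            )
            pref2 = np.vstack(
                [np.zeros(scaled.shape[1]), np.cumsum(scaled**2, axis=0)]
            )

            def cost(i, j):
                m = j - i
                s = pref[j] - pref[i]
                s2 = pref2[j] - pref2[i]
                return float(np.sum(s2 - s * s / m))

            bounds = _optimal_contiguous_partition(cost, len(idx), config.k)
            for i, j in bounds:
                members = idx[order[i:j]]
                centroid = work_block[i:j].mean(axis=0)
                repl = np.exp(centroid) if use_log else centroid
                for c, q in enumerate(observed):
                    df.loc[members, q] = repl[c]
                    cluster_labels[q][[pos[m] for m in members]] = next_cluster
                next_cluster += 1
        audit["clusters"] = {q: lab.tolist() for q, lab in cluster_labels.items()}

    # map retained output rows back to input row positions (audit trail;
    # also what aligned original-vs-anonymized comparisons need)
    audit["kept_row_positions"] = [int(i) for i in df.index]
    out = CohortTable(schema, df.reset_index(drop=True))
    audit["k_achieved"] = verify_k(out, qis)
    frac = audit["suppressed_records"] / max(n_input, 1)
    audit["record_suppression_fraction"] = frac
    if frac > config.record_suppression_limit:
        audit["warnings"].append(
            f"record suppression {frac:.1%} exceeds limit "
            f"{config.record_suppression_limit:.1%}"
        )
    if len(df) and audit["k_achieved"] < config.k:
        audit["warnings"].append("k-anonymity not reached")  # should not happen
    return AnonymizedTable(out, audit)


def cluster_entropy_loss(original, assignment) -> float:
    """Non-uniform-entropy-style information loss of a microaggregated
    column: sum over records of log2(cluster size / multiplicity of the
    record's original value within its cluster).  0 when clustering merges
    only identical values; grows with coarser clustering."""
    original = np.asarray(original)
    assignment = np.asarray(assignment)
    loss = 0.0
    for cid in np.unique(assignment):
        members = original[assignment == cid]
        _, counts = np.unique(members, return_counts=True)
        size = len(members)
        loss += float(np.sum(counts * np.log2(size / counts)))
    return loss
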