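"""Residual privacy risk estimation for protected tables.

Attack-based estimates follow the train/control paradigm: the input table
is split 1:1 into a training half (which the protection mechanism sees) and
a hold-out/control half (which it does not).  Randomized attacks —
singling out (univariate and multivariate predicates), linkage of two
auxiliary column fragments, and attribute inference — are mounted against
both halves; the excess success on the training half, normalized as
``max(0, (r_attack - r_control) / (1 - r_control))``, is the residual risk
in [0, 1].  Repetitions report mean and standard deviation.

Distance-based estimates (the hold-out approach) compute each protected
record's distance to the closest record (DCR, Gower distance) in the
training and hold-out sets: the *share* of records closer to training
(optimum 0.5) and the *median DCR ratio* (optimum 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, ConfigurationError
from .seeding import derive_seed


@dataclass
class SplitResult:
    """Disjoint 1:1 partition of a table into training and control."""

    training: CohortTable
    control: CohortTable
    seed: int


def split_train_control(table: CohortTable, seed: int) -> SplitResult:
    """Uniform random 1:1 partition (sizes differ by at most one)."""
    n = table.n_rows
    if n < 2:
        raise ConfigurationError("need at least 2 rows to split")
    rng = np.random.default_rng(derive_seed(seed, "split"))
    perm = rng.permutation(n)
    half = n // 2
    train_idx, ctrl_idx = np.sort(perm[: n - half]), np.sort(perm[n - half :])
    return SplitResult(
        training=CohortTable(table.schema, table.df.iloc[train_idx].reset_index(drop=True)),
        control=CohortTable(table.schema, table.df.iloc[ctrl_idx].reset_index(drop=True)),
        seed=seed,
    )


# -- Gower distance --------------------------------------------------------


def _ranges(schema, columns) -> dict:
    out = {}
    for name in columns:
        spec = schema[name]
        if spec.kind == "continuous":
            lo, hi = spec.plausible_range
            out[name] = hi - lo
    return out


def gower_distance(r1, r2, schema, columns=None) -> float:
    """Mixed-type record distance in [0, 1]: mean over variables of the
    range-scaled absolute difference (continuous) or 0/1 mismatch
    (categorical/boolean).  Both-missing variables are excluded; a
    one-sided missing counts as a full mismatch."""
    cols = list(columns) if columns is not None else schema.names
    ranges = _ranges(schema, cols)
    total, used = 0.0, 0
    for name in cols:
        a, b = r1[name], r2[name]
        a_miss, b_miss = pd.isna(a), pd.isna(b)
        if a_miss and b_miss:
            continue
        used += 1
        if a_miss or b_miss:
            total += 1.0
        elif name in ranges:
            total += min(abs(float(a) - float(b)) / ranges[name], 1.0)
        else:
            total += 0.0 if a == b else 1.0
    if used == 0:
        raise ConfigurationError("all comparisons missing")
    return total / used


def gower_matrix(a: CohortTable, b: CohortTable, columns=None) -> np.ndarray:
    """Pairwise Gower distances between the rows of two tables."""
    schema = a.schema
    cols = list(columns) if columns is not None else schema.names
    ranges = _ranges(schema, cols)
    na, nb = a.n_rows, b.n_rows
    total = np.zeros((na, nb))
    used = np.zeros((na, nb))
    for name in cols:
        if name in ranges:
            x = a.df[name].to_numpy(dtype=float)[:, None]
            y = b.df[name].to_numpy(dtype=float)[None, :]
            xm, ym = np.isnan(x), np.isnan(y)
            d = np.minimum(np.abs(x - y) / ranges[name], 1.0)
            d = np.where(xm | ym, 1.0, d)
            both = xm & ym
        else:
            xv = a.df[name].to_numpy(dtype=object)
            yv = b.df[name].to_numpy(dtype=object)
            xm = pd.isna(xv)[:, None]
            ym = pd.isna(yv)[None, :]
            d = (xv[:, None] != yv[None, :]).astype(float)
            d = np.where(xm | ym, 1.0, d)
            both = xm & ym
        total += np.where(both, 0.0, d)
        used += ~both
    if (used == 0).any():
        raise ConfigurationError("record pair with all comparisons missing")
    return total / used


# -- attack machinery ------------------------------------------------------


@dataclass
class AttackConfig:
    """Settings of the randomized privacy attacks."""

    n_attacks: int = 400
    repetitions: int = 50
    mode: str = "singling_out_multi"
    n_cols: int = 3
    aux_split: tuple | None = None  # (columns A, columns B) for linkage
    aux_cols: list | None = None  # inference auxiliary columns
    secret_col: str | None = None
    tolerance: float = 0.05  # fraction of range for numeric matching
    seed: int = 0

    def __post_init__(self):
        if self.n_attacks <= 0:
            raise ConfigurationError("n_attacks must be positive")
        if self.repetitions < 1:
            raise ConfigurationError("repetitions must be >= 1")


@dataclass
class RiskEstimate:
    """Normalized residual risk with repetition statistics."""

    risk: float
    sd: float
    per_repetition: list
    attack_rate: float
    control_rate: float
    flags: list = field(default_factory=list)

    def __str__(self) -> str:  # Table-2 style "mean (SD)"
        return f"{self.risk:.2f} ({self.sd:.2f})"

    def to_dict(self) -> dict:
        return {
            "risk": self.risk,
            "sd": self.sd,
            "per_repetition": self.per_repetition,
            "attack_rate": self.attack_rate,
            "control_rate": self.control_rate,
            "flags": self.flags,
        }


def normalize_risk(attack_rate: float, control_rate: float) -> float:
    """Excess attack success over the control baseline, clipped to [0, 1]."""
    for r in (attack_rate, control_rate):
        if not 0.0 <= r <= 1.0:
            raise ConfigurationError(f"rate {r} outside [0,1]")
    if control_rate >= 1.0:
        return 0.0  # degenerate: baseline already always succeeds
    return max(0.0, (attack_rate - control_rate) / (1.0 - control_rate))


def _single_estimate(attack_rate, control_rate, flags=None) -> RiskEstimate:
    risk = normalize_risk(attack_rate, control_rate)
    flags = list(flags or [])
    if control_rate >= 1.0:
        flags.append("degenerate_control")
    return RiskEstimate(
        risk=risk,
        sd=0.0,
        per_repetition=[risk],
        attack_rate=attack_rate,
        control_rate=control_rate,
        flags=flags,
    )


def _matches_univariate(df: pd.DataFrame, pred) -> int:
    col, op, val = pred
    s = df[col]
    if op == "==":
        return int((s == val).sum())
    if op == "<=":
        return int((s.astype(float) <= val).sum())
    return int((s.astype(float) >= val).sum())


def _matches_multivariate(df: pd.DataFrame, conds) -> int:
    mask = np.ones(len(df), dtype=bool)
    for col, lo, hi, val in conds:
        s = df[col]
        if val is not None:
            mask &= (s == val).to_numpy()
        else:
            x = s.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                mask &= ~np.isnan(x) & (x >= lo) & (x <= hi)
        if not mask.any():
            break
    return int(mask.sum())


def singling_out_risk(
    protected: CohortTable,
    training: CohortTable,
    control: CohortTable,
    cfg: AttackConfig,
    seed: int = 0,
) -> RiskEstimate:
    """Single repetition of the singling-out attack (uni- or multivariate).

    Predicates are generated from the protected table so that each matches
    exactly one protected record; an attack succeeds on a target table when
    the predicate also matches exactly one record there.
    """
    if cfg.mode not in ("singling_out_uni", "singling_out_multi"):
        raise ConfigurationError(f"bad mode {cfg.mode!r} for singling out")
    rng = np.random.default_rng(seed)
    schema = protected.schema
    cols = schema.names
    ranges = _ranges(schema, cols)
    preds = []
    seen = set()
    attempts = 0
    max_attempts = 20 * cfg.n_attacks
    pdf = protected.df
    while len(preds) < cfg.n_attacks and attempts < max_attempts:
        attempts += 1
        if cfg.mode == "singling_out_uni":
            # random (column, operator, value): equality on a random
            # protected value, or an extreme-value condition (<=/>= only
            # ever single out at the observed extremes)
            col = cols[rng.integers(len(cols))]
            vals = pdf[col].dropna()
            if vals.empty:
                continue
            if col in ranges:
                op = ("==", "<=", ">=")[rng.integers(3)]
                v = float(vals.iloc[rng.integers(len(vals))])
                pred = (col, op, v)
            else:
                pred = (col, "==", vals.iloc[rng.integers(len(vals))])
            if pred in seen:
                continue
            seen.add(pred)
            if _matches_univariate(pdf, pred) == 1:
                preds.append(("uni", pred))
        else:
            row = pdf.iloc[rng.integers(len(pdf))]
            chosen = list(rng.choice(len(cols), size=min(cfg.n_cols, len(cols)), replace=False))
            conds = []
            ok = True
            for ci in chosen:
                col = cols[ci]
                v = row[col]
                if pd.isna(v):
                    ok = False
                    break
                if col in ranges:
                    tol = cfg.tolerance * ranges[col]
                    conds.append((col, float(v) - tol, float(v) + tol, None))
                else:
                    conds.append((col, None, None, v))
            if not ok:
                continue
            key = tuple(conds)
            if key in seen:
                continue
            seen.add(key)
            if _matches_multivariate(pdf, conds) == 1:
                preds.append(("multi", conds))
    if not preds:
        return _single_estimate(0.0, 0.0, flags=["attack_not_successful"])

    def rate(target: CohortTable) -> float:
        hits = 0
        for kind, pred in preds:
            if kind == "uni":
                m = _matches_univariate(target.df, pred)
            else:
                m = _matches_multivariate(target.df, pred)
            hits += m == 1
        return hits / len(preds)

    return _single_estimate(rate(training), rate(control))


def _nearest_protected(targets: CohortTable, protected: CohortTable, columns) -> np.ndarray:
    d = gower_matrix(targets, protected, columns=columns)
    return d.argmin(axis=1)  # argmin resolves ties to the lowest index


def _sample_rows(table: CohortTable, n: int, rng) -> CohortTable:
    take = min(n, table.n_rows)
    idx = np.sort(rng.choice(table.n_rows, size=take, replace=False))
    return CohortTable(table.schema, table.df.iloc[idx].reset_index(drop=True))


def linkage_risk(
    protected: CohortTable,
    training: CohortTable,
    control: CohortTable,
    aux_split: tuple | None,
    cfg: AttackConfig,
    seed: int = 0,
) -> RiskEstimate:
    """Single repetition of the linkage attack: two disjoint auxiliary
    column fragments of a target record are each matched to their nearest
    protected record; linking succeeds when both point to the same one."""
    schema = protected.schema
    if aux_split is None:
        names = schema.names  # default: alternate columns
        aux_split = (names[0::2], names[1::2])
    cols_a, cols_b = list(aux_split[0]), list(aux_split[1])
    if not cols_a or not cols_b:
        raise ConfigurationError("both auxiliary column sets must be non-empty")
    rng = np.random.default_rng(seed)

    def rate(target_table: CohortTable) -> float:
        targets = _sample_rows(target_table, cfg.n_attacks, rng)
        na = _nearest_protected(targets, protected, cols_a)
        nb = _nearest_protected(targets, protected, cols_b)
        return float((na == nb).mean())

    return _single_estimate(rate(training), rate(control))


def inference_risk(
    protected: CohortTable,
    training: CohortTable,
    control: CohortTable,
    aux_cols: list,
    secret_col: str,
    cfg: AttackConfig,
    seed: int = 0,
) -> RiskEstimate:
    """Single repetition of the attribute-inference attack: the secret of a
    target record is predicted from its nearest protected record on the
    auxiliary columns; continuous secrets match within tolerance*range."""
    if secret_col in aux_cols:
        raise ConfigurationError("secret column must not be auxiliary")
    schema = protected.schema
    spec = schema[secret_col]
    secret_vals = protected.df[secret_col].dropna()
    if secret_vals.nunique() <= 1:
        return _single_estimate(0.0, 0.0, flags=["degenerate_secret"])
    rng = np.random.default_rng(seed)
    rng_cont = _ranges(schema, [secret_col]).get(secret_col)

    def rate(target_table: CohortTable) -> float:
        targets = _sample_rows(target_table, cfg.n_attacks, rng)
        nearest = _nearest_protected(targets, protected, aux_cols)
        guesses = protected.df[secret_col].to_numpy()[nearest]
        truth = targets.df[secret_col].to_numpy()
        if spec.kind == "continuous":
            g = guesses.astype(float)
            t = truth.astype(float)
            ok = ~np.isnan(g) & ~np.isnan(t) & (
                np.abs(g - t) <= cfg.tolerance * rng_cont
            )
        else:
            ok = np.array(
                [
                    (not pd.isna(a)) and (not pd.isna(b)) and a == b
                    for a, b in zip(guesses, truth)
                ]
            )
        return float(ok.mean())

    return _single_estimate(rate(training), rate(control))


def repeat_assessment(attack_fn, cfg: AttackConfig) -> RiskEstimate:
    """Run ``attack_fn(seed)`` for ``cfg.repetitions`` derived sub-seeds and
    report the mean (SD) of the per-repetition risks."""
    risks, attack_rates, control_rates, flags = [], [], [], []
    for i in range(cfg.repetitions):
        est = attack_fn(derive_seed(cfg.seed, "rep", i))
        risks.append(est.risk)
        attack_rates.append(est.attack_rate)
        control_rates.append(est.control_rate)
        for f in est.flags:
            if f not in flags:
                flags.append(f)
    arr = np.asarray(risks)
    return RiskEstimate(
        risk=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        per_repetition=[float(r) for r in risks],
        attack_rate=float(np.mean(attack_rates)),
        control_rate=float(np.mean(control_rates)),
        flags=flags,
    )


# -- hold-out (DCR) approach ----------------------------------------------


@dataclass
class DCRReport:
    """Distance-to-closest-record membership-risk metrics."""

    share: float
    median_dcr_ratio: float
    median_dcr_training: float
    median_dcr_holdout: float
    ratio_infinite: bool = False
    distance: str = "gower"

    def to_dict(self) -> dict:
        return {
            "share": self.share,
            "median_dcr_ratio": self.median_dcr_ratio,
            "median_dcr_training": self.median_dcr_training,
            "median_dcr_holdout": self.median_dcr_holdout,
            "ratio_infinite": self.ratio_infinite,
            "distance": self.distance,
        }


def dcr_metrics(
    protected: CohortTable,
    training: CohortTable,
    holdout: CohortTable,
    columns=None,
) -> DCRReport:
    """Share of protected records closer to training than hold-out (exact
    ties credit 0.5) and the ratio of median closest-record distances.

    For data independent of both reference sets the share is ~0.5 and the
    ratio ~1.0; deviations indicate residual membership signal.
    """
    if protected.n_rows == 0:
        raise ConfigurationError("empty protected set")
    if training.n_rows == 0 or holdout.n_rows == 0:
        raise ConfigurationError("training and holdout must be non-empty")
    d_train = gower_matrix(protected, training, columns=columns).min(axis=1)
    d_hold = gower_matrix(protected, holdout, columns=columns).min(axis=1)
    share = float((d_train < d_hold).mean() + 0.5 * (d_train == d_hold).mean())
    med_t = float(np.median(d_train))
    med_h = float(np.median(d_hold))
    infinite = med_h == 0.0
    ratio = float("inf") if infinite and med_t > 0 else (1.0 if infinite else med_t / med_h)
    return DCRReport(
        share=share,
        median_dcr_ratio=ratio,
        median_dcr_training=med_t,
        median_dcr_holdout=med_h,
        ratio_infinite=infinite,
    )
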