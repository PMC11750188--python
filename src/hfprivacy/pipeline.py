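"""End-to-end orchestration: generate/ingest -> clean -> score subset ->
protect (anonymize / synthesize / combined) -> score -> utility + privacy
reports, with one master seed fanning out to per-stage sub-seeds and a run
manifest sufficient to re-run bit-identically."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .anonymize import AnonConfig, anonymize, verify_k
from .cohort import CohortTable, ConfigurationError, GeneratorConfig, generate_cohort
from .preprocess import clean, score_subset
from .privacy import (
    AttackConfig,
    dcr_metrics,
    inference_risk,
    linkage_risk,
    repeat_assessment,
    singling_out_risk,
    split_train_control,
)
from .scores import load_biohf, load_maggic
from .seeding import derive_seed
from .synthesize import SynthConfig, fit_copula, sample
from .utility import compare_variables, overall_quality, score_utility

log = logging.getLogger(__name__)

ATTACK_MODES = ("linkage", "singling_out_uni", "singling_out_multi", "inference")
METHODS = ("anonymize", "synthesize", "combined")


@dataclass
class ProtectionMethod:
    """A protection recipe: anonymize, synthesize, or anonymize-then-
    synthesize (combined)."""

    name: str
    anon: AnonConfig | None = None
    synth: SynthConfig | None = None

    def __post_init__(self):
        if self.name not in METHODS:
            raise ConfigurationError(f"unknown method {self.name!r}")
        if self.name in ("anonymize", "combined") and self.anon is None:
            self.anon = AnonConfig()
        if self.name in ("synthesize", "combined") and self.synth is None:
            self.synth = SynthConfig()


def protect(table: CohortTable, method: ProtectionMethod, seed: int) -> tuple:
    """Apply a protection method; returns ``(protected_table, audit)``.

    The combined method aborts before synthesis if the anonymized training
    table fails k-verification, so the synthesizer never sees data below
    the k-anonymity guarantee.
    """
    audit = {"method": method.name, "seed": int(seed)}
    if method.name == "anonymize":
        res = anonymize(table, method.anon)
        audit["anonymize"] = _slim_audit(res.audit)
        return res.table, audit
    if method.name == "synthesize":
        model = fit_copula(table, derive_seed(seed, "fit"))
        n = method.synth.n_samples or table.n_rows
        out = sample(model, n, derive_seed(seed, "sample"))
        audit["synthesize"] = {"model": model.name, "n_samples": n, **model.fingerprint}
        return out, audit
    # combined: anonymize first, verify, then synthesize from the result
    res = anonymize(table, method.anon)
    k_ok = res.k_achieved >= method.anon.k if res.table.n_rows else False
    audit["anonymize"] = _slim_audit(res.audit)
    audit["k_verified_before_synthesis"] = bool(k_ok)
    if not k_ok:
        raise ConfigurationError(
            "combined method aborted: anonymized table fails k-verification"
        )
    model = fit_copula(res.table, derive_seed(seed, "fit"))
    n = method.synth.n_samples or table.n_rows
    out = sample(model, n, derive_seed(seed, "sample"))
    audit["synthesize"] = {"model": model.name, "n_samples": n, **model.fingerprint}
    return out, audit


def _slim_audit(a: dict) -> dict:
    slim = {k: v for k, v in a.items() if k != "clusters"}
    slim["n_numeric_clusters"] = (
        len(set().union(*[set(v) for v in a["clusters"].values()]))
        if a.get("clusters")
        else 0
    )
    return slim


@dataclass
class RunConfig:
    """Configuration of a full workflow run."""

    seed: int = 0
    out_dir: str = "out"
    input_csv: str | None = None  # None -> generate a synthetic cohort
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    scores: tuple = ("BioHF", "MAGGIC")
    methods: tuple = METHODS
    k: int = 2
    n_attacks: int = 400
    repetitions: int = 50
    secret_col: str = "lvef"


def _load_input(cfg: RunConfig) -> CohortTable:
    from .schema import default_schema

    if cfg.input_csv:
        return CohortTable.from_csv(cfg.input_csv, default_schema())
    gen = cfg.generator
    gen.seed = derive_seed(cfg.seed, "generate")
    return generate_cohort(default_schema(), gen)


def _score_definition(score_id: str):
    if score_id == "BioHF":
        return load_biohf()
    table, lut = load_maggic()

    class _MaggicProb:  # adapter: MAGGIC points + mortality lookup -> probability
        name = "MAGGIC"

        def compute(self, record, horizon=1):
            return lut(table.compute(record))

    return _MaggicProb()


def evaluate_privacy(
    protected: CohortTable,
    training: CohortTable,
    control: CohortTable,
    cfg: AttackConfig,
    secret_col: str = "lvef",
) -> dict:
    """All four attack scenarios plus the hold-out DCR metrics."""
    out = {}
    for mode in ATTACK_MODES:
        mode_cfg = AttackConfig(
            n_attacks=cfg.n_attacks,
            repetitions=cfg.repetitions,
            mode=mode,
            n_cols=cfg.n_cols,
            tolerance=cfg.tolerance,
            seed=derive_seed(cfg.seed, "attack", mode),
        )
        if mode.startswith("singling"):
            fn = lambda s, m=mode_cfg: singling_out_risk(protected, training, control, m, s)
        elif mode == "linkage":
            fn = lambda s, m=mode_cfg: linkage_risk(protected, training, control, None, m, s)
        else:
            sec = secret_col if secret_col in protected.schema else protected.schema.names[-1]
            aux = [n for n in protected.schema.names if n != sec]
            fn = lambda s, m=mode_cfg, a=aux, sc=sec: inference_risk(
                protected, training, control, a, sc, m, s
            )
        out[mode] = repeat_assessment(fn, mode_cfg).to_dict()
    out["dcr"] = dcr_metrics(protected, training, control).to_dict()
    return out


def run_all(cfg: RunConfig) -> dict:
    """Execute the full workflow for every score and protection method.

    Writes ``out/<score>/<method>/{data.csv, audit.json, utility.json,
    privacy.json}`` plus a top-level ``manifest.json`` and returns the
    manifest dict.
    """
    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    raw = _load_input(cfg)
    cleaned = clean(raw)
    manifest = {
        "seed": cfg.seed,
        "input": {
            "source": cfg.input_csv or "generated",
            "n_rows": raw.n_rows,
            "fingerprint": _fingerprint(raw),
        },
        "parameters": {
            "k": cfg.k,
            "n_attacks": cfg.n_attacks,
            "repetitions": cfg.repetitions,
            "methods": list(cfg.methods),
            "scores": list(cfg.scores),
        },
        "artifacts": {},
    }
    for score_id in cfg.scores:
        subset = score_subset(cleaned, score_id)
        definition = _score_definition(score_id)
        split = split_train_control(subset, derive_seed(cfg.seed, "split", score_id))
        for method_name in cfg.methods:
            mdir = out_root / score_id / method_name
            mdir.mkdir(parents=True, exist_ok=True)
            method = ProtectionMethod(
                name=method_name, anon=AnonConfig(k=cfg.k) if method_name != "synthesize" else None
            )
            seed_m = derive_seed(cfg.seed, "protect", score_id, method_name)
            protected, audit = protect(split.training, method, seed_m)
            if method_name != "synthesize":
                audit["k_achieved"] = verify_k(protected)
            protected.to_csv(mdir / "data.csv")
            (mdir / "audit.json").write_text(json.dumps(audit, indent=1))
            quality = overall_quality(split.training, protected)
            comparison = compare_variables(split.training, protected)
            score_rep = score_utility(
                split.training, protected, definition, score_name=score_id
            )
            score_rep.ecdf.to_csv(mdir / "score_ecdf.csv", index=False)
            score_rep.violin.to_csv(mdir / "score_violin.csv", index=False)
            utility_doc = {
                "quality": quality.to_dict(),
                "comparison": comparison.to_dict(),
                "score": score_rep.to_dict(),
            }
            (mdir / "utility.json").write_text(json.dumps(utility_doc, indent=1))
            privacy_doc = evaluate_privacy(
                protected,
                split.training,
                split.control,
                AttackConfig(
                    n_attacks=cfg.n_attacks,
                    repetitions=cfg.repetitions,
                    seed=derive_seed(cfg.seed, "privacy", score_id, method_name),
                ),
                secret_col=cfg.secret_col,
            )
            (mdir / "privacy.json").write_text(json.dumps(privacy_doc, indent=1))
            manifest["artifacts"][f"{score_id}/{method_name}"] = {
                "data": str(mdir / "data.csv"),
                "audit": str(mdir / "audit.json"),
                "utility": str(mdir / "utility.json"),
                "privacy": str(mdir / "privacy.json"),
                "protect_seed": seed_m,
            }
    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _fingerprint(table: CohortTable) -> str:
    h = hashlib.sha256()
    h.update(",".join(table.schema.names).encode())
    h.update(table.df.to_csv(index=False).encode())
    return h.hexdigest()[:16]


__all__ = [
    "ATTACK_MODES",
    "METHODS",
    "ProtectionMethod",
    "RunConfig",
    "evaluate_privacy",
    "protect",
    "run_all",
]
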