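#!/usr/bin/env python
"""Step 2 — protect the BioHF training half three ways.

Splits the BioHF subset 1:1 into training and hold-out halves, then
protects the training half by (i) k-anonymization (k=2), (ii) Gaussian-
copula synthesis, and (iii) the combined anonymize-then-synthesize method.
Writes each protected table and its audit under results/protected/ and the
split halves under results/ for the evaluation steps.
"""

import argparse
import json
from pathlib import Path

from hfprivacy import CohortTable, ProtectionMethod, protect, split_train_control
from hfprivacy.pipeline import METHODS
from hfprivacy.schema import default_schema
from hfprivacy.seeding import derive_seed


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    schema_b = default_schema().subset(default_schema().flagged("B"))
    subset = CohortTable.from_csv(args.results / "subset_biohf.csv", schema_b)
    split = split_train_control(subset, derive_seed(args.seed, "split"))
    split.training.to_csv(args.results / "training.csv")
    split.control.to_csv(args.results / "control.csv")
    print(f"split: {split.training.n_rows} training / {split.control.n_rows} hold-out")

    outdir = args.results / "protected"
    outdir.mkdir(exist_ok=True)
    for method in METHODS:
        protected, audit = protect(
            split.training,
            ProtectionMethod(method),
            derive_seed(args.seed, "protect", method),
        )
        protected.to_csv(outdir / f"{method}.csv")
        (outdir / f"{method}_audit.json").write_text(json.dumps(audit, indent=1))
        extra = ""
        if "anonymize" in audit:
            a = audit["anonymize"]
            extra = (
                f" (suppressed {a['suppressed_records']} records, "
                f"{a['suppressed_cells']} cells; k={a['k_achieved']})"
            )
        print(f"{method}: {protected.n_rows} records{extra}")


if __name__ == "__main__":
    main()
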