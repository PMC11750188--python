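#!/usr/bin/env python
"""Step 4 — residual privacy risk of each protected table.

Mounts the four attack scenarios (linkage, univariate and multivariate
singling out, attribute inference) with repetition statistics against the
training/hold-out halves, and computes the hold-out share and median DCR
ratio.  Prints a risk table in mean (SD) form, one row per attack and one
column per protection method.
"""

import argparse
import json
from pathlib import Path

from hfprivacy import AttackConfig, CohortTable
from hfprivacy.pipeline import ATTACK_MODES, METHODS, evaluate_privacy
from hfprivacy.schema import default_schema
from hfprivacy.seeding import derive_seed


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--n-attacks", type=int, default=400)
    ap.add_argument("--reps", type=int, default=10)
    args = ap.parse_args()

    schema_b = default_schema().subset(default_schema().flagged("B"))
    training = CohortTable.from_csv(args.results / "training.csv", schema_b)
    control = CohortTable.from_csv(args.results / "control.csv", schema_b)
    outdir = args.results / "privacy"
    outdir.mkdir(exist_ok=True)

    table = {}
    for method in METHODS:
        protected = CohortTable.from_csv(
            args.results / "protected" / f"{method}.csv", schema_b
        )
        doc = evaluate_privacy(
            protected,
            training,
            control,
            AttackConfig(
                n_attacks=args.n_attacks,
                repetitions=args.reps,
                seed=derive_seed(args.seed, "privacy", method),
            ),
        )
        (outdir / f"{method}.json").write_text(json.dumps(doc, indent=1))
        table[method] = doc

    header = f"{'attack':24s}" + "".join(f"{m:>14s}" for m in METHODS)
    print(header)
    for mode in ATTACK_MODES:
        cells = "".join(
            f"{table[m][mode]['risk']:.2f} ({table[m][mode]['sd']:.2f})".rjust(14)
            for m in METHODS
        )
        print(f"{mode:24s}{cells}")
    print(f"{'share':24s}" + "".join(f"{table[m]['dcr']['share']:.2f}".rjust(14) for m in METHODS))
    print(
        f"{'median DCR ratio':24s}"
        + "".join(f"{table[m]['dcr']['median_dcr_ratio']:.2f}".rjust(14) for m in METHODS)
    )


if __name__ == "__main__":
    main()
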