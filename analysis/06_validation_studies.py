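#!/usr/bin/env python
"""Seeded calibration studies for the whole pipeline.

Runs the validation experiments (rate-asymmetry recovery and power, LRT
type-I error, stepping-stone accuracy against quadrature, leaf-coding round
trip, parsimony-vs-enumeration agreement) at reduced replicate counts for a
quick look; the full-size versions run in scripts/acceptance.py.  Writes
results/validation_summary.json.
"""

import json
from pathlib import Path

from traitlink.validation import (asymmetry_recovery_experiment,
                                  coding_roundtrip_experiment,
                                  parsimony_agreement_experiment,
                                  stepping_stone_accuracy_experiment,
                                  type1_error_experiment)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = {
        "asymmetry_recovery": asymmetry_recovery_experiment(
            n_replicates=10, n_tips=300, seed=1),
        "type1_error": type1_error_experiment(n_datasets=40, n_tips=100, seed=2),
        "stepping_stone": stepping_stone_accuracy_experiment(seed=3),
        "coding_roundtrip": coding_roundtrip_experiment(n_species=200, seed=4),
        "parsimony_agreement": parsimony_agreement_experiment(n_trees=40, seed=5),
    }
    print(json.dumps(out, indent=2))
    (ROOT / "validation_summary.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
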