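#!/usr/bin/env python
"""Generate the four named synthetic fixtures with their ground truth.

Writes Newick trees, trait tables, leaf-measurement tables and truth JSON
under results/fixtures/.  These bundles are the inputs for the downstream
analysis steps; every file regenerates bit-identically from the embedded
seeds.
"""

from pathlib import Path

from traitlink.simulate import SCENARIOS, make_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    for name in sorted(SCENARIOS):
        truth = make_fixture(name, OUT)
        print(f"{name}: {truth['n_tips']} tips, model={truth['model']}, "
              f"seed={truth['seed']}")
    print(f"\nfixtures written to {OUT}")


if __name__ == "__main__":
    main()
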