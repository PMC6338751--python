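#!/usr/bin/env python
"""Parameter-recovery and oracle-agreement experiments: round-trip filter
inversion, brute-force equivalence, TCR-fraction recovery, expression-coupling
sign structure, and per-sample relative-damage recovery. Writes one JSON of
measured quantities."""

import json
from pathlib import Path

from strandrepair import experiments as ex

ROOT = Path(__file__).resolve().parents[1]
SEED = 2026


def main() -> None:
    out = {
        "roundtrip": ex.roundtrip_recovery(SEED),
        "oracle_agreement": ex.filter_oracle_agreement(SEED),
        "tcr_recovery": ex.tcr_recovery(SEED),
        "expression_sign_structure": ex.expression_sign_structure(SEED),
        "relative_damage_recovery": ex.relative_damage_recovery(SEED),
        "normalization_invariants": ex.normalization_invariants(SEED),
        "qc_fidelity": ex.qc_fidelity(),
        "mito_contrast": ex.mito_contrast_demo(SEED),
    }
    path = ROOT / "results" / "validation.json"
    path.parent.mkdir(exist_ok=True)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
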