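#!/usr/bin/env python
"""Parameter-recovery studies: how well can the delayed model's
physiology be read back from its own data?

Two conditions, ten subjects each, ground truth drawn log-uniformly
within the reported interquartile boxes with delays of 10-50 s:

* noiseless records generated by the identification recursion itself --
  isolates the optimiser: recovery should be exact;
* the same plus 0.5 mmHg Gaussian measurement noise -- isolates the
  information content of trend data.

Found in a typical run: noiseless recovery is exact (delay recovered
sample-exactly, rates to ~1e-13).  Under noise the metabolic rate and
tissue volume stay within ~2% and ~12%, but lung volume and cardiac
output degrade to tens of percent and the delay estimate scatters across
the grid: the delay enters the regression almost collinearly with the
other terms, so trend noise erases it (docs/methods.md, 'Identifiability
of the transport delay').
"""

import json
from pathlib import Path

from co2exchange.studies import recovery_study

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = {}
    for label, noise in (("noiseless", 0.0), ("noisy_0p5mmHg", 0.5)):
        res = recovery_study(n_subjects=10, noise_sd=noise, seed=42)
        out[label] = res
        print(f"{label}:")
        print(f"  delay exact: {res['n_tau_exact']}/10, within +/-1 sample: "
              f"{res['n_tau_within_1']}/10")
        print("  median relative errors: "
              + "  ".join(f"{k}={v:.3g}" for k, v in res["median_rel_err"].items()))
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "recovery_study.json", "w") as f:
        json.dump(out, f, indent=1,
                  default=lambda o: o.item() if hasattr(o, "item") else str(o))
    print(f"-> {RESULTS / 'recovery_study.json'}")


if __name__ == "__main__":
    main()
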