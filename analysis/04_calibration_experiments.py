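#!/usr/bin/env python
"""Monte-Carlo calibration of the two phylogenetic-signal estimators.

Verifies on freshly simulated data that the standardised Fritz–Purvis D
averages ~0 for Brownian-threshold binaries and ~1 for shuffled ones, and
that ML Pagel's lambda recovers 1 under pure Brownian traits and 0 after
tip shuffling. Writes the summary to results/calibration.tsv.
"""

from pathlib import Path

import pandas as pd

from mastphylo.calibration import dstat_calibration, lambda_recovery

ROOT = Path(__file__).resolve().parents[1]


def main():
    rows = []
    for mode, label in (("brownian_threshold", "D_stat | Brownian threshold"),
                        ("shuffle", "D_stat | shuffled")):
        d = dstat_calibration(mode, n_rep=200, n_tips=100, n_sim=500, seed=1)
        rows.append({"experiment": label, "mean": d.mean(), "sd": d.std(),
                     "n_rep": len(d)})
    for regime, label in (("brownian", "lambda | Brownian"),
                          ("shuffle", "lambda | shuffled")):
        l = lambda_recovery(regime, n_rep=200, n_tips=200, seed=2)
        rows.append({"experiment": label, "mean": l.mean(), "sd": l.std(),
                     "n_rep": len(l)})
    tab = pd.DataFrame(rows)
    out = ROOT / "results" / "calibration.tsv"
    out.parent.mkdir(exist_ok=True)
    tab.to_csv(out, sep="\t", index=False, float_format="%.4f")
    print(tab.to_string(index=False))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
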