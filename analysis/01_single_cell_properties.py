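#!/usr/bin/env python
"""Characterize the four tuned cell types: f-I curves and adaptation decay.

Writes results/cells_fi.tsv (rate vs injected current per type) and prints
the rheobase and the post-spike adaptation-current decay scale for the
pyramidal model (the clock behind the theta-interval spiking).
"""

import argparse
from pathlib import Path
from dataclasses import replace

import numpy as np
import pandas as pd

from ca3theta.cells import fi_curve, load_cell_catalog, rheobase

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

catalog = load_cell_catalog()
rows = []
for name in ("ca3_pyr", "dg_gc", "olm", "bc"):
    p = replace(catalog[name], h_enabled=False)
    rhb = rheobase(p)
    I = rhb * np.array([0.8, 1.0, 1.2, 1.5, 2.0, 3.0])
    rates = fi_curve(p, I)
    print(f"{name}: rheobase {rhb:.0f} pA; rates at (1.2, 2, 3)x rheobase = "
          f"{rates[2]:.1f}, {rates[4]:.1f}, {rates[5]:.1f} Hz")
    for i, r in zip(I, rates):
        rows.append((name, i, r))
pd.DataFrame(rows, columns=["cell_type", "I_pA", "rate_hz"]).to_csv(
    args.out / "cells_fi.tsv", sep="\t", index=False)

# adaptation decay after a spike (free decay at rest)
for a, label in ((0.01, "baseline (tau 100 ms)"), (0.04, "fast (tau 25 ms)"),
                 (0.1, "inactivated (tau 10 ms)")):
    t95 = -np.log(0.05) / a
    print(f"a={a} {label}: u decays to 5% of its jump in {t95:.0f} ms")
print(f"wrote {args.out/'cells_fi.tsv'}")
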