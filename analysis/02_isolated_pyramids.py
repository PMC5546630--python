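#!/usr/bin/env python
"""Theta spiking oscillations in fully disconnected CA3 pyramidal cells.

Each cell receives its own lognormal-rate (50 +/- 40 Hz) Poisson train;
the population spike-count spectrum and pooled inter-spike intervals are
computed over several network instantiations, at baseline adaptation
(a = 0.01, ~100 ms recovery) and with fast adaptation (a = 0.04), which
shifts the spiking oscillation to higher frequencies.
"""

import argparse
from pathlib import Path

from ca3theta.experiments import run_preset

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-seeds", type=int, default=10)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

for preset, label in (("fig4_isolated_pyr", "baseline adaptation"),
                      ("fig4d_fast_adaptation", "fast adaptation (a=0.04)")):
    res = run_preset(preset, args.seed, n_seeds=args.n_seeds)
    res["spectrum"].save(args.out / f"{preset}_spectrum.tsv",
                         args.out / f"{preset}_summary.json")
    print(f"{label}: spectral peak {res['peak_hz']:.1f} Hz, "
          f"mean rate {res['mean_rate_hz']:.2f} Hz, "
          f"pooled ISI mode {res['isi_mode_ms']:.0f} ms, "
          f"relative theta {res['relative_theta']:.3f}")
print(f"wrote spectra under {args.out}/")
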