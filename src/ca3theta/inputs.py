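"""Synthetic external drive: Poisson spike trains with place-cell statistics.

The study has no recorded data; all stimulus comes from here.  Two drive
modes stand in for the non-rhythmic component of medial-septal/entorhinal
afferents:

* a fixed 15 Hz Poisson train per EC cell (each cell gets a unique train), or
* direct drive to CA3 pyramidal cells at per-cell rates drawn from a
  lognormal distribution parameterized by its *arithmetic* mean and SD
  (50 +/- 40 Hz at baseline ACh; 20 +/- 20 low; 60 +/- 50 high), chosen so
  CA3 pyramidal firing reproduces the in-vivo place-cell rate distribution
  (right-skewed, mean ~7 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .utils import substream

__all__ = [
    "DriveConfig",
    "poisson_train",
    "lognormal_rates",
    "build_drive",
    "drive_table",
]

#: lognormal (mean, SD) of the direct-to-CA3 drive per cholinergic state
DIRECT_DRIVE_STATS = {0.0: (20.0, 20.0), 1.0: (50.0, 40.0), 2.0: (60.0, 50.0)}


@dataclass(frozen=True)
class DriveConfig:
    """External-input description for one target population."""

    target: str  # population id, e.g. "ec" or "ca3_pyr"
    base_rate: float | None = None  # fixed Hz per cell
    lognormal: tuple[float, float] | None = None  # (mean Hz, SD Hz) per cell
    duration: float = 5000.0  # ms
    transmission: float = 1.0

    def __post_init__(self):
        if (self.base_rate is None) == (self.lognormal is None):
            raise ValueError("specify exactly one of base_rate / lognormal")
        if self.base_rate is not None and self.base_rate < 0:
            raise ValueError("rate must be non-negative")
        if self.lognormal is not None and min(self.lognormal) <= 0:
            raise ValueError("lognormal mean and SD must be positive")


def poisson_train(rate: float, duration: float, rng) -> np.ndarray:
    """Homogeneous Poisson spike times (ms) on [0, duration)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0:
        return np.empty(0)
    n = rng.poisson(rate * duration / 1000.0)
    return np.sort(rng.uniform(0.0, duration, size=n))


def lognormal_rates(mean: float, sd: float, n: int, rng) -> np.ndarray:
    """Per-cell rates (Hz) with the given arithmetic mean and SD.

    The underlying normal parameters are moment-matched:
    sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2/2.
    """
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be positive and sd non-negative")
    if sd == 0:
        return np.full(n, mean)
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * s2
    return rng.lognormal(mean=mu, sigma=np.sqrt(s2), size=n)


def build_drive(cfg: DriveConfig, n_cells: int, seed: int) -> list[np.ndarray]:
    """One independent Poisson train per target cell; deterministic given seed."""
    rrng = substream(seed, f"input-rates:{cfg.target}")
    if cfg.base_rate is not None:
        rates = np.full(n_cells, cfg.base_rate)
    else:
        rates = lognormal_rates(*cfg.lognormal, n_cells, rrng)
    trains = []
    for i, r in enumerate(rates):
        rng = substream(seed, f"input-train:{cfg.target}:{i}")
        trains.append(poisson_train(float(r), cfg.duration, rng))
    return trains


def drive_table(trains: list[np.ndarray]) -> pd.DataFrame:
    """Two-column (cell id, time ms) spike table for replay or fixtures."""
    rows = [(i, t) for i, ts in enumerate(trains) for t in ts]
    return pd.DataFrame(rows, columns=["cell", "time_ms"])
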