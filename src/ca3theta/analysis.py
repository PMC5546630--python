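"""Spike-train analysis: population spectra, coherence, STAs, ISIs, rates.

The population power spectrum follows the spike-count convention: spikes of
all cells of a type are summed in 0.1 ms bins and the binned counts go
through Welch averaging with 1024 ms windows and 512 ms overlap (mean
subtracted per window, no taper by default; a Hann taper is available as a
robustness switch).  Spike counts act as a proxy for the LFP.  Pairwise
synchrony uses the Wang-Buzsaki coherence: two spikes are synchronous if
they fall in the same 5 ms bin, and the pair coherence is the zero-lag
normalized cross-correlation of the binned (0/1) trains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "SpectrumResult",
    "CoherenceResult",
    "bin_spikes",
    "population_spectrum",
    "relative_theta",
    "pairwise_coherence",
    "spike_triggered_average",
    "isi_histogram",
    "population_rate",
    "detect_peak",
]

BIN_MS = 0.1
WINDOW_MS = 1024.0
OVERLAP_MS = 512.0
THETA_BAND = (4.0, 12.0)
TOTAL_BAND = (0.0, 250.0)


@dataclass
class SpectrumResult:
    """Averaged population power spectrum."""

    freq: np.ndarray  # Hz
    power: np.ndarray
    sd: np.ndarray  # across instantiations (zeros for a single run)
    window_ms: float = WINDOW_MS
    overlap_ms: float = OVERLAP_MS
    bin_ms: float = BIN_MS
    n_instantiations: int = 1

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq_hz": self.freq, "power": self.power, "sd": self.sd})

    def summary(self, band=(1.0, 30.0)) -> dict:
        return {
            "peak_hz": detect_peak(self, band),
            "relative_theta": relative_theta(self),
            "n_instantiations": self.n_instantiations,
        }

    def save(self, table_path, summary_path=None, band=(1.0, 30.0)) -> None:
        self.to_frame().to_csv(table_path, sep="\t", index=False)
        if summary_path:
            with open(summary_path, "w") as fh:
                json.dump(self.summary(band), fh, indent=2)


@dataclass
class CoherenceResult:
    """Pairwise Wang-Buzsaki coherence over one population."""

    values: np.ndarray  # in [0, 1], one per retained pair
    pairs: np.ndarray  # (n_pairs, 2) cell indices
    distances: np.ndarray | None = None  # mm, longitudinal
    skipped: int = 0  # pairs dropped because one train was empty

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if len(self.values) else float("nan")


def bin_spikes(trains: list[np.ndarray], duration: float, bin_ms: float = BIN_MS) -> np.ndarray:
    """Summed spike counts of all cells in fixed-width bins."""
    n = int(round(duration / bin_ms))
    counts = np.zeros(n)
    for ts in trains:
        idx = np.minimum((np.asarray(ts) / bin_ms).astype(int), n - 1)
        np.add.at(counts, idx, 1)
    return counts


def _welch(counts: np.ndarray, bin_ms: float, window_ms: float, overlap_ms: float,
           taper: str):
    fs = 1000.0 / bin_ms
    nperseg = int(round(window_ms / bin_ms))
    noverlap = int(round(overlap_ms / bin_ms))
    win = "boxcar" if taper == "none" else taper
    freq, pxx = sps.welch(counts, fs=fs, window=win, nperseg=nperseg,
                          noverlap=noverlap, detrend="constant")
    return freq, pxx


def population_spectrum(
    spikes,
    population: str,
    bin_ms: float = BIN_MS,
    window_ms: float = WINDOW_MS,
    overlap_ms: float = OVERLAP_MS,
    taper: str = "none",
) -> SpectrumResult:
    """Welch-averaged spike-count spectrum, averaged across instantiations.

    ``spikes`` is one SpikeData or a sequence of them (one per network
    instantiation); per-instantiation spectra are averaged with their SD.
    """
    runs = spikes if isinstance(spikes, (list, tuple)) else [spikes]
    if not runs:
        raise ValueError("no runs given")
    spectra = []
    freq = None
    for sd in runs:
        trains = sd.times[population]
        if not trains:
            raise ValueError(f"population {population} is empty")
        if sd.duration < window_ms:
            raise ValueError("run shorter than one spectral window")
        counts = bin_spikes(trains, sd.duration, bin_ms)
        freq, pxx = _welch(counts, bin_ms, window_ms, overlap_ms, taper)
        spectra.append(pxx)
    spectra = np.asarray(spectra)
    return SpectrumResult(
        freq=freq,
        power=spectra.mean(axis=0),
        sd=spectra.std(axis=0, ddof=0),
        window_ms=window_ms,
        overlap_ms=overlap_ms,
        bin_ms=bin_ms,
        n_instantiations=len(runs),
    )


def relative_theta(spectrum: SpectrumResult,
                   band=THETA_BAND, total=TOTAL_BAND) -> float:
    """Power in the theta band divided by total power (0-250 Hz)."""
    f, p = spectrum.freq, spectrum.power
    tot = p[(f >= total[0]) & (f <= total[1])].sum()
    if tot <= 0:
        raise ValueError("zero total power")
    th = p[(f >= band[0]) & (f <= band[1])].sum()
    return float(th / tot)


def detect_peak(spectrum: SpectrumResult, band=(1.0, 30.0),
                smooth_hz: float = 2.0) -> float:
    """Frequency of maximum smoothed power within ``band``.

    Smoothing is a moving average of ~2 Hz bandwidth (the spectra are read
    at ~1 Hz resolution, so this spans two bins); ties resolve to the lower
    frequency (first maximum).
    """
    f, p = spectrum.freq, spectrum.power
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any():
        raise ValueError(f"band {band} outside spectrum range")
    df = f[1] - f[0] if len(f) > 1 else 1.0
    w = max(1, int(round(smooth_hz / df)))
    if w % 2 == 0:
        w += 1  # symmetric kernel: no half-bin bias on sharp peaks
    if w > 1:
        p = np.convolve(p, np.ones(w) / w, mode="same")
    fb, pb = f[sel], p[sel]
    return float(fb[int(np.argmax(pb))])


def pairwise_coherence(
    spikes,
    population: str,
    window: float = 5.0,
    distances_from=None,
) -> CoherenceResult:
    """Wang-Buzsaki pairwise coherence over all cell pairs of a population.

    Pairs involving a silent cell are skipped (their normalization is
    undefined) and counted in ``skipped``.  If ``distances_from`` (a
    NetworkSpec) is given, longitudinal pair distances are attached.
    """
    runs = spikes if isinstance(spikes, (list, tuple)) else [spikes]
    sd0 = runs[0]
    n = len(sd0.times[population])
    if n < 2:
        raise ValueError("need at least two cells")
    nb = int(round(sd0.duration / window))
    binned = []
    for sd in runs:
        b = np.zeros((n, nb), dtype=bool)
        for i, ts in enumerate(sd.times[population]):
            if len(ts):
                b[i, np.minimum((np.asarray(ts) / window).astype(int), nb - 1)] = True
        binned.append(b)
    vals, pairs = [], []
    skipped = 0
    for i in range(n):
        for j in range(i + 1, n):
            num = den_i = den_j = 0.0
            ok = True
            for b in binned:
                si, sj = b[i].sum(), b[j].sum()
                if si == 0 or sj == 0:
                    ok = False
                    break
                num += float((b[i] & b[j]).sum())
                den_i += float(si)
                den_j += float(sj)
            if not ok:
                skipped += 1
                continue
            vals.append(num / np.sqrt(den_i * den_j))
            pairs.append((i, j))
    vals = np.asarray(vals)
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    dists = None
    if distances_from is not None and len(pairs):
        from .network import AXIS_LENGTH, POPULATION_TYPES

        region = POPULATION_TYPES[population][0]
        x = distances_from.layouts[region].longitudinal_norm(population) * AXIS_LENGTH
        dists = np.abs(x[pairs[:, 0]] - x[pairs[:, 1]])
    return CoherenceResult(values=vals, pairs=pairs, distances=dists, skipped=skipped)


def spike_triggered_average(
    triggers: np.ndarray,
    trace: np.ndarray,
    dt: float,
    pre_ms: float = 50.0,
    post_ms: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of ``trace`` segments aligned to trigger times.

    Returns (lags_ms, averaged trace).  Windows that would cross either edge
    of the recording are dropped; raises if none remain.
    """
    npre = int(round(pre_ms / dt))
    npost = int(round(post_ms / dt))
    segs = []
    for t in np.atleast_1d(triggers):
        k = int(round(t / dt))
        if k - npre < 0 or k + npost >= len(trace):
            continue
        segs.append(trace[k - npre:k + npost + 1])
    if not segs:
        raise ValueError("no complete trigger windows")
    lags = (np.arange(-npre, npost + 1)) * dt
    return lags, np.mean(np.asarray(segs, dtype=float), axis=0)


def isi_histogram(spikes, population: str, bin_ms: float = 10.0,
                  max_ms: float = 500.0):
    """Pooled inter-spike-interval histogram and its mode (bin center, ms)."""
    runs = spikes if isinstance(spikes, (list, tuple)) else [spikes]
    isis = []
    for sd in runs:
        for ts in sd.times[population]:
            if len(ts) >= 2:
                isis.append(np.diff(ts))
    isis = np.concatenate(isis) if isis else np.empty(0)
    edges = np.arange(0.0, max_ms + bin_ms, bin_ms)
    hist, _ = np.histogram(isis, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = float(centers[int(np.argmax(hist))]) if hist.sum() else float("nan")
    return hist, centers, mode


def population_rate(spikes, population: str, window: float = 20.0,
                    dt: float = BIN_MS) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window population firing rate (Hz per cell), stepped at ``dt``."""
    sd = spikes
    trains = sd.times[population]
    n_cells = len(trains)
    counts = bin_spikes(trains, sd.duration, dt)
    w = max(1, int(round(window / dt)))
    kernel = np.ones(w)
    summed = np.convolve(counts, kernel, mode="same")
    rate = summed / (n_cells * window / 1000.0) if n_cells else summed * 0.0
    t = np.arange(len(counts)) * dt
    return t, rate
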