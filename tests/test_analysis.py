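"""Spectral, coherence, STA, ISI and rate analyses against closed-form oracles."""

import numpy as np
import pytest

from ca3theta.analysis import (
    SpectrumResult,
    bin_spikes,
    detect_peak,
    isi_histogram,
    pairwise_coherence,
    population_rate,
    population_spectrum,
    relative_theta,
    spike_triggered_average,
)
from ca3theta.engine import SpikeData, ExperimentConfig


def _spikedata(trains, duration=5000.0, pop="ca3_pyr"):
    return SpikeData(times={pop: [np.asarray(t, dtype=float) for t in trains]},
                     duration=duration, seed=0, config=ExperimentConfig())


def test_periodic_population_peak_at_8hz():
    trains = [np.arange(0.0, 5000.0, 125.0) + 3 * i for i in range(20)]
    sp = population_spectrum(_spikedata(trains), "ca3_pyr")
    assert detect_peak(sp, (4, 12)) == pytest.approx(8.0, abs=0.6)


def test_poisson_population_flat_in_theta():
    """Homogeneous Poisson spikes: no theta-band point exceeds the local
    baseline by 3 SD (white spectrum)."""
    rng = np.random.default_rng(0)
    trains = [np.sort(rng.uniform(0, 5000.0, size=rng.poisson(100)))
              for _ in range(40)]
    runs = [_spikedata(trains)]
    sp = population_spectrum(runs, "ca3_pyr")
    f, p = sp.freq, sp.power
    theta = p[(f >= 4) & (f <= 12)]
    base = p[(f >= 1) & (f <= 50)]
    assert theta.max() < base.mean() + 3 * base.std()


def test_relative_theta_flat_spectrum():
    f = np.linspace(0, 250, 2501)
    sp = SpectrumResult(freq=f, power=np.ones_like(f), sd=np.zeros_like(f))
    assert relative_theta(sp) == pytest.approx(8.0 / 250.0, abs=0.002)


def test_relative_theta_concentrated():
    f = np.linspace(0, 250, 2501)
    p = np.zeros_like(f)
    p[np.argmin(np.abs(f - 6.0))] = 5.0
    sp = SpectrumResult(freq=f, power=p, sd=np.zeros_like(f))
    assert relative_theta(sp) == 1.0


def test_relative_theta_scale_invariant():
    rngf = np.linspace(0, 250, 1001)
    rng = np.random.default_rng(1)
    p = rng.random(1001)
    a = relative_theta(SpectrumResult(freq=rngf, power=p, sd=0 * p))
    b = relative_theta(SpectrumResult(freq=rngf, power=7.3 * p, sd=0 * p))
    assert a == pytest.approx(b)


def test_relative_theta_zero_power_errors():
    f = np.linspace(0, 250, 100)
    sp = SpectrumResult(freq=f, power=np.zeros_like(f), sd=np.zeros_like(f))
    with pytest.raises(ValueError):
        relative_theta(sp)


def test_detect_peak_single_frequency():
    trains = [np.arange(0.0, 5000.0, 100.0)] * 10
    sp = population_spectrum(_spikedata(trains), "ca3_pyr")
    assert detect_peak(sp, (2, 30)) == pytest.approx(10.0, abs=0.6)


def test_detect_peak_tie_breaks_low():
    f = np.arange(0, 100.0, 1.0)
    p = np.zeros_like(f)
    p[10] = p[20] = 1.0
    sp = SpectrumResult(freq=f, power=p, sd=0 * p)
    assert detect_peak(sp, (1, 50), smooth_hz=0.0) == 10.0


def test_detect_peak_empty_band_errors():
    f = np.arange(0, 100.0, 1.0)
    sp = SpectrumResult(freq=f, power=np.ones_like(f), sd=0 * f)
    with pytest.raises(ValueError):
        detect_peak(sp, (300, 400))


def test_coherence_identical_trains():
    sd = _spikedata([[10, 100, 200], [10, 100, 200]], duration=1000.0)
    res = pairwise_coherence(sd, "ca3_pyr")
    assert res.values[0] == pytest.approx(1.0)


def test_coherence_disjoint_trains():
    sd = _spikedata([[10, 100], [300, 400]], duration=1000.0)
    res = pairwise_coherence(sd, "ca3_pyr")
    assert res.values[0] == 0.0


def test_coherence_hand_computed_example():
    """A={10,100,200}, B={12,150,203}: bins 2/20/40 vs 2/30/40 -> 2/3."""
    sd = _spikedata([[10, 100, 200], [12, 150, 203]], duration=1000.0)
    res = pairwise_coherence(sd, "ca3_pyr", window=5.0)
    assert res.values[0] == pytest.approx(2.0 / 3.0)


def test_coherence_brute_force_oracle(rng):
    """Implementation equals direct bin counting for random tiny trains."""
    duration, win = 500.0, 5.0
    nb = int(duration / win)
    for _ in range(25):
        a = np.sort(rng.uniform(0, duration, rng.integers(1, 6)))
        b = np.sort(rng.uniform(0, duration, rng.integers(1, 6)))
        sd = _spikedata([a, b], duration=duration)
        got = pairwise_coherence(sd, "ca3_pyr", window=win).values[0]
        xa = np.zeros(nb, bool)
        xb = np.zeros(nb, bool)
        xa[np.minimum((a / win).astype(int), nb - 1)] = True
        xb[np.minimum((b / win).astype(int), nb - 1)] = True
        want = (xa & xb).sum() / np.sqrt(xa.sum() * xb.sum())
        assert got == pytest.approx(want)


def test_coherence_skips_silent_cells():
    sd = _spikedata([[10, 100], [], [50, 60]], duration=1000.0)
    res = pairwise_coherence(sd, "ca3_pyr")
    assert res.skipped == 2
    assert len(res.values) == 1


def test_sta_constant_signal():
    lags, sta = spike_triggered_average(
        np.array([100.0, 200.0, 300.0]), np.full(5000, 3.3), dt=0.1)
    assert np.allclose(sta, 3.3)


def test_sta_recovers_embedded_pulse(rng):
    """Signal = delta at each trigger + noise: averaging recovers the delta."""
    dt = 0.1
    n = 100000
    sig = rng.normal(0, 1.0, n)
    trig = np.sort(rng.choice(np.arange(1000, n - 3000), 400, replace=False)) * dt
    for t in trig:
        sig[int(round(t / dt))] += 50.0
    lags, sta = spike_triggered_average(trig, sig, dt=dt, pre_ms=20, post_ms=20)
    k = np.argmin(np.abs(lags))
    assert sta[k] > 25.0
    assert np.abs(sta[k - 50]) < 2.0


def test_sta_no_complete_windows_errors():
    with pytest.raises(ValueError):
        spike_triggered_average(np.array([1.0]), np.zeros(100), dt=0.1,
                                pre_ms=50, post_ms=50)


def test_isi_periodic_cell():
    sd = _spikedata([np.arange(0.0, 5000.0, 125.0)])
    hist, centers, mode = isi_histogram(sd, "ca3_pyr")
    assert mode == 125.0
    assert hist.sum() == 39


def test_isi_empty():
    sd = _spikedata([[5.0]])
    hist, centers, mode = isi_histogram(sd, "ca3_pyr")
    assert np.isnan(mode)


def test_population_rate_zero():
    sd = _spikedata([[], []], duration=1000.0)
    t, r = population_rate(sd, "ca3_pyr")
    assert np.all(r == 0)


def test_population_rate_counting_identity(rng):
    """N asynchronous cells at r Hz: the time-mean of the trace is ~r."""
    r_hz, n, dur = 20.0, 30, 5000.0
    trains = [np.sort(rng.uniform(0, dur, rng.poisson(r_hz * dur / 1000)))
              for _ in range(n)]
    t, trace = population_rate(_spikedata(trains, dur), "ca3_pyr")
    assert np.mean(trace) == pytest.approx(r_hz, rel=0.1)


def test_spectrum_power_scales_with_rate(rng):
    """Total spectral power grows linearly with spike count for Poisson
    drive (R^2 > 0.95 across rates)."""
    totals, counts = [], []
    for r_hz in (5, 10, 20, 40, 80):
        trains = [np.sort(rng.uniform(0, 5000.0, rng.poisson(r_hz * 5)))
                  for _ in range(20)]
        sp = population_spectrum(_spikedata(trains), "ca3_pyr")
        totals.append(sp.power.sum())
        counts.append(sum(len(t) for t in trains))
    c = np.corrcoef(counts, totals)[0, 1]
    assert c ** 2 > 0.95


def test_spectrum_requires_enough_data():
    with pytest.raises(ValueError):
        population_spectrum(_spikedata([[1.0]], duration=500.0), "ca3_pyr")


def test_spectrum_serialization(tmp_path):
    trains = [np.arange(0.0, 5000.0, 125.0)]
    sp = population_spectrum(_spikedata(trains), "ca3_pyr")
    sp.save(tmp_path / "spec.tsv", tmp_path / "spec.json")
    import json, pandas as pd
    df = pd.read_csv(tmp_path / "spec.tsv", sep="\t")
    assert set(df.columns) == {"freq_hz", "power", "sd"}
    summ = json.loads((tmp_path / "spec.json").read_text())
    assert summ["peak_hz"] == pytest.approx(8.0, abs=0.6)


def test_bin_spikes_totals():
    counts = bin_spikes([np.array([0.05, 2.0, 2.04]), np.array([10.0])], 100.0)
    assert counts.sum() == 4
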