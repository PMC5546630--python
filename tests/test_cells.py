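"""Single-cell model: fixed points, resets, f-I behavior, cholinergic scaling."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from ca3theta.cells import (
    NeuronParams,
    NeuronState,
    apply_ach_to_neuron,
    fi_curve,
    integrate_neuron,
    rheobase,
    step_neuron,
)
from ._reference import reference_spike_times


def test_rest_is_fixed_point(cell_catalog):
    """At v = v_r with u = h = 0 and no input, the membrane does not move."""
    for p in cell_catalog.values():
        st0 = NeuronState(v=p.v_r)
        st1, spiked = step_neuron(st0, p, 0.0, 0.1)
        assert not spiked
        assert st1.v == pytest.approx(p.v_r, abs=1e-9)
        assert st1.u == pytest.approx(0.0, abs=1e-9)


def test_after_spike_reset_pyramidal(cell_catalog):
    """Crossing the cutoff resets v to c and increments u by d (pyr: -63, +60)."""
    p = replace(cell_catalog["ca3_pyr"], h_enabled=False)
    st0 = NeuronState(v=p.v_peak + 5.0, u=10.0)
    st1, spiked = step_neuron(st0, p, 0.0, 0.1)
    assert spiked
    assert st1.v == pytest.approx(-63.0)
    assert st1.u == pytest.approx(st0.u + 60.0, rel=0.05)


def test_olm_dynamic_reset_depends_on_u(cell_catalog):
    p = cell_catalog["olm"]
    lo, _ = step_neuron(NeuronState(v=p.v_peak + 1, u=0.0), p, 0.0, 0.1)
    hi, _ = step_neuron(NeuronState(v=p.v_peak + 1, u=80.0), p, 0.0, 0.1)
    assert hi.v > lo.v  # reset rises with u


def test_spike_count_matches_fine_step_reference(cell_catalog):
    """1 s at 1.1x rheobase: dt=0.1 ms spike count equals the dt=0.001 ms oracle."""
    p = replace(cell_catalog["ca3_pyr"], h_enabled=False)
    I = 1.1 * rheobase(p)
    coarse = integrate_neuron(p, I, 1000.0, dt=0.1)
    fine = reference_spike_times(p, I, 1000.0, dt=0.001)
    assert len(coarse) == len(fine)


def test_spike_times_match_fine_step_reference_over_5s(cell_catalog):
    """Single-neuron equivalence: spike times within 1 ms of the fine oracle."""
    p = replace(cell_catalog["ca3_pyr"], h_enabled=False)
    I = 1.3 * rheobase(p)
    coarse = integrate_neuron(p, I, 5000.0, dt=0.1)
    fine = reference_spike_times(p, I, 5000.0, dt=0.001)
    assert len(coarse) == len(fine)
    drift_per_spike = np.abs(coarse - fine) / (np.arange(len(fine)) + 1)
    assert np.max(drift_per_spike) < 1.0


def test_fi_zero_current_silent(cell_catalog):
    for name in ("ca3_pyr", "dg_gc", "olm", "bc"):
        p = replace(cell_catalog[name], h_enabled=False)
        assert fi_curve(p, [0.0])[0] == 0.0


def test_fi_monotone_all_types(cell_catalog):
    for name in ("ca3_pyr", "dg_gc", "olm", "bc"):
        p = replace(cell_catalog[name], h_enabled=False)
        I = rheobase(p) * np.array([0.5, 1.1, 1.5, 2.0, 3.0])
        rates = fi_curve(p, I)
        assert np.all(np.diff(rates) >= 0), name


def test_bc_fast_spiking(cell_catalog):
    """Basket cells reach fast-spiking rates with strictly increasing f-I."""
    p = cell_catalog["bc"]
    I = rheobase(p) * np.array([1.2, 1.6, 2.0, 3.0, 4.0])
    rates = fi_curve(p, I)
    assert np.all(np.diff(rates) > 0)
    assert rates[-1] > 80.0


def test_pyramidal_adaptation_first_isi_shortest(cell_catalog):
    """Step current: instantaneous initial rate exceeds the adapted rate."""
    p = replace(cell_catalog["ca3_pyr"], h_enabled=False)
    ts = integrate_neuron(p, 1.5 * rheobase(p), 2000.0)
    isis = np.diff(ts)
    assert len(isis) > 3
    assert isis[0] < isis[-1]


def test_adaptation_recovery_speed():
    """u after a spike decays to <=5% of its peak within 50 ms at a=0.1,
    but far slower at the baseline a=0.01 (~100 ms time constant)."""
    def u_after(a, t_ms):
        # free decay at rest: du/dt = a(b*0 - u)
        return 60.0 * np.exp(-a * t_ms)

    assert u_after(0.1, 50.0) <= 0.05 * 60.0
    assert u_after(0.01, 50.0) > 0.5 * 60.0
    assert 0.3 < u_after(0.01, 95.0) / 60.0 < 0.45  # ~90-100 ms scale


def test_ach_identity_at_baseline(cell_catalog):
    for name in ("ca3_pyr", "olm", "bc"):
        assert apply_ach_to_neuron(cell_catalog[name], 1.0) == cell_catalog[name]


def test_ach_burstiness_lowers_c_and_d(cell_catalog):
    p = cell_catalog["ca3_pyr"]
    q = apply_ach_to_neuron(p, 2.0, effect_set={"pyr_burstiness"})
    assert q.c < p.c and q.d < p.d


def test_ach_unknown_effect_raises(cell_catalog):
    with pytest.raises(ValueError):
        apply_ach_to_neuron(cell_catalog["ca3_pyr"], 2.0, effect_set={"bogus"})


def test_ach_raises_olm_firing(cell_catalog):
    """High ACh (depolarization + reduced adaptation) speeds OLM firing."""
    p = replace(cell_catalog["olm"], h_enabled=False)
    lo = apply_ach_to_neuron(p, 0.0)
    hi = apply_ach_to_neuron(p, 2.0)
    I = 1.4 * rheobase(p)
    assert fi_curve(replace(hi, h_enabled=False), [I])[0] > fi_curve(
        replace(lo, h_enabled=False), [I])[0]


def test_catalog_invariants(cell_catalog):
    for p in cell_catalog.values():
        assert p.v_r < p.v_t < p.v_peak
        assert p.a > 0 and p.C > 0 and p.k > 0
    assert cell_catalog["ca3_pyr"].h_enabled
    assert cell_catalog["olm"].h_enabled
    assert not cell_catalog["bc"].h_enabled
    assert not cell_catalog["ec"].h_enabled


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        NeuronParams(C=24, k=1.5, a=0.01, b=2, c=-63, d=60,
                     v_r=-50, v_t=-58, v_peak=29, name="bad").validate()


def test_nonfinite_state_diagnostic(cell_catalog):
    p = cell_catalog["ca3_pyr"]
    with pytest.raises(FloatingPointError):
        step_neuron(NeuronState(v=np.inf), p, 0.0, 0.1)


@settings(max_examples=30, deadline=None)
@given(I=st.floats(-50, 400), v0=st.floats(-90, 20))
def test_step_never_leaves_v_above_cutoff(I, v0):
    """After any step, the observed potential is at or below the spike cutoff."""
    p = NeuronParams(C=24, k=1.5, a=0.01, b=2, c=-63, d=60,
                     v_r=-75, v_t=-58, v_peak=29, name="ca3_pyr")
    stt, _ = step_neuron(NeuronState(v=v0), p, I, 0.1)
    assert stt.v <= p.v_peak
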