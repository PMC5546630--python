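"""Network engine: determinism, delays, inactivation switches, oracle parity."""

import numpy as np
import pytest
from dataclasses import replace

from ca3theta.cells import load_cell_catalog, rheobase
from ca3theta.engine import ExperimentConfig, inactivate_generator, run
from ca3theta.inputs import DriveConfig
from ca3theta.network import build_network
from ca3theta.utils import substream
from ._reference import reference_spike_times


def _iso_cfg(seed=0, duration=2000.0, **kw):
    base = dict(
        seed=seed, duration=duration,
        drives=(DriveConfig(target="ca3_pyr", lognormal=(50.0, 40.0),
                            duration=duration),),
        active_pathways=frozenset(),
        silenced_populations=frozenset({"ca3_bc", "ca3_olm"}),
        h_on=False,
    )
    base.update(kw)
    return ExperimentConfig(**base)


@pytest.fixture(scope="module")
def iso_net():
    return build_network(3, regions=("ca3",), pathways=[])


def test_zero_drive_no_spikes(iso_net):
    cfg = _iso_cfg(drives=(), duration=1000.0)
    sd = run(cfg, iso_net)
    assert all(len(t) == 0 for t in sd.times["ca3_pyr"])


def test_bit_identical_given_seed(iso_net):
    a = run(_iso_cfg(seed=5), iso_net)
    b = run(_iso_cfg(seed=5), iso_net)
    for x, y in zip(a.times["ca3_pyr"], b.times["ca3_pyr"]):
        assert np.array_equal(x, y)


def test_spike_times_sorted_in_range(iso_net):
    sd = run(_iso_cfg(seed=2), iso_net)
    for ts in sd.times["ca3_pyr"]:
        assert np.all(np.diff(ts) >= 0)
        assert np.all((ts >= 0) & (ts <= sd.duration))


def test_engine_matches_fine_step_oracle():
    """Constant-current network run reproduces the independent dt=0.001 ms
    scalar integration of each cell within 1 ms per spike over 5 s."""
    net = build_network(3, regions=("ca3",), pathways=[])
    cat = load_cell_catalog()
    p = replace(cat["ca3_pyr"], h_enabled=False)
    I = 1.25 * rheobase(p)
    cfg = _iso_cfg(seed=9, duration=5000.0, drives=(),
                   inject_current={"ca3_pyr": I})
    sd = run(cfg, net)
    v0 = substream(9, "init-v:ca3_pyr").normal(p.v_r, 10.0, size=63)
    checked = 0
    for i in range(10):
        ref = reference_spike_times(p, I, 5000.0, dt=0.001, v0=v0[i])
        got = sd.times["ca3_pyr"][i]
        assert len(got) == len(ref)
        if len(ref):
            drift = np.abs(got - ref) / (np.arange(len(ref)) + 1)
            assert np.max(drift) < 1.0
            checked += 1
    assert checked >= 5


def test_delay_fidelity():
    """With one presynaptic EC spike, the postsynaptic EC->pyr current starts
    delay (5 ms) after the spike, within one step."""
    net = build_network(1, regions=("ec", "ca3"), pathways=["ec_pyr"])
    # pick a pyramidal cell with at least one EC source
    df = net.edges["ec_pyr"]
    tgt = int(df["target"].iloc[0])
    cfg = ExperimentConfig(
        seed=1, duration=1000.0,
        drives=(DriveConfig(target="ec", base_rate=2.0, duration=1000.0),),
        active_pathways=frozenset({"ec_pyr"}),
        silenced_populations=frozenset({"ca3_bc", "ca3_olm", "ca3_pyr"}),
        h_on=False,
        record_syn=(("ec_pyr", tgt),),
    )
    sd = run(cfg, net)
    trace = sd.traces["syn"][0]
    sources = set(df[df["target"] == tgt]["source"])
    pre = sorted(t for s in sources for t in sd.times["ec"][s])
    if not pre:
        pytest.skip("no presynaptic spikes this seed")
    onset_idx = np.argmax(np.abs(trace) > 1e-12) * cfg.dt
    assert onset_idx >= pre[0] + 5.0 - cfg.dt - 1e-9
    assert onset_idx <= pre[0] + 5.0 + 3 * cfg.dt


def test_inactivate_spiking_oscillations():
    cfg = _iso_cfg()
    out = inactivate_generator(cfg, "spiking_oscillations")
    assert out.a_override["ca3_pyr"] == 0.1


def test_inactivate_recurrent_removes_pathway():
    cfg = _iso_cfg(active_pathways=frozenset({"rc", "pyr_olm"}))
    out = inactivate_generator(cfg, "recurrent")
    assert "rc" not in out.active_pathways
    assert "pyr_olm" in out.active_pathways


def test_inactivation_idempotent():
    cfg = _iso_cfg(active_pathways=frozenset({"rc"}))
    once = inactivate_generator(cfg, "olm")
    twice = inactivate_generator(once, "olm")
    assert once == twice


def test_inactivate_ec_projection_swaps_drive():
    cfg = ExperimentConfig(
        seed=0, duration=1000.0, ach=2.0,
        drives=(DriveConfig(target="ec", base_rate=15.0, duration=1000.0),),
        active_pathways=frozenset({"ec_pyr"}),
    )
    out = inactivate_generator(cfg, "ec_projection")
    assert "ec" in out.silenced_populations
    (d,) = out.drives
    assert d.target == "ca3_pyr"
    assert d.lognormal == (60.0, 50.0)  # high-ACh statistics


def test_unknown_generator_rejected():
    with pytest.raises(ValueError):
        inactivate_generator(_iso_cfg(), "gap_junctions")


def test_silenced_population_emits_nothing_and_no_current():
    """With basket cells clamped silent, BC->pyr GABA_A current is zero."""
    net = build_network(2, regions=("ec", "ca3"))
    cfg = ExperimentConfig(
        seed=4, duration=1500.0,
        drives=(DriveConfig(target="ec", base_rate=15.0, duration=1500.0),),
        silenced_populations=frozenset({"ca3_bc"}),
        h_on=False,
        record_syn=(("bc_pyr", 0), ("bc_pyr", 5)),
    )
    sd = run(cfg, net)
    assert all(len(t) == 0 for t in sd.times["ca3_bc"])
    assert np.all(sd.traces["syn"] == 0.0)


def test_config_naming_absent_pathway_errors():
    net = build_network(1, regions=("ca3",), pathways=["rc"])
    cfg = _iso_cfg(active_pathways=frozenset({"rc", "mossy"}))
    with pytest.raises(ValueError):
        run(cfg, net)


def test_u_trace_recording(iso_net):
    sd = run(_iso_cfg(seed=6, record_u="ca3_pyr"), iso_net)
    u = sd.traces["u"]
    assert u.shape == (63, 20000)
    # adaptation jumps at spikes: u rises after a cell's first spike
    for i in range(63):
        ts = sd.times["ca3_pyr"][i]
        if len(ts):
            k = int(ts[0] / 0.1)
            assert u[i, min(k + 5, u.shape[1] - 1)] > u[i, max(k - 50, 0)] - 1e-6
            break
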