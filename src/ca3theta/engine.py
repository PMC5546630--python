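"""Experiment configuration and the time-stepped network simulation loop.

A run is fully determined by (ExperimentConfig, NetworkSpec): all randomness
(wiring, weights, initial potentials, input trains) flows from the master
seed through named substreams.  "Inactivating" a population clamps it silent
rather than deleting it, so recorded structures stay comparable across
conditions; inactivating a pathway drops its synapses; the five named theta
generators map onto these switches via :func:`inactivate_generator`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernel
from .cells import apply_ach_to_neuron, load_cell_catalog
from .inputs import DIRECT_DRIVE_STATS, DriveConfig, build_drive
from .network import POPULATION_TYPES, NetworkSpec
from .params import load_model_config
from .synapses import ach_gain, load_pathway_catalog
from .utils import substream

__all__ = ["ExperimentConfig", "SpikeData", "run", "inactivate_generator", "GENERATORS"]

GENERATORS = ("spiking_oscillations", "recurrent", "olm", "bc", "ec_projection")

#: drive target population -> external pathway in the catalog
_EXT_PATHWAY = {"ec": "ext_ec", "ca3_pyr": "ext_pyr"}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything that defines one simulation besides the wired network."""

    seed: int = 0
    duration: float = 5000.0  # ms
    dt: float = 0.1  # ms
    drives: tuple[DriveConfig, ...] = ()
    active_pathways: frozenset[str] | None = None  # None = all built pathways
    silenced_populations: frozenset[str] = frozenset()
    h_on: bool = True
    a_override: dict | None = None  # cell type -> replacement adaptation rate a
    ach: float = 1.0
    ach_cell_effects: frozenset[str] | None = None  # None = all applicable
    ach_syn_pathways: frozenset[str] | None = None  # None = all with b_ach
    weight_scale: dict | None = None  # pathway -> replacement weight scale
    stp_disabled: frozenset[str] = frozenset()
    inject_current: dict | None = None  # population -> constant current (pA)
    record_u: str | None = None  # population whose u to record
    record_v: tuple = ()  # (population, local index) pairs
    record_syn: tuple = ()  # (pathway, local target index) pairs

    def with_(self, **kw) -> "ExperimentConfig":
        return replace(self, **kw)


@dataclass
class SpikeData:
    """Per-cell sorted spike times for one run plus provenance metadata."""

    times: dict[str, list[np.ndarray]]  # population -> list of arrays (ms)
    duration: float
    seed: int
    config: ExperimentConfig
    traces: dict = field(default_factory=dict)

    def rates(self, pop: str) -> np.ndarray:
        """Per-cell firing rates (Hz)."""
        return np.asarray([len(ts) for ts in self.times[pop]]) / (self.duration / 1000.0)

    def pooled(self, pop: str) -> np.ndarray:
        return np.sort(np.concatenate(self.times[pop])) if self.times[pop] else np.empty(0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pop, trains in self.times.items():
            region, ctype = POPULATION_TYPES[pop]
            for i, ts in enumerate(trains):
                for t in ts:
                    rows.append((i, ctype, region, pop, t))
        df = pd.DataFrame(rows, columns=["cell_id", "cell_type", "region", "population",
                                         "spike_time_ms"])
        return df.sort_values(["population", "cell_id", "spike_time_ms"], ignore_index=True)

    def save(self, path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed} duration_ms={self.duration} "
                     f"config={dataclasses.asdict(self.config)!r}\n")
            df.to_csv(fh, sep="\t", index=False)


def _population_slices(net: NetworkSpec) -> dict[str, tuple[int, int]]:
    out, off = {}, 0
    for pop in net.populations:
        n = net.n_cells(pop)
        out[pop] = (off, off + n)
        off += n
    return out


def run(config: ExperimentConfig, network: NetworkSpec) -> SpikeData:
    """Simulate the network under ``config``; deterministic given both."""
    cfg = load_model_config()
    cs = float(cfg["current_scale"])
    catalog = load_cell_catalog()
    pcat = load_pathway_catalog()
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    slices = _population_slices(network)
    pops = list(slices)
    N = sum(network.n_cells(p) for p in pops)

    # ---- per-cell parameter arrays -------------------------------------
    def f(): return np.zeros(N)
    nC, nk, na, nb, nc, nd = f(), f(), f(), f(), f(), f()
    nvr, nvt, nvpeak, nah, nbh, ndh = f(), f(), f(), f(), f(), f()
    nhen = np.zeros(N, dtype=np.int8)
    ndyn = np.zeros(N, dtype=np.int8)
    nsil = np.zeros(N, dtype=np.int8)
    i_inj = f()
    v0 = f()
    for pop in pops:
        lo, hi = slices[pop]
        ctype = POPULATION_TYPES[pop][1]
        p = catalog[ctype]
        if config.ach != 1.0 and config.ach_cell_effects != frozenset():
            p = apply_ach_to_neuron(p, config.ach, effect_set=(
                None if config.ach_cell_effects is None
                else set(config.ach_cell_effects)))
        if config.a_override and ctype in config.a_override:
            p = replace(p, a=config.a_override[ctype])
        nC[lo:hi], nk[lo:hi], na[lo:hi] = p.C, p.k, p.a
        nb[lo:hi], nc[lo:hi], nd[lo:hi] = p.b, p.c, p.d
        nvr[lo:hi], nvt[lo:hi], nvpeak[lo:hi] = p.v_r, p.v_t, p.v_peak
        h_en = p.h_enabled and config.h_on
        nhen[lo:hi] = 1 if h_en else 0
        nah[lo:hi], nbh[lo:hi], ndh[lo:hi] = p.a_h, p.b_h, p.d_h
        ndyn[lo:hi] = 1 if p.olm_dynamic_reset else 0
        if pop in config.silenced_populations:
            nsil[lo:hi] = 1
        rng = substream(config.seed, f"init-v:{pop}")
        # draws above threshold are clipped just below it so no cell starts
        # mid-spike
        v0[lo:hi] = np.minimum(
            rng.normal(p.v_r, cfg["init_v_sd"], size=hi - lo), p.v_t - 1.0)
        if config.inject_current and pop in config.inject_current:
            i_inj[lo:hi] = config.inject_current[pop]

    # ---- pathways -------------------------------------------------------
    built = set(network.edges)
    if config.active_pathways is None:
        active = built
    else:
        missing = set(config.active_pathways) - built - set(_EXT_PATHWAY.values())
        if missing:
            raise ValueError(f"config names pathways absent from the network: {missing}")
        active = built & set(config.active_pathways)
    path_names = sorted(active) + [_EXT_PATHWAY[d.target] for d in config.drives]
    P = len(path_names)
    p_delay_steps = np.zeros(P, dtype=np.int64)
    p_sign, p_frd, p_fdd, p_srd, p_sdd = (np.zeros(P) for _ in range(5))
    p_tgt_lo = np.zeros(P, dtype=np.int64)
    p_tgt_n = np.zeros(P, dtype=np.int64)
    p_off = np.zeros(P, dtype=np.int64)
    p_nmda = np.zeros(P, dtype=np.int8)
    p_satf = np.full(P, np.inf)
    p_sats = np.full(P, np.inf)
    sat_cap = cfg.get("saturation_cap")
    off = 0
    specs = []
    for ip, pw in enumerate(path_names):
        s = pcat[pw]
        specs.append(s)
        lo, hi = slices[s.tgt]
        p_tgt_lo[ip], p_tgt_n[ip], p_off[ip] = lo, hi - lo, off
        off += hi - lo
        p_delay_steps[ip] = max(1, int(round(s.delay / dt)))
        p_sign[ip] = s.sign
        p_frd[ip] = math.exp(-dt / s.fast.rise)
        p_fdd[ip] = math.exp(-dt / s.fast.decay)
        p_srd[ip] = math.exp(-dt / s.slow.rise)
        p_sdd[ip] = math.exp(-dt / s.slow.decay)
        p_nmda[ip] = 1 if (s.slow.kind == "nmda" and s.slow_mg) else 0
        cap = sat_cap if s.saturation == "global" else s.saturation
        capf = cap if s.saturation_fast == "same" else s.saturation_fast
        wsc = 1.0
        if config.weight_scale and pw in config.weight_scale:
            wsc = config.weight_scale[pw] / s.weight
        if cap is not None:
            p_sats[ip] = float(cap) * cs * wsc
        if capf is not None:
            p_satf[ip] = float(capf) * cs * wsc
    G = off
    gate = [np.zeros(G) for _ in range(4)]

    def syn_ach(s):
        if config.ach_syn_pathways is not None and s.pathway not in config.ach_syn_pathways:
            return 1.0
        return ach_gain(s.b_ach, config.ach)

    def slow_ratio(s):
        if s.slow_ratio is not None:
            return s.slow_ratio
        return cfg["nmda_ratio"] if s.slow.kind == "nmda" else cfg["gabab_ratio"]

    # ---- edges (CSR by global source cell) ------------------------------
    e_src, e_path, e_gidx = [], [], []
    e_amt_f, e_amt_s = [], []
    e_stp_kind, e_stp_f, e_stp_tau = [], [], []
    for ip, pw in enumerate(path_names):
        s = specs[ip]
        if s.src == "ext":
            continue
        df = network.edges[pw]
        w = df["weight"].to_numpy()
        if config.weight_scale and pw in config.weight_scale:
            w = w * (config.weight_scale[pw] / s.weight)
        src_lo = slices[s.src][0]
        e_src.append(df["source"].to_numpy() + src_lo)
        e_path.append(np.full(len(df), ip, dtype=np.int64))
        e_gidx.append(df["target"].to_numpy() + p_off[ip])
        ag = syn_ach(s)
        e_amt_f.append(w * s.gain * ag * s.fast.norm * cs)
        e_amt_s.append(w * s.gain * slow_ratio(s) * s.slow.norm * cs)
        kind = 0 if (s.stp_kind == "none" or pw in config.stp_disabled) else (
            1 if s.stp_kind == "depressing" else 2)
        e_stp_kind.append(np.full(len(df), kind, dtype=np.int8))
        e_stp_f.append(np.full(len(df), s.stp_f))
        e_stp_tau.append(np.full(len(df), max(s.stp_tau, 1e-9)))

    if e_src:
        e_src = np.concatenate(e_src)
        order = np.argsort(e_src, kind="stable")
        e_src = e_src[order]
        e_path = np.concatenate(e_path)[order]
        e_gidx = np.concatenate(e_gidx)[order].astype(np.int64)
        e_amt_f = np.concatenate(e_amt_f)[order]
        e_amt_s = np.concatenate(e_amt_s)[order]
        e_stp_kind = np.concatenate(e_stp_kind)[order]
        e_stp_f = np.concatenate(e_stp_f)[order]
        e_stp_tau = np.concatenate(e_stp_tau)[order]
    else:
        e_src = np.empty(0, dtype=np.int64)
        e_path = np.empty(0, dtype=np.int64)
        e_gidx = np.empty(0, dtype=np.int64)
        e_amt_f = e_amt_s = np.empty(0)
        e_stp_kind = np.empty(0, dtype=np.int8)
        e_stp_f = e_stp_tau = np.empty(0)
    src_ptr = np.zeros(N + 1, dtype=np.int64)
    np.add.at(src_ptr[1:], e_src, 1)
    src_ptr = np.cumsum(src_ptr)
    E = len(e_src)
    e_D, e_F = np.ones(E), np.ones(E)
    e_last = np.full(E, -1e12)

    # ---- external drive events ------------------------------------------
    xs, xg, xpath, xaf, xas = [], [], [], [], []
    for d in config.drives:
        pw = _EXT_PATHWAY[d.target]
        ip = path_names.index(pw)
        s = specs[ip]
        if d.target in config.silenced_populations:
            continue
        trains = build_drive(d, network.n_cells(d.target), config.seed)
        dlt = p_delay_steps[ip]
        ag = syn_ach(s)
        for i, ts in enumerate(trains):
            steps = np.floor(ts / dt).astype(np.int64) + dlt
            xs.append(steps)
            xg.append(np.full(len(ts), p_off[ip] + i, dtype=np.int64))
            xpath.append(np.full(len(ts), ip, dtype=np.int64))
            xaf.append(np.full(len(ts), s.weight * s.gain * ag * s.fast.norm * cs))
            xas.append(np.full(len(ts), s.weight * s.gain * slow_ratio(s) * s.slow.norm * cs))
    if xs:
        xs = np.concatenate(xs)
        order = np.argsort(xs, kind="stable")
        x_step = xs[order]
        x_g = np.concatenate(xg)[order]
        x_path = np.concatenate(xpath)[order]
        x_af = np.concatenate(xaf)[order]
        x_as = np.concatenate(xas)[order]
    else:
        x_step = np.empty(0, dtype=np.int64)
        x_g = np.empty(0, dtype=np.int64)
        x_path = np.empty(0, dtype=np.int64)
        x_af = x_as = np.empty(0)

    # ---- queues, outputs, traces ----------------------------------------
    Q = 1 << 14
    q_step = np.zeros((max(P, 1), Q), dtype=np.int64)
    q_g = np.zeros((max(P, 1), Q), dtype=np.int64)
    q_af = np.zeros((max(P, 1), Q))
    q_as = np.zeros((max(P, 1), Q))
    q_head = np.zeros(max(P, 1), dtype=np.int64)
    q_tail = np.zeros(max(P, 1), dtype=np.int64)
    cap = int(N * config.duration / 1000.0 * 500) + 1000
    spike_cell = np.zeros(cap, dtype=np.int64)
    spike_step = np.zeros(cap, dtype=np.int64)

    if config.record_u:
        lo, hi = slices[config.record_u]
        rec_u_idx = np.arange(lo, hi, dtype=np.int64)
    else:
        rec_u_idx = np.empty(0, dtype=np.int64)
    rec_v_idx = np.asarray(
        [slices[pop][0] + i for pop, i in config.record_v], dtype=np.int64)
    rg_path, rg_gidx, rg_cell = [], [], []
    for pw, i in config.record_syn:
        ip = path_names.index(pw)
        rg_path.append(ip)
        rg_gidx.append(p_off[ip] + i)
        rg_cell.append(p_tgt_lo[ip] + i)
    rec_g_path = np.asarray(rg_path, dtype=np.int64)
    rec_g_gidx = np.asarray(rg_gidx, dtype=np.int64)
    rec_g_cell = np.asarray(rg_cell, dtype=np.int64)
    rec_u = np.zeros((len(rec_u_idx), n_steps), dtype=np.float32)
    rec_v = np.zeros((len(rec_v_idx), n_steps), dtype=np.float32)
    rec_g = np.zeros((len(rec_g_path), n_steps), dtype=np.float32)

    mg = cfg["mg_block"]
    u0, h0 = np.zeros(N), np.zeros(N)
    code, err_cell, err_step, n_spikes = _kernel.simulate(
        n_steps, dt,
        nC, nk, na, nb, nc, nd, nvr, nvt, nvpeak,
        nhen, nah, nbh, ndh, ndyn, nsil, i_inj,
        v0, u0, h0,
        p_delay_steps, p_sign, p_tgt_lo, p_tgt_n, p_off,
        p_frd, p_fdd, p_srd, p_sdd, p_nmda, p_satf, p_sats,
        float(mg["slope"]), float(mg["k"]),
        gate[0], gate[1], gate[2], gate[3],
        src_ptr, e_path, e_gidx, e_amt_f, e_amt_s,
        e_stp_kind, e_stp_f, e_stp_tau, e_D, e_F, e_last,
        float(cfg["stp_f_max"]),
        q_step, q_g, q_af, q_as, q_head, q_tail,
        x_step, x_g, x_path, x_af, x_as,
        spike_cell, spike_step,
        rec_u_idx, rec_u, rec_v_idx, rec_v,
        rec_g_path, rec_g_gidx, rec_g_cell, rec_g,
    )
    if code == 1:
        pop = next(p for p, (lo, hi) in slices.items() if lo <= err_cell < hi)
        raise FloatingPointError(
            f"non-finite state: population {pop} cell {err_cell} at step {err_step} "
            f"(t={(err_step + 1) * dt:.1f} ms)")
    if code == 2:
        raise RuntimeError(f"spike buffer overflow at step {err_step}: runaway activity")
    if code == 3:
        raise RuntimeError(f"synaptic event queue overflow at step {err_step}")

    times: dict[str, list[np.ndarray]] = {}
    sc = spike_cell[:n_spikes]
    st = (spike_step[:n_spikes] + 1) * dt
    for pop in pops:
        lo, hi = slices[pop]
        times[pop] = [np.sort(st[sc == i]) for i in range(lo, hi)]
    traces = {}
    if len(rec_u):
        traces["u"] = rec_u
    if len(rec_v):
        traces["v"] = rec_v
    if len(rec_g):
        traces["syn"] = rec_g
    return SpikeData(times=times, duration=config.duration, seed=config.seed,
                     config=config, traces=traces)


def inactivate_generator(config: ExperimentConfig, generator: str) -> ExperimentConfig:
    """Return a copy of ``config`` with exactly one theta generator removed.

    * spiking_oscillations: pyramidal adaptation recovers in 10 ms (a = 0.1);
    * recurrent / olm / bc: the corresponding synapses or population off;
    * ec_projection: EC silenced and replaced by direct lognormal Poisson
      drive to the pyramids whose statistics depend on the cholinergic state
      (50+/-40 baseline, 20+/-20 low, 60+/-50 high).
    """
    if generator == "spiking_oscillations":
        ov = dict(config.a_override or {})
        ov["ca3_pyr"] = 0.1
        return config.with_(a_override=ov)
    if generator == "recurrent":
        if config.active_pathways is None:
            raise ValueError("config must enumerate active_pathways to inactivate one")
        return config.with_(active_pathways=frozenset(config.active_pathways) - {"rc"})
    if generator == "olm":
        return config.with_(
            silenced_populations=config.silenced_populations | {"ca3_olm"})
    if generator == "bc":
        return config.with_(
            silenced_populations=config.silenced_populations | {"ca3_bc"})
    if generator == "ec_projection":
        stats = DIRECT_DRIVE_STATS[min(DIRECT_DRIVE_STATS, key=lambda k: abs(k - config.ach))]
        drives = tuple(d for d in config.drives if d.target != "ec")
        if not any(d.target == "ca3_pyr" for d in drives):
            drives += (DriveConfig(target="ca3_pyr", lognormal=stats,
                                   duration=config.duration),)
        return config.with_(
            silenced_populations=config.silenced_populations | {"ec"},
            drives=drives)
    raise ValueError(f"unknown generator {generator!r}; one of {GENERATORS}")
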