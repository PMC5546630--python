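"""Kinetic receptor currents with short-term plasticity and cholinergic scaling.

Each connection class (pathway) carries a fast receptor (AMPA or GABA_A) and
a slow one (NMDA with a sigmoidal magnesium block, or GABA_B treated as a
slow linear current).  Both are difference-of-exponentials ("dual
exponential") kinetics

    g(t) = w * N * (exp(-t/tau_d) - exp(-t/tau_r)),   t >= spike arrival,

normalized by N so the peak equals the weight w, multiplied by a linear
driving-force factor of the postsynaptic potential (reversal at 0 mV for
excitation, -75/-90 mV for GABA_A/GABA_B).  Without receptor saturation the
gating is linear at fixed gain — the response to a spike train is the
superposition of shifted single-spike responses — so per-pathway lumped
gating per postsynaptic cell is exact and is what the network engine uses;
the engine additionally applies saturating (kinetic) binding per
postsynaptic site, configurable per pathway.

Short-term plasticity follows the multiplicative single-factor formulation of
Varela-style models: depressing pathways multiply a recovery variable D by a
per-spike factor (recovering exponentially toward 1); facilitating pathways
add a per-spike increment to a factor F that decays back to 1.  The per-spike
synaptic gain is the factor value at spike emission.

Cholinergic state (ACh in [0, 2]) scales the fast receptor increment by
``1 + b_ach * (ACh - 1)`` (clamped at 0); the slow receptor is untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import load_model_config, load_pathway_table

__all__ = [
    "ReceptorKinetics",
    "SynapseSpec",
    "SynapseState",
    "load_pathway_catalog",
    "ach_gain",
    "dual_exp_peak_time",
    "deliver_spike",
    "synaptic_current",
    "stp_gain_sequence",
]


@dataclass(frozen=True)
class ReceptorKinetics:
    """Rise/decay time constants (ms) of one receptor channel."""

    rise: float
    decay: float
    kind: str = "fast"  # fast | nmda | gabab

    def __post_init__(self):
        if not 0 < self.rise < self.decay:
            raise ValueError(
                f"require 0 < rise < decay, got {self.rise}/{self.decay}"
            )

    @property
    def norm(self) -> float:
        """Peak-normalization factor of the difference of exponentials."""
        tp = dual_exp_peak_time(self.rise, self.decay)
        return 1.0 / (math.exp(-tp / self.decay) - math.exp(-tp / self.rise))


@dataclass(frozen=True)
class SynapseSpec:
    """Static description of one connection class."""

    pathway: str
    src: str
    tgt: str
    sign: int  # +1 excitatory, -1 inhibitory
    fast: ReceptorKinetics
    slow: ReceptorKinetics
    delay: float
    weight: float
    b_ach: float = 0.0
    stp_kind: str = "none"  # none | depressing | facilitating
    stp_f: float = 0.0
    stp_tau: float = 1.0
    slow_mg: bool = True  # magnesium block on the slow (NMDA) channel
    slow_ratio: float | None = None  # per-pathway override of the slow/fast ratio
    saturation: float | str | None = "global"  # cap override; None disables
    saturation_fast: float | str | None = "same"  # fast-channel cap; None disables
    gain: float = 1.0  # charge-normalization multiplier (brief-kinetics synapses)

    def __post_init__(self):
        if self.delay <= 0:
            raise ValueError(f"{self.pathway}: delay must be positive")
        if self.stp_kind not in ("none", "depressing", "facilitating"):
            raise ValueError(f"{self.pathway}: unknown stp kind {self.stp_kind}")


def load_pathway_catalog() -> dict[str, SynapseSpec]:
    """Build validated SynapseSpec objects from the shipped pathway table."""
    out = {}
    for name, row in load_pathway_table().items():
        stp = row.get("stp", {"kind": "none"})
        out[name] = SynapseSpec(
            pathway=name,
            src=row["src"],
            tgt=row["tgt"],
            sign=int(row["sign"]),
            fast=ReceptorKinetics(row["fast"]["rise"], row["fast"]["decay"], "fast"),
            slow=ReceptorKinetics(
                row["slow"]["rise"], row["slow"]["decay"], row["slow"]["kind"]
            ),
            slow_mg=bool(row["slow"].get("mg", row["slow"]["kind"] == "nmda")),
            slow_ratio=row["slow"].get("ratio"),
            saturation=row.get("saturation", "global"),
            saturation_fast=row.get("saturation_fast", "same"),
            gain=float(row.get("gain", 1.0)),
            delay=float(row["delay"]),
            weight=float(row["weight"]),
            b_ach=float(row.get("b_ach", 0.0)),
            stp_kind=stp.get("kind", "none"),
            stp_f=float(stp.get("f", 0.0)),
            stp_tau=float(stp.get("tau", 1.0)),
        )
    return out


def ach_gain(b_ach: float, ach: float) -> float:
    """Linear cholinergic gain on the fast receptor, clamped at zero."""
    return max(0.0, 1.0 + b_ach * (ach - 1.0))


def dual_exp_peak_time(tau_r: float, tau_d: float) -> float:
    """Time to peak of exp(-t/tau_d) - exp(-t/tau_r)."""
    return tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)


def mg_block(v: float | np.ndarray, slope: float = 0.062, k: float = 3.57):
    """Sigmoidal voltage dependence of the NMDA conductance."""
    return 1.0 / (1.0 + np.exp(-slope * np.asarray(v)) / k)


@dataclass
class SynapseState:
    """Evolving state of one connection (reference, event-resolved).

    Gating is held as four exponential components (rise/decay for fast and
    slow receptor); pending deliveries wait in an arrival-time queue.  This
    object is the readable reference against which the vectorized engine is
    checked; it is exact for arbitrary event times.
    """

    spec: SynapseSpec
    t: float = 0.0
    fast_r: float = 0.0
    fast_d: float = 0.0
    slow_r: float = 0.0
    slow_d: float = 0.0
    stp_D: float = 1.0
    stp_F: float = 1.0
    last_pre: float | None = None
    queue: list = field(default_factory=list)  # (arrival time, fast amt, slow amt)

    def advance_to(self, t: float) -> None:
        """Exact-exponential advance, applying queued arrivals in order."""
        if t < self.t:
            raise ValueError("cannot advance backwards")
        self.queue.sort(key=lambda e: e[0])
        while self.queue and self.queue[0][0] <= t:
            ta, af, aslow = self.queue.pop(0)
            self._decay(ta - self.t)
            self.t = ta
            self.fast_r += af
            self.fast_d += af
            self.slow_r += aslow
            self.slow_d += aslow
        self._decay(t - self.t)
        self.t = t

    def _decay(self, dt: float) -> None:
        if dt <= 0:
            return
        s = self.spec
        self.fast_r *= math.exp(-dt / s.fast.rise)
        self.fast_d *= math.exp(-dt / s.fast.decay)
        self.slow_r *= math.exp(-dt / s.slow.rise)
        self.slow_d *= math.exp(-dt / s.slow.decay)


def _stp_advance(spec: SynapseSpec, state: SynapseState, t_spike: float) -> float:
    """Recover STP factors to t_spike, return the gain, apply the per-spike update."""
    f_max = load_model_config()["stp_f_max"]
    if state.last_pre is not None:
        dt = t_spike - state.last_pre
        rec = math.exp(-dt / spec.stp_tau)
        state.stp_D = 1.0 - (1.0 - state.stp_D) * rec
        state.stp_F = 1.0 + (state.stp_F - 1.0) * rec
    state.last_pre = t_spike
    if spec.stp_kind == "depressing":
        gain = state.stp_D
        state.stp_D *= spec.stp_f
    elif spec.stp_kind == "facilitating":
        gain = state.stp_F
        state.stp_F = min(f_max, state.stp_F + spec.stp_f)
    else:
        gain = 1.0
    return gain


def deliver_spike(
    state: SynapseState, spec: SynapseSpec, t_spike: float, ach: float = 1.0
) -> SynapseState:
    """Register a presynaptic spike at ``t_spike``; arrival is delayed by spec.delay.

    The fast-receptor increment is weight * stp_gain * ach_gain (ACh acts on
    the fast/AMPA component only); the slow increment is weight * stp_gain *
    slow_ratio.
    """
    if t_spike < state.t:
        raise ValueError("t_spike precedes current state time")
    cfg = load_model_config()
    if spec.slow_ratio is not None:
        ratio = spec.slow_ratio
    else:
        ratio = cfg["nmda_ratio"] if spec.slow.kind == "nmda" else cfg["gabab_ratio"]
    stp_gain = _stp_advance(spec, state, t_spike)
    base = spec.weight * spec.gain * stp_gain
    amt_fast = base * ach_gain(spec.b_ach, ach) * spec.fast.norm
    amt_slow = base * ratio * spec.slow.norm
    state.queue.append((t_spike + spec.delay, amt_fast, amt_slow))
    return state


def synaptic_current(
    state: SynapseState, spec: SynapseSpec, v_post: float, t: float
) -> float:
    """Signed synaptic current (weight units) at time ``t``.

    Excitatory pathways depolarize (positive), inhibitory hyperpolarize; the
    NMDA component is multiplied by the magnesium-block sigmoid of the
    postsynaptic potential.
    """
    state.advance_to(t)
    g_fast = state.fast_d - state.fast_r
    g_slow = state.slow_d - state.slow_r
    if spec.sign > 0:
        if spec.slow.kind == "nmda" and spec.slow_mg:
            mg = load_model_config()["mg_block"]
            g_slow *= float(mg_block(v_post, mg["slope"], mg["k"]))
        return (g_fast + g_slow) * (-v_post / 75.0)
    return -g_fast * (v_post + 75.0) / 20.0 - g_slow * (v_post + 90.0) / 35.0


def stp_gain_sequence(spec: SynapseSpec, spike_times) -> np.ndarray:
    """Per-spike multiplicative STP gain for a sorted spike train."""
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size and np.any(np.diff(spike_times) < 0):
        raise ValueError("spike_times must be sorted ascending")
    st = SynapseState(spec=spec)
    return np.asarray([_stp_advance(spec, st, float(t)) for t in spike_times])
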