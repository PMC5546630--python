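"""Izhikevich-formulation point neurons for the six hippocampal cell types.

The membrane model is the two-variable quadratic integrate-and-fire system

    C dv/dt = k (v - v_r)(v - v_t) - u + h + I
      du/dt = a (b (v - v_r) - u)
      du/dt applies the after-spike rule: if v >= v_peak then
          v <- c,  u <- u + d,  h <- h + d_h

with an optional slow restorative current ``h`` (a reduced h-current) obeying

      dh/dt = a_h (-b_h (v - v_r) - h)

which opposes slow voltage deviations from rest and, together with ``u``,
produces the subthreshold resonance of pyramidal and OLM cells.  OLM/HIPP
cells additionally use a state-dependent reset: the effective reset rises
and the effective cutoff falls with the recovery current (coupled through
u/C, clamped), reproducing the stereotypical shape of OLM firing.

Parameters for every cell type ship in ``data/cells.yaml`` (one entry per
type, mirroring the catalog column-for-column); :func:`load_cell_catalog`
validates the invariants on load.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "NeuronParams",
    "NeuronState",
    "load_cell_catalog",
    "step_neuron",
    "integrate_neuron",
    "rheobase",
    "fi_curve",
    "apply_ach_to_neuron",
    "ACH_EFFECTS",
]

#: effect name -> cell types it applies to
ACH_EFFECTS = {
    "pyr_depolarize": ("ca3_pyr", "ca3_pyr_burst"),
    "pyr_burstiness": ("ca3_pyr", "ca3_pyr_burst"),
    "olm_depolarize": ("olm", "dg_hipp"),
    "olm_adaptation": ("olm", "dg_hipp"),
    "bc_depolarize": ("bc",),
}


@dataclass(frozen=True)
class NeuronParams:
    """Constants of one cell type (units: pF, mV, 1/ms as noted in the catalog)."""

    C: float
    k: float
    a: float
    b: float
    c: float
    d: float
    v_r: float
    v_t: float
    v_peak: float
    h_enabled: bool = False
    a_h: float = 0.0
    b_h: float = 0.0
    d_h: float = 0.0
    olm_dynamic_reset: bool = False
    name: str = ""

    def validate(self) -> None:
        if not (self.v_r < self.v_t < self.v_peak):
            raise ValueError(
                f"{self.name or 'neuron'}: require v_r < v_t < v_peak, "
                f"got {self.v_r}, {self.v_t}, {self.v_peak}"
            )
        if self.a <= 0 or self.C <= 0 or self.k <= 0:
            raise ValueError(f"{self.name or 'neuron'}: a, C, k must be positive")
        if self.h_enabled and self.name not in (
            "ca3_pyr", "ca3_pyr_burst", "olm", "dg_hipp", "",
        ):
            raise ValueError(
                f"{self.name}: the slow h current is restricted to pyramidal "
                "and OLM/HIPP cells"
            )


@dataclass
class NeuronState:
    """Evolving state of one cell."""

    v: float
    u: float = 0.0
    h: float = 0.0
    last_spike_time: float | None = None


def load_cell_catalog(apply_h_scale: bool = True) -> dict[str, NeuronParams]:
    """Load and validate the per-type parameter catalog.

    HIPP cells use the OLM entry (the two types are modeled identically).
    With ``apply_h_scale`` (default) the h current's linear insertion gain
    from the model config is folded into b_h and d_h; pass False to read
    the catalog values verbatim.
    """
    from .params import load_model_config

    text = resources.files("ca3theta.data").joinpath("cells.yaml").read_text()
    raw = yaml.safe_load(text)
    hs = float(load_model_config().get("h_scale", 1.0)) if apply_h_scale else 1.0
    catalog: dict[str, NeuronParams] = {}
    for name, row in raw.items():
        p = NeuronParams(name=name, **row)
        if p.h_enabled and hs != 1.0:
            p = replace(p, b_h=p.b_h * hs, d_h=p.d_h * hs)
        p.validate()
        catalog[name] = p
    catalog["dg_hipp"] = replace(catalog["olm"], name="dg_hipp")
    return catalog


def _derivs(p: NeuronParams, v: float, u: float, h: float, I: float):
    # slow currents see v capped at v_t (bounded spike contribution)
    vc = min(v, p.v_t)
    dv = (p.k * (v - p.v_r) * (v - p.v_t) - u + h + I) / p.C
    du = p.a * (p.b * (vc - p.v_r) - u)
    dh = p.a_h * (-p.b_h * (vc - p.v_r) - h) if p.h_enabled else 0.0
    return dv, du, dh


def step_neuron(
    state: NeuronState,
    params: NeuronParams,
    I_total: float,
    dt: float,
    t: float | None = None,
) -> tuple[NeuronState, bool]:
    """Advance one cell by ``dt`` ms under total current ``I_total`` (pA).

    Midpoint (RK2) update of (v, u, h); crossing the (possibly u-dependent)
    cutoff applies the simultaneous reset v<-c(+10u), u<-u+d, h<-h+d_h and
    reports ``spiked=True``.  Raises on non-finite state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v, u, h = state.v, state.u, state.h
    # adaptive sub-stepping keeps the explosive spike upstroke accurate at
    # coarse dt (substeps sized so v moves at most ~2 mV per substep)
    dv0, _, _ = _derivs(params, v, u, h, I_total)
    if not np.isfinite(dv0):
        raise FloatingPointError(
            f"non-finite state for cell type '{params.name}' at t={t} ms")
    nsub = min(64, 1 + int(abs(dv0) * dt / 2.0))
    hsub = dt / nsub
    for _ in range(nsub):
        dv1, du1, dh1 = _derivs(params, v, u, h, I_total)
        vm, um, hm = (v + 0.5 * hsub * dv1, u + 0.5 * hsub * du1,
                      h + 0.5 * hsub * dh1)
        dv2, du2, dh2 = _derivs(params, vm, um, hm, I_total)
        v += hsub * dv2
        u += hsub * du2
        h += hsub * dh2
        if v >= params.v_peak:
            break
    if not (np.isfinite(v) and np.isfinite(u) and np.isfinite(h)):
        raise FloatingPointError(
            f"non-finite state for cell type '{params.name}' at t={t} ms"
        )
    if params.olm_dynamic_reset:
        # u-dependent reset/cutoff, coupled per unit capacitance; the cutoff
        # is floored 10 mV above the reset for stability under strong drive
        un = min(max(u / params.C, 0.0), 1.5)
        reset_v = params.c + 10.0 * un
        cutoff = params.v_peak - 30.0 * un
    else:
        reset_v, cutoff = params.c, params.v_peak
    spiked = v >= cutoff
    if spiked:
        v = reset_v
        if params.h_enabled:
            h += params.d_h
        u += params.d
    new = NeuronState(v=v, u=u, h=h, last_spike_time=t if spiked else state.last_spike_time)
    return new, spiked


def integrate_neuron(
    params: NeuronParams,
    I: float | np.ndarray,
    duration: float,
    dt: float = 0.1,
    v0: float | None = None,
) -> np.ndarray:
    """Integrate a single cell under fixed (or per-step) current; return spike times (ms).

    This scalar path is the reference integrator used to cross-check the
    network engine (including at very fine dt).
    """
    n = int(round(duration / dt))
    Iarr = np.broadcast_to(np.asarray(I, dtype=float), (n,))
    st = NeuronState(v=params.v_r if v0 is None else v0)
    out = []
    for i in range(n):
        st, spiked = step_neuron(st, params, float(Iarr[i]), dt, t=(i + 1) * dt)
        if spiked:
            out.append((i + 1) * dt)
    return np.asarray(out)


def rheobase(params: NeuronParams) -> float:
    """Minimal sustained current (pA) for repetitive firing.

    With u at its subthreshold equilibrium u = b (v - v_r), dv/dt = 0 loses
    its fixed points when I exceeds max_v [-k(v-v_r)(v-v_t) + b(v-v_r)];
    the maximum of that quadratic has a closed form.
    """
    # -k(v-vr)(v-vt) + b(v-vr) = -k(v-vr)(v - (vt + b/k)); peak at midpoint
    vt_eff = params.v_t + params.b / params.k
    vm = 0.5 * (params.v_r + vt_eff)
    return params.k * (vm - params.v_r) * (vt_eff - vm)


def fi_curve(
    params: NeuronParams,
    I_values,
    duration: float = 1000.0,
    dt: float = 0.1,
) -> np.ndarray:
    """Steady firing rate (Hz) for each injected current (vectorized over currents)."""
    if duration < 1000.0:
        raise ValueError("duration must be at least 1000 ms")
    I_values = np.asarray(I_values, dtype=float)
    n = int(round(duration / dt))
    m = I_values.size
    v = np.full(m, params.v_r)
    u = np.zeros(m)
    h = np.zeros(m)
    counts = np.zeros(m, dtype=int)

    def derivs(v, u, h):
        vc = np.minimum(v, params.v_t)
        dv = (params.k * (v - params.v_r) * (v - params.v_t) - u + h + I_values) / params.C
        du = params.a * (params.b * (vc - params.v_r) - u)
        dh = params.a_h * (-params.b_h * (vc - params.v_r) - h) if params.h_enabled else 0.0
        return dv, du, dh

    for _ in range(n):
        dv1, du1, dh1 = derivs(v, u, h)
        dv2, du2, dh2 = derivs(v + 0.5 * dt * dv1, u + 0.5 * dt * du1, h + 0.5 * dt * dh1)
        v = v + dt * dv2
        u = u + dt * du2
        h = h + dt * dh2
        if params.olm_dynamic_reset:
            un = np.clip(u / params.C, 0.0, 1.5)
            reset_v = params.c + 10.0 * un
            cutoff = params.v_peak - 30.0 * un
        else:
            reset_v = np.full_like(v, params.c)
            cutoff = params.v_peak
        sp = v >= cutoff
        if np.any(sp):
            counts[sp] += 1
            v[sp] = reset_v[sp] if params.olm_dynamic_reset else params.c
            h = h + np.where(sp, params.d_h, 0.0) if params.h_enabled else h
            u[sp] += params.d
    return counts / (duration / 1000.0)


def apply_ach_to_neuron(
    params: NeuronParams,
    ach: float,
    effect_set: set[str] | None = None,
    magnitudes: dict | None = None,
) -> NeuronParams:
    """Return a copy of ``params`` with cholinergic effects applied.

    Effects scale linearly in (ach - 1); at ach=1 the output equals the
    baseline exactly.  ``effect_set`` defaults to every effect appropriate to
    the cell type; unknown effect names raise.  Magnitudes come from the
    model config (see data/model.yaml) unless overridden.
    """
    if not 0.0 <= ach <= 2.0:
        raise ValueError(f"ach must lie in [0, 2], got {ach}")
    if magnitudes is None:
        from .params import load_model_config

        magnitudes = load_model_config()["ach_effects"]
    if effect_set is None:
        effect_set = {e for e, types in ACH_EFFECTS.items() if params.name in types}
    unknown = set(effect_set) - set(ACH_EFFECTS)
    if unknown:
        raise ValueError(f"unknown ACh effect(s): {sorted(unknown)}")
    delta = ach - 1.0
    out = params
    for eff in sorted(effect_set):
        if params.name not in ACH_EFFECTS[eff]:
            continue
        mag = magnitudes[eff]
        if eff in ("pyr_depolarize", "olm_depolarize", "bc_depolarize"):
            out = replace(out, v_r=out.v_r + mag["dv_r"] * delta,
                          v_t=out.v_t)  # threshold untouched
        elif eff == "pyr_burstiness":
            out = replace(out, c=out.c + mag["dc"] * delta, d=out.d + mag["dd"] * delta)
        elif eff == "olm_adaptation":
            scale = max(0.1, 1.0 + mag["slope"] * delta)
            out = replace(out, b=out.b * scale, d=out.d * scale)
    return out
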