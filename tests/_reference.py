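"""Independent fine-step reference integrator for the neuron ODEs.

Deliberately written apart from the package's engine: a plain scalar
midpoint integrator over the same equations, JIT-compiled so sub-millisecond
steps over seconds of model time stay fast in tests.
"""

import numpy as np
from numba import njit


@njit
def integrate_fine(C, k, a, b, c, d, v_r, v_t, v_peak,
                   h_en, a_h, b_h, d_h,
                   I, duration, dt, v0):
    n = int(round(duration / dt))
    v, u, h = v0, 0.0, 0.0
    out = np.empty(n, dtype=np.float64)
    m = 0
    for i in range(n):
        vc = v if v < v_t else v_t
        dv1 = (k * (v - v_r) * (v - v_t) - u + h + I) / C
        du1 = a * (b * (vc - v_r) - u)
        dh1 = a_h * (-b_h * (vc - v_r) - h) if h_en else 0.0
        vm = v + 0.5 * dt * dv1
        um = u + 0.5 * dt * du1
        hm = h + 0.5 * dt * dh1
        vcm = vm if vm < v_t else v_t
        dv2 = (k * (vm - v_r) * (vm - v_t) - um + hm + I) / C
        du2 = a * (b * (vcm - v_r) - um)
        dh2 = a_h * (-b_h * (vcm - v_r) - hm) if h_en else 0.0
        v += dt * dv2
        u += dt * du2
        h += dt * dh2
        if v >= v_peak:
            v = c
            if h_en:
                h += d_h
            u += d
            out[m] = (i + 1) * dt
            m += 1
    return out[:m]


def reference_spike_times(params, I, duration, dt=0.001, v0=None):
    return integrate_fine(
        params.C, params.k, params.a, params.b, params.c, params.d,
        params.v_r, params.v_t, params.v_peak,
        params.h_enabled, params.a_h, params.b_h, params.d_h,
        float(I), float(duration), float(dt),
        params.v_r if v0 is None else float(v0),
    )
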