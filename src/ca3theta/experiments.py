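"""Named, seed-swept experiment presets and the cholinergic analyses.

Each preset resolves to a (NetworkSpec, ExperimentConfig) pair; presets are
run over several network instantiations (different master seeds vary the
initial membrane potentials, synaptic connections, synaptic weights and the
random external inputs) and metrics are aggregated as mean +/- SD.

The sub-network presets follow the component-inactivation logic: only the
listed populations and pathways are active, the h-current is off, and the
pyramids receive direct lognormal Poisson drive whenever the entorhinal
relay is not part of the circuit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .analysis import detect_peak, isi_histogram, population_spectrum, relative_theta
from .engine import GENERATORS, ExperimentConfig, inactivate_generator, run
from .inputs import DIRECT_DRIVE_STATS, DriveConfig
from .network import build_network, randomize_longitudinal

__all__ = [
    "PRESETS",
    "make_preset",
    "run_preset",
    "contribution_sweep",
    "ach_effect_decomposition",
    "dg_addition_test",
]

CA3_INTERNAL = ("rc", "pyr_olm", "pyr_bc", "olm_pyr", "bc_pyr", "bc_olm")
FIG9_PATHWAYS = ("ec_pyr", "ec_bc") + CA3_INTERNAL

#: cholinergic cell effects relevant to each isolated sub-network
SUBNET_EFFECTS = {
    "recurrent": ("rc_suppression", "pyr_depolarize", "pyr_burstiness"),
    "olm_pyr": ("olm_depolarize", "olm_adaptation", "pyr_depolarize", "pyr_burstiness"),
}


def child_seed(master_seed: int, i: int) -> int:
    return (int(master_seed) * 100003 + 7919 * i + 1) % (2**31 - 1)


def _ec_drive(duration):
    return (DriveConfig(target="ec", base_rate=15.0, duration=duration),)


def _direct_drive(duration, ach=1.0):
    stats = DIRECT_DRIVE_STATS[min(DIRECT_DRIVE_STATS, key=lambda k: abs(k - ach))]
    return (DriveConfig(target="ca3_pyr", lognormal=stats, duration=duration),)


def make_preset(name: str, seed: int, duration: float = 5000.0, ach: float = 1.0):
    """Resolve a preset name to a concrete (NetworkSpec, ExperimentConfig)."""
    iso = dict(
        silenced_populations=frozenset({"ca3_bc", "ca3_olm"}),
        h_on=False, ach=ach, seed=seed, duration=duration,
    )
    if name == "fig3_full":
        net = build_network(seed)
        cfg = ExperimentConfig(seed=seed, duration=duration, ach=ach,
                               drives=_ec_drive(duration), h_on=True)
    elif name == "fig4_isolated_pyr":
        net = build_network(seed, regions=("ca3",), pathways=[])
        cfg = ExperimentConfig(drives=_direct_drive(duration, ach),
                               active_pathways=frozenset(), **iso)
    elif name == "fig4d_fast_adaptation":
        net = build_network(seed, regions=("ca3",), pathways=[])
        cfg = ExperimentConfig(drives=_direct_drive(duration, ach),
                               active_pathways=frozenset(),
                               a_override={"ca3_pyr": 0.04}, **iso)
    elif name in ("fig5_ec_divergence", "fig5d_shuffled"):
        net = build_network(seed, regions=("ec", "ca3"), pathways=["ec_pyr"])
        if name == "fig5d_shuffled":
            net = randomize_longitudinal(net, "ec_pyr", seed)
        cfg = ExperimentConfig(drives=_ec_drive(duration),
                               active_pathways=frozenset({"ec_pyr"}), **iso)
    elif name == "fig6_recurrent_only":
        net = build_network(seed, regions=("ca3",), pathways=["rc"])
        cfg = ExperimentConfig(drives=_direct_drive(duration, ach),
                               active_pathways=frozenset({"rc"}), **iso)
    elif name.startswith("fig7_olm"):
        w = {"fig7_olm_weak": 2.0, "fig7_olm_strong": 6.0,
             "fig7_olm_baseline": None}[name]
        net = build_network(seed, regions=("ca3",), pathways=["olm_pyr", "pyr_olm"])
        cfg = ExperimentConfig(
            drives=_direct_drive(duration, ach),
            active_pathways=frozenset({"olm_pyr", "pyr_olm"}),
            silenced_populations=frozenset({"ca3_bc"}),
            weight_scale=None if w is None else {"pyr_olm": w},
            h_on=False, ach=ach, seed=seed, duration=duration)
    elif name.startswith("fig8"):
        variant = name.removeprefix("fig8_")
        doubled = variant in ("double_conn", "both", "both_strong")
        overrides = (
            {"bc_pyr": {"p": 0.6}, "pyr_bc": {"p": 0.3}} if doubled else None)
        net = build_network(seed, regions=("ca3",), pathways=["bc_pyr", "pyr_bc"],
                            rule_overrides=overrides)
        cfg = ExperimentConfig(
            drives=_direct_drive(duration, ach),
            active_pathways=frozenset({"bc_pyr", "pyr_bc"}),
            silenced_populations=frozenset({"ca3_olm"}),
            stp_disabled=(frozenset({"bc_pyr", "pyr_bc"})
                          if variant in ("no_stp", "both", "both_strong")
                          else frozenset()),
            weight_scale={"pyr_bc": 6.0} if variant == "both_strong" else None,
            h_on=False, ach=ach, seed=seed, duration=duration)
    elif name == "fig9_baseline":
        net = build_network(seed, regions=("ec", "ca3"))
        cfg = ExperimentConfig(seed=seed, duration=duration, ach=ach, h_on=False,
                               drives=_ec_drive(duration),
                               active_pathways=frozenset(FIG9_PATHWAYS))
    elif name == "fig9_with_dg":
        net = build_network(seed)
        cfg = ExperimentConfig(seed=seed, duration=duration, ach=ach, h_on=False,
                               drives=_ec_drive(duration))
    else:
        raise ValueError(f"unknown preset {name!r}")
    return net, cfg


PRESETS = (
    "fig3_full", "fig4_isolated_pyr", "fig4d_fast_adaptation",
    "fig5_ec_divergence", "fig5d_shuffled", "fig6_recurrent_only",
    "fig7_olm_weak", "fig7_olm_strong", "fig7_olm_baseline",
    "fig8_original", "fig8_no_stp", "fig8_double_conn", "fig8_both",
    "fig8_both_strong", "fig9_baseline", "fig9_with_dg",
)


def run_preset(
    name: str,
    master_seed: int,
    n_seeds: int = 10,
    duration: float = 5000.0,
    ach: float = 1.0,
    population: str = "ca3_pyr",
    band=(1.0, 30.0),
    mutate=None,
) -> dict:
    """Run a preset over ``n_seeds`` instantiations and aggregate metrics.

    ``mutate`` optionally transforms each ExperimentConfig (e.g. a generator
    inactivation) before the run.  Returns the runs themselves plus the
    seed-averaged spectrum, its band peak, per-seed relative theta, per-seed
    mean firing rate of ``population``, and the pooled ISI mode.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}")
    runs = []
    for i in range(n_seeds):
        net, cfg = make_preset(name, child_seed(master_seed, i), duration, ach)
        if mutate is not None:
            cfg = mutate(cfg)
        runs.append(run(cfg, net))
    spectrum = population_spectrum(runs, population)
    per_seed_rel = [relative_theta(population_spectrum(r, population)) for r in runs]
    rates = [float(np.mean(r.rates(population))) for r in runs]
    _, _, isi_mode = isi_histogram(runs, population)
    return {
        "name": name,
        "runs": runs,
        "spectrum": spectrum,
        "peak_hz": detect_peak(spectrum, band),
        "relative_theta": float(np.mean(per_seed_rel)),
        "relative_theta_per_seed": per_seed_rel,
        "mean_rate_hz": float(np.mean(rates)),
        "rate_per_seed": rates,
        "isi_mode_ms": isi_mode,
    }


def contribution_sweep(
    ach_states=(0.0, 1.0, 2.0),
    generators=GENERATORS,
    master_seed: int = 0,
    n_seeds: int = 10,
    duration: float = 5000.0,
) -> pd.DataFrame:
    """Normalized relative-theta table per (generator x ACh state).

    For each cholinergic state the baseline circuit (input to EC, DG and
    h-current off) is run, then each theta generator is inactivated in turn;
    per-seed relative theta is normalized by the state's seed-matched
    full-model mean, so the full-model entry is 1 by construction.
    """
    rows = []
    for ach in ach_states:
        base = run_preset("fig9_baseline", master_seed, n_seeds, duration, ach)
        base_mean = float(np.mean(base["relative_theta_per_seed"]))
        rows.append({"generator": "full", "ach": ach, "norm_rel_theta": 1.0,
                     "sd": float(np.std(base["relative_theta_per_seed"]) / base_mean),
                     "rel_theta": base_mean,
                     "mean_rate_hz": base["mean_rate_hz"]})
        for gen in generators:
            res = run_preset("fig9_baseline", master_seed, n_seeds, duration, ach,
                             mutate=lambda c, g=gen: inactivate_generator(c, g))
            vals = np.asarray(res["relative_theta_per_seed"]) / base_mean
            rows.append({"generator": gen, "ach": ach,
                         "norm_rel_theta": float(vals.mean()),
                         "sd": float(vals.std()),
                         "rel_theta": float(np.mean(res["relative_theta_per_seed"])),
                         "mean_rate_hz": res["mean_rate_hz"]})
    return pd.DataFrame(rows)


def _effect_config(cfg: ExperimentConfig, effect: str | None) -> ExperimentConfig:
    """Restrict cholinergic action to a single named effect (or none/all)."""
    if effect == "all":
        return cfg
    if effect is None:
        return cfg.with_(ach_cell_effects=frozenset(), ach_syn_pathways=frozenset())
    if effect == "rc_suppression":
        return cfg.with_(ach_cell_effects=frozenset(),
                         ach_syn_pathways=frozenset({"rc"}))
    return cfg.with_(ach_cell_effects=frozenset({effect}),
                     ach_syn_pathways=frozenset())


def ach_effect_decomposition(
    subnet: str,
    effects=None,
    ach_values=None,
    master_seed: int = 0,
    n_seeds: int = 5,
    duration: float = 5000.0,
) -> pd.DataFrame:
    """Relative-theta curves vs ACh with one cholinergic effect active per run.

    ``subnet`` is ``recurrent`` (pyramids + recurrent synapses) or
    ``olm_pyr`` (pyramids reciprocally coupled to OLM cells).  The external
    drive keeps baseline statistics so curves isolate the modeled effect.
    Includes an ``all`` curve with every effect expressed.
    """
    if subnet not in SUBNET_EFFECTS:
        raise ValueError(f"unknown subnet {subnet!r}")
    preset = "fig6_recurrent_only" if subnet == "recurrent" else "fig7_olm_baseline"
    effects = list(effects if effects is not None else SUBNET_EFFECTS[subnet])
    bad = set(effects) - set(SUBNET_EFFECTS[subnet]) - {"all"}
    if bad:
        raise ValueError(f"effects {sorted(bad)} not applicable to {subnet}")
    if ach_values is None:
        ach_values = np.round(np.arange(0.0, 2.0 + 1e-9, 0.1), 1)
    rows = []
    for eff in ["all"] + effects:
        for ach in ach_values:
            res = run_preset(
                preset, master_seed, n_seeds, duration, float(ach),
                mutate=lambda c, e=eff: _effect_config(
                    c.with_(drives=_direct_drive(duration, 1.0)), e))
            rows.append({"subnet": subnet, "effect": eff, "ach": float(ach),
                         "rel_theta": res["relative_theta"],
                         "sd": float(np.std(res["relative_theta_per_seed"]))})
    return pd.DataFrame(rows)


def dg_addition_test(
    ach_states=(0.0, 1.0, 2.0),
    master_seed: int = 0,
    n_seeds: int = 10,
    duration: float = 5000.0,
) -> pd.DataFrame:
    """Seed-paired change in CA3 relative theta from adding the DG circuit.

    For each cholinergic state the EC-driven baseline is run with and
    without the dentate gyrus on seed-matched instantiations (the CA3 wiring,
    initial potentials and inputs are identical within a pair); the paired
    difference in relative theta is tested with a two-sided paired t-test
    (Wilcoxon signed-rank available as ``method='wilcoxon'`` in the output).
    """
    rows = []
    for ach in ach_states:
        without = run_preset("fig9_baseline", master_seed, n_seeds, duration, ach)
        with_dg = run_preset("fig9_with_dg", master_seed, n_seeds, duration, ach)
        a = np.asarray(with_dg["relative_theta_per_seed"])
        b = np.asarray(without["relative_theta_per_seed"])
        if n_seeds >= 2:
            t, p = sstats.ttest_rel(a, b)
            wstat = sstats.wilcoxon(a, b) if np.any(a != b) else None
            wp = float(wstat.pvalue) if wstat is not None else float("nan")
        else:
            p, wp = float("nan"), float("nan")
        rows.append({"ach": ach, "increase": float(np.mean(a - b)),
                     "sd": float(np.std(a - b)), "p_value": float(p),
                     "p_wilcoxon": wp, "n_seeds": n_seeds})
    return pd.DataFrame(rows)
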