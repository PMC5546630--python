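"""Cell placement in 3-D space and the typed, spatially structured wiring.

Cells are distributed uniformly inside per-region boxes.  Inter-region
projections follow the lamellar organization of the hippocampus: connection
probability is a Gaussian function of the *longitudinal* distance between the
two cells, with the longitudinal coordinate of each region mapped linearly
onto a common normalized axis (so an EC cell at 30% of the EC axis targets
the neighborhood of 30% of the CA3 axis).  Recurrent and pyramidal-to-basket
connections are spatially homogeneous (fixed probability); mossy fibers
contact exactly two pyramidal targets drawn with Gaussian weights; and
pyramidal-to-OLM connections are the exact reciprocal of the OLM-to-pyramidal
edges, as for local feedback cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import load_model_config, load_network_config, load_pathway_table
from .utils import substream

__all__ = [
    "POPULATION_TYPES",
    "RegionLayout",
    "ConnectionRule",
    "NetworkSpec",
    "build_layout",
    "build_network",
    "gaussian_probability",
    "shared_input_fraction",
    "randomize_longitudinal",
]

#: population id -> (region, cell-type catalog entry)
POPULATION_TYPES = {
    "ec": ("ec", "ec"),
    "dg_gc": ("dg", "dg_gc"),
    "dg_bc": ("dg", "bc"),
    "dg_hipp": ("dg", "dg_hipp"),
    "ca3_pyr": ("ca3", "ca3_pyr"),
    "ca3_bc": ("ca3", "bc"),
    "ca3_olm": ("ca3", "olm"),
}

#: longitudinal extent (mm) of the common lamellar axis (the CA3 box length)
AXIS_LENGTH = float(load_network_config()["regions"]["ca3"]["box"][0])


@dataclass(frozen=True)
class ConnectionRule:
    """Spatial rule for one pathway."""

    kind: str  # gaussian | fixed | gaussian_capped | reciprocal
    p: float = 0.0
    sigma: float = 0.0
    cap: int = 0
    of: str = ""
    allow_self: bool = True
    randomize_longitudinal: bool = False

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"probability must lie in [0,1], got {self.p}")
        if self.kind in ("gaussian", "gaussian_capped") and self.sigma <= 0:
            raise ValueError("gaussian rules need sigma > 0")


@dataclass
class RegionLayout:
    """Positions (mm) of every cell of one region, grouped by population."""

    region: str
    box: tuple[float, float, float]
    counts: dict[str, int]
    positions: dict[str, np.ndarray]  # population -> (n, 3)

    def longitudinal_norm(self, pop: str) -> np.ndarray:
        return self.positions[pop][:, 0] / self.box[0]


@dataclass
class NetworkSpec:
    """Instantiated network: layouts plus typed directed edge lists."""

    seed: int
    layouts: dict[str, RegionLayout]
    edges: dict[str, pd.DataFrame] = field(default_factory=dict)
    # pathway -> DataFrame(source, target, weight); indices are cell indices
    # *within* the source/target populations of that pathway

    def n_cells(self, pop: str) -> int:
        region = POPULATION_TYPES[pop][0]
        return self.layouts[region].counts[pop]

    @property
    def populations(self) -> list[str]:
        return [p for p in POPULATION_TYPES if POPULATION_TYPES[p][0] in self.layouts]

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(positions, edges) tables; together they reload bit-exactly."""
        pos_rows = []
        for region, lay in self.layouts.items():
            for pop, xyz in lay.positions.items():
                for i, (x, y, z) in enumerate(xyz):
                    pos_rows.append((pop, i, x, y, z))
        pos = pd.DataFrame(pos_rows, columns=["population", "cell", "x", "y", "z"])
        cat = load_pathway_table()
        edge_frames = []
        for pw, df in self.edges.items():
            d = df.copy()
            d.insert(0, "pathway", pw)
            d["delay"] = cat[pw]["delay"]
            edge_frames.append(d)
        edges = (
            pd.concat(edge_frames, ignore_index=True)
            if edge_frames
            else pd.DataFrame(columns=["pathway", "source", "target", "weight", "delay"])
        )
        return pos, edges

    def save(self, positions_path, edges_path) -> None:
        pos, edges = self.to_tables()
        # shortest-roundtrip float text, so reload is bit-exact
        fmt = lambda x: repr(float(x))
        pos.to_csv(positions_path, sep="\t", index=False, float_format=fmt)
        edges.to_csv(edges_path, sep="\t", index=False, float_format=fmt)


def build_layout(region: str, seed: int, config: dict | None = None) -> RegionLayout:
    """Place the region's cells uniformly inside its box."""
    cfg = (config or load_network_config())["regions"][region]
    rng = substream(seed, f"positions:{region}")
    positions = {
        pop: rng.uniform(0.0, 1.0, size=(n, 3)) * np.asarray(cfg["box"])
        for pop, n in cfg["counts"].items()
    }
    return RegionLayout(region, tuple(cfg["box"]), dict(cfg["counts"]), positions)


def _load_rules(overrides: dict | None = None) -> dict[str, ConnectionRule]:
    raw = load_network_config()["rules"]
    rules = {}
    for pw, row in raw.items():
        row = dict(row)
        if overrides and pw in overrides:
            row.update(overrides[pw])
        kind = row.pop("kind")
        allow_self = row.pop("self", True)
        rules[pw] = ConnectionRule(kind=kind, allow_self=allow_self, **row)
    return rules


def gaussian_probability(p, sigma, distance):
    """Connection probability at a given longitudinal distance (mm)."""
    return p * np.exp(-0.5 * (np.asarray(distance, dtype=float) / sigma) ** 2)


def _pair_distances(src_x: np.ndarray, tgt_x: np.ndarray) -> np.ndarray:
    """Longitudinal distances (mm) between normalized coordinates on the shared axis."""
    return np.abs(src_x[:, None] - tgt_x[None, :]) * AXIS_LENGTH


def build_network(
    seed: int,
    regions: tuple[str, ...] = ("ec", "dg", "ca3"),
    pathways: list[str] | None = None,
    rule_overrides: dict | None = None,
) -> NetworkSpec:
    """Instantiate layouts and draw every edge; deterministic given ``seed``.

    ``pathways`` restricts which connection classes are built (default: all
    whose endpoint populations exist in the included regions).  Per-edge
    weights are drawn Uniform(0.5 w, w) in catalog units.
    """
    net_cfg = load_network_config()
    jit_lo, jit_hi = load_model_config()["weight_jitter"]
    layouts = {r: build_layout(r, seed) for r in regions}
    spec = NetworkSpec(seed=seed, layouts=layouts)
    cat = load_pathway_table()
    rules = _load_rules(rule_overrides)

    pops = set(spec.populations)
    wanted = []
    for pw, row in cat.items():
        if row["src"] == "ext":
            continue
        if pathways is not None and pw not in pathways:
            continue
        if row["src"] in pops and row["tgt"] in pops:
            wanted.append(pw)
        elif pathways is not None:
            raise ValueError(f"pathway {pw} references populations outside {regions}")

    def pop_xnorm(pop):
        region = POPULATION_TYPES[pop][0]
        return layouts[region].longitudinal_norm(pop)

    # reciprocal rules need their source pathway first
    wanted.sort(key=lambda pw: rules[pw].kind == "reciprocal")
    for pw in wanted:
        rule = rules[pw]
        src_pop, tgt_pop = cat[pw]["src"], cat[pw]["tgt"]
        rng = substream(seed, f"connectivity:{pw}")
        if rule.kind == "reciprocal":
            if rule.of not in spec.edges:
                raise ValueError(f"{pw}: reciprocal of missing pathway {rule.of}")
            base = spec.edges[rule.of]
            src, tgt = base["target"].to_numpy(), base["source"].to_numpy()
        elif rule.kind == "fixed":
            n_s, n_t = spec.n_cells(src_pop), spec.n_cells(tgt_pop)
            mask = rng.random((n_s, n_t)) < rule.p
            if src_pop == tgt_pop and not rule.allow_self:
                np.fill_diagonal(mask, False)
            src, tgt = np.nonzero(mask)
        elif rule.kind == "gaussian":
            d = _pair_distances(pop_xnorm(src_pop), pop_xnorm(tgt_pop))
            prob = gaussian_probability(rule.p, rule.sigma, d)
            mask = rng.random(prob.shape) < prob
            if src_pop == tgt_pop and not rule.allow_self:
                np.fill_diagonal(mask, False)
            src, tgt = np.nonzero(mask)
        elif rule.kind == "gaussian_capped":
            d = _pair_distances(pop_xnorm(src_pop), pop_xnorm(tgt_pop))
            w = np.exp(-0.5 * (d / rule.sigma) ** 2)
            src_l, tgt_l = [], []
            for i in range(d.shape[0]):
                pvec = w[i] / w[i].sum()
                chosen = rng.choice(d.shape[1], size=min(rule.cap, d.shape[1]),
                                    replace=False, p=pvec)
                src_l.extend([i] * len(chosen))
                tgt_l.extend(chosen.tolist())
            src, tgt = np.asarray(src_l, dtype=int), np.asarray(tgt_l, dtype=int)
        else:  # pragma: no cover - guarded by ConnectionRule
            raise ValueError(f"unknown rule kind {rule.kind}")

        wrng = substream(seed, f"weights:{pw}")
        w0 = cat[pw]["weight"]
        weights = wrng.uniform(jit_lo * w0, jit_hi * w0, size=len(src))
        spec.edges[pw] = pd.DataFrame(
            {"source": np.asarray(src, dtype=int),
             "target": np.asarray(tgt, dtype=int),
             "weight": weights}
        )
    return spec


def shared_input_fraction(spec: NetworkSpec, pathway: str, target_pop: str | None = None,
                          mode: str = "mean_size") -> float:
    """Mean pairwise overlap of source sets across target-cell pairs.

    For each unordered pair of target cells with source sets A and B the
    overlap is |A n B| / mean(|A|, |B|) (``mode='mean_size'``, the default)
    or |A n B| / |A u B| (``mode='jaccard'``).  Pairs where both sets are
    empty are skipped.
    """
    if pathway not in spec.edges:
        raise ValueError(f"pathway {pathway} not present")
    cat = load_pathway_table()
    tgt_pop = target_pop or cat[pathway]["tgt"]
    n_t = spec.n_cells(tgt_pop)
    if n_t < 2:
        raise ValueError("need at least two target cells")
    df = spec.edges[pathway]
    n_s = spec.n_cells(cat[pathway]["src"])
    inc = np.zeros((n_t, n_s), dtype=bool)
    inc[df["target"].to_numpy(), df["source"].to_numpy()] = True
    sizes = inc.sum(axis=1).astype(float)
    common = (inc.astype(np.int64) @ inc.T.astype(np.int64)).astype(float)
    iu = np.triu_indices(n_t, k=1)
    inter = common[iu]
    if mode == "mean_size":
        denom = 0.5 * (sizes[:, None] + sizes[None, :])[iu]
    elif mode == "jaccard":
        denom = (sizes[:, None] + sizes[None, :])[iu] - inter
    else:
        raise ValueError(f"unknown mode {mode}")
    ok = denom > 0
    if not ok.any():
        raise ValueError("no pair has any sources")
    return float(np.mean(inter[ok] / denom[ok]))


def randomize_longitudinal(spec: NetworkSpec, pathway: str, seed: int) -> NetworkSpec:
    """Reconnect a pathway's edges uniformly, ignoring longitudinal distance.

    Exactly preserves the edge count (edges are resampled uniformly without
    replacement from all source-target pairs); weights are re-drawn from the
    same Uniform(0.5 w, w) law.  Used as the control that removes lamellar
    structure while keeping total drive constant.
    """
    if pathway not in spec.edges or len(spec.edges[pathway]) == 0:
        return spec
    cat = load_pathway_table()
    n_s = spec.n_cells(cat[pathway]["src"])
    n_t = spec.n_cells(cat[pathway]["tgt"])
    n_e = len(spec.edges[pathway])
    rng = substream(seed, f"shuffle:{pathway}")
    flat = rng.choice(n_s * n_t, size=n_e, replace=False)
    jit_lo, jit_hi = load_model_config()["weight_jitter"]
    w0 = cat[pathway]["weight"]
    new = NetworkSpec(seed=spec.seed, layouts=spec.layouts, edges=dict(spec.edges))
    new.edges[pathway] = pd.DataFrame(
        {"source": flat // n_t, "target": flat % n_t,
         "weight": rng.uniform(jit_lo * w0, jit_hi * w0, size=n_e)}
    )
    return new
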