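"""Two-network connectivity: local grids, inhibitory loops, long-range rewiring.

Each of the two networks is a sheet of pyramidal cells (PYs) on a 2-D grid
with a matched interneuron (IN) sheet.  Local excitation connects every PY to
a random 30% subset of the (up to) 120 cells in its surrounding 11x11 window;
inhibition is globally random (PY->IN excitation and IN->PY feedback).
Long-range projections (LRPs) are created by rewiring: each local PY-PY
connection is independently replaced with probability 1 - p_local by an
excitatory projection onto a PY of the *other* network, carrying a
conduction delay.

Grid coordinates are 0-based row-major; the local neighborhood is Chebyshev
radius 5, truncated (non-periodic) at the grid edges so rotors can pin at
open boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model_core import DT_MS

__all__ = [
    "POP_PY",
    "POP_IN",
    "G_PY_PY",
    "G_PY_IN",
    "G_IN_PY",
    "N_PY_TO_IN",
    "N_IN_TO_PY",
    "NEIGHBOR_RADIUS",
    "LOCAL_FRACTION",
    "GridSpec",
    "PAPER_GRID",
    "DESK_GRID",
    "LRPConfig",
    "NetworkGraph",
    "build_local_py_graph",
    "build_inhibitory_graphs",
    "merge_graphs",
    "rewire_lrps",
    "assign_delay",
]

POP_PY = 0
POP_IN = 1

G_PY_PY = 0.06  # local excitatory PY-PY conductance
G_PY_IN = 0.0001  # PY -> IN excitation
G_IN_PY = 0.0002  # IN -> PY feedback inhibition (printed label "G_PY-IN"
# read as the IN->PY weight: the sentence describes feedback IN-PY inhibition)
N_PY_TO_IN = 25  # outgoing PY->IN connections per PY
N_IN_TO_PY = 49  # outgoing IN->PY connections per IN
NEIGHBOR_RADIUS = 5  # Chebyshev radius of the 11x11 local window
LOCAL_FRACTION = 0.3  # fraction of eligible neighbors a PY connects to


@dataclass(frozen=True)
class GridSpec:
    """Grid extents of the PY and IN sheets of one network."""

    py_rows: int
    py_cols: int
    in_rows: int
    in_cols: int

    @property
    def n_py(self) -> int:
        return self.py_rows * self.py_cols

    @property
    def n_in(self) -> int:
        return self.in_rows * self.in_cols


PAPER_GRID = GridSpec(400, 400, 200, 200)
DESK_GRID = GridSpec(100, 100, 50, 50)


@dataclass(frozen=True)
class LRPConfig:
    """Long-range-projection rewiring parameters.

    p_local: probability a local PY-PY connection is kept.
    g_lrp:   LRP conductance.
    delay_ms: mean conduction delay.
    jitter:  relative half-width of the uniform delay distribution
             (0 = fixed delay, 0.2 = mean +/-20%, 1.0 = mean +/-100%).
    homologous: if True, LRPs target the same grid coordinate in the other
             network instead of a uniformly random PY.
    """

    p_local: float = 1.0
    g_lrp: float = 0.06
    delay_ms: float = 0.0
    jitter: float = 0.0
    homologous: bool = False

    def __post_init__(self):
        if not (0.0 < self.p_local <= 1.0):
            raise ValueError(f"p_local must be in (0, 1], got {self.p_local}")
        if self.delay_ms < 0:
            raise ValueError("delay_ms must be >= 0")


@dataclass
class NetworkGraph:
    """Outgoing projections of one network, as parallel edge arrays.

    ``post_network`` is 0 for targets within the same network and 1 for the
    other network (LRPs).  The excitatory/inhibitory channel is implied by
    the presynaptic population (PY -> excitatory, IN -> inhibitory);
    ``depressing`` is true exactly for PY->PY edges.
    """

    grid: GridSpec
    pre_pop: np.ndarray  # uint8, POP_PY/POP_IN
    pre: np.ndarray  # int32 flat index within presynaptic population
    post_pop: np.ndarray  # uint8
    post: np.ndarray  # int32 flat index within postsynaptic population
    post_network: np.ndarray  # uint8, 0 same network / 1 other network
    weight: np.ndarray  # float64
    delay_steps: np.ndarray  # int32

    def __post_init__(self):
        n = len(self.pre)
        for name in ("pre_pop", "post_pop", "post", "post_network", "weight", "delay_steps"):
            if len(getattr(self, name)) != n:
                raise ValueError("edge arrays must have equal length")

    def __len__(self) -> int:
        return len(self.pre)

    @property
    def depressing(self) -> np.ndarray:
        return (self.pre_pop == POP_PY) & (self.post_pop == POP_PY)

    def out_degree(self, pop: int = POP_PY) -> np.ndarray:
        n = self.grid.n_py if pop == POP_PY else self.grid.n_in
        mask = self.pre_pop == pop
        return np.bincount(self.pre[mask], minlength=n)

    def to_frame(self) -> pd.DataFrame:
        """Columnar edge list (round-trips through CSV)."""
        return pd.DataFrame(
            {
                "pre_pop": self.pre_pop,
                "pre": self.pre,
                "post_pop": self.post_pop,
                "post": self.post,
                "post_network": self.post_network,
                "weight": self.weight,
                "delay_steps": self.delay_steps,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, grid: GridSpec) -> "NetworkGraph":
        return cls(
            grid=grid,
            pre_pop=frame["pre_pop"].to_numpy(np.uint8),
            pre=frame["pre"].to_numpy(np.int32),
            post_pop=frame["post_pop"].to_numpy(np.uint8),
            post=frame["post"].to_numpy(np.int32),
            post_network=frame["post_network"].to_numpy(np.uint8),
            weight=frame["weight"].to_numpy(np.float64),
            delay_steps=frame["delay_steps"].to_numpy(np.int32),
        )

    @classmethod
    def from_csv(cls, path, grid: GridSpec) -> "NetworkGraph":
        return cls.from_frame(pd.read_csv(path), grid)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def build_local_py_graph(grid: GridSpec, rng: np.random.Generator) -> NetworkGraph:
    """Local PY-PY excitation: 30% of the 11x11 Chebyshev neighborhood.

    Interior PYs have exactly 36 outgoing projections (30% of 120 eligible
    neighbors); edge and corner PYs connect to round(0.3 * eligible) of their
    truncated in-grid neighborhood (rounding half away from zero).  No
    autapses; all weights G_PY_PY, zero delay, depressing.
    """
    R, C = grid.py_rows, grid.py_cols
    if R < 1 or C < 1:
        raise ValueError("grid must be at least 1x1")
    rad = NEIGHBOR_RADIUS
    # (dr, dc) offsets of the full window, excluding self.
    offs = np.array(
        [(dr, dc) for dr in range(-rad, rad + 1) for dc in range(-rad, rad + 1) if (dr, dc) != (0, 0)],
        dtype=np.int64,
    )
    n_full = len(offs)  # 120
    k_full = _round_half_away(LOCAL_FRACTION * n_full)  # 36

    pres: list[np.ndarray] = []
    posts: list[np.ndarray] = []

    # Interior neurons all share the full 120-cell window: vectorized choice
    # of k_full neighbors per neuron via per-row random keys.
    if R > 2 * rad and C > 2 * rad:
        ir = np.arange(rad, R - rad)
        ic = np.arange(rad, C - rad)
        rr, cc = np.meshgrid(ir, ic, indexing="ij")
        flat = (rr * C + cc).ravel()
        n_int = flat.size
        keys = rng.random((n_int, n_full))
        sel = np.argpartition(keys, k_full - 1, axis=1)[:, :k_full]
        post = flat[:, None] + (offs[sel, 0] * C + offs[sel, 1])
        pres.append(np.repeat(flat, k_full))
        posts.append(post.ravel())

    # Border neurons: truncated neighborhoods, handled one by one.
    for r in range(R):
        for c in range(C):
            if rad <= r < R - rad and rad <= c < C - rad:
                continue
            dr = offs[:, 0] + r
            dc = offs[:, 1] + c
            ok = (dr >= 0) & (dr < R) & (dc >= 0) & (dc < C)
            eligible = dr[ok] * C + dc[ok]
            k = _round_half_away(LOCAL_FRACTION * eligible.size)
            if k == 0:
                continue
            chosen = rng.choice(eligible, size=k, replace=False)
            pres.append(np.full(k, r * C + c, dtype=np.int64))
            posts.append(chosen)

    pre = np.concatenate(pres).astype(np.int32)
    post = np.concatenate(posts).astype(np.int32)
    n = len(pre)
    return NetworkGraph(
        grid=grid,
        pre_pop=np.full(n, POP_PY, dtype=np.uint8),
        pre=pre,
        post_pop=np.full(n, POP_PY, dtype=np.uint8),
        post=post,
        post_network=np.zeros(n, dtype=np.uint8),
        weight=np.full(n, G_PY_PY),
        delay_steps=np.zeros(n, dtype=np.int32),
    )


def build_inhibitory_graphs(grid: GridSpec, rng: np.random.Generator) -> NetworkGraph:
    """Global random PY->IN excitation and IN->PY feedback inhibition.

    Every PY projects to 25 distinct uniformly random INs (weight G_PY_IN);
    every IN projects to 49 distinct uniformly random PYs (weight G_IN_PY).
    Both loops stay within the network, with zero delay.
    """
    n_py, n_in = grid.n_py, grid.n_in
    if n_py < 1 or n_in < 1:
        raise ValueError("both populations must be nonempty")
    py_to_in = np.empty((n_py, N_PY_TO_IN), dtype=np.int32)
    for i in range(n_py):
        py_to_in[i] = rng.choice(n_in, size=N_PY_TO_IN, replace=False)
    in_to_py = np.empty((n_in, N_IN_TO_PY), dtype=np.int32)
    for i in range(n_in):
        in_to_py[i] = rng.choice(n_py, size=N_IN_TO_PY, replace=False)

    n_e = n_py * N_PY_TO_IN
    n_i = n_in * N_IN_TO_PY
    return NetworkGraph(
        grid=grid,
        pre_pop=np.concatenate(
            [np.full(n_e, POP_PY, dtype=np.uint8), np.full(n_i, POP_IN, dtype=np.uint8)]
        ),
        pre=np.concatenate(
            [
                np.repeat(np.arange(n_py, dtype=np.int32), N_PY_TO_IN),
                np.repeat(np.arange(n_in, dtype=np.int32), N_IN_TO_PY),
            ]
        ),
        post_pop=np.concatenate(
            [np.full(n_e, POP_IN, dtype=np.uint8), np.full(n_i, POP_PY, dtype=np.uint8)]
        ),
        post=np.concatenate([py_to_in.ravel(), in_to_py.ravel()]),
        post_network=np.zeros(n_e + n_i, dtype=np.uint8),
        weight=np.concatenate([np.full(n_e, G_PY_IN), np.full(n_i, G_IN_PY)]),
        delay_steps=np.zeros(n_e + n_i, dtype=np.int32),
    )


def merge_graphs(*graphs: NetworkGraph) -> NetworkGraph:
    """Concatenate edge tables of graphs sharing one GridSpec."""
    grid = graphs[0].grid
    if any(g.grid != grid for g in graphs):
        raise ValueError("all graphs must share the same GridSpec")
    cat = lambda name: np.concatenate([getattr(g, name) for g in graphs])
    return NetworkGraph(
        grid=grid,
        pre_pop=cat("pre_pop"),
        pre=cat("pre"),
        post_pop=cat("post_pop"),
        post=cat("post"),
        post_network=cat("post_network"),
        weight=cat("weight"),
        delay_steps=cat("delay_steps"),
    )


def assign_delay(config: LRPConfig, rng: np.random.Generator, size: int = None):
    """Conduction delay(s) in integer Euler steps.

    With jitter 0 the delay is round(delay_ms / dt); otherwise delays are
    uniform on [delay_ms (1 - jitter), delay_ms (1 + jitter)], rounded to
    steps and clipped at zero.
    """
    scalar = size is None
    n = 1 if scalar else size
    if config.jitter == 0 or config.delay_ms == 0:
        steps = np.full(n, int(round(config.delay_ms / DT_MS)), dtype=np.int32)
    else:
        lo = config.delay_ms * (1.0 - config.jitter)
        hi = config.delay_ms * (1.0 + config.jitter)
        ms = rng.uniform(lo, hi, size=n)
        steps = np.maximum(np.rint(ms / DT_MS), 0).astype(np.int32)
    return int(steps[0]) if scalar else steps


def rewire_lrps(
    graph: NetworkGraph, config: LRPConfig, rng: np.random.Generator
) -> NetworkGraph:
    """Replace local PY-PY connections with delayed LRPs to the other network.

    Each local PY-PY projection is independently rewired with probability
    1 - p_local.  The replacement keeps the presynaptic PY, targets a
    uniformly random PY of the other network (or the homologous grid
    coordinate), carries weight g_lrp and a delay from :func:`assign_delay`.
    Total out-degree of every PY is conserved.
    """
    if config.p_local >= 1.0:
        return graph
    local = (
        (graph.pre_pop == POP_PY)
        & (graph.post_pop == POP_PY)
        & (graph.post_network == 0)
    )
    idx = np.flatnonzero(local)
    hit = idx[rng.random(idx.size) < (1.0 - config.p_local)]
    post = graph.post.copy()
    post_network = graph.post_network.copy()
    weight = graph.weight.copy()
    delay_steps = graph.delay_steps.copy()
    if config.homologous:
        post[hit] = graph.pre[hit]
    else:
        post[hit] = rng.integers(0, graph.grid.n_py, size=hit.size, dtype=np.int32)
    post_network[hit] = 1
    weight[hit] = config.g_lrp
    delay_steps[hit] = assign_delay(config, rng, size=hit.size)
    return replace(
        graph, post=post, post_network=post_network, weight=weight, delay_steps=delay_steps
    )
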