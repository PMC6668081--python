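"""Information-optimized structural descriptors.

Backbone conformation is discretized by a Voronoi partition of the virtual
C-alpha dihedral-pair plane (gamma_{i-1}, gamma_i): ``k`` seed points on a
0.1-radian grid (62 x 62 = 3844 candidate positions spanning [0, 6.1]^2)
define ``k`` cells, and every observation is assigned to its nearest seed.
Contact structure is discretized by ``m`` equal-width distance bins on
(0, d_max].

Both resolutions are chosen by maximizing leave-one-out mutual information
(the "information maximization device"): a resolution that is too coarse
cannot express sequence dependence, while one that is too fine cannot be
populated by the data and is penalized by the leave-one-out correction, so
the objective rises and then falls and the maximizer is an interior optimum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .mc import MCParams

GRID_SPACING: float = 0.1
GRID_SIDE: int = 62  # grid values 0.0, 0.1, ..., 6.1
N_GRID_POINTS: int = GRID_SIDE * GRID_SIDE  # 3844

#: default search ranges for the contact discretization
DEFAULT_DMAX_VALUES: tuple[float, ...] = tuple(
    round(4.0 + 0.5 * i, 1) for i in range(17)
)  # 4.0 .. 12.0 A
DEFAULT_M_VALUES: tuple[int, ...] = tuple(range(4, 101))


def grid_points() -> np.ndarray:
    """The 3844 candidate seed positions, shape (3844, 2), radians."""
    vals = np.arange(GRID_SIDE) * GRID_SPACING
    g1, g2 = np.meshgrid(vals, vals, indexing="ij")
    return np.stack([g1.ravel(), g2.ravel()], axis=1)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class VoronoiPartition:
    """A k-cell Voronoi tessellation of the dihedral-pair plane."""

    seeds: tuple[tuple[float, float], ...]
    metric: str = "euclidean"  # or "toroidal" (period 2*pi per axis)

    def __post_init__(self) -> None:
        if self.metric not in ("euclidean", "toroidal"):
            raise ConfigurationError(f"unknown metric {self.metric!r}")
        if not 1 <= len(self.seeds) <= N_GRID_POINTS:
            raise ConfigurationError("k must be in 1..3844")
        if len(set(self.seeds)) != len(self.seeds):
            raise ConfigurationError("seeds must be distinct")
        arr = np.asarray(self.seeds, dtype=float)
        if arr.min() < 0.0 or arr.max() >= 6.2:
            raise ConfigurationError("seed coordinates must lie in [0, 6.2)")

    @property
    def k(self) -> int:
        return len(self.seeds)

    @property
    def seed_array(self) -> np.ndarray:
        return np.asarray(self.seeds, dtype=float)

    def assign(self, gamma_pairs: np.ndarray) -> np.ndarray:
        """0-based nearest-seed index per row; ties go to the lowest index."""
        g = np.atleast_2d(np.asarray(gamma_pairs, dtype=float))
        d = np.abs(g[:, None, :] - self.seed_array[None, :, :])
        if self.metric == "toroidal":
            d = np.minimum(d, 2.0 * np.pi - d)
        return np.argmin((d**2).sum(axis=2), axis=1)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"metric": self.metric, "seeds": [list(s) for s in self.seeds]}, fh)

    @classmethod
    def from_json(cls, path) -> "VoronoiPartition":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            seeds=tuple(tuple(s) for s in obj["seeds"]),
            metric=obj.get("metric", "euclidean"),
        )


def default_backbone_partition() -> VoronoiPartition:
    """The packaged 16-seed tessellation (information-optimal seeds derived
    from a large non-redundant X-ray structure set)."""
    text = resources.files("redalpha.data").joinpath(
        "voronoi_seeds_backbone16.json"
    ).read_text()
    obj = json.loads(text)
    return VoronoiPartition(
        seeds=tuple(tuple(s) for s in obj["seeds"]), metric=obj["metric"]
    )


@dataclass(frozen=True)
class ContactDiscretization:
    """Equal-width binning of the contact distance on (0, d_max]."""

    d_max: float
    m: int
    edges: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.d_max <= 12.0:
            raise ConfigurationError("d_max must be in (0, 12] A")
        if not 1 <= self.m <= 1000:
            raise ConfigurationError("m must be a positive bin count")
        object.__setattr__(
            self, "edges", np.linspace(0.0, self.d_max, self.m + 1)
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"d_max": self.d_max, "m": self.m}, fh)

    @classmethod
    def from_json(cls, path) -> "ContactDiscretization":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(d_max=obj["d_max"], m=obj["m"])


# ---------------------------------------------------------------------------
# assignment


def assign_cell(gamma_pair, partition: VoronoiPartition) -> int:
    """1-based index of the nearest seed (ties: lowest seed index)."""
    return int(partition.assign(np.asarray(gamma_pair, dtype=float))[0]) + 1


def assign_bins(distances: np.ndarray, disc: ContactDiscretization) -> np.ndarray:
    """0-based bins with left-open right-closed edges; -1 for d > d_max.

    Raises for nonpositive distances.
    """
    d = np.asarray(distances, dtype=float)
    if d.size and d.min() <= 0.0:
        raise ConfigurationError("distances must be positive")
    idx = np.searchsorted(disc.edges, d, side="left") - 1
    return np.where(d > disc.d_max, -1, np.clip(idx, 0, disc.m - 1)).astype(np.int64)


def assign_bin(distance: float, disc: ContactDiscretization) -> int | None:
    """1-based bin of a distance, or None beyond d_max."""
    b = int(assign_bins(np.asarray([distance]), disc)[0])
    return None if b < 0 else b + 1


# ---------------------------------------------------------------------------
# leave-one-out MI fast paths (dense-count versions of the estimator formulas)


def _mi_conditioned(
    cond: np.ndarray,
    states: np.ndarray,
    n_cond_levels: int,
    n_states: int,
    n_norm: float,
    lam: float,
    loo: bool,
    pair_factor: float = 1.0,
) -> float:
    """(pair_factor/n_norm) * sum ln f(state|cond)/f(state) over observations."""
    n = len(states)
    sub = 1.0 if loo else 0.0
    n_state = np.bincount(states, minlength=n_states).astype(float)
    bg = n_state / n
    keys = cond * n_states + states
    joint = np.bincount(keys, minlength=n_cond_levels * n_states).astype(float)
    n_cond = np.bincount(cond, minlength=n_cond_levels).astype(float)
    num = joint[keys] - sub + lam * bg[states]
    den = n_cond[cond] - sub + lam
    marg = (n_state[states] - sub + lam / n_states) / (n - sub + lam)
    if num.min() <= 0.0 or marg.min() <= 0.0:
        raise ConfigurationError("nonpositive frequency estimate; use lam > 0")
    return float(pair_factor * np.log(num / den / marg).sum() / n_norm)


# ---------------------------------------------------------------------------
# Voronoi seed optimization


def _distinct_grid_cells(gam: np.ndarray) -> int:
    snapped = np.clip(np.rint(gam / GRID_SPACING).astype(int), 0, GRID_SIDE - 1)
    return len(np.unique(snapped[:, 0] * GRID_SIDE + snapped[:, 1]))


def optimize_voronoi(
    dataset,
    k: int,
    mc: MCParams = MCParams(),
    seed: int = 0,
    metric: str = "euclidean",
    lam: float = 1.0,
    loo: bool = True,
    return_trace: bool = False,
):
    """Monte Carlo search for the k seeds maximizing central-residue MI.

    Candidate seeds live on the 0.1-radian grid.  Proposals either replace
    1..max_move random seeds with random grid points or displace that many
    seeds to neighboring grid points, with equal probability; only strictly
    improving proposals are accepted.  The sequence effect is restricted to
    the central residue of the trimer.  Returns ``(partition, objective)``
    (objective recomputed through the mi_core estimator), plus the
    accepted-objective trace when requested.
    """
    from . import mi_core  # deferred: mi_core imports this module

    tri, gam = dataset.backbone_arrays
    if len(tri) == 0:
        raise ConfigurationError("dataset has no backbone observations")
    if k > _distinct_grid_cells(gam):
        raise ConfigurationError("k exceeds the number of distinct observed grid cells")
    letters = tri[:, 1].copy()
    pts = grid_points()
    rng = np.random.default_rng(seed)
    max_move = mc.max_move if k <= 20 else max(mc.max_move, math.ceil(k / 8))
    two_pi = 2.0 * np.pi

    def eval_state(state: np.ndarray) -> float:
        seeds = pts[state]
        d = np.abs(gam[:, None, :] - seeds[None, :, :])
        if metric == "toroidal":
            d = np.minimum(d, two_pi - d)
        cells = np.argmin((d**2).sum(axis=2), axis=1)
        return _mi_conditioned(
            letters, cells, 20, k, float(len(cells)), lam, loo
        )

    best_state: np.ndarray | None = None
    best_obj = -np.inf
    trace: list[float] = []
    for _ in range(mc.restarts):
        state = rng.choice(N_GRID_POINTS, size=k, replace=False)
        obj = eval_state(state)
        trace.append(obj)
        stall = 0
        while stall < mc.patience:
            t = int(rng.integers(1, max_move + 1))
            t = min(t, k)
            which = rng.choice(k, size=t, replace=False)
            cand = state.copy()
            if rng.random() < 0.5:
                cand[which] = rng.choice(N_GRID_POINTS, size=t, replace=False)
            else:
                # displace to one of the 8 neighboring grid points
                gi, gj = cand[which] // GRID_SIDE, cand[which] % GRID_SIDE
                step = rng.integers(-1, 2, size=(t, 2))
                gi = np.clip(gi + step[:, 0], 0, GRID_SIDE - 1)
                gj = np.clip(gj + step[:, 1], 0, GRID_SIDE - 1)
                cand[which] = gi * GRID_SIDE + gj
            if len(np.unique(cand)) < k:
                stall += 1
                continue
            cand_obj = eval_state(cand)
            if cand_obj > obj:
                state, obj = cand, cand_obj
                trace.append(obj)
                stall = 0
            else:
                stall += 1
        if obj > best_obj:
            best_obj, best_state = obj, state.copy()

    seeds = tuple(
        (round(float(p[0]), 1), round(float(p[1]), 1)) for p in pts[np.sort(best_state)]
    )
    partition = VoronoiPartition(seeds=seeds, metric=metric)
    model = mi_core.fit_backbone(
        dataset, partition, lam=lam, loo=loo, conditioning="central"
    )
    objective = mi_core.mi_backbone(model)
    if return_trace:
        return partition, objective, trace
    return partition, objective


def scan_k(
    dataset,
    k_values: Sequence[int],
    mc: MCParams = MCParams(),
    seed: int = 0,
    **kwargs,
) -> tuple[int, pd.DataFrame]:
    """Run optimize_voronoi for each k; return (argmax k, table of objectives)."""
    rows = []
    for i, k in enumerate(k_values):
        _, obj = optimize_voronoi(dataset, k, mc=mc, seed=seed + i, **kwargs)
        rows.append({"k": int(k), "objective": obj})
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["objective"].idxmax(), "k"])
    return best_k, table


# ---------------------------------------------------------------------------
# contact discretization optimization


def optimize_contact_discretization(
    dataset,
    d_max_values: Sequence[float] = DEFAULT_DMAX_VALUES,
    m_values: Sequence[int] = DEFAULT_M_VALUES,
    lam: float = 1.0,
    loo: bool = True,
) -> tuple[ContactDiscretization, pd.DataFrame]:
    """Exhaustive (d_max, m) grid search maximizing contact MI on the full
    alphabet.  Contacts beyond a candidate d_max are excluded from both
    numerator and denominator counts at that setting."""
    if not len(d_max_values) or not len(m_values):
        raise ConfigurationError("empty search grid")
    pairs, dist = dataset.contact_arrays
    if len(dist) == 0:
        raise ConfigurationError("dataset has no contact observations")
    if dataset.n_d < 1:
        raise ConfigurationError("contact MI needs n_d >= 1")
    pk = (pairs[:, 0] * 20 + pairs[:, 1]).astype(np.int64)
    rows = []
    for d_max in d_max_values:
        keep = dist <= d_max
        pk_d, dist_d = pk[keep], dist[keep]
        for m in m_values:
            disc = ContactDiscretization(d_max=float(d_max), m=int(m))
            if len(dist_d) == 0:
                rows.append({"d_max": float(d_max), "m": int(m), "objective": 0.0})
                continue
            bins = assign_bins(dist_d, disc)
            obj = _mi_conditioned(
                pk_d, bins, 400, disc.m, float(dataset.n_d), lam, loo, pair_factor=2.0
            )
            rows.append({"d_max": float(d_max), "m": int(m), "objective": obj})
    table = pd.DataFrame(rows)
    best = table.loc[table["objective"].idxmax()]
    return ContactDiscretization(d_max=float(best["d_max"]), m=int(best["m"])), table
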