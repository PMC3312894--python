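"""GGH (cellular Potts) lattice representation and the Metropolis engine.

Cells are contiguous-by-construction (though fragmentation is permitted) sets
of lattice sites sharing an integer index; index 0 is the medium.  The pattern
evolves by energy-biased pixel-copy attempts: a target site and a random
neighbour source site are drawn, the source index overwrites the target with
the Metropolis probability of the induced change in the effective energy.
One Monte Carlo step (MCS) is a number of attempts equal to the lattice size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from . import _kernels
from .errors import ConfigurationError, InvalidParameterError

MEDIUM = 0

__all__ = [
    "MEDIUM",
    "PixelLattice",
    "CellRecord",
    "CellTable",
    "PottsParams",
    "RandomStream",
    "MCSStats",
    "neighbour_offsets",
    "acceptance_probability",
    "attempt_index_copy",
    "run_mcs",
    "count_fragments",
]


def neighbour_offsets(order: int, dimensionality: int = 3) -> np.ndarray:
    """Integer offset vectors up to the ``order``-th nearest neighbour shell.

    Shells are the distinct squared Euclidean lengths realisable on the integer
    lattice (3D: 1,2,3,4 -> 6+12+8+6 = 32 offsets; 2D: 1,2,4,5).  Offsets are
    returned lexicographically sorted, without the zero vector.
    """
    if not isinstance(order, (int, np.integer)) or not 1 <= order <= 4:
        raise InvalidParameterError(f"neighbour order must be in 1..4, got {order!r}")
    if dimensionality not in (2, 3):
        raise InvalidParameterError("dimensionality must be 2 or 3")
    rng = range(-2, 3)
    if dimensionality == 2:
        cand = [(i, j, 0) for i in rng for j in rng]
    else:
        cand = [(i, j, k) for i in rng for j in rng for k in rng]
    cand = [v for v in cand if v != (0, 0, 0)]
    sq = sorted({v[0] ** 2 + v[1] ** 2 + v[2] ** 2 for v in cand})
    keep = set(sq[:order])
    out = sorted(v for v in cand if v[0] ** 2 + v[1] ** 2 + v[2] ** 2 in keep)
    return np.array(out, dtype=np.int64)


def acceptance_probability(delta_h: float, temperature: float) -> float:
    """Metropolis acceptance: 1 if dH <= 0, exp(-dH/T) otherwise."""
    if temperature <= 0:
        raise InvalidParameterError("temperature (motility) must be positive")
    if delta_h <= 0:
        return 1.0
    return float(np.exp(-delta_h / temperature))


class RandomStream:
    """The single xorshift64* stream driving all stochastic choices."""

    def __init__(self, seed: int):
        if seed is None:
            raise InvalidParameterError("an explicit seed is required")
        # splitmix64 scramble so that small seeds give well-mixed states
        z = (int(seed) + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
        z = (z ^ (z >> 30)) * 0xBF58476D1CE4E5B9 & 0xFFFFFFFFFFFFFFFF
        z = (z ^ (z >> 27)) * 0x94D049BB133111EB & 0xFFFFFFFFFFFFFFFF
        z ^= z >> 31
        if z == 0:
            z = 0x1234567887654321
        self.seed = int(seed)
        self.state = np.array([z], dtype=np.uint64)

    def uniform(self) -> float:
        return _kernels.rng_uniform(self.state)

    def below(self, n: int) -> int:
        return _kernels.rng_below(self.state, n)

    def unit_vector(self) -> np.ndarray:
        """Uniform random direction on the sphere (Box-Muller gaussians)."""
        while True:
            g = []
            for _ in range(2):
                u1 = max(self.uniform(), 1e-300)
                u2 = self.uniform()
                r = np.sqrt(-2.0 * np.log(u1))
                g.extend([r * np.cos(2 * np.pi * u2), r * np.sin(2 * np.pi * u2)])
            v = np.array(g[:3])
            n = np.linalg.norm(v)
            if n > 1e-12:
                return v / n


@dataclass
class PixelLattice:
    """3D integer spin field: sigma(site) = cell index, 0 = medium."""

    dims: tuple[int, int, int]
    pixel_scale: float = 1.0
    spin: np.ndarray = None

    def __post_init__(self):
        if self.spin is None:
            self.spin = np.zeros(self.dims, dtype=np.int32)
        else:
            self.spin = np.ascontiguousarray(self.spin, dtype=np.int32)
            if self.spin.shape != tuple(self.dims):
                raise ConfigurationError("spin array shape does not match dims")
        self.dims = tuple(int(d) for d in self.dims)

    @property
    def n_sites(self) -> int:
        return int(np.prod(self.dims))


class CellTable:
    """Per-cell bookkeeping stored as flat arrays indexed by cell id.

    Index 0 is the medium pseudo-cell (tracked volume, exempt from
    constraints).  ``CellRecord`` proxies give a per-cell object view.
    """

    _COLS = ("ctype", "volume", "surface", "tvol", "tsurf", "init_volume",
             "cx", "cy", "cz", "alive", "g_now", "g_prev", "mode_detached")

    def __init__(self, capacity: int = 64):
        self._n = 1  # id 0 = medium
        cap = max(capacity, 4)
        self.ctype = np.zeros(cap, dtype=np.int32)
        self.volume = np.zeros(cap, dtype=np.int64)
        self.surface = np.zeros(cap, dtype=np.int64)
        self.tvol = np.zeros(cap, dtype=np.float64)
        self.tsurf = np.zeros(cap, dtype=np.float64)
        self.init_volume = np.zeros(cap, dtype=np.int64)
        self.cx = np.zeros(cap, dtype=np.float64)
        self.cy = np.zeros(cap, dtype=np.float64)
        self.cz = np.zeros(cap, dtype=np.float64)
        self.alive = np.zeros(cap, dtype=np.uint8)
        self.g_now = np.zeros(cap, dtype=np.float64)
        self.g_prev = np.zeros(cap, dtype=np.float64)
        self.mode_detached = np.zeros(cap, dtype=np.uint8)

    # -- storage -----------------------------------------------------------
    @property
    def capacity(self) -> int:
        return self.ctype.shape[0]

    @property
    def max_id(self) -> int:
        return self._n - 1

    def _grow(self):
        for name in self._COLS:
            arr = getattr(self, name)
            new = np.zeros(arr.shape[0] * 2, dtype=arr.dtype)
            new[: arr.shape[0]] = arr
            setattr(self, name, new)

    def new_cell(self, ctype: int) -> int:
        if self._n >= self.capacity:
            self._grow()
        cid = self._n
        self._n += 1
        self.ctype[cid] = ctype
        self.alive[cid] = 1
        return cid

    def live_ids(self) -> np.ndarray:
        return np.nonzero(self.alive[: self._n])[0]

    def record(self, cid: int) -> "CellRecord":
        if cid <= 0 or cid > self.max_id:
            raise LookupError(f"no such cell id {cid}")
        return CellRecord(self, int(cid))

    def records(self) -> Iterator["CellRecord"]:
        for cid in self.live_ids():
            yield CellRecord(self, int(cid))


class CellRecord:
    """Object view of one row of a :class:`CellTable`."""

    __slots__ = ("_t", "id")

    def __init__(self, table: CellTable, cid: int):
        self._t = table
        self.id = cid

    def _get(self, col):
        return getattr(self._t, col)[self.id]

    def _set(self, col, v):
        getattr(self._t, col)[self.id] = v

    type = property(lambda s: int(s._get("ctype")), lambda s, v: s._set("ctype", v))
    volume = property(lambda s: int(s._get("volume")), lambda s, v: s._set("volume", v))
    surface = property(lambda s: int(s._get("surface")), lambda s, v: s._set("surface", v))
    target_volume = property(lambda s: float(s._get("tvol")), lambda s, v: s._set("tvol", v))
    target_surface = property(lambda s: float(s._get("tsurf")), lambda s, v: s._set("tsurf", v))
    initial_volume = property(lambda s: int(s._get("init_volume")), lambda s, v: s._set("init_volume", v))
    alive = property(lambda s: bool(s._get("alive")), lambda s, v: s._set("alive", int(v)))

    @property
    def centroid(self) -> np.ndarray:
        v = max(self.volume, 1)
        return np.array([self._get("cx"), self._get("cy"), self._get("cz")]) / v

    @property
    def mode(self) -> str:
        return "detached" if self._get("mode_detached") else "attached"

    @mode.setter
    def mode(self, value: str):
        self._set("mode_detached", 1 if value == "detached" else 0)

    def __repr__(self):
        return (f"CellRecord(id={self.id}, type={self.type}, v={self.volume}, "
                f"s={self.surface}, mode={self.mode})")


@dataclass
class PottsParams:
    """Potts engine parameters.

    ``contact_table`` maps unordered type-name pairs to the boundary energy
    coefficient J; it must be symmetric and cover every pair of the declared
    ``type_names`` (index 0 is the medium type).
    """

    type_names: tuple[str, ...] = ("Medium", "LowBetaCat", "HighBetaCat")
    contact_table: dict = field(default_factory=dict)
    lambda_volume: float = 2.0
    lambda_surface: float = 0.5
    temperature: float = 8.0
    neighbour_order: int = 4
    rng_seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be > 0")
        if not 1 <= int(self.neighbour_order) <= 4:
            raise InvalidParameterError("neighbour_order must be in 1..4")
        for (a, b), v in list(self.contact_table.items()):
            if (b, a) in self.contact_table and self.contact_table[(b, a)] != v:
                raise ConfigurationError(
                    f"contact_table is not symmetric for pair ({a}, {b})")

    def type_index(self, name: str) -> int:
        return self.type_names.index(name)

    def j_matrix(self) -> np.ndarray:
        """Dense symmetric J(tau, tau') matrix; missing pairs are an error."""
        n = len(self.type_names)
        jm = np.zeros((n, n))
        for i, a in enumerate(self.type_names):
            for k, b in enumerate(self.type_names):
                if i == 0 and k == 0:
                    continue  # medium-medium links are same-index, never counted
                if (a, b) in self.contact_table:
                    jm[i, k] = self.contact_table[(a, b)]
                elif (b, a) in self.contact_table:
                    jm[i, k] = self.contact_table[(b, a)]
                else:
                    raise ConfigurationError(
                        f"contact_table missing type pair ({a}, {b})")
        return jm

    def lambda_v_array(self) -> np.ndarray:
        n = len(self.type_names)
        arr = np.full(n, float(self.lambda_volume))
        arr[0] = 0.0
        return arr

    def lambda_s_array(self) -> np.ndarray:
        n = len(self.type_names)
        arr = np.full(n, float(self.lambda_surface))
        arr[0] = 0.0
        return arr


@dataclass
class MCSStats:
    attempts: int
    acceptances: int
    net_delta_h: float
    net_delta_h_chemo: float = 0.0


_DUMMY_FIELD = np.zeros((1, 1, 1))


def _kernel_args(lattice, cells, params, chemo_field, mu_array):
    jm = params.j_matrix()
    use_chemo = chemo_field is not None
    field_arr = chemo_field if use_chemo else _DUMMY_FIELD
    mu = mu_array if mu_array is not None else np.zeros(len(params.type_names))
    return (lattice.spin, cells.ctype, cells.volume, cells.surface,
            cells.tvol, cells.tsurf, cells.cx, cells.cy, cells.cz, cells.alive,
            jm, params.lambda_v_array(), params.lambda_s_array(), mu,
            field_arr, use_chemo,
            neighbour_offsets(params.neighbour_order, 3),
            float(params.temperature))


def attempt_index_copy(lattice, cells, params, rng, chemo_field=None,
                       mu_array=None):
    """One pixel-copy attempt; returns ``(accepted, delta_H)``.

    Same-index draws and off-lattice source draws are no-ops reported as
    rejected with delta_H = 0.
    """
    args = _kernel_args(lattice, cells, params, chemo_field, mu_array)
    out = _kernels.run_mcs_kernel(*args, rng.state, 1)
    _, _, _, _, last_dh, last_acc, _, *_ = out
    return bool(last_acc), float(last_dh)


def run_mcs(lattice, cells, params, rng, chemo_field=None, mu_array=None,
            n_attempts=None) -> MCSStats:
    """One Monte Carlo step: ``n_sites`` pixel-copy attempts."""
    if n_attempts is None:
        n_attempts = lattice.n_sites
    args = _kernel_args(lattice, cells, params, chemo_field, mu_array)
    out = _kernels.run_mcs_kernel(*args, rng.state, int(n_attempts))
    attempts, acc, net_dh, net_dh_chemo, *_ = out
    return MCSStats(int(attempts), int(acc), float(net_dh), float(net_dh_chemo))


def recompute_geometry(lattice: PixelLattice, cells: CellTable) -> None:
    """Recompute volumes, surfaces and centroid sums from the spin field."""
    spin = lattice.spin
    ncap = cells.capacity
    counts = np.bincount(spin.ravel(), minlength=ncap)
    cells.volume[:] = counts[:ncap]
    boundary, _ = _kernels.contact_counts_kernel(spin, ncap)
    cells.surface[:] = boundary
    cells.surface[0] = 0
    for axis, col in enumerate(("cx", "cy", "cz")):
        coord = np.indices(lattice.dims)[axis].ravel()
        sums = np.bincount(spin.ravel(), weights=coord, minlength=ncap)
        getattr(cells, col)[:] = sums[:ncap]
    live = cells.volume[: cells.max_id + 1] > 0
    live[0] = False
    cells.alive[: cells.max_id + 1] = live.astype(np.uint8)


def paint_box(lattice, cells, cid, lo, hi):
    """Assign the half-open box [lo, hi) to cell ``cid`` (initialisation)."""
    x0, y0, z0 = lo
    x1, y1, z1 = hi
    lattice.spin[x0:x1, y0:y1, z0:z1] = cid


def count_fragments(lattice: PixelLattice, cells: CellTable) -> dict[int, int]:
    """Connected-component count per live cell (6-connectivity diagnostic)."""
    from scipy import ndimage

    out = {}
    for cid in cells.live_ids():
        mask = lattice.spin == cid
        _, n = ndimage.label(mask)
        out[int(cid)] = int(n)
    return out
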