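"""Lattice tractography: solid-angle transition probabilities and pathway scores.

Structural connectivity is scored between a seed and every reachable voxel by
(1) discretizing each voxel's fiber orientation distribution (FOD) onto the 26
lattice-neighbor directions, (2) converting it to a per-voxel transition
probability over those neighbors by integrating the FOD over the spherical
Voronoi cell (solid angle) of each neighbor direction, and (3) solving for the
best pathway score, defined as the maximum over lattice paths of the product of
step transition probabilities.  The solver is the deterministic limit of an
infinite ensemble of sampled random walks that retains the strongest path: it
is a best-first (max-product) fixed point, equivalent to a shortest path under
``-log p`` edge costs.  A sampled-walk Monte Carlo estimator is provided as an
independent consistency check.

Conventions
-----------
* The 26 neighbor offsets are ordered lexicographically over
  ``{-1,0,1}^3 \\ {0}`` (see :data:`OFFSETS`); FOD amplitude channel ``d``
  always refers to ``OFFSETS[d]``.
* FOD amplitudes are *cell-integrated* masses: channel ``d`` holds the FOD
  probability mass inside the spherical Voronoi cell of direction ``d``, so an
  isotropic (uniform-density) FOD has amplitudes equal to the solid-angle
  fractions, not ``1/26``.
* Neighbor geometry is computed in world mm, so anisotropic voxels are
  respected through ``voxel_size``.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import ConfigError
from .grid import VolumeGrid

# 26 offsets in {-1,0,1}^3 minus the origin, lexicographic order.
OFFSETS: np.ndarray = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
    dtype=int,
)
OFFSETS.setflags(write=False)

#: index of the antipodal offset of each offset
OPPOSITE: np.ndarray = np.array(
    [int(np.flatnonzero((OFFSETS == -OFFSETS[d]).all(axis=1))[0]) for d in range(26)]
)
OPPOSITE.setflags(write=False)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (n, 3)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@lru_cache(maxsize=8)
def _neighbor_geometry(voxel_size: tuple, n_samples: int) -> tuple:
    vs = np.asarray(voxel_size, dtype=float)
    vecs = OFFSETS * vs  # world-mm step vectors
    units = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    pts = _fibonacci_sphere(n_samples)
    # nearest direction by max cosine = spherical Voronoi assignment
    owner = np.argmax(pts @ units.T, axis=1)
    counts = np.bincount(owner, minlength=26)
    weights = counts / float(n_samples)
    units.setflags(write=False)
    weights.setflags(write=False)
    return units, weights


def neighbor_directions(
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_samples: int = 200_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors and solid-angle fractions of the 26 lattice neighbors.

    Each of the 26 offsets is scaled by ``voxel_size`` (world mm) and
    normalized; its weight is the fraction of the unit sphere whose nearest
    direction (spherical Voronoi cell) it is, estimated on a deterministic
    Fibonacci lattice of ``n_samples`` points.  Weights sum to 1 exactly
    because every sample is assigned to exactly one cell.

    Returns
    -------
    (units, weights):
        ``units`` is (26, 3) float; ``weights`` is (26,) float summing to 1.
    """
    return _neighbor_geometry(tuple(float(v) for v in voxel_size), int(n_samples))


def isotropic_amplitudes(voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Cell-mass amplitudes of a uniform-density FOD = the solid-angle fractions."""
    return neighbor_directions(voxel_size)[1].copy()


@dataclass
class FODField:
    """Per-voxel fiber orientation distribution on the 26-direction set.

    ``amplitudes`` has shape ``grid.shape + (26,)``; entries are nonnegative,
    antipodally symmetric cell masses summing to 1 per voxel.
    """

    grid: VolumeGrid
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=float)
        if amp.shape != self.grid.shape + (26,):
            raise ConfigError(
                f"amplitudes shape {amp.shape} != grid shape + (26,) {self.grid.shape + (26,)}"
            )
        self.amplitudes = amp

    @classmethod
    def normalized(cls, grid: VolumeGrid, amplitudes: np.ndarray) -> "FODField":
        """Build a field, clipping negatives to 0 and normalizing each voxel to sum 1."""
        amp = np.clip(np.asarray(amplitudes, dtype=float), 0.0, None)
        tot = amp.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            amp = np.where(tot > 0, amp / tot, 0.0)
        return cls(grid, amp)

    def validate(self, atol: float = 1e-8) -> None:
        amp = self.amplitudes
        if (amp < -atol).any():
            raise ValueError("FOD amplitudes must be nonnegative")
        if not np.allclose(amp, amp[..., OPPOSITE], atol=atol):
            raise ValueError("FOD amplitudes must be antipodally symmetric")
        tot = amp.sum(axis=-1)
        nz = tot > 0
        if not np.allclose(tot[nz], 1.0, atol=atol):
            raise ValueError("FOD amplitudes must sum to 1 per voxel")


@dataclass
class TransitionField:
    """Per-voxel probability of stepping to each of the 26 lattice neighbors.

    ``p`` has shape ``grid.shape + (26,)``; rows of in-mask voxels with at
    least one in-mask neighbor sum to 1, steps leaving the mask (or the grid)
    carry probability 0.
    """

    grid: VolumeGrid
    p: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.p.shape != self.grid.shape + (26,):
            raise ConfigError("transition p has wrong shape")
        if self.mask.shape != self.grid.shape:
            raise ConfigError("mask has wrong shape")


def _neighbor_valid(mask: np.ndarray) -> np.ndarray:
    """(shape + (26,)) bool: stepping by OFFSETS[d] stays in grid and in mask."""
    shape = mask.shape
    valid = np.zeros(shape + (26,), dtype=bool)
    for d, (di, dj, dk) in enumerate(OFFSETS):
        src = [slice(max(0, -di), min(shape[0], shape[0] - di)),
               slice(max(0, -dj), min(shape[1], shape[1] - dj)),
               slice(max(0, -dk), min(shape[2], shape[2] - dk))]
        dst = [slice(max(0, di), min(shape[0], shape[0] + di)),
               slice(max(0, dj), min(shape[1], shape[1] + dj)),
               slice(max(0, dk), min(shape[2], shape[2] + dk))]
        valid[tuple(src) + (d,)] = mask[tuple(dst)]
    return valid


def transition_probabilities(fod: FODField, mask: np.ndarray) -> TransitionField:
    """Solid-angle transition probabilities from a (normalized) FOD field.

    Because FOD amplitudes are already cell-integrated over the spherical
    Voronoi cells of the 26 neighbor directions, integrating the FOD over the
    solid angle toward neighbor ``d`` is exactly amplitude ``d``; transitions
    are then renormalized over in-mask neighbors.  In-mask voxels whose FOD is
    all zero fall back to an isotropic distribution (with a warning).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fod.grid.shape:
        raise ConfigError("mask shape does not match grid")
    if not mask.any():
        raise ConfigError("mask is empty")
    valid = _neighbor_valid(mask)
    p = np.where(valid, fod.amplitudes, 0.0)
    p[~mask] = 0.0

    row = p.sum(axis=-1)
    dead = mask & (row == 0)
    if dead.any():
        # all-zero FOD (or all mass pointing out of the mask): isotropic fallback
        warnings.warn(
            f"{int(dead.sum())} in-mask voxels had no usable FOD mass; "
            "using isotropic fallback",
            stacklevel=2,
        )
        iso = isotropic_amplitudes(fod.grid.voxel_size)
        fb = np.where(valid[dead], iso, 0.0)
        p[dead] = fb
        row = p.sum(axis=-1)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(row[..., None] > 0, p / np.where(row[..., None] > 0, row[..., None], 1.0), 0.0)
    return TransitionField(fod.grid, p, mask)


@dataclass
class ConnectivityField:
    """Best pathway score from the seed to every voxel, with predecessors.

    ``score`` is in [0, 1] (1 at the seed); ``predecessor`` holds the flat
    index of the previous voxel on the best path (-1 for seeds and unreachable
    voxels).
    """

    grid: VolumeGrid
    score: np.ndarray
    predecessor: np.ndarray
    seed_voxels: np.ndarray

    def seed_flat(self) -> np.ndarray:
        return np.ravel_multi_index(self.seed_voxels.T, self.grid.shape)


@dataclass
class Track:
    """An ordered voxel path from seed to target with its product score."""

    voxels: np.ndarray  # (L, 3) int
    score: float


def _flat_offsets(shape: tuple[int, int, int]) -> np.ndarray:
    _, sy, sz = shape
    return OFFSETS[:, 0] * (sy * sz) + OFFSETS[:, 1] * sz + OFFSETS[:, 2]


def solve_connectivity(
    trans: TransitionField, seed_voxels, mask: np.ndarray | None = None
) -> ConnectivityField:
    """Max-product pathway scores from the seed set to every mask voxel.

    ``score(v) = max over lattice paths seed -> v of the product of step
    transition probabilities`` — the value reached by an infinite number of
    sampled walks when only the strongest path is retained.  Computed by a
    best-first (Dijkstra-type) expansion, which is exact because step
    probabilities lie in (0, 1] so scores never increase along a path.

    Ties between equal-score routes are broken deterministically by keeping
    the lexicographically smallest (flat-index) predecessor.
    """
    if mask is None:
        mask = trans.mask
    mask = np.asarray(mask, dtype=bool)
    shape = trans.grid.shape
    seeds = np.atleast_2d(np.asarray(seed_voxels, dtype=int))
    if seeds.shape[1] != 3:
        raise ConfigError("seed_voxels must be (n, 3) voxel indices")
    for s in seeds:
        if not mask[tuple(s)]:
            raise ConfigError(f"seed voxel {tuple(s)} is not inside the mask")

    n = int(np.prod(shape))
    p = trans.p.reshape(n, 26)
    mflat = mask.reshape(n)
    score = np.zeros(n)
    pred = np.full(n, -1, dtype=np.int64)
    settled = np.zeros(n, dtype=bool)
    foff = _flat_offsets(shape)

    heap: list[tuple[float, int]] = []
    for s in seeds:
        f = int(np.ravel_multi_index(tuple(s), shape))
        score[f] = 1.0
        heapq.heappush(heap, (-1.0, f))

    while heap:
        neg, u = heapq.heappop(heap)
        if settled[u] or -neg < score[u]:
            continue
        settled[u] = True
        su = score[u]
        pu = p[u]
        for d in range(26):
            q = pu[d]
            if q <= 0.0:
                continue
            v = u + foff[d]
            # q > 0 guarantees the step stays in grid and in the transition mask,
            # but restrict to the (possibly smaller) query mask as well
            if not mflat[v] or settled[v]:
                continue
            cand = su * q
            if cand > score[v]:
                score[v] = cand
                pred[v] = u
                heapq.heappush(heap, (-cand, v))
            elif cand == score[v] and cand > 0.0 and (pred[v] == -1 or u < pred[v]):
                pred[v] = u

    return ConnectivityField(
        trans.grid, score.reshape(shape), pred.reshape(shape), seeds
    )


def backtrack_track(field: ConnectivityField, trans: TransitionField, target) -> Track:
    """Recover the best seed->target path by following predecessors.

    The product of the transition probabilities along the returned path is
    recomputed and checked against the stored score (1e-10 relative).
    """
    shape = field.grid.shape
    t = tuple(int(x) for x in np.asarray(target).ravel())
    if field.score[t] <= 0.0:
        raise ValueError(f"target {t} is unreachable from the seed (score 0)")

    pred = field.predecessor.reshape(-1)
    n = pred.size
    path = [int(np.ravel_multi_index(t, shape))]
    while pred[path[-1]] != -1:
        path.append(int(pred[path[-1]]))
        if len(path) > n:
            raise RuntimeError("predecessor chain does not terminate")
    path.reverse()
    voxels = np.column_stack(np.unravel_index(np.asarray(path), shape))

    # recompute the product along the path
    offset_index = {tuple(o): d for d, o in enumerate(OFFSETS)}
    prod = 1.0
    for a, b in zip(voxels[:-1], voxels[1:]):
        d = offset_index[tuple((b - a).tolist())]
        prod *= trans.p[tuple(a) + (d,)]
    stored = float(field.score[t])
    if stored > 0 and abs(prod - stored) > 1e-10 * stored:
        raise RuntimeError(
            f"recomputed track product {prod!r} disagrees with stored score {stored!r}"
        )
    return Track(voxels=voxels, score=prod)


def cortical_score_map(
    field: ConnectivityField,
    gm_mask: np.ndarray,
    log_scale: bool = True,
    floor: float = 1e-12,
) -> np.ndarray:
    """Restrict pathway scores to gray matter, optionally on a 0-10 log scale.

    The display mapping is monotone: a raw score of 1 maps to 10, scores at or
    below ``floor`` map to 0, intermediate scores map to
    ``10 * (1 - ln(s)/ln(floor))``.  Voxels outside ``gm_mask`` are NaN.
    """
    gm = np.asarray(gm_mask, dtype=bool)
    out = np.full(field.grid.shape, np.nan)
    s = field.score[gm]
    if not log_scale:
        out[gm] = s
        return out
    vals = np.zeros_like(s)
    pos = s > floor
    vals[pos] = 10.0 * (1.0 - np.log(s[pos]) / np.log(floor))
    out[gm] = np.clip(vals, 0.0, None)
    return out


def monte_carlo_oracle(
    trans: TransitionField,
    seed_voxel,
    n_walkers: int,
    max_steps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled-walk estimate of pathway scores (consistency check, not pipeline).

    Walkers start at the seed and step according to the transition
    probabilities.  Returns ``(best_product, hit_freq)`` over the grid: the
    maximum path product among walks reaching each voxel (a lower bound on the
    solver score, since sampling can only miss the optimum) and the fraction
    of walkers that visit each voxel at least once.

    Intended for small lattices: memory scales as ``n_walkers * n_voxels``.
    """
    if n_walkers < 1:
        raise ConfigError("n_walkers must be >= 1")
    shape = trans.grid.shape
    n = int(np.prod(shape))
    p = trans.p.reshape(n, 26)
    cum = np.cumsum(p, axis=1)
    foff = _flat_offsets(shape)

    start = int(np.ravel_multi_index(tuple(np.asarray(seed_voxel, int)), shape))
    pos = np.full(n_walkers, start, dtype=np.int64)
    prod = np.ones(n_walkers)
    alive = np.ones(n_walkers, dtype=bool)

    best = np.zeros(n)
    best[start] = 1.0
    visited = np.zeros((n_walkers, n), dtype=bool)
    visited[:, start] = True

    for _ in range(max_steps):
        rows = cum[pos[alive]]
        tot = rows[:, -1]
        dead_now = tot <= 0.0  # absorbing voxel (no outgoing mass)
        u = rng.random(alive.sum()) * np.where(tot > 0, tot, 1.0)
        step = (rows < u[:, None]).sum(axis=1).clip(max=25)
        q = p[pos[alive], step]
        newpos = pos[alive] + foff[step]
        idx = np.flatnonzero(alive)
        keep = ~dead_now
        alive_idx = idx[keep]
        pos[alive_idx] = newpos[keep]
        prod[alive_idx] = prod[alive_idx] * q[keep]
        alive[idx[dead_now]] = False
        if not alive.any():
            break
        visited[alive_idx, pos[alive_idx]] = True
        np.maximum.at(best, pos[alive_idx], prod[alive_idx])

    hit = visited.sum(axis=0) / float(n_walkers)
    return best.reshape(shape), hit.reshape(shape)


def brute_force_scores(
    trans: TransitionField, seed_voxel, mask: np.ndarray | None = None
) -> np.ndarray:
    """Exhaustive max-product path enumeration (reference oracle, small grids).

    Depth-first enumeration of lattice paths from the seed with dominance
    pruning: a branch is cut when its running product cannot beat the best
    value already found at its head voxel, which is sound because any
    continuation multiplies both alternatives by the same suffix factors.
    Independent of the best-first solver.
    """
    if mask is None:
        mask = trans.mask
    shape = trans.grid.shape
    n = int(np.prod(shape))
    p = trans.p.reshape(n, 26)
    mflat = np.asarray(mask, dtype=bool).reshape(n)
    foff = _flat_offsets(shape)
    best = np.zeros(n)
    start = int(np.ravel_multi_index(tuple(np.asarray(seed_voxel, int)), shape))
    if not mflat[start]:
        raise ConfigError("seed voxel is outside the mask")
    best[start] = 1.0

    stack = [(start, 1.0)]
    while stack:
        u, val = stack.pop()
        for d in range(26):
            q = p[u, d]
            if q <= 0.0:
                continue
            v = u + foff[d]
            if not mflat[v]:
                continue
            cand = val * q
            if cand > best[v]:
                best[v] = cand
                stack.append((v, cand))
    return best.reshape(shape)
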