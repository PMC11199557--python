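"""Simplified probabilistic streamline tractography with classification targets.

Reimplements the classification-targets tracking protocol on synthetic
orientation fields: streamlines are seeded at striatal voxel centres,
propagated in fixed steps through a per-voxel fibre-orientation mixture, and
credited to the first composite target they enter.  Defaults mirror the
standard parameterisation (5000 samples per seed voxel, 0.5 mm steps, 2000
steps per sample, curvature threshold 0.2 interpreted as the minimum cosine
of the turning angle) with an optional distance-correction mode in which a
sample contributes its path length in mm instead of a unit count.

Deliberate simplifications: nearest-voxel orientation lookup (no trilinear
interpolation), seed points at voxel centres, and tract direction treated as
undirected — at each step the orientation sign minimising the turning angle
is taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import LatentCompartmentField, ScoreMapPair
from .grid import VoxelGrid

TERMINAL_EXCLUSION = "exclusion"
TERMINAL_CURVATURE = "curvature_stop"
TERMINAL_MAX_STEPS = "max_steps"
TERMINAL_LEFT = "left_volume"


@dataclass(frozen=True)
class TrackingParams:
    n_samples: int = 5000
    step_mm: float = 0.5
    max_steps: int = 2000
    curvature_min_cos: float = 0.2
    distance_correction: bool = True
    #: von Mises-Fisher concentration of direction sampling; None = exact
    angular_dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.max_steps < 1:
            raise ValueError("n_samples and max_steps must be >= 1")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if not -1.0 <= self.curvature_min_cos <= 1.0:
            raise ValueError("curvature_min_cos must be in [-1, 1]")
        if self.angular_dispersion is not None and self.angular_dispersion <= 0:
            raise ValueError("angular_dispersion must be positive or None")


@dataclass
class OrientationField:
    """Per-voxel fibre orientation mixture: unit directions and weights."""

    grid: VoxelGrid
    directions: np.ndarray   # dims + (K, 3)
    weights: np.ndarray      # dims + (K,), nonnegative; sum 1 where defined

    def __post_init__(self) -> None:
        if self.directions.shape[:-2] != tuple(self.grid.dims):
            raise ValueError("directions must have shape dims + (K, 3)")
        if (self.weights < 0).any():
            raise ValueError("mixture weights must be nonnegative")
        wsum = self.weights.sum(axis=-1)
        defined = wsum > 0
        norms = np.linalg.norm(self.directions, axis=-1)
        used = defined[..., None] & (self.weights > 0)
        if not np.allclose(norms[used], 1.0, atol=1e-6):
            raise ValueError("orientation directions must be unit-norm")

    @property
    def defined(self) -> np.ndarray:
        return self.weights.sum(axis=-1) > 0


def uniform_field(grid: VoxelGrid, direction) -> OrientationField:
    """Single-fibre field pointing everywhere along ``direction``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    dirs = np.broadcast_to(d, tuple(grid.dims) + (1, 3)).copy()
    w = np.ones(tuple(grid.dims) + (1,))
    return OrientationField(grid, dirs, w)


def field_from_compartments(
    field: LatentCompartmentField,
    striosome_dir=(0.0, 0.0, -1.0),
    matrix_dir=(0.0, 0.0, 1.0),
) -> OrientationField:
    """Orientation field realising the latent compartments mechanically.

    Striosome voxels point toward the striosome-favoring target, matrix and
    background voxels toward the matrix-favoring one (the sign convention
    only matters at the seed; propagation is undirected).
    """
    grid = field.grid
    s = np.asarray(striosome_dir, float); s /= np.linalg.norm(s)
    m = np.asarray(matrix_dir, float); m /= np.linalg.norm(m)
    dirs = np.broadcast_to(m, tuple(grid.dims) + (1, 3)).copy()
    dirs[field.striosome] = s
    w = np.ones(tuple(grid.dims) + (1,))
    return OrientationField(grid, dirs, w)


@dataclass
class TargetSet:
    """Composite classification targets plus an optional exclusion mask."""

    striosome: np.ndarray
    matrix: np.ndarray
    exclusion: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.striosome & self.matrix).any():
            raise ValueError("target masks must be disjoint")
        if self.exclusion is not None and (
            self.exclusion & (self.striosome | self.matrix)
        ).any():
            raise ValueError("exclusion mask must be disjoint from targets")

    def names(self) -> tuple[str, str]:
        return ("striosome", "matrix")


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def _sample_vmf(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Draw unit vectors from a von Mises-Fisher distribution around each mu.

    Wood (1994) rejection-free inversion for the 2-sphere: the cosine of the
    polar angle has density proportional to exp(kappa * w).
    """
    n = mu.shape[0]
    u = rng.random(n)
    # inverse CDF of w on [-1, 1]
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = 2.0 * np.pi * rng.random(n)
    st = np.sqrt(np.clip(1.0 - w ** 2, 0.0, None))
    local = np.stack([st * np.cos(phi), st * np.sin(phi), w], axis=1)
    # rotate local +z onto mu
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(np.broadcast_to(z, mu.shape), mu)
    c = mu[:, 2]
    out = np.empty_like(mu)
    parallel = np.linalg.norm(v, axis=1) < 1e-12
    # Rodrigues rotation, batched
    k = v / np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-300)
    cos_t = c
    sin_t = np.linalg.norm(v, axis=1)
    kxl = np.cross(k, local)
    kdl = (k * local).sum(axis=1, keepdims=True)
    out = (local * cos_t[:, None] + kxl * sin_t[:, None]
           + k * kdl * (1.0 - cos_t[:, None]))
    out[parallel & (c > 0)] = local[parallel & (c > 0)]
    flipped = parallel & (c < 0)
    out[flipped] = -local[flipped]
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


def _propagate_batch(
    field: OrientationField,
    starts: np.ndarray,            # (n, 3) world mm
    params: TrackingParams,
    targets: TargetSet,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate n streamlines; returns (steps_taken, terminal_code).

    Terminal codes: 0 striosome target, 1 matrix target, 2 exclusion,
    3 curvature stop, 4 max steps, 5 left volume.
    """
    grid = field.grid
    n = starts.shape[0]
    pos = starts.astype(float).copy()
    prev = np.zeros((n, 3))
    has_prev = np.zeros(n, dtype=bool)
    steps = np.zeros(n, dtype=np.int64)
    terminal = np.full(n, -1, dtype=np.int8)
    active = np.ones(n, dtype=bool)
    defined = field.defined
    K = field.directions.shape[-2]

    for _ in range(params.max_steps):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        vox = np.rint(grid.world_to_index(pos[idx])).astype(np.int64)
        inside = grid.contains_index(vox)
        # leaving the gridded volume
        out = idx[~inside]
        terminal[out] = 5
        active[out] = False
        idx = idx[inside]
        if idx.size == 0:
            continue
        vox = vox[inside]
        vt = tuple(vox.T)

        # classification checks at the entered voxel
        if targets.exclusion is not None:
            hit = targets.exclusion[vt]
            terminal[idx[hit]] = 2
            active[idx[hit]] = False
            keep = ~hit
            idx, vox = idx[keep], vox[keep]
            vt = tuple(vox.T)
            if idx.size == 0:
                continue
        hit_s = targets.striosome[vt]
        hit_m = targets.matrix[vt]
        terminal[idx[hit_s]] = 0
        terminal[idx[hit_m]] = 1
        active[idx[hit_s | hit_m]] = False
        keep = ~(hit_s | hit_m)
        idx, vox = idx[keep], vox[keep]
        vt = tuple(vox.T)
        if idx.size == 0:
            continue

        # no orientation information -> wandered off the field
        ok = defined[vt]
        terminal[idx[~ok]] = 5
        active[idx[~ok]] = False
        idx, vox = idx[ok], vox[ok]
        vt = tuple(vox.T)
        if idx.size == 0:
            continue

        # sample a mixture component per streamline
        w = field.weights[vt]                     # (m, K)
        if K == 1:
            comp = np.zeros(idx.size, dtype=np.int64)
        else:
            cum = np.cumsum(w, axis=1)
            cum /= cum[:, -1:]
            comp = (rng.random(idx.size)[:, None] > cum).sum(axis=1)
        d = field.directions[vt + (comp,)]        # (m, 3)

        # undirected tracts: take the sign minimising the turning angle
        hp = has_prev[idx]
        dots = (d * prev[idx]).sum(axis=1)
        flip = hp & (dots < 0)
        d[flip] = -d[flip]

        if params.angular_dispersion is not None:
            d = _sample_vmf(d, params.angular_dispersion, rng)

        # curvature threshold on the realised turning angle
        dots = (d * prev[idx]).sum(axis=1)
        bad = hp & (dots < params.curvature_min_cos)
        terminal[idx[bad]] = 3
        active[idx[bad]] = False
        good = ~bad
        idx, d = idx[good], d[good]
        if idx.size == 0:
            continue

        pos[idx] += params.step_mm * d
        prev[idx] = d
        has_prev[idx] = True
        steps[idx] += 1

    terminal[terminal == -1] = 4
    return steps, terminal


_TERMINAL_NAMES = ("striosome", "matrix", TERMINAL_EXCLUSION,
                   TERMINAL_CURVATURE, TERMINAL_MAX_STEPS, TERMINAL_LEFT)


def propagate_streamline(
    field: OrientationField,
    start,
    params: TrackingParams,
    targets: TargetSet,
    rng: np.random.Generator,
) -> tuple[float, str]:
    """Propagate one streamline from a world-mm point.

    Returns (path length in mm, terminal class).  The terminal class is the
    name of the first target entered, or one of "exclusion",
    "curvature_stop", "max_steps", "left_volume".
    """
    start = np.asarray(start, dtype=float)
    vox = np.rint(field.grid.world_to_index(start)).astype(int)
    if not bool(field.grid.contains_index(vox)) or not bool(field.defined[tuple(vox)]):
        raise ValueError(f"start point {start.tolist()} outside the seeded volume")
    steps, term = _propagate_batch(field, start[None, :], params, targets, rng)
    return float(steps[0] * params.step_mm), _TERMINAL_NAMES[term[0]]


def classification_targets_track(
    seed_mask: np.ndarray,
    field: OrientationField,
    targets: TargetSet,
    params: TrackingParams,
    rng: np.random.Generator,
) -> ScoreMapPair:
    """Classification-targets tractography over a seed mask.

    Per seed voxel and target, the score is the number of samples whose
    first target entry is that target; with distance correction each sample
    contributes its path length in mm instead of 1.
    """
    if not seed_mask.any():
        raise ValueError("empty seed mask")
    if (seed_mask & (targets.striosome | targets.matrix)).any():
        raise ValueError("targets must be disjoint from the seed mask")
    grid = field.grid
    seeds = np.argwhere(seed_mask)
    n_seeds = seeds.shape[0]
    s_map = np.zeros(grid.dims, dtype=float)
    m_map = np.zeros(grid.dims, dtype=float)

    # batch all samples of a chunk of seed voxels together
    chunk = max(1, int(2e5 // params.n_samples))
    for lo in range(0, n_seeds, chunk):
        sub = seeds[lo:lo + chunk]
        starts = np.repeat(grid.index_to_world(sub), params.n_samples, axis=0)
        owner = np.repeat(np.arange(sub.shape[0]), params.n_samples)
        steps, term = _propagate_batch(field, starts, params, targets, rng)
        weight = steps * params.step_mm if params.distance_correction else \
            np.ones_like(steps, dtype=float)
        for code, out in ((0, s_map), (1, m_map)):
            hit = term == code
            if hit.any():
                acc = np.bincount(owner[hit], weights=weight[hit],
                                  minlength=sub.shape[0])
                out[tuple(sub.T)] += acc
    return ScoreMapPair(grid, s_map, m_map)
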