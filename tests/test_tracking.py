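"""Streamline tracker: propagation contracts, phantoms, conservation."""

import numpy as np
import pytest

from striamap.grid import VoxelGrid
from striamap.tracking import (
    OrientationField, TargetSet, TrackingParams, classification_targets_track,
    propagate_streamline, uniform_field,
)


def _masks(grid):
    return np.zeros(grid.dims, dtype=bool)


@pytest.fixture
def straight_phantom():
    """Uniform +x field, seed voxel in the middle, target slab to the right."""
    grid = VoxelGrid((15, 3, 3))
    field = uniform_field(grid, (1.0, 0.0, 0.0))
    strio = _masks(grid)
    matrix = _masks(grid)
    matrix[12:, :, :] = True
    seed = _masks(grid)
    seed[4, 1, 1] = True
    return grid, field, TargetSet(striosome=strio, matrix=matrix), seed


def test_straight_field_reaches_target_with_boundary_path_length(straight_phantom, rng):
    grid, field, targets, seed = straight_phantom
    start = grid.index_to_world(np.array([4, 1, 1]))
    params = TrackingParams(n_samples=1, step_mm=0.5, max_steps=500)
    length, terminal = propagate_streamline(field, start, params, targets, rng)
    assert terminal == "matrix"
    # distance from the seed centre to the slab's near boundary is
    # (12 - 4) * 2 mm - 1 mm; entry is detected within one step of it
    boundary = (12 - 4) * 2.0 - 1.0
    assert boundary <= length <= boundary + 2 * params.step_mm


def test_start_outside_volume_rejected(straight_phantom, rng):
    grid, field, targets, _ = straight_phantom
    with pytest.raises(ValueError, match="outside"):
        propagate_streamline(field, (1e4, 0, 0),
                             TrackingParams(n_samples=1), targets, rng)


def test_sharp_turn_triggers_curvature_stop(rng):
    """A 90-degree bend (cosine 0 < 0.2) terminates the sample."""
    grid = VoxelGrid((15, 3, 15))
    dirs = np.broadcast_to(np.array([1.0, 0.0, 0.0]),
                           tuple(grid.dims) + (1, 3)).copy()
    dirs[8:, :, :] = np.array([0.0, 0.0, 1.0])   # wall of vertical fibres
    field = OrientationField(grid, dirs, np.ones(tuple(grid.dims) + (1,)))
    matrix = _masks(grid)
    matrix[13:, :, :] = True                      # behind the wall, unreachable
    targets = TargetSet(striosome=_masks(grid), matrix=matrix)
    start = grid.index_to_world(np.array([2, 1, 7]))
    length, terminal = propagate_streamline(
        field, start, TrackingParams(n_samples=1, max_steps=500), targets, rng)
    assert terminal == "curvature_stop"
    assert length > 0


def test_undirected_sign_convention_keeps_straight_paths(rng):
    """Stored orientation signs are irrelevant after the first step."""
    grid = VoxelGrid((15, 3, 3))
    dirs = np.broadcast_to(np.array([1.0, 0.0, 0.0]),
                           tuple(grid.dims) + (1, 3)).copy()
    dirs[8:, :, :] = np.array([-1.0, 0.0, 0.0])   # flipped sign, same axis
    field = OrientationField(grid, dirs, np.ones(tuple(grid.dims) + (1,)))
    matrix = _masks(grid)
    matrix[13:, :, :] = True
    targets = TargetSet(striosome=_masks(grid), matrix=matrix)
    start = grid.index_to_world(np.array([2, 1, 1]))
    _, terminal = propagate_streamline(
        field, start, TrackingParams(n_samples=1, max_steps=500), targets, rng)
    assert terminal == "matrix"


def build_y_phantom():
    """Symmetric Y: the seed voxel mixes two 45-degree branches equally."""
    grid = VoxelGrid((17, 3, 24))
    d_left = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2)
    d_right = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
    dirs = np.zeros(tuple(grid.dims) + (2, 3))
    w = np.zeros(tuple(grid.dims) + (2,))
    dirs[:8, ...] = [d_left, d_left]
    dirs[9:, ...] = [d_right, d_right]
    dirs[8, ...] = [d_left, d_right]
    w[:8, :, :, 0] = 1.0
    w[9:, :, :, 0] = 1.0
    w[8, :, :] = 0.5
    strio = np.zeros(grid.dims, dtype=bool)
    matrix = np.zeros(grid.dims, dtype=bool)
    strio[0, :, :] = True     # left branch outlet
    matrix[16, :, :] = True   # right branch outlet
    seed = np.zeros(grid.dims, dtype=bool)
    seed[8, 1, 5] = True
    field = OrientationField(grid, dirs, w)
    return field, TargetSet(striosome=strio, matrix=matrix), seed


@pytest.fixture
def y_phantom():
    return build_y_phantom()


def test_symmetric_y_phantom_splits_evenly_within_binomial_error(y_phantom):
    field, targets, seed = y_phantom
    n = 5000
    # a 2 mm step leaves the two-fibre junction voxel immediately
    params = TrackingParams(n_samples=n, step_mm=2.0, max_steps=100,
                            distance_correction=False)
    pair = classification_targets_track(seed, field, targets, params,
                                        np.random.default_rng(123))
    s = pair.striosome[seed][0]
    m = pair.matrix[seed][0]
    assert s + m == n                         # every sample reaches a branch
    assert s / n == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / n))


def test_scores_without_distance_correction_are_integer_counts(straight_phantom):
    grid, field, targets, seed = straight_phantom
    params = TrackingParams(n_samples=50, distance_correction=False, max_steps=500)
    pair = classification_targets_track(seed, field, targets, params,
                                        np.random.default_rng(0))
    assert pair.matrix[seed][0] == 50          # all samples reach the slab
    assert pair.striosome[seed][0] == 0
    assert pair.matrix.sum() == np.rint(pair.matrix.sum())


def test_distance_correction_weights_by_path_length(straight_phantom, rng):
    grid, field, targets, seed = straight_phantom
    params_off = TrackingParams(n_samples=20, distance_correction=False,
                                max_steps=500)
    params_on = TrackingParams(n_samples=20, distance_correction=True,
                               max_steps=500)
    off = classification_targets_track(seed, field, targets, params_off,
                                       np.random.default_rng(0))
    on = classification_targets_track(seed, field, targets, params_on,
                                      np.random.default_rng(0))
    start = grid.index_to_world(np.array([4, 1, 1]))
    length, _ = propagate_streamline(field, start,
                                     TrackingParams(n_samples=1, max_steps=500),
                                     targets, rng)
    # deterministic phantom: every sample travels the same path
    assert on.matrix[seed][0] == pytest.approx(off.matrix[seed][0] * length)


def test_empty_seed_mask_rejected(straight_phantom, rng):
    grid, field, targets, _ = straight_phantom
    with pytest.raises(ValueError, match="empty seed"):
        classification_targets_track(np.zeros(grid.dims, bool), field, targets,
                                     TrackingParams(n_samples=1), rng)


def test_unreachable_targets_give_all_zero_maps(rng):
    grid = VoxelGrid((9, 3, 3))
    field = uniform_field(grid, (1.0, 0.0, 0.0))
    strio = _masks(grid)
    strio[0, 0, 0] = True        # behind the seed, never entered
    targets = TargetSet(striosome=strio, matrix=_masks(grid))
    seed = _masks(grid)
    seed[4, 1, 1] = True
    pair = classification_targets_track(
        seed, field, targets, TrackingParams(n_samples=10, max_steps=50), rng)
    assert pair.striosome.sum() == 0 and pair.matrix.sum() == 0


def test_enlarging_a_target_never_decreases_its_score():
    """Paired seeds: a superset target can only intercept more samples."""
    grid = VoxelGrid((15, 5, 5))
    field = uniform_field(grid, (1.0, 0.0, 0.0))
    seed = _masks(grid)
    seed[2, 2, 2] = True
    small = _masks(grid)
    small[12:, 2, 2] = True
    large = small.copy()
    large[11:, :, :] = True
    params = TrackingParams(n_samples=200, distance_correction=False,
                            max_steps=300, angular_dispersion=30.0)
    scores = []
    for target in (small, large):
        pair = classification_targets_track(
            seed, field, TargetSet(striosome=_masks(grid), matrix=target),
            params, np.random.default_rng(5))
        scores.append(pair.matrix[seed][0])
    assert scores[1] >= scores[0]


def test_orientation_field_validates_unit_norm():
    grid = VoxelGrid((3, 3, 3))
    dirs = np.full(tuple(grid.dims) + (1, 3), 0.5)
    with pytest.raises(ValueError, match="unit-norm"):
        OrientationField(grid, dirs, np.ones(tuple(grid.dims) + (1,)))


def test_target_and_exclusion_disjointness_enforced():
    grid = VoxelGrid((4, 4, 4))
    a = np.zeros(grid.dims, bool)
    a[0] = True
    with pytest.raises(ValueError, match="disjoint"):
        TargetSet(striosome=a, matrix=a)
    b = np.zeros(grid.dims, bool)
    b[1] = True
    with pytest.raises(ValueError, match="exclusion"):
        TargetSet(striosome=a, matrix=b, exclusion=a)


def test_midline_exclusion_blocks_contralateral_connections(rng):
    grid = VoxelGrid((16, 3, 3))
    field = uniform_field(grid, (1.0, 0.0, 0.0))
    matrix = _masks(grid)
    matrix[14:, :, :] = True
    exclusion = _masks(grid)
    exclusion[8, :, :] = True    # midline wall between seed and target
    targets = TargetSet(striosome=_masks(grid), matrix=matrix,
                        exclusion=exclusion)
    start = grid.index_to_world(np.array([2, 1, 1]))
    _, terminal = propagate_streamline(
        field, start, TrackingParams(n_samples=1, max_steps=200), targets, rng)
    assert terminal == "exclusion"
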