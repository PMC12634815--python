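"""Mix-norm: subdomain binning, exchange ratios, per-scale and
aggregate norms, and equivalence with the brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aqflow.mixing import (
    SCALES,
    EvaluationGrid,
    MixingError,
    brute_force_oracle,
    build_grid,
    compute_mixing,
    exchange_ratio,
    mix_norm,
    scale_norm,
)
from aqflow.tracking import ACTIVE, EXITED, ParticleSet


def _pset(origins, finals, status=None):
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    finals = np.atleast_2d(np.asarray(finals, dtype=float))
    n = origins.shape[0]
    return ParticleSet(
        positions=finals.copy(), origins=origins.copy(),
        status=np.zeros(n, np.int8) if status is None else np.asarray(status, np.int8),
        tet=np.zeros(n, np.int64), spacing=0.1,
    )


UNIT = EvaluationGrid(lo=[0, 0, 0], hi=[1, 1, 1])


def test_grid_subdomain_counts_and_tiling():
    rng_pts = np.random.default_rng(0).uniform(0, 1, (5000, 3))
    for i in (2, 10):
        idx = UNIT.subdomain_index(rng_pts, i)
        assert idx.min() >= 0 and idx.max() < i**3
        # the i^3 cell centers enumerate every subdomain exactly once
        ax = (np.arange(i) + 0.5) / i
        centers = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
        cidx = UNIT.subdomain_index(centers, i)
        assert np.unique(cidx).size == i**3


def test_interior_face_point_single_assignment():
    """Half-open convention: a point on an interior face belongs to the
    upper cell; the top face is closed."""
    idx = UNIT.subdomain_index(np.array([[0.5, 0.25, 0.25]]), 2)
    assert idx[0] == (1 * 2 + 0) * 2 + 0
    top = UNIT.subdomain_index(np.array([[1.0, 1.0, 1.0]]), 2)
    assert top[0] == (1 * 2 + 1) * 2 + 1


def test_degenerate_box_raises():
    with pytest.raises(MixingError):
        EvaluationGrid(lo=[0, 0, 0], hi=[1, 0, 1])


def test_exchange_ratio_no_motion_zero():
    pts = np.random.default_rng(1).uniform(0, 1, (200, 3))
    ps = _pset(pts, pts)
    res = compute_mixing(ps, UNIT)
    assert res.mix_norm == 0.0
    for i in SCALES:
        assert np.all(res.exchange_ratios[i] == 0.0)


def test_exchange_ratio_hand_example():
    """Five occupants of one subdomain: 3 originated inside, 2 outside."""
    sub = [0.1, 0.1, 0.1]
    inside = np.tile(sub, (3, 1)) + 0.05 * np.arange(3)[:, None] * [1, 0, 0]
    outside = np.array([[0.9, 0.9, 0.9], [0.6, 0.1, 0.1]])
    origins = np.vstack([inside, outside])
    finals = np.tile([0.1, 0.2, 0.1], (5, 1)) + 0.02 * np.arange(5)[:, None] * [0, 1, 0]
    ps = _pset(origins, finals)
    j = int(UNIT.subdomain_index(finals[:1], 2)[0])
    assert exchange_ratio(ps, UNIT, 2, j) == pytest.approx(0.4, rel=1e-12)


def test_exchange_ratio_all_from_outside():
    origins = np.tile([0.9, 0.9, 0.9], (4, 1))
    finals = np.tile([0.1, 0.1, 0.1], (4, 1))
    ps = _pset(origins, finals)
    j = int(UNIT.subdomain_index(finals[:1], 2)[0])
    assert exchange_ratio(ps, UNIT, 2, j) == 1.0


def test_scale_norm_values():
    assert scale_norm(np.zeros(8), 2) == 0.0
    assert scale_norm(np.full(8, 0.5), 2) == pytest.approx(0.5, rel=1e-12)
    c = np.zeros(8)
    c[0] = 1.0
    assert scale_norm(c, 2) == pytest.approx(np.sqrt(1 / 8), rel=1e-12)
    with pytest.raises(MixingError):
        scale_norm(np.zeros(7), 2)


def test_scale_norm_printed_formula_variant():
    c = np.full(8, 0.5)
    assert scale_norm(c, 2, normalization="unnormalized") == pytest.approx(
        np.sqrt(8 * 0.25), rel=1e-12
    )


def test_mix_norm_values():
    zeros = {i: 0.0 for i in SCALES}
    ones = {i: 1.0 for i in SCALES}
    third = {i: 0.3 for i in SCALES}
    assert mix_norm(zeros) == 0.0
    assert mix_norm(ones) == pytest.approx(1.0, rel=1e-12)
    assert mix_norm(third) == pytest.approx(0.3, rel=1e-12)
    with pytest.raises(MixingError):
        mix_norm({2: 0.1, 4: 0.1})


def test_build_grid_is_tight_aqueduct_bbox(medium_mesh):
    grid = build_grid(medium_mesh)
    z0, z1 = medium_mesh.meta["aqueduct_z"]
    assert grid.lo[2] == pytest.approx(z0, abs=1e-6)
    assert grid.hi[2] == pytest.approx(z1, abs=1e-6)
    r = 1.41
    assert grid.hi[0] - grid.lo[0] == pytest.approx(2 * r, rel=0.05)


def test_oracle_equivalence_random_configs():
    rng = np.random.default_rng(42)
    for _ in range(10):
        n = 100
        origins = rng.uniform(-0.3, 1.3, (n, 3))
        finals = origins.copy()
        perm = rng.permutation(n)[: n // 2]
        finals[perm] = rng.uniform(-0.3, 1.3, (len(perm), 3))
        status = np.zeros(n, np.int8)
        status[rng.random(n) < 0.1] = EXITED
        ps = _pset(origins, finals, status)
        fast = compute_mixing(ps, UNIT)
        slow = brute_force_oracle(ps, UNIT)
        for i in SCALES:
            np.testing.assert_array_equal(fast.counts_in[i], slow.counts_in[i])
            np.testing.assert_array_equal(fast.counts_out[i], slow.counts_out[i])
        assert abs(fast.mix_norm - slow.mix_norm) <= 1e-12


def test_all_exited_gives_zero_both_paths():
    origins = np.random.default_rng(3).uniform(0, 1, (50, 3))
    ps = _pset(origins, origins, status=np.full(50, EXITED))
    assert compute_mixing(ps, UNIT).mix_norm == 0.0
    assert brute_force_oracle(ps, UNIT).mix_norm == 0.0


def test_uniform_reshuffle_asymptotic_limit():
    """Random relocation over a much larger domain drives m -> 1."""
    rng = np.random.default_rng(7)
    n = 100_000
    origins = rng.uniform(-1, 2, (n, 3))
    finals = rng.uniform(-1, 2, (n, 3))
    ps = _pset(origins, finals)
    res = compute_mixing(ps, UNIT)
    assert res.mix_norm == pytest.approx(1.0, abs=0.05)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=15, deadline=None)
def test_mix_norm_range_property(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(1, 300)
    ps = _pset(rng.uniform(-1, 2, (n, 3)), rng.uniform(-1, 2, (n, 3)))
    res = compute_mixing(ps, UNIT)
    assert 0.0 <= res.mix_norm <= 1.0
    for i in SCALES:
        assert 0.0 <= res.scale_norms[i] <= 1.0
        assert np.all((res.exchange_ratios[i] >= 0) & (res.exchange_ratios[i] <= 1))


def test_initial_membership_variant():
    pts = np.random.default_rng(1).uniform(0, 1, (100, 3))
    ps = _pset(pts, pts)
    assert compute_mixing(ps, UNIT, membership="initial").mix_norm == 0.0
    gone = _pset(pts, pts + 10.0)
    res = compute_mixing(gone, UNIT, membership="initial")
    for i in SCALES:
        occupied = (res.counts_in[i] + res.counts_out[i]) > 0
        assert np.all(res.exchange_ratios[i][occupied] == 1.0)
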