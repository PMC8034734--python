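import numpy as np
import pytest

import phasebasket as pb
from phasebasket.errors import UsageError
from phasebasket.io_formats import BASKET_CHANNELS, BasketLayout
from phasebasket.recompose import wrap_phase
from phasebasket.singularity import PhaseSingularity

LAYOUT = BasketLayout.from_labels(list(BASKET_CHANNELS))


def unwrap_oracle(loop):
    """Independent oracle: unwrap the closed loop and read off the net
    phase advance; checked over every cyclic rotation."""
    results = set()
    loop = list(loop)
    for r in range(len(loop)):
        rotated = loop[r:] + loop[:r]
        closed = np.unwrap(np.array(rotated + rotated[:1]))
        results.add(int(round((closed[-1] - closed[0]) / (2 * np.pi))))
    assert len(results) == 1, "oracle inconsistent across rotations"
    return results.pop()


def brute_force_detect_2d(phases):
    """Exhaustive per-cell detector with independent wrapping arithmetic
    (complex-exponential angles), counterclockwise in (electrode, spline)
    axes like the implementation's convention."""
    def wrap(d):
        return np.angle(np.exp(1j * d))

    found = []
    for ix in range(28):
        for iy in range(28):
            loop = [
                phases[ix, iy], phases[ix, iy + 1],
                phases[ix + 1, iy + 1], phases[ix + 1, iy],
            ]
            total = sum(wrap(loop[(k + 1) % 4] - loop[k]) for k in range(4))
            q = int(round(total / (2 * np.pi)))
            if q:
                found.append((ix, iy, q))
    return found


class TestWindingNumber:
    def test_constant_loop(self):
        assert pb.winding_number([0.3, 0.3, 0.3, 0.3]) == 0

    def test_three_phase_loop_and_reverse(self):
        loop = [0.0, 2 * np.pi / 3, 4 * np.pi / 3]
        assert pb.winding_number(loop) == 1
        assert pb.winding_number(loop[::-1]) == -1

    def test_too_short_rejected(self):
        with pytest.raises(UsageError):
            pb.winding_number([0.0, 1.0])

    @pytest.mark.parametrize("length", [3, 4, 5])
    def test_all_loops_match_unwrap_oracle(self, length):
        alphabet = np.array([-2.8, -1.2, 0.0, 1.3, 2.9])
        grids = np.stack(
            np.meshgrid(*[alphabet] * length, indexing="ij"), axis=-1
        ).reshape(-1, length)
        for loop in grids:
            assert pb.winding_number(loop) == unwrap_oracle(loop)

    def test_random_long_loops(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            loop = rng.uniform(-np.pi, np.pi, rng.integers(3, 9))
            assert pb.winding_number(loop) == unwrap_oracle(loop)


def vortex_phases_2d(x0, y0, charge=1):
    """Analytic vortex on the 29x29 lattice with winding *charge* in the
    detection orientation (counterclockwise in (electrode, spline) axes)."""
    ix, iy = np.meshgrid(np.arange(29) / 4.0, np.arange(29) / 4.0,
                         indexing="ij")
    return wrap_phase(charge * np.arctan2(ix - x0, iy - y0))


class TestDetectPs2D:
    def test_uniform_frame_empty(self):
        frame = pb.PhaseFrame2D(np.full((29, 29), 1.1), 0.0)
        assert pb.detect_ps_2d(frame) == []

    def test_analytic_vortex_found(self):
        frame = pb.PhaseFrame2D(vortex_phases_2d(3.3, 4.1), 0.0)
        tips = pb.detect_ps_2d(frame)
        assert len(tips) == 1
        assert tips[0].charge == 1
        assert np.hypot(tips[0].x - 3.3, tips[0].y - 4.1) < 1.0

    def test_vortex_pair_net_zero(self):
        p = vortex_phases_2d(1.5, 3.5, 1) + vortex_phases_2d(5.5, 3.5, -1)
        tips = pb.detect_ps_2d(pb.PhaseFrame2D(wrap_phase(p), 0.0))
        assert len(tips) == 2
        assert sum(t.charge for t in tips) == 0

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            phases = rng.uniform(-np.pi, np.pi, (29, 29))
            tips = pb.detect_ps_2d(pb.PhaseFrame2D(phases, 0.0))
            got = {(int(t.x * 4 - 0.5), int(t.y * 4 - 0.5), t.charge)
                   for t in tips}
            assert got == set(brute_force_detect_2d(phases))

    def test_offset_invariance(self):
        rng = np.random.default_rng(10)
        phases = rng.uniform(-np.pi, np.pi, (29, 29))
        a = pb.detect_ps_2d(pb.PhaseFrame2D(phases, 0.0))
        b = pb.detect_ps_2d(
            pb.PhaseFrame2D(wrap_phase(phases + 1.234), 0.0)
        )
        assert [(t.x, t.y, t.charge) for t in a] == [
            (t.x, t.y, t.charge) for t in b
        ]


class TestDetectPs3D:
    def test_constant_phase_empty(self, basket):
        frame = pb.PhaseFrame3D(np.full(3970, 0.7), 0.0)
        assert pb.detect_ps_3d(basket, frame) == []

    def test_vortex_line_gives_two_opposite_tips(self, basket):
        """A phase field winding about the z axis pierces the closed
        surface at the two poles: exactly two tips, opposite charges."""
        v = basket.refined.vertices
        phases = wrap_phase(np.arctan2(v[:, 1], v[:, 0]))
        tips = pb.detect_ps_3d(basket, pb.PhaseFrame3D(phases, 0.0))
        assert len(tips) == 2
        assert sum(t.charge for t in tips) == 0
        assert {t.region[0] for t in tips} == {"pole"}

    def test_charge_conservation_random_frames(self, basket):
        rng = np.random.default_rng(11)
        for _ in range(30):
            phases = rng.uniform(-np.pi, np.pi, 3970)
            tips = pb.detect_ps_3d(basket, pb.PhaseFrame3D(phases, 0.0))
            assert sum(t.charge for t in tips) == 0

    def test_offset_invariance(self, basket):
        rng = np.random.default_rng(12)
        phases = rng.uniform(-np.pi, np.pi, 3970)
        a = pb.detect_ps_3d(basket, pb.PhaseFrame3D(phases, 0.0))
        b = pb.detect_ps_3d(
            basket, pb.PhaseFrame3D(wrap_phase(phases - 2.1), 0.0)
        )
        assert [(t.face, t.charge) for t in a] == [(t.face, t.charge) for t in b]


class TestBuildFrames:
    def test_identical_channels_constant_phase(self):
        t = np.arange(1000) / 1000.0
        rec = np.tile(np.cos(2 * np.pi * 5 * t), (64, 1))
        frames = pb.build_frames_2d(rec, LAYOUT, 1000.0, stride=100)
        for fr in frames:
            assert np.ptp(fr.phases) < 1e-9

    def test_stride_equal_to_length_one_frame(self):
        rec = np.random.default_rng(13).normal(size=(64, 500))
        frames = pb.build_frames_2d(rec, LAYOUT, 1000.0, stride=500)
        assert len(frames) == 1

    def test_planar_wave_phase_linear_on_lattice(self):
        """Small phase increments per electrode: bilinear interpolation
        of the analytic signal reproduces the linear phase ramp."""
        k = 0.02  # rad per electrode spacing, small enough for linearity
        t = np.arange(1000) / 1000.0
        xy = np.array([[sj, ei] for sj in range(8) for ei in range(8)])
        rec = np.stack(
            [np.cos(2 * np.pi * 5 * t - k * x) for x, _ in xy]
        )
        frames = pb.build_frames_2d(rec, LAYOUT, 1000.0, stride=500)
        ph = frames[0].phases
        ramp = ph - ph[0:1, :]  # remove time-common offset
        expected = -k * (np.arange(29) / 4.0)[:, None] * np.ones((1, 29))
        np.testing.assert_allclose(ramp, expected, atol=1e-6)

    def test_frames_2d_and_3d_consistent_at_electrodes(self, basket):
        rng = np.random.default_rng(14)
        t = np.arange(1000) / 1000.0
        rec = np.stack([
            np.cos(2 * np.pi * 5 * t + rng.uniform(-3, 3)) for _ in range(64)
        ])
        f2 = pb.build_frames_2d(rec, LAYOUT, 1000.0, stride=500)[0]
        f3 = pb.build_frames_3d(rec, LAYOUT, basket, 1000.0, stride=500)[0]
        # electrode (spline j, electrode i) = lattice node (4j, 4i) and
        # refined vertex j*8+i (original vertices come first)
        for j in range(8):
            for i in range(8):
                assert f2.phases[4 * j, 4 * i] == pytest.approx(
                    f3.phases[j * 8 + i], abs=1e-9
                )


def make_tip(frame, x, y, charge=1):
    i, j = min(int(y), 6) + 1, min(int(x), 6) + 1
    return PhaseSingularity(
        frame=frame, time_ms=frame * 10.0, charge=charge, x=x, y=y,
        region=("sub", i, j),
    )


class TestTracking:
    def test_stationary_tip_single_track(self):
        frames = [[make_tip(f, 3.4, 3.6)] for f in range(400)]
        tracks = pb.track_singularities(frames, 10.0, 180.0)
        assert len(tracks) == 1
        assert tracks[0].duration_ms >= 3 * 180.0

    def test_short_lived_tip_dropped(self):
        frames = [[make_tip(f, 3.4, 3.6)] for f in range(36)]  # 2 cycles
        frames += [[] for _ in range(364)]
        assert pb.track_singularities(frames, 10.0, 180.0) == []

    def test_two_distant_tips_never_merged(self):
        frames = [
            [make_tip(f, 1.2, 3.5), make_tip(f, 6.2, 3.5)] for f in range(400)
        ]
        tracks = pb.track_singularities(frames, 10.0, 180.0)
        assert len(tracks) == 2
        spreads = [np.ptp([t.x for t in tr.tips]) for tr in tracks]
        assert max(spreads) < 0.5

    def test_single_frame_gap_bridged(self):
        frames = [[make_tip(f, 3.5, 3.5)] if f != 200 else []
                  for f in range(400)]
        tracks = pb.track_singularities(frames, 10.0, 180.0)
        assert len(tracks) == 1

    def test_opposite_charges_not_linked(self):
        frames = [[make_tip(f, 3.5, 3.5, charge=1 if f % 2 else -1)]
                  for f in range(400)]
        tracks = pb.track_singularities(frames, 10.0, 180.0)
        assert all(
            len({t.charge for t in tr.tips}) == 1 for tr in tracks
        )


class TestTipDensity:
    def test_fixed_tip_full_occupancy(self):
        frames = [[make_tip(f, 3.2, 2.1)] for f in range(100)]
        d = pb.tip_density(frames, 100)
        assert d.matrix[2, 3] == 1.0  # region (i=3, j=4), 0-based (2, 3)
        assert d.matrix.sum() == 1.0

    def test_half_occupancy(self):
        frames = [[make_tip(f, 3.2, 2.1)] if f < 50 else []
                  for f in range(100)]
        d = pb.tip_density(frames, 100)
        assert d.matrix[2, 3] == 0.5

    def test_dimensions_always_7x7(self):
        rng = np.random.default_rng(15)
        frames = [
            [make_tip(f, rng.uniform(0, 7), rng.uniform(0, 7))
             for _ in range(rng.integers(0, 4))]
            for f in range(50)
        ]
        assert pb.tip_density(frames, 50).matrix.shape == (7, 7)

    def test_off_matrix_tally(self):
        tip = PhaseSingularity(frame=0, time_ms=0.0, charge=1, x=7.5,
                               y=3.5, region=("wrap", 4, 8))
        d = pb.tip_density([[tip]], 1)
        assert d.matrix.sum() == 0.0
        assert d.off_matrix == {"wrap_4": 1}

    def test_zero_frames_rejected(self):
        with pytest.raises(UsageError):
            pb.tip_density([], 0)
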