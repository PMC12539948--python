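"""Ring-plane geometry, angle histograms, autocorrelation times, bootstrap."""

import numpy as np
import pytest

from duplexdyn.stacking import (
    AngleSeries,
    DegenerateRingError,
    RingSpec,
    StackingError,
    angle_histogram,
    angle_series_from_frames,
    block_bootstrap_histogram,
    integrated_act,
    stacking_angle,
)
from duplexdyn.synthetic import AngleProcessSpec, gen_angle_series, gen_ring_frames


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestGeometry:
    def test_rigid_motion_invariance(self):
        frames = gen_ring_frames([23.0], noise_sd=0.0)
        coords = frames.coords[0]
        base = stacking_angle(coords)
        rng = np.random.default_rng(12)
        for _ in range(5):
            moved = coords @ random_rotation(rng).T + rng.normal(size=3)
            assert stacking_angle(moved) == pytest.approx(base, abs=1e-9)

    def test_ring_exchange_and_atom_order_invariance(self):
        coords = gen_ring_frames([37.0], noise_sd=0.0).coords[0]
        a = RingSpec(tuple(range(6)))
        b = RingSpec(tuple(range(6, 12)))
        assert stacking_angle(coords, None, a, b) == pytest.approx(
            stacking_angle(coords, None, b, a), abs=1e-9
        )
        # reversing the atom order flips the normal; |dot| convention absorbs it
        b_rev = RingSpec(tuple(range(11, 5, -1)))
        assert stacking_angle(coords, None, a, b_rev) == pytest.approx(
            stacking_angle(coords, None, a, b), abs=1e-9
        )

    def test_perpendicular_and_parallel_limits(self):
        coords = gen_ring_frames([0.0, 90.0], noise_sd=0.0).coords
        assert stacking_angle(coords[0]) == pytest.approx(0.0, abs=1e-9)
        assert stacking_angle(coords[1]) == pytest.approx(90.0, abs=1e-9)

    def test_collinear_spanning_vectors_rejected(self):
        coords = np.zeros((6, 3))
        coords[:, 0] = np.arange(6)  # all atoms on a line
        with pytest.raises(DegenerateRingError):
            stacking_angle(coords, coords, RingSpec((0, 1, 2)), RingSpec((3, 4, 5)))

    def test_series_from_frames_and_empty_input(self):
        frames = gen_ring_frames([10.0, 50.0, 90.0], noise_sd=0.0, dt=2.0)
        series = angle_series_from_frames(
            frames, RingSpec(tuple(range(6))), RingSpec(tuple(range(6, 12)))
        )
        np.testing.assert_allclose(series.angles, [10.0, 50.0, 90.0], atol=1e-6)
        assert series.dt == 2.0
        empty = gen_ring_frames([], noise_sd=0.0)
        out = angle_series_from_frames(
            empty, RingSpec(tuple(range(6))), RingSpec(tuple(range(6, 12)))
        )
        assert out.n == 0


class TestHistogram:
    def test_single_bin_density(self):
        series = AngleSeries(dt=1.0, angles=np.full(500, 10.5))
        hist = angle_histogram(series)
        assert hist.density[10] == pytest.approx(1.0)
        assert hist.density.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_series_is_flat(self):
        rng = np.random.default_rng(0)
        n = 90_000
        series = AngleSeries(dt=1.0, angles=rng.uniform(0, 90, n))
        hist = angle_histogram(series)
        rel_tol = 3.0 / np.sqrt(n / 90)
        np.testing.assert_allclose(hist.density, 1.0 / 90.0, rtol=rel_tol)
        assert np.sum(hist.density * np.diff(hist.bin_edges)) == pytest.approx(1.0)

    def test_empty_series_rejected(self):
        with pytest.raises(StackingError):
            angle_histogram(AngleSeries(dt=1.0, angles=np.empty(0)))


class TestIntegratedACT:
    def test_white_noise_limit(self):
        series = gen_angle_series(AngleProcessSpec(mean=45, sd=5, phi=0.0, n=100_000, seed=1))
        act = integrated_act(series)
        assert act.tau_int == pytest.approx(series.dt, rel=0.10)

    def test_slow_mixing_regime(self):
        # phi = 0.98 -> analytic tau_int = (1+phi)/(1-phi) dt = 99 dt
        series = gen_angle_series(
            AngleProcessSpec(mean=45, sd=5, phi=0.98, n=1_000_000, seed=2)
        )
        act = integrated_act(series)
        assert act.tau_int == pytest.approx(99.0, rel=0.20)
        assert act.block_length == int(np.ceil(5 * act.tau_int))

    def test_constant_series_rejected(self):
        with pytest.raises(StackingError):
            integrated_act(AngleSeries(dt=1.0, angles=np.full(1000, 30.0)))

    def test_short_series_rejected(self):
        with pytest.raises(StackingError):
            integrated_act(AngleSeries(dt=1.0, angles=np.arange(50.0) % 90))


class TestBlockBootstrap:
    def test_constant_series_has_zero_width_interval(self):
        series = AngleSeries(dt=1.0, angles=np.full(400, 12.3))
        hist = block_bootstrap_histogram(series, n_replicas=50, seed=0, block_length=10)
        assert hist.ci_low[12] == hist.ci_high[12] == hist.density[12] == 1.0
        assert np.all(hist.ci_high[np.arange(90) != 12] == 0.0)

    def test_seeded_bootstrap_is_reproducible(self):
        series = gen_angle_series(AngleProcessSpec(phi=0.8, n=5000, seed=4))
        h1 = block_bootstrap_histogram(series, n_replicas=100, seed=11)
        h2 = block_bootstrap_histogram(series, n_replicas=100, seed=11)
        np.testing.assert_array_equal(h1.ci_low, h2.ci_low)
        np.testing.assert_array_equal(h1.ci_high, h2.ci_high)

    def test_unit_block_reduces_to_ordinary_bootstrap(self):
        # with L = 1 the moving-block scheme is an iid resample; its bands
        # must match a multinomial percentile bootstrap within MC error
        rng = np.random.default_rng(5)
        n = 4000
        series = AngleSeries(dt=1.0, angles=rng.uniform(0, 30, n))
        hist = block_bootstrap_histogram(series, n_replicas=2000, seed=6, block_length=1)
        counts, _ = np.histogram(series.angles, bins=np.arange(91.0))
        reps = rng.multinomial(n, counts / n, size=2000) / n
        lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
        occupied = counts > 0
        width_block = (hist.ci_high - hist.ci_low)[occupied].mean()
        width_multi = (hi - lo)[occupied].mean()
        assert width_block == pytest.approx(width_multi, rel=0.15)
        assert np.abs((hist.ci_low - lo)[occupied]).mean() < 0.2 * width_multi

    def test_interval_width_shrinks_with_series_length(self):
        widths = []
        for n in (1000, 10_000, 100_000):
            per_seed = []
            for seed in range(5):
                series = gen_angle_series(
                    AngleProcessSpec(mean=10, sd=4, phi=0.8, n=n, seed=seed)
                )
                h = block_bootstrap_histogram(series, n_replicas=200, seed=seed)
                occ = h.density > 0
                per_seed.append((h.ci_high - h.ci_low)[occ].mean())
            widths.append(np.mean(per_seed))
        assert widths[0] > widths[1] > widths[2]

    def test_every_replica_density_normalized(self):
        series = gen_angle_series(AngleProcessSpec(phi=0.5, n=3000, seed=9))
        hist = block_bootstrap_histogram(series, n_replicas=200, seed=3)
        assert hist.density.sum() == pytest.approx(1.0, abs=1e-12)
        # bands bracket the point estimate on well-populated bins
        occ = hist.density > 5.0 / series.n
        assert np.all(hist.ci_low[occ] <= hist.density[occ] + 1e-12)
        assert np.all(hist.ci_high[occ] >= hist.density[occ] - 1e-12)

    def test_series_shorter_than_two_blocks_rejected(self):
        series = AngleSeries(dt=1.0, angles=np.linspace(0, 89, 30))
        with pytest.raises(StackingError):
            block_bootstrap_histogram(series, n_replicas=10, seed=0, block_length=20)
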