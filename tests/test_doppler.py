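import numpy as np
import pytest

from fusact import (
    AcquisitionParams,
    AngleFrameSequence,
    CompoundedSequence,
    SVDClutterFilter,
    build_casorati,
    casorati_to_stack,
    compound_angles,
    doppler_movie,
    power_doppler,
    stack_planes,
    svd_clutter_filter,
    temporal_average,
    to_db,
)


def _angle_seq(frames, acq=None):
    return AngleFrameSequence(frames=frames, acq=acq or AcquisitionParams())


class TestCompoundAngles:
    def test_mean_of_identical_frames(self, acq):
        rng = np.random.default_rng(0)
        frame = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
        frames = np.broadcast_to(frame, (3, 7, 4, 4)).copy()
        out = compound_angles(_angle_seq(frames))
        assert np.allclose(out, frame)

    def test_opposite_angles_cancel(self):
        acq = AcquisitionParams(angles_deg=(-2.0, 2.0))
        frames = np.stack([np.ones((1, 4, 4)), -np.ones((1, 4, 4))], axis=1).astype(complex)
        assert np.allclose(compound_angles(_angle_seq(frames, acq)), 0)

    def test_noise_variance_reduced_by_angle_count(self, acq):
        rng = np.random.default_rng(1)
        n = 120 * 120
        frames = (
            rng.standard_normal((1, 7, 120, 120)) + 1j * rng.standard_normal((1, 7, 120, 120))
        ) / np.sqrt(2)
        out = compound_angles(_angle_seq(frames))
        var = np.var(out.real) + np.var(out.imag)
        assert var == pytest.approx(1 / 7, rel=0.05)

    def test_angle_count_mismatch_rejected(self, acq):
        with pytest.raises(ValueError, match="angle"):
            _angle_seq(np.zeros((2, 5, 4, 4), dtype=complex))


class TestTemporalAverage:
    def test_triple_averaging_halves_rate_arithmetic(self):
        # 1500 Hz pre-averaging input, factor 3 -> 500 Hz
        frames = np.arange(1500, dtype=float)[:, None, None] * np.ones((1, 2, 2))
        out = temporal_average(frames, 3)
        assert out.shape[0] == 500

    def test_factor_one_identity(self):
        x = np.random.default_rng(0).standard_normal((5, 2, 2))
        assert temporal_average(x, 1) is x

    def test_mean_of_consecutive_frames(self):
        frames = np.array([1.0, 2.0, 3.0])[:, None, None] * np.ones((1, 2, 2))
        out = temporal_average(frames, 3)
        assert out.shape[0] == 1
        assert np.allclose(out, 2.0)

    def test_trailing_remainder_truncated(self):
        frames = np.ones((7, 2, 2))
        assert temporal_average(frames, 3).shape[0] == 2

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            temporal_average(np.ones((4, 2, 2)), 0)


class TestCasorati:
    def test_shape(self):
        assert build_casorati(np.zeros((3, 2, 2), dtype=complex)).shape == (4, 3)

    def test_round_trip_bit_identical(self):
        rng = np.random.default_rng(2)
        block = rng.standard_normal((5, 3, 4)) + 1j * rng.standard_normal((5, 3, 4))
        assert np.array_equal(casorati_to_stack(build_casorati(block), (3, 4)), block)

    def test_constant_stack_rank_one(self):
        block = np.broadcast_to(np.arange(6).reshape(2, 3) + 0j, (4, 2, 3))
        s = np.linalg.svd(build_casorati(block), compute_uv=False)
        assert s[1] / s[0] < 1e-12


class TestSVDClutterFilter:
    def test_removed_count_floor_rule(self):
        # 13% of a 250-frame block -> floor(32.5) = 32 components
        X = np.random.default_rng(0).standard_normal((40, 250))
        f = SVDClutterFilter(0.13).fit(X)
        assert f.n_removed_ == 32

    def test_static_tissue_fully_removed(self):
        col = np.random.default_rng(1).standard_normal(30) + 0j
        X = np.tile(col[:, None], (1, 10))
        filtered, rep = svd_clutter_filter(X, 0.13)
        assert np.linalg.norm(filtered) <= 1e-8 * np.linalg.norm(X)
        assert rep["n_removed"] == 1

    def test_zero_fraction_is_identity(self):
        X = np.random.default_rng(2).standard_normal((8, 5))
        filtered, _ = svd_clutter_filter(X, 0.0)
        assert np.array_equal(filtered, X)

    def test_energy_conservation(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 20)) + 1j * rng.standard_normal((50, 20))
        _, rep = svd_clutter_filter(X, 0.13)
        energy = np.sum(rep["singular_values"] ** 2)
        assert abs(energy - np.linalg.norm(X) ** 2) < 1e-10 * np.linalg.norm(X) ** 2

    def test_matches_brute_force_projection_oracle(self):
        # independent oracle: explicit outer-product subtraction of the
        # top-k singular components from a dense SVD
        rng = np.random.default_rng(4)
        for _ in range(100):
            X = rng.standard_normal((50, 20)) + 1j * rng.standard_normal((50, 20))
            frac = rng.uniform(0.0, 0.9)
            filtered, rep = svd_clutter_filter(X, frac)
            U, s, Vh = np.linalg.svd(X, full_matrices=False)
            expected = X.copy()
            for i in range(rep["n_removed"]):
                expected -= s[i] * np.outer(U[:, i], Vh[i])
            assert np.linalg.norm(filtered - expected) < 1e-8 * max(np.linalg.norm(X), 1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            SVDClutterFilter(1.0).fit(np.ones((4, 3)))
        with pytest.raises(ValueError):
            SVDClutterFilter(0.1).fit(np.array([[np.nan, 1.0], [0.0, 1.0]]))


class TestPowerDoppler:
    def test_zero_block(self):
        assert not power_doppler(np.zeros((3, 2, 2), dtype=complex)).any()

    def test_unit_magnitude(self):
        block = np.exp(1j * np.linspace(0, 3, 12)).reshape(12, 1, 1)
        assert power_doppler(block)[0, 0] == pytest.approx(1.0)

    def test_rotating_phase_amplitude_squared(self):
        a = 3.0
        block = a * np.exp(1j * np.linspace(0, 7, 25)).reshape(25, 1, 1)
        assert power_doppler(block)[0, 0] == pytest.approx(a**2)

    def test_db_view(self):
        img = np.array([[1.0, 0.1], [0.01, 0.0]])
        db = to_db(img)
        assert db[0, 0] == 0.0
        assert db[0, 1] == pytest.approx(-10.0)
        assert db[1, 1] == -80.0


class TestDopplerMovie:
    def test_250_frame_blocks_at_500hz_give_2hz(self, acq):
        rng = np.random.default_rng(5)
        frames = (rng.standard_normal((500, 4, 4)) + 1j * rng.standard_normal((500, 4, 4)))
        pds = doppler_movie(CompoundedSequence(frames=frames, acq=acq))
        assert pds.block_rate == pytest.approx(2.0)
        assert pds.n_blocks == 2
        assert np.all(np.diff(pds.block_timestamps) > 0)

    def test_95s_input_gives_190_blocks(self, acq):
        rng = np.random.default_rng(6)
        frames = (rng.standard_normal((47500, 2, 2)) + 1j * rng.standard_normal((47500, 2, 2)))
        pds = doppler_movie(CompoundedSequence(frames=frames, acq=acq))
        assert pds.n_blocks == 190

    def test_short_input_rejected(self, acq):
        frames = np.zeros((100, 2, 2), dtype=complex)
        with pytest.raises(ValueError, match="insufficient"):
            doppler_movie(CompoundedSequence(frames=frames, acq=acq))

    def test_provenance_recorded(self, acq):
        rng = np.random.default_rng(7)
        frames = rng.standard_normal((250, 2, 2)) + 0j
        pds = doppler_movie(CompoundedSequence(frames=frames, acq=acq), svd_fraction=0.13)
        assert pds.provenance["svd_fraction"] == 0.13
        assert pds.provenance["n_removed"] == 32


class TestStackPlanes:
    def _series(self, acq, seed=0):
        rng = np.random.default_rng(seed)
        frames = rng.standard_normal((250, 4, 4)) + 0j
        return doppler_movie(CompoundedSequence(frames=frames, acq=acq))

    def test_single_plane(self, acq):
        vol = stack_planes([self._series(acq)], [0.0])
        assert vol.volumes.shape[0] == 1

    def test_unsorted_positions_sorted_with_index_map(self, acq):
        series = [self._series(acq, s) for s in range(3)]
        vol = stack_planes(series, [2e-3, 0.0, 1e-3])
        assert list(vol.positions) == [0.0, 1e-3, 2e-3]
        assert list(vol.order_map) == [1, 2, 0]
        assert np.array_equal(vol.volumes[0], series[1].images)

    def test_mismatch_rejected(self, acq):
        a = self._series(acq)
        rng = np.random.default_rng(9)
        small = doppler_movie(
            CompoundedSequence(frames=rng.standard_normal((250, 3, 3)) + 0j, acq=acq)
        )
        with pytest.raises(ValueError):
            stack_planes([a, small], [0.0, 1e-3])
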