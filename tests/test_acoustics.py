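"""Acoustic forward stage: grid-design formulas, solvers, ring sampling."""

import dataclasses

import numpy as np
import pytest

from cavipact import acoustics as ac
from cavipact.fields import FieldMap, centered_origin
from cavipact.phantom import LABELS, UNIFORM_MEDIA


def _fields(shape=(121, 121), pitch=1.0, src=None):
    origin = centered_origin(shape, pitch)
    labels = FieldMap(np.full(shape, LABELS["substrate"], dtype=np.uint8),
                      pitch, origin, quantity="labels")
    p0 = np.zeros(shape)
    if src is not None:
        p0[src] = 1.0
    return FieldMap(p0, pitch, origin, quantity="initial_pressure"), labels


class TestGridDesignFormulas:
    def test_air_spatial_step_bound(self):
        # 340 m/s at 750 kHz: step must not exceed 0.226 mm
        dx = ac.max_spatial_step(340.0, 750e3)
        assert int(dx * 1e3 * 1000) / 1000 == 0.226  # truncated to 3 decimals

    def test_water_spatial_step_matches_1mm_pitch(self):
        assert ac.max_spatial_step(1500.0, 750e3) == pytest.approx(1.0e-3)

    def test_doubling_fmax_halves_step(self):
        assert ac.max_spatial_step(340.0, 1.5e6) == pytest.approx(
            ac.max_spatial_step(340.0, 750e3) / 2)

    def test_depth_in_air(self):
        assert round(ac.max_depth(4096, 340.0, 750e3), 3) == 1.857

    def test_depth_in_water(self):
        assert ac.max_depth(4096, 1500.0, 750e3) == pytest.approx(8.192)

    def test_depth_single_sample(self):
        assert ac.max_depth(1, 340.0, 750e3) == pytest.approx(340.0 / 750e3)

    def test_supported_frequency_water_1mm(self):
        assert ac.max_supported_frequency(1500.0, 1e-3) == pytest.approx(750e3)

    def test_air_frequency_near_fifth_of_water(self):
        f_air = ac.max_supported_frequency(340.0, 1e-3)
        f_water = ac.max_supported_frequency(1500.0, 1e-3)
        assert f_air == pytest.approx(170e3)
        assert f_air / f_water == pytest.approx(340 / 1500)

    def test_frequency_scale_invariance(self):
        assert ac.max_supported_frequency(1500.0, 1e-3) == pytest.approx(
            ac.max_supported_frequency(3000.0, 2e-3))

    @pytest.mark.parametrize("fn,args", [
        (ac.max_supported_frequency, (0, 1e-3)),
        (ac.max_supported_frequency, (1500, -1)),
        (ac.max_spatial_step, (-1, 750e3)),
        (ac.max_spatial_step, (340, 0)),
        (ac.max_depth, (0, 340, 750e3)),
        (ac.max_depth, (4096, 340, 0)),
    ])
    def test_nonpositive_inputs_rejected(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)


class TestSensorArray:
    def test_half_ring_geometry(self):
        arr = ac.SensorArray()
        pos = arr.element_positions
        assert pos.shape == (128, 2)
        np.testing.assert_allclose(np.linalg.norm(pos, axis=1), 55.0)
        assert pos[:, 1].min() >= -1e-9  # all elements on the upper arc
        # even angular spacing
        ang = np.degrees(np.arctan2(pos[:, 1], pos[:, 0]))
        assert np.allclose(np.diff(ang), ang[1] - ang[0])


class TestForwardSimulate:
    GRID = ac.AcousticGridSpec(n_samples=600)

    def test_zero_source_gives_zero_traces(self):
        p0, labels = _fields()
        data = ac.forward_simulate(p0, labels, UNIFORM_MEDIA, self.GRID)
        assert np.all(data.traces == 0)

    def test_point_source_arrival_time(self):
        # coarser dt so +-2 samples brackets the wavefront peak
        grid = ac.AcousticGridSpec(dt=0.3e-6, n_samples=200)
        p0, labels = _fields(src=(60, 60))
        data = ac.forward_simulate(p0, labels, UNIFORM_MEDIA, grid)
        for e in (0, 32, 64, 96, 127):
            d = np.linalg.norm(data.array.element_positions[e]) * 1e-3
            expected = d / 1500.0 / grid.dt
            peak = np.argmax(np.abs(data.traces[e]))
            assert abs(peak - expected) <= 2

    def test_deterministic_bitwise(self):
        p0, labels = _fields(src=(50, 70))
        a = ac.forward_simulate(p0, labels, UNIFORM_MEDIA, self.GRID)
        b = ac.forward_simulate(p0, labels, UNIFORM_MEDIA, self.GRID)
        np.testing.assert_array_equal(a.traces, b.traces)

    def test_stability_bound_reported(self):
        grid = ac.AcousticGridSpec(dt=1e-6)  # CFL 1.5 at 1500 m/s
        p0, labels = _fields(src=(60, 60))
        with pytest.raises(ValueError, match="CFL"):
            ac.forward_simulate(p0, labels, UNIFORM_MEDIA, grid)

    def test_short_window_warns(self):
        grid = ac.AcousticGridSpec(n_samples=100)  # 1.25 us << 37 us needed
        p0, labels = _fields(src=(60, 60))
        with pytest.warns(UserWarning, match="window"):
            ac.forward_simulate(p0, labels, UNIFORM_MEDIA, grid)

    def test_edge_source_warns_about_pml(self):
        p0, labels = _fields(src=(0, 60))
        with pytest.warns(UserWarning, match="PML"):
            ac.forward_simulate(p0, labels, UNIFORM_MEDIA, self.GRID)


class TestSolverPhysics:
    def test_energy_conservation_without_pml(self):
        c = np.full((64, 64), 1500.0)
        rho = np.full((64, 64), 1000.0)
        x = np.arange(64) - 32.0
        X, Y = np.meshgrid(x, x)
        p0 = np.exp(-(X**2 + Y**2) / (2 * 3.0**2))
        states = []
        ac._kspace_run(p0, c, rho, 1e-3, 1e-7, 300, 0, 0.0,
                       on_step=lambda n, p, u0, u1:
                       states.append((p.copy(), u0.copy(), u1.copy())))
        energies = [
            ac.acoustic_energy(states[n][0], states[n][1:], states[n + 1][1:],
                               c, rho)
            for n in range(1, len(states) - 1)
        ]
        drift = (max(energies) - min(energies)) / energies[0]
        assert drift < 0.01

    def test_kspace_vs_fdtd_cross_oracle(self):
        # independent discretisations must agree on a small fixture
        c = np.full((64, 64), 1500.0)
        rho = np.full((64, 64), 1000.0)
        x = np.arange(64) - 32.0
        X, Y = np.meshgrid(x, x)
        p0 = np.exp(-(X**2 + Y**2) / (2 * 2.0**2))
        sensor = np.array([[10.0, 45.0]])
        dt = 2e-7  # CFL 0.3; 120 steps stay clear of boundary returns
        tr_k = ac._kspace_run(p0, c, rho, 1e-3, dt, 120, 0, 0.0,
                              sensor_rc=sensor)
        tr_f = ac._fdtd_run(p0, c, rho, 1e-3, dt, 120, 0, 0.0,
                            sensor_rc=sensor)
        pk_k = np.argmax(np.abs(tr_k[0]))
        pk_f = np.argmax(np.abs(tr_f[0]))
        assert abs(int(pk_k) - int(pk_f)) <= 1
        corr = np.corrcoef(tr_k[0], tr_f[0])[0, 1]
        assert corr >= 0.99

    def test_reciprocity_in_homogeneous_medium(self):
        c = np.full((80, 80), 1500.0)
        rho = np.full((80, 80), 1000.0)
        a_rc, b_rc = (25.0, 30.0), (55.0, 52.0)

        def run(src, rec):
            p0 = np.zeros((80, 80))
            p0[int(src[0]), int(src[1])] = 1.0
            p0 = ac._smooth_p0(p0)
            return ac._kspace_run(p0, c, rho, 1e-3, 2e-7, 220, 0, 0.0,
                                  sensor_rc=np.array([rec]))[0]

        fwd = run(a_rc, b_rc)
        bwd = run(b_rc, a_rc)
        assert np.corrcoef(fwd, bwd)[0, 1] > 0.999

    def test_grid_refinement_keeps_arrival(self):
        # same physical source at half the pitch and dt: the peak arrival
        # must agree within one coarse sample
        def arrival(n, pitch, dt, steps):
            c = np.full((n, n), 1500.0)
            rho = np.full((n, n), 1000.0)
            coords = pitch * (np.arange(n) - n / 2)
            X, Y = np.meshgrid(coords, coords)
            p0 = np.exp(-(X**2 + Y**2) / (2 * 2.0**2))  # sigma 2 mm
            rec = np.array([[n / 2, n / 2 + 22.0 / pitch]])
            tr = ac._kspace_run(p0, c, rho, pitch * 1e-3, dt, steps, 0, 0.0,
                                sensor_rc=rec)[0]
            return np.argmax(np.abs(tr)) * dt

        t_coarse = arrival(64, 1.0, 2e-7, 140)
        t_fine = arrival(128, 0.5, 1e-7, 280)
        assert abs(t_coarse - t_fine) <= 2e-7


class TestHeterogeneousMedium:
    def test_air_inclusion_reflects(self):
        # an impedance mismatch must scatter energy back toward the source
        shape = (121, 121)
        p0, labels = _fields(shape, src=(60, 40))
        lab_air = labels.values.copy()
        lab_air[58:63, 58:63] = LABELS["air"]
        labels_air = FieldMap(lab_air, 1.0, labels.origin, quantity="labels")
        grid = ac.AcousticGridSpec(n_samples=600)
        hom = ac.forward_simulate(p0, labels, UNIFORM_MEDIA, grid)
        het = ac.forward_simulate(p0, labels_air, UNIFORM_MEDIA, grid)
        diff = het.traces - hom.traces
        assert np.abs(diff).max() > 0.01 * np.abs(hom.traces).max()


def test_sensor_data_h5_roundtrip(tmp_path):
    p0, labels = _fields(src=(60, 60))
    grid = ac.AcousticGridSpec(n_samples=600)
    data = ac.forward_simulate(p0, labels, UNIFORM_MEDIA, grid)
    path = ac.save_sensor_data(data, tmp_path / "sensor.h5")
    back = ac.load_sensor_data(path)
    np.testing.assert_array_equal(back.traces, data.traces)
    assert back.dt == data.dt
    assert back.array.n_elements == data.array.n_elements
    assert back.meta["solver"] == "kspace"


def test_h5_bytes_deterministic(tmp_path):
    p0, labels = _fields(src=(60, 60))
    grid = ac.AcousticGridSpec(n_samples=600)
    data = ac.forward_simulate(p0, labels, UNIFORM_MEDIA, grid)
    p1 = ac.save_sensor_data(data, tmp_path / "a.h5")
    p2 = ac.save_sensor_data(data, tmp_path / "b.h5")
    assert p1.read_bytes() == p2.read_bytes()
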