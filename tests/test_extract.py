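import numpy as np
import pytest

from silkfric import extract
from silkfric.synth import TOTAL, WATER_ONLY, PullTrace


def _trace(force, kind=TOTAL, velocity=1.0, replica=0, dt=1e-12):
    force = np.asarray(force, dtype=float)
    t = np.arange(force.size) * dt
    return PullTrace(time=t, spring_pos=velocity * t * 1e9,
                     bundle_pos=np.zeros_like(t), force=force,
                     velocity=velocity, replica=replica, kind=kind, dt=dt)


class TestPeakForce:
    def test_triangle_peak_exact(self):
        tri = np.concatenate([np.linspace(0, 100, 50), np.linspace(100, 0, 50)])
        assert extract.peak_force(_trace(tri), smooth_window=1e-12) == 100.0

    def test_constant_force_any_window(self):
        const = np.full(200, 42.0)
        for w in (1e-12, 5e-12, 50e-12, 200e-12):
            assert extract.peak_force(_trace(const), w) == pytest.approx(42.0)

    def test_noisy_plateau_within_running_mean_statistics(self):
        rng = np.random.default_rng(0)
        sigma, w_samples = 3.0, 64
        noisy = 100.0 + sigma * rng.standard_normal(4096)
        peak = extract.peak_force(_trace(noisy), smooth_window=w_samples * 1e-12)
        # smoothed max of pure noise: within a few sigma/sqrt(w) of the level
        assert abs(peak - 100.0) < 4 * sigma / np.sqrt(w_samples)

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            extract.peak_force(_trace(np.array([])))

    def test_window_longer_than_trace_raises(self):
        with pytest.raises(ValueError):
            extract.peak_force(_trace(np.ones(10)), smooth_window=1.0)


class TestAggregate:
    def _traces(self, totals, waters, velocity=1.0):
        out = []
        for r, f in enumerate(totals):
            out.append(_trace(np.full(100, float(f)), TOTAL, velocity, r))
        for r, f in enumerate(waters):
            out.append(_trace(np.full(100, float(f)), WATER_ONLY, velocity, r))
        return out

    def test_replica_statistics(self):
        ds = extract.aggregate(self._traces([10, 12, 14, 12], [1, 1, 1, 1]),
                               N=10, N_total=100)
        assert ds.f_total_pn[0] == pytest.approx(12.0)
        assert ds.f_total_sem_pn[0] == pytest.approx(np.std([10, 12, 14, 12], ddof=1) / 2)
        assert ds.f_total_sem_pn[0] == pytest.approx(0.8164965, rel=1e-5)

    def test_total_equals_water_gives_zero_difference(self):
        ds = extract.aggregate(self._traces([5, 6], [5, 6]), N=4, N_total=10)
        assert ds.f_ac_pn[0] == pytest.approx(0.0)
        assert ds.f_ac_sem_pn[0] == pytest.approx(np.hypot(0.5, 0.5))

    def test_decomposition_closure_and_per_residue(self, dataset):
        _, ds = dataset
        assert np.allclose(ds.f_total_pn, ds.f_water_pn + ds.f_ac_pn)
        assert np.allclose(ds.f_res_pn, ds.f_ac_pn / ds.N)
        assert np.all(ds.f_ac_pn > 0)
        assert np.all(np.diff(ds.f_ac_pn) > 0)       # increasing in V

    def test_mismatched_grids_rejected(self):
        traces = self._traces([5, 6], [5, 6], velocity=1.0)
        traces += [_trace(np.full(100, 2.0), WATER_ONLY, velocity=3.0)]
        with pytest.raises(ValueError, match="grid"):
            extract.aggregate(traces, N=4, N_total=10)

    def test_single_replica_rejected(self):
        traces = [_trace(np.full(100, 5.0), TOTAL),
                  _trace(np.full(100, 1.0), WATER_ONLY),
                  _trace(np.full(100, 1.0), WATER_ONLY, replica=1)]
        with pytest.raises(ValueError, match="replica"):
            extract.aggregate(traces, N=4, N_total=10)


class TestWaterLaw:
    def _ds(self, V, fw, sem, n_total=100):
        n = len(V)
        z = np.zeros(n)
        return extract.FrictionDataset(
            np.asarray(V, float), fw + z, sem + z, np.asarray(fw, float),
            np.asarray(sem, float), z, z, z, z, 4, 10, n_total)

    def test_exact_noiseless_recovery(self):
        V = np.array([0.1, 1.0, 10.0])
        xi_true = 1e-12
        fw = 100 * xi_true * V / 1e-12          # pN for N_total = 100
        slope, se = extract.fit_water_law(self._ds(V, fw, np.zeros(3)))
        assert slope == pytest.approx(xi_true, rel=1e-12)

    def test_zero_forces_zero_slope(self):
        slope, _ = extract.fit_water_law(self._ds([0.1, 1, 10], np.zeros(3), np.zeros(3)))
        assert slope == 0.0

    def test_too_few_velocities(self):
        with pytest.raises(ValueError):
            extract.fit_water_law(self._ds([1.0, 2.0], np.ones(2), np.ones(2)))


class TestStress:
    def test_unit_arithmetic(self, dataset):
        _, ds = dataset
        import copy
        d1 = extract.to_stress(copy.deepcopy(ds), area_nm2=100.0)
        # 1000 pN over 100 nm^2 is 10 MPa
        assert np.allclose(d1.tau_mpa, d1.f_ac_pn / 100.0)
        d2 = extract.to_stress(copy.deepcopy(ds), area_nm2=200.0)
        assert np.allclose(d2.tau_mpa, d1.tau_mpa / 2.0)

    def test_zero_area_rejected(self, dataset):
        _, ds = dataset
        with pytest.raises(ValueError):
            extract.to_stress(ds, area_nm2=0.0)

    def test_csv_round_trip(self, dataset, tmp_path):
        import copy
        _, ds = dataset
        ds = extract.to_stress(copy.deepcopy(ds), area_nm2=6.29)
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        back = extract.FrictionDataset.from_csv(path)
        assert np.allclose(back.velocities, ds.velocities)
        assert np.allclose(back.f_res_pn, ds.f_res_pn)
        assert np.allclose(back.tau_mpa, ds.tau_mpa)
        assert back.N == ds.N and back.N_total == ds.N_total
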