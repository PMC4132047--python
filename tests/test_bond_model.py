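import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import iv

from silkfric import bond_model as bm
from silkfric.constants import K_B, PN


def test_zero_corrugation_is_pure_background():
    p = bm.BondModelParams(a=1.32, m=1.0, U_bond=0.0, xi0=2e-12)
    V = np.array([1e-4, 0.02, 2.0, 20.0])
    expect = 2e-12 * V / PN
    assert np.allclose(bm.force_velocity(V, p), expect, rtol=1e-12)
    assert np.allclose(bm.fp_oracle(V, p), expect, rtol=1e-9)


def test_zero_velocity_and_oddness(best_fit_params):
    assert bm.force_velocity(0.0, best_fit_params) == 0.0
    f_pos = bm.force_velocity(2.0, best_fit_params)
    f_neg = bm.force_velocity(-2.0, best_fit_params)
    assert f_neg == pytest.approx(-f_pos, rel=1e-12)


def test_monotone_increasing(best_fit_params):
    V = np.logspace(-6, np.log10(20), 40)
    F = np.asarray(bm.force_velocity(V, best_fit_params))
    assert np.all(np.diff(F) > 0)


def test_forward_inverse_round_trip(best_fit_params):
    V = np.logspace(-5, 1.3, 12)
    F = bm.force_velocity(V, best_fit_params)
    assert np.allclose(bm.velocity_of_force(F, best_fit_params), V, rtol=1e-10)


@settings(max_examples=20, deadline=None)
@given(u=st.floats(1e-6, 12.0), ma=st.floats(0.3, 2.5),
       logv=st.floats(-6.0, 1.3))
def test_force_between_free_draining_and_viscous_bounds(u, ma, logv):
    p = bm.BondModelParams(a=ma, m=1.0, U_bond=u)
    v = 10.0 ** logv
    f = bm.force_velocity(v, p) * PN
    lo = p.xi0 * v * (1 - 1e-9)
    hi = p.xi0 * v * iv(0, u / 2.0) ** 2 * (1 + 1e-9)
    assert lo <= f <= hi


def test_viscous_limit_closed_form():
    assert bm.viscous_limit(bm.BondModelParams(U_bond=0.0)) == pytest.approx(1e-12)
    xs = [bm.viscous_limit(bm.BondModelParams(a=1.32, m=1.0, U_bond=u))
          for u in (0.0, 2.0, 4.0, 8.4, 12.0)]
    assert all(a < b for a, b in zip(xs, xs[1:]))    # deeper wells, more friction
    # Zwanzig amplification for the cosine corrugation, against the
    # independent quadrature route at U_bond = 4
    p = bm.BondModelParams(a=1.32, m=1.0, U_bond=4.0)
    f_lo = bm.fp_oracle(1e-7, p) * PN
    assert f_lo / 1e-7 == pytest.approx(p.xi0 * iv(0, 2.0) ** 2, rel=1e-4)


def test_viscous_limit_matches_oracle_at_tiny_velocity(best_fit_params):
    f = bm.fp_oracle(1e-6, best_fit_params) * PN
    assert f / 1e-6 == pytest.approx(bm.viscous_limit(best_fit_params), rel=1e-3)


@pytest.mark.parametrize("u,ma,f_pn", [
    (4.0, 1.32, 8.0),
    (8.4, 1.32, 30.0),
    (8.4, 0.7, 40.0),
])
def test_brownian_dynamics_cross_check(u, ma, f_pn):
    """Third, stochastic route: overdamped BD at fixed force reproduces the
    washboard mean velocity within 3 SEM."""
    p = bm.BondModelParams(a=ma, m=1.0, U_bond=u)
    v_model = bm.velocity_of_force(f_pn, p)
    v_bd, sem = bm.bd_velocity(f_pn, p, n_steps=400_000, n_replicas=4, seed=11)
    assert abs(v_bd - v_model) < 3 * sem + 0.02 * v_model


class _Data:
    def __init__(self, V, f, sem, N=None, area=None):
        self.velocities = V
        self.f_res_pn = f
        self.f_res_sem_pn = sem
        self.N = N
        self.area_nm2 = area


def test_fit_recovers_noiseless_truth(best_fit_params):
    V = np.array([0.02, 0.05, 0.2, 0.5, 2.0, 5.0, 20.0])
    f = np.asarray(bm.force_velocity(V, best_fit_params))
    ds = _Data(V, f, np.zeros_like(f))
    fit1 = bm.fit(ds, "fix_Ubond", init=best_fit_params)
    assert fit1.ma == pytest.approx(1.32, rel=1e-3)
    fit2 = bm.fit(ds, "fix_ma", init=best_fit_params)
    assert fit2.params.U_bond == pytest.approx(8.4, rel=1e-3)
    free = bm.fit(ds, "free", init=bm.BondModelParams(a=1.0, m=1.0, U_bond=6.0))
    assert free.ma == pytest.approx(1.32, rel=1e-2)
    assert free.params.U_bond == pytest.approx(8.4, rel=1e-2)


def test_fit_reports_interface_viscosity(best_fit_params):
    V = np.array([0.02, 0.2, 2.0, 20.0])
    f = np.asarray(bm.force_velocity(V, best_fit_params))
    ds = _Data(V, f, 0.01 * f, N=232, area=6.29)
    fr = bm.fit(ds, "fix_Ubond", init=best_fit_params)
    xi = bm.viscous_limit(fr.params)
    expect = xi * 232 * fr.params.a * 1e-9 / (6.29e-18)
    assert fr.eta_interface == pytest.approx(expect, rel=1e-9)
    assert fr.eta_viscous_res == pytest.approx(expect, rel=1e-9)


def test_fit_error_conditions(best_fit_params):
    V = np.array([0.1, 1.0, 10.0])
    f = np.asarray(bm.force_velocity(V, best_fit_params))
    with pytest.raises(bm.FitError):
        bm.fit(_Data(V, f, 0.01 * f), "fix_Ubond")
    V4 = np.array([0.1, 0.3, 1.0, 10.0])
    f4 = np.asarray(bm.force_velocity(V4, best_fit_params))
    sem = 0.01 * f4
    sem[1] = 0.0
    with pytest.raises(bm.FitError):
        bm.fit(_Data(V4, f4, sem), "fix_Ubond")
    with pytest.raises(ValueError):
        bm.fit(_Data(V4, f4, 0.01 * f4), "nonsense")


def test_presets_two_orders_of_magnitude_apart():
    """Sliding on the flat crystal face is ~50x less viscous than sliding
    within the entangled amorphous phase (2e2 vs 1e4 Ns/m^2)."""
    n_per_m2 = 36.9e18
    etas = {}
    for name in ("interface", "amorphous"):
        p = bm.preset(name)
        etas[name] = bm.viscous_limit(p) * n_per_m2 * p.a * 1e-9
    assert etas["interface"] == pytest.approx(2.0e2, rel=1e-6)
    assert etas["amorphous"] == pytest.approx(1.0e4, rel=1e-6)
    ratio = etas["amorphous"] / etas["interface"]
    assert 40 < ratio < 60


def test_parameter_validation():
    with pytest.raises(ValueError):
        bm.force_velocity(1.0, bm.BondModelParams(a=-1.0))
    with pytest.raises(ValueError):
        bm.force_velocity(1.0, bm.BondModelParams(xi0=0.0))
    with pytest.raises(ValueError):
        bm.force_velocity(1.0, bm.BondModelParams(U_bond=float("nan")))
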