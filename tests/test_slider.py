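import copy

import numpy as np
import pytest
from scipy.optimize import brentq

from silkfric import slider as sl

GPA = 1e9


# ---------------------------------------------------------------------------
# 1D closed-form drivers

def _uniaxial_step(card, state, deps_xx):
    """Apply a uniaxial-stress strain increment: lateral strain adjusted so
    sigma_yy = sigma_zz = 0 (isotropic => eps_yy = eps_zz)."""
    def syy(dlat):
        trial = copy.deepcopy(state)
        deps = np.array([deps_xx, dlat, dlat, 0.0])
        sig, _ = sl.plastic_update(deps, trial, card)
        return sig[1]
    lim = abs(deps_xx) + 1e-12
    dlat = brentq(syy, -lim, lim, xtol=1e-16)
    sig, _ = sl.plastic_update(np.array([deps_xx, dlat, dlat, 0.0]), state, card)
    return sig[0]


def _fresh_state():
    return {"stress": np.zeros(4), "alpha": np.zeros(4), "ep": 0.0}


class TestPlasticUpdate:
    def test_elastic_uniaxial_stress_is_youngs_modulus(self):
        card = sl.ElastoplasticCard()
        state = _fresh_state()
        eps = 1e-4
        sxx = _uniaxial_step(card, state, eps)
        assert sxx == pytest.approx(card.youngs_modulus * GPA * eps, rel=1e-9)

    def test_bilinear_hardening_closed_form(self):
        """Past yield the uniaxial curve is sigma = sy + Et (eps - sy/E)."""
        card = sl.ElastoplasticCard(hardening_mix=0.0)
        e_mod = card.youngs_modulus * GPA
        et = card.tangent_modulus * GPA
        sy = card.yield_stress * GPA
        state = _fresh_state()
        eps_tot, sxx = 0.0, 0.0
        n, eps_end = 400, 4.0 * sy / e_mod
        for _ in range(n):
            deps = eps_end / n
            sxx = _uniaxial_step(card, state, deps)
            eps_tot += deps
        expect = sy + et * (eps_tot - sy / e_mod)
        assert sxx == pytest.approx(expect, rel=1e-4)       # 4 s.f.

    def test_kinematic_bauschinger_shift(self):
        """Pure kinematic hardening: reverse yielding begins 2 sy below the
        pre-strain stress (shift equals twice the backstress)."""
        card = sl.ElastoplasticCard(hardening_mix=1.0)
        e_mod = card.youngs_modulus * GPA
        sy = card.yield_stress * GPA
        state = _fresh_state()
        eps_fwd = 3.0 * sy / e_mod
        n = 300
        s_fwd = 0.0
        for _ in range(n):
            s_fwd = _uniaxial_step(card, state, eps_fwd / n)
        # reverse loading: elastic down to s_fwd - 2 sy (the yield surface
        # centre translated by the backstress), then plastic again
        ep0 = state["ep"]
        eps_probe = -eps_fwd / n
        s_now = s_fwd
        while state["ep"] == ep0:
            s_now = _uniaxial_step(card, state, eps_probe)
        expect = s_fwd - 2.0 * sy
        assert s_now == pytest.approx(expect, rel=5e-3)

    def test_stress_on_or_inside_yield_surface(self):
        card = sl.ElastoplasticCard(hardening_mix=0.3)
        state = {"stress": np.zeros((5, 4)), "alpha": np.zeros((5, 4)),
                 "ep": np.zeros(5)}
        rng = np.random.default_rng(1)
        for _ in range(50):
            deps = rng.normal(scale=2e-4, size=(5, 4))
            sig, _ = sl.plastic_update(deps, state, card)
        h = card.hardening_modulus
        sy = card.yield_stress * GPA + (1 - card.hardening_mix) * h * state["ep"]
        xi = sig - (sig[..., :1] * 0 + sig[..., [0, 1, 2]].mean(-1, keepdims=True)
                    ) * np.array([1, 1, 1, 0]) - state["alpha"]
        q = np.sqrt(1.5 * ((xi * xi) * np.array([1, 1, 1, 2])).sum(-1))
        assert np.all(q <= sy * (1 + 1e-8))


class TestViscoelasticUpdate:
    def test_step_strain_relaxation_closed_form(self):
        card = sl.ViscoelasticCard()
        g0, ginf, beta = card.G0 * GPA, card.Ginf * GPA, card.beta
        gamma0 = 1e-3
        dt = 1e-13
        hist = {"eps": np.zeros(4), "q": np.zeros(4)}
        sig, _ = sl.viscoelastic_update(np.array([0, 0, 0, gamma0 / 2]), hist,
                                        card, dt)
        assert sig[3] == pytest.approx(g0 * gamma0, rel=1e-4)
        t = dt
        for target in (0.5e-9, 1.0e-9, 3.0e-9):
            n = int(round((target - t) / (dt * 1e3)))
            for _ in range(n):
                sig, _ = sl.viscoelastic_update(np.zeros(4), hist, card, dt * 1e3)
            t += n * dt * 1e3
            expect = (ginf + (g0 - ginf) * np.exp(-beta * (t - dt / 2))) * gamma0
            assert sig[3] == pytest.approx(expect, rel=1e-4)

    def test_equal_moduli_is_elastic(self):
        card = sl.ViscoelasticCard(G0=1.0, Ginf=1.0)
        hist = {"eps": np.zeros(4), "q": np.zeros(4)}
        sig, _ = sl.viscoelastic_update(np.array([0, 0, 0, 5e-4]), hist, card, 1e-12)
        s0 = sig[3]
        for _ in range(1000):
            sig, _ = sl.viscoelastic_update(np.zeros(4), hist, card, 1e-11)
        assert sig[3] == pytest.approx(s0, rel=1e-12)
        assert s0 == pytest.approx(2 * 1.0 * GPA * 5e-4, rel=1e-12)

    def test_constant_shear_rate_ramp(self):
        card = sl.ViscoelasticCard()
        g0, ginf, beta = card.G0 * GPA, card.Ginf * GPA, card.beta
        rate = 1e6            # engineering shear rate, 1/s
        dt = 2e-13
        hist = {"eps": np.zeros(4), "q": np.zeros(4)}
        t, n = 0.0, 20000
        for _ in range(n):
            sig, _ = sl.viscoelastic_update(np.array([0, 0, 0, rate * dt / 2]),
                                            hist, card, dt)
            t += dt
        expect = ginf * rate * t + (g0 - ginf) * rate / beta * (1 - np.exp(-beta * t))
        assert sig[3] == pytest.approx(expect, rel=2e-3)


class TestFilm:
    def test_definition_exact(self):
        tau = sl.film_traction(1.0, sl.FilmCard(eta=2.0e2, h=1.0))
        assert tau == pytest.approx(-2.0e11)

    def test_zero_velocity_zero_traction(self):
        assert sl.film_traction(0.0, sl.FilmCard()) == 0.0

    def test_opposes_relative_motion(self):
        dv = np.array([-3.0, -0.1, 0.5, 8.0])
        tau = sl.film_traction(dv, sl.FilmCard())
        assert np.all(np.sign(tau) == -np.sign(dv))


RIGID_C = sl.ElastoplasticCard(youngs_modulus=25e6, yield_stress=2e6,
                               tangent_modulus=2.5e6)
RIGID_A = sl.ViscoelasticCard(bulk_modulus=4e6, G0=1.5e6, Ginf=0.15e6)


class TestRunCase:
    def test_zero_velocity_zero_stresses(self):
        r = sl.run_case(sl.SliderCase(velocity=0.0, duration=0.02e-9))
        assert all(v == pytest.approx(0.0, abs=1e-3) for v in r.steady.values())

    def test_rigid_limit_couette(self):
        case = sl.SliderCase(velocity=1.0, duration=1e-12, damping=1e15,
                             drive="body")
        r = sl.run_case(case, RIGID_C, RIGID_A)
        film = sl.DEFAULT_FILM
        expect = film.eta * 1.0 / (film.h * 1e-9)
        assert r.steady_ok
        assert r.steady["film_shear"] == pytest.approx(expect, rel=0.01)

    def test_mesh_refinement_rigid(self):
        vals = []
        for h in (0.5, 0.25):
            case = sl.SliderCase(velocity=1.0, duration=0.6e-12, damping=1e15,
                                 drive="body", block_size=2.0, plate_width=6.0,
                                 element_size=h)
            vals.append(sl.run_case(case, RIGID_C, RIGID_A).steady["film_shear"])
        assert abs(vals[1] / vals[0] - 1) < 0.02

    def test_energy_balance_closes(self):
        for v, angle, tp in ((1.0, 0.0, 0.5), (0.5, 10.0, 2.85)):
            r = sl.run_case(sl.SliderCase(velocity=v, load_angle=angle,
                                          duration=0.1e-9, plate_thickness=tp))
            e = r.energies
            resid = e["external_work"] - (e["kinetic"] + e["material_work"]
                                          + e["film_dissipated"]
                                          + e["penalty_stored"]
                                          + e["damping_dissipated"])
            assert abs(resid) <= 0.01 * abs(e["external_work"])
            assert e["film_dissipated"] >= 0.0

    def test_sweep_monotone_and_low_velocity_insignificant(self):
        df = sl.velocity_sweep([0.05, 0.5, 5.0], sl.SliderCase(duration=0.15e-9))
        shear = df["film_shear_Pa"].to_numpy()
        assert np.all(np.diff(shear) > 0)
        assert np.all(np.diff(df["crystal_vm_Pa"].to_numpy()) > 0)
        assert shear[0] < 0.05 * shear[-1]       # low-V stresses insignificant

    def test_inclined_exceeds_horizontal(self):
        kw = dict(velocity=0.5, duration=0.2e-9, plate_thickness=2.85)
        horiz = sl.run_case(sl.SliderCase(load_angle=0.0, **kw))
        incl = sl.run_case(sl.SliderCase(load_angle=10.0, **kw))
        assert incl.steady["amorphous_vm_avg"] > horiz.steady["amorphous_vm_avg"]

    def test_vanishing_film_decouples(self):
        r = sl.run_case(sl.SliderCase(velocity=1.0, duration=0.05e-9),
                        film=sl.FilmCard(eta=1e-6, h=0.5))
        ref = sl.run_case(sl.SliderCase(velocity=1.0, duration=0.05e-9))
        assert r.steady["film_shear"] < 1e-4 * ref.steady["film_shear"]
        assert r.steady["amorphous_vm_avg"] < 1e-3 * ref.steady["amorphous_vm_avg"]

    def test_cfl_guard(self):
        with pytest.raises(ValueError, match="step"):
            sl.run_case(sl.SliderCase(velocity=1.0, duration=1.0,
                                      element_size=0.25))

    def test_card_validation(self):
        with pytest.raises(ValueError):
            sl.ElastoplasticCard(poisson=0.6).validate()
        with pytest.raises(ValueError):
            sl.ViscoelasticCard(Ginf=2.0, G0=1.0).validate()
        with pytest.raises(ValueError):
            sl.FilmCard(eta=-1.0).validate()
        with pytest.raises(ValueError):
            sl.SliderCase(load_angle=95.0).validate()
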