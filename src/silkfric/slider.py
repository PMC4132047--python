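"""Explicit-dynamics slider: an elastoplastic crystal block sliding over a
viscoelastic amorphous plate through a Newtonian lubrication film.

2D plane-strain reduction with bilinear quads (2x2 Gauss), lumped mass and
central-difference time integration.  The two bodies never share nodes: the
film couples the facing surfaces with a rate-dependent tangential traction
``tau = eta * dv / h`` plus a normal penalty preventing penetration.  The
crystal block is driven at a prescribed velocity (optionally inclined into
the plate); the plate base is fixed.  Outputs are von Mises stress histories
per phase and the interface shear traction, with steady-state values per
velocity - the qualitative structure of stress vs relative sliding velocity
for horizontal and inclined loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ElastoplasticCard", "ViscoelasticCard", "FilmCard", "SliderCase",
           "SliderResult", "plastic_update", "viscoelastic_update",
           "film_traction", "run_case", "velocity_sweep",
           "DEFAULT_CRYSTAL", "DEFAULT_AMORPHOUS", "DEFAULT_FILM"]

GPA = 1e9


@dataclass(frozen=True)
class ElastoplasticCard:
    """Bilinear J2 elastoplasticity with mixed isotropic/kinematic hardening."""

    youngs_modulus: float = 25.0   # GPa
    poisson: float = 0.3
    yield_stress: float = 2.0      # GPa
    tangent_modulus: float = 2.5   # GPa
    hardening_mix: float = 0.5     # 0 = isotropic, 1 = kinematic
    density: float = 1300.0        # kg/m^3

    def validate(self):
        if not (0.0 < self.poisson < 0.5):
            raise ValueError("poisson must be in (0, 0.5)")
        if self.tangent_modulus >= self.youngs_modulus:
            raise ValueError("tangent modulus must be below Young's modulus")
        if not (0.0 <= self.hardening_mix <= 1.0):
            raise ValueError("hardening_mix must be in [0, 1]")

    @property
    def mu(self):
        return self.youngs_modulus * GPA / (2.0 * (1.0 + self.poisson))

    @property
    def lam(self):
        e, nu = self.youngs_modulus * GPA, self.poisson
        return e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))

    @property
    def hardening_modulus(self):
        e, et = self.youngs_modulus * GPA, self.tangent_modulus * GPA
        return e * et / (e - et)


@dataclass(frozen=True)
class ViscoelasticCard:
    """Elastic bulk response + exponential shear relaxation
    G(t) = Ginf + (G0 - Ginf) exp(-beta t)."""

    bulk_modulus: float = 4.0      # GPa
    G0: float = 1.5                # GPa, short-time shear modulus
    Ginf: float = 0.15             # GPa, long-time shear modulus
    beta: float = 1.0e9            # 1/s
    density: float = 1300.0

    def validate(self):
        if not (self.G0 >= self.Ginf > 0):
            raise ValueError("need G0 >= Ginf > 0")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class FilmCard:
    """Newtonian lubrication film: tau = eta * dv / h."""

    eta: float = 2.0e2             # Ns/m^2, dynamic viscosity
    h: float = 0.5                 # nm, film thickness

    def validate(self):
        if self.eta <= 0 or self.h <= 0:
            raise ValueError("film viscosity and thickness must be positive")


@dataclass(frozen=True)
class SliderCase:
    """Geometry, loading and duration of one sliding simulation (nm, m/s)."""

    velocity: float = 1.0          # m/s, drive speed
    load_angle: float = 0.0        # degrees; > 0 tilts the drive into the plate
    plate_thickness: float = 0.5   # nm
    plate_width: float = 12.0      # nm
    block_size: float = 4.0        # nm (square crystal block)
    element_size: float = 0.5      # nm
    duration: float = 2.0e-9       # s
    cfl_safety: float = 0.5
    plate_base: str = "fixed"      # "fixed" | "normal_only"
    damping: float = 0.0           # 1/s, mass-proportional damping of elastic
                                   # ringing for quasi-static verification runs
    drive: str = "top"             # "top": prescribe the block's top face;
                                   # "body": prescribe every block node
                                   # (kinematic drive, e.g. rigid-limit checks)

    def validate(self):
        if not (0.0 <= self.load_angle < 90.0):
            raise ValueError("load_angle must be in [0, 90)")
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")


@dataclass
class SliderResult:
    time: np.ndarray
    crystal_vm_avg: np.ndarray     # Pa
    crystal_vm_max: np.ndarray
    amorphous_vm_avg: np.ndarray
    film_shear: np.ndarray         # Pa, mean |traction|
    energies: dict
    steady: dict                   # steady-state values (last-quarter means)
    steady_ok: bool                # windowed variation < 0.5%
    dt: float


# ---------------------------------------------------------------------------
# material point updates (vectorized over Gauss points)
# stress/strain component order: xx, yy, zz, xy (tensor shear)

_TRACE = np.array([1.0, 1.0, 1.0, 0.0])
_DEV_W = np.array([1.0, 1.0, 1.0, 2.0])   # double contraction weights


def _dev(sig):
    p = (sig[..., 0] + sig[..., 1] + sig[..., 2]) / 3.0
    return sig - p[..., None] * _TRACE


def von_mises(sig):
    s = _dev(sig)
    j2 = 0.5 * ((s * s) * _DEV_W).sum(axis=-1)
    return np.sqrt(3.0 * j2)


def elastic_stress_increment(deps, lam, mu):
    tr = deps[..., 0] + deps[..., 1] + deps[..., 2]
    return lam * tr[..., None] * _TRACE + 2.0 * mu * deps


def plastic_update(deps, state, card: ElastoplasticCard):
    """Radial-return J2 update with bilinear mixed hardening.

    ``state`` is a dict with ``stress`` (..., 4), ``alpha`` (backstress,
    ..., 4) and ``ep`` (equivalent plastic strain, ...); updated in place and
    returned with the new stress.
    """
    card.validate()
    mu, lam, H = card.mu, card.lam, card.hardening_modulus
    mix = card.hardening_mix
    sy0 = card.yield_stress * GPA
    sig = state["stress"] + elastic_stress_increment(deps, lam, mu)
    xi = _dev(sig) - state["alpha"]
    q = np.sqrt(1.5 * ((xi * xi) * _DEV_W).sum(axis=-1))
    sy = sy0 + (1.0 - mix) * H * state["ep"]
    f = q - sy
    yielding = f > 0.0
    if np.any(yielding):
        dlam = np.where(yielding, f / (3.0 * mu + H), 0.0)
        qs = np.where(q > 0, q, 1.0)
        nhat = xi / qs[..., None]
        sig = sig - (3.0 * mu * dlam)[..., None] * nhat
        state["alpha"] = state["alpha"] + (mix * H * dlam)[..., None] * nhat
        state["ep"] = state["ep"] + dlam
    state["stress"] = sig
    return sig, state


def viscoelastic_update(deps, history, card: ViscoelasticCard, dt: float):
    """Recursive exponential-integration update of the hereditary integral.

    ``history`` holds ``eps`` (total strain) and ``q`` (transient deviatoric
    overstress); volumetric response is elastic with the bulk modulus.
    """
    card.validate()
    if dt <= 0:
        raise ValueError("dt must be positive")
    k = card.bulk_modulus * GPA
    g0, ginf, beta = card.G0 * GPA, card.Ginf * GPA, card.beta
    history["eps"] = history["eps"] + deps
    de_dev = _dev(deps)
    fac = np.exp(-beta * dt)
    history["q"] = history["q"] * fac + 2.0 * (g0 - ginf) * np.exp(-0.5 * beta * dt) * de_dev
    eps = history["eps"]
    tr = eps[..., 0] + eps[..., 1] + eps[..., 2]
    sig = k * tr[..., None] * _TRACE + 2.0 * ginf * _dev(eps) + history["q"]
    history["stress"] = sig
    return sig, history


def film_traction(dv_tangential, card: FilmCard):
    """Shear traction (Pa) transmitted by the film; opposes relative motion."""
    card.validate()
    return -card.eta * np.asarray(dv_tangential) / (card.h * 1e-9)


# ---------------------------------------------------------------------------
# meshing and explicit dynamics

_GP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)


def _grid(x0, y0, wx, wy, hx):
    nx = max(1, int(round(wx / hx)))
    ny = max(1, int(round(wy / hx)))
    xs = np.linspace(x0, x0 + wx, nx + 1)
    ys = np.linspace(y0, y0 + wy, ny + 1)
    nodes = np.array([[x, y] for y in ys for x in xs])
    elems = []
    for j in range(ny):
        for i in range(nx):
            n0 = j * (nx + 1) + i
            elems.append([n0, n0 + 1, n0 + nx + 2, n0 + nx + 1])
    return nodes, np.array(elems, dtype=int), nx, ny


def _b_matrices(nodes, elems):
    """B matrices and Gauss weights for bilinear quads (reference config)."""
    ne = len(elems)
    B = np.zeros((ne, 4, 4, 8))     # elem, gp, strain comp (xx,yy,zz=0,xy), dof
    wdet = np.zeros((ne, 4))
    xy = nodes[elems]               # (ne, 4, 2)
    for g, (xi, eta) in enumerate(_GP):
        dn = 0.25 * np.array([
            [-(1 - eta), -(1 - xi)],
            [+(1 - eta), -(1 + xi)],
            [+(1 + eta), +(1 + xi)],
            [-(1 + eta), +(1 - xi)],
        ])                           # (4 nodes, 2)
        J = np.einsum("nia,nib->nab", xy, dn[None].repeat(ne, 0))
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        Jinv = np.empty_like(J)
        Jinv[:, 0, 0] = J[:, 1, 1] / detJ
        Jinv[:, 1, 1] = J[:, 0, 0] / detJ
        Jinv[:, 0, 1] = -J[:, 0, 1] / detJ
        Jinv[:, 1, 0] = -J[:, 1, 0] / detJ
        dndx = np.einsum("ia,nba->nib", dn, Jinv)   # (ne, 4, 2)
        for a in range(4):
            B[:, g, 0, 2 * a] = dndx[:, a, 0]
            B[:, g, 1, 2 * a + 1] = dndx[:, a, 1]
            B[:, g, 3, 2 * a] = 0.5 * dndx[:, a, 1]
            B[:, g, 3, 2 * a + 1] = 0.5 * dndx[:, a, 0]
        wdet[:, g] = detJ            # unit gauss weights
    return B, wdet


class _Body:
    def __init__(self, nodes, elems, card, kind):
        self.nodes = nodes
        self.elems = elems
        self.card = card
        self.kind = kind
        self.B, self.wdet = _b_matrices(nodes, elems)
        ne = len(elems)
        if kind == "plastic":
            self.state = {"stress": np.zeros((ne, 4, 4)),
                          "alpha": np.zeros((ne, 4, 4)),
                          "ep": np.zeros((ne, 4))}
        else:
            self.state = {"eps": np.zeros((ne, 4, 4)),
                          "q": np.zeros((ne, 4, 4)),
                          "stress": np.zeros((ne, 4, 4))}
        area = self.wdet.sum(axis=1)
        self.mass = np.zeros(len(nodes))
        np.add.at(self.mass, elems.ravel(),
                  np.repeat(card.density * area / 4.0, 4))

    def internal_force(self, v, dt):
        """Material update from nodal velocities; returns (nodal force,
        incremental material work)."""
        ue = v[self.elems].reshape(len(self.elems), 8) * dt
        deps = np.einsum("ngsd,nd->ngs", self.B, ue)
        if self.kind == "plastic":
            sig, _ = plastic_update(deps, self.state, self.card)
        else:
            sig, _ = viscoelastic_update(deps, self.state, self.card, dt)
        work = float(np.einsum("ngs,ngs,s,ng->", sig, deps, _DEV_W, self.wdet))
        fe = np.einsum("ngsd,ngs,s,ng->nd", self.B, sig, _DEV_W, self.wdet)
        f = np.zeros((len(self.nodes), 2))
        np.add.at(f, self.elems.ravel(),
                  fe.reshape(len(self.elems), 4, 2).reshape(-1, 2))
        return -f, work              # force on nodes = -B^T sigma

    def vm(self):
        return von_mises(self.state["stress"]).mean(axis=1)


def _wave_speed(card):
    if isinstance(card, ElastoplasticCard):
        m = card.lam + 2.0 * card.mu
    else:
        m = (card.bulk_modulus + 4.0 / 3.0 * card.G0) * GPA
    return np.sqrt(m / card.density)


def run_case(case: SliderCase,
             crystal: ElastoplasticCard | None = None,
             amorphous: ViscoelasticCard | None = None,
             film: FilmCard | None = None,
             n_record: int = 400) -> SliderResult:
    """Explicit central-difference run of one sliding load case."""
    crystal = crystal or DEFAULT_CRYSTAL
    amorphous = amorphous or DEFAULT_AMORPHOUS
    film = film or DEFAULT_FILM
    for c in (crystal, amorphous, film):
        c.validate()
    case.validate()

    nm = 1e-9
    h_el = case.element_size * nm
    hf = film.h * nm
    # early guard: step count at the CFL limit, before any meshing
    cmax_est = max(_wave_speed(crystal), _wave_speed(amorphous))
    n_est = int(case.duration / (case.cfl_safety * h_el / cmax_est))
    if n_est > 5_000_000:
        raise ValueError(f"stable step {case.cfl_safety * h_el / cmax_est:.2e}s "
                         f"needs {n_est} steps; shorten the duration or coarsen "
                         "the mesh")
    # plate below y=0, block above the film gap; the plate is widened when
    # the sweep would slide the block off its end
    travel = case.velocity * np.cos(np.deg2rad(case.load_angle)) * case.duration
    width = max(case.plate_width * nm,
                (2.0 + case.block_size) * nm + travel + 2.0 * h_el)
    p_nodes, p_elems, pnx, _ = _grid(0.0, -case.plate_thickness * nm,
                                     width, case.plate_thickness * nm,
                                     min(h_el, case.plate_thickness * nm))
    xb0 = 1.0 * nm
    b_nodes, b_elems, bnx, _ = _grid(xb0, hf, case.block_size * nm,
                                     case.block_size * nm, h_el)
    plate = _Body(p_nodes, p_elems, amorphous, "visco")
    block = _Body(b_nodes, b_elems, crystal, "plastic")

    # node sets (atol scaled to the mesh: coordinates are nm-sized)
    tol = 1e-3 * h_el
    p_top = np.nonzero(np.abs(p_nodes[:, 1]) < tol)[0]
    p_top = p_top[np.argsort(p_nodes[p_top, 0])]
    p_bot = np.nonzero(np.abs(p_nodes[:, 1] + case.plate_thickness * nm) < tol)[0]
    b_bot = np.nonzero(np.abs(b_nodes[:, 1] - hf) < tol)[0]
    b_bot = b_bot[np.argsort(b_nodes[b_bot, 0])]
    b_top = np.nonzero(np.abs(b_nodes[:, 1] - hf - case.block_size * nm) < tol)[0]

    # tributary film length per block-bottom node
    xb = b_nodes[b_bot, 0]
    seg = np.zeros(len(xb))
    seg[:-1] += 0.5 * np.diff(xb)
    seg[1:] += 0.5 * np.diff(xb)

    theta = np.deg2rad(case.load_angle)
    v_drive = np.array([case.velocity * np.cos(theta),
                        -case.velocity * np.sin(theta)])

    cmax = max(_wave_speed(crystal), _wave_speed(amorphous))
    k_pen = 0.3 * (amorphous.bulk_modulus + crystal.youngs_modulus) * GPA / h_el
    dt = case.cfl_safety * h_el / cmax
    # penalty springs must stay inside the explicit stability limit too
    m_min = min(plate.mass[p_top].min(), block.mass[b_bot].min())
    dt = min(dt, 0.5 * 2.0 / np.sqrt(k_pen * seg.max() / m_min))
    n_steps = max(200, int(case.duration / dt))
    if n_steps > 5_000_000:
        raise ValueError(f"stable step {dt:.2e}s needs {n_steps} steps; shorten "
                         "the duration or coarsen the mesh")
    rec_every = max(1, n_steps // n_record)

    body_drive = case.drive == "body"
    vp = np.zeros_like(p_nodes)
    vb = np.zeros_like(b_nodes)
    up = np.zeros_like(p_nodes)     # displacements
    ub = np.zeros_like(b_nodes)
    if body_drive:
        vb[:] = v_drive
    else:
        vb[b_top] = v_drive
    fp = np.zeros_like(p_nodes)     # internal forces lag one step (explicit)
    fb = np.zeros_like(b_nodes)

    W_ext_i = W_ext_f = W_film = W_int = W_pen = W_dmp = 0.0
    # startup impulse that sets the driven nodes in motion
    m_drv = block.mass.sum() if body_drive else block.mass[b_top].sum()
    W_ext_i += 0.5 * float(m_drv) * float(np.dot(v_drive, v_drive))
    t_hist, c_avg, c_max, a_avg, f_shear = [], [], [], [], []
    tau_eff = np.zeros(len(b_bot))

    for i in range(n_steps):
        # normal penalty on current coordinates (explicit, conservative)
        xbot = b_nodes[b_bot] + ub[b_bot]
        ptop = p_nodes[p_top] + up[p_top]
        fx = np.interp(xbot[:, 0], ptop[:, 0], ptop[:, 1])
        gap = xbot[:, 1] - fx - hf
        # deadband of 1% film thickness: sub-pm elastic bulges at the
        # traction edges must not be amplified by the penalty stiffness
        over = -gap - 0.01 * hf
        pen = np.where(over > 0.0, k_pen * over, 0.0)  # Pa, pushes block up
        f_pen_b = np.zeros_like(vb)
        f_pen_b[b_bot, 1] = pen * seg
        f_pen_p = np.zeros_like(vp)
        jr = np.clip(np.searchsorted(ptop[:, 0], xbot[:, 0]), 1, len(p_top) - 1)
        wr = np.clip((xbot[:, 0] - ptop[jr - 1, 0])
                     / (ptop[jr, 0] - ptop[jr - 1, 0]), 0.0, 1.0)
        np.add.at(f_pen_p[:, 1], p_top[jr - 1], -(1 - wr) * pen * seg)
        np.add.at(f_pen_p[:, 1], p_top[jr], -wr * pen * seg)

        vp_old = vp.copy()
        vb_old = vb.copy()
        f_dmp_p = -case.damping * plate.mass[:, None] * vp
        f_dmp_b = -case.damping * block.mass[:, None] * vb
        vp += (fp + f_pen_p + f_dmp_p) / plate.mass[:, None] * dt
        vb += (fb + f_pen_b + f_dmp_b) / block.mass[:, None] * dt
        # constrained dofs never integrate momentum
        if body_drive:
            vb[:] = v_drive
        else:
            vb[b_top] = v_drive
        if case.plate_base == "fixed":
            vp[p_bot] = 0.0
        else:
            vp[p_bot, 1] = 0.0
        # work ledger: every impulse paired with the same midpoint velocity
        # that carries it into the kinetic energy (exact discrete closure)
        vp_mid = 0.5 * (vp_old + vp)
        vb_mid = 0.5 * (vb_old + vb)
        W_int -= (float(np.sum(fp * vp_mid)) + float(np.sum(fb * vb_mid))) * dt
        W_pen -= (float(np.sum(f_pen_p * vp_mid))
                  + float(np.sum(f_pen_b * vb_mid))) * dt
        W_dmp -= (float(np.sum(f_dmp_p * vp_mid))
                  + float(np.sum(f_dmp_b * vb_mid))) * dt

        # film: exact exponential (OU) update of each pair's relative
        # tangential velocity with the other forces as a constant source -
        # the film damping is far too stiff for explicit integration, and a
        # plain implicit decay would wrongly suppress sliding in the stiff
        # limit instead of relaxing to the force-balance sliding speed
        c_damp = film.eta / hf * seg                   # Ns/m per pair
        vpx = np.interp(xbot[:, 0], ptop[:, 0], vp[p_top, 0])
        mp_eff = (1 - wr) * plate.mass[p_top[jr - 1]] + wr * plate.mass[p_top[jr]]
        mb_ = block.mass[b_bot]
        m_red = 1.0 / (1.0 / mb_ + 1.0 / mp_eff)
        r_p = np.interp(xbot[:, 0], ptop[:, 0],
                        (fp + f_pen_p)[p_top, 0] / plate.mass[p_top])
        if body_drive:
            # block side kinematic: infinite mass in the pair update
            m_red = mp_eff
            r_acc = -r_p
            dv_pre = v_drive[0] - vpx
        else:
            m_red = 1.0 / (1.0 / mb_ + 1.0 / mp_eff)
            r_acc = (fb + f_pen_b)[b_bot, 0] / mb_ - r_p
            dv_pre = vb[b_bot, 0] - vpx                # source kick included
        dv0 = dv_pre - r_acc * dt
        alpha = c_damp * dt / m_red
        dv_eq = r_acc * m_red / c_damp
        dv_new = dv_eq + (dv0 - dv_eq) * np.exp(-alpha)
        J = m_red * (dv_new - dv_pre)                  # film impulse on block
        ke_before = 0.5 * float(np.sum(mb_ * vb[b_bot, 0] ** 2)
                                + np.sum(plate.mass[p_top] * vp[p_top, 0] ** 2))
        if not body_drive:
            vb[b_bot, 0] += J / mb_
        np.add.at(vp[:, 0], p_top[jr - 1], -(1 - wr) * J / plate.mass[p_top[jr - 1]])
        np.add.at(vp[:, 0], p_top[jr], -wr * J / plate.mass[p_top[jr]])
        ke_after = 0.5 * float(np.sum(mb_ * vb[b_bot, 0] ** 2)
                               + np.sum(plate.mass[p_top] * vp[p_top, 0] ** 2))
        if body_drive:
            # block feeds the film through the constraint; plate KE change is
            # already inside ke_before/after
            W_ext_f -= float(np.sum(J)) * v_drive[0]
            W_film += -float(np.sum(J)) * v_drive[0] + (ke_before - ke_after)
        else:
            W_film += ke_before - ke_after
        tau_eff = -J / (dt * seg)                      # effective traction, Pa

        # reaction work on the driven face (material + penalty + damping)
        drv = slice(None) if body_drive else b_top
        W_ext_f -= float(np.sum((fb[drv] + f_pen_b[drv] + f_dmp_b[drv])
                                * v_drive[None, :])) * dt

        up += vp * dt
        ub += vb * dt
        fp, _ = plate.internal_force(vp, dt)
        fb, _ = block.internal_force(vb, dt)

        if i % rec_every == 0:
            t_hist.append((i + 1) * dt)
            bvm = block.vm()
            c_avg.append(bvm.mean())
            c_max.append(von_mises(block.state["stress"]).max())
            a_avg.append(plate.vm().mean())
            f_shear.append(float(np.abs(tau_eff).mean()))

    ke = 0.5 * float(np.sum(plate.mass[:, None] * vp**2)
                     + np.sum(block.mass[:, None] * vb**2))
    energies = {"external_work": W_ext_i + W_ext_f, "kinetic": ke,
                "film_dissipated": W_film, "material_work": W_int,
                "penalty_stored": W_pen, "damping_dissipated": W_dmp,
                "external_work_inertial": W_ext_i,
                "external_work_force": W_ext_f}

    t_hist = np.asarray(t_hist)
    arrs = dict(crystal_vm_avg=np.asarray(c_avg), crystal_vm_max=np.asarray(c_max),
                amorphous_vm_avg=np.asarray(a_avg), film_shear=np.asarray(f_shear))
    q = max(1, len(t_hist) // 4)
    steady = {k: float(v[-q:].mean()) for k, v in arrs.items()}
    prev = {k: float(v[-2 * q:-q].mean()) for k, v in arrs.items()}
    ok = all(abs(steady[k] - prev[k]) <= 5e-3 * max(abs(steady[k]), 1e-30) + 1e-30
             for k in ("film_shear",))
    return SliderResult(t_hist, arrs["crystal_vm_avg"], arrs["crystal_vm_max"],
                        arrs["amorphous_vm_avg"], arrs["film_shear"],
                        energies, steady, ok, dt)


def velocity_sweep(velocities, case: SliderCase | None = None,
                   crystal=None, amorphous=None, film=None) -> pd.DataFrame:
    """Run one case per velocity; table of steady stresses vs velocity."""
    case = case or SliderCase()
    rows = []
    for v in velocities:
        c = SliderCase(velocity=float(v), load_angle=case.load_angle,
                       plate_thickness=case.plate_thickness,
                       plate_width=case.plate_width, block_size=case.block_size,
                       element_size=case.element_size, duration=case.duration,
                       cfl_safety=case.cfl_safety, plate_base=case.plate_base)
        r = run_case(c, crystal, amorphous, film)
        rows.append({"velocity_m_per_s": float(v),
                     "crystal_vm_Pa": r.steady["crystal_vm_avg"],
                     "crystal_vm_max_Pa": r.steady["crystal_vm_max"],
                     "amorphous_vm_Pa": r.steady["amorphous_vm_avg"],
                     "film_shear_Pa": r.steady["film_shear"],
                     "steady_ok": r.steady_ok})
    return pd.DataFrame(rows)


DEFAULT_CRYSTAL = ElastoplasticCard()
DEFAULT_AMORPHOUS = ViscoelasticCard()
DEFAULT_FILM = FilmCard()
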