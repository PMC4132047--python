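"""Synthetic force-probe pulling traces.

Replaces the all-atom force-probe MD with an overdamped Langevin emulation of
the collective bundle coordinate: a harmonic spring moving at constant
velocity drags the amorphous bundles; the bundles respond with (i) water drag
``N_total * xi_w * u`` on all pulled residues, (ii) the bond-friction force of
the washboard model on the ``N`` residues in contact with the crystal, and
(iii) thermal noise satisfying fluctuation-dissipation at the instantaneous
differential friction.  Contact is constant while the bundles still cover the
crystal, then decays linearly to zero over ``detach_length`` as they slide
off, after which the trace ends - mirroring pulls that were stopped after the
amorphous phase detached.

The drift at each step solves the exact force balance
``xi_bg * u + N(x) * F_bond(u) = F_spring`` (Newton iteration on a tabulated
bond-force curve), so the emulator's steady-state force is the bond model's
prediction by physics, not by interpolation of the target quantity itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .bond_model import BondModelParams, force_velocity, preset
from .constants import (K_B, NM, PN, SPRING_K_PN_PER_NM, T_DEFAULT,
                        XI_WATER_PER_RESIDUE)

__all__ = ["PullProtocol", "GroundTruth", "PullTrace",
           "simulate_pull", "simulate_water_pull", "generate_dataset",
           "write_traces", "read_traces", "DEFAULT_VELOCITIES"]

#: pulling-velocity grid spanning the published 0.02-20 m/s range
DEFAULT_VELOCITIES = (0.02, 0.05, 0.2, 0.5, 2.0, 5.0, 20.0)

#: steady-contact plateau duration in units of the force-noise correlation
#: time xi/k; long enough that the smoothed peak is an unbiased plateau
#: estimate rather than an extreme-value statistic
PLATEAU_TAU_FACTOR = 400.0

TOTAL = "total"
WATER_ONLY = "water_only"


@dataclass(frozen=True)
class PullProtocol:
    """Loading protocol of one constant-velocity pull."""

    velocity: float                      # m/s
    spring_k: float = SPRING_K_PN_PER_NM  # pN/nm, per bundle spring
    n_springs: int = 7                   # one spring per amorphous bundle
    n_replicas: int = 4
    temperature: float = T_DEFAULT       # K
    dt: float | None = None              # s; None -> automatic stable choice
    seed: int = 0
    with_crystal: bool = True

    def validate(self) -> None:
        if self.velocity <= 0 or self.spring_k <= 0 or self.n_replicas < 1:
            raise ValueError(f"invalid pull protocol: {self}")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def k_eff_si(self) -> float:
        """Total spring stiffness of the bundle group, N/m."""
        return self.n_springs * self.spring_k * PN / NM


@dataclass(frozen=True)
class GroundTruth:
    """Generator truth: interface physics the extraction should recover."""

    bond_params: BondModelParams = field(default_factory=lambda: preset("interface"))
    xi_water_res: float = XI_WATER_PER_RESIDUE   # Ns/m per pulled residue
    N: int = 232                                  # contacting residues (composite)
    N_total: int = 1344                           # pulled residues (56 x 24)
    detach_length: float = 2.8                    # nm, contact decay window
    contact_plateau: float | None = None          # nm; None -> automatic

    def validate(self) -> None:
        self.bond_params.validate()
        if self.xi_water_res <= 0 or self.N < 0 or self.N_total < self.N:
            raise ValueError(f"invalid ground truth: {self}")
        if self.detach_length <= 0:
            raise ValueError("detach_length must be positive")


@dataclass
class PullTrace:
    """Recorded force-time trace of one replica at one velocity."""

    time: np.ndarray        # s
    spring_pos: np.ndarray  # nm
    bundle_pos: np.ndarray  # nm
    force: np.ndarray       # pN (spring force, as recorded in force-probe MD)
    velocity: float         # m/s
    replica: int
    kind: str               # "total" | "water_only"
    dt: float               # s, integration step
    detach_start_nm: float | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ps": self.time * 1e12,
            "spring_pos_nm": self.spring_pos,
            "bundle_pos_nm": self.bundle_pos,
            "force_pN": self.force,
        })


# ---------------------------------------------------------------------------
# numba kernel

@njit(cache=True)
def _interp_pos(xg, yg, x):
    """Linear interpolation with linear (viscous) extension below the grid."""
    if x <= xg[0]:
        return yg[0] * x / xg[0]
    if x >= xg[-1]:
        return yg[-1] + (yg[-1] - yg[-2]) / (xg[-1] - xg[-2]) * (x - xg[-1])
    j = np.searchsorted(xg, x) - 1
    w = (x - xg[j]) / (xg[j + 1] - xg[j])
    return yg[j] * (1.0 - w) + yg[j + 1] * w


@njit(cache=True)
def _solve_drift(Fa, xi_bg, Ncur, ug, Fb, dFb, xi_v0, u_init):
    """u >= 0 solving xi_bg*u + Ncur*F_bond(u) = Fa (monotone balance)."""
    if Fa <= 0.0:
        return 0.0
    u = u_init if u_init > 0.0 else Fa / (xi_bg + Ncur * xi_v0)
    for _ in range(8):
        B = _interp_pos(ug, Fb, u)
        dB = _interp_pos(ug, dFb, u)
        r = xi_bg * u + Ncur * B - Fa
        step = r / (xi_bg + Ncur * dB)
        u_new = u - step
        if u_new <= 0.0:
            u_new = 0.5 * u
        if abs(u_new - u) <= 1e-12 * (u + 1e-30):
            u = u_new
            break
        u = u_new
    r = xi_bg * u + Ncur * _interp_pos(ug, Fb, u) - Fa
    if abs(r) > 1e-6 * Fa:
        lo, hi = 0.0, Fa / xi_bg
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if xi_bg * mid + Ncur * _interp_pos(ug, Fb, mid) > Fa:
                hi = mid
            else:
                lo = mid
        u = 0.5 * (lo + hi)
    return u


@njit(cache=True)
def _contact(x, N0, detach_at, detach_len):
    if x < detach_at:
        return N0
    frac = 1.0 - (x - detach_at) / detach_len
    return N0 * frac if frac > 0.0 else 0.0


@njit(cache=True)
def _pull_kernel(n_max, dt, V, k, xi_bg, N0, plateau_len, detach_len, kT,
                 ug, Fb, dFb, xi_v0, noise, stride,
                 t_out, s_out, x_out, f_out, tail_steps, detach_at_fixed):
    """Integration of the bundle coordinate with small-signal thermal noise.

    The deterministic component ``x_det`` follows the exact quasi-static
    force balance; the stochastic component is linear response about it with
    the local differential friction ``xi_d`` (fluctuation-dissipation), so
    the ensemble-mean force equals the deterministic trajectory without
    thermal rectification of the nonlinear friction law.  Recording starts
    (and the contact countdown is armed, ``detach_at = x + plateau_len``)
    once the deterministic drift reaches 99.5% of the pull velocity;
    the equilibration ramp before that is discarded, as in trace
    post-processing of force-probe simulations.

    Returns (n_recorded, n_steps, x_final).
    """
    x_det = 0.0
    x = 0.0
    u_det = 0.0
    n_rec = 0
    tail = -1
    armed = False
    detach_at = detach_at_fixed if detach_at_fixed > 0.0 else 1e9
    for i in range(n_max):
        t = i * dt
        F_det = k * (V * t - x_det)
        N_det = _contact(x_det, N0, detach_at, detach_len)
        sgn = 1.0 if F_det >= 0.0 else -1.0
        u_det = _solve_drift(abs(F_det), xi_bg, N_det, ug, Fb, dFb, xi_v0, u_det)
        if not armed and u_det * sgn >= 0.995 * V:
            armed = True
            if detach_at_fixed <= 0.0:
                detach_at = x_det + plateau_len
        xi_d = xi_bg + N_det * _interp_pos(ug, dFb, u_det)
        if armed and (i % stride == 0) and n_rec < t_out.shape[0]:
            t_out[n_rec] = t
            s_out[n_rec] = V * t
            x_out[n_rec] = x
            f_out[n_rec] = k * (V * t - x)
            n_rec += 1
        # small-signal drift about the deterministic trajectory
        u = sgn * u_det + k * (x_det - x) / xi_d
        x += u * dt + np.sqrt(2.0 * kT * dt / xi_d) * noise[i]
        x_det += sgn * u_det * dt
        if armed:
            if N0 > 0.0:
                if _contact(x, N0, detach_at, detach_len) == 0.0 and tail < 0:
                    tail = i + tail_steps
                if tail >= 0 and i >= tail:
                    return n_rec, i, x
            elif x_det >= detach_at:
                return n_rec, i, x
    return n_rec, n_max, x


# ---------------------------------------------------------------------------

def _bond_tables(p: BondModelParams):
    ug = np.logspace(-8, 3, 700)
    Fb = np.asarray(force_velocity(ug, p)) * PN   # N per residue
    dFb = np.gradient(Fb, ug)
    xi_v0 = Fb[0] / ug[0]                         # viscous-limit slope
    return ug, Fb, dFb, xi_v0


def _auto_dt(protocol: PullProtocol, xi_min: float, xi_d_steady: float,
             a_nm: float) -> float:
    """Accuracy-driven step: resolve the steady-state force-noise correlation
    time xi_d/k (~30 steps), the washboard period at the drift speed, and
    stay well inside the explicit stability bound dt < 2 xi_min / k."""
    k = protocol.k_eff_si
    dt = 0.03 * xi_d_steady / k
    dt = min(dt, 0.05 * a_nm * NM / protocol.velocity, 0.3 * xi_min / k)
    return dt


def _run(protocol: PullProtocol, truth: GroundTruth, kind: str):
    protocol.validate()
    truth.validate()
    V = protocol.velocity
    k = protocol.k_eff_si
    kT = K_B * protocol.temperature
    xi_bg = truth.N_total * truth.xi_water_res
    N0 = float(truth.N) if kind == TOTAL else 0.0
    ug, Fb, dFb, xi_v0 = _bond_tables(truth.bond_params)
    a_nm = truth.bond_params.a

    xi_min = xi_bg + N0 * truth.bond_params.xi0   # free-draining floor
    # force-noise correlation time at the steady drift; the pre-detachment
    # plateau lasts several hundred of these so the smoothed peak estimates
    # the steady friction with negligible bias
    xi_d_steady = xi_bg + N0 * float(np.interp(V, ug, dFb))
    t_plateau = PLATEAU_TAU_FACTOR * xi_d_steady / k

    dt_stable = 2.0 * xi_min / k
    if protocol.dt is not None:
        if protocol.dt >= dt_stable:
            raise ValueError(
                f"dt={protocol.dt:g} s unstable for the spring relaxation; "
                f"need dt < 2*xi/k = {dt_stable:g} s")
        dt = protocol.dt
    else:
        dt = _auto_dt(protocol, xi_min, xi_d_steady, a_nm)

    dl = truth.detach_length * NM
    e_star = (xi_bg * V + N0 * float(np.interp(V, ug, Fb))) / k  # steady extension
    plateau_len = V * t_plateau              # m slid at full steady contact
    detach_at_fixed = (truth.contact_plateau * NM
                       if (kind == TOTAL and truth.contact_plateau is not None)
                       else 0.0)

    # recorded portion: plateau + detachment (+ short tail); the ramp to
    # steady is integrated but discarded
    t_ramp_est = 12.0 * e_star / V + 100.0 * xi_d_steady / k
    n_rec_steps = int((plateau_len + 2.0 * dl) / (V * dt)) + 1000
    n_max = int(t_ramp_est / dt) + 2 * n_rec_steps + 1000
    if n_max > 40_000_000:
        raise ValueError(f"trace too long ({n_max} steps); increase dt or velocity")
    stride = max(1, n_rec_steps // 4000)
    n_rec_max = n_rec_steps // stride + 64
    tail_steps = int(0.3 * dl / (V * dt)) + int(20.0 * xi_bg / (k * dt)) + 10

    traces = []
    ss = np.random.SeedSequence([protocol.seed, 1 if kind == TOTAL else 2])
    for rep, child in enumerate(ss.spawn(protocol.n_replicas)):
        rng = np.random.default_rng(child)
        noise = (rng.standard_normal(n_max) if protocol.temperature > 0
                 else np.zeros(n_max))
        t_out = np.empty(n_rec_max)
        s_out = np.empty(n_rec_max)
        x_out = np.empty(n_rec_max)
        f_out = np.empty(n_rec_max)
        n_rec, _, _ = _pull_kernel(
            n_max, dt, V, k, xi_bg, N0, plateau_len, dl, kT,
            ug, Fb, dFb, xi_v0, noise, stride,
            t_out, s_out, x_out, f_out, tail_steps, detach_at_fixed)
        traces.append(PullTrace(
            time=t_out[:n_rec].copy(),
            spring_pos=s_out[:n_rec] / NM,
            bundle_pos=x_out[:n_rec] / NM,
            force=f_out[:n_rec] / PN,
            velocity=V, replica=rep, kind=kind, dt=dt,
            detach_start_nm=None,
        ))
    return traces


def simulate_pull(protocol: PullProtocol, truth: GroundTruth) -> list[PullTrace]:
    """Pull the bundles across the crystal interface (``total`` friction)."""
    kind = TOTAL if protocol.with_crystal else WATER_ONLY
    return _run(protocol, truth, kind)


def simulate_water_pull(protocol: PullProtocol, truth: GroundTruth) -> list[PullTrace]:
    """Pull the same bundles through water only (no crystal contact)."""
    return _run(protocol, truth, WATER_ONLY)


def generate_dataset(velocities=DEFAULT_VELOCITIES,
                     protocol: PullProtocol | None = None,
                     truth: GroundTruth | None = None,
                     seed: int = 0) -> list[PullTrace]:
    """Full synthetic campaign: total and water-only pulls, ``n_replicas``
    each, per velocity; per-trace seeds derive deterministically from
    ``seed`` so the same master seed reproduces the dataset bit-exactly.
    """
    velocities = list(velocities)
    if any(v <= 0 or v > 100 for v in velocities):
        raise ValueError("velocities must lie in (0, 100] m/s")
    truth = truth or GroundTruth()
    base = protocol or PullProtocol(velocity=1.0)
    out: list[PullTrace] = []
    for iv, V in enumerate(velocities):
        sub = int(np.random.SeedSequence([seed, iv]).generate_state(1)[0] % (2**31))
        proto = PullProtocol(velocity=V, spring_k=base.spring_k,
                             n_springs=base.n_springs, n_replicas=base.n_replicas,
                             temperature=base.temperature, dt=base.dt, seed=sub)
        out.extend(_run(proto, truth, TOTAL))
        out.extend(_run(proto, truth, WATER_ONLY))
    return out


# ---------------------------------------------------------------------------
# CSV + manifest I/O (one CSV per trace)

def write_traces(traces: list[PullTrace], outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for tr in traces:
        name = f"v{tr.velocity:g}_r{tr.replica}_{tr.kind}.csv"
        tr.to_dataframe().to_csv(outdir / name, index=False, float_format="%.6g")
        manifest.append({"file": name, "velocity": tr.velocity,
                         "replica": tr.replica, "kind": tr.kind, "dt_s": tr.dt,
                         "detach_start_nm": tr.detach_start_nm})
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir / "manifest.json"


def read_traces(outdir) -> list[PullTrace]:
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    traces = []
    for meta in manifest:
        df = pd.read_csv(outdir / meta["file"])
        traces.append(PullTrace(
            time=df["time_ps"].to_numpy() * 1e-12,
            spring_pos=df["spring_pos_nm"].to_numpy(),
            bundle_pos=df["bundle_pos_nm"].to_numpy(),
            force=df["force_pN"].to_numpy(),
            velocity=float(meta["velocity"]), replica=int(meta["replica"]),
            kind=meta["kind"], dt=float(meta["dt_s"]),
            detach_start_nm=meta.get("detach_start_nm"),
        ))
    return traces
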