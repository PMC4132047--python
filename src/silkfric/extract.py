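"""Peak-force extraction and the per-velocity friction dataset.

Raw pulling traces become one row per velocity: mean and SEM of the smoothed
peak force over replicas for the total pull and for the water-only pull, the
amorphous-crystalline difference F_ac = F_total - F_water (SEMs combined in
quadrature), the per-residue force f_res = F_ac / N (the friction force is
taken as equally shared by all contacting residues), and, given a contact
area, the interface shear stress tau = F_ac / A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bond_model import regularize_sem
from .constants import NM, PN
from .synth import TOTAL, WATER_ONLY, PullTrace

__all__ = ["FrictionDataset", "peak_force", "aggregate", "fit_water_law",
           "to_stress"]


@dataclass
class FrictionDataset:
    """Per-velocity friction decomposition (forces in pN, stresses in MPa)."""

    velocities: np.ndarray
    f_total_pn: np.ndarray
    f_total_sem_pn: np.ndarray
    f_water_pn: np.ndarray
    f_water_sem_pn: np.ndarray
    f_ac_pn: np.ndarray
    f_ac_sem_pn: np.ndarray
    f_res_pn: np.ndarray
    f_res_sem_pn: np.ndarray
    n_replicas: int
    N: int                      # contacting residues
    N_total: int                # pulled residues
    area_nm2: float | None = None
    tau_mpa: np.ndarray | None = None
    eta_res: np.ndarray | None = None    # Ns/m^2, apparent per-residue viscosity

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "velocity_m_per_s": self.velocities,
            "F_total_pN": self.f_total_pn, "F_total_sem_pN": self.f_total_sem_pn,
            "F_water_pN": self.f_water_pn, "F_water_sem_pN": self.f_water_sem_pn,
            "F_ac_pN": self.f_ac_pn, "F_ac_sem_pN": self.f_ac_sem_pn,
            "f_res_pN": self.f_res_pn, "f_res_sem_pN": self.f_res_sem_pn,
        }
        if self.tau_mpa is not None:
            cols["tau_MPa"] = self.tau_mpa
        if self.eta_res is not None:
            cols["eta_res_Ns_per_m2"] = self.eta_res
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.attrs = {}
        with open(path, "w") as fh:
            fh.write(f"# n_replicas={self.n_replicas} N={self.N} "
                     f"N_total={self.N_total} area_nm2={self.area_nm2}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "FrictionDataset":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in header)
            df = pd.read_csv(fh)
        area = None if meta.get("area_nm2") in (None, "None") else float(meta["area_nm2"])
        return cls(
            df["velocity_m_per_s"].to_numpy(),
            df["F_total_pN"].to_numpy(), df["F_total_sem_pN"].to_numpy(),
            df["F_water_pN"].to_numpy(), df["F_water_sem_pN"].to_numpy(),
            df["F_ac_pN"].to_numpy(), df["F_ac_sem_pN"].to_numpy(),
            df["f_res_pN"].to_numpy(), df["f_res_sem_pN"].to_numpy(),
            int(meta["n_replicas"]), int(meta["N"]), int(meta["N_total"]),
            area,
            df["tau_MPa"].to_numpy() if "tau_MPa" in df else None,
            df["eta_res_Ns_per_m2"].to_numpy() if "eta_res_Ns_per_m2" in df else None,
        )


def _auto_window(f: np.ndarray, kind: str) -> int:
    """Default smoothing window, chosen to make the smoothed maximum an
    (essentially) unbiased plateau estimate rather than an extreme-value
    statistic of the thermal noise.

    Water-only traces are plateau throughout: the whole record is one window.
    Traces with a detachment drop use a window reaching from the start of the
    record to the detachment onset, located as the first crossing of a
    coarse running mean below the plateau level; any window shifted into the
    decay is then deterministically penalized, which pins the maximum.
    """
    if kind == WATER_ONLY or f.size < 20:
        return f.size
    w0 = max(3, f.size // 50)
    coarse = np.convolve(f, np.ones(w0) / w0, mode="valid")
    half = coarse[: max(1, coarse.size // 2)]
    level = float(np.median(half))
    sigma = float(half.std())
    thresh = level - max(5.0 * sigma, 0.02 * abs(level))
    below = np.nonzero(coarse < thresh)[0]
    if below.size == 0:
        return max(1, f.size // 2)
    return max(1, int(below[0]))


def peak_force(trace: PullTrace, smooth_window: float | None = None) -> float:
    """Maximum of the running-mean-smoothed force signal (pN).

    ``smooth_window`` is a time in seconds; ``None`` uses half the recorded
    span.  Traces are generated ramp + long steady plateau (+ detachment), so
    a half-span window makes the smoothed maximum an essentially unbiased
    estimate of the plateau force instead of an extreme-value statistic of
    the thermal noise.  The mean is taken over full windows only, so a
    constant signal returns exactly its value for any window.
    """
    f = np.asarray(trace.force, dtype=float)
    if f.size == 0:
        raise ValueError("empty trace")
    if smooth_window is None:
        w = _auto_window(f, trace.kind)
    else:
        sample_dt = float(np.median(np.diff(trace.time))) if f.size > 1 else 1.0
        w = int(round(smooth_window / sample_dt))
        if w > f.size:
            raise ValueError("trace shorter than the smoothing window")
        w = max(1, w)
    smoothed = np.convolve(f, np.ones(w) / w, mode="valid")
    return float(smoothed.max())


def aggregate(traces: list[PullTrace], N: int, N_total: int,
              smooth_window: float | None = None) -> FrictionDataset:
    """Group traces by velocity and kind; peak-force statistics per group.

    Requires >= 2 replicas per group and identical velocity grids for the
    total and water-only sets.
    """
    groups: dict[tuple[float, str], list[float]] = {}
    for tr in traces:
        groups.setdefault((tr.velocity, tr.kind), []).append(
            peak_force(tr, smooth_window))
    v_tot = sorted(v for v, k in groups if k == TOTAL)
    v_wat = sorted(v for v, k in groups if k == WATER_ONLY)
    if v_tot != v_wat:
        raise ValueError(f"mismatched velocity grids: total {v_tot} vs water {v_wat}")
    if not v_tot:
        raise ValueError("no traces to aggregate")

    def stats(kind):
        means, sems, ns = [], [], []
        for v in v_tot:
            peaks = np.asarray(groups[(v, kind)])
            if peaks.size < 2:
                raise ValueError(f"need >= 2 replicas at V={v} ({kind})")
            means.append(peaks.mean())
            sems.append(peaks.std(ddof=1) / np.sqrt(peaks.size))
            ns.append(peaks.size)
        return np.asarray(means), np.asarray(sems), min(ns)

    f_tot, s_tot, n_rep = stats(TOTAL)
    f_wat, s_wat, _ = stats(WATER_ONLY)
    f_ac = f_tot - f_wat
    s_ac = np.hypot(s_tot, s_wat)       # difference SEMs in quadrature
    f_res = f_ac / N
    s_res = s_ac / N
    return FrictionDataset(np.asarray(v_tot, dtype=float),
                           f_tot, s_tot, f_wat, s_wat, f_ac, s_ac,
                           f_res, s_res, n_rep, N, N_total)


def fit_water_law(ds: FrictionDataset):
    """Per-residue water friction coefficient from F_w = N_total xi_w V.

    Zero-intercept weighted least squares (weights 1/SEM^2; unweighted if any
    SEM is zero, e.g. noiseless data).  Returns ``(xi_w, se)`` in Ns/m.
    """
    if len(ds.velocities) < 3:
        raise ValueError("need >= 3 velocities for the water-law fit")
    x = ds.N_total * ds.velocities            # residue-velocity, m/s
    y = ds.f_water_pn * PN                    # N
    sem = regularize_sem(y, ds.f_water_sem_pn * PN)
    w = np.ones_like(x) if np.any(sem <= 0) else 1.0 / sem**2
    sxx = float(np.sum(w * x * x))
    if sxx == 0.0:
        raise ValueError("singular design: all velocities zero")
    slope = float(np.sum(w * x * y)) / sxx
    dof = max(1, len(x) - 1)
    if np.any(sem <= 0):
        resid = y - slope * x
        se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    else:
        # scale-factor convention: few-replica SEMs are themselves noisy, so
        # inflate the naive WLS error when the fit scatters more than the
        # stated uncertainties
        chi2 = float(np.sum(w * (y - slope * x) ** 2))
        se = float(np.sqrt(1.0 / sxx)) * max(1.0, np.sqrt(chi2 / dof))
    return slope, se


def to_stress(ds: FrictionDataset, area_nm2: float,
              d_shear_nm: float = 0.5) -> FrictionDataset:
    """Attach interface shear stress and apparent per-residue viscosity.

    tau = F_ac / A (pN/nm^2 = MPa); eta_res(V) = (f_res/V) * d_shear/A_res
    with A_res = A/N and a configurable shear-gap d_shear (nm).
    """
    if area_nm2 <= 0:
        raise ValueError("contact area must be positive")
    ds.area_nm2 = float(area_nm2)
    ds.tau_mpa = ds.f_ac_pn / area_nm2
    a_res_m2 = (area_nm2 / ds.N) * NM * NM
    ds.eta_res = (ds.f_res_pn * PN / ds.velocities) * (d_shear_nm * NM) / a_res_m2
    return ds
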