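"""Solvent-accessible surface areas and the amorphous-crystalline contact area.

SASA is computed with the Shrake-Rupley rolling-probe algorithm on a
deterministic golden-spiral (Fibonacci) point set, so results are bit-exact
reproducible for a fixed point count.  The interface (resistance) area
follows the inclusion-exclusion rule

    A = (SASA_amorphous + SASA_crystalline - SASA_combined) / 2

and a residue counts as "in contact" when the area it buries against the
other body exceeds a threshold (default 0.01 nm^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import PROBE_RADIUS
from .structures import Structure

__all__ = ["SasaResult", "ContactResult", "fibonacci_sphere", "shrake_rupley",
           "contact_area", "contact_area_frames"]


@dataclass
class SasaResult:
    per_atom_area: np.ndarray     # nm^2
    total_area: float             # nm^2
    probe_radius: float           # nm
    n_sphere_points: int

    def per_residue(self, s: Structure) -> dict[tuple[str, int], float]:
        """Aggregate per-atom areas to (chain_label, residue_index) keys."""
        out: dict[tuple[str, int], float] = {}
        for area, lab, idx in zip(self.per_atom_area,
                                  s.chain_labels.tolist(),
                                  s.residue_index.tolist()):
            key = (str(lab), int(idx))
            out[key] = out.get(key, 0.0) + float(area)
        return out


@dataclass
class ContactResult:
    area_contact: float                              # nm^2, symbol A
    n_contact_residues: int                          # symbol N
    buried_per_residue: dict[tuple[str, int], float]  # nm^2, both bodies
    threshold: float                                 # nm^2


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform points on the unit sphere (golden-spiral lattice).

    Deterministic: no RNG is involved anywhere in the SASA computation.
    """
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i          # golden angle increments
    cos_theta = 1.0 - 2.0 * i / n
    sin_theta = np.sqrt(np.maximum(0.0, 1.0 - cos_theta**2))
    return np.column_stack((np.cos(phi) * sin_theta,
                            np.sin(phi) * sin_theta,
                            cos_theta))


def shrake_rupley(s: Structure, probe: float = PROBE_RADIUS,
                  n_points: int = 960) -> SasaResult:
    """Per-atom solvent-accessible area by sphere-point sampling.

    A point on atom i's expanded sphere (radius r_i + probe) is accessible if
    it lies strictly outside every neighbour's expanded sphere; exactly
    coincident equal-radius atoms therefore occlude each other (zero area),
    so a body duplicated in place is completely buried.
    """
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    n = s.n_atoms
    if n == 0:
        return SasaResult(np.zeros(0), 0.0, probe, n_points)
    pts = fibonacci_sphere(n_points)
    centers = s.coords
    radii = s.radii + probe
    tree = cKDTree(centers)
    rmax = radii.max()
    neighbours = tree.query_ball_tree(tree, 2.0 * rmax)
    areas = np.empty(n)
    for i in range(n):
        ri = radii[i]
        nb = [j for j in neighbours[i] if j != i]
        if nb:
            cj = centers[nb]
            rj = radii[np.asarray(nb)]
            close = np.linalg.norm(cj - centers[i], axis=1) < ri + rj
            cj, rj = cj[close], rj[close]
        else:
            cj = np.empty((0, 3))
            rj = np.empty(0)
        if len(cj) == 0:
            areas[i] = 4.0 * np.pi * ri * ri
            continue
        test = centers[i] + ri * pts                       # (P, 3)
        d2 = ((test[:, None, :] - cj[None, :, :]) ** 2).sum(axis=2)
        # strictly outside every neighbour: exactly coincident equal-radius
        # atoms occlude each other (complete burial), rather than sharing
        accessible = np.all(d2 > (rj * rj)[None, :] * (1.0 + 1e-12), axis=1)
        areas[i] = 4.0 * np.pi * ri * ri * accessible.mean()
    return SasaResult(areas, float(areas.sum()), probe, n_points)


def contact_area(body_a: Structure, body_b: Structure,
                 probe: float = PROBE_RADIUS, n_points: int = 960,
                 threshold: float = 0.01) -> ContactResult:
    """Interface area and contacting-residue count between two bodies.

    Symmetric in its two arguments.  ``N`` counts residues of either body
    whose buried area (isolated SASA minus in-complex SASA) exceeds
    ``threshold`` (nm^2).  Empty bodies give A = 0, N = 0.
    """
    if body_a.n_atoms == 0 or body_b.n_atoms == 0:
        return ContactResult(0.0, 0, {}, threshold)
    sasa_a = shrake_rupley(body_a, probe, n_points)
    sasa_b = shrake_rupley(body_b, probe, n_points)
    combined = Structure.concat([body_a, body_b])
    sasa_ab = shrake_rupley(combined, probe, n_points)
    area = 0.5 * (sasa_a.total_area + sasa_b.total_area - sasa_ab.total_area)

    iso = sasa_a.per_residue(body_a)
    iso.update(sasa_b.per_residue(body_b))
    in_complex = sasa_ab.per_residue(combined)
    buried = {k: iso[k] - in_complex.get(k, 0.0) for k in iso}
    n_contact = sum(1 for v in buried.values() if v > threshold)
    return ContactResult(float(area), int(n_contact), buried, threshold)


def contact_area_frames(frames, probe: float = PROBE_RADIUS,
                        n_points: int = 960, threshold: float = 0.01):
    """Mean and SD of (A, N) over a list of ``(body_a, body_b)`` frames."""
    results = [contact_area(a, b, probe, n_points, threshold) for a, b in frames]
    areas = np.array([r.area_contact for r in results])
    counts = np.array([r.n_contact_residues for r in results], dtype=float)
    return {
        "area_mean": float(areas.mean()), "area_sd": float(areas.std(ddof=0)),
        "n_mean": float(counts.mean()), "n_sd": float(counts.std(ddof=0)),
        "frames": results,
    }
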