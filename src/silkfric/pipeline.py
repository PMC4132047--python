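"""End-to-end pipeline: build -> contact -> synth -> extract -> fit -> slide.

Every stage writes a plain artifact (PDB/CSV/JSON) so it can be re-run in
isolation; a final Markdown report collects the numbers.  The master seed
deterministically derives every per-stage seed, so identical config + seed
reproduce identical CSV/JSON artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bond_model, extract, sasa, slider, structures, synth

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_all"]


class ConfigError(ValueError):
    """Invalid run configuration; message lists every violation."""


@dataclass
class RunConfig:
    seed: int
    outdir: str = "silkfric_out"
    builder: structures.BuilderSpec = field(default_factory=structures.BuilderSpec)
    probe_radius: float = 0.14          # nm
    sasa_points: int = 960
    contact_threshold: float = 0.01     # nm^2 buried area per residue
    velocities: tuple = synth.DEFAULT_VELOCITIES
    protocol: synth.PullProtocol = field(
        default_factory=lambda: synth.PullProtocol(velocity=1.0))
    truth: synth.GroundTruth = field(default_factory=synth.GroundTruth)
    smooth_window: float | None = None  # s; None -> plateau-scaled default
    fit_modes: tuple = ("fix_Ubond", "fix_ma")
    d_shear: float | None = None        # nm; None -> fitted lattice constant
    slider_velocities: tuple = (0.01, 0.1, 1.0, 5.0)
    slider_duration: float = 0.2e-9     # s
    crystal_card: slider.ElastoplasticCard = field(
        default_factory=lambda: slider.DEFAULT_CRYSTAL)
    amorphous_card: slider.ViscoelasticCard = field(
        default_factory=lambda: slider.DEFAULT_AMORPHOUS)
    film_card: slider.FilmCard = field(default_factory=lambda: slider.DEFAULT_FILM)


_SECTIONS = {
    "seed", "outdir", "builder", "probe_radius", "sasa_points",
    "contact_threshold", "velocities", "protocol", "truth", "smooth_window",
    "fit_modes", "d_shear", "slider_velocities", "slider_duration",
    "crystal_card", "amorphous_card", "film_card",
}


def _build_dataclass(cls, data, errors, path):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in data.items():
        if key not in fields:
            errors.append(f"{path}: unknown key {key!r}")
            continue
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{path}: {exc}")
        return cls()


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are errors (no silent defaults for misspellings); every
    violation is collected and reported at once.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    for key in raw:
        if key not in _SECTIONS:
            errors.append(f"unknown key {key!r}")
    if "seed" not in raw:
        errors.append("missing required key 'seed'")

    cfg = RunConfig(seed=int(raw.get("seed", 0)))
    if "outdir" in raw:
        cfg.outdir = str(raw["outdir"])
    if "builder" in raw:
        cfg.builder = _build_dataclass(structures.BuilderSpec, raw["builder"],
                                       errors, "builder")
    for scalar in ("probe_radius", "sasa_points", "contact_threshold",
                   "smooth_window", "d_shear", "slider_duration"):
        if scalar in raw:
            setattr(cfg, scalar, raw[scalar])
    for tup in ("velocities", "fit_modes", "slider_velocities"):
        if tup in raw:
            setattr(cfg, tup, tuple(raw[tup]))
    if "protocol" in raw:
        cfg.protocol = _build_dataclass(synth.PullProtocol,
                                        {"velocity": 1.0, **raw["protocol"]},
                                        errors, "protocol")
    if "truth" in raw:
        tr = dict(raw["truth"])
        bp = tr.pop("bond_params", None)
        if isinstance(bp, str):
            tr["bond_params"] = bond_model.preset(bp)
        elif isinstance(bp, dict):
            tr["bond_params"] = _build_dataclass(bond_model.BondModelParams,
                                                 bp, errors, "truth.bond_params")
        cfg.truth = _build_dataclass(synth.GroundTruth, tr, errors, "truth")
    for card, cls in (("crystal_card", slider.ElastoplasticCard),
                      ("amorphous_card", slider.ViscoelasticCard),
                      ("film_card", slider.FilmCard)):
        if card in raw:
            setattr(cfg, card, _build_dataclass(cls, raw[card], errors, card))

    # value checks
    try:
        cfg.builder.validate()
    except Exception as exc:
        errors.append(f"builder: {exc}")
    if cfg.probe_radius < 0:
        errors.append("probe_radius must be >= 0")
    if cfg.sasa_points < 32:
        errors.append("sasa_points must be >= 32")
    for name in ("truth", "protocol"):
        try:
            getattr(cfg, name).validate()
        except Exception as exc:
            errors.append(f"{name}: {exc}")
    for card in ("crystal_card", "amorphous_card", "film_card"):
        try:
            getattr(cfg, card).validate()
        except Exception as exc:
            errors.append(f"{card}: {exc}")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % (2**31))


def run_all(cfg: RunConfig, make_plots: bool = True) -> dict:
    """Execute every stage; returns the report dictionary.

    Artifacts: composite.pdb, contact.json, traces/, friction_dataset.csv,
    fit_report.json, slider_sweep.csv, report.md (plus optional PNG figures).
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "artifacts": {}}

    def done(name, path):
        report["artifacts"][name] = {"path": str(path), "sha256": _sha256(Path(path))}

    # 1. structure
    try:
        comp = structures.assemble_composite(cfg.builder)
    except Exception as exc:
        raise RuntimeError(f"stage 'build' failed: {exc}") from exc
    pdb_path = out / "composite.pdb"
    structures.write_pdb(comp, pdb_path)
    done("composite", pdb_path)
    report["n_chains_crystalline"] = comp.select_phase("crystalline").n_chains
    report["n_chains_amorphous"] = comp.select_phase("amorphous").n_chains

    # 2. contact area
    amo = comp.select_phase("amorphous")
    cry = comp.select_phase("crystalline")
    try:
        contact = sasa.contact_area(amo, cry, cfg.probe_radius, cfg.sasa_points,
                                    cfg.contact_threshold)
    except Exception as exc:
        raise RuntimeError(f"stage 'contact' failed: {exc}") from exc
    contact_path = out / "contact.json"
    with open(contact_path, "w") as fh:
        json.dump({"area_nm2": contact.area_contact,
                   "n_contact_residues": contact.n_contact_residues,
                   "threshold_nm2": contact.threshold,
                   "probe_nm": cfg.probe_radius,
                   "n_sphere_points": cfg.sasa_points}, fh, indent=1)
    done("contact", contact_path)
    report["contact_area_nm2"] = contact.area_contact
    report["n_contact_residues"] = contact.n_contact_residues

    # 3. synthetic pulls; contact geometry feeds the ground truth
    n_total = amo.n_residues
    truth = dataclasses.replace(cfg.truth, N=contact.n_contact_residues,
                                N_total=n_total)
    try:
        traces = synth.generate_dataset(cfg.velocities, cfg.protocol, truth,
                                        seed=_stage_seed(cfg.seed, 3))
    except Exception as exc:
        raise RuntimeError(f"stage 'synth' failed: {exc}") from exc
    synth.write_traces(traces, out / "traces")
    done("traces_manifest", out / "traces" / "manifest.json")

    # 4. extraction
    try:
        ds = extract.aggregate(traces, truth.N, truth.N_total, cfg.smooth_window)
        xi_w, xi_se = extract.fit_water_law(ds)
        ds = extract.to_stress(ds, contact.area_contact,
                               cfg.d_shear or cfg.truth.bond_params.a)
    except Exception as exc:
        raise RuntimeError(f"stage 'extract' failed: {exc}") from exc
    ds_path = out / "friction_dataset.csv"
    ds.to_csv(ds_path)
    done("friction_dataset", ds_path)
    report["xi_water_Ns_per_m"] = xi_w
    report["xi_water_se"] = xi_se

    # 5. bond-model fits
    fits = {}
    for mode in cfg.fit_modes:
        try:
            fr = bond_model.fit(ds, mode, init=cfg.truth.bond_params,
                                d_shear_nm=cfg.d_shear)
        except Exception as exc:
            raise RuntimeError(f"stage 'fit' ({mode}) failed: {exc}") from exc
        fits[mode] = {
            "ma_nm": fr.ma, "U_bond_kT": fr.params.U_bond, "chi2": fr.chi2,
            "errors": {k: list(v) for k, v in fr.param_errors.items()},
            "eta_res_Ns_per_m2": fr.eta_viscous_res,
            "eta_interface_Ns_per_m2": fr.eta_interface,
            "xi_visc_res_Ns_per_m": bond_model.viscous_limit(fr.params),
        }
    fit_path = out / "fit_report.json"
    with open(fit_path, "w") as fh:
        json.dump(fits, fh, indent=1)
    done("fit_report", fit_path)
    report["fits"] = fits

    # 6. slider sweeps (horizontal + 10 deg inclined)
    sweeps = []
    for angle, tp in ((0.0, 0.5), (10.0, 2.85)):
        case = slider.SliderCase(load_angle=angle, plate_thickness=tp,
                                 duration=cfg.slider_duration)
        try:
            df = slider.velocity_sweep(cfg.slider_velocities, case,
                                       cfg.crystal_card, cfg.amorphous_card,
                                       cfg.film_card)
        except Exception as exc:
            raise RuntimeError(f"stage 'slide' (angle={angle}) failed: {exc}") from exc
        df.insert(0, "load_angle_deg", angle)
        sweeps.append(df)
    sweep = pd.concat(sweeps)
    sweep_path = out / "slider_sweep.csv"
    sweep.to_csv(sweep_path, index=False, float_format="%.6g")
    done("slider_sweep", sweep_path)

    if make_plots:
        _plots(out, ds, fits, sweep, cfg)

    # 7. report
    lines = [
        "# silkfric pipeline report", "",
        f"- master seed: {cfg.seed}",
        f"- crystalline / amorphous chains: {report['n_chains_crystalline']} / "
        f"{report['n_chains_amorphous']}",
        f"- contact area A = {contact.area_contact:.2f} nm^2, contacting residues "
        f"N = {contact.n_contact_residues}",
        f"- water friction per residue: xi_w = {xi_w:.3e} +- {xi_se:.1e} Ns/m", "",
        "## Friction dataset", "", ds.to_dataframe().to_markdown(index=False), "",
        "## Bond-model fits", "",
    ]
    for mode, f in fits.items():
        lines.append(f"- **{mode}**: ma = {f['ma_nm']:.3f} nm, U_bond = "
                     f"{f['U_bond_kT']:.2f} kT, chi2 = {f['chi2']:.1f}, "
                     f"eta_interface = {f['eta_interface_Ns_per_m2']:.3g} Ns/m^2")
    lines += ["", "## Slider sweep", "", sweep.to_markdown(index=False), "",
              "## Artifacts", ""]
    for name, meta in report["artifacts"].items():
        lines.append(f"- {name}: `{meta['path']}` sha256:{meta['sha256']}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
    report["report_path"] = str(out / "report.md")
    return report


def _plots(out, ds, fits, sweep, cfg):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # friction decomposition vs velocity
    fig, ax = plt.subplots(figsize=(5, 4))
    for col, sem, lab, color in (
            ("f_total_pn", "f_total_sem_pn", "total", "tab:red"),
            ("f_water_pn", "f_water_sem_pn", "water", "tab:green"),
            ("f_ac_pn", "f_ac_sem_pn", "amorphous-crystalline", "k")):
        ax.errorbar(ds.velocities, getattr(ds, col) / ds.N,
                    yerr=getattr(ds, sem) / ds.N, marker="o", label=lab,
                    color=color, lw=1)
    ax.set_xscale("log"); ax.set_yscale("log")
    ax.set_xlabel("pulling velocity V (m/s)")
    ax.set_ylabel("friction force per residue (pN)")
    ax.legend(); fig.tight_layout()
    fig.savefig(out / "friction_vs_velocity.png", dpi=150); plt.close(fig)

    # apparent per-residue viscosity vs shear stress with fit curves
    if ds.tau_mpa is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(ds.tau_mpa, ds.eta_res, "ko", label="extracted")
        for mode, f in fits.items():
            p = bond_model.BondModelParams(
                a=f["ma_nm"], m=1.0, U_bond=f["U_bond_kT"],
                xi0=cfg.truth.bond_params.xi0)
            v = np.logspace(np.log10(ds.velocities.min()) - 3,
                            np.log10(ds.velocities.max()), 80)
            fr = np.asarray(bond_model.force_velocity(v, p))
            tau = fr * ds.N / ds.area_nm2
            a_res = (ds.area_nm2 / ds.N) * 1e-18
            eta = fr * 1e-12 / v * ((cfg.d_shear or p.a) * 1e-9) / a_res
            ax.plot(tau, eta, label=f"fit {mode}")
        ax.set_xscale("log"); ax.set_yscale("log")
        ax.set_xlabel("shear stress tau (MPa)")
        ax.set_ylabel("per-residue viscosity (Ns/m^2)")
        ax.legend(); fig.tight_layout()
        fig.savefig(out / "viscosity_vs_stress.png", dpi=150); plt.close(fig)

    # slider stresses vs velocity
    fig, ax = plt.subplots(figsize=(5, 4))
    for angle, grp in sweep.groupby("load_angle_deg"):
        for col, style in (("crystal_vm_Pa", "-o"), ("amorphous_vm_Pa", "-s"),
                           ("film_shear_Pa", "-^")):
            ax.plot(grp["velocity_m_per_s"], grp[col] / 1e6, style,
                    label=f"{col.split('_')[0]} {angle:g} deg")
    ax.set_xscale("log"); ax.set_yscale("log")
    ax.set_xlabel("relative velocity (m/s)"); ax.set_ylabel("stress (MPa)")
    ax.legend(fontsize=7); fig.tight_layout()
    fig.savefig(out / "slider_stress_vs_velocity.png", dpi=150); plt.close(fig)
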