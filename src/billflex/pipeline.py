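"""End-to-end orchestration: simulate -> align -> variance -> ANOVA ->
rigidity -> axis alignment -> fluid report.

Each stage reads/writes plain-text artifacts (TPS, CSV, TIFF stacks) and
stamps every CSV with the configuration hash and seed so deterministic
stages re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fluidics, io, morphometry, rigidity, shapestats, synthetic

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "billflex_out",
    "subject": "synthetic",
    "kinematics": {
        "n_cycles": 10,
        "n_perm": 999,
        "slide": False,
        "scenario": {
            "hinge_positions": [0.65],
            "tip_deflections_mm": [0.5],
            "mode": "distal_rotation",
            "tracking_noise_sd": 0.02,
            "mandible_motion": 0.0,
        },
        "template": {
            "exposed_culmen_length": 18.0,
            "total_culmen_length": 20.0,
            "keratin_tip_length": 1.2,
        },
    },
    "rigidity": {
        "phantom": {
            "waist_fraction": 0.65,
            "outer_radius": 0.8,
            "waist_depth": 0.45,
            "n_slices": 60,
            "pixel_size": 0.02,
        },
        "calibration_densities": [200.0, 400.0, 800.0, 1200.0],
        "smooth_frac": 0.02,
        "roi": "section",
    },
    "fluid": {
        "mu": 1.7e-3,
        "R0": 0.25,
        "h": 0.32,
        "U_max": 60.0,
        "L": 10.0,
        "frequency": 15.0,
        "source_volume": 0.0,
        "n_steps": 400,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _stamp(path: Path, df: pd.DataFrame, cfg: dict) -> None:
    header = f"# billflex config={config_hash(cfg)} seed={cfg['seed']}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def _template_from(cfg: dict) -> synthetic.BillTemplate:
    return synthetic.default_template(**cfg["kinematics"]["template"])


def _scenario_from(cfg: dict) -> synthetic.BendingScenario:
    sc = dict(cfg["kinematics"]["scenario"])
    sc["hinge_positions"] = tuple(sc.get("hinge_positions", (0.65,)))
    sc["tip_deflections_mm"] = tuple(sc.get("tip_deflections_mm", (0.5,)))
    return synthetic.BendingScenario(seed=cfg["seed"], **sc)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: dict) -> dict:
    """Generate the synthetic study inputs: landmarks, phantom, calibration."""
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    template = _template_from(cfg)
    scenario = _scenario_from(cfg)
    frames = synthetic.generate_lick_dataset(
        template, scenario, cfg["kinematics"]["n_cycles"],
        subject_id=cfg["subject"],
    )
    io.write_tps(out / "landmarks.tps", frames)
    io.write_landmarks_csv(out / "landmarks.csv", frames)

    rcfg = cfg["rigidity"]
    spec = synthetic.waisted_annulus_spec(
        length_mm=template.total_culmen_length - template.keratin_tip_length,
        **rcfg["phantom"],
    )
    stack = synthetic.generate_beam_stack(spec)
    io.write_stack_tiff(out / "phantom_stack.tiff", stack.gray)
    io.write_mask_tiff(out / "phantom_mask_section.tiff",
                       stack.masks["section"])
    _stamp(out / "phantom_analytic_ei.csv",
           pd.DataFrame({"slice_index": np.arange(stack.z_mm.size),
                         "z_mm": stack.z_mm, "EI": stack.analytic_ei}), cfg)
    cal_table = synthetic.generate_phantom_calibration(
        rcfg["calibration_densities"],
        gray_slope=stack.gray_slope, gray_intercept=stack.gray_intercept,
        seed=cfg["seed"],
    )
    _stamp(out / "phantom_calibration.csv", cal_table, cfg)
    return {"frames": frames, "stack": stack, "calibration": cal_table,
            "template": template, "scenario": scenario}


def run_kinematics(cfg: dict, frames=None) -> dict:
    """GPA alignment, variance profile, PCA trajectory and Procrustes ANOVA."""
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    if frames is None:
        csv_path = out / "landmarks.csv"
        tps_path = out / "landmarks.tps"
        if csv_path.exists():
            frames = io.read_landmarks_csv(csv_path)
        elif tps_path.exists():
            frames = io.read_tps(tps_path)
        else:
            raise FileNotFoundError("no landmark file found; run simulate first")
    cycles = np.array([f.cycle_id for f in frames])
    frame_idx = np.array([f.frame_index for f in frames])
    if np.unique(cycles).size < 2:
        raise ValueError("kinematics needs >= 2 lick cycles")

    result = morphometry.gpa_align(frames)
    variance = morphometry.landmark_variance_profile(result, cycles)

    var_rows = []
    for name, sl in morphometry.LINE_SLICES.items():
        for j, k in enumerate(range(sl.start, sl.stop), start=1):
            var_rows.append(
                {
                    "line": name,
                    "landmark_index": j,
                    "S2_mean": variance.mean_s2[k],
                    "S2_ci_low": (variance.ci_low[k]
                                  if variance.ci_low is not None else np.nan),
                    "S2_ci_high": (variance.ci_high[k]
                                   if variance.ci_high is not None else np.nan),
                    "n_cycles": variance.n_groups,
                }
            )
    _stamp(out / "variance_profile.csv", pd.DataFrame(var_rows), cfg)

    pca_input = result
    if cfg["kinematics"].get("slide", False):
        pca_input = morphometry.slide_semilandmarks(result)
    traj = morphometry.shape_pca(pca_input)
    n_axes = min(5, traj.scores.shape[1])
    pca_df = pd.DataFrame(
        traj.scores[:, :n_axes],
        columns=[f"PC{i + 1}" for i in range(n_axes)],
    )
    pca_df.insert(0, "frame", frame_idx)
    pca_df.insert(0, "cycle", cycles)
    _stamp(out / "pc_scores.csv", pca_df, cfg)
    _stamp(out / "pc_variance.csv",
           pd.DataFrame({"axis": np.arange(1, traj.eigenvalues.size + 1),
                         "eigenvalue": traj.eigenvalues,
                         "percent_variance": traj.percent_variance}), cfg)

    anova = shapestats.procrustes_anova(
        result,
        factors={"cycle": cycles, "frame": frame_idx},
        blocks=("cycle",),
        n_perm=cfg["kinematics"]["n_perm"],
        seed=cfg["seed"],
    )
    tab = anova.table.reset_index()
    tab["n_perm"] = anova.n_perm
    tab["seed"] = cfg["seed"]
    _stamp(out / "procrustes_anova.csv", tab, cfg)
    return {"gpa": result, "variance": variance, "pca": traj, "anova": anova}


def run_rigidity(cfg: dict, sim: dict | None = None,
                 variance: morphometry.LandmarkVarianceProfile | None = None,
                 ) -> dict:
    """Rigidity profile, region segmentation and kinematics juxtaposition."""
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    template = _template_from(cfg)
    if sim is not None:
        stack_img = sim["stack"].gray
        mask = sim["stack"].masks["section"]
        cal_table = sim["calibration"]
        spacing = sim["stack"].slice_spacing
        pixel_size = sim["stack"].pixel_size
    else:
        stack_path = out / "phantom_stack.tiff"
        if not stack_path.exists():
            raise FileNotFoundError("phantom stack missing; run simulate first")
        stack_img = io.read_stack_tiff(stack_path)
        mask = io.read_stack_tiff(out / "phantom_mask_section.tiff")
        cal_table = pd.read_csv(out / "phantom_calibration.csv", comment="#")
        rcfg = cfg["rigidity"]["phantom"]
        pixel_size = rcfg["pixel_size"]
        bony = template.total_culmen_length - template.keratin_tip_length
        spacing = bony / max(rcfg["n_slices"] - 1, 1)

    cal = rigidity.fit_gray_density(cal_table)
    profile = rigidity.stack_profile(
        stack_img, {"section": mask}, pixel_size, cal,
        slice_spacing=spacing,
    )
    seg = rigidity.segment_regions(profile,
                                   smooth_frac=cfg["rigidity"]["smooth_frac"])
    _stamp(out / "rigidity_profile.csv", profile.to_frame(), cfg)

    hypothesis = None
    if seg.defined:
        means = rigidity.region_means(profile, seg)
        hypothesis = bool(means[2] < min(means[1], means[3]))
    align = rigidity.AxisAlignment(
        keratin_tip_offset=template.keratin_tip_length,
        exposed_culmen_length=template.exposed_culmen_length,
        total_culmen_length=template.total_culmen_length,
        ct_bony_length=float(profile.z_mm[-1]) if profile.n_slices > 1 else None,
    )
    merged = rigidity.align_axes(profile, align, variance)
    _stamp(out / "rigidity_kinematics_merged.csv", merged, cfg)
    report = {
        "regions_defined": seg.defined,
        "bending_zone_has_lowest_mean_EI": hypothesis,
        "calibration_r_squared": cal.r_squared,
        "config": config_hash(cfg),
        "seed": cfg["seed"],
    }
    (out / "rigidity_report.json").write_text(json.dumps(report, indent=2))
    return {"profile": profile, "segmentation": seg, "merged": merged,
            "report": report, "alignment": align}


def run_fluid(cfg: dict) -> dict:
    """Per-phase transport report with Couette/Poiseuille decomposition."""
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    fcfg = cfg["fluid"]
    state = fluidics.AnnularFlowState(
        mu=fcfg["mu"], R0=fcfg["R0"], h=fcfg["h"], U=0.0, L=fcfg["L"],
        dpdz=0.0, lick_frequency=fcfg["frequency"],
    )
    period = 1.0 / fcfg["frequency"]
    u_max = fcfg["U_max"]

    def u_of_t(t: float) -> float:
        # retraction (U > 0) in the first half of the cycle, protrusion after
        return u_max * math.sin(2.0 * math.pi * t / period)

    source_volume = fcfg.get("source_volume", 0.0)

    def source_of_t(t: float) -> float:
        # wringing flux injected at the tip during the protrusion phase
        phase = t / period
        if phase <= 0.5 or source_volume == 0.0:
            return 0.0
        return source_volume / (period / 2.0) * math.sin(
            2.0 * math.pi * (phase - 0.5)
        ) * (math.pi / 2.0)

    report = fluidics.lick_cycle_transport(
        state, u_of_t, source_of_t=source_of_t, n_steps=fcfg["n_steps"],
        period=period,
    )
    df = pd.DataFrame(
        {"t_s": report.t, "U_mm_s": report.U, "Q_mm3_s": report.Q,
         "Q_shear": report.Q_shear, "Q_pressure": report.Q_pressure,
         "F": report.F}
    )
    _stamp(out / "fluid_timeseries.csv", df, cfg)
    summary = {
        "net_volume_mm3": report.net_volume,
        "shear_volume_mm3": report.shear_volume,
        "pressure_volume_mm3": report.pressure_volume,
        "retraction_volume_mm3": report.retraction_volume,
        "protrusion_volume_mm3": report.protrusion_volume,
        "work": report.work,
        "config": config_hash(cfg),
        "seed": cfg["seed"],
    }
    (out / "fluid_report.json").write_text(json.dumps(summary, indent=2))
    return {"report": report, "summary": summary}


def run_all(cfg: dict) -> dict:
    sim = run_simulate(cfg)
    kin = run_kinematics(cfg, frames=sim["frames"])
    rig = run_rigidity(cfg, sim=sim, variance=kin["variance"])
    flu = run_fluid(cfg)
    return {"simulate": sim, "kinematics": kin, "rigidity": rig, "fluid": flu}
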