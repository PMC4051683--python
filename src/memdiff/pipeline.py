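"""Stage orchestration: peaks → phase → density → diff → locate → inplane.

Each stage consumes the previous stage's products (in memory and on
disk), writes delimited-text outputs into the run's output directory,
and contributes to a single JSON summary.  Re-running with identical
inputs and seeds is byte-identical (timestamps only ever go to logs).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .composition import leaflet_electron_budget
from .config import RunConfig
from .decomposition import embedded_fraction, fit_components
from .density import DensityProfile, ScaleState, fourier_synthesis, \
    landmark_report, scale_to_absolute
from .lattice import area_per_lipid_hex, fit_lattice, plaque_intensity_change
from .peakfit import SQRT2PI, Axis, chain_peak, fit_bragg_series, \
    form_factor_magnitudes, lamellar_spacing
from .phasing import assign_signs
from .projection import fit_pose, load_atomic_model
from .peakfit import FormFactorSet

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("peaks", "phase", "density", "diff", "locate", "inplane")
logger = logging.getLogger("memdiff")


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.summary: dict = {"sample": config.name, "seed": config.seed,
                              "warnings": []}
        self.curves: list = []       # (curve, source)
        self.ffsets: list[FormFactorSet] = []
        self.profile: DensityProfile | None = None
        self.diff = None             # (z, delta)

    def warn_sink(self, caught):
        for w in caught:
            msg = str(w.message)
            self.summary["warnings"].append(msg)
            logger.warning(msg)


def _stage_peaks(run: _Run) -> None:
    cfg = run.config
    if "reflectivity" not in cfg.files:
        raise RuntimeError("stage peaks: files.reflectivity is required")
    paths = [cfg.files["reflectivity"]]
    paths += list(cfg.files.get("swelling", []) or [])
    rows, d_spacings = [], []
    for i, path in enumerate(paths):
        curve = mio.read_curve(path, Axis.OUT_OF_PLANE)
        # the configured d-hint applies to the primary curve only; swelling
        # states have different periods and are auto-estimated
        hint = cfg.options.d_hint if i == 0 else None
        peaks = fit_bragg_series(curve, d_hint=hint,
                                 max_order=cfg.options.max_order)
        if not peaks:
            raise RuntimeError(f"stage peaks: no Bragg peaks found in {path}")
        d = lamellar_spacing(peaks)
        d_spacings.append(d)
        ffs = form_factor_magnitudes(peaks, d, cfg.options.lorentz_exponent)
        run.ffsets.append(ffs)
        for p in peaks:
            rows.append({"label": f"{Path(path).name}:{p.order}",
                         "position": p.center, "width": p.sigma,
                         "amplitude": p.amplitude, "area": p.area})
    mio.write_peak_table(run.out / "bragg_peaks.tsv", pd.DataFrame(rows))
    run.summary["d_spacings"] = d_spacings
    run.summary["orders"] = [[int(n) for n in f.orders] for f in run.ffsets]


def _f0(run: _Run, d: float) -> float:
    comp = run.config.composition
    budget = leaflet_electron_budget(comp)
    return 2.0 * budget / comp.area_per_lipid - 0.333 * d


def _stage_phase(run: _Run) -> None:
    if not run.ffsets:
        raise RuntimeError("stage phase: missing upstream output of stage 'peaks'")
    cfg = run.config
    if len(run.ffsets) >= 2:
        run.ffsets, sv = assign_signs(run.ffsets,
                                      f0=_f0(run, run.ffsets[0].d_spacing))
        run.summary["sign_misfit"] = sv.misfit
        run.summary["sign_degenerate"] = sv.degenerate
    else:
        signs = cfg.options.signs
        if signs is None:
            raise RuntimeError(
                "stage phase: a single d-spacing cannot be phased by swelling; "
                "supply analysis.signs in the config")
        if len(signs) != len(run.ffsets[0].orders):
            raise RuntimeError("stage phase: analysis.signs length does not "
                               "match the number of observed orders")
        run.ffsets[0] = run.ffsets[0].with_signs(signs)
    run.summary["signs"] = [int(s) for s in run.ffsets[0].signs]


def _stage_density(run: _Run) -> None:
    if not run.ffsets or not run.ffsets[0].assigned:
        raise RuntimeError("stage density: missing upstream output of stage 'phase'")
    cfg = run.config
    comp = cfg.composition
    budget = leaflet_electron_budget(comp)
    rel = fourier_synthesis(run.ffsets[0], cfg.options.grid_points)
    prof = scale_to_absolute(rel, budget, comp.area_per_lipid,
                             cfg.options.center_density)
    run.profile = prof
    head_z, center, head_val = landmark_report(prof)
    run.summary["electron_budget"] = budget
    run.summary["head_peak_z"] = head_z
    run.summary["center_density"] = center
    mio.write_profile(run.out / "density_profile.tsv", prof.z, prof.rho, {
        "d_spacing": prof.d_spacing, "area_per_lipid": comp.area_per_lipid,
        "budget": budget, "center_density": cfg.options.center_density,
        "signs": " ".join(str(int(s)) for s in run.ffsets[0].signs),
        "scale": prof.scale_state.value,
    })


def _load_reference(run: _Run) -> DensityProfile:
    z, rho, meta = mio.read_profile(run.config.files["reference_profile"])
    return DensityProfile(float(meta.get("d_spacing", 2 * z.max())), z, rho,
                          ScaleState.ABSOLUTE)


def _stage_diff(run: _Run) -> None:
    if run.profile is None:
        raise RuntimeError("stage diff: missing upstream output of stage 'density'")
    if "reference_profile" not in run.config.files:
        raise RuntimeError("stage diff: files.reference_profile is required")
    from .decomposition import difference_profile

    ref = _load_reference(run)
    z, delta = difference_profile(run.profile, ref)
    run.diff = (z, delta)
    cfg = run.config
    model = fit_components(z, delta, cfg.options.k_components,
                           cfg.composition.area_per_lipid, seed=cfg.seed)
    rows = []
    fracs = model.fractions
    for i, c in enumerate(model.components):
        rows.append({"label": f"G{i+1}", "position": c.center, "width": c.sigma,
                     "amplitude": c.amplitude, "electrons": c.electrons,
                     "fraction": fracs[i]})
    mio.write_component_table(run.out / "components.tsv", pd.DataFrame(rows))
    np.savetxt(run.out / "difference_profile.tsv", np.column_stack([z, delta]),
               header="z delta_rho", fmt="%.10g")
    run.summary["components"] = rows
    run.summary["embedded_fraction"] = embedded_fraction(
        model, boundary_z=cfg.options.embedded_boundary)
    run.summary["component_rms"] = model.residual_rms


def _stage_locate(run: _Run) -> None:
    if run.diff is None:
        raise RuntimeError("stage locate: missing upstream output of stage 'diff'")
    if "pdb" not in run.config.files:
        raise RuntimeError("stage locate: files.pdb is required")
    cfg = run.config
    model = load_atomic_model(cfg.files["pdb"])
    z, delta = run.diff
    d = run.profile.d_spacing
    z_grid = np.arange(0.0, d / 2.0 + 1e-9, cfg.options.pose_z_step)
    angle_grid = np.arange(0.0, 360.0, cfg.options.pose_angle_step)
    pose, scale, score = fit_pose(model, z, delta, d, z_grid, angle_grid,
                                  fwhm=cfg.options.fwhm)
    run.summary["pose"] = {"z_shift": pose.z_shift, "angles": list(pose.angles),
                           "scale": scale, "score": score}
    (run.out / "pose.json").write_text(
        json.dumps(run.summary["pose"], indent=2, sort_keys=True) + "\n")


def _stage_inplane(run: _Run) -> None:
    cfg = run.config
    result: dict = {}
    if "inplane" in cfg.files:
        curve = mio.read_curve(cfg.files["inplane"], Axis.IN_PLANE)
        q_T, sigma, area = chain_peak(curve)
        a_T, A_L = area_per_lipid_hex(q_T)
        result.update({"chain_q": q_T, "chain_sigma": sigma, "chain_area": area,
                       "tail_spacing": a_T, "area_per_lipid": A_L})
    if "peak_table_before" in cfg.files and "peak_table_after" in cfg.files:
        before = mio.read_peak_table(cfg.files["peak_table_before"])
        after = mio.read_peak_table(cfg.files["peak_table_after"])
        mono, chain = plaque_intensity_change(before, after)
        result.update({"plaque_area_change_pct": mono,
                       "chain_area_change_pct": chain})
        obs = [(1, 1, float(before.loc[before.label == "[110]", "position"].iloc[0])),
               (2, 0, float(before.loc[before.label == "[200]", "position"].iloc[0]))]
        lat = fit_lattice(obs, fixed={"gamma": 103.0})
        result["lattice"] = {"a": lat.a, "b": lat.b, "gamma": lat.gamma}
    if not result:
        raise RuntimeError("stage inplane: needs files.inplane or peak tables")
    run.summary["inplane"] = result


_STAGE_FUNCS = {
    "peaks": _stage_peaks,
    "phase": _stage_phase,
    "density": _stage_density,
    "diff": _stage_diff,
    "locate": _stage_locate,
    "inplane": _stage_inplane,
}


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Execute the requested stages in dependency order; returns the summary.

    Outputs (peak tables, profiles, component tables, pose report and
    ``summary.json``) land in ``config.output_dir``.  Idempotent for
    identical inputs and seeds.
    """
    requested = [s for s in STAGES if s in set(stages)]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    run = _Run(config)
    for stage in requested:
        logger.info("running stage %s", stage)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _STAGE_FUNCS[stage](run)
        run.warn_sink(caught)
    (run.out / "summary.json").write_text(
        json.dumps(run.summary, indent=2, sort_keys=True, default=float) + "\n")
    return run.summary
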