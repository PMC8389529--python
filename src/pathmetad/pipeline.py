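"""End-to-end orchestration: guess path -> principal path -> equidistant
resampling -> path CVs -> (toy) WT-MetaD -> FES -> divider -> dG°_b.

Every stage persists its intermediate artifact (snapped frame list,
resampled path, PCV definition, HILLS/COLVAR, FES grid, dG_b(s*) curve,
final report), so a run can be resumed or re-analyzed from any stage; in
particular a run can start from externally produced HILLS/COLVAR files and
perform analysis only.

Biased sampling itself is available for the built-in toy systems; real
systems are expected to bring their own hills (produced by any standard
metadynamics engine writing the common plain-text dialect).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fixtures
from .free_energy import (BindingResult, V_STANDARD, convergence_window,
                          dg_bound_unbound, dg_time_series, dg_time_stats,
                          dg_vs_divider_curve, fes_from_hills, find_x_star,
                          pmf_along_s, volume_correction)
from .geometry import AtomSelection, path_features
from .io import read_path, write_path
from .metad_engine import (PathCV, WTMetaDParams, read_colvar, read_hills,
                           run_wtmetad, write_colvar, write_hills)
from .path_cv import lambda_from_spacing
from .path_equidistance import (equidistant_resample, geometric_propagator,
                                interframe_distances)
from .principal_path import PointsCloud, fit_principal_path, snap_to_samples
from .ses_volume import SESParams, collect_unbound_atoms, ses_volume


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run, with explicit units in the field names."""

    # input: either a built-in toy or a multi-model PDB/XYZ guess path
    toy: str | None = "funnel"
    input_path: str | None = None
    align_indices: list | None = None  # None -> no superposition (toy mode)
    measure_indices: list | None = None  # None -> all atoms
    # principal path
    n_waypoints: int = 10
    smoothness: float = 1.0
    # equidistant resampling
    resample_threshold_nm: float = 0.1
    # path CVs
    lambda_mode: str | float = "auto"  # "auto" -> spacing heuristic
    # WT-MetaD (toy engine); defaults are a desk-scale calibration sized to
    # the built-in toys (capacity estimate: bias volume to fill ~ visited CV
    # area x (gamma-1) kT ln(1/residual) / hill volume), not the production
    # host-guest protocol that WTMetaDParams itself defaults to
    metad: WTMetaDParams = field(default_factory=lambda: WTMetaDParams(
        initial_height=0.2, bias_factor=8.0, sigma=(0.75, 0.01), pace=250,
        wall_position=0.03, wall_constant=10000.0))
    n_steps: int = 2_000_000
    dt_ps: float = 0.002
    friction_per_ps: float = 5.0
    stride: int = 100
    seed: int = 0
    # analysis
    grid_ns: int = 200
    grid_nz: int = 50
    temperature: float = 300.0
    n_checkpoints: int = 12
    # standard-state correction
    v_bulk_mode: str = "fixed"  # "fixed" | "ses"
    v_bulk_a3: float = V_STANDARD
    ses: SESParams = field(default_factory=SESParams)
    # stage bypass: analysis-only from existing files
    hills_file: str | None = None
    colvar_file: str | None = None
    # output
    outdir: str | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def _save(outdir: Path | None, name: str, writer) -> None:
    if outdir is not None:
        writer(outdir / name)


def run_pipeline(config: PipelineConfig) -> BindingResult:
    """Execute the full workflow and return the binding result.

    Raises :class:`StageError` naming the failing stage; referenced input
    files are checked before any computation starts.
    """
    outdir = None
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            log.append({"stage": name,
                        "wall_s": round(time.perf_counter() - t0, 3), **info})
        return done

    # -- validation ---------------------------------------------------------
    for fname in (config.input_path, config.hills_file, config.colvar_file):
        if fname is not None and not Path(fname).exists():
            raise StageError("validate", f"missing input file: {fname}")
    if config.toy is None and config.input_path is None \
            and config.hills_file is None:
        raise StageError("validate", "no input: set toy, input_path or "
                                     "hills_file")

    # -- input path ---------------------------------------------------------
    done = stage("input")
    system = None
    if config.toy is not None:
        if config.toy != "funnel":
            raise StageError("input", f"unknown toy system {config.toy!r}")
        system = fixtures.funnel_system()
        path = fixtures.funnel_guess_path(seed=config.seed)
    elif config.input_path is not None:
        path = read_path(config.input_path)
    else:
        path = None
    done(n_frames=None if path is None else len(path))

    align = (AtomSelection(config.align_indices, role="align")
             if config.align_indices is not None else None)

    refs_feat = None
    n_refs = None
    hills = colvar = None

    if config.hills_file is not None:
        done = stage("load-hills")
        hills = read_hills(config.hills_file)
        if config.colvar_file is not None:
            colvar = read_colvar(config.colvar_file)
        n_refs = int(round(hills.centers[:, 0].max()))
        done(n_hills=len(hills))
    else:
        if path is None:
            raise StageError("path-find", "no conformations to build a path "
                                          "from")
        measure = (AtomSelection(config.measure_indices)
                   if config.measure_indices is not None
                   else AtomSelection.all_atoms(path[0].n_atoms))

        # -- principal path -------------------------------------------------
        done = stage("path-find")
        feats = path_features(path, path[0], align, measure)
        cloud = PointsCloud(samples=feats,
                            source_frame_ids=np.array(
                                [c.frame_id for c in path]))
        endpoints = np.vstack([feats[0], feats[-1]])
        model = fit_principal_path(cloud, endpoints, config.n_waypoints,
                                   config.smoothness)
        snapped_ids = snap_to_samples(model, cloud)
        by_id = {c.frame_id: c for c in path}
        snapped = [by_id[i] for i in snapped_ids]
        _save(outdir, "snapped_frames.txt", lambda p: Path(p).write_text(
            "\n".join(str(i) for i in snapped_ids) + "\n"))
        done(n_waypoints=config.n_waypoints, n_snapped=len(snapped),
             final_cost=model.cost_trace[-1])

        # -- equidistant resampling ------------------------------------------
        done = stage("resample")
        resampled, report = equidistant_resample(
            snapped, threshold=config.resample_threshold_nm,
            propagator=geometric_propagator, align=align, measure=measure)
        _save(outdir, "resampled_path.xyz",
              lambda p: write_path(resampled, p))
        _save(outdir, "resample_report.csv", lambda p: Path(p).write_text(
            "gap_index,original_nm,inserted\n" + "\n".join(
                f"{i},{report.original_gaps[i]:.6f},{report.inserted_per_gap[i]}"
                for i in range(len(report.original_gaps))) + "\n"))
        done(n_frames=len(resampled), inserted=report.total_inserted())

        # -- path CVs --------------------------------------------------------
        done = stage("pcv")
        gaps = interframe_distances(resampled, align, measure)
        if config.lambda_mode == "auto":
            lam = lambda_from_spacing(float(np.mean(gaps ** 2)))
        else:
            lam = float(config.lambda_mode)
        refs_feat = path_features(resampled, resampled[0], align, measure)
        n_refs = len(resampled)
        _save(outdir, "pcv_definition.yaml", lambda p: Path(p).write_text(
            yaml.safe_dump({"lambda_per_nm2": lam, "n_frames": n_refs,
                            "mean_gap_nm": float(gaps.mean()),
                            "rescaled": False,
                            "reference_path": "resampled_path.xyz"})))
        done(lam=lam, n_refs=n_refs)

        # -- WT-MetaD --------------------------------------------------------
        if system is None:
            raise StageError(
                "metad", "biased sampling needs a built-in toy system; for "
                         "real systems supply hills_file from an external "
                         "engine")
        done = stage("metad")
        cv = PathCV(refs_feat, lam, n_atoms=len(measure.indices),
                    rescaled=False)
        grid = ((0.5, n_refs + 0.5, max(200, 4 * n_refs)),
                (-0.04, (config.metad.wall_position or 0.05) + 0.05, 60))
        hills, colvar = run_wtmetad(
            system, cv, config.metad, config.n_steps, seed=config.seed,
            dt=config.dt_ps, friction=config.friction_per_ps,
            x0=refs_feat[0], stride=config.stride, grid=grid)
        _save(outdir, "HILLS", lambda p: write_hills(hills, p))
        _save(outdir, "COLVAR", lambda p: write_colvar(colvar, p))
        done(n_hills=len(hills), last_height=float(hills.heights[-1]))

    # -- FES and divider ----------------------------------------------------
    done = stage("fes")
    smax = float(hills.centers[:, 0].max())
    n_refs = n_refs or int(round(smax))
    grid = ((0.5, n_refs + 0.5, config.grid_ns),
            (float(hills.centers[:, 1].min()) - 0.02,
             float(hills.centers[:, 1].max()) + 0.03, config.grid_nz))
    fes = fes_from_hills(hills, grid, rescale_s=n_refs)
    _save(outdir, "fes.dat", lambda p: _write_fes(fes, p))
    done(grid=[config.grid_ns, config.grid_nz])

    done = stage("xstar")
    cand = (np.arange(1, n_refs - 1)) / (n_refs - 1)
    curve = dg_vs_divider_curve(fes, config.temperature, cand)
    pmf = pmf_along_s(fes, config.temperature)
    divider = find_x_star(cand, curve, fes.s_axis, pmf, n_frames=n_refs)
    _save(outdir, "dg_vs_divider.csv", lambda p: Path(p).write_text(
        "s_star,dg_b\n" + "\n".join(f"{s:.6f},{d:.6f}"
                                    for s, d in zip(cand, curve)) + "\n"))
    done(s_star=divider.s_star, method=divider.method)

    # -- convergence and time statistics -------------------------------------
    done = stage("dg")
    zmax = config.metad.wall_position
    if colvar is not None:
        window = convergence_window(hills, colvar)
        t0, t1 = window.t_start, window.t_end
        if not window.converged or t0 >= t1:
            # no converged suffix found: average over the second half of the
            # run anyway (the report still flags converged=False)
            t0, t1 = hills.times[len(hills) // 2], hills.times[-1]
    else:
        window = None
        t0, t1 = hills.times[len(hills) // 2], hills.times[-1]
    checkpoints = np.linspace(t0, t1, config.n_checkpoints)
    series = dg_time_series(hills, grid, divider.s_star, config.temperature,
                            checkpoints, rescale_s=n_refs, z_max=zmax)
    dg_b, stderr = dg_time_stats(series[np.isfinite(series)])
    done(dg_b=dg_b, stderr=stderr)

    # -- standard-state correction -------------------------------------------
    done = stage("volume")
    if config.v_bulk_mode == "ses":
        if path is None:
            raise StageError("volume", "SES volume needs path frames")
        measure = (AtomSelection(config.measure_indices)
                   if config.measure_indices is not None
                   else AtomSelection.all_atoms(path[0].n_atoms))
        unbound = [c.frame_id for c in path
                   if (c.frame_id / max(len(path) - 1, 1)) > divider.s_star]
        spheres = collect_unbound_atoms(path, unbound, measure)
        v_bulk = ses_volume(spheres, config.ses)
    else:
        v_bulk = config.v_bulk_a3
    dg_v = volume_correction(v_bulk, config.temperature)
    done(v_bulk_a3=v_bulk, dg_v=dg_v)

    result = BindingResult(
        dg_b=dg_b, dg_v=dg_v, dg_standard=dg_b + dg_v, stderr=stderr,
        v_bulk=v_bulk, divider=divider,
        converged_window=(None if window is None
                          else (window.t_start, window.t_end)),
        details={
            "converged": None if window is None else window.converged,
            "residual_height_fraction":
                None if window is None else window.residual_fraction,
            "lambda_mode": config.lambda_mode,
            "v_bulk_mode": config.v_bulk_mode,
            "temperature_K": config.temperature,
            "seed": config.seed,
            "n_reference_frames": n_refs,
            "x_star_method": divider.method,
            "stages": log,
        })
    if outdir is not None:
        report = {
            "dg_b_kcal_mol": round(result.dg_b, 4),
            "dg_v_kcal_mol": round(result.dg_v, 4),
            "dg_standard_kcal_mol": round(result.dg_standard, 4),
            "stderr_kcal_mol": round(result.stderr, 4),
            "v_bulk_A3": round(result.v_bulk, 2),
            "s_star": round(divider.s_star, 5),
            "x_star_method": divider.method,
            "converged_window_ps": result.converged_window,
            "details": {k: v for k, v in result.details.items()
                        if k != "stages"},
            "stages": log,
        }
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, default=float) + "\n")
    return result


def _write_fes(fes, filename) -> None:
    lines = ["# s z F_kcal_mol" if fes.is_2d else "# s F_kcal_mol"]
    if fes.is_2d:
        for i, s in enumerate(fes.s_axis):
            for j, z in enumerate(fes.z_axis):
                lines.append(f"{s:.6f} {z:.6f} {fes.values[i, j]:.6f}")
    else:
        for i, s in enumerate(fes.s_axis):
            lines.append(f"{s:.6f} {fes.values[i]:.6f}")
    Path(filename).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# fixture generation to disk


@dataclass
class FixtureSpec:
    kind: str  # "arc-cloud" | "funnel-system" | "dg-curve"
    seed: int = 0
    size: int = 200
    noise: float = 0.05


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> list[Path]:
    """Write a reproducible synthetic fixture to disk; returns the files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if spec.kind == "arc-cloud":
        cloud, endpoints = fixtures.arc_cloud(spec.size, spec.noise, spec.seed)
        f = outdir / "arc_cloud.csv"
        rows = ["x,y"] + [f"{p[0]:.10g},{p[1]:.10g}" for p in cloud.samples]
        f.write_text("\n".join(rows) + "\n")
        g = outdir / "arc_endpoints.csv"
        g.write_text("x,y\n" + "\n".join(
            f"{p[0]:.10g},{p[1]:.10g}" for p in endpoints) + "\n")
        written += [f, g]
    elif spec.kind == "funnel-system":
        fspec = fixtures.FunnelSpec()
        dg = fixtures.funnel_exact_dg(fspec)
        f = outdir / "funnel_system.yaml"
        payload = dataclasses.asdict(fspec)
        payload["exact_dg_b_kcal_mol"] = float(dg)
        payload["divider_x_nm"] = fixtures.funnel_divider_x(fspec)
        f.write_text(yaml.safe_dump(payload))
        written.append(f)
    elif spec.kind == "dg-curve":
        s, dg = fixtures.logistic_dg_curve(spec.size + 1)
        f = outdir / "dg_curve_logistic.csv"
        f.write_text("s,dg\n" + "\n".join(
            f"{a:.10g},{b:.10g}" for a, b in zip(s, dg)) + "\n")
        s2, dg2 = fixtures.two_plateau_dg_curve(spec.size + 1)
        g = outdir / "dg_curve_two_plateau.csv"
        g.write_text("s,dg\n" + "\n".join(
            f"{a:.10g},{b:.10g}" for a, b in zip(s2, dg2)) + "\n")
        written += [f, g]
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    return written
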