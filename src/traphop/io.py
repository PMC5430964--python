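"""Trajectory files, run manifests and the staged pipeline.

Trajectory dialect: tab-separated text with '#' comment lines, a unit tag in
a header comment (``# units: um,s`` or ``# units: sigma,tD``) and a header row
``time<TAB>x<TAB>y`` for position tracks or ``time<TAB>r`` for displacement
series.  Simulation snapshots are written as extended XYZ so standard
molecular viewers open them.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (ComTrajectory, displacement_distribution,
                       fit_diffusivity, fit_exponentials, msd)
from .free_energy import BarrierModel, barrier_height, pmf_from_samples, transect_barrier
from .geometry import PostArrayGeometry
from .hmm import TrapHopHMM, scan_step_size
from .synthetic import SynthConfig, synth_brownian, synth_traphop, synth_trapped


class TrajectoryParseError(ValueError):
    pass


class PipelineConfigError(ValueError):
    pass


_UNIT_TAGS = {"um,s": "experimental", "sigma,tD": "simulation"}
_TAG_FOR_UNITS = {v: k for k, v in _UNIT_TAGS.items()}


def write_trajectory(traj: ComTrajectory, path) -> None:
    """Write the TSV dialect; the unit system goes in a header comment."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# traphop trajectory\n")
        fh.write(f"# units: {_TAG_FOR_UNITS.get(traj.units, traj.units)}\n")
        if traj.xy is not None:
            fh.write("time\tx\ty\n")
            for t, (x, y) in zip(traj.times, traj.xy):
                fh.write(f"{t:.12g}\t{x:.12g}\t{y:.12g}\n")
        else:
            fh.write("time\tr\n")
            for t, r in zip(traj.times, traj.r):
                fh.write(f"{t:.12g}\t{r:.12g}\n")


def read_trajectory(path, units: Optional[str] = None) -> ComTrajectory:
    """Read the TSV dialect; dispatches on column count (3 = track, 2 =
    displacement series).  Validates monotone time and uniform spacing,
    naming the offending line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header_units = None
    rows = []
    names = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                if "units:" in s:
                    tag = s.split("units:", 1)[1].strip()
                    header_units = _UNIT_TAGS.get(tag, tag)
                continue
            parts = s.split("\t")
            if names is None:
                names = [p.strip() for p in parts]
                if names not in (["time", "x", "y"], ["time", "r"]):
                    raise TrajectoryParseError(
                        f"{path}:{lineno}: expected header 'time\\tx\\ty' or "
                        f"'time\\tr', got {names}"
                    )
                continue
            if len(parts) != len(names):
                raise TrajectoryParseError(
                    f"{path}:{lineno}: expected {len(names)} columns, "
                    f"got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as err:
                raise TrajectoryParseError(f"{path}:{lineno}: {err}") from err
    if names is None or not rows:
        raise TrajectoryParseError(f"{path}: no data rows found")
    data = np.asarray(rows)
    times = data[:, 0]
    dt = np.diff(times)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 2  # header + 1-based data row
        raise TrajectoryParseError(
            f"{path}: non-increasing time at data row {bad}"
        )
    mean_dt = dt.mean()
    if np.any(np.abs(dt - mean_dt) > 1e-6 * mean_dt):
        bad = int(np.argmax(np.abs(dt - mean_dt) > 1e-6 * mean_dt)) + 2
        raise TrajectoryParseError(
            f"{path}: mixed frame spacing at data row {bad}"
        )
    u = units or header_units or "experimental"
    if len(names) == 3:
        return ComTrajectory(times=times, xy=data[:, 1:3], units=u)
    return ComTrajectory(times=times, r=data[:, 1], units=u)


def write_xyz(snapshots: np.ndarray, path, box=None, comment: str = "") -> None:
    """Extended-XYZ snapshot writer (element tag C, lattice in the comment)."""
    path = Path(path)
    snaps = np.atleast_3d(np.asarray(snapshots, dtype=float))
    if snaps.ndim == 3 and snaps.shape[2] != 3:
        raise ValueError("snapshots must have shape (n_frames, n_beads, 3)")
    with path.open("w") as fh:
        for frame in snaps:
            fh.write(f"{frame.shape[0]}\n")
            if box is not None:
                lattice = (f'Lattice="{box[0]} 0 0 0 {box[1]} 0 0 0 1" '
                           f"Properties=species:S:1:pos:R:3 {comment}")
            else:
                lattice = comment or "traphop snapshot"
            fh.write(lattice.strip() + "\n")
            for x, y, z in frame:
                fh.write(f"C {x:.8g} {y:.8g} {z:.8g}\n")


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, outputs, timestamps."""

    config: dict
    seed: int
    outputs: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "outputs": self.outputs,
            "started": self.started,
            "finished": self.finished,
        }


_STAGE_ORDER = ["simulate", "synth", "msd", "hmm", "scan_g", "pmf", "barrier"]
_SETTING_KEYS = {"seed", "outdir", "input"}


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config_path) -> RunManifest:
    """Execute the staged pipeline described by a YAML config.

    Top-level keys are stage names (simulate | synth | msd | hmm | scan_g |
    pmf | barrier) plus optional settings (seed, outdir, input).  Stages run
    in a fixed order; each writes ``<outdir>/<stage>.json`` (deterministic
    given the seed) and trajectory-producing stages also write
    ``trajectory.tsv`` consumed by the analysis stages.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    if not isinstance(cfg, dict) or not cfg:
        raise PipelineConfigError("config must be a non-empty mapping")
    unknown = set(cfg) - set(_STAGE_ORDER) - _SETTING_KEYS
    if unknown:
        raise PipelineConfigError(f"unknown stage(s)/key(s): {sorted(unknown)}")
    stages = [s for s in _STAGE_ORDER if s in cfg]
    if not stages:
        raise PipelineConfigError("config selects no stages")
    for s in stages:
        if not isinstance(cfg[s], dict):
            raise PipelineConfigError(f"stage {s!r} must be a mapping of options")
    # validate inputs before any compute
    input_path = cfg.get("input")
    needs_traj = {"msd", "hmm", "scan_g"} & set(stages)
    if needs_traj and not ({"synth", "simulate"} & set(stages)):
        if input_path is None:
            raise PipelineConfigError(
                "msd/hmm/scan_g stages need an 'input' trajectory or a "
                "synth/simulate stage"
            )
        if not Path(input_path).exists():
            raise FileNotFoundError(input_path)

    seed = int(cfg.get("seed", 0))
    outdir = Path(cfg.get("outdir", config_path.parent / "traphop_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed,
                           started=datetime.datetime.now().isoformat())
    traj: Optional[ComTrajectory] = None
    if input_path is not None:
        traj = read_trajectory(input_path)

    for stage in stages:
        opts = dict(cfg[stage])
        out_json = outdir / f"{stage}.json"
        if stage == "synth":
            traj = _stage_synth(opts, seed, outdir, out_json)
        elif stage == "simulate":
            traj = _stage_simulate(opts, seed, outdir, out_json)
        elif stage == "msd":
            _stage_msd(traj, opts, out_json)
        elif stage == "hmm":
            _stage_hmm(traj, opts, out_json)
        elif stage == "scan_g":
            _stage_scan(traj, opts, out_json)
        elif stage == "pmf":
            _stage_pmf(opts, seed, out_json)
        elif stage == "barrier":
            model = BarrierModel(gap_d=float(opts["d_um"]),
                                 r_g=float(opts["rg_um"]))
            _write_json({"d_um": model.gap_d, "rg_um": model.r_g,
                         "beta_F_star": barrier_height(model)}, out_json)
        manifest.outputs[stage] = str(out_json)
    manifest.finished = datetime.datetime.now().isoformat()
    _write_json(manifest.to_dict(), outdir / "manifest.json")
    return manifest


def _stage_synth(opts: dict, seed: int, outdir: Path, out_json: Path):
    mode = opts.pop("mode", "traphop")
    seed = int(opts.pop("seed", seed))
    if mode == "traphop":
        sc = SynthConfig(
            p_trap=float(opts.get("p_trap", 0.7)),
            step_size_g=float(opts.get("g", 0.84)),
            w_trap=float(opts.get("w_trap", 0.31)),
            frame_interval=float(opts.get("frame_interval", 3.0)),
            duration=float(opts.get("duration", 3000.0)),
            seed=seed,
        )
        traj = synth_traphop(sc)
        meta = {"mode": mode, "seed": seed, **{k: getattr(sc, k) for k in (
            "p_trap", "step_size_g", "w_trap", "frame_interval", "duration")}}
    elif mode == "brownian":
        traj = synth_brownian(float(opts.get("D", 0.028)),
                              float(opts.get("frame_interval", 3.0)),
                              float(opts.get("duration", 3000.0)), seed=seed)
        meta = {"mode": mode, "seed": seed, **opts}
    elif mode == "trapped":
        traj = synth_trapped(float(opts.get("w_trap", 0.31)),
                             float(opts.get("center", 0.4)),
                             float(opts.get("frame_interval", 3.0)),
                             float(opts.get("duration", 3000.0)), seed=seed)
        meta = {"mode": mode, "seed": seed, **opts}
    else:
        raise PipelineConfigError(f"unknown synth mode {mode!r}")
    tsv = outdir / "trajectory.tsv"
    write_trajectory(traj, tsv)
    meta["trajectory"] = str(tsv)
    _write_json(meta, out_json)
    return traj


def _stage_simulate(opts: dict, seed: int, outdir: Path, out_json: Path):
    from .geometry import build_hex_array
    from .simulation import SimConfig, run

    geo = None
    if "geometry" in opts:
        geo = PostArrayGeometry.from_dict(opts["geometry"])
    elif {"R", "d", "H"} <= set(opts):
        geo = build_hex_array(float(opts["R"]), float(opts["d"]),
                              float(opts["H"]))
    sim = SimConfig(
        n_beads=int(opts.get("n_beads", 160)),
        epsilon=float(opts.get("epsilon", 1.0)),
        r_cutoff=float(opts.get("r_cutoff", 2.5)),
        geometry=geo,
        seed=int(opts.get("seed", seed)),
        n_steps_total=int(opts.get("n_steps_total", 100_000)),
        n_steps_equil=int(opts.get("n_steps_equil", 0)),
        sample_every=int(opts.get("sample_every", 100)),
        snapshot_every=int(opts.get("snapshot_every", 0)),
    )
    trace = run(sim)
    traj = trace.com_track
    tsv = outdir / "trajectory.tsv"
    write_trajectory(traj, tsv)
    meta = {
        "n_beads": sim.n_beads, "epsilon": sim.epsilon, "seed": sim.seed,
        "n_steps_total": sim.n_steps_total, "sample_every": sim.sample_every,
        "mean_projected_rg": float(trace.rg_samples.mean()),
        "trajectory": str(tsv),
    }
    if sim.snapshot_every and trace.snapshots is not None:
        xyz = outdir / "snapshots.xyz"
        write_xyz(trace.snapshots, xyz,
                  box=geo.box if geo is not None else None)
        meta["snapshots"] = str(xyz)
    _write_json(meta, out_json)
    return traj


def _stage_msd(traj, opts: dict, out_json: Path) -> None:
    if traj is None:
        raise PipelineConfigError("msd stage has no trajectory to analyse")
    curve = msd(traj, max_lag=opts.get("max_lag"))
    out = {"lags": curve.lags.tolist(), "msd": curve.msd.tolist(),
           "n_pairs": curve.n_pairs.tolist()}
    if "window" in opts:
        fit = fit_diffusivity(curve, tuple(opts["window"]))
        out["D"] = fit.D
        out["window"] = list(fit.window)
    if "lag_for_distribution" in opts:
        hist = displacement_distribution(traj, float(opts["lag_for_distribution"]))
        fit = fit_exponentials(hist, model=opts.get("model", "single"))
        out["displacement_fit"] = {
            "lambda1": fit.lambda1, "derived_D": fit.derived_D,
            "lambda2": fit.lambda2, "stretch_beta": fit.stretch_beta,
        }
    _write_json(out, out_json)


def _stage_hmm(traj, opts: dict, out_json: Path) -> None:
    if traj is None:
        raise PipelineConfigError("hmm stage has no trajectory to analyse")
    res = TrapHopHMM(
        traj, step_size_g=float(opts.get("g", 0.84)),
        w_trap=float(opts.get("w_trap", 0.31)),
        n_steps=opts.get("n_steps"),
    ).fit(p0=float(opts.get("p0", 0.5)), tol=float(opts.get("tol", 1e-3)))
    _write_json(res.to_dict(), out_json)


def _stage_scan(traj, opts: dict, out_json: Path) -> None:
    if traj is None:
        raise PipelineConfigError("scan_g stage has no trajectory to analyse")
    g_grid = opts.get("g_grid")
    if g_grid is None:
        g_grid = np.linspace(float(opts.get("g_min", 0.4)),
                             float(opts.get("g_max", 1.6)),
                             int(opts.get("n_g", 13))).tolist()
    table = scan_step_size(traj.displacement, g_grid,
                           w_trap=float(opts.get("w_trap", 0.31)))
    _write_json(json.loads(table.to_json(orient="records")), out_json)


def _stage_pmf(opts: dict, seed: int, out_json: Path) -> None:
    from .geometry import build_hex_array
    from .simulation import SimConfig, run

    geo = build_hex_array(float(opts.get("R", 16.0)), float(opts["d"]),
                          float(opts.get("H", 3.0)))
    sim = SimConfig(
        n_beads=int(opts.get("n_beads", 160)),
        epsilon=float(opts.get("epsilon", 0.6)),
        r_cutoff=float(opts.get("r_cutoff", 2.5)),
        geometry=geo, seed=int(opts.get("seed", seed)),
        n_steps_total=int(opts.get("n_steps_total", 500_000)),
        n_steps_equil=int(opts.get("n_steps_equil", 50_000)),
        sample_every=int(opts.get("sample_every", 100)),
    )
    trace = run(sim)
    grid = pmf_from_samples(trace.com_samples, geo,
                            bins=int(opts.get("bins", 24)))
    bar = transect_barrier(grid)
    _write_json({
        "d": geo.gap_d, "epsilon": sim.epsilon,
        "transect_dr": grid.transect_dr.tolist(),
        "transect_u": [None if np.isnan(v) else float(v)
                       for v in grid.transect_u],
        "barrier": None if np.isnan(bar["barrier"]) else bar["barrier"],
        "barrier_undefined": bool(bar["undefined"]),
    }, out_json)
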