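"""File dialects, configuration and the seeded end-to-end pipeline.

CSV dialects
------------
trajectories : columns ``track_id, t_s, x_um, y_um`` (one row per
    localization) with a companion cells file ``track_id, base_x_um,
    base_y_um, condition``.
labels : ``track_id, step, state`` ground-truth sidecar.
velocities : ``track_id, t_s, v_axial_um_s, v_perp_um_s, direction``.
FRAP traces : ``t_s, f_bleached_segment, i0_unbleached_segment``.

Reports are JSON with sorted keys and floats rounded to 12 significant
digits, so identical seed + config produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import frap as frap_mod
from . import metrics, mixture, synthetic
from . import trajectories as traj_mod
from .trajectories import ANTEROGRADE, RETROGRADE, Trajectory, VelocitySample

__all__ = [
    "PipelineConfig",
    "read_trajectories",
    "write_trajectories",
    "write_labels",
    "read_velocities",
    "write_velocities",
    "read_frap_trace",
    "write_frap_trace",
    "write_report",
    "run_pipeline",
]

logger = logging.getLogger("ciliadyn")

TRAJ_COLUMNS = ["track_id", "t_s", "x_um", "y_um"]
CELL_COLUMNS = ["track_id", "base_x_um", "base_y_um", "condition"]
VEL_COLUMNS = ["track_id", "t_s", "v_axial_um_s", "v_perp_um_s", "direction"]
FRAP_COLUMNS = ["t_s", "f_bleached_segment", "i0_unbleached_segment"]


@dataclass
class PipelineConfig:
    """All knobs of the demo analysis, round-trippable through YAML.

    Defaults follow the imaging conditions the analysis assumes: frame
    interval 0.46 s and a stationary-track threshold of 0.1 μm² axial
    variance.
    """

    seed: int
    out_dir: str = "ciliadyn_out"
    # analysis parameters
    dt: float = 0.46  # s
    stationary_threshold: float = 0.1  # μm²
    bin_grid_candidates: int = 100
    series_tol: float = 1e-9
    # synthetic study conditions (used when no input paths are given)
    n_tracks: int = 200
    cilium_length: float = 4.0  # μm
    cilium_radius: float = 0.1  # μm
    D: float = 0.25  # μm²/s
    D_run: float = 0.016  # μm²/s while motor-bound (run velocity SD 0.26)
    v_anterograde: float = 0.41  # μm/s
    v_retrograde: float = 0.30  # μm/s
    k_start_a: float = 0.0667  # s⁻¹ (25% directed occupancy with k_stop 0.4)
    k_start_r: float = 0.0667  # s⁻¹
    k_stop: float = 0.4  # s⁻¹ (mean run 2.5 s, as in saltatory kymographs)
    sigma_loc: float = 0.03  # μm
    mean_duration: float = 45.0  # s
    frap_noise_sd: float = 0.01
    frap_f_b: float = 0.8
    # optional input paths (simulation is used when absent)
    live_trajectories: str | None = None
    reference_trajectories: str | None = None
    frap_trace: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "seed" not in payload:
            raise ValueError("config must set an explicit seed")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def write_trajectories(
    trajs: list[Trajectory], path: str | Path, cells_path: str | Path
) -> None:
    rows = []
    cells = []
    for tr in trajs:
        rows.append(
            pd.DataFrame(
                {"track_id": tr.track_id, "t_s": tr.t, "x_um": tr.x,
                 "y_um": tr.y}
            )
        )
        cells.append(
            {"track_id": tr.track_id, "base_x_um": tr.base[0],
             "base_y_um": tr.base[1], "condition": tr.condition}
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    pd.DataFrame(cells, columns=CELL_COLUMNS).to_csv(cells_path, index=False, float_format="%.17g")


def read_trajectories(
    path: str | Path, cells_path: str | Path
) -> list[Trajectory]:
    """Read the trajectory dialect; rows may arrive in any order.

    Rows are canonicalized by sorting on (track_id, t_s); a track whose
    times are not strictly increasing after sorting (duplicate frames)
    raises, naming the track.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    cells = pd.read_csv(cells_path, float_precision="round_trip")
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"{cells_path}: missing columns {missing}")
    cells = cells.set_index(cells["track_id"].astype(str))
    df = df.sort_values(["track_id", "t_s"], kind="stable")
    out = []
    for tid, grp in df.groupby("track_id", sort=True):
        tid = str(tid)
        if tid not in cells.index:
            raise ValueError(f"{cells_path}: no cell entry for track {tid}")
        cell = cells.loc[tid]
        if np.any(np.diff(grp["t_s"].to_numpy()) <= 0):
            raise ValueError(f"{path}: track {tid} has non-increasing times")
        cond = cell["condition"]
        out.append(
            Trajectory(
                track_id=tid,
                t=grp["t_s"].to_numpy(),
                x=grp["x_um"].to_numpy(),
                y=grp["y_um"].to_numpy(),
                base=np.array([cell["base_x_um"], cell["base_y_um"]]),
                condition="" if pd.isna(cond) else str(cond),
            )
        )
    return out


def write_labels(
    trajs: list[Trajectory],
    labels: list[synthetic.GroundTruthLabel],
    path: str | Path,
) -> None:
    rows = []
    for tr, lab in zip(trajs, labels):
        for i, state in enumerate(lab.states):
            rows.append({"track_id": tr.track_id, "step": i, "state": state})
    pd.DataFrame(rows, columns=["track_id", "step", "state"]).to_csv(
        path, index=False
    )


def write_velocities(sample: VelocitySample, path: str | Path) -> None:
    pd.DataFrame(
        {
            "track_id": sample.track_ids,
            "t_s": sample.t,
            "v_axial_um_s": sample.v_axial,
            "v_perp_um_s": sample.v_perp,
            "direction": sample.direction,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_velocities(path: str | Path, dt: float) -> VelocitySample:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in VEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return VelocitySample(
        v_axial=df["v_axial_um_s"].to_numpy(),
        v_perp=df["v_perp_um_s"].to_numpy(),
        direction=df["direction"].to_numpy(dtype=object),
        track_ids=df["track_id"].astype(str).to_numpy(dtype=object),
        t=df["t_s"].to_numpy(),
        dt=dt,
    )


def write_frap_trace(exp: frap_mod.FrapExperiment, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_s": exp.times,
            "f_bleached_segment": exp.intensities,
            "i0_unbleached_segment": exp.i0,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_frap_trace(
    path: str | Path, L: float, a: float, a1: float, a2: float
) -> frap_mod.FrapExperiment:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FRAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return frap_mod.FrapExperiment(
        L=L, a=a, a1=a1, a2=a2,
        times=df["t_s"].to_numpy(),
        intensities=df["f_bleached_segment"].to_numpy(),
        i0=float(df["i0_unbleached_segment"].iloc[0]),
    )


class _Float12Encoder(json.JSONEncoder):
    """JSON writer that rounds floats to 12 significant digits."""

    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def _round_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_report(obj: dict, path: str | Path) -> None:
    """Serialize a report dict as JSON with stable key order."""
    Path(path).write_text(
        json.dumps(_round_floats(obj), sort_keys=True, indent=2,
                   cls=_Float12Encoder)
        + "\n"
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _mixture_report(fit: mixture.MixtureFit, ks: mixture.KsResult) -> dict:
    return {
        "f": fit.f, "f_se": fit.f_se,
        "mu": fit.mu, "mu_se": fit.mu_se,
        "sigma": fit.sigma, "sigma_se": fit.sigma_se,
        "F": fit.F, "df": list(fit.df), "p_F": fit.p_F,
        "ks_stat": ks.statistic, "p_ks": ks.pvalue,
        "n_live": fit.n_live, "n_ref": fit.n_ref,
        "bin_width": fit.bin_width, "edges": fit.edges,
        "rss_mixed": fit.rss_mixed, "rss_ref": fit.rss_ref,
    }


def _velocities_for(
    trajs: list[Trajectory], cfg: PipelineConfig, condition: str
) -> tuple[VelocitySample, int, int]:
    projections = [traj_mod.fit_axis(tr) for tr in trajs]
    kept, excluded = traj_mod.filter_stationary(
        projections, cfg.stationary_threshold
    )
    samples = [traj_mod.instant_velocities(pr, cfg.dt) for pr in kept]
    pooled = traj_mod.pool_condition(samples, condition)
    return pooled, len(kept), len(excluded)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full demo analysis and write its report bundle.

    Simulates (or reads) live and reference conditions, projects and
    filters tracks, pools instant velocities, runs the KS comparison and
    mixture fits per direction plus the perpendicular control, fits the
    FRAP model, computes the transport metrics, and writes JSON reports
    plus a manifest to ``cfg.out_dir``.  Identical seed and config give
    byte-identical reports.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(cfg.seed).spawn(3)
    geometry = synthetic.CiliumGeometry(
        length=cfg.cilium_length, radius=cfg.cilium_radius
    )
    live_model = synthetic.MotionModel(
        D=cfg.D, D_run=cfg.D_run, v_a=cfg.v_anterograde,
        v_r=cfg.v_retrograde, k_start_a=cfg.k_start_a,
        k_start_r=cfg.k_start_r, k_stop=cfg.k_stop,
        sigma_loc=cfg.sigma_loc, dt=cfg.dt, mean_duration=cfg.mean_duration,
    )
    ref_model = dataclasses.replace(live_model, k_start_a=0.0, k_start_r=0.0)

    truth: dict = {}
    if cfg.live_trajectories:
        live_trajs = read_trajectories(
            cfg.live_trajectories, _cells_path(cfg.live_trajectories)
        )
    else:
        live_trajs, _, live_frac = synthetic.simulate_condition(
            cfg.n_tracks, geometry, live_model, streams[0], condition="live"
        )
        truth["live_active_fractions"] = list(live_frac)
        truth["directed_occupancy"] = live_model.stationary_occupancy()
    if cfg.reference_trajectories:
        ref_trajs = read_trajectories(
            cfg.reference_trajectories, _cells_path(cfg.reference_trajectories)
        )
    else:
        ref_trajs, _, _ = synthetic.simulate_condition(
            cfg.n_tracks, geometry, ref_model, streams[1],
            condition="reference",
        )

    live_pool, live_kept, live_excl = _velocities_for(live_trajs, cfg, "live")
    ref_pool, ref_kept, ref_excl = _velocities_for(ref_trajs, cfg, "reference")
    logger.info(
        "velocities: live %d steps (%d tracks, %d stationary), "
        "reference %d steps (%d tracks, %d stationary)",
        len(live_pool), live_kept, live_excl,
        len(ref_pool), ref_kept, ref_excl,
    )

    reports: dict = {"truth": truth} if truth else {}
    for direction in (ANTEROGRADE, RETROGRADE):
        fit = mixture.fit_mixture(live_pool, ref_pool, direction)
        ks = mixture.ks_two_sample(
            live_pool.velocities(direction), ref_pool.velocities(direction)
        )
        reports[direction] = _mixture_report(fit, ks)
    perp = mixture.perpendicular_control(live_pool, ref_pool)
    reports["perpendicular_control"] = {
        "ks_stat": perp.statistic, "p_ks": perp.pvalue,
    }

    # FRAP: half-cilium bleach on the forward model (or a supplied trace)
    frap_geom = dict(L=cfg.cilium_length, a=cfg.cilium_length / 2,
                     a1=0.2, a2=cfg.cilium_length / 2 - 0.2)
    if cfg.frap_trace:
        exp = read_frap_trace(cfg.frap_trace, **frap_geom)
    else:
        rng = np.random.default_rng(streams[2])
        times = np.arange(0.0, 60.5, 1.0)
        model_f = frap_mod.fractional_intensity(
            times, cfg.D, cfg.frap_f_b, 1.0, convention="conserved",
            **frap_geom,
        )
        trace = np.concatenate([[1.0], model_f]) + rng.normal(
            0.0, cfg.frap_noise_sd, size=len(times) + 1
        )
        exp = frap_mod.FrapExperiment(
            times=np.concatenate([[-1.0], times]), intensities=trace,
            i0=1.0, **frap_geom,
        )
        write_frap_trace(exp, out / "frap_trace.csv")
    frap_fit = frap_mod.fit_diffusion(exp)
    reports["frap"] = {
        "D": frap_fit.D, "D_se": frap_fit.D_se,
        "f_b": frap_fit.f_b, "f_m": frap_fit.f_m,
        "f_m_printed": frap_fit.f_m_printed,
        "f_m_consistent": frap_fit.f_m_consistent,
        "fm_disagree": frap_fit.fm_disagree,
        "f_max": frap_fit.f_max, "rss": frap_fit.rss,
        "truncation_order": frap_fit.truncation_order,
    }

    reports["metrics"] = {
        "peclet_receptor": metrics.peclet(1e-4, 1e-5, 2e-9),
        "peclet_tubulin": metrics.peclet(1e-4, 1e-5, 10e-9),
        "diffusive_transit_s": metrics.diffusive_transit_time(
            cfg.cilium_length, frap_fit.D
        ),
        "ballistic_transit_s": metrics.ballistic_transit_time(
            cfg.cilium_length, cfg.v_anterograde
        ),
    }

    for name in (ANTEROGRADE, RETROGRADE, "perpendicular_control", "frap",
                 "metrics"):
        write_report(reports[name], out / f"{name}.json")
    write_velocities(live_pool, out / "velocities_live.csv")
    write_velocities(ref_pool, out / "velocities_reference.csv")

    manifest = {
        "seed": cfg.seed,
        "simulation_truth": truth,
        "config": dataclasses.asdict(cfg),
        "counts": {
            "live_tracks": len(live_trajs),
            "live_tracks_stationary": live_excl,
            "reference_tracks": len(ref_trajs),
            "reference_tracks_stationary": ref_excl,
            "live_velocities": live_pool.counts(),
            "reference_velocities": ref_pool.counts(),
        },
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    manifest["report_hash"] = hashlib.sha256(
        json.dumps(_round_floats(reports), sort_keys=True,
                   cls=_Float12Encoder).encode()
    ).hexdigest()
    write_report(manifest, out / "manifest.json")
    reports["manifest"] = manifest
    return reports


def _cells_path(traj_path: str) -> str:
    p = Path(traj_path)
    return str(p.with_name(p.stem + "_cells" + p.suffix))
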