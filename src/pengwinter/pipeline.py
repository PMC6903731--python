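"""End-to-end orchestration: fixture generation, staged pipeline, manifest.

``make_fixture`` builds the deployment-table-shaped synthetic dataset
(three colonies, 40 adult + 10 juvenile releases, behavior mixes and
durations patterned on the study's summary tables, with enough sub-7-day
deployments that the retention filter keeps 34 adults and 7 juveniles).

``run_pipeline`` chains QC -> CTCRW fit -> multiple imputation -> HUD +
overlap -> migration classification -> habitat metrics, excludes any
deployment that fails a stage with a recorded reason, and writes CSV
products plus a JSON manifest (config snapshot, output hashes,
per-deployment status) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .ctcrw import (CtcrwFit, CtcrwParams, ErrorModel, ImputedTrackSet,
                    fit_ctcrw, impute_tracks, smoothed_mean_path)
from .habitat import (along_track_match, ice_residence_fraction,
                      monthly_habitat_table)
from .hud import HexGrid, assign_cells, hud_to_csv, overlap_table
from .migration import summarize_deployment, summary_table
from .qc import QcReport, run_qc
from .synthetic import (Deployment, EnvGridSet, SimulationConfig, TrueTrack,
                        child_seed, generate_env_grids, observe_argos,
                        simulate_true_track, write_deployments_csv,
                        write_fixes_csv)

# (colony, stage, n_deployed, deploy_date, viable behavior list,
#  viable duration range (transmission days), non-viable duration range)
FIXTURE_GROUPS = [
    ("Admiralty Bay", "adult", 10, "2017-03-09",
     ["east", "east", "local", "local", "local", "local", "local", "local",
      "west"], {"east": (94, 123), "local": (19, 124), "west": (100, 108)}),
    ("Cape Shirreff", "adult", 15, "2017-02-19",
     ["local"] * 7 + ["west"] * 8,
     {"local": (9.5, 150), "west": (46, 250)}),
    ("Cape Shirreff", "juvenile", 5, "2017-02-18",
     ["east", "local", "local", "local"],
     {"east": (45, 52), "local": (9.5, 10.5)}),
    ("Cierva Cove", "adult", 15, "2017-02-25",
     ["local"] * 8 + ["west"] * 2,
     {"local": (19, 140), "west": (135, 187)}),
    ("Cierva Cove", "juvenile", 5, "2017-02-25",
     ["local", "local", "local"], {"local": (10, 20)}),
]


@dataclass
class Fixture:
    deployments: List[Deployment]
    fixes: pd.DataFrame
    true_tracks: Dict[str, TrueTrack]
    behaviors: Dict[str, str]
    config: SimulationConfig


def make_fixture(seed: int = 0,
                 config: Optional[SimulationConfig] = None) -> Fixture:
    """Synthetic dataset shaped like the real deployment table.

    50 tags (40 adult, 10 juvenile) split 10/20/20 across the three
    colonies; per colony/stage group, the configured number of viable
    birds get behavior labels and duration ranges patterned on the
    tracking-summary table (no eastbound birds from Cierva Cove, no
    westbound juveniles), while the remainder transmit under 7 days.
    """
    config = config or SimulationConfig(seed=seed)
    config.validate()
    deployments: List[Deployment] = []
    tracks: Dict[str, TrueTrack] = {}
    behaviors: Dict[str, str] = {}
    fixes_frames = []
    counter = 0
    for colony, stage, n_dep, date, viable_behaviors, dur_ranges in FIXTURE_GROUPS:
        clon, clat = config.colony_locations[colony]
        n_viable = len(viable_behaviors)
        for j in range(n_dep):
            dep_id = f"cp{counter:03d}"
            counter += 1
            dep = Deployment(deployment_id=dep_id, colony=colony,
                             colony_lon=clon, colony_lat=clat, stage=stage,
                             release_time=pd.Timestamp(f"{date}T12:00:00"))
            rng = np.random.default_rng(child_seed(seed, f"fixture:{dep_id}"))
            if j < n_viable:
                behavior = viable_behaviors[j]
                lo, hi = dur_ranges[behavior]
                duration = float(rng.uniform(lo, hi))
            else:
                behavior = "local"
                duration = float(rng.uniform(2.0, 6.0))
            track = simulate_true_track(
                dep, behavior, config, duration,
                seed=child_seed(seed, f"track:{dep_id}"))
            fx = observe_argos(track, config, stage=stage,
                               seed=child_seed(seed, f"argos:{dep_id}"))
            deployments.append(dep)
            tracks[dep_id] = track
            behaviors[dep_id] = behavior
            fixes_frames.append(fx)
    fixes = pd.concat(fixes_frames, ignore_index=True)
    return Fixture(deployments=deployments, fixes=fixes, true_tracks=tracks,
                   behaviors=behaviors, config=config)


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the analysis constants
    (2.5 m/s, 7 d, 2 h, 100 draws, 25 km, 500 km, 5%/50% SIC, 2 °C,
    180°W-0°W)."""

    out_dir: str = "pengwinter_out"
    fixes_path: Optional[str] = None
    deployments_path: Optional[str] = None
    vmax_ms: float = 2.5
    min_days: float = 7.0
    step_hours: float = 2.0
    n_draws: int = 100
    hex_spacing_km: float = 25.0
    radius_km: float = 500.0
    sic_open_pct: float = 5.0
    sic_miz_hi_pct: float = 50.0
    sst_max_c: float = 2.0
    lon_window: Tuple[float, float] = (-180.0, 0.0)
    ice_threshold_pct: float = 5.0
    seed: int = 0
    write_imputed_netcdf: bool = False

    def to_dict(self) -> Dict[str, object]:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig,
                 fixture: Optional[Fixture] = None,
                 env: Optional[EnvGridSet] = None) -> Dict[str, object]:
    """Run every stage and write the output bundle; returns the manifest.

    Inputs come from ``config.fixes_path``/``deployments_path`` when set,
    from a passed-in fixture, or from :func:`make_fixture` at the
    configured seed.  A deployment that fails any stage is excluded
    downstream with its reason recorded in the manifest ledger.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: Dict[str, str] = {}

    sim_config = None
    if config.fixes_path:
        from .qc import read_argos_csv
        from .synthetic import read_deployments_csv
        fixes, rejected = read_argos_csv(config.fixes_path)
        deployments = read_deployments_csv(config.deployments_path)
    else:
        if fixture is None:
            fixture = make_fixture(seed=config.seed)
        fixes, deployments = fixture.fixes, fixture.deployments
        sim_config = fixture.config
    if env is None:
        env = generate_env_grids(sim_config or SimulationConfig(seed=config.seed))

    # --- stage 1: quality control
    retained, qc_report = run_qc(fixes, deployments, vmax_ms=config.vmax_ms,
                                 min_days=config.min_days)
    qc_report.to_csv(out / "qc_report.csv")
    raw_counts = qc_report.per_deployment.set_index("deployment_id")["n_raw"]
    for dep in deployments:
        if dep.deployment_id not in retained:
            n_raw = int(raw_counts.get(dep.deployment_id, 0))
            status[dep.deployment_id] = ("removed: no fixes" if n_raw == 0
                                         else "removed: <7 d of filtered fixes")

    meta = {d.deployment_id: d for d in deployments}
    error_model = ErrorModel()

    # --- stage 2: state-space fit + imputation
    fits: Dict[str, CtcrwFit] = {}
    imputed: List[ImputedTrackSet] = []
    param_rows = []
    for dep_id in sorted(retained):
        fx = retained[dep_id]
        try:
            fit = fit_ctcrw(fx, dep_id, release_time=meta[dep_id].release_time,
                            error_model=error_model,
                            step_hours=config.step_hours)
        except ValueError as exc:
            status[dep_id] = f"fit error: {exc}"
            continue
        if not fit.converged:
            status[dep_id] = f"fit did not converge: {fit.message}"
            continue
        fits[dep_id] = fit
        imputed.append(impute_tracks(fit, n_draws=config.n_draws,
                                     seed=config.seed))
        status[dep_id] = "ok"
        param_rows.append({"deployment_id": dep_id, "beta": fit.params.beta,
                           "sigma": fit.params.sigma, "loglik": fit.loglik})
    pd.DataFrame(param_rows).to_csv(out / "ctcrw_params.csv", index=False)
    if config.write_imputed_netcdf:
        for trk in imputed:
            trk.to_netcdf(out / f"imputed_{trk.deployment_id}.nc")

    # --- stage 3: HUD + overlap
    grid = HexGrid(spacing=config.hex_spacing_km)
    dep_meta = {d.deployment_id: {"colony": d.colony, "stage": d.stage}
                for d in deployments}
    hud = assign_cells(imputed, grid, dep_meta)
    hud_to_csv(hud, out / "hud.csv")
    overlap_table(hud).to_csv(out / "overlap.csv", index=False)

    # --- stage 4: migration classification on the smoothed mean path
    summaries = []
    for dep_id, fit in sorted(fits.items()):
        path = smoothed_mean_path(fit)
        d = meta[dep_id]
        summaries.append(summarize_deployment(
            path["timestamp"].to_numpy(), path["lon"].to_numpy(),
            path["lat"].to_numpy(), dep_id, d.colony, d.stage,
            origin=(d.colony_lon, d.colony_lat), radius_km=config.radius_km))
    summary_table(summaries).to_csv(out / "migration_summary.csv", index=False)

    # --- stage 5: habitat metrics
    habitat_tab = monthly_habitat_table(
        env, lon_window=config.lon_window, sst_max=config.sst_max_c,
        sic_open=config.sic_open_pct, sic_miz_hi=config.sic_miz_hi_pct)
    habitat_tab.to_csv(out / "habitat_area.csv", index=False)

    ice_rows = []
    for dep_id in sorted(fits):
        match = along_track_match(retained[dep_id], env.sic_daily,
                                  sst=env.monthly["sst"])
        frac, mean_sic = ice_residence_fraction(
            match, ice_threshold=config.ice_threshold_pct)
        ice_rows.append({"deployment_id": dep_id, "ice_fraction": frac,
                         "mean_sic_in_ice": mean_sic})
    pd.DataFrame(ice_rows).to_csv(out / "ice_residence.csv", index=False)

    (out / "land_mask.geojson").write_text(env.land_mask_geojson())

    manifest = {
        "software_version": __version__,
        "config": config.to_dict(),
        "deployment_status": dict(sorted(status.items())),
        "n_deployments": len(deployments),
        "n_retained": len(retained),
        "n_fitted": len(fits),
        "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
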