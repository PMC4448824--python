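"""Run orchestration: configuration, simulation driver, parameter sweeps, CLI.

A :class:`RunConfig` gathers the physical parameters (sperm number, actuation,
geometry) and numerical settings of one simulation; defaults follow the
human-sperm parameter set (m0 = 240, k = 6 pi, lambda = 80, head semi-axes
0.05/0.03/0.04 L, b = 0.01 L, q = 0.1 L) with full resolution Ns = 160 and
200 time steps per beat. Scaled-down presets are provided for quick runs.

The model is fully deterministic — identical configurations give identical
trajectories — so no random seeds are involved.
"""

from __future__ import annotations

import argparse
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis
from .meshes import HeadBody, make_flagellum_grid, make_wall
from .stepper import ActiveMoment, StepperConfig, Swimmer

__all__ = ["RunConfig", "TrajectoryLog", "run_simulation", "sweep", "main"]


@dataclass
class RunConfig:
    """Complete, serializable description of one simulation run."""

    # physics
    Sp: float = 15.0
    m0: float = 240.0
    k: float = 6.0 * np.pi
    lam: float = 80.0
    soft_start: bool = True
    # geometry (lengths in units of L)
    wall_kind: str = "backstep"  # strip | backstep | cliff | none
    h: float = 0.2
    x_step: float = 0.0
    wall_extents: tuple[float, float] = (2.0, 2.0)
    wall_resolution: int = 16
    head_semi_axes: tuple[float, float, float] = (0.05, 0.03, 0.04)
    head_refinement: int = 2
    b: float = 0.01
    q: float = 0.1
    x0: float = -0.5
    start_height: float = 0.2
    # numerics
    ns: int = 160
    steps_per_beat: int = 200
    tol: float = 0.005
    max_iters: int = 50
    beats: float = 200.0
    stop_x: float = 1.0
    project_z: bool = True
    # io
    snapshot_every: int = 41
    label: str = ""

    def __post_init__(self) -> None:
        self.wall_extents = tuple(self.wall_extents)
        self.head_semi_axes = tuple(self.head_semi_axes)
        if self.wall_kind not in ("strip", "backstep", "cliff", "none"):
            raise ValueError(f"unknown wall kind {self.wall_kind!r}")
        if self.wall_kind == "strip":
            self.h = 0.0

    # -- presets ---------------------------------------------------------
    @classmethod
    def full(cls, **kw) -> "RunConfig":
        """Full resolution (Ns = 160, 200 steps/beat, ~500 wall elements)."""
        return cls(**kw)

    @classmethod
    def desk(cls, **kw) -> "RunConfig":
        """Reduced resolution for desk-scale studies.

        The arclength grid is kept at 120 intervals: with k = 6 pi the beat
        wave has three wavelengths along the flagellum, and below ~20 nodes
        per wavelength the high-derivative stencils are too inaccurate for a
        stable inextensible beat at full actuation.
        """
        kw.setdefault("ns", 120)
        kw.setdefault("steps_per_beat", 100)
        kw.setdefault("wall_resolution", 8)
        kw.setdefault("head_refinement", 2)
        kw.setdefault("beats", 40.0)
        kw.setdefault("snapshot_every", 21)
        return cls(**kw)

    @classmethod
    def mini(cls, **kw) -> "RunConfig":
        """Smallest stable preset, for tests and quick qualitative runs."""
        kw.setdefault("ns", 100)
        kw.setdefault("steps_per_beat", 60)
        kw.setdefault("wall_resolution", 4)
        kw.setdefault("wall_extents", (1.5, 1.0))
        kw.setdefault("head_refinement", 1)
        kw.setdefault("beats", 25.0)
        kw.setdefault("x0", -0.1)
        kw.setdefault("stop_x", 0.1)
        kw.setdefault("snapshot_every", 13)
        return cls(**kw)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        d["wall_extents"] = list(d["wall_extents"])
        d["head_semi_axes"] = list(d["head_semi_axes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class TrajectoryLog:
    """Per-step head kinematics plus periodic waveform snapshots."""

    config: RunConfig
    steps: pd.DataFrame  # t, x, y, z, ex, ey, ez, iterations
    snapshots: list  # (t, X array) every config.snapshot_every steps
    steps_per_beat: int

    @property
    def total_beats(self) -> float:
        return float(self.steps["t"].iloc[-1] / (2.0 * np.pi)) if len(self.steps) else 0.0

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(d / "config.yaml")
        self.steps.to_csv(d / "steps.csv", index=False)
        snaps = pd.DataFrame(
            [
                {"t": t, "node": i, "x": p[0], "y": p[1], "z": p[2]}
                for t, X in self.snapshots
                for i, p in enumerate(X)
            ]
        )
        snaps.to_csv(d / "snapshots.csv", index=False)


def _build_swimmer(cfg: RunConfig) -> Swimmer:
    grid = make_flagellum_grid(cfg.ns)
    head = HeadBody.ellipsoid(*cfg.head_semi_axes, refinement=cfg.head_refinement)
    wall = None
    if cfg.wall_kind != "none":
        wall = make_wall(
            cfg.wall_kind, h=cfg.h, x_step=cfg.x_step,
            extents=cfg.wall_extents, resolution=cfg.wall_resolution,
        )
    scfg = StepperConfig(
        Sp=cfg.Sp, lam=cfg.lam, dt=2.0 * np.pi / cfg.steps_per_beat,
        tol=cfg.tol, max_iters=cfg.max_iters, b=cfg.b, q=cfg.q,
        project_z=cfg.project_z,
    )
    moment = ActiveMoment(m0=cfg.m0, k=cfg.k, tau=None if not cfg.soft_start else ActiveMoment.tau)
    return Swimmer(scfg, moment, grid, head, wall, x0=(cfg.x0, cfg.start_height, 0.0))


def run_simulation(cfg: RunConfig, progress: bool = False) -> TrajectoryLog:
    """Step the swimmer from rest until it passes ``stop_x`` (one flagellar
    length beyond the step by default) or exhausts the beat budget."""
    sw = _build_swimmer(cfg)
    records = []
    snapshots = []
    n_steps = int(round(cfg.beats * cfg.steps_per_beat))
    for istep in range(n_steps):
        info = sw.step()
        st = sw.state
        tangents = sw.ops[1] @ st.X
        stretch = float(np.max(np.abs(np.linalg.norm(tangents, axis=1) - 1.0)))
        records.append(
            {
                "t": st.t, "x": st.X[0, 0], "y": st.X[0, 1], "z": st.X[0, 2],
                "ex": tangents[0, 0], "ey": tangents[0, 1], "ez": tangents[0, 2],
                "iterations": info["iterations"],
                "stretch": stretch, "T_distal": float(st.T[-1]),
            }
        )
        if istep % cfg.snapshot_every == 0:
            snapshots.append((st.t, st.X.copy()))
        if progress and istep % cfg.steps_per_beat == 0:
            print(f"beat {istep // cfg.steps_per_beat}: x={st.X[0, 0]:+.3f} y={st.X[0, 1]:+.3f}")
        if st.X[0, 0] >= cfg.x_step + cfg.stop_x:
            break
    return TrajectoryLog(
        config=cfg, steps=pd.DataFrame(records), snapshots=snapshots,
        steps_per_beat=cfg.steps_per_beat,
    )


def sweep(
    base: RunConfig,
    sp_values,
    h_values,
    out_dir: str | Path | None = None,
    x_target: float | None = None,
) -> pd.DataFrame:
    """Run a (Sp, h) grid and tabulate final deflections.

    The h = 0 (strip) run of each Sp serves as the baseline for the
    strip-relative deflection ``delta_theta_d``. With ``out_dir`` the sweep is
    resumable: finished cells are stored as one-row CSVs and skipped on rerun.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sp in sp_values:
        cell_results = {}
        for h in list(h_values):
            tag = f"cell_Sp{sp:g}_h{h:g}.csv"
            if out is not None and (out / tag).exists():
                cell_results[h] = pd.read_csv(out / tag).iloc[0].to_dict()
                continue
            cfg = dataclasses.replace(
                base, Sp=float(sp), h=float(h),
                wall_kind="strip" if h == 0 else "backstep",
            )
            log = run_simulation(cfg)
            series = analysis.trajectory_angle(log)
            theta_d, _ = analysis.final_deflection(
                series, x_target=x_target if x_target is not None else cfg.stop_x
            )
            cell = {"Sp": float(sp), "h": float(h), "theta_d": theta_d}
            if out is not None:
                pd.DataFrame([cell]).to_csv(out / tag, index=False)
            cell_results[h] = cell
        base_theta = cell_results.get(0.0, {}).get("theta_d")
        for h, cell in cell_results.items():
            cell = dict(cell)
            cell["delta_theta_d"] = (
                cell["theta_d"] - base_theta if base_theta is not None else np.nan
            )
            rows.append(cell)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# command-line interface (thin wrapper over the library)
# ---------------------------------------------------------------------------

def main(argv=None) -> int:
    ap = argparse.ArgumentParser(prog="elastoswim", description=__doc__)
    sub = ap.add_subparsers(dest="cmd", required=True)

    p_run = sub.add_parser("run", help="run a single configuration")
    p_run.add_argument("config", help="YAML run configuration")
    p_run.add_argument("-o", "--out", default="run_out", help="output directory")

    p_sweep = sub.add_parser("sweep", help="run a (Sp, h) grid")
    p_sweep.add_argument("config", help="YAML base configuration")
    p_sweep.add_argument("--sp", type=float, nargs="+", required=True)
    p_sweep.add_argument("--heights", type=float, nargs="+", required=True)
    p_sweep.add_argument("-o", "--out", default="sweep_out")

    p_an = sub.add_parser("analyze", help="post-process a saved run")
    p_an.add_argument("rundir", help="directory written by `run`")

    p_fx = sub.add_parser("fixtures", help="dump a prescribed-wave fixture")
    p_fx.add_argument("--amplitude", type=float, default=0.1)
    p_fx.add_argument("--wavenumber", type=float, default=float(2 * np.pi))
    p_fx.add_argument("--nodes", type=int, default=41)

    args = ap.parse_args(argv)
    if args.cmd == "run":
        cfg = RunConfig.from_yaml(args.config)
        log = run_simulation(cfg, progress=True)
        log.save(args.out)
        print(f"saved {len(log.steps)} steps to {args.out}")
    elif args.cmd == "sweep":
        base = RunConfig.from_yaml(args.config)
        table = sweep(base, args.sp, args.heights, out_dir=args.out)
        table.to_csv(Path(args.out) / "deflections.csv", index=False)
        print(table.to_string(index=False))
    elif args.cmd == "analyze":
        d = Path(args.rundir)
        cfg = RunConfig.from_yaml(d / "config.yaml")
        steps = pd.read_csv(d / "steps.csv")
        snaps_df = pd.read_csv(d / "snapshots.csv")
        snapshots = [
            (t, g[["x", "y", "z"]].to_numpy()) for t, g in snaps_df.groupby("t", sort=True)
        ]
        log = TrajectoryLog(cfg, steps, snapshots, cfg.steps_per_beat)
        series = analysis.trajectory_angle(log)
        summary = {"beats": log.total_beats}
        try:
            theta_d, _ = analysis.final_deflection(series, x_target=cfg.stop_x)
            summary["theta_d"] = theta_d
        except ValueError:
            pass
        prof = analysis.waveform_asymmetry(log)
        summary["A_tip"] = prof.A_tip
        pd.DataFrame({"beat": series.beat, "theta_deg": series.theta_deg}).to_csv(
            d / "theta.csv", index=False
        )
        pd.DataFrame({"s": prof.s, "A": prof.A}).to_csv(d / "asymmetry.csv", index=False)
        print(json.dumps(summary, indent=2))
    elif args.cmd == "fixtures":
        from .fixtures import prescribed_wave
        from .meshes import make_flagellum_grid

        grid = make_flagellum_grid(args.nodes - 1)
        X, V = prescribed_wave(args.amplitude, args.wavenumber, 0.0, grid)
        df = pd.DataFrame(
            np.hstack([grid.s[:, None], X, V]), columns=["s", "x", "y", "z", "vx", "vy", "vz"]
        )
        print(df.to_string(index=False))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
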