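"""Post-processing of swimmer trajectories and waveforms.

Metrics:

* the trajectory tangent angle ``theta = arctan(dY/dX)`` at the head, sampled
  at the temporal midpoint of each beat cycle with centred differences
  (positive theta means heading away from the wall, toward +y);
* the final deflection angle ``theta_d``, the value of theta where the head
  first reaches a prescribed downstream station (one flagellar length past
  the step), optionally baselined against a strip run to isolate the effect
  of the step;
* the waveform asymmetry profile ``A(s)``: the mean lateral position of the
  flagellum in the head-fixed body frame over an averaging window, zero for
  a mirror-symmetric beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DeflectionSeries",
    "AsymmetryProfile",
    "trajectory_angle",
    "final_deflection",
    "waveform_asymmetry",
    "default_asymmetry_window",
]


@dataclass
class DeflectionSeries:
    """Mid-beat head positions and trajectory angle per (interior) beat."""

    beat: np.ndarray  # interior beat indices
    x: np.ndarray
    y: np.ndarray
    theta_deg: np.ndarray


@dataclass
class AsymmetryProfile:
    """Beat-averaged lateral flagellar position in the body frame."""

    s: np.ndarray
    A: np.ndarray
    n_snapshots: int

    @property
    def A_tip(self) -> float:
        return float(self.A[-1])


def trajectory_angle(log) -> DeflectionSeries:
    """Tangent angle of the head trajectory from mid-beat centred differences."""
    steps = log.steps
    spb = log.steps_per_beat
    n_beats = int(len(steps) // spb)
    if n_beats < 3:
        raise ValueError("need at least 3 complete beats for centred differences")
    mids = np.array([round((b + 0.5) * spb) for b in range(n_beats)], dtype=int)
    mids = mids[mids < len(steps)]
    xm = steps["x"].to_numpy()[mids]
    ym = steps["y"].to_numpy()[mids]
    dx = xm[2:] - xm[:-2]
    dy = ym[2:] - ym[:-2]
    theta = np.degrees(np.arctan2(dy, dx))
    beat = np.arange(1, len(mids) - 1)
    return DeflectionSeries(beat=beat, x=xm[1:-1], y=ym[1:-1], theta_deg=theta)


def final_deflection(
    series: DeflectionSeries,
    baseline: DeflectionSeries | None = None,
    x_target: float = 1.0,
) -> tuple[float, float | None]:
    """Deflection angle at the first crossing of ``x_target``.

    Linear interpolation of theta between the bracketing mid-beat samples;
    with a (strip) baseline series the strip-relative deflection
    ``delta = theta_d - theta_d(baseline)`` is returned as well.
    """

    def _at_crossing(s: DeflectionSeries) -> float:
        idx = np.nonzero(s.x >= x_target)[0]
        if len(idx) == 0:
            raise ValueError(f"trajectory never reaches x = {x_target}")
        i = int(idx[0])
        if i == 0:
            return float(s.theta_deg[0])
        frac = (x_target - s.x[i - 1]) / (s.x[i] - s.x[i - 1])
        return float(s.theta_deg[i - 1] + frac * (s.theta_deg[i] - s.theta_deg[i - 1]))

    theta_d = _at_crossing(series)
    if baseline is None:
        return theta_d, None
    return theta_d, theta_d - _at_crossing(baseline)


def default_asymmetry_window(total_beats: float) -> tuple[float, float]:
    """Averaging window in beats: 82-90 for long runs, scaled down otherwise."""
    if total_beats >= 90.0:
        return (82.0, 90.0)
    return (max(0.4 * total_beats, total_beats - 5.0), total_beats)


def waveform_asymmetry(
    log,
    window: tuple[float, float] | None = None,
) -> AsymmetryProfile:
    """Mean body-frame lateral flagellar position over the averaging window.

    Snapshots within the window (in beats) are projected into the head-fixed
    frame: origin at the junction, forward axis along the heading
    ``-X_s(0)``, lateral axis the in-plane normal (+90 degrees about +z).
    """
    if window is None:
        window = default_asymmetry_window(log.total_beats)
    lo, hi = window
    chosen = [(t, X) for t, X in log.snapshots if lo <= t / (2.0 * np.pi) <= hi]
    if not chosen:
        raise ValueError("averaging window contains no waveform snapshots")
    n = len(chosen[0][1])
    s = np.linspace(0.0, 1.0, n)
    ds = s[1] - s[0]
    acc = np.zeros(n)
    for _, X in chosen:
        xs0 = (-3.0 * X[0] + 4.0 * X[1] - X[2]) / (2.0 * ds)
        fwd = -xs0 / np.linalg.norm(xs0)
        lat = np.cross([0.0, 0.0, 1.0], fwd)
        acc += (X - X[0]) @ lat
    return AsymmetryProfile(s=s, A=acc / len(chosen), n_snapshots=len(chosen))
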