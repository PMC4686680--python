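"""In-silico perturbation experiments on the gap gene circuit.

Three experiment kinds, each compared against the unmodified ("control")
simulation:

* ``control``      - the unmodified model (Bcd A = 351 a.u.,
  lambda = 0.1651 EL);
* ``reduced_rate`` - one gap gene's (or all genes') maximum synthesis rate
  multiplied by a factor (default 0.8, i.e. a 20% reduction);
* ``scaled_bcd``   - the Bcd gradient of a larger embryo: amplitude
  multiplied by k (default 1.6) and the relative length scale reduced
  (default factor 0.8, giving 0.1321 EL).  The two exponentials then
  intersect at the critical position xi* = ln k / (1/lambda_s - 1/lambda_c)
  (0.311 for the defaults).

Model output is measured the way the imaging pipeline measures embryos:
a smoothed cubic spline is fitted to each spatial profile, boundaries are
the positions where the spline equals the mean of consecutive extrema, and
domain peak levels are spline maxima inside configured windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import brentq

from .genecircuit import (
    BcdGradient,
    CircuitParams,
    CircuitError,
    ExternalInputs,
    Schedule,
    Trajectory,
    simulate,
)

#: Observation clock (minutes after the thirteenth nuclear division) of the
#: standard output frames: early/late T1, early/late T2, T3, T4, T6, T8.
DEFAULT_OUTPUT_MINUTES = (3.125, 9.375, 15.625, 21.875, 28.125, 34.375, 40.625, 46.875)

#: Default smoothing parameter (penalty lambda of the smoothing spline).
#: Small enough that a noiseless single-bump profile's half-extremum
#: boundary is recovered to well under 0.5% EL on the nc14 grid.
DEFAULT_SPLINE_SMOOTHING = 1e-8

#: AP windows (EL) used to measure the four posterior-trunk domains of the
#: model output: posterior Hb, central Kr, posterior Gt, abdominal Kni.
DEFAULT_DOMAIN_WINDOWS = {
    "Hb": (0.70, 0.92),
    "Kr": (0.40, 0.66),
    "Gt": (0.62, 0.88),
    "Kni": (0.52, 0.82),
}


class ExperimentError(ValueError):
    """Invalid experiment specification or measurement input."""


@dataclass(frozen=True)
class ExperimentSpec:
    """Definition of one perturbation experiment."""

    kind: str = "control"  # control | reduced_rate | scaled_bcd
    reduced_genes: object = "all"  # subset of gene names or "all"
    rate_factor: float = 0.8
    bcd_amplitude_multiplier: float = 1.6
    bcd_lambda_factor: float = 0.8
    output_minutes: tuple[float, ...] = DEFAULT_OUTPUT_MINUTES

    def __post_init__(self) -> None:
        if self.kind not in ("control", "reduced_rate", "scaled_bcd"):
            raise ExperimentError(f"unknown experiment kind {self.kind!r}")
        if not 0 < self.rate_factor <= 1:
            raise ExperimentError("rate_factor must lie in (0, 1]")
        if self.bcd_amplitude_multiplier <= 0 or self.bcd_lambda_factor <= 0:
            raise ExperimentError("Bcd multipliers must be positive")


def critical_position(
    k: float, lambda_control: float = 0.1651, lambda_scaled: float = 0.1321
) -> float:
    """AP position where control and scaled Bcd gradients intersect.

    Solves A exp(-x/lambda_c) = k A exp(-x/lambda_s):
    xi* = ln(k) / (1/lambda_s - 1/lambda_c).  k = 1 gives 0 (the gradients
    coincide at the origin of the amplitude scaling); equal length scales
    with k != 1 admit no crossing.
    """
    if k <= 0 or lambda_control <= 0 or lambda_scaled <= 0:
        raise ExperimentError("k and length scales must be positive")
    if k == 1.0:
        return 0.0
    denom = 1.0 / lambda_scaled - 1.0 / lambda_control
    if denom == 0.0:
        raise ExperimentError("equal length scales with k != 1: no crossing")
    return math.log(k) / denom


@dataclass(frozen=True)
class ModelBoundary:
    """A half-extremum boundary of the spline-fitted model output."""

    position: float  # EL
    level_at_boundary: float  # a.u.
    side: str  # 'anterior' (rising) | 'posterior' (falling)


def _fit_spline(x: np.ndarray, y: np.ndarray, smoothing: float):
    return make_smoothing_spline(x, y, lam=smoothing if smoothing > 0 else None)


def _spline_extrema(spl, x_lo: float, x_hi: float, n_dense: int = 2001):
    """Ordered (position, value) extrema of the spline, endpoints included."""
    xs = np.linspace(x_lo, x_hi, n_dense)
    d = spl.derivative()
    dv = d(xs)
    roots = []
    for i in range(len(xs) - 1):
        a, b = dv[i], dv[i + 1]
        if a == 0.0:
            roots.append(xs[i])
        elif a * b < 0:
            roots.append(brentq(d, xs[i], xs[i + 1]))
    pts = [x_lo] + [r for r in roots if x_lo < r < x_hi] + [x_hi]
    return [(float(p), float(spl(p))) for p in pts]


def measure_spline_boundaries(
    x, profile, smoothing: float = DEFAULT_SPLINE_SMOOTHING
) -> tuple[list[ModelBoundary], list[tuple[float, float]]]:
    """Boundaries of a spatial model profile by the half-extremum rule.

    A smoothed cubic spline is fitted to the per-nucleus concentrations; its
    local extrema are located in order along x (for monotone profiles the
    endpoint values serve as the extrema), and between each consecutive
    extremum pair the boundary is the position where the spline equals the
    mean of the two extreme values.  Returns (boundaries, extrema).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(profile), dtype=float)
    if x.size < 4:
        raise ExperimentError("need at least 4 nuclei for a cubic spline")
    spl = _fit_spline(x, y, smoothing)
    extrema = _spline_extrema(spl, x[0], x[-1])
    boundaries: list[ModelBoundary] = []
    scale = max(1e-12, float(np.ptp(y)))
    for (x1, v1), (x2, v2) in zip(extrema[:-1], extrema[1:]):
        target = 0.5 * (v1 + v2)
        if abs(v2 - v1) <= 1e-6 * max(scale, abs(v1), abs(v2)):
            continue  # flat segment: no boundary
        f = lambda xx: float(spl(xx)) - target
        a, b = f(x1), f(x2)
        if a == 0.0:
            pos = x1
        elif b == 0.0:
            pos = x2
        elif a * b < 0:
            pos = brentq(f, x1, x2)
        else:  # pragma: no cover - extrema bracket their mean by construction
            continue
        side = "anterior" if v2 > v1 else "posterior"
        boundaries.append(ModelBoundary(float(pos), float(target), side))
    return boundaries, extrema


def peak_level_model(
    x, profile, window: tuple[float, float],
    smoothing: float = DEFAULT_SPLINE_SMOOTHING,
) -> float:
    """Peak expression level: maximum of the fitted spline inside ``window``."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(profile), dtype=float)
    lo, hi = window
    if lo >= hi or lo < x[0] - 1e-9 or hi > x[-1] + 1e-9:
        raise ExperimentError(f"window {window} outside grid [{x[0]}, {x[-1]}]")
    spl = _fit_spline(x, y, smoothing)
    xs = np.linspace(max(lo, x[0]), min(hi, x[-1]), 1001)
    return float(spl(xs).max())


def domain_measurements(
    x, profile, window: tuple[float, float],
    smoothing: float = DEFAULT_SPLINE_SMOOTHING,
) -> dict:
    """Peak and flanking boundaries of one domain inside an AP window.

    The domain peak is the spline maximum inside the window; the anterior
    (posterior) boundary is the nearest half-extremum boundary anterior
    (posterior) of the peak.  Missing boundaries are None.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(profile), dtype=float)
    lo, hi = window
    spl = _fit_spline(x, y, smoothing)
    xs = np.linspace(max(lo, x[0]), min(hi, x[-1]), 1001)
    vals = spl(xs)
    peak_xi = float(xs[int(np.argmax(vals))])
    peak = float(vals.max())
    boundaries, _ = measure_spline_boundaries(x, y, smoothing)
    ant = [b for b in boundaries if b.side == "anterior" and b.position <= peak_xi]
    post = [b for b in boundaries if b.side == "posterior" and b.position >= peak_xi]
    return {
        "peak_xi": peak_xi,
        "peak_level": peak,
        "anterior": max(ant, key=lambda b: b.position) if ant else None,
        "posterior": min(post, key=lambda b: b.position) if post else None,
    }


@dataclass
class ExperimentResult:
    """Paired control/perturbed trajectories with per-time measurements."""

    spec: ExperimentSpec
    control: Trajectory
    perturbed: Trajectory
    measurements: pd.DataFrame  # run, time_min, gene, peak_xi/level, boundaries


def _measure_trajectory(
    traj: Trajectory, run: str, minutes, windows: dict, smoothing: float
) -> pd.DataFrame:
    rows = []
    for t_after in minutes:
        x, v = traj.frame_after_division13(t_after)
        for gi, gene in enumerate(traj.genes):
            win = windows.get(gene)
            if win is None:
                continue
            meas = domain_measurements(x, v[gi], win, smoothing)
            rows.append(
                {
                    "run": run,
                    "time_min": t_after,
                    "gene": gene,
                    "peak_xi": meas["peak_xi"],
                    "peak_level": meas["peak_level"],
                    "anterior_xi": meas["anterior"].position if meas["anterior"] else np.nan,
                    "posterior_xi": meas["posterior"].position if meas["posterior"] else np.nan,
                }
            )
    return pd.DataFrame(rows)


def run_experiment(
    spec: ExperimentSpec,
    params: CircuitParams,
    bcd: BcdGradient | None = None,
    ext: ExternalInputs | None = None,
    init: np.ndarray | None = None,
    schedule: Schedule | None = None,
    windows: dict | None = None,
    smoothing: float = DEFAULT_SPLINE_SMOOTHING,
    solver_opts: dict | None = None,
) -> ExperimentResult:
    """Run one perturbation experiment against its control.

    Both runs share parameters, inputs, initial state, schedule and solver
    settings; only the perturbation differs.  The whole computation is
    deterministic.  Measurements use the configured per-gene AP windows.
    """
    from .genecircuit import synthetic_external_inputs

    sched = schedule or Schedule()
    bcd_c = bcd or BcdGradient()
    ext = ext or synthetic_external_inputs(sched)
    windows = windows or DEFAULT_DOMAIN_WINDOWS

    if spec.kind == "reduced_rate":
        params_p, bcd_p = params.with_reduced_rates(spec.reduced_genes, spec.rate_factor), bcd_c
    elif spec.kind == "scaled_bcd":
        params_p = params
        bcd_p = BcdGradient(
            A=bcd_c.A * spec.bcd_amplitude_multiplier,
            lam=bcd_c.lam * spec.bcd_lambda_factor,
        )
    else:
        params_p, bcd_p = params, bcd_c

    out_times = [sched.division_time + m for m in spec.output_minutes]
    control = simulate(params, bcd_c, ext, init, sched, out_times, solver_opts)
    perturbed = simulate(params_p, bcd_p, ext, init, sched, out_times, solver_opts)

    meas = pd.concat(
        [
            _measure_trajectory(control, "control", spec.output_minutes, windows, smoothing),
            _measure_trajectory(perturbed, spec.kind, spec.output_minutes, windows, smoothing),
        ],
        ignore_index=True,
    )
    return ExperimentResult(spec=spec, control=control, perturbed=perturbed, measurements=meas)
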