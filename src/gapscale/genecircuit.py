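"""Gap gene-circuit reaction-diffusion model on the blastoderm nuclear grid.

The model simulates the concentrations v_i^a of the four trunk gap proteins
(Hb, Kr, Gt, Kni) in nuclei lying between 0.35 and 0.92 EL, from just after
the twelfth nuclear division until gastrulation (~71 min).  Each nucleus
obeys

    dv_i^a/dt = R^a g(u_i^a) * gate(t)
                + D^a [(v_{i-1}^a - v_i^a) + (v_{i+1}^a - v_i^a)]
                - delta^a v_i^a,

    u_i^a = sum_b T^{ab} v_i^b + m^a v_i^Bcd + sum_beta E^{a beta} v_i^beta
            + h^a,

with g(u) = (u / sqrt(1 + u^2) + 1) / 2 the standard gene-circuit sigmoid,
T the genetic interconnectivity matrix (activation > 0, repression < 0),
m the strength of regulation by the maternal Bicoid gradient
v^Bcd(x) = A exp(-x/lambda), E the strengths of the time-dependent external
inputs Cad and Tll, and h a threshold.  ``gate(t)`` switches synthesis off
during mitosis.  Diffusion is nearest-neighbour exchange with zero-flux
ends; at the thirteenth division every nucleus splits into two daughters
that inherit the mother's concentrations.

Parameters are plain configuration (any well-formed set runs); the
package's default set lives in ``gapscale/data/default_circuit.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

GENES = ("Hb", "Kr", "Gt", "Kni")
EXTERNAL_INPUTS = ("Cad", "Tll")
X_MIN, X_MAX = 0.35, 0.92
N_NUCLEI_NC13 = 29
N_NUCLEI_NC14 = 58


class CircuitError(ValueError):
    """Invalid gene-circuit configuration or state."""


class IntegrationError(RuntimeError):
    """ODE solver failure, with the solver's diagnostic message."""


def nuclear_grid(n: int) -> np.ndarray:
    """Nucleus positions: centres of ``n`` equal bins on [0.35, 0.92] EL."""
    edges = np.linspace(X_MIN, X_MAX, n + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def g(u):
    """Sigmoidal regulation-to-synthesis function, g(u) in (0, 1).

    g(u) = (u / sqrt(1 + u^2) + 1) / 2; strictly increasing, g(0) = 1/2,
    limits 0 and 1, and g(-u) = 1 - g(u).
    """
    u = np.asarray(u, dtype=float)
    out = 0.5 * (u / np.sqrt(1.0 + u * u) + 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BcdGradient:
    """Exponential Bicoid gradient v(x) = A exp(-x / lambda), x in EL."""

    A: float = 351.0
    lam: float = 0.1651

    def __post_init__(self) -> None:
        if self.A <= 0 or self.lam <= 0:
            raise CircuitError("Bcd amplitude and length scale must be positive")

    def __call__(self, x) -> np.ndarray:
        return self.A * np.exp(-np.asarray(x, dtype=float) / self.lam)


@dataclass(frozen=True)
class CircuitParams:
    """Gene-circuit parameters; arrays indexed in the order of ``genes``."""

    R: np.ndarray  # (4,) max synthesis rate, a.u./min
    D: np.ndarray  # (4,) nearest-neighbour exchange rate, 1/min
    delta: np.ndarray  # (4,) degradation rate, 1/min
    T: np.ndarray  # (4, 4) gap-gap interconnectivity
    m: np.ndarray  # (4,) Bcd regulatory strength
    E: np.ndarray  # (4, 2) external-input strengths (Cad, Tll)
    h: np.ndarray  # (4,) threshold
    genes: tuple[str, ...] = GENES

    def __post_init__(self) -> None:
        ng = len(self.genes)
        for name in ("R", "D", "delta", "T", "m", "E", "h"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        shapes = {
            "R": (ng,), "D": (ng,), "delta": (ng,), "m": (ng,), "h": (ng,),
            "T": (ng, ng), "E": (ng, len(EXTERNAL_INPUTS)),
        }
        for name, shape in shapes.items():
            if getattr(self, name).shape != shape:
                raise CircuitError(
                    f"{name} must have shape {shape}, got {getattr(self, name).shape}"
                )
        if np.any(self.R < 0) or np.any(self.D < 0):
            raise CircuitError("R and D must be non-negative")
        if np.any(self.delta < 0):
            raise CircuitError("degradation rates must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        genes = tuple(d.get("genes", GENES))
        def vec(key):
            v = d[key]
            return [v[gene] for gene in genes] if isinstance(v, dict) else v
        T = d["T"]
        if isinstance(T, dict):
            T = [[T[a][b] for b in genes] for a in genes]
        E = d["E"]
        if isinstance(E, dict):
            E = [[E[a][b] for b in EXTERNAL_INPUTS] for a in genes]
        return cls(
            R=vec("R"), D=vec("D"), delta=vec("delta"), T=T,
            m=vec("m"), E=E, h=vec("h"), genes=genes,
        )

    def with_reduced_rates(self, genes, factor: float) -> "CircuitParams":
        """Copy with R^a multiplied by ``factor`` for the listed genes."""
        if not 0 < factor <= 1:
            raise CircuitError("rate factor must lie in (0, 1]")
        names = self.genes if genes == "all" else tuple(genes)
        R = self.R.copy()
        for gname in names:
            if gname not in self.genes:
                raise CircuitError(f"unknown gene {gname!r}")
            R[self.genes.index(gname)] *= factor
        return replace(self, R=R)


@dataclass(frozen=True)
class Schedule:
    """Timing of the simulated window (minutes from just after division 12).

    nc13 interphase, then mitosis 13 (synthesis gated off), an instantaneous
    division, and the nc14 interphase until gastrulation.  The default
    16 + 5 + 50 = 71 min matches the canonical duration; observation clocks
    are reported as minutes after the thirteenth division (t - division_time).
    """

    nc13_interphase: float = 16.0
    mitosis: float = 5.0
    nc14_duration: float = 50.0

    @property
    def division_time(self) -> float:
        return self.nc13_interphase + self.mitosis

    @property
    def t_end(self) -> float:
        return self.division_time + self.nc14_duration


class ExternalInputs:
    """Tabulated Cad/Tll concentrations, bilinearly interpolated in t and x.

    ``values[name]`` has shape (len(times), len(x)).  Outside the tabulated
    time range the nearest table row is used (constant extrapolation); the
    x grids of simulation phases are interpolated linearly with constant
    extrapolation at the ends.
    """

    def __init__(self, times, x, values: dict[str, np.ndarray]):
        self.times = np.asarray(times, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.values = {}
        for name in EXTERNAL_INPUTS:
            if name not in values:
                raise CircuitError(f"missing external input table {name!r}")
            arr = np.asarray(values[name], dtype=float)
            if arr.shape != (self.times.size, self.x.size):
                raise CircuitError(f"{name} table shape {arr.shape} mismatch")
            if np.any(arr < 0):
                raise CircuitError(f"{name} table must be non-negative")
            self.values[name] = arr

    def sampler(self, xgrid: np.ndarray):
        """Return f(t) -> array (2, n) of (Cad, Tll) at the grid nuclei."""
        xgrid = np.asarray(xgrid, dtype=float)
        onx = np.stack(
            [
                np.vstack([np.interp(xgrid, self.x, row) for row in self.values[name]])
                for name in EXTERNAL_INPUTS
            ]
        )  # (2, nt, n)
        times = self.times

        def f(t: float) -> np.ndarray:
            if t <= times[0]:
                return onx[:, 0]
            if t >= times[-1]:
                return onx[:, -1]
            k = int(np.searchsorted(times, t))
            w = (t - times[k - 1]) / (times[k] - times[k - 1])
            return (1.0 - w) * onx[:, k - 1] + w * onx[:, k]

        return f

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for name in EXTERNAL_INPUTS:
            for i, t in enumerate(self.times):
                for j, x in enumerate(self.x):
                    rows.append(
                        {"input": name, "time_min": t, "xi": x,
                         "value": self.values[name][i, j]}
                    )
        return pd.DataFrame(rows)


def synthetic_external_inputs(
    schedule: Schedule | None = None,
    cad_amplitude: tuple[float, float] = (80.0, 30.0),
    cad_midpoint: float = 0.52,
    cad_width: float = 0.06,
    tll_amplitude: float = 100.0,
    tll_midpoint: float = 0.85,
    tll_width: float = 0.02,
    tll_ramp: tuple[float, float] = (5.0, 35.0),
    n_times: int = 36,
) -> ExternalInputs:
    """Synthetic stand-in tables for the Cad and Tll inputs.

    These emulate the qualitative shape of the real maternal/terminal
    inputs — Cad as a broad posterior-high profile whose amplitude decays
    through nc14, Tll as a sharp posterior sigmoid whose amplitude ramps
    up — and are *synthetic stand-ins*, not measured data.  Every shape
    parameter is configurable and any table of the same layout can replace
    them.
    """
    sched = schedule or Schedule()
    times = np.linspace(0.0, sched.t_end, n_times)
    x = nuclear_grid(N_NUCLEI_NC14)
    cad_shape = 1.0 / (1.0 + np.exp(-(x - cad_midpoint) / cad_width))
    a0, a1 = cad_amplitude
    cad_amp = a0 + (a1 - a0) * times / sched.t_end
    cad = cad_amp[:, None] * cad_shape[None, :]
    tll_shape = 1.0 / (1.0 + np.exp(-(x - tll_midpoint) / tll_width))
    r0, r1 = tll_ramp
    tll_amp = tll_amplitude * np.clip((times - r0) / (r1 - r0), 0.0, 1.0)
    tll = tll_amp[:, None] * tll_shape[None, :]
    return ExternalInputs(times, x, {"Cad": cad, "Tll": tll})


def regulatory_input(
    v: np.ndarray, bcd: np.ndarray, ext: np.ndarray, params: CircuitParams
) -> np.ndarray:
    """Total regulatory input u^a per gene and nucleus.

    ``v`` is (n_genes, n_nuclei), ``bcd`` (n_nuclei,), ``ext``
    (n_inputs, n_nuclei).  u = T v + m bcd + E ext + h.
    """
    v = np.atleast_2d(np.asarray(v, dtype=float))
    bcd = np.asarray(bcd, dtype=float)
    ext = np.atleast_2d(np.asarray(ext, dtype=float))
    ng = len(params.genes)
    if v.shape[0] != ng or ext.shape[0] != len(EXTERNAL_INPUTS):
        raise CircuitError("state/input shape mismatch")
    if v.shape[1] != bcd.size or ext.shape[1] != bcd.size:
        raise CircuitError("nucleus-count mismatch between state and inputs")
    return (
        params.T @ v
        + params.m[:, None] * bcd[None, :]
        + params.E @ ext
        + params.h[:, None]
    )


def rhs(
    t: float,
    v: np.ndarray,
    params: CircuitParams,
    bcd_vals: np.ndarray,
    ext_at,
    synthesis_gate: float = 1.0,
) -> np.ndarray:
    """Time derivative of the state (shape (n_genes, n_nuclei)).

    Synthesis R g(u) (gated off during mitosis), nearest-neighbour
    diffusive exchange with zero-flux ends, first-order degradation.
    ``ext_at`` is a callable t -> (n_inputs, n_nuclei).
    """
    v = np.asarray(v, dtype=float)
    u = regulatory_input(v, bcd_vals, ext_at(t), params)
    syn = synthesis_gate * params.R[:, None] * g(u)
    left = np.empty_like(v)
    left[:, 0] = 0.0
    left[:, 1:] = v[:, :-1] - v[:, 1:]
    right = np.empty_like(v)
    right[:, -1] = 0.0
    right[:, :-1] = v[:, 1:] - v[:, :-1]
    diff = params.D[:, None] * (left + right)
    return syn + diff - params.delta[:, None] * v


@dataclass
class Trajectory:
    """Sampled model output: per-time nucleus grid and concentrations."""

    times: np.ndarray  # minutes since simulation start
    grids: list[np.ndarray]  # per-time nucleus positions (EL)
    states: list[np.ndarray]  # per-time (n_genes, n_nuclei) concentrations
    genes: tuple[str, ...] = GENES
    schedule: Schedule = field(default_factory=Schedule)

    def frame(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """(grid, state) at the sampled time nearest ``t``."""
        i = int(np.argmin(np.abs(self.times - t)))
        return self.grids[i], self.states[i]

    def frame_after_division13(self, minutes: float) -> tuple[np.ndarray, np.ndarray]:
        """(grid, state) at ``minutes`` after the thirteenth division."""
        return self.frame(self.schedule.division_time + minutes)

    def gene_profile(self, t: float, gene: str) -> tuple[np.ndarray, np.ndarray]:
        x, v = self.frame(t)
        return x, v[self.genes.index(gene)]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for t, x, v in zip(self.times, self.grids, self.states):
            for gi, gname in enumerate(self.genes):
                for xi, conc in zip(x, v[gi]):
                    rows.append(
                        {"time_min": t, "nucleus_xi": xi, "gene": gname,
                         "concentration": conc}
                    )
        return pd.DataFrame(rows)


def divide_nuclei(state: np.ndarray) -> np.ndarray:
    """Thirteenth division: each nucleus splits into two daughters that
    inherit the mother's concentrations (n doubles)."""
    return np.repeat(np.asarray(state, dtype=float), 2, axis=1)


def default_initial_state(
    params: CircuitParams,
    hb_level: float = 150.0,
    hb_boundary: float = 0.47,
    hb_steepness: float = 0.02,
) -> np.ndarray:
    """Synthetic nc13-start initial condition.

    Maternal/early Hb forms an anterior step (level ``hb_level`` anterior of
    ``hb_boundary``); Kr, Gt and Kni proteins are first detected in nc13 and
    start at zero.  This is a synthetic stand-in for embryo-derived nc12
    initial data, shaped by the same biology.
    """
    x = nuclear_grid(N_NUCLEI_NC13)
    v0 = np.zeros((len(params.genes), N_NUCLEI_NC13))
    v0[params.genes.index("Hb")] = hb_level / (
        1.0 + np.exp((x - hb_boundary) / hb_steepness)
    )
    return v0


def _integrate(fun, t0, t1, y0, t_eval, solver_opts):
    """Integrate one phase; returns (state at t1, requested times, states)."""
    teval = np.unique(np.append(np.asarray(t_eval, dtype=float), t1))
    sol = solve_ivp(
        fun, (t0, t1), y0, t_eval=teval,
        method=solver_opts.get("method", "LSODA"),
        rtol=solver_opts.get("rtol", 1e-6),
        atol=solver_opts.get("atol", 1e-6),
        max_step=solver_opts.get("max_step", np.inf),
    )
    if not sol.success:
        raise IntegrationError(f"solver failed on [{t0}, {t1}]: {sol.message}")
    keep = np.isin(sol.t, np.asarray(t_eval, dtype=float))
    return sol.y[:, -1], sol.t[keep], sol.y[:, keep]


def simulate(
    params: CircuitParams,
    bcd: BcdGradient,
    ext: ExternalInputs,
    init: np.ndarray | None = None,
    schedule: Schedule | None = None,
    output_times=None,
    solver_opts: dict | None = None,
) -> Trajectory:
    """Integrate the circuit from after division 12 to gastrulation.

    Three consecutive phases share the state: nc13 interphase (synthesis on,
    29 nuclei), mitosis 13 (synthesis gated off), then — after the
    instantaneous division that doubles the grid to 58 daughters inheriting
    their mothers' concentrations — the nc14 interphase.  ``output_times``
    are minutes since simulation start (default: one frame per minute).
    Deterministic for fixed solver options.
    """
    sched = schedule or Schedule()
    opts = solver_opts or {}
    v0 = default_initial_state(params) if init is None else np.asarray(init, float)
    if v0.shape != (len(params.genes), N_NUCLEI_NC13):
        raise CircuitError(
            f"initial state must be shape ({len(params.genes)}, {N_NUCLEI_NC13})"
        )
    if output_times is None:
        output_times = np.arange(0.0, sched.t_end + 1e-9, 1.0)
    output_times = np.asarray(sorted(output_times), dtype=float)
    if output_times.size and (
        output_times[0] < 0 or output_times[-1] > sched.t_end + 1e-9
    ):
        raise CircuitError("output_times must lie within the simulated window")

    x13 = nuclear_grid(N_NUCLEI_NC13)
    x14 = nuclear_grid(N_NUCLEI_NC14)
    bcd13, bcd14 = bcd(x13), bcd(x14)
    ext13, ext14 = ext.sampler(x13), ext.sampler(x14)

    times_out: list[float] = []
    grids: list[np.ndarray] = []
    states: list[np.ndarray] = []

    def record(ts, ys, grid, shape):
        for t, y in zip(ts, ys.T):
            times_out.append(float(t))
            grids.append(grid)
            states.append(y.reshape(shape))

    ng = len(params.genes)
    shape13, shape14 = (ng, N_NUCLEI_NC13), (ng, N_NUCLEI_NC14)
    segments = (
        (0.0, sched.nc13_interphase, 1.0),
        (sched.nc13_interphase, sched.division_time, 0.0),
    )
    y = v0.ravel()
    for t0, t1, gate in segments:
        if t1 <= t0:
            continue
        t_eval = output_times[(output_times >= t0) & (output_times < t1)]

        def fun(t, yy, gate=gate):
            return rhs(t, yy.reshape(shape13), params, bcd13, ext13, gate).ravel()

        y, t_req, y_req = _integrate(fun, t0, t1, y, t_eval, opts)
        record(t_req, y_req, x13, shape13)

    y = divide_nuclei(y.reshape(shape13)).ravel()
    t0, t1 = sched.division_time, sched.t_end
    t_eval = output_times[(output_times >= t0) & (output_times <= t1 + 1e-9)]

    def fun14(t, yy):
        return rhs(t, yy.reshape(shape14), params, bcd14, ext14, 1.0).ravel()

    y, t_req, y_req = _integrate(fun14, t0, t1, y, t_eval, opts)
    record(t_req, y_req, x14, shape14)

    order = np.argsort(times_out)
    return Trajectory(
        times=np.asarray(times_out)[order],
        grids=[grids[i] for i in order],
        states=[states[i] for i in order],
        genes=params.genes,
        schedule=sched,
    )
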