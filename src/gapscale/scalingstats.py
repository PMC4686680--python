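"""Scaling coefficients, threshold crossings and expression-level tests.

The scaling coefficient S of an expression boundary is the slope of the
ordinary least-squares regression of boundary position xi on normalized
embryo length L/<L>, where <L> is the mean of the two inbred lines' mean
lengths and the two lines are pooled within a time class.  S = 0 means the
boundary sits at a fixed fractional position regardless of embryo size
(perfect scaling); S < 0 is under-scaling, S > 0 over-scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class ScalingError(ValueError):
    """Invalid scaling-statistics input."""


@dataclass(frozen=True)
class ScalingResult:
    """OLS slope of xi on L/<L> with t-based 95% CI."""

    S: float
    ci95: tuple[float, float]
    intercept: float
    n: int
    L_ref: float

    def __post_init__(self) -> None:
        if not self.ci95[0] <= self.S <= self.ci95[1]:
            raise ScalingError("95% CI must contain the point estimate")


@dataclass(frozen=True)
class LevelComparison:
    """Two-line expression-level comparison with two-tailed t-test."""

    mean_large: float
    mean_small: float
    p: float
    stars: str  # 'n.s.' | '*' | '**'


def significance_stars(p: float) -> str:
    """Star coding: '**' for p<0.01, '*' for p<0.05, else 'n.s.'."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def scaling_coefficient(
    xis, lengths_um, line_means: tuple[float, float]
) -> ScalingResult:
    """Scaling coefficient S of a boundary from pooled large+small embryos.

    ``xis`` are boundary positions, ``lengths_um`` the matching embryo
    lengths, and ``line_means`` the two lines' mean lengths whose average
    defines the reference <L>.  Returns the OLS slope of xi on L/<L> with a
    t-based 95% confidence interval.
    """
    xi = np.asarray(list(xis), dtype=float)
    L = np.asarray(list(lengths_um), dtype=float)
    if xi.shape != L.shape:
        raise ScalingError("xis and lengths must have equal length")
    n = xi.size
    if n < 3:
        raise ScalingError("need at least 3 embryos for the regression")
    if any(m <= 0 for m in line_means):
        raise ScalingError("line mean lengths must be positive")
    L_ref = 0.5 * (line_means[0] + line_means[1])
    x = L / L_ref
    if np.ptp(x) == 0:
        raise ScalingError("degenerate regression: zero variance in length")
    fit = stats.linregress(x, xi)
    tcrit = stats.t.ppf(0.975, n - 2)
    stderr = fit.stderr if np.isfinite(fit.stderr) else 0.0  # exact fit
    half = tcrit * stderr
    return ScalingResult(
        S=float(fit.slope),
        ci95=(float(fit.slope - half), float(fit.slope + half)),
        intercept=float(fit.intercept),
        n=n,
        L_ref=L_ref,
    )


def threshold_crossings(
    xi_grid, mean_profile, thresholds, side: str
) -> list[float | None]:
    """Positions where an unnormalized mean profile crosses given thresholds.

    For each threshold the linearly interpolated crossing on the stated side
    of the profile peak is returned; with several crossings on that side the
    one nearest the peak is taken.  A threshold the profile never reaches on
    that side yields ``None`` (missing crossings are data, not errors: they
    keep time-series tables rectangular).
    """
    xi = np.asarray(list(xi_grid), dtype=float)
    vals = np.asarray(list(mean_profile), dtype=float)
    if xi.size == 0 or vals.size == 0:
        raise ScalingError("empty profile")
    if xi.shape != vals.shape:
        raise ScalingError("grid and profile must have equal length")
    if side not in ("anterior", "posterior"):
        raise ScalingError(f"unknown side {side!r}")
    peak = int(np.argmax(vals))
    if side == "anterior":
        seg_xi, seg_v = xi[: peak + 1], vals[: peak + 1]
    else:
        seg_xi, seg_v = xi[peak:], vals[peak:]
    out: list[float | None] = []
    for thr in thresholds:
        if thr <= 0:
            raise ScalingError("thresholds must be positive")
        v = seg_v - thr
        crossings = []
        for i in range(len(v) - 1):
            a, b = v[i], v[i + 1]
            if a == 0.0:
                crossings.append(seg_xi[i])
            elif a * b < 0:
                crossings.append(
                    seg_xi[i] + (seg_xi[i + 1] - seg_xi[i]) * (-a) / (b - a)
                )
        if len(v) and v[-1] == 0.0:
            crossings.append(seg_xi[-1])
        if not crossings:
            out.append(None)
        else:
            out.append(float(crossings[-1] if side == "anterior" else crossings[0]))
    return out


def peak_level(bins, domain_bins) -> float:
    """Expression level of a domain: mean of its three highest bins (a.u.)."""
    b = np.asarray(list(bins), dtype=float)
    dom = np.asarray(list(domain_bins), dtype=int)
    if dom.size < 3:
        raise ScalingError("domain must span at least 3 bins")
    top = np.sort(b[dom])[-3:]
    return float(top.mean())


def level_compare(levels_large, levels_small, welch: bool = False) -> LevelComparison:
    """Two-sample two-tailed Student's t-test on per-embryo peak levels.

    Equal-variance form by default (``welch=True`` for the unequal-variance
    variant).  Two constant groups with equal means are reported as p = 1.
    """
    a = np.asarray(list(levels_large), dtype=float)
    b = np.asarray(list(levels_small), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ScalingError("need n >= 2 per group")
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
    return LevelComparison(
        mean_large=float(a.mean()),
        mean_small=float(b.mean()),
        p=p,
        stars=significance_stars(p),
    )
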