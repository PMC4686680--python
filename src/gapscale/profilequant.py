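"""From raw intensity samples to background-subtracted, normalized profiles.

The AP axis of each embryo is divided into 50 equal bins (bin i covers
relative position [i/50, (i+1)/50), anterior = 0); intensities are in
arbitrary units that are linear in cytoplasmic mRNA concentration.  The
processing chain is:

1. ``bin_to_50``        - bin raw (position, intensity) samples;
2. ``subtract_background`` - embryo-specific constant subtraction using a
   declared non-expression window;
3. ``normalize_domain`` - per-domain normalization setting the mean of the
   three highest bins to 1 (posterior *tll* excludes the last three bins to
   avoid pole-cell signal);
4. ``group_mean_profile`` - per-bin mean and s.d. across embryos.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthgen import BIN_CENTRES, N_BINS


class ProfileError(ValueError):
    """Invalid profile-processing input."""


class DegenerateDomainError(ProfileError):
    """Domain expression too low to normalize reliably."""


@dataclass(frozen=True)
class EmbryoProfile:
    """One embryo x gene intensity record on the 50-bin AP grid."""

    embryo_id: str
    line: str
    length_um: float
    gene: str
    bins: np.ndarray  # shape (50,), a.u.
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=float)
        if b.shape != (N_BINS,):
            raise ProfileError(f"expected {N_BINS} bins, got shape {b.shape}")
        object.__setattr__(self, "bins", b)


@dataclass(frozen=True)
class MeanProfile:
    """Per-bin mean and s.d. over a group of embryos."""

    gene: str
    mean: np.ndarray  # (50,)
    sd: np.ndarray  # (50,)
    n: int


def bin_to_50(samples) -> np.ndarray:
    """Bin (xi, intensity) samples into the 50-bin grid by per-bin mean.

    ``samples`` is an iterable of (relative position in [0, 1], intensity)
    pairs; xi = 1.0 falls in the last bin.  Bins that receive no sample are
    filled by linear interpolation from their non-empty neighbours (constant
    extrapolation at the ends).
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.size == 0:
        raise ProfileError("no samples")
    xi, val = arr[:, 0], arr[:, 1]
    if np.any((xi < 0) | (xi > 1)):
        raise ProfileError("sample positions must lie in [0, 1]")
    idx = np.minimum((xi * N_BINS).astype(int), N_BINS - 1)
    sums = np.bincount(idx, weights=val, minlength=N_BINS)
    counts = np.bincount(idx, minlength=N_BINS)
    filled = counts > 0
    if not filled.any():
        raise ProfileError("no samples")  # pragma: no cover - guarded above
    out = np.empty(N_BINS)
    out[filled] = sums[filled] / counts[filled]
    if not filled.all():
        out[~filled] = np.interp(
            BIN_CENTRES[~filled], BIN_CENTRES[filled], out[filled]
        )
    return out


def subtract_background(profile: EmbryoProfile, background_bins) -> EmbryoProfile:
    """Subtract the mean of a declared non-expression window from all bins.

    The background window is embryo- and gene-specific; the subtracted
    profile is clipped at zero to keep intensities non-negative.
    """
    bg = np.asarray(list(background_bins), dtype=int)
    if bg.size == 0:
        raise ProfileError("background window is empty")
    if np.any((bg < 0) | (bg >= N_BINS)):
        raise ProfileError("background bin index out of range")
    level = float(profile.bins[bg].mean())
    return replace(
        profile,
        bins=np.clip(profile.bins - level, 0.0, None),
        background_subtracted=True,
    )


def _top3_mean(values: np.ndarray) -> float:
    top = np.sort(values)[-3:]
    return float(top.mean())


def normalize_domain(
    profile: EmbryoProfile, domain_bins, posterior_tll_rule: bool = False
) -> np.ndarray:
    """Normalize a domain so the mean of its three highest bins equals 1.

    Returns the normalized 50-bin vector (normalization uses only the
    domain's bins but is applied across all positions so flank crossings
    remain measurable).  With ``posterior_tll_rule`` the most posterior
    three bins are excluded from the top-3 computation, preventing
    pole-cell artefacts from setting the scale.
    """
    dom = np.asarray(list(domain_bins), dtype=int)
    if posterior_tll_rule:
        dom = dom[dom < N_BINS - 3]
    if dom.size < 3:
        raise ProfileError("domain must span at least 3 usable bins")
    scale = _top3_mean(profile.bins[dom])
    if scale <= 0:
        raise DegenerateDomainError(
            f"{profile.gene}: top-3 mean is 0; expression too low to normalize"
        )
    return profile.bins / scale


def group_mean_profile(profiles: list[EmbryoProfile]) -> MeanProfile:
    """Per-bin mean and s.d. (ddof=1; zero for a single embryo) of a group."""
    if not profiles:
        raise ProfileError("empty group")
    genes = {p.gene for p in profiles}
    if len(genes) > 1:
        raise ProfileError(f"mixed genes in group: {sorted(genes)}")
    stack = np.stack([p.bins for p in profiles])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(profiles) > 1 else np.zeros(N_BINS)
    return MeanProfile(gene=profiles[0].gene, mean=mean, sd=sd, n=len(profiles))


#: Default background windows (bin indices) per gene: a region where the
#: gene is not expressed in the trunk.  These ship as configuration because
#: non-expression regions are gene-specific.
DEFAULT_BACKGROUND_BINS = {
    "hb": range(30, 35),
    "Kr": range(0, 5),
    "gt": range(25, 30),
    "kni": range(0, 5),
    "otd": range(20, 25),
    "tll": range(20, 25),
}
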