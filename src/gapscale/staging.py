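"""Nuclear-cycle and nc14 time-class assignment from staging features.

Embryos are first sorted into cleavage cycle nc13 vs nc14 by the number of
nuclei on the dorsal side (counts double each syncytial division).  nc14
embryos are then placed into nine time classes T1..T9:

* invagination ratio < 15%  -> early classes T1/T2, split by ranking the
  measured nuclear lengths (median split within the analysed cohort);
* ratio in [15, 25) -> T3, [25, 35) -> T4, [35, 45) -> T5, [45, 55) -> T6,
  [55, 65) -> T7, [65, 75) -> T8, >= 75 -> T9.

The nine classes correspond to approximately 0-13.5, 13.5-25, 25-31, 31-35,
35-38, 38-42, 42-45, 45-48 and 48-60 min after the thirteenth nuclear
division.  Intervals are left-closed/right-open (the cut-off list carries no
closure; this convention is frozen here), except T9 which is closed above
at 100%.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthgen import INVAGINATION_INTERVALS, NC14_NUCLEI_THRESHOLD

#: Approximate minutes after the 13th nuclear division for T1..T9.
NC14_CLASS_MINUTES = {
    "T1": (0.0, 13.5),
    "T2": (13.5, 25.0),
    "T3": (25.0, 31.0),
    "T4": (31.0, 35.0),
    "T5": (35.0, 38.0),
    "T6": (38.0, 42.0),
    "T7": (42.0, 45.0),
    "T8": (45.0, 48.0),
    "T9": (48.0, 60.0),
}

EARLY_CUTOFF_PCT = 15.0


class StagingError(ValueError):
    """Invalid staging input."""


def invagination_ratio(depths, cortex_lengths) -> float:
    """Mean percent invagination over three dorsal locations.

    Each location contributes ``100 * depth / cortex_length``; the embryo's
    ratio is the average of the three.
    """
    depths = np.asarray(depths, dtype=float)
    cortex = np.asarray(cortex_lengths, dtype=float)
    if depths.shape != cortex.shape:
        raise StagingError("depths and cortex_lengths must have equal shape")
    if np.any(cortex <= 0):
        raise StagingError("cortex lengths must be positive")
    if np.any(depths < 0):
        raise StagingError("invagination depths must be non-negative")
    return float(np.mean(100.0 * depths / cortex))


def classify_cycle(n_nuclei_dorsal: int, threshold: int = NC14_NUCLEI_THRESHOLD) -> str:
    """nc13 vs nc14 from the dorsal nucleus count.

    nc14 iff ``n_nuclei_dorsal >= threshold`` (counts at the threshold are
    nc14 by convention).
    """
    if n_nuclei_dorsal < 0:
        raise StagingError("nucleus count must be non-negative")
    return "nc14" if n_nuclei_dorsal >= threshold else "nc13"


def classify_invagination(ratio_pct: float) -> str | None:
    """Map an invagination ratio to T3..T9, or None for the early (<15%) band."""
    if ratio_pct < 0 or ratio_pct > 100:
        raise StagingError("invagination ratio must lie in [0, 100]")
    if ratio_pct < EARLY_CUTOFF_PCT:
        return None
    for cls, (lo, hi) in INVAGINATION_INTERVALS.items():
        if cls == "T9":
            if ratio_pct >= lo:
                return cls
        elif lo <= ratio_pct < hi:
            return cls
    raise AssertionError("unreachable: intervals cover [15, 100]")


def assign_time_classes(staging: pd.DataFrame) -> pd.Series:
    """Assign T1..T9 to a cohort of nc14 embryos.

    ``staging`` needs columns ``invagination_pct`` and ``nuclear_length_um``
    (the synthetic-cohort staging dialect).  Embryos under 15% invagination
    are split T1/T2 at the median of their nuclear lengths: strictly below
    the median -> T1, at or above -> T2 (ties therefore resolve to T2; with
    equal-length runs straddling the median the stable input order decides
    which side of the count balance they fall on).

    Returns a Series of labels indexed like ``staging``.
    """
    if len(staging) == 0:
        raise StagingError("empty cohort")
    for col in ("invagination_pct", "nuclear_length_um"):
        if col not in staging.columns:
            raise StagingError(f"staging table missing column {col!r}")

    ratios = staging["invagination_pct"].to_numpy(dtype=float)
    labels = pd.Series(index=staging.index, dtype=object)
    early = ratios < EARLY_CUTOFF_PCT
    for idx, r in zip(staging.index[~early], ratios[~early]):
        labels.loc[idx] = classify_invagination(r)
    if early.any():
        nuc = staging.loc[early, "nuclear_length_um"].to_numpy(dtype=float)
        med = float(np.median(nuc))
        sub = np.where(nuc < med, "T1", "T2")
        labels.loc[staging.index[early]] = sub
    return labels


def stage_cohort(
    staging: pd.DataFrame, threshold: int = NC14_NUCLEI_THRESHOLD
) -> pd.DataFrame:
    """Full staging: cycle call plus nc14 time class for every embryo.

    Returns a copy of ``staging`` with added ``cycle`` and ``time_class``
    columns (``time_class`` is the cycle label, 'nc13', for pre-nc14 embryos).
    """
    out = staging.copy()
    out["cycle"] = [
        classify_cycle(int(n), threshold) for n in out["n_nuclei_dorsal"]
    ]
    out["time_class"] = out["cycle"]
    nc14 = out["cycle"] == "nc14"
    if nc14.any():
        out.loc[nc14, "time_class"] = assign_time_classes(out.loc[nc14])
    return out
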