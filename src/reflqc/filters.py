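"""Resolution-window exclusions: ice-ring detection and low-resolution cutoff.

Ice rings contaminate narrow resolution windows around the hexagonal-ice
powder spacings (3.90, 3.67, 3.44 Å by default).  Detection compares the
median merged intensity inside each candidate window against a local
baseline built from the two flanking windows of equal total width, using a
robust z-score of the in-window median:

    z = (median_in - median_flank) / (1.4826 * MAD_flank * 1.2533 / sqrt(n_in))

The flanking baseline straddles the window symmetrically, so the smooth
Wilson falloff cancels to first order and only a genuine local excess
registers.  Exclusion removes whole resolution regions (distinct from the
per-observation 4-sigma rejection, which is kept independent so the
interplay of the two paths can be studied), and reports the completeness
cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .merging import MergedData, merge, observations_frame
from .simulate import ICE_RING_CENTERS
from .symmetry import LaueClass, map_to_asu_array

__all__ = ["IceWindow", "detect_ice_rings", "apply_exclusions"]


@dataclass(frozen=True)
class IceWindow:
    """A flagged (detected) ice-contaminated resolution window."""

    d_center: float
    half_width: float
    zscore: float
    n_excluded: int = 0


def _check_disjoint(windows: Sequence[IceWindow]) -> None:
    spans = sorted((w.d_center - w.half_width, w.d_center + w.half_width) for w in windows)
    for (lo1, hi1), (lo2, hi2) in zip(spans[:-1], spans[1:]):
        if hi1 > lo2:
            raise ValueError("ice windows overlap")


def detect_ice_rings(
    merged: MergedData,
    candidate_centers: Sequence[float] = ICE_RING_CENTERS,
    half_width: float = 0.05,
    z_threshold: float = 4.0,
    min_groups: int = 5,
) -> list[IceWindow]:
    """Flag candidate windows whose merged intensities show a local excess.

    Returns only the windows whose robust z-score exceeds ``z_threshold``;
    candidates with fewer than ``min_groups`` merged groups inside the
    window or in the flanks are never flagged.
    """
    if not candidate_centers:
        return []
    d = merged.groups["d"].to_numpy()
    i_mean = merged.groups["I_mean"].to_numpy()
    out: list[IceWindow] = []
    for c in candidate_centers:
        inside = np.abs(d - c) <= half_width
        flank = (np.abs(d - c) > half_width) & (np.abs(d - c) <= 3 * half_width)
        n_in, n_fl = int(inside.sum()), int(flank.sum())
        if n_in < min_groups or n_fl < min_groups:
            continue
        baseline = float(np.median(i_mean[flank]))
        mad = float(np.median(np.abs(i_mean[flank] - baseline)))
        scale = 1.4826 * mad
        if scale == 0:
            continue
        se_median = scale * 1.2533 / np.sqrt(n_in)
        z = (float(np.median(i_mean[inside])) - baseline) / se_median
        if z > z_threshold:
            out.append(IceWindow(c, half_width, zscore=float(z), n_excluded=n_in))
    _check_disjoint(out)
    return out


def apply_exclusions(
    observations: pd.DataFrame,
    windows: Sequence[IceWindow],
    low_res_cutoff: Optional[float] = None,
    *,
    lc: LaueClass,
    unique_reference: set[tuple[int, int, int]],
) -> tuple[pd.DataFrame, float, float]:
    """Flag ice-window and low-resolution observations; report completeness.

    Observations with d inside any window gain ``rejected_ice``; those with
    d > ``low_res_cutoff`` gain ``rejected_lowres``.  Completeness before
    and after is the fraction of ``unique_reference`` covered by at least
    one unflagged observation.
    """
    _check_disjoint(list(windows))
    if not unique_reference:
        raise ValueError("unique_reference must be non-empty")
    df = observations_frame(observations)
    d = df["d"].to_numpy()

    def completeness(frame: pd.DataFrame) -> float:
        live = frame
        for col in ("rejected_outlier", "rejected_ice", "rejected_lowres"):
            live = live[~live[col].to_numpy(dtype=bool)]
        if len(live) == 0:
            return 0.0
        asu = map_to_asu_array(live[["h", "k", "l"]].to_numpy(dtype=np.int64), lc)
        present = {tuple(int(x) for x in row) for row in asu}
        return len(present & unique_reference) / len(unique_reference)

    before = completeness(df)
    ice = np.zeros(len(df), dtype=bool)
    for w in windows:
        ice |= np.abs(d - w.d_center) <= w.half_width
    df.loc[ice, "rejected_ice"] = True
    if low_res_cutoff is not None:
        df.loc[d > low_res_cutoff, "rejected_lowres"] = True
    after = completeness(df)
    return df, before, after
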