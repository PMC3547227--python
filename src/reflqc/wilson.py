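"""Wilson-B estimation and Laue-class discrimination.

The Wilson plot regresses the log of shell-averaged merged intensities on
s^2 = (sin(theta)/lambda)^2 = (1/(2d))^2; under the Wilson model
<I>(s) = C * exp(-2 B s^2) the slope is -2B.  The fit window excludes the
low-resolution non-Wilson regime (d > 4.5 Å by default, where solvent and
gross-structure scattering dominate).

Laue-class discrimination merges the same observations independently under
the tetragonal holohedry 4/mmm and its orthorhombic subgroup mmm and
compares the multiplicity-corrected residual R_meas.  If the crystal truly
has only mmm symmetry, pooling the pseudo-equivalent (h,k,l)/(k,h,l) pairs
inflates the 4/mmm residual; a delta above threshold decides mmm.  R_meas
is used rather than R_merge because it is unbiased under the differing
multiplicities of the two merge trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .merging import MergedData, MergeStats, compute_stats, merge, observations_frame
from .symmetry import UnitCell, generate_unique, get_laue_class

__all__ = [
    "WilsonFitError",
    "WilsonModel",
    "WilsonResults",
    "wilson_fit",
    "LaueUndecidableError",
    "LaueDecision",
    "laue_compare",
]


class WilsonFitError(RuntimeError):
    """Fewer than three usable shells in the fit window."""


class LaueUndecidableError(RuntimeError):
    """Too few multiply-observed groups in one of the compared classes."""


@dataclass
class WilsonResults:
    """Fitted Wilson plot: B (Å^2), intercept ln C, and fit diagnostics."""

    B: float
    lnC: float
    stderr_B: float
    s2_range: tuple[float, float]
    n_shells_used: int
    shell_table: pd.DataFrame = field(repr=False, default=None)

    def predicted_mean(self, s2):
        return np.exp(self.lnC - 2.0 * self.B * np.asarray(s2))

    def summary(self) -> str:
        lines = [
            "Wilson fit  ln<I> = lnC - 2 B s^2",
            "=" * 40,
            f"B (Å^2)        {self.B:10.3f} +/- {self.stderr_B:.3f}",
            f"lnC            {self.lnC:10.3f}",
            f"shells used    {self.n_shells_used:7d}",
            f"s^2 range      [{self.s2_range[0]:.5f}, {self.s2_range[1]:.5f}]",
        ]
        return "\n".join(lines)


class WilsonModel:
    """Ordinary-least-squares Wilson plot on shell-averaged merged intensities.

    Parameters
    ----------
    merged : MergedData
        Merged reflections (group means and d-spacings are used).
    d_fit_max : float
        Low-resolution limit of the fit window (Å); larger spacings are
        outside the Wilson regime and are excluded.
    n_shells : int
        Equal-group-count shells over s^2 within the window.
    """

    def __init__(self, merged: MergedData, d_fit_max: float = 4.5, n_shells: int = 20):
        self.merged = merged
        self.d_fit_max = d_fit_max
        self.n_shells = n_shells

    def fit(self) -> WilsonResults:
        g = self.merged.groups
        g = g[g["d"] <= self.d_fit_max]
        if len(g) < 3:
            raise WilsonFitError("fewer than 3 groups inside the fit window")
        s2 = (0.5 / g["d"].to_numpy()) ** 2
        i_mean = g["I_mean"].to_numpy()
        order = np.argsort(s2, kind="stable")
        n_shells = max(3, min(self.n_shells, len(g)))
        xs, ys, counts = [], [], []
        for idx in np.array_split(order, n_shells):
            if len(idx) == 0:
                continue
            mi = i_mean[idx].mean()
            if mi <= 0:  # non-positive shell mean: no log, drop
                continue
            xs.append(s2[idx].mean())
            ys.append(np.log(mi))
            counts.append(len(idx))
        if len(xs) < 3:
            raise WilsonFitError("fewer than 3 shells with positive mean intensity")
        xs_a, ys_a = np.asarray(xs), np.asarray(ys)
        res = sps.linregress(xs_a, ys_a)
        shell_table = pd.DataFrame(
            {"mean_s2": xs_a, "ln_mean_I": ys_a, "n_groups": counts}
        )
        return WilsonResults(
            B=float(-res.slope / 2.0),
            lnC=float(res.intercept),
            stderr_B=float(res.stderr / 2.0),
            s2_range=(float(xs_a.min()), float(xs_a.max())),
            n_shells_used=len(xs_a),
            shell_table=shell_table,
        )


def wilson_fit(merged: MergedData, d_fit_max: float = 4.5, n_shells: int = 20) -> WilsonResults:
    """Functional wrapper around :class:`WilsonModel`."""
    return WilsonModel(merged, d_fit_max=d_fit_max, n_shells=n_shells).fit()


# ---------------------------------------------------------------------------
# Laue-class discrimination


@dataclass
class LaueDecision:
    """Merging statistics under both Laue classes and the resulting choice."""

    stats_by_class: dict[str, MergeStats]
    chosen: str
    delta_r_meas: float  # r_meas(4/mmm) - r_meas(mmm)

    def summary(self) -> str:
        rows = []
        for name, st in self.stats_by_class.items():
            rows.append(
                f"  {name:7s} R_merge/R_meas/R_pim = "
                f"{st.r_merge:.4f}/{st.r_meas:.4f}/{st.r_pim:.4f}  "
                f"(n_unique={st.n_unique}, redundancy={st.redundancy:.1f})"
            )
        return "\n".join(
            ["Laue-class comparison", "=" * 40, *rows,
             f"  delta R_meas = {self.delta_r_meas:+.4f}  ->  chosen {self.chosen}"]
        )


def laue_compare(
    observations: pd.DataFrame,
    cell: UnitCell,
    classes: Sequence[str] = ("4/mmm", "mmm"),
    delta_threshold: float = 0.02,
    n_shells: int = 10,
    min_multi_groups: int = 50,
) -> LaueDecision:
    """Merge independently under each class and decide by the R_meas gap.

    ``mmm`` is chosen iff r_meas(4/mmm) - r_meas(mmm) exceeds
    ``delta_threshold``; otherwise the higher-symmetry 4/mmm is retained.
    """
    if set(classes) != {"4/mmm", "mmm"}:
        raise ValueError("classes must be ('4/mmm', 'mmm')")
    df = observations_frame(observations)
    d = df["d"].to_numpy()
    d_min, d_max = float(d.min()), float(d.max())
    stats_by_class: dict[str, MergeStats] = {}
    for name in classes:
        lc = get_laue_class(name)
        merged = merge(df, lc)
        n_multi = int((merged.groups["n"] >= 2).sum())
        if n_multi < min_multi_groups:
            raise LaueUndecidableError(
                f"{name}: only {n_multi} multiply-observed groups (< {min_multi_groups})"
            )
        ref = generate_unique(cell, lc, d_min, d_max)
        stats_by_class[name] = compute_stats(merged, ref, cell, n_shells=n_shells)
    delta = stats_by_class["4/mmm"].r_meas - stats_by_class["mmm"].r_meas
    chosen = "mmm" if delta > delta_threshold else "4/mmm"
    return LaueDecision(stats_by_class=stats_by_class, chosen=chosen, delta_r_meas=float(delta))
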