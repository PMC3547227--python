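"""Intensity variance model, chi-square normalisation and outlier rejection.

The variance of an integrated intensity is modelled as a second-order
polynomial in I,

    sigma^2 = k0 + k1*I + k2*I^2,

physically decomposed as

    sigma^2 = (sigma_dark^2 + sigma_read^2) + (sigma_bg^2 + I) + (g*I)^2,

so k0 collects the dark-current, read-out and background contributions,
k1 = 1 is the Poisson term (intensities on the photon-count scale) and
k2 = g^2 is a fractional instability term.  Integration programs typically
deliver sigmas from the first two terms only; scaling then refines a
correction

    sigma_new^2 = K * (sigma^2 + (g*<I>)^2)

so that the goodness-of-fit of symmetry equivalents to their group means,

    chi^2 = sum_h [N_h/(N_h-1)] sum_i (I_i - <I>_h)^2 / sigma_i^2  /  sum_h N_h,

is close to 1.  ``chi2`` here is the observation-count-weighted average,
which has expectation 1 when the sigmas are correctly scaled; the
per-group terms N*sum((I-<I>)^2/sigma^2)/(N-1) are exposed separately.

:class:`SigmaScalingModel` refines (K, g) by least squares on binned
chi-square: groups are binned by <I> and (K, g) minimise
sum_bins (chi2_bin - 1)^2.  Because chi2_bin(K, g) = f_bin(g)/K, the
optimal K for fixed g is the closed form K = sum(f^2)/sum(f), reducing the
search to a deterministic one-dimensional bounded minimisation over g.

Outliers among symmetry equivalents are rejected iteratively at
|I - <I>|/sigma > 4 (two-sided), with group means recomputed after each
pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .merging import MergedData, merge

__all__ = [
    "NoiseModel",
    "ErrorModel",
    "variance_model",
    "delivered_sigma",
    "group_chi2_terms",
    "chi2",
    "SigmaScalingModel",
    "SigmaScalingResults",
    "refine_error_model",
    "apply_error_model",
    "reject_outliers",
    "RejectionResult",
]


@dataclass(frozen=True)
class NoiseModel:
    """Generator/detector noise constants (ADU scale).

    k0 = sigma_dark^2 + sigma_read^2 + sigma_bg^2 is the intensity-
    independent variance floor; ``g_true`` the fractional instability;
    ``K_true`` a global misestimation factor applied to the additive and
    Poisson terms.
    """

    sigma_dark: float = 3.0
    sigma_read: float = 3.0
    sigma_bg: float = 5.0
    gain: float = 1.0  # ADU per photon
    g_true: float = 0.03
    K_true: float = 1.0
    include_poisson: bool = True  # False: noiseless debug data (no I term)

    def __post_init__(self) -> None:
        if min(self.sigma_dark, self.sigma_read, self.sigma_bg) < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if not 0 <= self.g_true < 1:
            raise ValueError("g_true must lie in [0, 1)")
        if self.K_true <= 0:
            raise ValueError("K_true must be positive")

    @property
    def k0(self) -> float:
        return self.sigma_dark**2 + self.sigma_read**2 + self.sigma_bg**2

    @property
    def k_coefficients(self) -> tuple[float, float, float]:
        """(k0, k1, k2) of the polynomial form."""
        return (self.k0, 1.0, self.g_true**2)


def variance_model(I, nm: NoiseModel):
    """True observation variance: (s_dark^2+s_read^2) + (s_bg^2 + max(I,0)) + (g I)^2."""
    I = np.asarray(I, dtype=float)
    return (
        nm.sigma_dark**2
        + nm.sigma_read**2
        + (nm.sigma_bg**2 + np.maximum(I, 0.0))
        + (nm.g_true * I) ** 2
    )


def delivered_sigma(I, nm: NoiseModel):
    """First-two-terms sigma, as integration programs deliver it: sqrt(k0 + max(I,0))."""
    I = np.asarray(I, dtype=float)
    return np.sqrt(nm.k0 + np.maximum(I, 0.0))


# ---------------------------------------------------------------------------
# chi-square


def _group_arrays(merged: MergedData):
    """Per-observation arrays restricted to groups with n >= 2."""
    groups = merged.groups
    df = merged.obs
    n = groups["n"].to_numpy()
    multi = n >= 2
    if not multi.any():
        raise ValueError("chi-square undefined: no group has two or more observations")
    gid = df["group"].to_numpy()
    keep = multi[gid]
    return df[keep], groups, gid[keep], n


def group_chi2_terms(merged: MergedData) -> pd.Series:
    """Per-group terms N * sum_i (I_i - <I>)^2/sigma_i^2 / (N - 1) for groups with n >= 2."""
    df, groups, gid, n = _group_arrays(merged)
    dev2 = (df["I"].to_numpy() - groups["I_mean"].to_numpy()[gid]) ** 2
    s = dev2 / df["sigma"].to_numpy() ** 2
    ssum = np.bincount(gid, weights=s, minlength=len(groups))
    multi = n >= 2
    terms = n[multi] * ssum[multi] / (n[multi] - 1)
    return pd.Series(terms, index=groups.index[multi], name="chi2_term")


def chi2(merged: MergedData) -> float:
    """Observation-count-weighted average of the per-group chi-square terms.

    Expectation 1 when the sigmas correctly describe the scatter of
    symmetry equivalents about their group means.
    """
    terms = group_chi2_terms(merged)
    n = merged.groups.loc[terms.index, "n"]
    return float(terms.sum() / n.sum())


# ---------------------------------------------------------------------------
# (K, g) refinement


@dataclass
class ErrorModel:
    """Refined sigma-correction parameters sigma_new^2 = K*(sigma^2 + (g <I>)^2)."""

    K: float
    g: float
    chi2_before: float
    chi2_after: float
    converged: bool = True


@dataclass
class SigmaScalingResults:
    """Results of a :class:`SigmaScalingModel` fit."""

    K: float
    g: float
    chi2_before: float
    chi2_after: float
    converged: bool
    n_groups: int
    n_bins: int
    bin_table: pd.DataFrame  # per-bin <I> and chi2 before/after
    objective: float

    @property
    def params(self) -> dict[str, float]:
        return {"K": self.K, "g": self.g}

    def as_error_model(self) -> ErrorModel:
        return ErrorModel(self.K, self.g, self.chi2_before, self.chi2_after, self.converged)

    def apply(self, merged: MergedData) -> MergedData:
        return apply_error_model(merged, self.as_error_model())

    def summary(self) -> str:
        lines = [
            "Sigma scaling (SADABS-style error model)",
            "=" * 44,
            f"K (variance scale)      {self.K:10.4f}",
            f"g (fractional error)    {self.g:10.4f}",
            f"chi2 before             {self.chi2_before:10.4f}",
            f"chi2 after              {self.chi2_after:10.4f}",
            f"groups (n>=2) / bins    {self.n_groups:7d} / {self.n_bins}",
            f"converged               {str(self.converged):>10s}",
            "",
            "Per-bin chi2:",
            self.bin_table.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class SigmaScalingModel:
    """Refine (K, g) of sigma_new^2 = K*(sigma^2 + (g <I>)^2) on merged data.

    Parameters
    ----------
    merged : MergedData
        Output of :func:`reflqc.merging.merge` with delivered sigmas.
    n_bins : int
        Equal-count bins of groups by <I> for the binned-chi2 target.
    g_bounds, k_bounds : tuple
        Search bounds; the group mean <I> inside (g <I>)^2 is held at the
        delivered-sigma weighted mean during refinement.
    min_groups : int
        Refinement floor: fewer multiply-observed groups raises.
    trim : float or None
        Robustness guard: observations deviating more than ``trim`` input
        sigmas from their group mean (iteratively, with means recomputed)
        are excluded from the refinement sums, so gross outliers such as
        ice-contaminated measurements cannot drag (K, g) away from the
        bulk of the data.  The final 4-sigma rejection still operates on
        the full data set with the corrected sigmas.  None disables.
    """

    def __init__(
        self,
        merged: MergedData,
        n_bins: int = 10,
        g_bounds: tuple[float, float] = (0.0, 0.2),
        k_bounds: tuple[float, float] = (0.1, 10.0),
        min_groups: int = 50,
        trim: float | None = 10.0,
    ):
        self.merged = merged
        self.n_bins = n_bins
        self.g_bounds = g_bounds
        self.k_bounds = k_bounds
        self.min_groups = min_groups
        self.trim = trim

    def fit(self) -> SigmaScalingResults:
        chi2_raw = chi2(self.merged)
        if self.trim is not None:
            merged, _ = reject_outliers(self.merged, threshold=self.trim)
        else:
            merged = self.merged
        df, groups, gid, n = _group_arrays(merged)
        multi_ids = np.flatnonzero(n >= 2)
        if len(multi_ids) < self.min_groups:
            raise ValueError(
                f"need at least {self.min_groups} groups with n >= 2, have {len(multi_ids)}"
            )
        chi2_before = chi2_raw

        i_mean = groups["I_mean"].to_numpy()
        dev2 = (df["I"].to_numpy() - i_mean[gid]) ** 2
        sig2 = df["sigma"].to_numpy() ** 2
        im_obs = i_mean[gid]
        n_obs_per_group = n.astype(float)

        # degenerate input: no scatter to calibrate against
        if float(dev2.max(initial=0.0)) == 0.0 or np.ptp(df["I"].to_numpy()) == 0.0:
            return SigmaScalingResults(
                K=1.0, g=0.0, chi2_before=chi2_before, chi2_after=chi2_before,
                converged=False, n_groups=len(multi_ids), n_bins=self.n_bins,
                bin_table=pd.DataFrame(), objective=np.nan,
            )

        # equal-count bins of multiply-observed groups by <I>
        order = np.argsort(i_mean[multi_ids], kind="stable")
        n_bins = min(self.n_bins, len(multi_ids))
        bin_of_group = np.full(len(groups), -1, dtype=np.int64)
        for b, idx in enumerate(np.array_split(order, n_bins)):
            bin_of_group[multi_ids[idx]] = b
        bin_obs = bin_of_group[gid]

        nh_term = n_obs_per_group / np.maximum(n_obs_per_group - 1, 1.0)
        # observation count per bin (each observation contributes once)
        denom_bin = np.bincount(bin_obs, minlength=n_bins).astype(float)

        def f_bins(g: float) -> np.ndarray:
            s = dev2 / (sig2 + (g * im_obs) ** 2)
            s_group = np.bincount(gid, weights=s, minlength=len(groups))
            term = nh_term * s_group  # N/(N-1) * sum
            num = np.bincount(bin_obs, weights=term[gid] / n_obs_per_group[gid], minlength=n_bins)
            return num / denom_bin

        k_lo, k_hi = self.k_bounds

        def profile(g: float) -> tuple[float, float]:
            f = f_bins(g)
            k = float(np.clip(f @ f / f.sum(), k_lo, k_hi))
            obj = float(((f / k - 1.0) ** 2).sum())
            return obj, k

        # coarse deterministic grid, then bounded 1-D polish
        g_lo, g_hi = self.g_bounds
        grid = np.linspace(g_lo, g_hi, 41)
        objs = [profile(g)[0] for g in grid]
        g0 = grid[int(np.argmin(objs))]
        lo = max(g_lo, g0 - (grid[1] - grid[0]))
        hi = min(g_hi, g0 + (grid[1] - grid[0]))
        res = minimize_scalar(lambda g: profile(g)[0], bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        g_hat = float(res.x) if res.fun <= min(objs) else float(g0)
        obj, k_hat = profile(g_hat)

        model = ErrorModel(k_hat, g_hat, chi2_before, np.nan)
        corrected = apply_error_model(merged, model)
        chi2_after = chi2(corrected)
        model.chi2_after = chi2_after

        f_before = f_bins(0.0) / 1.0
        f_after = f_bins(g_hat) / k_hat
        bin_means = np.bincount(
            bin_obs, weights=im_obs, minlength=n_bins
        ) / denom_bin
        bin_table = pd.DataFrame(
            {"bin": np.arange(n_bins), "mean_I": bin_means,
             "chi2_delivered": f_before, "chi2_corrected": f_after}
        )
        return SigmaScalingResults(
            K=k_hat, g=g_hat, chi2_before=chi2_before, chi2_after=chi2_after,
            converged=True, n_groups=len(multi_ids), n_bins=n_bins,
            bin_table=bin_table, objective=obj,
        )


def refine_error_model(merged: MergedData, n_bins: int = 10, min_groups: int = 50) -> ErrorModel:
    """Functional wrapper around :class:`SigmaScalingModel`; falls back to
    (K=1, g=0) on degenerate input."""
    return SigmaScalingModel(merged, n_bins=n_bins, min_groups=min_groups).fit().as_error_model()


def apply_error_model(merged: MergedData, model: ErrorModel) -> MergedData:
    """Replace delivered sigmas by sigma_new = sqrt(K*(sigma^2 + (g <I>)^2)) and re-merge."""
    df = merged.obs
    i_mean = merged.groups["I_mean"].to_numpy()[df["group"].to_numpy()]
    sig_new = np.sqrt(model.K * (df["sigma"].to_numpy() ** 2 + (model.g * i_mean) ** 2))
    out = df.drop(columns=["asu_h", "asu_k", "asu_l", "group"], errors="ignore").copy()
    out["sigma"] = sig_new
    return merge(out, merged.lc)


# ---------------------------------------------------------------------------
# outlier rejection


@dataclass
class RejectionResult:
    """Outcome of iterative outlier rejection.

    ``observations`` is the full observation frame with ``rejected_outlier``
    flags set; ``merged`` contains only the surviving observations.
    Supports tuple unpacking as (merged, n_rejected).
    """

    observations: pd.DataFrame
    merged: MergedData
    n_rejected: int

    def __iter__(self):
        return iter((self.merged, self.n_rejected))


def reject_outliers(
    merged: MergedData, threshold: float = 4.0, max_iter: int = 5
) -> RejectionResult:
    """Iteratively flag observations with |I - <I>|/sigma > threshold.

    Each pass recomputes group means from the currently unflagged members
    and re-evaluates every observation of groups that still have two or
    more unflagged members -- so an observation flagged against a mean
    that was itself dragged by a gross outlier is re-admitted once the
    mean has recovered.  Iteration stops at a fixed point or after
    ``max_iter`` passes.  Groups reduced to a single unflagged member stop
    participating (their flags freeze).  Rejection is two-sided: a
    measurement far below its equivalents is as invalid as one far above.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    from .symmetry import map_to_asu_array

    df = merged.obs.drop(columns=["asu_h", "asu_k", "asu_l", "group"], errors="ignore")
    df = df.copy().reset_index(drop=True)
    pre_flagged = np.zeros(len(df), dtype=bool)
    for col in ("rejected_ice", "rejected_lowres", "rejected_outlier"):
        if col in df.columns:
            pre_flagged |= df[col].to_numpy(dtype=bool)

    i_arr = df["I"].to_numpy()
    s_arr = df["sigma"].to_numpy()
    asu = map_to_asu_array(df[["h", "k", "l"]].to_numpy(dtype="int64"), merged.lc)
    gid, _ = pd.factorize(
        pd.MultiIndex.from_arrays([asu[:, 0], asu[:, 1], asu[:, 2]]), sort=True
    )
    n_groups = int(gid.max()) + 1 if len(gid) else 0
    w = 1.0 / s_arr**2

    flags = pre_flagged.copy()
    for it in range(max_iter):
        live = ~flags
        n_live = np.bincount(gid[live], minlength=n_groups)
        if it == 0:
            # first pass: deviations from the group lower quartile, which is
            # robust to the very outliers being sought -- contaminants (ice,
            # zingers) inflate intensities, so a gross outlier drags the
            # weighted mean (and, in heavily affected groups, the median)
            # upward and would otherwise flag the healthy equivalents.
            # Later passes re-admit against the unflagged weighted mean.
            mean = (
                pd.Series(i_arr[live]).groupby(gid[live]).quantile(0.25)
                .reindex(range(n_groups)).to_numpy()
            )
        else:
            sum_w = np.bincount(gid[live], weights=w[live], minlength=n_groups)
            sum_wi = np.bincount(gid[live], weights=(w * i_arr)[live], minlength=n_groups)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean = sum_wi / sum_w
        active = n_live[gid] >= 2  # groups still participating
        dev = np.zeros(len(df))
        dev[active] = np.abs(i_arr[active] - mean[gid[active]]) / s_arr[active]
        new_flags = np.where(active, dev > threshold, flags)
        new_flags |= pre_flagged
        if it > 0 and np.array_equal(new_flags, flags):
            break
        flags = new_flags

    n_rejected = int((flags & ~pre_flagged).sum())
    if "rejected_outlier" in df.columns:
        df["rejected_outlier"] = df["rejected_outlier"].to_numpy(dtype=bool) | (
            flags & ~pre_flagged
        )
    else:
        df["rejected_outlier"] = flags & ~pre_flagged
    surviving = merge(df, merged.lc)
    return RejectionResult(observations=df, merged=surviving, n_rejected=n_rejected)
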