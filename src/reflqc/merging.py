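"""Symmetry merging of unmerged reflection observations and merging statistics.

The operative in-memory container for unmerged data is a pandas DataFrame
with columns ``h k l batch I sigma d`` plus boolean flag columns
``rejected_outlier``, ``rejected_ice``, ``rejected_lowres`` (absent flags
are treated as all-False).  :func:`merge` maps each observation to its
Laue-class asymmetric-unit representative and forms inverse-variance
weighted group means; :func:`compute_stats` evaluates the standard
internal-agreement residuals

    R_merge = sum_h sum_i |I_i - <I>_h| / sum_h sum_i I_i
    R_meas  = sum_h sqrt(n_h/(n_h-1)) sum_i |I_i - <I>_h| / sum_h sum_i I_i
    R_pim   = sum_h sqrt(1/(n_h-1)) sum_i |I_i - <I>_h| / sum_h sum_i I_i

over groups with n >= 2, together with completeness, redundancy and the
mean merged I/sigma, overall and per resolution shell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .symmetry import LaueClass, UnitCell, d_spacing_array, map_to_asu_array

__all__ = [
    "FLAG_COLUMNS",
    "ReflectionObservation",
    "MergeGroup",
    "MergedData",
    "MergeStats",
    "ShellStats",
    "merge",
    "compute_stats",
    "observations_frame",
]

FLAG_COLUMNS = ("rejected_outlier", "rejected_ice", "rejected_lowres")
OBS_COLUMNS = ("h", "k", "l", "batch", "I", "sigma", "d")


@dataclass
class ReflectionObservation:
    """One unmerged measurement."""

    hkl: tuple[int, int, int]
    batch: int
    I: float
    sigma: float
    d: float
    flags: set[str] = field(default_factory=set)


def observations_frame(obs: Sequence[ReflectionObservation] | pd.DataFrame) -> pd.DataFrame:
    """Normalise observations to the canonical DataFrame layout."""
    if isinstance(obs, pd.DataFrame):
        df = obs.copy()
    else:
        df = pd.DataFrame(
            {
                "h": [o.hkl[0] for o in obs],
                "k": [o.hkl[1] for o in obs],
                "l": [o.hkl[2] for o in obs],
                "batch": [o.batch for o in obs],
                "I": [o.I for o in obs],
                "sigma": [o.sigma for o in obs],
                "d": [o.d for o in obs],
            }
        )
        for col in FLAG_COLUMNS:
            df[col] = [col in o.flags for o in obs]
    for col in FLAG_COLUMNS:
        if col not in df.columns:
            df[col] = False
        else:
            vals = df[col].to_numpy()
            df[col] = np.where(pd.isna(vals), False, vals).astype(bool)
    return df


def unflagged(df: pd.DataFrame) -> pd.DataFrame:
    mask = np.zeros(len(df), dtype=bool)
    for col in FLAG_COLUMNS:
        if col in df.columns:
            mask |= df[col].to_numpy(dtype=bool)
    return df[~mask]


@dataclass
class MergeGroup:
    """A symmetry-unique reflection with its participating observations."""

    asu_hkl: tuple[int, int, int]
    observations: pd.DataFrame
    I_mean: float
    sigma_mean: float
    n: int
    d: float


class MergedData:
    """Groups of symmetry-equivalent observations with weighted-mean statistics.

    Iterates as :class:`MergeGroup` records; the vectorised representation
    is exposed through ``obs`` (per-observation frame with ``group`` ids)
    and ``groups`` (per-group frame with columns
    ``h k l I_mean sigma_mean n d``).
    """

    def __init__(self, obs: pd.DataFrame, groups: pd.DataFrame, lc: LaueClass):
        self.obs = obs
        self.groups = groups
        self.lc = lc

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self) -> Iterator[MergeGroup]:
        g = self.groups
        for gid, row in g.iterrows():
            sub = self.obs[self.obs["group"] == gid]
            yield MergeGroup(
                asu_hkl=(int(row["h"]), int(row["k"]), int(row["l"])),
                observations=sub,
                I_mean=float(row["I_mean"]),
                sigma_mean=float(row["sigma_mean"]),
                n=int(row["n"]),
                d=float(row["d"]),
            )

    @property
    def n_obs(self) -> int:
        return len(self.obs)


def merge(observations: pd.DataFrame | Sequence[ReflectionObservation], lc: LaueClass) -> MergedData:
    """Group unflagged observations by ASU representative under ``lc``.

    Group means are inverse-variance weighted: I_mean = sum(w I)/sum(w)
    with w = 1/sigma^2, and sigma_mean = (sum w)^(-1/2).
    """
    df = observations_frame(observations)
    df = unflagged(df).reset_index(drop=True)
    if len(df) == 0:
        empty = pd.DataFrame(columns=["h", "k", "l", "I_mean", "sigma_mean", "n", "d"])
        return MergedData(df.assign(group=pd.Series(dtype=int)), empty, lc)
    if (df["sigma"] <= 0).any():
        raise ValueError("observations must carry positive sigmas")

    asu = map_to_asu_array(df[["h", "k", "l"]].to_numpy(dtype=np.int64), lc)
    df = df.assign(asu_h=asu[:, 0], asu_k=asu[:, 1], asu_l=asu[:, 2])
    gid, uniques = pd.factorize(
        pd.MultiIndex.from_arrays([df["asu_h"], df["asu_k"], df["asu_l"]]), sort=True
    )
    df["group"] = gid

    w = 1.0 / df["sigma"].to_numpy() ** 2
    wi = w * df["I"].to_numpy()
    n_groups = len(uniques)
    sum_w = np.bincount(gid, weights=w, minlength=n_groups)
    sum_wi = np.bincount(gid, weights=wi, minlength=n_groups)
    n = np.bincount(gid, minlength=n_groups)
    i_mean = sum_wi / sum_w
    sigma_mean = 1.0 / np.sqrt(sum_w)
    # representative d per group (first occurrence)
    first = np.full(n_groups, -1, dtype=np.int64)
    first[gid[::-1]] = np.arange(len(df) - 1, -1, -1)
    d_rep = df["d"].to_numpy()[first]

    hkl = np.array([list(t) for t in uniques], dtype=np.int64)
    groups = pd.DataFrame(
        {
            "h": hkl[:, 0],
            "k": hkl[:, 1],
            "l": hkl[:, 2],
            "I_mean": i_mean,
            "sigma_mean": sigma_mean,
            "n": n,
            "d": d_rep,
        }
    )
    return MergedData(df, groups, lc)


@dataclass
class ShellStats:
    d_max: float  # low-resolution edge of the shell (larger d)
    d_min: float  # high-resolution edge
    r_merge: Optional[float]
    r_meas: Optional[float]
    r_pim: Optional[float]
    mean_i_over_sigma: float
    redundancy: float
    completeness: float
    n_obs: int
    n_unique: int


@dataclass
class MergeStats:
    r_merge: Optional[float]
    r_meas: Optional[float]
    r_pim: Optional[float]
    mean_i_over_sigma: float
    redundancy: float
    completeness: float
    n_obs: int
    n_unique: int
    per_shell: list[ShellStats] = field(default_factory=list)

    @property
    def outer_shell(self) -> Optional[ShellStats]:
        """The highest-resolution (smallest d) shell."""
        return self.per_shell[-1] if self.per_shell else None


def _r_factors(df: pd.DataFrame, groups: pd.DataFrame) -> tuple:
    """(r_merge, r_meas, r_pim) over groups with n >= 2, or Nones."""
    n = groups["n"].to_numpy()
    multi = n >= 2
    if not multi.any():
        return None, None, None
    gid = df["group"].to_numpy()
    keep = multi[gid]
    dev = np.abs(
        df["I"].to_numpy()[keep] - groups["I_mean"].to_numpy()[gid[keep]]
    )
    num_per_group = np.bincount(gid[keep], weights=dev, minlength=len(groups))
    denom = float(np.bincount(gid[keep], weights=df["I"].to_numpy()[keep]).sum())
    if denom == 0:
        return None, None, None
    nh = n.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_meas = np.where(nh >= 2, np.sqrt(nh / np.maximum(nh - 1, 1)), 0.0)
        f_pim = np.where(nh >= 2, np.sqrt(1.0 / np.maximum(nh - 1, 1)), 0.0)
    r_merge = float(num_per_group.sum() / denom)
    r_meas = float((num_per_group * f_meas).sum() / denom)
    r_pim = float((num_per_group * f_pim).sum() / denom)
    return r_merge, r_meas, r_pim


def compute_stats(
    merged: MergedData,
    unique_reference: set[tuple[int, int, int]],
    cell: UnitCell,
    n_shells: int = 10,
) -> MergeStats:
    """Merging statistics overall and per equal-group-count resolution shell.

    ``unique_reference`` is the Laue-level unique set from
    :func:`reflqc.symmetry.generate_unique` on the same cell/class/range;
    completeness is |observed groups| / |reference|.  Shells partition the
    observed groups into ``n_shells`` equal-count bins ordered by d; the
    last (smallest-d) shell is the outer resolution shell.
    """
    if not unique_reference:
        raise ValueError("unique_reference must be non-empty")
    groups = merged.groups
    df = merged.obs
    if len(groups) == 0:
        raise ValueError("no merged groups")

    r_merge, r_meas, r_pim = _r_factors(df, groups)
    n_unique = len(groups)
    n_obs = int(groups["n"].sum())
    overall = MergeStats(
        r_merge=r_merge,
        r_meas=r_meas,
        r_pim=r_pim,
        mean_i_over_sigma=float((groups["I_mean"] / groups["sigma_mean"]).mean()),
        redundancy=n_obs / n_unique,
        completeness=n_unique / len(unique_reference),
        n_obs=n_obs,
        n_unique=n_unique,
    )

    n_shells = min(n_shells, len(groups))
    if n_shells < 1:
        return overall

    ref = np.array(sorted(unique_reference), dtype=np.int64)
    ref_d = d_spacing_array(cell, ref)

    order = np.argsort(-groups["d"].to_numpy(), kind="stable")
    bounds = [idx for idx in np.array_split(order, n_shells) if len(idx)]
    d_vals = groups["d"].to_numpy()
    # contiguous shell edges at midpoints between adjacent shells, with the
    # outermost edges open, so every reference member lands in one shell
    edges = [np.inf]
    for prev, nxt in zip(bounds[:-1], bounds[1:]):
        edges.append(0.5 * (d_vals[prev].min() + d_vals[nxt].max()))
    edges.append(0.0)
    shells: list[ShellStats] = []
    for i, idx in enumerate(bounds):
        shell_groups = groups.iloc[idx]
        d_hi = float(d_vals[idx].max())  # low-resolution edge
        d_lo = float(d_vals[idx].min())
        gset = set(idx.tolist())
        sub_df = df[df["group"].isin(gset)]
        # reindex group ids locally for bincount-based R factors
        local = {g: j for j, g in enumerate(shell_groups.index)}
        sub_df = sub_df.assign(group=sub_df["group"].map(local))
        local_groups = shell_groups.reset_index(drop=True)
        rm, rme, rp = _r_factors(sub_df, local_groups)
        in_shell = (ref_d > edges[i + 1]) & (ref_d <= edges[i])
        n_ref = max(int(in_shell.sum()), len(shell_groups))
        shells.append(
            ShellStats(
                d_max=d_hi,
                d_min=d_lo,
                r_merge=rm,
                r_meas=rme,
                r_pim=rp,
                mean_i_over_sigma=float(
                    (shell_groups["I_mean"] / shell_groups["sigma_mean"]).mean()
                ),
                redundancy=float(shell_groups["n"].sum() / len(shell_groups)),
                completeness=len(shell_groups) / n_ref,
                n_obs=int(shell_groups["n"].sum()),
                n_unique=len(shell_groups),
            )
        )
    overall.per_shell = shells
    return overall
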