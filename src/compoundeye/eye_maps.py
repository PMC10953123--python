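"""Eye-centred polar maps, binned profiles and azimuthal-slope contrasts.

Lens positions are expressed in polar coordinates about the fitted eye
centre: elevation is the angle above the equatorial plane and azimuth the
angle about the dorsoventral axis, anterior positive (0° lateral, +90°
anterior).  Profiles divide a metric into evenly spaced bins (20 by the
figure convention) with error bars of 3× the standard error of the mean;
azimuthal gradients are summarised per subject by the OLS slope of the
metric on azimuth and compared across species with a pooled-variance t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.transform import Rotation

from .io_core import logger
from .oda3d import EyeRecord

METRIC_ALIASES = {
    "volume": "volume_um3",
    "diameter": "diameter_um",
    "area": "area_um2",
    "length": "length_um",
    "io": "io_mean_deg",
}


def _metric_column(record: EyeRecord, metric: str) -> str:
    col = METRIC_ALIASES.get(metric, metric)
    if col not in record.lenses.columns:
        raise KeyError(f"metric {metric!r} not found in lens table")
    return col


# ---------------------------------------------------------------------------
# Polar coordinates and equator alignment
# ---------------------------------------------------------------------------


def to_polar(record: EyeRecord) -> EyeRecord:
    """Add per-lens elevation/azimuth (degrees) about the fitted eye centre."""
    if record.surface is None or record.surface.kind != "sphere":
        raise ValueError("polar coordinates need a fitted spherical surface")
    p = record.lenses[["x_um", "y_um", "z_um"]].to_numpy() - record.surface.centre
    r = np.linalg.norm(p, axis=1)
    lenses = record.lenses.copy()
    lenses["elevation_deg"] = np.degrees(np.arcsin(np.clip(p[:, 2] / r, -1, 1)))
    lenses["azimuth_deg"] = np.degrees(np.arctan2(p[:, 1], p[:, 0]))
    return EyeRecord(
        subject_id=record.subject_id, species=record.species, sex=record.sex,
        lenses=lenses, surface=record.surface, meta=dict(record.meta),
    )


def _rotate_record(record: EyeRecord, rot: Rotation) -> EyeRecord:
    lenses = record.lenses.copy()
    c = record.surface.centre
    pts = lenses[["x_um", "y_um", "z_um"]].to_numpy() - c
    lenses[["x_um", "y_um", "z_um"]] = rot.apply(pts) + c
    if {"axis_x", "axis_y", "axis_z"}.issubset(lenses.columns):
        lenses[["axis_x", "axis_y", "axis_z"]] = rot.apply(
            lenses[["axis_x", "axis_y", "axis_z"]].to_numpy()
        )
    out = EyeRecord(
        subject_id=record.subject_id, species=record.species, sex=record.sex,
        lenses=lenses, surface=record.surface, meta=dict(record.meta),
    )
    return to_polar(out)


def align_equator(
    record: EyeRecord,
    rotation: tuple[float, float, float] | str | None = None,
    decile: float = 0.1,
) -> EyeRecord:
    """Rotate the eye so the band of smallest lenses lies at elevation 0.

    ``rotation`` is a triple of xyz Euler angles in degrees (manual mode,
    the default convention of the source experiments), or ``"auto"`` to find
    the tilt (rotations about the lateral and anterior axes) minimising the
    mean |elevation| of the smallest-decile-diameter lenses.  The applied
    rotation is stored in ``meta['equator_rotation_deg']``.
    """
    if "elevation_deg" not in record.lenses.columns:
        record = to_polar(record)
    if rotation is None:
        rotation = (0.0, 0.0, 0.0)
    if isinstance(rotation, str):
        if rotation != "auto":
            raise ValueError(f"unknown rotation mode {rotation!r}")
        d = record.lenses["diameter_um"]
        if d.std() / max(d.mean(), 1e-12) < 5e-3:
            raise ValueError(
                "no detectable equatorial band (diameter variance too low); "
                "supply a manual rotation"
            )
        thresh = d.quantile(decile)
        small = record.lenses[d <= thresh]
        pts = small[["x_um", "y_um", "z_um"]].to_numpy() - record.surface.centre

        def cost(ab: np.ndarray) -> float:
            rot = Rotation.from_euler("xy", ab, degrees=True)
            q = rot.apply(pts)
            rr = np.linalg.norm(q, axis=1)
            elev = np.degrees(np.arcsin(np.clip(q[:, 2] / rr, -1, 1)))
            return float(np.abs(elev).mean())

        grid = np.arange(-30.0, 30.1, 3.0)
        best, best_c = (0.0, 0.0), math.inf
        for a in grid:
            for b in grid:
                c = cost(np.array([a, b]))
                if c < best_c:
                    best, best_c = (a, b), c
        res = optimize.minimize(cost, np.array(best), method="Nelder-Mead",
                                options={"xatol": 1e-3, "fatol": 1e-6})
        angles = (float(res.x[0]), float(res.x[1]), 0.0)
    else:
        angles = tuple(float(a) for a in rotation)
    rot = Rotation.from_euler("xyz", angles, degrees=True)
    out = _rotate_record(record, rot)
    out.meta["equator_rotation_deg"] = angles
    return out


# ---------------------------------------------------------------------------
# Binned profiles
# ---------------------------------------------------------------------------


@dataclass
class BinnedProfile:
    """Per-bin mean ± 3×SEM of a lens metric along elevation or azimuth."""

    axis: str
    metric: str
    edges: np.ndarray
    mean: np.ndarray
    sem3: np.ndarray
    count: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_deg": self.edges[:-1],
                "bin_hi_deg": self.edges[1:],
                "mean": self.mean,
                "sem3": self.sem3,
                "n": self.count,
            }
        )


def bin_profile(
    record: EyeRecord,
    metric: str,
    axis: str = "elevation",
    n_bins: int = 20,
    subset: pd.DataFrame | None = None,
) -> BinnedProfile:
    """Evenly spaced bins spanning the observed range of the profile axis.

    Empty bins are reported with count 0 and undefined (NaN) mean; the error
    is 3× the standard error of the mean (0 for single-lens bins).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    col = _metric_column(record, metric)
    axis_col = f"{axis}_deg"
    df = record.lenses if subset is None else subset
    if axis_col not in df.columns:
        raise KeyError(f"no {axis_col} column; run to_polar first")
    df = df[[axis_col, col]].dropna()
    if df.empty:
        raise ValueError(f"metric {metric!r} defined for no lens")
    x = df[axis_col].to_numpy()
    y = df[col].to_numpy()
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    mean = np.full(n_bins, np.nan)
    sem3 = np.zeros(n_bins)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        count[b] = sel.sum()
        if count[b]:
            mean[b] = y[sel].mean()
            if count[b] > 1:
                sem3[b] = 3.0 * y[sel].std(ddof=1) / math.sqrt(count[b])
    return BinnedProfile(axis=axis, metric=metric, edges=edges,
                         mean=mean, sem3=sem3, count=count)


def band_profile(
    record: EyeRecord,
    metric: str,
    axis: str = "elevation",
    band_halfwidth: float = 15.0,
    n_bins: int = 20,
) -> BinnedProfile:
    """Profile restricted to a narrow band of the orthogonal axis.

    For an elevation profile only lenses with |azimuth| ≤ halfwidth
    contribute; for an azimuth profile (equatorial statistics) only lenses
    with |elevation| ≤ halfwidth.
    """
    other = "azimuth" if axis == "elevation" else "elevation"
    if f"{other}_deg" not in record.lenses.columns:
        raise KeyError("run to_polar first")
    sel = record.lenses[np.abs(record.lenses[f"{other}_deg"]) <= band_halfwidth]
    if sel.empty:
        raise ValueError(f"no lenses within ±{band_halfwidth}° of {other} = 0")
    return bin_profile(record, metric, axis=axis, n_bins=n_bins, subset=sel)


def band_median(
    record: EyeRecord,
    metric: str = "io_mean_deg",
    band_axis: str = "elevation",
    band_halfwidth: float = 15.0,
) -> float:
    """Median of a metric inside |band_axis| ≤ halfwidth (e.g. the
    median equatorial IO angle with elevation = 0 ± 15°)."""
    col = _metric_column(record, metric)
    band = record.lenses[np.abs(record.lenses[f"{band_axis}_deg"]) <= band_halfwidth]
    if band.empty:
        raise ValueError("empty band")
    return float(band[col].median())


# ---------------------------------------------------------------------------
# Azimuthal slopes
# ---------------------------------------------------------------------------


@dataclass
class SlopeFit:
    """Per-subject OLS fit of a metric on azimuth (degrees)."""

    slope: float
    intercept: float
    se: float
    ci_lo: float
    ci_hi: float
    n: int
    ci_level: float


def azimuthal_slope(
    record: EyeRecord, metric: str, ci_level: float = 0.90
) -> SlopeFit:
    """OLS affine fit metric = intercept + slope·azimuth, per subject.

    The confidence interval uses the t distribution with n − 2 degrees of
    freedom.
    """
    col = _metric_column(record, metric)
    df = record.lenses[["azimuth_deg", col]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 lenses")
    x = df["azimuth_deg"].to_numpy()
    y = df[col].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("zero azimuth variance")
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    slope = ((x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    if n > 2:
        s2 = (resid**2).sum() / (n - 2)
        se = math.sqrt(s2 / sxx)
        tcrit = stats.t.ppf(0.5 + ci_level / 2.0, n - 2)
    else:
        se, tcrit = 0.0, 0.0
    return SlopeFit(
        slope=float(slope), intercept=float(intercept), se=float(se),
        ci_lo=float(slope - tcrit * se), ci_hi=float(slope + tcrit * se),
        n=n, ci_level=ci_level,
    )


@dataclass
class SlopeEstimate:
    """Two-group comparison of per-subject slopes (pooled-variance t)."""

    t: float
    df: int
    cohen_d: float
    p: float
    mean_difference: float


def compare_slopes(
    group_a: np.ndarray, group_b: np.ndarray, welch: bool = False
) -> SlopeEstimate:
    """Two-sample t-test of per-subject slopes, two-tailed.

    Pooled-variance by default (df = n₁ + n₂ − 2) with Cohen's d from the
    pooled SD; Welch's correction available via ``welch=True``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    na, nb = len(a), len(b)
    dof = na + nb - 2
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / dof
    diff = a.mean() - b.mean()
    if pooled_var == 0:
        if diff == 0:
            return SlopeEstimate(t=0.0, df=dof, cohen_d=0.0, p=1.0, mean_difference=0.0)
        logger.warning("zero pooled variance with unequal means; reporting p = 0")
        return SlopeEstimate(t=math.inf if diff > 0 else -math.inf, df=dof,
                             cohen_d=math.inf if diff > 0 else -math.inf,
                             p=0.0, mean_difference=float(diff))
    res = stats.ttest_ind(a, b, equal_var=not welch)
    d = diff / math.sqrt(pooled_var)
    return SlopeEstimate(
        t=float(res.statistic), df=int(res.df), cohen_d=float(d),
        p=float(res.pvalue), mean_difference=float(diff),
    )
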