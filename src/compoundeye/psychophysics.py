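"""Optomotor tuning curves and discernibility thresholds from ΔWBA traces.

The analysis chain follows the flight-arena protocol: for each fly and
grating, leftward-motion responses are averaged with the sign-inverse of
rightward-motion responses (cancelling directional bias), baseline-corrected
by the mean of the 0.1 s before motion onset, summarised as the mean response
0.5–1.25 s after onset, normalised to each fly's maximum mean response, and
bootstrapped 10,000 times at the subject level.  The half-width of the
central 68% bootstrap interval approximates the standard error, and a level
is discernible when the lower bound of the 90% interval (the 5th percentile)
is positive — a one-tailed test at α = 0.05.  Contrast sensitivity is the
reciprocal of the lowest discernible contrast; spatial and temporal acuity
are the highest discernible frequencies, at grid resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_core import logger

Axis = Literal["contrast", "sf", "tf"]
_AXIS_COLUMN = {"contrast": "contrast", "sf": "sf_cpd", "tf": "tf_hz"}


@dataclass(frozen=True)
class Grating:
    """A sinusoidal grating stimulus (Michelson contrast, cpd, Hz)."""

    contrast: float
    sf_cpd: float
    tf_hz: float
    direction: str = "left"  # left | right | folded
    still_duration: float = 0.2
    motion_duration: float = 1.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError(f"contrast must lie in [0, 1], got {self.contrast}")
        if self.sf_cpd < 0 or self.tf_hz < 0:
            raise ValueError("frequencies must be >= 0")

    @property
    def speed_dps(self) -> float:
        """Angular speed of the pattern, degrees/s (tf/sf)."""
        return self.tf_hz / self.sf_cpd if self.sf_cpd > 0 else math.nan

    def key(self) -> tuple:
        """Stimulus identity ignoring direction (for direction folding)."""
        return (self.contrast, self.sf_cpd, self.tf_hz)


@dataclass
class WBATrace:
    """One trial's left-minus-right wingbeat amplitude time series."""

    fly_id: int
    time_s: np.ndarray
    dwba: np.ndarray
    grating: Grating
    onset_s: float
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.dwba = np.asarray(self.dwba, dtype=float)
        if self.time_s.shape != self.dwba.shape:
            raise ValueError("time and ΔWBA must have the same length")
        dt = np.diff(self.time_s)
        if len(dt) and not np.allclose(dt, dt[0]):
            raise ValueError("sampling must be uniform")
        if not (self.time_s[0] <= self.onset_s <= self.time_s[-1]):
            raise ValueError("motion onset must lie within the trace")

    @property
    def fs_hz(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])


def fold_directions(traces: Sequence[WBATrace]) -> WBATrace:
    """Average leftward responses with the inverse of rightward responses.

    All traces must belong to one fly and one grating (both directions).
    The folded trace is positive when the fly steers with the motion
    direction; a constant directional bias cancels exactly.  If only one
    direction is present the mean of that direction is returned with a
    warning (bias not removed).
    """
    flies = {t.fly_id for t in traces}
    keys = {t.grating.key() for t in traces}
    if len(flies) != 1 or len(keys) != 1:
        raise ValueError("fold_directions expects one fly and one grating")
    left = [t for t in traces if t.grating.direction == "left"]
    right = [t for t in traces if t.grating.direction == "right"]
    ref = traces[0]
    if not left or not right:
        logger.warning(
            "fly %s grating %s: only one direction present; directional bias "
            "not removed",
            ref.fly_id,
            ref.grating.key(),
        )
        arrs = [t.dwba for t in left] or [-t.dwba for t in right]
        folded = np.mean(arrs, axis=0)
    else:
        mean_l = np.mean([t.dwba for t in left], axis=0)
        mean_r = np.mean([t.dwba for t in right], axis=0)
        folded = 0.5 * (mean_l - mean_r)
    return WBATrace(
        fly_id=ref.fly_id,
        time_s=ref.time_s,
        dwba=folded,
        grating=replace(ref.grating, direction="folded"),
        onset_s=ref.onset_s,
        trial_id=-1,
    )


def baseline_correct(trace: WBATrace, window_s: float = 0.1) -> WBATrace:
    """Subtract the mean response during ``window_s`` before motion onset."""
    pre = (trace.time_s >= trace.onset_s - window_s) & (trace.time_s < trace.onset_s)
    if not pre.any() or trace.time_s[pre][0] > trace.onset_s - window_s + 0.5 / trace.fs_hz:
        raise ValueError(f"need {window_s} s of pre-onset samples")
    corrected = trace.dwba - trace.dwba[pre].mean()
    return WBATrace(
        fly_id=trace.fly_id,
        time_s=trace.time_s,
        dwba=corrected,
        grating=trace.grating,
        onset_s=trace.onset_s,
        trial_id=trace.trial_id,
    )


def window_mean(trace: WBATrace, lo_s: float = 0.5, hi_s: float = 1.25) -> float:
    """Mean ΔWBA over onset-relative time in [lo_s, hi_s], inclusive bounds."""
    rel = trace.time_s - trace.onset_s
    eps = 0.25 / trace.fs_hz
    sel = (rel >= lo_s - eps) & (rel <= hi_s + eps)
    if rel[-1] < hi_s - eps or rel[0] > lo_s + eps:
        raise ValueError(f"window [{lo_s}, {hi_s}] s lies outside the trace span")
    return float(trace.dwba[sel].mean())


def windowed_responses(
    traces: Sequence[WBATrace],
    axis: Axis,
    baseline_window_s: float = 0.1,
    window: tuple[float, float] = (0.5, 1.25),
) -> pd.DataFrame:
    """Fold, baseline-correct and window every fly × level of one tuning axis.

    Returns a table (fly_id, level, response) of un-normalised windowed means.
    """
    col = _AXIS_COLUMN[axis]
    groups: dict[tuple, list[WBATrace]] = {}
    for t in traces:
        groups.setdefault((t.fly_id, t.grating.key()), []).append(t)
    rows = []
    for (fly, key), grp in sorted(groups.items()):
        folded = fold_directions(grp)
        corrected = baseline_correct(folded, baseline_window_s)
        g = grp[0].grating
        level = {"contrast": g.contrast, "sf_cpd": g.sf_cpd, "tf_hz": g.tf_hz}[col]
        rows.append(
            {
                "fly_id": fly,
                "level": level,
                "response": window_mean(corrected, *window),
            }
        )
    return pd.DataFrame(rows)


def normalize_per_fly(windowed: pd.DataFrame) -> pd.DataFrame:
    """Divide each fly's windowed means by that fly's maximum (signed) mean.

    The maximum becomes exactly 1; negative values are countersteering.
    Flies whose maximum is not positive are flagged (``normalised = False``)
    and left unscaled.
    """
    out = windowed.copy()
    out["normalised"] = True
    for fly, grp in windowed.groupby("fly_id"):
        m = grp["response"].max()
        if m > 0:
            out.loc[grp.index, "response"] = grp["response"] / m
        else:
            logger.warning("fly %s has no positive response; not normalised", fly)
            out.loc[grp.index, "normalised"] = False
    return out


def bootstrap_discernibility(
    responses: np.ndarray,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, bool]:
    """Subject-level bootstrap of a group-mean response.

    Resamples flies with replacement ``n_boot`` times; returns the sample
    mean, the half-width of the central 68% percentile interval (standard
    error approximation), and the discernibility flag: 5th percentile of the
    bootstrap distribution > 0 (lower bound of the 90% CI, one-tailed
    α = 0.05).
    """
    x = np.asarray(responses, dtype=float)
    if len(x) < 2:
        raise ValueError("need responses from at least 2 flies")
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(x), (n_boot, len(x)))
    means = x[idx].mean(axis=1)
    q16, q84, q05 = np.percentile(means, [16.0, 84.0, 5.0])
    return float(x.mean()), float((q84 - q16) / 2.0), bool(q05 > 0.0)


@dataclass
class TuningCurve:
    """Per-level group means, bootstrap SEs, flags and extracted threshold."""

    axis: Axis
    table: pd.DataFrame = field(repr=False)  # level, mean, se68, significant, n_flies
    threshold_level: float | None = None

    @property
    def levels(self) -> np.ndarray:
        return self.table["level"].to_numpy()


def tuning_curve(
    normalized: pd.DataFrame,
    axis: Axis,
    n_boot: int = 10_000,
    seed: int = 0,
) -> TuningCurve:
    """Bootstrap every level of a normalised per-fly response table."""
    rng = np.random.default_rng(seed)
    rows = []
    for level, grp in normalized.groupby("level", sort=True):
        vals = grp["response"].to_numpy()
        mean, se, sig = bootstrap_discernibility(vals, n_boot=n_boot, seed=rng)
        rows.append(
            {"level": level, "mean": mean, "se68": se, "significant": sig,
             "n_flies": len(vals)}
        )
    table = pd.DataFrame(rows)
    sig = table["significant"].to_numpy()
    if sig.any() and not _is_monotone_run(sig, axis):
        logger.warning("non-monotone significance pattern on %s axis: %s",
                       axis, sig.tolist())
    curve = TuningCurve(axis=axis, table=table)
    curve.threshold_level = extract_thresholds(curve)
    return curve


def _is_monotone_run(sig: np.ndarray, axis: Axis) -> bool:
    # contrast: expect False... then True...; frequencies: True... then False...
    s = sig.astype(int)
    if axis == "contrast":
        return bool(np.all(np.diff(s) >= 0))
    return bool(np.all(np.diff(s) <= 0))


def extract_thresholds(curve: TuningCurve) -> float | None:
    """Lowest discernible contrast, or highest discernible frequency.

    Zero-contrast levels are blank controls and are never threshold
    candidates.  Returns ``None`` (undefined) when no level is discernible.
    No interpolation between grid levels is attempted.
    """
    t = curve.table
    cand = t[t["significant"]]
    if curve.axis == "contrast":
        cand = cand[cand["level"] > 0]
    if cand.empty:
        logger.warning("no discernible level on %s axis; threshold undefined",
                       curve.axis)
        return None
    if curve.axis == "contrast":
        return float(cand["level"].min())
    return float(cand["level"].max())


def analyze_cohort(
    traces: Sequence[WBATrace],
    axis: Axis,
    n_boot: int = 10_000,
    seed: int = 0,
) -> TuningCurve:
    """Full chain: fold → baseline → window → normalise → bootstrap → threshold."""
    w = windowed_responses(traces, axis)
    norm = normalize_per_fly(w)
    return tuning_curve(norm, axis, n_boot=n_boot, seed=seed)
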