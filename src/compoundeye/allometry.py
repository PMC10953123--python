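"""Allometric scaling of optical summary metrics on eye surface area.

Each per-subject summary metric (lens count, mean lens diameter, median IO
angle, median equatorial IO angle, IO-angle IQR, …) is modelled by ordinary
least squares as

    metric = intercept + slope·SA + species_difference·species_dummy

where SA is the circular-facet eye surface area and the dummy codes the
RED3-labelled group, so ``species_difference`` is the RED3-minus-M3 contrast
after SA adjustment.  The post hoc species comparison is the Wald t-test on
the dummy coefficient.  Models are fitted on raw (untransformed) scales; a
log-log variant is available via ``log_transform=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .eye_maps import band_median
from .oda3d import EyeRecord

SUMMARY_METRICS = [
    "lens_count", "mean_lens_diameter", "median_io", "median_equatorial_io",
    "io_iqr", "lens_diameter_iqr", "SA",
]


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25.0, 75.0])  # linear-interpolation quantiles
    return float(q3 - q1)


def summary_metrics(record: EyeRecord, band_halfwidth: float = 15.0) -> dict:
    """Per-subject optical summary metrics.

    Medians and IQRs are taken over lenses with defined values; IO metrics
    are NaN (flagged) when no lens has a defined IO angle.
    """
    df = record.lenses
    d = df["diameter_um"].to_numpy()
    io = df["io_mean_deg"].dropna().to_numpy() if "io_mean_deg" in df else np.array([])
    out = {
        "subject": record.subject_id,
        "species": record.species,
        "sex": record.sex,
        "lens_count": record.lens_count,
        "mean_lens_diameter": float(d.mean()),
        "lens_diameter_iqr": _iqr(d),
        "SA": record.surface_area_um2,
    }
    if len(io) == 0:
        out.update(median_io=math.nan, median_equatorial_io=math.nan, io_iqr=math.nan)
    else:
        out["median_io"] = float(np.median(io))
        out["io_iqr"] = _iqr(io)
        if "elevation_deg" in df.columns:
            out["median_equatorial_io"] = band_median(
                record, "io_mean_deg", "elevation", band_halfwidth
            )
        else:
            out["median_equatorial_io"] = math.nan
    return out


def significance_stars(p: float) -> str:
    """Three-level significance key: * p<.05, ** p<.01, *** p<.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AllometryModel:
    """OLS fit of one outcome on SA plus a dummy-coded species variable."""

    outcome: str
    coded_species: str          # the group coded 1 (difference = coded − other)
    intercept: float
    slope: float
    species_difference: float
    se_intercept: float
    se_slope: float
    se_species: float
    r_squared: float
    f_statistic: float
    p_f: float
    p_intercept: float
    p_slope: float
    p_species: float
    n: int

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["stars_f"] = significance_stars(self.p_f)
        d["stars_slope"] = significance_stars(self.p_slope)
        d["stars_species"] = significance_stars(self.p_species)
        return d


def fit_allometry(
    metrics: pd.DataFrame,
    outcome: str,
    coded_species: str | None = None,
    sa_col: str = "SA",
    species_col: str = "species",
    log_transform: bool = False,
) -> AllometryModel:
    """OLS of an outcome on [1, SA, species_dummy] with the coefficient
    Wald t-test as the post hoc species comparison.

    ``coded_species`` names the group coded 1 (defaults to the label
    containing "RED3", else the lexicographically first label), so the sign
    convention of ``species_difference`` is explicit and label swaps negate
    it exactly.
    """
    df = metrics.dropna(subset=[outcome, sa_col]).copy()
    species = sorted(df[species_col].unique())
    if len(species) != 2:
        raise ValueError(f"need exactly 2 species, got {species}")
    if len(df) < 4:
        raise ValueError("need at least 4 subjects")
    if coded_species is None:
        red = [s for s in species if "RED3" in str(s)]
        coded_species = red[0] if red else species[0]
    sa = df[sa_col].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    if log_transform:
        sa, y = np.log(sa), np.log(y)
    dummy = (df[species_col] == coded_species).to_numpy(dtype=float)
    if np.ptp(sa) == 0:
        raise ValueError("all SA values equal; design is collinear")
    X = sm.add_constant(np.column_stack([sa, dummy]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("collinear design (species confounded with SA)")
    fit = sm.OLS(y, X).fit()
    return AllometryModel(
        outcome=outcome,
        coded_species=coded_species,
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        species_difference=float(fit.params[2]),
        se_intercept=float(fit.bse[0]),
        se_slope=float(fit.bse[1]),
        se_species=float(fit.bse[2]),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        p_f=float(fit.f_pvalue),
        p_intercept=float(fit.pvalues[0]),
        p_slope=float(fit.pvalues[1]),
        p_species=float(fit.pvalues[2]),
        n=len(df),
    )


def allometry_table(
    metrics: pd.DataFrame,
    outcomes: list[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Fit every outcome and return a model-parameter table (one row per
    outcome, mirroring the standard allometry summary layout)."""
    outcomes = outcomes or [
        "lens_count", "mean_lens_diameter", "median_io",
        "median_equatorial_io", "io_iqr",
    ]
    rows = [fit_allometry(metrics, o, **kwargs).to_dict() for o in outcomes]
    return pd.DataFrame(rows)
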