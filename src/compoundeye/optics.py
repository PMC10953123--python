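"""Closed-form optical limits of a hexagonally sampled compound eye.

A hexagonal ommatidial lattice with interommatidial (IO) angle Δɸ samples the
visual scene at an angular Nyquist limit of

    f_s = 1 / (√3 · Δɸ)        [cycles/degree, Δɸ in degrees]

and, conversely, a behaviourally measured spatial acuity f_s implies an ideal
IO angle Δɸ = 1/(√3·f_s).  Contrast sensitivity is the reciprocal of the
lowest discernible Michelson contrast.  Angles are accepted and returned in
degrees only; passing radians would silently change f_s by a factor of ~57,
so the interface is deliberately degree-typed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

_SQRT3 = math.sqrt(3.0)


def nyquist_from_io(io_deg: float) -> float:
    """Hexagonal-lattice Nyquist spatial frequency (cycles/degree) from Δɸ (degrees)."""
    if io_deg <= 0:
        raise ValueError(f"IO angle must be positive, got {io_deg}")
    return 1.0 / (_SQRT3 * io_deg)


def io_from_nyquist(fs_cpd: float) -> float:
    """Ideal IO angle Δɸ (degrees) for a Nyquist spatial frequency (cycles/degree)."""
    if fs_cpd <= 0:
        raise ValueError(f"spatial frequency must be positive, got {fs_cpd}")
    return 1.0 / (_SQRT3 * fs_cpd)


def contrast_sensitivity(lowest_discernible_contrast: float) -> float:
    """Reciprocal of the lowest discernible Michelson contrast in (0, 1]."""
    c = lowest_discernible_contrast
    if not (0.0 < c <= 1.0):
        raise ValueError(f"contrast must lie in (0, 1], got {c}")
    return 1.0 / c


@dataclass
class OpticalLimits:
    """Optical limits of one eye (or eye region).

    ``relative_sensitivity_proxy`` is the lens cross-sectional area in µm²:
    photon catch, and hence the number of discernible brightness levels,
    scales with lens aperture area; no absolute photon-catch model is
    attempted here.
    """

    io_angle_deg: float
    nyquist_fs_cpd: float
    contrast_sensitivity: float | None = None
    relative_sensitivity_proxy_um2: float | None = None

    @classmethod
    def from_io(
        cls,
        io_deg: float,
        lowest_contrast: float | None = None,
        lens_area_um2: float | None = None,
    ) -> "OpticalLimits":
        return cls(
            io_angle_deg=io_deg,
            nyquist_fs_cpd=nyquist_from_io(io_deg),
            contrast_sensitivity=(
                contrast_sensitivity(lowest_contrast) if lowest_contrast else None
            ),
            relative_sensitivity_proxy_um2=lens_area_um2,
        )
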