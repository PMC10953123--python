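"""Shared synthetic study cohort for the analysis scripts.

Twelve eyes (two species-like groups × 3 male + 3 female) spanning a range
of eye sizes.  The RED3-like group has larger facets at slightly lower
density; the M3-like group more, smaller facets — the qualitative contrast
the morphological comparison expects.  Generation is deterministic, so each
script can rebuild the cohort independently (lens tables are ~600 rows and
are not kept on disk).
"""

from __future__ import annotations

from compoundeye import eye_maps, oda3d, synthetic

GROUPS = {
    "mauritiana_RED3": dict(base_diameter=16.6, density=0.94),
    "simulans_M3": dict(base_diameter=15.4, density=1.06),
}
RADII = [258.0, 270.0, 282.0, 294.0, 306.0, 318.0]  # µm, small→large eyes
SEXES = ["m", "m", "m", "f", "f", "f"]


def build_cohort(seed: int = 0, voxel_size: float = 2.0):
    """Return a list of polar EyeRecords built from generator ground truth."""
    records = []
    for g_idx, (species, pars) in enumerate(sorted(GROUPS.items())):
        for s_idx, (radius, sex) in enumerate(zip(RADII, SEXES)):
            n = round(600 * pars["density"] * (radius / 290.0) ** 2)
            spec = synthetic.SyntheticEyeSpec(
                n_lenses=n,
                cap_radius=radius,
                cap_solid_angle=2.5,
                base_diameter=pars["base_diameter"] * radius / 290.0,
                azimuthal_gradient=0.02,
                equatorial_band_shrink=0.10,
                noise_sd=1.0,
                voxel_size=voxel_size,
                seed=seed + 100 * g_idx + s_idx,
            )
            _, truth = synthetic.generate_synthetic_eye(spec)
            rec = oda3d.eye_record_from_table(
                truth, radius, subject_id=f"{species}_{s_idx}",
                species=species, sex=sex,
            )
            records.append(eye_maps.to_polar(rec))
    return records
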