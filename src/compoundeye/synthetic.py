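"""Ground-truthed synthetic data for every pipeline stage.

Three generators:

* :func:`generate_synthetic_eye` — a binary voxel volume of plano-convex
  corneal lenses tiling a spherical cap, with a dorsal→anterior-ventral facet
  size gradient, an equatorial band of smaller facets, and controllable
  interommatidial (IO) angles, plus a complete ground-truth lens table.
* :func:`generate_wba_traces` — 1000 Hz ΔWBA steering traces of tethered
  flies viewing moving gratings, with per-fly gain, directional bias,
  baseline drift and additive noise.
* :func:`generate_landmark_sets` — six-corner facet landmark sets drawn from
  labelled template shapes under random similarity transforms.

All generators are deterministic given their seed, and every generated lens,
trial and facet appears exactly once in the returned truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_core import VolumeStack
from .psychophysics import Grating, WBATrace

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

# ---------------------------------------------------------------------------
# Synthetic eyes
# ---------------------------------------------------------------------------
#
# Coordinate frame (all physical 3D coordinates are (x, y, z) in µm):
#   +x lateral (azimuth 0), +y anterior (azimuth +90°), +z dorsal.
#   elevation = asin(z/r), azimuth = atan2(y, x); eye centre at the origin.


@dataclass
class SyntheticEyeSpec:
    """Study conditions of one synthetic eye.

    ``io_profile`` maps elevation (degrees) to the local target IO angle
    (degrees).  When ``None``, lenses are packed uniformly so that the IO
    angle follows from ``n_lenses`` and the cap geometry.  Defaults describe
    a fly-scale eye: ~600 lenses, 290 µm radius of curvature, 16 µm facets,
    IO angle near 4°, a mild anterior facet enlargement and a 10% smaller
    equatorial band.
    """

    n_lenses: int = 600
    cap_radius: float = 290.0              # µm, radius of eye curvature
    cap_solid_angle: float = 2.5           # steradians subtended by the eye
    base_diameter: float = 16.0            # µm
    azimuthal_gradient: float = 0.02       # µm lens diameter per degree azimuth
    equatorial_band_shrink: float = 0.10   # fractional diameter reduction in band
    equatorial_band_halfwidth: float = 15.0  # degrees elevation
    io_profile: Callable[[np.ndarray], np.ndarray] | None = None
    lens_length_frac: float = 0.6          # lens length as fraction of diameter
    noise_sd: float = 1.0                  # µm jitter of lens centres
    voxel_size: float = 2.0                # µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lenses < 7:
            raise ValueError("n_lenses must be >= 7")
        if self.base_diameter <= 0 or self.cap_radius <= 0:
            raise ValueError("diameters and radii must be positive")
        if not (0.0 <= self.equatorial_band_shrink < 1.0):
            raise ValueError("equatorial_band_shrink must lie in [0, 1)")


def make_io_profile(
    io_equator_deg: float,
    io_periphery_deg: float,
    band_halfwidth_deg: float = 15.0,
    periphery_elevation_deg: float = 60.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Elevation-dependent IO target: flat band around the equator, linear
    ramp to the peripheral value at ``periphery_elevation_deg``."""

    def profile(elev_deg: np.ndarray) -> np.ndarray:
        e = np.abs(np.asarray(elev_deg, dtype=float))
        frac = np.clip(
            (e - band_halfwidth_deg) / max(periphery_elevation_deg - band_halfwidth_deg, 1e-9),
            0.0,
            1.0,
        )
        return io_equator_deg + (io_periphery_deg - io_equator_deg) * frac

    return profile


def _cap_angular_radius(solid_angle: float) -> float:
    # Omega = 2*pi*(1 - cos(theta))
    return math.acos(1.0 - solid_angle / (2.0 * math.pi))


def _rot_z_to_x() -> np.ndarray:
    # rotate +z onto +x (cap generated about +z, eye looks laterally)
    return np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])


def _fibonacci_cap(n: int, theta_c: float) -> np.ndarray:
    k = np.arange(n) + 0.5
    z = 1.0 - (k / n) * (1.0 - math.cos(theta_c))
    az = k * GOLDEN_ANGLE
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(az), s * np.sin(az), z])


def _relax_lattice(
    dirs: np.ndarray, theta_c: float, target_chord: float, n_iter: int = 60
) -> np.ndarray:
    """Spring/repulsion relaxation toward quasi-hexagonal packing on the cap."""
    pts = dirs.copy()
    cap_axis = np.array([0.0, 0.0, 1.0])
    for _ in range(n_iter):
        tree = cKDTree(pts)
        pairs = tree.query_pairs(1.35 * target_chord, output_type="ndarray")
        if len(pairs):
            delta = pts[pairs[:, 0]] - pts[pairs[:, 1]]
            dist = np.linalg.norm(delta, axis=1)
            short = dist < target_chord
            if short.any():
                push = np.zeros_like(pts)
                step = 0.25 * (target_chord - dist[short])[:, None] * (
                    delta[short] / dist[short][:, None]
                )
                np.add.at(push, pairs[short, 0], step)
                np.add.at(push, pairs[short, 1], -step)
                pts = pts + push
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        # clamp back into the cap
        cosang = pts @ cap_axis
        outside = cosang < math.cos(theta_c)
        if outside.any():
            ang = np.arccos(np.clip(cosang[outside], -1, 1))
            perp = pts[outside] - cosang[outside, None] * cap_axis
            perp /= np.linalg.norm(perp, axis=1, keepdims=True)
            pts[outside] = (
                math.cos(theta_c) * cap_axis + math.sin(theta_c) * perp
            )
            del ang
    return pts


def _rosette_directions(spacing_rad: float) -> np.ndarray:
    """Centre lens plus a hexagonal ring at the given angular spacing."""
    dirs = [np.array([0.0, 0.0, 1.0])]
    for k in range(6):
        az = k * math.pi / 3.0
        dirs.append(
            np.array(
                [
                    math.sin(spacing_rad) * math.cos(az),
                    math.sin(spacing_rad) * math.sin(az),
                    math.cos(spacing_rad),
                ]
            )
        )
    return np.vstack(dirs)


def _row_lattice(
    io_profile: Callable[[np.ndarray], np.ndarray],
    elev_max_deg: float,
    az_max_deg: float,
) -> np.ndarray:
    """Hexagonal rows on a lat-long patch with elevation-dependent spacing."""
    rows: list[float] = [0.0]
    e = 0.0
    while True:
        a = math.radians(float(io_profile(np.array([math.degrees(e)]))[0]))
        e = e + a * math.sqrt(3.0) / 2.0
        if math.degrees(e) > elev_max_deg:
            break
        rows.append(e)
    elevs = np.array(sorted({-r for r in rows} | set(rows)))
    dirs = []
    for i, e in enumerate(elevs):
        a = math.radians(float(io_profile(np.array([math.degrees(e)]))[0]))
        daz = a / max(math.cos(e), 1e-6)
        n_half = int(math.floor(math.radians(az_max_deg) / daz))
        offset = 0.5 * daz if i % 2 else 0.0
        az = offset + daz * np.arange(-n_half, n_half + 1)
        az = az[np.abs(az) <= math.radians(az_max_deg)]
        for a_ in az:
            dirs.append(
                [
                    math.cos(e) * math.cos(a_),
                    math.cos(e) * math.sin(a_),
                    math.sin(e),
                ]
            )
    return np.asarray(dirs)


def generate_synthetic_eye(
    spec: SyntheticEyeSpec,
) -> tuple[VolumeStack, pd.DataFrame]:
    """Generate a binary lens volume and its ground-truth lens table.

    Returns the volume (physical frame centred on the eye centre of
    curvature) and a table with one row per lens: voxel-centroid position,
    on-sphere centre, outward axis, diameter, length, voxelised volume,
    elevation/azimuth, and the mean IO angle to lattice neighbours.

    Raises ``ValueError`` naming the maximum feasible lens count when the
    requested lenses cannot tile the cap without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.cap_radius
    theta_c = _cap_angular_radius(spec.cap_solid_angle)

    if spec.io_profile is not None:
        # patch half-extents chosen to match the requested solid angle:
        # Omega = 2*az_max * 2*sin(elev_max); use elev_max = az_max = t
        t = 0.5
        for _ in range(60):  # fixed-point solve of 4 t sin(t) = Omega
            t = spec.cap_solid_angle / (4.0 * math.sin(t)) if math.sin(t) > 0 else t
        dirs = _row_lattice(spec.io_profile, math.degrees(t), math.degrees(t))
        dirs = dirs @ np.eye(3)  # already in eye frame (x lateral)
    elif spec.n_lenses == 7:
        spacing = math.sqrt(spec.cap_solid_angle / (7 * math.sqrt(3.0) / 2.0))
        dirs = _rosette_directions(spacing) @ _rot_z_to_x().T
    else:
        spacing = math.sqrt(
            spec.cap_solid_angle / (spec.n_lenses * math.sqrt(3.0) / 2.0)
        )
        dirs = _fibonacci_cap(spec.n_lenses, theta_c)
        dirs = _relax_lattice(dirs, theta_c, 2.0 * math.sin(spacing / 2.0))
        dirs = dirs @ _rot_z_to_x().T

    nominal = R * dirs
    n = len(nominal)

    elev0 = np.degrees(np.arcsin(np.clip(dirs[:, 2], -1, 1)))
    azim0 = np.degrees(np.arctan2(dirs[:, 1], dirs[:, 0]))
    diam = spec.base_diameter + spec.azimuthal_gradient * azim0
    in_band = np.abs(elev0) <= spec.equatorial_band_halfwidth
    diam = np.where(in_band, diam * (1.0 - spec.equatorial_band_shrink), diam)
    if (diam <= 0).any():
        raise ValueError("lens diameters must stay positive; reduce the gradient")

    # tiling feasibility on the nominal lattice: if the requested lenses do
    # not fit their lattice cells the cap cannot be tiled at this n_lenses
    tree = cKDTree(nominal)
    dist, idx = tree.query(nominal, k=2)
    required = 0.5 * (diam + diam[idx[:, 1]])
    if (dist[:, 1] < required).any():
        cell = math.sqrt(3.0) / 2.0 * (np.median(required) / R) ** 2
        n_max = int(0.85 * spec.cap_solid_angle / cell)
        raise ValueError(
            f"{spec.n_lenses} lenses of ~{np.median(diam):.1f} µm cannot tile the "
            f"cap without overlap; maximum feasible n_lenses ≈ {n_max}"
        )

    centres = nominal
    if spec.noise_sd > 0:
        centres = centres + rng.normal(0.0, spec.noise_sd, centres.shape)
        norms = np.linalg.norm(centres, axis=1, keepdims=True)
        centres = centres / norms * R  # keep lenses on the sphere
    axes = centres / R

    elev = np.degrees(np.arcsin(np.clip(axes[:, 2], -1, 1)))
    azim = np.degrees(np.arctan2(axes[:, 1], axes[:, 0]))

    length = spec.lens_length_frac * diam

    # jitter can crowd a few pairs; crowded facets shrink to keep the tiling
    # non-overlapping (real facet lattices deform rather than overlap)
    for _ in range(3):
        tree = cKDTree(centres)
        dist, idx = tree.query(centres, k=2)
        required = 0.5 * (diam + diam[idx[:, 1]])
        tight = dist[:, 1] < required
        if not tight.any():
            break
        scale = np.ones(n)
        ratio = 0.999 * dist[tight, 1] / required[tight]
        np.minimum.at(scale, np.nonzero(tight)[0], ratio)
        np.minimum.at(scale, idx[tight, 1], ratio)
        diam = diam * scale
        length = length * scale

    # neighbour ground truth from the lattice (before voxelisation)
    kq = min(8, n)
    dists, nbrs = tree.query(centres, k=kq)
    io_true = np.full(n, np.nan)
    for i in range(n):
        d = dists[i, 1:]
        keep = d <= 1.45 * d[0]
        nb = centres[nbrs[i, 1:][keep]]
        cosang = np.clip((nb @ centres[i]) / (R * R), -1, 1)
        io_true[i] = np.degrees(np.arccos(cosang)).mean()

    # rasterise
    vs = spec.voxel_size
    pad = np.maximum(diam / 2, length) + 2 * vs
    lo = np.floor((centres - pad[:, None]).min(axis=0) / vs) * vs
    hi = np.ceil((centres + pad[:, None]).max(axis=0) / vs) * vs
    shape_xyz = np.round((hi - lo) / vs).astype(int) + 1
    grid = np.zeros(shape_xyz[::-1], dtype=bool)  # (z, y, x)
    vol_vox = np.zeros(n, dtype=int)
    centroid = np.zeros((n, 3))
    for i in range(n):
        c, u, r2, L = centres[i], axes[i], diam[i] / 2.0, length[i]
        b = max(r2, L) + vs
        i0 = np.floor((c - b - lo) / vs).astype(int)
        i1 = np.ceil((c + b - lo) / vs).astype(int)
        xs = lo[0] + vs * np.arange(i0[0], i1[0] + 1)
        ys = lo[1] + vs * np.arange(i0[1], i1[1] + 1)
        zs = lo[2] + vs * np.arange(i0[2], i1[2] + 1)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        P = np.stack([X - c[0], Y - c[1], Z - c[2]], axis=-1)
        tco = P @ u
        rho2 = (P * P).sum(-1) - tco**2
        inside = (tco >= 0) & ((rho2 / r2**2) + (tco / L) ** 2 <= 1.0)
        if not inside.any():
            continue
        ii, jj, kk = np.nonzero(inside)
        gx, gy, gz = ii + i0[0], jj + i0[1], kk + i0[2]
        grid[gz, gy, gx] = True
        vol_vox[i] = inside.sum()
        centroid[i] = np.column_stack(
            [lo[0] + vs * gx, lo[1] + vs * gy, lo[2] + vs * gz]
        ).mean(axis=0)

    truth = pd.DataFrame(
        {
            "lens_id": np.arange(n),
            "x_um": centroid[:, 0],
            "y_um": centroid[:, 1],
            "z_um": centroid[:, 2],
            "centre_x_um": centres[:, 0],
            "centre_y_um": centres[:, 1],
            "centre_z_um": centres[:, 2],
            "axis_x": axes[:, 0],
            "axis_y": axes[:, 1],
            "axis_z": axes[:, 2],
            "diameter_um": diam,
            "length_um": length,
            "volume_um3": vol_vox * vs**3,
            "n_vox": vol_vox,
            "elevation_deg": elev,
            "azimuth_deg": azim,
            "io_true_deg": io_true,
        }
    )
    volume = VolumeStack(voxels=grid, voxel_size=vs, origin=tuple(lo))
    return volume, truth


# ---------------------------------------------------------------------------
# Synthetic optomotor (ΔWBA) traces
# ---------------------------------------------------------------------------


@dataclass
class SyntheticResponseSpec:
    """Study conditions of a synthetic optomotor cohort.

    The steering response to a moving grating saturates logistically in
    log-contrast (centred ``log2_offset`` octaves below the discernibility
    threshold, slope ``octave_steepness`` per octave), passes gratings up to
    the spatial cutoff and attenuates sharply above it, and rises with
    temporal frequency up to the temporal cutoff.  Per-fly gain varies
    log-normally; a per-fly directional bias, a slow baseline random walk and
    white noise are added on top.
    """

    gain: float = 1.0                    # ΔWBA units at saturation
    contrast_threshold: float = 0.27     # Michelson
    spatial_cutoff: float = 0.1          # cycles/degree
    temporal_cutoff: float = 50.0        # Hz
    directional_bias: float = 0.3        # ΔWBA units (per-fly SD)
    baseline_drift_sd: float = 0.05      # ΔWBA units over one trace
    noise_sd: float = 0.3                # ΔWBA units per sample
    seed: int = 0
    octave_steepness: float = 6.0
    log2_offset: float = 0.5
    gain_spread: float = 0.1             # SD of log per-fly gain
    rise_tau: float = 0.15               # s, response rise time constant

    def __post_init__(self) -> None:
        if self.contrast_threshold <= 0:
            raise ValueError("contrast_threshold must be > 0")
        if self.spatial_cutoff <= 0 or self.temporal_cutoff <= 0:
            raise ValueError("cutoffs must be > 0")


def _contrast_response(c: float, spec: SyntheticResponseSpec) -> float:
    if c <= 0:
        return 0.0
    x = spec.octave_steepness * (
        math.log2(c / spec.contrast_threshold) + spec.log2_offset
    )
    return 1.0 / (1.0 + math.exp(-x))


def _spatial_response(sf: float, spec: SyntheticResponseSpec) -> float:
    if sf <= 0:
        return 0.0
    if sf <= spec.spatial_cutoff:
        return 1.0
    return math.exp(-(((sf / spec.spatial_cutoff) - 1.0) / 0.15) ** 2)


def _temporal_response(tf: float, spec: SyntheticResponseSpec) -> float:
    if tf <= 0:
        return 0.0
    rise = tf / (tf + 1.0)
    if tf <= spec.temporal_cutoff:
        return rise
    return rise * math.exp(-(((tf / spec.temporal_cutoff) - 1.0) / 0.15) ** 2)


def expected_response_fraction(g: Grating, spec: SyntheticResponseSpec) -> float:
    """Noise-free saturating response fraction (0..1) for a grating."""
    return (
        _contrast_response(g.contrast, spec)
        * _spatial_response(g.sf_cpd, spec)
        * _temporal_response(g.tf_hz, spec)
    )


def generate_wba_traces(
    spec: SyntheticResponseSpec,
    stimuli: Sequence[Grating],
    n_flies: int,
    n_trials: int = 4,
    fs: float = 1000.0,
) -> list[WBATrace]:
    """Simulate ΔWBA traces for every fly × stimulus × trial.

    The sign convention is positive ΔWBA = steering to the left, so a
    leftward grating drives the response positive and a rightward one
    negative.  Deterministic given ``spec.seed``.
    """
    if not stimuli:
        raise ValueError("stimulus list is empty")
    rng = np.random.default_rng(spec.seed)
    traces: list[WBATrace] = []
    for f in range(n_flies):
        gain_f = spec.gain * math.exp(rng.normal(0.0, spec.gain_spread))
        bias_f = rng.normal(0.0, spec.directional_bias)
        for g in stimuli:
            total = g.still_duration + g.motion_duration
            nsamp = int(round(total * fs)) + 1
            t = np.arange(nsamp) / fs
            onset = g.still_duration
            amp = gain_f * expected_response_fraction(g, spec)
            sign = 1.0 if g.direction == "left" else -1.0
            post = t >= onset
            shape = np.zeros(nsamp)
            shape[post] = 1.0 - np.exp(-(t[post] - onset) / spec.rise_tau)
            for trial in range(n_trials):
                drift = np.cumsum(rng.normal(0.0, 1.0, nsamp))
                drift *= spec.baseline_drift_sd / math.sqrt(nsamp)
                noise = rng.normal(0.0, spec.noise_sd, nsamp)
                dwba = bias_f + drift + noise + sign * amp * shape
                traces.append(
                    WBATrace(
                        fly_id=f,
                        time_s=t,
                        dwba=dwba,
                        grating=g,
                        onset_s=onset,
                        trial_id=trial,
                    )
                )
    return traces


def traces_to_table(traces: Sequence[WBATrace]) -> pd.DataFrame:
    """Long-format trace table (time_s, dwba, fly_id, trial_id, stimulus columns)."""
    frames = []
    for tr in traces:
        g = tr.grating
        frames.append(
            pd.DataFrame(
                {
                    "time_s": tr.time_s,
                    "dwba": tr.dwba,
                    "fly_id": tr.fly_id,
                    "trial_id": tr.trial_id,
                    "contrast": g.contrast,
                    "sf_cpd": g.sf_cpd,
                    "tf_hz": g.tf_hz,
                    "direction": g.direction,
                    "onset_s": tr.onset_s,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Synthetic facet landmarks
# ---------------------------------------------------------------------------


def regular_hexagon(elongation: float = 1.0, phase: float = 0.0) -> np.ndarray:
    """Unit-circumradius hexagon template, optionally elongated along x."""
    ang = phase + np.arange(6) * math.pi / 3.0
    pts = np.column_stack([np.cos(ang) * elongation, np.sin(ang)])
    return pts


def generate_landmark_sets(
    n_facets: int,
    shape_classes: Sequence[np.ndarray],
    noise_sd: float = 0.0,
    seed: int = 0,
    reflect_fraction: float = 0.0,
    scale_range: tuple[float, float] = (0.8, 1.25),
) -> pd.DataFrame:
    """Facets drawn from labelled 6-landmark templates under random
    similarity transforms (rotation, translation, scale, optional
    reflection) plus isotropic landmark noise.

    Returns a table with ``lm1_x`` … ``lm6_y``, the ground-truth
    ``true_class`` and balanced ``position``/``sex``/``strain`` labels.
    """
    rng = np.random.default_rng(seed)
    for tpl in shape_classes:
        tpl = np.asarray(tpl)
        if tpl.shape != (6, 2):
            raise ValueError(f"each template must be 6 planar points, got {tpl.shape}")
    rows = []
    for i in range(n_facets):
        cls = i % len(shape_classes)
        tpl = np.asarray(shape_classes[cls], dtype=float)
        ang = rng.uniform(0, 2 * math.pi)
        s = rng.uniform(*scale_range)
        Rm = s * np.array(
            [[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]]
        )
        reflected = rng.uniform() < reflect_fraction
        if reflected:
            Rm = Rm @ np.diag([1.0, -1.0])
        pts = tpl @ Rm.T + rng.uniform(-5, 5, 2)
        if noise_sd > 0:
            pts = pts + rng.normal(0.0, noise_sd, pts.shape)
        row: dict = {"facet_id": i, "true_class": cls, "reflected": reflected}
        for j, (x, y) in enumerate(pts, start=1):
            row[f"lm{j}_x"] = x
            row[f"lm{j}_y"] = y
        row["position"] = "frontal" if cls == 0 else "central"
        row["sex"] = "female" if (i // 2) % 2 == 0 else "male"
        row["strain"] = "RED3" if (i // 4) % 2 == 0 else "M3"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic allometric cohorts
# ---------------------------------------------------------------------------


def generate_allometry_cohort(
    n_per_species: int = 6,
    slope: float = 2.0,
    species_offset: float = 5.0,
    intercept: float = 3.0,
    sa_range: tuple[float, float] = (1.0e5, 3.0e5),
    noise_sd: float = 1.0,
    seed: int = 0,
    outcome: str = "outcome",
) -> pd.DataFrame:
    """Two-species cohort with a known SA slope and species offset.

    ``species_offset`` is added to the RED3-coded group after SA adjustment,
    matching the RED3-minus-M3 contrast convention.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_species
    sa = rng.uniform(*sa_range, n)
    species = np.array(["mauritiana_RED3"] * n_per_species + ["simulans_M3"] * n_per_species)
    dummy = (species == "mauritiana_RED3").astype(float)
    y = intercept + slope * sa + species_offset * dummy + rng.normal(0, noise_sd, n)
    return pd.DataFrame(
        {
            "subject": [f"s{i:02d}" for i in range(n)],
            "species": species,
            "SA": sa,
            outcome: y,
        }
    )
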