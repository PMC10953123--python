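"""3D ommatidia detection and lens metrology (ODA-3D stage).

Given a cleaned binary volume containing only corneal lenses, the chain is:

1. :func:`fit_eye_surface` — least-squares sphere through the lens voxel
   cloud (biquadratic height-field fallback for flat/degenerate clouds);
2. :func:`project_to_surface` — azimuthal-equidistant chart of every voxel
   about the cap centre plus a signed normal offset (invertible);
3. :func:`cluster_lenses` — lattice spacing from the dominant spatial-
   frequency peak of the projected image's periodogram, seeding marker-based
   watershed segmentation, one label per ommatidium;
4. :func:`measure_lenses` — per-lens volume, cross-sectional area, diameter,
   length and outward axis;
5. :func:`compute_io_angles` — immediate neighbours from a Delaunay
   triangulation of projected centroids (edges above 1.8× the median length
   discarded) and the mean interommatidial angle per lens;
6. :func:`estimate_surface_area` — eye surface area as the sum of circular
   facet areas, SA = Σ π·(d/2)².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Delaunay
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .io_core import RunConfig, VolumeStack, logger

LENS_COLUMNS = [
    "lens_id", "x_um", "y_um", "z_um", "volume_um3", "diameter_um",
    "area_um2", "length_um", "axis_x", "axis_y", "axis_z",
    "n_neighbours", "io_mean_deg",
]


# ---------------------------------------------------------------------------
# Surface fitting
# ---------------------------------------------------------------------------


@dataclass
class EyeSurface:
    """Cross-sectional surface through the lens cloud.

    Either a sphere (centre + radius) or a biquadratic height-field over the
    cloud's principal plane (origin, orthonormal basis, six coefficients).
    """

    kind: str                      # "sphere" | "quadratic"
    residual_um: float
    centre: np.ndarray | None = None
    radius: float | None = None
    origin: np.ndarray | None = None
    basis: np.ndarray | None = None     # rows: e_u, e_v, e_w
    coeffs: np.ndarray | None = None    # w = a + b u + c v + d u² + e uv + f v²

    def __post_init__(self) -> None:
        if not np.isfinite(self.residual_um):
            raise ValueError("surface residual must be finite")
        if self.kind == "sphere" and (self.radius is None or self.radius <= 0):
            raise ValueError("sphere surface needs a positive radius")


def _fit_sphere(coords: np.ndarray) -> tuple[np.ndarray, float, float]:
    A = np.column_stack([2.0 * coords, np.ones(len(coords))])
    b = (coords**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre, k = sol[:3], sol[3]
    r2 = k + centre @ centre
    if r2 <= 0:
        raise np.linalg.LinAlgError("degenerate sphere fit")
    radius = math.sqrt(r2)
    resid = np.linalg.norm(coords - centre, axis=1) - radius
    return centre, radius, float(np.sqrt((resid**2).mean()))


def _fit_quadratic(coords: np.ndarray) -> EyeSurface:
    mean = coords.mean(axis=0)
    centred = coords - mean
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    basis = vt  # rows ordered by decreasing variance; e_w = row 2
    uvw = centred @ basis.T
    u, v, w = uvw[:, 0], uvw[:, 1], uvw[:, 2]
    A = np.column_stack([np.ones_like(u), u, v, u**2, u * v, v**2])
    coeffs, *_ = np.linalg.lstsq(A, w, rcond=None)
    resid = w - A @ coeffs
    return EyeSurface(
        kind="quadratic",
        residual_um=float(np.sqrt((resid**2).mean())),
        origin=mean,
        basis=basis,
        coeffs=coeffs,
    )


def fit_eye_surface(
    volume: VolumeStack | np.ndarray,
    model: str = "auto",
    sphere_residual_limit_um: float | None = None,
) -> EyeSurface:
    """Least-squares surface through all lens-voxel coordinates.

    ``model`` is ``"sphere"``, ``"quadratic"`` or ``"auto"``.  Auto mode
    fits both and keeps the sphere unless it is degenerate (e.g. a planar
    cloud, where the height-field is near-exact and the sphere is not) or
    its RMS residual exceeds ``sphere_residual_limit_um``.
    """
    coords = volume.coords_um() if isinstance(volume, VolumeStack) else np.asarray(volume)
    if len(coords) < 100:
        raise ValueError(f"need at least 100 lens voxels, got {len(coords)}")
    extent = float(np.ptp(coords, axis=0).max())
    if extent == 0 or np.linalg.matrix_rank(coords - coords.mean(0)) < 2:
        raise ValueError("degenerate (collinear) voxel cloud")
    if model == "quadratic":
        return _fit_quadratic(coords)
    quad = _fit_quadratic(coords)
    try:
        centre, radius, resid = _fit_sphere(coords)
        sphere_ok = radius < 100.0 * extent
        # a flat or saddle cloud fits the height-field far better than any
        # sphere; keep the sphere only when it is competitive
        sphere_ok &= resid <= max(2.0 * quad.residual_um, 1e-9 * extent)
        if sphere_residual_limit_um is not None:
            sphere_ok &= resid <= sphere_residual_limit_um
    except np.linalg.LinAlgError:
        sphere_ok = False
    if model == "sphere":
        if not sphere_ok:
            raise ValueError("sphere fit rejected (degenerate or over residual limit)")
        return EyeSurface(kind="sphere", residual_um=resid, centre=centre, radius=radius)
    if sphere_ok:
        return EyeSurface(kind="sphere", residual_um=resid, centre=centre, radius=radius)
    logger.info("sphere fit rejected; falling back to biquadratic height-field")
    return quad


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


@dataclass
class Projection:
    """2D chart of the lens voxels with an exact inverse mapping.

    For a sphere the chart is azimuthal-equidistant about the cap centre
    (``xy = R·θ·(cos φ, sin φ)``) and ``offset`` is the signed radial
    distance from the fitted sphere; the local area distortion of the chart
    is ``sin θ / θ`` and is exposed per voxel for area correction.
    """

    surface: EyeSurface
    xy: np.ndarray          # (N, 2) chart coordinates, µm
    offset: np.ndarray      # (N,) signed normal offset, µm
    coords3d: np.ndarray    # (N, 3) original voxel coordinates, µm
    voxel_size: float
    chart_axes: np.ndarray | None = None   # rows: n0, e1, e2 (sphere charts)
    n_excluded: int = 0

    @property
    def theta(self) -> np.ndarray | None:
        """Angular distance (radians) from the chart centre (sphere charts)."""
        if self.surface.kind != "sphere":
            return None
        return np.linalg.norm(self.xy, axis=1) / self.surface.radius

    def area_correction(self) -> np.ndarray:
        """Per-voxel factor mapping chart area to true surface area."""
        th = self.theta
        if th is None:
            return np.ones(len(self.xy))
        return np.where(th > 1e-9, np.sin(np.minimum(th, np.pi)) / np.maximum(th, 1e-9), 1.0)

    def chart_coords(self, points: np.ndarray) -> np.ndarray:
        """Chart coordinates of arbitrary 3D points (same mapping as voxels)."""
        pts = np.atleast_2d(points)
        if self.surface.kind == "sphere":
            n0, e1, e2 = self.chart_axes
            v = pts - self.surface.centre
            w = v / np.linalg.norm(v, axis=1, keepdims=True)
            th = np.arccos(np.clip(w @ n0, -1, 1))
            ph = np.arctan2(w @ e2, w @ e1)
            r = self.surface.radius * th
            return np.column_stack([r * np.cos(ph), r * np.sin(ph)])
        local = (pts - self.surface.origin) @ self.surface.basis.T
        return local[:, :2]

    def to_3d(self, xy: np.ndarray, offset: np.ndarray) -> np.ndarray:
        """Invert the chart: (xy, offset) → 3D physical coordinates."""
        xy = np.atleast_2d(xy)
        offset = np.atleast_1d(offset)
        if self.surface.kind == "sphere":
            n0, e1, e2 = self.chart_axes
            R = self.surface.radius
            th = np.linalg.norm(xy, axis=1) / R
            ph = np.arctan2(xy[:, 1], xy[:, 0])
            w = (
                np.cos(th)[:, None] * n0
                + (np.sin(th) * np.cos(ph))[:, None] * e1
                + (np.sin(th) * np.sin(ph))[:, None] * e2
            )
            return self.surface.centre + (R + offset)[:, None] * w
        a, b, c, d, e, f = self.surface.coeffs
        u, v = xy[:, 0], xy[:, 1]
        w = a + b * u + c * v + d * u**2 + e * u * v + f * v**2 + offset
        return self.surface.origin + np.column_stack([u, v, w]) @ self.surface.basis


def project_to_surface(
    volume: VolumeStack,
    surface: EyeSurface,
    max_offset_um: float | None = None,
) -> Projection:
    """Assign every lens voxel 2D chart coordinates plus a signed offset.

    Voxels farther than ``max_offset_um`` from the surface are flagged,
    excluded and counted in the log.
    """
    coords = volume.coords_um()
    if surface.kind == "sphere":
        v = coords - surface.centre
        r = np.linalg.norm(v, axis=1)
        offset = r - surface.radius
        w = v / r[:, None]
        n0 = w.mean(axis=0)
        n0 /= np.linalg.norm(n0)
        helper = np.array([0.0, 0.0, 1.0])
        if abs(n0 @ helper) > 0.95:
            helper = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(helper, n0)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n0, e1)
        th = np.arccos(np.clip(w @ n0, -1, 1))
        ph = np.arctan2(w @ e2, w @ e1)
        rr = surface.radius * th
        xy = np.column_stack([rr * np.cos(ph), rr * np.sin(ph)])
        chart_axes = np.vstack([n0, e1, e2])
    else:
        local = (coords - surface.origin) @ surface.basis.T
        u, v = local[:, 0], local[:, 1]
        a, b, c, d, e, f = surface.coeffs
        offset = local[:, 2] - (a + b * u + c * v + d * u**2 + e * u * v + f * v**2)
        xy = local[:, :2]
        chart_axes = None
    keep = np.ones(len(coords), dtype=bool)
    if max_offset_um is not None:
        keep = np.abs(offset) <= max_offset_um
        if (~keep).any():
            logger.info("excluded %d voxels beyond %.1f µm from the surface",
                        int((~keep).sum()), max_offset_um)
    return Projection(
        surface=surface,
        xy=xy[keep],
        offset=offset[keep],
        coords3d=coords[keep],
        voxel_size=volume.voxel_size,
        chart_axes=chart_axes,
        n_excluded=int((~keep).sum()),
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class LensLabels:
    """Pixelised chart with one watershed label per ommatidium."""

    labels: np.ndarray         # 2D int array, 0 = background
    image: np.ndarray          # 2D voxel-count image on the same grid
    origin_xy: np.ndarray      # chart coordinate of pixel (0, 0) centre
    pixel_size: float
    spacing_um: float

    @property
    def n_lenses(self) -> int:
        return int(self.labels.max())

    def pixel_of(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rel = (np.atleast_2d(xy) - self.origin_xy) / self.pixel_size
        ij = np.round(rel).astype(int)
        ij = np.clip(ij, 0, np.array(self.labels.shape)[::-1] - 1)
        return ij[:, 1], ij[:, 0]  # row (y), col (x)


def estimate_lattice_spacing(
    image: np.ndarray, pixel_size: float, min_prominence: float = 3.0
) -> float:
    """Dominant lattice spacing from the radial periodogram of the image.

    Assumes a roughly hexagonal lattice, whose first spectral ring sits at
    f = 2/(√3·s); raises when no sufficiently prominent peak exists.
    """
    img = image.astype(float)
    img -= img.mean()
    F = np.abs(np.fft.rfft2(img)) ** 2
    fy = np.fft.fftfreq(image.shape[0], d=pixel_size)
    fx = np.fft.rfftfreq(image.shape[1], d=pixel_size)
    fr = np.hypot(fy[:, None], fx[None, :])
    extent = max(image.shape) * pixel_size
    lo, hi = 3.0 / extent, 1.0 / (3.0 * pixel_size)
    band = (fr >= lo) & (fr <= hi)
    if not band.any():
        raise ValueError("image too small for spectral spacing estimation; "
                         "pass spacing_um explicitly")
    nbins = 200
    edges = np.linspace(lo, hi, nbins + 1)
    idx = np.digitize(fr[band], edges) - 1
    power = np.bincount(idx.clip(0, nbins - 1), weights=F[band], minlength=nbins)
    count = np.bincount(idx.clip(0, nbins - 1), minlength=nbins).astype(float)
    occupied = count > 0
    prof = power[occupied] / count[occupied]
    freqs = 0.5 * (edges[:-1] + edges[1:])[occupied]
    # a lattice shows an interior spectral ring; blob/noise spectra decay
    # monotonically from DC, so require a prominent interior local maximum
    from scipy.signal import find_peaks
    med = float(np.median(prof[prof > 0])) if (prof > 0).any() else 0.0
    peaks, _ = find_peaks(prof, prominence=min_prominence * max(med, 1e-300))
    if med <= 0 or len(peaks) == 0:
        raise ValueError(
            "no periodic lattice detectable in the projected image; "
            "pass spacing_um explicitly to override"
        )
    f_peak = float(freqs[peaks[np.argmax(prof[peaks])]])
    return float(2.0 / (math.sqrt(3.0) * f_peak))


def cluster_lenses(
    projection: Projection,
    spacing_um: float | None = None,
    pixel_size: float | None = None,
) -> LensLabels:
    """Label each projected pixel with one ommatidium id.

    Expected lens spacing is estimated from the periodogram (or given
    explicitly); local maxima of the smoothed voxel-count image seed a
    watershed restricted to occupied pixels, so every lens pixel receives
    exactly one label.
    """
    if len(projection.xy) == 0:
        raise ValueError("empty projection")
    px = pixel_size or projection.voxel_size
    xy = projection.xy
    lo = xy.min(axis=0) - px
    hi = xy.max(axis=0) + px
    nx = int(np.ceil((hi[0] - lo[0]) / px)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / px)) + 1
    col = np.clip(np.round((xy[:, 0] - lo[0]) / px).astype(int), 0, nx - 1)
    row = np.clip(np.round((xy[:, 1] - lo[1]) / px).astype(int), 0, ny - 1)
    image = np.zeros((ny, nx), dtype=np.int32)
    np.add.at(image, (row, col), 1)
    if spacing_um is None:
        spacing_um = estimate_lattice_spacing(image, px)
    sp_px = spacing_um / px
    smooth = ndimage.gaussian_filter(image.astype(float), sigma=max(sp_px / 5.0, 0.8))
    min_dist = max(1, int(round(0.3 * sp_px)))
    peaks = peak_local_max(
        smooth, min_distance=min_dist, threshold_rel=0.05, exclude_border=False
    )
    markers = np.zeros_like(image, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-smooth, markers, mask=image > 0)
    # relabel contiguously from 1 (watershed can drop marker ids under the mask)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    labels = remap[labels]
    return LensLabels(
        labels=labels, image=image, origin_xy=lo, pixel_size=px, spacing_um=spacing_um
    )


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------


def measure_lenses(
    labels: LensLabels,
    projection: Projection,
    min_voxels: int = 20,
    length_along: str = "axis",
    axis_refine_weight: float = 0.25,
) -> pd.DataFrame:
    """Per-lens geometry from the labelled projection.

    volume = voxel count × voxel_size³; cross-sectional area = chart
    footprint area × local chart-area correction; diameter = that of the
    circle with the same area; axis = outward surface normal at the centroid
    blended toward the lens's principal (thinnest) inertial axis; length =
    extent along the axis (or the surface normal when
    ``length_along='normal'``).
    """
    vs = projection.voxel_size
    r_idx, c_idx = labels.pixel_of(projection.xy)
    vox_label = labels.labels[r_idx, c_idx]
    dropped_bg = int((vox_label == 0).sum())
    if dropped_bg:
        logger.info("%d voxels fell on unlabelled pixels and were dropped", dropped_bg)
    corr = projection.area_correction()
    rows = []
    n_small = 0
    for lab in range(1, labels.n_lenses + 1):
        sel = vox_label == lab
        n = int(sel.sum())
        if n < min_voxels:
            n_small += 1
            continue
        pts = projection.coords3d[sel]
        centroid = pts.mean(axis=0)
        # footprint: distinct chart pixels of this lens
        pix = set(zip(r_idx[sel].tolist(), c_idx[sel].tolist()))
        area = len(pix) * labels.pixel_size**2 * float(corr[sel].mean())
        diameter = 2.0 * math.sqrt(area / math.pi)
        # outward normal at centroid
        if projection.surface.kind == "sphere":
            normal = centroid - projection.surface.centre
            normal /= np.linalg.norm(normal)
        else:
            normal = projection.surface.basis[2].copy()
        # principal inertial axis: direction of least spatial variance
        centred = pts - centroid
        if len(pts) >= 4:
            cov = centred.T @ centred / len(pts)
            evals, evecs = np.linalg.eigh(cov)
            inertial = evecs[:, 0]
            if inertial @ normal < 0:
                inertial = -inertial
            w = axis_refine_weight
            axis = (1.0 - w) * normal + w * inertial
            axis /= np.linalg.norm(axis)
        else:
            axis = normal
        ref = axis if length_along == "axis" else normal
        proj = centred @ ref
        length = float(proj.max() - proj.min()) + vs
        rows.append(
            {
                "lens_id": lab,
                "x_um": centroid[0], "y_um": centroid[1], "z_um": centroid[2],
                "volume_um3": n * vs**3,
                "n_vox": n,
                "area_um2": area,
                "diameter_um": diameter,
                "length_um": length,
                "axis_x": axis[0], "axis_y": axis[1], "axis_z": axis[2],
            }
        )
    if n_small:
        logger.info("dropped %d lenses below %d voxels", n_small, min_voxels)
    df = pd.DataFrame(rows).reset_index(drop=True)
    if not df.empty:
        df["lens_id"] = np.arange(len(df))
    return df


def compute_io_angles(
    lenses: pd.DataFrame,
    projection: Projection,
    edge_factor: float = 1.8,
) -> pd.DataFrame:
    """Mean interommatidial angle of each lens with its immediate neighbours.

    Neighbours share a Delaunay edge in the chart projection of the lens
    centroids; edges longer than ``edge_factor`` × the median edge length
    (spurious hull edges) are discarded.  The pairwise IO angle is the angle
    between the two lens axes; lenses left without neighbours get an
    undefined (NaN) ``io_mean_deg`` and are flagged in the log.
    """
    if len(lenses) < 2:
        raise ValueError("need at least 2 lenses with axes")
    cent = lenses[["x_um", "y_um", "z_um"]].to_numpy()
    axes = lenses[["axis_x", "axis_y", "axis_z"]].to_numpy()
    xy = projection.chart_coords(cent)
    if len(lenses) == 2:
        edges = np.array([[0, 1]])
    else:
        tri = Delaunay(xy)
        e = set()
        for simplex in tri.simplices:
            for a in range(3):
                i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
                e.add((i, j))
        edges = np.array(sorted(e))
        lengths = np.linalg.norm(xy[edges[:, 0]] - xy[edges[:, 1]], axis=1)
        edges = edges[lengths <= edge_factor * np.median(lengths)]
    cosang = np.clip((axes[edges[:, 0]] * axes[edges[:, 1]]).sum(axis=1), -1, 1)
    ang = np.degrees(np.arccos(cosang))
    n = len(lenses)
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    np.add.at(sums, edges[:, 0], ang)
    np.add.at(sums, edges[:, 1], ang)
    np.add.at(counts, edges[:, 0], 1)
    np.add.at(counts, edges[:, 1], 1)
    out = lenses.copy()
    out["n_neighbours"] = counts
    out["io_mean_deg"] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    iso = int((counts == 0).sum())
    if iso:
        logger.warning("%d lenses have no neighbours after the edge filter; "
                       "io_mean undefined", iso)
    return out


def estimate_surface_area(lenses: pd.DataFrame) -> float:
    """Eye surface area as the sum of circular facet areas, Σ π·(d/2)²."""
    if len(lenses) < 1 or "diameter_um" not in lenses:
        raise ValueError("need at least one lens with a diameter")
    d = lenses["diameter_um"].to_numpy()
    return float((math.pi * (d / 2.0) ** 2).sum())


# ---------------------------------------------------------------------------
# Eye records
# ---------------------------------------------------------------------------


@dataclass
class EyeRecord:
    """One subject's detected lens set with species/sex labels.

    ``lenses`` columns follow :data:`LENS_COLUMNS` (plus any polar columns
    added downstream); SA is always the circular-facet sum so that
    A = SA/N holds by construction.
    """

    subject_id: str
    species: str
    sex: str
    lenses: pd.DataFrame
    surface: EyeSurface
    meta: dict = field(default_factory=dict)

    @property
    def lens_count(self) -> int:
        return len(self.lenses)

    @property
    def surface_area_um2(self) -> float:
        return estimate_surface_area(self.lenses)

    @property
    def mean_lens_area_um2(self) -> float:
        return self.surface_area_um2 / self.lens_count


def detect_eye(
    volume: VolumeStack,
    config: RunConfig | None = None,
    subject_id: str = "subject",
    species: str = "",
    sex: str = "",
    spacing_um: float | None = None,
) -> EyeRecord:
    """Run the full ODA-3D chain on one volume and return an EyeRecord."""
    cfg = config or RunConfig()
    surface = fit_eye_surface(volume, model=cfg.surface_model)
    projection = project_to_surface(volume, surface, cfg.max_surface_offset)
    labels = cluster_lenses(projection, spacing_um=spacing_um)
    lenses = measure_lenses(
        labels, projection, min_voxels=cfg.min_lens_voxels,
        length_along=cfg.length_along,
    )
    lenses = compute_io_angles(lenses, projection, edge_factor=cfg.neighbour_edge_factor)
    return EyeRecord(
        subject_id=subject_id, species=species, sex=sex,
        lenses=lenses, surface=surface,
        meta={"spacing_um": labels.spacing_um, "config_hash": cfg.param_hash(),
              "seed": cfg.seed},
    )


def eye_record_from_table(
    truth: pd.DataFrame,
    radius_um: float,
    centre: tuple[float, float, float] = (0.0, 0.0, 0.0),
    subject_id: str = "truth",
    species: str = "",
    sex: str = "",
) -> EyeRecord:
    """Wrap a ground-truth lens table as an EyeRecord (spherical surface)."""
    df = truth.copy()
    if "io_mean_deg" not in df and "io_true_deg" in df:
        df["io_mean_deg"] = df["io_true_deg"]
    surface = EyeSurface(
        kind="sphere", residual_um=0.0,
        centre=np.asarray(centre, dtype=float), radius=radius_um,
    )
    return EyeRecord(
        subject_id=subject_id, species=species, sex=sex, lenses=df, surface=surface
    )
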