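"""File formats, run configuration and logging for the pipeline.

Volumes are binary voxel grids (multi-page TIFF or voxel-coordinate CSV),
tables are plain CSV with mandatory headers, and run configuration is a small
dataclass serialisable to YAML.  Every table written through :func:`write_table`
can carry a JSON sidecar embedding the run seed and a parameter hash so any
output is regenerable from its metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


class NonBinaryVolumeError(ValueError):
    """Raised when a volume contains more than two intensity levels."""


@dataclass
class VolumeStack:
    """A binary voxel grid with isotropic physical spacing.

    Attributes
    ----------
    voxels : 3D bool array, indexed (z, y, x)
    voxel_size : edge length of one voxel, micrometres
    origin : physical coordinate (µm) of the centre of voxel (0, 0, 0),
        ordered (x, y, z)
    """

    voxels: np.ndarray
    voxel_size: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.voxels.shape}")
        if self.voxels.dtype != bool:
            self.voxels = _coerce_binary(self.voxels)
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if max(self.voxels.shape) <= 1:
            logger.warning("degenerate volume: no dimension exceeds 1")

    @property
    def n_true(self) -> int:
        return int(self.voxels.sum())

    def coords_um(self) -> np.ndarray:
        """Physical (x, y, z) coordinates (µm) of all true voxels, voxel-centred.

        The grid itself is indexed (z, y, x) as stored in TIFF pages; physical
        coordinates are always (x, y, z).
        """
        idx = np.argwhere(self.voxels).astype(float)
        return idx[:, ::-1] * self.voxel_size + np.asarray(self.origin)


def _coerce_binary(arr: np.ndarray) -> np.ndarray:
    levels = np.unique(arr)
    if len(levels) > 2:
        extra = levels[:8]
        raise NonBinaryVolumeError(
            f"volume is not binary: found {len(levels)} distinct values "
            f"(e.g. {extra.tolist()}); expected at most two levels"
        )
    return arr > levels.min() if len(levels) == 2 else arr.astype(bool)


def read_volume(path: str | Path, voxel_size: float | None = None) -> VolumeStack:
    """Read a binary volume from a multi-page TIFF or a voxel-coordinate CSV.

    CSV files must carry a ``# voxel_size_um: <v>`` comment line followed by a
    header ``z,y,x`` (voxel indices); the voxel list is rasterised onto the
    tightest enclosing grid.  An explicit ``voxel_size`` argument overrides the
    file's metadata; when neither is present, 1.0 µm is assumed with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        vs = voxel_size
        if vs is None:
            logger.warning("no voxel size given for %s; assuming 1.0 µm", path.name)
            vs = 1.0
        return VolumeStack(voxels=arr, voxel_size=vs)
    # CSV voxel list
    meta_vs = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "voxel_size_um" in first:
        meta_vs = float(first.split(":")[1])
    df = pd.read_csv(path, comment="#")
    for col in ("z", "y", "x"):
        if col not in df.columns:
            raise ValueError(f"voxel CSV must have columns z,y,x; missing {col!r}")
    idx = df[["z", "y", "x"]].to_numpy()
    if not np.allclose(idx, np.round(idx)):
        raise ValueError("voxel CSV coordinates must be integer voxel indices")
    idx = np.round(idx).astype(int)
    lo = idx.min(axis=0)
    shape = idx.max(axis=0) - lo + 1
    vox = np.zeros(shape, dtype=bool)
    rel = idx - lo
    vox[rel[:, 0], rel[:, 1], rel[:, 2]] = True
    vs = voxel_size if voxel_size is not None else meta_vs
    if vs is None:
        logger.warning("no voxel size in %s; assuming 1.0 µm", path.name)
        vs = 1.0
    return VolumeStack(voxels=vox, voxel_size=vs, origin=tuple(lo[::-1] * vs))


def write_volume(volume: VolumeStack, path: str | Path) -> Path:
    """Write a binary volume as an 8-bit multi-page TIFF or a voxel CSV."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, volume.voxels.astype(np.uint8))
    else:
        idx = np.argwhere(volume.voxels)
        with open(path, "w") as fh:
            fh.write(f"# voxel_size_um: {volume.voxel_size!r}\n")
            fh.write("z,y,x\n")
            for z, y, x in idx:
                fh.write(f"{z},{y},{x}\n")
    return path


def write_table(
    records: pd.DataFrame,
    path: str | Path,
    allow_empty: bool = False,
    config: "RunConfig | None" = None,
) -> Path:
    """Write a table as CSV (header row, full-precision floats).

    Floats are written with ``repr`` precision so re-reading reproduces the
    decimal text bit-identically.  When ``config`` is given, a JSON sidecar
    ``<path>.meta.json`` embeds the seed and parameter hash.
    """
    path = Path(path)
    df = pd.DataFrame(records)
    if df.empty and not allow_empty:
        raise ValueError("refusing to write an empty table without allow_empty=True")
    # shortest round-trip float repr so re-reading is bit-identical
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(
            json.dumps({"seed": config.seed, "param_hash": config.param_hash()}, indent=1)
        )
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


@dataclass
class RunConfig:
    """Pipeline-wide configuration.

    Detection, binning, bootstrap and synthetic-generator parameters live here
    so that every output can be regenerated from a seed + parameter hash.
    """

    seed: int = 0
    # detection
    surface_model: str = "auto"          # sphere | quadratic | auto
    min_lens_voxels: int = 20
    neighbour_edge_factor: float = 1.8   # Delaunay edge cutoff × median edge
    max_surface_offset: float | None = None  # µm; None keeps all voxels
    length_along: str = "axis"           # axis | normal
    # binning
    n_bins: int = 20
    band_halfwidth_deg: float = 15.0
    # bootstrap
    bootstrap_reps: int = 10_000
    alpha: float = 0.05
    # synthetic
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.min_lens_voxels < 1 or self.bootstrap_reps < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 < self.alpha < 0.5):
            raise ValueError(f"alpha must lie in (0, 0.5), got {self.alpha}")

    def param_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


logger = logging.getLogger("compoundeye")
if not logger.handlers:
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@contextmanager
def stage(name: str):
    """Log a pipeline stage with its wall-clock duration."""
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    finally:
        logger.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)
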