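"""Volume and report I/O shared by every pipeline stage.

Brain maps (R2, R2*, R2', B1+, frequency shift, susceptibility) travel
through the pipeline as :class:`ScalarVolume` objects: a 3-D array with
voxel geometry, a unit tag and an optional brain mask.  On disk they are
NIfTI-1 files; the unit tag lives in a small JSON sidecar because NIfTI
has no field for quantities like ppb or Hz, and the mask is a companion
``*_mask.nii`` volume.

All ppb <-> ppm conversion happens here at the boundary: internal solver
code works in ppm (the relaxometric constant Dr is in Hz/ppm) while
reports are written in ppb, the unit of the published tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("srcsep")

#: unit tags a ScalarVolume may carry
VALID_UNITS = ("Hz", "ppb", "ppm", "relative", "dimensionless")

#: proton gyromagnetic ratio times B0 for a 3 T scanner, in Hz
DEFAULT_IMAGING_FREQUENCY = 123.2e6

PPB_PER_PPM = 1000.0


class VolumeError(ValueError):
    """Raised on contract violations in volume handling."""


@dataclass
class ScalarVolume:
    """A 3-D scalar field with voxel geometry and a unit tag.

    Parameters
    ----------
    data:
        3-D float array.
    voxel_size:
        (dx, dy, dz) in mm, all positive.
    unit:
        one of :data:`VALID_UNITS`.
    mask:
        optional boolean array of the same shape; values inside the mask
        must be finite.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    unit: str
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeError(f"expected 3D volume, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise VolumeError("all three dimensions must be >= 1")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise VolumeError(f"voxel sizes must be three positive numbers, got {self.voxel_size}")
        if self.unit not in VALID_UNITS:
            raise VolumeError(f"unit {self.unit!r} not in {VALID_UNITS}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise VolumeError("mask shape differs from data shape")
            inside = self.data[self.mask]
        else:
            inside = self.data
        if not np.all(np.isfinite(inside)):
            raise VolumeError("non-finite voxels inside mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "ScalarVolume":
        """Same geometry/mask, new data (and optionally a new unit)."""
        return ScalarVolume(data, self.voxel_size, unit or self.unit, self.mask)

    def in_ppm(self) -> np.ndarray:
        """Data converted to ppm; only valid for susceptibility volumes."""
        if self.unit == "ppm":
            return self.data
        if self.unit == "ppb":
            return self.data / PPB_PER_PPM
        raise VolumeError(f"cannot convert unit {self.unit!r} to ppm")


@dataclass
class AcquisitionGeometry:
    """Grid, voxel size, main-field direction and imaging frequency."""

    matrix_size: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    imaging_frequency: float = DEFAULT_IMAGING_FREQUENCY

    def __post_init__(self) -> None:
        self.matrix_size = tuple(int(n) for n in self.matrix_size)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        b0 = np.asarray(self.b0_direction, dtype=float)
        norm = float(np.linalg.norm(b0))
        if abs(norm - 1.0) > 1e-9:
            raise VolumeError(f"b0_direction must be a unit vector, |b0| = {norm}")
        self.b0_direction = tuple(float(v) for v in b0)
        if self.imaging_frequency <= 0:
            raise VolumeError("imaging_frequency must be > 0")


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a full experiment run needs, with explicit seeds.

    The config echo written alongside every run (`to_yaml`) reproduces the
    run: deterministic stages bit-identically, seeded stages
    distribution-identically.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 2.0)
    n_replicates: int = 11
    seed: int = 0
    dr_true: float = 142.0          # Hz/ppm, ground-truth relaxometric constant
    dr_default: float = 137.0       # Hz/ppm, the fixed "toolbox default"
    noise_sd_tse: float = 0.005     # magnitude noise, unit-signal scale
    noise_sd_mege: float = 0.005    # per-channel complex noise, unit-signal scale
    texture_sd_chi: float = 4.0     # within-ROI ppb texture
    texture_sd_r2: float = 0.5      # within-ROI Hz texture
    b1_range: tuple[float, float] = (0.78, 1.15)
    self_consistent: bool = True
    t1_assumed: float = 1000.0      # ms, T1 during the echo train
    lambda_reg: float = 1.0         # solver regularization weight
    max_iters: int = 200
    tol: float = 1e-6
    error_factors: tuple[float, ...] | None = None   # None -> full 50-step series
    dr_modes: tuple[str, ...] = ("default", "regressed")
    output_dir: str | None = None

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


# --------------------------------------------------------------------------
# NIfTI I/O
# --------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    stem = path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    return path.with_name(stem + ".json")


def _mask_path(path: Path) -> Path:
    stem = path.name
    suffix = ".nii"
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            suffix = suf
            break
    return path.with_name(stem + "_mask" + suffix)


def write_volume(vol: ScalarVolume, path: str | Path) -> Path:
    """Write a ScalarVolume as NIfTI-1 plus a JSON unit sidecar.

    The mask, if present, is written as a companion ``*_mask.nii`` volume.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(vol.voxel_size) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float64), affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))
    with open(_sidecar_path(path), "w") as fh:
        json.dump({"unit": vol.unit}, fh)
    if vol.mask is not None:
        mimg = nib.Nifti1Image(vol.mask.astype(np.uint8), affine)
        nib.save(mimg, str(_mask_path(path)))
    return path


def read_volume(path: str | Path, unit: str | None = None) -> ScalarVolume:
    """Read a 3-D NIfTI-1 volume back into a ScalarVolume.

    The unit comes from the JSON sidecar when present, from the ``unit``
    argument otherwise (default "dimensionless").  Round-trips written
    volumes bit-exactly for identical dtype.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeError(f"expected 3D volume, got {data.ndim}D")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    sidecar = _sidecar_path(path)
    if unit is None:
        if sidecar.exists():
            with open(sidecar) as fh:
                unit = json.load(fh).get("unit", "dimensionless")
        else:
            unit = "dimensionless"
    mask = None
    mpath = _mask_path(path)
    if mpath.exists() and mpath != path:
        mask = np.asanyarray(nib.load(str(mpath)).dataobj).astype(bool)
    return ScalarVolume(np.asarray(data, dtype=np.float64), voxel_size, unit, mask)


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------

REPORT_COLUMNS = [
    "roi", "map", "condition",
    "mean_ppb", "sd", "diff_ppb", "MPE_percent", "p_value",
]


def write_report(report: pd.DataFrame, path: str | Path) -> Path:
    """Write an ROI/map/condition report as a tab-delimited table.

    One row per (ROI, map, error condition); values are kept to full float
    precision so a round-trip read preserves at least 6 significant digits.
    """
    if report is None or len(report) == 0:
        raise ValueError("empty report")
    missing = [c for c in REPORT_COLUMNS if c not in report.columns]
    if missing:
        raise ValueError(f"report missing columns: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(path, sep="\t", index=False)
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
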