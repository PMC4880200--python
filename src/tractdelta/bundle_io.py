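"""Reading, writing and in-memory containers for volumes, bundles and reports.

All internal computation happens in world millimetres.  Voxel lookup uses the
inverse affine with deterministic round-half-up on each axis; a fiber point is
associated with the scalar value of its single nearest voxel (no
interpolation).  Points falling outside the volume sample NaN and are excluded
from cross-section statistics at the affected nodes only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScalarVolume",
    "RawBundle",
    "read_volume",
    "read_bundle",
    "write_volume",
    "write_bundle",
    "write_report",
    "write_metadata",
    "read_metadata",
]


@dataclass
class ScalarVolume:
    """A 3D scalar diffusion-metric grid with its voxel-to-world affine.

    ``data[i, j, k]`` is the metric value of voxel ``(i, j, k)``;
    ``affine`` maps voxel indices to world millimetres (invertible).
    ``meta`` carries optional provenance (e.g. the noise-free field of a
    simulated phantom) and never participates in equality or I/O round-trips.
    """

    data: np.ndarray
    affine: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths (mm) of a voxel along each axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def nearest_voxel(self, points: np.ndarray) -> np.ndarray:
        """Round continuous voxel coordinates half-up to integer indices."""
        cont = self.world_to_voxel(points)
        return np.floor(cont + 0.5).astype(np.int64)

    def sample_nearest(self, points: np.ndarray) -> np.ndarray:
        """Value of the nearest voxel for each world point; NaN out of volume."""
        idx = self.nearest_voxel(points)
        inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        out = np.full(len(idx), np.nan)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.data[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


@dataclass
class RawBundle:
    """An unprocessed set of streamlines in world millimetres."""

    fibers: list[np.ndarray]
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fibers = [np.asarray(f, dtype=np.float64) for f in self.fibers]
        for f in self.fibers:
            if f.ndim != 2 or f.shape[1] != 3 or len(f) < 2:
                raise ValueError("each fiber must be an (n>=2, 3) polyline")
        if self.ids is None:
            self.ids = np.arange(len(self.fibers))
        else:
            self.ids = np.asarray(self.ids)
            if len(set(self.ids.tolist())) != len(self.fibers):
                raise ValueError("fiber ids must be unique")

    def __len__(self) -> int:
        return len(self.fibers)


def read_volume(path: str | Path) -> ScalarVolume:
    """Load a 3D NIfTI-1 scalar volume.

    NaN voxels are replaced by 0 (with a logged count); 4D inputs are
    rejected rather than silently squeezed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4:
        raise ValueError(
            f"{path} is 4D (extra dimension of length {data.shape[3]}); "
            "expected a single 3D metric volume"
        )
    if data.ndim != 3:
        raise ValueError(f"{path} has {data.ndim} dimensions; expected 3")
    n_nan = int(np.isnan(data).sum())
    if n_nan:
        logger.warning("%s: %d NaN voxel(s) replaced by 0", path, n_nan)
        data = np.nan_to_num(data, nan=0.0)
    vol = ScalarVolume(data=data, affine=np.asarray(img.affine))
    vol.meta["nan_replaced"] = n_nan
    logger.info("loaded %s: shape=%s voxel_size=%s", path, vol.shape,
                np.round(vol.voxel_size, 4))
    return vol


def write_volume(volume: ScalarVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))


def read_bundle(path: str | Path) -> RawBundle:
    """Load a TRK or TCK streamline bundle as world-mm polylines.

    TRK voxel-space quirks are normalized by nibabel's RAS+mm tractogram
    loader; the in-memory model never stores format-specific spaces.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in (".trk", ".tck"):
        raise ValueError(f"unsupported streamline format: {path.suffix!r}")
    tractogram_file = nib.streamlines.load(str(path))
    streamlines = [np.asarray(s) for s in tractogram_file.streamlines]
    if not streamlines:
        raise ValueError(f"{path} contains zero streamlines")
    return RawBundle(fibers=streamlines)


def write_bundle(bundle: RawBundle, path: str | Path,
                 volume: ScalarVolume | None = None) -> None:
    """Write a bundle as TCK or TRK.

    TRK headers need a reference grid (dimensions + affine); pass the
    companion ``volume`` when writing TRK.
    """
    path = Path(path)
    tractogram = nib.streamlines.Tractogram(
        [f.astype(np.float32) for f in bundle.fibers],
        affine_to_rasmm=np.eye(4),
    )
    if path.suffix.lower() == ".tck":
        nib.streamlines.save(tractogram, str(path))
    elif path.suffix.lower() == ".trk":
        header = {}
        if volume is not None:
            header[nib.streamlines.trk.Field.VOXEL_TO_RASMM] = volume.affine
            header[nib.streamlines.trk.Field.VOXEL_SIZES] = tuple(volume.voxel_size)
            header[nib.streamlines.trk.Field.DIMENSIONS] = volume.shape
        nib.streamlines.save(nib.streamlines.trk.TrkFile(tractogram, header),
                             str(path))
    else:
        raise ValueError(f"unsupported streamline format: {path.suffix!r}")


def write_report(rows: Iterable[dict[str, Any]] | pd.DataFrame,
                 path: str | Path) -> None:
    """Write a per-node or per-sweep table as UTF-8 CSV with a header row."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")


def write_metadata(metadata: dict[str, Any], path: str | Path) -> None:
    """Write run metadata (config, seeds, versions) as JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_metadata(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
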