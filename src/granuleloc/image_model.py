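"""Domain types, readers/writers and coordinate conventions.

Conventions used throughout the package
---------------------------------------
* Axis order is ``(z, y, x)`` everywhere: arrays, spacings, positions.
* Voxel indices are 0-based; the physical position of voxel ``i`` along an
  axis with spacing ``s`` is its *center*, at ``i * s`` micrometres.  This
  makes the µm↔voxel mapping a pure scaling, which is the only mapping that
  stays unambiguous for anisotropic stacks (the z-step is typically 0.2 µm
  while the in-plane pixel is ~0.1 µm).
* All geometry downstream of I/O is expressed in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from matplotlib.path import Path as MplPath
from skimage.draw import polygon2mask

__all__ = [
    "ImageStack",
    "EmbryoAnnotation",
    "Spot",
    "MoleculeSet",
    "ReferenceSpot",
    "read_stack",
    "write_stack",
    "read_annotation",
    "write_annotation",
    "write_molecule_table",
    "read_molecule_table",
]


@dataclass
class ImageStack:
    """A 3D single-channel intensity volume with anisotropic voxel spacing.

    Parameters
    ----------
    voxels
        Non-negative intensity grid, axis order ``(z, y, x)``.
    spacing
        Physical voxel spacing ``(dz, dy, dx)`` in µm; dz may differ from
        dx = dy.
    channel_label
        Free-text channel name (e.g. ``"smFISH"``, ``"GLH-1::GFP"``).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def um_to_voxel(self, positions_um: np.ndarray) -> np.ndarray:
        """Convert (N, 3) µm positions to fractional voxel indices."""
        return np.atleast_2d(positions_um) / np.asarray(self.spacing)

    def voxel_to_um(self, indices: np.ndarray) -> np.ndarray:
        """Convert (N, 3) voxel indices (voxel centers) to µm positions."""
        return np.atleast_2d(indices) * np.asarray(self.spacing)


@dataclass
class EmbryoAnnotation:
    """Manual annotation of one embryo: outline, membranes, nuclei, metadata.

    ``outline`` maps z-slice index -> closed polygon vertices (M, 2) in
    ``(y, x)`` µm.  ``membranes`` maps z-slice index -> list of polyline
    vertex arrays (M, 2) in ``(y, x)`` µm.  ``included_slices`` is the
    inclusive ``(z_lo, z_hi)`` range of slices used for quantification; by
    construction it excludes the uppermost and lowermost annotated slices,
    where cells are flattened against the slide or coverslip.
    """

    spacing: tuple[float, float, float]
    outline: dict[int, np.ndarray]
    membranes: dict[int, list[np.ndarray]] = field(default_factory=dict)
    nuclear_mask: Optional[np.ndarray] = None
    included_slices: Optional[tuple[int, int]] = None
    stage: int = 1
    condition: str = ""

    def __post_init__(self) -> None:
        self.outline = {int(z): np.asarray(p, dtype=float) for z, p in self.outline.items()}
        for z, poly in self.outline.items():
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError(f"outline polygon at slice {z} must be (M>=3, 2)")
        self.membranes = {
            int(z): [np.asarray(p, dtype=float) for p in lines]
            for z, lines in self.membranes.items()
        }
        if self.nuclear_mask is not None:
            self.nuclear_mask = np.asarray(self.nuclear_mask).astype(bool)
        if self.included_slices is None and self.outline:
            zs = sorted(self.outline)
            # drop first and last annotated slice
            if len(zs) > 2:
                self.included_slices = (zs[1], zs[-2])
            else:
                self.included_slices = (zs[0], zs[-1])

    @property
    def annotated_slices(self) -> list[int]:
        return sorted(self.outline)

    def slice_in_range(self, z_index: np.ndarray) -> np.ndarray:
        """Boolean mask of z-slice indices within the included range."""
        lo, hi = self.included_slices  # type: ignore[misc]
        z_index = np.asarray(z_index)
        return (z_index >= lo) & (z_index <= hi)

    def embryo_mask(self, shape: tuple[int, int, int], *, restrict_slices: bool = True) -> np.ndarray:
        """Rasterize the per-slice outline polygons into a boolean volume.

        Slices without an annotated outline (or outside the included range
        when ``restrict_slices``) are left empty.
        """
        dz, dy, dx = self.spacing
        mask = np.zeros(shape, dtype=bool)
        for z, poly in self.outline.items():
            if z < 0 or z >= shape[0]:
                continue
            if restrict_slices and not bool(self.slice_in_range(np.array([z]))[0]):
                continue
            poly_px = poly / np.array([dy, dx])
            mask[z] = polygon2mask(shape[1:], poly_px)
        return mask

    def contains(self, positions_um: np.ndarray, *, restrict_slices: bool = False) -> np.ndarray:
        """Point-in-embryo test for (N, 3) µm positions.

        Each point is tested against the outline polygon of its nearest
        annotated slice.
        """
        pos = np.atleast_2d(np.asarray(positions_um, dtype=float))
        dz = self.spacing[0]
        zs = np.array(self.annotated_slices)
        inside = np.zeros(len(pos), dtype=bool)
        if zs.size == 0:
            return inside
        z_idx = np.clip(np.round(pos[:, 0] / dz).astype(int), zs.min(), zs.max())
        for z in np.unique(z_idx):
            sel = z_idx == z
            z_ann = zs[np.argmin(np.abs(zs - z))]
            path = MplPath(self.outline[int(z_ann)])
            inside[sel] = path.contains_points(pos[sel, 1:])
        if restrict_slices:
            inside &= self.slice_in_range(z_idx)
        return inside


@dataclass
class Spot:
    """A fitted candidate single-molecule spot."""

    position: tuple[float, float, float]  # (z, y, x) µm
    amplitude: float
    sigma_z: float
    sigma_xy: float
    offset: float = 0.0
    quality: float = 0.0
    integrated_intensity: float = 0.0
    border: bool = False


@dataclass
class ReferenceSpot:
    """Median signature of an isolated single molecule.

    Used as the frozen component shape when decomposing dense regions.
    """

    amplitude: float
    sigma_z: float
    sigma_xy: float
    integrated_intensity: float

    def __post_init__(self) -> None:
        if min(self.amplitude, self.sigma_z, self.sigma_xy, self.integrated_intensity) <= 0:
            raise ValueError("reference spot parameters must all be positive")


PROVENANCE = ("isolated", "decomposed", "fallback")


@dataclass
class MoleculeSet:
    """Individual-molecule 3D positions with provenance.

    ``provenance`` is one of ``isolated`` (the molecule is a single fitted
    spot), ``decomposed`` (modeled within a dense region) or ``fallback``
    (count inferred from integrated intensity when the mixture fit failed).
    ``source_spot`` indexes the parent detected spot, -1 if not applicable.
    """

    positions: np.ndarray  # (N, 3) µm
    provenance: np.ndarray  # (N,) str
    source_spot: np.ndarray  # (N,) int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.provenance = np.asarray(self.provenance, dtype=object).reshape(-1)
        self.source_spot = np.asarray(self.source_spot, dtype=int).reshape(-1)
        n = len(self.positions)
        if len(self.provenance) != n or len(self.source_spot) != n:
            raise ValueError("positions, provenance and source_spot must have equal length")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def empty(cls) -> "MoleculeSet":
        return cls(np.empty((0, 3)), np.empty(0, dtype=object), np.empty(0, dtype=int))

    @classmethod
    def concatenate(cls, parts: Sequence["MoleculeSet"]) -> "MoleculeSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls.empty()
        return cls(
            np.vstack([p.positions for p in parts]),
            np.concatenate([p.provenance for p in parts]),
            np.concatenate([p.source_spot for p in parts]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
                "x_um": self.positions[:, 2],
                "provenance": self.provenance,
                "source_spot": self.source_spot,
            }
        )


# ---------------------------------------------------------------------------
# I/O


def read_stack(path: str | Path, spacing: Sequence[float], channel_label: str = "") -> ImageStack:
    """Read a multi-page TIFF as an :class:`ImageStack`.

    Page order maps to ascending z.  ``spacing`` is ``(dz, dy, dx)`` in µm
    and must always be user-supplied: TIFF metadata rarely carries a
    trustworthy z-step, and the in-plane pixel size depends on the camera
    and objective used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    voxels = tifffile.imread(str(path))
    if voxels.ndim != 3:
        raise ValueError(f"non-3D content in {path}: shape {voxels.shape}")
    return ImageStack(voxels=np.asarray(voxels, dtype=float), spacing=tuple(spacing), channel_label=channel_label)


def write_stack(image: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` to a multi-page float32 TIFF."""
    tifffile.imwrite(str(path), image.voxels.astype(np.float32), photometric="minisblack")


def write_annotation(annotation: EmbryoAnnotation, path: str | Path) -> None:
    """Write an annotation sidecar (JSON) plus an 8-bit nuclear-mask TIFF.

    Polygon vertices are stored in pixel units, as produced by annotation
    tools; they are converted back to µm on read using the stated spacing.
    """
    path = Path(path)
    dz, dy, dx = annotation.spacing
    scale = np.array([dy, dx])
    doc = {
        "spacing": list(annotation.spacing),
        "stage": int(annotation.stage),
        "condition": annotation.condition,
        "included_slices": list(annotation.included_slices) if annotation.included_slices else None,
        "outline": {str(z): (p / scale).tolist() for z, p in annotation.outline.items()},
        "membranes": {
            str(z): [(p / scale).tolist() for p in lines] for z, lines in annotation.membranes.items()
        },
        "nuclear_mask": None,
    }
    if annotation.nuclear_mask is not None:
        mask_path = path.with_suffix(".mask.tif")
        tifffile.imwrite(
            str(mask_path), annotation.nuclear_mask.astype(np.uint8) * 255, photometric="minisblack"
        )
        doc["nuclear_mask"] = mask_path.name
    path.write_text(json.dumps(doc, indent=1))


def read_annotation(path: str | Path, image: ImageStack) -> EmbryoAnnotation:
    """Read an annotation sidecar and validate it against ``image``.

    Raises on shape mismatch between the nuclear mask and the image, on
    open (non-closable) outline polygons, and on slice indices outside the
    stack.  A missing nuclear mask is allowed; nuclear operations will
    refuse to run later.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    dz, dy, dx = image.spacing
    scale = np.array([dy, dx])
    nz = image.shape[0]

    outline: dict[int, np.ndarray] = {}
    for z_str, verts in doc["outline"].items():
        z = int(z_str)
        if z < 0 or z >= nz:
            raise ValueError(f"outline slice index {z} out of range for {nz} slices")
        poly = np.asarray(verts, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError(f"open or degenerate outline polygon at slice {z}")
        outline[z] = poly * scale

    membranes: dict[int, list[np.ndarray]] = {}
    for z_str, lines in doc.get("membranes", {}).items():
        z = int(z_str)
        if z < 0 or z >= nz:
            raise ValueError(f"membrane slice index {z} out of range")
        membranes[z] = [np.asarray(v, dtype=float) * scale for v in lines]

    mask = None
    if doc.get("nuclear_mask"):
        mask = tifffile.imread(str(path.parent / doc["nuclear_mask"])) > 0
        if mask.shape != image.shape:
            raise ValueError(f"nuclear mask shape {mask.shape} != image shape {image.shape}")

    included = tuple(doc["included_slices"]) if doc.get("included_slices") else None
    return EmbryoAnnotation(
        spacing=image.spacing,
        outline=outline,
        membranes=membranes,
        nuclear_mask=mask,
        included_slices=included,  # type: ignore[arg-type]
        stage=int(doc.get("stage", 1)),
        condition=doc.get("condition", ""),
    )


_MOL_COLUMNS = ["z_um", "y_um", "x_um", "provenance", "source_spot"]


def write_molecule_table(molecules: MoleculeSet, path: str | Path) -> None:
    """Write molecules to a tab-delimited table (µm positions, 6 decimals)."""
    df = molecules.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_molecule_table(path: str | Path) -> MoleculeSet:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _MOL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"molecule table missing columns: {missing}")
    if len(df) == 0:
        return MoleculeSet.empty()
    return MoleculeSet(
        positions=df[["z_um", "y_um", "x_um"]].to_numpy(),
        provenance=df["provenance"].to_numpy(dtype=object),
        source_spot=df["source_spot"].to_numpy(dtype=int),
    )
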