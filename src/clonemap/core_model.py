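"""Domain types and CSV/TIFF persistence for multicolor fate-mapping data.

The central object is a :class:`StudyTable`: a collection of imaged z-stacks,
each holding fluorescently labeled cells with continuous, stack-local 3D
coordinates in micrometres and one of the four Confetti reporter colors
(mCFP, nGFP, YFP, RFP).  Stacks carry the geometry (x/y extent, z height)
that the ring-density statistic and the clone-density normalisation need,
plus mouse / hemisphere-condition / timepoint metadata for the averaging
hierarchy.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import tifffile

CONFETTI_COLORS = ("mCFP", "nGFP", "YFP", "RFP")

#: default vocabulary for stack metadata; free strings are accepted when a
#: different vocabulary is supplied to the validators.
DEFAULT_CONDITIONS = ("stroke", "contralateral")
DEFAULT_TIMEPOINTS = ("2d", "1w", "2w", "4w", "8w", "12w")

_REQUIRED_COLUMNS = (
    "image_id", "mouse_id", "condition", "timepoint",
    "x_um", "y_um", "z_um", "color",
    "x_extent_um", "y_extent_um", "z_height_um",
)


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


class ValidationError(ValueError):
    """Raised when data violate a domain invariant."""


@dataclass(frozen=True)
class CellRecord:
    """A single labeled cell: stack-local position (µm) and reporter color."""

    cell_id: str
    image_id: str
    x: float
    y: float
    z: float
    color: str
    ki67: Optional[bool] = None

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class ImageStack:
    """One imaged z-stack: an axis-aligned box of cells with metadata.

    Coordinates are stack-local micrometres with origin at a stack corner;
    ``z_height`` is the physical depth of the stack, which enters the
    cylindrical ring volume of the clonality statistic.
    """

    image_id: str
    mouse_id: str
    condition: str
    timepoint: str
    x_extent: float
    y_extent: float
    z_height: float
    cells: list[CellRecord] = field(default_factory=list)

    @property
    def volume_mm3(self) -> float:
        """Imaged volume in mm³ (extents are in µm)."""
        return self.x_extent * self.y_extent * self.z_height * 1e-9

    def positions(self, metric: str = "3d") -> np.ndarray:
        """(n, 2) or (n, 3) array of cell positions in µm."""
        if not self.cells:
            return np.empty((0, 2 if metric == "xy" else 3))
        pts = np.array([[c.x, c.y, c.z] for c in self.cells])
        return pts[:, :2] if metric == "xy" else pts

    def colors(self) -> np.ndarray:
        return np.array([c.color for c in self.cells], dtype=object)

    def with_colors(self, colors: Iterable[str]) -> "ImageStack":
        """Copy of the stack with cell colors replaced, positions unchanged."""
        colors = list(colors)
        if len(colors) != len(self.cells):
            raise ValueError("color vector length mismatch")
        cells = [replace(c, color=col) for c, col in zip(self.cells, colors)]
        return replace(self, cells=cells)


@dataclass
class StudyTable:
    """All stacks of a study, with a mouse_id → stacks index."""

    stacks: list[ImageStack] = field(default_factory=list)

    @property
    def mice(self) -> dict[str, list[ImageStack]]:
        idx: dict[str, list[ImageStack]] = {}
        for s in self.stacks:
            idx.setdefault(s.mouse_id, []).append(s)
        return idx

    def subset(self, timepoint: Optional[str] = None,
               condition: Optional[str] = None) -> "StudyTable":
        """Stacks of one (timepoint, condition) analysis group."""
        keep = [s for s in self.stacks
                if (timepoint is None or s.timepoint == timepoint)
                and (condition is None or s.condition == condition)]
        return StudyTable(stacks=keep)

    def n_cells(self) -> int:
        return sum(len(s.cells) for s in self.stacks)


@dataclass
class CellMask:
    """Binary 3D voxel mask of one segmented cell, with voxel size in µm.

    ``voxels`` is indexed (z, y, x); ``voxel_size`` is (dz, dy, dx) µm to
    match the array axis order.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValidationError("mask must be a 3D array")
        if not self.voxels.any():
            raise ValidationError("mask has no foreground voxel")
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size must be strictly positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def touches_boundary(self) -> bool:
        """True if any foreground voxel lies on an array face (cell may be cut)."""
        v = self.voxels
        return bool(v[0].any() or v[-1].any() or v[:, 0].any() or v[:, -1].any()
                    or v[:, :, 0].any() or v[:, :, -1].any())


# ---------------------------------------------------------------------------
# persistence

def study_to_frame(study: StudyTable) -> pd.DataFrame:
    rows = []
    for s in study.stacks:
        for c in s.cells:
            rows.append({
                "cell_id": c.cell_id, "image_id": s.image_id,
                "mouse_id": s.mouse_id, "condition": s.condition,
                "timepoint": s.timepoint,
                "x_um": c.x, "y_um": c.y, "z_um": c.z, "color": c.color,
                "ki67": "" if c.ki67 is None else str(bool(c.ki67)),
                "x_extent_um": s.x_extent, "y_extent_um": s.y_extent,
                "z_height_um": s.z_height,
            })
        if not s.cells:
            rows.append({
                "cell_id": "", "image_id": s.image_id, "mouse_id": s.mouse_id,
                "condition": s.condition, "timepoint": s.timepoint,
                "x_um": "", "y_um": "", "z_um": "", "color": "", "ki67": "",
                "x_extent_um": s.x_extent, "y_extent_um": s.y_extent,
                "z_height_um": s.z_height,
            })
    cols = ["cell_id"] + list(_REQUIRED_COLUMNS[:-3]) + ["ki67"] + list(_REQUIRED_COLUMNS[-3:])
    # reorder: cell_id, image_id, mouse_id, condition, timepoint, x, y, z, color, ki67, extents
    cols = ["cell_id", "image_id", "mouse_id", "condition", "timepoint",
            "x_um", "y_um", "z_um", "color", "ki67",
            "x_extent_um", "y_extent_um", "z_height_um"]
    return pd.DataFrame(rows, columns=cols)


def write_cell_table(study: StudyTable, path: str | Path) -> Path:
    """Write a study to CSV (comma-separated, UTF-8, '.' decimal, header)."""
    path = Path(path)
    study_to_frame(study).to_csv(path, index=False, float_format="%.10g")
    return path


def read_cell_table(path: str | Path) -> StudyTable:
    """Read a cell-table CSV into a validated :class:`StudyTable`.

    Expected columns: image_id, mouse_id, condition, timepoint, x_um, y_um,
    z_um, color plus per-image extent columns (x_extent_um, y_extent_um,
    z_height_um); cell_id and ki67 are optional.  Empty-cell placeholder rows
    (blank cell_id and coordinates) carry stack metadata for empty stacks.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"image_id": str, "mouse_id": str,
                                  "cell_id": str, "color": str,
                                  "condition": str, "timepoint": str})
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col}")
    stacks: dict[str, ImageStack] = {}
    auto_id = 0
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        image_id = row.image_id
        if image_id not in stacks:
            stacks[image_id] = ImageStack(
                image_id=image_id, mouse_id=row.mouse_id,
                condition=row.condition, timepoint=row.timepoint,
                x_extent=float(row.x_extent_um), y_extent=float(row.y_extent_um),
                z_height=float(row.z_height_um))
        stack = stacks[image_id]
        if pd.isna(row.x_um) or row.x_um == "":
            continue  # stack-metadata placeholder row
        color = row.color
        if color not in CONFETTI_COLORS:
            raise ValidationError(
                f"row {row_no}: color {color!r} is not one of {CONFETTI_COLORS}")
        x, y, z = float(row.x_um), float(row.y_um), float(row.z_um)
        if not (0 <= x <= stack.x_extent and 0 <= y <= stack.y_extent
                and 0 <= z <= stack.z_height):
            raise ValidationError(
                f"row {row_no}: cell at ({x}, {y}, {z}) outside stack "
                f"{image_id} bounds")
        cell_id = getattr(row, "cell_id", None)
        if cell_id is None or pd.isna(cell_id) or cell_id == "":
            cell_id = f"{image_id}:{auto_id}"
            auto_id += 1
        ki67_raw = getattr(row, "ki67", None)
        if ki67_raw is None or (isinstance(ki67_raw, float) and np.isnan(ki67_raw)) \
                or ki67_raw == "":
            ki67 = None
        else:
            ki67 = str(ki67_raw).strip().lower() in ("true", "1", "yes")
        stack.cells.append(CellRecord(cell_id=str(cell_id), image_id=image_id,
                                      x=x, y=y, z=z, color=color, ki67=ki67))
    return StudyTable(stacks=list(stacks.values()))


def read_mask(path: str | Path, voxel_size: tuple[float, float, float]) -> CellMask:
    """Read a binary multi-page TIFF (z-planes) as a :class:`CellMask`."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return CellMask(voxels=arr > 0, voxel_size=voxel_size)


def write_mask(mask: CellMask, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(str(path), mask.voxels.astype(np.uint8),
                     photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# validation

def validate_study(study: StudyTable,
                   conditions: tuple[str, ...] | None = None,
                   timepoints: tuple[str, ...] | None = None) -> list[str]:
    """Return a list of invariant violations (empty iff the study is valid).

    Pure: never mutates the study.  When ``conditions`` / ``timepoints``
    vocabularies are given, stack metadata is checked against them.
    """
    violations: list[str] = []
    seen_ids: set[str] = set()
    for s in study.stacks:
        if s.image_id in seen_ids:
            violations.append(f"duplicate image_id: {s.image_id}")
        seen_ids.add(s.image_id)
        if s.x_extent <= 0 or s.y_extent <= 0:
            violations.append(f"stack {s.image_id}: non-positive extent")
        if s.z_height <= 0:
            violations.append(f"stack {s.image_id}: non-positive z_height")
        if conditions is not None and s.condition not in conditions:
            violations.append(
                f"stack {s.image_id}: condition {s.condition!r} not in vocabulary")
        if timepoints is not None and s.timepoint not in timepoints:
            violations.append(
                f"stack {s.image_id}: timepoint {s.timepoint!r} not in vocabulary")
        for c in s.cells:
            if c.color not in CONFETTI_COLORS:
                violations.append(
                    f"cell {c.cell_id}: color {c.color!r} not a Confetti label")
            if not (0 <= c.x <= s.x_extent and 0 <= c.y <= s.y_extent
                    and 0 <= c.z <= s.z_height):
                violations.append(
                    f"cell {c.cell_id}: position outside stack {s.image_id} bounds")
    return violations
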