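"""Reading, validation and writing of binary lesion masks and cohort metadata.

A lesion mask is a 3D indicator grid (lesion voxels = 1, all other voxels = 0),
nominally in MNI space with millimetre voxel spacing.  Array axes map to
anatomical directions: axis 0 -> x (left-right), axis 1 -> y
(posterior-anterior), axis 2 -> z (inferior-superior); this can be overridden
when volumes are stored in a different orientation.

Subject metadata (gender, EDSS, disease type, acquisition offsets) lives in a
separate CSV rather than being parsed from filenames, so provenance stays
explicit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LesionMask",
    "SubjectRecord",
    "MaskValidationError",
    "NonBinaryMaskError",
    "DEFAULT_AXIS_SEMANTICS",
    "read_mask",
    "write_mask",
    "total_lesion_volume",
    "read_metadata",
    "write_metadata",
]

#: Default mapping of array axes to anatomical directions (MNI convention).
DEFAULT_AXIS_SEMANTICS: Mapping[str, int] = {"x": 0, "y": 1, "z": 2}

#: Values farther than this from both 0 and 1 make a volume non-binary.
BINARY_TOLERANCE = 1e-6


class MaskValidationError(ValueError):
    """A volume violates the lesion-mask contract (shape, spacing, ...)."""


class NonBinaryMaskError(MaskValidationError):
    """A volume contains values that are neither 0 nor 1.

    Probability maps must be thresholded upstream; this module never
    thresholds silently.
    """


@dataclasses.dataclass
class LesionMask:
    """Binary 3D lesion pattern with physical voxel spacing.

    Parameters
    ----------
    grid
        3D uint8 array of {0, 1} indicator values.
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in mm, all strictly positive.
    subject_id, timepoint
        Cohort bookkeeping; ``timepoint`` indexes the MRI session (1-based).
    axis_semantics
        Mapping from anatomical direction name to array axis.
    space_tag
        Coordinate-space label, e.g. ``"MNI"``.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    subject_id: str = ""
    timepoint: int = 1
    axis_semantics: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_AXIS_SEMANTICS)
    )
    space_tag: str = "MNI"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise MaskValidationError(
                f"lesion mask must be 3D, got {grid.ndim} dimensions"
            )
        if min(grid.shape) < 2:
            raise MaskValidationError(
                f"each mask dimension must have >= 2 voxels, got shape {grid.shape}"
            )
        if not np.issubdtype(grid.dtype, np.integer) or grid.dtype != np.uint8:
            grid = _coerce_binary(grid)
        elif grid.size and grid.max() > 1:
            raise NonBinaryMaskError("integer mask contains values outside {0, 1}")
        self.grid = grid.astype(np.uint8, copy=False)

        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in spacing):
            raise MaskValidationError(
                f"spacing must be three strictly positive finite numbers, got {spacing}"
            )
        self.spacing = spacing

        if sorted(self.axis_semantics.keys()) != ["x", "y", "z"] or sorted(
            self.axis_semantics.values()
        ) != [0, 1, 2]:
            raise MaskValidationError(
                "axis_semantics must map {'x','y','z'} onto axes {0,1,2}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def n_lesion_voxels(self) -> int:
        return int(self.grid.sum())

    def axis_of(self, direction: str) -> int:
        """Array axis carrying the given anatomical direction ('x'|'y'|'z')."""
        try:
            return self.axis_semantics[direction]
        except KeyError:
            raise ValueError(f"unknown direction {direction!r}; expected x, y or z")

    def spacing_along(self, direction: str) -> float:
        """Voxel edge length (mm) along an anatomical direction."""
        return self.spacing[self.axis_of(direction)]


def _coerce_binary(data: np.ndarray) -> np.ndarray:
    """Round values that are within tolerance of 0/1; reject anything else."""
    data = np.asarray(data, dtype=np.float64)
    if not np.isfinite(data).all():
        raise NonBinaryMaskError("mask contains non-finite values")
    near0 = np.abs(data) <= BINARY_TOLERANCE
    near1 = np.abs(data - 1.0) <= BINARY_TOLERANCE
    if not np.all(near0 | near1):
        bad = data[~(near0 | near1)]
        raise NonBinaryMaskError(
            f"mask contains {bad.size} non-binary values "
            f"(e.g. {bad.flat[0]!r}); threshold probability maps upstream"
        )
    return near1.astype(np.uint8)


@dataclasses.dataclass
class SubjectRecord:
    """One row of the cohort metadata table."""

    subject_id: str
    gender: str
    timepoint: int
    edss: float
    disease_type: str
    days_since_baseline: int

    def __post_init__(self) -> None:
        if self.gender not in ("F", "M"):
            raise ValueError(f"gender must be 'F' or 'M', got {self.gender!r}")
        if self.disease_type not in ("CIS", "RRMS"):
            raise ValueError(f"disease_type must be CIS or RRMS, got {self.disease_type!r}")
        edss = float(self.edss)
        if not (0.0 <= edss <= 10.0) or abs(edss * 2 - round(edss * 2)) > 1e-9:
            raise ValueError(f"EDSS must be a multiple of 0.5 in [0, 10], got {edss}")
        self.edss = edss
        if int(self.days_since_baseline) < 0:
            raise ValueError("days_since_baseline must be >= 0")
        self.days_since_baseline = int(self.days_since_baseline)
        self.timepoint = int(self.timepoint)


METADATA_COLUMNS = [
    "subject_id",
    "gender",
    "timepoint",
    "edss",
    "disease_type",
    "days_since_baseline",
]


def read_mask(
    path: str | Path,
    axis_semantics: Mapping[str, int] | None = None,
    subject_id: str = "",
    timepoint: int = 1,
) -> LesionMask:
    """Load a binary lesion mask from a NIfTI file.

    Voxel spacing is taken from the header.  Values must already be binary
    (within ``1e-6`` of 0 or 1); anything else raises
    :class:`NonBinaryMaskError`.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 else data
    if data.ndim != 3:
        raise MaskValidationError(
            f"{path}: expected a 3D volume, got {data.ndim} non-trivial dimensions"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LesionMask(
        grid=_coerce_binary(data),
        spacing=spacing,
        subject_id=subject_id,
        timepoint=timepoint,
        axis_semantics=dict(axis_semantics or DEFAULT_AXIS_SEMANTICS),
    )


def write_mask(mask: LesionMask, path: str | Path) -> None:
    """Write a lesion mask as NIfTI; inverse of :func:`read_mask` on grid and spacing."""
    affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def total_lesion_volume(mask: LesionMask) -> float:
    """Total lesion volume (TLV) in cm^3: lesion-voxel count x voxel volume."""
    voxel_mm3 = mask.spacing[0] * mask.spacing[1] * mask.spacing[2]
    return mask.n_lesion_voxels * voxel_mm3 / 1000.0


def read_metadata(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort metadata CSV and validate each row.

    The CSV must carry the header
    ``subject_id,gender,timepoint,edss,disease_type,days_since_baseline``.
    Timepoints must be unique per subject.
    """
    df = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    records = [
        SubjectRecord(
            subject_id=str(row.subject_id),
            gender=str(row.gender),
            timepoint=int(row.timepoint),
            edss=float(row.edss),
            disease_type=str(row.disease_type),
            days_since_baseline=int(row.days_since_baseline),
        )
        for row in df.itertuples(index=False)
    ]
    dupes = df.duplicated(subset=["subject_id", "timepoint"])
    if dupes.any():
        raise ValueError(
            f"duplicate subject/timepoint rows in metadata: "
            f"{df.loc[dupes, ['subject_id', 'timepoint']].values.tolist()}"
        )
    return records


def write_metadata(records: list[SubjectRecord], path: str | Path) -> None:
    """Write subject records as the canonical metadata CSV."""
    pd.DataFrame([dataclasses.asdict(r) for r in records])[METADATA_COLUMNS].to_csv(
        path, index=False
    )
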