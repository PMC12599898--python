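"""Axial CT volume container.

The common currency of every stage of the pipeline: a stack of axial
slices with *physical* per-slice z-coordinates in the patient coordinate
system (mm), never bare slice indices.  All downstream geometry is done
in mm on these positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AxialVolume"]

#: two slice centres closer than this (mm) are considered duplicates
DUPLICATE_Z_TOL = 1e-3


@dataclass
class AxialVolume:
    """A 3D axial intensity grid with explicit slice geometry.

    Parameters
    ----------
    voxels:
        Intensity array indexed ``(slice, row, col)``, in HU after rescale.
    positions:
        Per-slice z-coordinates of the slice centres, in mm, strictly
        ascending, in the DICOM patient coordinate frame.
    thickness:
        Nominal slice thickness in mm (axial extent of tissue contributing
        to one slice; independent of the centre-to-centre interval).
    in_plane_spacing:
        ``(row, col)`` pixel spacing in mm.
    """

    voxels: np.ndarray
    positions: np.ndarray
    thickness: float
    in_plane_spacing: tuple[float, float] = field(default=(1.0, 1.0))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64).ravel()
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (slice, row, col), got ndim={self.voxels.ndim}")
        if self.voxels.shape[0] == 0:
            raise ValueError("volume must contain at least one slice")
        if len(self.positions) != self.voxels.shape[0]:
            raise ValueError(
                f"positions length {len(self.positions)} does not match "
                f"slice count {self.voxels.shape[0]}"
            )
        diffs = np.diff(self.positions)
        if np.any(diffs <= 0):
            raise ValueError("slice positions must be strictly ascending")
        if np.any(diffs < DUPLICATE_Z_TOL):
            raise ValueError(
                f"slice positions closer than {DUPLICATE_Z_TOL} mm (overlapping "
                "reconstructions must be disambiguated by the caller)"
            )
        if not self.thickness > 0:
            raise ValueError(f"thickness must be > 0, got {self.thickness}")
        if not all(s > 0 for s in self.in_plane_spacing):
            raise ValueError(f"in-plane spacing must be > 0, got {self.in_plane_spacing}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def rows(self) -> int:
        return self.voxels.shape[1]

    @property
    def cols(self) -> int:
        return self.voxels.shape[2]

    def copy(self) -> "AxialVolume":
        return AxialVolume(
            voxels=self.voxels.copy(),
            positions=self.positions.copy(),
            thickness=self.thickness,
            in_plane_spacing=tuple(self.in_plane_spacing),
        )
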