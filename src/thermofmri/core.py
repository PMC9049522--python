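"""Shared containers and error types for the phantom fMRI pipeline.

The central in-memory object is :class:`BoldSeries`, a 4D voxel time series
with acquisition geometry (voxel size in mm), timing (TR in seconds, and the
acquisition time of the first retained volume, ``t0``) and an optional brain
mask. Series round-trip through NIfTI-1 with the TR stored in the header
zooms and ``t0`` in ``toffset``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


class InputError(ValueError):
    """Malformed or incompatible input data."""


class DesignError(ValueError):
    """Stimulation design inconsistent with the acquired series."""


class ConfigError(ValueError):
    """Invalid analysis configuration."""


class ParameterError(ValueError):
    """Invalid model parameter value."""


class GenerationError(RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""


@dataclass
class BoldSeries:
    """A 4D BOLD time series ``(x, y, z, t)`` with geometry and timing.

    Parameters
    ----------
    data:
        4D array of signal values; finite inside the brain mask.
    tr:
        Volume repetition time in seconds.
    voxel_size:
        Voxel edge lengths in mm, ``(dx, dy, dz)``.
    brain_mask:
        Boolean 3D array marking in-brain voxels, or None.
    t0:
        Acquisition time (s) of the first volume relative to the protocol
        clock. Pairwise averaging and volume discarding shift it.
    provenance:
        Free-form metadata (seeds, generator parameters, processing log).
    """

    data: np.ndarray
    tr: float
    voxel_size: tuple[float, float, float]
    brain_mask: np.ndarray | None = None
    t0: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise InputError(f"BoldSeries data must be 4D, got {self.data.ndim}D")
        if self.tr <= 0:
            raise InputError("tr must be positive")
        if self.n_volumes < 1:
            raise InputError("series must contain at least one volume")
        if self.brain_mask is not None:
            if self.brain_mask.shape != self.data.shape[:3]:
                raise InputError("brain mask shape does not match volume grid")
            if not np.all(np.isfinite(self.data[self.brain_mask])):
                raise InputError("non-finite values inside the brain mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def duration(self) -> float:
        """Total covered time in seconds (volumes x TR)."""
        return self.n_volumes * self.tr

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each volume in seconds."""
        return self.t0 + self.tr * np.arange(self.n_volumes)

    def copy_with(self, **kwargs) -> "BoldSeries":
        """Return a copy with selected fields replaced."""
        fields = dict(
            data=self.data,
            tr=self.tr,
            voxel_size=self.voxel_size,
            brain_mask=self.brain_mask,
            t0=self.t0,
            provenance=dict(self.provenance),
        )
        fields.update(kwargs)
        return BoldSeries(**fields)

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path) -> None:
        """Write the series as NIfTI-1 (.nii or .nii.gz) with TR in the header."""
        affine = np.diag([*self.voxel_size, 1.0])
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine)
        img.header.set_zooms((*self.voxel_size, self.tr))
        img.header["toffset"] = self.t0
        nib.save(img, str(path))
        sidecar = Path(str(path)).with_suffix("").with_suffix("")
        meta = {"tr_s": self.tr, "t0_s": self.t0, "provenance": self.provenance}
        Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=2, default=str))

    @classmethod
    def load(cls, path: str | Path, brain_mask: np.ndarray | None = None) -> "BoldSeries":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        data = np.asanyarray(img.dataobj).astype(np.float32)
        return cls(
            data=data,
            tr=float(zooms[3]) if len(zooms) > 3 else 1.0,
            voxel_size=tuple(float(z) for z in zooms[:3]),
            brain_mask=brain_mask,
            t0=float(img.header["toffset"]),
        )


def save_mask(mask: np.ndarray, voxel_size, path: str | Path) -> None:
    """Write a binary or integer label volume as NIfTI-1."""
    affine = np.diag([*voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.int16), affine), str(path))


def load_labels(path: str | Path) -> np.ndarray:
    """Read an integer label volume from NIfTI-1."""
    return np.asanyarray(nib.load(str(path)).dataobj).astype(np.int32)
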