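"""3D-to-2D MRI slice extraction.

Converts volumetric scans (NIfTI) into evenly spaced 2D slices along one of
the three anatomical planes.  Given ``m`` available slices along the plane
normal and a requested count ``n``, the sampling interval is

    i = floor(m / n)

and, after discarding ``k1`` leading and ``k2`` trailing boundary slices
(which in brain MRI mostly contain empty space or non-brain tissue), the
number of extracted slices is

    n_slices = ceil(m / i) - (k1 + k2)

with selected indices ``s = k1 + j*i`` for ``j = 0 .. n_slices-1``, keeping
only indices with ``s < m - k2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
import nibabel as nib
import numpy as np
from PIL import Image

PLANES = ("axial", "coronal", "sagittal")

#: Default mapping of array axes to plane normals: axis 0 varies along the
#: sagittal normal (x), axis 1 along the coronal normal (y), axis 2 along the
#: axial normal (z).
DEFAULT_AXIS_MAP = {"sagittal": 0, "coronal": 1, "axial": 2}


class SlicingError(ValueError):
    """Invalid slicing request (bad interval, empty plan, extent mismatch)."""


@dataclass
class Volume3D:
    """A 3D scalar voxel grid with a plane-normal axis assignment."""

    voxels: np.ndarray
    axis_map: dict = field(default_factory=lambda: dict(DEFAULT_AXIS_MAP))
    source_path: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise SlicingError(
                f"volume must be 3D, got {self.voxels.ndim}D array"
            )
        if min(self.voxels.shape) < 1:
            raise SlicingError(f"degenerate volume shape {self.voxels.shape}")
        if sorted(self.axis_map) != sorted(PLANES) or sorted(
            self.axis_map.values()
        ) != [0, 1, 2]:
            raise SlicingError(
                f"axis_map must bijectively map {PLANES} onto axes 0,1,2; "
                f"got {self.axis_map}"
            )

    def extent(self, plane: str) -> int:
        """Number of slices available along the normal of *plane*."""
        return self.voxels.shape[self.axis_map[plane]]


@dataclass(frozen=True)
class SlicePlan:
    """Extraction schedule for one volume and plane."""

    plane: str
    m: int
    n: int
    k1: int
    k2: int
    i: int
    n_slices: int
    indices: tuple


@dataclass
class SliceSet:
    """Ordered 2D slices plus the plan that produced them."""

    slices: list
    plan: SlicePlan
    normalized: bool = False


def compute_interval(m: int, n: int) -> int:
    """Sampling interval ``i = floor(m/n)`` between consecutive slices."""
    if n <= 0 or m < 1 or n > m:
        raise SlicingError(
            f"cannot take n={n} slices from m={m} available (need 1 <= n <= m)"
        )
    return m // n


def plan_slices(m: int, n: int, k1: int = 0, k2: int = 0, plane: str = "axial") -> SlicePlan:
    """Build the extraction schedule for ``m`` available slices.

    ``n_slices = ceil(m/i) - (k1 + k2)`` slices are scheduled at positions
    ``k1 + j*i``; positions falling into the trailing exclusion zone
    (``s >= m - k2``) are dropped.
    """
    if plane not in PLANES:
        raise SlicingError(f"unknown plane {plane!r}; expected one of {PLANES}")
    if k1 < 0 or k2 < 0:
        raise SlicingError(f"exclusion counts must be >= 0, got k1={k1}, k2={k2}")
    i = compute_interval(m, n)
    n_slices = math.ceil(m / i) - (k1 + k2)
    if n_slices < 1:
        raise SlicingError(
            f"empty plan: k1+k2={k1 + k2} >= ceil(m/i)={math.ceil(m / i)} "
            f"for m={m}, i={i}"
        )
    indices = tuple(
        s for s in (k1 + j * i for j in range(n_slices)) if s < m - k2
    )
    return SlicePlan(plane=plane, m=m, n=n, k1=k1, k2=k2, i=i,
                     n_slices=n_slices, indices=indices)


def extract_slices(vol: Volume3D, plan: SlicePlan) -> SliceSet:
    """Pull the planned 2D sections out of *vol*, in index order."""
    axis = vol.axis_map[plan.plane]
    extent = vol.voxels.shape[axis]
    if extent != plan.m:
        raise SlicingError(
            f"plan expects m={plan.m} along the {plan.plane} normal but the "
            f"volume has extent {extent}"
        )
    slices = [np.take(vol.voxels, s, axis=axis) for s in plan.indices]
    return SliceSet(slices=slices, plan=plan, normalized=False)


def normalize_and_resize(slice_: np.ndarray, side: int = 128) -> np.ndarray:
    """Min-max normalise a slice to [0, 1] and bilinearly resize to side x side.

    A constant slice maps to all zeros.
    """
    arr = np.asarray(slice_, dtype=np.float64)
    if arr.ndim != 2 or min(arr.shape) < 1:
        raise SlicingError(f"expected a non-degenerate 2D slice, got shape {arr.shape}")
    if side < 8:
        raise SlicingError(f"target side must be >= 8, got {side}")
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    if arr.shape != (side, side):
        img = Image.fromarray(arr.astype(np.float32), mode="F")
        img = img.resize((side, side), resample=Image.BILINEAR)
        arr = np.asarray(img, dtype=np.float64)
        # bilinear interpolation of in-range values stays in range
        arr = np.clip(arr, 0.0, 1.0)
    return arr


def read_volume(path) -> Volume3D:
    """Load a 3D NIfTI volume (.nii or .nii.gz)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise SlicingError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise SlicingError(
            f"{path}: expected a 3D volume, got {data.ndim}D data"
        )
    return Volume3D(voxels=np.asarray(data, dtype=np.float64),
                    source_path=str(path))


def write_slices(sset: SliceSet, out_dir, naming: str = "{subject}_{plane}_{index:03d}.png",
                 subject: str = "vol", side: int | None = None,
                 bit_depth: int = 8) -> list:
    """Write each slice as a grayscale PNG; returns the paths in index order.

    Slices are min-max normalised (and resized when *side* is given) before
    quantisation to 8- or 16-bit.
    """
    if bit_depth not in (8, 16):
        raise SlicingError(f"bit_depth must be 8 or 16, got {bit_depth}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for pos, (s, idx) in enumerate(zip(sset.slices, sset.plan.indices)):
        arr = normalize_and_resize(s, side) if side else _minmax(s)
        if bit_depth == 8:
            img = Image.fromarray((arr * 255).round().astype(np.uint8), mode="L")
        else:
            img = Image.fromarray((arr * 65535).round().astype(np.uint16))
        name = naming.format(subject=subject, plane=sset.plan.plane, index=idx,
                             position=pos)
        path = out_dir / name
        img.save(path)
        paths.append(path)
    return paths


def _minmax(slice_: np.ndarray) -> np.ndarray:
    arr = np.asarray(slice_, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)


def read_png(path) -> np.ndarray:
    """Read a grayscale PNG back to a float array in [0, 1]."""
    img = Image.open(path)
    arr = np.asarray(img, dtype=np.float64)
    scale = 65535.0 if img.mode.startswith("I") else 255.0
    return arr / scale


def slice_volume(vol: Volume3D, plane: str, n: int, k1: int = 2, k2: int = 2) -> SliceSet:
    """Plan + extract in one call, using the volume's own extent."""
    plan = plan_slices(vol.extent(plane), n, k1, k2, plane)
    return extract_slices(vol, plan)
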