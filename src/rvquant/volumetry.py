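"""Standard-method volumetry: disk summation and four-chamber measurement.

Disk summation ("Simpson's method of discs" as used in clinical CMR) turns a
contiguous stack of short-axis segmentations into a volume:

    V = sum_i A_i * t      (A_i = slice cross-section area, t = thickness)

with the slice area read off a binary mask as foreground-pixel count times
pixel area.  Four-chamber linear measurements are extracted from a long-axis
binary mask: basal diameter = foreground extent of the basal row, length =
number of rows from base to the last non-empty row, both times pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .cohort import MaskStack

__all__ = ["VolumeEstimate", "slice_area", "disk_summation_volume",
           "measure_four_chamber"]


@dataclass(frozen=True)
class VolumeEstimate:
    """Disk-summation result; ``volume`` is exactly sum(areas) * thickness."""

    volume: float  # mL
    n_slices: int
    per_slice_areas: Tuple[float, ...]  # cm^2
    method: str = "disk_summation"


def slice_area(mask: np.ndarray, pixel_size: float) -> float:
    """Area (cm^2) of a binary 2D mask: foreground pixels * pixel_size^2."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2D, got ndim={mask.ndim}")
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("mask must be binary (values in {0, 1})")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return float(mask.sum()) * pixel_size**2


def disk_summation_volume(stack: MaskStack) -> VolumeEstimate:
    """Sum of slice areas times slice thickness, in mL."""
    if stack.n_slices < 1:
        raise ValueError("empty mask stack")
    areas = tuple(slice_area(stack.data[i], stack.pixel_size)
                  for i in range(stack.n_slices))
    volume = float(sum(areas)) * stack.slice_thickness
    return VolumeEstimate(volume=volume, n_slices=stack.n_slices,
                          per_slice_areas=areas)


def measure_four_chamber(long_axis_mask: np.ndarray, pixel_size: float
                         ) -> Tuple[float, float]:
    """(basal diameter, baso-apical length) in cm from a long-axis mask.

    The base is at row 0 by convention; the basal row is the first non-empty
    row.  Diameter is the column extent of that row; length runs from the
    basal row through the last non-empty row, inclusive.
    """
    mask = np.asarray(long_axis_mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2D, got ndim={mask.ndim}")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    nonempty = np.flatnonzero(mask.any(axis=1))
    if nonempty.size == 0:
        raise ValueError("empty mask: no measurement possible")
    basal, apical = int(nonempty[0]), int(nonempty[-1])
    cols = np.flatnonzero(mask[basal])
    diameter = (cols[-1] - cols[0] + 1) * pixel_size
    length = (apical - basal + 1) * pixel_size
    return float(diameter), float(length)
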