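"""Detection sensitivity under reduced scan size (field of view).

Crops are centered at the FOV center (the fovea — scans are macula-centered)
and indexed by *size* on a 250 µm grid along each axis. For every crop size
(wx, wy) the sensitivity is the fraction of eyes that are positive in the
full 6×6 mm reference and still show at least one presence pixel inside the
crop. Centered crops are nested, so the map is non-decreasing along both
size axes, and the full-size entry is 1 by construction.

A pixel at index (ix, iy) sits at physical position (ix·pitch_x, iy·isd);
the crop rectangle is closed, so boundary pixels count as inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enface import EnFaceMap
from .errors import ValidationError
from .volume_io import Biomarker, ScanGeometry

__all__ = ["CropWindow", "SensitivityMap", "crop_presence", "sensitivity_map", "exemplary_sensitivities"]

_REL_TOL = 1e-9  # boundary ties included despite float rounding


@dataclass(frozen=True)
class CropWindow:
    width_x_um: float
    width_y_um: float
    center_x_um: float
    center_y_um: float

    def __post_init__(self) -> None:
        if not (self.width_x_um > 0 and self.width_y_um > 0):
            raise ValidationError("crop widths must be > 0")


@dataclass
class SensitivityMap:
    """Detection sensitivity per centered crop size, Fig.-3-style.

    ``sensitivity[i, j]`` is the sensitivity for the crop of size
    ``(sizes_x_um[j], sizes_y_um[i])`` — rows index slow-axis size, columns
    fast-axis size.
    """

    sensitivity: np.ndarray
    sizes_x_um: np.ndarray
    sizes_y_um: np.ndarray
    step_um: float
    biomarker: Biomarker
    n_positive_reference: int

    def value_at(self, width_x_um: float, width_y_um: float) -> float:
        ix = int(np.argmin(np.abs(self.sizes_x_um - width_x_um)))
        iy = int(np.argmin(np.abs(self.sizes_y_um - width_y_um)))
        return float(self.sensitivity[iy, ix])


def _check_window(w: CropWindow, g: ScanGeometry) -> None:
    tol = _REL_TOL * max(g.fov_x_um, g.fov_y_um)
    if (
        w.center_x_um - w.width_x_um / 2 < -tol
        or w.center_x_um + w.width_x_um / 2 > g.fov_x_um + tol
        or w.center_y_um - w.width_y_um / 2 < -tol
        or w.center_y_um + w.width_y_um / 2 > g.fov_y_um + tol
    ):
        raise ValidationError(f"crop window {w} extends outside the FOV")


def crop_presence(m: EnFaceMap, w: CropWindow) -> bool:
    """True iff any presence pixel lies inside the closed crop rectangle."""
    g = m.geometry
    _check_window(w, g)
    ys, xs = np.nonzero(m.presence)
    if ys.size == 0:
        return False
    px = xs * g.pitch_x_um
    py = ys * g.isd_um
    tol = _REL_TOL * max(g.fov_x_um, g.fov_y_um)
    inside = (
        (px >= w.center_x_um - w.width_x_um / 2 - tol)
        & (px <= w.center_x_um + w.width_x_um / 2 + tol)
        & (py >= w.center_y_um - w.width_y_um / 2 - tol)
        & (py <= w.center_y_um + w.width_y_um / 2 + tol)
    )
    return bool(inside.any())


def _size_grid(fov_um: float, step_um: float) -> np.ndarray:
    n = int(np.ceil(fov_um / step_um - _REL_TOL))
    return step_um * np.arange(1, n + 1)


def sensitivity_map(maps: "list[EnFaceMap]", step_um: float = 250.0) -> SensitivityMap:
    """Crop-size sensitivity grid over a cohort of same-biomarker en-face maps.

    Only eyes positive in the full reference FOV enter the denominator;
    reference-negative eyes cannot affect the map. The implementation maps
    each presence pixel to the smallest centered crop containing it, which is
    exactly equivalent to re-scanning every crop.
    """
    if not maps:
        raise ValidationError("empty cohort")
    first = maps[0]
    g = first.geometry
    for m in maps[1:]:
        if m.biomarker is not first.biomarker or m.geometry != g:
            raise ValidationError("maps must share biomarker and geometry")
    positives = [m for m in maps if m.presence.any()]
    if not positives:
        raise ValidationError(
            f"no eye is positive for {first.biomarker.value} in the full FOV; "
            "sensitivity is undefined"
        )

    sizes_x = _size_grid(g.fov_x_um, step_um)
    sizes_y = _size_grid(g.fov_y_um, step_um)
    cx, cy = g.fov_x_um / 2.0, g.fov_y_um / 2.0
    nx, ny = sizes_x.size, sizes_y.size
    tol = _REL_TOL * max(g.fov_x_um, g.fov_y_um)

    detected_total = np.zeros((ny, nx), dtype=np.int64)
    for m in positives:
        ys, xs = np.nonzero(m.presence)
        # smallest crop size along each axis that reaches this pixel
        rx = 2.0 * np.abs(xs * g.pitch_x_um - cx)
        ry = 2.0 * np.abs(ys * g.isd_um - cy)
        ix = np.searchsorted(sizes_x, rx - tol, side="left")
        iy = np.searchsorted(sizes_y, ry - tol, side="left")
        # a pixel needing (iy, ix) makes every crop with both sizes >= it hit;
        # per slow-axis level take the min fast-axis requirement, then the
        # running min downward gives the detection frontier
        min_ix = np.full(ny, nx, dtype=np.int64)
        np.minimum.at(min_ix, np.clip(iy, 0, ny - 1), np.clip(ix, 0, nx - 1))
        min_ix = np.minimum.accumulate(min_ix)
        det = np.zeros((ny, nx), dtype=bool)
        for level in range(ny):
            if min_ix[level] < nx:
                det[level, min_ix[level]:] = True
        detected_total += det

    return SensitivityMap(
        sensitivity=detected_total / len(positives),
        sizes_x_um=sizes_x,
        sizes_y_um=sizes_y,
        step_um=float(step_um),
        biomarker=first.biomarker,
        n_positive_reference=len(positives),
    )


def exemplary_sensitivities(smap: SensitivityMap) -> dict[str, float]:
    """The highlighted square crop sensitivities: full FOV, 3×3, 2×2, 1×1 mm."""
    full_x = float(smap.sizes_x_um[-1])
    full_y = float(smap.sizes_y_um[-1])
    return {
        "full": smap.value_at(full_x, full_y),
        "3x3_mm": smap.value_at(3000.0, 3000.0),
        "2x2_mm": smap.value_at(2000.0, 2000.0),
        "1x1_mm": smap.value_at(1000.0, 1000.0),
    }
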