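"""Population biomarker heatmaps and the isotropic 2D Gaussian fit.

Per-eye binary presence maps are averaged into a fraction-of-eyes-positive
heatmap, which is then fit by

    f(x, y) = A * exp(-((x - mu_x)^2 + (y - mu_y)^2) / (2 sigma^2))

by nonlinear least squares over all grid points in physical µm coordinates
(the two en-face axes have different pixel pitches, so fitting in pixel
indices would distort sigma). Goodness of fit is the standard coefficient of
determination R² = 1 − SS_res/SS_tot with SS_tot about the heatmap mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .enface import EnFaceMap
from .errors import ValidationError
from .volume_io import Biomarker, ScanGeometry

__all__ = ["PopulationHeatmap", "GaussianFitResult", "aggregate", "gaussian", "fit_gaussian"]


@dataclass
class PopulationHeatmap:
    """Elementwise fraction of cohort eyes positive at each en-face location."""

    fraction: np.ndarray
    n_eyes: int
    biomarker: Biomarker
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.fraction = np.asarray(self.fraction, dtype=float)
        expected = (self.geometry.n_bscans, self.geometry.n_ascans)
        if self.fraction.shape != expected:
            raise ValidationError(f"fraction shape {self.fraction.shape} != {expected}")
        if self.n_eyes < 1:
            raise ValidationError("n_eyes must be >= 1")
        if np.any(self.fraction < 0) or np.any(self.fraction > 1):
            raise ValidationError("fraction values must lie in [0, 1]")

    def grids_um(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (X, Y) coordinate grids of the heatmap pixels, µm."""
        return np.meshgrid(
            self.geometry.ascan_positions_um, self.geometry.bscan_positions_um
        )


@dataclass
class GaussianFitResult:
    A: float
    mu_x_um: float
    mu_y_um: float
    sigma_um: float
    r_squared: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "A": self.A,
            "mu_x_um": self.mu_x_um,
            "mu_y_um": self.mu_y_um,
            "sigma_um": self.sigma_um,
            "r_squared": self.r_squared,
            "converged": self.converged,
        }


def aggregate(maps: "list[EnFaceMap]") -> PopulationHeatmap:
    """Average per-eye presence maps into a population fraction heatmap.

    All maps must share biomarker and geometry; the denominator is the number
    of eyes aggregated.
    """
    if not maps:
        raise ValidationError("cannot aggregate an empty list of en-face maps")
    first = maps[0]
    for m in maps[1:]:
        if m.biomarker is not first.biomarker:
            raise ValidationError(
                f"mixed biomarkers: {m.biomarker.value} vs {first.biomarker.value}"
            )
        if m.geometry != first.geometry:
            raise ValidationError("mixed geometries in cohort aggregation")
    stack = np.stack([m.presence for m in maps]).astype(float)
    return PopulationHeatmap(
        fraction=stack.mean(axis=0),
        n_eyes=len(maps),
        biomarker=first.biomarker,
        geometry=first.geometry,
    )


def gaussian(x_um, y_um, A: float, mu_x_um: float, mu_y_um: float, sigma_um: float):
    """Isotropic 2D Gaussian surface; exact model evaluation."""
    if not sigma_um > 0:
        raise ValidationError("sigma_um must be > 0")
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    return A * np.exp(-((x - mu_x_um) ** 2 + (y - mu_y_um) ** 2) / (2.0 * sigma_um**2))


def _initial_guess(h: PopulationHeatmap) -> tuple[float, float, float, float]:
    # amplitude = max; center = intensity-weighted centroid; sigma = weighted
    # RMS radius about the centroid (isotropic, so the radial second moment
    # is 2 sigma^2)
    X, Y = h.grids_um()
    fr = h.fraction
    tot = fr.sum()
    mux = float((X * fr).sum() / tot)
    muy = float((Y * fr).sum() / tot)
    msr = float((((X - mux) ** 2 + (Y - muy) ** 2) * fr).sum() / tot)
    sig = math.sqrt(max(msr, 0.0) / 2.0)
    return float(fr.max()), mux, muy, sig


def fit_gaussian(h: PopulationHeatmap, area_weighted: bool = False) -> GaussianFitResult:
    """Least-squares fit of the isotropic Gaussian to a population heatmap.

    Every grid point enters the fit; on the regular en-face grid each pixel
    covers the same physical area, so ``area_weighted`` does not change the
    result there (it is honored for completeness). A constant heatmap has
    SS_tot = 0: R² is reported as NaN with ``converged=False``. An all-zero
    heatmap is rejected — the fit is undefined.
    """
    fr = h.fraction
    if not np.any(fr > 0):
        raise ValidationError("cannot fit an all-zero heatmap")
    g = h.geometry
    X, Y = h.grids_um()
    A0, mux0, muy0, sig0 = _initial_guess(h)

    if np.ptp(fr) == 0.0:
        return GaussianFitResult(
            A=A0,
            mu_x_um=g.fov_x_um / 2.0,
            mu_y_um=g.fov_y_um / 2.0,
            sigma_um=float("nan"),
            r_squared=float("nan"),
            converged=False,
        )

    pitch = min(g.pitch_x_um, g.isd_um)
    sigma_max = float(max(g.fov_x_um, g.fov_y_um))
    p0 = np.array([A0, mux0, muy0, min(max(sig0, pitch), sigma_max)])
    lo = np.array([0.0, -sig0 - pitch, -sig0 - pitch, 1e-3])
    hi = np.array(
        [1.5, g.fov_x_um + sig0 + pitch, g.fov_y_um + sig0 + pitch, sigma_max]
    )
    p0 = np.clip(p0, lo + 1e-12, hi - 1e-12)

    x = X.ravel()
    y = Y.ravel()
    z = fr.ravel()
    w = np.ones_like(z)
    if area_weighted:
        w[:] = math.sqrt(g.pitch_x_um * g.isd_um)  # uniform grid: constant weight

    def residuals(p):
        return w * (gaussian(x, y, *p) - z)

    res = least_squares(
        residuals, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000
    )
    A, mux, muy, sig = (float(v) for v in res.x)
    ss_res = float(np.sum((gaussian(x, y, *res.x) - z) ** 2))
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return GaussianFitResult(
        A=A,
        mu_x_um=mux,
        mu_y_um=muy,
        sigma_um=sig,
        r_squared=r2,
        converged=bool(res.success) and math.isfinite(r2),
    )
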