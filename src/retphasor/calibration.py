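"""Reflectance calibration of raw digital levels.

A fundus frame records digital levels (DL) that mix tissue reflectance with
LED power, sensor sensitivity and dark current.  With a white-reference frame
(a calibrated diffuse target imaged under the same exposure) and a dark-current
frame (no illumination), per-pixel per-band reflectance is

    Refl(i, j, λ) = (DL − DL_dark) / (DL_white − DL_dark) · Refl_ref(λ)

where ``Refl_ref`` is the manufacturer-calibrated reflectance of the white
target.  The ratio removes wavelength-dependent illumination and sensitivity;
values are deliberately NOT clipped to [0, 1]: noise can push them slightly
outside and downstream band-wise standardization makes clipping both
unnecessary and distorting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SpectralCube

__all__ = ["ReferenceSet", "compute_reflectance"]


@dataclass
class ReferenceSet:
    """White-reference and dark-current cubes plus the white target's reflectance."""

    white: SpectralCube
    dark: SpectralCube
    refl_ref: np.ndarray  # per-band calibrated white reflectance, each in (0, 1]

    def __post_init__(self):
        self.refl_ref = np.atleast_1d(np.asarray(self.refl_ref, dtype=float))
        if self.white.bands != self.dark.bands:
            raise ValueError("white and dark references must share a BandSet")
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark references must share H×W×n shape")
        if self.refl_ref.size == 1:
            self.refl_ref = np.full(self.white.bands.n, float(self.refl_ref))
        if self.refl_ref.shape != (self.white.bands.n,):
            raise ValueError("refl_ref must be scalar or one value per band")
        if np.any(self.refl_ref <= 0) or np.any(self.refl_ref > 1):
            raise ValueError("refl_ref values must lie in (0, 1]")


def compute_reflectance(raw: SpectralCube, refs: ReferenceSet,
                        eps: float = 1.0) -> SpectralCube:
    """Convert a raw digital-level cube to pixel-wise spectral reflectance.

    Parameters
    ----------
    raw
        Cube at stage ``raw_dl`` sharing BandSet and H×W with the references.
    refs
        White/dark reference pair and per-band white reflectance.
    eps
        Denominator guard in digital levels (default 1.0, below the sensor
        noise floor): pixels where any band's white−dark difference falls
        under ``eps`` are marked invalid rather than divided.

    Returns
    -------
    SpectralCube
        Stage ``reflectance``; validity = input validity AND denominator validity.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if raw.stage != "raw_dl":
        raise ValueError(f"expected a raw_dl cube, got stage '{raw.stage}'")
    if raw.bands != refs.white.bands:
        raise ValueError("cube and references have mismatched band sets")
    if raw.shape != refs.white.shape:
        raise ValueError("cube and references have mismatched shapes")

    denom = refs.white.pixels.astype(float) - refs.dark.pixels.astype(float)
    denom_ok = np.all(denom >= eps, axis=2)
    safe = np.where(np.abs(denom) < eps, 1.0, denom)
    refl = (raw.pixels.astype(float) - refs.dark.pixels) / safe * refs.refl_ref
    valid = raw.valid & denom_ok
    return SpectralCube(refl, raw.bands, stage="reflectance", valid=valid)


def digital_levels_from_reflectance(refl: np.ndarray, refs: ReferenceSet) -> np.ndarray:
    """Forward model inverse of :func:`compute_reflectance` (used by the generator)."""
    white = refs.white.pixels.astype(float)
    dark = refs.dark.pixels.astype(float)
    return dark + (white - dark) * refl / refs.refl_ref
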