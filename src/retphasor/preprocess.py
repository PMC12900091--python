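"""Band-wise Z-score normalization, percentile trimming, RGB-like band
extraction, and region-of-interest restriction.

These are the steps applied between reflectance calibration and phasor (or
band-average) feature extraction.  Z-scoring standardizes each band to zero
mean and unit variance over a scope mask, emphasizing relative spectral
contrast over absolute reflectance; percentile trimming then removes the
per-band distribution tails, which otherwise dominate averaged features after
standardization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ROIMask, SpectralCube, RGB_LIKE_CENTERS_NM, BandSet

__all__ = ["TrimPolicy", "PixelSet", "zscore_bands", "trim_percentiles",
           "extract_rgb_like", "apply_roi"]


@dataclass(frozen=True)
class TrimPolicy:
    """Symmetric-by-default percentile trimming of per-band value tails.

    The default removes the top and bottom 20th percentiles of each band's
    in-scope distribution.
    """

    lower_pct: float = 20.0
    upper_pct: float = 20.0
    enabled: bool = True

    def __post_init__(self):
        if not (0 <= self.lower_pct < 50 and 0 <= self.upper_pct < 50):
            raise ValueError("trim percentiles must lie in [0, 50)")
        if self.lower_pct + self.upper_pct >= 100:
            raise ValueError("lower_pct + upper_pct must be < 100")

    @classmethod
    def disabled(cls) -> "TrimPolicy":
        return cls(0.0, 0.0, enabled=False)


@dataclass
class PixelSet:
    """In-scope, valid spectra extracted from a cube: coordinates + values."""

    coords: np.ndarray   # (N, 2) int — (row, col)
    spectra: np.ndarray  # (N, n)
    bands: BandSet

    @property
    def n_pixels(self) -> int:
        return self.spectra.shape[0]


def _scope_selection(cube: SpectralCube, scope_mask: ROIMask | np.ndarray) -> np.ndarray:
    mask = scope_mask.mask if isinstance(scope_mask, ROIMask) else np.asarray(scope_mask, bool)
    if mask.shape != cube.pixels.shape[:2]:
        raise ValueError("scope mask shape does not match cube H×W")
    return mask & cube.valid


def zscore_bands(cube: SpectralCube, scope_mask: ROIMask | np.ndarray) -> SpectralCube:
    """Standardize each band to zero mean and unit variance over a scope.

    μ and σ (population standard deviation) are computed independently per
    band over ``scope_mask ∩ valid`` and the affine transform is applied to
    the whole image, so values of one band never affect another and the
    relative spatial pattern within each band is preserved.

    Raises on an empty scope (< 2 pixels) or on any zero-variance band.
    """
    if cube.stage != "reflectance":
        raise ValueError(f"zscore_bands expects a reflectance cube, got '{cube.stage}'")
    sel = _scope_selection(cube, scope_mask)
    if sel.sum() < 2:
        raise ValueError("z-score scope must contain at least 2 valid pixels")
    vals = cube.pixels[sel]  # (N, n)
    mu = vals.mean(axis=0)
    sigma = vals.std(axis=0)  # population sd (ddof=0)
    # a constant band can show sd ~1e-17 from accumulation error; treat as zero
    bad = np.flatnonzero(sigma <= 1e-12 * np.maximum(np.abs(mu), 1.0))
    if bad.size:
        centers = [cube.bands.centers[b] for b in bad]
        raise ValueError(f"zero-variance band(s) at {centers} nm: cannot z-score")
    z = (cube.pixels - mu) / sigma
    return SpectralCube(z, cube.bands, stage="zscored", valid=cube.valid.copy())


def trim_percentiles(cube: SpectralCube, policy: TrimPolicy,
                     scope_mask: ROIMask | np.ndarray) -> SpectralCube:
    """Invalidate per-band outlier pixels; surviving spectra are untouched.

    For each band, the ``lower_pct`` and ``100−upper_pct`` percentiles of the
    in-scope valid values are computed (linear interpolation between order
    statistics); pixels strictly below the lower or strictly above the upper
    bound in ANY band are marked invalid (union rule — the per-pixel phasor
    needs all bands, so partial spectra are unusable).  Pixel values are
    never altered, only the validity mask.
    """
    out = cube.copy()
    if not policy.enabled or (policy.lower_pct == 0 and policy.upper_pct == 0):
        return out
    if cube.stage != "zscored":
        raise ValueError("trim_percentiles operates on z-scored cubes")
    sel = _scope_selection(cube, scope_mask)
    if sel.sum() < 2:
        raise ValueError("trim scope must contain at least 2 valid pixels")
    vals = cube.pixels[sel]  # (N, n)
    lo = np.percentile(vals, policy.lower_pct, axis=0)
    hi = np.percentile(vals, 100.0 - policy.upper_pct, axis=0)
    outlier = np.any((cube.pixels < lo) | (cube.pixels > hi), axis=2)
    out.valid &= ~(outlier & sel)  # only in-scope pixels are invalidated
    if (_scope_selection(out, scope_mask)).sum() < 2:
        raise ValueError("trimming left fewer than 2 valid pixels in scope")
    return out


def extract_rgb_like(cube: SpectralCube,
                     centers_nm=RGB_LIKE_CENTERS_NM) -> SpectralCube:
    """Extract the 3-band sub-cube simulating a conventional color fundus camera.

    Defaults to the blue/green/red surrogate bands at 471, 595 and 732 nm;
    output bands are in ascending wavelength and the validity mask is carried
    over unchanged.
    """
    missing = []
    idx = []
    for c in sorted(centers_nm):
        try:
            idx.append(cube.bands.index_of(c))
        except KeyError:
            missing.append(c)
    if missing:
        raise ValueError(f"cube lacks required band(s) centered at {missing} nm")
    bands = BandSet([cube.bands.centers[i] for i in idx],
                    [cube.bands.bandwidths[i] for i in idx])
    return SpectralCube(cube.pixels[:, :, idx].copy(), bands,
                        stage=cube.stage, valid=cube.valid.copy())


def apply_roi(cube: SpectralCube, roi: ROIMask | np.ndarray) -> PixelSet:
    """Return exactly the pixels where the ROI mask AND the validity mask hold."""
    sel = _scope_selection(cube, roi)
    if not sel.any():
        raise ValueError("ROI ∩ valid is empty")
    coords = np.argwhere(sel)
    return PixelSet(coords, cube.pixels[sel], cube.bands)
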