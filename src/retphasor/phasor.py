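"""Per-pixel spectral phasor transform and phasor-cloud summarization.

The spectral phasor maps each pixel's n-band spectrum I(m), m = 0..n−1 in
ascending wavelength, to a point in the (g, s) plane via the normalized k-th
discrete Fourier harmonic:

    g(k) = Σ_m I(m) cos(2πkm/n) / Σ_m I(m)
    s(k) = Σ_m I(m) sin(2πkm/n) / Σ_m I(m)

For nonnegative spectra the point is a convex combination of unit-circle
points and therefore lies inside the unit disk; the transform is invariant to
a positive rescaling of the spectrum and linear under intensity-weighted
spectral mixing, which is what makes phasors useful as a low-dimensional
spectral-shape representation.  k ranges over 1..n−1 (k = 0 is identically
(1, 0) under the normalization and carries no shape information).

Two phase conventions are supported: uniform phase over the band *index*
(default; the bandwidth Δλ is constant per camera and cancels in the ratio),
or phase proportional to *wavelength* with per-band Δλ weighting, for cubes
with strongly non-uniform band spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ROIMask, SpectralCube, BandSet

__all__ = ["PhasorField", "PhasorSummary", "harmonics_available",
           "phasor_transform", "summarize_phasor", "band_average_features"]


@dataclass
class PhasorField:
    """Per-pixel (g, s) coordinates at one harmonic, with a validity mask."""

    g: np.ndarray
    s: np.ndarray
    harmonic: int
    valid: np.ndarray

    def __post_init__(self):
        if self.harmonic < 1:
            raise ValueError("harmonic must be ≥ 1")
        if not (self.g.shape == self.s.shape == self.valid.shape):
            raise ValueError("g, s and valid must share shape")


@dataclass
class PhasorSummary:
    """Phasor cloud summary over one scope: centroid and scalar dispersion.

    ``std`` is the rotation-invariant dispersion sqrt(var(g) + var(s)) with
    population variances, so the three-feature representation is exactly
    (g_avg, s_avg, STD).
    """

    g_avg: float
    s_avg: float
    std: float | None
    harmonic: int
    n_pixels: int


def harmonics_available(n_bands: int) -> list[int]:
    """Harmonics produced by an n-band cube: 1..n−1 (k=0 is the image average)."""
    if n_bands < 2:
        raise ValueError("need at least 2 bands")
    return list(range(1, n_bands))


def _phase(bands: BandSet, k: int, phase_axis: str):
    n = bands.n
    if phase_axis == "index":
        phi = 2.0 * np.pi * k * np.arange(n) / n
        w = np.ones(n)
    elif phase_axis == "wavelength":
        lam = np.asarray(bands.centers)
        phi = 2.0 * np.pi * k * (lam - lam[0]) / (lam[-1] - lam[0])
        w = np.asarray(bands.bandwidths)
    else:
        raise ValueError("phase_axis must be 'index' or 'wavelength'")
    return phi, w


def phasor_transform(cube: SpectralCube, k: int, eps: float = 1e-6,
                     phase_axis: str = "index", method: str = "direct") -> PhasorField:
    """Compute the per-pixel spectral phasor at harmonic ``k``.

    Parameters
    ----------
    cube
        Any-stage cube with n ≥ 2 bands.  Z-scored input is allowed; its
        per-pixel band sum can approach zero, so such pixels are invalidated
        by the ``eps`` guard instead of yielding unbounded phasors.
    k
        Harmonic, 1 ≤ k ≤ n−1.
    eps
        Denominator guard: pixels with \\|Σ_m I(m)\\| < eps become invalid.
    phase_axis
        'index' (default) or 'wavelength' (Δλ-weighted).
    method
        'direct' evaluates the sums with explicit cos/sin kernels; 'fft'
        takes the k-th output of a fast Fourier transform along the band
        axis (index phase only).  Both give identical values to numerical
        precision.
    """
    n = cube.bands.n
    if n < 2:
        raise ValueError("phasor transform needs at least 2 bands")
    if not (1 <= k <= n - 1):
        raise ValueError(f"harmonic must be in 1..{n - 1}, got {k}")
    if eps <= 0:
        raise ValueError("eps must be positive")

    I = cube.pixels.astype(float)
    if method == "fft":
        if phase_axis != "index":
            raise ValueError("the FFT path supports only the index phase axis")
        F = np.fft.fft(I, axis=2)
        denom = F[:, :, 0].real
        num_g, num_s = F[:, :, k].real, -F[:, :, k].imag
    elif method == "direct":
        phi, w = _phase(cube.bands, k, phase_axis)
        denom = I @ w
        num_g = I @ (np.cos(phi) * w)
        num_s = I @ (np.sin(phi) * w)
    else:
        raise ValueError("method must be 'direct' or 'fft'")

    denom_ok = np.abs(denom) >= eps
    safe = np.where(denom_ok, denom, 1.0)
    g = np.where(denom_ok, num_g / safe, 0.0)
    s = np.where(denom_ok, num_s / safe, 0.0)
    return PhasorField(g, s, k, cube.valid & denom_ok)


def summarize_phasor(field: PhasorField, scope: ROIMask | np.ndarray,
                     with_std: bool = True) -> PhasorSummary:
    """Average the phasor cloud over a scope into (g_avg, s_avg[, STD]).

    Averaging over thousands of pixels suppresses pixel-level noise while
    preserving the retina's global spectral signature; the scalar STD adds a
    measure of within-retina phasor variability.
    """
    mask = scope.mask if isinstance(scope, ROIMask) else np.asarray(scope, bool)
    sel = mask & field.valid
    npx = int(sel.sum())
    if npx == 0:
        raise ValueError("empty scope: no valid pixels to summarize")
    g, s = field.g[sel], field.s[sel]
    std = None
    if with_std:
        if npx < 2:
            raise ValueError("STD requires at least 2 valid pixels in scope")
        std = float(np.sqrt(g.var() + s.var()))  # population variances
    return PhasorSummary(float(g.mean()), float(s.mean()), std, field.harmonic, npx)


def band_average_features(cube: SpectralCube, scope: ROIMask | np.ndarray) -> np.ndarray:
    """Per-band mean over a scope — the Avg-MSI / Avg-RGB baseline feature vector."""
    mask = scope.mask if isinstance(scope, ROIMask) else np.asarray(scope, bool)
    sel = mask & cube.valid
    if not sel.any():
        raise ValueError("empty scope: no valid pixels to average")
    return cube.pixels[sel].mean(axis=0)
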