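"""Synthetic multispectral fundus dataset generator.

Emulates the data the analysis pipeline assumes: per-case 12-band cubes of
raw digital levels acquired through a white/dark-referenced camera, binary
ROI masks (vessels, optic disk, macula, background) with simple but
anatomically sensible geometry, and a shared white/dark reference pair.

Scene model, per case:

1. A circular retinal field fills the image.  Tissue classes get smooth
   reflectance spectra: a background whose reflectance rises toward the red
   (melanin/blood-dominated fundus), vessels darkened by hemoglobin-like
   absorption dips near 540–580 nm, a bright optic disk, and a slightly
   darker macula with a blue absorption dip.
2. Per-case biological variability: each tissue class's spectrum receives an
   independent smooth random perturbation (low-order polynomial in
   wavelength), and the disk/macula/vessel geometry is randomized.
3. Diseased cases add a band-limited reflectance perturbation (Gaussian
   profile in wavelength, peaked in the green) on drusen-like spots covering
   a configurable fraction of the configured spatial extent.  Spot-wise
   application matters: a spatially uniform per-band shift would be removed
   exactly by band-wise Z-scoring downstream.
4. Acquisition: a smooth multiplicative illumination nonuniformity field
   (shared across bands), per-pixel per-band multiplicative lognormal noise
   on reflectance, conversion to digital levels through the reference model
   DL = dark + (white − dark) · R / refl_ref, and additive Gaussian sensor
   noise on the digital levels.

Everything is driven by a single seed; identical configs produce bit-identical
datasets, and the label of a case changes nothing but the disease effect
(healthy and diseased cases with the same case index share every random draw).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation, disk as disk_footprint

from .calibration import ReferenceSet, digital_levels_from_reflectance
from .io import (BandSet, CaseEntry, DatasetManifest, ROIMask, SpectralCube,
                 write_cube, write_mask)

__all__ = ["SpectrumParams", "DiseaseEffect", "NoiseModel", "SyntheticConfig",
           "SyntheticCase", "tissue_spectrum", "generate_case",
           "generate_cases", "generate_dataset", "make_references"]

TISSUE_CLASSES = ("background", "vessels", "optic_disk", "macula")
EXTENTS = ("whole_retina", "macula_only", "disk_only", "vessels_only")


def _gauss(lam, center, width):
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SpectrumParams:
    """Parameters of the smooth tissue reflectance curves (reflectance units).

    Background: base + red-rising sigmoid (melanin-like darkening toward the
    blue).  Vessels: attenuated background minus hemoglobin-like Gaussian
    absorption dips at ~542/577 nm.  Optic disk: bright, weakly sloped.
    Macula: attenuated background minus a blue (lutein-like) dip.
    """

    bg_base: float = 0.10
    bg_amplitude: float = 0.45
    bg_inflection_nm: float = 610.0
    bg_slope_nm: float = 45.0
    vessel_attenuation: float = 0.85
    hb_dip_depth: float = 0.03
    hb_dip_centers_nm: tuple[float, float] = (542.0, 577.0)
    hb_dip_width_nm: float = 15.0
    hb_broad_depth: float = 0.02
    hb_broad_width_nm: float = 45.0
    disk_base: float = 0.35
    disk_amplitude: float = 0.50
    macula_attenuation: float = 0.88
    macula_dip_depth: float = 0.05
    macula_dip_center_nm: float = 460.0
    macula_dip_width_nm: float = 35.0


def tissue_spectrum(tissue_class: str, bands: BandSet,
                    params: SpectrumParams | None = None) -> np.ndarray:
    """Noise-free mean reflectance spectrum of one tissue class at the band centers.

    Guarantees by construction: all values in (0, 1]; vessels darker than
    background throughout 500–600 nm; the optic disk brightest of all classes
    at every band.
    """
    p = params or SpectrumParams()
    lam = np.asarray(bands.centers, dtype=float)
    bg = p.bg_base + p.bg_amplitude * _sigmoid((lam - p.bg_inflection_nm) / p.bg_slope_nm)
    if tissue_class == "background":
        r = bg
    elif tissue_class == "vessels":
        dips = sum(_gauss(lam, c, p.hb_dip_width_nm) for c in p.hb_dip_centers_nm)
        broad = _gauss(lam, np.mean(p.hb_dip_centers_nm), p.hb_broad_width_nm)
        r = bg * p.vessel_attenuation - p.hb_dip_depth * dips - p.hb_broad_depth * broad
    elif tissue_class == "optic_disk":
        r = p.disk_base + p.disk_amplitude * _sigmoid((lam - 500.0) / 80.0)
    elif tissue_class == "macula":
        r = bg * p.macula_attenuation - p.macula_dip_depth * _gauss(
            lam, p.macula_dip_center_nm, p.macula_dip_width_nm)
    else:
        raise ValueError(f"unknown tissue class '{tissue_class}'")
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError(f"spectrum parameters yield reflectance outside (0, 1] "
                         f"for '{tissue_class}'")
    return r


@dataclass(frozen=True)
class DiseaseEffect:
    """Band-limited additive reflectance perturbation on lesion-like spots.

    The spectral profile is a sum of Gaussian lobes in wavelength; the
    default places them at 524 and 645 nm — regions the 12-band camera
    samples densely but a 471/595/732 nm RGB surrogate essentially misses —
    producing a spectral *shape* change (drusen-like green-band brightening
    plus an adjacent red-band alteration) rather than a flat brightening.
    ``magnitude`` scales the profile's peak in reflectance units;
    ``delta_spectrum`` overrides it with an explicit per-band vector.
    Spots cover approximately ``lesion_fraction`` of the configured spatial
    extent, blurred into diffuse patches.
    """

    magnitude: float = 0.6
    extent: str = "whole_retina"
    profile_centers_nm: tuple[float, ...] = (524.0, 645.0)
    profile_widths_nm: tuple[float, ...] = (22.0, 20.0)
    profile_weights: tuple[float, ...] = (1.0, 0.8)
    delta_spectrum: tuple[float, ...] | None = None
    lesion_fraction: float = 0.45
    lesion_radius_px: tuple[int, int] = (3, 7)
    lesion_blur_px: float = 2.0

    def __post_init__(self):
        if self.magnitude < 0:
            raise ValueError("magnitude must be ≥ 0")
        if self.extent not in EXTENTS:
            raise ValueError(f"extent must be one of {EXTENTS}")
        if not (0 < self.lesion_fraction <= 1):
            raise ValueError("lesion_fraction must lie in (0, 1]")
        if not (len(self.profile_centers_nm) == len(self.profile_widths_nm)
                == len(self.profile_weights)):
            raise ValueError("profile centers/widths/weights must align")

    def profile(self, bands: BandSet) -> np.ndarray:
        if self.delta_spectrum is not None:
            d = np.asarray(self.delta_spectrum, float)
            if d.shape != (bands.n,):
                raise ValueError("delta_spectrum length must equal band count")
            return d
        lam = np.asarray(bands.centers)
        shape = sum(w * _gauss(lam, c, s) for c, s, w in
                    zip(self.profile_centers_nm, self.profile_widths_nm,
                        self.profile_weights))
        return self.magnitude * shape


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition noise: smooth illumination field + pixel noise.

    ``illumination_sd`` is the relative sd of a smooth multiplicative field
    shared across bands (uneven fundus illumination); ``texture_sd`` is the
    relative sd of a fine-grained multiplicative field, also shared across
    bands, emulating real tissue texture — without it, within-region pixel
    variation would be pure band-independent sensor noise, which no real
    fundus exhibits; ``multiplicative_sd`` is per-pixel per-band lognormal
    noise on reflectance; ``additive_sd`` is Gaussian sensor noise in
    digital levels.
    """

    multiplicative_sd: float = 0.02
    additive_sd: float = 3.0
    illumination_sd: float = 0.10
    illumination_scale_frac: float = 0.15
    texture_sd: float = 0.05
    texture_scale_px: float = 2.0

    def __post_init__(self):
        for v in (self.multiplicative_sd, self.additive_sd,
                  self.illumination_sd, self.texture_sd):
            if v < 0:
                raise ValueError("noise standard deviations must be ≥ 0")

    @classmethod
    def disabled(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, texture_sd=0.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic dataset.

    Defaults reproduce the study conditions the pipeline targets: 73 healthy
    + 60 diseased cases, the camera's 12 bands, an advanced-stage
    (whole-retina, strong) disease effect, and realistic acquisition noise.
    ``magnitude = 0`` makes healthy and diseased cubes draws from identical
    distributions.
    """

    n_healthy: int = 73
    n_diseased: int = 60
    image_size: tuple[int, int] = (128, 128)
    bands: BandSet = field(default_factory=BandSet.default_msi)
    base_spectrum_params: SpectrumParams = field(default_factory=SpectrumParams)
    disease_effect: DiseaseEffect = field(default_factory=DiseaseEffect)
    noise: NoiseModel = field(default_factory=NoiseModel)
    case_variability_sd: float = 0.003
    white_level: float = 45000.0
    dark_level: float = 800.0
    refl_ref: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.n_healthy < 0 or self.n_diseased < 0:
            raise ValueError("case counts must be ≥ 0")
        if min(self.image_size) < 24:
            raise ValueError("image too small to place optic disk and macula "
                             "(need at least 24×24)")
        if not (0 < self.refl_ref <= 1):
            raise ValueError("refl_ref must lie in (0, 1]")
        if self.white_level <= self.dark_level:
            raise ValueError("white_level must exceed dark_level in every band")


@dataclass
class SyntheticCase:
    """One generated case: raw cube, masks, label, and generation ground truth."""

    case_id: str
    label: str
    cube: SpectralCube
    masks: dict[str, ROIMask]
    reflectance: np.ndarray | None = None  # noisy reflectance field the DL encode
    lesion_mask: np.ndarray | None = None
    extent: str | None = None


def make_references(config: SyntheticConfig) -> ReferenceSet:
    """Shared white/dark reference pair for a dataset (one pair per band set)."""
    H, W = config.image_size
    n = config.bands.n
    white = SpectralCube(np.full((H, W, n), float(config.white_level)), config.bands)
    dark = SpectralCube(np.full((H, W, n), float(config.dark_level)), config.bands)
    return ReferenceSet(white, dark, np.full(n, float(config.refl_ref)))


# ---------------------------------------------------------------------------
# geometry

def _retina_geometry(H, W, rng):
    """Random but anatomically sensible masks for one case."""
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    R = min(H, W) / 2.0 - 1.0
    retina = (yy - cy) ** 2 + (xx - cx) ** 2 <= R ** 2

    # optic disk: bright ellipse offset to one side
    side = rng.choice([-1.0, 1.0])
    dx = side * R * rng.uniform(0.42, 0.50)
    dy = R * rng.uniform(-0.10, 0.10)
    r_disk = R * rng.uniform(0.12, 0.15)
    disk = np.zeros((H, W), bool)
    rr, cc = draw_ellipse(cy + dy, cx + dx, r_disk * rng.uniform(0.95, 1.05),
                          r_disk, shape=(H, W), rotation=rng.uniform(-0.3, 0.3))
    disk[rr, cc] = True
    disk &= retina

    # macula: darker disk near the center, opposite side from the disk
    mx = -side * R * rng.uniform(0.08, 0.16)
    my = R * rng.uniform(-0.08, 0.08)
    r_mac = R * rng.uniform(0.16, 0.19)
    macula = np.zeros((H, W), bool)
    rr, cc = draw_disk((cy + my, cx + mx), r_mac, shape=(H, W))
    macula[rr, cc] = True
    macula &= retina & ~disk

    # vessels: branching random walks emanating from the disk rim (the disk
    # face itself stays mostly vessel-free so the ROI keeps usable pixels)
    vessel_px = np.zeros((H, W), bool)
    n_vessels = 6
    angles = rng.uniform(0, 2 * np.pi, size=n_vessels)
    walks = [((cy + dy + 1.3 * r_disk * np.sin(a),
               cx + dx + 1.3 * r_disk * np.cos(a)), a) for a in angles]
    max_steps = int(2.2 * R)
    budget = int(0.10 * retina.sum())  # keep vessel trunks near a 10% area share
    while walks and vessel_px.sum() < budget:
        (y, x), ang = walks.pop()
        for step in range(max_steps):
            y += np.sin(ang)
            x += np.cos(ang)
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < H and 0 <= ix < W) or not retina[iy, ix]:
                break
            vessel_px[iy, ix] = True
            ang += rng.normal(0.0, 0.18)
            if step > 8 and rng.random() < 0.010 and len(walks) < 12:
                walks.append(((y, x), ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.1)))
    width = 1 if rng.random() < 0.7 else 2  # dilation radius → stroke 3–5 px
    vessels = dilation(vessel_px, disk_footprint(width)) & retina & ~disk

    background = retina & ~(disk | macula | vessels)
    disk_m = disk & ~vessels
    macula_m = macula & ~vessels
    return {
        "entire_retina": retina,
        "vessels": vessels,
        "optic_disk": disk_m,
        "macula": macula_m,
        "background": background,
    }


def _lesion_field(extent_mask, effect: DiseaseEffect, rng):
    """Diffuse drusen-like involvement: a smooth weight field in [0, 1].

    Spots covering ~lesion_fraction of the extent are drawn and then blurred,
    emulating the soft borders of advanced, spatially extended lesions; the
    field is zero outside the extent so the effect stays strictly local.
    Returns (weights, boolean support mask).
    """
    H, W = extent_mask.shape
    target = effect.lesion_fraction * extent_mask.sum()
    spots = np.zeros((H, W), bool)
    coords = np.argwhere(extent_mask)
    if coords.size == 0:
        return np.zeros((H, W)), spots
    covered = 0
    for _ in range(4000):
        if covered >= target:
            break
        y, x = coords[rng.integers(len(coords))]
        r = rng.integers(effect.lesion_radius_px[0], effect.lesion_radius_px[1] + 1)
        rr, cc = draw_disk((y, x), r, shape=(H, W))
        newly = ~spots[rr, cc] & extent_mask[rr, cc]
        covered += int(newly.sum())
        spots[rr, cc] = True
    w = ndimage.gaussian_filter(spots.astype(float), effect.lesion_blur_px)
    if w.max() > 0:
        w = w / w.max()
    w = np.where(extent_mask, w, 0.0)
    return w, w > 1e-3


def _smooth_field(H, W, sd, sigma_px, rng):
    """Multiplicative 1 + sd·(smoothed unit-variance noise) field."""
    raw = rng.standard_normal((H, W))  # drawn even when disabled: keeps the
    if sd == 0:                        # rng stream identical across configs
        return np.ones((H, W))
    smooth = ndimage.gaussian_filter(raw, max(sigma_px, 1e-6))
    s = smooth.std()
    if s == 0:
        return np.ones((H, W))
    return 1.0 + sd * (smooth - smooth.mean()) / s


def _case_rng(config: SyntheticConfig, case_index: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2 ** 31), int(case_index)])


def _smooth_perturbation(bands: BandSet, sd: float, rng) -> np.ndarray:
    """Low-order polynomial perturbation over normalized wavelength."""
    lam = np.asarray(bands.centers)
    u = 2.0 * (lam - lam[0]) / (lam[-1] - lam[0]) - 1.0
    coeffs = rng.normal(0.0, sd, size=4)
    basis = np.stack([np.ones_like(u), u, 2 * u ** 2 - 1, 4 * u ** 3 - 3 * u])
    return coeffs @ basis


def generate_case(config: SyntheticConfig, label: str, case_index: int,
                  extent: str | None = None) -> SyntheticCase:
    """Generate one case deterministically from (config.seed, case_index).

    All random draws are made identically regardless of ``label``; the
    disease perturbation is merely not applied for healthy cases, so a
    healthy and a diseased case at the same index differ only inside the
    lesion spots (and not at all when the effect magnitude is 0).
    """
    if label not in ("healthy", "diseased"):
        raise ValueError("label must be 'healthy' or 'diseased'")
    rng = _case_rng(config, case_index)
    H, W = config.image_size
    bands = config.bands
    effect = config.disease_effect if extent is None else replace(
        config.disease_effect, extent=extent)

    masks = _retina_geometry(H, W, rng)
    retina = masks["entire_retina"]

    # per-case tissue spectra = class mean + smooth per-class perturbation
    spectra = {}
    for cls in TISSUE_CLASSES:
        base = tissue_spectrum(cls, bands, config.base_spectrum_params)
        pert = _smooth_perturbation(bands, config.case_variability_sd, rng)
        spectra[cls] = np.clip(base + pert, 1e-3, 1.0)

    refl = np.zeros((H, W, bands.n))
    refl[masks["background"]] = spectra["background"]
    refl[masks["macula"]] = spectra["macula"]
    refl[masks["optic_disk"]] = spectra["optic_disk"]
    refl[masks["vessels"]] = spectra["vessels"]

    # disease: band-limited additive perturbation on lesion spots in the extent
    extent_mask = retina if effect.extent == "whole_retina" else masks[
        {"macula_only": "macula", "disk_only": "optic_disk",
         "vessels_only": "vessels"}[effect.extent]]
    weights, lesions = _lesion_field(extent_mask, effect, rng)
    if label == "diseased":
        delta = effect.profile(bands)
        w3 = weights[:, :, None]
        refl = np.where(w3 > 0, np.clip(refl + w3 * delta, 1e-3, 1.2), refl)

    # acquisition noise (draws taken for every case, label-independent)
    nz = config.noise
    illum = _smooth_field(H, W, nz.illumination_sd,
                          nz.illumination_scale_frac * min(H, W), rng)
    texture = _smooth_field(H, W, nz.texture_sd, nz.texture_scale_px, rng)
    mult = rng.standard_normal((H, W, bands.n))
    add = rng.standard_normal((H, W, bands.n))
    noisy = refl * (illum * texture)[:, :, None]
    if config.noise.multiplicative_sd > 0:
        noisy = noisy * np.exp(config.noise.multiplicative_sd * mult
                               - 0.5 * config.noise.multiplicative_sd ** 2)
    noisy = np.where(retina[:, :, None], noisy, 0.0)

    refs = make_references(config)
    dl = digital_levels_from_reflectance(noisy, refs)
    dl = dl + config.noise.additive_sd * add
    dl = np.clip(dl, 0.0, None)

    cube = SpectralCube(dl, bands, stage="raw_dl")
    roi_masks = {r: ROIMask(r, m) for r, m in masks.items()}
    return SyntheticCase(
        case_id=f"case_{case_index:04d}", label=label, cube=cube, masks=roi_masks,
        reflectance=noisy, lesion_mask=lesions,
        extent=effect.extent if label == "diseased" else None)


def generate_cases(config: SyntheticConfig,
                   extents: list[str] | None = None) -> list[SyntheticCase]:
    """Generate the full in-memory dataset: healthy cases first, then diseased.

    ``extents`` optionally assigns a per-diseased-case spatial extent
    (length ``n_diseased``); by default every diseased case uses the
    configured ``disease_effect.extent``.
    """
    if config.n_healthy + config.n_diseased < 2:
        raise ValueError("need at least 2 cases in total")
    if extents is not None and len(extents) != config.n_diseased:
        raise ValueError("extents must have one entry per diseased case")
    cases = [generate_case(config, "healthy", i) for i in range(config.n_healthy)]
    for j in range(config.n_diseased):
        idx = config.n_healthy + j
        ext = extents[j] if extents is not None else None
        cases.append(generate_case(config, "diseased", idx, extent=ext))
    return cases


def generate_dataset(config: SyntheticConfig, out_dir: str | Path,
                     extents: list[str] | None = None) -> DatasetManifest:
    """Generate a dataset and write cubes, masks, references and a manifest to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    refs = make_references(config)
    write_cube(refs.white, out / "white.tif")
    write_cube(refs.dark, out / "dark.tif")

    entries = []
    for case in generate_cases(config, extents=extents):
        cdir = out / case.case_id
        cdir.mkdir(exist_ok=True)
        write_cube(case.cube, cdir / "cube.tif")
        mask_paths = {}
        for region, roi in case.masks.items():
            write_mask(roi, cdir / f"mask_{region}.png")
            mask_paths[region] = f"{case.case_id}/mask_{region}.png"
        entries.append(CaseEntry(
            case_id=case.case_id, label=case.label,
            cube_path=f"{case.case_id}/cube.tif",
            metadata_path=f"{case.case_id}/cube.json",
            mask_paths=mask_paths, extent=case.extent))

    manifest = DatasetManifest(entries, "white.tif", "dark.tif",
                               [float(config.refl_ref)] * config.bands.n,
                               root=str(out))
    manifest.save(out / "manifest.json")
    return manifest
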