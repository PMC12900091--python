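"""Reading and writing of spectral cubes, ROI masks, manifests and feature tables.

On-disk conventions:

* cubes: multi-page TIFF, one page per band in ascending wavelength order,
  with a JSON sidecar ``{"centers_nm": [...], "bandwidths_nm": [...], "stage": "..."}``;
* ROI masks: single-channel 8-bit PNG, 0 = outside, any nonzero = inside;
* dataset manifests: JSON;
* feature tables: CSV with a header row (``case_id,label,<feature columns...>``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "BandSet",
    "SpectralCube",
    "ROIMask",
    "FeatureTable",
    "CaseEntry",
    "DatasetManifest",
    "REGIONS",
    "STAGES",
    "DEFAULT_CENTERS_NM",
    "RGB_LIKE_CENTERS_NM",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
    "read_feature_table",
    "write_feature_table",
]

#: Peak wavelengths (nm) of the 12 visible/NIR LED bands of the multispectral
#: fundus camera this pipeline targets.
DEFAULT_CENTERS_NM = (416.0, 450.0, 471.0, 494.0, 524.0, 595.0,
                      598.0, 624.0, 660.0, 732.0, 865.0, 955.0)

#: Bands combined into an RGB-like three-channel image (blue, green, red).
RGB_LIKE_CENTERS_NM = (471.0, 595.0, 732.0)

REGIONS = ("entire_retina", "vessels", "optic_disk", "macula", "background")
STAGES = ("raw_dl", "reflectance", "zscored")


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match its declared layout."""


@dataclass(frozen=True)
class BandSet:
    """Spectral band metadata: center wavelengths and per-channel bandwidths, nm."""

    centers: tuple[float, ...]
    bandwidths: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "centers", tuple(float(c) for c in self.centers))
        object.__setattr__(self, "bandwidths", tuple(float(b) for b in self.bandwidths))
        if len(self.centers) < 2:
            raise ValueError("a BandSet needs at least 2 channels")
        if len(self.bandwidths) != len(self.centers):
            raise ValueError("centers and bandwidths must have equal length")
        if any(b <= 0 for b in self.bandwidths):
            raise ValueError("bandwidths must be positive")
        if any(c1 >= c2 for c1, c2 in zip(self.centers, self.centers[1:])):
            raise ValueError("band centers must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.centers)

    @classmethod
    def default_msi(cls, bandwidth_nm: float = 20.0) -> "BandSet":
        """The camera's 12 visible/NIR bands with a nominal LED bandwidth."""
        return cls(DEFAULT_CENTERS_NM, (bandwidth_nm,) * len(DEFAULT_CENTERS_NM))

    def index_of(self, center_nm: float, atol: float = 0.5) -> int:
        for i, c in enumerate(self.centers):
            if abs(c - center_nm) <= atol:
                return i
        raise KeyError(f"no band centered at {center_nm} nm")


@dataclass
class SpectralCube:
    """H×W×n stack of per-band pixel values with band metadata.

    ``stage`` records the physical meaning of the values: raw digital levels
    (``raw_dl``, nonnegative), calibrated reflectance (``reflectance``), or
    band-wise standardized values (``zscored``, may be negative).  ``valid``
    is a per-pixel usability mask carried alongside the data so that outlier
    trimming never has to corrupt spectra with sentinel values.
    """

    pixels: np.ndarray
    bands: BandSet
    stage: str = "raw_dl"
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be an H×W×n array")
        if self.pixels.shape[2] != self.bands.n:
            raise FormatError(
                f"cube has {self.pixels.shape[2]} channels but BandSet has {self.bands.n}"
            )
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if self.stage == "raw_dl" and np.any(self.pixels < 0):
            raise ValueError("raw digital levels must be nonnegative")
        if self.valid is None:
            self.valid = np.ones(self.pixels.shape[:2], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.pixels.shape[:2]:
                raise ValueError("validity mask shape must match H×W")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def copy(self) -> "SpectralCube":
        return SpectralCube(self.pixels.copy(), self.bands, self.stage, self.valid.copy())


@dataclass
class ROIMask:
    """Binary mask for one anatomical region of the fundus."""

    region: str
    mask: np.ndarray

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class FeatureTable:
    """Per-case feature vectors with binary healthy/diseased labels.

    ``y`` uses 1 for diseased (the positive class throughout) and 0 for healthy.
    """

    case_ids: list[str]
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (cases × features)")
        if len(self.case_ids) != self.X.shape[0] or len(self.y) != self.X.shape[0]:
            raise ValueError("case_ids, X and y must align")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names must match X columns")
        if len(set(self.case_ids)) != len(self.case_ids):
            raise ValueError("duplicate case_id in feature table")
        if not np.all(np.isin(self.y, [0, 1])):
            raise ValueError("labels must be binary (0 healthy, 1 diseased)")

    @property
    def n_cases(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: Sequence[int]) -> "FeatureTable":
        idx = list(idx)
        return FeatureTable([self.case_ids[i] for i in idx], self.X[idx],
                            self.y[idx], list(self.feature_names))

    def select_features(self, names: Sequence[str]) -> "FeatureTable":
        cols = [self.feature_names.index(n) for n in names]
        return FeatureTable(list(self.case_ids), self.X[:, cols], self.y, list(names))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", np.where(self.y == 1, "diseased", "healthy"))
        df.insert(0, "case_id", self.case_ids)
        return df


@dataclass
class CaseEntry:
    case_id: str
    label: str  # "healthy" | "diseased"
    cube_path: str
    metadata_path: str
    mask_paths: dict[str, str] = field(default_factory=dict)
    extent: str | None = None  # diseased cases: spatial extent of the disease effect

    def __post_init__(self):
        if self.label not in ("healthy", "diseased"):
            raise ValueError("label must be 'healthy' or 'diseased'")


@dataclass
class DatasetManifest:
    """Index of one dataset: cases plus the shared reference images."""

    cases: list[CaseEntry]
    white_path: str
    dark_path: str
    refl_ref: list[float]
    root: str = "."

    def __post_init__(self):
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate case_id in manifest")

    def resolve(self, rel: str) -> Path:
        return Path(self.root) / rel

    def save(self, path: str | Path) -> None:
        payload = {
            "white_path": self.white_path,
            "dark_path": self.dark_path,
            "refl_ref": list(map(float, self.refl_ref)),
            "cases": [
                {
                    "case_id": c.case_id,
                    "label": c.label,
                    "cube_path": c.cube_path,
                    "metadata_path": c.metadata_path,
                    "mask_paths": c.mask_paths,
                    "extent": c.extent,
                }
                for c in self.cases
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path, check_files: bool = True) -> "DatasetManifest":
        path = Path(path)
        payload = json.loads(path.read_text())
        cases = [CaseEntry(**c) for c in payload["cases"]]
        man = cls(cases, payload["white_path"], payload["dark_path"],
                  payload["refl_ref"], root=str(path.parent))
        if check_files:
            missing = []
            for c in man.cases:
                for p in [c.cube_path, c.metadata_path, *c.mask_paths.values()]:
                    if not man.resolve(p).exists():
                        missing.append(p)
            for p in (man.white_path, man.dark_path):
                if not man.resolve(p).exists():
                    missing.append(p)
            if missing:
                raise FileNotFoundError(f"manifest references missing files: {missing[:5]}")
        return man


# ---------------------------------------------------------------------------
# cubes

def _sidecar_path(path: Path, metadata_path=None) -> Path:
    return Path(metadata_path) if metadata_path is not None else path.with_suffix(".json")


def write_cube(cube: SpectralCube, path: str | Path, metadata_path=None) -> None:
    """Write a cube as a multi-page TIFF (pages in ascending wavelength) + JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(cube.pixels, 2, 0)  # (n, H, W)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "centers_nm": list(cube.bands.centers),
        "bandwidths_nm": list(cube.bands.bandwidths),
        "stage": cube.stage,
    }
    _sidecar_path(path, metadata_path).write_text(json.dumps(meta))


def read_cube(path: str | Path, metadata_path=None) -> SpectralCube:
    """Read a multi-page TIFF cube and its JSON band-metadata sidecar.

    Pages are interpreted as bands in ascending-wavelength order; the page
    count must match the sidecar's channel count.
    """
    path = Path(path)
    meta = json.loads(_sidecar_path(path, metadata_path).read_text())
    centers = meta["centers_nm"]
    if any(a >= b for a, b in zip(centers, centers[1:])):
        raise FormatError("sidecar wavelengths are not strictly increasing")
    bands = BandSet(centers, meta["bandwidths_nm"])
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != bands.n:
        raise FormatError(
            f"cube has {pages.shape[0]} pages but sidecar declares {bands.n} bands"
        )
    pixels = np.moveaxis(pages, 0, 2)
    return SpectralCube(pixels, bands, stage=meta.get("stage", "raw_dl"))


# ---------------------------------------------------------------------------
# masks

def write_mask(mask: ROIMask, path: str | Path) -> None:
    iio.imwrite(Path(path), (mask.mask.astype(np.uint8) * 255))


def read_mask(path: str | Path, region: str) -> ROIMask:
    """Read a single-channel PNG mask; nonzero pixels are inside the region.

    An all-zero mask is accepted but flagged with a warning — downstream
    operations requiring in-scope pixels will reject it at use time.
    """
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:  # tolerate grey saved with redundant channels
        img = img[..., 0]
    roi = ROIMask(region, img != 0)
    if roi.empty:
        warnings.warn(f"mask {path} for region '{region}' has no pixels", stacklevel=2)
    return roi


# ---------------------------------------------------------------------------
# feature tables

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Serialize a feature table to CSV (lossless round trip via full precision)."""
    if table.n_cases < 1:
        raise ValueError("feature table must contain at least one case")
    if not np.all(np.isfinite(table.X)):
        raise ValueError("feature table contains NaN/inf features")
    df = table.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, dtype={"case_id": str}, float_precision="round_trip")
    feature_names = [c for c in df.columns if c not in ("case_id", "label")]
    y = (df["label"] == "diseased").astype(int).to_numpy()
    return FeatureTable(df["case_id"].tolist(), df[feature_names].to_numpy(float),
                        y, feature_names)
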