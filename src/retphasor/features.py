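"""Per-case feature extraction: raw cube → calibrated → normalized → features.

The pipeline order is fixed: calibrate, Z-score each band over the entire
retina (global statistics preserve inter-region contrast and keep σ stable),
optionally restrict to the RGB-like band subset, trim percentile outliers
over the analysis scope (the ROI being summarized), then summarize the
scoped pixels into phasor (g_avg, s_avg[, STD]) or per-band average features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import ReferenceSet, compute_reflectance
from .io import FeatureTable, SpectralCube, ROIMask
from .phasor import band_average_features, phasor_transform, summarize_phasor
from .preprocess import TrimPolicy, extract_rgb_like, trim_percentiles, zscore_bands
from .synth import SyntheticCase

__all__ = ["FeatureSpec", "REPRESENTATIONS", "case_features", "build_feature_table",
           "build_feature_tables"]

REPRESENTATIONS = ("phasor_msi", "phasor_rgb", "avg_msi", "avg_rgb")


@dataclass(frozen=True)
class FeatureSpec:
    """What to extract from each case."""

    representation: str = "phasor_msi"
    harmonic: int = 1
    normalization: str = "zscore"  # "zscore" | "none"
    trim: TrimPolicy = TrimPolicy()
    roi: str = "entire_retina"
    with_std: bool = False
    phase_axis: str = "index"
    # denominator guard for the phasor ratio; None picks a stage-appropriate
    # default: 1e-6 for nonnegative (reflectance) input, 0.5 for z-scored
    # input, where a per-pixel band sum within half a z-unit of zero carries
    # no interpretable spectral shape and would yield an unbounded phasor
    phasor_eps: float | None = None

    def __post_init__(self):
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"representation must be one of {REPRESENTATIONS}")
        if self.normalization not in ("zscore", "none"):
            raise ValueError("normalization must be 'zscore' or 'none'")

    @property
    def feature_names(self) -> tuple[str, ...]:
        if self.representation.startswith("phasor"):
            names = ("g_avg", "s_avg")
            return names + ("phasor_std",) if self.with_std else names
        return ()  # band names depend on the cube; filled at build time


def _prepare_cube(cube_raw: SpectralCube, refs: ReferenceSet,
                  entire_retina: np.ndarray, spec: FeatureSpec) -> SpectralCube:
    refl = compute_reflectance(cube_raw, refs)
    work = zscore_bands(refl, entire_retina) if spec.normalization == "zscore" else refl
    if spec.representation.endswith("rgb"):
        work = extract_rgb_like(work)
    return work


def case_features(cube_raw: SpectralCube, masks: dict[str, ROIMask],
                  refs: ReferenceSet, spec: FeatureSpec) -> tuple[np.ndarray, list[str]]:
    """Extract one case's feature vector according to ``spec``.

    Returns the vector and its feature names.  Percentile trimming (applied
    only to z-scored data, where distribution tails dominate averages) is
    computed over the ROI scope so that globally extreme but anatomically
    coherent regions (e.g. the bright optic disk) remain analyzable.
    """
    entire = masks["entire_retina"].mask
    roi_mask = masks[spec.roi].mask
    work = _prepare_cube(cube_raw, refs, entire, spec)
    if spec.trim.enabled and work.stage == "zscored":
        work = trim_percentiles(work, spec.trim, roi_mask & entire)

    scope = roi_mask & entire
    if spec.representation.startswith("phasor"):
        eps = spec.phasor_eps
        if eps is None:
            eps = 0.5 if work.stage == "zscored" else 1e-6
        field = phasor_transform(work, spec.harmonic, eps=eps,
                                 phase_axis=spec.phase_axis)
        summ = summarize_phasor(field, scope, with_std=spec.with_std)
        if spec.with_std:
            return (np.array([summ.g_avg, summ.s_avg, summ.std]),
                    ["g_avg", "s_avg", "phasor_std"])
        return np.array([summ.g_avg, summ.s_avg]), ["g_avg", "s_avg"]
    vec = band_average_features(work, scope)
    names = [f"avg_{c:.0f}nm" for c in work.bands.centers]
    return vec, names


def build_feature_table(cases: list[SyntheticCase], refs: ReferenceSet,
                        spec: FeatureSpec) -> FeatureTable:
    """One row of features per case, labels from the case metadata."""
    if not cases:
        raise ValueError("no cases")
    rows, names = [], None
    for case in cases:
        vec, names = case_features(case.cube, case.masks, refs, spec)
        rows.append(vec)
    X = np.vstack(rows)
    y = np.array([1 if c.label == "diseased" else 0 for c in cases])
    return FeatureTable([c.case_id for c in cases], X, y, list(names))


def build_feature_tables(cases: list[SyntheticCase], refs: ReferenceSet,
                         specs: dict[str, FeatureSpec]) -> dict[str, FeatureTable]:
    return {name: build_feature_table(cases, refs, spec) for name, spec in specs.items()}
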