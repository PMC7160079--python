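"""Low-contrast visibility scoring and dose matching.

A human reader's count of visible low-contrast discs is replaced here by an
explicit, deterministic rule: per object the contrast-to-noise ratio

    CNR = (mean inside a disc ROI at 0.8 x object diameter
           - mean of a surrounding background annulus) / SD of the annulus

is combined with object size in a Rose-style criterion

    visible  <=>  CNR * sqrt(object area in pixels) >= rule_threshold,

with ``rule_threshold`` defaulting to 4 (the classical Rose constant) and
fully configurable.  No claim is made that the rule reproduces a particular
human reader; it provides a reproducible, monotone visibility score.

Dose matching interpolates, on a (dose, score) series, the dose at which the
score first reaches a reference system's score, and reports the percent dose
increase relative to a base dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .volume import CircularROI, CTIQError, ImageVolume, ROIError, roi_mask

__all__ = [
    "ObjectCNR",
    "VisibilityResult",
    "DoseMatchResult",
    "LowContrastReader",
    "measure_object_cnr",
    "count_visible",
    "visibility_score",
    "dose_match",
]


@dataclass
class ObjectCNR:
    """Per-object readout: geometry, measured contrast and CNR."""

    diameter: float
    contrast_pct: float
    cnr: float
    area_px: float
    contrast_hu: float
    visible: bool = False


@dataclass
class VisibilityResult:
    """Visibility flags per object and counts per contrast level."""

    per_object: list[ObjectCNR]
    rule_threshold: float
    counts: dict[float, int] = field(init=False)

    def __post_init__(self) -> None:
        counts: dict[float, int] = {}
        for o in self.per_object:
            counts.setdefault(o.contrast_pct, 0)
            if o.visible:
                counts[o.contrast_pct] += 1
        self.counts = counts


@dataclass
class DoseMatchResult:
    """Dose needed to reach a reference visibility score."""

    doses: list[float]
    scores: list[float]
    reference_score: float
    base_dose: float
    matched_dose: Optional[float]
    percent_increase: Optional[float]
    reached: bool


class LowContrastReader(BaseEstimator):
    """Deterministic CNR/Rose-criterion reader for a low-contrast module.

    Parameters
    ----------
    rule_threshold : float
        Rose-criterion constant; an object is visible when
        ``CNR * sqrt(area_px) >= rule_threshold``.
    roi_fraction : float
        Diameter of the measurement disc ROI as a fraction of the object
        diameter (default 0.8, avoiding the blurred rim).
    annulus_inner, annulus_outer : float
        Background annulus radii as multiples of the object *radius*
        (defaults 1.5 and 2.1).
    slab_thickness : float, optional
        z extent (mm) averaged before reading, emulating a thick-slice
        reconstruction; None averages nothing (single/middle slice).

    Attributes (after ``fit``): ``per_object_``, ``result_``, ``counts_``,
    ``score_``.
    """

    def __init__(self, rule_threshold: float = 4.0, roi_fraction: float = 0.8,
                 annulus_inner: float = 1.5, annulus_outer: float = 2.1,
                 slab_thickness: Optional[float] = None):
        self.rule_threshold = rule_threshold
        self.roi_fraction = roi_fraction
        self.annulus_inner = annulus_inner
        self.annulus_outer = annulus_outer
        self.slab_thickness = slab_thickness

    def _slab(self, vol: ImageVolume) -> np.ndarray:
        if self.slab_thickness is None:
            return vol.voxels[vol.n_slices // 2]
        half = self.slab_thickness / 2.0
        centre = (vol.n_slices - 1) / 2.0
        k0 = max(0, int(np.ceil(centre - half / vol.dz)))
        k1 = min(vol.n_slices - 1, int(np.floor(centre + half / vol.dz)))
        return vol.voxels[k0:k1 + 1].mean(axis=0)

    def fit(self, vol: ImageVolume, layout: Sequence[dict]) -> "LowContrastReader":
        img = self._slab(vol)
        flat = ImageVolume(img[None], vol.dx, vol.dy, vol.dz, meta=vol.meta)
        objects: list[ObjectCNR] = []
        for i, obj in enumerate(layout):
            d = obj["diameter"]
            r_out = self.annulus_outer * d / 2.0
            for j, other in enumerate(layout):
                if j == i:
                    continue
                dist = math.hypot(obj["x"] - other["x"], obj["y"] - other["y"])
                if dist < r_out + other["diameter"] / 2.0:
                    raise ROIError(
                        f"background annulus of object {i} overlaps object {j}")
            inner = roi_mask(flat, CircularROI(obj["x"], obj["y"],
                                               self.roi_fraction * d))
            outer = roi_mask(flat, CircularROI(obj["x"], obj["y"], 2 * r_out))
            ann = outer & ~roi_mask(flat, CircularROI(obj["x"], obj["y"],
                                                      self.annulus_inner * d))
            if inner.sum() < 1 or ann.sum() < 8:
                raise ROIError(f"object {i} too small for CNR readout at this "
                               f"pixel pitch")
            mean_in = float(img[inner].mean())
            mean_bg = float(img[ann].mean())
            sd_bg = float(img[ann].std(ddof=1))
            contrast = mean_in - mean_bg
            cnr = math.inf if sd_bg == 0 else contrast / sd_bg
            area_px = math.pi * (d / 2.0) ** 2 / (vol.dx * vol.dy)
            objects.append(ObjectCNR(d, obj.get("contrast_pct", float("nan")),
                                     cnr, area_px, contrast))
        self.per_object_ = objects
        self.result_ = count_visible(objects, self.rule_threshold)
        self.counts_ = self.result_.counts
        self.score_ = visibility_score(self.result_)
        return self


def measure_object_cnr(vol: ImageVolume, layout: Sequence[dict],
                       slab_thickness: Optional[float] = None,
                       **opts) -> list[ObjectCNR]:
    """Per-object CNR readout; ``opts`` are :class:`LowContrastReader` params."""
    reader = LowContrastReader(slab_thickness=slab_thickness, **opts)
    return reader.fit(vol, layout).per_object_


def count_visible(per_object: Sequence[ObjectCNR],
                  rule_threshold: float = 4.0) -> VisibilityResult:
    """Apply the Rose-style rule and count visible objects per contrast level."""
    flagged = []
    for o in per_object:
        visible = o.cnr * math.sqrt(o.area_px) >= rule_threshold
        flagged.append(ObjectCNR(o.diameter, o.contrast_pct, o.cnr, o.area_px,
                                 o.contrast_hu, visible=visible))
    return VisibilityResult(flagged, rule_threshold)


def visibility_score(result: VisibilityResult) -> int:
    """Scalar visibility score: total visible objects across contrast levels."""
    return int(sum(result.counts.values()))


def dose_match(doses: Sequence[float], scores: Sequence[float],
               reference_score: float, base_dose: float) -> DoseMatchResult:
    """Dose at which the visibility score reaches a reference score.

    The matched dose is the smallest dose whose score is at or above the
    reference, refined by linear interpolation on the score axis between the
    bracketing doses.  ``percent_increase`` is relative to ``base_dose``.
    When no dose reaches the reference the result carries ``reached=False``
    and undefined (None) matched dose / percent increase.
    """
    doses = [float(d) for d in doses]
    scores = [float(s) for s in scores]
    if len(doses) != len(scores):
        raise CTIQError("doses and scores must have equal length")
    if not doses:
        raise CTIQError("empty dose series")
    if any(b <= a for a, b in zip(doses, doses[1:])):
        raise CTIQError("doses must be strictly ascending")
    if base_dose <= 0:
        raise CTIQError("base_dose must be > 0")
    reach = [i for i, s in enumerate(scores) if s >= reference_score]
    if not reach:
        return DoseMatchResult(doses, scores, reference_score, base_dose,
                               None, None, False)
    i = reach[0]
    if i == 0:
        matched = doses[0]
    else:
        s0, s1 = scores[i - 1], scores[i]
        matched = doses[i - 1] + (reference_score - s0) * (
            doses[i] - doses[i - 1]) / (s1 - s0)
    return DoseMatchResult(doses, scores, reference_score, base_dose,
                           matched, 100.0 * (matched / base_dose - 1.0), True)
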