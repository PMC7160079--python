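"""CT-number uniformity (5-ROI test) and accuracy against material HU ranges.

Uniformity follows the accreditation-style water-phantom test: the mean HU of
four peripheral 32-mm ROIs (12, 3, 6 and 9 o'clock) is compared with a central
ROI; all differences must stay within a limit (default 5 HU).

Accuracy compares measured insert HU values with closed expected intervals per
material; :data:`ACR_RANGES` carries the standard air/LDPE/water/acrylic/
Teflon intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .volume import CircularROI, CTIQError, ImageVolume, ROIError, extract_roi_pixels

__all__ = [
    "MaterialRange",
    "ACR_RANGES",
    "UniformityReport",
    "UniformityTest",
    "uniformity_test",
    "ct_number_check",
    "measure_insert_hu",
]


@dataclass
class MaterialRange:
    """Closed expected HU interval [lo, hi] for a material."""

    material: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise CTIQError(f"range for {self.material}: lo {self.lo} > hi {self.hi}")

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


#: Accreditation-style expected CT-number ranges (HU, inclusive).
ACR_RANGES: dict[str, MaterialRange] = {
    "air": MaterialRange("air", -1005, -970),
    "ldpe": MaterialRange("ldpe", -107, -84),
    "water": MaterialRange("water", -7, 7),
    "acrylic": MaterialRange("acrylic", 110, 135),
    "teflon": MaterialRange("teflon", 850, 970),
}

_CLOCK = {"12": (0.0, 1.0), "3": (1.0, 0.0), "6": (0.0, -1.0), "9": (-1.0, 0.0)}


@dataclass
class UniformityReport:
    """Result of the 5-ROI uniformity test."""

    centre_mean: float
    peripheral_means: dict[str, float]
    diffs: dict[str, float]
    limit: float
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passed = all(abs(d) <= self.limit for d in self.diffs.values())


class UniformityTest(BaseEstimator):
    """Water-phantom uniformity estimator.

    Peripheral ROI centres sit on the vertical/horizontal axes at radius
    ``phantom_diameter/2 - edge_margin - roi_diameter/2`` so each ROI clears
    the phantom edge by ``edge_margin`` (default 10 mm, configurable: the QA
    protocols leave the exact margin to the operator).

    Attributes (after ``fit``): ``report_``, ``centre_mean_``,
    ``peripheral_means_``, ``diffs_``, ``passed_``.
    """

    def __init__(self, phantom_diameter: float = 320.0, roi_diameter: float = 32.0,
                 limit: float = 5.0, edge_margin: float = 10.0):
        self.phantom_diameter = phantom_diameter
        self.roi_diameter = roi_diameter
        self.limit = limit
        self.edge_margin = edge_margin

    def fit(self, vol: ImageVolume, slice_index: Optional[int] = None
            ) -> "UniformityTest":
        k = vol.n_slices // 2 if slice_index is None else slice_index
        radius = (self.phantom_diameter / 2.0 - self.edge_margin
                  - self.roi_diameter / 2.0)
        if radius <= 0:
            raise ROIError("phantom too small for the requested ROI layout")

        def _mean(cx: float, cy: float) -> float:
            roi = CircularROI(cx, cy, self.roi_diameter, slice_index=k)
            return float(extract_roi_pixels(vol, roi).mean())

        centre = _mean(0.0, 0.0)
        periph = {name: _mean(radius * ux, radius * uy)
                  for name, (ux, uy) in _CLOCK.items()}
        diffs = {name: m - centre for name, m in periph.items()}
        self.report_ = UniformityReport(centre, periph, diffs, self.limit)
        self.centre_mean_ = centre
        self.peripheral_means_ = periph
        self.diffs_ = diffs
        self.passed_ = self.report_.passed
        return self


def uniformity_test(vol: ImageVolume, phantom_diameter: float = 320.0,
                    roi_diameter: float = 32.0, limit: float = 5.0,
                    edge_margin: float = 10.0,
                    slice_index: Optional[int] = None) -> UniformityReport:
    """Run the 5-ROI uniformity test on the central (or given) slice."""
    est = UniformityTest(phantom_diameter, roi_diameter, limit, edge_margin)
    return est.fit(vol, slice_index=slice_index).report_


def ct_number_check(measured: dict[str, float],
                    ranges: dict[str, MaterialRange] | list[MaterialRange] | None = None
                    ) -> dict[str, dict]:
    """Check measured material HU values against closed expected intervals.

    Returns ``{material: {"value", "lo", "hi", "passed"}}``.  Bounds are
    inclusive; a material without a range is an error.
    """
    if ranges is None:
        ranges = ACR_RANGES
    if isinstance(ranges, list):
        ranges = {r.material: r for r in ranges}
    out = {}
    for material, value in measured.items():
        if material not in ranges:
            raise CTIQError(f"no expected range for material {material!r}")
        r = ranges[material]
        out[material] = {"value": float(value), "lo": r.lo, "hi": r.hi,
                         "passed": r.contains(value)}
    return out


def measure_insert_hu(vol: ImageVolume, insert_layout: dict[str, dict],
                      roi_diameter: float = 10.0,
                      slab_thickness: Optional[float] = None) -> dict[str, float]:
    """Mean HU per insert over a circular ROI, averaged across a z slab.

    ``insert_layout`` maps material -> {"x", "y"[, "radius"]} (mm).  The slab
    spans ``slab_thickness`` mm centred on the stack (all slices when None),
    emulating a thick-slice reconstruction by averaging thin slices.  The ROI
    must not reach into a neighbouring insert.
    """
    if slab_thickness is None:
        sl = (0, vol.n_slices - 1)
    else:
        half = slab_thickness / 2.0
        centre = (vol.n_slices - 1) / 2.0
        k0 = max(0, int(np.ceil(centre - half / vol.dz)))
        k1 = min(vol.n_slices - 1, int(np.floor(centre + half / vol.dz)))
        sl = (k0, k1)
    r_roi = roi_diameter / 2.0
    names = list(insert_layout)
    for i, a in enumerate(names):
        pa = insert_layout[a]
        for b in names[i + 1:]:
            pb = insert_layout[b]
            dist = float(np.hypot(pa["x"] - pb["x"], pa["y"] - pb["y"]))
            if dist < r_roi + pb.get("radius", 0.0) or dist < r_roi + pa.get("radius", 0.0):
                raise ROIError(f"ROI at {a!r} would overlap insert {b!r}")
    out = {}
    for material, pos in insert_layout.items():
        roi = CircularROI(pos["x"], pos["y"], roi_diameter, slice_range=sl)
        out[material] = float(extract_roi_pixels(vol, roi).mean())
    return out
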