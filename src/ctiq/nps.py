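"""Noise characterisation: 2-D / radial 1-D noise power spectra and noise SD.

The image NPS is estimated from uniform (water-phantom) volumes by averaging
windowless periodograms of square ROIs,

    NPS(fx, fy) = (dx dy) / (Nx Ny) * < |DFT2(ROI - trend)|^2 >,

in HU^2 mm^2.  Two variants are provided:

* unsubtracted — each ROI is detrended with a fitted 2-D second-order
  polynomial (removes bowl/cupping artifacts of water phantoms) before the
  periodogram;
* subtracted — same-position slices from two repeated volumes are differenced
  and the accumulated power divided by 2, cancelling any structured
  background.  On stationary noise both variants agree.

The radial average collapses the 2-D spectrum into rings one DFT frequency
step wide; its argmax is the peak frequency, the conventional one-number
summary of noise texture.  Noise magnitude is the sample SD of a detrended
ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .volume import CircularROI, CTIQError, ImageVolume, roi_mask

__all__ = [
    "NPSResult",
    "NoisePowerSpectrum",
    "nps_2d",
    "radial_average",
    "peak_frequency",
    "noise_sd",
]


@dataclass
class NPSResult:
    """2-D NPS (HU^2 mm^2) with frequency axes, radial 1-D NPS and summaries.

    ``nps2d`` is fftshifted so frequencies ascend along both axes (``fx``,
    ``fy`` in lp/mm).  ``nps1d_freq``/``nps1d_power`` is the radial average,
    ``peak_frequency`` its argmax, ``noise_sd`` the RMS detrended pixel SD
    over the ROIs, ``n_rois`` the number of averaged periodograms.
    """

    nps2d: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    nps1d_freq: np.ndarray
    nps1d_power: np.ndarray
    peak_frequency: float
    noise_sd: float
    n_rois: int
    mode: str


def _poly2_design(ny: int, nx: int, order: int) -> np.ndarray:
    y, x = np.mgrid[0:ny, 0:nx]
    x = (x - x.mean()) / max(nx / 2.0, 1.0)
    y = (y - y.mean()) / max(ny / 2.0, 1.0)
    cols = [np.ones(x.size)]
    for total in range(1, order + 1):
        for p in range(total + 1):
            cols.append((x ** (total - p) * y ** p).ravel())
    return np.column_stack(cols)


def _detrend(roi: np.ndarray, order: int) -> np.ndarray:
    """Remove a fitted 2-D polynomial (least squares) of the given order."""
    if order == 0:
        return roi - roi.mean()
    A = _poly2_design(roi.shape[0], roi.shape[1], order)
    coef, *_ = np.linalg.lstsq(A, roi.ravel(), rcond=None)
    return roi - (A @ coef).reshape(roi.shape)


def radial_average(nps2d: np.ndarray, fx: np.ndarray, fy: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Radially average a 2-D NPS into rings one DFT frequency step wide.

    The zero-frequency sample is excluded (it holds no noise power after
    detrending and would otherwise bias the first ring).  Returns
    (frequencies, mean power per ring); empty rings are dropped.
    """
    fx = np.asarray(fx, dtype=float)
    fy = np.asarray(fy, dtype=float)
    df = float(np.min(np.abs(np.diff(np.sort(fx)))))
    fr = np.hypot(fy[:, None], fx[None, :])
    idx = np.round(fr / df).astype(int)
    vals = np.asarray(nps2d, dtype=float)
    dc = fr == 0
    sums = np.bincount(idx[~dc].ravel(), weights=vals[~dc].ravel())
    counts = np.bincount(idx[~dc].ravel())
    keep = counts > 0
    freqs = np.arange(len(sums))[keep] * df
    return freqs, sums[keep] / counts[keep]


def peak_frequency(freqs: np.ndarray, power: np.ndarray) -> float:
    """Frequency of the maximum-power bin; ties resolve to the lowest frequency."""
    power = np.asarray(power, dtype=float)
    if power.size == 0 or np.all(power == 0):
        raise CTIQError("cannot locate a peak in an empty/all-zero spectrum")
    return float(np.asarray(freqs, dtype=float)[int(np.argmax(power))])


class NoisePowerSpectrum(BaseEstimator):
    """NPS estimator over a grid of square ROIs in uniform volumes.

    Parameters
    ----------
    roi_size : int
        Side of the square ROIs, pixels (default 128).
    overlap : float
        Fractional ROI overlap of the grid (default 0.5 = half overlap).
    detrend_order : int
        Order of the per-ROI 2-D polynomial trend removed before the
        periodogram (default 2; 0 means mean subtraction only).
    mode : 'unsubtracted' | 'subtracted'
        Subtracted mode needs at least two volumes and differences
        same-position slices from consecutive volume pairs.
    slice_gap : int
        Minimum slice separation within one volume between slices entering
        the average (default 15, guarding against longitudinal noise
        correlation; set 0 for slices known to be independent).
    region : (row0, row1, col0, col1), optional
        Pixel bounding box of the uniform region holding the ROI grid;
        default is the full image.

    Attributes (after ``fit``): ``result_`` (:class:`NPSResult`) plus
    ``nps2d_``, ``nps1d_freq_``, ``nps1d_power_``, ``peak_frequency_``,
    ``noise_sd_``, ``n_rois_``.
    """

    def __init__(self, roi_size: int = 128, overlap: float = 0.5,
                 detrend_order: int = 2, mode: str = "unsubtracted",
                 slice_gap: int = 15,
                 region: Optional[tuple[int, int, int, int]] = None):
        self.roi_size = roi_size
        self.overlap = overlap
        self.detrend_order = detrend_order
        self.mode = mode
        self.slice_gap = slice_gap
        self.region = region

    def _roi_origins(self, shape: tuple[int, int]) -> list[tuple[int, int]]:
        r0, r1, c0, c1 = self.region if self.region is not None else (
            0, shape[0], 0, shape[1])
        step = max(1, int(round(self.roi_size * (1.0 - self.overlap))))
        rows = list(range(r0, r1 - self.roi_size + 1, step))
        cols = list(range(c0, c1 - self.roi_size + 1, step))
        return [(r, c) for r in rows for c in cols]

    def _used_slices(self, n: int) -> list[int]:
        return list(range(0, n, self.slice_gap + 1))

    def fit(self, volumes: Sequence[ImageVolume] | ImageVolume
            ) -> "NoisePowerSpectrum":
        if isinstance(volumes, ImageVolume):
            volumes = [volumes]
        volumes = list(volumes)
        if not volumes:
            raise CTIQError("no volumes given")
        if self.mode not in ("unsubtracted", "subtracted"):
            raise CTIQError(f"unknown NPS mode {self.mode!r}")
        if self.mode == "subtracted" and len(volumes) < 2:
            raise CTIQError("subtracted NPS needs at least two repeated volumes")
        v0 = volumes[0]
        dx, dy = v0.dx, v0.dy
        origins = self._roi_origins(v0.voxels.shape[1:])
        if not origins:
            raise CTIQError("ROI grid is empty; image smaller than roi_size")

        n = self.roi_size
        acc = np.zeros((n, n))
        var_acc = 0.0
        count = 0

        def _accumulate(field: np.ndarray, scale: float) -> None:
            nonlocal var_acc, count
            for (r, c) in origins:
                roi = _detrend(field[r:r + n, c:c + n], self.detrend_order)
                acc[:] += scale * np.abs(np.fft.fft2(roi)) ** 2
                var_acc += scale * roi.var(ddof=1)
                count += 1

        if self.mode == "unsubtracted":
            for vol in volumes:
                for k in self._used_slices(vol.n_slices):
                    _accumulate(vol.voxels[k], 1.0)
        else:
            for a, b in zip(volumes[::2], volumes[1::2]):
                n_sl = min(a.n_slices, b.n_slices)
                for k in self._used_slices(n_sl):
                    _accumulate(a.voxels[k] - b.voxels[k], 0.5)

        nps2d = (dx * dy) / (n * n) * acc / count
        fx = np.fft.fftfreq(n, d=dx)
        fy = np.fft.fftfreq(n, d=dy)
        f1, p1 = radial_average(nps2d, fx, fy)
        self.nps2d_ = np.fft.fftshift(nps2d)
        self.fx_ = np.fft.fftshift(fx)
        self.fy_ = np.fft.fftshift(fy)
        self.nps1d_freq_ = f1
        self.nps1d_power_ = p1
        self.peak_frequency_ = peak_frequency(f1, p1)
        self.noise_sd_ = float(np.sqrt(var_acc / count))
        self.n_rois_ = count
        self.result_ = NPSResult(self.nps2d_, self.fx_, self.fy_, f1, p1,
                                 self.peak_frequency_, self.noise_sd_,
                                 count, self.mode)
        return self


def nps_2d(volumes: Sequence[ImageVolume] | ImageVolume,
           roi_spec: Optional[dict] = None, **opts) -> NPSResult:
    """NPS estimation; ``roi_spec`` maps to ``roi_size``/``overlap``/``region``."""
    if roi_spec:
        opts = {**roi_spec, **opts}
    return NoisePowerSpectrum(**opts).fit(volumes).result_


def noise_sd(vol: ImageVolume, roi: CircularROI, detrend_order: int = 2,
             slice_index: Optional[int] = None) -> float:
    """Sample SD (n-1 denominator) of ROI pixels after polynomial detrending.

    Uses the same trend model as the unsubtracted NPS.  For very small ROIs
    (fewer than 10 pixels per fitted coefficient) only the mean is removed,
    so the statistic stays a plain sample SD rather than a perfect-fit zero.
    """
    mask = roi_mask(vol, roi)
    k = (roi.slice_index if roi.slice_index is not None
         else (slice_index if slice_index is not None else 0))
    vals = vol.voxels[k][mask]
    if vals.size < 2:
        raise CTIQError("noise SD needs at least 2 pixels in the ROI")
    n_terms = (detrend_order + 1) * (detrend_order + 2) // 2
    if detrend_order > 0 and vals.size >= 10 * n_terms:
        yy, xx = np.nonzero(mask)
        x = (xx - xx.mean()) / max(np.ptp(xx) / 2.0, 1.0)
        y = (yy - yy.mean()) / max(np.ptp(yy) / 2.0, 1.0)
        cols = [np.ones(vals.size)]
        for total in range(1, detrend_order + 1):
            for p in range(total + 1):
                cols.append(x ** (total - p) * y ** p)
        A = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(A, vals, rcond=None)
        vals = vals - A @ coef
    else:
        vals = vals - vals.mean()
    return float(np.sqrt(np.sum(vals ** 2) / (vals.size - 1)))
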