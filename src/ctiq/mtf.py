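"""In-plane spatial resolution: wire (point) and circular-edge MTF estimators.

Two standard routes to the modulation transfer function are provided:

* :class:`WireMTF` — point method.  A thin high-contrast wire imaged axially is
  a sampled point spread function; the 2-D DFT magnitude of the background-
  subtracted, zero-padded PSF crop, radially averaged, is the MTF.  Suited to
  linear (FBP) reconstructions; a finite-wire aperture correction divides out
  the wire's own jinc MTF.

* :class:`CircularEdgeMTF` — circular-edge method.  The edge of a large
  high-contrast rod yields an oversampled edge spread function when pixel
  values are binned by their radial distance to the fitted centre; its
  derivative (LSF), Hann-windowed, Fourier-transforms to the MTF.  Usable with
  non-linear (iterative) reconstructions that suppress thin wires.

Both return an :class:`MTFCurve` normalised to 1 at zero frequency and
truncated at the pixel Nyquist frequency.  Percent-MTF summary frequencies
(f90, f50, f10, f2 in lp/mm) are the conventional resolution figures of merit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, special
from sklearn.base import BaseEstimator

from .volume import CTIQError, ImageVolume

__all__ = [
    "MTFCurve",
    "WireMTF",
    "CircularEdgeMTF",
    "wire_aperture_mtf",
    "mtf_from_wire",
    "mtf_from_circular_edge",
    "mtf_percent_frequency",
    "mtf_summary",
    "mtf_vs_position",
]


@dataclass
class MTFCurve:
    """Modulation vs spatial frequency (lp/mm), normalised to 1 at f = 0."""

    frequencies: np.ndarray
    modulation: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.modulation = np.asarray(self.modulation, dtype=float)
        if self.frequencies.shape != self.modulation.shape:
            raise CTIQError("frequencies and modulation must have equal length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise CTIQError("frequencies must be strictly increasing")
        if abs(self.frequencies[0]) > 1e-12:
            raise CTIQError("curve must start at zero frequency")
        if abs(self.modulation[0] - 1.0) > 1e-9:
            raise CTIQError("modulation must be normalised to 1 at f = 0")

    def percent_frequency(self, percent: float) -> float:
        return mtf_percent_frequency(self, percent)


def mtf_percent_frequency(curve: MTFCurve, percent: float) -> float:
    """Lowest frequency at which the MTF first falls to ``percent``/100.

    The first downward crossing is used (noisy curves may be non-monotone);
    the crossing is located by linear interpolation between the bracketing
    samples.  Raises if the curve never reaches the threshold before Nyquist.
    """
    if not 0 < percent < 100:
        raise CTIQError(f"percent must be in (0, 100), got {percent}")
    level = percent / 100.0
    m, f = curve.modulation, curve.frequencies
    below = np.nonzero(m <= level)[0]
    if below.size == 0:
        raise CTIQError(f"threshold not reached: MTF never falls to {percent}%")
    i = below[0]
    if i == 0:
        return float(f[0])
    f0, f1, m0, m1 = f[i - 1], f[i], m[i - 1], m[i]
    if m0 == m1:
        return float(f1)
    return float(f0 + (m0 - level) * (f1 - f0) / (m0 - m1))


def mtf_summary(curve: MTFCurve,
                percents: tuple[float, ...] = (90, 50, 10, 2)) -> dict[str, Optional[float]]:
    """{'f90': ..., 'f50': ...} lookups; None where the threshold is not reached."""
    out: dict[str, Optional[float]] = {}
    for p in percents:
        key = f"f{p:g}"
        try:
            out[key] = mtf_percent_frequency(curve, p)
        except CTIQError:
            out[key] = None
    return out


def wire_aperture_mtf(f: np.ndarray, diameter: float) -> np.ndarray:
    """MTF of a uniform disc aperture of the given diameter: |2 J1(pi f d)/(pi f d)|."""
    x = math.pi * np.asarray(f, dtype=float) * diameter
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = np.abs(2.0 * special.j1(x[nz]) / x[nz])
    return out


def _radial_average(power: np.ndarray, fx: np.ndarray, fy: np.ndarray,
                    df: float) -> tuple[np.ndarray, np.ndarray]:
    """Bin-centre radial average: sample at |f| goes to bin round(|f|/df).

    Empty bins are dropped.  Returns (frequencies, mean values).
    """
    fr = np.hypot(fy[:, None], fx[None, :]).ravel()
    idx = np.round(fr / df).astype(int)
    vals = power.ravel()
    sums = np.bincount(idx, weights=vals)
    counts = np.bincount(idx)
    keep = counts > 0
    freqs = np.arange(len(sums))[keep] * df
    return freqs, sums[keep] / counts[keep]


class WireMTF(BaseEstimator):
    """Point-method MTF estimator from a thin-wire image.

    Parameters
    ----------
    roi_size : int
        Side of the square crop centred on the wire, pixels.
    pad : int
        Zero-padded DFT size; the radial bin width is 1/(pad * pixel pitch).
    annulus_inner, annulus_outer : float
        Radii (pixels) of the background-estimation annulus around the wire.
    correct_wire : bool
        Divide out the finite-wire aperture MTF (about 5% at 4 lp/mm for a
        50-um wire, so material at super-high-resolution frequencies).
    wire_diameter : float
        Physical wire diameter, mm, for the aperture correction.
    min_peak_snr : float
        Detection threshold: the wire peak must exceed the background by this
        many robust standard deviations.

    Attributes (after ``fit``)
    --------------------------
    curve_ : MTFCurve
    frequencies_, modulation_ : ndarray
    centroid_px_ : (row, col) wire position in the full image
    summary_ : dict with f90/f50/f10/f2 (None where not reached)
    """

    def __init__(self, roi_size: int = 32, pad: int = 256,
                 annulus_inner: float = 8.0, annulus_outer: float = 12.0,
                 correct_wire: bool = True, wire_diameter: float = 0.05,
                 min_peak_snr: float = 5.0):
        self.roi_size = roi_size
        self.pad = pad
        self.annulus_inner = annulus_inner
        self.annulus_outer = annulus_outer
        self.correct_wire = correct_wire
        self.wire_diameter = wire_diameter
        self.min_peak_snr = min_peak_snr

    def fit(self, vol: ImageVolume, slice_index: int = 0,
            search_box: Optional[tuple[int, int, int, int]] = None) -> "WireMTF":
        if abs(vol.dx - vol.dy) > 1e-9:
            raise CTIQError("wire MTF requires square pixels (dx == dy)")
        img = vol.voxels[slice_index]
        r0 = c0 = 0
        if search_box is not None:
            r0, r1, c0, c1 = search_box
            img = img[r0:r1, c0:c1]
        med = float(np.median(img))
        mad = float(np.median(np.abs(img - med)))
        robust_sd = 1.4826 * mad if mad > 0 else float(img.std())
        peak = float(img.max())
        if robust_sd > 0 and (peak - med) < self.min_peak_snr * robust_sd:
            raise CTIQError("no wire found: peak below 5 SD above background")
        excess = np.clip(img - med, 0, None)
        excess[excess < 0.05 * (peak - med)] = 0.0
        rr, cc = np.indices(img.shape)
        tot = excess.sum()
        crow = float((rr * excess).sum() / tot)
        ccol = float((cc * excess).sum() / tot)
        self.centroid_px_ = (crow + r0, ccol + c0)

        half = self.roi_size // 2
        ir, ic = int(round(crow)), int(round(ccol))
        if (ir - half < 0 or ic - half < 0
                or ir + half > img.shape[0] or ic + half > img.shape[1]):
            raise CTIQError("wire crop exceeds the image; enlarge the image or ROI")
        crop = img[ir - half: ir + half, ic - half: ic + half].astype(float)
        # wire must be well inside the crop
        if min(crow - (ir - half), (ir + half - 1) - crow,
               ccol - (ic - half), (ic + half - 1) - ccol) < 2:
            raise CTIQError("wire within 2 px of the crop border")

        yy, xx = np.indices(crop.shape)
        rad = np.hypot(yy - (crow - (ir - half)), xx - (ccol - (ic - half)))
        ann = (rad > self.annulus_inner) & (rad <= self.annulus_outer)
        if not ann.any():
            raise CTIQError("background annulus empty; adjust annulus radii")
        crop = crop - crop[ann].mean()

        padded = np.zeros((self.pad, self.pad))
        padded[:crop.shape[0], :crop.shape[1]] = crop
        mag = np.abs(np.fft.fft2(padded))
        fx = np.fft.fftfreq(self.pad, d=vol.dx)
        fy = np.fft.fftfreq(self.pad, d=vol.dy)
        df = 1.0 / (self.pad * vol.dx)
        freqs, mod = _radial_average(mag, fx, fy, df)
        if self.correct_wire and self.wire_diameter > 0:
            mod = mod / wire_aperture_mtf(freqs, self.wire_diameter)
        mod = mod / mod[0]
        keep = freqs <= vol.nyquist + 1e-12
        self.curve_ = MTFCurve(freqs[keep], mod[keep])
        self.frequencies_ = self.curve_.frequencies
        self.modulation_ = self.curve_.modulation
        self.summary_ = mtf_summary(self.curve_)
        return self


class CircularEdgeMTF(BaseEstimator):
    """Circular-edge MTF estimator from a high-contrast rod image.

    The rod centre is found by thresholded centroid and refined by a circle
    fit to the half-maximum contour; pixel values binned by radial distance
    give an ESF oversampled by ``oversample`` relative to the pixel pitch.
    The LSF (central finite difference) is Hann-windowed over ``window_mm``
    centred on its peak before the DFT.

    Attributes (after ``fit``): ``curve_``, ``frequencies_``, ``modulation_``,
    ``centre_mm_``, ``radius_mm_``, ``fit_residual_px_``, ``summary_``.
    """

    def __init__(self, oversample: int = 8, window_mm: float = 8.0,
                 n_angles: int = 360, max_fit_residual_px: float = 0.5):
        self.oversample = oversample
        self.window_mm = window_mm
        self.n_angles = n_angles
        self.max_fit_residual_px = max_fit_residual_px

    # -- centre refinement -------------------------------------------------
    def _half_max_radii(self, img: np.ndarray, centre_px: tuple[float, float],
                        r_lo: float, r_hi: float, level: float) -> np.ndarray:
        """Half-maximum crossing radius (px) along each of n_angles rays."""
        thetas = 2 * math.pi * np.arange(self.n_angles) / self.n_angles
        rs = np.arange(r_lo, r_hi, 0.25)
        rows = centre_px[0] + rs[None, :] * np.sin(thetas)[:, None]
        cols = centre_px[1] + rs[None, :] * np.cos(thetas)[:, None]
        prof = ndimage.map_coordinates(img, [rows.ravel(), cols.ravel()],
                                       order=1, mode="nearest")
        prof = prof.reshape(self.n_angles, rs.size)
        out = np.full(self.n_angles, np.nan)
        for k in range(self.n_angles):
            p = prof[k]
            below = np.nonzero(p <= level)[0]
            if below.size == 0 or below[0] == 0:
                continue
            i = below[0]
            out[k] = rs[i - 1] + (p[i - 1] - level) * 0.25 / (p[i - 1] - p[i])
        return out

    def fit(self, vol: ImageVolume, slice_index: int = 0) -> "CircularEdgeMTF":
        if abs(vol.dx - vol.dy) > 1e-9:
            raise CTIQError("edge MTF requires square pixels (dx == dy)")
        img = vol.voxels[slice_index].astype(float)
        lo, hi = float(img.min()), float(img.max())
        mask = img > (lo + hi) / 2.0
        if not mask.any():
            raise CTIQError("no high-contrast rod found")
        if (mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()):
            raise CTIQError("rod truncated by the image border")
        rr, cc = np.nonzero(mask)
        crow, ccol = float(rr.mean()), float(cc.mean())
        r_est = math.sqrt(mask.sum() / math.pi)

        rad = np.hypot(np.arange(img.shape[0])[:, None] - crow,
                       np.arange(img.shape[1])[None, :] - ccol)
        interior = img[rad < 0.6 * r_est].mean()
        outer = rad > 1.5 * r_est
        background = img[outer].mean() if outer.any() else lo
        level = (interior + background) / 2.0

        centre = np.array([crow, ccol])
        radius = r_est
        resid = np.inf
        for _ in range(4):
            radii = self._half_max_radii(img, (centre[0], centre[1]),
                                         max(0.5 * radius, 2.0), 1.5 * radius, level)
            ok = np.isfinite(radii)
            if ok.sum() < 16:
                raise CTIQError("circle fit failed: too few edge crossings")
            thetas = 2 * math.pi * np.arange(self.n_angles) / self.n_angles
            A = np.column_stack([np.ones(ok.sum()),
                                 np.cos(thetas[ok]), np.sin(thetas[ok])])
            coef, *_ = np.linalg.lstsq(A, radii[ok], rcond=None)
            radius = float(coef[0])
            centre = centre + np.array([coef[2], coef[1]])  # row ~ sin, col ~ cos
            resid = float(np.sqrt(np.mean((A @ coef - radii[ok]) ** 2)))
            if abs(coef[1]) < 1e-4 and abs(coef[2]) < 1e-4:
                break
        if resid > self.max_fit_residual_px:
            raise CTIQError(f"circle fit residual {resid:.3f} px exceeds "
                            f"{self.max_fit_residual_px} px")
        self.fit_residual_px_ = resid
        self.radius_mm_ = radius * vol.dx
        x = (centre[1] - (img.shape[1] - 1) / 2.0) * vol.dx
        y = ((img.shape[0] - 1) / 2.0 - centre[0]) * vol.dy
        self.centre_mm_ = (x, y)

        # -- oversampled ESF by radial binning ----------------------------
        binw = vol.dx / self.oversample
        span = self.window_mm / 2.0 + 1.0
        rad_mm = np.hypot((np.arange(img.shape[0]) - centre[0])[:, None],
                          (np.arange(img.shape[1]) - centre[1])[None, :]) * vol.dx
        sel = np.abs(rad_mm - self.radius_mm_) <= span
        r_sel = rad_mm[sel]
        v_sel = img[sel]
        b0 = self.radius_mm_ - span
        idx = np.floor((r_sel - b0) / binw).astype(int)
        nbin = int(np.ceil(2 * span / binw))
        idx = np.clip(idx, 0, nbin - 1)
        sums = np.bincount(idx, weights=v_sel, minlength=nbin)
        counts = np.bincount(idx, minlength=nbin)
        centres = b0 + (np.arange(nbin) + 0.5) * binw
        filled = counts > 0
        if filled.sum() < nbin:
            esf = np.interp(centres, centres[filled], sums[filled] / counts[filled])
        else:
            esf = sums / counts

        lsf = np.gradient(esf, binw)
        peak = int(np.argmax(np.abs(lsf)))
        nwin = int(round(self.window_mm / binw))
        nwin += nwin % 2  # even length, symmetric about the peak
        w = np.zeros_like(lsf)
        lo_i = max(0, peak - nwin // 2)
        hi_i = min(len(lsf), peak + nwin // 2)
        hann = np.hanning(nwin + 1)
        w[lo_i:hi_i] = hann[(lo_i - (peak - nwin // 2)):(hi_i - (peak - nwin // 2))]
        lsf_w = lsf * w

        nfft = 1 << max(12, int(np.ceil(np.log2(len(lsf_w) * 2))))
        spec = np.abs(np.fft.rfft(lsf_w, nfft))
        freqs = np.fft.rfftfreq(nfft, d=binw)
        if spec[0] == 0:
            raise CTIQError("degenerate edge: zero total contrast")
        mod = spec / spec[0]
        keep = freqs <= vol.nyquist + 1e-12
        self.curve_ = MTFCurve(freqs[keep], mod[keep])
        self.frequencies_ = self.curve_.frequencies
        self.modulation_ = self.curve_.modulation
        self.summary_ = mtf_summary(self.curve_)
        return self


# -- thin functional wrappers ------------------------------------------------

def mtf_from_wire(vol: ImageVolume,
                  search_box: Optional[tuple[int, int, int, int]] = None,
                  slice_index: int = 0, **opts) -> MTFCurve:
    """Wire-method MTF; ``opts`` are :class:`WireMTF` parameters."""
    return WireMTF(**opts).fit(vol, slice_index=slice_index,
                               search_box=search_box).curve_


def mtf_from_circular_edge(vol: ImageVolume, slice_index: int = 0,
                           **opts) -> MTFCurve:
    """Circular-edge MTF; ``opts`` are :class:`CircularEdgeMTF` parameters."""
    return CircularEdgeMTF(**opts).fit(vol, slice_index=slice_index).curve_


def mtf_vs_position(volumes_by_offset: dict[float, ImageVolume],
                    **opts) -> list[tuple[float, MTFCurve]]:
    """Edge-method MTF per off-centre position, sorted by offset (mm).

    Errors in individual volumes are re-raised with the offset label attached.
    """
    out = []
    for offset in sorted(volumes_by_offset):
        try:
            out.append((offset, mtf_from_circular_edge(volumes_by_offset[offset],
                                                       **opts)))
        except CTIQError as exc:
            raise CTIQError(f"offset {offset} mm: {exc}") from exc
    return out
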