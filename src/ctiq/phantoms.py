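"""Synthetic phantom generator with analytic ground truth.

Every image the QA pipeline consumes can be generated here: a thin tungsten
wire for the point-method MTF, a Teflon-rod edge for the circular-edge MTF, a
uniform water volume with spatially correlated noise for NPS/uniformity, a thin
tungsten foil z-stack for the slice sensitivity profile, a CTP515-style
low-contrast disc module and a CTP401-style HU-insert module.

The imaging system is modelled as an isotropic in-plane Gaussian PSF of width
``psf_sigma`` (mm); objects are rendered as indicator fields on a grid
oversampled 8x, convolved with the PSF, then area-averaged down to the pixel
grid.  The resulting in-plane MTF is exp(-2 pi^2 sigma^2 f^2) (times the small
apertures of the object and pixel), giving closed-form recovery targets.

Noise is filtered white Gaussian: a per-slice i.i.d. white field of standard
deviation ``noise_sigma_white`` circularly convolved with a small kernel ``h``,
so that the noise power spectrum is exactly

    NPS(fx, fy) = noise_sigma_white^2 * dx * dy * |H(fx, fy)|^2

with ``H`` the kernel's discrete-space Fourier transform, and the pixel
variance is ``noise_sigma_white^2 * sum(h^2)``.

Every generator is deterministic given ``rng_seed`` and returns its
:class:`PhantomTruth` alongside the image so recovery tests compare estimates
against the truth object rather than hard-coded numbers.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .volume import AcquisitionMeta, CTIQError, ImageVolume

__all__ = [
    "PhantomTruth",
    "default_insert_hus",
    "default_lc_layout",
    "dog_kernel",
    "averaging_kernel",
    "kernel_transfer",
    "analytic_nps",
    "gaussian_mtf",
    "gaussian_mtf_percent_frequency",
    "blurred_disc_profile",
    "simulate_wire_image",
    "simulate_rod_image",
    "simulate_noise_volume",
    "simulate_foil_stack",
    "simulate_low_contrast_module",
    "simulate_insert_module",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.35482...

#: Nominal insert HU values of a CTP401-style sensitometry module.
_DEFAULT_INSERT_HUS = {
    "air": -1000.0,
    "ldpe": -95.0,
    "water": 0.0,
    "acrylic": 120.0,
    "teflon": 990.0,
}

#: Fixed angular positions (degrees, 0 = +x, counter-clockwise) for the inserts.
_INSERT_ANGLES = {
    "air": 90.0,
    "ldpe": 162.0,
    "water": 234.0,
    "acrylic": 306.0,
    "teflon": 18.0,
}


def default_insert_hus() -> dict[str, float]:
    return dict(_DEFAULT_INSERT_HUS)


def default_lc_layout(
    contrasts_pct: tuple[float, ...] = (1.0, 0.5, 0.3),
    diameters_mm: tuple[float, ...] = (15.0, 9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0),
    arc_radius: float = 80.0,
    gap_mm: float = 9.0,
) -> list[dict]:
    """Supra-slice low-contrast layout: one 120-degree sector per contrast level.

    Within a sector, discs of decreasing diameter are laid out along the arc
    with centre-to-centre arc spacing ``(d_i + d_{i+1})/2 + gap_mm``.  The
    commercial module's exact geometry is not reproduced; only the structure
    (three contrast levels, nine diameters each) is.
    """
    layout = []
    for g, c in enumerate(contrasts_pct):
        theta = math.radians(90.0 + 120.0 * g)  # sector start angle
        arc = 0.0
        for i, d in enumerate(diameters_mm):
            if i > 0:
                arc += (diameters_mm[i - 1] + d) / 2.0 + gap_mm
            ang = theta + arc / arc_radius
            layout.append({
                "x": arc_radius * math.cos(ang),
                "y": arc_radius * math.sin(ang),
                "diameter": d,
                "contrast_pct": c,
            })
    return layout


@dataclass
class PhantomTruth:
    """Generator parameters that double as recovery targets.

    Units: mm for lengths, HU for intensities.  ``slice_profile`` selects the
    longitudinal response shape ('gaussian' or 'trapezoid') with full width at
    half maximum ``slice_fwhm``.  Low-contrast disc contrast is expressed in
    percent of 1000 HU (1% = 10 HU).
    """

    psf_sigma: float = 0.1874
    wire_diameter: float = 0.05
    wire_contrast: float = 20000.0
    rod_radius: float = 6.0
    rod_contrast: float = 990.0
    background_hu: float = 0.0
    noise_sigma_white: float = 0.0
    noise_kernel: Optional[np.ndarray] = None
    slice_profile: str = "gaussian"
    slice_fwhm: float = 0.45
    foil_contrast: float = 1000.0
    insert_hus: dict[str, float] = field(default_factory=default_insert_hus)
    lc_layout: list[dict] = field(default_factory=default_lc_layout)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma < 0:
            raise CTIQError("psf_sigma must be >= 0")
        if self.slice_fwhm <= 0:
            raise CTIQError("slice_fwhm must be > 0")
        if self.noise_sigma_white < 0:
            raise CTIQError("noise_sigma_white must be >= 0")
        if self.slice_profile not in ("gaussian", "trapezoid"):
            raise CTIQError(f"unknown slice_profile {self.slice_profile!r}")
        if self.noise_kernel is not None:
            self.noise_kernel = np.asarray(self.noise_kernel, dtype=float)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if d["noise_kernel"] is not None:
            d["noise_kernel"] = np.asarray(d["noise_kernel"]).tolist()
        return json.dumps(d, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# analytic oracles
# ---------------------------------------------------------------------------

def gaussian_mtf(f: np.ndarray | float, sigma: float) -> np.ndarray | float:
    """MTF of an isotropic Gaussian PSF of width ``sigma`` mm: exp(-2 pi^2 s^2 f^2)."""
    return np.exp(-2.0 * math.pi ** 2 * sigma ** 2 * np.square(f))


def gaussian_mtf_percent_frequency(sigma: float, percent: float) -> float:
    """Frequency (lp/mm) where the Gaussian MTF falls to ``percent``/100."""
    p = percent / 100.0
    return math.sqrt(math.log(1.0 / p) / (2.0 * math.pi ** 2 * sigma ** 2))


def blurred_disc_profile(r: np.ndarray | float, radius: float, sigma: float) -> np.ndarray:
    """Radial profile of a unit disc convolved with a Gaussian PSF.

    The value at distance ``r`` from the disc centre is the probability that a
    2-D Gaussian displacement lands inside the disc, i.e. a noncentral
    chi-square CDF: ``P(chi2_2((r/s)^2) <= (R/s)^2)``.  Exact, used as an
    independent oracle for the rendered images.
    """
    from scipy import stats

    r = np.atleast_1d(np.asarray(r, dtype=float))
    if sigma == 0:
        return (r <= radius).astype(float)
    return stats.ncx2.cdf((radius / sigma) ** 2, 2, (r / sigma) ** 2)


def kernel_transfer(kernel: np.ndarray, fx: np.ndarray, fy: np.ndarray,
                    dx: float, dy: float) -> np.ndarray:
    """|H(fx, fy)| of a small 2-D kernel, discrete-space Fourier transform.

    ``fx`` and ``fy`` are broadcastable arrays in lp/mm; the kernel tap at
    (row m, col n) contributes ``h[m, n] * exp(-2 pi i (fx n dx + fy m dy))``.
    """
    kernel = np.asarray(kernel, dtype=float)
    m, n = np.indices(kernel.shape)
    fx = np.asarray(fx, dtype=float)[..., None]
    fy = np.asarray(fy, dtype=float)[..., None]
    phase = -2j * math.pi * (fx * (n.ravel() * dx) + fy * (m.ravel() * dy))
    return np.abs((kernel.ravel() * np.exp(phase)).sum(axis=-1))


def analytic_nps(truth: PhantomTruth, fx: np.ndarray, fy: np.ndarray,
                 dx: float, dy: float) -> np.ndarray:
    """Closed-form NPS (HU^2 mm^2) of the filtered-white-noise model."""
    s2 = truth.noise_sigma_white ** 2
    if truth.noise_kernel is None:
        return np.full(np.broadcast_shapes(np.shape(fx), np.shape(fy)), s2 * dx * dy)
    H = kernel_transfer(truth.noise_kernel, fx, fy, dx, dy)
    return s2 * dx * dy * H ** 2


def dog_kernel(n: int, sigma1_px: float, sigma2_px: float) -> np.ndarray:
    """Difference-of-Gaussians band-pass kernel on an ``n x n`` tap grid.

    Mimics the band-shaped NPS of filtered-backprojection/hybrid-IR CT noise:
    the positive Gaussian sets the high-frequency roll-off, the subtracted
    wider Gaussian suppresses low frequencies.  Normalised to unit power
    (sum of squared taps = 1) so the white-noise SD is preserved.
    """
    if n % 2 == 0:
        raise CTIQError("kernel size must be odd")
    ax = np.arange(n) - n // 2
    xx, yy = np.meshgrid(ax, ax)
    g1 = np.exp(-(xx ** 2 + yy ** 2) / (2 * sigma1_px ** 2))
    g2 = np.exp(-(xx ** 2 + yy ** 2) / (2 * sigma2_px ** 2))
    k = g1 / g1.sum() - g2 / g2.sum()
    return k / math.sqrt((k ** 2).sum())


def averaging_kernel(shape: tuple[int, int]) -> np.ndarray:
    """Uniform box kernel (mean filter) of the given tap shape."""
    k = np.ones(shape, dtype=float)
    return k / k.size


# ---------------------------------------------------------------------------
# rendering machinery
# ---------------------------------------------------------------------------

def _oversampled_axes(n_rows: int, n_cols: int, pitch: float, os: int):
    """Physical (x, y) centres of the oversampled subpixels."""
    x = ((np.arange(n_cols * os) + 0.5) / os - 0.5 - (n_cols - 1) / 2.0) * pitch
    y = ((n_rows - 1) / 2.0 + 0.5 - (np.arange(n_rows * os) + 0.5) / os) * pitch
    return x, y


def _render_discs(n_rows: int, n_cols: int, pitch: float,
                  discs: list[tuple[float, float, float, float]],
                  psf_sigma: float, oversample: int = 8) -> np.ndarray:
    """Render (cx, cy, radius, amplitude) discs blurred by the Gaussian PSF.

    Rendering is on an ``oversample``-times finer grid, PSF convolution by
    ``scipy.ndimage.gaussian_filter`` there, then area-average downsampling to
    the pixel grid (which is exactly the pixel-aperture integration).
    """
    x, y = _oversampled_axes(n_rows, n_cols, pitch, oversample)
    img = np.zeros((n_rows * oversample, n_cols * oversample))
    h = pitch / oversample
    for cx, cy, radius, amp in discs:
        dist = np.hypot(y[:, None] - cy, x[None, :] - cx)
        # linear edge coverage over one subpixel: keeps flux and centroid
        # accurate to O(h^2) instead of hard thresholding the boundary
        img += amp * np.clip((radius - dist) / h + 0.5, 0.0, 1.0)
    if psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=psf_sigma / (pitch / oversample),
                                      mode="constant", truncate=6.0)
    return img.reshape(n_rows, oversample, n_cols, oversample).mean(axis=(1, 3))


def _correlated_noise(rng: np.random.Generator, shape: tuple[int, int],
                      sigma_white: float, kernel: Optional[np.ndarray]) -> np.ndarray:
    """One slice of filtered white Gaussian noise (circular convolution)."""
    white = rng.standard_normal(shape) * sigma_white
    if kernel is None or sigma_white == 0:
        return white
    kernel = np.asarray(kernel, dtype=float)
    pad = np.zeros(shape)
    km, kn = kernel.shape
    pad[:km, :kn] = kernel
    # shift so the kernel centre tap sits at the origin -> circular convolution
    pad = np.roll(pad, (-(km // 2), -(kn // 2)), axis=(0, 1))
    return np.real(np.fft.ifft2(np.fft.fft2(white) * np.fft.fft2(pad)))


def _add_noise(rng: np.random.Generator, voxels: np.ndarray,
               truth: PhantomTruth) -> np.ndarray:
    if truth.noise_sigma_white == 0:
        return voxels
    for k in range(voxels.shape[0]):
        voxels[k] += _correlated_noise(rng, voxels.shape[1:],
                                       truth.noise_sigma_white, truth.noise_kernel)
    return voxels


def _volume(voxels: np.ndarray, pitch: float, dz: float = 0.5,
            origin_z: float = 0.0, mode: str = "synthetic") -> ImageVolume:
    return ImageVolume(voxels, pitch, pitch, dz, origin_z=origin_z,
                       meta=AcquisitionMeta(mode_label=mode))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_wire_image(truth: PhantomTruth, grid_size: int = 96,
                        pixel_pitch: float = 0.05,
                        wire_position: tuple[float, float] = (0.0, 0.0),
                        oversample: int = 8) -> tuple[ImageVolume, PhantomTruth]:
    """Point-source image: a thin high-contrast wire cross-section.

    The wire is rendered as a disc of ``truth.wire_diameter`` at a subpixel
    position, blurred by the PSF.  Noise is added when
    ``truth.noise_sigma_white > 0``.
    """
    os_pix = pixel_pitch / oversample
    if truth.psf_sigma < os_pix / 8 and truth.wire_diameter < os_pix / 8:
        raise CTIQError(
            "wire and PSF both unresolvable on the oversampled grid; "
            "decrease pixel_pitch or increase oversample")
    half = grid_size * pixel_pitch / 2.0
    margin = 10.0 * truth.psf_sigma + truth.wire_diameter
    if (abs(wire_position[0]) + margin > half) or (abs(wire_position[1]) + margin > half):
        raise CTIQError("wire too close to the image border (need 10 sigma margin)")
    img = _render_discs(grid_size, grid_size, pixel_pitch,
                        [(wire_position[0], wire_position[1],
                          truth.wire_diameter / 2.0, truth.wire_contrast)],
                        truth.psf_sigma, oversample)
    voxels = truth.background_hu + img[None]
    rng = np.random.default_rng(truth.rng_seed)
    voxels = _add_noise(rng, voxels, truth)
    return _volume(voxels, pixel_pitch), truth


def simulate_rod_image(truth: PhantomTruth, grid_size: int = 256,
                       pixel_pitch: float = 0.1,
                       rod_centre: tuple[float, float] = (0.0, 0.0),
                       oversample: int = 8) -> tuple[ImageVolume, PhantomTruth]:
    """High-contrast rod cross-section for the circular-edge MTF method."""
    if truth.rod_radius < 10 * pixel_pitch:
        raise CTIQError("rod radius must span at least 10 pixels")
    half = grid_size * pixel_pitch / 2.0
    margin = truth.rod_radius + 6.0 * truth.psf_sigma + pixel_pitch
    if (abs(rod_centre[0]) + margin > half) or (abs(rod_centre[1]) + margin > half):
        raise CTIQError("rod touches the image border")
    img = _render_discs(grid_size, grid_size, pixel_pitch,
                        [(rod_centre[0], rod_centre[1],
                          truth.rod_radius, truth.rod_contrast)],
                        truth.psf_sigma, oversample)
    voxels = truth.background_hu + img[None]
    rng = np.random.default_rng(truth.rng_seed)
    voxels = _add_noise(rng, voxels, truth)
    return _volume(voxels, pixel_pitch), truth


def simulate_noise_volume(truth: PhantomTruth, grid_size: int = 256,
                          pixel_pitch: float = 0.5,
                          n_slices: int = 8) -> tuple[ImageVolume, PhantomTruth]:
    """Uniform water volume with spatially correlated noise.

    Slices are i.i.d. filtered white Gaussian fields on top of
    ``truth.background_hu``; the closed-form NPS is given by
    :func:`analytic_nps`.
    """
    rng = np.random.default_rng(truth.rng_seed)
    voxels = np.full((n_slices, grid_size, grid_size), truth.background_hu, float)
    voxels = _add_noise(rng, voxels, truth)
    return _volume(voxels, pixel_pitch), truth


def _slice_profile(truth: PhantomTruth, z: np.ndarray) -> np.ndarray:
    """Normalised longitudinal response at offsets ``z`` from the foil."""
    fw = truth.slice_fwhm
    if truth.slice_profile == "gaussian":
        sigma = fw / FWHM_PER_SIGMA
        return np.exp(-z ** 2 / (2 * sigma ** 2))
    # trapezoid: rect(core = fwhm) convolved with rect(ramp = fwhm/2),
    # normalised to unit peak; FWHM of the result equals the core width.
    a, b = fw, fw / 2.0
    lo = np.clip(z + b / 2, -a / 2, a / 2)
    hi = np.clip(z - b / 2, -a / 2, a / 2)
    return (lo - hi) / b


def simulate_foil_stack(truth: PhantomTruth, z_increment: float = 0.1,
                        z_extent: float = 4.0, grid_size: int = 64,
                        pixel_pitch: float = 0.3,
                        foil_z: float = 0.0) -> tuple[ImageVolume, PhantomTruth]:
    """Thin-foil z-stack for slice-sensitivity-profile measurement.

    A uniform in-plane disc (radius ``truth.rod_radius``) whose per-slice
    amplitude follows the chosen slice profile, sampled every ``z_increment``
    over ``z_extent`` centred on ``foil_z``.
    """
    if z_increment > truth.slice_fwhm / 3.0:
        raise CTIQError("z_increment must be <= fwhm/3 to sample the profile")
    if z_extent < 4.0 * truth.slice_fwhm:
        raise CTIQError("z_extent must span >= 4 FWHM for background estimation")
    n = int(round(z_extent / z_increment)) + 1
    origin_z = foil_z - (n - 1) / 2.0 * z_increment
    z = origin_z + z_increment * np.arange(n)
    amps = truth.foil_contrast * _slice_profile(truth, z - foil_z)
    disc = _render_discs(grid_size, grid_size, pixel_pitch,
                         [(0.0, 0.0, truth.rod_radius, 1.0)], truth.psf_sigma)
    voxels = truth.background_hu + amps[:, None, None] * disc[None]
    rng = np.random.default_rng(truth.rng_seed)
    voxels = _add_noise(rng, voxels, truth)
    return _volume(voxels, pixel_pitch, dz=z_increment, origin_z=origin_z), truth


def _check_disjoint(objs: list[dict], what: str) -> None:
    for i in range(len(objs)):
        for j in range(i + 1, len(objs)):
            a, b = objs[i], objs[j]
            dist = math.hypot(a["x"] - b["x"], a["y"] - b["y"])
            if dist < (a["diameter"] + b["diameter"]) / 2.0:
                raise CTIQError(f"{what} objects {i} and {j} overlap")


def simulate_low_contrast_module(truth: PhantomTruth, grid_size: int = 400,
                                 pixel_pitch: float = 0.5,
                                 n_slices: int = 1) -> tuple[ImageVolume, PhantomTruth]:
    """CTP515-style low-contrast module: faint discs in correlated noise.

    Disc amplitude is ``10 * contrast_pct`` HU (1% of the 1000-HU scale =
    10 HU).  The returned truth's ``lc_layout`` is the reader's ground truth.
    """
    layout = truth.lc_layout
    if not layout:
        raise CTIQError("lc_layout is empty")
    _check_disjoint(layout, "low-contrast")
    half = grid_size * pixel_pitch / 2.0
    for o in layout:
        if abs(o["x"]) + o["diameter"] / 2 > half or abs(o["y"]) + o["diameter"] / 2 > half:
            raise CTIQError("low-contrast object outside the grid")
    discs = [(o["x"], o["y"], o["diameter"] / 2.0, 10.0 * o["contrast_pct"])
             for o in layout]
    img = _render_discs(grid_size, grid_size, pixel_pitch, discs, truth.psf_sigma,
                        oversample=4)
    voxels = truth.background_hu + np.repeat(img[None], n_slices, axis=0)
    rng = np.random.default_rng(truth.rng_seed)
    voxels = _add_noise(rng, voxels, truth)
    return _volume(voxels, pixel_pitch), truth


def simulate_insert_module(truth: PhantomTruth, grid_size: int = 400,
                           pixel_pitch: float = 0.5, n_slices: int = 1,
                           insert_radius: float = 6.25,
                           ring_radius: float = 50.0
                           ) -> tuple[ImageVolume, PhantomTruth]:
    """CTP401-style sensitometry module: cylindrical HU inserts on a ring.

    Materials must be among the known insert positions (air, ldpe, water,
    acrylic, teflon); the layout is returned via :meth:`insert_layout`.
    """
    if not truth.insert_hus:
        raise CTIQError("insert_hus is empty")
    unknown = set(truth.insert_hus) - set(_INSERT_ANGLES)
    if unknown:
        raise CTIQError(f"unknown insert material(s): {sorted(unknown)}")
    layout = insert_layout(truth, insert_radius, ring_radius)
    objs = [{"x": p["x"], "y": p["y"], "diameter": 2 * insert_radius}
            for p in layout.values()]
    _check_disjoint(objs, "insert")
    discs = [(p["x"], p["y"], insert_radius, truth.insert_hus[m] - truth.background_hu)
             for m, p in layout.items()]
    img = _render_discs(grid_size, grid_size, pixel_pitch, discs, truth.psf_sigma,
                        oversample=4)
    voxels = truth.background_hu + np.repeat(img[None], n_slices, axis=0)
    rng = np.random.default_rng(truth.rng_seed)
    voxels = _add_noise(rng, voxels, truth)
    return _volume(voxels, pixel_pitch), truth


def insert_layout(truth: PhantomTruth, insert_radius: float = 6.25,
                  ring_radius: float = 50.0) -> dict[str, dict]:
    """Material -> {x, y, radius} positions used by :func:`simulate_insert_module`."""
    out = {}
    for m in truth.insert_hus:
        ang = math.radians(_INSERT_ANGLES[m])
        out[m] = {"x": ring_radius * math.cos(ang),
                  "y": ring_radius * math.sin(ang),
                  "radius": insert_radius}
    return out
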