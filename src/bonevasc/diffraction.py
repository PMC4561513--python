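"""Scanning micro-diffraction analysis of the collagen equatorial signal.

A 2D transmission diffraction pattern is mapped to scattering-vector
magnitude q = 4 pi sin(theta) / lambda (with 2 theta = atan(r / L)) and
azimuth Phi per pixel, then integrated radially to I(q) and azimuthally,
within a q window around the collagen ring at ~5.6 nm^-1, to I(Phi).

The collagen equatorial reflection in I(q) is fitted as a Gaussian on a
background (second-order polynomial, or power law); the peak position q_c
gives the lateral packing distance of the collagen molecules D = 2 pi / q_c
and the peak area tracks the collagen amount.  I(Phi) is fitted as a
constant background plus a pair of wrapped Gaussians 180 degrees apart
(equatorial symmetry); the orientation degree is A_Phi / A_BKG, the area
under the peaks (aligned molecules) over the area under the constant
background (randomly oriented molecules).

Units: q in nm^-1, wavelength in nm, detector distances in mm, angles in
degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit

__all__ = [
    "DetectorGeometry",
    "RadialProfile",
    "AzimuthalProfile",
    "CollagenPeakFit",
    "OrientationFit",
    "CollagenMap",
    "q_map",
    "radial_integrate",
    "azimuthal_integrate",
    "polar_rebin",
    "fit_collagen_peak",
    "fit_orientation",
    "build_collagen_map",
    "plot_collagen_map",
    "wrapped_gaussian_pair",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat 2D detector in transmission geometry.

    Defaults follow a synchrotron scanning setup: lambda = 0.0976 nm,
    sample-detector distance 110 cm, 50 um pixels, 2048^2 detector with the
    beam at the center.
    """

    wavelength_nm: float = 0.0976
    distance_mm: float = 1100.0
    pixel_size_mm: float = 0.05
    shape: tuple[int, int] = (2048, 2048)     # (ny, nx)
    beam_center: tuple[float, float] | None = None  # (cx, cy) pixels

    def __post_init__(self) -> None:
        for name in ("wavelength_nm", "distance_mm", "pixel_size_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DetectorGeometry.{name} must be positive")
        if self.beam_center is None:
            object.__setattr__(
                self, "beam_center",
                ((self.shape[1] - 1) / 2.0, (self.shape[0] - 1) / 2.0))
        cx, cy = self.beam_center
        if not (0 <= cx < self.shape[1] and 0 <= cy < self.shape[0]):
            raise ValueError("beam_center must lie inside the detector")

    def q_at_radius_mm(self, r_mm: float) -> float:
        theta = 0.5 * np.arctan2(r_mm, self.distance_mm)
        return float(4.0 * np.pi * np.sin(theta) / self.wavelength_nm)

    @property
    def q_max(self) -> float:
        cx, cy = self.beam_center
        corners = [(0, 0), (0, self.shape[1] - 1),
                   (self.shape[0] - 1, 0),
                   (self.shape[0] - 1, self.shape[1] - 1)]
        r = max(np.hypot(y - cy, x - cx) for y, x in corners)
        return self.q_at_radius_mm(r * self.pixel_size_mm)


@dataclass
class RadialProfile:
    """Azimuthally averaged intensity I(q)."""

    q: np.ndarray          # nm^-1, bin centers, strictly increasing
    intensity: np.ndarray  # mean counts per pixel in bin
    counts: np.ndarray     # pixels per bin (0 marks an empty bin)


@dataclass
class AzimuthalProfile:
    """Ring-averaged angular intensity I(Phi), Phi in [0, 360)."""

    phi: np.ndarray
    intensity: np.ndarray
    counts: np.ndarray
    q_window: tuple[float, float] = (0.0, 0.0)


@dataclass
class CollagenPeakFit:
    """Equatorial peak fit: Gaussian + background."""

    q_c: float
    sigma_q: float
    amplitude: float
    peak_area: float
    background_model: str
    background_coeffs: tuple
    lateral_spacing_nm: float
    residual_norm: float
    ok: bool = True
    message: str = ""


@dataclass
class OrientationFit:
    """Azimuthal fit: constant + wrapped Gaussian pair 180 deg apart."""

    orientation_angle_deg: float  # mod 180
    sigma_phi_deg: float
    amplitude: float
    background: float
    a_phi: float
    a_bkg: float
    degree: float
    residual_norm: float
    ok: bool = True
    message: str = ""


@dataclass
class CollagenMap:
    """Per-scan-position collagen amount / orientation / degree rasters."""

    amount: np.ndarray
    angle_deg: np.ndarray
    degree: np.ndarray
    quality: np.ndarray          # True where both fits are usable
    peak_fits: list = field(default_factory=list)
    orientation_fits: list = field(default_factory=list)

    def to_vector_table(self):
        import pandas as pd
        gy, gx = self.amount.shape
        rows = []
        for iy in range(gy):
            for ix in range(gx):
                rows.append({"x": ix, "y": iy,
                             "amount": self.amount[iy, ix],
                             "angle_deg": self.angle_deg[iy, ix],
                             "degree": self.degree[iy, ix],
                             "ok": bool(self.quality[iy, ix])})
        return pd.DataFrame(rows)


def q_map(geom: DetectorGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel q (nm^-1) and azimuth Phi (degrees in [0, 360))."""
    cx, cy = geom.beam_center
    yy, xx = np.indices(geom.shape)
    dx = (xx - cx) * geom.pixel_size_mm
    dy = (yy - cy) * geom.pixel_size_mm
    r = np.hypot(dx, dy)
    theta = 0.5 * np.arctan2(r, geom.distance_mm)
    q = 4.0 * np.pi * np.sin(theta) / geom.wavelength_nm
    phi = np.degrees(np.arctan2(dy, dx)) % 360.0
    return q, phi


def radial_integrate(pattern: np.ndarray, geom: DetectorGeometry,
                     n_bins: int = 200,
                     q_range: tuple[float, float] | None = None) -> RadialProfile:
    """Mean intensity per equal-width q bin (azimuthal average)."""
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != geom.shape:
        raise ValueError("pattern shape does not match detector geometry")
    q, _ = q_map(geom)
    if q_range is None:
        q_range = (0.0, float(q.max()))
    if q_range[0] >= q.max() or q_range[1] <= 0 or q_range[0] >= q_range[1]:
        raise ValueError(f"q_range {q_range} outside detector coverage "
                         f"(q_max = {q.max():.3g} nm^-1)")
    edges = np.linspace(q_range[0], q_range[1], n_bins + 1)
    sums, _ = np.histogram(q, bins=edges, weights=pattern)
    counts, _ = np.histogram(q, bins=edges)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(centers, mean, counts)


def azimuthal_integrate(pattern: np.ndarray, geom: DetectorGeometry,
                        q_window: tuple[float, float] = (4.6, 6.6),
                        n_bins: int = 72) -> AzimuthalProfile:
    """Mean intensity per azimuth bin over pixels with q inside the window."""
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != geom.shape:
        raise ValueError("pattern shape does not match detector geometry")
    q, phi = q_map(geom)
    sel = (q >= q_window[0]) & (q < q_window[1])
    if not sel.any():
        raise ValueError(f"q window {q_window} selects no pixels "
                         f"(detector q_max = {q.max():.3g} nm^-1)")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    sums, _ = np.histogram(phi[sel], bins=edges, weights=pattern[sel])
    counts, _ = np.histogram(phi[sel], bins=edges)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AzimuthalProfile(centers, mean, counts, q_window=q_window)


def polar_rebin(pattern: np.ndarray, geom: DetectorGeometry,
                n_q: int = 100, n_phi: int = 36,
                q_range: tuple[float, float] | None = None) -> np.ndarray:
    """Summed counts on a (q, Phi) grid; conserves total counts in range."""
    pattern = np.asarray(pattern, dtype=float)
    q, phi = q_map(geom)
    if q_range is None:
        q_range = (0.0, float(q.max()) * (1 + 1e-12))
    hist, _, _ = np.histogram2d(
        q.ravel(), phi.ravel(),
        bins=[np.linspace(*q_range, n_q + 1), np.linspace(0, 360, n_phi + 1)],
        weights=pattern.ravel())
    return hist


def _poly2(qv, c0, c1, c2):
    return c0 + c1 * qv + c2 * qv * qv


def _powerlaw(qv, a, k):
    return a * np.power(np.maximum(qv, 1e-9), -k)


def _gauss(qv, amp, q_c, sigma):
    return amp * np.exp(-((qv - q_c) ** 2) / (2.0 * sigma ** 2))


def fit_collagen_peak(profile: RadialProfile,
                      window: tuple[float, float] = (4.6, 6.6),
                      background_model: str = "poly2") -> CollagenPeakFit:
    """Fit Gaussian + background to I(q) inside a window around the peak.

    Initialization: peak position from the argmax of the median-filtered
    window, sigma = window width / 6, background from the outer 25% of the
    window's bins.  Non-convergence or a window with no interior maximum
    yields a flagged (ok=False) result, never an exception.
    """
    if background_model not in ("poly2", "powerlaw"):
        raise ValueError("background_model must be 'poly2' or 'powerlaw'")
    sel = ((profile.q >= window[0]) & (profile.q <= window[1])
           & (profile.counts > 0) & np.isfinite(profile.intensity))
    qv = profile.q[sel]
    iv = profile.intensity[sel]
    if qv.size < 8:
        raise ValueError(f"fit window {window} must contain >= 8 populated bins")

    smooth = median_filter(iv, size=3, mode="nearest")
    imax = int(np.argmax(smooth))
    q_c0 = float(qv[imax])
    sigma0 = (window[1] - window[0]) / 6.0

    # background from the outer quarter of the window
    n_edge = max(2, qv.size // 8)
    edge = np.r_[np.arange(n_edge), np.arange(qv.size - n_edge, qv.size)]
    flagged_no_peak = imax in (0, qv.size - 1)
    try:
        if background_model == "poly2":
            bcoef = np.polyfit(qv[edge], iv[edge], 2)
            bkg0 = (float(bcoef[2]), float(bcoef[1]), float(bcoef[0]))
            bfun = _poly2
        else:
            logq = np.log(np.maximum(qv[edge], 1e-9))
            logi = np.log(np.maximum(iv[edge], 1e-9))
            kfit = np.polyfit(logq, logi, 1)
            bkg0 = (float(np.exp(kfit[1])), float(-kfit[0]))
            bfun = _powerlaw
    except np.linalg.LinAlgError:
        bkg0 = (float(np.median(iv)), 0.0, 0.0)[: 3 if background_model == "poly2" else 2]
        bfun = _poly2 if background_model == "poly2" else _powerlaw

    amp0 = max(float(smooth[imax] - bfun(q_c0, *bkg0)), 1e-6)

    def model(qv, amp, q_c, sigma, *bc):
        return _gauss(qv, amp, q_c, sigma) + bfun(qv, *bc)

    p0 = [amp0, q_c0, sigma0, *bkg0]
    lower = [0.0, window[0], 1e-4] + [-np.inf] * len(bkg0)
    upper = [np.inf, window[1], (window[1] - window[0])] + [np.inf] * len(bkg0)
    try:
        popt, _ = curve_fit(model, qv, iv, p0=p0, bounds=(lower, upper),
                            maxfev=20000)
        resid = float(np.linalg.norm(iv - model(qv, *popt)))
        ok, msg = True, ""
    except (RuntimeError, ValueError) as exc:
        popt = p0
        resid = float(np.linalg.norm(iv - model(qv, *p0)))
        ok, msg = False, f"fit did not converge: {exc}"
    if flagged_no_peak:
        ok, msg = False, (msg + " no interior maximum in window").strip()

    amp, q_c, sigma = float(popt[0]), float(popt[1]), float(popt[2])
    peak_area = amp * sigma * np.sqrt(2.0 * np.pi)
    return CollagenPeakFit(
        q_c=q_c, sigma_q=sigma, amplitude=amp, peak_area=float(peak_area),
        background_model=background_model,
        background_coeffs=tuple(float(c) for c in popt[3:]),
        lateral_spacing_nm=float(2.0 * np.pi / q_c),
        residual_norm=resid, ok=ok, message=msg)


def wrapped_gaussian_pair(phi_deg: np.ndarray, amp: float, phi0_deg: float,
                          sigma_deg: float) -> np.ndarray:
    """Unit pair of wrapped Gaussians at phi0 and phi0 + 180 (period 360)."""
    phi_deg = np.asarray(phi_deg, dtype=float)
    out = np.zeros_like(phi_deg)
    for center in (phi0_deg, phi0_deg + 180.0):
        d = (phi_deg - center + 180.0) % 360.0 - 180.0
        for wrap in (-360.0, 0.0, 360.0):
            out += amp * np.exp(-((d + wrap) ** 2) / (2.0 * sigma_deg ** 2))
    return out


def fit_orientation(profile: AzimuthalProfile) -> OrientationFit:
    """Fit I(Phi) = c + wrapped Gaussian pair; degree = A_Phi / A_BKG.

    A_Phi = 2 * amp * sigma * sqrt(2 pi) (area under both peaks over the
    full circle); A_BKG = c * 360.  A flat profile yields degree 0.
    """
    sel = (profile.counts > 0) & np.isfinite(profile.intensity)
    phi = profile.phi[sel]
    iv = profile.intensity[sel]
    if phi.size < 8:
        raise ValueError("azimuthal profile has fewer than 8 populated bins")
    span = phi.max() - phi.min()
    if span < 300.0:
        raise ValueError("azimuthal profile must cover the full circle")

    c0 = float(np.percentile(iv, 10))
    amp0 = float(iv.max() - c0)
    rel = np.ptp(iv) / max(abs(float(np.mean(iv))), 1e-12)
    if amp0 <= 0 or rel < 1e-3:  # flat profile: no aligned fraction
        return OrientationFit(0.0, 0.0, 0.0, float(np.mean(iv)),
                              0.0, float(np.mean(iv)) * 360.0, 0.0, 0.0,
                              ok=True, message="flat profile")
    phi00 = float(phi[int(np.argmax(iv))]) % 180.0

    def model(p, c, amp, phi0, sigma):
        return c + wrapped_gaussian_pair(p, amp, phi0, sigma)

    try:
        popt, _ = curve_fit(model, phi, iv, p0=[c0, amp0, phi00, 20.0],
                            bounds=([-np.inf, 0.0, -90.0, 1.0],
                                    [np.inf, np.inf, 270.0, 90.0]),
                            maxfev=20000)
        resid = float(np.linalg.norm(iv - model(phi, *popt)))
        ok, msg = True, ""
    except (RuntimeError, ValueError) as exc:
        popt = [c0, amp0, phi00, 20.0]
        resid = float(np.linalg.norm(iv - model(phi, *popt)))
        ok, msg = False, f"fit did not converge: {exc}"

    c, amp, phi0, sigma = (float(v) for v in popt)
    if c < 0:
        ok, msg = False, (msg + " negative fitted background").strip()
    a_phi = 2.0 * amp * sigma * np.sqrt(2.0 * np.pi)
    a_bkg = c * 360.0
    degree = a_phi / a_bkg if a_bkg > 0 else np.inf
    return OrientationFit(
        orientation_angle_deg=phi0 % 180.0, sigma_phi_deg=sigma,
        amplitude=amp, background=c, a_phi=float(a_phi), a_bkg=float(a_bkg),
        degree=float(degree), residual_norm=resid, ok=ok, message=msg)


def build_collagen_map(patterns: np.ndarray, geom: DetectorGeometry,
                       q_window: tuple[float, float] = (4.6, 6.6),
                       background_model: str = "poly2",
                       n_radial_bins: int = 150,
                       n_phi_bins: int = 72) -> CollagenMap:
    """Fit every pattern of a (gy, gx, ny, nx) scan grid into rasters.

    Positions whose peak or orientation fit is flagged, or whose peak area
    is consistent with zero, are masked out in ``quality``.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 4:
        raise ValueError("patterns must be a (gy, gx, ny, nx) array")
    gy, gx = patterns.shape[:2]
    amount = np.zeros((gy, gx))
    angle = np.zeros((gy, gx))
    degree = np.zeros((gy, gx))
    quality = np.zeros((gy, gx), dtype=bool)
    pfits: list = []
    ofits: list = []
    for iy in range(gy):
        for ix in range(gx):
            pat = patterns[iy, ix]
            rp = radial_integrate(pat, geom, n_bins=n_radial_bins,
                                  q_range=(max(q_window[0] - 2.0, 0.05),
                                           q_window[1] + 2.0))
            pf = fit_collagen_peak(rp, window=q_window,
                                   background_model=background_model)
            ap = azimuthal_integrate(pat, geom, q_window=q_window,
                                     n_bins=n_phi_bins)
            of = fit_orientation(ap)
            pfits.append(pf)
            ofits.append(of)
            amount[iy, ix] = pf.peak_area
            angle[iy, ix] = of.orientation_angle_deg
            degree[iy, ix] = of.degree
            quality[iy, ix] = pf.ok and of.ok and pf.peak_area > 0
    return CollagenMap(amount, angle, degree, quality, pfits, ofits)


def plot_collagen_map(cmap: CollagenMap, path: str) -> None:
    """Vector-plot export: arrows show orientation/degree over an amount raster."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gy, gx = cmap.amount.shape
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(cmap.amount, origin="lower", cmap="viridis")
    yy, xx = np.mgrid[0:gy, 0:gx]
    ang = np.deg2rad(cmap.angle_deg)
    scale = np.where(cmap.quality, cmap.degree, 0.0)
    ax.quiver(xx, yy, scale * np.cos(ang), scale * np.sin(ang),
              color="black", pivot="middle",
              headwidth=1, headlength=0, headaxislength=0)
    ax.set_xlabel("scan x")
    ax.set_ylabel("scan y")
    ax.set_title("collagen amount / orientation / degree")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
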