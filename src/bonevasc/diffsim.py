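"""Synthetic 2D diffraction patterns with known collagen-ring parameters.

The forward model places an isotropic background plus a Gaussian ring at
q_c (the collagen equatorial reflection, ~5.6 nm^-1) with a preferred
azimuthal orientation on a flat detector:

    I(pixel) = B(q) + A * exp(-(q - q_c)^2 / (2 sigma_q^2)) * P(Phi)
    P(Phi)   = (1 - f) + f * [wrapped Gaussians at Phi0 and Phi0 + 180]

where f is the aligned fraction.  Optional Poisson noise emulates photon
counting.  Because every parameter is known, the analysis chain
(integration + peak/orientation fits) can be validated by round trip.

The default detector is a scaled-down stand-in (256 px of 50 um at 40 mm)
whose q coverage (~10 nm^-1 at the edge) comfortably contains the collagen
ring; any geometry can be passed instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .diffraction import DetectorGeometry, q_map, wrapped_gaussian_pair

__all__ = [
    "DiffractionSimSpec",
    "simulate_diffraction_pattern",
    "simulate_scan_grid",
    "expected_orientation_degree",
]


def _default_sim_geometry() -> DetectorGeometry:
    return DetectorGeometry(wavelength_nm=0.0976, distance_mm=40.0,
                            pixel_size_mm=0.05, shape=(256, 256))


@dataclass(frozen=True)
class DiffractionSimSpec:
    """True parameters of a simulated collagen diffraction pattern."""

    geometry: DetectorGeometry = field(default_factory=_default_sim_geometry)
    q_c_true: float = 5.6              # nm^-1
    peak_sigma_q: float = 0.35         # nm^-1
    peak_amplitude: float = 400.0      # counts at ring maximum
    background_model: str = "poly2"    # or "powerlaw"
    background_coeffs: tuple = (120.0, -8.0, 0.2)
    orientation_angle_true: float = 30.0   # degrees
    orientation_sigma_phi: float = 25.0    # degrees
    aligned_fraction_true: float = 0.5
    poisson_noise: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.q_c_true <= 0 or self.peak_sigma_q <= 0:
            raise ValueError("q_c_true and peak_sigma_q must be positive")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be non-negative")
        if not (0 <= self.aligned_fraction_true <= 1):
            raise ValueError("aligned_fraction_true must be in [0, 1]")
        if self.background_model not in ("poly2", "powerlaw"):
            raise ValueError("background_model must be 'poly2' or 'powerlaw'")
        if self.orientation_sigma_phi <= 0:
            raise ValueError("orientation_sigma_phi must be positive")

    def background(self, q: np.ndarray) -> np.ndarray:
        if self.background_model == "poly2":
            c0, c1, c2 = self.background_coeffs
            return c0 + c1 * q + c2 * q * q
        a, k = self.background_coeffs
        return a * np.power(np.maximum(q, 1e-3), -k)


def _angular_profile(spec: DiffractionSimSpec, phi: np.ndarray) -> np.ndarray:
    f = spec.aligned_fraction_true
    if f == 0:
        return np.ones_like(phi)
    peaks = wrapped_gaussian_pair(phi, 1.0, spec.orientation_angle_true,
                                  spec.orientation_sigma_phi)
    return (1.0 - f) + f * peaks


def simulate_diffraction_pattern(spec: DiffractionSimSpec) -> np.ndarray:
    """Render one detector image; deterministic given ``spec.rng_seed``."""
    geom = spec.geometry
    if spec.q_c_true >= geom.q_max:
        raise ValueError(
            f"q_c_true = {spec.q_c_true} nm^-1 is outside detector coverage "
            f"(q_max = {geom.q_max:.3g} nm^-1)")
    q, phi = q_map(geom)
    ring = spec.peak_amplitude * np.exp(
        -((q - spec.q_c_true) ** 2) / (2.0 * spec.peak_sigma_q ** 2))
    intensity = spec.background(q) + ring * _angular_profile(spec, phi)
    intensity = np.clip(intensity, 0.0, None)
    if spec.poisson_noise:
        rng = np.random.default_rng(spec.rng_seed)
        intensity = rng.poisson(intensity).astype(float)
    return intensity


def simulate_scan_grid(base_spec: DiffractionSimSpec,
                       amount_map: np.ndarray,
                       angle_map: np.ndarray,
                       degree_map: np.ndarray) -> np.ndarray:
    """One pattern per scan position, shape (gy, gx, ny, nx).

    amount_map scales the peak amplitude; angle_map and degree_map set the
    true orientation angle (degrees) and aligned fraction per position.
    Per-position noise seeds are derived from ``base_spec.rng_seed``.
    """
    amount_map = np.asarray(amount_map, dtype=float)
    angle_map = np.asarray(angle_map, dtype=float)
    degree_map = np.asarray(degree_map, dtype=float)
    if not (amount_map.shape == angle_map.shape == degree_map.shape):
        raise ValueError("amount, angle and degree maps must share shape")
    gy, gx = amount_map.shape
    ny, nx = base_spec.geometry.shape
    out = np.empty((gy, gx, ny, nx), dtype=float)
    for iy in range(gy):
        for ix in range(gx):
            spec = replace(
                base_spec,
                peak_amplitude=base_spec.peak_amplitude * amount_map[iy, ix],
                orientation_angle_true=float(angle_map[iy, ix]),
                aligned_fraction_true=float(degree_map[iy, ix]),
                rng_seed=(base_spec.rng_seed * 100003 + iy * gx + ix)
                % (2**31 - 1))
            out[iy, ix] = simulate_diffraction_pattern(spec)
    return out


def expected_orientation_degree(spec: DiffractionSimSpec,
                                q_window: tuple[float, float]) -> float:
    """Analytic A_Phi / A_BKG for a noiseless pattern's azimuthal profile.

    Within the q window the azimuthal profile is
    B_bar + R_bar * [(1 - f) + f * WG(Phi)], so the peak area is
    R_bar * f * 2 sigma_phi sqrt(2 pi) and the constant background is
    B_bar + R_bar (1 - f).  Radial means are taken with the detector's own
    per-q pixel weighting so the oracle matches what ring integration sees.
    """
    q, _ = q_map(spec.geometry)
    sel = (q >= q_window[0]) & (q < q_window[1])
    qs = q[sel]
    b_bar = float(np.mean(spec.background(qs)))
    r_bar = float(np.mean(
        spec.peak_amplitude
        * np.exp(-((qs - spec.q_c_true) ** 2) / (2.0 * spec.peak_sigma_q ** 2))))
    f = spec.aligned_fraction_true
    a_phi = r_bar * f * 2.0 * spec.orientation_sigma_phi * np.sqrt(2.0 * np.pi)
    a_bkg = (b_bar + r_bar * (1.0 - f)) * 360.0
    return a_phi / a_bkg
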