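"""Single-distance propagation imaging, Paganin phase retrieval, and FBP.

In-line (propagation-based) phase-contrast imaging of a homogeneous object
with refractive index n = 1 - delta + i*beta maps the projected thickness
T(x, y) to a near-field intensity through a linearized transport-of-intensity
model.  The forward transfer is, in Fourier space,

    I_z / I_0 = IFT[ FT[exp(-mu T)] * (1 + (z delta / mu) * 4 pi^2 |u|^2) ]

with mu = 4 pi beta / lambda the linear attenuation coefficient and u the
spatial frequency in cycles per micrometre.  Single-distance phase retrieval
divides the measured intensity by the same low-pass filter and takes the log:

    T = -(1/mu) * ln( IFT[ FT[I/I_0] / (1 + (z delta / mu) * 4 pi^2 |u|^2) ] )

so the pair is an exact inverse on the periodic FFT domain.  Slices are then
reconstructed from per-slice parallel-beam sinograms by filtered back
projection (ramp filter, optional Hann apodization).

All lengths are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import iradon, radon

__all__ = [
    "ImagingGeometry",
    "forward_propagate",
    "paganin_retrieve",
    "radon_project",
    "fbp_reconstruct",
    "volume_to_projections",
    "reconstruct_volume",
    "wavelength_um_from_kev",
]

#: hc in keV * nm
_HC_KEV_NM = 1.23984193


def wavelength_um_from_kev(energy_kev: float) -> float:
    """X-ray wavelength in micrometres for a photon energy in keV."""
    if energy_kev <= 0:
        raise ValueError("energy_kev must be positive")
    return _HC_KEV_NM / energy_kev * 1e-3


@dataclass(frozen=True)
class ImagingGeometry:
    """Acquisition geometry and single-material optical constants.

    Defaults mirror a synchrotron microtomography setup: 24 keV beam,
    5 cm propagation distance, 0.64 um detector pixels.  delta and beta
    are the refractive-index decrement and absorption index of the (single)
    material; only the ratio delta/mu enters the retrieval filter.
    """

    energy_kev: float = 24.0
    propagation_distance_um: float = 5.0e4
    pixel_size_um: float = 0.64
    delta: float = 1.0e-7
    beta: float = 1.0e-10

    def __post_init__(self) -> None:
        for name in ("energy_kev", "propagation_distance_um", "pixel_size_um",
                     "delta", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ImagingGeometry.{name} must be positive")

    @property
    def wavelength_um(self) -> float:
        return wavelength_um_from_kev(self.energy_kev)

    @property
    def mu_per_um(self) -> float:
        """Linear attenuation coefficient mu = 4 pi beta / lambda (1/um)."""
        return 4.0 * np.pi * self.beta / self.wavelength_um


def _paganin_filter(shape: tuple[int, int], g: ImagingGeometry) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0], d=g.pixel_size_um)
    fx = np.fft.fftfreq(shape[1], d=g.pixel_size_um)
    u2 = fy[:, None] ** 2 + fx[None, :] ** 2
    alpha = g.propagation_distance_um * g.delta / g.mu_per_um
    return 1.0 + alpha * 4.0 * np.pi**2 * u2


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def _pad_reflect(img: np.ndarray) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Reflect-pad to the next power of two per axis; return crop slices."""
    ny, nx = img.shape
    py, px = _next_pow2(ny) - ny, _next_pow2(nx) - nx
    lo_y, lo_x = py // 2, px // 2
    padded = np.pad(img, ((lo_y, py - lo_y), (lo_x, px - lo_x)), mode="reflect")
    return padded, (slice(lo_y, lo_y + ny), slice(lo_x, lo_x + nx))


def _apply_filter(img: np.ndarray, g: ImagingGeometry, pad: bool,
                  inverse: bool) -> np.ndarray:
    if pad:
        work, crop = _pad_reflect(img)
    else:
        work, crop = img, (slice(None), slice(None))
    H = _paganin_filter(work.shape, g)
    spec = np.fft.fft2(work)
    spec = spec / H if inverse else spec * H
    out = np.fft.ifft2(spec).real
    return out[crop]


def forward_propagate(T: np.ndarray, g: ImagingGeometry,
                      pad: bool = True) -> np.ndarray:
    """Propagate a projected-thickness map to a flat-normalized intensity.

    At z = 0 the filter is unity and the output reduces to Beer-Lambert
    absorption exp(-mu T).  With pad=False the operation is the plain
    periodic-FFT transfer and is exactly inverted by :func:`paganin_retrieve`.
    """
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("thickness map contains non-finite values")
    A = np.exp(-g.mu_per_um * T)
    return _apply_filter(A, g, pad=pad, inverse=False)


def paganin_retrieve(I_over_I0: np.ndarray, g: ImagingGeometry,
                     pad: bool = True) -> np.ndarray:
    """Single-distance phase retrieval: intensity -> projected thickness."""
    I = np.asarray(I_over_I0, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("intensity contains non-finite values")
    if np.any(I <= 0):
        idx = tuple(int(i) for i in np.unravel_index(int(np.argmin(I)),
                                                     I.shape))
        raise ValueError(f"non-positive intensity at pixel {idx}")
    B = _apply_filter(I, g, pad=pad, inverse=True)
    # the filtered intensity can graze zero for very noisy inputs; the log
    # needs a strictly positive argument
    B = np.clip(B, 1e-12, None)
    return -np.log(B) / g.mu_per_um


def radon_project(image: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """Parallel-beam line integrals of a square slice.

    Returns a sinogram of shape (n_detector, n_angles) in pixel units
    (multiply by the pixel size for physical path lengths).
    """
    image = np.asarray(image, dtype=float)
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if angles.size == 0:
        raise ValueError("angle list is empty")
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("slice must be a square 2D array")
    return radon(image, theta=angles, circle=False)


def _check_coverage(angles: np.ndarray) -> None:
    if angles.size < 2:
        raise ValueError("at least 2 projection angles are required")
    span = float(angles.max() - angles.min())
    step = float(np.median(np.diff(np.sort(angles))))
    if span + step < 180.0 - 1e-9:
        raise ValueError(
            f"angular coverage {span + step:.1f} deg is below the 180 deg "
            "needed for parallel-beam reconstruction")


def fbp_reconstruct(sinogram: np.ndarray, angles_deg: np.ndarray,
                    filter_name: str = "ramp",
                    output_size: int | None = None) -> np.ndarray:
    """Filtered back projection of a (n_detector, n_angles) sinogram."""
    angles = np.asarray(angles_deg, dtype=float)
    _check_coverage(angles)
    if filter_name not in ("ramp", "hann"):
        raise ValueError("filter_name must be 'ramp' or 'hann'")
    return iradon(np.asarray(sinogram, dtype=float), theta=angles,
                  filter_name=filter_name, circle=False,
                  output_size=output_size)


def volume_to_projections(volume: np.ndarray, angles_deg: np.ndarray,
                          voxel_size_um: float) -> np.ndarray:
    """Per-angle thickness projections of a z-major density volume.

    For rotation about the z axis each slice contributes one sinogram row;
    output shape is (n_angles, n_detector, nz) with values in micrometres of
    material (density * path length).
    """
    volume = np.asarray(volume, dtype=float)
    angles = np.asarray(angles_deg, dtype=float)
    nz = volume.shape[0]
    sino0 = radon_project(volume[0], angles)
    projs = np.empty((angles.size, sino0.shape[0], nz), dtype=float)
    projs[:, :, 0] = sino0.T * voxel_size_um
    for k in range(1, nz):
        projs[:, :, k] = radon_project(volume[k], angles).T * voxel_size_um
    return projs


def reconstruct_volume(projections: np.ndarray, angles_deg: np.ndarray,
                       voxel_size_um: float, output_size: int,
                       filter_name: str = "ramp") -> np.ndarray:
    """Invert :func:`volume_to_projections`: back to a z-major density volume."""
    projections = np.asarray(projections, dtype=float)
    nz = projections.shape[2]
    vol = np.empty((nz, output_size, output_size), dtype=float)
    for k in range(nz):
        vol[k] = fbp_reconstruct(projections[:, :, k].T, angles_deg,
                                 filter_name=filter_name,
                                 output_size=output_size) / voxel_size_um
    return vol
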