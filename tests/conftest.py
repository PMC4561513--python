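import numpy as np
import pytest

from bonevasc import (DetectorGeometry, DiffractionSimSpec, VesselMask,
                      VesselTreeTruth)
from bonevasc.phantoms import rasterize_tree

VOX = 0.64


def bandlimited_map(shape, seed, cutoff=0.1, mean=20.0, amp=5.0):
    """Smooth periodic thickness map with spectral support below cutoff."""
    rng = np.random.default_rng(seed)
    spec = np.fft.fft2(rng.normal(size=shape))
    fy = np.fft.fftfreq(shape[0])
    fx = np.fft.fftfreq(shape[1])
    keep = (np.abs(fy)[:, None] < cutoff) & (np.abs(fx)[None, :] < cutoff)
    f = np.fft.ifft2(spec * keep).real
    return mean + amp * f / np.max(np.abs(f))


def straight_tube_truth(diameter_um=12.0, shape=(64, 64, 64), vox=VOX):
    """Single axis-aligned tube along z spanning the full depth.

    Centered on a voxel center: thinning of a mask with perfect
    between-voxel mirror symmetry is degenerate.
    """
    e = [s * vox for s in shape]
    truth = VesselTreeTruth(extent_um=tuple(e))
    mid_x, mid_y = (shape[0] // 2 + 0.5) * vox, (shape[1] // 2 + 0.5) * vox
    truth.polylines.append(np.array([[mid_x, mid_y, 0.0],
                                     [mid_x, mid_y, e[2]]]))
    truth.radii.append(np.full(2, diameter_um / 2.0))
    truth.topology.append(-1)
    return truth


def y_tree_truth(shape=(64, 64, 96), vox=VOX, r_parent=5.0, r_child=3.5):
    """Parent tube splitting into two children at 45% depth."""
    e = [s * vox for s in shape]
    truth = VesselTreeTruth(extent_um=tuple(e))
    mid = (shape[0] // 2 + 0.5) * vox
    zj = e[2] * 0.45
    truth.polylines.append(np.array([[mid, mid, 1.0], [mid, mid, zj]]))
    truth.radii.append(np.full(2, r_parent))
    truth.topology.append(-1)
    for sgn in (-1, 1):
        truth.polylines.append(np.array(
            [[mid, mid, zj], [mid + sgn * e[0] / 3.2, mid, e[2] - 1]]))
        truth.radii.append(np.full(2, r_child))
        truth.topology.append(0)
    return truth


@pytest.fixture(scope="session")
def tube_mask():
    truth = straight_tube_truth()
    vol = rasterize_tree(truth, (64, 64, 64), VOX)
    return VesselMask(vol, VOX), truth


@pytest.fixture(scope="session")
def y_mask():
    truth = y_tree_truth()
    vol = rasterize_tree(truth, (64, 64, 96), VOX)
    return VesselMask(vol, VOX), truth


@pytest.fixture(scope="session")
def ring_mask():
    zz, yy, xx = np.indices((48, 48, 48))
    c, R, r = 23.5, 15.0, 4.0
    d = np.sqrt((np.sqrt((xx - c) ** 2 + (yy - c) ** 2) - R) ** 2
                + (zz - c) ** 2)
    return VesselMask(d <= r, VOX)


@pytest.fixture(scope="session")
def sim_geometry():
    """Scaled scan-diffraction detector whose edge q (~10 nm^-1) covers the
    collagen ring at 5.6 nm^-1."""
    return DetectorGeometry(wavelength_nm=0.0976, distance_mm=20.0,
                            pixel_size_mm=0.05, shape=(128, 128))


@pytest.fixture(scope="session")
def sim_spec(sim_geometry):
    return DiffractionSimSpec(geometry=sim_geometry)
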