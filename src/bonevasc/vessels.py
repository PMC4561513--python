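"""Vessel segmentation and depth-resolved quantification.

The quantitative readouts of a reconstructed scaffold volume:

* binary vessel mask (global threshold + morphological cleanup);
* per-slice vessel counts split into a small (10-15 um) and a large
  (15-20 um) diameter class, measured from each cross-section's
  equivalent circular diameter d = 2 sqrt(A / pi);
* the vascularization factor

      VF = [ s_small * int V_m(z) dz + s_large * int V_M(z) dz ] / Z_norm

  where V_m, V_M are the per-depth small/large counts, s_small and s_large
  are per-class section weights (circle area at the class-midpoint
  diameter, ~123 and ~240 um^2), and Z_norm a normalization depth.  VF is
  a flow-capacity proxy under the assumption that flow through a vessel is
  proportional to its cross-section.

Class intervals are half-open: a 15 um vessel counts as large.  Components
with equivalent diameter outside [10, 20] um contribute to the total count
but to neither class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball, opening

__all__ = [
    "PAPER_DEPTH_NORM_UM",
    "SizeClassConfig",
    "VesselMask",
    "DepthProfile",
    "QuantSummary",
    "default_section_weight",
    "segment_vessels",
    "per_slice_counts",
    "vascularization_factor",
    "summarize_sample",
]

#: Normalization depth (um) used when comparing samples over a fixed
#: 1.4 mm analysis cube regardless of how deep the vessels actually reach.
PAPER_DEPTH_NORM_UM = 1400.0

_STRUCT_3D_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_2D_8 = np.ones((3, 3), dtype=bool)


def default_section_weight(d_range: tuple[float, float],
                           rounded: bool = True) -> float:
    """Circle area (um^2) at the midpoint diameter of a class interval.

    With rounding on, values below 200 are reported to the nearest integer
    and larger ones to two significant figures, which yields the canonical
    ~123 um^2 (10-15 um class) and ~240 um^2 (15-20 um class) weights.
    """
    lo, hi = d_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid diameter range {d_range!r}: need 0 < lo < hi")
    area = math.pi * ((lo + hi) / 4.0) ** 2
    if not rounded:
        return area
    if area < 200.0:
        return float(round(area))
    ndigits = -(int(math.floor(math.log10(area))) - 1)
    return float(round(area, ndigits))


@dataclass(frozen=True)
class SizeClassConfig:
    """Diameter classes and section weights for vessel counting."""

    small_range: tuple[float, float] = (10.0, 15.0)
    large_range: tuple[float, float] = (15.0, 20.0)
    small_section: float | None = None   # um^2; default: midpoint circle area
    large_section: float | None = None
    total_depth_norm: float | None = None  # um; None -> analyzed depth

    def __post_init__(self) -> None:
        if not (0 < self.small_range[0] < self.small_range[1]):
            raise ValueError("small_range must satisfy 0 < lo < hi")
        if not (0 < self.large_range[0] < self.large_range[1]):
            raise ValueError("large_range must satisfy 0 < lo < hi")
        if self.small_range[1] != self.large_range[0]:
            raise ValueError("size classes must be contiguous and non-overlapping")
        if self.small_section is None:
            object.__setattr__(self, "small_section",
                               default_section_weight(self.small_range))
        if self.large_section is None:
            object.__setattr__(self, "large_section",
                               default_section_weight(self.large_range))
        if self.small_section <= 0 or self.large_section <= 0:
            raise ValueError("section weights must be positive")

    def classify(self, diameter_um: float) -> str:
        """'small', 'large' or 'other' (half-open small class, inclusive top)."""
        if self.small_range[0] <= diameter_um < self.small_range[1]:
            return "small"
        if self.large_range[0] <= diameter_um <= self.large_range[1]:
            return "large"
        return "other"


@dataclass
class VesselMask:
    """Binary vessel mask plus the parameters that produced it."""

    mask: np.ndarray
    voxel_size_um: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")


@dataclass
class DepthProfile:
    """Per-slice vessel counts along an axis (slice 0 = entry face)."""

    slice_thickness_um: float
    v_small: np.ndarray
    v_large: np.ndarray
    v_total: np.ndarray
    axis: str = "z"
    section_areas_um2: list | None = None

    def __post_init__(self) -> None:
        self.v_small = np.asarray(self.v_small, dtype=int)
        self.v_large = np.asarray(self.v_large, dtype=int)
        self.v_total = np.asarray(self.v_total, dtype=int)
        n = len(self.v_small)
        if len(self.v_large) != n or len(self.v_total) != n:
            raise ValueError("per-class count arrays must share length")

    @property
    def n_slices(self) -> int:
        return len(self.v_small)

    @property
    def depth_um(self) -> np.ndarray:
        return np.arange(self.n_slices) * self.slice_thickness_um

    @property
    def analyzed_depth_um(self) -> float:
        return self.n_slices * self.slice_thickness_um

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "slice": np.arange(self.n_slices),
            "depth_um": self.depth_um,
            "v_small": self.v_small,
            "v_large": self.v_large,
            "v_total": self.v_total,
        })


@dataclass
class QuantSummary:
    """Per-sample quantitative summary."""

    max_section_um2: float
    min_diameter_um: float
    n_branches: int
    total_v_small: int
    total_v_large: int
    vf: float

    def to_dict(self) -> dict:
        return {
            "max_section_um2": self.max_section_um2,
            "min_diameter_um": self.min_diameter_um,
            "n_branches": self.n_branches,
            "total_v_small": self.total_v_small,
            "total_v_large": self.total_v_large,
            "vf": self.vf,
        }


def segment_vessels(volume: np.ndarray, voxel_size_um: float,
                    threshold: float | str = "otsu",
                    min_component_voxels: int = 64,
                    opening_radius: int = 1) -> VesselMask:
    """Threshold a grayscale volume and clean the mask.

    threshold may be a fixed grayscale value or "otsu".  Cleanup is a
    morphological opening (ball of ``opening_radius`` voxels) followed by
    removal of 26-connected components below ``min_component_voxels``.
    A constant volume yields an empty mask rather than an error.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D")
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite voxels")

    if threshold == "otsu":
        if np.ptp(volume) == 0:  # constant volume: nothing to segment
            thr = np.inf
        else:
            thr = float(threshold_otsu(volume))
    else:
        thr = float(threshold)

    mask = volume > thr
    if opening_radius > 0 and mask.any():
        mask = opening(mask, ball(opening_radius))
    if mask.any() and min_component_voxels > 1:
        lbl, n = ndimage.label(mask, structure=_STRUCT_3D_26)
        if n:
            sizes = np.bincount(lbl.ravel())
            keep = sizes >= min_component_voxels
            keep[0] = False
            mask = keep[lbl]
    return VesselMask(mask, voxel_size_um, provenance={
        "threshold": thr if np.isfinite(thr) else "none (constant volume)",
        "min_component_voxels": min_component_voxels,
        "opening_radius": opening_radius,
    })


_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


def per_slice_counts(mask: VesselMask, axis: str = "z",
                     classes: SizeClassConfig | None = None) -> DepthProfile:
    """Count vessel cross-sections per slice perpendicular to an axis.

    2D connected components (8-connectivity) are extracted in every slice;
    each component of area A (um^2) gets an equivalent circular diameter
    d = 2 sqrt(A / pi) and is classed small / large / other.
    """
    if axis not in _AXIS_INDEX:
        raise ValueError(f"invalid axis {axis!r}; expected one of 'x', 'y', 'z'")
    classes = classes or SizeClassConfig()
    vol = np.moveaxis(mask.mask, _AXIS_INDEX[axis], 0)
    px_area = mask.voxel_size_um ** 2

    n = vol.shape[0]
    v_small = np.zeros(n, dtype=int)
    v_large = np.zeros(n, dtype=int)
    v_total = np.zeros(n, dtype=int)
    areas: list[np.ndarray] = []
    for k in range(n):
        lbl, ncomp = ndimage.label(vol[k], structure=_STRUCT_2D_8)
        if ncomp == 0:
            areas.append(np.empty(0))
            continue
        sizes = np.bincount(lbl.ravel())[1:]
        comp_areas = sizes * px_area
        areas.append(comp_areas)
        v_total[k] = ncomp
        d = 2.0 * np.sqrt(comp_areas / np.pi)
        for di in d:
            cls = classes.classify(float(di))
            if cls == "small":
                v_small[k] += 1
            elif cls == "large":
                v_large[k] += 1
    return DepthProfile(mask.voxel_size_um, v_small, v_large, v_total,
                        axis=axis, section_areas_um2=areas)


def vascularization_factor(profile: DepthProfile,
                           classes: SizeClassConfig | None = None,
                           total_depth_norm: float | None = None) -> float:
    """Section-weighted depth integral of vessel counts per unit depth (um^2).

    Integrals are slice sums times slice thickness.  The normalization depth
    defaults to the analyzed depth of the profile; pass
    ``PAPER_DEPTH_NORM_UM`` (1400 um) to normalize over a fixed analysis
    cube instead.
    """
    classes = classes or SizeClassConfig()
    norm = total_depth_norm
    if norm is None:
        norm = classes.total_depth_norm
    if norm is None:
        norm = profile.analyzed_depth_um
    if norm == 0:
        raise ValueError("total depth normalization must be non-zero")
    dz = profile.slice_thickness_um
    integral = (classes.small_section * float(profile.v_small.sum()) * dz
                + classes.large_section * float(profile.v_large.sum()) * dz)
    return integral / norm


def summarize_sample(mask: VesselMask, profile: DepthProfile, graph,
                     classes: SizeClassConfig | None = None,
                     min_branch_length_um: float = 5.0,
                     total_depth_norm: float | None = None) -> QuantSummary:
    """Assemble the per-sample summary table row."""
    from .skeleton import count_branches

    classes = classes or SizeClassConfig()
    max_section = 0.0
    min_diam = math.inf
    if profile.section_areas_um2:
        for comp_areas in profile.section_areas_um2:
            for a in np.atleast_1d(comp_areas):
                max_section = max(max_section, float(a))
                d = 2.0 * math.sqrt(float(a) / math.pi)
                if classes.classify(d) != "other":
                    min_diam = min(min_diam, d)
    if not math.isfinite(min_diam):
        min_diam = 0.0
    n_branches = count_branches(graph, min_branch_length_um) if graph else 0
    return QuantSummary(
        max_section_um2=max_section,
        min_diameter_um=min_diam,
        n_branches=n_branches,
        total_v_small=int(profile.v_small.sum()),
        total_v_large=int(profile.v_large.sum()),
        vf=vascularization_factor(profile, classes,
                                  total_depth_norm=total_depth_norm),
    )
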