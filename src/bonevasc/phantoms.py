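"""Synthetic scaffold + vessel-tree phantoms with analytic ground truth.

The phantom emulates a porous ceramic bone-scaffold cube containing tubular
branching vessel trees of 10-20 um diameter sampled on a 0.64 um voxel
grid.  Trees grow from an entry face as a persistent random walk with
Poisson branching per unit length; children taper and deflect by a bounded
random angle.  The continuous centerlines (polylines + per-segment radii)
are kept as ground truth, so every downstream measurement has an analytic
oracle: :func:`truth_depth_profile` counts centerline crossings of each
slice plane by size class, the geometric twin of the voxel-based per-slice
counts.

Coordinates are world (x, y, z) in micrometres; label volumes are z-major
arrays ``labels[z, y, x]`` with 0 = soft tissue, 1 = scaffold, 2 = vessel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vessels import DepthProfile, SizeClassConfig

__all__ = [
    "PhantomSpec",
    "VesselTreeTruth",
    "LabeledVolume",
    "generate_phantom",
    "rasterize_tree",
    "truth_depth_profile",
    "add_gaussian_noise",
]

_FACES = ("x-", "x+", "y-", "y+", "z-", "z+")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the scaffold/vessel phantom.

    The default 256^3 grid at 0.64 um/voxel is a ~164 um cube, a desk-scale
    stand-in for a 1.4 mm analysis volume; all statistics downstream are
    per-depth and therefore scale-free.
    """

    shape_voxels: tuple[int, int, int] = (256, 256, 256)  # (nx, ny, nz)
    voxel_size_um: float = 0.64
    n_trees: int = 3
    root_entry_face: str = "z-"
    branch_probability: float = 0.02      # per um of centerline
    diameter_range: tuple[float, float] = (10.0, 20.0)
    taper_factor: float = 0.85
    pore_radius_range: tuple[float, float] = (8.0, 20.0)
    scaffold_volume_fraction: float = 0.3
    direction_jitter: float = 0.15        # 0 -> perfectly straight tubes
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.shape_voxels):
            raise ValueError("shape_voxels: all dimensions must be >= 16")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.n_trees < 0:
            raise ValueError("n_trees must be non-negative")
        if self.root_entry_face not in _FACES:
            raise ValueError(f"root_entry_face must be one of {_FACES}")
        if self.branch_probability < 0:
            raise ValueError("branch_probability must be non-negative")
        d_min, d_max = self.diameter_range
        if not (0 < d_min < d_max):
            raise ValueError("diameter_range must satisfy 0 < d_min < d_max")
        if d_min <= 2 * self.voxel_size_um:
            raise ValueError(
                "diameter_range: d_min must exceed 2 voxels for vessels "
                "to be resolvable")
        if not (0 < self.taper_factor <= 1):
            raise ValueError("taper_factor must be in (0, 1]")
        if not (0 < self.pore_radius_range[0] < self.pore_radius_range[1]):
            raise ValueError("pore_radius_range must satisfy 0 < r_min < r_max")
        if not (0 <= self.scaffold_volume_fraction < 1):
            raise ValueError("scaffold_volume_fraction must be in [0, 1)")
        if self.direction_jitter < 0:
            raise ValueError("direction_jitter must be non-negative")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size_um for n in self.shape_voxels)


@dataclass
class VesselTreeTruth:
    """Analytic centerline ground truth for the vessel trees.

    polylines[i] is an (N, 3) array of (x, y, z) points in um; radii[i] the
    per-point radius (constant within a segment, halving events occur at
    branch points); topology[i] is the parent segment index (-1 for roots).
    """

    polylines: list = field(default_factory=list)
    radii: list = field(default_factory=list)
    topology: list = field(default_factory=list)
    extent_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def n_segments(self) -> int:
        return len(self.polylines)

    def total_length_um(self) -> float:
        return float(sum(
            np.linalg.norm(np.diff(p, axis=0), axis=1).sum()
            for p in self.polylines if len(p) > 1))


@dataclass
class LabeledVolume:
    """z-major label grid with voxel size and per-label optical constants."""

    labels: np.ndarray
    voxel_size_um: float
    materials: dict = field(default_factory=dict)  # label -> {delta, beta}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        bad = set(np.unique(self.labels)) - {0, 1, 2}
        if bad:
            raise ValueError(f"labels must be in {{0, 1, 2}}; found {bad}")
        for lab, props in self.materials.items():
            if props.get("delta", 1.0) <= 0 or props.get("beta", 1.0) <= 0:
                raise ValueError(f"material {lab}: delta and beta must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def _axis_and_sign(face: str) -> tuple[int, int]:
    return {"x": 0, "y": 1, "z": 2}[face[0]], (1 if face[1] == "-" else -1)


def _random_perpendicular(direction: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        v -= v.dot(direction) * direction
        n = np.linalg.norm(v)
        if n > 1e-8:
            return v / n


def _deflect(direction: np.ndarray, angle_rad: float,
             rng: np.random.Generator) -> np.ndarray:
    perp = _random_perpendicular(direction, rng)
    out = np.cos(angle_rad) * direction + np.sin(angle_rad) * perp
    return out / np.linalg.norm(out)


def _grow_trees(spec: PhantomSpec, rng: np.random.Generator) -> VesselTreeTruth:
    truth = VesselTreeTruth(extent_um=spec.extent_um)
    if spec.n_trees == 0:
        return truth
    ax, sign = _axis_and_sign(spec.root_entry_face)
    extent = np.asarray(spec.extent_um)
    d_min, d_max = spec.diameter_range
    step = 2.0 * spec.voxel_size_um
    max_steps = int(4 * extent[ax] / step)

    # entry positions kept apart so trees stay countable at the entry slice
    entries: list[np.ndarray] = []
    for _ in range(spec.n_trees):
        for _attempt in range(200):
            pos = rng.uniform(0.2, 0.8, size=3) * extent
            pos[ax] = 0.0 if sign > 0 else extent[ax]
            if all(np.linalg.norm(pos - e) > 1.5 * d_max for e in entries):
                break
        entries.append(pos)

    axis_unit = np.zeros(3)
    axis_unit[ax] = sign

    for pos0 in entries:
        root_r = 0.5 * rng.uniform(0.6 * d_max + 0.4 * d_min, d_max)
        # (start, direction, radius, parent segment index)
        stack = [(pos0.copy(), axis_unit.copy(), root_r, -1)]
        while stack:
            pos, direction, r, parent = stack.pop()
            pts = [pos.copy()]
            for _ in range(max_steps):
                if spec.direction_jitter > 0:
                    direction = direction + rng.normal(
                        scale=spec.direction_jitter, size=3)
                    direction += 0.05 * axis_unit  # persistence toward entry axis
                    direction /= np.linalg.norm(direction)
                nxt = pos + direction * step
                if np.any(nxt < 0) or np.any(nxt > extent):
                    # land exactly on the boundary so the tube reaches the face
                    t = np.inf
                    for i in range(3):
                        if direction[i] > 1e-12:
                            t = min(t, (extent[i] - pos[i]) / (direction[i] * step))
                        elif direction[i] < -1e-12:
                            t = min(t, -pos[i] / (direction[i] * step))
                    if np.isfinite(t) and t > 0:
                        pts.append(pos + direction * step * min(t, 1.0))
                    break
                pos = nxt
                pts.append(pos.copy())
                if rng.random() < spec.branch_probability * step:
                    child_r = max(r * spec.taper_factor, d_min / 2.0)
                    angle = np.deg2rad(rng.uniform(20.0, 60.0))
                    child_dir = _deflect(direction, angle, rng)
                    stack.append((pos.copy(), child_dir, child_r,
                                  len(truth.polylines)))
            if len(pts) > 1:
                poly = np.asarray(pts)
                truth.polylines.append(poly)
                truth.radii.append(np.full(len(poly), r))
                truth.topology.append(parent)
    return truth


def rasterize_tree(truth: VesselTreeTruth, shape_voxels: tuple[int, int, int],
                   voxel_size_um: float) -> np.ndarray:
    """Boolean z-major volume of voxels within the local radius of a centerline."""
    nx_, ny_, nz_ = shape_voxels
    out = np.zeros((nz_, ny_, nx_), dtype=bool)
    vs = voxel_size_um
    for poly, radii in zip(truth.polylines, truth.radii):
        r = float(radii[0])
        rv = r / vs  # radius in voxels
        for a, b in zip(poly[:-1], poly[1:]):
            # voxel-center coordinates (index + 0.5) * vs
            av = a / vs - 0.5
            bv = b / vs - 0.5
            lo = np.floor(np.minimum(av, bv) - rv - 1).astype(int)
            hi = np.ceil(np.maximum(av, bv) + rv + 1).astype(int)
            lo = np.maximum(lo, 0)
            hi = np.minimum(hi, [nx_ - 1, ny_ - 1, nz_ - 1])
            if np.any(lo > hi):
                continue
            xs = np.arange(lo[0], hi[0] + 1)
            ys = np.arange(lo[1], hi[1] + 1)
            zs = np.arange(lo[2], hi[2] + 1)
            gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
            pts = np.stack([gx, gy, gz], axis=-1).astype(float)
            seg = bv - av
            seg_len2 = seg.dot(seg)
            if seg_len2 == 0:
                d2 = ((pts - av) ** 2).sum(axis=-1)
            else:
                t = np.clip(((pts - av) @ seg) / seg_len2, 0.0, 1.0)
                closest = av + t[..., None] * seg
                d2 = ((pts - closest) ** 2).sum(axis=-1)
            inside = d2 <= rv * rv
            out[gz[inside], gy[inside], gx[inside]] = True
    return out


def _carve_pores(labels: np.ndarray, spec: PhantomSpec,
                 rng: np.random.Generator) -> None:
    """Subtract spherical pores until the scaffold fraction reaches target."""
    target = spec.scaffold_volume_fraction
    nz_, ny_, nx_ = labels.shape
    total = labels.size
    vs = spec.voxel_size_um
    zz, yy, xx = np.ogrid[:nz_, :ny_, :nx_]
    for _ in range(20000):
        if (labels == 1).sum() / total <= target:
            break
        c = rng.uniform(0, 1, size=3) * np.asarray([nx_, ny_, nz_])
        r = rng.uniform(*spec.pore_radius_range) / vs
        d2 = ((xx + 0.5 - c[0]) ** 2 + (yy + 0.5 - c[1]) ** 2
              + (zz + 0.5 - c[2]) ** 2)
        labels[d2 <= r * r] = 0


def generate_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, VesselTreeTruth]:
    """Generate a labeled scaffold volume and its vessel-tree ground truth.

    Deterministic for a fixed ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    nx_, ny_, nz_ = spec.shape_voxels
    labels = np.ones((nz_, ny_, nx_), dtype=np.uint8)
    _carve_pores(labels, spec, rng)
    truth = _grow_trees(spec, rng)
    if truth.n_segments:
        vess = rasterize_tree(truth, spec.shape_voxels, spec.voxel_size_um)
        labels[vess] = 2
    materials = {
        0: {"delta": 5e-8, "beta": 3e-11},
        1: {"delta": 4e-7, "beta": 5e-10},
        2: {"delta": 1e-7, "beta": 1e-10},
    }
    return LabeledVolume(labels, spec.voxel_size_um, materials), truth


def add_gaussian_noise(volume: np.ndarray, snr: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise with sigma = dynamic range / snr."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    volume = np.asarray(volume, dtype=float)
    sigma = (np.ptp(volume) or 1.0) / snr
    return volume + rng.normal(scale=sigma, size=volume.shape)


def truth_depth_profile(truth: VesselTreeTruth, axis: str = "z",
                        slice_thickness_um: float | None = None,
                        classes: SizeClassConfig | None = None,
                        n_slices: int | None = None) -> DepthProfile:
    """Ground-truth per-slice vessel counts from centerline crossings.

    A slice k covers depth [k, k+1) * slice_thickness; crossings are counted
    against the slice-center plane using the analytic local diameter, the
    geometric twin of the voxel-based per-slice component counts.
    """
    classes = classes or SizeClassConfig()
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    if slice_thickness_um is None:
        slice_thickness_um = 0.64
    if n_slices is None:
        n_slices = max(1, int(round(truth.extent_um[ax] / slice_thickness_um)))
    v_small = np.zeros(n_slices, dtype=int)
    v_large = np.zeros(n_slices, dtype=int)
    v_total = np.zeros(n_slices, dtype=int)
    st = slice_thickness_um
    for poly, radii in zip(truth.polylines, truth.radii):
        coord = poly[:, ax]
        d = 2.0 * float(radii[0])
        cls = classes.classify(d)
        for c0, c1 in zip(coord[:-1], coord[1:]):
            lo, hi = (c0, c1) if c0 <= c1 else (c1, c0)
            if hi == lo:
                continue
            # slice-center planes at (k + 0.5) * st inside [lo, hi)
            k0 = int(np.ceil(lo / st - 0.5))
            k1 = int(np.ceil(hi / st - 0.5))  # exclusive
            k0 = max(k0, 0)
            k1 = min(k1, n_slices)
            if k1 <= k0:
                continue
            v_total[k0:k1] += 1
            if cls == "small":
                v_small[k0:k1] += 1
            elif cls == "large":
                v_large[k0:k1] += 1
    return DepthProfile(st, v_small, v_large, v_total, axis=axis)
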