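"""TIFF / CSV / JSON plumbing with geometry sidecars.

Volumes are stored as multi-page TIFF stacks (one page per z slice) with a
JSON sidecar carrying voxel size, materials and seed; diffraction patterns
as 32-bit float TIFF with a geometry sidecar; tabular outputs as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .diffraction import DetectorGeometry
from .phantoms import LabeledVolume, VesselTreeTruth
from .vessels import DepthProfile, QuantSummary

__all__ = [
    "sidecar_path",
    "write_volume", "read_volume",
    "write_labeled_volume", "read_labeled_volume",
    "write_pattern", "read_pattern",
    "write_truth_csv", "read_truth_csv",
    "write_profile_csv", "write_summary_json",
    "write_skeleton_csv",
]


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def _write_sidecar(path: str | Path, meta: dict) -> None:
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def _read_sidecar(path: str | Path) -> dict:
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing geometry sidecar {sc}")
    return json.loads(sc.read_text())


def write_volume(path: str | Path, volume: np.ndarray, meta: dict) -> None:
    """Multi-page TIFF stack (page = z slice) + JSON sidecar."""
    tifffile.imwrite(str(path), np.asarray(volume))
    _write_sidecar(path, meta)


def read_volume(path: str | Path) -> tuple[np.ndarray, dict]:
    return tifffile.imread(str(path)), _read_sidecar(path)


def write_labeled_volume(path: str | Path, vol: LabeledVolume,
                         seed: int | None = None) -> None:
    write_volume(path, vol.labels.astype(np.uint8), {
        "voxel_size_um": vol.voxel_size_um,
        "materials": {str(k): v for k, v in vol.materials.items()},
        "seed": seed,
    })


def read_labeled_volume(path: str | Path) -> LabeledVolume:
    labels, meta = read_volume(path)
    materials = {int(k): v for k, v in meta.get("materials", {}).items()}
    return LabeledVolume(labels, float(meta["voxel_size_um"]), materials)


def write_pattern(path: str | Path, pattern: np.ndarray,
                  geom: DetectorGeometry) -> None:
    tifffile.imwrite(str(path), np.asarray(pattern, dtype=np.float32))
    _write_sidecar(path, dataclasses.asdict(geom))


def read_pattern(path: str | Path) -> tuple[np.ndarray, DetectorGeometry]:
    pattern = tifffile.imread(str(path))
    meta = _read_sidecar(path)
    try:
        geom = DetectorGeometry(
            wavelength_nm=float(meta["wavelength_nm"]),
            distance_mm=float(meta["distance_mm"]),
            pixel_size_mm=float(meta["pixel_size_mm"]),
            shape=tuple(meta["shape"]),
            beam_center=tuple(meta["beam_center"]) if meta.get("beam_center")
            else None)
    except KeyError as exc:
        raise ValueError(f"geometry sidecar missing field {exc}") from exc
    return pattern, geom


def write_truth_csv(path: str | Path, truth: VesselTreeTruth) -> None:
    rows = []
    for tid, (poly, radii) in enumerate(zip(truth.polylines, truth.radii)):
        for i, (p, r) in enumerate(zip(poly, radii)):
            rows.append({"tree_id": tid, "point_index": i,
                         "x": p[0], "y": p[1], "z": p[2], "radius": r})
    pd.DataFrame(rows, columns=["tree_id", "point_index",
                                "x", "y", "z", "radius"]).to_csv(path,
                                                                 index=False)


def read_truth_csv(path: str | Path,
                   extent_um: tuple[float, float, float] = (0, 0, 0)
                   ) -> VesselTreeTruth:
    df = pd.read_csv(path)
    truth = VesselTreeTruth(extent_um=extent_um)
    for _, grp in df.groupby("tree_id", sort=True):
        grp = grp.sort_values("point_index")
        truth.polylines.append(grp[["x", "y", "z"]].to_numpy(float))
        truth.radii.append(grp["radius"].to_numpy(float))
        truth.topology.append(-1)
    return truth


def write_profile_csv(path: str | Path, profile: DepthProfile) -> None:
    profile.to_dataframe().to_csv(path, index=False)


def write_summary_json(path: str | Path, summary: QuantSummary) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2))


def write_skeleton_csv(path: str | Path, sg) -> None:
    rows = []
    for u, v, d in sg.graph.edges(data=True):
        cu = sg.graph.nodes[u]["coord_um"]
        cv = sg.graph.nodes[v]["coord_um"]
        rows.append({"node_u": u, "node_v": v, "length_um": d["length_um"],
                     "u_z": cu[0], "u_y": cu[1], "u_x": cu[2],
                     "v_z": cv[0], "v_y": cv[1], "v_x": cv[2]})
    pd.DataFrame(rows, columns=["node_u", "node_v", "length_um",
                                "u_z", "u_y", "u_x",
                                "v_z", "v_y", "v_x"]).to_csv(path, index=False)
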