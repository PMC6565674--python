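"""Readers and writers for the pipeline's on-disk formats.

Volumes and supervoxel sets use HDF5 (h5py); fingerprints, summaries and
QA reports are plain CSV; selections and ground truth are JSON; dendrograms
export to Newick text for external tree viewers.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .atlas import AtlasLabels
from .clustering import ClusterTree, SelectionResult
from .connectivity import Fingerprint, metric_labels
from .synth.lfp import LFPTrace
from .voxels import SupervoxelSet, VolumeSeries


def write_volume(path: str | Path, volume: VolumeSeries, atlas: AtlasLabels | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("volume", data=volume.data.astype(np.float32), compression="gzip")
        f.create_dataset("times", data=np.arange(volume.n_frames) / volume.frame_rate)
        f.attrs["frame_rate"] = volume.frame_rate
        f.attrs["voxel_size"] = volume.voxel_size
        if atlas is not None:
            f.create_dataset("atlas", data=atlas.label_volume)
            f.attrs["region_names"] = [n.encode() for n in atlas.region_names]


def read_volume(path: str | Path) -> tuple[VolumeSeries, AtlasLabels | None]:
    with h5py.File(path, "r") as f:
        vol = VolumeSeries(
            data=f["volume"][...],
            frame_rate=float(f.attrs["frame_rate"]),
            voxel_size=tuple(f.attrs["voxel_size"]),
        )
        atlas = None
        if "atlas" in f:
            atlas = AtlasLabels(
                label_volume=f["atlas"][...],
                region_names=[
                    n.decode() if isinstance(n, bytes) else str(n)
                    for n in f.attrs["region_names"]
                ],
                voxel_size=tuple(f.attrs["voxel_size"]),
            )
    return vol, atlas


def write_volume_tiff(path: str | Path, volume: VolumeSeries, z: int = 0) -> None:
    """One z-plane of the recording as a multi-page (time) TIFF."""
    import tifffile

    tifffile.imwrite(path, volume.data[:, z].astype(np.float32))


def write_ground_truth(path: str | Path, truth) -> None:
    """Planted ground truth as JSON (keys serialized as 'i-j|state')."""
    payload = {
        "condition": truth.condition,
        "planted_connectivity": {
            f"{i}-{j}|{s}": v for (i, j, s), v in sorted(truth.planted_connectivity.items())
        },
        "drug_effect": {
            f"{i}-{j}|{s}": v for (i, j, s), v in sorted(truth.drug_effect.items())
        },
        "seizure_times": list(truth.seizure_times),
        "neuron_positions": [list(map(int, p)) for p in truth.neuron_positions],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_supervoxels(path: str | Path, sv: SupervoxelSet, csv_path: str | Path | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["frame_rate"] = sv.frame_rate
        f.attrs["voxel_size"] = sv.voxel_size
        f.create_dataset("traces", data=sv.traces.astype(np.float32), compression="gzip")
        if sv.dff is not None:
            f.create_dataset("dff", data=sv.dff.astype(np.float32), compression="gzip")
        flat = np.vstack(sv.members) if sv.members else np.empty((0, 3), dtype=int)
        counts = np.array([len(m) for m in sv.members])
        f.create_dataset("member_voxels", data=flat)
        f.create_dataset("member_counts", data=counts)
        if sv.region_of is not None:
            f.create_dataset("region_of", data=sv.region_of)
        if sv.active is not None:
            f.create_dataset("active", data=sv.active)
        f.create_dataset("diameter_um", data=sv.diameter_um)
    if csv_path is not None:
        pd.DataFrame({
            "id": np.arange(sv.n_supervoxels),
            "region": sv.region_of if sv.region_of is not None else -1,
            "n_voxels": [len(m) for m in sv.members],
            "diameter_um": sv.diameter_um,
            "active": sv.active if sv.active is not None else False,
        }).to_csv(csv_path, index=False)


def read_supervoxels(path: str | Path) -> SupervoxelSet:
    with h5py.File(path, "r") as f:
        counts = f["member_counts"][...]
        flat = f["member_voxels"][...]
        members = list(np.split(flat, np.cumsum(counts)[:-1])) if counts.size else []
        return SupervoxelSet(
            members=members,
            traces=f["traces"][...],
            frame_rate=float(f.attrs["frame_rate"]),
            voxel_size=tuple(f.attrs["voxel_size"]),
            region_of=f["region_of"][...] if "region_of" in f else None,
            dff=f["dff"][...] if "dff" in f else None,
            active=f["active"][...] if "active" in f else None,
            diameter_um=f["diameter_um"][...],
        )


def fingerprints_to_tidy(fps: dict[str, Fingerprint], atlas: AtlasLabels) -> pd.DataFrame:
    names = atlas.region_names
    rows = []
    for group, fp in fps.items():
        for (i, j, s), v in fp.values.items():
            rows.append({
                "group": group,
                "area_i": names[i - 1],
                "area_j": names[j - 1],
                "state": s,
                "value": v,
                "n_larvae": fp.n_larvae,
            })
    return pd.DataFrame(rows)


def fingerprints_to_wide(fps: dict[str, Fingerprint], atlas: AtlasLabels) -> pd.DataFrame:
    mat = pd.DataFrame({g: fp.values for g, fp in fps.items()}).T
    mat.columns = metric_labels(mat.columns, atlas)
    mat.index.name = "group"
    return mat


def write_newick(path: str | Path, tree: ClusterTree) -> None:
    """Dendrogram as Newick text with merge heights as branch lengths."""
    root = hierarchy.to_tree(tree.linkage)

    def rec(node) -> str:
        if node.is_leaf():
            return tree.labels[node.id].replace(" ", "_")
        left, right = rec(node.left), rec(node.right)
        bl_l = node.dist - (0 if node.left.is_leaf() else node.left.dist)
        bl_r = node.dist - (0 if node.right.is_leaf() else node.right.dist)
        return f"({left}:{bl_l:.6g},{right}:{bl_r:.6g})"

    Path(path).write_text(rec(root) + ";\n")


def write_selection(path: str | Path, sel: SelectionResult) -> None:
    Path(path).write_text(json.dumps(asdict(sel), indent=2) + "\n")


def write_lfp_csv(path: str | Path, trace: LFPTrace) -> None:
    t = np.arange(len(trace.samples)) / trace.rate
    pd.DataFrame({"time_s": t, "mV": trace.samples}).to_csv(path, index=False)


def read_lfp_csv(path: str | Path) -> LFPTrace:
    df = pd.read_csv(path)
    dt = np.diff(df["time_s"].values[:2])[0]
    return LFPTrace(samples=df["mV"].values, rate=float(1.0 / dt))
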