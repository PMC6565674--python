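"""Synthetic 3D brain atlas with labeled anatomical regions.

The analysis pipeline segments recordings into brain areas using a labeled
atlas volume. Eleven canonical larval-zebrafish areas are used by default:
cerebellum (Ce), left/right hindbrain (HBl/HBr), left/right olfactory bulb
(OBl/OBr), left/right optic tectum (OTl/OTr), pallium (Pa), sub-pallium
(SPa), habenula (Ha) and thalamus (Th). The synthetic atlas tiles a
brain-shaped (ellipsoidal) mask with connected Voronoi cells so that every
region is a contiguous blob and the labels form a partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical region abbreviations used throughout the pipeline.
REGION_NAMES = [
    "Ce", "HBl", "HBr", "OBl", "OBr", "OTl", "OTr", "Pa", "SPa", "Ha", "Th",
]


@dataclass
class AtlasLabels:
    """Labeled brain-atlas volume.

    Attributes
    ----------
    label_volume
        3D integer grid (z, y, x); 0 is background, regions are 1..R.
    region_names
        Ordered names; region id ``k`` corresponds to ``region_names[k-1]``.
    voxel_size
        (dz, dy, dx) in micrometres.
    """

    label_volume: np.ndarray
    region_names: list[str] = field(default_factory=lambda: list(REGION_NAMES))
    voxel_size: tuple[float, float, float] = (40.0, 1.6, 1.6)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def region_id(self, name: str) -> int:
        return self.region_names.index(name) + 1

    def voxels_of(self, region_id: int) -> np.ndarray:
        """(n, 3) array of (z, y, x) indices belonging to a region."""
        return np.argwhere(self.label_volume == region_id)

    def validate(self) -> None:
        labels = self.label_volume
        ids = np.unique(labels)
        expect = np.arange(0, self.n_regions + 1)
        present = ids[ids > 0]
        if not np.array_equal(present, np.arange(1, self.n_regions + 1)):
            raise ValueError(
                f"atlas labels {present.tolist()} do not cover regions "
                f"1..{self.n_regions}"
            )
        if labels.ndim != 3:
            raise ValueError("label_volume must be 3D (z, y, x)")


def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal mask occupying most of the grid -- the 'brain'."""
    nz, ny, nx = shape
    z, y, x = np.ogrid[:nz, :ny, :nx]
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    rz, ry, rx = max(nz / 2 - 0.5, 0.5), max(ny / 2 - 0.5, 0.5), max(nx / 2 - 0.5, 0.5)
    return ((z - cz) / rz) ** 2 + ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def generate_atlas(
    shape: tuple[int, int, int] = (8, 64, 64),
    n_regions: int = 11,
    seed: int = 0,
    region_names: list[str] | None = None,
    voxel_size: tuple[float, float, float] = (40.0, 1.6, 1.6),
) -> AtlasLabels:
    """Generate a deterministic labeled atlas of connected regions.

    Region seeds are drawn by farthest-point sampling inside an ellipsoidal
    brain mask and every mask voxel is assigned to its nearest seed. Voronoi
    cells of a convex mask are convex, hence connected.

    Raises
    ------
    ValueError
        If the mask holds fewer voxels than ``n_regions``.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if region_names is None:
        region_names = list(REGION_NAMES) if n_regions == 11 else [
            f"R{i + 1}" for i in range(n_regions)
        ]
    if len(region_names) != n_regions:
        raise ValueError("len(region_names) must equal n_regions")

    mask = _brain_mask(shape)
    coords = np.argwhere(mask).astype(float)
    if coords.shape[0] < n_regions:
        raise ValueError(
            f"shape {shape} too small: brain mask has {coords.shape[0]} voxels "
            f"but {n_regions} regions requested"
        )

    rng = np.random.default_rng(seed)
    # Farthest-point sampling for well-spread, deterministic seeds.
    first = rng.integers(coords.shape[0])
    seed_idx = [int(first)]
    d = np.linalg.norm(coords - coords[first], axis=1)
    for _ in range(n_regions - 1):
        nxt = int(np.argmax(d))
        seed_idx.append(nxt)
        d = np.minimum(d, np.linalg.norm(coords - coords[nxt], axis=1))
    seeds = coords[seed_idx]

    dist = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2)
    assign = np.argmin(dist, axis=1) + 1

    labels = np.zeros(shape, dtype=np.int32)
    labels[tuple(coords.astype(int).T)] = assign
    atlas = AtlasLabels(labels, region_names, voxel_size)
    atlas.validate()
    return atlas
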