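"""Reduce 4D fluorescence recordings to active supervoxels with dF/F traces.

Stages, applied per recording:

1. *Time-varying voxel filter.* The time-averaged signal of a voxel is the
   sample standard deviation of its intensity trace. Voxels whose signal is
   at least one SD below the per-slice mean (computed over the pre-stimulus
   window) are discarded as non-time-varying.
2. *Supervoxel merging.* Adjacent, highly time-correlated voxels are merged
   with k-means on trace features, the number of clusters chosen per slice
   by k-fold cross-validated reconstruction error; clusters are split into
   spatially connected components so every supervoxel is contiguous.
3. *dF/F extraction.* The baseline F of each supervoxel is a centred 20-s
   sliding mean (shrinking at the edges); dF/F = (f - F) / F.
4. *Active-supervoxel detection.* A supervoxel is active if its resting
   dF/F contains an excursion above a robust noise threshold
   (median + c * 1.4826 * MAD of its own resting trace).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .atlas import AtlasLabels
from .protocol import windows_to_frames

logger = logging.getLogger(__name__)


@dataclass
class VolumeSeries:
    """4D fluorescence recording (t, z, y, x) with acquisition geometry."""

    data: np.ndarray
    frame_rate: float
    voxel_size: tuple[float, float, float] = (40.0, 1.6, 1.6)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (t, z, y, x)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class SupervoxelSet:
    """Partition of retained voxels into contiguous co-varying units."""

    members: list[np.ndarray]            # per supervoxel: (n, 3) int (z, y, x)
    traces: np.ndarray                   # (n_sv, T) mean raw intensity
    frame_rate: float
    voxel_size: tuple[float, float, float] = (40.0, 1.6, 1.6)
    region_of: np.ndarray | None = None  # (n_sv,) atlas region id (0 = none)
    dff: np.ndarray | None = None        # (n_sv, T)
    active: np.ndarray | None = None     # (n_sv,) bool
    diameter_um: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_supervoxels(self) -> int:
        return len(self.members)

    def assign_regions(self, atlas: AtlasLabels) -> None:
        """Region of a supervoxel = majority atlas label of its members."""
        ids = np.empty(self.n_supervoxels, dtype=int)
        for k, m in enumerate(self.members):
            labels = atlas.label_volume[m[:, 0], m[:, 1], m[:, 2]]
            vals, counts = np.unique(labels, return_counts=True)
            ids[k] = vals[np.argmax(counts)]
        self.region_of = ids

    def in_region(self, region_id: int, active_only: bool = True) -> np.ndarray:
        """Indices of supervoxels assigned to a region."""
        if self.region_of is None:
            raise ValueError("regions not assigned; call assign_regions first")
        sel = self.region_of == region_id
        if active_only:
            if self.active is None:
                raise ValueError("activity not computed; call detect_active_supervoxels")
            sel &= self.active
        return np.flatnonzero(sel)


def time_averaged_signal(trace: np.ndarray) -> float:
    """Sample standard deviation of an intensity trace.

    For a trace **f** of length T with time-mean f0, returns
    sqrt(sum((f - f0)^2) / (T - 1)); zero iff the trace is constant.
    """
    f = np.asarray(trace, dtype=float)
    if f.ndim != 1 or f.size < 2:
        raise ValueError("trace must be 1D with at least 2 samples")
    return float(np.std(f, ddof=1))


def select_timevarying_voxels(
    volume: VolumeSeries, window: tuple[float, float]
) -> np.ndarray:
    """Boolean (z, y, x) mask of voxels retained as time-varying.

    Statistics are computed per z-slice over the pre-stimulus ``window``
    (half-open, seconds). A voxel is kept iff s > mean_slice(s) - sd_slice(s)
    (strict), so a degenerate slice where every voxel has identical signal
    keeps all voxels.
    """
    frames = windows_to_frames([window], volume.frame_rate, volume.n_frames)
    if frames.size < 2:
        raise ValueError("pre-stimulus window must contain at least 2 frames")
    data = volume.data[frames]  # (Tw, z, y, x)
    s = np.std(data, axis=0, ddof=1)
    mask = np.zeros(s.shape, dtype=bool)
    for z in range(s.shape[0]):
        sl = s[z]
        if sl.size == 0:
            logger.warning("slice %d is empty; retained mask empty", z)
            continue
        cutoff = sl.mean() - sl.std(ddof=1 if sl.size > 1 else 0)
        mask[z] = sl > cutoff
    return mask


def _sliding_mean(x: np.ndarray, width: int) -> np.ndarray:
    """Centred sliding mean along the last axis with shrinking edge windows."""
    T = x.shape[-1]
    half_lo = width // 2
    half_hi = width - half_lo
    cs = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x], axis=-1), axis=-1)
    t = np.arange(T)
    lo = np.clip(t - half_lo, 0, T)
    hi = np.clip(t + half_hi, 0, T)
    return (cs[..., hi] - cs[..., lo]) / (hi - lo)


def compute_dff(
    trace: np.ndarray, rate: float, baseline_window: float = 20.0
) -> np.ndarray:
    """dF/F with a centred sliding-mean baseline.

    F(t) is the mean intensity over a ``baseline_window``-second window
    centred on t (shrinking at the recording edges); dF/F = (f - F) / F.
    Accepts a single trace or a (n, T) matrix.
    """
    f = np.asarray(trace, dtype=float)
    width = int(round(baseline_window * rate))
    if f.shape[-1] <= width:
        raise ValueError(
            f"trace length {f.shape[-1]} must exceed baseline window "
            f"({width} frames)"
        )
    base = _sliding_mean(f, width)
    if np.any(base <= 0):
        raise ValueError("non-positive baseline encountered; raw intensities must be positive")
    return (f - base) / base


def _cluster_tile(
    Z: np.ndarray,
    coords: np.ndarray,
    slice_shape: tuple[int, int],
    k_range: range,
    cv_folds: int,
    seed: int,
    coord_weight: float,
    n_pca: int,
) -> np.ndarray:
    """k-means labels for one neighborhood's standardized traces.

    Features are unit-normalized standardized traces (squared distance then
    equals 2(1 - r)) reduced by PCA, concatenated with scaled in-plane
    coordinates. k is chosen by cross-validated reconstruction error over
    held-out timepoints: each voxel's held-out trace is predicted by the
    mean of the *other* members of its cluster (singletons predict the
    voxel's own time-mean), so spurious splits and spurious merges both
    cost error. Ties go to the smallest k.
    """
    n_vox, T = Z.shape
    if n_vox == 1:
        return np.zeros(1, dtype=int)
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    U = np.divide(Z, norms, out=np.zeros_like(Z), where=norms > 0)
    ny, nx = slice_shape
    C = coords.astype(float) / [max(ny - 1, 1), max(nx - 1, 1)] * coord_weight

    def features(time_idx: np.ndarray) -> np.ndarray:
        sub = U[:, time_idx]
        d = min(n_pca, n_vox - 1, sub.shape[1])
        if d >= 2:
            sub = PCA(n_components=d, random_state=seed).fit_transform(sub)
        return np.hstack([sub, C])

    folds = np.array_split(np.arange(T), cv_folds)
    errors: dict[int, float] = {}
    ks = [k for k in k_range if k <= n_vox]
    for k in ks:
        err = 0.0
        for fi, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(T), test_idx, assume_unique=True)
            km = KMeans(n_clusters=k, n_init=4, random_state=seed + fi)
            labels = km.fit_predict(features(train_idx))
            Zt = Z[:, test_idx]
            for c in np.unique(labels):
                m = labels == c
                n_c = int(m.sum())
                block = Zt[m]
                if n_c == 1:
                    err += float(np.sum(block**2))
                    continue
                tot = block.sum(axis=0)
                pred = (tot[None, :] - block) / (n_c - 1)
                err += float(np.sum((block - pred) ** 2))
        errors[k] = err
    # Smallest k within 0.5% of the minimum (one-SE-style rule): noise
    # plateaus in k should not trigger spurious splits.
    e_min = min(errors.values())
    best_k = min(k for k in ks if errors[k] <= e_min * 1.005 + 1e-12)
    km = KMeans(n_clusters=best_k, n_init=10, random_state=seed)
    return km.fit_predict(features(np.arange(T)))


def _cluster_slice(
    Z: np.ndarray,
    coords: np.ndarray,
    slice_shape: tuple[int, int],
    k_range: range | None,
    cv_folds: int,
    seed: int,
    coord_weight: float,
    n_pca: int,
    tile: int,
) -> np.ndarray:
    """Cluster a slice neighborhood by neighborhood.

    The slice is divided into ``tile`` x ``tile`` neighborhoods and k-means
    with cross-validated k runs within each, so the cluster budget scales
    with local voxel count and adjacent correlated voxels are separated
    from the (much larger) background cloud. Fragments cut by tile borders
    are re-joined later by the correlation merge pass.
    """
    labels = np.full(len(coords), -1, dtype=int)
    offset = 0
    ty = np.minimum(coords[:, 0] // tile, max((slice_shape[0] - 1) // tile, 0))
    tx = np.minimum(coords[:, 1] // tile, max((slice_shape[1] - 1) // tile, 0))
    for key in np.unique(ty * 10**6 + tx):
        sel = np.flatnonzero(ty * 10**6 + tx == key)
        ks = k_range if k_range is not None else range(1, min(12, len(sel)) + 1)
        sub = _cluster_tile(
            Z[sel], coords[sel], slice_shape, ks, cv_folds,
            seed + int(key % 1000), coord_weight, n_pca,
        )
        labels[sel] = sub + offset
        offset += int(sub.max()) + 1
    return labels


def _merge_adjacent(
    members: list[np.ndarray], traces: list[np.ndarray], merge_r: float
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Greedily merge spatially adjacent supervoxels whose mean traces
    correlate above ``merge_r`` (re-joins fragments of one unit that were
    split by clustering-neighborhood borders)."""

    def adjacent(a: np.ndarray, b: np.ndarray) -> bool:
        return bool(
            (np.abs(a[:, None, :] - b[None, :, :]).max(axis=2) <= 1).any()
        )

    changed = True
    while changed:
        changed = False
        n = len(members)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                if members[i][0, 0] != members[j][0, 0]:  # different slice
                    continue
                if not adjacent(members[i], members[j]):
                    continue
                si, sj = traces[i], traces[j]
                if si.std() == 0 or sj.std() == 0:
                    continue
                r = float(np.corrcoef(si, sj)[0, 1])
                if r > merge_r and (best is None or r > best[0]):
                    best = (r, i, j)
        if best is not None:
            _, i, j = best
            wi, wj = len(members[i]), len(members[j])
            traces[i] = (traces[i] * wi + traces[j] * wj) / (wi + wj)
            members[i] = np.vstack([members[i], members[j]])
            del members[j], traces[j]
            changed = True
    return members, traces


def build_supervoxels(
    volume: VolumeSeries,
    mask: np.ndarray,
    atlas: AtlasLabels | None = None,
    k_range: range | None = None,
    cv_folds: int = 3,
    seed: int = 0,
    coord_weight: float = 0.5,
    n_pca: int = 20,
    tile: int = 12,
    merge_r: float = 0.9,
    max_cluster_frames: int = 2000,
) -> SupervoxelSet:
    """Merge retained voxels into contiguous, co-varying supervoxels.

    Works slice by slice (planes are acquired far apart along z), clustering
    each slice neighborhood by neighborhood. Clusters from k-means are split
    into 8-connected in-plane components, so member voxels of a supervoxel
    are always spatially adjacent; fragments split by neighborhood borders
    are re-joined when their traces correlate above ``merge_r``.
    """
    if not np.any(mask):
        raise ValueError("no retained voxels")
    members: list[np.ndarray] = []
    traces: list[np.ndarray] = []
    T = volume.n_frames
    stride = max(T // max_cluster_frames, 1)
    for z in range(mask.shape[0]):
        coords = np.argwhere(mask[z])
        if coords.size == 0:
            continue
        X = volume.data[:, z, coords[:, 0], coords[:, 1]].T.astype(float)  # (n, T)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        Z = np.divide(X - mu, sd, out=np.zeros_like(X), where=sd > 0)
        labels = _cluster_slice(
            Z[:, ::stride], coords, mask.shape[1:], k_range, cv_folds, seed,
            coord_weight, n_pca, tile,
        )
        # Split each k-means cluster into spatially connected components.
        row_of = {(y, x): i for i, (y, x) in enumerate(map(tuple, coords))}
        for c in np.unique(labels):
            sel = coords[labels == c]
            grid = np.zeros(mask.shape[1:], dtype=bool)
            grid[sel[:, 0], sel[:, 1]] = True
            comp, n_comp = ndimage.label(grid, structure=np.ones((3, 3)))
            for ci in range(1, n_comp + 1):
                yx = np.argwhere(comp == ci)
                rows = [row_of[(y, x)] for y, x in map(tuple, yx)]
                members.append(np.column_stack([np.full(len(yx), z), yx]))
                traces.append(X[rows].mean(axis=0))
    members, traces = _merge_adjacent(members, traces, merge_r)
    trace_mat = np.vstack(traces) if traces else np.empty((0, T))
    dz, dy, dx = volume.voxel_size
    diam = np.array([2.0 * np.sqrt(len(m) * dy * dx / np.pi) for m in members])
    sv = SupervoxelSet(
        members=members,
        traces=trace_mat,
        frame_rate=volume.frame_rate,
        voxel_size=volume.voxel_size,
        diameter_um=diam,
    )
    if atlas is not None:
        sv.assign_regions(atlas)
    return sv


def detect_active_supervoxels(
    sv: SupervoxelSet,
    resting_window: tuple[float, float],
    c: float = 4.5,
    baseline_window: float = 20.0,
) -> SupervoxelSet:
    """Flag supervoxels with significant dF/F excursions as active.

    Computes dF/F if absent, then marks a supervoxel active iff the maximum
    of its resting-window dF/F exceeds median + c * 1.4826 * MAD of the same
    resting trace. The default c = 4.5 sits above the expected extreme of a
    plain-noise trace over ~10^3-frame resting windows (sqrt(2 ln T) ~ 3.8),
    so stationary noise is rarely flagged while calcium transients, which
    rise an order of magnitude above the noise floor, always are.
    """
    if sv.dff is None:
        sv.dff = compute_dff(sv.traces, sv.frame_rate, baseline_window)
    frames = windows_to_frames([resting_window], sv.frame_rate, sv.dff.shape[1])
    rest = sv.dff[:, frames]
    med = np.median(rest, axis=1)
    mad = np.median(np.abs(rest - med[:, None]), axis=1)
    thresh = med + c * 1.4826 * mad
    sv.active = rest.max(axis=1) > thresh
    return sv


def process_volume(
    volume: VolumeSeries,
    atlas: AtlasLabels,
    resting_window: tuple[float, float],
    c: float = 4.5,
    baseline_window: float = 20.0,
    **supervoxel_kwargs,
) -> SupervoxelSet:
    """Full reduction: voxel filter -> supervoxels -> dF/F -> active flags."""
    mask = select_timevarying_voxels(volume, resting_window)
    sv = build_supervoxels(volume, mask, atlas=atlas, **supervoxel_kwargs)
    sv.dff = compute_dff(sv.traces, sv.frame_rate, baseline_window)
    return detect_active_supervoxels(sv, resting_window, c, baseline_window)
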