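"""Larval skeleton tracking, locomotor features, and the side-effect score.

Each silhouette frame is skeletonized; the tips of head and tail are found
as skeleton endpoints (spurious branches pruned) and five equally spaced
vertex points are placed along the centreline, head first. The two anterior
points define the body centreline for the swimming-velocity features; the
three posterior points define the tail for the bending features. Six
features summarise a recording:

- ``FV_mean``: mean forward velocity (displacement parallel to the body
  centreline, px/s),
- ``AV_mean`` / ``AV_STD``: mean and SD of the velocity perpendicular to
  the centreline (px/s),
- ``HV_pct``: percentage of frames spent above the high-velocity threshold
  FV_mean + FV_STD,
- ``TB_mean``: mean summed absolute tail vertex angle (degrees),
- ``dTB_mean``: mean summed frame-to-frame tail-angle change (degrees/s).

The combined side-effect score of a treatment group is the root mean
square of the six features' fractional divergences from the untreated
baseline group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

logger = logging.getLogger(__name__)

FEATURE_NAMES = ["FV_mean", "AV_mean", "AV_STD", "HV_pct", "TB_mean", "dTB_mean"]


@dataclass
class SkeletonTrack:
    """5-point skeleton per frame, head to tail, (x, y) pixel coordinates."""

    points: np.ndarray          # (T, 5, 2), NaN where missing
    frame_rate: float
    missing: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __post_init__(self) -> None:
        if self.missing.size == 0:
            self.missing = np.isnan(self.points[:, 0, 0])

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]


@dataclass
class BehavioralFeatures:
    FV_mean: float
    AV_mean: float
    AV_STD: float
    HV_pct: float
    TB_mean: float
    dTB_mean: float

    def as_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in FEATURE_NAMES})


@dataclass
class SideEffectScore:
    """RMS aggregation of the six behavioral divergences."""

    divergences: dict[str, float]
    x_combined: float
    sd: float
    per_larva: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# Skeleton tracking


_NEIGH = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _skeleton_path(skel: np.ndarray) -> np.ndarray | None:
    """Ordered (row, col) path between the two skeleton endpoints.

    Prunes short spur branches (up to 10 rounds); returns None if no clean
    two-endpoint path remains.
    """
    skel = skel.copy()
    for _ in range(10):
        if skel.sum() < 2:
            return None
        deg = ndimage.convolve(skel.astype(int), _NEIGH, mode="constant")
        ends = np.argwhere(skel & (deg == 1))
        if len(ends) == 2:
            break
        if len(ends) < 2:
            return None
        # Remove the shortest spur: walk from each endpoint to a junction.
        spurs = []
        for e in ends:
            path = [tuple(e)]
            prev = None
            cur = tuple(e)
            while True:
                nbrs = [
                    (cur[0] + dy, cur[1] + dx)
                    for dy in (-1, 0, 1)
                    for dx in (-1, 0, 1)
                    if (dy, dx) != (0, 0)
                    and 0 <= cur[0] + dy < skel.shape[0]
                    and 0 <= cur[1] + dx < skel.shape[1]
                    and skel[cur[0] + dy, cur[1] + dx]
                    and (cur[0] + dy, cur[1] + dx) != prev
                ]
                if len(nbrs) != 1 or deg[cur] >= 3 or len(path) > skel.sum():
                    break
                prev, cur = cur, nbrs[0]
                path.append(cur)
                if deg[cur] >= 3:
                    break
            spurs.append(path)
        shortest = min(spurs, key=len)
        for p in shortest[:-1]:
            skel[p] = False
    else:
        return None

    # BFS along the skeleton from one endpoint to the other.
    start, goal = tuple(ends[0]), tuple(ends[1])
    prev_map: dict[tuple[int, int], tuple[int, int] | None] = {start: None}
    queue = [start]
    while queue:
        cur = queue.pop(0)
        if cur == goal:
            break
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                nxt = (cur[0] + dy, cur[1] + dx)
                if (
                    (dy, dx) != (0, 0)
                    and 0 <= nxt[0] < skel.shape[0]
                    and 0 <= nxt[1] < skel.shape[1]
                    and skel[nxt]
                    and nxt not in prev_map
                ):
                    prev_map[nxt] = cur
                    queue.append(nxt)
    if goal not in prev_map:
        return None
    path = [goal]
    while prev_map[path[-1]] is not None:
        path.append(prev_map[path[-1]])  # type: ignore[arg-type]
    return np.asarray(path[::-1])


def _extend_to_boundary(path: np.ndarray, mask: np.ndarray, width: np.ndarray) -> np.ndarray:
    """Prolong both path ends along their local direction towards the
    silhouette boundary, stopping one local half-width short of it.

    The body is a disk-swept curve, so its silhouette extends beyond the
    centreline tip by the local radius; the medial endpoint therefore sits
    at depth ~radius inside the boundary, which is where the extension
    stops.
    """
    out = [path]
    for end in (0, -1):
        k = min(4, len(path) - 1)
        d = (path[0] - path[k] if end == 0 else path[-1] - path[-1 - k]).astype(float)
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        d = d / norm
        ext = []
        p = path[end].astype(float)
        w0 = width[path[end][0], path[end][1]]
        # Blunt (wide) ends: the EDT falls off sharply past the medial
        # endpoint, so stop almost immediately; sharp tapered ends: the EDT
        # decline is dominated by the taper, so allow ~1 px of slack.
        margin = 0.25 if w0 > 2.5 else 1.0
        for _ in range(mask.shape[0] + mask.shape[1]):
            p = p + d
            q = np.round(p).astype(int)
            if not (
                0 <= q[0] < mask.shape[0]
                and 0 <= q[1] < mask.shape[1]
                and mask[q[0], q[1]]
                and width[q[0], q[1]] > w0 - margin
            ):
                break
            ext.append(q)
        if not ext:
            continue
        if end == 0:
            out.insert(0, np.asarray(ext)[::-1])
        else:
            out.append(np.asarray(ext))
    return np.vstack(out)


def _smooth_path(path: np.ndarray, n_out: int = 200) -> np.ndarray:
    """Sub-pixel centreline: smoothing spline through the pixel path."""
    from scipy.interpolate import splev, splprep

    steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    if arc[-1] == 0 or len(path) < 8:
        return path.astype(float)
    try:
        tck, _u = splprep(
            [path[:, 0].astype(float), path[:, 1].astype(float)],
            u=arc / arc[-1], s=len(path) * 0.4, k=3,
        )
    except Exception:
        return path.astype(float)
    rows, cols = splev(np.linspace(0.0, 1.0, n_out), tck)
    return np.column_stack([rows, cols])


def track_skeleton(frames: np.ndarray, rate: float) -> SkeletonTrack:
    """Track the 5-point skeleton in a stack of binary silhouette frames.

    The head is the endpoint at the wider body end (larger mean silhouette
    width along the first quarter of the centreline); ties fall back to
    continuity with the previous frame. Blank or ambiguous frames are
    flagged missing.
    """
    T = frames.shape[0]
    points = np.full((T, 5, 2), np.nan)
    prev_head: np.ndarray | None = None
    for i in range(T):
        mask = frames[i] > 0
        if not mask.any():
            continue
        path = _skeleton_path(skeletonize(mask))
        if path is None or len(path) < 5:
            continue
        width = ndimage.distance_transform_edt(mask)
        path = _extend_to_boundary(path, mask, width)
        path = _smooth_path(path)
        steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(steps)])
        q = len(path) // 4 + 1
        pp = np.clip(np.round(path).astype(int), 0, np.array(mask.shape) - 1)
        w_a = width[pp[:q, 0], pp[:q, 1]].mean()
        w_b = width[pp[-q:, 0], pp[-q:, 1]].mean()
        if abs(w_a - w_b) > 0.05 * max(w_a, w_b):
            head_first = w_a > w_b
        elif prev_head is not None:
            d_a = np.linalg.norm(path[0][::-1] - prev_head)
            d_b = np.linalg.norm(path[-1][::-1] - prev_head)
            head_first = d_a <= d_b
        else:
            head_first = True
        if not head_first:
            path = path[::-1]
            arc = arc[-1] - arc[::-1]
        targets = np.linspace(0.0, arc[-1], 5)
        rows = np.interp(targets, arc, path[:, 0])
        cols = np.interp(targets, arc, path[:, 1])
        points[i] = np.column_stack([cols, rows])  # (x, y)
        prev_head = points[i, 0]
    return SkeletonTrack(points=points, frame_rate=rate)


# ---------------------------------------------------------------------------
# Features


def _tail_angles(pts: np.ndarray) -> np.ndarray:
    """Signed angle (deg) of each posterior segment vs the body centreline."""
    back = pts[1] - pts[0]
    angles = np.empty(3)
    for k in range(3):
        seg = pts[k + 2] - pts[k + 1]
        angles[k] = np.degrees(
            np.arctan2(back[0] * seg[1] - back[1] * seg[0], back @ seg)
        )
    return angles


def compute_behavioral_features(
    track: SkeletonTrack, smooth_window: float = 0.0
) -> BehavioralFeatures:
    """Six locomotor features from a skeleton track.

    Velocities use displacement of the anterior midpoint between
    consecutive valid frames, decomposed parallel/perpendicular to the body
    centreline. HV_pct is defined as 0 when the forward-velocity SD is 0.
    ``smooth_window`` (s) optionally applies a moving average to the
    instantaneous velocities before the threshold statistics (0 keeps them
    instantaneous).
    """
    valid = ~track.missing
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid frames")
    pts = track.points
    rate = track.frame_rate

    par, perp, dta = [], [], []
    tails = []
    idx = np.flatnonzero(valid)
    for i in idx:
        tails.append(_tail_angles(pts[i]))
    tails_arr = np.asarray(tails)
    if smooth_window > 0:
        w = max(int(round(smooth_window * rate)), 1)
        if tails_arr.shape[0] >= w:
            kernel = np.ones(w) / w
            tails_arr = np.apply_along_axis(
                lambda col: np.convolve(col, kernel, mode="same"), 0, tails_arr
            )
    tb = np.abs(tails_arr).sum(axis=1)

    for a, b in zip(idx, idx[1:]):
        if b - a != 1:
            continue
        u = pts[a, 0] - pts[a, 1]
        nu = np.linalg.norm(u)
        if nu == 0:
            continue
        u = u / nu
        n = np.array([-u[1], u[0]])
        d = (pts[b, 0] + pts[b, 1]) / 2 - (pts[a, 0] + pts[a, 1]) / 2
        par.append((d @ u) * rate)
        perp.append((d @ n) * rate)  # signed; magnitude taken after smoothing
        ka, kb = np.searchsorted(idx, a), np.searchsorted(idx, b)
        dta.append(np.abs(tails_arr[kb] - tails_arr[ka]).sum() * rate)

    par_arr = np.asarray(par)
    perp_arr = np.asarray(perp)
    if smooth_window > 0 and par_arr.size:
        w = max(int(round(smooth_window * rate)), 1)
        kernel = np.ones(w) / w
        if par_arr.size >= w:
            par_arr = np.convolve(par_arr, kernel, mode="valid")
            perp_arr = np.convolve(perp_arr, kernel, mode="valid")
    perp_arr = np.abs(perp_arr)
    fv_mean = float(par_arr.mean()) if par_arr.size else 0.0
    fv_std = float(par_arr.std(ddof=1)) if par_arr.size > 1 else 0.0
    hv = 0.0
    if fv_std > 0:
        hv = 100.0 * float(np.mean(par_arr > fv_mean + fv_std))
    return BehavioralFeatures(
        FV_mean=fv_mean,
        AV_mean=float(perp_arr.mean()) if perp_arr.size else 0.0,
        AV_STD=float(perp_arr.std(ddof=1)) if perp_arr.size > 1 else 0.0,
        HV_pct=hv,
        TB_mean=float(tb.mean()),
        dTB_mean=float(np.mean(dta)) if dta else 0.0,
    )


def track_from_points(points: np.ndarray, rate: float) -> SkeletonTrack:
    """Wrap a (T, 5, 2) ground-truth vertex array as a SkeletonTrack."""
    return SkeletonTrack(points=np.asarray(points, dtype=float), frame_rate=rate)


# ---------------------------------------------------------------------------
# Side-effect score


def _divergences(features: pd.DataFrame, baseline_means: pd.Series) -> pd.DataFrame:
    div = {}
    for f in FEATURE_NAMES:
        base = baseline_means[f]
        delta = (features[f] - base).abs()
        if base == 0:
            logger.warning("baseline mean for %s is 0; using absolute difference", f)
            div[f] = delta
        else:
            div[f] = delta / abs(base)
    return pd.DataFrame(div)


def side_effect_score(
    treated: pd.DataFrame, baseline: pd.DataFrame
) -> SideEffectScore:
    """Combined behavioral score of a treated group vs untreated baseline.

    ``treated`` and ``baseline`` hold one row per larva and the six feature
    columns. Divergence of a feature is the absolute fractional deviation
    of the treated group mean from the baseline group mean; the combined
    score is the RMS of the six divergences. The SD is computed over
    per-larva combined scores.
    """
    if treated.empty or baseline.empty:
        raise ValueError("both groups must be non-empty")
    base_means = baseline[FEATURE_NAMES].mean()
    group_div = _divergences(
        treated[FEATURE_NAMES].mean().to_frame().T, base_means
    ).iloc[0]
    x_combined = float(np.sqrt(np.mean(group_div.values**2)))
    per_larva_div = _divergences(treated[FEATURE_NAMES], base_means)
    per_larva = np.sqrt((per_larva_div**2).mean(axis=1)).to_numpy()
    sd = float(np.std(per_larva, ddof=1)) if len(per_larva) > 1 else 0.0
    return SideEffectScore(
        divergences=group_div.to_dict(),
        x_combined=x_combined,
        sd=sd,
        per_larva=per_larva,
    )
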