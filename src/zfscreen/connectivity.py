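"""Inter-area correlation fingerprints and divergence maps.

Functional connectivity between two brain areas is the mean absolute
Pearson correlation over all pairs of active supervoxels (one from each
area), computed on dF/F traces restricted to the frames of an activity
state. A condition's fingerprint collects this metric for every area pair
and state -- 55 pairs x 3 states = 165 metrics for the 11-region atlas --
averaged over the larvae of the group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import AtlasLabels
from .protocol import STATES, StateWindows, segment_states, windows_to_frames  # noqa: F401
from .voxels import SupervoxelSet

logger = logging.getLogger(__name__)

#: A state contributing fewer frames than this is rejected for correlation.
MIN_FRAMES = 100


@dataclass
class Fingerprint:
    """Group-level connectivity fingerprint.

    ``values`` is indexed by (area_i, area_j, state) with i < j.
    """

    values: pd.Series
    n_larvae: int

    def __len__(self) -> int:
        return len(self.values)


def area_pairs(n_regions: int) -> list[tuple[int, int]]:
    """All unordered region-id pairs (i < j)."""
    return list(combinations(range(1, n_regions + 1), 2))


def metric_index(n_regions: int, states: tuple[str, ...] = STATES) -> pd.MultiIndex:
    """MultiIndex over (area_i, area_j, state) in canonical order."""
    tuples = [(i, j, s) for (i, j) in area_pairs(n_regions) for s in states]
    return pd.MultiIndex.from_tuples(tuples, names=["area_i", "area_j", "state"])


def metric_labels(index: pd.MultiIndex, atlas: AtlasLabels) -> list[str]:
    """Readable labels like ``"Pa-Th|pre"`` for a metric index."""
    names = atlas.region_names
    return [f"{names[i - 1]}-{names[j - 1]}|{s}" for i, j, s in index]


def _cross_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between every row of X and every row of Y (zero-variance
    rows yield NaN)."""
    def standardize(A: np.ndarray) -> np.ndarray:
        mu = A.mean(axis=1, keepdims=True)
        sd = A.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(sd > 0, (A - mu) / sd, np.nan)

    Zx, Zy = standardize(X), standardize(Y)
    return (Zx @ Zy.T) / X.shape[1]


def inter_area_correlation(
    sv: SupervoxelSet,
    pair: tuple[int, int],
    windows: list[tuple[float, float]],
    active_only: bool = True,
) -> float:
    """Mean absolute Pearson correlation between two areas' supervoxels.

    Computed on dF/F restricted to the concatenated ``windows``. Returns
    NaN (a missing metric) if either area has no active supervoxel or the
    windows contribute fewer than ``MIN_FRAMES`` frames.
    """
    i, j = min(pair), max(pair)
    if sv.dff is None:
        raise ValueError("dF/F not computed")
    frames = windows_to_frames(windows, sv.frame_rate, sv.dff.shape[1])
    if frames.size < MIN_FRAMES:
        logger.warning("pair (%d, %d): only %d frames available; metric missing", i, j, frames.size)
        return float("nan")
    idx_i = sv.in_region(i, active_only=active_only)
    idx_j = sv.in_region(j, active_only=active_only)
    if idx_i.size == 0 or idx_j.size == 0:
        return float("nan")
    R = _cross_correlations(sv.dff[np.ix_(idx_i, frames)], sv.dff[np.ix_(idx_j, frames)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmean(np.abs(R)))


def larva_metrics(
    sv: SupervoxelSet,
    atlas: AtlasLabels,
    windows: StateWindows,
    states: tuple[str, ...] = STATES,
    active_only: bool = True,
) -> pd.Series:
    """All (pair, state) metrics for one larva."""
    idx = metric_index(atlas.n_regions, states)
    vals = [
        inter_area_correlation(sv, (i, j), windows.of(s), active_only=active_only)
        for i, j, s in idx
    ]
    return pd.Series(vals, index=idx, name="mean_abs_r")


def assemble_fingerprint(
    per_larva: list[pd.Series], min_larvae: int = 5
) -> Fingerprint:
    """Average per-larva metric vectors into a group fingerprint.

    Missing (NaN) per-larva entries are excluded from the average; a metric
    missing in every larva stays missing and is logged.
    """
    if not per_larva:
        raise ValueError("need at least one larva")
    if len(per_larva) < min_larvae:
        logger.warning(
            "fingerprint averaged over %d larvae (< %d expected)",
            len(per_larva), min_larvae,
        )
    table = pd.concat(per_larva, axis=1)
    values = table.mean(axis=1, skipna=True)
    n_missing = int(values.isna().sum())
    if n_missing:
        logger.warning("%d metrics missing in every larva", n_missing)
    return Fingerprint(values=values, n_larvae=len(per_larva))


def per_larva_table(per_larva: list[pd.Series], state: str = "pre") -> pd.DataFrame:
    """Rows = larvae, columns = area pairs, restricted to one state."""
    table = pd.concat(per_larva, axis=1).T.reset_index(drop=True)
    sub = table.loc[:, table.columns.get_level_values("state") == state]
    sub.columns = [(i, j) for i, j, _s in sub.columns]
    return sub


def _shifted_surrogate(
    sv: SupervoxelSet, frames: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """dF/F restricted to frames with each supervoxel independently
    circularly shifted -- destroys cross-correlation, keeps autocorrelation."""
    sub = sv.dff[:, frames]
    out = np.empty_like(sub)
    n = sub.shape[1]
    for k in range(sub.shape[0]):
        out[k] = np.roll(sub[k], int(rng.integers(1, n)))
    return out


def significant_wt_pairs(
    svs: list[SupervoxelSet],
    atlas: AtlasLabels,
    resting_window: tuple[float, float],
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[tuple[int, int], float]:
    """Area pairs with significant resting-state wild-type correlation.

    Per larva, the observed resting mean |r| of a pair is compared against
    a chance level computed from circularly time-shifted surrogates of the
    same larva's supervoxel traces. An unpaired two-tailed t-test across
    larvae (observed vs surrogate samples) yields the pair's p-value;
    Jarque-Bera normality is checked on each sample with a warning on
    rejection. Returns {pair: p} for pairs with p < alpha.
    """
    if len(svs) < 3:
        raise ValueError("need at least 3 wild-type larvae")
    rng = np.random.default_rng(seed)
    pairs = area_pairs(atlas.n_regions)
    observed = {p: [] for p in pairs}
    surrogate = {p: [] for p in pairs}
    for sv in svs:
        frames = windows_to_frames([resting_window], sv.frame_rate, sv.dff.shape[1])
        obs_dff = sv.dff[:, frames]
        sur_dff = _shifted_surrogate(sv, frames, rng)
        for (i, j) in pairs:
            idx_i = sv.in_region(i)
            idx_j = sv.in_region(j)
            if idx_i.size == 0 or idx_j.size == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                observed[(i, j)].append(
                    float(np.nanmean(np.abs(_cross_correlations(obs_dff[idx_i], obs_dff[idx_j]))))
                )
                surrogate[(i, j)].append(
                    float(np.nanmean(np.abs(_cross_correlations(sur_dff[idx_i], sur_dff[idx_j]))))
                )
    result: dict[tuple[int, int], float] = {}
    for p in pairs:
        obs, sur = np.asarray(observed[p]), np.asarray(surrogate[p])
        if obs.size < 3 or np.std(obs) == 0 or np.std(sur) == 0:
            logger.warning("pair %s skipped (too few or zero-variance samples)", (p,))
            continue
        for name, sample in (("observed", obs), ("surrogate", sur)):
            if sample.size >= 8:
                jb_p = stats.jarque_bera(sample).pvalue
                if jb_p < 0.05:
                    logger.warning("pair %s: %s sample fails Jarque-Bera (p=%.3g)", p, name, jb_p)
        t = stats.ttest_ind(obs, sur)
        if t.pvalue < alpha:
            result[p] = float(t.pvalue)
    return result


def divergence_map(
    treated: pd.DataFrame,
    wt: pd.DataFrame,
    pairs: list[tuple[int, int]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pair divergence of a treated group from wild-type.

    Inputs are per-larva resting mean-|r| tables (rows = larvae, columns =
    pairs, as from :func:`per_larva_table`). Magnitude is the difference of
    group means; direction is its sign ('increase'/'decrease'), reported as
    'no change' when the unpaired t-test p >= alpha.
    """
    if treated.empty or wt.empty:
        raise ValueError("both groups must be non-empty")
    pairs = pairs if pairs is not None else list(treated.columns)
    rows = []
    for p in pairs:
        a, b = treated[p].dropna(), wt[p].dropna()
        mag = float(a.mean() - b.mean())
        pval = float(stats.ttest_ind(a, b).pvalue) if (a.std() > 0 or b.std() > 0) else 1.0
        direction = "no change"
        if pval < alpha:
            direction = "increase" if mag > 0 else "decrease"
        rows.append({"area_i": p[0], "area_j": p[1], "direction": direction,
                     "magnitude": mag, "p": pval})
    return pd.DataFrame(rows)
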