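"""Synthetic atlas-registered calcium recordings with planted connectivity.

The generator plants a target inter-area correlation structure with a
shared/private Poisson spike construction. Every neuron fires at a total
rate R; for an area pair (i, j) with target correlation rho in a given
activity state, a shared Poisson event stream of rate rho * R is injected
into *all* neurons of both areas, and each neuron tops up with private
Poisson events at rate (1 - sum of its areas' shared rates) * R. Binned
spike counts of a cross-pair neuron pair then have correlation exactly
rho (shared variance over total variance), which is analytically invertible
and is preserved when both traces pass through the same linear calcium
kernel. A target is unreachable when the shared rates assigned to one area
exceed its total rate; this raises with the attainable bound.

Spikes are convolved with a single-exponential calcium kernel (1-frame
rise, tau_decay = 1.5 s by default) and rendered into image planes as small
voxel clusters over a noisy baseline. The mutant condition multiplies all
firing rates by a stimulus-locked surge (x5, decaying over 5 s) after each
light stimulus, reproducing the photosensitive hyper-synchronous bursts of
the epilepsy model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from ..atlas import AtlasLabels
from ..protocol import STATES, StimulusSchedule
from ..voxels import VolumeSeries

PairKey = tuple[int, int, str]  # (area_i, area_j, state) with i < j


@dataclass
class ImagingParams:
    """Acquisition and biophysics parameters for the synthetic recorder."""

    rate: float = 20.0                 # volumetric frame rate, Hz
    noise_sd: float = 2.0              # additive Gaussian camera noise
    n_neurons_per_region: int = 20
    baseline: float = 30.0             # resting fluorescence inside the brain
    gain: float = 40.0                 # fluorescence per unit calcium
    spike_rate: float = 0.1            # total firing rate per neuron, Hz
    tau_decay: float = 1.5             # calcium kernel decay, s
    burst_gain: float = 5.0            # mutant stimulus-locked rate surge
    burst_decay: float = 5.0           # surge decay constant, s
    neuron_extent: tuple[int, int] = (2, 2)  # in-plane voxel footprint (y, x)


@dataclass
class GroundTruth:
    """Planted statistical structure of one synthetic recording."""

    planted_connectivity: dict[PairKey, float]
    condition: str = "wild_type"       # "wild_type" or "mutant"
    drug_effect: dict[PairKey, float] = field(default_factory=dict)
    seizure_times: list[float] = field(default_factory=list)
    neuron_positions: list[tuple[int, int, int, int]] = field(default_factory=list)
    # Filled by the simulator:
    spike_counts: np.ndarray | None = None     # (n_neurons, T)
    neuron_region: np.ndarray | None = None    # (n_neurons,)
    neuron_voxels: list[np.ndarray] = field(default_factory=list)

    def effective_connectivity(self) -> dict[PairKey, float]:
        """Planted rho with the drug perturbation applied, clipped to [0, 1]."""
        out = dict(self.planted_connectivity)
        for key, delta in self.drug_effect.items():
            out[key] = float(np.clip(out.get(key, 0.0) + delta, 0.0, 1.0))
        return out


def make_ground_truth(
    pair_rho: dict[tuple[int, int], float] | dict[PairKey, float],
    condition: str = "wild_type",
    drug_effect: dict[PairKey, float] | None = None,
) -> GroundTruth:
    """Build a GroundTruth from pair->rho targets.

    Keys may be (i, j) -- applied to all three states -- or (i, j, state).
    """
    planted: dict[PairKey, float] = {}
    for key, rho in pair_rho.items():
        if len(key) == 2:
            i, j = key  # type: ignore[misc]
            for s in STATES:
                planted[(min(i, j), max(i, j), s)] = float(rho)
        else:
            i, j, s = key  # type: ignore[misc]
            planted[(min(i, j), max(i, j), s)] = float(rho)
    return GroundTruth(planted, condition=condition, drug_effect=drug_effect or {})


def _place_neurons(
    atlas: AtlasLabels, n_per_region: int, extent: tuple[int, int], rng: np.random.Generator
) -> tuple[list[tuple[int, int, int, int]], list[np.ndarray], np.ndarray]:
    """Place non-overlapping neuron footprints fully inside their regions."""
    ey, ex = extent
    positions: list[tuple[int, int, int, int]] = []
    voxels: list[np.ndarray] = []
    regions: list[int] = []
    occupied: set[tuple[int, int, int]] = set()
    labels = atlas.label_volume
    for rid in range(1, atlas.n_regions + 1):
        cand = np.argwhere(labels == rid)
        placed = 0
        for _ in range(200 * n_per_region):
            if placed >= n_per_region:
                break
            z, y, x = cand[rng.integers(len(cand))]
            block = [(z, y + dy, x + dx) for dy in range(ey) for dx in range(ex)]
            ok = all(
                0 <= yy < labels.shape[1]
                and 0 <= xx < labels.shape[2]
                and labels[zz, yy, xx] == rid
                and (zz, yy, xx) not in occupied
                for zz, yy, xx in block
            )
            if not ok:
                continue
            occupied.update(block)
            positions.append((int(rid), int(z), int(y), int(x)))
            voxels.append(np.array(block))
            regions.append(rid)
            placed += 1
        if placed < n_per_region:
            raise ValueError(
                f"could not place {n_per_region} neurons in region {rid} "
                f"({placed} placed); enlarge the atlas or shrink neurons"
            )
    return positions, voxels, np.array(regions)


def _state_per_frame(
    schedule: StimulusSchedule, n_frames: int, rate: float
) -> np.ndarray:
    """State index (0 pre, 1 early, 2 late) for every frame.

    For generation the whole inter-stimulus span is covered: [t, t+60) is
    early-like, [t+60, next stimulus or end) late-like.
    """
    state = np.zeros(n_frames, dtype=int)
    times = list(schedule.stimulus_times)
    for k, t in enumerate(times):
        nxt = times[k + 1] * rate if k + 1 < len(times) else n_frames
        a = int(round(t * rate))
        b = int(round(min((t + 60.0) * rate, nxt)))
        c = int(round(nxt))
        state[a:min(b, n_frames)] = 1
        state[b:min(c, n_frames)] = 2
    return state


def simulate_condition_recording(
    atlas: AtlasLabels,
    truth: GroundTruth,
    schedule: StimulusSchedule,
    imaging: ImagingParams | None = None,
    seed: int = 0,
    duration: float | None = None,
) -> tuple[VolumeSeries, GroundTruth]:
    """Render a 4D recording with the planted connectivity structure.

    Returns the volume and the (augmented) ground truth carrying spike
    counts, neuron footprints and region labels for validation.
    """
    imaging = imaging or ImagingParams()
    rng = np.random.default_rng(seed)
    rho = truth.effective_connectivity()

    duration = float(duration) if duration is not None else schedule.duration_hint
    T = int(round(duration * imaging.rate))
    state = _state_per_frame(schedule, T, imaging.rate)

    # Reachability: per area and state, shared rates must not exceed total.
    pairs = sorted({(i, j) for (i, j, _s) in rho})
    for s_idx, s in enumerate(STATES):
        load = np.zeros(atlas.n_regions + 1)
        for (i, j) in pairs:
            r = rho.get((i, j, s), 0.0)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"planted rho for {(i, j, s)} outside [0, 1]")
            load[i] += r
            load[j] += r
        bad = np.flatnonzero(load > 1.0 + 1e-9)
        if bad.size:
            a = int(bad[0])
            raise ValueError(
                f"requested correlations unreachable: area {a} carries total "
                f"shared rate {load[a]:.3f} > 1 in state '{s}'; scale the rho "
                f"values for its pairs by <= {1.0 / load[a]:.3f}"
            )

    positions, voxels, regions = _place_neurons(
        atlas, imaging.n_neurons_per_region, imaging.neuron_extent, rng
    )
    n_neurons = len(positions)

    # Stimulus-locked rate surge (mutant condition only).
    mod = np.ones(T)
    if truth.condition == "mutant":
        tgrid = np.arange(T) / imaging.rate
        for ts in schedule.stimulus_times:
            after = tgrid >= ts
            mod[after] += (imaging.burst_gain - 1.0) * np.exp(
                -(tgrid[after] - ts) / imaging.burst_decay
            )
        truth.seizure_times = list(schedule.stimulus_times)

    per_frame = imaging.spike_rate / imaging.rate  # expected spikes/frame
    counts = np.zeros((n_neurons, T))
    shared_load = np.zeros((n_neurons, T))
    for (i, j) in pairs:
        lam = np.zeros(T)
        for s_idx, s in enumerate(STATES):
            lam[state == s_idx] = rho.get((i, j, s), 0.0)
        if not np.any(lam > 0):
            continue
        shared = rng.poisson(lam * per_frame * mod)
        in_pair = np.isin(regions, (i, j))
        counts[in_pair] += shared[None, :]
        shared_load[in_pair] += lam[None, :]
    private_rate = (1.0 - shared_load) * per_frame * mod[None, :]
    counts += rng.poisson(np.clip(private_rate, 0.0, None))

    # Calcium kernel: 1-frame rise, exponential decay.
    decay = np.exp(-1.0 / (imaging.tau_decay * imaging.rate))
    calcium = lfilter([1.0], [1.0, -decay], counts, axis=1)

    # Render into planes: brain baseline + neuron signal + shot noise inside
    # the brain; outside is dark (small constant camera offset, no noise).
    nz, ny, nx = atlas.label_volume.shape
    data = np.full((T, nz, ny, nx), 1.0, dtype=np.float32)
    brain = atlas.label_volume > 0
    data[:, brain] = imaging.baseline
    for n in range(n_neurons):
        sig = (imaging.gain * calcium[n]).astype(np.float32)
        for zz, yy, xx in voxels[n]:
            data[:, zz, yy, xx] += sig
    if imaging.noise_sd > 0:
        data[:, brain] += rng.normal(
            0.0, imaging.noise_sd, size=(T, int(brain.sum()))
        ).astype(np.float32)
    np.clip(data, 0.0, None, out=data)

    truth.neuron_positions = positions
    truth.neuron_voxels = voxels
    truth.neuron_region = regions
    truth.spike_counts = counts
    vol = VolumeSeries(data=data, frame_rate=imaging.rate, voxel_size=atlas.voxel_size)
    return vol, truth
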