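"""Shared fixtures: small synthetic recordings processed once per session."""

from __future__ import annotations

import numpy as np
import pytest

import zfscreen as z
from zfscreen.protocol import StimulusSchedule, segment_states
from zfscreen.synth import ImagingParams, make_ground_truth, simulate_condition_recording
from zfscreen.voxels import SupervoxelSet

ATLAS_SHAPE = (4, 24, 24)
PRE_S = 240.0
SCHEDULE = StimulusSchedule(pre_duration=PRE_S, stimulus_times=(PRE_S,))
PLANTED = {(1, 2): 0.8, (3, 4): 0.4}


@pytest.fixture(scope="session")
def atlas11():
    return z.generate_atlas(ATLAS_SHAPE, 11, seed=1)


@pytest.fixture(scope="session")
def wt_recording(atlas11):
    truth = make_ground_truth(PLANTED, condition="wild_type")
    vol, truth = simulate_condition_recording(
        atlas11, truth, SCHEDULE, ImagingParams(n_neurons_per_region=3), seed=2
    )
    return vol, truth


@pytest.fixture(scope="session")
def wt_supervoxels(wt_recording, atlas11):
    vol, _truth = wt_recording
    return z.process_volume(vol, atlas11, (0.0, PRE_S))


@pytest.fixture(scope="session")
def state_windows(wt_recording):
    vol, _ = wt_recording
    return segment_states(SCHEDULE, vol.duration)


def make_sv(region_traces: dict[int, np.ndarray], rate: float = 20.0) -> SupervoxelSet:
    """SupervoxelSet built directly from per-region dF/F trace matrices.

    Bypasses the imaging stage for statistics-level tests; every supervoxel
    is marked active and gets a dummy singleton footprint.
    """
    traces = np.vstack(list(region_traces.values()))
    regions = np.concatenate(
        [np.full(m.shape[0], rid) for rid, m in region_traces.items()]
    )
    n = traces.shape[0]
    members = [np.array([[0, 0, i]]) for i in range(n)]
    sv = SupervoxelSet(
        members=members,
        traces=traces,
        frame_rate=rate,
        region_of=regions,
        dff=traces,
        active=np.ones(n, dtype=bool),
        diameter_um=np.ones(n),
    )
    return sv
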