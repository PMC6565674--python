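"""Synthetic larva silhouette videos with ground-truth skeleton tracks.

Renders an elongated larva (wide head, tapering tail) following a motion
program: forward velocity along the heading, a constant turn rate, and a
sinusoidal tail beat. The true 5-point skeleton (head to tail tip, equal
arc-length spacing) is stored per frame for tracker validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import disk


@dataclass(frozen=True)
class MotionProgram:
    """Kinematic program for the synthetic larva.

    ``velocity_mod_amp`` sinusoidally modulates the forward speed
    (burst-and-glide swimming); with amplitude a the instantaneous speed is
    v * (1 + a * sin(2 pi f t)), giving a known high-velocity fraction.
    """

    velocity: float = 0.0          # forward speed, px/s
    turn_rate: float = 0.0         # heading change, deg/s
    tail_beat_amp: float = 0.0     # per-segment bend amplitude, deg
    tail_beat_freq: float = 2.0    # tail oscillation frequency, Hz
    velocity_mod_amp: float = 0.0  # fractional speed modulation
    velocity_mod_freq: float = 0.5 # speed modulation frequency, Hz
    turn_mod_amp: float = 0.0      # oscillatory yaw amplitude, deg/s
    turn_mod_freq: float = 0.5     # yaw oscillation frequency, Hz


def _rot(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def _vertices(head: np.ndarray, heading_deg: float, bend_deg: float, length: float) -> np.ndarray:
    """True 5-point skeleton; posterior segments bend cumulatively."""
    u = np.array([np.cos(np.deg2rad(heading_deg)), np.sin(np.deg2rad(heading_deg))])
    seg = length / 4.0
    pts = [head, head - seg * u]
    back = -u
    for k in range(1, 4):
        d = _rot(k * bend_deg) @ back
        pts.append(pts[-1] + seg * d)
    return np.asarray(pts)


def simulate_behavior(
    duration: float,
    rate: float,
    program: MotionProgram,
    seed: int = 0,
    frame_shape: tuple[int, int] = (96, 96),
    body_length: float = 36.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render silhouette frames plus the ground-truth 5-point track.

    Returns ``(frames, track)``: frames is (T, H, W) uint8, track is
    (T, 5, 2) with (x, y) pixel coordinates from head to tail tip.

    Raises if the larva would leave the frame at any time.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    rng = np.random.default_rng(seed)
    T = int(round(duration * rate))
    H, W = frame_shape
    t = np.arange(T) / rate
    heading0 = float(rng.uniform(0.0, 360.0))  # seed-dependent geometry
    omega = program.turn_rate + program.turn_mod_amp * np.sin(
        2 * np.pi * program.turn_mod_freq * t
    )
    heading = heading0 + np.concatenate([[0.0], np.cumsum(omega[:-1]) / rate])
    # Integrate head position, then centre the trajectory in the frame.
    u = np.column_stack([np.cos(np.deg2rad(heading)), np.sin(np.deg2rad(heading))])
    speed = program.velocity * (
        1.0 + program.velocity_mod_amp
        * np.sin(2 * np.pi * program.velocity_mod_freq * t)
    )
    head = np.cumsum(
        np.vstack([[0.0, 0.0], (speed[:-1] / rate)[:, None] * u[:-1]]), axis=0
    )
    bend = program.tail_beat_amp * np.sin(2 * np.pi * program.tail_beat_freq * t)

    track = np.stack([
        _vertices(head[i], heading[i], bend[i], body_length) for i in range(T)
    ])
    span_lo = track.reshape(-1, 2).min(axis=0)
    span_hi = track.reshape(-1, 2).max(axis=0)
    offset = (np.array([W, H]) - (span_hi - span_lo)) / 2.0 - span_lo
    track += offset

    frames = np.zeros((T, H, W), dtype=np.uint8)
    n_dense = 60
    for i in range(T):
        pts = track[i]
        for k in range(4):
            for a in np.linspace(0.0, 1.0, n_dense // 4, endpoint=False):
                p = pts[k] * (1 - a) + pts[k + 1] * a
                s = (k + a) / 4.0  # arc-length fraction from the head
                r = 1.2 + 3.0 * (1.0 - s) ** 2
                if not (r <= p[0] < W - r and r <= p[1] < H - r):
                    raise ValueError(f"larva leaves the frame at t={t[i]:.2f} s")
                rr, cc = disk((p[1], p[0]), r, shape=(H, W))
                frames[i, rr, cc] = 255
    return frames, track
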