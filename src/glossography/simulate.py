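"""Synthetic bedside recordings with known ground truth.

The simulator emulates a 30-second orofacial video tracked at four
landmarks (forehead, nose, tongue tip, chin) and reproduces the failure
modes the pipeline must tolerate:

* **baseline jitter** — independent Gaussian pixel noise on every
  landmark, the tracking/physiological noise floor;
* **head drift** — a slow sinusoidal translation shared by *all*
  landmarks: it inflates index-frame displacement but cancels out of
  inter-landmark distances, the head-repositioning bias mechanism;
* **dyskinetic tongue bursts** — additive Gaussian-shaped excursions of
  the tongue tip at Poisson event times (or a fixed schedule), in
  uniformly random directions;
* **confidence dropouts** — random tongue frames whose likelihood falls
  into [0, 0.5], exercising the cleaning/imputation stage.

All randomness flows from a single integer seed through NumPy's PCG64
generator, so sessions are bit-reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import AnalysisConfig
from .io import LandmarkTrack, Session, clean_track
from .kinematics import displacement_from_index, select_index_frame
from .metrics import detect_peaks

__all__ = [
    "MotionParams",
    "GroundTruth",
    "RecoveryReport",
    "simulate_session",
    "recovery_experiment",
    "severity_schedule",
]

_DEFAULT_GEOMETRY: dict[str, tuple[float, float]] = {
    "forehead": (320.0, 100.0),
    "nose": (320.0, 220.0),
    "tongue_tip": (320.0, 300.0),
    "chin": (320.0, 360.0),
}


@dataclass(frozen=True)
class MotionParams:
    """Generator settings for one synthetic session.

    Defaults describe a 30 s bedside clip at 25 fps with mild dyskinesia:
    ~6 tongue bursts (0.2 /s) of 40 px peak excursion and 0.5 s width
    over a 1 px jitter floor, 3 px of slow head drift and 2% tongue
    dropout frames.
    """

    fps: float = 25.0
    duration_s: float = 30.0
    geometry: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_GEOMETRY)
    )
    jitter_sd: float = 1.0
    burst_rate: float = 0.2          # bursts per second (Poisson intensity)
    burst_amp: float = 40.0          # peak excursion, px
    burst_dur_s: float = 0.5         # pulse FWHM, seconds
    drift_amp: float = 3.0           # shared head-drift amplitude, px
    drift_freq_hz: float = 0.05      # head-drift frequency
    dropout_prob: float = 0.02       # per-frame tongue dropout probability
    seed: int = 0
    burst_times_s: Sequence[float] | None = None  # fixed schedule override
    reference: str = "tongue_tip"

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be > 0")
        for name in ("jitter_sd", "burst_rate", "burst_amp", "burst_dur_s",
                     "drift_amp", "drift_freq_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.burst_times_s is not None:
            times = np.asarray(self.burst_times_s, dtype=float)
            if ((times < 0) | (times >= self.duration_s)).any():
                raise ValueError("burst_times_s must lie within [0, duration_s)")
        if self.reference not in self.geometry:
            raise ValueError(
                f"reference {self.reference!r} missing from geometry"
            )
        if len(self.geometry) < 2:
            raise ValueError("geometry needs at least 2 landmarks")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass(frozen=True)
class GroundTruth:
    """True burst schedule injected into a simulated session."""

    burst_frames: np.ndarray      # burst centre frames (int)
    burst_directions: np.ndarray  # (n_bursts, 2) unit vectors

    @property
    def n_bursts(self) -> int:
        return len(self.burst_frames)


@dataclass(frozen=True)
class RecoveryReport:
    """Detected peaks matched against the injected burst schedule."""

    n_true: int
    n_detected: int
    n_matched: int
    false_discoveries: int
    sensitivity: float
    detected_frames: np.ndarray
    true_frames: np.ndarray


def simulate_session(params: MotionParams, label: str = "sim") -> tuple[Session, GroundTruth]:
    """Generate one synthetic session and its ground truth.

    Deterministic given ``params.seed``; identical parameters produce
    bit-identical sessions.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    t = np.arange(n) / params.fps

    # shared slow head drift (same for every landmark)
    phase_x, phase_y = rng.uniform(0.0, 2.0 * np.pi, size=2)
    drift_x = params.drift_amp * np.sin(2 * np.pi * params.drift_freq_hz * t + phase_x)
    drift_y = params.drift_amp * np.sin(2 * np.pi * params.drift_freq_hz * t + phase_y)

    # independent jitter per landmark (fixed iteration order)
    names = list(params.geometry)
    jitter = {name: rng.normal(0.0, params.jitter_sd, size=(2, n)) for name in names}

    # tongue burst schedule
    if params.burst_times_s is not None:
        times = np.asarray(params.burst_times_s, dtype=float)
    else:
        n_bursts = rng.poisson(params.burst_rate * params.duration_s)
        times = np.sort(rng.uniform(0.0, params.duration_s, size=n_bursts))
    angles = rng.uniform(0.0, 2.0 * np.pi, size=len(times))
    directions = np.column_stack([np.cos(angles), np.sin(angles)])

    sigma_s = params.burst_dur_s / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM -> sd
    burst_x = np.zeros(n)
    burst_y = np.zeros(n)
    for time, (ux, uy) in zip(times, directions):
        pulse = params.burst_amp * np.exp(-0.5 * ((t - time) / max(sigma_s, 1e-9)) ** 2)
        burst_x += ux * pulse
        burst_y += uy * pulse

    # tongue confidence dropouts
    dropout = rng.random(n) < params.dropout_prob
    dropout_values = rng.uniform(0.0, 0.5, size=n)

    tracks = {}
    for name in names:
        rx, ry = params.geometry[name]
        x = rx + drift_x + jitter[name][0]
        y = ry + drift_y + jitter[name][1]
        likelihood = np.ones(n)
        if name == params.reference:
            x = x + burst_x
            y = y + burst_y
            likelihood = np.where(dropout, dropout_values, 1.0)
        tracks[name] = LandmarkTrack(name=name, x=x, y=y, likelihood=likelihood)

    truth = GroundTruth(
        burst_frames=np.round(times * params.fps).astype(int),
        burst_directions=directions,
    )
    return Session(label=label, fps=params.fps, tracks=tracks), truth


def recovery_experiment(
    params: MotionParams,
    min_prominence: float | None = None,
    min_distance: int | None = None,
    conf_threshold: float = 0.9,
) -> RecoveryReport:
    """Run the full pipeline on a simulated session and score peak recovery.

    Detected displacement peaks are matched one-to-one to injected burst
    centres within a window of one burst duration; unmatched detections
    count as false discoveries.
    """
    session, truth = simulate_session(params)
    max_gap = max(1, int(round(params.fps)))
    cleaned = {
        name: clean_track(tr, conf_threshold, max_gap)
        for name, tr in session.tracks.items()
    }
    session = Session(label=session.label, fps=session.fps, tracks=cleaned)

    index = select_index_frame(session, conf_threshold).frame
    mag = displacement_from_index(session.tracks[params.reference], index).magnitude
    rng_span = float(mag.max() - mag.min())
    prom = 0.1 * rng_span if min_prominence is None else min_prominence
    dist = max(1, round(0.5 * params.fps)) if min_distance is None else min_distance
    peaks = detect_peaks(mag, prom, dist)

    window = max(1, int(round(params.burst_dur_s * params.fps)))
    detected = peaks.indices.copy()
    used = np.zeros(len(detected), dtype=bool)
    matched = 0
    for true_frame in truth.burst_frames:
        if len(detected) == 0:
            break
        gaps = np.abs(detected - true_frame).astype(float)
        gaps[used] = np.inf
        best = int(np.argmin(gaps))
        if gaps[best] <= window:
            used[best] = True
            matched += 1
    return RecoveryReport(
        n_true=truth.n_bursts,
        n_detected=peaks.count,
        n_matched=matched,
        false_discoveries=peaks.count - matched,
        sensitivity=matched / truth.n_bursts if truth.n_bursts else 1.0,
        detected_frames=peaks.indices,
        true_frames=truth.burst_frames,
    )


_SCHEDULE = (  # (n_bursts, burst_amp px) per simulated day, decreasing severity
    (10, 80.0),
    (5, 40.0),
    (2, 20.0),
    (0, 0.0),
)


def severity_schedule(
    seed: int = 0,
    fps: float = 25.0,
    duration_s: float = 30.0,
) -> list[tuple[Session, GroundTruth]]:
    """Four sessions emulating a monotone clinical improvement.

    Burst count and amplitude decrease day by day (10x80, 5x40, 2x20,
    0 px) over an unchanged 1 px jitter floor, so every glossographic
    severity metric should decrease monotonically across the returned
    sessions.  Burst times are evenly spaced for unambiguous counting;
    head drift is off so the displacement signal is pure tongue motion.
    """
    out = []
    for day, (n_bursts, amp) in enumerate(_SCHEDULE, start=1):
        if n_bursts > 0:
            times = np.linspace(2.0, duration_s - 2.0, n_bursts)
        else:
            times = []
        params = MotionParams(
            fps=fps,
            duration_s=duration_s,
            burst_amp=amp,
            burst_times_s=times,
            drift_amp=0.0,
            dropout_prob=0.0,
            seed=seed + day,
        )
        out.append(simulate_session(params, label=f"Day {day}"))
    return out
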