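"""Kinematic series from landmark tracks.

Three series families feed the dyskinesia metrics:

* **displacement from the index frame** — per-frame (dx, dy) of one
  landmark relative to a fixed reference frame, plus the Euclidean
  magnitude;
* **inter-landmark distance** — per-frame Euclidean distance between two
  landmarks (translation-invariant, so insensitive to whole-head motion);
* **whole-face vector series** — the tongue-to-landmark distances summed
  over all other landmarks, either raw or as absolute deviation from the
  index frame.

Displacement series are deliberately *not* head-motion compensated by
default: a rigid translation of the whole face shifts them while leaving
distance-based series untouched, which is exactly the bias mechanism a
bedside recording is exposed to when the patient repositions.  An
optional nose-centred compensation helper is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import LandmarkTrack, Session

__all__ = [
    "DisplacementSeries",
    "DistanceSeries",
    "IndexFrameResult",
    "select_index_frame",
    "displacement_from_index",
    "landmark_distance",
    "whole_face_series",
    "center_on_landmark",
    "session_series",
    "tidy_series",
    "SERIES_SELECTORS",
]


@dataclass(frozen=True)
class DisplacementSeries:
    """Per-frame displacement of a landmark from a fixed index frame (px)."""

    dx: np.ndarray
    dy: np.ndarray
    magnitude: np.ndarray
    index_frame: int


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame Euclidean distance between two landmarks (px)."""

    pair: tuple[str, str]
    d: np.ndarray


class IndexFrameResult(NamedTuple):
    frame: int
    fallback: bool  # True when no frame met the confidence threshold


def select_index_frame(session: Session, conf_threshold: float = 0.9) -> IndexFrameResult:
    """Earliest frame at which every landmark is tracked confidently.

    The displacement reference is the recording's first frame; this guard
    skips ahead if that frame is poorly tracked for any landmark.  If no
    frame qualifies, frame 0 is returned with ``fallback=True``.
    """
    ok = np.ones(session.n_frames, dtype=bool)
    for track in session.tracks.values():
        ok &= track.likelihood >= conf_threshold
    qualifying = np.flatnonzero(ok)
    if qualifying.size == 0:
        return IndexFrameResult(0, True)
    return IndexFrameResult(int(qualifying[0]), False)


def displacement_from_index(track: LandmarkTrack, index_frame: int) -> DisplacementSeries:
    """dx, dy and Euclidean magnitude relative to ``index_frame``."""
    if not 0 <= index_frame < track.n_frames:
        raise ValueError(
            f"index_frame {index_frame} out of range [0, {track.n_frames})"
        )
    dx = track.x - track.x[index_frame]
    dy = track.y - track.y[index_frame]
    return DisplacementSeries(
        dx=dx, dy=dy, magnitude=np.hypot(dx, dy), index_frame=int(index_frame)
    )


def landmark_distance(a: LandmarkTrack, b: LandmarkTrack) -> DistanceSeries:
    """Per-frame Euclidean distance between landmarks ``a`` and ``b``."""
    if a.n_frames != b.n_frames:
        raise ValueError(
            f"length mismatch: {a.name!r} has {a.n_frames} frames, "
            f"{b.name!r} has {b.n_frames}"
        )
    return DistanceSeries(pair=(a.name, b.name), d=np.hypot(a.x - b.x, a.y - b.y))


def whole_face_series(
    session: Session,
    reference: str = "tongue_tip",
    mode: str = "deviation",
    index_frame: int = 0,
) -> np.ndarray:
    """Whole-face vector series V(t) from reference-to-landmark distances.

    With d_k(t) the distance from the reference landmark to landmark k:

    * ``mode="raw"``:        V(t) = sum_k d_k(t)
    * ``mode="deviation"``:  V(t) = sum_k |d_k(t) - d_k(index_frame)|

    Deviation mode isolates movement relative to the resting face
    geometry and is the default.
    """
    if reference not in session.tracks:
        raise ValueError(f"unknown reference landmark {reference!r}")
    if mode not in ("deviation", "raw"):
        raise ValueError(f"mode must be 'deviation' or 'raw', got {mode!r}")
    others = [n for n in session.tracks if n != reference]
    if not others:
        raise ValueError("whole-face series needs at least one non-reference landmark")
    ref = session.tracks[reference]
    total = np.zeros(session.n_frames)
    for name in others:
        d = landmark_distance(ref, session.tracks[name]).d
        if mode == "deviation":
            total += np.abs(d - d[index_frame])
        else:
            total += d
    return total


def center_on_landmark(session: Session, landmark: str = "nose") -> Session:
    """Head-motion compensation: subtract one landmark's track from all.

    Off by default in the pipeline; useful to probe how much of a
    displacement signal is whole-head translation.
    """
    if landmark not in session.tracks:
        raise ValueError(f"unknown landmark {landmark!r}")
    anchor = session.tracks[landmark]
    tracks = {
        name: replace(t, x=t.x - anchor.x, y=t.y - anchor.y)
        for name, t in session.tracks.items()
    }
    return Session(label=session.label, fps=session.fps, tracks=tracks)


SERIES_SELECTORS = ("tongue_dx", "tongue_dy", "tongue_magnitude", "whole_face")


def session_series(
    session: Session,
    selector: str = "tongue_dx",
    *,
    reference: str = "tongue_tip",
    mode: str = "deviation",
    index_frame: int | None = None,
    conf_threshold: float = 0.9,
) -> np.ndarray:
    """Build one named per-frame series for a session.

    Selectors: ``tongue_dx`` / ``tongue_dy`` (per-axis displacement of the
    reference landmark from the index frame), ``tongue_magnitude``
    (Euclidean displacement magnitude), ``whole_face`` (vector series).
    """
    if selector not in SERIES_SELECTORS:
        raise ValueError(f"unknown series selector {selector!r}; "
                         f"choose one of {SERIES_SELECTORS}")
    if reference not in session.tracks:
        raise ValueError(f"unknown reference landmark {reference!r}")
    if index_frame is None:
        index_frame = select_index_frame(session, conf_threshold).frame
    if selector == "whole_face":
        return whole_face_series(session, reference, mode, index_frame)
    disp = displacement_from_index(session.tracks[reference], index_frame)
    return {"tongue_dx": disp.dx, "tongue_dy": disp.dy,
            "tongue_magnitude": disp.magnitude}[selector]


def tidy_series(session: Session, series: dict[str, np.ndarray]) -> pd.DataFrame:
    """Long-format export: columns session, frame, time_s, series_name, value."""
    frames = np.arange(session.n_frames)
    parts = [
        pd.DataFrame(
            {
                "session": session.label,
                "frame": frames,
                "time_s": frames / session.fps,
                "series_name": name,
                "value": values,
            }
        )
        for name, values in series.items()
    ]
    return pd.concat(parts, ignore_index=True)
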