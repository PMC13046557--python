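"""Glossographic metrics for a per-frame kinematic series.

For each session two summary blocks are reported, mirroring the standard
glossographic layout:

* the **tongue block** — total, range, mean, SD, peak count and Poincaré
  SD1/SD2 of the tongue-tip displacement magnitude;
* the **whole-face block** — total, range, mean and SD of the whole-face
  vector series.

"Total displacement length" is the plain sum of the per-frame series
(so total = mean × n_frames), not an arc length; a path-length variant
is provided separately.  Totals are duration-dependent, hence each block
also carries a per-second normalisation.

Poincaré analysis treats the lag-1 scatter of (s(t), s(t+1)): SD1, the
dispersion across the identity line, captures frame-to-frame
variability; SD2, the dispersion along it, captures slower variability.
With the population standard deviation they satisfy
SD1² + SD2² = 2·Var(s) up to O(1/n) edge terms, which makes
``implied_std`` a useful internal-consistency check on any reported
(SD1, SD2, Std) triple.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.signal import find_peaks

from .config import AnalysisConfig
from .io import Session
from .kinematics import displacement_from_index, select_index_frame, whole_face_series

__all__ = [
    "SeriesSummary",
    "PeakSet",
    "PoincareDescriptors",
    "GlossoSummary",
    "summarize_series",
    "detect_peaks",
    "poincare",
    "implied_std",
    "path_length",
    "glossography_summary",
    "summary_frame",
]


class SeriesSummary(NamedTuple):
    total: float
    range: float
    mean: float
    std: float


@dataclass(frozen=True)
class PeakSet:
    """Accepted movement peaks of a series."""

    indices: np.ndarray          # frame ids, strictly increasing
    prominences: np.ndarray      # px, aligned with indices
    params: tuple[float, int]    # (min_prominence, min_distance)

    @property
    def count(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class PoincareDescriptors:
    sd1: float  # short-term (frame-to-frame) variability, px
    sd2: float  # long-term variability, px
    lag: int = 1


@dataclass(frozen=True)
class GlossoSummary:
    """One summary-table row for one series of one session."""

    label: str
    n_frames: int
    total: float
    range: float
    mean: float
    std: float
    peaks: int | None = None
    sd1: float | None = None
    sd2: float | None = None
    per_second_total: float | None = None


def summarize_series(s, ddof: int = 0) -> SeriesSummary:
    """Total, range, mean and standard deviation of a per-frame series."""
    s = np.asarray(s, dtype=float)
    if s.size < 2:
        raise ValueError("summarize_series needs at least 2 samples")
    return SeriesSummary(
        total=float(s.sum()),
        range=float(s.max() - s.min()),
        mean=float(s.mean()),
        std=float(s.std(ddof=ddof)),
    )


def detect_peaks(s, min_prominence: float, min_distance: int = 1) -> PeakSet:
    """Discrete movement peaks via SciPy's find-peaks algorithm.

    Local maxima (plateaus resolved to their midpoint) are first thinned
    so that surviving peaks are at least ``min_distance`` frames apart
    (higher peaks win), then filtered by topographic prominence.
    """
    if min_prominence < 0:
        raise ValueError("min_prominence must be >= 0")
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    s = np.asarray(s, dtype=float)
    if s.size < 3:
        raise ValueError("detect_peaks needs at least 3 samples")
    indices, props = find_peaks(
        s, distance=int(min_distance), prominence=(min_prominence, None)
    )
    return PeakSet(
        indices=indices,
        prominences=props["prominences"],
        params=(float(min_prominence), int(min_distance)),
    )


def poincare(s, lag: int = 1, ddof: int = 0) -> PoincareDescriptors:
    """Poincaré SD1/SD2 of the lag-``lag`` scatter of a series.

    sd1 = std(s[t+lag] - s[t]) / sqrt(2),
    sd2 = std(s[t+lag] + s[t]) / sqrt(2),
    using the population standard deviation by default.
    """
    s = np.asarray(s, dtype=float)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if s.size < lag + 2:
        raise ValueError(f"series too short for lag {lag}: need >= {lag + 2} samples")
    head, tail = s[:-lag], s[lag:]
    return PoincareDescriptors(
        sd1=float((tail - head).std(ddof=ddof) / np.sqrt(2)),
        sd2=float((tail + head).std(ddof=ddof) / np.sqrt(2)),
        lag=lag,
    )


def implied_std(sd1: float, sd2: float) -> float:
    """Overall standard deviation implied by Poincaré descriptors.

    Inverts the identity SD1² + SD2² = 2·Var(s):
    returns sqrt((sd1² + sd2²) / 2).  Useful to cross-check a reported
    (SD1, SD2, Std) triple without access to the underlying series.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("sd1 and sd2 must be >= 0")
    return float(np.sqrt((sd1 * sd1 + sd2 * sd2) / 2.0))


def path_length(x, y) -> float:
    """Arc length of a 2-D trajectory: sum of frame-to-frame step sizes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("path_length needs equal-length x, y with >= 2 samples")
    return float(np.hypot(np.diff(x), np.diff(y)).sum())


def _summarize_block(
    label: str,
    s: np.ndarray,
    fps: float,
    ddof: int,
    *,
    with_peaks: bool = False,
    min_prominence: float | None = None,
    min_distance: int = 1,
    poincare_lag: int = 1,
) -> GlossoSummary:
    base = summarize_series(s, ddof=ddof)
    peaks = sd1 = sd2 = None
    if with_peaks:
        prom = 0.1 * base.range if min_prominence is None else min_prominence
        peaks = detect_peaks(s, prom, min_distance).count
        pc = poincare(s, lag=poincare_lag, ddof=ddof)
        sd1, sd2 = pc.sd1, pc.sd2
    return GlossoSummary(
        label=label,
        n_frames=len(s),
        total=base.total,
        range=base.range,
        mean=base.mean,
        std=base.std,
        peaks=peaks,
        sd1=sd1,
        sd2=sd2,
        per_second_total=base.total * fps / len(s),
    )


def glossography_summary(
    session: Session,
    config: AnalysisConfig | None = None,
    *,
    index_frame: int | None = None,
) -> tuple[GlossoSummary, GlossoSummary]:
    """Tongue-displacement and whole-face summary blocks for one session.

    The tongue block is computed on the displacement magnitude of the
    reference landmark from the index frame and carries peak and
    Poincaré descriptors; the whole-face block summarises the
    whole-face vector series.  Expects a cleaned session.
    """
    cfg = config or AnalysisConfig(fps=session.fps)
    if cfg.reference not in session.tracks:
        raise ValueError(
            f"session {session.label!r} lacks reference landmark "
            f"{cfg.reference!r}"
        )
    if index_frame is None:
        index_frame = select_index_frame(session, cfg.conf_threshold).frame
    disp = displacement_from_index(session.tracks[cfg.reference], index_frame)
    face = whole_face_series(
        session, cfg.reference, cfg.whole_face_mode, index_frame
    )
    tongue_block = _summarize_block(
        session.label,
        disp.magnitude,
        session.fps,
        cfg.std_ddof,
        with_peaks=True,
        min_prominence=cfg.peak_min_prominence,
        min_distance=max(1, round(cfg.peak_min_distance_s * session.fps)),
    )
    face_block = _summarize_block(session.label, face, session.fps, cfg.std_ddof)
    return tongue_block, face_block


def summary_frame(rows: list[tuple[GlossoSummary, GlossoSummary]]):
    """Stack (tongue, whole-face) block pairs into a summary table.

    Column order follows the standard glossographic report: the tongue
    block (total, range, mean, std, peaks, SD1, SD2) then the whole-face
    block (total, range, mean, std), plus frame counts and per-second
    totals.
    """
    import pandas as pd

    records = []
    for tongue, face in rows:
        records.append(
            {
                "label": tongue.label,
                "tongue_total": tongue.total,
                "tongue_range": tongue.range,
                "tongue_mean": tongue.mean,
                "tongue_std": tongue.std,
                "tongue_peaks": tongue.peaks,
                "tongue_sd1": tongue.sd1,
                "tongue_sd2": tongue.sd2,
                "face_total": face.total,
                "face_range": face.range,
                "face_mean": face.mean,
                "face_std": face.std,
                "n_frames": tongue.n_frames,
                "tongue_total_per_s": tongue.per_second_total,
                "face_total_per_s": face.per_second_total,
            }
        )
    return pd.DataFrame.from_records(records)
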