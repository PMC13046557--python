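"""Reading, cleaning and writing landmark coordinate tables.

Two on-disk dialects are supported:

* the DeepLabCut CSV export — three header rows (``scorer``, ``bodyparts``,
  ``coords``) followed by one row per frame, with an ``x``, ``y``,
  ``likelihood`` column triplet per body part and a leading frame-index
  column;
* a plain wide CSV — columns ``frame``, ``<name>_x``, ``<name>_y`` and
  optionally ``<name>_likelihood`` (missing likelihood columns default
  to 1.0).

Coordinates are pixels in image convention: origin top-left, y increases
downward.  Time is ``frame / fps``; the file's frame-index column orders
the rows but is not trusted for timing.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataQualityError, FormatError

__all__ = [
    "LandmarkTrack",
    "Session",
    "read_dlc_csv",
    "read_plain_csv",
    "clean_track",
    "write_session_csv",
]

_DLC_HEADER_ROWS = ("scorer", "bodyparts", "coords")


@dataclass(frozen=True)
class LandmarkTrack:
    """One landmark's per-frame pixel coordinates and tracking confidence.

    Parameters
    ----------
    name
        Landmark label, e.g. ``"tongue_tip"``.
    x, y
        Per-frame pixel coordinates (image convention, y down).
    likelihood
        Per-frame tracking confidence in [0, 1].
    n_imputed
        Number of frames whose coordinates were replaced by
        :func:`clean_track` (0 for raw tracks).
    """

    name: str
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    n_imputed: int = 0

    def __post_init__(self) -> None:
        for attr in ("x", "y", "likelihood"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            object.__setattr__(self, attr, arr)
        if not (self.x.ndim == self.y.ndim == self.likelihood.ndim == 1):
            raise ValueError("x, y and likelihood must be 1-D")
        if not (len(self.x) == len(self.y) == len(self.likelihood)):
            raise ValueError(
                f"track {self.name!r}: x, y and likelihood lengths differ"
            )
        if len(self.x) < 1:
            raise ValueError(f"track {self.name!r}: needs at least one frame")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError(f"track {self.name!r}: non-finite coordinates")
        if ((self.likelihood < 0) | (self.likelihood > 1)).any():
            raise ValueError(f"track {self.name!r}: likelihood outside [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class Session:
    """A named recording: frame rate plus equal-length landmark tracks."""

    label: str
    fps: float
    tracks: Mapping[str, LandmarkTrack] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if not self.tracks:
            raise ValueError("session must contain at least one track")
        lengths = {t.n_frames for t in self.tracks.values()}
        if len(lengths) != 1:
            raise ValueError(f"tracks have differing frame counts: {lengths}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.tracks.values())).n_frames

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def __getitem__(self, name: str) -> LandmarkTrack:
        return self.tracks[name]


def _to_numeric(frame: pd.DataFrame, path: str) -> pd.DataFrame:
    """Coerce every cell to float, reporting the first offending cell."""
    coerced = frame.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & frame.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {frame.iat[r, c]!r} "
            f"in data row {r}, column {frame.columns[c]}"
        )
    if coerced.isna().to_numpy().any():
        r, c = np.argwhere(coerced.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value in data row {r}, column {frame.columns[c]}"
        )
    return coerced.astype(float)


def read_dlc_csv(path: str | Path, fps: float, label: str | None = None) -> Session:
    """Read a DeepLabCut-style CSV export into a :class:`Session`.

    The file must carry the three DeepLabCut header rows (``scorer``,
    ``bodyparts``, ``coords``) and an ``x, y, likelihood`` triplet per
    body part.  Frames are ordered by the leading index column.
    """
    if fps <= 0:
        raise ValueError(f"fps must be > 0, got {fps}")
    path = Path(path)
    with open(path, newline="") as fh:
        text = fh.read()
    lines = text.splitlines()
    if len(lines) < 4:
        raise FormatError(f"{path}: expected 3 header rows plus data")
    for i, expected in enumerate(_DLC_HEADER_ROWS):
        first = lines[i].split(",", 1)[0].strip().lower()
        if first != expected:
            raise FormatError(
                f"{path}: header row {i + 1} should start with "
                f"{expected!r}, found {first!r}"
            )

    df = pd.read_csv(_io.StringIO(text), header=[0, 1, 2], index_col=0)
    bodyparts = [c[1] for c in df.columns]
    coords = [str(c[2]).strip().lower() for c in df.columns]

    # group columns per body part, preserving file order, rejecting re-entries
    order: list[str] = []
    groups: dict[str, dict[str, int]] = {}
    for j, (bp, coord) in enumerate(zip(bodyparts, coords)):
        if bp not in groups:
            groups[bp] = {}
            order.append(bp)
        elif order[-1] != bp:
            raise FormatError(f"{path}: duplicate body part {bp!r}")
        base = coord.split(".")[0]
        if base in ("x", "y", "likelihood") and base != coord:
            # pandas mangles repeated column tuples to e.g. "x.1"
            raise FormatError(f"{path}: duplicate {base!r} column for {bp!r}")
        if coord not in ("x", "y", "likelihood"):
            raise FormatError(
                f"{path}: unexpected coords entry {coord!r} for {bp!r} "
                "(third header row must hold x, y, likelihood triplets)"
            )
        if coord in groups[bp]:
            raise FormatError(f"{path}: duplicate {coord!r} column for {bp!r}")
        groups[bp][coord] = j
    for bp in order:
        missing = {"x", "y", "likelihood"} - set(groups[bp])
        if missing:
            raise FormatError(
                f"{path}: body part {bp!r} lacks {sorted(missing)} "
                "column(s) in the 'coords' header row"
            )

    values = _to_numeric(df.reset_index(drop=True), str(path))
    frame_index = pd.to_numeric(pd.Series(df.index), errors="coerce")
    if frame_index.isna().any():
        raise FormatError(f"{path}: non-numeric frame index")
    row_order = np.argsort(frame_index.to_numpy(), kind="stable")

    tracks = {}
    for bp in order:
        g = groups[bp]
        tracks[bp] = LandmarkTrack(
            name=bp,
            x=values.iloc[row_order, g["x"]].to_numpy(),
            y=values.iloc[row_order, g["y"]].to_numpy(),
            likelihood=values.iloc[row_order, g["likelihood"]].to_numpy(),
        )
    return Session(label=label if label is not None else path.stem,
                   fps=fps, tracks=tracks)


def read_plain_csv(path: str | Path, fps: float, label: str | None = None) -> Session:
    """Read the plain wide-CSV dialect (``frame``, ``<name>_x``, ...)."""
    if fps <= 0:
        raise ValueError(f"fps must be > 0, got {fps}")
    path = Path(path)
    df = pd.read_csv(path)
    if "frame" not in df.columns:
        raise FormatError(f"{path}: missing 'frame' column")

    names = [c[:-2] for c in df.columns if c.endswith("_x")]
    if not names:
        raise FormatError(f"{path}: no '<name>_x' coordinate columns found")
    for name in names:
        if f"{name}_y" not in df.columns:
            raise FormatError(f"{path}: missing column {name + '_y'!r}")

    frame_col = pd.to_numeric(df["frame"], errors="coerce")
    if frame_col.isna().any():
        raise FormatError(f"{path}: non-numeric frame index")
    row_order = np.argsort(frame_col.to_numpy(), kind="stable")
    data_cols = [c for c in df.columns if c != "frame"]
    values = _to_numeric(df[data_cols], str(path))

    tracks = {}
    for name in names:
        lk_col = f"{name}_likelihood"
        likelihood = (
            values[lk_col].to_numpy()[row_order]
            if lk_col in values.columns
            else np.ones(len(df))
        )
        tracks[name] = LandmarkTrack(
            name=name,
            x=values[f"{name}_x"].to_numpy()[row_order],
            y=values[f"{name}_y"].to_numpy()[row_order],
            likelihood=likelihood,
        )
    return Session(label=label if label is not None else path.stem,
                   fps=fps, tracks=tracks)


def _low_confidence_runs(low: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of consecutive True values."""
    padded = np.concatenate(([False], low, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def clean_track(
    track: LandmarkTrack,
    conf_threshold: float = 0.9,
    max_gap: int = 12,
) -> LandmarkTrack:
    """Impute low-confidence frames by linear interpolation.

    Frames with ``likelihood < conf_threshold`` get x and y replaced by
    linear interpolation between the nearest confident neighbours;
    leading/trailing low-confidence runs take the nearest confident
    value.  Confident frames are never modified.

    Raises
    ------
    DataQualityError
        If a low-confidence run exceeds ``max_gap`` frames, or no frame
        is confident at all.
    """
    if track.n_frames < 2:
        raise ValueError("clean_track needs at least 2 frames")
    low = track.likelihood < conf_threshold
    if not low.any():
        return track
    if low.all():
        raise DataQualityError(
            f"track {track.name!r}: no frame reaches likelihood "
            f">= {conf_threshold}"
        )
    for start, stop in _low_confidence_runs(low):
        if stop - start > max_gap:
            raise DataQualityError(
                f"track {track.name!r}: low-confidence run of "
                f"{stop - start} frames ({start}-{stop - 1}) exceeds "
                f"max_gap={max_gap}"
            )
    good = np.flatnonzero(~low)
    idx = np.arange(track.n_frames)
    x = track.x.copy()
    y = track.y.copy()
    x[low] = np.interp(idx[low], good, track.x[good])
    y[low] = np.interp(idx[low], good, track.y[good])
    return replace(track, x=x, y=y, n_imputed=int(low.sum()))


def write_session_csv(session: Session, path: str | Path) -> None:
    """Write a session in the DeepLabCut 3-header-row dialect.

    Floats are written with ``repr`` so a read-back reproduces the
    coordinates exactly.
    """
    if not session.tracks:  # unreachable via the Session constructor
        raise ValueError("session has no tracks to write")
    path = Path(path)
    names = list(session.tracks)
    lines = [
        "scorer" + ",glossography" * (3 * len(names)),
        "bodyparts," + ",".join(f"{n},{n},{n}" for n in names),
        "coords" + ",x,y,likelihood" * len(names),
    ]
    cols = []
    for n in names:
        t = session.tracks[n]
        cols.extend([t.x, t.y, t.likelihood])
    for i in range(session.n_frames):
        lines.append(",".join([str(i)] + [repr(float(c[i])) for c in cols]))
    path.write_text("\n".join(lines) + "\n")
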