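"""Declarative analysis configuration.

A single YAML file (or the defaults) drives the whole pipeline.  Every
report echoes the full configuration for provenance, since kinematic
metrics are only comparable across sessions recorded and analysed with
the same parameters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["AnalysisConfig"]

_WHOLE_FACE_MODES = ("deviation", "raw")


@dataclass
class AnalysisConfig:
    """Parameters of the glossographic pipeline.

    Attributes
    ----------
    landmarks
        Landmark names expected in every session.
    reference
        The tracked landmark whose displacement defines the primary
        series (the tongue tip).
    fps
        Video frame rate (frames/s).
    conf_threshold
        Tracking-likelihood cutoff for cleaning and index-frame choice.
    max_gap_s
        Longest low-confidence run (seconds) that may be imputed.
    whole_face_mode
        ``"deviation"`` (default) or ``"raw"`` whole-face vector series.
    peak_min_prominence
        Absolute prominence floor (px) for peak detection; ``None``
        means 10% of the series range.
    peak_min_distance_s
        Minimum separation between accepted peaks, in seconds.
    std_ddof
        0 for population standard deviation (default; keeps the
        Poincaré identity SD1²+SD2² ≈ 2·Var exact), 1 for sample.
    alpha
        Significance level for session comparison.
    report_p_threshold
        Adjusted-p level flagged in comparison reports (the "highly
        significant" dash level).
    output_dir
        Where CLI commands write their files.
    """

    landmarks: list[str] = field(
        default_factory=lambda: ["forehead", "nose", "tongue_tip", "chin"]
    )
    reference: str = "tongue_tip"
    fps: float = 25.0
    conf_threshold: float = 0.9
    max_gap_s: float = 0.5
    whole_face_mode: str = "deviation"
    peak_min_prominence: float | None = None
    peak_min_distance_s: float = 0.5
    std_ddof: int = 0
    alpha: float = 0.05
    report_p_threshold: float = 0.001
    output_dir: str = "glossography_out"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ConfigError(f"fps must be > 0, got {self.fps}")
        if not 0 <= self.conf_threshold <= 1:
            raise ConfigError(
                f"conf_threshold must be in [0, 1], got {self.conf_threshold}"
            )
        if self.max_gap_s <= 0:
            raise ConfigError(f"max_gap_s must be > 0, got {self.max_gap_s}")
        if self.whole_face_mode not in _WHOLE_FACE_MODES:
            raise ConfigError(
                f"whole_face_mode must be one of {_WHOLE_FACE_MODES}, "
                f"got {self.whole_face_mode!r}"
            )
        if self.peak_min_prominence is not None and self.peak_min_prominence < 0:
            raise ConfigError("peak_min_prominence must be >= 0")
        if self.peak_min_distance_s <= 0:
            raise ConfigError("peak_min_distance_s must be > 0")
        if self.std_ddof not in (0, 1):
            raise ConfigError(f"std_ddof must be 0 or 1, got {self.std_ddof}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.report_p_threshold < 1:
            raise ConfigError("report_p_threshold must be in (0, 1)")
        if not self.landmarks:
            raise ConfigError("landmarks list must not be empty")
        if self.reference not in self.landmarks:
            raise ConfigError(
                f"reference {self.reference!r} is not among landmarks "
                f"{self.landmarks}"
            )

    @property
    def max_gap_frames(self) -> int:
        return max(1, round(self.max_gap_s * self.fps))

    @property
    def peak_min_distance_frames(self) -> int:
        return max(1, round(self.peak_min_distance_s * self.fps))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config file, rejecting unknown keys."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def to_dict(self) -> dict:
        return asdict(self)
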