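"""Between-session inference: one-way ANOVA with post-hoc Tukey HSD.

Per-frame displacement values are grouped by session ("day") and frames
are treated as independent observations.  That is the convention of the
underlying clinical analysis; video frames are of course autocorrelated,
so the resulting p-values are anti-conservative and should be read as
descriptive of this recording, not as population inference.  No
autocorrelation correction is applied.

The F statistic and the studentized-range statistic are computed from
the classical sums-of-squares formulas.  Tail probabilities of the
studentized range are obtained by direct numerical integration of its
distribution (see :func:`studentized_range_sf`); the unbalanced case
uses the Tukey–Kramer standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import integrate
from scipy import stats as sps
from scipy.special import gammaln, ndtr

from .config import AnalysisConfig
from .io import Session
from .kinematics import session_series

__all__ = [
    "AnovaResult",
    "TukeyEntry",
    "ComparisonResult",
    "NormalityReport",
    "anova_oneway",
    "tukey_hsd",
    "studentized_range_sf",
    "compare_sessions",
    "normality_screen",
]

logger = logging.getLogger(__name__)


class AnovaResult(NamedTuple):
    f_stat: float
    p_value: float


@dataclass(frozen=True)
class TukeyEntry:
    """One Tukey HSD pairwise comparison (each unordered pair once)."""

    pair: tuple[str, str]
    mean_diff: float   # mean(b) - mean(a), px
    q_stat: float      # studentized range statistic
    p_adj: float       # Tukey-adjusted p-value
    significant: bool  # p_adj < alpha


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    f_stat: float
    p_value: float
    tukey: list[TukeyEntry]
    alpha: float


@dataclass(frozen=True)
class NormalityReport:
    """Descriptive normality screen: moments and a histogram, never a gate."""

    n: int
    mean: float
    std: float
    skewness: float
    excess_kurtosis: float
    hist_counts: np.ndarray
    bin_edges: np.ndarray
    flagged: bool
    note: str


def _check_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = []
    for i, g in enumerate(groups):
        g = np.asarray(g, dtype=float).ravel()
        if g.size < 2:
            raise ValueError(f"group {i} has {g.size} values; need >= 2")
        out.append(g)
    return out


def _decompose(groups: list[np.ndarray]):
    """Classical one-way decomposition: (ss_between, ss_within, df_b, df_w)."""
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = all_values.size - len(groups)
    return ss_between, ss_within, df_between, df_within


def anova_oneway(groups: Sequence) -> AnovaResult:
    """One-way fixed-effects ANOVA from the sums-of-squares formulas.

    F = (SS_between/df_between) / (SS_within/df_within); the p-value is
    the upper tail of the F(df_between, df_within) distribution.  A
    completely constant data set yields F = 0, p = 1 by convention.
    """
    groups = _check_groups(groups)
    ss_b, ss_w, df_b, df_w = _decompose(groups)
    if ss_w == 0.0:
        if ss_b == 0.0:
            return AnovaResult(0.0, 1.0)
        return AnovaResult(float("inf"), 0.0)
    f = (ss_b / df_b) / (ss_w / df_w)
    return AnovaResult(float(f), float(sps.f.sf(f, df_b, df_w)))


# --- studentized range distribution -----------------------------------------

def _srange_cdf_inf(q: float, k: int) -> float:
    """CDF of the range of k standard normals (infinite df)."""
    if q <= 0:
        return 0.0

    def integrand(z: float) -> float:
        return np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi) * (
            ndtr(z) - ndtr(z - q)
        ) ** (k - 1)

    val, _ = integrate.quad(integrand, -np.inf, np.inf,
                            epsabs=1e-11, epsrel=1e-10, limit=200)
    return min(1.0, k * val)


def studentized_range_sf(q: float, k: int, df: float) -> float:
    """Upper-tail probability of the studentized range Q(k, df).

    Computed by numerical integration: the range CDF of k standard
    normals is averaged over the distribution of the scale estimate
    s = sqrt(chi²_df / df),

        P(Q <= q) = ∫₀^∞ f_s(s) · P_range(q·s; k) ds,

    with f_s the scaled-chi density.  For df above 1e5 the
    infinite-df limit is used.  Absolute accuracy ~1e-8.
    """
    if q <= 0:
        return 1.0
    if k < 2:
        raise ValueError("k must be >= 2")
    if df <= 0:
        raise ValueError("df must be > 0")
    if df > 1e5:
        return 1.0 - _srange_cdf_inf(q, k)

    half = df / 2.0
    log_norm = np.log(2.0) + half * np.log(half) - gammaln(half)

    def outer(s: float) -> float:
        if s <= 0:
            return 0.0
        log_f = log_norm + (df - 1.0) * np.log(s) - half * s * s
        return np.exp(log_f) * _srange_cdf_inf(q * s, k)

    # the scaled-chi density has mean ~1, sd ~1/sqrt(2 df)
    if df >= 10:
        spread = 14.0 / np.sqrt(2.0 * df)
        lo, hi = max(0.0, 1.0 - spread), 1.0 + spread
    else:
        lo, hi = 0.0, np.sqrt(2.0 * (60.0 / df + 1.0)) + 2.0
    cdf, _ = integrate.quad(outer, lo, hi, epsabs=1e-10, epsrel=1e-9, limit=200)
    return float(min(1.0, max(0.0, 1.0 - cdf)))


def tukey_hsd(
    groups: Sequence,
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> list[TukeyEntry]:
    """All-pairs Tukey HSD (Tukey–Kramer for unbalanced designs).

    For each pair (i, j):
    q = |mean_i - mean_j| / sqrt(MS_within/2 · (1/n_i + 1/n_j)),
    with the adjusted p-value from the studentized range distribution
    with k groups and the ANOVA within-group df.
    """
    groups = _check_groups(groups)
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    k = len(groups)
    if labels is None:
        labels = [str(i) for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match number of groups")
    _, ss_w, _, df_w = _decompose(groups)
    ms_w = ss_w / df_w
    entries = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            diff = b.mean() - a.mean()
            if ms_w == 0.0:
                q = 0.0 if diff == 0.0 else float("inf")
                p = 1.0 if diff == 0.0 else 0.0
            else:
                se = np.sqrt(ms_w / 2.0 * (1.0 / a.size + 1.0 / b.size))
                q = abs(diff) / se
                p = studentized_range_sf(q, k, df_w)
            entries.append(
                TukeyEntry(
                    pair=(labels[i], labels[j]),
                    mean_diff=float(diff),
                    q_stat=float(q),
                    p_adj=float(p),
                    significant=bool(p < alpha),
                )
            )
    return entries


def normality_screen(sample, bins: int = 10) -> NormalityReport:
    """Descriptive normality report: moments plus histogram counts.

    This mirrors a by-eye normality check: it flags clearly skewed,
    heavy-tailed, degenerate or too-small samples with a warning but
    never gates the downstream ANOVA.
    """
    sample = np.asarray(sample, dtype=float).ravel()
    n = sample.size
    if n < 8:
        return NormalityReport(
            n=n, mean=float(np.mean(sample)) if n else float("nan"),
            std=float(np.std(sample)) if n else float("nan"),
            skewness=float("nan"), excess_kurtosis=float("nan"),
            hist_counts=np.zeros(bins, dtype=int),
            bin_edges=np.zeros(bins + 1),
            flagged=True, note="insufficient sample (n < 8)",
        )
    std = float(sample.std())
    counts, edges = np.histogram(sample, bins=bins)
    if std == 0.0:
        return NormalityReport(
            n=n, mean=float(sample.mean()), std=0.0,
            skewness=float("nan"), excess_kurtosis=float("nan"),
            hist_counts=counts, bin_edges=edges,
            flagged=True, note="degenerate (constant) sample",
        )
    skew = float(sps.skew(sample))
    kurt = float(sps.kurtosis(sample))  # excess kurtosis
    flagged = abs(skew) > 1.0 or abs(kurt) > 2.0
    note = "ok"
    if flagged:
        note = (f"distribution looks non-normal "
                f"(skewness {skew:.2f}, excess kurtosis {kurt:.2f})")
    return NormalityReport(
        n=n, mean=float(sample.mean()), std=std,
        skewness=skew, excess_kurtosis=kurt,
        hist_counts=counts, bin_edges=edges,
        flagged=flagged, note=note,
    )


def compare_sessions(
    sessions: Sequence[Session],
    metric: str = "tongue_dx",
    alpha: float = 0.05,
    config: AnalysisConfig | None = None,
) -> ComparisonResult:
    """ANOVA + Tukey HSD of one per-frame series across sessions.

    The default metric is the tongue-tip x-axis displacement.  Each
    group is screened for gross non-normality (warning only).
    """
    if len(sessions) < 2:
        raise ValueError("compare_sessions needs at least 2 sessions")
    cfg = config or AnalysisConfig(fps=sessions[0].fps)
    groups, labels = [], []
    for session in sessions:
        s = session_series(
            session,
            metric,
            reference=cfg.reference,
            mode=cfg.whole_face_mode,
            conf_threshold=cfg.conf_threshold,
        )
        report = normality_screen(s)
        if report.flagged:
            logger.warning(
                "normality screen for session %r (%s): %s",
                session.label, metric, report.note,
            )
        groups.append(s)
        labels.append(str(session.label))
    f_stat, p_value = anova_oneway(groups)
    entries = tukey_hsd(groups, alpha=alpha, labels=labels)
    return ComparisonResult(
        metric=metric, f_stat=f_stat, p_value=p_value,
        tukey=entries, alpha=alpha,
    )
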