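"""Motion-based volume censoring (scrubbing) and subject inclusion.

Framewise displacement (FD) summarizes head motion between consecutive
volumes, in mm.  Volumes whose FD strictly exceeds the threshold
(default 0.3 mm) are removed together with the volume before and after;
subjects keeping fewer than half of their volumes are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

FD_THRESHOLD_MM = 0.3
MIN_FRAC_KEPT = 0.5


@dataclass
class MotionTrace:
    """Per-volume framewise displacement for one subject (mm)."""

    fd: np.ndarray

    def __post_init__(self):
        self.fd = np.asarray(self.fd, dtype=float)
        if self.fd.ndim != 1 or self.fd.size == 0:
            raise ValueError("FD trace must be a non-empty 1-D array")
        if np.any(self.fd < 0) or not np.all(np.isfinite(self.fd)):
            raise ValueError("FD values must be finite and non-negative")

    @property
    def n_volumes(self) -> int:
        return self.fd.size

    @property
    def mean_fd(self) -> float:
        return float(self.fd.mean())


@dataclass
class CensorMask:
    """Boolean keep-mask over volumes plus the retained fraction."""

    keep: np.ndarray

    def __post_init__(self):
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_volumes(self) -> int:
        return self.keep.size

    @property
    def frac_kept(self) -> float:
        return float(self.keep.mean())


def censor_volumes(trace: MotionTrace | np.ndarray,
                   threshold: float = FD_THRESHOLD_MM) -> CensorMask:
    """Censor every volume with FD > threshold plus its two neighbours.

    The inequality is strict (FD exactly at the threshold is kept) and
    the one-volume margin is clipped at the series boundaries.
    """
    if not isinstance(trace, MotionTrace):
        trace = MotionTrace(trace)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bad = trace.fd > threshold
    censored = bad.copy()
    censored[:-1] |= bad[1:]   # volume before a violation
    censored[1:] |= bad[:-1]   # volume after
    return CensorMask(keep=~censored)


def include_subject(mask: CensorMask,
                    min_frac: float = MIN_FRAC_KEPT) -> bool:
    """Whether a subject retains at least ``min_frac`` of volumes."""
    return mask.frac_kept >= min_frac


def percent_censored_by_group(cohort, threshold: float = FD_THRESHOLD_MM):
    """Mean +/- SEM censored fraction per group and the group-difference t.

    Returns ``(summary, t, p)`` where ``summary`` maps group label to
    ``(mean, sem, n)`` over subjects' censored fractions.  The t test is
    the pooled-variance two-sample t over the two groups in sorted
    label order (first minus second).
    """
    by_group: dict[str, list[float]] = {}
    for subj in cohort.subjects:
        mask = censor_volumes(subj.fd_trace, threshold=threshold)
        by_group.setdefault(subj.group, []).append(1.0 - mask.frac_kept)
    for g, vals in by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    if len(by_group) != 2:
        raise ValueError("exactly two groups required for the t test")
    g1, g2 = sorted(by_group)
    summary = {
        g: (float(np.mean(v)), float(stats.sem(v)), len(v))
        for g, v in by_group.items()
    }
    a, b = np.asarray(by_group[g1]), np.asarray(by_group[g2])
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: no within-group variance
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return summary, float(t), float(p)
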