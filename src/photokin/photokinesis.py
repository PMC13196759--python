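"""Photokinesis scoring: 30-s activity bins, transition deltas, and the PI.

The photokinesis index of one fish is

    PI = (dt_on_off - dt_off_on) / (dt_on_off + dt_off_on)

where each transition delta is the mean distance moved in the 30-s bin(s)
after a light transition minus the bin(s) before, averaged across all
transitions of that type.  PI > 0 marks a dark-activated (surface-like)
fish, PI < 0 a light-activated (cave-like) fish.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic_data import ON, OFF, LightSchedule, LocomotorTrack

logger = logging.getLogger("photokin")

#: Default activity bin width (s); raw tracker output is binned at 30 s.
DEFAULT_BIN_S = 30.0
#: Centroid steps below this length (mm) are treated as tracker jitter.
DEFAULT_JITTER_MM = 0.1
#: Fish whose total transition change is below this (mm) are flagged invalid.
DEFAULT_DENOM_EPSILON = 1e-6


@dataclass(frozen=True)
class BinnedActivity:
    """Distance moved (mm) per half-open, contiguous time bin for one well."""

    well_id: str
    bin_s: float
    bin_start_s: np.ndarray
    distance_mm: np.ndarray

    def __post_init__(self) -> None:
        if len(self.bin_start_s) != len(self.distance_mm):
            raise ValueError("bin_start_s and distance_mm must have equal length")
        if np.any(np.asarray(self.distance_mm) < 0):
            raise ValueError("binned distances must be non-negative")


@dataclass(frozen=True)
class TransitionDelta:
    """Averaged activity changes at light transitions for one fish.

    ``delta_on_off`` is the mean (across ON->OFF transitions) of
    post-window minus pre-window distance; likewise ``delta_off_on``.
    Per-transition values are retained for the per-transition PI variant.
    """

    well_id: str
    delta_on_off: float
    delta_off_on: float
    n_on_off: int
    n_off_on: int
    on_off_deltas: tuple[float, ...] = ()
    off_on_deltas: tuple[float, ...] = ()


@dataclass(frozen=True)
class PhotokinesisRecord:
    """PI statistic for one fish, or an exclusion with its reason."""

    well_id: str
    delta_on_off: float
    delta_off_on: float
    n_on_off: int
    n_off_on: int
    pi: float
    valid: bool
    reason: str = ""
    population: str = ""


@dataclass
class StatsReport:
    """Group-comparison report: omnibus test plus adjusted pairwise p-values."""

    test: str
    groups: dict[str, dict]
    statistic: float
    p_value: float
    pairwise: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "groups": self.groups,
            "pairwise": self.pairwise,
        }


def bin_activity(
    track: LocomotorTrack,
    bin_s: float = DEFAULT_BIN_S,
    jitter_mm: float = DEFAULT_JITTER_MM,
) -> BinnedActivity:
    """Sum Euclidean step lengths into contiguous bins from assay start.

    A step belongs to the bin containing its start time; steps shorter than
    ``jitter_mm`` are zeroed as centroid noise; a trailing partial bin is
    dropped.
    """
    t = np.asarray(track.time_s, dtype=float)
    if t.size < 2:
        raise ValueError("track must contain at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("track time must be strictly increasing")
    # dropped frames are tolerated; spacing must be a multiple of the base interval
    base = np.min(dt)
    mult = dt / base
    if np.max(np.abs(mult - np.round(mult))) > 1e-4:
        raise ValueError("track frame spacing must be a multiple of one interval")
    steps = np.hypot(np.diff(track.x_mm), np.diff(track.y_mm))
    if jitter_mm > 0:
        steps = np.where(steps < jitter_mm, 0.0, steps)
    n_bins = int(np.floor((t[-1] - t[0] + 1e-9) / bin_s))
    if n_bins < 1:
        raise ValueError("track shorter than one bin")
    idx = np.floor((t[:-1] - t[0]) / bin_s).astype(int)
    keep = idx < n_bins
    dist = np.bincount(idx[keep], weights=steps[keep], minlength=n_bins)
    starts = t[0] + bin_s * np.arange(n_bins)
    return BinnedActivity(track.well_id, bin_s, starts, dist)


def extract_transition_deltas(
    binned: BinnedActivity,
    schedule: LightSchedule,
    window_bins: int = 1,
    skip_acclimation: bool = True,
) -> TransitionDelta:
    """Average post-minus-pre activity around each light transition.

    The window is ``window_bins`` bins on each side of the transition.
    Transitions must align to bin edges; transitions whose windows are not
    fully covered by the binned record are dropped.  The acclimation-to-
    first-epoch boundary is excluded by default (it is not part of the
    alternating cycles).
    """
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    d = np.asarray(binned.distance_mm, dtype=float)
    n = len(d)
    on_off, off_on = [], []
    for time, before, after, ends_acc in schedule.transitions():
        if ends_acc and skip_acclimation:
            continue
        k = (time - binned.bin_start_s[0]) / binned.bin_s
        if abs(k - round(k)) > 1e-6:
            raise ValueError("schedule transitions must align to bin edges")
        k = int(round(k))
        if k - window_bins < 0 or k + window_bins > n:
            continue
        delta = float(np.mean(d[k : k + window_bins]) - np.mean(d[k - window_bins : k]))
        (on_off if (before, after) == (ON, OFF) else off_on).append(delta)
    return TransitionDelta(
        well_id=binned.well_id,
        delta_on_off=float(np.mean(on_off)) if on_off else float("nan"),
        delta_off_on=float(np.mean(off_on)) if off_on else float("nan"),
        n_on_off=len(on_off),
        n_off_on=len(off_on),
        on_off_deltas=tuple(on_off),
        off_on_deltas=tuple(off_on),
    )


def photokinesis_index(
    delta: TransitionDelta,
    denom_epsilon: float = DEFAULT_DENOM_EPSILON,
    population: str = "",
) -> PhotokinesisRecord:
    """Evaluate PI = (d_on_off - d_off_on) / (d_on_off + d_off_on).

    Records missing a transition type or with |denominator| below
    ``denom_epsilon`` are flagged invalid (with a reason) instead of
    producing an unbounded index.
    """
    base = dict(
        well_id=delta.well_id,
        delta_on_off=delta.delta_on_off,
        delta_off_on=delta.delta_off_on,
        n_on_off=delta.n_on_off,
        n_off_on=delta.n_off_on,
        population=population,
    )
    if delta.n_on_off < 1 or delta.n_off_on < 1:
        missing = "ON->OFF" if delta.n_on_off < 1 else "OFF->ON"
        return PhotokinesisRecord(
            pi=float("nan"), valid=False, reason=f"no {missing} transitions", **base
        )
    denom = delta.delta_on_off + delta.delta_off_on
    if not np.isfinite(denom) or abs(denom) < denom_epsilon:
        return PhotokinesisRecord(
            pi=float("nan"),
            valid=False,
            reason="total transition change below epsilon",
            **base,
        )
    pi = (delta.delta_on_off - delta.delta_off_on) / denom
    return PhotokinesisRecord(pi=float(pi), valid=True, **base)


def score_population(
    tracks: Sequence[LocomotorTrack],
    schedule: LightSchedule,
    *,
    population: str = "",
    bin_s: float = DEFAULT_BIN_S,
    jitter_mm: float = DEFAULT_JITTER_MM,
    window_bins: int = 1,
    skip_acclimation: bool = True,
    denom_epsilon: float = DEFAULT_DENOM_EPSILON,
    per_transition: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Score every track of one population; return PI table and summary.

    With ``per_transition=True`` the index is computed per paired transition
    and then averaged per fish, instead of averaging the deltas first
    (default; transitions pair in temporal order, extras are dropped).
    """
    if len(tracks) == 0:
        raise ValueError("at least one track is required")
    records = []
    for track in tracks:
        delta = extract_transition_deltas(
            bin_activity(track, bin_s=bin_s, jitter_mm=jitter_mm),
            schedule,
            window_bins=window_bins,
            skip_acclimation=skip_acclimation,
        )
        rec = photokinesis_index(delta, denom_epsilon=denom_epsilon, population=population)
        if per_transition and rec.valid:
            pis = []
            for d1, d2 in zip(delta.on_off_deltas, delta.off_on_deltas):
                if abs(d1 + d2) >= denom_epsilon:
                    pis.append((d1 - d2) / (d1 + d2))
            if pis:
                rec = PhotokinesisRecord(
                    **{**rec.__dict__, "pi": float(np.mean(pis))}
                )
            else:
                rec = PhotokinesisRecord(
                    **{
                        **rec.__dict__,
                        "pi": float("nan"),
                        "valid": False,
                        "reason": "no valid transition pairs",
                    }
                )
        records.append(rec)
    table = pd.DataFrame([r.__dict__ for r in records])
    valid = table[table["valid"]]
    n_excluded = int((~table["valid"]).sum())
    if n_excluded:
        logger.info(
            "%s: excluded %d of %d fish (%s)",
            population or "population",
            n_excluded,
            len(table),
            "; ".join(sorted(set(table.loc[~table["valid"], "reason"]))),
        )
    summary = {
        "population": population,
        "n": int(len(valid)),
        "n_excluded": n_excluded,
        "mean_pi": float(valid["pi"].mean()) if len(valid) else float("nan"),
        "sd_pi": float(valid["pi"].std(ddof=1)) if len(valid) > 1 else float("nan"),
    }
    return table, summary


# ---------------------------------------------------------------------------
# Population statistics
# ---------------------------------------------------------------------------


def _shapiro(values: np.ndarray) -> tuple[float, float]:
    if np.ptp(values) == 0:
        return float("nan"), float("nan")
    w, p = sps.shapiro(values)
    return float(w), float(p)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t-test, defined for zero-variance groups (p=1 when means agree)."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float("inf") * np.sign(np.mean(a) - np.mean(b)), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_populations(groups: Mapping[str, Sequence[float]]) -> StatsReport:
    """Compare PI distributions across labeled groups.

    Two groups: Welch (unequal-variance) t-test.  More than two: one-way
    ANOVA with Tukey-HSD-adjusted pairwise p-values (raw pairwise p from the
    pooled-variance t with N-k degrees of freedom, so adjusted >= raw).
    Shapiro-Wilk normality is reported per group but, following the study's
    procedure, does not switch the test.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("at least two groups are required")
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    for lab, arr in zip(labels, arrays):
        if arr.size < 3:
            raise ValueError(f"group {lab!r} has n < 3")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {lab!r} contains non-finite values")

    group_stats = {}
    for lab, arr in zip(labels, arrays):
        w, p = _shapiro(arr)
        group_stats[lab] = {
            "n": int(arr.size),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)),
            "shapiro_w": w,
            "shapiro_p": p,
        }

    if len(labels) == 2:
        t, p = _welch(arrays[0], arrays[1])
        pair = {
            "group_a": labels[0],
            "group_b": labels[1],
            "diff": float(arrays[0].mean() - arrays[1].mean()),
            "p_raw": p,
            "p_adj": p,
        }
        return StatsReport("welch_t", group_stats, t, p, [pair])

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        pairwise = [
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "diff": 0.0,
                "p_raw": 1.0,
                "p_adj": 1.0,
            }
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        return StatsReport("anova_tukey", group_stats, 0.0, 1.0, pairwise)

    f_stat, f_p = sps.f_oneway(*arrays)
    tukey = sps.tukey_hsd(*arrays)
    n_total = pooled.size
    k = len(labels)
    dof = n_total - k
    mse = sum((arr.size - 1) * arr.var(ddof=1) for arr in arrays) / dof
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(arrays[i].mean() - arrays[j].mean())
            se = np.sqrt(mse * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
            if se == 0:
                p_raw = 1.0 if diff == 0 else 0.0
            else:
                p_raw = float(2.0 * sps.t.sf(abs(diff) / se, dof))
            pairwise.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "diff": diff,
                    "p_raw": p_raw,
                    "p_adj": float(tukey.pvalue[i, j]),
                }
            )
    return StatsReport("anova_tukey", group_stats, float(f_stat), float(f_p), pairwise)
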