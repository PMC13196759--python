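"""Stimulus tuning and hierarchical clustering of GCaMP traces.

Raw fluorescence is normalized to dF/F against the 1-min no-light lead-in,
summarized into per-epoch means under the 30-s ON/OFF imaging schedule, and
clustered agglomeratively (Ward linkage, Euclidean distance on the per-epoch
vector) with the tree cut to at most ``max_clusters`` groups.  Cluster mean
responses are then compared between populations per light condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .photokinesis import _welch
from .synthetic_data import NONE, OFF, ON, LightSchedule

#: Preference dead-band (dF/F): |ON mean - OFF mean| below this is untuned.
DEFAULT_DEAD_BAND = 0.05
#: Default dF/F baseline window: the 1-min no-light lead-in of the protocol.
DEFAULT_BASELINE_WINDOW = (0.0, 60.0)


@dataclass(frozen=True)
class NeuronTrace:
    """One neuron's fluorescence samples at fixed frame rate."""

    neuron_id: str
    frame_rate: float
    fluorescence: np.ndarray
    subject: str = ""
    population: str = ""


@dataclass(frozen=True)
class TuningVector:
    """Per-epoch mean dF/F responses of one neuron, with ON/OFF preference."""

    neuron_id: str
    epoch_states: tuple[str, ...]
    epoch_means: np.ndarray
    on_mean: float
    off_mean: float
    preference: str


@dataclass(frozen=True)
class ClusterResult:
    """Hierarchical clustering of tuning vectors.

    Labels run 1..K (K <= max_clusters) and are renumbered by descending
    cluster size (ties broken by smallest member index).  ``mean_traces``
    maps label -> mean dF/F trace when traces were supplied.
    """

    labels: np.ndarray
    linkage: np.ndarray
    sizes: dict[int, int]
    preferences: dict[int, str] | None = None
    mean_traces: dict[int, np.ndarray] | None = None


def delta_f_over_f(
    trace: NeuronTrace | np.ndarray,
    frame_rate: float | None = None,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
) -> np.ndarray:
    """Normalize raw fluorescence to (f - f0)/f0.

    ``f0`` is the mean over ``baseline_window`` (seconds from trace start);
    a non-positive baseline is an error.
    """
    if isinstance(trace, NeuronTrace):
        f = np.asarray(trace.fluorescence, dtype=float)
        frame_rate = trace.frame_rate
    else:
        f = np.asarray(trace, dtype=float)
        if frame_rate is None:
            raise ValueError("frame_rate is required for a bare array")
    lo, hi = baseline_window
    i0, i1 = int(round(lo * frame_rate)), int(round(hi * frame_rate))
    if not (0 <= i0 < i1 <= len(f)):
        raise ValueError("baseline window must lie within the trace")
    f0 = float(np.mean(f[i0:i1]))
    if f0 <= 0:
        raise ValueError("baseline mean must be positive")
    return (f - f0) / f0


def compute_tuning(
    dff: np.ndarray,
    schedule: LightSchedule,
    frame_rate: float,
    dead_band: float = DEFAULT_DEAD_BAND,
    neuron_id: str = "",
) -> TuningVector:
    """Per-epoch mean dF/F and ON/OFF preference of one neuron.

    Epochs are the schedule's post-acclimation intervals.  Preference is the
    larger of the ON and OFF summary means unless their difference is within
    ``dead_band``, in which case the neuron is untuned (NONE).
    """
    dff = np.asarray(dff, dtype=float)
    states, means = [], []
    for state, start, end in schedule.epochs:
        i0, i1 = int(round(start * frame_rate)), int(round(end * frame_rate))
        i1 = min(i1, len(dff))
        if i1 - i0 < 2:
            raise ValueError("each epoch must contain at least two frames")
        states.append(state)
        means.append(float(np.mean(dff[i0:i1])))
    means_arr = np.array(means)
    states_arr = np.array(states)
    on_mean = float(means_arr[states_arr == ON].mean()) if np.any(states_arr == ON) else float("nan")
    off_mean = float(means_arr[states_arr == OFF].mean()) if np.any(states_arr == OFF) else float("nan")
    diff = on_mean - off_mean
    if not np.isfinite(diff) or abs(diff) < dead_band:
        pref = NONE
    else:
        pref = ON if diff > 0 else OFF
    return TuningVector(
        neuron_id=neuron_id,
        epoch_states=tuple(states),
        epoch_means=means_arr,
        on_mean=on_mean,
        off_mean=off_mean,
        preference=pref,
    )


def tuning_matrix(tuning: list[TuningVector] | np.ndarray) -> np.ndarray:
    if isinstance(tuning, np.ndarray):
        return np.asarray(tuning, dtype=float)
    return np.vstack([tv.epoch_means for tv in tuning])


def cluster_tuning(
    tuning: list[TuningVector] | np.ndarray,
    max_clusters: int = 5,
    dff_traces: np.ndarray | None = None,
    dead_band: float = DEFAULT_DEAD_BAND,
) -> ClusterResult:
    """Ward-linkage clustering of per-epoch tuning vectors.

    The dendrogram is cut to at most ``max_clusters`` flat clusters
    (degenerate data can yield fewer).  When the input is a list of
    :class:`TuningVector`, each cluster also gets an ON/OFF/NONE preference
    from its mean tuning; when ``dff_traces`` (neurons x frames) is given,
    per-cluster mean traces are returned.
    """
    X = tuning_matrix(tuning)
    n = X.shape[0]
    if n < max_clusters:
        raise ValueError(f"need at least {max_clusters} neurons, got {n}")
    Z = hierarchy.linkage(X, method="ward")
    raw = hierarchy.fcluster(Z, t=max_clusters, criterion="maxclust")

    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.argmax(raw == c))),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in raw])
    sizes = {lab: int((labels == lab).sum()) for lab in sorted(remap.values())}

    preferences = None
    if not isinstance(tuning, np.ndarray):
        states = np.array(tuning[0].epoch_states)
        preferences = {}
        for lab in sizes:
            mean_vec = X[labels == lab].mean(axis=0)
            on = mean_vec[states == ON].mean() if np.any(states == ON) else np.nan
            off = mean_vec[states == OFF].mean() if np.any(states == OFF) else np.nan
            diff = on - off
            if not np.isfinite(diff) or abs(diff) < dead_band:
                preferences[lab] = NONE
            else:
                preferences[lab] = ON if diff > 0 else OFF

    mean_traces = None
    if dff_traces is not None:
        dff_traces = np.asarray(dff_traces, dtype=float)
        if dff_traces.shape[0] != n:
            raise ValueError("dff_traces must have one row per neuron")
        mean_traces = {lab: dff_traces[labels == lab].mean(axis=0) for lab in sizes}

    return ClusterResult(
        labels=labels,
        linkage=Z,
        sizes=sizes,
        preferences=preferences,
        mean_traces=mean_traces,
    )


def compare_cluster_response(
    responses: pd.DataFrame,
    *,
    value_col: str = "value",
    cluster_col: str = "cluster",
    condition_col: str = "condition",
    population_col: str = "population",
    subject_col: str = "subject",
) -> pd.DataFrame:
    """Welch t-tests between two populations per cluster x light condition.

    ``responses`` holds one row per subject x cluster x condition with the
    subject's mean cluster dF/F in ``value_col``.  Raw p-values are
    BH-adjusted across the whole family of cluster x condition comparisons.
    """
    pops = sorted(responses[population_col].unique())
    if len(pops) != 2:
        raise ValueError(f"exactly two populations are required, got {pops}")
    conditions = set(responses[condition_col].unique())
    if not {ON, OFF}.issubset(conditions):
        raise ValueError("both ON and OFF conditions are required")

    rows = []
    for (cluster, condition), grp in responses.groupby(
        [cluster_col, condition_col], sort=True
    ):
        a = grp.loc[grp[population_col] == pops[0], value_col].to_numpy(dtype=float)
        b = grp.loc[grp[population_col] == pops[1], value_col].to_numpy(dtype=float)
        if a.size < 3 or b.size < 3:
            raise ValueError(
                f"cluster {cluster} condition {condition}: need >=3 subjects per population"
            )
        t, p = _welch(a, b)
        rows.append(
            dict(
                cluster=cluster,
                condition=condition,
                population_a=pops[0],
                population_b=pops[1],
                n_a=int(a.size),
                n_b=int(b.size),
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                t=t,
                p_raw=p,
            )
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_raw"].to_numpy(), method="fdr_bh")[1]
    return table
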