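"""Synthetic generators for every input the photokinesis pipeline consumes.

The real study records 96-well video of *Astyanax mexicanus* larvae under
alternating 5-min light/dark epochs (after 30 min of dark acclimation),
volumetric brain anatomy, GCaMP fluorescence traces under a 30-s on/off
imaging protocol, and whole-brain pERK stain volumes.  None of that raw data
is needed here: each generator below emits data with the statistical
structure the downstream analysis assumes, with planted ground truth, so the
whole pipeline is testable from a single integer seed.

All randomness flows from one top-level seed split into named substreams
(:func:`substream`), so individual generators are bitwise-reproducible and
independent of call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

ON = "ON"
OFF = "OFF"
NONE = "NONE"
_STATES = (ON, OFF)

GENERATIONS = ("P_surface", "P_cave", "F1", "F2")


def substream(seed: int | np.random.Generator, name: str) -> np.random.Generator:
    """Return a named child RNG derived from a single top-level seed.

    Passing an existing :class:`numpy.random.Generator` returns it unchanged,
    which lets callers thread one stream through several helpers when they
    want sequential draws instead of named substreams.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    entropy = np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf8"))])
    return np.random.default_rng(entropy)


# ---------------------------------------------------------------------------
# Light schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LightSchedule:
    """Ordered, contiguous ON/OFF intervals defining an assay or imaging run.

    ``intervals`` is a tuple of ``(state, start_s, end_s)`` triples starting
    at 0 s with alternating states.  ``acclimation_s`` marks how much of the
    leading dark interval is acclimation rather than an assay epoch; the
    boundary it ends at is excluded from transition scoring by default.
    """

    intervals: tuple[tuple[str, float, float], ...]
    acclimation_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("schedule must contain at least one interval")
        prev_end = 0.0
        prev_state = None
        for state, start, end in self.intervals:
            if state not in _STATES:
                raise ValueError(f"unknown light state {state!r}")
            if abs(start - prev_end) > 1e-9:
                raise ValueError("intervals must be contiguous and start at 0")
            if end <= start:
                raise ValueError("every interval must have end_s > start_s")
            if state == prev_state:
                raise ValueError("adjacent intervals must differ in state")
            prev_end, prev_state = end, state

    @property
    def duration(self) -> float:
        return self.intervals[-1][2]

    @property
    def epochs(self) -> tuple[tuple[str, float, float], ...]:
        """Assay epochs, i.e. intervals at or after the end of acclimation."""
        return tuple(iv for iv in self.intervals if iv[1] >= self.acclimation_s - 1e-9)

    def _starts(self) -> np.ndarray:
        return np.array([s for _, s, _ in self.intervals])

    def _index_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self._starts(), t, side="right") - 1
        return np.clip(idx, 0, len(self.intervals) - 1)

    def state_at(self, t) -> np.ndarray:
        """Vectorized light state at time(s) ``t`` (clamped to the schedule)."""
        is_on = np.array([st == ON for st, _, _ in self.intervals])
        return np.where(is_on[self._index_at(t)], ON, OFF)

    def entry_time_at(self, t) -> np.ndarray:
        """Start time of the interval containing each ``t``."""
        return self._starts()[self._index_at(t)]

    def transitions(self) -> list[tuple[float, str, str, bool]]:
        """Boundaries ``(time, state_before, state_after, ends_acclimation)``."""
        out = []
        for (s0, _, e0), (s1, b1, _) in zip(self.intervals, self.intervals[1:]):
            ends_acc = self.acclimation_s > 0 and abs(b1 - self.acclimation_s) < 1e-9
            out.append((b1, s0, s1, ends_acc))
        return out


def make_schedule(
    acclimation_s: float,
    epoch_s: float,
    n_cycles: int,
    first_state: str = ON,
) -> LightSchedule:
    """Build a dark acclimation followed by ``2*n_cycles`` alternating epochs.

    The behavioral assay is ``make_schedule(1800, 300, 3)`` (30 min dark, then
    alternating 5-min light/dark); the imaging protocol is
    ``make_schedule(60, 30, 4)`` (1 min no light, then 30-s on/off intervals).
    A dark acclimation followed by a first OFF epoch is merged into one OFF
    interval so that adjacent interval states always differ.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    if acclimation_s < 0:
        raise ValueError("acclimation_s must be non-negative")
    if n_cycles < 1:
        raise ValueError("n_cycles must be at least 1")
    if first_state not in _STATES:
        raise ValueError(f"first_state must be one of {_STATES}")

    intervals: list[tuple[str, float, float]] = []
    t = 0.0
    if acclimation_s > 0:
        intervals.append((OFF, 0.0, acclimation_s))
        t = acclimation_s
    state = first_state
    for _ in range(2 * n_cycles):
        intervals.append((state, t, t + epoch_s))
        t += epoch_s
        state = ON if state == OFF else OFF
    if len(intervals) >= 2 and intervals[0][0] == OFF == intervals[1][0]:
        intervals[:2] = [(OFF, 0.0, intervals[1][2])]
    return LightSchedule(tuple(intervals), acclimation_s=acclimation_s)


# ---------------------------------------------------------------------------
# Locomotor model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationParams:
    """Latent locomotor model of one population.

    Per-frame swim speed is
    ``max(0, baseline + [state == trigger]*(sustained + transient*exp(-dt/tau)) + noise)``
    where ``dt`` is the time since the triggering epoch began.  Surface fish
    are dark-triggered (``trigger_state=OFF``), cavefish light-triggered.
    Units: speeds/gains in mm/s, tau in s.
    """

    baseline_speed: float = 0.8
    trigger_state: str = OFF
    sustained_gain: float = 0.0
    transient_gain: float = 2.0
    transient_tau: float = 20.0
    noise_sd: float = 1.5
    label: str = ""

    def __post_init__(self) -> None:
        if self.baseline_speed < 0:
            raise ValueError("baseline_speed must be >= 0")
        if self.transient_tau <= 0:
            raise ValueError("transient_tau must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.trigger_state not in _STATES:
            raise ValueError(f"trigger_state must be one of {_STATES}")


@dataclass(frozen=True)
class MixedPopulationParams:
    """Weighted mixture of triggered responses for hybrid fish.

    A hybrid of genetic value ``g`` responds with weight ``g`` like a surface
    fish (dark-triggered) and weight ``1-g`` like a cavefish (light-triggered);
    baseline and noise interpolate linearly.  ``components`` is a tuple of
    ``(weight, PopulationParams)``.
    """

    components: tuple[tuple[float, PopulationParams], ...]
    baseline_speed: float
    noise_sd: float
    label: str = ""


def surface_like_params(**overrides) -> PopulationParams:
    """Default dark-activated (surface-like) population."""
    kw = dict(trigger_state=OFF, label="surface")
    kw.update(overrides)
    return PopulationParams(**kw)


def cave_like_params(**overrides) -> PopulationParams:
    """Default light-activated (cave-like) population."""
    kw = dict(trigger_state=ON, label="cave")
    kw.update(overrides)
    return PopulationParams(**kw)


def interpolate_params(
    cave: PopulationParams, surface: PopulationParams, g: float, label: str = ""
) -> MixedPopulationParams:
    """Linear interpolation between cave (g=0) and surface (g=1) models."""
    g = float(g)
    return MixedPopulationParams(
        components=((1.0 - g, cave), (g, surface)),
        baseline_speed=(1 - g) * cave.baseline_speed + g * surface.baseline_speed,
        noise_sd=(1 - g) * cave.noise_sd + g * surface.noise_sd,
        label=label,
    )


@dataclass(frozen=True)
class LocomotorTrack:
    """Positional samples of one larva at fixed frame spacing (mm, s)."""

    well_id: str
    frame_rate: float
    time_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        if t.ndim != 1 or len(t) != len(self.x_mm) or len(t) != len(self.y_mm):
            raise ValueError("time/x/y must be 1-D arrays of equal length")
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            # allow dropped frames: spacing must be an integer multiple of 1/frame_rate
            mult = dt * self.frame_rate
            if np.max(np.abs(mult - np.round(mult))) > 1e-6:
                raise ValueError("samples must be spaced at multiples of 1/frame_rate")
        if not (np.all(np.isfinite(self.x_mm)) and np.all(np.isfinite(self.y_mm))):
            raise ValueError("coordinates must be finite")


def _fold(u: np.ndarray, halfwidth: float) -> np.ndarray:
    """Reflect an unconstrained 1-D path into [-halfwidth, halfwidth].

    Triangle-wave folding is the exact billiard reflection for 1-D motion
    between two walls, so per-axis folding implements a reflective square
    arena without a sequential bounce loop.
    """
    if not np.isfinite(halfwidth):
        return u
    period = 4.0 * halfwidth
    v = np.mod(u + halfwidth, period)
    return np.where(v <= 2.0 * halfwidth, v - halfwidth, 3.0 * halfwidth - v)


def simulate_track(
    params: PopulationParams | MixedPopulationParams,
    schedule: LightSchedule,
    *,
    frame_rate: float = 25.0,
    duration_s: float | None = None,
    seed: int | np.random.Generator = 0,
    well_halfwidth_mm: float = 3.2,
    turn_sd: float = 0.35,
    well_id: str = "w0",
) -> LocomotorTrack:
    """Simulate one larva's track under the latent speed model.

    Speed per frame follows the population model; the heading performs a
    random walk (``turn_sd`` rad per frame) and positions integrate speed
    inside a reflective square well of half-width ``well_halfwidth_mm``
    (pass ``np.inf`` for an unbounded arena).  Identical seed and parameters
    give a bitwise-identical track.
    """
    if not isinstance(schedule, LightSchedule) or not schedule.intervals:
        raise ValueError("a non-empty LightSchedule is required")
    duration = schedule.duration if duration_s is None else float(duration_s)
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration > schedule.duration + 1e-9:
        raise ValueError("schedule does not cover the requested duration")

    if isinstance(params, MixedPopulationParams):
        components = params.components
        baseline, noise_sd = params.baseline_speed, params.noise_sd
    else:
        components = ((1.0, params),)
        baseline, noise_sd = params.baseline_speed, params.noise_sd

    rng = substream(seed, f"track:{well_id}")
    dt = 1.0 / frame_rate
    n_steps = int(round(duration * frame_rate))
    t = np.arange(n_steps) * dt
    state = schedule.state_at(t)
    entry = schedule.entry_time_at(t)

    mu = np.full(n_steps, baseline)
    for weight, comp in components:
        if weight == 0.0:
            continue
        active = state == comp.trigger_state
        resp = comp.sustained_gain + comp.transient_gain * np.exp(
            -(t - entry) / comp.transient_tau
        )
        mu = mu + weight * active * resp
    speed = mu
    if noise_sd > 0:
        speed = speed + noise_sd * rng.standard_normal(n_steps)
    else:
        # keep the stream position identical with and without noise draws
        rng.standard_normal(n_steps)
    speed = np.clip(speed, 0.0, None)

    heading = rng.uniform(0.0, 2.0 * np.pi) + np.cumsum(
        rng.normal(0.0, turn_sd, n_steps)
    )
    step = speed * dt
    ux = np.concatenate([[0.0], np.cumsum(step * np.cos(heading))])
    uy = np.concatenate([[0.0], np.cumsum(step * np.sin(heading))])
    times = np.arange(n_steps + 1) * dt
    return LocomotorTrack(
        well_id=well_id,
        frame_rate=frame_rate,
        time_s=times,
        x_mm=_fold(ux, well_halfwidth_mm),
        y_mm=_fold(uy, well_halfwidth_mm),
        label=getattr(params, "label", ""),
    )


def expected_speed(
    params: PopulationParams, schedule: LightSchedule, t
) -> np.ndarray:
    """Closed-form E[speed] at time(s) t, including the max(0, .) rectification.

    For speed = max(0, m + sigma*Z) with Z standard normal,
    E = m*Phi(m/sigma) + sigma*phi(m/sigma); used as the analytic oracle for
    Monte-Carlo checks of binned activity.
    """
    from scipy.stats import norm

    t = np.asarray(t, dtype=float)
    state = schedule.state_at(t)
    entry = schedule.entry_time_at(t)
    active = state == params.trigger_state
    m = params.baseline_speed + active * (
        params.sustained_gain
        + params.transient_gain * np.exp(-(t - entry) / params.transient_tau)
    )
    s = params.noise_sd
    if s == 0:
        return np.clip(m, 0.0, None)
    z = m / s
    return m * norm.cdf(z) + s * norm.pdf(z)


# ---------------------------------------------------------------------------
# Hybrid crosses (additive k-locus model)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossModel:
    """Additive equal-effect k-locus model of the surface x cave intercross.

    The genetic value g = (number of surface alleles) / (2k) maps linearly
    between the cave (g=0) and surface (g=1) locomotor models.  F1 fish are
    heterozygous at every locus (g = 1/2 exactly); F2 fish draw each locus
    Binomial(2, 1/2), giving Var(g) = 1/(8k).  ``env_sd`` adds per-fish
    environmental noise to g (clipped to [0, 1]).
    """

    n_loci: int = 4
    surface_params: PopulationParams = field(default_factory=surface_like_params)
    cave_params: PopulationParams = field(default_factory=cave_like_params)
    env_sd: float = 0.06

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.env_sd < 0:
            raise ValueError("env_sd must be >= 0")


@dataclass(frozen=True)
class CrossFish:
    """One simulated fish: latent genetic value and its locomotor model."""

    fish_id: str
    g_genetic: float
    g: float
    params: MixedPopulationParams


def simulate_cross(
    model: CrossModel,
    generation: str,
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[CrossFish]:
    """Draw ``n`` fish of one generation from the cross model."""
    if generation not in GENERATIONS:
        raise ValueError(f"unknown generation {generation!r}; expected one of {GENERATIONS}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = substream(seed, f"cross:{generation}")
    k = model.n_loci
    if generation == "P_surface":
        gg = np.ones(n)
    elif generation == "P_cave":
        gg = np.zeros(n)
    elif generation == "F1":
        gg = np.full(n, 0.5)
    else:  # F2
        gg = rng.binomial(2, 0.5, size=(n, k)).sum(axis=1) / (2.0 * k)
    g = gg + rng.normal(0.0, model.env_sd, size=n) if model.env_sd > 0 else gg.copy()
    g = np.clip(g, 0.0, 1.0)
    return [
        CrossFish(
            fish_id=f"{generation}_{i:04d}",
            g_genetic=float(gg[i]),
            g=float(g[i]),
            params=interpolate_params(
                model.cave_params, model.surface_params, g[i], label=generation
            ),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Region volumes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionSpec:
    """Latent model of one atlas region's volume (um^3) vs behavior.

    ``behavior_slope`` is um^3 per unit PI; 0 plants no correlation.
    """

    region_name: str
    mean_volume: float
    volume_sd: float
    behavior_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_volume <= 0:
            raise ValueError("mean_volume must be > 0")
        if self.volume_sd < 0:
            raise ValueError("volume_sd must be >= 0")


def slope_for_correlation(r: float, volume_sd: float, pi_sd: float) -> float:
    """Slope planting population Pearson correlation ``r`` between volume and PI.

    With volume = mean + slope*PI + N(0, volume_sd) and PI of SD ``pi_sd``,
    r = slope*pi_sd / sqrt(slope^2*pi_sd^2 + volume_sd^2); solving gives
    slope = r*volume_sd / (pi_sd*sqrt(1 - r^2)).
    """
    if not -1 < r < 1:
        raise ValueError("planted r must lie strictly inside (-1, 1)")
    return r * volume_sd / (pi_sd * np.sqrt(1.0 - r * r))


#: Atlas-like region names; the first three carry the planted negative
#: volume-behavior correlations observed in the ventral forebrain.
CORRELATED_REGIONS = ("tegmentum", "hypothalamus", "posterior_tuberculum")
NULL_REGIONS = (
    "optic_tectum",
    "pineal",
    "pallium",
    "subpallium",
    "preoptic_region",
    "thalamus",
    "habenula",
    "pretectum",
    "cerebellum",
    "torus_semicircularis",
    "medulla",
    "olfactory_bulb",
    "retina",
    "torus_longitudinalis",
    "raphe",
    "locus_coeruleus",
    "spinal_cord",
)


def default_region_specs(
    planted_r: float = -0.5, pi_sd: float = 0.4
) -> list[RegionSpec]:
    """Twenty-region screen: three planted negative correlations, 17 null."""
    means = {
        "tegmentum": 1.6e6,
        "hypothalamus": 2.5e6,
        "posterior_tuberculum": 8.0e5,
    }
    specs = []
    for name in CORRELATED_REGIONS:
        mv = means[name]
        sd = 0.10 * mv
        specs.append(
            RegionSpec(name, mv, sd, slope_for_correlation(planted_r, sd, pi_sd))
        )
    for i, name in enumerate(NULL_REGIONS):
        mv = 4.0e5 + 1.5e5 * i
        specs.append(RegionSpec(name, mv, 0.10 * mv, 0.0))
    return specs


def simulate_region_volumes(
    fish_pis: Iterable[tuple[str, float]] | pd.DataFrame,
    regions: Sequence[RegionSpec],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-fish, per-region volumes with planted volume-PI slopes.

    Returns a long table with columns ``fish_id, region, volume_um3``.
    """
    if isinstance(fish_pis, pd.DataFrame):
        pairs = list(zip(fish_pis["fish_id"], fish_pis["pi"]))
    else:
        pairs = list(fish_pis)
    if len(pairs) < 2:
        raise ValueError("at least two fish are required")
    ids = [fid for fid, _ in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate fish ids")
    pis = np.array([pi for _, pi in pairs], dtype=float)
    rng = substream(seed, "region_volumes")
    frames = []
    for spec in regions:
        vol = spec.mean_volume + spec.behavior_slope * pis
        vol = vol + rng.normal(0.0, spec.volume_sd, size=len(pis))
        frames.append(
            pd.DataFrame(
                {"fish_id": ids, "region": spec.region_name, "volume_um3": vol}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Calcium traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceClusterSpec:
    """Planted tuning cluster of simulated GCaMP neurons.

    Fluorescence is ``baseline*(1 + amplitude*r(t)) + baseline*noise_sd*N``
    where ``r`` is the preferred-state indicator low-pass filtered with a
    single-exponential kernel (``kernel_tau``, nuclear-GCaMP6s-like default
    1.8 s); NONE clusters have zero stimulus component.  ``response_amplitude``
    and ``noise_sd`` are in dF/F units.
    """

    cluster_id: int
    n_neurons: int
    preferred_state: str = ON
    response_amplitude: float = 0.5
    kernel_tau: float = 1.8
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.kernel_tau <= 0:
            raise ValueError("kernel_tau must be > 0")
        if self.preferred_state not in (ON, OFF, NONE):
            raise ValueError("preferred_state must be ON, OFF or NONE")


def default_trace_specs(noise_sd: float = 0.05) -> list[TraceClusterSpec]:
    """Five planted clusters: strong/weak ON, strong/weak OFF, untuned."""
    return [
        TraceClusterSpec(1, 20, ON, 1.0, noise_sd=noise_sd),
        TraceClusterSpec(2, 20, ON, 0.4, noise_sd=noise_sd),
        TraceClusterSpec(3, 20, OFF, 1.0, noise_sd=noise_sd),
        TraceClusterSpec(4, 20, OFF, 0.4, noise_sd=noise_sd),
        TraceClusterSpec(5, 20, NONE, 0.0, noise_sd=noise_sd),
    ]


def simulate_traces(
    specs: Sequence[TraceClusterSpec],
    schedule: LightSchedule,
    frame_rate: float = 5.0,
    seed: int | np.random.Generator = 0,
    baseline_f: float = 100.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate fluorescence traces with planted tuning-cluster labels.

    Returns ``(traces, labels)``: a long table with columns
    ``neuron_id, frame, time_s, fluorescence`` and a sidecar with
    ``neuron_id, cluster_id, preferred_state``.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    total = sum(s.n_neurons for s in specs)
    if total == 0:
        raise ValueError("at least one neuron is required")
    rng = substream(seed, "traces")
    n = int(round(schedule.duration * frame_rate))
    t = np.arange(n) / frame_rate
    state = schedule.state_at(t)

    rows, labels = [], []
    neuron = 0
    for spec in specs:
        if spec.preferred_state == NONE:
            resp = np.zeros(n)
        else:
            stim = (state == spec.preferred_state).astype(float)
            a = np.exp(-1.0 / (frame_rate * spec.kernel_tau))
            resp = _signal.lfilter([1.0 - a], [1.0, -a], stim)
        clean = baseline_f * (1.0 + spec.response_amplitude * resp)
        noise = baseline_f * spec.noise_sd * rng.standard_normal((spec.n_neurons, n))
        fl = clean[None, :] + noise
        for j in range(spec.n_neurons):
            nid = f"n{neuron:04d}"
            rows.append(
                pd.DataFrame(
                    {
                        "neuron_id": nid,
                        "frame": np.arange(n),
                        "time_s": t,
                        "fluorescence": fl[j],
                    }
                )
            )
            labels.append((nid, spec.cluster_id, spec.preferred_state))
            neuron += 1
    traces = pd.concat(rows, ignore_index=True)
    label_df = pd.DataFrame(labels, columns=["neuron_id", "cluster_id", "preferred_state"])
    return traces, label_df


# ---------------------------------------------------------------------------
# Voxel phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Blob:
    """Spherical activation blob in voxel coordinates."""

    center: tuple[float, float, float]
    radius: float
    effect_size: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("blob radius must be > 0")


@dataclass(frozen=True)
class VoxelPhantomSpec:
    """Phantom for the voxelwise activity-map comparison.

    Group A volumes carry ``effect_size`` added inside each blob; group B is
    background noise only.  Background is Gaussian with mean
    ``background_mean`` and SD ``noise_sd``.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 20)
    voxel_size_um: float = 10.0
    blobs: tuple[Blob, ...] = ()
    n_per_group: int = 10
    background_mean: float = 100.0
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for blob in self.blobs:
            for c, dim in zip(blob.center, self.grid_shape):
                if c - blob.radius < -1e-9 or c + blob.radius > dim + 1e-9:
                    raise ValueError("blob must lie within the grid")


def default_voxel_phantom(
    effect_over_noise: float = 3.0, n_per_group: int = 10
) -> VoxelPhantomSpec:
    """One activation blob at effect/noise = 3 on a 40x40x20 grid."""
    noise = 10.0
    return VoxelPhantomSpec(
        blobs=(Blob((14.0, 14.0, 10.0), 6.0, effect_over_noise * noise),),
        n_per_group=n_per_group,
        noise_sd=noise,
    )


def blob_mask(spec: VoxelPhantomSpec) -> np.ndarray:
    """Boolean mask of voxels inside any blob (voxel-center convention)."""
    nx, ny, nz = spec.grid_shape
    gx, gy, gz = np.ogrid[0:nx, 0:ny, 0:nz]
    mask = np.zeros(spec.grid_shape, dtype=bool)
    for blob in spec.blobs:
        cx, cy, cz = blob.center
        d2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
        mask |= d2 <= blob.radius**2
    return mask


def simulate_voxel_groups(
    spec: VoxelPhantomSpec, seed: int | np.random.Generator = 0
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Two groups of 3-D volumes: A = noise + blob effects, B = noise only."""
    rng = substream(seed, "voxels")
    effect = np.zeros(spec.grid_shape)
    for blob in spec.blobs:
        nx, ny, nz = spec.grid_shape
        gx, gy, gz = np.ogrid[0:nx, 0:ny, 0:nz]
        cx, cy, cz = blob.center
        inside = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2 <= blob.radius**2
        effect = effect + blob.effect_size * inside
    group_a = [
        spec.background_mean
        + effect
        + spec.noise_sd * rng.standard_normal(spec.grid_shape)
        for _ in range(spec.n_per_group)
    ]
    group_b = [
        spec.background_mean + spec.noise_sd * rng.standard_normal(spec.grid_shape)
        for _ in range(spec.n_per_group)
    ]
    return group_a, group_b
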