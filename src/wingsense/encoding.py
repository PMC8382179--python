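"""Linear-nonlinear probabilistic spiking encoder for wing strain.

Each candidate sensor convolves its local strain with a decaying-sinusoid
temporal filter

    f(t) = cos(2 pi omega (t + tau)) * exp(-(t + tau)^2 / delta^2),

(omega = 1/(2 pi) per ms, tau = 5 ms, delta = 4 ms by default; the peak sits
tau = 5 ms in the past), normalizes by a single constant shared across all
sensors so that the maximum filtered strain at the reference stiffness is 1,
and passes the result through a sigmoid nonlinearity

    N(g) = 1 / (1 + exp(-alpha (g - beta)))

to obtain a per-time-step firing probability.  Spikes are drawn by comparing
the probability to a uniform variate, with a 15 ms absolute refractory period
(next spike allowed at or after t_prev + refractory).  The classifier input
is the time to the first spike within each 40 ms wingbeat at 0.1 ms
precision, with 0 recording "no spike this wingbeat".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.signal import fftconvolve

__all__ = [
    "EncoderParams", "FiringProbability", "SpikeRaster", "FirstSpikeMatrix",
    "filter_kernel", "filter_strain", "compute_norm_constant", "nonlinearity",
    "generate_spikes", "first_spike_features", "first_spikes_from_probability",
]


@dataclass(frozen=True)
class EncoderParams:
    """Parameters of the linear-nonlinear spiking encoder.

    Times are in seconds internally; ``omega`` is in cycles per second
    (default 1/(2 pi) per ms).  ``omega_scale`` is a dimensionless multiplier
    on the filter frequency used by the filter-frequency sweep.
    ``norm_constant`` divides the filtered strain and is shared by every
    sensor; it is computed once from a reference-stiffness simulation.
    """

    omega: float = 1000.0 / (2.0 * np.pi)  # Hz  (= 1/(2 pi) per ms)
    omega_scale: float = 1.0
    tau: float = 5e-3
    delta: float = 4e-3
    alpha: float = 50.0
    beta: float = 0.2
    refractory: float = 15e-3
    norm_constant: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.refractory <= 0:
            raise ValueError("refractory period must be positive")
        if self.norm_constant <= 0:
            raise ValueError("norm_constant must be positive")

    def with_norm(self, norm_constant: float) -> "EncoderParams":
        return replace(self, norm_constant=norm_constant)


@dataclass
class FiringProbability:
    """Per-time-step spike probability at each sensor, values in [0, 1]."""

    data: np.ndarray  # (time_steps, n_locations)
    dt: float


@dataclass
class SpikeRaster:
    """Binary spike events, shape (repeats, time_steps, n_locations)."""

    data: np.ndarray
    dt: float
    seed: int | None = None


@dataclass
class FirstSpikeMatrix:
    """Per-wingbeat, per-sensor time to first spike in ms (0 = no spike).

    Rows are observations (wingbeats x repeats, repeats outermost); columns
    are sensor locations.  ``labels`` holds the per-observation class.
    """

    data: np.ndarray
    labels: np.ndarray | None = None

    @property
    def n_observations(self) -> int:
        return self.data.shape[0]

    @property
    def n_locations(self) -> int:
        return self.data.shape[1]


def _unpack(obj, default_dt: float = 1e-4):
    """Accept a StrainField/FiringProbability-like carrier or a bare array."""
    if isinstance(obj, np.ndarray):
        return obj, default_dt
    return np.asarray(obj.data), getattr(obj, "dt", default_dt)


def filter_kernel(params: EncoderParams | None = None, dt: float = 1e-4):
    """Sample the temporal filter on its lag support.

    Returns ``(lags, values)`` with lags in seconds spanning
    [-tau - 3 delta, -tau + 3 delta] (outside this window the Gaussian
    envelope is below e^-9).  Lag 0 is "now" and negative lags are the past;
    the kernel peaks with value 1 at lag -tau.  Causal application
    (:func:`filter_strain`) uses the lags <= 0 only.
    """
    params = params or EncoderParams()
    if dt <= 0:
        raise ValueError("dt must be positive")
    lo = -params.tau - 3.0 * params.delta
    hi = -params.tau + 3.0 * params.delta
    lags = np.arange(np.round(lo / dt), np.round(hi / dt) + 1) * dt
    om = params.omega * params.omega_scale
    values = (np.cos(2.0 * np.pi * om * (lags + params.tau))
              * np.exp(-((lags + params.tau) ** 2) / params.delta**2))
    return lags, values


def filter_strain(strain, params: EncoderParams | None = None) -> np.ndarray:
    """Causally convolve strain with the temporal filter and normalize.

    ``strain`` may be a :class:`~wingsense.wing.StrainField` or a plain
    (time, locations) array plus the encoder's dt.  Output g has the same
    shape; g at time t depends on strain at times <= t only (zero-padded
    history before the first sample).
    """
    params = params or EncoderParams()
    data, dt = _unpack(strain)
    lags, values = filter_kernel(params, dt)
    causal = values[lags <= 1e-15]
    # g[t] = sum_{v>=0} k[v] * s[t - v]  with k[v] = f(-v dt)
    kernel = causal[::-1].astype(data.dtype)
    g = fftconvolve(data, kernel[:, None], axes=0)[: data.shape[0]]
    return g / params.norm_constant


def compute_norm_constant(reference_strain, params: EncoderParams | None = None) -> float:
    """Normalization constant from a reference-stiffness, flapping-only run.

    Chosen so that max |g| over all sensors and times equals exactly 1 when
    the same constant is applied back to the reference field.  The constant
    is shared by all sensors and reused for every stiffness and condition.
    """
    params = (params or EncoderParams()).with_norm(1.0)
    g = filter_strain(reference_strain, params)
    peak = float(np.max(np.abs(g)))
    if peak == 0.0:
        raise ValueError("reference strain is identically zero; cannot normalize")
    return peak


def nonlinearity(g, params: EncoderParams | None = None) -> FiringProbability:
    """Static sigmoid nonlinearity mapping filtered strain to P(fire).

    Reaches half-maximum at g = beta; strictly increasing in g and strictly
    decreasing in beta.
    """
    params = params or EncoderParams()
    data, dt = _unpack(g)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-params.alpha * (data.astype(np.float64) - params.beta)))
    return FiringProbability(data=p, dt=dt)


@njit(cache=True)
def _spike_scan(p, n_ref, u):  # (T, n_loc), refractory steps, uniforms (T, n_loc)
    T, n = p.shape
    out = np.zeros((T, n), dtype=np.uint8)
    for j in range(n):
        next_allowed = 0
        for i in range(T):
            if i >= next_allowed and p[i, j] > u[i, j]:
                out[i, j] = 1
                next_allowed = i + n_ref
    return out


def generate_spikes(p: FiringProbability, refractory: float = 15e-3,
                    n_repeats: int = 1, seed: int | None = 0) -> SpikeRaster:
    """Draw probabilistic spikes with an absolute refractory period.

    At each time step a spike occurs iff P(fire) exceeds an independent
    Uniform(0,1) draw, except within the refractory window after a spike
    (next spike allowed at times >= t_prev + refractory).  One RNG stream
    per repeat, spawned from ``seed``; deterministic.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    n_ref = max(1, int(round(refractory / p.dt)))
    T, n = p.data.shape
    rasters = np.empty((n_repeats, T, n), dtype=np.uint8)
    seeds = np.random.SeedSequence(seed).spawn(n_repeats)
    for rep, ss in enumerate(seeds):
        u = np.random.default_rng(ss).random((T, n))
        rasters[rep] = _spike_scan(p.data, n_ref, u)
    return SpikeRaster(data=rasters, dt=p.dt, seed=seed)


def first_spike_features(raster: SpikeRaster, wingbeat_period: float = 0.04,
                         labels=None) -> FirstSpikeMatrix:
    """Time to first spike within each wingbeat, quantized to 0.1 ms.

    The spike at sample index j within a wingbeat is reported as
    (j + 1) * dt in ms, so values lie in (0, period]; 0 is the no-spike
    sentinel.  Observations are ordered repeat-major, wingbeat-minor.
    """
    n_rep, T, n_loc = raster.data.shape
    steps_per_beat = int(round(wingbeat_period / raster.dt))
    if steps_per_beat <= 0 or T % steps_per_beat != 0:
        raise ValueError("raster duration must be divisible by the wingbeat period")
    n_beats = T // steps_per_beat
    r = raster.data.reshape(n_rep, n_beats, steps_per_beat, n_loc)
    any_spike = r.any(axis=2)
    first_idx = r.argmax(axis=2)  # first True along the within-beat axis
    times_ms = (first_idx + 1) * (raster.dt * 1e3)
    times_ms = np.where(any_spike, times_ms, 0.0)
    data = np.round(times_ms.reshape(n_rep * n_beats, n_loc), 1)
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape[0] != data.shape[0]:
            raise ValueError("label count must match observation count")
    return FirstSpikeMatrix(data=data, labels=labels)


# ---------------------------------------------------------------------------
# fused fast path used by the pipeline (identical spiking law; lazily draws
# uniforms only where 0 < P(fire) < 1 within 1e-12, so the random stream
# differs from generate_spikes but the distribution of rasters does not)

@njit(cache=True, fastmath=True)
def _first_spike_candidates(starts, cand_t, cum_logq, n_ref, steps_per_beat,
                            seeds, n_beats, n_loc):
    """Sample spike trains over candidate times by inverse-CDF jumps.

    ``cum_logq[k]`` is the prefix sum of log(1 - p) over the time-sorted
    candidate list (per-sensor slices delimited by ``starts``), so the
    survival probability from candidate a through candidate b-1 is
    exp(cum_logq[b] - cum_logq[a]).  One uniform draw locates each next
    spike directly (binary search on the prefix sums), and a second search
    skips the refractory window — an exact sampling of the independent
    per-candidate Bernoulli law at O(spikes log candidates) cost.

    Returns (n_repeats, n_beats, n_loc) first-spike sample offsets
    (0 = none; offset is within-beat index + 1).
    """
    n_rep = seeds.shape[0]
    out = np.zeros((n_rep, n_beats, n_loc), dtype=np.float32)
    for rep in range(n_rep):
        np.random.seed(seeds[rep])
        for j in range(n_loc):
            k0 = starts[j]
            end = starts[j + 1]
            while k0 < end:
                lu = np.log(np.random.random())
                if lu < cum_logq[end] - cum_logq[k0]:
                    break  # survives every remaining candidate
                # smallest k with survival through k below u
                target = lu + cum_logq[k0]
                lo, hi = k0, end - 1
                while lo < hi:
                    mid = (lo + hi) // 2
                    if cum_logq[mid + 1] <= target:
                        hi = mid
                    else:
                        lo = mid + 1
                i = cand_t[lo]
                beat = i // steps_per_beat
                if out[rep, beat, j] == 0.0:
                    out[rep, beat, j] = np.float32(
                        i - beat * steps_per_beat + 1)
                next_allowed = i + n_ref
                # resume at the first candidate past the refractory window
                lo2, hi2 = lo + 1, end
                while lo2 < hi2:
                    mid = (lo2 + hi2) // 2
                    if cand_t[mid] < next_allowed:
                        lo2 = mid + 1
                    else:
                        hi2 = mid
                k0 = lo2
    return out


def first_spikes_from_probability(g: np.ndarray, params: EncoderParams,
                                  dt: float, wingbeat_period: float,
                                  n_repeats: int, seed: int | None) -> np.ndarray:
    """First-spike times (ms) straight from filtered strain, without
    materializing probability or raster arrays.  Shape
    (n_repeats * n_beats, n_locations); repeat-major ordering and the same
    spiking law and refractory convention as :func:`generate_spikes`.
    """
    steps_per_beat = int(round(wingbeat_period / dt))
    if g.shape[0] % steps_per_beat != 0:
        raise ValueError("duration must be divisible by the wingbeat period")
    n_ref = max(1, int(round(params.refractory / dt)))
    n_beats = g.shape[0] // steps_per_beat
    n_loc = g.shape[1]

    # candidate times where P(fire) exceeds numerical zero (~1e-9); the
    # log-survival prefix sums are computed once and shared across repeats
    gT = np.ascontiguousarray(np.asarray(g, dtype=np.float32).T)
    cut = np.float32(20.7 / params.alpha)
    js, ts = np.nonzero(gT > np.float32(params.beta) - cut)
    with np.errstate(over="ignore"):
        prob = 1.0 / (1.0 + np.exp(-params.alpha
                                   * (gT[js, ts].astype(np.float64)
                                      - params.beta)))
    logq = np.log1p(-np.minimum(prob, 1.0 - 1e-15))
    np.maximum(logq, -50.0, out=logq)  # saturated p: spike is certain here
    cum_logq = np.concatenate([[0.0], np.cumsum(logq)])
    starts = np.searchsorted(js, np.arange(n_loc + 1)).astype(np.int64)
    seeds = (np.random.SeedSequence(seed).generate_state(n_repeats)
             % (2**31)).astype(np.int64)
    offs = _first_spike_candidates(starts, ts.astype(np.int64), cum_logq,
                                   n_ref, steps_per_beat, seeds, n_beats,
                                   n_loc)
    times = offs.reshape(n_repeats * n_beats, n_loc) * (dt * 1e3)
    return np.round(times, 1)
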