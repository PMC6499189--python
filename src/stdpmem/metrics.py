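"""Comparison metrics: membrane/weight MSE and the van Rossum spike distance.

The van Rossum distance filters each spike train through a causal
exponential kernel and measures the L2 distance between the filtered
traces.  In discrete time the filter is

    f[t] = exp(-1/tau) * f[t-1] + s[t],      f[-1] = 0,

so a single spike at t0 leaves the trace exp(-(t - t0)/tau) for t >= t0,
and the per-neuron distance is

    D = sqrt( (1/tau) * sum_t (f[t] - g[t])**2 ),

summed (not averaged) across neurons for the network total.  The natural
time constant to pair with a leaky membrane of memory constant alpha is
tau = -1 / log(alpha) (about 9.5 steps for alpha = 0.9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MSEResult",
    "total_mse",
    "vr_time_constant",
    "van_rossum_trace",
    "van_rossum_distance",
]


@dataclass(frozen=True)
class MSEResult:
    """Squared-error summary of two aligned (steps x neurons) traces."""

    per_step: np.ndarray  # sum over neurons of squared differences, per step
    total: float          # sum over all entries
    mean: float           # mean over all entries


def _check_pair(a, b) -> tuple:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"trace shapes differ: {a.shape} vs {b.shape}")
    if a.ndim == 1:
        a = a[:, None]
        b = b[:, None]
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("traces must be finite")
    return a, b


def total_mse(a, b) -> MSEResult:
    """Squared error between aligned traces; zero iff they are identical."""
    a, b = _check_pair(a, b)
    sq = (a - b) ** 2
    per_step = sq.sum(axis=1)
    return MSEResult(per_step=per_step, total=float(sq.sum()),
                     mean=float(sq.mean()) if sq.size else 0.0)


def vr_time_constant(alpha: float) -> float:
    """Filter time constant matched to a membrane memory constant alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    return -1.0 / math.log(alpha)


def van_rossum_trace(raster, tau: float) -> np.ndarray:
    """Causal exponential filtering of a (steps x neurons) spike raster."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    raster = np.asarray(raster, dtype=float)
    if raster.ndim == 1:
        raster = raster[:, None]
    lam = math.exp(-1.0 / tau)
    f = np.zeros_like(raster)
    prev = np.zeros(raster.shape[1])
    for t in range(raster.shape[0]):
        prev = lam * prev + raster[t]
        f[t] = prev
    return f


def van_rossum_distance(raster_a, raster_b, tau: float,
                        per_neuron: bool = False):
    """van Rossum distance between two spike rasters of equal shape.

    Per neuron: sqrt((1/tau) * sum_t (f - g)^2); the scalar result sums the
    per-neuron distances across the network.
    """
    a, b = _check_pair(raster_a, raster_b)
    f = van_rossum_trace(a, tau)
    g = van_rossum_trace(b, tau)
    d = np.sqrt(((f - g) ** 2).sum(axis=0) / tau)
    if per_neuron:
        return d
    return float(d.sum())
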