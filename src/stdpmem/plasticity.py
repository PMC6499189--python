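"""STDP engines: classic bidirectional-access STDP and the forward-only
delayed-causal-update formulation.

Spike-timing-dependent plasticity changes a weight w_ij as a function of the
signed lag dt = t_post - t_pre: causal pairs (dt > 0) potentiate, acausal
pairs (dt < 0) depress, and the kernel is zero at dt = 0 and beyond the
window |dt| > T_stdp.  The classic ("original") engine applies acausal
updates at pre-synaptic spikes via forward connectivity access and causal
updates at post-synaptic spikes via reverse access.  The delayed engine
removes reverse access entirely: causal updates are postponed to
pre-synaptic timer-expiration events (and to the pending-update service that
runs at the start of every pre-synaptic spike), using only forward access.

Each neuron's recent spikes live in a multi-timer history: with
ceil(T_stdp / T_refr) timers of one refractory period each, every spike that
can occur inside the window is captured and the delayed engine is *exactly*
equivalent to the classic one — identical weights at every instant a weight
is delivered to a post-synaptic neuron, and identical final weights after a
flush.  With fewer timers (e.g. a single timer while T_refr < T_stdp) spike
times are overwritten and causal updates are lost, never duplicated: the
documented failure mode of high-firing post-synaptic neurons.

Conventions pinned down here (both engines, and the brute-force oracle,
share them so equivalence is bit-exact):

* Discrete time.  Within step t: (1) histories age and expiring pre-synaptic
  spikes are serviced (delayed causal updates), oldest first, pre index
  ascending; (2) this step's pre-synaptic spikes are processed in ascending
  index order — pending causal service, then acausal updates, then the row
  weights are delivered; (3) post-synaptic neurons integrate and this step's
  post spikes are registered (classic engine: causal updates now).
* A spike stays pairable for ages 1..T_stdp and is serviced/removed when its
  age reaches T_stdp + 1, so every |dt| <= T_stdp pair is realisable.
* dt = 0 (same-step pre and post spikes) contributes no update.
* Per-weight float accumulation order is canonical: updates are applied as
  individual additions ordered by (post-spike time ascending, pre-spike time
  ascending), which is exactly the chronological order of the classic engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .connectivity import SynapticStore

KERNEL_SHAPES = ("ramp", "box", "exp_truncated")
INTERACTION_MODES = ("nearest_neighbor", "all_to_all")
CAUSAL_VARIANTS = ("last_timer", "each_timer")
ENGINES = ("original", "delayed")

__all__ = [
    "KernelSpec",
    "PlasticityConfig",
    "SpikeHistory",
    "kernel_value",
    "OriginalEngine",
    "DelayedEngine",
    "make_engine",
    "stdp_oracle",
    "run_forced",
]


@dataclass(frozen=True)
class KernelSpec:
    """STDP kernel shape and scale.

    ``a_plus`` / ``a_minus`` are the maximum causal / acausal magnitudes (in
    weight units); ``t_stdp`` the window length in steps; ``tau`` the decay
    constant (steps) of the truncated exponential shape.  The ramp kernel is
    A * (T_stdp - |dt| + 1) / T_stdp, so the peak change +-A occurs at
    |dt| = 1 and the smallest nonzero change is A / T_stdp.
    """

    shape: str = "ramp"
    a_plus: float = 0.01
    a_minus: float = 0.01
    t_stdp: int = 16
    tau: Optional[float] = None

    def __post_init__(self):
        if self.shape not in KERNEL_SHAPES:
            raise ValueError(f"shape must be one of {KERNEL_SHAPES}")
        if self.t_stdp < 1:
            raise ValueError("T_stdp must be at least 1")
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("kernel amplitudes must be nonnegative")
        if self.shape == "exp_truncated" and (self.tau is None or self.tau <= 0):
            raise ValueError("exp_truncated kernel requires tau > 0")


def kernel_value(spec: KernelSpec, dt: int) -> float:
    """Signed weight change for lag dt = t_post - t_pre (zero at dt = 0 and
    outside the window)."""
    if dt == 0 or abs(dt) > spec.t_stdp:
        return 0.0
    adt = abs(dt)
    amp = spec.a_plus if dt > 0 else spec.a_minus
    if spec.shape == "ramp":
        mag = amp * (spec.t_stdp - adt + 1) / spec.t_stdp
    elif spec.shape == "box":
        mag = float(amp)
    else:  # exp_truncated
        mag = amp * math.exp(-(adt - 1) / spec.tau)
    return mag if dt > 0 else -mag


@dataclass(frozen=True)
class PlasticityConfig:
    """Engine configuration: kernel, refractory period, temporal interaction
    mode, causal-update variant and the spike-history depth.

    ``n_timers=None`` selects the exact rule ceil(T_stdp / T_refr); setting
    ``n_timers=1`` with T_refr < T_stdp reproduces the lossy single-timer
    configuration.
    """

    kernel: KernelSpec = field(default_factory=KernelSpec)
    t_refr: int = 4
    mode: str = "all_to_all"
    causal_variant: str = "last_timer"
    n_timers: Optional[int] = None

    def __post_init__(self):
        if self.t_refr < 1:
            raise ValueError("T_refr must be at least 1")
        if self.mode not in INTERACTION_MODES:
            raise ValueError(f"mode must be one of {INTERACTION_MODES}")
        if self.causal_variant not in CAUSAL_VARIANTS:
            raise ValueError(f"causal_variant must be one of {CAUSAL_VARIANTS}")
        if self.n_timers is not None and self.n_timers < 1:
            raise ValueError("n_timers must be at least 1")

    @property
    def exact_n_timers(self) -> int:
        return math.ceil(self.kernel.t_stdp / self.t_refr)

    @property
    def effective_n_timers(self) -> int:
        return self.exact_n_timers if self.n_timers is None else self.n_timers

    @property
    def is_exact(self) -> bool:
        return self.effective_n_timers >= self.exact_n_timers


class SpikeHistory:
    """Per-neuron multi-timer spike history (inspection / unit-test view).

    Holds up to ``n_timers`` spike ages; each slot models a hardware timer of
    one refractory period, so the bank encodes the exact times of every spike
    in the last T_stdp steps when ``n_timers = ceil(T_stdp / T_refr)``.
    """

    def __init__(self, n_timers: int, t_stdp: int, t_refr: int):
        if n_timers < 1:
            raise ValueError("need at least one timer")
        self.n_timers = n_timers
        self.t_stdp = t_stdp
        self.t_refr = t_refr
        self._times: list = []

    def record(self, t: int):
        """Register a spike; returns the overwritten spike time (info loss)
        if the bank was full, else None."""
        dropped = None
        if len(self._times) == self.n_timers:
            dropped = self._times.pop(0)
        self._times.append(t)
        return dropped

    def advance(self, t: int) -> list:
        """Drop (and return) spikes whose age at step t exceeds T_stdp."""
        expired = [s for s in self._times if t - s > self.t_stdp]
        self._times = [s for s in self._times if t - s <= self.t_stdp]
        return expired

    def all_spike_ages(self, t: int) -> list:
        return [t - s for s in self._times]

    @property
    def spike_times(self) -> list:
        return list(self._times)


class _HistoryBank:
    """Vectorised spike-time storage: (n_neurons, capacity) int64 array,
    ascending within a row, EMPTY-padded on the left, newest in the last
    column."""

    EMPTY = np.int64(-(2 ** 40))

    def __init__(self, n: int, capacity: int):
        self.capacity = capacity
        self.times = np.full((n, capacity), self.EMPTY, dtype=np.int64)

    def record(self, idx: int, t: int):
        row = self.times[idx]
        dropped = int(row[0])
        if self.capacity > 1:
            row[:-1] = row[1:]
        row[-1] = t
        return dropped if dropped != self.EMPTY else None

    def expire_before(self, cutoff: int) -> None:
        self.times[self.times < cutoff] = self.EMPTY

    def clear_row(self, idx: int) -> None:
        self.times[idx] = self.EMPTY

    def valid_times(self, idx: int) -> np.ndarray:
        row = self.times[idx]
        return row[row != self.EMPTY]

    def latest_before(self, rows: np.ndarray, t: int) -> np.ndarray:
        sub = self.times[rows]
        return np.where(sub < t, sub, self.EMPTY).max(axis=1)


class _EngineBase:
    """State and machinery shared by both engines."""

    kind = "abstract"

    def __init__(self, store: SynapticStore, config: PlasticityConfig):
        self.store = store
        self.cfg = config
        self.kernel = config.kernel
        self.T = config.kernel.t_stdp
        self.R = config.t_refr
        M, N = store.M, store.N
        # classic engine keeps exact histories regardless of the timer
        # budget; the delayed engine's depth is the configured timer count
        cap = config.exact_n_timers if self.kind == "original" \
            else config.effective_n_timers
        self.pre_hist = _HistoryBank(M, cap)
        self.post_hist = _HistoryBank(N, cap)
        self._last_pre = np.full(M, _HistoryBank.EMPTY, dtype=np.int64)
        self._last_post = np.full(N, _HistoryBank.EMPTY, dtype=np.int64)
        self.t = -1
        self.forward_accesses = 0
        self.reverse_accesses = 0
        # lag -> signed update lookup, index |dt| in 1..T (0 unused)
        self._mag_plus = np.array(
            [0.0] + [kernel_value(self.kernel, d) for d in range(1, self.T + 1)])
        self._mag_minus = np.array(
            [0.0] + [kernel_value(self.kernel, -d) for d in range(1, self.T + 1)])

    # -- event API -----------------------------------------------------------
    def advance_step(self, t: int) -> None:
        """Phase 1 of step t: age histories, service expirations, prune."""
        self.t = t
        self._service_expirations(t)
        self.pre_hist.expire_before(t - self.T)
        self.post_hist.expire_before(t - self.T)

    def on_pre_spike(self, j: int, t: int):
        """Phase 2 event; returns (posts, delivered row weights)."""
        raise NotImplementedError

    def on_post_spike(self, i: int, t: int) -> None:
        """Phase 3 event."""
        raise NotImplementedError

    def flush(self, t_final: int) -> None:
        """Service any pending causal updates (end of run)."""
        return None

    def weights(self) -> np.ndarray:
        return self.store.to_dense().weight

    # -- shared pieces -------------------------------------------------------
    def _service_expirations(self, t: int) -> None:
        return None

    def _check_refractory(self, last: np.ndarray, idx: int, t: int,
                          side: str) -> None:
        if last[idx] != _HistoryBank.EMPTY and t - int(last[idx]) <= self.R:
            raise ValueError(
                f"{side} neuron {idx} spiked at {t} inside its refractory "
                f"period (previous spike at {int(last[idx])}, T_refr={self.R})")
        last[idx] = t

    def _acausal_pass(self, j: int, t: int, posts: np.ndarray) -> None:
        """Depress w_j* against recent post-synaptic spikes (forward access)."""
        P = self.post_hist.times[posts]
        if self.cfg.mode == "all_to_all":
            for q in range(P.shape[1]):  # chronological, oldest slot first
                p = P[:, q]
                dt = t - p
                m = (p != _HistoryBank.EMPTY) & (dt >= 1) & (dt <= self.T)
                if m.any():
                    self.store.add_row(j, np.nonzero(m)[0], self._mag_minus[dt[m]])
        else:
            p = self.post_hist.latest_before(posts, t)
            dt = t - p
            m = (p != _HistoryBank.EMPTY) & (dt >= 1) & (dt <= self.T)
            if m.any():
                self.store.add_row(j, np.nonzero(m)[0], self._mag_minus[dt[m]])


class OriginalEngine(_EngineBase):
    """Classic STDP: acausal at pre-synaptic spikes (forward access), causal
    at post-synaptic spikes (reverse access)."""

    kind = "original"

    def on_pre_spike(self, j: int, t: int):
        self._check_refractory(self._last_pre, j, t, "pre")
        posts = self.store.row_posts(j)
        if len(posts):
            self.store.charge_forward(j)
            self.forward_accesses += 1
            self._acausal_pass(j, t, posts)
        self.pre_hist.record(j, t)
        return posts, self.store._row_weights(j).copy()

    def on_post_spike(self, i: int, t: int) -> None:
        self._check_refractory(self._last_post, i, t, "post")
        pres, _ = self.store.read_col(i)  # reverse access, counted
        self.reverse_accesses += 1
        if len(pres):
            Q = self.pre_hist.times[pres]
            if self.cfg.mode == "all_to_all":
                for q in range(Q.shape[1]):  # pre-spike times ascending
                    s = Q[:, q]
                    dt = t - s
                    m = (s != _HistoryBank.EMPTY) & (dt >= 1) & (dt <= self.T)
                    if m.any():
                        self.store.add_col(i, pres[m], self._mag_plus[dt[m]])
            else:
                s = self.pre_hist.latest_before(pres, t)
                dt = t - s
                m = (s != _HistoryBank.EMPTY) & (dt >= 1) & (dt <= self.T)
                if m.any():
                    self.store.add_col(i, pres[m], self._mag_plus[dt[m]])
        self.post_hist.record(i, t)


class DelayedEngine(_EngineBase):
    """Forward-only STDP: causal updates are delayed to pre-synaptic timer
    events, so reverse connectivity access is never performed."""

    kind = "delayed"

    def __init__(self, store: SynapticStore, config: PlasticityConfig):
        super().__init__(store, config)
        # time up to which all causal pairs of each pre row are applied
        self._serviced_until = np.full(store.M, -1, dtype=np.int64)

    # -- causal service ------------------------------------------------------
    def _service_causal(self, j: int, t: int, charge: bool) -> None:
        """Apply every unapplied causal pair (pre spike s of j, post spike p)
        with serviced_until < p < t, in (p asc, s asc) order."""
        su = int(self._serviced_until[j])
        j_times = self.pre_hist.valid_times(j)
        # pairs with posts up to t-1 are applied here; a post spike of this
        # very step registers later (phase 3) and stays pending
        self._serviced_until[j] = max(su, t - 1)
        if len(j_times) == 0:
            return
        posts = self.store.row_posts(j)
        if len(posts) == 0:
            return
        if charge:
            self.store.charge_forward(j)
            self.forward_accesses += 1
        P = self.post_hist.times[posts]
        if self.cfg.mode == "all_to_all":
            for q in range(P.shape[1]):  # post-spike times ascending
                p = P[:, q]
                block = (p != _HistoryBank.EMPTY) & (p > su) & (p < t)
                if not block.any():
                    continue
                for s in j_times:  # pre-spike times ascending
                    dt = p - s
                    m = block & (dt >= 1) & (dt <= self.T)
                    if m.any():
                        self.store.add_row(j, np.nonzero(m)[0],
                                           self._mag_plus[dt[m]])
        else:
            for q in range(P.shape[1]):
                p = P[:, q]
                block = (p != _HistoryBank.EMPTY) & (p > su) & (p < t)
                if not block.any():
                    continue
                # nearest surviving pre spike strictly before each p
                idx = np.searchsorted(j_times, p) - 1
                s = j_times[np.clip(idx, 0, None)]
                dt = p - s
                m = block & (idx >= 0) & (dt >= 1) & (dt <= self.T)
                if m.any():
                    self.store.add_row(j, np.nonzero(m)[0], self._mag_plus[dt[m]])

    def _service_expirations(self, t: int) -> None:
        times = self.pre_hist.times
        valid = times != _HistoryBank.EMPTY
        age = t - times
        if self.cfg.causal_variant == "last_timer":
            due = valid & (age == self.T + 1)
        else:  # each_timer: every refractory-period boundary plus final exit
            due = valid & ((age == self.T + 1)
                           | ((age > 0) & (age <= self.T) & (age % self.R == 0)))
        for j in np.nonzero(due.any(axis=1))[0]:
            self._service_causal(int(j), t, charge=True)

    # -- events --------------------------------------------------------------
    def on_pre_spike(self, j: int, t: int):
        self._check_refractory(self._last_pre, j, t, "pre")
        posts = self.store.row_posts(j)
        if len(posts):
            # one forward access covers pending causal service, the acausal
            # pass and the weight delivery of this spike
            self.store.charge_forward(j)
            self.forward_accesses += 1
        self._service_causal(j, t, charge=False)
        if len(posts):
            self._acausal_pass(j, t, posts)
        self.pre_hist.record(j, t)  # overflow drops the oldest spike
        return posts, self.store._row_weights(j).copy()

    def on_post_spike(self, i: int, t: int) -> None:
        # no weight updates: the spike is only recorded (possibly
        # overwriting an older one when the timer budget is too small)
        self._check_refractory(self._last_post, i, t, "post")
        self.post_hist.record(i, t)

    def flush(self, t_final: int) -> None:
        """Complete all pending causal updates, as if every pre-synaptic
        timer had expired after the end of the run."""
        horizon = t_final + self.T + 2
        for j in range(self.store.M):
            self._service_causal(j, horizon,
                                 charge=len(self.pre_hist.valid_times(j)) > 0)
            self.pre_hist.clear_row(j)


def make_engine(store: SynapticStore, config: PlasticityConfig,
                kind: str) -> _EngineBase:
    if kind == "original":
        return OriginalEngine(store, config)
    if kind == "delayed":
        return DelayedEngine(store, config)
    raise ValueError(f"engine kind must be one of {ENGINES}")


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def stdp_oracle(dense, pre_trains, post_trains, kernel: KernelSpec,
                mode: str) -> np.ndarray:
    """Windowed pair-sum STDP evaluated directly on complete spike trains.

    Independent of the engines: a scalar event loop over sorted spike times,
    pairing each pre spike with earlier post spikes (acausal) and each post
    spike with earlier pre spikes (causal), restricted to |dt| <= T_stdp and,
    in nearest-neighbor mode, to the most recent partner spike.  Update
    order matches the canonical chronology, so agreement with the engines is
    exact to the last bit.
    """
    if mode not in INTERACTION_MODES:
        raise ValueError(f"mode must be one of {INTERACTION_MODES}")
    T = kernel.t_stdp
    a_plus, a_minus, tau = kernel.a_plus, kernel.a_minus, kernel.tau

    def mag(amp, adt):
        if kernel.shape == "ramp":
            return amp * (T - adt + 1) / T
        if kernel.shape == "box":
            return float(amp)
        return amp * math.exp(-(adt - 1) / tau)

    M, N = dense.M, dense.N
    w = dense.weight.copy()
    pre_trains = [sorted(tr) for tr in pre_trains]
    post_trains = [sorted(tr) for tr in post_trains]
    row_posts = [np.nonzero(dense.exists[j])[0] for j in range(M)]
    col_pres = [np.nonzero(dense.exists[:, i])[0] for i in range(N)]
    all_times = sorted({t for tr in pre_trains for t in tr}
                       | {t for tr in post_trains for t in tr})
    for t in all_times:
        # pre-synaptic spikes of step t: acausal updates (phase 2)
        for j in range(M):
            if t not in pre_trains[j]:
                continue
            for i in row_posts[j]:
                earlier = [p for p in post_trains[i] if p < t]
                if mode == "nearest_neighbor":
                    earlier = earlier[-1:]
                for p in earlier:
                    if t - p <= T:
                        w[j, i] -= mag(a_minus, t - p)
        # post-synaptic spikes of step t: causal updates (phase 3)
        for i in range(N):
            if t not in post_trains[i]:
                continue
            for j in col_pres[i]:
                earlier = [s for s in pre_trains[j] if s < t]
                if mode == "nearest_neighbor":
                    earlier = earlier[-1:]
                for s in earlier:
                    if t - s <= T:
                        w[j, i] += mag(a_plus, t - s)
    return w


def run_forced(store: SynapticStore, config: PlasticityConfig, kind: str,
               pre_trains, post_trains, n_steps: int,
               flush: bool = True) -> _EngineBase:
    """Drive an engine with forced spike trains through the canonical step
    order (micro-scenario harness).

    Trains are per-neuron sorted lists of spike steps in [0, n_steps); they
    must respect the refractory period (the engines reject violations).
    """
    engine = make_engine(store, config, kind)
    pre_sets = [set(tr) for tr in pre_trains]
    post_sets = [set(tr) for tr in post_trains]
    for t in range(n_steps):
        engine.advance_step(t)
        for j in range(store.M):
            if t in pre_sets[j]:
                engine.on_pre_spike(j, t)
        for i in range(store.N):
            if t in post_sets[i]:
                engine.on_post_spike(i, t)
    if flush:
        engine.flush(n_steps - 1)
    return engine
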