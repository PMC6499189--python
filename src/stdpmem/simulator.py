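"""Discrete-time LIF network simulation driving either STDP engine.

M Bernoulli pre-synaptic sources feed N leaky integrate-and-fire
post-synaptic neurons through a :class:`~stdpmem.connectivity.SynapticStore`:

    V_i(t + 1) = alpha * V_i(t) + sum_j w_ij s_j(t)

with membrane memory constant alpha, threshold V_th (spike, hard reset to 0,
refractory freeze for T_refr steps) and per-step pre-synaptic spike
probability p_spike outside the refractory period.  The last ``quiet_tail``
steps force pre-synaptic silence so the delayed engine's pending causal
updates can complete before the final weights are read.

A single RNG stream drives the run; the only random draws are the M
pre-synaptic uniforms per step (ascending neuron index), so identical seeds
and configurations reproduce traces byte for byte, whichever engine runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .connectivity import SynapticStore, build_store
from .plasticity import PlasticityConfig, make_engine

__all__ = [
    "SimConfig",
    "LIFState",
    "SimTrace",
    "lif_step",
    "bernoulli_pre_spikes",
    "run_simulation",
    "compare_engines",
]


@dataclass(frozen=True)
class SimConfig:
    alpha: float = 0.9
    v_th: float = 1.0
    t_refr: int = 4
    t_stdp: int = 16
    steps: int = 1000
    p_spike: float = 0.1
    seed: int = 0
    quiet_tail: Optional[int] = None  # None -> t_stdp

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.steps < 0:
            raise ValueError("steps must be nonnegative")
        if not 0.0 <= self.p_spike <= 1.0:
            raise ValueError("p_spike must lie in [0, 1]")
        if self.t_refr < 1 or self.t_stdp < 1:
            raise ValueError("T_refr and T_stdp must be at least 1")

    @property
    def effective_quiet_tail(self) -> int:
        return self.t_stdp if self.quiet_tail is None else self.quiet_tail


@dataclass
class LIFState:
    """Membrane potential and remaining refractory steps per post neuron."""

    v: np.ndarray
    refr: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "LIFState":
        return cls(np.zeros(n), np.zeros(n, dtype=np.int64))


def lif_step(state: LIFState, weighted_input: np.ndarray,
             cfg: SimConfig) -> np.ndarray:
    """One membrane update; returns the boolean spike vector.

    Non-refractory neurons integrate V <- alpha*V + input and spike when
    V >= V_th (hard reset to 0, refractory for T_refr steps); refractory
    neurons neither integrate nor spike.
    """
    weighted_input = np.asarray(weighted_input, dtype=float)
    if not np.all(np.isfinite(weighted_input)):
        raise ValueError("weighted input must be finite")
    active = state.refr == 0
    state.v[active] = cfg.alpha * state.v[active] + weighted_input[active]
    spikes = active & (state.v >= cfg.v_th)
    state.refr[~active] -= 1
    state.v[spikes] = 0.0
    state.refr[spikes] = cfg.t_refr
    return spikes


def bernoulli_pre_spikes(rng: np.random.Generator, p_spike: float,
                         refr: np.ndarray, t_refr: int) -> np.ndarray:
    """Bernoulli spikes for non-refractory pre neurons; mutates ``refr``.

    One uniform is drawn per neuron per step, ascending index, whether or
    not the neuron is refractory — keeping the stream layout independent of
    the spike pattern.
    """
    u = rng.random(len(refr))
    active = refr == 0
    spikes = active & (u < p_spike)
    refr[~active] -= 1
    refr[spikes] = t_refr
    return spikes


@dataclass
class SimTrace:
    """Per-step record of a run plus final state."""

    v: np.ndarray            # (steps, N) membrane potentials
    pre_raster: np.ndarray   # (steps, M) bool
    post_raster: np.ndarray  # (steps, N) bool
    tracked_post: int
    tracked_weights: np.ndarray  # (steps, M) incoming weights of tracked post
    access: np.ndarray       # (steps, 4) cumulative AT/PT/WT reads, WT writes
    final_weights: np.ndarray    # (M, N) dense, post-flush
    engine: str
    forward_accesses: int
    reverse_accesses: int


def run_simulation(cfg: SimConfig, store: SynapticStore,
                   plasticity: PlasticityConfig, engine: str = "delayed",
                   tracked_post: int = 0) -> SimTrace:
    """Simulate ``cfg.steps`` steps of the LIF network over ``store`` with
    the chosen plasticity engine, then flush pending updates."""
    if plasticity.kernel.t_stdp != cfg.t_stdp or plasticity.t_refr != cfg.t_refr:
        raise ValueError("plasticity window/refractory must match SimConfig")
    if not 0 <= tracked_post < store.N:
        raise ValueError("tracked_post out of range")
    M, N = store.M, store.N
    rng = np.random.default_rng(cfg.seed)
    eng = make_engine(store, plasticity, engine)
    lif = LIFState.zeros(N)
    pre_refr = np.zeros(M, dtype=np.int64)
    quiet_from = cfg.steps - cfg.effective_quiet_tail

    v = np.zeros((cfg.steps, N))
    pre_raster = np.zeros((cfg.steps, M), dtype=bool)
    post_raster = np.zeros((cfg.steps, N), dtype=bool)
    tracked = np.zeros((cfg.steps, M))
    access = np.zeros((cfg.steps, 4), dtype=np.int64)

    col_peek = _ColumnPeek(store, tracked_post)
    for t in range(cfg.steps):
        eng.advance_step(t)
        if t < quiet_from:
            spikes = bernoulli_pre_spikes(rng, cfg.p_spike, pre_refr, cfg.t_refr)
        else:  # enforced pre-synaptic silence
            spikes = np.zeros(M, dtype=bool)
            pre_refr[pre_refr > 0] -= 1
        weighted_input = np.zeros(N)
        for j in np.nonzero(spikes)[0]:
            posts, w_row = eng.on_pre_spike(int(j), t)
            weighted_input[posts] += w_row
        post_spikes = lif_step(lif, weighted_input, cfg)
        for i in np.nonzero(post_spikes)[0]:
            eng.on_post_spike(int(i), t)
        pre_raster[t] = spikes
        post_raster[t] = post_spikes
        v[t] = lif.v
        tracked[t] = col_peek()
        c = store.counters
        access[t] = (c.reads_at, c.reads_pt, c.reads_wt, c.writes_wt)
    eng.flush(cfg.steps - 1)
    return SimTrace(
        v=v, pre_raster=pre_raster, post_raster=post_raster,
        tracked_post=tracked_post, tracked_weights=tracked, access=access,
        final_weights=store.to_dense().weight, engine=engine,
        forward_accesses=eng.forward_accesses,
        reverse_accesses=eng.reverse_accesses,
    )


class _ColumnPeek:
    """Uncounted structural view of one post neuron's incoming weights
    (trace recording, not part of the access-cost model)."""

    def __init__(self, store: SynapticStore, i: int):
        self.store = store
        self.i = i
        self.M = store.M
        if hasattr(store, "wt") and hasattr(store, "exists"):  # crossbar
            self._mode = "dense"
        else:
            flat = np.nonzero(store.indices == i)[0]
            self._pres = (np.searchsorted(store.indptr, flat, side="right") - 1)
            self._flat = flat
            self._mode = "flat"

    def __call__(self) -> np.ndarray:
        out = np.zeros(self.M)
        if self._mode == "dense":
            col = self.store.exists[:, self.i]
            out[col] = self.store.wt[col, self.i]
        else:
            out[self._pres] = self.store.data[self._flat]
        return out


def compare_engines(cfg: SimConfig, dense, plasticity: PlasticityConfig,
                    store_format: str = "crossbar", tracked_post: int = 0):
    """Run both engines from identical initial conditions and seed.

    Returns ``(original_trace, delayed_trace)``; each engine gets its own
    freshly built store so the runs are fully independent.
    """
    store_o = build_store(dense, store_format)
    store_d = build_store(dense, store_format)
    trace_o = run_simulation(cfg, store_o, plasticity, "original", tracked_post)
    trace_d = run_simulation(cfg, store_d, plasticity, "delayed", tracked_post)
    return trace_o, trace_d
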