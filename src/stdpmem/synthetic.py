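"""Synthetic networks, named fixtures and forced spike trains.

All inputs to this package are generated: random Bernoulli-density
connectivity with Gaussian weights (the proof-of-concept initialisation:
mean 0.1, unit variance), a small worked 4x4 network, single-synapse
micro-scenarios for the delayed-update event calculus, the four
single-timer failure-case spike patterns, and perfectly interleaved
adjacencies that realise the run-length worst-case bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .connectivity import DenseConnectivity
from .plasticity import KernelSpec, PlasticityConfig

__all__ = ["GenSpec", "Fixture", "random_network", "fixture", "FIXTURE_NAMES"]


@dataclass(frozen=True)
class GenSpec:
    """Random-network recipe: Bernoulli(rho) adjacency per pre/post pair,
    Gaussian(weight_mean, weight_std**2) weights on existent pairs only."""

    M: int
    N: int
    rho: float
    weight_mean: float = 0.1
    weight_std: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.M < 1 or self.N < 1:
            raise ValueError("M and N must be at least 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.weight_std < 0:
            raise ValueError("weight_std must be nonnegative")


def random_network(spec: GenSpec) -> DenseConnectivity:
    """Seeded random network; each connection exists independently with
    probability rho, weights drawn for existent pairs only."""
    rng = np.random.default_rng(spec.seed)
    exists = rng.random((spec.M, spec.N)) < spec.rho
    weight = np.zeros((spec.M, spec.N))
    weight[exists] = rng.normal(spec.weight_mean, spec.weight_std,
                                int(exists.sum()))
    return DenseConnectivity(exists, weight)


@dataclass(frozen=True)
class Fixture:
    """A named deterministic scenario: network plus optional forced trains."""

    name: str
    dense: DenseConnectivity
    pre_trains: Optional[tuple] = None   # per-pre sorted spike steps
    post_trains: Optional[tuple] = None  # per-post sorted spike steps
    config: Optional[PlasticityConfig] = None
    n_steps: int = 0
    note: str = ""


def _single_synapse(w0: float = 0.5) -> DenseConnectivity:
    return DenseConnectivity.from_entries(1, 1, [(0, 0, w0)])


# Fig-4-style failure cases share one deficient configuration: a window
# longer than the refractory period but only a single timer per neuron.
_CASE_KERNEL = KernelSpec(shape="ramp", a_plus=0.01, a_minus=0.01, t_stdp=8)


def _case_config(n_timers: Optional[int]) -> PlasticityConfig:
    return PlasticityConfig(kernel=_CASE_KERNEL, t_refr=2,
                            mode="nearest_neighbor", n_timers=n_timers)


def _build_f4() -> Fixture:
    # worked 4x4 network: rows 0 -> {0, 2}, 1 -> {}, 2 -> {1, 2, 3}, 3 -> {0},
    # weights .5 .25 .1 .2 .3 .4 assigned row-major over existent connections
    dense = DenseConnectivity.from_entries(4, 4, [
        (0, 0, 0.5), (0, 2, 0.25),
        (2, 1, 0.1), (2, 2, 0.2), (2, 3, 0.3),
        (3, 0, 0.4),
    ])
    return Fixture("F4", dense, note="worked 4x4 store-encoding example")


def _build_s1() -> Fixture:
    # single-synapse equivalence scenario: w0 = 0.5, ramp +-0.01, T_stdp = 8;
    # post spikes at 2 and 7, pre spikes at 5 -> acausal -0.0075 at t=5,
    # delayed causal +0.00875 at window exit, final weight 0.50125
    cfg = PlasticityConfig(
        kernel=KernelSpec(shape="ramp", a_plus=0.01, a_minus=0.01, t_stdp=8),
        t_refr=4, mode="all_to_all")
    return Fixture("S1", _single_synapse(0.5),
                   pre_trains=((5,),), post_trains=((2, 7),),
                   config=cfg, n_steps=24,
                   note="single-synapse original/delayed equivalence scenario")


def _build_case(name: str) -> Fixture:
    trains = {
        # high-firing pre: second pre spike while the first is in the window
        "case1": (((2, 5),), ((7,),)),
        # high-firing post: second post spike before the pre spike
        "case2": (((6,),), ((1, 4),)),
        # second pre spike before the first timer expires, posts around it
        "case3": (((2, 6),), ((4, 8),)),
        # high-firing post inside one pre timer span: the lost causal update
        "case4": (((2,),), ((4, 7),)),
    }
    pre, post = trains[name]
    return Fixture(name, _single_synapse(0.5), pre_trains=pre,
                   post_trains=post, config=_case_config(1), n_steps=24,
                   note="single-timer drawback pattern (T_refr < T_stdp)")


def _build_interleaved(M: int, N: int, rho: float) -> Fixture:
    """Alternating-gap adjacency: every existent connection is preceded by a
    one-step gap, so each row encodes to exactly 2*k run-length records and
    realises the rho < 0.5 worst case."""
    k = int(round(rho * N))
    if k > N // 2:
        raise ValueError("interleaved fixture requires rho <= 0.5")
    exists = np.zeros((M, N), dtype=bool)
    weight = np.zeros((M, N))
    for j in range(M):
        for c in range(k):
            i = 2 * c + 1  # leading gap before every weight
            exists[j, i] = True
            weight[j, i] = 0.5
    return Fixture(f"interleaved({M},{N},{rho})",
                   DenseConnectivity(exists, weight),
                   note="worst-case interleaved runs and weights")


FIXTURE_NAMES = ("F4", "S1", "case1", "case2", "case3", "case4", "interleaved")


def fixture(name: str, M: int = 4, N: int = 4, rho: float = 0.5) -> Fixture:
    """Built-in deterministic fixtures; ``interleaved`` takes (M, N, rho)."""
    if name == "F4":
        return _build_f4()
    if name == "S1":
        return _build_s1()
    if name in ("case1", "case2", "case3", "case4"):
        return _build_case(name)
    if name == "interleaved":
        return _build_interleaved(M, N, rho)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
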