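"""Analytic storage/access cost models and efficiency metrics.

For a network with M pre-synaptic neurons, N post-synaptic neurons, W-bit
weights and connectivity density rho, every memory arrangement has a
closed-form expected storage cost (bits of AT + PT + WT) and a per-neuron
forward/reverse access cost (table positions read).  Analytic costs are
real-valued — no integer ceilings — so they trace the idealised curves;
measured costs from built stores use the true integer field widths.  The
run-length format's closed forms are worst-case bounds for perfectly
interleaved runs and weights (regimes split at rho = 0.5).

Efficiencies compare against the incompressible minimum:

* storage:   eta_s = C_s_ref / C_s   with C_s_ref = M rho N W
             (bits of the existent weights alone),
* access:    eta_a = C_a_ref / C_a   with C_a_ref = rho M N
             (one read per existent connection, all rows swept once),
* budget:    eta = lambda * eta_s + (1 - lambda) * eta_a.

The spike-history model compares a per-neuron bitmap of the STDP window
(T_stdp bits) against a bank of ceil(T_stdp / T_refr) refractory-period
timers of ceil(log2(T_refr + 1)) bits each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

ANALYTIC_FORMATS = ("crossbar", "csr", "rle", "bmp")

__all__ = [
    "NetworkParams",
    "CostBreakdown",
    "AccessCost",
    "EfficiencyPoint",
    "analytic_storage_cost",
    "analytic_forward_cost",
    "analytic_reverse_cost",
    "storage_efficiency",
    "access_efficiency",
    "analytic_storage_efficiency",
    "analytic_access_efficiency",
    "budget_efficiency",
    "efficiency_table",
    "sweep_dataframe",
    "best_format_map",
    "BudgetMap",
    "spike_history_bits",
]


@dataclass(frozen=True)
class NetworkParams:
    """Parameter bundle (M, N, W, rho) driving every cost formula."""

    M: int
    N: int
    W: int
    rho: float

    def __post_init__(self):
        if self.M < 1 or self.N < 1:
            raise ValueError("M and N must be at least 1")
        if self.W < 1:
            raise ValueError("weight bit-length W must be at least 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("density rho must lie in [0, 1]")


@dataclass(frozen=True)
class CostBreakdown:
    """Per-table bit (or read) cost; real-valued analytic, integer measured."""

    at_bits: float
    pt_bits: float
    wt_bits: float

    @property
    def total(self) -> float:
        return self.at_bits + self.pt_bits + self.wt_bits


@dataclass(frozen=True)
class AccessCost:
    """Table positions read per neuron, split by table."""

    at: float
    pt: float
    wt: float

    @property
    def total(self) -> float:
        return self.at + self.pt + self.wt


@dataclass(frozen=True)
class EfficiencyPoint:
    eta_s: float
    eta_a: float
    lam: float

    @property
    def eta(self) -> float:
        return budget_efficiency(self.eta_s, self.eta_a, self.lam)


def _ptr_width(n_entries: float) -> float:
    """Real-valued pointer width log2(n); sub-unit entry counts clamp to one
    bit, zero entries need none (ultra-sparse guard)."""
    if n_entries <= 0:
        return 0.0
    return max(1.0, math.log2(n_entries))


def analytic_storage_cost(p: NetworkParams, format: str) -> CostBreakdown:
    """Closed-form expected storage bits per arrangement (RLE: worst case)."""
    M, N, W, rho = p.M, p.N, p.W, p.rho
    log_n = math.log2(N) if N > 1 else 0.0
    if format == "crossbar":
        return CostBreakdown(0.0, 0.0, M * N * W)
    if format == "csr":
        if rho == 0.0:
            return CostBreakdown(0.0, 0.0, 0.0)
        return CostBreakdown(0.0, M * _ptr_width(M * rho * N),
                             M * rho * N * (log_n + W))
    if format == "rle":
        pt = M * _ptr_width(M * N)
        if rho < 0.5:
            wt = M * rho * N * (2 + log_n + W) + M * log_n
        else:
            wt = M * N * (1 + (1 - rho) * log_n + rho * W)
        return CostBreakdown(0.0, pt, wt)
    if format == "bmp":
        return CostBreakdown(M * N, M * _ptr_width(M * rho * N),
                             M * rho * N * W)
    raise ValueError(f"unknown format {format!r}")


def analytic_forward_cost(p: NetworkParams, format: str) -> AccessCost:
    """Expected forward reads per pre-synaptic neuron (RLE: worst case)."""
    N, rho = p.N, p.rho
    if format == "crossbar":
        return AccessCost(0.0, 0.0, float(N))
    if format == "csr":
        return AccessCost(0.0, 2.0, rho * N)
    if format == "rle":
        return AccessCost(0.0, 1.0, 2 * rho * N if rho < 0.5 else float(N))
    if format == "bmp":
        return AccessCost(float(N), 1.0, rho * N)
    raise ValueError(f"unknown format {format!r}")


def analytic_reverse_cost(p: NetworkParams, format: str) -> AccessCost:
    """Expected reverse reads per post-synaptic neuron via the forward sweep
    (worst case for pointer-based formats)."""
    M, N, rho = p.M, p.N, p.rho
    if format == "crossbar":
        return AccessCost(0.0, 0.0, float(M))
    if format == "csr":
        return AccessCost(0.0, float(M), M * rho * N)
    if format == "rle":
        return AccessCost(0.0, float(M),
                          M * 2 * rho * N if rho < 0.5 else float(M * N))
    if format == "bmp":
        return AccessCost(M + rho * M * (N - 1), rho * M, rho * M)
    raise ValueError(f"unknown format {format!r}")


def storage_efficiency(total_bits: float, p: NetworkParams) -> float:
    """eta_s = M rho N W / C_s for a measured or analytic total cost."""
    ref = p.M * p.rho * p.N * p.W
    if total_bits <= 0:
        raise ValueError("storage cost must be positive")
    return ref / total_bits


def access_efficiency(total_reads: float, p: NetworkParams) -> float:
    """eta_a = rho M N / C_a; C_a is the whole-network forward read count
    (every pre-synaptic row swept once)."""
    ref = p.rho * p.M * p.N
    if total_reads <= 0:
        raise ValueError("access cost must be positive")
    return ref / total_reads


def analytic_storage_efficiency(p: NetworkParams, format: str) -> float:
    return storage_efficiency(analytic_storage_cost(p, format).total, p)


def analytic_access_efficiency(p: NetworkParams, format: str) -> float:
    return access_efficiency(p.M * analytic_forward_cost(p, format).total, p)


def budget_efficiency(eta_s: float, eta_a: float, lam: float) -> float:
    """Affine storage/access trade-off eta = lam*eta_s + (1-lam)*eta_a."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return lam * eta_s + (1.0 - lam) * eta_a


# ---------------------------------------------------------------------------
# Sweeps and budget maps
# ---------------------------------------------------------------------------

def _measure_network(dense, W: int):
    """Measured (storage bits, whole-network forward reads) per format."""
    from .connectivity import FORMATS, build_store

    out = {}
    for fmt in FORMATS:
        store = build_store(dense, fmt)
        bits = store.storage_bits(W).total
        store.counters.reset()
        for j in range(store.M):
            store.charge_forward(j)
        out[fmt] = (bits, store.counters.total_reads)
    return out


def efficiency_table(M: int, N: int, W: int, rhos, mode: str = "analytic",
                     n_networks: int = 100, seed: int = 0):
    """eta_s / eta_a per format over a density grid.

    Empirical mode averages measured costs of ``n_networks`` random
    Bernoulli-rho networks per density point (seeded); analytic mode
    evaluates the closed forms.  Returns
    ``{format: (eta_s array, eta_a array)}`` aligned with ``rhos``.
    """
    rhos = np.asarray(list(rhos), dtype=float)
    if rhos.size == 0:
        raise ValueError("empty density grid")
    if mode not in ("analytic", "empirical"):
        raise ValueError("mode must be 'analytic' or 'empirical'")
    table = {fmt: (np.empty_like(rhos), np.empty_like(rhos))
             for fmt in ANALYTIC_FORMATS}
    if mode == "analytic":
        for k, rho in enumerate(rhos):
            p = NetworkParams(M, N, W, float(rho))
            for fmt in ANALYTIC_FORMATS:
                table[fmt][0][k] = analytic_storage_efficiency(p, fmt)
                table[fmt][1][k] = analytic_access_efficiency(p, fmt)
        return table

    from .synthetic import GenSpec, random_network

    rng_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1,
                                                     size=(rhos.size, n_networks))
    for k, rho in enumerate(rhos):
        p = NetworkParams(M, N, W, float(rho))
        sums = {fmt: [0.0, 0.0] for fmt in ANALYTIC_FORMATS}
        for r in range(n_networks):
            dense = random_network(GenSpec(M=M, N=N, rho=float(rho),
                                           seed=int(rng_seeds[k, r])))
            for fmt, (bits, reads) in _measure_network(dense, W).items():
                sums[fmt][0] += bits
                sums[fmt][1] += reads
        for fmt in ANALYTIC_FORMATS:
            table[fmt][0][k] = storage_efficiency(sums[fmt][0] / n_networks, p)
            table[fmt][1][k] = access_efficiency(sums[fmt][1] / n_networks, p)
    return table


def sweep_dataframe(M: int, N: int, W: int, rhos, mode: str = "analytic",
                    n_networks: int = 100, seed: int = 0):
    """Tidy efficiency sweep (one row per format x density)."""
    import pandas as pd

    table = efficiency_table(M, N, W, rhos, mode, n_networks, seed)
    rows = []
    for fmt, (eta_s, eta_a) in table.items():
        for rho, es, ea in zip(rhos, eta_s, eta_a):
            rows.append({"format": fmt, "M": M, "N": N, "W": W,
                         "rho": float(rho), "lambda": np.nan,
                         "eta_s": es, "eta_a": ea, "eta": np.nan,
                         "mode": mode, "seed": seed})
    return pd.DataFrame(rows)


@dataclass
class BudgetMap:
    """Argmax-format map over the (rho, lambda) plane."""

    rhos: np.ndarray
    lams: np.ndarray
    formats: np.ndarray  # shape (len(lams), len(rhos)), dtype=object
    eta: np.ndarray      # best-format budget efficiency, same shape
    mode: str
    seed: int

    def tidy(self):
        import pandas as pd

        rows = []
        for a, lam in enumerate(self.lams):
            for b, rho in enumerate(self.rhos):
                rows.append({"rho": float(rho), "lambda": float(lam),
                             "format": self.formats[a, b],
                             "eta": float(self.eta[a, b]),
                             "mode": self.mode, "seed": self.seed})
        return pd.DataFrame(rows)


def best_format_map(rhos, lams, M: int = 256, N: int = 256, W: int = 8,
                    mode: str = "analytic", n_networks: int = 100,
                    seed: int = 0) -> BudgetMap:
    """For each (rho, lambda) grid point, the arrangement with the highest
    budget efficiency (ties broken by format declaration order)."""
    rhos = np.asarray(list(rhos), dtype=float)
    lams = np.asarray(list(lams), dtype=float)
    if rhos.size == 0 or lams.size == 0:
        raise ValueError("empty rho or lambda grid")
    table = efficiency_table(M, N, W, rhos, mode, n_networks, seed)
    formats = np.empty((lams.size, rhos.size), dtype=object)
    eta = np.zeros((lams.size, rhos.size))
    for a, lam in enumerate(lams):
        for b in range(rhos.size):
            best_fmt, best_eta = None, -np.inf
            for fmt in ANALYTIC_FORMATS:
                e = budget_efficiency(table[fmt][0][b], table[fmt][1][b],
                                      float(lam))
                if e > best_eta:
                    best_fmt, best_eta = fmt, e
            formats[a, b] = best_fmt
            eta[a, b] = best_eta
    return BudgetMap(rhos, lams, formats, eta, mode, seed)


# ---------------------------------------------------------------------------
# Spike-history storage
# ---------------------------------------------------------------------------

def spike_history_bits(t_stdp: int, t_refr: int, scheme: str) -> int:
    """Per-neuron bits to store every spike inside the STDP window.

    ``timers``: ceil(T_stdp / T_refr) timers, each ceil(log2(T_refr + 1))
    bits (one timer per refractory period captures every possible spike;
    reduces to a single timer when T_refr >= T_stdp).
    ``bitmap``: one bit per time step of the window, T_stdp bits.
    """
    if t_stdp < 1 or t_refr < 1:
        raise ValueError("T_stdp and T_refr must be at least 1")
    if scheme == "bitmap":
        return t_stdp
    if scheme == "timers":
        n_timers = math.ceil(t_stdp / t_refr)
        return n_timers * math.ceil(math.log2(t_refr + 1))
    raise ValueError("scheme must be 'timers' or 'bitmap'")


def n_exact_timers(t_stdp: int, t_refr: int) -> int:
    """Timer count guaranteeing no spike in the window is ever lost."""
    if t_stdp < 1 or t_refr < 1:
        raise ValueError("T_stdp and T_refr must be at least 1")
    return math.ceil(t_stdp / t_refr)
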