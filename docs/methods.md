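# Methods

This note records the model conventions, parameter choices and numerical
decisions behind `stdpmem`, and what the synthetic experiments do and do
not establish.

## Access-cost model

Storage and access are modelled at the data-structure level, deliberately
abstracting physical memory: every position of the adjacency table (AT),
pointer table (PT) or weight table (WT) holds one packet of information,
and each read or write of one position costs one computational unit.  Burst
reads, row/column strobes and controller scheduling of physical DRAM are
out of scope.  Storage cost is the number of bits the built tables occupy
under declared field widths; access cost is the number of positions touched
by a traversal.  The `AccessCounter` on every store measures the latter
exactly, per table.

Per-row forward-access costs, as measured (k_j = existent connections of
pre row j, N post neurons):

| arrangement | AT | PT | WT |
|---|---|---|---|
| crossbar | 0 | 0 | N |
| PB-CSR   | 0 | 2 | k_j |
| PB-RLE   | 0 | 1 | ≤ min(2·k_j, N) records |
| PB-BMP   | N | 1 | k_j |

Reverse access on pointer-based stores is implemented as the forward sweep
(no mirrored reverse tables).  The CSR sweep reads the boundary pointer
array PT[0..M] once — M+1 pointer reads, one more than the idealised M
of the closed form, a deliberate and documented divergence.  The bitmap
sweep probes AT(j, i) for every pre row and walks the remaining N−1 bits
only for connected rows, giving measured expectations M + ρM(N−1) AT, ρM
PT and ρM WT reads.

## Encoding conventions

* Indexing is 0-based everywhere; the crossbar row origin is j·N (the
  1-based pointer arithmetic A*_j = (j−1)N+1 translates directly).
* CSR keeps M+1 pointer entries so every row has a start and stop pointer;
  the storage model charges M pointers of ⌈log2(nnz)⌉ bits (the boundary
  entry is an implementation convenience charged to neither table).
* The crossbar reserves one of the 2^W weight codes for nonexistence.  At
  run time weights stay floats and existence is a boolean mask; the
  sentinel belongs to the storage model only.  This mirrors the separation
  between the accounting abstraction and physical storage.
* RLE rows alternate weight records (run bit + W weight bits) and run
  records (run bit + ⌈log2 N⌉ run-length bits).  Runs are merged maximally
  and trailing runs are not emitted, so a row holds at most
  min(2·k_j, N) records; leading-gap interleaved rows attain 2·k_j
  exactly, which is why the alternating fixtures realise the worst-case
  bound with equality.  The closed-form worst cases (regime split at
  ρ = 0.5) are upper bounds only.
* Pointer widths use ⌈log2(entries)⌉ clamped to ≥ 1 bit for nonempty
  tables and 0 bits for empty ones; analytic formulas are real-valued (no
  ceilings) so they trace the idealised curves, and the mode (analytic vs
  measured) is always explicit in the API.

## Efficiency metrics

η_s = C_s^ref / C_s with C_s^ref = MρNW (bits of existent weights alone);
η_a = C_a^ref / C_a with C_a^ref = ρMN (one read per existent connection
with all rows swept once).  Budget efficiency η = λη_s + (1−λ)η_a with
λ ∈ [0, 1].  Two closed-form consequences used as test anchors: the
crossbar's η_s equals ρ exactly, and the bitmap's
η_a = ρN/(N + 1 + ρN) < 1/2 for every finite configuration, approaching
50% as ρ → 1 and N grows.

Empirical sweeps average measured costs over 100 random networks per
density point by default (a flag restores 1000); the problem sizes keep a
desk-scale run in seconds while Monte-Carlo noise stays well inside the
5% agreement tolerance the tests use.  Sweep seeds are always recorded in
the output.

## STDP engines

Both engines operate in discrete time with a canonical intra-step order:

1. histories age; expiring pre-synaptic spikes are serviced (delayed
   engine's causal updates), oldest first, pre index ascending;
2. this step's pre-synaptic spikes, index ascending: pending causal
   service (the high-firing-pre rule), then the acausal pass, then the row
   weights are delivered to the simulator;
3. post-synaptic neurons integrate; post spikes are registered (classic
   engine: causal updates via reverse access now).

Conventions:

* A spike is pairable for lags 1..T_stdp and its history entry is serviced
  and removed at age T_stdp + 1, so a pair at exactly |Δt| = T_stdp is
  realisable.  Same-step pairs (Δt = 0) contribute nothing — the kernels
  are discontinuous at zero and no rule favours either sign; this is the
  package's convention, applied identically everywhere.
* Kernels: ramp A(T_stdp − |Δt| + 1)/T_stdp (peak ±A at |Δt| = 1, smallest
  nonzero step A/T_stdp), box A, truncated exponential
  A·exp(−(|Δt|−1)/τ).  No weight clipping.
* Nearest-neighbor interaction pairs each spike with the most recent
  partner spike only; all-to-all pairs every spike in the window.
* Causal variants: `last_timer` services a pre spike's pairs when its last
  timer expires (plus the pending service at the next pre spike);
  `each_timer` additionally services at every refractory-period boundary.
  Both leave identical weights after any full flush; the bookkeeping
  records, per pre neuron, the time up to which causal pairs are applied,
  so no pair is ever serviced twice.
* Bit-exactness: per weight, updates are individual float additions in
  (post-spike time ascending, pre-spike time ascending) order — exactly
  the classic engine's chronology — and kernel magnitudes come from a
  shared lag-indexed lookup, so classic engine, delayed engine and the
  brute-force pair-sum oracle agree to the last bit, not within a
  tolerance.
* Refractoriness: consecutive spikes of one neuron must be at least
  T_refr + 1 steps apart (that is what the LIF mechanics produce); forced
  trains violating this are rejected.
* Spike-history depth: ⌈T_stdp/T_refr⌉ timers of ⌈log2(T_refr+1)⌉ bits
  capture every spike that can occur in the window (a single timer when
  T_refr ≥ T_stdp).  Note the integer ceilings make the timer bank
  slightly *larger* than a T_stdp-bit window bitmap for some small
  parameter pairs (e.g. T_stdp = 3, T_refr = 2: 4 vs 3 bits); the
  advantage claim holds for the real-valued relaxation
  (T/R)·log2(R+1) ≤ T and grows with T_refr.  Configuring fewer timers
  (e.g. one, with T_refr < T_stdp) deliberately reproduces the lossy
  regime: overwritten history loses causal updates — never duplicates
  them — so delayed weights are bounded above by the exact ones.

The classic engine always keeps exact windowed histories; it is the
reference.  The delayed engine's history depth is the configured timer
budget.

## Simulator

Post-synaptic neurons are LIF units, V_i(t+1) = αV_i(t) + Σ_j w_ij s_j(t),
defaults α = 0.9 and V_th = 1.0; a spike hard-resets V to 0 and freezes
the neuron for T_refr steps (the reset/freeze rule is the simplest one
consistent with leaky integrate-and-fire and affects both engines
identically).  Pre-synaptic sources fire Bernoulli(p_spike = 0.1) outside
their own refractory period; one uniform per neuron per step is drawn in
ascending index order from a single seeded stream, so runs are exactly
reproducible and both engines see identical pre-synaptic input.  The last
`quiet_tail` steps (default T_stdp) force pre-synaptic silence so pending
delayed updates can complete; `flush` then services anything left.

The reference experiment is a 256×256 network, Gaussian(0.1, 1) initial
weights (unclipped — negative weights are legal and affect both engines
identically), density ρ = 0.1.  The density is the package's choice of a
sparse operating point, the regime where pointer-based stores are the
interesting ones; engine equivalence itself is density-independent.  A
scaled 32×32/300-step configuration exercises the identical code path in
under two seconds.  Full per-step weight-matrix snapshots at the reference
scale would cost ~0.5 GB per engine, so the trace records per-step incoming
weights for one tracked post-synaptic neuron (default B_0) plus the final
weight matrix; membrane potentials, rasters and access counters are
recorded every step.

## Metrics

Membrane (and tracked-weight) error is reported as a per-step sum of
squared differences across neurons plus total and mean; the equivalence
claims use exact zero, so the sum/mean convention never affects a verdict.
The van Rossum distance filters rasters with the causal exponential
f[t] = e^(−1/τ) f[t−1] + s[t] and takes per-neuron
sqrt((1/τ)Σ_t (f−g)²), summed across neurons; τ defaults to the
membrane-matched −1/log α ≈ 9.49 steps for α = 0.9.  The discrete filter
is the exact sampling of the continuous exponential kernel at the grid
points.

## What the synthetic data does and does not show

Generated networks are Bernoulli-per-pair (not fixed in/out-degree), with
Gaussian weights on existent connections only; fixtures (the worked 4×4
network, the single-synapse scenarios, the four single-timer failure
patterns, interleaved adjacencies) are deterministic constants guarded by
golden files.  Passing tests establish the combinatorial and numerical
claims — lossless encodings, exact accounting, bit-exact engine
equivalence, cost-formula agreement — for the stated model.  They do not
validate biological realism (no structured topology, no axonal delays, no
conductance dynamics, no weight dependence of the kernel), and the cost
model's single-packet abstraction means measured units are proxies for,
not predictions of, physical latency or energy.

## Known limitations

* Triplet-based interaction is not implemented: its timer bookkeeping
  would double the history span, and no update amplitudes are defined for
  it here.
* Reverse access via duplicated reverse PT/WT tables is out of scope
  (trivially forward access on mirrored tables at double storage).
* Structural plasticity is excluded: updates never create or destroy
  synapses, and writing to a nonexistent connection is an error.
* The RLE closed forms are worst-case bounds; exact expected costs depend
  on the run-length distribution and are measured, not derived.
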