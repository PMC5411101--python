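# Methods

## Model and state space

The model is a continuous-time Markov jump process. Its state is the
promoter occupancy pattern `(s_1 … s_{N_P})`, the number of TF-bound
competitor sites `c`, and the per-promoter mRNA counts `(m_1 … m_{N_P})`.
TF copy number is strictly conserved (`n + c ≤ N_TF` with `n = Σ s_i`);
there is no TF synthesis, degradation, or volume/concentration
approximation — all copy numbers are integers and all rates are s⁻¹.

Identical promoters make the aggregate chain over `(n, c, m)` (with
`m = Σ m_i`) lossless for every distribution-level quantity; the
per-promoter representation is kept because mRNA molecules are attributed
to the promoter that produced them, which is what makes the two-promoter
correlation observable. Since decay is linear, per-pool decay leaves the
aggregate dynamics unchanged.

Default parameters follow measured *E. coli* kinetics: `k_on = 0.0027`
(per TF per promoter), `k_off = 0.0023` (per complex), `r = 0.33` (per
transcribing promoter), `γ = 0.011` s⁻¹ (per mRNA), i.e. mRNA lifetime
≈ 91 s and TF residence time ≈ 435 s. Competitor-site rates default to
the promoter rates unless overridden. The basal rate `r_basal` (activator
mode only) defaults to 0.

## Stochastic simulation

The SSA is the direct Gillespie method with one refinement: exchangeable
channels are aggregated (total binding propensity `k_on·F·(N_P−n)`, etc.)
and the target promoter is drawn uniformly — or propensity-weighted where
rates differ, as with a nonzero basal rate or mRNA decay — by a second
uniform variate. This is equivalent in law to enumerating every
per-promoter channel and is exact; no tau-leaping or hybrid approximation
is used anywhere.

**Seeding.** One master integer seed; replicate `k` uses the stream
spawned at `SeedSequence(seed, spawn_key=(k,))`, so any replicate is
reproducible in isolation and all outputs are bit-reproducible.

**Steady-state protocol.** Population snapshots are independent replicates
started from the all-free, mRNA-free state and recorded after a burn-in.
The default burn-in is **ten times the slowest relaxation time** of the
system, `10 · max(1/γ, 1/(k_on+k_off), 1/(k_on_c+k_off_c))` (2000 s at
the default rates). The promoter-occupancy chain relaxes at order
`k_on + k_off`, which for slow TF kinetics is *slower* than the mRNA
lifetime; a burn-in scaled to `1/γ` alone leaves a percent-level
deterministic bias toward the initial condition that is detectable at
10⁴ replicates. Shorter user-supplied burn-ins trigger a warning. A
single-trajectory time-average mode (snapshots every five relaxation
times) is provided as an alternative and is cross-checked against the
replicate ensemble by an ergodicity test.

## Exact steady states

**Binding chain.** The mRNA-independent `(n, c)` chain is finite and
reversible. Its stationary law is computed by a sparse linear solve (one
balance row replaced by normalization) and verified against the
closed-form equilibrium product weights
`P(n,c) ∝ C(N_P,n) C(N_C,c) N_TF!/(N_TF−n−c)! (k_on/k_off)^n (k_on_c/k_off_c)^c`
(computed in log space); the two routes must agree to 1e−10 or the solver
raises. `k_off = 0` with active binding is an absorbing boundary and only
warns.

**Full master equation.** The generator on the aggregate `(n, c, m)`
lattice is assembled sparsely with the mRNA axis truncated at `m_max`
(initially `⌈cap + 10√cap⌉` with `cap = N_P·r/γ`, the saturated mean plus
ten Poisson widths). Transcription out of the top row is frozen
(reflecting truncation), and the probability resident at `m = m_max` is
reported as the truncation mass; `m_max` doubles until that mass falls
below `tol` (default 1e−8, at most six doublings before a hard error).
State spaces in all shipped experiments stay ≤ ~10⁴ states, where a
direct sparse LU solve is fast and accurate; no iterative solver is
needed. Internal consistency checks in the test suite: the
`(n, c)`-marginal equals the binding-chain law (mRNA does not feed back
on binding), moments are Cauchy in `m_max`, stationary edge fluxes of the
binding chain vanish (detailed balance), and the `N_TF = 0` repressor
case reproduces a Poisson(`r/γ`) law to 1e−9 total variation.

**Two-promoter correlation.** Because transcription and decay
propensities are *linear* in the mRNA counts, the conditional moments
`E[1_σ m_j]` and `E[1_σ m_j m_k]` over the occupancy microstate
`σ = (s_1, s_2, c)` satisfy closed linear systems
(`(γI − Qᵀ)x = ρ∘π`, and similarly at `2γ` for second moments). Solving
these gives the exact stationary Pearson correlation with **no mRNA
truncation at all**, at the cost of an occupancy-chain solve only. This
was chosen over solving the five-dimensional
`(s_1, s_2, c, m_1, m_2)` lattice, which is mathematically equivalent but
orders of magnitude larger; the SSA estimate cross-checks the result.

## Closed forms and the master curve

The telegraph-model mean and Fano factor (activator and repressor
variants) are implemented exactly as stated in the README and are valid
only for `N_P = 1`, `N_C = 0`, `r_basal = 0`; out-of-regime calls raise.
The master curve eliminates `k_on N_TF` between mean and variance. Two
properties define the pair and are enforced at 1e−10 in tests: plugging
the closed-form mean into the curve returns the closed-form variance, and
the closed form matches the exact CME across a ×0.1…×10 rate grid.

**How exact is the collapse?** For one promoter sharing TFs with decoys,
the exact solver shows the `(mean, variance)` point sits on the master
curve only to ~1–3% relative residual at the default rates (worse for
slow competitor kinetics, vanishing as competitor kinetics become fast or
TFs abundant). The effective-binding-rate picture is exact for the mean
but approximate for the variance: when the free-TF pool fluctuates, the
promoter's OFF→ON waiting time is phase-type rather than exponential.
Simulated scatter plots cannot resolve this; the exact solver can, and
the package reports it honestly rather than asserting a perfect collapse.
For two promoters at TF scarcity the residual grows to ~10–17% — an order
of magnitude above the single-promoter level — and returns monotonically
to it as `N_TF` grows, which is the usable signature distinguishing the
two competition scenarios.

## Moment closure for multiple promoters

For `N_P > 1` the moment hierarchy does not close (the binding propensity
is quadratic in `n`). The implemented approximation works at the level of
exchangeable promoter indicators `p = ⟨s_i⟩`, `q = ⟨s_i s_j⟩`,
`w = ⟨s_i m⟩`, closing by setting the third joint cumulants of
`(s_i, s_j, s_k)` and `(s_i, s_j, m)` to zero — second-order cumulant
neglect. Working with indicators rather than aggregate `n` builds
`s² = s` into the equations, so the closure is *exact* at `N_P = 1`
(it reproduces the telegraph moments to solver precision); a closure on
raw moments of `n` does not have this property. The five-equation steady
state is solved with a damped hybrid Newton method from the
independent-promoter initial guess; at `N_P = N_TF = 10` the closure mean
tracks the exact CME within ~10%, with the residual systematic (neglected
third cumulants), as expected of a second-order scheme.

## Mode counting

mRNA counts are integers, so modes are detected on the raw integer
support rather than with kernel density estimates (no bandwidth to
choose). The pmf is smoothed with a centered moving average (default
window 5, renormalized at the edges so boundary bins are not damped),
then local maxima with prominence ≥ 5% of the smoothed maximum (default)
are counted; plateaus merge to their leftmost index, and boundary maxima
— e.g. the pile-up of silent cells at `m = 0` when competitors sequester
the pool — count as modes. Window and prominence are exposed on the CLI,
and the shipped modality transitions are stable under halving/doubling
the window.

## Experiment layer and CLI

Sweeps return tidy tables (one row per swept value) carrying mean,
variance, Fano, fold change and — with the SSA engine — bootstrap
standard errors (default 1000 seeded resamples), plus a JSON provenance
sidecar (spec template, settings, seed, package version, timestamp).
Peak locations are reported as the swept value maximizing the statistic,
ties toward the smaller value; the exact (CME) engine is the recommended
one for peak-location questions since it has no sampling jitter. Default
figure-level sizes (10⁴ cells SSA, exact solves elsewhere) keep every
shipped experiment in the minutes range on one core.

## What the defaults do and do not show

The default parameter set places the model in the slow-switching, high-burst
regime of bacterial TFs; conclusions about peak *sharpness*, mode
*positions* and correlation *magnitudes* are specific to it, while the
structural results (noise peak at parity, single-promoter near-collapse,
multi-promoter collapse failure, competitor-induced multimodality,
anticorrelation signature) are reproduced across the rate grids exercised
in the tests. Known limitations: protein-level noise, autoregulation,
TF production/degradation, cell growth and gene replication are out of
scope; the exact solvers are practical only for the small copy numbers
(tens of promoters, hundreds of mRNA) typical of these questions; and the
activator variance/Fano peak sits within ±1 TF of parity rather than
exactly at it — the peak top is flat to ~0.1%, so its argmax is not a
robust observable.
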