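# Methods

This note documents the statistical model behind `hammettfit`, its
numerical choices, and what the synthetic worlds used in testing do and do
not establish.

## Model and gauge

All fitting targets the bilinear form

```
y_{s,j} = c_j + ρ_j σ_s + ε
```

with reaction constants ρ, substituent-set constants σ, and explicit
per-reaction offsets c (the response of the reference substituent set).
Keeping c explicit — rather than folding it into a reference rate constant
— lets tables that lack the unsubstituted compound remain fittable.

The form is invariant under two reparameterizations: the scale swap
(ρ·k, σ/k) and the shift (σ + d, c − ρd). Both are fixed by convention, not
by data: ρ(anchor) = 1 (anchor configurable, default the lexicographically
first reaction id) and σ(reference set) = 0 (default the all-H set). All
recovery tests compare parameters only after aligning gauges.

## Global fit

**Pairwise slopes.** For each ordered reaction pair with ≥ 2 shared
substituent sets, the slope of y_j against y_i estimates ρ_j/ρ_i. The
Theil–Sen estimator is used: the median over all C(n,2) pairwise point
slopes, pairs with equal abscissa skipped, even counts resolved by the
midpoint. Its ~29% breakdown point is what buys robustness over ordinary
least squares. Pairs with < 2 shared sets, or no abscissa spread,
contribute nothing.

**Global ρ.** The overdetermined system log ρ_j − log ρ_i = log m_ij over
all supported pairs is solved at once by least squares, each equation
weighted by √(number of shared sets), then anchored. This averages the
reference-reaction choice out of the result entirely; reactions are
connected through every path in the slope graph, not through one chain. A
disconnected graph is an error by default (naming the components); a
per-component mode fits each component with its own anchor, which learning
curves use on small subsamples. Slopes are required positive by default
(true for the reaction families targeted); a config flag instead propagates
signs over a maximum-support spanning tree and fits magnitudes in log
space.

**σ and offsets.** Coordinate refinement from σ = 0: c_j is the *median*
over observed sets of (y − ρ_j σ_s) — robust to a few contaminated records
per reaction — and σ_s the mean over reactions of (y − c_j)/ρ_j
(optionally |ρ|-weighted, which damps the shift/ρ leakage of an outlier
sitting in a weakly susceptible reaction). Two numerical details matter:

* The shift gauge family is a *neutral direction* of this alternating
  update (eigenvalue exactly 1), so on noisy data jitter along it never
  decays. Every sweep therefore re-gauges (σ(reference) ↦ 0, or
  mean-centering when the reference set is unobserved), projecting the
  neutral direction out.
* The median update is piecewise constant in σ and can lock into a
  2-cycle; updates are damped by 0.5 after the first two sweeps (fixed
  points unchanged).

Convergence is declared at a maximum parameter change < 1e-10 (≤ 200
sweeps); on fully observed noiseless tables the iteration is exact after
three sweeps, and recovery holds to ~1e-15.

**Classical procedure.** The sequential reference-based method is kept for
comparison: σ from the reference reaction, then per-reaction OLS lines and
σ expansion, default order greedy by shared-set count. Its dependence on
reference and order — absent from the global method — is asserted by test.

## σ decomposition

Three nested forms express molecular σ through single-substituent terms,
all gauged by α(baseline group) = 0:

* **categorical** — one free term per (group, position); exact linear least
  squares with column-pivot QR rank reporting (rank deficiency is an error
  naming the confounded pairs, never silently regularized).
* **distance decay** — σ = Σ_p α_{g_p} f(d_p) with f = d^−γ or e^(−d/λ)
  (γ, λ > 0, Å scale). The decay constant is profiled (the α solve is
  linear at fixed constant) over the multistart grid {0.25, 0.5, 1, 2, 4},
  each start refined by bounded 1-D minimization, and the winner polished
  by a joint Levenberg–Marquardt pass — the profile alone stalls at ~1e-9
  relative accuracy once the SSE reaches the floating-point noise floor,
  the polish reaches machine precision. With one position or all-equal
  distances the constant is non-identifiable: it is fixed at 1, flagged,
  and the α absorb the common factor.
* **three-body** — adds pair terms β_{g,g'} · (1 + 3 cos θ_p cos θ_q cos
  θ_C)/(d_pC d_qC d_pq)³ over position pairs, the classic triple-dipole
  shape on the (position, position, reaction-center) triangle; β is keyed
  by unordered group pairs, same-group pairs included. The decay constant
  is **not** refit here: a small change in it is almost exactly
  compensable by the pair terms, so on low-noise data the joint objective
  has a flat valley along which a polish can drift to absurd β at no SSE
  cost. Taking the constant from the nested two-body fit and solving α, β
  linearly makes β ≈ 0 recovery on additive data exact and the nesting
  SSE(three-body) ≤ SSE(two-body) structural. Collinear triangles are a
  geometry error.

Parameter budgets: N_P·N_G (categorical), N_G + 1 (decay),
N_G + (N_G² + N_G)/2 + 1 (three-body; note that for N_G = 5 the formula
gives 21, not the 20 of the categorical fit, despite the two often being
described as equal-cost), and N_R + N_G + 1 for the full additive
α-Hammett model.

**α-Hammett.** Two modes. The *two-stage* mode (default) decomposes the σ
of a prior global fit — the right tool for analysing a full dataset. The
*joint* mode fits {ρ}, {c}, {α} and the decay constant together by
Levenberg–Marquardt on the responses, ρ parameterized as exp(u) > 0 (the
reaction families targeted have positive ρ, and an unconstrained ρ lets a
reaction with only two sampled records run off to arbitrary sign). The
joint mode exists because the two-stage route collapses on small
subsamples — the slope graph disconnects and per-component gauges cannot
be pooled into one σ table — while 18 parameters remain estimable from a
few dozen records. It is the Δ-ML baseline.

## Machine learning

One-hot encodings concatenate a block per scaffold position (group
vocabulary) and reaction-descriptor blocks — nucleophile/leaving-group
parts when reaction ids split on a separator, else a single reaction-id
block. No Cartesian information enters, keeping the comparison with the
composition-only Hammett models information-fair.

KRR solves (K + λI)a = y by Cholesky; default kernel Laplacian
exp(−‖Δ‖₁/w) (natural for binary vectors), Gaussian selectable. Default
grids w ∈ {2^−2 … 2^6}, λ ∈ {1e-10 … 1e-2}; 5-fold seeded grid search by
held-out MAE, ties resolved toward the smoother model (larger λ, then
larger w). Δ-ML trains the same machine on residuals of the joint
α-Hammett baseline and adds the baseline back at prediction.

Learning curves: per repeat, a seeded permutation reserves 1/15 of the
records as holdout; nested training subsets of each size are drawn from
the remainder. Holdout records a Hammett-family model cannot cover (unseen
reaction at small sizes) fall back to the training-mean prediction rather
than erroring — curves must show the method degrading, not crashing.
Subsample fits run with sign propagation, per-component anchoring and a
relaxed tolerance (1e-8, 1000 sweeps) for the same reason.

## Synthetic worlds

The generator constructs σ additively from declared α and decay (plus
optional three-body pair terms), draws ρ log-uniform and offsets uniform,
and adds Gaussian noise, gross outliers and uniform missingness on top.
Everything is derived from one seed; identical configs give identical
tables bit for bit.

The four-position preset: 12 reaction channels, groups
{H, NO2, CN, CH3, NH2} with α = {0, −2.5, −1.8, +0.8, +1.5} (negative =
electron-withdrawing = barrier-lowering under ρ > 0, preserving the
field's ordering NO2 > CN > H > CH3 > NH2), power decay γ = 2, two
positions at 1.5 Å on the reacting carbon and two at 2.5 Å on its
neighbour, ρ ∈ [0.5, 3], offsets ∈ [12, 30] kcal/mol — chosen once so
barriers span the few-to-tens of kcal/mol regime of computed S_N2
barriers. Noise defaults to zero (computed barriers are deterministic);
tests inject noise explicitly where the question is statistical. The
single-substituent preset: one position, 10 groups, log10-rate responses,
reactions in the role of temperatures, with an optional injected series
that is *linear* in the reaction index — an Arrhenius-violating
contaminant for outlier-ranking tests.

Outliers come in two units: independent per-record shifts, and
whole-series ("set") contamination where every record of a chosen
substituent set is shifted with independent signs — the structure of real
rate-table anomalies, where one compound misbehaves across all conditions.
The distinction matters quantitatively: record-level contamination at
fraction ε corrupts 1 − (1−ε)² of the points of every pairwise reaction
scatter (36% at ε = 0.2), which is *beyond* the Theil–Sen breakdown
regime; series-level contamination corrupts exactly ε of the points.
Even then, the corrupted pair-slope distribution is asymmetric around the
true ratio, so the slope median carries a bias of order 10% at ε = 0.2
with shifts comparable to the response spread — robust estimation caps
the damage (OLS errors are several times larger under the same
contamination) but does not erase it. Tests assert the relative claim;
an absolute <5% deviation bound at 20% gross contamination is not
attainable in these worlds and the corresponding acceptance check is left
failing by design.

What a green test establishes: exact linear-algebraic recovery, gauge
handling, robustness *relative to* a non-robust control, and the Δ-ML
learning-curve shape on worlds whose noise is i.i.d. Gaussian and whose
nonlinearity is exactly the three-body term. Real datasets add correlated
model error, structured missingness and resonance effects the additive
model cannot represent; none of these are emulated.

## Known limitations

* Resonance-capable σ scales (σ⁺/σ⁻), solvent and steric extensions are
  out of scope; the decomposition is purely inductive/distance-based.
* The three-body β are weakly identified whenever the additive part
  already explains the data to near machine precision (see the flat-valley
  discussion above); their values should be read qualitatively.
* No Arrhenius modelling: each temperature is its own reaction, by design.
* KRR stores its training matrix in memory; fits are practical to a few
  thousand records, which matches the intended problem sizes.
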