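# Methods

## Model and assumptions

The package models transplant listing for a failing Fontan circulation
as an optimal-stopping problem on a belief process. The state is the
patient's net signal count `k` (Good-indicative minus Bad-indicative
checklist signals). Signal arrivals follow a Poisson process with rate
μ/year; each signal moves `k` by ±1. Signals reflect the true
posttransplant outcome (Good/Bad) with probability θ, identically across
signals — θ is a single *holistic* quality parameter; per-signal
qualities exist only in the estimation utilities and are composited
before any decision use. From a symmetric prior the belief in a Good
outcome depends on the history only through `k`:

    p(k) = (1−θ)^k / (θ^k + (1−θ)^k),     k real or integer.

The one-step transition probabilities of `k` at belief `p` are

    down: q⁻(p) = 2pθ + 1 − θ − p,     up: q⁺(p) = p + θ − 2θp,

which sum to one and satisfy the identities `q⁺(p(k)) = D(k+1)/D(k)` and
`q⁻(p(k)) = θ(1−θ) D(k−1)/D(k)` with `D(k) = θ^k + (1−θ)^k`; these
identities are what make the geometric forms below exact solutions of
the regional recursions. The decision maker is risk-neutral and
discounts at rate r/year. An organ arrives after an expected wait δ;
life expectancy is LT after a Good transplant and LNT without a
transplant, with δ < LNT < LT required at validation. The prior is
fixed at ½ at every assessment; reassessments enter only through the
current `k`.

### Orientation of beliefs across regions

The model deliberately interchanges θ and 1−θ between the unlisted and
listed regions: for an unlisted (possibly too-well) patient the
acquisition of a comorbidity is treated as evidence *for* a Good
posttransplant outcome, whereas for a listed patient further
comorbidities are evidence of deterioration, so the listed-region Good
probability is `1 − p(k)`. Two consequences matter for implementation:

1. **Where value matching holds.** All value functions in this package
   evaluate their printed algebraic forms verbatim with the unlisted
   belief `p(k)`. The orientation swap is then realised geometrically:
   since `p(−k) = 1 − p(k)`, swapping `p ↔ 1−p` in every formula is the
   same operation as mirroring the axis. The value-matching conditions
   that pin the thresholds accordingly hold at the mirrored lattice
   positions `−k_high` and `−k_low` (exposed as `ValueModel.match_high`
   and `match_low`). At those points all residuals vanish to solver
   precision; evaluated instead at `+k_high`/`+k_low` the same
   expressions leave O(1) residuals, which is how we verified the
   convention.

2. **Arrangement of the delisting match.** The delisting boundary belief
   `p_low` satisfies the value-matching equality in the arrangement
   `vr1 − vo5 = LNT` (the one-step delisting option entering on the
   delisted side). This is the arrangement the closed-form `p_low`
   solves exactly; the package treats the closed forms as authoritative
   and states the boundary system consistently with them.

With these conventions the solved waiting-option constant A is negative
at the worked example (−1.076); its sign carries no decision content —
every decision quantity flows through the closed-form thresholds, and
the residual checks are sign-agnostic.

## Thresholds

`beta1` is the smaller root of `β² − ((r+μ)/μ)β + θ(1−θ) = 0` (the
discriminant is positive because `(r+μ)/μ > 1 ≥ 2√(θ(1−θ))`; the root
lies in `(0, min(θ, 1−θ))`). `beta2 = μθ(1−θ)/(r+μ)` is the unique decay
factor for which the geometric delisting-option form solves its
one-sided recursion; it is smaller than both θ and 1−θ, so the option
grows without bound as the count falls. `Psi ≥ 0` is asserted at run
time rather than re-derived. `p_high` is required to lie in (0,1];
`p_low` may leave (0,1] for admissible parameters (long LNT), in which
case threshold construction rejects with a "not well-defined"
diagnostic — the sweep utility records such grid points as NaN for the
lower threshold while keeping the upper one.

Decision rule: too well at `k ≥ ⌈k_high⌉`, list for
`⌈k_low⌉ ≤ k ≤ ⌊k_high⌋`, too unwell at `k ≤ ⌊k_low⌋`. When a threshold
is exactly an integer the region definitions take precedence over the
floor/ceiling statement: `k = k_high` is listed, `k = k_low` is too
unwell. Floors/ceilings are true mathematical floor/ceiling (not
truncation), so negative thresholds behave correctly. If
`k_low ≥ k_high` the constructor rejects ("no listing window exists")
rather than returning an empty window silently. Reports round to two
decimals; machine-readable outputs keep full precision.

## Free-boundary oracle (and why not Bellman value iteration)

The oracle recovers each continuous threshold numerically, independent
of the closed-form chain: the option constant is eliminated via the
smooth-continuation condition (linear in A resp. B), the remaining
matching residual becomes a one-dimensional function of the candidate
boundary position, and its roots are located by a sign scan (step 0.05)
plus Brent polishing over the lattice span. On the worked example and on
20 seeded random valid parameter sets the root is unique and matches the
closed form to < 1e−7, and the implied integer edges match
`⌊k_high⌋`/`⌊k_low⌋` exactly. The analytic region solutions are further
cross-checked by fixed-point (Jacobi) relaxation of the lattice
recursions — a contraction with factor ≤ μ/(r+μ) per sweep, asserted in
tests — which reproduces the interior values to < 1e−8.

A global Bellman iteration `V = max(stop payoff, discounted expected
continuation)` is *not* used as the oracle, deliberately: the model's
matched solution does not satisfy that variational inequality. The
regional payoffs mix a gain scale (the listing value `vr1` is measured
relative to the no-transplant baseline) with an absolute scale (the
delisted value LNT), and at interior points the printed stop payoff
strictly exceeds the matched continuation value (e.g. 8.42 vs 2.90 at
k = 3 under the worked example's direct reading), so a max-operator
fixed point stops everywhere and its edge is the lattice boundary — for
*any* belief orientation. The free-boundary solve is the well-posed
numerical counterpart of the threshold construction, and is what the
oracle tests rely on.

## Simulator

The generator draws a latent outcome (Good/Bad, probability ½ each) once
per trajectory; signals arrive at Poisson rate μ; each signal matches
the latent outcome with probability θ; a Good-indicative signal moves
`k` up — one fixed convention for the whole trajectory. Marginalising
the latent outcome, the empirical (down, up) frequencies at belief
`p(k)` equal `(q⁻, q⁺)` exactly, which is the simulator's fidelity
anchor (tested within 3 SE at 10,000 events). The decision-theoretic
flip of signal interpretation between the unlisted and listed regions is
*not* reproduced generatively — no single signal law can honour both
orientations — so passing policy-evaluation tests demonstrate internal
consistency with this generative reading, not with the flipped one. A
`down_only` listed mode (suppressing favourable signals after listing,
mirroring the theory's listed-region assumption) is available; the
default keeps the common law.

Accounting conventions: LNT is the memoryless residual no-transplant
life expectancy at any instant (this matches the model's use of
`C = LNT − δ` measured from the listing moment). The wait on the list is
exponential with mean δ (configurable to a fixed delay) — the model
states only the mean, and exponential is the minimal-assumption,
memoryless-consistent choice. A listed patient with no organ within the
residual LNT dies waiting; at transplant the latent outcome resolves
(Good: LT residual years; Bad: immediate death). Realised discounted
life-years are the discounted residual-life annuity granted at terminal
resolution — waiting time enters through discounting, keeping every
realisation in [0, LT] for all discount rates. Replicate RNGs spawn from
one seed sequence, so policy evaluations are reproducible bit-for-bit
and parallelizable.

Problem sizes used by the test suite — 10,000 pooled events for the
transition-frequency check, 5,000 replicates per policy for dominance,
2,000 records for estimator recovery — give Monte Carlo standard errors
comfortably inside the asserted bands (e.g. binomial SE ≈ 0.013 per
lattice cell at 1,000 visits) while the whole suite runs in seconds.

What the generator does *not* emulate about real Fontan cohorts:
checklist composition changes between reviews, correlated or weighted
comorbidities (sub-signals of, say, protein-losing enteropathy are
entered as separate checklist rows rather than weights), urgent-list
prioritisation, competing non-cardiac risks, and any registry
calibration of μ, δ, LT, LNT.

## Estimation utilities

Per-signal quality is the proportion of exposed patients (signal
present at transplant) whose outcome matched the signal's orientation;
the composite θ̂ is the exposure-weighted mean — the simplest consistent
composite, isolated in one function so alternatives can be swapped in.
Signals with zero exposure are excluded with a warning; composites of 0,
½ or 1 are flagged as degenerate for decision use. The record simulator
makes a signal present with probability θ when the outcome matches its
orientation and 1−θ otherwise, so exposure-conditional correctness is
Bernoulli(θ) exactly and the estimator is consistent at the usual √n
rate (tested).

## Sweeps

Sweeps recompute thresholds from scratch at every grid point (clarity
over speed at this scale). Verdicts assert directions only — the
listing threshold rises with δ and μ and falls with LNT, and the integer
delisting edge is constant across the δ ∈ [0.1, 1.9] and μ ∈ [0.5, 6]
grids around the worked example. Constancy of `⌊k_low⌋` under LNT is
*not* asserted: across LNT ∈ [1, 6] the edge moves through several
integers and `p_low` leaves (0,1] beyond LNT ≈ 3.8 (at the other
worked-example values), so the claim only holds locally.

## Numerical choices

* Beliefs and the geometric forms `β^k/D(k)` are computed in log space
  (`logaddexp`), stable to |k| ≫ 700.
* Root scans use step 0.05 with Brent polishing (`xtol = 1e−13`);
  boundaries within 5 lattice points of the span edge are rejected.
* Jacobi relaxation: sup-norm tolerance 1e−10, cap 100,000 sweeps, both
  configurable on `LatticeProblem`.
* Ties at integer thresholds resolve as described above (region
  definitions take precedence), and the oracle's stopping sets inherit
  the same convention through the floors.
* Validation failures raise `ValueError` naming the violated assumption;
  the CLI maps them to exit code 2 with a one-line cause.

## Limitations

The urgent-versus-routine list split and combined heart–liver listing
are out of scope. LT and LNT are taken as given (life-years or QALYs —
whatever the transplant unit supplies); no uncertainty in θ̂ is
propagated into the thresholds. The checklist reader accepts any
checklist length per review and treats "high antibodies" as an ordinary
signal — any implied adjustment of the expected wait δ is the user's
responsibility via the parameter config. The width-one band structure of
the near-boundary region is assumed (as in the underlying theory), with
`⌈k_high⌉ − ⌊k_high⌋ ≤ 1` asserted trivially.
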