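# Methods

## Model and data-generating process

The package monitors a lifetime process whose batches are progressively
Type-II censored samples from the lower-truncated proportional-hazard-rate
family: survival Ḡ(x; μ, λ) = [F̄(x)/F̄(μ)]^λ for x ≥ μ, λ > 0, with an
absolutely continuous baseline survival F̄. The censoring scheme
r = (r₁,…,r_m) with n = m + Σ rⱼ fixes how many survivors are withdrawn at
each observed failure. Sampling uses the exponential-spacings construction:
with η_j = Σ_{k≥j} (1+r_k) units at risk before the j-th failure and
E₁…E_m iid standard exponentials, Y_j = Σ_{k≤j} E_k/(λη_k) are the
cumulative hazards of the progressively censored order statistics and
X_j = F̄⁻¹(F̄(μ)·e^{−Y_j}). The construction is exact and O(m); it exists
mainly for validation and for the raw-data monitoring entry point, because
everything else runs on the pivotal shortcut below.

Batch MLEs are closed-form: μ̂ = x₍₁₎ and
λ̂ = m·[−Σ (1+r_j) ln(F̄(x_j)/F̄(μ̂))]⁻¹ (m ≥ 2 required; a batch whose
observed times all coincide has no scale MLE and is rejected). In control,
Z₁ = F̄(μ̂)/F̄(μ₀) ~ Beta(nλ₀, 1) and Z₂ = 2mλ₀/λ̂ ~ χ²(2m−2),
independent, free of r and of the baseline. All simulation therefore draws
(F̄(μ̂), λ̂) = (F̄(μ)·B₁, 2mλ/B₂) directly; substituting shifted parameters
(F̄(μ₁), λ₁) gives the out-of-control sampling distribution. Shifts are
parameterized as δ₁ = λ₀ ln(F̄(μ₀)/F̄(μ₁)) and δ₂ = λ₀/λ₁, with (0, 1) the
in-control point.

## The four charts

* **EWMA-LR.** LRᵢ = m(d₂ − ln d₂ − 1) + d₁ with d₂ = λ₀/λ̂ᵢ,
  d₁ = nλ₀ ln(F̄(μ₀)/F̄(μ̂ᵢ)); LRᵢ = +∞ when μ̂ᵢ < μ₀ (the in-control
  lower endpoint is outside the estimated support). EWMA recursion
  ELᵢ = (1−γ)ELᵢ₋₁ + γLRᵢ from EL₀ = E[LR], which has no closed form as a
  start value in general but satisfies E[LR] = m(ln m − ψ(m−1)), free of n
  — the package estimates it by Monte Carlo and uses the closed form as a
  cross-check. The coefficient n (not Σ weights) on the d₁ term follows
  from −ln B₁ ~ Exp(nλ₀).
* **EWMA-Max-MLE.** Sᵢ = max(|Φ⁻¹(F_B(Z₁))|, |Φ⁻¹(F_χ²(Z₂))|); in control
  both transforms are standard normal, so E[S] = 2/√π = 1.1283791671
  (mean of the larger of two half-normals), used as the exact start value.
  The chart signals on EMᵢ > h; because S is a parameter-free function of
  the pivots, the calibrated limit depends on nothing but γ (observed:
  identical limits across all (n, m)).
* **EWMA-MD.** Manhattan distance
  MDᵢ = λ₀|ln(F̄(μ₀)/F̄(μ̂ᵢ))| + |λ₀/λ̂ᵢ − 1| between the estimated and
  in-control points in the (−λ₀ ln F̄(μ), λ₀/λ) plane. Its in-control mean
  has the closed form EMD₀ = 1/n + E|χ²₂ₘ₋₂ − 2m|/(2m); the Monte-Carlo
  start value is checked against it. The absolute-value form is the
  definition used throughout; a squared-form variant exists in circulation
  but does not match the tabulated EMD₀ values and is excluded.
* **WL.** Weighted log-likelihood ratio with weights w_{i,γ} = γ(1−γ)^{t−i}.
  The weighted MLEs are μ̃ₜ = min(μ̂₁,…,μ̂ₜ) and a closed-form λ̃ₜ;
  WLₜ = Wₜ[m(d₂ − ln d₂ − 1) + d₁] with Wₜ = 1 − (1−γ)ᵗ and d₁, d₂
  evaluated at the weighted MLEs; +∞ when μ̃ₜ < μ₀. The state is carried as
  two exponentially damped running sums (Σw·m/λ̂ᵢ and Σw·ln F̄(μ̂ᵢ)) plus
  the running maximum of F̄(μ̂ᵢ), making each update O(1) exactly — no
  refitting is needed when the running minimum changes, because μ̃ₜ enters
  λ̃ₜ only through Wₜ·ln F̄(μ̃ₜ). At t = 1, WL₁ = γ·LR₁. The chart has no
  start value; monitoring accumulates from the first batch.

Signals use strict inequality (statistic > h). An infinite LR/WL statistic
signals at that batch regardless of h: the EWMA recursion would otherwise
propagate +∞ forever, and an estimated support excluding μ₀ is
unambiguous evidence of a shift.

## Calibration

The control limit h is set by Monte-Carlo search to hit a target in-control
ARL (default 370, the usual false-alarm budget; M = 20 000 replications by
default). Zero-state run lengths are simulated in synchronous cohorts: all
live replications advance one batch per iteration, vectorizing the
statistic over the cohort while remaining distributionally identical to
one-at-a-time simulation. ARL is nondecreasing in h, so the search brackets
by doubling/halving and then bisects, accepting h when the achieved ARL is
within a relative tolerance (default 1% — a package choice; "close enough"
is not otherwise quantified). Two design choices bound the work:

* **Two-phase search.** A pilot bisection at min(M, 2000) replications
  localizes the bracket; the full-replication bisection then only evaluates
  limits whose ARL is near the target, where a 20 000-replication
  evaluation costs seconds. Within each phase every evaluation reuses the
  same seeded draws (common random numbers), so ARL(h) is a deterministic
  monotone function of h and the search is reproducible from the seed.
* **Search cap.** During the search, run lengths are truncated at 30× the
  target ARL. An on-target configuration hits that cap with probability
  ≈ e⁻³⁰, so the accepted ARL is unbiased at any practical tolerance,
  while a badly overshot trial limit costs bounded work (its truncated mean
  still orders correctly against the target). Outside the search, the
  default cap is 10⁶ with capped replications counted and reported (the
  ARL is then flagged as a lower bound).

Because the in-control statistic laws are parameter-free, limits calibrated
at the reference point (F̄(μ₀), λ₀) = (0.8, 1) are valid at any in-control
parameters with the same (n, m, γ) — this portability is tested.

## Numerical choices

* Survival probabilities are floored at 1e−300 before logs; probabilities
  entering Φ⁻¹ (and Z₁ before the Beta CDF) are clipped to
  [1e−12, 1−1e−12], keeping the Max-MLE statistic finite even when
  F̄(μ̂) > F̄(μ₀).
* The Beta(a, 1) CDF is evaluated as z^a and B₁ is drawn via U^{1/a}
  (the power distribution), avoiding the generic beta machinery in the hot
  loop; the χ² CDF goes through the regularized lower incomplete gamma.
* The log-likelihood drops the additive data-only constant (density and
  at-risk terms); it cancels in every ratio the package computes, and
  absolute log-likelihood values are reported up to that constant.
* The likelihood indicator is evaluated with the sup convention: the
  boundary μ = x₍₁₎ uses the finite branch (so the MLE attains the
  maximum); μ̂ ≥ μ₀, a measure-zero event in control, likewise takes the
  finite LR branch, which is continuous there.
* Ties among failure times are accepted (real data are rounded); only a
  batch with all m times identical is degenerate.
* Randomness is threaded explicitly as numpy Generators; nothing touches
  global random state. Calibration records (seed, reps, rl_cap).

## What the simulations emulate — and what they do not

The synthetic stream generator reproduces the study conditions used
throughout: pivotal batch draws at given (n, m), in-control reference
(0.8, 1), γ ∈ {0.05, 0.1}, ARL₀ = 370, M = 20 000, and sustained shifts
applied from the first monitored batch (zero-state). Real monitoring data
differ in ways the model does not capture: batch estimates assume the LTPHR
family with a *known* baseline and in-control parameters (Phase-I
estimation error is not modelled), shifts need not be sustained or start at
monitoring onset (steady-state ARL is out of scope), and recorded lifetimes
are rounded. Passing tests therefore certify the charts' behaviour under
the stated model, not robustness to model misspecification.

The mouse-lifetime example ships as printed in its source, including two
entries that break the sorted order of the conventional-environment table
("0.03100", "0.3364" — presumably typos); a cleaning flag re-sorts and a
helper reports the offenders. The gamma-uniform baseline
F̄(x) = Q(1.2809, x/(0.3902(1−x))) reproduces the fitted anchor
F̄(0.0364) = 0.9587, which fixes the otherwise ambiguous reading of the
incomplete-gamma argument; its shape/scale are taken as given, not refit.
The example's stated shift sizes round-trip from the printed parameters to
(0.0938, 2.3649) — δ₁ lands 5×10⁻⁵ away from the quoted 0.0939, consistent
with the source having used unrounded estimates.

## Problem sizes

Default test and acceptance runs use the design (n, m) = (5, 3), γ = 0.05:
start values at 4×10⁵ (tests) / 2×10⁶ (acceptance script) draws, limit
calibration and ARL evaluation at the reference M = 20 000, and property
checks at 2 000–10 000 replications — sizes chosen so the whole suite runs
on a laptop-class single core in a few minutes while keeping Monte-Carlo
standard errors a factor of a few below the tolerances tested.

## Known limitations

* No Phase-I machinery: (μ₀, λ₀) and the baseline are inputs.
* Zero-state ARL only; steady-state/conditional-delay metrics are not
  implemented.
* Progressive Type-II censoring only (no Type-I, hybrid, or adaptive
  variants).
* The WL chart's run-length distribution is strongly skewed in control
  (SDRL ≈ 2.4 × ARL at ARL₀ = 370); its ARL comparisons should be read
  with that in mind.
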