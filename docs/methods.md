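# Methods

## Model

The tipping element is a Markov decision process with states
S = {prosperous (p), degraded (d)} and actions A = {high (h), low (l)}.
Transitions and rewards are fixed by construction:

| from | action | to | probability | reward |
|------|--------|----|-------------|--------|
| p | h | p | 1 − δ | r_h |
| p | h | d | δ | 0 |
| p | l | p | 1 | r_l |
| d | l | p | ρ | 0 |
| d | l | d | 1 − ρ | 0 |
| d | h | d | 1 | 0 |

One time step is one year. The degraded state never pays; it can only be
left through the low-pressure recovery channel.

Policy values are *normalized* discounted sums,
`v_π(s) = (1−γ) E[Σ γ^t r_t | s_0 = s]`. The `(1−γ)` prefactor puts values
on the reward scale for every γ, so they can be compared directly with the
acceptability threshold `r_min`, and the γ → 1 limit is the long-run
average reward. All classification output depends on rewards only through
`r_l/r_h` and `r_min/r_h` (values are homogeneous of degree one in the
rewards; a tested property), so the model is effectively five-dimensional:
`(δ, ρ, γ, r_l/r_h, r_min/r_h)`, each in [0, 1].

## Value computation — three routes

1. **Closed forms** for the risky and cautious policies (the two
   undominated policies); valid for all γ ≤ 1 away from two measure-zero
   degenerate points (below).
2. **Bellman linear solve** `(I − γP^π) v = (1−γ) r^π` for any of the four
   deterministic policies at γ < 1; this is the independent oracle the
   closed forms are tested against (relative tolerance 1e-10 on 1000
   random parameter sets).
3. **Stationary-distribution evaluation** at γ = 1: `v = σ_π · r^π`, one
   scalar assigned to both states. The effective transition matrix is kept
   row-stochastic with the *from*-state in rows, orientation
   `P[i, j] = p(state_j | state_i)`; tests assert row sums and
   σP-invariance. For reducible chains (any off-diagonal transition
   probability zero — e.g. both trap policies, the cautious policy, or
   ρ = 0) the stationary distribution of the recurrent class reachable
   from the prosperous state is used and the result is flagged
   `reducible`/`degenerate` rather than raising, so hypercube sampling
   never aborts on boundary slices.

Degenerate denominators and their documented limits:

- risky at γ = 1 with δ = ρ = 0: `v_p = r_h, v_d = 0` (δ → 0 limit);
- cautious `v_d` at γ = 1 with ρ = 0: `v_d = 0` (γ → 1 limit at fixed
  ρ = 0; the degraded state is then absorbing and unpaid).

Both return a `degenerate` flag on the `StateValues` result.

## Classification

All comparisons are non-strict (≥), so points exactly on a boundary
surface classify as optimal/acceptable on both sides.

- **Optimality** is decided between risky and cautious only; the trap
  policies are statewise dominated (tested on random models). The verdict
  is state-independent — the sign of `v_r(d) − v_c(d)` equals that of
  `v_r(p) − v_c(p)` wherever ργ > 0, and the degraded values tie at
  ργ = 0 — so the prosperous state decides.
- **Sustainability** uses the states visited from a prosperous start: both
  states for the risky policy (it switches recurrently for δ, ρ > 0), only
  the prosperous state for the cautious one, i.e. `r_l ≥ r_min`.
- **Safety** follows the blanket rule: cautious always, risky never —
  including δ = 0, where the risky policy happens never to collapse. A
  reachability-based cross-check (`safe_by_reachability`,
  `sustainable_by_reachability`: recurrent class from a prosperous start)
  is provided and agrees everywhere except that measure-zero boundary,
  where it is deliberately left to disagree to expose the convention.

The five boundary hypersurfaces are exposed as signed polynomial residuals
(value comparisons multiplied through by the positive denominators), so
they are exact even at the degenerate points; positive sign ⇔ predicate
true. Roots along any single parameter are found by bisection to 1e-12 —
the residuals are continuous and monotone in each parameter on [0, 1], so
nothing fancier is warranted.

## Volume estimation

The eight-category volume report samples the unit hypercube uniformly
(`r_h` fixed at 1) and classifies *both* policies at every point with
weight 1/2 each. This weighting is the one under which the four safe
categories carry exactly the cautious-policy mass, the four unsafe ones
the risky-policy mass, and the safe-and-sustainable mass has the closed
form `0.5 · P(r_l ≥ r_min) = 1/4` — used as a sharp calibration of the
sampler.

Two samplers: a regular grid with endpoints included (boundary slices,
including γ = 1, are handled by the limit rules; their weight vanishes as
the grid refines) and seeded Monte Carlo with per-category standard errors
`sqrt((p/2 − p²)/n)` (per-point contributions are 0 or 1/2). Grid mode
iterates the first axis in chunks, so memory stays flat in resolution.
Default problem sizes: 21 points/axis (grid) for exploration, 51/axis for
the convergence-grade run, 10⁶ draws (MC). On a 51-point grid the
safe-and-just mass is exactly `(n+1)/(4n)` — the discretization of 1/4 —
which the tests assert.

## Case studies

Residence timescales map to per-year transition probabilities through the
geometric-distribution relation `⟨N⟩ = (1−p)/p ⇔ p = 1/(⟨N⟩+1)`. Presets:

| case | collapse ⟨N⟩ (y) | recovery ⟨N⟩ (y) | δ | ρ |
|------|------------------|-------------------|---|---|
| climate | 30–50 | 5000 | 1/51–1/31 | ≈ 2·10⁻⁴ |
| fisheries | 20 | 50 | 1/21 | 1/51 |
| farming | 100 | 300 | 1/101 | 1/301 |

The climate recovery timescale is only known to be multi-millennial; it is
encoded as 5000 years by default and is configurable. The climate collapse
range is carried as a δ-interval sampled uniformly on the probability
scale; point timescales give fixed δ, ρ.

Remaining parameters are sampled uniformly and independently from an
uncertainty box, by default γ ∈ [0.95, 0.99], r_l/r_h ∈ [0.3, 0.7],
r_min/r_h ∈ [0.1, 0.5] — a farsighted decision maker with broad reward and
threshold uncertainty. Under that box the probability that the cautious
policy is sustainable is the geometric closed form
`P(r_l ≥ r_min) = 1 − 0.5²/2 = 0.875` (two width-0.4 uniforms offset by
0.2), which the Monte-Carlo estimate must reproduce. Default 10⁵ draws
with a mandatory seed; probabilities are reported jointly over the box at
the case's (δ, ρ), with binomial standard errors.

## What the sampling emulates — and what it does not

Uniform sampling over the parameter hypercube stands for *ignorance*
about where a random agent–environment pair falls; it is not an empirical
distribution over real systems. The case-study timescales are
order-of-magnitude readings, not estimates from time series. Passing tests
therefore establish the internal mathematics (closed forms, boundaries,
volumes, conversions), and the qualitative case-study placements, but say
nothing about any particular real system's parameters.

## Known limitations

- Two states, two actions, deterministic policies only; no mixed policies
  (a deterministic optimal policy always exists here) and no multi-element
  interactions.
- The safe-operating-space definition has zero risk tolerance; alternative
  SOS definitions with tolerated collapse probability are out of scope.
- Figure-style region *data* (long-format sweep tables) are produced;
  rendered plots are not.
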