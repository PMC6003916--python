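# tippingmdp

Governance paradigms for a stylized human–environment tipping element,
modeled as a two-state, two-action Markov decision process.

An environment sits in a *prosperous* state (the only one that pays) or a
*degraded* one. Each year the managing agent exerts **high** or **low**
pressure: high pressure at the prosperous state pays `r_h` but triggers a
collapse with probability `δ`; low pressure pays `r_l ≤ r_h` and is
riskless. From the degraded state, only low pressure opens a recovery
channel with probability `ρ`. With discount factor `γ`, the normalized
value of a policy π is

    v_π(s) = (1 − γ) · E[ Σ_t γ^t r_t | s_0 = s ],

so values live on the reward scale. Of the four deterministic policies,
two matter: the **risky** policy (high at prosperous, low at degraded) and
the **cautious** policy (low everywhere); the other two trap the agent in
the degraded state and are dominated. Closed forms: for the risky policy

    v_r(p) = r_h (1−δ)(1−(1−ρ)γ) / (1−(1−δ−ρ)γ)
    v_r(d) = r_h (1−δ)ργ / (1−(1−δ−ρ)γ)

and for the cautious policy `v_c(p) = r_l`, `v_c(d) = ργ r_l / (1−(1−ρ)γ)`.
At `γ = 1` the value is the long-run average reward `σ_π · r^π` from the
stationary distribution of the policy-induced chain.

A (policy, parameters) pair is then classified under three paradigms:

- **optimal** — its value weakly dominates every other policy's in every state;
- **sustainable** — every state the agent eventually visits has value ≥ a
  normative threshold `r_min` (the risky policy must make even the degraded
  state acceptable; the cautious policy needs only `r_l ≥ r_min`);
- **safe** — the agent never leaves the safe operating space, identified
  with the prosperous state alone (the cautious policy always is; the risky
  one never is).

The package computes these values and labels analytically, exposes the five
boundary hypersurfaces between regimes, measures the parameter-space volume
of each of the eight (optimal, sustainable, safe) combinations over the
unit hypercube of `(δ, ρ, γ, r_l/r_h, r_min/r_h)`, and maps real tipping
elements (climate, fisheries, farming) into the classification via their
residence timescales, `p = 1/(⟨N⟩ + 1)` per year.

Intended for researchers in environmental governance, ecological economics
and sequential decision making who want a transparent, fully analytic
sandbox for the tension between welfare optimization, sustainability, and
safe-operating-space thinking.

## Worked example

Values and classification of the risky policy for a farsighted agent facing
a small collapse risk (`δ = 0.05, ρ = 0.2, γ = 0.9`, rewards at their
defaults `r_h = 1, r_l = 0.5, r_min = 0.3`):

```
$ tippingmdp classify --policy risky --delta 0.05 --rho 0.2 --gamma 0.9
{
  "config": { "command": "classify", "policy": "risky", "delta": 0.05,
              "rho": 0.2, "gamma": 0.9, "r_h": 1.0, "r_l": 0.5, "r_min": 0.3 },
  "label": "OSf",
  "optimal": true,
  "sustainable": true,
  "safe": false
}
```

`tippingmdp evaluate` with the same flags prints `v_p = 0.818461538462`
and `v_d = 0.526153846154`: both states clear the acceptability threshold
0.3, so the risky policy is sustainable and (beating `v_c(p) = 0.5`)
optimal — but it is not safe, because it will eventually visit the degraded
state. The label code packs the three flags as `O/o S/s F/f` (upper case =
true).

Sampling the whole parameter hypercube uniformly, classifying both policies
at every point with weight 1/2 each:

```
$ tippingmdp volumes --mode mc --n 100000 --seed 42 --out volumes.json
```

yields fractions whose top three categories are `osf` (0.268), `OSF`
(0.188) and `Osf` (0.165): the likeliest regime satisfies no paradigm, the
runner-up is the sweet spot where all three paradigms agree on the cautious
policy, and third comes the regime where welfare optimization endorses a
policy that is neither sustainable nor safe. The safe-and-just mass
(`OSF + oSF`, here 0.2505) equals `P(r_l ≥ r_min)/2 = 1/4` analytically —
about one in four random agent–environment pairs.

Other subcommands: `sweep` writes the long-format CSV behind the 2-D region
plots, `case --name {climate,fisheries,farming}` computes regime
probabilities under parameter uncertainty from residence timescales, and
`fixtures` exports the witness parameter points for all eight categories.
Every output embeds its generating config and seed; seeded runs are
byte-reproducible.

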