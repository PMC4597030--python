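# Methods

## Model

The package models a gene regulatory network as a **Boolean network with
perturbation (BNp)**.  Each of the `n` genes carries a binary expression
value; the *gene activity profile* `X(t) = (X_1, ..., X_n)` is encoded as
an integer state with gene 1 as the most significant bit, so for `n = 11`
the states in which gene 1 is ON are `{1024, ..., 2047}`.  A deterministic
rule `F` maps every state to its successor.  Throughout the synthetic
studies `F` is the **majority-vote rule** derived from a signed regulatory
matrix `R` (`R[i, j] ∈ {-1, 0, +1}`): gene i turns ON when
`Σ_j R[i,j] X_j > 0`, OFF when the sum is negative, and keeps its value on
a tie.

Perturbation makes the dynamics stochastic: at each step every gene flips
independently with probability `p` (default `p = 0.001`); when no gene
flips, `F` is applied.  This yields an ergodic Markov chain on `2^n`
states whose transition matrix is

    P[x, y] = (1 - p)^n [y = F(x)] + p^H(x,y) (1 - p)^(n - H(x,y)) [H(x,y) ≥ 1],

with `H` the Hamming distance.  The chain's unique steady-state
distribution (SSD) `π` summarises the long-run phenotype; the mass `π_U`
on the *undesirable* states `U` (target gene, by convention gene 1, ON) is
the quantity interventions try to reduce.

**Assumptions.** Synchronous updates; a single target gene defining `U`;
`0 < p < 1` (ergodicity); uncertainty restricted to the signs of known
regulations.

## Structural interventions

A single-state rewiring `(u, v)` sets `F(u) = v` and leaves every other
transition alone; only two TPM entries change.  The post-intervention SSD
has a closed form in the fundamental matrix `Z = (I - P + e π^T)^{-1}`
(the identity here is `2^n`-dimensional):

    π̃_i(u,v) = π_i + (1-p)^n π_u (z_vi - z_wi) / (1 - (1-p)^n (z_vu - z_wu)),

with `w = F(u)`.  The intervention error `ξ(u, v)` is the undesirable mass
of `π̃`.  The optimal intervention minimises `ξ` over all `2^n × 2^n`
pairs; the no-op `(u, F(u))` is in the search space, so the optimum never
exceeds `π_U`.  *Controllability* is the percentage drop
`Δ = (π_U - π̃_U)/π_U × 100` under the optimal intervention.

Implementation notes: the whole `2^n × 2^n` error table is evaluated at
once using the undesirable column sums `S_v = Σ_{i∈U} z_vi`, batched over
the uncertainty class with stacked LAPACK solves.  Pairs whose closed-form
denominator is within `1e-12` of zero are marked infeasible (`+inf`) and
skipped by every argmin rather than aborting the search.  The SSD is
obtained by a direct linear solve (balance equations with one row replaced
by normalisation), which is deterministic and exact to solver precision; a
residual above `1e-8` raises instead of silently returning.

## MOCU-based experimental design

Uncertainty is a set of `k` regulations whose sign `θ_i ∈ {-1, +1}` is
unknown, with independent (default uniform) priors; the class `Θ` contains
`2^k` concrete networks.  The **intrinsically Bayesian robust (IBR)**
intervention minimises the prior-expected error.  The **mean objective
cost of uncertainty**

    M(Θ) = E_θ[ ξ_θ(ψ_IBR(Θ)) - ξ_θ(ψ(θ)) ]  ≥ 0

is the expected price of not knowing `θ`.  Experiment `E_i` reveals `θ_i`
exactly; the design criterion is the expected remaining MOCU
`M(Θ, i) = E_{θ_i}[ M(Θ_{i,θ_i}) ]`, and the optimal experiment attains
its minimum.  Because each member's error table is cached, robust
interventions for every conditional class are weighted reductions of the
same tables — no additional chain computations are needed.

Tie-breaking is deterministic everywhere: lexicographically smallest
`(u, v)` for interventions, lowest index for experiments, smallest set for
deletions.  Class enumeration is capped (default `2^12` members) with a
capacity error, since the method is exponential in `k` by nature.

## Approximate design via network reduction

Deleting gene g collapses state pairs that differ only in gene g; the
collapsed state inherits the rule of the parent with *strictly* larger
steady-state probability (ties fall to the 0-parent, mirroring the strict
inequality in the collapsing rule).  Deleting several genes applies the
single-gene collapse sequentially in the given order, recomputing the
current SSD between steps — the single-gene rule is recovered exactly for
one deletion.  An intervention found on the reduced network is **induced**
back by completing the deleted bits with the completion of maximal SSD
(maximal *expected* SSD for robust interventions, conditioned on the
remaining class in question); exact ties prefer 1-bits, which reproduces
the `≥` branch of the single-gene completion rule for one deleted gene.

The **deletion cost** of a candidate set g is the total expected error of
the induced robust interventions over all conditional classes,

    c(g) = Σ_i E_{θ_i} E_{θ|θ_i}[ ξ_θ(ψ_IBR^ind(Θ_{i,θ_i}; g)) ].

Because the exact robust intervention is a true argmin, the induced robust
intervention can never beat it on average, so this surrogate ranks
candidates identically to the ranking-disruption form
`Σ_i |M^g(Θ,i) - M(Θ,i)|`; both are implemented and their argmin
equivalence is asserted in tests.  The approximate design deletes the
minimum-cost set and ranks experiments by expected remaining MOCU with
*both* the robust and the per-network optimal interventions replaced by
induced ones.

## CoD-based search-space pruning

The coefficient of determination of target `Y` given predictor set `X`,

    CoD_X(Y) = (ε_Y - ε_{X,Y}) / ε_Y ∈ [0, 1],

measures the relative reduction in optimal prediction error.  Genes whose
expected CoD (over the class prior) with the target is large are poor
deletion candidates and are excluded from the cost search: all 3-gene
predictor combinations are ranked by expected CoD, and the exclusion set
is filled by walking that ranking, taking each combination's unseen genes
in descending order of expected individual CoD.  The distribution behind
the error terms is a genuine modelling choice — the implementation reads
the joint law of `(X, Y)` off the same state under the network's SSD,
which is intrinsic to the model and needs no data.  A transition-based law
(predictors at `t`, target at `t+1`) or an empirical law are plausible
alternatives; a degenerate target (`ε_Y = 0`) receives CoD 0, so a
constant gene never drives exclusion.

## Synthetic-network study

The generator emulates the evaluation protocol: each gene receives exactly
3 distinct randomly chosen predictors (no self-loops), each activating or
suppressive with probability 1/2; `k` regulations are drawn uniformly
without replacement and their signs hidden; `p = 0.001`; target gene 1.
The hidden true signs `μ` score a design by the gain

    ρ = ξ_μ(ψ_IBR(Θ_rnd, μ_rnd)) - ξ_μ(ψ_IBR(Θ_i*, μ_i*))

of the chosen experiment over a uniformly random one, both followed by the
exact robust intervention of the revealed class (the induced-robust
variant exists for networks too large for exact design).  Sequential
designs repeat choose–conduct–measure until the class is a singleton, at
which point the gain is zero by construction.  All randomness flows from
one master seed through named substreams (topology/signs, uncertain
positions, random-experiment baseline), making studies bitwise
reproducible.

The analytic computational gain `λ = 2^{3p} / C(n - s - 1, p)` compares
the exact and approximate methods' operation counts when deleting `p`
genes after excluding `s`; it is hardware-free.

**What the generator does not emulate.**  Random majority-vote networks
are frequently barely controllable (interventions hardly move their SSD),
which compresses gains toward zero — the study therefore also stratifies
by controllability.  Real regulatory networks have hub structure,
autoregulation and non-majority logic; passing the synthetic studies shows
the design machinery is correct under the stated generative conditions,
not that the gains transfer quantitatively to any real pathway.

## Problem sizes and tolerances

Studies run at `n = 7` genes with `k ∈ {2, 4, 5}` uncertain regulations:
3000 trials for the k=5 gain estimates and 2000 per agreement percentage
in the reproduction script, 2000/1500/1500 in the test suite (the
original-scale protocol is 50,000 trials per configuration; at 3000 trials
the Monte-Carlo standard error of a mean gain is ≈ 0.003 given the
heavy-tailed gain distribution, sd ≈ 0.18).  Closed-form SSDs are checked
against direct recomputation to `1e-8`; steady-state residuals to
`1e-10`; MOCU identities to `1e-10`–`1e-12`.

## Known limitations

* Exhaustive enumeration in both `k` (class size `2^k`) and `n` (state
  space `2^n`) limits exact design to roughly `n ≤ 11` on commodity
  hardware; the approximate path extends this but still enumerates the
  class.
* Experiments are assumed to reveal a parameter exactly and noiselessly.
* Only sign-uncertainty over known regulation sites is modelled, not
  uncertain topology.
* Only single-state structural interventions are supported; dynamical
  (external control) interventions are out of scope.
* Multi-gene reduction order is a documented convention (ascending gene
  order, per-step SSDs); other collapse orders are legal and can produce
  different reduced rules.
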