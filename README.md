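# mocu-design

Optimal and computationally efficient experimental design for uncertain
gene regulatory networks, modelled as Boolean networks with perturbation
(BNp).

## The problem

Regulatory network models inferred from data are uncertain: for some
regulations we may not even know whether they activate or suppress their
target.  When the point of the model is to derive a therapeutic
intervention, not all uncertainty matters equally — what matters is the
uncertainty that degrades the intervention.  Given a limited experimental
budget, which regulation should be pinned down first?

The package answers this with the **mean objective cost of uncertainty
(MOCU)**.  A network with uncertainty vector `θ` (the unknown regulation
signs) has an optimal structural intervention `ψ(θ)`; under a prior over
`θ`, the intrinsically Bayesian robust intervention `ψ_IBR` minimises the
expected error.  MOCU is the expected excess error of acting robustly:

    M(Θ) = E_θ[ ξ_θ(ψ_IBR(Θ)) − ξ_θ(ψ(θ)) ],

where `ξ_θ(ψ)` is the steady-state probability mass of undesirable states
(target gene up-regulated) after applying `ψ`.  Experiment `E_i` reveals
`θ_i`; the experiment worth doing first minimises the **expected remaining
MOCU** `M(Θ, i) = E_{θ_i}[ M(Θ_{i,θ_i}) ]`.

Exact design needs optimal interventions for every network in the class —
`O(l^k · 2^{3n})`.  The package also implements an **approximate design**:
delete genes (SSD-guided state collapsing) chosen by a cost function that
measures how little the deletion disturbs the experiment ranking, design
interventions on the reduced networks, and *induce* them back to the full
network.  A coefficient-of-determination (CoD) step can prune the deletion
search space first.  The computational gain is
`λ = 2^{3p} / C(n−s−1, p)` for `p` deleted and `s` excluded genes.

Intended users: computational systems-biology researchers studying
objective-based uncertainty quantification, network intervention and
experimental design on rule-based network models.

## Worked example

```python
import numpy as np
from mocu_design import ExperimentDesign, UncertaintyClass, generate_random_network
from mocu_design.evaluation import sample_uncertain_positions

# a random 7-gene majority-vote network, 3 signed predictors per gene,
# with the signs of four of its regulations hidden
ss = np.random.SeedSequence(4)
s_net, s_pos = ss.spawn(2)
R = generate_random_network(7, rng=np.random.default_rng(s_net))
positions = sample_uncertain_positions(R, 4, np.random.default_rng(s_pos))
uc = UncertaintyClass(R, positions, p=0.001)

res = ExperimentDesign(uc).fit(method="approximate", n_delete=1)
print(res.summary())
```

```
MOCU experimental design results
========================================
method:              approximate
genes (n):           7
uncertain params (k): 4
MOCU of full class:  0.420716
excluded genes (s):  -
deleted genes (p):   (3,)

experiment position  expected_remaining_mocu selected
        E1   (5, 2)                 0.283500         
        E2   (6, 4)                 0.262958        *
        E3   (7, 1)                 0.420477         
        E4   (7, 5)                 0.420477         

selected experiment: E2
```

Reading the output: before any experiment, acting robustly instead of
knowing the true network costs an expected 0.42 of undesirable
steady-state mass.  The scores column says how much of that cost is
expected to remain after each candidate experiment: revealing the sign of
the regulation of gene 6 by gene 4 (experiment E2) leaves the least, so it
should be conducted first; pinning down either regulation of gene 7 would
barely help.  The ranking here was produced by the approximate method:
gene 3 had the minimum deletion cost, so interventions were designed on
the reduced 6-gene networks and induced back to the full state space.
With `method="optimal"` the exact ranking is computed instead; on this
example it selects E2 as well.

The same runs from the shell:

```sh
mocud generate --n 7 --k 4 --seed 1 --out net.json
mocud design --network net.json --method approx --delete 1 --out report.json
mocud evaluate --config study.json --out-prefix study
```

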