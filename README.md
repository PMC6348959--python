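# traitlink

Correlated evolution of two binary characters on a rooted phylogeny, built
around the question of whether **riparian habitat** and **narrowly
lanceolate leaf shape** evolve together in *Aster* (Asteraceae).  The
package is for comparative biologists who have a rooted tree with branch
lengths, per-taxon habitat information, and either leaf measurements or a
precomputed leaf-shape index, and who want the full battery of
discrete-character correlation analyses with reproducible seeds and
machine-readable reports.

## The model

Each taxon carries two binary characters: habitat (0 = non-riparian,
1 = riparian, under a *narrow* or *broad* definition of riparian) and leaf
shape (1 = "narrowly lanceolate", defined as a species-mean width/length
ratio ≤ 0.15).  The pair is one of four combined states

    1 = (0,0)   2 = (0,1)   3 = (1,0)   4 = (1,1)      (aliases A–D)

evolving along the tree as a continuous-time Markov chain.  The
**dependent** model has eight rates q12, q13, q21, q24, q31, q34, q42, q43
(simultaneous changes of both traits are forbidden, so Q₁₄ = Q₄₁ = Q₂₃ =
Q₃₂ = 0); each trait's rate may depend on the current state of the other
trait.  The **independent** model is the nested 4-parameter special case
q13 = q24 = α₁, q31 = q42 = β₁, q12 = q34 = α₂, q21 = q43 = β₂.

Tip-data likelihoods use Felsenstein pruning over the four states with
P(t) = exp(Qt).  Model comparison is by

* maximum likelihood: LR = 2(ln L_dep − ln L_indep), χ² with df 4
  (df 1 for single-parameter restrictions), or
* Bayes factors: log BF = 2(ln m_dep − ln m_indep) from stepping-stone
  marginal likelihoods, graded ≥2 positive / ≥5 strong / ≥10 very strong.

Restriction tests fix one rate at zero or equate a rate pair
(temporal-order and contingent-change contrasts: q12 vs q13, q13 vs q24,
q12 vs q34), and a parsimony counter reports the minimum number of
independent origins of a character.

## Worked example

```python
from traitlink import (simulate_yule_tree, simulate_traits, correlation_test,
                       count_min_transitions, MLConfig)
from traitlink.ctmc import DependentRates

tree = simulate_yule_tree(n_tips=300, birth_rate=1.0, seed=1)
truth = DependentRates(q12=0.15, q13=0.05, q21=0.15, q24=0.5,
                       q31=0.1, q34=0.3, q42=0.1, q43=0.1)   # q24 = 10·q13
traits = simulate_traits(tree, truth, root=1, seed=2)

rep = correlation_test(tree, traits, "ml",
                       MLConfig(n_tries=64, n_repeats=1, refine_top=2, seed=3))
print(f"LR={rep.statistic:.2f} df={rep.df} p={rep.p_value:.2g}")
print(f"q13_hat={rep.rates_alt['q13']:.3f}  q24_hat={rep.rates_alt['q24']:.3f}")
print("min origins of narrow leaves:",
      count_min_transitions(tree, traits.character('leaf')).min_changes)
```

prints

```
LR=29.45 df=4 p=6.3e-06
q13_hat=0.068  q24_hat=0.431
min origins of narrow leaves: 38
```

The likelihood-ratio test decisively rejects independent evolution of the
two characters on data generated with dependence, the fitted rates recover
the simulated asymmetry (the habitat shift into riparian conditions is an
order of magnitude faster in narrow-leaved lineages, q̂24 ≫ q̂13 — the
preadaptation signature), and the narrow-leaf state changed state at least
38 times on this simulated tree — scattered origins typical of convergent
evolution.

The same analyses run from the shell:

```bash
traitlink simulate --scenario preadaptation --n-tips 100 --seed 7 -o fx/
traitlink run --tree fx/preadaptation.nwk --traits fx/preadaptation_traits.csv \
              --definitions broad --methods ml -o out/
```

`analysis/01_make_fixtures.py` … `06_validation_studies.py` are the
numbered drivers of the full study on synthetic data; each states what it
found and writes its tables under `results/`.

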