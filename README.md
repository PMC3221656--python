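# hbcount

Hierarchical Bayesian analysis of ecological count data — choice and
preference experiments in particular — with MCMC estimation, DIC model
selection, and the classical rank-test comparators (Friedman, Quade,
arcsine-√ ANOVA) used to benchmark them.

## The problem

Many experiments in ecology, behavior, and evolution produce a
replicate-by-choice table of counts: each of *J* replicates (a female
butterfly in an oviposition arena, a cage, a feeding station) distributes
*n<sub>j</sub>* events (eggs laid, visits, deaths) across *K* choices.
Conventional analyses — paired *t*-tests, ANOVA on transformed
proportions, Friedman/Quade rank tests — test whether choices differ but
never estimate the quantity of actual interest: the strength of
preference at the individual and population level, with its uncertainty.

`hbcount` fits the hierarchical model

- **x**<sub>j</sub> ~ Multinomial(n<sub>j</sub>, **p**<sub>j</sub>) — each
  replicate has its own preference vector **p**<sub>j</sub>;
- **p**<sub>j</sub> ~ Dirichlet(*w* **q**) — individual preferences are
  drawn from a population Dirichlet whose parameter is decomposed into the
  mean preference **q** (a simplex vector) and a scalar concentration *w*
  that is inversely proportional to among-individual variance;
- hyperpriors: **q** ~ Dirichlet(1, …, 1), *w* ~ Uniform(0, *u*).

For *K* = 2 this reduces to a beta-binomial model. A
Metropolis-within-Gibbs sampler estimates all levels simultaneously:
individual rows have conjugate Dirichlet(**x**<sub>j</sub> + *w* **q**)
full conditionals (exact Gibbs draws); **q** and *w* are updated by
Metropolis–Hastings. Competing models — equal preference vs free
preference, and schemes that group populations into blocks sharing
(**q**, *w*) — are compared by DIC, with the deviance defined as −2 log
of (likelihood × conditional prior):

> DIC = D̄ + p<sub>D</sub>,  p<sub>D</sub> = D̄ − D(θ̄).

A built-in simulation study quantifies calibration under the null of no
preference: classical tests give uniform p-values, while the ΔDIC between
the equal- and free-preference models has a null 95% quantile near 8 —
considerably more than the conventional 2-unit rule — so DIC comparisons
for this model should be read conservatively.

## Worked example

Twelve females of an alpine population in arenas with three host plants
(`alpine.csv`, first column replicate IDs, header of choice labels):

```
replicate,astragalus,lotus,medicago
r1,27,5,0
r2,13,3,4
...
r12,23,11,3
```

```sh
hbcount fit --counts alpine.csv --out alpine_fit \
        --steps 40000 --burnin 10000 --seed 1
```

prints

```
astragalus: 0.73 (0.68, 0.78)
lotus: 0.17 (0.13, 0.22)
medicago: 0.09 (0.06, 0.13)
w: 502 (44, 974)  DIC: -7.18 (pD = 29.46)
```

i.e. the population-level preference for *Astragalus* is 0.73 with a 95%
equal-tail credible interval of (0.68, 0.78); the large posterior *w*
says individuals are homogeneous around that mean. The output directory
holds the full trace (`chain.tsv`), the summary table, pairwise
exceedance probabilities (`pairwise.tsv` — here P(preference for lotus ≥
preference for astragalus) = 0.00 and P(medicago ≥ lotus) = 0.002, a
Bayesian analogue of post-hoc tests), DIC, and a `run_config.json` echo
that reproduces the run byte-for-byte.

Is there any preference at all?

```sh
hbcount compare --counts alpine.csv --out alpine_cmp --steps 8000 --burnin 2000 --seed 1
# constrained DIC = 87.90, unconstrained DIC = -9.26
# delta DIC = 97.16 (positive favors the unconstrained model)
```

ΔDIC = 97 dwarfs the null 95% quantile (~8): clear evidence for a
preference hierarchy. Other subcommands: `group` ranks population
grouping schemes given TOML files like `groups = [["CP","MR"],["GV"]]`;
`classic` runs the Friedman/Quade/ANOVA comparators; `simulate` and
`calibrate` drive the synthetic-data studies. The same operations are
available as library functions (`run_chain`, `summarize`,
`pairwise_probabilities`, `compute_dic`, `compare_constrained`,
`fit_grouped`, `run_null_calibration`, …).

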