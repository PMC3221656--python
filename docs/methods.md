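# Methods

## Model

Data are a J×K table of non-negative integer counts **x**: rows are
replicates (individual females, arenas, cages — the lowest hierarchical
level the experiment identifies), columns are choices. Row totals
**n** may vary freely; replicates with a zero total are retained with a
warning (their posterior preference equals the population-level
conditional prior) rather than silently dropped.

The likelihood is a product of J multinomials, each with its own
probability vector **p**_j — individual preference. The **p**_j are
exchangeable draws from a population Dirichlet whose parameter is
factored as α = w·**q**:

* **q** — population mean preference, a point on the K-simplex;
* w — a scalar concentration, inversely proportional to
  among-individual variance (component variance q_k(1−q_k)/(w+1)).
  Large w: homogeneous individuals. Small w: polarized individuals —
  a population mean of 0.5 on two choices can mean "everyone is
  indifferent" (large w) or "half strongly prefer each" (small w), and
  the model distinguishes these.

Hyperpriors: **q** ~ Dirichlet(1,…,1) (uninformative; configurable),
w ~ Uniform(0, u). There is no canonical choice of u; the package
default is u = 1000, far above any concentration identifiable from tens
of replicates, and configurable. For K = 2 the model is exactly
beta-binomial; the test suite exploits this (see below). All densities
are computed in natural-log space; the multinomial coefficient is
included in the likelihood (it cancels in MCMC acceptance ratios but
matters for deviance comparability).

A caution that the worked example in the README illustrates: when the
data look homogeneous (individual counts all consistent with one shared
**p**), the marginal likelihood of w flattens as w → ∞ and the posterior
of w fills the prior's right tail up to u. Posterior summaries of w then
depend on u and should be read as "w is large" rather than as a point
estimate. **q** is unaffected.

## MCMC

Each sweep updates three blocks; information flows up and down the
hierarchy:

1. **Individual rows (Gibbs).** Conjugacy of multinomial and Dirichlet
   gives the exact full conditional p_j | x_j, q, w ~
   Dirichlet(x_j + w q). Rows are drawn exactly (gamma draws,
   normalized), so this block always accepts.
2. **Population mean (MH).** Proposal q′ ~ Dirichlet(δ·q) centred at the
   current value (δ = `q_proposal_scale`, default 100, larger = smaller
   steps), accepted with the Hastings correction for the asymmetric
   proposal. The target is the conditional prior of all rows times the
   Dirichlet hyperprior.
3. **Concentration (MH).** Random walk on log w with standard deviation
   `w_proposal_sd` (default 0.3), Jacobian-corrected; proposals ≥ u are
   rejected outright.

Defaults: burnin 10000 sweeps, 40000 recorded, thinning 1. The
constrained (equal-preference) model fixes **q** = (1/K,…,1/K) and skips
block 2. Initialization is data-driven and always interior:
p_j = (x_j+1)/(n_j+K), q = renormalized mean of the initial rows,
w = K. Chains are bit-reproducible given (data, prior, config, seed).

Grouped models (populations constrained to share preference parameters)
run the same sweep over several blocks of rows sharing one **q**, with w
either shared (default — the simplest reading of "same preference
parameters") or per-population (`share_w=False`). A grouping scheme is a
partition of populations; its DIC is the sum over groups, since groups
are fitted independently.

Implementation note: `run_chain` uses a fused single-block kernel
(cached log-gamma terms, batched `gammaln` calls) because the
calibration studies run millions of sweeps; the public per-step
operations (`gibbs_update_individuals`, `mh_update_q`, `mh_update_w`)
implement the identical updates and are what the unit tests exercise
directly. One consequence of vectorized gamma sampling is that choice-
column relabelling is equivariant only distributionally, not bit-wise:
rejection sampling consumes a data-dependent number of uniforms, so
permuting columns re-aligns the stream. The test suite checks
equivariance of posterior means within Monte-Carlo error.

### Sampler validation

Three independent oracles back the sampler:

* the Gibbs block against analytic Dirichlet/Beta moments and a
  Kolmogorov–Smirnov test at 10^5 draws;
* each MH block against a grid-normalized version of its own target
  density (max ECDF deviation < 0.02 over tens of thousands of updates);
* the whole chain, in the K = 2 case, against two-dimensional quadrature
  of the exact p-integrated posterior — the product of beta-binomial
  (Dirichlet-multinomial) marginals — which matches posterior means of
  both q and w to ~3 decimals.

## Posterior summaries

Credible intervals are equal-tail empirical quantiles by default
(reproducible without density estimation); shortest-interval HPD is
available behind a flag. Pairwise "significance" between choices a and b
is the fraction of stored draws with q_a > q_b; exactly tied draws (a
measure-zero event for the continuous sampler) count toward neither
side. No multiplicity correction is applied across the K(K−1)/2 pairs;
none is conventional for this analysis, and the report documents the
raw exceedance fractions.

## DIC

Deviance is D = −2 log(likelihood × conditional prior); hyperpriors are
excluded by definition. D̄ averages D over stored draws; D(θ̄) evaluates
D at the posterior means of all parameters, with mean preference rows
and mean **q** renormalized onto the simplex (stored-precision means can
drift off it); p_D = D̄ − D(θ̄) and DIC = D̄ + p_D hold exactly by
construction. Because the conditional prior is a density that can exceed
one, deviance and DIC can be negative — strongly concentrated
preferences with large w routinely produce large negative DICs.

ΔDIC between the constrained and unconstrained model is reported as
DIC(constrained) − DIC(unconstrained): positive favors the model in
which preference differs among choices.

## Simulation studies and what they show

The null design generates, per dataset, J = 20 replicates of K = 3
choices; totals are continuous U(5, 40) rounded to the nearest integer
(literal reading of the design; endpoints get half weight, and a
discrete-uniform mode exists); individual preferences come from the flat
Dirichlet(1,1,1) — a population with no preference. 1000 datasets are
used for classical-test calibration.

* **Classical calibration.** Friedman, Quade (with replicate-total block
  weights), and replicate-blocked arcsine-√ ANOVA all give approximately
  uniform null p-values with 5% quantiles near 0.05. The unblocked
  one-way ANOVA layout, by contrast, is conservative (5% quantile
  ≈ 0.01) because proportions within a replicate sum to one and the
  negative dependence inflates the error term — hence the blocked
  default.
* **ΔDIC calibration.** Fitting both hierarchical models to each of 200
  null datasets (shortened chains: burnin 2000, 8000 recorded sweeps —
  two MCMC fits per dataset make full-length chains a cluster-scale
  rather than desk-scale default; a flag restores 10000/40000) gives a
  null ΔDIC 95% quantile near 8. Selecting the free-preference model
  whenever ΔDIC > 2 would therefore favor over-parameterized models far
  more than 5% of the time; the package's ranking report says so.
* **Recovery.** 100 simulate-fit cycles at q = (0.6, 0.3, 0.1), w = 10,
  J = 50 give ~95% empirical coverage of the 95% intervals for every
  q_k and posterior-mean bias below 0.03 — the calibration expected of
  Bayesian intervals under the true model.
* **Model-selection direction.** With strong simulated preference
  (q = (0.8, 0.15, 0.05), w = 20, J = 20) the unconstrained model's DIC
  is lower in ≥95/100 datasets.

A directional claim that does **not** hold under these conditions: for
two populations simulated with identical (q, w) (q = (0.5, 0.3, 0.2),
w = 10, J = 15 each), the merged grouping scheme beats the split scheme
only in a minority (~30/100) of datasets. This is the same
over-parameterization bias quantified by the ΔDIC calibration, seen from
the other side: at this deviance focus (conditioning on the individual
rows), the split model re-centres each subgroup's Dirichlet on its own
sample and re-estimates w upward, lowering mean deviance by more than
the p_D penalty. The grouped sampler itself is verified (it agrees with
the equivalent pooled single-table fit to within Monte-Carlo error), and
the corresponding test is retained, failing, as an honest record. DIC
rankings of grouping schemes on real data should be interpreted with
this bias in mind.

What the generator does not emulate: real experiments have unbalanced
replicate counts across populations, overdispersion beyond the Dirichlet
(e.g. day effects), informative missingness (females that lay nothing
for reasons correlated with preference), and counts that are not
conditionally multinomial (egg clustering). Passing calibration here
shows the machinery is correct under the stated model, not that the
model fits any particular dataset.

## Numerical choices and edge cases

* Gamma draws are clipped at the smallest positive double before
  normalization so preference rows stay strictly interior.
* Simplex types require row sums within 1e-10 of one and strictly
  positive entries; boundary points are rejected at construction, so
  log-densities are always finite.
* Rank tests use midranks for ties throughout. The fully tied
  (all-constant) table yields statistic 0 and p = 1 (with a warning from
  the Quade test); perfect cross-replicate agreement in the Quade test
  yields the exact most-extreme p-value (1/K!)^(J−1).
* Chain files store float64 values with 17 significant digits, so
  write→read round-trips are bit-exact.
* Problem sizes for the built-in studies (200 DIC datasets, 100 recovery
  and direction repeats, shortened chains as listed above) were chosen
  as desk-scale defaults that keep Monte-Carlo error comfortably inside
  the tolerances being checked; all are configurable.
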