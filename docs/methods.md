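# Methods

`troposse` implements a complete macroevolutionary analysis pipeline for
state-dependent diversification on phylogenies, exercisable end to end on
synthetic data generated by the package itself.  This note documents the
models, the numerical choices, the synthetic-data generator and what it
does and does not emulate, and the design decisions that were genuinely
open.

## The multi-state birth-death (MuSSE) model

A k-state character evolves along a tree while governing diversification:
a lineage in state *i* speciates at rate λ_i, goes extinct at rate μ_i,
and transitions to state *j* at rate q_ij (all rates per Myr).  Net
diversification is the derived quantity r_i = λ_i − μ_i.  The likelihood
of tip data is computed by integrating, rootward along each branch, the
coupled ODEs for the extinction probability E_i(t) and the data partial
likelihood D_i(t):

    dE_i/dt = μ_i − (λ_i + μ_i) E_i + λ_i E_i² + Σ_j q_ij E_j
    dD_i/dt = −(λ_i + μ_i) D_i + 2 λ_i E_i D_i + Σ_j q_ij D_j

with tip conditions E_i = 0 (complete sampling of the present) and D_i =
1 on the tip's admissible states.  Daughter partials merge at nodes as
D_i ← λ_i D_i^L D_i^R.

**Root treatment.**  Default is likelihood-proportional state weighting
(FitzJohn-style, π_i ∝ D_root,i), with `flat` and user-supplied π as
options.  Conditioning on survival of both crown lineages (division by
Σ π_i λ_i (1 − E_i)²) is on by default and can be disabled; whether the
original protocol conditioned is not documented upstream, so the choice
is exposed rather than hidden.

**Integration.**  Branch propagation uses an embedded Dormand–Prince
5(4) pair with proportional step control, relative tolerance 1e-8 and
absolute tolerance 1e-10 by default.  The system is smooth and non-stiff
at diversification-rate scales, so an explicit pair is appropriate; the
stepper is hand-written and numba-jitted because the MCMC protocol needs
on the order of 10⁵ likelihood evaluations per tree, and a 500-tip
likelihood must run in milliseconds.  D is renormalized to unit sum at
every node and branch top with the log-scaler accumulated, so large
trees cannot underflow.  Tightening the tolerance tenfold moves the
log-likelihood of the standard fixtures by < 1e-5 (tested).

**Degenerate regimes.**  With λ = μ = 0 the per-node λ factors make the
raw SSE likelihood identically zero; the reduction to a pure character
(Mk) model is therefore verified on likelihood *ratios* across tip
configurations with λ = 1e-8, where the λ factors cancel.

## Maximum likelihood and parameter tying

`musse_ml` maximizes over log-parameters with L-BFGS-B inside positive
bounds (default [1e-6, 10] Myr⁻¹), starting from a state-independent
heuristic around the tree-wide pure-birth rate ((number of internal
nodes)/(total branch length) — the convention that counts the root
merge, matching the per-node λ factors).  The optimizer is restarted
from its own optimum; a restart that still improves the objective by
more than 1e-4 flags the fit unconverged instead of raising.

`SSEParamSpace` names every rate (`lam1..lamk`, `mu1..muk`, `q12`, ...)
and supports tying (several names share one free value) and fixing.
Hidden-regime (HiSSE-style) models are built by state-space expansion:
observed state s in hidden regime h becomes expanded state
(s−1)·H + h, tips become ambiguous over their hidden copies, and the
plain MuSSE machinery runs unchanged with parameters tied — observed
transitions shared across regimes, one global hidden switching rate,
dual transitions fixed at zero.  The `unconstrained` model frees λ, μ
per expanded state; the `constrained` model ties them across observed
states within a regime, so rate variation lives only in the hidden
layer.

## MCMC

The sampler is univariate slice sampling (stepping-out and shrinkage) on
the natural scale, one full sweep per generation, with independent
exponential priors on every free rate.  The default prior rate is
1/(2·r̂) with r̂ the tree-wide pure-birth estimate — the documented
heuristic of the upstream tool; the original analysis does not print its
prior rate.  A preliminary run (default 100 generations) sets the
per-parameter slice widths to twice the preliminary spread; the main
chain (default 2000 generations) is then drawn, the first 10% treated as
burn-in at summary time, and per-parameter effective sample sizes
(arviz) screened against a threshold of 200 with a warning below.
Random-walk Metropolis on log-scale is available as an alternative
kernel.  Posterior draws from all trees of a set are pooled post
burn-in; each quantity (λ_i, μ_i, r_i) is summarized by its Gaussian-KDE
mode and a central credibility interval, the presentation used for
across-tree net-diversification estimates.

## Marginal ancestral states and stochastic mapping

Marginal ASR clamps each node to each state in turn and recomputes the
full likelihood with the same root mode and conditioning, then
normalizes — the definitional brute-force computation, made O(depth) per
node by reusing all off-path subtree partials from one cached
likelihood pass.  This matches an independent clamp-and-recompute oracle
to < 1e-6 on the test fixtures.

Stochastic maps follow the "marginals-as-input" protocol: node states
are drawn top-down, the root from its marginal and each non-root node
from its marginal re-weighted by the parent-state row of exp(Q·t) for
its branch; each branch path is then drawn conditioned on its endpoints
by uniformization (a dominating Poisson process at rate
1.05·max|q_ii|, jump count sampled against the Poisson–R^n series,
intermediate states by forward filtering, jump times as uniform order
statistics).  Uniformization was chosen over rejection sampling for
bounded runtime on improbable endpoint pairs.  Two approximations are
deliberate and documented: (i) within branches only the character
process Q acts — state-dependent birth/death does not bend the path law,
matching the mapping tool the protocol derives from; (ii) node-state
draws use marginals rather than exact joint conditionals, because the
upstream protocol feeds the marginal ASR output into the mapper.  An
exact joint top-down sampler over the character process
(`method="joint"`) is provided for comparison.  Transition counts are
segment-boundary counts per map, averaged over maps and trees; the
chord table is the long-format (from, to, mean lineages) view.

## DR tip rates

The equal-splits measure of tip *i* is ES_i = Σ_j l_j·2^−(j−1) over the
edges of its root path (pendant edge first); the DR statistic is 1/ES_i.
DR estimates *speciation*, not net diversification, and the tables are
labeled accordingly; externally computed per-tip rates (e.g. from a
Bayesian rate-shift analysis) can be substituted in the same TSV schema.
Medians across a tree set are the standard midpoint median per tip.
On pure-birth trees the across-tip mean of DR overshoots the generating
λ by roughly a third (short pendant edges dominate the inverse
weighting); the sanity test freezes a simulation-calibrated band of
mean-DR/λ ∈ [0.8, 1.6] rather than pretending the statistic is unbiased.

## The boosting stage

Median (or per-tree) tip rates are modeled with XGBoost gradient-boosted
trees under a gamma objective (rates are positive and right-skewed),
native categorical splits, single-threaded histogram method for
bit-reproducibility.  Tuning is two-step: a systematic grid over
learning rate {0.01, 0.05, 0.1, 0.3} × depth {2, 4, 6, 8} ×
minimum-split-loss {0, 1, 5} × subsample {0.5, 0.75, 1.0} (the upstream
grid is unstated; these are conventional values and config-exposed),
then 1000 uniform re-draws within ±10% of the stage-1 optimum (depth
rounded to integer), minimum cross-validated rmse winning, ties to the
first encountered.  Validation repeats 80/20 splits: accuracy is the
signed mean bias (observed − predicted), reported both raw and as % of
the mean response because the upstream report is ambiguous between the
two; precision is the mean R² of a linear fit of observed on predicted.
Bootstrap resamples species rows with replacement; importance is
gain-based (cover/frequency alternatives exist upstream but gain is the
declared default), normalized to 100% per model, against a uniform
chance line of 100/p % for p predictors (the chance construction is
config-overridable; a permutation null is the obvious alternative).
Prediction profiles hold continuous predictors at their means and
categoricals at their modes while varying guild and/or a log-spaced
body-size grid (sizes are lognormal, so log spacing covers the small
classes); size-class effects are guild median minus global median within
the <10 cm, 10–30 cm and >30 cm classes, computed per bootstrap model
and summarized by 25/50/75% quantiles.  Effects need not sum to zero
across guilds (medians, not means) — recorded as a non-property.
Phylogenetic non-independence of species rows is not corrected,
matching the protocol this stage reproduces; treat importance p-values
accordingly.

## The synthetic-data generator

`treesim` is an exact Gillespie event simulation (exponential waiting
times with total rate λ_s + μ_s + Σ_j q_sj per lineage; no time
discretization), recording the complete pre-pruning character history
and exact transition counts, then pruning extinct lineages and
suppressing unifurcations.  Stopping is either a fixed time horizon
(total extinction is then a valid outcome) or "first moment the extant
count hits n", retrying on extinction up to 1000 attempts — the simple
n-stopping rule whose mild bias relative to the generalized sampling
approach is accepted and documented here.  Default start is a crown (two
lineages in the root state), since SSE likelihoods condition on the
crown; a stem start is available.  Simulated trees of a set are
independent; the 100-tree ensembles this emulates differ only in
imputed-tip placement, so per-tip median pooling across simulated trees
is structurally looser than in the real protocol (trees of a set share
tip labels t1..tn, making pooling well-defined but biologically
arbitrary) — the pipeline therefore also stacks per-tree rows for the
boosting stage, keeping each row's guild and rate from one tree.

Trait tables draw guild from a configurable 6-level distribution
(defaults roughly reef-like: GC .25, MI .25, OM .12, PK .15, SI .08,
HD .15), body length lognormal (median 15 cm, log-sd 0.9), and the
remaining columns from fixed documented distributions: activity
(.60/.25/.15 diurnal/nocturnal/both), position (.55/.30/.15
benthic/benthopelagic/pelagic), basin (.25/.60/.15
Atlantic/Indo-Pacific/both), occupied-cell range lognormal (median 30,
floor 1), |centroid latitude| uniform on [0°, 35°], distance to the
Indo-Australian Archipelago point uniform on [0, 14000] km, SST
28.5 − 0.28·|lat| ± N(0,1) °C, productivity lognormal.  The latent rate
is rate_fn(guild, size) × Gamma(shape, mean 1) multiplicative noise.
Geographic columns are independent draws — no spatial covariance, no
range cohesion — so passing boosting tests demonstrate correct protocol
mechanics and signal attribution, not realism of geographic predictors.
Real-data feature assembly (occupied-cell counts, centroid, great-circle
distance on a 6371-km sphere to lat 0°, lon +121°) is implemented in
`boostrates.assemble_features`; the distance uses the
(|centroid latitude|, centroid longitude) point, which equals the
signed-point distance because the reference sits on the equator.

## Validation-study sizes

The canonical studies (`troposse.validation`) run at desk scale, chosen
once as the package's own test sizes: ML rank recovery on 20 replicate
500-tip two-state trees (λ = 0.1/0.2, μ = 0.03, q = 0.01);
credible-interval calibration on 20 replicate 100-tip trees with
400-generation chains (calibration is a property of the sampler, not the
tree size); 10⁴ single-branch endpoint-conditioned paths against the
π₁q₁₂t identity; ground-truth transition recovery over 20 × 500-tip
trees × 10 maps; boosting checks at n = 2000 with 200 bootstraps; and a
discrimination study of 10 × 200-tip trees in which the HD state
speciates twice as fast as GC, checked for disjoint pooled 50% credible
intervals on r and for trophic identity leading the importance ranking.

## Known limitations

- No incomplete-sampling correction (sampling fraction fixed at 1), no
  time-dependent rates, no GeoSSE/QuaSSE variants.
- The marginals-as-input mapper is an approximation whose exact upstream
  counterpart is undocumented; sensitivity can be probed with
  `method="joint"`.
- n-stopping in the simulator has the known mild bias of naive stopping.
- DR pooling across independent simulated trees is an emulation of
  ensemble pooling, not a reconstruction of it.
- MCMC chains at the bundled smoke scale are far too short for converged
  posteriors (and are flagged by the ESS warning); they exercise the
  machinery, not the science.
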