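# Methods

This note documents the models, conventions and design choices behind
`zoosem`, in the spirit of a statistical software methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Composition metrics

All metrics are per institution, computed from a holdings matrix
(institutions × species individual counts with species attributes), in an
*abundance* mode and a *presence–absence* mode (every positive count treated
as one individual; total animals then equals species richness, the mean body
mass is unweighted, and the threatened share is a species fraction).

* **Threatened proportion.** "Threatened" is the IUCN Red List union
  CR ∪ EN ∪ VU; NT, LC, DD and NE all count as non-threatened. In abundance
  mode the share is individual-weighted (individuals of threatened species /
  total individuals).
* **Mean body mass** is the abundance-weighted species mean
  `Σ xᵢmᵢ / Σ xᵢ` in grams. Missing species masses are imputed as the
  arithmetic mean of reference-table masses at the genus, then family, then
  order level (first non-empty level wins, and the provenance level is
  returned); a species unresolved at every level is an error, never a silent
  drop. Resolution uses only the offline reference table's explicit hierarchy
  columns — no name-matching services.
* **Brillouin diversity** `(ln N! − Σ ln nᵢ!)/N` is evaluated through
  log-gamma, never raw factorials, and is exact against direct log-factorial
  arithmetic for small N (tested). It is the appropriate alpha diversity for
  a fully censused community such as an inventory, and is bounded above by
  the Shannon index of the same counts.
* **Raup–Crick dissimilarity** between two institutions with richness a and
  b, sharing s species from a pool of P (the union of species across all
  institutions in the dataset), is `P(X < s)` for
  `X ~ Hypergeometric(P, a, b)` — one minus the probability of sharing at
  least s species when both collections are drawn at random holding richness
  fixed. The default is this closed form (deterministic and checkable against
  exhaustive enumeration); a seeded Monte-Carlo randomization variant is
  available behind a flag. Two quirks are properties of the index, kept as
  defined: disjoint collections score 0 (sharing "at least zero" species is
  certain), and the index is conditioned on richness, so it measures
  composition given size, not size itself. The all-pairs matrix uses a
  vectorised log-gamma evaluation, tested equal to the scipy scalar path.
* The per-institution "Dissimilarity" variable is the mean Raup–Crick value
  against every other institution; it needs at least two institutions and is
  NaN for a single-institution dataset.

## Path models

A model is a directed acyclic graph over observed, standardized variables
plus free (co)variances: variances of all variables, covariances among all
exogenous variables (freed automatically, the usual path-analysis
convention), and any residual covariances declared with `~~` in the text
format (`outcome ~ pred1 + pred2`, `a ~~ b`, `#` comments).

**Estimation.** With coefficient matrix `A[outcome, predictor]` and
(co)variance matrix `Ψ`, the implied covariance is
`Σ = (I−A)⁻¹ Ψ (I−A)⁻ᵀ` and parameters minimise the Wishart discrepancy
`F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p` against the sample covariance `S`
(n−1 denominator). For recursive models with uncorrelated residuals the
minimiser is closed-form — each equation is its least-squares regression on
its parents computed from `S`, and the exogenous block of `Ψ` equals the
matching block of `S` — so the package fits those models without iteration
and the ML = per-equation-OLS identity holds to machine precision. Declared
residual covariances switch to L-BFGS-B with an analytic gradient, started
from the closed form; convergence is judged by the gradient norm. Data are
standardized *before* fitting (sample sd, n−1); for recursive models this
agrees with post-hoc standardization of raw-data coefficients, and that
agreement is a test.

**Conventions** (fixed so results can be reconciled with other software):
chi-square `T = (n−1)·F_ML`; standard errors from the numerical Hessian of
`F_ML` at the optimum, `acov = (2/(n−1))·H⁻¹`; `CFI = 1 − max(T−df,0) /
max(T₀−df₀, T−df, 0)` against the independence baseline (diagonal Σ, free
variances); SRMR over the p(p+1)/2 unique entries of the
sample-sd-standardized residual matrix; `AIC = T + 2k` on the chi-square
scale (so ΔAIC between nested models is invariant to the saturated
constant) and `AICc = AIC + 2k(k+1)/(n−k−1)`, undefined (an error) when
n ≤ k+1; `R²ᵥ = 1 − Ψᵥᵥ/Σᵥᵥ`.

**Effects.** Direct = A (standardized via the implied variances); total =
`(I−A)⁻¹ − I`; indirect = total − direct, so total = direct + indirect holds
exactly. A path-enumeration oracle (`enumerate_paths`, sum over simple
directed paths of coefficient products) is kept alongside and tested equal on
random DAGs.

**Mediation** uses the product-of-coefficients delta-method (Sobel-type)
test by default: estimate = product of chain coefficients, variance =
`Σⱼ (Π_{i≠j} bᵢ)² seⱼ²`, two-sided normal p. A seeded nonparametric bootstrap
variant refits on row resamples.

**Cluster-robust standard errors** (institutions within countries) use the
plain sandwich `H⁻¹ G H⁻¹` with per-cluster analytic score outer products
`G` and the numerical Hessian of the total log-likelihood as bread; no
small-cluster correction factor is applied. Point estimates never change.
The adjustment is optional and off by default.

## Stepwise structure search

The a priori meta-model (the theory-derived superset of admissible pathways;
the shipped attendance fixture) seeds the search, which alternates

1. **forward additions to exhaustion**: among whitelisted absent edges, the
   highest modification index strictly above 3.84 (the 0.05 critical value of
   χ²(1)) is freed, one edge per step. MIs are exact single-edge
   likelihood-ratio refits, not score-test approximations, so the 3.84
   criterion is a true 1-df LRT threshold. Cycle-creating candidates are
   listed as inadmissible with a reason.
2. **backward deletions to exhaustion**: the edge with the highest Wald p
   value strictly above 0.05 is removed, one per step.

until a fixed point (the phase order is one consistent reading of
"addition and deletion"; it is configurable in code). Every distinct model
visited joins a candidate pool; the returned model is the pool's AICc
minimum, flagged decisive only when it beats the runner-up by more than 2
AICc units. Ties in MI or p break lexicographically by edge, so the search
is deterministic given data and whitelist; visited models are hashed by edge
set and a revisit terminates with a loop flag. The search never invents an
edge outside the whitelist.

A removal may leave a variable with no pathway at all. Such a variable stays
in the model as a member of the saturated exogenous block (its correlations
with the other exogenous variables remain free; its association with the
endogenous variables is constrained to flow through them). This keeps every
candidate on the same variable set, so AICc values remain comparable — the
alternative, dropping the variable, silently changes the likelihood's
dimension. Named *mandatory* variables (the focal outcome of each analysis)
are protected from losing their last edge, with the skip recorded in the
trace.

Subset validation refits the selected model on seeded random subsets drawn
without replacement (4 × 200 by default), each re-standardized, and reports
per-parameter ranges and coefficients of variation.

## Synthetic data

**Variable level** (`simulate_variables`): exogenous variables are drawn
from a configurable correlation matrix — identity by default, since the
published tables print no exogenous correlations — and endogenous variables
follow in topological order as their structural linear combination plus an
independent Gaussian residual. Residual variances are solved recursively so
every variable has unit total variance; a coefficient set that would need a
non-positive residual variance is rejected with the variable named, never
rescaled silently. `default_attendance_config()` (n = 458, 58 country
labels) and `default_insitu_config()` (n = 119, GDP and its edges removed,
four countries) carry the published direct standardized coefficients.

**Species level** (`simulate_holdings`, defaults mirroring the study scale:
458 institutions, 58 countries, 4822-species pool): body masses are
log-normal (median 300 g, σ_log 2.3, right-skewed across classes); class
mixture 25/45/20/10% mammal/bird/reptile/amphibian; IUCN categories from a
fixed mixture (23% threatened); 12% of species lack a species-level mass and
exercise the taxonomic fallback (each order keeps at least one known mass so
imputation terminates). Institutions get a country, a log-normal area and
local population, and a per-institution richness
`⌊c·area^0.25·exp(noise)⌋`. Three mechanisms encode the trade-offs the
models are built to detect: per-species expected abundance scales as
`mass^(−0.2)` (negative abundance–mass elasticity) and `area^0.3`;
institutions deviate from a near-uniform "mainstream" collection by a
non-negative specialisation toward small-bodied taxa, which lowers mean body
mass, raises Raup–Crick dissimilarity (specialists are idiosyncratic) and
buys extra richness through a capacity trade-off. Attendance is then
generated by pushing the *realised* composition metrics through the
standardized attendance equation (plus Gaussian noise) and exponentiating to
a count; in situ project counts are generated the same way for a subset of
institutions (119/458 by default). Because the attendance equation is applied
to derived, transformed metrics, the holdings generator targets qualitative
structure — signs, skews, clustering — not exact coefficient magnitudes; the
end-to-end test accordingly checks coefficient *signs* for the strong
(|β| ≥ 0.15) edges only. Everything is bit-reproducible under a fixed seed.

## Pipeline

`run_attendance_analysis` computes profiles, joins covariates, transforms,
standardizes, searches from the meta-model and decomposes effects.
Institution ids must reconcile exactly between holdings and covariates (a
mismatch is an error listing the ids); rows with missing or non-positive
required covariates are dropped with a logged manifest. Size-like variables
(attendance, animal counts, richness, area, GDP, populations, mean body
mass) enter on the natural-log scale — standard for right-skewed size
measures and matching the generator's exponentiation; proportions,
dissimilarity and the Brillouin index enter raw; mammal richness and in situ
counts use log1p (zeros occur). The two holdings/covariate tables are treated
as contemporaneous.

`run_insitu_analysis` restricts to institutions reporting project counts,
drops GDP (and relies on re-estimating all attendance-side coefficients on
the subset), freezes the attendance-model edge structure, searches only the
three candidate in situ pathways (attendance, threatened proportion, area)
starting from the most complete model, and runs delta-method mediation tests
on every pathway into in situ that passes through attendance. Re-estimation
on the subset is deliberate: the published area → in situ total effect is
not reproducible from the attendance model's coefficients alone, which
implies subset-specific re-estimation in the original analysis; the
discrepancy is documented rather than resolved.

In presence–absence mode the total-animals variable duplicates species
richness exactly (singular covariance), so the presence variant of either
model drops it; the Brillouin "Diversity" variable is computed and reported
in every profile but is not part of the default meta-model, whose final
published structure contains no diversity pathway (in synthetic collections
it is also nearly collinear with log richness).

Reports are directories of CSV/JSON (coefficients, effects, fit indices,
search trace, DOT graph export, run metadata) and are byte-identical across
reruns with the same inputs, configuration and seed.

## Problem sizes used by the checks

The acceptance-style tests run at the study scale where that scale is cheap:
parameter recovery uses 100 replicates of n = 458; chi-square calibration
500 replicates of a correctly specified 6-variable submodel at n = 458
(df = 2); structure recovery 50 replicates of the stepwise search from a
five-extra-edge superset at n = 458; oracle equivalences use pools ≤ 12
(exhaustive enumeration), collections with N ≤ 50 (log-factorials), random
DAGs ≤ 8 nodes, and n = 100 regression datasets. Pipeline and generator
tests use scaled-down holdings (100–200 institutions, 700–900-species pools)
purely as smaller instances of the same generative process.

## Known limitations

* Observed variables only: no latent constructs, no FIML for missing data,
  no ordinal/robust (WLSMV-type) estimators, no multi-group models.
* The structure search is greedy and threshold-based by design (it
  reproduces a published procedure); it is not an exhaustive or
  causal-discovery search, and weak true pathways (standardized |β| around
  0.1 at n ≈ 458) are frequently pruned — a power property quantified in the
  acceptance suite, not a defect of the implementation.
* The holdings generator emulates marginal shapes and trade-off signs, not
  husbandry reality: no real taxon names, no record-keeping artefacts, no
  temporal dynamics, and country effects enter only through covariates. A
  pass on synthetic data shows the machinery recovers known structure; it
  does not validate the substantive model on real collections.
* AICc comparability across the candidate pool rests on all candidates
  sharing one variable set (see the isolated-variable convention above).
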