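# zoosem

Zoo collections sit at the centre of a system: what a zoo holds shapes how
many people visit, and visitor revenue in turn funds field ("in situ")
conservation projects. `zoosem` implements that system-wide analysis as a
reusable Python library. It takes a species-holdings table (which institution
holds how many individuals of which vertebrate species, with taxonomy, IUCN
Red List category and body mass) plus institution covariates (attendance,
area, GDP, local and national population), derives collection-composition
variables, and links composition and socio-economic context to attendance and
in situ project counts with observed-variable structural path models.

## What it computes

**Composition metrics** (per institution, abundance or presence–absence mode):
species richness, total animals, mammal species richness, the
abundance-weighted proportion of threatened (CR/EN/VU) species, the
abundance-weighted mean species body mass

$$\bar M = \frac{\sum_{i=1}^n x_i m_i}{\sum_{i=1}^n x_i},$$

the Brillouin diversity index $H_B = (\ln N! - \sum_i \ln n_i!)/N$
(the natural alpha diversity for a fully censused collection), and the mean
Raup–Crick dissimilarity — one minus the hypergeometric-null probability of
sharing at least the observed number of species with another institution.
Missing body masses are imputed from a reference table at the genus, family
or order level.

**Path models.** A model is a DAG of standardized linear equations over
observed variables. Coefficients are estimated by maximum likelihood against
the sample covariance $S$, with implied covariance
$\Sigma(\theta) = (I-A)^{-1}\Psi(I-A)^{-\top}$; for recursive models with
uncorrelated residuals the estimates coincide with per-equation least squares
(an identity the test suite enforces). The fit report carries
$\chi^2 = (n-1)F_{ML}$, CFI, SRMR, AIC/AICc, per-equation $R^2$, delta-method
mediation tests and optional cluster-robust (country-level) standard errors.
Standardized effects decompose into direct, indirect and total via
$(I-A)^{-1} - I$, which equals the sum over directed paths of the products of
path coefficients.

**Stepwise structure search.** An a priori meta-model (superset of admissible
pathways) is refined by modification-index-guided additions (single-edge
likelihood-ratio MI, threshold 3.84), p-value-guided deletions (threshold
0.05), and final AICc selection among all visited candidates (decisive only
beyond 2 AICc units), with random-subset validation of the selected model.

**Synthetic data.** `simulate_variables` draws institution-level data from
any standardized structural configuration; `default_attendance_config()` and
`default_insitu_config()` carry the published attendance-model (n = 458) and
in situ-model (n = 119) coefficient structures. `simulate_holdings` generates
an entire species-level dataset (log-normal body masses, negative
abundance–mass elasticity, richness–area scaling, IUCN mixture, country
clustering) so the whole pipeline can be exercised end to end against a known
truth.

## Worked example

```python
from zoosem import default_attendance_config, enumerate_paths, total_effects

A = default_attendance_config().coefficient_matrix()
for path, product in enumerate_paths(A, "body_mass", "attendance"):
    print(" -> ".join(path), f"{product:+.4f}")
print("total:", f"{total_effects(A).total_effect('body_mass', 'attendance'):+.3f}")
```

prints

```
body_mass -> attendance                                      +0.3400
body_mass -> dissimilarity -> attendance                     -0.0741
body_mass -> species_richness -> attendance                  +0.0789
body_mass -> species_richness -> total_animals -> attendance -0.1911
body_mass -> total_animals -> attendance                     -0.0922
total: +0.062
```

Large-bodied collections raise attendance directly (+0.340) but depress it
through lower species richness, fewer animals and less distinctive
collections — the total effect almost cancels (+0.062). The `examples/`
directory holds one short script per capability: composition metrics, model
fitting, effect decomposition, the stepwise search, and the full
holdings-to-report pipeline (attendance and in situ analyses). A thin CLI
(`zoosem metrics|fit|search|effects|simulate|validate|insitu`) wraps the same
functions for shell use.

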