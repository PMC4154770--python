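# Methods

## The scientific question and the modelling strategy

Managed grasslands are mown, grazed and fertilized at very different
intensities, and these management modes act on arthropod consumers both
directly and through the plant community.  Two classical mechanisms are
distinguished: under the *resource heterogeneity* view, consumer diversity
tracks resource diversity (plant species richness → herbivore richness →
predator richness); under the *more individuals* view it tracks resource
quantity, mediated by consumer biomass.  The package encodes each view as a
structural equation model (SEM) over plot-level variables and fits both per
region and year, so the two mechanisms can be compared on the same data.

### Variables

Per plot and year:

| variable | units | role |
| --- | --- | --- |
| `mowing` | cuts yr⁻¹ (3-yr mean, truncated at the sampling date in the final year) | land-use indicator |
| `fertilization` | kg N ha⁻¹ yr⁻¹ (3-yr mean) | land-use indicator |
| `grazing` | livestock-unit days ha⁻¹ yr⁻¹ (3-yr mean) | land-use indicator |
| `time_after_mowing` | days (mean over the two sampling dates; falls back to days since vegetation onset when never mown) | exogenous covariate |
| `plant_biomass` | g m⁻² (mean over subplots) | resource quantity |
| `plant_diversity` | species | resource diversity |
| `herbivore_diversity`, `predator_diversity` | species (adults, months pooled) | responses |
| `herbivore_biomass`, `predator_biomass` | g (allometric estimate summed over species) | quantity route (RA model only) |

Arthropod body mass per individual uses the general length–mass power law
`mass_mg = a·L^b` with defaults a = 0.0305, b = 2.62 (L in mm).  The
constants are configuration, not hard-coded science: published variants of
the power law differ by taxon, and nothing downstream depends on the
specific pair beyond monotonicity.

### Model structure

Both models share a measurement block: a latent "land-use intensity" drives
the three management indicators, with the mowing loading fixed to 1 to give
the latent a scale (mowing is the indicator most tightly coupled to overall
intensity in these systems).  Structurally, each management mode sends a
path to plant biomass and to plant diversity; plant biomass → plant
diversity; plant diversity → herbivore diversity → predator diversity plus
a direct plant-diversity → predator-diversity path; time-after-mowing sends
paths to the arthropod responses.  The Resource Abundance (RA) variant adds
plant biomass → herbivore biomass → {herbivore diversity, predator
biomass} and predator biomass → predator diversity, and a
time-after-mowing → herbivore biomass path; restricted to the shared
variables its graph is identical to the Resource Heterogeneity (RH) graph
(asserted structurally in the catalog).

A quadratic-grazing variant (squared grazing intensity as an extra
indicator with mirrored paths) is available and is meant to be retained
only when it lowers AICc.

## Estimation

Models are written in reticular-action-model (RAM) form: directed
coefficients `A`, residual covariances `P`, observed-variable filter `F`,
implied covariance `Σ(θ) = F(I−A)⁻¹P(I−A)⁻ᵀFᵀ`.  Estimation minimizes the
Wishart maximum-likelihood discrepancy

    F_ML(θ) = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p,

and `(N−1)·F_ML(θ̂)` is the model chi-square on `p(p+1)/2 − t` degrees of
freedom.  The overall model p-value tests whether the sample and implied
covariances differ beyond sampling error; p < 0.05 is read as an inadequate
structure.  The goodness-of-fit index is the Jöreskog–Sörbom GFI
`1 − tr[(Σ̂⁻¹S − I)²]/tr[(Σ̂⁻¹S)²]` — "GoF" is ambiguous across software,
and GFI is the index reported by the covariance-SEM tool family this
workflow mirrors.  Information criteria use `AIC = χ² + 2t` and
`AICc = AIC + 2t(t+1)/(N−t−1)`; only differences matter for model search.

Numerical choices:

- The search runs on the correlation scale (F_ML is invariant under
  diagonal rescaling) to keep the optimizer conditioned regardless of
  units, and estimates map back exactly — each latent is rescaled by its
  anchor indicator's SD.
- L-BFGS with the analytic RAM gradient, start values of zero paths, unit
  loadings and sample variances, up to 20 seeded jittered restarts, then a
  few damped Newton steps on the gradient.  The Newton polish matters:
  F_ML evaluations carry ~1e-16 cancellation noise, which caps quasi-Newton
  precision near √noise ≈ 1e-8, while the analytic gradient remains
  informative to machine precision.
- Standard errors come from the Hessian of F_ML (finite differences of the
  analytic gradient) scaled by 2/(N−1); significance stars at 0.05 / 0.01 /
  0.001.
- A negative estimated variance (Heywood case) marks the fit non-converged.
- Standardization multiplies each directed coefficient by SD(source)/
  SD(target) under the full implied covariance, so fixed loadings are
  generally not 1 after standardization; covariances become correlations.
- The pipeline applies log1p to biomass and abundance variables (identity
  to richness and land-use indices), then z-standardizes everything before
  the covariance is formed.  With z-scored inputs the standardized and
  unstandardized solutions coincide up to the fixed loadings; either
  convention yields the same standardized coefficients, which is all the
  effect decomposition consumes.

## Model search and fallbacks

When a latent-variable fit does not converge, the latent is replaced by
free correlations between the anchor indicator (mowing) and each remaining
indicator; all structural paths are unchanged.  When a converged model
misfits (p < alpha), single-path deletions are tried one at a time: every
free directed path is removed in turn, each candidate refitted (warm-started
from the parent solution), and the deletion that most lowers AICc is
accepted; the loop stops when no deletion lowers AICc or the fit becomes
adequate.  Loadings, variances and fallback covariances are never deletion
candidates, and ties on AICc break toward the path with the smaller |z|.
A final inadequate model is still reported for comparison when its GFI
exceeds 0.75 (`gof_rescue`), otherwise it is labelled `failed`.

The prune loop's trigger is a policy choice: the default (`trigger=
"pvalue"`) only prunes models that misfit, which is the workflow's rule;
`trigger="aicc"` prunes while AICc improves regardless of p and exists to
exercise and test the deletion-selection machinery on well-fitting models
(a spurious extra path is otherwise invisible to the p-value trigger).

## Total effects

The standardized total effect of a source on a target is the sum over all
directed simple paths between them of the product of standardized
coefficients along each path; loadings count as edges, so the latent can be
a source.  Path enumeration is exhaustive and order-stable; the test suite
cross-checks every total against the algebraic identity
`totals = (I − A_std)⁻¹ − I` computed by matrix inversion, an independent
second route.  Reported tables round half away from zero to two decimals.
For fallback fits (no latent) totals are reported per management mode, the
same reporting convention the study tables use.

## The synthetic study

The generator replaces the field campaign.  Defaults emulate the study
conditions: 3 regions × 2 years × 45 plots (the reported per-region plot
counts range 38–48), a herbivore pool of 392 species and a predator pool of
162 (the reported 2008 totals), log-normal body lengths.  Ground truth is a
numeric-coefficient RA (or RH) graph on the z-score scale; the significant
diversity-chain values (0.13, 0.64, −0.25) follow the reported Swabian-Alb
2008 pattern and the remaining magnitudes are plausible fixtures, not
claims about the original data.  Residual SDs are solved so every variable
has unit implied variance, making declared coefficients approximately
standardized ones.

Plot-level z-scores map to measurement scales as follows: right-skewed
quantities (fertilization, grazing, the three biomasses) are log-normal —
the z-score lives on the log1p scale, so the pipeline's transform recovers
Gaussianity exactly; richness and mowing are rounded counts;
time-after-mowing is linear.  Raw management events are constructed to
reproduce the intensity indices exactly where event granularity allows
(fertilizer amounts, grazing-period areas) and up to integer quantization
for cut counts and whole-day cut placement; the *realized* values
recomputed from the events are what the returned truth table carries, so
ingestion round trips are exact.  Species-level records recover each plot's
guild richness and adult abundance exactly by construction; biomass is
approximate (discrete body masses), realized by a greedy mass-targeted
allocation and recorded back into the truth table.  Juvenile records and a
decomposer bycatch are added to exercise the adults-only and guild filters
without touching the adult metrics.

What the generator does *not* emulate — and hence what green tests do not
show about field data: plots are independent (no spatial or temporal
autocorrelation; plot identities are not linked across years), species
abundances have no interaction structure beyond the plot-level targets,
covers are Dirichlet noise, and the measurement-scale quantization
(integer cuts, the vegetation-onset fallback for never-mown plots) is the
only source of model misfit.  Misfit on synthetic data therefore appears
exactly where those quantizations bite, which is also what makes the
pruning and GoF-rescue machinery reachable in the shipped analysis.

## Problem sizes

The shipped analysis uses 45 plots per region-year, the scale of the
original design.  The recovery driver runs 30 replicates of 500 plots; the
test suite's recovery check uses 50 replicates of 2000 plots (bias below 3
Monte-Carlo SEs for every directed coefficient) and the pruning check 100
replicates of 500 plots, sizes at which the checked properties are sharp
but the suite stays interactive.

## Known limitations

- Covariance-only ML: no mean structure, no GLS/WLS/robust estimators, no
  multi-group fitting (regions are always fitted separately).
- The GoF rescue threshold (0.75) and alpha (0.05) are conventions carried
  in configuration, not estimated.
- Heywood cases are treated as non-convergence rather than constrained to
  the boundary.
- The stepwise search deletes only; it cannot discover paths missing from
  the initial concept (by design — persistent misfit after deletion is the
  signal that a variable or arrow is missing).
- AICc's effective-sample-size convention (N − t − 1) is undefined for
  t ≥ N − 1; such models are flagged, not fitted.
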