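# Methods

This note describes the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate about real recordings.

## Scientific setting

*Drosophila melanogaster* nicotinic acetylcholine receptors (nAChRs) are
pentamers assembled combinatorially from α (Dα1–Dα4) and β (Dβ1–Dβ3)
subunits; Dβ1 is essential for functional expression and is present in every
receptor considered. Heterologous expression in *Xenopus laevis* oocytes
under two-electrode voltage clamp yields, for each receptor × agonist pair, a
concentration–response relationship summarized by a potency (pEC50 =
−log10 EC50, molar) and an efficacy (Imax, the maximal response as a
fraction of the maximal acetylcholine response, so Imax(ACh) ≡ 1). The
bundled panel covers 18 subunit combinations × 4 agonists (ACh and the
neonicotinoid insecticides imidacloprid, thiacloprid, clothianidin), mean ±
SE with n = 5 oocytes per value. Twelve of the receptors — every observed
combination of Dα1/Dα2/Dα3 with obligatory Dβ1, with and without Dβ2 — form
the *core panel* on which the three downstream analyses run; the remaining
six carry Dα4/Dβ3 substitutions.

## Hill concentration–response model

Normalized response at log-molar concentration X follows

    Y = Imax / (1 + 10^((logEC50 − X) · nH))

with nH the Hill coefficient. Estimation is nonlinear least squares
(`scipy.optimize.least_squares` with box bounds), with a deterministic
multistart: pEC50 starts on a half-log grid spanning the observed
concentration range ± 1 log unit, Imax seeded at the maximum observed
response, nH at 1. Sparse sigmoid fits are multimodal in pEC50, hence the
multistart; the grid is data-derived, so identical inputs give identical
fits.

Numerical choices:

- bounds nH ∈ [0.3, 5], Imax ∈ (0, 2]: keeps slopes and plateaus physical on
  non-plateau curves;
- pEC50 is confined to one decade beyond the multistart grid. An EC50
  further outside the tested concentration window is pure extrapolation and
  reporting it would be noise;
- convergence: `ftol` 1e-10 (reproducible 3-decimal pEC50s); if no start
  converges the best candidate is returned with `converged=False`, never
  silently;
- if the mean response at the top concentration is below 0.9 × fitted Imax
  the fit is flagged `extrapolated_plateau` but still returned — the panel
  includes weak partial agonists (Imax down to 0.01) whose plateaus are
  never directly observed;
- standard errors are asymptotic, from the Jacobian at the optimum scaled by
  RSS/(n − 3). Across-oocyte SEs can be had by fitting per oocyte
  (replicates are pooled into a single fit by default, matching how the
  published summaries were produced).

Potency arithmetic: EC50 = 10^(−pEC50) molar; the fold-change between two
potencies is 10^(pEC50_high − pEC50_low).

## Additive factor model

Each (receptor, ligand) summary mean is modelled as

    outcome = β0 + Σ_s β_s·1[subunit s present] + Σ_c γ_c·1[ligand = c]

with ACh the reference ligand and subunit covariates Dα1, Dα2, Dα3, Dβ2
(Dβ1 is constant across the panel and inestimable). On the core panel this
gives n = 48 rows and 40 residual degrees of freedom. The model is fitted on
the 48 summary means, not per-oocyte replicates — the panel's df dictates
this. The solve is ordinary least squares (statsmodels); CIs are
estimate ± t(0.975, df)·SE, and the significance flag is CI-excludes-zero
(equivalent to the two-sided t-test at α = 0.05). Both plain and
df-adjusted R² are reported; the published fit-quality statistic corresponds
to the adjusted one (0.878 for the potency model). AIC is reported under
both the n·ln(RSS/n) + 2k convention and the full Gaussian log-likelihood
convention, because conventions differ across software; it is informational
only.

Because every ligand is measured on every receptor, the design is balanced:
each ligand coefficient equals the raw mean difference from ACh and is
orthogonal to the subunit terms. A consequence worth knowing: the
per-compound coefficients recomputed from the panel match the published
per-compound rows only under a cyclic relabelling of the three
neonicotinoids, for both outcomes, while every label-invariant quantity
(subunit terms, extremes of the compound terms, R², df) matches exactly.
`reproduce_paper` flags those rows as `label-permuted` and excludes them
from pass/fail.

## CHAID regression tree

Continuous-outcome CHAID in the Kass tradition: for each predictor,
categories are merged stepwise — always the pair with the largest pairwise
one-way F-test p-value — until all pairs differ at `alpha_merge` (0.05) or
one group remains; binary predictors are left unchanged. The split candidate
for a predictor is its merged grouping, scored by the ANOVA F-test p across
groups times a Bonferroni multiplier counting the ways c categories can
collapse into r groups (1 for binary predictors). The node splits on the
smallest adjusted p; ties break by predictor order in the config. `max_depth`
counts levels including the root (so max_depth = 1 is the root alone, and
the published setting of 4 allows three nested splits); `min_node` (2) is
the smallest admissible child.

Stopping is by depth and node size by default (`alpha_split=None`): the best
admissible split is taken regardless of its p-value, which is what the
widely used Python CHAID implementation does and what reproduces the
published subunit tree — on the panel the within-node variance is dominated
by the ~2-pEC50-unit ligand spread, so the inner subunit splits have p ≈
0.1–0.6 and a significance-gated tree would stop at the root split. Setting
`alpha_split` enables the classic significance stop; with a single binary
predictor at α = 0.05 the false-split rate on pure-noise outcomes is at the
nominal level (checked by simulation). Reported p-values are descriptive
under greedy growth, inferential only under the gated rule.

The predictor set is configurable because the published analysis is
ambiguous: the methods name both subunits and compounds as explanatory
variables, but the published tree splits only on subunits (with compounds
included, the compound factor dominates the root). The subunit-only
configuration is the default.

## Lattice ΔpEC50 analysis

Receptor subunit sets form part of the powerset lattice under inclusion.
Covering edges connect sets differing by one subunit; each edge, per ligand,
carries ΔpEC50 = pEC50(larger) − pEC50(smaller), labelled "+subunit".
Grouping edges by added subunit and forming a t-based 95% CI on the mean
delta gives a model-free per-subunit contribution. Deltas are computed per
ligand and pooled across ligands for the summary (a per-ligand mode exists);
edge deltas are treated as independent observations in the CI, which
overstates precision somewhat since edges share nodes — the factor model is
the inferentially cleaner view of the same contrasts, and on the balanced
panel the pooled mean deltas coincide exactly with the factor-model subunit
coefficients. Dβ1 never occurs as an added subunit on the core panel and is
reported as absent, not zero. Subunits with a single edge get an undefined
CI rather than a guessed one.

## Synthetic data generator

`TruthConfig` defines a subunit-additive potency surface (defaults: the
fitted factor-model coefficients, intercept 6.96) and per-compound true
efficacies (defaults: ACh 1 by normalization; neonicotinoids at the panel
means 0.119 / 0.049 / 0.667). `simulate_curves` draws per-oocyte responses
on the implied Hill curves (true nH uniform in [1, 2], seeded) with additive
Gaussian noise σ = 0.03 — the scale of the published SEs — truncated at 0,
n = 5 oocytes per curve.

Concentration design: by default each curve is sampled at 8 half-log steps
centered on its own true EC50, emulating how dilution series are chosen in
practice (each measured curve reached its plateau). A single shared grid can
be forced via `NoiseConfig.concentrations` or `shared_median_grid`; on a
panel spanning ~4 potency decades a shared median-centered grid leaves the
extreme curves without coverage of their EC50, and their fits are then
biased toward the tested window — a useful failure mode to demonstrate, but
not a faithful emulation of the study design.

What the generator does *not* emulate: noise proportional to current
amplitude (real recording noise shrinks with the signal; additive normalized
noise therefore *overstates* noise on small-Imax curves — at σ = 0.03 the
thiacloprid-like 0.049-amplitude curves are at the edge of measurability and
their pEC50 estimates are heavy-tailed, which the real experiment did not
suffer), oocyte-level random effects, desensitization/rundown, and
truncation-induced bias is present but small for measurable curves. Passing
recovery tests therefore demonstrate correctness of the estimation chain
under the stated noise model, not instrument-level realism.

Problem sizes used by the test suite (chosen for thorough-but-quick runs):
CI-coverage calibration uses 100 replicates of the full 12-receptor panel;
the noise-monotonicity check uses 40 replicates of a 6-receptor panel with
the two measurable neonicotinoids; Hill-fit Monte-Carlo checks use 100–200
seeded replicates of single curves.

## Reproduction report

`reproduce_paper()` recomputes, from the bundled panel alone: the subunit
coefficients and adjusted R² of both factor models, the label-invariant
extreme compound coefficients, the CHAID root split and the
no-Dα1/no-Dα2/with-Dα3 node mean (7.506, n = 8), five pEC50→EC50
conversions, the imidacloprid Dα3/Dβ1 vs Dα1/Dβ1 fold change, and the sign
and significance of the +Dα2 lattice summary. Tolerances follow the printed
precision: ±0.001 on coefficients and node means (3 decimals), 1% on EC50
conversions and fold changes (3 significant figures).

## Known limitations

- Hill-fit SEs are asymptotic; for 8-point curves they can understate
  uncertainty near bounds.
- The lattice CI treats overlapping edges as independent.
- The factor model assumes additivity; receptor-specific interactions
  (e.g. Dα1×Dα3) are absorbed into residual. The generator can be pointed at
  non-additive surfaces only by editing the truth table it returns.
- CHAID p-values under the default greedy growth are descriptive.
- pEC50 estimates are confined to ±1 decade beyond the tested concentration
  window; on truly unmeasurable curves (efficacy below the noise floor) the
  estimate is a censored guess and should be judged by its SE and the
  `extrapolated_plateau` flag.
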