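# Methods

## Pipeline overview

The analysis estimates one network over all measured variables, partitioned
a priori into layers (mental health, cognition, gray-matter volume — the
partition is data, not inferred).  Stages, in order:

1. **Residualization.**  Each node is replaced by its OLS residual on its
   covariate set: age (years) for every node; age, total intracranial
   volume (TIV, mm³) and acquisition site for GMV nodes.  Site enters via
   reference-cell dummy coding (first category in sorted order is the
   reference; the choice cannot affect the residuals, only the coefficient
   parameterization).  Residualization is idempotent and never increases a
   node's variance; both properties are tested.
2. **Correlation.**  Pairwise correlations with per-pair method choice:
   Spearman if either variable is ordinal (all-integer values with ≤ 7
   distinct levels) or fails a Shapiro–Wilk normality screen at α = 0.05,
   Pearson otherwise.  Mixing methods can make the matrix indefinite, so it
   is projected to the nearest positive-semidefinite correlation matrix by
   eigenvalue clipping (floor 1e-8, rescaled to unit diagonal); an already
   PSD matrix passes through unchanged.
3. **Network estimation.**  Graphical LASSO along a log-spaced descending
   penalty path from λ_max = max|off-diagonal of S| to λ_max/100 in 100
   points; the Extended Bayesian Information Criterion with γ = 0.5 selects
   the model, ties resolving to the larger penalty (sparser network).
4. **Bridge centrality.**  Bridge strength = sum of absolute interlayer
   edge weights; bridge nodes are strictly above the 80th percentile
   (linear interpolation between closest ranks) of the raw strengths.
5. **Stability.**  Case-dropping bootstrap of the bridge-strength profile
   and the correlation-stability (CS) coefficient.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `gamma` | 0.5 | EBIC sparsity preference; 0 recovers BIC |
| `n_lambdas` / `lambda_min_ratio` | 100 / 0.01 | penalty-path resolution and depth |
| `edge_zero_tol` | 1e-6 | \|w_ij\| at or below this counts as no edge (density, bridge sums) |
| `percentile` | 80 | bridge-designation threshold on raw strengths |
| drop grid | 0.05–0.75 by 0.05 | case-dropping proportions |
| `n_boot` | 2000 | bootstrap replicates (spread over the grid) |
| `r_threshold`, `prob` | 0.70, 0.95 | the CS rule: retain r ≥ 0.70 with 95% probability |

Density bands: ≥ 50% of possible edges "high", 30–50% "medium", < 30%
"low".  CS bands: ≥ 0.50 stable, 0.25–0.50 caution, < 0.25 uninterpretable.

## Numerical choices

- **EBIC likelihood.**  L = (n/2)(log det K − tr(SK)) without the additive
  constant np/2 of the saturated fit.  The empty model K = I on S = I
  therefore scores np, not 0; since the offset is constant in K it cannot
  change which model the criterion selects.
- **Unpenalized limit.**  λ = 0 is solved by direct matrix inversion (the
  analytic MLE) rather than coordinate descent; the estimated partial
  correlations then equal the classical residual-based partial
  correlations, which is tested against a regression oracle.
- **Solver.**  The L1 solver is scikit-learn's coordinate-descent graphical
  lasso (off-diagonal penalty only, matching the objective above),
  tol 1e-4, max 200 sweeps.  At very small penalties on near-singular
  correlation matrices the solver may stop at its iteration cap with a
  dual gap within rounding of the tolerance; such estimates are used as-is.
  A path point where the solver fails outright is dropped with a warning
  rather than aborting the whole path.
- **Ties and degenerate cases.**  EBIC ties go to the sparser model.  An
  all-tied strength profile designates no bridges (strict inequality at the
  threshold).  A bootstrap replicate whose strength vector is constant has
  no defined correlation; it is recorded as missing and excluded from that
  proportion's tally.  Grid proportions leaving ≤ p + 2 participants are
  skipped with a warning.
- **CS location rule.**  CS is the largest drop proportion such that *all*
  smaller grid proportions also pass the 95%/0.70 rule, so an isolated
  non-monotone fluke cannot inflate it.

## The synthetic cohort generator

The generator emulates the study conditions the pipeline is designed for: a
multicentre cohort of n = 457 participants measured on 4 ordinal
mental-health nodes, 6 continuous cognitive nodes and 8 GMV nodes.

- **Dependence structure.**  A sparse precision matrix with Bernoulli
  off-diagonal support — within-layer density 0.6, between-layer 0.1, with
  between-layer entries scaled by 0.7 — so that, as in real
  brain–behaviour data, the strongest conditional associations are within a
  domain and cross-domain ones are sparse and weak.  Entry magnitudes are
  uniform on [0.2, 0.4]; 30% of implied partial correlations are negative.
  Positive definiteness is enforced by adding δ·I with doubling δ until the
  smallest eigenvalue is ≥ 0.05, which preserves the support exactly.
- **Confounding.**  Age (truncated normal, mean 38.3, SD 16, range 17–83
  years) loads on every node with standardized coefficient 0.25; TIV
  (normal, mean 1.5e6, SD 1.5e5 mm³) on GMV nodes at 0.4; site offsets
  (4 sites, per-node offsets drawn N(0, 0.3)) on GMV nodes only.  Four
  sites rather than the dozens of a large multicentre study keep per-site
  cell counts realistic at desk-scale sample sizes; what the pipeline must
  remove is the additive site shift, which does not depend on the count.
- **Ordinal nodes.**  Mental-health nodes are discretized at the empirical
  quantiles 0.50/0.75/0.90/0.97 of their latent values into 5 levels
  (0–4), reproducing the right-skew of symptom questionnaires where most
  respondents score low.
- **Planted bridge models.**  For recovery experiments,
  `make_planted_bridge_model` makes the bridge set identifiable by
  construction: the four designated nodes are pairwise connected across
  layers, each gains two further cross-layer edges to distinct
  non-designated partners, and no non-designated node carries more than one
  between-layer edge.  Within-layer support and all weights stay random.

What the generator does **not** emulate: realistic neuroanatomy or
questionnaire item content, missing data (the pipeline requires complete
cases), longitudinal structure, non-additive or nonlinear confounding, and
heavy-tailed measurement noise.  Passing recovery tests therefore shows the
estimator chain is correct under its own assumptions — not that any
particular clinical dataset satisfies those assumptions.

## Design decisions

- **Correlation for ordinal pairs.**  Ordinal-involving pairs use Spearman
  rather than polychoric/polyserial correlations: rank correlation is
  monotone-robust, needs no latent-threshold estimation, and handles the
  5-level sum-score coarseness well.  Polychoric input is a possible
  extension; note that in practice ordinality is mostly moot here because
  residualization (which precedes correlation) turns integer scores into
  continuous residuals that then fall under the normality screen.
- **Welch t-test** for group comparisons (unequal variances assumed), with
  Benjamini–Hochberg FDR across the variables compared in one call.
  Zero-variance-in-both-groups variables report p = 1 with a `degenerate`
  flag rather than NaN.
- **Insomnia Severity Index bands** use the instrument's standard
  cutpoints: 0–7 none, 8–14 subthreshold, 15–21 moderate, 22–28 severe.
- **Model/Results shape.**  The library is organised around a model object
  (`MultilayerGGM`) whose `fit()` returns a results object carrying the
  network, bridge profile, summary table and (on demand) stability — the
  pattern used by mainstream statistical modelling packages — with the
  stage functions (`estimate_network`, `bridge_strength`,
  `case_drop_bootstrap`, …) importable directly for scripting.
- **Serialized weights are never clamped** or thresholded for display;
  any visual emphasis of small edges belongs to plotting code only.

## Problem sizes

Bootstrap-heavy checks run with a 30-point penalty path and ~100–150
replicates; the recovery experiments use 10 seeds at n = 2000.  These sizes
give stable pass/fail behaviour for the properties tested (the CS contrast
between n = 2000 and n = 60 is large) while a full-fidelity run —
`n_boot=2000`, 100 path points — remains the library default.

## Known limitations

- Spearman substitution for ordinal pairs differs numerically from the
  polychoric correlations some psychometric toolchains compute; edge
  weights are therefore not pairwise comparable to analyses using them.
- The EBIC-selected density is sensitive to n/p; at small samples the
  selected network can be empty, in which case bridge strengths are all
  zero and the CS coefficient is 0 by construction.
- The case-dropping bootstrap re-runs the full estimator per replicate;
  cost grows linearly in `n_boot` and the path length.
- CS interpretive cutoffs (0.25/0.50) were calibrated for single-layer
  psychometric centrality indices; for multilayer bridge centrality they
  should be read as conventions, not guarantees.
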