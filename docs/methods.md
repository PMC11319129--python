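# Methods

## Scientific setting

`rhizostoich` analyses plot-level data from factorial forest-soil
experiments in which stands of several ages receive graded nitrogen
additions, and each plot contributes paired rhizospheric and
non-rhizospheric ("bulk") soil samples, rhizosphere extracellular enzyme
activities, and fine-root chemistry.  The package asks two coupled
questions: how strongly roots condition the soil around them
(rhizosphere effects), and which nutrient — N or P — limits the fine
roots and the rhizosphere microbial community (stoichiometric vector
analysis).

## Rhizosphere effects

For each soil variable v (SOC, TN, TP, NH4+-N, NO3--N, AP) and plot,

    RE_v = (C_rhizo - C_bulk) / C_bulk * 100  [percent]

REs are computed per plot from its own pair and only then averaged over
groups.  Computing them from group-mean concentrations instead would
discard the pairing and bias group contrasts; the per-pair form is the
one the field uses.  RE is scale-invariant, antisymmetric in sign under
exchange of the compartments, and bounded below by -100 when
concentrations are non-negative.  No log-ratio variant is offered in the
core output.

## Ecoenzymatic vector analysis

Let B = ln(BG), N = ln(NAG + LAP), P = ln(ACP) be the natural logs of
the C-, N- and P-acquiring activities (nmol g-1 h-1).  With the point
(x, y) = (B/P, B/N):

* vector length  = sqrt(x² + y²)  — relative microbial C limitation;
* vector angle   = atan(P/N) in degrees — > 45° relative P limitation,
  < 45° relative N limitation;
* microbial N limitation = atan(N/P) = 90° − vector angle — an
  increasing index of microbial N limitation;
* enzymatic N:P acquisition ratio N:P_SEE = N/P — crosses 1 exactly
  where the angle crosses 45°.

The angle formulas are implemented as single-argument arctangents of
positive ratios.  Spreadsheet-style two-argument ATAN2 conventions are
ambiguous about argument order; the single-argument form is fixed by the
two anchor facts that define the method — the angle is 45° when the N-
and P-acquiring activities are equal, and angles above 45° mean P
limitation.  The log-domain guard requires BG, NAG+LAP and ACP each to
exceed 1 nmol g⁻¹ h⁻¹ so that every log is strictly positive; inputs
below that raise an error rather than being clamped, because clamping
could silently flip a limitation call.  A unit rescale applied *before*
analysis (and recorded in the schema) is the supported way to handle
assays reported on other scales.  None of these metrics is invariant to
rescaling all activities by a common factor — an inherent property of
ln-ratio stoichiometry that the tests document rather than "fix".

## Root N:P vector classification

Fine-root N:P (mass ratio TN/TP, both mg g⁻¹) is classified through the
angle of the point (TN, TP) from the TN axis:

    root vector angle = atan(TP/TN)  [degrees]

The conventional foliar/root thresholds N:P = 14 (N limitation below)
and N:P = 16 (P limitation above) map to angles atan(1/14) = 4.0856° and
atan(1/16) = 3.5763°, conventionally printed as 4.09° and 3.58°.  Angles
above the high threshold call N limitation, below the low threshold P
limitation, between them neither.  Ties sitting exactly on a threshold
are classified as unlimited, matching the strict inequalities of the
rule.

The printed 2-dp thresholds are *roundings*: with 4.09° the angle rule
and the ratio rule disagree on the sliver N:P ∈ (13.985, 14.000) (and
analogously near 16).  `angle_threshold_from_np` supplies the exact
thresholds; the coherence checks use them, while the printed values
remain the config defaults for fidelity to common practice.  Both are
overridable per run.

## Standardized major axis fits

Enzyme stoichiometry scaling (ln-activity C:N, C:P, N:P pairs) is fitted
with standardized major axis regression: |slope| = sd(y)/sd(x), sign
from the Pearson correlation, intercept through the means.  SMA is the
appropriate symmetric line for stoichiometric scaling where neither
variable is the predictor.  Fits are reported per age class by default
(pooled on request); no bootstrap confidence intervals in core.

## Inferential statistics

* **Two-way ANOVA** (age × N level, fixed effects, with interaction).
  Balanced designs use the closed-form cell-means decomposition — exact,
  and fast enough for thousands of Monte-Carlo replicates.  Unbalanced
  data fall back to Type-II sums of squares via statsmodels OLS with a
  warning (on balanced data the types coincide; Type II is the least
  surprising default otherwise).  Blocks are not modelled by default —
  the residual then absorbs block variation, matching the degrees of
  freedom of the standard reporting layout — with an optional additive
  block term.
* **LSD comparisons**: unadjusted pairwise t tests on the residual mean
  square, t = (mᵢ − mⱼ)/√(MSE(1/nᵢ + 1/nⱼ)) on the residual df.  Compact
  letters come from the maximal cliques of the non-significance graph
  (exact subset enumeration; group counts here are ≤ 5), so two groups
  share a letter exactly when their pairwise p ≥ α.  LSD is deliberately
  unadjusted for multiplicity; no Tukey/Holm in the core path.
* **Pearson matrices** with two-sided p from the t transform on n − 2 df;
  stars at 0.05/0.01/0.001 in display columns only.
* **Trend fits**: OLS polynomials of order 1 or 2 on the ordinal N-level
  index, with R², the overall F-test p, and a 95% confidence band of the
  mean response.  "Non-linear" responses are modelled as quadratics;
  no exponential or asymptotic families, since nothing constrains the
  functional form.

All p-values are two-sided; α defaults to 0.05.

## Synthetic data generator

The generator emulates the 3 × 5 × 3 design with one pooled sample per
plot (no tree-level records — the plot is the atomic replication unit).

* **Noise model.**  Multiplicative lognormal noise with mean 1 and a
  per-family CV (soil 0.15, rhizosphere-specific 0.10, enzymes 0.15,
  roots 0.08) keeps every concentration positive, as the log-ratio
  mathematics requires; additive Gaussian noise could not.
* **Rhizosphere pairing.**  The rhizosphere concentration is the
  *realized* bulk value × (1 + RE_true/100) × independent mean-one
  noise.  Paired samples from one plot share the plot's realization of
  soil variation — which is what physical pairing means — and the
  per-plot realized RE is then (1 + RE_true/100)·ε − 1 with E[ε] = 1,
  i.e. unbiased for RE_true.  Had the rhizosphere been drawn around the
  bulk *expectation* with its own independent noise, the plot-level RE
  would inherit a Jensen bias of ≈ +1.3 percentage points at CV = 0.10
  (E[ε_r/ε_b] = exp(σ²) > 1), and mean-RE recovery would be biased by
  construction.  Recovery is still assessed on means over replicates,
  not single plots, since individual plot REs fluctuate with ε.
* **Baselines.**  Bulk soil near 20 g kg⁻¹ SOC, 1.5 g kg⁻¹ TN,
  0.55 g kg⁻¹ TP, with available pools of a few mg kg⁻¹ — typical
  temperate-forest topsoil.  Enzyme baselines are anchored so the
  noise-free ln-activity C:N:P stoichiometry is exactly 1 : 1.30 : 1.08
  (NAG+LAP = BG^1.30, ACP = BG^1.08 with BG = 30 nmol g⁻¹ h⁻¹), the
  ratio regime of temperate pine rhizosphere soil, which also puts the
  microbial vector angle at 39.7° (N-limited).  Root TN = 12, TP =
  0.92 mg g⁻¹ give N:P ≈ 13, inside the N-limited regime but close
  enough to 14 that realistic noise exercises both call branches.
* **Trends.**  Cell expectations are baseline × age factor × N factor,
  with factors 1 + lin·(i − ī) + quad·(i − ī)² on the centered ordinal
  index (validated positive).  Defaults impose mild, ecologically
  signed trends: N addition raises root TC/TN/TP with TP/TN falling
  (N limitation relieved by N supply), and older stands have relatively
  N-poorer roots (limitation deepens with succession).  Everything else
  is flat by default; `SyntheticConfig.null()` gives the no-effect,
  zero-RE configuration used for calibration.
* **Root TN–TP copula.**  A Gaussian copula on the log scale with target
  correlation 0.7.  The natural-scale Pearson r differs from the log-
  scale target by O(cv²) ≈ 0.005 at the default CV — inside the ±0.03
  band the generator promises.
* **Streams.**  One RNG stream per variable, spawned from the master
  seed in a fixed order, so adding a variable never perturbs another's
  draws, and (config, seed) determines the dataset bit-for-bit.

### What the generator does not emulate

Spatial rhizosphere gradients, temporal dynamics, tree-level
heterogeneity within plots, measurement censoring/detection limits, and
block effects (blocks replicate but carry no systematic offset by
default).  Passing tests therefore show that the *methods* are correct
and calibrated under the stated noise model, not that any particular
field system behaves this way.

## Numerical and design choices

* Angles exactly on a classification threshold (within 1e-9°) are
  called "balanced"/"unlimited" rather than assigned a side.
* The N-application level is ordinal (N0..N4) with the nominal rate kept
  as an annotation only; trend fits use the ordinal index.  Printed
  per-area rates in source field layouts are often inconsistent with
  plot dosing masses, so the label is the reliable quantity.
* Missing values are rejected, not imputed: the designs are balanced and
  imputation would silently change ANOVA sums of squares.
* Validation at construction enforces positivity; the stricter
  log-domain rule is enforced at the vector formulas and *reported* by
  `validate_dataset`.
* Monte-Carlo problem sizes: statistical calibration uses 2 000
  replicate null datasets (type-I error), recovery 200 replicate
  datasets of 45 plots, copula checks 6 000–10 000 plots.  At these
  sizes the binomial half-width of the type-I estimate is ≈ 0.010,
  small against the [0.03, 0.07] acceptance band.

## Known limitations

* The unbalanced ANOVA fallback reports Type-II sums of squares only.
* Compact letter displays support at most 20 groups (exact clique
  enumeration).
* SMA has no confidence intervals; trend fits have no model selection —
  both orders are always reported and the reader chooses.
* The generator's RE is constant across N levels within an age class
  (RE trends along the N gradient are outside its parameter space), so
  synthetic RE-vs-N trend fits are null by construction.
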