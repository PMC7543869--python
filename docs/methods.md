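# Methods

## Scope and model

`ceskit` treats a post-MDA coverage evaluation survey as a two-part
problem: (1) the *design* — how households and individuals are selected
from a district sampling frame under each of three field protocols (EPI
cluster survey, stratified LQAS, probability sampling with segmentation);
and (2) the *analysis* — design-based estimation of the coverage
proportion with uncertainty that respects the selection mechanism. A
synthetic-district generator supplies fully enumerated populations with
known truth, so the statistical properties of each design (bias,
variance, CI calibration, classification error) are established by
simulation against a census rather than asserted.

"Epidemiologic coverage" is the estimand throughout: treated individuals
over *all* individuals, not only those eligible.

## Synthetic districts

A district is a list of supervisory areas (SAs, default 5) holding PSUs
(villages / enumeration areas) in geographic order; each PSU holds
households with planar coordinates, each household holds individuals.

* **PSU household counts** are lognormal (default mean 80, log-sd 0.6),
  rounded, floored at 5. The floor plus the heavy right tail guarantee
  that one generated district exercises every code path: single-segment
  PSUs, multi-segment PSUs, multi-hit PPES selections, and the
  segment-then-enumerate LQAS fallback. No distributional claim about
  real districts is intended; defaults were chosen once for path
  coverage.
* **Household sizes** are 1 + negative binomial (default mean 5,
  dispersion 4), a standard overdispersed size model truncated at one
  person.
* **Coordinates** are uniform in a unit disc per PSU with the "village
  centre" at the origin. This gives the EPI random-direction step and
  nearest-neighbour walk a concrete geometry; real settlements are not
  radially uniform, so EPI bias magnitudes measured here characterise
  the mechanism, not any particular country.
* **Treatment truth** is beta-binomial: PSU-level coverage
  `p_j ~ Beta(a, b)` with mean equal to `mean_coverage` and
  `1/(1+a+b) = coverage_icc`, then per-individual Bernoulli with
  log-odds `logit(p_j) + spatial_effect·(distance from centre) +
  hh_size_effect·(household size − mean size)`. With both effects zero
  the ANOVA intraclass correlation of treatment converges to
  `coverage_icc` (verified to ±0.05 at 500 PSUs × 50 households). The
  two effects are the levers that make the non-probability designs
  demonstrably biased: the EPI walk starts at the centre, so a radial
  gradient shifts it; S-LQAS samples one person per household, so a
  household-size gradient shifts it.
* **Nonresponse** is a per-individual present flag (default absence
  10%) and a proxy-availability flag (default 80%): an absent individual
  with a proxy yields a proxy response, otherwise the designs follow
  their own protocols (EPI/PSS: drop, no make-up; S-LQAS: move to the
  nearest household and redraw). Proxy answers are taken as accurate;
  no proxy-error model is attempted. The field practice of
  return visits is collapsed into these flags.
* **Registers**: each PSU has a Bernoulli "household register exists"
  flag (default 0.5) so all three S-LQAS household-selection routes
  (register, leader enumeration ≤150 households, segment-then-enumerate)
  are reachable. The 150-household enumeration limit is a configurable
  convention; field practice names no number.

Frames export/import losslessly as two CSVs (`psus.csv`,
`individuals.csv`) plus a config JSON; export is byte-stable for a fixed
seed.

## Design computations

* **Sample size** `n = DEFF·z²·P(1−P)/δ²`, then `n/(1−r)`. Rounding is
  half-away-from-zero to the nearest integer — the only convention
  consistent with the canonical quartet 1537 / 1808 / 96 / 384 (e.g.
  1536.64 → 1537, 1808.24 → 1808); the convention is inferred, not
  stated, in the source material, and is flagged here for that reason.
* **Segment counts**: `max(1, round(households/50))`. The floor at 1 is
  a deliberate choice: the round-to-nearest rule alone would assign zero
  segments — hence zero selection probability — to PSUs under 25
  households.
* **Sampling fraction** `f = target_n / (30·avg_hh·50·(1−r))`; `f > 1`
  is an error (the design cannot reach the target).
* **PPES selection** is single-pass systematic over the geographically
  ordered frame: interval `I = Σsize/k`, one uniform start, `k` points;
  large units may be hit multiple times. The geographic ordering is what
  the paired variance model later exploits as implicit stratification.

## Samplers

All three samplers are seeded, deterministic procedures over a frame.
Decisions the field manuals leave to circumstance are resolved as
follows:

* EPI "spin a pen": a uniform bearing with a sector of half-width 15°,
  doubled until it contains a household; uniform start within the
  sector. Nearest-neighbour is Euclidean with ties broken by household
  id. A cluster that exhausts its PSU before quota stops at the border
  and records a shortfall.
* The EPI quota counts interviewed individuals, and the final household
  is always completed, so cluster takes overshoot the quota by up to one
  household.
* S-LQAS: a village hit twice by PPES contributes two independent
  household draws. The selected individual is drawn uniformly from the
  full household roster.
* PSS: households are put in polar-angle order around the PSU centre
  before being cut into the predetermined number of contiguous segments
  (sizes as equal as possible, remainder spread one per segment) — an
  area-like contiguity proxy. A PSU hit twice contributes two
  independent segment draws. Within a segment, systematic selection uses
  interval `1/f` with a uniform fractional start.

## Estimation

The `CoverageSurvey` → `fit()` → `CoverageResults` surface mirrors
standard statistical-modelling APIs.

* "Not sure" responses are excluded from numerator and denominator
  before anything else; an all-not-sure drug raises an explicit
  undefined-estimate error rather than returning 0/0.
* **EPI/PSS variance** is the collapsed-pair (paired selection) form on
  selection events in frame order: with per-cluster treated `y_i` and
  valid `x_i`, `r = Σy/Σx`, `z_i = y_i − r·x_i`,
  `v = [Σ_pairs (z_a − z_b)²] / (Σx)²`; an odd cluster count collapses
  the last three clusters into a triple whose squared deviations from
  the triple mean carry the standard 3/2 factor. DEFF is `v` over the
  binomial variance `p̂(1−p̂)/n`.
* **S-LQAS** uses `p̂ = Σ W_h p̂_h` with `W_h` proportional to projected
  SA population and `v = Σ W_h² p̂_h(1−p̂_h)/(n_h−1)`; the `n_h−1`
  denominator is the unbiased within-stratum choice.
* **Confidence limits** are Wald: `p̂ ± z_{α/2}·se` truncated to [0,1],
  plus a one-sided lower limit at `z_α` (1.645 at 95%). No
  transformation or exact interval is attempted; at the sample sizes
  these designs produce, Wald limits are the convention the reported
  tables use.
* **Decisions**: the "threshold met" flag is decided on the
  whole-percent rounded point estimate (the convention consistent with
  published decision columns), a separate flag reports whether the
  one-sided lower limit clears the threshold, and "reported coverage
  validated" means the reported figure lies in the *closed* two-sided
  CI.

### What the paired estimator estimates

Under systematic PPS the realized variance is conditional on how cluster
effects happen to be arranged along the ordered frame; on any single
frame it can sit tens of percent above or below the with-replacement
expectation the paired estimator targets (we measured single-frame
ratios of 0.6–1.65 at ICC 0.1–0.3). The estimator is validated in
expectation over the generator: pooled across 25 frames × 80 replicates
the mean estimated variance matches the empirical replicate variance to
within a few percent (measured ratio 0.98), and pooled two-sided 95%
CIs cover census truth at 94–95%. Single-survey variance estimates on a
specific district inherit the usual conditional uncertainty of
collapsed-stratum estimators.

## LQAS rules

Operating characteristics are exact binomial (`P(X ≥ d)` via the
survival function). `find_decision_rule` returns the admissible rule
(both error caps met) with the smallest α, ties to smaller `d`. The
package's default lower threshold is `p_upper − 0.30`: exhaustive search
over `d` shows 0.30 is the smallest gap at which `n = 19` admits a rule
with both errors below 10% at all of the conventional 65/75/80%
programme thresholds (the minimal gaps are 0.30, 0.30, 0.29). A 0.25
gap — sometimes assumed — admits no such rule at n = 19; users asserting
tighter alternatives must either grow `n` or accept larger errors.
Classification excludes "not sure" responses first, so an SA can be
undersized relative to the rule's `n`; it is classified anyway and
flagged, never padded.

## Simulation harness

`run_comparison` replays R independent surveys per design on one frame.
Seeds derive from a master seed through `SeedSequence(master,
spawn_key=(design_index,))` spawned per replicate, so designs never
share streams. Presence/proxy flags are redrawn per replicate while
treatment truth stays fixed: summaries therefore measure design
variance, not population variance. Failures (e.g. an undefined
estimate) are counted and reported, never silently dropped.

## Simulation sizes and numerical conventions

Monte-Carlo checks pool replicates across several generated frames
(5–25 frames, 60–400 replicates each, totals matching the stated
replicate counts of 1,000–2,000 per check; the LQAS error-rate check
uses 10,000 simulated lots). Pooling across frames is essential for the
variance and zero-bias checks for the conditional-inference reason
above. Study conditions were fixed once: mean coverage 0.7, ICC 0.05
(0/0.1/0.3 where a check spans the ICC range), spatial effect −1.5 and
household-size effect +0.3 for the bias demonstrations — values
representative of a reasonably well-run MDA with moderate geographic
heterogeneity.

## Known limitations

* The disc geometry and angle-ordered segmentation are idealisations;
  EPI bias magnitudes transfer qualitatively, not quantitatively, to
  real settlements.
* Proxy responses are error-free; recall error and differential recall
  across drugs are not modelled.
* First-stage selection is treated as with-replacement for variance
  purposes (no finite-population correction); on frames where 30
  clusters are a large share of all PSUs the estimator is accordingly
  conservative in expectation.
* Single-district frames only; no cost or field-logistics modelling.
* The age-restricted (preschool-children) eligibility variant of the
  sampling-fraction formula is out of scope.
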