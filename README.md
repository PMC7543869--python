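# ceskit

Design, simulation and analysis of **coverage evaluation surveys (CES)**
for mass drug administration (MDA) campaigns against neglected tropical
diseases. After an MDA round a programme needs to know what fraction of
the target population actually swallowed the drugs; `ceskit` implements
the three sampling designs used in practice for that question, end to
end, together with a synthetic-district generator so that every claim
about the designs can be checked by simulation:

* **EPI cluster survey** — 30 clusters selected by systematic
  probability-proportional-to-estimated-size (PPES) sampling on
  population; within each cluster a random direction from the village
  centre picks a start household and a nearest-neighbour walk enrols
  whole households until a per-cluster quota is met. Fast, familiar, and
  *not* a probability sample.
* **Stratified LQAS (S-LQAS)** — the district is split into five
  supervisory areas (SAs); 19 villages per SA are drawn by PPES on
  household counts, one household per draw and one randomly chosen
  member per household. Each SA is classified against a coverage
  threshold by a lot-quality decision rule, and a population-weighted
  stratified estimate is produced for the district.
* **Probability sampling with segmentation (PSS)** — each PSU is
  assigned `round(households / 50)` segments; 30 PSUs are drawn by PPES
  on segment counts, one segment is chosen at random per hit, and a
  fixed fraction *f* of its households is taken systematically, enrolling
  every member. The PSU and segment terms cancel, so every individual in
  the district has inclusion probability `30·f / (total segments)` — an
  equal-probability design whose point estimate needs no weighting.

The core quantities, in the field's notation:

* Sample size: `n = DEFF · z²_{α/2} · P(1−P) / δ²`, inflated by
  `1/(1−r)` for anticipated nonresponse `r`.
* Within-segment sampling fraction:
  `f = target n / (30 · avg household size · 50 · (1−r))`.
* LQAS operating characteristic: a lot of size `n` is classified
  "reaching the target" when at least `d` of `n` respondents report
  treatment; `α = P(X < d | p_upper)`, `β = P(X ≥ d | p_lower)` with
  `X ~ Binomial(n, p)`.
* Variance for the cluster designs uses the Kish paired-selection
  (collapsed stratum) model on clusters taken in geographic frame order;
  S-LQAS uses exact stratified-proportion theory.

## Worked example

```python
import ceskit as ck

# a synthetic district: 100 villages in 5 supervisory areas
frame = ck.generate_frame(ck.FrameConfig(seed=42))
print(ck.true_coverage(frame, "alb"))          # 0.7958... (census truth)

# PSS survey at the fraction implied by a target sample of 1,537
f = ck.sampling_fraction(1537, 30, float(frame.hh_size.mean()), 50, 0.0)
sample = ck.pss_survey(frame, f=f, seed=1)

result = ck.CoverageSurvey(sample).fit(threshold=0.65, reported=0.81)
print(result.summary())
```

prints

```
Coverage survey estimates (pss design, 95% confidence)
------------------------------------------------------------------------------
drug          n  treated  cov%      2-sided CI  lower 1-sided    DEFF
alb        1340     1067    80        (75, 84)            76    4.86
          target 65%: met; reported 81%: validated
```

i.e. 1,340 valid interviews ("not sure" answers are dropped from both
numerator and denominator), an estimated coverage of 80% with a
paired-selection 95% CI of (75, 84), a one-sided lower 95% limit of 76%
— above the 65% programme threshold — and an administratively reported
coverage of 81% that falls inside the CI and is therefore validated.

The same surface drives the other designs (`ck.epi_survey`,
`ck.slqas_survey` with `stratum_weights=frame.sa_populations()`), the
LQAS rule machinery (`ck.find_decision_rule(19, 0.80, 0.50)` →
`d=13, α=0.068, β=0.084`), and the Monte-Carlo comparison harness
(`ck.run_comparison(frame, ["epi", "slqas", "pss"], R=1000, seed=0)`).

Everything is also scriptable from the shell via the `ces` command:
`ces samplesize`, `ces generate`, `ces select`, `ces survey`,
`ces lqas`, `ces estimate`, `ces simulate` (see `ces --help`).

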