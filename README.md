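# motionqc

Head motion during MRI scanning biases automated estimates of brain
anatomy: participants who move produce T1-weighted (T1w) images with
ringing and blurring artifacts, and automated morphometry run on those
images systematically *underestimates* gray-matter thickness and volume.
Because a conventional T1w acquisition carries no intrinsic motion trace,
this bias is invisible unless it is inferred from somewhere else.
`motionqc` implements a practical inference route for studies that also
collect fMRI in the same session: a participant's tendency to move is
stable within a scan session, so framewise displacement summarised from
the fMRI realignment parameters can stand in as a motion index for the
T1w scan. The package is aimed at structural-neuroimaging groups (aging,
developmental and clinical cohorts in particular, where motion covaries
with the variables of interest) who want an objective, reproducible
flagging step next to their visual quality control.

## What it computes

**Framewise displacement.** For a run with rigid-body realignment
parameters (translations in mm, rotations in radians), rotations are
converted to arc length on a sphere of radius *r* = 50 mm and

FD(t) = Σ_i |Δd_i(t)|,  i over the six parameters,

the sum of absolute frame-to-frame changes. Run-level mean FD is averaged
within task and then across the four task types, giving the participant's
session-level motion index FD̄_all-task (so tasks with more runs or more
frames get no extra weight).

**Flagging rule.** A participant is flagged when

FD̄_all-task > mean + 1.5 × SD  (sample statistics, n−1 denominator)

or when the composite visual QC rating — the most stringent of the
raters' pass/warn/fail judgements — is *fail*.

**The statistics battery.** Around the flag rule the package provides the
full analysis suite for quantifying motion-related bias: Spearman
cross-run stability matrices with permutation nulls; Cohen's κ and
cohort-wise rating chi-squares; Kruskal–Wallis and rank-sum contrasts of
FD̄ across rating groups; sensitivity/specificity of *fail* ratings for
high-FD detection with a resampling null; ANCOVA (type III sums of
squares, partial η²) with a permutation test on the change in the age
effect size; vertex-wise full-partial correlation maps of thickness
against FD̄ with Benjamini–Hochberg FDR; age- and gender-matched
bootstrap nulls for the flagged group's mean thickness; leave-out control
envelopes for the post-flagging correlation CDF; vertex-wise group
t-maps; and before/after-flagging comparisons of the age effect
(Bartlett, Fisher-z, Kolmogorov–Smirnov, parcel-wise Δz(r)).

**Synthetic cohorts.** Because the motivating study's data are not
publicly deposited, `motionqc.synthetic_data` generates complete
lifespan cohorts with known ground truth: log-normal motion propensity
increasing with age (age–FD̄ Spearman ρ calibrated to 0.44), stable
cross-run ranks (run-pair ρ ≈ 0.8), two-rater ordinal ratings coupled to
motion (κ ≈ 0.48), and thickness maps with age-related thinning plus a
regionally confined motion bias. Every pipeline input file can be written
out and re-ingested, and a truth table supports parameter-recovery tests.

## Worked example

```python
import json
from motionqc import (GeneratorConfig, generate_cohort, write_cohort,
                      PipelineConfig, run_pipeline)

cohort = generate_cohort(GeneratorConfig(seed=7))     # n=266, ages 20-89
paths = write_cohort(cohort, "example_cohort")

cfg = PipelineConfig(
    outdir="example_out",
    covariates=paths["covariates"], manifest=paths["manifest"],
    realignment_dir=paths["realignment_dir"], ratings=paths["ratings"],
    thickness=paths["thickness"], parcels=paths["parcels"],
    n_perm=10_000, n_boot=10_000, n_envelope_groups=500, seed=7,
)
run_pipeline(cfg)

flags = json.load(open("example_out/flags.json"))
overlap = json.load(open("example_out/overlap.json"))
ancova = json.load(open("example_out/ancova.json"))
boot = json.load(open("example_out/matched_bootstrap.json"))
print("flagged:", flags["meta"]["n_flagged"], "of 266",
      "(threshold", round(flags["meta"]["threshold"], 3), "mm)")
print("sensitivity:", round(overlap["sensitivity"], 2),
      "specificity:", round(overlap["specificity"], 2))
ch = ancova["effect_size_change"]
print("age eta-squared:", round(ch["eta_sq_without"], 2), "->",
      round(ch["eta_sq_with"], 2), " reduction p =", round(ch["p_perm"], 3))
print("flagged-group mean thickness p =", round(boot["p"], 5))
```

prints

```
flagged: 33 of 266 (threshold 0.235 mm)
sensitivity: 0.61 specificity: 0.96
age eta-squared: 0.59 -> 0.49  reduction p = 0.001
flagged-group mean thickness p = 0.0001
```

Read: 33 participants are flagged (the all-task FD̄ threshold lands at
0.235 mm); *fail* ratings alone would catch 61% of the high movers in
this cohort while retaining 96% of the quiet ones; controlling for motion
and QC shrinks the apparent age effect on mean thickness from η² = 0.59
to 0.49, a reduction larger than any of 1,000 permutations produced; and
the flagged group's mean thickness is lower than essentially every one of
10,000 age- and gender-matched bootstrap samples.

The same run is available from the shell:

```sh
motionqc generate --out example_cohort --seed 7
motionqc all --config pipeline.yaml
```

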