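# sofpipe

Movement-ecology pipeline for a marine **seascape of fear**: how a
central-place-foraging seabird (the Cape gannet, *Morus capensis*)
rearranges its days and nights at sea around the predation risk posed by
Cape fur seals (*Arctocephalus pusillus pusillus*), competition with
purse-seine and trawl fisheries, and sea-surface temperature, in the
Benguela upwelling system.

The package is written for movement ecologists who have tracking data
(GPS trips of a central-place forager, Argos fixes of its predator),
environmental rasters and fisheries log-book grids, and want to run the
full analysis chain as tested, reusable code:

1. **Trajectory descriptors** — 1-min track reinterpolation, speed
   smoothed over the two steps before and after each fix, turning angle
   at constant step length (the angle at the focal fix between the
   backward and forward crossings of a circle with radius equal to the
   track's median step length), and solar day/night annotation.
2. **Segmentation-clustering** into rest / forage / commute phases:
   exact dynamic-programming segmentation under per-class bivariate
   Gaussian likelihoods, classification-EM refinement, BIC-style choice
   of the number of segments, and classification of each trip's
   nocturnal tactic (*rest at colony* vs *rest at sea*).
3. **Resource selection functions (RSFs)** — weighted use–availability
   mixed logistic regression in the infinitely-weighted-likelihood
   formulation: available points weighted W = 1000, a random intercept
   per individual with variance *fixed* at a large constant
   (σ₀² = 10⁶), and estimated diagonal random slopes, maximized via a
   Laplace approximation.  The fitted relative-occurrence surface is
   w(x) = exp(β̂ᵀx).
4. **Availability designs** — 95 % kernel-utilization-distribution
   random points (5 per used fix) for the predator; habitat-blind VAR(1)
   null tracks (10 per trip, segmented like real trips) for the
   central-place forager.
5. **Fearscape rasters** — each predator colony's RSF scores split into
   ten equal-count bins (1–10), overlaid by pixel-wise maximum across
   colonies, separately for day and night.
6. **Boyce-style validation** — leave-one-individual-out or 80/20
   k-fold refits, Spearman r̄ₛ between score-bin rank and area-adjusted
   frequency of held-out locations.
7. **Diel model** — probability of daytime foraging vs nighttime
   resting as a mixed logistic regression (random intercepts for bird
   and year) with linear or natural-spline (df = 4) forms per predictor,
   all 2⁴ form combinations ranked by AICc.
8. **Summaries** — habitat-use tables (mixed-model means with 95 % CIs),
   the nocturnal offshore shift (km), ΔSST between periods, the percent
   reduction in predator-encounter risk, and the tactic split.

A first-class synthetic-data module generates every input with known
ground truth (selection coefficients, behavioral states, tactic mix,
night shift), which is what the test suite exercises.

## Worked example

Run the whole chain on a synthetic cohort (16 birds, 3 seal colonies,
test scale) and print the headline numbers:

```bash
sofpipe run-all --seed 1 --outdir scratch/demo
```

```
rest-at-sea: 81.2% of 16 birds
night offshore shift: 9.6 km (95% CI 6.9..12.3)
risk reduction at night: 16.6%
delta SST (night - day): 0.22 C
artifacts in scratch/demo
```

Reading these: 13 of the 16 simulated birds slept at the sea surface
rather than returning to the colony (the cohort was generated with a
72 % rest-at-sea mix, so 81 % is within binomial noise of truth); those
birds rested on average 9.6 km farther offshore at night than where they
foraged by day (this cohort's realized generative shift was 9.8 km,
inside the CI); the offshore move lowered their mean seal-occurrence
index by 16.6 %; and their resting waters were 0.22 °C warmer — a large
safety gain for a small thermal one.  Per-fix states, trip tactics,
fearscape rasters, the habitat summary table and a JSON report are
written to the output directory.

The same stages are available individually (`sofpipe simulate`,
`segment`, `rsf-seal`, `fearscape`, `rsf-gannet`, `diel`, `summarize`,
`validate`), and everything can be driven from Python via
`sofpipe.pipeline.run_pipeline`.

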