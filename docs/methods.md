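# Methods notes

## The selection problem and its assumptions

The package selects, from an *unknown* cohort with only multivariate
biomarker measurements, the individuals most likely to occupy the low tail of
a validation trait that was recorded only in a separate *known* cohort. It is
aimed at the regime where each biomarker's linear correlation with the trait
is weak (|r| ≲ 0.25), so a regression fitted on the known cohort transfers
almost no signal; the working assumption is instead that low performers
occupy characteristic *regions* of each biomarker's within-cohort
distribution, and that those regions are preserved across cohorts once scale
differences are removed.

Two cross-cohort normalizations make positions comparable:

* **Rank transfer** rescales ordinal positions by the size ratio,
  `Ast = As · n_B / n_A`, mapping the unknown cohort's 1..n_A onto (0, n_B].
* **Score transfer** assumes each biomarker is roughly normal in both cohorts
  with different moments, and matches z-scores:
  `Axt = (Ax − mean_A) · sd_B / sd_A + mean_B`. Sample SDs (n−1 denominator)
  are used everywhere in the package; only the *ratio* of SDs enters, so the
  convention matters less than its uniformity.

A candidate low performer contributes one region per biomarker, delimited by
its rank-implied and score-implied anchors on the unknown cohort's
score-ordered axis (rightward when the score anchor is above the rank anchor,
leftward otherwise). Merged regions and the gaps between them partition each
axis into integer-labelled zones; matching is Manhattan distance on the zone
label vectors, followed by the five-tier admission cascade described in the
README.

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `fraction` | share of the known cohort taken as low-trait templates | 0.1 | the flock-selection use case culls ≈10% per stage; ties at the boundary always extend the set |
| `rank_direction` | orientation of ranks | ascending, fixed | only consistency across cohorts matters to zone distances; exposed read-only |
| `n_select` (regression) | baseline's cull count | zone method's count on the same inputs | makes the two methods' metrics comparable |
| `MissingPolicy` | rows with empty cells | `drop_object` | every downstream step needs complete profiles; drops are logged by id |

## Numerical and tie-breaking choices

* **Ranks are ordinal**, ties broken by input position (earlier row → smaller
  rank), so each rank column is an exact permutation — the zoning axis needs
  one object per position. Midranks are deliberately not offered.
* **Sorting by transferred score is stable**, which makes the score order
  consistent with the rank order under ties; object-level zone labels are
  therefore invariant to permuting the input rows (tested).
* **Anchor clamping.** When a candidate's rank anchor falls below every
  transferred rank the position is clamped to 1; above every rank, to n_A.
  When its score lies strictly between the scores at positions `pi` and
  `pi+1`, the region degenerates to `[pi, pi+1]` (the k = 1 limit of the
  rightward case). Clamping keeps every region inside [1, n_A].
* **Region boundary convention.** The leftward (Case II) walk includes the
  first object whose score has dropped to the candidate's concentration, the
  mirror image of the rightward walk including the first object that reaches
  it. Both boundary objects are inside the region.
* **Merging vs adjacency.** Regions merge only when they share at least one
  position; adjacent-but-disjoint regions stay distinct runs. Uncovered runs
  before the first and after the last region are numbered like interior gaps
  — the only convention that labels every object.
* **Filter arithmetic.** The per-candidate nearest sets take everything
  within the cn-th smallest row value (ties included, so |S_ej| ≥ cn).
  Objects in no set carry an infinite mean-distance sentinel and can never
  pass F1/F3. Top-third and top-quarter cutoffs are `ceil(U/3)` and
  `ceil(U/4)` over the U objects appearing in ≥ 1 set, with ties at the
  cutoff value included. The `min M = 2` conditions of tiers 3–4 read the
  minimum over candidates, the same reading the exact-match tiers force; the
  alternative (∃ej with M = 2) differs only on contrived matrices.
* **Rounding.** Egg-improvement percentages round half-up to one decimal,
  under-average percentages half-up to integers — the conventions that
  reproduce every printed worked value in the tests.
* **Degenerate inputs.** Constant biomarker columns make the score transfer
  undefined and raise a named error; n < 2 after missing-row drops, singular
  regression designs, and empty selections are all explicit errors rather
  than silent results.

## The synthetic flock generator

`prezone.synthetic` emulates the study conditions: batches of 60–77 hens,
biomarkers drawn per stage from normals truncated at zero with the published
per-batch means and SDs, egg counts as rounded normals clipped at zero
(published means 94.57 / 103.91 / 85.1; SD 19 by default — roughly a 20% CV,
typical of an unselected dual-purpose flock, since the source reports no
dispersion), and an enforced weak-correlation regime: each stage is
resampled (bounded retries) until every biomarker-egg |r| is within
`max_abs_corr` (default 0.25).

The optional planted signature shifts the biomarker means of the lowest
egg-decile hens by `signature_effect` SDs — half of the decile upward, half
downward, each hen keeping its direction across stages. The two-sided shift
is what keeps the planted signal *nonlinear*: Pearson correlations stay near
zero (the regime the method targets, and the reason the OLS baseline remains
nearly blind to it) while the low producers still occupy extreme, matchable
zones. A one-sided shift of the same size would push |r| to ≈ 0.3 and
contradict the weak-correlation premise.

What the generator does **not** emulate: the real batches' joint biomarker
correlation structure (columns are independent apart from the planted
signature), seasonal/cohort effects beyond per-stage moments, broodiness, and
any true physiological link between serum proteins and laying. Passing the
recovery tests therefore shows the pipeline detects a distributional low-tail
signature under weak linear correlation — not that such a signature exists in
real flocks.

The truncation at zero raises realized means above nominal for variables
whose SD is comparable to their mean (e.g. apo VLDL-II at 0.043 ± 0.080);
moment-matching checks are made on weakly truncated variables.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence tests run 1,000 random instances at n_A ≤ 12, m ≤ 3,
cn ≤ 4, where independent literal transcriptions of the zoning and cascade
rules are feasible; self-prediction runs 100 seeded cohorts of 10–40
individuals; recovery experiments use the published batch sizes (77 known,
76/60 unknown) over 100 seeded replicates. The acceptance script mirrors the
two study designs once per seed — single known batch over two continuous
stages, union of two known batches over three — and reports every metric it
computes.

## Known limitations and open choices

* The original implementation is unpublished; where its conventions are
  unstated (rank direction, terminal-gap numbering, adjacency vs overlap,
  filter rounding), this package fixes explicit, tested conventions. Results
  need not bit-match the original on shared data.
* The selection is a set-selector: it emits membership and the admitting
  tier, not a continuous risk score.
* Union mode concatenates known batches before joint re-ranking; an
  intersection variant is intentionally not provided.
* With very small cohorts (n_A < cn) the cascade reports a short selection
  rather than forcing a count.
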