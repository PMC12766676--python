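# Methods

## The problem

In a Sunburst-maze experiment a subject (rat, squirrel monkey or human) is
trained on a circuitous route to a reward and then confronted, once, with a
radial fan of K novel paths while the trained route is blocked. Each subject
contributes a single categorical choice. Across the dozen-plus replications
of Tolman, Ritchie and Kalish's 1946 design, the scientific question is not
whether any one arm was popular but *which kind* of arm won — the shortcut
(the map-based reading), the arms adjacent to the blocked route (a
stimulus-triggered response), the outermost arms (thigmotaxis or route
repetition), a cued arm (beaconing), or nothing at all. This package
implements that meta-analysis as a tested pipeline: chance model,
normalization, categorization, cross-experiment contrasts, and a synthetic
generator that makes every stage verifiable without external downloads.

## Chance model

With N single choices over K available arms, the null of "no preference" is
N draws from a uniform categorical distribution. The reference distribution
is built by Monte-Carlo reallocation (`resample_null`): R resamples (default
R = 1000, following the convention of the studies this pipeline mirrors) of
N uniform choices, each converted to per-arm percentages. Because arms are
exchangeable under this null, the mean μ_r and standard deviation σ_r are
pooled over all K·R per-arm percentages, giving one chance band per
experiment rather than K noisy per-arm bands.

One-sided thresholds come directly off the reference distribution:

    thr_05 = μ_r + 1.650·σ_r        thr_01 = μ_r + 2.326·σ_r

and observed percentages are normalized as z = (observed − μ_r)/σ_r, which
puts experiments with different K and N on one scale. Exceedance is strict:
a value exactly at threshold is not above chance.

Each per-arm count is Binomial(N, 1/K), so the null also has the closed
form μ = 100/K and σ = 100·√((1/K)(1 − 1/K)/N) (`closed_form_null`,
`analytic_null`). The resampler is validated against this oracle — at
R = 100 000 both moments agree within a fraction of a percent over a grid of
(N, K) — and the analytic version is available as a fast deterministic
policy (`NullPolicy(method="analytic")`). Arms excluded from scoring (for
example the six shortened left arms of the original apparatus) are removed
before K is counted.

Both the 1.650/2.326 percentage thresholds and a 1.96-SD criterion appear
in the source analyses: the former define the per-arm significance
thresholds, the latter the categorization criterion. Both are implemented
and independently configurable (`--threshold-mode`); the package defaults
to z > 1.96 for categorization.

## Categorization

Per-experiment role percentages: single-arm roles (shortcut, cued) report
that arm's percentage; multi-arm roles (adjacent, outer) report the
arithmetic mean over their members; an arm carrying several role flags
contributes to each. "Other" is the *maximum* percentage among unlabelled
arms, not an average — that category exists because in several studies an
arm with no remarkable feature won outright, and a max is the faithful
reading of "a path with no remarkable features was preferred". Whether
multi-arm roles are averaged before or after normalization is
operationally irrelevant under the pooled null (the map is affine); both
orders are implemented (`role_z(average_percentages_first=...)`) and their
equality is asserted in the tests rather than assumed.

A role is a candidate if its percentage exceeds the chance distribution by
more than z_cut = 1.96 SDs. Among candidates the highest percentage wins;
exact ties are broken by the fixed priority

    Shortcut > Adjacent > Outer > Cued > Other

which deliberately biases outcomes toward positive shortcutting. With no
candidate the experiment is `no_pref`. The rule is verified by brute-force
enumeration of all choice distributions over a 5-arm toy layout against an
independent re-derivation.

Inclusion rules for cross-study comparison are pure, composable filters:
drop mixed-order-scored records (with a whitelist for sources that reported
nothing else), drop lesioned and untrained groups (carried as opaque
`extra` metadata flags), and pool designated pre-op groups by summing
counts. Prevalence is the percentage of included experiments per category,
each experiment judged against its own (N, K) null.

## Contrasts

Finer cross-experiment questions are paired within experiments: the
adjacent arm more likely to intersect the blocked route versus the other
adjacent arm (`mode="intersect"`), the adjacent or outer arm heading with
the first training turn (`mode="first_turn"`), and the outer arm on the
rewarded side (`mode="reward_side"`). Only experiments with both arms of
the pair flagged and at least one above chance enter. The sources do not
name a group-level test for these panels; this package adopts a two-sided
sign-flip permutation test on the per-experiment z-differences — it is
distribution-free, respects the pairing, and matches the resampling spirit
of the rest of the pipeline. The null is enumerated exactly for up to 20
experiments (2^n sign patterns) and sampled with a seeded generator and the
add-one rule beyond that; both the per-arm above-chance percentages and the
group p-value are reported because a "significance line" can be read either
way. Distribution summaries across experiments (e.g., of the
shortcut-minus-adjacent z difference) use central empirical percentile
intervals with linear interpolation between order statistics at the 90/95/99%
levels.

## Auxiliary tests

* `chi_square_expected` — Pearson statistic against expected proportions
  (E_i = total·p_i, df = cells − 1), asymptotic p, no continuity
  correction; a warning is emitted when any expected count is below 5.
* `benjamini_hochberg` — step-up FDR adjustment (statsmodels), checked
  against a direct enumeration of the definition.
* `z_difference_test` — ((z_a − z_b) − (m_a − m_b))/√(s_a² + s_b²), where
  m and s² are the mean and variance of each experiment's shuffle
  distribution *pushed through the normalization*. They are ≈(0, 1) by
  construction but are computed and carried on the `NullDistribution`
  object, not assumed, so a finite-R resampled null contributes its actual
  moments. The shuffle moments are taken in z-space; the wording of the
  source analysis admits a raw-percentage reading, but after normalization
  the two coincide up to the same affine map.
* `gaussian_density_summary` — a normal density over a grid of alley
  positions, for sources that published only a mean ± SD of ordinal alley
  choices; it is a continuous density and is deliberately not renormalized
  over the grid.

## Synthetic generator

The generator (`synthetic`) models strategies as *path-role targets*, not
spatial trajectories. Each subject independently draws a strategy from a
mixture and then an arm:

| strategy   | target                                                        |
|------------|---------------------------------------------------------------|
| shortcut   | the shortcut arm; optionally "smeared" geometrically onto neighbours with decay λ (default 0.5 per arm) to emulate noisy vector navigation producing graded rather than peaked distributions |
| adjacent   | one of the two adjacent arms (configurable intersect split, default 0.5) |
| beacon     | the cued arm; uniform fallback when the layout has no cue     |
| outer      | one of the outer arms (configurable reward-side weight, default 0.5) |
| other      | one designated unlabelled arm (apparatus-driven bias — shadowed or walled arms that won in some studies without carrying any nominal role) |
| uniform    | any scorable arm                                              |

The sixth "other" component is a design choice of this package: the five
named strategies all target role-flagged arms, so without it the generator
could not produce the "other"-dominant experiments that occur in the
replication record. Abstentions are drawn with an optional `p_no_choice`
and recorded in `n_no_choice`, never in counts. Everything is driven by
`numpy.random.default_rng(seed)`; there is no hidden global state.

Layout presets encode the main apparatus families (18-arm original with six
excluded arms, full ring, 5-arm T-style fan, 8-arm enclosed, 6-arm variant
with an overlapping shortcut/adjacent arm). In these presets the blocked
training route is a stub that is not itself choosable, so no preset arm
carries `is_training`; the data model still accepts a training-flagged arm
for digitized records that list it. Within-preset index assignments
(which adjacent arm intersects, where the cue sits) are stylized but fixed
and documented in `make_layout`.

What the generator does *not* emulate: spatial trajectories, deliberation
or exploration before the committed choice, odour trails and inter-subject
correlation, light/shadow asymmetries except as they are summarized by role
flags, and subjects switching strategies mid-trial. Passing the recovery
tests therefore shows the pipeline correctly inverts a role-targeted
mixture at realistic N — it does not show that real animals are described
by such a mixture.

## Numerical choices and degenerate inputs

* Pooled SD uses ddof = 1; at R·K ≥ 2000 the difference from the population
  convention is far below Monte-Carlo error.
* Per-record resampling seeds are derived from the policy seed and a CRC of
  the record identity through `numpy.random.SeedSequence`, so results are
  independent of dataset ordering and reproducible per record.
* K < 2, N = 0, σ = 0, empty datasets, and contrasts with no eligible
  experiment raise typed errors (or return an explicitly `empty`-flagged
  summary) rather than NaNs.
* Ties in categorization are resolved by the fixed priority order; ties in
  the permutation statistic are counted into the null with a 1e-12 float
  margin.
* Percentages in human-readable reports are rounded to one decimal (two
  where a source printed two); machine outputs keep full precision.

## Problem sizes used in the checks

The acceptance script reproduces the worked proportions at their printed
sizes (N = 16–56), compares the resampler with the analytic oracle at
R = 100 000 over a 24-cell (N, K) grid, and runs the full pipeline on a
47-experiment generator-built dataset with N = 50 subjects per experiment
and R = 1000 resamples per null — the scale of the replication record
itself. The generator-recovery check uses 200 seeded simulations of an 80%
adjacent mixture at N = 50.

## Known limitations

* The prevalence figures of the published meta-analysis (shortcut 17%,
  adjacent 32%, …) are recomputed here on a generator-built dataset
  mirroring the published category counts, not on the released digitized
  dataset, which this package does not download; an import shim
  (`read_dataset` plus opaque extra columns) is the adapter point for it.
* The "other" role being a maximum over unlabelled arms inflates its
  false-alarm rate under pure chance (a max of several ≈standard-normal
  scores exceeds 1.96 more than 2.5% of the time). This is a property of
  the categorization rule itself, faithfully implemented; at desk scale it
  shows up as a few uniform experiments landing in "other" rather than
  "no preference".
* Percentage-valued data digitized from graphs can carry sub-percent
  digitization error; the pipeline treats counts as exact.
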