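# Methods

This note documents the models, conventions and numerical choices
behind `popshape`, in the order data flows through the pipeline.

## Studbook model and conventions

A studbook row is one individual: identifier, sex (female / male /
unknown), birth date, optional death date, status (dead / alive /
lost), dam and sire identifiers with a parentage-certainty percentage,
a wild-born flag and a holding region.  Dates are ISO-8601; files are
UTF-8 CSV.  Individuals of unknown sex are excluded from sex-specific
pyramids but participate in parentage curation.  Individuals lost to
follow-up keep their records and, having no death date, count as alive
— the same situation raw registry data presents; the longevity rule
below is what prevents such "immortal" records from distorting
results.  Parent identifiers that do not resolve within the studbook
(routine in regional extracts) are kept but exempted from sex- and
age-based plausibility rules.

## Curation

Four deterministic procedures, each logging every mutation to an audit
report (rule, affected ids, action, detail):

1. **Parentage plausibility.**  Links below 100 % recorded certainty are
   dropped; self-parentage links are dropped; a male recorded as dam
   together with a female recorded as sire is treated as a field swap
   and exchanged; when both parents share a sex, the wrongly-sexed
   parent's link is dropped (a male dam, a female sire).  Link removal
   never deletes individuals.
2. **Litter grouping.**  Same-dam births within a 3-day window (single
   linkage) form one litter and are re-dated to the litter's middle
   date (the earlier central date for even sizes — a fixed tie-break).
   Litters above the species maximum are treated as duplications and
   cut in half: ⌊size/2⌋ members are deleted uniformly at random under
   the run seed.  For an odd oversized litter the ⌈size/2⌉ survivors
   can still exceed the maximum; a further pass would trim again.  This
   is a consequence of the literal halving rule and is left as is.
3. **Interbirth intervals.**  Consecutive litters of a dam closer than
   90 % of the effective gestation (gestation + minimum pouch-eviction
   age for marsupials) invalidate the *later* litter's dam links; the
   earlier litter is the reference point and remains the comparison
   anchor for subsequent litters.  Litters are grouped *before* this
   check — litter mates share a date by construction and would
   otherwise trip any threshold.
4. **Maximum longevity.**  The record holder is the oldest zoo-born,
   dead individual (floored years): wild-born ages are import-time
   estimates, and living animals at the top of the range are usually
   never-closed records.  A manual override (e.g. a literature value)
   wins.

The underage-parent rule needs an age of first reproduction, which
itself derives from parentage; the pipeline estimates a provisional AFR
from the links surviving the other rules and applies the rule once, with
no fixed-point iteration.  With a purely data-derived AFR the rule is
vacuous (every link's age is at least the floored minimum); it becomes
active when an AFR override is configured, which is the intended use.

## Life stages

**AFR** is the floored minimum parent age at any offspring birth, per
sex (fractional age in 365.25-day years).  **Senescence onset** comes
from the reproduction profile: for each age class, the fraction of
proven breeders *alive during that class* that produced at least one
offspring in it.  Restricting the denominator to breeders alive at that
age keeps mortality from masquerading as reproductive decline; living
(censored) breeders count as alive up to their age at the studbook's
last event date.

A three-parameter curve A·gammaPDF(a + 0.5; k, θ) is fitted to the
profile by least squares at class midpoints.  The fit is deterministic:
a coarse grid over k ∈ {0.5, 1, …, 16} and θ ∈ {0.25, 0.5, …, 8} with
the amplitude profiled out in closed form (Â = Σpg / Σg²), followed by
Levenberg–Marquardt refinement in log-parameters; the refined solution
is kept only when finite, within 10× the grid bounds, and no worse in
residual sum of squares — near-flat profiles otherwise push θ to
infinity for no gain.  The onset is the age where the fitted density
falls to `gamma_tail_fraction` (default 0.75) of its peak on the right
tail, located by bracketing + Brent root-finding and *ceiled* to a whole
age class: an individual is senior only once past the threshold.
At least four age classes with positive probability are required;
degenerate profiles raise an error directing the user to manual
thresholds.

**Buckets.**  Juvenile `[0, AFR)`, adults `[AFR, onset)` in three
contiguous blocks as equal as possible (remainder years to the lower
blocks — an arbitrary but fixed convention), senior
`[onset, max longevity]`.  The adult span must be ≥ 3 years; shorter
spans are an error, as sub-year age resolution is out of scope.

## Pyramids and the step sequence

Alive on December 31st means born on or before that date and dead
strictly after it (death on the 31st counts as dead).  On December 31st
the floored age equals the difference of calendar years, so a 363-day-
old is in class 0 and a 365-day-old is in class 1 except when a leap
year puts the first birthday one day later.  Ages beyond the curated
maximum (possible for uncurated live records) clamp into the top class
rather than being dropped.

Each bucket carries mean count per class, SEM (sample n−1 standard
deviation / √n; zero for single-class buckets, making their comparisons
pure mean comparisons) and class count.  Buckets compare equal when the
m ± `sem_factor`·SEM intervals overlap (`sem_factor` 0.5).  This
equality is deliberately not transitive; the classifier only ever uses
pairwise comparisons.  The step sequence is the four bottom-up
comparisons, +1 / 0 / −1.

## The decision table

The complete 81-pattern mapping ships as
`src/popshape/data/decision_table.csv` (pattern, optional guard,
outcomes, provenance) rather than hard-coded logic, and is self-checked
at load: totality, known outcomes, and exact mirror anti-symmetry —
classifying an upside-down vector yields the mirrored shape, with
column, middle diamond and hourglass self-mirrored.

Rows derive from a level-path rule.  Monotone non-increasing patterns:
flat top → plunger; strict first and last decline → pyramid (a
stationary adult interior is subsumed — e.g. (−1,0,0,−1)); flat base
with a final decline → bell; mirrored for non-decreasing.  A single
rise then decline is a diamond named by the position of the level
maximum; a maximum plateau that reaches bucket 3 counts as a middle
diamond (the alternative centre-of-plateau convention labels a genuine
central bulge an upper diamond whenever buckets 3 and 4 tie under the
SEM test — both conventions are mirror-consistent, this one tracks
cohort mechanics better).  A single decline then recovery is an
hourglass candidate, guarded: the top bucket must not be smaller than
the bucket just below the interior minimum (for (−1,−1,−1,+1): bucket 5
vs bucket 3 — hourglass when the top recovers, pyramid otherwise);
symmetric decline-recovery patterns are unconditional hourglasses, and
mirrored orientations are defined through the mirror identity so
anti-symmetry holds exactly, guards included.  Patterns with several
direction changes resolve by their level extremes: interior maximum →
diamond, interior minimum → hourglass, otherwise by comparing the end
levels.  Rows pinned by the published shape descriptions are marked
`anchored`, rows forced by mirroring `mirror`, the rest
`reconstructed` — the reconstructed rows are the ones a literal
published complete mapping could override, and replacing the CSV is all
that would take.

Populations of ≤ `min_population_for_shape` (10) individuals per sex
yield `not_ascribed` — an ordinary value, not an error, so yearly series
keep their grid.

## Dynamics statistics

Transitions are consecutive-year shape pairs where both years are
ascribed; a `not_ascribed` year breaks the chain (bridging would
fabricate multi-year transitions).  The population change is
100·(N_next − N_prev)/N_prev on the sex-specific total — the unit that
was classified.  Aggregation yields 11×11 count, percentage-of-total,
mean-change and SD-change matrices (SD defined only for n ≥ 2); every
cell is stored, display thresholds are a rendering option of the CLI
only.  Age-group proportions are the per-shape means of each ascribed
entry's juvenile/adult/senior percentages (summing to 100 per entry).
Peak analysis takes each series' maximum total (earliest year on ties)
as the peak shape and expresses every occurrence of a shape as a
percentage of that series' maximum.

## The synthetic generator

The simulator is an individual-based yearly birth–death process with
age-indexed schedules.  Defaults describe a generic mid-sized mammal:
age of first reproduction 3, gamma-shaped annual litter probability
(k = 4, θ = 2 years, peaking near age 6, 75 %-of-peak right-tail
crossing at 9.02 years → onset class 10), maximum age 20, gestation
150 d, litters of 1–3 (probabilities 0.70/0.25/0.05), survival 0.70 in
the first year, 0.85 and 0.92 through the juvenile years, an adult
plateau of 0.92 and a senior decline of 0.08/year.  The peak litter
probability 0.50 was chosen so the Leslie-matrix growth rate of the
default schedules is ≈ 1.005 — the steady-state regime the pyramid
shape family describes.  Founders (wild-born, so they never hold the
longevity record) start at the survivorship-implied stable age
distribution.  Sires are drawn with probability proportional to their
age-fertility — uniform choice would give males a flat reproduction
profile and a degenerate male gamma fit, defeating the threshold
estimation the generator exists to exercise.  Litters are dated
mid-year ± 3 days (within the litter window), mates sharing one date;
deaths get a date within their year, so first-year mortality already
thins the birth cohort's December census.  Extinction is a valid
outcome recorded in the ground truth.

Scenario presets: `steady_state` (200/sex, 60 y), `reproduction_halt`
(halt in year 40) and `halt_then_resume` (8-year gap) with 2,000 per
sex — cohort tracking needs the bucket signal to dominate Poisson
noise — plus `low_mortality_reduced_reproduction`, `high_resilience`
and `low_resilience` contrasts.  The error injector corrupts disjoint
record sets per error type (wrong-sex dam, self-sire, swapped fields,
a second litter moved to 45 days after the first — beyond the litter
window, inside 90 % of gestation — duplicated litter members to twice
the species maximum, cleared death dates, underage sires) and returns
exact truth lists, so curation recall and false-repair counts are
measurable.

What the generator does *not* emulate: transfers between institutions,
pair bonds or mate monopolisation, genetics and inbreeding, density
dependence, estimated wild-born birth dates, and sub-year demography.
Passing tests therefore demonstrate the pipeline's correctness on
structurally faithful registry data, not robustness to every real-world
recording practice.

Binning note: the simulator draws events by age class (calendar-year
age), while AFR estimation floors fractional ages; a first litter
falling a few days before the dam's birthday can thus floor one class
below the schedule's nominal AFR.  This is inherent to the two
conventions, not an estimation error; scenario pipelines use the
ground-truth thresholds.

## Problem sizes and determinism

Tests and the acceptance script use populations of 150–2,000 per sex
over 40–60 simulated years, 2,000-breeder binomial reproduction
profiles, and 20-seed scenario replicates — sizes at which every
qualitative regime is stable while a full run stays in the tens of
seconds.  All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds reproduce studbooks
byte-for-byte.

## Known limitations

- The reconstructed decision-table rows beyond the anchored set are one
  consistent completion of the published constraints, not the published
  complete mapping itself.
- Species with adult spans under three years (or needing sub-year age
  classes) are rejected rather than adapted.
- The odd-oversized-litter halving edge described above.
- No survival analysis or actuarial-senescence modelling: the senior
  threshold is purely reproductive.
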