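# Methods

## Event model and conventions

All analyses run on a tidy event stream per session: lever presses
(`press_left`/`press_right`), food-cup photobeam entries and exits, pellet
deliveries, dispenser-cue emissions, CS onsets/offsets with cue identity,
and a terminal `session_end`. Time is in seconds from session start. A
"food-cup approach" is an *entry onset*; exits are kept only so that bout
durations remain recoverable and repeated beam breaks during one occupancy
can be distinguished from new approaches. Events at the same timestamp are
ordered deterministically (press < pellet < dispenser cue < entry < exit),
so a press and its instantaneous feedback always classify identically.
Times are serialized at millisecond precision, which makes CSV round-trips
exact for logs generated on that grid.

Interval conventions, used consistently everywhere: "within X s after" is
the half-open interval (t, t + X]; a CS window is the closed
[onset, offset] (an event exactly at onset belongs to the CS period); the
pre-CS window is the open 120 s interval before the onset.

## Microstructural classification

A press is **with approach** when a food-cup entry falls in (press,
press + cutoff] and no other press intervenes: attribution is always to the
*most recent* press, because the approach is taken to complete the press
that immediately precedes it. The cutoff defaults to 2.5 s — the
empirically conventional window separating press-contingent retrieval from
spontaneous checking — and is a parameter, never estimated from the data. A
press is **reinforced** when a pellet delivery or dispenser-cue emission
coincides with it; a dispenser cue alone suffices, so cues-only sessions
classify identically to food-and-cues sessions with the pellet rows
removed. A press performed during ongoing cup occupancy acquires no
approach (approaches are entry onsets).

Entries that are not press-contingent are grouped into **noncontingent
bouts**: a new bout starts at an entry only when neither a press nor a
prior entry occurred within the cutoff before it; closer entries continue
the open bout. One corner case is not covered by these two rules — a
noncontingent entry trailing a *press-contingent* entry within the cutoff,
with no bout open. We anchor a new bout at that entry, which keeps the
partition exact: every entry is either press-contingent or a member of
exactly one bout, and the two counts always sum to the total.

Peri-event histograms report, per bin (half-open, default 0.5 s over
(−5, +10] s), the fraction of alignment events with at least one entry
onset in that bin. The proportion of presses followed by approach over an
empty selection is *undefined*, returned as missing and excluded from
downstream analyses — never imputed as zero.

## Derived assay measures

PIT tests contribute a period table — press counts, with/without-approach
counts, noncontingent-bout counts and retrieval proportions per cue type
(CS+/CS−) and period (CS/pre-CS), summed over the four trials of each cue —
from which PIT scores are computed as *totals*: CS+ presses minus pre-CS+
presses, optionally restricted to presses with or without approach (the
three scores are exactly additive). Drug effects are summarized as score
differences (CNO − vehicle); when a design includes two tests per drug
condition, per-subject scores are averaged within drug before group
statistics — the conventional reduction to one value per subject per
condition. For proportion analyses the two pre-CS periods are collapsed
into a single three-level period factor, which cannot change any press
count.

Devaluation tests contribute extinction-phase (first 300 s) press counts
and retrieval proportions per lever value tag and press type. Pavlovian
conditioning is scored per trial as entry rates (per min) from CS onset to
the first pellet delivery — excluding pellet-driven, unconditioned
retrieval — against the 120 s pre-CS rate; trials without a pellet use the
full CS window.

## Statistics

Count responses are modeled as Poisson with a log link; proportion
responses are square-root transformed (skew correction) and modeled as
Gaussian. Fixed effects are the full factorial of the named categorical
factors (treatment coding, sorted first level as reference); random effects
are by-subject uncorrelated intercepts with one variance component per
within-subject factor, plus the plain subject intercept. Effect sizes are
unstandardized coefficients *b* on the link scale with Wald tests; Wald
F-tests are reported for term groups spanning more than one coefficient.
All tests are two-sided at α = .05 with no multiplicity correction.

The Poisson mixed model is fit by Laplace-approximate maximum likelihood:
for candidate variance components the joint penalized log-likelihood is
maximized over (β, u) by damped Newton iterations (the problem is concave),
and the marginal likelihood is approximated with the standard determinant
correction; variance parameters are optimized on the log-SD scale by
Nelder–Mead. This variant profiles β inside the penalized problem rather
than inside the Laplace objective, which can shift intercept-like terms by
a fraction of a percent relative to fully profiled implementations —
negligible at the counts this package analyzes, and checked in the test
suite against an independent Gauss–Hermite-quadrature MLE. With no random
effects the fit *is* the IRLS GLM (exact closed forms on saturated
designs). Non-convergence of either the inner Newton loop or the outer
search is reported in the fit's `converged` flag and warning list, never
silently. Gaussian-family models delegate to statsmodels (MixedLM/OLS).

Simple tests wrap scipy with fixed conventions: the paired t statistic is
computed on second-minus-first differences (post − pre, so a positive t
means the second condition is larger), zero-variance differences give
t = 0 when the mean equals the null value, and Pearson correlations
require n ≥ 3 and nonzero variance.

## The virtual-rat simulator

The generator emulates the statistical structure the analysis assumes, not
a learning animal. Press initiations follow a discrete-time Bernoulli
approximation of a Poisson process (default step 0.1 s; per-step hazard
rate·Δt, valid at the configured rates). Each press is either discrete or
the start of a press→approach chunk: after dispenser feedback the approach
probability is `p_approach_feedback` (default 0.9), after a nonreinforced
press `p_chunk_nonreinforced` (default 0.1); the chunk entry lags the press
by an exponential latency (mean 0.8 s) truncated at the classification
cutoff (2.5 s). Chunks are atomic: a press initiation arising between a
press and its contingent entry is *deferred* to the chunk's end — an animal
at the food cup cannot simultaneously press — which keeps the recovery of
the chunk probabilities unbiased under most-recent-press attribution and,
because deferral preserves counts, keeps window press counts at their
Poisson expectations (boundary leakage is under ~0.1 press per session at
default rates). Spontaneous entries form an independent Poisson background
(default 0.5/min) with exponential occupancies (mean 1 s) clipped to
maintain entry/exit alternation.

Schedules: RI arms after an exponential delay with mean equal to the
nominal interval, timed from the last reinforcer — the canonical
constant-hazard random interval; RR reinforces each press with probability
1/ratio (CRF ≡ RR 1); random-time delivery is a Poisson process (rate 1/30
per s during the CS, giving the standard ~4 pellets per 2-min trial).
Reward caps (default 20) and session-duration truncation are absolute; a
capping reward is given a 3 s grace period so its retrieval lands in the
log.

Session scripts follow the standard designs: 30-min single-lever
instrumental/feedback-test sessions (food-and-cues, cues-only, or
no-feedback modes); Pavlovian sessions with 2-min cues at 4–6 min
onset-to-onset spacing; PIT tests with 8 min of extinction lead-in then
four CS+ and four CS− 2-min trials in seeded pseudorandom order (no three
consecutive same-type trials) with a 180 s fixed ITI and no feedback;
devaluation tests with a 5-min two-lever nonreinforced phase followed by a
15-min reinforced phase (per lever, CRF for five rewards then RR-20).
During CS+ the press hazard is multiplied by `cs_press_multiplier` and the
chunk probability by `cs_chunk_multiplier` (both default 3, capped at 1
where applicable); CS− multipliers are fixed at 1. Devaluation scales the
devalued lever's extinction-phase initiation hazards by press type
(defaults 0.2 for discrete, 0.8 for chunked presses), which algebraically
yields fewer devalued presses but a *higher* devalued retrieval proportion
— the mixture signature the analysis is designed to expose. Pavlovian
sessions additionally scale the background entry rate by
`cs_entry_multiplier` during reinforced cues (conditioned approach). Drug
or group effects enter only as alternative parameter sets supplied for
tagged sessions.

Baseline rates are not calibrated to any real cohort (no numerical base
rates are available to calibrate against); the defaults — 8 presses/min,
0.5 background entries/min — are chosen as qualitatively realistic for a
trained rat on sparse schedules. Cohort generation is deterministic given a
root seed, with independent per-(subject, session) substreams derived by
seeding a PCG64 generator with the (seed, subject, session) tuple.

What the simulator does *not* model — and hence what passing tests cannot
certify about real data: acquisition and extinction learning curves,
within-session satiety dynamics, inter-response-time structure beyond the
Poisson/chunk mixture (no press bouts), pharmacokinetics, or individual
differences beyond independent sampling noise.

## Problem sizes and numerical choices

Test-suite and acceptance-script cohorts are sized for stable Monte-Carlo
estimates at desk scale: 20 subjects × 6 sessions for parameter recovery,
200 subjects for PIT calibration (null and 3× multiplier), 150 sessions for
the devaluation signature, 10,000 replicates for the t-test type-I error,
and 1,000 random logs (up to 10,000 events) for oracle equivalence. PIT
calibration is judged against the closed form (m − 1)·r·8 min; recovery of
the chunk probabilities is expected within ±0.05 of truth — the residual
bias from background-entry contamination is ≈ 0.02 at default rates.
Mixed-model optimization uses a fixed starting point (log SD = log 0.3),
bounded log-SD clipping to [−8, 4], and deterministic Nelder–Mead settings,
so fits are reproducible run to run.

## Known limitations

- Whether real photobeam records debounce repeated interruptions during one
  occupancy is apparatus-dependent; the entry/exit alternation rule here is
  a convention of the canonical format.
- The Laplace approximation can misestimate variance components when
  per-cell counts are very small (means near 1); the quadrature cross-check
  covers the moderate-count regime this package targets.
- Reinforced-phase devaluation behavior is summarized by raw counts only;
  no consumption or satiety model is attached.
- The CLI's `stats` subcommand fits one model per invocation; model
  comparison and post-hoc contrast machinery beyond factor splits are out
  of scope.
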