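# Methods

## The scientific problem

In a Posner cueing task with continuous colour report, each trial presents a
spatial cue (symbolic and predictive, or a peripheral flash and
uninformative), then a brief coloured target on the left or right; the
participant makes a speeded detection response and then clicks the
perceived hue on a randomly rotated colour wheel. The signed angular error
between the clicked and true hue carries information about two distinct
perceptual quantities: whether the colour was encoded at all, and how
precisely. `cuewheel` implements the full analysis chain for such
experiments — schedule generation, a generative simulator, exclusion rules,
a hierarchical Bayesian mixture model, and HDI-based effect summaries.

## Observation model

Colour errors follow the Zhang–Luck two-component mixture

    p(e | rho, kappa) = rho * VM(e; 0, kappa) + (1 - rho) / (2*pi),

where `VM(e; 0, kappa) = exp(kappa cos e) / (2 pi I0(kappa))` is the von
Mises density. `rho` in (0, 1) is the probability of encoding; `kappa > 0`
is the fidelity (concentration) of encoded responses; `1 - rho` is the
blind-guessing weight. This single-target form is appropriate here because
exactly one colour is shown per trial — set-size/swap working-memory
variants do not apply. Detection RTs are modelled as lognormal:
`log rt ~ Normal(mu_cell + subject offset, sigma)`.

## Hierarchical model

Three submodels (log-RT location, logit-`rho`, log-`kappa`) share the
condition-cell factor (cue type for the endogenous experiment; SOA x cue
type, six cells, for the exogenous one) and a subject grouping:

* dummy coding against the invalid-cue reference cell, so the
  valid − invalid cueing effect is a single coefficient per submodel;
* per-subject intercept deviations in all three submodels, non-centred
  (`z_s ~ N(0,1)` scaled by a group SD `tau`); no random slopes by default
  (a config switch is reserved but the default model matches the
  between-subject-variation structure described above);
* priors, deliberately weakly informative and configurable:
  `Normal(0, 1)` on condition coefficients, `half-Normal(1)` on all group
  SDs and the within-subject log-RT SD, `Normal(log 350 ms, 1)`,
  `Normal(2, 2)` and `Normal(log 8, 1)` on the RT, logit-`rho` and
  log-`kappa` intercepts. These priors are a re-specification: they are this
  package's own choice of weakly-informative defaults, not a transcription
  of any particular published analysis code.

Condition summaries are back-transformed draw-wise (`exp`, logistic, `exp`)
so RT effects are reported in ms and encoding effects on the probability
and kappa scales. Angles are stored in degrees and converted to radians
once, inside the likelihood (`cuewheel._angles` centralizes the
convention; errors live in (−180°, 180°], ties to +180°).

## Sampling

The joint posterior is sampled with emcee's affine-invariant ensemble
sampler, with the log-posterior vectorized across walkers so a fit costs a
few large numpy operations per step. Differential-evolution moves (80%
`DEMove`, 20% `DESnookerMove`) replace the default stretch move — they mix
far better in the ~130-dimensional hierarchical posterior. Walkers are
initialized in a tight ball around an MLE-informed point (pooled per-cell
mixture fits, RT cell means, empirical subject RT deviations), which
removes most burn-in. Defaults: `2*ndim + 2` walkers, 4000 steps, first
2000 discarded, thinned by 8. Walkers act as chains for split-R-hat
(arviz); typical values after the default run are 1.1–1.3, adequate for
medians and HDIs of the population-level quantities reported. The
diagnostics block records the mean acceptance fraction; a `divergences`
field is kept at 0 for schema compatibility with HMC workflows (ensemble
samplers have no divergence diagnostic). The RT likelihood is collapsed to
per-(subject x cell) sufficient statistics; the mixture term is evaluated
per trial.

Numerical safeguards: `log I0` is computed via the exponentially scaled
Bessel function (`i0e`), the mixture log-density via log-sum-exp, `sigma`
is floored at 1e-6 (an all-constant-RT dataset otherwise sends the
likelihood to +inf), and the log-kappa linear predictor is clipped at 12
(kappa ~ 1.6e5, far beyond any identifiable fidelity).

## Maximum-likelihood oracle

`fit_mle_cell` fits a single cell by EM (responsibilities for the von Mises
component; `kappa` updated by inverting the resultant-length relation
`A1(kappa) = I1/I0`, Fisher start plus Newton polish) and `fit_mle_grid` by
a dense `(rho, log kappa)` grid with local refinement. The two routes agree
in maximized log-likelihood to ~1e-6 on realistic cells and cross-validate
the Bayesian fit. `kappa` is constrained to [0.5, 1e4]: as `kappa -> 0` the
von Mises component collapses onto the uniform and `rho` loses
identifiability (a flat likelihood ridge); the floor — far below any
plausible colour-report fidelity — removes the ridge so uniform data yields
`rho` near 0. The ceiling keeps the degenerate all-zero-error case finite.

## Synthetic-data generator

The generator is first-class code: it emulates the two designs exactly
(E1: 60-trial blocks of 6 cue slots x 2 sides x (4 target + 1 catch),
80%-valid symbolic cues, 800 ms SOA, 7 test blocks + 30 practice trials;
E2: 3 cue locations x 2 sides x 2 SOAs x (4 + 1), uninformative flashes,
8 blocks + practice; 20% catch trials in both; counterbalance arms
alternate across subjects). Catch trials inherit the cue type and SOA of
their factorial cell — the count formulae imply one catch per four target
trials per cell, and the same 80/20 validity split is applied within
spatial-cue catch trials (the design formulas do not pin this down; it is
the natural reading and is asserted by the block-count tests).

Default generating values anchor each condition to the reported posterior
medians of the two experiments, with the intercept interpreted as the
neutral/reference cell and valid − invalid effects split symmetrically
around it (interpreting the probability intercept 0.992 as the invalid
cell would force valid `rho` = 1.000, a degenerate value):

| cell | RT (ms) | rho | kappa |
|---|---|---|---|
| E1 neutral | 359.86 | 0.992 | 9.08 |
| E1 valid | 349.01 | 0.996 | 9.305 |
| E1 invalid | 370.71 | 0.988 | 8.855 |
| E2 neutral@100 | 404.02 | 0.995 | 10.51 |
| E2 valid@100 | 407.33 | 0.9965 | 9.24 |
| E2 invalid@100 | 400.71 | 0.9935 | 9.26 |
| E2 neutral@800 | 393.78 | 0.995 | 9.78 |
| E2 valid@800 | 411.25 | 0.993 | 9.725 |
| E2 invalid@800 | 376.31 | 0.997 | 9.835 |

so the generating contrasts equal the reported effect medians exactly
(E1: −21.70 ms, +0.008, +0.45; E2 per SOA: +6.62/+34.94 ms, +0.003/−0.004,
−0.02/−0.11; neutral-over-spatial fidelity benefit +1.26 at the short
SOA). Contamination rates are the reported ones (E1: misses 0.32% of
target trials, false alarms 3.02% of catch trials, pre-target responses
1.22% of target trials; E2: 0.74%/2.67%/1.47%).

Values the source experiments do not report and that are therefore this
package's own realistic defaults: within-subject log-RT SD 0.18 (≈18% CV,
typical of speeded detection), subject-level SDs 0.15 (log-ms), 0.5
(logit-rho) and 0.2 (log-kappa). Miss trials carry no RT or colour click;
pre-target responses carry a uniform RT in [−SOA, 0) relative to target
onset and a uniform colour click; false alarms on catch trials get a model
RT and a uniform click (no target colour existed). Blind guesses are
generated as target + uniform offset, which makes responses co-rotate with
targets under a common hue shift (a property the tests exercise).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: learning and fatigue across blocks, heavy-tailed
RT contamination beyond the lognormal (so the 5x-MADM pass removes ~0.1%
of simulated trials versus the ~2.4% reported for real sessions),
response-stage biases (e.g. categorical colour memory), and any
mechanistic account of inhibition of return (condition effects are
injected directly).

## Preprocessing

Practice blocks (block 0), misses, false alarms and pre-target responses
are dropped first, each tallied against its natural denominator (target
trials, catch trials). Correct rejections are also removed — the modelled
dataset is target hits only — but counted separately, not as an exclusion.
Then, within each subject x cue-condition cell (subject x SOA x cue for
the exogenous design, and neutral cues form their own cell), log-RTs
deviating from the cell median by more than 5x the raw MADM (no 1.4826
consistency scaling) are excluded, strict inequality, in a single
non-iterative pass on the post-exclusion data. Even-sized cells use the
midpoint median; a zero-MADM cell drops nothing.

## Inference

HDIs use the exact sorted-window scan (shortest window containing
`ceil(mass*n)` draws; ties to the lowest start), which is exact for
unimodal empirical draw sets. Credibility labels: highly credible if the
95% HDI excludes zero; weakly credible if the 95% contains zero but the
50% does not; non-credible otherwise; zero on an endpoint counts as
contained (conservative). The neutral-versus-spatial fidelity contrast
pools valid and invalid by the unweighted draw-wise mean of their
log-kappa linear predictors, back-transforms, and subtracts from the
neutral-cue kappa; pooling on the log scale before back-transforming is
the package's choice where the reported analysis leaves the order
ambiguous (with near-equal spatial cells the two orders are numerically
indistinguishable).

## Problem sizes and runtime choices

The package's standard verification runs are sized so a full check remains
a coffee-break affair on one core: the recovery check simulates 40
subjects x 7 test blocks (~13k modelled trials) and fits the full
hierarchical model (~4 min); HDI calibration uses 50 replicates of 20
subjects x 1 block fit with the pooled (non-hierarchical) model — the same
likelihood, priors and HDI machinery at a fraction of the cost — and the
`scripts/acceptance.py` recovery run uses 40 subjects x 3 blocks. The
pooled-MLE fast path (`model.method: mle` in the pipeline config) gives
point estimates in seconds and is the recommended first pass.

## Known limitations

* Ensemble MCMC in ~130 dimensions mixes more slowly than gradient-based
  samplers; split-R-hat of 1.1–1.3 under default settings is adequate for
  the reported medians/HDIs but tails are less well resolved. Longer runs
  (`n_steps`) are the remedy.
* `rho` intercepts near ceiling (0.99+) are weakly identified in small
  cohorts; their posteriors lean on the weakly-informative logit prior.
* The simulator's clean lognormal RTs make the MADM stage nearly inert;
  real data exercise it much harder.
* Real-data ingestion is deliberately minimal: a CSV loader that accepts
  the documented trial schema (including a raw-click column variant); no
  result in this repository depends on external data.
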