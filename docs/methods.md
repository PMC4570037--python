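# Methods

## The design and its estimand

A split-manuscript trial randomizes subunits of one participant's writing
task: each participant drafts the six methods-section domains of a
randomized-trial manuscript from a protocol, three domains with a
CONSORT-based writing aid and three without.  Because both conditions are
observed within every participant, between-participant variability cancels
from the treatment contrast, but scores from the same participant are
correlated — strongly so within a condition (shared participant and
participant-condition effects) and less strongly across conditions (shared
participant effect only).  The package parametrizes this with a total
per-domain score variance σ² split by the within-condition intraclass
correlation ρ and the cross-condition correlation ρ′:

    σ_b² = ρ′σ²  (participant),  σ_c² = (ρ−ρ′)σ²  (participant-condition),
    σ_e² = (1−ρ)σ²  (residual),

so 0 ≤ ρ′ ≤ ρ ≤ 1 is required throughout.  The estimand is the fixed
intervention effect β on the 0–10 completeness score scale.

## Scoring

The domain score is `10·Σwᵢxᵢ/Σwᵢ` over the domain's rubric keywords, with
xᵢ binary (no partial credit) and the missing-information rule applied as
an OR: a keyword explicitly flagged by the writer as absent from the
source protocol is credited regardless of literal presence.  Weights are
arbitrary positive reals; the normalization makes the score invariant to
rescaling all weights of a rubric.  The essential-elements subscore
applies the same formula to the essential subset and is `None` — not 0 —
when a domain defines no essential keyword.  The global score of a
condition is the mean of the three per-domain scores (domain scores are
the unit of analysis; no pooled-keyword score across domains is computed).
Consensus is defined for exactly two raters; a disagreement without an
explicit resolution is excluded from scoring and reported, rather than
guessed by a voting rule.

The automatic matcher (`auto_match`) exists so synthetic pipelines can run
end to end; it is exact normalized-substring matching with optional
per-keyword synonyms, deliberately free of stemming or fuzzy logic so its
verdicts are auditable.  It does not emulate human rater behaviour.

## Sample size

The two-sample normal-approximation requirement per group,
`n₀ = 2(z_{1−α/2}+z_{power})²σ²/Δ²`, is multiplied by the design effect
`IF = 1+(m−1)ρ−mρ′` and then rounded up to a multiple of m so that the
result maps onto whole participants.  At the default parameters (α=0.05,
power 0.90, Δ=2, σ=4, m=3, ρ=0.8, ρ′=0.4) this gives IF=1.4, an unrounded
requirement of ≈117.7, 120 domain observations per group and 40
participants.  Inflate-then-round is declared explicitly because rounding
n₀ first happens to give the same answer here and the ambiguity would
otherwise be invisible.  `analytic_power` is the matching
normal-approximation expression `Φ(Δ/(σ√(2·IF/n)) − z_{1−α/2})`; being a
large-sample formula it sits slightly above the exact power of the
t-based analysis at small N (about 1.4 percentage points at N=40), which
is visible when comparing it with simulation.

## Estimation

For the balanced 3+3 layout the GLS solution of the mixed model is the
paired contrast: `β̂ = mean(d_p)`, `se = sd(d_p)/√N`,
`d_p = ȳ_p,tool − ȳ_p,control`, with t inference on N−1 df (the
degrees-of-freedom convention that the paired-contrast reduction makes
natural).  The closed form is exact, dependency-light, and verified in
the test suite against an iterative REML fit (statsmodels MixedLM) at
relative tolerance 1e-6 on both β̂ and its SE; that equivalence holds for
interior REML solutions — when a raw variance component estimate is
negative, REML truncates at the boundary and its model-based SE no longer
equals the contrast SE, so the equivalence check conditions on interior
datasets.  Variance components are ANOVA-type method-of-moments estimates
from the three mean squares of the balanced two-way layout, truncated at
zero with a flag.  Per-domain comparisons are classical equal-variance
Student t-tests (observations are independent across participants because
each participant contributes a given domain to exactly one condition).
The ancillary participant-vs-publication comparison averages paired
per-domain differences within protocol and treats protocol means as the
unit (the balanced closed form of the protocol-random-intercept model);
with zero between-protocol spread the CI degenerates to the mean and p is
1 for a zero mean, 0 otherwise.  No multiplicity adjustment is applied
anywhere, matching the analysis plan the package implements.

## Synthetic data: what it does and does not emulate

`generate_trial` draws scores from exactly the normal mixed model above,
on an unbounded scale by default (`clip_mode="none"`): the planning
assumptions (mean 4, SD 4) are themselves on that scale, and
variance-targeted tests need unclipped moments.  `clip_mode="truncate"`
clamps to [0, 10] for realistic-looking demo data and biases means and
variances toward the interior; tests of operating characteristics never
use it.  Defaults mirror the study conditions: 40 participants (the design
requirement), control mean 5.0 and effect 2.1 (the observed condition
means), σ=4, ρ=0.8, ρ′=0.4.  Optional fixed per-domain offsets (summing to
zero) emulate heterogeneous domain difficulty; the default is exchangeable
domains, as the sample-size model assumes.  The generator does not model
rater disagreement, non-normal score distributions, or manuscript text;
passing tests therefore demonstrate correctness of the design/score/
analysis machinery under the assumed model, not robustness to violations
of it.

Keyword realization (`realize_keywords`) turns a target score into a
presence vector by greedy largest-weight-first selection, never exceeding
the target; the realized score is within `10·w_max/Σw` of the target.
Shipped example rubrics are generated, clearly synthetic checklists (the
study's own per-protocol keyword lists were never published), with 4–6
keywords per domain, integer weights 1–5 and ≈40% essential flags.

## Simulations

Power/type-I simulation draws independent replicate trials (replicate
seeds spawned from one root seed, all below 2³¹), runs the primary
analysis on each, and reports the rejection proportion with its binomial
Monte-Carlo SE.  Problem sizes used by the shipped checks — 5000
replicates of 40 participants for operating characteristics, 2000-
participant trials for moment recovery, 200 datasets for the REML
equivalence, 1000 random rubrics for scoring properties — were chosen to
make Monte-Carlo uncertainty small relative to the tolerances being
asserted.  Weight sensitivity re-draws every keyword weight from a named
scheme — `uniform_integer` (iid integers 1–5) or `dirichlet` (symmetric
Dirichlet scaled to the rubric size, preserving total weight), plus the
degenerate `original` — rescoring all domains and re-estimating β per
replicate; the exact weighting systems explored in the original
sensitivity analysis were not published, so these two transparent schemes
are declared in the output metadata instead.

## Numerical and interface choices

Scores divide before scaling (`10·(Σwx/Σw)`) so a fully credited rubric
yields exactly 10.0.  Score tables validate the 3+3 balance but not the
[0,10] range, because unclipped synthetic scores legitimately exit it;
rubric-derived scores are in range by construction.  Degenerate inputs are
explicit errors rather than NaNs: zero-variance paired contrasts, fewer
than two participants, a single protocol in the ancillary comparison.
All randomization is through numpy Generators with explicit seeds; a
sequence records its seed, and every CLI run writes a manifest of its
effective parameters from which the run can be replayed bit for bit.  CLI
subcommands write fixed-name artifacts into a `--out` directory (rather
than per-file output flags) so the manifest fully determines the output
set.

## Known limitations

The scoring model is binary per keyword and presumes honest missing-
information flags.  The analytic power formula is a large-sample
approximation (see above).  Consensus supports exactly two raters.  The
truncated-normal demo mode biases moments by design.  k-of-K allocation
other than 3-of-6 is not surfaced.
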