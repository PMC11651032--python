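# Methods

This note documents the statistical model, the defaults, and the
design decisions behind `delphi-codes`: what the pipeline computes,
what the synthetic panel does and does not emulate, and the numerical
conventions that make runs reproducible.

## The consensus procedure

The pipeline classifies each ICD-9-CM code as *for inclusion* (a
clinical condition for which systemic antimicrobial therapy is
administered in at least 60% of hospital stays) or *for exclusion*.

**Proposal stage.** Two reviewers independently classify every code;
concordant pairs stand, discordant pairs are resolved by a third
reviewer. The invariant is structural and enforced at construction: a
proposal is adjudicated if and only if the first two reviews disagree,
in which case the third review is present and becomes the final
proposal.

**Voting stage.** Panelists score their agreement *with the proposal*
on the 9-point Likert scale. This endorsement semantics matters for
direction: a high-median agreement means the proposal stands, whatever
it proposed; a low-median agreement means the panel rejects the
proposal. Under the default `low_agreement="overturn"` policy a
rejected proposal is flipped (include ↔ exclude); the alternative
`reclassify_exclude` sends every rejected proposal to exclusion. Both
are defensible readings of a low-median outcome — a real study with
no observed overturns cannot distinguish them — so the choice is a
config switch rather than a hard-coded rule.

**Agreement rule.** For one code's votes with quartiles
(q₁, median, q₃):

- IPRAS = `ipras_base` + `ipras_slope` · |`ipras_center` − (q₁+q₃)/2|,
  with defaults 2.35, 1.5 and 5 — the RAND/UCLA appropriateness-method
  disagreement threshold. Its floor (2.35) is attained exactly when
  the interquartile midpoint sits on the scale center; the tolerance
  for spread grows as the panel's center of mass moves toward either
  end of the scale.
- median ≥ 7 and IQR ≤ IPRAS → agreement (high). A tie IQR = IPRAS
  counts as agreement: disagreement requires spread *strictly greater*
  than the threshold.
- median < 4 → agreement (low), by default regardless of dispersion.
  The enumerated non-agreement rules cover only the middle band and
  the high band; extending the dispersion condition symmetrically to
  the low band is plausible but a different rule, available as
  `symmetric_low_rule=true` and off by default.
- everything else → no agreement; the code is re-voted. The middle
  band is implemented as the half-open interval [4, 7) so that even
  panels (whose interpolated median can be e.g. 6.5) still map to
  exactly one status — the tripartition is total over attainable
  medians.

**Quantiles.** The default convention places the p-quantile of n
sorted values at fractional rank 1 + (n−1)p with linear interpolation
between neighbors — the common default across scientific software —
with a nearest-rank alternative (`quantile_method="nearest"`, ties to
the even rank). The quantile pair defaults to (0.25, 0.75), the IQR
proper; classic RAND practice uses the 0.30–0.70 interpercentile
range, and the pair is configurable for that reason. For 18 integer
votes the conventions rarely disagree, but the choice is pinned in
config rather than left implicit. The implementation computes the
interpolation directly; the test suite verifies it exhaustively
against numpy's independent implementation of the same convention.

**Iteration.** Round r+1 evaluates exactly the codes round r left
without agreement. `max_rounds` (default 10) bounds the loop; if it is
exhausted, the remaining codes are reported as an explicit partial
outcome (nonzero CLI exit), never silently classified. In strict mode
(default) missing votes for a pending code are an error; permissive
mode carries such codes forward with a warning. Missing panelist
votes are likewise surfaced against the roster — reported, never
imputed.

## The synthetic panel

Real panel votes for this kind of study are not published, so the
generator produces universes with the statistical structure the
procedure assumes. Its defaults are the study-replication conditions
and are not tuned per run:

| parameter | default | meaning |
|---|---|---|
| `n_codes` | 16,227 | codes carried through the voting flow |
| `n_panelists` | 18 | one vote per ID-unit representative |
| `proposal_threshold` | 0.60 | inclusion iff p_abx ≥ 0.60 (boundary included) |
| `reviewer_error_rate` | 0.02 | per-reviewer independent misclassification |
| `controversy_fraction` | 69/16,227 ≈ 0.43% | codes genuinely contested |
| `controversy_centered_share` | 0.5 | centered vs polarized contested codes |
| `convergence` | 0.8 | round-2 contraction toward the majority |
| `n_covid` | 17 | codes flagged as 2020 SARS-CoV-2 additions |

**Latent model.** Each code carries p_abx, the probability that an
admission under it receives systemic antimicrobials, drawn from a
two-component Beta mixture: a low mode Beta(1.5, 8) and a high mode
Beta(8, 2.5). Infection-like chapters (infectious/parasitic, injury
and poisoning, pregnancy complications) draw the high mode with weight
0.60, all others with weight 0.10. With the default chapter mix
(roughly a quarter of the universe in the infection-like chapters)
this puts the implied inclusion fraction near one in five — the
qualitative shape of a real inclusion set, heavy in injury/poisoning
and infectious chapters, without fitting any published composition.
The synthetic chapter mix itself is stylized, not estimated: no code
list is deposited to estimate it from.

**Votes.** Scores are drawn from explicit discrete distributions over
1..9 (exact, portable, seed-stable): endorsement mass (.25, .50, .25)
on {7, 8, 9}; rejection mass on {1, 2, 3}; centered mass on
{4, 5, 6}. A panelist endorses a correct proposal with probability
`concordance` (default 1.0) and rejects an incorrect one — so codes
whose proposal is wrong (both reviewers erred, probability e²) are
overturned by the panel rather than slipping through. The default
concordance of 1 is deliberate: first-round non-agreement should arise
only through the controversy channel, because any independent
per-panelist dissent across 16k codes would swamp a sub-percent
contested fraction. `severity_shift` (integer in [−2, 2], default 0)
models systematically harsh or lenient raters, clipped to the scale.

**Contested codes.** A Bernoulli(`controversy_fraction`) flag marks
contested codes. Half of them (configurable) vote *centered* — all
panelists in {4, 5, 6}, so the median lands in the middle band — and
half *polarized*: the low-tail share is drawn uniformly between 30%
and 50% of the panel, the rest vote the high tail. The split is drawn
at the panel level rather than iid per panelist: an iid 50/50 tail
mixture frequently lands 10+ of 18 votes in the low tail, where a
median below 4 is *agreement* (low) under the default rule, and such
codes would not actually be contested. With the panel-level split,
both contested regimes fail round-1 agreement with certainty at
n = 18.

**Convergence.** In rounds after the first, each panelist draws from
the majority-side distribution (majority = the side of the previous
round's mean) with probability 1 − 0.5·(1 − c)^(r−1), and otherwise
casts a *moderated dissent* at the scale point adjacent to the
agreement band — 6 when the majority endorses, 4 when it rejects —
rather than an extreme score. The behavioral reading: after seeing
the group's position, residual dissenters soften to moderate
disagreement instead of holding an opposite pole. At the default
c = 0.8 a contested 18-panelist code fails round 2 only if 9+
panelists dissent simultaneously (probability ≈ 1e-5), so a
study-scale run settles all contested codes in round two in the
overwhelming majority of seeds — the two-round termination shape. No
information flows back to panelists other than this majority side,
mirroring a procedure where per-round feedback goes to the research
team only.

**What the generator does not emulate.** Panelist identity is opaque
(no hospital covariates, no correlated blocs); comments and
justifications are not modeled; contested codes are not placed on the
specific clinical topics a real panel would dispute; and the chapter
mix and Beta parameters are declared, not estimated. Passing tests
therefore demonstrate that the *procedure* — statistics, rules,
iteration, accounting — behaves correctly under realistic load and
structure, not that the synthetic votes are distributionally faithful
to any real panel.

## Reporting conventions

Reports carry counts and recompute percentages from them at report
time (on exact rationals, so printed-precision reproduction is
independent of binary floating point). The default rounding is half
away from zero at the requested decimals; an explicit `truncate` mode
exists because real reports occasionally truncate — reproducing such
a figure is then a deliberate call-site choice, not a global default.
Known count inconsistencies between a declared universe size and the
number of codes actually evaluated are surfaced as validation
warnings; the tool never decides which figure is authoritative.

## Problem sizes

The default test suite runs the full pipeline at study scale (16,227
codes × 18 panelists), enumerates all 9^n vote vectors for n ≤ 6
(~598k classifications) against an independent transcription of the
rules, and calibrates the first-round non-agreement rate over 20
seeded universes; the whole suite completes in well under a minute
per component on one CPU. The acceptance script uses ten universes
for calibration and n ≤ 5 for the exhaustive check, keeping its end-
to-end runtime under a minute.

## Known limitations

- The engine treats votes as given; it does not model panelist
  attrition, vote revision within a round, or weighting by expertise.
- Chapter assignment is prefix-interval lookup over the 17 numeric
  chapters plus V/E supplementary classifications; no code-existence
  dictionary is bundled, so a syntactically valid but nonexistent
  code (e.g. 008.99) is accepted if its prefix is in range.
- The overturn-vs-reclassify question for low-median agreements is
  config-selectable precisely because no real-world outcome
  disambiguates it; downstream analyses should state which policy
  they ran.
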