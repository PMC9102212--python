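# Methods

## Design

`tsmr` implements two-sample Mendelian randomization for the
summary-statistics setting: variant–exposure associations from one GWAS,
variant–outcome associations from non-overlapping case–control GWAS, one
or more outcome cohorts per disease. The pipeline is two-stage, mirroring
the forest-plot layout such analyses report: a fixed-effects IVW estimate
per cohort (pooling per-SNP Wald ratios), then a fixed-effects
meta-analysis of the cohort estimates per outcome. When every cohort's
per-SNP ratios were pooled in a single stage instead, the combined beta
and SE would be identical (the weights compose; the test suite asserts
this decomposition) — only the partition of Cochran's Q differs, so the
two-stage form additionally yields the between-cohort Q that the report
prints.

Assumptions inherited from the estimator: instruments are valid (associated
with the exposure, no direct outcome effect, no confounding path),
mutually independent (the motivating design uses two variants on different
chromosomes, so no between-SNP correlation adjustment is offered), and a
single common causal effect underlies all SNPs and cohorts (fixed effects
everywhere — no random-effects variant is implemented, and pleiotropy-robust
estimators are out of scope because they need more instruments than this
design has).

## Wald ratio standard error

The per-SNP SE is the first-order delta method, se(θ̂ⱼ) = σ_Yj/|β̂_Xj|,
which ignores exposure-side sampling error. This is the convention under
which fixed-effects IVW over the ratios reduces to the standard weighted
formula, and it is accurate when instrument z-scores are large (here ~9
and ~7, so the exposure term contributes ~1% of the variance). The
second-order SE, sqrt(σ_Yj²/β̂_Xj² + β̂_Yj²σ_Xj²/β̂_Xj⁴), is available via
`wald_ratio(..., second_order=True)` but off by default. The small
anti-conservativeness of the first-order choice is visible in the null
calibration check as a rejection rate a fraction of a point above 5%.

## Harmonization

The exposure file's effect allele is canonical. Outcome records are
reconciled by exact allele match (`as_is`), effect/other swap
(`sign_flip`: outcome beta negated, frequency complemented), strand
complement (`strand_flip`: labels change, beta does not), or both. An
outcome record irreconcilable under all four actions is excluded with
reason `allele_mismatch`; exposure variants absent from an outcome table
are excluded with `missing_in_outcome`. Exclusions are recorded rows, not
exceptions; only a cohort with *zero* usable instruments aborts the run.

Palindromic variants (A/T, C/G) carry no strand information in their
labels. They are oriented by comparing minor/major allele frequency
between the two files and excluded with `palindromic_ambiguous` when
either frequency is missing or within `palindrome_eaf_window` of 0.5
(default 0.08, i.e. eaf in [0.42, 0.58] — a conservative standard choice;
the motivating instruments are non-palindromic C/T and T/C so the default
never binds there). For retained palindromes the action label records
both what happened to the letters and to the sign: frequency-concordant
readings give `as_is`/`sign_flip`, frequency-discordant readings imply
the other strand and give `strand_flip`/`strand_flip_and_sign_flip`.
The window comparison uses a 1e-9 absolute tolerance so decimal
boundaries like 0.42 fall inside the closed interval.

No proxy/LD lookup is attempted for missing variants, and indels or
multi-allelic records are rejected at read time.

## Numerical choices

- Confidence intervals use the exact normal quantile (≈1.959964 at
  α = 0.05), never 1.96; rounding happens only in the human-readable log
  (OR to 2 dp, p to 3 significant figures).
- P-values are never truncated to zero: beyond |z| ≈ 38.5, where the
  normal tail underflows double precision, the smallest positive
  subnormal (5e-324) is reported.
- Cochran's Q with df = 0 (a single pooled element) has no p-value; it is
  reported blank/NA, never 1.0.
- A Wald ratio with zero exposure beta is an error naming the variant
  (the instrument carries no information), distinct from a zero *outcome*
  beta, which is a valid θ̂ = 0.
- The machine-readable results table is written at full float precision;
  round-tripping reproduces beta and SE exactly.

## The synthetic generator

Summary statistics are simulated at the estimate level: each reported
beta is a normal draw around its truth with the stated SE —
β̂_Xj ~ N(γⱼ, σ_Xj²) and, per cohort c, β̂_Yjc ~ N(θγⱼ + αⱼ, σ_Yjc²) with
αⱼ an optional per-SNP direct (pleiotropic) effect. This is exactly the
sampling model under which IVW is derived, which is the point: it makes
bias, coverage and Q-calibration checks sharp. It deliberately does *not*
emulate genotype-level features of real data — LD between variants,
winner's curse from instrument selection, allele-frequency estimation
error, sample overlap between exposure and outcome studies, or
case–control ascertainment — so passing checks demonstrate correctness of
the estimation chain, not robustness to those real-data pathologies.

The canonical fixture emulates the motivating study's shape: two
instruments of clearly unequal strength (expected exposure z ≈ 9.3 and
7.4, matching p ≈ 1e-20 and 1.8e-13 at n = 9876, frequencies 0.27 and
0.37), three outcome cohorts for one disease (true log-OR −0.139, OR
0.87) and two for the other (−0.083, OR 0.92). Outcome-side SEs (0.0227
and 0.0237 per SNP per cohort) are sized so the combined estimate has
roughly 50% power at the 5% level — borderline by construction, so both
significant and non-significant runs are reachable by seed, as in the
study the design mirrors. One global seed drives everything through
`numpy.random.SeedSequence` spawning: the exposure study and each cohort
get independent child streams (two-sample independence), and replicate
seeds are derived deterministically, so all outputs are byte-stable for a
fixed seed. Simulated alleles cycle through non-palindromic pairs so the
generator never manufactures strand ambiguity unless asked.

Monte-Carlo checks use 2000 replicates of the full
simulate→harmonize→ratio→IVW→meta chain (a few seconds of CPU), which
puts the Monte-Carlo SE of a coverage proportion at ~0.5 percentage
points — tight enough to detect meaningful miscalibration.

## Open design points resolved

- Exposure units are opaque: results are "per unit increase in genetically
  predicted exposure" (the source exposure GWAS defines the scale), and the
  scale-equivariance test guarantees unit choices cannot change z-scores
  or p-values.
- The CLI `--outcome` flag accepts `[OUTCOME:]COHORT=PATH`; without the
  prefix the cohort label doubles as its outcome name.
- Outcomes are analyzed independently with no multiplicity adjustment
  across them.
- A failing cohort (no usable instruments) aborts before anything is
  written, so partial results never appear; the run log, created first,
  is the only artifact of a failed run.

## Known limitations

- Fixed-effects only; heterogeneity is *reported* via Q, never absorbed
  into wider intervals.
- No LD pruning, proxy lookup, liftover, or variant-ID resolution; inputs
  must already be on a common build with shared rsIDs.
- The first-order ratio SE slightly understates uncertainty for weak
  instruments; use `second_order=True` if instrument z-scores are modest.
- Binary-outcome betas are taken as log-odds at face value; no
  linear-to-logistic conversion is attempted.
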