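# Methods

## The admixture-constraint test

The target population is modelled as a two-source admixture. At site *i*
the observed data are the counted-allele count *Xᵢ* among *Nᵢ* observed
allele calls in the target, and point estimates of the source frequencies
*fᵢ^S1*, *fᵢ^S2*. Two binomial models for *Xᵢ* are compared:

* **unconstrained** — Xᵢ ~ B(Nᵢ, f) with f free; the MLE is
  fᵢ = Xᵢ/Nᵢ, log-likelihood ℓ₀;
* **constrained** — f must equal a mixture
  f̂ᵢᵀ = γ̂ᵢ fᵢ^S1 + (1 − γ̂ᵢ) fᵢ^S2, where γ̂ᵢ ∈ [0, 1] minimises the
  squared deviation (fᵢ − [γ fᵢ^S1 + (1 − γ) fᵢ^S2])²; log-likelihood ℓ₁.

In closed form γ̂ᵢ = clamp((fᵢ − fᵢ^S2)/(fᵢ^S1 − fᵢ^S2), 0, 1), and
γ̂ᵢ ≡ 1 when the sources are equally frequent (every γ is then optimal,
and the constrained model collapses to the shared source frequency).
Because fᵢ is the binomial MLE, ℓ₀ ≥ ℓ₁ always, and

  Λᵢ = 2(ℓ₀ − ℓ₁) ≥ 0,  p = P(χ²₂ > Λᵢ) = exp(−Λᵢ/2).

One notational subtlety: the statistic is sometimes written −2(ℓ₁ − ℓ₀)
with the labels of the two likelihoods swapped between sentences; the
implementation fixes ℓ₀ = unconstrained, ℓ₁ = constrained, which is the
only assignment making Λ non-negative.

### Assumptions and why the test is conservative

Source frequencies enter the likelihood as *fixed known* quantities; their
sampling noise is not propagated. The least-squares γ̂ is also the
likelihood-maximising mixture (the binomial log-likelihood is unimodal in
f with mode at fᵢ, so the best achievable mixture is the one closest to
fᵢ) — hence whenever fᵢ falls inside the interval spanned by the source
frequencies, the constraint is inactive and Λ = 0 exactly. Combined with
the boundary constraint on γ, the χ²₂ reference distribution strongly
over-covers: on simulated null data the fraction of sites with p < 0.05
is ~0.002. The nominal degrees-of-freedom bookkeeping would suggest fewer
than two; the reference is kept at χ²₂ as stated, and the significance
cutoff is calibrated empirically instead (below), so the conservativeness
is accounted for where it matters.

### Filters

A site is tested only if (a) each of target, source1 and source2 has at
least `min_individuals_per_pop` (default 10) individuals with a genotype
call — the count is individuals, while *Nᵢ* counts allele calls (1 per
pseudohaploid, 2 per diploid individual) — and (b) the counted allele is
present in both sources (frequency > 0). Sites where a source is *fixed*
for the counted allele are kept by default; `require_source_freq_not_fixed`
excludes them, which matters only if the counted-allele polarity is
ambiguous in the input. Filtered sites are reported with machine-readable
reason codes (`min_individuals:source1`, `source_freq_zero:source2`, …),
never silently dropped.

### Numerical choices

* p-values use the closed form exp(−Λ/2) evaluated in log space;
  `log10_p` stays exact far past double-precision underflow of p, and p
  itself is floored at 1e-320 so it remains in (0, 1].
* |Λ| < 1e-9 is clamped to 0 (floating-point guard near the inactive-
  constraint case); a genuinely negative Λ beyond that is an internal
  error, not a value to report.
* If f̂ᵢᵀ ∈ {0, 1} while 0 < Xᵢ < Nᵢ the constrained likelihood is −∞;
  the site is reported with Λ = +inf, p at the floor, and a `degenerate`
  flag. With the source-frequency-> 0 filter active this requires both
  sources fixed at 0, which the filter removes.
* 0·log 0 ≡ 0 at the support boundary (Xᵢ ∈ {0, Nᵢ}).

## Branch-length outlier scan

Per-SNP pairwise Fst among three populations uses Hudson's estimator with
finite-sample correction:

  num = (p̂₁ − p̂₂)² − p̂₁(1 − p̂₁)/(n₁ − 1) − p̂₂(1 − p̂₂)/(n₂ − 1),
  den = p̂₁(1 − p̂₂) + p̂₂(1 − p̂₁),

with nₖ observed allele calls. This single-locus ratio estimator needs no
variance components and behaves sensibly at the small, unequal sample
sizes of ancient cohorts; a Weir–Cockerham variant (allele-count form,
appropriate when within-individual heterozygosity is unobservable, as for
pseudohaploid calls) is available behind a flag. Sites with fewer than two
observed alleles in a population, or with both populations fixed for the
same allele (denominator 0), are invalid and excluded from ranking.

Branch lengths decompose the three pairwise values additively,
branch_A = (Fst_AB + Fst_AC − Fst_BC)/2 and cyclically, so
branch_A + branch_B = Fst_AB exactly. Raw (possibly negative) values are
ranked — truncating at zero first would tie a large mass of sites at rank
0 — and a truncated variant is reported alongside. The "empirical P value"
of a site is the upper-tail rank quantile: (# valid sites with branch ≥
this one)/(# valid sites), so quantiles lie in (0, 1] and ties share a
value. The prioritised set defaults to quantile ≤ 0.01 (inclusive, so
continuous data flags exactly the top 1%); a strict `<` mode mirrors the
convention of reporting "empirical P < 0.01".

Merged comparison groups (e.g. pooling the target with its major source
into a combined early-farmer population) are formed by summing x and n
per site before Fst — exact count pooling, not frequency averaging.

## Calibration simulation

The significance cutoff is calibrated on synthetic data with known truth:

| parameter | default | meaning |
|---|---|---|
| n_null_sites | 100 000 | sites whose target frequency is exactly the mixture |
| n_selected_sites | 1 000 | sites with the mixture shifted by ±δ |
| source_freq_model | uniform(0.05, 0.95) | joint draw of (f^S1, f^S2); a beta model or an empirical two-column frequency table (sampled with replacement) can be substituted |
| admixture_gamma | 0.93 | true mixing proportion of source 1 |
| sample_sizes | (100, 100, 100) | observed allele calls per population per site |
| selection_effect δ | 0.35 | additive target-frequency shift, sign randomised, clamped to [0, 1] |
| missing_rate | 0 | per-call thinning (scalar or per-population) |
| cutoff grid | 1e-2 … 1e-12 | decade steps |

Null target counts are binomial at the *true* mixture, but the scan sees
only the *estimated* source frequencies (source counts are drawn
binomially too), exactly as in real data — so the null is not a pure
χ² null and an occasional extreme statistic is possible: across seeds,
0–2 of 1e5 null sites fall below 1e-8. FDR = FP/(FP+TP) per cutoff (0
when nothing is called) and PDR = TP/n_selected_sites; the chosen cutoff
is the zero-FDR cutoff with the highest PDR, exact ties resolving to the
smaller (more conservative) cutoff. At the defaults the 1e-8 cutoff sits
in the zero-FDR region with PDR ≈ 0.4; PDR is bounded away from 1 because
a shifted frequency that lands back inside the source interval is
genuinely invisible to a frequency-based test.

All draws come from named random streams keyed on (seed, stream name)
(`numpy` Philox-seeded `default_rng([seed, crc32(name)])`), so enlarging a
study extends existing draws rather than reshuffling them, and a single
integer seed reproduces everything.

### The genotype-level generator

`generate_synthetic_dataset` shares the same per-site truth but draws one
allele per individual (Bernoulli at the population's true frequency,
coded 0/2, masked missing at the configured rate) and writes EIGENSTRAT
files plus a truth table; `compute_counts` on the read-back reproduces
the generator's count table exactly. What it emulates: pseudohaploid
sampling, per-population sample sizes and missingness of a capture-based
ancient-DNA cohort. What it does not: linkage (sites are independent),
genuine drift/coalescent structure (frequencies are drawn, not evolved),
reference bias, and post-mortem damage. Passing tests therefore validate
the statistics under the stated sampling model, not robustness to those
real-data artefacts.

## Formats and conventions

Coordinates are 1-based inclusive throughout (.snp and VCF convention);
BED annotation input is converted from 0-based half-open internally.
EIGENSTRAT genotype codes are copies of the counted allele with 9 =
missing; polarity (whether codes count the ALT or REF allele) is an
explicit switch defaulting to ALT, since producers differ. Per-individual
ploidy is inferred (all non-missing codes in {0, 2} ⇒ pseudohaploid) and
overridable — a diploid individual without observed heterozygotes is
indistinguishable from a pseudohaploid one. Multi-allelic VCF records are
skipped with a logged count rather than raised, as capture panels are
biallelic by design. Chromosome labels are normalised ("chr1" ≡ "1")
before intersection keying; candidate sets are keyed by (chromosome,
position) rather than SNP ID, the stable join key across tools.

## Problem sizes

The test suite runs the full calibration study (1e5 + 1e3 sites) once and
otherwise uses cohorts of a few hundred to a few thousand sites with
20–200 individuals, which already pin down every statistic to the asserted
tolerances; the estimator-vs-grid-search cross-check covers 1e4 random
sites at grid step 1e-6 via a coarse-to-fine scan (exact on the full grid
because the objective is quadratic in γ). The power-band check (majority
of shifted sites recovered at the zero-FDR cutoff) is run at 200 allele
calls per population; at 100 calls the recoverable fraction at that cutoff
is ~0.48, limited by shifts that remain inside the source interval.

## Limitations

* Two sources only; the constrained model has no concept of a third
  ancestry stream or of continuous gene flow.
* Per-site independence: no haplotype information, no LD-aware
  significance; XP-EHH is ingested from external tools, never computed.
* Source-frequency noise is unpropagated; with very small source samples
  the test loses calibration (mitigated by the ≥ 10-individuals filter
  and the simulation-based cutoff).
* The empirical-quantile prioritisation is relative by construction: the
  top 1% exists in any dataset, selected or not — it ranks candidates,
  it does not test them.
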