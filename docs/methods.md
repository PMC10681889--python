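# Methods

## Karyotype model

An ISCN karyotype is parsed into clones (split on `/`), each with a leading
chromosome count (single value or `51-56` / `51~56` range), a sex token, an
ordered abnormality list, and an optional bracketed cell count (`[12]`,
`[cp10]` for composite). Recognised abnormality tokens: whole-chromosome
gains/losses (`+8`, `-7`), markers (`+mar`, `+2mar`), `inc`, structural
tokens (`t/del/dup/der/inv/add/i/ins/dic/r/trp` with chromosomes and
breakpoints), `?` uncertainty prefixes, `c` constitutional suffixes, and
`idem`/`sl`/`sdl` stemline references (expanded by unioning the stemline's
abnormality list with the subclone's additions/removals). Anything else is
preserved as `kind=other` with a parse warning — the parser only hard-fails
on an empty string or a malformed leading count, because clinical corpora
must flow through rather than crash.

The copy-number profile of a clone starts from 46,XX/46,XY per the sex token
(unknown token → XX with a warning; the X/Y baseline is the multiplicity of
X/Y in the token, so `45,X` works) and applies each certain named gain/loss.
Markers raise the nominal count but name no chromosome; structural tokens
contribute no whole-chromosome change, since the risk profile is defined on
whole-chromosome trisomies only.

**Certainty semantics.** When a clone carries `+mar`, `inc` or a `?` token,
every chromosome *not* explicitly gained by a certain named token is labelled
uncertain — unidentified material could hide a gain of it — while a written
`+17` is always trusted. This is the one reading under which the
definite/provisional split is computable from the karyotype alone: named
gains anchor the certain statuses, everything else is enumerable.

**Clone selection.** One profile is classified per patient: the first
document-order clone whose count range intersects 51–67 (ISCN lists the
stemline first), falling back to the highest-count clone. Multi-clone
karyotypes with two distinct HeH clones therefore resolve to the stemline;
the choice is recorded in the reason trail.

## Classification

Eligibility: count range intersects modal 51–67 (a range crossing the
boundary is eligible with a warning). Exclusions, applied to eligible cases:

* **Ph-positive** — any clone matches t(9;22)(q34;q11); breakpoint matching
  tolerates sub-band refinement (q11 matches q11.2), `?` wildcards, and
  tokens written without breakpoints.
* **Masked doubled hypodiploidy** — a doubled near-haploid/low-hypodiploid
  genome mimics HeH but arrives in pairs. Operationalisation (the pattern
  itself is a package design choice): fully certain profile, all autosome
  copy numbers even (0/2/4), and ≥4 tetrasomic autosomes (threshold
  configurable). The detector never fires on an uncertain profile: a case
  is not excluded on ambiguous evidence.

The decision table over (gain5, gain17, gain18, gain20) is shipped as
versioned JSON (`rules/ukall_heh.json`) and the engine is table-driven, so a
transcription correction is a data edit. The default encodes: GR iff
(+17 ∨ +18) ∧ ¬(+5 ∧ +20). Uncertain statuses are resolved by exhaustive
enumeration (≤16 resolutions); agreement ⇒ definite, disagreement ⇒
provisional named from the baseline resolution uncertain → not gained
(a karyotype shows what was seen). Note a consequence worth knowing: with a
marker present, a good-risk call can never be definite (the marker could
always be the missing +5 or +20), while a poor-risk call can (e.g. certain
+5 and +20 force PR under every resolution).

Age-window and lineage filters are row filters on the clinical table, not
karyotype logic.

## Cohort simulator

The generator emulates, per record: a latent label drawn from
`group_mix` (defaults GR 0.64, PR 0.22, non-HeH 0.10, Ph-positive 0.02,
masked-doubled 0.02 — giving GR/PR ≈ 74/26 among HeH); an ISCN string whose
5/17/18/20 pattern is drawn uniformly from the decision-table combinations
of the target class, padded with extra gains weighted toward the classic HeH
chromosomes (21 twice, X, 14, 6, 4, 17, 18, 10 …) until the written modal
number (51–60, mass at 53–57) equals 46 + gains; ambiguity injected by
replacing a non-profile gain with `+mar` (rate 0.17) and/or dropping one and
appending `inc` (rate 0.12), so ~27% of HeH karyotypes are ambiguous and the
intended polarity is preserved by construction (only non-profile gains are
touched, so the baseline resolution equals the intended class).

Covariates use the published cohort's marginals: age bands 1–9/10–14/15–24/25+
at 78/9/9/4%, 53% male, WCC bands 0–49/50–99/100+ at 91/6/3%, and
log₁₀(MRD) ~ Normal(−4.71, 1.36), calibrated so that ~30% of records are
≥0.01% and ~19% ≥0.03%. MRD is independent of risk group by default
(matching the published null association); `mrd_group_shift` couples them
for sensitivity work.

Endpoints follow exact proportional hazards: cumulative hazard Λ(t) = λt^k
(Weibull shape k, default 1 = exponential) with λ set so the good-risk
5-year cumulative risk equals the configured value
(λ = −ln(1−risk)/5^k), and the PR hazard multiplied by the configured
hazard ratio (defaults 3.52 relapse, 2.80 event, 3.21 death). Censoring is
administrative: one shared trial-entry time per patient uniform over a
4-year accrual window against a 10-year horizon, so follow-up is uniform on
[6, 10] years with median 8. Contaminant records receive good-risk hazard
rates; they are excluded before validation anyway. Everything is a pure
function of (config, seed); the latent label is written to a sidecar file so
validation cannot silently use the truth.

What the simulator does **not** emulate: inter-chromosomal gain
correlations beyond marginals, age/WCC association with risk group,
competing risks, era effects, or informative censoring. Passing tests
therefore demonstrate that the machinery recovers known truth under the
assumed model, not that the profile is prognostic in any real population.

## Validation battery

* Kaplan–Meier product-limit with simultaneous decrement at ties, Greenwood
  variance, log(−log) 95% CIs; 5-year values read from the step function at
  t = 5.0 exactly.
* Log-rank chi-square across groups.
* Cox proportional hazards with the Efron tie correction (better behaved
  under the year-granularity ties registries export; Breslow available via
  lifelines options), Wald CIs and p-values. MRD enters continuously as
  log₁₀(MRD + 10⁻⁵); the offset keeps MRD-negative samples finite near the
  assay floor.
* Harrell's c: comparable-pair concordance with ties counted ½.
* Schoenfeld residual proportionality check, identity time transform;
  the global p sums the per-covariate chi-squares on k df (a pragmatic
  approximation; per-covariate tests are the primary readout).
* Subgroup forest over sex, age band, WCC band and NCI risk (standard iff
  age 1–9 **and** WCC < 50×10⁹/L — the conventional definition,
  reconstructed because it is used but rarely defined); levels with an
  eventless arm are dropped with a warning. Heterogeneity via Cochran's Q
  on the subgroup log-HRs with inverse-variance weights, χ² on
  (levels − 1) df.
* Demographic comparisons use chi-square, with Fisher's exact fallback when
  a 2×2 table has an expected cell < 5 (larger sparse tables keep chi-square
  and are flagged).
* The report also compares definite vs provisional strata by log-rank per
  endpoint; "5-year relapse rate" is computed as 1 − KM(relapse-free) — a
  cumulative-incidence estimator would differ in the presence of competing
  risks, which the simulator does not generate.

Numeric report fields are serialised at 10 significant digits for regression
testing; artifacts carry package version, config hash and seed headers.

## Problem sizes and numerical choices

Parameter-recovery studies use 50 replicate cohorts of 2500 per arm for
hazard-ratio recovery (Monte-Carlo SE of the mean ≈ 1% of the HR), single
20,000-subject arms for 5-year KM recovery (SE ≈ 0.2 percentage points),
200 replicates of n = 90 for the small-stratum study (median reported;
replicates with an eventless arm are skipped, as a forest would drop them),
and 200 replicates for the type-I-error calibration of the Schoenfeld and
Cochran's Q tests (acceptance band 1–10% around the nominal 5%). Toy-data
oracles (hand product-limit, manual log-rank tables, a 1e-4 grid over the
Efron partial likelihood, exhaustive concordance pair counts) pin the
estimators independently of the libraries that implement them.

## Known limitations

* The ISCN grammar is the subset needed for whole-chromosome risk
  profiling; ring/dicentric/hsr details, nested subclone trees beyond
  idem-chains, and FISH/array nomenclature (`ish`, `arr`) are out of scope
  (tokens are preserved with warnings).
* The masked-hypodiploidy detector is a heuristic; a doubled clone written
  with odd-count noise will evade it, and the true pattern space is wider
  than all-even-plus-tetrasomies.
* Near-triploid masked patterns above modal 67 are not separately handled
  (they fail eligibility).
* Provisional-group composition depends on which statuses the injected
  ambiguity hits; the simulator reproduces the overall ambiguity rate, not
  the published P-GR/P-PR split.
* The Schoenfeld global p is an approximation (see above).
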