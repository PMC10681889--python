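# hehprofile

Cytogenetic risk profiling for **high-hyperdiploid (HeH) acute lymphoblastic
leukaemia**, end to end: ISCN karyotype parsing, the UKALL-HeH trisomy
decision rule with definite/provisional assignment, synthetic cohort
simulation, and survival-analysis validation.

## The problem

HeH — the non-random gain of whole chromosomes giving a modal number of
51–67 — is the most common genetic subtype of childhood B-cell precursor
ALL. Outcome is good on average, but the subtype is so common that it still
contributes a large share of all relapses, so a within-HeH risk factor is
clinically valuable. The UKALL-HeH profile stratifies HeH patients by the
trisomy status of four chromosomes: a patient is **good risk (GR)** iff the
karyotype carries +17 and/or +18 *without* the +5/+20 combination, and
**poor risk (PR)** otherwise.

Real-world karyotypes are messy: marker chromosomes (`+mar`) and incomplete
karyotypes (`inc`) leave the identity of some gained material unknown, so
the classifier enumerates every resolution of the uncertain trisomy
statuses. If all resolutions agree the call is **definite** (D-GR / D-PR);
if they disagree it is **provisional** (P-GR / P-PR), named from the
baseline resolution (uncertain → not gained). Karyotypes with
t(9;22)(q34;q11) or a masked doubled-hypodiploid pattern (all-even autosome
counts with ≥4 tetrasomies) are excluded as distinct subtypes.

Validation of the merged GR/PR groups uses the standard survival battery:
Kaplan–Meier estimates with Greenwood variance and log(−log) CIs, log-rank
tests, Cox proportional-hazards models (Efron ties; unadjusted and adjusted
for end-of-induction MRD entered as log₁₀(MRD + 10⁻⁵)), Harrell's c-index,
Schoenfeld-residual proportionality checks, and a subgroup forest with
Cochran's Q heterogeneity test. Patient-level data behind published
validations are not public, so the package ships a cohort simulator whose
defaults emulate the published multi-trial cohort (GR/PR ≈ 74/26, ~27%
ambiguous karyotypes, 5-year good-risk relapse/event/death risks of
6%/9%/5%, PR hazard ratios 3.52/2.80/3.21, uniform entry over 4 years with
a 10-year horizon → median follow-up 8 years).

## Worked example

```python
from hehprofile import classify

a = classify("57,XX,+X,+4,+6,+10,+14,+17,+18,+21,+21,+mar[12]/46,XX[8]")
print(a.group.value, a.merged_group)   # P-GR GR
```

`+17` and `+18` are seen, but the marker could hide a +5 or +20, and one
resolution of those uncertain statuses is poor risk — hence provisional
good risk.

A full simulated validation (`python examples/validate_cohort.py`, n=2000,
seed 7) prints, for the relapse endpoint:

```
  events GR/PR        : 121/129
  5-year KM GR        : 94.6% (93.2%-95.7%)
  5-year KM PR        : 79.5% (75.4%-83.0%)
  unadjusted HR       : 3.54 (2.76-4.54), p=1.7e-23
  MRD-adjusted HR     : 3.55 (2.77-4.55)
  heterogeneity Q     : 6.24 (df=10), p=0.79
```

The unadjusted hazard ratio recovers the generating 3.52; adjusting for MRD
(simulated independent of risk group) barely moves it; Q finds no subgroup
heterogeneity because none was simulated. The other examples
(`examples/*.py`) cover parsing, cohort simulation and parameter recovery.

A thin CLI wraps the same functions:

```bash
heh simulate --out cohort.csv --seed 17 --n 1169
heh classify --in cohort.csv --out assigned.csv
heh validate --in assigned.csv --out report/
heh run --config pipeline.yaml       # all stages, reproducibility headers
heh parse --text "52,XY,+5,+8,+10,+17,inc[10]"
```

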