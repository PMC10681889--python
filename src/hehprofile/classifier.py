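"""UKALL-HeH risk classification of parsed karyotypes.

High hyperdiploidy (HeH) — the non-random gain of chromosomes giving a modal
number of 51–67 — is the most common genetic subtype of B-cell precursor ALL.
The UKALL-HeH profile stratifies HeH patients into a good-risk (GR) and a
poor-risk (PR) group from the trisomy status of chromosomes 5, 17, 18 and 20.
This module applies, in order:

1. *eligibility*: modal chromosome number intersects 51–67;
2. *exclusions*: Ph-positive karyotypes (t(9;22)(q34;q11)) and chromosome
   patterns indicative of a masked near-haploid / low-hypodiploid genome
   (a doubled hypodiploid clone mimics HeH but shows only even autosome
   copy numbers with multiple tetrasomies);
3. the four-chromosome *decision table*, shipped as versioned JSON data;
4. *definite vs provisional* assignment: markers, ``inc`` and ``?`` tokens
   leave some trisomy statuses uncertain, so every resolution of the
   uncertain statuses is enumerated — if all resolutions agree the call is
   definite (D-GR / D-PR), otherwise provisional (P-GR / P-PR) with the
   group named from the baseline resolution (uncertain → not gained: a
   karyotype shows what was seen).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources
from itertools import product

import pandas as pd

from .iscn import (
    CopyNumberProfile,
    ParsedKaryotype,
    copy_number_profile,
    has_structural,
    parse_karyotype,
    select_classification_clone,
)

__all__ = [
    "TrisomyStatus",
    "ProfileInput",
    "RiskRule",
    "RiskGroup",
    "RiskAssignment",
    "PROFILE_CHROMOSOMES",
    "PH_PATTERN",
    "is_heh_eligible",
    "detect_masked_doubled",
    "exclusion_check",
    "trisomy_status",
    "assign_risk",
    "classify",
    "classify_cohort",
]

#: The four chromosomes whose trisomy status defines the profile.
PROFILE_CHROMOSOMES: tuple[str, ...] = ("5", "17", "18", "20")

#: The Philadelphia translocation; its presence defines a distinct subtype.
PH_PATTERN = "t(9;22)(q34;q11)"

HEH_MODAL_LOW = 51
HEH_MODAL_HIGH = 67


class TrisomyStatus(Enum):
    GAINED = "gained"
    NOT_GAINED = "not_gained"
    UNCERTAIN = "uncertain"


class RiskGroup(Enum):
    D_GR = "D-GR"
    P_GR = "P-GR"
    D_PR = "D-PR"
    P_PR = "P-PR"
    NOT_HEH = "not_heh"
    EXCLUDED = "excluded"

    @property
    def merged(self) -> str:
        """Merged two-level group: provisional cases join their polarity."""
        if self in (RiskGroup.D_GR, RiskGroup.P_GR):
            return "GR"
        if self in (RiskGroup.D_PR, RiskGroup.P_PR):
            return "PR"
        return "none"

    @property
    def is_provisional(self) -> bool:
        return self in (RiskGroup.P_GR, RiskGroup.P_PR)


@dataclass(frozen=True)
class ProfileInput:
    """Trisomy statuses of chromosomes 5, 17, 18 and 20 plus ambiguity sources."""

    status5: TrisomyStatus
    status17: TrisomyStatus
    status18: TrisomyStatus
    status20: TrisomyStatus
    ambiguity_source: frozenset[str] = frozenset()

    @property
    def statuses(self) -> tuple[TrisomyStatus, TrisomyStatus, TrisomyStatus, TrisomyStatus]:
        return (self.status5, self.status17, self.status18, self.status20)


class RiskRule:
    """The 16-entry decision table over (gain5, gain17, gain18, gain20).

    Table-driven so that a transcription correction is a data edit.  The
    default table encodes the UKALL-HeH profile: good risk iff chromosome 17
    and/or 18 is gained and chromosomes 5 and 20 are not both gained.
    """

    def __init__(self, table: dict[tuple[bool, bool, bool, bool], str], version: str = "custom"):
        expected = set(product((False, True), repeat=4))
        if set(table) != expected or not all(v in ("GR", "PR") for v in table.values()):
            raise ValueError(
                "risk rule table must map all 16 (gain5, gain17, gain18, gain20) "
                "combinations to 'GR' or 'PR'"
            )
        self.table = dict(table)
        self.version = version

    def __call__(self, g5: bool, g17: bool, g18: bool, g20: bool) -> str:
        return self.table[(g5, g17, g18, g20)]

    @classmethod
    def from_mapping(cls, mapping: dict, version: str = "custom") -> "RiskRule":
        table = {}
        for key, val in mapping.items():
            bits = tuple(bool(int(b)) for b in key.split(","))
            if len(bits) != 4:
                raise ValueError(f"rule key {key!r} must have 4 comma-separated 0/1 flags")
            table[bits] = val
        return cls(table, version=version)

    @classmethod
    def from_json(cls, path) -> "RiskRule":
        with open(path) as f:
            obj = json.load(f)
        return cls.from_mapping(obj["table"], version=obj.get("version", "file"))

    @classmethod
    def default(cls) -> "RiskRule":
        return _load_default_rule()


@lru_cache(maxsize=1)
def _load_default_rule() -> "RiskRule":
    ref = resources.files("hehprofile").joinpath("rules/ukall_heh.json")
    obj = json.loads(ref.read_text())
    return RiskRule.from_mapping(obj["table"], version=obj.get("version", "default"))


@dataclass(frozen=True)
class RiskAssignment:
    """The outcome of classification plus a machine-readable reason trail."""

    group: RiskGroup
    reasons: tuple[str, ...] = ()

    @property
    def merged_group(self) -> str:
        return self.group.merged


def is_heh_eligible(pk: ParsedKaryotype) -> tuple[bool, str]:
    """Modal-number eligibility: the classification clone's count range must
    intersect 51–67.  Returns ``(eligible, reason)`` with reason one of
    ``in_range``, ``below_range``, ``above_range``."""
    clone = select_classification_clone(pk)
    if clone.intersects(HEH_MODAL_LOW, HEH_MODAL_HIGH):
        return True, "in_range"
    if clone.count_high < HEH_MODAL_LOW:
        return False, "below_range"
    return False, "above_range"


def detect_masked_doubled(
    profile: CopyNumberProfile, min_tetrasomies: int = 4
) -> bool:
    """Heuristic for a masked near-haploid / low-hypodiploid genome.

    A doubled hypodiploid clone lands in the HeH modal range but every
    chromosome arrives in pairs: autosome copy numbers are all even (0, 2 or
    4) with several tetrasomies, instead of the odd-numbered trisomies of
    true HeH.  Never fires on a profile with uncertain chromosomes — a case
    is not excluded on ambiguous evidence.
    """
    if not profile.fully_certain:
        return False
    autosome_counts = [profile.counts[c] for c in profile.counts if c not in ("X", "Y")]
    if any(n % 2 != 0 for n in autosome_counts):
        return False
    return sum(1 for n in autosome_counts if n >= 4) >= min_tetrasomies


def exclusion_check(
    pk: ParsedKaryotype, profile: CopyNumberProfile
) -> tuple[bool, str]:
    """Exclusion rules applied after modal eligibility.

    Ph-positive karyotypes and masked doubled-hypodiploid patterns constitute
    distinct ALL subtypes and are excluded; returns ``(excluded, reason)``.
    """
    if has_structural(pk, PH_PATTERN):
        return True, "ph_positive"
    if detect_masked_doubled(profile):
        return True, "masked_doubled"
    return False, "none"


def trisomy_status(profile: CopyNumberProfile, chromosome: str | int) -> TrisomyStatus:
    """Trisomy status of one profile chromosome: gained (certain copy ≥ 3),
    not gained (certain copy ≤ 2), or uncertain."""
    chrom = str(chromosome)
    if chrom not in profile.counts:
        raise KeyError(f"chromosome {chrom!r} outside the profile's domain")
    if not profile.is_certain(chrom):
        return TrisomyStatus.UNCERTAIN
    return TrisomyStatus.GAINED if profile.counts[chrom] >= 3 else TrisomyStatus.NOT_GAINED


def profile_input(pk: ParsedKaryotype, profile: CopyNumberProfile) -> ProfileInput:
    """Assemble the four trisomy statuses and their ambiguity sources."""
    clone = select_classification_clone(pk)
    sources = set()
    if clone.marker_gains > 0:
        sources.add("marker")
    if clone.has_inc:
        sources.add("incomplete")
    if clone.has_uncertain_token:
        sources.add("uncertain_token")
    s5, s17, s18, s20 = (trisomy_status(profile, c) for c in PROFILE_CHROMOSOMES)
    return ProfileInput(s5, s17, s18, s20, frozenset(sources))


def assign_risk(inp: ProfileInput, rule: RiskRule) -> RiskAssignment:
    """Resolve uncertain statuses by exhaustive enumeration.

    Each uncertain status is expanded to both gained and not-gained (at most
    2^4 = 16 resolutions); if every resolution lands in the same class the
    assignment is definite, otherwise provisional with the class taken from
    the baseline resolution (uncertain → not gained).
    """
    choices = [
        (True, False) if s is TrisomyStatus.UNCERTAIN else (s is TrisomyStatus.GAINED,)
        for s in inp.statuses
    ]
    classes = {rule(*bits) for bits in product(*choices)}
    baseline = rule(*(s is TrisomyStatus.GAINED for s in inp.statuses))
    reasons = [
        "statuses:" + ",".join(
            f"{c}={s.value}" for c, s in zip(PROFILE_CHROMOSOMES, inp.statuses)
        )
    ]
    if len(classes) == 1:
        group = RiskGroup.D_GR if baseline == "GR" else RiskGroup.D_PR
        reasons.append(f"definite:{baseline}")
    else:
        group = RiskGroup.P_GR if baseline == "GR" else RiskGroup.P_PR
        reasons.append(
            "provisional:" + (",".join(sorted(inp.ambiguity_source)) or "ambiguous")
        )
    return RiskAssignment(group=group, reasons=tuple(reasons))


def classify(
    text: str | ParsedKaryotype, rule: RiskRule | None = None
) -> RiskAssignment:
    """Full pipeline: parse → select clone → profile → eligibility →
    exclusions → trisomy statuses → risk table.  Parse errors propagate;
    ineligible and excluded karyotypes short-circuit with merged group
    ``none`` and the firing rule recorded in ``reasons``."""
    if rule is None:
        rule = RiskRule.default()
    pk = parse_karyotype(text) if isinstance(text, str) else text
    reasons: list[str] = []
    clone = select_classification_clone(pk)
    reasons.append(f"clone:modal={clone.count_low}"
                   + (f"-{clone.count_high}" if clone.count_high != clone.count_low else ""))

    eligible, why = is_heh_eligible(pk)
    if not eligible:
        reasons.append(f"not_heh:{why}")
        return RiskAssignment(RiskGroup.NOT_HEH, tuple(reasons))
    reasons.append(f"eligible:{why}")
    if clone.count_low < HEH_MODAL_LOW or clone.count_high > HEH_MODAL_HIGH:
        reasons.append("warning:count_range_crosses_heh_boundary")

    profile = copy_number_profile(clone)
    excluded, why = exclusion_check(pk, profile)
    if excluded:
        reasons.append(f"excluded:{why}")
        return RiskAssignment(RiskGroup.EXCLUDED, tuple(reasons))

    assignment = assign_risk(profile_input(pk, profile), rule)
    return RiskAssignment(assignment.group, tuple(reasons) + assignment.reasons)


def classify_cohort(
    df: pd.DataFrame,
    karyotype_col: str = "karyotype",
    rule: RiskRule | None = None,
) -> pd.DataFrame:
    """Classify every row of a cohort table.

    Returns a copy with columns ``heh_eligible``, ``excluded``, ``reason``,
    ``group`` and ``merged_group`` appended.  Unparseable karyotypes get
    group ``parse_error`` rather than aborting the cohort.
    """
    if rule is None:
        rule = RiskRule.default()
    rows = []
    for text in df[karyotype_col]:
        try:
            a = classify(text, rule)
            rows.append(
                {
                    "heh_eligible": a.group not in (RiskGroup.NOT_HEH,),
                    "excluded": a.group is RiskGroup.EXCLUDED,
                    "reason": ";".join(a.reasons),
                    "group": a.group.value,
                    "merged_group": a.merged_group,
                }
            )
        except Exception as exc:  # parse errors recorded per-row
            rows.append(
                {
                    "heh_eligible": False,
                    "excluded": False,
                    "reason": f"parse_error:{exc}",
                    "group": "parse_error",
                    "merged_group": "none",
                }
            )
    out = df.copy()
    for col in ("heh_eligible", "excluded", "reason", "group", "merged_group"):
        out[col] = [r[col] for r in rows]
    return out
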