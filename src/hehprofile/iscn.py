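"""Parsing of ISCN karyotype strings into clones and copy-number profiles.

Clinical cytogenetics records a karyotype as a comma-separated ISCN string,
e.g. ``57,XX,+X,+4,+6,+10,+14,+17,+18,+21,+21,+mar[12]/46,XX[8]``: a modal
chromosome count, a sex-chromosome token, a list of abnormality tokens, and
an optional cell count in brackets; clones are separated by ``/``.  This
module turns such strings into structured :class:`Clone` objects and resolves
one clone per patient into a :class:`CopyNumberProfile` — per-chromosome copy
counts with explicit *certainty* labels, because marker chromosomes (``+mar``),
incomplete karyotypes (``inc``) and ``?``-prefixed tokens leave the identity
of some gained material unknown.

The grammar covered is the subset needed for whole-chromosome risk profiling
of high-hyperdiploid ALL: numeric gains/losses, markers, ``inc``, composite
(``cp``) karyotypes, stemline references (``idem``/``sl``/``sdl``),
constitutional (``c``-suffixed) abnormalities, and structural tokens such as
``t(9;22)(q34;q11)`` (parsed for pattern matching but contributing no
whole-chromosome copy change).  Unrecognised tokens are preserved with a
parse warning rather than failing: real-world karyotype corpora are messy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "KaryotypeParseError",
    "InconsistentKaryotypeError",
    "StructuralPattern",
    "Abnormality",
    "Clone",
    "ParsedKaryotype",
    "CopyNumberProfile",
    "parse_karyotype",
    "select_classification_clone",
    "copy_number_profile",
    "has_structural",
    "CHROMOSOMES",
    "AUTOSOMES",
]

#: Valid whole-chromosome identifiers, in ISCN sort order.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

_CHROM_SET = frozenset(CHROMOSOMES)


class KaryotypeParseError(ValueError):
    """Raised for an empty string or a clone whose leading count is malformed."""


class InconsistentKaryotypeError(ValueError):
    """Raised when applying losses drives a chromosome's copy number below 0."""


_COUNT_RE = re.compile(r"^(\d{1,3})(?:[-~](\d{1,3}))?$")
_SEX_RE = re.compile(r"^[XY]+$")
_GAIN_LOSS_RE = re.compile(r"^([+-])(\d{1,2}|X|Y)(c?)$")
_MARKER_RE = re.compile(r"^\+(\d*)mar\d*(c?)$")
_STRUCT_RE = re.compile(
    r"^(t|del|dup|der|inv|add|i|ins|dic|r|trp)\(([^)]*)\)(?:\(([^)]*)\))?"
)
_CELLS_RE = re.compile(r"\[(cp)?\s*(\d+)?\]$")
_LINEAGE_RE = re.compile(r"^(idem|sl\d*|sdl\d*)$")


@dataclass(frozen=True)
class StructuralPattern:
    """A structural abnormality pattern: type, chromosomes and breakpoints.

    ``StructuralPattern.parse("t(9;22)(q34;q11)")`` yields type ``t``,
    chromosomes ``("9", "22")`` and breakpoints ``("q34", "q11")``.
    """

    abn_type: str
    chromosomes: tuple[str, ...]
    breakpoints: tuple[str, ...] = ()

    @classmethod
    def parse(cls, text: str) -> "StructuralPattern":
        m = _STRUCT_RE.match(text.strip().lstrip("?"))
        if not m:
            raise ValueError(f"not a structural abnormality pattern: {text!r}")
        abn_type, chroms, bps = m.group(1), m.group(2), m.group(3)
        return cls(
            abn_type=abn_type,
            chromosomes=tuple(c.strip() for c in chroms.split(";") if c.strip()),
            breakpoints=tuple(b.strip() for b in bps.split(";")) if bps else (),
        )

    def matches(self, other: "StructuralPattern") -> bool:
        """True if ``other`` (a token from a karyotype) satisfies this pattern.

        Chromosome lists compare as multisets; each breakpoint matches up to
        sub-band refinement (``q11`` matches ``q11.2``) and ``?`` wildcards.
        A token written without breakpoints matches any breakpoint pattern.
        """
        if self.abn_type != other.abn_type:
            return False
        if sorted(self.chromosomes) != sorted(other.chromosomes):
            return False
        if not self.breakpoints or not other.breakpoints:
            return True
        if len(self.breakpoints) != len(other.breakpoints):
            return False
        return all(
            _breakpoint_match(a, b)
            for a, b in zip(self.breakpoints, other.breakpoints)
        )


def _breakpoint_match(pat: str, tok: str) -> bool:
    if "?" in pat or "?" in tok:
        return True
    if pat == tok:
        return True
    # sub-band refinement: q11 matches q11.2 (either direction)
    longer, shorter = (pat, tok) if len(pat) > len(tok) else (tok, pat)
    return longer.startswith(shorter) and longer[len(shorter)] == "."


@dataclass(frozen=True)
class Abnormality:
    """One abnormality token from a clone.

    ``kind`` is one of ``gain``, ``loss``, ``structural``, ``marker``,
    ``other``; ``chromosome`` is set for whole-chromosome gains/losses.
    """

    kind: str
    token: str
    chromosome: str | None = None
    uncertain: bool = False
    constitutional: bool = False
    structure: StructuralPattern | None = None
    multiplicity: int = 1


@dataclass(frozen=True)
class Clone:
    count_low: int
    count_high: int
    sex_token: str
    abnormalities: tuple[Abnormality, ...]
    cell_count: int | None = None
    lineage_ref: str | None = None
    is_composite: bool = False
    has_inc: bool = False

    @property
    def marker_gains(self) -> int:
        return sum(a.multiplicity for a in self.abnormalities if a.kind == "marker")

    @property
    def has_uncertain_token(self) -> bool:
        return any(a.uncertain for a in self.abnormalities)

    def intersects(self, low: int, high: int) -> bool:
        return self.count_low <= high and self.count_high >= low


@dataclass(frozen=True)
class ParsedKaryotype:
    """A parsed karyotype: clones in document order plus ambiguity flags.

    ``marker_count`` and ``is_incomplete`` describe the clone selected for
    classification (see :func:`select_classification_clone`), which is where
    they matter for provisional risk assignment.
    """

    raw: str
    clones: tuple[Clone, ...]
    parse_warnings: tuple[str, ...] = ()

    @property
    def classification_clone(self) -> Clone:
        return select_classification_clone(self)

    @property
    def marker_count(self) -> int:
        return self.classification_clone.marker_gains

    @property
    def is_incomplete(self) -> bool:
        return self.classification_clone.has_inc

    @property
    def is_composite(self) -> bool:
        return any(c.is_composite for c in self.clones)

    def to_dict(self) -> dict:
        """JSON-serialisable view, for CLI debugging output."""
        return {
            "raw": self.raw,
            "clones": [
                {
                    "count_low": c.count_low,
                    "count_high": c.count_high,
                    "sex_token": c.sex_token,
                    "cell_count": c.cell_count,
                    "lineage_ref": c.lineage_ref,
                    "is_composite": c.is_composite,
                    "has_inc": c.has_inc,
                    "abnormalities": [
                        {
                            "kind": a.kind,
                            "token": a.token,
                            "chromosome": a.chromosome,
                            "uncertain": a.uncertain,
                            "constitutional": a.constitutional,
                        }
                        for a in c.abnormalities
                    ],
                }
                for c in self.clones
            ],
            "marker_count": self.marker_count,
            "is_incomplete": self.is_incomplete,
            "is_composite": self.is_composite,
            "parse_warnings": list(self.parse_warnings),
        }


@dataclass(frozen=True)
class CopyNumberProfile:
    """Per-chromosome copy counts with certainty labels for one clone.

    ``certainty[chrom]`` is ``"certain"`` or ``"uncertain"``.  A chromosome is
    uncertain when unidentified material (a marker, an ``inc`` truncation or a
    ``?`` token) could hide a gain of it; a written, certain ``+N`` is always
    trusted, so explicitly gained chromosomes stay certain.
    """

    counts: dict[str, int]
    certainty: dict[str, str]
    modal_low: int
    modal_high: int

    def is_certain(self, chrom: str) -> bool:
        return self.certainty[chrom] == "certain"

    @property
    def fully_certain(self) -> bool:
        return all(v == "certain" for v in self.certainty.values())

    @property
    def uncertain_chromosomes(self) -> tuple[str, ...]:
        return tuple(c for c in CHROMOSOMES if self.certainty[c] == "uncertain")


def parse_karyotype(text: str) -> ParsedKaryotype:
    """Parse an ISCN karyotype string.

    Raises :class:`KaryotypeParseError` for an empty string or a clone whose
    leading chromosome-count token is not an integer or integer range; every
    other irregularity is preserved as a ``kind="other"`` abnormality with a
    parse warning.
    """
    raw = text
    stripped = re.sub(r"\s+", "", text)
    if not stripped:
        raise KaryotypeParseError("empty karyotype string")

    warnings: list[str] = []
    clones: list[Clone] = []
    for i, clone_text in enumerate(stripped.split("/")):
        clones.append(_parse_clone(clone_text, i, warnings))
    return ParsedKaryotype(raw=raw, clones=tuple(clones), parse_warnings=tuple(warnings))


def _parse_clone(clone_text: str, index: int, warnings: list[str]) -> Clone:
    if not clone_text:
        raise KaryotypeParseError(f"clone {index + 1}: empty clone")

    is_composite = False
    cell_count = None
    m = _CELLS_RE.search(clone_text)
    if m:
        is_composite = m.group(1) == "cp"
        cell_count = int(m.group(2)) if m.group(2) else None
        clone_text = clone_text[: m.start()]

    fields = [f for f in clone_text.split(",")]
    if not fields or not (cm := _COUNT_RE.match(fields[0])):
        raise KaryotypeParseError(
            f"clone {index + 1}: malformed leading chromosome count "
            f"{fields[0] if fields else ''!r}"
        )
    count_low = int(cm.group(1))
    count_high = int(cm.group(2)) if cm.group(2) else count_low
    if count_low > count_high:
        count_low, count_high = count_high, count_low

    sex_token = ""
    lineage_ref = None
    abns: list[Abnormality] = []
    has_inc = False

    rest = fields[1:]
    if rest and _LINEAGE_RE.match(rest[0]):
        lineage_ref = rest[0]
        rest = rest[1:]
    elif rest and _SEX_RE.match(rest[0]):
        sex_token = rest[0]
        rest = rest[1:]

    for tok in rest:
        if not tok:
            continue
        if tok == "inc":
            has_inc = True
            continue
        if _LINEAGE_RE.match(tok) and lineage_ref is None:
            lineage_ref = tok
            continue
        abns.append(_parse_token(tok, index, warnings))

    return Clone(
        count_low=count_low,
        count_high=count_high,
        sex_token=sex_token,
        abnormalities=tuple(abns),
        cell_count=cell_count,
        lineage_ref=lineage_ref,
        is_composite=is_composite,
        has_inc=has_inc,
    )


def _parse_token(tok: str, clone_index: int, warnings: list[str]) -> Abnormality:
    uncertain = tok.startswith("?")
    body = tok.lstrip("?")

    if m := _MARKER_RE.match(body):
        return Abnormality(
            kind="marker",
            token=tok,
            uncertain=uncertain,
            constitutional=bool(m.group(2)),
            multiplicity=int(m.group(1) or 1),
        )
    if m := _GAIN_LOSS_RE.match(body):
        sign, chrom, const = m.groups()
        kind = "gain" if sign == "+" else "loss"
        if chrom not in _CHROM_SET:
            warnings.append(
                f"clone {clone_index + 1}: {kind} of unknown chromosome {tok!r}"
            )
            return Abnormality(kind=kind, token=tok, uncertain=True)
        if const:
            warnings.append(f"clone {clone_index + 1}: constitutional abnormality {tok!r}")
        return Abnormality(
            kind=kind,
            token=tok,
            chromosome=chrom,
            uncertain=uncertain,
            constitutional=bool(const),
        )
    if _STRUCT_RE.match(body):
        const = body.endswith("c")
        if const:
            warnings.append(f"clone {clone_index + 1}: constitutional abnormality {tok!r}")
        return Abnormality(
            kind="structural",
            token=tok,
            uncertain=uncertain,
            constitutional=const,
            structure=StructuralPattern.parse(body),
        )
    warnings.append(f"clone {clone_index + 1}: unrecognised token {tok!r}")
    return Abnormality(kind="other", token=tok, uncertain=uncertain)


def _resolve_lineage(pk: ParsedKaryotype, clone: Clone) -> Clone:
    """Expand an idem/sl/sdl clone against its stemline.

    The stemline is the first document-order clone that carries no lineage
    reference; the subclone inherits its sex token and abnormality list, with
    the subclone's own additions/removals appended.
    """
    if clone.lineage_ref is None:
        return clone
    stem = next((c for c in pk.clones if c.lineage_ref is None), None)
    if stem is None or stem is clone:
        return clone
    stem = _resolve_lineage(pk, stem)
    return replace(
        clone,
        sex_token=clone.sex_token or stem.sex_token,
        abnormalities=stem.abnormalities + clone.abnormalities,
        has_inc=clone.has_inc or stem.has_inc,
    )


def select_classification_clone(
    pk: ParsedKaryotype, low: int = 51, high: int = 67
) -> Clone:
    """Pick the clone used for risk classification.

    Returns the first document-order clone (after lineage expansion) whose
    chromosome-count range intersects ``[low, high]``; if none does, the clone
    with the highest count.  ISCN lists the stemline first, so ties between
    two in-range clones resolve to the stemline.
    """
    if not pk.clones:
        raise KaryotypeParseError("karyotype has no clones")
    for clone in pk.clones:
        if clone.intersects(low, high):
            return _resolve_lineage(pk, clone)
    best = max(pk.clones, key=lambda c: c.count_high)
    return _resolve_lineage(pk, best)


def copy_number_profile(clone: Clone) -> CopyNumberProfile:
    """Compute per-chromosome copy numbers and certainty for one clone.

    Starts from a 46,XX or 46,XY baseline per the sex token (unknown sex
    token falls back to XX), applies each certain whole-chromosome gain (+1)
    and loss (−1); markers raise the nominal count but name no chromosome;
    structural tokens contribute no whole-chromosome change.  When the clone
    carries markers, ``inc`` or ``?`` tokens, every chromosome *not* explicitly
    gained by a certain named token is labelled uncertain.
    """
    counts: dict[str, int] = {c: 2 for c in AUTOSOMES}
    sex = clone.sex_token if _SEX_RE.match(clone.sex_token or "") else "XX"
    counts["X"] = sex.count("X")
    counts["Y"] = sex.count("Y")

    gained_certain: set[str] = set()
    uncertain_tokens = False
    for a in clone.abnormalities:
        if a.kind in ("gain", "loss") and a.chromosome is not None:
            if a.uncertain:
                uncertain_tokens = True
                continue
            delta = 1 if a.kind == "gain" else -1
            counts[a.chromosome] += delta
            if counts[a.chromosome] < 0:
                raise InconsistentKaryotypeError(
                    f"copy number of chromosome {a.chromosome} driven below 0"
                )
            if a.kind == "gain":
                gained_certain.add(a.chromosome)
        elif a.uncertain or (a.kind in ("gain", "loss") and a.chromosome is None):
            uncertain_tokens = True

    ambiguous = clone.marker_gains > 0 or clone.has_inc or uncertain_tokens
    certainty = {
        c: "certain" if (not ambiguous or c in gained_certain) else "uncertain"
        for c in CHROMOSOMES
    }
    return CopyNumberProfile(
        counts=counts,
        certainty=certainty,
        modal_low=clone.count_low,
        modal_high=clone.count_high,
    )


def has_structural(pk: ParsedKaryotype, pattern: StructuralPattern | str) -> bool:
    """True iff any clone contains a structural token matching ``pattern``."""
    if isinstance(pattern, str):
        pattern = StructuralPattern.parse(pattern)
    for clone in pk.clones:
        for a in clone.abnormalities:
            if a.kind == "structural" and a.structure is not None:
                if pattern.matches(a.structure):
                    return True
    return False
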