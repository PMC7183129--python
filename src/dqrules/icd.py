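"""ICD-10 code parsing, truncation, and chapter classification.

The WHO ICD-10 classification is hierarchical: the first three characters
(one letter, two digits) give the *category* of diagnosis, an optional
fourth character adds etiology, anatomic site, or severity, and national
modifications (ICD-10-CA, ICD-10-CM) append further extension characters.
Analyses of coding associations work at the three- or four-character level,
so anything beyond the fourth significant character is discarded here.

Categories are grouped into 22 chapters.  Only chapters I-XVII describe
disease entities; the remaining chapters cover symptoms and signs (XVIII),
injury (XIX), external causes (XX), health-service contacts (XXI), and
codes for special purposes (XXII), and are excluded from rule mining.

The full WHO tabular list is licensed and is not shipped; only the chapter
boundary ranges (public structural information) are encoded.  Likewise the
dagger/asterisk (etiology/manifestation) designations are supplied by the
user as a small registry file rather than embedded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union


class InvalidCodeError(ValueError):
    """Raised when a string cannot be interpreted as an ICD-10 code."""


#: WHO ICD-10 chapter boundaries as (first category, last category, chapter).
#: Entries are lexicographically ordered and non-overlapping; categories
#: falling in the gaps (e.g. D49, E95) are not allocated by the WHO and are
#: rejected by :func:`chapter_of`.
CHAPTER_RANGES: tuple[tuple[str, str, str], ...] = (
    ("A00", "B99", "I"),
    ("C00", "D48", "II"),
    ("D50", "D89", "III"),
    ("E00", "E90", "IV"),
    ("F00", "F99", "V"),
    ("G00", "G99", "VI"),
    ("H00", "H59", "VII"),
    ("H60", "H95", "VIII"),
    ("I00", "I99", "IX"),
    ("J00", "J99", "X"),
    ("K00", "K93", "XI"),
    ("L00", "L99", "XII"),
    ("M00", "M99", "XIII"),
    ("N00", "N99", "XIV"),
    ("O00", "O99", "XV"),
    ("P00", "P96", "XVI"),
    ("Q00", "Q99", "XVII"),
    ("R00", "R99", "XVIII"),
    ("S00", "T98", "XIX"),
    ("U00", "U99", "XXII"),
    ("V01", "Y98", "XX"),
    ("Z00", "Z99", "XXI"),
)

#: Chapters whose codes enter association-rule mining (disease entities).
ANALYSIS_CHAPTERS: frozenset[str] = frozenset(
    {"I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI",
     "XII", "XIII", "XIV", "XV", "XVI", "XVII"}
)

_CATEGORY_RE = re.compile(r"^[A-Z][0-9]{2}$")


@dataclass(frozen=True)
class IcdCode:
    """A parsed ICD-10 code at WHO (four-character) granularity.

    Attributes
    ----------
    raw : str
        The string as supplied (before normalisation).
    category : str
        Three-character category, e.g. ``"I21"``.
    subcategory : str or None
        Fourth significant character (a digit) when present.
    chapter : str
        Roman-numeral chapter identifier, ``"I"`` .. ``"XXII"``.
    """

    raw: str
    category: str
    subcategory: Optional[str]
    chapter: str

    @property
    def code(self) -> str:
        """Canonical dotted rendering, e.g. ``"I21.0"`` or ``"P07"``."""
        if self.subcategory is None:
            return self.category
        return f"{self.category}.{self.subcategory}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


def parse_code(raw: str) -> IcdCode:
    """Parse an ICD-10 code string.

    Dots are treated as a rendering concern and ignored; characters beyond
    the fourth significant one (national extensions) are silently dropped.

    Raises
    ------
    InvalidCodeError
        If the string has no leading letter, fewer than two digits after
        it, a non-digit fourth character, or falls outside every chapter.
    """
    if raw is None:
        raise InvalidCodeError("empty code")
    s = raw.strip().upper().replace(".", "")
    if len(s) < 3:
        raise InvalidCodeError(f"malformed ICD-10 code: {raw!r}")
    category = s[:3]
    if not _CATEGORY_RE.match(category):
        raise InvalidCodeError(f"malformed ICD-10 code: {raw!r}")
    subcategory: Optional[str] = None
    if len(s) > 3:
        if not s[3].isdigit():
            raise InvalidCodeError(
                f"non-digit fourth character in ICD-10 code: {raw!r}"
            )
        subcategory = s[3]
    chapter = chapter_of(category)  # raises on unallocated categories
    return IcdCode(raw=raw, category=category, subcategory=subcategory,
                   chapter=chapter)


def chapter_of(category: str) -> str:
    """Map a three-character category to its chapter identifier.

    Deterministic lookup in :data:`CHAPTER_RANGES`; categories in the
    unallocated gaps of the WHO list are rejected.
    """
    if not _CATEGORY_RE.match(category or ""):
        raise InvalidCodeError(f"not a valid ICD-10 category: {category!r}")
    for start, end, chapter in CHAPTER_RANGES:
        if start <= category <= end:
            return chapter
    raise InvalidCodeError(f"category outside all ICD-10 chapters: {category!r}")


def truncate_code(code: Union[IcdCode, str], level: int) -> str:
    """Truncate a code to the three- or four-character level.

    Level 3 returns the category; level 4 keeps the subcategory when
    present (dotted rendering), otherwise the bare category.
    """
    if level not in (3, 4):
        raise ValueError(f"digit level must be 3 or 4, got {level!r}")
    if isinstance(code, str):
        code = parse_code(code)
    if level == 3:
        return code.category
    return code.code


def in_analysis_scope(code: Union[IcdCode, str]) -> bool:
    """True iff the code belongs to chapters I-XVII (disease entities)."""
    if isinstance(code, str):
        code = parse_code(code)
    return code.chapter in ANALYSIS_CHAPTERS


@dataclass(frozen=True)
class AsteriskRegistry:
    """Registry of manifestation (asterisk) codes and dagger pairings.

    The dagger-asterisk system doubles-codes a condition as etiology
    (dagger) plus manifestation (asterisk); such pairs co-occur by coding
    convention rather than clinical association, so rules built from them
    are spurious.  The designations belong to the licensed tabular list and
    are therefore loaded from a user-supplied file.
    """

    asterisk_codes: frozenset[str] = field(default_factory=frozenset)
    #: Known (dagger, asterisk) code pairings.
    pairings: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "AsteriskRegistry":
        """Read a registry file.

        One entry per line, ``#`` starts a comment.  A single code marks an
        asterisk code; two whitespace-separated codes mark a
        ``dagger asterisk`` pairing (the asterisk member is registered as
        an asterisk code).  Trailing ``*`` / dagger markers are stripped.
        """
        asterisks: set[str] = set()
        pairings: set[tuple[str, str]] = set()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = [t.strip("*†") for t in line.split()]
            tokens = [_canonical(t, lineno) for t in tokens if t]
            if len(tokens) == 1:
                asterisks.add(tokens[0])
            elif len(tokens) == 2:
                dagger, asterisk = tokens
                pairings.add((dagger, asterisk))
                asterisks.add(asterisk)
            else:
                raise InvalidCodeError(
                    f"registry line {lineno}: expected 1 or 2 codes, "
                    f"got {len(tokens)}"
                )
        return cls(frozenset(asterisks), frozenset(pairings))

    def paired_daggers(self, asterisk: str) -> frozenset[str]:
        """Dagger codes known to pair with the given asterisk code."""
        return frozenset(d for d, a in self.pairings if a == asterisk)


def _canonical(token: str, lineno: int) -> str:
    try:
        return parse_code(token).code
    except InvalidCodeError as exc:
        raise InvalidCodeError(f"registry line {lineno}: {exc}") from exc


def is_asterisk(code: Union[IcdCode, str], registry: AsteriskRegistry) -> bool:
    """True iff the code's category or four-character form is registered."""
    if isinstance(code, str):
        code = parse_code(code)
    return (code.category in registry.asterisk_codes
            or code.code in registry.asterisk_codes)


def registry_codes_in(codes: Iterable[str],
                      registry: AsteriskRegistry) -> frozenset[str]:
    """Subset of ``codes`` that are asterisk codes under ``registry``."""
    return frozenset(c for c in codes if is_asterisk(c, registry))
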