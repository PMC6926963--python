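"""Combined-code grammar linking HFDFC classification codes to recipe facets.

The HFDFC system (Taiwan's harmonized food classification and description
system) identifies a food with a code such as ``O010301`` — an uppercase
letter followed by two digits per hierarchy level.  A *description facet* is
attached with ``#``, and multiple facet tokens are chained with ``$``.  The
recipe facet implemented here carries the fixed identifier ``F07`` and one of
fourteen ingredient descriptors (``F07.1`` = whole grains … ``F07.14`` =
seasonings), so a fried-rice product whose recipes contain rice, seafood,
eggs, meats, vegetables and seasonings is written::

    O010301#F07.1$F07.4$F07.5$F07.6$F07.8$F07.14

Facets ``F01``–``F06`` belong to the earlier HFDFC description system; they
are parsed as opaque tokens (so legacy strings do not crash) but carry no
recipe semantics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "DESCRIPTOR_LABELS",
    "CodeError",
    "HfdfcCode",
    "TfrDescriptor",
    "CombinedCode",
    "descriptor_from_sub_code",
    "descriptor_from_label",
    "parse_combined",
    "format_combined",
    "taxonomy_table",
]

#: The fourteen recipe-facet ingredient descriptors, keyed by sub-code.
DESCRIPTOR_LABELS: dict[int, str] = {
    1: "whole grains",
    2: "water",
    3: "beans",
    4: "seafood",
    5: "eggs",
    6: "meats",
    7: "milk",
    8: "vegetables",
    9: "fruits",
    10: "nuts",
    11: "fats",
    12: "beverages",
    13: "wines",
    14: "seasonings",
}

_LABEL_TO_SUB = {v: k for k, v in DESCRIPTOR_LABELS.items()}

RECIPE_FACET_ID = "F07"

_HFDFC_RE = re.compile(r"^([A-Z])(\d{2,8})$", re.ASCII)
_FACET_RE = re.compile(r"^F(0[1-7])\.(\d{1,2})$", re.ASCII)


class CodeError(ValueError):
    """Raised for any malformed classification or combined code."""


@dataclass(frozen=True, order=True)
class HfdfcCode:
    """A hierarchical classification code: uppercase letter + 2–8 digits.

    Each pair of digits encodes one level below the letter category, so the
    hierarchy level is ``1 + n_digits / 2``.  The level is informational
    metadata only; no computation depends on it.
    """

    text: str

    def __post_init__(self) -> None:
        m = _HFDFC_RE.match(self.text)
        if m is None:
            raise CodeError(
                f"malformed HFDFC code {self.text!r}: expected an uppercase "
                "letter followed by 2-8 digits"
            )
        if len(m.group(2)) % 2 != 0:
            raise CodeError(
                f"malformed HFDFC code {self.text!r}: odd digit count "
                f"({len(m.group(2))})"
            )

    @property
    def level(self) -> int:
        return 1 + (len(self.text) - 1) // 2

    def __str__(self) -> str:
        return self.text


@dataclass(frozen=True, order=True)
class TfrDescriptor:
    """One of the fourteen recipe-facet ingredient descriptors."""

    sub_code: int
    label: str = field(compare=False)

    def __post_init__(self) -> None:
        expected = DESCRIPTOR_LABELS.get(self.sub_code)
        if expected is None:
            raise CodeError(
                f"descriptor sub-code {self.sub_code} outside 1-14"
            )
        if self.label != expected:
            raise CodeError(
                f"descriptor label {self.label!r} does not match sub-code "
                f"{self.sub_code} ({expected!r})"
            )

    @property
    def token(self) -> str:
        return f"{RECIPE_FACET_ID}.{self.sub_code}"


def descriptor_from_sub_code(sub_code: int) -> TfrDescriptor:
    """Return the descriptor for a sub-code in 1..14 (``CodeError`` outside)."""
    if sub_code not in DESCRIPTOR_LABELS:
        raise CodeError(f"descriptor sub-code {sub_code} outside 1-14")
    return TfrDescriptor(sub_code, DESCRIPTOR_LABELS[sub_code])


def descriptor_from_label(label: str) -> TfrDescriptor:
    sub = _LABEL_TO_SUB.get(label.strip().casefold())
    if sub is None:
        raise CodeError(f"unknown descriptor label {label!r}")
    return descriptor_from_sub_code(sub)


@dataclass(frozen=True)
class CombinedCode:
    """An HFDFC code joined to its description facets.

    ``descriptors`` holds the recipe-facet (F07) descriptors, unique and in
    ascending sub-code order.  ``foreign_facets`` preserves any F01–F06
    tokens verbatim (whitespace stripped); they carry no semantics here.  At
    least one facet token of either kind must be present.
    """

    hfdfc: HfdfcCode
    descriptors: tuple[TfrDescriptor, ...]
    foreign_facets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        subs = [d.sub_code for d in self.descriptors]
        if len(set(subs)) != len(subs):
            dup = next(s for s in subs if subs.count(s) > 1)
            raise CodeError(f"duplicate descriptor F07.{dup}")
        if subs != sorted(subs):
            object.__setattr__(
                self,
                "descriptors",
                tuple(descriptor_from_sub_code(s) for s in sorted(subs)),
            )
        if not self.descriptors and not self.foreign_facets:
            raise CodeError(
                f"combined code {self.hfdfc} carries no facet tokens"
            )

    @property
    def sub_codes(self) -> tuple[int, ...]:
        return tuple(d.sub_code for d in self.descriptors)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(d.label for d in self.descriptors)

    def __str__(self) -> str:
        return format_combined(self)


def combined(hfdfc_text: str, sub_codes: Iterable[int]) -> CombinedCode:
    """Convenience constructor from an HFDFC string and sub-codes."""
    return CombinedCode(
        HfdfcCode(hfdfc_text),
        tuple(descriptor_from_sub_code(s) for s in sorted(set(sub_codes))),
    )


def parse_combined(text: str) -> CombinedCode:
    """Parse a combined-code string into its structured form.

    Tolerates ASCII whitespace around the ``#`` and ``$`` separators and
    zero-padded sub-codes (``F07.01`` ≡ ``F07.1``).  Duplicate recipe
    descriptors are an error; F01–F06 tokens are accepted as opaque foreign
    facets.
    """
    if not text or not text.strip():
        raise CodeError("empty combined-code string")
    parts = text.split("#")
    if len(parts) != 2:
        raise CodeError(
            f"combined code must contain exactly one '#': {text!r}"
        )
    hfdfc = HfdfcCode(parts[0].strip())
    tokens = [t.strip() for t in parts[1].split("$")]
    if any(not t for t in tokens):
        raise CodeError(f"empty facet token in {text!r}")
    seen: list[int] = []
    foreign: list[str] = []
    for tok in tokens:
        m = _FACET_RE.match(tok)
        if m is None:
            raise CodeError(
                f"malformed facet token {tok!r}: expected F01-F07 "
                "followed by '.' and a sub-code"
            )
        facet_id, sub_text = m.groups()
        if f"F{facet_id}" != RECIPE_FACET_ID:
            foreign.append(f"F{facet_id}.{int(sub_text)}")
            continue
        sub = int(sub_text)
        if sub not in DESCRIPTOR_LABELS:
            raise CodeError(
                f"recipe descriptor sub-code {sub} outside 1-14 in {tok!r}"
            )
        if sub in seen:
            raise CodeError(f"duplicate descriptor F07.{sub} in {text!r}")
        seen.append(sub)
    return CombinedCode(
        hfdfc,
        tuple(descriptor_from_sub_code(s) for s in sorted(seen)),
        tuple(foreign),
    )


def format_combined(code: CombinedCode) -> str:
    """Serialize to canonical form: no whitespace, no zero padding,
    foreign facets first (input order), recipe descriptors ascending."""
    tokens = list(code.foreign_facets) + [d.token for d in code.descriptors]
    return f"{code.hfdfc.text}#" + "$".join(tokens)


def taxonomy_table() -> "list[tuple[int, str]]":
    """The descriptor taxonomy as (sub_code, label) rows, for export."""
    return sorted(DESCRIPTOR_LABELS.items())
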