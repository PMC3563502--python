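"""Parsing and canonical formatting of HGVS coding-DNA (c.) substitutions.

The supported grammar is the subset a referral laboratory's SNV tables use:

* exonic substitutions        ``c.1408A>G``
* intron-offset substitutions ``c.869+11C>T`` / ``c.1585-1G>A``
* upstream substitutions      ``c.-10G>A`` (positions 5' of the initiator ATG)

c.1 is the A of the initiator ATG. Intronic positions are anchored at the
nearest exonic base with a signed offset: positive offsets count into the
intron from the donor (end of the preceding exon), negative offsets count
back from the acceptor (start of the following exon). Whitespace around
tokens is tolerated on input ("c.2562 T > G"); the canonical form produced
by :func:`format_c` contains none and is the join key for every set
operation in the package.

Deletions, insertions, duplications and protein-level notation are out of
scope: every tabulated quantity this package computes concerns single
nucleotide substitutions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import HgvsParseError

BASES = ("A", "C", "G", "T")

# Unicode minus / dashes seen in copy-pasted variant lists.
_DASH_TRANSLATION = str.maketrans({"−": "-", "–": "-", "—": "-"})

_C_PATTERN = re.compile(
    r"""^c\.\s*
        (?P<up>-)?(?P<pos>\d+)\s*
        (?:(?P<osign>[+-])\s*(?P<off>\d+))?\s*
        (?P<ref>[ACGTacgt])\s*>\s*(?P<alt>[ACGTacgt])$""",
    re.VERBOSE,
)


@dataclass(frozen=True, order=True)
class VariantDescriptor:
    """A parsed c. substitution.

    ``coding_pos`` is the anchor exonic base for exonic and intron-offset
    variants, or the distance upstream of c.1 when ``upstream`` is true.
    """

    coding_pos: int
    intron_offset: int = 0
    upstream: bool = False
    ref_allele: str = "A"
    alt_allele: str = "G"

    def __post_init__(self) -> None:
        if self.coding_pos < 1:
            raise HgvsParseError(str(self.coding_pos), "position must be >= 1")
        if self.ref_allele not in BASES:
            raise HgvsParseError(self.ref_allele, "reference allele must be one of A/C/G/T")
        if self.alt_allele not in BASES:
            raise HgvsParseError(self.alt_allele, "alternate allele must be one of A/C/G/T")
        if self.ref_allele == self.alt_allele:
            raise HgvsParseError(
                f"{self.ref_allele}>{self.alt_allele}",
                "reference and alternate alleles are identical",
            )
        if self.upstream and self.intron_offset != 0:
            raise HgvsParseError(
                f"-{self.coding_pos}{self.intron_offset:+d}",
                "upstream positions cannot carry an intron offset",
            )

    @property
    def key(self) -> str:
        """Canonical string; unique per descriptor (see :func:`format_c`)."""
        return format_c(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key


def parse_c(text: str) -> VariantDescriptor:
    """Parse an HGVS c. substitution string into a :class:`VariantDescriptor`.

    Raises :class:`HgvsParseError` naming the offending token for malformed
    input, non-ACGT alleles, a zero position, or identical ref/alt alleles.
    """
    if not text or not text.strip():
        raise HgvsParseError(text, "empty variant string")
    cleaned = text.strip().translate(_DASH_TRANSLATION)
    match = _C_PATTERN.match(cleaned)
    if match is None:
        raise HgvsParseError(text, "not a c. single-nucleotide substitution")
    pos = int(match["pos"])
    if pos == 0:
        raise HgvsParseError(text, "position 0 does not exist in c. coordinates")
    offset = 0
    if match["off"] is not None:
        if match["up"]:
            raise HgvsParseError(text, "upstream position with intron offset")
        offset = int(match["off"])
        if offset == 0:
            raise HgvsParseError(text, "intron offset 0 is not a valid offset")
        if match["osign"] == "-":
            offset = -offset
    return VariantDescriptor(
        coding_pos=pos,
        intron_offset=offset,
        upstream=match["up"] is not None,
        ref_allele=match["ref"].upper(),
        alt_allele=match["alt"].upper(),
    )


def format_c(d: VariantDescriptor) -> str:
    """Canonical, whitespace-free rendering; the exact inverse of :func:`parse_c`."""
    if d.upstream:
        pos = f"-{d.coding_pos}"
    elif d.intron_offset:
        pos = f"{d.coding_pos}{d.intron_offset:+d}"
    else:
        pos = str(d.coding_pos)
    return f"c.{pos}{d.ref_allele}>{d.alt_allele}"


def canonicalize(text: str) -> str:
    """Normalize a variant string to its canonical key (parse then format)."""
    return format_c(parse_c(text))
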