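"""Functional-class annotation of variants against a transcript model.

Each variant receives a non-empty set of labels from {promoter, splice_site,
intronic, missense, nonsense, synonymous}. Exonic substitutions are resolved
by substituting the alternate allele into the affected codon and translating
both codons with the standard nuclear genetic code; stop-gain is nonsense,
identity is synonymous, anything else (including stop-loss and start-loss)
is missense. Multi-label sets arise only when the optional exonic splice
extension is enabled, mirroring the "missense and splice site" style of
dual assignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .errors import ReferenceMismatchError, ValidationError
from .gene_model import (
    EXONIC,
    INTRONIC,
    PROMOTER,
    SPLICE_SITE,
    TranscriptModel,
    classify_region,
    codon_index,
)
from .hgvs import VariantDescriptor

MISSENSE = "missense"
NONSENSE = "nonsense"
SYNONYMOUS = "synonymous"

CLASS_LABELS = (MISSENSE, INTRONIC, SYNONYMOUS, SPLICE_SITE, NONSENSE, PROMOTER)
_CODING_LABELS = frozenset({MISSENSE, NONSENSE, SYNONYMOUS})


@dataclass(frozen=True)
class ConsequenceSet:
    """Functional labels of one variant, plus the protein change if exonic."""

    labels: frozenset[str]
    protein_change: tuple[str, int, str] | None = None

    def __post_init__(self) -> None:
        labels = frozenset(self.labels)
        object.__setattr__(self, "labels", labels)
        if not labels:
            raise ValidationError("a consequence set cannot be empty")
        unknown = labels - set(CLASS_LABELS)
        if unknown:
            raise ValidationError(f"unknown consequence labels: {sorted(unknown)}")
        coding = labels & _CODING_LABELS
        if len(coding) > 1:
            raise ValidationError(
                f"at most one coding-effect label allowed, got {sorted(coding)}"
            )
        if bool(coding) != (self.protein_change is not None):
            raise ValidationError(
                "protein_change must be present exactly for coding-effect variants"
            )

    @property
    def coding_effect(self) -> str | None:
        for label in self.labels:
            if label in _CODING_LABELS:
                return label
        return None


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon, '*' for stop (standard nuclear code)."""
    return str(Seq(codon).translate())


def annotate(
    d: VariantDescriptor,
    model: TranscriptModel,
    splice_halfwidth: int = 2,
    exonic_splice_bases: int = 0,
) -> ConsequenceSet:
    """Assign the functional class set of a single variant.

    ``exonic_splice_bases`` optionally extends the splice-site definition to
    that many exonic bases adjacent to each boundary (0 = intronic-only
    splice sites, the default interpretation).
    """
    region = classify_region(d, model, splice_halfwidth=splice_halfwidth)
    if region.label == PROMOTER:
        return ConsequenceSet(frozenset({PROMOTER}))
    if region.label in (SPLICE_SITE, INTRONIC):
        return ConsequenceSet(frozenset({region.label}))

    # exonic: single-codon substitution
    pos = d.coding_pos
    ref_base = model.coding_sequence[pos - 1]
    if ref_base != d.ref_allele:
        raise ReferenceMismatchError(d.key, expected=ref_base, observed=d.ref_allele)
    codon_no, phase = codon_index(pos)
    codon = model.coding_sequence[3 * (codon_no - 1): 3 * codon_no]
    alt_codon = codon[: phase - 1] + d.alt_allele + codon[phase:]
    ref_aa = translate_codon(codon)
    alt_aa = translate_codon(alt_codon)
    if alt_aa == ref_aa:
        effect = SYNONYMOUS
    elif alt_aa == "*":
        effect = NONSENSE
    else:
        effect = MISSENSE  # includes stop-loss / start-loss
    labels = {effect}
    if exonic_splice_bases > 0:
        if model.exonic_distance_to_boundary(pos) <= exonic_splice_bases:
            labels.add(SPLICE_SITE)
    return ConsequenceSet(frozenset(labels), protein_change=(ref_aa, codon_no, alt_aa))


def format_protein_change(change: tuple[str, int, str] | None) -> str:
    """Render a protein change as e.g. 'p.M470V' ('' when absent, '*' = stop)."""
    if change is None:
        return ""
    ref_aa, codon_no, alt_aa = change
    return f"p.{ref_aa}{codon_no}{alt_aa}"


@dataclass(frozen=True)
class ClassTally:
    """Per-label counts over distinct variants; multi-label variants count in each label."""

    counts: tuple[tuple[str, int], ...]
    total: int

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(list(self.counts), columns=["variant_class", "n_variants"])
        return frame

    @property
    def column_sum(self) -> int:
        return sum(n for _, n in self.counts)


def tally_classes(consequences: list[ConsequenceSet]) -> ClassTally:
    """Count variants per functional class (one ConsequenceSet per distinct variant).

    A dual-class variant increments every label it carries, so the column sum
    can exceed the distinct-variant total; both are reported.
    """
    counter: Counter[str] = Counter()
    for cset in consequences:
        counter.update(cset.labels)
    counts = tuple((label, counter.get(label, 0)) for label in CLASS_LABELS)
    return ClassTally(counts=counts, total=len(consequences))


def annotations_frame(
    annotated: list[tuple[str, ConsequenceSet]],
) -> pd.DataFrame:
    """Per-variant annotation table (variant key, ';'-joined labels, protein change)."""
    rows = [
        {
            "variant": key,
            "labels": ";".join(sorted(cset.labels)),
            "protein_change": format_protein_change(cset.protein_change),
        }
        for key, cset in annotated
    ]
    return pd.DataFrame(rows, columns=["variant", "labels", "protein_change"])
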