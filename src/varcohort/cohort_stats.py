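"""Cohort bookkeeping: observation counts and ethnic-stratified variant summaries.

An observation is one patient carrying one variant at a stated zygosity; a
homozygous carrier contributes two observations. An *ethnic-specific*
variant is one whose full-cohort support is a single self-reported
ethnicity group. The Other/Mixed group (any multi-category or unlisted
self-report) never has its own ethnic-specific tally — its cell is
not-applicable in the summary — but by default its carriers still break the
exclusivity of variants shared with a named group.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from ._format import fmt_percent
from .errors import ValidationError

ETHNICITIES = (
    "African American",
    "Ashkenazi Jewish",
    "Asian/Oriental",
    "Caucasian",
    "Hispanic",
    "Middle Eastern",
    "Native American",
    "Other/Mixed",
)
OTHER_MIXED = "Other/Mixed"

HET = "het"
HOM = "hom"

NOT_APPLICABLE = "N/A"


@dataclass(frozen=True)
class Observation:
    """One patient x variant record."""

    patient_id: str
    ethnicity: str
    variant_key: str
    zygosity: str

    def __post_init__(self) -> None:
        if self.zygosity not in (HET, HOM):
            raise ValidationError(
                f"zygosity must be '{HET}' or '{HOM}', got {self.zygosity!r}",
                records=[self],
            )

    @property
    def allele_count(self) -> int:
        return 2 if self.zygosity == HOM else 1


def _validate(observations: Iterable[Observation]) -> list[Observation]:
    obs = list(observations)
    bad = [o for o in obs if o.ethnicity not in ETHNICITIES]
    if bad:
        raise ValidationError("unknown ethnicity value(s)", records=bad)
    seen: set[tuple[str, str]] = set()
    dupes = []
    for o in obs:
        pair = (o.patient_id, o.variant_key)
        if pair in seen:
            dupes.append(o)
        seen.add(pair)
    if dupes:
        raise ValidationError("duplicate (patient, variant) records", records=dupes)
    return obs


def observation_count(observations: Iterable[Observation], variant_key: str) -> int:
    """Occurrences of one variant across the cohort; a homozygote counts twice."""
    return sum(
        o.allele_count for o in observations if o.variant_key == variant_key
    )


def variant_observation_counts(observations: Iterable[Observation]) -> Counter:
    """Observation count per variant over the whole cohort (hom = 2)."""
    counter: Counter[str] = Counter()
    for o in observations:
        counter[o.variant_key] += o.allele_count
    return counter


def most_common_variants(
    observations: Iterable[Observation], k: int
) -> list[tuple[str, int]]:
    """Top-k variants by observation count, ties broken by canonical key order."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    counts = variant_observation_counts(observations)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def group_support(observations: Iterable[Observation]) -> dict[str, frozenset[str]]:
    """For each variant, the set of ethnicity groups it was observed in."""
    support: dict[str, set[str]] = defaultdict(set)
    for o in observations:
        support[o.variant_key].add(o.ethnicity)
    return {k: frozenset(v) for k, v in support.items()}


@dataclass(frozen=True)
class EthnicitySummary:
    """Per-group patient, variant and exclusivity counts (summary-table shape)."""

    rows: tuple[dict, ...]

    def row(self, group: str) -> dict:
        for r in self.rows:
            if r["ethnicity"] == group:
                return r
        raise KeyError(group)

    def to_frame(self) -> pd.DataFrame:
        """Formatted table with 'N/A' for the Other/Mixed ethnic-specific cell."""
        out = []
        for r in self.rows:
            total = r["total_snvs"]
            if r["ethnic_specific_count"] is None:
                specific = NOT_APPLICABLE
            elif total:
                specific = (
                    f"{r['ethnic_specific_count']} "
                    f"({fmt_percent(r['ethnic_specific_count'], total)}%)"
                )
            else:
                specific = "0"
            if total:
                novel = (
                    f"{r['novel_ethnic_specific_count']} "
                    f"({fmt_percent(r['novel_ethnic_specific_count'], total)}%)"
                )
            else:
                novel = "0"
            out.append(
                {
                    "ethnicity": r["ethnicity"],
                    "n_patients": r["n_patients"],
                    "total_snvs": total,
                    "ethnic_specific": specific,
                    "novel_ethnic_specific": novel,
                }
            )
        return pd.DataFrame(
            out,
            columns=[
                "ethnicity", "n_patients", "total_snvs",
                "ethnic_specific", "novel_ethnic_specific",
            ],
        )


def ethnic_summary(
    observations: Iterable[Observation],
    novel_keys: Iterable[str] = (),
    other_mixed_breaks_specificity: bool = True,
) -> EthnicitySummary:
    """Per-ethnicity patient counts, variant totals and ethnic-specific tallies.

    A variant is ethnic-specific to a named group when its full-cohort
    support is exactly that group; with
    ``other_mixed_breaks_specificity=False`` additional support from
    Other/Mixed is ignored when testing exclusivity. Other/Mixed itself
    never has an ethnic-specific count (None, rendered 'N/A'), but its
    novel-and-exclusive tally is still reported.
    """
    obs = _validate(observations)
    novel = frozenset(novel_keys)
    support = group_support(obs)

    patients: dict[str, set[str]] = defaultdict(set)
    variants: dict[str, set[str]] = defaultdict(set)
    for o in obs:
        patients[o.ethnicity].add(o.patient_id)
        variants[o.ethnicity].add(o.variant_key)

    rows = []
    for group in ETHNICITIES:
        group_variants = variants.get(group, set())
        exclusive = set()
        for key in group_variants:
            groups = support[key]
            if not other_mixed_breaks_specificity:
                groups = groups - {OTHER_MIXED} or groups
            if groups == {group}:
                exclusive.add(key)
        novel_exclusive = exclusive & novel
        specific_count: int | None = len(exclusive)
        if group == OTHER_MIXED:
            specific_count = None  # not-applicable by convention
        rows.append(
            {
                "ethnicity": group,
                "n_patients": len(patients.get(group, set())),
                "total_snvs": len(group_variants),
                "ethnic_specific_count": specific_count,
                "novel_ethnic_specific_count": len(novel_exclusive),
                "ethnic_specific_keys": frozenset(exclusive),
                "novel_ethnic_specific_keys": frozenset(novel_exclusive),
            }
        )
    return EthnicitySummary(rows=tuple(rows))


# -- cohort file I/O -----------------------------------------------------------

COHORT_COLUMNS = ["patient_id", "ethnicity", "variant", "zygosity"]


def read_cohort_tsv(path: str | Path) -> list[Observation]:
    """Read observations from a TSV with columns patient_id/ethnicity/variant/zygosity."""
    from .hgvs import canonicalize

    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"cohort file {path} lacks columns {sorted(missing)}")
    obs = [
        Observation(
            patient_id=row.patient_id,
            ethnicity=row.ethnicity,
            variant_key=canonicalize(row.variant),
            zygosity=row.zygosity,
        )
        for row in frame.itertuples()
    ]
    return _validate(obs)


def write_cohort_tsv(observations: Iterable[Observation], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "patient_id": o.patient_id,
                "ethnicity": o.ethnicity,
                "variant": o.variant_key,
                "zygosity": o.zygosity,
            }
            for o in observations
        ],
        columns=COHORT_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)
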