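"""Cross-referencing observed variants against mutation-database snapshots.

A snapshot is a named set of canonical c.-substitution keys (e.g. a dbSNP
build, a locus-specific database, a disease-mutation database) frozen at a
download date. Matching is exact canonical-string equality; a variant absent
from every snapshot is *novel*. Percentages are rounded half-up to two
decimals, the convention of the summary tables this package emits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from ._format import fmt_percent, percent
from .errors import FormatError, ValidationError
from .hgvs import canonicalize


@dataclass(frozen=True)
class DatabaseSnapshot:
    """Named set of known variant keys; optionally the snapshot's gene-wide size."""

    name: str
    keys: frozenset[str]
    total_gene_entries: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "keys", frozenset(self.keys))

    def __contains__(self, key: str) -> bool:
        return key in self.keys


class SnapshotLoadResult(NamedTuple):
    snapshot: DatabaseSnapshot
    rejects: list[tuple[int, str, str]]  # (line number, line, reason)
    duplicates: list[str]


@dataclass(frozen=True)
class XrefSummary:
    """Per-database presence counts plus the novel set, for one variant collection."""

    total: int
    per_database: tuple[tuple[str, int], ...]  # (name, present_count)
    union_present_count: int
    novel_keys: frozenset[str]

    @property
    def novel_count(self) -> int:
        return len(self.novel_keys)

    def present_count(self, name: str) -> int:
        return dict(self.per_database)[name]

    def absent_count(self, name: str) -> int:
        return self.total - self.present_count(name)

    def present_percent(self, name: str) -> float:
        return percent(self.present_count(name), self.total)

    @property
    def union_present_percent(self) -> float:
        return percent(self.union_present_count, self.total)

    @property
    def novel_percent(self) -> float:
        return percent(self.novel_count, self.total)

    def to_frame(self) -> pd.DataFrame:
        """Cross-reference table: one row per database plus a union total row."""
        rows = []
        for name, count in self.per_database:
            absent = self.total - count
            rows.append(
                {
                    "database": name,
                    "in_database": count,
                    "in_database_pct": fmt_percent(count, self.total),
                    "not_in_database": absent,
                    "not_in_database_pct": fmt_percent(absent, self.total),
                }
            )
        rows.append(
            {
                "database": "Total",
                "in_database": self.union_present_count,
                "in_database_pct": fmt_percent(self.union_present_count, self.total),
                "not_in_database": self.novel_count,
                "not_in_database_pct": fmt_percent(self.novel_count, self.total),
            }
        )
        return pd.DataFrame(rows)


def cross_reference(
    variants: Iterable[str], snapshots: list[DatabaseSnapshot]
) -> XrefSummary:
    """Set-membership summary of ``variants`` against every snapshot.

    ``variants`` must be canonical keys; the novel set is the complement of
    the union of all snapshots.
    """
    variant_set = frozenset(variants)
    if not variant_set:
        raise ValidationError("cross-reference undefined for an empty variant set")
    if not snapshots:
        raise ValidationError("at least one database snapshot is required")
    names = [s.name for s in snapshots]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate snapshot names: {names}")
    per_db = tuple(
        (snap.name, len(variant_set & snap.keys)) for snap in snapshots
    )
    union: frozenset[str] = frozenset().union(*(s.keys for s in snapshots))
    novel = variant_set - union
    return XrefSummary(
        total=len(variant_set),
        per_database=per_db,
        union_present_count=len(variant_set) - len(novel),
        novel_keys=novel,
    )


def load_snapshot(path: str | Path, name: str) -> SnapshotLoadResult:
    """Load a snapshot from a one-variant-per-line TSV ('#' comments allowed).

    Lines are canonicalized through the c. parser; malformed lines go to the
    rejects report and a file that is mostly malformed (>50%) raises
    :class:`FormatError`. Duplicate keys collapse with set semantics and are
    reported separately.
    """
    path = Path(path)
    keys: set[str] = set()
    rejects: list[tuple[int, str, str]] = []
    duplicates: list[str] = []
    n_content = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            n_content += 1
            token = line.split("\t")[0].strip()
            try:
                key = canonicalize(token)
            except Exception as exc:  # HgvsParseError
                rejects.append((lineno, line, str(exc)))
                continue
            if key in keys:
                duplicates.append(key)
            keys.add(key)
    if n_content and len(rejects) * 2 > n_content:
        raise FormatError(
            f"{path}: {len(rejects)}/{n_content} lines malformed; not a variant list"
        )
    return SnapshotLoadResult(
        snapshot=DatabaseSnapshot(name=name, keys=frozenset(keys)),
        rejects=rejects,
        duplicates=duplicates,
    )
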