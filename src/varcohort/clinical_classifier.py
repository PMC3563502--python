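"""Rule-based clinical classification of variants into five significance tiers.

The scheme codifies pre-ACMG referral-laboratory practice: database and
literature assertions are consulted first, then population frequency, then
the heuristic that common, synonymous and deep-intronic substitutions are
(suspected) benign absent contrary evidence; whatever remains is a variant
of unknown significance. In-silico predictors participate only as a
nudge between the "suspected" tiers around unknown significance — no call
is ever based solely on them. The sixth label, ``unrecorded``, marks legacy
variants that have never been scored and is assigned only when no evidence
bundle exists, never by :func:`classify` itself.

Every rule evaluation is logged to ``rule_trace`` so a call can be audited
and replayed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .consequence import SYNONYMOUS, ConsequenceSet
from .errors import ValidationError

PATHOGENIC = "pathogenic"
SUSPECTED_PATHOGENIC = "suspected_pathogenic"
UNKNOWN_SIGNIFICANCE = "unknown_significance"
SUSPECTED_BENIGN = "suspected_benign"
BENIGN = "benign"
UNRECORDED = "unrecorded"

TIERS = (
    PATHOGENIC,
    SUSPECTED_PATHOGENIC,
    UNKNOWN_SIGNIFICANCE,
    SUSPECTED_BENIGN,
    BENIGN,
    UNRECORDED,
)

#: benign (0) .. pathogenic (4); used for monotonicity reasoning and tests.
TIER_RANK = {
    BENIGN: 0,
    SUSPECTED_BENIGN: 1,
    UNKNOWN_SIGNIFICANCE: 2,
    SUSPECTED_PATHOGENIC: 3,
    PATHOGENIC: 4,
}

# database / literature assertion vocabularies
ASSERTION_LEVELS = ("pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign")
LIT_PATHOGENIC = "reported_pathogenic"
LIT_BENIGN = "reported_benign"
LIT_NONE = "none"

PRED_DAMAGING = "damaging"
PRED_TOLERATED = "tolerated"
PRED_NEUTRAL = "neutral"


@dataclass(frozen=True)
class DatabaseAssertion:
    """Presence of a variant in one database, with its reported classification if any."""

    database: str
    present: bool = True
    classification: str | None = None

    def __post_init__(self) -> None:
        if self.classification is not None and self.classification not in ASSERTION_LEVELS:
            raise ValidationError(
                f"unknown database classification {self.classification!r}"
            )


@dataclass(frozen=True)
class EvidenceBundle:
    """Everything the classifier may consult for one variant."""

    consequence: ConsequenceSet
    deep_intronic: bool = False
    db_assertions: tuple[DatabaseAssertion, ...] = ()
    literature_status: str = LIT_NONE
    population_frequency: float | None = None
    insilico: tuple[tuple[str, str], ...] = ()  # (predictor name, prediction)

    def __post_init__(self) -> None:
        object.__setattr__(self, "db_assertions", tuple(self.db_assertions))
        object.__setattr__(self, "insilico", tuple(self.insilico))
        if self.literature_status not in (LIT_PATHOGENIC, LIT_BENIGN, LIT_NONE):
            raise ValidationError(
                f"unknown literature status {self.literature_status!r}"
            )
        freq = self.population_frequency
        if freq is not None and not 0.0 <= freq <= 1.0:
            raise ValidationError(f"population frequency {freq} outside [0, 1]")
        for _, pred in self.insilico:
            if pred not in (PRED_DAMAGING, PRED_TOLERATED, PRED_NEUTRAL):
                raise ValidationError(f"unknown in-silico prediction {pred!r}")


@dataclass(frozen=True)
class ClinicalCall:
    tier: str
    rule_trace: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValidationError(f"unknown tier {self.tier!r}")
        if self.tier != UNRECORDED and not self.rule_trace:
            raise ValidationError("a scored call must carry a non-empty rule trace")


def _insilico_consensus(e: EvidenceBundle) -> str | None:
    """'damaging'/'tolerated' when >=2 predictors agree unanimously, else None."""
    verdicts = [p for _, p in e.insilico if p in (PRED_DAMAGING, PRED_TOLERATED)]
    if len(verdicts) >= 2 and len(set(verdicts)) == 1:
        return verdicts[0]
    return None


def classify(e: EvidenceBundle, common_threshold: float = 0.01) -> ClinicalCall:
    """Apply the stepwise classification rules to one evidence bundle.

    Rule order (first match wins):

    1. a database or literature pathogenic assertion -> pathogenic;
       a likely/limited pathogenic assertion -> suspected_pathogenic;
    2. a database or literature benign assertion -> benign
       (likely_benign -> suspected_benign);
    3. no contrary assertions: population frequency >= ``common_threshold``
       -> benign; synonymous or deep-intronic with unknown or sub-threshold
       frequency -> suspected_benign;
    4. otherwise unknown significance, which a unanimous in-silico consensus
       may nudge to the adjacent suspected tier.
    """
    trace: list[str] = []
    db_levels = {a.classification for a in e.db_assertions if a.present}

    # Rule 1: pathogenic assertions dominate.
    strong_path = "pathogenic" in db_levels or e.literature_status == LIT_PATHOGENIC
    trace.append(f"R1.pathogenic_assertion={'yes' if strong_path else 'no'}")
    if strong_path:
        trace.append(f"assign:{PATHOGENIC}")
        return ClinicalCall(PATHOGENIC, tuple(trace))
    likely_path = "likely_pathogenic" in db_levels
    trace.append(f"R1.limited_pathogenic_assertion={'yes' if likely_path else 'no'}")
    if likely_path:
        trace.append(f"assign:{SUSPECTED_PATHOGENIC}")
        return ClinicalCall(SUSPECTED_PATHOGENIC, tuple(trace))

    # Rule 2: benign assertions.
    strong_benign = "benign" in db_levels or e.literature_status == LIT_BENIGN
    trace.append(f"R2.benign_assertion={'yes' if strong_benign else 'no'}")
    if strong_benign:
        trace.append(f"assign:{BENIGN}")
        return ClinicalCall(BENIGN, tuple(trace))
    likely_benign = "likely_benign" in db_levels
    trace.append(f"R2.limited_benign_assertion={'yes' if likely_benign else 'no'}")
    if likely_benign:
        trace.append(f"assign:{SUSPECTED_BENIGN}")
        return ClinicalCall(SUSPECTED_BENIGN, tuple(trace))

    # Rule 3: heuristics for common / synonymous / deep-intronic variants.
    freq = e.population_frequency
    common = freq is not None and freq >= common_threshold
    trace.append(f"R3.frequency_common={'yes' if common else 'no'}")
    if common:
        trace.append(f"assign:{BENIGN}")
        return ClinicalCall(BENIGN, tuple(trace))
    quiet = SYNONYMOUS in e.consequence.labels or e.deep_intronic
    trace.append(f"R3.synonymous_or_deep_intronic={'yes' if quiet else 'no'}")
    if quiet:
        trace.append(f"assign:{SUSPECTED_BENIGN}")
        return ClinicalCall(SUSPECTED_BENIGN, tuple(trace))

    # Rule 4: VUS, nudged only by a unanimous in-silico consensus.
    consensus = _insilico_consensus(e)
    trace.append(f"R4.insilico_consensus={consensus or 'none'}")
    if consensus == PRED_DAMAGING:
        trace.append(f"assign:{SUSPECTED_PATHOGENIC}")
        return ClinicalCall(SUSPECTED_PATHOGENIC, tuple(trace))
    if consensus == PRED_TOLERATED:
        trace.append(f"assign:{SUSPECTED_BENIGN}")
        return ClinicalCall(SUSPECTED_BENIGN, tuple(trace))
    trace.append(f"assign:{UNKNOWN_SIGNIFICANCE}")
    return ClinicalCall(UNKNOWN_SIGNIFICANCE, tuple(trace))


def replay_trace(trace: tuple[str, ...]) -> str:
    """Tier implied by a rule trace (its terminal assignment)."""
    for entry in reversed(trace):
        if entry.startswith("assign:"):
            return entry.split(":", 1)[1]
    raise ValidationError("rule trace carries no assignment")


@dataclass(frozen=True)
class TierTally:
    counts: tuple[tuple[str, int], ...]
    total: int

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.counts), columns=["tier", "n_variants"])


def tally_tiers(calls: Iterable[ClinicalCall]) -> TierTally:
    """Count calls per tier; the total always equals the number of calls."""
    calls = list(calls)
    counter = Counter(c.tier for c in calls)
    counts = tuple((tier, counter.get(tier, 0)) for tier in TIERS)
    return TierTally(counts=counts, total=len(calls))


# -- evidence file I/O ---------------------------------------------------------

EVIDENCE_COLUMNS = ["variant", "databases", "literature", "frequency", "insilico"]


@dataclass(frozen=True)
class EvidenceRecord:
    """One evidence-TSV row, before transcript-dependent fields are attached."""

    variant_key: str
    db_assertions: tuple[DatabaseAssertion, ...] = ()
    literature_status: str = LIT_NONE
    population_frequency: float | None = None
    insilico: tuple[tuple[str, str], ...] = ()


def _parse_pairs(cell: str) -> list[tuple[str, str]]:
    pairs = []
    for item in cell.split(";"):
        item = item.strip()
        if not item:
            continue
        name, _, value = item.partition("=")
        pairs.append((name.strip(), value.strip() or None))
    return pairs


def read_evidence_tsv(path) -> dict[str, EvidenceRecord]:
    """Read per-variant evidence records keyed by canonical variant string.

    ``databases`` and ``insilico`` cells are ';'-separated ``name=value``
    pairs; empty cells mean no assertions / unknown frequency.
    """
    from .hgvs import canonicalize

    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    missing = set(EVIDENCE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"evidence file {path} lacks columns {sorted(missing)}")
    records: dict[str, EvidenceRecord] = {}
    for row in frame.itertuples():
        key = canonicalize(row.variant)
        assertions = tuple(
            DatabaseAssertion(database=name, present=True, classification=value)
            for name, value in _parse_pairs(row.databases)
        )
        freq_cell = str(row.frequency).strip()
        freq = float(freq_cell) if freq_cell else None
        if freq is not None and not 0.0 <= freq <= 1.0:
            raise ValidationError(
                f"malformed frequency {freq!r} for {key}", records=[key]
            )
        insilico = tuple(
            (name, value) for name, value in _parse_pairs(row.insilico)
        )
        records[key] = EvidenceRecord(
            variant_key=key,
            db_assertions=assertions,
            literature_status=(str(row.literature).strip() or LIT_NONE),
            population_frequency=freq,
            insilico=insilico,
        )
    return records


def write_evidence_tsv(records: Iterable[EvidenceRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "variant": r.variant_key,
                "databases": ";".join(
                    f"{a.database}={a.classification or ''}" for a in r.db_assertions
                ),
                "literature": r.literature_status,
                "frequency": "" if r.population_frequency is None
                else repr(r.population_frequency),
                "insilico": ";".join(f"{n}={p}" for n, p in r.insilico),
            }
        )
    pd.DataFrame(rows, columns=EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


def bundle_from_record(
    record: EvidenceRecord | None,
    consequence: ConsequenceSet,
    deep_intronic: bool,
) -> EvidenceBundle | None:
    """Attach transcript-derived fields to a raw evidence record (None stays None)."""
    if record is None:
        return None
    return EvidenceBundle(
        consequence=consequence,
        deep_intronic=deep_intronic,
        db_assertions=record.db_assertions,
        literature_status=record.literature_status,
        population_frequency=record.population_frequency,
        insilico=record.insilico,
    )


def classify_cohort(
    bundles: dict[str, EvidenceBundle | None], common_threshold: float = 0.01
) -> dict[str, ClinicalCall]:
    """Classify every variant; a missing bundle yields the unrecorded tier."""
    calls = {}
    for key, bundle in bundles.items():
        if bundle is None:
            calls[key] = ClinicalCall(UNRECORDED, ())
        else:
            calls[key] = classify(bundle, common_threshold=common_threshold)
    return calls
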