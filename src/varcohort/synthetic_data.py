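"""Seeded generators for transcripts, cohorts, database snapshots and evidence.

The generators emulate the statistical shape of a referral-laboratory SNV
dataset for a large multi-exon gene: a rare-variant-enriched allele
spectrum in which most variants are singletons, a handful of high-frequency
polymorphisms planted with exact observation counts, self-reported
ethnicity groups with very unequal sizes, database snapshots with
per-database coverage probabilities, and per-variant evidence bundles built
to land on a prescribed clinical-tier mix. Every generator takes an explicit
seed and uses a single private random stream; identical seeds give
byte-identical fixtures.

Ground truth for every planted property is returned alongside the data so
downstream summaries can be checked exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical_classifier import (
    BENIGN,
    EvidenceRecord,
    PATHOGENIC,
    SUSPECTED_BENIGN,
    SUSPECTED_PATHOGENIC,
    UNKNOWN_SIGNIFICANCE,
    UNRECORDED,
    DatabaseAssertion,
    LIT_NONE,
    LIT_PATHOGENIC,
    write_evidence_tsv,
)
from .cohort_stats import (
    ETHNICITIES,
    HET,
    HOM,
    Observation,
    write_cohort_tsv,
)
from .consequence import (
    MISSENSE,
    NONSENSE,
    SYNONYMOUS,
    annotate,
)
from .database_xref import DatabaseSnapshot
from .errors import ParameterError
from .gene_model import (
    INTRONIC,
    PROMOTER,
    SPLICE_SITE,
    STOP_CODONS,
    TranscriptModel,
    write_transcript,
)
from .hgvs import BASES, VariantDescriptor, format_c

_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
NONSTOP_CODONS = tuple(c for c in _ALL_CODONS if c not in STOP_CODONS)

#: per-group patient counts the default cohort reproduces (sums to 555)
DEFAULT_GROUP_COUNTS = (61, 1, 4, 403, 40, 3, 1, 42)

DEFAULT_CLASS_MIX = {
    MISSENSE: 105,
    SYNONYMOUS: 33,
    INTRONIC: 28,
    SPLICE_SITE: 12,
    NONSENSE: 3,
    PROMOTER: 3,
}

DEFAULT_TIER_MIX = {
    PATHOGENIC: 97,
    SUSPECTED_PATHOGENIC: 8,
    BENIGN: 37,
    UNKNOWN_SIGNIFICANCE: 30,
    SUSPECTED_BENIGN: 6,
    UNRECORDED: 6,
}

DEFAULT_SNAPSHOT_PROBS = {"CFMDB": 0.85, "HGMD": 0.64, "dbSNP132": 0.40}
DEFAULT_SNAPSHOT_TOTALS = {"CFMDB": 1383, "HGMD": 1057, "dbSNP132": 1430}


def _largest_remainder(weights: np.ndarray, n: int) -> np.ndarray:
    """Integer allocation of n items proportional to weights (largest remainder)."""
    quotas = weights / weights.sum() * n
    base = np.floor(quotas).astype(int)
    short = n - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:short]] += 1
    return base


@dataclass(frozen=True)
class CohortSpec:
    """Shape parameters of a synthetic referral cohort."""

    seed: int
    n_patients: int = 555
    ethnicity_weights: tuple[float, ...] = tuple(
        c / sum(DEFAULT_GROUP_COUNTS) for c in DEFAULT_GROUP_COUNTS
    )
    n_distinct_variants: int = 184
    singleton_fraction: float = 107 / 184
    common_variant_counts: tuple[int, ...] = (955, 728, 427, 236)
    n_high_count: int = 16
    hom_fraction: float = 0.05
    class_mix: tuple[tuple[str, int], ...] | None = None
    home_group_affinity: float = 0.8

    def resolved_class_mix(self) -> dict[str, int]:
        if self.class_mix is not None:
            mix = dict(self.class_mix)
        else:
            labels = list(DEFAULT_CLASS_MIX)
            weights = np.array([DEFAULT_CLASS_MIX[l] for l in labels], dtype=float)
            counts = _largest_remainder(weights, self.n_distinct_variants)
            mix = dict(zip(labels, (int(c) for c in counts)))
        if sum(mix.values()) != self.n_distinct_variants:
            raise ParameterError(
                f"class mix sums to {sum(mix.values())}, "
                f"expected {self.n_distinct_variants}"
            )
        return mix


@dataclass(frozen=True)
class SnapshotSpec:
    """Per-database inclusion probabilities and forced-novel count."""

    seed: int
    inclusion_probabilities: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_SNAPSHOT_PROBS.items()
    )
    forced_novel_count: int = 21
    total_entries: tuple[tuple[str, int], ...] = tuple(
        DEFAULT_SNAPSHOT_TOTALS.items()
    )

    def __post_init__(self) -> None:
        for name, p in self.inclusion_probabilities:
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"inclusion probability {p} for {name} outside [0,1]")


# -- transcript ---------------------------------------------------------------


def gen_transcript(
    seed: int,
    n_exons: int = 27,
    n_codons: int = 1480,
    min_exon: int = 30,
    intron_size_range: tuple[int, int] = (80, 2000),
    promoter_pad: int = 500,
    gene_symbol: str = "SYNCFTR",
) -> TranscriptModel:
    """Random multi-exon transcript with a clean CDS (defaults: 27 exons, 1480 codons).

    The CDS is ATG + random non-stop codons + one stop codon, 3*(n_codons+1)
    nucleotides in total, split over ``n_exons`` exons of random sizes
    (each at least ``min_exon``) separated by random introns on a synthetic
    plus-strand axis. Deterministic per seed.
    """
    if n_exons < 1:
        raise ParameterError("n_exons must be >= 1")
    if n_codons < 2:
        raise ParameterError("n_codons must be >= 2")
    cds_len = 3 * (n_codons + 1)  # protein codons + stop
    if cds_len < n_exons * min_exon:
        raise ParameterError(
            f"{n_exons} exons of >= {min_exon} bp cannot fit a {cds_len} bp CDS"
        )
    rng = np.random.default_rng(seed)
    body = rng.choice(len(NONSTOP_CODONS), size=n_codons - 1)
    stop = rng.choice(sorted(STOP_CODONS))
    cds = "ATG" + "".join(NONSTOP_CODONS[i] for i in body) + str(stop)

    extra = _largest_remainder(
        rng.dirichlet(np.ones(n_exons)), cds_len - n_exons * min_exon
    )
    exon_lengths = (min_exon + extra).astype(int)
    intron_lengths = (
        rng.integers(intron_size_range[0], intron_size_range[1] + 1, size=n_exons - 1)
        if n_exons > 1
        else np.array([], dtype=int)
    )
    exons = []
    pos = promoter_pad + 1
    for i, length in enumerate(exon_lengths):
        exons.append((pos, pos + int(length) - 1))
        pos += int(length)
        if i < n_exons - 1:
            pos += int(intron_lengths[i])
    return TranscriptModel(
        gene_symbol=gene_symbol,
        exons=tuple(exons),
        coding_sequence=cds,
        cds_start_exon_offset=1,
    )


# -- variant drawing ----------------------------------------------------------


def _draw_class_variants(
    rng: np.random.Generator, model: TranscriptModel, class_mix: dict[str, int]
) -> list[dict]:
    """Draw distinct variants realizing the requested per-class counts."""
    coding_classes = {MISSENSE, NONSENSE, SYNONYMOUS}
    needs_introns = class_mix.get(SPLICE_SITE, 0) or class_mix.get(INTRONIC, 0)
    if needs_introns and model.n_introns == 0:
        raise ParameterError("intronic/splice variants need a multi-exon transcript")
    if class_mix.get(SPLICE_SITE, 0) > 4 * model.n_introns:
        raise ParameterError(
            f"{class_mix[SPLICE_SITE]} splice variants exceed the "
            f"{4 * model.n_introns} available splice positions"
        )

    used: set[str] = set()
    out: list[dict] = []

    def push(d: VariantDescriptor, label: str) -> bool:
        key = format_c(d)
        if key in used:
            return False
        used.add(key)
        out.append({"descriptor": d, "class": label})
        return True

    # exonic classes by rejection sampling over coding positions
    for label in (MISSENSE, NONSENSE, SYNONYMOUS):
        needed = class_mix.get(label, 0)
        guard = 0
        while needed > 0:
            guard += 1
            if guard > 200_000:
                raise ParameterError(f"cannot place {label} variants in this CDS")
            pos = int(rng.integers(4, model.cds_length - 2))  # spare ATG and stop
            ref = model.coding_sequence[pos - 1]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            d = VariantDescriptor(pos, 0, False, ref, alt)
            cset = annotate(d, model)
            if cset.coding_effect == label and push(d, label):
                needed -= 1

    # splice sites: sample boundary slots without replacement
    n_splice = class_mix.get(SPLICE_SITE, 0)
    if n_splice:
        slots = [
            (i, side, off)
            for i in range(model.n_introns)
            for side in ("donor", "acceptor")
            for off in (1, 2)
        ]
        chosen = rng.choice(len(slots), size=n_splice, replace=False)
        for idx in chosen:
            intron, side, off = slots[int(idx)]
            if side == "donor":
                anchor, offset = model.donor_anchor(intron), off
            else:
                anchor, offset = model.acceptor_anchor(intron), -off
            ref = str(rng.choice(BASES))
            alt = str(rng.choice([b for b in BASES if b != ref]))
            push(VariantDescriptor(anchor, offset, False, ref, alt), SPLICE_SITE)

    # intronic: offsets 3..60, roughly half beyond the deep-intronic threshold
    needed = class_mix.get(INTRONIC, 0)
    guard = 0
    while needed > 0:
        guard += 1
        if guard > 200_000:
            raise ParameterError("cannot place intronic variants")
        intron = int(rng.integers(model.n_introns))
        off = int(rng.integers(3, 61))
        if rng.random() < 0.5:
            anchor, offset = model.donor_anchor(intron), off
        else:
            anchor, offset = model.acceptor_anchor(intron), -off
        ref = str(rng.choice(BASES))
        alt = str(rng.choice([b for b in BASES if b != ref]))
        if push(VariantDescriptor(anchor, offset, False, ref, alt), INTRONIC):
            needed -= 1

    # promoter: c.-N
    needed = class_mix.get(PROMOTER, 0)
    if needed:
        ns = rng.choice(np.arange(1, 301), size=needed, replace=False)
        for n in ns:
            ref = str(rng.choice(BASES))
            alt = str(rng.choice([b for b in BASES if b != ref]))
            push(VariantDescriptor(int(n), 0, True, ref, alt), PROMOTER)
    return out


# -- cohort -------------------------------------------------------------------


def gen_cohort(
    spec: CohortSpec, model: TranscriptModel
) -> tuple[list[Observation], pd.DataFrame]:
    """Generate observations plus a ground-truth table, both deterministic per seed.

    Plants: exact per-class variant counts, the common polymorphisms with
    their exact observation counts, the singleton count, and a configurable
    number of variants observed ten or more times. Carriers of non-common
    variants are biased toward a per-variant home ethnicity group so
    ethnic-specific structure emerges; ground truth records the realized
    group support of every variant.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_distinct_variants
    commons = list(spec.common_variant_counts)
    n_singletons = int(round(spec.singleton_fraction * n))
    if len(commons) + n_singletons > n:
        raise ParameterError(
            f"{len(commons)} common + {n_singletons} singleton variants exceed "
            f"{n} distinct variants"
        )
    for c in commons:
        if c > 2 * spec.n_patients:
            raise ParameterError(
                f"common count {c} exceeds 2 x {spec.n_patients} alleles"
            )
    weights = np.asarray(spec.ethnicity_weights, dtype=float)
    if len(weights) != len(ETHNICITIES):
        raise ParameterError(
            f"ethnicity_weights needs {len(ETHNICITIES)} entries, got {len(weights)}"
        )
    if not np.isclose(weights.sum(), 1.0):
        raise ParameterError("ethnicity weights must sum to 1")

    # patients: exact largest-remainder allocation of groups, shuffled over ids
    group_counts = _largest_remainder(weights, spec.n_patients)
    ethnicities = np.repeat(np.arange(len(ETHNICITIES)), group_counts)
    rng.shuffle(ethnicities)
    patient_ids = [f"P{i:04d}" for i in range(1, spec.n_patients + 1)]
    patient_group = {
        pid: ETHNICITIES[g] for pid, g in zip(patient_ids, ethnicities)
    }
    pools = {
        g: [pid for pid in patient_ids if patient_group[pid] == g]
        for g in ETHNICITIES
    }

    variants = _draw_class_variants(rng, model, spec.resolved_class_mix())

    # choose common variants: 1 missense, 2 synonymous, 1 shallow-intronic
    def first_match(pred, taken):
        for i, v in enumerate(variants):
            if i not in taken and pred(v):
                return i
        return None

    wanted = [
        lambda v: v["class"] == MISSENSE,
        lambda v: v["class"] == SYNONYMOUS,
        lambda v: v["class"] == SYNONYMOUS,
        lambda v: v["class"] == INTRONIC
        and 3 <= abs(v["descriptor"].intron_offset) <= 20,
    ]
    taken: set[int] = set()
    common_idx: list[int] = []
    for want in wanted[: len(commons)]:
        idx = first_match(want, taken)
        if idx is None:
            idx = first_match(lambda v: True, taken)
        taken.add(idx)
        common_idx.append(idx)
    # extra commons beyond the four archetypes, if requested
    while len(common_idx) < len(commons):
        idx = first_match(lambda v: True, taken)
        taken.add(idx)
        common_idx.append(idx)

    rest = [i for i in range(len(variants)) if i not in taken]
    rest_order = rng.permutation(len(rest))
    singleton_idx = [rest[i] for i in rest_order[:n_singletons]]
    mid_idx = [rest[i] for i in rest_order[n_singletons:]]

    n_high_mid = min(max(0, spec.n_high_count - len(commons)), len(mid_idx))
    counts: dict[int, int] = {}
    for idx, c in zip(common_idx, commons):
        counts[idx] = c
    for idx in singleton_idx:
        counts[idx] = 1
    for j, idx in enumerate(mid_idx):
        if j < n_high_mid:
            counts[idx] = int(rng.integers(10, 31))
        else:
            counts[idx] = int(rng.integers(2, 10))

    observations: list[Observation] = []
    truth_rows = []
    for i, v in enumerate(variants):
        d: VariantDescriptor = v["descriptor"]
        key = format_c(d)
        c = counts[i]
        h_min = max(0, c - spec.n_patients)
        h = max(h_min, int(round(spec.hom_fraction * c / 2)))
        h = min(h, c // 2)
        t = c - 2 * h
        n_carriers = t + h

        if i in common_idx:
            home = None
            carriers = list(rng.choice(patient_ids, size=n_carriers, replace=False))
        else:
            home = ETHNICITIES[int(rng.choice(len(ETHNICITIES), p=weights))]
            pool = pools[home]
            n_home = min(
                len(pool), max(1, int(round(spec.home_group_affinity * n_carriers)))
            )
            n_home = min(n_home, n_carriers)
            carriers = list(rng.choice(pool, size=n_home, replace=False))
            if n_carriers > n_home:
                others = [p for p in patient_ids if p not in set(carriers)]
                carriers += list(
                    rng.choice(others, size=n_carriers - n_home, replace=False)
                )
        hom_carriers = set(
            rng.choice(carriers, size=h, replace=False) if h else []
        )
        support = set()
        for pid in carriers:
            support.add(patient_group[pid])
            observations.append(
                Observation(
                    patient_id=pid,
                    ethnicity=patient_group[pid],
                    variant_key=key,
                    zygosity=HOM if pid in hom_carriers else HET,
                )
            )
        deep = d.intron_offset != 0 and abs(d.intron_offset) > 20
        truth_rows.append(
            {
                "variant": key,
                "class": v["class"],
                "coding_pos": d.coding_pos,
                "intron_offset": d.intron_offset,
                "upstream": d.upstream,
                "deep_intronic": deep,
                "is_common": i in common_idx,
                "is_singleton": c == 1,
                "n_obs": c,
                "n_carriers": n_carriers,
                "n_hom": h,
                "home_group": home or "",
                "support_groups": ";".join(sorted(support)),
                "cohort_frequency": c / (2 * spec.n_patients),
            }
        )
    observations.sort(key=lambda o: (o.patient_id, o.variant_key))
    truth = pd.DataFrame(truth_rows).sort_values("variant").reset_index(drop=True)
    return observations, truth


# -- database snapshots -------------------------------------------------------


def _random_key(rng: np.random.Generator, max_pos: int) -> str:
    """A random well-formed c. key (exonic, intronic or upstream), for decoy padding."""
    ref = str(rng.choice(BASES))
    alt = str(rng.choice([b for b in BASES if b != ref]))
    kind = rng.random()
    if kind < 0.70:
        return format_c(VariantDescriptor(int(rng.integers(1, max_pos + 1)), 0, False, ref, alt))
    if kind < 0.95:
        off = int(rng.integers(1, 500)) * (1 if rng.random() < 0.5 else -1)
        return format_c(
            VariantDescriptor(int(rng.integers(1, max_pos + 1)), off, False, ref, alt)
        )
    return format_c(VariantDescriptor(int(rng.integers(1, 2000)), 0, True, ref, alt))


def gen_snapshots(
    spec: SnapshotSpec, variant_keys: list[str] | set[str]
) -> list[DatabaseSnapshot]:
    """Database snapshots over the cohort's keys, with exact novel-count planting.

    Exactly ``forced_novel_count`` keys are withheld from every snapshot;
    each remaining key's membership vector is drawn with the per-database
    inclusion probabilities, conditioned on membership in at least one
    database (so the union-present count is exact by construction). Each
    snapshot is padded with random decoy keys to its nominal gene-wide size.
    """
    keys = sorted(set(variant_keys))
    if spec.forced_novel_count > len(keys):
        raise ParameterError(
            f"forced_novel_count {spec.forced_novel_count} exceeds {len(keys)} keys"
        )
    rng = np.random.default_rng(spec.seed)
    names = [name for name, _ in spec.inclusion_probabilities]
    probs = np.array([p for _, p in spec.inclusion_probabilities])
    totals = dict(spec.total_entries)

    novel = set(
        rng.choice(keys, size=spec.forced_novel_count, replace=False).tolist()
    )
    members: dict[str, set[str]] = {name: set() for name in names}
    for key in keys:
        if key in novel:
            continue
        while True:  # conditional on presence in >= 1 database
            vec = rng.random(len(names)) < probs
            if vec.any():
                break
        for name, hit in zip(names, vec):
            if hit:
                members[name].add(key)

    cohort_set = set(keys)
    snapshots = []
    max_pos = 4443  # decoy coordinate range; well-formedness is all that matters
    for name in names:
        target = totals.get(name, len(members[name]))
        decoys: set[str] = set()
        guard = 0
        while len(members[name]) + len(decoys) < target:
            guard += 1
            if guard > 1_000_000:
                raise ParameterError(f"cannot pad snapshot {name} to {target} entries")
            k = _random_key(rng, max_pos)
            if k not in cohort_set and k not in decoys:
                decoys.add(k)
        all_keys = frozenset(members[name] | decoys)
        snapshots.append(
            DatabaseSnapshot(name=name, keys=all_keys, total_gene_entries=len(all_keys))
        )
    return snapshots


# -- evidence -----------------------------------------------------------------


def gen_evidence(
    seed: int,
    ground_truth: pd.DataFrame,
    snapshots: list[DatabaseSnapshot],
    tier_mix: dict[str, int] | None = None,
) -> tuple[dict[str, EvidenceRecord | None], dict[str, str]]:
    """Evidence records engineered so the rule engine lands on a planted tier mix.

    Returns ``(records, planted_tiers)``; a None record means the variant is
    unscored (tier ``unrecorded``). Tier targets are assigned respecting
    rule-engine feasibility: suspected_benign only on synonymous or
    deep-intronic variants, unknown-significance never on them, common
    variants always benign.
    """
    rng = np.random.default_rng(seed)
    gt = ground_truth.set_index("variant")
    keys = list(gt.index)
    n = len(keys)

    if tier_mix is None:
        labels = list(DEFAULT_TIER_MIX)
        alloc = _largest_remainder(
            np.array([DEFAULT_TIER_MIX[t] for t in labels], dtype=float), n
        )
        tier_mix = dict(zip(labels, (int(a) for a in alloc)))
    if sum(tier_mix.values()) != n:
        raise ParameterError(
            f"tier mix sums to {sum(tier_mix.values())}, expected {n}"
        )

    membership = {s.name: s.keys for s in snapshots}

    def is_quiet(key: str) -> bool:
        row = gt.loc[key]
        return row["class"] == SYNONYMOUS or bool(row["deep_intronic"])

    planted: dict[str, str] = {}
    remaining = set(keys)

    # common polymorphisms are benign by definition of the frequency rule
    commons = [k for k in keys if gt.loc[k, "is_common"]]
    n_benign = tier_mix.get(BENIGN, 0)
    if len(commons) > n_benign:
        raise ParameterError("tier mix has fewer benign slots than common variants")
    for k in commons:
        planted[k] = BENIGN
        remaining.discard(k)

    def take(n_take: int, candidates: list[str], tier: str) -> None:
        if len(candidates) < n_take:
            raise ParameterError(
                f"only {len(candidates)} variants eligible for tier {tier}, "
                f"need {n_take}"
            )
        chosen = rng.choice(sorted(candidates), size=n_take, replace=False)
        for k in chosen:
            planted[k] = tier
            remaining.discard(k)

    take(
        tier_mix.get(SUSPECTED_BENIGN, 0),
        [k for k in remaining if is_quiet(k)],
        SUSPECTED_BENIGN,
    )
    take(
        tier_mix.get(UNKNOWN_SIGNIFICANCE, 0),
        [k for k in remaining if not is_quiet(k)],
        UNKNOWN_SIGNIFICANCE,
    )
    take(tier_mix.get(UNRECORDED, 0), sorted(remaining), UNRECORDED)
    take(n_benign - len(commons), sorted(remaining), BENIGN)
    # suspected_pathogenic: database members first, else the in-silico route
    # (which requires a non-quiet variant)
    n_sp = tier_mix.get(SUSPECTED_PATHOGENIC, 0)
    in_db = {
        k for k in remaining if any(k in m for m in membership.values())
    }
    sp_pool = list(in_db) + [
        k for k in remaining if k not in in_db and not is_quiet(k)
    ]
    take(n_sp, sp_pool, SUSPECTED_PATHOGENIC)
    for k in sorted(remaining):
        planted[k] = PATHOGENIC
    if sum(1 for t in planted.values() if t == PATHOGENIC) != tier_mix.get(PATHOGENIC, 0):
        raise ParameterError("pathogenic slots inconsistent with tier mix")

    records: dict[str, EvidenceRecord | None] = {}
    for key in keys:
        tier = planted[key]
        row = gt.loc[key]
        if tier == UNRECORDED:
            records[key] = None
            continue
        assertions: tuple[DatabaseAssertion, ...] = ()
        literature = LIT_NONE
        freq: float | None = None
        insilico: tuple[tuple[str, str], ...] = ()
        if tier == BENIGN:
            cohort_freq = float(row["cohort_frequency"])
            freq = cohort_freq if cohort_freq >= 0.01 else round(
                float(rng.uniform(0.01, 0.5)), 4
            )
        elif tier == SUSPECTED_BENIGN:
            if rng.random() < 0.5:
                freq = round(float(rng.uniform(0.0001, 0.009)), 4)
        elif tier == UNKNOWN_SIGNIFICANCE:
            if row["class"] == MISSENSE:
                insilico = (("SIFT", "damaging"), ("PolyPhen2", "tolerated"))
        elif tier == SUSPECTED_PATHOGENIC:
            holder = next(
                (name for name in membership if key in membership[name]), None
            )
            if holder is not None:
                assertions = (
                    DatabaseAssertion(holder, True, "likely_pathogenic"),
                )
            else:
                insilico = (("SIFT", "damaging"), ("PolyPhen2", "damaging"))
        elif tier == PATHOGENIC:
            if key in membership.get("HGMD", frozenset()):
                assertions = (DatabaseAssertion("HGMD", True, "pathogenic"),)
            elif key in membership.get("CFMDB", frozenset()):
                assertions = (DatabaseAssertion("CFMDB", True, "pathogenic"),)
            else:
                literature = LIT_PATHOGENIC
            if row["class"] == MISSENSE:
                insilico = (("SIFT", "damaging"), ("PolyPhen2", "damaging"))
        records[key] = EvidenceRecord(
            variant_key=key,
            db_assertions=assertions,
            literature_status=literature,
            population_frequency=freq,
            insilico=insilico,
        )
    return records, planted


# -- fixture writing ----------------------------------------------------------


def write_fixtures(
    outdir: str | Path,
    seed: int,
    n_exons: int = 27,
    n_codons: int = 1480,
    cohort_spec: CohortSpec | None = None,
    snapshot_spec: SnapshotSpec | None = None,
) -> dict[str, Path]:
    """Generate and write the full fixture set the pipeline consumes.

    Sub-generators get seeds derived from ``seed`` (kept below 2**31).
    Writes transcript GFF3 + CDS FASTA, cohort TSV, one TSV per snapshot,
    evidence TSV, ground-truth tables and a ready-to-run pipeline config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sub = [(seed + k) % (2**31) for k in range(4)]

    model = gen_transcript(sub[0], n_exons=n_exons, n_codons=n_codons)
    cohort_spec = cohort_spec or CohortSpec(seed=sub[1])
    snapshot_spec = snapshot_spec or SnapshotSpec(seed=sub[2])

    observations, truth = gen_cohort(cohort_spec, model)
    keys = sorted(truth["variant"])
    snapshots = gen_snapshots(snapshot_spec, keys)
    records, planted = gen_evidence(sub[3], truth, snapshots)

    paths: dict[str, Path] = {}
    paths["transcript_gff3"] = outdir / "transcript.gff3"
    paths["cds_fasta"] = outdir / "cds.fasta"
    write_transcript(model, paths["transcript_gff3"], paths["cds_fasta"])

    paths["cohort_tsv"] = outdir / "cohort.tsv"
    write_cohort_tsv(observations, paths["cohort_tsv"])

    snapshot_paths = {}
    for snap in snapshots:
        fname = outdir / f"snapshot_{snap.name.replace('/', '_')}.tsv"
        with open(fname, "w") as handle:
            handle.write(f"# snapshot {snap.name}: {len(snap.keys)} variant keys\n")
            for key in sorted(snap.keys):
                handle.write(key + "\n")
        snapshot_paths[snap.name] = fname
        paths[f"snapshot_{snap.name}"] = fname

    paths["evidence_tsv"] = outdir / "evidence.tsv"
    write_evidence_tsv(
        [r for r in records.values() if r is not None], paths["evidence_tsv"]
    )

    paths["truth_variants"] = outdir / "truth_variants.tsv"
    truth.to_csv(paths["truth_variants"], sep="\t", index=False)
    paths["truth_tiers"] = outdir / "truth_tiers.tsv"
    pd.DataFrame(
        sorted(planted.items()), columns=["variant", "planted_tier"]
    ).to_csv(paths["truth_tiers"], sep="\t", index=False)

    paths["config_json"] = outdir / "config.json"
    config = {
        "transcript_gff3": str(paths["transcript_gff3"]),
        "cds_fasta": str(paths["cds_fasta"]),
        "cohort_tsv": str(paths["cohort_tsv"]),
        "snapshots": {name: str(p) for name, p in snapshot_paths.items()},
        "evidence_tsv": str(paths["evidence_tsv"]),
        "splice_halfwidth": 2,
        "deep_intronic_threshold": 20,
        "common_threshold": 0.01,
    }
    paths["config_json"].write_text(json.dumps(config, indent=2) + "\n")
    return paths
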