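"""End-to-end pipeline: parse, annotate, cross-reference, summarize, classify.

``run_pipeline`` reads a transcript model, a cohort TSV, database-snapshot
TSVs and a per-variant evidence TSV, then writes the three summary tables
(ethnic-stratified counts, database cross-reference, functional classes),
the per-variant annotation and clinical-call tables, a rejects report and a
run log. All outputs are plain TSV with fixed headers and two-decimal
half-up percentages; a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import clinical_classifier as cc
from . import cohort_stats as cs
from .consequence import ConsequenceSet, annotate, annotations_frame, tally_classes
from .database_xref import XrefSummary, cross_reference, load_snapshot
from .errors import PipelineError, VarcohortError
from .gene_model import (
    INTRONIC,
    SPLICE_SITE,
    TranscriptModel,
    classify_region,
    is_deep_intronic,
    load_transcript,
)
from .hgvs import parse_c


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    transcript_gff3: str | Path
    cds_fasta: str | Path
    cohort_tsv: str | Path
    snapshots: dict[str, str | Path]
    evidence_tsv: str | Path | None
    outdir: str | Path
    splice_halfwidth: int = 2
    deep_intronic_threshold: int = 20
    common_threshold: float = 0.01
    exonic_splice_bases: int = 0

    def __post_init__(self) -> None:
        if self.splice_halfwidth < 1 or self.deep_intronic_threshold < 1:
            raise VarcohortError("thresholds must be positive")
        if self.common_threshold <= 0:
            raise VarcohortError("common_threshold must be positive")

    @classmethod
    def from_json(cls, path: str | Path, outdir: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(
            transcript_gff3=data["transcript_gff3"],
            cds_fasta=data["cds_fasta"],
            cohort_tsv=data["cohort_tsv"],
            snapshots=dict(data["snapshots"]),
            evidence_tsv=data.get("evidence_tsv"),
            outdir=outdir,
            splice_halfwidth=data.get("splice_halfwidth", 2),
            deep_intronic_threshold=data.get("deep_intronic_threshold", 20),
            common_threshold=data.get("common_threshold", 0.01),
            exonic_splice_bases=data.get("exonic_splice_bases", 0),
        )


@dataclass
class RunReport:
    """In-memory results of a pipeline run plus the paths written."""

    model: TranscriptModel
    n_observations: int
    n_patients: int
    distinct_variants: tuple[str, ...]
    consequences: dict[str, ConsequenceSet]
    xref: XrefSummary
    ethnicity: cs.EthnicitySummary
    class_tally: object
    tier_tally: object
    calls: dict[str, cc.ClinicalCall]
    outputs: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage; any validation failure aborts naming the stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = ["# varcohort run log"]
    log.append("## config")
    for key, value in vars(config).items():
        log.append(f"{key} = {value}")

    # stage: transcript
    try:
        model = load_transcript(config.transcript_gff3, config.cds_fasta)
    except VarcohortError as exc:
        raise PipelineError("transcript", str(exc)) from exc
    log.append("## transcript")
    log.append(
        f"gene={model.gene_symbol} exons={model.n_exons} cds_length={model.cds_length}"
    )

    # stage: cohort
    try:
        observations = cs.read_cohort_tsv(config.cohort_tsv)
    except VarcohortError as exc:
        raise PipelineError("cohort", str(exc)) from exc
    if not observations:
        raise PipelineError("cohort", f"{config.cohort_tsv} contains no observations")
    distinct = tuple(sorted({o.variant_key for o in observations}))
    n_patients = len({o.patient_id for o in observations})
    log.append("## cohort")
    log.append(
        f"observations={len(observations)} patients={n_patients} "
        f"distinct_variants={len(distinct)}"
    )

    # stage: annotate
    consequences: dict[str, ConsequenceSet] = {}
    deep: dict[str, bool] = {}
    failures = []
    for key in distinct:
        try:
            d = parse_c(key)
            region = classify_region(d, model, splice_halfwidth=config.splice_halfwidth)
            consequences[key] = annotate(
                d,
                model,
                splice_halfwidth=config.splice_halfwidth,
                exonic_splice_bases=config.exonic_splice_bases,
            )
            deep[key] = region.label in (INTRONIC, SPLICE_SITE) and is_deep_intronic(
                region, threshold=config.deep_intronic_threshold
            )
        except VarcohortError as exc:
            failures.append(f"{key}: {exc}")
    if failures:
        raise PipelineError(
            "annotate", f"{len(failures)} variants failed annotation", records=failures
        )
    log.append("## annotate")
    log.append(f"annotated={len(consequences)}")

    # stage: xref
    rejects_rows = []
    snapshots = []
    for name in sorted(config.snapshots):
        try:
            result = load_snapshot(config.snapshots[name], name)
        except VarcohortError as exc:
            raise PipelineError("xref", f"snapshot {name}: {exc}") from exc
        snapshots.append(result.snapshot)
        for lineno, line, reason in result.rejects:
            rejects_rows.append(
                {"source": name, "line_number": lineno, "line": line, "reason": reason}
            )
        for key in result.duplicates:
            rejects_rows.append(
                {"source": name, "line_number": "", "line": key,
                 "reason": "duplicate entry (set semantics applied)"}
            )
    try:
        xref = cross_reference(distinct, snapshots)
    except VarcohortError as exc:
        raise PipelineError("xref", str(exc)) from exc
    log.append("## xref")
    for name, count in xref.per_database:
        log.append(f"{name}: present={count} absent={xref.total - count}")
    log.append(
        f"union_present={xref.union_present_count} novel={xref.novel_count}"
    )

    # stage: summarize
    try:
        ethnicity = cs.ethnic_summary(observations, novel_keys=xref.novel_keys)
    except VarcohortError as exc:
        raise PipelineError("summarize", str(exc)) from exc
    log.append("## summarize")
    for row in ethnicity.rows:
        log.append(
            f"{row['ethnicity']}: patients={row['n_patients']} "
            f"snvs={row['total_snvs']}"
        )

    # stage: classify
    try:
        records = (
            cc.read_evidence_tsv(config.evidence_tsv)
            if config.evidence_tsv is not None
            else {}
        )
        bundles = {
            key: cc.bundle_from_record(records.get(key), consequences[key], deep[key])
            for key in distinct
        }
        calls = cc.classify_cohort(bundles, common_threshold=config.common_threshold)
    except VarcohortError as exc:
        raise PipelineError("classify", str(exc)) from exc
    tier_tally = cc.tally_tiers(calls.values())
    class_tally = tally_classes([consequences[k] for k in distinct])
    log.append("## classify")
    for tier, count in tier_tally.counts:
        log.append(f"{tier}: {count}")

    # stage: report
    outputs: dict[str, Path] = {}

    table1 = ethnicity.to_frame()
    outputs["table1"] = outdir / "table1.tsv"
    table1.to_csv(outputs["table1"], sep="\t", index=False)

    outputs["table2"] = outdir / "table2.tsv"
    xref.to_frame().to_csv(outputs["table2"], sep="\t", index=False)

    table3 = class_tally.to_frame()
    table3.loc[len(table3)] = ["Total (distinct variants)", class_tally.total]
    outputs["table3"] = outdir / "table3.tsv"
    table3.to_csv(outputs["table3"], sep="\t", index=False)

    outputs["annotations"] = outdir / "annotations.tsv"
    annotations_frame(
        [(key, consequences[key]) for key in distinct]
    ).to_csv(outputs["annotations"], sep="\t", index=False)

    outputs["calls"] = outdir / "calls.tsv"
    pd.DataFrame(
        [
            {
                "variant": key,
                "tier": calls[key].tier,
                "rule_trace": "|".join(calls[key].rule_trace),
            }
            for key in distinct
        ],
        columns=["variant", "tier", "rule_trace"],
    ).to_csv(outputs["calls"], sep="\t", index=False)

    outputs["tiers"] = outdir / "tiers.tsv"
    tier_tally.to_frame().to_csv(outputs["tiers"], sep="\t", index=False)

    outputs["rejects"] = outdir / "rejects.tsv"
    pd.DataFrame(
        rejects_rows, columns=["source", "line_number", "line", "reason"]
    ).to_csv(outputs["rejects"], sep="\t", index=False)

    outputs["run_log"] = outdir / "run_log.txt"
    outputs["run_log"].write_text("\n".join(log) + "\n")

    return RunReport(
        model=model,
        n_observations=len(observations),
        n_patients=n_patients,
        distinct_variants=distinct,
        consequences=consequences,
        xref=xref,
        ethnicity=ethnicity,
        class_tally=class_tally,
        tier_tally=tier_tally,
        calls=calls,
        outputs=outputs,
    )
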