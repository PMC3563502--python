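"""Rule engine: tier assignment, trace replay, monotonicity, tallies."""

import numpy as np
import pytest

from varcohort.clinical_classifier import (
    BENIGN,
    PATHOGENIC,
    SUSPECTED_BENIGN,
    SUSPECTED_PATHOGENIC,
    TIER_RANK,
    UNKNOWN_SIGNIFICANCE,
    UNRECORDED,
    ClinicalCall,
    DatabaseAssertion,
    EvidenceBundle,
    classify,
    classify_cohort,
    read_evidence_tsv,
    replay_trace,
    tally_tiers,
    write_evidence_tsv,
    EvidenceRecord,
    LIT_PATHOGENIC,
)
from varcohort.consequence import MISSENSE, NONSENSE, SYNONYMOUS, ConsequenceSet
from varcohort.errors import ValidationError
from varcohort.gene_model import INTRONIC

_MISSENSE = ConsequenceSet(frozenset({MISSENSE}), ("K", 10, "R"))
_NONSENSE = ConsequenceSet(frozenset({NONSENSE}), ("K", 10, "*"))
_SYN = ConsequenceSet(frozenset({SYNONYMOUS}), ("K", 10, "K"))
_INTRON = ConsequenceSet(frozenset({INTRONIC}))


def test_deep_intronic_without_evidence_is_suspected_benign():
    call = classify(EvidenceBundle(consequence=_INTRON, deep_intronic=True))
    assert call.tier == SUSPECTED_BENIGN


def test_literature_pathogenic_assertion_dominates():
    call = classify(
        EvidenceBundle(consequence=_NONSENSE, literature_status=LIT_PATHOGENIC)
    )
    assert call.tier == PATHOGENIC


def test_rare_missense_with_neutral_insilico_is_vus():
    call = classify(
        EvidenceBundle(
            consequence=_MISSENSE,
            insilico=(("SIFT", "damaging"), ("PolyPhen2", "tolerated")),
        )
    )
    assert call.tier == UNKNOWN_SIGNIFICANCE


def test_common_synonymous_is_benign():
    call = classify(EvidenceBundle(consequence=_SYN, population_frequency=0.30))
    assert call.tier == BENIGN


def test_rare_synonymous_is_suspected_benign():
    assert classify(EvidenceBundle(consequence=_SYN)).tier == SUSPECTED_BENIGN
    assert (
        classify(EvidenceBundle(consequence=_SYN, population_frequency=0.001)).tier
        == SUSPECTED_BENIGN
    )


def test_common_threshold_boundary():
    benign = classify(EvidenceBundle(consequence=_MISSENSE, population_frequency=0.01))
    rare = classify(EvidenceBundle(consequence=_MISSENSE, population_frequency=0.0099))
    assert benign.tier == BENIGN
    assert rare.tier == UNKNOWN_SIGNIFICANCE


def test_insilico_consensus_never_reaches_terminal_tiers():
    """Unanimous predictors reach only the suspected tiers, never pathogenic/benign."""
    damaging = classify(
        EvidenceBundle(
            consequence=_MISSENSE,
            insilico=(("SIFT", "damaging"), ("PolyPhen2", "damaging")),
        )
    )
    tolerated = classify(
        EvidenceBundle(
            consequence=_MISSENSE,
            insilico=(("SIFT", "tolerated"), ("PolyPhen2", "tolerated")),
        )
    )
    assert damaging.tier == SUSPECTED_PATHOGENIC
    assert tolerated.tier == SUSPECTED_BENIGN
    single = classify(EvidenceBundle(consequence=_MISSENSE, insilico=(("SIFT", "damaging"),)))
    assert single.tier == UNKNOWN_SIGNIFICANCE  # one predictor is no consensus


def test_likely_assertions_map_to_suspected_tiers():
    likely_path = classify(
        EvidenceBundle(
            consequence=_SYN,
            db_assertions=(DatabaseAssertion("HGMD", True, "likely_pathogenic"),),
        )
    )
    assert likely_path.tier == SUSPECTED_PATHOGENIC  # beats the synonymous heuristic
    likely_benign = classify(
        EvidenceBundle(
            consequence=_MISSENSE,
            db_assertions=(DatabaseAssertion("dbSNP132", True, "likely_benign"),),
        )
    )
    assert likely_benign.tier == SUSPECTED_BENIGN


def test_malformed_frequency_rejected():
    with pytest.raises(ValidationError):
        EvidenceBundle(consequence=_MISSENSE, population_frequency=1.5)


def _random_bundles(n=300, seed=23):
    rng = np.random.default_rng(seed)
    consequences = [_MISSENSE, _NONSENSE, _SYN, _INTRON]
    preds = ["damaging", "tolerated", "neutral"]
    bundles = []
    for _ in range(n):
        cset = consequences[rng.integers(len(consequences))]
        assertions = []
        if rng.random() < 0.3:
            level = ["pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign"][
                rng.integers(5)
            ]
            assertions.append(DatabaseAssertion("HGMD", True, level))
        freq = None if rng.random() < 0.5 else float(rng.uniform(0, 0.2))
        insilico = tuple(
            ("tool" + str(i), preds[rng.integers(3)]) for i in range(rng.integers(3))
        )
        bundles.append(
            EvidenceBundle(
                consequence=cset,
                deep_intronic=bool(cset is _INTRON and rng.random() < 0.5),
                db_assertions=tuple(assertions),
                population_frequency=freq,
                insilico=insilico,
            )
        )
    return bundles


def test_classification_is_deterministic_and_replayable():
    for bundle in _random_bundles():
        call1 = classify(bundle)
        call2 = classify(bundle)
        assert call1 == call2
        assert replay_trace(call1.rule_trace) == call1.tier
        assert call1.rule_trace  # every evaluation is recorded


def test_adding_pathogenic_assertion_never_moves_toward_benign():
    for bundle in _random_bundles(n=200, seed=31):
        before = TIER_RANK[classify(bundle).tier]
        stronger = EvidenceBundle(
            consequence=bundle.consequence,
            deep_intronic=bundle.deep_intronic,
            db_assertions=bundle.db_assertions
            + (DatabaseAssertion("HGMD", True, "pathogenic"),),
            literature_status=bundle.literature_status,
            population_frequency=bundle.population_frequency,
            insilico=bundle.insilico,
        )
        assert TIER_RANK[classify(stronger).tier] >= before


def test_raising_frequency_never_moves_toward_pathogenic():
    for bundle in _random_bundles(n=200, seed=37):
        before = TIER_RANK[classify(bundle).tier]
        base = bundle.population_frequency or 0.0
        commoner = EvidenceBundle(
            consequence=bundle.consequence,
            deep_intronic=bundle.deep_intronic,
            db_assertions=bundle.db_assertions,
            literature_status=bundle.literature_status,
            population_frequency=min(1.0, base + 0.05),
            insilico=bundle.insilico,
        )
        assert TIER_RANK[classify(commoner).tier] <= before


def test_tally_tiers_sums_to_number_of_calls():
    bundles = _random_bundles(n=184, seed=41)
    calls = [classify(b) for b in bundles]
    tally = tally_tiers(calls)
    assert tally.total == 184
    assert sum(tally.as_dict().values()) == 184
    assert tally_tiers([]).total == 0
    assert all(v == 0 for v in tally_tiers([]).as_dict().values())


def test_planted_novel_variant_tier_mix_recovered():
    """A 21-call mix of 8 benign / 3 suspected benign / 4 pathogenic / 6 VUS tallies exactly."""
    calls = (
        [ClinicalCall(BENIGN, ("assign:benign",))] * 8
        + [ClinicalCall(SUSPECTED_BENIGN, ("assign:suspected_benign",))] * 3
        + [ClinicalCall(PATHOGENIC, ("assign:pathogenic",))] * 4
        + [ClinicalCall(UNKNOWN_SIGNIFICANCE, ("assign:unknown_significance",))] * 6
    )
    counts = tally_tiers(calls).as_dict()
    assert (
        counts[BENIGN],
        counts[SUSPECTED_BENIGN],
        counts[PATHOGENIC],
        counts[UNKNOWN_SIGNIFICANCE],
    ) == (8, 3, 4, 6)
    assert tally_tiers(calls).total == 21


def test_missing_evidence_yields_unrecorded():
    calls = classify_cohort({"c.1A>G": None})
    assert calls["c.1A>G"].tier == UNRECORDED
    assert calls["c.1A>G"].rule_trace == ()


def test_unrecorded_requires_empty_trace_and_vice_versa():
    with pytest.raises(ValidationError):
        ClinicalCall(BENIGN, ())


def test_evidence_tsv_round_trip(tmp_path):
    records = [
        EvidenceRecord(
            "c.1408A>G",
            db_assertions=(DatabaseAssertion("HGMD", True, "pathogenic"),),
            population_frequency=0.43,
        ),
        EvidenceRecord(
            "c.869+11C>T",
            literature_status=LIT_PATHOGENIC,
            insilico=(("SIFT", "damaging"), ("PolyPhen2", "damaging")),
        ),
    ]
    path = tmp_path / "evidence.tsv"
    write_evidence_tsv(records, path)
    loaded = read_evidence_tsv(path)
    assert set(loaded) == {"c.1408A>G", "c.869+11C>T"}
    assert loaded["c.1408A>G"].population_frequency == 0.43
    assert loaded["c.1408A>G"].db_assertions[0].classification == "pathogenic"
    assert loaded["c.869+11C>T"].insilico == (
        ("SIFT", "damaging"), ("PolyPhen2", "damaging")
    )
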