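"""Determinism and planted structure of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from varcohort.database_xref import cross_reference
from varcohort.errors import ParameterError
from varcohort.synthetic_data import (
    CohortSpec,
    SnapshotSpec,
    gen_cohort,
    gen_evidence,
    gen_snapshots,
    gen_transcript,
    write_fixtures,
)


def test_default_transcript_shape():
    model = gen_transcript(1)
    assert model.n_exons == 27
    assert model.n_introns == 26
    assert model.cds_length == 4443  # 1480 codons + stop
    assert model.coding_sequence.startswith("ATG")


def test_transcript_generation_is_deterministic():
    assert gen_transcript(1) == gen_transcript(1)
    assert gen_transcript(1) != gen_transcript(2)


def test_transcript_infeasible_parameters():
    with pytest.raises(ParameterError):
        gen_transcript(1, n_exons=0)
    with pytest.raises(ParameterError):
        gen_transcript(1, n_exons=50, n_codons=10)  # CDS too short for 50 exons


def test_single_exon_model_rejects_intron_dependent_class_mix():
    model = gen_transcript(2, n_exons=1, n_codons=100)
    spec = CohortSpec(seed=3, n_patients=10, n_distinct_variants=10,
                      singleton_fraction=0.5, common_variant_counts=(),
                      class_mix=(("missense", 5), ("intronic", 5)))
    with pytest.raises(ParameterError):
        gen_cohort(spec, model)


def test_default_cohort_plants_headline_counts(fixture_paths):
    truth = pd.read_csv(fixture_paths["truth_variants"], sep="\t")
    assert len(truth) == 184
    assert truth.is_singleton.sum() == 107
    assert sorted(truth.loc[truth.is_common, "n_obs"]) == [236, 427, 728, 955]
    assert (truth.n_obs >= 10).sum() == 16
    # observation counts in the file equal the recorded ground truth
    cohort = pd.read_csv(fixture_paths["cohort_tsv"], sep="\t")
    counts = (
        cohort.assign(n=np.where(cohort.zygosity == "hom", 2, 1))
        .groupby("variant")["n"].sum()
    )
    for key, n_obs in zip(truth.variant, truth.n_obs):
        assert counts[key] == n_obs


def test_cohort_generation_is_deterministic():
    model = gen_transcript(7, n_exons=5, n_codons=120)
    spec = CohortSpec(seed=9, n_patients=40, n_distinct_variants=20,
                      singleton_fraction=0.5, common_variant_counts=(30, 20),
                      n_high_count=2,
                      class_mix=(("missense", 8), ("synonymous", 4),
                                 ("intronic", 4), ("splice_site", 2),
                                 ("nonsense", 1), ("promoter", 1)))
    obs1, truth1 = gen_cohort(spec, model)
    obs2, truth2 = gen_cohort(spec, model)
    assert obs1 == obs2
    assert truth1.equals(truth2)


def test_single_patient_cohort_is_all_single_patient():
    model = gen_transcript(7, n_exons=5, n_codons=120)
    spec = CohortSpec(seed=9, n_patients=1, n_distinct_variants=5,
                      singleton_fraction=1.0, common_variant_counts=(),
                      class_mix=(("missense", 3), ("synonymous", 2)))
    obs, truth = gen_cohort(spec, model)
    assert len({o.patient_id for o in obs}) == 1
    assert (truth.n_carriers == 1).all()


def test_infeasible_common_counts_rejected():
    model = gen_transcript(7, n_exons=5, n_codons=120)
    spec = CohortSpec(seed=9, n_patients=10, n_distinct_variants=5,
                      singleton_fraction=0.0, common_variant_counts=(25,),
                      class_mix=(("missense", 5),))
    with pytest.raises(ParameterError):
        gen_cohort(spec, model)  # 25 observations > 2 x 10 alleles


def test_snapshots_plant_exact_novel_count(fixture_paths):
    truth = pd.read_csv(fixture_paths["truth_variants"], sep="\t")
    keys = sorted(truth.variant)
    snaps = gen_snapshots(SnapshotSpec(seed=5), keys)
    summary = cross_reference(keys, snaps)
    assert summary.novel_count == 21
    assert summary.union_present_count == 163


def test_snapshot_inclusion_probability_one_means_no_novel():
    keys = [f"c.{i}A>G" for i in range(1, 51)]
    spec = SnapshotSpec(
        seed=1,
        inclusion_probabilities=(("db", 1.0),),
        forced_novel_count=0,
        total_entries=(("db", 0),),
    )
    snaps = gen_snapshots(spec, keys)
    assert cross_reference(keys, snaps).novel_count == 0


def test_snapshot_coverage_matches_conditional_inclusion_rates():
    """Non-novel coverage across seeds stays within 3 SE of the conditional rates.

    Membership vectors are drawn conditional on >=1 database, so the
    per-database rate is p / (1 - prod(1-p)) rather than the raw p.
    """
    keys = [f"c.{i}A>G" for i in range(1, 201)]
    probs = {"CFMDB": 0.85, "HGMD": 0.64, "dbSNP132": 0.40}
    miss_all = np.prod([1 - p for p in probs.values()])
    spec_kwargs = dict(
        inclusion_probabilities=tuple(probs.items()),
        forced_novel_count=20,
        total_entries=(("CFMDB", 0), ("HGMD", 0), ("dbSNP132", 0)),
    )
    n_seeds, n_eligible = 40, 180
    hits = {name: 0 for name in probs}
    for seed in range(n_seeds):
        snaps = gen_snapshots(SnapshotSpec(seed=seed, **spec_kwargs), keys)
        for snap in snaps:
            hits[snap.name] += len(snap.keys)
    for name, p in probs.items():
        expected = p / (1 - miss_all)
        rate = hits[name] / (n_seeds * n_eligible)
        se = np.sqrt(expected * (1 - expected) / (n_seeds * n_eligible))
        assert abs(rate - expected) < 3 * se, (name, rate, expected)


def test_forced_novel_exceeding_keys_rejected():
    with pytest.raises(ParameterError):
        gen_snapshots(SnapshotSpec(seed=1, forced_novel_count=5), ["c.1A>G"])


def test_evidence_tier_mix_infeasible_when_no_quiet_variants():
    model = gen_transcript(7, n_exons=5, n_codons=120)
    spec = CohortSpec(seed=9, n_patients=20, n_distinct_variants=6,
                      singleton_fraction=0.5, common_variant_counts=(),
                      class_mix=(("missense", 6),))
    _, truth = gen_cohort(spec, model)
    snaps = gen_snapshots(
        SnapshotSpec(seed=2, forced_novel_count=1,
                     total_entries=(("CFMDB", 0), ("HGMD", 0), ("dbSNP132", 0))),
        sorted(truth.variant),
    )
    with pytest.raises(ParameterError):
        gen_evidence(3, truth, snaps,
                     tier_mix={"suspected_benign": 6, "pathogenic": 0,
                               "suspected_pathogenic": 0, "benign": 0,
                               "unknown_significance": 0, "unrecorded": 0})


def test_fixture_files_byte_identical_across_runs(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    write_fixtures(a, seed=13, n_exons=6, n_codons=150,
                   cohort_spec=CohortSpec(
                       seed=14, n_patients=40, n_distinct_variants=20,
                       singleton_fraction=0.5, common_variant_counts=(30, 20),
                       n_high_count=2,
                       class_mix=(("missense", 8), ("synonymous", 4),
                                  ("intronic", 4), ("splice_site", 2),
                                  ("nonsense", 1), ("promoter", 1))),
                   snapshot_spec=SnapshotSpec(
                       seed=15, forced_novel_count=3,
                       total_entries=(("CFMDB", 30), ("HGMD", 25),
                                      ("dbSNP132", 20))))
    write_fixtures(b, seed=13, n_exons=6, n_codons=150,
                   cohort_spec=CohortSpec(
                       seed=14, n_patients=40, n_distinct_variants=20,
                       singleton_fraction=0.5, common_variant_counts=(30, 20),
                       n_high_count=2,
                       class_mix=(("missense", 8), ("synonymous", 4),
                                  ("intronic", 4), ("splice_site", 2),
                                  ("nonsense", 1), ("promoter", 1))),
                   snapshot_spec=SnapshotSpec(
                       seed=15, forced_novel_count=3,
                       total_entries=(("CFMDB", 30), ("HGMD", 25),
                                      ("dbSNP132", 20))))
    # config.json embeds absolute paths; compare everything else byte for byte
    for path_a in sorted(a.rglob("*.tsv")) + sorted(a.rglob("*.gff3")) + sorted(a.rglob("*.fasta")):
        path_b = b / path_a.name
        assert path_a.read_bytes() == path_b.read_bytes(), path_a.name
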