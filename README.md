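# varcohort

Referral-laboratory analysis of single-nucleotide variants (SNVs) observed by
full-gene diagnostic sequencing — built around the kind of dataset a
high-volume *CFTR* sequencing assay accumulates: hundreds of patients from
very unequal self-reported ethnicity groups, a rare-variant-enriched allele
spectrum in which most variants are seen exactly once, and a handful of
common polymorphisms observed hundreds of times.

`varcohort` provides, as a library plus a thin CLI:

- **HGVS c.-notation parsing** for single-nucleotide substitutions
  (`c.1408A>G`, `c.869+11C>T`, `c.-10G>A`), with a canonical string form used
  as the join key for every set operation;
- **a transcript coordinate model** (exon intervals, CDS, coding sequence)
  with the coordinate algebra on top: codon number and phase of a coding
  position (codon = ⌊(pos−1)/3⌋+1, phase = ((pos−1) mod 3)+1), region
  labelling (promoter / splice site / intronic / exonic), and the
  deep-intronic test (> 20 bp into the intron, strict);
- **consequence annotation**: exonic substitutions are translated codon-wise
  with the standard genetic code into missense / nonsense / synonymous calls
  with p.-style protein changes;
- **database cross-referencing** against named snapshot files (a dbSNP-like
  build, a locus-specific database, a disease-mutation database); a variant
  absent from every snapshot is *novel*;
- **ethnic-stratified cohort summaries**: per-group patient counts, distinct
  SNVs, ethnic-specific SNVs (seen in exactly one group cohort-wide) and
  novel-and-ethnic-specific SNVs, with homozygous carriers counted as two
  observations;
- **a rule-based clinical classifier** into pathogenic / suspected
  pathogenic / unknown significance / suspected benign / benign (+
  unrecorded), following pre-ACMG laboratory practice: assertions first,
  then population frequency, then the common/synonymous/deep-intronic
  heuristic, with in-silico predictors only ever nudging between the
  suspected tiers;
- **seeded synthetic-data generators** that produce transcript, cohort,
  snapshot and evidence fixtures with recorded ground truth for every
  planted quantity.

## Worked example

Generate the default synthetic dataset (27-exon / 1480-codon transcript,
555 patients, 184 distinct SNVs of which 107 singletons and 4 common
polymorphisms observed 955/728/427/236 times) and run the pipeline:

```bash
varcohort fixtures --seed 7 --outdir demo/fixtures
varcohort run-all --config demo/fixtures/config.json --outdir demo/out
# ok: 184 distinct variants, 21 novel; outputs in demo/out
cat demo/out/table2.tsv
```

```
database	in_database	in_database_pct	not_in_database	not_in_database_pct
CFMDB	147	79.89	37	20.11
HGMD	107	58.15	77	41.85
dbSNP132	75	40.76	109	59.24
Total	163	88.59	21	11.41
```

The total row is exact by construction for any seed: the snapshot generator
withholds exactly 21 of the 184 keys from every database and guarantees the
other 163 appear in at least one, so 163/184 = 88.59% are known and
21/184 = 11.41% are novel. The per-database rows are stochastic (drawn with
inclusion probabilities 0.85 / 0.64 / 0.40). The other outputs are
`table1.tsv` (ethnic-stratified summary; the Other/Mixed group's
ethnic-specific cell is `N/A` by convention), `table3.tsv` (functional-class
tally), `annotations.tsv`, `calls.tsv` (with an auditable rule trace per
variant), `tiers.tsv`, `rejects.tsv` and a run log. Re-running with the same
inputs reproduces every table byte for byte.

Single variants can be annotated directly:

```bash
varcohort annotate --transcript demo/fixtures/transcript.gff3 \
    --cds demo/fixtures/cds.fasta --variant "c.1408A>G" --variant "c.869+11C>T"
# c.1408A>G	missense	p.R470G
# c.869+11C>T	intronic
```

Coding position 1408 lands in codon 470, as in the familiar p.M470V
annotation of the real gene; the amino acids differ here because the
synthetic coding sequence is random.

## Layout

```
src/varcohort/
  hgvs.py                 c. substitution grammar and canonical keys
  gene_model.py           transcript model, codon/region algebra, GFF3+FASTA I/O
  consequence.py          functional-class annotation and tallies
  database_xref.py        snapshot loading, cross-referencing, novelty
  cohort_stats.py         observation counts, ethnic-stratified summaries
  clinical_classifier.py  five-tier rule engine with rule traces
  synthetic_data.py       seeded fixture generators with ground truth
  report.py, cli.py       pipeline orchestration and the varcohort CLI
```

See `docs/methods.md` for the modelling choices, defaults and limitations.
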