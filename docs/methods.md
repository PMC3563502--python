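# Methods

## Coordinate model

All annotation is phrased in HGVS coding-DNA (c.) coordinates against a
single transcript: c.1 is the A of the initiator ATG, intronic positions are
anchored at the nearest exonic base with a signed offset (`c.869+11` is 11
bases into the intron after the exonic base at c.869), and positions 5' of
the start codon are written `c.-N`. No genomic liftover is implemented; the
transcript's exon intervals live on a synthetic plus-strand axis and are
used only for geometry (boundary distances, splice windows) and for the
GFF3 representation. Codon arithmetic is exact integer arithmetic:
codon = ⌊(pos−1)/3⌋+1, phase = ((pos−1) mod 3)+1, a bijection between coding
positions and (codon, phase) pairs.

Scope is deliberately restricted to single-nucleotide substitutions: every
tabulated quantity the package computes (class tallies, database presence,
ethnic summaries, tier counts) concerns SNVs, and the canonical substitution
string is the join key everywhere. Indels, duplications and protein-level
notation are out of scope.

## Region vocabulary

- **promoter** — any position upstream of the translational start site,
  regardless of distance; no 5'UTR/promoter distinction is made.
- **splice site** — the intronic bases within `splice_halfwidth` (default 2)
  of an exon/intron boundary: donor +1/+2 and acceptor −1/−2, the canonical
  GT/AG dinucleotides. "The positions flanking a boundary" could also be
  read as two intronic plus two exonic bases; we default to the
  intronic-only reading and expose `exonic_splice_bases` (default 0) to
  enable the exonic extension, which is also the only route to dual-class
  assignments such as missense+splice-site. Transcript ends are not splice
  boundaries.
- **intronic** — intron offsets beyond the splice window. **Deep intronic**
  means strictly more than `deep_intronic_threshold` (default 20) bases into
  the intron; the strict inequality matters at exactly 20.
- **exonic** — offset-zero positions inside the CDS; their coding effect
  (missense / nonsense / synonymous) comes from single-codon substitution
  under the standard nuclear genetic code. Stop-loss and start-loss collapse
  into missense; the six classes above are exhaustive for this data model.
  A reference allele that contradicts the coding sequence raises an error
  rather than re-anchoring, because cohort files are trusted laboratory
  output.

## Cross-referencing and novelty

Database snapshots are local files — named sets of canonical keys frozen at
a download date. Matching is exact string equality on the canonical form;
no allele flipping, position fuzzing or rsID mapping. A variant is novel iff
it is absent from every provided snapshot. Percentages in all tables are
rounded half-up to two decimals (19/36 → 52.78%), computed on exact
rationals before rounding.

## Ethnic-stratified summaries

The closed ethnicity set is the eight reporting groups
(African American, Ashkenazi Jewish, Asian/Oriental, Caucasian, Hispanic,
Middle Eastern, Native American, Other/Mixed); Mediterranean or
multi-category self-reports belong in Other/Mixed. A variant is
ethnic-specific when its full-cohort support is exactly one group.
Other/Mixed never receives an ethnic-specific count (its cell is `N/A`):
a mixed-ancestry group has no coherent exclusivity interpretation. Two
further conventions, both configurable or explicit in the API:

- by default a variant seen in one named group *and* in Other/Mixed is not
  specific to the named group (`other_mixed_breaks_specificity=True`);
- the novel-and-exclusive tally *is* computed for Other/Mixed, since
  novelty does not depend on the exclusivity convention.

A homozygous carrier counts as two observations; zygosity affects only
observation counts, never distinct-variant counts.

## Clinical classification

The rule engine codifies stepwise pre-ACMG practice. Rules fire in order;
every evaluation is appended to an auditable trace ending in an
`assign:<tier>` entry, so a call can be replayed from its trace alone.

1. A pathogenic assertion from a database or the literature → pathogenic;
   a likely/limited assertion → suspected pathogenic.
2. A benign assertion → benign; likely benign → suspected benign.
3. Absent assertions: population frequency ≥ `common_threshold` → benign;
   synonymous or deep-intronic variants with unknown or sub-threshold
   frequency → suspected benign.
4. Otherwise unknown significance; a unanimous consensus of at least two
   in-silico predictors may nudge this — and only this — tier to the
   adjacent suspected tier. No call is ever based solely on predictors.

Two parameters are judgement calls made explicit: `common_threshold`
defaults to 1% (conventional carrier-screening practice; "common" has no
canonical definition) and assertion-precedence (rule 1/2 beats the
heuristics) is a fixed, documented order rather than an inferred weighting
of discordant sources. The `unrecorded` tier is reserved for variants with
no evidence record at all and is never produced by the rule engine itself.
Monotonicity holds by construction: adding a pathogenic assertion can only
move a call toward pathogenic, raising the frequency only toward benign.

## Synthetic data

The generators reproduce the statistical shape of a six-year single-gene
referral dataset; defaults are the study conditions, not tuning knobs:

- **transcript**: 27 exons, 1480 codons (CDS 4443 nt including the stop),
  exon sizes ≥ 30 bp by largest-remainder allocation of a Dirichlet draw,
  introns 80–2000 bp, 500 bp of upstream space. The sequence content is
  random non-stop codons — mutation-spectrum realism (Ti/Tv, CpG) is a
  non-goal.
- **cohort**: 555 patients allocated to the eight groups by largest
  remainder over weights proportional to 61/1/4/403/40/3/1/42; 184 distinct
  variants with a planted class mix (105 missense, 33 synonymous,
  28 intronic, 12 splice-site, 3 nonsense, 3 promoter — a single-label
  partition consistent with the missense majority); 107 singletons; four
  common polymorphisms planted with exact observation counts
  955/728/427/236 (one missense, two synonymous, one shallow-intronic, the
  archetypes of real common polymorphisms); 16 variants observed ≥10 times
  in total; homozygote fraction 5% of observations (forced higher where an
  observation count exceeds the patient count). Non-common variants draw
  their carriers preferentially (affinity 0.8) from a per-variant home
  group so ethnic-specific structure emerges; ground truth records the
  *realized* support set of every variant, so recovery checks are exact.
- **snapshots**: exactly `forced_novel_count` (default 21) keys withheld
  from every database; each remaining key's membership vector drawn with
  inclusion probabilities 0.85 / 0.64 / 0.40, conditioned on membership in
  at least one database. The conditioning makes the union identity
  (163 known / 21 novel of 184) exact for every seed at the cost of
  inflating each marginal coverage by a factor 1/(1−q), q = ∏(1−pᵢ) ≈ 0.032;
  the tests check coverage against the conditional rates. Snapshots are
  padded with random decoy keys to realistic gene-wide sizes
  (1383 / 1057 / 1430 entries).
- **evidence**: built backwards from a planted tier mix (defaults
  97 / 8 / 37 / 30 / 6 / 6 across the five tiers plus unrecorded, summing
  to 184) under rule-engine feasibility: suspected-benign targets go to
  synonymous or deep-intronic variants, unknown-significance targets avoid
  them, common polymorphisms are always benign, pathogenic assertions are
  attached to a database that actually contains the variant (literature
  otherwise). One known infeasibility is documented as a limitation below.

Every generator takes a mandatory seed, uses one private `numpy`
`default_rng` stream, and is byte-stable: the same seed yields identical
files. `write_fixtures` derives sub-seeds (seed+k mod 2³¹) for the four
generators.

## What passing tests do and do not show

The fixtures plant the headline counts (555 patients, 184 variants,
singleton and common counts, the tier mix), so end-to-end recovery verifies
the pipeline's *bookkeeping* — coordinate arithmetic, set operations,
exclusivity logic, rounding, rule evaluation — not any biological claim
about a real cohort. Quantities that depend on private patient data are
inputs here, never outputs. The synthetic cohort also simplifies real data
in known ways: no linkage between variants, no relatedness between
patients, random sequence content, and single-label consequence classes by
default.

## Numerical and degenerate-input choices

- Percent rounding: half-up on exact rationals (`Fraction` → `Decimal`),
  two decimals in tables, zero decimals only for the headline missense
  share.
- Ranking ties in `most_common_variants` break by canonical key order.
- Intronic genomic positions equidistant from both flanking exons anchor to
  the donor side.
- Empty cohort, empty variant set, duplicate snapshot names, unknown
  ethnicities, malformed frequencies and reference mismatches all raise
  typed errors naming the offending records; a snapshot file over 50%
  malformed is rejected outright, below that the bad lines go to a rejects
  report.
- Minus-strand or multi-transcript GFF3 input is rejected: the synthetic
  axis is always transcription-ordered.

## Known limitations

- The rule engine cannot assign plain benign or pathogenic to a variant
  with no assertions and unknown frequency; a laboratory's internal
  judgement on novel variants (e.g. calling a novel nonsense variant
  disease-causing) is therefore not reproducible by these rules, and the
  published-style novel-variant tier breakdown (8/3/4/6) is exercised only
  as a tally over constructed calls, not planted end-to-end.
- In-silico predictors are opaque categorical inputs; the scoring tools
  themselves (PolyPhen, SIFT, splice-strength models) are out of scope.
- Splice-strength, UTR and NMD annotation are not attempted; the six-class
  vocabulary is the whole model.
- The per-database coverage of generated snapshots is stochastic; only the
  union/novel split is exact by construction.
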