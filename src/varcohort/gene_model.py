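"""Transcript architecture and the c.-coordinate algebra built on it.

A :class:`TranscriptModel` holds the exon intervals of a single transcript
(1-based, closed, in transcription order on a plus-strand axis), the offset
of the initiator ATG within the concatenated exonic sequence, and the coding
sequence itself. Every annotation step in the package — codon lookup,
splice-region labelling, consequence calls — is phrased in HGVS c.
coordinates against this model; no genomic liftover is performed.

Region vocabulary follows clinical usage for this assay: *promoter* is any
position upstream of the translational start site, *splice site* covers the
intronic bases immediately flanking each exon/intron boundary (donor +1/+2,
acceptor -1/-2 by default), everything deeper is *intronic*, and positions
with a zero offset inside the CDS are *exonic*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .errors import (
    InvalidCoordinateError,
    OutOfRangeError,
    ValidationError,
    VarcohortError,
)
from .hgvs import VariantDescriptor

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

PROMOTER = "promoter"
SPLICE_SITE = "splice_site"
INTRONIC = "intronic"
EXONIC = "exonic"


@dataclass(frozen=True)
class RegionLabel:
    """Where a variant sits relative to the transcript architecture."""

    label: str
    intron_offset: int = 0
    upstream_offset: int = 0

    def __post_init__(self) -> None:
        if self.label not in (PROMOTER, SPLICE_SITE, INTRONIC, EXONIC):
            raise ValidationError(f"unknown region label {self.label!r}")
        if (self.intron_offset != 0) != (self.label in (SPLICE_SITE, INTRONIC)):
            raise ValidationError(
                f"intron_offset {self.intron_offset} inconsistent with label {self.label}"
            )
        if (self.upstream_offset > 0) != (self.label == PROMOTER):
            raise ValidationError(
                f"upstream_offset {self.upstream_offset} inconsistent with label {self.label}"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS architecture of one transcript plus its coding sequence.

    ``cds_start_exon_offset`` is the 1-based position of the A of the
    initiator ATG within the concatenation of the exonic sequence; 1 means
    the CDS starts at the first exonic base (no transcribed 5'UTR).
    """

    gene_symbol: str
    exons: tuple[tuple[int, int], ...]
    coding_sequence: str
    cds_start_exon_offset: int = 1

    def __post_init__(self) -> None:
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "coding_sequence", self.coding_sequence.upper())
        if len(exons) < 1:
            raise ValidationError("a transcript needs at least one exon")
        for start, end in exons:
            if start > end:
                raise ValidationError(f"exon ({start}, {end}) has start > end")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"exons ({s1},{e1}) and ({s2},{e2}) overlap or are unordered"
                )
        cds = self.coding_sequence
        if len(cds) == 0 or len(cds) % 3 != 0:
            raise ValidationError(f"coding sequence length {len(cds)} is not a multiple of 3")
        if set(cds) - {"A", "C", "G", "T"}:
            raise ValidationError("coding sequence contains non-ACGT characters")
        if not cds.startswith("ATG"):
            raise ValidationError("coding sequence must begin with the initiator ATG")
        if cds[-3:] not in STOP_CODONS:
            raise ValidationError("coding sequence must end with a stop codon")
        if self.cds_start_exon_offset < 1:
            raise ValidationError("cds_start_exon_offset must be >= 1")
        if self.cds_start_exon_offset - 1 + len(cds) > self.exonic_length:
            raise ValidationError(
                "CDS does not fit within the exonic sequence "
                f"({self.exonic_length} exonic bases, CDS needs "
                f"{self.cds_start_exon_offset - 1 + len(cds)})"
            )

    # -- simple size accessors -------------------------------------------------

    @property
    def cds_length(self) -> int:
        return len(self.coding_sequence)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    # -- coding-coordinate geometry -------------------------------------------

    def exon_coding_spans(self) -> list[tuple[int, int] | None]:
        """Coding-position interval covered by each exon (None if non-coding)."""
        spans: list[tuple[int, int] | None] = []
        exonic_pos = 0
        for start, end in self.exons:
            length = end - start + 1
            lo_exonic = exonic_pos + 1
            hi_exonic = exonic_pos + length
            lo_c = lo_exonic - (self.cds_start_exon_offset - 1)
            hi_c = hi_exonic - (self.cds_start_exon_offset - 1)
            lo_c = max(lo_c, 1)
            hi_c = min(hi_c, self.cds_length)
            spans.append((lo_c, hi_c) if lo_c <= hi_c else None)
            exonic_pos = hi_exonic
        return spans

    def exon_of_coding_pos(self, coding_pos: int) -> int:
        """Index (0-based, transcription order) of the exon holding a coding position."""
        if not 1 <= coding_pos <= self.cds_length:
            raise OutOfRangeError(
                f"coding position {coding_pos} outside CDS of length {self.cds_length}"
            )
        for i, span in enumerate(self.exon_coding_spans()):
            if span is not None and span[0] <= coding_pos <= span[1]:
                return i
        raise OutOfRangeError(f"coding position {coding_pos} not covered by any exon")

    def exonic_distance_to_boundary(self, coding_pos: int) -> float:
        """Bases from an exonic position to the nearest splice boundary (1 = boundary base).

        Transcript ends (start of first exon, end of last exon) are not splice
        boundaries; returns ``math.inf`` for a single-exon transcript.
        """
        i = self.exon_of_coding_pos(coding_pos)
        span = self.exon_coding_spans()[i]
        assert span is not None
        dist = math.inf
        if i > 0:
            dist = min(dist, coding_pos - span[0] + 1)
        if i < self.n_exons - 1:
            dist = min(dist, span[1] - coding_pos + 1)
        return dist

    def donor_anchor(self, intron_index: int) -> int:
        """Coding position of the last base of the exon preceding intron ``intron_index``."""
        span = self.exon_coding_spans()[intron_index]
        if span is None:
            raise OutOfRangeError(f"exon {intron_index} is non-coding; no donor anchor")
        return span[1]

    def acceptor_anchor(self, intron_index: int) -> int:
        """Coding position of the first base of the exon following intron ``intron_index``."""
        span = self.exon_coding_spans()[intron_index + 1]
        if span is None:
            raise OutOfRangeError(f"exon {intron_index + 1} is non-coding; no acceptor anchor")
        return span[0]

    # -- genomic bridge (used by the synthetic axis and oracle tests) ----------

    def genomic_to_c(self, gpos: int) -> tuple[int, int, bool]:
        """Map a genomic position on the transcript's axis to (anchor, offset, upstream).

        Returns ``(coding_pos, intron_offset, upstream)`` with HGVS anchoring:
        intronic positions anchor to the nearer exon end (ties to the donor
        side). Positions 3' of the stop codon are unsupported and raise.
        """
        first_start = self.exons[0][0]
        if gpos < first_start:
            up = (first_start - gpos) + (self.cds_start_exon_offset - 1)
            return up, 0, True
        exonic_before = 0
        for i, (start, end) in enumerate(self.exons):
            if start <= gpos <= end:
                exonic_index = exonic_before + (gpos - start + 1)
                coding = exonic_index - (self.cds_start_exon_offset - 1)
                if coding < 1:
                    return 1 - coding, 0, True
                if coding > self.cds_length:
                    raise OutOfRangeError(
                        f"genomic position {gpos} lies 3' of the stop codon"
                    )
                return coding, 0, False
            if i < self.n_exons - 1 and end < gpos < self.exons[i + 1][0]:
                dist_donor = gpos - end
                dist_acceptor = self.exons[i + 1][0] - gpos
                if dist_donor <= dist_acceptor:
                    return self.donor_anchor(i), dist_donor, False
                return self.acceptor_anchor(i), -dist_acceptor, False
            exonic_before += end - start + 1
        raise OutOfRangeError(f"genomic position {gpos} lies 3' of the transcript")


def codon_index(coding_pos: int) -> tuple[int, int]:
    """Codon number and within-codon phase (1..3) of a coding position.

    c.1..3 are codon 1; c.1408 is phase 1 of codon 470, hence the p.M470V-style
    protein numbering downstream.
    """
    if not isinstance(coding_pos, int) or isinstance(coding_pos, bool) or coding_pos < 1:
        raise InvalidCoordinateError(
            f"coding position must be a positive integer, got {coding_pos!r}"
        )
    return (coding_pos - 1) // 3 + 1, (coding_pos - 1) % 3 + 1


def classify_region(
    descriptor: VariantDescriptor,
    model: TranscriptModel,
    splice_halfwidth: int = 2,
) -> RegionLabel:
    """Label a variant's position as promoter / splice_site / intronic / exonic.

    Splice sites are the ``splice_halfwidth`` intronic bases on each side of
    every exon/intron boundary (default 2, the canonical GT/AG dinucleotides).
    """
    if descriptor.upstream:
        return RegionLabel(PROMOTER, upstream_offset=descriptor.coding_pos)
    if descriptor.coding_pos > model.cds_length:
        raise OutOfRangeError(
            f"anchor c.{descriptor.coding_pos} beyond CDS length {model.cds_length}"
        )
    offset = descriptor.intron_offset
    if offset != 0:
        label = SPLICE_SITE if abs(offset) <= splice_halfwidth else INTRONIC
        return RegionLabel(label, intron_offset=offset)
    return RegionLabel(EXONIC)


def is_deep_intronic(region: RegionLabel, threshold: int = 20) -> bool:
    """True when the position lies strictly more than ``threshold`` bases into the intron."""
    if region.label not in (INTRONIC, SPLICE_SITE):
        raise VarcohortError(
            f"deep-intronic test is undefined for {region.label} positions"
        )
    return abs(region.intron_offset) > threshold


# -- transcript I/O (GFF3-like + CDS FASTA) ------------------------------------


def load_transcript(gff3_path: str | Path, fasta_path: str | Path) -> TranscriptModel:
    """Read a transcript model from a GFF3 file (exon + CDS features) and a CDS FASTA.

    Only plus-strand, single-transcript files are supported; the CDS start
    offset is derived from the first CDS base's position within the exons.
    """
    import gffutils
    from Bio import SeqIO

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique", force=True,
    )
    exons = sorted(
        ((f.start, f.end, f.strand) for f in db.features_of_type("exon")),
        key=lambda t: t[0],
    )
    cds_feats = sorted(
        ((f.start, f.end) for f in db.features_of_type("CDS")), key=lambda t: t[0]
    )
    if not exons:
        raise ValidationError(f"{gff3_path}: no exon features found")
    if not cds_feats:
        raise ValidationError(f"{gff3_path}: no CDS features found")
    if any(strand == "-" for *_, strand in exons):
        raise ValidationError("minus-strand transcripts are not supported")
    gene_symbol = "unknown"
    for f in db.features_of_type("gene"):
        gene_symbol = f.attributes.get("Name", f.attributes.get("ID", ["unknown"]))[0]
        break

    record = SeqIO.read(str(fasta_path), "fasta")
    cds_seq = str(record.seq).upper()

    exon_intervals = tuple((s, e) for s, e, _ in exons)
    cds_first = cds_feats[0][0]
    exonic_before = 0
    offset = None
    for start, end in exon_intervals:
        if start <= cds_first <= end:
            offset = exonic_before + (cds_first - start + 1)
            break
        exonic_before += end - start + 1
    if offset is None:
        raise ValidationError("first CDS base does not fall inside any exon")
    return TranscriptModel(
        gene_symbol=gene_symbol,
        exons=exon_intervals,
        coding_sequence=cds_seq,
        cds_start_exon_offset=offset,
    )


def write_transcript(
    model: TranscriptModel,
    gff3_path: str | Path,
    fasta_path: str | Path,
    seqid: str = "synthetic_locus",
) -> None:
    """Write the GFF3-like and CDS-FASTA representation read by :func:`load_transcript`."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    gene_id = model.gene_symbol
    span = (model.exons[0][0], model.exons[-1][1])
    lines = ["##gff-version 3"]

    def row(ftype: str, start: int, end: int, attrs: str) -> str:
        return f"{seqid}\tvarcohort\t{ftype}\t{start}\t{end}\t.\t+\t.\t{attrs}"

    lines.append(row("gene", span[0], span[1], f"ID=gene:{gene_id};Name={gene_id}"))
    lines.append(row("mRNA", span[0], span[1], f"ID=tx:{gene_id};Parent=gene:{gene_id}"))
    for i, (start, end) in enumerate(model.exons, start=1):
        lines.append(
            row("exon", start, end, f"ID=exon:{gene_id}.{i};Parent=tx:{gene_id}")
        )
    # CDS genomic intervals: exonic positions cds_start .. cds_start+len-1.
    cds_lo = model.cds_start_exon_offset
    cds_hi = model.cds_start_exon_offset + model.cds_length - 1
    exonic_before = 0
    n_cds = 0
    for start, end in model.exons:
        length = end - start + 1
        lo = max(cds_lo, exonic_before + 1)
        hi = min(cds_hi, exonic_before + length)
        if lo <= hi:
            n_cds += 1
            g_lo = start + (lo - exonic_before - 1)
            g_hi = start + (hi - exonic_before - 1)
            lines.append(
                row("CDS", g_lo, g_hi, f"ID=cds:{gene_id}.{n_cds};Parent=tx:{gene_id}")
            )
        exonic_before += length
    Path(gff3_path).write_text("\n".join(lines) + "\n")

    record = SeqRecord(
        Seq(model.coding_sequence), id=f"{gene_id}_CDS",
        description=f"coding sequence, {model.cds_length} nt",
    )
    with open(fasta_path, "w") as handle:
        SeqIO.write([record], handle, "fasta")
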