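"""Annotate somatic variants relative to splice junctions and apply exclusions.

A variant within ``splice_window_bp`` (default 20, inclusive) of an
exon-intron boundary is classed ``splicing`` and carries the boundary side
(donor/acceptor), the signed intronic offset in transcript orientation
(+k past a donor, -k before an acceptor), and an HGVS-like ``c.`` name.
Known variants (dbSNP-style local list) and segmental-duplication overlaps
are hard exclusions; conservation is annotation-only by default since it is
a preference, not a filter, in the intended workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .genome_model import (
    COMPLEMENT,
    GenomeModelError,
    Transcript,
    cdna_coordinate,
)
from .somatic_caller import SomaticVariant


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotatorParams:
    splice_window_bp: int = 20
    require_absent_from_known: bool = True
    exclude_segdup: bool = True
    annotate_conservation: bool = True
    require_conserved: bool = False  # optional hard filter; off by default

    def __post_init__(self) -> None:
        if self.splice_window_bp < 1:
            raise AnnotationError("splice_window_bp must be >= 1")


@dataclass(frozen=True)
class SpliceAnnotation:
    variant: SomaticVariant
    transcript_id: str | None
    region: str  # exonic | splicing | intronic | intergenic
    side: str  # donor | acceptor | none
    offset: int  # signed, transcript orientation; 0 for non-splicing
    hgvs_c: str | None
    exon_index: int | None = None  # boundary's exon (transcript orientation)
    conserved: bool = False
    in_segdup: bool = False
    known: bool = False


def _nearest_boundary(
    transcript: Transcript, position: int
) -> tuple[str, int, int] | None:
    """(side, signed offset, boundary exon index) for an intronic position."""
    for gi in range(transcript.n_exons - 1):
        left_end = transcript.exons[gi][1]
        right_start = transcript.exons[gi + 1][0]
        if left_end < position < right_start:
            dist_left = position - left_end
            dist_right = right_start - position
            if transcript.strand == "+":
                donor = (dist_left, gi + 1)
                acceptor = (dist_right, gi + 2)
            else:
                donor = (dist_right, transcript.n_exons - gi - 1)
                acceptor = (dist_left, transcript.n_exons - gi)
            # nearest boundary wins; ties go to the donor
            if donor[0] <= acceptor[0]:
                return "donor", donor[0], donor[1]
            return "acceptor", -acceptor[0], acceptor[1]
    return None


def classify(
    variant: SomaticVariant,
    transcripts: Sequence[Transcript],
    params: AnnotatorParams = AnnotatorParams(),
) -> list[SpliceAnnotation]:
    """One annotation per overlapping transcript; intergenic if none overlap."""
    annotations = []
    for tr in transcripts:
        if tr.contig != variant.contig:
            continue
        lo, hi = tr.span
        if not lo <= variant.position <= hi:
            continue
        if tr.exon_index_at(variant.position) is not None:
            hgvs = _try_hgvs(variant, tr)
            annotations.append(
                SpliceAnnotation(variant, tr.transcript_id, "exonic", "none", 0, hgvs)
            )
            continue
        side, offset, exon_index = _nearest_boundary(tr, variant.position)
        if abs(offset) <= params.splice_window_bp:
            hgvs = _try_hgvs(variant, tr)
            annotations.append(
                SpliceAnnotation(
                    variant, tr.transcript_id, "splicing", side, offset, hgvs,
                    exon_index=exon_index,
                )
            )
        else:
            annotations.append(
                SpliceAnnotation(variant, tr.transcript_id, "intronic", "none", 0, None)
            )
    if not annotations:
        annotations.append(
            SpliceAnnotation(variant, None, "intergenic", "none", 0, None)
        )
    return annotations


def _try_hgvs(variant: SomaticVariant, transcript: Transcript) -> str | None:
    if not transcript.has_cds:
        return None
    try:
        return hgvs_string(variant, transcript)
    except GenomeModelError:
        return None


def hgvs_string(
    variant: SomaticVariant,
    transcript: Transcript,
    allele_convention: str = "genomic",
) -> str:
    """Format ``c.{n}{+/-k}{REF}>{ALT}``.

    ``allele_convention='genomic'`` prints the plus-strand alleles as stored on
    the variant (the convention used for reporting even on minus-strand genes);
    ``'transcript'`` complements them on minus-strand transcripts for strict
    coding-strand HGVS.
    """
    if not transcript.has_cds:
        raise GenomeModelError(f"{transcript.transcript_id}: no CDS, cannot name c.")
    if allele_convention not in ("genomic", "transcript"):
        raise AnnotationError(f"unknown allele convention {allele_convention!r}")
    coord = cdna_coordinate(transcript, variant.position)
    ref, alt = variant.ref_base, variant.alt_base
    if allele_convention == "transcript" and transcript.strand == "-":
        ref, alt = ref.translate(COMPLEMENT), alt.translate(COMPLEMENT)
    return f"{coord}{ref}>{alt}"


# -- exclusion resources -------------------------------------------------


def load_bed_intervals(path: str | Path) -> dict[str, IntervalTree]:
    """BED (0-based half-open) into per-contig interval trees on 1-based coords."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationError(f"{path}:{lineno}: BED line with <3 columns")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from None
            if end0 <= start0:
                raise AnnotationError(f"{path}:{lineno}: empty/inverted BED interval")
            # 0-based half-open [start0, end0) covers 1-based start0+1 .. end0;
            # IntervalTree is half-open, so store [start0+1, end0+1)
            trees.setdefault(fields[0], IntervalTree()).addi(start0 + 1, end0 + 1)
    return trees


def load_known_variants(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Known-variant set from a VCF (by extension) or 4-column TSV."""
    known: set[tuple[str, int, str, str]] = set()
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz")):
        from cyvcf2 import VCF

        for rec in VCF(p):
            for alt in rec.ALT:
                known.add((rec.CHROM, rec.POS, rec.REF, alt))
        return known
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AnnotationError(f"{path}:{lineno}: expected contig/pos/ref/alt")
            known.add((fields[0], int(fields[1]), fields[2].upper(), fields[3].upper()))
    return known


def _in_intervals(trees: dict[str, IntervalTree] | None, contig: str, pos: int) -> bool:
    if not trees or contig not in trees:
        return False
    return bool(trees[contig].overlap(pos, pos + 1))


def apply_exclusions(
    annotations: Iterable[SpliceAnnotation],
    known_set: set[tuple[str, int, str, str]] | None = None,
    segdup_intervals: dict[str, IntervalTree] | None = None,
    conserved_intervals: dict[str, IntervalTree] | None = None,
    params: AnnotatorParams = AnnotatorParams(),
) -> list[SpliceAnnotation]:
    """Drop known/segdup variants per params; mark conservation (annotation only
    unless ``require_conserved``)."""
    kept = []
    for ann in annotations:
        v = ann.variant
        is_known = bool(known_set) and (
            (v.contig, v.position, v.ref_base, v.alt_base) in known_set
        )
        in_segdup = _in_intervals(segdup_intervals, v.contig, v.position)
        conserved = _in_intervals(conserved_intervals, v.contig, v.position)
        ann = replace(ann, known=is_known, in_segdup=in_segdup, conserved=conserved)
        if params.require_absent_from_known and is_known:
            continue
        if params.exclude_segdup and in_segdup:
            continue
        if params.require_conserved and not conserved:
            continue
        kept.append(ann)
    return kept


def annotations_to_tsv(annotations: Iterable[SpliceAnnotation]) -> str:
    lines = [
        "locus\thgvs_c\ttranscript\tregion\tside\toffset\tcoverage_t\tcoverage_n"
        "\talt_count_t\talt_count_n\tpercent_t\tpercent_n\tconserved\tin_segdup\tknown"
    ]
    for a in annotations:
        v = a.variant
        lines.append(
            f"{v.locus}\t{a.hgvs_c or '.'}\t{a.transcript_id or '.'}\t{a.region}"
            f"\t{a.side}\t{a.offset}\t{v.tumor_depth}\t{v.normal_depth}"
            f"\t{v.tumor_alt_count}\t{v.normal_alt_count}\t{v.tumor_percent}"
            f"\t{v.normal_percent}\t{int(a.conserved)}\t{int(a.in_segdup)}\t{int(a.known)}"
        )
    return "\n".join(lines) + "\n"
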