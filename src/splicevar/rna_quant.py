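"""Transcript-level validation of splice-site losses from spliced RNA-seq.

Given the mutated boundary of a transcript, the reads local to that event are
partitioned into:

* wild-type      — junction reads matching the canonical adjacent-exon
                   junctions involving the mutated exon;
* exon skipping  — a junction joining the two exons flanking a skipped exon;
* intron retention — reads continuously spanning the mutated exon-intron
                   boundary (no splice over it);
* cryptic site   — a junction sharing one end with a canonical boundary whose
                   other end is shifted a few bases into exon or intron.

Percentages are integer fractions of the informative reads at the event.
Expression context is reported as FPKM (fragments per kilobase of exon model
per million mapped fragments) with a percentile rank within the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

from .genome_model import Transcript
from .somatic_caller import SomaticVariant, integer_percent
from .splice_annotator import SpliceAnnotation


class RnaQuantError(ValueError):
    pass


@dataclass(frozen=True)
class JunctionCount:
    contig: str
    donor_end: int  # 1-based last base of the left (genomic) exon
    acceptor_start: int  # 1-based first base of the right (genomic) exon
    read_count: int

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start - 1:
            raise RnaQuantError(
                f"junction {self.contig}:{self.donor_end}-{self.acceptor_start} "
                "has no intronic gap"
            )
        if self.read_count < 0:
            raise RnaQuantError("negative junction read count")


@dataclass(frozen=True)
class SpliceOutcome:
    kind: str  # wild_type | exon_skip | intron_retention | cryptic
    detail: str  # e.g. "skip_exon_5", "cryptic_+5_into_exon", "exon17-exon18"
    read_count: int
    percent: int


@dataclass(frozen=True)
class EventClassification:
    outcomes: list[SpliceOutcome]
    status: str  # "ok" | "not_expressed"

    @property
    def percent_by_kind(self) -> dict[str, int]:
        return {o.kind: o.percent for o in self.outcomes}


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    exon_model_length_bp: int
    fragment_count: int
    fpkm: float
    percentile: int | None = None


# -- SAM record handling --------------------------------------------------


def _open_records(source) -> Iterator[pysam.AlignedSegment]:
    if isinstance(source, (str, Path)):
        with pysam.AlignmentFile(str(source), "r", check_sq=False) as af:
            yield from af
    else:
        yield from source


def _usable(rec: pysam.AlignedSegment) -> bool:
    return not (
        rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.cigartuples is None
    )


def junctions_from_alignments(source) -> list[JunctionCount]:
    """Aggregate splice junctions from the N operations of spliced alignments.

    ``source`` is a SAM/BAM path or an iterable of aligned segments. Each N
    CIGAR operation yields one junction: the last aligned reference base
    before the gap and the first after it (both 1-based). Records with
    malformed CIGARs are skipped (counted, not fatal).
    """
    counts: dict[tuple[str, int, int], int] = {}
    skipped = 0
    for rec in _open_records(source):
        if not _usable(rec):
            continue
        try:
            ref = rec.reference_start + 1  # to 1-based
            for op, length in rec.cigartuples:
                if op in (0, 7, 8, 2):  # M, =, X, D consume reference
                    ref += length
                elif op == 3:  # N
                    key = (rec.reference_name, ref - 1, ref + length)
                    counts[key] = counts.get(key, 0) + 1
                    ref += length
                # I, S, H, P do not consume reference
        except (TypeError, ValueError):
            skipped += 1
    junctions = [
        JunctionCount(contig, donor_end, acceptor_start, n)
        for (contig, donor_end, acceptor_start), n in sorted(counts.items())
    ]
    junctions_from_alignments.last_skipped = skipped  # type: ignore[attr-defined]
    return junctions


def _match_blocks(rec: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Contiguous reference intervals covered by aligned bases, 1-based
    inclusive; deletions keep a block contiguous, N splits it."""
    blocks: list[tuple[int, int]] = []
    ref = rec.reference_start + 1
    cur_start: int | None = None
    for op, length in rec.cigartuples:
        if op in (0, 7, 8):  # aligned bases
            if cur_start is None:
                cur_start = ref
            ref += length
        elif op == 2:  # D: reference consumed, block stays contiguous
            ref += length
        elif op == 3:  # N: splice, close block
            if cur_start is not None:
                blocks.append((cur_start, ref - 1))
                cur_start = None
            ref += length
    if cur_start is not None:
        blocks.append((cur_start, ref - 1))
    return blocks


def _base_at(rec: pysam.AlignedSegment, ref_pos: int) -> str | None:
    """Query base aligned at a 1-based reference position (None in a deletion)."""
    ref = rec.reference_start + 1
    query = 0
    seq = rec.query_sequence
    for op, length in rec.cigartuples:
        if op in (0, 7, 8):
            if ref <= ref_pos < ref + length:
                return seq[query + (ref_pos - ref)] if seq else None
            ref += length
            query += length
        elif op in (2, 3):
            if op == 2 and ref <= ref_pos < ref + length:
                return None
            ref += length
        elif op in (1, 4):  # I, S consume query only
            query += length
    return None


def boundary_spanning_count(
    source,
    contig: str,
    boundary_position: int,
    min_anchor: int = 6,
    query_position: int | None = None,
) -> tuple[int, list[str]]:
    """Count reads continuously covering the exon-intron boundary.

    A read spans the boundary when one of its aligned match blocks covers
    ``[boundary - min_anchor + 1, boundary + min_anchor]`` — i.e. at least
    ``min_anchor`` aligned bases on each side with no splice over the
    boundary. When ``query_position`` is given, the aligned base of each
    spanning read at that position is also returned.
    """
    count = 0
    alleles: list[str] = []
    lo = boundary_position - min_anchor + 1
    hi = boundary_position + min_anchor
    for rec in _open_records(source):
        if not _usable(rec) or rec.reference_name != contig:
            continue
        if any(s <= lo and hi <= e for s, e in _match_blocks(rec)):
            count += 1
            if query_position is not None:
                base = _base_at(rec, query_position)
                if base is not None:
                    alleles.append(base)
    return count, alleles


# -- event classification -------------------------------------------------


def canonical_junction(transcript: Transcript, exon_index: int) -> tuple[int, int]:
    """Genomic (donor_end, acceptor_start) of the junction joining transcript
    exons ``exon_index`` and ``exon_index + 1``."""
    a = transcript.exon_by_index(exon_index)
    b = transcript.exon_by_index(exon_index + 1)
    left, right = (a, b) if a[0] < b[0] else (b, a)
    return left[1], right[0]


def _mutated_exon_and_boundary(
    annotation: SpliceAnnotation, transcript: Transcript
) -> tuple[int, int]:
    """(mutated exon index, genomic boundary position) from the annotation side.

    For a donor-side variant the mutated exon is the exon whose donor is hit;
    for an acceptor-side variant, the exon whose acceptor is hit.
    """
    if annotation.side not in ("donor", "acceptor") or annotation.exon_index is None:
        raise RnaQuantError("annotation does not name a mutated splice boundary")
    k = annotation.exon_index
    s, e = transcript.exon_by_index(k)
    if annotation.side == "donor":
        boundary = e if transcript.strand == "+" else s
    else:
        boundary = s if transcript.strand == "+" else e
    return k, boundary


def classify_splice_event(
    annotation: SpliceAnnotation,
    junctions: Sequence[JunctionCount],
    transcript: Transcript,
    spanning_count: int = 0,
    cryptic_window: int = 50,
) -> EventClassification:
    """Partition event-local reads into wild-type / skip / retention / cryptic.

    ``junctions`` may include junctions anywhere on the contig; only those in
    the locality of the mutated boundary (canonical pairs involving the
    mutated exon, the skip junction over it, and near-boundary cryptic
    junctions) are informative. ``spanning_count`` is the read count from
    :func:`boundary_spanning_count` at the mutated boundary.
    """
    k, boundary_pos = _mutated_exon_and_boundary(annotation, transcript)
    n = transcript.n_exons

    canonical: dict[tuple[int, int], str] = {}
    for i in (k - 1, k):
        if 1 <= i <= n - 1:
            canonical[canonical_junction(transcript, i)] = f"exon{i}-exon{i + 1}"
    skip_key: tuple[int, int] | None = None
    if 2 <= k <= n - 1:
        a = transcript.exon_by_index(k - 1)
        b = transcript.exon_by_index(k + 1)
        left, right = (a, b) if a[0] < b[0] else (b, a)
        skip_key = (left[1], right[0])
    canonical_ends = {p for key in canonical for p in key}

    outcomes: list[tuple[str, str, int]] = []
    for j in junctions:
        if j.contig != transcript.contig or j.read_count == 0:
            continue
        key = (j.donor_end, j.acceptor_start)
        if key in canonical:
            outcomes.append(("wild_type", canonical[key], j.read_count))
        elif skip_key is not None and key == skip_key:
            outcomes.append(("exon_skip", f"skip_exon_{k}", j.read_count))
        else:
            # cryptic: one end canonical, the other within the window of the
            # mutated boundary (but not the canonical boundary itself)
            for fixed, moving in ((j.donor_end, j.acceptor_start),
                                  (j.acceptor_start, j.donor_end)):
                if (
                    fixed in canonical_ends
                    and moving != boundary_pos
                    and abs(moving - boundary_pos) <= cryptic_window
                ):
                    shift = moving - boundary_pos
                    outcomes.append(("cryptic", f"cryptic_shift_{shift:+d}", j.read_count))
                    break

    if spanning_count > 0:
        outcomes.append(
            ("intron_retention", f"boundary_{transcript.contig}:{boundary_pos}",
             spanning_count)
        )

    # merge wild-type junction support into one outcome
    wt_total = sum(c for kind, _, c in outcomes if kind == "wild_type")
    wt_details = "+".join(sorted(d for kind, d, _ in outcomes if kind == "wild_type"))
    merged = [("wild_type", wt_details, wt_total)] if wt_total else []
    merged += [o for o in outcomes if o[0] != "wild_type"]

    total = sum(c for _, _, c in merged)
    if total == 0:
        return EventClassification([], "not_expressed")
    order = {"wild_type": 0, "exon_skip": 1, "intron_retention": 2, "cryptic": 3}
    merged.sort(key=lambda o: (order[o[0]], o[1]))
    return EventClassification(
        [SpliceOutcome(kind, detail, c, integer_percent(c, total))
         for kind, detail, c in merged],
        "ok",
    )


# -- allele support in retained-intron reads ------------------------------


@dataclass(frozen=True)
class AlleleSupport:
    mut_count: int
    wt_count: int
    exclusive_mutant: bool


def allele_support(alleles: Iterable[str], variant: SomaticVariant) -> AlleleSupport:
    """Tally per-read alleles at the variant site among boundary-spanning reads."""
    mut = sum(1 for a in alleles if a.upper() == variant.alt_base)
    wt = sum(1 for a in alleles if a.upper() == variant.ref_base)
    return AlleleSupport(mut, wt, mut >= 1 and wt == 0)


# -- expression ------------------------------------------------------------


def fpkm(fragment_count: int, exon_model_length_bp: int, total_mapped_fragments: int) -> float:
    """Fragments per kilobase of exon model per million mapped fragments."""
    if exon_model_length_bp <= 0 or total_mapped_fragments <= 0:
        raise RnaQuantError("exon model length and library total must be positive")
    if fragment_count < 0:
        raise RnaQuantError("negative fragment count")
    return fragment_count / ((exon_model_length_bp / 1000) * (total_mapped_fragments / 1e6))


def percentile_rank(value: float, dataset_values: Sequence[float]) -> int:
    """Percent of dataset values <= value, rounded to the nearest integer."""
    if not dataset_values:
        raise RnaQuantError("percentile of an empty dataset")
    n_le = sum(1 for v in dataset_values if v <= value)
    return round(100 * n_le / len(dataset_values))


def exon_model_length(transcript: Transcript) -> int:
    return sum(e - s + 1 for s, e in transcript.exons)


def fragment_count_for_gene(source, transcript: Transcript) -> int:
    """Fragments overlapping the gene's exon model (pairs counted once);
    junction-spanning reads count via their aligned blocks."""
    seen: set[str] = set()
    for rec in _open_records(source):
        if not _usable(rec) or rec.reference_name != transcript.contig:
            continue
        if rec.query_name in seen:
            continue
        for bs, be in _match_blocks(rec):
            if any(bs <= e and s <= be for s, e in transcript.exons):
                seen.add(rec.query_name)
                break
    return len(seen)


def expression_table(
    records: Sequence[ExpressionRecord], total_mapped_fragments: int
) -> list[ExpressionRecord]:
    """Recompute FPKM and percentile ranks across a dataset of genes."""
    out = []
    values = [
        fpkm(r.fragment_count, r.exon_model_length_bp, total_mapped_fragments)
        for r in records
    ]
    for r, v in zip(records, values):
        out.append(
            ExpressionRecord(
                r.gene_id, r.exon_model_length_bp, r.fragment_count, v,
                percentile_rank(v, values),
            )
        )
    return out


def outcomes_to_tsv(events: dict[str, EventClassification]) -> str:
    lines = ["event\tstatus\tkind\tdetail\tread_count\tpercent"]
    for name, ev in events.items():
        if not ev.outcomes:
            lines.append(f"{name}\t{ev.status}\t.\t.\t0\t.")
        for o in ev.outcomes:
            lines.append(f"{name}\t{ev.status}\t{o.kind}\t{o.detail}\t{o.read_count}\t{o.percent}")
    return "\n".join(lines) + "\n"
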