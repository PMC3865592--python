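"""Reference sequence and transcript models with splice-boundary arithmetic.

This module owns all coordinate conventions used by the pipeline:

* genomic positions are 1-based inclusive throughout;
* transcript orientation means 5'→3' of the mRNA, so on the minus strand
  transcript exon 1 is the genomically *rightmost* exon;
* coding (c.) coordinates follow the HGVS intronic convention: ``c.N+k``
  is k bases past the donor whose last exonic base is coding position N,
  ``c.N-k`` is k bases before the acceptor whose first exonic base is
  coding position N.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeModelError(ValueError):
    """Raised for malformed references, gene models or out-of-range queries."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """Uppercase ACGTN reference sequences keyed by contig name."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = set("ACGTN")
        for name, seq in self.contigs.items():
            bad = set(seq) - allowed
            if bad:
                raise GenomeModelError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the 1-based inclusive slice [start, end] of a contig."""
        try:
            seq = self.contigs[contig]
        except KeyError:
            raise GenomeModelError(f"unknown contig {contig!r}") from None
        if start < 1 or end > len(seq) or start > end:
            raise GenomeModelError(
                f"window {contig}:{start}-{end} exceeds contig bounds (len {len(seq)})"
            )
        return seq[start - 1 : end]

    def base(self, contig: str, position: int) -> str:
        return self.fetch(contig, position, position)


@dataclass(frozen=True)
class SpliceBoundary:
    """One side of one intron, anchored at its boundary exonic base.

    ``genomic_position`` is the last exonic base of the upstream exon for a
    donor, or the first exonic base of the downstream exon for an acceptor,
    both in transcript orientation.
    """

    transcript_id: str
    exon_index: int  # 1-based, transcript orientation
    kind: str  # "donor" | "acceptor"
    contig: str
    strand: str
    genomic_position: int


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]  # genomic order, 1-based inclusive
    cds_start: int | None = None  # genomic min of CDS
    cds_end: int | None = None  # genomic max of CDS

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeModelError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise GenomeModelError(f"{self.transcript_id}: transcript has no exons")
        self.exons = sorted(self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise GenomeModelError(f"{self.transcript_id}: exon {s}-{e} inverted")
            if s <= prev_end:
                raise GenomeModelError(
                    f"{self.transcript_id}: exons overlap or touch near {s}"
                )
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise GenomeModelError(f"{self.transcript_id}: partial CDS bounds")
        if self.cds_start is not None:
            if not (self.span[0] <= self.cds_start <= self.cds_end <= self.span[1]):
                raise GenomeModelError(f"{self.transcript_id}: CDS outside exon span")
            if not self._exonic(self.cds_start) or not self._exonic(self.cds_end):
                raise GenomeModelError(
                    f"{self.transcript_id}: CDS bound falls in an intron"
                )

    # -- basic geometry -------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    def _exonic(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def exon_by_index(self, exon_index: int) -> tuple[int, int]:
        """Genomic interval of the exon at a 1-based transcript-orientation index."""
        if not 1 <= exon_index <= self.n_exons:
            raise GenomeModelError(
                f"{self.transcript_id}: exon index {exon_index} out of 1..{self.n_exons}"
            )
        if self.strand == "+":
            return self.exons[exon_index - 1]
        return self.exons[self.n_exons - exon_index]

    def exon_index_at(self, pos: int) -> int | None:
        """1-based transcript-orientation exon index containing pos, or None."""
        for gi, (s, e) in enumerate(self.exons):
            if s <= pos <= e:
                return gi + 1 if self.strand == "+" else self.n_exons - gi
        return None

    # -- splice boundaries ----------------------------------------------

    def donors(self) -> list[SpliceBoundary]:
        """Donor of every non-terminal exon, transcript orientation."""
        out = []
        for i in range(1, self.n_exons):
            s, e = self.exon_by_index(i)
            pos = e if self.strand == "+" else s
            out.append(
                SpliceBoundary(self.transcript_id, i, "donor", self.contig, self.strand, pos)
            )
        return out

    def acceptors(self) -> list[SpliceBoundary]:
        """Acceptor of every non-initial exon, transcript orientation."""
        out = []
        for i in range(2, self.n_exons + 1):
            s, e = self.exon_by_index(i)
            pos = s if self.strand == "+" else e
            out.append(
                SpliceBoundary(self.transcript_id, i, "acceptor", self.contig, self.strand, pos)
            )
        return out

    def boundaries(self) -> list[SpliceBoundary]:
        return self.donors() + self.acceptors()

    # -- coding coordinates ---------------------------------------------

    def _coding_positions(self) -> list[int]:
        """Genomic positions of coding bases, in transcript orientation."""
        if not self.has_cds:
            raise GenomeModelError(f"{self.transcript_id}: no CDS bounds")
        pos = [
            p
            for s, e in self.exons
            for p in range(max(s, self.cds_start), min(e, self.cds_end) + 1)
        ]
        return pos if self.strand == "+" else pos[::-1]

    def cds_offset_of(self, genomic_position: int) -> int:
        """1-based coding coordinate of an exonic genomic position inside the CDS."""
        coding = self._coding_positions()
        try:
            return coding.index(genomic_position) + 1
        except ValueError:
            raise GenomeModelError(
                f"{self.transcript_id}: position {genomic_position} not a coding base"
            ) from None

    def genomic_of_cds_offset(self, cds_offset: int) -> int:
        coding = self._coding_positions()
        if not 1 <= cds_offset <= len(coding):
            raise GenomeModelError(
                f"{self.transcript_id}: c.{cds_offset} outside CDS of length {len(coding)}"
            )
        return coding[cds_offset - 1]


@dataclass(frozen=True)
class CdnaCoordinate:
    """HGVS-like coding descriptor: c.{cds_offset} or c.{cds_offset}{intron_offset:+d}."""

    cds_offset: int
    intron_offset: int

    def __str__(self) -> str:
        if self.intron_offset == 0:
            return f"c.{self.cds_offset}"
        return f"c.{self.cds_offset}{self.intron_offset:+d}"


def cdna_coordinate(transcript: Transcript, genomic_position: int) -> CdnaCoordinate:
    """Map a genomic position inside the transcript span to coding coordinates.

    Exonic positions yield ``(n, 0)``. Intronic positions are anchored at the
    nearer intron end: positions in the 5' half of an intron get ``(N, +k)``
    from the preceding donor, the 3' half get ``(M, -k)`` from the following
    acceptor; the exact midpoint goes to the donor side.
    """
    lo, hi = transcript.span
    if not lo <= genomic_position <= hi:
        raise GenomeModelError(
            f"{transcript.transcript_id}: position {genomic_position} outside "
            f"transcript span {lo}-{hi}"
        )
    if transcript.exon_index_at(genomic_position) is not None:
        return CdnaCoordinate(transcript.cds_offset_of(genomic_position), 0)

    # find the flanking intron: exons genomically sorted
    for gi in range(transcript.n_exons - 1):
        left_end = transcript.exons[gi][1]
        right_start = transcript.exons[gi + 1][0]
        if left_end < genomic_position < right_start:
            break
    else:  # pragma: no cover - excluded by span check + exonic check
        raise GenomeModelError("position not located in any intron")

    dist_left = genomic_position - left_end
    dist_right = right_start - genomic_position
    if transcript.strand == "+":
        donor_pos, acceptor_pos = left_end, right_start
        donor_dist, acceptor_dist = dist_left, dist_right
    else:
        donor_pos, acceptor_pos = right_start, left_end
        donor_dist, acceptor_dist = dist_right, dist_left

    if donor_dist <= acceptor_dist:
        return CdnaCoordinate(transcript.cds_offset_of(donor_pos), donor_dist)
    return CdnaCoordinate(transcript.cds_offset_of(acceptor_pos), -acceptor_dist)


def genomic_coordinate(transcript: Transcript, coord: CdnaCoordinate) -> int:
    """Inverse of :func:`cdna_coordinate` (round-trip partner)."""
    anchor = transcript.genomic_of_cds_offset(coord.cds_offset)
    if coord.intron_offset == 0:
        return anchor
    step = 1 if transcript.strand == "+" else -1
    return anchor + step * coord.intron_offset


# -- window extraction ---------------------------------------------------


@dataclass(frozen=True)
class WindowGeometry:
    """Footprint of a splice-site scoring window, in transcript orientation."""

    donor_exonic: int = 3
    donor_intronic: int = 6
    acceptor_intronic: int = 20
    acceptor_exonic: int = 3

    def length(self, kind: str) -> int:
        if kind == "donor":
            return self.donor_exonic + self.donor_intronic
        return self.acceptor_intronic + self.acceptor_exonic


def window_positions(boundary: SpliceBoundary, geometry: WindowGeometry) -> list[int]:
    """Genomic positions of the scoring window, ordered in transcript orientation.

    Donor windows read exon→intron; acceptor windows read intron→exon.
    """
    step = 1 if boundary.strand == "+" else -1
    b = boundary.genomic_position
    if boundary.kind == "donor":
        start = b - step * (geometry.donor_exonic - 1)
        n = geometry.length("donor")
    else:
        start = b - step * geometry.acceptor_intronic
        n = geometry.length("acceptor")
    return [start + step * i for i in range(n)]


def boundary_window(
    genome: GenomeSequence,
    boundary: SpliceBoundary,
    geometry: WindowGeometry = WindowGeometry(),
) -> str:
    """Extract the splice-site window sequence in transcript orientation."""
    positions = window_positions(boundary, geometry)
    lo, hi = min(positions), max(positions)
    seq = genome.fetch(boundary.contig, lo, hi)
    if boundary.strand == "-":
        seq = reverse_complement(seq)
    return seq


# -- file loading --------------------------------------------------------


def load_fasta(path: str | Path | io.TextIOBase) -> GenomeSequence:
    """Load a (multi-)FASTA reference; lowercase bases are uppercased."""
    handle = open(path) if isinstance(path, (str, Path)) else path
    contigs: dict[str, str] = {}
    try:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in contigs:
                raise GenomeModelError(f"duplicated contig name {record.id!r}")
            contigs[record.id] = str(record.seq).upper()
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    if not contigs:
        raise GenomeModelError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


def load_gene_models(path_gtf: str | Path) -> list[Transcript]:
    """Load transcripts (exon + CDS features) from a GTF file via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path_gtf),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, contig, strand)
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError:
            raise GenomeModelError(
                f"{path_gtf}: {feat.featuretype} feature at {feat.seqid}:{feat.start} "
                "lacks transcript_id/gene_id"
            ) from None
        meta.setdefault(tid, (gid, feat.seqid, feat.strand))
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tid, []).append((feat.start, feat.end))

    transcripts = []
    for tid, (gid, contig, strand) in meta.items():
        if tid not in exons:
            raise GenomeModelError(f"transcript {tid} has CDS but zero exons")
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        transcripts.append(
            Transcript(tid, gid, contig, strand, exons[tid], cds_start, cds_end)
        )
    transcripts.sort(key=lambda t: (t.contig, t.span[0], t.transcript_id))
    return transcripts
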