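"""Self-contained synthetic fixtures for the whole pipeline.

Each named scenario writes a miniature study to disk — reference FASTA, GTF
gene model, tumor/normal pileups, spliced RNA-seq SAM, exclusion BEDs and a
``truth.json`` — around one planted splice-site mutation with its intended
depths, allele counts and transcript-level outcome (exon skipping, intron
retention, cryptic-site activation, low/no expression, or nothing at all).

Toy transcripts are engineered so cumulative coding lengths reproduce the
intended ``c.`` coordinates; splice sites are painted with the canonical
motifs the bundled scoring models are trained on (CAG|GTAAGT donors,
CT-repeat tract + AG| acceptors). Gene structures are otherwise arbitrary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_model import GenomeSequence, Transcript, reverse_complement

QUAL40 = "I"  # Phred 40 at ASCII+33

SCENARIO_NAMES = (
    "gnaq_skip",
    "hook1_retention",
    "abcc3_cryptic",
    "apc_homozygous",
    "klhdc1_low_expression",
    "dnah9_not_expressed",
    "negative_control",
)


class ScenarioError(ValueError):
    pass


@dataclass
class Scenario:
    name: str
    seed: int
    directory: Path
    genome: GenomeSequence
    transcript: Transcript
    truth: dict

    @property
    def paths(self) -> dict[str, Path]:
        d = self.directory
        return {
            "fasta": d / "genome.fa",
            "gtf": d / "genes.gtf",
            "tumor_pileup": d / "tumor.pileup",
            "normal_pileup": d / "normal.pileup",
            "sam": d / "rna.sam",
            "segdup_bed": d / "segdup.bed",
            "conserved_bed": d / "conserved.bed",
            "known": d / "known.tsv",
            "truth": d / "truth.json",
        }


# -- gene assembly --------------------------------------------------------


@dataclass
class _GeneLayout:
    contig: str
    strand: str
    sequence: str  # full contig
    exons: list[tuple[int, int]]  # genomic order
    pad: int
    gene_length: int

    def exon_by_transcript_index(self, i: int, n: int) -> tuple[int, int]:
        return self.exons[i - 1] if self.strand == "+" else self.exons[n - i]


_DONOR_MOTIF = "GTAAGT"  # intron first 6, transcript orientation
_ACCEPTOR_MOTIF = "CTCTCTCTCTCTCTCTCT" + "AG"  # intron last 20
_EXON_START = "GTC"  # exon first 3 (acceptor exonic side)
_EXON_END = "CAG"  # exon last 3 (donor exonic side)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _build_gene(
    rng: np.random.Generator,
    contig: str,
    strand: str,
    exon_lengths: list[int],
    intron_length: int = 150,
    pad: int = 100,
) -> _GeneLayout:
    """Assemble the contig in transcript orientation, then place genomically."""
    if any(l < 8 for l in exon_lengths):
        raise ScenarioError("exons must be at least 8 bp to carry splice motifs")
    if intron_length < len(_DONOR_MOTIF) + len(_ACCEPTOR_MOTIF) + 2:
        raise ScenarioError("introns too short for donor+acceptor motifs")
    n = len(exon_lengths)
    segments: list[str] = []
    offsets: list[tuple[int, int]] = []  # exon offsets in gene sequence (0-based)
    cursor = 0
    for i, length in enumerate(exon_lengths):
        exon = list(_random_seq(rng, length))
        if i > 0:
            exon[:3] = _EXON_START
        if i < n - 1:
            exon[-3:] = _EXON_END
        segments.append("".join(exon))
        offsets.append((cursor, cursor + length))
        cursor += length
        if i < n - 1:
            intron = list(_random_seq(rng, intron_length))
            intron[: len(_DONOR_MOTIF)] = _DONOR_MOTIF
            intron[-len(_ACCEPTOR_MOTIF):] = _ACCEPTOR_MOTIF
            segments.append("".join(intron))
            cursor += intron_length
    gene_seq = "".join(segments)
    L = len(gene_seq)
    placed = gene_seq if strand == "+" else reverse_complement(gene_seq)
    contig_seq = _random_seq(rng, pad) + placed + _random_seq(rng, pad)
    exons = []
    for o_start, o_end in offsets:
        if strand == "+":
            exons.append((pad + o_start + 1, pad + o_end))
        else:
            exons.append((pad + L - o_end + 1, pad + L - o_start))
    exons.sort()
    return _GeneLayout(contig, strand, contig_seq, exons, pad, L)


def _make_transcript(layout: _GeneLayout, tid: str, gid: str) -> Transcript:
    cds_start = layout.exons[0][0]
    cds_end = layout.exons[-1][1]
    return Transcript(tid, gid, layout.contig, layout.strand, list(layout.exons),
                      cds_start, cds_end)


# -- file writers ----------------------------------------------------------


def _write_fasta(path: Path, contig: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")


def _write_gtf(path: Path, transcript: Transcript) -> None:
    lines = []
    attrs = f'gene_id "{transcript.gene_id}"; transcript_id "{transcript.transcript_id}";'
    for s, e in transcript.exons:
        lines.append(
            f"{transcript.contig}\tsynthetic\texon\t{s}\t{e}\t.\t{transcript.strand}\t.\t{attrs}"
        )
        cs = max(s, transcript.cds_start)
        ce = min(e, transcript.cds_end)
        if cs <= ce:
            lines.append(
                f"{transcript.contig}\tsynthetic\tCDS\t{cs}\t{ce}\t.\t{transcript.strand}\t0\t{attrs}"
            )
    path.write_text("\n".join(lines) + "\n")


def _pileup_line(contig: str, pos: int, ref: str, depth: int,
                 alt: str | None = None, alt_count: int = 0,
                 alt_quals: list[int] | None = None) -> str:
    """One canonical pileup line: alt calls first (alternating strand), ref rest."""
    bases, quals = [], []
    for i in range(alt_count):
        bases.append(alt if i % 2 == 0 else alt.lower())
        quals.append(alt_quals[i] if alt_quals else 40)
    for i in range(depth - alt_count):
        bases.append("." if i % 2 == 0 else ",")
        quals.append(40)
    return "\t".join([contig, str(pos), ref, str(depth), "".join(bases),
                      "".join(chr(q + 33) for q in quals)])


def _sam_header(contig: str, length: int) -> str:
    return f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{contig}\tLN:{length}\n"


def _sam_read(name: str, contig: str, pos: int, cigar: str, seq: str) -> str:
    qual = QUAL40 * len(seq)
    return f"{name}\t0\t{contig}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t{qual}"


def _junction_reads(genome_seq: str, contig: str, donor_end: int,
                    acceptor_start: int, count: int, prefix: str,
                    arm: int = 20) -> list[str]:
    gap = acceptor_start - donor_end - 1
    left = genome_seq[donor_end - arm : donor_end]
    right = genome_seq[acceptor_start - 1 : acceptor_start - 1 + arm]
    cigar = f"{arm}M{gap}N{arm}M"
    pos = donor_end - arm + 1
    return [
        _sam_read(f"{prefix}_{i}", contig, pos, cigar, left + right)
        for i in range(count)
    ]


def _spanning_reads(genome_seq: str, contig: str, boundary: int, count: int,
                    prefix: str, mutate_at: int | None = None,
                    mutate_to: str | None = None, n_mutant: int = 0,
                    half: int = 15) -> list[str]:
    start = boundary - half  # read covers [start, start + 2*half - 1]
    seq_wt = genome_seq[start - 1 : start - 1 + 2 * half]
    reads = []
    for i in range(count):
        seq = seq_wt
        if mutate_at is not None and i < n_mutant:
            idx = mutate_at - start
            seq = seq[:idx] + mutate_to + seq[idx + 1 :]
        reads.append(_sam_read(f"{prefix}_{i}", contig, start, f"{2 * half}M", seq))
    return reads


# -- planted variant geometry ---------------------------------------------


def _variant_genomics(layout: _GeneLayout, n_exons: int, side: str,
                      exon_index: int, offset: int,
                      t_ref: str, t_alt: str) -> tuple[int, str, str, int]:
    """Genomic (position, ref, alt, boundary_position) for a planted splice variant.

    ``t_ref``/``t_alt`` are transcript-strand alleles; offset is +k past the
    donor or -k before the acceptor, transcript orientation.
    """
    s, e = layout.exon_by_transcript_index(exon_index, n_exons)
    step = 1 if layout.strand == "+" else -1
    if side == "donor":
        boundary = e if layout.strand == "+" else s
        position = boundary + step * offset
    else:
        boundary = s if layout.strand == "+" else e
        position = boundary + step * offset  # offset negative
    ref, alt = t_ref, t_alt
    if layout.strand == "-":
        ref, alt = reverse_complement(ref), reverse_complement(alt)
    expected = layout.sequence[position - 1]
    if expected != ref:
        raise ScenarioError(
            f"planted ref {ref} does not match painted genome base {expected} "
            f"at {position}"
        )
    return position, ref, alt, boundary


@dataclass
class _Plan:
    strand: str
    exon_lengths: list[int]
    side: str
    exon_index: int
    offset: int
    t_ref: str
    t_alt: str
    tumor: tuple[int, int]  # depth, alt count
    normal: tuple[int, int]
    cds_offset: int  # for the expected c. name
    junctions: list[tuple[int, int, int]] = field(default_factory=list)  # (ex_i, ex_j, count)
    spanning: int = 0
    spanning_mutant: int = 0
    cryptic: tuple[int, int] | None = None  # (shift into exon (+) / intron (-), count)
    expect_loss: bool = True
    expression_status: str = "ok"


_PLANS: dict[str, _Plan] = {
    # minus-strand gene, donor +1 kill, exon 5 skipped in RNA
    "gnaq_skip": _Plan(
        "-", [150, 150, 120, 150, 165, 120, 145], "donor", 5, 1, "G", "A",
        (23, 8), (65, 0), 735,
        junctions=[(4, 6, 28), (5, 6, 5), (4, 5, 3)],
    ),
    # plus-strand gene, acceptor -1 kill, intron retained, mutation in all
    # retention reads
    "hook1_retention": _Plan(
        "+", [100] * 16 + [61, 130, 140], "acceptor", 18, -1, "G", "A",
        (186, 87), (153, 0), 1662,
        junctions=[(17, 18, 7)], spanning=5, spanning_mutant=5,
    ),
    # plus-strand gene, acceptor -1 kill, mixed wt/retention/cryptic outcome;
    # retention reads carry the reference allele
    "abcc3_cryptic": _Plan(
        "+", [137] * 12 + [138, 150, 140], "acceptor", 14, -1, "G", "A",
        (59, 30), (36, 0), 1783,
        junctions=[(13, 14, 58)], spanning=37, spanning_mutant=0,
        cryptic=(5, 5),
    ),
    # plus-strand gene, donor +5 kill at near-homozygous fraction; DNA only
    "apc_homozygous": _Plan(
        "+", [130] * 9 + [142, 150], "donor", 10, 5, "G", "A",
        (90, 73), (63, 0), 1312,
        expression_status="not_expressed",
    ),
    # acceptor -2 kill; gene barely expressed
    "klhdc1_low_expression": _Plan(
        "+", [95] * 5 + [92, 120, 130], "acceptor", 7, -2, "A", "G",
        (93, 48), (14, 1), 568,
        junctions=[(6, 7, 2)], expression_status="low",
    ),
    # donor +5 kill; gene silent in RNA
    "dnah9_not_expressed": _Plan(
        "+", [200] * 51 + [42, 150], "donor", 52, 5, "G", "A",
        (37, 19), (43, 0), 10242,
        expression_status="not_expressed",
    ),
}


def _scenario_seed(name: str, seed: int) -> int:
    return (seed * 1000 + sum(map(ord, name))) % (2**31 - 1)


def build_scenario(name: str, out_dir: str | Path, seed: int = 0) -> Scenario:
    """Write all fixture files for a named scenario and return it."""
    if name not in SCENARIO_NAMES:
        raise ScenarioError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    directory = Path(out_dir) / name
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(_scenario_seed(name, seed))
    if name == "negative_control":
        return _build_negative_control(directory, rng, seed)

    plan = _PLANS[name]
    contig = f"chr_{name}"
    gid, tid = name.upper().split("_")[0], f"TX_{name}"
    layout = _build_gene(rng, contig, plan.strand, plan.exon_lengths)
    transcript = _make_transcript(layout, tid, gid)
    n = len(plan.exon_lengths)
    position, ref, alt, boundary = _variant_genomics(
        layout, n, plan.side, plan.exon_index, plan.offset, plan.t_ref, plan.t_alt
    )

    scenario = Scenario(name, seed, directory, GenomeSequence({contig: layout.sequence}),
                        transcript, {})
    paths = scenario.paths
    _write_fasta(paths["fasta"], contig, layout.sequence)
    _write_gtf(paths["gtf"], transcript)

    # pileups: a few reference-only context sites plus the planted variant
    t_depth, t_alt_n = plan.tumor
    n_depth, n_alt_n = plan.normal
    context = [position - 30, position - 10, position + 10, position + 30]
    tumor_lines, normal_lines = [], []
    for p in sorted(context + [position]):
        base = layout.sequence[p - 1]
        if p == position:
            tumor_lines.append(_pileup_line(contig, p, ref, t_depth, alt, t_alt_n))
            normal_lines.append(_pileup_line(contig, p, ref, n_depth, alt, n_alt_n))
        else:
            tumor_lines.append(_pileup_line(contig, p, base, 30))
            normal_lines.append(_pileup_line(contig, p, base, 30))
    paths["tumor_pileup"].write_text("\n".join(tumor_lines) + "\n")
    paths["normal_pileup"].write_text("\n".join(normal_lines) + "\n")

    # RNA-seq SAM
    from .rna_quant import canonical_junction

    reads: list[str] = []
    for ei, ej, count in plan.junctions:
        if ej == ei + 1:
            de, ac = canonical_junction(transcript, ei)
        else:  # skip junction over the exons between ei and ej
            a = transcript.exon_by_index(ei)
            b = transcript.exon_by_index(ej)
            left, right = (a, b) if a[0] < b[0] else (b, a)
            de, ac = left[1], right[0]
        reads += _junction_reads(layout.sequence, contig, de, ac, count,
                                 f"jx_e{ei}e{ej}")
    if plan.cryptic is not None:
        shift, count = plan.cryptic
        # junction shifted into the mutated exon: canonical other end kept
        k = plan.exon_index
        de, _ = canonical_junction(transcript, k - 1)
        ac = boundary + shift
        reads += _junction_reads(layout.sequence, contig, de, ac, count, "jx_cryptic")
    if plan.spanning:
        reads += _spanning_reads(
            layout.sequence, contig, boundary, plan.spanning, "span",
            mutate_at=position, mutate_to=alt, n_mutant=plan.spanning_mutant,
        )
    paths["sam"].write_text(
        _sam_header(contig, len(layout.sequence)) + "\n".join(reads)
        + ("\n" if reads else "")
    )

    # exclusion resources: gene fully conserved, decoy segdup away from it,
    # decoy known variant at a context site
    span_lo, span_hi = transcript.span
    paths["conserved_bed"].write_text(f"{contig}\t{span_lo - 1}\t{span_hi}\n")
    paths["segdup_bed"].write_text(f"{contig}\t0\t50\n")
    paths["known"].write_text(f"{contig}\t{position - 30}\tA\tG\n")

    from .somatic_caller import integer_percent

    expected_outcomes = _expected_outcomes(plan)
    sign = "+" if plan.offset > 0 else ""
    truth = {
        "name": name,
        "seed": seed,
        "contig": contig,
        "transcript_id": tid,
        "strand": plan.strand,
        "variant": {
            "contig": contig, "position": position, "ref": ref, "alt": alt,
            "tumor_depth": t_depth, "tumor_alt_count": t_alt_n,
            "tumor_percent": integer_percent(t_alt_n, t_depth),
            "normal_depth": n_depth, "normal_alt_count": n_alt_n,
            "normal_percent": integer_percent(n_alt_n, n_depth),
        },
        "annotation": {
            "side": plan.side, "offset": plan.offset, "exon_index": plan.exon_index,
            "hgvs_c": f"c.{plan.cds_offset}{sign}{plan.offset}{ref}>{alt}",
        },
        "expect_loss": plan.expect_loss,
        "outcomes": expected_outcomes,
        "spanning": {"count": plan.spanning, "mutant_count": plan.spanning_mutant},
        "expression_status": plan.expression_status,
    }
    scenario.truth = truth
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return scenario


def _expected_outcomes(plan: _Plan) -> dict[str, int] | None:
    counts: dict[str, int] = {}
    k = plan.exon_index
    for ei, ej, c in plan.junctions:
        if ej == ei + 1 and ei in (k - 1, k):
            counts["wild_type"] = counts.get("wild_type", 0) + c
        elif (ei, ej) == (k - 1, k + 1):
            counts["exon_skip"] = counts.get("exon_skip", 0) + c
    if plan.spanning:
        counts["intron_retention"] = plan.spanning
    if plan.cryptic:
        counts["cryptic"] = plan.cryptic[1]
    total = sum(counts.values())
    if total == 0:
        return None
    # round half away from zero, as the caller does
    return {kind: (200 * c + total) // (2 * total) for kind, c in counts.items()}


def _build_negative_control(directory: Path, rng: np.random.Generator,
                            seed: int) -> Scenario:
    contig = "chr_negative"
    layout = _build_gene(rng, contig, "+", [120, 130, 110, 140])
    transcript = _make_transcript(layout, "TX_negative", "NEG1")
    scenario = Scenario("negative_control", seed, directory,
                        GenomeSequence({contig: layout.sequence}), transcript, {})
    paths = scenario.paths
    _write_fasta(paths["fasta"], contig, layout.sequence)
    _write_gtf(paths["gtf"], transcript)

    # identical tumor/normal pileups; one sub-threshold alternate site
    sub_pos = layout.exons[1][0] - 1  # acceptor -1 of exon 2, alt below count filter
    ref = layout.sequence[sub_pos - 1]
    alt = "A" if ref != "A" else "C"
    lines = []
    for p in sorted([layout.exons[0][0] + 5, sub_pos, layout.exons[2][0] + 5]):
        base = layout.sequence[p - 1]
        if p == sub_pos:
            lines.append(_pileup_line(contig, p, ref, 50, alt, 5))
        else:
            lines.append(_pileup_line(contig, p, base, 40))
    text = "\n".join(lines) + "\n"
    paths["tumor_pileup"].write_text(text)
    paths["normal_pileup"].write_text(text)

    from .rna_quant import canonical_junction

    reads = []
    for ei in (1, 2, 3):
        de, ac = canonical_junction(transcript, ei)
        reads += _junction_reads(layout.sequence, contig, de, ac, 10, f"jx_e{ei}")
    paths["sam"].write_text(_sam_header(contig, len(layout.sequence))
                            + "\n".join(reads) + "\n")
    span_lo, span_hi = transcript.span
    paths["conserved_bed"].write_text(f"{contig}\t{span_lo - 1}\t{span_hi}\n")
    paths["segdup_bed"].write_text(f"{contig}\t0\t50\n")
    paths["known"].write_text("")
    truth = {
        "name": "negative_control", "seed": seed, "contig": contig,
        "transcript_id": "TX_negative", "strand": "+",
        "variant": None, "annotation": None, "expect_loss": False,
        "outcomes": None, "spanning": {"count": 0, "mutant_count": 0},
        "expression_status": "ok",
    }
    scenario.truth = truth
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return scenario


# -- randomized planted pileups -------------------------------------------


def _brute_force_callable(t_depth: int, t_alt: int, t_quals: list[int],
                          n_depth: int, n_alt: int) -> bool:
    """Independent re-statement of the somatic filters, used only to label truth."""
    import math

    q_alt = sum(1 for q in t_quals if q >= 30)
    if t_depth < 20 or q_alt < 6:
        return False
    pct = math.floor(100 * q_alt / t_depth + 0.5)
    if pct < 25:
        return False
    if n_depth < 1:
        return False
    n_pct = math.floor(100 * n_alt / n_depth + 0.5) if n_depth else 0
    return n_pct <= 10


def random_scenario(
    seed: int,
    out_dir: str | Path,
    n_variants: int = 50,
    depth_range: tuple[int, int] = (10, 120),
    fraction_range: tuple[int, int] = (5, 95),
) -> Scenario:
    """Randomized planted tumor/normal pileups with brute-force truth labels."""
    if depth_range[0] < 1 or depth_range[0] > depth_range[1]:
        raise ScenarioError("invalid depth range")
    if not (0 <= fraction_range[0] <= fraction_range[1] <= 100):
        raise ScenarioError("invalid fraction range")
    directory = Path(out_dir) / f"random_{seed}"
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    contig = "chr_rand"
    layout = _build_gene(rng, contig, "+", [2000, 2000], intron_length=400)
    transcript = _make_transcript(layout, "TX_rand", "RAND1")
    positions = sorted(
        rng.choice(np.arange(101, len(layout.sequence) - 100), n_variants,
                   replace=False).tolist()
    )
    tumor_lines, normal_lines, truth_variants = [], [], []
    bases = "ACGT"
    for pos in positions:
        ref = layout.sequence[pos - 1]
        alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
        t_depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
        frac = int(rng.integers(fraction_range[0], fraction_range[1] + 1))
        t_alt = min(t_depth, round(t_depth * frac / 100))
        # some alt calls dip below the quality threshold
        t_quals = [20 if rng.random() < 0.15 else 40 for _ in range(t_alt)]
        n_depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
        n_alt = int(rng.integers(0, 4)) if rng.random() < 0.3 else 0
        n_alt = min(n_alt, n_depth)
        tumor_lines.append(_pileup_line(contig, pos, ref, t_depth, alt, t_alt,
                                        alt_quals=t_quals))
        normal_lines.append(_pileup_line(contig, pos, ref, n_depth, alt, n_alt))
        truth_variants.append({
            "position": pos, "ref": ref, "alt": alt,
            "tumor_depth": t_depth, "tumor_alt_count": t_alt,
            "normal_depth": n_depth, "normal_alt_count": n_alt,
            "callable": _brute_force_callable(t_depth, t_alt, t_quals,
                                              n_depth, n_alt),
        })
    scenario = Scenario(f"random_{seed}", seed, directory,
                        GenomeSequence({contig: layout.sequence}), transcript, {})
    paths = scenario.paths
    _write_fasta(paths["fasta"], contig, layout.sequence)
    _write_gtf(paths["gtf"], transcript)
    paths["tumor_pileup"].write_text("\n".join(tumor_lines) + "\n")
    paths["normal_pileup"].write_text("\n".join(normal_lines) + "\n")
    truth = {"name": scenario.name, "seed": seed, "contig": contig,
             "variants": truth_variants}
    scenario.truth = truth
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return scenario
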