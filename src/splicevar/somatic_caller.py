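"""Hard-filter somatic substitution caller over paired tumor/normal pileups.

A site is called somatic when the tumor sample shows a well-supported
non-reference allele and the matched normal is (near-)reference at the same
position. All thresholds are hard cut-offs — there is no genotype likelihood
model — mirroring a cross-match design:

* tumor depth >= 20, alternate read count >= 6, alternate fraction >= 25%
  (integer percent), with only Phred >= 30 calls counted toward the allele;
* the normal may carry the alternate at up to 10% (integer percent) and must
  be covered at all (min_normal_depth, default 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .pileup_io import PileupSite


class SomaticCallError(ValueError):
    pass


@dataclass(frozen=True)
class CallerParams:
    min_tumor_depth: int = 20
    min_alt_count: int = 6
    min_alt_percent: int = 25
    min_base_quality: int = 30
    max_normal_alt_percent: int = 10
    min_normal_depth: int = 1

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise SomaticCallError(f"{name} must be non-negative")
        for name in ("min_alt_percent", "max_normal_alt_percent"):
            if not 0 <= getattr(self, name) <= 100:
                raise SomaticCallError(f"{name} must be a percent in [0, 100]")


@dataclass(frozen=True)
class SomaticVariant:
    contig: str
    position: int
    ref_base: str
    alt_base: str
    tumor_depth: int
    tumor_alt_count: int
    tumor_percent: int
    normal_depth: int
    normal_alt_count: int
    normal_percent: int
    multi_allelic: bool = False

    @property
    def locus(self) -> str:
        """Two-number locus string: '<contig>,<pos-1>,<pos>,1,REF/ALT'."""
        return (
            f"{self.contig},{self.position - 1},{self.position},1,"
            f"{self.ref_base}/{self.alt_base}"
        )


def integer_percent(count: int, depth: int) -> int:
    """100*count/depth rounded half away from zero, as printed fractions are."""
    if depth <= 0:
        raise SomaticCallError("percent undefined at zero depth")
    if not 0 <= count <= depth:
        raise SomaticCallError(f"count {count} outside [0, depth={depth}]")
    return (200 * count + depth) // (2 * depth)


def allele_counts(site: PileupSite, min_base_quality: int) -> dict[str, int]:
    """Count A/C/G/T calls passing the base-quality filter ('*' and N excluded)."""
    counts: dict[str, int] = {}
    for call, qual in zip(site.calls, site.quals):
        if qual < min_base_quality or call.base not in "ACGT":
            continue
        counts[call.base] = counts.get(call.base, 0) + 1
    return counts


def _top_alt(counts: dict[str, int], ref_base: str) -> tuple[str | None, int, bool]:
    """Highest-count non-reference allele; ties go to the smaller base."""
    alts = sorted(
        ((b, c) for b, c in counts.items() if b != ref_base and c > 0),
        key=lambda bc: (-bc[1], bc[0]),
    )
    if not alts:
        return None, 0, False
    multi = len(alts) > 1 and alts[1][1] == alts[0][1]
    return alts[0][0], alts[0][1], multi


def call_site(
    tumor: PileupSite,
    normal: PileupSite | None,
    params: CallerParams = CallerParams(),
) -> SomaticVariant | None:
    """Apply the somatic filters to one tumor site with its matched normal."""
    if normal is not None and tumor.key != normal.key:
        raise SomaticCallError(
            f"tumor {tumor.contig}:{tumor.position} paired with "
            f"normal {normal.contig}:{normal.position}"
        )
    if tumor.depth < params.min_tumor_depth:
        return None
    t_counts = allele_counts(tumor, params.min_base_quality)
    alt, alt_count, multi = _top_alt(t_counts, tumor.ref_base)
    if alt is None or alt_count < params.min_alt_count:
        return None
    t_percent = integer_percent(alt_count, tumor.depth)
    if t_percent < params.min_alt_percent:
        return None
    if normal is None or normal.depth < params.min_normal_depth:
        return None
    n_alt = allele_counts(normal, params.min_base_quality).get(alt, 0)
    n_percent = integer_percent(n_alt, normal.depth) if normal.depth else 0
    if n_percent > params.max_normal_alt_percent:
        return None
    return SomaticVariant(
        tumor.contig, tumor.position, tumor.ref_base, alt,
        tumor.depth, alt_count, t_percent,
        normal.depth, n_alt, n_percent,
        multi_allelic=multi,
    )


def _check_sorted(sites: Iterable[PileupSite], label: str) -> Iterator[PileupSite]:
    contig_rank: dict[str, int] = {}
    last: tuple[int, int] | None = None
    for site in sites:
        rank = contig_rank.setdefault(site.contig, len(contig_rank))
        key = (rank, site.position)
        if last is not None and key <= last:
            raise SomaticCallError(
                f"{label} pileup not sorted at {site.contig}:{site.position}"
            )
        last = key
        yield site


def cross_match(
    tumor_sites: Iterable[PileupSite],
    normal_sites: Iterable[PileupSite],
    params: CallerParams = CallerParams(),
) -> list[SomaticVariant]:
    """Pair sorted tumor/normal pileups by position and emit somatic calls in order."""
    normal_by_key = {s.key: s for s in _check_sorted(normal_sites, "normal")}
    variants = []
    for tumor in _check_sorted(tumor_sites, "tumor"):
        variant = call_site(tumor, normal_by_key.get(tumor.key), params)
        if variant is not None:
            variants.append(variant)
    return variants


def variants_to_tsv(variants: Iterable[SomaticVariant]) -> str:
    """Tab-separated report with locus and tumor(normal) depth/count/percent pairs."""
    lines = [
        "locus\tref\talt\tcoverage_t\tcoverage_n\talt_count_t\talt_count_n\t"
        "percent_t\tpercent_n\tmulti_allelic"
    ]
    for v in variants:
        lines.append(
            f"{v.locus}\t{v.ref_base}\t{v.alt_base}\t{v.tumor_depth}\t{v.normal_depth}"
            f"\t{v.tumor_alt_count}\t{v.normal_alt_count}\t{v.tumor_percent}"
            f"\t{v.normal_percent}\t{int(v.multi_allelic)}"
        )
    return "\n".join(lines) + "\n"


def variants_to_vcf(variants: Iterable[SomaticVariant], contig_lengths: dict[str, int] | None = None) -> str:
    """Minimal VCF 4.2 rendering carrying tumor/normal counts in INFO."""
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=TDP,Number=1,Type=Integer,Description="Tumor depth">',
        '##INFO=<ID=TAC,Number=1,Type=Integer,Description="Tumor alt count">',
        '##INFO=<ID=TPC,Number=1,Type=Integer,Description="Tumor alt integer percent">',
        '##INFO=<ID=NDP,Number=1,Type=Integer,Description="Normal depth">',
        '##INFO=<ID=NAC,Number=1,Type=Integer,Description="Normal alt count">',
        '##INFO=<ID=NPC,Number=1,Type=Integer,Description="Normal alt integer percent">',
    ]
    for contig, length in (contig_lengths or {}).items():
        header.append(f"##contig=<ID={contig},length={length}>")
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in variants:
        info = (
            f"TDP={v.tumor_depth};TAC={v.tumor_alt_count};TPC={v.tumor_percent};"
            f"NDP={v.normal_depth};NAC={v.normal_alt_count};NPC={v.normal_percent}"
        )
        header.append(
            f"{v.contig}\t{v.position}\t.\t{v.ref_base}\t{v.alt_base}\t.\tPASS\t{info}"
        )
    return "\n".join(header) + "\n"
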