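"""Reader/writer for the legacy 6-column samtools pileup text format.

Columns: contig, 1-based position, reference base, depth, read-base string,
base-quality string. The read-base string grammar handled here:

* ``.`` / ``,``   — reference match on the forward / reverse strand
* ``ACGTN`` / ``acgtn`` — mismatch on the forward / reverse strand
* ``^X``          — read start; ``X`` encodes mapping quality and is discarded
* ``$``           — read end marker, discarded
* ``+n<seq>`` / ``-n<seq>`` — insertion/deletion text, parsed past, not called
* ``*``           — deletion placeholder occupying one read slot

Qualities are Phred, ASCII offset 33. Indels are never called downstream, so
their sequence text is skipped; ``*`` keeps its quality slot but never counts
as a substitution.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

MAX_PHRED = 93


class PileupFormatError(ValueError):
    pass


@dataclass(frozen=True)
class PileupCall:
    """One read's call at a site: the base ('*' for a deletion slot) and strand."""

    base: str
    forward: bool


@dataclass
class PileupSite:
    contig: str
    position: int
    ref_base: str
    depth: int
    calls: list[PileupCall] = field(default_factory=list)
    quals: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.calls) != self.depth or len(self.quals) != self.depth:
            raise PileupFormatError(
                f"{self.contig}:{self.position}: decoded {len(self.calls)} calls / "
                f"{len(self.quals)} quals for depth {self.depth}"
            )
        for q in self.quals:
            if not 0 <= q <= MAX_PHRED:
                raise PileupFormatError(
                    f"{self.contig}:{self.position}: Phred {q} outside [0, {MAX_PHRED}]"
                )

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.position)


def _decode_bases(text: str, ref_base: str, where: str) -> list[PileupCall]:
    calls: list[PileupCall] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c == "^":
            i += 2  # skip the mapping-quality character
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            i += 1
            num = ""
            while i < n and text[i].isdigit():
                num += text[i]
                i += 1
            if not num:
                raise PileupFormatError(f"{where}: indel without length after {c!r}")
            i += int(num)  # skip indel sequence
            continue
        if c == ".":
            calls.append(PileupCall(ref_base.upper(), True))
        elif c == ",":
            calls.append(PileupCall(ref_base.upper(), False))
        elif c in "ACGTN":
            calls.append(PileupCall(c, True))
        elif c in "acgtn":
            calls.append(PileupCall(c.upper(), False))
        elif c == "*":
            calls.append(PileupCall("*", True))
        else:
            raise PileupFormatError(f"{where}: unexpected character {c!r} in base string")
        i += 1
    return calls


def parse_pileup(source: str | Path | io.TextIOBase) -> Iterator[PileupSite]:
    """Stream PileupSite records from a pileup file (gzip-transparent) or handle."""
    if isinstance(source, (str, Path)):
        p = str(source)
        handle = gzip.open(p, "rt") if p.endswith(".gz") else open(p)
        close = True
    else:
        handle, close = source, False
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise PileupFormatError(
                    f"line {lineno}: expected 6 tab-separated columns, got {len(fields)}"
                )
            contig, pos_s, ref, depth_s, bases, quals_s = fields
            where = f"line {lineno} ({contig}:{pos_s})"
            try:
                position, depth = int(pos_s), int(depth_s)
            except ValueError:
                raise PileupFormatError(f"{where}: non-integer position/depth") from None
            calls = _decode_bases(bases, ref, where)
            quals = [ord(ch) - 33 for ch in quals_s]
            if len(calls) != depth or len(quals) != depth:
                raise PileupFormatError(
                    f"{where}: depth {depth} but decoded {len(calls)} calls "
                    f"and {len(quals)} qualities"
                )
            yield PileupSite(contig, position, ref.upper(), depth, calls, quals)
    finally:
        if close:
            handle.close()


def encode_site(site: PileupSite) -> str:
    """Canonical single-line encoding: '.'/',' for ref matches, explicit bases else."""
    bases = []
    for call in site.calls:
        if call.base == "*":
            bases.append("*")
        elif call.base == site.ref_base:
            bases.append("." if call.forward else ",")
        else:
            bases.append(call.base if call.forward else call.base.lower())
    quals = "".join(chr(q + 33) for q in site.quals)
    return "\t".join(
        [site.contig, str(site.position), site.ref_base, str(site.depth),
         "".join(bases), quals]
    )


def write_pileup(sites: Iterable[PileupSite], sink: str | Path | io.TextIOBase) -> None:
    """Write sites in canonical encoding; parse(write(x)) == x for substitution sites."""
    if isinstance(sink, (str, Path)):
        handle, close = open(sink, "w"), True
    else:
        handle, close = sink, False
    try:
        for site in sites:
            handle.write(encode_site(site) + "\n")
    finally:
        if close:
            handle.close()
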