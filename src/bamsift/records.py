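"""Alignment records and SAM flag-bit algebra.

An :class:`AlignmentFields` holds the eleven mandatory SAM columns plus the
optional TAG:TYPE:VALUE fields, all kept in their text representation so
that parse → serialize is byte-identical.  The flag helpers translate
between the integer FLAG column and the twelve standard bit names.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable

from .errors import MalformedInputError, ValidationError

#: The 12 standard SAM flag bits, by conventional short name.
FLAG_BITS: dict[str, int] = {
    "paired": 0x1,
    "proper_pair": 0x2,
    "unmapped": 0x4,
    "mate_unmapped": 0x8,
    "reverse": 0x10,
    "mate_reverse": 0x20,
    "first_in_template": 0x40,
    "second_in_template": 0x80,
    "secondary": 0x100,
    "qc_fail": 0x200,
    "duplicate": 0x400,
    "supplementary": 0x800,
}

_BIT_NAMES = {bit: name for name, bit in FLAG_BITS.items()}

_CIGAR_RE = re.compile(r"^(\d+[MIDNSHP=X])+$")


def encode_flag(names: Iterable[str]) -> int:
    """Combine flag bit names into the integer FLAG value.

    >>> encode_flag({"paired", "proper_pair", "reverse", "first_in_template"})
    83
    """
    flag = 0
    for name in names:
        try:
            flag |= FLAG_BITS[name]
        except KeyError:
            raise ValidationError(
                f"unknown SAM flag bit name {name!r}; "
                f"expected one of {sorted(FLAG_BITS)}"
            ) from None
    return flag


def decode_flag(flag: int) -> set[str]:
    """Names of the standard bits set in ``flag``.

    Accepts the full 16-bit FLAG range; bits above 0x800 are reserved by
    the format and carry no name, so they are not reported.
    """
    if not 0 <= flag < 2 ** 16:
        raise ValidationError(f"flag {flag} outside [0, 65536)")
    return {name for name, bit in FLAG_BITS.items() if flag & bit}


@dataclass(frozen=True)
class AlignmentFields:
    """One alignment, mandatory SAM columns plus optional tags.

    ``pos`` and ``pnext`` are 1-based as in SAM text (0 marks the unmapped
    placeholder).  ``tlen`` keeps its sign: positive for the leftmost mate,
    negative for the rightmost.  Tags are ``(tag, type, value)`` triples
    with the value kept as its SAM text form.
    """

    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: str
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"
    tags: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self):
        if not 0 <= self.flag < 2 ** 16:
            raise ValidationError(f"flag {self.flag} outside [0, 65536)")
        if self.pos < 0:
            raise ValidationError(f"pos {self.pos} negative")
        if self.cigar != "*" and not _CIGAR_RE.match(self.cigar):
            raise ValidationError(f"invalid CIGAR {self.cigar!r}")

    # -- flag convenience ------------------------------------------------
    def has_flag(self, name: str) -> bool:
        return bool(self.flag & FLAG_BITS[name])

    @property
    def is_unmapped(self) -> bool:
        return self.has_flag("unmapped")

    # -- text (de)serialization -----------------------------------------
    def tag_block(self) -> str:
        """Optional tags serialized exactly as SAM columns, tab-joined."""
        return "\t".join(f"{t}:{ty}:{v}" for t, ty, v in self.tags)

    def to_sam_line(self) -> str:
        cols = [
            self.qname,
            str(self.flag),
            self.rname,
            str(self.pos),
            str(self.mapq),
            self.cigar,
            self.rnext,
            str(self.pnext),
            str(self.tlen),
            self.seq,
            self.qual,
        ]
        if self.tags:
            cols.append(self.tag_block())
        return "\t".join(cols)

    @classmethod
    def from_sam_line(cls, line: str) -> "AlignmentFields":
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 11:
            raise MalformedInputError(
                f"SAM line has {len(cols)} columns, need at least 11"
            )
        tags = []
        for col in cols[11:]:
            parts = col.split(":", 2)
            if len(parts) != 3:
                raise MalformedInputError(f"malformed optional tag {col!r}")
            tags.append((parts[0], parts[1], parts[2]))
        try:
            return cls(
                qname=cols[0],
                flag=int(cols[1]),
                rname=cols[2],
                pos=int(cols[3]),
                mapq=int(cols[4]),
                cigar=cols[5],
                rnext=cols[6],
                pnext=int(cols[7]),
                tlen=int(cols[8]),
                seq=cols[9],
                qual=cols[10],
                tags=tuple(tags),
            )
        except ValueError as exc:
            raise MalformedInputError(str(exc)) from exc

    def with_(self, **changes) -> "AlignmentFields":
        return replace(self, **changes)


@dataclass(frozen=True)
class IafRecord:
    """One line of individual alignment format (IAF).

    IAF is header-free SAM with two leading columns — the individual the
    alignment came from and the region label of the job that produced it —
    so every line is self-contained and grepable by sample.
    """

    individual_id: str
    region_label: str
    fields: AlignmentFields

    def to_line(self) -> str:
        return f"{self.individual_id}\t{self.region_label}\t{self.fields.to_sam_line()}"

    @classmethod
    def from_line(cls, line: str, line_number: int = 0) -> "IafRecord":
        from .errors import IafParseError

        cols = line.rstrip("\n").split("\t", 2)
        if len(cols) != 3:
            raise IafParseError(
                line_number, f"expected individual, region and SAM columns; got {len(cols)} fields"
            )
        try:
            fields = AlignmentFields.from_sam_line(cols[2])
        except MalformedInputError as exc:
            raise IafParseError(line_number, str(exc)) from exc
        return cls(individual_id=cols[0], region_label=cols[1], fields=fields)
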