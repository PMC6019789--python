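"""Filter specifications and the per-record inclusion predicate.

A :class:`FilterSpec` bundles every supported criterion: minimum mapping
quality, flag bits to require or exclude, a template-length window applied
to \\|TLEN\\| (so both mates of a pair get the same verdict regardless of
sign), a nucleotide pattern the sequence must contain, a full-match regex
on the CIGAR string, a regex over the serialized optional-tag block,
genomic regions, and a cohort subset.  An absent criterion never excludes
a record, so the all-empty spec is the identity filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ValidationError
from .records import AlignmentFields

_NUCLEOTIDES = frozenset("ACGTN")


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive genomic interval."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise ValidationError(f"region start {self.start} < 1")
        if self.start > self.end:
            raise ValidationError(
                f"region start {self.start} > end {self.end} on {self.chromosome}"
            )

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "Region":
        """Parse ``chrom:start-end`` (commas in numbers allowed)."""
        m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", text.strip())
        if not m:
            raise ValidationError(f"cannot parse region {text!r}; expected chrom:start-end")
        return cls(m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", "")))


def in_regions(record: AlignmentFields, regions: Sequence[Region]) -> bool:
    """Start-containment region test.

    A record belongs to a region iff its leftmost position lies inside the
    interval (no CIGAR-length arithmetic).  Empty region list means no
    constraint.  Unmapped records (or pos 0 placeholders) fail any
    non-empty region constraint.
    """
    if not regions:
        return True
    if record.is_unmapped or record.pos == 0:
        return False
    return any(
        r.chromosome == record.rname and r.start <= record.pos <= r.end
        for r in regions
    )


@dataclass(frozen=True)
class FilterSpec:
    """The full predicate of a filter job.  All criteria optional."""

    mapq_min: Optional[int] = None
    flag_required: Optional[int] = None
    flag_excluded: Optional[int] = None
    tlen_min: Optional[int] = None
    tlen_max: Optional[int] = None
    seq_pattern: Optional[str] = None
    cigar_regex: Optional[str] = None
    tag_regex: Optional[str] = None
    regions: tuple[Region, ...] = ()
    samples: frozenset[str] = frozenset()
    populations: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.mapq_min is not None and self.mapq_min < 0:
            raise ValidationError("mapq_min must be >= 0")
        if (
            self.tlen_min is not None
            and self.tlen_max is not None
            and self.tlen_min > self.tlen_max
        ):
            raise ValidationError(
                f"tlen_min {self.tlen_min} > tlen_max {self.tlen_max}"
            )
        if (
            self.flag_required is not None
            and self.flag_excluded is not None
            and self.flag_required & self.flag_excluded
        ):
            raise ValidationError(
                "flag_required and flag_excluded share set bits: "
                f"{self.flag_required & self.flag_excluded:#x}"
            )
        if self.seq_pattern is not None:
            bad = set(self.seq_pattern.upper()) - _NUCLEOTIDES
            if bad:
                raise ValidationError(
                    f"seq_pattern contains non-nucleotide characters {sorted(bad)}"
                )
        # compile regexes once, at construction; a malformed regex is a
        # spec error, never a per-record one
        for attr in ("cigar_regex", "tag_regex"):
            pattern = getattr(self, attr)
            if pattern is not None:
                try:
                    compiled = re.compile(pattern)
                except re.error as exc:
                    raise ValidationError(f"invalid {attr} {pattern!r}: {exc}") from exc
                object.__setattr__(self, "_" + attr, compiled)
            else:
                object.__setattr__(self, "_" + attr, None)
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "samples", frozenset(self.samples))
        object.__setattr__(self, "populations", frozenset(self.populations))

    # -- config round-trip ----------------------------------------------
    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "FilterSpec":
        """Build from a flat config mapping (keys mirror field names).

        Flag values accept decimal or 0x-hex strings; regions accept
        ``chrom:start-end`` strings or ``(chrom, start, end)`` triples.
        """
        kw: dict = {}
        for key in ("mapq_min", "tlen_min", "tlen_max"):
            if mapping.get(key) is not None:
                kw[key] = int(mapping[key])
        for key in ("flag_required", "flag_excluded"):
            val = mapping.get(key)
            if val is not None:
                kw[key] = int(val, 0) if isinstance(val, str) else int(val)
        for key in ("seq_pattern", "cigar_regex", "tag_regex"):
            if mapping.get(key) is not None:
                kw[key] = str(mapping[key])
        regions = []
        for item in mapping.get("regions") or []:
            if isinstance(item, str):
                regions.append(Region.parse(item))
            else:
                chrom, start, end = item
                regions.append(Region(str(chrom), int(start), int(end)))
        kw["regions"] = tuple(regions)
        for key in ("samples", "populations"):
            val = mapping.get(key)
            if val:
                if isinstance(val, str):
                    val = [v for v in val.split(",") if v]
                kw[key] = frozenset(str(v) for v in val)
        unknown = set(mapping) - {
            "mapq_min", "flag_required", "flag_excluded", "tlen_min", "tlen_max",
            "seq_pattern", "cigar_regex", "tag_regex", "regions", "samples",
            "populations",
        }
        if unknown:
            raise ValidationError(f"unknown filter keys {sorted(unknown)}")
        return cls(**kw)

    def to_mapping(self) -> dict:
        out: dict = {}
        for key in (
            "mapq_min", "flag_required", "flag_excluded", "tlen_min", "tlen_max",
            "seq_pattern", "cigar_regex", "tag_regex",
        ):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        if self.regions:
            out["regions"] = [str(r) for r in self.regions]
        if self.samples:
            out["samples"] = sorted(self.samples)
        if self.populations:
            out["populations"] = sorted(self.populations)
        return out

    def region_label(self) -> str:
        """Label embedded in IAF output; 'all' when no region constraint."""
        return ",".join(str(r) for r in self.regions) if self.regions else "all"


def matches_filter(record: AlignmentFields, spec: FilterSpec) -> bool:
    """True iff every *present* criterion of ``spec`` holds for ``record``.

    Cohort criteria (samples, populations) operate on whole files and are
    applied at job-planning time, not here.  Records with CIGAR ``*`` or
    the unmapped bit fail any cigar constraint (there is no alignment to
    constrain) but remain eligible under flag-only filters.
    """
    if spec.mapq_min is not None and record.mapq < spec.mapq_min:
        return False
    if spec.flag_required is not None and (record.flag & spec.flag_required) != spec.flag_required:
        return False
    if spec.flag_excluded is not None and (record.flag & spec.flag_excluded) != 0:
        return False
    tlen = abs(record.tlen)
    if spec.tlen_min is not None and tlen < spec.tlen_min:
        return False
    if spec.tlen_max is not None and tlen > spec.tlen_max:
        return False
    if spec.seq_pattern is not None:
        if spec.seq_pattern.upper() not in record.seq.upper():
            return False
    if spec.cigar_regex is not None:
        if record.cigar == "*" or record.is_unmapped:
            return False
        if not spec._cigar_regex.fullmatch(record.cigar):  # type: ignore[attr-defined]
            return False
    if spec.tag_regex is not None:
        if not spec._tag_regex.search(record.tag_block()):  # type: ignore[attr-defined]
            return False
    if not in_regions(record, spec.regions):
        return False
    return True
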