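"""Reading and writing alignments: BAM/SAM sources, IAF, the manifest.

BAM access goes through pysam/htslib, which also understands HTTP(S) and
FTP locators, so a :class:`DataSource` is a thin descriptor around a
locator string plus a random-access capability bit.  Random-access
(region) requests against a source without a reachable index are rejected
outright rather than silently degraded to a full download.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pysam

from .errors import (
    IafParseError,
    MalformedInputError,
    SourceUnavailableError,
    ValidationError,
)
from .filters import Region, in_regions
from .records import AlignmentFields, IafRecord

_REMOTE_SCHEMES = {"http": "http-url", "https": "http-url", "ftp": "ftp-url"}


@dataclass(frozen=True)
class DataSource:
    """Where a BAM lives and whether it can serve region queries."""

    kind: str  # local-path | http-url | ftp-url
    locator: str
    supports_random_access: bool = False

    def __post_init__(self):
        if not self.locator:
            raise ValidationError("empty source locator")
        if self.kind not in ("local-path", "http-url", "ftp-url"):
            raise ValidationError(f"unknown source kind {self.kind!r}")

    @classmethod
    def from_locator(cls, locator: Union[str, Path]) -> "DataSource":
        """Classify a locator and probe for an index sidecar.

        For local paths the ``.bai`` sidecar (or ``.bam.bai``) determines
        random-access support.  Remote sources are conservatively marked
        non-random-access; callers that know an index URL is reachable can
        construct the source explicitly.
        """
        loc = str(locator)
        scheme = loc.split("://", 1)[0].lower() if "://" in loc else ""
        if scheme in _REMOTE_SCHEMES:
            return cls(kind=_REMOTE_SCHEMES[scheme], locator=loc)
        has_index = os.path.exists(loc + ".bai") or os.path.exists(
            os.path.splitext(loc)[0] + ".bai"
        )
        return cls(kind="local-path", locator=loc, supports_random_access=has_index)

    def size_bytes(self) -> int:
        """On-disk size for local sources; 0 when unknown (remote)."""
        if self.kind == "local-path":
            try:
                return os.path.getsize(self.locator)
            except OSError:
                return 0
        return 0


def _open_alignment_file(source: DataSource) -> pysam.AlignmentFile:
    if source.kind == "local-path" and not os.path.exists(source.locator):
        raise SourceUnavailableError(f"no such file: {source.locator}")
    try:
        return pysam.AlignmentFile(source.locator, "rb")
    except (OSError, IOError) as exc:
        raise SourceUnavailableError(f"cannot open {source.locator}: {exc}") from exc
    except ValueError as exc:
        raise MalformedInputError(f"cannot parse {source.locator}: {exc}") from exc


def stream_alignments(
    source: DataSource, regions: Sequence[Region] = ()
) -> Iterator[AlignmentFields]:
    """Stream records from a BAM source, optionally restricted to regions.

    With regions the source must support random access; records are
    yielded in file order within each region and restricted by the
    start-containment convention of :func:`bamsift.filters.in_regions`
    (the index fetch over-returns reads that merely overlap).
    """
    if regions and not source.supports_random_access:
        raise ValidationError(
            f"region query against non-indexed source {source.locator}; "
            "provide an index or stream the whole file"
        )
    af = _open_alignment_file(source)
    try:
        if not regions:
            for seg in af.fetch(until_eof=True):
                yield AlignmentFields.from_sam_line(seg.to_string())
        else:
            seen: set[tuple] = set()
            for region in regions:
                try:
                    it = af.fetch(region.chromosome, region.start - 1, region.end)
                except ValueError as exc:
                    raise MalformedInputError(
                        f"bad region {region} for {source.locator}: {exc}"
                    ) from exc
                for seg in it:
                    rec = AlignmentFields.from_sam_line(seg.to_string())
                    if not in_regions(rec, [region]):
                        continue
                    key = (rec.qname, rec.flag, rec.rname, rec.pos)
                    if key in seen:  # overlapping request regions
                        continue
                    seen.add(key)
                    yield rec
    finally:
        af.close()


def read_header(source: DataSource) -> pysam.AlignmentHeader:
    af = _open_alignment_file(source)
    try:
        return af.header
    finally:
        af.close()


# ---------------------------------------------------------------------------
# Individual alignment format
# ---------------------------------------------------------------------------

def write_iaf(
    records: Iterable[AlignmentFields],
    individual_id: str,
    region_label: str,
    destination: Union[str, Path],
) -> int:
    """Write records as IAF lines; returns the record count.

    Each line is individual, region, then the 11 mandatory SAM columns and
    any optional tags, tab-joined, no header.  On a write failure the
    partial output file is removed.
    """
    path = Path(destination)
    count = 0
    try:
        with open(path, "w") as fh:
            for rec in records:
                fh.write(IafRecord(individual_id, region_label, rec).to_line())
                fh.write("\n")
                count += 1
    except OSError as exc:
        path.unlink(missing_ok=True)
        raise SourceUnavailableError(f"write to {path} failed: {exc}") from exc
    return count


def read_iaf(source: Union[str, Path, Iterable[str]]) -> Iterator[IafRecord]:
    """Parse IAF text into records; malformed lines raise with their number."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from _parse_iaf_lines(fh)
    else:
        yield from _parse_iaf_lines(source)


def _parse_iaf_lines(lines: Iterable[str]) -> Iterator[IafRecord]:
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        yield IafRecord.from_line(line, line_number=lineno)


# ---------------------------------------------------------------------------
# BAM output
# ---------------------------------------------------------------------------

def write_bam(
    records: Iterable[AlignmentFields],
    template_header: Union[pysam.AlignmentHeader, dict],
    destination: Union[str, Path],
) -> int:
    """Write records to a valid BAM; returns the record count.

    Every record's reference name must exist in the header, otherwise the
    record is a validation error (nothing is silently dropped).
    """
    path = str(destination)
    if isinstance(template_header, dict):
        template_header = pysam.AlignmentHeader.from_dict(template_header)
    references = set(template_header.references)
    count = 0
    with pysam.AlignmentFile(path, "wb", header=template_header) as out:
        for rec in records:
            if rec.rname != "*" and rec.rname not in references:
                raise ValidationError(
                    f"record {rec.qname} references unknown chromosome {rec.rname!r}"
                )
            seg = pysam.AlignedSegment.fromstring(rec.to_sam_line(), template_header)
            out.write(seg)
            count += 1
    return count


# ---------------------------------------------------------------------------
# Sample manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleInfo:
    file: str
    individual_id: str
    population: str
    superpopulation: str


class Manifest:
    """Tab-separated cohort manifest: file, individual, population, superpopulation.

    Population selectors resolve against both the population and
    superpopulation columns; a ``nonX`` selector is the complement of X.
    """

    def __init__(self, samples: Sequence[SampleInfo]):
        self.samples = list(samples)
        self._by_individual = {s.individual_id: s for s in self.samples}
        if len(self._by_individual) != len(self.samples):
            raise ValidationError("duplicate individual ids in manifest")

    @classmethod
    def read(cls, path: Union[str, Path]) -> "Manifest":
        samples = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) != 4:
                    raise MalformedInputError(
                        f"{path} line {lineno}: expected 4 columns, got {len(cols)}"
                    )
                samples.append(SampleInfo(*cols))
        return cls(samples)

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for s in self.samples:
                fh.write(
                    f"{s.file}\t{s.individual_id}\t{s.population}\t{s.superpopulation}\n"
                )

    def __len__(self) -> int:
        return len(self.samples)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_individual

    @property
    def individuals(self) -> list[str]:
        return [s.individual_id for s in self.samples]

    def info(self, individual_id: str) -> SampleInfo:
        try:
            return self._by_individual[individual_id]
        except KeyError:
            raise ValidationError(
                f"individual {individual_id!r} absent from manifest"
            ) from None

    def population_codes(self) -> set[str]:
        out: set[str] = set()
        for s in self.samples:
            out.add(s.population)
            out.add(s.superpopulation)
        return out

    def select(self, selector: str) -> set[str]:
        """Individuals matching a population/superpopulation selector.

        ``nonEUR`` selects everyone whose population and superpopulation
        both differ from ``EUR``.
        """
        negate = selector.startswith("non") and selector[3:] in self.population_codes()
        code = selector[3:] if negate else selector
        if code not in self.population_codes():
            raise ValidationError(f"unknown population code {code!r}")
        chosen = {
            s.individual_id
            for s in self.samples
            if code in (s.population, s.superpopulation)
        }
        if negate:
            return set(self.individuals) - chosen
        return chosen

    def subset(self, samples: frozenset = frozenset(), populations: frozenset = frozenset()) -> set[str]:
        """Cohort subset for a FilterSpec: union of sample ids and population codes;
        empty criteria mean everyone."""
        if not samples and not populations:
            return set(self.individuals)
        chosen: set[str] = set()
        for sid in samples:
            if sid in self:
                chosen.add(sid)
        for code in populations:
            chosen |= self.select(code)
        return chosen
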