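"""Inversion-signature scan over TLEN-reduced alignment sets.

An inversion changes the strand of one mate, so after alignment both reads
of a spanning pair carry the same orientation bit (0x10 equals 0x20) and
the observed template length is inflated by the event span.  The scan
takes alignments that already passed a minimum-|TLEN| reduction filter,
keeps same-strand pairs, discards impure alignments (CIGAR not a single
full-length match, or any XA alternative-alignment tag), requires each
alignment's kb-scale (start, |TLEN|) bin to hold at least ``min_support``
distinct individuals, and summarizes survivors as per-chromosome
frequency-of-individuals matrices at coarse display scales.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .alignment_io import Manifest
from .errors import ValidationError
from .records import AlignmentFields, IafRecord

_CLEAN_CIGAR = re.compile(r"\d+M")

#: kb-scale binning used for the distinct-individual support filter.
SUPPORT_START_SCALE = 1_000
SUPPORT_TLEN_SCALE = 1_000
#: Coarse scales used for the display / frequency matrices.
DISPLAY_START_SCALE = 1_000_000
DISPLAY_TLEN_SCALE = 10_000
DEFAULT_MIN_SUPPORT = 20


def same_strand_pair(record: AlignmentFields) -> bool:
    """Both mates on the same strand: orientation bit 0x10 equals mate bit 0x20.

    Evaluated per record so a single streaming pass suffices; both mates
    of a pair get the identical verdict.  Unpaired records are excluded
    (False), not an error.
    """
    if not record.has_flag("paired"):
        return False
    return record.has_flag("reverse") == record.has_flag("mate_reverse")


def is_clean_alignment(record: AlignmentFields) -> bool:
    """CIGAR is a single full match (``nnM``) and no XA tag is present."""
    if not _CLEAN_CIGAR.fullmatch(record.cigar):
        return False
    return not any(tag == "XA" for tag, _, _ in record.tags)


@dataclass(frozen=True)
class BinKey:
    """A (chromosome, scaled start, scaled |TLEN|) bin.

    Start bins use 0-based positions (SAM pos − 1) under floor division.
    """

    chromosome: str
    start_bin: int
    tlen_bin: int

    @classmethod
    def for_record(
        cls, fields: AlignmentFields, start_scale: int, tlen_scale: int
    ) -> "BinKey":
        if start_scale <= 0 or tlen_scale <= 0:
            raise ValidationError("bin scales must be positive")
        return cls(
            chromosome=fields.rname,
            start_bin=max(fields.pos - 1, 0) // start_scale,
            tlen_bin=abs(fields.tlen) // tlen_scale,
        )


class SupportTable:
    """Mapping bin → set of distinct individuals with ≥1 alignment there."""

    def __init__(self, start_scale: int, tlen_scale: int):
        if start_scale <= 0 or tlen_scale <= 0:
            raise ValidationError("bin scales must be positive")
        self.start_scale = start_scale
        self.tlen_scale = tlen_scale
        self._bins: dict[BinKey, set[str]] = {}

    def add(self, record: IafRecord) -> BinKey:
        key = BinKey.for_record(record.fields, self.start_scale, self.tlen_scale)
        self._bins.setdefault(key, set()).add(record.individual_id)
        return key

    def support(self, key: BinKey) -> int:
        return len(self._bins.get(key, ()))

    def individuals(self, key: BinKey) -> frozenset[str]:
        return frozenset(self._bins.get(key, ()))

    def __len__(self) -> int:
        return len(self._bins)

    def items(self):
        return self._bins.items()


def bin_alignments(
    records: Iterable[IafRecord],
    start_scale: int = SUPPORT_START_SCALE,
    tlen_scale: int = SUPPORT_TLEN_SCALE,
) -> SupportTable:
    """Project each alignment to its (chrom, start, |TLEN|) bin and collect
    distinct individuals per bin; duplicates from one individual count once."""
    table = SupportTable(start_scale, tlen_scale)
    for rec in records:
        table.add(rec)
    return table


def support_filter(
    records: Iterable[IafRecord],
    table: SupportTable,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[IafRecord]:
    """Keep records whose bin holds at least ``min_support`` distinct individuals."""
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    out = []
    for rec in records:
        key = BinKey.for_record(rec.fields, table.start_scale, table.tlen_scale)
        if table.support(key) >= min_support:
            out.append(rec)
    return out


@dataclass
class FrequencyMatrix:
    """Per-chromosome fraction of cohort individuals with ≥1 surviving
    alignment in each (start, |TLEN|) display bin.

    Rows are start bins, columns are |TLEN| bins; the denominator is the
    cohort (or population) size, so cells live in [0, 1].
    """

    chromosome: str
    values: np.ndarray  # shape (n_start_bins, n_tlen_bins)
    cohort_size: int
    start_scale: int = DISPLAY_START_SCALE
    tlen_scale: int = DISPLAY_TLEN_SCALE

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("frequency matrix must be 2-D")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values)
        df.index.name = "start_bin"
        df.columns.name = "tlen_bin"
        return df

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def nonzero_bins(self) -> list[tuple[int, int, float]]:
        rows, cols = np.nonzero(self.values)
        return [(int(r), int(c), float(self.values[r, c])) for r, c in zip(rows, cols)]


@dataclass(frozen=True)
class ScanParams:
    """Tunables of the scan; defaults are the published analysis settings."""

    min_support: int = DEFAULT_MIN_SUPPORT
    support_start_scale: int = SUPPORT_START_SCALE
    support_tlen_scale: int = SUPPORT_TLEN_SCALE
    display_start_scale: int = DISPLAY_START_SCALE
    display_tlen_scale: int = DISPLAY_TLEN_SCALE


def scan_records(
    records: Iterable[IafRecord],
    manifest: Manifest,
    params: ScanParams = ScanParams(),
    individuals: Optional[set[str]] = None,
) -> dict[str, FrequencyMatrix]:
    """Full scan pipeline on in-memory records.

    Stages: same-strand pair selection → purity filter → kb-scale
    distinct-individual support filter → display-scale frequency
    matrices.  ``individuals`` restricts the cohort (e.g. one population)
    and becomes the denominator; default is the whole manifest.

    The input is expected to be the output of a minimum-|TLEN| reduction
    filter job; that stage belongs to the engine and is not re-applied.
    """
    if individuals is None:
        individuals = set(manifest.individuals)
    cohort_size = len(individuals)
    if cohort_size == 0:
        raise ValidationError("empty cohort")

    candidates = []
    for rec in records:
        if rec.individual_id not in manifest:
            raise ValidationError(
                f"individual {rec.individual_id!r} in records but absent from manifest"
            )
        if rec.individual_id not in individuals:
            continue
        if not same_strand_pair(rec.fields):
            continue
        if not is_clean_alignment(rec.fields):
            continue
        candidates.append(rec)

    table = bin_alignments(
        candidates, params.support_start_scale, params.support_tlen_scale
    )
    survivors = support_filter(candidates, table, params.min_support)

    # accumulate distinct individuals per display bin, then normalize
    per_chrom: dict[str, dict[tuple[int, int], set[str]]] = {}
    for rec in survivors:
        key = BinKey.for_record(
            rec.fields, params.display_start_scale, params.display_tlen_scale
        )
        per_chrom.setdefault(key.chromosome, {}).setdefault(
            (key.start_bin, key.tlen_bin), set()
        ).add(rec.individual_id)

    matrices: dict[str, FrequencyMatrix] = {}
    for chrom, bins in per_chrom.items():
        n_rows = max(r for r, _ in bins) + 1
        n_cols = max(c for _, c in bins) + 1
        values = np.zeros((n_rows, n_cols))
        for (r, c), inds in bins.items():
            values[r, c] = len(inds) / cohort_size
        matrices[chrom] = FrequencyMatrix(
            chromosome=chrom,
            values=values,
            cohort_size=cohort_size,
            start_scale=params.display_start_scale,
            tlen_scale=params.display_tlen_scale,
        )
    return matrices


def run_scan(
    iaf_source,
    manifest: Manifest,
    params: ScanParams = ScanParams(),
    individuals: Optional[set[str]] = None,
) -> dict[str, FrequencyMatrix]:
    """Like :func:`scan_records` but reading IAF from paths or iterables."""
    from .alignment_io import read_iaf

    def _iter():
        if isinstance(iaf_source, (str, Path)):
            yield from read_iaf(iaf_source)
        elif isinstance(iaf_source, (list, tuple)) and iaf_source and isinstance(
            iaf_source[0], (str, Path)
        ):
            for path in iaf_source:
                yield from read_iaf(path)
        else:
            yield from iaf_source

    return scan_records(_iter(), manifest, params, individuals)


def population_difference(
    matrix_a: FrequencyMatrix, matrix_b: FrequencyMatrix
) -> FrequencyMatrix:
    """Cellwise A − B of two frequency matrices (each with its own
    population denominator); positive cells mark higher frequency in A.

    Matrices may differ in shape (bins observed); the result is padded to
    the union of their extents.
    """
    if matrix_a.chromosome != matrix_b.chromosome:
        raise ValidationError(
            f"chromosome mismatch: {matrix_a.chromosome} vs {matrix_b.chromosome}"
        )
    if (matrix_a.start_scale, matrix_a.tlen_scale) != (
        matrix_b.start_scale,
        matrix_b.tlen_scale,
    ):
        raise ValidationError("scale mismatch between matrices")
    rows = max(matrix_a.values.shape[0], matrix_b.values.shape[0])
    cols = max(matrix_a.values.shape[1], matrix_b.values.shape[1])

    def _pad(v):
        out = np.zeros((rows, cols))
        out[: v.shape[0], : v.shape[1]] = v
        return out

    diff = _pad(matrix_a.values) - _pad(matrix_b.values)
    return FrequencyMatrix(
        chromosome=matrix_a.chromosome,
        values=diff,
        cohort_size=0,
        start_scale=matrix_a.start_scale,
        tlen_scale=matrix_a.tlen_scale,
    )


def render_heatmap(
    matrix: FrequencyMatrix,
    destination: Union[str, Path],
    log_scale: bool = True,
    title: Optional[str] = None,
) -> Path:
    """Render a frequency matrix as a PNG heat map.

    Start bins run down the y axis, |TLEN| bins along x.  Under log
    scaling zero cells are masked to the background color (log of zero is
    undefined, and absence of evidence should look like background).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    values = matrix.values
    fig, ax = plt.subplots(figsize=(8, 6))
    if log_scale:
        masked = np.ma.masked_where(values == 0, values)
        positive = values[values > 0]
        norm = (
            LogNorm(vmin=float(positive.min()), vmax=float(positive.max()))
            if positive.size
            else None
        )
        im = ax.imshow(masked, aspect="auto", origin="upper", norm=norm, cmap="viridis")
    else:
        im = ax.imshow(values, aspect="auto", origin="upper", cmap="viridis")
    ax.set_xlabel(f"|TLEN| bin ({matrix.tlen_scale} bp)")
    ax.set_ylabel(f"start bin ({matrix.start_scale} bp)")
    ax.set_title(title or f"chromosome {matrix.chromosome}")
    fig.colorbar(im, ax=ax, label="individual frequency")
    path = Path(destination)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
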