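"""Synthetic paired-end cohorts with planted structural-variant signatures.

The generator fabricates alignment geometry directly (no reference
sequence, no realignment): background read pairs are properly oriented
with insert sizes from a truncated normal, inversion carriers get
same-strand pairs whose |TLEN| is the event span plus an insert draw, and
deletion carriers get properly oriented pairs with the same inflated
|TLEN|.  Noise injection rewrites a chosen fraction of records to carry a
soft-clipped CIGAR or an XA alternative-alignment tag, mirroring the two
purity-discard classes of the scan.  Every byte is a function of the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pysam

from .alignment_io import Manifest, SampleInfo
from .errors import ValidationError
from .records import AlignmentFields, encode_flag

_DEF_CHROM_LENGTHS = {"1": 60_000_000}

# flags of a proper forward/reverse pair
_FLAG_PROPER_1 = encode_flag({"paired", "proper_pair", "mate_reverse", "first_in_template"})   # 99
_FLAG_PROPER_2 = encode_flag({"paired", "proper_pair", "reverse", "second_in_template"})       # 147
# same-strand (forward/forward) pair: the inversion signature
_FLAG_INV_1 = encode_flag({"paired", "first_in_template"})                                     # 65
_FLAG_INV_2 = encode_flag({"paired", "second_in_template"})                                    # 129
# discordant but properly oriented pair: the deletion signature
_FLAG_DEL_1 = encode_flag({"paired", "mate_reverse", "first_in_template"})                     # 97
_FLAG_DEL_2 = encode_flag({"paired", "reverse", "second_in_template"})                         # 145


@dataclass(frozen=True)
class CohortSpec:
    """Shape of a synthetic cohort: one BAM per individual.

    Insert sizes are normal(mean, sd) truncated to
    [max(read_length + 1, mean − 4·sd), mean + 4·sd], so background
    template lengths stay within a known window.  The defaults emulate a
    low-coverage short-read cohort: 100 bp reads, ~400 bp fragments.
    """

    n_individuals: int = 10
    population_assignment: Optional[Mapping[str, tuple[str, str]]] = None
    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEF_CHROM_LENGTHS)
    )
    read_length: int = 100
    insert_mean: float = 400.0
    insert_sd: float = 45.0
    background_pairs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        if self.read_length < 1 or self.insert_mean <= self.read_length:
            raise ValidationError("insert_mean must exceed read_length")

    def individual_ids(self) -> list[str]:
        if self.population_assignment is not None:
            return list(self.population_assignment)
        return [f"IND{i:04d}" for i in range(self.n_individuals)]

    def population_of(self, individual_id: str) -> tuple[str, str]:
        """(population, superpopulation); default split: first half CEU/EUR,
        second half YRI/AFR."""
        if self.population_assignment is not None:
            return tuple(self.population_assignment[individual_id])
        idx = int(individual_id[3:])
        half = self.n_individuals // 2
        return ("CEU", "EUR") if idx < half else ("YRI", "AFR")


@dataclass(frozen=True)
class PlantedEvent:
    """A structural variant planted into a subset of the cohort."""

    kind: str  # inversion | deletion
    chromosome: str
    locus: int  # 1-based leftmost read start of carrier pairs
    span: int
    carriers: tuple[str, ...]
    pairs_per_carrier: int = 3

    def __post_init__(self):
        object.__setattr__(self, "carriers", tuple(self.carriers))
        if self.kind not in ("inversion", "deletion"):
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.span <= 0:
            raise ValidationError("event span must be positive")
        if self.locus < 1:
            raise ValidationError("event locus must be >= 1")
        if self.pairs_per_carrier < 1:
            raise ValidationError("pairs_per_carrier must be >= 1")


@dataclass(frozen=True)
class TruthRow:
    """Ground-truth sidecar entry: where one carrier's signal must appear."""

    kind: str
    chromosome: str
    locus: int
    span: int
    carrier: str
    kb_start_bin: int
    kb_tlen_bin: int
    display_start_bin: int
    display_tlen_bin: int


@dataclass
class CohortResult:
    out_dir: Path
    manifest_path: Path
    sidecar_path: Path
    bam_paths: dict[str, Path]
    truth: list[TruthRow]

    @property
    def manifest(self) -> Manifest:
        return Manifest.read(self.manifest_path)


def _insert_bounds(spec: CohortSpec) -> tuple[float, float]:
    lo = max(spec.read_length + 1, spec.insert_mean - 4 * spec.insert_sd)
    hi = spec.insert_mean + 4 * spec.insert_sd
    return lo, hi


def _draw_insert(rng: np.random.Generator, spec: CohortSpec) -> int:
    lo, hi = _insert_bounds(spec)
    return int(round(float(np.clip(rng.normal(spec.insert_mean, spec.insert_sd), lo, hi))))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _pair_records(
    qname: str,
    chrom: str,
    pos1: int,
    tlen: int,
    flag1: int,
    flag2: int,
    read_length: int,
    rng: np.random.Generator,
    mapq: int = 60,
) -> list[AlignmentFields]:
    pos2 = pos1 + tlen - read_length
    cigar = f"{read_length}M"
    qual = "I" * read_length
    return [
        AlignmentFields(
            qname=qname, flag=flag1, rname=chrom, pos=pos1, mapq=mapq,
            cigar=cigar, rnext="=", pnext=pos2, tlen=tlen,
            seq=_random_seq(rng, read_length), qual=qual,
        ),
        AlignmentFields(
            qname=qname, flag=flag2, rname=chrom, pos=pos2, mapq=mapq,
            cigar=cigar, rnext="=", pnext=pos1, tlen=-tlen,
            seq=_random_seq(rng, read_length), qual=qual,
        ),
    ]


def _validate_events(spec: CohortSpec, events: Sequence[PlantedEvent]) -> None:
    ids = set(spec.individual_ids())
    _, insert_hi = _insert_bounds(spec)
    for ev in events:
        if not set(ev.carriers) <= ids:
            raise ValidationError(
                f"event carriers {sorted(set(ev.carriers) - ids)} not in cohort"
            )
        if ev.chromosome not in spec.chromosome_lengths:
            raise ValidationError(f"unknown chromosome {ev.chromosome!r}")
        length = spec.chromosome_lengths[ev.chromosome]
        if ev.locus + ev.span + insert_hi > length:
            raise ValidationError(
                f"event at {ev.chromosome}:{ev.locus} span {ev.span} exceeds "
                f"chromosome length {length}"
            )
        if spec.insert_mean >= ev.span:
            raise ValidationError("insert mean must be below every event span")


def _event_records(
    ev: PlantedEvent, individual_id: str, spec: CohortSpec, rng: np.random.Generator
) -> list[AlignmentFields]:
    flag1, flag2 = (
        (_FLAG_INV_1, _FLAG_INV_2) if ev.kind == "inversion" else (_FLAG_DEL_1, _FLAG_DEL_2)
    )
    out = []
    for k in range(ev.pairs_per_carrier):
        tlen = ev.span + _draw_insert(rng, spec)
        out.extend(
            _pair_records(
                qname=f"{individual_id}:{ev.kind}:{ev.chromosome}:{ev.locus}:{k}",
                chrom=ev.chromosome,
                pos1=ev.locus,
                tlen=tlen,
                flag1=flag1,
                flag2=flag2,
                read_length=spec.read_length,
                rng=rng,
            )
        )
    return out


def _background_records(
    individual_id: str, spec: CohortSpec, rng: np.random.Generator
) -> list[AlignmentFields]:
    chroms = list(spec.chromosome_lengths)
    lengths = np.array([spec.chromosome_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    out = []
    for j in range(spec.background_pairs):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        tlen = _draw_insert(rng, spec)
        pos1 = int(rng.integers(1, spec.chromosome_lengths[chrom] - tlen))
        out.extend(
            _pair_records(
                qname=f"{individual_id}:bg:{j}",
                chrom=chrom,
                pos1=pos1,
                tlen=tlen,
                flag1=_FLAG_PROPER_1,
                flag2=_FLAG_PROPER_2,
                read_length=spec.read_length,
                rng=rng,
            )
        )
    return out


def _write_sorted_bam(
    records: list[AlignmentFields],
    chromosome_lengths: Mapping[str, int],
    path: Path,
) -> None:
    chrom_order = {c: i for i, c in enumerate(chromosome_lengths)}
    records = sorted(records, key=lambda r: (chrom_order[r.rname], r.pos))
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": chrom, "LN": int(length)}
                for chrom, length in chromosome_lengths.items()
            ],
        }
    )
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for rec in records:
            out.write(pysam.AlignedSegment.fromstring(rec.to_sam_line(), header))
    pysam.index(str(path))


def simulate_cohort(
    spec: CohortSpec,
    events: Sequence[PlantedEvent] = (),
    out_dir: Union[str, Path] = ".",
) -> CohortResult:
    """Write one coordinate-sorted, indexed BAM per individual plus a
    manifest and a ground-truth sidecar; fully determined by the seed.

    Each individual's records derive from an independent child stream of
    the cohort seed, so adding individuals never perturbs existing ones.
    """
    _validate_events(spec, events)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ids = spec.individual_ids()
    bam_paths: dict[str, Path] = {}
    truth: list[TruthRow] = []
    for i, individual_id in enumerate(ids):
        rng = np.random.default_rng([spec.seed, i])
        records = _background_records(individual_id, spec, rng)
        for ev in events:
            if individual_id in ev.carriers:
                records.extend(_event_records(ev, individual_id, spec, rng))
        path = out_dir / f"{individual_id}.bam"
        _write_sorted_bam(records, spec.chromosome_lengths, path)
        bam_paths[individual_id] = path

    expected_tlen = {ev: ev.span + int(round(spec.insert_mean)) for ev in events}
    for ev in events:
        for carrier in ev.carriers:
            truth.append(
                TruthRow(
                    kind=ev.kind,
                    chromosome=ev.chromosome,
                    locus=ev.locus,
                    span=ev.span,
                    carrier=carrier,
                    kb_start_bin=(ev.locus - 1) // 1_000,
                    kb_tlen_bin=expected_tlen[ev] // 1_000,
                    display_start_bin=(ev.locus - 1) // 1_000_000,
                    display_tlen_bin=expected_tlen[ev] // 10_000,
                )
            )

    manifest_path = out_dir / "manifest.tsv"
    manifest = Manifest(
        [
            SampleInfo(
                file=str(bam_paths[ind]),
                individual_id=ind,
                population=spec.population_of(ind)[0],
                superpopulation=spec.population_of(ind)[1],
            )
            for ind in ids
        ]
    )
    manifest.write(manifest_path)

    sidecar_path = out_dir / "truth.tsv"
    with open(sidecar_path, "w") as fh:
        fh.write(
            "kind\tchromosome\tlocus\tspan\tcarrier\tkb_start_bin\tkb_tlen_bin"
            "\tdisplay_start_bin\tdisplay_tlen_bin\n"
        )
        for row in truth:
            fh.write(
                f"{row.kind}\t{row.chromosome}\t{row.locus}\t{row.span}\t{row.carrier}"
                f"\t{row.kb_start_bin}\t{row.kb_tlen_bin}"
                f"\t{row.display_start_bin}\t{row.display_tlen_bin}\n"
            )

    return CohortResult(
        out_dir=out_dir,
        manifest_path=manifest_path,
        sidecar_path=sidecar_path,
        bam_paths=bam_paths,
        truth=truth,
    )


@dataclass(frozen=True)
class NoiseReport:
    n_records: int
    n_softclip: int
    n_xa: int


def inject_noise(
    bam_path: Union[str, Path],
    fraction_softclip: float,
    fraction_xa: float,
    seed: int,
    out_path: Optional[Union[str, Path]] = None,
) -> NoiseReport:
    """Rewrite fractions of a BAM's records with soft-clip CIGARs or XA tags.

    Counts are ``round(fraction · n)`` drawn without replacement from a
    seeded permutation, so the modified set is exact and reproducible.
    The two noise classes never overlap within one record.
    """
    if not 0 <= fraction_softclip <= 1 or not 0 <= fraction_xa <= 1:
        raise ValidationError("noise fractions must lie in [0, 1]")
    if fraction_softclip + fraction_xa > 1:
        raise ValidationError("noise fractions sum above 1")
    bam_path = Path(bam_path)
    dest = Path(out_path) if out_path is not None else bam_path

    with pysam.AlignmentFile(str(bam_path), "rb") as af:
        header = af.header
        segments = [seg for seg in af.fetch(until_eof=True)]
    n = len(segments)
    n_sc = int(round(fraction_softclip * n))
    n_xa = int(round(fraction_xa * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    softclip_idx = set(perm[:n_sc].tolist())
    xa_idx = set(perm[n_sc : n_sc + n_xa].tolist())

    tmp = dest.with_suffix(".tmp.bam")
    with pysam.AlignmentFile(str(tmp), "wb", header=header) as out:
        for i, seg in enumerate(segments):
            if i in softclip_idx:
                length = seg.query_length or len(seg.query_sequence or "")
                clip = max(1, min(5, length - 1))
                seg.cigarstring = f"{clip}S{length - clip}M"
            elif i in xa_idx:
                seg.set_tag("XA", "alt,+1000,100M,0;", value_type="Z")
            out.write(seg)
    os.replace(tmp, dest)
    pysam.index(str(dest))
    return NoiseReport(n_records=n, n_softclip=n_sc, n_xa=n_xa)
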