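"""Shared fixtures and independent oracles.

``oracle_matches`` is a deliberately naive clause-by-clause re-evaluation
of the filter predicate, kept separate from the implementation so the two
can disagree.  Record/spec generators use a caller-supplied seeded
``random.Random`` for reproducibility.
"""

from __future__ import annotations

import random
import re

import pytest

from bamsift import AlignmentFields, FilterSpec, Region

CHROMS = ["1", "2", "X"]
CIGARS = ["100M", "76M", "50M2I48M", "5S95M", "10M5D90M", "*"]


# ---------------------------------------------------------------------------
# independent clause-by-clause predicate
# ---------------------------------------------------------------------------

def oracle_matches(rec: AlignmentFields, spec: FilterSpec) -> bool:
    """Brute-force evaluator: each criterion checked in isolation."""
    clauses = []
    if spec.mapq_min is not None:
        clauses.append(rec.mapq >= spec.mapq_min)
    if spec.flag_required is not None:
        bits = [b for b in range(16) if spec.flag_required >> b & 1]
        clauses.append(all(rec.flag >> b & 1 for b in bits))
    if spec.flag_excluded is not None:
        bits = [b for b in range(16) if spec.flag_excluded >> b & 1]
        clauses.append(not any(rec.flag >> b & 1 for b in bits))
    if spec.tlen_min is not None:
        clauses.append(abs(rec.tlen) >= spec.tlen_min)
    if spec.tlen_max is not None:
        clauses.append(abs(rec.tlen) <= spec.tlen_max)
    if spec.seq_pattern is not None:
        clauses.append(spec.seq_pattern.upper() in rec.seq.upper())
    if spec.cigar_regex is not None:
        usable = rec.cigar != "*" and not (rec.flag & 0x4)
        clauses.append(usable and re.fullmatch(spec.cigar_regex, rec.cigar) is not None)
    if spec.tag_regex is not None:
        block = "\t".join(f"{t}:{ty}:{v}" for t, ty, v in rec.tags)
        clauses.append(re.search(spec.tag_regex, block) is not None)
    if spec.regions:
        inside = False
        if not (rec.flag & 0x4) and rec.pos > 0:
            for r in spec.regions:
                if r.chromosome == rec.rname and r.start <= rec.pos <= r.end:
                    inside = True
        clauses.append(inside)
    return all(clauses)


# ---------------------------------------------------------------------------
# randomized generators
# ---------------------------------------------------------------------------

def random_record(rng: random.Random) -> AlignmentFields:
    tags = []
    if rng.random() < 0.3:
        tags.append(("NM", "i", str(rng.randrange(5))))
    if rng.random() < 0.3:
        tags.append(("XA", "Z", "alt,+100,76M,1;"))
    seq = "".join(rng.choice("ACGT") for _ in range(20))
    return AlignmentFields(
        qname=f"r{rng.randrange(10_000)}",
        flag=rng.randrange(4096),
        rname=rng.choice(CHROMS),
        pos=rng.randrange(0, 2_000_000),
        mapq=rng.randrange(61),
        cigar=rng.choice(CIGARS),
        rnext="=",
        pnext=rng.randrange(0, 2_000_000),
        tlen=rng.randrange(-1_000_000, 1_000_000),
        seq=seq,
        qual="I" * 20,
        tags=tuple(tags),
    )


def random_spec(rng: random.Random) -> FilterSpec:
    kw = {}
    if rng.random() < 0.4:
        kw["mapq_min"] = rng.randrange(61)
    if rng.random() < 0.4:
        kw["flag_required"] = rng.randrange(4096)
    if rng.random() < 0.4:
        excl = rng.randrange(4096)
        excl &= ~kw.get("flag_required", 0)  # invariant: disjoint masks
        kw["flag_excluded"] = excl
    if rng.random() < 0.4:
        lo = rng.randrange(0, 900_000)
        kw["tlen_min"] = lo
        if rng.random() < 0.5:
            kw["tlen_max"] = lo + rng.randrange(0, 500_000)
    if rng.random() < 0.3:
        kw["seq_pattern"] = "".join(rng.choice("ACGT") for _ in range(rng.randrange(1, 4)))
    if rng.random() < 0.3:
        kw["cigar_regex"] = rng.choice([r"\d+M", r"\d+M\d+I\d+M", r"76M", r".*S.*"])
    if rng.random() < 0.3:
        kw["tag_regex"] = rng.choice(["XA:", "NM:i:[0-2]", "XA:Z:alt"])
    if rng.random() < 0.3:
        start = rng.randrange(1, 1_500_000)
        kw["regions"] = (
            Region(rng.choice(CHROMS), start, start + rng.randrange(0, 500_000)),
        )
    return FilterSpec(**kw)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
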