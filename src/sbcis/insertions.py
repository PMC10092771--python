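"""Reading and aggregating mapped SB insertion records.

Input is one file per tumor with mapped insertion coordinates (the TA site's
T position, 0-based) and the genomic orientation of the transposon's CAG
promoter.  Two formats are accepted: 6-column BED (strand column carries the
orientation) and the package's native TSV, which additionally carries a
weight for duplicate-collapsed records.  Upstream read processing (adapter /
transposon trimming, the <20 bp read filter, alignment) is out of scope:
callers provide mapped coordinates.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .genome_index import GenomeIndex

logger = logging.getLogger(__name__)

NATIVE_HEADER = ("sample_id", "chrom", "pos", "orientation", "weight")


@dataclass(frozen=True)
class InsertionRecord:
    """One mapped SB insertion read (or collapsed duplicate stack).

    ``pos`` is the 0-based coordinate of the TA's T; ``orientation`` is the
    genomic strand the transposon's internal CAG promoter points along.
    """

    sample_id: str
    chrom: str
    pos: int
    orientation: str
    read_id: str | None = None
    weight: int = 1

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.orientation not in "+-":
            raise ValueError(f"orientation must be + or -, got {self.orientation!r}")
        if self.weight < 1:
            raise ValueError(f"weight must be positive, got {self.weight}")


@dataclass
class SampleGeneCount:
    """Per-sample, per-gene read aggregate.

    ``read_count`` is k, the observed insertion (mapped read) number of the
    gene; ``forward_count`` is the subset whose CAG orientation equals the
    gene's strand; ``site_positions`` maps position -> read weight.
    """

    sample_id: str
    gene_id: str
    read_count: int = 0
    forward_count: int = 0
    site_positions: Counter = field(default_factory=Counter)


class InsertionFileError(ValueError):
    """Raised for empty or wholly malformed insertion files."""


def _parse_bed_row(fields: Sequence[str], sample_id: str) -> InsertionRecord:
    chrom, start, _end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
    strand = fields[5]
    return InsertionRecord(sample_id=sample_id, chrom=chrom, pos=start,
                           orientation=strand, read_id=name or None)


def _parse_native_row(fields: Sequence[str], sample_id: str) -> InsertionRecord:
    # sample_id column in the file is informational; the caller's wins.
    return InsertionRecord(sample_id=sample_id, chrom=fields[1],
                           pos=int(fields[2]), orientation=fields[3],
                           weight=int(fields[4]) if len(fields) > 4 else 1)


def load_insertions(path: str | Path, sample_id: str) -> list[InsertionRecord]:
    """Load insertion records for one sample from BED or native TSV.

    Native files start with a ``sample_id`` header line; anything else is
    treated as 6-column BED.  Malformed rows are rejected with their line
    numbers logged; a file yielding zero valid records is an error.
    """
    path = Path(path)
    records: list[InsertionRecord] = []
    bad_lines: list[int] = []
    native = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == NATIVE_HEADER[0]:
                native = True
                continue
            try:
                if native:
                    rec = _parse_native_row(fields, sample_id)
                else:
                    if len(fields) < 6:
                        raise ValueError("BED row with fewer than 6 columns")
                    rec = _parse_bed_row(fields, sample_id)
            except (ValueError, IndexError):
                bad_lines.append(lineno)
                continue
            records.append(rec)
    if bad_lines:
        logger.warning("%s: rejected %d malformed rows (lines %s%s)", path,
                       len(bad_lines), bad_lines[:10],
                       "..." if len(bad_lines) > 10 else "")
    if not records:
        raise InsertionFileError(f"no valid insertion records in {path}")
    return records


def write_insertions(records: Iterable[InsertionRecord], path: str | Path) -> None:
    """Write records in the native TSV format (round-trips with load)."""
    with open(path, "w") as fh:
        fh.write("\t".join(NATIVE_HEADER) + "\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.chrom}\t{r.pos}\t{r.orientation}\t{r.weight}\n")


def collapse_sites(records: Iterable[InsertionRecord]) -> list[InsertionRecord]:
    """Collapse duplicate records at the same (chrom, pos, orientation).

    Off by default in the pipeline: the method counts reads, not unique
    sites, so duplicates are independent evidence.  Collapsing sums weights
    and is therefore count-preserving.
    """
    agg: Counter = Counter()
    sample = None
    for r in records:
        sample = r.sample_id
        agg[(r.chrom, r.pos, r.orientation)] += r.weight
    return [
        InsertionRecord(sample_id=sample, chrom=c, pos=p, orientation=o, weight=w)
        for (c, p, o), w in sorted(agg.items())
    ]


def total_reads(records: Iterable[InsertionRecord]) -> int:
    """Total clean read count n of a sample (sum of record weights)."""
    return sum(r.weight for r in records)


def count_per_gene(
    records: Sequence[InsertionRecord], index: "GenomeIndex"
) -> tuple[dict[str, SampleGeneCount], int]:
    """Aggregate records into per-gene counts against the index.

    A record contributes its weight to *every* gene whose extended interval
    contains its position (overlapping genes each get the read).  ``n`` is
    the sample's total read weight, including reads overlapping no gene —
    it is the binomial test's number of trials and does not depend on the
    annotation.
    """
    counts: dict[str, SampleGeneCount] = {}
    n = 0
    sample_id = records[0].sample_id if records else ""
    lookup_cache: dict[tuple[str, int], tuple[str, ...]] = {}
    for rec in records:
        n += rec.weight
        key = (rec.chrom, rec.pos)
        hit = lookup_cache.get(key)
        if hit is None:
            hit = tuple(sorted(index.genes_at(rec.chrom, rec.pos)))
            lookup_cache[key] = hit
        for gene_id in hit:
            sgc = counts.get(gene_id)
            if sgc is None:
                sgc = counts[gene_id] = SampleGeneCount(sample_id=sample_id,
                                                        gene_id=gene_id)
            sgc.read_count += rec.weight
            sgc.site_positions[rec.pos] += rec.weight
            if rec.orientation == index.genes[gene_id].strand:
                sgc.forward_count += rec.weight
    return counts, n
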