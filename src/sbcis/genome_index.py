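"""TA-dinucleotide and gene-interval index.

The Sleeping Beauty transposon reintegrates exclusively at TA dinucleotides,
so the expected insertion probability of a gene under the null (uniform,
independent jumps) is the fraction of the genome's TA sites that fall inside
the gene.  This module counts TA sites genome-wide (``T_G``) and per gene
(``T_g``, over a strand-aware upstream-extended interval so that promoter
insertions are captured), and exposes fast coordinate -> gene lookup.

Coordinates are 0-based half-open internally; GFF3's 1-based inclusive
intervals are converted on read.  A TA occurrence is attributed to an
interval iff the position of its T lies inside the interval.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

# Upper-case IUPAC nucleotide one-letter codes (U allowed for completeness).
IUPAC_CODES = frozenset("ACGTUNRYSWKMBDHV")

#: GFF3 feature types treated as top-level genes (Ensembl dialect).  Every
#: biotype is kept: protein-coding, ncRNA genes, pseudogenes, etc.
GENE_FEATURE_TYPES = frozenset(
    {"gene", "ncRNA_gene", "pseudogene", "processed_pseudogene",
     "polymorphic_pseudogene", "unprocessed_pseudogene"}
)

DEFAULT_UPSTREAM_BP = 3000


class SequenceFormatError(ValueError):
    """A sequence contains characters outside the IUPAC nucleotide alphabet."""


def count_ta(sequence: str, motif: str = "TA") -> int:
    """Count occurrences of ``motif`` (default the SB target site TA).

    Matching is case-insensitive; any position containing ``N`` (or another
    ambiguity code) never matches, so assembly gaps do not inflate counts.
    ``motif`` must not be able to overlap itself (true for TA and TTAA).

    Raises
    ------
    SequenceFormatError
        If ``sequence`` contains a character that is not an IUPAC nucleotide
        code.
    """
    seq = sequence.upper()
    bad = set(seq) - IUPAC_CODES
    if bad:
        raise SequenceFormatError(
            f"non-nucleotide characters in sequence: {sorted(bad)!r}"
        )
    return seq.count(motif.upper())


@dataclass
class GeneRecord:
    """One annotated gene with its TA content and null insertion probability.

    ``[start, end)`` is the annotated span; ``[extended_start, extended_end)``
    additionally includes up to ``upstream_bp`` bases on the strand-aware
    upstream (5') side, clipped at the chromosome edge.  ``ta_count`` is
    ``T_g`` over the extended interval and ``insert_prob = T_g / T_G``.
    """

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    extended_start: int
    extended_end: int
    ta_count: int
    insert_prob: float


def extend_interval(
    start: int, end: int, strand: str, chrom_len: int, upstream_bp: int
) -> tuple[int, int]:
    """Strand-aware upstream extension of a 0-based half-open interval.

    Adds ``min(upstream_bp, distance to chromosome edge)`` bases 5' of the
    gene: before ``start`` for + strand genes, after ``end`` for - strand.
    """
    if strand == "-":
        return start, min(chrom_len, end + upstream_bp)
    return max(0, start - upstream_bp), end


def _count_ta_in_interval(seq: str, start: int, end: int, motif: str = "TA") -> int:
    # A motif occurrence belongs to [start, end) iff its first base does, so
    # include len(motif)-1 trailing bases to catch boundary-spanning hits.
    return count_ta(seq[start : end + len(motif) - 1], motif)


@dataclass
class GenomeIndex:
    """Per-gene TA counts plus genome-wide total and interval lookup."""

    genes: dict[str, GeneRecord]
    total_ta: int
    genome_id: str
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._trees:
            self._trees = _build_trees(self.genes.values())

    def genes_at(self, chrom: str, pos: int) -> set[str]:
        """Gene ids whose extended interval contains ``pos`` on ``chrom``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos)}

    def __len__(self) -> int:
        return len(self.genes)

    # -- serialization ----------------------------------------------------

    def to_tsv(self, tsv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the index as TSV plus a one-line JSON sidecar with T_G."""
        tsv_path = Path(tsv_path)
        rows = [
            (g.gene_id, g.gene_name, g.chrom, g.start, g.end, g.strand,
             g.biotype, g.extended_start, g.extended_end, g.ta_count,
             g.insert_prob)
            for g in self.genes.values()
        ]
        df = pd.DataFrame(
            rows,
            columns=["gene_id", "gene_name", "chrom", "start", "end", "strand",
                     "biotype", "extended_start", "extended_end", "ta_count",
                     "insert_prob"],
        )
        df.to_csv(tsv_path, sep="\t", index=False)
        sidecar = Path(sidecar_path) if sidecar_path else tsv_path.with_suffix(".json")
        sidecar.write_text(
            json.dumps({"total_ta": self.total_ta, "genome_id": self.genome_id})
            + "\n"
        )

    @classmethod
    def from_tsv(cls, tsv_path: str | Path, sidecar_path: str | Path | None = None) -> "GenomeIndex":
        tsv_path = Path(tsv_path)
        sidecar = Path(sidecar_path) if sidecar_path else tsv_path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        total_ta = int(meta["total_ta"])
        df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
        genes: dict[str, GeneRecord] = {}
        for row in df.itertuples(index=False):
            genes[row.gene_id] = GeneRecord(
                gene_id=row.gene_id, gene_name=row.gene_name, chrom=row.chrom,
                start=int(row.start), end=int(row.end), strand=row.strand,
                biotype=row.biotype, extended_start=int(row.extended_start),
                extended_end=int(row.extended_end), ta_count=int(row.ta_count),
                # recomputed rather than parsed: exact, immune to TSV rounding
                insert_prob=int(row.ta_count) / total_ta,
            )
        return cls(genes=genes, total_ta=total_ta,
                   genome_id=str(meta["genome_id"]))


def _build_trees(genes: Iterable[GeneRecord]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.extended_start, g.extended_end, g.gene_id
        )
    return trees


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into a chrom -> sequence dict."""
    with _open_maybe_gzip(path) as handle:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


def _iter_gene_features(gff3_path: str | Path) -> Iterator[gffutils.Feature]:
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    for ftype in db.featuretypes():
        if ftype in GENE_FEATURE_TYPES or ftype.endswith("_gene"):
            yield from db.features_of_type(ftype)


def build_index(
    genome_fasta: str | Path,
    annotation_gff3: str | Path,
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
    motif: str = "TA",
) -> GenomeIndex:
    """Build the TA/gene index from a genome FASTA and an Ensembl-style GFF3.

    One :class:`GeneRecord` is made per top-level gene feature of any
    biotype.  ``T_g`` is counted on the strand-aware extended interval and
    ``T_G`` over all FASTA sequences; ``insert_prob = T_g / T_G``.

    Features on chromosomes absent from the FASTA are skipped with a logged
    count; parsing zero genes is a hard error.
    """
    if upstream_bp < 0:
        raise ValueError("upstream_bp must be >= 0")
    seqs = read_fasta(genome_fasta)
    if not seqs:
        raise ValueError(f"no sequences in FASTA {genome_fasta}")
    total_ta = sum(count_ta(s, motif) for s in seqs.values())
    if total_ta == 0:
        raise ValueError("genome contains no TA sites; cannot normalize")

    genes: dict[str, GeneRecord] = {}
    skipped = 0
    for feat in _iter_gene_features(annotation_gff3):
        chrom = feat.seqid
        if chrom not in seqs:
            skipped += 1
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        # Ensembl prefixes IDs with "gene:"; strip for a clean key.
        gene_id = gene_id.split(":", 1)[-1]
        name = feat.attributes.get("Name", [gene_id])[0]
        biotype = feat.attributes.get("biotype", [feat.featuretype])[0]
        start, end = feat.start - 1, feat.end  # 1-based inclusive -> 0-based half-open
        strand = feat.strand if feat.strand in "+-" else "+"
        ext_start, ext_end = extend_interval(
            start, end, strand, len(seqs[chrom]), upstream_bp
        )
        ta = _count_ta_in_interval(seqs[chrom], ext_start, ext_end, motif)
        genes[gene_id] = GeneRecord(
            gene_id=gene_id, gene_name=name, chrom=chrom, start=start, end=end,
            strand=strand, biotype=biotype, extended_start=ext_start,
            extended_end=ext_end, ta_count=ta, insert_prob=ta / total_ta,
        )
    if skipped:
        logger.warning("skipped %d gene features on chromosomes absent from FASTA", skipped)
    if not genes:
        raise ValueError(f"no gene features parsed from {annotation_gff3}")
    return GenomeIndex(genes=genes, total_ta=total_ta,
                       genome_id=Path(genome_fasta).stem)
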