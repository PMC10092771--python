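"""Candidate calling, cohort common-insertion-gene (CIS) detection, and
oncogene / tumor-suppressor classification.

A gene is a per-tumor candidate when its read count reaches the tumor's
tailored depth cutoff.  Candidates recurring in at least
max(min_tumors, ceil(min_frac * cohort size)) tumors are cohort-level
common insertion genes.  Each CIS gene is then classified from the pooled
insertion pattern of its supporting tumors: a transposon whose internal CAG
promoter points along the host gene's transcriptional direction ("forward")
can overexpress it, so a gene dominated by forward reads concentrated in a
few hotspot regions looks like an activated oncogene, whereas scattered,
orientation-balanced insertions look like gene-trap disruption of a tumor
suppressor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .genome_index import GeneRecord
    from .saturation import DepthCutoff
    from .significance import SampleLibrary

ONCOGENE = "oncogene"
TUMOR_SUPPRESSOR = "tumor_suppressor"


@dataclass(frozen=True)
class CandidateCall:
    """A gene passing both the binomial test and the depth cutoff in one tumor."""

    sample_id: str
    gene_id: str
    read_count: int
    depth_cutoff: int
    p_value: float


@dataclass
class HotspotParams:
    """Operational definition of "few hotspot insertion regions".

    Positions carrying less than ``min_site_read_frac`` of the gene's
    pooled reads are dropped first (sporadic background insertions would
    otherwise bridge distinct insertion clusters); the survivors are merged
    into regions when consecutive positions are at most ``merge_gap_bp``
    apart, and a region counts as a hotspot when it carries at least
    ``min_region_read_frac`` of the pooled reads.  A gene is oncogene-like
    when its forward fraction exceeds ``forward_threshold`` (strict) and
    its hotspot count is at most ``max_regions_for_oncogene``.
    """

    merge_gap_bp: int = 500
    min_site_read_frac: float = 0.002
    min_region_read_frac: float = 0.05
    max_regions_for_oncogene: int = 3
    forward_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.merge_gap_bp <= 0 or self.max_regions_for_oncogene <= 0:
            raise ValueError("hotspot params must be positive")
        if not 0 < self.forward_threshold < 1:
            raise ValueError("forward_threshold must be in (0, 1)")
        if not 0 < self.min_region_read_frac < 1:
            raise ValueError("min_region_read_frac must be in (0, 1)")
        if not 0 <= self.min_site_read_frac < 1:
            raise ValueError("min_site_read_frac must be in [0, 1)")


@dataclass
class CISGene:
    """A cohort-level common insertion gene."""

    gene_id: str
    tumor_count: int
    cohort_size: int
    supporting_samples: list[str]
    total_reads: int
    frequency: float = field(init=False)
    classification: str | None = None
    forward_fraction: float | None = None
    hotspot_regions: int | None = None

    def __post_init__(self) -> None:
        self.frequency = self.tumor_count / self.cohort_size


def call_candidates(library: "SampleLibrary", cutoff: "DepthCutoff") -> list[CandidateCall]:
    """Emit every library gene whose read count k reaches the depth cutoff."""
    calls = [
        CandidateCall(sample_id=library.sample_id, gene_id=gene_id,
                      read_count=e.read_count, depth_cutoff=cutoff.depth,
                      p_value=e.p_value)
        for gene_id, e in library.entries.items()
        if e.read_count >= cutoff.depth
    ]
    calls.sort(key=lambda c: (-c.read_count, c.gene_id))
    return calls


def cis_tumor_threshold(cohort_size: int, min_tumors: int = 3, min_frac: float = 0.05) -> int:
    """Recurrence threshold: max(min_tumors, ceil(min_frac * cohort_size))."""
    return max(min_tumors, math.ceil(min_frac * cohort_size))


def call_cis(
    calls: Iterable[CandidateCall],
    cohort_size: int,
    min_tumors: int = 3,
    min_frac: float = 0.05,
) -> list[CISGene]:
    """Common insertion genes: candidates recurring across enough tumors.

    Output is sorted by tumor count descending, ties broken by total read
    count descending then gene_id, so reports are bit-reproducible.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    threshold = cis_tumor_threshold(cohort_size, min_tumors, min_frac)
    by_gene: dict[str, dict[str, int]] = {}
    for c in calls:
        by_gene.setdefault(c.gene_id, {})[c.sample_id] = c.read_count
    out = [
        CISGene(gene_id=g, tumor_count=len(samples), cohort_size=cohort_size,
                supporting_samples=sorted(samples), total_reads=sum(samples.values()))
        for g, samples in by_gene.items()
        if len(samples) >= threshold
    ]
    out.sort(key=lambda c: (-c.tumor_count, -c.total_reads, c.gene_id))
    return out


def hotspot_regions(
    site_weights: Mapping[int, int] | Sequence[tuple[int, int]],
    params: HotspotParams,
) -> int:
    """Count insertion regions carrying a substantial share of reads.

    Positions below ``min_site_read_frac`` of the total read weight are
    discarded, the rest are clustered by single-linkage gap merging (gap <=
    ``merge_gap_bp``), and only clusters holding >= ``min_region_read_frac``
    of the total count as hotspot regions.  Fractions are of the *full*
    pooled read weight, including the filtered sites.
    """
    items = sorted(dict(site_weights).items())
    if not items:
        return 0
    total = sum(w for _, w in items)
    items = [(p, w) for p, w in items if w >= params.min_site_read_frac * total]
    if not items:
        return 0
    regions: list[int] = []
    run_mass = 0
    prev_pos: int | None = None
    for pos, w in items:
        if prev_pos is not None and pos - prev_pos > params.merge_gap_bp:
            regions.append(run_mass)
            run_mass = 0
        run_mass += w
        prev_pos = pos
    regions.append(run_mass)
    return sum(1 for m in regions if m >= params.min_region_read_frac * total)


def classify(
    insertions: Iterable[tuple[int, str, int]],
    gene: "GeneRecord",
    params: HotspotParams | None = None,
) -> tuple[str, float, int]:
    """Classify a gene from its pooled (pos, orientation, weight) insertions.

    Forward reads are those whose CAG-promoter orientation equals the gene
    strand.  Returns (classification, forward_fraction, hotspot_regions);
    oncogene iff forward_fraction > forward_threshold (strict) and the
    hotspot-region count is at most max_regions_for_oncogene.  Invariant to
    how reads are split across samples, since everything is pooled first.
    """
    params = params or HotspotParams()
    total = 0
    forward = 0
    sites: dict[int, int] = {}
    for pos, orientation, weight in insertions:
        total += weight
        if orientation == gene.strand:
            forward += weight
        sites[pos] = sites.get(pos, 0) + weight
    if total == 0:
        raise ValueError(f"gene {gene.gene_id}: cannot classify with zero reads")
    forward_fraction = forward / total
    n_regions = hotspot_regions(sites, params)
    if forward_fraction > params.forward_threshold and n_regions <= params.max_regions_for_oncogene:
        label = ONCOGENE
    else:
        label = TUMOR_SUPPRESSOR
    return label, forward_fraction, n_regions


def write_cis_report(
    cis_genes: Sequence[CISGene],
    path: str | Path,
    gene_names: Mapping[str, str] | None = None,
) -> None:
    rows = []
    for c in cis_genes:
        rows.append({
            "gene_id": c.gene_id,
            "gene_name": (gene_names or {}).get(c.gene_id, c.gene_id),
            "tumor_count": c.tumor_count,
            "frequency": round(c.frequency, 4),
            "classification": c.classification or "NA",
            "forward_fraction": ("NA" if c.forward_fraction is None
                                 else round(c.forward_fraction, 4)),
            "hotspot_regions": ("NA" if c.hotspot_regions is None
                                else c.hotspot_regions),
            "total_reads": c.total_reads,
            "supporting_samples": ",".join(c.supporting_samples),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_sample_gene_matrix(
    cis_genes: Sequence[CISGene], sample_ids: Sequence[str], path: str | Path
) -> None:
    """Oncoplot-ready binary sample x gene matrix (1 = candidate in sample)."""
    mat = pd.DataFrame(0, index=list(sample_ids),
                       columns=[c.gene_id for c in cis_genes], dtype=int)
    for c in cis_genes:
        mat.loc[c.supporting_samples, c.gene_id] = 1
    mat.index.name = "sample_id"
    mat.to_csv(path, sep="\t")
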