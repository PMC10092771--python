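"""End-to-end orchestration of the six analysis stages.

index -> per-sample libraries -> saturation fits -> depth cutoffs ->
candidate calls -> cohort CIS report with oncogene/TSG classification.
Stage outputs are pure functions of (inputs, config, seed); a run writes a
metadata JSON (versions, seed, config hash, statistical conventions) and
re-running with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .drivers import (CandidateCall, CISGene, HotspotParams, call_candidates,
                      call_cis, classify, write_cis_report,
                      write_sample_gene_matrix)
from .genome_index import DEFAULT_UPSTREAM_BP, GenomeIndex, build_index
from .insertions import count_per_gene, load_insertions
from .saturation import (DEFAULT_N_GRADIENTS, DepthCutoff, SaturationFit,
                         depth_cutoff, fit_curve, make_gradients,
                         subsample_curve)
from .significance import DEFAULT_ALPHA, SampleLibrary, build_library

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; every stated method threshold is a default,
    never hard-coded."""

    genome: Path
    gff3: Path
    manifest: Path
    outdir: Path
    seed: int = 0
    alpha: float = DEFAULT_ALPHA
    upstream_bp: int = DEFAULT_UPSTREAM_BP
    n_gradients: int = DEFAULT_N_GRADIENTS
    model: str = "hyperbolic"
    use_observed_genes: bool = False
    min_tumors: int = 3
    min_frac: float = 0.05
    hotspot: HotspotParams = field(default_factory=HotspotParams)
    fdr: bool = False
    keep_going: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("genome", "gff3", "manifest", "outdir"):
            setattr(self, name, Path(getattr(self, name)))

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in dataclasses.asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SampleResult:
    sample_id: str
    library: SampleLibrary
    fit: SaturationFit
    cutoff: DepthCutoff
    calls: list[CandidateCall]


@dataclass
class RunResult:
    index: GenomeIndex
    samples: dict[str, SampleResult]
    cis_genes: list[CISGene]
    skipped: list[str]


def read_manifest(path: str | Path) -> list[tuple[str, Path]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty or "sample_id" not in df.columns or "path" not in df.columns:
        raise ValueError(f"manifest {path} is empty or lacks sample_id/path columns")
    out = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = path.parent / p
        out.append((str(row.sample_id), p))
    return out


def process_sample(
    sample_id: str,
    records,
    index: GenomeIndex,
    config: RunConfig,
) -> SampleResult:
    """Run one tumor through library, saturation, depth, and calling."""
    counts, n = count_per_gene(records, index)
    library = build_library(counts, n, index, alpha=config.alpha, fdr=config.fdr)
    gradients = make_gradients(n, config.n_gradients)
    # Per-sample seed derived from the run seed so samples are independent
    # yet reproducible regardless of processing order.
    sample_seed = int.from_bytes(
        hashlib.sha256(f"{config.seed}:{sample_id}".encode()).digest()[:4], "big"
    )
    points = subsample_curve(records, library, index, gradients, seed=sample_seed)
    fit = fit_curve(points, model=config.model, sample_id=sample_id,
                    seed=sample_seed)
    cutoff = depth_cutoff(fit, x_total=n,
                          use_observed_genes=config.use_observed_genes,
                          observed_genes=len(library))
    calls = call_candidates(library, cutoff)
    return SampleResult(sample_id=sample_id, library=library, fit=fit,
                        cutoff=cutoff, calls=calls)


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write the report bundle to outdir."""
    logging.basicConfig(level=config.log_level)
    manifest = read_manifest(config.manifest)  # validate before any compute
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("building genome index from %s", config.genome)
    index = build_index(config.genome, config.gff3, upstream_bp=config.upstream_bp)
    index.to_tsv(outdir / "genome_index.tsv")

    sample_dir = outdir / "samples"
    sample_dir.mkdir(exist_ok=True)
    results: dict[str, SampleResult] = {}
    records_by_sample: dict[str, list] = {}
    skipped: list[str] = []
    for sample_id, path in manifest:
        try:
            records = load_insertions(path, sample_id)
            res = process_sample(sample_id, records, index, config)
        except Exception as exc:
            if config.keep_going:
                logger.warning("skipping sample %s: %s", sample_id, exc)
                skipped.append(sample_id)
                continue
            raise RuntimeError(f"stage failure for sample {sample_id!r}") from exc
        records_by_sample[sample_id] = records
        results[sample_id] = res
        res.library.to_tsv(sample_dir / f"{sample_id}.library.tsv")
        res.fit.points_to_tsv(sample_dir / f"{sample_id}.saturation.tsv")
        res.fit.to_json(sample_dir / f"{sample_id}.fit.json", depth=res.cutoff.depth)
        with open(sample_dir / f"{sample_id}.candidates.tsv", "w") as fh:
            fh.write("gene_id\tread_count\tdepth_cutoff\tp_value\n")
            for c in res.calls:
                fh.write(f"{c.gene_id}\t{c.read_count}\t{c.depth_cutoff}\t{c.p_value:.6g}\n")

    cohort_size = len(results)
    all_calls = [c for r in results.values() for c in r.calls]
    cis_genes = call_cis(all_calls, cohort_size=cohort_size,
                         min_tumors=config.min_tumors, min_frac=config.min_frac) \
        if cohort_size else []

    # Classify each CIS gene from reads pooled across its supporting samples.
    for cg in cis_genes:
        gene = index.genes[cg.gene_id]
        pooled = [
            (r.pos, r.orientation, r.weight)
            for sid in cg.supporting_samples
            for r in records_by_sample[sid]
            if r.chrom == gene.chrom and gene.extended_start <= r.pos < gene.extended_end
        ]
        label, ff, n_regions = classify(pooled, gene, config.hotspot)
        cg.classification = label
        cg.forward_fraction = ff
        cg.hotspot_regions = n_regions

    write_cis_report(cis_genes, outdir / "cis_report.tsv",
                     gene_names={g.gene_id: g.gene_name for g in index.genes.values()})
    write_sample_gene_matrix(cis_genes, sorted(results), outdir / "sample_gene_matrix.tsv")
    if not cis_genes:
        (outdir / "cis_report.NOTE.txt").write_text(
            "No common insertion genes: no candidate recurred in at least "
            f"max({config.min_tumors}, ceil({config.min_frac} * {cohort_size})) tumors.\n"
        )

    metadata = {
        "sbcis_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "cohort_size": cohort_size,
        "skipped_samples": skipped,
        "conventions": {
            "binomial_tail": "P(X >= k)",
            "multi_overlap_assignment": "read counted for every overlapping extended gene interval",
            "depth_y": ("observed library size" if config.use_observed_genes
                        else "fitted curve at total reads"),
            "saturation_model": config.model,
            "cis_threshold": "max(min_tumors, ceil(min_frac * cohort_size)) "
                             "(conservative combination of the two stated readings)",
        },
    }
    (outdir / "run_metadata.json").write_text(json.dumps(metadata, indent=1) + "\n")
    return RunResult(index=index, samples=results, cis_genes=cis_genes, skipped=skipped)
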