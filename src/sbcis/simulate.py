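"""Synthetic SB tumor cohorts with known ground truth.

Generates a toy genome (random nucleotides at a target TA density), a
non-overlapping gene annotation, and per-tumor insertion read sets that
reproduce the features the method is built for:

* every read falls on a TA site of the emitted genome (SB's target site);
* tumors differ in driver count (log-uniform) and sequencing depth;
* a pool of cohort-level drivers recurs across tumors, each tumor adds
  private drivers, and read mass is split over a tumor's drivers by a
  weighted Dirichlet to emulate clonal skew;
* planted oncogenes concentrate promoter-aligned reads on one or two fixed
  TA hotspots, planted tumor suppressors scatter orientation-balanced reads
  over well-separated sites spanning the gene body;
* the remaining read mass is background, uniform over all genome TA sites
  (the method's null).

Private drivers are planted in at most ``max_private_recurrence`` tumors
(default 2, below the CIS floor of 3), so the cohort driver pool is the
unique recurrent signal and the emitted truth table gives well-defined
recall/false-discovery targets.  Everything is deterministic under a fixed
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .drivers import ONCOGENE, TUMOR_SUPPRESSOR
from .insertions import InsertionRecord, write_insertions

@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    Defaults give a toy cohort (3 x 2 Mb chromosomes, 300 genes, 30 tumors,
    2e4-1e5 reads each) that runs through the full pipeline in minutes on
    one CPU while exercising every stage.
    """

    seed: int = 0
    n_chroms: int = 3
    chrom_len_bp: int = 2_000_000
    ta_density: float = 0.0625          # expected TA starts per bp (iid uniform bases)
    n_genes: int = 300
    gene_len_range: tuple[int, int] = (8_000, 16_000)
    min_intergenic_gap_bp: int = 3_500  # > upstream extension: no interval overlap
    n_samples: int = 30
    drivers_per_sample: tuple[int, int] = (5, 50)      # log-uniform range
    reads_per_sample: tuple[int, int] = (20_000, 100_000)  # log-uniform range
    cohort_driver_pool: int = 15
    cis_presence_range: tuple[float, float] = (0.35, 0.8)
    driver_read_mass: float = 0.85
    clonal_skew: float = 1.0            # Dirichlet concentration for private drivers
    cis_driver_weight: float = 4.0      # concentration multiplier for pool drivers
    oncogene_frac: float = 0.5
    forward_bias: float = 0.95          # forward-read fraction for oncogenes
    max_private_recurrence: int = 2
    suppressor_site_gap_bp: int = 1200  # min separation of suppressor scatter sites

    def __post_init__(self) -> None:
        if self.drivers_per_sample[0] < 1:
            raise ValueError("drivers_per_sample lower bound must be >= 1")
        for frac in (self.driver_read_mass, self.oncogene_frac, self.forward_bias):
            if not 0 < frac < 1:
                raise ValueError("fractions must lie in (0, 1)")


@dataclass
class TruthTable:
    """Planted ground truth of one simulated cohort."""

    sample_drivers: dict[str, dict[str, int]]   # sample -> gene -> planted reads
    gene_class: dict[str, str]                  # driver gene -> oncogene/tumor_suppressor
    cis_genes: set[str]                         # pool genes planted above the CIS threshold
    planted_tumor_counts: dict[str, int]        # driver gene -> tumors planted in

    def to_tsv(self, genes_path: str | Path, sample_path: str | Path) -> None:
        with open(genes_path, "w") as fh:
            fh.write("gene_id\tclass\tn_tumors_planted\tis_cis\n")
            for g in sorted(self.planted_tumor_counts):
                fh.write(f"{g}\t{self.gene_class[g]}\t{self.planted_tumor_counts[g]}"
                         f"\t{int(g in self.cis_genes)}\n")
        with open(sample_path, "w") as fh:
            fh.write("sample_id\tgene_id\tplanted_reads\n")
            for s in sorted(self.sample_drivers):
                for g in sorted(self.sample_drivers[s]):
                    fh.write(f"{s}\t{g}\t{self.sample_drivers[s][g]}\n")


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    ta_sites: np.ndarray = field(repr=False)


@dataclass
class SimGenome:
    sequences: dict[str, str]
    genes: list[SimGene]
    ta_by_chrom: dict[str, np.ndarray]

    @property
    def all_ta(self) -> list[tuple[str, np.ndarray]]:
        return list(self.ta_by_chrom.items())


@dataclass
class SimulatedCohort:
    """File locations and truth for one emitted cohort."""

    fasta_path: Path
    gff3_path: Path
    manifest_path: Path
    sample_paths: dict[str, Path]
    truth: TruthTable


def _random_sequence(rng: np.random.Generator, length: int, ta_density: float) -> np.ndarray:
    # P(TA at a position) = P(T) * P(A); symmetric base probabilities hit
    # the target density: P(T) = P(A) = sqrt(ta_density).
    t = math.sqrt(ta_density)
    rest = (1 - 2 * t) / 2
    bases = np.frombuffer(b"ATCG", dtype="S1")
    return rng.choice(bases, size=length, p=[t, t, rest, rest])


def _ta_positions(arr: np.ndarray) -> np.ndarray:
    return np.where((arr[:-1] == b"T") & (arr[1:] == b"A"))[0]


def build_genome(config: SimConfig, rng: np.random.Generator) -> SimGenome:
    """Random genome + non-overlapping gene placement + per-gene TA sites."""
    sequences: dict[str, str] = {}
    arrays: dict[str, np.ndarray] = {}
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        arr = _random_sequence(rng, config.chrom_len_bp, config.ta_density)
        arrays[chrom] = arr
        sequences[chrom] = arr.tobytes().decode("ascii")

    per_chrom = config.n_genes // config.n_chroms
    extra = config.n_genes % config.n_chroms
    genes: list[SimGene] = []
    gi = 0
    lo, hi = config.gene_len_range
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        n_here = per_chrom + (1 if c < extra else 0)
        lengths = rng.integers(lo, hi + 1, size=n_here)
        min_gap = config.min_intergenic_gap_bp
        free = config.chrom_len_bp - int(lengths.sum()) - (n_here + 1) * min_gap
        if free < 0:
            raise ValueError(
                f"cannot place {n_here} genes of {lo}-{hi} bp with "
                f"{min_gap} bp gaps on a {config.chrom_len_bp} bp chromosome"
            )
        gaps = min_gap + np.floor(rng.dirichlet(np.ones(n_here + 1)) * free).astype(int)
        ta = _ta_positions(arrays[chrom])
        cursor = 0
        for j in range(n_here):
            cursor += int(gaps[j])
            start, end = cursor, cursor + int(lengths[j])
            cursor = end
            gi += 1
            genes.append(SimGene(
                gene_id=f"simg{gi:04d}", chrom=chrom, start=start, end=end,
                strand="+" if rng.random() < 0.5 else "-",
                ta_sites=ta[(ta >= start) & (ta < end - 1)],
            ))
    ta_by_chrom = {c: _ta_positions(a) for c, a in arrays.items()}
    return SimGenome(sequences=sequences, genes=genes, ta_by_chrom=ta_by_chrom)


def write_genome(genome: SimGenome, fasta_path: str | Path, gff3_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, seq in genome.sequences.items():
            fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
        for g in genome.genes:
            fh.write(
                f"{g.chrom}\tsbcis_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID=gene:{g.gene_id};Name={g.gene_id.upper()};"
                f"biotype=protein_coding\n"
            )


class _DriverCatalog:
    """Lazily assigns each driver gene a class and its planted site set.

    Oncogenes get 1-2 fixed hotspot TA sites reused by every tumor carrying
    them; suppressors get 6-14 scatter sites separated by at least
    ``suppressor_site_gap_bp`` so pooled insertions form many distinct
    regions.
    """

    def __init__(self, config: SimConfig, rng: np.random.Generator) -> None:
        self.config = config
        self.rng = rng
        self.gene_class: dict[str, str] = {}
        self.gene_sites: dict[str, np.ndarray] = {}

    def ensure(self, gene: SimGene) -> None:
        if gene.gene_id in self.gene_class:
            return
        cfg, rng = self.config, self.rng
        if rng.random() < cfg.oncogene_frac:
            cls = ONCOGENE
            n_sites = int(rng.integers(1, 3))
            sites = rng.choice(gene.ta_sites, size=min(n_sites, len(gene.ta_sites)),
                               replace=False)
        else:
            cls = TUMOR_SUPPRESSOR
            span = gene.end - gene.start
            target = int(np.clip(span // cfg.suppressor_site_gap_bp, 6, 14))
            chosen: list[int] = []
            for pos in rng.permutation(gene.ta_sites):
                if all(abs(int(pos) - p) >= cfg.suppressor_site_gap_bp for p in chosen):
                    chosen.append(int(pos))
                    if len(chosen) == target:
                        break
            sites = np.array(sorted(chosen))
        self.gene_class[gene.gene_id] = cls
        self.gene_sites[gene.gene_id] = np.sort(np.asarray(sites, dtype=np.int64))


def _log_uniform_int(rng: np.random.Generator, low: int, high: int) -> int:
    return int(round(math.exp(rng.uniform(math.log(low), math.log(high)))))


def _emit_driver_reads(
    gene: SimGene, n_reads: int, catalog: _DriverCatalog, rng: np.random.Generator,
    config: SimConfig, out: list[tuple[str, int, str, int]],
) -> None:
    """Append (chrom, pos, orientation, weight) tuples for one driver gene."""
    sites = catalog.gene_sites[gene.gene_id]
    cls = catalog.gene_class[gene.gene_id]
    split = rng.multinomial(n_reads, np.full(len(sites), 1.0 / len(sites)))
    fwd_p = config.forward_bias if cls == ONCOGENE else 0.5
    for pos, cnt in zip(sites, split):
        if cnt == 0:
            continue
        n_fwd = int(rng.binomial(cnt, fwd_p))
        fwd_strand = gene.strand
        rev_strand = "-" if gene.strand == "+" else "+"
        if n_fwd:
            out.append((gene.chrom, int(pos), fwd_strand, n_fwd))
        if cnt - n_fwd:
            out.append((gene.chrom, int(pos), rev_strand, cnt - n_fwd))


def _emit_background_reads(
    genome: SimGenome, n_reads: int, rng: np.random.Generator,
    out: list[tuple[str, int, str, int]],
) -> None:
    chroms = list(genome.ta_by_chrom)
    sizes = np.array([len(genome.ta_by_chrom[c]) for c in chroms], dtype=float)
    counts = rng.multinomial(n_reads, sizes / sizes.sum())
    for chrom, cnt in zip(chroms, counts):
        if cnt == 0:
            continue
        positions = rng.choice(genome.ta_by_chrom[chrom], size=cnt, replace=True)
        orientations = rng.random(cnt) < 0.5
        for pos, fwd in zip(positions, orientations):
            out.append((chrom, int(pos), "+" if fwd else "-", 1))


def _tuples_to_records(
    tuples: list[tuple[str, int, str, int]], sample_id: str
) -> list[InsertionRecord]:
    agg: dict[tuple[str, int, str], int] = {}
    for chrom, pos, orient, w in tuples:
        agg[(chrom, pos, orient)] = agg.get((chrom, pos, orient), 0) + w
    return [
        InsertionRecord(sample_id=sample_id, chrom=c, pos=p, orientation=o, weight=w)
        for (c, p, o), w in sorted(agg.items())
    ]


def simulate_cohort(config: SimConfig, outdir: str | Path) -> SimulatedCohort:
    """Emit a full synthetic cohort (FASTA, GFF3, insertion TSVs, manifest,
    truth tables) under ``outdir``.  Byte-identical under a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome = build_genome(config, rng)
    fasta_path = outdir / "genome.fa"
    gff3_path = outdir / "genes.gff3"
    write_genome(genome, fasta_path, gff3_path)

    genes_by_id = {g.gene_id: g for g in genome.genes}
    catalog = _DriverCatalog(config, rng)

    # Cohort driver pool and its per-gene tumor membership.
    pool_ids = [g.gene_id for g in
                rng.choice(np.array(genome.genes, dtype=object),
                           size=config.cohort_driver_pool, replace=False)]
    lo_f, hi_f = config.cis_presence_range
    pool_samples: dict[str, set[int]] = {}
    for gid in pool_ids:
        frac = rng.uniform(lo_f, hi_f)
        k = max(1, int(round(frac * config.n_samples)))
        pool_samples[gid] = set(
            int(s) for s in rng.choice(config.n_samples, size=k, replace=False)
        )
        catalog.ensure(genes_by_id[gid])

    private_usage: dict[str, int] = {}
    non_pool = [g.gene_id for g in genome.genes if g.gene_id not in pool_ids]

    sample_paths: dict[str, Path] = {}
    sample_drivers: dict[str, dict[str, int]] = {}
    d_lo, d_hi = config.drivers_per_sample
    r_lo, r_hi = config.reads_per_sample
    for s in range(config.n_samples):
        sample_id = f"tumor{s + 1:03d}"
        n_reads = _log_uniform_int(rng, r_lo, r_hi)
        n_drivers = _log_uniform_int(rng, d_lo, d_hi)
        cis_here = sorted(g for g in pool_ids if s in pool_samples[g])
        n_private = max(0, n_drivers - len(cis_here))
        available = [g for g in non_pool
                     if private_usage.get(g, 0) < config.max_private_recurrence]
        chosen_private = [
            str(g) for g in rng.choice(np.array(available, dtype=object),
                                       size=min(n_private, len(available)),
                                       replace=False)
        ]
        for g in chosen_private:
            private_usage[g] = private_usage.get(g, 0) + 1
            catalog.ensure(genes_by_id[g])

        driver_ids = cis_here + sorted(chosen_private)
        conc = np.array([
            config.cis_driver_weight * config.clonal_skew
            if g in pool_samples else config.clonal_skew
            for g in driver_ids
        ])
        shares = rng.dirichlet(conc)
        driver_total = int(round(config.driver_read_mass * n_reads))
        per_driver = rng.multinomial(driver_total, shares)

        tuples: list[tuple[str, int, str, int]] = []
        planted: dict[str, int] = {}
        for gid, cnt in zip(driver_ids, per_driver):
            planted[gid] = int(cnt)
            if cnt > 0:
                _emit_driver_reads(genes_by_id[gid], int(cnt), catalog, rng,
                                   config, tuples)
        _emit_background_reads(genome, n_reads - driver_total, rng, tuples)

        records = _tuples_to_records(tuples, sample_id)
        path = outdir / f"{sample_id}.insertions.tsv"
        write_insertions(records, path)
        sample_paths[sample_id] = path
        sample_drivers[sample_id] = planted

    manifest_path = outdir / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("sample_id\tpath\n")
        for sid in sorted(sample_paths):
            fh.write(f"{sid}\t{sample_paths[sid].name}\n")

    planted_counts: dict[str, int] = {}
    for drivers in sample_drivers.values():
        for g, cnt in drivers.items():
            if cnt > 0:
                planted_counts[g] = planted_counts.get(g, 0) + 1
    threshold = max(3, math.ceil(0.05 * config.n_samples))
    cis_truth = {g for g in pool_ids if planted_counts.get(g, 0) >= threshold}

    truth = TruthTable(sample_drivers=sample_drivers,
                       gene_class=dict(catalog.gene_class),
                       cis_genes=cis_truth,
                       planted_tumor_counts=planted_counts)
    truth.to_tsv(outdir / "truth_genes.tsv", outdir / "truth_sample_drivers.tsv")
    return SimulatedCohort(fasta_path=fasta_path, gff3_path=gff3_path,
                           manifest_path=manifest_path, sample_paths=sample_paths,
                           truth=truth)


def simulate_skewed_sample(
    config: SimConfig,
    dominant_site_frac: float,
    outdir: str | Path,
    n_reads: int = 200_000,
    n_other_drivers: int = 10,
) -> tuple[Path, dict]:
    """One tumor whose reads pile overwhelmingly onto a single TA site.

    Emulates the extreme clonal-skew failure mode: a huge read total carried
    almost entirely by one insertion, which should yield a small candidate
    list despite the deep sequencing.  Returns (insertion file path, info
    dict with the dominant gene/site, planted drivers, and genome paths).
    """
    if not 0 < dominant_site_frac < 1:
        raise ValueError("dominant_site_frac must be in (0, 1)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome = build_genome(config, rng)
    fasta_path = outdir / "genome.fa"
    gff3_path = outdir / "genes.gff3"
    write_genome(genome, fasta_path, gff3_path)

    catalog = _DriverCatalog(config, rng)
    order = rng.permutation(len(genome.genes))
    dominant_gene = genome.genes[int(order[0])]
    others = [genome.genes[int(i)] for i in order[1 : 1 + n_other_drivers]]
    dom_site = int(rng.choice(dominant_gene.ta_sites))

    n_dom = int(round(dominant_site_frac * n_reads))
    rest = n_reads - n_dom
    driver_total = int(round(config.driver_read_mass * rest))
    tuples: list[tuple[str, int, str, int]] = [
        (dominant_gene.chrom, dom_site, dominant_gene.strand, n_dom)
    ]
    planted: dict[str, int] = {dominant_gene.gene_id: n_dom}
    if others and driver_total > 0:
        shares = rng.dirichlet(np.full(len(others), config.clonal_skew))
        for gene, cnt in zip(others, rng.multinomial(driver_total, shares)):
            catalog.ensure(gene)
            planted[gene.gene_id] = int(cnt)
            if cnt > 0:
                _emit_driver_reads(gene, int(cnt), catalog, rng, config, tuples)
    _emit_background_reads(genome, rest - driver_total, rng, tuples)

    sample_id = "skewed001"
    records = _tuples_to_records(tuples, sample_id)
    path = outdir / f"{sample_id}.insertions.tsv"
    write_insertions(records, path)
    info = {
        "sample_id": sample_id,
        "dominant_gene": dominant_gene.gene_id,
        "dominant_site": dom_site,
        "planted": planted,
        "fasta_path": fasta_path,
        "gff3_path": gff3_path,
        "n_reads": n_reads,
    }
    return path, info
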