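"""Per-gene binomial insertion significance and sample gene libraries.

Under the null, each of a tumor's n mapped reads lands on any genome TA
site with equal probability, so the read count k of a gene with TA content
T_g is Binomial(n, p) with p = T_g / T_G.  A gene is a significant SB
insertion gene for the sample when the upper tail P(X >= k) falls below
alpha (default 0.05, uncorrected); the significant genes of one tumor form
its gene library, the substrate for saturation analysis and driver calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .genome_index import GenomeIndex
    from .insertions import SampleGeneCount

DEFAULT_ALPHA = 0.05


def binomial_tail(k: int, n: int, p: float) -> float:
    """Upper-tail binomial probability P(X >= k) for X ~ Binomial(n, p).

    Computed through the regularized incomplete beta function (scipy's
    survival function), which is numerically stable in the far tail; the
    result may underflow to exactly 0.0 for extreme k, mirroring reported
    P values of 0.

    Raises ``ValueError`` when k is outside [0, n] or p outside [0, 1].
    """
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n]; got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1]; got {p}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


@dataclass
class LibraryEntry:
    read_count: int
    p_value: float


@dataclass
class SampleLibrary:
    """One tumor's significant-insertion gene library.

    ``entries`` maps gene_id -> (k, P_g) for every gene with P_g < alpha;
    ``total_reads`` is the binomial n (the sample's total clean reads).
    """

    sample_id: str
    total_reads: int
    entries: dict[str, LibraryEntry] = field(default_factory=dict)
    alpha: float = DEFAULT_ALPHA

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tk\tn\tp_value\n")
            for gene_id in sorted(self.entries):
                e = self.entries[gene_id]
                fh.write(f"{gene_id}\t{e.read_count}\t{self.total_reads}\t{e.p_value:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str,
                 alpha: float = DEFAULT_ALPHA) -> "SampleLibrary":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        if header[:4] != ["gene_id", "k", "n", "p_value"]:
            raise ValueError(f"{path} is not a sample library TSV")
        n = int(rows[0][2]) if rows else 1
        lib = cls(sample_id=sample_id, total_reads=n, alpha=alpha)
        for gene_id, k, _, pval in rows:
            lib.entries[gene_id] = LibraryEntry(read_count=int(k),
                                                p_value=float(pval))
        return lib


def build_library(
    counts: Mapping[str, "SampleGeneCount"],
    n: int,
    index: "GenomeIndex",
    alpha: float = DEFAULT_ALPHA,
    fdr: bool = False,
) -> SampleLibrary:
    """Test every gene with k >= 1 reads and keep those with P_g < alpha.

    Genes with no reads are never tested.  ``fdr=True`` switches to
    Benjamini-Hochberg adjusted P values (off by default: the method uses
    raw P < 0.05).  A counted gene missing from the index is a hard error
    (index/annotation mismatch).
    """
    if n < 1:
        raise ValueError("total read count n must be >= 1")
    sample_id = next(iter(counts.values())).sample_id if counts else ""
    tested: list[tuple[str, int, float]] = []
    for gene_id, sgc in counts.items():
        if sgc.read_count == 0:
            continue
        gene = index.genes.get(gene_id)
        if gene is None:
            raise KeyError(
                f"gene {gene_id!r} has counts but is absent from the index"
            )
        pval = binomial_tail(sgc.read_count, n, gene.insert_prob)
        tested.append((gene_id, sgc.read_count, pval))

    if fdr and tested:
        adjusted = stats.false_discovery_control([t[2] for t in tested])
        tested = [(g, k, float(q)) for (g, k, _), q in zip(tested, adjusted)]

    lib = SampleLibrary(sample_id=sample_id, total_reads=n, alpha=alpha)
    for gene_id, k, pval in tested:
        if pval < alpha:
            lib.entries[gene_id] = LibraryEntry(read_count=k, p_value=pval)
    return lib
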