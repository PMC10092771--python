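"""Per-tumor saturation analysis and the tailored depth cutoff.

Tumors differ widely in how many drivers they carry, so a single read-depth
cutoff across a cohort is either too strict for driver-rich tumors or too
lenient for driver-poor ones.  For each tumor we subsample its reads at 50
increasing sizes (nested draws without replacement), count how many of the
tumor's library genes each subsample detects, fit a saturating curve
y = a*x / (b + x) (or y = a*(1 - exp(-x/b))) by nonlinear least squares,
and set the tumor's depth cutoff to

    depth = round(x_total / y(x_total)),

the average read support per detected gene at full depth.  Driver-poor
tumors thus get strict cutoffs and driver-rich tumors lenient ones.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

if TYPE_CHECKING:  # pragma: no cover
    from .genome_index import GenomeIndex
    from .insertions import InsertionRecord
    from .significance import SampleLibrary

logger = logging.getLogger(__name__)

DEFAULT_N_GRADIENTS = 50

MODELS: dict[str, Callable] = {
    "hyperbolic": lambda x, a, b: a * x / (b + x),
    "exponential": lambda x, a, b: a * (1.0 - np.exp(-x / b)),
}


def make_gradients(total_reads: int, n_gradients: int = DEFAULT_N_GRADIENTS) -> list[int]:
    """Subsample sizes g, 2g, ..., total_reads with g = total // n_gradients.

    The division remainder is folded into the last step so the final
    gradient always equals ``total_reads``.  When the sample has fewer reads
    than gradients, one gradient per read (1..total) is emitted with a
    warning.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if total_reads < n_gradients:
        logger.warning(
            "sample has %d reads < %d gradients; using one gradient per read",
            total_reads, n_gradients,
        )
        return list(range(1, total_reads + 1))
    g = total_reads // n_gradients
    sizes = [g * i for i in range(1, n_gradients)]
    sizes.append(total_reads)
    return sizes


def subsample_curve(
    records: Sequence["InsertionRecord"],
    library: "SampleLibrary",
    index: "GenomeIndex",
    gradients: Sequence[int],
    seed: int,
) -> list[tuple[int, int]]:
    """Nested random subsampling: (reads drawn, library genes detected).

    Each read unit is annotated once (a weight-w record contributes w
    units), a single seeded permutation orders all units, and each gradient
    is the prefix of that permutation — so larger subsamples extend smaller
    ones and y is monotone non-decreasing within a run.  y counts distinct
    library genes hit by at least one subsampled read.
    """
    n_units = sum(r.weight for r in records)
    if gradients and max(gradients) > n_units:
        raise ValueError("gradient size exceeds total read count")

    # Per unique site: tuple of library-gene ids covering it (usually 0 or 1).
    unit_sites = np.empty(n_units, dtype=np.int64)
    site_ids: list[tuple[str, ...]] = []
    site_index: dict[tuple[str, int], int] = {}
    u = 0
    for rec in records:
        key = (rec.chrom, rec.pos)
        idx = site_index.get(key)
        if idx is None:
            genes = tuple(g for g in index.genes_at(rec.chrom, rec.pos)
                          if g in library)
            idx = site_index[key] = len(site_ids)
            site_ids.append(genes)
        unit_sites[u : u + rec.weight] = idx
        u += rec.weight

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_units)
    seen: set[str] = set()
    points: list[tuple[int, int]] = []
    boundaries = iter(sorted(gradients))
    next_b = next(boundaries, None)
    for i, unit in enumerate(order, start=1):
        for gene in site_ids[unit_sites[unit]]:
            seen.add(gene)
        while next_b is not None and i == next_b:
            points.append((next_b, len(seen)))
            next_b = next(boundaries, None)
    return points


@dataclass
class SaturationFit:
    """Fitted saturation curve for one tumor."""

    sample_id: str
    points: list[tuple[int, int]]
    a: float
    b: float
    r_squared: float
    model: str = "hyperbolic"
    seed: int | None = None
    degenerate: bool = False

    def predict(self, x: float) -> float:
        if self.degenerate:
            return self.a
        return float(MODELS[self.model](x, self.a, self.b))

    def to_json(self, path: str | Path, depth: int | None = None) -> None:
        payload = {
            "sample_id": self.sample_id, "model": self.model, "a": self.a,
            "b": self.b, "r_squared": self.r_squared, "seed": self.seed,
            "degenerate": self.degenerate,
        }
        if depth is not None:
            payload["depth"] = depth
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    def points_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("x_reads\ty_genes\n")
            for x, y in self.points:
                fh.write(f"{x}\t{y}\n")


def fit_curve(
    points: Sequence[tuple[float, float]],
    model: str = "hyperbolic",
    sample_id: str = "",
    seed: int | None = None,
) -> SaturationFit:
    """Nonlinear least-squares fit of the saturation model to (x, y) points.

    Falls back to a grid of initial values when the default initialization
    fails to converge.  Degenerate input (all y equal) is reported as a flat
    curve a = y with b undefined and flagged, rather than an error, since
    fully saturated tumors genuinely produce flat curves.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points to fit")

    if np.ptp(y) == 0:
        logger.warning("sample %s: degenerate saturation curve (constant y=%g)",
                       sample_id, y[0])
        return SaturationFit(sample_id=sample_id, points=list(points), a=float(y[0]),
                             b=float("nan"), r_squared=1.0, model=model, seed=seed,
                             degenerate=True)

    func = MODELS[model]
    ymax = y.max()
    inits = [(ymax * 1.2, np.median(x))]
    # grid fallback initializations
    for fa in (1.0, 1.5, 3.0, 10.0):
        for fb in np.geomspace(max(x.min(), 1.0), x.max() * 10, 5):
            inits.append((max(ymax * fa, 1e-6), fb))

    best: tuple[float, float, float] | None = None  # (sse, a, b)
    for i, p0 in enumerate(inits):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    func, x, y, p0=p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                    maxfev=10000,
                )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y - func(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, float(popt[0]), float(popt[1]))
        if i == 0 and best[0] < 1e-20:
            break
    if best is None:
        raise RuntimeError(f"saturation fit failed for sample {sample_id!r}")

    sse, a, b = best
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sstot if sstot > 0 else 1.0
    return SaturationFit(sample_id=sample_id, points=[(float(px), float(py)) for px, py in points],
                         a=a, b=b, r_squared=r2, model=model, seed=seed)


@dataclass
class DepthCutoff:
    """Per-tumor read-depth cutoff: average reads per detected gene."""

    sample_id: str
    depth: int
    x_total: int
    y_at_total: float


def tailored_depth(x_total: int, y_at_total: float) -> int:
    """depth = round-half-up(x_total / y_at_total), floored at 1."""
    if y_at_total <= 0:
        raise ValueError(f"gene number at full depth must be > 0; got {y_at_total}")
    return max(1, int(np.floor(x_total / y_at_total + 0.5)))


def depth_cutoff(
    fit: SaturationFit,
    x_total: int,
    use_observed_genes: bool = False,
    observed_genes: int | None = None,
) -> DepthCutoff:
    """Derive a tumor's depth cutoff from its saturation fit.

    By default y at full depth is the *fitted* curve evaluated at x_total
    (smoothing subsampling noise); ``use_observed_genes=True`` substitutes
    the raw library size instead.
    """
    if use_observed_genes:
        if observed_genes is None:
            raise ValueError("observed_genes required when use_observed_genes=True")
        y = float(observed_genes)
    else:
        y = fit.predict(x_total)
    if y <= 0:
        raise ValueError(
            f"sample {fit.sample_id!r}: pathological fit, predicted gene "
            f"number {y} at x={x_total}"
        )
    return DepthCutoff(sample_id=fit.sample_id, depth=tailored_depth(x_total, y),
                       x_total=x_total, y_at_total=y)
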