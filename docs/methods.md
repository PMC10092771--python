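# Methods

## Model

Sleeping Beauty transposons reintegrate only at TA dinucleotides, jumps are
taken to be uniform over the genome's TA sites and mutually independent.
Under that null, the read count of gene $g$ in a tumor with $n$ mapped reads
is $X \sim \mathrm{Binomial}(n, p_g)$ with $p_g = T_g/T_G$, where $T_g$
counts TA sites in the gene's extended interval and $T_G$ in the whole
genome. Significance is the upper tail $P(X \ge k)$: the question is always
whether a gene attracted *surprisingly many* reads. $n$ is the tumor's
total clean mapped read count, not the sum of gene-assigned reads — a read
in intergenic space still counts as a trial.

Conventions chosen where a fixed rule was needed:

* **Coordinates** are 0-based half-open internally; GFF3's 1-based
  inclusive intervals are converted on read.
* **Upstream extension** (default 3000 bp) is strand-aware (5′ of the
  gene), since its purpose is to capture promoter-engaging oncogenic
  insertions; it is clipped at chromosome edges.
* A TA **spanning an interval boundary** belongs to the interval iff the
  position of its T does. Dinucleotides containing `N` never count, so
  assembly gaps cannot inflate $T_g$.
* A read inside **several overlapping extended intervals** is counted for
  every one of them; $n$ is unaffected.
* The binomial tail is $P(X \ge k)$, not $P(X > k)$ (negligible difference
  at screen scale; recorded in run metadata).
* No multiple-testing correction by default ($P_g < 0.05$ raw); a
  Benjamini–Hochberg mode exists but is off.

## Saturation analysis and the tailored depth

Each tumor's reads are subsampled at 50 sizes $g, 2g, \dots, n$ with
$g = \lfloor n/50 \rfloor$ (remainder folded into the last step; one
gradient per read if $n < 50$). Draws are uniform without replacement and
*nested* — each larger subsample extends the previous one — so the detected
gene count $y$ is monotone within a run and the whole curve costs one
permutation. $y$ counts distinct library genes hit by at least one
subsampled read; because read-to-gene assignment is deterministic,
subsampling pre-annotated records is mathematically identical to
re-annotating each subsample, at a fraction of the cost.

The saturating relationship between read number $x$ and gene number $y$ is
not pinned to a functional form by the design it follows; the default here
is the two-parameter hyperbolic saturation $y = ax/(b+x)$ (saturating at
$a$, linear near the origin, half-saturation at $x=b$), with
$y = a(1-e^{-x/b})$ selectable. The chosen model is recorded in every
output. Fits use Levenberg–Marquardt least squares (trust-region with
positivity bounds), initialized at $a_0 = 1.2\,y_{\max}$,
$b_0 = \mathrm{median}(x)$, with a grid of fallback initializations before
declaring failure; $R^2 = 1 - SS_{res}/SS_{tot}$ is reported from the final
fit. A curve with constant $y$ (a tumor already saturated at the first
gradient) is reported as the flat fit $a = y$, $b$ undefined, flagged
`degenerate`, and predicts $y$ everywhere — a real phenomenon for strongly
clonal tumors, not an error.

The cutoff is $\mathrm{depth} = \max(1, \mathrm{round}(x_{total}/y(x_{total})))$
(round half up; integer depths). By default $y(x_{total})$ is the *fitted*
curve at the full read count, smoothing subsampling noise; a
`--use-observed-genes` switch substitutes the raw library size, the literal
"total significant insertion gene number" reading. For the hyperbolic
model depth $(b+x)/a$ increases with $x$: deeper sequencing of the same
gene richness demands proportionally more support per candidate.

## Cohort calling and classification

Candidates ($k \ge$ depth, within the library) are aggregated; a gene is a
common insertion gene when it recurs in at least
$\max(\texttt{min\_tumors}, \lceil \texttt{min\_frac} \cdot N \rceil)$
tumors (defaults 3 and 5%). The two stated readings of the recurrence rule
("at least 3" / "more than 5%") are combined conservatively as a max; both
knobs are exposed and the choice is recorded in run metadata. Output
ordering is fully deterministic (tumor count, then read total, then
gene id).

Classification pools the supporting tumors' reads inside the gene's
extended interval. The forward fraction is the share of reads whose
transposon CAG-promoter orientation matches the gene strand. Hotspot
regions are counted operationally: positions carrying less than
`min_site_read_frac` (default 0.2%) of the pooled reads are dropped first —
sporadic background insertions would otherwise bridge genuinely distinct
clusters into one — then surviving positions are gap-merged (≤ 500 bp) and
clusters holding ≥ 5% of the pooled reads count as hotspots. A gene is an
oncogene iff forward fraction > 0.5 (strict) **and** hotspots ≤ 3;
otherwise a tumor suppressor. All four constants are configurable
(`HotspotParams`); the 0.2% site floor and 5% region floor mirror the
read-share floors used when insertion patterns of this kind are displayed
and summarized in practice.

## Synthetic cohorts

The generator emulates exactly the features the method is sensitive to:

* genomes as iid nucleotide sequences with $P(T)=P(A)=\sqrt{d}$ so the TA
  start density is approximately $d$ (default 1/16, the iid-uniform value);
* non-overlapping genes placed with intergenic gaps of at least 3500 bp —
  deliberately larger than the 3000 bp upstream extension so extended
  intervals never overlap and planted ground truth is unambiguous;
* per-tumor read totals (log-uniform 2×10⁴–10⁵) and driver counts
  (log-uniform 5–50), a 15-gene cohort driver pool each planted in 35–80%
  of tumors, private drivers capped at 2 tumors each (below the CIS floor
  of 3), and read mass split over a tumor's drivers by a Dirichlet whose
  concentration is 4× higher for pool drivers (recurrent drivers as
  stronger clones);
* oncogenes as 1–2 fixed TA hotspots with 95% promoter-aligned reads;
  suppressors as 6–14 scatter sites ≥ 1200 bp apart reused across tumors,
  with balanced orientation; 85% of a tumor's reads on its drivers, the
  rest uniform over all genome TA sites (the null);
* an extreme-skew generator placing a chosen fraction (e.g. 97%) of a large
  read total on a single TA site.

Everything derives from one seed and regenerating a cohort is
byte-identical. What the simulator does **not** model: sequencing or
mapping error, local hopping near the transposon donor locus, chromatin or
expression biases of integration, and realistic genome composition. At toy
scale genes also occupy a far larger fraction of the genome than in a real
mammalian assembly, so per-gene null probabilities are orders of magnitude
larger; consequently toy libraries contain only strongly clonal drivers and
saturation curves typically plateau at the first gradient (the degenerate
flat-fit path). Passing tests therefore demonstrate the pipeline's logic,
determinism and thresholds, not performance on realistic noise spectra —
curve-fit accuracy is instead validated directly on synthetic saturation
curves spanning $a \in [50, 2000]$, $b \in [10^3, 10^6]$.

## Problem sizes used in validation

The simulation-based checks run a 30-tumor default cohort (3 × 2 Mb
chromosomes, 300 genes), 100 synthetic saturation curves at 1% noise, a
40-point randomized binomial grid with $n \le 1000$ against an exact
big-integer rational oracle, and a 200 000-read skewed sample — sizes
chosen so a full validation completes in well under a minute per component
on one CPU while leaving each estimate's sampling error far from the
asserted margins.

## Known limitations

* The functional form of the saturation curve is the method's largest open
  choice; both provided forms are phenomenological.
* The binomial null ignores TA-site accessibility bias and local hopping,
  which inflate significance near donor loci in real screens.
* Classification is a two-feature heuristic; genes with mixed mechanisms
  (e.g. truncating insertions clustered at one exon) can be mislabeled.
* With `min_site_read_frac = 0`, a fully scattered gene can present zero
  qualifying hotspot regions and then classification rests on the forward
  fraction alone.
* Reads are assigned to all overlapping extended intervals; in gene-dense
  regions of real genomes this double-counts evidence across neighbors.
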