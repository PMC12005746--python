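# Methods

This note documents the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a user auditing results should
know about.

## X:A dosage ratio and bootstrap null (`pgcx.dosage`)

The X:A ratio for a sample is the median TPM of expressed X-linked genes
over the median TPM of expressed autosomal genes, with "expressed"
meaning strictly above `min_tpm` (default 1 TPM). Catalogued escapees are
removed from the X-linked numerator set only: escapees are X-linked by
definition, so they cannot be removed from the autosomal background, and
leaving them in the numerator would raise the X estimate in every
genotype regardless of XCI state — the quantity of interest is the
dosage of the silenceable X.

Because the X chromosome contributes far fewer genes than all autosomes,
the ratio of medians has a sampling spread that depends on the X gene
count. The null therefore resamples `set_size` autosomal genes (default:
the filtered X gene count) without replacement, scores each subset's
median over the global autosomal median, and repeats `n_boot = 1000`
times. Reported are the empirical central 95% interval (2.5/97.5
percentiles) and an add-one two-sided empirical p-value,
`(1 + #{|b−1| ≥ |observed−1|}) / (n_boot+1)`; the add-one correction
keeps p strictly positive at finite replication. Sampling is without
replacement within a replicate ("random sets" of genes are subsets), and
replicates are independent.

Medians use the standard midpoint convention for even counts. The
chromosome expression track assigns genes to sliding windows by TSS and
reports the window mean; windows with no gene carry NaN, never zero,
since absence of annotation is not absence of expression.

## DEG sets and escapee classification (`pgcx.degsets`)

The package's differential test is a deliberately simple stand-in: per
gene, Welch's t on log2(TPM+1) with Benjamini–Hochberg correction, and a
linear fold-change screen (>1.5× in either direction, i.e.
|log2FC| > log2 1.5) at FDR < 0.05. It makes no attempt at count
dispersion modelling; externally computed DEG tables (edgeR, DESeq2,
MAST, ...) are first-class inputs through `read_deg_tsv` and none of the
downstream set logic depends on which test produced the table.
Degenerate genes with zero variance in both groups get p = 0 when the
means differ and p = 1 otherwise.

"Commonly dysregulated" genes are the intersection of all contrast
tables. Direction agreement across contrasts is required by default —
a gene up in three contrasts and down in a fourth is not evidence of a
shared dosage effect — but `require_direction=False` keeps such genes
flagged `mixed`, since the literature's Venn-style summaries do not
always state the convention.

Per-chromosome partitioning reports up/down counts and their ratio
(`inf` when nothing is downregulated; chromosomes with no DEGs are
omitted). Escapee classification partitions the X-linked upregulated
set by catalog membership into constitutive / variable / novel; the
partition is always exhaustive and disjoint, and when an annotation is
supplied, non-X input genes are an error rather than a silent drop.

## QP identity scoring (`pgcx.identity`)

The model: a cell is a non-negative convex mixture of K reference
lineage profiles, fitted by `min‖x − Sw‖²` over the probability simplex.
The optimum is found by enumerating the 2^K − 1 active sets of the
equality-constrained KKT system and keeping the feasible face solution
with the smallest objective. Enumeration is exact — there is no
convergence tolerance — and is used for every K up to 12 (at the K = 3
used here, 7 faces per cell); larger K is refused rather than silently
approximated. Ties between equally optimal faces (degenerate geometry)
resolve toward the lower lineage index by enumeration order, with a
strict-improvement margin of 1e-12 on the objective.

Inputs are taken as pre-harmonized: references and queries must share
gene order and scale. The package applies no transform inside the
solver; the conventional space is log2(TPM+1) restricted to the
reference's informative genes, and the synthetic mixtures are generated
and fitted in one consistent space. `grid_search_objective` provides an
independent brute-force verification: the objective evaluated on every
simplex point with coordinates in multiples of 0.001 (~5×10^5 points for
K = 3). A coarse grid cannot certify the optimum beyond its own
curvature resolution, so the meaningful checks are one-sided (the exact
solver is never worse than the grid by more than 1e-6) and two-sided at
the bound λ_max(SᵀS)·K·step².

Weight densities in population summaries use fixed 0.02-width histogram
bins on [0,1] — reproducible and kernel-free.

## Pseudotime, temporal smoothing, exclusivity (`pgcx.trajectory`)

Pseudotime is a single-lineage principal-curve procedure: PCA on
log2(x+1) expression, centred but never variance-scaled (scaling would
let low-information genes dominate the geometry); then alternate
(1) cubic B-spline smoothing of each PC coordinate against the current
ordering and (2) orthogonal projection of every cell onto the resulting
polyline (100 grid points), until the mean ordering change falls below
1e-4 or 50 iterations. Arc length along the curve, rescaled to [0,1], is
the pseudotime. PC signs follow a rotation-invariant convention (the
largest-magnitude score on each component is positive), so a rigid
rotation of the input space cannot flip the axis. Arc length cannot
distinguish start from end, so a root population is a required input and
the axis is oriented to put its mean below 0.5. Duplicated cells receive
identical pseudotime (average ranks at initialisation, identical
projections afterwards). This is a deliberately single-lineage tool: no
branching, no multi-curve averaging.

Temporal profiles are least-squares cubic B-splines with `df` basis
functions (default 6; interior knots at pseudotime quantiles), solved by
`lstsq` without penalty so that any polynomial of degree ≤ 3 is
reproduced exactly.

The mutual-exclusivity statistic binarizes both genes at `on_threshold`
(default 1 TPM, the same expression filter used elsewhere), compares the
observed double-positive count with the independence expectation
n·p_a·p_b, and scores (expected − observed)/max(expected, 1), clipped to
[−1, 1] (the clip matters only when expected < 1, where the unclipped
value is ill-scaled). The one-sided p-value permutes the second gene's
labels (`n_perm = 10000`, add-one corrected), asking whether so few
double positives could arise under independence. If either gene has no
positive cells the question is undecidable and the result is flagged
`undetermined` (score 0, p 1) instead of fabricating a signal. No named
test exists in the source literature for this pattern; this permutation
construction is this package's operationalization and is labelled as
such.

## Cistrome analysis (`pgcx.cistrome`)

Coordinates: peaks are BED-convention (0-based, half-open) throughout;
gene annotation arrives 1-based inclusive and TSSs are shifted to the
0-based axis on use. Peak filtering keeps scores ≥ `min_score`
(default 25 — "under 25" is removed, so the boundary stays). TSS
annotation anchors at the peak midpoint `floor((start+end)/2)` and links
every gene whose TSS lies within a closed ±125 kb window, the reported
median enhancer–promoter distance in the human genome; distances are
signed (TSS − midpoint). Midpoint anchoring and the closed boundary are
this package's choices where the convention is typically unstated.

PWM scanning scores Σ log₂(p_j(base)/bg(base)) in bits over every offset
and both strands (the reverse strand via the reverse-complemented
matrix), with `N` contributing 0 bits — exactly neutral under the
background. Ties within 1e-9 bits (below which summation order could
flip the winner) resolve to the smaller offset, then the forward strand.
A pseudocount of 1e-3 is applied to PWM probabilities on construction so
log-odds are finite; consequently writing and re-reading a JASPAR matrix
reapplies it and round trips are approximate at ~2×10⁻³ in probability.

The high/low-affinity split is a log-odds threshold θ in bits, a
required explicit parameter: the conservation information that
originally motivated such splits is not computable from sequence alone
and is out of scope here. Peak-set intersection keeps peaks of A with
≥ `min_overlap_bp` (default 1) overlap with any peak of B, with an
optional minimum fraction of the A-peak's length; the exact criterion
behind published common-site counts (minimum bp, reciprocal fraction,
summit distance) is generally unstated, so both knobs are exposed.
Dynamic-gene classification between two stages uses the 1 TPM on/off
threshold: on→off is "activated then silenced", off→on the reverse,
everything else static; the three sets partition the input exactly.

## Mitochondrial morphology (`pgcx.mitomorph`)

Surface areas are exposed-voxel-face counts: every face of a component
voxel bordering a different label, the background, or the array boundary
contributes its physical face area (a face normal to z has area dy·dx,
etc.). This is exact on the voxel grid, orientation-robust, and
hand-checkable — a 1 µm voxel scores 6 µm², a 2×1×1 bar 10 µm². It is
not a smooth-surface estimator: on digital spheres it converges to ~3/2
of 4πr² (the classic staircase bias), so absolute areas are not
comparable with mesh-based tools such as Imaris. Threshold-based
comparisons applied consistently across conditions are unaffected, which
is the mode of use here; the thresholds themselves (bins at 5/10/50 µm²,
clusters strictly above 500 µm², clustering degree as cluster-area
fraction) are the field's printed conventions. Labels are trusted as
given — each label is one object whether or not it is connected — and an
optional 26-connectivity relabeling is available when a mask arrives as
a single foreground label.

## Synthetic data (`pgcx.synthio`)

The generator produces every input with its ground truth:

* **Bulk dosage matrices.** Per-gene baselines are log-normal in TPM
  (default mean 2, sd 1 in log units — heavy-tailed like real TPM and
  trivially invertible), shared across genotypes at a fixed seed, so
  genotypes differ only through dosage multipliers: 1× on X for XY; 2×
  for escapees under intact XCI (a simple additive two-copy model); 2×
  chromosome-wide for eroded genotypes. XIST is a single dedicated
  X-linked gene, high (50 TPM) exactly when an inactive X exists.
  Escapees are an exact `round(fraction × n)` subset (default fraction
  0.15, within the known 15–25% range). Per-sample noise is
  multiplicative log-normal, default sd 0.1 in log-TPM — on the order of
  replicate variability of clonal hPSC lines in bulk RNA-seq. Defaults:
  22 autosomes × 100 genes, 80 X genes, 4 samples per line.
* **Lineage mixtures.** Cells are Dirichlet-weighted convex combinations
  of three reference profiles (disjoint 10-gene marker blocks at 100 TPM
  over a ~5 TPM baseline), with the same multiplicative noise model;
  true weights are returned.
* **Trajectory cells.** A half-circle arc in a 2-D latent space embedded
  linearly into gene space as a function of generative time u ~ U(0,1),
  with cells at u < 0.2 tagged as the root stage.
* **Motif sets.** Positives carry one instance sampled position-wise
  from the PWM at a uniform offset and strand inside background
  sequence; the study motif is a 9-mer with 0.97 dominant-base
  probabilities, comparable to a strong SOX-family JASPAR entry.
* **Mito masks.** Components are axis-aligned boxes (closed-form face
  areas) and digital spheres (area from an independent construction-time
  face count on the isolated occupancy mask), laid out disjointly;
  explicit placements that overlap raise an error.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: read-level artefacts (mapping, UMI
collapse), scRNA-seq dropout beyond log-normal noise, correlated gene
modules, batch effects, partial or heterogeneous XCI erosion (the 2×
multiplier is a clean modeling choice, configurable via
`escapee_multiplier`), irregular mitochondrial geometry, and real
conservation structure in motif flanks. The tests certify the
correctness and calibration of the machinery under the stated model, not
robustness to those artefacts.

## Problem sizes and determinism

The acceptance script and test suite run 100 simulation replicates for
the bootstrap machinery (1000 bootstrap replicates each), 100 cells
against the 0.001-step grid oracle, 300 cells for noisy weight recovery,
200 sequences against exhaustive scanning and 200 for affinity-label
recovery, 200 trajectory cells, and 100 synthetic mito cells — sizes at
which the checked statistics are stable across seeds while the whole
suite stays interactive. Every stochastic component takes an explicit
integer seed (`numpy.random.default_rng`; no global state); the pipeline
derives per-stage seeds from the run seed by hashing, and a rerun with
an identical configuration is byte-identical including the output
manifest (only the timestamped log differs and is excluded from
checksums).

## Known limitations

* The DE stand-in is not a count model; with few replicates its power
  differs from edgeR's, which is why external DEG tables are supported
  everywhere.
* Pseudotime handles a single lineage only, and like any principal-curve
  method can fold on strongly self-intersecting manifolds.
* Face-count areas are grid-biased (above); only within-method
  comparisons are meaningful.
* The affinity split substitutes an explicit log-odds threshold for
  conservation-based classification.
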