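# Methods

This note documents the models, parameter choices and numerical decisions
behind `neurotrace`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Synthetic data model

The generator emulates two assay classes with full ground truth.

**Plate-based neurons.** Five subpopulations (CG1, CG2 sympathetic; NEFM,
PEP, NPEP sensory) × 5 replicates (2 healthy, 3 tumour) × 40 cells by
default. Counts are negative-binomial with `var = mu + alpha·mu²` and a
declining mean–dispersion trend `alpha(m) = 0.05 + 2/m` (a constant
dispersion is configurable). A cell's expected count is
`base_mean · 2^(planted log2 effects) · depth/E[depth]`, so the expected
count of a planted gene equals its base mean times its planted fold change
exactly — the property the generator's analytic-mean tests rely on.
Per-gene base means are log-normal (log-mean 2.0, log-sd 1.2, i.e. median
≈ 7 counts); per-cell mapped reads are log-normal (median ≈ 500k, log-sd
0.4); mitochondrial read fractions are Beta(2, 38) (mean 5%).

Parameters that deserve justification:

- *Markers: 80 genes per subpopulation at log2fc 2 (4-fold), base means
  log-uniform on 20–200.* Real neuronal subtype programs span hundreds of
  well-expressed genes. Breadth matters beyond realism: the rank-based
  second annotator weighs all HVGs equally, so identity must be encoded in
  many genes for rank correlation to discriminate — exactly as in real
  atlases. With 25-gene programs the Pearson annotator is still perfect but
  the Spearman one falls to ~30% accuracy.
- *Planted differential genes draw base means log-uniform on 1,000–4,000.*
  The signature recipe explicitly restricts itself to robustly expressed
  genes (mean ≥ 500 in a population, pooled over conditions); planting a
  2-fold-squared down-shift on a base mean `b` leaves a pooled mean of
  ≈ 0.55·b, so recoverable planted genes need `b ≳ 900`. The planted
  program in the demonstration run is 30 genes down in the three sensory
  subpopulations, 20 up in two subpopulations spanning both super-types,
  and 10 up only in the two CG subpopulations (decoys the consensus rules
  must reject).
- *Low-quality cells: exactly `round(0.1·n)`, alternating between depth at
  50% of the 50,000-read floor and mitochondrial fraction at 1.5× the 20%
  cap*, so both QC rules are exercised. Non-planted cells are clamped
  safely inside every boundary (depth ≥ 1.3× floor, mito ≤ 0.9× cap, and
  base-mean parameters that keep detected genes ≈ 4,800–5,500 at the
  depth clamp): the generator's contract is that the planted set equals
  the QC-removed set exactly, which the exact-recovery checks require.

**Droplet-based microenvironment.** Six receiver types (PDAC cancer cells
— human, tumour condition only — plus epithelial, endothelial, immune and
two fibroblast populations, mouse). Genes are species-tagged (`mm:`/`hg:`,
mitochondrial genes `mt-` per species); mouse types draw 98% of expected
counts from mouse genes, cancer cells 90% from human genes, so majority
species assignment is exact. Expected totals follow a log-normal UMI depth
(median ≈ 8,000); mitochondrial counts are realised in the counts
themselves at the target fraction.

Cell-type identity is modelled as per-(type, gene) log-normal expression
jitter (log2-sd 0.5) drawn once per type and shared by conditions and
replicates. This is load-bearing for the interaction analysis: z-scoring
across receiver types rescales whatever between-type variation exists to
unit scale, so if types differed only by sampling noise the z-scores would
amplify noise and drown any planted signal. Condition-stable jitter gives
the z-scores a real, reproducible denominator, as genuine cell types do.
Planted ligand-receptor genes carry no jitter — their type-specificity is
exactly the planted effect. The demonstration setup plants a CAF ligand
program (21 ligands, 4-fold up in tumour CAFs) whose headline pair couples
a CAF ligand to the most highly expressed neuronal receptor, mirroring an
interleukin-like axis; pair genes are drawn from the upper half of the
gene universe, which carries no markers and no differential planting.

**What the synthetic data does not model.** Doublets, ambient RNA, batch
effects beyond replicate labels, read-level structure, dispersion
outliers, and correlated gene programs other than the planted ones.
Passing benchmarks therefore demonstrates correctness of the computations
under the stated model, not performance on real tissue; in particular the
near-perfect annotation accuracy and DE power reflect the planted effect
sizes, not an expectation for real data.

## Quality control and normalization

Boundary semantics are literal: "fewer than X" removes strictly below X (a
cell at exactly 50,000 reads or 1,000 UMIs is kept); "more than Y" removes
strictly above Y. "Detected" means count > 0. Plate QC reads depth and
mitochondrial content from cell metadata (mapped reads are an alignment
property); droplet QC computes both from the counts. Species assignment
uses a strict majority (> 50%) of counts; ties are `ambiguous` and
excluded downstream. Size factors are median-of-ratios over genes positive
in every cell (library-size fallback when no such gene exists), rescaled
to geometric mean 1; expression is `log2(count/factor + 1)`. Mitochondrial
genes are recognised by a case-insensitive `mt-` name prefix after the
species tag.

## Annotation

HVGs are the `n` (default 1,000) genes with the largest positive residual
of log-expression variance over a second-degree polynomial trend in the
mean, fitted by least squares on the standardized mean (raw means can be
nearly collinear with their square, making the fit unstable); ties break
lexicographically. Label transfer correlates each cell against type
centroids over the HVG∩query∩atlas intersection (≥ 3 genes required);
constant profiles are `unassignable`; correlation ties break by type label
and are flagged. The second annotator is identical but rank-based
(Spearman); concordance is the agreement rate over cells both annotators
could assign. Clustering: PCA (default 50 components) → self-inclusive
k-nearest-neighbour sets (default k = 10) → edges between cells with
intersecting sets, weight `|shared|/(2k − |shared|)` → Louvain modularity
maximization, node order shuffled once from the seed, labels ordered by
decreasing cluster size.

## Pseudobulk differential expression

Libraries are per-(replicate × condition), optionally per subpopulation;
the Wald path requires ≥ 2 libraries per condition and otherwise refuses
with a message naming the Wilcoxon fallback. Genes all-zero across
libraries are excluded before testing and before the BH correction (they
change the number of hypotheses m).

Dispersion estimation was the one genuinely open design point. The
per-gene method-of-moments estimate solves
`var(q) = mu·mean(1/s) + alpha·mu²` from the pooled within-condition
variance of normalized counts, but with 5 libraries it carries ~3 degrees
of freedom. The trend `alpha(mu) = a1 + a0/mu` is fitted by maximizing the
normal-theory chi-square likelihood of the within-condition variances —
binned medians underestimate the level (the median of a 3-df chi-square is
79% of its mean) and per-gene least squares is wrecked by low-mean
leverage, and both mis-estimate the asymptotic term `a1` that governs
high-count genes. The final dispersion is `w·trend + (1−w)·raw` with
default `w = 1` (pure trend): blending the 3-df raw estimate at equal
weight injects enough noise into the plug-in Wald statistic to push null
type-I error at alpha = 0.05 to 0.062–0.083, while the pure trend sits at
0.040–0.054 across seeds. Lower `w` only with many replicates or when
gene-specific dispersion outliers are a concern — a known limitation of
the pure-trend default, since the synthetic data has no such outliers.
The Wald z uses the expected-information standard error from the IRLS fit;
log2 fold changes are the natural-log coefficient divided by ln 2;
coefficients are clipped to ±30 on the natural-log scale for separation
cases (zero counts in one condition). Significance defaults to padj < 0.1.

The Wilcoxon fallback uses exact enumeration when both groups have ≤ 10
cells and the gene is tie-free, otherwise the tie-corrected normal
approximation; its fold change is the difference of group mean log2
expression.

## Signature construction

Per population and direction, genes are ranked by the signed Wald
statistic (the statistic blends fold change and precision; the ranking
metric is configurable in principle but fixed here), truncated to the top
500, then filtered by mean expression ≥ 500 and padj ≤ 0.2 — truncate,
then filter. "Mean expression" is the mean normalized count over the
population's cells with both conditions pooled; the scale and threshold
are parameters precisely because reasonable alternatives (per-condition
means, pseudobulk scale) exist. Consensus: down requires recurrence in
≥ 3 populations, up in ≥ 2; genes whose entire support is CG-derived are
removed; genes qualifying for both directions are dropped from both and
logged (disjointness keeps enrichment well-defined). The output is
invariant to population order.

## Enrichment

The ranking is by descending DE Wald statistic with lexicographic ties.
Hit increments are `|score|^p / sum_set |score|^p` (default p = 1, equal
weights if every member score is zero), miss decrements `1/(N − |S|)`; ES
is the signed maximum deviation of the running sum, with exact
positive/negative ties resolving positive under a 1e-9 tolerance so that
independent implementations agree deterministically. The null permutes
gene sets (random same-size sets from the ranking), not phenotypes — with
2–3 libraries per condition a phenotype permutation null is degenerate.
Permutation ES values are computed in closed form from sorted hit
positions (the running sum is piecewise linear with extremes adjacent to
hits), which is exactly equivalent to the running-sum definition and
vectorizes across permutations. `p = (1 + #{same-sign null at least as
extreme}) / (1 + #same-sign null)`; NES divides ES by the mean |same-sign
null ES|; q-values are BH across the tested sets.

## Interaction potentials

A ligand or receptor is expressed in a sender population when
`log10(aggregate counts + 1) > 2` (log base and threshold configurable;
the pseudocount makes zero aggregates well-defined). Cognate genes are the
table partners of neuron-expressed genes; cognates absent from the
receiver matrix are dropped and counted. Within each replicate, per-gene
receiver-type means of log expression are z-scored across the types
present in that replicate using the population (ddof = 0) standard
deviation; zero-variance genes contribute 0. A receiver's raw score is the
mean z over cognate genes; the potential subtracts the minimum raw score
over the sender's whole frame — every receiver type, replicate and
condition — so the frame minimum is exactly 0 and healthy and tumour
potentials share a scale. Potentials are frame-relative by construction:
removing a receiver type can move every other potential, which is asserted
as documented behaviour rather than assumed away.

Differential pair ranking scores each (pair, direction, receiver type) as
neuronal mean log expression of the neuron-side gene (per condition) times
the z-scored receiver-type mean of the cognate gene, and ranks by
|tumour − healthy|. Here the z-frames are restricted to receiver types
present in both conditions: a tumour-only type has no healthy score, and
leaving it in one frame would systematically reshape every other type's z
and make the deltas incomparable.

## Pipeline

Stages run as simulate/load → QC → normalize → annotate → DE (per assigned
subpopulation and whole-ganglion aggregate) → signature → enrichment →
interactome; any failure halts with the stage named. All tabular outputs
are TSV, the signature is GMT, the run report is JSON; one seed controls
the generators, Louvain and the permutation null, and two runs with the
same seed are byte-identical in every TSV/GMT output. Problem sizes in the
demonstration and verification runs (1,000 neurons × 6,000 genes, 1,120
stromal cells, 1,000 permutations, 2,000-gene DE calibrations) are chosen
so a full verification pass completes in about a minute on one CPU while
keeping Monte-Carlo tolerances tight.

## Known limitations

- The pure-trend dispersion default trades gene-specific dispersion
  variation for Wald calibration at n = 5; real data with dispersion
  outliers warrants `w < 1` (and inspection of the raw estimates).
- The correlation annotator uses type centroids, not per-cell references;
  rare or continuous identities are out of scope.
- Interaction potentials inherit every caveat of z-scored expression
  scoring: they are relative to the receiver-type frame, blind to absolute
  magnitude, and carry no significance calibration (the ranked deltas are
  descriptive, matching how such tables are reported).
- The literal published 45/46-gene signature lists derive from the
  deposited real datasets and are not reproducible from synthetic data;
  the benchmarks test the recipe, not the list.
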