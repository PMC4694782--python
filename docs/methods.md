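# Methods

`p53response` implements an integrated analysis of transcription-factor
ChIP-seq binding and genotype-dependent transcriptional response, modeled
on the biology of p53 activation by ionizing radiation (IR) in wild-type
(WT) versus *Trp53* knockout (KO) cells. This note describes the models,
the numerical choices, and what the synthetic-data experiments do and do
not demonstrate.

## The dimeric response-element model

The p53 response element (p53-RE) is two decameric half sites, each with
degenerate consensus `RRRCWWGYYY` (R = A/G, W = A/T, Y = C/T), adjacent
("unsplit") or separated by a 1–15 nt spacer. The scanner represents this
as an array of 16 position weight matrices: a 20-column dimeric PWM plus
15 variants in which `s` spacer columns between the half sites are fixed
to the background distribution, so spacer bases contribute zero bits to
the log-odds score. This is the natural construction for "uniformly
distributed nucleotides between the two halves" and means all 16 variants
share one score distribution.

Scoring is the standard log2 likelihood ratio against an i.i.d.
background (uniform by default; estimable from a supplied genome). `N`
bases score 0 (background-equivalent), so N-rich window edges can never
create hits.

### Exact match p-values

A match's significance is `P(score' >= score)` for a background-drawn
sequence of the variant's width, with no correction across positions —
per-match semantics, as in standard PWM scanners. The survival function is
built by dynamic programming: per-column score mass functions (four atoms
each) are convolved column by column.

* For matrices up to width 10 the convolution is carried out on the exact
  score atoms (the atom count is bounded by 4^w), so the p-value is exact
  to machine precision. This is also what the enumeration-oracle test
  compares against: the DP convolves per-column distributions, the oracle
  enumerates all 4^w sequences — two independent routes to the same
  distribution.
* For wider matrices (the 20–35-column spacer variants) the atoms are
  rounded to a lattice of bin width `granularity` (default 1e-3 bits).
  Because the sum of per-column roundings can differ from the rounding of
  the sum by up to width/2 bins, the lookup index is shifted down by that
  slack: every sequence whose exact score reaches the query is counted
  (ties at the query score are never dropped), at the cost of also
  counting probability mass within `width * granularity` bits below the
  query — about 0.035 bits for the widest variant, negligible at the
  scales where hits are called.

The p-value is monotonically non-increasing in the score and equals 1 at
or below the minimum achievable score.

### Window scanning and classification

Each peak contributes the 600 bases flanking its summit (summit ± 300;
"600 bases flanking the summit" is ambiguous between 600 total and 600
per side, and the total-600 reading is the default, configurable). All
positions, both strands and all 16 variants are scanned; candidates with
p < 1e-4 (the conventional scanner default; the threshold is a flag) are
kept and the lowest-p-value hit is reported. Ties break by smaller
spacer, then smaller offset, then + strand, making results deterministic.
Peaks are then classed `UNSPLIT` (best hit has spacer 0), `SPACED`
(spacer 1–15) or `NO_MOTIF`.

Note an inherent property of per-match p-values: a 600-bp window contains
~1,200 position×strand candidates, so motif-free windows produce a hit
with probability well above 1e-4 × 1,200 would naively suggest only if
candidates were independent; empirically ~30% of background-only windows
yield some hit at the 1e-4 threshold. The planted-truth experiments
therefore quantify recovery of planted unsplit/spaced sites (≥ 95% / ≥
90% measured) rather than the false-positive rate, which is a property of
the scanning semantics, not a defect of the implementation.

## Motif discovery (ZOOPS-EM)

De novo discovery uses the ZOOPS model: each sequence carries zero or one
motif occurrence (mixing weight gamma), uniformly positioned on either
strand, in an i.i.d. background estimated from the input base
composition. EM maximizes the Dirichlet-smoothed (pseudocount 0.5)
observed-data likelihood; since the M-step solves the penalized problem
exactly, the penalized objective is non-decreasing and is asserted at
every iteration (tolerance 1e-6 for floating-point noise). Convergence is
declared when the objective gains less than 1e-6.

Local optima are handled with two standard devices:

* deterministic restarts (default 10), each seeding the PWM from a random
  input subsequence smoothed with the pseudocount;
* phase-shift refinement after convergence: the motif window is proposed
  shifted by ±1 or ±2 columns (exposed columns filled with background)
  and a short EM probe is run; the shift is adopted only when it improves
  the objective, so the recorded trace stays monotone. This reliably
  repairs off-by-one registers, the dominant failure mode for tandem
  half-site motifs.

The restart with the highest final log-likelihood wins. No E-value
machinery is provided; the information content of the result (bits,
uniform-background convention) is reported instead. Background-only runs
at n = 300–500 sequences stay well below 6 bits, which is the working
"no signal" reference.

## Peak enrichment and the chromatin landscape

Peak enrichment is `log2(rpm(ChIP) - rpm(input))`, where rpm is reads per
million library reads. The subtraction is done on the rpm scale — the
only reading under which the statistic is well defined for typical
counts, and consistent with the adjacent definition of normalized read
counts. When ChIP does not exceed input the value is undefined (`None`)
and the peak is excluded from rankings; no epsilon floor is applied, so
rankings contain no artifacts.

Binding sites partition into three classes with strict precedence:

1. `PROMOTER` — overlapping a strand-aware −5 kb/+2 kb window around a
   TSS (on `-` genes the window is mirrored in genome coordinates);
2. `ENHANCER` — otherwise overlapping an H3K4me1 peak;
3. `UNMARKED_DISTAL` — everything else (candidate "proto-enhancers").

Overlap uses the whole peak interval with a ≥ 1 bp rule by default;
summit-only overlap is a flag. Both the minimum-overlap rule and the
summit question are not settled by the source analyses, so both are
exposed as options.

For peak-set comparisons, quintile overlap ranks peaks by enrichment
ascending, splits them into five bins whose sizes differ by at most one
(remainders to the lowest bins; ties broken by peak name), and reports
the fraction of each bin overlapping the other set, peak-wise (a peak
overlapping two target peaks counts once).

## Expression: RPKM, differential expression, dependence

RPKM uses exon-mapped reads as the library size:
`rpkm = counts * 1e9 / (exon_length * exon_mapped_total)`. A gene is
"expressed" when RPKM > 1 in at least one sample.

The differential-expression engine is an intentionally simple
negative-binomial Wald test, a documented stand-in for a full
shrinkage-based engine (externally computed tables with
`gene_id/log2fc/qvalue` can be imported instead):

* median-of-ratios size factors (reference = per-gene geometric mean);
* log2 fold change of normalized group means with pseudo-mean 0.5;
* gene-wise NB dispersion by method of moments, `(var - mean) / mean^2`,
  floored at 1e-8. Dispersion is a property of the gene, not of one
  contrast, so the estimate averages over every (genotype, treatment)
  replicate group available — with the standard 2×2 design and n
  replicates this quadruples the information behind the estimate relative
  to using the two contrasted arms alone;
* delta-method standard error of the log2 fold change, and a t reference
  with the residual degrees of freedom of the dispersion estimate
  (Σ(n_g − 1) over groups; 12 for a 2×2 design at n = 4). The t reference
  accounts for the estimated variance at small n; with these choices the
  measured null type-I error at p < 0.05 is ≈ 0.05 (10,000 null genes,
  dispersion 0.1, n = 4);
* Benjamini–Hochberg correction across genes passing a mean normalized
  count ≥ 1 filter (a simple independent-filtering floor).

DEGs are called with strict thresholds: q < 0.05, |log2FC| > 0.58
(≈ 1.5-fold), and RPKM > 1 in ≥ 1 sample. A WT DEG is p53-dependent when
its WT fold response exceeds the KO response by a factor of ≥ 1.5
(inclusive), on the linear fold scale; for repression the rule is
mirrored. Genes missing a KO estimate are treated as KO fold = 1 (no
measured response), which biases toward dependence; this is a documented
convention, flaggable, not an inference about upstream intent.

Sample-level structure is summarized by average-linkage hierarchical
clustering on 1 − Spearman rho over expressed genes (the linkage method
is a free choice; average linkage is the default). Gene-set enrichment is
the hypergeometric upper tail on sets restricted to the universe and
filtered to sizes strictly between 10 and 2,000.

## Integration and the core response

A gene is p53-bound when ≥ 1 peak overlaps its promoter window. With
several candidate peaks the gene inherits the single peak with the lowest
best-hit p-value (then highest enrichment, then name), so each bound gene
has exactly one motif category — keeping the mode × motif cross-tabs a
partition. The "core response" is the intersection, across two cell
populations, of genes that are dependently up-regulated and bound via an
unsplit-motif peak; the two per-set coverage fractions are reported with
the intersection.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of a `SimConfig` (a fixed seed gives
byte-identical files) and emit a toy genome (FASTA), peak calls
(narrowPeak + a count table), chromatin-mark BEDs, a gene table, NB count
matrices with sample metadata, and ground-truth tables.

Default study conditions: 500 peaks in classes (promoter, enhancer,
unmarked distal) = (0.4, 0.4, 0.2), matching the observation that
unmarked distal sites are the minority (~15–20%) with the rest split
between promoters and enhancers; motif rates per class of (unsplit,
spaced, none) = (0.30, 0.20, 0.50) at promoters and enhancers and (0.55,
0.20, 0.25) at unmarked sites, reflecting the strong consensus enrichment
of unmarked distal sites; spacers uniform on 1–15; mean ChIP signal 120 /
80 / 40 rpm for unsplit / spaced / motif-free sites over a 10 rpm input
(Poisson counts, 0.25 log2-units of lognormal site-to-site variation),
reproducing the observed enrichment ordering by motif class; genes ×
(WT, KO) × (mock, IR) × 4 replicates with NB dispersion 0.05; planted
effects (WT fold, KO fold) of (4, 1) for dependent induction, (3, 3) for
independent induction, mirrored reciprocals for repression; 70% null
genes. Planted sites are sampled from the bundled high-information
consensus PWM (invariant positions 0.97, two-fold degenerate positions
0.485 + 0.485) so scanner sensitivity is genuinely exercised; a
consensus-only switch plants exact degenerate-consensus sequences for
exact-recovery experiments. DE genes draw base expression from the
expressed range (log-normal around 200), since a response is only
observable on an expressed gene.

Geometry is deliberately clean: peak loci sit on a 12-kb grid so promoter
windows, enhancer marks and neighboring peaks cannot collide, and
unbound genes live on a separate decoy chromosome. Chromatin
classification on default output is therefore exact by construction —
that experiment validates the classification logic, not its robustness
to overlapping annotation, which real genomes do exhibit. Similarly not
modeled: read-level artifacts, fragment-length and GC bias,
peak-boundary uncertainty, correlated replicates, and isoform structure.
Passing the synthetic experiments demonstrates correctness of the
implemented rules and calibration of the test under the stated model; it
does not by itself demonstrate performance on real data.

Two cell types are simulated by running the generator twice with
partially shared truth: a configurable core gene set is dependent and
unsplit-bound in both, private gene sets in one each, enabling the
cross-cell-type intersection experiment (the planted 50-gene core is
recovered exactly under consensus-only planting).

## Problem sizes and determinism

The standing experiments use: 20 random PWMs (widths 4–8) against full
enumeration; 500 scanned windows; 500 simulated peaks; 10,000 null genes;
2,200 genes for the dependence experiment; 500 sequences for discovery;
and a 120-peak / 300-gene two-cell-type pipeline run, chosen so the whole
suite completes in a few minutes on one core. Every random draw flows
from a single seed; the pipeline writes a manifest with SHA-256 digests
of each output table and a manifest hash that is byte-identical across
reruns with the same seed and configuration.

## Known limitations

* The DE engine has no dispersion trend or outlier handling; it is meant
  for simulation-scale validation and as a fallback, not as a replacement
  for a mature DE package on real data.
* Per-match p-value semantics imply a substantial per-window false hit
  rate at the default threshold (see above); downstream analyses that
  need a controlled peak-level error rate should tighten the threshold.
* ZOOPS-EM discovers a single motif; multiple-motif discovery, OOPS/ANR
  models and E-value significance are out of scope.
* The gene-set step takes sets as given (no ontology propagation).
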