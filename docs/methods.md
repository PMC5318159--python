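# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `orfstruct`. Everything stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
external data.

## Coordinates and formats

Internal coordinates are 0-based half-open on the forward strand; position
0 of every per-ORF vector is the first nucleotide of the start codon in
transcript orientation, so minus-strand ORFs are reported reversed.
Intergenic spacing between adjacent ORFs is `start_B − end_A` in these
coordinates, making "overlapping" a sign test (spacing ≤ 0). On disk:
FASTA for replicons, GFF3 CDS features with an optional `operon` attribute
(1-based inclusive, converted on read), bedGraph per sample and strand
with a JSON library-size sidecar (tracks alone cannot reconstruct RPKM
denominators), and TSV for every report table.

## DMS signal model

Only A and C are DMS-reactive, so calls exist only at A/C positions.
Normalization is per scored region: values above the region's 95th
percentile are capped at that percentile (one-sided, matching how probing
outliers are usually tamed), then divided by the maximum. Quantiles use
linear interpolation between order statistics; the convention matters at
small n and is fixed here. The unpaired-call threshold is 0.2 of the
maximum; the ORF coverage filter is an inclusive ≥ 15 raw reads/nt. The
normalization span defaults to the scored region itself (ORF or window),
because structure scores are region-relative throughout; the span is a
parameter for sub-gene windows. Untreated-control tracks go through the
identical path — no control subtraction is applied.

## Gini index

Computed over the A/C positions of a region from raw (coverage-scaled)
counts: the index is invariant to positive rescaling, so normalized and raw
signal give identical values (asserted in tests). The Lorenz-area
definition with trapezoidal areas equals the pairwise
mean-absolute-difference formula exactly; both are implemented and cross-
checked to 1e−9. Conventions: all-zero or single-position input is
undefined (NaN, flagged); ORF halves split at floor(L/2) nucleotides (the
nucleotide split, not an A/C-count split, is an assumption); rolling
windows report at the window center and windows that would extend past the
region are dropped rather than shrunk, keeping n constant across positions.
The translation-dependent structure change is
(G_untranslated − G_translated) / mean(G).

## Footprint corrections and TE

mRNA RPKM: per-base counts over the ORF are 90% Winsorized (both tails),
summed, scaled by 1e9/(L × library size). Footprint density applies, in
fixed order: (1) first and last 5 codons masked; (2) ramp correction — a
dataset-wide mean relative density per codon position over the first 100
codons, normalized to a plateau of 1, divided out (the simplest functional
form consistent with a multiplicative early-elongation artifact); (3)
optional per-site anti-Shine-Dalgarno weights (off by default on synthetic
data — their construction needs an external model); (4) 90% Winsorization,
applied after masking (assumption). TE = density/RPKM for genes with ≥ 128
footprint reads, positive RPKM and no exclusion flag. The excluded-gene
list ships with the conventional selenoprotein and near-identical-paralog
names and is fully configurable. Center-weighting of raw footprint
intervals (1/N over residues ≥ 12 nt from either read end) is provided for
ingesting raw reads.

## Operon same-message calling

Both cutoffs are calibrated per dataset at 2σ: mean-level agreement against
the distribution of log2 first-half/second-half ratios within ORFs (σ on
log2 ratios — fold-space symmetry), and continuity against the distribution
of 80-nt window Ginis inside ORF bodies. The intergenic test tiles windows
whose centers span the gap at step 40 (half-overlap); a window with zero
total signal has no Gini and is treated as failing — a dead gap is exactly
the discontinuity the test exists to find. Overlapping pairs have no gap
and skip continuity. Only the intergenic region is tested, not ORF-proximal
margins (assumption). Genes whose whole-body mRNA Gini exceeds the cohort
mean + 2σ are flagged discontinuous and excluded from structure tables.

## Folding engines

The internal engine scores −1 per Watson–Crick or GU pair, minimum hairpin
loop 3 nt, no stacking. This model is the point: its MFE is checkable by
exhaustive enumeration and its McCaskill-style pair probabilities by
ensemble enumeration, to 1e−9, which the suite does on thousands of random
sequences. Co-optimal MFE ties are broken deterministically by preferring
the pair with the smallest opening index. The partition function uses
per-base scaling with automatic retry on overflow/underflow; probabilities
are scale-invariant. The Boltzmann weight per pair is exp(β) with β = 2 by
default — high enough that designed helices dominate the ensemble, low
enough that the two-state and β→0 limits remain testable. ViennaRNA (via
its Python bindings) is a drop-in engine for thermodynamic realism;
absolute energies are only meaningful there, and the boundary statistics
are engine-agnostic by API.

Boundary statistics fold −250..+250 nt around the downstream start codon of
each adjacent pair, constrained by unpaired calls from the DMS track over
that window (same 0.2 threshold). The directionality ratio at each position
is the pooled-across-pairs sum of pairing probability into the downstream
60 nt divided by the pooled sum into the upstream 60 nt. Pooling sums
before dividing (rather than averaging per-pair ratios) is a deliberate
choice: per-pair ratios are unstable wherever a pair's upstream sum
approaches zero, and the pooled form is the natural cross-mRNA estimator.
Offsets with zero pooled upstream mass are NaN-flagged.

## Synthetic data generator

The generator defines the study conditions for every recovery test.

* **Genome.** Operons of 2–4 ORFs (lengths 300–600 nt, multiples of 3),
  intergenic spacings 1 + Geometric(mean 20) so most pairs sit within
  ~25 nt, 15% of junctions overlapping with spacing −1 or −4, 30% of
  operons on the minus strand, 300-nt pads.
* **Structures.** Tiled hairpins with exact per-base ground truth. 5′ arms
  are drawn from {A, C}, 3′ arms are their reverse complements ({T, G}),
  and every other transcribed base is {A, C}. Hence: the paired fraction
  over A/C bases is exactly the 5′-arm content (solved analytically per
  ORF, realized within ±0.005 of target); noiseless reactivity plus the
  0.2 threshold reproduces the truth perfectly; {A, C} spacers cannot pair
  with each other, so after constraining called-unpaired bases the
  designed stems are essentially the only available helices. The first
  25 nt of each ORF stay unstructured (the start-proximal zone) and
  hairpins are anchored at the zone edge and the stop codon so the
  boundary geometry is coherent across ORFs. A boundary-violation flag
  adds one start-codon-crossing stem per operon for perturbation
  experiments. Default preferred stem is 6 bp, loop 4 nt; high paired
  fractions automatically use fewer, longer stems.
* **Counts.** Negative-binomial (Poisson–gamma) with dispersion 0.2 by
  default: variance = m(1 + 0.2 m). Rates: unpaired A/C = 1, paired A/C =
  0.1 (the reactivity leak of paired bases is a free parameter — it is not
  a measured quantity), G/U = 0.05 background. Per-ORF scaling delivers a
  target ORF-mean depth; a lognormal per-ORF depth multiplier with its own
  seed models expression spread and lets replicate pairs share abundances.
* **Expression.** ln TE = a − b·paired_fraction + N(0, σ) with defaults
  (0, 4, 0.3). mRNA coverage is uniform (plus NB noise) along each
  transcription unit including intergenic gaps; internal
  promoter/terminator breaks multiply the downstream unit's level by a
  log-uniform 2.5–8-fold factor (random direction) and leave the junction
  gap uncovered. Ribosome counts are proportional to mRNA level × TE with
  optional constant ramp multiplier over the first k codons and optional
  per-codon pause factors.

What the generator does **not** emulate: sequence-realistic thermodynamic
ensembles, RNase footprints and ligation biases, RNA-binding proteins,
degradation kinetics, or operon-level correlated noise. Passing recovery
tests therefore demonstrates the correctness and calibration of the
pipeline's statistical machinery under the stated noise model, not its
performance on any particular real library.

## Codon metrics

tAI uses the wobble-discounted supply W(codon) = Σ (1−s)·tGCN over decoding
anticodons, max-scaled, with zero-supply codons filled by the geometric mean
of nonzero weights; the gene score is the geometric mean over codons with
start and stop excluded, computed in log space. The default s-values are the
dos Reis-style set (G:U 0.41, I:C 0.28, I:A 0.9999, U:G 0.68); the wobble
bookkeeping indexes anticodons by the codon they read Watson–Crick, and the
bacterial lysidine special case for AUA is approximated by the generic
third-position-A rule. The bundled tGCN table is deterministic and
explicitly synthetic (non-biological); organism-specific work must supply a
measured table.

## Statistics

Spearman uses average ranks for ties (count data tie often). Bootstrap CIs
are case-resampling percentile intervals; the bootstrap core is vectorized
(rank-then-Pearson over a resample matrix) and verified against
scipy.stats.spearmanr row by row. Regression is on log TE, which spans
orders of magnitude; stepwise additions are scored by nested-model ANOVA
F-tests with the usual significance codes. The outlier test is the
externally studentized residual from the x–y regression with two-sided
p × n (Bonferroni), capped at 1 — the procedure behind "outlier test"
p-values in scatter comparisons. ROC positives are bases both unpaired and
solvent-accessible in the reference; negatives are paired bases;
unpaired-but-buried bases are excluded since a probe can legitimately miss
them; accuracy at a threshold is (TP + TN)/tested.

## Problem sizes and determinism

All generators and analyses are bit-reproducible under fixed seeds (master
seeds are split with `numpy.random.SeedSequence`). The shipped test suite
and the acceptance script run cohorts of ~200 ORFs / ~200 junctions at
30–50 reads/nt, 15 folded boundary windows of 500 nt, 1000-sequence folding
oracles, and 500-dataset bootstrap-coverage simulations — sizes chosen so a
complete desk-scale replication of every property finishes in about a
minute on one CPU while keeping every statistical check well-powered.

## Known limitations

* The internal energy model reproduces the *shapes* of structure statistics,
  not absolute folding energies; −ΔG/nt values in engine units are only
  comparable within an engine.
* The ramp correction assumes a multiplicative, dataset-wide profile; gene-
  specific elongation effects are absorbed by the Winsorization step.
* The same-message caller tests only level equivalence and gap continuity;
  convergent transcripts overlapping on the opposite strand are out of
  scope.
* Operon grouping is taken from the annotation (or the generator); the
  package does not re-derive transcription units from coverage alone.
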