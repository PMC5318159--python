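# orfstruct

**ORF-centric mRNA secondary structure and translation efficiency in
bacterial operons.**

Bacterial operons pack several open reading frames (ORFs) onto one
polycistronic mRNA, yet adjacent ORFs can be translated at rates differing
by two orders of magnitude. A strong predictor of an ORF's translation
efficiency is how much secondary structure its mRNA carries — and that
structure is organized in ORF-sized modules: each ORF folds onto itself,
with an unstructured zone at the translation start insulating it from its
neighbors. `orfstruct` is a tested, reusable pipeline for this style of
analysis, taking per-base chemical-probing (DMS-seq), mRNA-seq, and
ribosome-profiling count tracks to structure scores, translation
efficiencies, operon maps, and boundary-folding statistics. A first-class
synthetic-data generator makes every stage testable without any external
download.

## What it computes

* **Gini structure score.** DMS methylates unpaired A and C bases. For a
  region with per-base reactivities \(x_1..x_n\) over its A/C positions,
  the Gini index \(G = \sum_{i,j} |x_i - x_j| / (2 n^2 \bar x)\) — the
  normalized area between the Lorenz curve of the sorted signal and the
  diagonal — measures how unevenly reactivity is distributed. Uniform
  reactivity (unstructured RNA) gives \(G \approx 0\); signal concentrated
  on a few unprotected bases (structured RNA) gives high \(G\). Raw counts
  are normalized per region by one-sided 95% Winsorization and max-scaling;
  A/C bases with normalized reactivity > 0.2 are called unpaired; ORFs need
  ≥ 15 DMS reads/nt to be scored.
* **Translation efficiency.** TE = corrected average ribosome footprint
  density / mRNA RPKM, with the footprint corrections applied in a fixed
  order: first/last 5 codons masked, early-elongation ramp (first 50–100
  codons) divided out via a dataset-wide per-codon profile, optional
  anti-Shine-Dalgarno site weights, then 90% Winsorization; genes with
  < 128 footprint reads or on the unconventional-translation exclusion list
  carry QC flags instead of values.
* **Same-message operon pairs.** Adjacent ORFs are placed on one transcript
  when their mean mRNA levels agree within a 2σ cutoff calibrated from
  within-ORF half-vs-half variability, and every 80-nt window over the
  intergenic gap passes a 2σ continuity cutoff calibrated from within-ORF
  window Ginis.
* **Constraint-guided folding.** An internal exactly-testable energy model
  (−1 per Watson–Crick/GU pair, minimum loop 3) provides MFE structures and
  McCaskill-style base-pair probability matrices under hard unpaired
  constraints derived from DMS calls; ViennaRNA is available as a drop-in
  thermodynamic engine. Boundary statistics fold −250..+250 nt around each
  downstream start codon and report the per-position ratio of pairing
  probability into the downstream vs upstream 60 nt (folding
  directionality) and the metagene pairing profile.
* **Codon metrics and statistics.** tRNA adaptation index (geometric mean
  of wobble-discounted relative adaptiveness weights, start/stop excluded),
  Spearman correlations with case-resampling bootstrap CIs, two-sample K-S
  comparisons, ROC agreement against a reference structure, stepwise
  TE regression with nested-model ANOVA, and a Bonferroni-adjusted
  studentized-residual outlier test.

## Worked example

```python
from orfstruct import simulate as sim, dms, expression
from orfstruct.gini import ac_gini
from scipy.stats import spearmanr

bundle = sim.make_dataset(seed=1, n_operons=30, paired_fraction=(0.0, 0.8),
                          dms_depth=30.0, n_dms_replicates=1)
ann = bundle.annotation
table = expression.expression_table(bundle.tracks["ribo"],
                                    bundle.tracks["mrna"], ann)
ginis = [ac_gini(dms.orf_reactivity(bundle.tracks["dms"], ann, o))
         for o in ann.orfs]
table["gini"] = ginis
ok = table["te"].notna()
print(f"{ok.sum()} ORFs with TE")
print("Spearman(TE, Gini) = %.3f" % spearmanr(table.te[ok], table.gini[ok]).statistic)
```

prints

```
90 ORFs with TE
Spearman(TE, Gini) = -0.895
```

i.e. on a 90-ORF synthetic cohort whose latent log-TE declines with the
ground-truth paired fraction, the pipeline's TE estimates are strongly
anti-correlated with its Gini structure scores, recovering the generative
relationship almost exactly (the truth-level correlation of the latent TE
with the same Gini scores is −0.898).

The same analysis runs from the shell:

```bash
orfstruct all --seed 1 --outdir run1        # simulate + every stage
orfstruct operons --outdir run1             # re-run one stage on run1/data
```

producing TSV reports (`gini.tsv`, `expression.tsv`, `pairs.tsv`,
`directionality.tsv`, ...) stamped with the config hash, plus
`manifest.json` with the stage log.

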