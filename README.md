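# gbmkit

Expression preprocessing, cross-species GBM-subtype classification and
SNP-array copy-number calling for glioblastoma model studies — as a tested,
fully simulatable pipeline.

## The problem

Mouse models of glioblastoma (GBM) are routinely profiled with expression
bead arrays and SNP genotyping arrays, then compared against human tumor
cohorts. Four computational steps carry most of the weight, and `gbmkit`
implements each of them with synthetic data generators that plant a known
ground truth, so every stage can be validated end to end:

1. **Expression preprocessing and "rescue" classification.** Raw intensities
   are variance-stabilized with a generalized-log transform
   `glog(x; c) = log2((x + sqrt(x² + c²)) / 2)`, quantile-normalized across
   samples, and technical duplicates are averaged (with a Pearson-correlation
   QC report). Per-condition mean log2 fold changes against a reference
   (wild-type) condition feed a 1.5-fold selection
   (`|logFC| > log2 1.5`), and genes deregulated in one mutant are flagged as
   *rescued* when a second comparison falls back inside the fold band
   (`|logFC| ≤ log2 1.5`).
2. **Nearest-centroid subtype assignment with a simulation test.** A mouse
   fold-change profile is mapped through a gene-symbol map onto a human
   signature and compared to fixed per-subtype centroids (Proneural, Neural,
   Classical, Mesenchymal) by `d = 1 − ρ_Spearman` (Pearson and Euclidean
   selectable). A bootstrap null resamples the profile's values onto the
   signature positions B=1000 times — breaking the gene pairing, so the null
   describes "no association" — and the one-sided p-value is the add-one
   lower-tail probability `p = (1 + #{d_null ≤ d_obs}) / (B + 1)`.
   Assignment goes to the subtype minimizing the *relative* distance
   `d_obs / E[d_null]`.
3. **Copy-number calling from Log-R-Ratio (LRR) tracks.** Genomic waviness —
   long-range LRR oscillation tracking regional GC content — is removed by
   subtracting `c* · (GC − median GC)` with `c* = Cov(LRR, GC~)/Var(GC~)`,
   the unique variance-minimizing coefficient. The corrected signal is
   segmented by recursive binary splitting with a permutation test and an
   SD-undo merge pass, segment means are mapped to the five-state coding
   (0 homozygous loss, 1 hemizygous loss, 2 normal, 3 gain,
   4 amplification), and only non-normal segments strictly longer than 1 Mb
   are reported.
4. **Cohort z-score comparisons.** Per-gene expression z-scores
   (`z = (x − mean_ref)/sd_ref`) are compared between genotype or subtype
   groups with the two-sided Wilcoxon rank-sum test, and cross-platform
   agreement is checked with Spearman rank correlation.

## Worked example

Classify a noisy profile against a synthetic four-subtype centroid set:

```python
import numpy as np, pandas as pd
from gbmkit import simulate as sim
from gbmkit.subtype import CentroidSubtypeClassifier

centroids = sim.gen_centroids(n_genes=60, seed=1)
rng = np.random.default_rng(5)
profile = pd.Series(
    centroids["Proneural"].to_numpy()
    + rng.normal(0, 0.5 * centroids["Proneural"].std(), 60),
    index=centroids.index,
)
clf = CentroidSubtypeClassifier(B=1000, random_state=11).fit(centroids)
result = clf.classify(profile)
print(result.table.round(3)); print("assigned:", result.assigned)
```

```
             observed  expected  relative  p_value  significant
subtype
Classical       1.140     1.001     1.139    0.848        False
Mesenchymal     1.069     0.996     1.073    0.697        False
Neural          1.176     1.000     1.175    0.909        False
Proneural       0.106     0.995     0.106    0.001         True
assigned: Proneural
```

The profile sits far inside the lower 5% tail of the Proneural null
(observed Spearman distance 0.106 against an expected 0.995; add-one
p = 1/1001), while the three other subtypes are indistinguishable from
no association — exactly the pattern a planted Proneural signal should give.

The same analysis runs from the shell on simulated or user-supplied TSVs:

```bash
gbmkit all --out-dir run1 --seed 4          # simulate + every stage
gbmkit cnv --config my.yaml --out-dir run2  # one stage on your marker track
gbmkit validate --config my.yaml            # range-check a config
```

Each run directory gets the stage outputs, a `config.resolved.yaml` with all
defaults applied, and a `manifest.json` with input checksums, per-stage seeds
and headline results; identical config + seed gives byte-identical outputs.

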