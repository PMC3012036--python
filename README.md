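# gelimpute

Missing-value imputation, differential testing and multiple-testing
error control for two-dimensional gel electrophoresis (2-DE)
spot-volume matrices — together with the Monte-Carlo machinery to
decide *which* imputation method and *which* test to trust on data
like yours.

## The problem

A two-condition 2-DE study yields a spots × gels matrix of normalized
spot volumes in which 20–30% of cells are typically missing — spots
present on the reference gel that were not detected or matched on
other gels, more often for low-abundance proteins. Dropping incomplete
spots wastes most of the data; substituting zeros fabricates signal.
The alternative is a three-step analysis:

1. **Impute** the missing volumes: row average (RA), k-nearest
   neighbors (KNN), the least-squares family (spot-wise, gel-wise, EM
   with gel covariance, combined/adaptive mixtures), or NIPALS PCA.
2. **Test** each spot between conditions: Welch *t*, exact/Monte-Carlo
   permutation *t*, the distribution-free Chebyshev bound
   p = min(1, 1/t²), or one of three bootstrap tests obtained by
   inverting the normal / percentile / pivotal confidence interval of
   the mean difference.
3. **Control the error** across spots: per-comparison thresholding
   (p < α), the generalized family-wise error rate gFWER(k) by Holm +
   augmentation (P(more than k false positives) ≤ α), or
   Benjamini–Hochberg FDR as a comparator.

Because each choice changes the discovery list, the package also
implements the benchmarking protocol that arbitrates: mask known cells
at random (or preferentially in low-intensity spots), impute, and
score the normalized RMSE over the masked cells, the variance
shrinkage of the completed matrix, and the stability of the discovery
sets across masking replicates.

## Worked example

```python
import numpy as np
from gelimpute import (SyntheticConfig, generate_complete_dataset,
                       remove_at_random, get_imputer, normalized_rmse,
                       stattests, select_gfwer)

# a realistic two-group study: 70 spots, 6 gels per condition,
# 10 truly differential spots shifted 1.5 on the log scale
ds = generate_complete_dataset(SyntheticConfig(seed=7))
masked, record = remove_at_random(ds.matrix, 0.20, seed=7)
print("masked cells:", masked.n_missing)

for label in ("RowAve", "KNN(5)", "LSM.EM.A"):
    res = get_imputer(label)(masked)
    print(f"{label:10s} NRMSE = {normalized_rmse(record, res):.3f}")

completed = get_imputer("LSM.EM.A")(masked).matrix
table = stattests.test_matrix(completed, "t.welch")
rejected = select_gfwer(table["p_value"], alpha=0.05, k_allow=1)
hits = set(table.loc[rejected, "spot_id"])
print("selected spots:", len(hits), "| truly differential among them:",
      len(hits & ds.de_spots), "of", len(ds.de_spots))
```

prints

```
masked cells: 168
RowAve     NRMSE = 0.550
KNN(5)     NRMSE = 0.499
LSM.EM.A   NRMSE = 0.391
selected spots: 9 | truly differential among them: 9 of 10
```

Read it as: with 20% of the 840 cells masked, EM imputation with a gel
covariance structure reconstructs the hidden values with roughly 30%
less error than row averaging (NRMSE is RMSE over the masked cells
divided by the SD of the complete data); running Welch tests on the
completed matrix and controlling gFWER at k = 1 recovers 9 of the 10
planted differential spots with no false positive.

The same steps are available from the shell:

```sh
gelimpute simulate --seed 7 --fraction 0.2 --out data/
gelimpute pipeline --input data/matrix_masked.tsv --design data/design.tsv \
    --method LSM.EM.A --test t.welch --procedure gfwer --k-allow 1 --out run/
gelimpute benchmark --config bench.yaml --out bench/
```

Every run writes a `manifest.json` (seed, config hash, versions);
rerunning with the same seed reproduces the output files byte for
byte.

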