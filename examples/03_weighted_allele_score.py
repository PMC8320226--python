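"""Build the tenfold cross-validated weighted allele score.

Each fold's subjects are scored with per-SNP logistic coefficients
estimated on the other nine folds, then the score is the weight-sum-
normalised dosage combination (W1*SNP1 + ... + Wp*SNPp) / (W1+...+Wp).
"""

import numpy as np

import arhiscore as a

matrix, cohort = a.simulate_study(a.paper_like_spec(seed=7))
y = cohort.is_case.to_numpy()

folds, weights, scores = a.cross_validated_allele_score(matrix, y, k=10,
                                                        seed=20210728)
print("fold sizes:", folds.sizes())   # 861 -> nine folds of 86, one of 87
print("per-fold weight sums:", np.round(weights.weight_sums(), 3))
print("fold-1 weights:")
for snp, w in zip(weights.snp_ids, weights.weights[0]):
    print(f"  {snp:12s} W = {w:+.3f}")
print(f"score: mean {np.nanmean(scores.score):.3f}, "
      f"sd {np.nanstd(scores.score):.3f}")
print("-> positive weights mark risk alleles, negative ones protective;")
print("   each subject's own outcome never influenced their weights.")
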