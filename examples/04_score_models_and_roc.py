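"""Score association models and ROC-based prediction assessment.

Model 1: ARHI ~ score (unadjusted). Model 2: ARHI ~ score + covariates.
The prediction model (score + covariates) is assessed with an in-sample
ROC curve; its AUC equals the probability that a random ARHI case gets
a higher predicted risk than a random normal-hearing control.
"""

import arhiscore as a

matrix, cohort = a.simulate_study(a.paper_like_spec(seed=7))
_, _, scores = a.cross_validated_allele_score(
    matrix, cohort.is_case.to_numpy(), k=10, seed=20210728)

for spec in (a.MODEL1, a.MODEL2_ALL):
    eff = a.score_effect(scores, cohort, spec)
    print(f"{spec.name}: OR {eff.or_:.3f} "
          f"(95% CI {eff.ci_low:.3f}-{eff.ci_high:.3f}), p = {eff.p:.3g}")

fit, roc = a.prediction_model(scores, cohort)
print(f"prediction model terms: {fit.terms}")
print(f"AUC = {roc.auc:.3f} ({roc.n_cases} cases / {roc.n_controls} controls)")
print("-> OR is per unit score; AUC 0.5 = chance, 1.0 = perfect ranking.")
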