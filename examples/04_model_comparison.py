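"""Compare risk models: does an index add discrimination beyond baseline FBG?

Fits the classical-risk-factor model plus three contenders and compares
each against the reference (classical + baseline FBG) with the paired
DeLong test, IDI, categorical NRI and AIC/BIC deltas.
"""

import pandas as pd

from fbgrisk import (
    CLASSICAL_COVARIATES,
    GeneratorParams,
    ModelSpec,
    analysis_frame,
    apply_eligibility_filters,
    compare_models,
    compute_all_indices,
    compute_auc,
    fit_logistic,
    generate_cohort,
    impute_missing_covariates,
)

sc = generate_cohort(GeneratorParams(n_participants=5054, seed=11))
cohort, _ = apply_eligibility_filters(sc.cohort)
cohort, _ = impute_missing_covariates(cohort)
indices, _ = compute_all_indices(cohort.visits)
df = analysis_frame(cohort, indices)
y = pd.to_numeric(df["dr_status"]).to_numpy()

classical = tuple(CLASSICAL_COVARIATES)
specs = [
    ModelSpec(name="classical+fbg_baseline", terms=classical + ("fbg_baseline",)),
    ModelSpec(name="classical", terms=classical),
    ModelSpec(name="classical+m_fbg", terms=classical + ("m_fbg",)),
    ModelSpec(name="classical+cum_load", terms=classical + ("cum_load",)),
]
fits = [fit_logistic(df, s) for s in specs]
results = compare_models(fits, "classical+fbg_baseline", y)

ref_auc = compute_auc(fits[0].predicted_risks, y).auc
print(f"reference model AUC (classical + baseline FBG): {ref_auc:.4f}\n")
print(f"{'model':<24}{'AUC':>8}{'dAUC':>9}{'p':>8}{'IDI':>9}{'NRI':>9}{'dAIC':>9}")
for r in results:
    print(
        f"{r.comparator:<24}{r.auc_comparator.auc:>8.4f}"
        f"{r.delta_auc.delta_auc:>9.4f}{r.delta_auc.p_value:>8.3f}"
        f"{r.idi.idi:>9.4f}{r.nri.nri:>9.4f}{r.delta_aic:>9.1f}"
    )
# a positive dAUC/IDI/NRI with negative dAIC says the comparator improves
# on snapshot FBG; with load-driven outcomes, cum_load should win
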