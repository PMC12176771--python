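"""Train per-modality severity models and their equal-weight ensemble.

A multimodal cohort (glottal, acoustic, and clinical blocks, each reading the
latent severity through its own noisy channel) is split subject-disjointly
with all repeat visits in the test set.  One logistic model is trained per
modality; the ensemble averages their posterior probabilities.  The Spearman
correlation between the continuous severity score y_hat and the ordinal
hoarseness rating H should increase from the single-modality models to the
ensemble, and the paired pre/post visits probe predicted severity *change*.
"""

import numpy as np

import gawlab
from gawlab.cohort import split_train_test
from gawlab.evaluation import evaluate_predictions, make_pairs
from gawlab.modeling import ModelSpec, ensemble_predict, fit_final, predict_severity
from gawlab.synth import ACOUSTIC_COLUMNS

X_V = ["WTV_mean", "NNE_std", "HI", "GGI_std", "CQ_std"]
X_C = ["VRQOL", "Fmax", "Imax", "Jit_pct"]

cohort = gawlab.generate_cohort(
    gawlab.CohortSynthesisParams(n_subjects=400, revisit_fraction=0.1, seed=3)
)
v = cohort.visits
split = split_train_test(v, target_test_fraction=0.2, seed=3)
tr = v[v.visit_id.isin(split.train_ids)]
te = v[v.visit_id.isin(split.test_ids)]

spec = ModelSpec("logistic_regression", seed=3)
models = {
    "glottal (m_V)": fit_final(spec, tr[X_V], tr["label"].to_numpy()),
    "acoustic (m_A)": fit_final(spec, tr[ACOUSTIC_COLUMNS], tr["label"].to_numpy()),
    "clinical (m_C)": fit_final(spec, tr[X_C], tr["label"].to_numpy()),
}
h_te = te["H"].to_numpy()
from gawlab.evaluation import severity_correlation

for name, model in models.items():
    rho = severity_correlation(predict_severity(model, te).y_hat, h_te)
    print(f"{name:15s} Spearman rho(y_hat, H) = {rho:.3f}")

ens = ensemble_predict(list(models.values()), te)
report = evaluate_predictions(
    te["label"].to_numpy(), ens.y_hat, h_te,
    pairs=make_pairs(te, ens.y_hat), n_resamples=2000, seed=3,
)
print(f"{'ensemble (m_VAC)':15s} Spearman rho(y_hat, H) = {report.spearman_rho_yhat_h:.3f}")
print(f"test accuracy {report.accuracy:.3f} "
      f"(95% CI {report.ci['accuracy'][0]:.3f}-{report.ci['accuracy'][1]:.3f}), "
      f"AUC {report.auc:.3f}")
print(f"paired-change correlation rho(dy_hat, dH) = {report.spearman_rho_delta:.3f} "
      f"over {len(split.paired_test_ids)} pre/post pairs")
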