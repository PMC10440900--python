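"""The full classifier pipeline on the questionnaire-shaped synthetic cohort.

2165 subjects (976 cases / 1189 controls), 64 binary attributes in five
subdomain blocks.  Fits plain NB, NB-BLCA by EM and NB-BLCA by Gibbs on a
70% split, scores the held-out 30%, and prints the conventional validity
panel: accuracy with exact 95% CI, no-information rate, kappa, McNemar
against the NB baseline, sensitivity and specificity.  Because this cohort
is generated from a latent-block model, the latent-layer classifiers
should match or beat NB.
"""

import numpy as np

from nbblca.data_model import RunConfig, split_train_test
from nbblca.evaluation import full_report
from nbblca.fixtures import GCNUD_BLOCK_SIZES, make_gcnud_like
from nbblca.naive_bayes import nb_fit, nb_predict
from nbblca.nb_blca import LatentLayout, fit_em, fit_gibbs, information_criteria, predict

cohort = make_gcnud_like()
train, test = split_train_test(cohort, 0.7, np.random.default_rng(1))
layout = LatentLayout.from_sizes(list(GCNUD_BLOCK_SIZES), [2] * 5)

nb_labels = nb_predict(nb_fit(train), test.X)
em_model = fit_em(train, layout, run=RunConfig(seed=2, n_restarts=10))
gibbs_model, chain = fit_gibbs(
    train, layout, run=RunConfig(seed=3, gibbs_iters=1500, burn_in=500, thin=2)
)

for name, labels in [
    ("NB", nb_labels),
    ("NB-BLCA (EM)", predict(em_model, test.X)),
    ("NB-BLCA (Gibbs)", predict(gibbs_model, test.X)),
]:
    r = full_report(test.y, labels, baseline_pred=nb_labels, positive_label="GC")
    lo, hi = r["accuracy_ci"]
    print(
        f"{name:16s} acc {r['accuracy']:.2f} ({lo:.2f}-{hi:.2f})  NIR {r['nir']:.2f}"
        f"  kappa {r['kappa']:.2f}  McNemar p {r['mcnemar_p']:.3g}"
        f"  sens {r['sensitivity']:.2f}  spec {r['specificity']:.2f}"
    )

ic = information_criteria(gibbs_model, train, chain)
print("Gibbs model: BIC", round(ic["BIC"], 1), " DIC", round(ic["DIC"], 1))
# Higher accuracy than the ~55% NIR shows real signal; the latent-layer
# models gain a few points over NB because the cohort's dependence really
# is block-structured.
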