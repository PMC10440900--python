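"""Fit plain Naive Bayes on a tiny dataset and inspect the posterior.

Builds the four-row worked example (one attribute perfectly aligned with
the class), fits with and without Laplace smoothing, and prints the
posterior for x = 1.  Without smoothing the posterior is degenerate (the
negative class never showed x = 1); with smoothing it stays strictly
positive.
"""

import numpy as np

from nbblca.fixtures import make_toy
from nbblca.naive_bayes import nb_fit, nb_predict_proba

train = make_toy("nb4")
print("training rows (x, class):", [(int(x), str(c)) for x, c in zip(train.X[:, 0], train.y)])

for s in (0.0, 1.0):
    params = nb_fit(train, smoothing=s)
    post = nb_predict_proba(params, np.array([[1]]))[0]
    print(f"smoothing={s}: P(class | x=1) =",
          {c: round(float(p), 4) for c, p in zip(train.class_labels, post)})
# smoothing=0 gives (1.0, 0.0): the zero count forces certainty.
# smoothing=1 gives (0.75, 0.25): pseudo-counts keep every class possible.
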