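"""Train the logistic apnea classifier and screen a held-out subject.

Sixteen synthetic subjects (distinct seeds, random breath and heart
rates) provide labeled breath frames; the maximum-likelihood logistic
regression is fit on their six-feature vectors and applied to four
unseen subjects, reproducing the per-subject accuracy layout.
"""

import numpy as np

from bedapnea import evaluate, fit_mle
from bedapnea.experiments import labeled_feature_set
from bedapnea.features import FEATURE_NAMES

X_train, y_train, _ = labeled_feature_set(range(16))
model, report = fit_mle(X_train, y_train, feature_names=FEATURE_NAMES)
print(f"trained on {report.n_samples} frames in {report.iterations} Newton steps, "
      f"log-likelihood {report.loglik_trace[-1]:.2f}")
print("raw-scale weights:",
      {n: round(w, 3) for n, w in zip((*FEATURE_NAMES, "intercept"), model.raw_weights)})

X_test, y_test, groups = labeled_feature_set(range(100, 104))
result = evaluate(model, X_test, y_test, groups)
print("\nper-subject verification:")
print("subject  actual  identified  missed  accuracy")
for g, row in result["groups"].items():
    print(f"{g:>7}  {row['actual_apnea']:>6}  {row['identified_apnea']:>10}  "
          f"{row['missed']:>6}  {row['pct_accuracy']:.1f}%")
ov = result["overall"]
print(f"overall  {ov['actual_apnea']:>6}  {ov['identified_apnea']:>10}  "
      f"{ov['missed']:>6}  {ov['pct_accuracy']:.1f}%")
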