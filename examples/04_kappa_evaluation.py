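"""Cohen's kappa with the adjusted-Wald lower bound.

The decoder is judged significantly above chance when the lower confidence
bound of the cross-validated kappa is positive.
"""

import numpy as np

from gaitdecode.evaluate import classwise_accuracy, kappa

# A pooled confusion matrix of 160 trials at 72 % accuracy
cm = np.array([[58, 22],
               [23, 57]])
acc, sd = classwise_accuracy(cm)
r = kappa(cm)
print(f"accuracy: {acc:.1f} % +- {sd:.1f}")
print(f"kappa = {r.k:.3f}  (p = {r.p:.3f}, chance p0 = {r.p0:.3f})")
print(f"adjusted-Wald lower bound k_l = {r.k_lower:.3f} "
      f"-> {'significant' if r.significant else 'not significant'} at alpha=0.05")

# A borderline case, worked by hand: N = 16 trials, 12 correct, symmetric
# marginals. The bound lands just below zero — not significant.
cm_small = np.array([[6, 2], [2, 6]])
r2 = kappa(cm_small)
print(f"\nN=16, C=12: k = {r2.k:.2f}, k_hat = {r2.k_hat:.2f}, "
      f"k_l = {r2.k_lower:.5f} -> significant: {r2.significant}")
# Small samples are why the bound matters: the point estimate k = 0.5 looks
# convincing, but 16 trials cannot exclude chance at the 95 % level.
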