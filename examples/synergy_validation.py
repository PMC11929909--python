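"""Quantify a drug-pair interaction with the combination index and the
Bliss independence excess score."""

import numpy as np

import qpop
from qpop.dose_response import MedianEffectFit

# median-effect fits of two single agents and of their 1:4 constant-ratio
# combination (fitted on total dose); the combination needs less total
# drug than Loewe additivity predicts -> CI < 1
fit_a = MedianEffectFit(m=1.8, dm=2.0, r_squared=0.99, n_used=8)
fit_b = MedianEffectFit(m=2.2, dm=8.0, r_squared=0.99, n_used=8)
fit_ab = MedianEffectFit(m=2.0, dm=4.0, r_squared=0.99, n_used=8)

curve = qpop.combination_index(
    fit_a, fit_b, fit_ab, ratio=(1.0, 4.0), fa_grid=np.linspace(0.1, 0.9, 9)
)
print("fa    CI")
for fa, ci in zip(curve.fa, curve.ci):
    print(f"{fa:.2f}  {ci:.3f}")
print("CI < 1 indicates synergy, CI = 1 additivity, CI > 1 antagonism.\n")

# 5x5 Bliss matrix: survival under combination is 0.7x the product of
# monotherapy survivals (potentiation), so excess inhibition is positive
doses_a = [0.0, 0.5, 1.0, 2.0, 4.0]
doses_b = [0.0, 1.0, 2.0, 4.0, 8.0]
surv_a = np.array([1.0, 0.9, 0.78, 0.6, 0.42])
surv_b = np.array([1.0, 0.88, 0.74, 0.55, 0.38])
viability = surv_a[:, None] * surv_b[None, :]
viability[1:, 1:] *= 0.7

res = qpop.bliss_matrix(doses_a, doses_b, viability)
print(f"Bliss summary score = {res.score:.1f} -> {res.classification}")
print(
    "the score is the mean excess inhibition (percentage points) over the "
    "16 cells where both drugs are present; > 10 classifies as synergistic, "
    "< -10 as antagonistic."
)
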